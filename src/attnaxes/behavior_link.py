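"""Behavioral metrics and the projection-to-performance linkage.

Detection performance is summarized with the signal-detection index
``d' = Phi^-1(hit rate) - Phi^-1(false-alarm rate)`` (log-linear corrected
when a rate is 0 or 1).  The moment-to-moment linkage bins the attention-axis
projections preceding targets into quintiles per axis (5 x 5 = 25 cells),
computes the hit rate per cell normalized by the session's overall hit rate,
and tests the rank relationship between quintile index and hit rate across
sessions via Fisher-z-transformed Spearman correlations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BehavioralSummary",
    "BinnedPerformanceMap",
    "compute_dprime",
    "behavioral_summary",
    "bin_projections_quintiles",
    "marginal_performance",
    "rank_correlation_sessions",
]

log = logging.getLogger(__name__)
N_QUANTILES = 5
_CLIP = 1.0 - 1e-10   # perfect correlations are clipped before Fisher z


def compute_dprime(hits: int, misses: int, fa: int,
                   fa_opportunities: int) -> float:
    """Discriminability index with the log-linear correction.

    ``d' = Phi^-1(H) - Phi^-1(F)`` with ``H = hits/(hits+misses)`` and
    ``F = fa/fa_opportunities``.  When any rate is 0 or 1 the log-linear
    correction (add 0.5 to each cell, 1 to each denominator) is applied to
    both rates so d' stays finite.
    """
    for name, v in (("hits", hits), ("misses", misses), ("fa", fa),
                    ("fa_opportunities", fa_opportunities)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    n_t = hits + misses
    if n_t == 0:
        raise ValueError("no targets: hits + misses == 0")
    if fa_opportunities == 0:
        raise ValueError("fa_opportunities must be positive")
    H = hits / n_t
    F = fa / fa_opportunities
    if H in (0.0, 1.0) or F in (0.0, 1.0):
        H = (hits + 0.5) / (n_t + 1)
        F = (fa + 0.5) / (fa_opportunities + 1)
    return float(stats.norm.ppf(H) - stats.norm.ppf(F))


@dataclass
class BehavioralSummary:
    by_condition: pd.DataFrame   # delta_deg, validity, hits, misses, dprime
    mean_rt_ms: dict             # validity -> mean RT over hits
    fa_rate: float               # per completed non-target flash
    n_fa: int
    n_fa_opportunities: int


def behavioral_summary(flashes: pd.DataFrame) -> BehavioralSummary:
    """Session behavior: per |delta| x validity d', RT means, FA rate.

    Cue trials are excluded.  The false-alarm denominator counts all
    completed non-target flashes; the session FA rate enters every d' cell.
    """
    fl = flashes[~flashes["is_cue_trial"].astype(bool)]
    nontgt = fl[~fl["is_target"].astype(bool)]
    n_fa = int((nontgt["outcome"] == "false_alarm").sum())
    n_opp = len(nontgt)
    tgt = fl[fl["is_target"].astype(bool)].copy()
    tgt["validity"] = np.where(
        tgt["target_location"] == tgt["cue_location"], "valid", "invalid")
    tgt["delta_deg"] = tgt["delta_orientation"].abs()
    rows = []
    for (delta, validity), grp in tgt.groupby(["delta_deg", "validity"]):
        h = int((grp["outcome"] == "hit").sum())
        m = int((grp["outcome"] == "miss").sum())
        d = compute_dprime(h, m, n_fa, n_opp) if h + m else np.nan
        rows.append((delta, validity, h, m, d))
    by_cond = pd.DataFrame(rows, columns=["delta_deg", "validity",
                                          "hits", "misses", "dprime"])
    rt = {v: float(grp.loc[grp["outcome"] == "hit", "response_time_ms"].mean())
          for v, grp in tgt.groupby("validity")}
    return BehavioralSummary(by_cond, rt, n_fa / n_opp if n_opp else np.nan,
                             n_fa, n_opp)


@dataclass
class BinnedPerformanceMap:
    counts: np.ndarray           # (5, 5) trial counts, [pre_q, post_q]
    hit_rate: np.ndarray         # (5, 5); NaN where empty
    norm_hit_rate: np.ndarray    # hit_rate / overall hit rate
    overall_hit_rate: float
    n_targets: int
    target_side: str


def _quintile_bins(values: np.ndarray, n_bins: int = N_QUANTILES) -> np.ndarray:
    """Rank-based bins differing in size by <= 1; stable order breaks ties
    (first occurrence to the lower bin)."""
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0:
        raise ValueError("all projections identical; quintile binning impossible")
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=np.int64)
    ranks[order] = np.arange(len(values))
    return (ranks * n_bins) // len(values)


def bin_projections_quintiles(target_table: pd.DataFrame,
                              target_side: str = "RF") -> BinnedPerformanceMap:
    """5 x 5 normalized hit-rate map over (pre, post) projection quintiles.

    ``target_table`` is the per-target projection table of a session
    (:func:`attnaxes.attention_axes.target_projection_table`).  Quintile
    edges come from that session's target-preceding projections; each target
    is assigned a (pre, post) cell; cell hit rates are divided by the overall
    hit rate among the same targets.  Empty cells are NaN.
    """
    t = target_table[(target_table["target_location"] == target_side)
                     & target_table["outcome"].isin(["hit", "miss"])]
    t = t[np.isfinite(t["a_pre"]) & np.isfinite(t["a_post"])]
    n = len(t)
    if n < N_QUANTILES ** 2:
        warnings.warn(f"only {n} target-preceding intervals for a "
                      f"{N_QUANTILES}x{N_QUANTILES} map", stacklevel=2)
    if n == 0:
        raise ValueError("no target-preceding intervals with projections")
    qp = _quintile_bins(t["a_pre"].to_numpy())
    qo = _quintile_bins(t["a_post"].to_numpy())
    hit = (t["outcome"] == "hit").to_numpy()
    counts = np.zeros((N_QUANTILES, N_QUANTILES), dtype=np.int64)
    hits = np.zeros_like(counts)
    np.add.at(counts, (qp, qo), 1)
    np.add.at(hits, (qp, qo), hit.astype(np.int64))
    with np.errstate(invalid="ignore"):
        rate = np.where(counts > 0, hits / np.maximum(counts, 1), np.nan)
    overall = hit.mean()
    norm = rate / overall if overall > 0 else np.full_like(rate, np.nan)
    return BinnedPerformanceMap(counts, rate, norm, float(overall), n,
                                target_side)


def marginal_performance(pmap: BinnedPerformanceMap, axis: str) -> np.ndarray:
    """Marginal normalized hit rate along one axis: the unweighted mean of
    defined cells within each quintile of ``axis`` ('pre' or 'post'),
    averaging over the other axis to isolate this axis's contribution."""
    if axis not in ("pre", "post"):
        raise ValueError("axis must be 'pre' or 'post'")
    grid = pmap.norm_hit_rate
    out = np.full(N_QUANTILES, np.nan)
    for q in range(N_QUANTILES):
        cells = grid[q, :] if axis == "pre" else grid[:, q]
        finite = cells[np.isfinite(cells)]
        if len(finite):
            out[q] = finite.mean()
    return out


@dataclass
class RankCorrelationResult:
    axis: str
    per_session_rho: np.ndarray
    mean_rho: float              # back-transformed mean Fisher z
    t: float
    p: float
    n_sessions: int
    paired_t: float              # pre vs post z values
    paired_p: float


def _session_rho(pmap: BinnedPerformanceMap, axis: str,
                 variant: str) -> float:
    """Spearman rho between quintile index and hit rate for one session."""
    if variant == "cells25":
        grid = pmap.hit_rate
        idx = (np.repeat(np.arange(N_QUANTILES), N_QUANTILES)
               if axis == "pre" else np.tile(np.arange(N_QUANTILES),
                                             N_QUANTILES))
        vals = grid.ravel()
        ok = np.isfinite(vals)
        idx, vals = idx[ok], vals[ok]
    elif variant == "marginal5":
        vals = marginal_performance(pmap, axis)
        idx = np.arange(N_QUANTILES)
        ok = np.isfinite(vals)
        idx, vals = idx[ok], vals[ok]
    else:
        raise ValueError("variant must be 'cells25' or 'marginal5'")
    if len(vals) < 3 or np.ptp(vals) == 0:
        return np.nan
    return float(stats.spearmanr(idx, vals).statistic)


def rank_correlation_sessions(maps: list[BinnedPerformanceMap],
                              axis: str = "pre",
                              variant: str = "cells25",
                              alpha: float = 0.05) -> RankCorrelationResult:
    """Across-session test of the quintile-index/hit-rate rank correlation.

    Per session, Spearman's rho between the chosen axis's quintile index and
    the hit rate across the defined cells of the 25-cell map (``variant=
    'cells25'``; ``'marginal5'`` uses the 5 marginal bins instead -- both are
    exposed because the binning convention is a genuine analysis choice).
    The rho values are Fisher z-transformed (perfect correlations clipped),
    tested against zero with a one-sample two-tailed t-test, and compared
    between the two axes with a paired t-test.  The mean z is back-transformed
    to a correlation for reporting.  Sessions with undefined rho are excluded
    with a log message.
    """
    if axis not in ("pre", "post"):
        raise ValueError("axis must be 'pre' or 'post'")
    if len(maps) < 3:
        raise ValueError("need >= 3 sessions")
    rhos, z_this, z_other = [], [], []
    other = "post" if axis == "pre" else "pre"
    for k, pmap in enumerate(maps):
        r1 = _session_rho(pmap, axis, variant)
        r2 = _session_rho(pmap, other, variant)
        if not np.isfinite(r1) or not np.isfinite(r2):
            log.info("session %d: undefined rank correlation; excluded", k)
            continue
        rhos.append(r1)
        z_this.append(np.arctanh(np.clip(r1, -_CLIP, _CLIP)))
        z_other.append(np.arctanh(np.clip(r2, -_CLIP, _CLIP)))
    if len(rhos) < 3:
        raise ValueError("fewer than 3 sessions with defined correlations")
    z_this, z_other = np.asarray(z_this), np.asarray(z_other)

    try:
        from statsmodels.stats.diagnostic import lilliefors
        if np.std(z_this) > 0 and lilliefors(z_this)[1] < alpha:
            warnings.warn("Fisher-z correlations violate normality "
                          "(Lilliefors)", stacklevel=2)
    except Exception:
        pass

    if np.std(z_this, ddof=1) == 0:
        t1, p1 = np.nan, np.nan
    else:
        res = stats.ttest_1samp(z_this, 0.0)
        t1, p1 = float(res.statistic), float(res.pvalue)
    diff = z_this - z_other
    if np.std(diff, ddof=1) == 0:
        tp, pp = np.nan, np.nan
    else:
        res = stats.ttest_rel(z_this, z_other)
        tp, pp = float(res.statistic), float(res.pvalue)
    return RankCorrelationResult(axis, np.asarray(rhos),
                                 float(np.tanh(z_this.mean())), t1, p1,
                                 len(rhos), tp, pp)
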