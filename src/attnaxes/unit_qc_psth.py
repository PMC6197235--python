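"""Unit screening, normalized PSTHs, and the grand-average condition contrast.

Unit inclusion follows two criteria: recording *stability* (coefficient of
variation of the unit's firing rate across 10 equal-duration blocks of the
session must not exceed 1) and a minimum overall rate of 1 spike/s.  For the
grand-averaged PSTH, units additionally need a significant visual response
(some 50 ms window during the stimulus with a rate different from baseline).
PSTHs are smoothed with the causal half-Gaussian (sigma = 20 ms), baseline
subtracted and normalized per unit by the absolute value of its most extreme
average deviation from baseline over non-target flashes pooled across cue
conditions, so facilitated and suppressed units contribute on a common scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .session_model import (EPOCHS, SessionData, binned_spike_counts,
                            smooth_spike_train)

__all__ = [
    "UnitScreenReport",
    "NormalizedPsth",
    "GrandPsthComparison",
    "screen_units",
    "test_visual_responsiveness",
    "compute_normalized_psth",
    "session_mean_psth",
    "grand_average_comparison",
]

#: Sliding-window grid for the visual-responsiveness test: 50 ms windows
#: stepped by 10 ms across the 400 ms stimulus.
RESPONSIVENESS_WINDOW_MS = 50
RESPONSIVENESS_STEP_MS = 10

#: Search window (ms from flash onset) for the most extreme PSTH deviation.
EXTREME_SEARCH_MS = (0, 700)


@dataclass
class UnitScreenReport:
    unit_id: object
    blockwise_rates: np.ndarray   # 10 mean rates, spikes/s
    cv: float                     # sample SD / mean of blockwise rates
    mean_rate: float              # spikes/s over the whole session
    kept: bool
    reason: str                   # ok | unstable | low_rate


@dataclass
class NormalizedPsth:
    unit_id: object
    time_ms: np.ndarray                    # PSTH window, 1 ms grid
    traces: dict                           # condition -> normalized rate series
    divisor: float                         # spikes/s
    visually_responsive: bool


@dataclass
class GrandPsthComparison:
    time_ms: np.ndarray
    mean: dict          # condition -> across-session mean trace
    sem: dict
    t_values: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray      # boolean mask, paired t-test p < alpha
    earliest_significant_ms: float   # first significant ms; NaN if mask empty
    earliest_sustained_ms: float     # first run of >= 20 consecutive sig. ms
    n_sessions: int


def screen_units(session: SessionData) -> list[UnitScreenReport]:
    """Stability and minimum-rate screening for every unit.

    The session's total time span (concatenated trial durations) is divided
    into 10 equal-duration blocks; the CV of the unit's block rates uses the
    sample (n-1) standard deviation.  Kept iff CV <= 1 and the whole-session
    mean rate is >= 1 spike/s.
    """
    spans = session.trial_spans()
    durations = spans["duration_ms"].to_numpy(dtype=float)
    offsets = np.concatenate([[0.0], np.cumsum(durations)])
    total = offsets[-1]
    if total < 10:
        raise ValueError("session too short to divide into 10 blocks")
    trial_pos = {tr: offsets[i] for i, tr in enumerate(spans["trial_id"])}
    dur_by_trial = dict(zip(spans["trial_id"], durations))
    edges = np.linspace(0.0, total, 11)
    block_dur_s = (total / 10.0) / 1000.0

    index = session.spike_index()
    reports = []
    for u in session.units["unit_id"]:
        per_trial = index.get(u, {})
        if per_trial:
            gtimes = np.concatenate([
                t[t < dur_by_trial[tr]] + trial_pos[tr]
                for tr, t in per_trial.items()])
        else:
            gtimes = np.array([])
        counts, _ = np.histogram(gtimes, bins=edges)
        rates = counts / block_dur_s
        mean_rate = len(gtimes) / (total / 1000.0)
        mu = rates.mean()
        cv = float(rates.std(ddof=1) / mu) if mu > 0 else np.inf
        if mean_rate < 1.0:
            kept, reason = False, "low_rate"
        elif cv > 1.0:
            kept, reason = False, "unstable"
        else:
            kept, reason = True, "ok"
        reports.append(UnitScreenReport(u, rates, cv, mean_rate, kept, reason))
    return reports


def _nontarget_flash_rows(session: SessionData) -> pd.DataFrame:
    fl = session.flashes
    return fl[~fl["is_target"].astype(bool)]


def _window_starts() -> np.ndarray:
    return np.arange(0, 400 - RESPONSIVENESS_WINDOW_MS + 1,
                     RESPONSIVENESS_STEP_MS)


def _responsive_from_counts(win: np.ndarray, base: np.ndarray,
                            alpha: float) -> bool:
    """Shared decision rule: any window's paired t-test against the
    rate-matched baseline significant at alpha (degenerate windows skipped)."""
    if win.sum() == 0 and base.sum() == 0:
        return False
    for w in range(win.shape[0]):
        diff = win[w] - base
        if np.allclose(diff.std(ddof=1), 0.0):
            # a constant nonzero difference is certain, not degenerate
            if abs(diff.mean()) > 0:
                return True
            continue
        _, p = stats.ttest_rel(win[w], base)
        if p < alpha:
            return True
    return False


def test_visual_responsiveness(session: SessionData, unit,
                               alpha: float = 0.05) -> bool:
    """True iff some 50 ms stimulus window differs from baseline.

    Per non-target flash, spike counts in sliding 50 ms windows over
    [0, 400) ms are compared against the flash's baseline count ([-100, 0) ms
    rate-matched to 50 ms) with paired two-tailed t-tests, uncorrected.
    Degenerate windows (zero variance of the paired differences) are skipped;
    a unit with no spikes is not responsive.
    """
    fl = _nontarget_flash_rows(session)
    if len(fl) < 2:
        raise ValueError("need at least 2 non-target flashes")
    index = session.spike_index().get(unit, {})
    n = len(fl)
    base = np.zeros(n)
    starts = _window_starts()
    win = np.zeros((len(starts), n))
    onsets = fl["onset_ms"].to_numpy()
    trials = fl["trial_id"].to_numpy()
    for i in range(n):
        times = index.get(trials[i])
        if times is None or not len(times):
            continue
        rel = times - onsets[i]
        base[i] = np.count_nonzero((rel >= -100) & (rel < 0)) * 0.5
        win[:, i] = (np.searchsorted(rel, starts + RESPONSIVENESS_WINDOW_MS)
                     - np.searchsorted(rel, starts))
    return _responsive_from_counts(win, base, alpha)


def _flash_psth_matrix(session: SessionData, unit, flash_rows: pd.DataFrame):
    """Binned per-flash spike trains over the PSTH window (n_flashes x T)."""
    start, end = session.params.get("epochs", EPOCHS)["psth"]
    T = end - start
    out = np.zeros((len(flash_rows), T))
    index = session.spike_index().get(unit, {})
    for i, (_, row) in enumerate(flash_rows.iterrows()):
        t0 = int(row["onset_ms"])
        lo, hi = t0 + start, t0 + end
        if lo < 0:
            # first flash of a trial: the window dips before trial start;
            # missing time is treated as silent (permissive extension).
            times = index.get(row["trial_id"])
            if times is not None and len(times):
                sel = times[(times >= 0) & (times < hi)] - lo
                np.add.at(out[i], sel.astype(np.int64), 1)
        else:
            out[i] = binned_spike_counts(session, unit, row["trial_id"], lo, hi)
    return out, np.arange(start, end)


def compute_normalized_psth(session: SessionData, unit,
                            sigma_ms: float = 20.0) -> NormalizedPsth:
    """Smoothed, baseline-subtracted, extremum-normalized PSTH per condition.

    The normalization divisor is computed once from all non-target flashes
    pooled across cue conditions (the most extreme average deviation from the
    [-100, 0) ms baseline within [0, 700) ms); per-condition traces share it,
    so the normalized pooled trace has extremum magnitude exactly 1 and
    baseline mean 0.
    """
    fl = _nontarget_flash_rows(session)
    mat, time_ms = _flash_psth_matrix(session, unit, fl)
    pooled = smooth_spike_train(mat.mean(axis=0), sigma_ms)
    bmask = (time_ms >= -100) & (time_ms < 0)
    baseline = pooled[bmask].mean()
    smask = (time_ms >= EXTREME_SEARCH_MS[0]) & (time_ms < EXTREME_SEARCH_MS[1])
    divisor = float(np.abs(pooled[smask] - baseline).max())
    if divisor == 0:
        raise ValueError(f"unit {unit!r}: no deviation from baseline "
                         "(not visually responsive)")
    traces = {"pooled": (pooled - baseline) / divisor}
    for cond in ("RF", "away"):
        sel = (fl["cue_location"] == cond).to_numpy()
        if sel.any():
            tr = smooth_spike_train(mat[sel].mean(axis=0), sigma_ms)
            traces[cond] = (tr - baseline) / divisor
    return NormalizedPsth(unit, time_ms, traces, divisor, True)


def _all_unit_flash_data(session: SessionData):
    """Binned PSTH-window trains and responsiveness counts for all units.

    One pass over the spike table per trial; returns the non-target flash
    frame, mean binned trains per condition/pooled ``(n_units, T)``, and the
    per-flash window/baseline counts used by the responsiveness test.
    """
    fl = _nontarget_flash_rows(session)
    units = list(session.units["unit_id"])
    upos = {u: j for j, u in enumerate(units)}
    start, end = session.params.get("epochs", EPOCHS)["psth"]
    T = end - start
    starts = _window_starts()
    n, U, W = len(fl), len(units), len(starts)
    sums = {"RF": np.zeros((U, T)), "away": np.zeros((U, T)),
            "pooled": np.zeros((U, T))}
    nf = {"RF": 0, "away": 0, "pooled": 0}
    base = np.zeros((n, U))
    win = np.zeros((n, U, W))

    onsets = fl["onset_ms"].to_numpy()
    cues = fl["cue_location"].to_numpy()
    ftrial = fl["trial_id"].to_numpy()
    by_trial: dict = {}
    for i in range(n):
        by_trial.setdefault(ftrial[i], []).append(i)
    index = session.spike_index()
    for tr, idxs in by_trial.items():
        length = int(max(onsets[i] for i in idxs)) + end
        binned = np.zeros((U, length))
        for u, per_trial in index.items():
            times = per_trial.get(tr)
            if times is not None and len(times):
                sel = times[times < length]
                np.add.at(binned[upos[u]], sel.astype(np.int64), 1)
        cs = np.concatenate([np.zeros((U, 1)), np.cumsum(binned, axis=1)],
                            axis=1)
        for i in idxs:
            t0 = int(onsets[i])
            lo = t0 + start
            if lo < 0:
                seg = np.zeros((U, T))
                seg[:, -lo:] = binned[:, :t0 + end]
            else:
                seg = binned[:, lo:t0 + end]
            sums["pooled"] += seg
            nf["pooled"] += 1
            if cues[i] in sums:
                sums[cues[i]] += seg
                nf[cues[i]] += 1
            b_lo = max(t0 - 100, 0)  # guard short pre-flash segments
            scale = (RESPONSIVENESS_WINDOW_MS / (t0 - b_lo)) if t0 > b_lo else 0.0
            base[i] = (cs[:, t0] - cs[:, b_lo]) * scale
            win[i] = (cs[:, t0 + starts + RESPONSIVENESS_WINDOW_MS]
                      - cs[:, t0 + starts])
    means = {c: sums[c] / nf[c] if nf[c] else None for c in sums}
    time_ms = np.arange(start, end)
    return fl, units, time_ms, means, base, win


def session_mean_psth(session: SessionData, sigma_ms: float = 20.0,
                      alpha: float = 0.05):
    """Mean normalized PSTH per cue condition over kept, responsive units.

    Returns ``(time_ms, {condition: trace})`` or ``None`` if no unit passes
    screening and the responsiveness test.  Equivalent to combining
    :func:`test_visual_responsiveness` and :func:`compute_normalized_psth`
    per unit, but computed in one pass over the spike table.
    """
    kept = {r.unit_id for r in screen_units(session) if r.kept}
    fl, units, time_ms, means, base, win = _all_unit_flash_data(session)
    if means["RF"] is None or means["away"] is None:
        return None
    bmask = (time_ms >= -100) & (time_ms < 0)
    smask = (time_ms >= EXTREME_SEARCH_MS[0]) & (time_ms < EXTREME_SEARCH_MS[1])
    traces = {"RF": [], "away": []}
    for j, u in enumerate(units):
        if u not in kept:
            continue
        if not _responsive_from_counts(win[:, j, :].T, base[:, j], alpha):
            continue
        pooled = smooth_spike_train(means["pooled"][j], sigma_ms)
        baseline = pooled[bmask].mean()
        divisor = float(np.abs(pooled[smask] - baseline).max())
        if divisor == 0:
            continue
        for cond in ("RF", "away"):
            tr = smooth_spike_train(means[cond][j], sigma_ms)
            traces[cond].append((tr - baseline) / divisor)
    if not traces["RF"]:
        return None
    return time_ms, {c: np.mean(np.asarray(v), axis=0)
                     for c, v in traces.items()}


def grand_average_comparison(sessions: list[SessionData],
                             sigma_ms: float = 20.0,
                             alpha: float = 0.05) -> GrandPsthComparison:
    """Across-session paired comparison of condition PSTHs at each ms.

    Per session the normalized PSTHs of kept, visually responsive units are
    averaged per cue condition; the two conditions are compared with a
    per-millisecond paired (repeated-measures) t-test across sessions,
    uncorrected.  Normality of the paired differences is checked at a
    subsample of time points (Lilliefors composite test); a violation emits a
    warning, not an error.
    """
    if len(sessions) < 2:
        raise ValueError("need at least 2 sessions")
    per_session = []
    time_ms = None
    for s in sessions:
        res = session_mean_psth(s, sigma_ms, alpha)
        if res is not None:
            time_ms, tr = res
            per_session.append(tr)
    if len(per_session) < 2:
        raise ValueError("fewer than 2 sessions with analyzable units")
    rf = np.asarray([tr["RF"] for tr in per_session])
    aw = np.asarray([tr["away"] for tr in per_session])
    diff = rf - aw
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_rel(rf, aw, axis=0)
    p = np.where(np.isnan(p), 1.0, p)
    sig = p < alpha

    try:
        from statsmodels.stats.diagnostic import lilliefors
        probe = diff[:, ::50]
        pl = [lilliefors(probe[:, j])[1] for j in range(probe.shape[1])
              if np.std(probe[:, j]) > 0]
        if pl and min(pl) < alpha:
            warnings.warn("paired PSTH differences violate normality at some "
                          "time points (Lilliefors p < %.2f)" % alpha,
                          stacklevel=2)
    except Exception:  # diagnostic only; never fatal
        pass

    earliest = float(time_ms[sig][0]) if sig.any() else float("nan")
    # single uncorrected milliseconds flicker by chance; the sustained onset
    # (first run of >= 20 consecutive significant ms) is the robust latency
    sustained = float("nan")
    run = 0
    for i, flag in enumerate(sig):
        run = run + 1 if flag else 0
        if run >= 20:
            sustained = float(time_ms[i - run + 1])
            break
    sem = {"RF": rf.std(axis=0, ddof=1) / np.sqrt(len(rf)),
           "away": aw.std(axis=0, ddof=1) / np.sqrt(len(aw))}
    return GrandPsthComparison(time_ms, {"RF": rf.mean(axis=0),
                                         "away": aw.mean(axis=0)},
                               sem, t, p, sig, earliest, sustained,
                               len(per_session))
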