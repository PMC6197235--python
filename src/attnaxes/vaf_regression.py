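"""Two-step time-resolved regression of stimulus responses on attention state.

The population response to each eligible sample flash is reduced to a
one-dimensional time series by projecting smoothed population activity onto a
*stimulus-response axis* (baseline point to the point of maximal departure
from baseline).  At each millisecond the mean-centered response vector across
flashes, ``r_t``, is regressed first onto the post-stimulus attention-axis
projections measured during the *preceding* stimulus (scalar coefficient
``beta_t = <a, r_t>/<a, a>``; step-1 VAF), then the residual onto the
pre-stimulus projections from the interval immediately preceding the flash
(step-2 VAF of residual variance).  Significance versus the trial-shuffled
null (theoretical level ``1/(n-1)``) uses per-time one-sample t-tests across
sessions with a run-length multiple-comparisons correction calibrated by
autocorrelation-matched null simulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .session_model import EPOCHS, SessionData, smooth_spike_train

__all__ = [
    "StimulusResponseSeries",
    "VafSeries",
    "select_eligible_flashes",
    "response_windows",
    "fit_stimulus_response_axis",
    "compute_response_series",
    "two_step_vaf",
    "session_predictors",
    "compute_session_vaf",
    "shuffled_null_vaf",
    "runlength_threshold",
    "significance_mask",
    "max_run_length",
]

log = logging.getLogger(__name__)


@dataclass
class StimulusResponseSeries:
    time_ms: np.ndarray      # [-100, 600) at 1 ms
    r: np.ndarray            # (T, n) mean-centered per time point
    axis: np.ndarray         # unit-norm stimulus-response axis over units
    peak_time_ms: float      # time of maximal departure from baseline
    flash_rows: np.ndarray   # rows into the session flash table


@dataclass
class VafSeries:
    time_ms: np.ndarray
    beta_post: np.ndarray
    beta_pre: np.ndarray
    vaf_post: np.ndarray
    vaf_pre: np.ndarray
    n: int                   # number of observations (flashes)


def select_eligible_flashes(flashes: pd.DataFrame) -> np.ndarray:
    """Positional rows of flashes eligible for the regression.

    Eligible flashes are sample (non-target) stimuli outside cue trials whose
    immediate predecessor on the same trial exists and is also a sample
    stimulus: target responses are contaminated by the saccade, and the first
    flash of a trial follows the fixational eye movement.
    """
    is_tgt = flashes["is_target"].to_numpy().astype(bool)
    is_cue = flashes["is_cue_trial"].to_numpy().astype(bool)
    trial = flashes["trial_id"].to_numpy()
    fidx = flashes["flash_index"].to_numpy()
    prev_sample = {(t, f): not tg for t, f, tg in zip(trial, fidx, is_tgt)}
    keep = []
    for r in range(len(flashes)):
        if is_tgt[r] or is_cue[r] or fidx[r] < 2:
            continue
        if prev_sample.get((trial[r], fidx[r] - 1), False):
            keep.append(r)
    return np.asarray(keep, dtype=np.int64)


def response_windows(session: SessionData, rows: np.ndarray,
                     units: list | None = None,
                     sigma_ms: float = 20.0) -> np.ndarray:
    """Smoothed per-unit rates around each flash: (n_flashes, n_units, T).

    Each trial's spike trains are binned at 1 ms over the whole trial,
    smoothed causally once, and sliced to the response window, so windows of
    consecutive flashes share consistent filter state.
    """
    if units is None:
        units = list(session.units["unit_id"])
    start, end = session.params.get("epochs", EPOCHS)["response"]
    T = end - start
    fl = session.flashes
    out = np.zeros((len(rows), len(units), T), dtype=np.float32)
    index = session.spike_index()
    trial = fl["trial_id"].to_numpy()
    onset = fl["onset_ms"].to_numpy()
    by_trial: dict = {}
    for k, r in enumerate(rows):
        by_trial.setdefault(trial[r], []).append(k)
    for tr, ks in by_trial.items():
        length = int(max(onset[rows[k]] for k in ks)) + end
        binned = np.zeros((len(units), length))
        for j, u in enumerate(units):
            times = index.get(u, {}).get(tr)
            if times is not None and len(times):
                sel = times[times < length]
                np.add.at(binned[j], sel.astype(np.int64), 1)
        sm = smooth_spike_train(binned, sigma_ms)
        for k in ks:
            lo = int(onset[rows[k]]) + start
            out[k] = sm[:, lo:lo + T]
    return out


def fit_stimulus_response_axis(windows: np.ndarray, time_ms: np.ndarray):
    """Stimulus-response axis from trial-averaged smoothed activity.

    ``windows`` is (n_flashes, n_units, T).  The axis is the unit vector from
    the trial-averaged baseline point (mean over [-100, 0) ms) to the point
    on the trial-averaged trajectory furthest from baseline; also returns that
    peak time.
    """
    mean_traj = windows.mean(axis=0)                    # (n_units, T)
    bmask = (time_ms >= -100) & (time_ms < 0)
    b = mean_traj[:, bmask].mean(axis=1)
    dist = np.linalg.norm(mean_traj - b[:, None], axis=0)
    t_star = int(np.argmax(dist))
    d = mean_traj[:, t_star] - b
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("trajectory never leaves baseline; degenerate axis")
    return d / norm, float(time_ms[t_star])


def compute_response_series(session: SessionData, rows: np.ndarray,
                            units: list | None = None,
                            sigma_ms: float = 20.0) -> StimulusResponseSeries:
    """One-dimensional population stimulus response per eligible flash."""
    if len(rows) == 0:
        raise ValueError("no eligible flashes")
    start, end = session.params.get("epochs", EPOCHS)["response"]
    time_ms = np.arange(start, end)
    win = response_windows(session, rows, units, sigma_ms)
    axis, peak = fit_stimulus_response_axis(win, time_ms)
    proj = np.einsum("fut,u->tf", win, axis)            # (T, n)
    r = proj - proj.mean(axis=1, keepdims=True)
    return StimulusResponseSeries(time_ms, r, axis, peak, np.asarray(rows))


def _vaf_step(R: np.ndarray, a: np.ndarray):
    """Scalar least squares of each row of R onto a; returns (beta, vaf, resid).

    Closed form ``beta_t = <a, r_t> / <a, a>``; VAF is in [0, 1] per time
    point because the predictor is mean-centered like the response.
    """
    denom = float(a @ a)
    if denom == 0:
        raise ValueError("zero-variance predictor")
    beta = (R @ a) / denom
    resid = R - np.outer(beta, a)
    ss_tot = np.einsum("tf,tf->t", R, R)
    ss_res = np.einsum("tf,tf->t", resid, resid)
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
    return beta, np.clip(vaf, 0.0, 1.0), resid, ss_tot, ss_res


def two_step_vaf(series: StimulusResponseSeries, a_post: np.ndarray,
                 a_pre: np.ndarray) -> VafSeries:
    """Sequential regression of ``r_t`` on post- then pre-axis projections.

    Predictors are mean-centered before the no-intercept fits (the response
    is already centered per time point).  Step 1 regresses ``r_t`` on the
    post-axis projections; step 2 regresses the step-1 residual ``eta_t`` on
    the pre-axis projections, so the reported step-2 VAF is the proportion of
    *residual* variance accounted for.
    """
    a_post = np.asarray(a_post, dtype=float)
    a_pre = np.asarray(a_pre, dtype=float)
    n = series.r.shape[1]
    if len(a_post) != n or len(a_pre) != n:
        raise ValueError("projection vectors must match the number of flashes")
    a_post = a_post - a_post.mean()
    a_pre = a_pre - a_pre.mean()
    beta_post, vaf_post, resid, ss_r, ss_eta = _vaf_step(series.r, a_post)
    beta_pre, vaf_pre, _, _, _ = _vaf_step(resid, a_pre)
    # where step 1 explains the response to numerical precision the residual
    # is pure float noise; its "variance accounted for" is meaningless
    negligible = ss_eta <= 1e-12 * ss_r
    vaf_pre = np.where(negligible, 0.0, vaf_pre)
    beta_pre = np.where(negligible, 0.0, beta_pre)
    return VafSeries(series.time_ms, beta_post, beta_pre, vaf_post, vaf_pre, n)


def session_predictors(session: SessionData, records: pd.DataFrame):
    """Align attention-axis projections to eligible flashes.

    For an eligible flash the step-1 predictor is the post-axis projection of
    the *preceding* stimulus response and the step-2 predictor the pre-axis
    projection of the interval immediately preceding the flash.  Flashes with
    undefined predictors are dropped.  Returns ``(rows, a_post, a_pre)``.
    """
    fl = session.flashes
    rows = select_eligible_flashes(fl)
    rec = records.set_index("flash_row")
    row_of = {(t, f): r for r, (t, f) in enumerate(
        zip(fl["trial_id"], fl["flash_index"]))}
    a_post, a_pre, keep = [], [], []
    for r in rows:
        prev = row_of.get((fl["trial_id"].iloc[r], fl["flash_index"].iloc[r] - 1))
        po = rec["a_post"].get(prev, np.nan) if prev is not None else np.nan
        pr = rec["a_pre"].get(r, np.nan)
        if np.isfinite(po) and np.isfinite(pr):
            a_post.append(po)
            a_pre.append(pr)
            keep.append(r)
    return (np.asarray(keep, dtype=np.int64), np.asarray(a_post),
            np.asarray(a_pre))


def compute_session_vaf(session: SessionData, records: pd.DataFrame,
                        sigma_ms: float = 20.0) -> VafSeries:
    """End-to-end per-session VAF: eligibility, response series, two steps."""
    rows, a_post, a_pre = session_predictors(session, records)
    if len(rows) < 3:
        raise ValueError("fewer than 3 eligible flashes with projections")
    series = compute_response_series(session, rows, None, sigma_ms)
    return two_step_vaf(series, a_post, a_pre)


def shuffled_null_vaf(series: StimulusResponseSeries, a_post: np.ndarray,
                      a_pre: np.ndarray, n_shuffles: int = 100,
                      rng: np.random.Generator | None = None):
    """Chance VAF level from trial-shuffled projections.

    The flash order of the projection pair is permuted within session,
    breaking the projection-response pairing while preserving both marginals;
    both regression steps are recomputed and the resulting VAF is averaged
    over shuffles and time.  Returns ``(null_mean, 1/(n-1))`` -- the second
    element is the analytic expectation for independent Gaussian predictor
    and response.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n = series.r.shape[1]
    if n < 3:
        raise ValueError("need n >= 3 observations (n = 2 gives VAF = 1 "
                         "identically)")
    a_post = np.asarray(a_post, dtype=float)
    a_pre = np.asarray(a_pre, dtype=float)
    acc = 0.0
    for _ in range(n_shuffles):
        perm = rng.permutation(n)
        v = two_step_vaf(series, a_post[perm], a_pre[perm])
        acc += 0.5 * (v.vaf_post.mean() + v.vaf_pre.mean())
    return acc / n_shuffles, 1.0 / (n - 1)


def max_run_length(mask: np.ndarray) -> int:
    """Length of the longest run of True values in a 1-D boolean array."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return 0
    padded = np.concatenate([[0], m.astype(np.int8), [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return int((ends - starts).max())


def _ar_coefficients(series_matrix: np.ndarray, order: int) -> np.ndarray:
    """Average AR coefficients across sessions (Yule-Walker per session)."""
    import statsmodels.api as sm

    coefs = []
    for s in series_matrix:
        x = s - s.mean()
        if np.std(x) == 0:
            continue
        rho, _ = sm.regression.yule_walker(x, order=order, method="mle")
        coefs.append(rho)
    if not coefs:
        return np.zeros(order)
    return np.mean(np.asarray(coefs), axis=0)


def runlength_threshold(vaf_matrix: np.ndarray, alpha: float = 0.05,
                        ar_order: int = 1, n_sims: int = 1000,
                        rng: np.random.Generator | None = None,
                        familywise: float = 0.05) -> dict:
    """Minimum run length controlling the familywise rate of spurious runs.

    The average autocorrelation of the observed per-session VAF series
    (sessions x time) is summarized by an AR fit (default order 1); null
    Gaussian experiments with matched autocorrelation are simulated; each
    simulated experiment is scanned with the same per-time one-sided t-test
    across sessions used on the real data, and its maximum significant run
    recorded.  The threshold is the smallest run length exceeded in at most
    ``familywise`` (default 5%) of simulated experiments.  A non-stationary
    AR fit falls back to phase-randomized surrogates of the observed series.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    vaf_matrix = np.atleast_2d(np.asarray(vaf_matrix, dtype=float))
    S, T = vaf_matrix.shape
    if S < 2:
        raise ValueError("need >= 2 sessions")
    coefs = _ar_coefficients(vaf_matrix, ar_order)
    roots = np.roots(np.concatenate([[1.0], -coefs])) if ar_order else []
    stationary = all(abs(r) < 1 for r in roots)
    t_crit = stats.t.ppf(1 - alpha, df=S - 1)

    maxruns = np.zeros(n_sims, dtype=np.int64)
    chunk = max(1, min(n_sims, 200))
    done = 0
    while done < n_sims:
        k = min(chunk, n_sims - done)
        if stationary:
            sims = _simulate_ar(coefs, (k, S, T), rng)
        else:
            log.warning("non-stationary AR fit; using phase-randomized "
                        "surrogates")
            sims = _phase_randomize(vaf_matrix, k, rng)
        mean = sims.mean(axis=1)
        sd = sims.std(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            tval = mean / (sd / np.sqrt(S))
        sig = tval > t_crit
        for i in range(k):
            maxruns[done + i] = max_run_length(sig[i])
        done += k
    # smallest L with P(max run >= L) <= familywise
    L = 1
    while (maxruns >= L).mean() > familywise:
        L += 1
    return {"threshold": int(L), "ar_coefficients": coefs.tolist(),
            "stationary": bool(stationary), "n_sims": int(n_sims),
            "alpha": alpha, "familywise": familywise,
            "max_run_distribution": np.bincount(maxruns).tolist()}


def _simulate_ar(coefs: np.ndarray, shape: tuple,
                 rng: np.random.Generator) -> np.ndarray:
    k, S, T = shape
    order = len(coefs)
    burn = 10 * max(order, 1)
    x = rng.standard_normal((k, S, T + burn))
    if order:
        out = np.zeros_like(x)
        for t in range(T + burn):
            acc = x[..., t].copy()
            for j, c in enumerate(coefs, start=1):
                if t - j >= 0:
                    acc += c * out[..., t - j]
            out[..., t] = acc
        x = out
    return x[..., burn:]


def _phase_randomize(series_matrix: np.ndarray, k: int,
                     rng: np.random.Generator) -> np.ndarray:
    S, T = series_matrix.shape
    centered = series_matrix - series_matrix.mean(axis=1, keepdims=True)
    F = np.fft.rfft(centered, axis=1)
    out = np.empty((k, S, T))
    for i in range(k):
        phases = np.exp(2j * np.pi * rng.random(F.shape))
        phases[:, 0] = 1.0
        out[i] = np.fft.irfft(np.abs(F) * phases, n=T, axis=1)
        sd = out[i].std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        out[i] /= sd
    return out


def significance_mask(vaf_matrix: np.ndarray, null_level: float,
                      run_threshold: int, alpha: float = 0.05) -> dict:
    """Run-length-corrected significance of the VAF series versus chance.

    Per time point a one-sample t-test across sessions asks whether the mean
    VAF exceeds ``null_level``; runs of individually significant points
    shorter than ``run_threshold`` are erased.  Returns the corrected mask,
    the uncorrected p-values, and the peak time (argmax of the mean series).
    """
    if run_threshold < 1:
        raise ValueError("run_threshold must be >= 1")
    vaf_matrix = np.atleast_2d(np.asarray(vaf_matrix, dtype=float))
    S, T = vaf_matrix.shape
    mean = vaf_matrix.mean(axis=0)
    sd = vaf_matrix.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tval = (mean - null_level) / (sd / np.sqrt(S))
    p = stats.t.sf(tval, df=S - 1)
    p = np.where(np.isfinite(p), p, 1.0)
    sig = p < alpha
    mask = sig.copy()
    padded = np.concatenate([[0], sig.astype(np.int8), [0]])
    d = np.diff(padded)
    for st, en in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
        if en - st < run_threshold:
            mask[st:en] = False
    return {"mask": mask, "p_values": p, "mean": mean,
            "peak_index": int(np.argmax(mean))}
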