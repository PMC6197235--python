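"""Cross-validated attention axes with pre/post orthogonalization.

An *attention axis* is the unit vector along the line connecting the
trial-averaged population activity of the two cue conditions in firing-rate
space.  Two axes are fit per session:

* the **post-stimulus axis** from spike counts 200-400 ms after the onset of
  the sample flash immediately preceding each validly cued, correctly
  detected target, and
* the **pre-stimulus axis** from counts in the 200 ms immediately preceding
  each such target, *orthogonalized* (Gram-Schmidt) against the fixed
  post-stimulus axis so it can only capture anticipatory population patterns
  linearly independent of the stimulus-response modulation.

Cross-validation: each fold trains both axes on a random half of the
training-eligible targets per cue condition and projects everything else.
Projections are affinely normalized per fold and axis so the fold's training
cue-in-RF mean maps to +1 and the cue-away mean to -1; a given interval's
final projection is the average over the folds in which it was held out.
Held-out averages are *not* constrained to +/-1 -- how far they regress
toward 0 measures how reliable the axis is.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .session_model import SessionData, extract_epoch_counts

__all__ = [
    "AttentionAxisModel",
    "DegenerateAxisError",
    "fit_attention_axis",
    "orthogonalize_pre_axis",
    "cross_validated_projections",
    "target_projection_table",
    "compare_hit_miss_projections",
]

log = logging.getLogger(__name__)

#: Raw pre-axis within this angle of the post axis is considered degenerate.
MIN_ANGLE_DEG = 1.0
ORTHO_TOL = 1e-10


class DegenerateAxisError(ValueError):
    """Condition means coincide, or the pre axis is parallel to the post axis."""


@dataclass
class AttentionAxisModel:
    """Fitted axes plus per-fold bookkeeping.

    ``w_post``/``w_pre`` are the axes fit on *all* training-eligible targets
    (useful as the session's representative directions); the per-fold axes
    used for projection are summarized by their normalization parameters
    (offset ``c``, half-range ``s`` mapping training means to +/-1) and
    training-target row sets.
    """

    unit_ids: list
    w_post: np.ndarray
    w_pre: np.ndarray
    fold_norms: pd.DataFrame          # per fold: c_post, s_post, c_pre, s_pre
    fold_train_rows: list             # per fold: flash-table row ids of training targets
    train_means_norm: pd.DataFrame    # per fold: normalized training means per axis/condition
    epochs: tuple = ("pre", "post")
    n_degenerate_folds: int = 0


def fit_attention_axis(counts_in: np.ndarray,
                       counts_away: np.ndarray) -> np.ndarray:
    """Difference-of-means axis, unit norm, cue-in-RF side positive.

    ``counts_in`` / ``counts_away`` are (n_flashes, n_units) count matrices
    for the two cue conditions.
    """
    counts_in = np.atleast_2d(np.asarray(counts_in, dtype=float))
    counts_away = np.atleast_2d(np.asarray(counts_away, dtype=float))
    if counts_in.shape[0] == 0 or counts_away.shape[0] == 0:
        raise ValueError("both condition groups must be nonempty")
    d = counts_in.mean(axis=0) - counts_away.mean(axis=0)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise DegenerateAxisError("condition means are identical")
    return d / norm


def orthogonalize_pre_axis(pre_raw: np.ndarray, w_post: np.ndarray,
                           min_angle_deg: float = MIN_ANGLE_DEG) -> np.ndarray:
    """Component of the raw pre-stimulus vector orthogonal to the post axis.

    Gram-Schmidt step: ``normalize(pre_raw - <pre_raw, w_post> w_post)``.
    Raises :class:`DegenerateAxisError` when ``pre_raw`` lies within
    ``min_angle_deg`` of (anti-)parallel to ``w_post``, where the residual
    direction is numerically meaningless.
    """
    pre_raw = np.asarray(pre_raw, dtype=float)
    w_post = np.asarray(w_post, dtype=float)
    norm_raw = np.linalg.norm(pre_raw)
    if norm_raw == 0:
        raise DegenerateAxisError("raw pre-stimulus vector is zero")
    resid = pre_raw - np.dot(pre_raw, w_post) * w_post
    # second pass sweeps out float residue so <w_pre, w_post> ~ 1e-17
    resid -= np.dot(resid, w_post) * w_post
    norm_resid = np.linalg.norm(resid)
    if norm_resid < norm_raw * np.sin(np.deg2rad(min_angle_deg)):
        raise DegenerateAxisError(
            "raw pre-stimulus vector within %.2f deg of the post axis"
            % min_angle_deg)
    return resid / norm_resid


def _training_targets(session: SessionData) -> pd.DataFrame:
    """Training-eligible targets: validly cued hits outside cue trials, with a
    preceding sample flash on the same trial."""
    fl = session.flashes
    tgt = fl[fl["is_target"].astype(bool) & ~fl["is_cue_trial"].astype(bool)
             & (fl["outcome"] == "hit")
             & (fl["target_location"] == fl["cue_location"])
             & (fl["flash_index"] > 1)]
    return tgt


def cross_validated_projections(session: SessionData, n_folds: int = 1000,
                                rng: np.random.Generator | None = None,
                                min_eligible: int = 2):
    """Fit attention axes with repeated random half-splits; project everything.

    Returns ``(model, records)`` where ``records`` has one row per non-cue
    flash: ``flash_row`` (positional row in the flash table), ``a_pre`` (its
    own pre-stimulus interval projected on the orthogonalized pre axis),
    ``a_post`` (its own 200-400 ms response projected on the post axis; NaN
    for target flashes, whose responses are excluded from analysis),
    held-out fold counts, and ``role``.

    Folds whose axes are degenerate (identical condition means, or a raw pre
    vector within 1 degree of the post axis) are resampled with a logged
    warning; resampling is capped at ``3 * n_folds`` attempts.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    fl = session.flashes
    noncue = lambda f: ~f["is_cue_trial"].astype(bool)
    pre = extract_epoch_counts(session, "pre", flash_filter=noncue)
    post = extract_epoch_counts(session, "post", flash_filter=noncue)
    pre_pos = {r: i for i, r in enumerate(pre.flash_rows)}
    post_pos = {r: i for i, r in enumerate(post.flash_rows)}
    PRE = pre.counts.astype(float)
    POST = post.counts.astype(float)

    tgt = _training_targets(session)
    # map each training target to its pre row and its predecessor's post row
    row_of = {(t, f): r for r, (t, f) in enumerate(
        zip(fl["trial_id"], fl["flash_index"]))}
    elig = []
    for r, row in tgt.iterrows():
        rr = row_of[(row["trial_id"], row["flash_index"])]
        prev = row_of.get((row["trial_id"], row["flash_index"] - 1))
        if rr in pre_pos and prev is not None and prev in post_pos:
            elig.append((rr, prev, row["cue_location"]))
    elig = pd.DataFrame(elig, columns=["target_row", "prev_row", "cue"])
    n_in = int((elig["cue"] == "RF").sum())
    n_away = int((elig["cue"] == "away").sum())
    if n_in < min_eligible or n_away < min_eligible:
        raise ValueError(
            f"need >= {min_eligible} training-eligible targets per condition "
            f"(have RF={n_in}, away={n_away})")
    idx_in = elig.index[elig["cue"] == "RF"].to_numpy()
    idx_away = elig.index[elig["cue"] == "away"].to_numpy()
    pre_idx = elig["target_row"].map(pre_pos).to_numpy()
    post_idx = elig["prev_row"].map(post_pos).to_numpy()

    sum_pre = np.zeros(len(PRE))
    cnt_pre = np.zeros(len(PRE), dtype=np.int64)
    sum_post = np.zeros(len(POST))
    cnt_post = np.zeros(len(POST), dtype=np.int64)

    norms, train_rows, train_means = [], [], []
    n_degenerate = 0
    attempts = 0
    completed = 0
    max_attempts = 3 * n_folds
    while completed < n_folds and attempts < max_attempts:
        attempts += 1
        tr_in = rng.choice(idx_in, size=max(1, n_in // 2), replace=False)
        tr_away = rng.choice(idx_away, size=max(1, n_away // 2), replace=False)
        train = np.concatenate([tr_in, tr_away])
        try:
            w_post = fit_attention_axis(POST[post_idx[tr_in]],
                                        POST[post_idx[tr_away]])
            pre_raw = (PRE[pre_idx[tr_in]].mean(axis=0)
                       - PRE[pre_idx[tr_away]].mean(axis=0))
            w_pre = orthogonalize_pre_axis(pre_raw, w_post)
        except DegenerateAxisError as exc:
            n_degenerate += 1
            log.warning("degenerate fold resampled: %s", exc)
            continue
        p_post = POST @ w_post
        p_pre = PRE @ w_pre
        mi, ma = p_post[post_idx[tr_in]].mean(), p_post[post_idx[tr_away]].mean()
        c_post, s_post = (mi + ma) / 2.0, (mi - ma) / 2.0
        mi, ma = p_pre[pre_idx[tr_in]].mean(), p_pre[pre_idx[tr_away]].mean()
        if mi < ma:       # orient the pre axis so cue-in-RF projects higher
            w_pre = -w_pre
            p_pre = -p_pre
            mi, ma = -mi, -ma
        c_pre, s_pre = (mi + ma) / 2.0, (mi - ma) / 2.0
        if s_post <= 0 or s_pre <= 0:
            n_degenerate += 1
            log.warning("degenerate fold resampled: zero projection half-range")
            continue
        assert abs(np.dot(w_pre, w_post)) < ORTHO_TOL

        z_post = (p_post - c_post) / s_post
        z_pre = (p_pre - c_pre) / s_pre
        train_means.append((
            z_post[post_idx[tr_in]].mean(), z_post[post_idx[tr_away]].mean(),
            z_pre[pre_idx[tr_in]].mean(), z_pre[pre_idx[tr_away]].mean()))

        held_pre = np.ones(len(PRE), dtype=bool)
        held_pre[pre_idx[train]] = False
        held_post = np.ones(len(POST), dtype=bool)
        held_post[post_idx[train]] = False
        sum_pre[held_pre] += z_pre[held_pre]
        cnt_pre[held_pre] += 1
        sum_post[held_post] += z_post[held_post]
        cnt_post[held_post] += 1

        norms.append((c_post, s_post, c_pre, s_pre))
        train_rows.append(elig["target_row"].to_numpy()[train])
        completed += 1
    if completed < n_folds:
        warnings.warn(
            f"only {completed}/{n_folds} folds completed after "
            f"{max_attempts} attempts ({n_degenerate} degenerate)",
            stacklevel=2)
    if completed == 0:
        raise DegenerateAxisError("no non-degenerate folds")

    # representative axes on all eligible targets
    w_post_all = fit_attention_axis(POST[post_idx[idx_in]],
                                    POST[post_idx[idx_away]])
    pre_raw_all = (PRE[pre_idx[idx_in]].mean(axis=0)
                   - PRE[pre_idx[idx_away]].mean(axis=0))
    w_pre_all = orthogonalize_pre_axis(pre_raw_all, w_post_all)

    model = AttentionAxisModel(
        unit_ids=list(pre.unit_ids),
        w_post=w_post_all, w_pre=w_pre_all,
        fold_norms=pd.DataFrame(norms, columns=["c_post", "s_post",
                                                "c_pre", "s_pre"]),
        fold_train_rows=train_rows,
        train_means_norm=pd.DataFrame(
            train_means, columns=["post_in", "post_away", "pre_in", "pre_away"]),
        n_degenerate_folds=n_degenerate)

    eligible_target_rows = set(elig["target_row"])
    rows = []
    with np.errstate(invalid="ignore"):
        a_pre = np.divide(sum_pre, cnt_pre, out=np.full(len(PRE), np.nan),
                          where=cnt_pre > 0)
    a_post_map = dict(zip(post.flash_rows,
                          np.divide(sum_post, cnt_post,
                                    out=np.full(len(POST), np.nan),
                                    where=cnt_post > 0)))
    cnt_post_map = dict(zip(post.flash_rows, cnt_post))
    for i, r in enumerate(pre.flash_rows):
        rows.append((r, fl["trial_id"].iloc[r], fl["flash_index"].iloc[r],
                     a_pre[i], a_post_map.get(r, np.nan),
                     int(cnt_pre[i]), int(cnt_post_map.get(r, 0)),
                     "training-eligible" if r in eligible_target_rows
                     else "always-held-out"))
    records = pd.DataFrame(rows, columns=[
        "flash_row", "trial_id", "flash_index", "a_pre", "a_post",
        "n_folds_held_out_pre", "n_folds_held_out_post", "role"])
    return model, records


def target_projection_table(session: SessionData, records: pd.DataFrame,
                            target_side: str | None = None) -> pd.DataFrame:
    """Per-target interval projections, aligned for behavioral analysis.

    For every non-cue-trial target: ``a_pre`` is the projection of the 200 ms
    immediately preceding the target, ``a_post`` the projection of the
    sustained response to the *preceding* sample flash.  Optionally filtered
    by target side.
    """
    fl = session.flashes
    rec = records.set_index("flash_row")
    tgt = fl[fl["is_target"].astype(bool) & ~fl["is_cue_trial"].astype(bool)]
    if target_side is not None:
        tgt = tgt[tgt["target_location"] == target_side]
    row_of = {(t, f): r for r, (t, f) in enumerate(
        zip(fl["trial_id"], fl["flash_index"]))}
    out = []
    for r, row in tgt.iterrows():
        rr = row_of[(row["trial_id"], row["flash_index"])]
        prev = row_of.get((row["trial_id"], row["flash_index"] - 1))
        a_pre = rec["a_pre"].get(rr, np.nan)
        a_post = rec["a_post"].get(prev, np.nan) if prev is not None else np.nan
        out.append((rr, row["trial_id"], row["flash_index"],
                    row["target_location"], row["cue_location"],
                    row["delta_orientation"], row["outcome"], a_pre, a_post))
    return pd.DataFrame(out, columns=[
        "flash_row", "trial_id", "flash_index", "target_location",
        "cue_location", "delta_orientation", "outcome", "a_pre", "a_post"])


@dataclass
class HitMissComparison:
    target_side: str
    per_session: pd.DataFrame   # session, axis, hit_mean, miss_mean
    t_pre: float
    p_pre: float
    t_post: float
    p_post: float
    n_sessions: int
    excluded_sessions: list = field(default_factory=list)


def compare_hit_miss_projections(session_tables: list[pd.DataFrame],
                                 target_side: str = "RF") -> HitMissComparison:
    """Across-session paired test of projections preceding hits vs misses.

    ``session_tables`` are outputs of :func:`target_projection_table`, one per
    session.  Per session the mean ``a_pre`` and ``a_post`` preceding hit and
    missed targets of ``target_side`` are compared; across sessions a paired
    one-tailed t-test asks whether hits are shifted toward +1 for RF targets
    (toward -1 for away targets).  Sessions lacking hits or misses of the
    requested side -- or with degenerate (zero-variance) paired differences --
    are excluded and reported.
    """
    alt = "greater" if target_side == "RF" else "less"
    rows, excluded = [], []
    for k, tab in enumerate(session_tables):
        t = tab[tab["target_location"] == target_side]
        hits = t[t["outcome"] == "hit"]
        misses = t[t["outcome"] == "miss"]
        if not len(hits) or not len(misses):
            excluded.append(k)
            log.info("session %d: no %s-target hits or misses; excluded",
                     k, target_side)
            continue
        rows.append((k,
                     hits["a_pre"].mean(), misses["a_pre"].mean(),
                     hits["a_post"].mean(), misses["a_post"].mean()))
    per = pd.DataFrame(rows, columns=["session", "pre_hit", "pre_miss",
                                      "post_hit", "post_miss"])
    if len(per) < 2:
        raise ValueError("need >= 2 sessions with both hits and misses")

    def paired(h, m):
        diff = h.to_numpy() - m.to_numpy()
        if np.allclose(diff.std(ddof=1), 0):
            return np.nan, np.nan
        res = stats.ttest_rel(h, m, alternative=alt)
        return float(res.statistic), float(res.pvalue)

    t_pre, p_pre = paired(per["pre_hit"], per["pre_miss"])
    t_post, p_post = paired(per["post_hit"], per["post_miss"])
    return HitMissComparison(target_side, per, t_pre, p_pre, t_post, p_post,
                             len(per), excluded)
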