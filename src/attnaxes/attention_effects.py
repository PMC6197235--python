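"""Per-unit attention effects and their joint pre/post classification.

The relative attention effect of a unit in an epoch is
``([cue in RF] - [cue away]) / [cue away]`` computed on raw per-flash epoch
spike counts, with significance from a two-sided Mann-Whitney (rank-sum) test
on the same counts.  The joint classification counts units significant in
both the pre- and post-stimulus epochs by the sign quadrant of their effects;
the *flip fraction* is the share of doubly significant units whose effect
changes sign between epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .session_model import SessionData, extract_epoch_counts

__all__ = [
    "UnitAttentionEffect",
    "relative_attention_effect",
    "compute_unit_effects",
    "classify_joint_effects",
    "correlate_effects_across_epochs",
]

ALPHA = 0.05


@dataclass
class UnitAttentionEffect:
    unit_id: object
    epoch: str                # "pre" | "post"
    effect: float             # relative rate change; NaN if undefined
    p_value: float
    significant: bool


def relative_attention_effect(counts_in, counts_away):
    """Relative attention effect and rank-sum p-value for one unit/epoch.

    Returns ``(effect, p)`` with ``effect = (mean_in - mean_away)/mean_away``
    (NaN when the cue-away mean is zero; the rank-sum test still applies) and
    ``p`` the two-sided Mann-Whitney U p-value on the raw per-flash counts,
    which is invariant under strictly monotone transforms of the counts.
    """
    x = np.asarray(counts_in, dtype=float)
    y = np.asarray(counts_away, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    mean_away = y.mean()
    effect = (x.mean() - mean_away) / mean_away if mean_away > 0 else np.nan
    if np.ptp(np.concatenate([x, y])) == 0:
        p = 1.0  # all counts tied: no evidence either way
    else:
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    return effect, p


def compute_unit_effects(session: SessionData, epochs=("pre", "post"),
                         alpha: float = ALPHA) -> pd.DataFrame:
    """Attention effects for every unit in the given epochs.

    Counts come from bilateral non-target sample flashes (cue trials carry a
    unilateral stimulus and are excluded), split by the trial's cue side.
    Returns a tidy frame: unit_id, epoch, effect, p_value, significant,
    n_in, n_away.
    """
    rows = []
    for epoch in epochs:
        ecm = extract_epoch_counts(
            session, epoch,
            flash_filter=lambda f: ((f["stimulus_locations"] == "bilateral")
                                    & ~f["is_target"].astype(bool)))
        cue = session.flashes["cue_location"].to_numpy()[ecm.flash_rows]
        sel_in, sel_away = cue == "RF", cue == "away"
        if not sel_in.any() or not sel_away.any():
            raise ValueError(f"epoch {epoch}: need flashes in both cue conditions")
        for j, u in enumerate(ecm.unit_ids):
            eff, p = relative_attention_effect(ecm.counts[sel_in, j],
                                               ecm.counts[sel_away, j])
            rows.append((u, epoch, eff, p, bool(p < alpha),
                         int(sel_in.sum()), int(sel_away.sum())))
    return pd.DataFrame(rows, columns=["unit_id", "epoch", "effect", "p_value",
                                       "significant", "n_in", "n_away"])


def classify_joint_effects(pre: pd.DataFrame, post: pd.DataFrame):
    """Quadrant counts and sign-flip fraction for doubly significant units.

    ``pre`` and ``post`` are frames with columns (unit_id, effect, p_value,
    significant) for matched unit sets.  Quadrants are keyed
    ``(sign_pre, sign_post)`` with signs '+'/'-'.  The flip fraction is
    computed among units significant in both epochs with defined effects;
    NaN if there are none.
    """
    pre = pre.set_index("unit_id")
    post = post.set_index("unit_id")
    if set(pre.index) != set(post.index):
        raise ValueError("pre and post unit sets differ")
    post = post.loc[pre.index]
    both = (pre["significant"].to_numpy() & post["significant"].to_numpy()
            & np.isfinite(pre["effect"].to_numpy())
            & np.isfinite(post["effect"].to_numpy()))
    sp = np.sign(pre["effect"].to_numpy()[both])
    so = np.sign(post["effect"].to_numpy()[both])
    quadrants = {(a, b): int(np.sum((sp == (1 if a == "+" else -1))
                                    & (so == (1 if b == "+" else -1))))
                 for a in "+-" for b in "+-"}
    n_both = int(both.sum())
    flips = int(np.sum(sp != so))
    return {"quadrants": quadrants, "n_both_significant": n_both,
            "n_flips": flips,
            "flip_fraction": flips / n_both if n_both else np.nan}


def correlate_effects_across_epochs(pre_effects, post_effects):
    """Pearson correlation between per-unit pre and post attention effects.

    Pairs with non-finite effects are dropped; requires >= 3 finite pairs and
    nonzero variance in both vectors.  Returns ``(r, p)``.
    """
    x = np.asarray(pre_effects, dtype=float)
    y = np.asarray(post_effects, dtype=float)
    if x.shape != y.shape:
        raise ValueError("effect vectors must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 paired finite effects")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in an effect vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
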