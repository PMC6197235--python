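"""Synthetic change-detection sessions with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage can be exercised and validated without recordings:

* **Task**: block-cued two-location change detection.  Within a block one
  hemifield is cued; blocks begin with unilateral *cue trials* until the
  subject scores ``cue_trial_hits`` hits, then stimuli are bilateral until the
  block reaches ``hits_per_block`` hits, at which point the cue side switches.
  Every flash after the first in a trial is a target with fixed probability
  (a uniform hazard), targets occur at the cued side with probability
  ``p_valid``, and a trial ends at its target or at a false alarm.

* **Latent attention state**: each trial carries a scalar state ``a_k``
  following an AR(1) process around a cue-side-dependent mean (+1 cue-in-RF,
  -1 cue-away); ``s_k = tanh(a_k)`` maps it into [-1, +1].  A second AR(1)
  *readiness* component ``q_k`` (zero mean, cue-independent) models
  trial-to-trial anticipatory fluctuations within a cue condition.

* **Spiking**: unit ``i`` fires as an inhomogeneous Poisson process around
  ``lambda_i * template(t)`` where the template is 1 between stimuli and a
  transient-plus-sustained profile during each RF stimulus.  Attention acts
  multiplicatively: during the sustained stimulus response the factor is
  ``1 + (g_i - 1) * s_k`` (a per-unit gain ``g_i``, mean ~1.09); between
  stimuli it is ``1 + m_i * (s_k + q_k)`` with a near-zero-mean, mixed-sign
  per-unit pattern ``m_i`` correlated with ``g_i - 1``; the same ``m``
  pattern also modulates the onset transient (scaled by
  ``transient_pre_coupling``), so the anticipatory state carries into the
  earliest stimulus response.

* **Behavior**: hit probability is logistic in the attention state signed
  toward the target side, the readiness state, and log target-change
  magnitude; false alarms occur per non-target flash with a small
  state-dependent probability; hit response times are shifted log-normal with
  an attention-dependent median.

``generate_gain_only_session`` forces ``m_i`` proportional to ``g_i - 1``
(a stimulation-invariant gain), the negative-control model under which the
orthogonalized pre-stimulus axis should carry no signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .session_model import STIMULUS_MS, SessionData

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_task_sequence",
    "generate_session",
    "generate_gain_only_session",
    "simulate_coupled_pair",
    "write_ground_truth",
]


@dataclass
class GeneratorConfig:
    """All tunable parameters of the synthetic session generator.

    Task constants default to the study conditions they emulate: a 30% (or
    40%) per-flash target hazard, 90% cue validity, cue-side switches after
    80 hits with 5 initial cue-trial hits, 400 ms flashes and 300-500 ms
    fixation/inter-stimulus intervals.
    """

    # --- population -------------------------------------------------------
    n_units: int = 40
    baseline_rate_log_mean: float = math.log(5.0)   # log spikes/s
    baseline_rate_log_sd: float = 0.7

    # --- task structure ---------------------------------------------------
    n_blocks: int = 2
    hits_per_block: int = 80          # includes cue-trial hits
    cue_trial_hits: int = 5
    p_target_per_flash: float = 0.3   # uniform hazard (0.3 monkey P, 0.4 monkey W)
    p_valid: float = 0.9
    fixation_ms: tuple = (300, 500)
    isi_ms: tuple = (300, 500)
    stimulus_ms: int = STIMULUS_MS
    first_cue: str = "RF"
    max_flashes_per_trial: int = 100
    max_trials_per_block: int = 5000

    # --- PSTH template (multiplies baseline rate during RF stimuli) -------
    psth_transient_amp: float = 1.5       # peak transient gain above baseline
    psth_transient_latency_ms: float = 40.0
    psth_transient_peak_ms: float = 60.0
    psth_transient_width_ms: float = 20.0  # Gaussian SD of the bump
    psth_sustained_amp: float = 0.7
    psth_sustained_rise_ms: float = 30.0
    psth_offset_decay_ms: float = 30.0

    # --- attention modulation patterns ------------------------------------
    post_gain_mean: float = 1.09      # E[g_i]
    post_gain_sd: float = 0.12
    pre_mod_mean: float = 0.02        # E[m_i], near zero, mixed sign
    pre_mod_sd: float = 0.15
    gain_mod_correlation: float = 0.46  # target corr(g_i - 1, m_i)
    transient_pre_coupling: float = 1.0  # weight of m pattern on the transient
    # Gain-only control: m_i = gain_only_scale * (g_i - 1).  0.2 is the
    # observed ratio of mean pre-stimulus to post-stimulus attention effects
    # (~0.02 / ~0.09), i.e. baseline modulation at the slight level the
    # invariant-gain account reports, kept collinear with the stimulus gains.
    gain_only_scale: float = 0.2

    # --- latent trial state -----------------------------------------------
    latent_mean: float = 1.0          # |E a_k|, sign set by cue side
    latent_persistence: float = 0.7   # AR(1) coefficient across trials
    latent_sd: float = 0.6            # stationary SD of AR(1) fluctuations
    readiness_persistence: float = 0.7
    readiness_sd: float = 0.6

    # --- behavior link ----------------------------------------------------
    behavior_intercept: float = 0.1
    behavior_attention_slope: float = 0.9   # on s_k signed toward target side
    behavior_readiness_slope: float = 0.45  # on q_k signed toward target side
    behavior_delta_slope: float = 0.9       # on ln(|dtheta| / 3 deg)
    fa_rate: float = 0.01                   # per non-target flash
    fa_attention_slope: float = 0.4         # on s_k, logit scale
    rt_shift_ms: float = 120.0
    rt_scale_ms: float = 70.0
    rt_sigma: float = 0.25
    rt_attention_slope: float = 0.15

    seed: int = 0

    def validate(self) -> None:
        for name in ("p_target_per_flash", "p_valid", "fa_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        for name in ("n_units", "n_blocks", "hits_per_block", "cue_trial_hits",
                     "stimulus_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("post_gain_sd", "pre_mod_sd", "latent_sd", "readiness_sd",
                     "rt_scale_ms", "rt_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1.0 <= self.gain_mod_correlation <= 1.0:
            raise ValueError("gain_mod_correlation must be in [-1, 1]")
        if abs(self.latent_persistence) >= 1 or abs(self.readiness_persistence) >= 1:
            raise ValueError("AR(1) persistence must have |phi| < 1")
        if self.first_cue not in ("RF", "away"):
            raise ValueError("first_cue must be 'RF' or 'away'")
        for name in ("fixation_ms", "isi_ms"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive (lo, hi) range")

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]


@dataclass
class GroundTruth:
    """Latent parameters behind a generated session."""

    units: pd.DataFrame    # unit_id, baseline_rate, gain, pre_mod
    trials: pd.DataFrame   # trial_id, cue_location, a, s, q
    targets: pd.DataFrame  # trial_id, flash_index, p_hit


def _other(side: str) -> str:
    return "away" if side == "RF" else "RF"


def _simulate_task(config: GeneratorConfig, rng: np.random.Generator,
                   session_id: str):
    """Run the behavioral task; returns (flash rows, trial rows, target rows)."""
    config.validate()
    phi_a, sd_a = config.latent_persistence, config.latent_sd
    phi_q, sd_q = config.readiness_persistence, config.readiness_sd
    x = rng.normal(0.0, sd_a)
    q = rng.normal(0.0, sd_q)
    flash_rows, trial_rows, target_rows = [], [], []
    trial_id = 0
    deltas = np.array([1.0, 3.0, 6.0, 15.0])

    for block in range(config.n_blocks):
        cue = config.first_cue if block % 2 == 0 else _other(config.first_cue)
        block_hits = 0
        cue_phase_hits = 0
        trials_in_block = 0
        while (block_hits < config.hits_per_block
               and trials_in_block < config.max_trials_per_block):
            cue_phase = cue_phase_hits < config.cue_trial_hits
            trial_id += 1
            trials_in_block += 1
            x = phi_a * x + rng.normal(0.0, sd_a * math.sqrt(1 - phi_a ** 2))
            q = phi_q * q + rng.normal(0.0, sd_q * math.sqrt(1 - phi_q ** 2))
            a = (config.latent_mean if cue == "RF" else -config.latent_mean) + x
            s = math.tanh(a)
            trial_rows.append((trial_id, cue, a, s, q))

            stim_locs = ("RF-only" if cue == "RF" else "away-only") \
                if cue_phase else "bilateral"
            ori = float(rng.choice([45.0, 135.0]))
            has_rf_stim = stim_locs in ("RF-only", "bilateral")
            onset = int(rng.integers(config.fixation_ms[0],
                                     config.fixation_ms[1] + 1))
            flash_index = 0
            while True:
                flash_index += 1
                is_target = (flash_index > 1
                             and rng.random() < config.p_target_per_flash)
                if is_target:
                    if cue_phase:
                        t_loc, delta_mag = cue, float(rng.choice(deltas))
                    else:
                        valid = rng.random() < config.p_valid
                        t_loc = cue if valid else _other(cue)
                        delta_mag = float(rng.choice(deltas)) if valid else 3.0
                    delta = delta_mag * (1.0 if rng.random() < 0.5 else -1.0)
                    t_sign = 1.0 if t_loc == "RF" else -1.0
                    drive = (config.behavior_intercept
                             + config.behavior_attention_slope * s * t_sign
                             + config.behavior_readiness_slope * q * t_sign
                             + config.behavior_delta_slope
                             * math.log(delta_mag / 3.0))
                    p_hit = float(expit(drive))
                    hit = rng.random() < p_hit
                    target_rows.append((trial_id, flash_index, p_hit))
                    rt = np.nan
                    if hit:
                        rt = config.rt_shift_ms + float(rng.lognormal(
                            math.log(config.rt_scale_ms)
                            - config.rt_attention_slope * s * t_sign,
                            config.rt_sigma))
                        block_hits += 1
                        if cue_phase:
                            cue_phase_hits += 1
                    ori_here = ori + delta if (t_loc == "RF" and has_rf_stim) else ori
                    flash_rows.append((
                        session_id, trial_id, flash_index, onset, cue_phase,
                        cue, stim_locs, ori_here if has_rf_stim else np.nan,
                        True, t_loc, delta, "hit" if hit else "miss", rt))
                    break
                p_fa = float(expit(logit(config.fa_rate)
                                   + config.fa_attention_slope * s))
                fa = rng.random() < p_fa
                flash_rows.append((
                    session_id, trial_id, flash_index, onset, cue_phase, cue,
                    stim_locs, ori if has_rf_stim else np.nan, False, "none",
                    0.0, "false_alarm" if fa else "none", np.nan))
                if fa or flash_index >= config.max_flashes_per_trial:
                    break
                onset += config.stimulus_ms + int(rng.integers(
                    config.isi_ms[0], config.isi_ms[1] + 1))

    from .session_model import FLASH_COLUMNS
    flashes = pd.DataFrame(flash_rows, columns=FLASH_COLUMNS)
    trials = pd.DataFrame(trial_rows,
                          columns=["trial_id", "cue_location", "a", "s", "q"])
    targets = pd.DataFrame(target_rows,
                           columns=["trial_id", "flash_index", "p_hit"])
    return flashes, trials, targets


def generate_task_sequence(config: GeneratorConfig,
                           rng: np.random.Generator | None = None,
                           session_id: str = "S0") -> pd.DataFrame:
    """Generate the behavioral flash table only (no spikes).

    Cheap enough to run for very long experiments, e.g. to verify the
    empirical target hazard and cue validity against their configured values.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    flashes, _, _ = _simulate_task(config, rng, session_id)
    return flashes


def _template_arrays(config: GeneratorConfig, length: int,
                     onsets: np.ndarray):
    """Transient (B), sustained (S) and inter-stimulus (I) weight series.

    B peaks at 1 at the transient peak; S rises to ~1 during the plateau and
    decays after stimulus offset; I is 1 wherever no stimulus drive is
    present and fades to 0 during stimuli.
    """
    t = np.arange(config.stimulus_ms + 120, dtype=float)
    lat = config.psth_transient_latency_ms
    on = t >= lat
    bump = np.where(
        (t >= lat) & (t < config.stimulus_ms),
        np.exp(-0.5 * ((t - config.psth_transient_peak_ms)
                       / config.psth_transient_width_ms) ** 2), 0.0)
    sust = np.where(on, 1.0 - np.exp(-(t - lat) / config.psth_sustained_rise_ms),
                    0.0)
    off = t >= config.stimulus_ms
    sust = np.where(off, sust[int(config.stimulus_ms) - 1]
                    * np.exp(-(t - config.stimulus_ms)
                             / config.psth_offset_decay_ms), sust)
    B = np.zeros(length)
    S = np.zeros(length)
    for onset in onsets:
        lo = int(onset)
        hi = min(length, lo + len(t))
        B[lo:hi] += bump[: hi - lo]
        S[lo:hi] += sust[: hi - lo]
    I = 1.0 - np.clip(B + S, 0.0, 1.0)
    return B, S, I


def _sample_unit_params(config: GeneratorConfig, rng: np.random.Generator,
                        gain_only: bool):
    lam = rng.lognormal(config.baseline_rate_log_mean,
                        config.baseline_rate_log_sd, config.n_units)
    rho = float(np.clip(config.gain_mod_correlation, -1.0, 1.0))
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=config.n_units,
                                method="cholesky")
    g = config.post_gain_mean + config.post_gain_sd * z[:, 0]
    if gain_only:
        m = config.gain_only_scale * (g - 1.0)
    else:
        m = config.pre_mod_mean + config.pre_mod_sd * z[:, 1]
    g = np.clip(g, 0.05, None)
    m = np.clip(m, -0.9, 0.9)
    return lam, g, m


def _generate(config: GeneratorConfig, rng: np.random.Generator | None,
              session_id: str, gain_only: bool):
    if rng is None:
        rng = np.random.default_rng(config.seed)
    flashes, trials, targets = _simulate_task(config, rng, session_id)
    lam, g, m = _sample_unit_params(config, rng, gain_only)
    unit_ids = [f"{session_id}-u{i:03d}" for i in range(config.n_units)]
    kappa = config.transient_pre_coupling

    spike_unit, spike_trial, spike_time = [], [], []
    s_by_trial = dict(zip(trials["trial_id"], trials["s"]))
    q_by_trial = dict(zip(trials["trial_id"], trials["q"]))
    for trial_id, grp in flashes.groupby("trial_id", sort=True):
        s = s_by_trial[trial_id]
        q = q_by_trial[trial_id]
        length = int(grp["onset_ms"].max()) + config.stimulus_ms + 300
        rf_stim = grp["stimulus_locations"].isin(["RF-only", "bilateral"])
        onsets = grp.loc[rf_stim, "onset_ms"].to_numpy()
        B, S, I = _template_arrays(config, length, onsets)
        drive = 1.0 + config.psth_transient_amp * B + config.psth_sustained_amp * S
        mod = (1.0
               + np.outer(g - 1.0, S) * s
               + np.outer(m, kappa * B + I) * (s + q))
        rate = np.clip(lam[:, None] * drive[None, :] * mod, 0.0, None)
        counts = rng.poisson(rate * 1e-3)
        ui, ti = np.nonzero(counts)
        reps = counts[ui, ti]
        spike_unit.append(np.repeat(ui, reps))
        spike_time.append(np.repeat(ti, reps))
        spike_trial.append(np.full(int(reps.sum()), trial_id, dtype=np.int64))

    spikes = pd.DataFrame({
        "unit_id": pd.Series(np.concatenate(spike_unit) if spike_unit else [],
                             dtype=np.int64).map(lambda i: unit_ids[i]),
        "trial_id": np.concatenate(spike_trial) if spike_trial else
        np.array([], dtype=np.int64),
        "time_ms": np.concatenate(spike_time) if spike_time else
        np.array([], dtype=np.int64),
    })
    units = pd.DataFrame({"unit_id": unit_ids, "snr": np.nan})
    session = SessionData(flashes, spikes, units)
    session.params["stimulus_ms"] = config.stimulus_ms
    from .session_model import _canonicalize
    session = _canonicalize(session)
    session.validate()
    gt = GroundTruth(
        units=pd.DataFrame({"unit_id": unit_ids, "baseline_rate": lam,
                            "gain": g, "pre_mod": m}),
        trials=trials,
        targets=targets,
    )
    return session, gt


def generate_session(config: GeneratorConfig,
                     rng: np.random.Generator | None = None,
                     session_id: str = "S0"):
    """Generate a complete synthetic session plus its ground truth.

    Deterministic given (config, seed): the same seed yields an identical
    session.  Pass an explicit ``rng`` to draw several sessions from one
    stream.
    """
    return _generate(config, rng, session_id, gain_only=False)


def generate_gain_only_session(config: GeneratorConfig,
                               rng: np.random.Generator | None = None,
                               session_id: str = "S0"):
    """Negative-control generator: stimulation-invariant gain.

    Identical to :func:`generate_session` except the pre-stimulus modulation
    pattern is forced collinear with the post-stimulus gain pattern
    (``m_i = gain_only_scale * (g_i - 1)``), so no population direction
    orthogonal to the post-stimulus attention axis carries attention signal.
    """
    return _generate(config, rng, session_id, gain_only=True)


def simulate_coupled_pair(stimulus_drive: np.ndarray, gain: float,
                          coupling, tau_ms: float = 200.0,
                          dt_ms: float = 1.0):
    """Two-neuron population-coupling model.

    Neuron A is weakly population-coupled: its rate is ``gain * drive``.
    Neuron B is strongly population-coupled: its rate is a monotone function
    of A's *recent* rate -- ``coupling`` applied to a causal exponential
    moving average of A with time constant ``tau_ms`` (``tau_ms = 0`` gives
    instantaneous coupling).  The memory is what lets an attention gain on
    A's stimulus response shift B's rate during the following inter-stimulus
    interval even while A itself has returned to its unmodulated level.

    Returns ``(rate_A, rate_B)`` aligned with ``stimulus_drive``.
    """
    drive = np.asarray(stimulus_drive, dtype=float)
    if (drive < 0).any():
        raise ValueError("stimulus drive must be non-negative")
    a = gain * drive
    if tau_ms > 0:
        alpha = dt_ms / float(tau_ms)
        e = np.empty_like(a)
        acc = a[0] if len(a) else 0.0
        for i, v in enumerate(a):
            acc += alpha * (v - acc)
            e[i] = acc
    else:
        e = a
    b = np.asarray(coupling(e), dtype=float)
    return a, b


def write_ground_truth(gt: GroundTruth, out_dir: str) -> dict:
    """Write ground truth to ``groundtruth.csv`` (per-unit) and ``latent.csv``
    (per-trial)."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {"groundtruth": os.path.join(out_dir, "groundtruth.csv"),
             "latent": os.path.join(out_dir, "latent.csv")}
    gt.units.to_csv(paths["groundtruth"], index=False)
    gt.trials.to_csv(paths["latent"], index=False)
    return paths
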