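"""Session data model: file formats, epoch extraction, and spike-train smoothing.

A *session* is one recording of a block-cued two-location change-detection
experiment: a flash table (one row per 400 ms stimulus presentation, with cue,
target and outcome annotations), a spike-event table (unit, trial, time in ms),
and a unit-metadata table.  All downstream analysis operates on spike-count
matrices extracted for named epochs relative to flash onset:

========== ================= =========================================
epoch      window (ms)       use
========== ================= =========================================
pre        [-200, 0)         anticipatory (pre-stimulus) activity
post       [200, 400)        sustained stimulus response
baseline   [-100, 0)         PSTH baseline
response   [-100, 600)       time-resolved regression window
psth       [-300, 700)       PSTH display window
========== ================= =========================================

All epoch windows are half-open ``[start, end)`` so a spike contributes to
exactly one of two abutting epochs.  Spike times and flash onsets are integer
milliseconds relative to trial start (1 ms binning).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EPOCHS",
    "STIMULUS_MS",
    "SessionData",
    "EpochCountMatrix",
    "SchemaError",
    "CrossReferenceError",
    "read_session",
    "write_session",
    "extract_epoch_counts",
    "smooth_spike_train",
    "half_gaussian_kernel",
]

#: Default epoch definitions, ms relative to flash onset, half-open [start, end).
EPOCHS: dict[str, tuple[int, int]] = {
    "pre": (-200, 0),
    "post": (200, 400),
    "baseline": (-100, 0),
    "response": (-100, 600),
    "psth": (-300, 700),
}

#: Stimulus flash duration (ms).
STIMULUS_MS = 400

FLASH_COLUMNS = [
    "session_id", "trial_id", "flash_index", "onset_ms", "is_cue_trial",
    "cue_location", "stimulus_locations", "orientation_RF", "is_target",
    "target_location", "delta_orientation", "outcome", "response_time_ms",
]
SPIKE_COLUMNS = ["unit_id", "trial_id", "time_ms"]
UNIT_COLUMNS = ["unit_id", "snr"]


class SchemaError(ValueError):
    """A delimited input file violates the session schema."""


class CrossReferenceError(ValueError):
    """A table references unit or trial IDs absent from session metadata."""


@dataclass
class SessionData:
    """A validated session: flash table, spike events, unit metadata.

    ``params`` holds the epoch definitions and stimulus duration; they default
    to the module-level constants and travel with the session so epoch
    extraction is self-describing.
    """

    flashes: pd.DataFrame
    spikes: pd.DataFrame
    units: pd.DataFrame
    params: dict = field(default_factory=lambda: {"epochs": dict(EPOCHS),
                                                  "stimulus_ms": STIMULUS_MS})
    _spike_index: dict | None = field(default=None, repr=False, compare=False)

    @property
    def session_id(self) -> str:
        return str(self.flashes["session_id"].iloc[0]) if len(self.flashes) else ""

    @property
    def unit_ids(self) -> list:
        return list(self.units["unit_id"])

    def trial_ids(self) -> np.ndarray:
        return self.flashes["trial_id"].unique()

    def spike_index(self) -> dict:
        """Mapping ``unit_id -> {trial_id -> sorted int array of spike times}``.

        Built lazily and cached; every counting routine goes through it.
        """
        if self._spike_index is None:
            index: dict = {u: {} for u in self.units["unit_id"]}
            if len(self.spikes):
                for (u, tr), grp in self.spikes.groupby(
                        ["unit_id", "trial_id"], sort=False):
                    index.setdefault(u, {})[tr] = np.sort(
                        grp["time_ms"].to_numpy(dtype=np.int64))
            self._spike_index = index
        return self._spike_index

    def trial_spans(self) -> pd.DataFrame:
        """Per-trial time span used for whole-session rate computations.

        A trial spans ``[0, last flash onset + stimulus + 300)`` ms; the 300 ms
        tail covers the post-offset window without claiming time the recording
        never contained.
        """
        stim = self.params.get("stimulus_ms", STIMULUS_MS)
        last = self.flashes.groupby("trial_id", sort=True)["onset_ms"].max()
        return pd.DataFrame({"trial_id": last.index,
                             "duration_ms": last.to_numpy() + stim + 300})

    def validate(self) -> None:
        """Check all internal invariants; raise on the first violation."""
        fl, sp, un = self.flashes, self.spikes, self.units
        for df, cols, name in ((fl, FLASH_COLUMNS, "flashes"),
                               (sp, SPIKE_COLUMNS, "spikes"),
                               (un, UNIT_COLUMNS, "units")):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise SchemaError(f"{name}: missing columns {missing}")
        for tr, grp in fl.groupby("trial_id", sort=False):
            fi = grp["flash_index"].to_numpy()
            if not np.array_equal(fi, np.arange(1, len(fi) + 1)):
                raise SchemaError(
                    f"flashes: trial {tr}: flash_index must be 1..n contiguous")
            on = grp["onset_ms"].to_numpy()
            if np.any(np.diff(on) <= 0):
                raise SchemaError(
                    f"flashes: trial {tr}: onset_ms not strictly increasing")
            if grp["cue_location"].nunique() > 1:
                raise SchemaError(
                    f"flashes: trial {tr}: cue_location varies within trial")
            tmask = grp["is_target"].to_numpy().astype(bool)
            if tmask.sum() > 1:
                raise SchemaError(f"flashes: trial {tr}: more than one target")
            if tmask.sum() == 1 and not tmask[-1]:
                raise SchemaError(
                    f"flashes: trial {tr}: target must end the trial")
        tgt = fl["is_target"].astype(bool)
        bad = tgt & ((fl["target_location"] == "none")
                     | (fl["delta_orientation"] == 0))
        if bad.any():
            raise SchemaError(
                f"flashes: rows {list(fl.index[bad])}: target flash requires "
                "target_location != none and delta_orientation != 0")
        bad = fl["outcome"].isin(["hit", "miss"]) & ~tgt
        if bad.any():
            raise SchemaError(
                f"flashes: rows {list(fl.index[bad])}: hit/miss on non-target")
        bad = (fl["outcome"] == "false_alarm") & tgt
        if bad.any():
            raise SchemaError(
                f"flashes: rows {list(fl.index[bad])}: false_alarm on target")
        if len(sp):
            orphan_u = set(sp["unit_id"]) - set(un["unit_id"])
            if orphan_u:
                raise CrossReferenceError(
                    f"spikes: unknown unit_id values: {sorted(orphan_u)}")
            orphan_t = set(sp["trial_id"]) - set(fl["trial_id"])
            if orphan_t:
                raise CrossReferenceError(
                    f"spikes: unknown trial_id values: {sorted(orphan_t)}")
            if (sp["time_ms"] < 0).any():
                raise SchemaError("spikes: negative time_ms")


@dataclass
class EpochCountMatrix:
    """Flashes x units spike-count matrix for one named epoch.

    ``flash_rows`` are positional row indices into the session's flash table,
    so rows can be joined back to behavioral annotations.
    """

    counts: np.ndarray          # (n_flashes, n_units) non-negative ints
    flash_rows: np.ndarray      # positional indices into SessionData.flashes
    unit_ids: list
    epoch: str

    def __post_init__(self):
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.unit_ids)) != len(self.unit_ids):
            raise ValueError("duplicate unit labels")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _canonicalize(session: SessionData) -> SessionData:
    fl = session.flashes.sort_values(
        ["trial_id", "flash_index"], kind="stable").reset_index(drop=True)
    sp = session.spikes.sort_values(
        ["unit_id", "trial_id", "time_ms"], kind="stable").reset_index(drop=True)
    un = session.units.sort_values("unit_id", kind="stable").reset_index(drop=True)
    return SessionData(fl, sp, un, dict(session.params))


def _fmt_num(x) -> str:
    if pd.isna(x):
        return ""
    f = float(x)
    return str(int(f)) if f == int(f) else repr(f)


def write_session(session: SessionData, out_dir: str) -> dict:
    """Write a session to ``flashes.csv``, ``spikes.csv``, ``units.csv``.

    Rows are canonically ordered -- flashes by (trial_id, flash_index), spikes
    by (unit_id, trial_id, time_ms) -- so output bytes are a pure function of
    session content.
    """
    session = _canonicalize(session)
    os.makedirs(out_dir, exist_ok=True)
    paths = {k: os.path.join(out_dir, f"{k}.csv")
             for k in ("flashes", "spikes", "units")}

    buf = io.StringIO()
    buf.write(",".join(FLASH_COLUMNS) + "\n")
    for row in session.flashes.itertuples(index=False):
        buf.write(",".join([
            str(row.session_id), str(int(row.trial_id)),
            str(int(row.flash_index)), str(int(row.onset_ms)),
            str(int(bool(row.is_cue_trial))), str(row.cue_location),
            str(row.stimulus_locations), _fmt_num(row.orientation_RF),
            str(int(bool(row.is_target))), str(row.target_location),
            _fmt_num(row.delta_orientation), str(row.outcome),
            _fmt_num(row.response_time_ms)]) + "\n")
    with open(paths["flashes"], "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())

    buf = io.StringIO()
    buf.write(",".join(SPIKE_COLUMNS) + "\n")
    for row in session.spikes.itertuples(index=False):
        buf.write(f"{row.unit_id},{int(row.trial_id)},{int(row.time_ms)}\n")
    with open(paths["spikes"], "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())

    buf = io.StringIO()
    buf.write(",".join(UNIT_COLUMNS) + "\n")
    for row in session.units.itertuples(index=False):
        buf.write(f"{row.unit_id},{_fmt_num(row.snr)}\n")
    with open(paths["units"], "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())
    return paths


def _read_csv(path: str, columns: list[str], name: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise SchemaError(f"{name}: file not found: {path}") from None
    if list(df.columns) != columns:
        raise SchemaError(
            f"{name} ({path}): expected columns {columns}, got {list(df.columns)}")
    return df


def _parse_col(df, name, col, parser):
    try:
        return parser(df[col])
    except (ValueError, TypeError) as exc:
        # locate the first offending row for the diagnostic
        for i, v in enumerate(df[col]):
            try:
                parser(pd.Series([v]))
            except (ValueError, TypeError):
                raise SchemaError(
                    f"{name}: row {i + 2}, column {col!r}: "
                    f"cannot parse {v!r}") from exc
        raise


def read_session(in_dir: str) -> SessionData:
    """Read and validate a session from a directory of CSV files.

    Raises :class:`SchemaError` naming file, row and column on malformed
    input, and :class:`CrossReferenceError` listing orphan IDs.
    """
    fl = _read_csv(os.path.join(in_dir, "flashes.csv"), FLASH_COLUMNS, "flashes")
    sp = _read_csv(os.path.join(in_dir, "spikes.csv"), SPIKE_COLUMNS, "spikes")
    un = _read_csv(os.path.join(in_dir, "units.csv"), UNIT_COLUMNS, "units")

    as_int = lambda s: s.astype(np.int64)
    as_float = lambda s: pd.to_numeric(s.mask(s == "", None),
                                       errors="raise").astype(np.float64)
    as_bool = lambda s: s.astype(np.int64).astype(bool)

    for col in ("trial_id", "flash_index", "onset_ms"):
        fl[col] = _parse_col(fl, "flashes", col, as_int)
    for col in ("is_cue_trial", "is_target"):
        fl[col] = _parse_col(fl, "flashes", col, as_bool)
    for col in ("orientation_RF", "delta_orientation", "response_time_ms"):
        fl[col] = _parse_col(fl, "flashes", col, as_float)
    for col in ("trial_id", "time_ms"):
        sp[col] = _parse_col(sp, "spikes", col, as_int)
    un["snr"] = _parse_col(un, "units", "snr", as_float)

    session = _canonicalize(SessionData(fl, sp, un))
    session.validate()
    return session


# ---------------------------------------------------------------------------
# Epoch extraction
# ---------------------------------------------------------------------------

def _included_flash_mask(flashes: pd.DataFrame, start: int, end: int) -> np.ndarray:
    """Flashes whose window [onset+start, onset+end) ends strictly before any
    target onset on the same trial (neural data from target onset onward are
    excluded from analysis).  For the target flash itself this admits only
    windows ending at or before its own onset (e.g. the pre-stimulus epoch).
    """
    onset = flashes["onset_ms"].to_numpy()
    include = np.ones(len(flashes), dtype=bool)
    tgt = flashes["is_target"].to_numpy().astype(bool)
    tgt_onset_by_trial = dict(zip(flashes.loc[tgt, "trial_id"],
                                  flashes.loc[tgt, "onset_ms"]))
    trial = flashes["trial_id"].to_numpy()
    for i in range(len(flashes)):
        t_on = tgt_onset_by_trial.get(trial[i])
        if t_on is not None and onset[i] + end > t_on:
            include[i] = False
    return include


def extract_epoch_counts(session: SessionData, epoch: str,
                         units: list | None = None,
                         flash_filter=None) -> EpochCountMatrix:
    """Count spikes per flash and unit in a named epoch window.

    Element ``(i, j)`` is the number of spikes of unit ``j`` in
    ``[onset_i + start, onset_i + end)``.  Flashes whose window would touch or
    follow a target onset on the same trial are omitted (the target flash
    itself only contributes windows that end strictly before its onset, such
    as the pre-stimulus epoch).

    Parameters
    ----------
    epoch : name from ``session.params["epochs"]``.
    units : subset of unit IDs (default: all, in unit-table order).
    flash_filter : optional boolean predicate on flash-table rows
        (called with the flash DataFrame, returns a boolean mask).
    """
    epochs = session.params.get("epochs", EPOCHS)
    if epoch not in epochs:
        raise KeyError(f"unknown epoch {epoch!r}; defined: {sorted(epochs)}")
    start, end = epochs[epoch]
    if units is None:
        units = list(session.units["unit_id"])
    else:
        unknown = set(units) - set(session.units["unit_id"])
        if unknown:
            raise KeyError(f"unknown units: {sorted(unknown)}")

    fl = session.flashes
    mask = _included_flash_mask(fl, start, end)
    if flash_filter is not None:
        mask &= np.asarray(flash_filter(fl), dtype=bool)
    rows = np.flatnonzero(mask)

    counts = np.zeros((len(rows), len(units)), dtype=np.int64)
    index = session.spike_index()
    trial = fl["trial_id"].to_numpy()
    onset = fl["onset_ms"].to_numpy()
    # group selected flashes by trial so each (unit, trial) array is scanned once
    by_trial: dict = {}
    for k, r in enumerate(rows):
        by_trial.setdefault(trial[r], []).append(k)
    for j, u in enumerate(units):
        per_trial = index.get(u, {})
        for tr, ks in by_trial.items():
            times = per_trial.get(tr)
            if times is None or not len(times):
                continue
            ks = np.asarray(ks)
            starts = onset[rows[ks]] + start
            ends = onset[rows[ks]] + end
            counts[ks, j] = (np.searchsorted(times, ends, side="left")
                             - np.searchsorted(times, starts, side="left"))
    return EpochCountMatrix(counts, rows, list(units), epoch)


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def half_gaussian_kernel(sigma_ms: float, dt_ms: float = 1.0) -> np.ndarray:
    """Causal half-Gaussian kernel, truncated at 4*sigma, unit mass.

    ``k[u] = exp(-u^2 / 2 sigma^2)`` for lags ``u >= 0`` only, renormalized so
    the discrete support sums to 1 (truncation discards <0.01% of the mass).
    """
    if sigma_ms <= 0:
        raise ValueError("sigma_ms must be positive")
    lags = np.arange(0, int(np.ceil(4 * sigma_ms / dt_ms)) + 1) * dt_ms
    k = np.exp(-0.5 * (lags / sigma_ms) ** 2)
    return k / k.sum()


def smooth_spike_train(binned_spikes: np.ndarray, sigma_ms: float = 20.0,
                       dt_ms: float = 1.0) -> np.ndarray:
    """Convolve 1 ms-binned spike counts with a causal half-Gaussian.

    Returns a rate series in spikes/s:
    ``out[t] = (1000/dt) * sum_{u>=0} k[u] * spikes[t-u]``.  Strictly causal:
    the output is zero before the first spike.  The kernel has unit mass, so
    ``sum(out) * dt/1000`` equals the total spike count whenever the last
    spike falls at least 4 sigma before the end of the series (the output is
    truncated to the input length).  Accepts 1-D series or 2-D
    ``(n_series, time)`` arrays (smoothed along the last axis).
    """
    k = half_gaussian_kernel(sigma_ms, dt_ms)
    x = np.asarray(binned_spikes, dtype=float)
    if x.ndim == 1:
        out = np.convolve(x, k)[: x.shape[0]]
    else:
        from scipy.signal import fftconvolve
        out = fftconvolve(x, k[np.newaxis, :], axes=-1)[..., : x.shape[-1]]
        np.maximum(out, 0.0, out=out)  # clip fft ringing below zero
    return out * (1000.0 / dt_ms)


def binned_spike_counts(session: SessionData, unit, trial,
                        t_start: int, t_stop: int) -> np.ndarray:
    """Per-ms spike counts of one unit in ``[t_start, t_stop)`` of a trial."""
    times = session.spike_index().get(unit, {}).get(trial)
    out = np.zeros(int(t_stop - t_start), dtype=np.int64)
    if times is not None and len(times):
        sel = times[(times >= t_start) & (times < t_stop)] - t_start
        np.add.at(out, sel.astype(np.int64), 1)
    return out
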