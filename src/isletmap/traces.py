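"""Trace containers and signal processing: normalization, EMD denoise, binarization.

The processing chain mirrors the standard islet functional-mapping recipe:
raw per-cell fluorescence -> F/F_min (or channel-ratio) normalization ->
EMD-based removal of noise and baseline trend -> 20%-of-dynamic-range
binarization into an ON/OFF activity raster -> per-cell response metrics
(amplitude, pulse duration, responsiveness, oscillation frequency).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .emd import EmdDecomposition, emd_decompose, mean_period_s

logger = logging.getLogger(__name__)

__all__ = [
    "StimEpoch",
    "FluorescenceTraceSet",
    "NormalizedTraceSet",
    "BinaryRaster",
    "ResponseMetrics",
    "normalize_traces",
    "detrend_denoise",
    "binarize_activity",
    "response_metrics",
]

VALID_EPOCH_LABELS = ("baseline", "glucose", "kcl", "silenced")


@dataclass(frozen=True)
class StimEpoch:
    """One stimulation epoch of the recording protocol.

    drive_level in [0, 1] scales the propensity of cells to burst; in the
    simulator a KCl epoch depolarizes every cell regardless of drive_level.
    """

    label: str
    start_s: float
    end_s: float
    drive_level: float = 0.0

    def __post_init__(self):
        if self.label not in VALID_EPOCH_LABELS:
            raise ValueError(
                f"epoch label {self.label!r} not in {VALID_EPOCH_LABELS}"
            )
        if not (self.start_s < self.end_s):
            raise ValueError(f"epoch {self.label}: start_s must be < end_s")
        if not (0.0 <= self.drive_level <= 1.0):
            raise ValueError(f"epoch {self.label}: drive_level must be in [0,1]")

    def frame_slice(self, frame_rate_hz: float, n_frames: int) -> slice:
        a = int(round(self.start_s * frame_rate_hz))
        b = int(round(self.end_s * frame_rate_hz))
        return slice(max(a, 0), min(b, n_frames))


def _check_epochs(epochs: list[StimEpoch]) -> list[StimEpoch]:
    for prev, nxt in zip(epochs, epochs[1:]):
        if nxt.start_s < prev.end_s:
            raise ValueError(
                f"epochs overlap or are unordered: {prev.label} ends at "
                f"{prev.end_s}s but {nxt.label} starts at {nxt.start_s}s"
            )
    return list(epochs)


@dataclass
class FluorescenceTraceSet:
    """Cell x frame fluorescence matrix with acquisition metadata."""

    values: np.ndarray
    frame_rate_hz: float
    cell_ids: list[str] = None  # type: ignore[assignment]
    coords: np.ndarray = None  # type: ignore[assignment]  # (n_cells, 2)
    epochs: list[StimEpoch] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace matrix contains non-finite values")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        n = self.values.shape[0]
        if self.cell_ids is None:
            self.cell_ids = [f"cell{i:03d}" for i in range(n)]
        if len(self.cell_ids) != n:
            raise ValueError("cell_ids length does not match number of cells")
        if self.coords is None:
            self.coords = np.zeros((n, 2))
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (n, 2):
            raise ValueError("coords must be (n_cells, 2)")
        self.epochs = _check_epochs(self.epochs)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    def epoch(self, label: str) -> StimEpoch:
        for ep in self.epochs:
            if ep.label == label:
                return ep
        raise KeyError(f"no epoch labelled {label!r}")

    # -- CSV dialect: cell_id, x, y, then one column per frame time ---------
    def to_csv(self, path: str | Path) -> None:
        times = self.times_s
        df = pd.DataFrame(self.values, columns=[f"{t:.9g}" for t in times])
        df.insert(0, "y", self.coords[:, 1])
        df.insert(0, "x", self.coords[:, 0])
        df.insert(0, "cell_id", self.cell_ids)
        df.to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        frame_rate_hz: float | None = None,
        epochs: list[StimEpoch] | None = None,
    ) -> "FluorescenceTraceSet":
        df = pd.read_csv(path)
        meta = ["cell_id", "x", "y"]
        times = np.array([float(c) for c in df.columns if c not in meta])
        if frame_rate_hz is None:
            if len(times) < 2:
                raise ValueError("cannot infer frame rate from a single frame")
            frame_rate_hz = 1.0 / float(np.median(np.diff(times)))
        return cls(
            values=df.drop(columns=meta).to_numpy(dtype=float),
            frame_rate_hz=frame_rate_hz,
            cell_ids=[str(c) for c in df["cell_id"]],
            coords=df[["x", "y"]].to_numpy(dtype=float),
            epochs=epochs or [],
        )


@dataclass
class NormalizedTraceSet:
    """Dimensionless traces: F/F_min, a ratiometric channel quotient, or raw."""

    values: np.ndarray
    frame_rate_hz: float
    mode: str = "f_over_fmin"
    f_min: np.ndarray | None = None
    cell_ids: list[str] = None  # type: ignore[assignment]
    coords: np.ndarray = None  # type: ignore[assignment]
    epochs: list[StimEpoch] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        n = self.values.shape[0]
        if self.cell_ids is None:
            self.cell_ids = [f"cell{i:03d}" for i in range(n)]
        if self.coords is None:
            self.coords = np.zeros((n, 2))
        self.coords = np.asarray(self.coords, dtype=float)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class BinaryRaster:
    """Cell x frame ON/OFF activity matrix."""

    states: np.ndarray
    frame_rate_hz: float
    threshold_fraction: float = 0.20
    cell_ids: list[str] = None  # type: ignore[assignment]

    def __post_init__(self):
        states = np.atleast_2d(np.asarray(self.states))
        uniq = np.unique(states)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("raster entries must be exactly 0 or 1")
        self.states = states.astype(np.uint8)
        if self.cell_ids is None:
            self.cell_ids = [f"cell{i:03d}" for i in range(self.states.shape[0])]

    @property
    def n_cells(self) -> int:
        return self.states.shape[0]

    @property
    def n_frames(self) -> int:
        return self.states.shape[1]

    def on_fraction(self) -> np.ndarray:
        return self.states.mean(axis=1)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.states.astype(int))
        df.insert(0, "cell_id", self.cell_ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, frame_rate_hz: float) -> "BinaryRaster":
        df = pd.read_csv(path)
        ids = [str(c) for c in df["cell_id"]]
        return cls(
            states=df.drop(columns=["cell_id"]).to_numpy(dtype=int),
            frame_rate_hz=frame_rate_hz,
            cell_ids=ids,
        )


# ---------------------------------------------------------------------------
# normalization


def normalize_traces(
    raw: FluorescenceTraceSet,
    mode: str = "f_over_fmin",
    *,
    channel_b: np.ndarray | None = None,
    f_min_percentile: float = 5.0,
) -> NormalizedTraceSet:
    """Normalize raw fluorescence to a dimensionless signal.

    Modes
    -----
    ``f_over_fmin``
        Divide each cell's trace by its F_min, estimated as the
        ``f_min_percentile``-th percentile of the baseline epoch (or of the
        whole trace when no baseline epoch is present).  The percentile rule
        makes the "minimum fluorescence" robust to single-frame dropouts.
    ``fura_340_385`` / ``epac_cer_cit``
        Element-wise ratio of the primary channel (``raw.values``) over the
        second channel ``channel_b`` (385 nm or Citrine respectively).
    ``raw``
        Pass-through.
    """
    common = dict(
        frame_rate_hz=raw.frame_rate_hz,
        cell_ids=list(raw.cell_ids),
        coords=raw.coords.copy(),
        epochs=list(raw.epochs),
    )
    if mode == "raw":
        return NormalizedTraceSet(values=raw.values.copy(), mode=mode, **common)
    if mode in ("fura_340_385", "epac_cer_cit"):
        if channel_b is None:
            raise ValueError(f"mode {mode!r} requires channel_b")
        b = np.asarray(channel_b, dtype=float)
        if b.shape != raw.values.shape:
            raise ValueError("channel_b shape does not match primary channel")
        if np.any(b == 0):
            bad = np.unique(np.where(b == 0)[0])
            raise ValueError(
                "zero denominator frames for cells: "
                + ", ".join(raw.cell_ids[i] for i in bad)
            )
        return NormalizedTraceSet(values=raw.values / b, mode=mode, **common)
    if mode == "f_over_fmin":
        try:
            base = raw.epoch("baseline")
            window = base.frame_slice(raw.frame_rate_hz, raw.n_frames)
        except KeyError:
            window = slice(None)
        f_min = np.percentile(raw.values[:, window], f_min_percentile, axis=1)
        if np.any(f_min <= 0):
            bad = np.where(f_min <= 0)[0]
            raise ValueError(
                "non-positive F_min for cells: "
                + ", ".join(raw.cell_ids[i] for i in bad)
            )
        return NormalizedTraceSet(
            values=raw.values / f_min[:, None], mode=mode, f_min=f_min, **common
        )
    raise ValueError(f"unknown normalization mode {mode!r}")


# ---------------------------------------------------------------------------
# EMD detrend / denoise


def _select_components(
    dec: EmdDecomposition,
    frame_rate_hz: float,
    duration_s: float,
    noise_rule: str,
    noise_period_max_s: float,
) -> np.ndarray:
    """Sum of the IMFs kept as signal (noise IMFs and trend components dropped)."""
    n_imfs = dec.n_imfs
    if n_imfs < 2:
        # too coarse a decomposition to separate noise; only the trend
        # (residue) is removed
        logger.info("cell yielded < 2 IMFs; removing residue only")
        return sum(dec.imfs, np.zeros_like(dec.residue))
    keep = []
    half_record = duration_s / 2.0
    for k, imf in enumerate(dec.imfs):
        period = mean_period_s(imf, frame_rate_hz)
        if period > half_record:  # slow component: part of the baseline trend
            continue
        if noise_rule == "imf1" and k == 0:
            continue
        if noise_rule == "fast_imfs" and k == 0 and period < noise_period_max_s:
            # leading IMF dropped only when it oscillates faster than any
            # plausible Ca2+ transient, i.e. when it actually carries noise
            continue
        keep.append(imf)
    if not keep:
        return np.zeros_like(dec.residue)
    return sum(keep, np.zeros_like(dec.residue))


def detrend_denoise(
    traces: NormalizedTraceSet,
    *,
    noise_rule: str = "none",
    noise_period_max_s: float = 0.25,
    sd_stop: float = 0.2,
    max_siftings: int = 50,
    max_imfs: int = 12,
) -> NormalizedTraceSet:
    """Remove baseline trend (and optionally fast noise IMFs) via EMD.

    Per cell the trace is sifted into IMFs + residue; the output is the sum of
    the intermediate IMFs.  The residue, and any IMF whose mean period exceeds
    half the record, are treated as baseline trend and dropped.  The noise
    component is controlled by ``noise_rule``:

    - ``"none"`` (default): keep all non-trend IMFs.  Fast Ca2+ transients
      share the fastest IMF with shot noise, so removing it smears burst
      timing; zero-mean noise left in the trace is rejected downstream by the
      amplitude threshold of ``binarize_activity`` instead.
    - ``"imf1"``: always drop IMF 1 (classical noise removal, appropriate for
      heavily oversampled smooth recordings);
    - ``"fast_imfs"``: drop IMF 1 only when its mean period is below
      ``noise_period_max_s`` (default 0.25 s, faster than islet transients).
    """
    if noise_rule not in ("fast_imfs", "imf1", "none"):
        raise ValueError(f"unknown noise_rule {noise_rule!r}")
    duration_s = traces.n_frames / traces.frame_rate_hz
    out = np.empty_like(traces.values)
    for i in range(traces.n_cells):
        row = traces.values[i]
        if np.allclose(row, row[0]):
            out[i] = 0.0
            continue
        dec = emd_decompose(
            row, sd_stop=sd_stop, max_siftings=max_siftings, max_imfs=max_imfs
        )
        out[i] = _select_components(
            dec, traces.frame_rate_hz, duration_s, noise_rule, noise_period_max_s
        )
    return NormalizedTraceSet(
        values=out,
        frame_rate_hz=traces.frame_rate_hz,
        mode=traces.mode,
        f_min=traces.f_min,
        cell_ids=list(traces.cell_ids),
        coords=traces.coords.copy(),
        epochs=list(traces.epochs),
    )


# ---------------------------------------------------------------------------
# binarization


def binarize_activity(
    traces: NormalizedTraceSet,
    threshold_fraction: float = 0.20,
    *,
    baseline_anchor: str = "median",
    robust_percentiles: tuple[float, float] = (1.0, 99.0),
) -> BinaryRaster:
    """Threshold each denoised trace at a fraction of its dynamic range.

    A frame is ON when ``signal - robust_min > threshold_fraction *
    (robust_max - robust_min)``.  ``robust_max`` is the 99th percentile of
    the trace (spikes cannot stretch the range).  ``robust_min`` is the
    trace median by default (``baseline_anchor="median"``): a detrended
    trace is zero-centred and its minimum sits in the noise/undershoot
    floor, whereas the median tracks the quiescent baseline as long as
    cells are OFF most of the time — the operating regime of islet
    recordings.  ``baseline_anchor="percentile"`` uses the 1st percentile
    instead.  Cells with zero dynamic range come out all-OFF.
    """
    if not (0.0 <= threshold_fraction < 1.0):
        raise ValueError("threshold_fraction must be in [0, 1)")
    if baseline_anchor not in ("median", "percentile"):
        raise ValueError(f"unknown baseline_anchor {baseline_anchor!r}")
    lo_p, hi_p = robust_percentiles
    if baseline_anchor == "median":
        lo_p = 50.0
    lo = np.percentile(traces.values, lo_p, axis=1)
    hi = np.percentile(traces.values, hi_p, axis=1)
    rng = hi - lo
    states = np.zeros(traces.values.shape, dtype=np.uint8)
    active = rng > 0
    if np.any(~active):
        logger.info(
            "%d cell(s) with zero dynamic range set all-OFF", int(np.sum(~active))
        )
    thr = lo + threshold_fraction * rng
    states[active] = (traces.values[active] > thr[active, None]).astype(np.uint8)
    return BinaryRaster(
        states=states,
        frame_rate_hz=traces.frame_rate_hz,
        threshold_fraction=threshold_fraction,
        cell_ids=list(traces.cell_ids),
    )


# ---------------------------------------------------------------------------
# response metrics


@dataclass
class ResponseMetrics:
    """Per-cell summary of the stimulus response."""

    amplitude: np.ndarray  # mean(stimulus) - mean(baseline)
    pulse_duration_s: np.ndarray  # mean contiguous ON-run length in stimulus
    responsive: np.ndarray  # amplitude > k * SD(baseline)
    oscillation_frequency_hz: np.ndarray  # ON-run onsets / stimulus duration
    cell_ids: list[str]

    @property
    def fraction_responsive(self) -> float:
        return float(np.mean(self.responsive))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "amplitude": self.amplitude,
                "pulse_duration_s": self.pulse_duration_s,
                "responsive": self.responsive,
                "oscillation_frequency_hz": self.oscillation_frequency_hz,
            }
        )


def _on_runs(row: np.ndarray) -> list[int]:
    """Lengths of contiguous ON runs in a 0/1 row."""
    padded = np.concatenate([[0], row, [0]])
    d = np.diff(padded)
    starts = np.where(d == 1)[0]
    ends = np.where(d == -1)[0]
    return list((ends - starts).astype(int))


def response_metrics(
    traces: NormalizedTraceSet,
    raster: BinaryRaster,
    epochs: list[StimEpoch] | None = None,
    *,
    baseline_label: str = "baseline",
    stimulus_label: str = "glucose",
    k_sd: float = 2.0,
) -> ResponseMetrics:
    """Amplitude, pulse duration, responsiveness and frequency per cell.

    amplitude = mean over the stimulus epoch minus mean over baseline;
    a cell is responsive when amplitude > ``k_sd`` baseline standard
    deviations; oscillation frequency counts ON-run onsets per stimulus
    second.
    """
    epochs = epochs if epochs is not None else traces.epochs
    labels = {ep.label: ep for ep in epochs}
    for need in (baseline_label, stimulus_label):
        if need not in labels:
            raise ValueError(f"missing required epoch {need!r}")
    base = labels[baseline_label].frame_slice(traces.frame_rate_hz, traces.n_frames)
    stim_ep = labels[stimulus_label]
    stim = stim_ep.frame_slice(traces.frame_rate_hz, traces.n_frames)
    stim_duration = stim_ep.end_s - stim_ep.start_s

    amp = traces.values[:, stim].mean(axis=1) - traces.values[:, base].mean(axis=1)
    base_sd = traces.values[:, base].std(axis=1)
    responsive = amp > k_sd * base_sd

    n = traces.n_cells
    pulse = np.zeros(n)
    freq = np.zeros(n)
    dt = 1.0 / raster.frame_rate_hz
    for i in range(n):
        runs = _on_runs(raster.states[i, stim])
        if runs:
            pulse[i] = float(np.mean(runs)) * dt
            freq[i] = len(runs) / stim_duration
    return ResponseMetrics(
        amplitude=amp,
        pulse_duration_s=pulse,
        responsive=responsive,
        oscillation_frequency_hz=freq,
        cell_ids=list(traces.cell_ids),
    )
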