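"""Synthetic islet data: coupled-burster Ca2+ recordings and nuclei-stain images.

Two generators make every downstream stage testable without real recordings:

``generate_islet_traces``
    A discrete-time Markov two-state (quiescent/bursting) cell model on a
    spatial proximity graph.  A small planted subpopulation of *hub* cells
    receives top degree in the graph (edges to most of the islet) and a
    multiplicative boost to its influence weight, so hubs both initiate
    bursts and join the bursts of every local group — their activity spans
    that of the rest of the population, which is exactly the signature the
    downstream network analysis is meant to detect.  Fluorescence is
    baseline x (1 + slow sinusoidal drift) + burst amplitude x state +
    Gaussian shot noise; the noiseless state matrix is kept as ground truth.

``generate_stain_image``
    A 2-D image of well-separated Gaussian nuclei over constant background,
    with per-cell peak intensities drawn from a two-component (LOW/HIGH)
    mixture emulating the bimodal PDX1/MAFA maturity distribution.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .traces import BinaryRaster, FluorescenceTraceSet, StimEpoch

__all__ = [
    "IsletSimConfig",
    "SyntheticIsletDataset",
    "StainSimConfig",
    "StainGroundTruth",
    "REFERENCE_COUPLING",
    "default_protocol",
    "generate_islet_traces",
    "generate_stain_image",
]

#: Per-edge, per-frame ON-transition probability contributed by one active
#: neighbor of unit influence weight.  At this coupling, planted hubs are
#: reliably recovered by the permutation network analysis (the simulator's
#: reference operating point).
REFERENCE_COUPLING = 0.0015


def default_protocol(duration_s: float = 150.0) -> list[StimEpoch]:
    """Baseline (low glucose) then sustained glucose stimulation."""
    t_base = min(30.0, duration_s / 5.0)
    return [
        StimEpoch("baseline", 0.0, t_base, drive_level=0.05),
        StimEpoch("glucose", t_base, duration_s, drive_level=0.5),
    ]


def _validate_positive(name: str, value: float, strict: bool = True) -> None:
    if not np.isfinite(value) or (value <= 0 if strict else value < 0):
        kind = "positive" if strict else "non-negative"
        raise ValueError(f"config field {name!r} must be a finite {kind} number, got {value}")


@dataclass
class IsletSimConfig:
    """Parameters of the synthetic Ca2+ recording.

    Defaults describe a fast (20 Hz) recording of a mid-sized rodent islet
    cross-section: 50-300 cells, a few percent hubs, 10% shot noise and a
    slow 10% baseline drift.
    """

    n_cells: int = 100
    hub_fraction: float = 0.05
    coupling_strength: float = REFERENCE_COUPLING
    frame_rate_hz: float = 20.0
    duration_s: float = 150.0
    noise_sd: float = 0.10  # fraction of burst amplitude
    drift_amplitude: float = 0.10  # fraction of baseline
    protocol: list[StimEpoch] = None  # type: ignore[assignment]
    seed: int = 0
    layout_radius: float = 100.0
    # model internals (exposed, but the defaults are the reference condition)
    knn_k: int = 4
    hub_reach_fraction: float = 0.45  # fraction of the islet a hub connects to
    hub_boost: float = 12.0  # multiplier on a hub's influence weight
    p_spont_hub: float = 0.01  # per-frame ON rate of a hub at drive 1
    p_spont_follower: float = 0.002
    p_off_hub: float = 0.022  # hub bursts are long (~2.3 s at 20 Hz)
    p_off_follower: float = 0.25  # follower bursts are short (~0.2 s)
    drift_period_s: float = 100.0

    def __post_init__(self):
        if self.protocol is None:
            self.protocol = default_protocol(self.duration_s)
        if int(self.n_cells) != self.n_cells or self.n_cells < 1:
            raise ValueError(f"config field 'n_cells' must be a positive integer, got {self.n_cells}")
        self.n_cells = int(self.n_cells)
        if not (0.0 <= self.hub_fraction <= 1.0):
            raise ValueError(f"config field 'hub_fraction' must be in [0,1], got {self.hub_fraction}")
        _validate_positive("coupling_strength", self.coupling_strength, strict=False)
        _validate_positive("frame_rate_hz", self.frame_rate_hz)
        _validate_positive("duration_s", self.duration_s)
        _validate_positive("noise_sd", self.noise_sd, strict=False)
        _validate_positive("drift_amplitude", self.drift_amplitude, strict=False)
        _validate_positive("layout_radius", self.layout_radius)
        if self.frame_rate_hz * self.duration_s < 2:
            raise ValueError("config requires frame_rate_hz * duration_s >= 2 frames")

    @property
    def n_frames(self) -> int:
        return int(round(self.frame_rate_hz * self.duration_s))

    @property
    def n_hubs(self) -> int:
        return int(round(self.hub_fraction * self.n_cells))

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["protocol"] = [asdict(ep) for ep in self.protocol]
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "IsletSimConfig":
        d = json.loads(Path(path).read_text())
        d["protocol"] = [StimEpoch(**ep) for ep in d["protocol"]]
        return cls(**d)


@dataclass
class SyntheticIsletDataset:
    traces: FluorescenceTraceSet
    truth_raster: BinaryRaster
    truth_hubs: np.ndarray  # boolean per cell
    config: IsletSimConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.traces.to_csv(outdir / "traces.csv")
        self.truth_raster.to_csv(outdir / "truth_raster.csv")
        pd.DataFrame(
            {"cell_id": self.traces.cell_ids, "is_hub": self.truth_hubs.astype(int)}
        ).to_csv(outdir / "truth_hubs.csv", index=False)
        self.config.to_json(outdir / "sim_config.json")


def _farthest_point_sample(coords: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k spatially spread indices (greedy farthest-point), seeded start."""
    n = len(coords)
    if k <= 0:
        return np.array([], dtype=int)
    chosen = [int(rng.integers(n))]
    d = np.linalg.norm(coords - coords[chosen[0]], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(coords - coords[nxt], axis=1))
    return np.array(sorted(chosen), dtype=int)


def _build_graph(cfg: IsletSimConfig, coords: np.ndarray, hubs: np.ndarray) -> np.ndarray:
    """Symmetric adjacency: kNN proximity edges plus hub long-range edges."""
    n = cfg.n_cells
    dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    np.fill_diagonal(dist, np.inf)
    adj = np.zeros((n, n), dtype=bool)
    k = min(cfg.knn_k, n - 1)
    if k > 0:
        nearest = np.argsort(dist, axis=1)[:, :k]
        rows = np.repeat(np.arange(n), k)
        adj[rows, nearest.ravel()] = True
    # hubs reach most of the islet: top-degree nodes by construction
    reach = min(int(round(cfg.hub_reach_fraction * n)), n - 1)
    for h in np.where(hubs)[0]:
        targets = np.argsort(dist[h])[:reach]
        adj[h, targets] = True
    adj |= adj.T
    np.fill_diagonal(adj, False)
    return adj


def generate_islet_traces(config: IsletSimConfig) -> SyntheticIsletDataset:
    """Simulate one islet recording; deterministic given ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, T = cfg.n_cells, cfg.n_frames

    # spatial layout: uniform in a disk
    r = cfg.layout_radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0, 2 * np.pi, size=n)
    coords = np.column_stack([r * np.cos(theta), r * np.sin(theta)])

    hubs = np.zeros(n, dtype=bool)
    hub_idx = _farthest_point_sample(coords, cfg.n_hubs, rng)
    hubs[hub_idx] = True

    adj = _build_graph(cfg, coords, hubs)
    influence = np.where(hubs, cfg.hub_boost, 1.0)  # weight of j as a source
    # W[i, j] = per-frame ON-probability contribution of active neighbor j to i
    W = cfg.coupling_strength * adj * influence[None, :]

    p_spont = np.where(hubs, cfg.p_spont_hub, cfg.p_spont_follower)
    p_off = np.where(hubs, cfg.p_off_hub, cfg.p_off_follower)

    # per-frame drive level and epoch kind
    drive = np.zeros(T)
    forced_on = np.zeros(T, dtype=bool)
    silenced = np.zeros(T, dtype=bool)
    for ep in cfg.protocol:
        sl = ep.frame_slice(cfg.frame_rate_hz, T)
        drive[sl] = ep.drive_level
        if ep.label == "kcl":
            forced_on[sl] = True
        elif ep.label == "silenced":
            silenced[sl] = True

    states = np.zeros((n, T), dtype=np.uint8)
    s = np.zeros(n, dtype=np.uint8)
    for t in range(T):
        if forced_on[t]:
            s = np.ones(n, dtype=np.uint8)
        else:
            p_on = p_spont * drive[t] + W @ s
            if silenced[t]:
                p_on = p_on * drive[t]
            np.clip(p_on, 0.0, 0.95, out=p_on)
            u = rng.uniform(size=n)
            turn_on = (s == 0) & (u < p_on)
            turn_off = (s == 1) & (u < p_off)
            s = s.copy()
            s[turn_on] = 1
            s[turn_off] = 0
        states[:, t] = s

    # fluorescence: baseline*(1+drift) + amplitude*state + Gaussian noise
    times = np.arange(T) / cfg.frame_rate_hz
    phase = rng.uniform(0, 2 * np.pi, size=n)
    drift = cfg.drift_amplitude * np.sin(
        2 * np.pi * times[None, :] / cfg.drift_period_s + phase[:, None]
    )
    baseline, amplitude = 1.0, 1.0
    values = (
        baseline * (1.0 + drift)
        + amplitude * states
        + cfg.noise_sd * amplitude * rng.standard_normal((n, T))
    )

    cell_ids = [f"cell{i:03d}" for i in range(n)]
    traces = FluorescenceTraceSet(
        values=values,
        frame_rate_hz=cfg.frame_rate_hz,
        cell_ids=cell_ids,
        coords=coords,
        epochs=list(cfg.protocol),
    )
    raster = BinaryRaster(
        states=states, frame_rate_hz=cfg.frame_rate_hz, cell_ids=cell_ids
    )
    return SyntheticIsletDataset(
        traces=traces, truth_raster=raster, truth_hubs=hubs, config=cfg
    )


# ---------------------------------------------------------------------------
# nuclei-stain images


@dataclass
class StainSimConfig:
    """Parameters of the synthetic immunofluorescence image.

    Intensity units are 16-bit camera counts.  The LOW/HIGH peak means sit
    well apart, as in a bimodal maturity-marker distribution, with the LOW
    component close enough to background to occupy the bottom normalized
    bins downstream.
    """

    n_cells: int = 60
    low_fraction: float = 0.20
    low_mean: float = 5000.0
    high_mean: float = 20000.0
    low_sd: float = 600.0
    high_sd: float = 2500.0
    background_level: float = 300.0
    nucleus_sigma_px: float = 4.0
    image_shape: tuple[int, int] = (512, 512)
    noise_sd: float = 50.0  # additive camera noise, counts
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.low_fraction <= 1.0):
            raise ValueError("config field 'low_fraction' must be in [0,1]")
        if not self.low_mean < self.high_mean:
            raise ValueError("config requires low_mean < high_mean")
        for name in ("low_mean", "high_mean", "low_sd", "high_sd", "background_level"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"config field {name!r} must be finite and >= 0")
        _validate_positive("nucleus_sigma_px", self.nucleus_sigma_px)


@dataclass
class StainGroundTruth:
    """Planted cells: centers, class and noiseless intensities."""

    table: pd.DataFrame  # cell_id, x, y, sigma_px, is_low, peak, true_mean_intensity

    @property
    def n_cells(self) -> int:
        return len(self.table)

    @property
    def low_fraction(self) -> float:
        return float(self.table["is_low"].mean())


def _place_centers(
    cfg: StainSimConfig, rng: np.random.Generator, min_sep: float, margin: float
) -> np.ndarray:
    h, w = cfg.image_shape
    centers: list[tuple[float, float]] = []
    max_attempts = 20000
    for _ in range(max_attempts):
        if len(centers) == cfg.n_cells:
            break
        x = rng.uniform(margin, w - margin)
        y = rng.uniform(margin, h - margin)
        if all((x - cx) ** 2 + (y - cy) ** 2 >= min_sep**2 for cx, cy in centers):
            centers.append((x, y))
    if len(centers) < cfg.n_cells:
        raise ValueError(
            f"image {cfg.image_shape} cannot hold {cfg.n_cells} nuclei at "
            f"minimum separation {min_sep:.1f} px"
        )
    return np.array(centers)


def generate_stain_image(
    config: StainSimConfig,
) -> tuple[np.ndarray, StainGroundTruth]:
    """Render a 16-bit nuclei image plus its ground-truth cell table.

    Nuclei are isotropic Gaussians of width ``nucleus_sigma_px`` placed with
    minimum separation 4 sigma (well-separated regime); peak intensities are
    drawn from the LOW/HIGH mixture, truncated at zero.  ``true_mean_intensity``
    is the mean of the noiseless image over the disk of radius 2 sigma around
    each center — the quantity the segmentation pipeline should approximate.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    sig = cfg.nucleus_sigma_px
    min_sep = 4.0 * sig
    centers = _place_centers(cfg, rng, min_sep, margin=3.0 * sig)

    n_low = int(round(cfg.low_fraction * cfg.n_cells))
    is_low = np.zeros(cfg.n_cells, dtype=bool)
    is_low[rng.permutation(cfg.n_cells)[:n_low]] = True
    peaks = np.where(
        is_low,
        rng.normal(cfg.low_mean, cfg.low_sd, cfg.n_cells),
        rng.normal(cfg.high_mean, cfg.high_sd, cfg.n_cells),
    )
    peaks = np.clip(peaks, 0.0, None)

    h, w = cfg.image_shape
    yy, xx = np.mgrid[0:h, 0:w]
    clean = np.full((h, w), cfg.background_level, dtype=float)
    for (cx, cy), pk in zip(centers, peaks):
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        local = r2 <= (5 * sig) ** 2  # truncate far tails for speed
        clean[local] += pk * np.exp(-r2[local] / (2 * sig**2))
    true_means = np.empty(cfg.n_cells)
    for i, (cx, cy) in enumerate(centers):
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= (2 * sig) ** 2
        true_means[i] = clean[disk].mean()

    noisy = clean + cfg.noise_sd * rng.standard_normal((h, w))
    image = np.clip(np.round(noisy), 0, 65535).astype(np.uint16)

    truth = StainGroundTruth(
        pd.DataFrame(
            {
                "cell_id": [f"cell{i:03d}" for i in range(cfg.n_cells)],
                "x": centers[:, 0],
                "y": centers[:, 1],
                "sigma_px": sig,
                "is_low": is_low,
                "peak": peaks,
                "true_mean_intensity": true_means,
            }
        )
    )
    return image, truth
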