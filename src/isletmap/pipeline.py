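"""Reproducible pipeline runs: simulate -> process -> connect -> spectral -> quantify -> report.

Each stage reads only the persisted outputs of its upstream stages, so any
stage can be re-run from intermediates with identical results.  A single
global seed fans out to per-stage seeds through a fixed counter-based
derivation, and every floating-point CSV is written at 9 significant
digits, which makes full runs byte-reproducible for the data artifacts
(``summary.json`` and all CSVs).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .connectivity import (
    build_connectivity_map,
    classify_hubs,
    coactivity_matrix,
    connectivity_summary,
    permutation_significance,
)
from .simulate import (
    IsletSimConfig,
    StainSimConfig,
    generate_islet_traces,
    generate_stain_image,
)
from .stain import classify_maturity, intensity_distribution, measure_cells
from .traces import (
    BinaryRaster,
    FluorescenceTraceSet,
    NormalizedTraceSet,
    binarize_activity,
    detrend_denoise,
    normalize_traces,
    response_metrics,
)
from .wavelet import dominant_period, morlet_cwt

logger = logging.getLogger(__name__)

STAGES = ("simulate", "process", "connect", "spectral", "quantify", "report")

#: counter offsets for the per-stage seed derivation
_STAGE_OFFSET = {name: i + 1 for i, name in enumerate(STAGES)}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return int((global_seed * 1_000_003 + _STAGE_OFFSET[stage]) % (2**31))


@dataclass
class SignalConfig:
    """`signal` block: trace normalization, EMD detrend, binarization."""

    normalization_mode: str = "f_over_fmin"
    f_min_percentile: float = 5.0
    noise_rule: str = "none"
    noise_period_max_s: float = 0.25
    threshold_fraction: float = 0.20
    baseline_anchor: str = "median"
    responsive_k_sd: float = 2.0
    baseline_label: str = "baseline"
    stimulus_label: str = "glucose"


@dataclass
class ConnectivityConfig:
    """`connectivity` block: permutation test and hub rule."""

    alpha: float = 0.05
    n_permutations: int = 1000
    scheme: str = "circular_shift"
    bh_correction: bool = False
    hub_threshold_percent: float = 60.0
    normalization: str = "max_observed"


@dataclass
class SpectralConfig:
    """`spectral` block: wavelet parameters."""

    dj: float = 1.0 / 12.0
    window_s: tuple[float, float] | None = None


@dataclass
class StainConfig:
    """`stain` block: segmentation and maturity classification."""

    sigma: float = 2.0
    threshold_method: str = "li"
    min_area_px: int = 20
    watershed_split: bool = True
    normalization: str = "p1p99"
    cutoff_units: float = 15.0


@dataclass
class RunConfig:
    """Full pipeline configuration; serialized alongside every run."""

    seed: int = 0
    outdir: str = "islet_run"
    stages: tuple[str, ...] = STAGES
    simulation: IsletSimConfig = field(default_factory=IsletSimConfig)
    stain_simulation: StainSimConfig = field(default_factory=StainSimConfig)
    signal: SignalConfig = field(default_factory=SignalConfig)
    connectivity: ConnectivityConfig = field(default_factory=ConnectivityConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    stain: StainConfig = field(default_factory=StainConfig)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        from .traces import StimEpoch

        d = json.loads(Path(path).read_text())
        sim = d.get("simulation", {})
        if sim.get("protocol"):
            sim["protocol"] = [StimEpoch(**ep) for ep in sim["protocol"]]
        kwargs = dict(
            seed=d.get("seed", 0),
            outdir=d.get("outdir", "islet_run"),
            stages=tuple(d.get("stages", STAGES)),
            simulation=IsletSimConfig(**sim),
            stain_simulation=StainSimConfig(**{
                **d.get("stain_simulation", {}),
                **(
                    {"image_shape": tuple(d["stain_simulation"]["image_shape"])}
                    if d.get("stain_simulation", {}).get("image_shape")
                    else {}
                ),
            }),
            signal=SignalConfig(**d.get("signal", {})),
            connectivity=ConnectivityConfig(**d.get("connectivity", {})),
            spectral=SpectralConfig(**{
                **d.get("spectral", {}),
                **(
                    {"window_s": tuple(d["spectral"]["window_s"])}
                    if d.get("spectral", {}).get("window_s")
                    else {}
                ),
            }),
            stain=StainConfig(**d.get("stain", {})),
        )
        return cls(**kwargs)


def _write_float_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format="%.9g")


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{needed_by}' requires {path.name} from stage '{stage}'; "
            f"run that stage first or provide the file"
        )
    return path


# ---------------------------------------------------------------------------
# stages


def run_simulate(cfg: RunConfig, outdir: Path) -> dict:
    sim = dataclasses.replace(cfg.simulation, seed=stage_seed(cfg.seed, "simulate"))
    ds = generate_islet_traces(sim)
    ds.write(outdir)
    stain_sim = dataclasses.replace(
        cfg.stain_simulation, seed=stage_seed(cfg.seed, "simulate") + 1
    )
    image, truth = generate_stain_image(stain_sim)
    tifffile.imwrite(outdir / "stain_image.tif", image)
    _write_float_csv(truth.table, outdir / "stain_truth.csv")
    return {
        "n_cells": sim.n_cells,
        "n_frames": sim.n_frames,
        "planted_hub_fraction": sim.n_hubs / sim.n_cells,
        "stain_planted_low_fraction": truth.low_fraction,
    }


def _load_traces(cfg: RunConfig, outdir: Path) -> FluorescenceTraceSet:
    sim_cfg_path = _require(outdir / "sim_config.json", "simulate", "process")
    sim = IsletSimConfig.from_json(sim_cfg_path)
    return FluorescenceTraceSet.from_csv(
        _require(outdir / "traces.csv", "simulate", "process"),
        frame_rate_hz=sim.frame_rate_hz,
        epochs=sim.protocol,
    )


def run_process(cfg: RunConfig, outdir: Path) -> dict:
    raw = _load_traces(cfg, outdir)
    sg = cfg.signal
    norm = normalize_traces(
        raw, sg.normalization_mode, f_min_percentile=sg.f_min_percentile
    )
    den = detrend_denoise(
        norm, noise_rule=sg.noise_rule, noise_period_max_s=sg.noise_period_max_s
    )
    raster = binarize_activity(
        den, sg.threshold_fraction, baseline_anchor=sg.baseline_anchor
    )
    den_df = pd.DataFrame(den.values, columns=[f"{t:.9g}" for t in raw.times_s])
    den_df.insert(0, "cell_id", den.cell_ids)
    _write_float_csv(den_df, outdir / "denoised.csv")
    raster.to_csv(outdir / "raster.csv")
    # amplitude/responsiveness compare stimulus vs baseline levels, so they
    # are measured on the normalized traces (detrending removes the rise)
    metrics = response_metrics(
        norm,
        raster,
        raw.epochs,
        baseline_label=sg.baseline_label,
        stimulus_label=sg.stimulus_label,
        k_sd=sg.responsive_k_sd,
    )
    _write_float_csv(metrics.to_frame(), outdir / "response_metrics.csv")
    out = {
        "fraction_responsive": metrics.fraction_responsive,
        "mean_amplitude": float(np.mean(metrics.amplitude)),
        "mean_pulse_duration_s": float(np.mean(metrics.pulse_duration_s)),
        "mean_oscillation_frequency_hz": float(
            np.mean(metrics.oscillation_frequency_hz)
        ),
        "on_fraction": float(raster.states.mean()),
    }
    truth_path = outdir / "truth_raster.csv"
    if truth_path.exists():
        truth = BinaryRaster.from_csv(truth_path, raw.frame_rate_hz)
        out["truth_raster_agreement"] = float(
            (truth.states == raster.states).mean()
        )
    return out


def run_connect(cfg: RunConfig, outdir: Path) -> dict:
    sim = IsletSimConfig.from_json(
        _require(outdir / "sim_config.json", "simulate", "connect")
    )
    raster = BinaryRaster.from_csv(
        _require(outdir / "raster.csv", "process", "connect"), sim.frame_rate_hz
    )
    cc = cfg.connectivity
    coact = coactivity_matrix(raster)
    coact = permutation_significance(
        raster,
        coact,
        n_permutations=cc.n_permutations,
        alpha=cc.alpha,
        seed=stage_seed(cfg.seed, "connect"),
        scheme=cc.scheme,
        bh_correction=cc.bh_correction,
    )
    hubs = classify_hubs(
        coact, cc.hub_threshold_percent, normalization=cc.normalization
    )
    ids = coact.cell_ids
    _write_float_csv(
        pd.DataFrame(coact.C, index=ids, columns=ids), outdir / "coactivity.csv",
        index=True,
    )
    _write_float_csv(
        pd.DataFrame(coact.p_values, index=ids, columns=ids),
        outdir / "pvalues.csv",
        index=True,
    )
    traces = _load_traces(cfg, outdir)
    cmap = build_connectivity_map(coact, hubs, traces.coords)
    cmap.write(outdir)
    summary = connectivity_summary(coact)
    out = {
        "hub_fraction": hubs.hub_fraction,
        "n_hubs": int(hubs.is_hub.sum()),
        "percent_connected_pairs": summary["percent_connected_pairs"],
        "mean_significant_C": summary["mean_significant_C"],
        "n_active_cells": summary["n_active_cells"],
    }
    truth_path = outdir / "truth_hubs.csv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path)["is_hub"].to_numpy(bool)
        tp = int((hubs.is_hub & truth).sum())
        fn = int((~hubs.is_hub & truth).sum())
        fp = int((hubs.is_hub & ~truth).sum())
        tn = int((~hubs.is_hub & ~truth).sum())
        out["hub_sensitivity"] = tp / (tp + fn) if tp + fn else float("nan")
        out["hub_specificity"] = tn / (tn + fp) if tn + fp else float("nan")
    return out


def run_spectral(cfg: RunConfig, outdir: Path) -> dict:
    sim = IsletSimConfig.from_json(
        _require(outdir / "sim_config.json", "simulate", "spectral")
    )
    den = pd.read_csv(_require(outdir / "denoised.csv", "process", "spectral"))
    values = den.drop(columns=["cell_id"]).to_numpy(float)
    # mean-wave convention: arithmetic mean of per-cell bias-corrected power
    # on the common period grid
    powers = []
    spectrum = None
    for row in values:
        spectrum = morlet_cwt(row, sim.frame_rate_hz, dj=cfg.spectral.dj)
        powers.append(spectrum.power)
    spectrum.power = np.mean(powers, axis=0)
    spectrum.to_csv(outdir / "wavelet_power.csv")
    spectrum.render(outdir / "wavelet_power.png")
    _, median_period = dominant_period(spectrum, cfg.spectral.window_s)
    return {"median_dominant_period_s": median_period}


def run_quantify(cfg: RunConfig, outdir: Path) -> dict:
    image = tifffile.imread(
        _require(outdir / "stain_image.tif", "simulate", "quantify")
    )
    st = cfg.stain
    table = measure_cells(
        image,
        sigma=st.sigma,
        threshold_method=st.threshold_method,
        min_area_px=st.min_area_px,
        watershed_split=st.watershed_split,
    )
    _write_float_csv(table.table, outdir / "stain_cells.csv")
    dist = intensity_distribution(
        table, normalization=st.normalization, low_cutoff_units=st.cutoff_units
    )
    _write_float_csv(dist.to_frame(), outdir / "stain_distribution.csv")
    labels = classify_maturity(dist)
    labels.insert(0, "cell_id", table.table["cell_id"].to_numpy())
    _write_float_csv(labels, outdir / "stain_labels.csv")
    return {
        "n_cells_segmented": table.n_cells,
        "low_fraction_percent": dist.low_fraction_percent,
        "bottom_three_bin_percent": float(dist.frequency_percent[:3].sum()),
    }


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the requested stages in dependency order.

    Writes per-stage CSV/TIFF/PNG artifacts plus ``summary.json`` (the
    machine-readable result record), ``run_config.json`` and ``run.log``
    into ``cfg.outdir`` and returns that directory.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_json(outdir / "run_config.json")

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("isletmap")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    logger.info(
        "isletmap %s | python %s | numpy %s | seed %d | stages %s",
        __version__, sys.version.split()[0], np.__version__, cfg.seed,
        ",".join(cfg.stages),
    )

    runners = {
        "simulate": run_simulate,
        "process": run_process,
        "connect": run_connect,
        "spectral": run_spectral,
        "quantify": run_quantify,
    }
    summary: dict[str, dict] = {"seed": cfg.seed, "stages": {}}
    existing = outdir / "summary.json"
    if existing.exists():  # stage-wise runs accumulate into one record
        prior = json.loads(existing.read_text())
        if prior.get("seed") == cfg.seed:
            summary["stages"].update(prior.get("stages", {}))
    try:
        for stage in STAGES:
            if stage == "report" or stage not in cfg.stages:
                continue
            logger.info("running stage %s (seed %d)", stage, stage_seed(cfg.seed, stage))
            try:
                summary["stages"][stage] = runners[stage](cfg, outdir)
            except Exception as exc:
                raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        (outdir / "summary.json").write_text(
            json.dumps(_round_floats(summary, 9), indent=2, sort_keys=True)
        )
    finally:
        root.removeHandler(handler)
        handler.close()
    return outdir


def _round_floats(obj, sig: int):
    """Round every float to ``sig`` significant digits for stable diffs."""
    if isinstance(obj, float):
        if obj == 0 or not np.isfinite(obj):
            return obj
        return float(f"%.{sig}g" % obj)
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    return obj
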