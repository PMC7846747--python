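"""Co-activity network inference and hub-cell classification.

For a binarized raster the pairwise co-activity coefficient is

    C_ij = T_ij / sqrt(T_i * T_j)

where T_i and T_j are the frame counts each cell spends ON and T_ij the
frames both spend ON together; C ranges 0 (disjoint) to 1 (identical).
Significance of each pair is assessed against a permutation null built by
randomizing the binarized rows; cells holding 60-100% of the correlated
links (relative to the most-linked cell of the islet) are classified as
hubs and can be drawn on a functional connectivity map at their Euclidean
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .traces import BinaryRaster

__all__ = [
    "CoactivityResult",
    "HubClassification",
    "ConnectivityMap",
    "coactivity_matrix",
    "permutation_significance",
    "classify_hubs",
    "connectivity_summary",
    "build_connectivity_map",
]


@dataclass
class CoactivityResult:
    """Symmetric co-activity matrix with (optionally) its permutation test."""

    C: np.ndarray
    T_on: np.ndarray
    T_joint: np.ndarray
    cell_ids: list[str]
    p_values: np.ndarray | None = None
    adjacency: np.ndarray | None = None
    alpha: float | None = None
    n_permutations: int | None = None

    @property
    def n_cells(self) -> int:
        return len(self.T_on)

    @property
    def active(self) -> np.ndarray:
        return self.T_on > 0

    def link_counts(self) -> np.ndarray:
        if self.adjacency is None:
            raise ValueError("permutation significance has not been computed")
        return self.adjacency.sum(axis=1).astype(int)


def coactivity_matrix(raster: BinaryRaster) -> CoactivityResult:
    """C_ij, T_i and T_ij for all cell pairs of a binary raster.

    Pairs involving an all-OFF (inactive) cell get C = 0; such cells are
    flagged via ``result.active``.
    """
    S = raster.states.astype(np.float64)
    if S.size == 0:
        raise ValueError("raster is empty")
    T_on = S.sum(axis=1)
    T_joint = S @ S.T
    denom = np.sqrt(np.outer(T_on, T_on))
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(denom > 0, T_joint / denom, 0.0)
    return CoactivityResult(
        C=C,
        T_on=T_on.astype(int),
        T_joint=T_joint.astype(int),
        cell_ids=list(raster.cell_ids),
    )


def _circular_crosscorr_counts(fi: np.ndarray, fj: np.ndarray, n: int) -> np.ndarray:
    """Joint ON counts of two rows at every relative circular lag (integers)."""
    cc = np.fft.irfft(fi * np.conj(fj), n=n)
    return np.rint(cc).astype(np.int64)


def permutation_significance(
    raster: BinaryRaster,
    coact: CoactivityResult | None = None,
    *,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    scheme: str = "circular_shift",
    bh_correction: bool = False,
) -> CoactivityResult:
    """Per-pair permutation p-values and the significant-link adjacency.

    Each binarized row is randomized independently per permutation —
    by a random circular shift (default; preserves each cell's burst-length
    autocorrelation while destroying cross-cell alignment) or by a full
    shuffle of its frames.  The p-value uses the add-one estimator
    ``p = (1 + #{T_null >= T_obs}) / (1 + n_permutations)`` so it is never
    exactly zero; pairs involving an inactive cell get p = 1.

    For the circular-shift scheme only the relative shift of a pair matters,
    so the null statistic for pair (i, j) at permutation k is the circular
    cross-correlation of the two rows evaluated at lag ``d_j[k] - d_i[k]``;
    the cross-correlations are computed once per pair by FFT, which makes the
    test fast without changing its definition.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    if scheme not in ("circular_shift", "full_shuffle"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    if coact is None:
        coact = coactivity_matrix(raster)
    n, T = raster.n_cells, raster.n_frames
    rng = np.random.default_rng(seed)
    active = coact.active

    counts = np.zeros((n, n), dtype=np.int64)
    if scheme == "circular_shift":
        shifts = rng.integers(0, T, size=(n_permutations, n))
        F = np.fft.rfft(raster.states.astype(np.float64), axis=1)
        for i in range(n):
            if not active[i]:
                continue
            for j in range(i + 1, n):
                if not active[j]:
                    continue
                cc = _circular_crosscorr_counts(F[i], F[j], T)
                lags = (shifts[:, j] - shifts[:, i]) % T
                counts[i, j] = int(np.sum(cc[lags] >= coact.T_joint[i, j]))
    else:  # full_shuffle
        S = raster.states
        obs = coact.T_joint
        for _ in range(n_permutations):
            perm = np.empty_like(S)
            for i in range(n):
                perm[i] = S[i, rng.permutation(T)]
            null_joint = perm.astype(np.int64) @ perm.T.astype(np.int64)
            counts += (null_joint >= obs).astype(np.int64)
        counts = np.triu(counts, k=1)

    p = np.ones((n, n))
    iu = np.triu_indices(n, k=1)
    p[iu] = (1.0 + counts[iu]) / (1.0 + n_permutations)
    p = np.minimum(p, p.T)
    pair_ok = np.outer(active, active)
    p[~pair_ok] = 1.0
    np.fill_diagonal(p, 1.0)

    if bh_correction:
        flat = p[iu][pair_ok[iu]]
        order = np.argsort(flat)
        m = len(flat)
        adj_p = np.empty(m)
        ranked = flat[order] * m / (np.arange(m) + 1)
        adj_p[order] = np.minimum.accumulate(ranked[::-1])[::-1]
        q = np.ones((n, n))
        tmp = q[iu]
        tmp[pair_ok[iu]] = np.clip(adj_p, 0, 1)
        q[iu] = tmp
        q = np.minimum(q, q.T)
        np.fill_diagonal(q, 1.0)
        decision = q
    else:
        decision = p

    adjacency = (decision <= alpha) & pair_ok
    np.fill_diagonal(adjacency, False)

    coact.p_values = p
    coact.adjacency = adjacency
    coact.alpha = alpha
    coact.n_permutations = n_permutations
    return coact


@dataclass
class HubClassification:
    """Per-cell hub call from the significant-link degree distribution."""

    link_count: np.ndarray
    link_percent: np.ndarray
    is_hub: np.ndarray
    hub_fraction: float
    threshold_percent: float
    cell_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "link_count": self.link_count,
                "link_percent": self.link_percent,
                "is_hub": self.is_hub,
            }
        )


def classify_hubs(
    coact: CoactivityResult,
    threshold_percent: float = 60.0,
    *,
    normalization: str = "max_observed",
) -> HubClassification:
    """Flag cells holding ``threshold_percent``-100% of the correlated links.

    ``link_percent`` expresses each cell's significant-link count as a
    percentage of the best-connected cell of the same islet
    (``normalization="max_observed"``, default) or of the maximum possible
    degree ``n_active - 1`` (``normalization="n_minus_1"``).  Ties at the
    threshold are hubs (>= comparison).  ``hub_fraction`` counts hubs among
    active cells only.
    """
    if coact.adjacency is None:
        raise ValueError("classify_hubs requires permutation significance first")
    if normalization not in ("max_observed", "n_minus_1"):
        raise ValueError(f"unknown normalization {normalization!r}")
    counts = coact.link_counts()
    active = coact.active
    n_active = int(active.sum())
    if normalization == "max_observed":
        denom = counts.max()
    else:
        denom = max(n_active - 1, 0)
    if denom == 0:
        percent = np.zeros_like(counts, dtype=float)
    else:
        percent = 100.0 * counts / denom
    is_hub = (percent >= threshold_percent) & (counts > 0)
    hub_fraction = float(is_hub.sum() / n_active) if n_active else 0.0
    return HubClassification(
        link_count=counts,
        link_percent=percent,
        is_hub=is_hub,
        hub_fraction=hub_fraction,
        threshold_percent=threshold_percent,
        cell_ids=list(coact.cell_ids),
    )


def connectivity_summary(coact: CoactivityResult) -> dict:
    """Population-level connectivity indices.

    Returns the percentage of significantly co-active pairs among all
    active-cell pairs, the mean C over significant pairs, and the per-cell
    link-count histogram.
    """
    if coact.adjacency is None:
        raise ValueError("connectivity_summary requires permutation significance")
    active = coact.active
    n_active = int(active.sum())
    n_pairs = n_active * (n_active - 1) // 2
    iu = np.triu_indices(coact.n_cells, k=1)
    sig = coact.adjacency[iu]
    n_sig = int(sig.sum())
    pct = 100.0 * n_sig / n_pairs if n_pairs else 0.0
    mean_sig_c = float(coact.C[iu][sig].mean()) if n_sig else float("nan")
    counts = coact.link_counts()
    hist = np.bincount(counts, minlength=1)
    return {
        "n_active_cells": n_active,
        "n_pairs": n_pairs,
        "n_significant_pairs": n_sig,
        "percent_connected_pairs": pct,
        "mean_significant_C": mean_sig_c,
        "link_count_histogram": hist.tolist(),
    }


@dataclass
class ConnectivityMap:
    """Node/edge structure of the islet network at Euclidean coordinates."""

    nodes: pd.DataFrame  # cell_id, x, y, link_count, link_percent, is_hub
    edges: pd.DataFrame  # cell_a, cell_b, C, p
    _node_index: dict = field(default_factory=dict, repr=False)

    def write(self, outdir: str | Path, *, render: bool = True) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.nodes.to_csv(outdir / "nodes.csv", index=False, float_format="%.9g")
        self.edges.to_csv(outdir / "edges.csv", index=False, float_format="%.9g")
        if render:
            self.render(outdir / "connectivity_map.png")

    def render(self, path: str | Path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 6))
        pos = {r.cell_id: (r.x, r.y) for r in self.nodes.itertuples()}
        for r in self.edges.itertuples():
            (x0, y0), (x1, y1) = pos[r.cell_a], pos[r.cell_b]
            ax.plot([x0, x1], [y0, y1], color="0.7", lw=0.5, zorder=1)
        hubs = self.nodes[self.nodes.is_hub]
        rest = self.nodes[~self.nodes.is_hub]
        ax.scatter(rest.x, rest.y, s=25, c="tab:blue", zorder=2, label="cell")
        ax.scatter(
            hubs.x, hubs.y, s=60, c="tab:red", zorder=3, label="hub", edgecolors="k"
        )
        ax.set_aspect("equal")
        ax.set_xlabel("x (a.u.)")
        ax.set_ylabel("y (a.u.)")
        ax.legend(loc="upper right", fontsize=8)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def build_connectivity_map(
    coact: CoactivityResult,
    hubs: HubClassification,
    coords: np.ndarray,
) -> ConnectivityMap:
    """Assemble node table and significant-edge list on islet coordinates."""
    coords = np.asarray(coords, dtype=float)
    n = coact.n_cells
    if coords.shape != (n, 2) or not np.all(np.isfinite(coords)):
        missing = (
            [coact.cell_ids[i] for i in np.where(~np.isfinite(coords).all(axis=1))[0]]
            if coords.shape == (n, 2)
            else coact.cell_ids
        )
        raise ValueError("missing coordinates for cells: " + ", ".join(missing))
    if coact.adjacency is None:
        raise ValueError("build_connectivity_map requires permutation significance")
    nodes = pd.DataFrame(
        {
            "cell_id": coact.cell_ids,
            "x": coords[:, 0],
            "y": coords[:, 1],
            "link_count": hubs.link_count,
            "link_percent": hubs.link_percent,
            "is_hub": hubs.is_hub,
        }
    )
    ia, ja = np.where(np.triu(coact.adjacency, k=1))
    edges = pd.DataFrame(
        {
            "cell_a": [coact.cell_ids[i] for i in ia],
            "cell_b": [coact.cell_ids[j] for j in ja],
            "C": coact.C[ia, ja],
            "p": coact.p_values[ia, ja],
        }
    )
    return ConnectivityMap(nodes=nodes, edges=edges)
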