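"""Empirical mode decomposition (Hilbert–Huang sifting) for 1-D fluorescence traces.

EMD adaptively splits a signal into intrinsic mode functions (IMFs) — locally
zero-mean oscillations ordered fast to slow — plus a monotone-ish residue.
Here it serves to strip shot noise (fast IMFs) and baseline drift (the residue
and very slow IMFs) from Ca2+ recordings before binarization.

The sifting loop follows the classical recipe: cubic-spline envelopes through
the local maxima and minima, subtract the envelope mean, iterate until a
Cauchy-type SD criterion falls below ``sd_stop``, then peel the IMF off and
repeat on the remainder.  Boundaries are handled by mirroring extrema so the
splines do not swing wildly at the edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["EmdDecomposition", "emd_decompose", "mean_period_s"]


@dataclass
class EmdDecomposition:
    """Result of sifting one trace: ``sum(imfs) + residue == signal``.

    imfs are ordered from highest frequency (index 0) to lowest.
    """

    imfs: list[np.ndarray] = field(default_factory=list)
    residue: np.ndarray = None  # type: ignore[assignment]

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima; plateau midpoints count once."""
    dx = np.diff(x)
    # collapse flat segments: sign of slope, carrying the last nonzero sign forward
    sign = np.sign(dx)
    nz = sign != 0
    if not nz.any():
        return np.array([], dtype=int), np.array([], dtype=int)
    # forward-fill zero signs so a plateau inherits the approach slope
    idx = np.where(nz, np.arange(len(sign)), -1)
    np.maximum.accumulate(idx, out=idx)
    filled = np.where(idx >= 0, sign[np.clip(idx, 0, None)], 0)
    turn = np.diff(filled)
    maxima = np.where(turn < 0)[0] + 1
    minima = np.where(turn > 0)[0] + 1
    return maxima, minima


def _mirror_extend(idx: np.ndarray, val: np.ndarray, n: int, n_mirror: int = 2):
    """Reflect up to ``n_mirror`` extrema about each end of the record."""
    if len(idx) == 0:
        return idx, val
    left_i = 2 * idx[0] - idx[1 : n_mirror + 1][::-1] if len(idx) > 1 else -idx[:1]
    left_v = val[1 : n_mirror + 1][::-1] if len(idx) > 1 else val[:1]
    right_i = (
        2 * idx[-1] - idx[-n_mirror - 1 : -1][::-1]
        if len(idx) > 1
        else 2 * (n - 1) - idx[-1:]
    )
    right_v = val[-n_mirror - 1 : -1][::-1] if len(idx) > 1 else val[-1:]
    # keep mirrors strictly outside the record
    lm = left_i < idx[0]
    rm = right_i > idx[-1]
    ei = np.concatenate([left_i[lm], idx, right_i[rm]])
    ev = np.concatenate([left_v[lm], val, right_v[rm]])
    order = np.argsort(ei)
    ei, ev = ei[order], ev[order]
    keep = np.concatenate([[True], np.diff(ei) > 0])
    return ei[keep], ev[keep]


def _envelope_mean(x: np.ndarray) -> np.ndarray | None:
    """Mean of upper/lower cubic-spline envelopes, or None if too few extrema."""
    maxima, minima = _local_extrema(x)
    if len(maxima) < 2 or len(minima) < 2:
        return None
    n = len(x)
    t = np.arange(n)
    mi, mv = _mirror_extend(maxima, x[maxima], n)
    ni, nv = _mirror_extend(minima, x[minima], n)
    upper = CubicSpline(mi, mv)(t)
    lower = CubicSpline(ni, nv)(t)
    return 0.5 * (upper + lower)


def _is_monotone(x: np.ndarray) -> bool:
    dx = np.diff(x)
    return bool(np.all(dx >= 0) or np.all(dx <= 0))


def emd_decompose(
    trace: np.ndarray,
    *,
    sd_stop: float = 0.2,
    max_siftings: int = 50,
    max_imfs: int = 12,
) -> EmdDecomposition:
    """Decompose a single trace into IMFs plus residue.

    Parameters
    ----------
    trace
        1-D array, at least 8 finite samples.
    sd_stop
        Cauchy SD stop criterion: sifting of one IMF ends when
        ``sum((h_prev - h)**2) / sum(h_prev**2) < sd_stop``.
    max_siftings
        Cap on sifting iterations per IMF.
    max_imfs
        Cap on extracted IMFs; whatever remains becomes the residue.

    Returns
    -------
    EmdDecomposition
        With ``sum(imfs) + residue`` equal to the input to float round-off.
    """
    x = np.asarray(trace, dtype=float).ravel()
    if x.size < 8:
        raise ValueError(f"EMD needs >= 8 samples, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("EMD input contains non-finite values")

    dec = EmdDecomposition()
    residual = x.copy()
    for _ in range(max_imfs):
        if _is_monotone(residual):
            break
        h = residual.copy()
        extracted = False
        for _ in range(max_siftings):
            mean_env = _envelope_mean(h)
            if mean_env is None:
                break
            h_new = h - mean_env
            denom = float(np.sum(h * h))
            if denom == 0.0:
                h = h_new
                extracted = True
                break
            sd = float(np.sum((h - h_new) ** 2)) / denom
            h = h_new
            extracted = True
            if sd < sd_stop:
                break
        if not extracted:
            break
        dec.imfs.append(h)
        residual = residual - h
    dec.residue = residual
    return dec


def mean_period_s(imf: np.ndarray, frame_rate_hz: float) -> float:
    """Crude mean oscillation period of an IMF from its zero-crossing count.

    A full period contains two zero crossings, so the mean period is
    ``2 * duration / n_crossings``; an IMF with fewer than two crossings is
    treated as slower than the record (period = +inf).
    """
    x = np.asarray(imf, dtype=float)
    s = np.sign(x)
    s = s[s != 0]
    crossings = int(np.sum(s[1:] != s[:-1]))
    if crossings < 2:
        return float("inf")
    duration = len(x) / float(frame_rate_hz)
    return 2.0 * duration / crossings
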