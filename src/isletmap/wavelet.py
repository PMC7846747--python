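"""Bias-corrected continuous Morlet wavelet spectra of Ca2+ traces.

The transform follows the standard Torrence & Compo parameterization: a
Morlet mother wavelet with omega0 = 6, dyadic scales from 2*dt up to half
the record at resolution ``dj`` octaves, computed by FFT convolution with
zero padding to the next power of two.  Raw wavelet power |W|^2 grows with
scale for equal-amplitude oscillations; dividing by scale (the Liu-style
bias correction) equalizes power across periods so slow oscillations are
not artificially favored.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["WaveletSpectrum", "morlet_cwt", "dominant_period"]

OMEGA0 = 6.0
#: Fourier period per unit scale for the omega0=6 Morlet wavelet (~1.033).
FOURIER_FACTOR = 4.0 * np.pi / (OMEGA0 + np.sqrt(2.0 + OMEGA0**2))


@dataclass
class WaveletSpectrum:
    """Bias-corrected power on a period x time grid with cone of influence."""

    power: np.ndarray  # (n_periods, n_times), |W|^2 / scale
    periods_s: np.ndarray  # increasing
    times_s: np.ndarray  # increasing
    coi_s: np.ndarray  # max reliable period per time point
    scales: np.ndarray

    def time_averaged_power(self, *, inside_coi: bool = False) -> np.ndarray:
        """Mean power per period, optionally masking the cone of influence."""
        if not inside_coi:
            return self.power.mean(axis=1)
        mask = self.periods_s[:, None] <= self.coi_s[None, :]
        with np.errstate(invalid="ignore"):
            out = np.where(mask, self.power, np.nan)
        return np.nanmean(out, axis=1)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.power,
            index=pd.Index(self.periods_s, name="period_s"),
            columns=[f"{t:.9g}" for t in self.times_s],
        )
        df.to_csv(path, float_format="%.9g")

    def render(self, path: str | Path) -> None:
        """Period-vs-time heatmap with the cone of influence overlaid."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 4))
        mesh = ax.pcolormesh(
            self.times_s, self.periods_s, self.power, shading="auto", cmap="viridis"
        )
        ax.plot(self.times_s, self.coi_s, "w--", lw=1)
        ax.set_yscale("log")
        ax.set_ylim(self.periods_s[0], self.periods_s[-1])
        ax.invert_yaxis()
        ax.set_xlabel("time (s)")
        ax.set_ylabel("period (s)")
        fig.colorbar(mesh, ax=ax, label="bias-corrected power")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def morlet_cwt(
    trace: np.ndarray,
    frame_rate_hz: float,
    *,
    dj: float = 1.0 / 12.0,
    detrend_mean: bool = True,
) -> WaveletSpectrum:
    """Continuous Morlet (omega0=6) transform with |W|^2/scale power.

    Parameters
    ----------
    trace
        Detrended single-cell series, at least 32 samples.
    frame_rate_hz
        Sampling rate; dt = 1/frame_rate_hz.
    dj
        Scale resolution in octaves (default 1/12: twelve sub-octaves).
    detrend_mean
        Remove the series mean before transforming (the zero-frequency
        offset otherwise leaks into the largest scales).
    """
    x = np.asarray(trace, dtype=float).ravel()
    n = x.size
    if n < 32:
        raise ValueError(f"wavelet transform needs >= 32 samples, got {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("wavelet input contains non-finite values")
    dt = 1.0 / frame_rate_hz
    if detrend_mean:
        x = x - x.mean()

    # zero-pad to next power of two
    n_pad = int(2 ** np.ceil(np.log2(n)))
    xp = np.zeros(n_pad)
    xp[:n] = x
    fx = np.fft.fft(xp)
    omega = 2.0 * np.pi * np.fft.fftfreq(n_pad, d=dt)

    # dyadic scales: s0 = 2 dt up to half the record
    s0 = 2.0 * dt
    j_max = int(np.floor(np.log2(n * dt / (2.0 * s0)) / dj))
    scales = s0 * 2.0 ** (dj * np.arange(j_max + 1))

    # Morlet daughter in frequency space, analytic (positive frequencies)
    norm = np.sqrt(2.0 * np.pi * scales[:, None] / dt) * np.pi**-0.25
    arg = scales[:, None] * omega[None, :] - OMEGA0
    daughter = norm * np.exp(-0.5 * arg**2) * (omega[None, :] > 0)
    W = np.fft.ifft(fx[None, :] * daughter, axis=1)[:, :n]

    power = np.abs(W) ** 2 / scales[:, None]  # bias correction
    periods = FOURIER_FACTOR * scales
    times = np.arange(n) * dt
    # cone of influence: e-folding time sqrt(2)*s of the Morlet envelope,
    # expressed as the largest trustworthy period at each time point
    edge = np.minimum(times, times[-1] - times)
    coi = FOURIER_FACTOR / np.sqrt(2.0) * np.maximum(edge, dt * 1e-9)
    return WaveletSpectrum(
        power=power, periods_s=periods, times_s=times, coi_s=coi, scales=scales
    )


def dominant_period(
    spectrum: WaveletSpectrum,
    window_s: tuple[float, float] | None = None,
) -> tuple[np.ndarray, float]:
    """Per-time dominant oscillation period and its window median.

    At each time point inside ``window_s`` the period of maximum
    bias-corrected power is taken, considering only periods inside the cone
    of influence; time points whose entire period axis lies outside the COI
    are excluded.  Returns the per-time series (NaN outside the window or
    COI) and the median over valid points.
    """
    t = spectrum.times_s
    if window_s is None:
        window_s = (float(t[0]), float(t[-1]))
    lo, hi = window_s
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9 or lo >= hi:
        raise ValueError(f"window {window_s} outside record [{t[0]}, {t[-1]}]")
    in_win = (t >= lo) & (t <= hi)
    valid_period = spectrum.periods_s[:, None] <= spectrum.coi_s[None, :]
    masked = np.where(valid_period, spectrum.power, -np.inf)
    best = np.argmax(masked, axis=0)
    any_valid = valid_period.any(axis=0)
    series = np.where(in_win & any_valid, spectrum.periods_s[best], np.nan)
    if not np.any(np.isfinite(series)):
        raise ValueError("window lies entirely outside the cone of influence")
    return series, float(np.nanmedian(series))
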