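"""Reflectance-to-absorbance conversion and Savitzky-Golay smoothing.

The study pipeline converts reflectance R to absorbance A = log10(1/R)
(Beer-Lambert heuristic: absorbance is approximately linear in pigment
concentration) and then smooths each absorbance spectrum with a
Savitzky-Golay filter, first-order polynomial, window of 15 bands. The
order matters: smoothing is applied to the absorbance, never the other
way round.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .spectra_io import SpectraSet, SpectraError


@dataclass(frozen=True)
class SGConfig:
    """Savitzky-Golay smoother settings.

    window
        Odd window length in bands (default 15).
    polyorder
        Local polynomial degree (default 1); must be < window.
    edge_policy
        ``"polyfit-extend"`` evaluates the edge-window polynomial at the
        edge positions (no bands are discarded); ``"shrink-window"``
        shrinks the window symmetrically towards the spectrum ends.
    """

    window: int = 15
    polyorder: int = 1
    edge_policy: str = "polyfit-extend"

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 3, got {self.window}")
        if self.polyorder < 0 or self.polyorder >= self.window:
            raise ValueError(
                f"polyorder must satisfy 0 <= polyorder < window, "
                f"got {self.polyorder} vs window {self.window}"
            )
        if self.edge_policy not in ("polyfit-extend", "shrink-window"):
            raise ValueError(f"unknown edge_policy {self.edge_policy!r}")


def reflectance_to_absorbance(s: SpectraSet) -> SpectraSet:
    """A = log10(1/R), elementwise. Requires reflectance in (0, 1]."""
    if s.mode != "reflectance":
        raise SpectraError(f"expected reflectance spectra, got mode {s.mode!r}")
    if (s.values <= 0).any():
        raise SpectraError("reflectance <= 0 encountered; log10(1/R) undefined")
    return replace(s, values=np.log10(1.0 / s.values), mode="absorbance")


def _check_uniform_grid(wavelengths: np.ndarray, rtol: float = 1e-6) -> float:
    steps = np.diff(wavelengths)
    step = steps.mean()
    if np.any(np.abs(steps - step) > rtol * abs(step)):
        raise SpectraError(
            "wavelength grid is not uniform; resample before Savitzky-Golay "
            "smoothing"
        )
    return step


def _shrink_window_filter(row: np.ndarray, window: int, polyorder: int) -> np.ndarray:
    out = savgol_filter(row, window, polyorder, mode="interp")
    half = window // 2
    n = row.size
    # near each end, refit with the largest symmetric odd window that fits
    for i in range(half):
        for pos in (i, n - 1 - i):
            w = 2 * i + 1
            if w <= polyorder:
                out[pos] = row[pos]  # too few points: fit interpolates
                continue
            lo, hi = pos - i, pos + i + 1
            x = np.arange(lo, hi) - pos
            coefs = np.polynomial.polynomial.polyfit(x, row[lo:hi], polyorder)
            out[pos] = coefs[0]
    return out


def sg_filter(values: np.ndarray, cfg: SGConfig | None = None) -> np.ndarray:
    """Exact Savitzky-Golay filter on rows of a plain array.

    This is the linear filter itself: each output point is the local
    least-squares polynomial fit of degree ``polyorder`` over ``window``
    points, evaluated at the window centre (and at the edge positions
    according to the edge policy). No range clipping is applied.
    """
    cfg = cfg or SGConfig()
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[1] < cfg.window:
        raise SpectraError(
            f"need at least window={cfg.window} points, got {values.shape[1]}"
        )
    if cfg.edge_policy == "polyfit-extend":
        return savgol_filter(values, cfg.window, cfg.polyorder, axis=1, mode="interp")
    return np.vstack(
        [_shrink_window_filter(row, cfg.window, cfg.polyorder) for row in values]
    )


def savgol_smooth(s: SpectraSet, cfg: SGConfig | None = None) -> SpectraSet:
    """Row-wise Savitzky-Golay filtering on a uniform wavelength grid.

    Each spectrum is independently replaced by its local least-squares
    polynomial fit evaluated at the window centre; spectra are never mixed
    across samples. Mode and grid are unchanged. For absorbance spectra the
    output is floored at zero: edge polynomial extrapolation can undershoot
    on near-zero baselines, and absorbance is non-negative by definition.
    """
    cfg = cfg or SGConfig()
    _check_uniform_grid(s.wavelengths)
    smoothed = sg_filter(s.values, cfg)
    if s.mode == "absorbance":
        smoothed = np.maximum(smoothed, 0.0)
    else:  # edge extrapolation may overshoot the physical reflectance range
        smoothed = np.clip(smoothed, np.finfo(float).tiny, 1.0)
    return replace(s, values=smoothed)


def trim_wavelengths(s: SpectraSet, lo: float, hi: float) -> SpectraSet:
    """Restrict to the half-open interval ``[lo, hi)`` nm (optional step;
    noisy spectral ends are kept by default)."""
    return s.band(lo, hi)


def preprocess(
    s: SpectraSet,
    sg: SGConfig | None = None,
    trim: tuple[float, float] | None = None,
) -> SpectraSet:
    """Standard chain: optional trim, absorbance transform, SG smoothing."""
    if trim is not None:
        s = trim_wavelengths(s, *trim)
    if s.mode == "reflectance":
        s = reflectance_to_absorbance(s)
    return savgol_smooth(s, sg)
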