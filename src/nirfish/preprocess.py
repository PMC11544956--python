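"""Spectral pretreatments.

Four stages, applied in this order when a model is built:

1. one row-local pretreatment — SNV scatter correction, or a 5-point
   quadratic Savitzky–Golay first/second derivative (the three compete as
   alternatives in the report);
2. optional paired-day centering, which subtracts each analysis day's mean
   spectrum so every control/treated fish pair is expressed relative to its
   own average (this is what removes fish-level biological variability);
3. column autoscaling with training-set means/sds (fit/apply split so
   cross-validation cannot leak held-out rows into the scaling).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_coeffs

from .labels import SpectrumSet

PRETREATMENTS = ("snv", "der1", "der2")


def snv(spectra: SpectrumSet) -> SpectrumSet:
    """Standard normal variate: centre and scale each spectrum (row).

    Removes additive offsets and multiplicative scatter per acquisition.
    Uses the n-1 standard-deviation denominator.
    """
    X = spectra.intensities
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    zero = np.flatnonzero(sd.ravel() == 0)
    if zero.size:
        raise ValueError(f"constant spectrum in row(s) {zero.tolist()}: SNV undefined")
    return spectra.replace_intensities((X - mu) / sd)


def sg_coefficients(derivative_order: int) -> np.ndarray:
    """5-point quadratic Savitzky–Golay derivative weights (index units).

    Returned in dot-product order for a window ``x[i-2..i+2]``.
    """
    if derivative_order not in (1, 2):
        raise ValueError("derivative_order must be 1 or 2")
    return savgol_coeffs(5, 2, deriv=derivative_order, delta=1.0, use="dot")


def sg_derivative(spectra: SpectrumSet, derivative_order: int, spacing_rtol: float = 0.05) -> SpectrumSet:
    """Savitzky–Golay derivative, window 5, quadratic fit.

    The derivative is taken per index step (the grid is treated as uniform;
    a global 1/Δλ scale would not change any classification).  Two
    wavelengths are dropped at each edge, so p -> p-4.
    """
    p = spectra.n_wavelengths
    if p < 5:
        raise ValueError(f"need at least 5 wavelengths for a 5-point window, got {p}")
    steps = np.diff(spectra.wavelengths)
    if np.max(np.abs(steps / steps.mean() - 1.0)) > spacing_rtol:
        raise ValueError("wavelength grid is non-uniform beyond tolerance")
    c = sg_coefficients(derivative_order)
    windows = np.lib.stride_tricks.sliding_window_view(spectra.intensities, 5, axis=1)
    out = windows @ c
    return spectra.replace_intensities(out, wavelengths=spectra.wavelengths[2:-2])


def pair_center(spectra: SpectrumSet) -> SpectrumSet:
    """Centre every row on its analysis day's mean spectrum.

    Each day holds one control and one treated fish (all replicates); the
    day mean is computed over both classes together, so the operation never
    looks at class identity and can be applied to held-out days unchanged.
    """
    X = spectra.intensities.copy()
    for d in np.unique(spectra.day):
        rows = spectra.day == d
        groups = {l.group for l, m in zip(spectra.labels, rows) if m}
        if groups != {"C", "T"}:
            raise ValueError(f"day {d} lacks a control/treated pair (groups present: {sorted(groups)})")
        X[rows] -= X[rows].mean(axis=0)
    return spectra.replace_intensities(X)


@dataclass
class AutoscaleParams:
    """Training-set per-wavelength means and sds (n-1 denominator)."""

    means: np.ndarray
    sds: np.ndarray

    def to_json(self) -> str:
        return json.dumps({"means": self.means.tolist(), "sds": self.sds.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "AutoscaleParams":
        d = json.loads(text)
        return cls(np.array(d["means"], dtype=float), np.array(d["sds"], dtype=float))


def autoscale_fit(train: SpectrumSet | np.ndarray, wavelengths: np.ndarray | None = None) -> AutoscaleParams:
    """Column means/sds from the training rows only."""
    X = train.intensities if isinstance(train, SpectrumSet) else np.asarray(train, dtype=float)
    if wavelengths is None and isinstance(train, SpectrumSet):
        wavelengths = train.wavelengths
    if X.shape[0] < 2:
        raise ValueError("autoscaling needs at least 2 training rows")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    # sd of a constant column is ~1e-15 after mean subtraction, not 0
    const = np.flatnonzero(sds < 1e-12 * np.maximum(1.0, np.abs(means)))
    if const.size:
        names = wavelengths[const].tolist() if wavelengths is not None else const.tolist()
        raise ValueError(f"constant training column(s) at wavelength(s) {names}")
    return AutoscaleParams(means, sds)


def autoscale_apply(spectra: SpectrumSet | np.ndarray, params: AutoscaleParams):
    """(x - mean)/sd per column with the stored training parameters."""
    if isinstance(spectra, SpectrumSet):
        return spectra.replace_intensities((spectra.intensities - params.means) / params.sds)
    return (np.asarray(spectra, dtype=float) - params.means) / params.sds


def apply_pretreatment(spectra: SpectrumSet, name: str, day_center: bool = True,
                       snv_first: bool = False) -> SpectrumSet:
    """One named pretreatment (``snv`` | ``der1`` | ``der2``), then optional
    paired-day centering.

    ``snv_first`` chains SNV before a derivative instead of treating the
    three as alternatives (non-default reading of the pretreatment list).
    Autoscaling is *not* applied here: it belongs to model fitting, inside
    cross-validation folds.
    """
    if name == "snv":
        out = snv(spectra)
    elif name in ("der1", "der2"):
        out = snv(spectra) if snv_first else spectra
        out = sg_derivative(out, 1 if name == "der1" else 2)
    else:
        raise ValueError(f"unknown pretreatment {name!r} (expected one of {PRETREATMENTS})")
    if day_center:
        out = pair_center(out)
    return out
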