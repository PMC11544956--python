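"""Synthetic paired-design fish NIR spectra with known ground truth.

The generator emulates the study layout: 12 analysis days, one control and
one Cafodos-treated fish per day (days 1-6 carry the 3 h short-term pairs,
days 7-12 the 24 h long-term pairs), four sample matrices (eye, gill,
muscle, skin), three replicate spectra per fish and matrix, 125 wavelengths
over 908-1676 nm.

A spectrum is a sum of Gaussian absorbance bands: the dominant water O-H
first overtone near 1400 nm, a weak water band near 1000 nm, a lipid C-H
second-overtone band at 1150-1200 nm whose amplitude depends strongly on
the matrix (muscle > eye ~ gill > skin), and a C-H combination shoulder at
1330-1370 nm.  On top of the bands sit, in nested order: a per-fish
perturbation of every band amplitude plus a per-fish per-wavelength
"texture" (both shared by that fish's replicates — the biological
variability that, by default, exceeds the treatment effect), per-replicate
multiplicative scatter and additive offset, and white replicate noise.  Treated fish additionally receive term-specific band
amplitude deltas; by default the long-term deltas flip sign relative to
the short-term ones, mirroring the fresh-vs-treated versus stored-vs-
treated contrast the design encodes.

Every random quantity is drawn from one seeded stream in a fixed order,
and each draw is multiplied by its standard deviation afterwards — so
zeroing a variance component never shifts the remaining draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .labels import SampleLabel, SpectrumSet

WAVELENGTH_MIN = 908.0
WAVELENGTH_MAX = 1676.0


@dataclass(frozen=True)
class Band:
    """One Gaussian absorbance band: centre/width in nm, amplitude per matrix."""

    center: float
    sigma: float
    amplitude: dict[str, float]


#: Base band table.  Amplitudes are simulator calibration constants chosen to
#: reproduce the qualitative band structure (water dominant, lipid band
#: matrix-ordered muscle > eye ~ gill > skin), not measured values.
DEFAULT_BANDS = (
    Band(1400.0, 40.0, {"E": 1.00, "G": 1.00, "M": 1.00, "S": 1.00}),   # water O-H 1st overtone
    Band(1000.0, 30.0, {"E": 0.12, "G": 0.12, "M": 0.12, "S": 0.12}),   # weak water band
    Band(1180.0, 25.0, {"E": 0.12, "G": 0.12, "M": 0.30, "S": 0.03}),   # lipid C-H 2nd overtone
    Band(1350.0, 30.0, {"E": 0.25, "G": 0.25, "M": 0.25, "S": 0.25}),   # C-H combination shoulder
)

#: Default treatment effect: small band-amplitude shifts, opposite in sign
#: between short and long term, and well below the fish-level variability.
DEFAULT_DELTAS_SHORT = (
    Band(1400.0, 40.0, {m: +0.010 for m in "EGMS"}),
    Band(1180.0, 25.0, {m: -0.008 for m in "EGMS"}),
    Band(1350.0, 30.0, {m: +0.006 for m in "EGMS"}),
)
DEFAULT_DELTAS_LONG = (
    Band(1400.0, 40.0, {m: -0.010 for m in "EGMS"}),
    Band(1180.0, 25.0, {m: +0.008 for m in "EGMS"}),
    Band(1350.0, 30.0, {m: -0.006 for m in "EGMS"}),
)


@dataclass
class SyntheticStudyConfig:
    """Design dimensions, band model, variance components and effect sizes."""

    n_days: int = 12                      # half short-term, half long-term
    replicates: int = 3
    matrices: tuple[str, ...] = ("E", "G", "M", "S")
    n_wavelengths: int = 125
    wavelength_min: float = WAVELENGTH_MIN
    wavelength_max: float = WAVELENGTH_MAX
    bands: tuple[Band, ...] = DEFAULT_BANDS
    deltas_short: tuple[Band, ...] = DEFAULT_DELTAS_SHORT
    deltas_long: tuple[Band, ...] = DEFAULT_DELTAS_LONG
    fish_effect_sd: float = 0.04          # relative band-amplitude sd per fish
    fish_texture_sd: float = 0.02         # per-fish per-wavelength absorbance sd
    replicate_noise_sd: float = 0.003     # additive white noise per wavelength
    scatter_mult_sd: float = 0.05         # per-replicate multiplicative scatter
    offset_sd: float = 0.02               # per-replicate additive offset
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.matrices:
            raise ValueError("matrices list is empty")
        bad = [m for m in self.matrices if m not in "EGMS"]
        if bad:
            raise ValueError(f"unknown matrices {bad}")
        for name in ("fish_effect_sd", "fish_texture_sd", "replicate_noise_sd", "scatter_mult_sd", "offset_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_days < 2 or self.n_days % 2:
            raise ValueError("n_days must be even and >= 2 (half per exposure term)")

    def wavelength_grid(self) -> np.ndarray:
        return np.linspace(self.wavelength_min, self.wavelength_max, self.n_wavelengths)

    def max_delta(self) -> float:
        amps = [abs(a) for b in self.deltas_short + self.deltas_long for a in b.amplitude.values()]
        return max(amps, default=0.0)


def _band_profile(bands: tuple[Band, ...], matrix: str, wl: np.ndarray) -> np.ndarray:
    out = np.zeros_like(wl)
    for b in bands:
        amp = b.amplitude.get(matrix, 0.0)
        out += amp * np.exp(-0.5 * ((wl - b.center) / b.sigma) ** 2)
    return out


def _band_matrix(bands: tuple[Band, ...], matrix: str, wl: np.ndarray) -> np.ndarray:
    """Per-band profiles stacked (n_bands x p), for fish-level perturbations."""
    rows = []
    for b in bands:
        amp = b.amplitude.get(matrix, 0.0)
        rows.append(amp * np.exp(-0.5 * ((wl - b.center) / b.sigma) ** 2))
    return np.array(rows)


def simulate_study(config: SyntheticStudyConfig) -> tuple[SpectrumSet, dict]:
    """Generate the paired study and its ground truth.

    Returns the :class:`SpectrumSet` (labels follow the 9-character code;
    day indices 1..n_days) and a truth dict with the per-term treatment
    delta profiles, the affected wavelength indices, the per-fish band
    perturbations, and the config.
    """
    rng = np.random.default_rng(config.seed)
    wl = config.wavelength_grid()
    half = config.n_days // 2

    rows, labels, days = [], [], []
    fish_effects: dict[tuple[int, str], np.ndarray] = {}
    for day in range(1, config.n_days + 1):
        term = 3 if day <= half else 24
        control_fish, treated_fish = 2 * day - 1, 2 * day
        for matrix in config.matrices:
            base = _band_matrix(config.bands, matrix, wl)
            delta_bands = config.deltas_short if term == 3 else config.deltas_long
            delta = _band_profile(delta_bands, matrix, wl)
            for fish_id, group in ((control_fish, "C"), (treated_fish, "T")):
                # nested draws: fish-level band + texture perturbations first,
                # then replicates
                pert = config.fish_effect_sd * rng.standard_normal(len(config.bands))
                texture = config.fish_texture_sd * rng.standard_normal(wl.size)
                fish_effects[(fish_id, matrix)] = pert
                spectrum = base.sum(axis=0) + pert @ base + texture
                if group == "T":
                    spectrum = spectrum + delta
                for rep in range(1, config.replicates + 1):
                    mult = 1.0 + config.scatter_mult_sd * rng.standard_normal()
                    off = config.offset_sd * rng.standard_normal()
                    noise = config.replicate_noise_sd * rng.standard_normal(wl.size)
                    rows.append(mult * spectrum + off + noise)
                    # the label's fish field has two digits; beyond the study
                    # scale it wraps, and the day index disambiguates pairs
                    code_fish = (fish_id - 1) % 99 + 1
                    labels.append(SampleLabel(matrix, code_fish, group, term, rep))
                    days.append(day)

    spectra = SpectrumSet(wl, np.array(rows), labels, np.array(days))
    truth = {
        "delta_short": {m: _band_profile(config.deltas_short, m, wl) for m in config.matrices},
        "delta_long": {m: _band_profile(config.deltas_long, m, wl) for m in config.matrices},
        "affected_short": {m: _affected(_band_profile(config.deltas_short, m, wl)) for m in config.matrices},
        "affected_long": {m: _affected(_band_profile(config.deltas_long, m, wl)) for m in config.matrices},
        "fish_effects": fish_effects,
        "config": config,
    }
    return spectra, truth


def _affected(delta: np.ndarray, rel_threshold: float = 0.05) -> np.ndarray:
    """Wavelength indices whose |delta| exceeds 5% of the largest |delta|."""
    m = np.abs(delta).max()
    if m == 0:
        return np.array([], dtype=int)
    return np.flatnonzero(np.abs(delta) > rel_threshold * m)


#: Grid indices of the 10 narrow treatment bands in the "strong" preset.
STRONG_INFORMATIVE_INDEX = (15, 25, 35, 45, 55, 65, 75, 85, 95, 105)

#: Band amplitude of the "strong" treatment effect — calibrated once so the
#: full pipeline separates the classes perfectly while every informative
#: wavelength still carries only a partial share of the signal, then frozen.
STRONG_DELTA_AMPLITUDE = 0.10


def preset(name: str, seed: int = 0) -> SyntheticStudyConfig:
    """Named study conditions.

    ``null``    — no treatment effect at all (type-I calibration runs);
    ``weak``    — band deltas comparable to the fish-level variability;
    ``strong``  — ten narrow (sigma 2 nm) treatment bands centred on grid
                  points, alternating in sign and flipped between terms, so
                  exactly ten wavelengths are informative and the full
                  pipeline separates the classes perfectly.
    """
    base = SyntheticStudyConfig(seed=seed)
    if name == "null":
        return replace(base, deltas_short=(), deltas_long=())
    if name == "weak":
        scale = base.fish_effect_sd / 0.010  # push max |delta| up to the fish sd
        return replace(
            base,
            deltas_short=tuple(_scale_band(b, scale) for b in base.deltas_short),
            deltas_long=tuple(_scale_band(b, scale) for b in base.deltas_long),
        )
    if name == "strong":
        wl = base.wavelength_grid()
        short, long_ = [], []
        for k, idx in enumerate(STRONG_INFORMATIVE_INDEX):
            amp = STRONG_DELTA_AMPLITUDE * (1 if k % 2 == 0 else -1)
            short.append(Band(float(wl[idx]), 2.0, {m: amp for m in "EGMS"}))
            long_.append(Band(float(wl[idx]), 2.0, {m: -amp for m in "EGMS"}))
        return replace(base, deltas_short=tuple(short), deltas_long=tuple(long_))
    raise ValueError(f"unknown preset {name!r} (expected 'null', 'weak' or 'strong')")


def _scale_band(b: Band, scale: float) -> Band:
    return Band(b.center, b.sigma, {m: a * scale for m, a in b.amplitude.items()})
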