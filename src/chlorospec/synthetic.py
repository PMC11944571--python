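"""Synthetic leaf spectra and chlorophyll metadata.

The generator emulates the statistical structure of the study design:
5 species x 10 months (February-November) x 7 replicates = 350 leaf
samples, chlorophyll in mg g^-1 with the species means of the field data
(1.47, 1.95, 1.88, 1.10, 1.77), values clipped to the observed range
[0.79, 3.03], and a seasonal factor peaking in August.

Spectra are built with a light-weight additive-absorbance model (a
Beer-Lambert heuristic, deliberately not a radiative-transfer code such
as PROSPECT — the downstream pipeline only needs chlorophyll-correlated
features in the bands the field of leaf spectroscopy names):

    A(lambda) = baseline_species(lambda)
              + beta_vis * chl * B_vis(lambda)      # 500-640 nm window
              + beta_nir * chl * B_nir(lambda)      # 740-1100 nm shoulder
              + w * [G(lambda; 1450) + G(lambda; 1940)]   # leaf water
              + eps(lambda),   eps ~ N(0, sigma_A^2) iid

with raised-cosine pigment windows compactly supported on exactly
500-640 nm and 740-1100 nm, Gaussian water bands at 1450/1940 nm, smooth
seeded per-species baselines (one species gets a deviant 1200-2400 nm
baseline, mimicking the odd species of the field data), and per-sample
water content drawn independently of chlorophyll (an optional knob adds
correlation to study water confounding). Reflectance is R = 10^-A with A
capped into [1e-3, 4] so R stays in (0, 1].
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra_io import SpectraSet, write_metadata, write_spectra

SPECIES = (
    "Galium aparine",
    "Chrysanthemum indicum",
    "Cercis chinensis Bunge",
    "Cinnamomum camphora",
    "Spathiphyllum",
)
SPECIES_CHL_MEAN = (1.47, 1.95, 1.88, 1.10, 1.77)  # mg g^-1, field values
DEVIANT_SPECIES = "Cinnamomum camphora"  # distinct 1200-2400 nm baseline


def substream(seed: int, name: str) -> np.random.Generator:
    """Named random substream derived from a root seed, so adding one
    consumer never perturbs another."""
    return np.random.default_rng([int(seed), zlib.crc32(name.encode())])


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design and spectral-model parameters.

    Chlorophyll (mg g^-1): per-species means times a cosine seasonal
    factor peaking in August (amplitude ``seasonal_amp``), plus Gaussian
    noise ``sigma_chl``, clipped to ``chl_range``. Spectra: see module
    docstring; ``sigma_A`` is iid absorbance noise (default 0.005, a
    realistic bench-spectrometer noise floor after averaging).
    """

    seed: int
    n_months: int = 10
    month_start: int = 2                       # February
    n_reps: int = 7
    wl_start: float = 350.0
    wl_stop: float = 2500.0
    n_wavelengths: int = 2151                  # 1 nm grid by default
    species: tuple[str, ...] = SPECIES
    chl_means: tuple[float, ...] = SPECIES_CHL_MEAN
    chl_range: tuple[float, float] = (0.79, 3.03)
    seasonal_amp: float = 0.25
    seasonal_peak_month: int = 8               # August
    sigma_chl: float = 0.18
    vis_band: tuple[float, float] = (500.0, 640.0)
    nir_band: tuple[float, float] = (740.0, 1100.0)
    beta_vis: float = 0.22                     # absorbance per (mg g^-1)
    beta_nir: float = 0.10
    water_centers: tuple[float, float] = (1450.0, 1940.0)
    water_sigma: float = 45.0
    water_mean: float = 0.35
    water_sd: float = 0.08
    water_chl_corr: float = 0.0                # confounding knob, off by default
    baseline_level: float = 0.45
    baseline_species_sd: float = 0.06
    sigma_A: float = 0.005
    absorbance_cap: tuple[float, float] = (1e-3, 4.0)

    def __post_init__(self) -> None:
        if len(self.species) != len(self.chl_means):
            raise ValueError("species and chl_means lengths differ")
        if self.sigma_chl < 0 or self.sigma_A < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not (1 <= self.seasonal_peak_month <= 12):
            raise ValueError("seasonal_peak_month must be a calendar month")

    @property
    def months(self) -> tuple[int, ...]:
        return tuple(self.month_start + i for i in range(self.n_months))

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wl_start, self.wl_stop, self.n_wavelengths)


def seasonal_factor(month: np.ndarray | int, cfg: GeneratorConfig) -> np.ndarray:
    """Multiplicative seasonal factor, maximal at the peak month (cosine
    over a 12-month period)."""
    month = np.asarray(month, dtype=float)
    return 1.0 + cfg.seasonal_amp * np.cos(
        np.pi * (month - cfg.seasonal_peak_month) / 6.0
    )


def simulate_chlorophyll(cfg: GeneratorConfig) -> pd.DataFrame:
    """Sample-metadata table for the full design (one row per sample).

    chl(species, month, rep) = species_mean * seasonal_factor(month)
    + N(0, sigma_chl), clipped to the configured range.
    """
    rng = substream(cfg.seed, "chlorophyll")
    rows = []
    for si, sp in enumerate(cfg.species):
        for month in cfg.months:
            for rep in range(1, cfg.n_reps + 1):
                rows.append((f"S{si:02d}M{month:02d}R{rep}", sp, month, rep))
    meta = pd.DataFrame(rows, columns=["sample_id", "species", "month", "replicate"])
    means = dict(zip(cfg.species, cfg.chl_means))
    base = meta["species"].map(means).to_numpy()
    chl = base * seasonal_factor(meta["month"].to_numpy(), cfg)
    if cfg.sigma_chl > 0:
        chl = chl + rng.normal(0.0, cfg.sigma_chl, size=chl.size)
    chl = np.clip(chl, *cfg.chl_range)
    meta.insert(1, "chlorophyll", chl)
    return meta


def _raised_cosine(wl: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Smooth bump compactly supported on exactly [lo, hi] nm."""
    out = np.zeros_like(wl)
    inside = (wl >= lo) & (wl <= hi)
    out[inside] = 0.5 * (1 - np.cos(2 * np.pi * (wl[inside] - lo) / (hi - lo)))
    return out


def _gaussian(wl: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def species_baselines(cfg: GeneratorConfig) -> dict[str, np.ndarray]:
    """Smooth seeded per-species absorbance baselines: a shared gentle
    slope plus a few wide random Gaussian bumps per species; the deviant
    species gets an extra 1200-2400 nm excursion."""
    wl = cfg.wavelengths
    rng = substream(cfg.seed, "baselines")
    u = (wl - wl[0]) / (wl[-1] - wl[0])
    shared = cfg.baseline_level * (1.0 - 0.3 * u)
    out: dict[str, np.ndarray] = {}
    for sp in cfg.species:
        bumps = np.zeros_like(wl)
        for _ in range(4):
            center = rng.uniform(wl[0], wl[-1])
            width = rng.uniform(150.0, 450.0)
            amp = rng.normal(0.0, cfg.baseline_species_sd)
            bumps += amp * _gaussian(wl, center, width)
        if sp == DEVIANT_SPECIES:
            bumps += 0.12 * _raised_cosine(wl, 1200.0, 2400.0)
        out[sp] = np.maximum(shared + bumps, 0.02)
    return out


def simulate_spectra(meta: pd.DataFrame, cfg: GeneratorConfig) -> SpectraSet:
    """Reflectance spectra for a metadata table (see module docstring)."""
    wl = cfg.wavelengths
    rng_w = substream(cfg.seed, "water")
    rng_n = substream(cfg.seed, "spectral-noise")
    baselines = species_baselines(cfg)
    vis = _raised_cosine(wl, *cfg.vis_band)
    # NIR shoulder: raised cosine over the full 740-1100 window (zero outside)
    nir = _raised_cosine(wl, *cfg.nir_band)
    water_shape = sum(_gaussian(wl, c, cfg.water_sigma) for c in cfg.water_centers)

    chl = meta["chlorophyll"].to_numpy(dtype=float)
    z = rng_w.normal(size=chl.size)
    if cfg.water_chl_corr != 0.0:
        chl_std = (chl - chl.mean()) / max(chl.std(), 1e-12)
        z = cfg.water_chl_corr * chl_std + np.sqrt(1 - cfg.water_chl_corr**2) * z
    water = np.maximum(cfg.water_mean + cfg.water_sd * z, 0.0)

    A = np.empty((len(meta), wl.size))
    for i, sp in enumerate(meta["species"]):
        A[i] = (
            baselines[sp]
            + cfg.beta_vis * chl[i] * vis
            + cfg.beta_nir * chl[i] * nir
            + water[i] * water_shape
        )
    if cfg.sigma_A > 0:
        A += rng_n.normal(0.0, cfg.sigma_A, size=A.shape)
    lo, hi = cfg.absorbance_cap
    n_clipped = int(np.sum((A < lo) | (A > hi)))
    if n_clipped:
        import warnings

        warnings.warn(
            f"clipped {n_clipped} absorbance values into [{lo:g}, {hi:g}]",
            stacklevel=2,
        )
    A = np.clip(A, lo, hi)
    return SpectraSet(
        wavelengths=wl,
        values=np.power(10.0, -A),
        mode="reflectance",
        sample_ids=meta["sample_id"].tolist(),
    )


def simulate_dataset(cfg: GeneratorConfig) -> tuple[SpectraSet, pd.DataFrame]:
    """Full design: metadata plus matching reflectance spectra."""
    meta = simulate_chlorophyll(cfg)
    return simulate_spectra(meta, cfg), meta


def tiny_config(seed: int) -> GeneratorConfig:
    """3 species x 2 months x 2 reps on a 200-band grid — fast test size."""
    return GeneratorConfig(
        seed=seed,
        species=SPECIES[:3],
        chl_means=SPECIES_CHL_MEAN[:3],
        n_months=2,
        n_reps=2,
        n_wavelengths=200,
    )


def study_config(seed: int, **overrides) -> GeneratorConfig:
    """The full 350-sample x 2151-band study design."""
    return GeneratorConfig(seed=seed, **overrides)


def make_fixture(
    size: str, seed: int, out_dir: str | Path | None = None
) -> tuple[Path, Path] | tuple[SpectraSet, pd.DataFrame]:
    """Generate the tiny or study fixture; write CSVs when ``out_dir`` is
    given (regeneration with the same seed is byte-identical), otherwise
    return the in-memory pair."""
    if size == "tiny":
        cfg = tiny_config(seed)
    elif size == "study":
        cfg = study_config(seed)
    else:
        raise ValueError(f"unknown fixture size {size!r}")
    spectra, meta = simulate_dataset(cfg)
    if out_dir is None:
        return spectra, meta
    out_dir = Path(out_dir)
    spath = write_spectra(spectra, out_dir / "spectra.csv")
    mpath = write_metadata(meta, out_dir / "meta.csv")
    return spath, mpath
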