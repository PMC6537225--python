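"""Synthetic linear MALDI-TOF serum spectra with known ground truth.

Real reference sera for the TTR screen are not publicly deposited, so every
downstream stage is exercised against simulated spectra that emulate the
acquisition: a 1,000-20,000 Da window, Gaussian peaks whose width follows a
constant resolving power R (sigma = m / (R * 2.3548)), the reduced WT and
variant TTR monomers as a doublet in heterozygotes, the four protein
calibrants, optional doubly charged companions, an exponential chemical
baseline, heteroscedastic counting-like noise, and an optional affine
miscalibration of the m/z axis.

The defaults are the study conditions, not tuning knobs: a 1:1 allele ratio
for heterozygotes, calibrants on, and a resolving power chosen so that the
peak-splitting criterion of the detector places the two-peak resolution
limit just below 12 Da at the TTR mass — the platform's empirical minimum
identifiable shift (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .masses import (
    PointMutation,
    TTR_MATURE,
    WT_TTR_MONOMER_MASS,
    apply_mutation,
    average_mass,
    parse_mutation,
)
from .signal import Spectrum

__all__ = [
    "PROTON_MASS",
    "CALIBRANT_MASSES",
    "calibrant_masses",
    "SimulationConfig",
    "Genotype",
    "TruthRecord",
    "simulate_spectrum",
    "generate_cohort",
    "table1_genotypes",
]

#: Mass of a proton (Da), used for multiply charged companion ions.
PROTON_MASS = 1.00728

#: External calibrant average masses (Da): insulin, ubiquitin I,
#: cytochrome c, myoglobin — the standard intact-protein calibration mix.
CALIBRANT_MASSES = (5734.51, 8565.76, 12360.97, 16952.30)

_FWHM_PER_SIGMA = 2.3548200450309493

#: average mass added by S-cysteinylation of a free thiol (disulfide-linked Cys)
CYSTEINYLATION_MASS = 119.1442
#: average mass difference of an [M-H+Na] sodium adduct
SODIUM_ADDUCT_MASS = 21.9818


def calibrant_masses() -> list[float]:
    """The four calibrant masses, ascending."""
    return list(CALIBRANT_MASSES)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the spectrum generator; defaults define the study conditions."""

    mz_min: float = 1000.0
    mz_max: float = 20000.0
    grid_step: float = 0.5
    #: FWHM-based resolving power R = m / FWHM, constant across the window
    resolving_power: float = 1500.0
    #: fraction of total TTR ion current carried by the variant allele
    variant_fraction: float = 0.5
    baseline_amplitude: float = 60.0
    baseline_decay: float = 3000.0
    noise_sd_scale: float = 0.3
    include_calibrants: bool = True
    include_doubly_charged: bool = True
    miscal_slope: float = 1.0
    miscal_offset: float = 0.0
    seed: int = 0
    #: total TTR ion area (arbitrary units x Da), split between alleles
    ttr_area: float = 12000.0
    calibrant_area: float = 3000.0
    doubly_charged_fraction: float = 0.3
    #: flag-gated satellites, off by default: S-cysteinylation of Cys10
    #: (+119.14 Da; removed by DTT reduction in the assay being emulated)
    #: and sodium adducts (+21.98 Da), as area fractions of each TTR peak
    cysteinylated_fraction: float = 0.0
    sodium_adduct_fraction: float = 0.0

    def validate(self) -> None:
        if not self.mz_min < self.mz_max:
            raise ConfigError("mz_min must be < mz_max")
        if self.grid_step <= 0 or self.resolving_power <= 0:
            raise ConfigError("grid_step and resolving_power must be positive")
        if not 0.0 <= self.variant_fraction <= 1.0:
            raise ConfigError("variant_fraction must lie in [0, 1]")
        fwhm_ttr = WT_TTR_MONOMER_MASS / self.resolving_power
        if self.grid_step > fwhm_ttr / 3:
            raise ConfigError(
                f"grid_step {self.grid_step} Da too coarse for FWHM "
                f"{fwhm_ttr:.2f} Da at the TTR mass (need <= FWHM/3)"
            )


@dataclass(frozen=True)
class Genotype:
    """WT homozygote (mutation=None) or a heterozygous carrier of one variant."""

    mutation: PointMutation | None = None

    def __post_init__(self) -> None:
        if self.mutation is not None:
            apply_mutation(TTR_MATURE, self.mutation)  # validates vs reference

    @classmethod
    def from_label(cls, label: str) -> "Genotype":
        if label.strip().upper() == "WT":
            return cls(None)
        return cls(parse_mutation(label))

    @property
    def label(self) -> str:
        return "WT" if self.mutation is None else self.mutation.label


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth attached to each simulated spectrum."""

    genotype_label: str
    wt_mass: float
    variant_mass: float | None
    miscal_slope: float
    miscal_offset: float
    seed: int

    @property
    def true_shift(self) -> float | None:
        if self.variant_mass is None:
            return None
        return self.variant_mass - self.wt_mass


def _add_gaussian(
    grid: np.ndarray, signal: np.ndarray, center: float, sigma: float, area: float
) -> None:
    # evaluate only within +-8 sigma: negligible truncation, big speedup
    lo = np.searchsorted(grid, center - 8 * sigma)
    hi = np.searchsorted(grid, center + 8 * sigma)
    if hi <= lo:
        return
    x = grid[lo:hi]
    signal[lo:hi] += (
        area / (sigma * np.sqrt(2 * np.pi)) * np.exp(-((x - center) ** 2) / (2 * sigma**2))
    )


def simulate_spectrum(
    config: SimulationConfig, genotype: Genotype
) -> tuple[Spectrum, TruthRecord]:
    """One synthetic serum spectrum plus its ground truth.

    Identical (config, genotype) always yields an identical spectrum; the
    RNG is seeded from ``config.seed`` alone.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    grid = np.arange(config.mz_min, config.mz_max + config.grid_step / 2, config.grid_step)
    signal = np.zeros_like(grid)

    wt_mass = WT_TTR_MONOMER_MASS
    variant_mass = None
    species: list[tuple[float, float]] = []  # (neutral mass as singly-charged m/z, area)
    if genotype.mutation is None:
        species.append((wt_mass, config.ttr_area))
    else:
        variant_mass = average_mass(apply_mutation(TTR_MATURE, genotype.mutation))
        f = config.variant_fraction
        species.append((wt_mass, config.ttr_area * (1.0 - f)))
        species.append((variant_mass, config.ttr_area * f))
    for mass, area in list(species):  # TTR adduct satellites, if enabled
        if config.cysteinylated_fraction > 0:
            species.append((mass + CYSTEINYLATION_MASS, area * config.cysteinylated_fraction))
        if config.sodium_adduct_fraction > 0:
            species.append((mass + SODIUM_ADDUCT_MASS, area * config.sodium_adduct_fraction))
    if config.include_calibrants:
        species.extend((m, config.calibrant_area) for m in CALIBRANT_MASSES)

    ions = list(species)
    if config.include_doubly_charged:
        ions.extend(
            ((m + 2 * PROTON_MASS) / 2.0, a * config.doubly_charged_fraction)
            for m, a in species
        )

    for mz_ion, area in ions:
        if area <= 0:
            continue
        center = config.miscal_slope * mz_ion + config.miscal_offset
        sigma = mz_ion / (config.resolving_power * _FWHM_PER_SIGMA)
        _add_gaussian(grid, signal, center, sigma, area)

    baseline = config.baseline_amplitude * np.exp(-grid / config.baseline_decay)
    clean = signal + baseline
    if config.noise_sd_scale > 0:
        sd = config.noise_sd_scale * np.sqrt(clean + 1.0)
        intensity = clean + rng.normal(0.0, 1.0, size=grid.shape) * sd
    else:
        intensity = clean

    meta = {
        "genotype": genotype.label,
        "wt_mass": wt_mass,
        "variant_mass": variant_mass,
        **{k: v for k, v in asdict(config).items()},
    }
    truth = TruthRecord(
        genotype_label=genotype.label,
        wt_mass=wt_mass,
        variant_mass=variant_mass,
        miscal_slope=config.miscal_slope,
        miscal_offset=config.miscal_offset,
        seed=config.seed,
    )
    return Spectrum(mz=grid, intensity=intensity, metadata=meta), truth


def generate_cohort(
    config: SimulationConfig,
    genotypes: Sequence[Genotype | str],
    seed: int | None = None,
) -> list[tuple[Spectrum, TruthRecord]]:
    """One spectrum per genotype with per-spectrum seeds derived from a master seed.

    The master seed defaults to ``config.seed``; child seeds come from
    numpy's SeedSequence so any cohort is reproducible from (config,
    genotype list, seed) alone.
    """
    master = config.seed if seed is None else seed
    gts = [g if isinstance(g, Genotype) else Genotype.from_label(g) for g in genotypes]
    children = np.random.SeedSequence(master).generate_state(max(len(gts), 1)) % (2**31)
    out = []
    for gt, child in zip(gts, children):
        cfg = replace(config, seed=int(child))
        out.append(simulate_spectrum(cfg, gt))
    return out


def table1_genotypes() -> list[Genotype]:
    """The 42 reference-cohort genotypes (from the bundled fixture)."""
    from .cohort import load_table1

    return [Genotype.from_label(p.label) for p in load_table1()]
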