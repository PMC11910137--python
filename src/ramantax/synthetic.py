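"""Synthetic single-cell Raman spectra with taxonomy and growth-stage structure.

The generator emulates the statistical shape of a reference library of
cultured bacteria measured across growth stages: 36 strains in 16 genera and
4 phyla, four growth stages (exponential phase plus early/mid/late stationary
phase), and >100 spectra per strain per stage (~17k spectra at full scale).

Generative model per spectrum::

    intensity(w) = sum_k  a_k * m_k(stage) * (1 + jitter) * exp(-(w-c_k)^2 / 2s_k^2)
                 + polynomial baseline (degree <= 3, random coefficients)
                 + iid Gaussian noise

Peaks come in four tiers: *shared* peaks common to all organisms (generic
biomass bands), *genus* and *strain* peaks whose amplitudes scale with
``taxon_separation`` (taxonomic signal), and *stage* peaks plus global
per-stage amplitude modulation scaling with ``stage_separation``
(growth-stage signal, consistent across taxa).  The early stationary stage
S1 defaults to the lowest within-stage amplitude jitter, making it the most
internally consistent stage.  An environmental mode adds a broad fluorescence
hump and multiplicative amplitude jitter, emulating the signal degradation a
FISH-labelling step introduces.

This is a statistical emulation, not a physical Raman simulation: no
instrument response, cosmic rays or real band assignments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import STAGES, SpectraDataset, WavenumberGrid


class ConfigurationError(ValueError):
    """Inconsistent synthetic-data configuration."""


#: default within-stage relative amplitude jitter; S1 is the most consistent
STAGE_JITTER_DEFAULT = {"Exp": 0.06, "S1": 0.02, "S2": 0.05, "S3": 0.08}


@dataclass(frozen=True)
class PeakSpec:
    """One Gaussian Raman band: center/width in cm^-1, amplitude in a.u."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigurationError("peak width must be positive")
        if self.amplitude < 0:
            raise ConfigurationError("peak amplitude must be nonnegative")


@dataclass
class StageModulation:
    """Per-stage amplitude multipliers (aligned with base peaks) + extra bands."""

    multipliers: np.ndarray
    extra_peaks: list[PeakSpec] = field(default_factory=list)


@dataclass
class TaxonProfile:
    """Spectral signature of one strain across the four growth stages."""

    strain_id: str
    genus: str
    phylum: str
    base_peaks: list[PeakSpec]
    stage_modulation: dict[str, StageModulation]


@dataclass
class SyntheticConfig:
    """Study-condition knobs for the generator.

    Defaults mirror the full-scale reference library (36 strains / 16
    genera / 4 phyla, 120 spectra per strain per stage).  ``taxon_separation``
    and ``stage_separation`` are dimensionless effect-size scalars; zero
    removes the corresponding signal entirely.
    """

    n_strains: int = 36
    genus_partition: tuple = (4, 4, 3, 3, 3, 2, 2, 2, 2, 2, 2, 2, 2, 1, 1, 1)
    phylum_partition: tuple = (5, 5, 3, 3)  # genera per phylum
    spectra_per_strain_per_stage: int = 120
    grid: tuple = (600.0, 1800.0, 700)  # start, stop (cm^-1), n_channels
    noise_sd: float = 0.02
    baseline_range: float = 0.15  # max |coefficient| of the random baseline
    baseline_degree: int = 3
    stage_separation: float = 1.0
    taxon_separation: float = 1.0
    stage_jitter: dict = field(default_factory=lambda: dict(STAGE_JITTER_DEFAULT))
    environmental_mode: bool = False
    env_strength: float = 1.0
    seed: int = 0
    # peak-count architecture
    n_shared_peaks: int = 12
    n_genus_peaks: int = 6
    n_strain_peaks: int = 4
    n_stage_peaks: int = 2
    #: strain-peak attenuation for the designated overlapping pair (the first
    #: two strains of the first multi-strain genus), emulating a pair of
    #: closely related strains that dominate the confusion structure
    confusable_attenuation: float = 0.3

    def __post_init__(self) -> None:
        if self.n_strains < 1 or self.spectra_per_strain_per_stage < 1:
            raise ConfigurationError("counts must be >= 1")
        if sum(self.genus_partition) != self.n_strains:
            raise ConfigurationError(
                f"genus_partition sums to {sum(self.genus_partition)}, "
                f"expected n_strains = {self.n_strains}"
            )
        if any(g < 1 for g in self.genus_partition):
            raise ConfigurationError("every genus needs >= 1 strain")
        if sum(self.phylum_partition) != len(self.genus_partition):
            raise ConfigurationError(
                "phylum_partition must sum to the number of genera"
            )
        if self.taxon_separation < 0 or self.stage_separation < 0:
            raise ConfigurationError("separations must be nonnegative")
        if self.noise_sd < 0 or self.baseline_range < 0:
            raise ConfigurationError("noise_sd and baseline_range must be >= 0")
        if not 0 <= self.baseline_degree <= 3:
            raise ConfigurationError("baseline_degree must be in 0..3")
        if set(self.stage_jitter) != set(STAGES):
            raise ConfigurationError("stage_jitter needs entries for all four stages")

    def wavenumbers(self) -> np.ndarray:
        lo, hi, n = self.grid
        return np.linspace(float(lo), float(hi), int(n))


def small_config(**overrides) -> SyntheticConfig:
    """A scaled-down configuration (12 strains / 8 genera, 50 spectra per
    strain per stage, 300 channels) used for desk-scale analyses and tests."""
    base = dict(
        n_strains=12,
        genus_partition=(2, 2, 2, 2, 1, 1, 1, 1),
        phylum_partition=(3, 3, 2),
        spectra_per_strain_per_stage=50,
        grid=(600.0, 1800.0, 300),
    )
    base.update(overrides)
    return SyntheticConfig(**base)


# ---------------------------------------------------------------------------
# taxonomy construction
# ---------------------------------------------------------------------------


def _draw_peaks(rng: np.random.Generator, n: int, lo: float, hi: float,
                amp_lo: float, amp_hi: float, scale: float = 1.0) -> list[PeakSpec]:
    centers = rng.uniform(lo, hi, n)
    widths = rng.uniform(8.0, 25.0, n)
    amps = scale * rng.uniform(amp_lo, amp_hi, n)
    # always consume the stream, but drop zero-amplitude (switched-off) bands
    return [
        PeakSpec(float(c), float(w), float(a))
        for c, w, a in zip(centers, widths, amps)
        if a > 0
    ]


def make_taxonomy(config: SyntheticConfig) -> list[TaxonProfile]:
    """Build one :class:`TaxonProfile` per strain, deterministic given the seed.

    Strains within a genus share the genus-level peaks; with
    ``taxon_separation = 0`` all taxon-specific bands vanish and every strain
    carries the identical shared peak set.
    """
    rng = np.random.default_rng([config.seed, 101])
    lo, hi, _ = config.grid
    lo, hi = float(lo) + 30.0, float(hi) - 30.0  # keep peaks inside the grid

    shared = _draw_peaks(rng, config.n_shared_peaks, lo, hi, 0.3, 1.0)

    # global stage signal, identical across taxa so stages are recognizable
    # irrespective of the organism
    stage_mult_shared = {
        s: np.exp(config.stage_separation * rng.normal(0.0, 0.25, len(shared)))
        for s in STAGES
    }
    stage_extras = {
        s: _draw_peaks(rng, config.n_stage_peaks, lo, hi, 0.2, 0.5,
                       scale=config.stage_separation)
        for s in STAGES
    }

    # map genus index -> phylum name
    genus_phylum = []
    for p_idx, n_genera in enumerate(config.phylum_partition):
        genus_phylum.extend([f"phylum{p_idx:02d}"] * n_genera)

    confusable_genus = next(
        (g for g, size in enumerate(config.genus_partition) if size >= 2), None
    )

    profiles: list[TaxonProfile] = []
    strain_idx = 0
    for g_idx, g_size in enumerate(config.genus_partition):
        genus = f"genus{g_idx:02d}"
        genus_peaks = _draw_peaks(rng, config.n_genus_peaks, lo, hi, 0.15, 0.5,
                                  scale=config.taxon_separation)
        for j in range(g_size):
            atten = (
                config.confusable_attenuation
                if (g_idx == confusable_genus and j < 2)
                else 1.0
            )
            strain_peaks = _draw_peaks(
                rng, config.n_strain_peaks, lo, hi, 0.1, 0.4,
                scale=config.taxon_separation * atten,
            )
            base = list(shared) + list(genus_peaks) + list(strain_peaks)
            n_taxon = len(genus_peaks) + len(strain_peaks)
            modulation = {}
            for s in STAGES:
                taxon_mult = np.exp(
                    config.stage_separation * rng.normal(0.0, 0.15, n_taxon)
                )
                modulation[s] = StageModulation(
                    multipliers=np.concatenate([stage_mult_shared[s], taxon_mult]),
                    extra_peaks=list(stage_extras[s]),
                )
            profiles.append(
                TaxonProfile(
                    strain_id=f"strain{strain_idx:02d}",
                    genus=genus,
                    phylum=genus_phylum[g_idx],
                    base_peaks=base,
                    stage_modulation=modulation,
                )
            )
            strain_idx += 1
    return profiles


def confusable_pair(profiles: list[TaxonProfile]) -> tuple[str, str]:
    """The designated overlapping strain pair: the first two strains of the
    first multi-strain genus (their strain-specific bands are attenuated)."""
    by_genus: dict[str, list[str]] = {}
    for p in profiles:
        by_genus.setdefault(p.genus, []).append(p.strain_id)
    for genus in sorted(by_genus):
        if len(by_genus[genus]) >= 2:
            return tuple(by_genus[genus][:2])
    raise ConfigurationError("no genus with at least two strains")


# ---------------------------------------------------------------------------
# spectrum generation
# ---------------------------------------------------------------------------


def _peak_matrix(peaks: list[PeakSpec], w: np.ndarray) -> np.ndarray:
    if not peaks:
        return np.zeros((0, w.size))
    c = np.array([p.center for p in peaks])[:, None]
    s = np.array([p.width for p in peaks])[:, None]
    return np.exp(-0.5 * ((w[None, :] - c) / s) ** 2)


def clean_spectrum(profile: TaxonProfile, stage: str, w: np.ndarray) -> np.ndarray:
    """The noiseless, jitter-free peak-sum model for one strain x stage."""
    mod = profile.stage_modulation[stage]
    amps = np.array([p.amplitude for p in profile.base_peaks]) * mod.multipliers
    out = amps @ _peak_matrix(profile.base_peaks, w)
    if mod.extra_peaks:
        extra_amps = np.array([p.amplitude for p in mod.extra_peaks])
        out = out + extra_amps @ _peak_matrix(mod.extra_peaks, w)
    return out


def _generate_block(profile: TaxonProfile, stage: str, config: SyntheticConfig,
                    rng: np.random.Generator, w: np.ndarray) -> np.ndarray:
    mod = profile.stage_modulation[stage]
    peaks = list(profile.base_peaks) + list(mod.extra_peaks)
    amps = np.concatenate([
        np.array([p.amplitude for p in profile.base_peaks]) * mod.multipliers,
        np.array([p.amplitude for p in mod.extra_peaks]),
    ]) if mod.extra_peaks else (
        np.array([p.amplitude for p in profile.base_peaks]) * mod.multipliers
    )
    G = _peak_matrix(peaks, w)
    n = config.spectra_per_strain_per_stage
    jitter = config.stage_jitter[stage]
    A = amps[None, :] * (1.0 + jitter * rng.standard_normal((n, amps.size)))
    np.clip(A, 0.0, None, out=A)
    X = A @ G
    # random low-order polynomial baseline on a normalized axis
    x = np.linspace(-1.0, 1.0, w.size)
    powers = np.vstack([x ** k for k in range(config.baseline_degree + 1)])
    coeffs = rng.uniform(-config.baseline_range, config.baseline_range,
                         (n, config.baseline_degree + 1))
    X += coeffs @ powers
    X += config.noise_sd * rng.standard_normal((n, w.size))
    return X


def generate_dataset(profiles: list[TaxonProfile],
                     config: SyntheticConfig) -> SpectraDataset:
    """Simulate the labelled library: one block per strain x stage.

    Row count is ``n_strains * 4 * spectra_per_strain_per_stage``.  Each
    strain x stage block draws from its own deterministic substream of the
    master seed, so datasets are bit-identical given (config, seed).
    """
    if not profiles:
        raise ConfigurationError("no taxon profiles given")
    w = config.wavenumbers()
    blocks, rows = [], []
    for si, prof in enumerate(profiles):
        for gi, stage in enumerate(STAGES):
            rng = np.random.default_rng([config.seed, 202, si, gi])
            blocks.append(_generate_block(prof, stage, config, rng, w))
            rows.extend(
                {
                    "cell_id": f"{prof.strain_id}_{stage}_{k:04d}",
                    "strain": prof.strain_id,
                    "genus": prof.genus,
                    "phylum": prof.phylum,
                    "stage": stage,
                }
                for k in range(config.spectra_per_strain_per_stage)
            )
    return SpectraDataset(
        grid=WavenumberGrid(w),
        intensities=np.vstack(blocks),
        labels=pd.DataFrame(rows),
        meta={"synthetic_config": dataclasses.asdict(config)},
    )


def generate_environmental_testset(profiles: list[TaxonProfile],
                                   config: SyntheticConfig) -> SpectraDataset:
    """Environmental/FISH-perturbed variant of :func:`generate_dataset`.

    Adds a broad fluorescence hump and multiplicative amplitude jitter of
    magnitude ``env_strength`` on top of the ordinary generative model; with
    strength 0 the output equals :func:`generate_dataset` bit-for-bit.
    Genus and strain labels are retained (strain for bookkeeping only);
    stage labels keep the simulated truth.
    """
    if not config.environmental_mode:
        raise ConfigurationError(
            "environmental_mode is disabled; enable it in the config"
        )
    ds = generate_dataset(profiles, config)
    s = config.env_strength
    if s > 0:
        rng = np.random.default_rng([config.seed, 303])
        w = ds.grid.values
        n = ds.n_cells
        center = rng.uniform(1100.0, 1600.0)
        width = rng.uniform(150.0, 300.0)
        hump = np.exp(-0.5 * ((w - center) / width) ** 2)
        amp = s * rng.uniform(0.5, 1.5, n)
        scale = np.clip(1.0 + 0.1 * s * rng.standard_normal(n), 0.1, None)
        ds = ds.with_intensities(
            ds.intensities * scale[:, None] + amp[:, None] * hump[None, :]
        )
    ds.meta["environmental"] = True
    return ds
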