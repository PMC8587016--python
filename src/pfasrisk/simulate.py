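"""Synthetic data generators with the statistical structure each stage assumes.

The original descriptor and toxicity tables behind the published models are
not deposited anywhere machine-readable, so these generators stand in for
them: a descriptor matrix for a homologous fluorinated series whose log10
toxicity is a sparse linear function of a few descriptors plus Gaussian
noise (QSAR stage), log10-log10 linear surrogate/predicted toxicity pairs
(ICE stage), and species toxicity values drawn from a log-normal with known
μ, σ (SSD stage).  Every generator is a pure function of its configuration,
including the seed; each one draws from its own named substream so adding a
generator never perturbs the output of an existing one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import (
    ChemicalRecord,
    Endpoint,
    Provenance,
    SpeciesClass,
    SpeciesToxicity,
    ToxicityRecord,
)
from .errors import ConfigError
from .published import published_values  # re-exported: embedded reference bundle

__all__ = [
    "SimulationConfig",
    "generate_qsar_dataset",
    "generate_ice_pairs",
    "generate_ssd_species",
    "published_values",
]

# fixed substream tags (second word of the rng seed sequence)
_STREAM_QSAR = 101
_STREAM_ICE = 202
_STREAM_SSD = 303


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generators.

    QSAR defaults mimic a homologous PFAS-like series: descriptors driven
    by a shared chain length (hence strongly collinear, as AM1 descriptors
    of a homologous series are), with log10 toxicity depending on the
    partition coefficient (negatively) and the LUMO energy (positively),
    plus log10-scale noise of 0.1.  ICE defaults (slope 0.8, intercept 0.5,
    log-noise 0.05, n = 100) and SSD defaults (μ = 4.0, σ = 1.5 on the
    natural-log mg/L scale, 17 species — a 4-QSAR + 13-ICE sized pool) match
    the scales the respective stages are used at.
    """

    seed: int = 0
    # QSAR stage
    n_chemicals: int = 50
    n_descriptors: int = 13
    true_terms: tuple[tuple[str, float], ...] = (("Kow", -0.5), ("ELUMO", 0.8))
    true_intercept: float = 2.0
    noise_sd_log10: float = 0.1
    # ICE stage
    n_pairs: int = 100
    ice_slope: float = 0.8
    ice_intercept: float = 0.5
    ice_noise_sd_log10: float = 0.05
    # SSD stage
    ssd_mu: float = 4.0
    ssd_sigma: float = 1.5
    n_species: int = 17

    def __post_init__(self) -> None:
        if self.noise_sd_log10 < 0 or self.ice_noise_sd_log10 < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        if self.ssd_sigma <= 0:
            raise ConfigError("ssd_sigma must be positive")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


#: Descriptor construction for a homologous series of chain length L:
#: (base, per-unit slope, idiosyncratic sd).  Energies in eV are negative
#: and grow in magnitude with L; surface/volume grow linearly; the orbital
#: and gradient descriptors are only weakly size-dependent.
_DESCRIPTOR_LAYOUT: dict[str, tuple[float, float, float]] = {
    "MW": (64.0, 50.0, 4.0),
    "TE": (-500.0, -180.0, 30.0),
    "EE": (-2000.0, -900.0, 120.0),
    "ECCR": (1500.0, 700.0, 100.0),
    "CA": (100.0, 30.0, 8.0),
    "CV": (80.0, 40.0, 8.0),
    "HOF": (-200.0, -100.0, 25.0),
    "Kow": (-2.0, 0.7, 0.6),
    "ELUMO": (1.5, 0.0, 0.6),
    "EHOMO": (-10.5, 0.0, 0.7),
    "IP": (11.0, 0.0, 0.8),
    "GN": (1.0, 0.0, 0.4),
    "GNpA": (0.1, 0.0, 0.03),
}


def generate_qsar_dataset(
    config: SimulationConfig,
    species: str = "Danio syntheticus",
    species_class: SpeciesClass = SpeciesClass.fish,
) -> tuple[list[ChemicalRecord], list[ToxicityRecord]]:
    """Chemicals with descriptors plus toxicity records for one test species.

    log10 LC50 = intercept + Σ coef·descriptor + N(0, noise_sd_log10), with
    descriptors for every chemical derived from a latent chain length (2-15)
    plus idiosyncratic Gaussian noise, so size-related descriptors are
    mutually collinear as in a real homologous series.
    """
    if config.n_chemicals < 10:
        raise ConfigError(f"n_chemicals must be >= 10, got {config.n_chemicals}")
    if not 1 <= config.n_descriptors <= len(_DESCRIPTOR_LAYOUT):
        raise ConfigError(
            f"n_descriptors must be in 1..{len(_DESCRIPTOR_LAYOUT)}, got {config.n_descriptors}"
        )
    symbols = list(_DESCRIPTOR_LAYOUT)[: config.n_descriptors]
    for sym, _ in config.true_terms:
        if sym not in symbols:
            raise ConfigError(f"true term descriptor {sym!r} not among generated columns")

    rng = _rng(config, _STREAM_QSAR)
    n = config.n_chemicals
    chain = rng.integers(2, 16, size=n)
    chemicals: list[ChemicalRecord] = []
    for i in range(n):
        desc: dict[str, float] = {}
        for sym in symbols:
            base, slope, sd = _DESCRIPTOR_LAYOUT[sym]
            desc[sym] = base + slope * float(chain[i]) + rng.normal(0.0, sd)
        if "MW" in desc:
            desc["MW"] = max(desc["MW"], 50.0)
        chemicals.append(
            ChemicalRecord(
                chem_id=f"SYN-{i:03d}",
                cas=f"{100000 + i}-{i % 90 + 10:02d}-{i % 10}",
                name=f"synthetic fluorocompound {i}",
                chain_length=int(chain[i]),
                descriptors=desc,
            )
        )

    noise = rng.normal(0.0, config.noise_sd_log10, size=n) if config.noise_sd_log10 > 0 else np.zeros(n)
    records: list[ToxicityRecord] = []
    for i, chem in enumerate(chemicals):
        log10_tox = config.true_intercept + sum(
            coef * chem.descriptors[sym] for sym, coef in config.true_terms
        ) + noise[i]
        records.append(
            ToxicityRecord(
                chem_id=chem.chem_id,
                species=species,
                species_class=species_class,
                endpoint=Endpoint.LC50,
                duration_h=48.0 if species_class is SpeciesClass.invertebrate else 96.0,
                concentration=10.0 ** log10_tox,
                provenance=Provenance.measured,
            )
        )
    return chemicals, records


def generate_ice_pairs(config: SimulationConfig) -> list[tuple[float, float]]:
    """(surrogate, predicted) mg/L pairs obeying the log-log ICE line.

    Surrogate log10 values are uniform on [-1, 3] (0.1 to 1000 mg/L);
    log10(predicted) = intercept + slope·log10(surrogate) + N(0, sd).
    """
    if config.n_pairs < 3:
        raise ConfigError(f"n_pairs must be >= 3 for an ICE fit, got {config.n_pairs}")
    rng = _rng(config, _STREAM_ICE)
    log_s = rng.uniform(-1.0, 3.0, size=config.n_pairs)
    noise = (
        rng.normal(0.0, config.ice_noise_sd_log10, size=config.n_pairs)
        if config.ice_noise_sd_log10 > 0
        else np.zeros(config.n_pairs)
    )
    log_p = config.ice_intercept + config.ice_slope * log_s + noise
    return list(zip((10.0 ** log_s).tolist(), (10.0 ** log_p).tolist()))


def generate_ssd_species(config: SimulationConfig) -> list[SpeciesToxicity]:
    """Species toxicity values drawn from LogNormal(ssd_mu, ssd_sigma)."""
    if config.n_species < 3:
        raise ConfigError(f"n_species must be >= 3, got {config.n_species}")
    rng = _rng(config, _STREAM_SSD)
    draws = np.exp(rng.normal(config.ssd_mu, config.ssd_sigma, size=config.n_species))
    return [
        SpeciesToxicity(
            species=f"Synthetica species{i:03d}",
            value=float(v),
            n_source_records=1,
            provenance=Provenance.measured,
        )
        for i, v in enumerate(draws)
    ]
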