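"""Virtual patient populations.

Genotypes are sampled at stated frequencies; 20% inter-individual
variability (log-normal, unit mean) is applied to designated clotting
factor production rates and to the PK parameters.  Everything is a pure
function of (spec, seed): same seed, same population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .drug_effects import GenotypeProfile
from .errors import SchemaError, ValidationError
from .network import NetworkModel
from .pk import PKParameters

#: paper-reported genotype frequencies of the model development dataset
DEFAULT_CYP2C9_FREQS = {"*1": 0.72, "*2": 0.19, "*3": 0.09}
DEFAULT_VKORC1_FREQS = {"GG": 0.53, "GA": 0.36, "AA": 0.11}

#: factors whose production rates receive inter-individual variability
DEFAULT_VARIABILITY_TARGETS = (
    "II", "V", "VII", "IX", "X", "XI", "XII", "XIII", "PC", "PS",
)
#: PK parameters receiving variability (F and ka excluded by default)
DEFAULT_PK_TARGETS = ("cl", "v")


def _check_freqs(freqs: dict[str, float], labels: tuple[str, ...], name: str):
    unknown = set(freqs) - set(labels)
    if unknown:
        raise ValidationError(f"{name}: unknown categories {sorted(unknown)}")
    if any(v < 0 for v in freqs.values()):
        raise ValidationError(f"{name}: negative frequency")
    if abs(sum(freqs.values()) - 1.0) > 1e-9:
        raise ValidationError(f"{name}: frequencies must sum to 1")


@dataclass
class PopulationSpec:
    n: int = 1000
    cyp2c9_freqs: dict = field(default_factory=lambda: dict(DEFAULT_CYP2C9_FREQS))
    vkorc1_freqs: dict = field(default_factory=lambda: dict(DEFAULT_VKORC1_FREQS))
    cv: float = 0.20
    seed: int = 0
    variability_targets: tuple = DEFAULT_VARIABILITY_TARGETS
    pk_targets: tuple = DEFAULT_PK_TARGETS

    def validate(self) -> None:
        if self.n < 1:
            raise ValidationError("population size n must be >= 1")
        if self.cv < 0:
            raise ValidationError("cv must be >= 0")
        _check_freqs(self.cyp2c9_freqs, ("*1", "*2", "*3"), "cyp2c9_freqs")
        _check_freqs(self.vkorc1_freqs, ("GG", "GA", "AA"), "vkorc1_freqs")


@dataclass(frozen=True)
class VirtualPatient:
    patient_id: int
    genotype: GenotypeProfile
    production_multipliers: dict  # species id -> positive factor
    pk_multipliers: dict  # pk field -> positive factor


def _draw_categorical(rng: np.random.Generator, freqs: dict, size: int) -> list[str]:
    labels = list(freqs.keys())
    p = np.array([freqs[k] for k in labels], dtype=float)
    p = p / p.sum()
    return [labels[i] for i in rng.choice(len(labels), size=size, p=p)]


def sample_genotypes(
    spec: PopulationSpec, rng: np.random.Generator | None = None
) -> list[GenotypeProfile]:
    """Independent categorical draws per patient per locus."""
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    cyp = _draw_categorical(rng, spec.cyp2c9_freqs, spec.n)
    vko = _draw_categorical(rng, spec.vkorc1_freqs, spec.n)
    return [GenotypeProfile(cyp2c9=c, vkorc1=v) for c, v in zip(cyp, vko)]


def sample_variability(
    n: int, cv: float, rng_or_seed: np.random.Generator | int
) -> np.ndarray:
    """Log-normal multipliers with unit mean and coefficient of variation cv.

    sigma^2 = ln(1 + cv^2), mu = -sigma^2/2; cv = 0 returns all ones.
    """
    if cv < 0:
        raise ValidationError("cv must be >= 0")
    if cv == 0:
        return np.ones(n)
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=n)


def build_population(
    spec: PopulationSpec,
    base_network: NetworkModel,
    base_pk: PKParameters | None = None,
) -> list[VirtualPatient]:
    """Sample a reproducible population of individualized patients.

    Draw order is fixed (genotypes, then per-target multipliers), so the
    whole population is a pure function of the spec.
    """
    spec.validate()
    ids = set(base_network.index)
    missing = [t for t in spec.variability_targets if t not in ids]
    if missing:
        raise SchemaError(
            f"variability target species missing from network: {missing}"
        )
    rng = np.random.default_rng(spec.seed)
    genotypes = sample_genotypes(spec, rng=rng)
    prod_mult = {
        t: sample_variability(spec.n, spec.cv, rng)
        for t in spec.variability_targets
    }
    pk_mult = {t: sample_variability(spec.n, spec.cv, rng) for t in spec.pk_targets}
    return [
        VirtualPatient(
            patient_id=i,
            genotype=genotypes[i],
            production_multipliers={t: float(prod_mult[t][i])
                                    for t in spec.variability_targets},
            pk_multipliers={t: float(pk_mult[t][i]) for t in spec.pk_targets},
        )
        for i in range(spec.n)
    ]


def population_manifest(patients: list[VirtualPatient]):
    """Tidy manifest: patient_id, genotype, multipliers."""
    import pandas as pd

    rows = []
    for p in patients:
        row = {
            "patient_id": p.patient_id,
            "cyp2c9": p.genotype.cyp2c9,
            "vkorc1": p.genotype.vkorc1,
        }
        row.update({f"prod_{k}": v for k, v in p.production_multipliers.items()})
        row.update({f"pk_{k}": v for k, v in p.pk_multipliers.items()})
        rows.append(row)
    return pd.DataFrame(rows)
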