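"""Pharmacodynamic coupling of drugs and genotype to the network.

Warfarin inhibits the vitamin-K-epoxide -> vitamin-K regeneration step
(Imax/IC50 form, Hill coefficient 1); the VKORC1 genotype limits the
vitamin K available to the system (GA: -22%, AA: -44%).  Rivaroxaban
reversibly scales the catalytic activity of factor Xa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .errors import ValidationError

CYP2C9_ALLELES = ("*1", "*2", "*3")
VKORC1_GENOTYPES = ("GG", "GA", "AA")

#: single-variant-allele fractional loss of VKOR activity
VKORC1_VARIANT_ALLELE_EFFECT = 0.44


@dataclass(frozen=True)
class GenotypeProfile:
    """CYP2C9 and VKORC1 allele states for one patient."""

    cyp2c9: str = "*1"
    vkorc1: str = "GG"

    def __post_init__(self):
        if self.cyp2c9 not in CYP2C9_ALLELES:
            raise ValidationError(f"unknown CYP2C9 allele {self.cyp2c9!r}")
        if self.vkorc1 not in VKORC1_GENOTYPES:
            raise ValidationError(f"unknown VKORC1 genotype {self.vkorc1!r}")


@dataclass(frozen=True)
class DrugActionParams:
    """Drug-action constants, shipped in the parameter table.

    ``vk_km`` shapes the saturable dependence of VK-dependent factor
    production on available vitamin K; ``xa_catalysts`` lists the species
    whose Michaelis-Menten kcats rivaroxaban scales.
    """

    warfarin_imax: float = 1.0
    warfarin_ic50: float = 1500.0  # nM
    rivaroxaban_ki: float = 70.0  # nM
    vk_normal: float = 100.0  # nM
    vk_km: float = 80.0  # nM
    vk_species: str = "VK"
    vko_species: str = "VKO"
    fibrin_species: str = "Fbn"
    fibrinogen_species: str = "Fg"
    xa_catalysts: tuple[str, ...] = ("Xa", "Xa_Va")

    def __post_init__(self):
        if not 0 < self.warfarin_imax <= 1:
            raise ValidationError("warfarin_imax must be in (0, 1]")
        if self.warfarin_ic50 <= 0 or self.rivaroxaban_ki <= 0:
            raise ValidationError("ic50 and ki must be > 0")
        if self.vk_normal <= 0 or self.vk_km <= 0:
            raise ValidationError("vk_normal and vk_km must be > 0")

    @classmethod
    def from_table_params(cls, params: dict[str, str]) -> "DrugActionParams":
        kwargs = {}
        floats = {
            "warfarin_imax", "warfarin_ic50", "rivaroxaban_ki",
            "vk_normal", "vk_km",
        }
        strings = {"vk_species", "vko_species", "fibrin_species",
                   "fibrinogen_species"}
        for name, value in params.items():
            if name in floats:
                kwargs[name] = float(value)
            elif name in strings:
                kwargs[name] = value
            elif name == "xa_catalysts":
                kwargs[name] = tuple(value.split(","))
            else:
                raise ValidationError(f"unknown drug-action parameter {name!r}")
        return cls(**kwargs)

    def as_table_rows(self) -> list[tuple[str, str]]:
        return [
            ("warfarin_imax", repr(self.warfarin_imax)),
            ("warfarin_ic50", repr(self.warfarin_ic50)),
            ("rivaroxaban_ki", repr(self.rivaroxaban_ki)),
            ("vk_normal", repr(self.vk_normal)),
            ("vk_km", repr(self.vk_km)),
            ("vk_species", self.vk_species),
            ("vko_species", self.vko_species),
            ("fibrin_species", self.fibrin_species),
            ("fibrinogen_species", self.fibrinogen_species),
            ("xa_catalysts", ",".join(self.xa_catalysts)),
        ]


def heterozygote_reduction(variant_allele_effect: float) -> float:
    """Allele-averaged reduction for one normal + one variant allele."""
    if not 0 <= variant_allele_effect <= 1:
        raise ValidationError("variant_allele_effect must be in [0, 1]")
    return variant_allele_effect / 2.0


#: available-vitamin-K multipliers per VKORC1 genotype
VKORC1_VK_FACTOR = {
    "GG": 1.0,
    "GA": 1.0 - heterozygote_reduction(VKORC1_VARIANT_ALLELE_EFFECT),  # 0.78
    "AA": 1.0 - VKORC1_VARIANT_ALLELE_EFFECT,  # 0.56
}


def apply_vkorc1(vk_normal: float, genotype: str) -> float:
    """Available vitamin K (nM) for a VKORC1 genotype."""
    if vk_normal <= 0:
        raise ValidationError("vk_normal must be > 0")
    if genotype not in VKORC1_VK_FACTOR:
        raise ValidationError(f"unknown VKORC1 genotype {genotype!r}")
    return vk_normal * VKORC1_VK_FACTOR[genotype]


def warfarin_vkor_inhibition(c_warfarin: float, params: DrugActionParams) -> float:
    """Fractional inhibition of the VK regeneration step at concentration C."""
    if c_warfarin < 0:
        raise ValidationError("c_warfarin must be >= 0")
    return params.warfarin_imax * c_warfarin / (params.warfarin_ic50 + c_warfarin)


def rivaroxaban_xa_scaling(c_riva: float, ki: float) -> float:
    """Remaining fraction of Xa catalytic activity under rivaroxaban."""
    if c_riva < 0:
        raise ValidationError("c_riva must be >= 0")
    if ki <= 0:
        raise ValidationError("ki must be > 0")
    return 1.0 / (1.0 + c_riva / ki)


@dataclass
class DrugCoupling:
    """Binds a drug concentration source to the network RHS.

    ``conc_fn`` maps time (on the simulation's time base) to plasma drug
    concentration in nM; for in-vitro assays the concentration is the
    constant ``conc_nM`` drawn with the plasma sample.
    """

    drug: str
    params: DrugActionParams
    conc_fn: Callable[[float], float] | None = None
    conc_nM: float = 0.0

    def __post_init__(self):
        if self.drug not in ("warfarin", "rivaroxaban"):
            raise ValidationError(f"unknown drug {self.drug!r}")

    def concentration(self, t: float) -> float:
        if self.conc_fn is not None:
            return self.conc_fn(t)
        return self.conc_nM
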