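"""Drug-specific parameters and age-scaling of intrinsic clearances.

Four CYP3A4 substrates are packaged: midazolam (albumin-bound), and the
opioids fentanyl, alfentanil and sufentanil (alpha1-acid-glycoprotein
bound).  Hepatic intrinsic clearance is stored per mg of microsomal protein
and scaled to a whole-liver value with the subject's CYP3A activity ratio,
microsomal protein density (MPPGL) and liver weight; intestinal intrinsic
clearance is stored as a whole-gut value and scaled with the intestinal
CYP3A ontogeny (pediatrics) or body weight (elderly).

Internal unit regime: amounts mg, volumes L, flows and clearances L/h,
time h, concentrations mg/L.  The single uL/min -> L/h conversion happens
in :func:`scale_clint_hepatic`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import yaml

from .physiology import (
    AgeSpec,
    PhysiologyProfile,
    adult_reference_protein,
    unbound_fraction,
)

__all__ = [
    "DrugParams",
    "AVAILABLE_DRUGS",
    "load_drug",
    "scale_clint_hepatic",
    "scale_clint_intestinal",
    "age_adjusted_fu",
]

AVAILABLE_DRUGS = ("midazolam", "fentanyl", "alfentanil", "sufentanil")

#: uL/min -> L/h
UL_PER_MIN_TO_L_PER_H = 60.0 / 1.0e6


class DrugLookupError(KeyError):
    pass


@dataclass(frozen=True)
class DrugParams:
    """Physicochemical and pharmacokinetic constants of one model drug."""

    name: str
    molecular_weight: float  # g/mol
    peff: float  # effective permeability, 1e-4 cm/s
    fu_p_adult: float  # unbound fraction in plasma, adult
    rb: float  # blood:plasma concentration ratio
    binding_protein: str  # 'ALB' or 'AAG'
    clint_l_adult: float  # uL/min/mg microsomal protein
    clint_i_adult: float  # L/h, whole intestine
    cyp3a_abundance_intestine_adult: float  # pmol
    intestinal_abundance_fraction: Mapping[str, float]
    renal_cl_adult: float  # L/h
    ktp: Mapping[str, float]  # tissue:plasma partition coefficients

    @property
    def fu_b_adult(self) -> float:
        """Adult unbound fraction referenced to whole blood."""
        return min(self.fu_p_adult / self.rb, 1.0)

    def validate(self) -> None:
        positive = {
            "molecular_weight": self.molecular_weight,
            "peff": self.peff,
            "rb": self.rb,
            "clint_l_adult": self.clint_l_adult,
            "clint_i_adult": self.clint_i_adult,
            "cyp3a_abundance_intestine_adult": self.cyp3a_abundance_intestine_adult,
        }
        for key, val in positive.items():
            if val <= 0:
                raise ValueError(f"{self.name}: {key} must be positive, got {val}")
        if not (0 < self.fu_p_adult <= 1):
            raise ValueError(f"{self.name}: fu_p_adult must be in (0,1]")
        if self.renal_cl_adult < 0:
            raise ValueError(f"{self.name}: renal_cl_adult must be >= 0")
        if self.binding_protein not in ("ALB", "AAG"):
            raise ValueError(f"{self.name}: binding_protein must be ALB or AAG")
        if any(k <= 0 for k in self.ktp.values()):
            raise ValueError(f"{self.name}: all partition coefficients must be positive")
        frac_sum = sum(self.intestinal_abundance_fraction.values())
        if abs(frac_sum - 1.0) > 1e-6:
            raise ValueError(f"{self.name}: intestinal abundance fractions must sum to 1")


def load_drug(name: str) -> DrugParams:
    """Load the packaged parameter record for one of the four model drugs."""
    key = name.lower()
    if key not in AVAILABLE_DRUGS:
        raise DrugLookupError(
            f"unknown drug {name!r}; available: {', '.join(AVAILABLE_DRUGS)}"
        )
    ref = resources.files("agepbpk").joinpath(f"data/drugs/{key}.yaml")
    with ref.open("r") as fh:
        raw = yaml.safe_load(fh)
    params = DrugParams(
        name=raw["name"],
        molecular_weight=float(raw["molecular_weight"]),
        peff=float(raw["peff"]),
        fu_p_adult=float(raw["fu_p_adult"]),
        rb=float(raw["rb"]),
        binding_protein=raw["binding_protein"],
        clint_l_adult=float(raw["clint_l_adult"]),
        clint_i_adult=float(raw["clint_i_adult"]),
        cyp3a_abundance_intestine_adult=float(raw["cyp3a_abundance_intestine_adult"]),
        intestinal_abundance_fraction=dict(raw["intestinal_abundance_fraction"]),
        renal_cl_adult=float(raw["renal_cl_adult"]),
        ktp=dict(raw["ktp"]),
    )
    params.validate()
    return params


def scale_clint_hepatic(
    clint_adult_per_mg: float,
    r_cyp3a: float,
    mppgl: float,
    liver_weight_g: float,
) -> float:
    """Whole-liver intrinsic clearance (L/h).

    Product of the adult per-mg intrinsic clearance (uL/min/mg), the CYP3A
    activity ratio, MPPGL (mg/g) and liver weight (g); the uL/min -> L/h
    conversion is applied here, once.
    """
    for label, val in (
        ("clint_adult_per_mg", clint_adult_per_mg),
        ("r_cyp3a", r_cyp3a),
        ("mppgl", mppgl),
        ("liver_weight_g", liver_weight_g),
    ):
        if val <= 0:
            raise ValueError(f"{label} must be positive, got {val}")
    return clint_adult_per_mg * r_cyp3a * mppgl * liver_weight_g * UL_PER_MIN_TO_L_PER_H


def scale_clint_intestinal(
    clint_i_adult: float,
    population: str,
    r_cyp3a_i: float = 1.0,
    r_cyp3a_hepatic: float = 1.0,
    bw_ratio: float = 1.0,
) -> float:
    """Whole-intestine intrinsic clearance (L/h) for one subject.

    Pediatric subjects (including neonates) scale the adult value by the
    product of the hepatic CYP3A maturation ratio and the intestinal CYP3A
    ontogeny fraction (the pediatric intestinal clearance is defined in
    terms of the maturing pediatric enzyme activity times the intestinal
    abundance fraction); elderly subjects keep the adult intrinsic activity
    corrected by relative body weight; adults return the packaged value
    unchanged.
    """
    if clint_i_adult <= 0 or r_cyp3a_i <= 0 or r_cyp3a_hepatic <= 0 or bw_ratio <= 0:
        raise ValueError("intestinal clearance scaling inputs must be positive")
    if population in ("neonate_preterm", "pediatric"):
        return clint_i_adult * r_cyp3a_hepatic * r_cyp3a_i
    if population == "elderly":
        return clint_i_adult * bw_ratio
    return clint_i_adult


def age_adjusted_fu(drug: DrugParams, profile: PhysiologyProfile) -> float:
    """Unbound plasma fraction for a subject, from their binding-protein level.

    Applies the competitive-binding rescaling with the concentration of the
    drug's dominant binding protein (ALB or AAG) relative to the adult
    reference level.
    """
    p_subject = profile.alb if drug.binding_protein == "ALB" else profile.aag
    p_adult = adult_reference_protein(drug.binding_protein)
    return unbound_fraction(drug.fu_p_adult, p_subject, p_adult)
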