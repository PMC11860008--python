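"""Age-dependent human physiology for whole-body PBPK simulation.

Every anatomical and biochemical quantity the PBPK model needs — body size,
organ volumes and perfusion, hepatic microsomal protein, plasma binding
proteins, and CYP3A activity relative to a healthy adult — is computed here
as a pure, deterministic function of age.  Ages are real numbers in years;
the perinatal window additionally carries a gestational age so that
postmenstrual age (PMA = gestational + postnatal age) can drive the
neonatal enzyme-maturation and albumin curves.

Four age regimes are distinguished:

* ``neonate_preterm`` — immediate postnatal window (or preterm birth), where
  hepatic CYP3A activity rises linearly with PMA and albumin follows a Hill
  curve in PMA;
* ``pediatric`` — 1 month to 20 years, with a saturating CYP3A maturation
  curve, a log-linear albumin trajectory and a cubic-in-age (log10) curve
  for microsomal protein per gram of liver (MPPGL);
* ``adult`` — 20 to 40 years, the reference state (activity ratio 1);
* ``elderly`` — beyond 40 years, with an 8 %-per-decade decline in CYP3A
  activity, polynomial MPPGL curves and a linear fall in albumin.

The regime switches are hard (no blending); the jumps at the boundaries are
small for MPPGL (<1 %) and are reported by :func:`regime_discontinuity`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "AgeSpec",
    "PhysiologyProfile",
    "growth_curve",
    "body_surface_area",
    "intestinal_radius",
    "cyp3a_hepatic_ratio",
    "cyp3a_intestinal_ratio",
    "mppgl",
    "plasma_proteins",
    "unbound_fraction",
    "build_physiology",
    "classify_population",
    "load_physiology_tables",
    "adult_reference_protein",
]

WEEKS_PER_YEAR = 52.0
DAYS_PER_YEAR = 365.25
#: Postnatal age (years) below which a term newborn uses the neonatal regime.
NEONATAL_WINDOW = 1.0 / 12.0
#: Postnatal age (years) below which a preterm infant uses the neonatal regime.
PRETERM_WINDOW = 0.5
PEDIATRIC_LIMIT = 20.0
ELDERLY_ONSET = 40.0


class PhysiologyError(ValueError):
    """Raised for out-of-domain ages or inconsistent parameterizations."""


@dataclass(frozen=True)
class AgeSpec:
    """Age descriptor of a (virtual) subject.

    Parameters
    ----------
    postnatal_age : float
        Time since birth, years (>= 0).
    gestational_age : float
        Gestational age at birth, years. Default is term birth,
        40 weeks = 40/52 y ~= 0.7692 y.  Must lie in [0.42, 0.85] y
        (22-44 weeks).
    sex : str
        Carried for interface completeness; the model is sex-agnostic.
    """

    postnatal_age: float
    gestational_age: float = 40.0 / WEEKS_PER_YEAR
    sex: str = "unspecified"

    def __post_init__(self) -> None:
        if self.postnatal_age < 0:
            raise PhysiologyError(f"postnatal_age must be >= 0, got {self.postnatal_age}")
        if not (0.42 <= self.gestational_age <= 0.85):
            raise PhysiologyError(
                "gestational_age must be within [0.42, 0.85] years (22-44 weeks), "
                f"got {self.gestational_age}"
            )

    @property
    def pma(self) -> float:
        """Postmenstrual age (years): gestational + postnatal age."""
        return self.gestational_age + self.postnatal_age

    @property
    def is_preterm(self) -> bool:
        return self.gestational_age < 37.0 / WEEKS_PER_YEAR


@dataclass(frozen=True)
class PhysiologyProfile:
    """All age-resolved parameters needed to assemble one PBPK system."""

    age: AgeSpec
    population: str
    body_weight: float  # kg
    height: float  # cm
    bsa: float  # m^2
    intestinal_radius: float  # m
    organ_volumes: Mapping[str, float]  # L
    organ_flows: Mapping[str, float]  # L/h; 'liver' is total liver inflow
    cardiac_output: float  # L/h
    liver_weight: float  # g
    mppgl: float  # mg microsomal protein / g liver
    pbsf: float  # mg microsomal protein, whole liver
    alb: float  # g/L
    aag: float  # g/L
    r_cyp3a_hepatic: float
    r_cyp3a_intestinal: float
    gastric_emptying_time: float  # min
    intestinal_transit_times: Mapping[str, float] = field(default_factory=dict)  # min


_TABLES = None


def load_physiology_tables() -> dict:
    """Load (and cache) the packaged age-equation parameter tables."""
    global _TABLES
    if _TABLES is None:
        ref = resources.files("agepbpk").joinpath("data/physiology.yaml")
        with ref.open("r") as fh:
            _TABLES = yaml.safe_load(fh)
    return _TABLES


def classify_population(age_spec: AgeSpec) -> str:
    """Map an :class:`AgeSpec` to its physiological regime.

    Preterm infants remain in the neonatal regime until 6 months postnatal
    age; term newborns leave it at 1 month.  The pediatric regime spans up
    to 20 years, adults 20-40 years, elderly beyond 40.
    """
    pna = age_spec.postnatal_age
    window = PRETERM_WINDOW if age_spec.is_preterm else NEONATAL_WINDOW
    if pna < window:
        return "neonate_preterm"
    if pna < PEDIATRIC_LIMIT:
        return "pediatric"
    if pna < ELDERLY_ONSET:
        return "adult"
    return "elderly"


# ---------------------------------------------------------------------------
# Body size
# ---------------------------------------------------------------------------

def growth_curve(age: float, coeffs: Mapping[str, float]) -> float:
    """Rational growth curve Y = (a + b*A) / (1 + c*A + d*A^2).

    ``coeffs`` holds the correlation coefficients a, b, c, d for one
    quantity (body weight in kg, or height in cm).  At A = 0 the curve
    reduces to ``a``.
    """
    if age < 0:
        raise PhysiologyError(f"age must be >= 0, got {age}")
    a, b, c, d = coeffs["a"], coeffs["b"], coeffs["c"], coeffs["d"]
    denom = 1.0 + c * age + d * age * age
    if denom <= 0:
        raise PhysiologyError(
            f"growth-curve denominator non-positive at age {age}: coeffs {dict(coeffs)}"
        )
    value = (a + b * age) / denom
    if value <= 0:
        raise PhysiologyError(f"growth curve returned non-positive value at age {age}")
    return value


def _growth_piecewise(age: float, which: str) -> float:
    tables = load_physiology_tables()
    for segment in tables["growth"][which]:
        if age <= segment["max_age"]:
            return growth_curve(age, segment)
    return growth_curve(age, tables["growth"][which][-1])


def body_weight_height(age: float) -> tuple[float, float]:
    """Body weight (kg) and height (cm) from the packaged growth-coefficient
    sets (separate sets for infancy, childhood and adulthood)."""
    return _growth_piecewise(age, "body_weight"), _growth_piecewise(age, "height")


def body_surface_area(bw: float, h: float) -> float:
    """Body surface area (m^2) from weight (kg) and height (cm).

    Uses the adult power law ``0.007184 * BW^0.425 * H^0.725`` above 15 kg
    and the infant/child law ``0.024265 * BW^0.5378 * H^0.3964`` below.
    Exactly 15 kg is resolved on the adult side.
    """
    if bw <= 0 or h <= 0:
        raise PhysiologyError(f"bw and h must be positive, got bw={bw}, h={h}")
    if bw >= 15.0:
        return 0.007184 * bw**0.425 * h**0.725
    return 0.024265 * bw**0.5378 * h**0.3964


def intestinal_radius(bsa: float) -> float:
    """Small-intestinal radius (m), linear in BSA: r = (0.016*BSA + 0.0159)/2."""
    if bsa < 0:
        raise PhysiologyError(f"bsa must be >= 0, got {bsa}")
    return (0.016 * bsa + 0.0159) / 2.0


# ---------------------------------------------------------------------------
# Enzyme ontogeny and senescence
# ---------------------------------------------------------------------------

def cyp3a_hepatic_ratio(age_spec: AgeSpec, population: str | None = None) -> float:
    """Hepatic CYP3A activity as a fraction of the healthy-adult value.

    * neonate/preterm: ``0.003 + 0.1331 * PMA`` (PMA in years);
    * pediatric: ``A^0.83 / (0.31 + A^0.83)``;
    * adult (20-40 y): 1;
    * elderly: ``0.92^((A - 40)/10)`` (8 % loss per decade).

    The result is clipped to (0, 1.05].
    """
    if population is None:
        population = classify_population(age_spec)
    a = age_spec.postnatal_age
    if population == "neonate_preterm":
        value = 0.003 + 0.1331 * age_spec.pma
    elif population == "pediatric":
        if a <= 0:
            raise PhysiologyError("pediatric CYP3A ratio requires age > 0")
        value = a**0.83 / (0.31 + a**0.83)
    elif population == "adult":
        value = 1.0
    elif population == "elderly":
        value = 0.92 ** ((a - ELDERLY_ONSET) / 10.0)
    else:
        raise PhysiologyError(f"unknown population regime {population!r}")
    return float(min(max(value, 1e-12), 1.05))


def cyp3a_intestinal_ratio(age: float, form: str = "saturating_linear") -> float:
    """Intestinal CYP3A activity as a fraction of the adult value.

    The default ``saturating_linear`` form is
    ``0.639 * A / (2.36 + A) + 0.42``: roughly 42 % of adult activity at
    birth, converging to ~1 by early adulthood.  An alternative Hill form
    ``0.639 * A^2.36 / (A^2.36 + 0.42)`` is selectable; both satisfy
    R(adult) ~= 1 and are monotone non-decreasing on [0, 20].
    """
    if age < 0:
        raise PhysiologyError(f"age must be >= 0, got {age}")
    if form == "saturating_linear":
        return 0.639 * age / (2.36 + age) + 0.42
    if form == "hill":
        # literal alternative reading; converges to 0.639, not 1, which is
        # why it is not the default
        if age == 0:
            return 0.0
        p = age**2.36
        return 0.639 * p / (p + 0.42)
    raise PhysiologyError(f"unknown intestinal ontogeny form {form!r}")


def mppgl(age: float) -> float:
    """Microsomal protein per gram of liver (mg/g) across the lifespan.

    Pediatric (A < 20): ``10^(1.407 + 0.0158*A - 0.00038*A^2 + 0.0000024*A^3)``;
    20 <= A <= 80: ``0.0001653*A^3 - 0.02739*A^2 + 1.143*A + 25.52``;
    A > 80: ``-0.08155*A^2 + 14.48*A - 612.7`` (a late-life rebound).
    """
    if age < 0:
        raise PhysiologyError(f"age must be >= 0, got {age}")
    if age < PEDIATRIC_LIMIT:
        return 10.0 ** (1.407 + 0.0158 * age - 0.00038 * age**2 + 0.0000024 * age**3)
    if age <= 80.0:
        return 0.0001653 * age**3 - 0.02739 * age**2 + 1.143 * age + 25.52
    return -0.08155 * age**2 + 14.48 * age - 612.7


def regime_discontinuity(func, boundary: float, eps: float = 1e-6) -> float:
    """Relative jump of a piecewise age function at a regime boundary."""
    lo, hi = func(boundary - eps), func(boundary + eps)
    return abs(hi - lo) / max(abs(lo), 1e-300)


# ---------------------------------------------------------------------------
# Plasma binding proteins
# ---------------------------------------------------------------------------

def plasma_proteins(age_spec: AgeSpec, population: str | None = None) -> tuple[float, float]:
    """Plasma albumin and alpha1-acid glycoprotein concentrations (g/L).

    Albumin: Hill curve in PMA for the neonatal regime
    (``41.3 * PMA^2.70 / (0.383^2.70 + PMA^2.70)``), log-linear in age for
    pediatrics (``1.1287*ln A + 33.746``) and linearly declining for
    adults/elderly (``51.4 - 0.107*A``).

    AAG: the pediatric level is the adult 0.61 g/L scaled by the percentage
    ``0.01137*days + 53.4`` (capped at 100 %); adults 0.61 g/L; 0.58 g/L
    from age 60.
    """
    if population is None:
        population = classify_population(age_spec)
    a = age_spec.postnatal_age
    if population == "neonate_preterm" or (population == "pediatric" and a <= 0):
        pma = age_spec.pma
        alb = 41.3 * pma**2.70 / (0.383**2.70 + pma**2.70)
    elif population == "pediatric":
        alb = 1.1287 * math.log(a) + 33.746
    else:
        alb = 51.4 - 0.107 * a

    aag_adult = 0.61
    if population in ("neonate_preterm", "pediatric"):
        days = a * DAYS_PER_YEAR
        r_aag = min(0.01137 * days + 53.4, 100.0)
        aag = aag_adult * r_aag / 100.0
    elif a >= 60.0:
        aag = 0.58
    else:
        aag = aag_adult
    return float(alb), float(aag)


def adult_reference_protein(protein: str) -> float:
    """Adult reference plasma concentration (g/L) of ALB or AAG, evaluated
    at the packaged adult reference age."""
    tables = load_physiology_tables()
    ref_age = tables["adult_reference_age"]
    spec = AgeSpec(postnatal_age=float(ref_age))
    alb, aag = plasma_proteins(spec, population="adult")
    return {"ALB": alb, "AAG": aag}[protein]


def unbound_fraction(fu_adult: float, p_subject: float, p_adult: float) -> float:
    """Unbound plasma fraction rescaled for a subject's binding-protein level.

    ``fu = 1 / (1 + P_subject*(1 - fu_adult) / (P_adult*fu_adult))``.
    Equal protein levels return ``fu_adult``; zero protein returns 1.
    """
    if not (0 < fu_adult <= 1):
        raise PhysiologyError(f"fu_adult must be in (0, 1], got {fu_adult}")
    if p_adult <= 0 or p_subject < 0:
        raise PhysiologyError("protein concentrations must be positive (subject may be 0)")
    return 1.0 / (1.0 + p_subject * (1.0 - fu_adult) / (p_adult * fu_adult))


# ---------------------------------------------------------------------------
# Whole-profile assembly
# ---------------------------------------------------------------------------

def _interp_fraction(table: Mapping, age: float) -> float:
    ages = np.asarray(table["ages"], dtype=float)
    values = np.asarray(table["values"], dtype=float)
    return float(np.interp(age, ages, values))


def _gastric_emptying(age: float) -> float:
    for band in load_physiology_tables()["gastric_emptying"]:
        if age < band["max_age"]:
            return float(band["minutes"])
    return float(load_physiology_tables()["gastric_emptying"][-1]["minutes"])


def _elderly_scale(age: float, rate: float, onset: float, floor: float) -> float:
    if age <= onset:
        return 1.0
    return max(1.0 - rate * (age - onset), floor)


def build_physiology(age_spec: AgeSpec) -> PhysiologyProfile:
    """Assemble the full :class:`PhysiologyProfile` for one subject.

    Organ volumes are age-interpolated fractions of body weight; perfusion
    is distributed as age-interpolated fractions of an allometric cardiac
    output (CO ~ BW^0.75).  Beyond age 40, cardiac output declines linearly
    (~0.7 %/y) and liver volume and the hepatic and renal perfusion paths
    carry additional declines so that by ~age 90 liver volume is ~70 %,
    hepatic flow ~57 % and renal flow ~70 % of the young-adult value; the
    flow difference is reassigned to the residual ('rest') path so the
    perfusion balance closes exactly.  Deterministic: identical input
    always yields an identical profile.
    """
    tables = load_physiology_tables()
    population = classify_population(age_spec)
    a = age_spec.postnatal_age

    bw, height = body_weight_height(a)
    bsa = body_surface_area(bw, height)
    radius = intestinal_radius(bsa)

    eld = tables["elderly"]
    liver_vol_scale = _elderly_scale(a, eld["liver_volume_decline_per_year"], eld["onset_age"], eld["floor"])
    hep_flow_scale = _elderly_scale(a, eld["hepatic_flow_decline_per_year"], eld["onset_age"], eld["floor"])
    renal_flow_scale = _elderly_scale(a, eld["renal_flow_decline_per_year"], eld["onset_age"], eld["floor"])

    age_clip = min(a, PEDIATRIC_LIMIT)
    volumes: dict[str, float] = {}
    for tissue, spec in tables["tissues"].items():
        frac = _interp_fraction(spec["volume_fraction"], age_clip)
        vol = frac * bw
        if tissue == "liver":
            vol *= liver_vol_scale
        if vol <= 0:
            raise PhysiologyError(f"non-positive volume for tissue {tissue!r}")
        volumes[tissue] = vol
    total_body_volume = bw * tables["body_volume_per_kg"]
    rest_vol = total_body_volume - sum(volumes.values())
    if rest_vol <= 0:
        raise PhysiologyError("residual-tissue volume non-positive; check volume fractions")
    volumes["rest"] = rest_vol

    co_scale = _elderly_scale(a, eld["cardiac_output_decline_per_year"], eld["onset_age"], eld["floor"])
    co = (
        tables["cardiac_output"]["adult_L_h"]
        * (bw / tables["cardiac_output"]["reference_bw"]) ** tables["cardiac_output"]["allometric_exponent"]
        * co_scale
    )
    hepatic_path = set(tables["hepatic_inflow_tissues"])
    flows: dict[str, float] = {}
    for tissue, spec in tables["tissues"].items():
        if "flow_fraction" not in spec:
            continue
        q = _interp_fraction(spec["flow_fraction"], age_clip) * co
        if tissue in hepatic_path:
            q *= hep_flow_scale
        if tissue == "kidney":
            q *= renal_flow_scale
        flows[tissue] = q
    q_ha = _interp_fraction(tables["hepatic_artery_flow_fraction"], age_clip) * co * hep_flow_scale
    flows["hepatic_artery"] = q_ha
    assigned = sum(flows.values())
    if assigned >= co:
        raise PhysiologyError("assigned perfusion exceeds cardiac output")
    flows["rest"] = co - assigned
    flows["liver"] = q_ha + sum(flows[t] for t in hepatic_path)

    liver_weight = volumes["liver"] * 1000.0 * tables["liver_density_g_per_ml"]
    mp = mppgl(a)
    alb, aag = plasma_proteins(age_spec, population)

    transit = {k: float(v) for k, v in tables["intestinal_transit_min"].items()}

    return PhysiologyProfile(
        age=age_spec,
        population=population,
        body_weight=bw,
        height=height,
        bsa=bsa,
        intestinal_radius=radius,
        organ_volumes=volumes,
        organ_flows=flows,
        cardiac_output=co,
        liver_weight=liver_weight,
        mppgl=mp,
        pbsf=mp * liver_weight,
        alb=alb,
        aag=aag,
        r_cyp3a_hepatic=cyp3a_hepatic_ratio(age_spec, population),
        r_cyp3a_intestinal=cyp3a_intestinal_ratio(a),
        gastric_emptying_time=_gastric_emptying(a),
        intestinal_transit_times=transit,
    )
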