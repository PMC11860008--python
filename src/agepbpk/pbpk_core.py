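"""Whole-body mass-balance ODE system and its integrator.

The model is a closed, flow-limited whole-body circuit: venous blood ->
lung -> arterial blood -> tissues -> venous blood.  Non-eliminating tissues
are perfusion-limited (``dA_t/dt = Q_t*(C_art - C_t*R_b/K_t:p)``).  The
liver receives the hepatic artery plus the portal vein (spleen and the
five gut-wall segments) and eliminates drug by the well-stirred model in
intrinsic-clearance form; the kidney eliminates at a renal clearance
referenced to its emergent venous concentration.  The gut lumen is a
serial transit chain (stomach -> duodenum -> jejunum -> ileum -> cecum ->
colon -> feces) with first-order emptying/transit at 1/mean-residence-time;
absorption (rate ``2*P_eff/r`` per segment) and gut-wall CYP3A metabolism
occur in duodenum, jejunum and ileum only.

All rate processes are linear, so the state equation is
``dy/dt = A y + u(t)`` with a constant matrix ``A`` and a piecewise-
constant infusion input ``u``; oral doses are impulses into the stomach
lumen.  Cumulative hepatic, intestinal (gut-wall) and renal elimination
and fecal loss are carried as extra states, which makes the mass balance
checkable to solver precision.

The stomach wall is not an explicit compartment; its (small) volume and
perfusion are part of the residual 'rest' tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .drugs import DrugParams, age_adjusted_fu, scale_clint_hepatic, scale_clint_intestinal
from .physiology import AgeSpec, PhysiologyProfile, build_physiology, load_physiology_tables

__all__ = [
    "DoseEvent",
    "Individual",
    "SimResult",
    "PbpkSystem",
    "build_system",
    "simulate",
    "mass_balance_report",
    "make_individual",
    "STATE_NAMES",
]

#: Duration (h) used to represent an iv bolus as a short infusion.
BOLUS_DURATION_H = 0.5 / 60.0

RANDOM_EFFECT_PARAMS = ("peff", "fu_b", "clint_l", "clint_i", "rb", "pbsf")

_PERFUSED = ("heart", "brain", "muscle", "adipose", "skin", "rest")
_GUT_SEGMENTS = ("duodenum", "jejunum", "ileum", "cecum", "colon")
_ABSORBING = ("duodenum", "jejunum", "ileum")

STATE_NAMES: tuple[str, ...] = (
    "venous_blood",
    "arterial_blood",
    "lung",
    *_PERFUSED,
    "spleen",
    "kidney",
    "liver",
    "stomach_lumen",
    *(f"{s}_lumen" for s in _GUT_SEGMENTS),
    *(f"{s}_wall" for s in _GUT_SEGMENTS),
    "elim_hepatic",
    "elim_intestinal",
    "elim_renal",
    "fecal",
)
_IDX = {name: i for i, name in enumerate(STATE_NAMES)}
N_STATES = len(STATE_NAMES)


class ConfigurationError(ValueError):
    pass


class IntegrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class DoseEvent:
    """One administration: iv bolus, iv infusion, or oral."""

    route: str  # 'iv_bolus' | 'iv_infusion' | 'oral'
    amount: float  # mg
    start: float = 0.0  # h
    duration: float = 0.0  # h; 0 for bolus/oral

    def __post_init__(self) -> None:
        if self.route not in ("iv_bolus", "iv_infusion", "oral"):
            raise ConfigurationError(f"unknown route {self.route!r}")
        if self.amount <= 0:
            raise ConfigurationError("dose amount must be positive")
        if self.duration < 0 or self.start < 0:
            raise ConfigurationError("dose start/duration must be >= 0")
        if self.route == "iv_infusion" and self.duration <= 0:
            raise ConfigurationError("iv_infusion requires duration > 0")

    @property
    def end(self) -> float:
        if self.route == "iv_bolus":
            return self.start + BOLUS_DURATION_H
        return self.start + self.duration


@dataclass(frozen=True)
class Individual:
    """One virtual subject: physiology, drug, and random-effect multipliers.

    ``multipliers`` may carry the six sampled random effects (peff, fu_b,
    clint_l, clint_i, rb, pbsf, each in [0.67, 1.5]) plus the deterministic
    sensitivity-analysis handles ``q_l`` (liver inflow) and ``ktp`` (all
    partition coefficients jointly).
    """

    physiology: PhysiologyProfile
    drug: DrugParams
    multipliers: Mapping[str, float] = field(default_factory=dict)

    def mult(self, key: str) -> float:
        return float(self.multipliers.get(key, 1.0))

    def validate_random_effects(self, lo: float = 0.67, hi: float = 1.5) -> None:
        for key in RANDOM_EFFECT_PARAMS:
            m = self.mult(key)
            if not (lo <= m <= hi):
                raise ConfigurationError(f"multiplier {key}={m} outside [{lo}, {hi}]")


@dataclass
class SimResult:
    """Time courses for one subject and regimen (amounts in mg, conc mg/L)."""

    times: np.ndarray  # h
    plasma_conc: np.ndarray  # mg/L
    amounts: Mapping[str, np.ndarray]  # per-compartment mg
    eliminated: Mapping[str, np.ndarray]  # cumulative mg
    dose_total: float  # mg
    individual: Individual | None = None

    def amount_matrix(self) -> np.ndarray:
        return np.vstack([self.amounts[name] for name in STATE_NAMES[:22]])


@dataclass
class PbpkSystem:
    """Assembled linear system for one individual."""

    matrix: np.ndarray  # (N_STATES, N_STATES)
    v_venous: float  # L
    rb_eff: float
    individual: Individual

    def rhs(self, u: np.ndarray):
        A = self.matrix

        def fun(t: float, y: np.ndarray) -> np.ndarray:
            return A @ y + u

        return fun


def make_individual(
    age_spec: AgeSpec,
    drug: DrugParams,
    multipliers: Mapping[str, float] | None = None,
) -> Individual:
    """Convenience constructor: build physiology and wrap it with a drug."""
    return Individual(
        physiology=build_physiology(age_spec),
        drug=drug,
        multipliers=dict(multipliers or {}),
    )


def _adult_reference_profile() -> PhysiologyProfile:
    tables = load_physiology_tables()
    return build_physiology(AgeSpec(postnatal_age=float(tables["adult_reference_age"])))


_ADULT_REF_CACHE: dict[str, PhysiologyProfile] = {}


def adult_reference_profile() -> PhysiologyProfile:
    if "profile" not in _ADULT_REF_CACHE:
        _ADULT_REF_CACHE["profile"] = _adult_reference_profile()
    return _ADULT_REF_CACHE["profile"]


def build_system(individual: Individual) -> PbpkSystem:
    """Assemble the constant coefficient matrix for one subject.

    Partition coefficients are rescaled by the subject's relative unbound
    plasma fraction (unbound tissue affinity held age-invariant), hepatic
    intrinsic clearance by CYP3A ontogeny x microsomal protein mass, and
    renal clearance by relative renal perfusion.
    """
    ph = individual.physiology
    drug = individual.drug
    tables = load_physiology_tables()

    rb_eff = drug.rb * individual.mult("rb")
    fu_p = age_adjusted_fu(drug, ph)
    fu_b = min(fu_p / rb_eff * individual.mult("fu_b"), 1.0)
    kp_scale = (fu_p / drug.fu_p_adult) * individual.mult("ktp")

    missing = [t for t in (*_PERFUSED[:-1], "rest", "lung", "spleen", "kidney", "liver", *_GUT_SEGMENTS) if t not in drug.ktp]
    if missing:
        raise ConfigurationError(f"{drug.name}: missing K_t:p for tissue(s) {missing}")

    # blood pools
    v_blood = ph.organ_volumes["blood"]
    art_frac = tables["arterial_blood_fraction"]
    v_art = v_blood * art_frac
    v_ven = v_blood * (1.0 - art_frac)

    q_l_mult = individual.mult("q_l")
    flows = dict(ph.organ_flows)
    hepatic_path = ["hepatic_artery", "spleen", *_GUT_SEGMENTS]
    for t in hepatic_path:
        flows[t] = flows[t] * q_l_mult
    # stomach wall is folded into 'rest'
    flows["rest"] = flows["rest"] + flows.pop("stomach")
    q_liver_total = flows["hepatic_artery"] + flows["spleen"] + sum(flows[s] for s in _GUT_SEGMENTS)
    co_eff = sum(v for k, v in flows.items() if k not in ("liver",))
    # note: with q_l != 1 total perfusion (lung flow) changes accordingly

    def ktb(tissue: str) -> float:
        return drug.ktp[tissue] * kp_scale / rb_eff  # tissue:blood ratio

    # scaled clearances (L/h)
    clint_l = scale_clint_hepatic(
        drug.clint_l_adult * individual.mult("clint_l"),
        ph.r_cyp3a_hepatic,
        1.0,  # MPPGL and liver weight enter via PBSF below
        ph.pbsf * individual.mult("pbsf"),
    )
    adult_ref = adult_reference_profile()
    bw_ratio = ph.body_weight / adult_ref.body_weight
    clint_i_total = scale_clint_intestinal(
        drug.clint_i_adult * individual.mult("clint_i"),
        ph.population,
        r_cyp3a_i=ph.r_cyp3a_intestinal,
        r_cyp3a_hepatic=ph.r_cyp3a_hepatic,
        bw_ratio=bw_ratio,
    )
    renal_cl = drug.renal_cl_adult * (flows["kidney"] / adult_ref.organ_flows["kidney"])

    # absorption rate constants: ka = 2*Peff/r  (Peff in 1e-4 cm/s, r in m)
    peff_cm_s = drug.peff * individual.mult("peff") * 1e-4
    ka = 2.0 * peff_cm_s / (ph.intestinal_radius * 100.0) * 3600.0  # 1/h

    kge = 60.0 / ph.gastric_emptying_time  # 1/h
    ktr = {s: 60.0 / ph.intestinal_transit_times[s] for s in _GUT_SEGMENTS}

    A = np.zeros((N_STATES, N_STATES))
    i_ven, i_art, i_lung = _IDX["venous_blood"], _IDX["arterial_blood"], _IDX["lung"]
    c_art = 1.0 / v_art
    c_ven = 1.0 / v_ven

    # lung: receives total venous return, feeds arterial blood
    k_lung_out = co_eff / (ktb("lung") * ph.organ_volumes["lung"])
    A[i_lung, i_ven] += co_eff * c_ven
    A[i_ven, i_ven] -= co_eff * c_ven
    A[i_art, i_lung] += k_lung_out
    A[i_lung, i_lung] -= k_lung_out

    def perfuse(tissue: str, venous_target: int) -> float:
        """Wire arterial inflow and venous outflow of one tissue; return the
        outflow rate coefficient (fraction of tissue amount per hour)."""
        i_t = _IDX[tissue]
        q = flows[tissue]
        k_out = q / (ktb(tissue) * ph.organ_volumes[tissue])
        A[i_t, i_art] += q * c_art
        A[i_art, i_art] -= q * c_art
        A[venous_target, i_t] += k_out
        A[i_t, i_t] -= k_out
        return k_out

    for tissue in _PERFUSED:
        perfuse(tissue, i_ven)

    i_liv = _IDX["liver"]
    perfuse("spleen", i_liv)

    # kidney: perfusion + renal elimination referenced to venous concentration
    i_kid = _IDX["kidney"]
    perfuse("kidney", i_ven)
    k_renal = renal_cl / (ktb("kidney") * ph.organ_volumes["kidney"])
    A[_IDX["elim_renal"], i_kid] += k_renal
    A[i_kid, i_kid] -= k_renal

    # gut walls: perfusion (venous side joins the portal vein -> liver),
    # absorption from the lumen, and wall metabolism in duod/jej/ileum
    clint_i_seg = {
        s: clint_i_total * drug.intestinal_abundance_fraction[s] for s in _ABSORBING
    }
    for seg in _GUT_SEGMENTS:
        i_w = _IDX[f"{seg}_wall"]
        perfuse_q = flows[seg]
        k_out = perfuse_q / (ktb(seg) * ph.organ_volumes[seg])
        A[i_w, i_art] += perfuse_q * c_art
        A[i_art, i_art] -= perfuse_q * c_art
        A[i_liv, i_w] += k_out
        A[i_w, i_w] -= k_out
        if seg in _ABSORBING:
            k_met = fu_b * clint_i_seg[seg] / (ktb(seg) * ph.organ_volumes[seg])
            A[_IDX["elim_intestinal"], i_w] += k_met
            A[i_w, i_w] -= k_met

    # liver: hepatic artery inflow + total outflow + well-stirred elimination
    A[i_liv, i_art] += flows["hepatic_artery"] * c_art
    A[i_art, i_art] -= flows["hepatic_artery"] * c_art
    k_liv_out = q_liver_total / (ktb("liver") * ph.organ_volumes["liver"])
    A[i_ven, i_liv] += k_liv_out
    A[i_liv, i_liv] -= k_liv_out
    k_hep = fu_b * clint_l / (ktb("liver") * ph.organ_volumes["liver"])
    A[_IDX["elim_hepatic"], i_liv] += k_hep
    A[i_liv, i_liv] -= k_hep

    # lumen transit chain
    i_st = _IDX["stomach_lumen"]
    A[i_st, i_st] -= kge
    A[_IDX["duodenum_lumen"], i_st] += kge
    prev = None
    for seg in _GUT_SEGMENTS:
        i_lum = _IDX[f"{seg}_lumen"]
        A[i_lum, i_lum] -= ktr[seg]
        if prev is not None:
            A[i_lum, prev] += ktr_prev
        if seg in _ABSORBING:
            A[i_lum, i_lum] -= ka
            A[_IDX[f"{seg}_wall"], i_lum] += ka
        prev, ktr_prev = i_lum, ktr[seg]
    A[_IDX["fecal"], _IDX["colon_lumen"]] += ktr["colon"]

    return PbpkSystem(matrix=A, v_venous=v_ven, rb_eff=rb_eff, individual=individual)


def _default_grid(regimen: Sequence[DoseEvent], t_end: float, n_points: int) -> np.ndarray:
    grid = [np.linspace(0.0, t_end, n_points)]
    for ev in regimen:
        lo = max(ev.start - 0.02, 0.0)
        hi = min(ev.end + 0.3, t_end)
        grid.append(np.arange(lo, hi, 0.01))
        grid.append(np.array([ev.start, min(ev.end, t_end)]))
    return np.unique(np.concatenate(grid))


def simulate(
    individual: Individual,
    regimen: Sequence[DoseEvent],
    t_end: float = 24.0,
    n_points: int = 481,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    system: PbpkSystem | None = None,
) -> SimResult:
    """Integrate the system for one subject under a dosing regimen.

    Uses LSODA with the exact (constant) Jacobian; the output grid is the
    requested uniform grid refined to 0.01 h around dose events.  Plasma
    concentration is venous blood concentration divided by R_b.
    """
    if not regimen:
        raise ConfigurationError("regimen must contain at least one DoseEvent")
    if t_end <= max(ev.end for ev in regimen):
        raise ConfigurationError("t_end must exceed the last dose event")
    sys_ = system if system is not None else build_system(individual)
    A = sys_.matrix

    grid = _default_grid(regimen, t_end, n_points)

    # breakpoints where the input vector changes or impulses occur
    breaks = {0.0, t_end}
    oral_at: dict[float, float] = {}
    for ev in regimen:
        breaks.add(ev.start)
        if ev.route == "oral":
            oral_at[ev.start] = oral_at.get(ev.start, 0.0) + ev.amount
        else:
            breaks.add(ev.end)
    breaks = sorted(b for b in breaks if 0.0 <= b <= t_end)

    def input_vector(t: float) -> np.ndarray:
        u = np.zeros(N_STATES)
        for ev in regimen:
            if ev.route == "oral":
                continue
            if ev.start <= t < ev.end:
                dur = ev.end - ev.start
                u[_IDX["venous_blood"]] += ev.amount / dur
        return u

    y = np.zeros(N_STATES)
    times_out = [np.array([0.0])]
    states_out = [y.copy()[None, :]]
    jac = lambda t, y_: A  # noqa: E731

    for t0, t1 in zip(breaks[:-1], breaks[1:]):
        if t0 in oral_at:
            y[_IDX["stomach_lumen"]] += oral_at[t0]
        if t1 <= t0:
            continue
        t_eval = grid[(grid > t0 + 1e-12) & (grid <= t1 + 1e-12)]
        t_eval = np.clip(t_eval, t0, t1)
        u = input_vector(0.5 * (t0 + t1))
        fun = lambda t, y_: A @ y_ + u  # noqa: E731
        sol = solve_ivp(
            fun,
            (t0, t1),
            y,
            method="LSODA",
            jac=jac,
            rtol=rtol,
            atol=atol,
            t_eval=t_eval if t_eval.size else None,
            dense_output=False,
        )
        if not sol.success:
            raise IntegrationError(f"ODE solver failed on [{t0}, {t1}]: {sol.message}")
        if t_eval.size:
            times_out.append(sol.t)
            states_out.append(sol.y.T)
        y = sol.y[:, -1] if sol.y.size else y

    times = np.concatenate(times_out)
    states = np.vstack(states_out)
    times, keep = np.unique(np.round(times, 9), return_index=True)
    states = states[keep]

    tables = load_physiology_tables()
    v_ven = sys_.v_venous
    plasma = states[:, _IDX["venous_blood"]] / v_ven / sys_.rb_eff

    amounts = {name: states[:, i] for name, i in _IDX.items() if not name.startswith("elim") and name != "fecal"}
    eliminated = {
        "hepatic": states[:, _IDX["elim_hepatic"]],
        "intestinal": states[:, _IDX["elim_intestinal"]],
        "renal": states[:, _IDX["elim_renal"]],
        "fecal": states[:, _IDX["fecal"]],
    }
    return SimResult(
        times=times,
        plasma_conc=plasma,
        amounts=amounts,
        eliminated=eliminated,
        dose_total=sum(ev.amount for ev in regimen),
        individual=individual,
    )


def administered_by(regimen: Sequence[DoseEvent], times: np.ndarray) -> np.ndarray:
    """Cumulative administered amount (mg) at each time point.

    An oral impulse is counted strictly after its event time (the output
    snapshot exactly at the event time is pre-impulse).
    """
    total = np.zeros_like(times, dtype=float)
    for ev in regimen:
        if ev.route == "oral":
            total += np.where(times > ev.start + 1e-12, ev.amount, 0.0)
        else:
            dur = ev.end - ev.start
            frac = np.clip((times - ev.start) / dur, 0.0, 1.0)
            total += ev.amount * frac
    return total


def mass_balance_report(result: SimResult, regimen: Sequence[DoseEvent]) -> float:
    """Maximum relative mass-balance error over the simulated time course."""
    in_body = sum(result.amounts[name] for name in result.amounts)
    lost = sum(result.eliminated[name] for name in result.eliminated)
    dosed = administered_by(regimen, result.times)
    err = np.abs(dosed - (in_body + lost)) / max(result.dose_total, 1e-300)
    return float(np.max(err))
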