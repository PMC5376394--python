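"""Virtual ICU cohorts with the study population's statistical structure.

The source plasma dataset (102 intensive-care patients on ciprofloxacin
infusion therapy, 588 concentrations) is not public, so end-to-end testing of
the population machinery relies on cohorts that emulate its design: weight
77 +/- 16 kg, creatinine clearance 82 +/- 51 ml/min (both truncated at
physiologic floors), 27/102 female, a regimen mix dominated by 400 mg 1-h
infusions twice daily, treatment for 3-21 days, and sparse sampling of about
5.8 plasma concentrations per patient spread over about 3.1 dosing occasions
(an occasion = one dose administration interval).

Observations are simulated from the whole-body model with log-normal
between-subject variability on clearance and on the shared partition
coefficients, plus additive noise on the log concentration. Everything is
deterministic given the design seed.

What the generator does **not** emulate: covariate correlations (weight and
renal function are drawn independently), dropout, concentrations below the
quantification limit, and the unknown true sampling schedule — the
within-occasion template (samples around the infusion peak and trough) is a
stand-in for a typical therapeutic-drug-monitoring design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .dataset import Subject
from .pbpk_core import DoseEvent
from .physiology import Individual, PhysiologyTable
from .population_fit import PBPKLikelihood, VarianceParameters

__all__ = ["Regimen", "CohortDesign", "CohortMember", "generate_cohort",
           "generate_observations"]


@dataclass(frozen=True)
class Regimen:
    """A maintenance regimen: ``dose`` mg every ``tau`` h as a ``tinf``-h
    infusion."""

    dose: float
    tau: float
    tinf: float


#: Study regimen mix (patients per regimen out of 102).
DEFAULT_REGIMEN_MIX: dict[Regimen, float] = {
    Regimen(400.0, 12.0, 1.0): 86 / 102,
    Regimen(400.0, 8.0, 1.0): 9 / 102,
    Regimen(200.0, 12.0, 0.5): 6 / 102,
    Regimen(600.0, 12.0, 1.0): 1 / 102,
}


@dataclass
class CohortDesign:
    """Cohort-level design constants (defaults = the study population)."""

    n_subjects: int = 30
    weight_mean: float = 77.0
    weight_sd: float = 16.0
    weight_floor: float = 30.0
    age_mean: float = 60.0          # carried as metadata only
    age_sd: float = 17.0
    crcl_mean: float = 82.0
    crcl_sd: float = 51.0
    crcl_floor: float = 5.0
    female_fraction: float = 27 / 102
    regimen_mix: Mapping[Regimen, float] = field(
        default_factory=lambda: dict(DEFAULT_REGIMEN_MIX))
    samples_per_subject_mean: float = 5.8
    occasions_mean: float = 3.1
    treatment_days_min: int = 3
    treatment_days_max: int = 21
    anc: float = 2500.0
    seed: int = 12345

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("weight_sd", "crcl_sd", "age_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must lie in [0, 1]")
        wsum = sum(self.regimen_mix.values())
        if abs(wsum - 1.0) > 1e-9:
            raise ValueError(f"regimen weights must sum to 1, got {wsum}")


@dataclass(frozen=True)
class CohortMember:
    """One generated patient: covariates, regimen, dosing records, metadata."""

    individual: Individual
    regimen: Regimen
    duration_days: int
    doses: list[DoseEvent]
    age: float


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      floor: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    a = (floor - mean) / sd
    dist = stats.truncnorm(a, np.inf, loc=mean, scale=sd)
    return dist.rvs(size=size, random_state=rng)


def generate_cohort(design: CohortDesign, seed: int | None = None) -> list[CohortMember]:
    """Draw a virtual cohort with dosing records; deterministic given seed."""
    rng = np.random.default_rng(design.seed if seed is None else seed)
    n = design.n_subjects
    weights = _truncated_normal(rng, design.weight_mean, design.weight_sd,
                                design.weight_floor, n)
    crcls = _truncated_normal(rng, design.crcl_mean, design.crcl_sd,
                              design.crcl_floor, n)
    ages = rng.normal(design.age_mean, design.age_sd, size=n)
    female = rng.random(n) < design.female_fraction
    regimens = list(design.regimen_mix)
    reg_ix = rng.choice(len(regimens), size=n,
                        p=[design.regimen_mix[r] for r in regimens])
    durations = rng.integers(design.treatment_days_min,
                             design.treatment_days_max + 1, size=n)

    members = []
    for i in range(n):
        reg = regimens[reg_ix[i]]
        n_doses = int(durations[i] * 24 // reg.tau)
        doses = [DoseEvent(reg.dose, k * reg.tau, reg.tinf) for k in range(n_doses)]
        ind = Individual(
            id=f"S{i + 1:03d}", weight=float(weights[i]),
            sex="female" if female[i] else "male",
            crcl=float(crcls[i]), anc=design.anc,
        )
        members.append(CohortMember(individual=ind, regimen=reg,
                                    duration_days=int(durations[i]),
                                    doses=doses, age=float(ages[i])))
    return members


def _sampling_times(rng: np.random.Generator, member: CohortMember,
                    design: CohortDesign) -> np.ndarray:
    """Sparse sampling: ~Poisson(5.8) samples over ~Poisson(3.1) occasions."""
    tau = member.regimen.tau
    n_intervals = len(member.doses)
    n_obs = max(1, int(rng.poisson(design.samples_per_subject_mean)))
    n_occ = max(1, min(n_intervals, int(rng.poisson(design.occasions_mean))))
    occasions = np.sort(rng.choice(n_intervals, size=n_occ, replace=False))
    # TDM-style template: infusion peak, distribution phase, trough
    template = np.array([0.5, 1.0, 1.5, 2.0, tau / 2.0, tau - 0.5])
    times = []
    for j in range(n_obs):
        occ = occasions[j % n_occ]
        base = template[j % template.size]
        t = occ * tau + base + rng.normal(0.0, 0.15)
        t = occ * tau + np.clip(t - occ * tau, 1.0 / 12.0, tau - 1.0 / 12.0)
        times.append(t)
    return np.unique(np.asarray(times))


def generate_observations(
    cohort: Sequence[CohortMember],
    theta: Mapping[str, float],
    variance: VarianceParameters,
    design: CohortDesign,
    seed: int | None = None,
    table: PhysiologyTable | None = None,
    fu_plasma: float | None = None,
    elimination_site: str = "organ",
    eta_cl_on: str = "total",
) -> list[Subject]:
    """Simulate sparse log plasma concentrations for a cohort.

    Per subject: draw the two random effects, predict the plasma profile
    from the whole-body model under the subject's own regimen, sample the
    sparse schedule, and add residual noise on the log scale
    (``DV = log C + N(0, sigma^2)``). Deterministic given ``seed``.
    """
    rng = np.random.default_rng(design.seed + 1 if seed is None else seed)
    schedules = [_sampling_times(rng, m, design) for m in cohort]
    skeleton = [Subject(individual=m.individual, doses=m.doses,
                        obs_times=t, dv=np.zeros(t.size))
                for m, t in zip(cohort, schedules)]
    lik = PBPKLikelihood(skeleton, table=table, fu_plasma=fu_plasma,
                         elimination_site=elimination_site, eta_cl_on=eta_cl_on)
    subjects = []
    for i, member in enumerate(cohort):
        eta = (rng.normal(0.0, variance.omega_cl) if variance.omega_cl > 0 else 0.0,
               rng.normal(0.0, variance.omega_kp) if variance.omega_kp > 0 else 0.0)
        f = lik.predict_log(theta, eta, i)
        noise = (rng.normal(0.0, variance.sigma, size=f.size)
                 if variance.sigma > 0 else 0.0)
        subjects.append(Subject(individual=member.individual, doses=member.doses,
                                obs_times=skeleton[i].obs_times, dv=f + noise))
    return subjects
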