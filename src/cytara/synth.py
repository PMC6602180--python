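"""Synthetic cohorts with the statistical structure of consolidation-cycle data.

The generator emulates a small AML consolidation cohort: 23 patients with
one to three cycles each (9/9/5 patients), schedules D135/d135/D123/D12 in
the cycle-frequency mix 23/15/2/2, almost-daily WBC counts (G/L) over
~30-day cycles with multiplicative lognormal measurement noise, patient-level
lognormal variability of the four personalised parameters, and a per-cycle
"carry-over" perturbation of the starting WBC count around the baseline.
It also produces sparse plasma-concentration samples for the PK submodel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .fitting import CycleData, DEFAULT_BOUNDS
from .models import ModelConstants, ModelSpec, PDParameters, simulate_model
from .pk import InfusionSchedule, PKParameters, PKSolution
from .schedules import build_schedule

#: median "true" parameters of the default cohort.  Baseline 5.5 G/L (normal
#: range minus the post-induction deficit), k_tr 0.1875/day (a 128-h mean
#: maturation time with one transit compartment), and slope/gamma chosen so
#: that the reference D135 course of the median patient reaches a nadir of
#: ~0.3 G/L and recovers above 1 G/L around day 23, matching observed
#: consolidation-cycle summaries.
DEFAULT_MEDIANS = {"b": 5.5, "slope": 5.5, "k_tr": 0.1875, "gamma": 0.55}


@dataclass
class CohortSpec:
    """Study-design knobs of the synthetic cohort."""

    n_patients: int = 23
    cycle_counts: tuple[int, ...] = (1, 2, 3)
    cycle_count_weights: tuple[float, ...] = (9.0, 9.0, 5.0)
    schedule_weights: dict = field(default_factory=lambda: {
        "D135": 23.0, "d135": 15.0, "D123": 2.0, "D12": 2.0})
    medians: dict = field(default_factory=lambda: dict(DEFAULT_MEDIANS))
    cv: dict = field(default_factory=lambda: {"b": 0.25, "slope": 0.3,
                                              "k_tr": 0.25, "gamma": 0.3})
    carryover_cv: float = 0.2
    sigma_log: float = 0.15
    cycle_length: float = 30.0
    sample_interval: float = 1.0
    dropout: float = 0.1
    bsa_mean: float = 1.78
    bsa_sd: float = 0.15
    seed: int = 12345

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.cycle_count_weights) or any(
                w < 0 for w in self.schedule_weights.values()):
            raise ValueError("weights must be non-negative")
        for d in (self.medians, self.cv):
            for v in d.values():
                if v < 0:
                    raise ValueError("scales must be non-negative")


@dataclass
class SyntheticPatient:
    patient_id: str
    params: PDParameters  # core parameters (no initial-state entries)
    n_cycles: int
    schedule_label: str
    bsa: float


def _lognormal(rng: np.random.Generator, median: float, cv: float) -> float:
    if cv == 0:
        return median
    return median * math.exp(rng.normal(0.0, math.sqrt(math.log1p(cv * cv))))


def sample_parameters(spec: CohortSpec, rng: np.random.Generator | None = None
                      ) -> list[SyntheticPatient]:
    """Draw per-patient true parameters, cycle counts, schedules and BSA.

    Parameters are lognormal around the spec medians and clipped into the
    personalisation bounds so every generated patient is representable by
    the estimator.  Reproducible for a fixed spec seed.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    cw = np.asarray(spec.cycle_count_weights, dtype=float)
    cw = cw / cw.sum()
    labels = list(spec.schedule_weights)
    sw = np.asarray([spec.schedule_weights[k] for k in labels], dtype=float)
    sw = sw / sw.sum()
    patients = []
    for i in range(spec.n_patients):
        draws = {}
        for name in ("b", "slope", "k_tr", "gamma"):
            lo, hi = DEFAULT_BOUNDS[name]
            draws[name] = float(np.clip(
                _lognormal(rng, spec.medians[name], spec.cv.get(name, 0.0)), lo, hi))
        n_cycles = int(rng.choice(spec.cycle_counts, p=cw))
        label = str(rng.choice(labels, p=sw))
        bsa = float(np.clip(rng.normal(spec.bsa_mean, spec.bsa_sd), 1.2, 2.5))
        patients.append(SyntheticPatient(
            patient_id=f"P{i + 1:02d}", params=PDParameters(**draws),
            n_cycles=n_cycles, schedule_label=label, bsa=bsa))
    return patients


def _cycle_initial_params(core: PDParameters, consts: ModelConstants,
                          spec: CohortSpec, rng: np.random.Generator) -> PDParameters:
    """Carry-over emulation: perturb the cycle's starting state around the
    homeostatic values with lognormal CVs."""
    bbm = core.b_bm(consts)
    return replace(core,
                   b0=_lognormal(rng, core.b, spec.carryover_cv),
                   xpr0=_lognormal(rng, bbm, spec.carryover_cv),
                   xtr0=_lognormal(rng, bbm, spec.carryover_cv))


def simulate_cycle(model: ModelSpec, params: PDParameters, consts: ModelConstants,
                   pk: PKParameters, schedule: InfusionSchedule, spec: CohortSpec,
                   rng: np.random.Generator, cycle_id: str,
                   patient_id: str | None = None) -> CycleData:
    """One observed cycle: model trajectory sampled on a thinned daily grid
    with multiplicative lognormal noise (DV always > 0)."""
    grid_days = np.arange(0.0, spec.cycle_length + 1e-9, spec.sample_interval)
    keep = rng.random(grid_days.size) >= spec.dropout
    keep[0] = True  # always keep the pre-dose baseline sample
    times = grid_days[keep]
    sim_grid = np.unique(np.concatenate([[0.0], times]))
    traj = simulate_model(model, params, consts, pk, schedule, sim_grid)
    lookup = dict(zip(traj.times, traj.wbc))
    clean = np.array([lookup[t] for t in times])
    noise = np.exp(rng.normal(0.0, spec.sigma_log, size=clean.size)) if spec.sigma_log > 0 else 1.0
    wbc = np.maximum(clean * noise, 1e-6)
    return CycleData(cycle_id=cycle_id, times=times, wbc=wbc, schedule=schedule,
                     label=schedule.label, patient_id=patient_id)


def simulate_cohort(spec: CohortSpec, model: ModelSpec, pk: PKParameters,
                    consts: ModelConstants | None = None,
                    ) -> tuple[list[CycleData], list[SyntheticPatient]]:
    """Generate the full cohort of cycles under one true model variant.

    Per-cycle initial states are perturbed around homeostasis (the carry-over
    effect) when the model's strategy can represent them (I2/I3); I1 models
    start each cycle at the steady state.  A failed simulation is logged and
    regenerated with a fresh sub-seed.
    """
    consts = ModelConstants.from_pk(pk) if consts is None else consts
    rng = np.random.default_rng(spec.seed)
    patients = sample_parameters(spec, rng)
    cycles = []
    for patient in patients:
        schedule = build_schedule(patient.schedule_label, bsa=patient.bsa)
        for c in range(patient.n_cycles):
            cid = f"{patient.patient_id}C{c + 1}"
            for attempt in range(5):
                params = patient.params
                if model.init == "I2":
                    params = replace(params, b0=_lognormal(rng, params.b, spec.carryover_cv))
                elif model.init == "I3":
                    params = _cycle_initial_params(params, consts, spec, rng)
                try:
                    cycles.append(simulate_cycle(model, params, consts, pk, schedule,
                                                 spec, rng, cid, patient.patient_id))
                    break
                except RuntimeError:
                    continue
            else:
                raise RuntimeError(f"could not generate cycle {cid} after 5 attempts")
    return cycles, patients


def gen_pk_concentration_data(pk: PKParameters, schedule: InfusionSchedule,
                              sample_times: np.ndarray, sigma_log: float = 0.2,
                              seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Sparse concentration samples under the exponential error model
    conc = (x1/Vc) * exp(sigma * z); returns (times, concentrations)."""
    rng = np.random.default_rng(seed)
    sample_times = np.asarray(sample_times, dtype=float)
    sol = PKSolution(pk, schedule)
    clean = sol.amounts(sample_times)[:, 0] / pk.vc
    if np.any(clean <= 0):
        raise ValueError("sample times must fall where the concentration is positive")
    noise = np.exp(rng.normal(0.0, sigma_log, size=clean.size)) if sigma_log > 0 else 1.0
    return sample_times, clean * noise


def pk_reference_schedule(bsa: float = 1.78) -> InfusionSchedule:
    """The concentration-sampling regimen behind the default PK parameters:
    3 g/m2 over 3 h every 12 h on days 1, 2, 8 and 9."""
    from .pk import DoseEvent
    events = []
    for day in (1, 2, 8, 9):
        for half in (0.0, 0.5):
            events.append(DoseEvent((day - 1) + half, 0.125, 3000.0 * bsa))
    return InfusionSchedule(tuple(events), bsa=bsa, label="PK-reference")


def pk_reference_sample_times(n: int = 86, seed: int = 0) -> np.ndarray:
    """Sampling times mimicking day-1 and day-8 pharmacokinetic profiling:
    draws within 12 h of the first infusion of each sampled day."""
    rng = np.random.default_rng(seed)
    half = n // 2
    day1 = rng.uniform(1.0 / 24.0, 0.5, size=half)
    day8 = 7.0 + rng.uniform(1.0 / 24.0, 0.5, size=n - half)
    return np.sort(np.concatenate([day1, day8]))
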