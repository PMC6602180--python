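"""Schedule construction, recovery statistics and the simulation studies.

Recovery statistics are the model-discrimination currency here: ``t_rec``
(first time the WBC count recovers above 1 G/L after the nadir), ``t_leu``
(total time with WBC <= 1 G/L) and the ``nadir`` (minimum WBC).  Schedule
labels follow the consolidation-therapy convention: capital D = 3 g/m2,
lowercase d = 1 g/m2, given as two 3-h infusions 12 h apart on the listed
cycle days (day d of a cycle maps to t = d - 1, first dose at t = 0);
C100/C400 are 5-day continuous infusions at 100 or 400 mg/m2 per day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .fitting import CycleData
from .models import (ModelConstants, ModelSpec, PDParameters, Trajectory,
                     get_model, simulate_model)
from .pk import DoseEvent, InfusionSchedule, PKParameters

_BOLUS_SCHEDULES = {
    "D135": ((1, 3, 5), 3000.0),
    "d135": ((1, 3, 5), 1000.0),
    "D123": ((1, 2, 3), 3000.0),
    "D12": ((1, 2), 3000.0),
}
_CONTINUOUS_SCHEDULES = {"C100": 100.0, "C400": 400.0}

INFUSION_DURATION = 0.125  # 3 h in days
LEUKOPENIA_THRESHOLD = 1.0  # G/L


def build_schedule(label: str, bsa: float = 1.78, start: float = 0.0) -> InfusionSchedule:
    """Expand a schedule label into BSA-scaled infusion events.

    ``start`` offsets the whole block (days); the first dose of day 1 is at
    t = start.  Total administered mass is exactly
    sum(per-dose g/m2) * bsa * 1000.
    """
    if label in _BOLUS_SCHEDULES:
        days, per_m2 = _BOLUS_SCHEDULES[label]
        events = []
        for d in days:
            for half in (0.0, 0.5):
                events.append(DoseEvent(start + (d - 1) + half, INFUSION_DURATION, per_m2 * bsa))
        return InfusionSchedule(tuple(events), bsa=bsa, label=label)
    if label in _CONTINUOUS_SCHEDULES:
        daily = _CONTINUOUS_SCHEDULES[label]
        return InfusionSchedule((DoseEvent(start, 5.0, daily * 5.0 * bsa),), bsa=bsa, label=label)
    raise ValueError(f"unknown schedule label {label!r}; expected one of "
                     f"{sorted(_BOLUS_SCHEDULES) + sorted(_CONTINUOUS_SCHEDULES)}")


@dataclass
class RecoveryStats:
    """t_rec and t_leu in days (NaN when undefined), nadir in G/L."""

    t_rec: float
    t_leu: float
    nadir: float


def recovery_stats(traj: Trajectory | tuple[np.ndarray, np.ndarray],
                   threshold: float = LEUKOPENIA_THRESHOLD) -> RecoveryStats:
    """Recovery statistics of a dense simulated trajectory.

    ``t_leu`` is the total time spent at or below the threshold (linear
    interpolation of the crossings); ``t_rec`` is the first up-crossing of
    the threshold after the global nadir, NaN if the WBC never dips to the
    threshold or never recovers within the trajectory.
    """
    if isinstance(traj, Trajectory):
        t, w = traj.times, traj.wbc
    else:
        t, w = np.asarray(traj[0], dtype=float), np.asarray(traj[1], dtype=float)
    nadir = float(np.min(w))
    if nadir > threshold:
        return RecoveryStats(t_rec=math.nan, t_leu=0.0, nadir=nadir)

    below = w <= threshold
    t_leu = 0.0
    # accumulate interval lengths below threshold, interpolating the edges
    for i in range(len(t) - 1):
        b0, b1 = below[i], below[i + 1]
        dt = t[i + 1] - t[i]
        if b0 and b1:
            t_leu += dt
        elif b0 != b1:
            frac = (threshold - w[i]) / (w[i + 1] - w[i])
            t_leu += dt * (1.0 - frac) if b1 else dt * frac

    i_nadir = int(np.argmin(w))
    t_rec = math.nan
    for i in range(i_nadir, len(t) - 1):
        if w[i] <= threshold < w[i + 1]:
            frac = (threshold - w[i]) / (w[i + 1] - w[i])
            t_rec = float(t[i] + frac * (t[i + 1] - t[i]))
            break
    return RecoveryStats(t_rec=t_rec, t_leu=t_leu, nadir=nadir)


def observed_recovery_stats(cycle: CycleData,
                            threshold: float = LEUKOPENIA_THRESHOLD) -> RecoveryStats:
    """Same statistics evaluated on the discrete measurement grid.

    ``t_leu`` counts measurement days with WBC <= threshold; ``t_rec`` is the
    first measurement time after the observed minimum with WBC > threshold.
    """
    if cycle.times.size == 0:
        raise ValueError("cycle has no observations")
    w = cycle.wbc
    nadir = float(np.min(w))
    if nadir > threshold:
        return RecoveryStats(t_rec=math.nan, t_leu=0.0, nadir=nadir)
    t_leu = float(np.sum(w <= threshold))
    i_nadir = int(np.argmin(w))
    t_rec = math.nan
    for i in range(i_nadir, w.size):
        if w[i] > threshold:
            t_rec = float(cycle.times[i])
            break
    return RecoveryStats(t_rec=t_rec, t_leu=t_leu, nadir=nadir)


# ---------------------------------------------------------------------------
# model discrimination across schedules
# ---------------------------------------------------------------------------

@dataclass
class PersonalisedModel:
    """A model variant with parameters estimated from one cycle/patient."""

    pm_id: str
    spec: ModelSpec
    params: PDParameters
    consts: ModelConstants
    bsa: float = 1.78


@dataclass
class DiscriminationReport:
    included: list[str]
    excluded: list[str]
    stats: dict  # (model, schedule) -> {"t_rec": array, "t_leu": array, "nadir": array}
    summary: dict  # (model, schedule) -> {stat: {"median","sd","min","max"}}
    median_trec_diff: dict  # model -> median per-PM t_rec difference between schedules


def _summaries(values: np.ndarray) -> dict:
    v = values[np.isfinite(values)]
    if v.size == 0:
        return {"median": math.nan, "sd": math.nan, "min": math.nan, "max": math.nan}
    return {"median": float(np.median(v)), "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
            "min": float(np.min(v)), "max": float(np.max(v))}


def discrimination_study(pms: Sequence[PersonalisedModel], pk: PKParameters,
                         schedules: tuple[str, str] = ("D123", "D135"),
                         threshold: float = LEUKOPENIA_THRESHOLD,
                         horizon: float = 45.0, step: float = 0.05) -> DiscriminationReport:
    """Simulate every personalised model under both schedules and compare.

    Any personalised cycle (identified by ``pm_id``) for which at least one
    (model, schedule) prediction produces no WBC count below the threshold is
    excluded entirely, so that recovery times are never compared against a
    non-event.  Per model and schedule, median/SD/min/max of t_rec, t_leu and
    nadir over the included cycles are reported, plus each model's median
    per-cycle t_rec difference (second schedule minus first).
    """
    grid = np.arange(0.0, horizon + step / 2, step)
    raw: dict = {}
    pm_ids = sorted({pm.pm_id for pm in pms})
    no_leukopenia = set()
    for pm in pms:
        for label in schedules:
            sched = build_schedule(label, bsa=pm.bsa)
            traj = simulate_model(pm.spec, pm.params, pm.consts, pk, sched, grid)
            rs = recovery_stats(traj, threshold)
            raw[(pm.pm_id, pm.spec.name, label)] = rs
            if rs.nadir > threshold:
                no_leukopenia.add(pm.pm_id)
    included = [i for i in pm_ids if i not in no_leukopenia]
    if not included:
        raise RuntimeError("every personalised model was excluded (no leukopenia predicted)")

    model_names = sorted({pm.spec.name for pm in pms}, key=lambda n: (len(n), n))
    stats: dict = {}
    summary: dict = {}
    diffs: dict = {}
    for model in model_names:
        per_sched = {}
        for label in schedules:
            rs_list = [raw[(i, model, label)] for i in included if (i, model, label) in raw]
            arrs = {
                "t_rec": np.array([r.t_rec for r in rs_list]),
                "t_leu": np.array([r.t_leu for r in rs_list]),
                "nadir": np.array([r.nadir for r in rs_list]),
            }
            stats[(model, label)] = arrs
            summary[(model, label)] = {k: _summaries(v) for k, v in arrs.items()}
            per_sched[label] = arrs["t_rec"]
        a, b = per_sched[schedules[0]], per_sched[schedules[1]]
        if a.size and a.size == b.size:
            d = b - a
            d = d[np.isfinite(d)]
            diffs[model] = float(np.median(d)) if d.size else math.nan
    return DiscriminationReport(included=included, excluded=sorted(no_leukopenia),
                                stats=stats, summary=summary, median_trec_diff=diffs)


# ---------------------------------------------------------------------------
# treatment-timing study
# ---------------------------------------------------------------------------

def timing_study(spec: ModelSpec, params: PDParameters, consts: ModelConstants,
                 pk: PKParameters, last_schedule: InfusionSchedule,
                 shifts: Sequence[int] = tuple(range(-10, 11)),
                 history: Optional[InfusionSchedule] = None,
                 post_horizon: float = 35.0, step: float = 0.05,
                 y0: Optional[np.ndarray] = None) -> dict:
    """Translate the last cycle's dosing block and record the resulting nadir.

    ``history`` holds the patient's earlier, already-administered cycles;
    those events stay fixed while the last block is moved by each shift in
    days (the clinically actionable lever).  The nadir is the minimum WBC
    after the shifted block's first dose.  Shifts that would push dosing
    before the simulation origin raise ``ValueError``.
    """
    fixed = history.events if history is not None else ()
    results = []
    nominal = math.nan
    for shift in shifts:
        moved = last_schedule.shifted(float(shift))
        sched = InfusionSchedule(fixed + moved.events, bsa=last_schedule.bsa,
                                 label=last_schedule.label)
        t_end = sched.end + post_horizon
        grid = np.arange(0.0, t_end + step / 2, step)
        traj = simulate_model(spec, params, consts, pk, sched, grid, y0=y0)
        t_first = min(e.start for e in moved.events)
        nadir = float(np.min(traj.wbc[traj.times >= t_first]))
        if shift == 0:
            nominal = nadir
        else:
            results.append((int(shift), nadir))
    return {"shifts": results, "nominal_nadir": nominal}


# ---------------------------------------------------------------------------
# PK inter-individual-variability sensitivity study
# ---------------------------------------------------------------------------

def lognormal_draws(median: float, cv: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Lognormal samples with the given median and coefficient of variation
    (sdlog = sqrt(ln(1 + cv^2)), meanlog = ln(median))."""
    if cv == 0:
        return np.full(n, median)
    sdlog = math.sqrt(math.log1p(cv * cv))
    return median * np.exp(rng.normal(0.0, sdlog, size=n))


def iiv_study(pop_params: PDParameters, pk: PKParameters,
              model_names: tuple[str, ...] = ("M3", "M10"),
              cv_cl: float = 0.45, cv_vc: float = 0.70, n: int = 500,
              seed: int = 0, schedules: tuple[str, ...] = ("D123", "D135"),
              bsa: float = 1.78, k_ma: float | None = None,
              threshold: float = LEUKOPENIA_THRESHOLD,
              horizon: float = 45.0, step: float = 0.05) -> dict:
    """Propagate lognormal PK variability (CV on CL and Vc) into t_rec.

    Per draw, CL and Vc are sampled at the stated CVs with Q and Vp held
    fixed, the micro constants and the unit constant c_V are re-derived, and
    every model x schedule combination is simulated with the same fixed
    population PD parameters (steady-state initial conditions, I1).  Returns
    arrays of t_rec (NaN where no leukopenia occurred) keyed by
    (model, schedule), plus the realised CL/Vc draws.
    """
    rng = np.random.default_rng(seed)
    cl = lognormal_draws(pk.cl, cv_cl, n, rng)
    vc = lognormal_draws(pk.vc, cv_vc, n, rng)
    kma = k_ma if k_ma is not None else ModelConstants().k_ma

    grid = np.arange(0.0, horizon + step / 2, step)
    out = {(m, s): np.full(n, math.nan) for m in model_names for s in schedules}
    failures = 0
    for i in range(n):
        pk_i = PKParameters.from_macro(cl=cl[i], q=pk.q, vc=vc[i], vp=pk.vp)
        consts_i = ModelConstants.from_pk(pk_i, k_ma=kma)
        for name in model_names:
            spec = replace(get_model(name), init="I1")
            for label in schedules:
                sched = build_schedule(label, bsa=bsa)
                try:
                    traj = simulate_model(spec, pop_params, consts_i, pk_i, sched, grid)
                except RuntimeError:
                    failures += 1
                    continue
                out[(name, label)][i] = recovery_stats(traj, threshold).t_rec
    return {"t_rec": out, "cl": cl, "vc": vc, "n_failures": failures}
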