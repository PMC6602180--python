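"""Transit-compartment models of Ara-C-induced myelosuppression (M1-M12).

All twelve variants share the Friberg-type structure: a proliferating
compartment ``x_pr``, ``n_tr`` transit (maturation) compartments, and the
circulating white-blood-cell pool ``x_ma`` (G/L):

    dx_pr/dt    = F x_pr - G x_pr
    dx_tr,1/dt  = G (x_pr - x_tr,1)
    ...
    dx_ma/dt    = G x_tr,n - k_ma x_ma

The drug acts through the central-compartment Ara-C amount ``x1`` via the
log-linear effect  E = slope * ln(1 + c_V x1)  and, in the extended variants,
through the secondary saturation term  S(x1) = 1 + ln(1 + c_V x1)  which
rescales rates or the feedback exponent.  The variants differ only in the
proliferation law F, the maturation law G, and the initial-condition
strategy:

=====  ====  ====  ==========================================================
model  n_tr  init  F (proliferation rate), G (maturation rate)
=====  ====  ====  ==========================================================
M1     6     I1    F = (1-E) k_tr (B/x_ma)^gamma,            G = k_tr
M2     3     I1    (the classical three-transit model)
M3     1     I1    single transit compartment
M4     1     I2    as M3, initial circulating count B0 estimated
M5     1     I3    as M3, all initial states estimated (penalised)
M6     1     I3    F = k_tr (B/x_ma)^gamma - E  (direct kill on x_pr)
M7     1     I3    F = (1-E) k_tr/S (B/x_ma)^gamma,          G = k_tr/S
M8     1     I3    F = (1-E) k_tr/S (B/x_ma)^gamma
M9     1     I3    F = (1-E) k_tr/S (B/x_ma)^(gamma S)
M10    1     I3    F = (1-E) k_tr (B/x_ma)^(gamma S)
M11    1     I3    F = (1-E) k_tr (B_bm/(0.01 x_pr + 0.99 x_tr))^gamma
M12    1     I3    as M11 with exponent gamma S
=====  ====  ====  ==========================================================

with B_bm = B k_ma / k_tr the bone-marrow baseline.  Initial-condition
strategies: I1 pins every compartment at its homeostatic steady state; I2
frees the initial circulating count B0; I3 additionally frees the initial
proliferating/transit amounts (deviations from B_bm are penalised during
fitting, see :mod:`cytara.fitting`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.integrate

from .pk import HOURS_PER_DAY, InfusionSchedule, PKParameters, PKSolution

#: molar mass of cytarabine, g/mol
MM_CYTARABINE = 243.22

#: default apoptosis rate of circulating WBC, 1/day (7 h circulating half-life)
KMA_DEFAULT = 2.3765

_DENOM_FLOOR = 1e-12


@dataclass(frozen=True)
class ModelConstants:
    """Fixed constants shared by all model variants.

    ``k_ma`` (1/day) is the death rate of circulating WBC; ``c_v`` (1/mg)
    converts a central-compartment Ara-C amount into its molar central
    concentration in umol/L, c_V = 1000/(Vc * MM_cyt), the scale on which
    the log-linear effect E and the secondary term S operate (a 3 g/m2
    infusion peaks near 50 umol/L, so E and S are O(1) quantities there).
    """

    k_ma: float = KMA_DEFAULT
    c_v: float = 1000.0 / (37.6571 * MM_CYTARABINE)

    def __post_init__(self) -> None:
        if not (self.k_ma > 0 and self.c_v > 0):
            raise ValueError("k_ma and c_v must be strictly positive")

    @classmethod
    def from_pk(cls, pk: PKParameters, k_ma: float = KMA_DEFAULT,
                mm_cyt: float = MM_CYTARABINE) -> "ModelConstants":
        return cls(k_ma=k_ma, c_v=1000.0 / (pk.vc * mm_cyt))


@dataclass(frozen=True)
class PDParameters:
    """Personalised parameters: baseline B (G/L), drug-effect slope,
    transition rate k_tr (1/day), feedback exponent gamma, plus the optional
    initial-state parameters used by I2 (b0) and I3 (b0, xpr0, xtr0)."""

    b: float
    slope: float
    k_tr: float
    gamma: float
    b0: Optional[float] = None
    xpr0: Optional[float] = None
    xtr0: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("b", "slope", "k_tr", "gamma"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        for name in ("b0", "xpr0", "xtr0"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be strictly positive when given, got {v}")

    def b_bm(self, consts: ModelConstants) -> float:
        """Bone-marrow baseline B_bm = B * k_ma / k_tr (G/L-equivalent)."""
        return self.b * consts.k_ma / self.k_tr


@dataclass(frozen=True)
class ModelSpec:
    """Structural choices of one variant; see the module docstring table."""

    name: str
    n_tr: int
    init: str  # I1 | I2 | I3
    direct_kill: bool = False      # E subtracted from the per-cell rate (M6)
    f_over_s: bool = False         # whole F divided by S (M7, M8, M9)
    gamma_scaled: bool = False     # feedback exponent gamma*S (M9, M10, M12)
    g_over_s: bool = False         # maturation rate k_tr/S (M7)
    marrow_feedback: bool = False  # feedback on 0.01 x_pr + 0.99 x_tr (M11, M12)

    def __post_init__(self) -> None:
        if self.init not in ("I1", "I2", "I3"):
            raise ValueError(f"unknown initial-condition strategy {self.init!r}")
        if self.n_tr < 1:
            raise ValueError("n_tr must be >= 1")

    @property
    def n_states(self) -> int:
        """PD state dimension: x_pr, n_tr transits, x_ma."""
        return self.n_tr + 2


MODELS: dict[str, ModelSpec] = {
    "M1": ModelSpec("M1", 6, "I1"),
    "M2": ModelSpec("M2", 3, "I1"),
    "M3": ModelSpec("M3", 1, "I1"),
    "M4": ModelSpec("M4", 1, "I2"),
    "M5": ModelSpec("M5", 1, "I3"),
    "M6": ModelSpec("M6", 1, "I3", direct_kill=True),
    "M7": ModelSpec("M7", 1, "I3", f_over_s=True, g_over_s=True),
    "M8": ModelSpec("M8", 1, "I3", f_over_s=True),
    "M9": ModelSpec("M9", 1, "I3", f_over_s=True, gamma_scaled=True),
    "M10": ModelSpec("M10", 1, "I3", gamma_scaled=True),
    "M11": ModelSpec("M11", 1, "I3", marrow_feedback=True),
    "M12": ModelSpec("M12", 1, "I3", marrow_feedback=True, gamma_scaled=True),
}


def get_model(name: str) -> ModelSpec:
    try:
        return MODELS[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; expected one of {sorted(MODELS)}") from None


# ---------------------------------------------------------------------------
# rate laws
# ---------------------------------------------------------------------------

def pd_effect(x1: float, slope: float, c_v: float) -> float:
    """Log-linear drug effect E = slope * ln(1 + c_V x1); E(0) = 0."""
    if x1 < 0:
        raise ValueError(f"x1 must be non-negative, got {x1}")
    return slope * math.log1p(c_v * x1)


def saturation(x1: float, c_v: float) -> float:
    """Secondary-effect term S(x1) = 1 + ln(1 + c_V x1) >= 1, increasing."""
    if x1 < 0:
        raise ValueError(f"x1 must be non-negative, got {x1}")
    return 1.0 + math.log1p(c_v * x1)


def proliferation_rate(spec: ModelSpec, p: PDParameters, consts: ModelConstants,
                       x1: float, xpr: float, xtr1: float, xma: float) -> float:
    """Per-cell proliferation rate F (1/day) of the variant ``spec``.

    For the direct-kill variant (M6) the returned value is the *net* rate
    k_tr (B/x_ma)^gamma - E, which may be negative; no clipping is applied.
    """
    e = pd_effect(x1, p.slope, consts.c_v)
    if spec.marrow_feedback:
        denom = max(0.01 * xpr + 0.99 * xtr1, _DENOM_FLOOR)
        base = p.b_bm(consts) / denom
    else:
        base = p.b / max(xma, _DENOM_FLOOR)
    exponent = p.gamma
    s = 1.0
    if spec.gamma_scaled or spec.f_over_s or spec.g_over_s:
        s = saturation(x1, consts.c_v)
    if spec.gamma_scaled:
        exponent = p.gamma * s
    feedback = base ** exponent
    if spec.direct_kill:
        f = p.k_tr * feedback - e
    else:
        f = (1.0 - e) * p.k_tr * feedback
    if spec.f_over_s:
        f = f / s
    return f


def maturation_rate(spec: ModelSpec, p: PDParameters, consts: ModelConstants,
                    x1: float) -> float:
    """Maturation rate G (1/day): k_tr, reduced to k_tr/S(x1) for M7."""
    if spec.g_over_s:
        return p.k_tr / saturation(x1, consts.c_v)
    return p.k_tr


# ---------------------------------------------------------------------------
# vector fields
# ---------------------------------------------------------------------------

def rhs_pd(spec: ModelSpec, p: PDParameters, consts: ModelConstants,
           x1: float, y: np.ndarray) -> np.ndarray:
    """Time derivative of the PD states ``y = [x_pr, x_tr1..x_trn, x_ma]``
    given the current central Ara-C amount ``x1`` (mg)."""
    xpr = y[0]
    xma = y[-1]
    f = proliferation_rate(spec, p, consts, x1, xpr, y[1], xma)
    g = maturation_rate(spec, p, consts, x1)
    dy = np.empty_like(y)
    dy[0] = (f - g) * xpr
    prev = xpr
    for i in range(1, spec.n_tr + 1):
        dy[i] = g * (prev - y[i])
        prev = y[i]
    dy[-1] = g * y[spec.n_tr] - consts.k_ma * xma
    if not np.all(np.isfinite(dy)):
        raise FloatingPointError(f"non-finite derivative at state {y!r}, x1={x1}")
    return dy


def rhs(spec: ModelSpec, p: PDParameters, consts: ModelConstants,
        pk: PKParameters, schedule: InfusionSchedule, t: float,
        state: np.ndarray) -> np.ndarray:
    """Full coupled vector field over ``state = [x1, x2, x_pr, x_tr.., x_ma]``.

    The closed-form PK route in :func:`simulate_model` is the production
    path; this explicit RHS exists for checking and for custom integration.
    """
    x1, x2 = state[0], state[1]
    rate = sum(e.rate for e in schedule.events if e.start <= t < e.end)
    k10 = pk.k10 * HOURS_PER_DAY
    k12 = pk.k12 * HOURS_PER_DAY
    k21 = pk.k21 * HOURS_PER_DAY
    dpk = np.array([-(k10 + k12) * x1 + k21 * x2 + rate, k12 * x1 - k21 * x2])
    return np.concatenate([dpk, rhs_pd(spec, p, consts, max(x1, 0.0), state[2:])])


def initial_state(spec: ModelSpec, p: PDParameters, consts: ModelConstants) -> np.ndarray:
    """PD initial state per the variant's strategy (PK always starts at 0).

    I1: every compartment at its steady state (x_pr = x_tr = B_bm, x_ma = B);
    I2: x_ma = B0 estimated, marrow compartments at B_bm;
    I3: x_pr = xpr0, x_tr = xtr0, x_ma = B0, all estimated.
    """
    bbm = p.b_bm(consts)
    if spec.init == "I1":
        y = [bbm] * (spec.n_tr + 1) + [p.b]
    elif spec.init == "I2":
        if p.b0 is None:
            raise ValueError("I2 requires the initial-count parameter b0")
        y = [bbm] * (spec.n_tr + 1) + [p.b0]
    else:  # I3
        if p.b0 is None or p.xpr0 is None or p.xtr0 is None:
            raise ValueError("I3 requires b0, xpr0 and xtr0")
        y = [p.xpr0] + [p.xtr0] * spec.n_tr + [p.b0]
    return np.array(y, dtype=float)


def _make_fast_rhs(spec: ModelSpec, p: PDParameters, consts: ModelConstants,
                   central_amount) -> "callable":
    """Specialised odeint-style RHS with all constants bound to locals.

    Semantically identical to :func:`rhs_pd` (asserted in the test suite);
    exists because the integrator evaluates the vector field thousands of
    times per simulated cycle.
    """
    b, slope, k_tr, gamma = p.b, p.slope, p.k_tr, p.gamma
    k_ma, c_v = consts.k_ma, consts.c_v
    n_tr = spec.n_tr
    bbm = b * k_ma / k_tr
    direct, f_os = spec.direct_kill, spec.f_over_s
    g_sc, g_os, marrow = spec.gamma_scaled, spec.g_over_s, spec.marrow_feedback
    log1p = math.log1p
    floor = _DENOM_FLOOR

    def fun(y, t):
        x1 = central_amount(t)
        lg = log1p(c_v * x1)
        xpr = y[0]
        xma = y[n_tr + 1]
        if marrow:
            base = bbm / max(0.01 * xpr + 0.99 * y[1], floor)
        else:
            base = b / max(xma, floor)
        fb = base ** (gamma * (1.0 + lg)) if g_sc else base ** gamma
        f = k_tr * fb - slope * lg if direct else (1.0 - slope * lg) * k_tr * fb
        if f_os:
            f = f / (1.0 + lg)
        g = k_tr / (1.0 + lg) if g_os else k_tr
        dy = [(f - g) * xpr]
        prev = xpr
        for i in range(1, n_tr + 1):
            yi = y[i]
            dy.append(g * (prev - yi))
            prev = yi
        dy.append(g * prev - k_ma * xma)
        return dy

    return fun


@dataclass
class Trajectory:
    """Simulated time courses; ``wbc`` is the circulating x_ma series (G/L)."""

    times: np.ndarray
    states: np.ndarray  # (n_times, n_tr + 2): x_pr, transits, x_ma
    x1: np.ndarray
    x2: np.ndarray

    @property
    def wbc(self) -> np.ndarray:
        return self.states[:, -1]


def simulate_model(spec: ModelSpec, p: PDParameters, consts: ModelConstants,
                   pk: PKParameters, schedule: InfusionSchedule,
                   grid: np.ndarray, rtol: float = 1e-8, atol: float = 1e-10,
                   y0: np.ndarray | None = None) -> Trajectory:
    """Integrate one variant over ``grid`` (days, increasing, starting at t0).

    The linear PK block is decoupled from the cell compartments and is
    evaluated by its exact piecewise solution; only the (non-stiff) PD states
    are integrated numerically, with the integration broken at every dosing
    discontinuity.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be 1-d, strictly increasing, length >= 2")
    sol = PKSolution(pk, schedule)
    y = initial_state(spec, p, consts) if y0 is None else np.asarray(y0, dtype=float)

    t0, t_end = grid[0], grid[-1]
    breaks = np.array(sorted(
        {e.start for e in schedule.events if t0 < e.start < t_end}
        | {e.end for e in schedule.events if t0 < e.end < t_end}))
    t_all = np.unique(np.concatenate([grid, breaks]))

    fun = _make_fast_rhs(spec, p, consts, sol.central_amount)

    # divergent parameter draws overflow before the failure is detected
    # below; keep the exploration quiet and report once
    with np.errstate(over="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw, info = scipy.integrate.odeint(
            fun, y, t_all, tcrit=breaks if breaks.size else None,
            rtol=rtol, atol=atol, mxstep=100000, full_output=True)
    if info["message"] != "Integration successful.":
        raise RuntimeError(f"integration failed: {info['message']}")
    # trajectories from positive states stay non-negative; trim roundoff
    raw[(raw < 0) & (raw > -1e-7)] = 0.0
    if np.any(raw < 0) or not np.all(np.isfinite(raw)):
        raise RuntimeError("negative or non-finite state beyond tolerance")
    out = raw[np.searchsorted(t_all, grid)]
    pk_amounts = sol.amounts(grid)
    return Trajectory(times=grid, states=out, x1=pk_amounts[:, 0], x2=pk_amounts[:, 1])


def mean_maturation_time(n_tr: int, k_tr: float) -> tuple[float, float]:
    """Mean maturation time in hours: (n_tr/k_tr, (n_tr+1)/k_tr).

    The first entry is the corrected convention (transit compartments only),
    the second the original one that also counts the proliferating stage;
    ``k_tr`` is in 1/day.
    """
    if not k_tr > 0:
        raise ValueError("k_tr must be positive")
    return (n_tr / k_tr * HOURS_PER_DAY, (n_tr + 1) / k_tr * HOURS_PER_DAY)
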