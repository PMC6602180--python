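"""Two-compartment pharmacokinetics of intravenous cytarabine (Ara-C).

Ara-C given as short (3 h) or continuous intravenous infusions distributes
between a central compartment (plasma plus rapidly equilibrating tissue) and
a peripheral compartment, with first-order elimination from the central
compartment:

    dx1/dt = -(k10 + k12) x1 + k21 x2 + r(t)
    dx2/dt =   k12 x1 - k21 x2

where ``x1``/``x2`` are drug amounts (mg) and ``r(t)`` is the infusion rate
(mg/day), piecewise constant over the dosing events of a schedule.  Because
the system is linear with piecewise-constant input it is solved exactly by a
piecewise matrix-exponential; no numerical integrator is involved.

Rate constants are conventionally reported in 1/h and volumes in L; all
simulation happens on a time axis in days, so rates are converted (x24)
internally.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.optimize

from .results import FitResult

HOURS_PER_DAY = 24.0


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0 and math.isfinite(value)):
            raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class PKParameters:
    """Micro rate constants (1/h) and central volume (L) of the 2-cpt model."""

    k10: float
    k12: float
    k21: float
    vc: float

    def __post_init__(self) -> None:
        _require_positive(k10=self.k10, k12=self.k12, k21=self.k21, vc=self.vc)

    # macro (clearance) parameterisation -------------------------------
    @property
    def cl(self) -> float:
        """Clearance CL = k10 * Vc (L/h)."""
        return self.k10 * self.vc

    @property
    def q(self) -> float:
        """Inter-compartmental clearance Q = k12 * Vc (L/h)."""
        return self.k12 * self.vc

    @property
    def vp(self) -> float:
        """Peripheral volume Vp = Q / k21 (L)."""
        return self.q / self.k21

    @classmethod
    def from_macro(cls, cl: float, q: float, vc: float, vp: float) -> "PKParameters":
        """Build micro constants from (CL, Q, Vc, Vp); inverse of cl/q/vp."""
        _require_positive(cl=cl, q=q, vc=vc, vp=vp)
        return cls(k10=cl / vc, k12=q / vc, k21=q / vp, vc=vc)


#: Default parameters for high-dose Ara-C, estimated by naive pooling of
#: published plasma concentrations measured under 3 g/m2, 3-h, q12h infusions
#: (Kern et al., 1997).  CL 154.2 L/h, Q 4.18 L/h, Vc 37.66 L, Vp 7.78 L.
HIDAC_PK = PKParameters(k10=4.0955, k12=0.1109, k21=0.5366, vc=37.6571)


@dataclass(frozen=True)
class DoseEvent:
    """One infusion: start and duration in days, total amount in mg."""

    start: float
    duration: float
    amount: float

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError(f"infusion duration must be > 0, got {self.duration}")
        if self.amount < 0:
            raise ValueError(f"dose amount must be >= 0, got {self.amount}")

    @property
    def rate(self) -> float:
        """Infusion rate in mg/day."""
        return self.amount / self.duration

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class InfusionSchedule:
    """Ordered infusion events plus the body surface area they were scaled by.

    Event amounts are absolute (mg), i.e. already BSA-adjusted; overlapping
    events sum their rates.
    """

    events: tuple[DoseEvent, ...]
    bsa: float = 1.78
    label: str = "custom"

    def __post_init__(self) -> None:
        _require_positive(bsa=self.bsa)
        object.__setattr__(self, "events", tuple(sorted(self.events, key=lambda e: e.start)))

    @property
    def total_dose(self) -> float:
        return sum(e.amount for e in self.events)

    @property
    def end(self) -> float:
        return max((e.end for e in self.events), default=0.0)

    def shifted(self, dt: float) -> "InfusionSchedule":
        """Translate every event by ``dt`` days (dosing must stay at t >= 0)."""
        if self.events and min(e.start for e in self.events) + dt < 0:
            raise ValueError(f"shift {dt} pushes dosing before the simulation origin")
        return replace(self, events=tuple(replace(e, start=e.start + dt) for e in self.events))

    def scaled(self, factor: float) -> "InfusionSchedule":
        return replace(self, events=tuple(replace(e, amount=e.amount * factor) for e in self.events))


def single_infusion(dose_mg: float, duration_days: float = 0.125, start: float = 0.0,
                    bsa: float = 1.78, label: str = "single") -> InfusionSchedule:
    return InfusionSchedule((DoseEvent(start, duration_days, dose_mg),), bsa=bsa, label=label)


class PKSolution:
    """Exact solution of the two-compartment system under a schedule.

    Precomputes, per piecewise-constant-input segment, the particular
    solution and the eigen-coefficients of the homogeneous part; amounts at
    arbitrary times are then evaluated in closed form.
    """

    def __init__(self, params: PKParameters, schedule: InfusionSchedule):
        self.params = params
        self.schedule = schedule
        a = params.k10 * HOURS_PER_DAY  # elimination, 1/day
        b = params.k12 * HOURS_PER_DAY
        c = params.k21 * HOURS_PER_DAY
        self._A = np.array([[-(a + b), c], [b, -c]])
        lam, V = np.linalg.eig(self._A)
        # 2-cpt mamillary systems have real, negative, distinct eigenvalues
        self._lam = np.real(lam)
        self._V = np.real(V)
        self._Vinv = np.linalg.inv(self._V)

        breaks = sorted({0.0} | {e.start for e in schedule.events} | {e.end for e in schedule.events})
        breaks = [t for t in breaks if t >= 0.0]
        self._breaks = breaks
        self._seg_rate = []
        for i, t0 in enumerate(breaks):
            t1 = breaks[i + 1] if i + 1 < len(breaks) else math.inf
            tm = t0 + min(1.0, (t1 - t0)) / 2 if math.isfinite(t1) else t0 + 1.0
            self._seg_rate.append(sum(e.rate for e in schedule.events if e.start <= tm < e.end))

        # march the state across segments; store per-segment closed form
        self._seg_xp = []   # particular (forced steady-state) solution
        self._seg_coef = []  # eigen-coordinates of (x0 - xp)
        x0 = np.zeros(2)
        self._seg_x0 = []
        for i, t0 in enumerate(breaks):
            u = np.array([self._seg_rate[i], 0.0])
            xp = np.linalg.solve(self._A, -u)
            coef = self._Vinv @ (x0 - xp)
            self._seg_x0.append(x0.copy())
            self._seg_xp.append(xp)
            self._seg_coef.append(coef)
            if i + 1 < len(breaks):
                dt = breaks[i + 1] - t0
                x0 = xp + self._V @ (coef * np.exp(self._lam * dt))
        # flattened scalars for the fast scalar path
        self._flat = []
        for xp, coef in zip(self._seg_xp, self._seg_coef):
            c1, c2 = coef
            v = self._V
            self._flat.append((xp[0], xp[1], c1 * v[0, 0], c2 * v[0, 1], c1 * v[1, 0], c2 * v[1, 1]))
        self._l1, self._l2 = float(self._lam[0]), float(self._lam[1])

    def amounts(self, t: np.ndarray) -> np.ndarray:
        """Amounts (mg) in both compartments at times ``t`` (days); shape (n, 2)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros(t.shape + (2,))
        idx = np.searchsorted(self._breaks, t, side="right") - 1
        idx = np.clip(idx, 0, len(self._breaks) - 1)
        for i in np.unique(idx):
            m = idx == i
            dt = t[m] - self._breaks[i]
            e = np.exp(np.outer(dt, self._lam))
            out[m] = self._seg_xp[i] + (e * self._seg_coef[i]) @ self._V.T
        out[t < 0] = 0.0
        return out

    def central_amount(self, t: float) -> float:
        """Scalar fast path for x1(t) (mg)."""
        if t <= 0.0:
            return 0.0
        i = bisect.bisect_right(self._breaks, t) - 1
        xp1, _, c11, c12, _, _ = self._flat[i]
        dt = t - self._breaks[i]
        return xp1 + c11 * math.exp(self._l1 * dt) + c12 * math.exp(self._l2 * dt)

    def concentration(self, t: np.ndarray) -> np.ndarray:
        """Central-compartment concentration x1/Vc (mg/L)."""
        return self.amounts(t)[..., 0] / self.params.vc


@dataclass
class PKTrajectory:
    times: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    conc: np.ndarray


def simulate_pk(params: PKParameters, schedule: InfusionSchedule, grid: np.ndarray) -> PKTrajectory:
    """Amounts and concentration on ``grid`` (days, increasing), from (0, 0)."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be one-dimensional and strictly increasing")
    sol = PKSolution(params, schedule)
    x = sol.amounts(grid)
    if np.min(x) < -1e-9 * max(schedule.total_dose, 1.0):
        raise RuntimeError("negative compartment amounts beyond tolerance")
    return PKTrajectory(grid, x[:, 0], x[:, 1], x[:, 0] / params.vc)


def washout_time(params: PKParameters, schedule: InfusionSchedule,
                 threshold: float = 1e-6, horizon: float = 60.0) -> float:
    """First time (days) at which both compartment amounts fall below ``threshold`` mg.

    Scans a fine grid after the last infusion ends and refines the crossing
    by bisection on max(x1, x2) - threshold.
    """
    sol = PKSolution(params, schedule)
    t = np.arange(schedule.end, horizon, 1e-3)
    m = np.max(sol.amounts(t), axis=1)
    below = np.nonzero(m < threshold)[0]
    if below.size == 0:
        raise RuntimeError(f"amounts did not fall below {threshold} mg within {horizon} days")
    i = below[0]
    if i == 0:
        return float(t[0])
    lo, hi = t[i - 1], t[i]
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if max(sol.amounts(np.array([mid]))[0]) < threshold:
            hi = mid
        else:
            lo = mid
    return float(hi)


# ---------------------------------------------------------------------------
# pooled estimation from concentration data
# ---------------------------------------------------------------------------

def _log_residuals(log_theta: np.ndarray, times: np.ndarray, conc: np.ndarray,
                   schedule: InfusionSchedule) -> np.ndarray:
    k10, k12, k21, vc = np.exp(log_theta)
    sol = PKSolution(PKParameters(k10, k12, k21, vc), schedule)
    pred = sol.amounts(times)[:, 0] / vc
    return np.log(np.maximum(pred, 1e-300)) - np.log(conc)


def fit_pk_pooled(times: np.ndarray, conc: np.ndarray, schedule: InfusionSchedule,
                  start: PKParameters = HIDAC_PK, n_starts: int = 10,
                  seed: int = 1, span: float = 100.0) -> FitResult:
    """Naive-pooled least squares on log concentrations.

    All records are treated as coming from one subject; the objective is the
    sum of squared log residuals (exponential error model).  Multistart over
    log-uniform boxes spanning ``1/span .. span`` times the starting values
    guards against local minima; every start is polished by trust-region
    least squares in log-parameter space (positivity by construction).
    """
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("all concentrations must be strictly positive (log residuals)")
    if times.shape != conc.shape or times.ndim != 1:
        raise ValueError("times and conc must be matching 1-d arrays")

    base = np.log(np.array([start.k10, start.k12, start.k21, start.vc]))
    rng = np.random.default_rng(seed)
    starts = [base]
    width = math.log(span)
    for _ in range(max(n_starts - 1, 0)):
        starts.append(base + rng.uniform(-width, width, size=4))

    best = None
    for x0 in starts:
        try:
            res = scipy.optimize.least_squares(
                _log_residuals, x0, args=(times, conc, schedule), method="trf",
                bounds=(base - width - 1, base + width + 1), xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all PK multistart attempts failed")

    theta = np.exp(best.x)
    resid = best.fun
    n, p = resid.size, theta.size
    # J wrt natural parameters via the chain rule d/dtheta = (1/theta) d/dlog
    jac = best.jac / theta
    rss = float(resid @ resid)
    names = ("k10", "k12", "k21", "vc")
    cov = None
    rse = None
    singular = False
    if n > p:
        jtj = jac.T @ jac
        try:
            cov = rss / (n - p) * np.linalg.inv(jtj)
            rse = 100.0 * np.sqrt(np.diag(cov)) / theta
        except np.linalg.LinAlgError:
            singular = True
    pred = np.exp(np.log(conc) + resid)
    rmse = float(np.sqrt(np.mean((pred - conc) ** 2)))
    return FitResult(names=names, estimates=theta, objective=rss, covariance=cov,
                     rse=rse, residuals=resid, rmse=rmse, n_obs=n,
                     extra={"singular": singular,
                            "cl": theta[0] * theta[3], "q": theta[1] * theta[3],
                            "vp": theta[1] * theta[3] / theta[2]})


def pk_rse(fit: FitResult) -> dict[str, float]:
    """Relative standard errors 100*sqrt(cov_ii)/estimate_i (%), NaN where undefined."""
    if fit.covariance is None:
        raise ValueError("fit carries no covariance; RSEs undefined")
    out = {}
    for i, name in enumerate(fit.names):
        est = fit.estimates[i]
        var = fit.covariance[i, i]
        out[name] = float("nan") if est == 0 or var < 0 else 100.0 * math.sqrt(var) / abs(est)
    return out
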