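"""Two-stage inverse estimation of loss-factor and diffusivity models.

The estimation problem: given one treatment's measured drying record
(mean surface temperature and mean moisture versus time), find the
coefficients of the dielectric loss-factor polynomial eps''(T', M), the
Arrhenius-type effective diffusivity D(T, M), and the heat/mass Biot
numbers, such that the forward coupled heat-moisture FEM reproduces the
record.  Two sum-square errors are formed, SSE_T (degC^2) against the
surface-temperature series and SSE_M ((d.b.)^2) against the moisture
series, and treated as a multi-objective problem.

Stage 1 (initial guesses): the seed is taken spatially uniform at the
Fourier-smoothed measured state, decoupling the equations.  The lumped
moisture balance dM/dt = -(Bi_m D(T,M)/L^2)(M - Me) is fitted for the
diffusivity coefficients, and the lumped energy balance
rho Cp dT/dt = q_MW - (Bi_h k/L^2)(T - Ta) - Hevap rho dM/dt for the
loss-factor coefficients, each by bound-clipped Nelder-Mead simplex from
a variable-projection starting point, with a bounded quasi-Newton polish
accepted only on improvement.

Stage 2 (goal attainment): minimise the attainment level gamma subject
to F_i(C) - w_i*gamma <= goal_i with unit weights, the constraint
eps'' > 0 along the traversed trajectory, and box bounds on the
coefficients.  The goals default to the SSE pair the stage-1 point
achieves through the full coupled FEM (so the start is feasible at
gamma = 0), and the moisture objective is scaled to make the two goals
commensurate.  The scalarised problem is solved by a sequential
quadratic method with finite-difference gradients; iterates are ranked
by their implied attainment level (equal to the slack variable at
optimality) and accepted when feasible and improving, so gamma is
non-increasing along the accepted sequence; the search also stops when
the step norm falls below twice the step-size tolerance (1e-6) at a
feasible point.

Identifiability: the mean-moisture data constrain the product
Bi_m * D(T, M) (exactly so in the lumped limit), so D is recoverable
only up to the Bi_m scale when Bi_m is free; temperature dynamics do
separate Bi_h from the heating scale.  When transfer coefficients are
known, pass ``optimize_biot=False`` with the known Biot numbers.  The
documented contract of the fit is the eps''(T', M) and D(T, M) surfaces
over the traversed trajectory, not the individual coefficients.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear, minimize

from . import props, tables
from .fem import Assembly, BoundaryModel, FieldSolution, ForwardBlowup, SimulationConfig, run_forward
from .lensgeom import LensGeometry, characteristic_length, generate_mesh
from .obs import DryingRecord, FitStatistics, fit_fourier, fit_statistics
from .props import DiffusivityModel, LossFactorModel, MicrowaveSource

logger = logging.getLogger(__name__)

PARAM_NAMES = (
    "g0", "g1", "g2", "g3", "g4", "g5", "g6", "g7",
    "D0", "Ea", "a0", "a1", "Bi_heat", "Bi_mass",
)
_LOG_PARAMS = frozenset({"D0", "Bi_heat", "Bi_mass"})
_LOSS_IDX = slice(0, 8)
_DIFF_IDX = slice(8, 12)


@dataclass(frozen=True)
class CoefficientVector:
    """Named concatenation of all estimated coefficients."""

    values: np.ndarray
    names: tuple[str, ...] = PARAM_NAMES

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.values) != len(self.names):
            raise ValueError("coefficient vector / name length mismatch")

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.names, self.values)}

    def loss_model(self, ash_db: float = 2.6) -> LossFactorModel:
        return LossFactorModel(g=tuple(self.values[_LOSS_IDX]), ash_db=ash_db)

    def diff_model(self) -> DiffusivityModel:
        D0, Ea, a0, a1 = self.values[_DIFF_IDX]
        return DiffusivityModel(D0=D0, Ea=Ea, a0=a0, a1=a1)

    @property
    def bi_heat(self) -> float:
        return self["Bi_heat"]

    @property
    def bi_mass(self) -> float:
        return self["Bi_mass"]

    @classmethod
    def from_models(cls, loss: LossFactorModel, diff: DiffusivityModel,
                    bi_heat: float, bi_mass: float) -> "CoefficientVector":
        return cls(np.array(list(loss.g) + [diff.D0, diff.Ea, diff.a0, diff.a1,
                                            bi_heat, bi_mass]))


@dataclass(frozen=True)
class Bounds:
    """Box bounds with per-parameter linear or logarithmic scaling."""

    lb: np.ndarray
    ub: np.ndarray
    log: np.ndarray  # bool mask: map to unit cube in log10 space

    def __post_init__(self):
        for name in ("lb", "ub"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "log", np.asarray(self.log, dtype=bool))
        if np.any(self.lb >= self.ub):
            raise ValueError("need lb < ub componentwise")
        if np.any(self.lb[self.log] <= 0):
            raise ValueError("log-scaled parameters need positive lower bounds")

    def _scaled_ends(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = self.lb.copy(), self.ub.copy()
        lo[self.log] = np.log10(lo[self.log])
        hi[self.log] = np.log10(hi[self.log])
        return lo, hi

    def to_unit(self, x: np.ndarray) -> np.ndarray:
        lo, hi = self._scaled_ends()
        v = np.asarray(x, dtype=float).copy()
        v[self.log] = np.log10(np.clip(v[self.log], self.lb[self.log], None))
        return (v - lo) / (hi - lo)

    def from_unit(self, u: np.ndarray) -> np.ndarray:
        u = np.clip(u, 0.0, 1.0)
        lo, hi = self._scaled_ends()
        v = lo + u * (hi - lo)
        v[self.log] = 10.0 ** v[self.log]
        return v

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lb, self.ub)

    def subset(self, idx) -> "Bounds":
        return Bounds(self.lb[idx], self.ub[idx], self.log[idx])


@lru_cache(maxsize=1)
def default_bounds() -> Bounds:
    """Published per-treatment coefficient columns, min/max expanded by
    50 % of the half-range (or of the magnitude where the column is
    constant), plus Bi in (1e-4, 0.1) on a log scale."""
    lf = tables.loss_factor_table()
    dt = tables.diffusivity_table()
    lb, ub, logm = [], [], []
    for name in PARAM_NAMES[:12]:
        col = (lf if name.startswith("g") else dt)[name].to_numpy()
        lo, hi = col.min(), col.max()
        half = (hi - lo) / 2.0
        if half == 0:
            half = 0.5 * max(abs(lo), 1e-12)
        lo, hi = lo - half, hi + half
        if name in ("D0", "Ea"):
            lo = max(lo, 0.05 * col.min())
        lb.append(lo)
        ub.append(hi)
        logm.append(name in _LOG_PARAMS)
    lb += [1e-4, 1e-4]
    ub += [0.1, 0.1]
    logm += [True, True]
    return Bounds(np.array(lb), np.array(ub), np.array(logm))


@dataclass
class GoalAttainmentProblem:
    """Scalarised multi-objective contract: minimise gamma subject to
    F(C) - weight*gamma <= goal, eps'' > 0 on the trajectory, and bounds.

    ``goals=None`` (default) sets the goals to the SSE pair achieved by
    the initial point through the full coupled model.  The moisture
    objective is multiplied by a scale s making the two goals
    commensurate (s = goal_T / goal_M unless given), so the unit weight
    pair exerts symmetric relative pressure on both objectives."""

    goals: tuple[float, float] | None = None
    weights: tuple[float, float] = (1.0, 1.0)
    bounds: Bounds = field(default_factory=default_bounds)
    eps_floor: float = 1e-3
    tol_step: float = 1e-6
    moisture_scale: float | None = None  # s: SSE_M multiplier; None = auto
    maxiter: int = 40

    def __post_init__(self):
        if not all(w > 0 for w in self.weights):
            raise ValueError("weights must be positive")
        if self.goals is not None and not all(np.isfinite(g) for g in self.goals):
            raise ValueError("goals must be finite")


@dataclass
class Stage1Result:
    """Decoupled (lumped, uniform-field) initial-guess fit."""

    params: np.ndarray  # stage-specific parameter subset, natural units
    sse: float
    n_restarts: int = 0
    flags: list[str] = field(default_factory=list)


class _Converged(Exception):
    pass


def _bounded_nelder_mead(fun, x0_unit, maxiter, rng=None, max_restarts=3):
    """Derivative-free simplex in the unit cube; evaluations are clipped
    into the cube (bound-clipped simplex).  Non-finite objectives trigger
    a restart from a perturbed start, at most ``max_restarts`` times."""
    rng = rng or np.random.default_rng(0)
    n_restarts = 0
    x0 = np.asarray(x0_unit, dtype=float)
    blew_up = False

    def wrapped(u):
        nonlocal blew_up
        v = fun(np.clip(u, 0.0, 1.0))
        if not np.isfinite(v):
            blew_up = True
            return 1e30
        return v

    best = None
    for attempt in range(max_restarts + 1):
        blew_up = False
        res = minimize(wrapped, x0, method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 1e-5, "fatol": 1e-10})
        cand = (res.fun, np.clip(res.x, 0.0, 1.0))
        if best is None or cand[0] < best[0]:
            best = cand
        if not blew_up:
            break
        n_restarts += 1
        logger.warning("non-finite objective during simplex search; restarting (%d)", n_restarts)
        x0 = np.clip(x0 + rng.normal(0.0, 0.05, size=len(x0)), 0.0, 1.0)
    # gradient polish: the simplex stalls in the long collinear valleys of
    # these objectives; a bounded quasi-Newton descent from its endpoint is
    # cheap (the objective is smooth) and only accepted if it improves
    try:
        pol = minimize(wrapped, best[1], method="L-BFGS-B",
                       bounds=[(0.0, 1.0)] * len(x0),
                       options={"maxiter": 200, "ftol": 1e-14, "gtol": 1e-12})
        if np.isfinite(pol.fun) and pol.fun < best[0]:
            best = (pol.fun, np.clip(pol.x, 0.0, 1.0))
    except (ValueError, FloatingPointError):  # pragma: no cover - defensive
        pass
    return best[1], best[0], n_restarts


class MicrowaveDryingModel:
    """Inverse model of one microwave drying treatment.

    Built from a :class:`~seedwave.obs.DryingRecord` plus the treatment
    configuration; ``fit()`` runs the two-stage estimation and returns a
    :class:`DryingEstimationResults`.

    Parameters
    ----------
    record : DryingRecord
        Measured (t, M, T_surface) series for one treatment.
    source : MicrowaveSource, optional
        Magnetron power / reflection / field configuration; defaults to
        values found in ``record.meta`` (``pav_watts``, ``s11``).
    geom : LensGeometry
        Seed geometry (default 4.4 x 2.2 mm lens).
    ash_db : float
        Ash content, percent dry basis, entering the loss-factor model.
    target_h, dt : float
        Mesh edge length and time step of the forward solver used inside
        the objective.  The defaults are the package's validated
        operating point for estimation; self-convergence is tested
        separately.
    optimize_biot : bool
        Include (Bi_heat, Bi_mass) in the estimated vector (default).
        With mean-series data the moisture objective fixes only the
        product Bi_m * D, so pass False with known Biot numbers when the
        diffusivity scale itself is wanted.
    bi_known : (float, float), optional
        Known (Bi_heat, Bi_mass) when ``optimize_biot=False``.
    """

    def __init__(
        self,
        record: DryingRecord,
        source: MicrowaveSource | None = None,
        geom: LensGeometry = LensGeometry(),
        ash_db: float = 2.6,
        target_h: float = 2.5e-4,
        dt: float = 1.0,
        Ta: float = 296.15,
        Me: float = 0.0,
        optimize_biot: bool = True,
        bi_known: tuple[float, float] | None = None,
        bounds: Bounds | None = None,
        n_harmonics: int = 5,
        seed: int = 0,
    ):
        if record.surface_T_C is None or len(record.surface_T_C) == 0:
            raise ValueError("record is missing the surface temperature column")
        self.record = record
        if source is None:
            meta = record.meta
            if "pav_watts" not in meta:
                raise ValueError("no MicrowaveSource given and record.meta lacks 'pav_watts'")
            source = MicrowaveSource(Pav=meta["pav_watts"], S11=meta.get("s11", 0.0))
        self.source = source
        self.geom = geom
        self.ash_db = ash_db
        self.Ta = Ta
        self.Me = Me
        self.dt = dt
        self.optimize_biot = optimize_biot
        self.seed = seed
        if not optimize_biot:
            if bi_known is None:
                bi_known = (record.meta.get("bi_heat"), record.meta.get("bi_mass"))
            if bi_known[0] is None or bi_known[1] is None:
                raise ValueError("optimize_biot=False requires known Biot numbers")
        self.bi_known = bi_known
        self.L = characteristic_length(geom)
        self.assembly = Assembly(generate_mesh(geom, target_h))
        self.bounds = bounds if bounds is not None else default_bounds()
        self.E = props.field_strength(source)
        self.T0 = 273.15 + record.surface_T_C[0]
        self.M0 = record.moisture_db[0]
        self.n_harmonics = n_harmonics
        # Fourier smoothing of the measured series (stage-1 driver only)
        self.T_smooth = fit_fourier(record.times, record.surface_T_C, n_harmonics)
        self.M_smooth = fit_fourier(record.times, record.moisture_db, n_harmonics)
        self._fwd_cache: dict[bytes, FieldSolution] = {}

    @classmethod
    def from_csv(cls, path, treatment_id="", M0=None, meta=None, **kwargs):
        return cls(DryingRecord.from_csv(path, treatment_id, M0=M0, meta=meta), **kwargs)

    # ---------------- forward objective ----------------

    def _bc(self, bi_heat: float, bi_mass: float) -> BoundaryModel:
        return BoundaryModel(Bi_heat=bi_heat, Bi_mass=bi_mass, L=self.L,
                             Ta=self.Ta, Me=self.Me)

    def forward(self, coeffs: CoefficientVector) -> FieldSolution:
        """Run (and cache) the coupled FEM for a coefficient vector."""
        key = np.round(coeffs.values, 14).tobytes()
        sol = self._fwd_cache.get(key)
        if sol is None:
            cfg = SimulationConfig(T0=self.T0, M0=self.M0,
                                   t_end=float(self.record.times[-1]), dt=self.dt)
            sol = run_forward(self.assembly, cfg, coeffs.loss_model(self.ash_db),
                              coeffs.diff_model(), self.source,
                              self._bc(coeffs.bi_heat, coeffs.bi_mass))
            if len(self._fwd_cache) > 64:
                self._fwd_cache.clear()
            self._fwd_cache[key] = sol
        return sol

    #: objective value standing in for a rejected (blown-up) forward run;
    #: sloped in the blow-up time so gradient methods are pushed back out
    _BLOWUP_SSE = 1e8

    def _blowup_penalty(self, exc: ForwardBlowup) -> float:
        # sloped in both the blow-up time and the envelope overshoot so
        # finite-difference gradients point back toward the feasible region
        return self._BLOWUP_SSE * (2.0 - exc.t / exc.t_end) + 1e4 * exc.magnitude

    def objective_pair(self, coeffs: CoefficientVector) -> tuple[float, float]:
        """(SSE of surface temperature in degC^2, SSE of mean moisture in
        (d.b.)^2) of the forward model against the record.  A solver
        blow-up maps to effectively infinite objectives (rejected point)."""
        try:
            sol = self.forward(coeffs)
        except ForwardBlowup as exc:
            logger.debug("forward solve rejected at %s: %s", coeffs.as_dict(), exc)
            pen = self._blowup_penalty(exc)
            return pen, pen
        except (RuntimeError, FloatingPointError, ValueError) as exc:
            logger.debug("forward solve rejected at %s: %s", coeffs.as_dict(), exc)
            return math.inf, math.inf
        t = self.record.times
        sse_T = float(((sol.sample(t, "surface_T_C") - self.record.surface_T_C) ** 2).sum())
        sse_M = float(((sol.sample(t, "mean_M") - self.record.moisture_db) ** 2).sum())
        return sse_T, sse_M

    def _trajectory_states(self, sol: FieldSolution) -> tuple[np.ndarray, np.ndarray]:
        t = self.record.times
        return sol.sample(t, "mean_T"), sol.sample(t, "mean_M")

    def min_loss_factor(self, coeffs: CoefficientVector) -> float:
        """Minimum eps'' over the traversed (T', M) trajectory."""
        try:
            sol = self.forward(coeffs)
        except ForwardBlowup as exc:
            return -self._blowup_penalty(exc)
        except (RuntimeError, FloatingPointError, ValueError):
            return -math.inf
        T, M = self._trajectory_states(sol)
        lm = coeffs.loss_model(self.ash_db)
        return float(np.min(lm(T, M)))

    # ---------------- stage 1: lumped initial guesses ----------------

    def _ode_grid(self) -> np.ndarray:
        t = self.record.times
        sub = max(1, int(math.ceil(np.max(np.diff(t)) / 5.0)))
        grid = [np.linspace(t[i], t[i + 1], sub + 1)[:-1] for i in range(len(t) - 1)]
        return np.concatenate(grid + [t[-1:]])

    def _integrate_lumped_moisture(self, diff: DiffusivityModel, bi_mass: float) -> np.ndarray:
        """RK4 of dM/dt = -(Bi_m D(T(t), M)/L^2)(M - Me) on the record
        window, T(t) from the Fourier smoother; returns M at record times."""
        L2 = self.L**2
        Tof = lambda t: self.T_smooth(t) + 273.15

        def rhs(t, M):
            M = max(M, 0.0)
            return -bi_mass * float(diff(Tof(t), M)) / L2 * (M - self.Me)

        grid = self._ode_grid()
        M = np.empty(len(grid))
        M[0] = self.M0
        for i in range(len(grid) - 1):
            h = grid[i + 1] - grid[i]
            t0, y = grid[i], M[i]
            k1 = rhs(t0, y)
            k2 = rhs(t0 + h / 2, y + h * k1 / 2)
            k3 = rhs(t0 + h / 2, y + h * k2 / 2)
            k4 = rhs(t0 + h, y + h * k3)
            M[i + 1] = y + h * (k1 + 2 * k2 + 2 * k3 + k4) / 6
        return np.interp(self.record.times, grid, M)

    #: lumped-integration temperature clamp (K); excursions beyond it are
    #: clipped and penalised so the simplex search is steered away from
    #: thermally explosive coefficient regions instead of overflowing
    _T_CLAMP = (223.15, 523.15)

    def _integrate_lumped_heat(self, loss: LossFactorModel, bi_heat: float
                               ) -> tuple[np.ndarray, float]:
        """RK4 of the lumped energy balance driven by the smoothed M(t).

        Returns temperatures at record times plus a clamp penalty (K^2,
        zero for trajectories that stay inside the physical envelope)."""
        L2 = self.L**2
        q_fac = 2.0 * math.pi * self.source.f * self.source.eps0 * self.E**2
        Mof = self.M_smooth
        dMof = self.M_smooth.derivative
        lo, hi = self._T_CLAMP

        def rhs(t, T):
            T = min(max(T, lo), hi)
            M = max(float(Mof(t)), 0.0)
            rho = float(props.density(M))
            cp = float(props.specific_heat(T, M))
            k = float(props.thermal_conductivity(T, M))
            q = q_fac * float(loss(T, M))
            conv = bi_heat * k / L2 * (T - self.Ta)
            evap = float(props.latent_heat(T)) * rho * float(dMof(t))
            return (q - conv + evap) / (rho * cp)

        grid = self._ode_grid()
        T = np.empty(len(grid))
        T[0] = self.T0
        penalty = 0.0
        for i in range(len(grid) - 1):
            h = grid[i + 1] - grid[i]
            t0, y = grid[i], T[i]
            k1 = rhs(t0, y)
            k2 = rhs(t0 + h / 2, y + h * k1 / 2)
            k3 = rhs(t0 + h / 2, y + h * k2 / 2)
            k4 = rhs(t0 + h, y + h * k3)
            y_new = y + h * (k1 + 2 * k2 + 2 * k3 + k4) / 6
            if y_new < lo or y_new > hi:
                over = max(lo - y_new, y_new - hi)
                penalty += over**2 + 1.0
                y_new = min(max(y_new, lo), hi)
            T[i + 1] = y_new
        return np.interp(self.record.times, grid, T), penalty

    def _stage1_diff_init(self, bi_mass: float) -> np.ndarray:
        """Variable-projection start: invert the smoothed record for the
        required D(t) and fit log D linearly in (1/T, T*M, M)."""
        t = self.record.times
        tm = 0.5 * (t[:-1] + t[1:])
        M = np.maximum(self.M_smooth(tm), 1e-6)
        T = self.T_smooth(tm) + 273.15
        dMdt = self.M_smooth.derivative(tm)
        D_req = -(self.L**2) * dMdt / (bi_mass * np.maximum(M - self.Me, 1e-6))
        ok = D_req > 0
        if ok.sum() < 4:
            return None
        X = np.column_stack([np.ones(ok.sum()), -1e3 / (props.R_GAS * T[ok]),
                             T[ok] * M[ok], -M[ok]])
        beta, *_ = np.linalg.lstsq(X, np.log(D_req[ok]), rcond=None)
        return np.array([math.exp(beta[0]), beta[1], beta[2], beta[3]])

    def stage1_diffusivity(self, maxiter: int = 400) -> Stage1Result:
        """Fit (D0, Ea, a0, a1[, Bi_mass]) on the lumped moisture balance."""
        if self.record.n < 2 * self.n_harmonics + 3:
            raise ValueError("record too short for the Fourier-smoothed stage-1 fit")
        flags = []
        if (self.record.moisture_db.max() - self.record.moisture_db.min()) < 1e-4:
            flags.append("degenerate_moisture_record")
        free = self.optimize_biot
        idx = list(range(8, 12)) + ([13] if free else [])
        b = self.bounds.subset(idx)
        bi_fixed = None if free else self.bi_known[1]

        def unpack(x):
            diff = DiffusivityModel(D0=x[0], Ea=x[1], a0=x[2], a1=x[3])
            bi = x[4] if free else bi_fixed
            return diff, bi

        def objective(u):
            x = b.from_unit(u)
            try:
                diff, bi = unpack(x)
                pred = self._integrate_lumped_moisture(diff, bi)
            except (FloatingPointError, OverflowError, ValueError):
                return math.inf
            return float(((pred - self.record.moisture_db) ** 2).sum())

        bi_init = math.sqrt(b.lb[-1] * b.ub[-1]) if free else bi_fixed
        init_nat = self._stage1_diff_init(bi_init)
        if init_nat is None:
            u0 = np.full(len(idx), 0.5)
            flags.append("mid_bounds_start")
        else:
            full = np.concatenate([init_nat, [bi_init]]) if free else init_nat
            u0 = np.clip(b.to_unit(b.clip(full)), 0.0, 1.0)
        f0 = objective(u0)
        u, f, n_restarts = _bounded_nelder_mead(objective, u0, maxiter,
                                                rng=np.random.default_rng(self.seed))
        if f > f0:  # descent guarantee relative to the start
            u, f = u0, f0
        x = b.from_unit(u)
        at_lb = np.isclose(b.to_unit(x)[0], 0.0, atol=1e-3)
        if flags and at_lb:
            flags.append("diffusivity_at_lower_bound")
        params = x if free else np.concatenate([x, [bi_fixed]])
        return Stage1Result(params=params, sse=f, n_restarts=n_restarts, flags=flags)

    def _stage1_loss_init(self, bi_heat: float) -> np.ndarray:
        """Variable-projection start: invert the smoothed record for the
        required eps''(t) and fit the eight polynomial terms by linear
        least squares restricted to the coefficient bounds."""
        t = self.record.times
        tm = 0.5 * (t[:-1] + t[1:])
        T = self.T_smooth(tm) + 273.15
        M = np.maximum(self.M_smooth(tm), 0.0)
        dTdt = self.T_smooth.derivative(tm)
        dMdt = self.M_smooth.derivative(tm)
        rho = props.density(M)
        cp = props.specific_heat(T, M)
        k = props.thermal_conductivity(T, M)
        q_fac = 2.0 * math.pi * self.source.f * self.source.eps0 * self.E**2
        eps_req = (rho * cp * dTdt + bi_heat * k / self.L**2 * (T - self.Ta)
                   - props.latent_heat(T) * rho * dMdt) / q_fac
        Tc = T - 273.15
        A = self.ash_db / (1.0 + M)
        X = np.column_stack([np.ones_like(Tc), Tc, Tc**2, 100 * M, 100 * M * Tc,
                             A, A**2, A * Tc])
        gb = self.bounds.subset(list(range(8)))
        sol = lsq_linear(X, eps_req, bounds=(gb.lb, gb.ub))
        return sol.x

    def stage1_lossfactor(self, maxiter: int = 600) -> Stage1Result:
        """Fit (g0..g7[, Bi_heat]) on the lumped energy balance."""
        if self.record.n < 2 * self.n_harmonics + 3:
            raise ValueError("record too short for the Fourier-smoothed stage-1 fit")
        flags = []
        t_range = self.record.surface_T_C.max() - self.record.surface_T_C.min()
        if t_range < 1.0:
            flags.append("unidentifiable_temperature_record")
        free = self.optimize_biot
        idx = list(range(0, 8)) + ([12] if free else [])
        b = self.bounds.subset(idx)
        bi_fixed = None if free else self.bi_known[0]

        def unpack(x):
            loss = LossFactorModel(g=tuple(x[:8]), ash_db=self.ash_db)
            bi = x[8] if free else bi_fixed
            return loss, bi

        def objective(u):
            x = b.from_unit(u)
            try:
                loss, bi = unpack(x)
                pred, penalty = self._integrate_lumped_heat(loss, bi)
                pred = pred - 273.15
            except (FloatingPointError, OverflowError, ValueError):
                return math.inf
            return float(((pred - self.record.surface_T_C) ** 2).sum()) + 1e3 * penalty

        bi_init = math.sqrt(b.lb[-1] * b.ub[-1]) if free else bi_fixed
        if flags:
            u0 = np.full(len(idx), 0.5)
        else:
            g_init = self._stage1_loss_init(bi_init)
            full = np.concatenate([g_init, [bi_init]]) if free else g_init
            u0 = np.clip(b.to_unit(b.clip(full)), 0.0, 1.0)
        f0 = objective(u0)
        if flags:
            x = b.from_unit(u0)
            params = x if free else np.concatenate([x, [bi_fixed]])
            return Stage1Result(params=params, sse=f0, flags=flags)
        u, f, n_restarts = _bounded_nelder_mead(objective, u0, maxiter,
                                                rng=np.random.default_rng(self.seed + 1))
        if f > f0:
            u, f = u0, f0
        x = b.from_unit(u)
        params = x if free else np.concatenate([x, [bi_fixed]])
        return Stage1Result(params=params, sse=f, n_restarts=n_restarts, flags=flags)

    def initial_coefficients(self, maxiter_diff: int = 400,
                             maxiter_loss: int = 600) -> tuple[CoefficientVector, tuple[float, float], list[str]]:
        """Stage-1 orchestration: returns the concatenated initial vector,
        the (SSE_T, SSE_M) stage-1 goals, and any flags."""
        s1m = self.stage1_diffusivity(maxiter=maxiter_diff)
        s1t = self.stage1_lossfactor(maxiter=maxiter_loss)
        vals = np.empty(14)
        vals[_LOSS_IDX] = s1t.params[:8]
        vals[_DIFF_IDX] = s1m.params[:4]
        vals[12] = s1t.params[-1]
        vals[13] = s1m.params[-1]
        return CoefficientVector(vals), (s1t.sse, s1m.sse), s1t.flags + s1m.flags

    # ---------------- stage 2: goal attainment ----------------

    def goal_attainment(
        self,
        init: CoefficientVector,
        problem: GoalAttainmentProblem,
    ) -> "DryingEstimationResults":
        """Refine all coefficients jointly on the full coupled FEM."""
        free_idx = list(range(12)) + ([12, 13] if self.optimize_biot else [])
        b = self.bounds.subset(free_idx)
        fixed = init.values.copy()

        def coeffs_of(u):
            vals = fixed.copy()
            vals[free_idx] = b.from_unit(u)
            return CoefficientVector(vals)

        def start_ok(u):
            c = coeffs_of(u)
            return (
                self.min_loss_factor(c) > problem.eps_floor
                and self.objective_pair(c)[0] < self._BLOWUP_SSE
            )

        u0 = np.clip(b.to_unit(b.clip(init.values[free_idx])), 0.0, 1.0)
        # the lumped stage-1 temperature fit can occasionally land far from
        # the coupled model's optimum (its instability amplifies noise); if
        # the bounded regression of the required eps'' trajectory gives a
        # better start through the full model, prefer it
        alt_vals = coeffs_of(u0).values.copy()
        alt_vals[_LOSS_IDX] = self._stage1_loss_init(alt_vals[12])
        u_alt = np.clip(b.to_unit(b.clip(alt_vals[free_idx])), 0.0, 1.0)
        var_T = max(float(np.var(self.record.surface_T_C) * self.record.n), 1e-12)
        var_M = max(float(np.var(self.record.moisture_db) * self.record.n), 1e-12)

        def start_quality(u):
            sse_T, sse_M = self.objective_pair(coeffs_of(u))
            return sse_T / var_T + sse_M / var_M

        if start_quality(u_alt) < start_quality(u0):
            logger.info("eps-regression start preferred over lumped stage-1 start")
            u0 = u_alt
        # infeasible start (eps'' <= 0 on trajectory, or solver blow-up):
        # shrink toward mid-bounds; if that fails (mid-bounds itself can be
        # thermally explosive), replace the loss-factor block with the
        # bounded regression fit of the required eps'' trajectory
        repaired = False
        u_try = u0.copy()
        for _ in range(30):
            if start_ok(u_try):
                break
            u_try = 0.5 + 0.9 * (u_try - 0.5)
            repaired = True
        if not start_ok(u_try):
            vals = coeffs_of(u0).values.copy()
            vals[_LOSS_IDX] = self._stage1_loss_init(vals[12])
            u_try = np.clip(b.to_unit(b.clip(vals[free_idx])), 0.0, 1.0)
            repaired = True
        u0 = u_try
        if repaired:
            logger.warning("infeasible start repaired (shrink / eps-regression fallback)")

        sse0 = self.objective_pair(coeffs_of(u0))
        if problem.goals is None:
            goal_T, goal_M = max(sse0[0], 1e-12), max(sse0[1], 1e-14)
        else:
            goal_T, goal_M = problem.goals
        w_T, w_M = problem.weights
        if problem.moisture_scale is None:
            s = goal_T / goal_M  # scaled goals coincide; unit weights symmetric
        else:
            s = problem.moisture_scale
        # normaliser keeping the slack variable on the same O(1) scale as the
        # unit-cube coefficients; reported gamma stays in scaled-SSE units
        N = max(goal_T / w_T, goal_M * s / w_M)

        def implied_gamma(sse_T: float, sse_M: float) -> float:
            """Attainment level of a point: the smallest gamma for which it
            satisfies both goal constraints.  The slack variable equals it
            at optimality; iterates are ranked by this quantity."""
            return max((sse_T - goal_T) / w_T, (sse_M - goal_M) * s / w_M)

        gamma0 = implied_gamma(*sse0)
        x0 = np.concatenate([u0, [gamma0 / N]])

        trace: list[dict] = []
        accepted: list[dict] = []
        state = {"last_x": None, "best": None}

        def evaluate(x):
            c = coeffs_of(x[:-1])
            sse_T, sse_M = self.objective_pair(c)
            eps_min = self.min_loss_factor(c)
            return c, sse_T, sse_M, eps_min

        def cons(x):
            _, sse_T, sse_M, eps_min = evaluate(x)
            gamma = x[-1] * N
            if not np.isfinite(sse_T):
                return np.array([-self._BLOWUP_SSE] * 3)
            return np.array([
                (goal_T + w_T * gamma - sse_T) / N,
                (goal_M * s + w_M * gamma - sse_M * s) / N,
                eps_min - problem.eps_floor,
            ])

        def on_iterate(x):
            c, sse_T, sse_M, eps_min = evaluate(x)
            gamma = implied_gamma(sse_T, sse_M) if np.isfinite(sse_T) else math.inf
            entry = {"gamma": gamma, "slack_gamma": float(x[-1]) * N,
                     "sse_T": sse_T, "sse_M": sse_M, "eps_min": eps_min}
            trace.append(entry)
            feasible = np.isfinite(gamma) and eps_min >= problem.eps_floor * (1 - 1e-9)
            if feasible and (state["best"] is None or gamma < state["best"]["gamma"]):
                state["best"] = {**entry, "x": x.copy()}
                accepted.append(entry)
            if state["last_x"] is not None:
                step = np.linalg.norm(x - state["last_x"])
                entry["step_norm"] = step
                if step < 2.0 * problem.tol_step and feasible:
                    raise _Converged
            state["last_x"] = x.copy()

        on_iterate(x0)  # the (possibly repaired) start is the first accepted point

        # the slack variable cannot usefully go below the gamma of a perfect
        # fit (both SSEs zero); expressed on the normalised scale
        gamma_lo = -min(goal_T / w_T, goal_M * s / w_M) * (1.0 + 1e-9) / N
        lo = np.concatenate([np.zeros(len(free_idx)), [gamma_lo]])
        hi = np.concatenate([np.ones(len(free_idx)), [max(abs(gamma0) / N * 10, 1.0)]])
        try:
            res = minimize(
                lambda x: x[-1],
                x0,
                jac=lambda x: np.concatenate([np.zeros(len(free_idx)), [1.0]]),
                method="SLSQP",
                bounds=list(zip(lo, hi)),
                constraints=[{"type": "ineq", "fun": cons}],
                callback=on_iterate,
                options={"maxiter": problem.maxiter, "ftol": problem.tol_step},
            )
            x_final = res.x
        except _Converged:
            x_final = state["last_x"]
        # rank the solver endpoint against the best accepted iterate by the
        # implied attainment level; fall back to the start if the solver
        # never produced an acceptable point
        _, fT, fM, f_eps = evaluate(x_final)
        final_gamma = implied_gamma(fT, fM) if np.isfinite(fT) else math.inf
        final_ok = np.isfinite(final_gamma) and f_eps >= problem.eps_floor * (1 - 1e-9)
        if state["best"] is not None and (not final_ok or state["best"]["gamma"] < final_gamma):
            x_final = state["best"]["x"]
            final_gamma = state["best"]["gamma"]
        elif not final_ok:
            logger.warning("goal attainment produced no acceptable iterate; keeping start")
            x_final, final_gamma = x0, gamma0

        coeffs = coeffs_of(x_final[:-1])
        return self._build_results(coeffs, float(final_gamma), problem, trace, accepted,
                                   stage1_goals=(goal_T, goal_M))

    def _build_results(self, coeffs, gamma, problem, trace, accepted, stage1_goals,
                       flags=None) -> "DryingEstimationResults":
        sse_T, sse_M = self.objective_pair(coeffs)
        sol = self.forward(coeffs)
        t = self.record.times
        pred_T = sol.sample(t, "surface_T_C")
        pred_M = sol.sample(t, "mean_M")
        return DryingEstimationResults(
            model=self,
            params=coeffs,
            gamma=gamma,
            sse_T=sse_T,
            sse_M=sse_M,
            stats_T=fit_statistics(self.record.surface_T_C, pred_T),
            stats_M=fit_statistics(self.record.moisture_db, pred_M),
            trace=pd.DataFrame(trace),
            accepted_trace=pd.DataFrame(accepted),
            goals=stage1_goals,
            problem=problem,
            flags=flags or [],
        )

    def fit(
        self,
        maxiter: int = 40,
        maxiter_stage1: tuple[int, int] = (400, 600),
        problem: GoalAttainmentProblem | None = None,
    ) -> "DryingEstimationResults":
        """Run the full two-stage estimation.

        Stage-1 lumped fits provide the initial coefficient vector and the
        goal values; goal attainment on the coupled FEM refines them.
        Deterministic given the record and configuration.
        """
        init, stage1_sse, flags = self.initial_coefficients(*maxiter_stage1)
        if problem is None:
            # goals are the SSEs the stage-1 point achieves through the full
            # coupled model (goals=None -> evaluated inside goal_attainment)
            problem = GoalAttainmentProblem(bounds=self.bounds, maxiter=maxiter)
        else:
            problem = replace(problem, bounds=self.bounds)
        results = self.goal_attainment(init, problem)
        results.flags.extend(flags)
        results.init_params = init
        results.stage1_sse = stage1_sse
        return results


@dataclass
class DryingEstimationResults:
    """Estimates, diagnostics and reporting for one fitted treatment.

    The stored SSE values are recomputed from the stored coefficients
    (round-trip consistency); ``summary()`` renders the coefficient and
    statistics rows in the layout of the published per-treatment tables.
    """

    model: MicrowaveDryingModel
    params: CoefficientVector
    gamma: float
    sse_T: float
    sse_M: float
    stats_T: FitStatistics
    stats_M: FitStatistics
    trace: pd.DataFrame
    accepted_trace: pd.DataFrame
    goals: tuple[float, float]
    problem: GoalAttainmentProblem
    flags: list[str] = field(default_factory=list)
    init_params: CoefficientVector | None = None
    stage1_sse: tuple[float, float] | None = None

    @property
    def loss_model(self) -> LossFactorModel:
        return self.params.loss_model(self.model.ash_db)

    @property
    def diff_model(self) -> DiffusivityModel:
        return self.params.diff_model()

    def predict(self, times=None) -> pd.DataFrame:
        """Fitted surface temperature (degC) and mean moisture (d.b.)."""
        t = self.model.record.times if times is None else np.asarray(times, dtype=float)
        sol = self.model.forward(self.params)
        return pd.DataFrame({
            "time_s": t,
            "surface_T_C": sol.sample(t, "surface_T_C"),
            "mean_M_db": sol.sample(t, "mean_M"),
        })

    def trajectory(self) -> pd.DataFrame:
        """Mean (T, M) path with the fitted eps'' and D along it."""
        sol = self.model.forward(self.params)
        t = self.model.record.times
        T = sol.sample(t, "mean_T")
        M = sol.sample(t, "mean_M")
        return pd.DataFrame({
            "time_s": t, "mean_T_K": T, "mean_M_db": M,
            "loss_factor": self.loss_model(T, M),
            "diffusivity_m2_s": self.diff_model(T, M),
        })

    def to_dict(self) -> dict:
        return {
            "treatment_id": self.model.record.treatment_id,
            "coefficients": self.params.as_dict(),
            "gamma": self.gamma,
            "goals": {"sse_T": self.goals[0], "sse_M": self.goals[1]},
            "stats_T": vars(self.stats_T).copy(),
            "stats_M": vars(self.stats_M).copy(),
            "flags": list(self.flags),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Microwave drying inverse estimation",
            "=" * 64,
            f"treatment: {self.model.record.treatment_id or '(unnamed)'}"
            f"    n obs: {self.model.record.n}",
            f"attainment gamma: {self.gamma:.6g}"
            f"    goals (SSE_T, SSE_M): {self.goals[0]:.6g}, {self.goals[1]:.6g}",
            "-" * 64,
            "loss factor eps''(T', M):",
            "  " + "  ".join(f"g{i}={p.values[i]:.4g}" for i in range(8)),
            f"  ash (d.b. %): {self.model.ash_db}",
            "diffusivity D(T, M):",
            f"  D0={p['D0']:.4g} m^2/s  Ea={p['Ea']:.4g} kJ/mol"
            f"  a0={p['a0']:.4g} 1/K  a1={p['a1']:.4g}",
            f"Biot numbers: heat {p['Bi_heat']:.4g}, mass {p['Bi_mass']:.4g}"
            + ("" if self.model.optimize_biot else " (fixed)"),
            "-" * 64,
            "fit to record        SSE         R^2      RMSE      MRPE(%)",
            f"  surface T (degC) {self.stats_T.sse:10.4g}  {self.stats_T.r2:8.4f}"
            f"  {self.stats_T.rmse:8.4g}  {self.stats_T.mrpe:8.4g}",
            f"  moisture  (d.b.) {self.stats_M.sse:10.4g}  {self.stats_M.r2:8.4f}"
            f"  {self.stats_M.rmse:8.4g}  {self.stats_M.mrpe:8.4g}",
        ]
        if self.flags:
            lines.append("flags: " + ", ".join(self.flags))
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Measured vs fitted temperature and moisture curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(1, 2, figsize=(9, 3.5))
        rec = self.model.record
        pred = self.predict()
        ax[0].plot(rec.times, rec.surface_T_C, "k.", ms=3, label="measured")
        ax[0].plot(pred.time_s, pred.surface_T_C, "-", label="fitted")
        ax[0].set_xlabel("time (s)"), ax[0].set_ylabel("surface T (degC)")
        ax[1].plot(rec.times, rec.moisture_db, "k.", ms=3, label="measured")
        ax[1].plot(pred.time_s, pred.mean_M_db, "-", label="fitted")
        ax[1].set_xlabel("time (s)"), ax[1].set_ylabel("moisture (d.b.)")
        ax[0].legend()
        return ax


def estimate_treatment(record: DryingRecord, maxiter: int = 40,
                       **model_kwargs) -> DryingEstimationResults:
    """One-call pipeline: stage-1 guesses then goal attainment."""
    return MicrowaveDryingModel(record, **model_kwargs).fit(maxiter=maxiter)
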