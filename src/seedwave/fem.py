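"""Transient axisymmetric FEM for coupled heat and moisture transport.

Solves, on the half-lens cross-section revolved about the z axis,

    rho*Cp dT/dt = div(k grad T) + q_MW - Hevap*Mv      (heat)
    dM/dt        = div(D grad M)                        (moisture)

with Robin conditions on the curved surface,

    n.(k grad T) = h (Ta - T),      h  = Bi_heat * k / L
    n.(-D grad M) = hm (M - Me),    hm = Bi_mass * D / L

a uniform microwave source q_MW = 2*pi*f*eps0*eps''(T', M)*E^2, and the
evaporation sink Mv = -rho dM/dt applied nodewise.  Discretisation is
linear (P1) triangles with r-weighted matrices, backward-Euler in time,
and a segregated coupling: one moisture step then one heat step per dt,
with all property coefficients lagged to the start of the step.  Systems
are a few hundred unknowns and are solved with a direct sparse solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from . import props
from .lensgeom import Mesh
from .props import DiffusivityModel, LossFactorModel, MicrowaveSource


class ForwardBlowup(RuntimeError):
    """Forward run left the physical envelope (|T| > 600 K or M < 0).

    ``magnitude`` measures how far past the envelope the first offending
    step landed; together with the blow-up time it lets callers build a
    smoothly sloped rejection penalty."""

    def __init__(self, t: float, t_end: float, step: int, magnitude: float, detail: str):
        self.t = t
        self.t_end = t_end
        self.step = step
        self.magnitude = magnitude
        super().__init__(f"forward run blew up at t={t:.2f}s (step {step}): {detail}")


@dataclass(frozen=True)
class BoundaryModel:
    """Robin boundary data expressed through fixed Biot numbers.

    The transfer coefficients are recovered locally at each step as
    h = Bi_heat*k/L and hm = Bi_mass*D/L (set ``freeze_coefficients`` to
    evaluate them once at the initial state instead).
    """

    Bi_heat: float
    Bi_mass: float
    L: float
    Ta: float = 296.15
    Me: float = 0.0
    freeze_coefficients: bool = False

    def __post_init__(self):
        if not (self.Bi_heat > 0 and self.Bi_mass >= 0 and self.L > 0):
            raise ValueError("Biot numbers must be positive and L > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Initial conditions and time-marching controls."""

    T0: float
    M0: float
    t_end: float
    dt: float = 0.5
    coupling: str = "segregated-lagged"
    output_times: tuple[float, ...] | None = None
    include_evaporation: bool = True
    store_fields: bool = False
    #: stop marching once the volume-mean moisture falls to this value
    #: (None = run to t_end); used to end drying runs at the target moisture
    stop_below_mean_M: float | None = None

    def __post_init__(self):
        if not (self.dt > 0 and self.t_end >= self.dt):
            raise ValueError("need dt > 0 and t_end >= dt")
        if not (273.0 <= self.T0 <= 373.0):
            raise ValueError(f"initial temperature {self.T0} K outside sanity band [273, 373]")
        if self.M0 < 0:
            raise ValueError("initial moisture must be non-negative")


@dataclass
class FieldSolution:
    """Time series extracted from a forward simulation.

    Temperatures in kelvin, moisture dry-basis decimal.  ``mean_*`` are
    revolved-volume weighted, ``surface_*`` revolved-area weighted over
    the convective boundary, ``center_*`` the nodal value nearest the
    seed centre (r, z) = (0, 0).
    """

    times: np.ndarray
    mean_T: np.ndarray
    surface_T: np.ndarray
    center_T: np.ndarray
    mean_M: np.ndarray
    surface_M: np.ndarray
    center_M: np.ndarray
    field_times: np.ndarray | None = None
    T_nodes: np.ndarray | None = None
    M_nodes: np.ndarray | None = None
    absorbed_energy: float = 0.0
    enthalpy_gain: float = 0.0

    _SERIES = ("mean_T", "surface_T", "center_T", "mean_M", "surface_M", "center_M")

    def sample(self, times, name: str) -> np.ndarray:
        """Linear-in-time interpolation of a stored summary series.

        Temperature series may be requested in Celsius by appending
        ``_C`` to the name.  Extrapolation outside the simulated window
        is rejected.
        """
        celsius = name.endswith("_C")
        base = name[:-2] if celsius else name
        if base not in self._SERIES:
            raise KeyError(f"unknown series {name!r}")
        t = np.atleast_1d(np.asarray(times, dtype=float))
        if np.any(t < self.times[0] - 1e-9) or np.any(t > self.times[-1] + 1e-9):
            raise ValueError("requested times outside the simulated interval")
        vals = np.interp(t, self.times, getattr(self, base))
        if celsius:
            vals = vals - 273.15
        return vals

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.times,
                "mean_T_C": self.mean_T - 273.15,
                "surface_T_C": self.surface_T - 273.15,
                "center_T_C": self.center_T - 273.15,
                "mean_M_db": self.mean_M,
                "surface_M_db": self.surface_M,
                "center_M_db": self.center_M,
            }
        )


def summaries(solution: FieldSolution, times) -> tuple[np.ndarray, np.ndarray]:
    """(mean temperature in Celsius, mean moisture d.b.) at given instants."""
    return solution.sample(times, "mean_T_C"), solution.sample(times, "mean_M")


class Assembly:
    """Precomputed element quantities and matrix builders for one mesh.

    All matrices are r-weighted; the common 2*pi factor is omitted
    consistently (it cancels in every discrete equation and ratio).
    """

    def __init__(self, mesh: Mesh):
        mesh.validate()
        self.mesh = mesh
        nodes, tris = mesh.nodes, mesh.triangles
        p = nodes[tris]  # (m, 3, 2)
        self.area = mesh.triangle_areas()
        if np.any(self.area <= 0):
            raise ValueError("mesh has degenerate triangles; assembly aborted")
        self.rbar = p[:, :, 0].mean(axis=1)
        # P1 shape-function gradients: N_i = (a_i + b_i r + c_i z)/(2A)
        b = np.stack(
            [p[:, 1, 1] - p[:, 2, 1], p[:, 2, 1] - p[:, 0, 1], p[:, 0, 1] - p[:, 1, 1]], axis=1
        )
        c = np.stack(
            [p[:, 2, 0] - p[:, 1, 0], p[:, 0, 0] - p[:, 2, 0], p[:, 1, 0] - p[:, 0, 0]], axis=1
        )
        grads = np.stack([b, c], axis=2) / (2.0 * self.area)[:, None, None]
        # local stiffness geometry: (grad N_i . grad N_j) * rbar * A
        self.k_local = (
            np.einsum("eik,ejk->eij", grads, grads) * (self.rbar * self.area)[:, None, None]
        )
        local_mass = (np.ones((3, 3)) + np.eye(3)) / 12.0
        self.m_local = local_mass[None, :, :] * (self.rbar * self.area)[:, None, None]
        rows = np.repeat(tris, 3, axis=1)  # (m, 9)
        cols = np.tile(tris, (1, 3))
        self._rows = rows.ravel()
        self._cols = cols.ravel()
        self.n = mesh.n_nodes

        edges = mesh.boundary_edges
        ep = nodes[edges]
        self.edge_len = np.linalg.norm(ep[:, 1] - ep[:, 0], axis=1)
        self.edge_rbar = ep[:, :, 0].mean(axis=1)
        eb_local = (np.ones((2, 2)) + np.eye(2)) / 6.0
        self.b_local = eb_local[None, :, :] * (self.edge_rbar * self.edge_len)[:, None, None]
        self._erows = np.repeat(edges, 2, axis=1).ravel()
        self._ecols = np.tile(edges, (1, 2)).ravel()
        self.edges = edges

        # combined sparsity pattern (element + boundary entries) built once;
        # per-step system matrices are then a single bincount into it
        all_rows = np.concatenate([self._rows, self._erows])
        all_cols = np.concatenate([self._cols, self._ecols])
        key = all_rows.astype(np.int64) * self.n + all_cols
        uniq, self._slot = np.unique(key, return_inverse=True)
        self._pat_indices = (uniq % self.n).astype(np.int32)
        self._pat_indptr = np.searchsorted(uniq // self.n, np.arange(self.n + 1)).astype(np.int32)
        self._n_slots = uniq.size

        # unit-coefficient matrices reused for extraction and loads
        self.mass_unit = self._mat(np.ones(len(tris)), self.m_local)
        self.boundary_unit = self._bmat(np.ones(len(edges)))
        self.vol_weights = np.asarray(self.mass_unit.sum(axis=1)).ravel()
        self.surf_weights = np.asarray(self.boundary_unit.sum(axis=1)).ravel()
        self.center_node = int(np.argmin(np.linalg.norm(nodes, axis=1)))
        self.revolved_volume = 2.0 * math.pi * float(self.vol_weights.sum())
        if np.any(self.vol_weights <= 0):
            raise ValueError("singular mass matrix (non-positive nodal volume): broken mesh")

    def _mat(self, coeff_e: np.ndarray, local: np.ndarray) -> sp.csr_matrix:
        data = (coeff_e[:, None, None] * local).ravel()
        return sp.coo_matrix((data, (self._rows, self._cols)), shape=(self.n, self.n)).tocsr()

    def _bmat(self, coeff_edge: np.ndarray) -> sp.csr_matrix:
        data = (coeff_edge[:, None, None] * self.b_local).ravel()
        return sp.coo_matrix((data, (self._erows, self._ecols)), shape=(self.n, self.n)).tocsr()

    def system_matrix(
        self,
        mass_coeff_e: np.ndarray,
        stiff_coeff_e: np.ndarray,
        bnd_coeff_edge: np.ndarray,
        dt: float,
    ) -> sp.csr_matrix:
        """Backward-Euler LHS  Mass(c_m)/dt + K(c_k) + B(c_b) in one pass."""
        elem = (
            np.asarray(mass_coeff_e)[:, None, None] * self.m_local / dt
            + np.asarray(stiff_coeff_e)[:, None, None] * self.k_local
        ).ravel()
        bnd = (np.asarray(bnd_coeff_edge)[:, None, None] * self.b_local).ravel()
        data = np.bincount(
            self._slot, weights=np.concatenate([elem, bnd]), minlength=self._n_slots
        )
        return sp.csr_matrix(
            (data, self._pat_indices, self._pat_indptr), shape=(self.n, self.n)
        )

    def mass_apply(self, coeff_e: np.ndarray, u: np.ndarray) -> np.ndarray:
        """Matrix-free product Mass(coeff) @ u."""
        contrib = np.einsum(
            "eij,ej->ei", self.m_local, u[self.mesh.triangles]
        ) * np.asarray(coeff_e)[:, None]
        out = np.zeros(self.n)
        np.add.at(out, self.mesh.triangles.ravel(), contrib.ravel())
        return out

    def elem_state(self, T: np.ndarray, M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        tris = self.mesh.triangles
        return T[tris].mean(axis=1), M[tris].mean(axis=1)

    def edge_state(self, T: np.ndarray, M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return T[self.edges].mean(axis=1), M[self.edges].mean(axis=1)

    def mass_matrix(self, coeff_e: np.ndarray) -> sp.csr_matrix:
        return self._mat(np.asarray(coeff_e, dtype=float), self.m_local)

    def stiffness_matrix(self, coeff_e: np.ndarray) -> sp.csr_matrix:
        return self._mat(np.asarray(coeff_e, dtype=float), self.k_local)

    def boundary_matrix(self, coeff_edge: np.ndarray) -> sp.csr_matrix:
        return self._bmat(np.asarray(coeff_edge, dtype=float))

    def source_load(self, q_e: np.ndarray) -> np.ndarray:
        """Consistent load vector for an elementwise-constant source."""
        contrib = (np.asarray(q_e, dtype=float) * self.rbar * self.area / 3.0)
        f = np.zeros(self.n)
        np.add.at(f, self.mesh.triangles.ravel(), np.repeat(contrib, 3))
        return f

    def boundary_load(self, coeff_edge: np.ndarray, value: float) -> np.ndarray:
        contrib = np.asarray(coeff_edge, dtype=float) * self.edge_rbar * self.edge_len * value / 2.0
        f = np.zeros(self.n)
        np.add.at(f, self.edges.ravel(), np.repeat(contrib, 2))
        return f

    def mean(self, u: np.ndarray) -> float:
        return float(self.vol_weights @ u / self.vol_weights.sum())

    def surface_mean(self, u: np.ndarray) -> float:
        return float(self.surf_weights @ u / self.surf_weights.sum())


def assemble(mesh: Mesh) -> Assembly:
    """Build the discrete operator bundle for a mesh."""
    return Assembly(mesh)


def _transfer_coeffs(
    asm: Assembly,
    bc: BoundaryModel,
    T: np.ndarray,
    M: np.ndarray,
    diffmodel: DiffusivityModel,
):
    Te, Me_ = asm.edge_state(T, M)
    h = bc.Bi_heat * props.thermal_conductivity(Te, Me_) / bc.L
    hm = bc.Bi_mass * diffmodel(Te, Me_) / bc.L
    return h, hm


def step_moisture(
    asm: Assembly,
    T: np.ndarray,
    M: np.ndarray,
    dt: float,
    diffmodel: DiffusivityModel,
    bc: BoundaryModel,
    hm_edge: np.ndarray | None = None,
) -> np.ndarray:
    """One implicit step of the moisture equation; coefficients frozen at
    the start-of-step state."""
    Te, Me_ = asm.elem_state(T, M)
    D_e = diffmodel(Te, Me_)
    if hm_edge is None:
        _, hm_edge = _transfer_coeffs(asm, bc, T, M, diffmodel)
    ones = np.ones(asm.mesh.n_triangles)
    A = asm.system_matrix(ones, D_e, hm_edge, dt)
    rhs = asm.mass_unit @ M / dt + asm.boundary_load(hm_edge, bc.Me)
    M_new = spsolve(A.tocsc(), rhs)
    if not np.all(np.isfinite(M_new)):
        raise RuntimeError("moisture solve produced non-finite values")
    return M_new


def step_heat(
    asm: Assembly,
    T: np.ndarray,
    M_old: np.ndarray,
    M_new: np.ndarray,
    dt: float,
    lossmodel: LossFactorModel,
    source: MicrowaveSource,
    bc: BoundaryModel,
    include_evaporation: bool = True,
    h_edge: np.ndarray | None = None,
    diffmodel: DiffusivityModel | None = None,
    E: float | None = None,
) -> tuple[np.ndarray, float]:
    """One implicit heat step following the moisture step of the same
    interval.  Returns the new field and the absorbed microwave energy
    (r-weighted, no 2*pi) of the step for energy bookkeeping."""
    Te, Me_ = asm.elem_state(T, M_old)
    rho_e = props.density(Me_)
    cp_e = props.specific_heat(Te, Me_)
    k_e = props.thermal_conductivity(Te, Me_)
    if E is None:
        E = props.field_strength(source)
    q_e = props.volumetric_heating(E, lossmodel(Te, Me_), source)
    if h_edge is None:
        Tedge, Medge = asm.edge_state(T, M_old)
        h_edge = bc.Bi_heat * props.thermal_conductivity(Tedge, Medge) / bc.L

    rho_cp = rho_e * cp_e
    A = asm.system_matrix(rho_cp, k_e, h_edge, dt)
    rhs = asm.mass_apply(rho_cp, T) / dt + asm.source_load(q_e) + asm.boundary_load(h_edge, bc.Ta)
    if include_evaporation:
        Mv = -props.density(M_old) * (M_new - M_old) / dt  # nodewise, kg/m^3/s
        rhs -= asm.mass_unit @ (props.latent_heat(T) * Mv)
    T_new = spsolve(A.tocsc(), rhs)
    if not np.all(np.isfinite(T_new)):
        raise RuntimeError("heat solve produced non-finite values")
    absorbed = float((q_e * asm.rbar * asm.area).sum()) * dt
    return T_new, absorbed


def run_forward(
    mesh_or_asm,
    config: SimulationConfig,
    lossmodel: LossFactorModel,
    diffmodel: DiffusivityModel,
    source: MicrowaveSource,
    bc: BoundaryModel,
) -> FieldSolution:
    """March the segregated coupled system from t = 0 to t_end.

    Per interval: one implicit moisture step, then one implicit heat step
    using the fresh moisture increment for the evaporation sink.  The run
    is deterministic given its inputs.  Blow-up (|T| > 600 K or M < -1e-6)
    aborts with step diagnostics.
    """
    asm = mesh_or_asm if isinstance(mesh_or_asm, Assembly) else Assembly(mesh_or_asm)
    n_steps = int(round(config.t_end / config.dt))
    dt = config.t_end / n_steps
    T = np.full(asm.n, float(config.T0))
    M = np.full(asm.n, float(config.M0))
    E = props.field_strength(source)

    h_frozen = hm_frozen = None
    if bc.freeze_coefficients:
        h_frozen, hm_frozen = _transfer_coeffs(asm, bc, T, M, diffmodel)

    times = np.zeros(n_steps + 1)
    series = {k: np.zeros(n_steps + 1) for k in FieldSolution._SERIES}

    def record(i, T, M):
        series["mean_T"][i] = asm.mean(T)
        series["surface_T"][i] = asm.surface_mean(T)
        series["center_T"][i] = T[asm.center_node]
        series["mean_M"][i] = asm.mean(M)
        series["surface_M"][i] = asm.surface_mean(M)
        series["center_M"][i] = M[asm.center_node]

    record(0, T, M)
    out_times = np.asarray(config.output_times, dtype=float) if config.output_times else None
    stored_t, stored_T, stored_M = [], [], []
    if config.store_fields:
        stored_t.append(0.0)
        stored_T.append(T.copy())
        stored_M.append(M.copy())

    absorbed = 0.0
    enthalpy = 0.0
    for i in range(1, n_steps + 1):
        t = i * dt
        if bc.freeze_coefficients:
            h_edge, hm_edge = h_frozen, hm_frozen
        else:
            h_edge, hm_edge = _transfer_coeffs(asm, bc, T, M, diffmodel)
        M_new = step_moisture(asm, T, M, dt, diffmodel, bc, hm_edge=hm_edge)
        Te, Me_ = asm.elem_state(T, M)
        rho_cp = props.density(Me_) * props.specific_heat(Te, Me_)
        T_new, dE = step_heat(
            asm, T, M, M_new, dt, lossmodel, source, bc,
            include_evaporation=config.include_evaporation,
            h_edge=h_edge, E=E,
        )
        absorbed += dE
        enthalpy += float(asm.mass_apply(rho_cp, T_new - T).sum())
        if np.max(np.abs(T_new)) > 600.0 or np.min(M_new) < -1e-6:
            magnitude = max(float(np.max(np.abs(T_new))) - 600.0, 0.0) + 1e6 * max(
                -float(np.min(M_new)), 0.0
            )
            raise ForwardBlowup(
                t, config.t_end, i, magnitude,
                f"max|T|={np.max(np.abs(T_new)):.1f} K, min M={np.min(M_new):.3e}",
            )
        T, M = T_new, M_new
        times[i] = t
        record(i, T, M)
        if config.store_fields and (
            out_times is None or np.any(np.isclose(t, out_times, atol=dt / 2))
        ):
            stored_t.append(t)
            stored_T.append(T.copy())
            stored_M.append(M.copy())
        if (
            config.stop_below_mean_M is not None
            and series["mean_M"][i] <= config.stop_below_mean_M
        ):
            times = times[: i + 1]
            series = {k: v[: i + 1] for k, v in series.items()}
            break

    return FieldSolution(
        times=times,
        **{k: v for k, v in series.items()},
        field_times=np.asarray(stored_t) if config.store_fields else None,
        T_nodes=np.asarray(stored_T) if config.store_fields else None,
        M_nodes=np.asarray(stored_M) if config.store_fields else None,
        absorbed_energy=2.0 * math.pi * absorbed,
        enthalpy_gain=2.0 * math.pi * enthalpy,
    )
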