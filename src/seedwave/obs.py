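"""Measured drying records, Fourier-series smoothing and fit statistics.

A drying record holds, per treatment, the irregular time series measured
during the process: the sample mass (g) or its dry-basis moisture, and
the mean surface temperature (degC).  Mass series are converted to
dry-basis moisture on ingest.  Smoothing with a five-harmonic Fourier
series provides differentiable stand-ins for the measured trajectories;
it only drives the stage-1 lumped estimators and is never reported as a
result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar


@dataclass
class DryingRecord:
    """One treatment's measured drying curves.

    times in seconds (strictly increasing, starting at 0), moisture
    dry-basis decimal, surface temperature in Celsius.  ``meta`` carries
    the treatment configuration (power_kW, imc_db, initial_T_C, ...).
    """

    treatment_id: str
    times: np.ndarray
    moisture_db: np.ndarray
    surface_T_C: np.ndarray
    mass_g: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.moisture_db = np.asarray(self.moisture_db, dtype=float)
        self.surface_T_C = np.asarray(self.surface_T_C, dtype=float)
        order = np.argsort(self.times)
        self.times = self.times[order]
        self.moisture_db = self.moisture_db[order]
        self.surface_T_C = self.surface_T_C[order]
        if self.mass_g is not None:
            self.mass_g = np.asarray(self.mass_g, dtype=float)[order]
        if self.times[0] != 0.0:
            raise ValueError("record must start at t = 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("record times must be strictly increasing")
        if np.any(self.moisture_db < 0):
            raise ValueError("moisture series must be non-negative")
        if len({len(self.times), len(self.moisture_db), len(self.surface_T_C)}) != 1:
            raise ValueError("record series must have equal length")

    @property
    def n(self) -> int:
        return len(self.times)

    @classmethod
    def from_csv(cls, path, treatment_id: str = "", M0: float | None = None, meta: dict | None = None):
        """Read a record from CSV with columns
        ``time_s, mass_g | moisture_db, surface_T_C``.

        Exactly one of the mass/moisture columns must be present; a mass
        column requires the initial dry-basis moisture ``M0``.
        """
        df = pd.read_csv(path)
        for col in ("time_s", "surface_T_C"):
            if col not in df.columns:
                raise ValueError(f"record CSV is missing required column {col!r}")
        has_mass = "mass_g" in df.columns
        has_moist = "moisture_db" in df.columns
        if has_mass == has_moist:
            raise ValueError("record CSV needs exactly one of 'mass_g' or 'moisture_db'")
        meta = dict(meta or {})
        if has_mass:
            if M0 is None:
                M0 = meta.get("imc_db")
            if M0 is None:
                raise ValueError("mass-based record needs the initial moisture M0")
            moisture = moisture_from_mass(df["mass_g"].to_numpy(), M0)
            mass = df["mass_g"].to_numpy()
        else:
            moisture = df["moisture_db"].to_numpy()
            mass = None
        return cls(
            treatment_id=treatment_id,
            times=df["time_s"].to_numpy(),
            moisture_db=moisture,
            surface_T_C=df["surface_T_C"].to_numpy(),
            mass_g=mass,
            meta=meta,
        )

    def to_csv(self, path) -> None:
        cols = {"time_s": self.times}
        if self.mass_g is not None:
            cols["mass_g"] = self.mass_g
        cols["moisture_db"] = self.moisture_db
        cols["surface_T_C"] = self.surface_T_C
        pd.DataFrame(cols).to_csv(path, index=False)


def moisture_from_mass(mass_g, M0: float) -> np.ndarray:
    """Dry-basis moisture from a mass series and the initial moisture.

    The dry-matter mass is fixed by the first sample: m_dry = m(0)/(1+M0);
    then M(t) = (m(t) - m_dry)/m_dry.
    """
    mass_g = np.asarray(mass_g, dtype=float)
    if np.any(mass_g <= 0):
        raise ValueError("mass series must be positive")
    if M0 < 0:
        raise ValueError("initial moisture must be non-negative")
    m_dry = mass_g[0] / (1.0 + M0)
    M = (mass_g - m_dry) / m_dry
    if np.any(M < -1e-6):
        raise ValueError("computed moisture < 0: inconsistent initial moisture M0")
    return M


@dataclass
class FourierSeriesFit:
    """Truncated Fourier series a0 + sum_k a_k cos(k w t) + b_k sin(k w t).

    Valid only inside the fitted domain; the fundamental frequency omega
    is a fitted parameter.
    """

    a0: float
    a: np.ndarray
    b: np.ndarray
    omega: float
    domain: tuple[float, float]
    sse: float = np.nan

    @property
    def n_harmonics(self) -> int:
        return len(self.a)

    def _check(self, t):
        t = np.asarray(t, dtype=float)
        lo, hi = self.domain
        if np.any(t < lo - 1e-9) or np.any(t > hi + 1e-9):
            raise ValueError("evaluation outside the fitted domain")
        return t

    def __call__(self, t):
        t = self._check(t)
        k = np.arange(1, self.n_harmonics + 1)
        ang = np.multiply.outer(t, k) * self.omega
        return self.a0 + np.cos(ang) @ self.a + np.sin(ang) @ self.b

    def derivative(self, t):
        """d/dt of the series (analytic)."""
        t = self._check(t)
        k = np.arange(1, self.n_harmonics + 1)
        ang = np.multiply.outer(t, k) * self.omega
        kw = k * self.omega
        return -np.sin(ang) @ (self.a * kw) + np.cos(ang) @ (self.b * kw)


def _design(t: np.ndarray, omega: float, n_harm: int) -> np.ndarray:
    k = np.arange(1, n_harm + 1)
    ang = np.multiply.outer(t, k) * omega
    return np.hstack([np.ones((len(t), 1)), np.cos(ang), np.sin(ang)])


def fit_fourier(times, values, n_harmonics: int = 5) -> FourierSeriesFit:
    """Nonlinear least-squares Fourier-series smoother (variable projection).

    For any fixed fundamental frequency omega the problem is linear in the
    2*n_harmonics + 1 amplitude coefficients; the nonlinearity is confined
    to omega, optimised by a bounded scalar search around its initialiser
    2*pi/(t_max - t_min).  If the search fails to improve (e.g. a
    rank-deficient design), omega stays at the initialiser and only the
    linear problem is solved.  Deterministic given the data.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    n_par = 2 * n_harmonics + 2
    if len(t) < n_par + 1:
        raise ValueError(f"need at least {n_par + 1} points for {n_harmonics} harmonics")
    omega0 = 2.0 * np.pi / (t[-1] - t[0])

    def linear_fit(omega):
        X = _design(t, omega, n_harmonics)
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(((X @ coef - y) ** 2).sum())
        return coef, sse

    coef0, sse0 = linear_fit(omega0)
    coef, omega, sse = coef0, omega0, sse0
    # skip the omega search when the linear fit is already at the data's
    # floating-point floor (the search would only chase round-off)
    if sse0 > 1e-14 * max(float((y**2).sum()), 1e-30):
        sol = minimize_scalar(lambda w: linear_fit(w)[1],
                              bounds=(0.3 * omega0, 3.0 * omega0), method="bounded",
                              options={"xatol": 1e-10 * omega0, "maxiter": 200})
        if np.isfinite(sol.fun) and sol.fun < sse0:
            omega = float(sol.x)
            coef, sse = linear_fit(omega)
    return FourierSeriesFit(
        a0=float(coef[0]),
        a=np.asarray(coef[1 : n_harmonics + 1]),
        b=np.asarray(coef[n_harmonics + 1 :]),
        omega=omega,
        domain=(float(t[0]), float(t[-1])),
        sse=sse,
    )


@dataclass(frozen=True)
class FitStatistics:
    """Goodness-of-fit summary: SSE, R^2, RMSE and the mean relative
    percentage error (MRPE, %), with zero-observed points excluded from
    MRPE and counted."""

    sse: float
    r2: float
    rmse: float
    mrpe: float
    n: int
    mrpe_excluded: int = 0


def fit_statistics(observed, predicted) -> FitStatistics:
    """Compute SSE, R^2, RMSE and MRPE of predictions against observations.

    mrpe = (100/n) * sum |o - p| / |o| over points with o != 0.
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1 or len(o) < 2:
        raise ValueError("observed/predicted must be equal-length 1-d series, n >= 2")
    resid = o - p
    sse = float((resid**2).sum())
    ss_tot = float(((o - o.mean()) ** 2).sum())
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else (1.0 if sse == 0 else -np.inf)
    rmse = float(np.sqrt(sse / len(o)))
    nz = o != 0
    n_excluded = int((~nz).sum())
    if nz.any():
        mrpe = float(100.0 * (np.abs(resid[nz]) / np.abs(o[nz])).mean())
    else:
        mrpe = np.nan
    return FitStatistics(sse=sse, r2=r2, rmse=rmse, mrpe=mrpe, n=len(o), mrpe_excluded=n_excluded)
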