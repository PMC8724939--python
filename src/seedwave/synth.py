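"""Synthetic drying records with the structure of the bench experiments.

The generator runs the forward coupled model with known ("true")
loss-factor and diffusivity models, samples mean surface temperature and
mean moisture on a measurement schedule, and adds independent Gaussian
noise per channel.  It emulates microwave drying of a thin layer of
tempered lentil: six presets (2 nominal powers x 3 tempering moistures)
use the published per-treatment coefficient rows as ground truth, 15 s
sampling, and run until the mean moisture returns to the 0.10 d.b.
initial storage moisture (capped at 30 simulated minutes).

Default noise levels: sigma_T = 0.5 degC (infrared camera sensitivity
plus handling), sigma_M = 0.003 d.b. (a 0.01 g scale on ~50 g samples,
with margin).  The initial moisture sample is exact by construction
(the tempering target is known, not measured).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import tables
from .fem import Assembly, BoundaryModel, SimulationConfig, run_forward
from .lensgeom import LensGeometry, characteristic_length, generate_mesh
from .obs import DryingRecord
from .props import DiffusivityModel, LossFactorModel, MicrowaveSource

#: Moisture content at which drying stops (seeds returned to storage moisture).
FINAL_MOISTURE_DB = 0.10
#: Hard cap on simulated process duration, s.
MAX_DURATION_S = 1800.0


@dataclass(frozen=True)
class SyntheticScenario:
    """Ground truth + measurement protocol for one synthetic treatment."""

    treatment_id: str
    true_loss_model: LossFactorModel
    true_diff_model: DiffusivityModel
    true_bi: tuple[float, float]  # (Bi_heat, Bi_mass)
    source: MicrowaveSource
    schedule: np.ndarray  # sampling times, s
    noise: tuple[float, float] = (0.5, 0.003)  # (sigma_T degC, sigma_M d.b.)
    seed: int = 0
    T0: float = 277.15  # 4 degC, inside the 3-6 degC initial band
    M0: float = 0.35
    geom: LensGeometry = field(default_factory=LensGeometry)

    def __post_init__(self):
        sched = np.asarray(self.schedule, dtype=float)
        if sched[0] != 0.0 or np.any(np.diff(sched) <= 0):
            raise ValueError("schedule must start at 0 and be strictly increasing")
        object.__setattr__(self, "schedule", sched)
        if any(s < 0 for s in self.noise):
            raise ValueError("noise standard deviations must be non-negative")


def make_paper_like_scenarios(
    noise: tuple[float, float] = (0.5, 0.003),
    seed: int = 0,
    sampling_s: float = 15.0,
) -> list[SyntheticScenario]:
    """The six study presets: 2 powers x 3 tempering moistures.

    Coefficients come from the published per-treatment rows, Biot numbers
    from the published optima, and the microwave source from the
    calibrated magnetron power and reflection coefficient of each power
    level.
    """
    scenarios = []
    for i, tid in enumerate(tables.TREATMENTS):
        imc = tables.load_tables()["loss_factor"]["treatments"][tid]["imc_db"]
        bi = tables.biot_numbers(tid)
        schedule = np.arange(0.0, MAX_DURATION_S + sampling_s / 2, sampling_s)
        scenarios.append(
            SyntheticScenario(
                treatment_id=tid,
                true_loss_model=tables.loss_factor_model(tid),
                true_diff_model=tables.diffusivity_model(tid),
                true_bi=bi,
                source=tables.microwave_source(tid),
                schedule=schedule,
                noise=noise,
                seed=seed + i,
                M0=imc,
            )
        )
    return scenarios


def generate_record(
    scenario: SyntheticScenario,
    target_h: float = 1.8e-4,
    dt: float = 0.5,
    as_mass: bool = False,
    sample_g: float = 50.0,
    assembly: Assembly | None = None,
) -> DryingRecord:
    """Run the true forward model and sample a noisy drying record.

    The record is truncated at the first scheduled sample where the clean
    mean moisture has fallen to FINAL_MOISTURE_DB (if reached).  Noise is
    i.i.d. Gaussian per channel, seeded by the scenario; the moisture
    sample at t = 0 is exact.
    """
    asm = assembly if assembly is not None else Assembly(generate_mesh(scenario.geom, target_h))
    L = characteristic_length(scenario.geom)
    bc = BoundaryModel(Bi_heat=scenario.true_bi[0], Bi_mass=scenario.true_bi[1], L=L)
    t_end = float(scenario.schedule[-1])
    # marching stops shortly below the final moisture so the sampled record
    # always contains the crossing (and the dried-out seed is never driven on)
    cfg = SimulationConfig(T0=scenario.T0, M0=scenario.M0, t_end=t_end, dt=dt,
                           stop_below_mean_M=0.97 * FINAL_MOISTURE_DB)
    sol = run_forward(asm, cfg, scenario.true_loss_model, scenario.true_diff_model,
                      scenario.source, bc)

    sched = scenario.schedule[scenario.schedule <= sol.times[-1] + 1e-9]
    clean_M = sol.sample(sched, "mean_M")
    clean_T = sol.sample(sched, "surface_T_C")
    done = np.nonzero(clean_M <= FINAL_MOISTURE_DB)[0]
    if done.size:
        sched = sched[: done[0] + 1]
        clean_M = clean_M[: done[0] + 1]
        clean_T = clean_T[: done[0] + 1]

    rng = np.random.default_rng(scenario.seed)
    sigma_T, sigma_M = scenario.noise
    noisy_T = clean_T + rng.normal(0.0, sigma_T, size=len(sched)) if sigma_T > 0 else clean_T.copy()
    noise_M = rng.normal(0.0, sigma_M, size=len(sched)) if sigma_M > 0 else np.zeros(len(sched))
    noise_M[0] = 0.0  # tempering target is known exactly
    noisy_M = np.maximum(clean_M + noise_M, 0.0)

    mass = None
    if as_mass:
        m_dry = sample_g / (1.0 + scenario.M0)
        mass = m_dry * (1.0 + noisy_M)

    return DryingRecord(
        treatment_id=scenario.treatment_id,
        times=sched,
        moisture_db=noisy_M,
        surface_T_C=noisy_T,
        mass_g=mass,
        meta={
            "power_kW": scenario.source.Pav / 880.0,  # nominal = Pav/0.88/1000
            "pav_watts": scenario.source.Pav,
            "s11": scenario.source.S11,
            "imc_db": scenario.M0,
            "initial_T_C": scenario.T0 - 273.15,
            "bi_heat": scenario.true_bi[0],
            "bi_mass": scenario.true_bi[1],
            "seed": scenario.seed,
        },
    )
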