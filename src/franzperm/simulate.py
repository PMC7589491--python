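"""Two-compartment Franz-cell simulator with known true permeability.

The simulator produces receiver concentration–time series for a passive
two-compartment diffusion cell with donor depletion, discrete sampling
events with buffer replacement, and multiplicative analytic noise, so that
every downstream estimator can be tested against ground truth.

Model
-----
Between sampling events the receiver concentration obeys

    dC_r/dt = P_eff · S · (C_d − C_r) / V_r,      C_d = (Q − C_r·V_r) / V_d

with Q the total dissolved mass in both chambers.  This linear ODE has the
closed-form solution implemented by :func:`propagate_interval`: the system
relaxes exponentially toward the well-mixed equilibrium Q/(V_r + V_d) with
rate constant P_eff·S·(1/V_r + 1/V_d).

At each sampling time a volume ``sample_volume`` is withdrawn from the
receiver and replaced with fresh buffer: the receiver concentration drops
by the dilution factor f = (V_r − V_s)/V_r and the withdrawn mass
C_r·V_s leaves the system.  The simulator always conserves mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from franzperm.core import CellGeometry, PermeationExperiment, SamplingSchedule

__all__ = ["SimulationConfig", "propagate_interval", "simulate_permeation"]

SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for one simulated permeation experiment.

    ``noise_cv`` is the relative standard deviation of multiplicative
    Gaussian measurement noise applied to *recorded* concentrations only
    (HPLC error scales roughly with concentration); the propagated physical
    state is never perturbed.
    """

    true_peff: float                 # cm/s
    geometry: CellGeometry
    schedule: SamplingSchedule
    donor_concentration_0: float     # µg/mL
    n_replicates: int = 3
    noise_cv: float = 0.0
    seed: int = 0
    drug_name: str = "simulated"

    def __post_init__(self) -> None:
        if self.true_peff < 0:
            raise ValueError("true_peff must be non-negative")
        if self.donor_concentration_0 <= 0:
            raise ValueError("donor_concentration_0 must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


def propagate_interval(
    c_receiver_start: float,
    q_total: float,
    peff: float,
    geometry: CellGeometry,
    delta_t: float,
) -> float:
    """Advance the receiver concentration by ``delta_t`` seconds.

    Closed-form solution of the two-compartment diffusion ODE: the receiver
    concentration approaches the equilibrium value q_total/(V_r + V_d)
    exponentially with rate P_eff·S·(1/V_r + 1/V_d).

    Parameters
    ----------
    c_receiver_start:
        Receiver concentration at the start of the interval, µg/mL.
    q_total:
        Total dissolved mass in donor + receiver, µg.
    peff:
        Permeability coefficient, cm/s.
    geometry:
        Cell constants (area cm², volumes mL).
    delta_t:
        Interval length in **seconds**.
    """
    if delta_t < 0:
        raise ValueError("delta_t must be non-negative")
    if peff < 0:
        raise ValueError("peff must be non-negative")
    v_r = geometry.receiver_volume
    v_d = geometry.donor_volume
    c_eq = q_total / (v_r + v_d)
    rate = peff * geometry.area * (1.0 / v_r + 1.0 / v_d)
    return c_eq + (c_receiver_start - c_eq) * np.exp(-rate * delta_t)


def simulate_permeation(config: SimulationConfig) -> PermeationExperiment:
    """Simulate one multi-replicate Franz-cell permeation experiment.

    Each replicate starts from an empty receiver and a donor holding
    V_donor · C0 of drug.  Schedule intervals are propagated with the
    closed-form solution; at each sampling time the *pre-replacement*
    receiver concentration is recorded (optionally noise-perturbed), then
    the sampling event removes C_r·V_s of mass and dilutes the receiver by
    f = (V_r − V_s)/V_r.  Identical seeds give identical experiments.
    """
    geom = config.geometry
    rng = np.random.default_rng(config.seed)
    intervals_s = config.schedule.intervals_h * SECONDS_PER_HOUR
    f = geom.dilution_factor

    replicates: list[np.ndarray] = []
    for _ in range(config.n_replicates):
        c_r = 0.0
        q_total = geom.donor_volume * config.donor_concentration_0
        recorded = np.empty(len(config.schedule))
        for k, dt_s in enumerate(intervals_s):
            c_r = propagate_interval(c_r, q_total, config.true_peff, geom, dt_s)
            value = c_r
            if config.noise_cv > 0:
                value = max(0.0, value * rng.normal(1.0, config.noise_cv))
            recorded[k] = value
            # sampling event: withdraw V_s at the true concentration,
            # replace with fresh buffer
            q_total -= c_r * geom.sample_volume
            c_r *= f
        replicates.append(recorded)

    return PermeationExperiment(
        drug_name=config.drug_name,
        geometry=geom,
        schedule=config.schedule,
        donor_concentration_0=config.donor_concentration_0,
        replicates=replicates,
    )
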