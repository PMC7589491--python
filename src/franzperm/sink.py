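"""Steady-state flux and sink-condition apparent permeability.

Under sink conditions (receiver concentration negligible against the
donor) the cumulative mass transported across the membrane grows linearly
in time, and the flux at steady state is

    J = (dQ/dt) / A          [µg cm⁻² s⁻¹]

from which the apparent permeability follows by normalising against the
donor concentration:

    Papp = J / C0            [cm/s]  (C0 in µg/cm³ ≡ µg/mL).

The slope dQ/dt is taken from an ordinary least-squares fit through the
*linear portion* of the cumulative transport curve, selected as the
contiguous window (at least ``min_window`` points) maximising R².
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from franzperm.core import CellGeometry, FluxEstimate, PermeationExperiment

__all__ = [
    "cumulative_amount",
    "find_linear_portion",
    "estimate_flux",
    "papp_sink",
]

SECONDS_PER_HOUR = 3600.0

#: Smallest admissible linear window.  With a 10-point schedule this leaves
#: at least two residual degrees of freedom for the R² to be meaningful.
MIN_WINDOW = 4

_TIE_TOL = 1e-9


def cumulative_amount(
    concentrations: np.ndarray, geometry: CellGeometry
) -> np.ndarray:
    """Cumulative mass transported into the receiver, corrected for sampling.

    At sampling time t_k the mass that has crossed the membrane is the mass
    currently in the receiver plus everything previously withdrawn:

        Q(t_k) = C_k · V_receiver + Σ_{i<k} C_i · V_sample

    where C_i are the measured (pre-replacement) concentrations.
    """
    c = np.asarray(concentrations, dtype=float)
    withdrawn = np.concatenate([[0.0], np.cumsum(c[:-1])]) * geometry.sample_volume
    return c * geometry.receiver_volume + withdrawn


def _window_fit(t: np.ndarray, q: np.ndarray) -> tuple[float, float, float]:
    """OLS slope, intercept and R² on one window; R² = 1 for an exact fit."""
    if np.ptp(q) == 0.0:
        # constant window: a zero-slope line fits exactly
        return 0.0, float(q[0]), 1.0
    fit = stats.linregress(t, q)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue) ** 2


def find_linear_portion(
    times_h: np.ndarray,
    cumulative: np.ndarray,
    min_window: int = MIN_WINDOW,
) -> tuple[int, int, float]:
    """Select the best-fit linear window of a cumulative transport curve.

    Among all contiguous windows of at least ``min_window`` points, returns
    ``(start, end, r_squared)`` (end inclusive) for the window maximising
    the OLS R².  Ties within 1e-9 are broken in favour of the longer
    window, then of the later start (closer to steady state).
    """
    t = np.asarray(times_h, dtype=float)
    q = np.asarray(cumulative, dtype=float)
    n = len(t)
    if len(q) != n:
        raise ValueError("times and cumulative series must have equal length")
    if n < min_window:
        raise ValueError(f"series has {n} points; at least {min_window} required")

    best: tuple[int, int, float] | None = None
    for start in range(0, n - min_window + 1):
        for end in range(start + min_window - 1, n):
            _, _, r2 = _window_fit(t[start:end + 1], q[start:end + 1])
            if best is None:
                best = (start, end, r2)
                continue
            b_start, b_end, b_r2 = best
            if r2 > b_r2 + _TIE_TOL:
                best = (start, end, r2)
            elif abs(r2 - b_r2) <= _TIE_TOL:
                length, b_length = end - start, b_end - b_start
                if length > b_length or (length == b_length and start > b_start):
                    best = (start, end, r2)
    assert best is not None
    return best


def estimate_flux(exp: PermeationExperiment) -> FluxEstimate:
    """Steady-state flux from the linear portion, averaged over replicates.

    Each replicate is converted to cumulative mass, its linear portion is
    selected independently, and the per-replicate slopes give per-replicate
    fluxes J_i = slope_i / (A · 3600); the reported flux is their mean and
    ``cv_percent`` their coefficient of variation (0 for one replicate).
    The reported window and R² come from the fit on the replicate-mean
    cumulative series, matching the mean-plot convention.
    """
    if exp.n_replicates < 1:
        raise ValueError("experiment must contain at least one replicate")
    t = np.asarray(exp.schedule.times)
    area = exp.geometry.area

    slopes = []
    for rep in exp.replicates:
        q = cumulative_amount(rep, exp.geometry)
        if np.all(q == 0.0):
            slopes.append(0.0)
            continue
        start, end, _ = find_linear_portion(t, q)
        slope, _, _ = _window_fit(t[start:end + 1], q[start:end + 1])
        slopes.append(slope)
    slopes = np.asarray(slopes)

    q_mean = cumulative_amount(exp.mean_series(), exp.geometry)
    if np.all(q_mean == 0.0):
        # no transport at all: flux 0, R² undefined
        return FluxEstimate(
            slope=0.0, window_start_index=0, window_end_index=len(t) - 1,
            r_squared=None, flux_J=0.0, cv_percent=0.0,
        )
    w_start, w_end, r2 = find_linear_portion(t, q_mean)

    mean_slope = float(np.mean(slopes))
    flux = mean_slope / (area * SECONDS_PER_HOUR)
    fluxes = slopes / (area * SECONDS_PER_HOUR)
    if len(fluxes) > 1 and np.mean(fluxes) != 0.0:
        cv = 100.0 * float(np.std(fluxes, ddof=1) / np.mean(fluxes))
    else:
        cv = 0.0
    return FluxEstimate(
        slope=mean_slope,
        window_start_index=w_start,
        window_end_index=w_end,
        r_squared=r2,
        flux_J=flux,
        cv_percent=abs(cv),
    )


def papp_sink(flux_J: float, c0: float) -> float:
    """Apparent permeability Papp = J / C0 in cm/s.

    ``flux_J`` in µg cm⁻² s⁻¹ and ``c0`` in µg/mL (= µg/cm³), so the units
    cancel to cm/s directly.
    """
    if c0 <= 0:
        raise ValueError("donor concentration c0 must be positive")
    return flux_J / c0
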