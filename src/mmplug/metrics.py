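"""Derived pharmacokinetic metrics and closed-form reference solutions.

Cmax/Tmax are read directly off the recorded grid (no interpolation), so the
output interval of the integrator sets the Tmax resolution.  AUC uses the
linear trapezoidal rule; extrapolation to infinity, when requested, uses the
terminal log-linear slope.

:func:`analytic_two_compartment` is the standard three-exponential solution
for first-order absorption into a two-compartment model with central
elimination.  It is the pre-dissolved limit of the full simulator (all drug
in solution, constant ka) and serves as an independent oracle in the tests;
with ``k12 = k21 = 0`` it reduces exactly to the Bateman function.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .model import PKParameters

__all__ = [
    "PKMetrics",
    "cmax_tmax",
    "auc_trapezoid",
    "auc_infinity",
    "analytic_two_compartment",
    "bateman",
    "compute_metrics",
]


@dataclass(frozen=True)
class PKMetrics:
    """Summary exposure metrics of one concentration-time profile."""

    cmax: float  # mg/mL
    tmax: float  # min
    auc_0_t: float  # mg*min/mL over the recorded window
    auc_0_inf: float | None = None  # optional log-linear extrapolation

    def __post_init__(self) -> None:
        if self.auc_0_inf is not None and self.auc_0_inf < self.auc_0_t - 1e-15:
            raise ValueError("AUC(0-inf) cannot be smaller than AUC(0-t)")


def cmax_tmax(times: np.ndarray, cp: np.ndarray) -> tuple[float, float]:
    """Peak concentration and its time on the recorded grid.

    Ties break to the earliest time.  A profile still rising at the last
    recorded point triggers a truncation warning, since the true peak lies
    beyond the simulated window.
    """
    times = np.asarray(times, dtype=float)
    cp = np.asarray(cp, dtype=float)
    if times.size == 0 or times.size != cp.size:
        raise ValueError("times and cp must be non-empty series of equal length")
    k = int(np.argmax(cp))
    if k == times.size - 1 and times.size > 1:
        warnings.warn(
            "profile maximum at the final recorded time; Tmax may be truncated",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(cp[k]), float(times[k])


def auc_trapezoid(times: np.ndarray, cp: np.ndarray) -> float:
    """Linear trapezoidal AUC over the recorded grid (mg*min/mL)."""
    times = np.asarray(times, dtype=float)
    cp = np.asarray(cp, dtype=float)
    if times.size != cp.size:
        raise ValueError("times and cp must have equal length")
    if times.size < 2:
        return 0.0
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(cp, times))


def auc_infinity(times: np.ndarray, cp: np.ndarray, terminal_fraction: float = 0.2):
    """AUC extrapolated to infinity via the terminal log-linear slope.

    The elimination rate ``lambda_z`` is fit by least squares to ``ln(cp)``
    over the last ``terminal_fraction`` of positive points; the tail adds
    ``cp_last / lambda_z``.  Returns ``None`` when no credible terminal
    phase exists (fewer than three positive points, or non-negative slope).
    """
    times = np.asarray(times, dtype=float)
    cp = np.asarray(cp, dtype=float)
    auc_t = auc_trapezoid(times, cp)
    pos = cp > 0
    if pos.sum() < 3:
        return None
    n_tail = max(3, int(math.ceil(pos.sum() * terminal_fraction)))
    idx = np.flatnonzero(pos)[-n_tail:]
    slope = np.polyfit(times[idx], np.log(cp[idx]), 1)[0]
    if slope >= 0:
        return None
    return auc_t + float(cp[idx[-1]] / (-slope))


def _disposition_eigenvalues(pk: PKParameters) -> tuple[float, float]:
    a = pk.k12 + pk.k21 + pk.ke
    disc = math.sqrt(max(a * a - 4.0 * pk.k21 * pk.ke, 0.0))
    return (a + disc) / 2.0, (a - disc) / 2.0


def analytic_two_compartment(
    t: np.ndarray | float,
    dose: float,
    ka: float,
    f_bio: float,
    pk: PKParameters,
) -> np.ndarray | float:
    """Plasma concentration (mg/mL) for first-order absorption, two compartments.

    Closed form for ``Xa' = -ka Xa``, ``Xp' = F ka Xa - (k12 + ke) Xp + k21
    Xt``, ``Xt' = k12 Xp - k21 Xt`` with all drug initially in solution::

        Cp(t) = (F D ka / Vc) * [ (k21-a) e^{-a t} / ((ka-a)(b-a))
                                + (k21-b) e^{-b t} / ((ka-b)(a-b))
                                + (k21-ka) e^{-ka t} / ((a-ka)(b-ka)) ]

    where a, b are the disposition eigenvalues.  Raises if ``ka`` coincides
    with either eigenvalue (perturb a parameter slightly in that case).
    """
    alpha, beta = _disposition_eigenvalues(pk)
    scale = max(alpha, ka, 1e-30)
    if min(abs(ka - alpha), abs(ka - beta)) < 1e-12 * scale:
        raise ValueError(
            "ka coincides with a disposition eigenvalue; perturb a parameter slightly"
        )
    t_arr = np.asarray(t, dtype=float)
    coef_a = (pk.k21 - alpha) / ((ka - alpha) * (beta - alpha))
    coef_b = (pk.k21 - beta) / ((ka - beta) * (alpha - beta))
    coef_k = (pk.k21 - ka) / ((alpha - ka) * (beta - ka))
    cp = (f_bio * dose * ka / pk.vc) * (
        coef_a * np.exp(-alpha * t_arr)
        + coef_b * np.exp(-beta * t_arr)
        + coef_k * np.exp(-ka * t_arr)
    )
    return cp if isinstance(t, np.ndarray) else float(cp)


def bateman(
    t: np.ndarray | float, dose: float, ka: float, f_bio: float, pk: PKParameters
) -> np.ndarray | float:
    """One-compartment oral-absorption profile (k12 = k21 = 0 limit)."""
    ke = pk.ke
    if abs(ka - ke) < 1e-12 * max(ka, ke, 1e-30):
        raise ValueError("ka coincides with ke; perturb a parameter slightly")
    t_arr = np.asarray(t, dtype=float)
    cp = (f_bio * dose * ka / (pk.vc * (ka - ke))) * (
        np.exp(-ke * t_arr) - np.exp(-ka * t_arr)
    )
    return cp if isinstance(t, np.ndarray) else float(cp)


def compute_metrics(times: np.ndarray, cp: np.ndarray, extrapolate: bool = False) -> PKMetrics:
    """Cmax/Tmax/AUC bundle for one profile."""
    cmax, tmax = cmax_tmax(times, cp)
    auc_t = auc_trapezoid(times, cp)
    auc_inf = auc_infinity(times, cp) if extrapolate else None
    return PKMetrics(cmax=cmax, tmax=tmax, auc_0_t=auc_t, auc_0_inf=auc_inf)
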