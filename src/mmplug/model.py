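"""State types and rate laws for the moving-plug dissolution/absorption model.

The gastrointestinal tract is modelled as a set of discrete fluid plugs that
empty from the stomach at scheduled times and then move independently; there
is no mass transfer between plugs.  Within plug *j*, each particle-size
fraction *i* contributes four coupled masses (all in mg):

``Xs``  solid drug remaining in the lumen,
``Xd``  dissolved drug in the plug fluid,
``Xp``  drug in the central (plasma) compartment,
``Xt``  drug in the peripheral (tissue) compartment.

Solid drug dissolves by the Noyes-Whitney law for shrinking monodisperse
spheres, so the remaining mass enters the rate as ``X0^(1/3) * Xs^(2/3)`` and
the diffusion-layer thickness shrinks with the particle radius.  Dissolved
drug is absorbed first-order with a plug-specific, time-dependent rate
constant (zero while the plug is in the stomach), attenuated by a presystemic
bioavailability factor ``F``.  Disposition is a linear two-compartment model
with clearance acting on the central compartment.

Two cumulative ledgers (drug eliminated by clearance, drug lost to first-pass
metabolism) close the mass balance: at any time the four state masses plus
the two ledgers sum to the administered dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .transitions import ParameterSchedule, as_schedule

__all__ = [
    "DomainError",
    "DrugProperties",
    "ParticleFractionState",
    "Plug",
    "PKParameters",
    "SystemState",
    "current_radius",
    "diffusion_layer_thickness",
    "dissolution_rate",
    "dissolved_rate",
    "plasma_rate",
    "tissue_rate",
    "total_dissolved",
    "total_plasma_mass",
    "plasma_concentration",
    "MASS_SNAP_MG",
]

#: Solid masses below this (mg) are treated as fully dissolved; avoids
#: fractional powers of vanishing numbers at the cube-root extinction point.
MASS_SNAP_MG = 1e-12


class DomainError(ValueError):
    """An argument lies outside the model's physical domain."""


@dataclass(frozen=True)
class DrugProperties:
    """Physicochemical constants of the drug.

    Parameters
    ----------
    diffusion_coefficient
        Aqueous diffusion coefficient ``D`` (cm^2/min).
    density
        True density of the solid ``rho`` (mg/cm^3).
    solubility
        Solubility ``Cs`` (mg/mL) as a constant or a time schedule; a
        schedule is the hook for e.g. a pH program.  Individual plugs may
        override it.
    h_max
        Cap on the diffusion-layer thickness (cm).  Below the cap the layer
        thickness equals the particle radius (Hintz-Johnson rule); default
        30 um.
    """

    diffusion_coefficient: float
    density: float
    solubility: ParameterSchedule | float
    h_max: float = 30e-4

    def __post_init__(self) -> None:
        object.__setattr__(self, "solubility", as_schedule(self.solubility))
        if self.diffusion_coefficient <= 0:
            raise DomainError("diffusion_coefficient must be > 0")
        if self.density <= 0:
            raise DomainError("density must be > 0")
        if self.h_max <= 0:
            raise DomainError("h_max must be > 0")
        if self.solubility.baseline < 0 or any(
            s.v_start < 0 or s.v_end < 0 for s in self.solubility.segments
        ):
            raise DomainError("solubility must be non-negative")


@dataclass
class ParticleFractionState:
    """State of one particle-size fraction within one plug (masses in mg)."""

    r0: float  # initial particle radius (cm)
    x0: float  # initial solid mass in this plug (mg)
    xs: float = None  # type: ignore[assignment]  # current solid mass
    xd: float = 0.0  # dissolved mass in the plug
    xp: float = 0.0  # mass in the plasma compartment
    xt: float = 0.0  # mass in the tissue compartment

    def __post_init__(self) -> None:
        if self.xs is None:
            self.xs = self.x0
        if self.x0 < 0:
            raise DomainError("initial solid mass must be >= 0")
        if self.x0 > 0 and self.r0 <= 0:
            raise DomainError("particle radius must be > 0 when solid mass is present")
        for name in ("xs", "xd", "xp", "xt"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if self.xs > self.x0:
            raise DomainError("solid mass cannot exceed its initial value")

    @classmethod
    def predissolved(cls, dose: float, r0: float = 1e-4) -> "ParticleFractionState":
        """A fraction whose entire dose starts in solution (no solid)."""
        return cls(r0=r0, x0=0.0, xs=0.0, xd=dose)

    @property
    def total(self) -> float:
        return self.xs + self.xd + self.xp + self.xt


@dataclass
class Plug:
    """One independent fluid plug.

    The plug carries its fluid volume (mL, possibly time-dependent), the
    presystemic bioavailability factor ``f_bio`` in (0, 1], the absorption
    rate-constant schedule built by the transitions module, and one
    :class:`ParticleFractionState` per particle-size fraction.  ``onset`` and
    ``transition`` record the gastric-emptying timing the ka schedule was
    built from (metadata used when plugs are grouped).
    """

    index: int
    volume: ParameterSchedule | float
    f_bio: float
    ka: ParameterSchedule
    fractions: list[ParticleFractionState] = field(default_factory=list)
    solubility: ParameterSchedule | float | None = None
    onset: float | None = None
    transition: float | None = None

    def __post_init__(self) -> None:
        self.volume = as_schedule(self.volume)
        if self.solubility is not None:
            self.solubility = as_schedule(self.solubility)
        if not (0.0 < self.f_bio <= 1.0):
            raise DomainError("f_bio must lie in (0, 1]")
        if self.volume.baseline <= 0 or any(
            s.v_start <= 0 or s.v_end <= 0 for s in self.volume.segments
        ):
            raise DomainError("plug volume must be > 0 at all times")

    @property
    def dose(self) -> float:
        return sum(f.x0 + f.xd for f in self.fractions)

    def solubility_schedule(self, drug: DrugProperties) -> ParameterSchedule:
        return self.solubility if self.solubility is not None else drug.solubility


@dataclass(frozen=True)
class PKParameters:
    """Two-compartment disposition parameters.

    ``cl`` (mL/min/kg) and ``vd`` (mL/kg) are normalised to body mass ``mb``
    (kg); elimination from plasma is first-order with rate ``cl / vd``
    (units cancel to min^-1).  ``k12``/``k21`` exchange drug between the
    plasma and tissue compartments.
    """

    cl: float
    vd: float
    mb: float
    k12: float = 0.0
    k21: float = 0.0

    def __post_init__(self) -> None:
        if self.cl < 0:
            raise DomainError("clearance must be >= 0")
        if self.vd <= 0 or self.mb <= 0:
            raise DomainError("vd and mb must be > 0")
        if self.k12 < 0 or self.k21 < 0:
            raise DomainError("k12 and k21 must be >= 0")

    @property
    def ke(self) -> float:
        """First-order elimination rate constant cl/vd (min^-1)."""
        return self.cl / self.vd

    @property
    def vc(self) -> float:
        """Central-compartment volume Vd * mb (mL)."""
        return self.vd * self.mb


@dataclass
class SystemState:
    """Full state at time ``t``: per-fraction masses plus the two ledgers.

    Fractions are stored flat in a fixed order (ascending plug index, then
    fraction order within the plug); ``frac_plug`` maps each flat fraction
    slot to its plug position.  The flat layout round-trips to the state
    vector used by the integrator: ``[xs | xd | xp | xt | eliminated,
    firstpass]``.
    """

    t: float
    xs: np.ndarray
    xd: np.ndarray
    xp: np.ndarray
    xt: np.ndarray
    frac_plug: np.ndarray
    eliminated: float = 0.0
    firstpass: float = 0.0

    @classmethod
    def from_plugs(cls, plugs: Sequence[Plug], t: float = 0.0) -> "SystemState":
        xs, xd, xp, xt, owner = [], [], [], [], []
        for pos, plug in enumerate(sorted(plugs, key=lambda p: p.index)):
            for frac in plug.fractions:
                xs.append(frac.xs)
                xd.append(frac.xd)
                xp.append(frac.xp)
                xt.append(frac.xt)
                owner.append(pos)
        return cls(
            t=t,
            xs=np.asarray(xs, dtype=np.float64),
            xd=np.asarray(xd, dtype=np.float64),
            xp=np.asarray(xp, dtype=np.float64),
            xt=np.asarray(xt, dtype=np.float64),
            frac_plug=np.asarray(owner, dtype=np.int64),
        )

    @property
    def n_fractions(self) -> int:
        return self.xs.shape[0]

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [self.xs, self.xd, self.xp, self.xt, [self.eliminated, self.firstpass]]
        )

    @classmethod
    def from_vector(cls, t: float, y: np.ndarray, frac_plug: np.ndarray) -> "SystemState":
        nf = frac_plug.shape[0]
        return cls(
            t=t,
            xs=y[0:nf].copy(),
            xd=y[nf : 2 * nf].copy(),
            xp=y[2 * nf : 3 * nf].copy(),
            xt=y[3 * nf : 4 * nf].copy(),
            frac_plug=frac_plug,
            eliminated=float(y[4 * nf]),
            firstpass=float(y[4 * nf + 1]),
        )

    def total_mass(self) -> float:
        """All drug accounted for, including the two cumulative ledgers."""
        return float(
            self.xs.sum() + self.xd.sum() + self.xp.sum() + self.xt.sum()
            + self.eliminated + self.firstpass
        )


# ---------------------------------------------------------------------------
# rate laws


def current_radius(xs: float, x0: float, r0: float) -> float:
    """Particle radius (cm) under spherical shrinkage.

    ``r = r0 * (xs / x0)^(1/3)``; zero once the fraction is fully dissolved.
    """
    if xs < 0 or xs > x0:
        raise DomainError("require 0 <= xs <= x0")
    if x0 <= 0 or r0 <= 0:
        raise DomainError("require x0 > 0 and r0 > 0")
    if xs == 0.0:
        return 0.0
    return r0 * float(np.cbrt(xs / x0))


def diffusion_layer_thickness(r_current: float, h_max: float) -> float:
    """Hintz-Johnson diffusion-layer rule: ``h = min(r, h_max)``."""
    if r_current < 0:
        raise DomainError("radius must be >= 0")
    if h_max <= 0:
        raise DomainError("h_max must be > 0")
    return min(r_current, h_max)


def dissolution_rate(
    frac: ParticleFractionState,
    drug: DrugProperties,
    xd_j_total: float,
    v_j: float,
    t: float,
    *,
    sink: bool = False,
    clamp_supersaturation: bool = False,
) -> float:
    """Rate of change of solid mass ``dXs/dt`` (mg/min), normally negative.

    Noyes-Whitney for shrinking spheres::

        dXs/dt = -(3 D / (rho h r0)) * X0^(1/3) * Xs^(2/3) * (Cs - Xd_total/V)

    where the driving force uses the plug-total dissolved mass (all fractions
    share one fluid pool).  Under ``sink=True`` the bulk-concentration term
    is dropped.  A supersaturated plug (``Xd/V > Cs``) makes the rate
    positive (precipitation back onto particles), capped so the solid never
    exceeds its initial mass; ``clamp_supersaturation`` clamps it to zero
    instead.
    """
    if v_j <= 0:
        raise DomainError("plug volume must be > 0")
    xs = frac.xs
    if xs <= 0.0 or frac.x0 <= 0.0:
        return 0.0
    cs = drug.solubility(t)
    drive = cs if sink else cs - xd_j_total / v_j
    if drive == 0.0:
        return 0.0
    r = current_radius(min(xs, frac.x0), frac.x0, frac.r0)
    h = diffusion_layer_thickness(r, drug.h_max)
    if h <= 0.0:
        return 0.0
    rate = (
        -(3.0 * drug.diffusion_coefficient / (drug.density * h * frac.r0))
        * float(np.cbrt(frac.x0))
        * float(np.cbrt(xs)) ** 2
        * drive
    )
    if rate > 0.0 and (clamp_supersaturation or xs >= frac.x0):
        rate = 0.0
    return rate


def dissolved_rate(
    frac: ParticleFractionState, dissolution_rate_value: float, ka_j: float
) -> float:
    """``dXd/dt = -(dXs/dt) - ka * Xd`` (mg/min).

    Mass leaving the solid enters the dissolved pool; first-order absorption
    removes dissolved drug.
    """
    if ka_j < 0:
        raise DomainError("ka must be >= 0")
    return -dissolution_rate_value - ka_j * frac.xd


def plasma_rate(
    frac: ParticleFractionState, ka_j: float, f_j: float, pk: PKParameters
) -> float:
    """``dXp/dt = F ka Xd - (k12 + cl/Vd) Xp + k21 Xt`` (mg/min)."""
    return f_j * ka_j * frac.xd - (pk.k12 + pk.ke) * frac.xp + pk.k21 * frac.xt


def tissue_rate(frac: ParticleFractionState, pk: PKParameters) -> float:
    """``dXt/dt = k12 Xp - k21 Xt`` (mg/min)."""
    return pk.k12 * frac.xp - pk.k21 * frac.xt


def total_dissolved(plug: Plug) -> float:
    """Plug-total dissolved mass (mg); the bulk term in the driving force."""
    return sum(f.xd for f in plug.fractions)


def total_plasma_mass(state: SystemState) -> float:
    """Total plasma-compartment mass over all plugs and fractions (mg)."""
    return float(state.xp.sum())


def plasma_concentration(total_xp: float, pk: PKParameters) -> float:
    """Plasma concentration ``Cp = Xp_total / (Vd * mb)`` (mg/mL)."""
    if total_xp < 0:
        raise DomainError("plasma mass must be >= 0")
    if pk.vc <= 0:
        raise DomainError("Vd * mb must be > 0")
    return total_xp / pk.vc
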