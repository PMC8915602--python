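"""Fixed-step RK4 integration of the full multi-plug system.

The coupled mass balances for all (fraction, plug) pairs are advanced with
the classical fourth-order Runge-Kutta scheme at a fixed step (default
0.001 min).  Plugs are fully independent -- the right-hand side contains no
cross-plug terms -- and per-plug plasma contributions are summed at every
recorded time in a fixed order (ascending plug index, then fraction order),
so results are bit-reproducible.

Two engines compute identical arithmetic: a compiled kernel
(:mod:`mmplug._kernel`) used by default, and a pure-Python reference built
from the rate laws in :mod:`mmplug.model`, kept for transparency and as a
cross-check in the tests.

Numerical treatment of the cube-root extinction point: the shrinking-sphere
rate behaves like ``Xs^(1/3)`` near complete dissolution, so the last step of
a fraction's life can carry the solid slightly below zero.  That overshoot is
mass that left the solid within the step; it is folded into the dissolved
pool (keeping the ledger exact to machine precision) and the solid is set to
zero.  Excursions beyond ``instability_threshold`` abort the run instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from . import _kernel
from .model import (
    MASS_SNAP_MG,
    DrugProperties,
    ParticleFractionState,
    PKParameters,
    Plug,
    SystemState,
    dissolution_rate,
    dissolved_rate,
    plasma_rate,
    tissue_rate,
)
from .transitions import ParameterSchedule

__all__ = [
    "IntegratorConfig",
    "SimulationResult",
    "MassBalanceReport",
    "NumericalError",
    "InstabilityError",
    "assemble_rhs",
    "rk4_step",
    "simulate",
    "mass_balance",
]


class NumericalError(RuntimeError):
    """A non-finite derivative or state was produced at time ``t``."""

    def __init__(self, message: str, t: float):
        super().__init__(f"{message} (t = {t:.6g} min)")
        self.t = t


class InstabilityError(NumericalError):
    """A state component fell below the negative-mass tolerance."""


@dataclass(frozen=True)
class IntegratorConfig:
    """Integration controls.

    ``step_size`` is the RK4 step in minutes; ``output_interval`` thins the
    recorded output (storing every 0.001-min step over hours of simulated
    time is wasteful).  ``transition_mode`` selects smooth sigmoidal or
    abrupt ka transitions; ``sink`` forces sink-condition dissolution
    (bulk-concentration term dropped); ``instability_threshold`` is the
    largest tolerated negative excursion of any mass component (mg).
    """

    step_size: float = 0.001
    duration: float = 720.0
    output_interval: float = 0.5
    record_per_plug: bool = True
    transition_mode: str = "smooth"
    sink: bool = False
    clamp_supersaturation: bool = False
    engine: str = "compiled"
    instability_threshold: float = 1e-4

    def __post_init__(self) -> None:
        if self.step_size <= 0:
            raise ValueError("step_size must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.output_interval < self.step_size:
            raise ValueError("output_interval must be >= step_size")
        if self.transition_mode not in ("smooth", "step"):
            raise ValueError("transition_mode must be 'smooth' or 'step'")
        if self.engine not in ("compiled", "python"):
            raise ValueError("engine must be 'compiled' or 'python'")


@dataclass
class StateLayout:
    """Mapping between the flat state vector and (fraction, plug) structure."""

    frac_plug: np.ndarray  # fraction slot -> plug position (0-based)
    r0: np.ndarray
    x0: np.ndarray
    n_plugs: int

    @property
    def n_fractions(self) -> int:
        return self.frac_plug.shape[0]

    @property
    def n_states(self) -> int:
        return 4 * self.n_fractions + 2


@dataclass
class SimulationResult:
    """Recorded time series of a run plus provenance.

    Concentrations are mg/mL; per-plug series are stacked ``(n_plugs,
    n_times)``.  ``cp_total`` is by construction the fixed-order sum of the
    per-plug series at every recorded time.
    """

    times: np.ndarray
    cp_total: np.ndarray
    cp_per_plug: np.ndarray
    xs_per_plug: np.ndarray
    xd_per_plug: np.ndarray
    xp_per_plug: np.ndarray
    xt_per_plug: np.ndarray
    eliminated: np.ndarray
    firstpass: np.ndarray
    total_dose: float
    scenario: object
    config: IntegratorConfig
    warnings: list[str] = field(default_factory=list)
    max_negative_excursion: float = 0.0

    @property
    def n_plugs(self) -> int:
        return self.cp_per_plug.shape[0]


@dataclass(frozen=True)
class MassBalanceReport:
    """Dose minus everything tracked, at each recorded time."""

    times: np.ndarray
    residuals: np.ndarray
    max_abs_residual: float
    total_dose: float


def assemble_rhs(
    plugs: Sequence[Plug],
    drug: DrugProperties,
    pk: PKParameters,
    *,
    transition_mode: str = "smooth",
    sink: bool = False,
    clamp_supersaturation: bool = False,
) -> tuple[Callable[[np.ndarray, float], np.ndarray], StateLayout]:
    """Build the derivative function for the coupled system.

    Returns ``(rhs, layout)`` where ``rhs(y, t)`` evaluates, for every
    (fraction, plug) pair, the solid/dissolved/plasma/tissue mass balances
    using the rate laws of :mod:`mmplug.model`, plus the two ledger
    derivatives ``d(eliminated)/dt = (cl/Vd) * sum(Xp)`` and
    ``d(firstpass)/dt = sum((1 - F) ka Xd)``.  No cross-plug coupling exists
    beyond each plug's own shared dissolved pool.
    """
    ordered = sorted(plugs, key=lambda p: p.index)
    if not ordered or not any(p.fractions for p in ordered):
        raise ValueError("need at least one plug with at least one fraction")
    owner: list[int] = []
    r0: list[float] = []
    x0: list[float] = []
    for pos, plug in enumerate(ordered):
        for frac in plug.fractions:
            owner.append(pos)
            r0.append(frac.r0)
            x0.append(frac.x0)
    layout = StateLayout(
        frac_plug=np.asarray(owner, dtype=np.int64),
        r0=np.asarray(r0, dtype=np.float64),
        x0=np.asarray(x0, dtype=np.float64),
        n_plugs=len(ordered),
    )
    nf = layout.n_fractions
    # per-plug drug view so a plug-level solubility override reaches Eq. 1
    plug_drug = [
        drug if p.solubility is None else replace_solubility(drug, p.solubility_schedule(drug))
        for p in ordered
    ]
    scratch = ParticleFractionState.__new__(ParticleFractionState)

    def rhs(y: np.ndarray, t: float) -> np.ndarray:
        if y.shape[0] != layout.n_states:
            raise ValueError(
                f"state vector has {y.shape[0]} entries, layout expects {layout.n_states}"
            )
        dy = np.empty_like(y)
        ka_p = [p.ka.evaluate(t, mode=transition_mode) for p in ordered]
        v_p = [p.volume(t) for p in ordered]
        xd_tot = np.zeros(layout.n_plugs)
        for f in range(nf):
            xd = y[nf + f]
            if xd > 0.0:
                xd_tot[owner[f]] += xd
        elim = 0.0
        fp = 0.0
        for f in range(nf):
            p = owner[f]
            scratch.r0 = r0[f]
            scratch.x0 = x0[f]
            scratch.xs = y[f]
            scratch.xd = y[nf + f]
            scratch.xp = y[2 * nf + f]
            scratch.xt = y[3 * nf + f]
            rate = dissolution_rate(
                scratch, plug_drug[p], float(xd_tot[p]), v_p[p], t,
                sink=sink, clamp_supersaturation=clamp_supersaturation,
            ) if scratch.xs > 0.0 else 0.0
            dy[f] = rate
            dy[nf + f] = dissolved_rate(scratch, rate, ka_p[p])
            dy[2 * nf + f] = plasma_rate(scratch, ka_p[p], ordered[p].f_bio, pk)
            dy[3 * nf + f] = tissue_rate(scratch, pk)
            elim += pk.ke * scratch.xp
            fp += (1.0 - ordered[p].f_bio) * ka_p[p] * scratch.xd
        dy[4 * nf] = elim
        dy[4 * nf + 1] = fp
        return dy

    return rhs, layout


def replace_solubility(drug: DrugProperties, sched: ParameterSchedule) -> DrugProperties:
    return DrugProperties(
        diffusion_coefficient=drug.diffusion_coefficient,
        density=drug.density,
        solubility=sched,
        h_max=drug.h_max,
    )


def rk4_step(y, t: float, dt: float, rhs, clamp_threshold: float | None = 1e-9):
    """One classical RK4 update: stages at t, t+dt/2 (twice), t+dt, 1:2:2:1.

    ``clamp_threshold`` (mg) controls the generic negativity guard: tiny
    negative components are clamped to zero, larger ones raise
    :class:`InstabilityError`.  Pass ``None`` to skip the guard (the driving
    loop in :func:`simulate` applies its own mass-conserving fix-up).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    k1 = rhs(y, t)
    k2 = rhs(y + 0.5 * dt * k1, t + 0.5 * dt)
    k3 = rhs(y + 0.5 * dt * k2, t + 0.5 * dt)
    k4 = rhs(y + dt * k3, t + dt)
    y_new = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    if np.isscalar(y_new) or isinstance(y_new, float):
        if not math.isfinite(y_new):
            raise NumericalError("non-finite state after RK4 step", t + dt)
        if clamp_threshold is not None and y_new < 0:
            if y_new < -clamp_threshold:
                raise InstabilityError("state below clamp threshold", t + dt)
            y_new = 0.0
        return y_new
    if not np.all(np.isfinite(y_new)):
        raise NumericalError("non-finite state after RK4 step", t + dt)
    if clamp_threshold is not None:
        neg = y_new < 0
        if np.any(y_new < -clamp_threshold):
            raise InstabilityError("state below clamp threshold", t + dt)
        y_new[neg] = 0.0
    return y_new


def _steps_plan(config: IntegratorConfig) -> tuple[int, float, int]:
    dt = config.step_size
    n_full = int(math.floor(config.duration / dt + 1e-9))
    rem = config.duration - n_full * dt
    dt_last = rem if rem > 1e-9 * max(1.0, config.duration) else 0.0
    record_every = max(1, int(round(config.output_interval / dt)))
    return n_full, dt_last, record_every


def _postfix(y: np.ndarray, layout: StateLayout, instab: float, t: float) -> float:
    """Mirror of the kernel's post-step fix-up; returns worst negative Xs."""
    nf = layout.n_fractions
    max_neg = 0.0
    for f in range(nf):
        xs = y[f]
        if xs < _kernel.SNAP:
            if xs < -instab:
                raise InstabilityError("solid mass below instability threshold", t)
            if xs != 0.0:
                max_neg = max(max_neg, -xs)
                y[nf + f] += xs
                y[f] = 0.0
        elif xs > layout.x0[f]:
            y[nf + f] += xs - layout.x0[f]
            y[f] = layout.x0[f]
        for blk in range(1, 4):
            v = y[blk * nf + f]
            if v < 0.0:
                if v < -instab:
                    raise InstabilityError("mass below instability threshold", t)
                y[blk * nf + f] = 0.0
    return max_neg


def _pack_schedules(scheds: Sequence[ParameterSchedule]):
    bases = np.array([s.to_arrays()[0] for s in scheds], dtype=np.float64)
    tables = [s.to_arrays()[1] for s in scheds]
    off = np.zeros(len(scheds) + 1, dtype=np.int64)
    for i, tab in enumerate(tables):
        off[i + 1] = off[i] + tab.shape[0]
    segs = np.concatenate(tables, axis=0) if tables else np.zeros((0, 4))
    if segs.size == 0:
        segs = np.zeros((0, 4), dtype=np.float64)
    return bases, segs, off


def simulate(scenario, config: IntegratorConfig | None = None) -> SimulationResult:
    """Run a scenario from t = 0 to ``config.duration``.

    Records per-plug plasma concentrations ``Cp_j = sum_i Xp_ij / (Vd mb)``
    and their fixed-order total at every ``output_interval``, along with
    per-plug solid/dissolved/tissue masses and the two cumulative ledgers.
    The final time point is always included, via a shortened last step if the
    duration is not a step multiple (noted in ``result.warnings``).
    """
    if config is None:
        config = getattr(scenario, "integrator", None) or IntegratorConfig()
    plugs = sorted(scenario.plugs, key=lambda p: p.index)
    drug: DrugProperties = scenario.drug
    pk: PKParameters = scenario.pk

    _, layout = assemble_rhs(plugs, drug, pk)  # validation + layout
    state0 = SystemState.from_plugs(plugs)
    y0 = state0.to_vector()
    n_steps, dt_last, record_every = _steps_plan(config)
    run_warnings: list[str] = []
    if dt_last > 0.0:
        run_warnings.append(
            f"duration {config.duration} min is not a multiple of the step size; "
            f"final partial step of {dt_last:.3g} min taken"
        )

    ka_scheds = [p.ka for p in plugs]
    cs_scheds = [p.solubility_schedule(drug) for p in plugs]
    v_scheds = [p.volume for p in plugs]
    f_plug = np.array([p.f_bio for p in plugs], dtype=np.float64)
    ka_base, ka_segs, ka_off = _pack_schedules(ka_scheds)
    cs_base, cs_segs, cs_off = _pack_schedules(cs_scheds)
    v_base, v_segs, v_off = _pack_schedules(v_scheds)

    if config.engine == "compiled":
        (status, t_fail, max_neg, irec, times, xs_r, xd_r, xp_r, xt_r,
         el_r, fp_r, _yfin) = _kernel.run_kernel(
            y0, layout.frac_plug, layout.r0, layout.x0,
            drug.diffusion_coefficient, drug.density, drug.h_max,
            pk.ke, pk.k12, pk.k21, f_plug,
            ka_base, ka_segs, ka_off, config.transition_mode == "smooth",
            cs_base, cs_segs, cs_off,
            v_base, v_segs, v_off,
            config.sink, config.clamp_supersaturation,
            config.step_size, n_steps, dt_last, record_every,
            config.instability_threshold,
        )
        if status == 1:
            raise NumericalError("non-finite derivative in compiled kernel", t_fail)
        if status == 2:
            raise InstabilityError("mass below instability threshold", t_fail)
        times = times[:irec]
        xs_r, xd_r, xp_r, xt_r = (a[:irec] for a in (xs_r, xd_r, xp_r, xt_r))
        el_r, fp_r = el_r[:irec], fp_r[:irec]
    else:
        rhs, _ = assemble_rhs(
            plugs, drug, pk,
            transition_mode=config.transition_mode,
            sink=config.sink,
            clamp_supersaturation=config.clamp_supersaturation,
        )
        times_l, recs = [], []
        y = y0.copy()
        max_neg = 0.0
        nf = layout.n_fractions
        npg = layout.n_plugs

        def _snapshot(t):
            xs_s = np.zeros(npg)
            xd_s = np.zeros(npg)
            xp_s = np.zeros(npg)
            xt_s = np.zeros(npg)
            np.add.at(xs_s, layout.frac_plug, y[0:nf])
            np.add.at(xd_s, layout.frac_plug, y[nf : 2 * nf])
            np.add.at(xp_s, layout.frac_plug, y[2 * nf : 3 * nf])
            np.add.at(xt_s, layout.frac_plug, y[3 * nf : 4 * nf])
            times_l.append(t)
            recs.append((xs_s, xd_s, xp_s, xt_s, y[4 * nf], y[4 * nf + 1]))

        _snapshot(0.0)
        n_total = n_steps + (1 if dt_last > 0 else 0)
        for s in range(n_total):
            h = config.step_size if s < n_steps else dt_last
            t = s * config.step_size if s < n_steps else n_steps * config.step_size
            y = rk4_step(y, t, h, rhs, clamp_threshold=None)
            max_neg = max(max_neg, _postfix(y, layout, config.instability_threshold, t + h))
            if (s + 1) % record_every == 0 or s == n_total - 1:
                _snapshot(t + h)
        times = np.asarray(times_l)
        xs_r = np.stack([r[0] for r in recs])
        xd_r = np.stack([r[1] for r in recs])
        xp_r = np.stack([r[2] for r in recs])
        xt_r = np.stack([r[3] for r in recs])
        el_r = np.asarray([r[4] for r in recs])
        fp_r = np.asarray([r[5] for r in recs])

    cp_per_plug = (xp_r / pk.vc).T.copy()  # (n_plugs, n_times)
    cp_total = cp_per_plug.sum(axis=0)
    total_dose = float(layout.x0.sum() + state0.xd.sum() + state0.xp.sum() + state0.xt.sum())
    return SimulationResult(
        times=times,
        cp_total=cp_total,
        cp_per_plug=cp_per_plug,
        xs_per_plug=xs_r.T.copy(),
        xd_per_plug=xd_r.T.copy(),
        xp_per_plug=xp_r.T.copy(),
        xt_per_plug=xt_r.T.copy(),
        eliminated=el_r,
        firstpass=fp_r,
        total_dose=total_dose,
        scenario=scenario,
        config=config,
        warnings=run_warnings,
        max_negative_excursion=float(max_neg),
    )


def mass_balance(result: SimulationResult) -> MassBalanceReport:
    """Ledger check: dose minus all tracked masses at each recorded time."""
    tracked = (
        result.xs_per_plug.sum(axis=0)
        + result.xd_per_plug.sum(axis=0)
        + result.xp_per_plug.sum(axis=0)
        + result.xt_per_plug.sum(axis=0)
        + result.eliminated
        + result.firstpass
    )
    residuals = result.total_dose - tracked
    return MassBalanceReport(
        times=result.times,
        residuals=residuals,
        max_abs_residual=float(np.abs(residuals).max()),
        total_dose=result.total_dose,
    )
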