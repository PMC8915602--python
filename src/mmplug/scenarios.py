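"""Scenario construction: presets, config files, grouping, stochastic emptying.

A :class:`Scenario` bundles the drug, the disposition parameters and the
plug layout (per-plug dose, volume, particle-size fractions and gastric
emptying schedule).  The bundled presets reproduce the published
demonstration runs of the model: three 80-mL plugs of a nifedipine-like drug
emptying at 0/15/30 min with 1-um or 10-um particles, a variant with the
first plug empty, a single-plug reference, and a seven-plug split.

The stochastic generator draws plug counts, emptying onsets, volumes and
dose allocations from a seeded :class:`EmptyingDistribution`, for Monte-Carlo
exploration of how gastric-emptying variability propagates to Cmax/Tmax.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .integrator import IntegratorConfig
from .model import DomainError, DrugProperties, ParticleFractionState, PKParameters, Plug
from .transitions import ParameterSchedule, TransitionSegment

__all__ = [
    "Scenario",
    "ScenarioError",
    "EmptyingDistribution",
    "REFERENCE_DRUG",
    "REFERENCE_PK",
    "KA_INTESTINE",
    "TRANSITION_MIN",
    "build_plug",
    "preset",
    "PRESET_NAMES",
    "load_scenario",
    "scenario_to_dict",
    "build_size_fractions",
    "group_plugs",
    "sample_emptying",
]

SCHEMA_VERSION = 1


class ScenarioError(ValueError):
    """Configuration error; the message names the offending key."""


# Reference parameter set (nifedipine-like hypothetical drug):
# solubility 0.01 mg/mL, density 1.3 g/cm^3, D 3e-4 cm^2/min; F 0.5,
# cl 4 mL/min/kg, Vd 600 mL/kg, mb 70 kg, k12 0.03 / k21 0.01 min^-1.
REFERENCE_DRUG = DrugProperties(
    diffusion_coefficient=3e-4, density=1300.0, solubility=0.01, h_max=30e-4
)
REFERENCE_PK = PKParameters(cl=4.0, vd=600.0, mb=70.0, k12=0.03, k21=0.01)
#: absorption rate constant in the small intestine (min^-1)
KA_INTESTINE = 0.07
#: default gastric-emptying transition duration (min)
TRANSITION_MIN = 1.0
TOTAL_VOLUME_ML = 240.0
TOTAL_DOSE_MG = 2.4
F_BIO = 0.5


@dataclass
class Scenario:
    """A fully specified simulation input."""

    drug: DrugProperties
    pk: PKParameters
    plugs: list[Plug]
    label: str = ""
    seed: int | None = None
    integrator: IntegratorConfig | None = None

    def __post_init__(self) -> None:
        if not self.plugs:
            raise ScenarioError("plugs: a scenario needs at least one plug")
        seen = {p.index for p in self.plugs}
        if len(seen) != len(self.plugs):
            raise ScenarioError("plugs: plug indices must be unique")

    @property
    def total_dose(self) -> float:
        return sum(p.dose for p in self.plugs)

    @property
    def total_volume(self) -> float:
        return sum(p.volume(0.0) for p in self.plugs)


def build_plug(
    index: int,
    *,
    volume: float,
    dose: float,
    onset: float | None,
    transition: float = TRANSITION_MIN,
    radius: float = 1e-4,
    ka_si: float = KA_INTESTINE,
    f_bio: float = F_BIO,
    predissolved: bool = False,
    fractions: list[ParticleFractionState] | None = None,
) -> Plug:
    """Assemble one plug with its gastric-emptying ka schedule.

    ``onset=None`` means the plug is already in the intestine (constant ka),
    otherwise ka is 0 in the stomach and transitions sigmoidally to
    ``ka_si`` over [onset, onset + transition].
    """
    if onset is None:
        ka = ParameterSchedule.constant(ka_si)
    else:
        if onset < 0:
            raise ScenarioError("onset_min: emptying onset must be >= 0")
        ka = ParameterSchedule(
            baseline=0.0,
            segments=(TransitionSegment(onset, onset + transition, 0.0, ka_si),),
        )
    if fractions is None:
        if predissolved:
            fractions = [ParticleFractionState.predissolved(dose, r0=radius)]
        elif dose > 0:
            fractions = [ParticleFractionState(r0=radius, x0=dose)]
        else:
            fractions = [ParticleFractionState(r0=radius, x0=0.0)]
    return Plug(
        index=index,
        volume=volume,
        f_bio=f_bio,
        ka=ka,
        fractions=fractions,
        onset=onset,
        transition=transition if onset is not None else None,
    )


def _even_plugs(
    n: int, radius: float, onsets: Sequence[float],
    volume: float | None = None, dose: float | None = None,
) -> list[Plug]:
    # per-plug values as printed (0.8 mg / 80 mL) where available, to avoid
    # one-ULP drift from dividing the totals
    v = TOTAL_VOLUME_ML / n if volume is None else volume
    d = TOTAL_DOSE_MG / n if dose is None else dose
    return [
        build_plug(j + 1, volume=v, dose=d, onset=onsets[j], radius=radius)
        for j in range(n)
    ]


def _preset_figure2() -> Scenario:
    return Scenario(
        drug=REFERENCE_DRUG, pk=REFERENCE_PK,
        plugs=_even_plugs(3, 1e-4, (0.0, 15.0, 30.0), volume=80.0, dose=0.8),
        label="figure2",
    )


def _preset_figure3() -> Scenario:
    return Scenario(
        drug=REFERENCE_DRUG, pk=REFERENCE_PK,
        plugs=_even_plugs(3, 10e-4, (0.0, 15.0, 30.0), volume=80.0, dose=0.8),
        label="figure3",
    )


def _preset_figure4() -> Scenario:
    doses = (0.0, 1.2, 1.2)
    plugs = [
        build_plug(j + 1, volume=80.0, dose=doses[j], onset=(0.0, 15.0, 30.0)[j], radius=1e-4)
        for j in range(3)
    ]
    return Scenario(drug=REFERENCE_DRUG, pk=REFERENCE_PK, plugs=plugs, label="figure4")


def _preset_figure5_single() -> Scenario:
    plugs = [build_plug(1, volume=240.0, dose=2.4, onset=0.0, radius=1e-4)]
    return Scenario(drug=REFERENCE_DRUG, pk=REFERENCE_PK, plugs=plugs, label="figure5_single")


def _preset_figure6_seven() -> Scenario:
    onsets = tuple(5.0 * j for j in range(7))  # evenly spanning 0-30 min
    return Scenario(
        drug=REFERENCE_DRUG, pk=REFERENCE_PK,
        plugs=_even_plugs(7, 1e-4, onsets),
        label="figure6_seven",
    )


_PRESETS = {
    "figure2": _preset_figure2,
    "figure3": _preset_figure3,
    "figure4": _preset_figure4,
    "figure5_single": _preset_figure5_single,
    "figure6_seven": _preset_figure6_seven,
}
PRESET_NAMES = tuple(sorted(_PRESETS))


def preset(name: str) -> Scenario:
    """One of the bundled demonstration scenarios (see module docstring)."""
    try:
        factory = _PRESETS[name]
    except KeyError:
        raise ScenarioError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        ) from None
    return factory()


# ---------------------------------------------------------------------------
# config files

_DRUG_KEYS = {
    "solubility_mg_per_ml", "density_mg_per_cm3",
    "diffusion_coefficient_cm2_per_min", "h_max_cm",
}
_PK_KEYS = {
    "clearance_ml_per_min_per_kg", "volume_of_distribution_ml_per_kg",
    "body_mass_kg", "k12_per_min", "k21_per_min",
}
_ABS_KEYS = {"ka_intestine_per_min", "bioavailability_factor"}
_TOTAL_KEYS = {"volume_ml", "dose_mg"}
_INT_KEYS = {"step_min", "duration_min", "output_interval_min"}
_PLUG_KEYS = {
    "onset_min", "transition_min", "volume_ml", "dose_mg",
    "particle_radius_um", "size_distribution", "n_size_groups", "predissolved",
}
_OPTION_KEYS = {"particle_size_interpretation", "clamp_supersaturation"}
_TOP_KEYS = {
    "schema_version", "label", "drug", "pk", "absorption", "totals",
    "integrator", "plugs", "options", "stochastic", "seed",
}
_STOCH_KEYS = {
    "n_plugs", "n_plugs_min", "n_plugs_max", "onset_min", "onset_max",
    "fixed_onsets", "volume_mode", "volume_alpha", "dose_mode", "dose_alpha",
    "transition_min", "particle_radius_um",
}


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ScenarioError(f"{where}: unknown key(s) {sorted(unknown)}")


def _get(section: dict, key: str, where: str, default=None, required=False):
    if key not in section:
        if required:
            raise ScenarioError(f"{where}: missing required key '{key}'")
        return default
    return section[key]


def _positive(value, key: str):
    if not isinstance(value, (int, float)) or value <= 0:
        raise ScenarioError(f"{key}: must be a positive number, got {value!r}")
    return float(value)


def load_scenario(path: str | Path) -> Scenario:
    """Parse and validate a YAML scenario file (schema in the README).

    Unknown keys are rejected; declared totals must match the plug list.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ScenarioError(f"{path}: top level must be a mapping")
    _check_keys(raw, _TOP_KEYS, "top level")
    if raw.get("schema_version", SCHEMA_VERSION) != SCHEMA_VERSION:
        raise ScenarioError(f"schema_version: expected {SCHEMA_VERSION}")

    dsec = _get(raw, "drug", "top level", default={}) or {}
    _check_keys(dsec, _DRUG_KEYS, "drug")
    drug = DrugProperties(
        diffusion_coefficient=_positive(
            _get(dsec, "diffusion_coefficient_cm2_per_min", "drug",
                 default=REFERENCE_DRUG.diffusion_coefficient),
            "drug.diffusion_coefficient_cm2_per_min"),
        density=_positive(
            _get(dsec, "density_mg_per_cm3", "drug", default=REFERENCE_DRUG.density),
            "drug.density_mg_per_cm3"),
        solubility=_positive(
            _get(dsec, "solubility_mg_per_ml", "drug",
                 default=REFERENCE_DRUG.solubility.baseline),
            "drug.solubility_mg_per_ml"),
        h_max=_positive(
            _get(dsec, "h_max_cm", "drug", default=REFERENCE_DRUG.h_max),
            "drug.h_max_cm"),
    )

    psec = _get(raw, "pk", "top level", default={}) or {}
    _check_keys(psec, _PK_KEYS, "pk")
    try:
        pk = PKParameters(
            cl=float(_get(psec, "clearance_ml_per_min_per_kg", "pk", default=REFERENCE_PK.cl)),
            vd=float(_get(psec, "volume_of_distribution_ml_per_kg", "pk", default=REFERENCE_PK.vd)),
            mb=float(_get(psec, "body_mass_kg", "pk", default=REFERENCE_PK.mb)),
            k12=float(_get(psec, "k12_per_min", "pk", default=REFERENCE_PK.k12)),
            k21=float(_get(psec, "k21_per_min", "pk", default=REFERENCE_PK.k21)),
        )
    except DomainError as exc:
        raise ScenarioError(f"pk: {exc}") from exc

    asec = _get(raw, "absorption", "top level", default={}) or {}
    _check_keys(asec, _ABS_KEYS, "absorption")
    ka_si = float(_get(asec, "ka_intestine_per_min", "absorption", default=KA_INTESTINE))
    f_bio = float(_get(asec, "bioavailability_factor", "absorption", default=F_BIO))
    if ka_si < 0:
        raise ScenarioError("absorption.ka_intestine_per_min: must be >= 0")
    if not (0 < f_bio <= 1):
        raise ScenarioError("absorption.bioavailability_factor: must lie in (0, 1]")

    osec = _get(raw, "options", "top level", default={}) or {}
    _check_keys(osec, _OPTION_KEYS, "options")
    size_interp = _get(osec, "particle_size_interpretation", "options", default="radius")
    if size_interp not in ("radius", "diameter"):
        raise ScenarioError(
            "options.particle_size_interpretation: must be 'radius' or 'diameter'"
        )
    size_factor = 1.0 if size_interp == "radius" else 0.5

    isec = _get(raw, "integrator", "top level", default=None)
    integrator = None
    if isec:
        _check_keys(isec, _INT_KEYS, "integrator")
        try:
            integrator = IntegratorConfig(
                step_size=float(_get(isec, "step_min", "integrator", default=0.001)),
                duration=float(_get(isec, "duration_min", "integrator", default=720.0)),
                output_interval=float(_get(isec, "output_interval_min", "integrator", default=0.5)),
                clamp_supersaturation=bool(
                    _get(osec, "clamp_supersaturation", "options", default=False)
                ),
            )
        except ValueError as exc:
            raise ScenarioError(f"integrator: {exc}") from exc

    plug_list = _get(raw, "plugs", "top level", required=True)
    if not isinstance(plug_list, list) or not plug_list:
        raise ScenarioError("plugs: must be a non-empty list")
    plugs: list[Plug] = []
    for j, pd in enumerate(plug_list, start=1):
        where = f"plugs[{j}]"
        if not isinstance(pd, dict):
            raise ScenarioError(f"{where}: must be a mapping")
        _check_keys(pd, _PLUG_KEYS, where)
        volume = _positive(_get(pd, "volume_ml", where, required=True), f"{where}.volume_ml")
        dose = _get(pd, "dose_mg", where, required=True)
        if not isinstance(dose, (int, float)) or dose < 0:
            raise ScenarioError(f"{where}.dose_mg: must be a non-negative number")
        onset = _get(pd, "onset_min", where, default=None)
        if onset is not None:
            onset = float(onset)
        transition = float(_get(pd, "transition_min", where, default=TRANSITION_MIN))
        predis = bool(_get(pd, "predissolved", where, default=False))
        fractions = None
        if "size_distribution" in pd:
            dist = [
                (size_factor * float(row["radius_um"]) * 1e-4, float(row["mass_fraction"]))
                for row in pd["size_distribution"]
            ]
            n_groups = int(_get(pd, "n_size_groups", where, default=len(dist)))
            fractions = build_size_fractions(dist, float(dose), n_groups)
            radius = 1e-4
        else:
            radius_um = _positive(
                _get(pd, "particle_radius_um", where, default=1.0),
                f"{where}.particle_radius_um")
            radius = size_factor * radius_um * 1e-4
        try:
            plugs.append(build_plug(
                j, volume=volume, dose=float(dose), onset=onset,
                transition=transition, radius=radius, ka_si=ka_si,
                f_bio=f_bio, predissolved=predis, fractions=fractions,
            ))
        except DomainError as exc:
            raise ScenarioError(f"{where}: {exc}") from exc

    tsec = _get(raw, "totals", "top level", default=None)
    if tsec:
        _check_keys(tsec, _TOTAL_KEYS, "totals")
        tv = _get(tsec, "volume_ml", "totals", default=None)
        td = _get(tsec, "dose_mg", "totals", default=None)
        got_v = sum(p.volume(0.0) for p in plugs)
        got_d = sum(p.dose for p in plugs)
        if tv is not None and abs(got_v - float(tv)) > 1e-9 * max(1.0, float(tv)):
            raise ScenarioError(
                f"totals.volume_ml: declared {tv} mL but plug volumes sum to {got_v} mL"
            )
        if td is not None and abs(got_d - float(td)) > 1e-9 * max(1.0, float(td)):
            raise ScenarioError(
                f"totals.dose_mg: declared {td} mg but plug doses sum to {got_d} mg"
            )

    return Scenario(
        drug=drug, pk=pk, plugs=plugs,
        label=str(raw.get("label", path.stem)),
        seed=raw.get("seed"),
        integrator=integrator,
    )


def scenario_to_dict(scenario: Scenario) -> dict:
    """JSON-serialisable echo of a scenario (used in result sidecars)."""
    return {
        "schema_version": SCHEMA_VERSION,
        "label": scenario.label,
        "seed": scenario.seed,
        "drug": {
            "solubility_mg_per_ml": scenario.drug.solubility.baseline,
            "density_mg_per_cm3": scenario.drug.density,
            "diffusion_coefficient_cm2_per_min": scenario.drug.diffusion_coefficient,
            "h_max_cm": scenario.drug.h_max,
        },
        "pk": {
            "clearance_ml_per_min_per_kg": scenario.pk.cl,
            "volume_of_distribution_ml_per_kg": scenario.pk.vd,
            "body_mass_kg": scenario.pk.mb,
            "k12_per_min": scenario.pk.k12,
            "k21_per_min": scenario.pk.k21,
        },
        "plugs": [
            {
                "index": p.index,
                "onset_min": p.onset,
                "transition_min": p.transition,
                "volume_ml": p.volume(0.0),
                "dose_mg": p.dose,
                "f_bio": p.f_bio,
                "ka_final_per_min": p.ka.final_value,
                "fractions": [
                    {"r0_cm": f.r0, "x0_mg": f.x0, "xd0_mg": f.xd}
                    for f in p.fractions
                ],
            }
            for p in sorted(scenario.plugs, key=lambda p: p.index)
        ],
    }


# ---------------------------------------------------------------------------
# polydisperse size grouping and plug grouping


def build_size_fractions(
    size_distribution: Sequence[tuple[float, float]],
    dose: float,
    n_groups: int,
) -> list[ParticleFractionState]:
    """Group a discrete particle-size distribution into representative bins.

    ``size_distribution`` is a list of ``(radius_cm, mass_fraction)`` points
    with mass fractions summing to one.  Points are sorted by radius and
    split into ``n_groups`` contiguous bins of roughly equal mass; each bin
    is represented by a single fraction at the bin's mass-weighted mean
    radius.  Bin masses sum to ``dose`` exactly (the final bin absorbs the
    rounding remainder).
    """
    if not size_distribution:
        raise ScenarioError("size_distribution: must not be empty")
    if n_groups < 1:
        raise ScenarioError("n_size_groups: must be >= 1")
    pts = sorted((float(r), float(m)) for r, m in size_distribution)
    total_frac = sum(m for _, m in pts)
    if abs(total_frac - 1.0) > 1e-9:
        raise ScenarioError(
            f"size_distribution: mass fractions sum to {total_frac}, expected 1"
        )
    n_groups = min(n_groups, len(pts))
    bins: list[list[tuple[float, float]]] = [[] for _ in range(n_groups)]
    cum = 0.0
    g = 0
    for k, (r, m) in enumerate(pts):
        # advance once the current bin has met its equal-mass target, or when
        # exactly enough points remain to populate the remaining bins
        if bins[g] and g < n_groups - 1 and (
            cum >= (g + 1) / n_groups - 1e-12 or len(pts) - k <= n_groups - g - 1
        ):
            g += 1
        bins[g].append((r, m))
        cum += m
    bins = [b for b in bins if b]
    fracs: list[ParticleFractionState] = []
    assigned = 0.0
    for i, b in enumerate(bins):
        mass_frac = sum(m for _, m in b)
        r_rep = sum(r * m for r, m in b) / mass_frac if mass_frac > 0 else b[0][0]
        if i == len(bins) - 1:
            x0 = dose - assigned  # largest-remainder correction
        else:
            x0 = dose * mass_frac
            assigned += x0
        fracs.append(ParticleFractionState(r0=r_rep, x0=x0))
    return fracs


def group_plugs(plugs: Sequence[Plug], window: float) -> list[Plug]:
    """Merge plugs whose emptying onsets fall in the same time window.

    Windows are ``[k*window, (k+1)*window)``.  Merged plugs pool their
    volumes and per-radius doses; the merged onset is the dose-weighted mean
    onset (volume-weighted when the window carries no drug), preserving the
    timing centroid of the drug mass.  A window of ~0 is the identity.
    """
    if window <= 0:
        raise ScenarioError("window: must be > 0")
    groups: dict[int, list[Plug]] = {}
    for p in plugs:
        onset = p.onset if p.onset is not None else 0.0
        groups.setdefault(int(math.floor(onset / window)), []).append(p)
    merged: list[Plug] = []
    for idx, key in enumerate(sorted(groups), start=1):
        members = groups[key]
        if len(members) == 1:
            p = members[0]
            merged.append(build_plug(
                idx,
                volume=p.volume(0.0), dose=0.0, onset=p.onset,
                transition=p.transition if p.transition is not None else TRANSITION_MIN,
                ka_si=p.ka.final_value, f_bio=p.f_bio,
                fractions=[ParticleFractionState(r0=f.r0, x0=f.x0, xs=f.xs, xd=f.xd)
                           for f in p.fractions],
            ))
            continue
        volume = sum(p.volume(0.0) for p in members)
        doses = [p.dose for p in members]
        onsets = [p.onset if p.onset is not None else 0.0 for p in members]
        total_d = sum(doses)
        if total_d > 0:
            onset = sum(o * d for o, d in zip(onsets, doses)) / total_d
        else:
            vols = [p.volume(0.0) for p in members]
            onset = sum(o * v for o, v in zip(onsets, vols)) / sum(vols)
        transition = members[0].transition or TRANSITION_MIN
        by_radius: dict[float, list[ParticleFractionState]] = {}
        for p in members:
            for f in p.fractions:
                by_radius.setdefault(f.r0, []).append(f)
        fractions = [
            ParticleFractionState(
                r0=r,
                x0=sum(f.x0 for f in fl),
                xs=sum(f.xs for f in fl),
                xd=sum(f.xd for f in fl),
            )
            for r, fl in sorted(by_radius.items())
        ]
        merged.append(build_plug(
            idx, volume=volume, dose=0.0, onset=onset, transition=transition,
            ka_si=members[0].ka.final_value, f_bio=members[0].f_bio,
            fractions=fractions,
        ))
    return merged


# ---------------------------------------------------------------------------
# stochastic gastric emptying


@dataclass(frozen=True)
class EmptyingDistribution:
    """Distributional description of gastric emptying for Monte-Carlo runs.

    Defaults emulate fasted-state emptying of a 240-mL water dose: a handful
    of plugs (2-6, uniform) leaving the stomach at uniformly distributed
    onsets over the first 30 minutes, with Dirichlet-distributed volume
    splits and drug allocated proportionally to plug volume (a well-stirred
    stomach).  ``fixed_onsets`` overrides the onset draw (degenerate
    distribution).
    """

    n_plugs: int | tuple[int, int] = (2, 6)
    onset_low: float = 0.0
    onset_high: float = 30.0
    fixed_onsets: tuple[float, ...] | None = None
    volume_mode: str = "dirichlet"  # or "equal"
    volume_alpha: float = 2.0
    dose_mode: str = "proportional"  # or "equal" or "dirichlet"
    dose_alpha: float = 2.0
    transition: float = TRANSITION_MIN
    particle_radius: float = 1e-4

    def __post_init__(self) -> None:
        if self.volume_mode not in ("dirichlet", "equal"):
            raise ScenarioError("volume_mode: must be 'dirichlet' or 'equal'")
        if self.dose_mode not in ("proportional", "equal", "dirichlet"):
            raise ScenarioError("dose_mode: must be 'proportional', 'equal' or 'dirichlet'")

    @classmethod
    def from_config(cls, section: dict) -> "EmptyingDistribution":
        _check_keys(section, _STOCH_KEYS, "stochastic")
        n = section.get("n_plugs")
        if n is None:
            lo = int(section.get("n_plugs_min", 2))
            hi = int(section.get("n_plugs_max", 6))
            n = (lo, hi)
        fixed = section.get("fixed_onsets")
        return cls(
            n_plugs=n,
            onset_low=float(section.get("onset_min", 0.0)),
            onset_high=float(section.get("onset_max", 30.0)),
            fixed_onsets=tuple(fixed) if fixed else None,
            volume_mode=section.get("volume_mode", "dirichlet"),
            volume_alpha=float(section.get("volume_alpha", 2.0)),
            dose_mode=section.get("dose_mode", "proportional"),
            dose_alpha=float(section.get("dose_alpha", 2.0)),
            transition=float(section.get("transition_min", TRANSITION_MIN)),
            particle_radius=float(section.get("particle_radius_um", 1.0)) * 1e-4,
        )


def sample_emptying(
    dist: EmptyingDistribution,
    total_volume: float,
    total_dose: float,
    seed: int,
    *,
    drug: DrugProperties = REFERENCE_DRUG,
    pk: PKParameters = REFERENCE_PK,
    ka_si: float = KA_INTESTINE,
    f_bio: float = F_BIO,
    max_retries: int = 100,
) -> Scenario:
    """Draw one stochastic gastric-emptying scenario.

    Sampled plug volumes sum to ``total_volume`` and doses to ``total_dose``
    exactly; onsets are sorted non-decreasing.  The same seed and
    distribution always produce a bit-identical scenario.
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        if isinstance(dist.n_plugs, int):
            n = dist.n_plugs
        else:
            lo, hi = dist.n_plugs
            n = int(rng.integers(lo, hi + 1))
        if n >= 1:
            break
    else:
        raise ScenarioError("n_plugs: distribution never produced a positive plug count")

    if dist.fixed_onsets is not None:
        if len(dist.fixed_onsets) != n:
            raise ScenarioError("fixed_onsets: length must equal the number of plugs")
        onsets = np.asarray(sorted(dist.fixed_onsets), dtype=float)
    else:
        onsets = np.sort(rng.uniform(dist.onset_low, dist.onset_high, size=n))

    if dist.volume_mode == "equal" or n == 1:
        vol_frac = np.full(n, 1.0 / n)
    else:
        vol_frac = rng.dirichlet(np.full(n, dist.volume_alpha))
    volumes = vol_frac * total_volume
    volumes[-1] = total_volume - volumes[:-1].sum()  # exact closure

    if dist.dose_mode == "proportional":
        dose_frac = volumes / total_volume
    elif dist.dose_mode == "equal" or n == 1:
        dose_frac = np.full(n, 1.0 / n)
    else:
        dose_frac = rng.dirichlet(np.full(n, dist.dose_alpha))
    doses = dose_frac * total_dose
    doses[-1] = total_dose - doses[:-1].sum()

    plugs = [
        build_plug(
            j + 1,
            volume=float(volumes[j]),
            dose=float(doses[j]),
            onset=float(onsets[j]),
            transition=dist.transition,
            radius=dist.particle_radius,
            ka_si=ka_si,
            f_bio=f_bio,
        )
        for j in range(n)
    ]
    return Scenario(drug=drug, pk=pk, plugs=plugs, label="sampled", seed=int(seed))
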