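"""Result serialisation: a CSV time-series plus a JSON metadata sidecar.

The CSV carries full-precision (repr-faithful) decimals so that a write/read
round trip reproduces the simulated series exactly.  The sidecar echoes the
scenario, seed, integrator settings, derived metrics and the mass-balance
residual; field order is fixed so identical runs produce identical bytes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .integrator import SimulationResult, mass_balance
from .metrics import compute_metrics
from .scenarios import scenario_to_dict

__all__ = ["write_result", "read_result", "result_frame", "scenario_hash"]

CSV_NAME = "timeseries.csv"
JSON_NAME = "run.json"


def scenario_hash(scenario) -> str:
    """Short stable digest of the scenario definition."""
    blob = json.dumps(scenario_to_dict(scenario), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def result_frame(result: SimulationResult) -> pd.DataFrame:
    """Tidy wide-format frame of the recorded series."""
    cols: dict[str, np.ndarray] = {
        "time_min": result.times,
        "cp_total_mg_per_ml": result.cp_total,
    }
    if result.config.record_per_plug:
        for j in range(result.n_plugs):
            cols[f"cp_plug_{j + 1}_mg_per_ml"] = result.cp_per_plug[j]
        for j in range(result.n_plugs):
            cols[f"xs_plug_{j + 1}_mg"] = result.xs_per_plug[j]
        for j in range(result.n_plugs):
            cols[f"xd_plug_{j + 1}_mg"] = result.xd_per_plug[j]
    cols["eliminated_mg"] = result.eliminated
    cols["firstpass_mg"] = result.firstpass
    return pd.DataFrame(cols)


def write_result(result: SimulationResult, out_dir: str | Path) -> tuple[Path, Path]:
    """Write ``timeseries.csv`` and ``run.json`` under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = result_frame(result)
    csv_path = out / CSV_NAME
    # default pandas float formatting is repr-shortest, which round-trips
    frame.to_csv(csv_path, index=False)

    metrics = compute_metrics(result.times, result.cp_total, extrapolate=True)
    mb = mass_balance(result)
    sidecar = {
        "software": "mmplug",
        "software_version": __version__,
        "scenario": scenario_to_dict(result.scenario),
        "scenario_hash": scenario_hash(result.scenario),
        "seed": getattr(result.scenario, "seed", None),
        "integrator": {
            "step_min": result.config.step_size,
            "duration_min": result.config.duration,
            "output_interval_min": result.config.output_interval,
            "transition_mode": result.config.transition_mode,
            "engine": result.config.engine,
            "sink": result.config.sink,
        },
        "metrics": {
            "cmax_mg_per_ml": metrics.cmax,
            "tmax_min": metrics.tmax,
            "auc_0_t_mg_min_per_ml": metrics.auc_0_t,
            "auc_0_inf_mg_min_per_ml": metrics.auc_0_inf,
            "cmax_per_plug_mg_per_ml": [
                float(result.cp_per_plug[j].max()) for j in range(result.n_plugs)
            ],
        },
        "mass_balance_max_residual_mg": mb.max_abs_residual,
        "max_negative_excursion_mg": result.max_negative_excursion,
        "warnings": list(result.warnings),
    }
    json_path = out / JSON_NAME
    with open(json_path, "w") as fh:
        json.dump(sidecar, fh, indent=2)
        fh.write("\n")
    return csv_path, json_path


def read_result(run_dir: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read back a run directory written by :func:`write_result`."""
    run_dir = Path(run_dir)
    # the default pandas float parser is not correctly rounded; round_trip
    # restores the exact written values
    frame = pd.read_csv(run_dir / CSV_NAME, float_precision="round_trip")
    with open(run_dir / JSON_NAME) as fh:
        sidecar = json.load(fh)
    return frame, sidecar
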