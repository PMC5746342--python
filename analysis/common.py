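"""Shared helpers for the analysis scripts.

Calibration is the slow step every downstream script needs, so the first
script to run caches it in ``results/calibration.json`` and later scripts
rebuild the calibrated model pair from the stored densities.
"""
from __future__ import annotations

import json
import pathlib

from fsikir.calibrate import CalibratedModel, CalibrationTargets, calibrate_full
from fsikir.mechanisms import KirSpec
from fsikir.model import CellModel, default_model

RESULTS = pathlib.Path(__file__).resolve().parent.parent / "results"


def results_dir() -> pathlib.Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS


def calibration_payload(cal: CalibratedModel) -> dict:
    r = cal.result
    return {
        "g_k_leak_density": r.g_k_leak_density,
        "g_na_leak_density": r.g_na_leak_density,
        "g_kir_density": r.g_kir_density,
        "kir_share": r.kir_share,
        "kir_v_half": r.kir_v_half,
        "reduction_fraction": r.reduction_fraction,
        "achieved_vm": r.achieved_vm,
        "achieved_rin": r.achieved_rin,
        "achieved_dvm": r.achieved_dvm,
        "achieved_drin_percent": r.achieved_drin_percent,
        "converged": r.converged,
        "synapse_weight_uS": cal.synapse_weight,
        "synapse_tau_decay_ms": cal.synapse_tau_decay,
        "synapse_tau_rise_ms": cal.synapse_tau_rise,
    }


def models_from_payload(d: dict) -> tuple[CellModel, CellModel, dict]:
    kir = KirSpec(g_density=d["g_kir_density"], v_half=d["kir_v_half"])
    base = default_model(g_k_density=d["g_k_leak_density"],
                         g_na_density=d["g_na_leak_density"], kir=kir)
    reduced = base.with_reduction(d["reduction_fraction"], scope="both")
    syn = {"tau_rise": d["synapse_tau_rise_ms"],
           "tau_decay": d["synapse_tau_decay_ms"],
           "weight": d["synapse_weight_uS"]}
    return base, reduced, syn


def get_calibrated() -> tuple[CellModel, CellModel, dict, dict]:
    """(baseline model, reduced model, synapse kwargs, payload), cached."""
    path = results_dir() / "calibration.json"
    if path.exists():
        payload = json.loads(path.read_text())
    else:
        cal = calibrate_full(targets=CalibrationTargets())
        payload = calibration_payload(cal)
        path.write_text(json.dumps(payload, indent=1))
    base, reduced, syn = models_from_payload(payload)
    return base, reduced, syn, payload
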