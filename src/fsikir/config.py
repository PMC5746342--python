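"""Structured-text (TOML) configuration for models and mechanisms.

A config file may contain any of the blocks below; omitted values fall back
to the package defaults (units fixed as stated):

    [morphology]            # µm
    n_dendrites = 5
    dendrite_length = 200.0
    dendrite_diameter = 1.5
    soma_length = 15.0
    soma_diameter = 15.0
    max_compartment_length = 10.0
    ra = 172.0              # Ω·cm
    swc = "path.swc"        # overrides the reduced morphology

    [leak]                  # S/cm² and mV
    g_k_density = 2.4e-4
    g_na_density = 1.0e-4
    e_k = -107.0
    e_na = 53.0

    [kir]
    g_density = 4.4e-4      # S/cm² (maximal)
    v_half = -85.0          # mV
    k_slope = 12.0          # mV

    [synapses]              # ms / µS
    tau_rise = 0.5
    tau_decay = 14.0
    weight = 1e-3
    distances = [100.0, 99.0, 98.0, 97.0, 96.0]   # µm from soma

    [noise]                 # µS / ms / mV
    scale = 1.0
    seed = 0
    g0_exc = 0.0121
    ...

    [engine]
    dt = 0.025              # ms
    cm = 1.0                # µF/cm²
"""
from __future__ import annotations

import dataclasses
import tomllib

from .engine import EngineConfig
from .mechanisms import KirSpec, LeakSpec, Mechanisms, NoiseSpec
from .model import CellModel
from .morphology import build_reduced_fsi, discretize, load_swc

__all__ = ["load_config", "model_from_config", "synapse_params_from_config"]


def load_config(path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _fill(cls, block: dict, **fixed):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - names
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**{**block, **fixed})


def model_from_config(cfg: dict) -> CellModel:
    morph_cfg = dict(cfg.get("morphology", {}))
    mcl = morph_cfg.pop("max_compartment_length", 10.0)
    ra = morph_cfg.pop("ra", 172.0)
    swc = morph_cfg.pop("swc", None)
    morph = load_swc(swc) if swc else build_reduced_fsi(**morph_cfg)
    tree = discretize(morph, max_compartment_length=mcl, ra=ra)

    leak = _fill(LeakSpec, cfg.get("leak", {"g_k_density": 1.5e-4,
                                            "g_na_density": 0.45e-4}))
    kir = _fill(KirSpec, cfg.get("kir", {"g_density": 0.0}))
    noise_cfg = dict(cfg.get("noise", {}))
    noise = None
    if noise_cfg:
        targets = tuple(noise_cfg.pop("targets", ()))
        noise = _fill(NoiseSpec, noise_cfg, targets=targets)
    engine = _fill(EngineConfig, cfg.get("engine", {}))
    mech = Mechanisms(leak=leak, kir=kir, noise=noise)
    model = CellModel(tree=tree, mech=mech, config=engine)
    if noise is not None and not noise.targets:
        model = model.with_noise(
            dataclasses.replace(noise, targets=model.noise_targets_default()))
    return model


def synapse_params_from_config(cfg: dict) -> dict:
    syn = cfg.get("synapses", {})
    return {
        "tau_rise": syn.get("tau_rise", 0.5),
        "tau_decay": syn.get("tau_decay", 14.0),
        "weight": syn.get("weight", 1e-3),
        "sites": tuple(syn.get("distances",
                               (100.0, 99.0, 98.0, 97.0, 96.0))),
    }
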