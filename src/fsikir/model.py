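"""Convenience bundle of a compartment tree plus its mechanisms.

:class:`CellModel` is what the protocol and calibration layers pass around:
the discretized reduced fast-spiking interneuron with its leak/Kir densities,
synapses and optional background noise, plus helpers for scoped K⁺-pool
scaling and synapse placement at path distances along a dendrite.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .engine import EngineConfig
from .mechanisms import KirSpec, LeakSpec, Mechanisms, NoiseSpec, SynapseSpec, kir_open_fraction
from .morphology import CompartmentTree, build_reduced_fsi, discretize

__all__ = ["CellModel", "default_model"]

#: Synapse distances from the soma used by the stimulation protocols, µm
#: (five sites, 1 µm apart, starting 96 µm out — most distal activated first).
SYNAPSE_DISTANCES = (100.0, 99.0, 98.0, 97.0, 96.0)


@dataclass(frozen=True)
class CellModel:
    tree: CompartmentTree
    mech: Mechanisms
    config: EngineConfig = EngineConfig()

    # -- masks ----------------------------------------------------------
    def mask(self, scope: str) -> np.ndarray:
        """Boolean compartment mask for ``soma``, ``dendrites`` or ``both``."""
        soma_section = self.tree.compartments[0].section_id
        is_soma = np.array([c.section_id == soma_section
                            for c in self.tree.compartments])
        if scope == "soma":
            out = is_soma
        elif scope == "dendrites":
            out = ~is_soma
        elif scope == "both":
            out = np.ones(len(self.tree), dtype=bool)
        else:
            raise ValueError(f"unknown scope {scope!r}")
        if not out.any():
            raise ValueError(f"scope {scope!r} selects no compartments")
        return out

    # -- transformations ------------------------------------------------
    def with_reduction(self, f: float, scope: str = "both") -> "CellModel":
        """Scale the 5HT-sensitive K⁺ pool by (1−f) in the scoped region."""
        mech = self.mech.with_uniform_reduction(f, len(self.tree),
                                                mask=self.mask(scope))
        return replace(self, mech=mech)

    def with_graded_reduction(self, weights: np.ndarray) -> "CellModel":
        """Scale the K⁺ pool by (1 − w_i) per compartment (w in [0, 1])."""
        w = np.asarray(weights, dtype=float)
        base = np.array(self.mech.k_scale) if self.mech.k_scale is not None \
            else np.ones(len(self.tree))
        return replace(self, mech=self.mech.with_k_scale(base * (1.0 - w)))

    def with_synapses(
        self,
        distances=SYNAPSE_DISTANCES,
        dendrite_section: int = 1,
        tau_rise: float = 0.5,
        tau_decay: float = 14.0,
        weight: float = 1e-3,
        onsets_per_synapse=None,
    ) -> "CellModel":
        """Place one synapse per path distance (µm) on one dendrite.

        ``onsets_per_synapse`` is a sequence of onset-time tuples aligned
        with ``distances`` (empty tuples for silent synapses).
        """
        if onsets_per_synapse is None:
            onsets_per_synapse = [()] * len(distances)
        syns = []
        for d, onsets in zip(distances, onsets_per_synapse, strict=True):
            ci = self.tree.locate_path_distance(d, dendrite_section)
            syns.append(SynapseSpec(compartment=ci, tau_rise=tau_rise,
                                    tau_decay=tau_decay, weight=weight,
                                    onsets=tuple(onsets)))
        return replace(self, mech=replace(self.mech, synapses=tuple(syns)))

    def with_noise(self, noise: NoiseSpec | None) -> "CellModel":
        return replace(self, mech=replace(self.mech, noise=noise))

    def without_synapses(self) -> "CellModel":
        return replace(self, mech=replace(self.mech, synapses=()))

    def noise_targets_default(self) -> tuple[int, ...]:
        """Midpoint compartment of every dendrite except the synapse-bearing
        one (section 1): background noise lands on a subset of dendrites."""
        sections = sorted({c.section_id for c in self.tree.compartments
                           if c.section_id not in (self.tree.compartments[0].section_id, 1)})
        out = []
        for sid in sections:
            comps = [c for c in self.tree.compartments if c.section_id == sid]
            lengths = sum(c.length for c in comps)
            out.append(self.tree.locate(sid, lengths / 2))
        return tuple(out)

    def kir_resting_share(self, v_rest: float) -> float:
        """Share of the resting K⁺ chord conductance carried by Kir at
        voltage ``v_rest`` (uniform densities assumed)."""
        m0 = float(kir_open_fraction(v_rest, self.mech.kir))
        gk = self.mech.leak.g_k_density
        gkir = self.mech.kir.g_density * m0
        return gkir / (gk + gkir)


def default_model(
    max_compartment_length: float = 10.0,
    g_k_density: float = 1.5e-4,
    g_na_density: float = 0.45e-4,
    g_kir_density: float = 0.0,
    kir: KirSpec | None = None,
    config: EngineConfig = EngineConfig(),
) -> CellModel:
    """The reduced FSI stand-in with uncalibrated starting densities.

    Soma 15 µm × 15 µm, five dendrites 200 µm × 1.5 µm, Ra 172 Ω·cm.  The
    starting leak densities put rest near the original single-passive
    reversal; calibration replaces them.
    """
    morph = build_reduced_fsi()
    tree = discretize(morph, max_compartment_length=max_compartment_length)
    kir = kir if kir is not None else KirSpec(g_density=g_kir_density)
    if kir.g_density != g_kir_density and g_kir_density:
        kir = replace(kir, g_density=g_kir_density)
    mech = Mechanisms(
        leak=LeakSpec(g_k_density=g_k_density, g_na_density=g_na_density),
        kir=kir,
    )
    return CellModel(tree=tree, mech=mech, config=config)
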