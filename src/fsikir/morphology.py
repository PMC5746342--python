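"""Neuron morphologies and their spatial discretization.

A :class:`Morphology` is a rooted tree of unbranched cable sections (a soma
cylinder plus dendrites).  Morphologies come from three sources: the SWC
interchange format (:func:`load_swc`), a JSON serialization
(:func:`morphology_from_json`), or the built-in reduced fast-spiking
interneuron stand-in (:func:`build_reduced_fsi`) — a soma cylinder with a
small number of identical unbranched dendrites, which is the default model
used throughout this package.

:func:`discretize` splits each section into equal-length compartments and
returns a :class:`CompartmentTree`, the container the cable solver consumes.
All lengths and diameters are in µm, areas in µm², axial resistances in MΩ.
"""
from __future__ import annotations

from dataclasses import dataclass, field
import json
import math

__all__ = [
    "Section",
    "Morphology",
    "Compartment",
    "CompartmentTree",
    "MorphologyError",
    "SwcParseError",
    "load_swc",
    "write_swc",
    "build_reduced_fsi",
    "discretize",
    "morphology_to_json",
    "morphology_from_json",
]

#: Default axial resistivity, Ω·cm.
DEFAULT_RA = 172.0
#: Default dendritic diameter, µm.
DEFAULT_DENDRITE_DIAMETER = 1.5


class MorphologyError(ValueError):
    """Structural problem in a morphology (cycles, bad parents, bad geometry)."""


class SwcParseError(MorphologyError):
    """Malformed SWC content; carries the offending line number."""


@dataclass(frozen=True)
class Section:
    """One unbranched cable section.

    ``parent_id`` is ``-1`` for the soma (root).  Dendrite sections attach to
    their parent's distal end; sections whose parent is the soma attach at the
    soma-dendrite junction, which is the origin of "path distance from soma".
    """

    id: int
    parent_id: int
    kind: str  # "soma" | "dendrite"
    length: float  # µm
    diameter: float  # µm

    def __post_init__(self) -> None:
        if self.kind not in ("soma", "dendrite"):
            raise MorphologyError(f"unknown section kind {self.kind!r}")
        if self.length <= 0 or self.diameter <= 0:
            raise MorphologyError(
                f"section {self.id}: length and diameter must be > 0"
            )


@dataclass(frozen=True)
class Morphology:
    """Rooted tree of sections; section 0 is always the soma."""

    sections: tuple[Section, ...]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sections]
        if len(set(ids)) != len(ids):
            raise MorphologyError("duplicate section ids")
        by_id = {s.id: s for s in self.sections}
        roots = [s for s in self.sections if s.parent_id == -1]
        if len(roots) != 1 or roots[0].kind != "soma":
            raise MorphologyError("need exactly one root section of kind 'soma'")
        for s in self.sections:
            if s.parent_id == -1:
                continue
            if s.parent_id not in by_id:
                raise MorphologyError(
                    f"section {s.id} references unknown parent {s.parent_id}"
                )
            # walk to root to catch cycles
            seen = {s.id}
            cur = s
            while cur.parent_id != -1:
                if cur.parent_id in seen:
                    raise MorphologyError(f"cycle through section {s.id}")
                seen.add(cur.parent_id)
                cur = by_id[cur.parent_id]

    @property
    def soma(self) -> Section:
        return next(s for s in self.sections if s.parent_id == -1)

    @property
    def dendrites(self) -> tuple[Section, ...]:
        return tuple(s for s in self.sections if s.kind == "dendrite")

    def total_length(self) -> float:
        """Total cable length (all sections), µm."""
        return sum(s.length for s in self.sections)

    def total_area(self) -> float:
        """Total lateral membrane area, µm² (cylinders, no end caps)."""
        return sum(math.pi * s.diameter * s.length for s in self.sections)


@dataclass(frozen=True)
class Compartment:
    index: int
    parent_index: int  # -1 at root
    section_id: int
    center: float  # µm along the section from its proximal end
    length: float  # µm
    diameter: float  # µm
    area: float  # µm² lateral
    r_axial: float  # MΩ — axial resistance of this compartment's own cylinder


@dataclass(frozen=True)
class CompartmentTree:
    """Discretized morphology: compartments in parent-before-child order.

    The stored ``r_axial`` of a compartment is the axial resistance of its own
    cylinder, Ra·L/(π d²/4) converted to MΩ.  The coupling resistance between
    a compartment and its parent used by the solver is the sum of the two
    facing half-cylinder resistances.
    """

    compartments: tuple[Compartment, ...]
    ra: float  # axial resistivity, Ω·cm

    def __post_init__(self) -> None:
        for i, c in enumerate(self.compartments):
            if c.index != i:
                raise MorphologyError("compartment indices must be 0..n-1 in order")
            if c.parent_index >= i:
                raise MorphologyError("compartments must be parent-before-child")
        if self.compartments[0].parent_index != -1:
            raise MorphologyError("compartment 0 must be the root")

    def __len__(self) -> int:
        return len(self.compartments)

    def coupling_resistance(self, i: int) -> float:
        """Axial resistance (MΩ) between compartment *i* and its parent."""
        c = self.compartments[i]
        if c.parent_index < 0:
            raise IndexError("root has no parent")
        p = self.compartments[c.parent_index]
        half_child = 0.5 * c.r_axial
        # soma-dendrite junctions: dendrites attach at the junction point, so
        # only the child half-cylinder counts toward the coupling when the
        # parent is the soma root (the soma is close to isopotential anyway).
        half_parent = 0.0 if p.section_id == 0 and c.section_id != 0 else 0.5 * p.r_axial
        return half_child + half_parent

    def path_distance(self, i: int) -> float:
        """Path distance (µm) from the soma-dendrite junction to the center
        of compartment *i*.  Distance is 0 anywhere inside the soma."""
        c = self.compartments[i]
        soma_section = self.compartments[0].section_id
        if c.section_id == soma_section:
            return 0.0
        # center already measures from the proximal end of c's own section;
        # every ancestor compartment belonging to an intermediate dendrite
        # section contributes its full length (children attach distally).
        d = c.center
        j = c.parent_index
        while j >= 0:
            p = self.compartments[j]
            if p.section_id == soma_section:
                break
            if p.section_id != c.section_id:
                d += p.length
            j = p.parent_index
        return d

    def locate(self, section_id: int, position: float) -> int:
        """Index of the compartment of *section_id* whose span contains
        *position* (µm from the section's proximal end)."""
        for c in self.compartments:
            if c.section_id != section_id:
                continue
            lo = c.center - c.length / 2
            hi = c.center + c.length / 2
            if lo - 1e-9 <= position <= hi + 1e-9:
                return c.index
        raise MorphologyError(
            f"position {position} µm not on section {section_id}"
        )

    def locate_path_distance(self, distance: float, dendrite_section: int) -> int:
        """Index of the compartment on *dendrite_section* whose span contains
        the given path distance from the soma junction (unbranched chains)."""
        return self.locate(dendrite_section, distance)

    def total_area(self) -> float:
        return sum(c.area for c in self.compartments)


def _axial_resistance_mohm(ra: float, length: float, diameter: float) -> float:
    """Ra (Ω·cm) · L (µm) / cross-section (µm²) → MΩ."""
    area = math.pi * diameter**2 / 4.0
    return ra * length / area * 1e-2


def load_swc(path) -> Morphology:
    """Read an SWC morphology.

    Only types 1 (soma) and 3 (basal dendrite) are honored; any other sample
    type is rejected.  Consecutive dendrite samples with the same parent chain
    are merged into unbranched sections; section length is the summed 3-D
    distance between successive samples, section diameter the length-weighted
    mean sample diameter.  The soma is represented as a cylinder whose length
    is the extent of the type-1 samples (or its diameter, for a single-point
    soma) and whose diameter is twice the mean soma radius.
    """
    samples: dict[int, tuple[int, float, float, float, float, int]] = {}
    order: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SwcParseError(f"line {lineno}: expected 7 columns, got {len(parts)}")
            try:
                sid = int(parts[0])
                stype = int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise SwcParseError(f"line {lineno}: {exc}") from None
            if stype not in (1, 3):
                raise SwcParseError(
                    f"line {lineno}: unsupported SWC type {stype} (only 1=soma, 3=dendrite)"
                )
            if r <= 0:
                raise SwcParseError(f"line {lineno}: non-positive radius")
            if sid in samples:
                raise SwcParseError(f"line {lineno}: duplicate sample id {sid}")
            if parent == sid:
                raise MorphologyError(f"line {lineno}: sample {sid} is its own parent")
            if parent != -1 and parent not in samples:
                raise MorphologyError(
                    f"line {lineno}: sample {sid} references later/unknown parent {parent}"
                )
            samples[sid] = (stype, x, y, z, r, parent)
            order.append(sid)

    soma_ids = [i for i in order if samples[i][0] == 1]
    if not soma_ids:
        raise MorphologyError("no soma (type 1) samples")

    # soma cylinder from the type-1 samples
    pts = [samples[i] for i in soma_ids]
    mean_r = sum(p[4] for p in pts) / len(pts)
    if len(pts) > 1:
        first, last = pts[0], pts[-1]
        extent = math.dist(first[1:4], last[1:4])
        soma_len = extent if extent > 0 else 2 * mean_r
    else:
        soma_len = 2 * mean_r
    sections = [Section(0, -1, "soma", soma_len, 2 * mean_r)]

    # dendrite sections: break chains at branch points and at soma attachment
    children: dict[int, list[int]] = {}
    for i in order:
        p = samples[i][5]
        children.setdefault(p, []).append(i)

    def is_soma(i: int) -> bool:
        return i != -1 and samples[i][0] == 1

    sec_id = 0
    sec_of_sample: dict[int, int] = {}
    # walk every type-3 sample chain, breaking at branch points and at the soma
    visited: set[int] = set()
    for start in order:
        if samples[start][0] != 1 and start not in visited:
            parent_sample = samples[start][5]
            if parent_sample != -1 and samples[parent_sample][0] == 3 and \
                    len(children.get(parent_sample, [])) == 1:
                continue  # interior of a chain; picked up by its start
            # collect the unbranched chain
            chain = [start]
            visited.add(start)
            cur = start
            while True:
                kids = [k for k in children.get(cur, []) if samples[k][0] == 3]
                if len(kids) != 1:
                    break
                cur = kids[0]
                chain.append(cur)
                visited.add(cur)
            # geometry
            length = 0.0
            wdiam = 0.0
            prev = samples[start][5]
            for sidx in chain:
                s = samples[sidx]
                if prev != -1:
                    p = samples[prev]
                    seg = math.dist(s[1:4], p[1:4])
                else:
                    seg = 0.0
                length += seg
                wdiam += seg * (2 * s[4])
                prev = sidx
            if length <= 0:
                raise MorphologyError(
                    f"dendrite section starting at sample {start} has zero length"
                )
            diameter = wdiam / length
            sec_id += 1
            parent_sec = 0 if (samples[start][5] == -1 or is_soma(samples[start][5])) \
                else sec_of_sample[samples[start][5]]
            sections.append(Section(sec_id, parent_sec, "dendrite", length, diameter))
            for sidx in chain:
                sec_of_sample[sidx] = sec_id
    return Morphology(tuple(sections))


def write_swc(morph: Morphology, path) -> None:
    """Serialize a morphology back to SWC (one sample per section end).

    The writer is the inverse of :func:`load_swc` for morphologies consisting
    of a soma plus unbranched dendrites laid out along separate axes: topology
    and per-section cable length round-trip exactly.
    """
    lines = ["# fsikir morphology export"]
    soma = morph.soma
    r = soma.diameter / 2
    half = soma.length / 2
    lines.append(f"1 1 {-half:.6f} 0 0 {r:.6f} -1")
    lines.append(f"2 1 {half:.6f} 0 0 {r:.6f} 1")
    next_id = 3
    sample_of_section = {0: 1}
    # lay each dendrite chain along its own direction to avoid overlap
    direction = {}
    dendrites = [s for s in morph.sections if s.kind == "dendrite"]
    for k, sec in enumerate(dendrites):
        ang = 2 * math.pi * k / max(len(dendrites), 1) + 0.1
        direction[sec.id] = (math.cos(ang), math.sin(ang))

    # process in id order so parents are written first; dendrites start at
    # the position of their parent's attachment sample so that section
    # lengths round-trip exactly
    pos: dict[int, tuple[float, float, float]] = {0: (-half, 0.0, 0.0)}
    for sec in sorted(dendrites, key=lambda s: s.id):
        px, py, pz = pos[sec.parent_id]
        dx, dy = direction.get(sec.id, direction[dendrites[0].id])
        ex, ey, ez = px + dx * sec.length, py + dy * sec.length, pz
        parent_sample = sample_of_section[sec.parent_id]
        r = sec.diameter / 2
        # two samples: proximal attachment point and distal end
        lines.append(f"{next_id} 3 {px:.9f} {py:.9f} {pz:.9f} {r:.6f} {parent_sample}")
        lines.append(f"{next_id + 1} 3 {ex:.9f} {ey:.9f} {ez:.9f} {r:.6f} {next_id}")
        sample_of_section[sec.id] = next_id + 1
        pos[sec.id] = (ex, ey, ez)
        next_id += 2
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def build_reduced_fsi(
    n_dendrites: int = 5,
    dendrite_length: float = 200.0,
    dendrite_diameter: float = DEFAULT_DENDRITE_DIAMETER,
    soma_length: float = 15.0,
    soma_diameter: float = 15.0,
) -> Morphology:
    """Reduced fast-spiking interneuron stand-in.

    A soma cylinder (default 15 µm × 15 µm) with ``n_dendrites`` identical
    unbranched dendrites (default 5 × 200 µm × 1.5 µm) attached at the soma.
    The defaults admit synapse sites 96–100 µm from the soma on every
    dendrite, matching the synapse placement used by the stimulation
    protocols.
    """
    if n_dendrites < 1:
        raise MorphologyError("need at least one dendrite (synapse placement)")
    if min(dendrite_length, dendrite_diameter, soma_length, soma_diameter) <= 0:
        raise MorphologyError("all geometry arguments must be > 0")
    sections = [Section(0, -1, "soma", soma_length, soma_diameter)]
    for k in range(n_dendrites):
        sections.append(
            Section(k + 1, 0, "dendrite", dendrite_length, dendrite_diameter)
        )
    return Morphology(tuple(sections))


def discretize(
    morph: Morphology,
    max_compartment_length: float = 10.0,
    ra: float = DEFAULT_RA,
) -> CompartmentTree:
    """Split every section into ``ceil(L/max_compartment_length)`` equal
    compartments and assemble the compartment tree (parent-before-child)."""
    if max_compartment_length <= 0:
        raise MorphologyError("max_compartment_length must be > 0")
    comps: list[Compartment] = []
    last_comp_of_section: dict[int, int] = {}
    by_id = {s.id: s for s in morph.sections}
    # sections ordered so parents precede children
    ordered: list[Section] = []
    placed: set[int] = set()
    pending = sorted(morph.sections, key=lambda s: s.id)
    while pending:
        progressed = False
        rest = []
        for s in pending:
            if s.parent_id == -1 or s.parent_id in placed:
                ordered.append(s)
                placed.add(s.id)
                progressed = True
            else:
                rest.append(s)
        pending = rest
        if not progressed:
            raise MorphologyError("sections do not form a rooted tree")

    for sec in ordered:
        n = max(1, math.ceil(sec.length / max_compartment_length - 1e-12))
        dl = sec.length / n
        for j in range(n):
            if j == 0:
                parent = -1 if sec.parent_id == -1 else last_comp_of_section[sec.parent_id]
            else:
                parent = len(comps) - 1
            comps.append(
                Compartment(
                    index=len(comps),
                    parent_index=parent,
                    section_id=sec.id,
                    center=(j + 0.5) * dl,
                    length=dl,
                    diameter=sec.diameter,
                    area=math.pi * sec.diameter * dl,
                    r_axial=_axial_resistance_mohm(ra, dl, sec.diameter),
                )
            )
        last_comp_of_section[sec.id] = len(comps) - 1
    return CompartmentTree(tuple(comps), ra=ra)


def morphology_to_json(morph: Morphology) -> str:
    return json.dumps(
        {
            "sections": [
                {
                    "id": s.id,
                    "parent_id": s.parent_id,
                    "kind": s.kind,
                    "length_um": s.length,
                    "diameter_um": s.diameter,
                }
                for s in morph.sections
            ]
        },
        indent=1,
    )


def morphology_from_json(text: str) -> Morphology:
    data = json.loads(text)
    return Morphology(
        tuple(
            Section(d["id"], d["parent_id"], d["kind"], d["length_um"], d["diameter_um"])
            for d in data["sections"]
        )
    )
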