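"""Neuron morphology: trees of cylindrical sections and their compartment grids.

A neuron is described as a tree of unbranched cylinders (*sections*), each
subdivided into ``nseg`` compartments.  The membrane potential is evaluated at
the centre of each compartment; sealed ends are realized by simply omitting
axial coupling beyond terminal compartments (the "virtual point" construction
carries zero axial current, so nothing is stored for it).

Compartments are numbered so that every node's parent has a smaller index
(Hines ordering), which is what makes the tree-tridiagonal system solvable in
linear time by one backward and one forward sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Section",
    "CompartmentGrid",
    "MorphologyError",
    "build_grid",
    "validate_grid",
]


class MorphologyError(ValueError):
    """Invalid geometry or section-tree structure."""


@dataclass
class Section:
    """An unbranched cylindrical cable with homogeneous electrical properties.

    Parameters
    ----------
    name:
        Unique label ("soma", "axon", "dend1", ...).
    length:
        Section length in um.
    diameter:
        Diameter in um. Either a scalar (constant-diameter cylinder) or a
        ``(proximal, distal)`` pair; tapered sections interpolate linearly.
    nseg:
        Number of compartments the section is divided into.
    Ra:
        Axial resistivity in Ohm*cm.
    Cm:
        Specific membrane capacitance in uF/cm^2.
    channel_densities:
        Map channel-name -> maximal conductance density in S/cm^2.
    reversal_potentials:
        Optional map channel-or-ion name -> reversal potential in mV,
        overriding the channel definition's default for this section.
    parent:
        ``None`` for the root section, else ``(parent_name, end)`` with
        ``end`` in {"proximal", "distal"}: which end of the *parent* this
        section's proximal end attaches to.
    """

    name: str
    length: float
    diameter: float | tuple[float, float]
    nseg: int = 1
    Ra: float = 150.0
    Cm: float = 1.0
    channel_densities: dict[str, float] = field(default_factory=dict)
    reversal_potentials: dict[str, float] = field(default_factory=dict)
    parent: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        d = self.diam_pair()
        if self.length <= 0 or d[0] <= 0 or d[1] <= 0:
            raise MorphologyError(
                f"section {self.name!r}: length and diameter must be positive"
            )
        if int(self.nseg) != self.nseg or self.nseg < 1:
            raise MorphologyError(f"section {self.name!r}: nseg must be a positive integer")
        if self.Ra <= 0 or self.Cm <= 0:
            raise MorphologyError(f"section {self.name!r}: Ra and Cm must be positive")
        if self.parent is not None and self.parent[1] not in ("proximal", "distal"):
            raise MorphologyError(
                f"section {self.name!r}: attachment end must be 'proximal' or 'distal'"
            )

    def diam_pair(self) -> tuple[float, float]:
        """(proximal, distal) diameter in um."""
        if isinstance(self.diameter, (tuple, list)):
            return float(self.diameter[0]), float(self.diameter[1])
        return float(self.diameter), float(self.diameter)

    def radius_at(self, s: float) -> float:
        """Radius (um) at normalized axial position s in [0, 1]."""
        d0, d1 = self.diam_pair()
        return 0.5 * (d0 + (d1 - d0) * s)


@dataclass
class CompartmentGrid:
    """The discretized tree: one entry per compartment, Hines-ordered.

    ``parent[i]`` is the index of node i's parent (-1 at the root) and
    satisfies ``parent[i] < i``.  ``iface_radius[i]`` is the cable radius at
    the boundary shared with the parent (the a_{i-1/2} of the axial-coupling
    coefficient); it is meaningless at the root.
    """

    n_nodes: int
    parent: np.ndarray          # int, parent[root] == -1
    radius: np.ndarray          # um, at compartment centre (a_i)
    iface_radius: np.ndarray    # um, at boundary with parent
    dx: np.ndarray              # um, compartment length (section length / nseg)
    area: np.ndarray            # um^2, lateral area 2*pi*a_i*dx_i
    cm: np.ndarray              # uF/cm^2 per node
    ra: np.ndarray              # Ohm*cm per node
    section_of: list[str]       # node -> section name
    node_position: np.ndarray   # centre position within section, in (0, 1)
    sections: dict[str, Section] = field(default_factory=dict)

    @property
    def area_cm2(self) -> np.ndarray:
        return self.area * 1e-8

    @property
    def cap_nF(self) -> np.ndarray:
        """Per-node membrane capacitance in nF (Cm [uF/cm^2] * area [cm^2] * 1e3)."""
        return self.cm * self.area_cm2 * 1e3

    def nodes_of(self, section: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.section_of) if s == section])


def _order_sections(sections: list[Section]) -> list[Section]:
    """Topological order, root first, children after parents (declaration order)."""
    by_name = {}
    for sec in sections:
        if sec.name in by_name:
            raise MorphologyError(f"duplicate section name {sec.name!r}")
        by_name[sec.name] = sec
    roots = [s for s in sections if s.parent is None]
    if len(roots) != 1:
        raise MorphologyError(f"expected exactly one root section, found {len(roots)}")
    children: dict[str, list[Section]] = {s.name: [] for s in sections}
    for sec in sections:
        if sec.parent is not None:
            pname = sec.parent[0]
            if pname not in by_name:
                raise MorphologyError(
                    f"section {sec.name!r} attaches to unknown section {pname!r}"
                )
            children[pname].append(sec)
    ordered: list[Section] = []
    stack = [roots[0]]
    while stack:
        sec = stack.pop(0)
        ordered.append(sec)
        stack = children[sec.name] + stack
    if len(ordered) != len(sections):
        raise MorphologyError("section parent relation contains a cycle or orphan")
    return ordered


def build_grid(sections: list[Section]) -> CompartmentGrid:
    """Discretize a tree of sections into a Hines-ordered compartment grid.

    Compartment centres sit at normalized positions (k + 0.5)/nseg within each
    section, with dx = length/nseg.  The first compartment of a child section
    attaches to the parent section's compartment nearest the declared
    attachment end (distal -> parent's last node, proximal -> first).
    """
    ordered = _order_sections(list(sections))
    first_node: dict[str, int] = {}
    last_node: dict[str, int] = {}

    parent, radius, iface, dx, area, cm, ra = [], [], [], [], [], [], []
    section_of: list[str] = []
    node_pos: list[float] = []

    for sec in ordered:
        n0 = len(parent)
        first_node[sec.name] = n0
        step = sec.length / sec.nseg
        for k in range(sec.nseg):
            idx = n0 + k
            if k == 0:
                if sec.parent is None:
                    parent.append(-1)
                else:
                    pname, end = sec.parent
                    parent.append(first_node[pname] if end == "proximal" else last_node[pname])
            else:
                parent.append(idx - 1)
            a_c = sec.radius_at((k + 0.5) / sec.nseg)
            radius.append(a_c)
            # boundary with predecessor: proximal face of this compartment
            iface.append(sec.radius_at(k / sec.nseg))
            dx.append(step)
            area.append(2.0 * np.pi * a_c * step)
            cm.append(sec.Cm)
            ra.append(sec.Ra)
            section_of.append(sec.name)
            node_pos.append((k + 0.5) / sec.nseg)
        last_node[sec.name] = len(parent) - 1

    grid = CompartmentGrid(
        n_nodes=len(parent),
        parent=np.asarray(parent, dtype=np.int64),
        radius=np.asarray(radius, dtype=float),
        iface_radius=np.asarray(iface, dtype=float),
        dx=np.asarray(dx, dtype=float),
        area=np.asarray(area, dtype=float),
        cm=np.asarray(cm, dtype=float),
        ra=np.asarray(ra, dtype=float),
        section_of=section_of,
        node_position=np.asarray(node_pos, dtype=float),
        sections={s.name: s for s in ordered},
    )
    issues = validate_grid(grid)
    if issues:
        raise MorphologyError("; ".join(issues))
    return grid


def validate_grid(grid: CompartmentGrid) -> list[str]:
    """Diagnostic scan of a grid; returns an empty list iff all invariants hold.

    Checks Hines ordering (parent[i] < i), a single root, connectivity
    (no orphan components) and positive geometry.  Purely diagnostic: never
    raises.
    """
    issues: list[str] = []
    n = grid.n_nodes
    p = grid.parent
    if len(p) != n:
        issues.append(f"parent vector length {len(p)} != n_nodes {n}")
        return issues
    roots = np.flatnonzero(p < 0)
    if len(roots) != 1:
        issues.append(f"expected exactly one root, found {len(roots)}")
    for i in range(n):
        if p[i] >= i:
            issues.append(f"Hines ordering violation at node {i}: parent {p[i]} >= {i}")
        if p[i] >= n:
            issues.append(f"node {i}: parent index {p[i]} out of range")
    for name, arr in (("radius", grid.radius), ("dx", grid.dx), ("area", grid.area),
                      ("cm", grid.cm), ("ra", grid.ra)):
        if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
            issues.append(f"non-positive or non-finite {name}")
    return issues
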