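"""Compartmentalized neuron morphologies.

A neuron is represented as a tree of short cylindrical compartments
(:class:`CompartmentGraph`), each carrying a section label that keys into
the channel-density tables of :mod:`retstim.mechanisms`.  Two stylized
builders provide the bipolar cell (BC) and retinal ganglion cell (RGC)
used throughout the stimulation protocols; standard SWC files can be
loaded and written for interchange.

Coordinate convention: z is retinal depth with z = 0 at the subretinal
implant/electrode plane and +z toward the vitreous.  The BC therefore has
its dendritic tuft at low z (outer plexiform layer, next to the implant)
and its axon terminals at high z (inner plexiform layer); the RGC soma
sits near the vitreal surface.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, StructuralError, SWCParseError
from .units import RHO_AXIAL_BC, RHO_AXIAL_RGC, C_M_UF_CM2

BC_SECTIONS = ("dendrite", "soma", "axon", "terminal")
RGC_SECTIONS = ("dendrite", "soma", "soma_AIS", "AIS", "axon")

#: SWC type code -> section label (overridable in load_swc).
#: 1/2/3 follow the SWC standard; 4, 5, 6 are custom codes because SWC has
#: no convention for axon hillock, AIS or presynaptic terminals.
DEFAULT_TYPE_MAP = {1: "soma", 2: "axon", 3: "dendrite",
                    4: "soma_AIS", 5: "AIS", 6: "terminal"}


@dataclass
class Compartment:
    """Read-only view of one compartment of a :class:`CompartmentGraph`."""

    id: int
    section_label: str
    center: np.ndarray          # µm
    length: float               # µm
    diameter: float             # µm
    neighbors: tuple[int, ...]
    axial_resistance_half: float  # MΩ, center to either end


class CompartmentGraph:
    """Discretized neuron morphology.

    Parameters are plain arrays; use :func:`build_stylized_bc`,
    :func:`build_stylized_rgc` or :func:`load_swc` to construct one.
    """

    def __init__(self, cell_kind: str, centers, lengths, diameters,
                 sections, edges, soma_position=None,
                 proximal=None, distal=None):
        if cell_kind not in ("BC", "RGC"):
            raise ConfigError(f"unknown cell_kind {cell_kind!r}")
        self.cell_kind = cell_kind
        self.centers = np.asarray(centers, dtype=float).reshape(-1, 3)
        self.lengths = np.asarray(lengths, dtype=float)
        self.diameters = np.asarray(diameters, dtype=float)
        self.sections = list(sections)
        self.edges = [(int(i), int(j)) for i, j in edges]
        # exact cylinder endpoints (used for faithful SWC export)
        self.proximal = (np.asarray(proximal, dtype=float).reshape(-1, 3)
                         if proximal is not None else None)
        self.distal = (np.asarray(distal, dtype=float).reshape(-1, 3)
                       if distal is not None else None)
        n = self.n_compartments
        if not (len(self.lengths) == len(self.diameters)
                == len(self.sections) == n):
            raise StructuralError("inconsistent array lengths")
        if np.any(self.lengths <= 0) or np.any(self.diameters <= 0):
            raise StructuralError("non-positive compartment geometry")
        valid = BC_SECTIONS if cell_kind == "BC" else RGC_SECTIONS
        for s in self.sections:
            if s not in valid:
                raise StructuralError(
                    f"section label {s!r} not valid for {cell_kind}")
        self._check_connected()
        if soma_position is None:
            soma = [i for i, s in enumerate(self.sections) if s == "soma"]
            soma_position = (self.centers[soma].mean(axis=0) if soma
                             else self.centers[0])
        self.soma_position = np.asarray(soma_position, dtype=float)

    # -- derived geometry ------------------------------------------------

    @property
    def n_compartments(self) -> int:
        return self.centers.shape[0]

    @property
    def rho_axial(self) -> float:
        """Intracellular resistivity, Ω·cm."""
        return RHO_AXIAL_BC if self.cell_kind == "BC" else RHO_AXIAL_RGC

    @property
    def axial_resistance_half(self) -> np.ndarray:
        """R_n/2 in MΩ: ρ_i·(L/2)/(π·(d/2)²) from center to either end."""
        r_cm = self.diameters / 2.0 * 1e-4
        half_len_cm = self.lengths / 2.0 * 1e-4
        return self.rho_axial * half_len_cm / (math.pi * r_cm ** 2) / 1e6

    @property
    def areas_cm2(self) -> np.ndarray:
        """Lateral membrane area per compartment, cm²."""
        return math.pi * self.diameters * self.lengths * 1e-8

    @property
    def capacitances_nf(self) -> np.ndarray:
        """Membrane capacitance per compartment, nF (C_m = 1 µF/cm²)."""
        return C_M_UF_CM2 * self.areas_cm2 * 1e3

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())

    @property
    def z_extent(self) -> tuple[float, float]:
        z = self.centers[:, 2]
        return float(z.min()), float(z.max())

    @property
    def neighbors(self) -> list[tuple[int, ...]]:
        nb: list[list[int]] = [[] for _ in range(self.n_compartments)]
        for i, j in self.edges:
            nb[i].append(j)
            nb[j].append(i)
        return [tuple(v) for v in nb]

    @property
    def compartments(self) -> list[Compartment]:
        rh = self.axial_resistance_half
        nb = self.neighbors
        return [Compartment(i, self.sections[i], self.centers[i],
                            float(self.lengths[i]), float(self.diameters[i]),
                            nb[i], float(rh[i]))
                for i in range(self.n_compartments)]

    def section_indices(self, label: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.sections) if s == label],
                        dtype=int)

    def edge_conductances_us(self) -> np.ndarray:
        """Axial conductance per edge, µS: 1/(R_i/2 + R_j/2)."""
        rh = self.axial_resistance_half
        return np.array([1.0 / (rh[i] + rh[j]) for i, j in self.edges])

    def path_distances_from(self, start: int) -> np.ndarray:
        """Path length (µm) from compartment ``start`` along the tree,
        measured center-to-center."""
        dist = np.full(self.n_compartments, np.inf)
        dist[start] = 0.0
        nb = self.neighbors
        queue = deque([start])
        while queue:
            i = queue.popleft()
            for j in nb[i]:
                step = 0.5 * (self.lengths[i] + self.lengths[j])
                if dist[i] + step < dist[j]:
                    dist[j] = dist[i] + step
                    queue.append(j)
        return dist

    def _check_connected(self) -> None:
        n = self.n_compartments
        if n == 0:
            raise StructuralError("empty morphology")
        seen = np.zeros(n, dtype=bool)
        nb = self.neighbors
        queue = deque([0])
        seen[0] = True
        while queue:
            i = queue.popleft()
            for j in nb[i]:
                if not seen[j]:
                    seen[j] = True
                    queue.append(j)
        if not seen.all():
            missing = int(np.flatnonzero(~seen)[0])
            raise StructuralError(
                f"morphology graph is disconnected (compartment {missing} "
                "unreachable from 0)")

    def summary(self) -> str:
        """One-line-per-section delimited summary (label, n, length, area)."""
        lines = ["section\tn_compartments\tlength_um\tarea_cm2"]
        for label in dict.fromkeys(self.sections):
            idx = self.section_indices(label)
            lines.append(f"{label}\t{len(idx)}\t"
                         f"{self.lengths[idx].sum():.3f}\t"
                         f"{self.areas_cm2[idx].sum():.6e}")
        return "\n".join(lines)


# ----------------------------------------------------------------------
# internal builder
# ----------------------------------------------------------------------

class _Builder:
    def __init__(self):
        self.centers: list[np.ndarray] = []
        self.lengths: list[float] = []
        self.diameters: list[float] = []
        self.sections: list[str] = []
        self.edges: list[tuple[int, int]] = []
        self.p0: list[np.ndarray] = []
        self.p1: list[np.ndarray] = []

    def add(self, center, length, diameter, section,
            parent: int | None = None, axis=(0.0, 0.0, 1.0)) -> int:
        idx = len(self.lengths)
        center = np.asarray(center, dtype=float)
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        self.centers.append(center)
        self.lengths.append(float(length))
        self.diameters.append(float(diameter))
        self.sections.append(section)
        self.p0.append(center - axis * length / 2.0)
        self.p1.append(center + axis * length / 2.0)
        if parent is not None:
            self.edges.append((parent, idx))
        return idx

    def add_cable(self, start, end, diameter, section, max_len,
                  parent: int | None = None) -> int:
        """Straight cable from start to end, subdivided to <= max_len.
        Returns the index of the distal-most compartment."""
        start = np.asarray(start, dtype=float)
        end = np.asarray(end, dtype=float)
        total = float(np.linalg.norm(end - start))
        if total <= 0:
            raise ConfigError("zero-length cable")
        n = max(1, math.ceil(total / max_len - 1e-12))
        direction = (end - start) / total
        seg = total / n
        last = parent
        for k in range(n):
            center = start + direction * seg * (k + 0.5)
            last = self.add(center, seg, diameter, section, parent=last,
                            axis=direction)
        return last

    def graph(self, cell_kind, soma_position=None) -> CompartmentGraph:
        return CompartmentGraph(cell_kind, self.centers, self.lengths,
                                self.diameters, self.sections, self.edges,
                                soma_position=soma_position,
                                proximal=self.p0, distal=self.p1)


# ----------------------------------------------------------------------
# stylized cells
# ----------------------------------------------------------------------

@dataclass
class BCGeometry:
    """Stylized rat ON bipolar cell, vertically oriented across the retina.

    Defaults give a ~45 µm z-extent (dendritic tuft in the OPL near the
    implant, soma in the INL, axon descending the IPL, 8 terminal boutons),
    the depth scale of a degenerate rat retina.
    """

    soma_diameter_um: float = 6.0
    soma_z_um: float = 25.0
    n_dendrites: int = 4
    dendrite_length_um: float = 4.0     # retracted tuft (degenerate retina)
    dendrite_diameter_um: float = 1.0
    dendrite_depth_um: float = 1.5      # vertical reach into the thin OPL band
    axon_length_um: float = 30.0
    axon_diameter_um: float = 0.55
    n_terminals: int = 8
    terminal_diameter_um: float = 3.0
    terminal_length_um: float = 4.0
    terminal_spread_um: float = 4.0     # ring radius of the boutons
    max_compartment_length_um: float = 5.0

    def validate(self):
        for name in ("soma_diameter_um", "dendrite_length_um",
                     "dendrite_diameter_um", "axon_length_um",
                     "axon_diameter_um", "terminal_diameter_um",
                     "terminal_length_um", "max_compartment_length_um"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_terminals < 1 or self.n_dendrites < 1:
            raise ConfigError("need at least one terminal and one dendrite")
        if self.dendrite_depth_um >= self.dendrite_length_um:
            raise ConfigError("dendrite_depth_um must be < dendrite length")


def build_stylized_bc(config: BCGeometry | None = None) -> CompartmentGraph:
    """Build the stylized bipolar cell.  Deterministic given the config."""
    cfg = config or BCGeometry()
    cfg.validate()
    b = _Builder()
    max_len = cfg.max_compartment_length_um
    d_soma = cfg.soma_diameter_um
    soma_pos = np.array([0.0, 0.0, cfg.soma_z_um])

    # soma as a vertical cylinder of length = diameter, subdivided
    soma_bottom = soma_pos + [0, 0, -d_soma / 2]
    soma_top = soma_pos + [0, 0, d_soma / 2]
    soma_last = b.add_cable(soma_bottom, soma_top, d_soma, "soma", max_len)
    soma_first = 0

    # dendritic tuft: branches from the soma bottom into the OPL, mostly
    # lateral (the OPL is a thin stratum a few µm below the INL somata)
    spread = math.sqrt(cfg.dendrite_length_um ** 2 - cfg.dendrite_depth_um ** 2)
    for k in range(cfg.n_dendrites):
        theta = 2 * math.pi * k / cfg.n_dendrites
        tip = soma_bottom + np.array([
            spread * math.cos(theta),
            spread * math.sin(theta),
            -cfg.dendrite_depth_um])
        b.add_cable(soma_bottom, tip, cfg.dendrite_diameter_um, "dendrite",
                    max_len, parent=soma_first)

    # single axon ascending toward the IPL (+z)
    axon_end = soma_top + [0, 0, cfg.axon_length_um]
    axon_last = b.add_cable(soma_top, axon_end, cfg.axon_diameter_um, "axon",
                            max_len, parent=soma_last)

    # terminal boutons on a ring at the axon tip
    for k in range(cfg.n_terminals):
        theta = 2 * math.pi * k / max(cfg.n_terminals, 1)
        center = axon_end + np.array([
            cfg.terminal_spread_um * math.cos(theta),
            cfg.terminal_spread_um * math.sin(theta),
            cfg.terminal_length_um / 2])
        b.add(center, cfg.terminal_length_um, cfg.terminal_diameter_um,
              "terminal", parent=axon_last)

    return b.graph("BC", soma_position=soma_pos)


@dataclass
class RGCGeometry:
    """Stylized ON-alpha ganglion cell: soma in the GCL, dendritic field in
    the IPL, and a >= 950 µm axon running laterally so that the
    spike-propagation threshold criterion can be evaluated."""

    soma_diameter_um: float = 15.0
    soma_z_um: float = 85.0
    n_dendrites: int = 4
    dendrite_length_um: float = 60.0
    dendrite_diameter_um: float = 1.5
    dendrite_depth_um: float = 15.0     # vertical reach into the IPL
    hillock_length_um: float = 10.0     # soma_AIS taper region
    hillock_diameter_um: float = 2.5
    ais_length_um: float = 40.0
    ais_diameter_um: float = 1.2
    axon_length_um: float = 1000.0
    axon_diameter_um: float = 1.0
    max_compartment_length_um: float = 5.0
    min_compartment_length_um: float = 3.0

    def validate(self):
        for name in ("soma_diameter_um", "dendrite_length_um",
                     "dendrite_diameter_um", "hillock_length_um",
                     "ais_length_um", "axon_length_um", "axon_diameter_um",
                     "max_compartment_length_um"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.axon_length_um < 950.0:
            raise ConfigError("axon_length_um must be >= 950 µm so the "
                              "distal-propagation criterion is testable")
        if self.dendrite_depth_um >= self.dendrite_length_um:
            raise ConfigError("dendrite_depth_um must be < dendrite length")


def build_stylized_rgc(config: RGCGeometry | None = None) -> CompartmentGraph:
    """Build the stylized retinal ganglion cell (all five sections)."""
    cfg = config or RGCGeometry()
    cfg.validate()
    b = _Builder()
    max_len = cfg.max_compartment_length_um
    soma_pos = np.array([0.0, 0.0, cfg.soma_z_um])
    d = cfg.soma_diameter_um

    soma_bottom = soma_pos + [0, 0, -d / 2]
    soma_top = soma_pos + [0, 0, d / 2]
    soma_last = b.add_cable(soma_bottom, soma_top, d, "soma", max_len)
    soma_first = 0

    # dendrites descend into the IPL and spread laterally
    lateral = math.sqrt(cfg.dendrite_length_um ** 2 - cfg.dendrite_depth_um ** 2)
    for k in range(cfg.n_dendrites):
        theta = 2 * math.pi * k / cfg.n_dendrites + math.pi / cfg.n_dendrites
        tip = soma_bottom + np.array([lateral * math.cos(theta),
                                      lateral * math.sin(theta),
                                      -cfg.dendrite_depth_um])
        b.add_cable(soma_bottom, tip, cfg.dendrite_diameter_um, "dendrite",
                    max_len, parent=soma_first)

    # hillock -> AIS -> axon, running laterally (+x) in the fiber layer
    x0 = soma_pos + [d / 2, 0, 0]
    x1 = x0 + [cfg.hillock_length_um, 0, 0]
    last = b.add_cable(x0, x1, cfg.hillock_diameter_um, "soma_AIS", max_len,
                       parent=soma_last)
    x2 = x1 + [cfg.ais_length_um, 0, 0]
    last = b.add_cable(x1, x2, cfg.ais_diameter_um, "AIS", max_len, parent=last)
    x3 = x2 + [cfg.axon_length_um, 0, 0]
    b.add_cable(x2, x3, cfg.axon_diameter_um, "axon", max_len, parent=last)

    return b.graph("RGC", soma_position=soma_pos)


# ----------------------------------------------------------------------
# SWC interchange
# ----------------------------------------------------------------------

def load_swc(path, cell_kind: str, max_compartment_length: float = 5.0,
             type_map: dict[int, str] | None = None) -> CompartmentGraph:
    """Load a standard 7-column SWC morphology.

    Each parent->child segment is subdivided into compartments no longer
    than ``max_compartment_length`` µm, with diameter 2x the child radius.
    The root node becomes a compartment of its own (length = 2·radius)
    only when it maps to the soma; for plain cable fixtures the sum of
    compartment lengths then equals the traced cable length exactly.
    """
    if max_compartment_length <= 0:
        raise ConfigError("max_compartment_length must be positive")
    tmap = dict(DEFAULT_TYPE_MAP)
    if type_map:
        tmap.update(type_map)

    nodes: dict[int, tuple[int, np.ndarray, float, int]] = {}
    order: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCParseError(
                    f"expected 7 columns, got {len(parts)}", lineno)
            try:
                nid = int(parts[0])
                ntype = int(parts[1])
                xyz = np.array([float(parts[2]), float(parts[3]),
                                float(parts[4])])
                radius = float(parts[5])
                parent = int(parts[6])
            except ValueError as exc:
                raise SWCParseError(str(exc), lineno) from None
            if radius <= 0:
                raise SWCParseError("non-positive radius", lineno)
            if nid in nodes:
                raise SWCParseError(f"duplicate node id {nid}", lineno)
            nodes[nid] = (ntype, xyz, radius, parent)
            order.append(nid)

    if not nodes:
        raise SWCParseError("no nodes in SWC file")
    roots = [nid for nid in order if nodes[nid][3] == -1]
    if len(roots) != 1:
        raise StructuralError(f"expected exactly one root, found {len(roots)}")
    for nid in order:
        parent = nodes[nid][3]
        if parent != -1 and parent not in nodes:
            raise StructuralError(
                f"node {nid} references missing parent {parent}")

    def section_of(ntype: int) -> str:
        if ntype not in tmap:
            raise StructuralError(f"SWC type {ntype} has no section mapping")
        return tmap[ntype]

    b = _Builder()
    node_comp: dict[int, int | None] = {}
    root = roots[0]
    rtype, rxyz, rrad, _ = nodes[root]
    if section_of(rtype) == "soma":
        node_comp[root] = b.add(rxyz, 2 * rrad, 2 * rrad, "soma")
    else:
        node_comp[root] = None  # pure cable: root is just a start point

    for nid in order:
        if nid == root:
            continue
        ntype, xyz, radius, parent = nodes[nid]
        pxyz = nodes[parent][1]
        parent_comp = node_comp[parent]
        seg = float(np.linalg.norm(xyz - pxyz))
        if seg <= 0:
            raise StructuralError(f"zero-length segment at node {nid}")
        node_comp[nid] = b.add_cable(pxyz, xyz, 2 * radius, section_of(ntype),
                                     max_compartment_length,
                                     parent=parent_comp)

    return b.graph(cell_kind)


def save_swc(graph: CompartmentGraph, path,
             type_map: dict[int, str] | None = None) -> None:
    """Write the morphology back out as SWC nodes.

    Each compartment becomes one node placed so that the node-to-parent
    distance equals the compartment length exactly (a soma root becomes
    a single node re-imported as a 2·radius stub; a non-soma root gets
    an extra start node).  Re-importing with the same maximum
    compartment length therefore reproduces the compartment count and
    total length exactly; branches attached off their parent's distal
    end (e.g. terminal boutons on the axon tip) keep their length but
    shift position slightly, since SWC cannot represent offset
    attachment points.
    """
    tmap = dict(DEFAULT_TYPE_MAP)
    if type_map:
        tmap.update(type_map)
    inv = {v: k for k, v in tmap.items()}

    nb = graph.neighbors
    soma = graph.section_indices("soma")
    root = int(soma[0]) if len(soma) else 0
    if graph.distal is not None:
        distal = graph.distal
        proximal = graph.proximal
    else:
        distal = graph.centers
        proximal = graph.centers

    node_of: dict[int, int] = {}
    lines = []
    counter = [0]

    def emit(x, ntype, radius, parent_node):
        counter[0] += 1
        lines.append(f"{counter[0]} {ntype} {x[0]:.9f} {x[1]:.9f} {x[2]:.9f} "
                     f"{radius:.9f} {parent_node}")
        return counter[0]

    pos_of: dict[int, np.ndarray] = {}
    rsec = graph.sections[root]
    if rsec == "soma":
        # children of a loaded soma stub attach at its center
        node_of[root] = emit(graph.centers[root], inv[rsec],
                             graph.lengths[root] / 2.0, -1)
        pos_of[root] = np.asarray(graph.centers[root], dtype=float)
    else:
        start_node = emit(proximal[root], inv[rsec],
                          graph.diameters[root] / 2.0, -1)
        node_of[root] = emit(distal[root], inv[rsec],
                             graph.diameters[root] / 2.0, start_node)
        pos_of[root] = np.asarray(distal[root], dtype=float)

    seen = {root}
    queue = deque([root])
    while queue:
        i = queue.popleft()
        for j in nb[i]:
            if j in seen:
                continue
            seen.add(j)
            # place the node so its distance to the parent node equals
            # the compartment length exactly
            vec = np.asarray(distal[j], dtype=float) - pos_of[i]
            norm = float(np.linalg.norm(vec))
            direction = vec / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
            pos = pos_of[i] + direction * graph.lengths[j]
            node_of[j] = emit(pos, inv[graph.sections[j]],
                              graph.diameters[j] / 2.0, node_of[i])
            pos_of[j] = pos
            queue.append(j)

    with open(path, "w") as fh:
        fh.write("# SWC export\n")
        fh.write("\n".join(lines) + "\n")
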