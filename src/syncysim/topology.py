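"""Builders for 1-D chains and k-cube lattices, site classes, pacemaker maps."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .membrane import MembraneParams

__all__ = [
    "Topology",
    "PacemakerSpec",
    "build_chain",
    "build_cube",
    "classify_site",
    "site_cell",
    "site_census",
    "place_pacemakers",
]

BASELINE_GNA = 0.12  # S/cm^2, the non-pacemaking peak Na conductance


@dataclass(frozen=True)
class Topology:
    """Cell-level connectivity of a syncytium.

    ``adjacency`` lists each coupled cell pair once, ``(a, b)`` with a < b;
    every pair carries exactly one gap junction.  ``coordinates`` holds the
    integer lattice position of each cell (1-D index for chains, (x, y, z)
    for cubes).
    """

    kind: str
    n_cells: int
    adjacency: tuple[tuple[int, int], ...]
    coordinates: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        for a, b in self.adjacency:
            if a == b:
                raise ValueError("self-links are not allowed")
            if not (0 <= a < self.n_cells and 0 <= b < self.n_cells):
                raise ValueError("adjacency references unknown cell")

    @property
    def n_junctions(self) -> int:
        return len(self.adjacency)

    def neighbors(self, cell: int) -> list[int]:
        out = []
        for a, b in self.adjacency:
            if a == cell:
                out.append(b)
            elif b == cell:
                out.append(a)
        return sorted(out)

    @property
    def central_cell(self) -> int:
        """The unique middle cell (odd chain length / odd cube side)."""
        if self.kind == "chain":
            if self.n_cells % 2 == 0:
                raise ValueError("even chain has no unique central cell")
            return (self.n_cells - 1) // 2
        k = round(self.n_cells ** (1 / 3))
        if k % 2 == 0:
            raise ValueError("even-sided cube has no unique central cell")
        c = (k - 1) // 2
        return _cell_index(c, c, c, k)

    def dump_adjacency(self) -> str:
        """Adjacency list as tab-delimited text (one pair per line)."""
        lines = [f"{a}\t{b}" for a, b in self.adjacency]
        return "\n".join(lines) + ("\n" if lines else "")


def build_chain(n_cells: int) -> Topology:
    """Linear chain of ``n_cells`` with n-1 junctions between neighbours."""
    if n_cells < 1:
        raise ValueError("a chain needs at least one cell")
    adjacency = tuple((i, i + 1) for i in range(n_cells - 1))
    coords = np.arange(n_cells).reshape(-1, 1)
    return Topology("chain", n_cells, adjacency, coords)


def _cell_index(x: int, y: int, z: int, k: int) -> int:
    return x * k * k + y * k + z


def build_cube(k: int) -> Topology:
    """k x k x k lattice with 6-neighbour (face-adjacent) coupling.

    Yields k^3 cells and 3 k^2 (k-1) junctions, one per face-adjacent pair.
    """
    if k < 1:
        raise ValueError("cube side must be >= 1")
    coords = np.array([(x, y, z) for x in range(k) for y in range(k) for z in range(k)])
    adjacency = []
    for x in range(k):
        for y in range(k):
            for z in range(k):
                i = _cell_index(x, y, z, k)
                if x + 1 < k:
                    adjacency.append((i, _cell_index(x + 1, y, z, k)))
                if y + 1 < k:
                    adjacency.append((i, _cell_index(x, y + 1, z, k)))
                if z + 1 < k:
                    adjacency.append((i, _cell_index(x, y, z + 1, k)))
    adjacency = tuple(sorted(tuple(sorted(p)) for p in adjacency))
    return Topology("cube", k**3, adjacency, coords)


def classify_site(topology: Topology, cell: int) -> str:
    """Site class of a cube cell: center, vertex, edge, surface or interior.

    Classification counts boundary coordinates (3 -> vertex, 2 -> edge,
    1 -> surface, 0 -> interior); the unique middle cell of an odd cube is
    the center.  Neighbour counts follow: vertex 3, edge 4, surface 5,
    interior/center 6.
    """
    if topology.kind != "cube":
        raise ValueError("site classes are defined for cube topologies only")
    k = round(topology.n_cells ** (1 / 3))
    x, y, z = topology.coordinates[cell]
    n_boundary = sum(int(c in (0, k - 1)) for c in (x, y, z))
    if n_boundary == 0 and k % 2 == 1 and all(c == (k - 1) // 2 for c in (x, y, z)):
        return "center"
    return {3: "vertex", 2: "edge", 1: "surface", 0: "interior"}[n_boundary]


def site_census(topology: Topology) -> dict[str, int]:
    """Number of cells in each site class (partition of all k^3 cells)."""
    census: dict[str, int] = {}
    for cell in range(topology.n_cells):
        cls = classify_site(topology, cell)
        census[cls] = census.get(cls, 0) + 1
    return census


def site_cell(topology: Topology, site: str) -> int:
    """The canonical representative cell of a site class.

    For reproducibility the cell chosen is the one of that class closest to
    the midpoint of its own edge/face (so 'edge' picks an edge-midpoint cell,
    'surface' a face-centre cell), ties broken by lexicographically smallest
    coordinates.  'center' requires an odd cube side; 'vertex' returns the
    origin corner.
    """
    if topology.kind != "cube":
        raise ValueError("named sites are defined for cube topologies only")
    k = round(topology.n_cells ** (1 / 3))
    if site == "center":
        return topology.central_cell  # raises for even k
    candidates = [c for c in range(topology.n_cells)
                  if classify_site(topology, c) == site]
    if not candidates:
        raise ValueError(f"no cell of class {site!r} in this topology")
    mid = (k - 1) / 2.0

    def badness(cell: int):
        coord = topology.coordinates[cell]
        # distance of the non-boundary coordinates from the edge/face midpoint
        interior = [c for c in coord if c not in (0, k - 1)]
        dist = sum((c - mid) ** 2 for c in interior)
        return (dist, tuple(coord))

    return min(candidates, key=badness)


@dataclass(frozen=True)
class PacemakerSpec:
    """A pacemaker cell: raised peak Na conductance at one cell."""

    cell: int
    gbar_na: float

    def __post_init__(self) -> None:
        if self.gbar_na <= BASELINE_GNA:
            raise ValueError(
                f"pacemaker gbar_na must exceed the baseline {BASELINE_GNA} S/cm^2"
            )


def place_pacemakers(
    topology: Topology,
    specs: list[PacemakerSpec],
    baseline: MembraneParams | None = None,
) -> list[MembraneParams]:
    """Per-cell membrane map with pacemaker overrides applied.

    All cells get the baseline parameters except the listed pacemakers, whose
    peak Na conductance is overridden.  Duplicate cell ids are rejected.
    """
    base = baseline if baseline is not None else MembraneParams()
    cells = [s.cell for s in specs]
    if len(set(cells)) != len(cells):
        raise ValueError("duplicate pacemaker cell ids")
    for c in cells:
        if not (0 <= c < topology.n_cells):
            raise ValueError(f"pacemaker cell {c} outside topology")
    membrane_map = [base] * topology.n_cells
    for s in specs:
        membrane_map[s.cell] = base.with_gbar_na(s.gbar_na)
    return membrane_map
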