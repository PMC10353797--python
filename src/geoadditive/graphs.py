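"""Region adjacency graphs for structured spatial effects.

A :class:`RegionGraph` is an undirected, irreflexive graph over labelled
administrative regions (here: the divisions of Bangladesh).  Regions that
share a boundary are neighbours; the intrinsic CAR prior on the structured
spatial effect smooths each region toward the mean of its neighbours.

The bundled division presets are plausible hand-drawn approximations of
the first-level administrative adjacency (7 divisions for the 2014 survey
round, 8 after Mymensingh was carved out of Dhaka in 2015); they exist so
the pipeline can be exercised and tested, and are not an authoritative
cartographic product.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class GraphValidationError(ValueError):
    """Raised when an adjacency structure is malformed."""


@dataclass(frozen=True)
class RegionGraph:
    """Undirected region adjacency with deterministic region ordering."""

    region_ids: tuple[str, ...]
    edges: frozenset[frozenset]
    neighbors: dict = field(compare=False)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def neighbor_counts(self) -> dict:
        return {k: len(v) for k, v in self.neighbors.items()}

    def index(self, region: str) -> int:
        return self.region_ids.index(region)

    def isolated_regions(self) -> list:
        return [k for k, v in self.neighbors.items() if not v]


# Approximate division adjacency; deliberately synthetic stand-ins for the
# real boundary files (which the package does not ship).
_PRESETS = {
    "bdhs2014": (
        ["Barisal", "Chittagong", "Dhaka", "Khulna", "Rajshahi", "Rangpur", "Sylhet"],
        [
            ("Barisal", "Khulna"),
            ("Barisal", "Dhaka"),
            ("Barisal", "Chittagong"),
            ("Chittagong", "Dhaka"),
            ("Chittagong", "Sylhet"),
            ("Dhaka", "Khulna"),
            ("Dhaka", "Rajshahi"),
            ("Dhaka", "Rangpur"),
            ("Dhaka", "Sylhet"),
            ("Khulna", "Rajshahi"),
            ("Rajshahi", "Rangpur"),
        ],
    ),
    "bdhs2018": (
        [
            "Barisal",
            "Chittagong",
            "Dhaka",
            "Khulna",
            "Mymensingh",
            "Rajshahi",
            "Rangpur",
            "Sylhet",
        ],
        [
            ("Barisal", "Khulna"),
            ("Barisal", "Dhaka"),
            ("Barisal", "Chittagong"),
            ("Chittagong", "Dhaka"),
            ("Chittagong", "Sylhet"),
            ("Dhaka", "Khulna"),
            ("Dhaka", "Rajshahi"),
            ("Dhaka", "Mymensingh"),
            ("Dhaka", "Sylhet"),
            ("Khulna", "Rajshahi"),
            ("Mymensingh", "Rangpur"),
            ("Mymensingh", "Sylhet"),
            ("Rajshahi", "Rangpur"),
        ],
    ),
    "lattice2x2": (
        ["R00", "R01", "R10", "R11"],
        [("R00", "R01"), ("R00", "R10"), ("R01", "R11"), ("R10", "R11")],
    ),
}


def build_region_graph(region_ids, edges) -> RegionGraph:
    """Validate an edge list and build a :class:`RegionGraph`.

    Duplicate edges (in either orientation) collapse to a single
    undirected edge.  Self-loops and edges naming undeclared regions are
    rejected.  Regions are kept in the order given, which fixes the row
    order of every spatial matrix downstream.
    """
    region_ids = tuple(str(r) for r in region_ids)
    if len(set(region_ids)) != len(region_ids):
        raise GraphValidationError("duplicate region labels")
    known = set(region_ids)
    undirected = set()
    for a, b in edges:
        a, b = str(a), str(b)
        if a == b:
            raise GraphValidationError(f"self-loop on region {a!r}")
        if a not in known or b not in known:
            raise GraphValidationError(f"edge ({a!r}, {b!r}) references an unknown region")
        undirected.add(frozenset((a, b)))
    neighbors = {r: set() for r in region_ids}
    for e in undirected:
        a, b = sorted(e)
        neighbors[a].add(b)
        neighbors[b].add(a)
    return RegionGraph(
        region_ids=region_ids,
        edges=frozenset(undirected),
        neighbors={k: frozenset(v) for k, v in neighbors.items()},
    )


def make_region_graph(preset_or_edges) -> RegionGraph:
    """Build a graph from a preset name or an (region_ids, edges) pair.

    Presets: ``"bdhs2014"`` (7 divisions), ``"bdhs2018"`` (8 divisions,
    Mymensingh separate), ``"lattice2x2"`` (toy rook lattice).
    """
    if isinstance(preset_or_edges, str):
        try:
            region_ids, edges = _PRESETS[preset_or_edges]
        except KeyError:
            raise GraphValidationError(
                f"unknown graph preset {preset_or_edges!r}; "
                f"known: {sorted(_PRESETS)}"
            ) from None
        return build_region_graph(region_ids, edges)
    region_ids, edges = preset_or_edges
    return build_region_graph(region_ids, edges)


def write_adjacency(graph: RegionGraph, edge_path, node_path=None) -> None:
    """Write a two-column edge list (and optionally one region per line)."""
    with open(edge_path, "w") as fh:
        for e in sorted(tuple(sorted(x)) for x in graph.edges):
            fh.write(f"{e[0]}\t{e[1]}\n")
    if node_path is not None:
        with open(node_path, "w") as fh:
            for r in graph.region_ids:
                fh.write(r + "\n")


def read_adjacency(edge_path, node_path=None) -> RegionGraph:
    """Read a graph from a two-column edge list.

    If ``node_path`` is given it fixes the region set and ordering
    (allowing regions with no edges to be declared); otherwise regions are
    taken from the edge list in sorted order.
    """
    edges = []
    with open(edge_path, newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) != 2:
                raise GraphValidationError(
                    f"{edge_path}:{lineno}: expected two region labels, got {line!r}"
                )
            edges.append((parts[0], parts[1]))
    if node_path is not None:
        with open(node_path, newline=None) as fh:
            region_ids = [ln.strip() for ln in fh if ln.strip()]
    else:
        region_ids = sorted({r for e in edges for r in e})
    return build_region_graph(region_ids, edges)
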