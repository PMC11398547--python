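"""Complex census: connected components over bond modes, canonical topology labels.

A microstate is converted into a multiset of species by building the
particle-bond graph (vertices: excited particle modes; edges: excited bond
modes) and canonically labeling each connected component.  Chains, rings,
trees, and groves (one ring with pendant trees) get structured labels; any
other topology falls back to a brute-force canonical string.

Canonicalization respects vertex colors (particle fields), edge colors (bond
field plus the site port occupied at each end plus directedness), ring
rotation/reflection symmetry, and is invariant under relabeling of particle
indices.
"""

from __future__ import annotations

import hashlib
import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import networkx as nx
import numpy as np
import pandas as pd

from .fock import CompiledModel, Microstate, compile_model
from .model import ModelSpec
from .ssa import Trajectory

__all__ = [
    "StructuralIntegrityError",
    "SpeciesLabel",
    "microstate_to_complexes",
    "build_complex_graphs",
    "classify_topology",
    "trajectory_census",
    "ensemble_stats",
    "species_count_labeler",
]

BRUTE_FORCE_LIMIT = 7


class StructuralIntegrityError(ValueError):
    """A bond without its endpoint excitations, or an orphan site excitation."""


@dataclass(frozen=True)
class SpeciesLabel:
    kind: str  # chain | ring | tree | grove | other
    size: int  # number of component particles
    canonical: str

    @property
    def name(self) -> str:
        if self.kind == "chain":
            if self.size == 1:
                return "monomer"
            if self.size == 2 and "~sym~" in self.canonical:
                return "dimer"
            base = f"chain-{self.size}"
        elif self.kind == "ring":
            base = f"ring-{self.size}"
        else:
            base = f"{self.kind}-{self.size}"
        if self.kind in ("tree", "grove", "other") or _is_heterogeneous(self.canonical):
            digest = hashlib.md5(self.canonical.encode()).hexdigest()[:8]
            return f"{base}:{digest}"
        return base

    def __repr__(self) -> str:
        return f"SpeciesLabel({self.name})"


def _is_heterogeneous(canonical: str) -> bool:
    return "#het#" in canonical


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------


def _site_host(model: ModelSpec, site_or_particle: str) -> str:
    spec = model.field(site_or_particle)
    if spec.kind == "site":
        return spec.host
    return spec.name  # bond endpoint given directly as a particle field


def build_complex_graphs(
    s: Union[Microstate, int],
    model: Union[ModelSpec, CompiledModel],
    check_integrity: bool = True,
) -> List[nx.MultiGraph]:
    """Connected components of the particle-bond graph of a microstate."""
    cm = model if isinstance(model, CompiledModel) else compile_model(model)
    spec = cm.model
    modes = cm.state_of(s) if isinstance(s, int) else s

    particles = set()
    sites = set()
    bonds = []
    for m in modes:
        kind = spec.field(m.field).kind
        if kind == "particle":
            particles.add((m.field, m.indices[0]))
        elif kind == "site":
            sites.add((m.field, m.indices[0]))
        else:
            bonds.append(m)

    g = nx.MultiGraph()
    for p in particles:
        g.add_node(p, color=p[0])
    used_sites: Counter = Counter()
    for m in bonds:
        f = spec.field(m.field)
        e1, e2 = f.endpoints
        i, j = m.indices
        h1 = (_site_host(spec, e1), i)
        h2 = (_site_host(spec, e2), j)
        for h, e, idx in ((h1, e1, i), (h2, e2, j)):
            if h not in g:
                raise StructuralIntegrityError(
                    f"bond {m} references missing particle {h[0]}({h[1]})"
                )
            if spec.field(e).kind == "site":
                if check_integrity and (e, idx) not in sites:
                    raise StructuralIntegrityError(
                        f"bond {m} requires unexcited site {e}({idx})"
                    )
                used_sites[(e, idx)] += 1
        g.add_edge(
            h1,
            h2,
            bond=m.field,
            ports=(e1, e2),
            directed=not f.symmetric,
            _first=h1,  # which endpoint carries ports[0] / the (i, .) index
        )
    if check_integrity:
        for site in sites:
            if used_sites.get(site, 0) != 1:
                raise StructuralIntegrityError(
                    f"site {site[0]}({site[1]}) excited but used by "
                    f"{used_sites.get(site, 0)} bonds"
                )
    return [g.subgraph(c).copy() for c in nx.connected_components(g)]


# ---------------------------------------------------------------------------
# Canonical labeling
# ---------------------------------------------------------------------------


def _edge_token(data: Mapping, from_first: bool) -> str:
    """Deterministic edge encoding relative to a traversal direction."""
    p1, p2 = data["ports"]
    if not data["directed"]:
        if p1 == p2:
            return f"{data['bond']}~sym~{p1}"
        a, b = (p1, p2) if from_first else (p2, p1)
        return f"{data['bond']}~{a}>{b}"
    a, b = (p1, p2) if from_first else (p2, p1)
    arrow = ">" if from_first else "<"
    return f"{data['bond']}{arrow}{a}:{b}"


def _vcolor(g: nx.MultiGraph, v) -> str:
    return g.nodes[v]["color"]


def _mark_orientation(g: nx.MultiGraph) -> None:
    # fallback for hand-built graphs: record which endpoint carries ports[0]
    for u, v, key, data in g.edges(keys=True, data=True):
        if "_first" not in data:
            data["_first"] = u


def classify_topology(g: nx.MultiGraph) -> SpeciesLabel:
    """Canonical species label of one connected complex graph."""
    _mark_orientation(g)
    n = g.number_of_nodes()
    m = g.number_of_edges()
    degrees = dict(g.degree())  # self-loops count twice
    maxdeg = max(degrees.values()) if degrees else 0
    het = len({_vcolor(g, v) for v in g}) > 1 or len(
        {_edge_token(d, True) for *_, d in g.edges(data=True)}
    ) > 1

    if m == n - 1 and maxdeg <= 2:
        kind, canon = "chain", _canon_path(g)
    elif m == n and n > 0 and all(d == 2 for d in degrees.values()):
        kind, canon = "ring", _canon_cycle(g)
    elif m == n - 1:
        kind, canon = "tree", _canon_tree(g)
    elif m == n:
        kind, canon = "grove", _canon_unicyclic(g)
    else:
        kind, canon = "other", _canon_brute(g)
    if het:
        canon = "#het#" + canon
    return SpeciesLabel(kind, n, canon)


def _walk_encoding(g: nx.MultiGraph, order: Sequence, edges: Sequence[Tuple]) -> str:
    parts = []
    for i, v in enumerate(order):
        parts.append(f"v:{_vcolor(g, v)}")
        if i < len(edges):
            u, w, data = edges[i]
            parts.append(_edge_token(data, data.get("_first") == u))
    return "|".join(parts)


def _canon_path(g: nx.MultiGraph) -> str:
    if g.number_of_nodes() == 1:
        v = next(iter(g))
        return f"v:{_vcolor(g, v)}"
    ends = [v for v, d in g.degree() if d == 1]
    best = None
    for start in ends:
        order = [start]
        edges = []
        prev = None
        cur = start
        while True:
            nxts = [
                (u, data)
                for u in g[cur]
                for key, data in g[cur][u].items()
                if u != prev
            ]
            if not nxts:
                break
            u, data = nxts[0]
            edges.append((cur, u, data))
            order.append(u)
            prev, cur = cur, u
        enc = _walk_encoding(g, order, edges)
        if best is None or enc < best:
            best = enc
    return best


def _cycle_walks(g: nx.MultiGraph):
    """All closed walks (order, edges) of a pure cycle, over starts/directions."""
    nodes = list(g.nodes)
    n = len(nodes)
    for start in nodes:
        incident = [
            (u, key, data)
            for u in g[start]
            for key, data in g[start][u].items()
        ]
        # self loop: single walk
        for first_u, first_key, first_data in incident:
            order = [start]
            edges = [(start, first_u, first_data)]
            used = {(frozenset((start, first_u)), first_key)}
            cur, prev_key = first_u, first_key
            ok = True
            while cur != start:
                order.append(cur)
                nxts = [
                    (u, key, data)
                    for u in g[cur]
                    for key, data in g[cur][u].items()
                    if (frozenset((cur, u)), key) not in used
                ]
                if not nxts:
                    ok = False
                    break
                u, key, data = nxts[0]
                edges.append((cur, u, data))
                used.add((frozenset((cur, u)), key))
                cur = u
            if ok and len(edges) == g.number_of_edges():
                yield order, edges


def _canon_cycle(g: nx.MultiGraph) -> str:
    best = None
    for order, edges in _cycle_walks(g):
        enc = _walk_encoding(g, order + [order[0]], edges)
        if best is None or enc < best:
            best = enc
    return best


def _rooted_encoding(g: nx.MultiGraph, v, parent) -> str:
    children = []
    for u in g[v]:
        if u == parent:
            continue
        for key, data in g[v][u].items():
            token = _edge_token(data, data.get("_first") == v)
            children.append(f"({token}{_rooted_encoding(g, u, v)})")
    return f"v:{_vcolor(g, v)}[" + "".join(sorted(children)) + "]"


def _tree_centroids(g: nx.MultiGraph) -> List:
    if g.number_of_nodes() == 1:
        return list(g.nodes)
    gg = nx.Graph(g)  # iterative leaf pruning leaves 1 or 2 centroids
    while gg.number_of_nodes() > 2:
        layer = [v for v in gg if gg.degree(v) == 1]
        gg.remove_nodes_from(layer)
    return list(gg.nodes)


def _canon_tree(g: nx.MultiGraph) -> str:
    return min(_rooted_encoding(g, c, None) for c in _tree_centroids(g))


def _canon_unicyclic(g: nx.MultiGraph) -> str:
    # peel leaves to expose the cycle
    core = nx.MultiGraph(g)
    while True:
        leaves = [v for v in core if core.degree(v) == 1]
        if not leaves:
            break
        core.remove_nodes_from(leaves)
    cycle_nodes = set(core.nodes)

    def pendant(v) -> str:
        # AHU encoding of the tree hanging off cycle vertex v
        parts = []
        for u in g[v]:
            if u in cycle_nodes:
                continue
            for key, data in g[v][u].items():
                token = _edge_token(data, data.get("_first") == v)
                parts.append(f"({token}{_rooted_encoding(g, u, v)})")
        return "".join(sorted(parts))

    best = None
    for order, edges in _cycle_walks(core):
        parts = []
        for i, v in enumerate(order):
            parts.append(f"v:{_vcolor(g, v)}{{{pendant(v)}}}")
            u, w, data = edges[i]
            parts.append(_edge_token(data, data.get("_first") == u))
        enc = "|".join(parts)
        if best is None or enc < best:
            best = enc
    return best


def _canon_brute(g: nx.MultiGraph) -> str:
    n = g.number_of_nodes()
    if n > BRUTE_FORCE_LIMIT:
        raise ValueError(
            f"generic canonical labeling limited to {BRUTE_FORCE_LIMIT} vertices "
            f"(got {n})"
        )
    nodes = list(g.nodes)
    best = None
    for perm in itertools.permutations(range(n)):
        relabel = {nodes[i]: perm[i] for i in range(n)}
        vcols = [None] * n
        for v, i in relabel.items():
            vcols[i] = _vcolor(g, v)
        edges = []
        for u, v, key, data in g.edges(keys=True, data=True):
            a, b = relabel[u], relabel[v]
            if a <= b:
                edges.append((a, b, _edge_token(data, data.get("_first") == u)))
            else:
                edges.append((b, a, _edge_token(data, data.get("_first") == v)))
        enc = ";".join(f"v{i}:{c}" for i, c in enumerate(vcols)) + "//" + ";".join(
            f"{a}-{b}:{t}" for a, b, t in sorted(edges)
        )
        if best is None or enc < best:
            best = enc
    return best


# ---------------------------------------------------------------------------
# Census
# ---------------------------------------------------------------------------

_MONOMER_CACHE: Dict[str, SpeciesLabel] = {}


def _monomer_label(field: str) -> SpeciesLabel:
    if field not in _MONOMER_CACHE:
        _MONOMER_CACHE[field] = SpeciesLabel("chain", 1, f"v:{field}")
    return _MONOMER_CACHE[field]


def microstate_to_complexes(
    s: Union[Microstate, int],
    model: Union[ModelSpec, CompiledModel],
    check_integrity: bool = True,
) -> Counter:
    """Multiset of species labels of all complexes in a microstate."""
    cm = model if isinstance(model, CompiledModel) else compile_model(model)
    if isinstance(s, int):
        # fast path: no bonds excited -> every excited particle is a monomer
        bond_mask = 0
        for f in cm.model.fields:
            if f.kind == "bond":
                bond_mask |= cm.field_bitmask(f.name)
        if s & bond_mask == 0:
            out: Counter = Counter()
            site_mask = 0
            for f in cm.model.fields:
                if f.kind == "site":
                    site_mask |= cm.field_bitmask(f.name)
            if check_integrity and s & site_mask:
                raise StructuralIntegrityError("site excited without any bond")
            for f in cm.model.fields:
                if f.kind == "particle":
                    cnt = (s & cm.field_bitmask(f.name)).bit_count()
                    if cnt:
                        out[_monomer_label(f.name)] = cnt
            return out
    graphs = build_complex_graphs(s, cm, check_integrity=check_integrity)
    return Counter(classify_topology(g) for g in graphs)


def species_count_labeler(cm: CompiledModel):
    """Labeler for macrostate_distribution: mask -> frozen species count vector."""
    cache: Dict[int, Tuple] = {}

    def labeler(mask: int, compiled: CompiledModel):
        if mask not in cache:
            counts = microstate_to_complexes(mask, compiled)
            cache[mask] = tuple(sorted((lbl.name, c) for lbl, c in counts.items()))
        return cache[mask]

    return labeler


def trajectory_census(
    traj: Trajectory,
    times: Sequence[float],
    model: Optional[Union[ModelSpec, CompiledModel]] = None,
) -> pd.DataFrame:
    """Piecewise-constant species counts at query times (rows: time, cols: species)."""
    cm = traj.compiled if model is None else (
        model if isinstance(model, CompiledModel) else compile_model(model)
    )
    times = list(times)
    if times and (min(times) < 0 or max(times) > traj.t_end):
        raise ValueError("query times must lie within [0, trajectory end]")
    masks = traj.masks_at(times)
    rows = []
    cache: Dict[int, Dict[str, int]] = {}
    for mask in masks:
        if mask not in cache:
            counts = microstate_to_complexes(mask, cm)
            cache[mask] = {lbl.name: c for lbl, c in counts.items()}
        rows.append(cache[mask])
    df = pd.DataFrame(rows, index=pd.Index(times, name="time")).fillna(0).astype(int)
    return df.reindex(sorted(df.columns), axis=1)


def ensemble_stats(runs: Sequence[pd.DataFrame]) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Pointwise mean and sample standard deviation across census tables.

    All runs must share one time grid.  Species absent from every run are
    omitted (they never appear as columns); species absent from some runs
    count as zero there.
    """
    if len(runs) < 2:
        raise ValueError("need at least two runs")
    grid = runs[0].index
    for df in runs[1:]:
        if not df.index.equals(grid):
            raise ValueError("mismatched time grids across runs")
    cols = sorted(set().union(*[set(df.columns) for df in runs]))
    stack = np.stack([df.reindex(columns=cols, fill_value=0).to_numpy() for df in runs])
    mean = pd.DataFrame(stack.mean(axis=0), index=grid, columns=cols)
    sd = pd.DataFrame(stack.std(axis=0, ddof=1), index=grid, columns=cols)
    return mean, sd
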