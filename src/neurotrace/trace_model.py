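"""Graph representation of neurite traces.

A trace is a graph of nodes, each carrying a 3D physical position and a
caliber (local neurite radius), with arbitrary symmetric adjacency. Unlike
the traditional SWC tree format, this representation permits loops, which
arise naturally in initial traces before their topology has been verified.
SWC is supported as an import/export format with an explicit cycle guard.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx
import numpy as np


class CyclicTraceError(ValueError):
    """Raised when exporting a cyclic trace to a format that forbids loops."""


@dataclass
class Branch:
    """A maximal chain of degree-2 nodes between two topology-critical nodes.

    ``nodes`` lists node ids in path order; endpoints have degree != 2 in the
    parent trace (or are the split point of an isolated cycle). ``length`` is
    the sum of edge lengths; ``mean_intensity`` is filled in when a reference
    stack is available.
    """

    nodes: list[int]
    length: float
    mean_intensity: float | None = None


class Trace:
    """A neurite trace: nodes with positions/calibers plus symmetric adjacency."""

    def __init__(self) -> None:
        self.graph = nx.Graph()

    # -- construction -----------------------------------------------------
    def add_node(self, position, caliber: float = 1.0) -> int:
        """Append a node; returns its integer id."""
        if caliber <= 0:
            raise ValueError(f"caliber must be positive, got {caliber}")
        nid = self.graph.number_of_nodes()
        while self.graph.has_node(nid):  # ids need not be dense after deletions
            nid += 1
        self.graph.add_node(nid, pos=np.asarray(position, dtype=float), radius=float(caliber))
        return nid

    def add_edge(self, a: int, b: int) -> None:
        if a == b:
            raise ValueError("self-links are not allowed")
        self.graph.add_edge(a, b)

    # -- basic queries ----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def position(self, nid: int) -> np.ndarray:
        return self.graph.nodes[nid]["pos"]

    def caliber(self, nid: int) -> float:
        return self.graph.nodes[nid]["radius"]

    def positions(self, nids=None) -> np.ndarray:
        nids = list(self.graph.nodes) if nids is None else list(nids)
        if not nids:
            return np.zeros((0, 3))
        return np.array([self.graph.nodes[n]["pos"] for n in nids])

    def degree(self, nid: int) -> int:
        return self.graph.degree[nid]

    def terminal_nodes(self) -> list[int]:
        """Nodes of degree 1."""
        return [n for n in self.graph.nodes if self.graph.degree[n] == 1]

    def branch_nodes(self) -> list[int]:
        """Nodes of degree >= 3."""
        return [n for n in self.graph.nodes if self.graph.degree[n] >= 3]

    def edge_length(self, a: int, b: int) -> float:
        return float(np.linalg.norm(self.position(a) - self.position(b)))

    def total_length(self) -> float:
        return sum(self.edge_length(a, b) for a, b in self.graph.edges)

    def has_cycle(self) -> bool:
        return self.graph.number_of_edges() >= 1 and bool(nx.cycle_basis(self.graph))

    def copy(self) -> "Trace":
        t = Trace()
        t.graph = self.graph.copy()
        for n in t.graph.nodes:
            t.graph.nodes[n]["pos"] = np.array(t.graph.nodes[n]["pos"])
        return t

    def relabeled(self) -> "Trace":
        """Copy with node ids renumbered densely 0..n-1 (sorted order)."""
        mapping = {n: i for i, n in enumerate(sorted(self.graph.nodes))}
        t = Trace()
        t.graph = nx.relabel_nodes(self.graph, mapping, copy=True)
        return t


def decompose_branches(trace: Trace) -> list[Branch]:
    """Split a trace into branches at nodes of degree != 2.

    Every edge belongs to exactly one branch. Isolated cycles (components in
    which every node has degree 2) are split at their lowest-id node.
    """
    g = trace.graph
    critical = {n for n in g.nodes if g.degree[n] != 2}
    # isolated cycles / isolated degree-2 paths: add a split node per component
    for comp in nx.connected_components(g):
        if not comp & critical:
            critical.add(min(comp))

    branches: list[Branch] = []
    seen_edges: set[frozenset] = set()
    for start in sorted(critical):
        for nb in sorted(g.neighbors(start)):
            e = frozenset((start, nb))
            if e in seen_edges:
                continue
            chain = [start, nb]
            seen_edges.add(e)
            while chain[-1] not in critical:
                prev, cur = chain[-2], chain[-1]
                nxt = [x for x in g.neighbors(cur) if x != prev]
                # degree-2 interior guaranteed: exactly one continuation
                chain.append(nxt[0])
                seen_edges.add(frozenset((cur, nxt[0])))
            length = sum(trace.edge_length(a, b) for a, b in zip(chain, chain[1:]))
            branches.append(Branch(chain, length))
    return branches


def branch_mean_intensity(trace: Trace, branch: Branch, stack) -> float:
    """Mean trilinearly-interpolated stack intensity over the branch's nodes."""
    pos = trace.positions(branch.nodes)
    return float(np.mean(stack.interpolate(pos)))


def resample(trace: Trace, d: float) -> Trace:
    """Resample every branch at uniform spacing <= d along its polyline.

    Topology-critical nodes (degree != 2) are preserved exactly; interior
    samples lie on the original piecewise-linear centerline, so total length
    is preserved. Calibers are linearly interpolated by arc length.
    """
    if d <= 0:
        raise ValueError(f"d must be positive, got {d}")
    out = Trace()
    node_map: dict[int, int] = {}

    def _map(nid: int) -> int:
        if nid not in node_map:
            node_map[nid] = out.add_node(trace.position(nid), trace.caliber(nid))
        return node_map[nid]

    for br in decompose_branches(trace):
        pts = trace.positions(br.nodes)
        cal = np.array([trace.caliber(n) for n in br.nodes])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        total = arc[-1]
        if total == 0:
            a, b = _map(br.nodes[0]), _map(br.nodes[-1])
            if a != b:
                out.add_edge(a, b)
            continue
        n_seg = max(1, int(np.ceil(total / d - 1e-12)))
        uniform = np.linspace(0.0, total, n_seg + 1)[1:-1]
        # keep the original vertices: chords then never cut polyline bends,
        # so total length is preserved exactly
        targets = np.unique(np.concatenate([uniform, arc[1:-1]]))
        targets = targets[(targets > 1e-12) & (targets < total - 1e-12)]
        keep = np.ones(len(targets), dtype=bool)
        keep[1:] = np.diff(targets) > 1e-9
        targets = targets[keep]
        chain = [_map(br.nodes[0])]
        for s in targets:
            p = np.array([np.interp(s, arc, pts[:, c]) for c in range(3)])
            r = float(np.interp(s, arc, cal))
            chain.append(out.add_node(p, r))
        chain.append(_map(br.nodes[-1]))
        for a, b in zip(chain, chain[1:]):
            if a != b:
                out.add_edge(a, b)
    # carry over isolated nodes (degree 0)
    for n in trace.graph.nodes:
        if trace.graph.degree[n] == 0:
            _map(n)
    return out


# -- I/O -------------------------------------------------------------------

def write_json(trace: Trace, path=None) -> str:
    """Serialize nodes + adjacency losslessly (cycles allowed) as JSON."""
    t = trace.relabeled()
    obj = {
        "nodes": [
            {"pos": [float(x) for x in t.position(n)], "radius": float(t.caliber(n))}
            for n in sorted(t.graph.nodes)
        ],
        "edges": sorted([sorted((int(a), int(b))) for a, b in t.graph.edges]),
    }
    text = json.dumps(obj, indent=1, sort_keys=True)
    if path is not None:
        with open(path, "w") as f:
            f.write(text)
    return text


def read_json(path) -> Trace:
    with open(path) as f:
        obj = json.load(f)
    t = Trace()
    ids = [t.add_node(nd["pos"], nd["radius"]) for nd in obj["nodes"]]
    for a, b in obj["edges"]:
        t.add_edge(ids[a], ids[b])
    return t


def write_swc(trace: Trace, path=None) -> str:
    """Export as standard 7-column SWC (requires a forest: no cycles).

    Columns: id, type (0), x, y, z, radius, parent (-1 for roots). Ids are
    1-based; each connected component is rooted at its lowest node id.
    """
    if trace.has_cycle():
        cyc = nx.cycle_basis(trace.graph)[0]
        raise CyclicTraceError(
            f"trace contains a loop through nodes {sorted(cyc)}; SWC cannot represent "
            "loops — use write_json instead"
        )
    lines = []
    swc_id: dict[int, int] = {}
    next_id = 1
    for comp in sorted(nx.connected_components(trace.graph), key=min):
        root = min(comp)
        for parent, child in [(None, root)] + list(nx.bfs_edges(trace.graph, root)):
            swc_id[child] = next_id
            x, y, z = trace.position(child)
            pid = -1 if parent is None else swc_id[parent]
            lines.append(f"{next_id} 0 {x:.6g} {y:.6g} {z:.6g} {trace.caliber(child):.6g} {pid}")
            next_id += 1
    text = "\n".join(lines) + ("\n" if lines else "")
    if path is not None:
        with open(path, "w") as f:
            f.write(text)
    return text


def read_swc(path) -> Trace:
    t = Trace()
    id_map: dict[int, int] = {}
    parents: list[tuple[int, int]] = []
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            sid, _, x, y, z, r, pid = cols[:7]
            id_map[int(sid)] = t.add_node((float(x), float(y), float(z)), float(r))
            if int(pid) != -1:
                parents.append((int(sid), int(pid)))
    for sid, pid in parents:
        t.add_edge(id_map[sid], id_map[pid])
    return t


def write_csv(trace: Trace, path) -> None:
    """Node table export: id, x, y, z, radius, degree."""
    import pandas as pd

    t = trace.relabeled()
    rows = [
        {
            "id": n,
            "x": t.position(n)[0],
            "y": t.position(n)[1],
            "z": t.position(n)[2],
            "radius": t.caliber(n),
            "degree": t.degree(n),
        }
        for n in sorted(t.graph.nodes)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
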