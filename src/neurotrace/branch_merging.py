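"""Branch-merging topology: terminal clusters, scenarios, and features.

After the initial trace is disconnected into branches, the branch endpoints
("terminal points") are clustered by single linkage: links longer than a
threshold (default ``10*s_x``) are removed from the all-to-all endpoint
graph, and each surviving connected component of two or more endpoints
becomes a :class:`MergeCluster`. Within a cluster, every way of merging the
endpoints is one :class:`MergeScenario` — a set partition in which each
block of size >= 2 becomes one junction and singletons stay free terminals —
so the number of scenarios equals the Bell number B(n).

Each scenario is summarized by a 9-component feature vector; because
scenarios are only ever compared within a cluster, classification uses
feature *differences* ``dx = x_erroneous - x_correct`` (subtractive
normalization), which cancels any per-cluster additive offset such as local
intensity or neurite density.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from neurotrace.trace_model import Trace, Branch, branch_mean_intensity, decompose_branches

N_FEATURES = 9


@dataclass
class TerminalPoint:
    """One branch endpoint entering the merging pool."""

    branch_id: int
    position: np.ndarray
    tangent: np.ndarray  # outward unit vector (away from the branch interior)
    mean_intensity: float = 0.0
    mean_caliber: float = 1.0
    node_id: int | None = None


@dataclass
class MergeScenario:
    """One candidate topology: a set partition of the cluster's endpoints."""

    partition: tuple[tuple[int, ...], ...]  # blocks of endpoint indices
    features: np.ndarray | None = None

    @property
    def merged_pairs(self):
        for block in self.partition:
            if len(block) >= 2:
                yield from combinations(block, 2)

    def rgs(self) -> str:
        """Restricted-growth-string encoding, e.g. '0010' for {0,1,3}{2}."""
        n = sum(len(b) for b in self.partition)
        code = [0] * n
        for bi, block in enumerate(sorted(self.partition, key=min)):
            for e in block:
                code[e] = bi
        return "".join(str(c) for c in code)


@dataclass
class MergeCluster:
    """A group of nearby terminal points resolved jointly."""

    terminals: list[TerminalPoint]
    scenarios: list[MergeScenario] = field(default_factory=list)
    label: int | None = None  # index of the correct scenario
    weight: float = 1.0

    @property
    def n(self) -> int:
        return len(self.terminals)


def set_partitions(n: int):
    """All set partitions of range(n) in canonical restricted-growth order."""
    if n == 0:
        yield ()
        return
    code = [0] * n
    while True:
        blocks: dict[int, list[int]] = {}
        for i, c in enumerate(code):
            blocks.setdefault(c, []).append(i)
        yield tuple(tuple(blocks[c]) for c in sorted(blocks))
        # next restricted growth string
        for i in range(n - 1, 0, -1):
            if code[i] <= max(code[:i]):
                code[i] += 1
                for j in range(i + 1, n):
                    code[j] = 0
                break
        else:
            return


def bell_number(n: int) -> int:
    """Bell numbers via the recurrence B(n+1) = sum_k C(n,k) B(k)."""
    from math import comb

    b = [1]
    for m in range(n):
        b.append(sum(comb(m, k) * b[k] for k in range(m + 1)))
    return b[n]


def estimate_tangent(trace: Trace, branch: Branch, at_start: bool, n_fit: int = 5) -> np.ndarray:
    """Outward unit tangent at a branch endpoint.

    Fit a least-squares line through the last ``min(n_fit, len)`` nodes of
    the branch and orient it away from the branch interior.
    """
    nodes = branch.nodes if at_start else branch.nodes[::-1]
    pts = trace.positions(nodes[: max(2, min(n_fit, len(nodes)))])
    center = pts.mean(axis=0)
    if len(pts) == 2:
        v = pts[0] - pts[1]
    else:
        _, _, vt = np.linalg.svd(pts - center)
        v = vt[0]
        if np.dot(v, pts[0] - center) < 0:
            v = -v
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else np.array([1.0, 0.0, 0.0])


def extract_terminals(trace: Trace, stack=None, resample_step: float | None = None):
    """All branch endpoints of a trace as TerminalPoints.

    Branch summary stats (mean intensity, mean caliber) are computed per
    branch; tangents come from a line fit to the endpoint's last nodes.
    """
    branches = decompose_branches(trace)
    terminals: list[TerminalPoint] = []
    for bid, br in enumerate(branches):
        mi = branch_mean_intensity(trace, br, stack) if stack is not None else 0.0
        br.mean_intensity = mi
        mc = float(np.mean([trace.caliber(n) for n in br.nodes]))
        for at_start, node in ((True, br.nodes[0]), (False, br.nodes[-1])):
            terminals.append(
                TerminalPoint(
                    branch_id=bid,
                    position=np.array(trace.position(node)),
                    tangent=estimate_tangent(trace, br, at_start),
                    mean_intensity=mi,
                    mean_caliber=mc,
                    node_id=node,
                )
            )
    return terminals, branches


def cluster_terminals(terminals: list[TerminalPoint], threshold: float) -> list[MergeCluster]:
    """Single-linkage clustering of terminal points at the given distance.

    Connected components of the all-to-all endpoint graph after removing
    links longer than ``threshold``; singleton components (true isolated
    terminals) are dropped from the merging pool.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    n = len(terminals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    pos = np.array([t.position for t in terminals]).reshape(n, 3)
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(pos[i] - pos[j]) <= threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [
        MergeCluster([terminals[i] for i in sorted(g)])
        for g in sorted(groups.values(), key=min)
        if len(g) >= 2
    ]


def limit_cluster_sizes(
    clusters: list[MergeCluster],
    threshold: float,
    cap: int = 8,
    shrink: float = 0.75,
) -> list[MergeCluster]:
    """Split clusters larger than ``cap`` by re-clustering at shrinking
    thresholds.

    Scenario enumeration is exponential (Bell numbers), so clusters beyond
    the cap are re-clustered among their own terminals with the linkage
    threshold reduced by ``shrink`` until every piece fits; pieces that
    cannot be split below the cap even at one-voxel linkage are dropped
    with a warning (left unmerged in the pipeline).
    """
    import logging

    out: list[MergeCluster] = []
    for cl in clusters:
        if cl.n <= cap:
            out.append(cl)
            continue
        t = threshold * shrink
        pieces = [cl]
        while any(p.n > cap for p in pieces) and t >= 1e-3:
            next_pieces = []
            for p in pieces:
                if p.n <= cap:
                    next_pieces.append(p)
                else:
                    next_pieces.extend(cluster_terminals(p.terminals, t))
            pieces = next_pieces
            t *= shrink
        for p in pieces:
            if p.n <= cap:
                out.append(p)
            else:
                logging.getLogger(__name__).warning(
                    "dropping unsplittable cluster of %d terminal points", p.n)
    return out


def enumerate_scenarios(cluster: MergeCluster, max_terminals: int = 8) -> list[MergeScenario]:
    """All branch-merging scenarios (set partitions) of a cluster.

    The count equals the Bell number B(n); ordering is canonical
    (restricted-growth strings, lexicographic). Clusters larger than
    ``max_terminals`` are refused — raise the cap explicitly to proceed.
    """
    n = cluster.n
    if n < 2:
        raise ValueError("cluster must have at least 2 terminal points")
    if n > max_terminals:
        raise ValueError(
            f"cluster has {n} terminal points; B({n}) = {bell_number(n)} scenarios. "
            f"Raise max_terminals above {max_terminals} to enumerate anyway."
        )
    cluster.scenarios = [MergeScenario(p) for p in set_partitions(n)]
    return cluster.scenarios


def _bridge_path(pa: np.ndarray, pb: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    """Sample points along the bridging polyline a -> block centroid -> b."""
    seg1 = np.linspace(pa, centroid, 6)
    seg2 = np.linspace(centroid, pb, 6)[1:]
    return np.vstack([seg1, seg2])


def scenario_features(scenario: MergeScenario, cluster: MergeCluster, stack=None) -> np.ndarray:
    """The 9-component feature vector of a merging scenario.

    Aggregated over all merged endpoint pairs (a, b) within junction blocks:

    1. mean endpoint distance |r_b - r_a|
    2. mean overrun: max(0, -(r_b - r_a) . u_a), averaged over both orders
    3. mean perpendicular offset of r_b - r_a relative to u_a (both orders)
    4. mean tangent alignment -u_a . u_b (1 = ideally facing tangents)
    5. mean |difference of branch mean intensities|
    6. mean intensity standard deviation along the bridging path
    7. mean |difference of branch mean calibers|
    8. mean bridging-path tortuosity (path length / endpoint distance)
    9. number of free terminal points (singleton blocks)

    Scenarios with no merged pair have features 1-8 equal to 0 by
    convention. Bridging paths run endpoint -> block centroid -> endpoint.
    """
    t = cluster.terminals
    f = np.zeros(N_FEATURES)
    pairs = list(scenario.merged_pairs)
    if pairs:
        dists, overruns, offsets, aligns, dint, istd, dcal, torts = ([] for _ in range(8))
        for block in scenario.partition:
            if len(block) < 2:
                continue
            centroid = np.mean([t[i].position for i in block], axis=0)
            for a, b in combinations(block, 2):
                ra, rb = t[a].position, t[b].position
                ua, ub = t[a].tangent, t[b].tangent
                v = rb - ra
                d = float(np.linalg.norm(v))
                dists.append(d)
                overruns.append(0.5 * (max(0.0, -float(np.dot(v, ua)))
                                       + max(0.0, float(np.dot(v, ub)))))
                offsets.append(0.5 * (float(np.linalg.norm(v - np.dot(v, ua) * ua))
                                      + float(np.linalg.norm(v - np.dot(v, ub) * ub))))
                aligns.append(-float(np.dot(ua, ub)))
                dint.append(abs(t[a].mean_intensity - t[b].mean_intensity))
                dcal.append(abs(t[a].mean_caliber - t[b].mean_caliber))
                path = _bridge_path(ra, rb, centroid)
                plen = float(np.sum(np.linalg.norm(np.diff(path, axis=0), axis=1)))
                torts.append(plen / d if d > 0 else 1.0)
                if stack is not None:
                    istd.append(float(np.std(stack.interpolate(path))))
                else:
                    istd.append(0.0)
        f[0] = np.mean(dists)
        f[1] = np.mean(overruns)
        f[2] = np.mean(offsets)
        f[3] = np.mean(aligns)
        f[4] = np.mean(dint)
        f[5] = np.mean(istd)
        f[6] = np.mean(dcal)
        f[7] = np.mean(torts)
    f[8] = sum(1 for b in scenario.partition if len(b) == 1)
    scenario.features = f
    return f


def compute_cluster_features(cluster: MergeCluster, stack=None, force: bool = False) -> None:
    """Fill in missing scenario feature vectors (idempotent unless forced)."""
    if not cluster.scenarios:
        enumerate_scenarios(cluster)
    for s in cluster.scenarios:
        if force or s.features is None:
            scenario_features(s, cluster, stack)


def normalize_within_cluster(cluster: MergeCluster, label: int | None = None) -> np.ndarray:
    """Subtractively normalized feature differences of a labeled cluster.

    Returns the (B(n) - 1, 9) array of ``dx = x_erroneous - x_correct`` for
    every erroneous scenario; the correct scenario's zero difference is
    excluded.
    """
    if label is None:
        label = cluster.label
    if label is None:
        raise ValueError("cluster is unlabeled")
    if any(s.features is None for s in cluster.scenarios):
        raise ValueError("scenario features not computed; call compute_cluster_features")
    x_correct = cluster.scenarios[label].features
    return np.array(
        [s.features - x_correct for i, s in enumerate(cluster.scenarios) if i != label]
    ).reshape(-1, N_FEATURES)


def apply_scenario(trace: Trace, cluster: MergeCluster, scenario: MergeScenario) -> None:
    """Realize a merging scenario in-place on the (disconnected) trace.

    Blocks of size 2 connect the two endpoint nodes directly; blocks of
    size >= 3 create one junction node at the block centroid connected to
    every endpoint in the block.
    """
    t = cluster.terminals
    for block in scenario.partition:
        if len(block) == 2:
            a, b = (t[i].node_id for i in block)
            if a is not None and b is not None and a != b:
                trace.add_edge(a, b)
        elif len(block) >= 3:
            centroid = np.mean([t[i].position for i in block], axis=0)
            caliber = float(np.mean([t[i].mean_caliber for i in block]))
            j = trace.add_node(centroid, max(caliber, 1e-6))
            for i in block:
                if t[i].node_id is not None:
                    trace.add_edge(j, t[i].node_id)


def merge_trace(trace: Trace, stack, w, threshold: float):
    """Dismantle a trace and re-merge every cluster by its best scenario.

    Scenario scores are ``w . x`` (lower = better); the argmin scenario of
    each cluster is applied. Terminal points outside any cluster stay
    free. Returns ``(merged_trace, clusters)``.
    """
    disconnected, terminals = dismantle_trace(trace, stack)
    clusters = limit_cluster_sizes(cluster_terminals(terminals, threshold), threshold)
    merged = disconnected.copy()
    for cl in clusters:
        compute_cluster_features(cl, stack)
        scores = np.array([s.features @ np.asarray(w) for s in cl.scenarios])
        apply_scenario(merged, cl, cl.scenarios[int(np.argmin(scores))])
    return merged, clusters


def dismantle_trace(trace: Trace, stack=None):
    """Take a trace apart into free branches.

    Every branch of the trace becomes its own path component in the
    returned trace; junction nodes shared by several branches are
    duplicated per incident branch, so all former topology is dissolved and
    must be re-established by merging scenarios. Returns
    ``(disconnected_trace, terminals)`` where the terminal points carry the
    node ids of the branch endpoints in the disconnected trace.
    """
    branches = decompose_branches(trace)
    out = Trace()
    terminals: list[TerminalPoint] = []
    for bid, br in enumerate(branches):
        mi = branch_mean_intensity(trace, br, stack) if stack is not None else 0.0
        mc = float(np.mean([trace.caliber(n) for n in br.nodes]))
        new_ids = [out.add_node(trace.position(n), trace.caliber(n)) for n in br.nodes]
        for a, b in zip(new_ids, new_ids[1:]):
            out.add_edge(a, b)
        for at_start, nid in ((True, new_ids[0]), (False, new_ids[-1])):
            terminals.append(
                TerminalPoint(
                    branch_id=bid,
                    position=np.array(trace.position(br.nodes[0 if at_start else -1])),
                    tangent=estimate_tangent(trace, br, at_start),
                    mean_intensity=mi,
                    mean_caliber=mc,
                    node_id=nid,
                )
            )
    return out, terminals
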