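"""Ground-truthed synthetic data: tubular phantom stacks and planted
merge-cluster pools.

``render_stack`` emulates light-microscopy stacks of labeled axons: bright
tubes with Gaussian cross-sections on a noisy background, optional labeling
gaps (zeroed arc intervals, mimicking imperfect fills), and near-crossings
of distinct axons (the situation that produces erroneously merged "stolen"
branches in initial traces). Single long tubes emulate sparse single-axon
stacks; several crossing tubes emulate dense multi-axon cortical stacks.

``planted_clusters`` builds a pool of labeled merge clusters whose correct
scenario is, by construction, the score argmin under a planted weight
vector w*, providing a fully controlled harness for the classifiers and
the active-learning loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from neurotrace.branch_merging import (
    MergeCluster,
    MergeScenario,
    N_FEATURES,
    TerminalPoint,
    set_partitions,
)
from neurotrace.image_stack import ImageStack
from neurotrace.trace_model import Trace


@dataclass
class TubeSpec:
    """One neurite: a centerline polyline with radius and peak amplitude."""

    points: np.ndarray  # (n, 3) physical control points
    sigma: float = 1.0  # Gaussian cross-section std (physical units)
    amplitude: float = 1.0  # peak intensity in (0, 1]
    gaps: list[tuple[float, float]] = field(default_factory=list)  # arc intervals zeroed

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if not 0 < self.amplitude <= 1:
            raise ValueError("amplitude must be in (0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class SyntheticSpec:
    """Full description of a synthetic stack, reproducible given its seed."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tubes: list[TubeSpec] = field(default_factory=list)
    background: float = 0.05
    noise_std: float = 0.02
    rng_seed: int = 0


def _sample_centerline(tube: TubeSpec, step: float):
    """Densely sampled centerline points and their arc-length positions."""
    pts = tube.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    n = max(2, int(np.ceil(total / step)) + 1)
    s = np.linspace(0, total, n)
    samp = np.column_stack([np.interp(s, arc, pts[:, c]) for c in range(3)])
    return samp, s


def render_stack(spec: SyntheticSpec, truth_step: float | None = None):
    """Render a spec into ``(ImageStack, ground_truth_trace)``.

    Voxel intensity = background + sum over tubes of
    ``amplitude * exp(-dist(voxel, centerline)^2 / (2 sigma^2))`` + Gaussian
    noise, clipped to [0, 1]. Gap intervals remove the tube's contribution
    (and the corresponding ground-truth nodes stay — the gap is a labeling
    artifact, not missing anatomy — but gapped arcs are tracked on the
    trace as the ``in_gap`` node attribute). The ground-truth trace is the
    resampled centerline with caliber sigma; distinct tubes are distinct
    components.
    """
    rng = np.random.default_rng(spec.rng_seed)
    svec = np.array(spec.voxel_size)
    shape = spec.shape
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    vox_pos = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1) * svec

    img = np.full(shape, spec.background, dtype=float).ravel()
    step = 0.25 * svec.min()
    for tube in spec.tubes:
        samp, s = _sample_centerline(tube, step)
        keep = np.ones(len(s), dtype=bool)
        for a, b in tube.gaps:
            keep &= ~((s >= a) & (s <= b))
        if not keep.any():
            continue
        tree = cKDTree(samp[keep])
        cutoff = 4.0 * tube.sigma
        d, _ = tree.query(vox_pos, distance_upper_bound=cutoff)
        near = np.isfinite(d)
        img[near] += tube.amplitude * np.exp(-d[near] ** 2 / (2 * tube.sigma**2))
    img = img.reshape(shape)
    if spec.noise_std > 0:
        img = img + rng.normal(0.0, spec.noise_std, size=shape)
    img = np.clip(img, 0.0, 1.0)
    stack = ImageStack(img, spec.voxel_size)

    truth = Trace()
    tstep = truth_step if truth_step is not None else svec[0]
    for tid, tube in enumerate(spec.tubes):
        samp, s = _sample_centerline(tube, tstep)
        in_gap = np.zeros(len(s), dtype=bool)
        for a, b in tube.gaps:
            in_gap |= (s >= a) & (s <= b)
        prev = None
        for p, sa, g in zip(samp, s, in_gap):
            nid = truth.add_node(p, tube.sigma)
            truth.graph.nodes[nid]["tube"] = tid
            truth.graph.nodes[nid]["arc"] = float(sa)
            truth.graph.nodes[nid]["in_gap"] = bool(g)
            if prev is not None:
                truth.add_edge(prev, nid)
            prev = nid
    return stack, truth


# -- planted clusters ------------------------------------------------------

DEFAULT_W_STAR = np.array([1.0, 0.8, 0.8, -0.6, 0.5, 0.3, 0.4, 0.3, 0.7])


def _random_scenario_features(rng, partition) -> np.ndarray:
    """Plausible random features for one scenario of a synthetic cluster."""
    x = np.zeros(N_FEATURES)
    has_pair = any(len(b) >= 2 for b in partition)
    if has_pair:
        x[0] = rng.exponential(1.0)  # mean endpoint distance
        x[1] = rng.exponential(0.7)  # mean overrun
        x[2] = rng.exponential(0.7)  # mean offset
        x[3] = rng.uniform(-1.0, 1.0)  # mean tangent alignment
        x[4] = rng.exponential(0.3)  # |d mean intensity|
        x[5] = rng.exponential(0.2)  # bridge intensity std
        x[6] = rng.exponential(0.3)  # |d caliber|
        x[7] = 1.0 + rng.exponential(0.3)  # tortuosity
    x[8] = sum(1 for b in partition if len(b) == 1)
    return x


def planted_clusters(
    n_clusters: int = 200,
    w_star: np.ndarray | None = None,
    noise: float = 0.0,
    rng_seed: int = 0,
    min_margin: float = 0.1,
    terminal_range: tuple[int, int] = (2, 5),
) -> list[MergeCluster]:
    """A pool of labeled merge clusters with a planted decision rule.

    Each cluster has 2-5 terminal points and one feature vector per
    scenario; the label is the scenario minimizing ``w* . x + eps`` with
    eps ~ N(0, noise). Clusters are redrawn until the margin between the
    best and second-best planted score is at least ``min_margin`` times
    |w*| (separability control); margins above the floor vary widely, so
    pools contain both easy and informative borderline clusters.
    """
    if w_star is None:
        w_star = DEFAULT_W_STAR
    w_star = np.asarray(w_star, dtype=float)
    if len(w_star) != N_FEATURES:
        raise ValueError(f"w_star must have {N_FEATURES} components")
    rng = np.random.default_rng(rng_seed)
    wnorm = np.linalg.norm(w_star)
    pool: list[MergeCluster] = []
    while len(pool) < n_clusters:
        n = int(rng.integers(terminal_range[0], terminal_range[1] + 1))
        parts = list(set_partitions(n))
        X = np.array([_random_scenario_features(rng, p) for p in parts])
        scores = X @ w_star
        order = np.sort(scores)
        if (order[1] - order[0]) < min_margin * wnorm:
            continue
        noisy = scores + (rng.normal(0, noise, size=len(scores)) if noise > 0 else 0.0)
        label = int(np.argmin(noisy))
        terminals = [
            TerminalPoint(branch_id=i, position=np.zeros(3), tangent=np.array([1.0, 0, 0]))
            for i in range(n)
        ]
        cl = MergeCluster(terminals)
        cl.scenarios = [MergeScenario(p, features=x) for p, x in zip(parts, X)]
        cl.label = label
        pool.append(cl)
    return pool


def ground_truth_partition(
    cluster: MergeCluster,
    disconnected: Trace,
    truth: Trace,
    max_pos_error: float = 4.0,
    max_join_arc: float = 25.0,
):
    """The correct merging partition of a cluster, derived from ground truth.

    Each endpoint is projected onto the nearest ground-truth node, giving a
    (tube, arc-length) coordinate; the direction its branch *faces* (beyond
    the endpoint) is the sign of the arc change over a few interior nodes.
    Two endpoints of different branches merge when they lie on the same
    tube, face each other along the arc, and their arc gap is below
    ``max_join_arc``; ambiguous candidates resolve to the smallest arc gap.
    Endpoints farther than ``max_pos_error`` from any tube stay free.

    Returns the scenario index within ``cluster.scenarios`` (enumerating
    them first if needed).
    """
    from neurotrace.branch_merging import enumerate_scenarios

    t_nodes = sorted(truth.graph.nodes)
    t_pos = truth.positions(t_nodes)
    tube = np.array([truth.graph.nodes[n]["tube"] for n in t_nodes])
    arc = np.array([truth.graph.nodes[n]["arc"] for n in t_nodes])
    tree = cKDTree(t_pos)

    info = []
    for tp in cluster.terminals:
        d, j = tree.query(tp.position)
        if d > max_pos_error:
            info.append(None)
            continue
        # walk a few nodes into the branch to find the covered arc direction
        interior = tp.node_id
        prev = None
        for _ in range(3):
            nbs = [x for x in disconnected.graph.neighbors(interior) if x != prev]
            if not nbs:
                break
            prev, interior = interior, nbs[0]
        d2, j2 = tree.query(disconnected.position(interior))
        if tube[j2] != tube[j] or d2 > max_pos_error:
            info.append((int(tube[j]), float(arc[j]), 0.0))
            continue
        covered = float(arc[j2] - arc[j])  # branch covers this arc direction
        info.append((int(tube[j]), float(arc[j]), -np.sign(covered)))  # faces opposite

    candidates = []
    for a in range(cluster.n):
        for b in range(a + 1, cluster.n):
            if info[a] is None or info[b] is None:
                continue
            if cluster.terminals[a].branch_id == cluster.terminals[b].branch_id:
                continue
            ta, sa, fa = info[a]
            tb, sb, fb = info[b]
            if ta != tb:
                continue
            gap = abs(sa - sb)
            if gap > max_join_arc:
                continue
            faces = (fa == 0 or fa == np.sign(sb - sa) or sa == sb) and \
                    (fb == 0 or fb == np.sign(sa - sb) or sa == sb)
            if faces:
                candidates.append((gap, a, b))
    used: set[int] = set()
    pairs = []
    for gap, a, b in sorted(candidates):
        if a not in used and b not in used:
            pairs.append((a, b))
            used.update((a, b))
    blocks = [tuple(sorted(p)) for p in pairs]
    blocks += [(i,) for i in range(cluster.n) if i not in used]
    target = frozenset(frozenset(b) for b in blocks)

    if not cluster.scenarios:
        enumerate_scenarios(cluster)
    for i, sc in enumerate(cluster.scenarios):
        if frozenset(frozenset(b) for b in sc.partition) == target:
            return i
    raise RuntimeError("ground-truth partition not found among scenarios")


def truth_oracle(pool):
    """Labeling callback for active learning on a planted pool."""
    truth = {id(cl): cl.label for cl in pool}

    def oracle(cluster):
        return truth[id(cluster)]

    return oracle
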