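"""Multi-seed Fast Marching initial tracing.

The arrival-time field T solves the Eikonal boundary-value problem

    |grad T(r)| * I(r) = 1,    T on the boundary = 0,

with the normalized image intensity I acting as the propagation speed, so
fronts spread preferentially along bright neurites. T is computed on the
voxel lattice with the standard upwind (Rouy–Tourin) discretization: per
axis, only the smaller of the two neighbor values enters, and

    sum_axes (max(T - T_axis_min, 0) / s_axis)^2 = 1 / I^2,

where (s_x, s_y, s_z) are the voxel dimensions. Voxels with I = 0 are hard
barriers (the update is singular there) and are never accepted.

The initial trace grows iteratively: the front marches a limited Euclidean
distance D_max from the current boundary, a gradient-descent path from the
farthest point is added to the boundary (T = 0), and marching restarts.
Fronts of distinct seeds that collide are joined by gradient-descent paths
back-propagated from the collision voxel into each colliding region. Growth
stops when the mean intensity of the last added path drops below a set
fraction (default 20%) of the mean intensity of the existing trace.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from neurotrace.image_stack import ImageStack, SeedSet
from neurotrace.trace_model import Trace

FAR, TRIAL, ACCEPTED = 0, 1, 2

# 26-neighborhood index offsets, computed once
_OFFSETS26 = np.array(
    [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
     if (i, j, k) != (0, 0, 0)]
)


@dataclass
class TimeMap:
    """Arrival times plus front bookkeeping from one Fast Marching run.

    ``T`` is +inf on far voxels and 0 exactly on the boundary; ``label``
    holds the id of the seed front that accepted each voxel (-1 = none);
    ``state`` is FAR/TRIAL/ACCEPTED per voxel.
    """

    T: np.ndarray
    label: np.ndarray
    state: np.ndarray
    collisions: list[tuple[tuple[int, int, int], int, int]] = field(default_factory=list)


@dataclass
class MarchResult:
    tmap: TimeMap
    farthest: tuple[int, int, int] | None
    exhausted: bool
    collision: tuple[int, int, int] | None = None
    collision_labels: tuple[int, int] | None = None
    dist: np.ndarray | None = None  # physical EDT to the march boundary


def _upwind_solve(t_axis: list[float], s_axis: list[float], inv_speed: float) -> float:
    """Solve sum((max(T - t_a, 0)/s_a)^2) = inv_speed^2 for T.

    ``t_axis`` holds the per-axis upwind neighbor values (may be inf);
    the standard incremental solution drops axes whose neighbor value
    exceeds the candidate T.
    """
    pairs = sorted((t, s) for t, s in zip(t_axis, s_axis) if np.isfinite(t))
    if not pairs:
        return np.inf
    # try with the n smallest neighbor values until consistent
    for n in range(len(pairs), 0, -1):
        use = pairs[:n]
        a = sum(1.0 / s**2 for _, s in use)
        b = -2.0 * sum(t / s**2 for t, s in use)
        c = sum(t**2 / s**2 for t, s in use) - inv_speed**2
        disc = b * b - 4 * a * c
        if disc < 0:
            continue
        T = (-b + np.sqrt(disc)) / (2 * a)
        if n == 1 or T >= use[-1][0]:
            return T
    # fallback: one-axis update from the smallest neighbor
    t0, s0 = pairs[0]
    return t0 + s0 * inv_speed


class _Marcher:
    """Min-heap Fast Marching engine over one stack."""

    def __init__(self, stack: ImageStack, boundary: dict[tuple[int, int, int], int]):
        if not boundary:
            raise ValueError("boundary must be nonempty")
        self.stack = stack
        shape = stack.shape
        self.T = np.full(shape, np.inf)
        self.label = np.full(shape, -1, dtype=int)
        self.state = np.zeros(shape, dtype=np.int8)
        self.heap: list[tuple[float, int, tuple[int, int, int]]] = []
        self._counter = 0
        self.collisions: list[tuple[tuple[int, int, int], int, int]] = []
        self.inv_I = np.where(stack.voxels > 0, 1.0 / np.maximum(stack.voxels, 1e-300), np.inf)
        for vox, lab in boundary.items():
            if stack.voxels[vox] <= 0:
                raise ValueError(f"boundary voxel {vox} has zero intensity")
            self.T[vox] = 0.0
            self.label[vox] = lab
            self.state[vox] = ACCEPTED
        for vox in boundary:
            self._update_neighbors(vox)

    def _axis_neighbors(self, vox):
        i, j, k = vox
        shape = self.T.shape
        out = []
        for ax, (lo, hi) in enumerate([((i - 1, j, k), (i + 1, j, k)),
                                       ((i, j - 1, k), (i, j + 1, k)),
                                       ((i, j, k - 1), (i, j, k + 1))]):
            best = np.inf
            for nb in (lo, hi):
                if 0 <= nb[0] < shape[0] and 0 <= nb[1] < shape[1] and 0 <= nb[2] < shape[2]:
                    if self.state[nb] == ACCEPTED and self.T[nb] < best:
                        best = self.T[nb]
            out.append(best)
        return out

    def _update_neighbors(self, vox) -> None:
        i, j, k = vox
        shape = self.T.shape
        lab = int(self.label[vox])
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            nb = (i + di, j + dj, k + dk)
            if not (0 <= nb[0] < shape[0] and 0 <= nb[1] < shape[1] and 0 <= nb[2] < shape[2]):
                continue
            if self.state[nb] == ACCEPTED:
                continue
            inv = self.inv_I[nb]
            if np.isinf(inv):
                continue  # zero intensity: hard barrier
            t_new = _upwind_solve(self._axis_neighbors(nb), list(self.stack.voxel_size), inv)
            if t_new < self.T[nb]:
                self.T[nb] = t_new
                if self.label[nb] >= 0 and self.label[nb] != lab:
                    self.collisions.append((nb, int(self.label[nb]), lab))
                self.label[nb] = lab
                self.state[nb] = TRIAL
                self._counter += 1
                heapq.heappush(self.heap, (t_new, self._counter, nb))
            elif self.label[nb] >= 0 and self.label[nb] != lab:
                # a second front reached this trial voxel without improving it
                self.collisions.append((nb, int(self.label[nb]), lab))

    def step(self):
        """Accept the next voxel; returns it, or None when exhausted."""
        while self.heap:
            t, _, vox = heapq.heappop(self.heap)
            if self.state[vox] == ACCEPTED or t > self.T[vox]:
                continue
            self.state[vox] = ACCEPTED
            self._update_neighbors(vox)
            return vox
        return None

    def as_timemap(self) -> TimeMap:
        return TimeMap(self.T, self.label, self.state, self.collisions)


def solve_eikonal(stack: ImageStack, boundary) -> TimeMap:
    """Solve the Eikonal problem to completion from a set of boundary voxels.

    ``boundary`` is an iterable of voxel index triples (all get T = 0 and
    their own front label by enumeration order) or a dict voxel -> label.
    """
    if not isinstance(boundary, dict):
        boundary = {tuple(v): i for i, v in enumerate(boundary)}
    m = _Marcher(stack, boundary)
    while m.step() is not None:
        pass
    return m.as_timemap()


def march_to_distance(
    stack: ImageStack,
    boundary,
    d_max: float,
    stop_on_collision: bool = True,
    collision_filter=None,
) -> MarchResult:
    """March until a newly accepted voxel lies farther than ``d_max``
    (physical Euclidean distance to the nearest boundary voxel).

    Returns the farthest accepted voxel with distance <= d_max, an
    exhaustion flag (front ran out of reachable voxels first), and the
    first front collision, if any (ties broken by lowest arrival time).
    ``collision_filter(marcher, voxel, label_a, label_b)`` may veto a
    collision (return falsy), in which case marching continues — used to
    reject front meetings across dim gaps.
    """
    if not isinstance(boundary, dict):
        boundary = {tuple(v): i for i, v in enumerate(boundary)}
    mask = np.ones(stack.shape, dtype=bool)
    for vox in boundary:
        mask[vox] = False
    dist = ndimage.distance_transform_edt(mask, sampling=stack.voxel_size)

    m = _Marcher(stack, boundary)
    farthest, far_d = None, -1.0
    exhausted = False
    n_coll_seen = 0
    vetoed: set[tuple[tuple[int, int, int], int, int]] = set()
    while True:
        if stop_on_collision and len(m.collisions) > n_coll_seen:
            new = [c for c in m.collisions[n_coll_seen:] if c not in vetoed]
            n_coll_seen = len(m.collisions)
            for vox, la, lb in sorted(new, key=lambda c: m.T[c[0]]):
                if collision_filter is None or collision_filter(m, vox, la, lb):
                    return MarchResult(m.as_timemap(), farthest, False, vox, (la, lb), dist)
                vetoed.add((vox, la, lb))
        vox = m.step()
        if vox is None:
            exhausted = True
            break
        d = dist[vox]
        if d > d_max:
            break
        if d > far_d:
            farthest, far_d = vox, d
    return MarchResult(m.as_timemap(), farthest, exhausted, dist=dist)


def gradient_descent_path(tmap: TimeMap, start, region_label: int | None = None):
    """Steepest-descent voxel chain on T from ``start`` to the T = 0 boundary.

    Each step moves to the 26-neighbor with the smallest T (strictly
    decreasing). With ``region_label``, steps are restricted to voxels of
    that front label (used to back-propagate from a collision voxel into one
    colliding region). Raises if stuck at a positive local minimum, which
    signals an invalid arrival-time map.
    """
    start = tuple(int(c) for c in start)
    if tmap.state[start] != ACCEPTED and not np.isfinite(tmap.T[start]):
        raise ValueError(f"start voxel {start} was not reached by the front")
    shape = tmap.T.shape
    chain = [start]
    cur = start
    while tmap.T[cur] > 0:
        nbs = _OFFSETS26 + np.array(cur)
        ok = np.all((nbs >= 0) & (nbs < np.array(shape)), axis=1)
        nbs = nbs[ok]
        best, best_t = None, tmap.T[cur]
        for nb in map(tuple, nbs):
            if tmap.state[nb] != ACCEPTED:
                continue
            if region_label is not None and tmap.T[nb] > 0 and tmap.label[nb] != region_label:
                continue
            if tmap.T[nb] < best_t:
                best, best_t = nb, tmap.T[nb]
        if best is None:
            raise RuntimeError(
                f"gradient descent stuck at positive local minimum {cur} "
                "(invalid upwind time map)"
            )
        chain.append(best)
        cur = best
    return chain


def _boundary_components(trace: Trace, node_of: dict) -> dict[tuple[int, int, int], int]:
    """Label boundary voxels by connected component of the trace graph.

    Graph connectivity (not spatial adjacency) defines the fronts, so two
    touching but unconnected trace pieces still count as distinct fronts
    whose collision can join them.
    """
    import networkx as nx

    comp_of: dict[int, int] = {}
    for ci, comp in enumerate(nx.connected_components(trace.graph)):
        for n in comp:
            comp_of[n] = ci
    return {vox: comp_of[nid] for vox, nid in node_of.items()}


def grow_initial_trace(
    stack: ImageStack,
    seeds: SeedSet,
    d_max: float | None = None,
    stop_fraction: float = 0.2,
    max_paths: int = 10000,
    stop_callback=None,
    min_branch_length: float | None = None,
) -> Trace:
    """Grow the initial trace from seed points by iterated Fast Marching.

    Each iteration marches the front up to ``d_max`` (default ``15*s_x``)
    from the current boundary, adds the gradient-descent path from either
    the farthest front point or — if two fronts collided — from the
    collision voxel into both colliding regions, and re-initializes T = 0
    along the enlarged boundary. Growth stops when the mean intensity of the
    last added path falls below ``stop_fraction`` times the mean intensity
    of the existing trace (``stop_callback(path_mean, trace_mean)`` may
    override and continue), or when the front is exhausted. Targets closer
    than ``min_branch_length`` (default ``4*s_x``, the neurite caliber
    scale) never spawn paths, which suppresses surface-halo spurs.

    Returns a :class:`Trace` whose nodes are path voxels at physical
    coordinates with initial caliber ``1*s_x``.
    """
    if len(seeds) == 0:
        raise ValueError("seeds must be nonempty")
    if d_max is None:
        d_max = 15.0 * stack.voxel_size[0]
    s_x = stack.voxel_size[0]

    trace = Trace()
    node_of: dict[tuple[int, int, int], int] = {}

    def _node(vox) -> int:
        vox = tuple(int(c) for c in vox)
        if vox not in node_of:
            node_of[vox] = trace.add_node(stack.index_to_physical(vox), caliber=s_x)
        return node_of[vox]

    def _add_chain(chain) -> None:
        for a, b in zip(chain, chain[1:]):
            na, nb = _node(a), _node(b)
            if na != nb:
                trace.add_edge(na, nb)

    boundary: set[tuple[int, int, int]] = set()
    for p in seeds.points:
        vox = tuple(int(c) for c in p)
        boundary.add(vox)
        _node(vox)

    min_target = min_branch_length if min_branch_length is not None else 4.0 * s_x
    for _ in range(max_paths):
        labels = _boundary_components(trace, node_of)
        trace_mean = float(np.mean([stack.voxels[v] for v in boundary]))
        join_chain: list = []

        def _collision_ok(m, vox, la, lb) -> bool:
            # fronts meeting in dim territory (below the stop rule at the
            # meeting voxel) are crossing a labeling gap or background, not
            # a neurite: veto the join and keep marching
            if stack.voxels[vox] < stop_fraction * trace_mean and not (
                stop_callback is not None
                and stop_callback(float(stack.voxels[vox]), trace_mean)
            ):
                return False
            tm = m.as_timemap()
            try:
                chain_a = gradient_descent_path(tm, vox, region_label=la)
                chain_b = gradient_descent_path(tm, vox, region_label=lb)
            except RuntimeError:
                return False
            join_chain[:] = list(reversed(chain_a)) + chain_b[1:]
            return True

        res = march_to_distance(stack, labels, d_max, collision_filter=_collision_ok)
        tmap = res.tmap

        if res.collision is not None:
            _add_chain(join_chain)
            boundary.update(join_chain)
            continue

        # march targets in decreasing-distance order; a target whose
        # gradient-descent path is dim (below the stop rule) is rejected
        # and its path suppressed; growth stops when no target is left.
        # Targets closer than the neurite caliber scale never spawn paths
        # (D_max must exceed the caliber precisely so that surface-halo
        # voxels are not proposed as branches), and a target voxel dimmer
        # than the stop threshold cannot end a bright branch.
        cand = (
            (tmap.state == ACCEPTED) & (tmap.T > 0)
            & (res.dist <= d_max) & (res.dist >= min_target)
            & (stack.voxels >= stop_fraction * trace_mean)
        )
        accepted_path = False
        flat_dist = np.where(cand.ravel(), res.dist.ravel(), -1.0)
        while flat_dist.max() > 0:
            target = np.unravel_index(int(np.argmax(flat_dist)), stack.shape)
            new_chain = list(reversed(gradient_descent_path(tmap, target)))
            new_vox = [v for v in new_chain if v not in boundary]
            if not new_vox:
                flat_dist[np.ravel_multi_index(target, stack.shape)] = -1.0
                continue
            path_mean = float(np.mean([stack.voxels[v] for v in new_vox]))
            if path_mean >= stop_fraction * trace_mean or (
                stop_callback is not None and stop_callback(path_mean, trace_mean)
            ):
                _add_chain(new_chain)
                boundary.update(new_chain)
                accepted_path = True
                break
            for v in new_chain:  # dim path: suppress and try the next target
                flat_dist[np.ravel_multi_index(v, stack.shape)] = -1.0
        if not accepted_path:
            break
    return trace
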