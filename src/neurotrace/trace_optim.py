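"""Newton refinement of trace node positions and calibers.

The trace fitness consists of the image intensity integrated along the
trace against a Laplacian-of-Gaussian kernel, plus quadratic smoothness
penalties on the positions and calibers of connected nodes:

    F = sum_k sum_m I(l_m) K_{R_k}(l_m - r_k)
        - alpha_r * lam * |D r|^2  -  alpha_R * lam * |D R|^2

where l_m runs over voxel centers near node k, lam is the average node
density (nodes per voxel), alpha_r, alpha_R > 0 set the stiffness of the
regularizers, and D is a neighbor difference operator. The default D takes
second differences over each node's neighbor pairs (discrete curvature),
which penalizes bending without contracting the trace; plain first
differences over edges are available as an option. The kernel K_sigma = -sigma^2 * laplacian(G_sigma) is the
scale-normalized inverted LoG ("mexican hat"), truncated at 4 sigma and
shifted to zero mean over its support; with this normalization the response
to a tube of Gaussian cross-section sigma_t is maximal at caliber
R = sigma_t, so maximizing F recovers both the centerline and the caliber.

All node variables {r_k, R_k} are updated synchronously by a damped
(Levenberg-regularized) Newton step with step-size control beta and
backtracking, so the fitness never decreases across accepted iterations.
Optimization stops when the relative changes of all three fitness terms
fall below ``rel_tol`` (default 1e-8).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from neurotrace.image_stack import ImageStack
from neurotrace.trace_model import Trace

logger = logging.getLogger(__name__)


@dataclass
class FitnessParams:
    """Tunable parameters of the trace fitness and its Newton maximization."""

    alpha_r: float = 1.0
    alpha_R: float = 1.0
    beta: float = 0.5
    rel_tol: float = 1e-8
    max_iter: int = 100
    min_caliber: float = 0.3
    truncation_sigmas: float = 4.0
    regularizer: str = "second_diff"  # or "first_diff"

    def __post_init__(self) -> None:
        if self.alpha_r <= 0 or self.alpha_R <= 0 or self.beta <= 0:
            raise ValueError("alpha_r, alpha_R and beta must be positive")
        if not 0 < self.rel_tol < 1:
            raise ValueError("rel_tol must be in (0, 1)")
        if self.regularizer not in ("second_diff", "first_diff"):
            raise ValueError(f"unknown regularizer {self.regularizer!r}")


def _log_kernel(dpos: np.ndarray, sigma: float) -> np.ndarray:
    """Zero-mean, scale-normalized inverted LoG at displacements (n, 3)."""
    r2 = np.sum(dpos**2, axis=-1)
    g = np.exp(-r2 / (2 * sigma**2)) / ((2 * np.pi) ** 1.5 * sigma**3)
    k = g * (3 * sigma**2 - r2) / sigma**2
    return k - k.mean()


class _NodeWindow:
    """Fixed voxel window around one node for smooth local evaluations.

    The window is only rebuilt when the node drifts more than one voxel
    from the cached center or its caliber outgrows the cached support;
    keeping it fixed between iterations makes the intensity term a smooth
    function of the node variables, which the convergence test and the
    finite-difference derivatives rely on.
    """

    def __init__(self, stack: ImageStack, center: np.ndarray, sigma: float, n_sigmas: float):
        svec = np.array(stack.voxel_size)
        support = 1.5 * sigma  # headroom so caliber growth rarely forces a rebuild
        self.half = np.ceil(n_sigmas * support / svec).astype(int) + 2
        self.c_idx = np.round(stack.physical_to_index(center)).astype(int)
        self.sigma_max = support
        lo = np.maximum(self.c_idx - self.half, 0)
        hi = np.minimum(self.c_idx + self.half + 1, np.array(stack.shape))
        ii, jj, kk = np.meshgrid(*(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij")
        idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
        self.coords = stack.index_to_physical(idx)
        self.I = stack.voxels[ii.ravel(), jj.ravel(), kk.ravel()]

    def still_valid(self, stack: ImageStack, center: np.ndarray, sigma: float) -> bool:
        c = stack.physical_to_index(center)
        return bool(np.all(np.abs(c - self.c_idx) <= 1.6)) and sigma <= self.sigma_max

    def intensity_term(self, r: np.ndarray, R: float) -> float:
        return float(np.dot(self.I, _log_kernel(self.coords - r, R)))


def _get_windows(stack, nodes, pos, cal, n_sigmas, cache):
    for k in nodes:
        w = cache.get(k)
        if w is None or not w.still_valid(stack, pos[k], cal[k]):
            cache[k] = _NodeWindow(stack, pos[k], cal[k], n_sigmas)
    return cache


def _smoothness_operator(trace: Trace, nodes, slot, kind: str):
    """Sparse difference operator D whose rows measure trace roughness.

    ``second_diff``: one row r_a - 2 r_k + r_b per neighbor pair (a, b) of
    each node k — a discrete curvature; zero on uniformly spaced straight
    chains, so it penalizes bending without contracting the trace.
    ``first_diff``: one row r_a - r_b per edge.
    """
    from itertools import combinations as _comb

    rows, cols, vals = [], [], []
    r = 0
    if kind == "first_diff":
        for a, b in trace.graph.edges:
            rows += [r, r]
            cols += [slot[a], slot[b]]
            vals += [1.0, -1.0]
            r += 1
    else:
        for k in nodes:
            nbs = sorted(trace.graph.neighbors(k))
            for a, b in _comb(nbs, 2):
                rows += [r, r, r]
                cols += [slot[a], slot[k], slot[b]]
                vals += [1.0, -2.0, 1.0]
                r += 1
    return sp.csr_matrix((vals, (rows, cols)), shape=(r, len(nodes)))


def _terms(trace: Trace, windows: dict, params: FitnessParams, lam: float,
           pos: dict, cal: dict, D=None, nodes=None, slot=None,
           unit: float = 1.0) -> tuple[float, float, float]:
    if nodes is None:
        nodes = sorted(trace.graph.nodes)
        slot = {k: i for i, k in enumerate(nodes)}
    if D is None:
        D = _smoothness_operator(trace, nodes, slot, params.regularizer)
    it = sum(windows[k].intensity_term(pos[k], cal[k]) for k in windows)
    P = np.array([pos[k] for k in nodes]).reshape(len(nodes), 3)
    R = np.array([cal[k] for k in nodes])
    pt = -params.alpha_r * lam * float(np.sum((D @ P) ** 2))
    ct = -params.alpha_R * lam * float(np.sum((D @ R) ** 2))
    return it, pt, ct


def fitness(trace: Trace, stack: ImageStack, params: FitnessParams | None = None):
    """Evaluate the trace fitness.

    Returns ``(total, intensity_term, position_term, caliber_term)``. Nodes
    outside the stack are clamped to the boundary with a warning.
    """
    if trace.n_nodes == 0:
        raise ValueError("trace is empty")
    params = params or FitnessParams()
    _clamp_nodes(trace, stack)
    lam = trace.n_nodes / stack.voxels.size
    pos = {k: trace.position(k) for k in trace.graph.nodes}
    cal = {k: trace.caliber(k) for k in trace.graph.nodes}
    windows = {k: _NodeWindow(stack, pos[k], cal[k], params.truncation_sigmas)
               for k in trace.graph.nodes}
    it, pt, ct = _terms(trace, windows, params, lam, pos, cal,
                        unit=stack.voxel_size[0])
    return it + pt + ct, it, pt, ct


def _clamp_nodes(trace: Trace, stack: ImageStack) -> None:
    lo = stack.origin
    hi = stack.index_to_physical(np.array(stack.shape) - 1)
    for k in trace.graph.nodes:
        p = trace.position(k)
        q = np.clip(p, lo, hi)
        if not np.allclose(p, q):
            logger.warning("node %s outside stack bounds; clamped", k)
            trace.graph.nodes[k]["pos"] = q


def optimize_trace(trace: Trace, stack: ImageStack, params: FitnessParams | None = None) -> Trace:
    """Maximize the trace fitness over all node positions and calibers.

    A damped Newton step on the full variable set (4 per node) is computed
    from a sparse Hessian — finite-difference 4x4 intensity blocks per node
    plus the exact quadratic regularizer coupling — regularized to be
    negative definite. Steps are accepted only if the total fitness
    increases (backtracking halving), so fitness is non-decreasing. Stops
    when the relative changes of all three fitness terms drop below
    ``rel_tol`` or after ``max_iter`` iterations.
    """
    params = params or FitnessParams()
    trace = trace.copy()
    if trace.n_nodes == 0:
        return trace
    _clamp_nodes(trace, stack)

    nodes = sorted(trace.graph.nodes)
    n = len(nodes)
    slot = {k: i for i, k in enumerate(nodes)}
    lam = n / stack.voxels.size
    lo = stack.origin
    hi_b = stack.index_to_physical(np.array(stack.shape) - 1)

    theta = np.empty(4 * n)
    for k in nodes:
        i = slot[k]
        theta[4 * i: 4 * i + 3] = trace.position(k)
        theta[4 * i + 3] = trace.caliber(k)

    def unpack(th):
        pos = {k: th[4 * slot[k]: 4 * slot[k] + 3] for k in nodes}
        cal = {k: max(th[4 * slot[k] + 3], params.min_caliber) for k in nodes}
        return pos, cal

    D = _smoothness_operator(trace, nodes, slot, params.regularizer)
    DtD = (D.T @ D).tocsr()

    def total_of(th, windows):
        pos, cal = unpack(th)
        return sum(_terms(trace, windows, params, lam, pos, cal, D=D,
                          nodes=nodes, slot=slot, unit=stack.voxel_size[0]))

    h_fd = 1e-3 * stack.voxel_size[0]
    prev_terms = None
    trace.converged_in = None

    window_cache: dict = {}
    for it_no in range(params.max_iter):
        pos, cal = unpack(theta)
        windows = _get_windows(stack, nodes, pos, cal, params.truncation_sigmas, window_cache)
        terms = _terms(trace, windows, params, lam, pos, cal, D=D,
                       nodes=nodes, slot=slot, unit=stack.voxel_size[0])
        if prev_terms is not None:
            # relative change per term, with a scale floor so terms that are
            # negligible against the total fitness cannot stall convergence
            floor = 1e-6 * (abs(sum(terms)) + 1.0)
            rel = [abs(t - p) / max(abs(p), floor) for t, p in zip(terms, prev_terms)]
            if max(rel) < params.rel_tol:
                trace.converged_in = it_no
                break
        prev_terms = terms

        # gradient and Hessian of the intensity term: per-node finite differences
        grad = np.zeros(4 * n)
        rows, cols, vals = [], [], []
        for k in nodes:
            i = slot[k]
            w = windows[k]

            def f(d):
                return w.intensity_term(pos[k] + d[:3], max(cal[k] + d[3], params.min_caliber))

            f0 = f(np.zeros(4))
            e = np.eye(4) * h_fd
            fp = np.array([f(e[j]) for j in range(4)])
            fm = np.array([f(-e[j]) for j in range(4)])
            grad[4 * i: 4 * i + 4] = (fp - fm) / (2 * h_fd)
            hblk = np.zeros((4, 4))
            for j in range(4):
                hblk[j, j] = (fp[j] - 2 * f0 + fm[j]) / h_fd**2
            for j in range(4):
                for l in range(j + 1, 4):
                    fpp = f(e[j] + e[l])
                    hblk[j, l] = hblk[l, j] = (
                        fpp - fp[j] - fp[l] + f0
                    ) / h_fd**2
            for j in range(4):
                for l in range(4):
                    rows.append(4 * i + j)
                    cols.append(4 * i + l)
                    vals.append(hblk[j, l])

        # exact gradient/Hessian of the quadratic regularizers:
        # term = -alpha * lam * |D v|^2  =>  grad = -2 alpha lam DtD v,
        # Hessian = -2 alpha lam DtD per coordinate
        P = theta.reshape(n, 4)[:, :3]
        R = theta.reshape(n, 4)[:, 3]
        gP = -2 * params.alpha_r * lam * (DtD @ P)
        gR = -2 * params.alpha_R * lam * (DtD @ R)
        grad_reg = np.zeros(4 * n)
        grad_reg.reshape(n, 4)[:, :3] = gP
        grad_reg.reshape(n, 4)[:, 3] = gR
        grad += grad_reg

        H = sp.csc_matrix((vals, (rows, cols)), shape=(4 * n, 4 * n))
        coo = DtD.tocoo()
        reg_rows, reg_cols, reg_vals = [], [], []
        for i, j, v in zip(coo.row, coo.col, coo.data):
            for c in range(3):
                reg_rows.append(4 * i + c)
                reg_cols.append(4 * j + c)
                reg_vals.append(-2 * params.alpha_r * lam * v)
            reg_rows.append(4 * i + 3)
            reg_cols.append(4 * j + 3)
            reg_vals.append(-2 * params.alpha_R * lam * v)
        H = H + sp.csc_matrix((reg_vals, (reg_rows, reg_cols)), shape=(4 * n, 4 * n))

        # Levenberg damping: shift H toward -tau*I until the step ascends
        scale = max(float(np.abs(H.diagonal()).max()), 1e-12)
        step = None
        tau = 1e-4 * scale
        for _ in range(30):
            try:
                d = spla.spsolve(-H + tau * sp.eye(4 * n, format="csc"), grad)
            except Exception:
                tau *= 10
                continue
            if np.all(np.isfinite(d)) and np.dot(d, grad) > 0:
                step = d
                break
            tau *= 10
        if step is None:
            gn = np.linalg.norm(grad)
            if gn < 1e-14:
                trace.converged_in = it_no
                break
            logger.info("Hessian solve failed; falling back to gradient ascent")
            step = grad / max(gn, 1e-12)

        f_cur = sum(terms)
        # trial steps: the doubled base step first (full Newton when
        # beta = 0.5), then backtracking halving from beta; a trust cap
        # keeps any single node from moving more than one voxel per step
        disp = np.linalg.norm(step.reshape(n, 4)[:, :3], axis=1).max()
        beta_cap = 2.0 * stack.voxel_size[0] / disp if disp > 0 else 1.0
        betas = [min(2 * params.beta, 1.0, beta_cap), min(params.beta, beta_cap)]
        while betas[-1] > params.beta / 2**18:
            betas.append(betas[-1] / 2)
        accepted = False
        for beta in betas:
            th_new = theta + beta * step
            th_new[3::4] = np.clip(th_new[3::4], params.min_caliber, None)
            for i in range(n):
                th_new[4 * i: 4 * i + 3] = np.clip(th_new[4 * i: 4 * i + 3], lo, hi_b)
            if total_of(th_new, windows) > f_cur:
                theta = th_new
                accepted = True
                break
            beta *= 0.5
        if not accepted:
            trace.converged_in = it_no
            break
    else:
        trace.converged_in = params.max_iter

    pos, cal = unpack(theta)
    for k in nodes:
        trace.graph.nodes[k]["pos"] = np.array(pos[k])
        trace.graph.nodes[k]["radius"] = float(cal[k])
    return trace
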