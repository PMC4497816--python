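"""Willshaw marker-induction model (type I matching with plastic SC markers).

Each RGC carries fixed receptor levels R_A, R_B.  Innervating axons
induce markers I^A, I^B in each SC neuron (weighted means of presynaptic
receptor levels), and the plastic SC ligand fields T^A, T^B relax toward
the induced markers while diffusing over the Delaunay graph of SC
neurons:

    dT^A = (sigma (1 - zeta I^A T^A) + delta lap(T^A)) dt
    dT^B = (sigma (I^B - T^B)        + delta lap(T^B)) dt

Weights then grow according to the receptor/marker similarity

    Phi_ij = exp(-[(zeta R_A T^A_j - 1)^2 + (R_B - T^B_j)^2] / (2 kappa^2))

with presynaptic normalisation keeping every RGC's weights summing to 1.
The A system matches multiplicatively (R_A T^A ~ 1/zeta), the B system
by value.  Near-degenerate Delaunay edges (sliver triangles) are pruned
from the diffusion graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial import Delaunay

from ephmap.connections import ConnectionState
from ephmap.rng import split_streams
from ephmap.substrate import Substrate

SIGMA = 0.05
DELTA = 0.01
THETA = 0.1
KAPPA = 0.0504
ZETA = 1.0
DT = 0.1
N_STEPS = 48_000
W_MIN = 0.001
W_INIT_MAX = 1e-4
PRUNE_ANGLE_DEG = 10.0


@dataclass(frozen=True)
class WillshawParams:
    sigma: float = SIGMA
    delta: float = DELTA
    theta: float = THETA
    kappa: float = KAPPA
    zeta: float = ZETA
    dt: float = DT
    w_min: float = W_MIN


def sc_laplacian_graph(sc_points: np.ndarray, prune_angle_deg: float = PRUNE_ANGLE_DEG):
    """Adjacency of the SC Delaunay graph with sliver edges removed.

    Within each triangle, an edge makes two angles at its endpoints; if
    both are below the pruning angle (i.e. the edge subtends the flat
    apex of a sliver) the edge is dropped.  This removes the long edges
    of boundary slivers that would otherwise let markers diffuse between
    distant neurons, while keeping the short edges of the same triangle.
    """
    tri = Delaunay(sc_points)
    keep: set[tuple[int, int]] = set()
    drop: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        pts = sc_points[simplex]
        # angle at each vertex
        angles = np.zeros(3)
        for k in range(3):
            v1 = pts[(k + 1) % 3] - pts[k]
            v2 = pts[(k + 2) % 3] - pts[k]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-300)
            angles[k] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        for k in range(3):
            a, b = sorted((simplex[(k + 1) % 3], simplex[(k + 2) % 3]))
            # the edge opposite vertex k makes the angles at its endpoints
            end_angles = (angles[(k + 1) % 3], angles[(k + 2) % 3])
            if max(end_angles) < prune_angle_deg:
                drop.add((a, b))
            else:
                keep.add((a, b))
    edges = np.array(sorted(keep - drop), dtype=np.int64)
    n = sc_points.shape[0]
    if edges.size == 0:
        return sparse.csr_matrix((n, n))
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    A = sparse.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    return A


@dataclass
class WillshawState:
    W: np.ndarray
    T_A: np.ndarray
    T_B: np.ndarray
    I_A: np.ndarray
    I_B: np.ndarray
    adjacency: sparse.csr_matrix
    degree: np.ndarray
    params: WillshawParams
    step: int = 0
    zero_afferent_events: int = 0


def induced_markers(W: np.ndarray, substrate: Substrate):
    """Weighted-mean presynaptic receptor levels per SC neuron.

    Returns ``(I_A, I_B, has_afferent)``; SC neurons with zero total
    afferent weight are flagged and get NaN entries (the stepper carries
    their previous induced values forward).
    """
    colsum = W.sum(axis=0)
    ok = colsum > 0
    I_A = np.full(W.shape[1], np.nan)
    I_B = np.full(W.shape[1], np.nan)
    I_A[ok] = (substrate.R_A @ W[:, ok]) / colsum[ok]
    I_B[ok] = (substrate.R_B @ W[:, ok]) / colsum[ok]
    return I_A, I_B, ok


def init_state(
    substrate: Substrate,
    rng: np.random.Generator,
    params: WillshawParams = WillshawParams(),
) -> WillshawState:
    """Uniform random tiny weights; T fields start at the static gradients."""
    W = rng.uniform(0.0, W_INIT_MAX, size=(substrate.n_rgc, substrate.n_sc))
    A = sc_laplacian_graph(substrate.sc)
    degree = np.asarray(A.sum(axis=1)).ravel()
    return WillshawState(
        W=W,
        T_A=substrate.L_A.copy(),
        T_B=substrate.L_B.copy(),
        I_A=np.zeros(substrate.n_sc),
        I_B=np.zeros(substrate.n_sc),
        adjacency=A,
        degree=degree,
        params=params,
    )


def marker_step(state: WillshawState, substrate: Substrate) -> WillshawState:
    """Relax the plastic SC markers toward the induced markers."""
    p = state.params
    lap_A = state.adjacency @ state.T_A - state.degree * state.T_A
    lap_B = state.adjacency @ state.T_B - state.degree * state.T_B
    state.T_A = state.T_A + (p.sigma * (1.0 - p.zeta * state.I_A * state.T_A) + p.delta * lap_A) * p.dt
    state.T_B = state.T_B + (p.sigma * (state.I_B - state.T_B) + p.delta * lap_B) * p.dt
    return state


def weight_step(state: WillshawState, substrate: Substrate) -> WillshawState:
    """Grow weights by marker similarity, then normalise each RGC row to 1."""
    p = state.params
    a = p.zeta * np.outer(substrate.R_A, state.T_A) - 1.0
    b = substrate.R_B[:, None] - state.T_B[None, :]
    phi = np.exp(-(a * a + b * b) / (2.0 * p.kappa**2))
    Wn = state.W + p.theta * p.dt * phi
    state.W = Wn / Wn.sum(axis=1, keepdims=True)
    return state


def willshaw_step(state: WillshawState, substrate: Substrate) -> WillshawState:
    """Full update: induced markers -> marker step -> weight step."""
    I_A, I_B, ok = induced_markers(state.W, substrate)
    if not ok.all():
        state.zero_afferent_events += int(np.sum(~ok))
        I_A[~ok] = state.I_A[~ok]
        I_B[~ok] = state.I_B[~ok]
    state.I_A, state.I_B = I_A, I_B
    marker_step(state, substrate)
    weight_step(state, substrate)
    state.step += 1
    return state


def run_willshaw(
    substrate: Substrate,
    n_steps: int = N_STEPS,
    dt: float = DT,
    seed: int = 0,
    params: WillshawParams | None = None,
    snapshot_every: int | None = None,
) -> ConnectionState:
    """Run the marker-induction dynamics.

    Uses preallocated buffers for the dense similarity update; records
    optional snapshots of the plastic marker fields.
    """
    if params is None:
        params = WillshawParams(dt=dt)
    else:
        params = WillshawParams(**{**params.__dict__, "dt": dt})
    streams = split_streams(seed)
    state = init_state(substrate, streams["model"], params)

    n_r, n_sc = substrate.n_rgc, substrate.n_sc
    W = state.W
    T_A, T_B = state.T_A, state.T_B
    I_A, I_B = state.I_A, state.I_B
    R_A, R_B = substrate.R_A, substrate.R_B
    A = state.adjacency
    deg = state.degree
    sigma, delta, theta, kappa, zeta = (
        params.sigma, params.delta, params.theta, params.kappa, params.zeta,
    )
    inv2k2 = 1.0 / (2.0 * kappa**2)
    phi = np.empty((n_r, n_sc))
    tmp = np.empty((n_r, n_sc))
    snapshots = {"T_A": [], "T_B": []} if snapshot_every else None
    zero_aff = 0

    for step in range(n_steps):
        colsum = W.sum(axis=0)
        ok = colsum > 0
        if ok.all():
            I_A = (R_A @ W) / colsum
            I_B = (R_B @ W) / colsum
        else:
            zero_aff += int(np.sum(~ok))
            newA = (R_A @ W[:, ok]) / colsum[ok]
            newB = (R_B @ W[:, ok]) / colsum[ok]
            I_A = I_A.copy()
            I_B = I_B.copy()
            I_A[ok] = newA
            I_B[ok] = newB

        T_A = T_A + (sigma * (1.0 - zeta * I_A * T_A) + delta * (A @ T_A - deg * T_A)) * dt
        T_B = T_B + (sigma * (I_B - T_B) + delta * (A @ T_B - deg * T_B)) * dt

        np.multiply.outer(R_A, zeta * T_A, out=phi)
        phi -= 1.0
        np.square(phi, out=phi)
        np.subtract.outer(R_B, T_B, out=tmp)
        np.square(tmp, out=tmp)
        phi += tmp
        phi *= -inv2k2
        np.exp(phi, out=phi)

        W += theta * dt * phi
        W /= W.sum(axis=1, keepdims=True)

        if snapshot_every and (step + 1) % snapshot_every == 0:
            snapshots["T_A"].append(T_A.copy())
            snapshots["T_B"].append(T_B.copy())

    log = {"zero_afferent_events": np.array([zero_aff])}
    if snapshots:
        log["T_A_snapshots"] = np.array(snapshots["T_A"])
        log["T_B_snapshots"] = np.array(snapshots["T_B"])
    log["T_A_final"] = T_A
    log["T_B_final"] = T_B
    return ConnectionState(W=W, model="willshaw", w_min=params.w_min, log=log)
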