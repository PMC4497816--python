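"""Gierer terminal-movement model (type II chemoaffinity + competition).

Each RGC axon carries ``N_term = 16`` terminals that walk on the Delaunay
graph of SC neurons, moving downhill on the potential

    p(r_i, s_j) = R_A(r_i) L_A(s_j) - R_B(r_i) L_B(s_j) + c(s_j)

(the A system is repulsive, the B system attractive).  The competition
level ``c`` grows with the local terminal density rho and decays:

    dc/dt = eps * rho - eta * c

integrated with an explicit Euler step of one epoch per unit time after
each terminal sweep.  The steady state ``c = (eps/eta) * rho`` serves as
a convergence gauge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.spatial import Delaunay

from ephmap.connections import ConnectionState
from ephmap.rng import integer_seed, split_streams
from ephmap.substrate import Substrate

N_TERM = 16
EPSILON = 0.005
ETA = 0.1


def sc_neighbor_graph(sc_points: np.ndarray):
    """Delaunay adjacency of SC neurons in CSR form (indptr, indices)."""
    tri = Delaunay(sc_points)
    indptr, indices = tri.vertex_neighbor_vertices
    return indptr.astype(np.int64), indices.astype(np.int64)


@dataclass
class GiererState:
    """Terminal assignment and competition field for one simulation."""

    term_sc: np.ndarray  # (N_R, N_term) SC index of each terminal
    c: np.ndarray  # (N_SC,) competition level
    counts: np.ndarray  # (N_SC,) terminal density rho
    indptr: np.ndarray
    indices: np.ndarray
    n_term: int = N_TERM
    epsilon: float = EPSILON
    eta: float = ETA
    epoch: int = 0
    moves: list = field(default_factory=list)
    c_gap: list = field(default_factory=list)


def init_state(
    substrate: Substrate,
    rng: np.random.Generator,
    n_term: int = N_TERM,
    epsilon: float = EPSILON,
    eta: float = ETA,
) -> GiererState:
    """Connect each RGC to ``n_term`` uniformly random SC neurons; c = 0."""
    term_sc = rng.integers(0, substrate.n_sc, size=(substrate.n_rgc, n_term))
    counts = np.bincount(term_sc.ravel(), minlength=substrate.n_sc)
    indptr, indices = sc_neighbor_graph(substrate.sc)
    return GiererState(
        term_sc=term_sc.astype(np.int64),
        c=np.zeros(substrate.n_sc),
        counts=counts.astype(np.int64),
        indptr=indptr,
        indices=indices,
        n_term=n_term,
        epsilon=epsilon,
        eta=eta,
    )


def gierer_potential(i: int, j: int, state: GiererState, substrate: Substrate) -> float:
    """Potential seen by a terminal of RGC ``i`` sitting on SC neuron ``j``."""
    return float(
        substrate.R_A[i] * substrate.L_A[j]
        - substrate.R_B[i] * substrate.L_B[j]
        + state.c[j]
    )


@njit(cache=False, inline="always")
def _refresh(j, now, c, last_t, counts, epsilon, eta, min_dt):
    """Bring c[j] up to time ``now`` under constant terminal density.

    Between move events the density on j is constant, so the competition
    ODE integrates exactly:
    ``c -> c exp(-eta dt) + (eps/eta) rho (1 - exp(-eta dt))``.

    ``min_dt`` allows bounded staleness for read-only refreshes: below
    it the update is postponed (it stays exact when finally applied; the
    only effect is that a potential evaluation may see a c value at most
    ``min_dt`` epochs old, a drift below eps * rho * min_dt).  Pass 0
    whenever the density on ``j`` is about to change.
    """
    dt = now - last_t[j]
    if dt > min_dt:
        decay = np.exp(-eta * dt)
        c[j] = c[j] * decay + (epsilon / eta) * counts[j] * (1.0 - decay)
        last_t[j] = now


# staleness bound (in epochs) for read-only competition refreshes
_READ_DT = 0.0


@njit(cache=False)
def _sweep(term_sc, counts, c, last_t, t0, RA, RB, LA, LB, indptr, indices, n_term,
           epsilon, eta):
    """One epoch's terminal sweep; visits every terminal in random order.

    A terminal moves to the Delaunay neighbour with the lowest potential
    iff that potential is strictly below the potential at its current
    position; ties among equally minimal neighbours break uniformly at
    random.  Each terminal step advances time by 1/(total terminals), so
    the sweep advances one time unit and the competition field evolves
    continuously within the sweep.  Returns the number of accepted moves.
    """
    n_total = term_sc.size
    dt = 1.0 / n_total
    order = np.random.permutation(n_total)
    moves = 0
    now = t0
    for t in order:
        now += dt
        i = t // n_term
        k = t % n_term
        j = term_sc[i, k]
        _refresh(j, now, c, last_t, counts, epsilon, eta, _READ_DT)
        p_here = RA[i] * LA[j] - RB[i] * LB[j] + c[j]
        best = -1
        best_p = 1e300
        n_best = 0
        for idx in range(indptr[j], indptr[j + 1]):
            jn = indices[idx]
            _refresh(jn, now, c, last_t, counts, epsilon, eta, _READ_DT)
            p = RA[i] * LA[jn] - RB[i] * LB[jn] + c[jn]
            if p < best_p:
                best_p = p
                best = jn
                n_best = 1
            elif p == best_p:
                n_best += 1
                if np.random.random() < 1.0 / n_best:
                    best = jn
        if best >= 0 and best_p < p_here:
            # densities change here: both sites must be exactly current
            _refresh(j, now, c, last_t, counts, epsilon, eta, 0.0)
            _refresh(best, now, c, last_t, counts, epsilon, eta, 0.0)
            term_sc[i, k] = best
            counts[j] -= 1
            counts[best] += 1
            moves += 1
    return moves


@njit(cache=False)
def _run(term_sc, counts, c, RA, RB, LA, LB, indptr, indices, n_term,
         epsilon, eta, n_epochs, seed, moves_log, gap_log):
    np.random.seed(seed)
    last_t = np.zeros(c.size)
    for e in range(n_epochs):
        t0 = float(e)
        moves_log[e] = _sweep(
            term_sc, counts, c, last_t, t0, RA, RB, LA, LB, indptr, indices,
            n_term, epsilon, eta
        )
        # synchronise the field at the epoch boundary for the gauge
        gap = 0.0
        for j in range(c.size):
            _refresh(j, t0 + 1.0, c, last_t, counts, epsilon, eta, 0.0)
            g = abs(c[j] - (epsilon / eta) * counts[j])
            if g > gap:
                gap = g
        gap_log[e] = gap


def gierer_epoch(state: GiererState, substrate: Substrate, seed: int) -> GiererState:
    """Advance the state by one epoch (sweep + Euler competition update)."""
    moves = np.zeros(1, dtype=np.int64)
    gap = np.zeros(1)
    _run(
        state.term_sc, state.counts, state.c,
        substrate.R_A, substrate.R_B, substrate.L_A, substrate.L_B,
        state.indptr, state.indices, state.n_term,
        state.epsilon, state.eta, 1, seed, moves, gap,
    )
    state.epoch += 1
    state.moves.append(int(moves[0]))
    state.c_gap.append(float(gap[0]))
    return state


def run_gierer(
    substrate: Substrate,
    n_epochs: int = 10_000,
    seed: int = 0,
    n_term: int = N_TERM,
    epsilon: float = EPSILON,
    eta: float = ETA,
) -> ConnectionState:
    """Run the model to convergence and return integer terminal counts."""
    streams = split_streams(seed)
    state = init_state(substrate, streams["model"], n_term, epsilon, eta)
    moves_log = np.zeros(n_epochs, dtype=np.int64)
    gap_log = np.zeros(n_epochs)
    _run(
        state.term_sc, state.counts, state.c,
        substrate.R_A, substrate.R_B, substrate.L_A, substrate.L_B,
        state.indptr, state.indices, state.n_term,
        state.epsilon, state.eta, n_epochs, integer_seed(streams["model"]),
        moves_log, gap_log,
    )
    W = np.zeros((substrate.n_rgc, substrate.n_sc), dtype=np.int32)
    np.add.at(W, (np.repeat(np.arange(substrate.n_rgc), n_term),
                  state.term_sc.ravel()), 1)
    return ConnectionState(
        W=W,
        model="gierer",
        w_min=0.0,
        log={"moves": moves_log, "c_gap": gap_log},
    )
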