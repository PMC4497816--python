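"""Whitelaw Hebbian model with chemospecific adhesion and dual normalization.

Continuous weights start fully connected at 1.  Each epoch sweeps every
RGC once as the centre of a circular retinal wave of radius ``r_R``; the
wave activity is normalised to total 2.  Induced SC activity is smoothed
over SC neighbourhoods of radius ``r_SC`` and drives a Hebbian update
gated by the adhesion matrix

    M_ij = R_A(r_i) [max_k L_A(s_k) - L_A(s_j)] + R_B(r_i) L_B(s_j)

(repulsive A system folded into a nonnegative coefficient; attractive B
system).  The accumulated update is applied once per epoch, small
weights are zeroed, and the matrix is normalised per SC neuron (columns
to N_R) and then per RGC (rows to N_SC) - in that order, which is what
preserves the knock-in phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from ephmap.connections import ConnectionState
from ephmap.substrate import Substrate

R_RETINA = 0.07
R_SC = 0.0289
MU = 0.1
DT = 0.0001
W_MIN = 1e-5
K_LATERAL = 0.5  # lateral proportionality constant; keeps induced SC
                 # activity below the retinal input level


@dataclass(frozen=True)
class WhitelawParams:
    r_retina: float = R_RETINA
    r_sc: float = R_SC
    mu: float = MU
    dt: float = DT
    w_min: float = W_MIN
    k: float = K_LATERAL


def adhesion_matrix(substrate: Substrate) -> np.ndarray:
    """Nonnegative chemospecific adhesion coefficients M_ij."""
    la_max = float(np.max(substrate.L_A))
    M = np.outer(substrate.R_A, la_max - substrate.L_A) + np.outer(
        substrate.R_B, substrate.L_B
    )
    return M


def _neighbour_lists(points: np.ndarray, radius: float) -> list[np.ndarray]:
    tree = cKDTree(points)
    return [np.asarray(nb, dtype=np.int64) for nb in tree.query_ball_point(points, radius)]


def wave_activity(q: int, substrate: Substrate, r_retina: float = R_RETINA) -> np.ndarray:
    """Retinal activity vector for a wave centred on RGC ``q`` (sums to 2)."""
    tree = cKDTree(substrate.retina)
    nb = np.asarray(tree.query_ball_point(substrate.retina[q], r_retina))
    x = np.zeros(substrate.n_rgc)
    x[nb] = 2.0 / nb.size
    return x


@dataclass
class WhitelawState:
    W: np.ndarray
    M: np.ndarray
    X: sparse.csr_matrix  # row q: wave activity when q is the centre
    S: sparse.csr_matrix  # row j: lateral SC averaging (k / |neigh|)
    params: WhitelawParams
    epoch: int = 0
    zero_rows: int = 0
    zero_cols: int = 0


def init_state(substrate: Substrate, params: WhitelawParams = WhitelawParams()) -> WhitelawState:
    n_r, n_sc = substrate.n_rgc, substrate.n_sc
    W = np.ones((n_r, n_sc))
    M = adhesion_matrix(substrate)

    r_nb = _neighbour_lists(substrate.retina, params.r_retina)
    rows = np.concatenate([np.full(nb.size, q) for q, nb in enumerate(r_nb)])
    cols = np.concatenate(r_nb)
    vals = np.concatenate([np.full(nb.size, 2.0 / nb.size) for nb in r_nb])
    X = sparse.csr_matrix((vals, (rows, cols)), shape=(n_r, n_r))

    s_nb = _neighbour_lists(substrate.sc, params.r_sc)
    rows = np.concatenate([np.full(nb.size, j) for j, nb in enumerate(s_nb)])
    cols = np.concatenate(s_nb)
    vals = np.concatenate([np.full(nb.size, params.k / nb.size) for nb in s_nb])
    S = sparse.csr_matrix((vals, (rows, cols)), shape=(n_sc, n_sc))
    return WhitelawState(W=W, M=M, X=X, S=S, params=params)


def whitelaw_epoch(state: WhitelawState, substrate: Substrate) -> WhitelawState:
    """One epoch: all RGCs act as wave centres, then update + normalise."""
    p = state.params
    W = state.W
    # Y_I[q, j]: induced SC activity for wave q; Y: laterally smoothed.
    YI = state.X @ W
    Y = YI @ state.S.T
    hebb = state.X.T @ Y  # sum_q x_i^q y_j^q
    ysum = Y.sum(axis=0)
    W += p.dt * ((state.M + 1.0) * hebb - p.mu * ysum[None, :])
    W[W < p.w_min] = 0.0

    colsum = W.sum(axis=0)
    ok = colsum > 0
    state.zero_cols += int(np.sum(~ok))
    W[:, ok] *= substrate.n_rgc / colsum[ok]

    rowsum = W.sum(axis=1)
    ok = rowsum > 0
    state.zero_rows += int(np.sum(~ok))
    W[ok, :] *= substrate.n_sc / rowsum[ok, None]

    state.epoch += 1
    return state


def run_whitelaw(
    substrate: Substrate,
    n_epochs: int = 500,
    seed: int = 0,
    params: WhitelawParams = WhitelawParams(),
) -> ConnectionState:
    """Run the model; the dynamics are deterministic given the substrate.

    The wave centre order within an epoch is immaterial because updates
    are accumulated over the epoch and applied once, so the sweep is the
    fixed order 1..N_R.  ``seed`` is accepted for interface symmetry.
    """
    state = init_state(substrate, params)
    dw_log = np.zeros(n_epochs)
    for e in range(n_epochs):
        prev = state.W.copy()
        whitelaw_epoch(state, substrate)
        dw_log[e] = float(np.mean(np.abs(state.W - prev)))
    return ConnectionState(
        W=state.W,
        model="whitelaw",
        w_min=params.w_min,
        log={
            "mean_weight_change": dw_log,
            "zero_rows": np.array([state.zero_rows]),
            "zero_cols": np.array([state.zero_cols]),
        },
    )
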