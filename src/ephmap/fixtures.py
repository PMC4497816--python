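"""Synthetic mappings with known ground truth for exercising the analysis.

Constructions: an ideal topographic map, a noisy version, a mirrored
map, a duplicated (knock-in-like) map, a duplicated map merging at a
chosen NT position, a randomly scrambled map, and a map compressed into
the anterior half of the SC.  Each construction also yields a consistent
one-hot weight matrix so analysis code can be fed either form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ephmap.analysis.mapping import PointMapping
from ephmap.substrate import Substrate

KINDS = (
    "identity",
    "noisy",
    "mirrored",
    "duplicated",
    "merged_at",
    "random",
    "half_coverage",
)


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    noise: float = 0.0
    offset: float = 0.3  # AP separation of the duplicated submaps
    merge_at: float = 0.7  # NT position where duplicated maps join
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")


def _transfer(retina: np.ndarray, ap: np.ndarray | None = None) -> np.ndarray:
    """Biologically correct affine transfer of retinal points into the SC.

    Both axes reverse: temporal retina (x = 1) maps to anterior SC
    (x = 0) and ventral retina (y = 1) to medial SC (y = 0).
    """
    out = np.empty_like(retina)
    out[:, 0] = (1.0 - retina[:, 0]) if ap is None else ap
    out[:, 1] = 1.0 - retina[:, 1]
    return out


def make_mapping(spec: FixtureSpec, substrate: Substrate):
    """Build ``(PointMapping, W)`` for the named construction."""
    rng = np.random.default_rng(spec.seed)
    retina = substrate.retina
    n_r = substrate.n_rgc
    x = retina[:, 0]
    ap_base = 1.0 - x  # canonical NT -> AP transfer

    if spec.kind in ("identity", "noisy"):
        target = _transfer(retina)
    elif spec.kind == "mirrored":
        target = _transfer(retina, ap=x)  # AP direction reversed
    elif spec.kind == "duplicated":
        # knock-in-like: one interleaved population shifted anteriorly,
        # two parallel full-length bands separated by `offset`
        pop = rng.random(n_r) < 0.5
        ap = np.where(
            pop,
            (1.0 - spec.offset) * ap_base,  # anterior band (Isl2+-like)
            spec.offset + (1.0 - spec.offset) * ap_base,
        )
        target = _transfer(retina, ap=ap)
    elif spec.kind == "merged_at":
        pop = rng.random(n_r) < 0.5
        nasal = x < spec.merge_at
        ap = np.where(
            nasal & pop,
            np.clip(ap_base - spec.offset / 2.0, 0.0, 1.0),
            np.where(nasal, np.clip(ap_base + spec.offset / 2.0, 0.0, 1.0), ap_base),
        )
        target = _transfer(retina, ap=ap)
    elif spec.kind == "random":
        target = _transfer(retina)
    elif spec.kind == "half_coverage":
        target = _transfer(retina, ap=0.5 * ap_base)  # anterior half only
    else:  # pragma: no cover
        raise AssertionError

    if spec.noise > 0:
        target = target + rng.normal(0.0, spec.noise, size=target.shape)
    if spec.kind == "random":
        target = target[rng.permutation(n_r)]

    # The mapping carries the exact constructed SC positions; the weight
    # matrix snaps each target to the nearest SC neuron (one-hot rows) so
    # weight-based operations stay consistent with the construction.
    tree = cKDTree(substrate.sc)
    _, sc_idx = tree.query(target)
    W = np.zeros((n_r, substrate.n_sc))
    W[np.arange(n_r), sc_idx] = 1.0
    mapping = PointMapping(
        retina=retina.copy(),
        sc=target,
        rgc_index=np.arange(n_r),
        isl2=substrate.isl2.copy() if substrate.isl2 is not None else None,
        n_excluded=0,
    )
    return mapping, W
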