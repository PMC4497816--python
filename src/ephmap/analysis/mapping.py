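"""Point-to-point mapping extracted from a weight matrix.

For each RGC the corresponding SC point is the neuron receiving its
strongest connection; RGCs whose (thresholded) rows are all zero are
excluded and counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ephmap.connections import ConnectionState
from ephmap.substrate import Substrate


@dataclass
class PointMapping:
    """Paired retinal and SC coordinates, one pair per mapped RGC."""

    retina: np.ndarray  # (N, 2)
    sc: np.ndarray  # (N, 2)
    rgc_index: np.ndarray  # (N,) original RGC indices
    isl2: np.ndarray | None = None  # (N,) bool, when the genotype labels RGCs
    n_excluded: int = 0

    def __len__(self) -> int:
        return self.retina.shape[0]

    def subset(self, mask: np.ndarray) -> "PointMapping":
        return PointMapping(
            retina=self.retina[mask],
            sc=self.sc[mask],
            rgc_index=self.rgc_index[mask],
            isl2=None if self.isl2 is None else self.isl2[mask],
            n_excluded=self.n_excluded,
        )


def strongest_target_mapping(state: ConnectionState, substrate: Substrate) -> PointMapping:
    """Build the strongest-connection mapping from a model output."""
    target = state.strongest_target()
    mapped = target >= 0
    idx = np.nonzero(mapped)[0]
    return PointMapping(
        retina=substrate.retina[idx],
        sc=substrate.sc[target[idx]],
        rgc_index=idx,
        isl2=substrate.isl2[idx] if substrate.isl2 is not None else None,
        n_excluded=int(np.sum(~mapped)),
    )


def central_third_mask(mapping: PointMapping, axis: str = "dv") -> np.ndarray:
    """Mask of RGCs in the central third of the named retinal axis.

    ``axis='dv'`` keeps the central dorsoventral band (used when plotting
    NT -> AP projections); ``axis='nt'`` the central nasotemporal band.
    """
    coord = mapping.retina[:, 1] if axis == "dv" else mapping.retina[:, 0]
    return (coord >= 1.0 / 3.0) & (coord <= 2.0 / 3.0)
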