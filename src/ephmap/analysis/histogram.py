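"""Projection histograms (NT -> AP and DV -> ML density plots)."""

from __future__ import annotations

import numpy as np

from ephmap.analysis.mapping import PointMapping, central_third_mask


def projection_histogram(
    mapping: PointMapping,
    axes: str = "nt-ap",
    band: str | None = "central_third",
    bins: int = 50,
):
    """2D density of retinal axis position vs SC axis position.

    ``axes`` is ``"nt-ap"`` or ``"dv-ml"``; ``band="central_third"``
    restricts to the central third of the orthogonal retinal axis.
    Returns ``(H, retina_edges, sc_edges)`` with H normalised to sum 1.
    """
    if axes == "nt-ap":
        r_coord, s_coord, ortho = 0, 0, "dv"
    elif axes == "dv-ml":
        r_coord, s_coord, ortho = 1, 1, "nt"
    else:
        raise ValueError("axes must be 'nt-ap' or 'dv-ml'")
    m = mapping
    if band == "central_third":
        m = mapping.subset(central_third_mask(mapping, axis=ortho))
    H, r_edges, s_edges = np.histogram2d(
        m.retina[:, r_coord], m.sc[:, s_coord], bins=bins, range=[[0, 1], [0, 1]]
    )
    total = H.sum()
    if total > 0:
        H = H / total
    return H, r_edges, s_edges
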