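"""Virtual paired retrograde injections and the segregation measure.

Two virtual tracer injections are placed in the SC; every RGC whose
strongest SC target lies within the injection radius is labelled with
that injection's colour (ties go to the nearer centre).  The segregation
measure is the fraction of labelled RGCs whose nearest labelled
neighbour in the retina carries the same colour: 1 for two fully
segregated projections, 0.5 for two overlapping ones.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from ephmap.analysis.mapping import PointMapping

DEFAULT_RADIUS = 0.05


class InjectionError(ValueError):
    """Raised when an injection labels too few RGCs."""


def label_injection(mapping: PointMapping, centers, radius: float = DEFAULT_RADIUS):
    """Colour labels (0/1) and the labelled subset for two SC injections."""
    centers = np.asarray(centers, dtype=float)
    if centers.shape != (2, 2):
        raise ValueError("exactly two 2D injection centres are required")
    d = np.linalg.norm(mapping.sc[:, None, :] - centers[None, :, :], axis=2)
    within = d <= radius
    labelled = within.any(axis=1)
    colour = np.argmin(d, axis=1)  # ties between overlapping injections -> nearer
    for c in (0, 1):
        if np.sum(labelled & (colour == c)) < 2:
            raise InjectionError(
                f"injection {c} labelled fewer than 2 RGCs (radius={radius})"
            )
    return labelled, colour


def segregation(
    mapping: PointMapping,
    centers,
    radius: float = DEFAULT_RADIUS,
) -> float:
    """Fraction of labelled RGCs whose nearest labelled neighbour matches."""
    labelled, colour = label_injection(mapping, centers, radius)
    pts = mapping.retina[labelled]
    col = colour[labelled]
    tree = cKDTree(pts)
    _, nn = tree.query(pts, k=2)
    neighbour = nn[:, 1]  # first column is the point itself
    return float(np.mean(col == col[neighbour]))
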