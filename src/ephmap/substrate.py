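"""Substrate generation: neuron placement, Eph/ephrin gradients, genotypes.

The retina is a circle of unit diameter; its axes are nasotemporal
(x: 0 = nasal, 1 = temporal) and dorsoventral (y: 0 = dorsal,
1 = ventral).  The SC outline is a smooth blob with unit anteroposterior
extent (x: 0 = anterior, 1 = posterior) and a shorter mediolateral extent
(y: 0 = medial, 1 = lateral).  Neurons are placed by rejection sampling
with a hard minimum-distance (exclusion) constraint, with buffer points
placed outside the outline so the density is not inflated at the edge.

Each receptor/ligand subtype follows an exponential profile
``G(x) = max(0, G0 + G1 * exp(-G2 * |x - G3|))`` along one axis.  The
subtype profiles are summed per family (EphA, EphB, ephrin-A, ephrin-B)
and scaled by a fixed constant chosen so that each summed wild-type
family peaks at 1 on its axis; the same scaling is reused for every
genotype, so knock-ins peak above 1 and knock-outs below 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

# ---------------------------------------------------------------------------
# Gradient profiles (one exponential per protein subtype)
# ---------------------------------------------------------------------------


class GradientParams(NamedTuple):
    """Exponential profile parameters for one protein subtype.

    ``G(x) = max(0, G0 + G1 * exp(-G2 * |x - G3|))`` with ``x`` in [0, 1].
    """

    G0: float
    G1: float
    G2: float
    G3: float


# Retinal EphA subtypes along the nasotemporal axis (measured profiles).
RETINAL_EPHA = {
    "EphA4": GradientParams(1.05, 0.0, 0.0, 1.0),
    "EphA5": GradientParams(0.0, 0.85, 1.8, 1.0),
    "EphA6": GradientParams(0.0, 1.64, 2.9, 1.0),
}

# Knocked-in EphA3 levels (flat along the axis), added only to Isl2+ RGCs.
EPHA3_KNOCKIN = {
    "homozygous": GradientParams(1.86, 0.0, 0.0, 1.0),
    "heterozygous": GradientParams(0.93, 0.0, 0.0, 1.0),
}

# Retinal EphB along the dorsoventral axis (ventral high).
RETINAL_EPHB = {"EphB": GradientParams(0.0, 1.0, 1.0, 1.0)}

# SC ephrin-A subtypes along the anteroposterior axis (posterior high).
SC_EPHRINA = {
    "ephrin-A2": GradientParams(-0.06, 0.35, 2.0, 0.8),
    "ephrin-A3": GradientParams(0.05, 0.0, 0.0, 1.0),
    "ephrin-A5": GradientParams(-0.1, 0.9, 3.0, 1.0),
}

# SC ephrin-B along the mediolateral axis (medial high).
SC_EPHRINB = {"ephrin-B": GradientParams(0.0, 1.0, 1.0, 0.0)}


def eval_gradient(params: GradientParams, x) -> np.ndarray | float:
    """Evaluate one subtype profile at axis position(s) ``x`` in [0, 1]."""
    x = np.asarray(x, dtype=float)
    if params.G2 < 0:
        raise ValueError("decay constant G2 must be nonnegative")
    val = params.G0 + params.G1 * np.exp(-params.G2 * np.abs(x - params.G3))
    out = np.maximum(0.0, val)
    return float(out) if out.ndim == 0 else out


def summed_gradient(table: dict[str, GradientParams], x) -> np.ndarray | float:
    """Sum of all subtype profiles in ``table`` at position(s) ``x``."""
    x = np.asarray(x, dtype=float)
    total = np.zeros_like(x)
    for params in table.values():
        total = total + eval_gradient(params, x)
    return float(total) if total.ndim == 0 else total


def _grid_peak(table: dict[str, GradientParams], n: int = 4001) -> float:
    grid = np.linspace(0.0, 1.0, n)
    return float(np.max(summed_gradient(table, grid)))


# Wild-type peak of each summed family; computed once and reused for every
# genotype so that mutant gradients keep their absolute scale.
WT_PEAKS = {
    "EphA": _grid_peak(RETINAL_EPHA),
    "EphB": _grid_peak(RETINAL_EPHB),
    "ephrin-A": _grid_peak(SC_EPHRINA),
    "ephrin-B": _grid_peak(SC_EPHRINB),
}


# ---------------------------------------------------------------------------
# Structure outlines
# ---------------------------------------------------------------------------


class Circle:
    """Unit-diameter circular retina, centred at (0.5, 0.5)."""

    def __init__(self, center=(0.5, 0.5), radius=0.5):
        self.center = np.asarray(center, dtype=float)
        self.radius = float(radius)

    @property
    def bbox(self):
        cx, cy = self.center
        r = self.radius
        return (cx - r, cy - r, cx + r, cy + r)

    @property
    def area(self) -> float:
        return np.pi * self.radius**2

    def contains(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d2 = np.sum((pts - self.center) ** 2, axis=1)
        return d2 <= self.radius**2


class SCOutline:
    """Smooth convex blob approximating the SC, unit AP extent.

    The mediolateral half-width at AP position ``x`` is
    ``w * (4 x (1 - x))**p`` about the midline y = 0.5, giving a rounded
    outline that is longer anteroposteriorly than mediolaterally.  The
    exact experimental outline is not recoverable; downstream analysis is
    outline-agnostic.
    """

    def __init__(self, half_width: float = 0.42, power: float = 0.6):
        self.half_width = float(half_width)
        self.power = float(power)

    def _hw(self, x):
        x = np.clip(x, 0.0, 1.0)
        return self.half_width * (4.0 * x * (1.0 - x)) ** self.power

    @property
    def bbox(self):
        return (0.0, 0.5 - self.half_width, 1.0, 0.5 + self.half_width)

    @property
    def area(self) -> float:
        x = np.linspace(0.0, 1.0, 20001)
        return float(np.trapezoid(2.0 * self._hw(x), x))

    def contains(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        x, y = pts[:, 0], pts[:, 1]
        inside_x = (x >= 0.0) & (x <= 1.0)
        return inside_x & (np.abs(y - 0.5) <= self._hw(x))

    def polygon(self, n: int = 64) -> np.ndarray:
        """Closed polygon approximation (for export / plotting)."""
        x = np.linspace(0.0, 1.0, n // 2)
        top = np.column_stack([x, 0.5 + self._hw(x)])
        bot = np.column_stack([x[::-1], 0.5 - self._hw(x[::-1])])
        return np.vstack([top, bot])


# ---------------------------------------------------------------------------
# Neuron placement
# ---------------------------------------------------------------------------


class PackingError(RuntimeError):
    """Raised when the rejection budget is exhausted during placement."""


def place_neurons(
    count: int,
    outline,
    exclusion: float,
    rng: np.random.Generator,
    buffer_factor: float = 3.0,
) -> np.ndarray:
    """Place ``count`` points inside ``outline`` with a minimum spacing.

    Candidate positions are drawn uniformly from the outline's bounding
    box expanded by ``buffer_factor * exclusion`` on every side; accepted
    points outside the outline act as virtual neighbours (avoiding edge
    density inflation) and are discarded at the end.  A candidate closer
    than ``exclusion`` to any accepted point is rejected; after
    ``1000 * count`` rejections a :class:`PackingError` is raised.
    """
    if count < 1:
        raise ValueError("count must be positive")
    x0, y0, x1, y1 = outline.bbox
    pad = buffer_factor * exclusion
    lo = np.array([x0 - pad, y0 - pad])
    hi = np.array([x1 + pad, y1 + pad])

    cell = max(exclusion, 1e-12)
    grid: dict[tuple[int, int], list[int]] = {}
    accepted: list[np.ndarray] = []
    inside_flags: list[bool] = []
    n_inside = 0
    rejections = 0
    budget = 1000 * count
    excl2 = exclusion**2

    while n_inside < count:
        if rejections >= budget:
            raise PackingError(
                f"placed {n_inside}/{count} points before exhausting "
                f"{budget} rejections (exclusion={exclusion})"
            )
        p = lo + (hi - lo) * rng.random(2)
        key = (int(p[0] // cell), int(p[1] // cell))
        clash = False
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for idx in grid.get((key[0] + dx, key[1] + dy), ()):
                    if np.sum((accepted[idx] - p) ** 2) < excl2:
                        clash = True
                        break
                if clash:
                    break
            if clash:
                break
        if clash:
            rejections += 1
            continue
        grid.setdefault(key, []).append(len(accepted))
        accepted.append(p)
        inside = bool(outline.contains(p[None, :])[0])
        inside_flags.append(inside)
        if inside:
            n_inside += 1

    pts = np.array(accepted)[np.array(inside_flags)]
    return pts[:count]


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

GENOTYPES = ("wild_type", "isl2_epha3_ki_ki", "isl2_epha3_ki_het", "tko", "math5")


@dataclass(frozen=True)
class GenotypeSpec:
    """Recipe for genotype-specific initial conditions.

    ``K`` scales the SC ephrin-A gradient in the triple knock-out (0 means
    complete removal; 0 < K < 1 reintroduces a weak gradient of wild-type
    shape).  ``population_fraction`` scales the RGC count (0.1 for the
    Math5 null).  ``isl2_fraction`` is the probability that an RGC carries
    the Isl2-EphA3 knock-in label; ``epha3_g0`` is the flat EphA3 level
    added to labelled cells.
    """

    name: str
    K: float = 1.0
    population_fraction: float = 1.0
    isl2_fraction: float = 0.0
    epha3_g0: float = 0.0

    def __post_init__(self):
        if self.name not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.name!r}")
        if not (0.0 <= self.K <= 1.0):
            raise ValueError("K must lie in [0, 1]")
        if not (0.0 < self.population_fraction <= 1.0):
            raise ValueError("population fraction must lie in (0, 1]")


def genotype(name: str, K: float = 0.0) -> GenotypeSpec:
    """Construct the spec for one of the five study genotypes."""
    if name == "wild_type":
        return GenotypeSpec("wild_type")
    if name == "isl2_epha3_ki_ki":
        return GenotypeSpec(
            "isl2_epha3_ki_ki",
            isl2_fraction=0.4,
            epha3_g0=EPHA3_KNOCKIN["homozygous"].G0,
        )
    if name == "isl2_epha3_ki_het":
        return GenotypeSpec(
            "isl2_epha3_ki_het",
            isl2_fraction=0.4,
            epha3_g0=EPHA3_KNOCKIN["heterozygous"].G0,
        )
    if name == "tko":
        return GenotypeSpec("tko", K=K)
    if name == "math5":
        return GenotypeSpec("math5", population_fraction=0.1)
    raise ValueError(f"unknown genotype {name!r}")


# ---------------------------------------------------------------------------
# Substrate assembly
# ---------------------------------------------------------------------------

# Exclusion distances that pack 2000 neurons into each structure; scaled as
# 1/sqrt(N) when a different population size is requested, preserving the
# packing fraction.
D_R_REFERENCE = 0.0139
D_SC_REFERENCE = 0.0119
N_REFERENCE = 2000


@dataclass
class Substrate:
    """Neuron positions and sampled gradient levels for one run."""

    genotype: GenotypeSpec
    retina: np.ndarray  # (N_R, 2)
    sc: np.ndarray  # (N_SC, 2)
    R_A: np.ndarray  # per-RGC summed EphA (scaled)
    R_B: np.ndarray  # per-RGC summed EphB (scaled)
    L_A: np.ndarray  # per-SC summed ephrin-A (scaled)
    L_B: np.ndarray  # per-SC summed ephrin-B (scaled)
    isl2: np.ndarray  # per-RGC bool
    d_R: float
    d_SC: float
    seed: int
    retina_outline: Circle = field(default_factory=Circle)
    sc_outline: SCOutline = field(default_factory=SCOutline)

    @property
    def n_rgc(self) -> int:
        return self.retina.shape[0]

    @property
    def n_sc(self) -> int:
        return self.sc.shape[0]

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            g = f.create_group("positions")
            g.create_dataset("retina", data=self.retina)
            g.create_dataset("sc", data=self.sc)
            g = f.create_group("gradients")
            for name in ("R_A", "R_B", "L_A", "L_B"):
                g.create_dataset(name, data=getattr(self, name))
            f.create_dataset("flags/isl2", data=self.isl2.astype(np.uint8))
            m = f.create_group("metadata")
            m.attrs["genotype"] = self.genotype.name
            m.attrs["K"] = self.genotype.K
            m.attrs["population_fraction"] = self.genotype.population_fraction
            m.attrs["isl2_fraction"] = self.genotype.isl2_fraction
            m.attrs["epha3_g0"] = self.genotype.epha3_g0
            m.attrs["d_R"] = self.d_R
            m.attrs["d_SC"] = self.d_SC
            m.attrs["seed"] = self.seed

    @classmethod
    def load(cls, path) -> "Substrate":
        import h5py

        with h5py.File(path, "r") as f:
            m = f["metadata"].attrs
            spec = GenotypeSpec(
                name=str(m["genotype"]),
                K=float(m["K"]),
                population_fraction=float(m["population_fraction"]),
                isl2_fraction=float(m["isl2_fraction"]),
                epha3_g0=float(m["epha3_g0"]),
            )
            return cls(
                genotype=spec,
                retina=f["positions/retina"][...],
                sc=f["positions/sc"][...],
                R_A=f["gradients/R_A"][...],
                R_B=f["gradients/R_B"][...],
                L_A=f["gradients/L_A"][...],
                L_B=f["gradients/L_B"][...],
                isl2=f["flags/isl2"][...].astype(bool),
                d_R=float(m["d_R"]),
                d_SC=float(m["d_SC"]),
                seed=int(m["seed"]),
            )

    def to_dataframes(self):
        """Per-neuron tables (retina, SC) for inspection/CSV export."""
        import pandas as pd

        retina = pd.DataFrame(
            {
                "x_nt": self.retina[:, 0],
                "y_dv": self.retina[:, 1],
                "R_A": self.R_A,
                "R_B": self.R_B,
                "isl2": self.isl2,
            }
        )
        sc = pd.DataFrame(
            {
                "x_ap": self.sc[:, 0],
                "y_ml": self.sc[:, 1],
                "L_A": self.L_A,
                "L_B": self.L_B,
            }
        )
        return retina, sc


def build_substrate(
    spec: GenotypeSpec,
    n_rgc: int = 2000,
    n_sc: int = 2000,
    seed: int = 0,
    d_R: float | None = None,
    d_SC: float | None = None,
) -> Substrate:
    """Assemble genotype-specific initial conditions.

    ``n_rgc`` is the wild-type RGC count; genotypes with a reduced retina
    (Math5) keep only ``population_fraction * n_rgc`` cells.  Exclusion
    distances default to the reference values for 2000 neurons, rescaled
    as 1/sqrt(N) for other population sizes.
    """
    from ephmap.rng import split_streams

    streams = split_streams(seed)
    n_r_eff = max(1, int(round(spec.population_fraction * n_rgc)))
    if d_R is None:
        d_R = D_R_REFERENCE * np.sqrt(N_REFERENCE / max(n_rgc, 1))
    if d_SC is None:
        d_SC = D_SC_REFERENCE * np.sqrt(N_REFERENCE / max(n_sc, 1))

    retina_outline = Circle()
    sc_outline = SCOutline()
    # The exclusion constraint applies to the wild-type density; the Math5
    # retina is sparser but keeps the same spacing rule.
    retina = place_neurons(n_r_eff, retina_outline, d_R, streams["retina"])
    sc = place_neurons(n_sc, sc_outline, d_SC, streams["sc"])

    isl2 = np.zeros(n_r_eff, dtype=bool)
    if spec.isl2_fraction > 0:
        isl2 = streams["isl2"].random(n_r_eff) < spec.isl2_fraction

    R_A = summed_gradient(RETINAL_EPHA, retina[:, 0])
    R_A = (R_A + spec.epha3_g0 * isl2) / WT_PEAKS["EphA"]
    R_B = summed_gradient(RETINAL_EPHB, retina[:, 1]) / WT_PEAKS["EphB"]

    L_A = summed_gradient(SC_EPHRINA, sc[:, 0]) / WT_PEAKS["ephrin-A"]
    if spec.name == "tko":
        L_A = spec.K * L_A
    L_B = summed_gradient(SC_EPHRINB, sc[:, 1]) / WT_PEAKS["ephrin-B"]

    return Substrate(
        genotype=spec,
        retina=retina,
        sc=sc,
        R_A=R_A,
        R_B=R_B,
        L_A=L_A,
        L_B=L_B,
        isl2=isl2,
        d_R=d_R,
        d_SC=d_SC,
        seed=seed,
        retina_outline=retina_outline,
        sc_outline=sc_outline,
    )
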