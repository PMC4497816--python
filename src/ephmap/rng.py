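"""Seed management.

Every run takes one master seed which is split deterministically into
independent streams for neuron placement, Isl2 labelling, model dynamics
and analysis, so that repeats of a genotype differ only through the seed.
"""

from __future__ import annotations

import numpy as np

_STREAMS = ("retina", "sc", "isl2", "model", "analysis")


def split_streams(seed: int) -> dict[str, np.random.Generator]:
    """Split a master seed into named, independent generator streams."""
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def integer_seed(rng: np.random.Generator) -> int:
    """Draw a plain integer seed (< 2**31) for components that need one."""
    return int(rng.integers(0, 2**31 - 1))
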