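"""Shared container for model output: the RGC x SC connection matrix.

Gierer and Koulakov produce integer weights (terminal / synapse counts);
Whitelaw and Willshaw produce continuous weights that are thresholded at
a model-specific ``w_min`` before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ConnectionState:
    """Weight matrix ``W[i, j]`` from RGC ``i`` to SC neuron ``j``."""

    W: np.ndarray
    model: str = ""
    w_min: float = 0.0
    log: dict = field(default_factory=dict)

    @property
    def n_rgc(self) -> int:
        return self.W.shape[0]

    @property
    def n_sc(self) -> int:
        return self.W.shape[1]

    def thresholded(self) -> np.ndarray:
        """Weights with entries below ``w_min`` zeroed (copy)."""
        W = self.W.astype(float, copy=True)
        if self.w_min > 0:
            W[W < self.w_min] = 0.0
        return W

    def strongest_target(self) -> np.ndarray:
        """Index of the strongest SC target per RGC; -1 for empty rows."""
        W = self.thresholded()
        out = np.argmax(W, axis=1)
        out[W.max(axis=1) <= 0] = -1
        return out

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("W", data=self.W, compression="gzip")
            f.attrs["model"] = self.model
            f.attrs["w_min"] = self.w_min
            g = f.create_group("log")
            for key, val in self.log.items():
                g.create_dataset(key, data=np.asarray(val))

    @classmethod
    def load(cls, path) -> "ConnectionState":
        import h5py

        with h5py.File(path, "r") as f:
            log = {k: f["log"][k][...] for k in f["log"]}
            return cls(
                W=f["W"][...],
                model=str(f.attrs["model"]),
                w_min=float(f.attrs["w_min"]),
                log=log,
            )
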