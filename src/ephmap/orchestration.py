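"""Run management: genotype x model x repeats, analysis, aggregation.

A :class:`RunConfig` fixes the model, genotype, population sizes, epoch
budget and master seed.  ``run_experiment`` executes the pipeline
(substrate -> model -> analysis) for each repeat with deterministically
split seeds and aggregates the measures as mean +/- SD over repeats
(sample SD, n-1 denominator).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ephmap.analysis import (
    central_third_mask,
    collapse_point,
    lattice_analysis,
    sc_coverage,
    strongest_target_mapping,
)
from ephmap.connections import ConnectionState
from ephmap.models import RUNNERS
from ephmap.substrate import build_substrate, genotype

DEFAULT_EPOCHS = {
    "gierer": 10_000,
    "koulakov": 10_000,
    "whitelaw": 500,
    "willshaw": 48_000,  # steps
}


@dataclass
class RunConfig:
    model: str
    genotype: str
    K: float = 0.0  # TKO weak-gradient scale
    n_rgc: int = 2000
    n_sc: int = 2000
    epochs: int | None = None
    repeats: int = 10
    seed: int = 0
    model_kwargs: dict = field(default_factory=dict)
    measures: tuple = ("lattice", "collapse", "coverage")
    lattice_centers: int = 100
    collapse_bins: int = 50
    outdir: str | None = None

    def __post_init__(self):
        if self.model not in RUNNERS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.epochs is None:
            self.epochs = DEFAULT_EPOCHS[self.model]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a flat key/value YAML run description."""
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        if "measures" in data:
            data["measures"] = tuple(data["measures"])
        return cls(**data)


def repeat_seeds(master_seed: int, repeats: int) -> list[int]:
    """Per-repeat master seeds derived deterministically (< 2**31)."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(repeats)]


def run_single(config: RunConfig, seed: int) -> tuple[ConnectionState, dict]:
    """One repeat: substrate, model run, and the configured measures."""
    spec = genotype(config.genotype, K=config.K)
    substrate = build_substrate(spec, config.n_rgc, config.n_sc, seed=seed)
    runner = RUNNERS[config.model]
    kwargs = dict(config.model_kwargs)
    if config.model == "koulakov" and "params" not in kwargs:
        # activity balance follows the wild-type network size
        from ephmap.models.koulakov import scaled_params

        kwargs["params"] = scaled_params(config.n_rgc)
    if config.model == "willshaw":
        state = runner(substrate, n_steps=config.epochs, seed=seed, **kwargs)
    else:
        state = runner(substrate, n_epochs=config.epochs, seed=seed, **kwargs)

    row: dict = {"seed": seed}
    mapping = strongest_target_mapping(state, substrate)
    if "lattice" in config.measures:
        lat = lattice_analysis(mapping, n_centers=config.lattice_centers)
        row.update(
            lattice_nodes_pct=lat.pct_nodes,
            lattice_edges_pct=lat.pct_edges,
            ap_polarity_pct=lat.ap_polarity,
            ml_polarity_pct=lat.ml_polarity,
            orientation_diff_deg=lat.orientation_diff_deg,
        )
    if "collapse" in config.measures:
        central = mapping.subset(central_third_mask(mapping))
        res = collapse_point(central, n_bins=config.collapse_bins)
        row["collapse_position_pct"] = res.collapse_position
        row["collapse_kind"] = res.kind
    if "coverage" in config.measures:
        row["sc_coverage_pct"] = sc_coverage(state.thresholded(), substrate)
    return state, row


def run_experiment(config: RunConfig):
    """All repeats; returns (per-repeat DataFrame, summary DataFrame)."""
    rows = []
    for seed in repeat_seeds(config.seed, config.repeats):
        _, row = run_single(config, seed)
        rows.append(row)
    per_repeat = pd.DataFrame(rows)
    numeric = per_repeat.select_dtypes("number").drop(columns=["seed"])
    summary = pd.DataFrame(
        {"mean": numeric.mean(), "sd": numeric.std(ddof=1), "n": numeric.count()}
    )
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        per_repeat.to_csv(out / "per_repeat.csv", index=False)
        summary.to_csv(out / "summary.csv")
        meta = {k: v for k, v in config.__dict__.items() if k != "model_kwargs"}
        (out / "config.json").write_text(json.dumps(meta, indent=2, default=str))
    return per_repeat, summary


def sweep_K(config: RunConfig, K_values=(1.0, 0.1, 0.01, 0.002)):
    """TKO weak-gradient sweep; per-K lattice edge % and AP polarity."""
    results = []
    for K in K_values:
        cfg = RunConfig(**{**config.__dict__, "genotype": "tko", "K": K})
        _, summary = run_experiment(cfg)
        results.append(
            {
                "K": K,
                "lattice_edges_pct": summary.loc["lattice_edges_pct", "mean"],
                "ap_polarity_pct": summary.loc["ap_polarity_pct", "mean"],
            }
        )
    return pd.DataFrame(results)
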