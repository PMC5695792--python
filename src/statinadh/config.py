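"""Serializable pipeline configuration."""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Everything a full run needs besides the input tables.

    A run is reproducible from (inputs, config): every stochastic stage
    derives its randomness from the seeds recorded here.
    """

    statin_codes: list = field(default_factory=lambda: ["STATIN_A", "STATIN_B", "STATIN_C"])
    group_code_map: dict = field(default_factory=lambda: {
        "DX_MI": "MI", "DX_STROKE": "stroke", "DX_CAD": "CAD",
        "DX_KIDNEY": "kidney"})
    prescribing_window: tuple | None = None   # (start, end) months; None = infer
    count_window_months: int = 6
    min_patients_per_variable: int = 100
    lab_lookback_months: int = 24
    n_factors: int = 30
    log1p_counts: bool = False
    n_folds: int = 30
    n_trees: int = 500
    risk_horizon_years: int = 1               # 1 or 3
    include_first_refill_model: bool = True
    use_precomputed_scores: bool = False      # take factor scores from input
    nmf_max_iter: int = 500
    nmf_tol: float = 1e-5
    seed: int = 0
    risk_fixed_lambda: tuple | None = None    # skip nested lambda search

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if data.get("prescribing_window") is not None:
            data["prescribing_window"] = tuple(data["prescribing_window"])
        if data.get("risk_fixed_lambda") is not None:
            data["risk_fixed_lambda"] = tuple(data["risk_fixed_lambda"])
        return cls(**data)
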