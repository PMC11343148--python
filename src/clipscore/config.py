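"""Run configuration for the CLIP-score pipeline.

All thresholds that define target tiers, significance calls and
reproducibility filters live here so that every stage reads the same
values and every output can record a hash of them.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

VALID_STRINGENCY_MODES = ("per_replicate", "mean")
VALID_SCORE_CONVENTIONS = ("as_printed", "residual")


@dataclass
class PipelineConfig:
    """Thresholds and policies shared across pipeline stages.

    Parameters
    ----------
    stringent_threshold, high_threshold, low_threshold
        CLIP-score tier boundaries (score units, log2 scale). A transcript
        is a stringent target above ``stringent_threshold`` (> 2 by
        default), a high-binding target above ``high_threshold``, a
        low-binding target above ``low_threshold``; anything else is a
        nontarget. Strict inequalities throughout.
    stringency_mode
        ``per_replicate``: stringent requires the score to exceed the
        threshold in every biological replicate. ``mean``: the
        replicate-mean score is compared instead. Lower tiers always use
        the mean.
    score_convention
        ``as_printed``: score = log2 CLIP TPM - slope * log2 RiboTag TPM
        + intercept. ``residual``: ordinary regression residual
        (subtracting the intercept instead of adding it). The two differ
        by the constant 2*intercept per replicate.
    pseudocount
        TPM added before any log2 transform (TPM units).
    clip_diff_alpha
        Significance level for differential CLIP binding (raw p).
    ribo_diff_alpha
        Significance level for differential ribosome association
        (BH-adjusted p).
    ribo_lfc_floor
        Minimum |log2FC| for a RiboTag change call (0 = no floor).
    bc_min_tags
        Tags required in a replicate for that replicate to "support" a
        gene in the biological-complexity filter.
    bc_required
        Number of supporting replicates required to keep a gene.
    rng_seed
        Seed for every stochastic step (simulation only; the analysis
        itself is deterministic).
    """

    stringent_threshold: float = 2.0
    high_threshold: float = 1.0
    low_threshold: float = 0.0
    stringency_mode: str = "per_replicate"
    score_convention: str = "as_printed"
    pseudocount: float = 1e-2
    clip_diff_alpha: float = 0.05
    ribo_diff_alpha: float = 0.05
    ribo_lfc_floor: float = 0.0
    bc_min_tags: int = 5
    bc_required: int = 4
    marker_concordance: float = 0.8
    expression_floor: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.stringent_threshold > self.high_threshold > self.low_threshold):
            raise ValueError(
                "tier thresholds must satisfy stringent > high > low, got "
                f"{self.stringent_threshold}, {self.high_threshold}, {self.low_threshold}"
            )
        for name in ("clip_diff_alpha", "ribo_diff_alpha"):
            a = getattr(self, name)
            if not 0.0 < a < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {a}")
        if self.stringency_mode not in VALID_STRINGENCY_MODES:
            raise ValueError(f"unknown stringency_mode {self.stringency_mode!r}")
        if self.score_convention not in VALID_SCORE_CONVENTIONS:
            raise ValueError(f"unknown score_convention {self.score_convention!r}")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if self.bc_min_tags < 0 or self.bc_required < 0:
            raise ValueError("bc_min_tags and bc_required must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Stable short hash of the full configuration."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
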