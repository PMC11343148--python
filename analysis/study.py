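"""Shared setup for the numbered analysis drivers.

The synthetic study mirrors the deposited experiments' shape: 2
conditions (Control, Opto) x 4 CLIP replicates and 2 conditions x 3
RiboTag replicates (IP + Input) over 5000 genes plus the CA1 marker
panel. Scores are residual-centered and stringency is assessed on the
replicate mean, the configuration under which planted binding offsets
are commensurate with the tier thresholds.
"""
from __future__ import annotations

import argparse

from clipscore import GeneratorParams, PipelineConfig


def study_args(description: str) -> argparse.Namespace:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results")
    return ap.parse_args()


def study_config(seed: int) -> PipelineConfig:
    return PipelineConfig(score_convention="residual", stringency_mode="mean",
                          rng_seed=seed)


def study_params(seed: int, **overrides) -> GeneratorParams:
    return GeneratorParams(seed=seed, **overrides)
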