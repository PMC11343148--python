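from pathlib import Path

import pytest

from clipscore import PipelineConfig
from clipscore.io import (
    CountMatrix,
    lengths_of,
    read_gtf,
    read_table,
    transcript_gene_map,
)
from clipscore.pipeline import quantify_stage
from clipscore.scoring import score_table
from clipscore.simulate import TINY_PARAMS, generate_dataset

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def tiny_dir() -> Path:
    return DATA / "tiny"


@pytest.fixture(scope="session")
def tiny_dataset():
    """The tiny study regenerated in memory (identical to the committed one)."""
    return generate_dataset(TINY_PARAMS)


@pytest.fixture(scope="session")
def tiny_from_disk(tiny_dir):
    clip = CountMatrix(read_table(tiny_dir / "clip_counts.tsv"),
                       read_table(tiny_dir / "clip_samples.tsv"))
    ribo = CountMatrix(read_table(tiny_dir / "ribo_counts.tsv"),
                       read_table(tiny_dir / "ribo_samples.tsv"))
    models = read_gtf(tiny_dir / "models.gtf")
    return clip, ribo, models


@pytest.fixture(scope="session")
def tiny_scores(tiny_from_disk):
    """Score table for the committed tiny fixture under default config."""
    clip, ribo, models = tiny_from_disk
    cfg = PipelineConfig()
    rep, clip_sel, ribo_ip_tpm, clip_tpm = quantify_stage(
        clip, ribo, lengths_of(models), transcript_gene_map(models), cfg)
    return score_table(clip_tpm, ribo_ip_tpm, cfg)
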