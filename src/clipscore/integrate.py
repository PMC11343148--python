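"""Quadrant model: cross-classify transcripts by the direction of their
FMRP-binding change (CLIP-score differential, Opto vs Control) and their
ribosome-association change (RiboTag differential, Opto vs Control)."""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import PipelineConfig

QUADRANT_LABELS = (
    "fmrp_down_ribo_up", "fmrp_down_ribo_down", "fmrp_down_ribo_unchanged",
    "fmrp_up_ribo_up", "fmrp_up_ribo_down", "fmrp_up_ribo_unchanged",
    "unchanged",
)


def quadrant_classify(
    clip_diff: pd.DataFrame,
    ribo_diff: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Join the two differential results and assign quadrant labels.

    FMRP direction: sign of the CLIP-score effect at raw
    p < ``clip_diff_alpha``. Ribosome direction: sign of the RiboTag
    log2FC at BH-adjusted p < ``ribo_diff_alpha`` and
    |log2FC| > ``ribo_lfc_floor``. Both inputs must share an id space
    (the representative-transcript universe) with unique ids.
    """
    cfg = config or PipelineConfig()
    for name, df in (("clip_diff", clip_diff), ("ribo_diff", ribo_diff)):
        if df.index.has_duplicates:
            raise ValueError(f"duplicated ids in {name}")
    common = clip_diff.index.intersection(ribo_diff.index)
    union = clip_diff.index.union(ribo_diff.index)
    if len(union) and len(common) / len(union) < 0.5:
        warnings.warn(
            f"quadrant join keeps only {len(common)}/{len(union)} ids",
            RuntimeWarning)
    cd = clip_diff.loc[common]
    rd = ribo_diff.loc[common]

    fmrp_sig = cd["p"] < cfg.clip_diff_alpha
    fmrp = np.where(fmrp_sig & (cd["effect"] < 0), "down",
                    np.where(fmrp_sig & (cd["effect"] > 0), "up", "unchanged"))
    ribo_sig = (rd["padj"] < cfg.ribo_diff_alpha) & (
        rd["effect"].abs() > cfg.ribo_lfc_floor)
    ribo = np.where(ribo_sig & (rd["effect"] > 0), "up",
                    np.where(ribo_sig & (rd["effect"] < 0), "down", "unchanged"))
    quad = np.where(
        fmrp == "unchanged", "unchanged",
        np.char.add(np.char.add(np.char.add("fmrp_", fmrp.astype(str)), "_ribo_"),
                    ribo.astype(str)))
    return pd.DataFrame({
        "fmrp_direction": fmrp, "ribo_direction": ribo, "quadrant": quad,
        "clip_effect": cd["effect"], "clip_p": cd["p"],
        "ribo_log2fc": rd["effect"], "ribo_padj": rd["padj"],
    }, index=common)


def quadrant_counts(quadrants: pd.DataFrame) -> pd.Series:
    """Per-label transcript counts over the full label vocabulary."""
    counts = quadrants["quadrant"].value_counts()
    return counts.reindex(QUADRANT_LABELS, fill_value=0).rename("n")


def quadrant_summary(quadrants: pd.DataFrame) -> dict:
    """JSON-ready summary: label counts plus the FMRP-Down/Up margin."""
    counts = quadrant_counts(quadrants)
    n_down = int((quadrants["fmrp_direction"] == "down").sum())
    n_up = int((quadrants["fmrp_direction"] == "up").sum())
    changed = n_down + n_up
    return {
        "n_transcripts": int(quadrants.shape[0]),
        "counts": {k: int(v) for k, v in counts.items()},
        "n_fmrp_down": n_down,
        "n_fmrp_up": n_up,
        "frac_fmrp_down_of_changed": (n_down / changed) if changed else float("nan"),
    }
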