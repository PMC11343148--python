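"""Abundance-normalized CLIP scores and target-tier classification.

For each condition, each CLIP replicate's log2 TPM is regressed on the
condition's mean RiboTag log2 TPM (ordinary least squares). The CLIP
score of a transcript quantifies FMRP binding relative to transcripts of
similar ribosome-associated abundance:

    as_printed:  score = y - b*x + a      (the formula as published)
    residual:    score = y - (b*x + a)    (ordinary regression residual)

with y = log2 CLIP TPM, x = log2 RiboTag TPM, (b, a) the fitted slope
and intercept. The two conventions differ by the constant 2a per
replicate, so they never reorder transcripts within a replicate.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io import QuantTable

TIERS = ("stringent", "high", "low", "nontarget")
CROSS_CLASSES = ("stringent_both", "control_only", "opto_only", "neither")


@dataclass(frozen=True)
class RegressionFit:
    condition: str
    replicate: str
    slope: float
    intercept: float
    n_points: int
    residual_sd: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("non-finite regression fit")
        if self.n_points < 3:
            raise ValueError("regression fit needs >= 3 points")


def fit_abundance_regression(
    clip_log2: pd.Series,
    ribo_mean_log2: pd.Series,
    condition: str = "",
    replicate: str = "",
) -> RegressionFit:
    """OLS of one replicate's log2 CLIP TPM on mean log2 RiboTag TPM.

    Closed form: b = cov(x, y)/var(x), a = mean(y) - b*mean(x).
    Non-finite pairs are dropped; zero variance in x is a degenerate fit.
    """
    x = ribo_mean_log2.to_numpy(dtype=float)
    y = clip_log2.loc[ribo_mean_log2.index].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"need >= 3 finite points to fit, got {x.size}")
    xm, ym = x.mean(), y.mean()
    varx = np.mean((x - xm) ** 2)
    if varx == 0:
        raise ValueError("zero variance in RiboTag log2 TPM: degenerate fit")
    b = np.mean((x - xm) * (y - ym)) / varx
    a = ym - b * xm
    resid = y - (a + b * x)
    sd = float(np.sqrt(np.sum(resid**2) / max(x.size - 2, 1)))
    return RegressionFit(condition, replicate, float(b), float(a), int(x.size), sd)


def clip_score(
    y: np.ndarray | pd.Series | float,
    x: np.ndarray | pd.Series | float,
    fit: RegressionFit,
    convention: str = "as_printed",
) -> np.ndarray | pd.Series | float:
    """CLIP score of points (x, y) under a fitted line."""
    if convention == "as_printed":
        return y - fit.slope * x + fit.intercept
    if convention == "residual":
        return y - (fit.slope * x + fit.intercept)
    raise ValueError(f"unknown score convention {convention!r}")


@dataclass
class ClipScoreTable:
    """Per-replicate and per-condition-mean CLIP scores.

    ``scores`` has a (condition, replicate) column MultiIndex; ``means``
    one column per condition (mean over finite replicate scores);
    ``fits`` indexed the same way as the score columns.
    """

    scores: pd.DataFrame
    means: pd.DataFrame
    fits: dict[tuple[str, str], RegressionFit]
    convention: str

    def conditions(self) -> list[str]:
        return list(self.means.columns)


def condition_mean_ribo_log2(
    ribo_quant: QuantTable, condition: str, pseudocount: float
) -> pd.Series:
    """Mean log2(TPM + pc) across the condition's RiboTag IP replicates."""
    if ribo_quant.scale != "linear":
        raise ValueError("expected linear-scale RiboTag TPM")
    return np.log2(ribo_quant.values + pseudocount).mean(axis=1).rename(condition)


def score_table(
    clip_quant: dict[str, QuantTable],
    ribo_quant: dict[str, QuantTable],
    config: PipelineConfig,
) -> ClipScoreTable:
    """Fit per-replicate regressions and score every transcript.

    ``clip_quant``/``ribo_quant`` map condition -> linear-scale QuantTable
    (CLIP: one column per replicate; RiboTag: the condition's IP
    replicates). Transcripts with zero CLIP TPM in a replicate are
    excluded from that replicate's fit and receive a missing score there.
    """
    if set(clip_quant) != set(ribo_quant):
        raise ValueError("conditions of CLIP and RiboTag tables differ")
    pc = config.pseudocount
    score_cols: dict[tuple[str, str], pd.Series] = {}
    fits: dict[tuple[str, str], RegressionFit] = {}
    for cond in clip_quant:
        ctab = clip_quant[cond]
        if ctab.scale != "linear":
            raise ValueError("expected linear-scale CLIP TPM")
        x = condition_mean_ribo_log2(ribo_quant[cond], cond, pc)
        for rep in ctab.values.columns:
            tpm = ctab.values[rep]
            expressed = tpm > 0
            y = np.log2(tpm + pc)
            fit = fit_abundance_regression(
                y[expressed], x.loc[y.index[expressed]], cond, str(rep))
            s = clip_score(y, x.loc[y.index], fit, config.score_convention)
            s[~expressed] = np.nan
            score_cols[(cond, str(rep))] = s
            fits[(cond, str(rep))] = fit
    scores = pd.DataFrame(score_cols)
    scores.columns = pd.MultiIndex.from_tuples(scores.columns,
                                               names=["condition", "replicate"])
    means = scores.T.groupby(level="condition").mean().T
    return ClipScoreTable(scores, means, fits, config.score_convention)


def classify_targets(scores: ClipScoreTable, config: PipelineConfig) -> pd.DataFrame:
    """Assign each transcript a binding tier per condition.

    stringent: score > stringent_threshold — in every replicate
    (``per_replicate`` mode; a missing replicate score disqualifies) or
    on the replicate mean (``mean`` mode). The high and low tiers are
    always evaluated on the mean, with strict inequalities; everything
    else (including transcripts with no finite score) is a nontarget.
    """
    cfg = config
    out = {}
    for cond in scores.conditions():
        mean = scores.means[cond]
        if cfg.stringency_mode == "per_replicate":
            rep = scores.scores[cond]
            stringent = (rep > cfg.stringent_threshold).all(axis=1) & rep.notna().all(axis=1)
        elif cfg.stringency_mode == "mean":
            stringent = mean > cfg.stringent_threshold
        else:  # pragma: no cover - guarded by PipelineConfig
            raise ValueError(f"unknown stringency mode {cfg.stringency_mode!r}")
        tier = pd.Series("nontarget", index=mean.index, dtype=object)
        tier[(mean > cfg.low_threshold) & (mean <= cfg.high_threshold)] = "low"
        tier[(mean > cfg.high_threshold) & (mean <= cfg.stringent_threshold)] = "high"
        tier[(mean > cfg.stringent_threshold)] = "high"  # above 2 but not stringent
        tier[stringent & mean.notna()] = "stringent"
        tier[mean.isna()] = "nontarget"
        out[cond] = tier
    return pd.DataFrame(out)


def cross_condition_classes(tiers: pd.DataFrame) -> pd.Series:
    """Cross-condition target class from per-condition tiers.

    stringent_both / control_only / opto_only / neither, following the
    stringent-tier calls in the Control and Opto conditions.
    """
    for cond in ("Control", "Opto"):
        if cond not in tiers.columns:
            raise ValueError(f"missing condition {cond!r} in tier table")
    if tiers[["Control", "Opto"]].isna().any().any():
        raise ValueError("tier table contains missing entries")
    ctrl = tiers["Control"] == "stringent"
    opto = tiers["Opto"] == "stringent"
    cls = pd.Series("neither", index=tiers.index, dtype=object)
    cls[ctrl & opto] = "stringent_both"
    cls[ctrl & ~opto] = "control_only"
    cls[~ctrl & opto] = "opto_only"
    return cls.rename("cross_class")
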