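"""Differential testing: empirical-Bayes moderated t for CLIP scores,
negative-binomial Wald tests for RiboTag counts, BH FDR control.

Both tests are deliberately minimal two-group versions of their
reference implementations: the moderated t shrinks per-transcript
variances toward a scaled-F prior fitted by closed-form moments of
log s_g^2 (no variance trend, no robustification); the NB Wald test uses
median-of-ratios size factors, gene-wise method-of-moments dispersion
(no shrinkage toward a trend), and a delta-method standard error for the
log2 fold change.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import CountMatrix

D0_CAP = 1e6
DISPERSION_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = p_(i) * m / i on the ascending sort, with monotonicity
    enforced from the largest rank down and values capped at 1.
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("bh_adjust expects a 1-d vector")
    if arr.size == 0:
        return p if isinstance(p, pd.Series) else arr
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = arr.size
    order = np.argsort(arr, kind="mergesort")
    q = arr[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    if isinstance(p, pd.Series):
        return pd.Series(out, index=p.index, name="padj")
    return out


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration (vectorized)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if np.all(np.abs(dif) < 1e-10 * y):
            break
    return y

def fit_f_dist(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of a scaled F prior to sample variances.

    Models s_g^2 ~ s0^2 * F(df_g, d0) and estimates (d0, s0^2) from the
    mean and variance of log s_g^2, using digamma/trigamma moments of
    the log-chi-square distribution. d0 = inf (capped) when the observed
    spread of log-variances is no larger than expected from chi-square
    sampling alone.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    s2, df = s2[ok], df[ok]
    if s2.size < 2:
        raise ValueError("need >= 2 positive variances to fit the prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    ebar = e.mean()
    n = e.size
    excess = np.mean((e - ebar) ** 2 * n / (n - 1.0) - special.polygamma(1, df / 2.0))
    if excess > 0:
        d0 = float(2.0 * _trigamma_inverse(np.array([excess]))[0])
        d0 = min(d0, D0_CAP)
        s02 = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = D0_CAP
        s02 = float(np.exp(ebar))
    return d0, s02


def moderated_t(
    control_scores: pd.DataFrame,
    opto_scores: pd.DataFrame,
    alpha: float = 0.05,
    use_padj: bool = False,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-sample t per transcript.

    Rows are transcripts, columns replicates; missing replicate values
    are dropped per transcript (>= 2 finite per group required, others
    removed). The effect is mean(opto) - mean(control) in score units.
    ``d0_override`` forces the prior df (0 recovers the ordinary pooled
    t); by default (d0, s0^2) are estimated from all residual variances.

    Direction labels: FMRP-Up for a positive significant effect, FMRP-Down
    for a negative one, at raw p < alpha (or padj when ``use_padj``).
    """
    common = control_scores.index.intersection(opto_scores.index)
    c = control_scores.loc[common].to_numpy(dtype=float)
    o = opto_scores.loc[common].to_numpy(dtype=float)
    n1 = np.isfinite(c).sum(axis=1)
    n2 = np.isfinite(o).sum(axis=1)
    keep = (n1 >= 2) & (n2 >= 2)
    if keep.sum() < common.size:
        warnings.warn(
            f"dropping {int(common.size - keep.sum())} transcript(s) with "
            "fewer than 2 finite replicates per condition", RuntimeWarning)
    ids = common[keep]
    c, o, n1, n2 = c[keep], o[keep], n1[keep], n2[keep]
    m1 = np.nanmean(c, axis=1)
    m2 = np.nanmean(o, axis=1)
    ss1 = np.nansum((c - m1[:, None]) ** 2, axis=1)
    ss2 = np.nansum((o - m2[:, None]) ** 2, axis=1)
    dg = n1 + n2 - 2.0
    s2 = (ss1 + ss2) / dg
    effect = m2 - m1

    if d0_override is not None:
        d0 = float(d0_override)
        s02 = float(np.mean(s2[s2 > 0])) if np.any(s2 > 0) else 1.0
    elif ids.size < 2:
        warnings.warn("fewer than 2 transcripts: falling back to ordinary t",
                      RuntimeWarning)
        d0, s02 = 0.0, 1.0
    else:
        d0, s02 = fit_f_dist(s2, dg)

    post_var = (d0 * s02 + dg * s2) / (d0 + dg)
    se = np.sqrt(post_var * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = effect / se
    df_total = np.minimum(d0 + dg, 1e300)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    pvals = np.clip(np.nan_to_num(pvals, nan=1.0), 0.0, 1.0)
    padj = bh_adjust(pvals)
    crit = padj if use_padj else pvals
    direction = np.where(
        (crit < alpha) & (effect > 0), "FMRP-Up",
        np.where((crit < alpha) & (effect < 0), "FMRP-Down", "unchanged"))
    return pd.DataFrame({
        "effect": effect, "statistic": tstat, "p": pvals, "padj": padj,
        "direction": direction, "n_control": n1.astype(int),
        "n_opto": n2.astype(int), "s2": s2, "df_resid": dg,
        "prior_df": d0, "prior_var": s02, "assay": "CLIP",
    }, index=ids)


# ---------------------------------------------------------------------------
# NB differential
# ---------------------------------------------------------------------------

def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    factor_j = median over all-nonzero genes of count_gj / geomean_g.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    vals = mat.to_numpy(dtype=float)
    allpos = (vals > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene with nonzero counts in every sample; supply a "
            "pseudo-reference or filter samples")
    sub = vals[allpos]
    log_geo = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_geo[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=mat.columns, name="size_factor")


def _moments_dispersion(norm: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Gene-wise NB dispersion by method of moments on normalized counts,
    pooled across groups: alpha = (pooled within-group var - mean)/mean^2."""
    n_tot = sum(g.sum() for g in groups)
    var_num = np.zeros(norm.shape[0])
    mean_num = np.zeros(norm.shape[0])
    for g in groups:
        sub = norm[:, g]
        mu = sub.mean(axis=1)
        var_num += ((sub - mu[:, None]) ** 2).sum(axis=1)
        mean_num += mu * g.sum()
    pooled_var = var_num / max(n_tot - len(groups), 1)
    pooled_mean = mean_num / n_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - pooled_mean) / pooled_mean**2
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    return np.maximum(alpha, DISPERSION_FLOOR)


def nb_wald_test(
    counts: CountMatrix | pd.DataFrame,
    design: pd.Series,
    sf: pd.Series | None = None,
    alpha: float = 0.05,
    pseudo_mu: float = 0.5,
) -> pd.DataFrame:
    """Two-group NB Wald test per gene (reference-level first).

    ``design`` maps sample -> group label with exactly two levels; the
    log2 fold change is level2 vs level1 in the sorted label order
    unless ``design`` is categorical with an explicit order. Group means
    are estimated on size-factor-normalized counts, dispersion by
    method of moments (floored at 1e-8), and the Wald z statistic is
    log2FC / SE(log2FC) with a delta-method SE. Genes where a group has
    all-zero counts get a ``pseudo_mu`` mean for that group and are
    flagged in ``zero_group``.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    design = design.loc[mat.columns]
    if isinstance(design.dtype, pd.CategoricalDtype):
        levels = [l for l in design.cat.categories if (design == l).any()]
    else:
        levels = sorted(design.unique())
    if len(levels) != 2:
        raise ValueError(f"design must have exactly 2 groups, got {levels}")
    g1 = (design == levels[0]).to_numpy()
    g2 = (design == levels[1]).to_numpy()
    if g1.sum() < 2 or g2.sum() < 2:
        raise ValueError("need >= 2 samples per group")
    if sf is None:
        sf = size_factors(mat)
    sfv = sf.loc[mat.columns].to_numpy(dtype=float)
    vals = mat.to_numpy(dtype=float)
    norm = vals / sfv[None, :]

    alpha_g = _moments_dispersion(norm, [g1, g2])
    mu1 = norm[:, g1].mean(axis=1)
    mu2 = norm[:, g2].mean(axis=1)
    zero_group = (mu1 == 0) | (mu2 == 0)
    mu1 = np.where(mu1 == 0, pseudo_mu, mu1)
    mu2 = np.where(mu2 == 0, pseudo_mu, mu2)
    log2fc = np.log2(mu2 / mu1)

    # Var(mean of K_i/s_i) with K_i ~ NB(s_i mu, alpha): per sample
    # Var = mu/s_i + alpha mu^2; delta method onto log2 mu.
    ln2sq = np.log(2.0) ** 2
    var_log2 = np.zeros_like(mu1)
    for mu, g in ((mu1, g1), (mu2, g2)):
        n = g.sum()
        var_mu = (mu[:, None] / sfv[None, g] + alpha_g[:, None] * mu[:, None] ** 2).sum(axis=1) / n**2
        var_log2 += var_mu / (mu**2 * ln2sq)
    se = np.sqrt(var_log2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals = np.clip(np.nan_to_num(pvals, nan=1.0), 0.0, 1.0)
    padj = bh_adjust(pvals)
    direction = np.where((padj < alpha) & (log2fc > 0), "up",
                         np.where((padj < alpha) & (log2fc < 0), "down", "unchanged"))
    return pd.DataFrame({
        "effect": log2fc, "statistic": z, "p": pvals, "padj": padj,
        "direction": direction, "base_mean_1": mu1, "base_mean_2": mu2,
        "dispersion": alpha_g, "zero_group": zero_group,
        "contrast": f"{levels[1]}_vs_{levels[0]}", "assay": "RiboTag",
    }, index=mat.index)
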