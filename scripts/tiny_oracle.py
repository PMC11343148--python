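"""Brute-force CLIP-score oracle for the committed tiny fixture.

Recomputes per-replicate and mean CLIP scores directly from the fixture
TSV/GTF files by literal formula evaluation (numpy/pandas only, no
pipeline imports), and writes tests/data/tiny/oracle_clip_scores.tsv.

Run from the repository root:  python scripts/tiny_oracle.py
"""
from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd

PSEUDOCOUNT = 0.01
FIXTURE = Path(__file__).resolve().parents[1] / "tests" / "data" / "tiny"


def gtf_exon_lengths(path: Path) -> pd.Series:
    lengths: dict[str, int] = {}
    for line in path.read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if f[2] != "exon":
            continue
        tid = line.split('transcript_id "')[1].split('"')[0]
        lengths[tid] = lengths.get(tid, 0) + int(f[4]) - (int(f[3]) - 1)
    return pd.Series(lengths)


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    rate = counts.div(lengths.loc[counts.index], axis=0)
    return rate.div(rate.sum(axis=0), axis=1) * 1e6


def main() -> None:
    clip = pd.read_csv(FIXTURE / "clip_counts.tsv", sep="\t", comment="#", index_col=0)
    clip_samples = pd.read_csv(FIXTURE / "clip_samples.tsv", sep="\t", comment="#", index_col=0)
    ribo = pd.read_csv(FIXTURE / "ribo_counts.tsv", sep="\t", comment="#", index_col=0)
    ribo_samples = pd.read_csv(FIXTURE / "ribo_samples.tsv", sep="\t", comment="#", index_col=0)
    lengths = gtf_exon_lengths(FIXTURE / "models.gtf")

    # representative transcript per gene: highest mean TPM over ALL RiboTag
    # IP replicates of both conditions; ties -> lexicographically smallest id
    ip_cols = ribo_samples.index[ribo_samples["assay"] == "RiboTag-IP"]
    ip_tpm_all = tpm(ribo[ip_cols], lengths)
    gene_of = pd.Series({t: t.rsplit(".", 1)[0] for t in ribo.index})
    mean_tpm = ip_tpm_all.mean(axis=1)
    selected = []
    for gene, grp in mean_tpm.groupby(gene_of):
        best = grp[grp == grp.max()].index.min()
        if grp.max() > 0:
            selected.append(best)
    selected = sorted(selected)

    clip_sel = clip.loc[[t for t in clip.index if t in set(selected)]]
    out = {}
    for cond in ("Control", "Opto"):
        ip_cond = ribo_samples.index[(ribo_samples["assay"] == "RiboTag-IP")
                                     & (ribo_samples["condition"] == cond)]
        x = np.log2(tpm(ribo.loc[clip_sel.index, ip_cond], lengths) + PSEUDOCOUNT).mean(axis=1)
        cond_cols = clip_samples.index[clip_samples["condition"] == cond]
        clip_tpm = tpm(clip_sel[cond_cols], lengths)
        rep_scores = []
        for col in cond_cols:
            t = clip_tpm[col]
            expressed = t > 0
            y = np.log2(t + PSEUDOCOUNT)
            b, a = np.polyfit(x[expressed].to_numpy(), y[expressed].to_numpy(), 1)
            s = y - b * x + a              # the published formula, literally
            s[~expressed] = np.nan
            rep_scores.append(s.rename(f"score_{cond}_{col}"))
            out[f"fit_slope_{col}"] = b
            out[f"fit_intercept_{col}"] = a
        block = pd.concat(rep_scores, axis=1)
        out[f"scores_{cond}"] = block
        out[f"mean_{cond}"] = block.mean(axis=1)

    table = pd.concat(
        [out["scores_Control"], out["scores_Opto"],
         out["mean_Control"].rename("mean_Control"),
         out["mean_Opto"].rename("mean_Opto")], axis=1)
    fit_rows = {k: v for k, v in out.items() if k.startswith("fit_")}
    fits = pd.Series(fit_rows, name="value")
    table.index.name = "transcript_id"
    with open(FIXTURE / "oracle_clip_scores.tsv", "w") as fh:
        table.to_csv(fh, sep="\t", float_format="%.12g")
    fits.to_csv(FIXTURE / "oracle_fits.tsv", sep="\t", float_format="%.12g")
    print(f"wrote oracle for {table.shape[0]} transcripts to {FIXTURE}")


if __name__ == "__main__":
    sys.exit(main())
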