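"""Synthetic CLIP + RiboTag datasets with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* per-transcript ribosome-associated abundance (log-normal TPM shape),
  NB-sampled Input counts and IP counts (IP means scaled by a cell-type
  enrichment for marker genes),
* activity-induced ribosome-association fold changes (2^ribo_log2fc on
  the Opto IP means) for planted subsets,
* a log-linear CLIP-vs-RiboTag abundance relation: expected log2 CLIP
  TPM per replicate = a + b * (realized mean RiboTag log2 TPM of the
  matching condition) + beta_g (+ delta_g in Opto) + N(0, sigma),
* CLIP counts drawn multinomially to the configured library size from
  the implied TPM composition (counts are proportional to TPM x length).

Because TPM is compositional, renormalizing the multinomial counts back
to TPM shifts every log2 value by a per-sample constant: the slope b
survives the count route but the intercept a does not. The generator
therefore also returns its realized CLIP log2-TPM table, against which
(a, b) recovery is exact in expectation.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CountMatrix,
    Feature,
    QuantTable,
    TranscriptModel,
    lengths_of,
    transcript_gene_map,
    write_gtf,
    write_table,
    write_tags_bed,
)
from .quantify import MARKER_PANEL, compute_tpm

TRUTH_CLASSES = ("stringent_both", "control_only", "opto_only", "nontarget")


@dataclass
class GeneratorParams:
    """Study-scale defaults: 2 conditions x 4 CLIP replicates and
    2 conditions x 3 RiboTag replicates (IP + Input)."""

    n_genes: int = 5000
    isoforms_per_gene: int = 1
    slope: float = 1.0                 # b of the CLIP-vs-RiboTag relation
    intercept: float = -2.0            # a, log2 TPM units
    clip_noise_sd: float = 0.5         # sigma, log2 units, per replicate
    clip_library_size: int = 2_000_000
    ribo_library_size: int = 2_000_000
    abundance_mean_log2: float = 5.0   # log-normal TPM shape
    abundance_sd_log2: float = 2.0
    nb_dispersion: float = 0.05
    frac_stringent: float = 0.06       # beta=+binding_offset, delta=0
    frac_fmrp_down: float = 0.05       # beta=+binding_offset, delta=-binding_shift
    frac_fmrp_up: float = 0.01         # beta=0, delta=+binding_shift
    binding_offset: float = 3.0        # beta_g, CLIP-score (log2) units
    binding_shift: float = 3.0         # |delta_g|
    ribo_effect: float = 1.0           # |ribo_log2fc|
    # probabilities of a ribosome-association change, conditional on the
    # FMRP-binding class (changes concentrate among FMRP-Down transcripts)
    p_ribo_up_fmrp_down: float = 0.125
    p_ribo_down_fmrp_down: float = 0.096
    p_ribo_up_other: float = 0.022
    p_ribo_down_other: float = 0.026
    celltype_enrichment: float = 2.0   # log2 IP/Input for excitatory markers
    include_markers: bool = True
    n_clip_reps: int = 4
    n_ribo_reps: int = 3
    pseudocount: float = 0.01
    min_length: int = 600
    max_length: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        fr = (self.frac_stringent, self.frac_fmrp_down, self.frac_fmrp_up)
        if any(f < 0 or f > 1 for f in fr) or sum(fr) > 1:
            raise ValueError("class fractions must lie in [0,1] and sum to <= 1")
        if self.clip_noise_sd <= 0:
            raise ValueError("clip_noise_sd must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")


@dataclass
class SyntheticDataset:
    clip_counts: CountMatrix
    ribo_counts: CountMatrix
    clip_log2_tpm: QuantTable     # the generated y (log2 CLIP TPM), per replicate
    models: list[TranscriptModel]
    truth: pd.DataFrame
    params: GeneratorParams

    @property
    def lengths(self) -> pd.Series:
        return lengths_of(self.models)

    @property
    def gene_map(self) -> pd.Series:
        return transcript_gene_map(self.models)


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) with Var = mu + dispersion * mu^2; Poisson at 0."""
    mean = np.clip(mean, 1e-12, None)
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _make_model(gene_id: str, transcript_id: str, chrom: str, offset: int,
                mature_len: int, strand: str) -> TranscriptModel:
    """Two-exon gene model with 5'UTR(100) / CDS / 3'UTR(300) on the
    mature transcript, an internal intron of 500 nt."""
    e1 = max(150, mature_len // 4)
    e2 = mature_len - e1
    intron = 500
    exon1 = (offset, offset + e1)
    exon2 = (offset + e1 + intron, offset + e1 + intron + e2)
    utr5, utr3 = 100, 300
    if strand == "+":
        regions = [("5UTR", 0, utr5), ("CDS", utr5, mature_len - utr3),
                   ("3UTR", mature_len - utr3, mature_len)]
    else:
        # mature coordinates run right-to-left on the genome
        regions = [("3UTR", 0, utr3), ("CDS", utr3, mature_len - utr5),
                   ("5UTR", mature_len - utr5, mature_len)]
    feats = [Feature("exon", chrom, *exon1, strand=strand),
             Feature("exon", chrom, *exon2, strand=strand)]
    # map mature-left-to-right intervals onto the two genomic exons
    for label, lo, hi in regions:
        for (gs, ge), base in ((exon1, 0), (exon2, e1)):
            s = max(lo, base) - base + gs
            e = min(hi, base + (ge - gs)) - base + gs
            if s < e:
                feats.append(Feature(label, chrom, s, e, strand=strand))
    m = TranscriptModel(gene_id, transcript_id, chrom, strand, feats)
    m.validate()
    return m


def _assign_classes(par: GeneratorParams, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Plant binding classes and ribosome-association effects."""
    n_str = int(round(par.frac_stringent * n))
    n_down = int(round(par.frac_fmrp_down * n))
    n_up = int(round(par.frac_fmrp_up * n))
    cls = np.array(["nontarget"] * n, dtype=object)
    order = rng.permutation(n)
    cls[order[:n_str]] = "stringent_both"
    cls[order[n_str:n_str + n_down]] = "control_only"
    cls[order[n_str + n_down:n_str + n_down + n_up]] = "opto_only"

    beta = np.where(np.isin(cls, ["stringent_both", "control_only"]),
                    par.binding_offset, 0.0)
    delta = np.where(cls == "control_only", -par.binding_shift,
                     np.where(cls == "opto_only", par.binding_shift, 0.0))

    is_down = cls == "control_only"
    u = rng.random(n)
    p_up = np.where(is_down, par.p_ribo_up_fmrp_down, par.p_ribo_up_other)
    p_dn = np.where(is_down, par.p_ribo_down_fmrp_down, par.p_ribo_down_other)
    ribo = np.where(u < p_up, par.ribo_effect,
                    np.where(u < p_up + p_dn, -par.ribo_effect, 0.0))
    return pd.DataFrame({"truth_class": cls, "beta": beta, "delta": delta,
                         "ribo_log2fc": ribo})


def _quadrant_truth(delta: np.ndarray, ribo: np.ndarray) -> np.ndarray:
    fmrp = np.where(delta < 0, "fmrp_down", np.where(delta > 0, "fmrp_up", "unchanged"))
    rdir = np.where(ribo > 0, "ribo_up", np.where(ribo < 0, "ribo_down", "ribo_unchanged"))
    out = np.where(fmrp == "unchanged", "unchanged",
                   np.char.add(np.char.add(fmrp.astype(str), "_"), rdir.astype(str)))
    return out


def generate_dataset(params: GeneratorParams | None = None) -> SyntheticDataset:
    """Generate CLIP counts, RiboTag IP/Input counts, gene models and truth.

    All randomness flows from ``params.seed``; the same seed yields
    byte-identical matrices.
    """
    par = params or GeneratorParams()
    rng = np.random.default_rng(par.seed)

    # --- gene universe ------------------------------------------------
    gene_ids = [f"G{i:05d}" for i in range(par.n_genes)]
    symbols = list(gene_ids)
    marker_dir: dict[str, float] = {}
    if par.include_markers:
        for _set, (direction, genes) in MARKER_PANEL.items():
            for g in genes:
                marker_dir[g] = (par.celltype_enrichment if direction == "enriched"
                                 else -par.celltype_enrichment)
        symbols += list(marker_dir)
    models: list[TranscriptModel] = []
    offset, chrom = 1000, "chr1"
    lengths_list: list[int] = []
    tids: list[str] = []
    t_genes: list[str] = []
    for i, g in enumerate(symbols):
        strand = "+" if i % 2 == 0 else "-"
        for k in range(par.isoforms_per_gene):
            L = int(rng.integers(par.min_length, par.max_length + 1))
            tid = f"{g}.{k + 1}"
            models.append(_make_model(g, tid, chrom, offset, L, strand))
            offset += L + 2000
            lengths_list.append(L)
            tids.append(tid)
            t_genes.append(g)
    n = len(tids)
    lengths = np.array(lengths_list, dtype=float)

    # --- truth --------------------------------------------------------
    truth = _assign_classes(par, n, rng)
    # planted effects only on each gene's first isoform; markers stay null
    is_major = np.array([t.endswith(".1") for t in tids])
    is_marker = np.array([g in marker_dir for g in t_genes])
    for col, neutral in (("truth_class", "nontarget"), ("beta", 0.0),
                         ("delta", 0.0), ("ribo_log2fc", 0.0)):
        truth.loc[~is_major | is_marker, col] = neutral
    truth.index = pd.Index(tids, name="transcript_id")
    truth.insert(0, "gene_id", t_genes)

    # --- abundance ----------------------------------------------------
    base = rng.normal(par.abundance_mean_log2, par.abundance_sd_log2, size=n)
    minor = ~is_major
    base[minor] -= 2.0  # minor isoforms ~4x lower expressed
    tpm = 2.0 ** base
    tpm = tpm / tpm.sum() * 1e6
    truth["base_abundance"] = np.log2(tpm)

    # --- RiboTag counts ----------------------------------------------
    enrich = np.array([2.0 ** marker_dir.get(g, 0.0) for g in t_genes])
    ribo_cols: dict[str, np.ndarray] = {}
    ribo_meta = []
    for cond in ("Control", "Opto"):
        fc = 2.0 ** truth["ribo_log2fc"].to_numpy() if cond == "Opto" else 1.0
        input_share = tpm * lengths
        input_mean = input_share / input_share.sum() * par.ribo_library_size
        ip_share = tpm * fc * enrich * lengths
        ip_mean = ip_share / ip_share.sum() * par.ribo_library_size
        for r in range(1, par.n_ribo_reps + 1):
            s = f"{cond}_RiboIP_{r}"
            ribo_cols[s] = _nb_sample(rng, ip_mean, par.nb_dispersion)
            ribo_meta.append((s, "RiboTag-IP", cond, r))
            s = f"{cond}_RiboInput_{r}"
            ribo_cols[s] = _nb_sample(rng, input_mean, par.nb_dispersion)
            ribo_meta.append((s, "RiboTag-Input", cond, r))
    ribo_samples = pd.DataFrame(ribo_meta, columns=["sample", "assay", "condition", "replicate"]).set_index("sample")
    ribo_counts = CountMatrix(
        pd.DataFrame(ribo_cols, index=truth.index), ribo_samples)

    # --- CLIP: log-linear relation to realized RiboTag abundance ------
    lengths_ser = pd.Series(lengths, index=truth.index, name="length").astype(int)
    clip_cols: dict[str, np.ndarray] = {}
    clip_y: dict[str, np.ndarray] = {}
    clip_meta = []
    for cond in ("Control", "Opto"):
        ip = ribo_counts.select(assay="RiboTag-IP", condition=cond)
        ip_tpm = compute_tpm(ip, lengths_ser)
        x = np.log2(ip_tpm.values + par.pseudocount).mean(axis=1).to_numpy()
        offset_g = truth["beta"].to_numpy() + (
            truth["delta"].to_numpy() if cond == "Opto" else 0.0)
        for r in range(1, par.n_clip_reps + 1):
            eps = rng.normal(0.0, par.clip_noise_sd, size=n)
            y = par.intercept + par.slope * x + offset_g + eps
            share = (2.0 ** y) * lengths
            p = share / share.sum()
            s = f"{cond}_CLIP_{r}"
            clip_cols[s] = rng.multinomial(par.clip_library_size, p)
            clip_y[s] = y
            clip_meta.append((s, "CLIP", cond, r))
    clip_samples = pd.DataFrame(clip_meta, columns=["sample", "assay", "condition", "replicate"]).set_index("sample")
    clip_counts = CountMatrix(pd.DataFrame(clip_cols, index=truth.index), clip_samples)
    clip_log2 = QuantTable(pd.DataFrame(clip_y, index=truth.index),
                           scale="log2", pseudocount=par.pseudocount,
                           lengths=lengths_ser)

    truth["quadrant_truth"] = _quadrant_truth(
        truth["delta"].to_numpy(), truth["ribo_log2fc"].to_numpy())
    return SyntheticDataset(clip_counts, ribo_counts, clip_log2, models, truth, par)


def generate_tags(
    dataset: SyntheticDataset,
    max_tags_per_sample: int = 5000,
    tag_length: int = 30,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Emit per-replicate BED6 tag sets consistent with the CLIP counts.

    Tag starts are drawn uniformly over each transcript's mature
    coordinates and mapped to the genome (so most fall in the CDS, the
    dominant mature region). Intended for fixture-scale datasets.
    """
    par = dataset.params
    rng = np.random.default_rng(par.seed + 1 if seed is None else seed)
    by_tid = {m.transcript_id: m for m in dataset.models}
    out: dict[str, pd.DataFrame] = {}
    for sample in dataset.clip_counts.counts.columns:
        col = dataset.clip_counts.counts[sample]
        total = int(col.sum())
        scale = min(1.0, max_tags_per_sample / max(total, 1))
        rows = []
        for tid, c in col.items():
            n_tags = int(round(c * scale))
            if n_tags == 0:
                continue
            m = by_tid[tid]
            exons = sorted((f for f in m.features if f.label == "exon"),
                           key=lambda f: f.start)
            mature_len = m.length
            starts = rng.integers(0, max(mature_len - tag_length, 1), size=n_tags)
            for st in np.sort(starts):
                pos = int(st)
                # map mature offset to genomic coordinate (+ strand layout)
                for ex in exons:
                    ex_len = ex.end - ex.start
                    if pos < ex_len:
                        gstart = ex.start + pos
                        break
                    pos -= ex_len
                gend = min(gstart + tag_length, exons[-1].end)
                rows.append((m.chrom, gstart, gend, tid, 1, m.strand))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
        df["replicate"] = sample
        out[sample] = df
    return out


TINY_PARAMS = GeneratorParams(
    n_genes=50,
    clip_library_size=60_000,
    ribo_library_size=60_000,
    frac_stringent=0.12,
    frac_fmrp_down=0.12,
    frac_fmrp_up=0.08,
    p_ribo_up_fmrp_down=0.5,
    p_ribo_down_fmrp_down=0.4,
    include_markers=True,
    seed=20_240_501,
)


def make_fixture(name: str, outdir: str | Path) -> SyntheticDataset:
    """Write a frozen on-disk dataset (counts, sample sheets, GTF, tags,
    truth) for regression tests. ``tiny`` = 50 genes plus marker genes."""
    if name == "tiny":
        par = TINY_PARAMS
    elif name == "default":
        par = GeneratorParams()
    else:
        raise ValueError(f"unknown fixture {name!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = generate_dataset(par)

    write_table(ds.clip_counts.counts, outdir / "clip_counts.tsv")
    write_table(ds.clip_counts.samples, outdir / "clip_samples.tsv")
    write_table(ds.ribo_counts.counts, outdir / "ribo_counts.tsv")
    write_table(ds.ribo_counts.samples, outdir / "ribo_samples.tsv")
    write_table(ds.clip_log2_tpm.values, outdir / "clip_log2_tpm.tsv")
    write_table(ds.truth, outdir / "truth.tsv")
    write_gtf(ds.models, outdir / "models.gtf")
    if name == "tiny":
        tags = generate_tags(ds, max_tags_per_sample=150)
        for sample, df in tags.items():
            write_tags_bed(df, outdir / f"tags_{sample}.bed")
    return ds
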