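"""External representations: count tables, TPM tables, BED6 tags, GTF models.

Coordinate conventions: BED is 0-based half-open, GTF is 1-based inclusive;
everything is converted to 0-based half-open internally and converted back
on write, so coordinates round-trip bit-exactly.
"""
from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd

ASSAYS = ("CLIP", "RiboTag-IP", "RiboTag-Input")
CONDITIONS = ("Control", "Opto")

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Feature:
    """A labeled genomic interval (0-based half-open)."""

    label: str  # exon, CDS, 5UTR, 3UTR
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(f"feature {self.label} has start >= end ({self.start} >= {self.end})")
        if self.strand not in "+-":
            raise FormatError(f"feature strand must be + or -, got {self.strand!r}")


@dataclass
class TranscriptModel:
    """One transcript of one gene, with its genomic feature intervals.

    ``length`` is the mature-transcript length in nucleotides (sum of
    exon lengths), the quantity entering TPM.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    features: list[Feature] = field(default_factory=list)

    @property
    def length(self) -> int:
        return sum(f.end - f.start for f in self.features if f.label == "exon")

    @property
    def span(self) -> tuple[int, int]:
        starts = [f.start for f in self.features]
        ends = [f.end for f in self.features]
        return min(starts), max(ends)

    def validate(self) -> None:
        if self.length <= 0:
            raise FormatError(f"transcript {self.transcript_id} has no exon length")
        lo, hi = self.span
        for f in self.features:
            if f.chrom != self.chrom or f.strand != self.strand:
                raise FormatError(
                    f"feature of {self.transcript_id} on {f.chrom}{f.strand} "
                    f"disagrees with transcript {self.chrom}{self.strand}"
                )
            if not (lo <= f.start < f.end <= hi):
                raise FormatError(f"feature outside transcript span in {self.transcript_id}")


def lengths_of(models: Iterable[TranscriptModel]) -> pd.Series:
    """transcript_id -> mature length (nt)."""
    out = {m.transcript_id: m.length for m in models}
    return pd.Series(out, name="length", dtype=int)


def transcript_gene_map(models: Iterable[TranscriptModel]) -> pd.Series:
    return pd.Series({m.transcript_id: m.gene_id for m in models}, name="gene_id")


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Transcript x sample integer tag/read counts with sample metadata.

    ``samples`` is indexed by sample label with columns
    ``assay`` (CLIP / RiboTag-IP / RiboTag-Input), ``condition``
    (Control / Opto) and integer ``replicate``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicated transcript ids: {dups[:5]}")
        if self.counts.shape[0] == 0:
            raise FormatError("no transcripts in count table")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise FormatError("non-numeric values in count table")
        if (vals < 0).any():
            raise FormatError("negative values in count table")
        if not np.allclose(vals, np.round(vals)):
            raise FormatError("non-integer values in count table")
        self.counts = self.counts.astype(np.int64)
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise FormatError(f"samples missing from sample sheet: {sorted(missing)}")
        self.samples = self.samples.loc[list(self.counts.columns)].copy()
        bad_assay = set(self.samples["assay"]) - set(ASSAYS)
        if bad_assay:
            raise FormatError(f"unknown assay labels: {sorted(bad_assay)}")
        bad_cond = set(self.samples["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise FormatError(f"unknown condition labels: {sorted(bad_cond)}")

    @property
    def transcripts(self) -> pd.Index:
        return self.counts.index

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def select(self, assay: str | None = None, condition: str | None = None) -> "CountMatrix":
        keep = pd.Series(True, index=self.samples.index)
        if assay is not None:
            keep &= self.samples["assay"] == assay
        if condition is not None:
            keep &= self.samples["condition"] == condition
        cols = self.samples.index[keep]
        return CountMatrix(self.counts[cols], self.samples.loc[cols])

    def restrict(self, transcripts: Sequence[str]) -> "CountMatrix":
        keep = self.counts.index.intersection(pd.Index(transcripts))
        if len(keep) == 0:
            raise FormatError("restriction leaves no transcripts")
        return CountMatrix(self.counts.loc[keep], self.samples)


# ---------------------------------------------------------------------------
# quant table
# ---------------------------------------------------------------------------

@dataclass
class QuantTable:
    """Transcript x sample TPM values, linear or log2 scale."""

    values: pd.DataFrame
    scale: str = "linear"  # "linear" | "log2"
    pseudocount: float = 0.0
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise FormatError(f"unknown scale {self.scale!r}")
        if self.scale == "linear" and (self.values.to_numpy() < 0).any():
            raise FormatError("negative TPM on linear scale")
        if self.pseudocount < 0:
            raise FormatError("pseudocount must be non-negative")

    def to_log2(self, pseudocount: float) -> "QuantTable":
        if self.scale != "linear":
            raise FormatError("to_log2 requires a linear-scale table")
        return QuantTable(
            np.log2(self.values + pseudocount),
            scale="log2",
            pseudocount=pseudocount,
            lengths=self.lengths,
        )

    def check_normalized(self, rel_tol: float = 1e-9) -> None:
        if self.scale != "linear":
            return
        sums = self.values.sum(axis=0)
        nonzero = sums[sums > 0]
        if not np.allclose(nonzero, 1e6, rtol=rel_tol):
            raise FormatError("linear TPM columns do not sum to 1e6")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample", "assay", "condition", "replicate"}
    if not required.issubset(sheet.columns):
        raise FormatError(f"sample sheet needs columns {sorted(required)}")
    return sheet.set_index("sample")


def read_count_table(path: str | Path, sample_sheet: pd.DataFrame) -> CountMatrix:
    """Read a transcript x sample TSV of integer counts.

    Every data column must be described in ``sample_sheet`` (indexed by
    sample label, columns assay/condition/replicate).
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.shape[0] == 0:
        raise FormatError("no transcripts in count table")
    missing = set(df.columns) - set(sample_sheet.index)
    if missing:
        raise FormatError(f"columns absent from sample sheet: {sorted(missing)}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise FormatError(f"non-numeric counts in column {col}")
    return CountMatrix(df, sample_sheet)


def read_quant_files(
    paths: Mapping[str, str | Path] | str | Path,
    dialect: str = "salmon_like",
) -> QuantTable:
    """Read per-sample quantification tables into one linear-scale QuantTable.

    ``salmon_like``: one file per sample with columns Name / Length / TPM
    (extra columns ignored). ``matrix``: a single TSV with transcript_id,
    length, then one TPM column per sample.
    """
    if dialect == "salmon_like":
        if not isinstance(paths, Mapping):
            raise FormatError("salmon_like dialect needs a mapping sample -> path")
        cols: dict[str, pd.Series] = {}
        lengths: pd.Series | None = None
        for sample, path in paths.items():
            df = pd.read_csv(path, sep="\t", comment="#")
            rename = {c: c.lower() for c in df.columns}
            df = df.rename(columns=rename)
            need = {"name", "length", "tpm"}
            if not need.issubset(df.columns):
                raise FormatError(f"{path}: expected columns Name/Length/TPM")
            df = df.set_index("name")
            if lengths is None:
                lengths = df["length"].astype(int)
            else:
                common = lengths.index.intersection(df.index)
                if not (lengths.loc[common] == df.loc[common, "length"]).all():
                    bad = common[lengths.loc[common] != df.loc[common, "length"]]
                    raise FormatError(f"conflicting lengths for {list(bad[:5])}")
            cols[sample] = df["tpm"]
        values = pd.DataFrame(cols)
        assert lengths is not None
        return QuantTable(values, scale="linear", lengths=lengths.rename("length"))
    if dialect == "matrix":
        df = pd.read_csv(paths, sep="\t", comment="#", index_col=0)
        if "length" not in df.columns:
            raise FormatError("matrix dialect needs a 'length' column")
        lengths = df.pop("length").astype(int)
        return QuantTable(df.astype(float), scale="linear",
                          lengths=lengths.rename("length"))
    raise FormatError(f"unknown dialect {dialect!r}")


def read_tags_bed(
    path: str | Path,
    replicate: str | None = None,
    allow_unstranded: bool = False,
) -> pd.DataFrame:
    """Read a BED6 of PCR-collapsed CLIP tags.

    Returns a DataFrame with chrom/start/end/name/score/strand and a
    ``replicate`` column. CLIP tags are stranded; records with strand '.'
    are rejected unless ``allow_unstranded`` is set.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=BED_COLUMNS)
    if df.shape[0] and (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]]
        raise FormatError(f"BED records with start >= end (first at line {bad.index[0] + 1})")
    good = df["strand"].isin(["+", "-"])
    if not good.all():
        if not allow_unstranded:
            raise FormatError("unstranded BED records present (strand '.'); CLIP tags must be stranded")
        df = df[good].reset_index(drop=True)
    df["replicate"] = replicate if replicate is not None else str(Path(path).stem)
    return df


def write_tags_bed(tags: pd.DataFrame, path: str | Path) -> None:
    tags[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Parse gene models from a GTF (1-based inclusive -> 0-based half-open)."""
    db = gffutils.create_db(
        str(path), ":memory:", force=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
        keep_order=True,
    )
    models: dict[str, TranscriptModel] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS", "5UTR", "3UTR",
                                    "five_prime_utr", "three_prime_utr"):
            continue
        label = {"five_prime_utr": "5UTR", "three_prime_utr": "3UTR"}.get(
            feat.featuretype, feat.featuretype)
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes["gene_id"][0]
        model = models.get(tid)
        if model is None:
            model = models[tid] = TranscriptModel(gid, tid, feat.seqid, feat.strand)
        elif model.gene_id != gid:
            raise FormatError(f"transcript {tid} assigned to multiple genes")
        model.features.append(
            Feature(label, feat.seqid, feat.start - 1, feat.end, feat.strand))
    out = sorted(models.values(), key=lambda m: m.transcript_id)
    for m in out:
        m.validate()
    return out


def write_gtf(models: Iterable[TranscriptModel], path: str | Path, source: str = "clipscore") -> None:
    order = {"exon": 0, "CDS": 1, "5UTR": 2, "3UTR": 3}
    with open(path, "w") as fh:
        for m in sorted(models, key=lambda m: m.transcript_id):
            for f in sorted(m.features, key=lambda f: (order.get(f.label, 9), f.start)):
                attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
                fh.write(
                    f"{f.chrom}\t{source}\t{f.label}\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_table(
    df: pd.DataFrame,
    path: str | Path,
    config_hash: str | None = None,
    seed: int | None = None,
    index: bool = True,
    float_format: str = "%.10g",
) -> None:
    """Write a results TSV with a deterministic provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    if config_hash is not None:
        buf.write(f"# config_hash={config_hash}\n")
    if seed is not None:
        buf.write(f"# seed={seed}\n")
    df.to_csv(buf, sep="\t", index=index, float_format=float_format)
    path.write_text(buf.getvalue())


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_results(
    tables: Mapping[str, pd.DataFrame],
    outdir: str | Path,
    config_hash: str | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write every table as <name>.tsv under outdir; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in tables.items():
        p = outdir / f"{name}.tsv"
        if {"p", "padj"}.issubset(df.columns):
            df = df.sort_values(["p", "padj"], kind="mergesort")
        write_table(df, p, config_hash=config_hash, seed=seed)
        written[name] = p
    return written
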