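"""TPM, representative-transcript selection, biological complexity, and
RiboTag enrichment.

Biological complexity (BC) is the number of biological replicates in which
a gene is independently supported by at least ``bc_min_tags`` CLIP tags —
the reproducibility filter used in place of peak calling for an RBP with
continuous CDS coverage.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix, QuantTable

log = logging.getLogger(__name__)

# CA1 cell-type marker panel: excitatory genes are expected enriched in the
# RiboTag IP, all other cell-type markers depleted.
MARKER_PANEL: dict[str, tuple[str, list[str]]] = {
    "CA1_excitatory": ("enriched", ["Neurod6", "Camk2a", "Rbfox3", "Snap25",
                                    "Nrgn", "Hpca", "Crym", "Chn1"]),
    "inhibitory": ("depleted", ["Gad2", "Sst", "Calb2"]),
    "OPC": ("depleted", ["Pdgfra", "Ptprz1"]),
    "oligodendrocyte": ("depleted", ["Mag", "Mal", "Mbp", "Mobp", "Plp1"]),
    "astrocyte": ("depleted", ["Gfap", "Glul", "Aqp4", "Aldh1l1", "Pla2g7",
                               "Slc1a3", "Aldoc"]),
}


def compute_tpm(counts: CountMatrix, lengths: pd.Series) -> QuantTable:
    """Transcripts-per-million from counts and mature transcript lengths.

    TPM_i = (c_i / L_i) / sum_j (c_j / L_j) * 1e6, per sample. A sample
    with zero total counts yields an all-zero column (with a warning)
    rather than a division error.
    """
    missing = counts.transcripts.difference(lengths.index)
    if len(missing):
        raise KeyError(f"no length for transcripts: {list(missing[:5])}")
    L = lengths.loc[counts.transcripts].to_numpy(dtype=float)
    rate = counts.counts.to_numpy(dtype=float) / L[:, None]
    denom = rate.sum(axis=0)
    zero = denom == 0
    if zero.any():
        warnings.warn(
            f"{zero.sum()} sample(s) with zero total counts; TPM set to 0",
            RuntimeWarning,
        )
        denom = np.where(zero, 1.0, denom)
    tpm = rate / denom * 1e6
    tpm[:, zero] = 0.0
    values = pd.DataFrame(tpm, index=counts.transcripts, columns=counts.counts.columns)
    return QuantTable(values, scale="linear", lengths=lengths.loc[counts.transcripts])


def select_representative_transcripts(
    ribo_quant: QuantTable,
    gene_map: pd.Series,
    expression_floor: float = 0.0,
) -> pd.Series:
    """One transcript per gene: the isoform with the highest mean TPM
    across all RiboTag replicates of both conditions.

    Exact ties break to the lexicographically smallest transcript_id.
    Genes whose best isoform has mean TPM <= ``expression_floor`` are
    dropped (logged). Returns a Series gene_id -> transcript_id.
    """
    if ribo_quant.scale != "linear":
        raise ValueError("representative selection requires linear-scale TPM")
    mean_tpm = ribo_quant.values.mean(axis=1)
    df = pd.DataFrame({
        "gene_id": gene_map.loc[mean_tpm.index],
        "mean_tpm": mean_tpm,
    })
    # argmax with lexicographic tie-break, independent of input row order
    df = df.assign(_tid=df.index)
    df = df.sort_values(["mean_tpm", "_tid"], ascending=[False, True], kind="mergesort")
    best = df.groupby("gene_id", sort=True).head(1)
    kept = best[best["mean_tpm"] > expression_floor]
    dropped = best.shape[0] - kept.shape[0]
    if dropped:
        log.info("dropped %d gene(s) with mean TPM <= %g", dropped, expression_floor)
    return pd.Series(kept.index.values, index=kept["gene_id"].values, name="transcript_id")


def restrict_clip_to_expressed(
    clip_counts: CountMatrix, selected: pd.Series
) -> CountMatrix:
    """Keep only CLIP counts on the RiboTag-expressed representative set."""
    before = clip_counts.library_sizes()
    out = clip_counts.restrict(list(selected.values))
    removed = before - out.library_sizes()
    log.info("restrict_clip_to_expressed removed tags per sample: %s",
             removed.to_dict())
    return out


@dataclass
class BCProfile:
    """Per-entity replicate support at a given tag threshold."""

    support: pd.Series          # entity -> number of supporting replicates
    per_replicate: pd.DataFrame  # entity x replicate tag counts
    bc_min_tags: int
    n_replicates: int

    def passing(self, bc_required: int) -> pd.Index:
        if bc_required > self.n_replicates:
            raise ValueError(
                f"bc_required={bc_required} exceeds replicate count {self.n_replicates}"
            )
        return self.support.index[self.support >= bc_required]


def biological_complexity(
    clip_counts: CountMatrix,
    bc_min_tags: int = 5,
    level: str = "transcript",
    gene_map: pd.Series | None = None,
) -> BCProfile:
    """Count, per transcript or gene, the CLIP replicates with >= bc_min_tags tags."""
    counts = clip_counts.counts
    if level == "gene":
        if gene_map is None:
            raise ValueError("gene-level BC needs a transcript->gene map")
        counts = counts.groupby(gene_map.loc[counts.index].values).sum()
        counts.index.name = "gene_id"
    elif level != "transcript":
        raise ValueError(f"unknown level {level!r}")
    support = (counts >= bc_min_tags).sum(axis=1)
    return BCProfile(
        support=support,
        per_replicate=counts,
        bc_min_tags=bc_min_tags,
        n_replicates=counts.shape[1],
    )


def ribotag_enrichment(
    ip_quant: QuantTable,
    input_quant: QuantTable,
    diff: pd.DataFrame | None = None,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """log2((IP TPM + pc) / (Input TPM + pc)), optionally joined with the
    IP-vs-Input differential result (columns p, padj)."""
    common = ip_quant.values.index.intersection(input_quant.values.index)
    lost = len(ip_quant.values.index.symmetric_difference(input_quant.values.index))
    if lost:
        warnings.warn(f"{lost} transcript(s) missing from one table; dropped",
                      RuntimeWarning)
    ip = ip_quant.values.loc[common].mean(axis=1)
    inp = input_quant.values.loc[common].mean(axis=1)
    enr = np.log2(ip + pseudocount) - np.log2(inp + pseudocount)
    out = pd.DataFrame({"ip_tpm": ip, "input_tpm": inp, "enrichment": enr})
    if diff is not None:
        out = out.join(diff[["p", "padj"]], how="left")
    return out


def marker_panel_check(
    enr: pd.DataFrame,
    panel: dict[str, tuple[str, list[str]]] | None = None,
    id_map: pd.Series | None = None,
    concordance: float = 0.8,
) -> pd.DataFrame:
    """Per marker set: mean enrichment, fraction concordant with the
    expected direction (strict inequality vs 0), and pass/fail at the
    given concordance fraction.

    ``id_map`` maps gene symbols to the ids used in ``enr`` (identity if
    omitted). Missing genes are reported, not errors.
    """
    panel = MARKER_PANEL if panel is None else panel
    rows = []
    for name, (direction, genes) in panel.items():
        ids = [id_map.get(g, g) if id_map is not None else g for g in genes]
        present = [i for i in ids if i in enr.index]
        n_missing = len(ids) - len(present)
        if not present:
            rows.append({"set": name, "direction": direction, "n": 0,
                         "n_missing": n_missing, "mean_enrichment": np.nan,
                         "frac_concordant": np.nan, "status": "not_evaluable"})
            continue
        vals = enr.loc[present, "enrichment"]
        conc = (vals > 0).mean() if direction == "enriched" else (vals < 0).mean()
        rows.append({
            "set": name, "direction": direction, "n": len(present),
            "n_missing": n_missing, "mean_enrichment": float(vals.mean()),
            "frac_concordant": float(conc),
            "status": "pass" if conc >= concordance else "fail",
        })
    return pd.DataFrame(rows).set_index("set")
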