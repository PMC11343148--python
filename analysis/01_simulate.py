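"""Generate the synthetic CLIP + RiboTag study and write it to disk.

Emits count matrices, sample sheets, gene models and the ground truth
under <outdir>/data, and prints the planted class composition.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from study import study_args, study_params

from clipscore.io import write_gtf, write_table
from clipscore.simulate import generate_dataset


def main() -> None:
    args = study_args(__doc__)
    ds = generate_dataset(study_params(args.seed))
    out = Path(args.outdir) / "data"
    out.mkdir(parents=True, exist_ok=True)
    write_table(ds.clip_counts.counts, out / "clip_counts.tsv", seed=args.seed)
    write_table(ds.clip_counts.samples, out / "clip_samples.tsv")
    write_table(ds.ribo_counts.counts, out / "ribo_counts.tsv", seed=args.seed)
    write_table(ds.ribo_counts.samples, out / "ribo_samples.tsv")
    write_table(ds.truth, out / "truth.tsv", seed=args.seed)
    write_gtf(ds.models, out / "models.gtf")

    t = ds.truth
    print(f"simulated {t.shape[0]} transcripts "
          f"({ds.clip_counts.counts.shape[1]} CLIP, "
          f"{ds.ribo_counts.counts.shape[1]} RiboTag samples)")
    print("planted binding classes:",
          t["truth_class"].value_counts().to_dict())
    print("planted ribosome-association changes: "
          f"{int((t['ribo_log2fc'] > 0).sum())} up, "
          f"{int((t['ribo_log2fc'] < 0).sum())} down")
    print(f"wrote dataset to {out}")


if __name__ == "__main__":
    main()
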