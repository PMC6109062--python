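#!/usr/bin/env python
"""Generate the synthetic ribosome-profiling study used by the later steps.

Builds a 50-transcript transcriptome, then footprints for three WT and three
KO replicates (2e5 reads each) under a dwell model where KO slows the two
lysine codons AAA/AAG by a factor 1.5.  Raw reads go to scratch/synthetic/
(they are bulky and fully regenerable); the sample sheet and ORF table are
written alongside.
"""

import argparse
from pathlib import Path

from ribomethyl.io_formats import write_fasta, write_footprints, write_orf_table
from ribomethyl.synthdata import DwellModel, SimSpec, make_transcriptome, simulate_experiment


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", type=Path, default=Path("scratch/synthetic"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    spec = SimSpec(n_reads=200_000, replicates={"WT": 3, "KO": 3}, seed=args.seed)
    dwell = DwellModel(condition_overrides={"KO": {"AAA": 1.5, "AAG": 1.5}})
    transcriptome = make_transcriptome(spec)
    footprints, sheet = simulate_experiment(transcriptome, dwell, spec)

    write_fasta(transcriptome, args.out_dir / "transcripts.fa")
    write_orf_table(transcriptome, args.out_dir / "orfs.tsv")
    sheet.to_csv(args.out_dir / "samples.tsv", sep="\t", index=False)
    write_footprints(footprints, args.out_dir / "footprints.tsv")

    n_codons = sum(transcriptome.n_sense_codons(tid) for tid in transcriptome.transcript_ids)
    print(f"wrote {len(transcriptome.transcript_ids)} transcripts "
          f"({n_codons} sense codons) and {len(footprints)} footprints "
          f"across {len(sheet)} samples to {args.out_dir}")
    print("KO dwell perturbation: AAA, AAG x1.5")


if __name__ == "__main__":
    main()
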