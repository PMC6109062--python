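#!/usr/bin/env python
"""A-site codon occupancy: filter footprints, tally sites, form KO/WT ratios.

Reads the synthetic study from scratch/synthetic/ (run 01_simulate_data.py
first), applies the 29-31 nt / frame / ORF-exclusion filters, and writes the
per-codon occupancy table (ratio, sd, +1-site control, frequency quartile)
plus the filter funnel to results/.
"""

import argparse
from pathlib import Path

from ribomethyl.io_formats import (
    read_fasta,
    read_footprints,
    read_orf_table,
    read_sample_sheet,
    write_table,
)
from ribomethyl.riboprof import filter_footprints, occupancy_table, tally_site_codons


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("scratch/synthetic"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    if not (args.data_dir / "footprints.tsv").exists():
        raise SystemExit(f"no synthetic study in {args.data_dir}; run 01_simulate_data.py first")
    args.out_dir.mkdir(parents=True, exist_ok=True)

    transcriptome = read_orf_table(args.data_dir / "orfs.tsv",
                                   read_fasta(args.data_dir / "transcripts.fa"))
    sheet = read_sample_sheet(args.data_dir / "samples.tsv")
    footprints = read_footprints(args.data_dir / "footprints.tsv", sheet)

    kept, funnel = filter_footprints(footprints, transcriptome)
    counts = tally_site_codons(kept, transcriptome)
    table = occupancy_table([c for c in counts if c.condition == "KO"],
                            [c for c in counts if c.condition == "WT"], transcriptome)

    write_table(funnel, args.out_dir / "funnel.tsv", sort_by=None)
    write_table(table.reset_index(), args.out_dir / "occupancy.tsv", sort_by="codon")

    print(f"kept {len(kept)} of {len(footprints)} reads")
    top = table.relative_occupancy.sort_values(ascending=False).head(4)
    print("highest KO/WT relative occupancy:")
    for codon, ratio in top.items():
        ctrl = table.loc[codon, "control_relative_occupancy"]
        print(f"  {codon}: {ratio:.3f} (control {ctrl:.3f}, "
              f"quartile {table.loc[codon, 'frequency_quartile']})")
    print(f"unaffected-codon median ratio: "
          f"{table.drop(['AAA', 'AAG']).relative_occupancy.median():.3f}")


if __name__ == "__main__":
    main()
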