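#!/usr/bin/env python
"""Processive vs distributive N-terminal trimethylation across a titration.

Runs a 21-point enzyme:substrate titration to end point under both
mechanisms, writes the Me0-Me3 profiles, and classifies each titration by
its maximum intermediate burden at partial conversion.
"""

import argparse
from pathlib import Path

import pandas as pd

from ribomethyl.io_formats import write_table
from ribomethyl.kinetics import MechanismModel, classify_mechanism, default_ratios, run_titration


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    ratios = default_ratios()
    frames = []
    for mech in ("processive", "distributive"):
        tit = run_titration(MechanismModel(mechanism=mech), ratios)
        label, score = classify_mechanism(tit)
        tit.insert(0, "mechanism", mech)
        frames.append(tit)
        print(f"{mech}: classified {label} "
              f"(max Me1+Me2 at partial conversion = {score:.4f}); "
              f"Me3 at equimolar enzyme = {tit.Me3.iloc[-2]:.3f}")
    write_table(pd.concat(frames), args.out_dir / "titration.tsv",
                sort_by=["mechanism", "ratio"])


if __name__ == "__main__":
    main()
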