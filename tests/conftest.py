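import numpy as np
import pandas as pd
import pytest

from ribomethyl.io_formats import Transcriptome
from ribomethyl.motiflogo import ARRAY_RESIDUES


@pytest.fixture
def tiny_transcriptome() -> Transcriptome:
    """Two hand-built transcripts with 10 nt UTRs and known codons.

    t1 ORF (0-based [10, 70)): ATG + 18 sense codons + TAA.
    """
    body = "AAA GGG CCC TTT ACA CAC GAC TAC AAG GAA ATC CTG TTC GGA AGA TCA GTG TGG".replace(" ", "")
    orf = "ATG" + body + "TAA"
    seq1 = "GCGCGCGCGC" + orf + "ATATATATAT"
    seq2 = "TTTTTTTTTT" + "ATG" + "CCC" * 30 + "TGA" + "GGGGGGGGGG"
    return Transcriptome(
        sequences={"t1": seq1, "t2": seq2},
        orfs={"t1": (10, 10 + len(orf)), "t2": (10, 10 + 3 + 90 + 3)},
    )


@pytest.fixture
def planted_activity_matrix() -> pd.DataFrame:
    """Relative-activity matrix with classes [GAP]/[KRFYQH]/[E]/[KRQHIL]
    planted at positions 1-4 (actives 1.0, background 0.05) and no
    selectivity at positions 5-9."""
    classes = {1: set("GAP"), 2: set("KRFYQH"), 3: set("E"), 4: set("KRQHIL")}
    rows = {}
    for p in range(1, 10):
        rows[p] = {a: (1.0 if (p not in classes or a in classes[p]) else 0.05)
                   for a in ARRAY_RESIDUES}
    return pd.DataFrame(rows).T


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
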