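"""Peptide-array quantification, activity logos, and N-terminal motif scans.

A mutational-scanning SPOT array varies each of the first nine residues of
the substrate frame (position 1 = the residue exposed after iMet cleavage,
Gly2 of eEF1A) across all proteinogenic amino acids except tryptophan and
cysteine.  Spot intensities relative to the wild-type peptide give an
activity matrix; treating relative activity as letter frequency yields a
sequence logo; thresholding it yields a degenerate anchored consensus such
as M-[GAP]-[KRFYQH]-E-[KRQHIL], which is then matched exactly against
protein N termini.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

#: the 18 residues varied on the array (all proteinogenic minus C and W)
ARRAY_RESIDUES = tuple(sorted(set("ACDEFGHIKLMNPQRSTVWY") - {"C", "W"}))

#: alphabet size used for logo information content (full proteinogenic set)
LOGO_ALPHABET_SIZE = 20


@dataclass
class SpotArray:
    """Quantified peptide-array grid: intensity per (position, residue) plus
    the wild-type reference spot intensity."""

    intensities: pd.DataFrame  # index = 1-based positions, columns = residues
    reference_intensity: float

    def __post_init__(self) -> None:
        if self.reference_intensity <= 0:
            raise ValueError("reference (wild-type) spot intensity must be > 0")
        if (self.intensities.fillna(0.0) < 0).any().any():
            raise ValueError("spot intensities must be non-negative")


@dataclass(frozen=True)
class NTerminalPattern:
    """Anchored degenerate N-terminal pattern; the first class is always {M}
    (the initiator methionine)."""

    classes: tuple[frozenset, ...]

    def __post_init__(self) -> None:
        if not self.classes or self.classes[0] != frozenset("M"):
            raise ValueError("pattern must start with the fixed initiator-methionine class {M}")
        if any(not cls for cls in self.classes):
            raise ValueError("pattern classes must be non-empty")

    @classmethod
    def parse(cls, text: str) -> "NTerminalPattern":
        """Parse e.g. "M[GAP][KRFYQH]E[KRQHIL]" into a pattern."""
        tokens = re.findall(r"\[([A-Z]+)\]|([A-Z])", text)
        classes = tuple(frozenset(group or single) for group, single in tokens)
        return cls(classes)

    def __str__(self) -> str:
        parts = []
        for cls_ in self.classes:
            letters = "".join(sorted(cls_))
            parts.append(letters if len(letters) == 1 else f"[{letters}]")
        return "".join(parts)

    def __len__(self) -> int:
        return len(self.classes)


#: the consensus recognised by the eEF1A N-terminal methyltransferase domain
EEF1A_CONSENSUS = NTerminalPattern.parse("M[GAP][KRFYQH]E[KRQHIL]")


def normalize_array(array: SpotArray) -> pd.DataFrame:
    """Relative activity per (position, residue): spot / wild-type spot.

    1.0 means as active as the unmutated substrate; missing spots stay NaN.
    """
    return array.intensities / array.reference_intensity


def build_logo(matrix: pd.DataFrame) -> pd.DataFrame:
    """Activity-weighted sequence logo from a relative-activity matrix.

    Per position p: f(p, a) = activity(p, a) / sum_a activity(p, a);
    information = log2(20) - H(f(p, .)) in bits (no small-sample correction);
    letter height = f * information.  Returns a long-form frame with columns
    position, residue, frequency, information, height.
    """
    if (matrix.fillna(0.0) < 0).any().any():
        raise ValueError("activity matrix must be non-negative")
    rows = []
    for position in matrix.index:
        activities = matrix.loc[position].dropna()
        total = activities.sum()
        if total <= 0:
            raise ValueError(f"all-zero activity column at position {position}")
        freqs = activities / total
        nonzero = freqs[freqs > 0]
        entropy = float(-(nonzero * np.log2(nonzero)).sum())
        information = np.log2(LOGO_ALPHABET_SIZE) - entropy
        for residue, f in freqs.items():
            rows.append({"position": position, "residue": residue, "frequency": f,
                         "information": information, "height": f * information})
    return pd.DataFrame(rows)


def derive_consensus(matrix: pd.DataFrame, theta: float = 0.25) -> NTerminalPattern:
    """Threshold the activity matrix into a degenerate anchored pattern.

    A residue joins the class at position p iff its relative activity is at
    least theta times the maximum at p.  The initiator methionine is
    prepended as a fixed first class, and trailing positions whose class
    contains every array residue (no selectivity) are dropped.
    """
    if not 0 < theta <= 1:
        raise ValueError(f"theta must be in (0, 1], got {theta}")
    classes: list[frozenset] = [frozenset("M")]
    for position in matrix.index:
        activities = matrix.loc[position].dropna()
        peak = activities.max()
        members = frozenset(activities[activities >= theta * peak].index)
        if not members:
            raise ValueError(f"empty class at position {position}")
        classes.append(members)
    full = frozenset(ARRAY_RESIDUES)
    while len(classes) > 1 and full <= classes[-1]:
        classes.pop()
    return NTerminalPattern(tuple(classes))


def scan_proteome(proteome: dict[str, str] | str, pattern: NTerminalPattern) -> pd.DataFrame:
    """Exact anchored matching of the pattern against protein N termini.

    ``proteome`` is a mapping id -> sequence or a FASTA path.  A protein
    matches iff residues 1..len(pattern) each belong to the corresponding
    class; shorter sequences are non-matches (counted in the 'too_short'
    attribute).  Output is sorted by protein id.
    """
    if isinstance(proteome, str):
        proteome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(proteome, "fasta")}
    hits = []
    n_short = 0
    for pid in sorted(proteome):
        seq = proteome[pid]
        if len(seq) < len(pattern):
            n_short += 1
            continue
        if all(seq[i] in cls for i, cls in enumerate(pattern.classes)):
            hits.append({"protein_id": pid, "prefix": seq[: len(pattern)]})
    result = pd.DataFrame(hits, columns=["protein_id", "prefix"])
    result.attrs["too_short"] = n_short
    return result
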