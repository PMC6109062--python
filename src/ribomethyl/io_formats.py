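"""Readers and writers for the external formats the pipeline touches.

All coordinates are 0-based half-open internally; SAM (1-based) is converted
on ingest.  Footprint alignments are carried in bulk as a pandas DataFrame
with one column per :class:`FootprintAlignment` field; the dataclass is the
single-record view.  Every filter logs its funnel (input, kept, reason-coded
drops) at INFO level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam
import yaml
from Bio import SeqIO

from ._codons import STOP_CODONS

logger = logging.getLogger("ribomethyl")

FOOTPRINT_COLUMNS = ["read_id", "transcript_id", "five_prime", "length", "sample_id", "condition"]

#: accepted read lengths at ingest; analysis filters narrow further
INGEST_LENGTH_RANGE = (20, 45)


@dataclass
class Transcriptome:
    """Transcript sequences plus ORF intervals (the coordinate frame for all
    footprint arithmetic).

    ``sequences`` maps transcript_id -> nucleotide string over {A,C,G,T,N};
    ``orfs`` maps transcript_id -> (cds_start, cds_end), 0-based half-open.
    """

    sequences: dict[str, str]
    orfs: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, (start, end) in self.orfs.items():
            self._check_orf(tid, start, end)

    def _check_orf(self, tid: str, start: int, end: int) -> None:
        if tid not in self.sequences:
            raise ValueError(f"ORF references unknown transcript {tid!r}")
        seq = self.sequences[tid]
        if not (0 <= start < end <= len(seq)):
            raise ValueError(f"ORF [{start}, {end}) outside transcript {tid!r} (length {len(seq)})")
        if (end - start) % 3 != 0:
            raise ValueError(f"ORF length of {tid!r} ({end - start} nt) is not a multiple of 3")
        last = seq[end - 3 : end]
        if last not in STOP_CODONS:
            # real inputs may lack an annotated stop; flagged, not fatal
            logger.warning("ORF of %s does not end in a stop codon (got %s)", tid, last)

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.sequences)

    def n_sense_codons(self, tid: str) -> int:
        start, end = self.orfs[tid]
        return (end - start) // 3 - 1  # last codon is the stop


@dataclass
class FootprintAlignment:
    """One ribosome-footprint read placed on a transcript (0-based 5' end)."""

    read_id: str
    transcript_id: str
    five_prime: int
    length: int
    sample_id: str
    condition: str = ""

    def __post_init__(self) -> None:
        if self.five_prime < 0:
            raise ValueError(f"five_prime must be >= 0, got {self.five_prime}")
        lo, hi = INGEST_LENGTH_RANGE
        if not lo <= self.length <= hi:
            raise ValueError(f"read length {self.length} outside ingest range [{lo}, {hi}]")


@dataclass
class RunConfig:
    """Analysis constants; the stated footprint geometry is the default.

    Read-window coordinates are 1-based within the read: the A-site is read
    positions 15-17 and the +1 site 18-20 for every accepted length.
    """

    analysis_length_min: int = 29
    analysis_length_max: int = 31
    a_site_window: tuple[int, int] = (15, 17)
    plus1_window: tuple[int, int] = (18, 20)
    orf_exclusion: int = 15
    ppm_tolerance: dict = field(default_factory=lambda: {"glu_c": 10.0, "chymotryptic": 20.0})
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("a_site_window", self.a_site_window), ("plus1_window", self.plus1_window)):
            if hi - lo + 1 != 3:
                raise ValueError(f"{name} must span exactly 3 nt, got {lo}-{hi}")
        if self.a_site_window[1] >= self.plus1_window[0]:
            raise ValueError("a_site_window and plus1_window must not overlap")
        if self.orf_exclusion < 0:
            raise ValueError("orf_exclusion must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("a_site_window", "plus1_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["a_site_window"] = list(self.a_site_window)
        data["plus1_window"] = list(self.plus1_window)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


def read_fasta(path: str | Path) -> Transcriptome:
    """Read a nucleotide FASTA into a Transcriptome (no ORFs yet).

    Sequences are uppercased; U is mapped to T with a logged warning.
    Duplicate ids and empty files are errors.
    """
    sequences: dict[str, str] = {}
    n_u = 0
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate transcript id {record.id!r} in {path}")
        seq = str(record.seq).upper()
        if "U" in seq:
            n_u += seq.count("U")
            seq = seq.replace("U", "T")
        sequences[record.id] = seq
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    if n_u:
        logger.warning("mapped %d U bases to T while reading %s", n_u, path)
    return Transcriptome(sequences=sequences)


def write_fasta(transcriptome: Transcriptome | Mapping[str, str], path: str | Path, width: int = 70) -> None:
    seqs = transcriptome.sequences if isinstance(transcriptome, Transcriptome) else transcriptome
    with open(path, "w") as fh:
        for tid, seq in seqs.items():
            fh.write(f">{tid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_orf_table(path: str | Path, transcriptome: Transcriptome) -> Transcriptome:
    """Attach ORF intervals from a BED-like TSV (transcript_id, cds_start,
    cds_end; 0-based half-open) to an existing Transcriptome."""
    table = pd.read_csv(path, sep="\t", comment="#", header=None,
                        names=["transcript_id", "cds_start", "cds_end"],
                        dtype={"transcript_id": str})
    unknown = sorted(set(table["transcript_id"]) - set(transcriptome.sequences))
    if unknown:
        raise ValueError(f"ORF table references unknown transcripts: {', '.join(unknown)}")
    bad = table[(table["cds_end"] - table["cds_start"]) % 3 != 0]
    if not bad.empty:
        rows = ", ".join(f"{r.transcript_id}:[{r.cds_start},{r.cds_end})" for r in bad.itertuples())
        raise ValueError(f"ORF length not a multiple of 3 for rows: {rows}")
    orfs = {r.transcript_id: (int(r.cds_start), int(r.cds_end)) for r in table.itertuples()}
    return Transcriptome(sequences=transcriptome.sequences, orfs=orfs)


def write_orf_table(transcriptome: Transcriptome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid, (start, end) in transcriptome.orfs.items():
            fh.write(f"{tid}\t{start}\t{end}\n")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet TSV with header: sample_id, condition, replicate[, path].

    The sheet is the single source of condition/replicate labels."""
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    required = {"sample_id", "condition", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet {path} lacks columns: {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        dupes = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in sheet: {dupes}")
    return sheet


def _attach_conditions(frame: pd.DataFrame, samples: pd.DataFrame | None) -> pd.DataFrame:
    if samples is None:
        frame["condition"] = frame.get("condition", "")
        return frame
    lookup = samples.set_index("sample_id")["condition"]
    unknown = sorted(set(frame["sample_id"]) - set(lookup.index))
    if unknown:
        raise ValueError(f"footprints reference samples absent from the sheet: {unknown}")
    frame["condition"] = frame["sample_id"].map(lookup)
    return frame


def read_footprints(path: str | Path, samples: pd.DataFrame | None = None,
                    dialect: str = "tsv", sample_id: str | None = None) -> pd.DataFrame:
    """Read footprint alignments into the bulk DataFrame container.

    ``dialect='tsv'``: columns read_id, transcript_id, five_prime, length,
    sample_id (no header).  ``dialect='sam'``: transcript-space SAM; POS is
    converted to 0-based; reverse-strand, spliced, and unmapped records are
    skipped with counted warnings; ``sample_id`` labels all reads of the file.
    Reads outside the ingest length range are dropped with a counted warning.
    """
    if dialect == "tsv":
        frame = pd.read_csv(path, sep="\t", header=None,
                            names=["read_id", "transcript_id", "five_prime", "length", "sample_id"],
                            dtype={"read_id": str, "transcript_id": str, "sample_id": str})
    elif dialect == "sam":
        if sample_id is None:
            raise ValueError("sample_id is required for SAM ingestion")
        rows = []
        skipped = {"reverse_strand": 0, "spliced": 0, "unmapped": 0}
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            for rec in sam:
                if rec.is_unmapped:
                    skipped["unmapped"] += 1
                    continue
                if rec.is_reverse:
                    skipped["reverse_strand"] += 1
                    continue
                if rec.cigartuples and any(op == 3 for op, _ in rec.cigartuples):  # N = spliced
                    skipped["spliced"] += 1
                    continue
                rows.append((rec.query_name, rec.reference_name,
                             rec.reference_start, rec.query_length or rec.infer_read_length(), sample_id))
        for reason, n in skipped.items():
            if n:
                logger.info("SAM ingest %s: skipped %d %s records", path, n, reason)
        frame = pd.DataFrame(rows, columns=["read_id", "transcript_id", "five_prime", "length", "sample_id"])
    else:
        raise ValueError(f"unknown footprint dialect {dialect!r}")

    lo, hi = INGEST_LENGTH_RANGE
    in_range = (frame["length"] >= lo) & (frame["length"] <= hi)
    n_dropped = int((~in_range).sum())
    if n_dropped:
        logger.info("ingest %s: dropped %d reads outside length range [%d, %d]", path, n_dropped, lo, hi)
        frame = frame[in_range].reset_index(drop=True)
    if (frame["five_prime"] < 0).any():
        raise ValueError("negative five_prime coordinate in footprint input")
    return _attach_conditions(frame, samples)


def footprints_to_frame(alignments: Iterable[FootprintAlignment] | pd.DataFrame) -> pd.DataFrame:
    """Normalize either container to the bulk DataFrame."""
    if isinstance(alignments, pd.DataFrame):
        return alignments
    return pd.DataFrame([asdict(a) for a in alignments], columns=FOOTPRINT_COLUMNS)


def frame_to_footprints(frame: pd.DataFrame) -> list[FootprintAlignment]:
    return [FootprintAlignment(r.read_id, r.transcript_id, int(r.five_prime), int(r.length),
                               r.sample_id, getattr(r, "condition", ""))
            for r in frame.itertuples(index=False)]


def write_footprints(frame: pd.DataFrame, path: str | Path) -> None:
    frame[["read_id", "transcript_id", "five_prime", "length", "sample_id"]].to_csv(
        path, sep="\t", header=False, index=False)


def write_table(rows: pd.DataFrame | Iterable[Mapping], path: str | Path,
                sort_by: str | list[str] | None = None, float_fmt: str = "%.6g") -> None:
    """Write a TSV with deterministic column and row order.

    Rows are sorted by ``sort_by`` (default: the first column); floats use a
    fixed format so that writes are reproducible byte-for-byte.
    """
    frame = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    if len(frame):
        keys = sort_by if sort_by is not None else list(frame.columns[:1])
        frame = frame.sort_values(keys, kind="mergesort")
    frame.to_csv(path, sep="\t", index=False, float_format=float_fmt)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
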