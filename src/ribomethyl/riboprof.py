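"""A-site codon occupancy from ribosome footprints.

The pipeline keeps 29-31 nt reads starting in frame 0, defines the A-site as
read positions 15-17 (1-based), excludes reads decoding the first 15 nt of
each ORF, and normalises each codon's A-site count by the mean of its counts
at the +1/+2/+3 downstream sites — a codon-usage correction that makes
occupancy a dimensionless quantity equal to 1 under uniform dwell.  The +1
site, normalised by +2/+3/+4, serves as a negative control: it reflects
codons the ribosome has not yet decoded, so condition effects on decoding
speed should vanish there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from ._codons import SENSE_CODONS, SENSE_INDICES, STOP_INDICES, codons_at, encode_sequence
from .io_formats import RunConfig, Transcriptome, footprints_to_frame

logger = logging.getLogger("ribomethyl")

SITES = ("A", "P1", "P2", "P3", "P4")
#: 0-based offset of each site's codon start from the read 5' end
SITE_OFFSETS = {"A": 14, "P1": 17, "P2": 20, "P3": 23, "P4": 26}


@dataclass
class SiteCodonCounts:
    """Per-sample codon tallies at the A-site and the four downstream sites.

    ``counts``: DataFrame indexed by the 61 sense codons, one column per
    site; ``n_reads_used``: reads contributing to each site (codons with N
    are skipped per site).
    """

    sample_id: str
    condition: str
    counts: pd.DataFrame
    n_reads_used: dict[str, int]

    def __post_init__(self) -> None:
        for site in SITES:
            if int(self.counts[site].sum()) != self.n_reads_used[site]:
                raise ValueError(f"count/total mismatch at site {site} for {self.sample_id}")


def filter_footprints(alignments, transcriptome: Transcriptome,
                      config: RunConfig | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the analysis filters; returns (kept reads, funnel report).

    Kept reads satisfy all of: length within the analysis range; 5' end in
    frame 0 at or after the ORF start; A-site codon beyond the excluded
    first 15 nt of the ORF; A-site through +4 codons fully within the ORF's
    sense codons (whole reads are dropped near the stop so every site is
    tallied over the identical read set).  Drops are reported, never raised.
    """
    config = config or RunConfig()
    frame = footprints_to_frame(alignments).copy()
    unknown = set(frame["transcript_id"]) - set(transcriptome.orfs)
    if unknown:
        raise ValueError(f"footprints reference transcripts without ORFs: {sorted(unknown)[:5]}")

    cds_start = frame["transcript_id"].map({t: se[0] for t, se in transcriptome.orfs.items()})
    cds_end = frame["transcript_id"].map({t: se[1] for t, se in transcriptome.orfs.items()})
    fp = frame["five_prime"]
    a_start = fp + SITE_OFFSETS["A"]

    rules = [
        ("length", frame["length"].between(config.analysis_length_min, config.analysis_length_max)),
        ("frame", (fp + SITE_OFFSETS["A"] - cds_start) % 3 == 0),
        # implies five_prime >= cds_start whenever the exclusion is >= 1 nt
        ("orf_exclusion", a_start >= cds_start + config.orf_exclusion),
        ("within_sense", fp + SITE_OFFSETS["P4"] + 3 <= cds_end - 3),
    ]
    keep = pd.Series(True, index=frame.index)
    funnel = [{"rule": "input", "n": len(frame), "dropped": 0}]
    for name, ok in rules:
        dropped = int((keep & ~ok).sum())
        keep &= ok
        funnel.append({"rule": name, "n": int(keep.sum()), "dropped": dropped})
    report = pd.DataFrame(funnel)
    for row in report.itertuples():
        logger.info("filter %-14s kept=%d dropped=%d", row.rule, row.n, row.dropped)
    return frame[keep].reset_index(drop=True), report


def tally_site_codons(filtered: pd.DataFrame, transcriptome: Transcriptome) -> list[SiteCodonCounts]:
    """Tally the codon at each of the five sites for every read, per sample.

    Codons containing N are skipped for that site only; in-frame stop
    triplets (possible in unvalidated real data) are likewise excluded so
    tallies cover sense codons only.
    """
    encoded = {tid: encode_sequence(seq) for tid, seq in transcriptome.sequences.items()}
    results = []
    for sample_id, sub in filtered.groupby("sample_id", sort=True):
        condition = sub["condition"].iloc[0] if "condition" in sub else ""
        counts = np.zeros((len(SITES), 64), dtype=np.int64)
        for tid, reads in sub.groupby("transcript_id", sort=False):
            enc = encoded[tid]
            fp = reads["five_prime"].to_numpy()
            for s, site in enumerate(SITES):
                idx = codons_at(enc, fp + SITE_OFFSETS[site])
                valid = idx >= 0
                counts[s] += np.bincount(idx[valid], minlength=64)
        sense = counts[:, SENSE_INDICES]
        table = pd.DataFrame(sense.T, index=list(SENSE_CODONS), columns=list(SITES))
        n_used = {site: int(sense[s].sum()) for s, site in enumerate(SITES)}
        results.append(SiteCodonCounts(sample_id=sample_id, condition=condition,
                                       counts=table, n_reads_used=n_used))
    return results


def codon_occupancy(counts: SiteCodonCounts, site: str = "A") -> pd.Series:
    """Usage-normalised occupancy: site count over the mean of the same
    codon's counts at the three downstream sites.

    site='A' uses +1/+2/+3; site='P1' uses +2/+3/+4.  Codons whose
    downstream mean is zero get NaN (missing, not zero).
    """
    if site == "A":
        down = ["P1", "P2", "P3"]
    elif site == "P1":
        down = ["P2", "P3", "P4"]
    else:
        raise ValueError(f"no +1..+3 tallies available downstream of site {site!r}")
    denom = counts.counts[down].mean(axis=1)
    occ = counts.counts[site] / denom.where(denom > 0)
    n_missing = int(occ.isna().sum())
    if n_missing:
        logger.info("occupancy %s site %s: %d codons with zero denominator", counts.sample_id, site, n_missing)
    return occ.rename(counts.sample_id)


def relative_occupancy(tables_ko: list[SiteCodonCounts],
                       tables_wt: list[SiteCodonCounts]) -> pd.DataFrame:
    """Per-codon KO/WT relative occupancy with the +1-site control.

    ratio = mean over KO replicates / mean over WT replicates of the
    per-replicate occupancies; sd = standard deviation over all pairwise
    (KO replicate / WT replicate) ratios.  The control columns repeat the
    computation at the +1 site.  Codons missing in any replicate are flagged
    and their ratio omitted (NaN).
    """
    if not tables_ko or not tables_wt:
        raise ValueError("need at least one replicate per condition")
    out = pd.DataFrame(index=list(SENSE_CODONS))
    for label, site in (("", "A"), ("control_", "P1")):
        ko = pd.concat([codon_occupancy(t, site) for t in tables_ko], axis=1)
        wt = pd.concat([codon_occupancy(t, site) for t in tables_wt], axis=1)
        if label == "":
            for t, occ in zip(tables_ko, ko.items()):
                out[f"occ_{occ[0]}"] = occ[1]
            for t, occ in zip(tables_wt, wt.items()):
                out[f"occ_{occ[0]}"] = occ[1]
        incomplete = ko.isna().any(axis=1) | wt.isna().any(axis=1)
        ratio = ko.mean(axis=1) / wt.mean(axis=1)
        ratio[incomplete] = np.nan
        pair_ratios = pd.DataFrame(
            {f"{i}/{j}": ko.iloc[:, i] / wt.iloc[:, j]
             for i, j in product(range(ko.shape[1]), range(wt.shape[1]))})
        sd = pair_ratios.std(axis=1, ddof=1) if pair_ratios.shape[1] > 1 else pd.Series(0.0, index=out.index)
        sd[incomplete] = np.nan
        out[f"{label}ko_mean"] = ko.mean(axis=1)
        out[f"{label}wt_mean"] = wt.mean(axis=1)
        out[f"{label}relative_occupancy"] = ratio
        out[f"{label}sd"] = sd
        out[f"{label}flagged"] = incomplete
    out.index.name = "codon"
    return out


def codon_frequency_quartiles(transcriptome: Transcriptome) -> pd.Series:
    """Quartile (1 = rarest, 4 = most frequent) of each sense codon's
    frequency over all ORF sense codons; ties broken alphabetically; the
    rarest quartile takes the extra codon (sizes 16/15/15/15)."""
    if not transcriptome.orfs:
        raise ValueError("transcriptome has no ORFs")
    counts = np.zeros(64, dtype=np.int64)
    for tid, (start, end) in transcriptome.orfs.items():
        enc = encode_sequence(transcriptome.sequences[tid])
        starts = np.arange(start, end - 3, 3)  # sense codons only
        idx = codons_at(enc, starts)
        valid = (idx >= 0) & ~np.isin(idx, list(STOP_INDICES))
        counts += np.bincount(idx[valid], minlength=64)
    freq = pd.Series(counts[SENSE_INDICES], index=list(SENSE_CODONS), name="frequency")
    order = freq.sort_index().sort_values(kind="mergesort").index  # alphabetical within ties
    sizes = [16, 15, 15, 15]
    quartile = pd.Series(0, index=freq.index, dtype=int, name="frequency_quartile")
    pos = 0
    for q, size in enumerate(sizes, start=1):
        quartile[order[pos : pos + size]] = q
        pos += size
    return quartile


def occupancy_table(tables_ko: list[SiteCodonCounts], tables_wt: list[SiteCodonCounts],
                    transcriptome: Transcriptome) -> pd.DataFrame:
    """Full per-codon summary: relative occupancy, control, and quartiles."""
    table = relative_occupancy(tables_ko, tables_wt)
    table["frequency_quartile"] = codon_frequency_quartiles(transcriptome)
    return table
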