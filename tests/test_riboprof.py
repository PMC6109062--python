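import numpy as np
import pandas as pd
import pytest

from ribomethyl.io_formats import FootprintAlignment, Transcriptome
from ribomethyl.riboprof import (
    SiteCodonCounts,
    codon_frequency_quartiles,
    codon_occupancy,
    filter_footprints,
    relative_occupancy,
    tally_site_codons,
)
from ribomethyl._codons import SENSE_CODONS


def read(fp, length=30, tid="t2", sample="s1", cond="WT"):
    return FootprintAlignment(f"r{fp}_{length}", tid, fp, length, sample, cond)


class TestFilter:
    """t2 fixture: cds [10, 106); sense codons at 10..103; stop at 103."""

    def test_length_28_dropped(self, tiny_transcriptome):
        kept, funnel = filter_footprints([read(42, 28)], tiny_transcriptome)
        assert kept.empty
        assert funnel.set_index("rule").loc["length", "dropped"] == 1

    def test_a_site_in_excluded_region_dropped(self, tiny_transcriptome):
        # A-site codon starting at ORF nt 12 < 15: five_prime = 10 + 12 - 14
        kept, funnel = filter_footprints([read(8)], tiny_transcriptome)
        assert kept.empty
        assert funnel.set_index("rule").loc["orf_exclusion", "dropped"] == 1

    def test_a_site_at_exclusion_boundary_kept(self, tiny_transcriptome):
        # A-site codon starting at ORF nt 15: five_prime = 10 + 15 - 14 = 11
        kept, _ = filter_footprints([read(11)], tiny_transcriptome)
        assert len(kept) == 1

    def test_off_frame_read_dropped(self, tiny_transcriptome):
        kept, funnel = filter_footprints([read(12)], tiny_transcriptome)
        assert kept.empty
        assert funnel.set_index("rule").loc["frame", "dropped"] == 1

    def test_p4_crossing_stop_drops_whole_read(self, tiny_transcriptome):
        # last acceptable five_prime: fp + 29 <= cds_end - 3 = 103 -> fp = 74
        kept, _ = filter_footprints([read(74), read(77)], tiny_transcriptome)
        assert kept.read_id.tolist() == ["r74_30"]

    def test_unknown_transcript_is_error(self, tiny_transcriptome):
        with pytest.raises(ValueError, match="tX"):
            filter_footprints([read(11, tid="tX")], tiny_transcriptome)

    def test_funnel_accounts_for_every_read(self, tiny_transcriptome, rng):
        reads = [read(int(fp), int(ln)) for fp, ln in
                 zip(rng.integers(0, 60, 200), rng.integers(27, 33, 200))]
        kept, funnel = filter_footprints(reads, tiny_transcriptome)
        assert funnel.dropped.sum() + len(kept) == len(reads)


class TestTally:
    def test_hand_built_codons_per_site(self, tiny_transcriptome):
        # t1 ORF body starts at 13: AAA GGG CCC TTT ACA ...
        # five_prime = 13 + 3*5 - 14 = 14 -> A-site = codon 6 of the ORF (CAC)
        counts = tally_site_codons(
            filter_footprints([read(14, 30, tid="t1")], tiny_transcriptome)[0],
            tiny_transcriptome)[0]
        expect = {"A": "CAC", "P1": "GAC", "P2": "TAC", "P3": "AAG", "P4": "GAA"}
        for site, codon in expect.items():
            assert counts.counts.loc[codon, site] == 1
            assert counts.n_reads_used[site] == 1

    def test_length_29_p4_window_inside_read(self, tiny_transcriptome):
        counts = tally_site_codons(
            filter_footprints([read(14, 29, tid="t1")], tiny_transcriptome)[0],
            tiny_transcriptome)[0]
        assert counts.n_reads_used["P4"] == 1  # positions 27-29 of a 29-nt read

    def test_site_totals_match_read_count(self, tiny_transcriptome, rng):
        fps = 13 + 3 * rng.integers(5, 25, size=300) - 14
        reads = [read(int(fp), 30, tid="t1") for fp in fps]
        kept, _ = filter_footprints(reads, tiny_transcriptome)
        counts = tally_site_codons(kept, tiny_transcriptome)[0]
        for site in ("A", "P1", "P2", "P3", "P4"):
            assert counts.counts[site].sum() == len(kept)


def make_counts(a, p1, p2, p3, p4, sample="s", cond="WT"):
    table = pd.DataFrame(
        {"A": a, "P1": p1, "P2": p2, "P3": p3, "P4": p4},
        index=list(SENSE_CODONS), dtype=np.int64)
    n = {s: int(table[s].sum()) for s in table.columns}
    return SiteCodonCounts(sample, cond, table, n)


class TestOccupancy:
    def test_downstream_mean_normalisation(self):
        a = np.zeros(61, dtype=int); a[0] = 30
        d1 = np.zeros(61, dtype=int); d1[0] = 10
        d2 = np.zeros(61, dtype=int); d2[0] = 20
        d3 = np.zeros(61, dtype=int); d3[0] = 30
        counts = make_counts(a, d1, d2, d3, np.zeros(61, dtype=int))
        assert codon_occupancy(counts)["AAA"] == pytest.approx(30 / 20)

    def test_all_sites_equal_gives_unity(self, rng):
        base = rng.integers(10, 100, size=61)
        counts = make_counts(base, base, base, base, base)
        occ = codon_occupancy(counts)
        assert np.allclose(occ.to_numpy(), 1.0)

    def test_zero_denominator_is_missing_not_zero(self):
        a = np.ones(61, dtype=int)
        z = np.zeros(61, dtype=int)
        occ = codon_occupancy(make_counts(a, z, z, z, z))
        assert occ.isna().all()

    def test_site_beyond_p1_rejected(self, rng):
        base = rng.integers(10, 100, size=61)
        with pytest.raises(ValueError, match="P2"):
            codon_occupancy(make_counts(base, base, base, base, base), site="P2")

    def test_counts_and_frequencies_give_same_occupancy(self, rng):
        """Every kept read contributes one codon per site, so within-site
        frequencies and raw counts give identical occupancy."""
        p = rng.dirichlet(np.ones(61))
        tables = [rng.multinomial(5000, p) for _ in range(5)]  # equal site totals
        counts = make_counts(*tables)
        occ_counts = codon_occupancy(counts)
        freq = counts.counts / counts.counts.sum(axis=0)
        occ_freq = freq["A"] / freq[["P1", "P2", "P3"]].mean(axis=1)
        np.testing.assert_allclose(occ_counts.to_numpy(), occ_freq.to_numpy(), rtol=1e-12)


class TestRelativeOccupancy:
    def test_identical_conditions_give_unit_ratio(self, rng):
        base = [rng.integers(50, 150, size=61) for _ in range(5)]
        ko = [make_counts(*base, sample="ko1", cond="KO")]
        wt = [make_counts(*base, sample="wt1", cond="WT")]
        table = relative_occupancy(ko, wt)
        assert np.allclose(table.relative_occupancy.to_numpy(), 1.0)
        assert np.allclose(table.sd.fillna(0).to_numpy(), 0.0)

    def test_swapping_conditions_inverts_ratios(self, rng):
        t1 = [rng.integers(50, 150, size=61) for _ in range(5)]
        t2 = [rng.integers(50, 150, size=61) for _ in range(5)]
        a = [make_counts(*t1, sample="a")]
        b = [make_counts(*t2, sample="b")]
        fwd = relative_occupancy(a, b).relative_occupancy
        rev = relative_occupancy(b, a).relative_occupancy
        np.testing.assert_allclose(fwd.to_numpy(), 1.0 / rev.to_numpy(), rtol=1e-12)

    def test_missing_replicate_value_flags_codon(self, rng):
        base = [rng.integers(50, 150, size=61) for _ in range(5)]
        broken = [arr.copy() for arr in base]
        for arr in broken[1:]:
            arr[0] = 0  # zero downstream counts for AAA
        ko = [make_counts(*broken, sample="ko1")]
        wt = [make_counts(*base, sample="wt1")]
        table = relative_occupancy(ko, wt)
        assert table.loc["AAA", "flagged"]
        assert np.isnan(table.loc["AAA", "relative_occupancy"])


class TestQuartiles:
    def test_partition_sizes(self, tiny_transcriptome):
        q = codon_frequency_quartiles(tiny_transcriptome)
        assert q.value_counts().sort_index().tolist() == [16, 15, 15, 15]

    def test_dominant_codon_in_top_quartile(self, tiny_transcriptome):
        # t2 is CCC x 30: overwhelmingly the most frequent codon
        assert codon_frequency_quartiles(tiny_transcriptome)["CCC"] == 4

    def test_order_invariance(self, tiny_transcriptome):
        shuffled = Transcriptome(
            sequences=dict(reversed(tiny_transcriptome.sequences.items())),
            orfs=tiny_transcriptome.orfs)
        pd.testing.assert_series_equal(
            codon_frequency_quartiles(tiny_transcriptome),
            codon_frequency_quartiles(shuffled))

    def test_no_orfs_is_error(self, tiny_transcriptome):
        with pytest.raises(ValueError, match="no ORFs"):
            codon_frequency_quartiles(Transcriptome(sequences=tiny_transcriptome.sequences))
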