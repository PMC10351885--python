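import math

import numpy as np
import pytest
from scipy import stats as sps

from oracles import ranksum_exact_oracle
from tribestamp.annotate import (
    AnnotationError,
    TranscriptModel,
    assign_feature,
    compute_read_distribution,
    editing_fraction_stats,
    feature_fold_enrichment,
    iupac_to_regex,
    motif_fraction,
    normalize_per_million,
    read_gtf,
    reverse_complement,
    shift_toward_3prime,
    sites_per_transcript,
    triplet_context,
    write_gtf,
)
from tribestamp.calling import EditingSite, Signature
from tribestamp.countmatrix import matrix_from_rows
from tribestamp.intervals import GenomicInterval

A_G = Signature("A", "G", "+")
T_C = Signature("T", "C", "-")


def site(position, contig="chr1", sig=A_G, frac=0.1):
    return EditingSite(contig, position, sig, 20, 2, frac)


def coding_tx(tid="tx1", contig="chr1", strand="+", exons=((10, 110),),
              cds=(30, 80)):
    return TranscriptModel(tid, f"g_{tid}", contig, strand, list(exons),
                           cds[0], cds[1])


class TestTranscriptModel:
    def test_coordinate_round_trip_plus(self):
        m = coding_tx(exons=((10, 60), (100, 150)), cds=(30, 120))
        assert m.length == 100
        for off in range(m.length):
            assert m.to_transcript_coord(m.from_transcript_coord(off)) == off

    def test_coordinate_round_trip_minus(self):
        m = coding_tx(strand="-", exons=((10, 60), (100, 150)), cds=(30, 120))
        # transcript 5' end is the genomic right-most base
        assert m.from_transcript_coord(0) == 150
        for off in range(m.length):
            assert m.to_transcript_coord(m.from_transcript_coord(off)) == off

    def test_feature_partition_plus(self):
        m = coding_tx(exons=((10, 110),), cds=(30, 80))
        feats = [m.feature_of(p) for p in range(11, 111)]
        assert feats.count("5UTR") == 20
        assert feats.count("CDS") == 50
        assert feats.count("3UTR") == 30

    def test_feature_partition_minus(self):
        m = coding_tx(strand="-", exons=((10, 110),), cds=(30, 80))
        assert m.feature_of(11) == "3UTR"
        assert m.feature_of(109) == "5UTR"
        assert m.feature_of(50) == "CDS"

    def test_partition_exhaustive_invariant(self):
        m = coding_tx(exons=((10, 60), (100, 150)), cds=(30, 120))
        n = sum(1 for s, e in m.exons for p in range(s + 1, e + 1)
                if m.feature_of(p) in ("5UTR", "CDS", "3UTR"))
        assert n == m.length

    def test_noncoding_has_no_feature(self):
        m = TranscriptModel("nc", "g", "chr1", "+", [(10, 110)])
        assert m.feature_of(50) is None

    def test_overlapping_exons_rejected(self):
        with pytest.raises(AnnotationError):
            TranscriptModel("t", "g", "chr1", "+", [(10, 60), (50, 100)])

    def test_cds_outside_span_rejected(self):
        with pytest.raises(AnnotationError):
            coding_tx(exons=((10, 110),), cds=(5, 80))


class TestGtfIO:
    def test_round_trip(self, tmp_path):
        models = [coding_tx(exons=((10, 60), (100, 150)), cds=(30, 120)),
                  coding_tx(tid="tx2", strand="-", contig="chr2")]
        path = tmp_path / "x.gtf"
        write_gtf(models, str(path))
        back = {m.transcript_id: m for m in read_gtf(str(path))}
        for m in models:
            b = back[m.transcript_id]
            assert b.exons == m.exons
            assert (b.cds_start, b.cds_end) == (m.cds_start, m.cds_end)
            assert (b.strand, b.contig, b.gene_id) \
                == (m.strand, m.contig, m.gene_id)

    def test_missing_transcript_id_fails(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text('chr1\tsrc\texon\t1\t10\t.\t+\t.\tgene_id "g";\n')
        with pytest.raises(AnnotationError):
            read_gtf(str(path))


class TestSitesPerTranscript:
    def test_three_sites_one_transcript(self):
        models = [coding_tx()]
        counts, summary = sites_per_transcript(
            [site(20), site(50), site(100)], models)
        assert counts == {"tx1": 3}
        assert summary["mean"] == 3

    def test_intronic_site_not_counted(self):
        m = coding_tx(exons=((10, 60), (100, 150)), cds=(30, 120))
        counts, _ = sites_per_transcript([site(80)], [m])
        assert counts == {}

    def test_empty_annotation_fails(self):
        with pytest.raises(AnnotationError):
            sites_per_transcript([site(1)], [])

    def test_matches_containment_oracle(self):
        rng = np.random.default_rng(30)
        models = [coding_tx(tid=f"tx{i}", contig=f"chr{i % 3}",
                            exons=((s, s + 100),), cds=(s + 20, s + 70))
                  for i, s in enumerate(rng.integers(10, 400, size=12))]
        sites_list = [site(int(p), contig=f"chr{int(c)}")
                      for p, c in zip(rng.integers(1, 600, 200),
                                      rng.integers(0, 3, 200))]
        counts, _ = sites_per_transcript(sites_list, models)
        expected = {}
        for m in models:
            n = sum(1 for s in sites_list
                    if s.contig == m.contig and m.contains(s.position))
            if n:
                expected[m.transcript_id] = n
        assert counts == expected


class TestRankSum:
    def test_identical_multisets_give_one(self):
        out = editing_fraction_stats([0.1, 0.2, 0.2], [0.1, 0.2, 0.2])
        assert out["p_value"] == 1.0
        assert out["method"] == "exact"

    def test_fully_separated_three_vs_three(self):
        out = editing_fraction_stats([0.1, 0.2, 0.3], [0.7, 0.8, 0.9])
        assert out["p_value"] == pytest.approx(0.1)

    def test_agrees_with_enumeration_battery(self):
        rng = np.random.default_rng(31)
        for _ in range(15):
            n, m = rng.integers(2, 7, size=2)
            a = list(np.round(rng.uniform(0, 1, n), 1))  # rounding forces ties
            b = list(np.round(rng.uniform(0, 1, m), 1))
            got = editing_fraction_stats(a, b)["p_value"]
            assert got == pytest.approx(ranksum_exact_oracle(a, b))

    def test_p_decreases_with_effect_size(self):
        rng = np.random.default_rng(32)
        base = rng.normal(0, 1, 10)
        ps = [editing_fraction_stats(base, base + shift)["p_value"]
              for shift in (0.0, 1.0, 3.0)]
        assert ps[0] > ps[1] > ps[2]

    def test_large_samples_use_asymptotic(self):
        rng = np.random.default_rng(33)
        a = rng.normal(0, 1, 50)
        b = rng.normal(1, 1, 50)
        out = editing_fraction_stats(a, b)
        assert out["method"] == "asymptotic"
        ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic").pvalue
        assert out["p_value"] == pytest.approx(float(ref))

    def test_empty_sample_fails(self):
        with pytest.raises(AnnotationError):
            editing_fraction_stats([], [0.1])


class TestTripletContext:
    GENOME = {"chr1": "CCTAGCC"}

    def test_plus_strand_triplet(self):
        profile = triplet_context([site(4)], self.GENOME)  # the A of TAG
        assert profile.fractions == {"TAG": 1.0}

    def test_minus_strand_reverse_complement(self):
        profile = triplet_context([site(4, sig=T_C)], self.GENOME)
        assert profile.fractions == {"CTA": 1.0}

    def test_terminal_site_skipped(self):
        profile = triplet_context([site(1), site(4)], self.GENOME)
        assert profile.n_skipped == 1
        assert profile.fractions == {"TAG": 1.0}

    def test_fractions_sum_to_one(self):
        genome = {"chr1": "ACGTACGTACGTACGT"}
        profile = triplet_context([site(p) for p in range(2, 15)], genome)
        assert sum(profile.fractions.values()) == pytest.approx(1.0)


class TestFeatureEnrichment:
    def test_fold_ratio(self):
        models = [coding_tx(exons=((10, 110),), cds=(30, 80))]
        # 2 sites 3UTR (positions 81..110), 1 CDS, 1 5UTR
        sites_list = [site(90), site(100), site(50), site(20)]
        rd = {"5UTR": 0.25, "CDS": 0.5, "3UTR": 0.25}
        dist = feature_fold_enrichment(sites_list, models, rd)
        assert dist.features["3UTR"].fold_enrichment == pytest.approx(2.0)
        assert sum(fs.site_fraction for fs in dist.features.values()) \
            == pytest.approx(1.0)

    def test_null_case(self):
        models = [coding_tx(exons=((10, 110),), cds=(30, 80))]
        sites_list = ([site(p) for p in range(11, 31)]      # 20 5'UTR
                      + [site(p) for p in range(31, 81)]    # 50 CDS
                      + [site(p) for p in range(81, 111)])  # 30 3'UTR
        rd = {"5UTR": 0.2, "CDS": 0.5, "3UTR": 0.3}
        dist = feature_fold_enrichment(sites_list, models, rd)
        for fs in dist.features.values():
            assert fs.fold_enrichment == pytest.approx(1.0)
            assert fs.p_value == pytest.approx(1.0)

    def test_planted_3utr_enrichment(self):
        models = [coding_tx(exons=((10, 410),), cds=(100, 300))]
        sites_list = [site(p) for p in range(301, 411)]  # all 3'UTR
        rd = {"5UTR": 0.3, "CDS": 0.4, "3UTR": 0.3}
        dist = feature_fold_enrichment(sites_list, models, rd)
        assert dist.features["3UTR"].fold_enrichment > 1
        assert dist.features["3UTR"].p_value < 0.01
        assert dist.features["CDS"].fold_enrichment < 1

    def test_zero_read_fraction_sentinel(self):
        models = [coding_tx(exons=((10, 110),), cds=(30, 80))]
        dist = feature_fold_enrichment([site(90)], models,
                                       {"5UTR": 0.5, "CDS": 0.5, "3UTR": 0.0})
        assert math.isinf(dist.features["3UTR"].fold_enrichment)
        assert dist.features["3UTR"].p_value < 0.05

    def test_bad_read_distribution_fails(self):
        models = [coding_tx()]
        with pytest.raises(AnnotationError):
            feature_fold_enrichment([site(50)], models,
                                    {"5UTR": 0.5, "CDS": 0.1, "3UTR": 0.1})

    def test_tie_priority_3utr_over_cds(self):
        # same position: 3'UTR in tx1, CDS in tx2 -> tie -> 3UTR
        tx1 = coding_tx(tid="t1", exons=((10, 110),), cds=(30, 80))
        tx2 = coding_tx(tid="t2", exons=((10, 110),), cds=(30, 105))
        by = {"chr1": [tx1, tx2]}
        assert assign_feature("chr1", 90, by) == "3UTR"

    def test_read_distribution_from_matrix(self):
        models = [coding_tx(exons=((10, 110),), cds=(30, 80))]
        rows = [("chr1", p, (10, 0, 0, 0)) for p in range(11, 111)]
        rd = compute_read_distribution(matrix_from_rows(rows), models)
        assert rd["5UTR"] == pytest.approx(0.2)
        assert rd["CDS"] == pytest.approx(0.5)
        assert rd["3UTR"] == pytest.approx(0.3)


class TestShift3Prime:
    def test_plus_strand_cds_to_3utr(self):
        m = coding_tx(exons=((10, 410),), cds=(100, 300))
        shifted, n_un = shift_toward_3prime([site(295)], [m], shift=50)
        assert n_un == 0
        assert shifted[0].position == 345
        assert m.feature_of(295) == "CDS" and m.feature_of(345) == "3UTR"

    def test_clamped_at_transcript_end(self):
        m = coding_tx(exons=((10, 110),), cds=(30, 80))
        shifted, _ = shift_toward_3prime([site(105)], [m], shift=50)
        assert shifted[0].position == 110  # last exonic base

    def test_minus_strand_moves_left(self):
        m = coding_tx(strand="-", exons=((10, 410),), cds=(100, 300))
        shifted, _ = shift_toward_3prime([site(200)], [m], shift=50)
        assert shifted[0].position == 150

    def test_crosses_exon_junction(self):
        m = coding_tx(exons=((10, 60), (100, 150)), cds=(30, 120))
        # tpos of genomic 55 is 44; +20 -> tpos 64 -> second exon
        shifted, _ = shift_toward_3prime([site(55)], [m], shift=20)
        assert shifted[0].position == 115

    def test_orphan_site_unshifted_and_flagged(self):
        m = coding_tx()
        shifted, n_un = shift_toward_3prime([site(500)], [m], shift=50)
        assert n_un == 1 and shifted[0].position == 500

    def test_shift_zero_is_identity(self):
        m = coding_tx()
        sites_list = [site(20), site(50), site(100)]
        shifted, _ = shift_toward_3prime(sites_list, [m], shift=0)
        assert [s.position for s in shifted] \
            == [s.position for s in sites_list]


class TestNormalize:
    def test_arithmetic(self):
        assert normalize_per_million(30_000, 15_000_000) == 2000.0
        assert normalize_per_million(0, 10) == 0.0
        assert normalize_per_million(1, 10**6) == 1.0

    def test_nonpositive_reads_fail(self):
        with pytest.raises(AnnotationError):
            normalize_per_million(1, 0)


class TestMotif:
    def test_simple_fraction(self):
        genome = {"r1": "ACGTGTGTGTAC", "r2": "AAAAAAAAAAAA"}
        regions = [GenomicInterval("r1", 0, 12), GenomicInterval("r2", 0, 12)]
        assert motif_fraction(regions, genome, "GTGTGT") == 0.5

    def test_reverse_strand_counted(self):
        genome = {"r1": "TTACACACACTT"}
        regions = [GenomicInterval("r1", 0, 12)]
        assert motif_fraction(regions, genome, "GTGTGT") == 1.0

    def test_planted_fraction_recovered(self):
        rng = np.random.default_rng(34)
        genome, regions = {}, []
        planted = 0
        for i in range(200):
            # A/G background cannot contain GTGTGT on either strand
            seq = list("".join(rng.choice(list("AG"), size=60)))
            if rng.random() < 0.4:
                pos = int(rng.integers(0, 54))
                seq[pos:pos + 6] = "GTGTGT"
                planted += 1
            genome[f"r{i}"] = "".join(seq)
            regions.append(GenomicInterval(f"r{i}", 0, 60))
        assert motif_fraction(regions, genome) \
            == pytest.approx(planted / 200)

    def test_iupac_codes(self):
        assert iupac_to_regex("GKN").fullmatch("GTC")
        with pytest.raises(AnnotationError):
            motif_fraction([], {}, "")
        with pytest.raises(AnnotationError):
            iupac_to_regex("GZ")

    def test_reverse_complement(self):
        assert reverse_complement("ACGTN") == "NACGT"
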