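"""Fragment evidence model: Phred conversions, likelihood curves, BAM extraction."""

import math

import numpy as np
import pandas as pd
import pysam
import pytest

from haploquant.catalog import VariantRecord
from haploquant.evidence import (
    DEFAULT_PI_UNAVAILABLE,
    FragmentObservation,
    allele_likelihoods,
    extract_observations,
    fragment_loglik,
    likelihoods_from_observations,
    map_vaf,
    mapq_to_prob,
    observations_from_table,
    variant_likelihood,
)

SNV = VariantRecord("ref", 3, "G", "T")


def perfect_obs(alt: bool, n: int = 1, j: int = 0):
    la, lr = (0.0, math.log(1e-10)) if alt else (math.log(1e-10), 0.0)
    return [
        FragmentObservation(j, prob_mapped=1.0, loglik_alt=la, loglik_ref=lr)
        for _ in range(n)
    ]


class TestMapqToProb:
    @pytest.mark.parametrize(
        "mapq,expected",
        [(0, 0.0), (10, 0.9), (20, 0.99), (60, 1 - 1e-6)],
    )
    def test_phred_formula(self, mapq, expected):
        assert mapq_to_prob(mapq) == pytest.approx(expected, abs=1e-12)

    def test_unavailable_mapq_uses_default(self):
        assert mapq_to_prob(255) == DEFAULT_PI_UNAVAILABLE
        assert mapq_to_prob(255, unavailable_prob=0.5) == 0.5

    def test_negative_mapq_rejected(self):
        with pytest.raises(ValueError):
            mapq_to_prob(-1)


class TestAlleleLikelihoods:
    def test_alt_base_at_q30(self):
        lr, la = allele_likelihoods("T", 30, SNV)
        assert la == pytest.approx(math.log(0.999))
        assert lr == pytest.approx(math.log(0.001 / 3))

    def test_ref_base_high_quality_limit(self):
        lr, la = allele_likelihoods("G", 200, SNV)
        assert lr == pytest.approx(0.0, abs=1e-12)
        assert la == math.log(1e-10)  # floored, not -inf

    def test_mnv_positions_multiply(self):
        mnv = VariantRecord("ref", 3, "CG", "TA")
        lr, la = allele_likelihoods("TA", 20, mnv)
        assert la == pytest.approx(2 * math.log(0.99))
        assert lr == pytest.approx(2 * math.log(0.01 / 3))

    def test_non_acgt_base_is_uninformative(self):
        lr, la = allele_likelihoods("N", 30, SNV)
        assert lr == la == pytest.approx(math.log(0.25))


class TestFragmentLoglik:
    def test_theta_zero_collapses_to_ref(self):
        obs = FragmentObservation(0, 1.0, loglik_alt=-2.0, loglik_ref=-0.5)
        assert fragment_loglik(obs, 0.0) == pytest.approx(-0.5)

    def test_theta_one_collapses_to_alt(self):
        obs = FragmentObservation(0, 1.0, loglik_alt=-2.0, loglik_ref=-0.5)
        assert fragment_loglik(obs, 1.0) == pytest.approx(-2.0)

    def test_mismapped_fragment_is_flat_in_theta(self):
        obs = FragmentObservation(0, 0.0, loglik_alt=-2.0, loglik_ref=-0.5)
        bg = math.log(0.5 * (math.exp(-2.0) + math.exp(-0.5)))
        for theta in (0.0, 0.3, 1.0):
            assert fragment_loglik(obs, theta) == pytest.approx(bg)

    def test_theta_outside_unit_interval_rejected(self):
        obs = FragmentObservation(0, 1.0, -1.0, -1.0)
        with pytest.raises(ValueError):
            fragment_loglik(obs, 1.5)

    def test_tau_scales_alt_probability(self):
        obs = FragmentObservation(0, 1.0, -1.0, -3.0, tau=0.5)
        direct = math.log(0.5 * math.exp(-1.0) + 0.5 * math.exp(-3.0))
        assert fragment_loglik(obs, 1.0) == pytest.approx(direct)


class TestVariantLikelihood:
    def test_no_observations_gives_flat_zero_curve(self):
        vl = variant_likelihood([])
        assert np.all(vl.values == 0.0)
        assert vl(0.37) == 0.0

    def test_grid_values_match_fragment_sum(self):
        """Curve at grid points equals the direct per-fragment recomputation."""
        rng = np.random.default_rng(11)
        obs = [
            FragmentObservation(
                0,
                prob_mapped=float(rng.uniform(0.1, 1.0)),
                loglik_alt=float(-rng.uniform(0, 5)),
                loglik_ref=float(-rng.uniform(0, 5)),
                tau=float(rng.uniform(0.5, 1.0)),
            )
            for _ in range(30)
        ]
        vl = variant_likelihood(obs)
        for theta in vl.grid[::10]:
            direct = sum(fragment_loglik(o, float(theta)) for o in obs)
            assert vl(float(theta)) == pytest.approx(direct, abs=1e-9)

    def test_single_perfect_alt_fragment_maximised_at_one(self):
        vl = variant_likelihood(perfect_obs(alt=True))
        assert map_vaf(vl) == 1.0

    def test_balanced_fragments_peak_at_half(self):
        vl = variant_likelihood(perfect_obs(True, 10) + perfect_obs(False, 10))
        assert map_vaf(vl) == pytest.approx(0.5)

    def test_mixed_variant_indices_rejected(self):
        with pytest.raises(ValueError):
            variant_likelihood(perfect_obs(True, 1, j=0) + perfect_obs(True, 1, j=1))

    def test_adding_alt_evidence_steepens_curve(self):
        """An extra perfect alt fragment never decreases curve(t2) - curve(t1), t2 > t1."""
        rng = np.random.default_rng(3)
        base = [
            FragmentObservation(
                0,
                prob_mapped=float(rng.uniform(0.2, 1.0)),
                loglik_alt=float(-rng.uniform(0, 4)),
                loglik_ref=float(-rng.uniform(0, 4)),
            )
            for _ in range(20)
        ]
        extra = FragmentObservation(0, 1.0, 0.0, math.log(1e-10))
        before = variant_likelihood(base)
        after = variant_likelihood(base + [extra])
        diff = (after.values - before.values)  # the added fragment's curve
        assert np.all(np.diff(diff) >= -1e-12)


class TestMapVaf:
    def test_flat_curve_ties_break_to_zero(self):
        assert map_vaf(variant_likelihood([])) == 0.0

    def test_pure_alt_fragments(self):
        assert map_vaf(variant_likelihood(perfect_obs(True, 3))) == 1.0


class TestObservationTable:
    def test_calls_map_to_allele_likelihoods(self, carrier_pair_matrix):
        table = pd.DataFrame(
            {
                "variant_index": [0, 0, 0],
                "mapq": [60, 60, 0],
                "allele_call": ["alt", "ref", "other"],
                "base_qual": [30, 30, 30],
            }
        )
        obs = observations_from_table(table, carrier_pair_matrix)
        eps = 1e-3
        assert obs[0].loglik_alt == pytest.approx(math.log(1 - eps))
        assert obs[0].loglik_ref == pytest.approx(math.log(eps / 3))
        assert obs[1].loglik_ref == pytest.approx(math.log(1 - eps))
        assert obs[2].loglik_alt == obs[2].loglik_ref  # 'other' is symmetric
        assert obs[2].prob_mapped == 0.0

    def test_bad_call_and_bad_index_rejected(self, carrier_pair_matrix):
        bad_call = pd.DataFrame(
            {"variant_index": [0], "mapq": [60], "allele_call": ["x"], "base_qual": [30]}
        )
        with pytest.raises(ValueError):
            observations_from_table(bad_call, carrier_pair_matrix)
        bad_idx = bad_call.assign(allele_call=["alt"], variant_index=[5])
        with pytest.raises(ValueError):
            observations_from_table(bad_idx, carrier_pair_matrix)

    def test_likelihoods_align_with_matrix_columns(self, three_hap_matrix):
        table = pd.DataFrame(
            {
                "variant_index": [1, 1],
                "mapq": [60, 60],
                "allele_call": ["alt", "alt"],
                "base_qual": [30, 30],
            }
        )
        obs = observations_from_table(table, three_hap_matrix)
        curves = likelihoods_from_observations(obs, three_hap_matrix)
        assert len(curves) == 2
        assert curves[0].n_fragments == 0 and curves[1].n_fragments == 2
        assert curves[0].variant_index == 0 and curves[1].variant_index == 1


def _make_bam(tmp_path, reference: str, reads):
    """Write an indexed BAM from (name, pos0, cigar, seq, qual, mapq, flag) tuples."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": "ref", "LN": len(reference)}]}
    path = str(tmp_path / "sample.bam")
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for name, pos0, cigar, seq, qual, mapq, flag in sorted(reads, key=lambda r: r[1]):
            a = pysam.AlignedSegment()
            a.query_name = name
            a.query_sequence = seq
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos0
            a.mapping_quality = mapq
            a.cigarstring = cigar
            a.query_qualities = pysam.qualitystring_to_array(qual)
            bam.write(a)
    pysam.index(path)
    return path


class TestExtractObservations:
    REF = "ACGTACGTACGTACGTACGT"

    def test_empty_bam_gives_no_observations(self, tmp_path, carrier_pair_matrix):
        path = _make_bam(tmp_path, self.REF, [])
        assert extract_observations(path, carrier_pair_matrix) == []

    def test_snv_read_composes_mapq_and_base_quality(self, tmp_path, carrier_pair_matrix):
        # carrier_pair_matrix: single SNV A>T at pos 5 (0-based 4)
        seq = "TACGT"  # aligned at pos0=4, alt base T at the variant
        path = _make_bam(
            tmp_path, self.REF, [("r1", 4, "5M", seq, "?" * 5, 60, 0)]
        )  # '?' = Q30
        [obs] = extract_observations(path, carrier_pair_matrix)
        assert obs.prob_mapped == pytest.approx(1 - 1e-6)
        assert obs.loglik_alt == pytest.approx(math.log(0.999))
        assert obs.loglik_ref == pytest.approx(math.log(0.001 / 3))

    def test_read_not_overlapping_contributes_nothing(self, tmp_path, carrier_pair_matrix):
        path = _make_bam(
            tmp_path, self.REF, [("r1", 10, "5M", "GTACG", "?" * 5, 60, 0)]
        )
        assert extract_observations(path, carrier_pair_matrix) == []

    def test_read_pair_merges_into_one_fragment(self, tmp_path, carrier_pair_matrix):
        reads = [
            ("frag", 2, "5M", "GTTCG", "?" * 5, 60, 0x1 | 0x40),
            ("frag", 4, "5M", "TACGT", "?" * 5, 40, 0x1 | 0x80),
        ]
        path = _make_bam(tmp_path, self.REF, reads)
        [obs] = extract_observations(path, carrier_pair_matrix)
        # both mates see the alt base: log-likelihoods add, pi is the weaker mate's
        assert obs.loglik_alt == pytest.approx(2 * math.log(0.999))
        assert obs.prob_mapped == pytest.approx(mapq_to_prob(40))

    def test_deletion_read_skipped_as_ambiguous_at_snv(self, tmp_path, carrier_pair_matrix):
        from haploquant.evidence import ExtractionStats

        stats = ExtractionStats()
        path = _make_bam(
            tmp_path, self.REF, [("r1", 2, "2M1D3M", "GTACG", "?" * 5, 60, 0)]
        )
        out = extract_observations(path, carrier_pair_matrix, stats=stats)
        assert out == []
        assert stats.n_skipped_ambiguous == 1

    def test_insertion_cigar_concordance(self, tmp_path):
        v = VariantRecord("ref", 5, "A", "AGG")
        import numpy as np
        from haploquant.catalog import VariantMatrix

        m = VariantMatrix(["h1"], [v], np.array([[1]]), np.array([[1]]), {"ref": 20})
        reads = [
            ("ins", 2, "3M2I4M", "GTAGGCGTA", "?" * 9, 60, 0),  # has the insertion
            ("noins", 2, "7M", "GTACGTA", "?" * 7, 60, 0),  # spans without it
        ]
        path = _make_bam(tmp_path, self.REF, reads)
        obs = {o.loglik_alt > o.loglik_ref for o in extract_observations(path, m)}
        assert obs == {True, False}

    def test_unindexed_bam_rejected(self, tmp_path, carrier_pair_matrix):
        path = _make_bam(tmp_path, self.REF, [])
        import os

        os.remove(path + ".bai")
        with pytest.raises(ValueError, match="index"):
            extract_observations(path, carrier_pair_matrix)

    def test_reference_name_mismatch_rejected(self, tmp_path, three_hap_matrix):
        # three_hap_matrix variants are on "ref"; build a BAM over "chrX"
        header = {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": "chrX", "LN": 50}]}
        path = str(tmp_path / "other.bam")
        with pysam.AlignmentFile(path, "wb", header=header) as bam:
            pass
        pysam.index(path)
        with pytest.raises(ValueError, match="ref"):
            extract_observations(path, three_hap_matrix)
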