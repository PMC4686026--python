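"""Frequencies, gene diversity, distance matrices and pairwise summaries."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mthaplostat as mh
from mthaplostat.diversity import DiversityError


class TestFrequencies:
    def test_survey_frequencies_and_sd(self, study_counts):
        table = mh.haplotype_frequencies(study_counts["overall"])
        row = dict(zip(table.names, zip(table.frequencies, table.sd)))
        assert row["H9"][0] == pytest.approx(0.3697, abs=5e-5)
        assert row["H9"][1] == pytest.approx(0.0377, abs=5e-5)
        assert row["Z1"][0] == pytest.approx(0.3091, abs=5e-5)
        assert row["Z1"][1] == pytest.approx(0.0361, abs=5e-5)
        assert row["Z3"][1] == pytest.approx(0.0224, abs=5e-5)
        assert table.n == 165 and table.n_haplotypes == 8

    def test_frequencies_sum_to_one(self, study_counts):
        table = mh.haplotype_frequencies(study_counts["overall"])
        assert sum(table.frequencies) == pytest.approx(1.0)

    def test_single_haplotype_degenerate(self):
        table = mh.haplotype_frequencies({"X": 7})
        assert table.frequencies == (1.0,)
        assert table.sd == (0.0,)

    def test_negative_counts_rejected(self):
        with pytest.raises(DiversityError):
            mh.haplotype_frequencies({"X": -1})

    def test_sd_maximal_near_half(self):
        # for fixed n, sqrt(p(1-p)/(n-1)) peaks at p = 0.5
        n = 100
        sds = []
        for k in range(1, n):
            t = mh.haplotype_frequencies({"A": k, "B": n - k})
            sds.append(t.sd[0])
        assert max(range(len(sds)), key=lambda i: sds[i]) == n // 2 - 1


class TestGeneDiversity:
    def test_survey_wide_value(self, study_counts):
        res = mh.gene_diversity(study_counts["overall"])
        assert round(res.h, 4) == 0.7319
        assert round(res.sd, 4) == 0.0174

    def test_regional_pools(self, study_counts):
        values = sorted(
            (round(mh.gene_diversity(c).h, 4), round(mh.gene_diversity(c).sd, 4))
            for c in study_counts["region"].values()
        )
        assert values == [(0.5014, 0.0336), (0.5057, 0.0575)]

    def test_monomorphic_population(self):
        res = mh.gene_diversity({"X": 10})
        assert res.h == 0.0 and res.sd == 0.0

    def test_requires_two_samples(self):
        with pytest.raises(DiversityError):
            mh.gene_diversity({"X": 1})


class TestDistanceMatrix:
    def test_published_single_step_neighbours(self, reference_catalog):
        m = mh.pairwise_difference_matrix(reference_catalog)
        assert m["H11", "Z1"] == 2
        assert m["Z1", "H10"] == 1
        assert m["H9", "Z4"] == 1
        assert m["H9", "Z5"] == 1
        assert m["H9", "H11"] == 3

    def test_identity_mode_is_indicator(self, reference_catalog):
        m = mh.pairwise_difference_matrix(reference_catalog, "identity")
        off_diag = m.values[~np.eye(len(m.names), dtype=bool)]
        assert set(off_diag) == {1.0}

    def test_symmetry_and_triangle_inequality(self, reference_catalog):
        m = mh.pairwise_difference_matrix(reference_catalog)
        v = m.values
        assert np.array_equal(v, v.T)
        k = len(m.names)
        for i, j, l in itertools.combinations(range(k), 3):
            assert v[i, j] <= v[i, l] + v[l, j]

    def test_unknown_mode_rejected(self, reference_catalog):
        with pytest.raises(DiversityError):
            mh.pairwise_difference_matrix(reference_catalog, "euclid")


class TestPairwiseSummaries:
    def test_within_lv_identity(self, study_counts, reference_catalog):
        m = mh.pairwise_difference_matrix(reference_catalog, "identity")
        members = list(study_counts["area"]["LV"].elements())
        value = mh.mean_pairwise_within(members, m)
        assert value == pytest.approx(819 / 1770)
        assert round(value, 2) == 0.46

    def test_within_za_all_distinct(self, study_counts, reference_catalog):
        m = mh.pairwise_difference_matrix(reference_catalog, "identity")
        members = list(study_counts["area"]["ZA"].elements())
        assert mh.mean_pairwise_within(members, m) == pytest.approx(1.0)

    def test_monomorphic_within_is_zero(self, reference_catalog):
        m = mh.pairwise_difference_matrix(reference_catalog, "identity")
        assert mh.mean_pairwise_within(["H9"] * 5, m) == 0.0

    def test_self_distance_is_zero(self, study_counts, reference_catalog):
        m = mh.pairwise_difference_matrix(reference_catalog, "identity")
        pool = list(study_counts["region"]["eastern"].elements())
        assert mh.neis_distance(pool, pool, m) == pytest.approx(0.0)

    def test_fixed_populations_forced_values(self, reference_catalog):
        m = mh.pairwise_difference_matrix(reference_catalog, "identity")
        x, y = ["H9"] * 4, ["Z1"] * 4
        assert mh.mean_pairwise_between(x, y, m) == pytest.approx(1.0)
        assert mh.neis_distance(x, y, m) == pytest.approx(1.0)

    def test_east_west_nei_d_against_brute_force(self, study_counts, reference_catalog):
        m = mh.pairwise_difference_matrix(reference_catalog, "identity")
        east = list(study_counts["region"]["eastern"].elements())
        west = list(study_counts["region"]["western"].elements())
        # brute-force double loop over all sample pairs
        def delta(a, b):
            return 0.0 if a == b else 1.0
        pi_xy = sum(delta(a, b) for a in east for b in west) / (len(east) * len(west))
        pi_x = (
            sum(delta(a, b) for a, b in itertools.combinations(east, 2))
            / math.comb(len(east), 2)
        )
        pi_y = (
            sum(delta(a, b) for a, b in itertools.combinations(west, 2))
            / math.comb(len(west), 2)
        )
        expected = pi_xy - (pi_x + pi_y) / 2
        assert mh.neis_distance(east, west, m) == pytest.approx(expected)

    def test_empty_population_rejected(self, reference_catalog):
        m = mh.pairwise_difference_matrix(reference_catalog, "identity")
        with pytest.raises(DiversityError):
            mh.mean_pairwise_between([], ["H9"], m)


class TestNucleotideDiversity:
    def test_monomorphic_is_zero(self, reference_catalog):
        m = mh.pairwise_difference_matrix(reference_catalog)
        assert mh.nucleotide_diversity(["H9", "H9"], m, 1882) == 0.0

    def test_two_sample_direct_value(self, reference_catalog):
        m = mh.pairwise_difference_matrix(reference_catalog)
        assert mh.nucleotide_diversity(["H11", "Z1"], m, 1882) == pytest.approx(2 / 1882)

    def test_survey_value_against_sequence_brute_force(self, study, study_calls):
        aln, _meta, _cat = study
        assignments, _updated, _ = study_calls
        members = [a.haplotype for a in assignments]
        m = mh.pairwise_difference_matrix(mh.load_reference_catalog())
        value = mh.nucleotide_diversity(members, m, aln.n_columns)
        # brute force over all C(165, 2) sequence pairs
        arr = np.array([list(aln.sequences[s]) for s in aln.ids])
        total = 0
        for i in range(len(arr)):
            total += (arr[i + 1:] != arr[i]).sum()
        expected = total / math.comb(len(arr), 2) / aln.n_columns
        assert value == pytest.approx(expected)

    def test_identity_mode_rejected(self, reference_catalog):
        m = mh.pairwise_difference_matrix(reference_catalog, "identity")
        with pytest.raises(DiversityError):
            mh.nucleotide_diversity(["H9", "Z1"], m, 1882)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    counts=st.lists(st.integers(min_value=0, max_value=40), min_size=2, max_size=8)
    .filter(lambda c: sum(1 for x in c if x > 0) >= 1 and sum(c) >= 2)
)
def test_identity_within_equals_gene_diversity(counts):
    """Mean identity-mode pairwise difference within a pool is exactly the
    unbiased gene diversity h (algebraic identity)."""
    names = [f"h{i}" for i in range(len(counts))]
    tally = {n: c for n, c in zip(names, counts) if c > 0}
    members = [n for n, c in tally.items() for _ in range(c)]
    k = len(tally)
    values = np.ones((k, k)) - np.eye(k)
    matrix = mh.DistanceMatrix(names=tuple(tally), values=values, mode="identity")
    h = mh.gene_diversity(tally).h
    assert mh.mean_pairwise_within(members, matrix) == pytest.approx(h, abs=1e-12)
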