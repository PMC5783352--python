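"""Expressed filtering, TMM, Fisher contrasts and sex-bias classification.

The TMM and Benjamini-Hochberg checks compare the implementation against
independently coded direct-formula oracles; the Fisher check against full
hypergeometric enumeration.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb

from trfbin.errors import DegenerateSampleError, ValidationError
from trfbin.simulate import DEFAULT_SEX_PLAN_TABLE
from trfbin.stats import (
    FEMALE_BIASED,
    INCONSISTENT,
    MALE_BIASED,
    bh_adjust,
    classify_sex_bias,
    filter_expressed,
    fisher_pair,
    pairwise_contrast,
    tmm_factors,
)

# ---------------------------------------------------------------- oracles


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration over the
    support of the 2x2 table with fixed margins."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(k):
        return comb(col1, k) * comb(n - col1, row1 - k) / comb(n, row1)

    lo = max(0, row1 - (n - col1))
    hi = min(row1, col1)
    p_obs = prob(a)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-7))


def bh_oracle(pvals):
    """Benjamini-Hochberg by the sort / p*m/rank / cummin definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def tmm_oracle(df, libs, trim_m=0.30, trim_a=0.05):
    """Direct-formula TMM evaluation, coded independently (sorted-index
    trimming instead of rank filtering, explicit loops)."""
    cols = list(df.columns)
    f75 = []
    for c in cols:
        f75.append(np.quantile(df[c].to_numpy() / libs[c], 0.75))
    f75 = np.array(f75)
    ref_c = cols[int(np.argmin(np.abs(f75 - f75.mean())))]
    factors = []
    for c in cols:
        o = df[c].to_numpy(dtype=float)
        r = df[ref_c].to_numpy(dtype=float)
        use = (o > 0) & (r > 0)
        o, r = o[use], r[use]
        M = np.log2((o / libs[c]) / (r / libs[ref_c]))
        A = 0.5 * (np.log2(o / libs[c]) + np.log2(r / libs[ref_c]))
        if np.max(np.abs(M)) < 1e-6:
            factors.append(1.0)
            continue
        n = len(M)
        lo_m, hi_m = math.floor(n * trim_m) + 1, n - math.floor(n * trim_m)
        lo_a, hi_a = math.floor(n * trim_a) + 1, n - math.floor(n * trim_a)
        # positional trimming through sorted index sets
        keep_m = set(np.argsort(M, kind="mergesort")[lo_m - 1 : hi_m])
        keep_a = set(np.argsort(A, kind="mergesort")[lo_a - 1 : hi_a])
        keep = sorted(keep_m & keep_a)
        num = den = 0.0
        for i in keep:
            v = (libs[c] - o[i]) / (libs[c] * o[i]) + (libs[ref_c] - r[i]) / (
                libs[ref_c] * r[i]
            )
            num += M[i] / v
            den += 1.0 / v
        factors.append(2.0 ** (num / den))
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


# ----------------------------------------------------------------- tests


class TestFilterExpressed:
    @pytest.mark.parametrize(
        "row,kept",
        [
            ([150, 120, 101, 5], True),   # three samples strictly over 100
            ([101, 99, 150, 2], False),   # only two samples strictly over
            ([100, 100, 100, 100], False),  # strict inequality
        ],
    )
    def test_threshold_rule(self, row, kept):
        df = pd.DataFrame([row], index=["b"], columns=list("wxyz"))
        out = filter_expressed(df)
        assert ("b" in out.index) is kept

    def test_all_zero_matrix_empties(self):
        df = pd.DataFrame(0, index=["a", "b"], columns=list("xyz"))
        assert filter_expressed(df).empty

    def test_idempotent(self, small_counts):
        once = filter_expressed(small_counts, min_count=50, min_samples=3)
        twice = filter_expressed(once, min_count=50, min_samples=3)
        assert list(once.counts.index) == list(twice.counts.index)


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        col = np.array([10, 200, 35, 400, 55])
        df = pd.DataFrame({"a": col, "b": col})
        f = tmm_factors(df, pd.Series({"a": 1000, "b": 1000}))
        assert np.allclose(f.factors, [1.0, 1.0])

    def test_doubled_column_symmetric_factors(self):
        col = np.array([10, 200, 35, 400, 55, 90, 120, 60])
        df = pd.DataFrame({"a": col, "b": 2 * col})
        f = tmm_factors(df, pd.Series({"a": 2000, "b": 2000}))
        fa, fb = f.factors
        assert fa * fb == pytest.approx(1.0, abs=1e-12)
        assert fb / fa == pytest.approx(2.0, rel=1e-9)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(5)
        counts = rng.negative_binomial(4, 0.02, size=(50, 5))
        counts[7, 2] *= 12  # one inflated bin
        df = pd.DataFrame(counts, columns=list("abcde"))
        libs = pd.Series(counts.sum(axis=0) + 500, index=df.columns, dtype=float)
        ours = tmm_factors(df, libs).factors
        oracle = tmm_oracle(df, libs)
        assert np.allclose(ours, oracle, atol=1e-9)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(11)
        counts = rng.negative_binomial(4, 0.02, size=(40, 4))
        df = pd.DataFrame(counts, columns=list("abcd"))
        libs = pd.Series(counts.sum(axis=0), index=df.columns, dtype=float)
        base = tmm_factors(df, libs).as_series()
        perm = ["c", "a", "d", "b"]
        permuted = tmm_factors(df[perm], libs[perm]).as_series()
        assert np.allclose(base[perm].to_numpy(), permuted.to_numpy(), atol=1e-12)

    def test_geometric_mean_one(self, small_counts):
        f = tmm_factors(filter_expressed(small_counts, min_count=50))
        assert np.exp(np.mean(np.log(f.factors))) == pytest.approx(1.0, abs=1e-12)

    def test_rescaling_invariance(self):
        """Multiplying one (non-reference) library's counts and size by a
        constant leaves its count fractions unchanged, so the other
        samples' pairwise factors are untouched: their factor ratios are
        exactly preserved, and absolute factors move only through the
        scaled sample's precision weights (sub-percent)."""
        rng = np.random.default_rng(13)
        counts = rng.negative_binomial(4, 0.02, size=(40, 4)).astype(float)
        df = pd.DataFrame(counts, columns=list("abcd"))
        libs = pd.Series(counts.sum(axis=0), index=df.columns, dtype=float)
        base = tmm_factors(df, libs)
        assert base.reference_sample != "a"
        scaled = df.copy()
        scaled["a"] *= 7.0
        libs2 = libs.copy()
        libs2["a"] *= 7.0
        after = tmm_factors(scaled, libs2)
        fa, fb = base.as_series(), after.as_series()
        for x in "bcd":
            for y in "bcd":
                assert fa[x] / fa[y] == pytest.approx(fb[x] / fb[y], abs=1e-12)
        assert np.allclose(fa.to_numpy(), fb.to_numpy(), atol=0.01)

    def test_degenerate_sample_raises(self):
        df = pd.DataFrame({"a": [5, 0, 7], "b": [0, 9, 0]})
        with pytest.raises(DegenerateSampleError):
            tmm_factors(df, pd.Series({"a": 100, "b": 100}))


class TestFisher:
    def test_example_table_matches_enumeration(self):
        assert fisher_pair(3, 4, 1, 4) == pytest.approx(
            fisher_two_sided_oracle(3, 1, 1, 3), abs=1e-9
        )
        assert fisher_pair(3, 4, 1, 4) == pytest.approx(0.485714285, abs=1e-6)

    @pytest.mark.parametrize("ca,la,cb,lb", [(10, 100, 10, 100), (0, 100, 0, 100)])
    def test_equal_proportions_p_one(self, ca, la, cb, lb):
        assert fisher_pair(ca, la, cb, lb) == pytest.approx(1.0)

    def test_zero_library_rejected(self):
        with pytest.raises(ValidationError):
            fisher_pair(0, 0, 1, 10)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12))
    def test_matches_enumeration_and_symmetry(self, a, b, c, d):
        la, lb = a + b, c + d
        if la == 0 or lb == 0:
            return
        p = fisher_pair(a, la, c, lb)
        assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), rel=1e-9, abs=1e-12)
        assert p == pytest.approx(fisher_pair(c, lb, a, la), rel=1e-12)

    def test_p_decreases_with_imbalance_at_fixed_margins(self):
        # support of tables with margins row=20/col=20, n=40
        ps = [fisher_pair(k, 20, 20 - k, 20) for k in range(10, 21)]
        assert all(ps[i + 1] <= ps[i] + 1e-12 for i in range(len(ps) - 1))


class TestBh:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_matches_hand_rolled_oracle(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=20)
        assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)
        assert (bh_adjust(p) >= p - 1e-12).all()


class TestPairwiseContrast:
    def _cm(self):
        rng = np.random.default_rng(3)
        counts = rng.negative_binomial(4, 0.01, size=(20, 6))
        return pd.DataFrame(counts, columns=[f"s{i}" for i in range(6)])

    def test_identical_pooled_fractions_unchanged(self):
        df = pd.DataFrame({"a1": [50], "a2": [50], "b1": [50], "b2": [50]}, index=["x"])
        (r,) = pairwise_contrast(df, None, ["a1", "a2"], ["b1", "b2"])
        assert r.p_value == pytest.approx(1.0)
        assert r.direction == "unchanged"

    def test_single_bin_q_equals_p(self):
        df = pd.DataFrame({"a": [40], "b": [400]}, index=["x"])
        (r,) = pairwise_contrast(df, None, ["a"], ["b"])
        assert r.q_value == pytest.approx(r.p_value)

    def test_q_values_match_oracle(self):
        df = self._cm()
        res = pairwise_contrast(df, None, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        p = np.array([r.p_value for r in res])
        q = np.array([r.q_value for r in res])
        assert np.allclose(q, bh_oracle(p), atol=1e-12)

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            pairwise_contrast(self._cm(), None, ["s0", "s1"], ["s1", "s2"])

    def test_direction_tracks_sign_of_log2fc(self):
        df = pd.DataFrame({"a": [900, 10], "b": [10, 900]}, index=["x", "y"])
        res = pairwise_contrast(df, None, ["a"], ["b"])
        assert res[0].direction == "up_in_a" and res[0].log2fc > 0
        assert res[1].direction == "up_in_b" and res[1].log2fc < 0


def _table2_fixture(multipliers=(0.8, 0.9, 1.0, 1.1, 1.2)):
    """Per-strain counts whose means equal the printed sex-bias table and
    whose per-strain orderings match the printed bias direction."""
    mult = np.asarray(multipliers)
    mult = mult / mult.mean()
    strains = [f"strain{i}" for i in range(1, 6)]
    cols, meta_rows = {}, []
    for i, s in enumerate(strains):
        cols[f"F_{s}"] = [mf * mult[i] for _, mf, _ in DEFAULT_SEX_PLAN_TABLE]
        cols[f"M_{s}"] = [mm * mult[i] for _, _, mm in DEFAULT_SEX_PLAN_TABLE]
        meta_rows += [
            {"sample_id": f"F_{s}", "sex": "female", "strain": s},
            {"sample_id": f"M_{s}", "sex": "male", "strain": s},
        ]
    index = [f"tRF{i:02d}:{label}" for i, (label, _, _) in enumerate(DEFAULT_SEX_PLAN_TABLE)]
    counts = pd.DataFrame(cols, index=index)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return counts, meta


class TestClassifySexBias:
    def test_published_pattern_recovered(self):
        counts, meta = _table2_fixture()
        out = classify_sex_bias(counts, meta)
        assert (out["label"] == FEMALE_BIASED).sum() == 4
        assert (out["label"] == MALE_BIASED).sum() == 12
        top = out.iloc[0]
        assert top["label"] == FEMALE_BIASED
        assert top["mean_female"] == pytest.approx(17334.6)
        assert top["mean_male"] == pytest.approx(10792.4)

    def test_equal_counts_in_one_strain_inconsistent(self):
        counts, meta = _table2_fixture()
        counts.loc[counts.index[0], "M_strain3"] = counts.loc[
            counts.index[0], "F_strain3"
        ]
        out = classify_sex_bias(counts, meta)
        assert out.iloc[0]["label"] == INCONSISTENT

    def test_invariant_to_per_strain_scaling(self):
        counts, meta = _table2_fixture()
        base = classify_sex_bias(counts, meta)["label"]
        scaled = counts.copy()
        for i, s in enumerate([f"strain{i}" for i in range(1, 6)]):
            scaled[[f"F_{s}", f"M_{s}"]] *= 1.5 + i
        assert (classify_sex_bias(scaled, meta)["label"] == base).all()

    def test_missing_sex_rejected(self):
        counts, meta = _table2_fixture()
        with pytest.raises(ValidationError, match="strain"):
            classify_sex_bias(counts.drop(columns=["M_strain2"]), meta.drop(index=["M_strain2"]))


class TestWindowSweep:
    def test_single_size_one_row(self, small_genome, small_reads, small_counts):
        from trfbin.annotation import filter_trnas
        from trfbin.counting import exact_match_map
        from trfbin.stats import window_sweep

        sources = {
            sid: exact_match_map(reads, small_genome.reference).records
            for sid, reads in small_reads.samples.items()
        }
        genes = filter_trnas(small_genome.genes)
        table, best = window_sweep(
            sources,
            genes,
            small_genome.structures,
            [s for s in sources if s.startswith("female")],
            [s for s in sources if s.startswith("male")],
            available_flanks=small_genome.available_flanks,
            sizes=[15],
        )
        assert len(table) == 1 and best == 15
        assert table.loc[0, "n_significant"] > 0

    def test_zero_reads_reports_smallest_size(self, small_genome):
        from trfbin.annotation import filter_trnas
        from trfbin.stats import window_sweep

        sources = {"a_1": [], "a_2": [], "b_1": [], "b_2": []}
        table, best = window_sweep(
            sources,
            filter_trnas(small_genome.genes),
            small_genome.structures,
            ["a_1", "a_2"],
            ["b_1", "b_2"],
            available_flanks=small_genome.available_flanks,
            sizes=[20, 15, 25],
        )
        assert (table["n_expressed"] == 0).all() and (table["n_significant"] == 0).all()
        assert best == 15
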