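"""TPM normalization, NB Wald bias tests, categories, dynamics, transitions."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from allelekit import ase
from allelekit.ase import (
    BiasCall,
    build_profiles,
    classify_bias,
    compute_tpm,
    filter_expressed,
    nb_wald_test,
    rank_dynamic_stable,
    size_factors,
    transition_summary,
)
from allelekit.ase import test_allelic_bias as run_bias_tests
from allelekit.pairing import AllelePair


class TestTpm:
    def test_single_gene_is_one_million(self):
        counts = pd.DataFrame({"s1": [7]}, index=["g1"])
        tpm = compute_tpm(counts, pd.Series({"g1": 500}))
        assert tpm.loc["g1", "s1"] == pytest.approx(1e6)

    def test_hand_arithmetic_two_genes(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["g1", "g2"])
        tpm = compute_tpm(counts, pd.Series({"g1": 1000, "g2": 2000}))
        assert tpm.loc["g1", "s1"] == pytest.approx(666666.67, abs=0.01)
        assert tpm.loc["g2", "s1"] == pytest.approx(333333.33, abs=0.01)

    def test_columns_sum_to_one_million(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 1000, size=(50, 4)),
            index=[f"g{i}" for i in range(50)],
            columns=list("abcd"),
        )
        lengths = pd.Series(rng.integers(200, 5000, size=50), index=counts.index)
        tpm = compute_tpm(counts, lengths)
        assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_all_zero_sample_warns(self):
        counts = pd.DataFrame({"s1": [0, 0], "s2": [5, 5]}, index=["g1", "g2"])
        with pytest.warns(UserWarning, match="all-zero"):
            tpm = compute_tpm(counts, pd.Series({"g1": 100, "g2": 100}))
        assert (tpm["s1"] == 0).all()

    def test_nonpositive_length_rejected(self):
        counts = pd.DataFrame({"s1": [1]}, index=["g1"])
        with pytest.raises(ValueError):
            compute_tpm(counts, pd.Series({"g1": 0}))


class TestFilterExpressed:
    def _tpm(self, values):
        return pd.DataFrame({"s1": values}, index=[f"g{i}" for i in range(len(values))])

    def test_above_threshold_expressed(self):
        assert "g0" in filter_expressed(self._tpm([0.6]))

    def test_exactly_at_threshold_not_expressed(self):
        assert "g0" not in filter_expressed(self._tpm([0.5]))

    def test_all_zero_not_expressed(self):
        assert len(filter_expressed(self._tpm([0.0]))) == 0

    def test_one_sample_suffices(self):
        tpm = pd.DataFrame({"s1": [0.0], "s2": [0.7]}, index=["g0"])
        assert "g0" in filter_expressed(tpm)


class TestNbWald:
    def test_identical_vectors_null(self):
        log2fc, p = nb_wald_test(np.array([5, 6, 7.0]), np.array([5, 6, 7.0]), 0.05)
        assert log2fc == 0.0
        assert p == 1.0

    def test_fewer_than_two_replicates_rejected(self):
        with pytest.raises(ValueError):
            nb_wald_test(np.array([5.0]), np.array([5.0, 6.0]), 0.05)

    def test_label_swap_negates_log2fc(self):
        a = np.array([100.0, 120, 90, 110])
        b = np.array([20.0, 25, 18, 22])
        fc_ab, p_ab = nb_wald_test(a, b, 0.05)
        fc_ba, p_ba = nb_wald_test(b, a, 0.05)
        assert fc_ab == pytest.approx(-fc_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_type_i_error_calibrated(self):
        """Planted-null pairs: raw p < 0.05 fraction ~= 0.05 (3 binomial se)."""
        rng = np.random.default_rng(0)
        n = 4000
        alpha = 0.05
        rejections = 0
        for _ in range(n):
            mean = float(np.exp(rng.normal(5.5, 0.5)))
            npar = 1 / alpha
            pp = npar / (npar + mean)
            a = rng.negative_binomial(npar, pp, 4).astype(float)
            b = rng.negative_binomial(npar, pp, 4).astype(float)
            _, p = nb_wald_test(a, b, alpha)
            rejections += p < 0.05
        se = np.sqrt(0.05 * 0.95 / n)
        assert rejections / n <= 0.05 + 3 * se

    def test_fold_change_recovery(self):
        """Planted FC=10, dispersion 0.05, 4 reps: median |log2fc| within
        +-0.3 of log2(10)."""
        rng = np.random.default_rng(1)
        estimates = []
        for _ in range(500):
            base = float(np.exp(rng.normal(6, 0.5)))
            npar = 1 / 0.05
            a = rng.negative_binomial(npar, npar / (npar + base * 10), 4).astype(float)
            b = rng.negative_binomial(npar, npar / (npar + base), 4).astype(float)
            fc, _ = nb_wald_test(a, b, 0.05)
            estimates.append(abs(fc))
        assert np.median(estimates) == pytest.approx(np.log2(10), abs=0.3)


class TestClassifyBias:
    def test_not_significant_none(self):
        assert classify_bias(0.0, 0.8) == "none"

    def test_fc3_larger(self):
        assert classify_bias(np.log2(3), 0.01) == "larger"

    def test_fc10_largest(self):
        assert classify_bias(np.log2(10), 0.001) == "largest"

    def test_boundaries(self):
        assert classify_bias(1.0, 0.01) == "smaller"  # FC = 2 -> smaller
        assert classify_bias(3.0, 0.01) == "largest"  # FC = 8 -> largest
        assert classify_bias(-3.0, 0.01) == "largest"  # sign-symmetric

    def test_alpha_boundary(self):
        assert classify_bias(5.0, 0.05) == "none"  # p_adj >= 0.05


class TestSizeFactors:
    def test_equal_libraries_unit_factors(self):
        counts = pd.DataFrame(
            {"s1": [10, 20, 30], "s2": [10, 20, 30]}, index=list("abc")
        )
        assert size_factors(counts).values == pytest.approx([1.0, 1.0])

    def test_doubled_library_factor_two(self):
        counts = pd.DataFrame(
            {"s1": [10, 20, 30], "s2": [20, 40, 60]}, index=list("abc")
        )
        sf = size_factors(counts)
        assert sf["s2"] / sf["s1"] == pytest.approx(2.0)


def _make_calls(vectors: dict[str, dict[str, tuple[float, float]]]) -> list[BiasCall]:
    calls = []
    for locus, per_tissue in vectors.items():
        for tissue, (log2fc, p_adj) in per_tissue.items():
            calls.append(
                BiasCall(
                    locus_id=locus,
                    tissue=tissue,
                    log2fc=log2fc,
                    p=p_adj,
                    p_adj=p_adj,
                    category=classify_bias(log2fc, p_adj),
                )
            )
    return calls


class TestProfilesAndRanking:
    def test_nonsignificant_masked_to_zero(self):
        calls = _make_calls({"L1": {"t1": (2.0, 0.5), "t2": (1.0, 0.01)}})
        profiles = build_profiles(calls, ["t1", "t2"])
        assert profiles[0].effective_log2fc == {"t1": 0.0, "t2": 1.0}
        assert profiles[0].fc_range == pytest.approx(1.0)

    def test_all_null_profile_zero_range(self):
        calls = _make_calls({"L1": {"t1": (2.0, 0.9), "t2": (-1.0, 0.9)}})
        profiles = build_profiles(calls, ["t1", "t2"])
        assert profiles[0].fc_range == 0.0

    def test_exact_ten_percent_labeled(self):
        vectors = {
            f"L{i:03d}": {"t1": (i * 0.1, 0.001), "t2": (0.0, 0.9)}
            for i in range(100)
        }
        profiles = rank_dynamic_stable(build_profiles(_make_calls(vectors), ["t1", "t2"]))
        assert sum(p.label == "dynamic" for p in profiles) == 10
        assert sum(p.label == "stable" for p in profiles) == 10

    def test_permutation_invariance(self):
        vectors = {
            f"L{i:03d}": {"t1": (i * 0.05, 0.001)} for i in range(40)
        }
        calls = _make_calls(vectors)
        labels1 = {
            p.locus_id: p.label
            for p in rank_dynamic_stable(build_profiles(calls, ["t1"]))
        }
        labels2 = {
            p.locus_id: p.label
            for p in rank_dynamic_stable(build_profiles(calls[::-1], ["t1"]))
        }
        assert labels1 == labels2

    def test_too_few_loci_withheld(self):
        calls = _make_calls({"L1": {"t1": (1.0, 0.01)}})
        with pytest.warns(UserWarning, match="withheld"):
            profiles = rank_dynamic_stable(build_profiles(calls, ["t1"]))
        assert profiles[0].label == "neither"


class TestTransitions:
    def test_neighboring(self):
        calls = _make_calls(
            {"L1": {"t1": (0.5, 0.01), "t2": (1.5, 0.01)}}  # smaller -> larger
        )
        summary = transition_summary(calls, ["t1", "t2"])
        assert summary["per_locus"]["L1"] == "neighboring"

    def test_jumping(self):
        calls = _make_calls(
            {"L1": {"t1": (0.5, 0.01), "t2": (4.0, 0.01)}}  # smaller -> largest
        )
        summary = transition_summary(calls, ["t1", "t2"])
        assert summary["per_locus"]["L1"] == "jumping"

    def test_constant_category_none(self):
        calls = _make_calls({"L1": {"t1": (1.5, 0.01), "t2": (1.6, 0.01)}})
        summary = transition_summary(calls, ["t1", "t2"])
        assert summary["per_locus"]["L1"] == "none"

    def test_none_categories_ignored(self):
        calls = _make_calls({"L1": {"t1": (0.5, 0.01), "t2": (4.0, 0.9)}})
        summary = transition_summary(calls, ["t1", "t2"])
        assert summary["per_locus"]["L1"] == "none"

    def test_counts_per_tissue_pair(self):
        calls = _make_calls(
            {
                "L1": {"t1": (0.5, 0.01), "t2": (1.5, 0.01)},
                "L2": {"t1": (0.5, 0.01), "t2": (4.0, 0.01)},
            }
        )
        summary = transition_summary(calls, ["t1", "t2"])
        assert summary["per_tissue_pair"]["t1|t2"] == {
            "neighboring": 1,
            "jumping": 1,
        }


class TestEndToEnd:
    def test_categories_partition_and_proportions(self, small_dataset):
        truth = small_dataset["truth"]
        counts = small_dataset["counts"]
        pairs = [
            AllelePair(f"L{i:04d}", a, b, 0)
            for i, (a, b) in enumerate(truth.allele_pairs)
        ]
        calls = run_bias_tests(
            counts, pairs, small_dataset["sample_tissue"], include_global=False
        )
        frame = ase.calls_to_frame(calls)
        for _, sub in frame.groupby("tissue"):
            fractions = sub["category"].value_counts(normalize=True)
            assert fractions.sum() == pytest.approx(1.0)

    def test_bh_applied_within_tissue(self, small_dataset):
        truth = small_dataset["truth"]
        counts = small_dataset["counts"]
        pairs = [
            AllelePair(f"L{i:04d}", a, b, 0)
            for i, (a, b) in enumerate(truth.allele_pairs)
        ]
        calls = run_bias_tests(
            counts, pairs, small_dataset["sample_tissue"], include_global=False
        )
        frame = ase.calls_to_frame(calls)
        for _, sub in frame.groupby("tissue"):
            sub = sub.sort_values("p")
            assert (sub["p_adj"].values >= sub["p"].values - 1e-12).all()

    def test_swap_alleles_flips_sign_only(self, small_dataset):
        truth = small_dataset["truth"]
        counts = small_dataset["counts"]
        pairs = [
            AllelePair(f"L{i:04d}", a, b, 0)
            for i, (a, b) in enumerate(truth.allele_pairs[:20])
        ]
        swapped = [AllelePair(p.locus_id, p.gene_b, p.gene_a, 0) for p in pairs]
        st = small_dataset["sample_tissue"]
        calls = run_bias_tests(counts, pairs, st, include_global=False)
        calls_swapped = run_bias_tests(counts, swapped, st, include_global=False)
        for c1, c2 in zip(calls, calls_swapped):
            assert c1.log2fc == pytest.approx(-c2.log2fc)
            assert c1.p == pytest.approx(c2.p)
            assert c1.category == c2.category
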