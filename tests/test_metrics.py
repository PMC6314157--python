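"""Accuracy metrics: dosage R², IQS, concordance, binning, window LD."""

import math

import numpy as np
import pandas as pd
import pytest

from pedimpute.metrics import (
    MafBinning,
    best_guess_iqs,
    concordance_rate,
    dosage_r2,
    iqs,
    mean_window_ld,
    summarize_by_bin,
)


def one_hot(calls):
    calls = np.asarray(calls)
    P = np.zeros((calls.size, 3))
    P[np.arange(calls.size), calls] = 1.0
    return P


class TestDosageR2:
    def test_perfect_imputation(self):
        assert dosage_r2([0, 1, 2, 1], [0, 1, 2, 1]) == pytest.approx(1.0)

    def test_constant_vector_undefined(self):
        assert math.isnan(dosage_r2([0, 1, 2], [1, 1, 1]))
        assert math.isnan(dosage_r2([1, 1, 1], [0, 1, 2]))

    def test_hand_value(self):
        # cov = 1.5/n, var_t = 2/n, var_d = 1.18/n  ->  r^2 = 2.25/2.36
        got = dosage_r2([0, 1, 2, 1], [0.2, 0.9, 1.7, 1.2])
        assert got == pytest.approx(2.25 / 2.36, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dosage_r2([0, 1], [0, 1, 2])

    def test_affine_invariance(self, rng):
        t = rng.integers(0, 3, 50).astype(float)
        d = np.clip(t + rng.normal(0, 0.4, 50), 0, 2)
        base = dosage_r2(t, d)
        # count scale vs fraction scale (and any affine map)
        assert dosage_r2(t / 2, d / 2) == pytest.approx(base, rel=1e-12)
        assert dosage_r2(t, 0.31 * d + 1.7) == pytest.approx(base, rel=1e-12)


class TestIQS:
    def test_perfect_hard_calls(self):
        truth = np.array([0, 1, 2, 1, 0])
        assert iqs(truth, one_hot(truth)) == pytest.approx(1.0)

    def test_marginal_posteriors_give_zero(self):
        truth = np.array([0, 0, 0, 1, 1, 2, 0, 1, 0, 2])
        marg = np.bincount(truth, minlength=3) / truth.size
        P = np.tile(marg, (truth.size, 1))
        assert iqs(truth, P) == pytest.approx(0.0, abs=1e-12)

    def test_constant_call_gives_exactly_zero(self):
        # a constant prediction has Po = Pc, so chance correction zeroes it
        truth = np.array([0, 0, 0, 2])
        assert iqs(truth, one_hot([0, 0, 0, 0])) == pytest.approx(0.0, abs=1e-12)

    def test_negative_hand_value(self):
        # Po = 1/4, Pc = 7/16  ->  IQS = (4 - 7) / (16 - 7) = -1/3
        truth = np.array([0, 0, 1, 2])
        assert iqs(truth, one_hot([1, 0, 0, 0])) == pytest.approx(-1 / 3)

    def test_monomorphic_agreement_undefined(self):
        truth = np.zeros(5, dtype=int)
        assert math.isnan(iqs(truth, one_hot([0] * 5)))

    def test_bounded_above_by_one(self, rng):
        for _ in range(20):
            truth = rng.integers(0, 3, 30)
            P = rng.dirichlet(np.ones(3), size=30)
            v = iqs(truth, P)
            assert math.isnan(v) or v <= 1.0 + 1e-12

    def test_invalid_posterior_rejected(self):
        with pytest.raises(ValueError):
            iqs(np.array([0, 1]), np.array([[0.5, 0.2, 0.1], [1, 0, 0]]))

    def test_hard_call_iqs_matches_cohen_kappa(self, rng):
        from sklearn.metrics import cohen_kappa_score

        for _ in range(20):
            truth = rng.integers(0, 3, 40)
            calls = rng.integers(0, 3, 40)
            if len(set(truth)) == 1 and set(truth) == set(calls):
                continue
            ours = best_guess_iqs(truth, one_hot(calls))
            ref = cohen_kappa_score(calls, truth, labels=[0, 1, 2])
            if math.isnan(ours):
                assert math.isnan(ref) or ref == 0
            else:
                assert ours == pytest.approx(ref, abs=1e-10)


class TestConcordance:
    def test_perfect(self):
        truth = np.array([0, 1, 2])
        assert concordance_rate(truth, one_hot(truth)) == 1.0

    def test_major_call_on_rare_truth(self, rng):
        # HWE truth at MAF 0.01, constant major-homozygote call
        p = 0.01
        g = rng.choice([0, 1, 2], size=20_000,
                       p=[(1 - p) ** 2, 2 * p * (1 - p), p**2])
        cr = concordance_rate(g, one_hot(np.zeros_like(g)))
        assert cr == pytest.approx((1 - p) ** 2, abs=0.005)

    def test_ties_break_to_smaller_genotype(self):
        P = np.array([[0.4, 0.4, 0.2]])
        assert concordance_rate(np.array([0]), P) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            concordance_rate(np.array([], dtype=int), np.zeros((0, 3)))


class TestBinning:
    def test_default_edges_partition(self):
        b = MafBinning()
        assert b.assign(np.array([0.005]))[0] == 0
        assert b.assign(np.array([0.01]))[0] == 1   # [0.01, 0.05)
        assert b.assign(np.array([0.5]))[0] == 6    # closed top bin
        assert b.assign(np.array([0.0]))[0] == -1
        assert b.assign(np.array([0.6]))[0] == -1
        assert len(b.labels) == 7

    def test_summaries_hand_averaged(self):
        df = pd.DataFrame({
            "snp_id": [f"s{i}" for i in range(6)],
            "maf": [0.005, 0.005, 0.02, 0.02, 0.45, 0.45],
            "r2": [0.2, 0.4, 0.6, np.nan, 1.0, 0.5],
            "iqs": [0.1, 0.1, np.nan, np.nan, 0.9, 0.7],
        })
        out = summarize_by_bin(df, metrics=("r2", "iqs"))
        row0 = out[out["bin"] == "(0,0.01)"].iloc[0]
        assert row0["mean_r2"] == pytest.approx(0.3)
        row1 = out[out["bin"] == "[0.01,0.05)"].iloc[0]
        assert row1["mean_r2"] == pytest.approx(0.6)
        assert row1["n_undefined_r2"] == 1
        assert math.isnan(row1["mean_iqs"])
        assert row1["n_undefined_iqs"] == 2
        row6 = out[out["bin"] == "[0.4,0.5]"].iloc[0]
        assert row6["mean_iqs"] == pytest.approx(0.8)

    def test_empty_bin_reported_empty_not_zero(self):
        df = pd.DataFrame({"snp_id": ["a"], "maf": [0.25], "r2": [0.5],
                           "iqs": [0.4]})
        out = summarize_by_bin(df)
        empty = out[out["bin"] == "[0.3,0.4)"].iloc[0]
        assert empty["n_snps"] == 0 and math.isnan(empty["mean_r2"])


class TestWindowLD:
    def test_duplicated_columns_give_one(self, rng):
        col = (rng.random(50) < 0.4).astype(float)
        H = np.tile(col[:, None], (1, 4))
        H[0, :] = 1 - H[0, :]  # keep polymorphic, still perfectly correlated
        assert mean_window_ld(H, window=4) == pytest.approx(1.0)

    def test_independent_sites_null(self, rng):
        H = (rng.random((400, 200)) < 0.3).astype(float)
        got = mean_window_ld(H, window=100)
        assert got == pytest.approx(1 / 399, rel=0.4)

    def test_window_larger_than_sites_rejected(self, rng):
        with pytest.raises(ValueError):
            mean_window_ld(np.zeros((10, 5)), window=6)
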