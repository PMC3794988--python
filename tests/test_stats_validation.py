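import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lncprofile.stats_validation import (
    ValidationError,
    ddct_fold_change,
    fisher_enrichment,
    signed_fc_from_ratio,
    spearman_rho,
)
from tests.oracles import brute_force_hypergeom_tail


def _qpcr(rows):
    return pd.DataFrame(
        rows, columns=["target_id", "sample_id", "group", "ct_target", "ct_reference"]
    )


class TestDdct:
    def test_identical_ct_gives_one(self):
        df = _qpcr(
            [("t", f"{g}{i}", g, 20.0, 15.0) for g in "NA" for i in range(3)]
        )
        assert ddct_fold_change(df, "t", "A", "N") == pytest.approx(1.0)

    def test_closed_form(self):
        # dCt_test = 5, dCt_ref = 10 -> ddCt = -5 -> 2^5 = 32
        df = _qpcr(
            [("t", "A1", "A", 20.0, 15.0), ("t", "N1", "N", 25.0, 15.0)]
        )
        assert ddct_fold_change(df, "t", "A", "N") == pytest.approx(32.0)

    def test_invariant_to_uniform_reference_shift(self):
        rng = np.random.default_rng(0)
        rows = [
            ("t", f"{g}{i}", g, float(rng.uniform(18, 28)), float(rng.uniform(14, 16)))
            for g in "NA" for i in range(3)
        ]
        df = _qpcr(rows)
        shifted = df.copy()
        shifted["ct_reference"] += 3.7
        assert ddct_fold_change(df, "t", "A", "N") == pytest.approx(
            ddct_fold_change(shifted, "t", "A", "N")
        )

    def test_missing_group_errors(self):
        df = _qpcr([("t", "A1", "A", 20.0, 15.0)])
        with pytest.raises(ValidationError):
            ddct_fold_change(df, "t", "A", "N")

    def test_planted_qpcr_ratios_recovered(self, dataset):
        ds = dataset
        for target in ds.qpcr["target_id"].unique():
            ratio = ddct_fold_change(ds.qpcr, target, "A", "N")
            fc = signed_fc_from_ratio(ratio)
            planted = ds.truth.loc[target, "planted_fold_change"]
            assert fc == pytest.approx(planted, rel=0.15)
            assert np.sign(fc) == np.sign(planted)


class TestSignedRatio:
    @pytest.mark.parametrize("r, expected", [(32, 32.0), (0.25, -4.0), (1, 1.0)])
    def test_examples(self, r, expected):
        assert signed_fc_from_ratio(r) == pytest.approx(expected)

    def test_non_positive_rejected(self):
        with pytest.raises(ValidationError):
            signed_fc_from_ratio(0.0)


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = [1.0, 2.5, 7.0, 9.0, 20.0]
        rho, _ = spearman_rho(x, [v**3 for v in x])
        assert rho == pytest.approx(1.0)

    def test_reversed_gives_minus_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        rho, _ = spearman_rho(x, x[::-1])
        assert rho == pytest.approx(-1.0)

    def test_agrees_with_closed_form_on_tie_free_data(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(4, 15))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            rho, _ = spearman_rho(x, y)
            rx, ry = sps.rankdata(x), sps.rankdata(y)
            d2 = ((rx - ry) ** 2).sum()
            closed = 1 - 6 * d2 / (n * (n**2 - 1))
            assert rho == pytest.approx(closed, abs=1e-12)

    def test_rho_matches_scipy_with_ties(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 7.0]
        y = [2.0, 1.0, 4.0, 4.0, 6.0, 8.0, 8.0]
        rho, _ = spearman_rho(x, y)
        assert rho == pytest.approx(sps.spearmanr(x, y).statistic, abs=1e-12)

    def test_exact_permutation_p_for_perfect_rank_agreement(self):
        # n=5: only 2 of 120 orderings reach |rho| = 1 -> p = 1/60
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        _, p = spearman_rho(x, [10.0, 20.0, 30.0, 40.0, 50.0])
        assert p == pytest.approx(2 / 120)

    def test_constant_vector_sentinel(self):
        rho, p = spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(rho) and np.isnan(p)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        y = x + rng.normal(scale=0.5, size=40)
        rho, p = spearman_rho(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestFisherEnrichment:
    def test_hand_example_two_of_two(self):
        term_map = {"g1": ["T"], "g2": ["T"], "g3": [], "g4": []}
        res = fisher_enrichment(["g1", "g2"], ["g1", "g2", "g3", "g4"], term_map)
        assert len(res) == 1
        assert res[0].p_fisher == pytest.approx(1 / 6)

    def test_zero_study_hits_gives_p_one(self):
        term_map = {"g1": ["T"], "g2": [], "g3": []}
        res = fisher_enrichment(["g2"], ["g1", "g2", "g3"], term_map)
        assert res[0].k == 0
        assert res[0].p_fisher == pytest.approx(1.0)

    def test_study_outside_background_rejected(self):
        with pytest.raises(ValidationError, match="gX"):
            fisher_enrichment(["gX"], ["g1"], {})

    def test_adjusted_p_matches_hand_step_up_rule(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(20)]
        term_map = {
            g: [f"T{j}" for j in range(6) if rng.random() < 0.35] for g in genes
        }
        res = fisher_enrichment(genes[:8], genes, term_map)
        raw = np.array([r.p_fisher for r in res])
        m = len(raw)
        order = np.argsort(raw)
        hand = np.empty(m)
        running_min = 1.0
        for rank in range(m - 1, -1, -1):  # step-up from the largest p
            i = order[rank]
            running_min = min(running_min, raw[i] * m / (rank + 1))
            hand[i] = running_min
        np.testing.assert_allclose([r.p_bh for r in res], hand, atol=1e-12)

    def test_bh_monotone_and_capped(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(12)]
        term_map = {
            g: [f"T{j}" for j in range(5) if rng.random() < 0.4] for g in genes
        }
        study = genes[:5]
        res = fisher_enrichment(study, genes, term_map)
        in_raw_order = sorted(res, key=lambda r: r.p_fisher)
        adj = [r.p_bh for r in in_raw_order]
        assert all(a <= b + 1e-12 for a, b in zip(adj, adj[1:]))
        assert all(0 <= r.p_bh <= 1 and r.p_bh >= r.p_fisher - 1e-12 for r in res)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_bg = int(rng.integers(4, 13))
        genes = [f"g{i}" for i in range(n_bg)]
        n_study = int(rng.integers(1, n_bg))
        study = list(rng.choice(genes, size=n_study, replace=False))
        term_map = {g: (["T"] if rng.random() < 0.5 else []) for g in genes}
        if not any(term_map.values()):
            term_map[genes[0]] = ["T"]
        res = fisher_enrichment(study, genes, term_map)
        K = sum(1 for g in genes if term_map[g])
        k = sum(1 for g in study if term_map[g])
        oracle = brute_force_hypergeom_tail(k, n_bg, K, n_study)
        assert res[0].p_fisher == pytest.approx(oracle, abs=1e-12)
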