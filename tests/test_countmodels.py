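"""Count-model selection, detection-rate ranking and exact 2x2 inference."""

import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.stats import contingency

from scbinary import (
    BinaryMatrix,
    fisher_exact_2x2,
    fit_count_models,
    fit_models_table,
    rank_genes_binary,
    zero_inflation_enrichment,
)


class TestFitCountModels:
    def test_poisson_mle_and_loglik(self):
        with pytest.warns(UserWarning, match="observations"):
            fit = fit_count_models(np.array([2, 2, 2, 2]))
        assert fit.params["poisson"]["lam"] == 2.0
        assert fit.loglik["poisson"] == pytest.approx(4 * (-2 + np.log(2)), abs=1e-9)

    def test_zip_mle_against_grid_oracle(self):
        x = np.array([0, 0, 0, 0, 2, 2, 2, 2])
        with pytest.warns(UserWarning):
            fit = fit_count_models(x)
        # oracle: dense grid over (pi, lambda)
        best = (-np.inf, None, None)
        for pi in np.linspace(0.0, 0.8, 401):
            for lam in np.linspace(0.5, 3.5, 601):
                p0 = pi + (1 - pi) * np.exp(-lam)
                ll = 4 * np.log(p0) + 4 * (
                    np.log1p(-pi) + stats.poisson.logpmf(2, lam)
                )
                if ll > best[0]:
                    best = (ll, pi, lam)
        assert fit.loglik["zip"] >= best[0] - 1e-6
        assert fit.params["zip"]["lam"] == pytest.approx(1.594, abs=2e-3)
        assert fit.params["zip"]["pi"] == pytest.approx(0.372, abs=2e-3)

    def test_nested_models_never_lose_likelihood(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            mu, theta, pi = rng.uniform(0.3, 4), rng.uniform(0.4, 4), rng.uniform(0, 0.5)
            x = rng.negative_binomial(theta, theta / (theta + mu), size=300)
            x[rng.random(300) < pi] = 0
            if not x.any():
                continue
            fit = fit_count_models(x)
            assert fit.loglik["nb"] >= fit.loglik["poisson"] - 1e-7
            assert fit.loglik["zip"] >= fit.loglik["poisson"] - 1e-7
            assert fit.loglik["zinb"] >= fit.loglik["nb"] - 1e-7

    def test_nb_parameter_recovery(self):
        rng = np.random.default_rng(3)
        rel_err = []
        for _ in range(50):
            mu, theta = rng.uniform(0.5, 5), rng.uniform(0.5, 3)
            x = rng.negative_binomial(theta, theta / (theta + mu), size=2000)
            fit = fit_count_models(x)
            rel_err.append(
                (
                    abs(fit.params["nb"]["mu"] - mu) / mu,
                    abs(fit.params["nb"]["theta"] - theta) / theta,
                )
            )
        med = np.median(np.array(rel_err), axis=0)
        assert med[0] < 0.15 and med[1] < 0.15

    def test_bimodal_mixture_called_zero_inflated(self):
        rng = np.random.default_rng(4)
        x = np.concatenate(
            [np.zeros(300, dtype=int), rng.poisson(6.0, 300)]
        )
        assert fit_count_models(x).zero_inflated

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            fit_count_models(np.zeros(50, dtype=int))


class TestRankGenes:
    def _binary(self, dense):
        dense = np.asarray(dense, dtype=np.uint8)
        return BinaryMatrix.from_dense(
            dense,
            gene_ids=np.array([f"g{i}" for i in range(dense.shape[0])], dtype=object),
            cell_ids=np.array([f"c{i}" for i in range(dense.shape[1])], dtype=object),
        )

    def test_two_proportion_z_value(self):
        # detection 0.9 vs 0.1 at n=100 per group -> |z| ~ 11.31
        dense = np.zeros((1, 200), dtype=np.uint8)
        dense[0, :90] = 1
        dense[0, 100:110] = 1
        groups = ["a"] * 100 + ["b"] * 100
        b = self._binary(dense)
        # reproduce through the ranking contract: a clearly DE gene tops "de"
        top = rank_genes_binary(b, groups, mode="de", top_n=1)
        assert top[0] == "g0"
        p1, p2, pooled = 0.9, 0.1, 0.5
        z = (p1 - p2) / np.sqrt(pooled * (1 - pooled) * (2 / 100))
        assert z == pytest.approx(11.31, abs=0.01)

    def test_equal_detection_tops_stable(self):
        rng = np.random.default_rng(5)
        dense = (rng.random((5, 80)) < 0.4).astype(np.uint8)
        dense[2, :40] = dense[2, 40:]  # gene 2 identical in both groups
        groups = ["a"] * 40 + ["b"] * 40
        stable = rank_genes_binary(self._binary(dense), groups, mode="stable", top_n=1)
        assert stable[0] == "g2"

    def test_undetected_gene_excluded_from_stable(self):
        dense = np.zeros((2, 80), dtype=np.uint8)
        dense[1] = 1
        groups = ["a"] * 40 + ["b"] * 40
        stable = rank_genes_binary(self._binary(dense), groups, mode="stable", top_n=5)
        assert "g0" not in stable.tolist()

    def test_missing_group_rejected(self):
        dense = np.ones((2, 10), dtype=np.uint8)
        with pytest.raises(ValueError):
            rank_genes_binary(self._binary(dense), ["a"] * 10, mode="de")


def _enumerate_p(table):
    """Brute-force two-sided Fisher p by enumerating all tables with the
    observed margins, using exact rational hypergeometric probabilities."""
    from fractions import Fraction
    from math import comb

    a, b, c, d = np.asarray(table).ravel().tolist()
    m1, n1, total = a + b, a + c, a + b + c + d
    lo, hi = max(0, n1 - (total - m1)), min(m1, n1)
    denom = comb(total, n1)
    probs = {
        x: Fraction(comb(m1, x) * comb(total - m1, n1 - x), denom)
        for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestFisherExact:
    def test_symmetric_table(self):
        r = fisher_exact_2x2([[5, 5], [5, 5]])
        assert r.log_or_cmle == 0.0
        assert r.p_two_sided == pytest.approx(1.0)

    def test_five_table_enumeration(self):
        r = fisher_exact_2x2([[3, 1], [1, 3]])
        assert r.p_two_sided == pytest.approx(34 / 70, abs=1e-12)

    def test_p_matches_exact_enumeration_on_random_tables(self):
        rng = np.random.default_rng(6)
        checked = 0
        while checked < 200:
            t = rng.integers(0, 11, size=(2, 2))
            if t.sum() > 40 or (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            r = fisher_exact_2x2(t)
            assert abs(r.p_two_sided - _enumerate_p(t)) < 1e-12
            checked += 1

    def test_p_matches_scipy(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            t = rng.integers(1, 30, size=(2, 2))
            r = fisher_exact_2x2(t)
            assert r.p_two_sided == pytest.approx(
                stats.fisher_exact(t)[1], rel=1e-9, abs=1e-300
            )

    def test_cmle_matches_scipy_conditional_odds_ratio(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            t = rng.integers(1, 25, size=(2, 2))
            r = fisher_exact_2x2(t)
            ref = contingency.odds_ratio(t, kind="conditional").statistic
            assert r.log_or_cmle == pytest.approx(np.log(ref), abs=5e-3)

    def test_cmle_monotone_in_observed_count(self):
        # margins fixed at rows (10, 10), columns (8, 12)
        values = []
        for a in range(0, 9):
            t = [[a, 10 - a], [8 - a, 2 + a]]
            values.append(fisher_exact_2x2(t).log_or_cmle)
        assert all(x < y for x, y in zip(values, values[1:]))

    def test_boundary_table_infinite_or(self):
        r = fisher_exact_2x2([[5, 0], [0, 5]])
        assert r.log_or_cmle == np.inf
        assert r.ci95_log[1] == np.inf
        assert np.isfinite(r.ci95_log[0])

    def test_estimate_inside_ci(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            t = rng.integers(1, 20, size=(2, 2))
            r = fisher_exact_2x2(t)
            assert r.ci95_log[0] <= r.log_or_cmle <= r.ci95_log[1]

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact_2x2([[0, 0], [3, 4]])


class TestEnrichment:
    def _fits(self, zi_flags):
        import pandas as pd

        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(zi_flags))],
                "zero_inflated": zi_flags,
            }
        )

    def test_counts_delegate_to_fisher(self):
        fits = self._fits([True] * 99 + [False] * 1 + [True] * 35 + [False] * 65)
        de = [f"g{i}" for i in range(100)]
        stable = [f"g{i}" for i in range(100, 200)]
        r = zero_inflation_enrichment(fits, de, stable)
        assert np.array_equal(r.table, [[99, 1], [35, 65]])
        assert r.log_or_cmle == pytest.approx(5.19, abs=0.01)

    def test_identical_fractions_show_no_enrichment(self):
        fits = self._fits(([True] * 5 + [False] * 5) * 2)
        de = [f"g{i}" for i in range(10)]
        stable = [f"g{i}" for i in range(10, 20)]
        r = zero_inflation_enrichment(fits, de, stable)
        assert abs(r.log_or_cmle) < 1e-9
        assert r.p_two_sided > 0.5

    def test_overlapping_lists_rejected(self):
        fits = self._fits([True, False, True])
        with pytest.raises(ValueError, match="overlap"):
            zero_inflation_enrichment(fits, ["g0", "g1"], ["g1", "g2"])

    def test_marker_genes_pool_to_zero_inflated_fits(self, celltype_data):
        m, truth = celltype_data
        rng = np.random.default_rng(10)
        markers = truth.index[truth.gene_class == "marker"].to_numpy()
        hk = truth.index[truth.gene_class == "housekeeping"].to_numpy()
        pick_m = rng.choice(markers, 15, replace=False)
        pick_h = rng.choice(hk, 15, replace=False)
        fits = fit_models_table(
            m.values[np.concatenate([pick_m, pick_h])],
            m.gene_ids[np.concatenate([pick_m, pick_h])],
        )
        zi = fits.set_index("gene_id")["zero_inflated"]
        assert zi.iloc[:15].mean() > zi.iloc[15:].mean()
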