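"""Energy model: exact clamped conditioning, fitting, sign-test convergence."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pertconv import lnctp
from pertconv.lnctp import (
    LnctpModel,
    PerturbationSpec,
    assemble_model,
    call_insilico_convergent,
    compare_convergent_sets,
    fit_reduced_model,
    leading_edge_jaccard,
    perturb,
    perturb_set,
    sample_model,
    semantic_distance_test,
    sign_test_pvalue,
)


def two_gene_model():
    return LnctpModel(
        panel=["a", "b"],
        cell_types=[],
        precision=np.array([[2.0, -1.0], [-1.0, 2.0]]),
        mean=np.zeros(2),
        lambda_=0.0,
        fractions=np.array([]),
    )


def chain_model(n_genes=10, seed=0, weight_range=(0.1, 0.6)):
    rng = np.random.default_rng(seed)
    panel = [f"p{i}" for i in range(n_genes)]
    ws = rng.uniform(*weight_range, size=n_genes - 1)
    grn = {"bulk": [(panel[i], panel[i + 1], w) for i, w in enumerate(ws)]}
    return assemble_model(panel, grn, lambda_=0.0, cell_fractions=[]), grn


class TestAssembly:
    def test_empty_grn_lambda_zero_is_diagonal(self):
        m = assemble_model(["a", "b", "c"], {"bulk": []}, 0.0, [])
        assert np.allclose(m.precision, np.eye(3))

    def test_mask_honored_exactly(self):
        m, grn = chain_model(6, seed=1)
        off_support = ~m.support & ~np.eye(len(m.panel), dtype=bool)
        assert np.all(m.precision[off_support] == 0.0)

    def test_large_lambda_couples_bulk_and_cell_copy(self):
        """With one cell type at fraction 1 and large lambda, bulk and
        cell-type copies of a gene are nearly duplicated in samples."""
        m = assemble_model(
            ["a", "b"], {"bulk": [], "neuron": []}, lambda_=50.0, cell_fractions=[1.0]
        )
        x = sample_model(m, 500, seed=2)
        r = np.corrcoef(x[("bulk", "a")], x[("neuron", "a")])[0, 1]
        assert r > 0.9

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            assemble_model(["a"], {"bulk": [], "n": []}, 1.0, [0.5])

    def test_edge_outside_panel_rejected(self):
        with pytest.raises(ValueError):
            assemble_model(["a"], {"bulk": [("a", "zzz", 0.3)]}, 0.0, [])


class TestPerturb:
    def test_two_gene_conditioning_by_hand(self):
        """Clamping gene b at -2 moves E[a|.] to -1, so Delta_a = +1."""
        res = perturb(two_gene_model(), PerturbationSpec("bulk", "b", k=2, sign=-1))
        assert res.deltas[("bulk", "a")] == pytest.approx(1.0, abs=1e-12)

    def test_clamped_coordinate_identity(self):
        """Delta at the clamped coordinate equals mean - sign*k exactly."""
        m, _ = chain_model(8, seed=3)
        res = perturb(m, PerturbationSpec("bulk", "p3", k=2, sign=-1))
        assert res.deltas[("bulk", "p3")] == pytest.approx(2.0, abs=1e-14)
        res_pos = perturb(m, PerturbationSpec("bulk", "p3", k=1.5, sign=1))
        assert res_pos.deltas[("bulk", "p3")] == pytest.approx(-1.5, abs=1e-14)

    def test_sampling_agrees_with_closed_form(self):
        """Monte-Carlo deltas fall within 3 reported SEs of the closed form."""
        m, _ = chain_model(10, seed=4)
        closed = perturb(m, PerturbationSpec("bulk", "p5", k=2, sign=-1))
        mc = perturb(
            m,
            PerturbationSpec(
                "bulk", "p5", k=2, sign=-1, estimator="sampling",
                n_samples=2000, seed=5,
            ),
        )
        for coord in closed.deltas.index:
            if coord == ("bulk", "p5"):
                continue
            se = mc.standard_errors[coord]
            assert abs(mc.deltas[coord] - closed.deltas[coord]) <= 3 * se

    def test_genotype_offsets_average_over_individuals(self):
        """Per-individual bulk mean shifts change the clamped gap, and Delta
        averages over individuals."""
        offs = np.array([[0.0, 0.0], [1.0, 1.0]])
        m = assemble_model(
            ["a", "b"], {"bulk": [("a", "b", 0.5)]}, 0.0, [], genotype_offsets=offs
        )
        res = perturb(m, PerturbationSpec("bulk", "b", k=2, sign=-1))
        # clamped coordinate: mean over individuals of mu_b - (-2)
        assert res.deltas[("bulk", "b")] == pytest.approx(0.5 * ((0 + 2) + (1 + 2)))

    def test_deconvolution_limit_monotone_in_lambda(self):
        """The bulk/cell-type discrepancy shrinks monotonically in lambda."""
        gaps = []
        for lam in (0.1, 1.0, 10.0, 100.0):
            m = assemble_model(
                ["a"], {"bulk": [], "n": []}, lambda_=lam, cell_fractions=[1.0]
            )
            x = sample_model(m, 400, seed=8)
            gaps.append(np.mean(np.abs(x[("bulk", "a")] - x[("n", "a")])))
        assert all(np.diff(gaps) < 0)


class TestFitReducedModel:
    def test_recovers_chain_precision(self):
        """Node-wise ridge fit recovers supported off-diagonals, r >= 0.9."""
        rs = []
        for seed in range(5):
            truth, grn = chain_model(10, seed=seed)
            x = sample_model(truth, 500, seed=100 + seed)
            fit = fit_reduced_model(x, truth.support)
            iu = np.triu_indices(10, 1)
            sup = truth.support[iu]
            r = np.corrcoef(truth.precision[iu][sup], fit.precision[iu][sup])[0, 1]
            rs.append(r)
        assert np.mean(rs) >= 0.9

    def test_support_mask_exact_zero(self):
        truth, _ = chain_model(8, seed=6)
        x = sample_model(truth, 300, seed=7)
        fit = fit_reduced_model(x, truth.support)
        off_support = ~truth.support & ~np.eye(8, dtype=bool)
        assert np.all(fit.precision[off_support] == 0.0)

    def test_self_consistency_on_refit(self):
        """Refitting on data regenerated from the fit reproduces it closely."""
        truth, _ = chain_model(6, seed=9)
        x = sample_model(truth, 2000, seed=10)
        fit1 = fit_reduced_model(x, truth.support)
        x2 = sample_model(fit1, 2000, seed=11)
        fit2 = fit_reduced_model(x2, truth.support)
        sup = truth.support | np.eye(6, dtype=bool)
        rel = np.abs(fit2.precision[sup] - fit1.precision[sup]) / np.abs(
            fit1.precision[sup]
        )
        assert np.median(rel) < 0.10

    def test_zero_variance_column_rejected(self):
        truth, _ = chain_model(4, seed=12)
        x = sample_model(truth, 50, seed=13)
        x.iloc[:, 0] = 1.0
        with pytest.raises(ValueError):
            fit_reduced_model(x, truth.support)


class TestSignTestConvergence:
    @pytest.mark.parametrize("n", range(1, 13))
    def test_matches_exact_binomial_enumeration(self, n):
        """Two-tailed sign-test p equals full binomial enumeration, n <= 12."""
        for k in range(n + 1):
            # oracle: total probability of outcomes at least as extreme
            d = abs(k - n / 2)
            p_oracle = sum(
                math.comb(n, j) * 0.5**n
                for j in range(n + 1)
                if abs(j - n / 2) >= d - 1e-12
            )
            assert sign_test_pvalue(k, n) == pytest.approx(min(1.0, p_oracle), rel=1e-9)

    def test_five_consistent_perturbations_required(self):
        """At alpha = 0.1, all-same-sign needs n >= 5: p(5) = 0.0625 < 0.1
        but p(4) = 0.125."""
        assert sign_test_pvalue(5, 5) == pytest.approx(2 * 0.5**5)
        assert sign_test_pvalue(4, 4) == pytest.approx(0.125)
        smallest = min(
            n for n in range(1, 10) if sign_test_pvalue(n, n) < 0.1
        )
        assert smallest == 5

    def test_call_table(self):
        cols = pd.MultiIndex.from_tuples(
            [("bulk", "gA"), ("bulk", "gB"), ("bulk", "gC")],
            names=["context", "gene"],
        )
        deltas = pd.DataFrame(
            [
                [0.5, 0.5, 0.5],
                [0.6, 0.6, -0.6],
                [0.4, 0.7, 0.4],
                [0.5, 0.4, -0.5],
                [0.9, 0.1, 0.5],  # gB entry below tau
                [0.7, 0.5, -0.4],
            ],
            columns=cols,
        )
        calls = call_insilico_convergent(deltas, tau=0.3, alpha=0.1)
        # gA: 6 qualifying, all positive -> p = 2/64 < 0.1 -> convergent
        assert calls.loc[("bulk", "gA"), "convergent"]
        assert calls.loc[("bulk", "gA"), "sign"] == 1
        # gB: 5 qualifying, all positive -> p = 0.0625 -> convergent
        assert calls.loc[("bulk", "gB"), "convergent"]
        # gC: 3 up / 3 down -> p = 1 -> not convergent
        assert not calls.loc[("bulk", "gC"), "convergent"]

    def test_untestable_flagged_not_called(self):
        cols = pd.MultiIndex.from_tuples([("bulk", "g")], names=["context", "gene"])
        deltas = pd.DataFrame([[0.5]] * 4, columns=cols)
        calls = call_insilico_convergent(deltas)
        assert not calls.loc[("bulk", "g"), "testable"]
        assert not calls.loc[("bulk", "g"), "convergent"]

    def test_perturb_set_shape(self):
        m, _ = chain_model(5, seed=20)
        targets = [("bulk", "p0"), ("bulk", "p2")]
        d = perturb_set(m, targets, k=2, sign=-1)
        assert d.shape == (2, 5)
        assert d.loc[("bulk", "p0"), ("bulk", "p0")] == pytest.approx(2.0)


class TestSetComparison:
    def test_identical_sets(self):
        r = compare_convergent_sets({"a", "b"}, {"a", "b"}, {"a", "b", "c"})
        assert r["jaccard"] == 1.0 and r["overlap"] == 2

    def test_empty_set(self):
        r = compare_convergent_sets(set(), {"a"}, {"a", "b"})
        assert r["overlap"] == 0 and r["jaccard"] == 0.0

    def test_two_sided_fisher_matches_scipy(self):
        universe = set(range(20))
        a, b = set(range(8)), set(range(5, 12))
        r = compare_convergent_sets(a, b, universe)
        inter = len(a & b)
        table = [[inter, len(a) - inter], [len(b) - inter, 20 - len(a | b)]]
        assert r["p_hypergeom"] == pytest.approx(
            stats.fisher_exact(table).pvalue
        )

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            compare_convergent_sets(set(), set(), set())


class TestSemanticDistance:
    def test_jaccard_by_hand(self):
        assert leading_edge_jaccard({"a", "b", "c"}, {"b", "c", "d"}) == pytest.approx(0.5)

    def test_identical_leading_edges_no_separation(self):
        terms = {f"t{i}": {"a", "b"} for i in range(3)}
        res = semantic_distance_test(terms, {f"u{i}": {"a", "b"} for i in range(3)})
        assert res["p"] == pytest.approx(1.0)

    def test_separated_lists_significant(self):
        """Within-set Jaccard 1.0, between-set 0: rank-sum p below 0.01."""
        terms_a = {f"t{i}": {"a1", "a2", "a3"} for i in range(4)}
        terms_b = {f"u{i}": {"b1", "b2", "b3"} for i in range(4)}
        res = semantic_distance_test(terms_a, terms_b)
        between = [0.0] * 16
        within = [1.0] * 12
        p_oracle = stats.mannwhitneyu(between, within, alternative="less").pvalue
        assert res["p"] == pytest.approx(p_oracle)
        assert res["p"] < 0.01

    def test_short_lists_missing(self):
        res = semantic_distance_test({"t": {"a"}}, {"u1": {"a"}, "u2": {"b"}})
        assert math.isnan(res["p"])
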