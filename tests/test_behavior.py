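"""Behavioral fingerprints, drug matching, WTCS/NCS and rescue classification."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from pertconv.behavior import (
    RankedSignature,
    behavioral_fingerprint,
    classify_rescue,
    cluster_mutants,
    cmap_query,
    fit_behavior_effect,
    match_drugs,
    rescue_profile,
    wtcs,
)
from pertconv.synthetic import simulate_behavior_table


class TestBehaviorEffect:
    def test_planted_shift_detected(self):
        """A 2-residual-sd genotype shift at n=30/group reaches P <= 0.06
        in at least 19 of 20 seeds."""
        hits = 0
        for seed in range(20):
            tab = simulate_behavior_table(
                30, parameters=["p1"], genotype_effects={"p1": 2.0}, seed=seed
            )
            beta, p = fit_behavior_effect(tab, "p1")
            hits += p <= 0.06
        assert hits >= 19

    def test_null_pvalues_not_inflated(self):
        """Without a planted effect, small p-values appear at chance rates."""
        ps = []
        for seed in range(20):
            tab = simulate_behavior_table(20, parameters=["p1"], seed=100 + seed)
            _, p = fit_behavior_effect(tab, "p1")
            ps.append(p)
        assert np.median(ps) > 0.1
        assert np.mean(np.array(ps) < 0.05) <= 0.25

    def test_balanced_batches_unbiased(self):
        """Large but balanced batch intercepts leave the effect unbiased."""
        betas = []
        for seed in range(10):
            tab = simulate_behavior_table(
                30, parameters=["p1"], genotype_effects={"p1": 1.0},
                n_batches=4, batch_sd=3.0, seed=200 + seed,
            )
            beta, _ = fit_behavior_effect(tab, "p1")
            betas.append(beta)
        assert abs(np.mean(betas) - 1.0) < 0.2

    def test_single_batch_ols_fallback(self):
        tab = simulate_behavior_table(
            10, parameters=["p1"], genotype_effects={"p1": 3.0},
            n_batches=1, seed=3,
        )
        beta, p = fit_behavior_effect(tab, "p1")
        assert p < 0.05 and beta > 1.0

    def test_requires_three_per_group(self):
        tab = simulate_behavior_table(3, parameters=["p1"], seed=4)
        tab = tab[~((tab["genotype"] == "mutant") & (tab["larva_id"] == tab["larva_id"].unique()[-1]))]
        with pytest.raises(ValueError):
            fit_behavior_effect(tab, "p1")


class TestFingerprint:
    def test_antisymmetry_under_label_swap(self):
        """Swapping genotype labels flips every signed score exactly."""
        tab = simulate_behavior_table(
            15, parameters=["p1", "p2", "p3"],
            genotype_effects={"p1": 1.5, "p2": -1.0}, seed=5,
        )
        fp = behavioral_fingerprint(tab)
        swapped = tab.copy()
        swapped["genotype"] = swapped["genotype"].map(
            {"control": "mutant", "mutant": "control"}
        )
        fp_swapped = behavioral_fingerprint(swapped)
        np.testing.assert_allclose(
            fp.signed_scores.to_numpy(),
            -fp_swapped.signed_scores.to_numpy(),
            atol=1e-6,
        )

    def test_null_scores_small(self):
        tab = simulate_behavior_table(20, parameters=[f"p{i}" for i in range(8)], seed=6)
        fp = behavioral_fingerprint(tab)
        assert fp.signed_scores.abs().median() < 1.0

    def test_deterministic(self):
        tab = simulate_behavior_table(10, parameters=["p1", "p2"], seed=7)
        a = behavioral_fingerprint(tab).table
        b = behavioral_fingerprint(tab).table
        pd.testing.assert_frame_equal(a, b)

    def test_missing_parameter_flagged(self):
        tab = simulate_behavior_table(10, parameters=["p1"], seed=8)
        fp = behavioral_fingerprint(tab, parameters=["p1", "p2"])
        assert math.isnan(fp.table.loc["p2", "p"])


class TestClusterMutants:
    def test_self_and_negated_correlations(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=24)
        fps = pd.DataFrame(
            [base, -base], index=["m1", "m2"],
        )
        corr, _, _ = cluster_mutants(fps)
        assert corr.loc["m1", "m1"] == pytest.approx(1.0)
        assert corr.loc["m1", "m2"] == pytest.approx(-1.0)

    def test_planted_groups_recovered(self):
        """Four planted fingerprint groups are recovered at k=4
        (adjusted Rand >= 0.9 over 10 seeds)."""
        aris = []
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            centers = rng.normal(scale=3.0, size=(4, 24))
            fps, truth = [], []
            for gi in range(4):
                for j in range(4):
                    fps.append(centers[gi] + rng.normal(scale=0.5, size=24))
                    truth.append(gi)
            fps = pd.DataFrame(fps, index=[f"m{i}" for i in range(16)])
            _, _, labels = cluster_mutants(fps, k=4)
            aris.append(adjusted_rand_score(truth, labels.to_numpy()))
        assert np.mean(aris) >= 0.9

    def test_constant_fingerprint_missing(self):
        fps = pd.DataFrame(
            [[1.0] * 10, list(range(10)), list(range(10))[::-1]],
            index=["flat", "m1", "m2"],
        )
        corr, _, _ = cluster_mutants(fps)
        assert corr.loc["flat"].isna().all()


class TestMatchDrugs:
    def test_exact_anticorrelation(self):
        rng = np.random.default_rng(10)
        mut = pd.Series(rng.normal(size=24), index=[f"p{i}" for i in range(24)])
        drugs = pd.DataFrame(
            {c: v for c, v in zip(mut.index, -mut.to_numpy())}, index=["drugA"]
        )
        out = match_drugs(mut, drugs)
        assert out.loc["drugA", "match"] == "anti-correlate"
        assert out.loc["drugA", "r"] == pytest.approx(-1.0)

    def test_thresholds_respected(self):
        """r below 0.5 never matches, whatever the p-value; r above with
        small p does."""
        rng = np.random.default_rng(11)
        mut = pd.Series(rng.normal(size=24), index=[f"p{i}" for i in range(24)])
        noise = rng.normal(size=24)
        rows = {}
        for label, mix in [("weak", 0.25), ("strong", 3.0)]:
            v = mix * mut.to_numpy() + noise
            rows[label] = v
        drugs = pd.DataFrame(rows, index=mut.index).T
        out = match_drugs(mut, drugs)
        for label in rows:
            r, p = stats.pearsonr(mut, drugs.loc[label])
            expect = (
                "correlate" if (r > 0.5 and p < 0.05)
                else "anti-correlate" if (r < -0.5 and p < 0.05)
                else "none"
            )
            assert out.loc[label, "match"] == expect
        assert out.loc["strong", "match"] == "correlate"

    def test_few_shared_parameters_missing(self):
        mut = pd.Series([1.0, 2.0], index=["p1", "p2"])
        drugs = pd.DataFrame([[1.0, 2.0]], index=["d"], columns=["p1", "p2"])
        out = match_drugs(mut, drugs)
        assert out.loc["d", "match"] == "missing"


def make_signature(sig_id, group, genes, scores, null=False):
    return RankedSignature(
        signature_id=sig_id, group_id=group,
        scores=pd.Series(scores, index=genes, dtype=float), is_null=null,
    )


class TestCmapQuery:
    def _universe(self, n=40):
        return [f"g{i}" for i in range(n)]

    def test_extreme_connectivity_and_reversal(self):
        """Query up-set at the top and down-set at the bottom gives a large
        positive WTCS; the negated signature gives the mirror negative."""
        genes = self._universe()
        scores = np.linspace(5, -5, len(genes))
        sig = make_signature("s1", "drugA", genes, scores)
        up, down = set(genes[:5]), set(genes[-5:])
        w = wtcs(sig, up, down)
        assert w > 0.9
        sig_rev = make_signature("s2", "drugA", genes, -scores)
        assert wtcs(sig_rev, up, down) == pytest.approx(-w, abs=1e-12)

    def test_same_sign_es_gives_zero(self):
        """Up and down query sets both enriched at the top force WTCS = 0."""
        genes = self._universe()
        scores = np.linspace(5, -5, len(genes))
        sig = make_signature("s1", "d", genes, scores)
        assert wtcs(sig, set(genes[:5]), set(genes[5:10])) == 0.0

    def _collection(self, scale=1.0):
        """Three perturbation groups of three signatures each (one strong,
        two diluted), plus six vehicle nulls."""
        genes = self._universe()
        rng = np.random.default_rng(12)
        sigs = []
        base = np.linspace(5, -5, len(genes))
        for i, flip in enumerate([1, 1, -1]):
            for j, mix in enumerate([1.0, 0.3, 0.2]):
                noise = rng.permutation(base)
                scores = flip * (mix * base + (1 - mix) * noise) * scale
                sigs.append(
                    make_signature(f"drug{i}_rep{j}", f"g{i}", genes, scores)
                )
        for i in range(6):
            sigs.append(
                make_signature(
                    f"null{i}", "dmso", genes,
                    rng.permutation(base) * scale, null=True,
                )
            )
        return sigs, set(genes[:5]), set(genes[-5:])

    def test_ncs_invariant_to_group_rescaling(self):
        sigs1, up, down = self._collection(1.0)
        sigs2, _, _ = self._collection(2.0)
        df1 = cmap_query(up, down, sigs1)
        df2 = cmap_query(up, down, sigs2)
        np.testing.assert_allclose(df1["ncs"], df2["ncs"], atol=1e-9)

    def test_reverser_flag_thresholds(self):
        sigs, up, down = self._collection()
        df = cmap_query(up, down, sigs)
        rev = df.loc["drug2_rep0"]  # the strong flipped signature
        assert rev["ncs"] <= -1.0
        assert rev["fdr"] <= 0.05
        assert bool(rev["reverser"])
        assert not df.loc["drug0_rep0", "reverser"]
        assert not df.loc[df["is_null"], "reverser"].any()

    def test_disjoint_query_required(self):
        sigs, up, down = self._collection()
        with pytest.raises(ValueError):
            cmap_query(up, up, sigs)


def oracle_rescue(mut_beta, mut_p, drug_beta, drug_p, alpha=0.06):
    """Independent restatement of the five-category rule."""
    if mut_p >= alpha:
        return None
    if drug_p >= alpha:
        return "rescued"
    if (mut_beta > 0) != (drug_beta > 0):
        return "over_corrected"
    if abs(drug_beta) < abs(mut_beta):
        return "partial_rescue"
    if drug_p <= mut_p and abs(drug_beta) > abs(mut_beta):
        return "exacerbated"
    return "unchanged"


class TestClassifyRescue:
    @pytest.mark.parametrize(
        "mut,drug,expect",
        [
            ((2.0, 0.01), (0.5, 0.5), "rescued"),
            ((2.0, 0.01), (-2.0, 0.01), "over_corrected"),
            ((2.0, 0.01), (1.0, 0.03), "partial_rescue"),
            ((2.0, 0.03), (3.0, 0.01), "exacerbated"),
            ((2.0, 0.01), (2.0, 0.02), "unchanged"),
            ((2.0, 0.07), (0.5, 0.5), None),  # gate: mutant not significant
        ],
    )
    def test_examples(self, mut, drug, expect):
        assert classify_rescue(mut, drug).category == expect

    def test_matches_truth_table_over_full_grid(self):
        """The classifier agrees with a brute-force oracle over the full
        (p, beta) grid."""
        ps = [0.001, 0.05, 0.059, 0.06, 0.5]
        betas = [-2, -1, -0.5, 0.5, 1, 2]
        for mut_p, drug_p, mut_b, drug_b in itertools.product(ps, ps, betas, betas):
            got = classify_rescue((mut_b, mut_p), (drug_b, drug_p)).category
            want = oracle_rescue(mut_b, mut_p, drug_b, drug_p)
            assert got == want, (mut_b, mut_p, drug_b, drug_p)

    def test_rescue_profile_end_to_end(self):
        """A drug generated to cancel the planted mutant shift is classified
        rescued on the affected parameter."""
        tab = simulate_behavior_table(
            30,
            parameters=["p1", "p2"],
            genotype_effects={"p1": 2.0},
            drug_effects={"p1": -2.0},
            include_drug_groups=True,
            seed=21,
        )
        prof = rescue_profile(tab, parameters=["p1", "p2"])
        assert prof.loc["p1", "category"] == "rescued"
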