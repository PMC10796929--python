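import numpy as np
import pandas as pd
import pytest

import trajgwas as tg
from trajgwas.pipeline import outcome_tables
from trajgwas.prs import bonferroni_threshold, compute_prs, select_and_align
from trajgwas.prs import test_prs_trajectory as prs_trajectory_association
from trajgwas.simulate import CohortData


def _weights(rows):
    return pd.DataFrame(
        rows, columns=["variant_id", "effect_allele", "other_allele", "beta", "p"]
    )


@pytest.fixture(scope="module")
def prs_cohort():
    cfg = tg.SimulationConfig(n_candidates=600, n_variants=40, seed=51)
    cohort, _ = tg.simulate_cohort(cfg)
    return cohort


class TestSelectAndAlign:
    def test_effect_allele_equal_ref_flips_weight(self, prs_cohort):
        meta = prs_cohort.variant_meta.set_index("variant_id")
        # pick a non-palindromic variant and quote it with swapped alleles
        vid = next(
            v for v in meta.index
            if {meta.loc[v, "ref"], meta.loc[v, "alt"]} not in ({"A", "T"}, {"C", "G"})
        )
        w = _weights([[vid, meta.loc[vid, "ref"], meta.loc[vid, "alt"], 0.4, 1e-9]])
        model = select_and_align(w, prs_cohort)
        assert model.variants["aligned_weight"].iloc[0] == pytest.approx(-0.4)

    def test_palindromic_variant_dropped(self, prs_cohort):
        vid = prs_cohort.variant_meta["variant_id"].iloc[5]
        w = _weights(
            [
                [vid, "A", "T", 0.2, 1e-9],
                ["other", "A", "G", 0.1, 1e-9],
            ]
        )
        with pytest.raises(ValueError):
            # A/T row is ambiguous, 'other' unmatched: nothing survives
            select_and_align(w, prs_cohort)
        # ledger semantics checked through a surviving mix
        meta = prs_cohort.variant_meta.set_index("variant_id")
        good = next(
            v for v in meta.index
            if {meta.loc[v, "ref"], meta.loc[v, "alt"]} not in ({"A", "T"}, {"C", "G"})
        )
        w2 = _weights(
            [
                [vid, "A", "T", 0.2, 1e-9],
                [good, meta.loc[good, "alt"], meta.loc[good, "ref"], 0.1, 1e-9],
            ]
        )
        model = select_and_align(w2, prs_cohort)
        reasons = model.ledger.set_index("variant_id")["reason"]
        assert reasons.loc[vid] == "ambiguous"
        assert model.variants["variant_id"].tolist() == [good]

    def test_source_p_filter(self, prs_cohort):
        meta = prs_cohort.variant_meta.set_index("variant_id")
        good = next(
            v for v in meta.index
            if {meta.loc[v, "ref"], meta.loc[v, "alt"]} not in ({"A", "T"}, {"C", "G"})
        )
        w = _weights(
            [
                [good, meta.loc[good, "alt"], meta.loc[good, "ref"], 0.1, 1e-9],
                ["weak", "A", "G", 0.5, 1e-4],
            ]
        )
        model = select_and_align(w, prs_cohort)
        assert model.ledger.set_index("variant_id").loc["weak", "reason"] == "source_p"

    def test_perfect_ld_pair_clumped_to_one(self):
        cfg = tg.SimulationConfig(
            n_candidates=500, n_variants=8, ld_block_size=2, ld_flip_prob=0.0, seed=52
        )
        cohort, _ = tg.simulate_cohort(cfg)
        meta = cohort.variant_meta.set_index("variant_id")
        pair = ["var0001", "var0002"]  # same block, identical columns
        rows = []
        for v in pair:
            if {meta.loc[v, "ref"], meta.loc[v, "alt"]} in ({"A", "T"}, {"C", "G"}):
                pytest.skip("palindromic draw for this seed")
            rows.append([v, meta.loc[v, "alt"], meta.loc[v, "ref"], 0.3, 1e-10])
        model = select_and_align(_weights(rows), cohort)
        assert model.n_variants == 1
        assert (model.ledger["reason"] == "clumped").sum() == 1


class TestComputePRS:
    def _toy_cohort(self, dosages, ids=("vA", "vB", "vC")):
        dosages = np.asarray(dosages, dtype=float)
        n = dosages.shape[0]
        meta = pd.DataFrame(
            {
                "variant_id": list(ids),
                "chrom": ["1"] * len(ids),
                "pos": [100 * (i + 1) for i in range(len(ids))],
                "ref": ["A"] * len(ids),
                "alt": ["G"] * len(ids),
                "imputation_r2": [1.0] * len(ids),
            }
        )
        return CohortData(
            dosages=np.asarray(dosages, float),
            subject_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
            variant_meta=meta,
            covariates=pd.DataFrame({"subject_id": [f"s{i}" for i in range(n)]}),
            phenotypes=pd.DataFrame(columns=["subject_id", "time_days", "test_id", "score"]),
        )

    def _model(self, weights, ids=("vA", "vB", "vC")):
        from trajgwas.prs import PRSModel

        return PRSModel(
            trait="toy",
            variants=pd.DataFrame(
                {"variant_id": list(ids), "effect_allele": ["G"] * len(ids), "aligned_weight": weights}
            ),
            ledger=pd.DataFrame(columns=["variant_id", "reason"]),
        )

    def test_weighted_sum_arithmetic(self):
        cohort = self._toy_cohort([[0.0, 1.0, 2.0], [1.0, 1.0, 1.0]])
        model = self._model([0.1, -0.2, 0.3])
        raw = compute_prs(model, cohort, standardize=False)
        assert raw[0] == pytest.approx(0.0 * 0.1 + 1.0 * -0.2 + 2.0 * 0.3)  # 0.4

    def test_all_zero_weights_cannot_standardise(self):
        cohort = self._toy_cohort([[0.0, 1.0, 2.0], [1.0, 1.0, 1.0]])
        model = self._model([0.0, 0.0, 0.0])
        assert np.all(compute_prs(model, cohort, standardize=False) == 0.0)
        with pytest.raises(ValueError, match="constant"):
            compute_prs(model, cohort)

    def test_doubling_weights_leaves_standardized_score_unchanged(self, rng):
        D = rng.binomial(2, 0.4, size=(50, 3)).astype(float)
        cohort = self._toy_cohort(D)
        s1 = compute_prs(self._model([0.1, -0.2, 0.3]), cohort)
        s2 = compute_prs(self._model([0.2, -0.4, 0.6]), cohort)
        assert np.allclose(s1, s2)

    def test_variant_order_invariance(self, rng):
        D = rng.binomial(2, 0.4, size=(50, 3)).astype(float)
        cohort = self._toy_cohort(D)
        s1 = compute_prs(self._model([0.1, -0.2, 0.3]), cohort)
        model_rev = self._model([0.3, -0.2, 0.1], ids=("vC", "vB", "vA"))
        s2 = compute_prs(model_rev, cohort)
        assert np.allclose(s1, s2)

    def test_missing_dosage_mean_imputed(self, rng):
        D = rng.binomial(2, 0.4, size=(50, 3)).astype(float)
        cohort = self._toy_cohort(D)
        D2 = D.copy()
        D2[0, 0] = np.nan
        cohort2 = self._toy_cohort(D2)
        s = compute_prs(self._model([0.1, -0.2, 0.3]), cohort2)
        assert np.isfinite(s).all()


class TestTrajectoryAssociation:
    def test_intercept_effect_recovered_within_ci(self):
        hits = 0
        for r in range(10):
            cfg = tg.SimulationConfig(n_candidates=700, n_variants=30, seed=700 + r)
            eff = tg.TrueEffects.null().with_effect("var0010", (0.3, 0.0, 0.0, 0.0))
            cohort, _ = tg.simulate_cohort(cfg, eff)
            _, tables = outcome_tables(cohort.phenotypes)
            d = cohort.dosage_of("var0010")
            score = (d - d.mean()) / d.std(ddof=1)
            assoc = prs_trajectory_association(
                cohort, tables["global"], score, risk_variant_ids=("var0001", "var0002")
            )
            # true per-SD-of-score effect on the z scale
            age = cohort.covariates["baseline_age_years"].to_numpy()
            f = 1 / np.sqrt(
                cfg.random_intercept_sd**2 + cfg.resid_sd**2 + cfg.test_noise_sd**2
                + cfg.mean_age_slope**2 * age.var() + 2 * 0.3**2 * d.var() / 2
            )
            truth = 0.3 * d.std(ddof=1) * f
            b = assoc.blocks["intercept"]
            hits += abs(b["beta"] - truth) < 2.5 * b["se"]
        assert hits >= 8

    def test_permuted_score_is_null(self):
        quiet = 0
        for r in range(10):
            cfg = tg.SimulationConfig(n_candidates=400, n_variants=20, seed=800 + r)
            cohort, _ = tg.simulate_cohort(cfg)
            _, tables = outcome_tables(cohort.phenotypes)
            rng = np.random.default_rng(900 + r)
            score = rng.permutation(np.linspace(-2, 2, cohort.n_subjects))
            assoc = prs_trajectory_association(cohort, tables["global"], score)
            quiet += all(v["p"] > 0.05 for v in assoc.blocks.values())
        assert quiet >= 7  # roughly matches four independent 5% tests

    def test_negative_age_interaction_sign_recovered(self):
        cfg = tg.SimulationConfig(n_candidates=1500, n_variants=20, seed=53)
        eff = tg.TrueEffects.null().with_effect("var0010", (0.0, -0.05, 0.0, 0.0))
        cohort, _ = tg.simulate_cohort(cfg, eff)
        _, tables = outcome_tables(cohort.phenotypes)
        d = cohort.dosage_of("var0010")
        score = (d - d.mean()) / d.std(ddof=1)
        assoc = prs_trajectory_association(cohort, tables["global"], score)
        assert assoc.blocks["age"]["beta"] < 0  # effect weakens with age

    def test_gee_fallback_produces_same_blocks(self, prs_cohort):
        _, tables = outcome_tables(prs_cohort.phenotypes)
        rng = np.random.default_rng(54)
        score = rng.normal(size=prs_cohort.n_subjects)
        a_lmm = prs_trajectory_association(prs_cohort, tables["global"], score, family="lmm")
        a_gee = prs_trajectory_association(prs_cohort, tables["global"], score, family="gee")
        assert a_gee.family == "gee"
        for b in a_lmm.blocks:
            assert a_lmm.blocks[b]["beta"] == pytest.approx(
                a_gee.blocks[b]["beta"], abs=0.02
            )


class TestBonferroni:
    def test_six_models_rounds_to_printed_value(self):
        assert bonferroni_threshold(6) == 0.008

    def test_seventy_two_models_rounds_to_printed_value(self):
        assert bonferroni_threshold(72) == pytest.approx(7e-4)

    def test_single_model_is_alpha(self):
        assert bonferroni_threshold(1) == 0.05

    def test_unrounded_value(self):
        assert bonferroni_threshold(6, rounded=False) == pytest.approx(0.05 / 6)

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)
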