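import numpy as np
import pandas as pd
import pytest
from scipy import stats

import trajgwas as tg
from trajgwas.pipeline import outcome_tables
from trajgwas.scan import (
    build_scan_design,
    clump,
    genomic_lambda,
    lookup_variants,
    manhattan_table,
    qq_table,
    run_scan,
    scan_variant,
)


@pytest.fixture(scope="module")
def design_and_cohort():
    cfg = tg.SimulationConfig(n_candidates=400, n_variants=50, seed=21)
    cohort, _ = tg.simulate_cohort(cfg)
    _, tables = outcome_tables(cohort.phenotypes)
    pcs, _ = tg.genotype_pca(cohort.dosages, k=5)
    design = build_scan_design(
        cohort, tables["global"], pcs=pcs, risk_variant_ids=("var0001", "var0002")
    )
    return cohort, tables, pcs, design


class TestScanVariant:
    def test_permuted_dosage_never_extreme(self, design_and_cohort):
        cohort, _, _, design = design_and_cohort
        rng = np.random.default_rng(22)
        d = cohort.dosage_of("var0010")
        worst = 0.0
        for _ in range(100):
            rec = scan_variant(design, rng.permutation(d))
            zs = [
                abs(rec[f"{b}_beta"] / rec[f"{b}_se"])
                for b in ("intercept", "age", "slope1", "slope2")
            ]
            worst = max(worst, max(zs))
        assert worst < 4.0  # permutation breaks any genotype-outcome link

    def test_monomorphic_dosage_raises(self, design_and_cohort):
        _, _, _, design = design_and_cohort
        with pytest.raises(ValueError, match="monomorphic"):
            scan_variant(design, np.ones(design.subj_of_row.max() + 1))

    def test_injected_slope1_sign_recovered(self):
        hits = 0
        for r in range(20):
            cfg = tg.SimulationConfig(n_candidates=800, n_variants=20, seed=600 + r)
            eff = tg.TrueEffects.null().with_effect("var0005", (0.0, 0.0, 0.4, 0.0))
            cohort, _ = tg.simulate_cohort(cfg, eff)
            _, tables = outcome_tables(cohort.phenotypes)
            design = build_scan_design(
                cohort, tables["global"], risk_variant_ids=("var0001", "var0002")
            )
            rec = scan_variant(design, cohort.dosage_of("var0005"))
            hits += rec["slope1_beta"] > 0
        assert hits >= 19  # positive slope-1 effect recovered essentially always

    def test_missing_dosages_mean_imputed(self, design_and_cohort):
        cohort, _, _, design = design_and_cohort
        d = cohort.dosage_of("var0012").copy()
        rec_full = scan_variant(design, d)
        d_miss = d.copy()
        d_miss[:3] = np.nan
        rec_miss = scan_variant(design, d_miss)  # must not raise
        assert abs(rec_miss["slope2_beta"] - rec_full["slope2_beta"]) < 0.5


class TestRunScan:
    def test_duplicated_variant_columns_identical_records(self, design_and_cohort):
        cohort, tables, pcs, _ = design_and_cohort
        # make var0021 an exact copy of var0020
        j0 = cohort.variant_index("var0020")
        j1 = cohort.variant_index("var0021")
        cohort.dosages[:, j1] = cohort.dosages[:, j0]
        rec, _ = run_scan(
            cohort,
            tables["global"],
            variant_ids=["var0020", "var0021"],
            pcs=pcs,
            risk_variant_ids=("var0001", "var0002"),
        )
        r = rec.set_index("variant_id")
        for b in ("intercept", "age", "slope1", "slope2"):
            assert r.loc["var0020", f"{b}_beta"] == r.loc["var0021", f"{b}_beta"]
            assert r.loc["var0020", f"{b}_p"] == r.loc["var0021", f"{b}_p"]

    def test_causal_slope2_variant_is_top_hit(self):
        cfg = tg.SimulationConfig(n_candidates=1000, n_variants=60, seed=23)
        eff = tg.TrueEffects.null().with_effect("var0030", (0.0, 0.0, 0.0, -0.8))
        cohort, _ = tg.simulate_cohort(cfg, eff)
        _, tables = outcome_tables(cohort.phenotypes)
        rec, summary = run_scan(
            cohort, tables["global"], risk_variant_ids=("var0001", "var0002")
        )
        top = rec.loc[rec["slope2_p"].idxmin(), "variant_id"]
        assert top == "var0030"
        assert rec["slope2_p"].min() < 5e-8
        assert summary.n_significant >= 1

    def test_subject_order_invariance(self):
        cfg = tg.SimulationConfig(n_candidates=250, n_variants=20, seed=24)
        cohort, _ = tg.simulate_cohort(cfg)
        _, tables = outcome_tables(cohort.phenotypes)
        rec1, _ = run_scan(cohort, tables["global"], variant_ids=["var0010"])
        perm = np.random.default_rng(25).permutation(cohort.n_subjects)
        shuffled = tg.CohortData(
            dosages=cohort.dosages[perm],
            subject_ids=cohort.subject_ids[perm],
            variant_meta=cohort.variant_meta,
            covariates=cohort.covariates.iloc[perm].reset_index(drop=True),
            phenotypes=cohort.phenotypes,
        )
        rec2, _ = run_scan(shuffled, tables["global"], variant_ids=["var0010"])
        for b in ("intercept", "age", "slope1", "slope2"):
            assert rec1[f"{b}_beta"].iloc[0] == pytest.approx(
                rec2[f"{b}_beta"].iloc[0], rel=1e-8
            )

    def test_skips_and_logs_bad_variants(self, design_and_cohort):
        cohort, tables, pcs, _ = design_and_cohort
        mono = cohort.dosages.copy()
        j = cohort.variant_index("var0040")
        mono[:, j] = 2.0
        c2 = tg.CohortData(
            dosages=mono,
            subject_ids=cohort.subject_ids,
            variant_meta=cohort.variant_meta,
            covariates=cohort.covariates,
            phenotypes=cohort.phenotypes,
        )
        rec, summary = run_scan(c2, tables["global"], variant_ids=["var0040", "var0041"])
        assert summary.n_skipped == 1
        assert rec["variant_id"].tolist() == ["var0041"]


class TestGenomicLambda:
    def test_null_median_chi2_gives_one(self):
        assert genomic_lambda(chi2=np.full(11, 0.4549364231)) == pytest.approx(1.0, abs=1e-6)

    def test_doubling_chi2_doubles_lambda(self):
        assert genomic_lambda(chi2=np.full(11, 2 * 0.4549364231)) == pytest.approx(2.0, abs=1e-6)

    def test_uniform_p_values_lambda_near_one(self):
        rng = np.random.default_rng(26)
        p = rng.uniform(size=100_000)
        assert genomic_lambda(p=p) == pytest.approx(1.0, abs=0.01)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            genomic_lambda(p=np.array([]))


def _ld_toy():
    """Three synthetic dosage columns with r2(A,B)=0.5, r2(B,C)=0.5, r2(A,C)=0."""
    rng = np.random.default_rng(27)
    z1 = rng.normal(size=4000)
    z2 = rng.normal(size=4000)
    A = z1
    B = (z1 + z2) / np.sqrt(2)
    C = z2
    D = np.column_stack([A, B, C])
    D = (D - D.min()) / (D.max() - D.min()) * 2  # affine into [0, 2]
    meta = pd.DataFrame(
        {
            "variant_id": ["A", "B", "C"],
            "chrom": ["1", "1", "1"],
            "pos": [1000, 2000, 3000],
            "ref": ["A", "A", "A"],
            "alt": ["G", "G", "G"],
            "imputation_r2": [1.0, 1.0, 1.0],
        }
    )
    return D, meta


def _records(pvals, meta):
    return pd.DataFrame(
        {
            "variant_id": meta["variant_id"],
            "chrom": meta["chrom"],
            "pos": meta["pos"],
            "slope2_p": pvals,
        }
    )


class TestClump:
    def test_correlated_pair_forms_one_clump(self):
        D, meta = _ld_toy()
        rec = _records([1e-10, 1e-9, 1.0], meta)  # A, B significant; r2 = 0.5
        index_ids, assign = clump(rec, "slope2", D, meta, r2_threshold=0.1)
        assert index_ids == ["A"]
        assert set(assign["variant_id"]) == {"A", "B"}

    def test_uncorrelated_pair_stays_separate(self):
        D, meta = _ld_toy()
        rec = _records([1e-10, 1.0, 1e-9], meta)  # A, C significant; r2 = 0
        index_ids, _ = clump(rec, "slope2", D, meta, r2_threshold=0.1)
        assert index_ids == ["A", "C"]

    def test_chain_absorbs_middle_only(self):
        # A-B r2=0.5, B-C r2=0.5, A-C r2=0; p ascending A < B < C
        D, meta = _ld_toy()
        rec = _records([1e-12, 1e-10, 1e-9], meta)
        index_ids, assign = clump(rec, "slope2", D, meta, r2_threshold=0.1)
        assert index_ids == ["A", "C"]
        assigned_to_A = assign.loc[assign["index_id"] == "A", "variant_id"].tolist()
        assert "B" in assigned_to_A

    def test_window_limits_absorption(self):
        D, meta = _ld_toy()
        meta = meta.copy()
        meta.loc[1, "pos"] = 5_000_000  # push B outside a 1 Mb window of A
        rec = _records([1e-10, 1e-9, 1.0], meta)
        index_ids, _ = clump(rec, "slope2", D, meta, r2_threshold=0.1, window_kb=1000)
        assert index_ids == ["A", "B"]

    def test_clump_invariants_on_simulated_blocks(self):
        cfg = tg.SimulationConfig(
            n_candidates=600, n_variants=40, ld_block_size=4, ld_flip_prob=0.02, seed=28
        )
        geno, meta = tg.simulate.simulate_genotypes(cfg)
        rng = np.random.default_rng(29)
        rec = _records(10.0 ** -rng.uniform(8, 15, size=40), meta)
        index_ids, assign = clump(rec, "slope2", geno, meta, r2_threshold=0.1)
        pos = meta.set_index("variant_id")
        col = {v: i for i, v in enumerate(meta["variant_id"])}
        for i, a in enumerate(index_ids):
            for b in index_ids[i + 1 :]:
                if pos.loc[a, "chrom"] != pos.loc[b, "chrom"]:
                    continue
                if abs(int(pos.loc[a, "pos"]) - int(pos.loc[b, "pos"])) > 1_000_000:
                    continue
                r2 = np.corrcoef(geno[:, col[a]], geno[:, col[b]])[0, 1] ** 2
                assert r2 < 0.1  # index variants pairwise independent
        for row in assign.itertuples(index=False):
            assert row.r2_with_index >= 0.1 or row.variant_id == row.index_id


class TestLookup:
    def _scan_records(self):
        return pd.DataFrame(
            {
                "variant_id": ["v1", "v2"],
                "chrom": ["1", "2"],
                "pos": [100, 200],
                "effect_allele": ["G", "T"],
                "other_allele": ["A", "C"],
                "eaf": [0.3, 0.2],
                **{
                    f"{b}_{x}": [0.1, -0.2] if x == "beta" else [0.05, 0.08] if x == "se" else [0.04, 0.5]
                    for b in ("intercept", "age", "slope1", "slope2")
                    for x in ("beta", "se", "p")
                },
            }
        )

    def test_allele_flip_negates_betas(self):
        rec = self._scan_records()
        ext = pd.DataFrame({"variant_id": ["v1"], "effect_allele": ["A"], "beta": [0.5]})
        out = lookup_variants(rec, ext)
        assert out["intercept_beta"].iloc[0] == pytest.approx(-0.1)

    def test_absent_variant_reported_untested(self):
        rec = self._scan_records()
        ext = pd.DataFrame({"variant_id": ["nope"], "effect_allele": ["A"]})
        out = lookup_variants(rec, ext)
        assert not out["tested"].iloc[0]
        assert out["note"].iloc[0] == "not tested"

    def test_bonferroni_threshold_166_variants(self):
        rec = self._scan_records()
        ext = pd.DataFrame(
            {"variant_id": [f"x{i}" for i in range(165)] + ["v1"], "effect_allele": ["G"] * 166}
        )
        out = lookup_variants(rec, ext)
        # 0.05 / (166 * 4) = 7.53e-5, the threshold printed as 8e-5
        assert out["bonferroni_threshold"].iloc[0] == pytest.approx(0.05 / 664)
        tested = out[out["tested"] == True]  # noqa: E712
        assert not tested["significant_bonferroni"].any()  # p=0.04 does not survive


class TestPlotTables:
    def test_qq_table_monotone(self):
        rng = np.random.default_rng(30)
        t = qq_table(rng.uniform(size=500))
        assert (np.diff(t["expected_neglog10"]) <= 0).all()
        assert len(t) == 500

    def test_manhattan_table_columns(self):
        rec = pd.DataFrame(
            {"variant_id": ["a"], "chrom": ["1"], "pos": [5], "slope1_p": [1e-4]}
        )
        t = manhattan_table(rec, "slope1")
        assert t["neglog10_p"].iloc[0] == pytest.approx(4.0)
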