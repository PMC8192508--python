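"""Marker calling: sex adjustment, DMP/DEG detection, DMP-TF linking and
hypergeometric overlap enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ageflow import markers as mk
from ageflow.containers import (
    CohortTable,
    ExpressionMatrix,
    GeneAnnotation,
    MethylationMatrix,
)
from ageflow.simulate import SimulationConfig, generate_cohort, generate_true_network, simulate_methylation

from conftest import small_config


def _meth_from_array(arr, samples):
    ids = [f"chr1:{1000 + 10 * i}" for i in range(arr.shape[0])]
    positions = pd.DataFrame(
        {"chrom": "chr1", "pos": [1000 + 10 * i for i in range(arr.shape[0])]}, index=ids
    )
    return MethylationMatrix(positions, pd.DataFrame(arr, index=ids, columns=samples))


def _cohort(ages, sexes):
    return CohortTable(
        pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(len(ages))],
                "age": ages,
                "sex": sexes,
                "smoking": ["non_smoker"] * len(ages),
            }
        )
    )


class TestAdjustSex:
    def test_group_means_shift_to_pooled(self):
        sexes = ["male"] * 4 + ["female"] * 4
        cohort = _cohort(np.linspace(30, 60, 8), sexes)
        arr = np.array([[0.6] * 4 + [0.4] * 4])
        adj = mk.adjust_sex(_meth_from_array(arr, cohort.sample_ids), cohort)
        vals = adj.beta.to_numpy()[0]
        assert vals[:4].mean() == pytest.approx(0.5, abs=1e-12)
        assert vals[4:].mean() == pytest.approx(0.5, abs=1e-12)

    def test_no_sex_effect_is_identity(self):
        rng = np.random.default_rng(1)
        sexes = ["male", "female"] * 5
        cohort = _cohort(np.linspace(25, 70, 10), sexes)
        arr = np.tile(rng.uniform(0.2, 0.8, (6, 1)), (1, 10))
        adj = mk.adjust_sex(_meth_from_array(arr, cohort.sample_ids), cohort)
        np.testing.assert_allclose(adj.beta.to_numpy(), arr, atol=1e-12)

    def test_planted_sex_offset_removed(self):
        cfg = small_config(seed=21, n_samples=200, n_cpg=200, sex_affected_frac=1.0)
        cohort = generate_cohort(cfg)
        _, truth = generate_true_network(cfg)
        meth = simulate_methylation(cohort, cfg, truth)
        adj = mk.adjust_sex(meth, cohort)
        male = (cohort.sexes == "male").to_numpy(float)
        for row in adj.beta.to_numpy()[:50]:
            r = np.corrcoef(row, male)[0, 1]
            assert abs(r) < 0.05

    def test_small_sex_group_skips_with_warning(self):
        cohort = _cohort([30, 40, 50, 60], ["male", "female", "female", "female"])
        m = _meth_from_array(np.full((2, 4), 0.5), cohort.sample_ids)
        with pytest.warns(UserWarning, match="skipped"):
            out = mk.adjust_sex(m, cohort)
        np.testing.assert_array_equal(out.beta.to_numpy(), m.beta.to_numpy())


class TestCallDmps:
    def test_noise_free_slope_gives_perfect_correlation(self):
        ages = np.linspace(20, 70, 10)
        cohort = _cohort(ages, ["male", "female"] * 5)
        arr = np.vstack([0.2 + 0.01 * (ages - 20), np.full(10, 0.5)])
        res = mk.call_dmps(_meth_from_array(arr, cohort.sample_ids), cohort)
        assert len(res) == 1  # constant row untestable
        assert res.attrs["n_untestable"] == 1
        assert res["r"].iloc[0] == pytest.approx(1.0)
        assert bool(res["is_dmp"].iloc[0])

    def test_null_positions_type_one_error_calibrated(self):
        rng = np.random.default_rng(9)
        n_pos, n_samp = 1000, 60
        ages = rng.uniform(20, 74, n_samp)
        cohort = _cohort(ages, ["male", "female"] * (n_samp // 2))
        arr = np.clip(rng.normal(0.5, 0.1, (n_pos, n_samp)), 0.01, 0.99)
        res = mk.call_dmps(_meth_from_array(arr, cohort.sample_ids), cohort)
        frac = res["is_dmp"].mean()
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / n_pos)
        assert abs(frac - 0.05) < half_width

    def test_p_matches_t_transform(self):
        rng = np.random.default_rng(2)
        n = 40
        cohort = _cohort(rng.uniform(20, 74, n), ["male", "female"] * (n // 2))
        arr = np.clip(rng.normal(0.5, 0.1, (20, n)), 0.01, 0.99)
        res = mk.call_dmps(_meth_from_array(arr, cohort.sample_ids), cohort)
        recomputed = mk.pearson_p_from_r(res["r"].to_numpy(), n)
        np.testing.assert_allclose(res["p"].to_numpy(), recomputed, atol=1e-12)

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(3)
        n = 30
        ages = rng.uniform(20, 74, n)
        cohort = _cohort(ages, ["male", "female"] * (n // 2))
        arr = np.clip(rng.normal(0.5, 0.1, (15, n)), 0.01, 0.99)
        m = _meth_from_array(arr, cohort.sample_ids)
        res1 = mk.call_dmps(m, cohort)
        perm = list(rng.permutation(cohort.sample_ids))
        m2 = MethylationMatrix(m.positions.copy(), m.beta[perm])
        res2 = mk.call_dmps(m2, cohort)
        np.testing.assert_allclose(res1["r"].to_numpy(), res2["r"].to_numpy(), atol=1e-12)


class TestCallDegs:
    def test_constant_gene_is_null(self, toy_cohort):
        counts = pd.DataFrame(
            {s: [50, 7] for s in toy_cohort.sample_ids}, index=["flat", "also_flat"]
        )
        res = mk.call_degs(ExpressionMatrix(counts), toy_cohort)
        assert abs(res["lfc_per_year"]).max() < 1e-6
        assert (res["p"] > 0.9).all()

    def test_bh_adjustment_matches_direct_formula(self):
        # BH on sorted raw P: adj_i = min over j>=i of p_j * m / j
        raw = np.array([0.001, 0.01, 0.02, 0.8])
        from statsmodels.stats.multitest import multipletests

        adj = multipletests(raw, method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.004, 0.02, 0.0266667, 0.8], atol=1e-6)

    def test_planted_lfc_recovered_without_bias(self):
        from ageflow.simulate import simulate_all

        errs = []
        for seed in (31, 32, 33, 34):
            st = simulate_all(small_config(seed=seed, n_samples=100, expr_signal_scale=0.0))
            degs = mk.call_degs(st.expression, st.cohort).set_index("gene_id")
            for g, eff in st.truth.deg_effects.items():
                errs.append(degs.loc[g, "lfc_per_year"] - eff)
        assert abs(np.mean(errs)) < 0.005

    def test_padj_at_least_p(self, study):
        degs = mk.call_degs(study.expression, study.cohort)
        assert (degs["p_adj"] >= degs["p"] - 1e-12).all()


class TestLinkDmpToTf:
    @staticmethod
    def _setup(positions, tf_pos=(10_000, 20_000)):
        ann = GeneAnnotation(
            pd.DataFrame(
                {
                    "gene_id": ["TF1"],
                    "chrom": ["chr1"],
                    "tss": [tf_pos[0]],
                    "body_start": [tf_pos[0]],
                    "body_end": [tf_pos[1]],
                    "strand": ["+"],
                    "is_tf": [True],
                }
            )
        )
        rng = np.random.default_rng(0)
        n = 30
        ages = np.linspace(20, 74, n)
        cohort = _cohort(ages, ["male", "female"] * (n // 2))
        beta_signal = np.clip(0.3 + 0.006 * (ages - 20) + rng.normal(0, 0.02, n), 0, 1)
        ids = [f"chr1:{p}" for p in positions]
        pos_df = pd.DataFrame({"chrom": "chr1", "pos": positions}, index=ids)
        beta = pd.DataFrame(
            np.tile(beta_signal, (len(positions), 1)), index=ids, columns=cohort.sample_ids
        )
        # constant reference genes keep size factors from absorbing the signal
        counts = pd.DataFrame(
            {
                s: [int(100 * np.exp(0.02 * (a - 40))), 200, 300, 500]
                for s, a in zip(cohort.sample_ids, ages)
            },
            index=["TF1", "R1", "R2", "R3"],
        )
        dmps = pd.DataFrame(
            {
                "feature_id": ids,
                "r": [0.9] * len(ids),
                "p": [1e-6] * len(ids),
                "direction": [1] * len(ids),
                "is_dmp": [True] * len(ids),
            }
        )
        return dmps, ann, MethylationMatrix(pos_df, beta), ExpressionMatrix(counts), cohort

    def test_cpg_beyond_window_excluded(self):
        # 6,000 bp past the last body base (19,999)
        dmps, ann, meth, expr, _ = self._setup([25_999])
        links = mk.link_dmp_to_tf(dmps, ann, meth, expr)
        assert links.empty

    def test_cpg_at_exact_window_boundary_included(self):
        # exactly 5,000 bp from the last body base: "within 5 kb" is inclusive
        dmps, ann, meth, expr, _ = self._setup([24_999])
        links = mk.link_dmp_to_tf(dmps, ann, meth, expr)
        assert len(links) == 1
        assert links["distance"].iloc[0] == 5000

    def test_cpg_inside_gene_body_distance_zero(self):
        dmps, ann, meth, expr, _ = self._setup([15_000])
        links = mk.link_dmp_to_tf(dmps, ann, meth, expr)
        assert links["distance"].iloc[0] == 0

    def test_most_significant_link_is_representative(self, study, analysis):
        links = analysis.links
        for tf, grp in links.groupby("tf_gene_id"):
            rep = grp[grp["representative"]]
            assert len(rep) == 1
            assert rep["p"].iloc[0] == grp["p"].min()


class TestOverlapEnrichment:
    def test_epigenetic_marker_panel_value(self):
        res = mk.overlap_enrichment(2_682_537, 32, 222_032, 32)
        assert res["p"] == pytest.approx(2.3e-35, rel=0.05)

    def test_transcriptomic_marker_panel_value(self):
        res = mk.overlap_enrichment(19_229, 50, 188, 20)
        assert res["p"] == pytest.approx(8.3e-28, rel=0.05)

    def test_zero_overlap_is_certain(self):
        assert mk.overlap_enrichment(1000, 10, 50, 0)["p"] == pytest.approx(1.0)

    def test_duality_in_marker_and_selection_counts(self):
        a = mk.overlap_enrichment(5000, 40, 300, 12)["p"]
        b = mk.overlap_enrichment(5000, 300, 40, 12)["p"]
        assert a == pytest.approx(b, rel=1e-10)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            mk.overlap_enrichment(100, 10, 20, 15)
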