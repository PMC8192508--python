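"""Per-sample DACs, age association, input influence and reverse-target
ranking."""

import numpy as np
import pandas as pd
import pytest

from ageflow import sfa, targets as tg
from ageflow.containers import CohortTable, MethylationMatrix, SignedGRN


def _cohort(ages):
    return CohortTable(
        pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(len(ages))],
                "age": ages,
                "sex": ["male", "female"] * (len(ages) // 2),
                "smoking": ["non_smoker"] * len(ages),
            }
        )
    )


def _meth(rows, samples):
    ids = [f"chr1:{100 + i}" for i in range(rows.shape[0])]
    positions = pd.DataFrame(
        {"chrom": "chr1", "pos": [100 + i for i in range(rows.shape[0])]}, index=ids
    )
    return MethylationMatrix(positions, pd.DataFrame(rows, index=ids, columns=samples))


def _rep_links(pairs):
    return pd.DataFrame(
        [
            {"dmp_id": d, "tf_gene_id": t, "distance": 0, "r": r, "p": 1e-4,
             "representative": True}
            for d, t, r in pairs
        ]
    )


class TestComputeSampleDacs:
    def _setup(self, seed=0, n=20):
        rng = np.random.default_rng(seed)
        ages = np.linspace(20, 74, n)
        cohort = _cohort(ages)
        beta = np.clip(
            0.3 + 0.007 * (ages - 20) + rng.normal(0, 0.03, (1, n)), 0.01, 0.99
        )
        meth = _meth(beta, cohort.sample_ids)
        net = SignedGRN.from_edges(
            [("TFA", "M", 1), ("M", "OUT", -1)], inputs=["TFA"], outputs=["OUT"]
        )
        links = _rep_links([("chr1:100", "TFA", 0.9)])
        return net, meth, links, cohort

    def test_sample_at_cohort_mean_has_zero_activity(self):
        net, meth, links, cohort = self._setup()
        acts = tg.compute_sample_dacs(net, meth, links, cohort)
        b = meth.beta.to_numpy()[0]
        closest = np.argmin(np.abs(b - b.mean()))
        # input scales linearly with the z-score, so near-mean sample ~ 0
        assert abs(acts.iloc[:, closest]).max() < abs(acts.to_numpy()).max() * 0.2

    def test_matches_per_sample_single_solves(self):
        net, meth, links, cohort = self._setup(seed=1)
        acts = tg.compute_sample_dacs(net, meth, links, cohort)
        prob = sfa.build_weight_matrix(net, alpha=0.5)
        for s in cohort.sample_ids:
            signals = sfa.methylation_to_input(meth, links, s)
            b = sfa.input_vector(prob, signals)
            x = sfa.solve_steady_state(prob.with_b(b)).x
            np.testing.assert_allclose(acts[s].to_numpy(), x.to_numpy(), atol=1e-12)

    def test_linearity_doubled_inputs_double_activities(self):
        net, meth, links, cohort = self._setup(seed=2)
        prob = sfa.build_weight_matrix(net, alpha=0.5)
        signals = sfa.methylation_to_input(meth, links, cohort.sample_ids[0])
        b = sfa.input_vector(prob, signals)
        x1 = sfa.solve_steady_state(prob.with_b(b)).x.to_numpy()
        x2 = sfa.solve_steady_state(prob.with_b(2 * b)).x.to_numpy()
        np.testing.assert_allclose(x2, 2 * x1, atol=1e-12)


class TestDacAgeAssociation:
    def test_negative_edge_flips_classification(self):
        n = 30
        ages = np.linspace(20, 74, n)
        cohort = _cohort(ages)
        rng = np.random.default_rng(3)
        beta = np.clip(0.3 + 0.008 * (ages - 20) + rng.normal(0, 0.02, (1, n)), 0.01, 0.99)
        meth = _meth(beta, cohort.sample_ids)
        links = _rep_links([("chr1:100", "TFA", 0.9)])
        degs = pd.DataFrame(
            {"gene_id": ["OUT"], "lfc_per_year": [0.02], "p": [1e-5],
             "p_adj": [1e-4], "is_deg": [True]}
        )
        classes = {}
        for sign in (1, -1):
            net = SignedGRN.from_edges(
                [("TFA", "M", 1), ("M", "OUT", sign)], inputs=["TFA"], outputs=["OUT"]
            )
            acts = tg.compute_sample_dacs(net, meth, links, cohort)
            dac = tg.dac_age_association(acts, cohort, degs)
            classes[sign] = dac["class"].iloc[0]
        assert classes[1] == "consistent"
        assert classes[-1] == "inconsistent"

    def test_permuted_ages_flag_near_nominal_rate(self):
        rng = np.random.default_rng(6)
        n_feat, n_samp = 1000, 80
        ages = rng.permutation(np.linspace(20, 74, n_samp))
        cohort = _cohort(ages)
        acts = pd.DataFrame(
            rng.normal(size=(n_feat, n_samp)),
            index=[f"g{i}" for i in range(n_feat)],
            columns=cohort.sample_ids,
        )
        degs = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n_feat)],
                "lfc_per_year": rng.choice([-0.02, 0.02], n_feat),
                "p": 1e-4,
                "p_adj": 1e-3,
                "is_deg": True,
            }
        )
        dac = tg.dac_age_association(acts, cohort, degs)
        frac = (dac["class"] != "nonsignificant").mean()
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / n_feat)
        assert abs(frac - 0.05) < half_width

    def test_constant_activity_is_nonsignificant_with_zero_r(self):
        cohort = _cohort(np.linspace(20, 74, 10))
        acts = pd.DataFrame(
            np.full((1, 10), 0.4), index=["g"], columns=cohort.sample_ids
        )
        degs = pd.DataFrame(
            {"gene_id": ["g"], "lfc_per_year": [0.02], "p": [1e-4],
             "p_adj": [1e-3], "is_deg": [True]}
        )
        dac = tg.dac_age_association(acts, cohort, degs)
        assert dac["class"].iloc[0] == "nonsignificant"
        assert dac["r_age"].iloc[0] == 0.0


class TestInputInfluence:
    def test_single_input_has_unit_influence(self):
        n = 20
        ages = np.linspace(20, 74, n)
        cohort = _cohort(ages)
        rng = np.random.default_rng(5)
        beta = np.clip(0.3 + 0.008 * (ages - 20) + rng.normal(0, 0.02, (1, n)), 0.01, 0.99)
        meth = _meth(beta, cohort.sample_ids)
        links = _rep_links([("chr1:100", "TFA", 0.9)])
        net = SignedGRN.from_edges(
            [("TFA", "M", 1), ("M", "OUT", 1)], inputs=["TFA"], outputs=["OUT"]
        )
        infl = tg.input_influence(net, meth, links, cohort)
        assert infl.loc["TFA", "OUT"] == pytest.approx(1.0)

    def test_columns_sum_to_one_and_slopes_add(self, study, analysis):
        res = analysis
        infl = res.influence
        sums = infl.sum(axis=0).to_numpy()
        np.testing.assert_allclose(sums[np.isfinite(sums)], 1.0, atol=1e-10)
        # per-input age slopes of contributions add to the slope of the total
        slopes = infl.attrs["raw_slopes"]
        ages = study.cohort.ages.reindex(res.activities.columns).to_numpy()
        ages_c = ages - ages.mean()
        denom = ages_c @ ages_c
        for g in slopes.columns[:10]:
            y = res.activities.loc[g].to_numpy()
            total = ages_c @ (y - y.mean()) / denom
            assert slopes[g].sum() == pytest.approx(total, abs=1e-10)


def _scan_toy():
    edges = [
        ("IN", "A", 1), ("IN", "B", -1), ("A", "B", 1),
        ("A", "O1", 1), ("A", "O2", -1), ("B", "O2", 1), ("B", "O3", 1),
        ("IN", "C", 1), ("C", "O3", -1), ("C", "O1", 1),
    ]
    net = SignedGRN.from_edges(edges, inputs=["IN"], outputs=["O1", "O2", "O3"])
    dacs = pd.DataFrame(
        {
            "gene_id": ["O1", "O2", "O3"],
            "r_age": [0.5, -0.5, 0.5],
            "p": [0.01] * 3,
            "dac_direction": [1, -1, 1],
            "class": ["consistent"] * 3,
        }
    )
    return net, dacs


class TestPerturbNodeScan:
    def test_matches_brute_force_enumeration(self):
        net, dacs = _scan_toy()
        scores = tg.perturb_node_scan(net, dacs)
        prob = sfa.build_weight_matrix(net, alpha=0.5)
        directions = dacs.set_index("gene_id")["dac_direction"]
        for _, row in scores.iterrows():
            x = sfa.solve_steady_state(
                prob.with_b({row["node_id"]: float(row["perturb_sign"])})
            ).x
            expected = sum(
                1
                for g in directions.index
                if abs(x[g]) > 1e-9 and np.sign(x[g]) == -directions[g]
            )
            assert row["n_reversed"] == expected

    def test_sign_antisymmetry_and_disjoint_reversal_sets(self):
        net, dacs = _scan_toy()
        prob = sfa.build_weight_matrix(net, alpha=0.5)
        directions = dacs.set_index("gene_id")["dac_direction"]
        for m in net.intermediates:
            xp = sfa.solve_steady_state(prob.with_b({m: 1.0})).x
            xm = sfa.solve_steady_state(prob.with_b({m: -1.0})).x
            np.testing.assert_array_equal(xm.to_numpy(), -xp.to_numpy())
            rev_p = {g for g in directions.index
                     if abs(xp[g]) > 1e-9 and np.sign(xp[g]) == -directions[g]}
            rev_m = {g for g in directions.index
                     if abs(xm[g]) > 1e-9 and np.sign(xm[g]) == -directions[g]}
            assert not rev_p & rev_m

    def test_reversal_count_invariant_to_perturbation_magnitude(self):
        net, dacs = _scan_toy()
        prob = sfa.build_weight_matrix(net, alpha=0.5)
        directions = dacs.set_index("gene_id")["dac_direction"]
        for scale in (1.0, 7.3, 1e4):
            x = sfa.solve_steady_state(prob.with_b({"A": scale})).x
            n_rev = sum(
                1 for g in directions.index
                if abs(x[g]) > 1e-9 and np.sign(x[g]) == -directions[g]
            )
            if scale == 1.0:
                baseline = n_rev
            assert n_rev == baseline

    def test_constructed_full_reverser(self):
        # a node inhibiting every up-in-aging DEG reverses all of them at +1
        edges = [("IN", "M", 1)] + [(f"M", f"O{i}", -1) for i in range(5)]
        net = SignedGRN.from_edges(edges, inputs=["IN"], outputs=[f"O{i}" for i in range(5)])
        dacs = pd.DataFrame(
            {
                "gene_id": [f"O{i}" for i in range(5)],
                "r_age": [0.5] * 5,
                "p": [0.01] * 5,
                "dac_direction": [1] * 5,
                "class": ["consistent"] * 5,
            }
        )
        scores = tg.perturb_node_scan(net, dacs)
        best = scores[(scores["node_id"] == "M") & (scores["perturb_sign"] == 1)]
        assert int(best["n_reversed"].iloc[0]) == 5


class TestRankTargets:
    @staticmethod
    def _scores(n_nodes, n_reversed=None, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_nodes):
            for sigma in (1, -1):
                rows.append(
                    {
                        "node_id": f"m{i:03d}",
                        "perturb_sign": sigma,
                        "n_reversed": (
                            n_reversed if n_reversed is not None else int(rng.integers(0, 20))
                        ),
                        "tiebreak_mass": float(rng.random()),
                    }
                )
        return pd.DataFrame(rows)

    def test_top_five_percent_of_167_intermediates_is_8(self):
        ranked = tg.rank_targets(self._scores(167))
        assert int(ranked["candidate"].sum()) == 8

    def test_all_tied_scores_resolve_lexicographically(self):
        scores = self._scores(40, n_reversed=5)
        scores["tiebreak_mass"] = 1.0
        ranked = tg.rank_targets(scores)
        assert ranked.iloc[0]["node_id"] == "m000"
        assert int(ranked["candidate"].sum()) == 2

    def test_ranking_invariant_to_row_order(self):
        scores = self._scores(30, seed=5)
        shuffled = scores.sample(frac=1.0, random_state=9).reset_index(drop=True)
        r1 = tg.rank_targets(scores).reset_index(drop=True)
        r2 = tg.rank_targets(shuffled).reset_index(drop=True)
        pd.testing.assert_frame_equal(r1, r2)

    def test_minimum_one_candidate(self):
        ranked = tg.rank_targets(self._scores(5))
        assert int(ranked["candidate"].sum()) == 1
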