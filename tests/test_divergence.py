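"""Divergence screen, Ward gene grouping, trajectories, correlation, ORA."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from mitosig.containers import ExpressionMatrix, GeneSignature
from mitosig.divergence import (
    TimecourseDesign,
    cluster_gene_groups,
    fit_divergence,
    group_signature_trajectory,
    ora_hypergeometric,
    signature_correlation,
    _standardize_genes,
)
from mitosig.simulate import SimConfig, simulate_timecourse

from .conftest import hypergeom_upper_tail, scipy_merge_sequence, ward_merge_sequence_bruteforce


def small_design(n_rep=2):
    rows = []
    for geno in ("wild-type", "transgenic"):
        for t in (1.0, 2.0, 6.0):
            for r in range(n_rep):
                rows.append({"sample": f"{geno}_{t}_{r}", "genotype": geno, "age": t})
    return pd.DataFrame(rows).set_index("sample")


class TestDesignValidation:
    def test_single_timepoint_rejected(self):
        bad = small_design()
        bad = bad[bad["age"] == 1.0]
        bad["genotype"] = ["wild-type", "wild-type", "transgenic", "transgenic"]
        with pytest.raises(ValueError, match="timepoints"):
            TimecourseDesign(bad)

    def test_unknown_genotype_label_rejected(self):
        bad = small_design()
        bad.iloc[0, bad.columns.get_loc("genotype")] = "het"
        with pytest.raises(ValueError, match="unknown genotype"):
            TimecourseDesign(bad)


class TestFitDivergence:
    def test_noiseless_slope_recovered_and_q_monotone(self):
        design = small_design()
        d = TimecourseDesign(design)
        g, t = d.genotype, d.age
        data = pd.DataFrame(
            {
                "diverging": 5.0 + (g - 0.5) * 2.0 * t,   # interaction slope 2
                "null": 5.0 + 0.3 * t,
                "noisy": 5.0 + np.linspace(-0.1, 0.1, len(g)) * 1.0,
            },
            index=design.index,
        )
        fit = fit_divergence(ExpressionMatrix(data), d, alpha=0.05)
        assert fit.table.loc["diverging", "beta_interaction"] == pytest.approx(2.0)
        assert fit.table.loc["diverging", "p"] < 1e-12
        assert (fit.table["q"] >= fit.table["p"] - 1e-15).all()
        assert fit.selected_genes == ["diverging"]

    def test_permuted_labels_select_near_alpha_fraction(self):
        """Permutation null: average selection count stays near the false
        positive budget (BH under the global null rejects rarely)."""
        rng = np.random.default_rng(0)
        expr, design, _ = simulate_timecourse(
            400, 0.0, 0.0, SimConfig(seed=10, noise_sd=0.5)
        )
        hits = 0
        n_perm = 50
        for _ in range(n_perm):
            permuted = design.copy()
            permuted["genotype"] = rng.permutation(permuted["genotype"].to_numpy())
            try:
                d = TimecourseDesign(permuted)
            except ValueError:
                continue
            fit = fit_divergence(expr, d, alpha=0.05)
            hits += len(fit.selected_genes) > 0
        assert hits / n_perm <= 0.12

    def test_recall_at_three_sd_effect(self):
        cfg = SimConfig(seed=21, noise_sd=0.4, n_replicates=3)
        expr, design, truth = simulate_timecourse(500, 0.1, 3 * cfg.noise_sd, cfg)
        fit = fit_divergence(expr, TimecourseDesign(design), alpha=0.05)
        selected = set(fit.selected_genes)
        true_set = set(truth.index[truth])
        recall = len(selected & true_set) / len(true_set)
        assert recall >= 0.9

    def test_misaligned_design_rejected(self):
        expr, design, _ = simulate_timecourse(10, 0.1, 1.0, SimConfig(seed=0))
        with pytest.raises(ValueError, match="align"):
            fit_divergence(
                ExpressionMatrix(expr.data.iloc[::-1]), TimecourseDesign(design)
            )


class TestWardClustering:
    def test_matches_bruteforce_oracle_on_random_instances(self, rng):
        for _ in range(30):
            points = rng.normal(size=(8, 5))
            Z = hierarchy.linkage(points, method="ward")
            assert scipy_merge_sequence(Z, 8) == ward_merge_sequence_bruteforce(points)

    def test_three_archetypes_recovered_exactly(self):
        t = np.array([1.0, 2.0, 6.0, 1.0, 2.0, 6.0])
        arche = {1: t, 2: -t, 3: np.array([1, -1, 1, -1, 1, -1], dtype=float)}
        cols = {}
        for gid, traj in arche.items():
            for i in range(4):
                cols[f"a{gid}_g{i}"] = traj * (1 + 0.01 * i)
        expr = ExpressionMatrix(pd.DataFrame(cols, index=[f"s{i}" for i in range(6)]))
        groups = cluster_gene_groups(expr, k=3)
        for gid in (1, 2, 3):
            members = {g for g in groups.index if g.startswith(f"a{gid}")}
            assert groups[list(members)].nunique() == 1

    def test_duplicate_genes_share_a_cluster_and_gene_order_irrelevant(self, rng):
        data = pd.DataFrame(
            rng.normal(size=(10, 6)), columns=[f"g{i}" for i in range(6)]
        )
        data["g_dup"] = data["g0"]
        expr = ExpressionMatrix(data)
        groups = cluster_gene_groups(expr, k=3)
        assert groups["g0"] == groups["g_dup"]
        shuffled = ExpressionMatrix(data[list(rng.permutation(data.columns))])
        regrouped = cluster_gene_groups(shuffled, k=3)
        # same partition (group ids may be renamed)
        for a in data.columns:
            for b in data.columns:
                assert (groups[a] == groups[b]) == (regrouped[a] == regrouped[b])

    def test_k_larger_than_gene_count_rejected(self, small_expr):
        with pytest.raises(ValueError, match="exceeds"):
            cluster_gene_groups(small_expr, k=10)


class TestTrajectories:
    def test_constant_matrix_scores_zero(self):
        design = small_design()
        data = pd.DataFrame(
            {"a": 3.0, "b": 7.0}, index=design.index, dtype=float
        )
        agg = group_signature_trajectory(
            ExpressionMatrix(data), ["a", "b"], TimecourseDesign(design)
        )
        assert (agg["mean"] == 0.0).all()

    def test_single_gene_signature_reproduces_gene_z_trajectory(self):
        design = small_design()
        d = TimecourseDesign(design)
        vals = pd.Series(np.arange(len(design), dtype=float), index=design.index)
        expr = ExpressionMatrix(vals.to_frame("g"))
        agg = group_signature_trajectory(expr, ["g"], d)
        z = (vals - vals.mean()) / vals.std(ddof=1)
        expected = z.groupby([d.genotype, d.age]).mean()
        np.testing.assert_allclose(agg["mean"].to_numpy(), expected.to_numpy())

    def test_divergent_group_trajectory_directions(self):
        cfg = SimConfig(seed=30, noise_sd=0.05)
        expr, design, truth = simulate_timecourse(60, 0.25, 1.0, cfg)
        d = TimecourseDesign(design)
        agg = group_signature_trajectory(expr, truth.index[truth], d)
        for geno, sign in ((1, 1.0), (0, -1.0)):
            sub = agg[agg["genotype"] == geno].sort_values("age")
            assert (np.diff(sub["mean"]) * sign > 0).all()


class TestSignatureCorrelation:
    def test_affine_flip_and_independent(self, rng):
        a = pd.Series(rng.normal(size=500))
        assert signature_correlation(a, 3 * a + 1)["pearson_r"] == pytest.approx(1.0)
        assert signature_correlation(a, -a)["pearson_r"] == pytest.approx(-1.0)
        r = signature_correlation(a, pd.Series(rng.normal(size=500)))["pearson_r"]
        assert abs(r) < 0.1


class TestOra:
    def test_group_equal_set_equal_universe_gives_one(self):
        universe = [f"g{i}" for i in range(8)]
        out = ora_hypergeometric(universe, {"all": universe}, universe)
        assert out.loc["all", "p"] == pytest.approx(1.0)

    def test_worked_closed_form_value(self):
        universe = [f"g{i}" for i in range(20)]
        group = universe[:5]
        out = ora_hypergeometric(group, {"hit": group}, universe)
        assert out.loc["hit", "p"] == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_zero_overlap_with_small_set_near_one(self):
        universe = [f"g{i}" for i in range(25)]
        out = ora_hypergeometric(universe[:3], {"s": universe[-2:]}, universe)
        assert out.loc["s", "p"] > 0.9

    def test_exhaustive_agreement_with_analytic_tail(self):
        """All (M <= 30, K, n, overlap-achievable) configurations match the
        combinatorial upper-tail sum."""
        rng = np.random.default_rng(4)
        for M in (5, 9, 14, 21, 30):
            universe = [f"g{i}" for i in range(M)]
            for K in range(1, M + 1, max(1, M // 4)):
                for n in range(1, M + 1, max(1, M // 4)):
                    members = list(rng.choice(universe, size=K, replace=False))
                    group = list(rng.choice(universe, size=n, replace=False))
                    x = len(set(members) & set(group))
                    out = ora_hypergeometric(group, {"s": members}, universe)
                    assert out.loc["s", "p"] == pytest.approx(
                        hypergeom_upper_tail(x, M, K, n), rel=1e-10
                    )

    def test_group_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            ora_hypergeometric(["x"], {"s": ["a"]}, ["a", "b"])


def test_standardize_genes_rows_are_unit_variance(rng):
    data = pd.DataFrame(rng.normal(size=(12, 5)))
    z = _standardize_genes(data)
    np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
    np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-12)
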