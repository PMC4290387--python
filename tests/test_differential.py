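"""Permutation DE machinery: transforms, statistics, exact enumeration, FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epimarks.differential import (
    PairwiseDesign,
    median_positive_filter,
    double_quantile_transform,
    species_lm_stat,
    enumerate_species_label_assignments,
    permutation_de_test,
    classify_de,
    direction_consistent,
    overlap_fold_enrichment,
)


@pytest.fixture
def mini_design():
    """2+2 individuals, both sexes per species."""
    return PairwiseDesign(
        species_a="A",
        species_b="B",
        individual_ids=["A1", "A2", "B1", "B2"],
        species=np.array(["A", "A", "B", "B"]),
        sex=np.array(["M", "F", "M", "F"]),
    )


class TestMedianFilter:
    def test_all_zero_gene_excluded(self, mini_design):
        m = pd.DataFrame(
            np.zeros((2, 4)), index=["g0", "g1"], columns=mini_design.individual_ids
        )
        m.loc["g1"] = [1, 2, 3, 4]
        assert median_positive_filter(m, mini_design) == ["g1"]

    def test_median_exactly_zero_excluded(self, mini_design):
        m = pd.DataFrame(
            [[-1.0, -1.0, 1.0, 1.0]], index=["g0"], columns=mini_design.individual_ids
        )
        assert median_positive_filter(m, mini_design) == []

    def test_matches_brute_force(self, mini_design):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(
            rng.normal(size=(10, 4)),
            index=[f"g{i}" for i in range(10)],
            columns=mini_design.individual_ids,
        )
        got = set(median_positive_filter(m, mini_design))
        expected = {g for g in m.index if np.median(m.loc[g]) > 0}
        assert got == expected


class TestDoubleQuantileTransform:
    def test_monotone_transform_invariance(self, mini_design):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(
            rng.normal(size=(8, 4)),
            index=[f"g{i}" for i in range(8)],
            columns=mini_design.individual_ids,
        )
        a = double_quantile_transform(m, mini_design)
        b = double_quantile_transform(np.exp(m) * 3 + 1, mini_design)
        pd.testing.assert_frame_equal(a, b)

    def test_each_gene_gets_identical_normal_scores(self, mini_design):
        # circulant ranks: every gene holds a different rank in every
        # individual, so the stage-2 scores are tie-free by construction
        g = 6
        m = pd.DataFrame(
            [[(i + j) % g for j in range(4)] for i in range(g)],
            index=[f"g{i}" for i in range(g)],
            columns=mini_design.individual_ids,
            dtype=float,
        )
        out = double_quantile_transform(m, mini_design)
        rows = np.sort(out.to_numpy(), axis=1)
        assert np.allclose(rows, rows[0])
        expected = stats.norm.ppf(np.arange(1, 5) / 5)
        assert np.allclose(rows[0], expected)

    def test_matches_brute_force_rank_ppf(self, mini_design):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(
            rng.normal(size=(5, 4)),
            index=[f"g{i}" for i in range(5)],
            columns=mini_design.individual_ids,
        )
        out = double_quantile_transform(m, mini_design)
        stage1 = np.empty((5, 4))
        for j in range(4):
            r = stats.rankdata(m.iloc[:, j])
            stage1[:, j] = stats.norm.ppf(r / 6)
        stage2 = np.empty((5, 4))
        for i in range(5):
            r = stats.rankdata(stage1[i])
            stage2[i] = stats.norm.ppf(r / 5)
        assert np.allclose(out.to_numpy(), stage2)


class TestSpeciesLmStat:
    def test_constant_y_gives_zero(self, toy_design):
        assert species_lm_stat(np.full(16, 3.0), toy_design) == 0.0

    def test_equals_pooled_t_without_sex_effect(self):
        """Balanced two-group design, no sex column variation: the species
        t equals the classic pooled-variance two-sample t."""
        design = PairwiseDesign(
            species_a="A",
            species_b="B",
            individual_ids=[f"i{k}" for k in range(8)],
            species=np.array(["A"] * 4 + ["B"] * 4),
            sex=np.array(["M"] * 8),
        )
        rng = np.random.default_rng(0)
        y = rng.normal(size=8)
        with pytest.warns(UserWarning):
            got = permutation_de_test(
                pd.DataFrame([y, y * 2 + 1], index=["g0", "g1"], columns=design.individual_ids),
                design,
            )
        t_manual = stats.ttest_ind(y[:4], y[4:], equal_var=True).statistic
        assert got.table.loc["g0", "t_stat"] == pytest.approx(t_manual, abs=1e-10)

    def test_shift_invariance(self, toy_design):
        rng = np.random.default_rng(5)
        y = rng.normal(size=16)
        assert species_lm_stat(y, toy_design) == pytest.approx(
            species_lm_stat(y + 100.0, toy_design)
        )


class TestEnumeration:
    def test_full_design_counts(self):
        assert enumerate_species_label_assignments(16, 8).shape == (12870, 16)
        assert enumerate_species_label_assignments(15, 8).shape == (6435, 15)

    def test_four_choose_two_listing(self):
        got = enumerate_species_label_assignments(4, 2)
        expected = [
            [1, 1, 0, 0],
            [1, 0, 1, 0],
            [1, 0, 0, 1],
            [0, 1, 1, 0],
            [0, 1, 0, 1],
            [0, 0, 1, 1],
        ]
        assert got.astype(int).tolist() == expected

    def test_row_sums_and_uniqueness(self):
        a = enumerate_species_label_assignments(7, 3)
        assert a.shape[0] == 35
        assert (a.sum(axis=1) == 3).all()
        assert len({tuple(r) for r in a.astype(int)}) == 35

    def test_refuses_oversized_designs(self):
        with pytest.raises(ValueError, match="sampling"):
            enumerate_species_label_assignments(31, 15)

    def test_degenerate_group_sizes_rejected(self):
        with pytest.raises(ValueError):
            enumerate_species_label_assignments(8, 0)


def _brute_force_perm_test(matrix, design):
    """Oracle: loop over all label assignments with per-gene OLS t-stats."""
    n = design.n_total
    k = design.n_group_a
    sex = design.sex_numeric()
    assignments = list(itertools.combinations(range(n), k))
    obs = tuple(np.flatnonzero(design.group_a_mask()))
    t_abs = np.zeros((len(assignments), len(matrix)))
    for a_i, combo in enumerate(assignments):
        lab = np.zeros(n)
        lab[list(combo)] = 1.0
        x = np.column_stack([np.ones(n), sex, lab])
        if np.linalg.matrix_rank(x) < 3:
            x = np.column_stack([np.ones(n), lab])
        xtx_inv = np.linalg.inv(x.T @ x)
        p = x.shape[1]
        for g_i, (_, row) in enumerate(matrix.iterrows()):
            y = row.to_numpy(dtype=float)
            beta = xtx_inv @ x.T @ y
            resid = y - x @ beta
            dof = n - p
            sigma2 = resid @ resid / dof
            if sigma2 == 0:
                t_abs[a_i, g_i] = 0.0
            else:
                t_abs[a_i, g_i] = abs(
                    beta[-1] / np.sqrt(sigma2 * xtx_inv[-1, -1])
                )
    obs_idx = assignments.index(obs)
    k_total = len(assignments)
    # same tie-quantization convention as the implementation
    t_abs = t_abs.astype(np.float32)
    p_obs = (t_abs >= t_abs[obs_idx][None, :]).mean(axis=0)
    p_perm = np.array(
        [
            [(t_abs[:, g] >= t_abs[a, g]).mean() for g in range(t_abs.shape[1])]
            for a in range(k_total)
        ]
    )
    fdr = {}
    for t in sorted(set(p_obs)):
        mean_null = (p_perm <= t).sum() / k_total
        fdr[t] = mean_null / (p_obs <= t).sum()
    # monotonize ascending
    running = 0.0
    fdr_mono = {}
    for t in sorted(fdr):
        running = max(running, fdr[t])
        fdr_mono[t] = min(running, 1.0)
    return p_obs, np.array([fdr_mono[t] for t in p_obs])


def test_permutation_test_matches_exhaustive_oracle(mini_design):
    """2+2 individuals, 3 genes: p and FDR equal brute-force enumeration."""
    rng = np.random.default_rng(9)
    m = pd.DataFrame(
        rng.normal(size=(3, 4)),
        index=["g0", "g1", "g2"],
        columns=mini_design.individual_ids,
    )
    res = permutation_de_test(m, mini_design)
    p_oracle, fdr_oracle = _brute_force_perm_test(m, mini_design)
    assert np.allclose(res.table["p"].to_numpy(), p_oracle)
    assert np.allclose(res.table["fdr"].to_numpy(), fdr_oracle)
    assert res.n_assignments == 6


def test_maximal_separation_gives_minimal_p(toy_design):
    """A perfectly separated gene attains the smallest achievable p.

    In a balanced design the complement of the observed labelling yields the
    same |t|, so the minimum two-sided permutation p is 2/K."""
    y = np.r_[np.full(8, 5.0), np.zeros(8)] + np.r_[np.arange(8) * 1e-3, np.arange(8) * 1e-3]
    m = pd.DataFrame([y, y[::-1]], index=["g0", "g1"], columns=toy_design.individual_ids)
    res = permutation_de_test(m, toy_design)
    assert res.table.loc["g0", "p"] == pytest.approx(2 / 12870)


def test_degenerate_gene_gets_p_one(mini_design):
    m = pd.DataFrame(
        [[1.0, 1.0, 1.0, 1.0], [0.0, 1.0, 2.0, 3.0]],
        index=["flat", "g1"],
        columns=mini_design.individual_ids,
    )
    res = permutation_de_test(m, mini_design)
    assert res.table.loc["flat", "p"] == 1.0


def test_label_swap_antisymmetry(toy_design):
    """Swapping the species labels flips effect signs, keeps p and FDR."""
    rng = np.random.default_rng(12)
    m = pd.DataFrame(
        rng.normal(size=(12, 16)),
        index=[f"g{i}" for i in range(12)],
        columns=toy_design.individual_ids,
    )
    res = permutation_de_test(m, toy_design)
    swapped = PairwiseDesign(
        species_a="B",
        species_b="A",
        individual_ids=toy_design.individual_ids,
        species=toy_design.species,
        sex=toy_design.sex,
    )
    res2 = permutation_de_test(m, swapped)
    assert np.allclose(res.table["p"], res2.table["p"])
    assert np.allclose(res.table["fdr"], res2.table["fdr"])
    assert np.allclose(res.table["effect"], -res2.table["effect"])


class TestClassifyDe:
    def test_cutoff_zero_empty_unless_exact_zero(self, null_matrix, toy_design):
        res = permutation_de_test(null_matrix, toy_design)
        assert classify_de(res, 0.0) == set(
            res.table.loc[res.table["fdr"] == 0.0, "gene_id"]
        )

    def test_cutoff_one_keeps_all(self, null_matrix, toy_design):
        res = permutation_de_test(null_matrix, toy_design)
        assert classify_de(res, 1.0) == set(null_matrix.index)


@pytest.mark.parametrize("seed", [29, 30])
def test_de_recovery_on_shifted_genes(seed):
    """10% shifted genes at large effect: sensitivity > 0.8, FDR <= 1.5x nominal.

    Shifts use the fixed-magnitude signed distribution, so every shifted
    gene either has a large expression effect for the tested pair or is
    exactly null for it (identical shift in both species)."""
    from epimarks import SimulationConfig, simulate_cohort
    from epimarks.synthetic import simulate_observed_matrices

    cfg = SimulationConfig(
        n_genes=1000,
        n_species=2,
        seed=seed,
        species_shift_fraction=0.1,
        species_shift_scale=0.4,
        shift_distribution="signed",
        sigma_structural=2.0,
        sigma_species=0.0,
        emulate_missing_individual=False,
    )
    sample_table, _, truth = simulate_cohort(cfg)
    _, expr = simulate_observed_matrices(truth, cfg)
    design = PairwiseDesign.from_sample_table(sample_table, "human", "chimpanzee")
    m = pd.DataFrame(expr, index=truth.gene_ids, columns=truth.individual_ids)
    kept = median_positive_filter(m, design)
    res = permutation_de_test(
        double_quantile_transform(m.loc[kept], design), design
    )
    de = classify_de(res, 0.05)
    true_de = truth.pair_de_genes("human", "chimpanzee") & set(kept)
    sensitivity = len(de & true_de) / len(true_de)
    realized_fdr = len(de - true_de) / max(len(de), 1)
    assert sensitivity > 0.8
    assert realized_fdr <= 1.5 * 0.05


class TestDirectionRule:
    @pytest.mark.parametrize(
        "mark,de,dm,expected",
        [
            ("H3K27me3", 1.0, -1.0, True),
            ("H3K27me3", 1.0, 1.0, False),
            ("H3K27me3", -1.0, 1.0, True),
            ("H3K27me3", -1.0, -1.0, False),
            ("H3K4me3", 1.0, 1.0, True),
            ("H3K4me3", 1.0, -1.0, False),
            ("H3K4me1", -1.0, -1.0, True),
            ("H3K27ac", -1.0, 1.0, False),
            ("PolII", 1.0, 1.0, True),
            ("H3K4me3", 1.0, 0.0, False),
            ("H3K27me3", 0.0, 1.0, False),
        ],
    )
    def test_truth_table(self, mark, de, dm, expected):
        assert direction_consistent(de, dm, mark) is expected


class TestOverlapEnrichment:
    def test_arithmetic_oracle(self):
        de = {f"d{i}" for i in range(100)}
        non_de = {f"n{i}" for i in range(1000)}
        diff = {f"d{i}" for i in range(30)} | {f"n{i}" for i in range(100)}
        fold, p = overlap_fold_enrichment(de, diff, de | non_de)
        assert fold == pytest.approx(3.0)
        # exact binomial tail oracle
        expected_p = sum(
            stats.binom.pmf(k, 100, 0.1) for k in range(30, 101)
        )
        assert p == pytest.approx(expected_p, rel=1e-9)

    def test_equal_proportions_fold_one(self):
        de = {"a", "b", "c", "d"}
        non_de = {"e", "f", "g", "h"}
        diff = {"a", "b", "e", "f"}
        fold, _ = overlap_fold_enrichment(de, diff, de | non_de)
        assert fold == pytest.approx(1.0)

    def test_empty_overlap_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            fold, p = overlap_fold_enrichment({"a"}, set(), {"a", "b"})
        assert np.isnan(fold)
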