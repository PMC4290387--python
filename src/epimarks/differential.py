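"""Cross-species differential testing by exhaustive label permutation.

For a pair of species with a handful of individuals each, asymptotic null
distributions are unreliable.  Instead, the species-label coefficient of a
per-gene linear model (intercept + sex + species) is compared against its
exact permutation null: every possible assignment of the species labels to
the individuals is enumerated (12,870 for 8+8, 6,435 for 8+7), and both the
per-gene p-value and the false-discovery rate are read off this empirical
null.  Values are double quantile-normalized first — across genes within
each individual, then across individuals within each gene — so the test is
distribution-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

MAX_ENUMERATION_N = 30


@dataclass
class PairwiseDesign:
    """Two-species comparison design: individuals, labels, and sexes."""

    species_a: str
    species_b: str
    individual_ids: list[str]
    species: np.ndarray  # per-individual species label
    sex: np.ndarray  # per-individual "M"/"F"

    def __post_init__(self) -> None:
        self.species = np.asarray(self.species)
        self.sex = np.asarray(self.sex)
        labels = set(self.species)
        if labels != {self.species_a, self.species_b}:
            raise ValueError("design must contain exactly the two named species")
        for s in (self.species_a, self.species_b):
            if int((self.species == s).sum()) < 2:
                raise ValueError(f"need at least 2 individuals for {s}")

    @classmethod
    def from_sample_table(
        cls,
        sample_table: pd.DataFrame,
        species_a: str,
        species_b: str,
        mark: str | None = None,
    ) -> "PairwiseDesign":
        """Build a design from a cohort table, honouring missing-mark flags."""
        sub = sample_table[sample_table["species"].isin([species_a, species_b])]
        if mark is not None and "missing_mark" in sub.columns:
            sub = sub[sub["missing_mark"] != mark]
        return cls(
            species_a=species_a,
            species_b=species_b,
            individual_ids=list(sub["individual_id"]),
            species=sub["species"].to_numpy(),
            sex=sub["sex"].to_numpy(),
        )

    @property
    def n_total(self) -> int:
        return len(self.individual_ids)

    @property
    def n_group_a(self) -> int:
        return int((self.species == self.species_a).sum())

    def group_a_mask(self) -> np.ndarray:
        return self.species == self.species_a

    def sex_numeric(self) -> np.ndarray:
        return (self.sex == "F").astype(float)


@dataclass
class DEResult:
    """Per-gene permutation-test results for one matrix and species pair."""

    table: pd.DataFrame  # gene_id, effect, p, fdr, direction
    n_assignments: int
    design: PairwiseDesign = field(repr=False)


def _as_frame(matrix, individual_ids=None) -> pd.DataFrame:
    if isinstance(matrix, xr.DataArray):
        matrix = matrix.to_pandas()
    if individual_ids is not None:
        matrix = matrix[individual_ids]
    return matrix


def median_positive_filter(matrix, design: PairwiseDesign) -> list[str]:
    """Genes whose median value across the design's individuals is above zero.

    The cutoff is strict: a median of exactly zero is excluded.
    """
    df = _as_frame(matrix, design.individual_ids)
    med = df.median(axis=1)
    return list(df.index[med > 0])


def double_quantile_transform(matrix, design: PairwiseDesign) -> pd.DataFrame:
    """Two-stage quantile normalization to standard-normal scores.

    Stage 1 replaces each individual's values by normal scores over genes
    (making individuals comparable); stage 2 replaces each gene's values by
    normal scores over the design's individuals (guarding against model
    misspecification).  Ties get average ranks; an all-tied gene is flagged
    with a warning (its scores are all zero).
    """
    df = _as_frame(matrix, design.individual_ids)
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 individuals")

    def normal_scores(a: np.ndarray, axis: int) -> np.ndarray:
        n = a.shape[axis]
        ranks = stats.rankdata(a, method="average", axis=axis)
        return stats.norm.ppf(ranks / (n + 1))

    stage1 = normal_scores(df.to_numpy(dtype=float), axis=0)
    tied = np.ptp(stage1, axis=1) == 0
    if tied.any():
        warnings.warn(f"{int(tied.sum())} gene(s) all-tied across individuals")
    stage2 = normal_scores(stage1, axis=1)
    return pd.DataFrame(stage2, index=df.index, columns=df.columns)


def species_lm_stat(y: np.ndarray, design: PairwiseDesign) -> float:
    """t-statistic of the species coefficient (intercept + sex + species OLS)."""
    t = _t_stats_for_assignments(
        np.asarray(y, dtype=float)[None, :].T,
        design.group_a_mask()[None, :],
        design.sex_numeric(),
    )
    return float(t[0, 0])


def enumerate_species_label_assignments(n_total: int, n_group_a: int) -> np.ndarray:
    """All C(n_total, n_group_a) species-label assignments as a boolean matrix.

    Row order is the lexicographic order of the chosen index sets, so the
    enumeration is deterministic and always contains the observed labelling.
    """
    if not 0 < n_group_a < n_total:
        raise ValueError("group A size must be strictly between 0 and n_total")
    if n_total > MAX_ENUMERATION_N:
        raise ValueError(
            f"refusing to enumerate C({n_total}, {n_group_a}) assignments; "
            "use random sampling for designs this large"
        )
    k = comb(n_total, n_group_a)
    out = np.zeros((k, n_total), dtype=bool)
    for row, idx in enumerate(combinations(range(n_total), n_group_a)):
        out[row, list(idx)] = True
    return out


def _t_stats_for_assignments(
    y_matrix: np.ndarray,  # n x G
    assignments: np.ndarray,  # K x n boolean
    sex: np.ndarray,  # n
    chunk: int = 2000,
) -> np.ndarray:
    """Species-coefficient t-statistics for every assignment and gene (K x G).

    For each assignment the design is [intercept, sex, species]; if sex is
    constant or collinear with the permuted species labels, the sex column is
    dropped for that assignment (with a warning for the observed design
    handled by the caller).  Degenerate fits yield a statistic of 0.
    """
    n, n_genes = y_matrix.shape
    k_total = assignments.shape[0]
    yy = np.einsum("ng,ng->g", y_matrix, y_matrix)
    out = np.empty((k_total, n_genes))

    use_sex = np.ptp(sex) > 0
    for lo in range(0, k_total, chunk):
        a = assignments[lo : lo + chunk].astype(float)
        kk = a.shape[0]
        if use_sex:
            x = np.empty((kk, n, 3))
            x[:, :, 0] = 1.0
            x[:, :, 1] = sex
            x[:, :, 2] = a
            p = 3
        else:
            x = np.empty((kk, n, 2))
            x[:, :, 0] = 1.0
            x[:, :, 1] = a
            p = 2
        xtx = np.einsum("knp,knq->kpq", x, x)
        det = np.linalg.det(xtx)
        singular = det < 1e-8
        if singular.any():
            # sex collinear with these particular label assignments: drop it
            x2 = x[singular][:, :, [0, p - 1]]
            xtx2 = np.einsum("knp,knq->kpq", x2, x2)
            t_sub = _t_from_design(x2, xtx2, y_matrix, yy)
            x = x[~singular]
            xtx = xtx[~singular]
        t_main = _t_from_design(x, xtx, y_matrix, yy)
        block = np.empty((kk, n_genes))
        if singular.any():
            block[singular] = t_sub
            block[~singular] = t_main
        else:
            block = t_main
        out[lo : lo + kk] = block
    return out


def _t_from_design(x, xtx, y_matrix, yy):
    """t-stats for a batch of designs sharing the response matrix."""
    kk, n, p = x.shape
    n_genes = y_matrix.shape[1]
    xtx_inv = np.linalg.inv(xtx)
    xty = np.einsum("knp,ng->kpg", x, y_matrix)
    beta = np.einsum("kpq,kqg->kpg", xtx_inv, xty)
    fit_ss = np.einsum("kpg,kpg->kg", xty, beta)
    rss = np.maximum(yy[None, :] - fit_ss, 0.0)
    dof = n - p
    sigma2 = rss / dof
    v_sp = xtx_inv[:, p - 1, p - 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[:, p - 1, :] / np.sqrt(sigma2 * v_sp[:, None])
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def permutation_null_pvalues(y: np.ndarray, design: PairwiseDesign) -> np.ndarray:
    """Exact permutation distribution of the p-value for one response vector.

    Returns the K-vector of p-values each label assignment would receive
    (the rank of its |t| within the full enumeration).  After the double
    quantile transform all genes share the same score multiset, so this is
    the common null distribution of the per-gene p-value — the reference
    for goodness-of-fit checks of observed p-values.
    """
    assignments = enumerate_species_label_assignments(
        design.n_total, design.n_group_a
    )
    k_total = assignments.shape[0]
    t_abs = np.abs(
        _t_stats_for_assignments(
            np.asarray(y, dtype=float)[:, None], assignments, design.sex_numeric()
        )
    ).astype(np.float32)[:, 0]
    rank_min = stats.rankdata(t_abs, method="min")
    return (k_total - rank_min + 1) / k_total


def permutation_de_test(
    matrix,
    design: PairwiseDesign,
    transformed: bool = True,
) -> DEResult:
    """Exhaustive-permutation species test with empirical FDR.

    ``matrix`` is a genes x individuals table (already double
    quantile-transformed unless ``transformed=False``, in which case the
    transform is applied here).  Per gene, p is the proportion of label
    assignments whose |t| is at least the observed |t| (the observed
    assignment is included, so p >= 1/K).  The FDR at each observed p-level
    t is  mean-over-assignments #(permutation p <= t)  divided by
    #(observed p <= t), monotonized by a running maximum from smallest to
    largest p and clipped to [0, 1].
    """
    if not transformed:
        matrix = double_quantile_transform(matrix, design)
    df = _as_frame(matrix, design.individual_ids)
    y = df.to_numpy(dtype=float).T  # n x G
    n = design.n_total
    n_a = design.n_group_a
    assignments = enumerate_species_label_assignments(n, n_a)
    k_total = assignments.shape[0]
    observed = design.group_a_mask()
    obs_idx = int(np.flatnonzero((assignments == observed).all(axis=1))[0])

    sex = design.sex_numeric()
    if np.ptp(sex) == 0:
        warnings.warn("sex constant across individuals; dropping the covariate")
    # |t| quantized to float32: a label assignment and its species-swapped
    # mirror have identical |t| in exact arithmetic but can differ by an ulp
    # numerically; quantizing makes those exact-math ties count as ties
    t_abs = np.abs(_t_stats_for_assignments(y, assignments, sex)).astype(np.float32)
    t_obs = t_abs[obs_idx]

    # observed p: share of assignments at least as extreme, per gene
    p_obs = (t_abs >= t_obs[None, :]).mean(axis=0)

    # permutation p for every assignment, per gene, via descending ranks;
    # only the pooled sorted values are needed for the FDR curve
    flat = (
        (k_total - stats.rankdata(t_abs, method="min", axis=0) + 1) / k_total
    ).ravel()
    flat.sort()

    order = np.argsort(p_obs, kind="stable")
    p_sorted = p_obs[order]
    mean_null = np.searchsorted(flat, p_sorted, side="right") / k_total
    n_discoveries = np.searchsorted(p_sorted, p_sorted, side="right")
    fdr_sorted = np.maximum.accumulate(mean_null / n_discoveries)
    fdr = np.empty_like(fdr_sorted)
    fdr[order] = np.clip(fdr_sorted, 0.0, 1.0)

    # observed effect: species coefficient sign/magnitude via group-mean diff
    # of the (transformed) values — equal to the OLS species coefficient when
    # sex is balanced, and the quantity whose sign defines direction
    t_signed = _t_stats_for_assignments(y, assignments[obs_idx : obs_idx + 1], sex)[0]
    eff = df.loc[:, np.asarray(design.individual_ids)[observed]].mean(
        axis=1
    ) - df.loc[:, np.asarray(design.individual_ids)[~observed]].mean(axis=1)

    table = pd.DataFrame(
        {
            "gene_id": df.index,
            "effect": eff.to_numpy(),
            "t_stat": t_signed,
            "p": p_obs,
            "fdr": fdr,
            "direction": np.sign(eff.to_numpy()),
        }
    ).set_index("gene_id", drop=False)
    return DEResult(table=table, n_assignments=k_total, design=design)


def classify_de(result: DEResult, fdr_cutoff: float = 0.05) -> set[str]:
    """Genes surviving the empirical-FDR threshold."""
    t = result.table
    return set(t.loc[t["fdr"] <= fdr_cutoff, "gene_id"])


def direction_consistent(delta_expr: float, delta_mark: float, mark: str) -> bool:
    """Expected-direction rule for expression and mark differences.

    H3K27me3 moves opposite to expression; the other four marks move with
    it.  A zero mark difference is never consistent (the gene is excluded
    from direction-filtered analyses).
    """
    if delta_expr == 0 or delta_mark == 0:
        return False
    same = (delta_expr > 0) == (delta_mark > 0)
    return (not same) if mark == "H3K27me3" else same


def overlap_fold_enrichment(
    de_set: set,
    mark_diff_set: set,
    universe: set,
    direction_filter: set | None = None,
) -> tuple[float, float]:
    """Fold enrichment of mark-difference regions among DE genes.

    fold = (|DE ∩ diff| / |DE|) / (|nonDE ∩ diff| / |nonDE|), with a
    one-sided binomial p-value for the DE overlap count at the non-DE
    overlap proportion.  ``direction_filter``, when given, restricts the
    universe to genes whose expression and mark differences point in the
    expected direction.
    """
    if direction_filter is not None:
        universe = universe & direction_filter
    de = de_set & universe
    non_de = universe - de
    if not de or not non_de:
        warnings.warn("degenerate DE/non-DE partition; fold undefined")
        return float("nan"), float("nan")
    k_de = len(de & mark_diff_set)
    k_non = len(non_de & mark_diff_set)
    if k_non == 0:
        warnings.warn("no non-DE gene overlaps a mark difference; fold undefined")
        return float("nan"), float("nan")
    p0 = k_non / len(non_de)
    fold = (k_de / len(de)) / p0
    pval = stats.binomtest(k_de, len(de), p0, alternative="greater").pvalue
    return float(fold), float(pval)
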