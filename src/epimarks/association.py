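"""Variance partitioning: feature sets, cross-validated R², grouped summaries.

Feature sets over the five marks' per-gene enrichment levels (averaged
across individuals):

* ``marginal`` — the 5 mark levels;
* ``interactions`` — the marginals plus all 26 first-order products (10
  pairs, 10 triples, 5 quadruples, 1 quintuple), 31 columns total;
* ``states`` — the marginals plus the per-chromatin-state mark levels
  (signal restricted to each state within the TSS window), up to 75 extra
  columns.

Model fit quality is measured by 10-fold cross-validated test-set R²
repeated over 20 fold-split replicates, pooling SSE/SST across the folds of
a replicate and reporting the mean and SD across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import xarray as xr

from epimarks.constants import MARKS
from epimarks.bvsr import BVSRConfig, bvsr_mcmc, predict_r2, standardize_covariates


@dataclass
class FeatureSet:
    matrix: pd.DataFrame  # genes x features
    labels: list[str]
    mode: str


@dataclass
class CVResult:
    mean_r2: float
    sd_r2: float
    replicate_r2: np.ndarray
    n_replicates: int
    n_folds: int


def _mean_over_individuals(enrichment: xr.DataArray) -> pd.DataFrame:
    """Per-gene mark levels averaged across individuals (NaN-tolerant)."""
    return enrichment.mean(dim="individual", skipna=True).to_pandas()


def build_features(
    enrichment: xr.DataArray | pd.DataFrame,
    mode: str = "marginal",
    state_levels: pd.DataFrame | None = None,
) -> FeatureSet:
    """Design matrix over per-gene mark levels.

    ``enrichment`` is either the genes x individuals x marks array (averaged
    here) or an already-averaged genes x marks frame.  For ``states`` mode,
    ``state_levels`` supplies the per-gene state-restricted mark levels with
    columns named ``"<state>:<mark>"``.
    """
    if isinstance(enrichment, xr.DataArray):
        base = _mean_over_individuals(enrichment)
    else:
        base = enrichment.copy()
    base = base[[m for m in MARKS if m in base.columns]]
    if mode == "marginal":
        return FeatureSet(matrix=base, labels=list(base.columns), mode=mode)
    if mode == "interactions":
        cols = {m: base[m] for m in base.columns}
        marks = list(base.columns)
        for order in range(2, len(marks) + 1):
            for combo in combinations(marks, order):
                label = "*".join(combo)
                cols[label] = np.prod([base[m] for m in combo], axis=0)
        mat = pd.DataFrame(cols, index=base.index)
        return FeatureSet(matrix=mat, labels=list(mat.columns), mode=mode)
    if mode == "states":
        if state_levels is None:
            raise ValueError("states mode requires state_levels")
        bad = [
            c
            for c in state_levels.columns
            if ":" not in c or c.split(":", 1)[1] not in MARKS
        ]
        if bad:
            raise ValueError(f"unknown state feature label(s): {bad}")
        mat = pd.concat([base, state_levels.reindex(base.index)], axis=1)
        return FeatureSet(matrix=mat, labels=list(mat.columns), mode=mode)
    raise ValueError(f"unknown feature mode: {mode}")


def _pooled_fold_r2(y, x, train_idx_list, test_idx_list, model, bvsr_config, rep_seed):
    """Pooled SSE/SST over one replicate's folds."""
    sse = 0.0
    sst_parts = []
    preds = np.empty_like(y)
    for fold, (tr, te) in enumerate(zip(train_idx_list, test_idx_list)):
        if len(te) == 0:
            continue
        if model == "ols":
            xtr = np.column_stack([np.ones(len(tr)), x[tr]])
            xte = np.column_stack([np.ones(len(te)), x[te]])
            beta, *_ = np.linalg.lstsq(xtr, y[tr], rcond=None)
            pred = xte @ beta
        else:
            xtr_std, transform = standardize_covariates(x[tr])
            cfg = BVSRConfig(
                burn_in=bvsr_config.burn_in,
                sampling=bvsr_config.sampling,
                slab_variance=bvsr_config.slab_variance,
                sample_slab=bvsr_config.sample_slab,
                seed=rep_seed * 1000 + fold,
            )
            fit = bvsr_mcmc(y[tr], xtr_std, cfg)
            pred = fit.y_mean + transform.apply(x[te]) @ fit.beta_mean
        preds[te] = pred
        sse += float(((y[te] - pred) ** 2).sum())
    # SST about each test fold's own mean, pooled
    for te in test_idx_list:
        if len(te):
            sst_parts.append(float(((y[te] - y[te].mean()) ** 2).sum()))
    sst = sum(sst_parts)
    return 1.0 - sse / sst


def cv_r2(
    y: np.ndarray,
    features: FeatureSet | pd.DataFrame | np.ndarray,
    model: str = "ols",
    folds: int = 10,
    replicates: int = 20,
    seed: int = 0,
    bvsr_config: BVSRConfig | None = None,
) -> CVResult:
    """Cross-validated test-set R² with repeated fold splits.

    Genes are stratified by response decile within each split to reduce
    split variance.  Per replicate, R² is pooled over the folds
    (1 - total SSE / total SST); the mean and SD are taken across
    replicates.
    """
    if isinstance(features, FeatureSet):
        x = features.matrix.to_numpy(dtype=float)
    elif isinstance(features, pd.DataFrame):
        x = features.to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < folds:
        raise ValueError("need at least as many genes as folds")
    if model not in ("ols", "bvsr"):
        raise ValueError("model must be 'ols' or 'bvsr'")
    bvsr_config = bvsr_config or BVSRConfig(burn_in=1000, sampling=10_000)

    rng = np.random.default_rng(seed)
    # stratify by response decile for stable splits
    decile = np.argsort(np.argsort(y)) * 10 // n
    rep_r2 = np.empty(replicates)
    for rep in range(replicates):
        fold_of = np.empty(n, dtype=int)
        for d in range(10):
            idx = np.flatnonzero(decile == d)
            perm = rng.permutation(idx)
            fold_of[perm] = np.arange(len(perm)) % folds
        train_list = [np.flatnonzero(fold_of != f) for f in range(folds)]
        test_list = [np.flatnonzero(fold_of == f) for f in range(folds)]
        rep_r2[rep] = _pooled_fold_r2(
            y, x, train_list, test_list, model, bvsr_config, rep_seed=seed + rep
        )
    return CVResult(
        mean_r2=float(rep_r2.mean()),
        sd_r2=float(rep_r2.std(ddof=1)) if replicates > 1 else 0.0,
        replicate_r2=rep_r2,
        n_replicates=replicates,
        n_folds=folds,
    )


def interspecies_differences(
    enrichment: xr.DataArray,
    expression: xr.DataArray,
    sample_table: pd.DataFrame,
    species_a: str,
    species_b: str,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene species-mean differences (species_a - species_b).

    Returns (delta_enrichment genes x marks, delta_expression genes).
    Missing individual-mark slices are ignored in the means.
    """
    inds_a = sample_table.loc[sample_table["species"] == species_a, "individual_id"]
    inds_b = sample_table.loc[sample_table["species"] == species_b, "individual_id"]
    e_a = enrichment.sel(individual=list(inds_a)).mean(dim="individual", skipna=True)
    e_b = enrichment.sel(individual=list(inds_b)).mean(dim="individual", skipna=True)
    x_a = expression.sel(individual=list(inds_a)).mean(dim="individual")
    x_b = expression.sel(individual=list(inds_b)).mean(dim="individual")
    delta_e = (e_a - e_b).to_pandas()
    delta_x = (x_a - x_b).to_pandas()
    return delta_e, delta_x


def _minmax_scale(values: np.ndarray, symmetric: bool) -> np.ndarray:
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi == lo:
        return np.zeros_like(values)
    if symmetric:
        # scale to [-1, 1] preserving zero when the data straddle it
        m = max(abs(lo), abs(hi))
        return values / m
    return (values - lo) / (hi - lo)


def sliding_window_summary(
    order_by: pd.Series,
    values: pd.DataFrame,
    window: int = 200,
    nonexpressed_mask: pd.Series | None = None,
    symmetric_scale: bool = False,
) -> pd.DataFrame:
    """Group means of scaled values over expression-ordered gene windows.

    Genes are sorted by ``order_by``; consecutive disjoint groups of
    ``window`` genes are formed.  When ``nonexpressed_mask`` is given, those
    genes form the first group regardless of size; the last group may hold
    fewer than ``window`` genes.  Values are min-max scaled to [0, 1]
    (or [-1, 1] with ``symmetric_scale``) before grouping.
    """
    if window > len(order_by):
        raise ValueError("window exceeds the number of genes")
    values = values.loc[order_by.index]
    scaled = values.apply(
        lambda col: _minmax_scale(col.to_numpy(dtype=float), symmetric_scale)
    )
    scaled["__order"] = order_by.to_numpy()

    groups: list[pd.Index] = []
    if nonexpressed_mask is not None and bool(nonexpressed_mask.any()):
        first = order_by.index[nonexpressed_mask.loc[order_by.index]]
        groups.append(first)
        rest = order_by[~nonexpressed_mask.loc[order_by.index]].sort_values().index
    else:
        rest = order_by.sort_values().index
    for i in range(0, len(rest), window):
        groups.append(rest[i : i + window])

    rows = []
    for gi, idx in enumerate(groups):
        if len(idx) == 0:
            continue
        sub = scaled.loc[idx]
        row = {"group": gi, "n_genes": len(idx), "mean_order": float(sub["__order"].mean())}
        for c in values.columns:
            row[c] = float(sub[c].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def expression_tertiles(expression: pd.Series) -> tuple[pd.Index, pd.Index, pd.Index]:
    """Split genes evenly into low / medium / high expression sets by rank.

    Sizes differ by at most one; ties at the boundaries are broken by stable
    input order.
    """
    order = expression.sort_values(kind="stable").index
    n = len(order)
    base, extra = divmod(n, 3)
    sizes = [base + (1 if i < extra else 0) for i in range(3)]
    low = order[: sizes[0]]
    mid = order[sizes[0] : sizes[0] + sizes[1]]
    high = order[sizes[0] + sizes[1] :]
    return low, mid, high
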