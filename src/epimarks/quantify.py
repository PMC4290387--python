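"""TSS-window quantification of mark enrichment and gene expression.

Units follow the field's conventions for this analysis:

* mark enrichment level — square root of (input-subtracted RPKM in the TSS
  window divided by the genome-wide average RPKM);
* gene expression level — log2 of exon RPKM plus a small offset.

The module also provides the TSS fold-enrichment test (one-sided
Mann-Whitney against genome-wide background), binned TSS profiles, and the
inter-mark correlation matrix.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from epimarks.constants import MARKS
from epimarks.synthetic import tss_windows  # noqa: F401  (re-exported convenience)

DEFAULT_LOG2_OFFSET = 0.25


def normalized_peak_rpkm(
    chip_reads,
    input_reads,
    region_length,
    chip_library,
    input_library,
):
    """Input-subtracted reads per kilobase per million mapped reads.

    Input reads are scaled to the ChIP library depth before subtraction;
    negative input-subtracted counts are floored at zero (the downstream
    square-root transform requires non-negative values).
    """
    region_length = np.asarray(region_length, dtype=float)
    if np.any(region_length <= 0):
        raise ValueError("region length must be positive")
    chip_library = np.asarray(chip_library, dtype=float)
    input_library = np.asarray(input_library, dtype=float)
    if np.any(chip_library <= 0) or np.any(input_library <= 0):
        raise ValueError("library sizes must be positive")
    net = np.maximum(
        0.0,
        np.asarray(chip_reads, dtype=float)
        - np.asarray(input_reads, dtype=float) * chip_library / input_library,
    )
    return net / (region_length / 1000.0 * chip_library / 1e6)


def mark_enrichment_level(
    counts: pd.DataFrame,
    genome_average: float | dict = 1.0,
    gene_ids: list[str] | None = None,
    individual_ids: list[str] | None = None,
    state: str = "all",
) -> xr.DataArray:
    """Genes x individuals x marks enrichment levels from a count table.

    ``counts`` holds one row per (region, individual, mark[, state]) with
    chip/input reads, region length, and library sizes.  The RPKM of each
    region is divided by the genome-wide average (a scalar, or a dict keyed
    by individual) and square-root transformed.  Missing individual-mark
    slices are NaN and recorded in the array attributes.
    """
    df = counts
    if "state" in df.columns:
        df = df[df["state"] == state]
    rpkm = normalized_peak_rpkm(
        df["chip_reads"],
        df["input_reads"],
        df["region_length"],
        df["chip_library"],
        df["input_library"],
    )
    if isinstance(genome_average, dict):
        avg = df["individual_id"].map(genome_average).to_numpy(dtype=float)
    else:
        avg = float(genome_average)
    if np.any(np.asarray(avg) <= 0):
        raise ValueError("genome-wide average RPKM must be positive")
    level = np.sqrt(rpkm / avg)

    tall = pd.DataFrame(
        {
            "gene_id": df["gene_id"].to_numpy(),
            "individual_id": df["individual_id"].to_numpy(),
            "mark": df["mark"].to_numpy(),
            "level": level,
        }
    )
    genes = gene_ids if gene_ids is not None else sorted(tall["gene_id"].unique())
    inds = (
        individual_ids
        if individual_ids is not None
        else list(pd.unique(tall["individual_id"]))
    )
    marks = [m for m in MARKS if m in set(tall["mark"])]
    data = np.full((len(genes), len(inds), len(marks)), np.nan)
    gi = pd.Categorical(tall["gene_id"], categories=genes).codes
    ii = pd.Categorical(tall["individual_id"], categories=inds).codes
    mi = pd.Categorical(tall["mark"], categories=marks).codes
    ok = (gi >= 0) & (ii >= 0) & (mi >= 0)
    data[gi[ok], ii[ok], mi[ok]] = tall["level"].to_numpy()[ok]
    arr = xr.DataArray(
        data,
        coords={"gene": genes, "individual": inds, "mark": marks},
        dims=("gene", "individual", "mark"),
        name="enrichment_level",
    )
    missing = [
        (i, m)
        for m in marks
        for i in inds
        if bool(np.isnan(arr.sel(individual=i, mark=m)).all())
    ]
    arr.attrs["missing_slices"] = missing
    return arr


def expression_level(
    exon_counts: pd.DataFrame,
    offset: float = DEFAULT_LOG2_OFFSET,
    gene_ids: list[str] | None = None,
    individual_ids: list[str] | None = None,
) -> xr.DataArray:
    """Genes x individuals log2(RPKM + offset) from per-exon counts.

    Reads are summed over each gene's orthologous exons and normalized by
    total mapped reads and total exon length.
    """
    grouped = exon_counts.groupby(["gene_id", "individual_id"]).agg(
        reads=("reads", "sum"),
        exon_length=("exon_length", "sum"),
        rna_library=("rna_library", "first"),
    )
    if (grouped["exon_length"] <= 0).any():
        bad = grouped.index[grouped["exon_length"] <= 0][0]
        raise ValueError(f"gene with zero total exon length: {bad[0]}")
    rpkm = grouped["reads"] / (
        grouped["exon_length"] / 1000.0 * grouped["rna_library"] / 1e6
    )
    level = np.log2(rpkm + offset)

    genes = (
        gene_ids
        if gene_ids is not None
        else sorted(exon_counts["gene_id"].unique())
    )
    inds = (
        individual_ids
        if individual_ids is not None
        else list(pd.unique(exon_counts["individual_id"]))
    )
    data = np.full((len(genes), len(inds)), np.nan)
    lev = level.rename("level").reset_index()
    gi = pd.Categorical(lev["gene_id"], categories=genes).codes
    ii = pd.Categorical(lev["individual_id"], categories=inds).codes
    ok = (gi >= 0) & (ii >= 0)
    data[gi[ok], ii[ok]] = lev["level"].to_numpy()[ok]
    return xr.DataArray(
        data,
        coords={"gene": genes, "individual": inds},
        dims=("gene", "individual"),
        name="expression_level",
        attrs={"log2_offset": offset},
    )


def tss_fold_enrichment_test(
    tss_values: np.ndarray, genome_values: np.ndarray
) -> tuple[float, float]:
    """TSS-over-genome fold enrichment with a one-sided rank-sum p-value.

    ``tss_values`` and ``genome_values`` are per-unit signal measurements
    (e.g. per-gene TSS-window RPKM versus background-window RPKM).  The fold
    is the ratio of means; the p-value is from a one-sided Mann-Whitney test
    of TSS values exceeding the background.
    """
    tss_values = np.asarray(tss_values, dtype=float)
    genome_values = np.asarray(genome_values, dtype=float)
    if len(tss_values) < 1 or len(genome_values) < 1:
        raise ValueError("need values in both groups")
    fold = float(tss_values.mean() / genome_values.mean())
    if np.all(tss_values == tss_values[0]) and np.all(
        genome_values == tss_values[0]
    ):
        warnings.warn("all values tied; rank-sum p undefined, returning 0.5")
        return fold, 0.5
    res = stats.mannwhitneyu(
        tss_values, genome_values, alternative="greater", method="exact"
        if (len(tss_values) + len(genome_values)) <= 25
        else "asymptotic",
    )
    return fold, float(res.pvalue)


def tss_profile(
    offsets: np.ndarray,
    weights: np.ndarray | None = None,
    half_width: int = 2000,
    bin_size: int = 100,
    n_units: int = 1,
) -> pd.DataFrame:
    """Binned mean signal around the TSS, strand-oriented.

    ``offsets`` are read positions relative to the TSS (negative = upstream),
    already strand-oriented by the caller.  ``weights`` converts reads to
    normalized units (e.g. sqrt-RPKM per read); ``n_units`` is the number of
    gene x individual units averaged over.  Returns a table of
    (offset_bp, value) with offset_bp the bin's left edge.
    """
    if (2 * half_width) % bin_size != 0:
        raise ValueError("bin size must divide the window")
    offsets = np.asarray(offsets, dtype=float)
    edges = np.arange(-half_width, half_width + bin_size, bin_size)
    w = np.ones_like(offsets) if weights is None else np.asarray(weights, dtype=float)
    hist, _ = np.histogram(offsets, bins=edges, weights=w)
    return pd.DataFrame(
        {"offset_bp": edges[:-1], "value": hist / max(n_units, 1)}
    )


def mark_correlation_matrix(enrichment: xr.DataArray) -> pd.DataFrame:
    """Inter-mark correlation of per-gene mean enrichment levels.

    Averages over individuals (ignoring missing slices), then correlates
    across genes.  Marks constant across genes yield NaN entries and a
    warning.
    """
    if enrichment.sizes["gene"] < 3:
        raise ValueError("need at least 3 genes")
    per_gene = enrichment.mean(dim="individual", skipna=True).to_pandas()
    sds = per_gene.std(axis=0)
    if (sds == 0).any():
        warnings.warn(
            f"constant mark(s) {list(sds.index[sds == 0])}: correlation undefined"
        )
    return per_gene.corr()
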