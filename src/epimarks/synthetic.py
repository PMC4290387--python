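"""Synthetic comparative ChIP-seq / RNA-seq cohort with recorded ground truth.

The generator emulates the data model of a three-species lymphoblastoid-cell
study: per-species cohorts of individuals profiled for five marks (Pol II and
four histone modifications) plus RNA, with

* gene-level latent "mark enrichment levels" (sqrt of input-subtracted RPKM
  fold over the genome-wide average) drawn from a configurable inter-mark
  covariance in which H3K27me3 is anti-correlated with the active marks,
* latent expression driven linearly by the marks plus structural noise,
* species-level mean shifts at a configurable fraction of genes (the ground
  truth for differential analysis),
* peak-caller-style outputs (narrow-peak FDRs, broad-domain scores),
* per-region ChIP/input read counts and per-exon RNA counts whose expected
  normalized values equal the latent signal plus measurement noise, and
* a 15-state chromatin segmentation tiling the synthetic genome.

Every generator is deterministic given its seed, and zero-noise settings
collapse the observables exactly onto the latent ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from epimarks.constants import (
    MARKS,
    BROAD_MARKS,
    REPRESSIVE_INDEX,
    SPECIES_NAMES,
    SPECIES_PREFIXES,
)

# -- latent-model defaults ---------------------------------------------------

#: direction loading of species shifts on each mark: active marks move with
#: expression, the repressive mark against it
SHIFT_LOADINGS = np.array([0.5, 0.5, 0.5, -0.5, 0.5])

DEFAULT_MARK_MEAN = np.array([1.0, 1.2, 1.1, 0.9, 1.1])
DEFAULT_BETA = np.array([0.2, 0.8, 0.7, -0.6, 0.9])


def default_mark_covariance(sd: float = 0.4) -> np.ndarray:
    """Inter-mark covariance of latent enrichment levels.

    Active marks (H3K4me1/3, H3K27ac, Pol II) are mutually positively
    correlated; H3K27me3 is negatively correlated with all of them.
    """
    r = np.full((5, 5), 0.55)
    r[REPRESSIVE_INDEX, :] = -0.35
    r[:, REPRESSIVE_INDEX] = -0.35
    np.fill_diagonal(r, 1.0)
    return (sd * sd) * r


def calibrate_structural_sds(
    beta: np.ndarray,
    mark_covariance: np.ndarray,
    species_shift_scale: float,
    species_shift_fraction: float,
    r2_within: float = 0.58,
    r2_between: float = 0.40,
) -> tuple[float, float]:
    """Structural-noise SDs that place the latent variance-explained at targets.

    Two gene-level noise components enter latent expression: a cross-species
    component at every gene (SD ``sigma_structural``) and a per-species
    component confined to the shifted (DE) genes (SD ``sigma_species``, the
    mark-independent part of their expression divergence).  Given the mark
    effects and shift model, the latent within-species R² is

        B / (B + s_struct² + f·s_spec²),   B = β'Σβ + f·A,  A = (w'β·scale)²,

    and the latent between-species R² on the shifted genes is

        2A / (2A + 2·s_spec²)

    (the shared component cancels in species differences; non-shifted genes
    have none of either, so they are exact nulls for differential testing).
    Solving for the two SDs yields the returned pair.  Raises if the
    targets are infeasible for the given effect sizes.
    """
    a = float(np.dot(SHIFT_LOADINGS, beta) * species_shift_scale) ** 2
    b = float(beta @ mark_covariance @ beta) + species_shift_fraction * a
    sigma_species2 = a * (1.0 / r2_between - 1.0)
    sigma_struct2 = (
        b * (1.0 / r2_within - 1.0) - species_shift_fraction * sigma_species2
    )
    if sigma_struct2 < 0:
        raise ValueError(
            "infeasible R2 targets: species-shift variance too large relative "
            "to the marks' within-species variance"
        )
    return float(np.sqrt(sigma_struct2)), float(np.sqrt(sigma_species2))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the reference design: 3 species x 8 individuals, five
    marks with an H3K27me3-anti-correlated covariance, species shifts at 10%
    of genes, and structural-noise SDs calibrated so the latent
    variance-explained is 0.58 within species and 0.40 between species on
    shifted genes.
    """

    n_genes: int = 2000
    n_species: int = 3
    n_individuals_per_species: int = 8
    n_marks: int = 5
    mark_mean: np.ndarray = field(default_factory=lambda: DEFAULT_MARK_MEAN.copy())
    mark_covariance: np.ndarray = field(default_factory=default_mark_covariance)
    beta: np.ndarray = field(default_factory=lambda: DEFAULT_BETA.copy())
    expr_baseline: float = 3.0
    species_shift_fraction: float = 0.1
    species_shift_scale: float = 0.25
    #: "normal": per-species shift sizes ~ N(0, scale²) (graded effects);
    #: "signed": ±scale with random sign (every shifted gene has a large
    #: effect for a species pair, or is exactly null for that pair)
    shift_distribution: str = "normal"
    #: cross-species structural noise SD on latent expression; None → calibrated
    sigma_structural: float | None = None
    #: per-species structural noise SD on latent expression; None → calibrated
    sigma_species: float | None = None
    #: measurement noise SD per mark, on the input-subtracted RPKM scale
    noise_sd_marks: np.ndarray = field(default_factory=lambda: np.full(5, 0.15))
    #: measurement noise SD on expression, log2-RPKM scale
    noise_sd_expr: float = 0.15
    seed: int = 0
    # genome layout
    gene_spacing: int = 20_000
    genes_per_chromosome: int = 1000
    tss_half_width: int = 2000
    # sequencing emulation
    chip_library_size: float = 1.0e7
    input_library_size: float = 4.0e7
    rna_library_size: float = 1.0e7
    genome_average_rpkm: float = 1.0
    input_rpkm: float = 0.5
    log2_offset: float = 0.25
    #: drop the last individual of the third species for H3K27ac (N=7 design)
    emulate_missing_individual: bool = True

    def __post_init__(self) -> None:
        self.mark_mean = np.asarray(self.mark_mean, dtype=float)
        self.mark_covariance = np.asarray(self.mark_covariance, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.noise_sd_marks = np.asarray(self.noise_sd_marks, dtype=float)
        if self.n_marks != 5:
            raise ValueError("the cohort model is defined for exactly 5 marks")
        if self.mark_covariance.shape != (5, 5):
            raise ValueError("mark_covariance must be 5x5")
        if not np.allclose(self.mark_covariance, self.mark_covariance.T):
            raise ValueError("mark_covariance is not symmetric")
        eigmin = float(np.linalg.eigvalsh(self.mark_covariance).min())
        if eigmin <= 0:
            raise ValueError(
                f"mark_covariance is not positive definite (min eigenvalue {eigmin:.3g})"
            )
        if not 0.0 <= self.species_shift_fraction <= 1.0:
            raise ValueError("species_shift_fraction must lie in [0, 1]")
        if self.n_individuals_per_species < 2:
            raise ValueError("need at least 2 individuals per species")
        if np.any(self.noise_sd_marks < 0) or self.noise_sd_expr < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.shift_distribution not in ("normal", "signed"):
            raise ValueError("shift_distribution must be 'normal' or 'signed'")
        if self.sigma_structural is None or self.sigma_species is None:
            s_struct, s_spec = calibrate_structural_sds(
                self.beta,
                self.mark_covariance,
                self.species_shift_scale,
                self.species_shift_fraction,
            )
            if self.sigma_structural is None:
                self.sigma_structural = s_struct
            if self.sigma_species is None:
                self.sigma_species = s_spec

    def species_names(self) -> list[str]:
        if self.n_species <= len(SPECIES_NAMES):
            return list(SPECIES_NAMES[: self.n_species])
        extra = [f"species{k + 1}" for k in range(len(SPECIES_NAMES), self.n_species)]
        return list(SPECIES_NAMES) + extra


@dataclass
class GroundTruth:
    """Latent signals and answers recorded at generation time."""

    gene_ids: list[str]
    individual_ids: list[str]
    #: genes x individuals x marks latent enrichment levels (sqrt-fold scale)
    latent_marks: np.ndarray
    #: genes x individuals latent log2 expression levels
    latent_expression: np.ndarray
    true_beta: np.ndarray
    de_genes: set[str]
    #: directed edges of the generating structure over the marks and RNA
    true_dag: list[tuple[str, str]]
    #: genes x species x marks species-level mark shifts
    species_shifts: np.ndarray
    #: per-gene structural noise (shared across species)
    structural_noise: np.ndarray
    #: genes x species per-species structural noise
    species_noise: np.ndarray
    #: species order of the species axes above
    species_names: list[str] = field(default_factory=list)

    def pair_de_genes(self, species_a: str, species_b: str) -> set[str]:
        """Genes whose latent expression differs between the two species.

        A gene is differential for a pair when its species-level shift
        (through the marks) or its mark-independent species component
        differs between exactly these two species — a gene shifted
        identically in both is null for the pair.
        """
        ia = self.species_names.index(species_a)
        ib = self.species_names.index(species_b)
        delta = (self.species_shifts[:, ia, :] - self.species_shifts[:, ib, :]) @ (
            self.true_beta
        ) + (self.species_noise[:, ia] - self.species_noise[:, ib])
        return {g for g, d in zip(self.gene_ids, delta) if abs(d) > 1e-12}

    def latent_r2_within(self, sample_table: pd.DataFrame, species: str) -> float:
        """Realized latent variance-explained across genes within one species."""
        idx = np.flatnonzero((sample_table["species"] == species).to_numpy())
        x = self.latent_marks[:, idx, :].mean(axis=1)
        y = self.latent_expression[:, idx].mean(axis=1)
        fit = x @ self.true_beta
        return float(np.var(fit) / np.var(y))


def _individual_ids(config: SimulationConfig) -> tuple[list[str], list[str], list[str]]:
    names = config.species_names()
    ids, species, sexes = [], [], []
    for s in names:
        prefix = SPECIES_PREFIXES.get(s, s[:1].upper())
        for i in range(config.n_individuals_per_species):
            ids.append(f"{prefix}{i + 1}")
            species.append(s)
            sexes.append("F" if i % 2 else "M")
    return ids, species, sexes


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw samples, gene models, and latent signals for a full study.

    Returns
    -------
    sample_table : DataFrame
        individual_id, species, sex, library sizes, and (if the missing-
        individual design is emulated) the mark the individual lacks.
    gene_table : DataFrame
        gene_id, chrom, tss, strand and >=2 orthologous exons per gene
        (0-based half-open coordinates).
    truth : GroundTruth
    """
    rng = np.random.default_rng(config.seed)
    ids, species_col, sexes = _individual_ids(config)
    n_ind = len(ids)
    names = config.species_names()

    sample_table = pd.DataFrame(
        {
            "individual_id": ids,
            "species": species_col,
            "sex": sexes,
            "chip_library": config.chip_library_size,
            "input_library": config.input_library_size,
            "rna_library": config.rna_library_size,
            "missing_mark": "",
        }
    )
    if config.emulate_missing_individual and config.n_species >= 3:
        # the reference design lacks one H3K27ac sample in the third species
        miss = (config.n_species - 1) * config.n_individuals_per_species + (
            config.n_individuals_per_species - 1
        )
        sample_table.loc[miss, "missing_mark"] = "H3K27ac"

    # gene models on a synthetic genome: one chromosome per block of genes,
    # genes spaced so +/-2 kb TSS windows do not overlap
    g = np.arange(config.n_genes)
    chrom = np.array([f"chr{c + 1}" for c in g // config.genes_per_chromosome])
    within = g % config.genes_per_chromosome
    start = 10_000 + within * config.gene_spacing
    strand = np.where(rng.random(config.n_genes) < 0.5, "+", "-")
    gene_ids = [f"gene{i:05d}" for i in g]
    body = 3_000  # TSS to last exon end
    tss = np.where(strand == "+", start, start + body)
    rows = []
    for i in range(config.n_genes):
        if strand[i] == "+":
            exon_starts = [tss[i], tss[i] + 1200, tss[i] + 2500]
            exon_ends = [tss[i] + 300, tss[i] + 1700, tss[i] + 3000]
        else:
            # transcription runs right-to-left; exons stored in transcription
            # order (first exon nearest the TSS), each as start < end
            exon_starts = [tss[i] - 300, tss[i] - 1700, tss[i] - 3000]
            exon_ends = [tss[i], tss[i] - 1200, tss[i] - 2500]
        rows.append(
            {
                "gene_id": gene_ids[i],
                "chrom": chrom[i],
                "tss": int(tss[i]),
                "strand": strand[i],
                "exon_starts": ",".join(str(int(s)) for s in exon_starts),
                "exon_ends": ",".join(str(int(e)) for e in exon_ends),
            }
        )
    gene_table = pd.DataFrame(rows)

    # latent marks: gene-level draw shared across individuals, plus
    # species-level shifts at the DE genes
    base = rng.multivariate_normal(
        config.mark_mean, config.mark_covariance, size=config.n_genes
    )
    base = np.clip(base, 0.0, None)

    de_mask = rng.random(config.n_genes) < config.species_shift_fraction
    shift_u = np.zeros((config.n_genes, config.n_species))
    n_de = int(de_mask.sum())
    if config.shift_distribution == "normal":
        shift_u[de_mask] = rng.normal(
            0.0, config.species_shift_scale, size=(n_de, config.n_species)
        )
    else:
        shift_u[de_mask] = config.species_shift_scale * rng.choice(
            [-1.0, 1.0], size=(n_de, config.n_species)
        )
    species_shifts = shift_u[:, :, None] * SHIFT_LOADINGS[None, None, :]

    species_of = np.repeat(np.arange(config.n_species), config.n_individuals_per_species)
    latent_marks = np.clip(
        base[:, None, :] + species_shifts[:, species_of, :], 0.0, None
    )

    structural = rng.normal(0.0, config.sigma_structural, size=config.n_genes)
    # mark-independent species divergence exists only at the shifted genes;
    # all other genes are exact nulls for the differential test
    species_noise = rng.normal(
        0.0, config.sigma_species, size=(config.n_genes, config.n_species)
    ) * de_mask[:, None]
    latent_expression = (
        config.expr_baseline
        + latent_marks @ config.beta
        + structural[:, None]
        + species_noise[:, species_of]
    )

    true_dag = [(MARKS[j], "RNA") for j in range(5) if config.beta[j] != 0.0]
    truth = GroundTruth(
        gene_ids=gene_ids,
        individual_ids=ids,
        latent_marks=latent_marks,
        latent_expression=latent_expression,
        true_beta=config.beta.copy(),
        de_genes={gene_ids[i] for i in np.flatnonzero(de_mask)},
        true_dag=true_dag,
        species_shifts=species_shifts,
        structural_noise=structural,
        species_noise=species_noise,
        species_names=names,
    )
    return sample_table, gene_table, truth


# -- observable layers -------------------------------------------------------


def tss_windows(gene_table: pd.DataFrame, half_width: int = 2000) -> pd.DataFrame:
    """Strand-aware TSS analysis windows.

    The window runs from ``half_width`` upstream of the TSS to the earlier of
    ``half_width`` downstream or the start of the second exon (in
    transcription order).
    """
    rows = []
    for rec in gene_table.itertuples(index=False):
        starts = [int(s) for s in rec.exon_starts.split(",")]
        ends = [int(e) for e in rec.exon_ends.split(",")]
        if rec.strand == "+":
            second_exon_start = starts[1]
            lo = rec.tss - half_width
            hi = min(rec.tss + half_width, second_exon_start)
        else:
            # transcription runs right-to-left; "start" of the second exon is
            # its rightmost base boundary
            second_exon_start = ends[1]
            hi = rec.tss + half_width
            lo = max(rec.tss - half_width, second_exon_start)
        if hi <= lo:
            raise ValueError(f"empty TSS window for {rec.gene_id}")
        rows.append(
            {
                "gene_id": rec.gene_id,
                "chrom": rec.chrom,
                "start": lo,
                "end": hi,
                "tss": rec.tss,
                "strand": rec.strand,
            }
        )
    return pd.DataFrame(rows)


def _missing_pairs(sample_table: pd.DataFrame) -> set[tuple[str, str]]:
    out = set()
    for rec in sample_table.itertuples(index=False):
        if rec.missing_mark:
            out.add((rec.individual_id, rec.missing_mark))
    return out


def simulate_mark_observables(
    truth: GroundTruth,
    config: SimulationConfig,
    sample_table: pd.DataFrame,
    gene_table: pd.DataFrame,
    states: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Peak/domain calls and region-level ChIP/input counts.

    The expected input-subtracted RPKM of each TSS-window region equals the
    latent fold (squared latent level times the genome-wide average) plus
    Gaussian measurement noise of SD ``noise_sd_marks``.  Counts are
    real-valued so the zero-noise configuration reproduces the latent levels
    exactly after quantification.  Narrow marks receive per-peak FDR values
    concentrated below the stringent cutoff for strong signal; the broad mark
    receives RSEG-style domain scores.

    When ``states`` is given, each region's expected signal is additionally
    split across the chromatin states overlapping the window (proportional to
    overlap length) and the count table carries a ``state`` column
    ("all" rows preserve the unsplit totals).
    """
    rng = np.random.default_rng(config.seed + 1)
    windows = tss_windows(gene_table, config.tss_half_width)
    missing = _missing_pairs(sample_table)
    n_genes, n_ind, _ = truth.latent_marks.shape

    win_len = (windows["end"] - windows["start"]).to_numpy()
    chip_lib = config.chip_library_size
    input_lib = config.input_library_size

    state_overlap = None
    if states is not None:
        state_overlap = _window_state_overlap(windows, states)

    call_rows = []
    count_rows = []
    for j, mark in enumerate(MARKS):
        fold_latent = truth.latent_marks[:, :, j] ** 2 * config.genome_average_rpkm
        noise = rng.normal(0.0, config.noise_sd_marks[j], size=(n_genes, n_ind))
        rpkm_obs = np.clip(fold_latent + noise, 0.0, None)
        # peak-caller confidence: strong signal -> small FDR / high score
        u_strong = rng.beta(1.0, 40.0, size=(n_genes, n_ind))
        u_weak = rng.beta(1.5, 12.0, size=(n_genes, n_ind))
        score_strong = 20.0 + rng.gamma(2.0, 15.0, size=(n_genes, n_ind))
        score_weak = rng.uniform(1.0, 20.0, size=(n_genes, n_ind))
        jitter = rng.integers(-200, 201, size=(n_genes, n_ind, 2))

        for i_col, ind in enumerate(truth.individual_ids):
            if (ind, mark) in missing:
                continue
            kb = win_len / 1000.0
            input_reads = config.input_rpkm * kb * input_lib / 1e6
            chip_reads = (
                rpkm_obs[:, i_col] * kb * chip_lib / 1e6
                + input_reads * chip_lib / input_lib
            )
            base_row = {
                "individual_id": ind,
                "mark": mark,
                "chip_library": chip_lib,
                "input_library": input_lib,
            }
            if state_overlap is None:
                count_rows.append(
                    pd.DataFrame(
                        {
                            "region_id": windows["gene_id"],
                            "gene_id": windows["gene_id"],
                            "state": "all",
                            "chip_reads": chip_reads,
                            "input_reads": input_reads,
                            "region_length": win_len,
                            **base_row,
                        }
                    )
                )
            else:
                for state_label, frac in state_overlap.items():
                    keep = frac > 0
                    if not keep.any():
                        continue
                    count_rows.append(
                        pd.DataFrame(
                            {
                                "region_id": windows["gene_id"][keep],
                                "gene_id": windows["gene_id"][keep],
                                "state": state_label,
                                "chip_reads": (
                                    rpkm_obs[keep, i_col]
                                    * frac[keep]
                                    * win_len[keep]
                                    / 1000.0
                                    * chip_lib
                                    / 1e6
                                    + config.input_rpkm
                                    * frac[keep]
                                    * win_len[keep]
                                    / 1000.0
                                    * chip_lib
                                    / 1e6
                                ),
                                "input_reads": config.input_rpkm
                                * frac[keep]
                                * win_len[keep]
                                / 1000.0
                                * input_lib
                                / 1e6,
                                "region_length": win_len[keep] * frac[keep],
                                **base_row,
                            }
                        )
                    )
                count_rows.append(
                    pd.DataFrame(
                        {
                            "region_id": windows["gene_id"],
                            "gene_id": windows["gene_id"],
                            "state": "all",
                            "chip_reads": chip_reads,
                            "input_reads": input_reads,
                            "region_length": win_len,
                            **base_row,
                        }
                    )
                )

            # peak calls: emitted only where there is latent signal
            species = sample_table.loc[
                sample_table["individual_id"] == ind, "species"
            ].iloc[0]
            fold = fold_latent[:, i_col]
            has_signal = fold > 0
            strong = fold >= 1.0
            for gidx in np.flatnonzero(has_signal):
                if mark in BROAD_MARKS:
                    conf = (
                        score_strong[gidx, i_col] if strong[gidx] else score_weak[gidx, i_col]
                    )
                else:
                    conf = u_strong[gidx, i_col] if strong[gidx] else u_weak[gidx, i_col]
                t = windows["tss"].iloc[gidx]
                call_rows.append(
                    (
                        f"{windows['gene_id'].iloc[gidx]}|{ind}|{mark}",
                        windows["chrom"].iloc[gidx],
                        int(t - 1000 + jitter[gidx, i_col, 0]),
                        int(t + 1000 + jitter[gidx, i_col, 1]),
                        mark,
                        ind,
                        species,
                        float(conf),
                        windows["gene_id"].iloc[gidx],
                    )
                )

    calls = pd.DataFrame(
        call_rows,
        columns=[
            "region_id",
            "chrom",
            "start",
            "end",
            "mark",
            "individual_id",
            "species",
            "confidence",
            "gene_id",
        ],
    )
    counts = pd.concat(count_rows, ignore_index=True)
    return calls, counts


def _window_state_overlap(
    windows: pd.DataFrame, states: pd.DataFrame
) -> dict[str, np.ndarray]:
    """Fraction of each TSS window covered by each chromatin state."""
    labels = sorted(states["state"].unique())
    out = {lab: np.zeros(len(windows)) for lab in labels}
    by_chrom = {c: df.sort_values("start") for c, df in states.groupby("chrom")}
    for i, rec in enumerate(windows.itertuples(index=False)):
        df = by_chrom.get(rec.chrom)
        if df is None:
            continue
        s = df["start"].to_numpy()
        e = df["end"].to_numpy()
        lo = np.searchsorted(e, rec.start, side="right")
        hi = np.searchsorted(s, rec.end, side="left")
        for k in range(lo, hi):
            ov = min(rec.end, e[k]) - max(rec.start, s[k])
            if ov > 0:
                out[df["state"].iloc[k]][i] += ov / (rec.end - rec.start)
    return out


def simulate_expression_counts(
    truth: GroundTruth,
    config: SimulationConfig,
    sample_table: pd.DataFrame,
    gene_table: pd.DataFrame,
) -> pd.DataFrame:
    """Per-exon RNA read counts whose log2 RPKM recovers latent expression.

    The observed log2 expression target is latent expression plus Gaussian
    noise of SD ``noise_sd_expr``; counts are real-valued and are split
    across a gene's orthologous exons in proportion to exon length.
    """
    rng = np.random.default_rng(config.seed + 2)
    n_genes, n_ind = truth.latent_expression.shape
    noise = rng.normal(0.0, config.noise_sd_expr, size=(n_genes, n_ind))
    target_log2 = truth.latent_expression + noise
    rpkm = np.clip(np.exp2(target_log2) - config.log2_offset, 0.0, None)

    exon_lens = []
    for rec in gene_table.itertuples(index=False):
        starts = [int(s) for s in rec.exon_starts.split(",")]
        ends = [int(e) for e in rec.exon_ends.split(",")]
        exon_lens.append([abs(e - s) for s, e in zip(starts, ends)])

    rows = []
    rna_lib = config.rna_library_size
    for i_col, ind in enumerate(truth.individual_ids):
        for gidx in range(n_genes):
            lens = exon_lens[gidx]
            total_kb = sum(lens) / 1000.0
            total_reads = rpkm[gidx, i_col] * total_kb * rna_lib / 1e6
            for e_idx, ln in enumerate(lens):
                rows.append(
                    (
                        gene_table["gene_id"].iloc[gidx],
                        e_idx,
                        ln,
                        ind,
                        total_reads * ln / sum(lens),
                        rna_lib,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "exon_index", "exon_length", "individual_id", "reads", "rna_library"],
    )


def simulate_observed_matrices(
    truth: GroundTruth, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Observed enrichment levels and expression, bypassing count tables.

    Applies the identical measurement model as the count-level emulation
    (Gaussian noise on the input-subtracted RPKM scale for marks, on the
    log2 scale for expression, with the same seed offsets), returning the
    genes x individuals x marks level array and the genes x individuals
    expression array directly.  Equivalent to running the observable layers
    through quantification; used when only the matrices are needed at scale.
    """
    rng = np.random.default_rng(config.seed + 1)
    n_genes, n_ind, _ = truth.latent_marks.shape
    levels = np.empty_like(truth.latent_marks)
    for j in range(len(MARKS)):
        fold_latent = truth.latent_marks[:, :, j] ** 2 * config.genome_average_rpkm
        noise = rng.normal(0.0, config.noise_sd_marks[j], size=(n_genes, n_ind))
        rpkm_obs = np.clip(fold_latent + noise, 0.0, None)
        levels[:, :, j] = np.sqrt(rpkm_obs / config.genome_average_rpkm)
        # keep the stream aligned with simulate_mark_observables
        rng.beta(1.0, 40.0, size=(n_genes, n_ind))
        rng.beta(1.5, 12.0, size=(n_genes, n_ind))
        rng.gamma(2.0, 15.0, size=(n_genes, n_ind))
        rng.uniform(1.0, 20.0, size=(n_genes, n_ind))
        rng.integers(-200, 201, size=(n_genes, n_ind, 2))
    rng2 = np.random.default_rng(config.seed + 2)
    noise_e = rng2.normal(0.0, config.noise_sd_expr, size=(n_genes, n_ind))
    target_log2 = truth.latent_expression + noise_e
    rpkm = np.clip(np.exp2(target_log2) - config.log2_offset, 0.0, None)
    expression = np.log2(rpkm + config.log2_offset)
    return levels, expression


def simulate_chromatin_states(
    gene_table: pd.DataFrame,
    seed: int,
    n_states: int = 15,
    mean_length: float = 2000.0,
) -> pd.DataFrame:
    """Tile the synthetic genome with labelled chromatin-state intervals.

    Interval lengths are exponential with the configured mean; labels are
    drawn uniformly from S1..Sn.  Intervals are non-overlapping and cover
    each chromosome from 0 to just past the last gene.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, df in gene_table.groupby("chrom", sort=True):
        end = int(df["tss"].max() + 10_000)
        pos = 0
        while pos < end:
            ln = max(1, int(round(rng.exponential(mean_length))))
            state = int(rng.integers(1, n_states + 1))
            rows.append((chrom, pos, min(pos + ln, end), f"S{state}"))
            pos += ln
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])


def simulate_mappable_windows(
    gene_table: pd.DataFrame, seed: int, drop_fraction: float = 0.05
) -> pd.DataFrame:
    """200-bp windows passing the cross-species mappability screen.

    Emulates the consumed mappability track: the genome is tiled in 200-bp
    windows and a small random fraction is discarded as unmappable.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, df in gene_table.groupby("chrom", sort=True):
        end = int(df["tss"].max() + 10_000)
        starts = np.arange(0, end, 200)
        keep = rng.random(len(starts)) >= drop_fraction
        for s in starts[keep]:
            rows.append((chrom, int(s), int(s) + 200))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def simulate_ortholog_map(
    gene_table: pd.DataFrame,
    species: list[str],
    seed: int,
    half_width: int = 2000,
    low_fraction_rate: float = 0.02,
) -> pd.DataFrame:
    """Cross-genome correspondence of TSS-window regions.

    The synthetic species share a coordinate system, so orthologous regions
    coincide; the aligned-base fraction is concentrated near 1 with a small
    rate of poorly aligning regions (below the 20% retention cutoff).
    Pairs are stored once per unordered species pair; consumers treat the
    mapping symmetrically.
    """
    rng = np.random.default_rng(seed)
    windows = tss_windows(gene_table, half_width)
    rows = []
    for ai in range(len(species)):
        for bi in range(ai + 1, len(species)):
            frac = rng.beta(20.0, 1.5, size=len(windows))
            low = rng.random(len(windows)) < low_fraction_rate
            frac = np.where(low, rng.uniform(0.0, 0.2, size=len(windows)), frac)
            for i, rec in enumerate(windows.itertuples(index=False)):
                rows.append(
                    (
                        species[ai],
                        rec.chrom,
                        rec.start,
                        rec.end,
                        species[bi],
                        rec.chrom,
                        rec.start,
                        rec.end,
                        float(frac[i]),
                        rec.gene_id,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "species_a",
            "chrom_a",
            "start_a",
            "end_a",
            "species_b",
            "chrom_b",
            "start_b",
            "end_b",
            "aligned_fraction",
            "region_id",
        ],
    )


def simulate_read_offsets(
    mark: str, n_reads: int, seed: int, half_width: int = 2000
) -> np.ndarray:
    """Read positions relative to the TSS for profile plots.

    Active marks are bimodal with modes flanking the TSS; the repressive mark
    is broader and flatter.
    """
    rng = np.random.default_rng(seed)
    if mark in BROAD_MARKS:
        offs = rng.uniform(-half_width, half_width, size=n_reads)
    else:
        comp = rng.random(n_reads) < 0.5
        offs = np.where(
            comp,
            rng.normal(-450.0, 220.0, size=n_reads),
            rng.normal(550.0, 260.0, size=n_reads),
        )
    return np.clip(offs, -half_width, half_width - 1)


def simulate_replicate_noise_study(
    n_genes: int,
    n_individuals: int,
    latent_r2: float,
    noise_sd_x: float,
    noise_sd_y: float,
    seed: int,
    mark_covariance: np.ndarray | None = None,
    beta: np.ndarray | None = None,
) -> dict:
    """Direct replicate-noise study for the errors-in-variables estimator.

    Generates latent covariates X (genes x 5) and response y = Xb + e with
    the requested latent variance-explained, then per-individual replicates
    equal to the latent values plus iid Gaussian measurement noise — the
    exact measurement model assumed by the maximal-R² correction.  Returns a
    dict with latent and observed (per-individual and averaged) arrays and
    the realized latent R².
    """
    rng = np.random.default_rng(seed)
    cov = default_mark_covariance() if mark_covariance is None else mark_covariance
    b = DEFAULT_BETA if beta is None else np.asarray(beta, dtype=float)
    x = rng.multivariate_normal(np.zeros(5), cov, size=n_genes)
    signal_var = float(b @ cov @ b)
    sigma2 = signal_var * (1.0 / latent_r2 - 1.0)
    y = x @ b + rng.normal(0.0, np.sqrt(sigma2), size=n_genes)
    per_x = x[None, :, :] + rng.normal(
        0.0, noise_sd_x, size=(n_individuals, n_genes, 5)
    )
    per_y = y[None, :] + rng.normal(0.0, noise_sd_y, size=(n_individuals, n_genes))
    fit = x @ b
    realized = float(np.var(fit) / np.var(y))
    return {
        "x_latent": x,
        "y_latent": y,
        "per_individual_x": per_x,
        "per_individual_y": per_y,
        "x_obs": per_x.mean(axis=0),
        "y_obs": per_y.mean(axis=0),
        "beta": b,
        "latent_r2": realized,
    }


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Persist the ground-truth bundle as JSON (arrays as nested lists)."""
    payload = {
        "gene_ids": truth.gene_ids,
        "individual_ids": truth.individual_ids,
        "true_beta": truth.true_beta.tolist(),
        "de_genes": sorted(truth.de_genes),
        "true_dag": [list(e) for e in truth.true_dag],
        "latent_marks": truth.latent_marks.tolist(),
        "latent_expression": truth.latent_expression.tolist(),
    }
    Path(path).write_text(json.dumps(payload))
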