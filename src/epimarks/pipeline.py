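"""End-to-end orchestration of the synthetic comparative-epigenomics study.

Stages: simulate → classify → quantify → de-test → associate → maximal-r2 →
bayesnet.  Every stage reads its inputs from, and writes its outputs to, the
run directory, so stages can be re-run individually or fed externally
prepared fixtures.  A run manifest records the configuration hash, per-stage
seeds, and the gene/region counts surviving every filter.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from epimarks import io as eio
from epimarks.constants import MARKS
from epimarks.synthetic import (
    SimulationConfig,
    simulate_cohort,
    simulate_mark_observables,
    simulate_expression_counts,
    simulate_chromatin_states,
    simulate_mappable_windows,
    simulate_ortholog_map,
    simulate_read_offsets,
    tss_windows,
    write_ground_truth,
)
from epimarks.classify import CutoffPolicy, filter_mappable_regions, two_step_classify
from epimarks.quantify import (
    mark_enrichment_level,
    expression_level,
    mark_correlation_matrix,
    normalized_peak_rpkm,
    tss_profile,
)
from epimarks.differential import (
    PairwiseDesign,
    median_positive_filter,
    double_quantile_transform,
    permutation_de_test,
    classify_de,
    direction_consistent,
    overlap_fold_enrichment,
)
from epimarks.association import (
    build_features,
    cv_r2,
    interspecies_differences,
    sliding_window_summary,
    expression_tertiles,
)
from epimarks.noise import MaximalR2Input, estimate_noise_variances, maximal_r2
from epimarks.bayesnet import NetScoreConfig, mark_rna_network

log = logging.getLogger("epimarks")


@dataclass
class PipelineConfig:
    outdir: str = "epimarks_run"
    seed: int = 0
    n_genes: int = 400
    window_kb: float = 2.0
    fdr_cutoff: float = 0.05
    cv_folds: int = 10
    cv_replicates: int = 20
    use_bvsr_cv: bool = False
    bvsr_burn_in: int = 1000
    bvsr_sampling: int = 10_000
    edge_prior: float = 0.01
    de_pairs: str = "all"  # "all" | "first"
    simulate_states: bool = True
    sim_overrides: dict = field(default_factory=dict)

    def simulation_config(self) -> SimulationConfig:
        kwargs = dict(
            n_genes=self.n_genes,
            seed=self.seed,
            tss_half_width=int(self.window_kb * 1000),
        )
        kwargs.update(self.sim_overrides)
        return SimulationConfig(**kwargs)

    def scientific_params(self) -> dict:
        """Config without the run location: what determines the results."""
        params = asdict(self)
        params.pop("outdir")
        return params

    def config_hash(self) -> str:
        payload = json.dumps(self.scientific_params(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**eio.config_read(path))


def _outdir(config: PipelineConfig) -> Path:
    p = Path(config.outdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _stage_record(manifest: dict, stage: str, seed: int, counts: dict) -> None:
    manifest["stages"][stage] = {"seed": seed, "counts": counts}
    log.info("stage %s: %s", stage, counts)


# --------------------------------------------------------------------------


def stage_simulate(config: PipelineConfig, manifest: dict) -> None:
    out = _outdir(config)
    sim = config.simulation_config()
    sample_table, gene_table, truth = simulate_cohort(sim)
    states = simulate_chromatin_states(gene_table, seed=sim.seed + 10)
    mappable = simulate_mappable_windows(gene_table, seed=sim.seed + 11)
    orthologs = simulate_ortholog_map(
        gene_table, sim.species_names(), seed=sim.seed + 12, half_width=sim.tss_half_width
    )
    calls, counts = simulate_mark_observables(
        truth,
        sim,
        sample_table,
        gene_table,
        states=states if config.simulate_states else None,
    )
    exon_counts = simulate_expression_counts(truth, sim, sample_table, gene_table)

    eio.tsv_write(sample_table, out / "sample_table.tsv")
    eio.tsv_write(gene_table, out / "gene_models.tsv")
    states_bed = states.rename(columns={"state": "name"})
    eio.bed_write(states_bed, out / "states.bed")
    eio.bed_write(mappable, out / "mappable.bed")
    eio.tsv_write(orthologs, out / "ortholog_map.tsv")
    eio.tsv_write(counts, out / "counts_marks.tsv")
    eio.tsv_write(exon_counts, out / "counts_rna.tsv")
    write_ground_truth(truth, out / "ground_truth.json")

    peaks_dir = out / "peaks"
    peaks_dir.mkdir(exist_ok=True)
    for (mark, ind), sub in calls.groupby(["mark", "individual_id"]):
        bed = sub.rename(columns={"region_id": "name", "confidence": "score"})
        eio.bed_write(bed, peaks_dir / f"{mark}.{ind}.bed")
    # species lookup for re-reading the per-individual files
    eio.tsv_write(
        calls[["region_id", "mark", "individual_id", "species", "gene_id"]],
        out / "call_index.tsv",
    )
    _stage_record(
        manifest,
        "simulate",
        sim.seed,
        {
            "genes": len(gene_table),
            "individuals": len(sample_table),
            "calls": len(calls),
            "de_genes": len(truth.de_genes),
        },
    )


def _read_calls(out: Path) -> pd.DataFrame:
    index = eio.tsv_read(out / "call_index.tsv")
    frames = []
    for (mark, ind), sub in index.groupby(["mark", "individual_id"]):
        bed = eio.bed_read(out / "peaks" / f"{mark}.{ind}.bed")
        bed = bed.rename(columns={"name": "region_id", "score": "confidence"})
        bed["mark"] = mark
        bed["individual_id"] = ind
        bed["species"] = sub["species"].iloc[0]
        bed = bed.merge(sub[["region_id", "gene_id"]], on="region_id", how="left")
        frames.append(bed)
    return pd.concat(frames, ignore_index=True)


def stage_classify(config: PipelineConfig, manifest: dict) -> None:
    out = _outdir(config)
    calls = _read_calls(out)
    mappable = eio.bed_read(out / "mappable.bed")
    orthologs = eio.ortholog_read(out / "ortholog_map.tsv")
    filtered = filter_mappable_regions(calls, mappable, orthologs)
    status = two_step_classify(filtered, orthologs, CutoffPolicy())
    eio.tsv_write(
        status[["region_id", "mark", "individual_id", "species", "status", "enriched"]],
        out / "enrichment_status.tsv",
    )
    _stage_record(
        manifest,
        "classify",
        config.seed,
        {
            "calls_in": len(calls),
            "calls_mappable": len(filtered),
            "stringent": int((status["status"] == "stringent").sum()),
            "relaxed": int((status["status"] == "relaxed").sum()),
        },
    )


def stage_quantify(config: PipelineConfig, manifest: dict) -> None:
    out = _outdir(config)
    sim = config.simulation_config()
    sample_table = eio.tsv_read(out / "sample_table.tsv")
    gene_table = eio.gene_model_read(out / "gene_models.tsv")
    counts = eio.tsv_read(out / "counts_marks.tsv")
    exon_counts = eio.tsv_read(out / "counts_rna.tsv")
    gene_ids = list(gene_table["gene_id"])
    individuals = list(sample_table["individual_id"])

    enrichment = mark_enrichment_level(
        counts,
        genome_average=sim.genome_average_rpkm,
        gene_ids=gene_ids,
        individual_ids=individuals,
    )
    expression = expression_level(
        exon_counts, offset=sim.log2_offset, gene_ids=gene_ids, individual_ids=individuals
    )
    for mark in MARKS:
        eio.matrix_write(
            enrichment.sel(mark=mark).to_pandas(), out / f"enrichment_{mark}.tsv"
        )
    eio.matrix_write(expression.to_pandas(), out / "expression.tsv")
    corr = mark_correlation_matrix(enrichment)
    eio.matrix_write(corr, out / "mark_correlations.tsv", index_name="mark")

    # state-restricted levels (for chromatin-state features), species-mean
    if "state" in counts.columns and (counts["state"] != "all").any():
        state_rows = counts[counts["state"] != "all"].copy()
        state_rows["rpkm"] = normalized_peak_rpkm(
            state_rows["chip_reads"],
            state_rows["input_reads"],
            state_rows["region_length"],
            state_rows["chip_library"],
            state_rows["input_library"],
        )
        state_rows["level"] = np.sqrt(state_rows["rpkm"] / sim.genome_average_rpkm)
        lvl = (
            state_rows.groupby(["gene_id", "state", "mark"])["level"]
            .mean()
            .reset_index()
        )
        lvl["feature"] = lvl["state"] + ":" + lvl["mark"]
        wide = lvl.pivot_table(index="gene_id", columns="feature", values="level").fillna(
            0.0
        )
        eio.matrix_write(wide, out / "state_levels.tsv")

    # TSS profile (bimodal for active marks), averaged over genes/individuals
    windows = tss_windows(gene_table, sim.tss_half_width)
    prof_rows = []
    rng_seed = sim.seed + 13
    for mark in MARKS:
        offsets = simulate_read_offsets(
            mark, n_reads=20_000, seed=rng_seed, half_width=sim.tss_half_width
        )
        prof = tss_profile(
            offsets, half_width=sim.tss_half_width, bin_size=100, n_units=len(windows)
        )
        prof["mark"] = mark
        prof_rows.append(prof)
        rng_seed += 1
    eio.tsv_write(pd.concat(prof_rows, ignore_index=True), out / "tss_profile.tsv")

    # expression-ordered summaries for the first species
    species0 = sample_table["species"].iloc[0]
    inds0 = list(sample_table.loc[sample_table["species"] == species0, "individual_id"])
    expr0 = expression.sel(individual=inds0).mean(dim="individual").to_pandas()
    marks0 = enrichment.sel(individual=[i for i in inds0]).mean(
        dim="individual", skipna=True
    ).to_pandas()
    nonexpr = expr0 <= np.log2(sim.log2_offset) + 1e-9
    window = min(200, max(10, len(expr0) // 5))
    summary = sliding_window_summary(
        expr0, marks0, window=window, nonexpressed_mask=nonexpr
    )
    eio.tsv_write(summary, out / "window_summary.tsv")
    low, mid, high = expression_tertiles(expr0)
    tert = pd.DataFrame(
        {
            "gene_id": list(low) + list(mid) + list(high),
            "tertile": ["low"] * len(low) + ["mid"] * len(mid) + ["high"] * len(high),
        }
    )
    eio.tsv_write(tert, out / "expression_tertiles.tsv")
    _stage_record(
        manifest,
        "quantify",
        sim.seed,
        {
            "genes": len(gene_ids),
            "individuals": len(individuals),
            "missing_slices": len(enrichment.attrs["missing_slices"]),
        },
    )


def _species_pairs(sample_table: pd.DataFrame, which: str) -> list[tuple[str, str]]:
    species = list(pd.unique(sample_table["species"]))
    pairs = [
        (species[i], species[j])
        for i in range(len(species))
        for j in range(i + 1, len(species))
    ]
    return pairs[:1] if which == "first" else pairs


def stage_de(config: PipelineConfig, manifest: dict) -> None:
    out = _outdir(config)
    sample_table = eio.tsv_read(out / "sample_table.tsv")
    sample_table["missing_mark"] = sample_table.get(
        "missing_mark", pd.Series("", index=sample_table.index)
    ).fillna("")
    expression = eio.matrix_read(out / "expression.tsv")
    counts_summary = {}
    overlap_rows = []

    for species_a, species_b in _species_pairs(sample_table, config.de_pairs):
        pair_tag = f"{species_a}_vs_{species_b}"
        de_sets = {}
        deltas = {}
        universes = {}
        for target in ["RNA"] + list(MARKS):
            if target == "RNA":
                matrix = expression
                design = PairwiseDesign.from_sample_table(
                    sample_table, species_a, species_b
                )
            else:
                matrix = eio.matrix_read(out / f"enrichment_{target}.tsv")
                design = PairwiseDesign.from_sample_table(
                    sample_table, species_a, species_b, mark=target
                )
                matrix = matrix[design.individual_ids]
            tested = median_positive_filter(matrix, design)
            sub = matrix.loc[tested]
            transformed = double_quantile_transform(sub, design)
            result = permutation_de_test(transformed, design)
            eio.tsv_write(
                result.table.reset_index(drop=True), out / f"de_{pair_tag}_{target}.tsv"
            )
            de_sets[target] = classify_de(result, config.fdr_cutoff)
            universes[target] = set(tested)
            a_ids = np.asarray(design.individual_ids)[design.group_a_mask()]
            b_ids = np.asarray(design.individual_ids)[~design.group_a_mask()]
            deltas[target] = sub[list(a_ids)].mean(axis=1) - sub[list(b_ids)].mean(axis=1)
            counts_summary[f"{pair_tag}:{target}"] = len(de_sets[target])

        # direction-filtered overlap of DE genes with mark-difference regions
        for mark in MARKS:
            universe = universes["RNA"] & universes[mark]
            direction_ok = {
                g
                for g in universe
                if direction_consistent(
                    float(deltas["RNA"].get(g, 0.0)), float(deltas[mark].get(g, 0.0)), mark
                )
            }
            fold, pval = overlap_fold_enrichment(
                de_sets["RNA"], de_sets[mark], universe, direction_filter=direction_ok
            )
            overlap_rows.append(
                {
                    "pair": pair_tag,
                    "mark": mark,
                    "fold_enrichment": fold,
                    "binomial_p": pval,
                    "n_universe": len(universe & direction_ok),
                }
            )
    eio.tsv_write(pd.DataFrame(overlap_rows), out / "overlap_enrichment.tsv")
    _stage_record(manifest, "de", config.seed, counts_summary)


def stage_associate(config: PipelineConfig, manifest: dict) -> None:
    out = _outdir(config)
    sample_table = eio.tsv_read(out / "sample_table.tsv")
    expression = eio.matrix_read(out / "expression.tsv")
    enrichment = {m: eio.matrix_read(out / f"enrichment_{m}.tsv") for m in MARKS}

    species0 = sample_table["species"].iloc[0]
    inds0 = list(sample_table.loc[sample_table["species"] == species0, "individual_id"])
    per_gene = pd.DataFrame(
        {m: enrichment[m][[c for c in inds0 if c in enrichment[m]]].mean(axis=1) for m in MARKS}
    )
    y0 = expression[inds0].mean(axis=1)

    model = "bvsr" if config.use_bvsr_cv else "ols"
    rows = []
    for mode in ("marginal", "interactions"):
        feats = build_features(per_gene, mode=mode)
        res = cv_r2(
            y0.to_numpy(),
            feats,
            model=model,
            folds=config.cv_folds,
            replicates=config.cv_replicates,
            seed=config.seed + 20,
        )
        rows.append(
            {
                "analysis": f"within_{species0}",
                "features": mode,
                "model": model,
                "n_genes": len(y0),
                "mean_r2": res.mean_r2,
                "sd_r2": res.sd_r2,
            }
        )
    state_path = out / "state_levels.tsv"
    if state_path.exists():
        state_levels = eio.matrix_read(state_path)
        feats = build_features(per_gene, mode="states", state_levels=state_levels)
        res = cv_r2(
            y0.to_numpy(),
            feats,
            model=model,
            folds=config.cv_folds,
            replicates=config.cv_replicates,
            seed=config.seed + 21,
        )
        rows.append(
            {
                "analysis": f"within_{species0}",
                "features": "states",
                "model": model,
                "n_genes": len(y0),
                "mean_r2": res.mean_r2,
                "sd_r2": res.sd_r2,
            }
        )

    # between-species on the DE subset of the first pair
    pairs = _species_pairs(sample_table, "first")
    species_a, species_b = pairs[0]
    pair_tag = f"{species_a}_vs_{species_b}"
    de_path = out / f"de_{pair_tag}_RNA.tsv"
    if de_path.exists():
        de_table = eio.tsv_read(de_path)
        de_genes = list(de_table.loc[de_table["fdr"] <= config.fdr_cutoff, "gene_id"])
        if len(de_genes) >= config.cv_folds:
            import xarray as xr

            enr_arr = xr.DataArray(
                np.stack([enrichment[m].to_numpy() for m in MARKS], axis=-1),
                coords={
                    "gene": list(expression.index),
                    "individual": list(enrichment[MARKS[0]].columns),
                    "mark": list(MARKS),
                },
                dims=("gene", "individual", "mark"),
            )
            expr_arr = xr.DataArray(
                expression.to_numpy(),
                coords={"gene": list(expression.index), "individual": list(expression.columns)},
                dims=("gene", "individual"),
            )
            delta_e, delta_x = interspecies_differences(
                enr_arr, expr_arr, sample_table, species_a, species_b
            )
            de_idx = [g for g in de_genes if g in delta_x.index]
            feats = build_features(delta_e.loc[de_idx], mode="marginal")
            res = cv_r2(
                delta_x.loc[de_idx].to_numpy(),
                feats,
                model=model,
                folds=config.cv_folds,
                replicates=config.cv_replicates,
                seed=config.seed + 22,
            )
            rows.append(
                {
                    "analysis": f"between_{pair_tag}_DE",
                    "features": "marginal",
                    "model": model,
                    "n_genes": len(de_idx),
                    "mean_r2": res.mean_r2,
                    "sd_r2": res.sd_r2,
                }
            )
            summary = sliding_window_summary(
                delta_x,
                delta_e,
                window=min(200, max(10, len(delta_x) // 5)),
                symmetric_scale=True,
            )
            eio.tsv_write(summary, out / f"window_summary_{pair_tag}.tsv")
    eio.tsv_write(pd.DataFrame(rows), out / "cv_r2.tsv")
    _stage_record(manifest, "associate", config.seed, {"analyses": len(rows)})


def stage_maximal_r2(config: PipelineConfig, manifest: dict) -> None:
    out = _outdir(config)
    sample_table = eio.tsv_read(out / "sample_table.tsv")
    expression = eio.matrix_read(out / "expression.tsv")
    enrichment = {m: eio.matrix_read(out / f"enrichment_{m}.tsv") for m in MARKS}

    rows = []
    for species in pd.unique(sample_table["species"]):
        inds = list(sample_table.loc[sample_table["species"] == species, "individual_id"])
        inds = [
            i
            for i in inds
            if all(i in enrichment[m].columns and enrichment[m][i].notna().all() for m in MARKS)
        ]
        if len(inds) < 2:
            continue
        per_y = expression[inds].to_numpy().T  # N x G
        per_x = np.stack(
            [enrichment[m][inds].to_numpy().T for m in MARKS], axis=-1
        )  # N x G x 5
        noise = estimate_noise_variances(per_y, per_x)
        inp = MaximalR2Input.from_replicates(per_y, per_x)
        try:
            corrected, naive = maximal_r2(inp, noise)
        except ValueError as exc:
            log.warning("maximal R2 failed for %s: %s", species, exc)
            continue
        rows.append(
            {
                "analysis": f"within_{species}",
                "n_individuals": len(inds),
                "naive_r2": naive,
                "corrected_r2": corrected,
                "corrected_r2_reported": float(np.clip(corrected, 0.0, 1.0)),
                "sigma_y2": noise.sigma_y2,
            }
        )
    eio.tsv_write(pd.DataFrame(rows), out / "maximal_r2.tsv")
    _stage_record(manifest, "maximal_r2", config.seed, {"analyses": len(rows)})


def stage_bayesnet(config: PipelineConfig, manifest: dict) -> None:
    out = _outdir(config)
    sample_table = eio.tsv_read(out / "sample_table.tsv")
    expression = eio.matrix_read(out / "expression.tsv")
    enrichment = {m: eio.matrix_read(out / f"enrichment_{m}.tsv") for m in MARKS}
    species0 = sample_table["species"].iloc[0]
    inds0 = list(sample_table.loc[sample_table["species"] == species0, "individual_id"])
    data = pd.DataFrame(
        {m: enrichment[m][inds0].mean(axis=1) for m in MARKS}
        | {"RNA": expression[inds0].mean(axis=1)}
    ).dropna()
    edges, score = mark_rna_network(data, NetScoreConfig(edge_prior=config.edge_prior))
    eio.tsv_write(
        pd.DataFrame(edges, columns=["from", "to"]), out / "bayesnet_edges.tsv"
    )
    dot = ["digraph marks {"] + [f'  "{a}" -> "{b}";' for a, b in edges] + ["}"]
    (out / "bayesnet.dot").write_text("\n".join(dot) + "\n")
    _stage_record(
        manifest, "bayesnet", config.seed, {"edges": len(edges), "score": round(score, 3)}
    )


STAGES = {
    "simulate": stage_simulate,
    "classify": stage_classify,
    "quantify": stage_quantify,
    "de-test": stage_de,
    "associate": stage_associate,
    "maximal-r2": stage_maximal_r2,
    "bayesnet": stage_bayesnet,
}


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Run the requested stages (default: all) and write the run manifest.

    A stage failure halts the run with the failing stage named; outputs of
    completed stages are retained on disk.
    """
    out = _outdir(config)
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": config.scientific_params(),
        "stages": {},
    }
    for name in stages or list(STAGES):
        try:
            STAGES[name](config, manifest)
        except Exception as exc:
            manifest["failed_stage"] = name
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
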