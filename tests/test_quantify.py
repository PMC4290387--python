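"""Quantification: RPKM arithmetic, level transforms, TSS tests and profiles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from epimarks import (
    normalized_peak_rpkm,
    mark_enrichment_level,
    expression_level,
    tss_fold_enrichment_test,
    tss_profile,
    mark_correlation_matrix,
    SimulationConfig,
    simulate_cohort,
)
from epimarks.synthetic import simulate_observed_matrices
import xarray as xr


class TestNormalizedPeakRpkm:
    def test_chip_equal_to_scaled_input_gives_zero(self):
        assert normalized_peak_rpkm(40, 160, 2000, 1e6, 4e6) == 0.0

    def test_arithmetic_oracle(self):
        # net reads 30-10=20 over 2 kb at 1e6 library -> 20/(2*1) = 10 RPKM
        assert normalized_peak_rpkm(30, 10, 2000, 1e6, 1e6) == pytest.approx(10.0)

    def test_scale_invariance(self):
        a = normalized_peak_rpkm(30, 10, 2000, 1e6, 1e6)
        b = normalized_peak_rpkm(60, 20, 2000, 2e6, 2e6)
        assert a == pytest.approx(b)

    def test_negative_subtraction_floored(self):
        assert normalized_peak_rpkm(5, 50, 1000, 1e6, 1e6) == 0.0

    def test_zero_length_region_errors(self):
        with pytest.raises(ValueError, match="length"):
            normalized_peak_rpkm(10, 1, 0, 1e6, 1e6)


def _count_row(gene, ind, mark, chip, inp, length=2000, lib=1e6):
    return {
        "region_id": gene,
        "gene_id": gene,
        "individual_id": ind,
        "mark": mark,
        "chip_reads": chip,
        "input_reads": inp,
        "region_length": length,
        "chip_library": lib,
        "input_library": lib,
    }


class TestMarkEnrichmentLevel:
    def test_region_at_genome_average_is_one(self):
        counts = pd.DataFrame([_count_row("g1", "H1", "H3K4me3", chip=4, inp=2)])
        # net 2 reads / 2 kb = 1 RPKM; genome average 1 -> fold 1 -> sqrt 1
        arr = mark_enrichment_level(counts, genome_average=1.0)
        assert float(arr.sel(gene="g1", individual="H1", mark="H3K4me3")) == pytest.approx(1.0)

    def test_all_zero_region_is_zero(self):
        counts = pd.DataFrame([_count_row("g1", "H1", "H3K4me3", chip=0, inp=0)])
        arr = mark_enrichment_level(counts, genome_average=1.0)
        assert float(arr.sel(gene="g1", individual="H1", mark="H3K4me3")) == 0.0

    def test_nonpositive_genome_average_errors(self):
        counts = pd.DataFrame([_count_row("g1", "H1", "H3K4me3", chip=3, inp=1)])
        with pytest.raises(ValueError, match="average"):
            mark_enrichment_level(counts, genome_average=0.0)

    def test_matches_brute_force_on_fixture(self):
        rng = np.random.default_rng(8)
        rows = []
        for g in range(20):
            for ind in ["H1", "H2"]:
                rows.append(
                    _count_row(
                        f"g{g:02d}",
                        ind,
                        "PolII",
                        chip=float(rng.uniform(0, 100)),
                        inp=float(rng.uniform(0, 30)),
                    )
                )
        counts = pd.DataFrame(rows)
        arr = mark_enrichment_level(counts, genome_average=2.0)
        for row in rows:
            net = max(0.0, row["chip_reads"] - row["input_reads"])
            rpkm = net / (2.0 * 1.0)
            expected = np.sqrt(rpkm / 2.0)
            got = float(
                arr.sel(gene=row["gene_id"], individual=row["individual_id"], mark="PolII")
            )
            assert got == pytest.approx(expected)


class TestExpressionLevel:
    def _exon_rows(self, reads_by_exon, lengths, gene="g1", ind="H1", lib=1e6):
        return pd.DataFrame(
            [
                {
                    "gene_id": gene,
                    "exon_index": i,
                    "exon_length": ln,
                    "individual_id": ind,
                    "reads": r,
                    "rna_library": lib,
                }
                for i, (r, ln) in enumerate(zip(reads_by_exon, lengths))
            ]
        )

    def test_zero_counts_give_log2_offset(self):
        arr = expression_level(self._exon_rows([0, 0], [500, 500]), offset=0.25)
        assert float(arr.sel(gene="g1", individual="H1")) == pytest.approx(np.log2(0.25))

    def test_single_exon_arithmetic(self):
        # 100 reads over 1 kb at 1e6 library -> 100 RPKM
        arr = expression_level(self._exon_rows([100], [1000]), offset=0.25)
        assert float(arr.sel(gene="g1", individual="H1")) == pytest.approx(
            np.log2(100.25)
        )

    def test_exon_order_invariance(self):
        a = expression_level(self._exon_rows([10, 90], [300, 700]))
        b = expression_level(self._exon_rows([90, 10], [700, 300]))
        assert float(a.sel(gene="g1", individual="H1")) == pytest.approx(
            float(b.sel(gene="g1", individual="H1"))
        )

    def test_zero_exon_length_errors(self):
        with pytest.raises(ValueError, match="exon length"):
            expression_level(self._exon_rows([10], [0]))


class TestTssFoldEnrichment:
    def test_exact_enumeration_oracle(self):
        """{3,4,5} vs {1,2}: all C(5,2) label splits put the observed rank sum
        at the extreme, so the one-sided p is 1/10."""
        pooled = [3, 4, 5, 1, 2]
        observed = sum(sorted(range(5), key=lambda i: -pooled[i])[:3])
        count = 0
        total = 0
        obs_stat = sum(pooled[:3])
        for combo in itertools.combinations(range(5), 3):
            total += 1
            if sum(pooled[i] for i in combo) >= obs_stat:
                count += 1
        assert count / total == pytest.approx(0.1)
        fold, p = tss_fold_enrichment_test([3, 4, 5], [1, 2])
        assert p == pytest.approx(0.1)
        assert fold == pytest.approx(4 / 1.5)

    def test_identical_distributions_fold_one(self):
        fold, p = tss_fold_enrichment_test([1, 2, 3], [1, 2, 3])
        assert fold == pytest.approx(1.0)
        assert p > 0.4

    def test_all_tied_returns_half_with_warning(self):
        with pytest.warns(UserWarning, match="tied"):
            fold, p = tss_fold_enrichment_test([2, 2], [2, 2])
        assert p == 0.5

    def test_enriched_marks_significant_in_all_species(self):
        """Synthetic TSS signal clears background for all marks and species."""
        cfg = SimulationConfig(n_genes=300, seed=17)
        sample_table, _, truth = simulate_cohort(cfg)
        levels, _ = simulate_observed_matrices(truth, cfg)
        rng = np.random.default_rng(0)
        background = rng.uniform(0.0, 0.2, size=300) ** 2  # genome-wide RPKM draws
        for s in sample_table["species"].unique():
            idx = np.flatnonzero((sample_table["species"] == s).to_numpy())
            for j in range(5):
                tss_vals = (levels[:, idx, j] ** 2).mean(axis=1)
                fold, p = tss_fold_enrichment_test(tss_vals, background)
                assert p < 0.05
                assert fold > 1


class TestTssProfile:
    def test_uniform_reads_flat_profile(self):
        offsets = np.arange(-2000, 2000)
        prof = tss_profile(offsets, half_width=2000, bin_size=100)
        assert prof["value"].nunique() == 1

    def test_bimodal_profile_has_modes_flanking_tss(self):
        from epimarks.synthetic import simulate_read_offsets

        offs = simulate_read_offsets("H3K4me3", 50_000, seed=2)
        prof = tss_profile(offs, half_width=2000, bin_size=100)
        values = prof.set_index("offset_bp")["value"]
        up_peak = values[values.index < 0].idxmax()
        down_peak = values[values.index >= 0].idxmax()
        assert -900 < up_peak < -100
        assert 100 < down_peak < 1100
        assert values.loc[min(abs(values.index))] < values.loc[up_peak]

    def test_profile_mass_conserved(self):
        rng = np.random.default_rng(1)
        offs = rng.uniform(-2000, 1999, size=1000)
        w = rng.uniform(0, 2, size=1000)
        prof = tss_profile(offs, weights=w, half_width=2000, bin_size=200, n_units=4)
        assert prof["value"].sum() * 4 == pytest.approx(w.sum())

    def test_bin_must_divide_window(self):
        with pytest.raises(ValueError, match="divide"):
            tss_profile(np.zeros(3), half_width=2000, bin_size=300)


class TestMarkCorrelations:
    def _array(self, data, marks):
        genes = [f"g{i}" for i in range(data.shape[0])]
        return xr.DataArray(
            data[:, None, :],
            coords={"gene": genes, "individual": ["H1"], "mark": marks},
            dims=("gene", "individual", "mark"),
        )

    def test_unit_diagonal_and_symmetry(self):
        rng = np.random.default_rng(0)
        arr = self._array(rng.normal(size=(30, 3)), ["H3K4me1", "H3K4me3", "H3K27ac"])
        corr = mark_correlation_matrix(arr)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr, corr.T)

    def test_recovers_generator_sign_pattern(self):
        cfg = SimulationConfig(n_genes=3000, seed=13)
        _, _, truth = simulate_cohort(cfg)
        levels, _ = simulate_observed_matrices(truth, cfg)
        arr = xr.DataArray(
            levels,
            coords={
                "gene": truth.gene_ids,
                "individual": truth.individual_ids,
                "mark": ["H3K4me1", "H3K4me3", "H3K27ac", "H3K27me3", "PolII"],
            },
            dims=("gene", "individual", "mark"),
        )
        corr = mark_correlation_matrix(arr)
        off = corr.drop(index="H3K27me3").drop(columns="H3K27me3")
        assert (off.to_numpy()[np.triu_indices(4, 1)] > 0.2).all()
        others = corr.loc["H3K27me3"].drop("H3K27me3")
        assert (others < -0.1).all()

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(20, 3))
        marks = ["H3K4me1", "H3K4me3", "PolII"]
        a = mark_correlation_matrix(self._array(data, marks))
        perm = rng.permutation(20)
        b = mark_correlation_matrix(self._array(data[perm], marks))
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_constant_mark_flagged(self):
        data = np.ones((10, 2))
        data[:, 1] = np.arange(10)
        with pytest.warns(UserWarning, match="constant"):
            corr = mark_correlation_matrix(self._array(data, ["H3K4me1", "PolII"]))
        assert np.isnan(corr.loc["H3K4me1", "PolII"])
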