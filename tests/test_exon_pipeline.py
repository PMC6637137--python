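"""Normalization, summarization, DABG, the three filters, and SI arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import exonsi
from exonsi.design import ExonArrayDesign
from exonsi.matrices import IntensityMatrix
from exonsi.pipeline import (
    apply_filters,
    dabg_pvalues,
    gene_summary,
    probesets_to_exons,
    quantile_normalize,
    splicing_index,
    summarize_probes,
)


def _matrix(values, level="probeset", rows=None, cols=None):
    values = np.asarray(values, dtype=float)
    rows = rows or [f"f{i}" for i in range(values.shape[0])]
    cols = cols or [f"s{j}" for j in range(values.shape[1])]
    return IntensityMatrix(values=pd.DataFrame(values, index=rows, columns=cols), level=level)


def _design(spec, crosshyb=None, probes_per_ps=1):
    """Tiny design from {gene: {exon: [transcripts]}}; one probeset per exon."""
    rows, exon_tx, gene_exons = [], {}, {}
    probe_ids, probe_ps = [], []
    for gene, exons in spec.items():
        gene_exons[gene] = tuple(exons)
        for exon, txs in exons.items():
            ps = f"{exon}_ps0"
            flag = (crosshyb or {}).get(exon, 1)
            rows.append((ps, exon, gene, flag))
            exon_tx[exon] = frozenset(txs)
            for k in range(probes_per_ps):
                probe_ids.append(f"{ps}_p{k}")
                probe_ps.append(ps)
    probesets = pd.DataFrame(
        rows, columns=["probeset_id", "exon_id", "gene_id", "crosshyb_type"]
    ).set_index("probeset_id")
    return ExonArrayDesign(
        probesets=probesets,
        exon_transcripts=exon_tx,
        gene_exons=gene_exons,
        probes=pd.Series(probe_ps, index=probe_ids),
    )


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        m = _matrix([[1.0, 1.0], [3.0, 3.0], [2.0, 2.0]])
        out = quantile_normalize(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_two_columns_become_mean_of_sorted(self):
        m = _matrix(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
        out = quantile_normalize(m)
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        np.testing.assert_allclose(out.values.to_numpy(), expected)

    def test_ties_get_mean_of_spanned_quantiles(self):
        # column 0 has a 3-way tie spanning reference values 1, 2 and 4
        m = _matrix(np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 4.0], [9.0, 9.0]]))
        out = quantile_normalize(m)
        ref = np.sort(m.values.to_numpy(), axis=0).mean(axis=1)  # [3, 3.5, 4.5, 9]
        np.testing.assert_allclose(
            out.values.to_numpy()[:, 0], [ref[:3].mean()] * 3 + [ref[3]]
        )

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            quantile_normalize(_matrix([[np.nan, 1.0], [2.0, 3.0]]))

    @given(
        arrays(
            np.float64,
            (8, 4),
            elements=st.floats(min_value=0, max_value=16, allow_nan=False),
            unique=True,
        )
    )
    def test_column_means_equal_and_idempotent(self, values):
        out = quantile_normalize(_matrix(values))
        means = out.values.mean(axis=0)
        np.testing.assert_allclose(means, means.iloc[0], atol=1e-12)
        again = quantile_normalize(out)
        np.testing.assert_allclose(again.values.to_numpy(), out.values.to_numpy(), atol=1e-12)


class TestSummarizeProbes:
    def test_single_probe_probeset_passthrough(self):
        design = _design({"g": {"e0": ["t0", "t1"]}}, probes_per_ps=1)
        probe = _matrix([[5.0, 7.0, 6.0]], level="probe", rows=["e0_ps0_p0"])
        out = summarize_probes(probe, design)
        np.testing.assert_allclose(out.values.loc["e0_ps0"], [5.0, 7.0, 6.0])

    def test_additive_model_fixed_point(self, rng):
        """On exactly additive probe data r_i + c_j, median polish preserves
        sample-to-sample differences exactly."""
        design = _design({"g": {"e0": ["t0", "t1"]}}, probes_per_ps=5)
        r = rng.normal(0, 1, size=5)
        c = rng.normal(8, 2, size=6)
        probe = _matrix(
            r[:, None] + c[None, :], level="probe", rows=[f"e0_ps0_p{k}" for k in range(5)]
        )
        out = summarize_probes(probe, design)
        got = out.values.loc["e0_ps0"].to_numpy()
        np.testing.assert_allclose(np.diff(got), np.diff(c), atol=1e-9)

    def test_median_method(self):
        design = _design({"g": {"e0": ["t0", "t1"]}}, probes_per_ps=3)
        probe = _matrix(
            np.array([[5.0, 5.0], [7.0, 7.0], [9.0, 9.0]]),
            level="probe",
            rows=[f"e0_ps0_p{k}" for k in range(3)],
        )
        out = summarize_probes(probe, design, method="median")
        np.testing.assert_allclose(out.values.loc["e0_ps0"], [7.0, 7.0])

    def test_unmapped_probe_is_error(self):
        design = _design({"g": {"e0": ["t0", "t1"]}})
        probe = _matrix([[1.0, 2.0]], level="probe", rows=["mystery_probe"])
        with pytest.raises(ValueError, match="not mapped"):
            summarize_probes(probe, design)


class TestDabg:
    def test_counting_definition(self):
        pool = np.arange(999, dtype=float)  # 0..998, distinct
        m = _matrix([[2000.0], [-5.0], [499.0]])
        # single sample: pad a second column with the same values
        m = _matrix([[2000.0, 2000.0], [-5.0, -5.0], [499.0, 499.0]])
        p = dabg_pvalues(m, pool)
        assert p.iloc[0, 0] == pytest.approx(1 / 1000)  # above max
        assert p.iloc[1, 0] == pytest.approx(1.0)  # below min
        assert p.iloc[2, 0] == pytest.approx(0.5, abs=0.002)  # at the median

    def test_empty_or_small_pool_rejected(self):
        m = _matrix([[1.0, 2.0]])
        with pytest.raises(ValueError):
            dabg_pvalues(m, [])
        with pytest.raises(ValueError):
            dabg_pvalues(m, list(range(50)))


class TestApplyFilters:
    @staticmethod
    def _setup():
        design = _design(
            {
                "g1": {"e0": ["t0", "t1"], "e1": ["t0"], "e2": ["t0", "t1"]},
                "g2": {"e3": ["t2", "t3"], "e4": ["t2", "t3"]},
            },
            crosshyb={"e3": 2},
        )
        rows = [f"{e}_ps0" for e in ["e0", "e1", "e2", "e3", "e4"]]
        cols = [f"n{i}" for i in range(10)] + [f"t{i}" for i in range(10)]
        values = np.full((5, 20), 10.0)
        matrix = _matrix(values, rows=rows, cols=cols)
        groups = pd.Series(["normal"] * 10 + ["tumor"] * 10, index=cols)
        dabg = pd.DataFrame(0.001, index=rows, columns=cols)
        return design, matrix, groups, dabg

    def test_crosshyb_removed_regardless_of_signal(self):
        design, matrix, groups, dabg = self._setup()
        filtered, audit = apply_filters(matrix, design, dabg, groups)
        assert "e3_ps0" not in filtered.values.index
        assert audit.removed_crosshyb == 1

    def test_detected_in_six_of_ten_tumor_samples_is_retained(self):
        design, matrix, groups, dabg = self._setup()
        dabg.loc["e0_ps0"] = 0.9
        dabg.loc["e0_ps0", [f"t{i}" for i in range(6)]] = 0.01  # 6 >= ceil(5)
        filtered, audit = apply_filters(matrix, design, dabg, groups)
        assert "e0_ps0" in filtered.values.index

    def test_detected_in_four_of_ten_in_both_groups_is_removed(self):
        design, matrix, groups, dabg = self._setup()
        dabg.loc["e0_ps0"] = 0.9
        dabg.loc["e0_ps0", ["t0", "t1", "t2", "t3", "n0", "n1", "n2", "n3"]] = 0.01
        filtered, audit = apply_filters(matrix, design, dabg, groups)
        assert "e0_ps0" not in filtered.values.index
        assert audit.removed_dabg == 1

    def test_single_transcript_exon_removed(self):
        design, matrix, groups, dabg = self._setup()
        filtered, audit = apply_filters(matrix, design, dabg, groups)
        assert "e1_ps0" not in filtered.values.index  # e1 only in t0
        assert audit.removed_unique_exon == 1

    def test_audit_telescopes(self):
        design, matrix, groups, dabg = self._setup()
        _, audit = apply_filters(matrix, design, dabg, groups)
        audit.check_consistent()
        assert audit.probesets_in == 5
        assert audit.probesets_out == 3

    def test_filters_1_and_3_commute(self, small_dataset):
        """Cross-hyb and unique-exon filters are signal-independent, so the
        surviving set is the same whichever order they are applied in."""
        design, cohort, expr = small_dataset
        probesets = summarize_probes(expr.probe_matrix, design)
        dabg = dabg_pvalues(probesets, expr.background_pool)
        groups = cohort.groups()
        surviving, _ = apply_filters(probesets, design, dabg, groups)

        # reversed order: unique-exon first, then cross-hyb, then DABG
        n_tx = design.transcript_counts()
        info = design.probesets.loc[probesets.values.index]
        keep3 = ~info["exon_id"].map(n_tx).eq(1)
        keep1 = info["crosshyb_type"] == 1
        sizes = groups.value_counts()
        detected = pd.Series(False, index=probesets.values.index)
        for g, size in sizes.items():
            cols = groups.index[groups == g]
            detected |= (dabg[cols] < 0.05).sum(axis=1) >= int(np.ceil(0.5 * size))
        reversed_set = set(probesets.values.index[keep3 & keep1 & detected])
        assert set(surviving.values.index) == reversed_set

    def test_zero_sample_group_rejected(self):
        design, matrix, groups, dabg = self._setup()
        bad_groups = pd.Series("tumor", index=groups.index)
        # a declared group with zero samples arises from a categorical with
        # unused levels; emulate via an empty selection
        with pytest.raises(ValueError):
            apply_filters(matrix.values.iloc[:, :0].pipe(
                lambda v: IntensityMatrix(values=v, level="probeset")
            ), design, dabg.iloc[:, :0], pd.Series(dtype=object))


class TestGeneSummaryAndSI:
    def test_median_and_mean(self):
        design = _design({"g": {"e0": ["t0", "t1"], "e1": ["t0", "t1"], "e2": ["t0", "t1"]}})
        exons = _matrix([[4.0], [6.0], [8.0]], level="exon", rows=["e0", "e1", "e2"], cols=["s0"])
        assert gene_summary(exons, design, method="median").values.loc["g", "s0"] == 6.0
        assert gene_summary(exons, design, method="mean").values.loc["g", "s0"] == 6.0

    def test_single_exon_gene_forces_si_zero(self):
        design = _design({"g": {"e0": ["t0", "t1"]}})
        exons = _matrix([[7.3, 9.1]], level="exon", rows=["e0"])
        genes = gene_summary(exons, design)
        si = splicing_index(exons, genes, design)
        np.testing.assert_allclose(si.values.to_numpy(), 0.0)

    def test_si_is_exon_minus_gene(self):
        design = _design({"g": {"e0": ["t0", "t1"], "e1": ["t0", "t1"]}})
        exons = _matrix([[8.0], [6.0]], level="exon", rows=["e0", "e1"], cols=["s0"])
        genes = _matrix([[6.0]], level="gene", rows=["g"], cols=["s0"])
        si = splicing_index(exons, genes, design)
        assert si.values.loc["e0", "s0"] == pytest.approx(2.0)
        assert si.values.loc["e1", "s0"] == pytest.approx(0.0)

    def test_si_shift_invariance(self):
        design = _design({"g": {"e0": ["t0", "t1"], "e1": ["t0", "t1"]}})
        exons = _matrix([[8.0, 5.0], [6.0, 7.0]], level="exon", rows=["e0", "e1"])
        genes = gene_summary(exons, design)
        si = splicing_index(exons, genes, design)
        shifted = _matrix(exons.values.to_numpy() + 3.7, level="exon", rows=["e0", "e1"])
        si2 = splicing_index(shifted, gene_summary(shifted, design), design)
        np.testing.assert_allclose(si.values.to_numpy(), si2.values.to_numpy(), atol=1e-12)

    def test_missing_gene_is_error(self):
        design = _design({"g": {"e0": ["t0", "t1"]}})
        exons = _matrix([[8.0]], level="exon", rows=["e0"], cols=["s0"])
        genes = _matrix([[6.0]], level="gene", rows=["other_gene"], cols=["s0"])
        with pytest.raises(ValueError, match="absent"):
            splicing_index(exons, genes, design)


class TestPipelineProperties:
    def test_zero_noise_zero_effect_si_is_zero(self):
        params = exonsi.SimulationParams(
            n_genes=30, exons_per_gene=(5, 5), n_subjects=10,
            gene_de_fraction=0.0, splice_fraction=0.0, undetected_fraction=0.0,
            noise_sd=0.0, subject_sd=0.0, probe_noise_sd=0.0, exon_sd=0.0, seed=13,
        )
        design = exonsi.make_design(params)
        cohort = exonsi.simulate_cohort(params)
        expr = exonsi.simulate_intensities(design, cohort, params)
        si = exonsi.run_exon_pipeline(
            expr.probe_matrix, design, expr.background_pool, cohort.groups()
        )
        assert np.abs(si.values.to_numpy()).max() < 1e-9

    def test_undetected_exons_removed_by_dabg_filter(self):
        params = exonsi.SimulationParams(
            n_genes=80, exons_per_gene=(5, 5), n_subjects=10,
            undetected_fraction=0.2, crosshyb_fraction=0.0, seed=17,
        )
        design = exonsi.make_design(params)
        cohort = exonsi.simulate_cohort(params)
        expr = exonsi.simulate_intensities(design, cohort, params)
        probesets = summarize_probes(quantile_normalize(expr.probe_matrix), design)
        dabg = dabg_pvalues(probesets, expr.background_pool)
        filtered, _ = apply_filters(probesets, design, dabg, cohort.groups())
        surviving_exons = set(design.probesets.loc[filtered.values.index, "exon_id"])
        undetected = set(expr.truth.exons.index[~expr.truth.exons["is_detected"]])
        removed_fraction = 1 - len(undetected & surviving_exons) / len(undetected)
        assert removed_fraction >= 0.99
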