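"""End-to-end analysis: simulate (or load) → exon pipeline → differential
usage → variants → survival → qPCR, with a machine-readable summary.

Every stage logs its row counts in and out; the summary JSON telescopes the
filter audit and records how many features were significant at each
threshold, the consequence-class percentages, the clinical association
statistics and the survival comparison, so a run is fully described by one
file.  All randomness flows from the single config seed through named
substreams, so repeated runs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, pipeline, qpcr, simulate, survival, variants
from .config import PipelineConfig
from .design import ExonArrayDesign
from .matrices import IntensityMatrix
from .simulate import CODON72_POS, ClinicalTable

log = logging.getLogger(__name__)


def _load_inputs(config: PipelineConfig):
    design = ExonArrayDesign.from_tsv(config.design_path)
    probe_matrix = IntensityMatrix.from_tsv(config.probe_matrix_path, level="probe")
    # rebuild the probe → probeset map from probe ids written by the simulator
    ps = probe_matrix.values.index.str.rsplit("_p", n=1).str[0]
    design.probes = pd.Series(ps.to_numpy(), index=probe_matrix.values.index)
    pool = pd.read_csv(config.background_path, sep="\t")["intensity"].to_numpy()
    clinical = ClinicalTable.read(config.clinical_path, config.sample_sheet_path)
    records = variants.read_vcf(config.vcf_path) if config.vcf_path else []
    cq = pd.read_csv(config.cq_path, sep="\t") if config.cq_path else None
    return design, probe_matrix, pool, clinical, records, cq


def run_all(config: PipelineConfig) -> dict:
    """Run the full pipeline per the configuration; returns the summary dict.

    Writes under ``config.out_dir``: the simulated dataset (when simulating),
    the SI matrix, all result tables (TSV) and ``summary.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    summary: dict = {"seed": config.seed, "correction": th.correction}

    stage = "simulate" if config.simulate else "load inputs"
    try:
        if config.simulate:
            params = config.sim.model_copy(update={"seed": config.seed})
            design = simulate.make_design(params)
            cohort = simulate.simulate_cohort(params, recurrence_rate=config.recurrence_rate)
            expr = simulate.simulate_intensities(design, cohort, params)
            vs = config.variant_sim
            records, clinical, vtruth = simulate.simulate_variant_cohort(
                cohort,
                prevalence=vs.prevalence,
                hazard_ratio=vs.hazard_ratio,
                baseline_hazard=vs.baseline_hazard,
                censor_time=vs.censor_time,
                fail_qual_fraction=vs.fail_qual_fraction,
                fail_dp4_fraction=vs.fail_dp4_fraction,
                fail_pl_fraction=vs.fail_pl_fraction,
                seed=config.seed,
            )
            cq_table = simulate.simulate_cq_table(cohort, seed=config.seed) if config.run_qpcr else None
            probe_matrix, pool = expr.probe_matrix, expr.background_pool
            design.to_tsv(out / "design.tsv")
            clinical.write(out)
            expr.truth.write(out)
            vtruth.write(out)
            variants.write_vcf(records, out / "variants.vcf")
        else:
            design, probe_matrix, pool, clinical, records, cq_table = _load_inputs(config)

        # -- exon pipeline -------------------------------------------------
        stage = "exon_pipeline"
        groups = clinical.groups()
        si = pipeline.run_exon_pipeline(
            probe_matrix,
            design,
            pool,
            groups,
            alpha=th.dabg_alpha,
            detect_fraction=th.detect_fraction,
            unique_exon_rule=th.unique_exon_rule,
            gene_method=th.gene_summary_method,
        )
        si.to_tsv(out / "splicing_index.tsv")
        summary["filters"] = si.audit.as_dict()
        log.info("exon pipeline: %d exons with SI values", len(si.values))

        # -- differential exon usage --------------------------------------
        stage = "diffexpr"
        pairing = clinical.pairing()
        tumor_res = diffexpr.exon_usage_test(
            si,
            groups,
            paired=True,
            pairing=pairing,
            shrink_variance=th.shrink_variance,
            correction=th.correction,
        )
        tumor_res.to_csv(out / "exon_usage_tumor_vs_normal.tsv", sep="\t", index=False)
        summary["exon_usage_tumor_vs_normal"] = {
            "n_tested": int(tumor_res["p"].notna().sum()),
            "n_significant": int((tumor_res["p_adj"] < th.si_alpha_tumor).sum()),
            "alpha": th.si_alpha_tumor,
        }

        tumor_samples = clinical.samples[clinical.samples["tissue"] == "tumor"]
        recur = clinical.subjects.loc[tumor_samples["subject_id"], "recurrence"].to_numpy()
        rec_groups = pd.Series(
            np.where(recur == 1, "recurrent", "non_recurrent"), index=tumor_samples.index
        )
        if rec_groups.value_counts().min() >= 2 and rec_groups.nunique() == 2:
            rec_res = diffexpr.exon_usage_test(
                si.values[tumor_samples.index],
                rec_groups,
                paired=False,
                shrink_variance=th.shrink_variance,
                correction=th.correction,
            )
            rec_res.to_csv(out / "exon_usage_recurrence.tsv", sep="\t", index=False)
            summary["exon_usage_recurrent_vs_nonrecurrent"] = {
                "n_tested": int(rec_res["p"].notna().sum()),
                "n_significant": int((rec_res["p_adj"] < th.si_alpha_recurrence).sum()),
                "alpha": th.si_alpha_recurrence,
            }

        # -- qPCR ----------------------------------------------------------
        if cq_table is not None:
            stage = "qpcr"
            qres = qpcr.paired_readout_comparison(cq_table, pairing, reference="TBP")
            qres.to_csv(out / "qpcr_results.tsv", sep="\t", index=False)
            summary["qpcr"] = {
                row["feature_id"]: {
                    "log2_ratio": round(float(row["effect"]), 6),
                    "p": round(float(row["p"]), 8),
                }
                for _, row in qres.iterrows()
            }

        # -- variants ------------------------------------------------------
        stage = "variants"
        alt_records = [r for r in records if r.is_alt]
        passing, audit = variants.filter_variants(
            alt_records, qual_min=th.qual_min, dp4_min=th.dp4_min, pl_min=th.pl_min
        )
        csq = variants.consequence_summary(passing)
        summary["variant_filters"] = audit.as_dict()
        summary["consequences"] = {
            "total_distinct_snvs": csq.total,
            "percentages": {k: round(v, 4) for k, v in sorted(csq.percentages.items())},
        }
        subjects = list(clinical.subjects.index)
        carrier_flags = {s: csq.carriers.get(s, False) for s in subjects}
        stage_flag = variants.dichotomize_stage(clinical.subjects["stage"])
        grade_flag = clinical.subjects["grade"] == "high"
        fisher_stage = variants.fisher_association(carrier_flags, stage_flag)
        fisher_grade = variants.fisher_association(carrier_flags, grade_flag)
        summary["associations"] = {
            "carrier_vs_stage": {"odds_ratio": fisher_stage.odds_ratio, "p": fisher_stage.p_value},
            "carrier_vs_grade": {"odds_ratio": fisher_grade.odds_ratio, "p": fisher_grade.p_value},
        }

        # -- survival ------------------------------------------------------
        stage = "survival"
        geno = variants.genotype_partition(records, ("17", CODON72_POS), subjects=subjects)
        clin = clinical.subjects.assign(codon72=[geno[s] for s in subjects])
        two = clin[clin["codon72"].isin(["CC", "GC"])].dropna(subset=["time", "event"])
        if len(two) and two["codon72"].nunique() == 2:
            lr = survival.logrank_test(two["time"], two["event"], two["codon72"])
            summary["survival"] = {
                "groups": {g: int(n) for g, n in two["codon72"].value_counts().sort_index().items()},
                "logrank_chi2": round(lr.chi_square, 6),
                "logrank_p": round(lr.p_value, 8),
            }
            curves = survival.survival_by_group(two, "codon72")
            for label, curve in curves.items():
                curve.table.to_csv(out / f"km_{label}.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001 — abort with the failing stage named
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary_json = json.dumps(summary, indent=2, sort_keys=True, allow_nan=False, default=float)
    (out / "summary.json").write_text(summary_json + "\n")
    _write_human_report(summary, out / "report.txt")
    return summary


def _write_human_report(summary: dict, path: Path) -> None:
    lines = [
        "Splicing-index pipeline report",
        "==============================",
        f"seed: {summary['seed']}   multiple-testing correction: {summary['correction']}",
        "",
    ]
    f = summary.get("filters", {})
    if f:
        lines += [
            f"Probesets in: {f['probesets_in']}",
            f"  removed (cross-hyb flag != 1): {f['removed_crosshyb']}",
            f"  removed (not detected above background): {f['removed_dabg']}",
            f"  removed (exon unique to one transcript): {f['removed_unique_exon']}",
            f"Probesets out: {f['probesets_out']}  ({f['exons_out']} exons)",
            "",
        ]
    for key, title in [
        ("exon_usage_tumor_vs_normal", "Tumor vs normal (paired)"),
        ("exon_usage_recurrent_vs_nonrecurrent", "Recurrent vs non-recurrent"),
    ]:
        if key in summary:
            s = summary[key]
            lines.append(
                f"{title}: {s['n_significant']} / {s['n_tested']} exons significant "
                f"(adjusted p < {s['alpha']})"
            )
    if "consequences" in summary:
        c = summary["consequences"]
        lines += ["", f"Distinct SNVs after quality filters: {c['total_distinct_snvs']}"]
        for k, v in c["percentages"].items():
            lines.append(f"  {k}: {v:.1f}%")
    if "survival" in summary:
        s = summary["survival"]
        lines += [
            "",
            f"Log-rank CC vs GC: chi2 = {s['logrank_chi2']:.4f}, p = {s['logrank_p']:.4g}",
        ]
    path.write_text("\n".join(lines) + "\n")
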