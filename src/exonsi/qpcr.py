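"""Efficiency-corrected relative quantification of qPCR read-outs.

Quantification follows the single-reference-gene efficiency-corrected
(Pfaffl) model: the expression of a target gene in a case sample relative to
its control, normalized to a reference gene, is

    ratio = E_target^(ΔCq_target) / E_ref^(ΔCq_ref),   ΔCq = Cq_control − Cq_case,

where E is the amplification factor per cycle estimated from a standard
dilution series (E = 10^(−1/slope) for the OLS slope of Cq on log10
concentration).  With both efficiencies equal to 2 this reduces to the
classic 2^(−ΔΔCq) method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import paired_t_test

log = logging.getLogger(__name__)


@dataclass
class EfficiencyEstimate:
    """Amplification efficiency from a dilution series."""

    slope: float  # cycles per log10 dilution, negative for an amplifying assay
    intercept: float
    efficiency: float  # amplification factor per cycle, 2.0 = perfect doubling
    r_squared: float
    gene_id: str | None = None


def efficiency_from_dilution(
    dilution_log10: Sequence[float], cq: Sequence[float], gene_id: str | None = None
) -> EfficiencyEstimate:
    """Estimate amplification efficiency E = 10^(−1/slope) by OLS.

    Needs at least 3 strictly monotone dilution points; a non-negative slope
    (Cq not decreasing with template amount) means the assay does not
    amplify and is an error.
    """
    x = np.asarray(dilution_log10, dtype=float)
    y = np.asarray(cq, dtype=float)
    if x.size < 3:
        raise ValueError("dilution series needs at least 3 points")
    diffs = np.diff(x)
    if not ((diffs > 0).all() or (diffs < 0).all()):
        raise ValueError("dilutions must be strictly monotone")
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError(f"non-amplifying assay: slope {fit.slope:.3f} >= 0")
    return EfficiencyEstimate(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        efficiency=float(10.0 ** (-1.0 / fit.slope)),
        r_squared=float(fit.rvalue**2),
        gene_id=gene_id,
    )


def relative_expression(
    target_cq: tuple[float, float],
    reference_cq: tuple[float, float],
    e_target: float = 2.0,
    e_ref: float = 2.0,
) -> float:
    """Efficiency-corrected expression ratio of case over control.

    Both Cq arguments are (control, case) pairs; a ratio above 1 means the
    target is higher in the case sample.
    """
    for cq in (*target_cq, *reference_cq):
        if not np.isfinite(cq):
            raise ValueError("all Cq values must be finite")
    d_target = target_cq[0] - target_cq[1]
    d_ref = reference_cq[0] - reference_cq[1]
    return float(e_target**d_target / e_ref**d_ref)


def paired_readout_comparison(
    cq_table: pd.DataFrame,
    pairing: Mapping[str, tuple[str, str]],
    reference: str = "TBP",
    efficiencies: Mapping[str, float] | None = None,
    correction: str | None = "BH",
) -> pd.DataFrame:
    """Per-gene paired comparison of tumor vs normal qPCR read-outs.

    Replicate Cq values are averaged per (sample, gene); for every pair the
    efficiency-corrected ratio against the reference gene is computed and the
    log2 ratios are tested against zero with the paired t machinery.  Pairs
    missing the reference Cq in either sample are excluded and logged.
    """
    required = {"sample", "gene", "cq"}
    if not required <= set(cq_table.columns):
        raise ValueError(f"Cq table must have columns {sorted(required)}")
    efficiencies = dict(efficiencies or {})
    mean_cq = cq_table.groupby(["gene", "sample"], sort=False)["cq"].mean()
    genes = [g for g in cq_table["gene"].unique() if g != reference]
    if reference not in set(cq_table["gene"]):
        raise ValueError(f"reference gene {reference!r} absent from Cq table")

    log_ratios: dict[str, dict[str, float]] = {g: {} for g in genes}
    n_excluded = 0
    for subject, (control, case) in pairing.items():
        try:
            ref_pair = (mean_cq[(reference, control)], mean_cq[(reference, case)])
        except KeyError:
            n_excluded += 1
            continue
        for g in genes:
            try:
                tgt_pair = (mean_cq[(g, control)], mean_cq[(g, case)])
            except KeyError:
                continue
            ratio = relative_expression(
                tgt_pair,
                ref_pair,
                e_target=efficiencies.get(g, 2.0),
                e_ref=efficiencies.get(reference, 2.0),
            )
            log_ratios[g][subject] = np.log2(ratio)
    if n_excluded:
        log.warning("excluded %d pair(s) lacking reference-gene Cq", n_excluded)

    # one-sample paired t on log2 ratios: reuse the paired machinery by
    # presenting ratios as case columns against zero controls
    subjects = sorted({s for g in genes for s in log_ratios[g]})
    if len(subjects) < 3:
        raise ValueError("need at least 3 complete pairs")
    ratio_matrix = pd.DataFrame(
        {f"{s}_ratio": [log_ratios[g].get(s, np.nan) for g in genes] for s in subjects},
        index=genes,
    )
    zero = pd.DataFrame(0.0, index=genes, columns=[f"{s}_zero" for s in subjects])
    combined = pd.concat([zero, ratio_matrix], axis=1)
    fake_pairing = {s: (f"{s}_zero", f"{s}_ratio") for s in subjects}
    res = paired_t_test(combined, fake_pairing, correction=correction)
    res["method"] = "qpcr_paired_log2_ratio"
    return res
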