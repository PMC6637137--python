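"""Exon-array processing: normalization, summarization, filtering, splicing index.

The splicing index (SI) of an exon in a sample is the log2 exon intensity
minus the log2 intensity of its gene, so it measures exon inclusion relative
to overall gene expression.  Before the SI is computed the probeset matrix
passes three filters:

1. drop probesets whose ``crosshyb_type`` flag differs from 1 (probes that
   hybridise to off-target sequences);
2. drop probesets not detected above background (DABG p < alpha) in at least
   ~50% of the samples of at least one group;
3. drop exons contained in a single transcript — their inclusion cannot vary
   between isoforms, so they carry no alternative-splicing information.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .design import ExonArrayDesign
from .matrices import FilterAudit, IntensityMatrix, SIMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Force every sample onto the common quantile distribution.

    Each column is replaced by the row-wise mean of the sorted columns,
    assigned by rank; tied values receive the mean of the quantile values
    their ranks span.  This is the normalization step of RMA.
    """
    matrix.require_finite()
    X = matrix.values.to_numpy(dtype=float)
    n, m = X.shape
    if m < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(m):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n)
        assigned[order] = ref
        # ties: average the reference values spanned by each tied group
        out[:, j] = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
    return IntensityMatrix(
        values=pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        level=matrix.level,
    )


# ---------------------------------------------------------------------------
# probe → probeset summarization
# ---------------------------------------------------------------------------

def _median_polish_stack(A: np.ndarray, tol: float = 1e-6, max_iter: int = 10) -> np.ndarray:
    """Vectorised Tukey median polish on a stack of (probe × sample) blocks.

    ``A`` has shape (n_blocks, n_probes, n_samples).  Returns the probeset
    signal per block and sample: overall effect + column (sample) effect.
    """
    resid = A.astype(float).copy()
    overall = np.zeros(A.shape[0])
    row = np.zeros(A.shape[:2])
    col = np.zeros((A.shape[0], A.shape[2]))
    for _ in range(max_iter):
        rmed = np.median(resid, axis=2)
        resid -= rmed[:, :, None]
        row += rmed
        rshift = np.median(row, axis=1)
        row -= rshift[:, None]
        overall += rshift
        cmed = np.median(resid, axis=1)
        resid -= cmed[:, None, :]
        col += cmed
        cshift = np.median(col, axis=1)
        col -= cshift[:, None]
        overall += cshift
        if max(np.abs(rmed).max(), np.abs(cmed).max()) < tol:
            break
    return overall[:, None] + col


def summarize_probes(
    probe_matrix: IntensityMatrix,
    design: ExonArrayDesign,
    method: Literal["median_polish", "median"] = "median_polish",
) -> IntensityMatrix:
    """Summarise probe rows into one signal per probeset.

    ``median_polish`` fits the additive two-way model (row = probe,
    column = sample) by Tukey median polish and reports overall + sample
    effects, as in RMA; ``median`` takes the per-sample median across probes.
    """
    if probe_matrix.level != "probe":
        raise ValueError("summarize_probes expects a probe-level matrix")
    if design.probes is None:
        raise ValueError("design carries no probe → probeset mapping")
    probe_map = design.probes
    unmapped = probe_matrix.values.index.difference(probe_map.index)
    if len(unmapped):
        raise ValueError(f"{len(unmapped)} probe rows not mapped to a probeset")

    groups = probe_map.loc[probe_matrix.values.index]
    by_ps = probe_matrix.values.groupby(groups, sort=False)
    sizes = by_ps.size()
    empty = set(design.probesets.index) - set(sizes.index)
    if empty:
        raise ValueError(f"probeset(s) with zero probes: {sorted(empty)[:5]}")

    samples = probe_matrix.values.columns
    if method == "median":
        summarized = by_ps.median()
    elif method == "median_polish":
        pieces = []
        X = probe_matrix.values.to_numpy(dtype=float)
        positions = {p: i for i, p in enumerate(probe_matrix.values.index)}
        for k, size_group in sizes.groupby(sizes):
            ps_ids = list(size_group.index)
            idx = np.array(
                [[positions[p] for p in by_ps.groups[ps]] for ps in ps_ids], dtype=int
            )
            stack = X[idx]  # (n_probesets_k, k, n_samples)
            vals = _median_polish_stack(stack)
            pieces.append(pd.DataFrame(vals, index=ps_ids, columns=samples))
        summarized = pd.concat(pieces).loc[sizes.index]
    else:
        raise ValueError(f"unknown summarization method {method!r}")
    return IntensityMatrix(values=summarized, level="probeset")


def probesets_to_exons(
    matrix: IntensityMatrix, design: ExonArrayDesign, method: str = "median"
) -> IntensityMatrix:
    """Collapse probeset rows to exon rows (median across a probeset's exon)."""
    if matrix.level != "probeset":
        raise ValueError("expected a probeset-level matrix")
    exon_of = design.probesets.loc[matrix.values.index, "exon_id"]
    grouped = matrix.values.groupby(exon_of, sort=False)
    values = grouped.median() if method == "median" else grouped.mean()
    return IntensityMatrix(values=values, level="exon")


# ---------------------------------------------------------------------------
# detection above background
# ---------------------------------------------------------------------------

def dabg_pvalues(matrix: IntensityMatrix, background_pool: Iterable[float]) -> pd.DataFrame:
    """Empirical 'detected above background' p-values.

    p(feature, sample) = (1 + #{b in pool : b >= intensity}) / (1 + |pool|),
    the exceedance probability against the background distribution with an
    add-one correction, so p is always in (0, 1].
    """
    pool = np.sort(np.asarray(list(background_pool), dtype=float))
    if pool.size == 0:
        raise ValueError("background pool is empty")
    if pool.size < 100:
        raise ValueError("background pool must hold at least 100 intensities")
    X = matrix.values.to_numpy(dtype=float)
    n_ge = pool.size - np.searchsorted(pool, X, side="left")
    p = (1.0 + n_ge) / (1.0 + pool.size)
    return pd.DataFrame(p, index=matrix.values.index, columns=matrix.values.columns)


# ---------------------------------------------------------------------------
# the three filters
# ---------------------------------------------------------------------------

def apply_filters(
    matrix: IntensityMatrix,
    design: ExonArrayDesign,
    dabg: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
    detect_fraction: float = 0.5,
    unique_exon_rule: Literal["single_transcript", "private_to_transcript"] = "single_transcript",
) -> tuple[IntensityMatrix, FilterAudit]:
    """Apply the cross-hyb, DABG-detection and unique-exon filters in order.

    Filter 2 keeps a probeset iff, in at least ``ceil(detect_fraction × group
    size)`` samples of at least one group, its DABG p-value is below ``alpha``.
    Filter 3 removes exons whose transcript set has size 1
    (``single_transcript``, the default) or, under ``private_to_transcript``,
    only such exons in genes that have several transcripts.
    """
    if matrix.level != "probeset":
        raise ValueError("filters operate on the probeset-level matrix")
    if not dabg.index.equals(matrix.values.index) or not dabg.columns.equals(
        matrix.values.columns
    ):
        raise ValueError("DABG p-value matrix is not aligned with the intensity matrix")
    groups = groups.loc[matrix.values.columns]
    sizes = groups.value_counts()
    if (sizes == 0).any() or sizes.empty:
        raise ValueError("every group must contain at least one sample")

    audit = FilterAudit()
    audit.probesets_in = len(matrix.values)
    info = design.probesets.loc[matrix.values.index]
    audit.exons_in = info["exon_id"].nunique()

    # (1) cross-hybridising probesets
    keep1 = info["crosshyb_type"] == 1
    audit.removed_crosshyb = int((~keep1).sum())

    # (2) detected above background in ~detect_fraction of one group
    detected_any = pd.Series(False, index=matrix.values.index)
    for g, size in sizes.items():
        cols = groups.index[groups == g]
        need = math.ceil(detect_fraction * size)
        n_det = (dabg[cols] < alpha).sum(axis=1)
        detected_any |= n_det >= need
    keep2 = keep1 & detected_any
    audit.removed_dabg = int((keep1 & ~detected_any).sum())

    # (3) exons unique for a transcript
    surviving = info.loc[keep2]
    n_tx = design.transcript_counts()
    if unique_exon_rule == "single_transcript":
        unique_exons = set(n_tx.index[n_tx == 1])
    elif unique_exon_rule == "private_to_transcript":
        gene_of = design.gene_of_exon()
        gene_n_tx = pd.Series(
            {
                g: len({t for e in exons for t in design.exon_transcripts[e]})
                for g, exons in design.gene_exons.items()
            }
        )
        unique_exons = {
            e for e in n_tx.index[n_tx == 1] if gene_n_tx.get(gene_of.get(e), 1) >= 2
        }
    else:
        raise ValueError(f"unknown unique_exon_rule {unique_exon_rule!r}")
    keep3 = keep2 & ~info["exon_id"].isin(unique_exons)
    audit.removed_unique_exon = int((keep2 & info["exon_id"].isin(unique_exons)).sum())

    filtered = matrix.values.loc[keep3]
    audit.probesets_out = len(filtered)
    audit.exons_out = info.loc[keep3, "exon_id"].nunique()
    audit.check_consistent()
    log.info(
        "filters: %d probesets in, %d cross-hyb, %d below background, %d unique-exon, %d out",
        audit.probesets_in,
        audit.removed_crosshyb,
        audit.removed_dabg,
        audit.removed_unique_exon,
        audit.probesets_out,
    )
    return IntensityMatrix(values=filtered, level="probeset"), audit


# ---------------------------------------------------------------------------
# gene summary and splicing index
# ---------------------------------------------------------------------------

def gene_summary(
    exon_matrix: IntensityMatrix,
    design: ExonArrayDesign,
    method: Literal["median", "mean"] = "median",
) -> IntensityMatrix:
    """Gene intensity per sample as the median (or mean) of its surviving exons."""
    if exon_matrix.level != "exon":
        raise ValueError("gene_summary expects an exon-level matrix")
    gene_of = design.gene_of_exon()
    missing = exon_matrix.values.index.difference(gene_of.index)
    if len(missing):
        raise ValueError(f"{len(missing)} exon rows not present in the design")
    grouped = exon_matrix.values.groupby(gene_of.loc[exon_matrix.values.index], sort=False)
    values = grouped.median() if method == "median" else grouped.mean()
    n_dropped = len(set(design.gene_exons) - set(values.index))
    if n_dropped:
        log.warning("%d genes have no surviving exons and were dropped", n_dropped)
    return IntensityMatrix(values=values, level="gene")


def splicing_index(exon_matrix: IntensityMatrix, gene_matrix: IntensityMatrix,
                   design: ExonArrayDesign) -> SIMatrix:
    """SI(exon, sample) = log2 exon intensity − log2 intensity of its gene."""
    if exon_matrix.level != "exon" or gene_matrix.level != "gene":
        raise ValueError("splicing_index expects exon- and gene-level matrices")
    if list(exon_matrix.values.columns) != list(gene_matrix.values.columns):
        raise ValueError("exon and gene matrices must share the same samples")
    gene_of = design.gene_of_exon().loc[exon_matrix.values.index]
    absent = set(gene_of) - set(gene_matrix.values.index)
    if absent:
        raise ValueError(f"gene(s) absent from gene matrix: {sorted(absent)[:5]}")
    gene_rows = gene_matrix.values.loc[gene_of].to_numpy()
    si = exon_matrix.values.to_numpy() - gene_rows
    return SIMatrix(
        values=pd.DataFrame(si, index=exon_matrix.values.index, columns=exon_matrix.values.columns)
    )


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

def run_exon_pipeline(
    probe_matrix: IntensityMatrix,
    design: ExonArrayDesign,
    background_pool: Iterable[float],
    groups: pd.Series,
    alpha: float = 0.05,
    detect_fraction: float = 0.5,
    unique_exon_rule: str = "single_transcript",
    summarize_method: str = "median_polish",
    gene_method: str = "median",
) -> SIMatrix:
    """Probe matrix → quantile normalization → summarization → filters → SI."""
    normalized = quantile_normalize(probe_matrix)
    probesets = summarize_probes(normalized, design, method=summarize_method)
    dabg = dabg_pvalues(probesets, background_pool)
    filtered, audit = apply_filters(
        probesets,
        design,
        dabg,
        groups,
        alpha=alpha,
        detect_fraction=detect_fraction,
        unique_exon_rule=unique_exon_rule,  # type: ignore[arg-type]
    )
    exons = probesets_to_exons(filtered, design)
    genes = gene_summary(exons, design, method=gene_method)  # type: ignore[arg-type]
    si = splicing_index(exons, genes, design)
    si.audit = audit
    return si
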