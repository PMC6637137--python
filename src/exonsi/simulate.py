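"""Synthetic exon-array cohorts with known ground truth.

The generator emulates the five inputs the analysis consumes — an array
design table, a probe-level log2 intensity matrix with a background probe
pool, a paired normal/tumor sample sheet with clinical covariates, a VCF of
TP53-region variant calls, and qPCR Cq tables — and records every injected
effect in a truth table so recovery can be scored exactly.

The intensity model is additive on the log2 scale: the probeset signal for
exon *e* of gene *g* in sample *s* is

    mu_g + delta_e + beta_g * 1[tumor] + gamma_e * 1[tumor and spliced(e)]
         + u_subject(s) + eps,

with gene baseline mu_g ~ Uniform(6, 12), exon inclusion offset
delta_e ~ Normal(0, exon_sd), subject effect u ~ Normal(0, subject_sd^2) and
measurement noise eps ~ Normal(0, noise_sd^2).  Because the model is additive
in log2 units, the tumor−normal splicing-index difference of a spliced exon
equals the injected shift gamma exactly in the noise-free limit.  To keep the
median gene summary an exact anchor, the spliced exon of an affected gene is
the exon with the largest baseline offset delta among the gene's analyzable
exons (detected, multi-transcript, clean cross-hyb probesets), so adding a
positive gamma never moves the gene median.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .design import ExonArrayDesign
from .matrices import IntensityMatrix
from .variants import VariantRecord, write_vcf

TP53_REGION = ("17", 7_571_720, 7_590_868)  # GRCh37
CODON72_POS = 7_579_472  # rs1042522; middle base C encodes proline, G arginine

# substream ids so stages can be re-run independently from one master seed
_STREAM_DESIGN, _STREAM_COHORT, _STREAM_INTENSITY, _STREAM_VARIANTS, _STREAM_QPCR = range(5)


def stage_rng(seed: int, stream: int) -> np.random.Generator:
    """Named substream of the master seed (stable across stages)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


class SimulationParams(BaseModel):
    """Study-condition knobs for the synthetic cohort.

    All intensity-scale quantities are log2 units.  Proportions are in
    [0, 1].  ``exons_per_gene`` must start at 2 or more: a single-exon gene's
    summary equals its exon, forcing SI = 0 and making the exon untestable.
    """

    model_config = ConfigDict(extra="forbid")

    n_genes: int = Field(default=200, ge=1)
    transcripts_per_gene: tuple[int, int] = (2, 4)
    exons_per_gene: tuple[int, int] = (4, 8)
    probes_per_probeset: int = Field(default=4, ge=1)
    probesets_per_exon: int = Field(default=1, ge=1)
    crosshyb_fraction: float = Field(default=0.05, ge=0.0, le=1.0)
    n_subjects: int = Field(default=20, ge=1)
    gene_de_fraction: float = Field(default=0.1, ge=0.0, le=1.0)
    gene_effect: float = 1.0
    splice_fraction: float = Field(default=0.1, ge=0.0, le=1.0)
    splice_effect: float = 1.5  # gamma, log2 shift of the spliced exon in tumors
    exon_sd: float = Field(default=0.5, ge=0.0)  # spread of baseline offsets delta_e
    subject_sd: float = Field(default=0.3, ge=0.0)
    noise_sd: float = Field(default=0.4, ge=0.0)  # sigma
    probe_noise_sd: float = Field(default=0.1, ge=0.0)
    background_mean: float = 4.0
    background_sd: float = Field(default=0.25, ge=0.0)
    undetected_fraction: float = Field(default=0.05, ge=0.0, le=1.0)
    n_background: int = Field(default=2000, ge=1000)
    seed: int = 0

    @model_validator(mode="after")
    def _check_ranges(self) -> "SimulationParams":
        lo, hi = self.exons_per_gene
        if lo < 2:
            raise ValueError("exons_per_gene minimum must be >= 2")
        if hi < lo:
            raise ValueError("exons_per_gene range is inverted")
        tlo, thi = self.transcripts_per_gene
        if tlo < 1 or thi < tlo:
            raise ValueError("transcripts_per_gene range is invalid")
        return self


@dataclass
class ClinicalTable:
    """Per-subject clinical covariates plus the paired sample sheet."""

    subjects: pd.DataFrame  # subject_id (index), recurrence, stage, grade, time, event
    samples: pd.DataFrame  # sample_id (index), subject_id, tissue in {normal, tumor}

    def pairing(self) -> dict[str, tuple[str, str]]:
        """subject → (normal sample, tumor sample)."""
        out: dict[str, tuple[str, str]] = {}
        for subject, grp in self.samples.groupby("subject_id", sort=False):
            tissues = dict(zip(grp["tissue"], grp.index))
            if "normal" not in tissues or "tumor" not in tissues:
                raise ValueError(f"subject {subject} lacks a normal/tumor pair")
            out[str(subject)] = (tissues["normal"], tissues["tumor"])
        return out

    def groups(self) -> pd.Series:
        return self.samples["tissue"].rename("group")

    def write(self, outdir: Path) -> None:
        self.subjects.to_csv(outdir / "clinical.tsv", sep="\t", index_label="subject_id")
        self.samples.to_csv(outdir / "sample_sheet.tsv", sep="\t", index_label="sample_id")

    @classmethod
    def read(cls, clinical_path, sample_sheet_path) -> "ClinicalTable":
        return cls(
            subjects=pd.read_csv(clinical_path, sep="\t", index_col="subject_id"),
            samples=pd.read_csv(sample_sheet_path, sep="\t", index_col="sample_id"),
        )


@dataclass
class TruthTable:
    """Ground-truth labels for every injected effect."""

    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    exons: pd.DataFrame = field(default_factory=pd.DataFrame)
    subjects: pd.DataFrame = field(default_factory=pd.DataFrame)
    variant_records: pd.DataFrame = field(default_factory=pd.DataFrame)

    def write(self, outdir: Path) -> None:
        if len(self.genes):
            self.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index_label="gene_id")
        if len(self.exons):
            self.exons.to_csv(outdir / "truth_exons.tsv", sep="\t", index_label="exon_id")
        if len(self.subjects):
            self.subjects.to_csv(outdir / "truth_subjects.tsv", sep="\t", index_label="subject_id")
        if len(self.variant_records):
            self.variant_records.to_csv(outdir / "truth_variants.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def make_design(params: SimulationParams) -> ExonArrayDesign:
    """Build a gene → transcript → exon → probeset hierarchy.

    Transcript 1 of each gene contains every exon; each further transcript
    drops at least one exon, so whenever a gene has two or more transcripts
    at least one exon is shared between transcripts and some exons may be
    unique to the full-length transcript (exercising the unique-exon filter).
    Exactly ``floor(crosshyb_fraction × n_probesets)`` probesets get a
    cross-hyb flag different from 1, chosen by a seeded draw.
    """
    if params.n_genes < 1:
        raise ValueError("n_genes must be at least 1")
    rng = stage_rng(params.seed, _STREAM_DESIGN)
    rows: list[tuple[str, str, str, int]] = []
    exon_transcripts: dict[str, frozenset[str]] = {}
    gene_exons: dict[str, tuple[str, ...]] = {}
    probe_ids: list[str] = []
    probe_ps: list[str] = []

    for gi in range(params.n_genes):
        gene = f"g{gi:04d}"
        n_exons = int(rng.integers(params.exons_per_gene[0], params.exons_per_gene[1] + 1))
        n_tx = int(rng.integers(params.transcripts_per_gene[0], params.transcripts_per_gene[1] + 1))
        exons = [f"{gene}_e{ei}" for ei in range(n_exons)]
        gene_exons[gene] = tuple(exons)
        membership = {e: {f"{gene}_t0"} for e in exons}
        for ti in range(1, n_tx):
            keep = rng.random(n_exons) < 0.7
            if keep.all():
                keep[rng.integers(n_exons)] = False
            if not keep.any():
                keep[rng.integers(n_exons)] = True
            for e, k in zip(exons, keep):
                if k:
                    membership[e].add(f"{gene}_t{ti}")
        for e in exons:
            exon_transcripts[e] = frozenset(membership[e])
            for pi in range(params.probesets_per_exon):
                ps = f"{e}_ps{pi}"
                rows.append((ps, e, gene, 1))
                for k in range(params.probes_per_probeset):
                    probe_ids.append(f"{ps}_p{k}")
                    probe_ps.append(ps)

    probesets = pd.DataFrame(
        rows, columns=["probeset_id", "exon_id", "gene_id", "crosshyb_type"]
    ).set_index("probeset_id")
    n_cross = math.floor(params.crosshyb_fraction * len(probesets))
    if n_cross:
        flagged = rng.choice(len(probesets), size=n_cross, replace=False)
        probesets.iloc[flagged, probesets.columns.get_loc("crosshyb_type")] = (
            2 + rng.integers(0, 2, size=n_cross)
        )
    probes = pd.Series(probe_ps, index=pd.Index(probe_ids, name="probe_id"), name="probeset_id")
    return ExonArrayDesign(
        probesets=probesets,
        exon_transcripts=exon_transcripts,
        gene_exons=gene_exons,
        probes=probes,
    )


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

DEFAULT_STAGE_PROBS = {"Ta": 0.44, "T1": 0.43, "T2": 0.13}
DEFAULT_GRADE_PROBS = {"low": 0.57, "high": 0.43}


def _check_distribution(probs: Mapping[str, float], name: str) -> None:
    vals = np.array(list(probs.values()), dtype=float)
    if (vals < 0).any():
        raise ValueError(f"{name} contains negative probabilities")
    if abs(vals.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (got {vals.sum()!r})")


def simulate_cohort(
    params: SimulationParams,
    recurrence_rate: float = 0.75,
    stage_probs: Mapping[str, float] | None = None,
    grade_probs: Mapping[str, float] | None = None,
) -> ClinicalTable:
    """Draw a paired normal/tumor cohort with recurrence, stage and grade.

    One normal and one tumor sample per subject share the subject id;
    recurrence, stage and grade are drawn independently with the stated
    probabilities.  Survival time and event are filled in later by
    :func:`simulate_variant_cohort`.
    """
    if not 0.0 <= recurrence_rate <= 1.0:
        raise ValueError("recurrence_rate must be in [0, 1]")
    stage_probs = dict(stage_probs or DEFAULT_STAGE_PROBS)
    grade_probs = dict(grade_probs or DEFAULT_GRADE_PROBS)
    _check_distribution(stage_probs, "stage_probs")
    _check_distribution(grade_probs, "grade_probs")

    rng = stage_rng(params.seed, _STREAM_COHORT)
    subjects = [f"S{i:04d}" for i in range(params.n_subjects)]
    recurrence = rng.random(params.n_subjects) < recurrence_rate
    stage = rng.choice(list(stage_probs), size=params.n_subjects, p=list(stage_probs.values()))
    grade = rng.choice(list(grade_probs), size=params.n_subjects, p=list(grade_probs.values()))
    subj = pd.DataFrame(
        {
            "recurrence": recurrence.astype(int),
            "stage": stage,
            "grade": grade,
            "time": np.nan,
            "event": np.nan,
        },
        index=pd.Index(subjects, name="subject_id"),
    )
    sample_rows = []
    for s in subjects:
        sample_rows.append((f"{s}_N", s, "normal"))
        sample_rows.append((f"{s}_T", s, "tumor"))
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "subject_id", "tissue"]
    ).set_index("sample_id")
    return ClinicalTable(subjects=subj, samples=samples)


# ---------------------------------------------------------------------------
# intensities
# ---------------------------------------------------------------------------

@dataclass
class SimulatedExpression:
    probe_matrix: IntensityMatrix
    background_pool: np.ndarray
    truth: TruthTable


def simulate_intensities(
    design: ExonArrayDesign, cohort: ClinicalTable, params: SimulationParams
) -> SimulatedExpression:
    """Draw a probe-level log2 intensity matrix under the additive model.

    Exons flagged undetected (``floor(undetected_fraction × n_exons)`` of
    them) are drawn from the background distribution in every sample; a
    background probe pool of ``n_background`` draws is emitted alongside for
    DABG p-value computation.
    """
    pairing = cohort.pairing()  # validates pairing
    rng = stage_rng(params.seed, _STREAM_INTENSITY)
    genes = list(design.gene_exons)
    exon_ids = [e for g in genes for e in design.gene_exons[g]]
    n_genes, n_exons = len(genes), len(exon_ids)

    # gene-level differential expression
    n_de = math.floor(params.gene_de_fraction * n_genes)
    de_idx = rng.choice(n_genes, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    beta = np.zeros(n_genes)
    if n_de:
        beta[de_idx] = params.gene_effect * rng.choice([-1.0, 1.0], size=n_de)

    # undetected exons sit at background level in every sample
    n_undet = math.floor(params.undetected_fraction * n_exons)
    undet_idx = rng.choice(n_exons, size=n_undet, replace=False) if n_undet else np.array([], dtype=int)
    undetected = np.zeros(n_exons, dtype=bool)
    undetected[undet_idx] = True
    undet_set = {exon_ids[i] for i in undet_idx}

    mu = rng.uniform(6.0, 12.0, size=n_genes)
    delta = rng.normal(0.0, params.exon_sd, size=n_exons)
    delta_of = dict(zip(exon_ids, delta))

    # differential exon usage: one spliced exon per affected gene, chosen as
    # the analyzable exon with the largest baseline offset (see module doc)
    n_tx = design.transcript_counts()
    clean_ps = design.probesets[design.probesets["crosshyb_type"] == 1]
    clean_exons = set(clean_ps["exon_id"]) - set(
        design.probesets.loc[design.probesets["crosshyb_type"] != 1, "exon_id"]
    )
    # a gene is eligible for a splice event only if >= 3 of its exons are
    # analyzable: with just two, the gene median is the two-exon mean and
    # shifts by gamma/2, so it could not anchor the SI of the other exon
    eligible_by_gene: dict[str, list[str]] = {}
    for g in genes:
        elig = [
            e
            for e in design.gene_exons[g]
            if e not in undet_set and n_tx[e] >= 2 and e in clean_exons
        ]
        if len(elig) >= 3:
            eligible_by_gene[g] = elig
    n_spliced = math.floor(params.splice_fraction * n_genes)
    eligible_genes = [g for g in genes if g in eligible_by_gene]
    if n_spliced > len(eligible_genes):
        raise ValueError("not enough genes with analyzable exons for splice_fraction")
    spliced_genes = (
        set(rng.choice(eligible_genes, size=n_spliced, replace=False)) if n_spliced else set()
    )
    gamma = {g: max(eligible_by_gene[g], key=lambda e: delta_of[e]) for g in spliced_genes}
    spliced_exons = set(gamma.values())

    # assemble the probeset-level signal
    samples = list(cohort.samples.index)
    is_tumor = (cohort.samples["tissue"] == "tumor").to_numpy()
    subj_of_sample = cohort.samples["subject_id"].to_numpy()
    u = dict(
        zip(
            cohort.subjects.index,
            rng.normal(0.0, params.subject_sd, size=len(cohort.subjects)),
        )
    )
    u_sample = np.array([u[s] for s in subj_of_sample])

    ps_index = design.probesets.index
    gene_pos = {g: i for i, g in enumerate(genes)}
    exon_pos = {e: i for i, e in enumerate(exon_ids)}
    ps_gene = design.probesets["gene_id"].map(gene_pos).to_numpy()
    ps_exon = design.probesets["exon_id"].map(exon_pos).to_numpy()
    ps_undet = undetected[ps_exon]
    base = mu[ps_gene] + delta[ps_exon]
    tumor_shift = beta[ps_gene].copy()
    spliced_mask = design.probesets["exon_id"].isin(spliced_exons).to_numpy()
    tumor_shift[spliced_mask] += params.splice_effect

    n_ps, n_samples = len(ps_index), len(samples)
    values = (
        base[:, None]
        + tumor_shift[:, None] * is_tumor[None, :]
        + u_sample[None, :]
        + rng.normal(0.0, params.noise_sd, size=(n_ps, n_samples))
    )
    if ps_undet.any():
        values[ps_undet] = rng.normal(
            params.background_mean, params.background_sd, size=(int(ps_undet.sum()), n_samples)
        )

    # probe replicates around the probeset signal
    k = params.probes_per_probeset
    probe_vals = np.repeat(values, k, axis=0)
    if params.probe_noise_sd > 0:
        probe_vals = probe_vals + rng.normal(0.0, params.probe_noise_sd, size=probe_vals.shape)
    probe_index = [f"{ps}_p{j}" for ps in ps_index for j in range(k)]
    probe_matrix = IntensityMatrix(
        values=pd.DataFrame(probe_vals, index=probe_index, columns=samples), level="probe"
    )
    pool = rng.normal(params.background_mean, params.background_sd, size=params.n_background)

    gene_of_exon = design.gene_of_exon()
    truth = TruthTable(
        genes=pd.DataFrame(
            {"is_de": beta != 0.0, "gene_effect": beta},
            index=pd.Index(genes, name="gene_id"),
        ),
        exons=pd.DataFrame(
            {
                "gene_id": [gene_of_exon[e] for e in exon_ids],
                "is_spliced": [e in spliced_exons for e in exon_ids],
                "splice_effect": [params.splice_effect if e in spliced_exons else 0.0 for e in exon_ids],
                "is_detected": ~undetected,
            },
            index=pd.Index(exon_ids, name="exon_id"),
        ),
    )
    return SimulatedExpression(probe_matrix=probe_matrix, background_pool=pool, truth=truth)


# ---------------------------------------------------------------------------
# variants and survival
# ---------------------------------------------------------------------------

DEFAULT_CONSEQUENCE_PROBS = {
    "missense_variant": 0.529,
    "intron_variant": 0.235,
    "synonymous_variant": 0.118,
    "splice_acceptor_variant": 0.059,
    "frameshift_variant": 0.0295,
    "stop_gained": 0.0295,
}
DEFAULT_CODON72_FREQS = {"CC": 0.647, "GC": 0.294, "GG": 0.059}
_BASES = np.array(list("ACGT"))


def simulate_variant_cohort(
    cohort: ClinicalTable,
    prevalence: float = 0.404,
    consequence_probs: Mapping[str, float] | None = None,
    codon72_geno_freqs: Mapping[str, float] | None = None,
    hazard_ratio: float = 2.0,
    baseline_hazard: float = 0.02,
    censor_time: float = 60.0,
    fail_qual_fraction: float = 0.1,
    fail_dp4_fraction: float = 0.1,
    fail_pl_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[list[VariantRecord], ClinicalTable, TruthTable]:
    """Draw TP53-region variant calls, codon-72 genotypes and survival.

    ``floor(prevalence × n_subjects)`` subjects carry 1–3 somatic variant
    records each; independently of that, every record may be generated to
    fail one of the three quality filters (QUAL, total DP4, PL margin) with
    the stated fractions, and the failures are truth-labelled.  The codon-72
    site is emitted, with a genotype for every subject, whenever at least one
    subject carries the arginine (G) allele — a variant caller only reports
    polymorphic sites.  Recurrence-free time is exponential with rate
    ``baseline_hazard × hazard_ratio^1[genotype == GC]``, right-censored at
    ``censor_time``.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must be in [0, 1]")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    consequence_probs = dict(consequence_probs or DEFAULT_CONSEQUENCE_PROBS)
    codon72_geno_freqs = dict(codon72_geno_freqs or DEFAULT_CODON72_FREQS)
    _check_distribution(consequence_probs, "consequence_probs")
    _check_distribution(codon72_geno_freqs, "codon72_geno_freqs")

    rng = stage_rng(seed, _STREAM_VARIANTS)
    subjects = list(cohort.subjects.index)
    n = len(subjects)
    n_carriers = math.floor(prevalence * n)
    carriers = set(rng.choice(subjects, size=n_carriers, replace=False)) if n_carriers else set()
    genotypes = dict(
        zip(
            subjects,
            rng.choice(list(codon72_geno_freqs), size=n, p=list(codon72_geno_freqs.values())),
        )
    )

    records: list[VariantRecord] = []
    truth_rows: list[dict] = []
    chrom, lo, hi = TP53_REGION

    def _pl_for(gt: str, margin: int) -> tuple[int, ...]:
        called = {"0/0": 0, "0/1": 1, "1/1": 2}[gt]
        pl = [margin, margin, margin]
        pl[called] = 0
        pl[(called + 2) % 3] = margin + int(rng.integers(0, 120))
        return tuple(pl)

    # codon-72 polymorphism: one site, genotype per subject, only if polymorphic.
    # QUAL and DP4 are site-level (mpileup pools evidence across samples).
    if any(genotypes[s] != "CC" for s in subjects):
        site_qual = int(rng.integers(60, 200))
        depth = int(rng.integers(30, 120)) * max(1, n // 2)
        alt_frac = float(
            np.mean([{"CC": 0.01, "GC": 0.5, "GG": 0.98}[genotypes[s]] for s in subjects])
        )
        n_alt = int(rng.binomial(depth, alt_frac))
        n_ref = depth - n_alt
        rf, af = int(rng.binomial(n_ref, 0.5)), int(rng.binomial(n_alt, 0.5))
        site_dp4 = (rf, n_ref - rf, af, n_alt - af)
        for s in subjects:
            gt = {"CC": "0/0", "GC": "0/1", "GG": "1/1"}[genotypes[s]]
            rec = VariantRecord(
                chrom=chrom,
                pos=CODON72_POS,
                ref="C",
                alt="G",
                qual=site_qual,
                dp4=site_dp4,
                gt=gt,
                pl=_pl_for(gt, int(rng.integers(100, 256))),
                consequence="missense_variant",
                subject=s,
            )
            records.append(rec)
            truth_rows.append(
                {
                    "chrom": chrom,
                    "pos": CODON72_POS,
                    "subject": s,
                    "fails_qual": False,
                    "fails_dp4": False,
                    "fails_pl": False,
                }
            )

    # somatic variant records, 1-3 per carrier
    used_pos = {CODON72_POS}
    for s in subjects:
        if s not in carriers:
            continue
        for _ in range(int(rng.integers(1, 4))):
            pos = int(rng.integers(lo, hi + 1))
            while pos in used_pos:
                pos = int(rng.integers(lo, hi + 1))
            used_pos.add(pos)
            ref, alt = rng.choice(4, size=2, replace=False)
            gt = "0/1" if rng.random() < 0.8 else "1/1"
            fails_qual = rng.random() < fail_qual_fraction
            fails_dp4 = rng.random() < fail_dp4_fraction
            fails_pl = rng.random() < fail_pl_fraction
            qual = int(rng.integers(0, 20)) if fails_qual else int(rng.integers(30, 200))
            depth = int(rng.integers(4, 20)) if fails_dp4 else int(rng.integers(30, 120))
            n_alt = int(rng.binomial(depth, 0.5 if gt == "0/1" else 0.95))
            n_ref = depth - n_alt
            rf = int(rng.binomial(n_ref, 0.5))
            af = int(rng.binomial(n_alt, 0.5))
            margin = int(rng.integers(10, 100)) if fails_pl else int(rng.integers(100, 256))
            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=pos,
                    ref=str(_BASES[ref]),
                    alt=str(_BASES[alt]),
                    qual=qual,
                    dp4=(rf, n_ref - rf, af, n_alt - af),
                    gt=gt,
                    pl=_pl_for(gt, margin),
                    consequence=str(
                        rng.choice(list(consequence_probs), p=list(consequence_probs.values()))
                    ),
                    subject=s,
                )
            )
            truth_rows.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "subject": s,
                    "fails_qual": fails_qual,
                    "fails_dp4": fails_dp4,
                    "fails_pl": fails_pl,
                }
            )

    # recurrence-free survival with a multiplicative heterozygote hazard
    rates = np.array(
        [baseline_hazard * (hazard_ratio if genotypes[s] == "GC" else 1.0) for s in subjects]
    )
    raw = rng.exponential(1.0 / rates)
    time = np.minimum(raw, censor_time)
    event = (raw <= censor_time).astype(int)
    subj = cohort.subjects.copy()
    subj["time"] = time
    subj["event"] = event
    subj["codon72"] = [genotypes[s] for s in subjects]
    clinical = ClinicalTable(subjects=subj, samples=cohort.samples.copy())

    truth = TruthTable(
        subjects=pd.DataFrame(
            {
                "is_carrier": [s in carriers for s in subjects],
                "codon72": [genotypes[s] for s in subjects],
                "hazard_multiplier": [
                    hazard_ratio if genotypes[s] == "GC" else 1.0 for s in subjects
                ],
            },
            index=pd.Index(subjects, name="subject_id"),
        ),
        variant_records=pd.DataFrame(
            truth_rows,
            columns=["chrom", "pos", "subject", "fails_qual", "fails_dp4", "fails_pl"],
        ),
    )
    return records, clinical, truth


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

DEFAULT_QPCR_LOG2FC = {
    # Notch read-outs down in tumor, Hedgehog read-outs up; TBP is the reference
    "HES1": -1.0,
    "HEYL": -1.0,
    "HEY1": -0.8,
    "GLI1": 1.0,
    "GLI2": 0.8,
    "PTCH1": 0.2,
    "TBP": 0.0,
}


def simulate_cq_table(
    cohort: ClinicalTable,
    log2fc: Mapping[str, float] | None = None,
    n_replicates: int = 3,
    cq_noise_sd: float = 0.15,
    subject_sd: float = 0.4,
    seed: int = 0,
) -> pd.DataFrame:
    """Cq table (sample, gene, replicate, cq) with tumor/normal fold changes.

    With amplification efficiency 2, a log2 fold change f in the tumor lowers
    the tumor Cq by f relative to the paired normal sample.
    """
    log2fc = dict(log2fc or DEFAULT_QPCR_LOG2FC)
    rng = stage_rng(seed, _STREAM_QPCR)
    genes = list(log2fc)
    base = dict(zip(genes, rng.uniform(22.0, 30.0, size=len(genes))))
    rows = []
    for subject, grp in cohort.samples.groupby("subject_id", sort=False):
        for gene in genes:
            level = rng.normal(0.0, subject_sd)  # subject-specific abundance
            for sample_id, tissue in zip(grp.index, grp["tissue"]):
                cq_true = base[gene] - level - (log2fc[gene] if tissue == "tumor" else 0.0)
                for r in range(n_replicates):
                    rows.append(
                        (sample_id, gene, r, cq_true + rng.normal(0.0, cq_noise_sd))
                    )
    return pd.DataFrame(rows, columns=["sample", "gene", "replicate", "cq"])


# ---------------------------------------------------------------------------
# full dataset on disk
# ---------------------------------------------------------------------------

def write_dataset(
    outdir: str | Path,
    params: SimulationParams,
    recurrence_rate: float = 0.75,
    variant_kwargs: Mapping | None = None,
) -> dict[str, Path]:
    """Simulate and write the full synthetic dataset as TSV/VCF files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = make_design(params)
    cohort = simulate_cohort(params, recurrence_rate=recurrence_rate)
    expr = simulate_intensities(design, cohort, params)
    records, clinical, vtruth = simulate_variant_cohort(
        cohort, seed=params.seed, **dict(variant_kwargs or {})
    )
    cq = simulate_cq_table(cohort, seed=params.seed)

    design.to_tsv(outdir / "design.tsv")
    expr.probe_matrix.to_tsv(outdir / "probe_matrix.tsv")
    pd.Series(expr.background_pool, name="intensity").to_csv(
        outdir / "background.tsv", sep="\t", index=False
    )
    clinical.write(outdir)
    write_vcf(records, outdir / "variants.vcf")
    cq.to_csv(outdir / "cq.tsv", sep="\t", index=False)
    expr.truth.write(outdir)
    vtruth.write(outdir)
    return {
        "design": outdir / "design.tsv",
        "probe_matrix": outdir / "probe_matrix.tsv",
        "background": outdir / "background.tsv",
        "sample_sheet": outdir / "sample_sheet.tsv",
        "clinical": outdir / "clinical.tsv",
        "vcf": outdir / "variants.vcf",
        "cq": outdir / "cq.tsv",
    }
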