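"""TP53-region variant handling: VCF I/O, quality filters, consequence
summaries, genotype partitioning and contingency tests.

Records are stored per (site, subject): a multi-sample VCF line with three
called genotypes yields three records.  The quality filters follow the usual
mpileup-calling conventions: a site-level QUAL, the strand-split DP4 read
counts, and phred-scaled genotype likelihoods (PL) in which the called
genotype has PL 0.  "Definitive genotype" is read as a genotype-quality
margin — the second-smallest PL — since the smallest is 0 by construction
and a literal threshold on it could never filter anything.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
import pysam
from scipy import stats

log = logging.getLogger(__name__)

CONSEQUENCE_CLASSES = (
    "missense_variant",
    "intron_variant",
    "synonymous_variant",
    "splice_acceptor_variant",
    "frameshift_variant",
    "stop_gained",
)


@dataclass(frozen=True)
class VariantRecord:
    """One called genotype at one site for one subject."""

    chrom: str
    pos: int  # 1-based, as printed in the VCF
    ref: str
    alt: str
    qual: float
    dp4: tuple[int, int, int, int]  # ref-fwd, ref-rev, alt-fwd, alt-rev
    gt: str
    pl: tuple[int, ...]
    consequence: str
    subject: str

    def __post_init__(self) -> None:
        if self.qual < 0:
            raise ValueError("QUAL must be non-negative")
        if any(d < 0 for d in self.dp4):
            raise ValueError("DP4 counts must be non-negative")
        if 0 not in self.pl:
            raise ValueError("PL must contain a zero for the called genotype")

    @property
    def site(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_alt(self) -> bool:
        """True if the called genotype carries the alternate allele."""
        return any(a not in ("0", ".") for a in self.gt.replace("|", "/").split("/"))

    @property
    def pl_margin(self) -> int:
        """Second-smallest PL: the phred margin of the called genotype."""
        return sorted(self.pl)[1] if len(self.pl) > 1 else 0


# ---------------------------------------------------------------------------
# VCF I/O (pysam)
# ---------------------------------------------------------------------------

_VCF_HEADER_LINES = [
    ('INFO', '<ID=DP4,Number=4,Type=Integer,Description='
     '"Read counts: ref-forward, ref-reverse, alt-forward, alt-reverse">'),
    ('INFO', '<ID=CSQ,Number=1,Type=String,Description="Consequence annotation">'),
    ('FORMAT', '<ID=GT,Number=1,Type=String,Description="Genotype">'),
    ('FORMAT', '<ID=PL,Number=G,Type=Integer,Description='
     '"Phred-scaled genotype likelihoods">'),
]


def write_vcf(records: Sequence[VariantRecord], path: str | Path) -> None:
    """Write records as a multi-sample VCF v4.2.

    Records sharing (chrom, pos, ref, alt) are emitted on one line with one
    genotype column per subject; subjects without a call at a site get `./.`.
    """
    subjects = sorted({r.subject for r in records})
    header = pysam.VariantHeader()
    for kind, line in _VCF_HEADER_LINES:
        header.add_line(f"##{kind}={line}")
    header.add_line("##contig=<ID=17,length=81195210>")
    for s in subjects:
        header.add_sample(s)

    by_site: dict[tuple[str, int, str, str], list[VariantRecord]] = {}
    for r in records:
        by_site.setdefault(r.site, []).append(r)

    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for site in sorted(by_site, key=lambda s: (s[0], s[1], s[2], s[3])):
            site_records = by_site[site]
            quals = {r.qual for r in site_records}
            dp4s = {r.dp4 for r in site_records}
            csqs = {r.consequence for r in site_records}
            if len(quals) > 1 or len(csqs) > 1:
                raise ValueError(f"inconsistent site-level fields at {site}")
            rec = vcf.new_record(
                contig=site[0],
                start=site[1] - 1,
                stop=site[1] - 1 + len(site[2]),
                alleles=(site[2], site[3]),
            )
            rec.qual = site_records[0].qual
            # DP4 is site-level in mpileup output; pool if subjects differ
            dp4 = (
                site_records[0].dp4
                if len(dp4s) == 1
                else tuple(int(sum(d[i] for d in dp4s)) for i in range(4))
            )
            rec.info["DP4"] = dp4
            rec.info["CSQ"] = site_records[0].consequence
            for r in site_records:
                alleles = [
                    None if a == "." else int(a)
                    for a in r.gt.replace("|", "/").split("/")
                ]
                rec.samples[r.subject]["GT"] = tuple(alleles)
                rec.samples[r.subject]["PL"] = list(r.pl)
            vcf.write(rec)


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Parse a VCF into per-(site, subject) records.

    Lines without DP4, and genotype columns without a called GT or without
    PL, are flagged unparseable: counted, logged and skipped.
    """
    records: list[VariantRecord] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if "DP4" not in rec.info or rec.alts is None:
                n_skipped += 1
                continue
            dp4 = tuple(int(x) for x in rec.info["DP4"])
            csq = str(rec.info.get("CSQ", "other"))
            for subject, call in rec.samples.items():
                gt = call.get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                pl = call.get("PL")
                if pl is None or any(x is None for x in pl):
                    n_skipped += 1
                    continue
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=rec.alts[0],
                        qual=rec.qual if rec.qual is not None else 0.0,
                        dp4=dp4,  # type: ignore[arg-type]
                        gt="/".join(str(a) for a in gt),
                        pl=tuple(int(x) for x in pl),
                        consequence=csq,
                        subject=subject,
                    )
                )
    if n_skipped:
        log.warning("skipped %d unparseable record(s) while reading %s", n_skipped, path)
    return records


# ---------------------------------------------------------------------------
# quality filters
# ---------------------------------------------------------------------------

@dataclass
class VariantFilterAudit:
    n_total: int = 0
    fail_qual: int = 0
    fail_dp4: int = 0
    fail_pl: int = 0
    n_pass: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def filter_variants(
    records: Iterable[VariantRecord],
    qual_min: float = 20.0,
    dp4_min: int = 20,
    pl_min: int = 100,
    pl_rule: Literal["margin", "max"] = "margin",
) -> tuple[list[VariantRecord], VariantFilterAudit]:
    """Keep records with QUAL >= qual_min, total DP4 >= dp4_min and a
    definitive genotype: second-smallest PL >= pl_min (rule ``margin``), or
    max PL >= pl_min under the literal reading (rule ``max``).

    The audit counts, per criterion, how many records fail it; a record can
    fail several criteria and is counted under each.
    """
    audit = VariantFilterAudit()
    passing: list[VariantRecord] = []
    for r in records:
        audit.n_total += 1
        ok_qual = r.qual >= qual_min
        ok_dp4 = sum(r.dp4) >= dp4_min
        pl_stat = r.pl_margin if pl_rule == "margin" else max(r.pl)
        ok_pl = pl_stat >= pl_min
        audit.fail_qual += not ok_qual
        audit.fail_dp4 += not ok_dp4
        audit.fail_pl += not ok_pl
        if ok_qual and ok_dp4 and ok_pl:
            passing.append(r)
    audit.n_pass = len(passing)
    return passing, audit


# ---------------------------------------------------------------------------
# consequence summary
# ---------------------------------------------------------------------------

@dataclass
class ConsequenceSummary:
    """Distinct-SNV consequence counts, percentages and per-subject carriers."""

    counts: dict[str, int]
    percentages: dict[str, float]
    total: int
    carriers: dict[str, bool] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "count": pd.Series(self.counts),
                "percentage": pd.Series(self.percentages),
            }
        ).rename_axis("consequence")


def consequence_summary(
    records: Iterable[VariantRecord], coding_only_carriers: bool = False
) -> ConsequenceSummary:
    """Summarise consequence classes over distinct alternate-allele SNVs.

    SNVs are keyed by (chrom, pos, ref, alt): the same variant observed in
    several subjects counts once in the class percentages, while every
    subject with an alternate genotype at any variant is flagged a carrier
    (restricted to coding classes if ``coding_only_carriers``).
    """
    noncoding = {"intron_variant"}
    seen: dict[tuple[str, int, str, str], str] = {}
    carriers: dict[str, bool] = {}
    for r in records:
        if not r.is_alt:
            carriers.setdefault(r.subject, False)
            continue
        csq = r.consequence
        if csq not in CONSEQUENCE_CLASSES:
            log.warning("unknown consequence %r at %s:%d -> 'other'", csq, r.chrom, r.pos)
            csq = "other"
        seen.setdefault(r.site, csq)
        carriers.setdefault(r.subject, False)
        if not coding_only_carriers or csq not in noncoding:
            carriers[r.subject] = True
    counts = Counter(seen.values())
    total = len(seen)
    percentages = {c: 100.0 * n / total for c, n in counts.items()} if total else {}
    return ConsequenceSummary(
        counts=dict(counts), percentages=percentages, total=total, carriers=carriers
    )


# ---------------------------------------------------------------------------
# association tests
# ---------------------------------------------------------------------------

@dataclass
class FisherResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    degenerate: bool = False


def fisher_association(
    carrier_flags: Mapping[str, bool] | pd.Series,
    clinical_category: Mapping[str, bool] | pd.Series,
) -> FisherResult:
    """Two-sided Fisher exact test of carrier status against a binary
    clinical category, over the subjects present in both mappings.

    Degenerate margins (an all-zero row or column) give p = 1 by convention
    and are flagged.  The reported odds ratio is the sample odds ratio.
    """
    flags = pd.Series(dict(carrier_flags)).astype(bool)
    cat = pd.Series(dict(clinical_category)).astype(bool)
    common = flags.index.intersection(cat.index)
    if len(common) == 0:
        raise ValueError("no subjects shared between carrier flags and category")
    f, c = flags.loc[common], cat.loc[common]
    a = int((f & c).sum())
    b = int((f & ~c).sum())
    cc = int((~f & c).sum())
    d = int((~f & ~c).sum())
    table = ((a, b), (cc, d))
    if min(a + b, cc + d, a + cc, b + d) == 0:
        return FisherResult(table=table, odds_ratio=float("nan"), p_value=1.0, degenerate=True)
    odds = (a * d) / (b * cc) if b * cc > 0 else float("inf")
    _, p = stats.fisher_exact([[a, b], [cc, d]], alternative="two-sided")
    return FisherResult(table=table, odds_ratio=odds, p_value=float(p))


def dichotomize_stage(stage: pd.Series, cut: str = "Ta") -> pd.Series:
    """Stage Ta/T1/T2 → binary 'beyond the cut' (default: Ta vs T1+)."""
    order = ["Ta", "T1", "T2"]
    if cut not in order[:-1]:
        raise ValueError(f"stage cut must be one of {order[:-1]}")
    threshold = order.index(cut)
    return stage.map(lambda s: order.index(s) > threshold)


# ---------------------------------------------------------------------------
# codon-72 genotype partition
# ---------------------------------------------------------------------------

def genotype_partition(
    records: Iterable[VariantRecord],
    locus: tuple[str, int],
    subjects: Iterable[str] | None = None,
) -> dict[str, str]:
    """Partition subjects by the codon-72 genotype at ``locus``.

    Labels are the two middle-codon bases implied by GT and the site's
    ref/alt alleles: CC (proline homozygote), GC (heterozygote), GG
    (arginine homozygote).  Subjects without the locus, or with alleles
    outside {C, G}, are 'unknown'.
    """
    chrom, pos = locus
    out: dict[str, str] = {s: "unknown" for s in subjects} if subjects else {}
    for r in records:
        if (r.chrom, r.pos) != (chrom, pos):
            continue
        alleles = {"0": r.ref, "1": r.alt}
        parts = r.gt.replace("|", "/").split("/")
        if len(parts) != 2 or any(p not in alleles for p in parts):
            log.warning("unresolvable genotype %r for %s at %s:%d", r.gt, r.subject, chrom, pos)
            out[r.subject] = "unknown"
            continue
        bases = sorted(alleles[p] for p in parts)
        if set(bases) <= {"C", "G"}:
            label = {("C", "C"): "CC", ("C", "G"): "GC", ("G", "G"): "GG"}[tuple(bases)]
        else:
            label = "unknown"
        out[r.subject] = label
    return out
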