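"""Exon-array design tables.

The design table is the coordinate system for every exon-level statistic:
each probeset measures one exon, each exon belongs to one gene and is
contained in one or more annotated transcripts.  A ``crosshyb_type`` flag
marks probesets whose probes hybridise to sequences other than their
intended target (only flag value 1 is target-specific).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

DESIGN_COLUMNS = ["probeset_id", "exon_id", "transcript_ids", "gene_id", "crosshyb_type"]


@dataclass
class ExonArrayDesign:
    """Probeset → exon → transcript(s) → gene hierarchy.

    Parameters
    ----------
    probesets
        Frame indexed by ``probeset_id`` with columns ``exon_id``,
        ``gene_id`` and ``crosshyb_type`` (int; 1 = target-specific).
    exon_transcripts
        Mapping of exon id to the frozen set of transcript ids containing it.
    gene_exons
        Mapping of gene id to the ordered tuple of its exon ids; the order
        is stable and defines exon position within the gene.
    probes
        Optional mapping of probe id → probeset id for probe-level matrices.
    """

    probesets: pd.DataFrame
    exon_transcripts: dict[str, frozenset[str]]
    gene_exons: dict[str, tuple[str, ...]]
    probes: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = {"exon_id", "gene_id", "crosshyb_type"} - set(self.probesets.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        if self.probesets.index.has_duplicates:
            raise ValueError("duplicate probeset ids in design")
        exon_set = set(self.probesets["exon_id"])
        unmapped = exon_set - set(self.exon_transcripts)
        if unmapped:
            raise ValueError(f"{len(unmapped)} exons lack transcript annotation")
        for exon, txs in self.exon_transcripts.items():
            if len(txs) == 0:
                raise ValueError(f"exon {exon} maps to no transcript")

    # -- convenience lookups -------------------------------------------------

    @property
    def n_probesets(self) -> int:
        return len(self.probesets)

    @property
    def exon_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for exons in self.gene_exons.values():
            for e in exons:
                seen[e] = None
        return list(seen)

    def exon_of(self, probeset_id: str) -> str:
        return self.probesets.at[probeset_id, "exon_id"]

    def gene_of_exon(self) -> pd.Series:
        """exon_id → gene_id over all exons in the design."""
        pairs = {e: g for g, exons in self.gene_exons.items() for e in exons}
        return pd.Series(pairs, name="gene_id")

    def transcript_counts(self) -> pd.Series:
        """exon_id → number of transcripts containing the exon."""
        return pd.Series({e: len(t) for e, t in self.exon_transcripts.items()})

    # -- TSV dialect ---------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = self.probesets.reset_index()
        rows = rows.rename(columns={rows.columns[0]: "probeset_id"})
        rows["transcript_ids"] = rows["exon_id"].map(
            lambda e: ";".join(sorted(self.exon_transcripts[e]))
        )
        return rows[DESIGN_COLUMNS]

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExonArrayDesign":
        frame = frame.copy()
        exon_transcripts = {
            str(e): frozenset(str(t).split(";"))
            for e, t in zip(frame["exon_id"], frame["transcript_ids"])
        }
        gene_exons: dict[str, list[str]] = {}
        seen: set[str] = set()
        for e, g in zip(frame["exon_id"], frame["gene_id"]):
            e, g = str(e), str(g)
            if e not in seen:
                gene_exons.setdefault(g, []).append(e)
                seen.add(e)
        probesets = frame.set_index("probeset_id")[["exon_id", "gene_id", "crosshyb_type"]]
        probesets["crosshyb_type"] = probesets["crosshyb_type"].astype(int)
        return cls(
            probesets=probesets,
            exon_transcripts=exon_transcripts,
            gene_exons={g: tuple(v) for g, v in gene_exons.items()},
        )

    @classmethod
    def from_tsv(cls, path) -> "ExonArrayDesign":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str).astype({"crosshyb_type": int}))
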