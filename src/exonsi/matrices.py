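"""Containers for intensity and splicing-index matrices."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LEVELS = ("probe", "probeset", "exon", "gene")


@dataclass
class IntensityMatrix:
    """Feature × sample matrix of log2 intensities.

    ``level`` tags what the rows are (probe, probeset, exon or gene); most
    operations check it so that, e.g., a gene summary is never fed probe rows.
    """

    values: pd.DataFrame
    level: str = "probeset"

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}; expected one of {LEVELS}")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    def require_finite(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("intensity matrix contains non-finite values")

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label=f"{self.level}_id")

    @classmethod
    def from_tsv(cls, path, level: str = "probeset") -> "IntensityMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=frame, level=level)


@dataclass
class FilterAudit:
    """Row counts removed by each exon filter, in application order."""

    probesets_in: int = 0
    removed_crosshyb: int = 0
    removed_dabg: int = 0
    removed_unique_exon: int = 0
    probesets_out: int = 0
    exons_in: int = 0
    exons_out: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)

    def check_consistent(self) -> None:
        total_removed = self.removed_crosshyb + self.removed_dabg + self.removed_unique_exon
        if self.probesets_in - total_removed != self.probesets_out:
            raise AssertionError("filter audit counts do not telescope")


@dataclass
class SIMatrix:
    """Exon × sample splicing-index values with the filter audit trail."""

    values: pd.DataFrame
    audit: FilterAudit = field(default_factory=FilterAudit)

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("splicing index must be finite everywhere")

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="exon_id")

    @classmethod
    def from_tsv(cls, path) -> "SIMatrix":
        return cls(values=pd.read_csv(path, sep="\t", index_col=0))
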