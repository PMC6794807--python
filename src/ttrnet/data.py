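"""Shared containers for the pipeline.

All expression values are FPKM (transcripts x samples); coordinates are
1-based inclusive throughout (GTF convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BIOTYPES = ("coding", "lncRNA", "novel_lncRNA")
LNC_BIOTYPES = ("lncRNA", "novel_lncRNA")


class TtrnetError(Exception):
    """Base class for package errors."""


class ConfigError(TtrnetError):
    """A configuration invariant was violated."""


class ValidationError(TtrnetError):
    """Input data violated a documented precondition."""


class ConsistencyError(TtrnetError):
    """Identifiers disagree between objects that must share a universe."""


class ParseError(TtrnetError):
    """A file could not be parsed in the documented dialect."""


class GenerationError(TtrnetError):
    """The synthetic generator could not satisfy its constraints."""


@dataclass
class ExpressionMatrix:
    """FPKM table (transcripts x samples) plus the sample -> group design.

    Parameters
    ----------
    values
        Non-negative FPKM, index = transcript ids, columns = sample ids.
    design
        Series mapping sample id -> group label; must cover every column.
    """

    values: pd.DataFrame
    design: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate transcript id: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("negative FPKM values are not allowed")
        missing = set(self.values.columns) - set(self.design.index)
        if missing:
            raise ValidationError(f"samples missing from design: {sorted(missing)}")
        self.design = self.design.loc[self.values.columns]

    @property
    def transcripts(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def group_samples(self, group: str) -> list[str]:
        return list(self.design.index[self.design == group])

    def log2p1(self) -> pd.DataFrame:
        """log2(FPKM + 1), the additive-noise scale used for tests and correlations."""
        return np.log2(self.values + 1.0)


@dataclass
class TranscriptAnnotation:
    """Per-transcript gene mapping, biotype and genomic span.

    ``table`` is indexed by transcript id with columns
    gene_id, gene_name, biotype, chrom, start, end, strand.
    Rows are kept sorted by transcript id so that round-trips compare equal.
    """

    table: pd.DataFrame

    COLUMNS = ("gene_id", "gene_name", "biotype", "chrom", "start", "end", "strand")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValidationError(f"annotation missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValidationError(f"duplicate transcript id in annotation: {dup!r}")
        bad = self.table[self.table["start"] > self.table["end"]]
        if len(bad):
            raise ValidationError(f"start > end for transcript {bad.index[0]!r}")
        bad_strand = set(self.table["strand"]) - {"+", "-"}
        if bad_strand:
            raise ValidationError(f"invalid strand values: {sorted(bad_strand)}")
        self.table = self.table.loc[:, list(self.COLUMNS)].sort_index()

    @property
    def transcripts(self) -> pd.Index:
        return self.table.index

    def gene_of(self, transcript_id: str) -> str:
        try:
            return self.table.at[transcript_id, "gene_id"]
        except KeyError as exc:
            raise ValidationError(f"transcript {transcript_id!r} not annotated") from exc

    def biotype_mask(self, biotypes: tuple[str, ...]) -> pd.Series:
        return self.table["biotype"].isin(biotypes)

    def lncrna_ids(self) -> list[str]:
        return list(self.table.index[self.biotype_mask(LNC_BIOTYPES)])

    def coding_ids(self) -> list[str]:
        return list(self.table.index[self.biotype_mask(("coding",))])


@dataclass
class GroundTruth:
    """Planted structure emitted by the synthetic generator.

    ``cis_pairs`` lists (lncrna_id, mrna_id, relation) tuples that the cis
    caller must recover (the boundary pair sits at gap == window exactly);
    ``cis_decoy_pairs`` sit outside the window and must not be called.
    """

    de_hg_vs_lg: dict[str, str] = field(default_factory=dict)
    de_ttr_vs_hg: dict[str, str] = field(default_factory=dict)
    trend_reversal_set: list[str] = field(default_factory=list)
    module_labels: dict[str, int] = field(default_factory=dict)
    cis_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    cis_boundary_pairs: list[tuple[str, str]] = field(default_factory=list)
    cis_decoy_pairs: list[tuple[str, str]] = field(default_factory=list)
    planted_triads: list[tuple[str, str, str]] = field(default_factory=list)

    def __eq__(self, other: object) -> bool:  # list-of-tuple vs list-of-list safe
        if not isinstance(other, GroundTruth):
            return NotImplemented

        def norm(x):
            if isinstance(x, list):
                return [tuple(e) if isinstance(e, (list, tuple)) else e for e in x]
            return x

        return all(
            norm(getattr(self, f)) == norm(getattr(other, f))
            for f in (
                "de_hg_vs_lg",
                "de_ttr_vs_hg",
                "trend_reversal_set",
                "module_labels",
                "cis_pairs",
                "cis_boundary_pairs",
                "cis_decoy_pairs",
                "planted_triads",
            )
        )
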