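"""Core domain types shared across the pipeline.

All genomic coordinates in this package are 1-based inclusive (the native
GTF convention). Any half-open arithmetic needed for interval indexes is
localized in small helper predicates; nothing else ever converts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from intervaltree import IntervalTree

VALID_STRANDS = ("+", "-")
VALID_BIOTYPES = ("coding", "candidate", "unknown")


@dataclass(eq=True)
class TranscriptModel:
    """One transcript: a stranded, ordered chain of exons on a chromosome.

    Parameters
    ----------
    transcript_id, gene_id : str
        Identifiers; ``transcript_id`` is unique within a catalog.
    chrom : str
        Chromosome / scaffold name.
    strand : {"+", "-"}
    exons : sequence of (start, end)
        1-based inclusive, sorted ascending, non-overlapping.
    biotype : {"coding", "candidate", "unknown"}
        ``coding`` marks reference protein-coding transcripts; assembled
        transcripts entering the filter cascade are ``candidate``.
    attributes : mapping
        Extra GTF attributes preserved opaquely for round-trip fidelity.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]
    biotype: str = "unknown"
    attributes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r} for {self.transcript_id}")
        if self.biotype not in VALID_BIOTYPES:
            raise ValueError(f"invalid biotype {self.biotype!r} for {self.transcript_id}")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        if not exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        prev_end = None
        for s, e in exons:
            if e < s:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon end {e} < start {s}"
                )
            if prev_end is not None and s <= prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = e
        self.exons = exons

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        """Spliced length: sum of exon lengths (end - start + 1)."""
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> Tuple[Tuple[int, int], ...]:
        """Intron intervals (1-based inclusive) between consecutive exons."""
        return tuple(
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        )

    def shifted(self, offset: int) -> "TranscriptModel":
        """Copy with all coordinates translated by ``offset``."""
        return TranscriptModel(
            self.transcript_id,
            self.gene_id,
            self.chrom,
            self.strand,
            tuple((s + offset, e + offset) for s, e in self.exons),
            self.biotype,
            dict(self.attributes),
        )


def intervals_overlap(a: Tuple[int, int], b: Tuple[int, int]) -> bool:
    """True when two 1-based inclusive intervals share >= 1 base."""
    return a[0] <= b[1] and b[0] <= a[1]


def interval_gap(a: Tuple[int, int], b: Tuple[int, int]) -> int:
    """Number of bases strictly between two intervals; 0 when they overlap."""
    if intervals_overlap(a, b):
        return 0
    if a[1] < b[0]:
        return b[0] - a[1] - 1
    return a[0] - b[1] - 1


class TranscriptCatalog:
    """A validated collection of transcripts with per-chromosome indexes."""

    def __init__(self, transcripts: Sequence[TranscriptModel]):
        self.transcripts: List[TranscriptModel] = list(transcripts)
        self._by_id: Dict[str, TranscriptModel] = {}
        self._by_chrom: Dict[str, List[TranscriptModel]] = {}
        for t in self.transcripts:
            if t.transcript_id in self._by_id:
                raise ValueError(f"duplicate transcript_id {t.transcript_id!r}")
            self._by_id[t.transcript_id] = t
            self._by_chrom.setdefault(t.chrom, []).append(t)
        self._span_trees: Optional[Dict[str, IntervalTree]] = None

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._by_id

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TranscriptCatalog):
            return NotImplemented
        return sorted(self.transcripts, key=lambda t: t.transcript_id) == sorted(
            other.transcripts, key=lambda t: t.transcript_id
        )

    def get(self, transcript_id: str) -> TranscriptModel:
        return self._by_id[transcript_id]

    @property
    def ids(self) -> List[str]:
        return [t.transcript_id for t in self.transcripts]

    @property
    def chromosomes(self) -> List[str]:
        return sorted(self._by_chrom)

    def on_chrom(self, chrom: str) -> List[TranscriptModel]:
        return self._by_chrom.get(chrom, [])

    def span_trees(self) -> Dict[str, IntervalTree]:
        """Per-chromosome interval tree over transcript spans.

        intervaltree uses half-open intervals, so a span [s, e] (inclusive)
        is stored as Interval(s, e + 1, transcript).
        """
        if self._span_trees is None:
            trees: Dict[str, IntervalTree] = {}
            for chrom, ts in self._by_chrom.items():
                trees[chrom] = IntervalTree.from_tuples(
                    (t.start, t.end + 1, t) for t in ts
                )
            self._span_trees = trees
        return self._span_trees

    def subset(self, transcript_ids: Sequence[str]) -> "TranscriptCatalog":
        return TranscriptCatalog([self._by_id[i] for i in transcript_ids])


class ExpressionMatrix:
    """FPKM expression values (transcripts x samples) with group labels."""

    def __init__(self, values: pd.DataFrame, groups: pd.Series):
        values = values.astype(float)
        if (values.values < 0).any():
            raise ValueError("FPKM values must be non-negative")
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate transcript ids in expression matrix: {dups}")
        missing = [s for s in values.columns if s not in groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        self.values = values
        self.groups = groups.loc[list(values.columns)].astype(str)

    @property
    def transcript_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def samples(self) -> List[str]:
        return list(self.values.columns)

    @property
    def group_labels(self) -> List[str]:
        return sorted(self.groups.unique())

    def samples_in(self, group: str) -> List[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def subset(self, transcript_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(transcript_ids)], self.groups)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.values.equals(other.values) and self.groups.equals(other.groups)
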