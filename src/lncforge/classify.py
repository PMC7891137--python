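"""Positional classification of lncRNAs relative to protein-coding genes.

Each lncRNA receives exactly one of four categories, applied in precedence
order (exonic evidence outranks intronic containment):

* ``sense``      — >= 1 base of same-strand exon-exon overlap with a PCG;
* ``antisense``  — else, >= 1 base of opposite-strand exon-exon overlap;
* ``intronic``   — else, the whole transcript span lies inside a single
  intron of one reference transcript (strand-agnostic);
* ``intergenic`` — otherwise.

Distances are genomic gaps in bases (0 when overlapping); the nearest PCG is
chosen by minimal gap with lexicographic gene-id tie-breaking.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from intervaltree import IntervalTree

from .models import TranscriptCatalog, TranscriptModel, interval_gap

CATEGORIES = ("intergenic", "intronic", "sense", "antisense")

DEFAULT_LENGTH_BINS: Tuple[Tuple[int, int], ...] = (
    (200, 400),
    (401, 600),
    (601, 800),
    (801, 1000),
)
DEFAULT_MAX_EXON_BIN = 10


@dataclass(frozen=True)
class LncClass:
    transcript_id: str
    category: str
    nearest_pcg_id: Optional[str]
    distance_to_pcg: Optional[int]


@dataclass
class FeatureSummary:
    """Category tallies plus length/exon histograms for two populations."""

    category_counts: Dict[str, int]
    category_pct: Dict[str, float]
    length_counts: pd.DataFrame
    length_fractions: pd.DataFrame
    exon_counts: pd.DataFrame
    exon_fractions: pd.DataFrame


class ReferenceIndex:
    """Interval-tree indexes over a coding reference catalog."""

    def __init__(self, reference: TranscriptCatalog):
        self.reference = reference
        self.exon_trees: Dict[str, IntervalTree] = {}
        self.intron_trees: Dict[str, IntervalTree] = {}
        self.spans: Dict[str, List[Tuple[int, int, str]]] = {}
        for t in reference:
            et = self.exon_trees.setdefault(t.chrom, IntervalTree())
            for s, e in t.exons:
                et.addi(s, e + 1, (t.strand, t.gene_id))
            it = self.intron_trees.setdefault(t.chrom, IntervalTree())
            for s, e in t.introns:
                if e >= s:
                    it.addi(s, e + 1, t.gene_id)
            self.spans.setdefault(t.chrom, []).append((t.start, t.end, t.gene_id))


def _nearest_gene(
    lnc: TranscriptModel, spans: Sequence[Tuple[int, int, str]]
) -> Tuple[Optional[str], Optional[int]]:
    best: Tuple[int, str] | None = None
    for s, e, gid in spans:
        gap = interval_gap((lnc.start, lnc.end), (s, e))
        if best is None or gap < best[0] or (gap == best[0] and gid < best[1]):
            best = (gap, gid)
    if best is None:
        return None, None
    return best[1], best[0]


def classify_lncrna(
    lnc: TranscriptModel, reference: TranscriptCatalog | ReferenceIndex
) -> LncClass:
    """Assign one positional category to a lncRNA (see module docstring)."""
    index = reference if isinstance(reference, ReferenceIndex) else ReferenceIndex(reference)

    sense_genes: set = set()
    antisense_genes: set = set()
    exon_tree = index.exon_trees.get(lnc.chrom)
    if exon_tree is not None:
        for s, e in lnc.exons:
            for iv in exon_tree.overlap(s, e + 1):
                strand, gid = iv.data
                (sense_genes if strand == lnc.strand else antisense_genes).add(gid)
    if sense_genes:
        return LncClass(lnc.transcript_id, "sense", min(sense_genes), 0)
    if antisense_genes:
        return LncClass(lnc.transcript_id, "antisense", min(antisense_genes), 0)

    intron_tree = index.intron_trees.get(lnc.chrom)
    if intron_tree is not None:
        hosts = {
            iv.data
            for iv in intron_tree.overlap(lnc.start, lnc.end + 1)
            if iv.begin <= lnc.start and lnc.end + 1 <= iv.end
        }
        if hosts:
            return LncClass(lnc.transcript_id, "intronic", min(hosts), 0)

    gid, gap = _nearest_gene(lnc, index.spans.get(lnc.chrom, []))
    return LncClass(lnc.transcript_id, "intergenic", gid, gap)


def classify_all(
    lncs: Iterable[TranscriptModel], reference: TranscriptCatalog
) -> Tuple[List[LncClass], FeatureSummary]:
    """Classify every lncRNA and summarize features against the reference."""
    lncs = list(lncs)
    index = ReferenceIndex(reference)
    classes = [classify_lncrna(t, index) for t in lncs]
    summary = summarize_features(lncs, list(reference))
    counts = Counter(c.category for c in classes)
    total = sum(counts.values())
    summary.category_counts = {cat: counts.get(cat, 0) for cat in CATEGORIES}
    summary.category_pct = {
        cat: (round(100.0 * counts.get(cat, 0) / total, 2) if total else 0.0)
        for cat in CATEGORIES
    }
    return classes, summary


def _length_bin_labels(bins: Sequence[Tuple[int, int]]) -> List[str]:
    labels = [f"<{bins[0][0]}"]
    labels += [f"{lo}-{hi}" for lo, hi in bins]
    labels.append(f">{bins[-1][1]}")
    return labels


def _length_bin(length: int, bins: Sequence[Tuple[int, int]]) -> str:
    if length < bins[0][0]:
        return f"<{bins[0][0]}"
    for lo, hi in bins:
        if lo <= length <= hi:
            return f"{lo}-{hi}"
    return f">{bins[-1][1]}"


def _exon_bin_labels(max_bin: int) -> List[str]:
    return [str(k) for k in range(1, max_bin + 1)] + [f">{max_bin}"]


def _exon_bin(n: int, max_bin: int) -> str:
    return str(n) if n <= max_bin else f">{max_bin}"


def summarize_features(
    lncs: Sequence[TranscriptModel],
    coding: Sequence[TranscriptModel],
    length_bins: Sequence[Tuple[int, int]] = DEFAULT_LENGTH_BINS,
    max_exon_bin: int = DEFAULT_MAX_EXON_BIN,
) -> FeatureSummary:
    """Two-population length and exon-count histograms over identical bins."""
    llabels = _length_bin_labels(length_bins)
    elabels = _exon_bin_labels(max_exon_bin)
    populations = {"lncRNA": list(lncs), "coding": list(coding)}

    length_counts = pd.DataFrame(0, index=llabels, columns=list(populations))
    exon_counts = pd.DataFrame(0, index=elabels, columns=list(populations))
    for name, ts in populations.items():
        for t in ts:
            length_counts.loc[_length_bin(t.length, length_bins), name] += 1
            exon_counts.loc[_exon_bin(t.n_exons, max_exon_bin), name] += 1

    def _fractions(counts: pd.DataFrame) -> pd.DataFrame:
        totals = counts.sum(axis=0)
        out = counts.astype(float)
        for col in out.columns:
            out[col] = out[col] / totals[col] if totals[col] > 0 else 0.0
        return out

    return FeatureSummary(
        category_counts={},
        category_pct={},
        length_counts=length_counts,
        length_fractions=_fractions(length_counts),
        exon_counts=exon_counts,
        exon_fractions=_fractions(exon_counts),
    )
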