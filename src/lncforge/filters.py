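"""Five-stage candidate-lncRNA filter cascade with per-stage accounting.

Stage order is fixed:

1. ``known_coding``      — drop candidates that structure-match a reference
   protein-coding transcript (identical intron chain, or a same-strand
   contained fragment sharing >= 1 splice boundary). Mere exonic overlap is
   not grounds for removal — overlapping-but-distinct transcripts are the
   later "sense" lncRNA class.
2. ``protein_similarity`` — drop candidates whose best protein-database hit
   has E-value <= cutoff (default 1e-5); transcripts absent from the hit
   table are retained (no hit).
3. ``structure``          — drop candidates shorter than 200 nt or with a
   single exon.
4. ``coding_potential``   — keep only the three-tool consensus of
   non-coding calls: CNCI score < 0 AND PLEK score < 0 AND CPAT coding
   probability < 0.44 (strict inequalities, as the thresholds are quoted).
5. ``min_samples``        — keep transcripts detected (FPKM > 0) in at
   least two samples.

Stages 2-5 are pure per-transcript predicates, so the retained set is
independent of input order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd

from .io import SchemaError
from .models import ExpressionMatrix, TranscriptCatalog, TranscriptModel

logger = logging.getLogger(__name__)

STAGE_NAMES = (
    "known_coding",
    "protein_similarity",
    "structure",
    "coding_potential",
    "min_samples",
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the five filter stages (defaults follow the study)."""

    evalue_cutoff: float = 1e-5
    min_length: int = 200
    min_exons: int = 2
    cnci_max: float = 0.0
    plek_max: float = 0.0
    cpat_max: float = 0.44
    min_samples_expressed: int = 2
    expressed_fpkm_gt: float = 0.0

    def __post_init__(self) -> None:
        for name in ("evalue_cutoff", "cnci_max", "plek_max", "cpat_max",
                     "expressed_fpkm_gt"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.min_samples_expressed < 1:
            raise ValueError("min_samples_expressed must be >= 1")


@dataclass(frozen=True)
class StageRecord:
    """Retention accounting for one stage; percentages recompute from counts."""

    stage_name: str
    n_in: int
    n_removed: int

    @property
    def n_retained(self) -> int:
        return self.n_in - self.n_removed

    @property
    def pct_removed(self) -> float:
        return 0.0 if self.n_in == 0 else round(100.0 * self.n_removed / self.n_in, 2)

    @property
    def pct_retained(self) -> float:
        return 0.0 if self.n_in == 0 else round(100.0 * self.n_retained / self.n_in, 2)


@dataclass
class FilterReport:
    """Ordered stage records plus the surviving (putative lncRNA) id list."""

    stages: List[StageRecord]
    final_ids: List[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage_name": [s.stage_name for s in self.stages],
                "n_in": [s.n_in for s in self.stages],
                "n_removed": [s.n_removed for s in self.stages],
                "n_retained": [s.n_retained for s in self.stages],
                "pct_removed": [s.pct_removed for s in self.stages],
                "pct_retained": [s.pct_retained for s in self.stages],
            }
        )


Partition = Tuple[List[TranscriptModel], List[TranscriptModel]]


def _as_list(candidates: Iterable[TranscriptModel]) -> List[TranscriptModel]:
    return list(candidates)


def _is_contiguous_subchain(
    sub: Sequence[Tuple[int, int]], chain: Sequence[Tuple[int, int]]
) -> bool:
    if not sub or len(sub) > len(chain):
        return False
    for i in range(len(chain) - len(sub) + 1):
        if tuple(chain[i : i + len(sub)]) == tuple(sub):
            return True
    return False


def _structure_matches_coding(cand: TranscriptModel, ref: TranscriptModel) -> bool:
    """Candidate is a redundant copy/fragment of a coding reference transcript.

    True when (a) the intron chains are identical (multi-exon exact match),
    or (b) the candidate lies within the reference span on the same strand
    and is a contained fragment sharing >= 1 splice boundary: for a
    single-exon candidate, containment within one reference exon with one
    end on that exon's splice boundary; for a multi-exon candidate, an
    intron chain that is a contiguous sub-chain of the reference's.
    """
    if cand.strand != ref.strand:
        return False
    if cand.n_exons > 1 and cand.introns == ref.introns:
        return True
    if not (ref.start <= cand.start and cand.end <= ref.end):
        return False
    if cand.n_exons == 1:
        s, e = cand.exons[0]
        for a, b in ref.exons:
            if a <= s and e <= b and (s == a or e == b):
                return True
        return False
    return _is_contiguous_subchain(cand.introns, ref.introns)


def filter_known_coding(
    candidates: Iterable[TranscriptModel], reference: TranscriptCatalog
) -> Partition:
    """Stage 1: remove candidates that structure-match coding reference transcripts."""
    cands = _as_list(candidates)
    coding = TranscriptCatalog([t for t in reference if t.biotype == "coding"])
    trees = coding.span_trees()
    ref_chroms = set(coding.chromosomes)
    warned: set = set()
    retained, removed = [], []
    for c in cands:
        if c.chrom not in ref_chroms:
            if c.chrom not in warned:
                logger.warning(
                    "chromosome %s has no coding reference features; "
                    "candidates there are retained as non-matching", c.chrom
                )
                warned.add(c.chrom)
            retained.append(c)
            continue
        tree = trees[c.chrom]
        hit = any(
            _structure_matches_coding(c, iv.data)
            for iv in tree.overlap(c.start, c.end + 1)
        )
        (removed if hit else retained).append(c)
    return retained, removed


def filter_protein_similarity(
    candidates: Iterable[TranscriptModel],
    hits: pd.Series,
    config: FilterConfig = FilterConfig(),
) -> Partition:
    """Stage 2: remove candidates with a protein hit at E-value <= cutoff."""
    retained, removed = [], []
    for c in _as_list(candidates):
        ev = hits.get(c.transcript_id)
        if ev is not None and ev <= config.evalue_cutoff:
            removed.append(c)
        else:
            retained.append(c)
    return retained, removed


def filter_structure(
    candidates: Iterable[TranscriptModel], config: FilterConfig = FilterConfig()
) -> Partition:
    """Stage 3: remove candidates shorter than min_length or with too few exons."""
    retained, removed = [], []
    for c in _as_list(candidates):
        if c.length < config.min_length or c.n_exons < config.min_exons:
            removed.append(c)
        else:
            retained.append(c)
    return retained, removed


def filter_coding_potential(
    candidates: Iterable[TranscriptModel],
    scores: pd.DataFrame,
    config: FilterConfig = FilterConfig(),
) -> Partition:
    """Stage 4: keep the three-way intersection of CNCI/PLEK/CPAT non-coding calls."""
    cands = _as_list(candidates)
    missing = [c.transcript_id for c in cands if c.transcript_id not in scores.index]
    if missing:
        raise SchemaError(
            f"coding-potential scores are mandatory; missing rows for: {missing}"
        )
    retained, removed = [], []
    for c in cands:
        row = scores.loc[c.transcript_id]
        noncoding = (
            row["cnci"] < config.cnci_max
            and row["plek"] < config.plek_max
            and row["cpat"] < config.cpat_max
        )
        (retained if noncoding else removed).append(c)
    return retained, removed


def filter_min_samples(
    candidates: Iterable[TranscriptModel],
    expr: ExpressionMatrix,
    config: FilterConfig = FilterConfig(),
) -> Partition:
    """Stage 5: keep candidates detected in >= min_samples_expressed samples."""
    retained, removed = [], []
    for c in _as_list(candidates):
        if c.transcript_id not in expr.values.index:
            logger.warning(
                "transcript %s missing from expression matrix; treated as unexpressed",
                c.transcript_id,
            )
            removed.append(c)
            continue
        row = expr.values.loc[c.transcript_id]
        n_expressed = int((row > config.expressed_fpkm_gt).sum())
        (retained if n_expressed >= config.min_samples_expressed else removed).append(c)
    return retained, removed


def run_cascade(
    candidates: Iterable[TranscriptModel],
    reference: TranscriptCatalog,
    hits: pd.Series,
    scores: pd.DataFrame,
    expr: ExpressionMatrix,
    config: FilterConfig = FilterConfig(),
) -> Tuple[FilterReport, List[TranscriptModel]]:
    """Apply all five stages in order and account for every transcript."""
    current = _as_list(candidates)
    stages: List[StageRecord] = []

    stage_fns = [
        ("known_coding", lambda cs: filter_known_coding(cs, reference)),
        ("protein_similarity", lambda cs: filter_protein_similarity(cs, hits, config)),
        ("structure", lambda cs: filter_structure(cs, config)),
        ("coding_potential", lambda cs: filter_coding_potential(cs, scores, config)),
        ("min_samples", lambda cs: filter_min_samples(cs, expr, config)),
    ]
    for name, fn in stage_fns:
        retained, removed = fn(current)
        stages.append(StageRecord(name, n_in=len(current), n_removed=len(removed)))
        current = retained
    return FilterReport(stages, [c.transcript_id for c in current]), current
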