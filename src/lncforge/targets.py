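"""Three-mode lncRNA -> gene target prediction.

* ``trans``      — co-expression: Pearson correlation of FPKM profiles over
  all samples (both groups pooled); pairs with |PCC| above a cutoff
  (default 0.99) are targets, signed by the correlation.
* ``cis``        — proximity: same chromosome and a genomic gap of at most
  a window (default 100 kb) between the closest transcript ends; overlap
  counts as gap 0; strand is ignored.
* ``similarity`` — sequence: Smith-Waterman local alignment (match +1,
  mismatch -1, gap open -2, gap extend -1); a pair is a target when the
  best local alignment contains >= ``min_aligned_length`` contiguous
  columns at >= ``min_identity`` identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from Bio import Align

from .models import ExpressionMatrix, TranscriptCatalog, interval_gap

logger = logging.getLogger(__name__)

DEFAULT_DEGREE_BUCKETS: Tuple[Tuple[int, int], ...] = (
    (1, 10), (11, 20), (21, 30), (31, 40), (41, 50), (51, 60),
)


@dataclass(frozen=True)
class TargetPair:
    lnc_id: str
    gene_id: str
    mode: str  # trans | cis | similarity
    score: float  # PCC (trans), gap in bases (cis), alignment score (similarity)
    sign: str  # positive | negative | na


@dataclass
class PccSummary:
    """Distribution of all computed lnc x gene correlations.

    Bins of width 0.2 over [-1, 1]; the last bin is closed at 1.
    ``n_excluded`` counts pairs skipped because one profile had zero
    variance (PCC undefined).
    """

    bin_counts: pd.Series
    bin_fractions: pd.Series
    n_positive: int
    n_negative: int
    n_zero: int
    n_total: int
    n_excluded: int


def _as_frame(expr: Union[ExpressionMatrix, pd.DataFrame]) -> pd.DataFrame:
    return expr.values if isinstance(expr, ExpressionMatrix) else expr


PCC_BIN_LABELS = [
    "[-1.0,-0.8)", "[-0.8,-0.6)", "[-0.6,-0.4)", "[-0.4,-0.2)", "[-0.2,0.0)",
    "[0.0,0.2)", "[0.2,0.4)", "[0.4,0.6)", "[0.6,0.8)", "[0.8,1.0]",
]


def trans_targets(
    lnc_expr: Union[ExpressionMatrix, pd.DataFrame],
    gene_expr: Union[ExpressionMatrix, pd.DataFrame],
    pcc_cutoff: float = 0.99,
) -> Tuple[List[TargetPair], PccSummary]:
    """Co-expression targets: all-pairs PCC with |PCC| > cutoff retained."""
    lnc = _as_frame(lnc_expr)
    gene = _as_frame(gene_expr)
    if set(lnc.columns) != set(gene.columns):
        raise ValueError("lncRNA and gene matrices must share identical sample columns")
    gene = gene[lnc.columns]

    lx = lnc.to_numpy(float)
    gx = gene.to_numpy(float)
    n = lx.shape[1]

    lc = lx - lx.mean(axis=1, keepdims=True)
    gc = gx - gx.mean(axis=1, keepdims=True)
    lnorm = np.sqrt((lc ** 2).sum(axis=1))
    gnorm = np.sqrt((gc ** 2).sum(axis=1))
    lnc_ok = lnorm > 0
    gene_ok = gnorm > 0
    n_excluded = lx.shape[0] * gx.shape[0] - int(lnc_ok.sum()) * int(gene_ok.sum())

    li = np.where(lnc_ok)[0]
    gi = np.where(gene_ok)[0]
    corr = (lc[li] @ gc[gi].T) / np.outer(lnorm[li], gnorm[gi])
    corr = np.clip(corr, -1.0, 1.0)

    pairs: List[TargetPair] = []
    lnc_ids = list(lnc.index)
    gene_ids = list(gene.index)
    keep = np.abs(corr) > pcc_cutoff
    for a, b in zip(*np.nonzero(keep)):
        r = float(corr[a, b])
        pairs.append(
            TargetPair(
                lnc_ids[li[a]], gene_ids[gi[b]], "trans", r,
                "positive" if r > 0 else "negative",
            )
        )

    flat = corr.ravel()
    idx = np.clip(np.floor((flat + 1.0) / 0.2).astype(int), 0, 9)
    counts = np.bincount(idx, minlength=10)
    total = flat.size
    bin_counts = pd.Series(counts, index=PCC_BIN_LABELS)
    bin_fractions = bin_counts / total if total else bin_counts.astype(float)
    summary = PccSummary(
        bin_counts=bin_counts,
        bin_fractions=bin_fractions,
        n_positive=int((flat > 0).sum()),
        n_negative=int((flat < 0).sum()),
        n_zero=int((flat == 0).sum()),
        n_total=int(total),
        n_excluded=int(n_excluded),
    )
    return pairs, summary


@dataclass
class DegreeCategories:
    """Per-lncRNA out-degree bucketed; unique lncRNA/gene counts per bucket."""

    table: pd.DataFrame


def degree_categories(
    pairs: Sequence[TargetPair],
    buckets: Sequence[Tuple[int, int]] = DEFAULT_DEGREE_BUCKETS,
) -> DegreeCategories:
    if pairs is None:
        raise ValueError("pairs must not be None")
    by_lnc: Dict[str, List[str]] = {}
    for p in pairs:
        by_lnc.setdefault(p.lnc_id, []).append(p.gene_id)

    labels = [f"{lo}-{hi}" for lo, hi in buckets] + [f">{buckets[-1][1]}"]
    lnc_count = {lab: 0 for lab in labels}
    genes: Dict[str, set] = {lab: set() for lab in labels}
    for lnc_id, targets in by_lnc.items():
        degree = len(targets)
        label = labels[-1]
        for (lo, hi), lab in zip(buckets, labels):
            if lo <= degree <= hi:
                label = lab
                break
        lnc_count[label] += 1
        genes[label].update(targets)
    table = pd.DataFrame(
        {
            "n_lncrna": [lnc_count[lab] for lab in labels],
            "n_genes": [len(genes[lab]) for lab in labels],
        },
        index=labels,
    )
    return DegreeCategories(table)


def cis_targets(
    lnc_catalog: TranscriptCatalog,
    gene_catalog: TranscriptCatalog,
    window: int = 100_000,
) -> List[TargetPair]:
    """Proximity targets: same chromosome, gap <= window (boundary inclusive).

    The gap is the number of bases strictly between the closest transcript
    ends (0 when the features overlap); strand is ignored; score = gap.
    Genes are reported at gene level (minimum gap over their transcripts).
    """
    pairs: List[TargetPair] = []
    trees = gene_catalog.span_trees()
    for lnc in lnc_catalog:
        tree = trees.get(lnc.chrom)
        if tree is None:
            continue
        best: Dict[str, int] = {}
        lo = lnc.start - window - 1
        hi = lnc.end + window + 2
        for iv in tree.overlap(lo, hi):
            gene = iv.data
            gap = interval_gap((lnc.start, lnc.end), (gene.start, gene.end))
            if gap <= window:
                gid = gene.gene_id
                if gid not in best or gap < best[gid]:
                    best[gid] = gap
        for gid in sorted(best):
            pairs.append(TargetPair(lnc.transcript_id, gid, "cis", float(best[gid]), "na"))
    return pairs


@dataclass(frozen=True)
class SimilarityParams:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0
    min_identity: float = 0.90
    min_aligned_length: int = 100


def make_aligner(params: SimilarityParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def alignment_match_columns(
    alignment: Align.Alignment, seq_a: str, seq_b: str
) -> List[int]:
    """Per-column match indicator (1 = identical bases, 0 = mismatch or gap)."""
    blocks_a, blocks_b = alignment.aligned
    columns: List[int] = []
    prev_a_end: Optional[int] = None
    prev_b_end: Optional[int] = None
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        if prev_a_end is not None:
            columns.extend([0] * ((a0 - prev_a_end) + (b0 - prev_b_end)))
        columns.extend(
            1 if x == y else 0 for x, y in zip(seq_a[a0:a1], seq_b[b0:b1])
        )
        prev_a_end, prev_b_end = a1, b1
    return columns


def alignment_identity(alignment: Align.Alignment, seq_a: str, seq_b: str) -> Tuple[int, int]:
    """(matches, aligned columns incl. gap columns) of a local alignment."""
    columns = alignment_match_columns(alignment, seq_a, seq_b)
    return sum(columns), len(columns)


def _has_identity_window(columns: List[int], min_len: int, min_identity: float) -> bool:
    """True when >= min_len contiguous columns reach min_identity.

    The score-optimal local alignment may extend past a high-identity core
    into low-identity flanks whenever the extension is net-positive under
    the scoring scheme; gating the whole alignment's identity would then
    reject genuinely similar pairs. The gate therefore asks for a window of
    min_len columns at min_identity anywhere inside the alignment.
    """
    if len(columns) < min_len:
        return False
    need = min_identity * min_len
    window = sum(columns[:min_len])
    if window >= need:
        return True
    for i in range(min_len, len(columns)):
        window += columns[i] - columns[i - min_len]
        if window >= need:
            return True
    return False


def similarity_targets(
    lnc_seqs: Mapping[str, str],
    mrna_seqs: Mapping[str, str],
    params: SimilarityParams = SimilarityParams(),
) -> List[TargetPair]:
    """Sequence-similarity targets by all-vs-all local alignment."""
    aligner = make_aligner(params)
    pairs: List[TargetPair] = []
    for lnc_id, lseq in lnc_seqs.items():
        if not lseq:
            logger.warning("empty sequence for %s; skipped", lnc_id)
            continue
        for gene_id, mseq in mrna_seqs.items():
            if not mseq:
                logger.warning("empty sequence for %s; skipped", gene_id)
                continue
            alignments = aligner.align(lseq, mseq)
            if alignments.score <= 0:
                continue
            best = alignments[0]
            columns = alignment_match_columns(best, lseq, mseq)
            if _has_identity_window(
                columns, params.min_aligned_length, params.min_identity
            ):
                pairs.append(
                    TargetPair(lnc_id, gene_id, "similarity", float(best.score), "na")
                )
    return pairs


def pairs_to_frame(pairs: Sequence[TargetPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lnc_id": [p.lnc_id for p in pairs],
            "gene_id": [p.gene_id for p in pairs],
            "mode": [p.mode for p in pairs],
            "score": [p.score for p in pairs],
            "sign": [p.sign for p in pairs],
        }
    )


def frame_to_pairs(df: pd.DataFrame) -> List[TargetPair]:
    return [
        TargetPair(r.lnc_id, r.gene_id, r.mode, float(r.score), r.sign)
        for r in df.itertuples()
    ]
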