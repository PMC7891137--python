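"""Differential expression of lncRNAs between treatment and control groups.

Fold change is ``log2((mean FPKM_treatment + c) / (mean FPKM_control + c))``
with pseudocount ``c`` (default 1). Significance comes from a two-sided
two-sample t-test on ``log2(FPKM + c)``; transcripts with p < alpha
(default 0.05, no multiple-testing correction) are called differentially
expressed, up or down by the sign of the fold change. The pooled-variance
(Student) form is the default: with three replicates per group it holds the
nominal type-I rate under a homoscedastic log-normal model, whereas Welch's
degrees-of-freedom approximation is markedly conservative at n = 3
(empirical size ~0.033 at nominal 0.05); pass ``equal_var=False`` for
Welch when heteroscedasticity is a concern. The module also bins DE calls by
linear fold-change thresholds, intersects DE sets across tissues, and
computes RT-qPCR relative expression (2^-ddCt) and its concordance with
RNA-seq fold changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .models import ExpressionMatrix

DEFAULT_FC_THRESHOLDS = (2.0, 4.0, 5.0, 8.0, 10.0)


@dataclass(frozen=True)
class DERecord:
    transcript_id: str
    mean_fpkm_control: float
    mean_fpkm_treatment: float
    log2fc: float
    p_value: float
    direction: str  # up | down | ns


def compute_de(
    expr: ExpressionMatrix,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    control: str = "Control",
    treatment: str = "H120",
    equal_var: bool = True,
) -> List[DERecord]:
    """Per-transcript fold change and two-sample t-test between two groups.

    Raises if either group has fewer than two samples (within-group
    variance is undefined). Transcripts with undefined test statistics
    (e.g. identical values in both groups) get p = 1 and direction ``ns``.
    """
    ctrl_samples = expr.samples_in(control)
    trt_samples = expr.samples_in(treatment)
    for label, samples in ((control, ctrl_samples), (treatment, trt_samples)):
        if len(samples) < 2:
            raise ValueError(
                f"group {label!r} has {len(samples)} sample(s); >= 2 required"
            )
    ctrl = expr.values[ctrl_samples].to_numpy(float)
    trt = expr.values[trt_samples].to_numpy(float)

    mean_ctrl = ctrl.mean(axis=1)
    mean_trt = trt.mean(axis=1)
    log2fc = np.log2((mean_trt + pseudocount) / (mean_ctrl + pseudocount))

    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant rows yield nan statistics (mapped to p = 1 below); scipy
        # flags them with a precision-loss RuntimeWarning that is expected here
        warnings.simplefilter("ignore", RuntimeWarning)
        _, pvals = stats.ttest_ind(
            np.log2(trt + pseudocount),
            np.log2(ctrl + pseudocount),
            axis=1,
            equal_var=equal_var,
        )
    pvals = np.where(np.isnan(pvals), 1.0, pvals)

    records = []
    for tid, mc, mt, lfc, p in zip(
        expr.transcript_ids, mean_ctrl, mean_trt, log2fc, pvals
    ):
        if p < alpha and lfc > 0:
            direction = "up"
        elif p < alpha and lfc < 0:
            direction = "down"
        else:
            direction = "ns"
        records.append(DERecord(tid, float(mc), float(mt), float(lfc), float(p), direction))
    return records


@dataclass
class FCBinTable:
    """DE counts binned by linear fold-change thresholds.

    ``table`` rows: ``no_filter`` then ``|FC|>t`` for each threshold t;
    columns ``total``/``up``/``down``. |FC| is linear fold change, i.e.
    ``|FC| > t`` means ``|log2fc| > log2(t)``, so rows nest monotonically.
    """

    table: pd.DataFrame


def bin_by_fc(
    records: Sequence[DERecord],
    thresholds: Sequence[float] = DEFAULT_FC_THRESHOLDS,
) -> FCBinTable:
    de = [r for r in records if r.direction in ("up", "down")]
    rows = {}
    labels = ["no_filter"] + [f"|FC|>{t:g}" for t in thresholds]
    cuts = [0.0] + [math.log2(t) for t in thresholds]
    for label, cut in zip(labels, cuts):
        if cut == 0.0:
            selected = de
        else:
            selected = [r for r in de if abs(r.log2fc) > cut]
        up = sum(1 for r in selected if r.direction == "up")
        down = sum(1 for r in selected if r.direction == "down")
        rows[label] = {"total": up + down, "up": up, "down": down}
    return FCBinTable(pd.DataFrame.from_dict(rows, orient="index")[["total", "up", "down"]])


def cross_tissue_overlap(
    de_a: Set[str], de_b: Set[str]
) -> Tuple[Set[str], Set[str], Set[str]]:
    """Partition two DE id sets into (shared, a-only, b-only)."""
    de_a, de_b = set(de_a), set(de_b)
    return de_a & de_b, de_a - de_b, de_b - de_a


def qpcr_relative_expression(
    ct: pd.DataFrame,
    control: str = "Control",
    treatment: str = "H120",
) -> pd.DataFrame:
    """Relative expression by the comparative-Ct method.

    Per replicate, dCt = Ct_target - Ct_reference; ddCt = mean dCt(treatment)
    - mean dCt(control); relative expression = 2^-ddCt; log2 FC = -ddCt.
    Raises when a reference-gene Ct is missing, naming the offending well.
    """
    required = ["transcript_id", "group", "replicate", "ct_target", "ct_reference"]
    missing_cols = [c for c in required if c not in ct.columns]
    if missing_cols:
        raise ValueError(f"Ct table missing columns {missing_cols}")
    bad = ct[ct["ct_reference"].isna() | ct["ct_target"].isna()]
    if len(bad):
        wells = [
            f"({r.transcript_id}, {r.group}, rep {r.replicate})"
            for r in bad.itertuples()
        ]
        raise ValueError(f"missing Ct value(s) for well(s): {', '.join(wells)}")

    out = {}
    for tid, sub in ct.groupby("transcript_id", sort=False):
        dct = sub["ct_target"] - sub["ct_reference"]
        groups = sub["group"]
        for label in (control, treatment):
            if not (groups == label).any():
                raise ValueError(f"transcript {tid}: no wells for group {label!r}")
        ddct = dct[groups == treatment].mean() - dct[groups == control].mean()
        out[tid] = {
            "ddct": ddct,
            "relative_expression": 2.0 ** (-ddct),
            "log2fc": -ddct,
        }
    result = pd.DataFrame.from_dict(out, orient="index")
    result.index.name = "transcript_id"
    return result


def concordance(qpcr_log2fc: Sequence[float], rnaseq_log2fc: Sequence[float]) -> float:
    """Pearson correlation between paired qPCR and RNA-seq log2 fold changes."""
    x = np.asarray(qpcr_log2fc, dtype=float)
    y = np.asarray(rnaseq_log2fc, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    if x.size < 3:
        raise ValueError("concordance requires >= 3 paired fold changes")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance in one of the vectors; correlation undefined")
    return float(stats.pearsonr(x, y)[0])
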