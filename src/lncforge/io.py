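"""Readers and writers for the standard formats the pipeline touches.

GTF 2.2 for transcript models, TSV-with-header for score / hit / expression /
Ct tables, FASTA for sequences. Files use 1-based inclusive coordinates, as
does the in-memory representation, so no conversion happens here.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Dict, List, Mapping, Tuple, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

from .models import ExpressionMatrix, TranscriptCatalog, TranscriptModel

PathLike = Union[str, Path]

# attribute keys we map onto TranscriptModel fields; everything else is
# preserved opaquely for round-trip fidelity
_CORE_ATTRS = ("transcript_id", "gene_id", "biotype")


class GtfParseError(ValueError):
    """A malformed GTF line; the message names the file and line number."""


class SchemaError(ValueError):
    """A table is missing required columns or contains invalid cells."""


def _open_text(path: PathLike):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_gtf(path: PathLike, biotype: str = "unknown") -> TranscriptCatalog:
    """Read a GTF file into a :class:`TranscriptCatalog`.

    Only ``exon`` features are used to build transcript models; each must
    carry ``transcript_id`` and ``gene_id`` attributes. Exons of a transcript
    are sorted and overlapping/adjacent exons merged. A ``biotype`` attribute
    on the file overrides the ``biotype`` argument.
    """
    exons: Dict[str, List[Tuple[int, int]]] = {}
    meta: Dict[str, Dict[str, str]] = {}
    order: List[str] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises a mix of types
                raise GtfParseError(f"{path}:{lineno}: malformed GTF line ({exc})")
            if feat.featuretype != "exon":
                continue
            if feat.end < feat.start:
                raise GtfParseError(
                    f"{path}:{lineno}: exon end {feat.end} < start {feat.start}"
                )
            attrs = {k: v[0] for k, v in feat.attributes.items() if v}
            if "transcript_id" not in attrs or "gene_id" not in attrs:
                raise GtfParseError(
                    f"{path}:{lineno}: exon lacks transcript_id/gene_id attributes"
                )
            tid = attrs["transcript_id"]
            if tid not in exons:
                exons[tid] = []
                order.append(tid)
                meta[tid] = {
                    "gene_id": attrs["gene_id"],
                    "chrom": feat.seqid,
                    "strand": feat.strand,
                    "biotype": attrs.get("biotype", biotype),
                    "_line": str(lineno),
                }
                meta[tid].update(
                    {k: v for k, v in attrs.items() if k not in _CORE_ATTRS}
                )
            else:
                if feat.strand != meta[tid]["strand"] or feat.seqid != meta[tid]["chrom"]:
                    raise GtfParseError(
                        f"{path}:{lineno}: transcript {tid} mixes chromosomes/strands"
                    )
            exons[tid].append((feat.start, feat.end))

    transcripts = []
    for tid in order:
        m = meta[tid]
        merged = _merge_intervals(exons[tid])
        extra = {
            k: v
            for k, v in m.items()
            if k not in ("gene_id", "chrom", "strand", "biotype", "_line")
        }
        try:
            transcripts.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=m["gene_id"],
                    chrom=m["chrom"],
                    strand=m["strand"],
                    exons=tuple(merged),
                    biotype=m["biotype"],
                    attributes=extra,
                )
            )
        except ValueError as exc:
            raise GtfParseError(f"{path}:{m['_line']}: {exc}")
    return TranscriptCatalog(transcripts)


def _merge_intervals(ivs: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    ivs = sorted(ivs)
    merged: List[Tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def write_gtf(catalog: TranscriptCatalog, path: PathLike, source: str = "lncforge") -> None:
    """Write a catalog as GTF 2.2; re-reading yields an equal catalog."""
    with open(path, "wt") as fh:
        for t in catalog:
            attrs = [f'gene_id "{t.gene_id}"', f'transcript_id "{t.transcript_id}"']
            attrs.append(f'biotype "{t.biotype}"')
            for k, v in t.attributes.items():
                attrs.append(f'{k} "{v}"')
            attr_str = "; ".join(attrs) + ";"
            fh.write(
                "\t".join(
                    [t.chrom, source, "transcript", str(t.start), str(t.end), ".",
                     t.strand, ".", attr_str]
                )
                + "\n"
            )
            for s, e in t.exons:
                fh.write(
                    "\t".join(
                        [t.chrom, source, "exon", str(s), str(e), ".", t.strand, ".",
                         attr_str]
                    )
                    + "\n"
                )


def _read_table(path: PathLike, required: List[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return df


def _numeric(df: pd.DataFrame, columns: List[str], path: PathLike) -> pd.DataFrame:
    df = df.copy()
    for c in columns:
        converted = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[converted.isna() & df[c].notna()]
        if len(bad):
            raise SchemaError(
                f"{path}: non-numeric value in column {c!r} at row(s) {list(bad)}"
            )
        if converted.isna().any():
            raise SchemaError(f"{path}: missing value in column {c!r}")
        df[c] = converted
    return df


def _reject_duplicate_ids(df: pd.DataFrame, path: PathLike) -> None:
    dup = df["transcript_id"][df["transcript_id"].duplicated()].unique().tolist()
    if dup:
        raise SchemaError(f"{path}: duplicated transcript_id rows: {dup}")


def read_scores(path: PathLike) -> pd.DataFrame:
    """Coding-potential score table: index transcript_id, columns cnci/plek/cpat."""
    df = _read_table(path, ["transcript_id", "cnci", "plek", "cpat"])
    df = _numeric(df, ["cnci", "plek", "cpat"], path)
    _reject_duplicate_ids(df, path)
    if ((df["cpat"] < 0) | (df["cpat"] > 1)).any():
        raise SchemaError(f"{path}: cpat probabilities must lie in [0, 1]")
    return df.set_index("transcript_id")[["cnci", "plek", "cpat"]]


def read_hits(path: PathLike) -> pd.Series:
    """Protein-hit table: best E-value per transcript (absence means no hit)."""
    df = _read_table(path, ["transcript_id", "best_evalue"])
    df = _numeric(df, ["best_evalue"], path)
    _reject_duplicate_ids(df, path)
    if (df["best_evalue"] < 0).any():
        raise SchemaError(f"{path}: E-values must be >= 0")
    return df.set_index("transcript_id")["best_evalue"]


def read_fpkm(fpkm_path: PathLike, groups_path: PathLike) -> ExpressionMatrix:
    """FPKM matrix (transcript rows, sample columns) plus a sample->group map."""
    values = pd.read_csv(fpkm_path, sep="\t", index_col=0)
    for c in values.columns:
        converted = pd.to_numeric(values[c], errors="coerce")
        if converted.isna().any():
            bad = values.index[converted.isna()].tolist()
            raise SchemaError(f"{fpkm_path}: non-numeric FPKM in column {c!r}, rows {bad}")
        values[c] = converted
    gdf = _read_table(groups_path, ["sample", "group"])
    groups = gdf.set_index("sample")["group"]
    return ExpressionMatrix(values, groups)


def write_fpkm(expr: ExpressionMatrix, fpkm_path: PathLike, groups_path: PathLike) -> None:
    expr.values.to_csv(fpkm_path, sep="\t", index_label="transcript_id")
    expr.groups.rename("group").to_csv(groups_path, sep="\t", index_label="sample")


def read_ct(path: PathLike) -> pd.DataFrame:
    """Ct table: one row per (transcript, group, replicate) well."""
    df = _read_table(
        path, ["transcript_id", "group", "replicate", "ct_target", "ct_reference"]
    )
    df = _numeric(df, ["ct_target", "ct_reference"], path)
    if ((df["ct_target"] <= 0) | (df["ct_reference"] <= 0)).any():
        raise SchemaError(f"{path}: Ct values must be positive")
    return df


def read_fasta(path: PathLike) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
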