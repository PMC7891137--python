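"""Interaction-network assembly and hypergeometric term enrichment.

The network is a multigraph: lncRNA and gene nodes, one edge per supporting
prediction mode between a pair (trans_positive / trans_negative / cis /
similarity), so a pair supported by two modes keeps two distinctly typed
edges. Enrichment is database-agnostic: the caller supplies the gene->term
map and the background universe, and each term gets an upper-tail
hypergeometric p-value and a fold-enrichment score (k/n)/(K/N).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Union

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .targets import TargetPair

PathLike = Union[str, Path]


def _edge_type(pair: TargetPair) -> str:
    if pair.mode == "trans":
        return f"trans_{pair.sign}"
    return pair.mode


def _as_direction_map(ids: Union[Mapping[str, str], Iterable[str]]) -> Dict[str, str]:
    if isinstance(ids, Mapping):
        return dict(ids)
    return {i: "na" for i in ids}


def build_network(
    pairs: Sequence[TargetPair],
    de_lncs: Union[Mapping[str, str], Iterable[str]],
    de_genes: Union[Mapping[str, str], Iterable[str]],
    gene_annotations: Optional[Mapping[str, Mapping[str, object]]] = None,
    restrict_flag: Optional[str] = None,
) -> nx.MultiGraph:
    """Assemble the lncRNA-gene interaction multigraph from target pairs.

    ``de_lncs`` / ``de_genes`` map ids to DE direction (or are plain id
    collections). Pairs referencing ids outside these universes raise,
    listing the offenders. With ``restrict_flag``, only genes whose
    annotation has that flag truthy (e.g. an HSP-family flag) and their
    lncRNA neighbours are kept.
    """
    lnc_dir = _as_direction_map(de_lncs)
    gene_dir = _as_direction_map(de_genes)
    annotations = gene_annotations or {}

    unknown = sorted(
        {p.gene_id for p in pairs if p.gene_id not in gene_dir}
        | {p.lnc_id for p in pairs if p.lnc_id not in lnc_dir}
    )
    if unknown:
        raise ValueError(f"pairs reference unknown node ids: {unknown}")

    net = nx.MultiGraph()
    for p in pairs:
        if p.lnc_id not in net:
            net.add_node(p.lnc_id, kind="lncRNA", de_direction=lnc_dir[p.lnc_id])
        if p.gene_id not in net:
            attrs = {str(k): v for k, v in annotations.get(p.gene_id, {}).items()}
            net.add_node(p.gene_id, kind="gene", de_direction=gene_dir[p.gene_id], **attrs)
        net.add_edge(
            p.lnc_id, p.gene_id, key=_edge_type(p),
            edge_type=_edge_type(p), score=float(p.score),
        )

    if restrict_flag is not None:
        keep_genes = {
            n for n, d in net.nodes(data=True)
            if d.get("kind") == "gene" and d.get(restrict_flag)
        }
        keep = set(keep_genes)
        for g in keep_genes:
            keep.update(net.neighbors(g))
        net = net.subgraph(keep).copy()
        # drop edges whose gene endpoint is not flagged
        drop = [
            (u, v, k) for u, v, k in net.edges(keys=True)
            if not (
                (net.nodes[u].get("kind") == "gene" and u in keep_genes)
                or (net.nodes[v].get("kind") == "gene" and v in keep_genes)
            )
        ]
        net.remove_edges_from(drop)
        net.remove_nodes_from([n for n in list(net) if net.degree(n) == 0])
    return net


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # term hits in the gene set
    K: int  # term hits in the background
    n: int  # gene-set size
    N: int  # background size
    p_value: float
    fold_enrichment: float
    q_value: Optional[float] = None


def hypergeometric_p(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k)."""
    return float(hypergeom.sf(k - 1, N, K, n))


def hypergeometric_enrichment(
    gene_set: Iterable[str],
    background: Iterable[str],
    term_map: pd.DataFrame,
    fdr: bool = False,
) -> List[EnrichmentResult]:
    """Over-representation test of each term in ``gene_set`` vs ``background``.

    ``term_map`` columns: gene_id, term_id and optionally term_name. Genes
    without terms are allowed; genes in the set but not the background are
    an error. Results sorted by p-value. With ``fdr=True`` a
    Benjamini-Hochberg q-value is attached.
    """
    gene_set = set(gene_set)
    background = set(background)
    stray = sorted(gene_set - background)
    if stray:
        raise ValueError(f"genes in set but not in background: {stray}")

    if "term_name" not in term_map.columns:
        term_map = term_map.assign(term_name=term_map["term_id"])
    term_map = term_map[term_map["gene_id"].isin(background)]

    N = len(background)
    n = len(gene_set)
    results: List[EnrichmentResult] = []
    for term_id, sub in term_map.groupby("term_id", sort=True):
        genes = set(sub["gene_id"])
        K = len(genes)
        k = len(genes & gene_set)
        p = hypergeometric_p(k, N, K, n)
        fold = 0.0 if (k == 0 or n == 0) else (k / n) / (K / N)
        results.append(
            EnrichmentResult(
                term_id=str(term_id),
                term_name=str(sub["term_name"].iloc[0]),
                k=k, K=K, n=n, N=N,
                p_value=p, fold_enrichment=fold,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.term_id))
    if fdr and results:
        qvals = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        results = [
            EnrichmentResult(
                r.term_id, r.term_name, r.k, r.K, r.n, r.N, r.p_value,
                r.fold_enrichment, float(q),
            )
            for r, q in zip(results, qvals)
        ]
    return results


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def export_network(
    net: nx.MultiGraph, out_dir: PathLike, basename: str = "network"
) -> Dict[str, Path]:
    """Write node/edge TSVs plus GraphML; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    node_path = out_dir / f"{basename}.nodes.tsv"
    edge_path = out_dir / f"{basename}.edges.tsv"
    graphml_path = out_dir / f"{basename}.graphml"

    node_rows = [
        {"id": n, **{k: v for k, v in d.items()}} for n, d in net.nodes(data=True)
    ]
    cols = ["id", "kind", "de_direction"]
    ndf = pd.DataFrame(node_rows, columns=sorted(
        {c for row in node_rows for c in row} | set(cols),
        key=lambda c: (cols.index(c) if c in cols else len(cols), c),
    ) if node_rows else cols)
    ndf.to_csv(node_path, sep="\t", index=False)

    edge_rows = [
        {"lnc_id": u if net.nodes[u].get("kind") == "lncRNA" else v,
         "gene_id": v if net.nodes[u].get("kind") == "lncRNA" else u,
         "edge_type": d.get("edge_type"), "score": d.get("score")}
        for u, v, d in net.edges(data=True)
    ]
    edf = pd.DataFrame(edge_rows, columns=["lnc_id", "gene_id", "edge_type", "score"])
    edf.to_csv(edge_path, sep="\t", index=False)

    nx.write_graphml(net, graphml_path)
    return {"nodes": node_path, "edges": edge_path, "graphml": graphml_path}


def load_network(graphml_path: PathLike) -> nx.MultiGraph:
    """Read a network written by :func:`export_network` back from GraphML."""
    g = nx.read_graphml(str(graphml_path), force_multigraph=True)
    return nx.MultiGraph(g)
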