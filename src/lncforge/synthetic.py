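"""Synthetic study generator: every pipeline input with known ground truth.

The generator emulates the design of a two-group (Control at room
temperature vs. heat-stressed H120), three-replicates-per-group RNA-seq
study of a small genome: stranded multi-exon protein-coding genes (PCGs),
candidate transcripts planted unambiguously in each positional class
(intergenic / intronic / sense / antisense), coding-potential score and
protein-hit tables engineered so each candidate's fate in the five-stage
filter cascade is known, a log-normal FPKM matrix with planted group
effects and planted near-perfect lncRNA-gene co-expression, cis pairs both
within and beyond the 100 kb window, and lncRNA/mRNA sequences with planted
high-identity substrings.

Everything is driven by one integer seed; a fixed scenario reproduces
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import io as lio
from .models import ExpressionMatrix, TranscriptCatalog, TranscriptModel, interval_gap

LN2 = float(np.log(2.0))

FILTER_FATES = (
    "pass", "fail_stage1", "fail_stage2", "fail_stage3", "fail_stage4", "fail_stage5",
)
POSITIONAL_CLASSES = ("intergenic", "intronic", "sense", "antisense")

# share of positional candidates assigned to each fate; stage-1 failures are
# the separate coding-like candidates (n_coding_like)
FATE_SHARES = {
    "pass": 0.60,
    "fail_stage2": 0.10,
    "fail_stage3": 0.10,
    "fail_stage4": 0.10,
    "fail_stage5": 0.10,
}

TRANS_LATENT_SD = 1.5  # log-scale spread of the shared co-expression factor


class PlacementError(RuntimeError):
    """The scenario is over-packed: features cannot be placed without overlap."""


@dataclass(frozen=True)
class SyntheticScenario:
    """Study conditions for one synthetic dataset.

    Defaults mirror the emulated design: 3 biological replicates per group,
    a 100 kb cis window, ~50 PCGs hosting ~200 positional candidates, 10%
    of candidates differentially expressed with |log2 FC| = 3 over
    log-normal noise.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 4_000_000
    n_pcgs: int = 50
    n_candidates_per_class: int = 50
    n_coding_like: int = 10
    n_samples_per_group: int = 3
    de_fraction: float = 0.1
    planted_log2fc: float = 3.0
    noise_sd: float = 0.1
    cis_window_bases: int = 100_000
    n_planted_trans_pairs: int = 5
    n_planted_similarity_pairs: int = 3

    def __post_init__(self) -> None:
        if self.n_samples_per_group < 2:
            raise ValueError("n_samples_per_group must be >= 2")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be a proportion")


@dataclass
class SyntheticDataset:
    """All generated inputs plus the truth table."""

    scenario: SyntheticScenario
    reference: TranscriptCatalog
    candidates: TranscriptCatalog
    scores: pd.DataFrame
    hits: pd.Series
    expression: ExpressionMatrix
    truth: pd.DataFrame
    lnc_sequences: Dict[str, str]
    mrna_sequences: Dict[str, str]

    def write(self, out_dir: Union[str, Path]) -> Dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "reference": out / "reference.gtf",
            "candidates": out / "candidates.gtf",
            "scores": out / "scores.tsv",
            "hits": out / "hits.tsv",
            "fpkm": out / "fpkm.tsv",
            "groups": out / "groups.tsv",
            "truth": out / "truth.tsv",
            "lnc_fasta": out / "candidates.fa",
            "mrna_fasta": out / "mrna.fa",
        }
        lio.write_gtf(self.reference, paths["reference"])
        lio.write_gtf(self.candidates, paths["candidates"])
        self.scores.to_csv(paths["scores"], sep="\t", index_label="transcript_id")
        self.hits.rename("best_evalue").to_csv(
            paths["hits"], sep="\t", index_label="transcript_id"
        )
        lio.write_fpkm(self.expression, paths["fpkm"], paths["groups"])
        self.truth.to_csv(paths["truth"], sep="\t", index_label="transcript_id")
        lio.write_fasta(self.lnc_sequences, paths["lnc_fasta"])
        lio.write_fasta(self.mrna_sequences, paths["mrna_fasta"])
        return paths


def _rng(scenario_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(scenario_seed), stream]))


# ---------------------------------------------------------------------------
# genome + candidate geometry
# ---------------------------------------------------------------------------

def _make_pcg(
    rng: np.random.Generator, chrom: str, cursor: int, idx: int, large_gap: bool
) -> Tuple[TranscriptModel, int]:
    gap = 260_000 if large_gap else int(rng.integers(20_000, 50_001))
    n_ex = int(rng.integers(2, 6))
    exon_lens = rng.integers(400, 901, n_ex)
    if exon_lens.sum() <= 1000:
        exon_lens[-1] += 1001 - exon_lens.sum()
    intron_lens = rng.integers(4_000, 12_001, n_ex - 1)
    start = cursor + gap
    exons = []
    pos = start
    for i in range(n_ex):
        exons.append((pos, pos + int(exon_lens[i]) - 1))
        pos = exons[-1][1] + 1
        if i < n_ex - 1:
            pos += int(intron_lens[i])
    strand = str(rng.choice(["+", "-"]))
    t = TranscriptModel(
        transcript_id=f"PCGT_{idx:05d}",
        gene_id=f"GENE_{idx:05d}",
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
        biotype="coding",
    )
    return t, t.end


def _fate_list(rng: np.random.Generator, n: int) -> List[str]:
    counts = {f: int(np.floor(s * n)) for f, s in FATE_SHARES.items()}
    counts["pass"] += n - sum(counts.values())
    fates = [f for f, c in counts.items() for _ in range(c)]
    return list(rng.permutation(fates))


class _Placer:
    """Tracks candidate-occupied intervals so candidates never overlap."""

    def __init__(self) -> None:
        self.trees: Dict[str, IntervalTree] = {}

    def free(self, chrom: str, start: int, end: int) -> bool:
        tree = self.trees.get(chrom)
        return tree is None or not tree.overlaps(start, end + 1)

    def claim(self, chrom: str, start: int, end: int) -> None:
        self.trees.setdefault(chrom, IntervalTree()).addi(start, end + 1)


def _two_exon(rng: np.random.Generator, start: int) -> Tuple[Tuple[int, int], ...]:
    l1 = int(rng.integers(150, 401))
    l2 = int(rng.integers(150, 401))
    gap = int(rng.integers(300, 901))
    return ((start, start + l1 - 1), (start + l1 + gap, start + l1 + gap + l2 - 1))


def _one_exon(rng: np.random.Generator, start: int) -> Tuple[Tuple[int, int], ...]:
    return ((start, start + int(rng.integers(250, 601)) - 1),)


def generate_genome_annotation(
    scenario: SyntheticScenario,
) -> Tuple[TranscriptCatalog, TranscriptCatalog, pd.DataFrame]:
    """Build the reference PCG catalog, candidate catalog and truth skeleton.

    The truth skeleton carries ``true_class``, ``filter_fate`` and
    ``cis_partners`` for every candidate; expression/target truth columns
    are added by :func:`generate_scenario`.
    """
    rng = _rng(scenario.seed, 1)
    chroms = [f"chr{i + 1}" for i in range(scenario.n_chromosomes)]

    refs: List[TranscriptModel] = []
    per_chrom = {c: [] for c in chroms}
    for k in range(scenario.n_pcgs):
        chrom = chroms[k % len(chroms)]
        per_chrom[chrom].append(k)
    idx = 0
    for chrom in chroms:
        cursor = 10_000
        for j, _ in enumerate(per_chrom[chrom]):
            large = (j % 5 == 4)
            t, cursor = _make_pcg(rng, chrom, cursor, idx, large)
            if cursor > scenario.chrom_length - 10_000:
                raise PlacementError(
                    f"chromosome {chrom} too short for {len(per_chrom[chrom])} PCGs"
                )
            refs.append(t)
            idx += 1
    reference = TranscriptCatalog(refs)

    # coding-like candidates get dedicated template genes so no candidate
    # overlaps another candidate
    if scenario.n_coding_like > scenario.n_pcgs and scenario.n_coding_like > 0:
        raise PlacementError("n_coding_like exceeds the number of PCGs")
    template_ids = (
        sorted(rng.choice(scenario.n_pcgs, scenario.n_coding_like, replace=False))
        if scenario.n_coding_like
        else []
    )
    host_refs = [t for i, t in enumerate(refs) if i not in set(template_ids)]
    if scenario.n_candidates_per_class > 0 and not host_refs and scenario.n_pcgs > 0:
        raise PlacementError(
            "no host PCGs left for positional candidates "
            "(n_coding_like consumes every gene)"
        )

    placer = _Placer()
    candidates: List[TranscriptModel] = []
    rows: List[Dict[str, object]] = []
    cand_idx = 0

    def add_candidate(exons, chrom, strand, true_class, fate):
        nonlocal cand_idx
        cand_idx += 1
        tid = f"TCONS_{cand_idx:08d}"
        t = TranscriptModel(tid, f"CGENE_{cand_idx:08d}", chrom, strand, tuple(exons),
                            biotype="candidate")
        placer.claim(chrom, t.start, t.end)
        candidates.append(t)
        rows.append({"transcript_id": tid, "true_class": true_class, "filter_fate": fate})

    # gaps between consecutive PCGs per chromosome (for intergenic planting)
    gaps: List[Tuple[str, int, int]] = []
    for chrom in chroms:
        spans = sorted((t.start, t.end) for t in reference.on_chrom(chrom))
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 - e1 > 6_000:
                gaps.append((chrom, e1 + 1, s2 - 1))
        if not spans and scenario.n_candidates_per_class > 0:
            gaps.append((chrom, 10_000, scenario.chrom_length - 10_000))
        elif spans and len(spans) < 2 and scenario.n_candidates_per_class > 0:
            # single-gene chromosome: use the region downstream of the gene
            gaps.append((chrom, spans[-1][1] + 1,
                         min(spans[-1][1] + 150_000, scenario.chrom_length - 10_000)))

    margin = 2_000

    def place_intergenic(fate: str) -> None:
        for _ in range(200):
            chrom, gs, ge = gaps[int(rng.integers(len(gaps)))]
            span_budget = 2_200
            lo, hi = gs + margin, ge - margin - span_budget
            if hi <= lo:
                continue
            if (ge - gs) >= 2 * scenario.cis_window_bases + 40_000:
                center = (gs + ge) // 2
                start = int(center + rng.integers(-2_000, 2_001))
            else:
                start = int(rng.integers(lo, hi))
            exons = _one_exon(rng, start) if fate == "fail_stage3" else _two_exon(rng, start)
            if exons[-1][1] > ge - margin:
                continue
            if placer.free(chrom, exons[0][0], exons[-1][1]):
                strand = str(rng.choice(["+", "-"]))
                add_candidate(exons, chrom, strand, "intergenic", fate)
                return
        raise PlacementError("could not place an intergenic candidate")

    def place_intronic(fate: str) -> None:
        for _ in range(200):
            host = host_refs[int(rng.integers(len(host_refs)))]
            introns = [iv for iv in host.introns if iv[1] - iv[0] + 1 >= 4_000]
            if not introns:
                continue
            s, e = introns[int(rng.integers(len(introns)))]
            span_budget = 1_800
            lo, hi = s + 200, e - 200 - span_budget
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            exons = _one_exon(rng, start) if fate == "fail_stage3" else _two_exon(rng, start)
            if exons[-1][1] > e - 200:
                continue
            if placer.free(host.chrom, exons[0][0], exons[-1][1]):
                strand = str(rng.choice(["+", "-"]))
                add_candidate(exons, host.chrom, strand, "intronic", fate)
                return
        raise PlacementError("could not place an intronic candidate")

    def place_exonic(fate: str, same_strand: bool) -> None:
        for _ in range(200):
            host = host_refs[int(rng.integers(len(host_refs)))]
            ei = int(rng.integers(host.n_exons))
            a, b = host.exons[ei]
            s1 = a + (b - a) // 2  # strictly inside: no shared splice boundary
            e1 = b + int(rng.integers(120, 201))
            if fate == "fail_stage3":
                exons = ((s1, e1),)
            else:
                g = int(rng.integers(200, 401))
                l2 = int(rng.integers(150, 301))
                exons = ((s1, e1), (e1 + g + 1, e1 + g + l2))
            # stay inside the following intron (or past the gene end)
            if ei < host.n_exons - 1 and exons[-1][1] >= host.exons[ei + 1][0] - 50:
                continue
            if placer.free(host.chrom, exons[0][0], exons[-1][1]):
                strand = host.strand if same_strand else ("-" if host.strand == "+" else "+")
                add_candidate(exons, host.chrom, strand,
                              "sense" if same_strand else "antisense", fate)
                return
        raise PlacementError("could not place an exon-overlapping candidate")

    placers = {
        "intergenic": place_intergenic,
        "intronic": lambda f: place_intronic(f),
        "sense": lambda f: place_exonic(f, True),
        "antisense": lambda f: place_exonic(f, False),
    }
    for cls in POSITIONAL_CLASSES:
        fates = _fate_list(rng, scenario.n_candidates_per_class)
        for fate in fates:
            placers[cls](fate)

    # stage-1 failing candidates: exact intron-chain copies of template PCGs
    for gi in template_ids:
        host = refs[int(gi)]
        exons = list(host.exons)
        exons[0] = (max(1, exons[0][0] - int(rng.integers(0, 80))), exons[0][1])
        exons[-1] = (exons[-1][0], exons[-1][1] + int(rng.integers(0, 80)))
        cand_exons = tuple(exons)
        add_candidate(cand_exons, host.chrom, host.strand, "coding", "fail_stage1")

    cand_catalog = TranscriptCatalog(candidates)
    truth = pd.DataFrame(rows).set_index("transcript_id") if rows else pd.DataFrame(
        columns=["true_class", "filter_fate"]
    )

    # cis truth by direct O(n^2) gap scan
    cis_partners = []
    for t in candidates:
        partners = sorted(
            r.gene_id
            for r in reference.on_chrom(t.chrom)
            if interval_gap((t.start, t.end), (r.start, r.end)) <= scenario.cis_window_bases
        )
        cis_partners.append(",".join(partners))
    if len(truth):
        truth["cis_partners"] = cis_partners
    else:
        truth["cis_partners"] = pd.Series(dtype=str)
    return reference, cand_catalog, truth


# ---------------------------------------------------------------------------
# filter inputs
# ---------------------------------------------------------------------------

def generate_filter_inputs(
    scenario: SyntheticScenario, truth: pd.DataFrame
) -> Tuple[pd.DataFrame, pd.Series]:
    """Score and protein-hit tables realizing each candidate's filter fate.

    Every candidate gets a score row (score tables are dense); hit rows
    exist only for stage-2 failures and a random subset of weak,
    above-cutoff hits (hit tables are sparse).
    """
    rng = _rng(scenario.seed, 2)
    score_rows = {}
    hit_rows = {}
    for tid, row in truth.iterrows():
        fate = row["filter_fate"]
        cnci = rng.uniform(-3.0, -0.5)
        plek = rng.uniform(-2.0, -0.2)
        cpat = rng.uniform(0.01, 0.35)
        if fate == "fail_stage4":
            which = rng.choice(3, int(rng.integers(1, 4)), replace=False)
            if 0 in which:
                cnci = rng.uniform(0.5, 3.0)
            if 1 in which:
                plek = rng.uniform(0.2, 2.0)
            if 2 in which:
                cpat = rng.uniform(0.5, 0.95)
        score_rows[tid] = {"cnci": cnci, "plek": plek, "cpat": cpat}

        if fate == "fail_stage2":
            hit_rows[tid] = 10.0 ** rng.uniform(-30.0, -6.0)
        elif rng.random() < 0.5:
            hit_rows[tid] = 10.0 ** rng.uniform(-4.0, 1.0)

    scores = pd.DataFrame.from_dict(score_rows, orient="index")
    if not len(scores):
        scores = pd.DataFrame(columns=["cnci", "plek", "cpat"])
    scores = scores[["cnci", "plek", "cpat"]] if len(scores) else scores
    scores.index.name = "transcript_id"
    hits = pd.Series(hit_rows, dtype=float, name="best_evalue")
    hits.index.name = "transcript_id"
    return scores, hits


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def generate_expression(
    scenario: SyntheticScenario,
    transcripts: Union[pd.DataFrame, Sequence[str], Sequence[TranscriptModel]],
) -> ExpressionMatrix:
    """Log-normal FPKM matrix with planted effects.

    ``transcripts`` is either an expression plan (DataFrame indexed by id
    with columns ``is_de``, ``true_log2fc``, ``filter_fate`` and
    ``trans_pair``) or a plain id/transcript list, in which case all rows
    are null (no effect, no pairing). Log-FPKM is mu_t plus the group
    effect (true_log2fc * ln 2 on treated samples), plus a shared latent
    factor for members of a planted trans pair, plus N(0, noise_sd) noise.
    Stage-5-failing transcripts are zeroed in all but one sample.
    """
    if not isinstance(transcripts, pd.DataFrame):
        ids = [
            t.transcript_id if isinstance(t, TranscriptModel) else str(t)
            for t in transcripts
        ]
        transcripts = pd.DataFrame(
            {
                "is_de": False,
                "true_log2fc": 0.0,
                "filter_fate": "pass",
                "trans_pair": -1,
            },
            index=pd.Index(ids, name="transcript_id"),
        )
    plan = transcripts

    rng = _rng(scenario.seed, 3)
    n = scenario.n_samples_per_group
    samples = [f"Control_{i + 1}" for i in range(n)] + [f"H120_{i + 1}" for i in range(n)]
    groups = pd.Series(
        ["Control"] * n + ["H120"] * n, index=pd.Index(samples, name="sample"),
        name="group",
    )
    treated = np.array([0.0] * n + [1.0] * n)

    pair_ids = sorted({int(p) for p in plan.get("trans_pair", pd.Series(dtype=int)) if int(p) >= 0})
    latents = {p: rng.normal(0.0, TRANS_LATENT_SD, 2 * n) for p in pair_ids}

    data = np.zeros((len(plan), 2 * n))
    for i, (tid, row) in enumerate(plan.iterrows()):
        mu = rng.uniform(np.log(5.0), np.log(200.0))
        profile = np.full(2 * n, mu)
        pair = int(row.get("trans_pair", -1))
        if pair >= 0:
            profile = profile + latents[pair]
        profile = profile + float(row["true_log2fc"]) * LN2 * treated
        profile = profile + rng.normal(0.0, scenario.noise_sd, 2 * n)
        values = np.exp(profile)
        if row["filter_fate"] == "fail_stage5":
            keep = int(rng.integers(2 * n))
            mask = np.zeros(2 * n)
            mask[keep] = 1.0
            values = values * mask
        data[i] = values

    values = pd.DataFrame(data, index=plan.index.copy(), columns=samples)
    return ExpressionMatrix(values, groups)


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    return alphabet[rng.integers(0, 4, length)].tobytes().decode("ascii")


def generate_sequences(
    scenario: SyntheticScenario,
    candidates: TranscriptCatalog,
    reference: TranscriptCatalog,
    sim_pairs: Sequence[Tuple[str, str]],
) -> Tuple[Dict[str, str], Dict[str, str]]:
    """Random transcript sequences with planted 150-nt shared substrings.

    mRNA sequences are keyed by gene id (one transcript per gene in the
    synthetic genome). For each (lnc, gene) pair in ``sim_pairs`` a random
    150-mer of the mRNA is copied into the lncRNA sequence.
    """
    rng = _rng(scenario.seed, 4)
    mrna = {t.gene_id: _random_seq(rng, t.length) for t in reference}
    lnc = {t.transcript_id: _random_seq(rng, max(t.length, 200)) for t in candidates}
    for lnc_id, gene_id in sim_pairs:
        source = mrna[gene_id]
        frag_len = 150
        fs = int(rng.integers(0, len(source) - frag_len + 1))
        frag = source[fs : fs + frag_len]
        target = lnc[lnc_id]
        ts = int(rng.integers(0, len(target) - frag_len + 1))
        lnc[lnc_id] = target[:ts] + frag + target[ts + frag_len :]
    return lnc, mrna


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def generate_ct_table(
    log2fcs: Mapping[str, float],
    n_replicates: int = 3,
    seed: int = 0,
    noise_sd: float = 0.0,
    control: str = "Control",
    treatment: str = "H120",
    reference_ct: float = 18.0,
    base_ct: float = 26.0,
) -> pd.DataFrame:
    """Ct table constructed so the comparative-Ct method recovers ``log2fcs``.

    Treatment target Ct = base - log2fc (one cycle per doubling), so
    -ddCt equals the generating log2 fold change exactly when noise_sd=0.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 5]))
    rows = []
    for tid, lfc in log2fcs.items():
        for group in (control, treatment):
            target = base_ct - (lfc if group == treatment else 0.0)
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "transcript_id": tid,
                        "group": group,
                        "replicate": rep,
                        "ct_target": target + rng.normal(0.0, noise_sd),
                        "ct_reference": reference_ct + rng.normal(0.0, noise_sd),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def generate_scenario(scenario: SyntheticScenario) -> SyntheticDataset:
    """Generate the full dataset: genome, tables, expression, sequences, truth."""
    reference, candidates, truth = generate_genome_annotation(scenario)
    rng = _rng(scenario.seed, 6)

    positional = truth[truth["true_class"] != "coding"] if len(truth) else truth
    recoverable = (
        positional[positional["filter_fate"] != "fail_stage5"].index.tolist()
        if len(positional)
        else []
    )
    pass_ids = (
        positional[positional["filter_fate"] == "pass"].index.tolist()
        if len(positional)
        else []
    )

    gene_ids = [t.gene_id for t in reference]

    # trans pairs: pass-fate lncRNAs paired with distinct genes; the shared
    # latent factor acts as large per-sample variation, so pair members are
    # kept free of planted group effects to keep DE truth recoverable
    n_pairs = min(scenario.n_planted_trans_pairs, len(pass_ids), len(gene_ids))
    trans_lncs = [str(x) for x in rng.choice(pass_ids, n_pairs, replace=False)] if n_pairs else []
    trans_genes = [str(x) for x in rng.choice(gene_ids, n_pairs, replace=False)] if n_pairs else []

    # DE plants among candidates whose expression is recoverable
    de_pool = [i for i in recoverable if i not in set(trans_lncs)]
    n_de = min(int(round(scenario.de_fraction * len(positional))), len(de_pool))
    de_ids = [str(x) for x in rng.choice(de_pool, n_de, replace=False)] if n_de else []

    truth["is_de"] = truth.index.isin(de_ids)
    signs = {tid: (1.0 if rng.random() < 0.5 else -1.0) for tid in de_ids}
    truth["true_log2fc"] = [
        signs[tid] * scenario.planted_log2fc if tid in signs else 0.0
        for tid in truth.index
    ]
    truth["trans_pair"] = -1
    truth["trans_partners"] = ""
    for k, (lnc_id, gid) in enumerate(zip(trans_lncs, trans_genes)):
        truth.loc[lnc_id, "trans_pair"] = k
        truth.loc[lnc_id, "trans_partners"] = gid

    # similarity plants: pass-fate lncRNAs with embedded mRNA fragments
    n_sim = min(scenario.n_planted_similarity_pairs, len(pass_ids), len(gene_ids))
    sim_lncs = list(rng.choice(pass_ids, n_sim, replace=False)) if n_sim else []
    sim_genes = list(rng.choice(gene_ids, n_sim, replace=False)) if n_sim else []
    truth["sim_partners"] = ""
    for lnc_id, gid in zip(sim_lncs, sim_genes):
        truth.loc[lnc_id, "sim_partners"] = gid

    # expression plan: candidates plus gene-level rows for the reference;
    # trans-pair genes inherit the pair id and effect of their lncRNA
    gene_plan = pd.DataFrame(
        {
            "is_de": False,
            "true_log2fc": 0.0,
            "filter_fate": "reference",
            "trans_pair": -1,
        },
        index=pd.Index(gene_ids, name="transcript_id"),
    )
    for k, (lnc_id, gid) in enumerate(zip(trans_lncs, trans_genes)):
        gene_plan.loc[gid, "trans_pair"] = k
        gene_plan.loc[gid, "is_de"] = bool(truth.loc[lnc_id, "is_de"])
        gene_plan.loc[gid, "true_log2fc"] = float(truth.loc[lnc_id, "true_log2fc"])

    plan_cols = ["is_de", "true_log2fc", "filter_fate", "trans_pair"]
    plan = pd.concat([truth[plan_cols], gene_plan[plan_cols]]) if len(truth) else gene_plan
    expression = generate_expression(scenario, plan)

    scores, hits = generate_filter_inputs(scenario, truth)
    lnc_seqs, mrna_seqs = generate_sequences(
        scenario, candidates, reference, list(zip(sim_lncs, sim_genes))
    )

    return SyntheticDataset(
        scenario=scenario,
        reference=reference,
        candidates=candidates,
        scores=scores,
        hits=hits,
        expression=expression,
        truth=truth,
        lnc_sequences=lnc_seqs,
        mrna_sequences=mrna_seqs,
    )


def generate_trans_experiment(
    seed: int,
    n_lnc: int = 50,
    n_gene: int = 50,
    n_pairs: int = 5,
    noise_sd: float = 0.001,
    n_samples_per_group: int = 10,
) -> Tuple[pd.DataFrame, pd.DataFrame, List[Tuple[str, str]]]:
    """Co-expression recovery experiment: planted latent-factor pairs.

    Returns lncRNA and gene FPKM frames over shared samples plus the list
    of planted (lnc, gene) pairs; non-planted rows are independent noise,
    so only planted pairs approach |PCC| = 1.

    The default uses 10 samples per group rather than the emulated study's
    3: the null distribution of a Pearson correlation over n samples has
    density proportional to (1-r^2)^((n-4)/2), so with n = 6 an
    unstructured pair crosses |r| > 0.99 with probability ~1.5e-4 and a
    50 x 50 screen expects ~0.4 background pairs (the real study likewise
    saw thousands of pairs above 0.99 among millions). At n = 20 the
    crossing probability is < 1e-12, making exact planted-set recovery a
    meaningful check of the thresholding machinery.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    n_samples = 2 * n_samples_per_group
    samples = [f"Control_{i + 1}" for i in range(n_samples_per_group)] + [
        f"H120_{i + 1}" for i in range(n_samples_per_group)
    ]
    lnc_ids = [f"LNC_{i:04d}" for i in range(n_lnc)]
    gene_ids = [f"GENE_{i:04d}" for i in range(n_gene)]
    pairs = [(lnc_ids[k], gene_ids[k]) for k in range(n_pairs)]

    def matrix(ids, pair_slot):
        data = np.zeros((len(ids), n_samples))
        for i, _ in enumerate(ids):
            mu = rng.uniform(np.log(5.0), np.log(200.0))
            profile = np.full(n_samples, mu)
            if i < n_pairs and pair_slot[i] is not None:
                profile = profile + pair_slot[i]
            profile = profile + rng.normal(0.0, noise_sd, n_samples)
            data[i] = np.exp(profile)
        return pd.DataFrame(data, index=ids, columns=samples)

    latents = [rng.normal(0.0, TRANS_LATENT_SD, n_samples) for _ in range(n_pairs)]
    lnc = matrix(lnc_ids, latents + [None] * (n_lnc - n_pairs))
    gene = matrix(gene_ids, latents + [None] * (n_gene - n_pairs))
    return lnc, gene, pairs
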