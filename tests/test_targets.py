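import numpy as np
import pandas as pd
import pytest

from oracle_utils import (
    oracle_cis_pairs,
    oracle_local_alignment_score,
    oracle_pearson,
    random_catalog,
)

from lncforge import targets as tg
from lncforge.models import TranscriptCatalog, TranscriptModel

SAMPLES = [f"s{i}" for i in range(6)]


def frame(rows):
    return pd.DataFrame(rows, columns=SAMPLES).astype(float)


class TestTrans:
    def test_identical_profile_positive_pair(self):
        lnc = pd.DataFrame([[1, 2, 3, 4, 5, 6]], index=["l"], columns=SAMPLES, dtype=float)
        gene = pd.DataFrame([[1, 2, 3, 4, 5, 6]], index=["g"], columns=SAMPLES, dtype=float)
        pairs, _ = tg.trans_targets(lnc, gene)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.sign == "positive" and p.score == pytest.approx(1.0)

    def test_anticorrelated_profile_negative_pair(self):
        lnc = pd.DataFrame([[1, 2, 3, 4, 5, 6]], index=["l"], columns=SAMPLES, dtype=float)
        gene = pd.DataFrame([[6, 5, 4, 3, 2, 1]], index=["g"], columns=SAMPLES, dtype=float)
        pairs, _ = tg.trans_targets(lnc, gene)
        assert pairs[0].sign == "negative"
        assert pairs[0].score == pytest.approx(-1.0)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.lognormal(1, 1, 6)
        lnc = pd.DataFrame([x], index=["l"], columns=SAMPLES)
        gene = pd.DataFrame([3.5 * x + 2.0], index=["g"], columns=SAMPLES)
        pairs, _ = tg.trans_targets(lnc, gene)
        assert pairs[0].score == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_rows_excluded_with_tally(self):
        lnc = pd.DataFrame([[2, 2, 2, 2, 2, 2], [1, 2, 3, 4, 5, 6]],
                           index=["flat", "l"], columns=SAMPLES, dtype=float)
        gene = pd.DataFrame([[1, 2, 3, 4, 5, 6]], index=["g"], columns=SAMPLES, dtype=float)
        pairs, summary = tg.trans_targets(lnc, gene)
        assert {p.lnc_id for p in pairs} == {"l"}
        assert summary.n_excluded == 1
        assert summary.n_total == 1

    def test_summary_partition_and_fractions(self):
        rng = np.random.default_rng(8)
        lnc = pd.DataFrame(rng.lognormal(1, 1, (12, 6)),
                           index=[f"l{i}" for i in range(12)], columns=SAMPLES)
        gene = pd.DataFrame(rng.lognormal(1, 1, (15, 6)),
                            index=[f"g{i}" for i in range(15)], columns=SAMPLES)
        _, summary = tg.trans_targets(lnc, gene)
        assert summary.n_total == 12 * 15
        assert summary.bin_counts.sum() == summary.n_total
        assert summary.bin_fractions.sum() == pytest.approx(1.0)
        assert summary.n_positive + summary.n_negative + summary.n_zero == summary.n_total

    def test_mismatched_samples_rejected(self):
        lnc = pd.DataFrame([[1, 2]], index=["l"], columns=["a", "b"])
        gene = pd.DataFrame([[1, 2]], index=["g"], columns=["a", "c"])
        with pytest.raises(ValueError, match="sample"):
            tg.trans_targets(lnc, gene)


class TestDegreeCategories:
    def test_fifty_seven_targets_fall_in_51_60_bucket(self):
        pairs = [tg.TargetPair("lnc1", f"g{i}", "trans", 0.995, "positive")
                 for i in range(57)]
        table = tg.degree_categories(pairs).table
        assert table.loc["51-60", "n_lncrna"] == 1
        assert table.loc["51-60", "n_genes"] == 57
        assert table.drop("51-60").values.sum() == 0

    def test_empty_pairs_all_zero(self):
        assert (tg.degree_categories([]).table.values == 0).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_degree_conservation_random_bipartite(self, seed):
        rng = np.random.default_rng(seed)
        pairs = []
        seen = set()
        for _ in range(int(rng.integers(0, 200))):
            edge = (f"l{rng.integers(0, 10)}", f"g{rng.integers(0, 150)}")
            if edge not in seen:
                seen.add(edge)
                pairs.append(tg.TargetPair(edge[0], edge[1], "trans", 1.0, "positive"))
        table = tg.degree_categories(pairs).table
        assert table["n_lncrna"].sum() == len({p.lnc_id for p in pairs})
        # sum of bucketed degrees equals the number of pairs
        degrees = {}
        for p in pairs:
            degrees[p.lnc_id] = degrees.get(p.lnc_id, 0) + 1
        assert sum(degrees.values()) == len(pairs)


def mk(tid, exons, chrom="chr1", strand="+", biotype="candidate"):
    return TranscriptModel(tid, f"g_{tid}", chrom, strand, tuple(exons), biotype)


class TestCis:
    def test_window_boundary_inclusive(self):
        lnc = TranscriptCatalog([mk("l", [(500, 1000)])])
        inside = TranscriptCatalog([mk("gin", [(101_001, 102_000)], biotype="coding")])
        outside = TranscriptCatalog([mk("gout", [(101_002, 102_000)], biotype="coding")])
        hit = tg.cis_targets(lnc, inside)
        assert [(p.lnc_id, p.gene_id, p.score) for p in hit] == [("l", "g_gin", 100_000.0)]
        assert tg.cis_targets(lnc, outside) == []

    def test_overlap_is_gap_zero(self):
        lnc = TranscriptCatalog([mk("l", [(500, 1000)])])
        gene = TranscriptCatalog([mk("g", [(900, 2000)], biotype="coding")])
        (p,) = tg.cis_targets(lnc, gene)
        assert p.score == 0.0

    def test_different_chromosome_never_pairs(self):
        lnc = TranscriptCatalog([mk("l", [(500, 1000)])])
        gene = TranscriptCatalog([mk("g", [(1100, 2000)], chrom="chr2", biotype="coding")])
        assert tg.cis_targets(lnc, gene) == []

    def test_translation_invariance(self):
        rng = np.random.default_rng(2)
        lncs = random_catalog(rng, 20, "L")
        genes = random_catalog(rng, 20, "G", biotype="coding")
        a = tg.cis_targets(TranscriptCatalog(lncs), TranscriptCatalog(genes), 10_000)
        b = tg.cis_targets(
            TranscriptCatalog([t.shifted(977) for t in lncs]),
            TranscriptCatalog([t.shifted(977) for t in genes]),
            10_000,
        )
        assert {(p.lnc_id, p.gene_id, p.score) for p in a} == {
            (p.lnc_id, p.gene_id, p.score) for p in b
        }

    @pytest.mark.parametrize("seed", [1, 6, 11])
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        lncs = random_catalog(rng, 40, "L", span=500_000)
        genes = random_catalog(rng, 40, "G", biotype="coding", span=500_000)
        got = tg.cis_targets(TranscriptCatalog(lncs), TranscriptCatalog(genes), 50_000)
        want = oracle_cis_pairs(lncs, genes, 50_000)
        assert {(p.lnc_id, p.gene_id) for p in got} == want


class TestSimilarity:
    def test_exact_shared_substring_reported_identity_one(self):
        rng = np.random.default_rng(7)
        core = "".join(rng.choice(list("AC"), 150))
        lnc = {"l": "T" * 60 + core + "T" * 60}
        mrna = {"g": "G" * 60 + core + "G" * 60}
        pairs = tg.similarity_targets(lnc, mrna)
        assert [(p.lnc_id, p.gene_id) for p in pairs] == [("l", "g")]
        assert pairs[0].score == pytest.approx(150.0)

    def test_random_unrelated_sequences_not_reported(self):
        rng = np.random.default_rng(13)
        alphabet = list("ACGT")
        for _ in range(100):
            a = "".join(rng.choice(alphabet, 500))
            b = "".join(rng.choice(alphabet, 500))
            assert tg.similarity_targets({"l": a}, {"g": b}) == []

    def test_empty_sequence_skipped(self, caplog):
        with caplog.at_level("WARNING"):
            assert tg.similarity_targets({"l": ""}, {"g": "ACGT"}) == []
        assert "l" in caplog.text

    @pytest.mark.parametrize("seed", range(12))
    def test_aligner_score_matches_exhaustive_oracle(self, seed):
        """SW score equals the max over all monotone matchings (n <= 8)."""
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(2, 9)), int(rng.integers(2, 9))
        a = "".join(rng.choice(list("ACGT"), n))
        b = "".join(rng.choice(list("ACGT"), m))
        aligner = tg.make_aligner(tg.SimilarityParams())
        got = float(aligner.align(a, b).score)
        assert got == pytest.approx(oracle_local_alignment_score(a, b))

    def test_planted_scenario_pairs_recovered(self, default_dataset):
        ds = default_dataset
        planted = ds.truth[ds.truth.sim_partners != ""]
        lnc_seqs = {tid: ds.lnc_sequences[tid] for tid in planted.index}
        mrna_seqs = {g: ds.mrna_sequences[g] for g in planted.sim_partners}
        got = {(p.lnc_id, p.gene_id) for p in tg.similarity_targets(lnc_seqs, mrna_seqs)}
        assert got == set(zip(planted.index, planted.sim_partners))
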