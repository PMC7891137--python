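import numpy as np
import pandas as pd
import pytest

from lncforge import filters as fl
from lncforge.io import SchemaError
from lncforge.models import ExpressionMatrix, TranscriptCatalog, TranscriptModel


def mk(tid, exons, strand="+", chrom="chr1", biotype="candidate"):
    return TranscriptModel(tid, f"g_{tid}", chrom, strand, tuple(exons), biotype)


REF = TranscriptCatalog(
    [mk("ref1", [(1000, 1500), (2000, 2500), (3000, 3600)], biotype="coding")]
)


class TestKnownCoding:
    def test_identical_intron_chain_removed(self):
        cand = mk("c1", [(900, 1500), (2000, 2500), (3000, 3700)])
        retained, removed = fl.filter_known_coding([cand], REF)
        assert [t.transcript_id for t in removed] == ["c1"]

    def test_opposite_strand_copy_retained(self):
        cand = mk("c1", [(900, 1500), (2000, 2500), (3000, 3700)], strand="-")
        retained, _ = fl.filter_known_coding([cand], REF)
        assert len(retained) == 1

    def test_contained_fragment_with_shared_splice_boundary_removed(self):
        # mono-exon candidate inside ref exon, right end on the splice site
        cand = mk("c1", [(2100, 2500)])
        _, removed = fl.filter_known_coding([cand], REF)
        assert len(removed) == 1
        # contiguous sub-chain fragment
        cand2 = mk("c2", [(1200, 1500), (2000, 2500), (3000, 3300)])
        _, removed2 = fl.filter_known_coding([cand2], REF)
        assert len(removed2) == 1

    def test_contained_without_shared_boundary_retained(self):
        cand = mk("c1", [(2100, 2400)])  # strictly inside the exon
        retained, _ = fl.filter_known_coding([cand], REF)
        assert len(retained) == 1

    def test_partial_exon_overlap_retained(self):
        # sense-style overlap crossing the exon boundary survives stage 1
        cand = mk("c1", [(2300, 2700), (2900, 2950)])
        retained, _ = fl.filter_known_coding([cand], REF)
        assert len(retained) == 1

    def test_chromosome_absent_from_reference_retained(self):
        cand = mk("c1", [(100, 400), (600, 900)], chrom="chrX")
        retained, _ = fl.filter_known_coding([cand], REF)
        assert len(retained) == 1


class TestProteinSimilarity:
    @pytest.mark.parametrize(
        "evalue,removed", [(1e-6, True), (1e-5, True), (1e-4, False)]
    )
    def test_cutoff_boundary(self, evalue, removed):
        cand = mk("c1", [(1, 300), (500, 800)])
        hits = pd.Series({"c1": evalue})
        retained, gone = fl.filter_protein_similarity([cand], hits)
        assert (len(gone) == 1) is removed

    def test_absent_from_hit_table_retained(self):
        cand = mk("c1", [(1, 300), (500, 800)])
        retained, _ = fl.filter_protein_similarity([cand], pd.Series(dtype=float))
        assert len(retained) == 1


class TestStructure:
    @pytest.mark.parametrize(
        "exons,removed",
        [
            ([(1, 100), (200, 250), (300, 347)], True),   # length 199, 3 exons
            ([(1, 100), (200, 299)], False),              # length 200, 2 exons
            ([(1, 5000)], True),                          # single exon, long
        ],
        ids=["len199", "len200", "mono-exon"],
    )
    def test_boundaries(self, exons, removed):
        retained, gone = fl.filter_structure([mk("c1", exons)])
        assert (len(gone) == 1) is removed


class TestCodingPotential:
    @pytest.mark.parametrize(
        "cnci,plek,cpat,kept",
        [(-1, -1, 0.1, True), (-1, -1, 0.44, False), (0.0, -1, 0.1, False),
         (-1, 0.0, 0.1, False)],
    )
    def test_strict_thresholds(self, cnci, plek, cpat, kept):
        cand = mk("c1", [(1, 300), (500, 800)])
        scores = pd.DataFrame({"cnci": [cnci], "plek": [plek], "cpat": [cpat]},
                              index=["c1"])
        retained, _ = fl.filter_coding_potential([cand], scores)
        assert (len(retained) == 1) is kept

    def test_missing_score_row_is_hard_error(self):
        cand = mk("c1", [(1, 300), (500, 800)])
        scores = pd.DataFrame(columns=["cnci", "plek", "cpat"])
        with pytest.raises(SchemaError, match="c1"):
            fl.filter_coding_potential([cand], scores)

    def test_retained_equals_three_way_venn_intersection(self):
        """Consensus call == brute-force intersection of the three pass sets."""
        rng = np.random.default_rng(9)
        ids = [f"t{i}" for i in range(200)]
        scores = pd.DataFrame(
            {
                "cnci": rng.uniform(-2, 2, 200),
                "plek": rng.uniform(-2, 2, 200),
                "cpat": rng.uniform(0, 1, 200),
            },
            index=ids,
        )
        cands = [mk(i, [(1, 300), (500, 800)]) for i in ids]
        retained, _ = fl.filter_coding_potential(cands, scores)
        venn = (
            {i for i in ids if scores.loc[i, "cnci"] < 0}
            & {i for i in ids if scores.loc[i, "plek"] < 0}
            & {i for i in ids if scores.loc[i, "cpat"] < 0.44}
        )
        assert {t.transcript_id for t in retained} == venn


def _expr(rows):
    values = pd.DataFrame(rows).T
    values.columns = [f"Control_{i}" for i in (1, 2, 3)] + [f"H120_{i}" for i in (1, 2, 3)]
    groups = pd.Series(
        ["Control"] * 3 + ["H120"] * 3, index=values.columns, name="group"
    )
    return ExpressionMatrix(values, groups)


class TestMinSamples:
    def test_detection_count_boundary(self):
        expr = _expr({"a": [0, 0, 0, 0, 0, 3], "b": [0, 0, 1, 0, 0, 3],
                      "c": [0, 0, 0, 0, 0, 0]})
        cands = [mk(i, [(1, 300), (500, 800)]) for i in "abc"]
        retained, removed = fl.filter_min_samples(cands, expr)
        assert {t.transcript_id for t in retained} == {"b"}
        assert {t.transcript_id for t in removed} == {"a", "c"}

    def test_missing_row_removed_with_warning(self, caplog):
        expr = _expr({"a": [1, 1, 1, 1, 1, 1]})
        cands = [mk("zz", [(1, 300), (500, 800)])]
        with caplog.at_level("WARNING"):
            retained, removed = fl.filter_min_samples(cands, expr)
        assert len(removed) == 1 and "zz" in caplog.text


class TestCascade:
    def test_empty_candidates_all_zero_report(self, default_dataset):
        ds = default_dataset
        report, retained = fl.run_cascade(
            [], ds.reference, ds.hits, ds.scores, ds.expression
        )
        assert retained == []
        assert all(s.n_in == 0 and s.n_removed == 0 for s in report.stages)

    def test_truth_recovery_and_accounting(self, default_dataset):
        """Each stage removes exactly its planted fate; report chains consistently."""
        ds = default_dataset
        report, retained = fl.run_cascade(
            list(ds.candidates), ds.reference, ds.hits, ds.scores, ds.expression
        )
        fates = ds.truth["filter_fate"].value_counts()
        for stage, fate in zip(report.stages, [f"fail_stage{i}" for i in range(1, 6)]):
            assert stage.n_removed == fates.get(fate, 0)
        assert set(report.final_ids) == set(ds.truth[ds.truth.filter_fate == "pass"].index)
        # monotone attrition and count conservation
        for prev, nxt in zip(report.stages, report.stages[1:]):
            assert nxt.n_in == prev.n_retained
            assert nxt.n_retained <= prev.n_retained
        for s in report.stages:
            assert s.n_removed + s.n_retained == s.n_in

    def test_stage_predicates_order_invariant(self, default_dataset):
        """Stages 2-5 are per-transcript predicates: input order never matters."""
        ds = default_dataset
        cands = list(ds.candidates)
        rng = np.random.default_rng(0)
        shuffled = [cands[i] for i in rng.permutation(len(cands))]
        r1, _ = fl.run_cascade(cands, ds.reference, ds.hits, ds.scores, ds.expression)
        r2, _ = fl.run_cascade(shuffled, ds.reference, ds.hits, ds.scores, ds.expression)
        assert set(r1.final_ids) == set(r2.final_ids)
        assert [s.n_removed for s in r1.stages] == [s.n_removed for s in r2.stages]
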