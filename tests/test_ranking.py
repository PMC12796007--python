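"""Phenopacket ingestion, ranking, recall@k, subset and augmentation evaluation."""

import json

import numpy as np
import pytest

from phenoaudit import synthetic as syn
from phenoaudit.kb import AnnotationKB, Annotation
from phenoaudit.ontology import build_corpus, information_content
from phenoaudit.ranking import (
    PatientCase,
    RankedList,
    augmentation_experiment,
    ingest_external_ranking,
    rank_by_similarity,
    read_phenopackets,
    recall_at_k,
    subset_evaluation,
)


def packet(case_id, features, truth, excluded=()):
    return {
        "id": case_id,
        "phenotypicFeatures": [
            {"type": {"id": t}, "excluded": t in excluded} for t in features
        ],
        "diseases": [{"term": {"id": truth}}],
    }


class TestReadPhenopackets:
    def test_excluded_features_dropped(self, tmp_path):
        doc = packet("c1", ["TT:0000002", "TT:0000003", "TT:0000004"], "DZ:0000001",
                     excluded={"TT:0000004"})
        (tmp_path / "c1.json").write_text(json.dumps(doc))
        cases, skipped = read_phenopackets(tmp_path)
        assert skipped == 0
        assert cases[0].observed == {"TT:0000002", "TT:0000003"}

    def test_missing_disease_block_skipped(self, tmp_path):
        doc = {"id": "c2", "phenotypicFeatures": [{"type": {"id": "TT:0000002"}}]}
        (tmp_path / "c2.json").write_text(json.dumps(doc))
        (tmp_path / "bad.json").write_text("{not json")
        cases, skipped = read_phenopackets(tmp_path)
        assert cases == [] and skipped == 2

    def test_interpretation_fallback(self, tmp_path):
        doc = {
            "id": "c3",
            "phenotypicFeatures": [{"type": {"id": "TT:0000002"}}],
            "interpretations": [
                {"diagnosis": {"disease": {"id": "OMIM:100000"}}}
            ],
        }
        (tmp_path / "c3.json").write_text(json.dumps(doc))
        cases, _ = read_phenopackets(tmp_path)
        assert cases[0].truth == "OMIM:100000"

    def test_synthetic_roundtrip(self, tmp_path):
        spec = syn.SyntheticSpec(seed=4, n_terms=60, n_diseases=10)
        graph = syn.generate_ontology(spec)
        kb, _ = syn.generate_reference_kb(spec, graph)
        noise = syn.PatientNoiseSpec(n_per_disease=2)
        syn.generate_patients(kb, graph, noise, seed=4, out_dir=tmp_path)
        cases, skipped = read_phenopackets(tmp_path)
        assert skipped == 0
        assert len(cases) == 20
        assert {c.truth for c in cases} == kb.diseases()


@pytest.fixture
def ranked_fixture(random_dag_with_ic):
    graph, ic = random_dag_with_ic
    terms = graph.active_terms()
    kb = AnnotationKB(name="ref")
    for i, start in enumerate((4, 10, 16, 22), start=1):
        for t in terms[start : start + 4]:
            kb.add(f"DZ:{i:07d}", Annotation(t))
    return graph, ic, kb


class TestRankBySimilarity:
    def test_self_retrieval(self, ranked_fixture):
        graph, ic, kb = ranked_fixture
        case = PatientCase("c1", frozenset(kb.terms("DZ:0000002")), "DZ:0000002")
        ranked = rank_by_similarity(kb, graph, ic, case)
        assert ranked.entries[0][0] == "DZ:0000002"

    def test_singleton_kb(self, ranked_fixture):
        graph, ic, kb = ranked_fixture
        from phenoaudit.kb import restrict_to_diseases

        solo = restrict_to_diseases(kb, {"DZ:0000001"})
        case = PatientCase("c1", frozenset(kb.terms("DZ:0000003")), "DZ:0000003")
        assert len(rank_by_similarity(solo, graph, ic, case).entries) == 1

    def test_scores_non_increasing_and_cap(self, ranked_fixture):
        graph, ic, kb = ranked_fixture
        case = PatientCase("c1", frozenset(kb.terms("DZ:0000001")), "DZ:0000001")
        ranked = rank_by_similarity(kb, graph, ic, case, cap=3)
        scores = [s for _, s in ranked.entries]
        assert scores == sorted(scores, reverse=True)
        assert len(ranked.entries) == 3


class TestIngestExternal:
    TSV = "case_id\tdisease_id\tscore\n" + "\n".join(
        f"c1\tOMIM:{100000 + i}\t{1.0 - i / 20:.3f}" for i in range(15)
    )

    def test_cap_trims_rows(self):
        lists = ingest_external_ranking(self.TSV, cap=10)
        assert len(lists) == 1 and len(lists[0].entries) == 10
        assert lists[0].entries[0][0] == "OMIM:100000"

    def test_column_profile_remap(self):
        tsv = "case\tdz\ts\nc1\tORPHA:1\t0.5\n"
        lists = ingest_external_ranking(
            tsv, column_profile={"case_id": "case", "disease_id": "dz", "score": "s"}
        )
        assert lists[0].entries == [("ORPHA:1", 0.5)]

    def test_missing_column_fails(self):
        with pytest.raises(ValueError, match="score"):
            ingest_external_ranking("case_id\tdisease_id\nc1\tORPHA:1\n")

    def test_empty_file(self):
        assert ingest_external_ranking("") == []


class TestRecallAtK:
    def cases_and_results(self):
        cases = [PatientCase(f"c{i}", frozenset({"TT:0000002"}), "DZ:0000001") for i in range(4)]
        entries = [("DZ:0000009", 9.0)] * 6 + [("DZ:0000001", 1.0)]
        results = [RankedList(c.case_id, list(entries)) for c in cases]
        return cases, results

    def test_rank7_threshold(self):
        cases, results = self.cases_and_results()
        assert recall_at_k(results, cases, 10) == 1.0
        assert recall_at_k(results, cases, 5) == 0.0

    def test_non_decreasing_in_k(self):
        cases, results = self.cases_and_results()
        values = [recall_at_k(results, cases, k) for k in range(1, 11)]
        assert values == sorted(values)

    def test_broader_matching(self):
        case = PatientCase("c1", frozenset({"TT:0000002"}), "DZ:0000042")
        results = [RankedList("c1", [("GRP:0000001", 1.0)])]
        bmap = {"GRP:0000001": {"DZ:0000042", "DZ:0000043"}}
        assert recall_at_k(results, [case], 1, mode="exact", broader=bmap) == 0.0
        assert recall_at_k(results, [case], 1, mode="broader", broader=bmap) == 1.0

    def test_broader_never_below_exact(self):
        rng = np.random.default_rng(5)
        cases = [
            PatientCase(f"c{i}", frozenset({"TT:0000002"}), f"DZ:{int(rng.integers(1, 6)):07d}")
            for i in range(20)
        ]
        results = [
            RankedList(
                c.case_id,
                [(f"DZ:{int(rng.integers(1, 8)):07d}", 1.0 - j / 10) for j in range(5)],
            )
            for c in cases
        ]
        bmap = {"DZ:0000007": {"DZ:0000001", "DZ:0000002"}}
        for k in (1, 3, 5):
            assert recall_at_k(results, cases, k, mode="broader", broader=bmap) >= recall_at_k(
                results, cases, k, mode="exact"
            )

    def test_equivalent_ids_count_as_hits(self):
        case = PatientCase("c1", frozenset({"TT:0000002"}), "OMIM:100000")
        results = [RankedList("c1", [("ORPHA:558", 1.0)])]
        eq = {"OMIM:100000": {"ORPHA:558"}}
        assert recall_at_k(results, [case], 1, equivalents=eq) == 1.0

    def test_case_without_result_is_miss(self):
        case = PatientCase("orphan", frozenset({"TT:0000002"}), "DZ:0000001")
        assert recall_at_k([], [case], 1) == 0.0


class TestSubsetEvaluation:
    def test_model_specific_and_common_subsets(self, ranked_fixture):
        graph, ic, kb = ranked_fixture
        from phenoaudit.kb import restrict_to_diseases

        half = restrict_to_diseases(kb, {"DZ:0000001", "DZ:0000002"})
        cases = [
            PatientCase(f"case-{d}", frozenset(kb.terms(d)), d) for d in sorted(kb.diseases())
        ]
        reports = subset_evaluation({"full": kb, "half": half}, cases, graph, ic)
        assert reports["full"]["coverage"]["model_specific_cases"] == 4
        assert reports["half"]["coverage"]["model_specific_cases"] == 2
        # common subset = coverage intersection = half's coverage
        assert reports["full"]["coverage"]["common_cases"] == 2
        assert reports["half"]["model_specific"]["recall@1"] == 1.0

    def test_disjoint_coverage_empty_common(self, ranked_fixture):
        graph, ic, kb = ranked_fixture
        from phenoaudit.kb import restrict_to_diseases

        a = restrict_to_diseases(kb, {"DZ:0000001"})
        b = restrict_to_diseases(kb, {"DZ:0000002"})
        cases = [PatientCase("c1", frozenset(kb.terms("DZ:0000001")), "DZ:0000001")]
        reports = subset_evaluation({"a": a, "b": b}, cases, graph, ic)
        assert reports["a"]["notice"] == "common subset is empty"


class TestAugmentation:
    def test_empty_additions_zero_delta(self, ranked_fixture):
        graph, ic, kb = ranked_fixture
        cases = [
            PatientCase(f"case-{d}", frozenset(kb.terms(d)), d) for d in sorted(kb.diseases())
        ]
        report = augmentation_experiment(kb, {}, cases, graph, ic)
        for subset in report["delta"].values():
            assert all(v == 0.0 for v in subset.values())

    def test_restoring_dropped_terms_non_negative_delta(self, ranked_fixture):
        """Completing truncated profiles never hurts top-rank retrieval."""
        graph, ic, kb = ranked_fixture
        truncated = AnnotationKB(name="truncated")
        dropped: dict[str, set[str]] = {}
        for d in kb.diseases():
            terms = sorted(kb.terms(d))
            for t in terms[:2]:
                truncated.add(d, Annotation(t))
            dropped[d] = set(terms[2:])
        cases = [
            PatientCase(f"case-{d}", frozenset(kb.terms(d)), d) for d in sorted(kb.diseases())
        ]
        report = augmentation_experiment(truncated, dropped, cases, graph, ic)
        assert report["delta"]["model_specific"]["recall@1"] >= 0.0
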