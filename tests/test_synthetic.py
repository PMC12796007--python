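"""Synthetic-data generator: determinism, round trips, planted parameters."""

import io

import networkx as nx
import numpy as np
import pytest

from phenoaudit import synthetic as syn
from phenoaudit.assessors import MockAssessor, VotePanel
from phenoaudit.novelty import AbstractDoc, EvidenceStatus, assess_evidence
from phenoaudit.ontology import load_ontology


class TestGenerateOntology:
    def test_single_root_and_depth(self):
        spec = syn.SyntheticSpec(seed=3, n_terms=50, n_diseases=5)
        graph = syn.generate_ontology(spec)
        assert len(graph.roots) == 1
        assert nx.dag_longest_path_length(graph.graph) >= 4

    def test_tiny_ontology(self):
        spec = syn.SyntheticSpec(seed=3, n_terms=3, n_diseases=1)
        graph = syn.generate_ontology(spec)
        assert len(graph) == 3 and len(graph.roots) == 1

    def test_deterministic_obo_bytes(self):
        spec = syn.SyntheticSpec(seed=8, n_terms=40, n_diseases=5)
        obo1 = syn.ontology_to_obo(syn.generate_ontology(spec))
        obo2 = syn.ontology_to_obo(syn.generate_ontology(spec))
        assert obo1 == obo2

    def test_obo_roundtrip(self):
        spec = syn.SyntheticSpec(seed=8, n_terms=50, n_diseases=5)
        graph = syn.generate_ontology(spec)
        reloaded = load_ontology(io.StringIO(syn.ontology_to_obo(graph)))
        assert set(reloaded.terms) == set(graph.terms)
        assert set(reloaded.graph.edges) == set(graph.graph.edges)
        for t in graph.terms:
            assert reloaded.terms[t].synonyms == graph.terms[t].synonyms


class TestGenerateReferenceKb:
    def test_profile_size_mean(self):
        """Empirical mean profile size tracks the log-normal target."""
        sizes = []
        for seed in range(30):
            spec = syn.SyntheticSpec(
                seed=seed, n_terms=80, n_diseases=10, profile_mean=6.0,
                profile_min=2, profile_max=20,
            )
            graph = syn.generate_ontology(spec)
            kb, _ = syn.generate_reference_kb(spec, graph)
            sizes.extend(len(v) for v in kb.annotations.values())
        assert 4.0 <= np.mean(sizes) <= 8.0

    def test_degenerate_clip(self):
        spec = syn.SyntheticSpec(seed=2, n_terms=60, n_diseases=8,
                                 profile_min=5, profile_max=5)
        graph = syn.generate_ontology(spec)
        kb, _ = syn.generate_reference_kb(spec, graph)
        assert all(len(v) == 5 for v in kb.annotations.values())

    def test_deterministic_and_gene_counts(self):
        spec = syn.SyntheticSpec(seed=5, n_terms=60, n_diseases=8)
        graph = syn.generate_ontology(spec)
        kb1, genes1 = syn.generate_reference_kb(spec, graph)
        kb2, genes2 = syn.generate_reference_kb(spec, graph)
        assert kb1.triples() == kb2.triples()
        assert genes1.genes == genes2.genes
        assert all(1 <= len(v) <= 3 for v in genes1.genes.values())


class TestCorruptProfile:
    @pytest.fixture
    def graph_and_profile(self):
        spec = syn.SyntheticSpec(seed=6, n_terms=80, n_diseases=10)
        graph = syn.generate_ontology(spec)
        kb, _ = syn.generate_reference_kb(spec, graph)
        disease = sorted(kb.annotations)[0]
        return graph, kb.terms(disease)

    def test_identity_corruption(self, graph_and_profile):
        graph, profile = graph_and_profile
        cp = syn.corrupt_profile(
            profile, graph,
            syn.CorruptionSpec(dropout_keep=1.0, ancestor_sub_rate=0.0, hallucination_rate=0.0),
            seed=1,
        )
        assert cp.kept == frozenset(profile)
        assert not cp.substituted and not cp.hallucinated
        assert len(cp.lines) == len(profile)

    def test_total_dropout_leaves_only_hallucinations(self, graph_and_profile):
        graph, profile = graph_and_profile
        cp = syn.corrupt_profile(
            profile, graph,
            syn.CorruptionSpec(dropout_keep=0.0, ancestor_sub_rate=0.0, hallucination_rate=0.3),
            seed=1,
        )
        assert not cp.kept and not cp.substituted
        assert len(cp.hallucinated) == len(cp.lines) > 0

    def test_binomial_retention_mean(self, graph_and_profile):
        """Mean retained-term count over repeated corruptions matches n·keep."""
        graph, _ = graph_and_profile
        non_root = [t for t in graph.active_terms() if t not in graph.roots]
        profiles = [non_root[i * 10 : (i + 1) * 10] for i in range(5)]
        corruption = syn.CorruptionSpec(dropout_keep=0.5, ancestor_sub_rate=0.0,
                                        hallucination_rate=0.0)
        retained = [
            len(syn.corrupt_profile(profile, graph, corruption, seed=s * 5 + j).kept)
            for s in range(200)
            for j, profile in enumerate(profiles)
        ]
        assert np.mean(retained) == pytest.approx(5.0, abs=0.2)

    def test_hallucinations_are_novelty_positive(self, graph_and_profile):
        from phenoaudit.novelty import detect_novel_terms

        graph, profile = graph_and_profile
        cp = syn.corrupt_profile(
            profile, graph,
            syn.CorruptionSpec(dropout_keep=0.5, ancestor_sub_rate=0.2, hallucination_rate=0.4),
            seed=2,
        )
        assert cp.hallucinated <= detect_novel_terms(cp.output_terms, profile, graph)


class TestCandidateGenes:
    POOL = [f"GENE{i:04d}" for i in range(1, 201)]

    def test_perfect_truth(self):
        truth = {"GENE0001", "GENE0002"}
        out = syn.generate_candidate_genes(truth, syn.GeneTruthSpec(1.0, 1.0), self.POOL, seed=1)
        assert out == truth

    def test_zero_recall_only_decoys(self):
        truth = {"GENE0001", "GENE0002"}
        out = syn.generate_candidate_genes(truth, syn.GeneTruthSpec(0.0, 0.5), self.POOL, seed=1)
        assert out & truth == set()

    def test_zero_precision_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_candidate_genes({"GENE0001"}, syn.GeneTruthSpec(0.5, 0.0), self.POOL, 1)

    def test_parameter_recovery_small(self):
        """Aggregated precision/recall approach the planted (r*, p*)."""
        from phenoaudit.metrics import gene_precision_recall

        rng = np.random.default_rng(0)
        tp = fp = fn = 0
        for i in range(400):
            truth = {str(g) for g in rng.choice(self.POOL, size=3, replace=False)}
            cand = syn.generate_candidate_genes(
                truth, syn.GeneTruthSpec(0.6, 0.7), self.POOL, seed=10_000 + i
            )
            pr = gene_precision_recall(cand, truth)
            tp += pr.tp
            fp += pr.fp
            fn += pr.fn
        assert tp / (tp + fn) == pytest.approx(0.6, abs=0.05)
        assert tp / (tp + fp) == pytest.approx(0.7, abs=0.05)


class TestPatientsAndAbstracts:
    def test_noise_free_patients_match_profiles(self, tmp_path):
        from phenoaudit.ranking import read_phenopackets

        spec = syn.SyntheticSpec(seed=12, n_terms=60, n_diseases=6)
        graph = syn.generate_ontology(spec)
        kb, _ = syn.generate_reference_kb(spec, graph)
        noise = syn.PatientNoiseSpec(imprecision_rate=0.0, noise_terms=0, n_per_disease=1)
        syn.generate_patients(kb, graph, noise, seed=1, out_dir=tmp_path)
        cases, _ = read_phenopackets(tmp_path)
        for case in cases:
            assert case.observed == frozenset(kb.terms(case.truth))

    def test_noise_terms_added(self, tmp_path):
        from phenoaudit.ranking import read_phenopackets

        spec = syn.SyntheticSpec(seed=12, n_terms=60, n_diseases=3)
        graph = syn.generate_ontology(spec)
        kb, _ = syn.generate_reference_kb(spec, graph)
        noise = syn.PatientNoiseSpec(imprecision_rate=0.0, noise_terms=3, n_per_disease=1)
        syn.generate_patients(kb, graph, noise, seed=1, out_dir=tmp_path)
        cases, _ = read_phenopackets(tmp_path)
        for case in cases:
            profile = frozenset(kb.terms(case.truth))
            assert profile <= case.observed
            assert len(case.observed) <= len(profile) + 3

    def test_patient_bytes_deterministic(self, tmp_path):
        spec = syn.SyntheticSpec(seed=12, n_terms=40, n_diseases=3)
        graph = syn.generate_ontology(spec)
        kb, _ = syn.generate_reference_kb(spec, graph)
        noise = syn.PatientNoiseSpec(n_per_disease=1)
        p1 = syn.generate_patients(kb, graph, noise, seed=9, out_dir=tmp_path / "a")
        p2 = syn.generate_patients(kb, graph, noise, seed=9, out_dir=tmp_path / "b")
        assert [p.read_bytes() for p in p1] == [p.read_bytes() for p in p2]

    def test_mock_abstracts_keyed_verdicts(self):
        spec = syn.SyntheticSpec(seed=12, n_terms=40, n_diseases=3)
        graph = syn.generate_ontology(spec)
        kb, _ = syn.generate_reference_kb(spec, graph)
        terms = [t for t in graph.active_terms() if t not in graph.roots]
        plan = [
            {"disease": "DZ:0000001", "term": terms[0], "expect": "validated"},
            {"disease": "DZ:0000001", "term": terms[1], "expect": "unvalidated"},
            {"disease": "DZ:0000002", "term": terms[2], "expect": "no_abstracts"},
        ]
        corpora, key = syn.mock_abstracts(kb, plan, graph, seed=3)
        panel = VotePanel([MockAssessor(policy="keyword") for _ in range(3)])
        for entry in plan:
            docs = [AbstractDoc(**d) for d in corpora[(entry["disease"], entry["term"])]]
            record = assess_evidence(
                panel, docs, entry["disease"],
                kb.disease_labels.get(entry["disease"], ""),
                entry["term"], graph.terms[entry["term"]].label,
            )
            assert record.evidence_status.value == key[f"{entry['disease']}|{entry['term']}"]
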