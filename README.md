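# phenoaudit

Audit candidate phenotype/gene knowledge — for example, disease
descriptions externalized by a large language model — against curated
rare-disease knowledge bases.

Rare-disease diagnosis leans on curated resources: the Human Phenotype
Ontology (HPO), disease–phenotype annotation files in the
`phenotype.hpoa` dialect, Orphanet phenotype and gene exports. When a
new knowledge source claims to know which phenotypes characterize a
disease, three questions matter to curators and method developers:

1. **Reproduction** — how much of the curated annotation set does it
   recover? Measured by the Jaccard index on exact term identity (with a
   one-sided hypergeometric test against the ontology's concept
   population) and by a normalized Resnik semantic similarity
   that credits taxonomically close, non-identical terms:

   ```
   IC(t)        = -ln(TF(t)/N)
   sim(S1→S2)   = (1/|S1|) Σ_{t1∈S1} max_{t2∈S2} IC(MICA(t1,t2))
   sim(S1,S2)   = 0.5·sim(S1→S2) + 0.5·sim(S2→S1)
   norm(S1,S2)  = 2·sim(S1,S2) / (sim(S1,S1) + sim(S2,S2))
   ```

   Gene lists are scored by precision/recall after alias normalization,
   restricted to causative associations.
2. **Extension** — which proposed annotations are genuinely novel (the
   term and its parents/grandparents all absent from the reference),
   which of those the literature supports (evidence voting by an
   assessor panel over abstracts, with two-of-three cases exported for
   manual review), and which are proposed convergently by independent
   sources.
3. **Substitution** — if the candidate knowledge replaces the curated
   KB inside a phenotype-driven disease ranker, how does recall@1/5/10
   over patient Phenopackets change? Both a built-in semantic ranker and
   file-level integration with external rankers are supported, with
   exact and broader-category matching.

A synthetic-data module generates every input — ontology, reference KB,
corrupted free-text candidate profiles (dropout, taxonomic substitution,
hallucination), gene sets with planted precision/recall, patient
Phenopackets, abstract corpora with verdict keys — so the whole pipeline
is testable offline with known ground truth. All LLM-style judgment
services sit behind a record/replay executor interface with
deterministic mocks; no network is ever required.

## Worked example

```python
import io
from phenoaudit import synthetic as syn
from phenoaudit.ontology import build_corpus, information_content
from phenoaudit.alignment import build_lexicon, align_profile
from phenoaudit.assessors import MockAssessor, VotePanel
from phenoaudit.metrics import compare_term_sets
from phenoaudit.novelty import detect_novel_terms

# synthetic study conditions: 100-term ontology, 20-disease reference KB
spec = syn.SyntheticSpec(seed=1, n_terms=100, n_diseases=20)
graph = syn.generate_ontology(spec)
reference, genes = syn.generate_reference_kb(spec, graph)
ic = information_content(build_corpus(reference, graph))

# render one disease's profile as corrupted free text and align it back
disease = sorted(reference.annotations)[0]
corrupted = syn.corrupt_profile(reference.terms(disease), graph,
                                spec.corruption, seed=7)
panel = VotePanel([MockAssessor(policy="accept") for _ in range(3)])
profile = align_profile(build_lexicon(graph), panel, corrupted.lines,
                        graph, ic, disease=disease)
print(len(corrupted.lines), len(profile.aligned_terms), len(profile.residuals))
# -> 2 2 0          (every corrupted line aligned, nothing residual)

result = compare_term_sets(profile.aligned_terms, reference.terms(disease),
                           graph, ic)
print(round(result.jaccard, 3), round(result.normalized, 3))
# -> 0.2 0.415      (low exact overlap, moderate semantic similarity)

novel = detect_novel_terms(profile.aligned_terms, reference.terms(disease), graph)
print(novel == set(corrupted.hallucinated))
# -> True           (the planted hallucination is flagged as novel)
```

The first line shows the corruption at work: of the disease's annotated
terms, dropout left two lines, and alignment recovered both. The Jaccard
of 0.2 against the full reference profile reflects the dropped terms;
the normalized semantic similarity of 0.415 shows the surviving terms
still carry much of the profile's meaning. The novelty detector isolates
exactly the hallucinated term that was injected outside the profile's
2-hop neighbourhood.

A thin CLI covers the shell-scale entry points:

```
phenoaudit synth --seed 2 --n-terms 60 --n-diseases 8 --out demo/
phenoaudit ontology-stats demo/ontology.obo
phenoaudit rank --obo demo/ontology.obo --kb demo/reference.hpoa \
                --corpus demo/phenopackets
```

The `rank` call above prints, for the generated corpus:

```
{"n_cases": 40, "skipped_files": 0, "recall@1": 0.95, "recall@5": 1.0, "recall@10": 1.0}
```

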