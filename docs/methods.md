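# Methods

`phenoaudit` evaluates how faithfully a *candidate* source of rare-disease
knowledge — typically the externalized output of a large language model,
but any per-disease phenotype/gene list works — reproduces, extends, and
can substitute for *curated* knowledge bases (HPOA-style annotation files,
Orphanet phenotype and gene exports). This note describes the models and
procedures the package implements, the choices made where the design was
genuinely open, and what the synthetic test bed does and does not show
about real data.

## Ontology model and information content

Phenotype terms form a rooted DAG connected by `is_a` edges; all other
relationship types are ignored. Obsolete terms are loadable (so stale
identifiers in annotation files can be resolved through a single
`replaced_by` hop) but carry no edges and never participate in traversal.

Term specificity is measured by Resnik information content in nats,

    IC(t) = -ln( TF(t) / N ),

where `N` is the number of diseases in an annotation corpus and `TF(t)`
the number of *distinct* diseases annotated to `t`. Two choices here were
open and are worth stating:

- **Annotation propagation is on by default.** A disease annotated to a
  term counts once toward every ancestor of that term (set-union
  semantics, so two sibling annotations of one disease do not double-count
  at their shared ancestor). Propagation is what makes `TF`
  non-decreasing and `IC` non-increasing from child to parent, which in
  turn makes the most-informative-common-ancestor query well defined; it
  is also standard Resnik practice. A raw (non-propagated) mode is kept
  for diagnostics.
- **Zero-frequency terms get a pseudo-count of one** (`TF' = max(TF, 1)`)
  instead of infinite IC. Candidate profiles routinely mention terms the
  reference corpus never annotates; the pseudo-count keeps every
  similarity finite at the cost of a slight underestimate of the IC of
  truly unseen terms.

`MICA(t1, t2)` is the common ancestor (ancestor sets include the terms
themselves) with maximal IC; IC ties are broken by lexicographically
smallest term ID so results are identical across runs and platforms. In
multi-root graphs a pair without common ancestors yields a sentinel
`(None, 0.0)`.

## Agreement metrics

Two complementary views are computed per disease over the profiles shared
by a candidate and a reference KB:

- **Jaccard index** on exact term identity, no ancestor closure — the
  strict set-based view. Its significance is a one-sided upper-tail
  hypergeometric test `P(X >= overlap)` with population equal to the
  number of non-obsolete phenotype concepts in the loaded ontology
  (whether obsolete concepts should count is undecidable from the sources;
  the non-obsolete count is used).
- **Semantic similarity**: the best-match average
  `sim(S1→S2) = (1/|S1|) Σ max IC(MICA(·,·))`, symmetrized as
  `0.5·sim(S1→S2) + 0.5·sim(S2→S1)`, and normalized by the sets'
  self-similarities. The normalization constant is a deliberate choice:
  the plain ratio `sim(S1,S2) / (sim(S1,S1)+sim(S2,S2))` caps identical
  profiles at 0.5, an awkward scale on which perfect agreement is not 1;
  the default therefore multiplies by 2 so that self-similarity
  normalizes to exactly 1. The un-scaled variant remains available
  (`factor2=False`). An empty opposite set
  contributes 0 per term, keeping degenerate candidates comparable, and
  all-root sets (self-similarity 0) return an explicit undefined rather
  than a division error.

Gene agreement uses plain precision/recall after alias normalization
through a user-supplied alias→approved-symbol table; disease-gene links
are essentially one-to-one, so set-overlap statistics add nothing.
Only associations whose class denotes a causative relationship
(disease-causing germline/somatic mutation, documented pathogenic
variants) enter the reference gene sets; everything else — "candidate
gene tested in", modifiers, susceptibility factors — is recorded verbatim
but excluded.

Raw hypergeometric p-values are emitted without multiple-testing
correction; callers that compare many diseases should correct downstream
(e.g. `statsmodels.stats.multitest`).

## Concept alignment

Free-text phenotype lines are mapped to terms in three stages:

1. a transparent dictionary matcher (normalized labels + synonyms;
   normalization is ASCII-lowercase, Unicode-dash folding,
   punctuation-to-space, whitespace collapse) proposes candidate terms by
   longest-match-first scanning, preferring a full-phrase exact match;
2. each (phrase, term) pair is validated by a panel of assessors under a
   unanimity rule (all members must vote yes; the tally is kept so
   one-vote-short cases can be exported for manual review). Phrases with
   no accepted candidate get a second pass: panel members propose
   synonyms, which are re-recognized and re-voted;
3. still-unmatched phrases are retained verbatim as residuals.

No phrase is silently lost: `mapped + residual + rejected` always equals
the input count, where "rejected" is reserved for assessor *failures*
(transport or parse errors), not negative votes. When several accepted
terms compete for the same text span, the best vote tally wins, then the
higher-IC (more specific) term, then the smallest ID; the tie-break is a
package choice — voting alone cannot resolve exact ties.

The dictionary matcher deliberately replaces external concept
recognizers so the pipeline is self-contained and auditable; the
interface accepts a drop-in adapter where a stronger recognizer is
available.

## Assessor panels, record/replay

All externally-queried judgments (alignment validation, synonym
generation, evidence relevance, knowledge externalization, direct
diagnosis) go through an executor interface. Live endpoints are out of
scope; instead:

- a **mock assessor** is a pure function of the task content and a seed —
  policies `accept`/`reject` give the degenerate panels used in property
  tests, `keyword` votes from the task's own content (a term label
  occurring in an abstract counts as supporting evidence);
- a **recording executor** wraps any executor and appends one JSON record
  per call (content hash, template id, payload, raw text) to an
  append-only JSONL cache;
- a **replay executor** serves from that cache and, in strict mode,
  raises on unseen tasks — offline runs can never silently hit a network.

Votes are order-invariant; a member whose output cannot be parsed counts
as a negative vote (conservative, matching the unanimity bar) and is
flagged in the tally. Prompt templates are configuration, identified by
`template_id` in every cache record, so cached results remain traceable
to prompt versions.

## Novelty triage

A candidate term is *potentially novel* for a disease when neither the
term nor any ancestor reachable within two `is_a` hops (any parent path
— the inclusive reading a multi-parent DAG requires) appears in the
reference profile; the hop bound is a parameter. Potential novelties are
triaged against per-pair abstract corpora: the panel is asked whether the
phenotype is described as a manifestation of the disease in each
abstract; the first unanimous positive validates the association
(short-circuit by default — the claim being validated is the
association, not each abstract; a full-scan mode exists for audit
exports); a best tally one vote short of unanimity routes the record to
a TSV review sheet, with optional fixed-seed subsampling for spot
checks. Convergence across sources (items proposed by at least
`min_sources` sources, optionally excluding anything curated or
literature-validated) and a top-level-category breakdown — flagging
novelties in organ systems the reference profile never touches — round
out the module.

## Ranking evaluation

Patient cases are Phenopacket v2 JSON documents; observed terms are
phenotypic features not marked `excluded`, the truth disease comes from
the `diseases` block (with an `interpretations` fallback). The built-in
ranker scores every KB disease by symmetric semantic similarity to the
observed set — the same family of ontology-based scoring used by
established phenotype-driven rankers — sorts descending with
lexicographic tie-break, and retains the top 10 by default. External
likelihood-ratio rankers are integrated at the file level only
(`export_hpoa` out, TSV in with a configurable column profile): their
internals are out of scope, and the built-in ranker keeps the harness
testable offline.

`recall@k` counts a case as a hit when the truth (or a declared
OMIM↔ORPHA equivalent) appears in the top k; *broader* matching
additionally accepts a ranked entry that is a group whose member set
contains the truth. Both the equivalence map and the broader-category
map are explicit user-supplied tables — no automatic inference is
attempted. Each KB is evaluated on its *model-specific* subset (cases
whose truth it covers) and on the *common* subset covered by every KB
under comparison. The augmentation experiment re-runs the evaluation on
`augment_kb(base, additions)` with identical cases and settings and
reports per-k deltas; additions carry an `augmented` provenance tag and
class `unknown`.

## Synthetic data generator

The generator produces every input with known ground truth, at desk
scale:

- **Ontology**: a single-rooted DAG grown by random parent attachment
  (first five terms form a chain so depth ≥ 4; later terms attach to one
  recent-half parent, plus a second parent with probability 0.3; a node
  with `max_children` children stops accepting more). Labels `Term NNNN`
  with 0–2 synonyms; serialized to OBO and re-loadable losslessly.
- **Reference KB**: 50 diseases by default; profile sizes from a clipped
  log-normal (mean 8, range 3–20 — curated-annotation shape at reduced
  scale), terms drawn leaf-biased (3:1), frequency classes from a fixed
  categorical, profiles kept pairwise distinct; 1–3 causative genes per
  disease from a synthetic symbol pool.
- **Corruption** renders a reference profile as free-text lines (label or
  a random synonym per line, so alignment is genuinely exercised, never
  bypassed) with three mechanisms: per-term dropout (`dropout_keep`,
  default 0.6), taxonomic substitution (`ancestor_sub_rate`, default
  0.2) drawing a replacement from the ancestors within `sub_hops` = 2
  hops — substitution is mild generalization to a parent/grandparent;
  sampling the whole ancestor closure would mostly land near the root
  and destroy the semantic signal the mechanism is meant to preserve —
  and hallucination (`hallucination_rate`, default 0.2) appending terms
  sampled outside the profile's 2-hop ancestor neighbourhood so they are
  guaranteed novelty-positive.
- **Patients**: per disease, cases whose terms are generalized to a
  parent with probability `imprecision_rate` (0.2) plus `noise_terms`
  (2) random terms, written as valid Phenopackets; 5 cases per disease.
- **Gene sets** keep each true gene with probability r\* (0.6) and add
  decoys at `tp·(1−p*)/p*` in expectation (stochastic rounding —
  deterministic rounding is biased upward for small true-gene counts),
  so aggregate precision converges to p\* (0.7).
- **Abstract corpora**: template abstracts that mention (or avoid) the
  term label, with a planted verdict key, matched to the keyword-policy
  mock panel.

Everything is a pure function of (spec, seed): repeated generation is
byte-identical.

### What the synthetic bed does not show

The generator emulates the *statistical structure* of candidate-knowledge
errors (dropout, generalization, hallucination, gene decoys), not
clinical language: surface forms are exact labels/synonyms, so alignment
on synthetic data exercises the machinery but not robustness to free
phrasing; abstracts are templates, so evidence voting is checked for
plumbing and verdict logic, not for judgment quality; and the built-in
ranker is not the external likelihood-ratio tool, so ranking numbers
measure the harness, not that tool. Passing tests therefore demonstrate
correctness of the pipeline's computations and contracts — they do not
predict absolute performance of any real knowledge source.

## Numerical and scale choices

Default problem sizes (200-term ontology, 50 diseases, 5 patients per
disease, 2,000 simulated diseases for gene-parameter recovery, 200
random pairs for oracle-equivalence sweeps) keep the full suite and the
acceptance script in the tens of seconds on one CPU while leaving the
statistical checks well-powered; the binomial retention check corrupts
five 10-term profiles per seed over 200 seeds (1,000 corruptions,
standard error ≈ 0.05 against a ±0.2 band). Floating-point comparisons
in tests use relative tolerance 1e-9; the normalized similarity is
asserted into [0, 1] within 1e-9. Degenerate inputs are explicit
throughout: empty KBs and empty panels raise, both-empty Jaccard and
zero-denominator normalization return flagged undefineds, diseases left
empty by filtering are dropped from annotation maps while their labels
stay addressable.

## Known limitations

- The dictionary matcher has no abbreviation expansion or statistical
  NER; heavily abbreviated clinical text will under-align.
- OMIM raw files and Orphanet classification hierarchies are not parsed;
  equivalence and broader-category maps must be supplied.
- Hypergeometric p-values are uncorrected by design (see above).
- The evidence short-circuit means `abstracts_checked` undercounts the
  corpus when an early abstract validates; use full-scan mode for
  complete audit trails.
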