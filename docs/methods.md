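# Methods

## Problem setting

The pipeline extracts gene–gene interactions (physical protein–protein
interactions and transcription-factor–target relations, treated uniformly as
"interactions") from a dependency-parsed corpus. The unit of extraction is
the candidate relation: two distinct gene symbols co-occurring in one
sentence plus a set of binary textual features. The system never sees
sentence-level annotation; supervision comes entirely from interaction
databases (distant supervision), which is noisy at the sentence level — a
known-interacting pair may co-occur in a sentence that asserts nothing.

## Gene tagging

Tagging is dictionary-based, exact and case-sensitive, single tokens only;
full names ("adenomatous polyposis coli") are out of scope. This trades
precision for recall deliberately: symbols that double as ordinary acronyms
(APC, PTB) are still tagged, and the learned feature weights are expected to
suppress non-gene contexts. Symbols may map to several gene identifiers;
ambiguity is carried through the pipeline and resolved only when reporting
identifier-level pairs, where any pair involving an ambiguous symbol is
excluded rather than guessed.

## Feature grammar

Candidates are only built for sentences of at most `max_sentence_tokens`
(default 50); longer sentences are mostly parse or sentence-splitting errors.
gene1 is always the leftmost mention. In every payload, tokens whose word
equals either mention's symbol render as the literal `GENE`; payload tokens
are sanitized so the `<template>_[<payload>]` rendering parses back
unambiguously.

Families, with the conventions that window n-grams and phrases use surface
words while verb and path features use lemmas:

- `Window_{Left,Right}_{Gene1,Gene2}_{1gram,2gram}`: the one or two tokens
  adjacent to each mention, truncated at sentence boundaries (a truncated
  2-gram emits its single remaining token rather than nothing).
- `Window_*_Phrase`: the masked two-token window rendered as a phrase,
  emitted alongside the n-grams. It duplicates the 2-gram payload by
  construction; both names are kept because downstream weight tables are
  read by feature name.
- `Phrase_Between_Genes`: the full masked word sequence strictly between the
  mentions, emitted only when its length is ≤ `between_phrase_max` (default
  6). Unbounded between-phrases explode the feature space; the bound keeps
  the family while capping its noisiest tail.
- `Verb_Between_Genes_[lemma]` per verb (POS prefix `VB`) strictly between
  the mentions; `Single_Verb_Between_Genes_[lemma]` only when exactly one
  verb lies between — the cleanest interaction signal, and deliberately
  absent from negated constructions like "does not interact" (two verbs).
- `Verb_On_Dependency_Path_[lemma]`, `Dependency_Path`,
  `Collapsed_Dependency_Path`: computed on the shortest undirected path in
  the dependency graph, ties broken lexicographically on (direction, label,
  token index) step sequences; no path features when the mentions sit in
  disconnected parse fragments. The collapsed variant maps intermediate
  tokens to VERB/NOUN/OTHER (`GENE—VERB—GENE`).
- `Prep_Pattern_[noun prep1 prep2]`: emitted when both genes attach to one
  common noun through prepositional edges. Two encodings are recognized:
  collapsed labels (`prep_of`, `nmod:of`) directly on the noun, and basic
  parses where the gene is the `pobj` of a `prep` token governed by the
  noun. "Prepositional interaction pattern" admits many concretizations;
  this common-noun-governor definition is ours, and the family can be
  disabled in `FeatureConfig`.

Punctuation counts toward windows and between-spans; filtering it would add
a tokenizer-dependent rule, and uninformative punctuation features are
suppressed by learned weights instead.

## Distant supervision

Label precedence per candidate: (1) pairs on the high-frequency list are
Unknown (demotion guards against overfitting the weights to a few famous
interactions; the list is the set of known-positive pairs with more than
`high_frequency_threshold` = 50 candidates, a reproducible analogue of a
manually curated list); (2) pairs in the positive KB — BioGRID-like rows
restricted to Co-crystal Structure / Reconstituted Complex / Co-purification
evidence, ChEA-like rows unconditionally — or in the snowball set are True;
(3) pairs in the negative KB are False (positives outrank negatives when
databases disagree, since negative annotations have been observed to be
wrong in text more often than the curated physical evidence; configurable);
(4) exactly ⌊0.08 · n_eligible⌋ random negatives are drawn, without
replacement, from candidates whose pair is no known positive and whose
sentence contains no interaction-evidence lemma; (5) everything else is
Unknown.

"No interaction evidence" is concretized as: no sentence lemma in
`trigger_lemmas`. The default list covers the verb triggers (bind, interact,
regulate, associate, phosphorylate, activate, inhibit, complex, target) plus
their nominal forms (binding, interaction, association), since nominalized
mentions are interaction evidence too. The list is configurable and
auditable.

Labeled candidates are split 50/50 into train (clamped evidence during
learning) and holdout (calibration) by ordering on a seeded cryptographic
hash of the candidate id and cutting at ⌊n/2⌋ — stable across reruns and
insertion order, and exact to within one candidate. All candidates,
labeled or not, remain query variables: the model scores its own training
sentences, which is what makes the snowball computation possible. The
snowball set of an iteration is the pairs that were Unknown, called at the
cutoff, and curated true from the text; it is added to the positive side of
the next iteration's labeling.

## Factor-graph model and learning

One binary variable per candidate. Feature factors contribute their weight
when the variable is 1 (logistic parameterization, with an always-on BIAS
intercept — the corpus is dominated by non-interacting co-occurrences, so an
intercept is required). Linkage factors tie each candidate to the previous
candidate of the same pair in the same document with a single shared
Ising-style agreement weight (per-pair weights would be unlearnable from
sparse chains). The single-variable conditional is
`logistic(bias + Σ active weights + w_link Σ_nb (2 v_nb − 1))`.

Learning is stochastic gradient ascent on the conditional likelihood of the
train-split evidence with contrastive clamped-versus-free Gibbs samples from
persistent chains: per iteration, one sweep of each chain, gradient = the
difference of each factor's sufficient statistic between the clamped and
free sample, learning rate 0.001 multiplied by 0.95 per iteration, 1000
iterations. The linkage weight is learned by default and can be frozen
(`learn_linkage=False`). The decay cadence (per iteration) follows the
stated hyperparameters; note that a 0.95-per-iteration decay spends
essentially its whole step budget in the first few hundred iterations.
Those defaults are tied to corpus-scale label counts (tens of thousands of
evidence variables, so per-feature gradients are large and weights saturate
before the decay bites). At desk scale the same budget freezes learning
while logits are still small, so `recovery_experiment` — the package's
desk-scale analogue of a corpus run — defaults to `diminish_rate=0.995`,
rescaling the decay horizon to the problem size while keeping every other
hyperparameter at its default. The package-wide defaults remain the
corpus-scale values.

## Marginals

The linkage factors the pipeline builds form disjoint chains (each candidate
has at most one predecessor and one successor), so the joint distribution
factorizes over chain components. Marginals for chains and isolated
variables are therefore computed exactly by transfer-matrix
forward–backward with evidence clamped — the zero-variance limit of
Rao-Blackwellized Gibbs sweep averaging, adopted after sweep averaging at
the 1000-sweep default proved to leave worst-case Monte-Carlo error of the
same order as the tolerances we verify against exact enumeration. For
hand-built graphs whose linkage is not chain-structured, the estimator falls
back to sampling: 10% burn-in sweeps, then the per-variable resampling
conditional averaged over `inference_iterations` sweeps. An exact
enumeration oracle (`bruteforce_marginals`, ≤ 20 free variables) exists for
testing and diagnostics.

Extractions are called at probability ≥ 0.90 (inclusive). Document-level
aggregation keeps, per (document, pair), the maximum-probability record,
ties broken toward the earliest sentence.

## Evaluation

Precision/recall are computed against a per-document gold standard;
predictions in documents the gold standard never curated are ignored (their
truth status is unmeasurable), and rescue sets — curated lists of true
positives the gold database missed — augment the true positives without
entering the recall denominator. Sentence-level curation precision counts
only verdicts that the sentence itself asserts the interaction;
document-level precision additionally accepts interactions true elsewhere in
the document. Calibration uses ten equal-width probability bins over the
holdout split, the last bin closed, reporting per-bin count and fraction of
True labels. Interaction trends count, per gene and year, documents with at
least one called interaction involving the gene, normalized by the year's
total interaction-document count; documents without a publication year are
excluded and logged.

## Synthetic corpora

The generator emulates the data conditions the extractor faces, not the
surface statistics of real text. Sentences are instantiated from
hand-authored templates with fixed dependency parses, so tests are hermetic
and bit-stable. Template inventory: interaction templates built around the
trigger verbs (three *interact* variants, three *bind* variants including
the nominal "binding of X to Y", three *regulate* variants, one
*phosphorylate*, and "interaction between X and Y"), two negation templates
("X does not interact with Y" — two verbs between the genes, hence no
single-verb feature), five co-occurrence templates with no trigger lemma
(two of them gene-final, so sentence position alone cannot separate the
classes), and two filler templates with ≤ 1 gene. Verb-lemma variants exist
so that trigger-verb features have the broadest coverage within the
interaction class, so single-verb trigger features are expected to
dominate the learned weight ranking when recovery succeeds.

Defaults (chosen once as a realistic desk-scale regime): 200 documents of
4–10 sentences, 40 fake symbols (GENAA…, disjoint from real HGNC symbols),
5% of symbol pairs planted true, KB coverage 0.8, KB false-positive rate
0.01, 35% co-occurrence sentences, 15% negations, 20% filler, publication
years 2004–2014. Distant-supervision noise is therefore present by
construction: uncovered true pairs produce interaction sentences labeled
Unknown or even sampled as random negatives, and KB noise plants True labels
on co-occurrence sentences.

What the generator does not emulate: lexical diversity, parse errors, OCR
noise, full-name mentions, cross-sentence evidence, topic drift. Passing
recovery thresholds on these corpora demonstrates that the machinery —
feature grammar, labeling, learning, inference, calling, scoring — recovers
planted signal under noisy distant supervision; it does not certify
corpus-scale precision/recall on real literature.

## Numerical and reproducibility choices

All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence` (child streams per purpose); the random-negative
draw and the train/holdout split additionally use SHA-256-based ordering so
they are independent of iteration order. Generator outputs and every
pipeline stage file are byte-identical across reruns of the same config;
the run manifest records the config hash, seeds and per-stage row counts.
Probabilities are printed with six decimals; weight tables are sorted by
|weight| descending with BIAS and LINKAGE as special rows. Degenerate
inputs: empty corpora and empty marginal tables yield empty outputs;
zero-token sentences, out-of-range dependency heads, blank dictionary
symbols and unknown KB source tags are rejected with located errors;
learning without any evidence variable is an error.

## Known limitations

- Single-token, case-sensitive tagging misses full names, non-standard and
  non-human symbols, all common in real text; recognizing them is out of
  scope here.
- The prepositional-pattern operator and the dependency-path rendering
  alphabet are declared concretizations; other parsers' label conventions
  may need the collapsed/basic encodings extended.
- The gene1/gene2 naming convention is fixed to leftmost/rightmost; weight
  tables learned under a different convention are not interchangeable.
- The default learning schedule is scale-dependent (see above); the
  recovery experiment documents its own decay choice.
- Snowball iteration requires human curation input by design; only the set
  computation is automated.
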