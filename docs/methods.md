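# Methods

## The task and the model

`chemnmt` treats chemical nomenclature as machine translation between two
deterministic serialisations of a molecular graph: SMILES strings and
systematic IUPAC names. The model is the classical encoder–decoder
transformer: learned token embeddings scaled by √d_model, sinusoidal
positional encodings, multi-head scaled dot-product attention (causal
self-attention in the decoder, additive −10⁹ padding masks on both streams)
and position-wise ReLU feed-forward blocks. The residual blocks use
pre-sublayer normalisation (x + Sublayer(LN(x)), with a final LN after each
stack) rather than the original post-norm arrangement: at desk scale,
pre-norm converges several times faster and is insensitive to the warmup
length, which matters when the whole training budget is a few CPU-minutes;
the attention/feed-forward mathematics is unchanged. Training is
teacher-forced; the loss is sparse categorical
cross-entropy averaged over non-padding positions only, and the reported
training accuracy is the fraction of non-padding positions whose argmax
matches the label. Optimisation uses Adam (β₁ = 0.9, β₂ = 0.98, ε = 10⁻⁹)
under the inverse-square-root warmup schedule

    lr(step) = d_model^(−1/2) · min(step^(−1/2), step · warmup^(−3/2))

with warmup = 4000 by default. Label smoothing and gradient clipping are
exposed in the configuration but default to off: the desk-scale corpora are
small and regular enough that neither is needed, and leaving them off keeps
the loss directly comparable to the hand-computed oracles in the tests.

Two presets exist. The full-scale configuration (4 layers, 8 heads,
d_model 512, d_ff 2048, dropout 0.1, batch 96) matches the architecture the
method was designed around; it is constructible and trainable but is not
exercised by the test suite. The desk preset (2 layers, 4 heads, d_model
128, d_ff 512) — and the still smaller variants used in the tests — exists
so the complete pipeline runs on one CPU in minutes. Accuracy figures
obtained with desk models characterise the pipeline, never the full-scale
model.

The whole network, including reverse-mode differentiation, runs on NumPy in
float32. Gradients are validated against central finite differences in the
test suite. Batches are length-bucketed: each epoch the example order is
reshuffled (seeded), stably sorted by target length, cut into batches, and
the batch order reshuffled; every batch is trimmed to its own maximum
length. This keeps padding work proportional to actual sequence lengths
while preserving exact reproducibility — two runs with the same seed produce
identical loss traces.

Decoding is greedy argmax from the start token until the end token or a cap
(1000 generated tokens for names, 600 for SMILES). Greedy decoding is the
default because the tool reports a single deterministic name per molecule;
beam search is deliberately out of scope.

## Canonicalisation

Every SMILES entering the pipeline — training data, or a user query at
inference time — is reduced to a canonical, kekulised, stereochemistry-
preserving form via RDKit. Kekulisation alone is not resonance-stable (two
Kekulé spellings of quinoline canonicalise to different kekulised strings),
so the implementation first takes RDKit's canonical *aromatic* form and then
kekulises that canonically-ordered molecule; every spelling of one molecule
maps to exactly one string. This is what makes model predictions a function
of the molecule rather than of the input spelling, and the invariance is
asserted over hundreds of random atom-renumberings in the acceptance tests.
The canonicaliser name and version are recorded in every shard manifest;
canonical forms are only promised stable within one RDKit version.

## Name → structure parsing

Round-trip evaluation needs an independent route from a predicted name back
to a structure. `chemnmt.nomen` is a rule-based recursive-descent parser
covering substitutive nomenclature over acyclic hydrides (chains to C30,
-ene/-yne, the common suffixes and esters), monocycles, von Baeyer
polycycles with flattened superscript descriptors (``tricyclo[7.4.1.05,14]``),
skeletal replacement (oxa/aza/thia/phospha with λ-valence markers), a
lexicon of retained ring systems with their fixed numbering, nested
bracketed substituents with di/tri/bis/tris multipliers, hydro prefixes and
indicated hydrogen. Ambiguous flattened bridge descriptors are resolved
against the global atom-count constraint of the alkane stem.

Tautomeric adjustments (a ketone suffix on an aromatic ring, N-substitution
at a fully bonded ring nitrogen, hydro prefixes) are handled uniformly by a
double-bond reassignment step: the perturbed ring system's double bonds are
cleared and re-derived as a matching in which every affected carbon must
regain a double bond (unless explicitly saturated) while heteroatoms may
carry hydrogen instead. Failure to cover a required carbon is reported as a
double-bond assignment error.

Stereodescriptors are parsed and *validated* — the referenced locant must
exist and be a plausible stereocentre, and pseudo-asymmetric lowercase r/s
descriptors are rejected as unsupported — but the descriptors are not
encoded in the output structure, because downstream comparison uses
substructure-key fingerprints, which are stereo-agnostic. Parse failures
carry a category (unfindable locant, valency violation, stereochemistry
limitation, disconnected name, double-bond assignment failure, unsupported
construct) so evaluation reports can classify why a generated name failed.

Out of grammar: spiro and fusion-bracket nomenclature, multi-component
(salt) names, and most retained trivial names. A name outside the grammar
fails with a typed error and scores zero in the round-trip metrics — the
same conservative convention applied to genuinely malformed predictions.

## Fingerprints and similarity

Structure pairs are compared with an 881-bit substructure-key fingerprint
organised in the seven classical sections of the CACTVS/PubChem key design
(hierarchic element counts; ring counts by size and composition; bonded
element pairs; atom-neighbourhood patterns; bond-order-specific pairs;
linear SMARTS; ring-substitution SMARTS), computed with RDKit substructure
matching. It is an independent implementation of that key family: section
semantics follow the published layout, but bit-for-bit identity with other
toolkits is not guaranteed, so fractional Tanimoto values can differ from
values computed elsewhere by a few hundredths while structure-identity
(similarity 1.0) judgements are robust. The Tanimoto coefficient is
|A∩B|/|A∪B| over the bit sets, defined as 1.0 for two all-zero vectors.

In aggregate metrics, a prediction that fails to parse back into a valid
structure is assigned similarity 0 and kept in the mean (never dropped),
giving a conservative estimate that mixes fluency and validity.

## BLEU

No BLEU implementation ships in the supported environment, so the package
implements sentence BLEU-1..4 directly: modified (clipped) n-gram precision,
geometric mean over orders, standard brevity penalty, no smoothing (a
missing n-gram order scores 0). Names are tokenised into letter runs, digit
runs and individual punctuation marks — BLEU over raw characters saturates
for chemical names. The corpus report carries the four per-order averages,
their mean, and the fraction of sentences with a perfect BLEU-4.

## Diversity selection

Train/test construction uses greedy MaxMin selection: starting from a chosen
item, repeatedly add the item maximising the minimum distance to everything
already selected (ties broken by lowest index). Features default to
2048-bit hashed circular (Morgan, radius 2) fingerprints with Tanimoto
distance; the diversity of the selection, not one specific fingerprint, is
the contract. The implementation is the exact O(k·n) incremental greedy and
is tested for index-sequence agreement against an exhaustive oracle and
against RDKit's independent MaxMin picker. The default start index is 0 for
determinism; `maxmin_split` derives the start from its seed.

## The synthetic corpus

Desk-scale training needs paired data with exactly one deterministic name
per structure. The generator enumerates all non-isomorphic carbon trees up
to `max_carbons` (the classic alkane isomer series — 13 cumulative isomers
through C6 — is asserted in the tests), decorates them with a configured
set of simple groups (methyl, ethyl, hydroxy, oxo, amino, halogens; carbon
branching also arises from the trees themselves), and names every structure
with a
deterministic simplified-IUPAC namer: longest chain preferring suffix
groups, lowest locants, alphabetical prefixes, di/tri/tetra multipliers.
The namer and the parser are independent code paths, and every emitted pair
must survive ``canonicalize(parse(name)) == smiles``; failures are
discarded and logged, so the emitted corpus satisfies the round-trip
contract by construction (a handful of highly branched polyols whose names
would need doubly nested substituent prefixes are discarded this way).

What the generator emulates: the statistical shape the method assumes —
a deterministic, consistent naming function over a closed chemical
subspace, with token vocabularies closed between train and test splits.
What it does not emulate: rings, stereocentres, charged species, the
length distribution and diversity of real compound databases, or the
naming style of any commercial generator. Passing the learning tests
therefore demonstrates that the pipeline (canonicalisation, tokenisation,
training, decoding, evaluation) is correct end to end, not that the desk
model approaches full-scale accuracy on real data.

Default study conditions for the learning demonstration: `max_carbons 8`,
methyl and hydroxy substituents (up to three decorations), seed 11 — 2869
validated pairs, of which a MaxMin-selected 10% (286 structures) are held
out. The demonstration trains a 2-layer, 4-head, d_model-64 model for 180
epochs (7380 steps, batch 64, dropout 0.1, warmup 200) in roughly a quarter
hour on one CPU. Under these conditions the model reaches ≈99.1%
teacher-forced token accuracy on its training data (measured with dropout
off) and reproduces ≈46% of held-out names byte-exactly, while ≈98% of its
generated names parse to valid structures with a mean fingerprint Tanimoto
of ≈0.97 against the references — the characteristic behaviour of this
method in the small-data regime: errors are chemically near-correct names,
not noise. Byte-exact generalisation to the MaxMin-extreme held-out
structures keeps improving with corpus size and training length; the
figures above are what this package's default, CPU-budgeted conditions
deliver, not a ceiling of the approach.

## Numerical and convention choices

* float32 throughout the network; loss/accuracy reductions in float64.
* Specials fixed at pad=0/start=1/end=2/unknown=3; unknown inference-time
  tokens map to the unknown id with a warning rather than failing.
* Vocabularies are sorted token lists, so vocabulary construction is
  order-independent and byte-stable across runs.
* Duplicate SMILES in corpus curation: first record wins; conflicting names
  are reported, never silently merged.
* Shards are a framework-neutral length-prefixed record stream (optionally
  gzip), with record counts and the canonicaliser version in a JSON
  manifest; reading shards in manifest order reproduces the input exactly.
* Length filtering is by raw character count, bounds inclusive (a
  600-character SMILES survives a 600-character limit).
* Length-stratified reports use fixed windows of 60 characters (bin 1:
  0–60, bin 2: 61–120, … bin 10: 541–600); longer inputs go to a flagged
  overflow bin; empty bins report absent metrics, not zeros.

## Known limitations

* The name parser covers a defined grammar subset; valid IUPAC names
  outside it (spiro, fused-ring brackets, trivial names) are rejected.
* The fingerprint is not bit-compatible with any other toolkit's
  implementation of the 881-key design; fractional similarities are
  comparable within this package only.
* The namer produces *a* systematic name, not the Preferred IUPAC Name.
* Desk-scale models are trained on a closed, regular subspace; their
  accuracy says nothing about performance on drug-like molecules.
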