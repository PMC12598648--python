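# Methods

This note documents the models and procedures `plmmsa` implements, the
parameters that matter, what the synthetic fixtures do and do not emulate,
and the numerical and design choices made where the design was open.

## Encoder contract and the toy encoder

Every pipeline stage consumes per-residue embedding matrices `[L, D]`.
The encoder contract is deliberately small — a callable returning such a
matrix plus a static spec (name, `D`, optional input window `max_len`,
optional database admission cap `db_max_len`) — so trained PLM encoders
can be plugged in unchanged.

The bundled toy encoder hashes every k-mer window (default k = 3) into
two signed buckets of a D-dimensional space (feature hashing keyed by a
seed through BLAKE2b, so the mapping is stable across processes), and row
*i* is the L2-normalised sum of features of all windows covering position
*i*.  Consequences that the tests rely on: identical sequences give
bit-identical matrices; interior positions of a homopolymer run have
identical rows; a point mutation perturbs only the ≤ k rows whose windows
changed, so homologs stay nearby in embedding space while unrelated
sequences decorrelate at a rate set by `1/√D`.

Pooling is the column mean of the residue matrix.  For encoders with a
bounded window, sequences are split into consecutive non-overlapping
chunks of `max_len`, each chunk encoded and pooled, and chunk pools are
combined weighted by chunk length — algebraically identical to the mean
over all encoded residues.  For a context-bounded encoder like the toy
k-mer hasher, the chunked pool equals the unchunked one exactly when each
boundary falls inside a homopolymer run wider than the k-mer context;
otherwise they differ by the boundary rows only (O(k/L)).

Dimensions in use: retrieval databases default to D = 64 ("esm"-like,
window 1022) and D = 96 ("ankh"-like, database cap 3000 residues);
alignment uses a separate D = 128 encoder.  D = 128 was fixed by a
design-time separation experiment: with semiglobal alignment and gaps
(−0.5, −0.1) on a 60-residue query, true family members (10 %
substitutions, 2 % indels) score ≥ 28 while 200 random decoys score
≤ 3.8, leaving a wide corridor around the filter thresholds (12.0
relative, 8.0 absolute).  Lower D narrows the corridor because per-cell
cosine noise scales as `1/√D`.

## Contrastive loss and adapter training

The MSA-aware contrastive loss over a batch `h ∈ R^[Nq, Nt, H]` (slot 0 =
query, slots 1..Nt−1 = homologs from its MSA) is implemented literally as
printed in its source formulation: positives for anchor *i* are its
homolog slots only; negatives are *all* slots of other queries, including
their query slot; the anchor's own slot enters neither sum.  With a
single query the negative sum is empty and the loss is exactly zero — a
useful degenerate check.  Temperature τ = 0.05 puts raw exponentials near
e^20, so both sums are evaluated as max-subtracted log-sum-exps; the
nested-loop oracle agreement tolerance in the tests is 1e−9, and observed
deviations are ~1e−15.

The adapter is a linear projection `x ↦ Wx` (the production counterpart —
a ConvBERT block — is out of scope; the loss, not the adapter
architecture, is the testable contribution).  Its gradient is derived
analytically through the cosine and the L2 normalisation and verified
against central finite differences to 1e−6.  Training uses Adam with
betas (0.9, 0.98), ε = 1e−8.  The production recipe (lr 2e−6 with cosine
decay and 700 warm-up steps, batch 64, 12 targets per query, 2 epochs) is
recorded as configuration provenance; at the synthetic scale used here
(10 families × 12 members, H = 16) a constant lr of 3e−3 for 200 steps
with Nq = 6, Nt = 4 decreases the loss monotonically in the mean and
raises the held-out within-minus-between family cosine margin for every
seed tried; lr = 1e−2 made the per-step loss oscillate and was rejected
during calibration.

Synthetic embedding families are unit centres plus isotropic Gaussian
noise (σ = 0.5 before renormalisation), giving a starting margin of
~0.2 — far from both the trivial (margin ≈ 1) and hopeless (margin ≈ 0)
regimes, so training has room to demonstrate an effect.

## IVF-SQ8 retrieval index

Pooled vectors are L2-normalised at build time so inner product equals
cosine.  Coarse centroids come from scikit-learn k-means (k-means++ init,
`n_init=1`, 25 iterations, fixed `random_state`) — reproducibility is
preferred over convergence.  The centroid count follows
`round2sf(C·√N)` with C = 5 (the worked example: N = 63 M → 40,000);
at package scale the count is clamped to the database size.  Quantizer
ranges are global per dimension over the build set (per-list ranges are a
possible extension, not implemented).  Codes are
`round(255·(v−min)/(max−min))` clamped to [0, 255]; degenerate dimensions
encode to 0 and dequantize to their minimum; the round-trip error is at
most range/255 per dimension.

Search probes the `nprobe` centroids nearest by cosine and ranks
dequantized candidates by cosine to the query, ties broken by ascending
id — every floating-point comparison runs through the same code path as
the brute-force reference, so `nprobe = nlist` reproduces the exact
ranking bit for bit.  The package default is `nprobe = None` (probe
everything): at the few-hundred-vector scale this package targets,
exactness costs nothing; the `nlist/16` production-style budget remains
available through configuration, and recall is measured in the tests at
`nlist/4` against the brute-force ranking.  On the 20 × 20 family
fixture, quarter-probe search recovers ≥ 99 % of the family members that
exact search itself ranks in the top 20.  (Exact search recovers ~87 % of
the generator's truth table: members carrying several indels genuinely
drift out of the pooled-cosine top 20.  That is an embedding property,
not an index property, so recall is defined against the exact-search
ceiling.)

## Embedding alignment and filtering

Alignment maximises the summed per-cell cosine over matched pairs plus
affine gap penalties, in a three-state DP (match / gap-in-target /
gap-in-query).  Modes: `global` (ends charged), `semiglobal` (free end
gaps; the MSA default, since homologs may be partial length), `local`
(best non-negative sub-path).  Defaults: gap_open = −0.5,
gap_extend = −0.1 — mild penalties suited to scores bounded in [−1, 1] —
with the canonical affine constraint `gap_open ≤ gap_extend ≤ 0` enforced:
if opening were cheaper than extending, the optimum would fragment gap
runs by alternating gap states and the run-based accounting that makes
the score interpretable (and enumerable by the test oracle) would break.
Traceback ties prefer diagonal over vertical over horizontal, making
output deterministic.  The DP core is numba-compiled; an exhaustive
enumerator over all monotone matchings (feasible up to 4 × 4) is the
correctness oracle.

Per-cell cosine (rather than raw dot product) keeps every cell in
[−1, 1], which is what makes the absolute filter floor of 8.0 readable as
"about eight confidently aligned residues".  The filter keeps a hit iff
its score is ≥ 20 % of the query's self-alignment score *and* ≥ 8.0 —
the two discard rules are applied independently, and both thresholds are
configurable.  The self-alignment score of a query with normalised rows
and a diagonal-dominant self-similarity is exactly its length in global
mode.

## MSA assembly and Neff

Candidates retrieved by multiple databases are deduplicated keeping the
best retrieval score; queries shorter than 128 residues search only the
short-sequence database.  Surviving alignments are rendered as A3M rows:
matched query positions carry the uppercase target residue, unmatched
query positions `-`, and target residues between consecutive matched
pairs become lowercase insertions placed after the left match.  Target
residues outside the aligned span are trimmed — the row represents the
alignment, not the full hit sequence.  Rows are sorted by descending
alignment score, ties by id; the ungapped query is row 0.  The A3M column
invariant (uppercase + `-` per row equals query length) is validated on
construction and on file read.

Neff uses the standard effective-sequence weighting of the coevolution
literature: over match columns only, row *i* is weighted by the
reciprocal of the number of rows within 80 % identity of it (self
included, `-` treated as an ordinary 21st symbol), and Neff is the weight
sum.  Edge cases are exact: N identical rows → 1; all rows below the
threshold → N; two duplicate pairs → 2.  No length normalisation (√L or
otherwise) is applied; the threshold is configurable.

## Multimer feature stages

Taxonomy pairing follows the AlphaFold-Multimer convention: within each
taxon present in at least two chains, rows are sorted by descending
alignment score and paired rank by rank up to the smallest per-chain
count; chains lacking the taxon contribute all-gap segments
(`require_all_chains` switches to strict all-chain pairing).  Paired and
block-diagonal rows are built from match-state rows (insertions
stripped), so each combined row's length is the sum of chain query
lengths and per-chain spans never overlap.  Rows consumed by pairing are
excluded from the block-diagonal remainder, conserving row counts.

Template gating accepts a predicted monomer model when its *mean*
per-residue pLDDT strictly exceeds 70; per-residue masking is out of
scope.  The recycling controller stops once the CA RMSD between
consecutive iterations is strictly below 1 Å; RMSD is computed after
optimal superposition (proper rotations only, via quaternion-based
alignment), with an unsuperposed shared-frame variant behind a flag.
Superposed RMSD on well-spread coordinate sets is numerically accurate to
~1e−6 Å, which bounds how close to zero a "rigid copy" test can assert.

## Synthetic fixtures

The family generator emulates homology by descent: a uniform-random
ancestor, per-site substitutions at rate 0.1 (uniform over the 19
alternatives, so expected per-site identity is exactly 0.9), and indel
events at rate 0.02 per site (insertion/deletion equiprobable, geometric
lengths p = 0.5 capped at 5).  Decoys are i.i.d. uniform-composition
sequences; coordinate pairs are 3.8 Å-step random walks under a random
rigid transform plus optional Gaussian noise.  All generators are pure
functions of their seeds.

What passing tests therefore show: the pipeline separates
mutationally-derived families from compositionally random sequences under
a deterministic, homology-sensitive encoder.  What they do not show:
performance on real PLM embedding geometry, realistic indel/domain
structure, phylogenetic correlation between families, or biased amino-acid
composition — decoys here are a much easier null than real non-homologs,
so the wide score corridor observed in the fixtures should not be read as
an expected margin on biological data.

## Problem sizes and determinism

Default test and acceptance workloads are deliberately desk-scale: 500
random vectors for index exactness, 400 (20 × 20) family vectors for
recall, a 15-member family against 200 decoys for the end-to-end run, 100
random batches for the loss oracle, 200 matrices up to 4 × 4 for the DP
oracle, 200 adapter steps.  These sizes exercise every code path while
keeping the whole suite in the tens of seconds.  Every stage is
deterministic given its seed; the end-to-end pipeline writes
byte-identical A3M, metadata and report files on re-run (timings are
logged, never written into the report).

## Known limitations

- The toy encoder's k-mer geometry is far simpler than PLM embedding
  space; thresholds calibrated here (filter corridor, recall behaviour)
  do not transfer to trained encoders without re-measurement.
- Per-list quantizer ranges, product quantization and delegation to an
  external ANN backend are not implemented.
- The pairing stage ranks rows by alignment score; the original
  production systems may rank by other statistics, which is unknowable
  from their public description.
- A3M rows trim target residues outside the aligned span, so hit rows do
  not preserve full-length hit sequences.
- Neff at real database scale depends on retrieval depth and database
  redundancy; values computed on desk-scale fixtures are not comparable
  to database-scale reports.
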