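# Methods

This note documents the models, parameter choices and numerical
conventions behind aptakit, and what the synthetic-data tests do and do
not demonstrate about real data.

## Library model and read handling

A library member is `forward_constant + N(36) + reverse_constant`, with
the 20-nt constant regions `GTTCGTGGTGTGCTGGATGT` / `TGACACATCCAGCAGCACGA`
and the reverse primer equal to the reverse complement of the 3'
constant region (an invariant the constructor enforces, which doubles
as a transcription check on the sequences themselves).

Insert extraction searches each read, then its reverse complement, for
the forward constant region, then for the reverse constant region
downstream of it; the insert is the span between them. Matching is
exact by default and configurable to a small per-region substitution
tolerance (`max_mismatch`); sequencing platforms and trimming settings
vary, and exact matching is the reproducible baseline. Inserts whose
length differs from 36 are rejected rather than padded (the library is
fixed-length by construction), and N-containing inserts are rejected
because they cannot be tallied as a unique 4-letter sequence.
Rejections carry reason codes (`no_forward`, `no_reverse`,
`bad_insert_length`, `bad_alphabet`, `ambiguous_insert`) and are counted,
never raised, so counted + unmatched always equals the input read count.

Coordinates are 0-based half-open internally; report files use 1-based
inclusive spans.

## Enrichment and candidate selection

Counts are normalized to reads per million (RPM) so pools of unequal
depth compare; the selection statistic is the RPM fold change between a
configurable early round (default round 2, the earliest pool that is
typically sequenced) and the arm's final round. "Increased abundance"
is formalized as fold change strictly greater than 1; the threshold is
exposed (`min_fold`). Sequences absent from the early pool receive a
pseudocount of 0.5 RPM — about half of one read at 2M depth — keeping
fold changes finite and monotone. Only the final pool's top-k (default
100) sequences are scored, per arm.

Candidates passing in at least `min_arms` (default 2) injury models
form the priority tier, ordered by their best final-pool RPM; the
single-arm tier follows. All orderings break ties lexicographically by
sequence, so the pipeline is deterministic. Multi-arm candidates are
named S1, S2, … in list order; single-arm candidates take their arm's
prefix plus their abundance rank in that arm.

A dynamic worth knowing when interpreting results: with several strong
binders in one pool, a weaker binder's *relative* frequency can peak in
mid rounds and then decline as stronger binders take over, pushing its
late/early fold change below 1 even though it outcompetes the
background throughout. The strict fold filter is therefore faithful to
late-vs-early comparison but can drop weak binders in
binder-saturated pools; comparing against a later "early" round, or
lowering `min_fold`, recovers them.

## Clustering

Distances are computed on random-region inserts only — the constant
flanks are shared by every candidate and carry no signal. The default
metric is Levenshtein distance (unit-cost substitutions and indels,
computed with edlib); an alignment-score distance
d(a,b) = (s(a,a)+s(b,b))/2 − s(a,b) over a +1/−1/−1 global alignment is
available.

Neighbor joining is implemented directly so its determinism is under
our control: when several pairs minimize the Q-criterion equally, the
lexicographically smallest label pair is joined; negative branch
lengths are clamped to zero with a logged warning. On additive
matrices NJ is exact, which the tests exploit as an oracle (random
additive trees, recovered to ≤1e-9), with scikit-bio's independent NJ
as a cross-check. Families come from removing the longest branches
(ties broken by the smallest leaf label below the edge) until the
leaves fall into k components. The tree is a similarity dendrogram for
grouping, not a phylogeny, and the number of families in any real
campaign depends on alignment settings that published studies rarely
report — so k is a user choice, not a reproduction target.

## Secondary structure

Folding is a weighted maximum-pairing (Nussinov-style) dynamic program
over Watson–Crick and G·T wobble pairs with weights GC=3, AT=2, GT=1 —
the 3/2/1 ladder mirrors relative pair stabilities — and a minimum
hairpin loop of 3 nt. The downstream design steps need topology (where
helices are, where their defects sit), not free energies, so a
maximum-pairing objective is sufficient and has an exact brute-force
oracle (exhaustive enumeration of nested pairings for n ≤ 10, which the
test suite runs on 200 random sequences). Temperature and ionic
strength are recorded as metadata only; a nearest-neighbor
thermodynamic engine can be substituted through the same `FoldResult`
interface for cross-checks.

The traceback is deterministic: where choices tie, the left end of an
interval is paired rather than left single-stranded, with its
outermost admissible score-optimal partner. This local rule extends
helices outward and in practice maximizes stacked runs; a global
tie-break over all co-optimal structures would be exponential to
evaluate and buys nothing for the design steps. `fold_suboptimal`
enumerates distinct structures within a score margin of the optimum,
approximating a folding server's alternative-structure output without
claiming to reproduce any particular server's ensemble.

Stems are maximal stacked runs merged across interior defects of at
most `max_defect` (default 2) unpaired bases per strand; multibranch
junctions never merge. Corrected variants close a stem's defects by
substitution: opposed defect positions are paired off from the helix
outward and the 3'-side base is replaced with the complement of the
5'-side base. Unopposed (bulge) bases are left untouched — a
substitution cannot close a bulge without changing length, and
corrected variants preserve the parent's length by contract. Because
only unpaired positions change, the parent's optimal structure remains
feasible for the variant, so refolding can only raise the score (the
tests assert this, and strict improvement on the constructed defect
cases). One variant is emitted per defective stem, mirroring the
one-variant-per-structure-element design pattern.

Truncations span hairpin elements: each top-level helix yields the
subsequence from its outermost pair's 5' to 3' index; runs of adjacent
elements (spacer included) and the full parent are appended, so two
hairpins yield the characteristic four-variant panel. Because the
objective is additive over disjoint intervals, a truncated element's
restricted pair set is optimal for the subsequence, and refolding it in
isolation reproduces that score.

Chimeras follow the fixed assembly rule: sense strand = aptamer (DNA)
+ UU linker (RNA) + siRNA sense (RNA) + TT overhang (DNA); antisense
strand = siRNA antisense + TT overhang. The duplex is validated as an
RNA reverse complement, and per-position alphabet metadata is kept
instead of converting T↔U.

## Binding model

Specific MFI is sample minus control, negatives preserved — clamping
at zero would bias Kd upward. The one-site model `Y = Bmax·X/(Kd+X)`
is fitted by bounded least squares (trust-region reflective via
scipy's `curve_fit`) with Bmax₀ = max(Y), Kd₀ = the concentration whose
signal is nearest Bmax₀/2, both parameters bounded positive, and tight
convergence tolerances (1e-14) so noiseless curves recover the
generating Kd to ≤1e-6 relative error across 10–500 nM. The default
grid is the standard assay series 0–600 nM (8 points).

Replicates are fitted separately and summarized as mean ± sample SD
(n−1), matching how binding assays report "mean ± SD, n = 3"; a pooled
fit over all points is available via `pooled=True`. A 2-D grid search
over (Kd, Bmax) serves as the independent oracle for noisy fits in the
tests. Scale equivariance (Y-scaling moves Bmax only; X-scaling moves
Kd proportionally) is asserted as a property.

## Synthetic data: what it does and does not show

The generator's defaults are the study conditions the tests run under:
10⁴ distinct background 36-mers, 5 spiked binders with target capture
probabilities spread over 0.5–0.9 and off-target 0.02, background
capture 0.1, 8 rounds, 10⁵ reads per sequenced pool, per-base
substitution error 0.001. The stringency schedule multiplies the
background capture by a geometric decay from 1.0 to 0.2 across rounds,
emulating the ~5-fold experimental tightening (more competitor cells,
fewer target cells, longer washes). Round dynamics are a deterministic
expectation update — counter-selection removes mass proportional to
off-target affinity, positive selection multiplies by capture
probability, renormalize — so closed-form trajectories are checkable;
stochasticity enters only at sequencing (multinomial draws plus
substitution errors). Only the rounds the analysis consumes are
written to FASTQ by default; intermediate pools carry no extra
information under a deterministic update.

Deliberately not modeled: PCR amplification bias and chimeras, indel
sequencing errors, realistic quality-score profiles, binder-binder
competition for binding sites, and the true (unknowable) per-round
enrichment dynamics of any real selection. Passing the spike-in test
therefore shows that the pipeline's counting, normalization, filtering
and prioritization logic is correct under the assumed enrichment
model — not that the model describes any particular wet-lab campaign.

## Problem sizes and determinism

The test suite and the acceptance script size their simulations to the
conditions above (3 arms × 8 rounds at 10⁵ reads is the largest run,
about a minute); oracle suites use 50–200 random instances at sizes
where exhaustive enumeration is exact. Every stochastic component
takes an explicit seed, and derived RNG streams are spawned per
(round, arm) so outputs are pure functions of (config, seed); pipeline
reruns are byte-identical, which the CLI tests assert.
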