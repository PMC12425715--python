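# Methods

## Germline annotation

Segments are located by local alignment of known-gene templates
(match +2 / mismatch −2 / gap open −6 / extend −1) against the genomic
sequence, both strands, iterating with masking so duplicated segments
surface. A hit is accepted at ≥ 70% identity (default; configurable)
over ≥ 80% of the template length; overlapping hits are suppressed in
favour of the higher score, ties broken by longer alignment then lower
coordinate. Recombination signal sequences are scanned as
heptamer–spacer–nonamer motifs (consensus `CACAGTG` / `ACAAAAACC`,
spacer 12 ± 1 or 23 ± 1, ≤ 1 heptamer and ≤ 2 nonamer mismatches by
default; `N` never matches). Per locus the spacer classes follow the
bovid organisation: IGH V-23 / D-12×2 / J-23; IGK V-12 / J-23; IGL
V-23 / J-12. A V pairs with the RSS 3′ of its coding end, a J with
the RSS 5′, a D with one on each side, searched within a 40-bp gap
window.

Two safeguards keep the D inventory clean. D templates are short
enough (10–40 bp) that chance local hits pass any reasonable identity
gate, so a template-derived D is only accepted when both flanking
RSS12s are found — under the 12/23 rule the paired signals are what
make a D segment a D segment. The template-free nomination route
(motif pairing alone, for D candidates no template matches) demands
near-exact signals (exact heptamer, ≤ 1 nonamer mismatch, exact
spacer): an exact heptamer pair arises by chance only once per ~10⁸ bp,
whereas looser budgets nominate freely in random sequence. RSS-only
candidates falling inside an already-located V/J/C interval are
discarded as chance signal pairs inside coding sequence.

Functionality is a simplified IMGT decision tree: pseudogene on an
in-frame stop or a frameshift relative to the template; functional when
the frame is intact, the RSS is present within budgets, and the
conserved anchors are found (V: both cysteines; J: [FW]GXG); ORF
otherwise. Splice sites and leader exons are not modelled. V
subgroups are single-linkage clusters over pairwise global nucleotide
identity at the conventional 0.75 cutoff, labelled by descending
cluster size then first genomic coordinate. FR/CDR delimitation is
never inferred; it is taken from the reference (the toy germline
carries it; for discovered segments it must be supplied), and SHM maps
are emitted without region labels when absent.

## Read filtering

A read passes iff its raw length is ≥ 400 bp (a structurally complete
rearrangement — primers, leader, V, junction, J, partial C — exceeds
400 bp, so shorter reads are likely incomplete) and both amplification
primers are found by Hamming match (≤ 2 mismatches, no indels — 5′RACE
primers are short and high fidelity) within 60-bp end windows.
Rejections are charged to the first failing gate (too_short,
missing_fwd_primer, missing_rev_primer); kept reads are trimmed to the
inter-primer insert. Paired-end merging is out of scope; input is
assumed pre-merged.

## V(D)J assignment

Candidate V and J genes are pre-screened by edit distance (edlib,
infix mode; ties by name) and the chosen candidate is aligned with the
affine-gap local aligner above. The V 3′ and J 5′ boundaries are then
re-fixed by a gapless walk scoring +1 per match and −7 per mismatch,
taking the prefix-score argmax (X-drop 21). The penalty is the crux:
a mismatch is bridged only when ≥ 8 of the following bases match, so an
isolated point mutation inside the segment is tolerated (the walk
recovers and continues) while extension past the true junction by
chance — probability ≈ (1/4)⁸ per event — is effectively impossible.
At zero SHM the walk returns exactly the maximal exact germline
extension, which is the parsimony boundary; clustered mutations within
the terminal zone can still clip it, which is why SHM tallies exclude
that zone (below). D (IGH only) is the longest exact ungapped match of
any germline D inside the V–J gap, requiring ≥ 5 consecutive matches
and implied end deletions ≤ 8 bp per side; below the minimum the whole
gap is untemplated. Ties break by name, then smaller D offset, so
calls are reproducible. Reads are reverse-complemented when the minus
orientation screens better. Identity gates: V ≥ 0.70, J ≥ 0.80.

Productivity requires the full 2nd-CYS codon and J anchor codon to be
retained, V and J in frame across the junction, and no stop codon from
the first complete V codon through the anchor. CDR3 runs strictly
between the 2nd-CYS and the J-anchor codon (both excluded; the
anchor-inclusive junction is also reported, so the +6-bp convention can
be recomputed). A rearrangement whose anchors are deleted, unmapped,
or mutated to a stop is excluded from CDR3 statistics with reason
`missing_anchor`.

## Junction decomposition

Boundaries come from the refined alignments; the untemplated gaps are
split greedily into P and N: a P tract requires the abutting deletion
to be zero and is the maximal prefix (suffix) of the gap equal to the
reverse complement of the germline end read inward, capped at 4 bp
(observed P tracts are short); remaining bases are N. P-before-N and
V-side-before-J-side order makes the split deterministic. The
concatenation invariant — retained V + P/N + retained D + P/N +
retained J equals the read's junction region — holds by construction.

An exhaustive decomposer enumerates every valid decomposition of a
junction window (all deletion combinations within caps, all exact
retained-D placements, the same maximal-P convention). Validity alone
is vacuous — any decomposition degrades into another by deleting more
germline into N — so the meaningful ambiguity class is the
maximal-parsimony subset: minimal V deletion, then minimal J deletion,
then longest retained D. The greedy decomposer always lands in this
class; the simulator flags a read `ambiguous_junction` whenever the
class is not the singleton equal to the drawn truth, and exact truth
recovery is claimed (and tested) only for unambiguous reads. With the
default generator settings roughly half the reads are ambiguous — one
chance base match at either boundary suffices — which is a property of
junction decomposition itself, not of this implementation.

### Trimming-bias-corrected deletion estimator

Parsimony re-attributes a deleted germline base to the segment whenever
the adjacent untemplated base matches it by chance (probability
q = 1/4 under uniform N composition), so measured deletions are
stochastically shorter than the generative draws:
`E[measured] = μ(p) − Σ_{j≥1} q^j S(j; p)` for a truncated-geometric
deletion law with survival function S. `ovig.stats.fit_geometric_deletion`
inverts this by the method of moments (scalar root-finding in p) and
reports the implied generative mean; on simulations at n ≥ 3000 the
corrected mean lands within ~2% of the law mean where the raw mean is
~12–15% low.

## SHM profiling

Only substitutions count as SHM; alignment gaps are excluded from
numerator and denominator. Mutations and coverage are tallied per
germline V position, excluding a 4-nt 5′ and 48-nt 3′ margin
unconditionally: terminal alignment trimming and junction-boundary
refinement drop end bases *conditionally on their being mutated*, so
including those zones would bias every rate estimate downward, while
unconditional exclusion leaves the estimators unbiased (the 3′ margin
spans the V-deletion range the boundary walk operates over). The
12-type spectrum is the fraction of total mutations per ordered
substitution; the hotspot mask flags the C of each WRCY and the G of
each RGYW (a base in both contexts counts once, both flags recorded);
hotspot tables report per-type counts, the hotspot fraction of all
mutations, and hotspot-vs-background per-base rates. Clonal collapsing
by identical junction is available behind a flag (default off — usage
statistics are defined without duplicate removal).

## Synthetic repertoire

Each read is built V → (P,N,P) → D → (P,N,P) → J (light chains: one
gap), wrapped in a random leader (48 bp), a constant-region stub
(60 bp) and the 5′RACE universal / gene-specific primers, giving
~500-bp reads. Defaults emulate the measured ranges of a ruminant IgH
repertoire: truncated-geometric deletions (3′V p=0.35 cap 32, D ends
p=0.35 cap 8, 5′J p=0.25 cap 12 — concentrating 3′V deletions at
0–4 bp and 5′J at 0–12 bp with the observed maxima as caps), P tracts
at 30% probability on undeleted ends (1–4 bp), N tracts
truncated-geometric (p=0.3, cap 12, uniform composition), SHM at 2%
per base with a fivefold multiplier at hotspot C/G, and a
transition-heavy 12-type weight table in which A>G leads, G>A is
second and T>A is last. The target base of each mutation is drawn
from the weight row of its source base, so the *marginal* measured
spectrum also depends on germline composition and hotspot boost —
`expected_spectrum` computes that implied marginal in closed form, and
it is what recovery tests compare against. Under the default fivefold
boost the AID channel (G>A, C>T at hotspots) overtakes A>G in the
marginal even though the per-event weights favour A>G.

A single seeded generator drives all draws in fixed order, so output
is byte-identical across runs and platforms. The truth record stores
everything needed to rebuild the read exactly (asserted in tests).
The toy germline builder emits anchor-correct segments: V of 98 codons
with both conserved cysteines (codons 22 and 96) and FR/CDR labels, J
of 16 codons with exactly one [FW]GXG anchor, D segments flanked by
RSS12 pairs including one carrying a (YG)n-style motif, and C stubs;
`make_toy_genome` plants them with proper RSS flanks in random spacer
for annotation round trips.

What the generator does not emulate: indels (neither SHM-derived nor
sequencing), gene conversion, paired-end error profiles or read
merging, clonal lineage structure, region-targeted SHM (hotspot
context is the only positional signal), and real locus architecture
(intergenic distances, pseudogene content). Passing tests therefore
demonstrate correctness of the algorithms under a substitution-only,
single-locus model — not performance on real 5′RACE data, where indel
handling and primer chemistry add failure modes this package does not
model.

## Problem sizes and tolerances

The test suite runs repertoires of 800–1500 reads per condition;
acceptance runs 3000 reads for the junction/usage channel, 2000 for
the SHM channel and 1200 for hotspot enrichment — sizes at which the
3-standard-error and 5% bands used by the statistical checks are
meaningfully tight while a full run stays in the minutes range on one
CPU. Statistical assertions use 3 binomial SE for proportions (4 SE
for the twelve simultaneous spectrum fractions), a 0.05–0.06 bound on
the empirical-vs-law CDF distance for distribution recovery, and 5%
relative error for the bias-corrected deletion means. Exactness
claims (junction truth recovery, productivity, CDR3, byte-identical
reruns) are asserted without tolerance on the subsets where exactness
is attainable in principle (unambiguous junctions, interior
mutations), as documented above.
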