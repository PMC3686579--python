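# Methods

This note documents the models and procedures implemented in `minicoi`, the
parameters that matter, the numerical choices at points where the design was
genuinely open, what the synthetic-data generator does and does not emulate,
and known limitations.

## Sequence algebra and translation

IUPAC ambiguity codes are modelled as subsets of {A,C,G,T}; U is normalised
to T on input and lower case is upper-cased. Inosine (I) is treated as a
universal base with two deliberately different conventions, both exposed:
it contributes a factor of **1** to fold degeneracy (one physical
nucleotide in the synthesis tube) but expands to all four bases in
`expand()` (four concrete sequences it can stand in for). Expansion refuses
inputs past a cap (default 65,536) to prevent combinatorial blow-up.

Translation uses the invertebrate mitochondrial code (NCBI table 5, via
Biopython's codon tables) because the marker is metazoan mitochondrial COI;
the code is configurable since different host groups may warrant table 2 or
others. Codons containing ambiguity codes translate to `X`, never silently
dropped; trailing partial codons are ignored. This choice matters for the
stop-codon filter: AGA/AGG are serine under table 5 but stops under the
standard code, so running the QC with the wrong table would discard valid
reads.

The printed reverse mini-barcode primer is *not* the literal reverse
complement of the forward primer: five positions that reverse-complement to
W (A/T) were synthesised as S (G/C). The package stores the printed sequence
verbatim in its fixture table and computes the literal reverse complement
separately; nothing ever conflates them. One consequence: a concrete
forward-site sequence can never match the printed reverse primer at zero
mismatches (S ∩ W = ∅), so in-silico amplification with that pairing needs a
five-mismatch allowance — which is how the 319-bp geometry is exercised in
the tests.

## Entropy profiling and consensus

Column variability is Shannon entropy h(x) = −Σ f·log₂ f in **bits** (0 at a
conserved column, 2 at uniform base usage); the unit is fixed here because
plotted entropy traces in the literature are often unlabelled. Gaps are
excluded from the frequencies but tracked as per-column coverage; all-gap
columns are *undefined* (NaN), never reported as conserved. Ambiguity codes
contribute 1/|base set| to each base they denote (a `drop` mode treats them
as gaps instead). Window search ranks all width-w windows passing a mean
entropy ceiling and a per-column coverage floor by (mean entropy, max
entropy, start); there is no field-standard threshold for "conserved enough",
so the ceiling is an explicit toolkit parameter. Reported coordinates are
1-based inclusive; internals are 0-based half-open.

The degenerate consensus takes, per column, the IUPAC symbol covering
exactly the bases with frequency ≥ `min_base_freq` (default 0.05, about the
level at which a variant is worth a degenerate position in a 26-mer), with
the modal base always included and absent bases never included — this makes
`min_base_freq=0` an exact round-trip over a primer's expansion.

## In-silico PCR

Annealing is gapless set-intersection matching: a primer position mismatches
iff its base set and the template's are disjoint; inosine never mismatches;
template N matches everything by default (a strict mode counts it as a
mismatch). No 3′-end weighting is applied, because the mismatch statistics
being reproduced are raw counts along the oligo; a 3′-window report exists
behind a flag. Binding-site search scans both strands (vectorised over 4-bit
base masks); amplicons arise from every properly oriented forward/reverse
site pair, the insert excluding both footprints. Mismatch distributions use
the minimum-mismatch site per template (ties: leftmost), or fixed
coordinates when the priming site is known; templates with no site under a
generous ceiling land in an explicit "unalignable" bin. Thermodynamics
(melting temperature, secondary structure, touchdown kinetics) are out of
scope.

## Blocking primers

A blocking primer overlaps the 3′ end of a universal priming site by
`overlap_len` bases and extends `total_len − overlap_len` bases into
host-specific template in the universal primer's extension direction; it is
3′-blocked (Spacer-C3) so it suppresses extension without consuming prey
template. Candidates are vetted by searching the host-specific extension
against every prey reference and rejecting the design if any prey shows
fewer than `min_prey_mismatches` (default 4) — fewer mismatches would mean
the blocker silences prey too.

## Read QC

Demultiplexing is exact on the (MID, tag) prefix — tags are short enough
that a single error can cross samples, so no tolerance is the default
(configurable in principle, but the scheme uniqueness check assumes exact
keys). The forward primer is then located immediately after the tag and
compared IUPAC-aware; reads with more than `max_primer_mismatches` (default
2) are discarded. The reverse primer's reverse complement is searched in the
remainder and everything from it onwards trimmed. A minimum trimmed-insert
length (default 150 nt) stands in for platform-specific signal filters:
flow counts have no exact base-space equivalent, so the floor is defined on
bases.

Frame classification aligns each read to its closest reference (candidate
chosen by edit distance; the classification alignment is end-free affine,
match +1, mismatch −2, gap open −10, extend −1, end gaps free). References
must be in-frame and stop-free; the read inherits the reading frame through
the alignment. Internal gap runs are classified by length mod 3: multiples
of three are whole-codon insertions/deletions, anything else is a
frameshift. Stops are counted on the *frame-corrected* read: frameshift-
affected codons are excised and the remaining complete codons translated, so
a downstream frameshift does not fabricate spurious stops and a genuine stop
is not masked. When a gap run starts exactly on a codon boundary the codon
on the 3′ side is deemed affected (a deterministic tie rule; within
homopolymers the aligner's leftmost placement decides, and the excised codon
is the one containing that placement).

Keep rules: **pass** = no stops, no frameshifts, no codon insertions, fewer
than four codon deletions; **repaired** = exactly one frameshift and nothing
else wrong, with the affected codon removed entirely (the true indel
position inside the codon is unknowable, so the whole codon goes); otherwise
the verdict names the first violated rule in the fixed precedence
stop > frameshift > insertion > deletion, so every read gets exactly one
verdict. Repaired outputs are trimmed to complete codons of the inherited
frame, hence always length ≡ 0 mod 3 and stop-free; `pass` outputs keep the
raw trimmed insert (which may carry a trailing partial codon).

The chimera screen compares the best single-parent identity against the
best one-breakpoint two-parent identity (left segment from one reference,
right from another, each ≥ `min_segment` read bases, default 30); the score
is the identity gain. The maximisation includes the degenerate pair A = B,
which pins the gain at ≥ 0 and makes a clonal read's gain exactly zero. The
default decision threshold is 0.05 gain — conservative for noisy real data.
The acceptance-style sensitivity test passes 0.005 explicitly: its
construction (segments ≥ 50 nt of a 313-nt read) bounds the attainable gain
from below at roughly two divergent sites (2/313 ≈ 0.006), and with
noise-free clonal reads any positive threshold yields zero false positives,
so the threshold is set from that a-priori bound, not from the data. This
detector is a behavioural stand-in for full chimera tools: two parents, one
breakpoint, no abundance priors.

## OTU analysis

Clustering is deterministic greedy centroid clustering over dereplicated
sequences visited in abundance-descending order (ties lexicographic): a
sequence joins the first centroid within the dissimilarity radius, else
founds an OTU. The default radius 0.07 is the midpoint of the 6–8%
dissimilarity band used for COI species delineation in marine invertebrates.
This is a behavioural, not algorithmic, surrogate for Bayesian OTU pickers:
it reproduces the delineation scale, not their variance modelling. Identity
is matches / alignment columns with end-gap columns excluded, under global
(unit-cost) alignment — stated explicitly because BLAST-style local identity
uses a different denominator.

Taxonomy: best identity ≥ 0.98 (inclusive — "at least 98%") gives a
species-level match to the best hit. Below that, identity bands cap the
assignable rank (defaults ≥0.95 → genus, ≥0.90 → family, ≥0.85 → order,
≥0.80 → class, ≥0.70 → phylum — toolkit defaults standing in for a
phylogenetic posterior, not literature values) and the assignment is the
deepest rank on which all hits above the band floor agree. Below 0.70 the
OTU is unidentified. Predator self-OTUs are removed only on species-level
matches to the host of a sample the OTU occurs in; congeners are kept.

Diet summaries count, per predator species, OTUs present in exactly one,
exactly two, or more than two individuals (with phylum breakdowns of the
shared fraction), and across species the proportion of each predator's OTUs
shared with any other predator. Abundance classes are {1, 2–9, 10–99,
100–999, ≥1000}. Rarefaction is the exact hypergeometric expectation
E[S(d)] = Σᵢ (1 − C(N−nᵢ,d)/C(N,d)), computed with log-gamma for stability,
and is validated in the tests against exhaustive enumeration and Monte-Carlo
subsampling.

## Synthetic data

`make_reference_panel` builds a 658-nt codon-structured region per reference:
stop-free under table 5, carrying one concrete expansion member of the
forward primer at the conserved window (identical across species — conserved
priming is the premise), with species centroids mutated from a common
ancestor at the inter-species rate (default 0.12 on the 313-nt insert) and
conspecific references at the intra-species rate (default 0.02), both
enforced pairwise by construction with rejection sampling; infeasible specs
fail explicitly. Lineages are synthetic Linnaean paths cycling four phyla,
with species paired into genera. `make_window_alignment` separately encodes
a primer's base sets as column frequencies (balanced assignment, so
single-base columns have exactly h = 0) for the consensus round-trip.

`make_gut_reads` emits MID + tag + forward site + insert + rc(reverse site)
+ rc(tag) + rc(MID) reads per sample, prey mixed with predator reads at the
contamination fraction (default 0.15), and plants violations at spec rates:
in-frame TAA/TAG substitutions, single-nucleotide deletions (frameshifts),
whole-codon insertions (non-stop codons, at codon boundaries), one-to-three-
codon deletions (tolerated) and four-codon deletions (discarded), plus
two-parent chimeras between species centroids with breakpoints in the read's
middle third. Indels are planted ≥10 nt from the insert ends because an
end-free aligner necessarily absorbs terminal indels into free end gaps —
an edge event is not classifiable even in principle. Every read appears
exactly once in the truth table, with verdicts in the QC vocabulary; the
same spec and seed reproduce byte-identical outputs.

What the generator does **not** emulate — and therefore what passing tests
do not show about real data: flowgram-level 454 noise (only substitutions
and discrete planted events), digestion gradients and DNA damage, copy-
number and primer-bias effects on abundances, co-amplified non-target taxa
(bacteria appear only via their proxy, stop-codon reads), and reference
databases with gaps or misannotations. Verdict-recovery rates near 100% at
zero noise establish correctness of the classification logic, not expected
field performance.

## Problem sizes

The test suite exercises the pipeline at the scale the properties need:
~5,000 reads across 16 samples for keep-rule recovery, 12 species × 3
references for clustering recovery, 200 constructed chimeras for the screen,
60-row alignments for entropy round-trips, and 1,000-replicate Monte-Carlo
for rarefaction. These sizes make every property sharp (multinomial noise on
5,000 reads is well under the 1% agreement margin) while the whole suite
runs in well under a minute of alignment work.

## Known limitations

* Annealing is gapless; primer-template indels (reported for some phyla at
  classic priming sites) register as multiple mismatches instead.
* The chimera screen assumes exactly two parents and one breakpoint.
* Greedy clustering is order-dependent by design (deterministic via the
  abundance/lexicographic rule) and has no notion of cluster variance.
* Rank-consensus fallback has no statistical support value; bands are
  heuristics.
* The QC inherits its frame from the single best reference; a read equally
  close to two references in different frames is resolved by list order.
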