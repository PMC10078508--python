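# Methods

## Coordinate model and layout accounting

Features live on a circular genome in 1-based inclusive J-strand coordinates,
the convention of published mitogenome annotation tables. N-strand features are
stored with `start < stop` and reverse-complemented on extraction; annotation
tables that print the 5′ end first for N-strand genes (start > stop) are
normalized on ingestion, so such tables can be transcribed verbatim. A feature
may wrap the circular origin (`wraps=True`), in which case its length is
`(L − start + 1) + stop`.

Signed intergenic values are always recomputed as `next.start − prev.stop − 1`
over features sorted by start, closing the circle with the (last, first) pair;
positive values are spacers, negative values overlaps. Printed "intergenic"
columns in annotation tables are treated as display-only: the bundled reference
table prints +8 for a tRNA pair whose coordinates overlap by 8 bp, and +7 for a
PCG pair overlapping by 7 bp. Because rRNA boundaries are annotation-soft
(rRNAs have no reading frame to delimit them), overlaps involving an rRNA are
tallied separately from the headline PCG/tRNA overlap statistics; both views
appear in `LayoutReport`. The coverage identity
Σ sizes + Σ signed gaps = genome length holds algebraically for any sorted
circular layout and is asserted as a sanity check on every report.

Two internal inconsistencies of the reference paper-style table are worth
knowing: its PCG sizes sum to 11,099 bp while the text quotes 11,064 bp, and
its tRNA sizes sum to 1,462 bp against a quoted 1,459 bp. The package always
reports coordinate-derived values. The quoted 11,064 bp turns out to be the
*counted-codon* length: excluding stop codons and truncated trailing codons,
the architecture carries exactly (11,099 − 2)/3 − 11 = 3,688 codons, and
11,064 = 3,688 × 3. The codon-usage module reproduces this number on any
genome built on the reference architecture.

## Start/stop classification

A CDS of length ≡ 0 (mod 3) must end in a stop codon of the chosen genetic
code; length ≡ 1 must end in `T` ("T--") and length ≡ 2 in `TA` ("TA-") —
truncated stops completed to TAA by post-transcriptional polyadenylation and
flagged incomplete. Anything else raises a malformed-CDS error. The genetic
code defaults to the invertebrate mitochondrial code (NCBI table 5, embedded
as data and cross-checked against Biopython's copy in the suite); other NCBI
tables resolve through Biopython.

## Composition and skews

AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C); zero denominators yield an
explicit undefined value (`None`), never 0 or NaN. N bases count toward totals
but not skew denominators. Per-class strand conventions are explicit because
published per-class statistics rarely state them: genome and control region on
the J strand as stored; PCG, tRNA and codon-position classes on the coding
(sense) strand; rRNA on the rRNA sense strand (N in the typical insect
arrangement) — the choice forced by published rRNA compositions being T-rich.
Codon-position classes use complete codons only. Reporting rounds skews to two
decimals (the precision of published tables); internal values keep full
precision.

## Codon usage

Counts pool complete codons across the CDS set; stop codons and truncated
trailing codons are excluded, matching the convention that recovers the
published codon totals (above). RSCU_c = n_c · d_aa / Σ_{c′∈aa} n_c′, where
d_aa is the family degeneracy; families with zero occurrences have undefined
RSCU (reported NA), and Σ RSCU over any used family equals its degeneracy
exactly. Codons are reported RNA-style (UUA) and stored DNA-style.

## Nucleotide diversity and Ka/Ks

π is the mean over unordered pairs of d_ij/L_ij with site-wise pairwise
deletion of gaps and ambiguous bases; it is reordering-invariant.

Ka/Ks uses Nei & Gojobori (1986) with equal pathway weighting — the classic
counting estimator behind the common population-genetics workflows. Per codon,
the synonymous-site fraction at each position is (synonymous one-step changes)
/ (one-step changes not creating a stop), so N + S = 3 × compared codons holds
exactly; site counts average the two sequences. Observed differences enumerate
all orderings of single-base steps between the codon pair, discard pathways
through stop codons (if all are blocked — possible only for multi-step pairs
hemmed in by stops — all pathways are used unweighted), and average the rest.
p_N = N_d/N and p_S = S_d/S receive the Jukes–Cantor correction
d = −¾ ln(1 − 4p/3); p ≥ ¾ raises an explicit saturation error, and ω is
undefined (not infinite) when dS = 0. Codons containing gaps or ambiguity in
either sequence are dropped whole (codon-wise complete deletion), and so are
codons that are stops in either sequence. Multi-taxon panels report the mean
over all unordered pairs, dropping (and counting) pairs with undefined ω.
Published Ka/Ks values computed with other software variants may differ
slightly; no exact reproduction is promised.

## Repeat detection

A hit is an exact substring of length ≥ `min_len` (default 9 bp, the smallest
repeat class of interest in control regions) occurring at ≥ 2 positions. The
detector enumerates right-maximal repeats via a suffix array and LCP intervals,
then suppresses any hit whose every occurrence lies inside an occurrence of a
longer kept hit — this single containment rule removes both non-maximal
sub-repeats and nested duplicates. Hits whose copies overlap (period < motif
length) are canonicalized into tandem arrays: the unit is the minimal period of
the spanned region (padded to a multiple of the period ≥ `min_len` when the
period is shorter), copies are counted as ⌊span/unit⌋ with fractional trailing
copies truncated. The identical output contract is implemented a second time in
the test suite as a naive per-length substring scan, and the two routes are
asserted equal on constructed and random regions up to 2 kb. Approximate
(mismatch-tolerant) repeats are out of scope.

## Supermatrix preparation

Terminal stop-codon column triplets are removed when every sequence with bases
there ends in a stop; an internal stop raises a frame error naming taxon and
codon. Column filtering is a codon-column gap/ambiguity cap (default 0 — drop
any codon column containing a gap anywhere), an honest simplification of
block-based alignment cleaning whose published parameters are typically
unreported; the cap is adjustable. Concatenation uses the canonical
alphabetical PCG order (atp6 … nad6), fills missing taxon×gene blocks with
gaps, and emits a partition table that provably tiles the matrix. Partition
files are written in RAxML (`DNA, gene = start-end`) and NEXUS `charset`
styles. The neighbor-joining tree (Biopython's NJ on p- or JC distances with
pairwise deletion, negative branch lengths clamped to zero) is a sanity check
for the data path, not an inference method; Bayesian/ML inference is
deliberately out of scope.

## Synthetic data

**Genome generator.** The default template is the reference 38-feature
architecture (names, strands, coordinates, start/stop codon types) with the
published whole-genome composition targets (A 41.8 %, T 24.9 %, G 12.3 %,
C 21.0 %) and a control region carrying an 89-bp motif duplicated with a spacer
plus a 9-bp tandem duplication — the repeat structure reported for the
reference control region. Generation proceeds by constraint layers: start/stop
codon bases are hard-assigned first (overlapping genes' constraints are checked
for consistency — the reference architecture's atp6/cox3 single-base overlap is
consistent); PCG codons are then filled from the target composition with
rejection of stop codons given already-fixed bases, followed by a small
brute-force repair pass for codons fully determined by an overlapping
neighbor; the control region is built with greedily k-mer-unique background
(k = detection `min_len`), which makes it repeat-free by construction apart
from the planted copies; all remaining positions are filled from a
composition-balancing pool that steers whole-genome base counts onto the
targets. Every generated parameter is returned in a truth record, and the
generator self-checks that each PCG classifies exactly as generated.

**Ortholog simulator.** A rejection sampler, not a codon-model matrix
exponential: single-base proposals (uniform site, ts/tv-weighted base) are
rejected if they create a stop, accepted with relative probability ω if
nonsynonymous and 1 if synonymous, until the requested number of accepted
substitutions per codon is reached; realized synonymous/nonsynonymous counts
are recorded as truth. Defaults: 6 taxa (a typical family-level panel),
0.3 accepted substitutions per codon per lineage (interspecific-scale
divergence that stays well below Jukes–Cantor saturation), ts/tv = 1.0 —
matching the equal-weighting assumption of the Nei–Gojobori estimator the
simulator exists to validate; a transition bias would bias that estimator by
construction, which is a property of the estimator, not a bug in either
component. A star phylogeny is used for estimator recovery;
`simulate_on_tree` evolves along an arbitrary nested-tuple tree for end-to-end
supermatrix/NJ tests. No indels are simulated, so simulated "alignments" are
trivially correct; gap handling is exercised with hand-built fixtures instead.

**What passing tests show — and don't.** The closed loops demonstrate that the
statistics recover what the generator put in (composition to ±0.5 pp, planted
repeats exactly, ω to ±20 % at 300 codons over 20 replicates, topologies from
additive or simulated data). They do not validate annotation quality, alignment
of real diverged sequences, heterogeneous base composition along the molecule,
transition bias, or selection heterogeneity among sites — all absent from the
generator by design.

## Numerical and interface choices

Skews and report floats are rounded to 2 dp for display only; JSON output
carries full precision, NaN is serialized as null, and undefined statistics are
`NA` in TSV. Reports are deterministic for fixed inputs and seed; every number
in a TSV also appears in `report.json`. Sequence-dependent stages on a
coordinates-only record are skipped with an explicit "sequence required"
notice rather than failing the whole run. Problem sizes in the suite and the
acceptance script (300-codon genes, 20 replicates, ≤ 2-kb oracle regions, one
full 15.6-kb genome) are chosen so the entire pipeline validates in seconds
while keeping Monte-Carlo error well inside the asserted tolerances.
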