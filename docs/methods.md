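# Methods

This note documents the models and procedures ndokit implements, the
parameters that matter, the numerical choices made where conventions differ,
and what the synthetic fixtures do and do not establish about real data.

## Degeneracy arithmetic

A degenerate oligonucleotide over the 15-letter IUPAC alphabet denotes the
Cartesian product of per-position base sets; its degeneracy is the exact
integer product of the set sizes. Expansion, reverse complementation
(ambiguity codes map to the code of the complemented set) and degeneracy are
mutually consistent by construction and are cross-checked against each other
in property tests. Case is provenance only (lower case = degenerate core of
a hybrid primer) and never affects matching.

Reverse translation uses, per amino acid, the minimal-length IUPAC codon
whose expansion covers every standard codon of that residue. For Arg (MGN),
Leu (YTN) and Ser (WSN) this is over-inclusive — the expansion also contains
codons of other residues — which is the correct trade-off for primer design:
a primer must anneal to every true coding variant, and extra expansions only
add degeneracy that the ≤ 64 budget already polices. The printed reverse
core of the reference primer pair implies exactly this choice for Arg.

## Hybrid primer design

Conserved blocks are core-length (default 4) windows of alignment columns
whose majority-residue conservation, computed over non-gap residues, is at
least `min_conservation` (default 0.8) in every column, and whose degenerate
reverse translation stays within `max_degeneracy` (default 64). Columns with
more than 50% gaps are disqualified from blocks and clamps. Ties in majority
residues break alphabetically, making the whole design deterministic.

The clamp encodes the `clamp_aa` (default 6) consensus residues flanking the
block, each by its top-ranked codon in a configurable codon-usage table (an
E. coli K-12 table ships as the default; usage can also be estimated from
user CDS). With `extend_nt=2` the clamp gains the first two (non-wobble)
nucleotides of the top codon of one additional flanking residue, yielding
20-nt clamps from an 18-bp base length. On the forward primer that residue
sits at the clamp–core junction; on the reverse primer it lands at the 5'
terminus. This placement was chosen because it is the only reading of the
reference primer pair consistent with its printed clamps; note that a single
per-amino-acid usage table cannot reproduce those clamps letter-for-letter
(the same leucine appears under two different codons there), so exact clamp
identity is not asserted anywhere — the degenerate cores are.

The wobble-trim policy drops a 3'-terminal degenerate position when doing so
halves the degeneracy: on by default for the forward primer (11-nt core,
degeneracy 64 → 32) and off for the reverse (12-nt core, 64). Expected
product size is computed in ungapped consensus coordinates from the forward
primer's 5' end to the reverse primer's 5' end, inclusive of both primers;
with 20-nt clamps and a 246-residue motif spacing this gives 790 bp, at the
upper edge of the ~0.75-kb band such assays report — product size is
therefore treated as a band (`product_range`), never an exact value.

## In-silico PCR

A primer position matches a template base iff the base lies in the primer
code's set; template N is a wildcard (configurable), and any other template
ambiguity code is a validation error, because templates are sequenced
molecules. The 3' core must match exactly by default (extension chemistry);
the clamp tolerates `max_clamp_mismatch` (default 2). Both orientations of a
convergent site pair are predicted, so results on a reverse-complemented
template mirror the original. Product length is 5'-end to 5'-end inclusive;
for the reference pair this is 63 bp plus the inter-primer spacer.

## OPUs and phylogeny

Pairwise protein identity is computed from a global alignment with
mismatch = −1, gap open = −10, gap extend = −1, and nearly free end gaps
(−1 open, −0.1 extend); identity = matches / aligned columns excluding
terminal gap columns. The end-gap choices matter: fully free end gaps would
let an optimal alignment stagger a diverged prefix into pseudo-terminal
overhangs and report identity 1.0 between genuinely different sequences,
while penalties at mismatch level would punish the ragged ends that
primer-trimmed clones legitimately have. The steep open penalty keeps
substitution-only pairs aligned without gaps.

OPUs are built by complete-linkage agglomeration on 1 − identity, cut at
1 − threshold (default 0.98). Complete linkage is the interpretation of "at
least 98% similarity" under which the guarantee holds for *every*
within-cluster pair, and it is asserted as an invariant. Labels are assigned
by descending cluster size. The nearest-reference labeling step uses best
global identity against a user-supplied reference FASTA (no web services).

Tree building follows the classical pipeline: complete deletion of every
column containing a gap or unknown residue; Poisson-corrected distances
d = −ln(1 − p) (saturation p ≥ 1 is an error on observed data); Saitou–Nei
neighbor joining with deterministic first-minimum tie-breaking and negative
branch lengths clamped to zero with the deficit logged. Bootstrap support
resamples columns with replacement, rebuilds the NJ tree per replicate, and
tallies the reference tree's internal bipartitions; inside replicates a
saturated distance is capped at p = 1 − 1/(2L) rather than discarded, which
keeps the replicate count fixed. The default replicate count is 1000 in
configuration and 200 in tests for desk-scale runtimes.

## T-RFLP

Digestion cuts at every left-to-right occurrence of the recognition site
(AluI AG^CT, cut after position 2); fragment lengths always sum to the
sequence length. Only the fragment at the labeled (5', forward-primer) end
is detected. Peak area is the relative abundance of the source sequence —
fluorescence response is out of scope. In silico fragment lengths are exact
integers, so a configurable Gaussian sizing-noise model (σ in bp) emulates
capillary electrophoresis and makes the 0.5-bp consensus interval
meaningful. Replicate profiles merge greedily nearest-first within the
tolerance; peaks present in only one replicate are dropped, and consensus
areas are renormalised to sum to 1. PCA is the SVD of the column-centered
matrix, components ordered by eigenvalue, sign fixed so each component's
largest-magnitude loading is positive; explained variances (n−1 denominator)
sum to the total variance.

## Adherence assays

The cutoff is A_C = negative-control mean + 3 × sample standard deviation
(n−1 denominator; the convention had to be fixed, and the sample SD is the
conservative choice for few control wells). Replicate wells are averaged per
isolate before classification — the aggregation rule likewise had to be
chosen. The four classes use inclusive upper boundaries (A = A_C is
non-adherent, A = 2 A_C weakly, A = 4 A_C moderately adherent). Extreme
biofilm producers are reported through the raw A/A_C ratio rather than a
fifth category, whose bound would be arbitrary.

## Synthetic fixtures

Generators take explicit integer seeds and are bit-reproducible. Protein
families enforce the per-column conservation target by an exact substitution
count, round((1−c)·n) rows per column, rather than per-row Bernoulli noise:
with realistic family sizes (~10 rows) Bernoulli noise would let a 0.9
target column fall below the 0.8 design threshold often enough to make
recovery assertions meaningless, whereas the exact count makes the planted
conservation a guarantee. Clone sets plant clusters by rewriting disjoint
blocks of ceil(between_divergence·L) positions per cluster center (so
centers differ at ≥ 2·between_divergence of sites) and capping member
mutations at floor(max_divergence·L/2) (so within-cluster identity ≥
1 − max_divergence by the triangle inequality). T-RF communities plant the
first restriction site exactly at the desired cut and scrub accidental
upstream sites. Plate assays draw wells at 0.5×, 1.5×, 3× and 6× the planted
cutoff with Gaussian noise, apportioning classes by largest remainder.

The substitution model is uniform over alternative residues, sequences have
no indels, and abundances have no compositional noise — so passing recovery
tests demonstrates that the algorithms honor their thresholds and recover
planted structure, not that they are robust to the full messiness of real
alignments, chromatograms or plates.

## Problem sizes

Default test and demonstration sizes are desk-scale by design: families of
8–10 sequences × 160–320 residues, clone sets of ~48 sequences × 240
residues, 3-taxon communities over 4 time points × 2 replicates, 20–40
isolate plates, bootstrap at 20–200 replicates. These sizes exercise every
code path while keeping the full suite in the seconds-to-minutes range.

## Known limitations

- No melting-temperature, dimer or multiplex screening in primer design.
- In-silico PCR has no thermodynamic annealing model; specificity is purely
  sequence-combinatorial.
- The identity metric is global; surveys whose published cluster counts
  derive from local (BLAST-style) identity may need the reference-labeling
  route instead.
- The T-RFLP consensus drops single-replicate peaks; low-abundance taxa near
  the detection limit are therefore under-represented, as in the laboratory
  procedure it mirrors.
- The E. coli codon-usage default is a convention; clamp sequences change
  with the table, and for taxa far from enterobacteria a user-supplied table
  is preferable.
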