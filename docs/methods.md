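# Methods

This note documents the models, parameter choices and numerical conventions
behind `mirsnp`, and what the synthetic fixtures do and do not establish
about real data.

## Coordinates and alphabets

Transcript positions are 1-based inclusive from the 5′ end; genomic
intervals are BED-style 0-based half-open; all sequences are RNA (ACGU)
internally, with DNA input converted T→U on load. BED strand is ignored:
tracks are treated as unstranded regions. Variant records are validated
against the transcript (the stated reference base must match) before any
allele sequence is built, and applying a variant and then its ref/alt swap
restores the input exactly.

## Seed-site model

A site is an exact Watson–Crick reverse complement of the guide seed — no
G:U wobble, so C:G counts as a match and G:G as a mismatch. The canonical
hierarchy is applied per locus: a 2–8 match with an A opposite guide nt 1
is an 8mer; without the A, a 7mer-m8; a 2–7 match with the A, a 7mer-A1;
bare 2–7, a 6mer. One locus yields one site per miRNA (its best type);
sites of different miRNAs are independent. A site at the transcript 3′
terminus (no base opposite nt 1) can be a 7mer-m8 or 6mer but never an
8mer/7mer-A1. The allelic verdict compares sites whose seed interval
contains the variant; when neither allele has such a site the verdict is
`unaffected` if the miRNA has sites elsewhere on the transcript and
`absent` if it has none. No conservation, context features, or
3′-supplementary pairing are scored.

## Folding energy model

Secondary structures are pseudoknot-free sets of canonical pairs (WC +
G:U) with hairpin loops of at least 3 nt. The energy of a structure is the
sum over its loops: nearest-neighbor stack terms for adjacent pairs,
tabulated hairpin/bulge/interior penalties by loop size (linear
interpolation between tabulated anchors, logarithmic extrapolation
dG(n) = dG(n_max) + 1.75·RT·ln(n/n_max) beyond them, RT = 0.616 kcal/mol at
37 °C), and an affine multiloop term a + b·branches + c·unpaired with
a = 3.4, b = 0.4, c = 0.0 kcal/mol. There are no dangling ends, coaxial
stacks, terminal-AU penalties or sequence-dependent loop bonuses, and
lonely pairs are allowed — deliberate simplifications that keep the
dynamic program and the exhaustive-enumeration test oracle exactly
consistent. The parameter table ships as versioned package data
(`data/rna_params.yaml`); stack entries are listed once per symmetry class
and expanded on load with a completeness check.

Absolute energies from this compact table are not comparable to mfold or
RNAfold output, and no published free-energy value is treated as a numeric
contract; everything downstream rests on internal consistency (DP ≡
enumeration; re-scoring identity) and on orderings between alleles.

### Dynamic program

Zuker-style recurrences over integer centi-kcal (so DP, traceback and
scorer agree bit-exactly): V(i,j) for (i,j) paired, with hairpin, interior
(search capped at 30 unpaired nt, the standard MAXLOOP approximation — the
penalty table itself extends beyond 30 for scoring), and multiloop cases; a
multiloop-component matrix WM requiring ≥1 branch; and an exterior matrix W
with free unpaired bases. The kernel is JIT-compiled with numba (an 800-nt
window folds in under a second; the full 180-window default ensemble takes
about 45 s). Constraints are positions forced unpaired, implemented by
blocking them from V; constrained optima can therefore never beat
unconstrained ones, which is what makes the opening cost non-negative.
Ties are broken deterministically in traceback: decompositions are tried
in a fixed order preferring to pair the leftmost position with its
smallest admissible partner.

## Window ensembles

The ensemble places the SNP at internal offsets step, 2·step, … ≤ size for
each window size, mapped to transcript coordinates; a window that would
extend past the transcript is an error, not clipped, because unequal
windows would break the paired allele comparison. The default grid — sizes
100/200/400/800 nt with steps 10/10/20/20 — gives 10+20+20+40 = 90 windows
per allele, 180 folded structures for the pair; the size/step ranges follow
the published design and the exact grid is pinned so the default ensemble
reproduces that published total, with everything configurable. The binary
loop/stem classification maps paired → stem and any unpaired context
(hairpin, interior/bulge, multiloop, exterior) → loop. Probing concordance
treats a Pb²⁺ record as concordant iff the residue is predicted unpaired
and an RNase-T1 record additionally requires a G residue; T1 records on
non-G residues are flagged invalid and excluded from the denominator.

## Duplex energetics and ΔΔG

The guide:site duplex aligns guide nt 2 opposite the site 3′ end
(seed-site geometry; the base opposite nt 1 is not part of the site),
ungapped and antiparallel. Paired positions contribute stack terms; an
internal run of m mismatches flanked by pairs is scored as a 2m-nt interior
loop; end overhangs are free; one bimolecular initiation penalty
(4.09 kcal/mol) applies; with no pairable position there is no duplex and
the energy is 0. The accessibility term is
ΔG_open = E(MFE with site forced unpaired) − E(MFE), which is ≥ 0 by
construction, and ΔΔG = ΔG_duplex + ΔG_open — an open-cost-penalized
hybridization score, chosen because it reproduces the published sign
pattern (favorable negative for the matched allele, positive for the
mismatched one) without claiming the unstated original tool's convention.
The published numeric values (−2.43/4.67) are that tool's output under an
unrecoverable parameterization and are deliberately not reproduced; the
binding contract is the ordering ΔΔG(matched) < ΔΔG(mismatched).

## Annealing kinetics

Association is modeled as irreversible A + B → AB (the assays fit
association-only rate constants; complexes are stable on the gel), giving
dx/dt = k(A0−x)(B0−x) with the closed form evaluated through e^(−|r|) so
either sign of B0−A0 stays finite at large kt. Defaults mirror the assay:
A0 = 0.5 nM labeled miRNA, B0 = 5 nM target; the sampling grid
10–1200 s is a package choice (the original sampling times are not
printed). Simulation noise is multiplicative unit-mean lognormal with a
configurable CV, clipped to [0,1]. Fitting is single-parameter bounded
least squares on the fraction scale in log10 k over [10², 10¹⁰] M⁻¹s⁻¹,
initialized from the initial-slope approximation slope ≈ k·B0. The test
oracle is adaptive ODE integration (agreement within 10⁻⁶).

## Allelic imbalance statistics

Each heterozygous sample is normalized by its own gDNA ratio
(normalized = (a_cDNA/b_cDNA)/(a_gDNA/b_gDNA)); swapping allele labels
inverts the ratio exactly, and cDNA ≡ gDNA gives exactly 1.0. Cohort
inference runs on log₂ ratios because ratios are multiplicative: a paired
t-test of log₂ cDNA vs log₂ gDNA ratios, and a one-sample t-test of the
log₂ normalized ratio against 0, both two-sided; a zero-variance cohort is
handled as a degenerate case (p = 1 exactly at no imbalance). qPCR standard
curves are OLS of Ct on log₁₀ quantity (slope < 0 required for inversion;
slope −3.3219 ↔ efficiency 2.0). Pearson correlation uses the t transform
for its two-sided p.

## Genome overlap

LD expansion is single-hop (standard proxy-SNP practice; no transitive
closure) with a strict r² > threshold, symmetric and idempotent. SNP
membership uses interval trees with half-open semantics; a SNP on an
unknown chromosome counts as non-overlap. Venn marginals include the
double-overlap SNPs; fractions are denominated by the total SNP count.
Enrichment is the upper-tail binomial P(X ≥ k) with the annotation's
fraction of the background genome as success probability, computed through
the stable survival function and checked in tests against exact rational
summation. The published genome-scale counts require external ENCODE/
miRcode/NHGRI downloads and are reproduced in report structure on synthetic
tracks, not in value.

## Synthetic data

A single root seed fans out to fixed per-generator substreams
(`default_rng([seed, stream_id])`), so generators are bit-stable and
adding one never perturbs another. The UTR generator plants a seed
heptamer on a uniform-ACGU background (configurable GC) and
rejection-samples until the heptamer's 6-nt core is unique on the
reference allele and absent from the alternate, guaranteeing
scanner round-trips; an in-site SNP at heptamer offset 1 cannot fully
disrupt the site (the 2–7 core survives) and is rejected with an
explanatory error. The AEI generator draws gDNA ratios lognormal around 1
and cDNA ratios lognormal around the planted fold. The track generator
places engineered TF+miR double-overlap regions and assigns SNPs to
both/TF-only/miR-only/neither categories multinomially, rejection-sampling
the "neither" class outside both tracks. The packaged TCF21-like fixture
fixes the published coordinate geometry (heptamer at 1054–1060, C>G at
1058, a G forced at 1070 so the packaged T1 cleavage records all sit on G
residues) on such a background.

What passing tests show — and do not. The generators reproduce the
*statistical structure* each stage assumes (planted sites, fold-imbalance
with lognormal noise, second-order kinetics, configured co-occurrence),
so green tests demonstrate correct inference under the stated model. They
do not show robustness to real-data features the generators omit:
non-uniform sequence composition and repeats, assay-specific biases
(probe calibration, gel quantitation nonlinearity), reversible or
facilitated annealing, realistic peak-length and LD structure, or the true
TCF21 UTR fold.

## Problem sizes and determinism

Default analysis sizes are chosen to run on one CPU in seconds to about a
minute per script: the 180-window ensemble (~45 s), 100-replicate kinetics
recovery, a 5,000-SNP toy genome, and oracle comparisons at ≤12 nt
(exhaustive structure enumeration) and 10⁴ SNPs × 10³ intervals
(all-pairs). Every stochastic step takes an explicit seed; reports render
numbers at 6 significant digits so repeated runs diff cleanly.

## Known limitations

- The folding model is intentionally compact; predicted structures are
  qualitatively reasonable but not Turner-2004-complete (no dangles,
  coaxial stacking, or special hairpins), and no partition function or
  base-pair probabilities are computed.
- The duplex model is ungapped (no bulged alignments) and scores 3′
  pairing with the same table as the seed, without a supplementary-pairing
  bonus.
- Whether the published 180-structure ensemble was split 90/90 between
  alleles is not stated; the default grid assumes symmetry, and whether
  exterior bases belong in the published "loop" class is likewise pinned
  by choice (they do here).
- LD is an input table; the package never computes r² from genotypes.
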