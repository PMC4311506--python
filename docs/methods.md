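# Methods

This note documents the models behind each stage, the defaults and why
they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical decisions that matter for reproducing output.

## Codon substitution model and the branch test

`selection` implements the Goldman–Yang (1994) codon model over the 61
sense codons of the standard code.  For codons *i* ≠ *j* differing at one
position, q_ij = π_j · κ^[transition] · ω^[nonsynonymous]; multi-position
changes have rate 0; Q is rescaled so the stationary mean rate is 1, so
branch lengths are expected substitutions per codon.  Equilibrium
frequencies are F3X4: empirical nucleotide frequencies per codon
position, multiplied and renormalized over sense codons (a 1e-10 floor
avoids zero frequencies; observed codons always have positive mass).

The likelihood is computed by Felsenstein pruning with site-pattern
compression; codons containing gaps or ambiguity are missing data
(marginalized).  P(t) comes from eigendecomposition of the
π-symmetrized rate matrix; tiny negative round-off entries are clipped
to zero.  Trees with a basal bifurcation are derooted so every edge
length is identifiable.  No per-node rescaling is performed — per-site
likelihoods stay far from underflow at the tens-of-taxa,
≤ 1 substitutions/codon scale this package targets; very deep or very
large trees would need rescaling.

Fitting maximizes lnL jointly over κ, ω (or ω_background and
ω_foreground in the two-ratio model) and all branch lengths with
L-BFGS-B.  Gradients with respect to branch lengths are analytic
(outside/inside two-pass, one extra pruning sweep for all edges);
κ and ω derivatives use forward differences with cached
eigendecompositions.  Bounds: t ∈ [1e-7, 50], κ ∈ [0.05, 100],
ω ∈ [1e-6, 60]; convergence at ftol 1e-10.  Cold starts evaluate
ω ∈ {0.1, 1, 2} at κ = 2 and optimize from the best; the two-ratio fit
is warm-started at the one-ratio optimum (which it nests), guaranteeing
lnL_alt ≥ lnL_null up to optimizer tolerance, with a cold-start retry if
the warm start stalls.  This single-optimization-from-best-start scheme
replaces running the full grid to completion for every start; on the
simulation scales below it reaches the same optimum at a third of the
cost.

The branch test compares the two fits by 2ΔlnL against χ²(1) (statistic
clamped at 0), genes are corrected by Benjamini–Hochberg (independence
form), and results with foreground dS > 3 or dN/dS > 5 are flagged and
excluded from the accelerated list.  The dS/ω post-filter is evaluated
on the foreground branch only (the filter exists to remove saturated or
unstable foreground estimates); a flag argument widens it if desired.
Per-branch dN and dS decompose t by substitution flux, with site
proportions taken from the ω = 1 mutational-opportunity matrix (the
codeml convention), so dN/dS per branch equals the fitted ω.

NG86 counting uses the unweighted variant: per-position site counts as
the fraction of the three changes that are synonymous (changes to stops
count as nonsynonymous; N + S = 3 per codon), differences averaged with
equal weight over all minimal pathways avoiding stop codons (all
pathways used in the rare all-blocked case), and Jukes–Cantor correction
d = −(3/4)·ln(1 − (4/3)p applied to both proportions; p ≥ 3/4 is
reported as saturated with ω = NaN.

## McDonald–Kreitman test

Per codon column across ≥ 2 within-species haplotypes plus an outgroup:
exactly two segregating states contribute polymorphic changes
(classified between the two within-species codons); a monomorphic column
differing from the outgroup contributes fixed changes; columns both
polymorphic and divergent count their polymorphic changes only; columns
with > 2 states are excluded and tallied as "ambiguous".  Multi-position
codon differences are apportioned by the same pathway averaging as NG86,
so counts can be fractional; they are rounded to integers for the Fisher
test (at realistic divergences multi-hit codons are rare and rounding is
a no-op).  No frequency cutoff is applied to polymorphisms — a
minor-allele filter could be added, but the standard test uses all
segregating changes.

The two-sided Fisher exact p sums hypergeometric probabilities of all
tables with the observed margins whose probability does not exceed the
observed table's (relative tolerance 1e-7 for float ties), computed from
log-binomials.  A gene is flagged only when p < 0.05 *and* the direction
is adaptive (Dn·Ps > Pn·Ds): a significant excess of nonsynonymous
polymorphism is segregating deleterious variation, not positive
selection.  NI and α are NaN whenever a required denominator (Ps, Dn,
Ds) is zero.

## Distance phylogenetics

K2P distances use per-pair observed transition/transversion fractions
with pairwise deletion of gapped/ambiguous sites (the PHYLIP DNADIST
behavior); the pooled Ts/Tv estimate is reported as metadata and is not
fed back into the distance formula.  Saturated pairs (log argument ≤ 0)
are NA and refuse NJ.  Neighbor joining is the standard Saitou–Nei
Q-criterion agglomeration; ties break to the lowest current index pair
(first row-major argmin), and a negative branch length is clamped to
zero with the deficit moved to its sibling so the pair sum is preserved.
Bootstrap resamples columns with replacement, rebuilds the NJ tree per
pseudoreplicate, and maps bipartition percentages onto the full-data NJ
tree after collapsing zero-length internal edges (an unresolved edge
should not carry a support value).  Majority-rule consensus keeps
bipartitions in > 50% of trees — such sets are always mutually
compatible — and assembles them largest-first into a tree with
percentage supports, leaving polytomies elsewhere.

## Assembly reconciliation

Matching uses global (Needleman–Wunsch) peptide alignment with BLOSUM62
and affine gaps (−11/−1) in place of BLASTP; identity is computed over
both-aligned columns and coverage as the fraction of each sequence
aligned opposite a residue.  The coverage clause of the match filter is
read symmetrically — both coverages strictly inside (70, 130) — since a
one-sided reading would leave subject coverage unbounded below and break
the reciprocal intent.  Clustering is single linkage over kept matches.

Extension and bridging assume substitution-only differences between
same-region contigs (the generator makes no indels, and the
k-mer-anchored placement is exact-coordinate): candidate placements come
from shared 16-mers, the best ungapped placement needs ≥ 100 bp overlap
at ≥ 95% identity (both configurable), and reverse-complement placements
are tried.  Anchor contigs are never truncated: a protruding clustered
contig extends an anchor end; a contig overlapping two anchors
consistently bridges them (longest total overlap wins, ties by contig
id; inconsistent orientations or overlapping anchors are skipped and
logged).  Anchor-less clusters contribute a column-majority consensus
over shift-stacked contigs (ties to the alphabetically first base);
contigs whose genes are all sample-specific are appended verbatim.  N50
is the largest L such that contigs ≥ L hold at least half the assembly.

## Variant hard filtering

The five annotation rules use strict comparisons, so records exactly on
a threshold pass.  An absent annotation cannot fail its rule (the GATK
hard-filter convention); MQ0/DP with DP absent or zero is logged and
skipped.  The missingness rule discards any record with ≥ 1 missing
genotype — the strict reading of "found in one sample" — and is
switchable off.  Filtering is per-record and therefore idempotent and
permutation-equivariant.

## Synthetic data: what it emulates, and what it does not

*Contig universes* emulate four independent fragmented assemblies of one
gene-bearing genome: a 150 kb genome, 12 stop-free genes of 450–900 bp
in evenly spaced slots, 3–8 kb fragments separated by 20–200 bp assembly
gaps, per-sample gene dropout at rate 0.2, substitution-only sequencing
error, and a 2 kb contig length cutoff.  Genes are annotated only when
wholly contained in a contig.  Not emulated: indels, repeats, paralogy,
chimeric contigs, coverage-dependent error — so passing merge tests
shows the reconciliation logic is correct, not that it is robust to
misassembly.

*Codon alignments* are exact CTMC endpoint samples (matrix exponential
per branch) under the same GY94/F3X4 machinery used for inference, with
per-branch ω.  The eight-taxon study tree spans 0.08–0.2
substitutions/codon terminal branches with the foreground at 0.2 — long
enough that a 500-codon gene carries tens of foreground events, the
regime where a branch test is meaningfully powered.  Simulating under
the inference model makes recovery tests a check of the estimator, not
of model robustness.

*Polymorphism/divergence* uses star-genealogy mutation sprinkling: event
counts are Poisson (θ·L segregating events assigned to single random
haplotypes; D·L fixed events on the outgroup lineage), each event is a
single-nucleotide codon change accepted with probability min(1, ω) if
nonsynonymous and min(1, 1/ω) if synonymous, and at most one event per
codon so truth counts are exact.  Defaults θ = 0.02/site and
D = 0.05/site over 500 codons give ~30 polymorphic and ~75 fixed
changes — enough counts for the 2×2 test to be informative.  Not
emulated: real coalescent genealogies, frequency spectra, linkage, or
segregating sites shared with the divergence lineage; the generator
validates counting and calibration, not demographic robustness.

*K2P alignments* are i.i.d. sites with equal base frequencies.  The
`tstv` parameter is the expected transition:transversion **count** ratio
R = α/2β (0.5 = all substitution classes equally likely); the codon
model's κ remains the conventional per-event rate ratio α/β.

*VCF fixtures* construct records violating exactly one named rule each,
with annotation values placed so no second rule trips.

## Problem sizes

The test suite runs the branch-model recovery at 100 replicates of 500
codons (eight taxa) and the null calibration at 200 replicates of 300
codons (six taxa), MKT calibration and power at 200 replicates each, NJ
recovery on 200 random additive matrices, and Fisher exactness over all
2×2 tables with margins ≤ 30.  `scripts/acceptance.py` recomputes the
same quantities at 20/40/200 replicates respectively, sized for a
single-CPU run of a couple of minutes.

## Known limitations

- Site and branch-site models (NSsites > 0), codon frequency models
  other than F3X4, and tree search are out of scope; topologies are
  supplied by the user.
- NG86 estimates are mildly biased against GY94-generated data at κ > 1
  (transition/transversion asymmetry is not modeled in its site counts);
  the likelihood machinery is the estimator of record.
- The merge procedure handles substitution-level divergence between
  samples; indel-bearing overlaps would need banded alignment in
  `_best_shift`.
- `classify_changes` drops codon columns with > 2 within-species states
  rather than partitioning them along a genealogy.
- No per-node likelihood rescaling (see above): intended for small
  phylogenies.
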