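# Methods

This note records the models and conventions `cubkit` implements, the
choices made where the literature is ambiguous, and what the synthetic
validation panels do and do not establish about real data.

## Sequence handling

Coding sequences are stored in the DNA alphabet (U→T on input); all
report output spells codons with U, the convention of the codon-usage
literature. Validation trims a trailing incomplete codon and removes
codons containing ambiguity symbols, tallying them — dropping rather than
imputing avoids biasing composition. Missing ATG starts and internal
stops are flagged but not altered: stop codons stay in the sequence and
are excluded where the statistics themselves demand it. The genetic code
is fixed to the standard nuclear code; virus and mammalian host both use
it.

Whole-genome statistics for segmented genomes pool the L+M+S codon
counts per strain, with each segment's stop codons removed before
pooling so no reading frame is crossed.

## Composition

The synonymous pool is the 59 sense codons excluding ATG and TGG (no
synonym). A3s/U3s/G3s/C3s are raw percentage shares of each base at
third positions of that pool; the quadruple sums to 100 by construction.
An alternative convention weights third-position bases by their
potential for synonymy (codonW offers it); the raw-share definition is
used here because it keeps the printed quadruple additive, and the two
cannot be distinguished from most published tables. GC1s/GC2s/GC3s are
computed over the same pool for internal consistency, GC12s is their
first/second mean. Overall base percentages include stop codons by
default (`include_stops=False` restricts to sense codons); published
analyses rarely state which was used, so both are exposed.

GRAVY uses the Kyte–Doolittle hydropathy constants embedded as a
documented table; ARO is the Phe+Tyr+Trp residue fraction.

## RSCU and classification

RSCU(c) = x_c / ((1/n_i) Σ_j x_j). Amino acids with zero counts yield
`nan` values and a missing-family flag, not zeros. Group-level RSCU
defaults to RSCU of pooled counts (the "overall genome" convention);
a mean-of-vectors mode exists as a sensitivity check. Classification
thresholds (1.6 / 0.6) are strict inequalities applied to unrounded
values. Ties for a family's maximum report all tied codons with a flag;
in cross-profile comparison a family tied in either profile is counted
as a non-match, which is the only reading consistent with published
virus–host comparisons where a host family is exactly balanced.

## ENC

Wright's estimator with degeneracy classes 2-fold {F,Y,H,Q,N,K,D,E,C},
3-fold {I}, 4-fold {V,P,T,A,G} and 6-fold {L,S,R} (matching the 9/1/5/3
coefficients). Per-family homozygosity F = (nΣ(nᵢ/n)² − 1)/(n − 1) is
computed only for n ≥ 2; non-positive F (possible at small n) is dropped
from the class mean. An empty 3-fold class is imputed as (F̄₂+F̄₄)/2
(Wright's recommendation); any other empty class leaves ENC undefined
rather than guessed. Values above 61 are capped.

The ENC-plot expectation is 2 + s + 29/(s² + (1−s)²). Note a structural
mismatch at the top of the curve: truly uniform within-family usage
drives ENC to 61 while the expectation peaks at 60.5, so "on the curve"
is judged with a 1-unit band (`ON_CURVE_TOL`); the below-curve flag
itself is the raw comparison enc < enc_expected.

## PR2 and neutrality

PR2 tallies third-position bases over the eight fourfold codon boxes
(CTN, GTN, TCN, CCN, ACN, GCN, CGN, GGN); for the sixfold families only
the fourfold box contributes, since "fourfold third position" is only
well-defined there. Coordinates are undefined (flagged, not zero) when a
strand pair is absent.

The neutrality fit is ordinary least squares of GC12 on GC3 with Pearson
r and a two-sided p; the slope is unit-invariant, so fractions and
percentages may be used interchangeably as long as both axes agree. The
mutation/selection split is 100·slope / 100·(1−slope), reported to two
decimals.

## CAI, RCDI, SiD

Relative adaptiveness w is the reference frequency over the family
maximum; reference codons with zero frequency are floored at w = 0.01
(CAIcal's convention, exposed as a parameter) and flagged. CAI is the
geometric mean of w over the 59 scoreable codons, computed in log space.
RCDI follows the eRCDI definition: the usage-weighted mean of
per-amino-acid relative-frequency ratios, Σ(CiFa/CiFh·N_c)/N, which is
exactly 1 against a reference built from the query's own counts.
Zero reference ratios are floored at 1% of the family's smallest
positive frequency with a logged warning. SiD uses the cosine form
R = ⟨a,b⟩/(|a||b|) on the 59-codon RSCU vectors and D = (1−R)/2, which
keeps D in [0, 1] with D = 0 for proportional usage; SiD is computed
between group-level RSCU vectors, as the index is defined on overall
usage.

## Correspondence analysis and correlations

CA takes the strains × 59 RSCU matrix directly as the correspondence
table (the codonW convention; a raw-counts mode exists). Standard
chi-square-metric CA: SVD of D_r^{-1/2}(P − rcᵀ)D_c^{-1/2}, principal
coordinates as mass-rescaled singular vectors times singular values,
inertia fractions as normalized squared singular values; total inertia
equals the Pearson chi-square over the grand total. Axis signs are fixed
by making the largest-magnitude column loading positive, so results are
backend-independent. All-zero codon columns are dropped with a warning;
singular values below ~machine epsilon are treated as rank noise, so a
table of proportional rows reports exactly zero inertia.

Correlation matrices use Spearman's rho with average-rank ties and
two-sided p-values, uncorrected by default (a Benjamini–Hochberg flag
exists). Group contrasts use Mann–Whitney U (two groups, asymptotic
with continuity correction) or one-way ANOVA at α = 0.05. Note a
small-sample limit of the rank test: with three observations per group
the smallest achievable two-sided Mann–Whitney p is 0.1, so significance
at 0.05 requires at least four per group no matter how separated the
groups are.

## Synthetic panels

The generator emulates only the codon-usage statistics the analyses
consume, not any real genome. Codons are drawn per amino acid from
(1 − w)·mutation kernel + w·selection kernel. The mutation kernel gives
the family's G/C-ending codons total mass gc3 (split equally) and the
A/T-ending codons 1 − gc3, making the third-position G+C marginal equal
to the parameter in every family, including the odd-sized Ile family.
The selection kernel is the target RSCU normalized within each family,
so at w = 1 the empirical RSCU converges to the target. First and second
positions are fixed by the amino-acid choice; an optional GC12 target is
met by exponentially tilting the amino-acid weights of the degenerate
families (solved by bracketed root-finding), which is what makes
neutrality-plot panels with a prescribed GC12-on-GC3 slope possible.
One seeded NumPy generator drives a whole panel; output is byte-stable.

Defaults mirror a hantavirus whole-genome panel: 88 strains, L/M/S of
2151/1135/429 codons, gc3 = 0.31, GC12 operating point 0.425, uniform
protein model over the 18 degenerate amino acids plus low-rate Met/Trp
so every ENC class is populated. Tests and examples use smaller panels
(tens of strains, hundreds to thousands of codons) — large enough for
the quoted recovery bands, chosen as this package's own validation
sizes.

What passing synthetic tests establish: the estimators recover the
parameters of the generating model (third-position GC, RSCU targets,
GC12/GC3 slopes, group structure) at the stated sample sizes. What they
do not establish: behavior under features real data have and the
generator lacks — phylogenetic correlation between strains, within-gene
heterogeneity, dinucleotide constraints, amino-acid composition drift,
sequencing artifacts. Conclusions about real genomes still require the
usual caution about non-independence of related strains.

## Numerical notes

* RSCU sampling error scales with family degeneracy (a sixfold codon's
  RSCU is 6× its within-family frequency), so uniform convergence bounds
  across all 59 codons need several hundred thousand codons; tests size
  accordingly.
* CAI is computed as exp(mean log w) to avoid underflow on long genes.
* SiD is clamped to [0, 1] against cosine rounding drift.
* Degenerate inputs fail loudly: empty sequences, all-zero reference
  families, zero-norm RSCU vectors and constant regression abscissas all
  raise with the offending record or amino acid named.
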