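# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `iripsim`.

## Genetic map and coordinates

Coordinates are continuous centimorgans, 0-based at the start of each
chromosome. The built-in rice map has 12 chromosomes totalling 1526.8 cM.
Marker grids place fully informative markers at 0, s, 2s, … up to the last
whole multiple of the spacing s on each chromosome; at 1 cM this gives 1532
markers. Marker endpoints are a convention (nothing forces a marker at
0 cM); starting at 0 and ending at ⌊L⌋ makes counts reproducible
(⌊L⌋+1 per chromosome). Drift metrics are evaluated on a 0.1-cM bin grid
(bin centres), while breakpoints themselves are stored continuously, so
segment arithmetic is exact and bin-wise metrics are grid-faithful.

## Meiosis

Crossover counts per chromosome per gamete are Poisson with mean L/100 —
the map length in Morgans, the standard map-length definition under which
100 cM equals one expected crossover per gamete. Crossover positions are
i.i.d. uniform on (0, L); there is no chiasma interference, no sex
difference, no mutation, and no recombination hot/cold spots (the map is a
linkage map, so simulating on map coordinates sidesteps physical-position
rate variation by construction). The haplotype a gamete starts from is a
fair coin per chromosome, and chromosomes segregate independently.
Crossovers are sampled per gamete rather than per bivalent; at the level of
single gametes the two models are equivalent for all quantities computed
here. Coincident crossover positions (a measure-zero event) collapse the
empty interval between them; adjacent segments with equal founder labels
are merged, so haplotypes are always normalized partitions.

Two exact shortcuts matter for performance: a crossover between two
genetically identical haplotypes returns the same haplotype (so chromosomes
that have fixed during selfing stop paying for recombination), and
chromosome objects are immutable and shared between generations.

## Breeding scheme

- **Mixing.** The eight-way funnel is fixed as P1×P2 / P3×P4 / P5×P6 /
  P7×P8. Founders are inbred, so all F1s of a pair are genetically
  identical; independent meioses begin at the four-way generation, where
  `n_crossing` four-way plants per funnel half are generated and paired
  disjointly one-to-one to produce `n_crossing` eight-way individuals.
  Each eight-way individual therefore carries one (P1–P4) and one (P5–P8)
  gamete. Two-way designs skip the mixing stage (the population starts as
  F1 copies; meioses are independent from the next generation).
- **Recurrent crossing.** Each cycle partitions the population into random
  disjoint pairs; each pair leaves exactly two progeny. This keeps the
  census size constant and, because every parent contributes exactly two
  gametes, gives an effective size close to 2N.
- **Selfing.** Seven generations by default (expected residual
  heterozygosity 0.5⁷ ≈ 0.78%). Generation 1 uses multiple-seed descent:
  ⌈n_final/n⌉ selfed seeds per plant, truncated uniformly at random to
  exactly n_final lines; generations 2+ are single-seed descent. The
  per-plant seed count is a design choice (only the mechanism, not the
  count, is standard); uniform truncation keeps plant contributions
  exchangeable.

The default study conditions are a crossing population of n = 100 and 800
final lines (two-way comparisons use 200 lines per population, four
populations covering all eight founders).

### Chromosome marginalization

Given the pedigree, chromosomes are conditionally independent (independent
Poisson counts and starting coins per chromosome), and the pedigree itself
is generated without reference to genotypes. The marginal distribution of
any chromosome subset in a simulated population is therefore exactly the
distribution obtained by simulating only those chromosomes. The power
experiments exploit this: linked-QTL runs simulate chromosome 1 only (plus
chromosome 2 for the unlinked baseline), and the multi-QTL experiments
simulate only the chromosomes that carry QTLs. This is an exact
marginalization, not an approximation; genome-wide null thresholds are of
course computed on the full genome.

## Genome-structure metrics

Non-recombinant segments are maximal single-founder runs, counted on one
haplotype per inbred line (lines are > 99% homozygous; residual
heterozygosity is reported separately rather than folded into segment
counts, since no standard rule exists for mixed stretches). Segment
statistics on final lines reflect all recombination accumulated through
mixing, intercrossing and selfing. Drift is the percentage of 0.1-cM bins
at which fewer than the full founder complement survives among all
haplotypes of the population.

Under these definitions the simulation gives, for the standard conditions:
drift of the n = 100 crossing population below 1% at 10 cycles but
~12–14% at 20 cycles, and a mean segment length of ~12.3 cM for the
4-cycle eight-way design after selfing (~15.6 cM both for 2 cycles
post-selfing and for 4 cycles measured before selfing). An independent
single-locus pedigree simulation (which needs no genome at all, because
single-locus genealogy is independent of recombination) reproduces the
20-cycle drift value, confirming that these numbers are properties of the
stated breeding scheme itself.

## QTL models and calibration

Only additive effects: a QTL assigns each founder a homozygous genotypic
value; heterozygotes take the midpoint; dominance and epistasis are zero;
QTLs are completely linked to a marker. Multi-allelic patterns assign
equally spaced class levels a·(c−1−j)/(c−1) for class j of c classes — the
rule that regenerates the published calibration tables (e.g. 2:2:2:2 →
a, 2a/3, a/3, 0). Scale calibration solves Var(g) = V (variance
parameterization, founder values at equal frequency 1/8 in inbred lines)
or Var(g) = Vₑ·v/(1−v) (PVE parameterization). Calibration assumes the
idealized final population — equal founder frequencies and full
homozygosity; realized frequencies drift, so realized PVE varies between
replicates, exactly as in a real experiment.

The multi-QTL experiments place QTLs at known rice QTL positions (11
blast-resistance loci, 9 heading-date loci, 10 seed-morphology loci) with
experiment-specific multisets of allele patterns and genetic variances;
the pattern↔variance pairing, the pattern↔locus assignment and the
founder-to-class permutation are re-randomized each replicate, and the
noise is N(0, 0.5) (variance 0.5, consistent with reading "N(0, 1)" as
unit variance).

## Scans, detection and thresholds

Marker genotypes are the unordered founder-label pairs; residual
heterozygote classes are kept as their own levels (affects < 1% of lines
and keeps the sample size fixed) rather than dropped. The single-locus
statistic is the one-way ANOVA omnibus F-test; the two-locus statistic is
the overall (model-vs-intercept) F-test of the additive two-factor model —
chosen because M₂ measures the fit of the two-QTL model as a whole, not a
partial effect. Monomorphic markers are flagged NaN and excluded from
maxima; confounded pairs lose rank, which is handled by rank-aware degrees
of freedom (rank from the least-squares solve), and pairs with no model or
residual degrees of freedom are excluded.

Both tests are computed from sufficient statistics — per-class counts and
phenotype sums (single locus), cross-cell counts/sums and small normal
equations (two-locus) — which is algebraically identical to the
least-squares fits (verified against statsmodels/scipy oracles to 1e-8)
and fast enough to run thousands of genome-wide null scans. −log₁₀P is
computed through `scipy.special.fdtrc`, falling back to the log survival
function where it underflows. Constant phenotypes return 0 by convention
(F = 0). Argmax ties resolve to the smallest (chromosome, position).

Detection: single-QTL rule — max single-locus −log₁₀P within 20 cM of the
true position exceeds T₁ (for a QTL at chromosome 1, 90 cM this is the
70–110 cM window); two-QTL separation rule — M₂ > T₂ and M₂ᵥₛ₁ > T₂ᵥₛ₁
over the 70–(110+x) cM chromosome-1 search range, where x is the QTL
spacing. Signals outside the window count as false positives, not
detections.

Thresholds are 95th percentiles of GEV fits (maximum likelihood,
`scipy.stats.genextreme`) to per-replicate null maxima; a Gumbel fit is the
recorded fallback if the three-parameter optimization fails. Null
replicates reuse one simulated population with fresh N(0, 1) phenotypes
(the null maxima distribution depends on the population's LD structure,
which one n = 800 realization captures well; a fresh-population mode
exists behind a flag). A library of reference thresholds for the standard
designs (from 10,000-replicate null runs) ships with the package so that
power experiments are decoupled from the null stage; at 1,000 replicates
the recomputed cycle-0 T₁ agrees with the reference 4.03 to within ~0.1.

## Power experiments

Defaults follow the study conditions: 400 replicates for power curves
(overridable; the desk-scale acceptance runs use 100), thresholds from the
reference set, N(0, 1) noise for one- and two-QTL experiments. The
"highest frequency" carrier arrangement puts the carrier allele on founders
P1, P3, P5, P7 (one per funnel pair, maximizing carrier/non-carrier
heterozygosity through the funnel) and "lowest" on P1–P4 (one funnel half).
The unlinked baseline for relative power moves QTL2 to chromosome 2 at
90 cM with identical effects and thresholds — the natural
"same architecture, no linkage" control; detection then uses the union of
the two QTLs' 20-cM windows. Common-random-number comparisons (same seed
across configurations) are used in monotonicity tests only; production
runs are independent.

## What desk-scale agreement does and does not show

The simulator reproduces the calibration tables exactly, the selfing
fixation and drift-at-10-cycles claims, the genome-wide threshold
(T₁ ≈ 4.1 vs 4.03), near-zero separation power for small coupling pairs,
~9.7/11 detected QTLs in the blast-resistance experiment, and < 50%
relative power for 20-cM repulsion pairs at cycle 0. Two structural
quantities land near but not on the published anchors (drift ~13% vs
"about 10%" at 20 cycles; mean segment length 12.3 vs 13.9 cM at 4
cycles); the independent pedigree oracle indicates these are the exact
values implied by the stated breeding scheme, so the residual gap lies
between that scheme and the published figures, not in this implementation.

All genomes are idealized founder mosaics: markers are fully informative
and error-free, founder origin needs no HMM reconstruction, there is no
selection, mortality, genotyping error, QTL×environment interaction,
dominance or epistasis. Power estimates are therefore upper bounds
relative to real experiments, and comparisons across designs are more
trustworthy than absolute values.
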