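# Methods

## The grazing model and its assumptions

The bottle-incubation inference assumes each prey taxon follows an
exponential trajectory over the incubation: C(t) = C₀·e^{kt} in
predator-free controls and C(t) = C₀·e^{(k−g)t} in predator
treatments, with k the apparent growth coefficient (d⁻¹, lumping true
growth, mortality other than the added predators, and bottle effects)
and g the added predators' grazing coefficient (d⁻¹).  Both are
assumed constant over the incubation, and bottles are assumed well
mixed.  Ingestion per predator uses the time-averaged concentration of
the exponential trajectory, ⟨C⟩ = C₀·(e^{(k−g)t} − 1)/((k−g)·t),
clearance F = g·V/n and I = F·⟨C⟩.  This is the canonical exponential
formulation for control/treatment bottle designs and is dimensionally
consistent with all the units carried by the pipeline.

Estimation layout: C₀ is the mean over the T0 analytical replicates;
one k per taxon from the mean of the T24 controls; g, ⟨C⟩, F and I per
treatment replicate, so the reported SD reflects experimental
(between-bottle) variability.  A taxon present at T0 but counted as 0
in a T24 treatment bottle is set to 1 cell L⁻¹ (the smallest recordable
concentration) so the logarithm is defined; taxa absent at T0, or
absent from all T24 controls (k undefined), are excluded with a log
entry.  Negative mean ingestion (prey apparently benefiting from
predators) fails the 2×SD reporting filter by construction, since the
filter requires mean I > 2·SD *and* mean I > 0.

Degenerate-input handling: ⟨C⟩ → C₀ continuously as k → g; the limit
is taken explicitly when |k−g| < 10⁻¹².

## Carbon conversions

Protist per-cell quotas follow the standard allometric volume-carbon
regressions, pg C = 0.288·V^0.811 for diatoms and pg C = 0.216·V^0.939
for other protists.  The bundled reference table assigns the diatom
model to two taxa conventionally listed with the coccolithophores
(*Cocconeis* sp., *Calciosolenia murray*): only the diatom equation
reconciles their tabulated biomasses with their abundances and
biovolumes, so the assignment follows the numbers rather than the
group label, and the `carbon_model` column makes the override explicit
per taxon.  Microplankton biomass columns on the reference table's
"×10 μg C" scale are read as ×10⁻¹ μg C — the only reading consistent
with abundance × per-cell quota; the package's column names say
`_x10ugC` and all arithmetic is done in pg internally, converting to μg
only at reporting.

Nanoplankton size classes (2–3, 3–5, 5–10 μm) are approximated as
spheres at the arithmetic midpoints 2.5, 4.0, 7.5 μm (the sources are
silent on the class representative) × 183 fg C μm⁻³.  Prokaryotes use
20 fg C cell⁻¹ (heterotrophs) and 200 fg C cell⁻¹ (*Synechococcus*).

## Assay conversions

Leucine incorporation: net DPM = mean of replicate aliquots minus one
killed control, floored at 0; moles via 1 Ci = 2.22×10¹² DPM and the
tracer specific activity (default 52.9 Ci mmol⁻¹); scaled by aliquot
volume and incubation time to nmol Leu L⁻¹ h⁻¹; carbon via 1.55 kg C
mol⁻¹ Leu × isotope dilution 2 (both overridable in the config).  The
1.55 base constant is the standard leucine-to-protein-carbon factor;
only the dilution factor is independently constrained here.

Aminopeptidase activity: two-point (start/end) rate estimation over the
1-h incubation rather than a regression over a time course, matching
the stopped-assay protocol; blank-corrected fluorescence increase ÷
calibration slope ÷ time.  Calibration is ordinary least squares with a
free intercept (blanks handle background separately, so the line is not
forced through the origin).  Predator-associated consortium rates:
vial rate × dilution (10) − ambient seawater rate, per individual.
Negative corrected rates floor at 0 with a logged warning — expected
behaviour at low signal, not an error.

## Community statistics

All resemblance statistics are implemented from their definitions with
explicit conventions, and cross-checked in the test suite against
scipy (Bray–Curtis, average linkage, Mann–Whitney) and scikit-bio
(ANOSIM R):

- **Bray–Curtis** on the % scale, computed on rarefied full-resolution
  relative-abundance vectors; the <1 % → 'Others' lumping is
  presentation-level only and never feeds the similarity input.
- **UPGMA** (group-average linkage) on dissimilarity 100 − S, with a
  deterministic tie-break by the lexicographically smallest member
  label; merge heights are monotone by the linkage's properties.  The
  Newick export is ultrametric with node heights at half the merge
  dissimilarity.
- **ANOSIM** uses dissimilarity ranks with average-rank ties and
  R = (r̄_between − r̄_within)/(n(n−1)/4), the standard rank-based
  denominator (R = 1 when all between-group dissimilarities exceed all
  within-group ones).  The test is one-sided (large R).  When the
  number of distinct label arrangements does not exceed the requested
  permutation count the null is enumerated exhaustively and
  p = #{R_perm ≥ R_obs}/N (identity included); otherwise arrangements
  are sampled with the run seed and p = (1 + hits)/(1 + permutations).
- **Mann–Whitney U** from rank sums with average-rank ties; two-sided p
  by full enumeration of all C(m+n, m) group assignments when
  m+n ≤ 16, counting arrangements at least as extreme in |U − mn/2|;
  tie-corrected normal approximation with continuity correction
  otherwise.  Note the exact two-sided test at n = m = 3 cannot produce
  p < 0.1; reports of p < 0.05 at that size necessarily come from some
  other variant, which this package deliberately does not emulate.
- **Rarefaction** subsamples each sample without replacement
  (multivariate hypergeometric) to a common depth, averaging counts
  over repeats (default 100) and rounding half-up; the seed is part of
  the run configuration.

## The synthetic generator

The generator emulates the statistical structure the estimators
assume, not the ocean: counting error is Poisson on the cells
enumerated in a finite counted subvolume (default 0.5 L, the full
settled volume — an upper bound, hence a lower bound on counting
noise); OTU counts are Dirichlet-multinomial with group-level profiles
and a concentration parameter controlling replicate tightness; assay
signals are generated by inverting the conversion chains from known
rates with Poisson (DPM) or Gaussian (fluorescence) noise.  Every
generator is a deterministic function of (truth, seed), and with noise
disabled each estimator recovers its truth exactly — the tests assert
this identity.

The `table1_like` preset encodes the bundled 28-taxon reference table:
C₀ from the tabulated T0 abundances, controls held constant (k = 0),
and g solved per taxon so the noise-free ingestion equals the
tabulated per-ephyra rate.  For three low-abundance taxa the tabulated
rate exceeds the zero-growth ceiling (V/n)·C₀/t, which is only
reachable if grazed prey are replenished; those taxa get near-total
depletion (g = 5 d⁻¹) with k solved instead.  The assay truth defaults
sit at the study's T0 magnitudes (HCP 0.23 μg C L⁻¹ h⁻¹,
aminopeptidase 39 nM h⁻¹ ambient, ≈1083 nM h⁻¹ ind⁻¹ associated).

What passing tests therefore show: the estimators are correct inverses
of the stated forward models and are well calibrated under Poisson /
Dirichlet-multinomial / Gaussian noise at the study's magnitudes.  What
they do not show: robustness to real-data features the generator omits
— taxonomic misassignment, counting biases, colony/chain ingestion
(cells-per-colony is carried as annotation only), chimeras and
sequencing error, non-exponential prey dynamics, or predator handling
effects.

## Problem sizes and numerical choices in the test suite

Stochastic checks use fixed seeds throughout: 100 simulated microcosm
experiments for parameter recovery and filter specificity; 1000
null-label ANOSIM simulations for type-I calibration, on a 5+4 design
whose exhaustive permutation grid (126 arrangements) admits a nominal
level near 0.05 (equal 4+4 groups cap the achievable level at ≈0.03
because of the group-swap symmetry); 1000 draws for assay
unbiasedness; exact Mann–Whitney oracles enumerated for all m, n ≤ 5.
Hypothesis-based property tests are derandomized.

## Known limitations

- The grazing model cannot separate k from g within a single treatment
  bottle; k is identified only through the controls, and control/
  treatment bottle effects are assumed identical.
- Recovery precision for low-abundance taxa (C₀ ≲ 20 cells L⁻¹) is
  limited by Poisson counting noise at any realistic counted volume;
  single-replicate grazing coefficients for such taxa should be read
  with their SDs.
- The 1-cell L⁻¹ substitution for prey absent at T24 bounds, rather
  than estimates, deep depletion; grazing coefficients at the
  substitution boundary are lower bounds.
- DESeq-style differential-abundance testing, OTU picking, taxonomy
  assignment and ordination are out of scope; the package starts from
  a finished OTU table.
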