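# Methods

This note documents the models behind `cfdna-fragscore`, the choices made
where the design was genuinely open, and what the synthetic data do and do
not establish about real samples.

## Size-dependent PCR detectability

A PCR product of length *A* can only be templated by a cfDNA fragment that
fully contains the amplicon interval. We model fragmentation breakpoints as
uniform on the genome, so of the *L* equally likely phases of a length-*L*
fragment relative to a fixed *A*-bp window, exactly *L* − *A* + 1 leave the
window intact:

    P(contain) = max(0, L − A + 1) / L.

This is 0 for *L* < *A*, 1/*A* at *L* = *A*, and → 1 as *L*/*A* → ∞. The
package keeps a brute-force simulator (`simulate_containment_fraction`)
that fragments an infinite molecule on a random-phase grid and counts
window hits; the closed form is tested against it across a grid of lengths.
The model deliberately ignores sequence effects (GC-rich templates,
polymerase drop-off) — it is a geometry-only formalization.

Expected amplifiable copies in a reaction combine mass, genomic copy
number, and the containment mean over the sample's empirical length
distribution:

    copies = (mass / 3.3 pg) × copies_per_haploid_genome × E_L[P(contain)].

The 3.3 pg haploid genome mass gives the familiar ~303 copies per nanogram.

## ddPCR quantification

Wells are quantified by the Poisson occupancy law λ = −ln(1 − p) with
p the positive-droplet fraction; copies/µL = λ / 0.85 nL (droplet volume),
copies/ng = copies/µL × 20 µL (reaction volume) / input mass. The 95% CI is
a Wilson interval on p mapped through −ln(1 − p); Wilson was chosen for its
behavior at p near 0 and 1, and the map is monotone so the interval
transforms directly. Saturated wells (p = 1) are flagged and reported with
infinite point estimate and upper bound — never a silent number. Wells
under 8,000 accepted droplets are flagged low-quality but still
quantified. Droplet volume and reaction volume are conventions of the
common 20,000-droplet instruments and are parameters, not constants baked
into results.

The forward simulator thins expected copies to the fraction of the
reaction volume actually partitioned (20,000 × 0.85 nL of 20 µL), draws a
Poisson copy count, and multinomially assigns copies to droplets. This
makes the estimator consistent: recovered copies/ng matches the generative
expectation, verified by a 200-replicate coverage test.

## ∆∆Ct contamination scoring

Per sample, ∆Ct = mean Cq(612 bp) − mean Cq(106 bp) over detected
replicates (arithmetic mean; Cq ≥ 40 cycles is a non-detect). Against the
50%-HMW control standard, ∆∆Ct = ∆Ct_sample − ∆Ct_control and
RNE = E^(−∆∆Ct); with distinct per-assay efficiencies the Pfaffl form
E_long^(∆Cq_long) / E_short^(∆Cq_short) is used, which collapses to the
former at equal efficiency. The contamination percentage is RNE × 50%, so
the control scores exactly 50% by construction. Efficiencies default to
2.0 (exact doubling) because assay-specific standard-curve efficiencies
are instrument- and lot-dependent; they are per-row inputs. A sample whose
long amplicon never amplifies is scored at the last cycle and flagged
`below_loq` — the resulting percent is an upper bound, never silently 0.

Two detectability regimes matter:

* **Idealized model** (`idealized_panel_cq`): the short amplicon amplifies
  from *all* DNA mass and the long amplicon only from the unfragmented
  mass. Under this model the algebra is exact and the 1/5/25/50% panel is
  recovered perfectly — this is the calibration contract of the scoring
  procedure, and what the acceptance script recomputes.
* **Realistic containment model**: when Cq values are generated from the
  containment geometry (short amplicon detects ~38% of 170 bp fragments,
  long amplicon essentially only HMW molecules), the fraction-dependent
  part of ∆∆Ct is the HMW:fragmented *odds*, so the recovered percent is
  ≈ 50·f/(1 − f). That under-reads the true mass percent for fractions
  below the control (0.5% at a true 1%, 17% at a true 25%) and is exact at
  50%. The direction and magnitude of this bias are pinned by a regression
  test; in practice the score remains strictly monotone in the true
  fraction, which is what a screening threshold needs.

## Electrophoresis analysis

Molar density is mass density / (L × 650 g/mol/bp); integrals above the
106 bp and 612 bp cutoffs use trapezoidal quadrature with interpolated cut
points on the instrument's grid (1–25 bp spacing for synthetic traces).
The above-cutoff-integral definition of the molarity ratio was chosen over
vendor "smear region" tables; the ratio is scale-invariant and returns an
explicit no-HMW sentinel (∞) when nothing lies above 612 bp. Peak calling
smooths with a Savitzky–Golay window of 15 bp (polynomial order 2) before
a local-maxima search restricted to the 360–400 and 540–600 bp
di-/tri-nucleosome windows.

## Interval summarization

Fragments are assigned to regions by midpoint containment in 0-based
half-open coordinates. Midpoint assignment (rather than any-overlap or
full containment) guarantees a partition on disjoint regions: no fragment
is double-counted, at the price of dropping fragments straddling a region
edge with their midpoint outside. Overlapping region definitions are
rejected at construction. Quartiles use linear interpolation (the numpy
default), so {1,2,3,4} has median 2.5. Strand is ignored — cfDNA fragments
are double-stranded. The shipped OCR1/OCR2/CCR BED is a synthetic
placeholder (the assay coordinates are not published) and exists only to
exercise the machinery.

## Cohort statistics

`levene_test` defaults to mean-centering (the classic Levene statistic;
median-centering, i.e. Brown–Forsythe, by flag). `rank_sum_test` uses the
exact two-sided null when both arms have n ≤ 8 without ties, otherwise the
tie-corrected normal approximation without continuity correction (so
identical samples give p = 1 exactly). `pearson_with_ci` reports r, R² and
Fisher-z intervals; the R² interval squares the r-interval endpoints, with
lower bound 0 whenever the r-interval spans 0 (the sign is unresolved
there). No multiple-testing correction is applied by default; a
Benjamini–Hochberg helper exists. These wrap scipy/statsmodels routines
and are validated against independent arithmetic (hand-computed Levene F,
exhaustive rank-sum enumeration) and coverage/power simulations.

## Synthetic-data generator

Mixture components are truncated-at-1-bp Gaussians (location = mean bp,
scale = SD bp, 0 allowed for point masses) or lognormals (location =
median bp, scale = log-SD) — the latter for HMW genomic DNA, whose spread
covers orders of magnitude. Defaults:

| population | spec | rationale |
| --- | --- | --- |
| healthy cfDNA | Gaussian(170, 20) | mononucleosomal peak; 20 bp SD keeps the IQR plausible for plasma |
| CRC-like cfDNA | 0.3 × Gaussian(145, 15) + 0.7 × Gaussian(170, 20) | cancer plasma is enriched in sub-mononucleosomal fragments |
| sheared standard | Gaussian(170, 35) | ultrasonically sheared DNA, mean ~170 bp, broader than native cfDNA |
| storage-degraded | 0.5/0.3/0.2 at 170/380/570 bp | mono/di/tri nucleosome ladder from leukocyte apoptosis |
| HMW DNA | lognormal median 15 kb, log-SD 0.5 | intact genomic DNA; must exceed 612 bp by orders of magnitude (true length distribution in stored blood is unknown — this is an assumption, configurable) |

`mix_by_mass` treats mass as total base-pair content: all of population A
is kept and B fragments are resampled until the cumulative bp is as close
to the target mass share as a whole fragment allows, which keeps realized
panel fractions within a couple of percent even when single HMW molecules
carry ~90 mononucleosome-equivalents of mass. The calibration panel mixes
the sheared standard with HMW DNA at 1/5/25/50% unfragmented mass.

The qPCR forward model is Cq = intercept − log_E(copies) + Gaussian
replicate noise (default intercept 37 cycles ≈ single-copy crossing;
noise SD 0.2 cycles in the scenarios), with non-detects at ≥ 40 cycles.
The electropherogram renderer spreads each fragment's mass (∝ length)
over the size grid with a Gaussian kernel (default 10 bp bandwidth).

In the cohort scenario, per-sample/per-region amplifiable yield is a
lognormal multiplier (log-SD 0.15 sample-wide plus 0.45 at open-chromatin
loci vs 0.10 at the pericentromeric locus): open chromatin's variable
nucleosome occupancy makes local fragment survival vary more across
individuals, which is what makes the short−long *differences* more
dispersed at OCRs (Levene) while the short/long *ratios*, in which the
yield cancels, carry the healthy-vs-cancer shift (rank-sum). The CRC
short-component weight is 0.30 vs 0.05 in healthy samples, in every
region.

What the generator does **not** emulate: sequencing-style end motifs and
GC bias, droplet rain/partial amplification, qPCR inhibitors, ladder/marker
artifacts of real electrophoresis, and genuinely unknown biology such as
the true HMW length distribution in stored blood. Passing tests therefore
demonstrate internal consistency of the estimators and scoring algebra
under a plausible generative model — not clinical performance on real
plasma.

## Problem sizes and numerics

Simulation-based tests use 3,000–50,000 fragments per population, 20,000
droplets per well, and 200–2,000 replicates for coverage/power checks —
enough for the binomial tolerances asserted (3–4 SDs) while keeping the
full suite around ten seconds. Quadrature tolerances are relative 10⁻²–10⁻³
against closed-form totals; determinism is bit-exact for equal seeds (all
randomness flows through explicit `numpy` generators; no global state).
Degenerate inputs have defined behavior throughout: zero-variance mixture
components, empty regions, saturated ddPCR wells, all-non-detect long
amplicons, zero-mass reactions, traces with no HMW material.
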