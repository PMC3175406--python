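# Methods

## The model

Bone collagen records the protein component of diet over roughly the last
decade of life, trophically enriched relative to the diet itself: collagen
sits 0.8–1.3 ‰ above the diet in δ¹³C and 3–5 ‰ in δ¹⁵N. The package works
in *diet space*: the mean collagen point of a hominid cohort minus a point
enrichment offset (range midpoints 1.05 ‰ and 4.0 ‰ by default; the ranges
are config-exposed so sensitivity runs at the endpoints are one flag away).

Three food sources span the mixing triangle:

- **fish** (source 1): a fixed literature-style signature, high δ¹⁵N. The
  default is mean (−20.0, 12.0) ‰ with SD (0.5, 1.0) ‰, inside the
  freshwater-fish compartment and positioned so the three source roles
  (fish highest δ¹⁵N, meat highest δ¹³C, plants lowest on both axes) hold
  against the herbivore-derived sources.
- **meat** (source 2): the herbivore source, computed from the faunal
  records of the cohort's period and spatial cluster as the *unweighted*
  average of per-taxon means and per-taxon SDs. Equal weights per taxon are
  deliberate: a species sampled 230 times must not dominate one sampled 88
  times. Condition switches remove reindeer or horse, or keep reindeer
  alone, and the ±1 SD δ¹⁵N sensitivity conditions shift the source mean by
  one source-SD.
- **plants** (source 3): the herbivore source minus the
  herbivore-over-plant enrichment, with the SD carried through unchanged
  (derivation shifts the mean; the herbivore spread is the only spread
  available). Because the same 0.8–1.3/3–5 ‰ offsets are quoted for this
  step in the modelling context, they are the default here too; a preset
  with the 5 ‰-carbon plant→herbivore enrichment ships alongside
  (`HERBIVORE_PLANT_OFFSETS`).

When the δ¹⁵N shift conditions are active, plants are derived from the
*shifted* herbivore source, so the whole herbivore-derived side of the
triangle moves coherently.

Two geometry modes place the vertices. `average` uses the source means.
`extended` pushes each vertex coordinate `sd_multiplier` (default 1) SDs
away from the mixture on each axis — a formalisation of building the
construction on "the largest isotopic values of sources around the
mixture". This per-axis rule is an interpretation, not a theorem-grade
radial expansion: with unequal source SDs the extended edges rotate, so the
extended triangle always has at least the average area and keeps interior
mixtures interior, but can cut marginally inside an average *vertex* in
thin configurations. Geometry validation reports (rather than raises on)
an outside mixture and source-role violations; only collinear vertices are
a hard error.

## Feasible-mixture enumeration

The determined system (3 sources, 2 isotopes, Σp = 1) has a unique
barycentric solution, but the field's convention is to report the whole
set of near-feasible compositions. The enumerator visits every integer
composition (a, b, c) with a+b+c = 1/increment (5 151 points at the 1 %
default), predicts each composition's mixture as the proportion-weighted
vertex average, and keeps compositions whose deviation from the observed
mixture is within the mass-balance tolerance (default 0.1 ‰, per-isotope
maximum; Euclidean offered). Solutions are stored as integer grid counts so
proportions never drift; summaries report mean, min, max and 1st/99th
percentiles per source. An empty set returns the minimum achieved deviation
as a diagnostic, never a silent empty table.

In the pipeline, an empty set at the base tolerance triggers tolerance
doubling up to 0.5 ‰ before the cell is declared infeasible — the standard
practice with feasible-mixture tools, needed here because the construction
makes the triangle inherently thin in δ¹³C (plants sit one enrichment
offset left of meat, with fish between), so small mixture shifts can leave
the strict 0.1 ‰ band. The tolerance actually used is recorded in every
result. Cells that stay infeasible, or that lack a source or a mixture,
become explicit NA results with reasons and propagate as NA cells of the
comparison table.

## Statistics

**Homogeneity screening.** Within a spatial cluster and chronological
group, each faunal type's per-site values are compared per isotope with the
tie-corrected midrank Kruskal-Wallis H. For two groups with pooled N ≤ 10
the p-value is the exact permutation tail (all C(N, n₁) assignments);
otherwise the χ²(k−1) approximation is used. All pooled values identical
gives H = 0, p = 1 by convention. Screening level 0.01; fewer than two
sites yields an explicit "untestable" status. Heterogeneous groups get
divergent sites flagged by iterating: drop the site whose mean is farthest
from the grand mean in pooled-SD units, re-test, stop at homogeneity or two
sites. This heuristic is a declared automation of what is otherwise a
manual judgement; a config exclusion list (which ships with the three
published divergent bovid sites) takes precedence over it.

**Cohort comparison.** Mean feasible contributions (the quantity the
summary diagrams report) are converted to integer resource units by
largest-remainder rounding to a 100-unit total — equal protein weight per
source by default, with an optional per-source protein-weight vector
exposing the under-specified "protein intake" weighting for sensitivity
analyses. Pairwise 2×3 Pearson χ² (no continuity correction; sources with
zero counts in both cohorts are dropped with df reduced and noted) is
applied to the three cohort pairs; significance uses the Bonferroni cutoff
α/m with α = 0.05, m = 3, applied at its 3-decimal rounding, 0.017.

## The synthetic food web

The generator emulates the structure the analysis assumes: compartment
ranges for plants (−35…−20 / 0…6 ‰), herbivores (−30…−18 / 3…8 ‰),
carnivores (−24…−16 / 7…13 ‰) and freshwater fish (−23…−19 / 9…15 ‰);
per-taxon herbivore means at the ¹³C-enriched end of the herbivore
compartment, where glacial European reindeer/horse/bovid collagen sits
(reindeer (−18.8, 4.8), horse (−20.4, 5.6), bovid (−19.6, 6.2) ‰); a site
layout spanning the three geographic regions and both cold and non-cold
environments, including one hominid-only site so the whole- vs
fauna-associated-hominid conditions genuinely differ. Faunal values are
exact truncated-normal draws inside the compartment range around the taxon
mean plus any per-site offset (between-individual scatter 0.5/0.8 ‰);
`plant_site_shift` plants a recorded heterogeneity for screening tests, and
shifts wider than the compartment are rejected. Hominid collagen is
Σ p_true·source + enrichment offsets + noise, with smaller residual scatter
(0.3/0.4 ‰ — cohort members share one true diet, so only analytical and
physiological variation remains) and cohort sizes 10/8/20, about half the
published cohort sizes. True diets default to the reported contribution
patterns: fish-dominated MOIS3 cohorts (0.55, 0.10, 0.35) and
(0.64, 0.08, 0.28), a meat-shifted MOIS2 cohort (0.35, 0.45, 0.20).
Identical parameters and seed reproduce byte-identical files, and every
dataset ships a truth record (diets, source signatures, planted shifts,
counts).

What the generator does **not** emulate: spatial/temporal baseline drift in
the isotopic background, diagenetic loss and quality filtering (C:N
ratios), taxon-specific physiology beyond a fixed mean, correlated
site-level ecology (site offsets default to zero), or the reindeer's
locally variable behaviour the study handled via with/without-reindeer
conditions. Passing tests therefore show the *pipeline* is correct under
the assumed trophic structure, not that real compilations satisfy the
assumptions.

## Numerical choices and problem sizes

Increment 1 % and tolerance 0.1 ‰ mirror the conventional settings of the
published enumeration tool; both are recorded in every result. Grid
arithmetic is integer; closure is exact. Largest-remainder ties break in
fixed source order (fish, meat, plants). Barycentric solves go through a
3×3 linear system with a determinant guard (|det| < 1e-12 is degenerate).
The exact Kruskal-Wallis path caps enumeration at pooled N = 10 (≤ 252
assignments). Validation windows at load are δ¹³C ∈ [−40, −5] and
δ¹⁵N ∈ [−5, 25] ‰. Test-suite and acceptance problem sizes — 100 seeded
geometries for solver agreement, 50 seeds for noisy recovery, 100 seeds for
screening power, 100 datasets × 4 tests for the type-I rate — were chosen
to estimate rates at the resolution the thresholds require while keeping a
laptop run in seconds.

## Known limitations

- The exact 945→599 specimen filter of the original compilation is not
  reconstructable without its supplement; the loader exposes generic
  filters instead of a hard-coded reproduction, and the published per-taxon
  totals ship as reference constants only.
- The printed condition matrix implies 30 south-western and 18
  cold-environment simulations where the running text states 28 and 16;
  the packaged preset ships the matrix as printed.
- The resource-unit weighting behind the original χ² inputs is not
  recoverable; equal protein weights are the default, so published
  p-values are reproducible in pattern, not bit-for-bit.
- Concentration-weighted mixing, source-uncertainty propagation
  (IsoError-style confidence intervals) and >3-source geometries are out of
  scope.
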