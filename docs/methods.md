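# Methods

## The metabolic model

The bundled network (`aerotype.network.reference_model`, serialized as
`data/reference_model.json`) reduces *E. coli* central carbon metabolism to
56 reactions over 55 metabolites in three compartments (cytosol, periplasm,
extracellular): glucose uptake by PTS, EMP and ED glycolysis, the oxidative
and non-oxidative pentose phosphate pathway, the TCA cycle with
anaplerosis, acetate overflow (PTAr/ACKr with proton-symport export),
nitrogen assimilation, a lumped biomass reaction with standard precursor
and ATP coefficients, and an explicit electron transport system. Reaction
and metabolite identifiers follow BiGG where an equivalent exists, written
in the BiGG direction — PGK, SUCOAS and ACKr therefore run net-negative in
growing cells, which the ATP accounting relies on. All reactions outside
the `exchange` and `biomass` subsystems are element- and charge-balanced
against explicit formulas; the validator enforces this on load. Transport
reactions are filed under the `exchange` subsystem and nitrogen
assimilation plus maintenance under `biomass`, because the subsystem
vocabulary is deliberately closed to the five ATS subsystems plus those
two.

### Proton bookkeeping and the ETS

Each ETS reaction moves `2·(H⁺/e⁻)` protons from cytosol to periplasm per
NADH or per ½ O₂. The four components are fixed at NDH-I = 2, NDH-II = 0,
CYO = 2, CBD = 1 H⁺/e⁻ — the unique assignment that makes the four
unbranched designs pump 1–4 H⁺/e⁻ with one dehydrogenase and one oxidase
each. The two *bd*-type oxidases are collapsed into a single CBD component
since they generate proton-motive force the same way. These per-component
values are parameters of this model, not measured constants. ATP synthase
consumes `h` periplasmic protons per ATP and returns `h − 1` to the
cytosol (one proton is fixed in phosphorylation), so its stoichiometry
stays balanced for any real `h > 1`; `set_h_per_atp` rewrites it, which is
how the H⁺/ATP scan works. The default is the rotational-catalysis value
10/3.

### Enzyme parameters

Each catalysed reaction carries one representative gene with a molecular
weight (assembled functional unit, kDa) and an effective turnover number
(s⁻¹). Two ratios are the load-bearing proteome-economics parameters: the
NDH-I complex is 10× the mass of NDH-II (470 vs 47 kDa), and the EMP route
costs ≈3.5× more protein per glucose than the ED route. Absolute kcat
values are effective in-vivo rates chosen so that proteome-limited growth
of the wild type lands near 0.8 h⁻¹ under the default budget; they are
deliberately slower than in-vitro turnover numbers. The biomass reaction
carries an explicit translation-machinery cost (a 2.3 MDa ribosome proxy
at 2.5 s⁻¹), which makes growth itself proteome-priced — without it, ATP
surplus states are carbon-limited and the growth rate becomes insensitive
to the H⁺/ATP ratio, destroying identifiability of the scan.

## Growth maximisation

`solve_growth` builds a split-variable LP (forward/backward nonnegative
fluxes per reaction) solved with HiGHS at 1e-9 tolerances, maximising the
biomass flux. Three constraint regimes:

* plain FBA (no proteome information);
* per-gene capacity, `v_j ≤ kcat_j·(φ_j·P)/mw_j`, with expression shares
  φ summing to one over enzymatic genes and budget `P = 0.55 g/gDW`;
* a shared budget, `Σ_j (mw_j/kcat_j)·|v_j| ≤ P`, one knapsack row
  coupling all enzymes — the reduced analogue of a metabolism-and-
  expression model's coupling constraints, and the regime used by the
  forward generator and the H⁺/ATP scan.

Measured phenotypes enter as bounds: glucose uptake as an upper bound on
uptake, acetate secretion as a fixed exchange value, O₂ as an uptake cap.
Among alternate optima the reported fluxes are parsimonious (secondary
minimisation of total absolute flux at fixed optimal μ), so outputs are
reproducible. Infeasible constraint sets return a solution with
`status="infeasible"` rather than raising.

Proteome allocation weights enzyme demand (`|v|/kcat`) by molecular weight
and growth: per-protein mass flux `mw_i · μ · demand_i`; the ATS fraction
sums genes in the model's ATS set. With the ribosome proxy in the
denominator the evolved strains allocate ≈60% of the modelled proteome to
the ATS.

## ATP accounting and aero-types

Total ATP production is the signed sum `Σ c_i v_i` over the bundled
17-entry coefficient table, applied to net fluxes in the written reaction
direction. Because PGK, SUCOAS and ACKr are written ATP-consuming
(c = −1) but run in reverse during aerobic growth and acetate overflow,
the single signed sum automatically credits them as producers — this is
the documented reconciliation between the table's signs and the usual
four-producer picture (ATPS, ACKr, SUCOAS, PGK), which the breakdown
reports by name. `fraction_atps` divides the synthase contribution by the
sum of positive contributions only, so fermentation-heavy states get low
but well-defined fractions. Aero-type class = number of boundaries below
the fraction; the default boundaries (0.25, 0.5, 0.75) are a configuration
parameter, not a measured stratification.

## H⁺/ATP estimation

For each evolved replicate the strain-specific model (variant knockouts +
the replicate's kcat factor) is re-solved over a ratio grid (default 2.5
to 4.5 in steps of 0.05, 41 points) under the replicate's measured
exchange rates and the shared budget; the estimate is the ratio minimising
|μ_predicted − μ_observed|, with ties — including numerical ties below
1e-6 in μ — resolved toward the lower (more proton-efficient) ratio. The
absolute-difference criterion is our reading of "matching" the measured
growth rate. Under the shared budget μ(h) is non-increasing: each extra
proton per ATP costs pumping flux, hence enzyme mass, hence growth. The
median over replicates is the headline estimate; with the default 2%
phenotype noise individual replicates scatter by roughly ±0.5 around the
planted ratio because ∂μ/∂h is a few 10⁻³ per grid step, which is also why
noiseless recovery is exact to one grid step.

## Robust ICA and iModulons

The ATS expression matrix (genes × conditions, log scale) is centered on
the unevolved wild-type column. PCA retains 99% of variance (capped at
k_max = 8); FastICA runs from 50 seeded restarts; all components are
pooled, clustered by absolute Pearson correlation of gene-weight vectors
(average linkage, cut at |r| = 0.7), and clusters reproduced in at least
half the restarts are kept as centroids with the largest-magnitude weight
oriented positive. Activities are least-squares fitted against the
column-centered matrix. Membership uses a 3σ rule with one robust trim:
provisional outliers beyond 3·1.4826·MAD of the median are removed, the
mean + 3σ threshold is re-estimated on the remaining background, and a
relative floor (5% of the maximum weight) guards the noise-free limit. The
plain mean + 3σ rule fails here because a planted module can hold over 10%
of the 209 genes and inflates its own σ. Component orientation is
arbitrary up to sign, so planted-sign checks first align each recovered
component with its planted counterpart.

Correlation analyses use tie-corrected Spearman; aero-type enters as an
ordinal 0–3 variable; pairings with fewer than three observations are
reported as undefined rather than numbers.

## The synthetic study generator

The generator emits the full design — uETS-1H…4H, eETS-1HA…4HD, and
unevolved/evolved wild types, 22 conditions — with all ground truth
serialized to `truth.json`; every recovery test reads the truth only from
that file.

**Phenotypes** are forward solutions of the bundled model under the shared
budget at the chosen true H⁺/ATP ratio, glucose in excess (≤50) and O₂ ≤
40 mmol gDW⁻¹ h⁻¹ (well-aerated cultures). Unevolved strains carry
per-variant sub-unity ATS kcat factors (0.35–0.6; wild type 0.75),
modelling unadapted catalytic use of the rewired chain; this yields
unevolved rates of 0.33–0.67 h⁻¹ with no monotone relation to H⁺/e⁻.
Evolved strains' factors are calibrated by bisection so every variant
reaches a common plateau of 0.85 h⁻¹, reproducing the signature
observation that all variants evolve to the same rate with different
bioenergetic strategies (ETS-1H: high uptake, heavy overflow, low synthase
fraction; ETS-4H: low uptake, oxidative). Exchange rates and μ receive 2%
multiplicative Gaussian noise; the per-condition kcat factor is emitted in
`phenotype.tsv` so the scan can reconstruct each strain's model.

**Expression** is a block-sparse low-rank signal over the 209-gene
registry (model ATS genes plus synthetic fillers grouped into the five ATS
subsystems): six disjoint modules of 15–30 genes with signed weights
(induced and repressed members — also the regime ICA separates cleanly;
all-positive blocks are provably hard for it), activities composed of a
small aero-type gradient (oxic modules rise with class, anoxic fall), a
per-(variant, phase) signature shared by replicate lineages, and
per-condition jitter, with the unevolved wild type as the zero-activity
reference. The signature is orthogonalised against the gradient so the
planted oxic/anoxic sign is guaranteed, and the gradient is kept a
minority of the variance because strongly collinear sources are not
separable by ICA. The unevolved signature shares 60% of its variance with
the evolved one, so endpoint replicates correlate more strongly with each
other than with their ancestor. Noise is Gaussian at SNR 10 by default.

**Mutations** plant one convergent driver per variant in all four
lineages — two intergenic units (*pyrE–rph*, *hns–tdk*), *sdhA* with a
premature stop in lineage B, *yjjX* with an ATG→ATA start-codon loss in
lineage A — plus Poisson(2) passengers from an 80-gene pool, midpoint-
sample duplicates to exercise deduplication, and a designated *mutS*
hypermutator lineage (ETS-4H C) with a five-fold load. Because flagged
hypermutators are excluded from convergence analysis, the per-experiment
threshold is capped at the number of analyzable lineages; *yjjX* is
therefore reported with count 3.

## What the synthetic data does and does not show

Passing the planted-truth suite shows the machinery is correct and
self-consistent: the LP agrees with brute-force vertex enumeration, the
scan inverts the generator exactly when noise is zero, ICA recovers
disjoint planted modules at SNR 10, and the mutation logic returns exactly
the planted convergence pattern. It does not show that the reduced model
reproduces genome-scale estimates on real data: real transcriptomes have
correlated, non-block regulons and non-Gaussian noise; real proteome
budgets, turnover numbers and maintenance costs are condition-dependent;
and the published genome-scale median H⁺/ATP (3.25) and ~38% ATS proteome
depend on the full metabolism-and-expression reconstruction plus measured
exchange and expression data, which are outside this package's scope.

## Numerical choices and degenerate inputs

LP tolerances 1e-9; parsimonious tie-break for alternate optima; scan ties
to the lower ratio with a 1e-6 μ tolerance; zero-flux solutions report
zero allocation with a warning instead of dividing by zero; empty iModulon
memberships are flagged, not errors; Spearman on fewer than three pairs is
undefined (None); knockout of a gene absent from all reactions warns
rather than failing; carbon-free constraint sets are zero-growth, not
infeasible, because no hard non-growth maintenance floor is imposed (the
growth-associated ATP cost sits in the biomass reaction). All randomness
flows through `numpy.random.SeedSequence` children of the user seed; ICA
restarts, the generator and the pipeline are byte-deterministic for a
fixed seed.

## Problem sizes

The default study is deliberately desk-scale: a 56-reaction model, 22
conditions, a 41-point scan over 16 evolved replicates (~650 LP solves),
and 50 ICA restarts on a 209 × 22 matrix. A full synthetic generation plus
pipeline run completes in well under a minute on one core.
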