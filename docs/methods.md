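# Methods

`fluxforest` estimates metabolic flux ratios from measurable ¹³C labeling
patterns by surrogate modeling: it builds, *in silico*, a cohort of
steady-state flux maps for a user-defined metabolic network, simulates the
mass-isotopomer distributions (MDVs) each flux map would produce under a
chosen tracer, projects them onto the measurable fragment set with
realistic noise, and trains a quantile regression forest that maps
measured features to the flux ratio of interest. This note records the
model, the numerical choices, and what the bundled synthetic conditions do
and do not demonstrate.

## Networks and atom transitions

A network is a list of reactions with per-carbon atom transition maps
(letter notation; `fba: fbp (abcdef) <-> dhap (cba) + g3p (def)`), a set
of unbalanced substrates, and sink reactions. Substrates do not enter the
stoichiometric system; every balanced metabolite must have a producer and
a consumer; a separate output flux exists for each biomass precursor and
secreted product, so results do not depend on biomass-vector coefficients.
Carbon conservation is enforced by the letter bijection: each letter
appears exactly once on each side of a reaction.

Rotationally symmetric molecules (succinate, fumarate) are declared
`@symmetric`; every production of such a metabolite is split into the
stated and the carbon-reversed atom map with weight ½ each. This is the
standard treatment of two-fold rotational symmetry and is required to
reproduce the label scrambling of the TCA cycle.

CO₂ is modeled as a balanced one-carbon pool with a venting sink, so
refixation by carboxylases dilutes label realistically. A user network can
instead declare it a substrate/output if the unbalanced convention is
preferred.

### Bundled reference models

`ecoli_ccm` (39 reactions: 29 conversions + 10 sinks) covers glycolysis,
oxidative/non-oxidative PPP, Entner-Doudoroff, TCA cycle, glyoxylate
shunt, PEP carboxylase, PEP carboxykinase, and malic enzyme.
`bsubtilis_ccm` (35 reactions) omits Entner-Doudoroff and the glyoxylate
shunt and uses pyruvate carboxylase for anaplerosis. Both are
reconstructions from standard central-carbon biochemistry with
conventional ¹³C-MFA atom mappings (e.g. citrate numbered so that
isocitrate dehydrogenase releases the OAA C1 carboxyl and glutamate C5
derives from the acetyl carboxyl). The phosphoglycerate→PEP and
malate→OAA steps are kept irreversible so that every bundled ratio is a
linear function of net fluxes (needed for exact ratio-bin constraints
during sampling); reversibility and exchange are retained on
phosphoglucose isomerase, aldolase, triose-phosphate isomerase, GAPDH,
the non-oxidative PPP, fumarase, and succinate dehydrogenase→fumarate
steps. Divergences from any specific published model variant are
possible; the models are bundled as editable text and every analysis
accepts a user network.

### Flux ratios

A ratio is `numerator/denominator`, each a signed linear combination of
reaction fluxes (net, forward, or backward). The bundled definitions:

- glycolysis vs PPP: `pgi / (pgi + zwf)` at the G6P branch point;
- pyruvate from Entner-Doudoroff: `eda / (pyk + eda + mae)`;
- PEP from gluconeogenesis: `pck / (pck + eno)`;
- pyruvate from malic enzyme: `mae / (pyk + eda + mae)`;
- OAA from PEP (anaplerosis): `ppc / (ppc + mdh)`;
- OAA origin three-way split: `mas / (ppc + fum + mas)` (glyoxylate
  shunt) and `fum / (ppc + fum + mas)` (TCA). Malate reaching OAA is
  attributed proportionally to its sources; note the glyoxylate share is
  structurally capped at 0.5 because each shunt turn also routes one
  succinate through fumarate into malate (`fum ≥ mas` at steady state).

Samples where a ratio is undefined (denominator ≤ 1e-12) or falls outside
[0, 1] beyond 1e-9 are labeled NaN and dropped from training.

## Flux sampling

Bounds are [-100, 100] for reversible and [0, 100] for irreversible
reactions; the major uptake flux is fixed to 10 (arbitrary units — all
MDVs are invariant to flux rescaling, which is asserted in tests). Each
multi-carbon sink is additionally required to carry at least 1% of the
uptake (0.1), expressing that every biomass precursor is actually
produced; this also guarantees that every measured pool has label
throughput. One-carbon sinks (CO₂ venting) are unconstrained.

The initial net-flux vector minimizes Σv² subject to stoichiometry,
bounds, the fixed uptake, and output/ratio inequalities (SLSQP with a
trust-region fallback; an LP probe proves infeasibility quickly and
provides a warm start). Monte-Carlo sampling then moves in the null space
of the stoichiometric matrix: Gaussian perturbations with per-direction
scales matched to the box widths and rejection of bound violations, with
an automatic switch to a hit-and-run walk over the constraint polytope
when acceptance drops below 1% (burn-in 200, thinning 5, started from a
Chebyshev-type interior point — the min-norm solution sits on a vertex
where a walk cannot move). Fixed seeds make cohorts bit-reproducible.

For uniform coverage of a ratio, [0, 1] is split into bins (default 10)
and sampling repeats per bin with the bin edges imposed as linear
constraints (`lo·den ≤ num ≤ hi·den`, plus `den ≥ 10⁻³·uptake` so the
pool carries flux). Internal bin edges are tightened by 10⁻⁶ so bins
feasible only on a measure-zero boundary face register as infeasible
(with a warning and a metadata record) instead of emitting boundary
samples. `multi_ratio_cohort` concatenates per-ratio stratified cohorts
and labels every sample with every ratio, so several predictors can share
one set of flux maps (required by the design-scan and sensitivity
contracts).

Exchange fluxes: for each reversible reaction, `exch = u·β·|net|` with
`u ~ Uniform(0,1)` and β the user's exchange-magnitude bound (default 1);
forward/backward fluxes are `exch + max(±net, 0)`. Reversible reactions
with numerically zero net flux receive `exch = u·β·(10⁻³·uptake)` so a
fully equilibrated zero-net reaction remains representable. The
distribution of exchange magnitudes is a modeling choice (only an upper
bound relative to the net flux is specified by the procedure this
follows); uniform-on-[0, β|net|] is the minimal reading and is what the
robustness analysis varies.

## Label simulation (EMU cascade)

Steady-state label propagation uses the elementary-metabolite-unit
decomposition: only the carbon subsets (EMUs) that the measured fragments
depend on are balanced, grouped by size, and solved as a cascade of
linear systems `A(v)X = -B(v)Y` where Y collects substrate-fragment MDVs
(per-position Bernoulli convolutions of the tracer mixture, mixture-
weighted; natural ¹³C abundance 0.0107 at unspecified substrate
positions) and Cauchy products of smaller EMUs. Reversible reactions are
expanded into forward/backward unidirectional reactions weighted by
`fwd`/`bwd`. The decomposition depends only on network structure and is
cached; per flux map only matrix values change, and whole cohorts are
simulated with stacked (batched) LU solves — about a millisecond per
flux map for the central-carbon models, which is what makes cohorts of
10⁴–10⁵ simulations routine on one core.

Degenerate flux maps need care. A pool is *dead* when no material path
of flux > 10⁻⁶ connects it (transitively) to a substrate — shut-off
branches, or sub-loops circulating purely on exchange fluxes. Their
isotopic state is physically ill-defined (history-dependent) but also
irrelevant: by the steady-state balance every flux coupling them to live
pools is below the threshold. Dead EMUs are pinned to the unlabeled MDV
to keep the solve regular; a dead *measured* pool raises an error (the
sampler's output constraints make this unreachable for the bundled
specs). One fed reactant certifies a reaction's whole reactant set live,
because sampled fluxes satisfy the stoichiometric balance exactly.
Negative solved fractions beyond -10⁻⁶ raise an internal-consistency
error; smaller excursions (ill-conditioned nearly-dead loops) are
clipped to zero.

The independent oracle `brute_force_isotopomers` solves the full
positional-isotopomer balance (≤ 2¹⁶ states) with all first-order terms
assembled into one exact linear system (term operators built by basis
probing) and outer fixed-point relaxation only over condensations of two
balanced pools. EMU-vs-oracle agreement to |Δ|∞ < 10⁻⁸ is asserted on
five toy networks (chain, condensation with carbon permutation, a
TCA-like condensation cycle with a symmetric intermediate, a reversible
symmetric pair, and the two-substrate mixing node).

## Measurement model

A measurement spec lists fragments (ordered carbon subsets, 1-based in
files) per platform. Bundled specs: `gcms` — 21 fragments of
proteinogenic-amino-acid carbon backbones expressed on their precursor
metabolites (full backbone plus the usual C1-loss and C1–C2 fragments);
`lcms` — intact central intermediates; `lcmsms` — intact plus
characteristic product-ion fragments; `mrm` — all contiguous carbon
windows of the LC-MS metabolites (a large feature count that exercises
feature selection). Measured data are assumed corrected to the carbon
backbone (derivatization and heteroatom natural abundance removed), the
standard output of MS correction pipelines.

Noise is additive symmetric `Uniform(-ε, +ε)` per feature (default
ε = 0.01, the precision of careful peak integration), clipped at zero,
then each fragment block renormalized to sum 1 — mirroring how measured
MDVs are normalized. Clip-then-renormalize is our choice for the
(unspecified) treatment of negative noised fractions; at ε ≤ 0.05 the
noised features are unbiased to within Monte-Carlo error (tested).

## Predictor

A random forest (scikit-learn `RandomForestRegressor`) with ntree = 100
trees and mtry = 20 split candidates — the accuracy/cost balance found by
five-fold cross-validation over a 4×4 grid, reproducible via
`cross_validate`. Training sets are built by binning the cohort's ratio
labels (default 10 bins over [0, 1]), drawing an equal count per feasible
bin without replacement, and splitting 2:1 into train and test; bins
recorded as structurally infeasible by the sampler are excluded, and
under-populated bins are an error rather than a silent shrink.

Prediction intervals follow the quantile-regression-forest algorithm:
for a query point, each training point is weighted by terminal-node
co-occupancy (1/leaf-size per tree, averaged over trees) and quantiles
are read from the weighted empirical CDF of training labels — no
smoothing; the median is the point estimate, [10%, 90%] the interval,
everything clipped to [0, 1]. Measured held-out coverage of the nominal
80% interval on the bundled E. coli problems is ≈88–96% per ratio: QRF
intervals are conservative on low-noise problems, and varying the leaf
size (1–25) does not change this materially. Treat the intervals as
upper bounds on uncertainty, not exact probability statements.

Feature selection (used in design scans, where feature counts differ by
an order of magnitude between platforms): rank by the forest's impurity
importance from a full fit, re-fit on the top {100, 50, 25, 10, 5}% of
features, and keep the fraction with the smallest cross-validated MAE
(ties to the larger fraction). CV folds are stratified by ratio bins to
stabilize fold MAEs. Impurity importance (rather than out-of-bag
permutation importance) is used because the candidates are nested
fractions of strongly correlated MDV features, where the cheap ranking
performs equivalently; the ranking is only a pre-filter ahead of the
cross-validated choice.

## Design scans and robustness

`scan_designs` evaluates tracer × platform × ratio cells on one shared
cohort (so cells differ only in the experimental setup), with per-cell
feature selection and per-cell failure capture. `sensitivity_grid`
samples one set of net fluxes, redraws exchange fluxes per magnitude
bound in {0.1, 1, 10, 100}, superimposes noise in {0, 0.01, 0.05, 0.1},
and holds the train/test split fixed across all 16 cells; mismatch
matrices train at one assumption and test at another. The reproducible
qualitative findings: under-estimating noise in training strictly
degrades accuracy on noisier test data, over-estimating it is benign on
cleaner data, and mismatched exchange-magnitude assumptions degrade
accuracy in both directions. `iqr_diagnostic` compares prediction-
interval widths of two prediction sets with a right-tailed
Wilcoxon–Mann–Whitney rank-sum test (exact enumeration for n ≤ 20,
normal approximation with tie correction otherwise) — the practical
check that simulated training assumptions match a new dataset.

## Problem sizes and what the bundled conditions show

Default study conditions used by the test suite and
`scripts/acceptance.py`: per-ratio stratified cohorts of 9,500 flux maps
(10 bins × 950), balanced draws of 9,000 with 6,000 training points,
noise 0.01, exchange bound 1 (10 and 100 in the robustness analyses) —
a deliberate scale-down of the 60,000-map cohorts such workflows use in
production, chosen because accuracy saturates near 10⁴ training points
on these networks (the monotone data-size property is tested). Typical
held-out MAEs on `ecoli_ccm`: ≈0.01–0.02 for the E-D, glycolysis/PPP,
malic-enzyme, anaplerosis, and both OAA-origin ratios, ≈0.09 for the
gluconeogenesis ratio (the hardest of the set).

The synthetic cohorts emulate steady-state fluxes with uniform ratio
coverage and homoscedastic uniform measurement noise. They do not
emulate: correlated biological flux states (regulation), heteroscedastic
or correlated MS noise, residual natural-abundance correction error,
compartmentation, or metabolite channeling. Passing the in-silico tests
therefore certifies the estimator given the network and error model;
applying it to real data inherits the network's correctness, as with any
model-based flux analysis.

## Known limitations

- Ratios used for stratified sampling must be linear in net fluxes;
  forward/backward-flux ratios can be evaluated but not used as sampling
  constraints.
- Isotopically non-stationary (time-course) labeling is out of scope;
  the EMU cascade here assumes isotopic steady state.
- Single-element (¹³C) tracers only.
- The brute-force oracle is capped at 2¹⁶ isotopomer states and is a
  test tool, not a production simulator.
- Self-sustaining loops with zero external influx have undefined label
  content; they are reported (if measured) or neutralized (if not)
  rather than simulated.
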