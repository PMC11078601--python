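# Methods

## The surrogate dynamical system

The package analyzes rare-event reaction kinetics; the propagator it ships
is a deliberately simple stand-in for a quantum-chemical engine that keeps
the statistical structure the analysis assumes. The configuration is the
anion position relative to the cation center in 2-D polar coordinates
(reduced units: lengths in Å-like units, time in ps-like units, energies in
kT). The potential is a sum of five smooth terms:

1. **Screened long-range attraction** −c·exp(−s/λ)/s with the softened
   distance s = √(r² + a²) (c = 6, λ = 4, a = 1). It is attractive at all
   ranges, smooth at the origin, and numerically zero (< 10⁻⁶ kT) beyond
   r ≈ 50, giving a well-defined unassociated reference. A bare Coulomb
   −c/r tail cannot both matter near contact and vanish at r = 50, hence
   the screened form.
2. **Site wells**: Gaussians of per-label depth and width (default width
   0.55) centered on a ring of n = 6 sites at the contact radius r_c = 3.5
   — the peripheral carbons of the phenyl propellers. Labels follow the
   symmetry-adapted alphabet: {O, P} on unsubstituted rings, {X, S} on a
   substituted ring, T the central carbon. Negative depths are allowed and
   act as repulsive patches (a disfavoured ring). All site terms are
   multiplied by a smooth radial envelope (tanh cutoff, default r = 4.65
   with width 0.12; the wide-welled OCH3 preset cuts off at 4.35 so its
   broad tails die equally early), so the landscape beyond r ≈ 4.6–4.9 —
   the entire diffusional-approach region — is *identical for every
   preset*; this is what makes the encounter rate k₁
   substituent-independent by construction rather than approximately.
3. **Product well**: a deep Gaussian (12 kT, width 0.6) at the origin — the
   covalent adduct.
4. **Activation-barrier ring**: a Gaussian ridge (width 0.22) at r = 1.8,
   between the product radius (1.3) and the inner ion-pair threshold
   (2.25). Its amplitude is *calibrated at construction* (1-D bisection
   along the deepest site's ray) so that the realized barrier — saddle
   minus ion-pair minimum — equals the requested `barrier_height` exactly;
   a 2-D grid saddle search in the tests confirms the calibration to ~5%.
5. **Confining wall**: a soft quartic beyond r = 60, the finite
   "simulation box" that makes the unassociated state normalizable.

Macrostates follow fixed distance thresholds: unassociated r > 10, ion pair
2.25 ≤ r ≤ 5, product r < 1.6; the gaps are unlabeled buffer zones.
Dynamics is overdamped Euler–Maruyama, x ← x + (dt/γ)F + √(2kT·dt/γ)·ξ with
dt = 0.002, γ = kT = 1; the per-step displacement (~0.06) is far below
every feature width, and a free-diffusion test verifies the 2-D Einstein
relation MSD = 4(kT/γ)t to 5%.

### Presets and the regime they encode

The three presets describe a substituent series through two dials: the
activation barrier and the site-well depths.

| preset | barrier (kT) | site wells (kT) | meaning |
|--------|-------------|------------------|---------|
| OCH3   | 7.0         | 2.2 deep, wide (0.75) on all of O,P,X,S | electron-donating: slowest activation; overlapping wells form a ring channel → widest crawling |
| H      | 4.9         | 1.6 (O,P)        | unsubstituted, three-letter alphabet |
| CF3    | 3.3         | 1.2 (O,P); broad repulsive patches at X,S (−1.5, width 1.2) | electron-withdrawing: fastest activation; the substituted ring is avoided and addition never occurs at S |

`long_range_strength` is identical across presets and the site envelope
keeps the approach region preset-independent: the diffusional encounter
step does not depend on the substituent. The barrier values place the ring
crossing ~4.5 / 3.0 / 1.75 kT *above the unassociated baseline*, which is
what makes the system activation-limited: a typical collision bounces back
off the ridge, so k₋₁ ≫ k₂ (measured ratios ≈ 15–25 / 5–7 / 3–4) and only a few
percent to a few tens of percent of collisions are productive, ordered
OCH3 < H < CF3. With lower crossings the encounter itself becomes
rate-determining and the two-step analysis degenerates; the presets encode
the activation-controlled regime by construction. The contact-label
contrast is likewise structural: OCH3's connected well channel spreads
activation-step contacts over all six sites (highest label entropy), while
CF3's repulsive substituted ring concentrates contacts on O and P.

### The initial ensemble and recycling

Fifty unassociated configurations are drawn on the r = 20 ring at uniform
random angles (the analog of an equilibrated, distance-restrained reactant
ensemble). Each WE run starts from five of them picked without replacement;
a recycled walker respawns from a uniformly random pool member (switchable
to a fixed member), with its statistical weight unchanged and its lineage
restarted.

## The weighted-ensemble engine

The progress coordinate is (distance to the cation center, distance to the
nearest site including the center) — the surrogate analog of the minimum
anion–carbon separations. Bins are rectilinear: 0.25-wide below 6 on both
axes (resolving the ion-pair shell and the barrier), 2-wide to 20, then
coarse unbounded outer bins. Each iteration propagates τ = 250 steps
(0.5 reduced ps), stores frames at τ/2 and τ, evaluates macrostates and
flux at the τ frame, recycles, bins, then splits/merges every occupied bin
to 5 walkers. Splitting apportions the target count by weight (largest
remainder, ≥ 1 copy each) and divides weights equally among copies; merging
repeatedly combines the two lowest-weight walkers, the survivor chosen with
probability proportional to weight. Both operations conserve per-bin weight
exactly (tested to 10⁻¹⁴), and the total weight is 1 at every iteration
boundary to 10⁻¹².

**Flux attribution.** Every walker carries last-visit times for all labeled
macrostates. A flux event into state S is attributed to every state A
visited more recently than S, and the matching population p_A for the pair
(A, S) sums walkers with A more recent than S. This pairwise "color"
scheme is what makes the Hill relation exact on a chain that passes through
an intermediate: with a single last-label rule the direct U→B flux would
vanish identically. On the discrete twin the estimators reproduce 1/MFPT
for U→B and I→B to within replicate noise with no systematic bias.

**Dissociation rate.** The Hill identity k = 1/MFPT(A→B) holds for the
steady state recycled at the *target of the measured transition*. In a
product-recycled run the I→U estimator converges instead to the elementary
dissociation rate (through-product excursions are terminated by recycling)
— the chemically meaningful k₋₁, and the quantity the study reports. The
oracle-validation suite measures k₋₁ = 1/MFPT(I→U) exactly by running the
engine with target = unassociated and source = I, which is the recycling
scheme the identity requires.

**WESS reweighting.** After the main run, the bin-to-bin transition matrix
is accumulated from the trailing 75% of iterations (recycling jumps
included), its stationary vector is solved by eigendecomposition (an error
is raised if the occupied-bin graph is not strongly connected), and each
bin's walkers are rescaled to the steady occupancies, preserving relative
weights within bins. A run already at the steady distribution is a fixed
point to 10⁻¹⁰; on a hand-built two-bin record the reweighted occupancies
equal the analytic eigenvector. The study then continues each run for extra
iterations from the reweighted ensemble and reports pre- and post-WESS
rates side by side.

## Kinetics

Fluxes and populations are running averages from iteration 1 (no burn-in; a
configurable discard could be added but the convergence diagnostic makes
the transient visible instead). k_rxn and k₁ are normalized by the
effective concentration; the reduced-unit study uses C₀ = 1 so bimolecular
and unimolecular numbers coincide numerically, while
`effective_concentration` implements the physical C₀ = 1/(N_A·V) mapping
(V = 4.486×10⁵ Å³ ↔ 3.70 mM) for reporting in molar units. The
ion-pair-entry flux in the percent-productive denominator uses the first
crossing of the 5 Å contact threshold, consistent with the ion-pair band's
outer edge; every re-collision counts as a new collision. Credibility
regions are Bayesian bootstrap over replicate simulations: Dirichlet(1,…,1)
weights, 10⁴ draws, 2.5/97.5 percentiles of the weighted means, reported as
asymmetric offsets `mean ± [below, above]`. Convergence is assessed on the
replicate-averaged running k_rxn; the plateau flag requires the trailing
quarter of the series to vary by < 10% of the final value.

## Pathway analysis

Pathways are traced backwards from every recycling event through the
split/merge lineage to the last unassociated frame; pathways sharing
ancestry are kept as distinct observations with their own weights (no
deduplication), as in clustering ensembles pooled over replicates. Strings
are the per-τ-frame nearest-site labels; the tie-break (lowest site index,
T first) makes discretization deterministic. The Gestalt similarity
2M/(L₁+L₂) uses the recursive longest-common-substring decomposition with
earliest-match tie-breaking; because the greedy decomposition is
argument-order dependent, `pathway_distance` canonicalizes each pair
lexicographically before matching, making the distance exactly symmetric.
The length correction divides 1 − similarity by c = min(L)/max(L)
(pluggable), inflating distances between unequal-length pathways. Ward
linkage runs on the precomputed distance matrix (Lance–Williams recursion;
cross-checked in the tests against an independent O(n³) implementation);
the dendrogram is cut in the largest gap between consecutive merge heights,
ties resolved toward fewer classes, with a degenerate all-equal-heights
tree collapsing to one flagged class. Clustering is unweighted; pathway
weights enter only the class probabilities. For tractability the study
clusters a weight-proportional subsample (default cap 150) of the traced
ensemble.

Contact distributions restrict each pathway to its activation segment
(first crossing below 5 to product entry), sample labels at τ/2 resolution,
and weight by pathway probability; the Shannon entropy of the distribution
quantifies the range of propeller crawling. The surrogate's addition site
is defined as the ring site nearest in angle at product entry (the final
approach direction) — an analog, not a claim that the surrogate forms
peripheral adducts.

## Problem sizes

Full-scale defaults follow the reference protocol: 5 independent WE runs of
500 iterations per preset, 5 walkers/bin, WESS at 75%, 100 post-WESS
iterations. The bundled validation study and acceptance script run a
reduced design — 5 replicates × 250 iterations, no post-WESS extension —
which this landscape's relaxation times comfortably fit; Markov-chain
validations use 5 replicates × 600–900 lags with 20 walkers per state bin.
Contact statistics are accumulated over the full traced pathway ensemble;
only the O(n²) clustering uses a weight-proportional subsample.

## What the surrogate does and does not show

Passing tests demonstrate that the *analysis machinery* is correct
(estimators exact on solvable models; bookkeeping conserves weight; string
clustering recovers planted structure) and that the surrogate reproduces
the mechanistic phenomenology it encodes (two-step kinetics, activation
control, barrier-ordered k₂, crawling-ordered contact entropy). They say
nothing about chemical accuracy: the surrogate has no electronic structure,
no solvent, no 3-D orientation degrees of freedom, and its reduced-unit
rates map to physical units only through an explicit, declared conversion
constant. The 2-D reduction also tends to produce pathway classes defined
by approach topology rather than by chemically distinct crawling routes;
class counts on the surrogate are therefore illustrative, not predictions.

## Known limitations

- The pairwise-color flux ledger stores aggregate per-iteration matrices;
  per-event provenance beyond (source, target, weight) is not kept.
- WESS assumes the occupied-bin transition graph is strongly connected over
  the window; short or cold runs can legitimately fail reweighting, in
  which case the study falls back to the unreweighted ensemble and logs it.
- `exact_mfpt` requires the target to be reachable; it reports an error for
  reducible hand-specified chains rather than a censored estimate.
- Sub-τ recrossings are invisible to the flux ledger by design (states are
  evaluated at τ boundaries, as in the resampling protocol itself).
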