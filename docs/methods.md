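# Methods

This note documents the models implemented in `biogeodiv`, the choices made
where the design was genuinely open, and what the synthetic studies do and
do not demonstrate. Ages are always Myr before present (present = 0).

## Time conventions and tree handling

Trees are ultrametric, bifurcating for all likelihood work (polytomies are
accepted on input but rejected by the likelihood modules, because DEC
cladogenesis is defined for two daughters). Ultrametricity is enforced to
1e-6 Myr; deviations up to 1e-3 Myr — typical rounding noise in published
summary trees — are repaired by resetting tip ages to zero, larger ones are
rejected. Newick is written with 12 significant digits so that a
read–write–read round trip preserves branch lengths to better than 1e-9 Myr
even on ~100 Myr trees.

Supertree grafting multiplies every subclade node age by
(attachment age / subclade root age) and splices the rescaled subclade in
place of a placeholder tip. The rescaled root age is set to the attachment
age exactly (not via the product) so the operation is age-exact. Grafting
operates on point trees; posterior-distribution grafting and consensus
summarisation are out of scope.

## Time-stratified DEC

**State space.** Ranges are bitsets over 2–16 named areas, restricted to
subsets connected under the epoch's adjacency matrix, optionally capped in
size, plus one absorbing null range. States are ordered by (range size,
lexicographic area order); this ordering is also the deterministic tie-break
for most-probable ranges. With per-epoch adjacency the likelihood indexes a
*master* space — the union of the per-epoch permitted sets — and each
epoch's generator only permits gains into ranges allowed in that epoch.

**Generator.** From range r, area b is gained at rate `d·Σ_{a∈r} m[a,b]`
(m = epoch dispersal multipliers); each occupied area is lost at rate `e`,
single-area ranges losing into the null range. Transitions into ranges
outside the state space are censored (the diagonal only balances permitted
transitions), which is the canonical construction. A consequence worth
knowing: removing an adjacency edge lowers total exit rates and can
*increase* the likelihood even when the removed ranges have no tip support,
so state-space pruning is not a monotone operation on logL.

**Cladogenesis.** Single-area parents are copied to both daughters. A
widespread parent of size k has 4k ordered outcomes — vicariance (one area
vs the remainder) and subset sympatry (one area vs the full range), both
orders — deduplicated for k = 2 where the two families coincide (6 distinct
outcomes), all equiprobable. Outcomes whose daughters fall outside the state
space are dropped without renormalisation.

**Likelihood and ancestral ranges.** Standard pruning with per-node
rescaling; branch transition probabilities are ordered products of
per-epoch-segment matrix exponentials, oldest segment first. Matrix
exponentials use eigendecomposition with a scaling-and-squaring (`expm`)
fallback when the eigenbasis is ill-conditioned; the pruning pass only needs
matrix–vector products, so large state spaces stay tractable. The root
likelihood is a flat (unweighted) sum over non-null ranges, configurable to
1/|range| weighting. Ancestral ranges are *marginal* probabilities from a
standard outside/conditioning pass at the ML point, not joint
reconstructions. The pruning likelihood is verified against an independent
exhaustive-enumeration oracle (all ancestral state combinations, series
matrix exponentials) to ~1e-15 relative error.

**ML fit.** Nelder-Mead on (log d, log e), multi-start. The dispersal rate d
is well identified (typically within 10–20% on 300-tip simulations). The
extirpation rate e is *not*: DEC cladogenesis reproduces any range
contraction at zero likelihood cost (a daughter may inherit a single area
regardless of branch lengths), so anagenetic loss competes with a free
alternative explanation and its MLE collapses toward zero — on simulations
with true e = 0.005 the fitted e is ~0 in essentially every replicate, under
range-extinct-pruned, redraw-on-null and widespread-root designs alike.
Survival-conditioned variants of the likelihood overcorrect (e overshoots
4–6×) because null-range extinction also distorts tree shape, which DEC
treats as fixed. This mirrors the common empirical experience that DEC
returns e ≈ 0; fitted extirpation rates should not be interpreted as
estimates of range-loss rates. The corresponding joint recovery check in the
acceptance suite is deliberately left failing on the e component rather than
weakened.

**Dispersal events.** For each branch, each area in (child range minus
parent range) at the most-probable-range reconstruction yields one event
with the full parent range as source; pure losses are extirpations, not
events. Epoch summary tables attribute widespread sources fractionally
(1/|source|) per source area by default, configurable to full attribution.

## Branch rates through time

Rate-shift configurations follow the event format of reversible-jump
birth-death samplers: per posterior sample, a set of events, each starting a
regime `λ(age) = λ_init·exp(λ_shape·(t₀ − age))`, `μ = μ_init` on the branch
carrying it and everything downstream until overridden. Rates are evaluated
on a global age grid (default Δt = 0.5 Myr, matching the lineage-count
binning) at cell midpoints clipped to the branch; the mean branch net rate
uses exact closed-form regime integrals. Posterior samples are averaged per
branch-grid-cell (grid evaluation is linear, so averaging commutes with it);
per-sample series can be propagated instead. The package does not run the
shift MCMC; a constant or fitted episodic regime can stand in as the
tree-wide rate source to keep the pipeline self-contained.

## Combination summaries

**Event timing.** Each dispersal event receives n_draws (default 1000)
i.i.d. uniform times on its branch interval; draw k across all events forms
timing replicate k. One master seed drives everything; per-stage substreams
are derived deterministically.

**Epoch percentage tables.** Four geological summary periods by default
(Paleocene 66–56, Eocene 56–34, Oligocene 34–23, Miocene-to-present 23–0
Myr), nine areas merged to six regions (E/W Nearctic and Palearctic halves
merged, India folded into SEAsia). Per replicate and period, cell (src, dst)
is 100 × events / total events in the period; matrices are averaged over
replicates, and each replicate matrix sums to exactly 100 where events
exist (periods without events give NaN rows, counted separately). The full
matrix is retained — any display threshold is presentation only.

**Lineage-area frequency.** Lineages are counted at 0.5 Myr bin midpoints,
once per occupied region, with range changes applied at the branch midpoint.
Default normalisation makes regions sum to 1 per bin; an alternative
normalises by lineage count (widespread lineages then push sums above 1),
exposed as a flag since either reading of "relative proportion" is
defensible.

**Sliding-window regional rates.** Windows of 4 Myr stepped by 1 Myr. Per
timing replicate, occupancy along each branch is reconstructed from drawn
gain times; losses are drawn uniformly the same way (the symmetric
treatment; unstated in the source analyses). The regional mean is
Σ∫rate·dt over occupied-segment∩window divided by the matching occupied
length, with widespread lineages contributing full weight to each occupied
region (fractional attribution is a config option). Integration is exact
interval arithmetic over the piecewise-constant rate grid, so splitting a
branch at a grid edge leaves results unchanged to 1e-9. Because gain and
loss times on the same branch are drawn independently, a branch that swaps
areas can be momentarily doubly- or un-occupied within a replicate; this
vanishes on averaging and is the reason conservation identities are stated
for single-occupancy configurations. The replicate spread (default 100
replicates) is reported as per-window quantiles.

## Regional diversification events

A regional event is a maximal clade with ≥ min_tips (default 4) sampled
tips in which at least `purity` (default 0.90) of tips *and* of internal
nodes are confined to one region of the five-region scheme (SEAsia and
Australasia combined). "Mostly diversified in a single region" has no
published operationalisation, so the purity threshold is a headline config
value recorded in output metadata. Maximality makes events non-nested, so
each tip belongs to at most one event. Described richness per clade sums a
per-genus richness table, genera assigned to the event holding the majority
of their sampled members; richness is floored at the sampled count, and
f = sampled/described.

### Episodic birth–death likelihood

With λ(t) = λ₀e^{αt} (t = age; α > 0 means faster speciation toward the
origin), constant μ, and sampling fraction f at present, write
r(t) = λ(t) − μ, R(t) = ∫₀ᵗ r, and g(t) = 1/f + ∫₀ᵗ λ(u)e^{R(u)}du. Then
the probability of exactly one sampled descendant lineage is
e^{R}/(f·g²) and of at least one is e^{R}/g, and the crown-conditioned
log-likelihood of branching ages x₁ (crown) > x₂ ≥ … ≥ x_{n−1} is

    Σ_{i=2}^{n−1} [log λ(x_i) + R(x_i) − 2 log g(x_i)] − 2 log g(x₁) − n log f.

Conditioning is on the crown age and survival of both crown lineages
(default) or crown age only; stem conditioning is not offered because stem
ages are not part of the clade report. The g-integral has no closed form
for α ≠ 0 and is evaluated by 64-node Gauss–Legendre quadrature per
endpoint (halving the step changes logL by < 1e-8; the α = 0 limit is
verified to 1e-8 against an independently coded constant-rate closed form,
and the Yule case exactly). Fitting runs multi-start Nelder–Mead on
(log λ₀, α, log μ); μ converging to its boundary is flagged
(`boundary_mu`), not treated as an error. Derived quantities:
λ_crown = λ₀e^{αT}, netDiv₀ = λ₀ − μ, netDiv_crown = λ_crown − μ.
Profile-likelihood intervals (χ²₁-based) are available for λ₀, α, μ and —
by reparametrising λ₀ = netDiv₀ + μ — for netDiv₀.

### Recovery properties (what the synthetic study shows)

On 100 clades simulated at λ₀ = 0.2, α = 0.05, μ = 0.1 with 150 tips and
f = 0.8 (crown age 19 Myr, chosen so the expected survivor count matches
the target; rejection until exactly 150 survivors, because conditioning on
"≥ n then subsample" injects extra sampling the fitted f does not account
for and biases λ₀ down ~30%):

* median λ̂₀ within ~5% and median α̂ within ~12% of truth;
* 95% profile intervals cover the truth for 96–99% of replicates on all
  three of λ₀, α, netDiv₀;
* median netDiv₀ is biased upward ~10–30% depending on the seed set: μ̂
  sits on its zero boundary in ~40% of replicates (the familiar
  extinction-underestimation pathology of reconstructed-tree ML), and
  netDiv₀ = λ₀ − μ inherits the skew. Every audited replicate has
  logL(MLE) > logL(truth), so this is a property of the estimator at this
  design, not of the optimiser. The acceptance-level check of a 20% median
  band on netDiv₀ fails at 28.9% on the prescribed replicate set and is
  left failing rather than widened; point estimates of netDiv₀ from single
  clades of this size should be read with that skew in mind.

## Richness statistics

One-way ANOVA per clade-level parameter across regions, with Tukey HSD
pairwise comparisons computed only when ANOVA p < 0.05 (otherwise the
omission and reason are recorded). Hierarchical partitioning fits all 2⁴
subsets of {crown age, netDiv₀, netDiv_crown, α} by OLS on log described
richness and reports each predictor's independent contribution I_k — the
average R² gain over all orderings (the Shapley value of the R² game) — and
joint contribution J_k = R²_k − I_k. The identities Σ I_k = R²_full and
I_k + J_k = R²_k hold to 1e-10 (note Σ(I) + Σ(J) equals R²_full only for
orthogonal predictors). Subset ranking uses AICc, appropriate for the small
per-region clade counts, and the criterion is recorded in the output.
Variance-explained percentages are reported both as 100·I_k/ΣI and raw I_k
since "% of variance" is ambiguous between bases. Clades are treated as
independent observations — no phylogenetic regression — which is a known
limitation.

## Synthetic data

The generator produces the statistical structure each stage assumes and
nothing more: forward birth–death (thinning of a bounding Poisson process)
from a crown with λ(t) = λ₀e^{αt}, μ constant, pruned to the reconstructed
tree; forward DEC range histories (per-epoch CTMC plus cladogenetic draws)
with the full truth recorded — node ranges, event times, range-extinct
lineages; Bernoulli(ρ) tip retention with per-genus sampled/described
tables (synthetic genera are consecutive tip blocks of geometric size);
BAMM-format event files that round-trip through the parser to 1e-12; and
planted monoregional clades built by grafting exact-size pure-birth
subclades onto a pectinate backbone whose background nodes carry a
two-region range so no unplanned pure clade can arise.

It deliberately omits features of real data: no range-dependent
diversification (ranges and rates are simulated independently, exactly as
the inference assumes), no rate heterogeneity beyond the configured
regimes, no phylogenetic error or calibration uncertainty, and no
taxonomic mis-assignment in the richness tables. Passing recovery tests
therefore demonstrates internal consistency of estimator and generator,
not robustness to model violation.

## Numerical choices

* DEC matrix exponentials: eigendecomposition when the eigenbasis is
  well-conditioned (reconstruction checked at 1e-9), else `expm`.
* DEC optimisation: log-parameter Nelder–Mead, default 3 starts
  (1 start and loosened tolerances in the large simulation studies, where
  the likelihood surface is clean and 50 replicates bound the runtime).
* Birth–death quadrature: Gauss–Legendre, default 64 nodes, exposed as
  `quad_n` for convergence checks.
* Profile intervals: outward geometric/additive bracket search from the
  MLE followed by 12 bisection steps, warm-starting the two-parameter
  inner optimisation at the MLE.
* Degenerate inputs: zero-length event intervals collapse to a point;
  periods or windows with no events/occupancy give NaN (counted, never
  silently dropped); zero within-group variance in every ANOVA group is an
  error.
* Study sizes in the test suite: the DEC recovery study runs 50 replicates
  of 300-tip trees with a 4-area single-epoch model; the birth–death
  recovery runs 100 clades; the acceptance script scales these to 12 and
  30 replicates respectively so a full from-scratch rerun stays within a
  few minutes on one CPU.
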