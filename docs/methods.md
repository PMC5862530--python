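# Methods

This note documents the models, estimators and numerical choices behind
`antflow`, and what the synthetic colony does and does not emulate.

## Data model

A colony experiment is three tables on a shared clock (absolute seconds
from recording start): trophallactic interactions (time span, donor,
recipient, signed volume, both participants' crop loads at onset), feeding
events (forager, time span at the food source), and per-ant crop timelines
on a uniform grid (default dt = 2 s, i.e. 0.5 Hz) with boolean activity
flags (in trophallaxis / at food / in nest). Volumes are signed positive
when food leaves a forager and negative when it returns to one; that single
sign convention is used everywhere.

Crop intensities are raw fluorescence-like units. Two normalizations serve
different questions: *between experiments* divides every measurement by the
experiment's 90th-percentile crop measurement (absolute loads comparable
across recordings; used for all volume-law analyses), and *per forager*
divides each forager's series by her own maximum (her personal [0, 1]
satiety scale; used for exit decisions). Both normalizers are returned so
the transforms invert.

Foragers are classified from feeding counts: at least 8 feedings makes a
consistent forager, at most 4 a casual visitor; the 5–7 range is flagged
for manual review rather than forced into either class, because observed
colonies show a clean gap and any cutoff inside it would be invented. Each
forager's analysis window starts at her first return to the nest from the
food source (end of her first feeding).

## Macro scale

**Colony state.** F(t) is the cumulative signed volume of forager ↔
non-forager interactions divided by the intake target. The target is the
plateau of accumulated food, estimated post hoc as the mean of the smoothed
accumulation over the final 10% of the record; if the last hour still rose
by more than 2% (relative) the estimate is flagged, echoing the saturation
criterion used to time perturbations. On synthetic data the ground-truth
normalizer (the recipients' summed crop targets) is available and is what
validation tests use, since a still-rising record biases the plateau
estimate low.

**Flows.** Accumulations are smoothed with a centered moving average
(default 2000 s, wide enough to span several trophallactic events) and
differentiated with a symmetric difference quotient over 200–500 s (default
300 s); the windows are validated by requiring the integrated flow to
reproduce the net accumulation. Per-forager feedback slopes come from
through-origin least squares of flow against vacancy (1 − F) over each
forager's active window. All R² values use the 1 − SSres/SStot convention
(negative values meaningful), and every R² quoted for a law is computed on
binned means or whole-trajectory fits, not pointwise scatter — individual
smoothed flows still oscillate at the foraging-cycle scale, and with a
handful of foragers the pointwise scatter R² of flow vs vacancy varies
widely (≈0.5–0.9 across seeds) even when the law is exact in expectation.
The emergent macro law is therefore asserted in its integral form: after
onsets stabilize, F(t) must fit 1 − (1 − F0)e^(−k·t) (R² > 0.95 holds
robustly on the default configuration).

**Trajectory prediction.** dF/dt = n(t)·m·(1 − F) is integrated exactly
piecewise (constant coefficient between onsets), so the constant-n limit
reproduces 1 − e^(−N·m·t) to machine precision.

**Cycles.** A foraging cycle is the interval between consecutive feeding
starts, split into indoor/outdoor phases by the in-nest flags. The nest
exit instant is the first grid point where the in-nest flag flips false;
the crop at exit is read there on the per-forager scale. Frequency (1/cycle
interval) is binned into equally spaced colony-state bins (default 5) and
bin means are fit linearly against vacancy, unweighted (bin means are the
fitted objects throughout; a 1/SEM² weighted option exists). Perturbation
response bins in-nest durations over time with the perturbation instant
pinned to a bin edge, so no bin mixes pre- and post-influx cycles; the
contrast statistic is (last pre-bin mean) − (first post-bin mean).

## Micro scale

**Exponential rates.** The rate of an exponential volume distribution is
estimated two ways: (a) the *histogram sweep* — least-squares fit of
λe^(−λv) to the empirical density at bin centers, repeated over 17
binwidths uniform on [0.01, 0.09], reported as mean ± STD across the
sweep — and (b) the maximum-likelihood rate 1/mean. The two agree within a
few percent on genuinely exponential samples and the MLE is the permanent
cross-check. Within a *crop bin*, however, volumes are a mixture of
exponentials across the bin's crop range; the MLE of the mixture recovers
λ0/(C0 − c̄) exactly (since E[v | bin] = (C0 − c̄)/λ0), while the density
fit over-weights the fast components and inflates λ0 by up to ~15%. Both
per-bin estimators are exposed; recovery-critical analyses use the MLE,
binning-sensitivity reports use the sweep.

**Hyperbolic law.** Positive volumes are split into 7 equal-width bins of
the conditioning ant's crop (bins merged when sparse); the bin abscissa is
the mean conditioning crop in the bin. λc = λ0/(C0 − c) is fit by nonlinear
least squares; a fitted C0 below the largest observed crop is flagged
non-physical. In donor-conditioned (forager) mode the analogous const/c
form is fit *and* compared against a constant; the estimator null — data
whose drawn fractions are independent of donor load by construction —
yields negative R², i.e. no better than a constant. On full simulated
colony runs a donor-load signature can nonetheless appear: it comes
entirely from physical truncation of transfers at the donor's remaining
load, not from the drawn fraction.

**Collapse.** ṽ = v/(C0 − c_recipient), with records at c ≥ C0 excluded
and counted. Exponentiality of the pooled ṽ is tested with a Lilliefors
test (parameter estimated from the data); per-crop-bin distributions are
compared to the pool with two-sample Kolmogorov–Smirnov tests. On synthetic
data, truncation-censored draws are excluded via the ground-truth flag;
outcome-based exclusion leaves a ~5% downward selection bias on the mean
(censoring strikes large draws), which is documented rather than corrected
because censoring is unobservable on real data.

**Interaction rate.** Intervals between consecutive interaction *starts*
of a forager within one nest visit (a feeding between two interactions,
boundaries inclusive, splits them). The per-bin rate is the inverse of the
mean interval — consistent for a Poisson stream, whereas the mean of
inverse intervals diverges for exponential gaps — and bin rates are fit
linearly as r(F) = r0 − r1·F.

**Unloading decomposition.** Per-visit unloading rate = (1 − crop at
exit)/indoor duration on the forager scale. Three one-parameter models are
fit to the binned means: a scale times the interaction-rate line, times the
mean-volume line (C0/λ0)(1 − F), or times their product. On data generated
with a constant interaction rate the volume-only model must and does
dominate.

**Representativeness.** Crop loads of actual interaction partners are
compared per colony-state bin against random snapshots of all non-foragers
at times in the same bin (202 population draws per bin by default),
summarized as the difference of means in pooled-SEM units.

## Exit decisions

Decision points are reconstructed from the logs under three schedules:
every in-nest grid sample outside trophallaxis (*constant*), the first
sample at/after each interaction end (*interaction rate*), and one point
per further Δcrop = 0.10 of capacity unloaded since nest entry
(*unloading rate*; the decrement accumulator resets on crop increases,
which are rare). A point is an exit if the forager leaves before the next
point of the same schedule; the final point of a visit that ends at the end
of the record carries no label. kNN probability surfaces follow the
fraction-of-exits-among-n-nearest construction with the probability plotted
at the neighbours' mean location (n = 300 for the constant schedule, 30
otherwise, reflecting the point counts).

Exit logistics are maximum-likelihood binary fits by default (a mode
fitting the kNN surface instead is provided); complete separation triggers
a flagged ridge-regularized refit. Logistic R² is reported two ways, since
the notion is not canonical: McFadden's pseudo-R² and the squared Pearson
correlation between fitted probabilities and the kNN surface at the data
points. The 1-D G(crop) projection excludes the lowest crop interval
(exit probability 1 there by construction, as a forager's lowest in-visit
crop observation is almost always her exit).

The separation-of-variables report fits the 2-D logistic under all three
schedules. The colony influence is summarized as |colony coefficient| /
|crop coefficient| — comparable because both covariates live on [0, 1] —
and the crop-triggered rule predicts monotone shrinkage of that ratio from
constant → interaction-rate → unloading-rate, reaching a CI that covers
zero; the raw colony coefficient need not shrink monotonically (the
interaction-rate schedule concentrates points late in visits, inflating
it). The monotone ordering requires the measured interaction-rate decline
(r1 = 0.017 per second per unit F) to be active in the generator: with a
constant rate the per-interaction schedule paces decisions exactly like the
constant one and cannot sit between the extremes. A colony-dependent exit
rule serves as the negative control: its colony coefficient stays bounded
away from zero under every schedule.

## Synthetic colony

The simulator emulates the observation experiments: ~60 ants, a few
foragers with onsets staggered over the first 10% of a 4-hour run,
recipients with crop targets of mean C0 = 1.14 (between-experiment
normalized units) and 5% spread (configurable to constant — the
parameter-recovery preset), volume rule with λ0 = 7.01, in-nest interaction
attempts at r(F) = r0 − r1·F (r0 = 0.032 s⁻¹; r1 = 0 by default since
volumes, not rates, dominate the feedback — r1 = 0.017 reproduces the
measured decline), constant 200 s outdoor trips refilling the crop to
capacity, exit decisions at every 10% of capacity unloaded with
G(crop) = logistic(−0.093 − 3.092·crop), forced exit on an empty crop, and
an optional mid-run influx of hungry ants with the colony-state normalizer
recomputed over the enlarged colony. Mass moves from donor to recipient
exactly; same seed gives bitwise-identical logs. The perturbation
demonstration mirrors the manipulation protocol: a small accessible group
(31 ants, 16 foragers) satiates before the 64 blocked ants join —
perturbing a colony mid-rise produces only a weak, binning-sensitive dip,
which is exactly why the original protocol waits for satiation.

Mean-field oracles accompany the simulator. The expected unload per visit
composes the geometric chain of exit decisions (with the decision-crop
overshoot treated as exponential, by memorylessness of the volume draws);
flow per forager is unload-per-visit over cycle time; integrating
dF/dt = n(t)·flow(F)/W gives the deterministic trajectory. Because the
smoothing and differentiation filters attenuate measured slopes, the
m-recovery oracle pushes the mean-field trajectory through the *identical*
estimator (same windows, same per-forager onsets); against it the fitted
pooled m is unbiased with ~5% per-seed scatter, so validation averages
three replicate colonies.

**What the generator does not emulate:** spatial structure (no nest
geometry, no depth; partner choice is uniform, which already realizes the
observed representative sampling), recruitment signalling beyond staggered
onsets, negative (recipient→forager) transfers (importers accept them; the
analysis treats them as a reported correction), queen/brood feeding,
secondary non-forager↔non-forager distribution, measurement noise in crop
estimates, and interaction durations (one grid tick each, versus minutes in
reality — so absolute interaction rates, not their state dependence, are
stylized). Passing tests therefore certify the estimators and the internal
consistency of the micro → macro composition on clean event logs; they do
not certify robustness to imaging noise or to the un-modelled behaviours
above.

## Known limitations

* The post-hoc intake target underestimates the plateau on records that
  end before full saturation; downstream slopes inherit a few percent of
  bias. The flag exists and synthetic validations bypass it with the
  ground-truth normalizer.
* Histogram-sweep rates are biased on within-bin mixtures (see above);
  the MLE mode is preferred for recovery.
* Outcome-based censoring exclusion is mildly selective; covariate-based
  filtering (keeping records whose donor load exceeds the recipient's
  space) removes the volume bias but induces an artificial donor-load
  signature, so it is used only where the recipient-side law is the target.
* Logistic CIs assume independent decision points; within-visit points
  share a trajectory, so real coverage is slightly below nominal (the
  replicate-coverage test budgets for this).
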