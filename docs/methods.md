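# Methods

This note documents the statistical procedures, the synthetic microcosm
model behind the test bed, the parameter choices that matter, and the
design decisions taken where the problem left the design open.

## Experimental design

`design.generate_partition` implements the random partitions design: at
each richness level the pool is shuffled with a seeded generator and
chunked consecutively into disjoint communities, so each isolate appears
exactly once per level and the community count per partition is
Σ_L S/L (31 for S=16, L ∈ {1,2,4,8,16}).  Partitions are spawned from
independent child seed streams of one experiment seed.  Replicates of a
partition share community composition (biological replicates of one
design); the default experiment is three independent partitions × one
replicate = 93 microcosms, i.e. the partitions are the replication.  The
alternative reading — re-randomizing composition within replicate — is
available by generating more partitions instead.

Community IDs are deterministic (`P{partition}.R{richness}.{index}`) so
downstream joins never depend on randomization order.
`validate_design` returns violations as data (never exceptions), naming
the level and isolate involved, so externally supplied designs can be
audited before analysis.

## Assay conversions

**CO₂.** The indicator-plate calibration is read as
`mass_mg = exp((ln Δλ + 0.305414)/0.282164)`: this parenthesization is
the only one that makes the relationship log-linear, which is what a
calibrated absorbance↔mass relationship with a quoted R² implies.  The
negative control (atmospheric CO₂) is subtracted on the absorbance scale
before inversion.  A corrected Δλ ≤ 0 yields a flagged missing value,
never a silent zero or a negative mass.  Daily rates divide the interval
mass by the interval length (7, 21, 21 days for sampling at days
7/28/49).

**Per-capita respiration** divides the CO₂ rate (µg day⁻¹ → pg day⁻¹) by
total cells (density × 0.88 ml).  Zero-cell records are flagged.

**Enzyme fluorescence** is normalized by `value × grand_mean /
enzyme_mean`, equalizing each enzyme's dataset-wide mean to the grand
mean before conversion to nM MUB h⁻¹ (the MUB conversion factor is a
config parameter, default 1.0, because no standard-curve constants are
assumed).  This form removes enzyme-specific fluorescence yield — the
purpose of normalizing across the data set — and preserves the grand
mean exactly (the rule redistributes signal; it does not rescale the
total).  The inverse factor would amplify between-enzyme scale
differences and does not preserve the total.

## tRFLP attribution

Fragment intensities below 0.5% of the profile total (configurable) are
zeroed as baseline noise.  Intensity on fragments no community member can
produce is excluded with a warning and reported as a contamination
diagnostic (`stray_fraction`); the remainder is renormalized.  Shared
fragments are resolved by the equal-sharing rule (the null hypothesis) or
by seeded whole-fragment random assignment (the most extreme
alternative); on collision-free maps the two rules coincide exactly, and
the random rule's expectation over seeds equals the equal rule.  The
pipeline's sensitivity harness runs both rules on identical inputs and
reports per-day divergences of the interaction summaries.

## Response-ratio inference

Monoculture functioning M_i is matched by day, partition and replicate —
a mixture is always compared against monocultures grown alongside it;
same-day matching is the default (a config switch allows a fixed
reference day, since the matching convention is genuinely ambiguous).
The default functioning measure is per-capita respiration; total
respiration is selectable.

Zero or undetected observed contributions are floored at half the
smallest positive contribution in the data set (configurable) before the
log, and flagged; ln(0) is undefined and dropping undetected isolates
would bias the summaries toward survivors.

Pairs inherit their two members' whole-community log ratios (richness >
2 reuses each isolate's single value for all its pairs) — an attribution
convention for visualization and summary, not a causal pairwise
estimate.  Classification uses a neutral band ε = 0.05 on the log scale
(configurable); a band is needed because measurement noise makes exact
zeros impossible.

**Summary statistics.** Per-day summaries pool both members of every
pair.  Pooled values within a microcosm share the community measurement
(same P_observed, same noise draws), so the reported standard error of
the mean is cluster-robust by microcosm; the naive iid formula would
understate uncertainty by roughly the pair multiplicity (up to 120 pairs
per 16-species microcosm).  Variances and class frequencies are reported
as effect sizes; significance machinery (ANOVA, t-tests, corrections) is
deliberately out of scope.

## Additive partitioning

With observed yields Y_obs,i = ra_i·P_observed, relative yields
RY_obs,i = Y_obs,i/M_i, expected relative yield 1/N (equal inocula), and
ΔRY_i = RY_obs,i − 1/N:

    ΔY  = Σ Y_obs,i − Σ M_i/N
    CE  = N · mean(ΔRY) · mean(M)
    SE  = N · cov_pop(ΔRY, M)

The covariance is the population form (÷N): only then is
ΔY = CE + SE an algebraic identity (N·cov_pop + N·mean·mean = Σ ΔRY_i·M_i
= ΔY); the sample covariance (÷(N−1)) is a common implementation bug and
is tested against.  ΔRY is implemented as observed minus expected
relative yield — the standard form, and the only one consistent with the
partition identity.  Isolates with M_i = 0 are excluded with N adjusted
and the exclusion logged, since their relative yield is undefined.
Richness trends are OLS slopes per day (statsmodels), effect sizes only.

## The synthetic microcosm model

The simulator exists to exercise the analysis under known truth; it is a
plausible stand-in, not a calibrated model of any real community.  Each
880-µl microcosm holds member cell counts N_i, a labile carbon pool
(shared fraction + per-isolate private niches) and a recalcitrant pool,
in µg CO₂-equivalent carbon.  Forward Euler with Δt = 0.1 day and a
positivity clamp:

- Labile uptake is Monod-limited; a `niche_fraction` (0.4) of the labile
  supply is split into per-isolate substrate classes.  The private
  niches stabilize coexistence, so relative abundances equilibrate over
  the seven weeks rather than collapsing to the best competitor — the
  analogue of the abundance equilibration seen in real succession.
- Recalcitrant uptake engages as labile carbon runs out (gate
  `K_gate/(K_gate+C_L)`), requires enzymatic competence g_i, and has a
  lower growth efficiency (0.5 vs 0.9): costly carbon.
- Interference: `f_i = clip(1 + φ_I(C_L)·Σ_j α_ij N_j, 0.02, 2)`
  throttles all of isolate i's metabolism (uptake and maintenance — the
  dormancy response to antagonism).  Interference is fueled by labile
  carbon through φ_I, so realized antagonism is strong while the initial
  labile endowment lasts and fades once weekly feed pulses are consumed
  within hours by the grown community: this is the attenuation mechanism
  the inference is meant to recover, encoded explicitly.
- Consumed carbon splits into biomass (yield 1100 cells per unit
  invested) and respired CO₂; maintenance consumption (5×10⁻⁵ units
  cell⁻¹ day⁻¹) is respired entirely; deaths (0.04 day⁻¹) accumulate as
  necromass.  Carbon is conserved to float precision: pools + biomass
  equivalent + necromass + cumulative CO₂ + dilution removals = supplied
  (tested at 1e-9 relative).
- Weekly dilution (post-sampling) multiplies every culture component by
  exactly 580/880 and adds 300/880 of the stock (a community receives
  only its members' private-niche substrates; the mass ledger credits
  what actually arrives).

Parameter scales were chosen once to land the emergent observables in
the regime the experiment describes: ~500-cell inocula growing to
~10⁵ cells ml⁻¹, a few µg CO₂ day⁻¹, day-7 per-capita respiration of a
few tens of pg cell⁻¹ day⁻¹, predominantly negative interactions (mean
α = −1.2×10⁻⁵, s.d. 6×10⁻⁶ per cell per day) that attenuate across
sampling days 7/28/49.  The joint constraints are tight — e.g. 4 µg
day⁻¹ at 10⁵ cells ml⁻¹ already implies ~45 pg cell⁻¹ day⁻¹ — so the
defaults favour internal consistency over matching any single reported
magnitude.

**Observation model.**  Absorbance inverts the CO₂ calibration exactly
(plus a 0.02 control offset and Gaussian noise, s.d. 0.004);
flow-cytometry counts carry mean-preserving lognormal noise (σ = 0.08);
tRF profiles pool isolates sharing a fragment and are drawn from a
Dirichlet with precision 300 (minor peaks are proportionally noisier, as
in real electropherograms); enzyme fluorescence is linear in
Σ N_i·allocation plus multiplicative noise.  All stochasticity flows
from named seeds (design / dynamics / noise) recorded in output
metadata.

**Scenarios.**  `paper_default` is the 93-microcosm configuration above.
`neutral` is the null control: α = 0, fully private resource pools,
per-member inocula and *exchangeable* (identical-physiology) isolates —
each mixture is then exactly N independent monocultures, so every
systematic term in the inference is zero and departures reflect
observation noise alone.  Both relaxations matter: with heterogeneous
physiology the equal-abundance predictor is violated even without
interactions (a genuine property of the estimator, not a bug), and with
split inocula the smaller per-member starting density delays growth and
depresses early per-capita respiration.  `mutualistic` flips the
interaction mean positive; `tiny` (4 isolates, levels {1,2,4}, unique
fragments) is the fast smoke configuration.

**What the simulator does not emulate:** evolution within the
experiment, spatial structure, chitin→cellulose chemistry, plate-reader
artifacts, or tRFLP peak-calling.  Passing tests show the analysis
recovers truth under this model's assumptions; they do not certify the
model as a description of real treehole communities.

## Known limitations

- Per-isolate log response ratios of noisy proportions are biased
  slightly negative (Jensen: E[ln ra] < ln E[ra]), by about
  (1−ra)/(2·precision·ra) — ≈0.03 for a 1/16 share at Dirichlet
  precision 300.  This is inherent to log-ratio estimators, visible in
  the neutral control as a small negative offset well inside the
  cluster-robust uncertainty.
- The pairwise expansion reuses whole-community ratios; it cannot
  disentangle which partner drives an interaction in mixtures of
  richness > 2.
- The symmetry correlation of pair values is depressed by the zero-sum
  constraint on relative abundances (one member's positive abundance
  deviation is its partners' negative one), so it understates mechanistic
  symmetry of the underlying α matrix.
- Problem sizes in the test suite and acceptance script (93 microcosms ×
  3 sampling days, Δt = 0.1 day) are the experiment's own scale; the
  simulator handles larger pools but the defaults are not tuned for
  them.
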