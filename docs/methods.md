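# Methods

This note documents the models behind `tauhcn`, the parameter choices that
matter, and what the synthetic-data validation does and does not establish.

## Membrane model and sag extraction

The simulator is a single-compartment membrane with a leak, a
hyperpolarization-activated mixed-cation conductance (HCN-type, carrying
I_h), and an optional non-inactivating potassium conductance:

    C_m dV/dt = −g_L (V−E_L) − g_h m (V−E_h) − g_K n (V−E_K) + I_inj(t)
    dm/dt = (m_∞(V) − m)/τ_h,   m_∞(V) = 1/(1 + exp((V − V_half)/k))

with m rising on hyperpolarization and n its depolarization-activated
mirror for the K conductance.  Defaults: C_m = 100 pF, g_L = 10 nS
(R_in = 100 MΩ), E_L = −80 mV, E_h = −30 mV, V_half = −82 mV, k = 7 mV,
τ_h = 100 ms, E_K = −100 mV — round values in the range typical of cultured
hippocampal pyramidal neurons.  Integration is classical fixed-step RK4 at
dt = 0.05 ms (deterministic; a dt = 0.005 ms reference run agrees to
< 0.05 mV).  A holding current is solved (Brent root-find on the
steady-state I–V) so the pre-stimulus voltage sits exactly at the
protocol's −80 mV target, mirroring constant-current holding in real
recordings.  Recording noise is available as additive Gaussian voltage
noise (`noise_sd`) applied after integration; the genotype presets leave it
at zero because every sag quantity of interest is an extremum- or
fit-derived deflection and the validation targets the extraction logic, not
noise robustness.

Sag extraction follows the standard deflection conventions: baseline `V0`
is the 50 ms pre-onset mean; `C` is the deepest within-step deflection; `A`
is the mean over the last 20 % of the step; `B`, `τ_m` come from a
single-exponential fit restricted to the initial falling phase where the
deflection lies between 0.10·C and 0.90·C (the only monotone reading of a
10–90 % fit window); sag_sub = 100(C−A)/C, sag_fit = 100(B−A)/B;
`R_in = A/I_step`; rebound is the maximum over 200 ms after offset.  The
baseline and steady-state window widths and the rebound window are this
package's choices — sag values move by far less than a percentage point
under reasonable alternatives.

The WT preset uses g_h = 2 nS; the Tau35 preset g_h = 6.23 nS, solved by
root-finding so that extracted sag_sub doubles exactly — the h-conductance
must more than double because the sag measure saturates in g_h.

## IV analysis

Outward non-inactivating currents (12 × 10 mV steps from −90 mV) are leak
subtracted (ohmic leak from the two most hyperpolarized steps, where the
channels are taken as closed; a known leak can be supplied instead, e.g.
from generator metadata), normalized to capacitance, and converted to a
specific conductance with a fixed 100 mV potassium driving force — the
literal published convention; the physical per-step `V − E_K` variant sits
behind a flag, off by default.  The per-cell Boltzmann fit
`G = G_max/(1+exp(−(V−V_½)/k))` uses nonlinear least squares.  A leak-only
family is flagged rather than fitted.  With the leak known, noiseless model
currents invert to machine precision; with the leak estimated, the residual
channel current at −90/−80 mV biases G_max by under 2 % for activation
midpoints ≥ −30 mV.

## sEPSC generation and detection

Events are a homogeneous Poisson process convolved with a biexponential
kernel `a(e^{−t/τ_d} − e^{−t/τ_r})` scaled to the preset peak, in Gaussian
noise, at 10 kHz.  WT: 2.0 Hz, −20 pA, τ_r = 0.8 ms, τ_d = 4 ms, noise
2 pA (signal-to-noise 10).  Tau35: 0.46 Hz (the 77 % reduction), equal
amplitude, τ_r = 1.87 ms, τ_d = 9.11 ms — solved against the analytic
kernel so the maximum-rise ratio is 0.43 and the half-width ratio 2.3.

Detection is a scaled-template (Clements–Bekkers-style) search: the
criterion is the fitted template scale over its standard error, computed
for every offset with FFT rolling sums.  The published workflow's manual
false-positive check is replaced by two deterministic screens: (i) fitted
amplitude ≥ 3× the robust noise SD (MAD of first differences); (ii) a
tail screen — a candidate within the decay horizon of accepted events must
exceed 1.2× their predicted remaining tail plus the same 3σ margin, because
the criterion is amplitude-independent and re-fires on the exponential tail
of every real event.  Threshold 4.0 and the 5 ms refractory give ≤ 1 false
positive per 30 s noise-only trace and ≥ 95 % sensitivity at SNR 10.  One
WT-kinetics template serves both genotypes, as a single Clampfit template
would; detection lag then depends on the template/event mismatch, so event
averaging aligns snippets on the event peak and refines alignment by
correlation against the running mean (matched-filter timing, ~sub-sample
accurate at these SNRs).

Waveform statistics come from the averaged event: amplitude is the
baseline-subtracted extremum; half-width is the time below half-amplitude
with interpolated crossings; the rate of rise is read off a continuous
free-onset biexponential fit of the mean waveform.  The fit matters: the
kernel's steepest instant is its onset kink, which sampled derivatives
under-read by a kinetics-dependent amount (−27 % for the WT kernel at
10 kHz but only −7 % for the slower Tau35 kernel), enough to push the
between-genotype ratio from 0.43 to ~0.55 if measured naively.

## Vesicle maps and the clustering statistic

Per synapse, the SV count is negative binomial (gamma–Poisson, dispersion
10 — overdispersion typical of EM counts; means 110/80.3 at 4 months,
100/61 at 10 months).  A docked fraction (0.05) is placed touching the
500 nm active-zone segment (this is a 1-D packing and saturates near
0.6·AZ/40 nm vesicles, hence the low fraction; docked percentage shows no
genotype effect and is not a benchmark quantity).  The remaining vesicles
form an isotropic Gaussian cluster centred one `cluster_sd` above the AZ
midpoint, placed sequentially under a 40 nm hard-core constraint
(centre-to-centre ≥ mean diameter).  Dense-core vesicles are a separate
class (larger diameter, wider spread) excluded from SV counts and NN
analysis.

Cluster spreads: WT 220 nm at both ages; Tau35 236.3 nm (4 mo) and
215.0 nm (10 mo), calibrated by brute-force simulation (≥ 10⁴ vesicles) so
the group mean nearest-neighbour distance exceeds WT's by exactly 10 nm
under each age's count preset — note the 10-month Tau35 spread is *below*
WT's because the lower vesicle count already loosens nearest-neighbour
spacing.  The NN statistic follows the per-synapse-then-average convention
throughout: per-vesicle NN distances, per-synapse ECDF on a fixed 0–400 nm
grid, pointwise-averaged across synapses; the group mean is the unweighted
mean of per-synapse means.  A test pins the fact that this is *not* the
pooled-distance statistic on unbalanced synapses.

## Morphology generator and morphometry

Each neuron grows 5 basal primaries by recursive bifurcation up to depth 4;
segment lengths are gamma-distributed (shape 10) and directions random
walks on the sphere.  Branch probabilities 0.54699 (WT) and 0.40701
(Tau35) are exact closed-form solutions of the branching recursion
`E_b(d) = p(1 + 2E_b(d−1))` for expected branch-point counts 9 and 5.04
(the 44 % reduction); the Tau35 segment length (42.706 µm vs 35 µm) is
solved so its sparser tree has a 20 % shorter mean dendrite.  Spines are a
Poisson process along the cable (0.80 vs 0.328 per µm) with type-conditional
geometry ranges chosen to be separable by the deterministic classifier
(mushroom: head/neck > 1.5 and head > 0.35 µm; stubby: length/neck < 1;
thin: otherwise — the field names types without printing criteria, so the
rule is this package's own, stated explicitly).

Sholl analysis counts true sphere–segment crossings in 3-D around the soma
centroid (10 µm steps by default); a node exactly on a sphere counts once
when the path passes through, and a terminal tip touching a sphere is not a
crossing.  A 2-D projected variant is available for parity with
projection-based reconstructions.

## Statistics

Two-group comparisons use the classic pooled-variance two-tailed t test
(identical constant groups take the p = 1 convention); factorial designs
use two-way ANOVA with Type II sums of squares (robust to the mild
unbalance of realistic cohorts; the variant is unstated in typical reports)
and Tukey HSD across the four genotype×age cells.  No multiple-testing
correction is applied across metrics, mirroring field practice; the report
records this.  Units of analysis are cells (electrophysiology), synapses
(EM), neurons (morphometry), with no nesting by animal or culture.

## Paired cohort designs in the recovery experiments

The effect-recovery experiments (`tauhcn.recovery`, also behind
`scripts/acceptance.py`) compare genotype cohorts of the sizes such studies
report (16 synapses, 20 cells, 50 neurons, 100–200 synapses per group).  At
those sizes, naive independent sampling leaves the Monte-Carlo error of a
ratio-of-means comparable to the effects themselves, so the generators are
built for common-random-number pairing: unit *i* of each genotype draws
from the same seed stream, counts pass through shared inverse-CDF
quantiles, vesicle coordinates use per-vesicle substreams (so differing
counts do not desynchronize pairs), and branching decisions are pre-indexed
by tree position (the sparser tree is a pruning of the denser one).  Three
cohort-level quantities are additionally *designed* rather than sampled:
DCV-positive synapses are quota-assigned (the prevalence is itself the
estimand), vesicle-count mixing quantiles are shuffled stratum midpoints of
the negative-binomial, and branching uniforms are level-wise systematic
within a neuron (marginally Bernoulli, variance-balanced per cell).  Across
replicate seeds the recovered effects centre on the encoded values with
spreads of ≤ 0.9 pp (frequencies, counts, spine density), 2.0 pp (branch
points), and 1.0 nm (the NN gap — the one quantity whose replicate spread
remains comparable to its tolerance, since subset-removal noise at 16
synapse pairs is irreducible without altering the point process itself).

## Problem sizes

The test suite and the acceptance script use the cohort sizes above; the
heaviest computations are forty 30 s gap-free traces (12 × 10⁶ samples
through detection) and a 200 k-step reference integration, together well
under a minute on one core.

## What passing does and does not show

The generators realize exactly the structural assumptions the analyses
make: stationary Poisson event trains with one shared kernel, isotropic
Gaussian vesicle clusters, spherical soma, independent cells.  Real data
break all of these — bursting and non-stationary event rates, multiple
amplitude classes and dendritic filtering, anisotropic vesicle clouds and
section-angle artifacts, reconstruction errors, animal-level nesting.
Recovery of the encoded effects therefore validates the *measurement
pipeline* (detection, fitting, counting, geometry) under controlled
conditions; it does not certify accuracy on recordings or micrographs, and
per-preset parameters (noise levels, dispersions, geometry ranges) are
plausible-scale choices, not fitted distributions of biological
variability.

## Known limitations

Single-compartment simulation only (no dendritic I_h gradients, no action
potentials in the presets — the AP analyzer is exercised on constructed
spikes); the detection criterion is an explicit Clements–Bekkers-style
stand-in for a proprietary tool; 2-D single-section vesicle analysis with
no stereological correction; docked fraction capped by 1-D packing; spine
classification thresholds are conventions, not measurements.
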