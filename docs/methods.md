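# Methods

This note documents the models, estimators and design choices behind
`neuroplex`: a pipeline that fuses band-limited functional connectivity
from source-level MEG-style ROI time series with weighted structural
connectivity into two-layer multiplex networks, scores each region with
the multiplex participation coefficient, and runs a two-group /
median-split / FDR statistical workflow — together with a synthetic
cohort generator that plants known ground truth through every stage.

## Spectral processing

**Individual alpha frequency (IAF).** Per subject, a Welch periodogram
(Hann window, 50% overlap, frequency resolution 0.25 Hz) is computed for
each ROI in a configurable detection subset (by default the
occipitoparietal regions when the 68-region Desikan–Killiany atlas is in
use, otherwise all ROIs). Within the search range (default 7–13 Hz), a
local maximum counts as a peak only when its power is at least twice the
median in-range power — this prominence rule rejects the ripples of a
peakless spectrum, so white noise raises a "no alpha peak" error rather
than returning an artefact. The IAF is the mean of the per-ROI peak
frequencies. Replicate studies use a fixed 6-ROI detection subset,
mirroring the practice of detecting the peak on a posterior sensor
subset; with a shared per-subject carrier any subset is representative.

**Band scheme.** All five bands are fixed offsets from the IAF: delta
(IAF−8, IAF−6), theta (IAF−6, IAF−2), alpha (IAF−2, IAF+2), beta (IAF+2,
IAF+14), gamma (IAF+15, IAF+80). The one-hertz gap between beta and
gamma is intentional and left uncovered. The IAF must exceed 8 Hz so the
delta low edge stays positive.

**ROI reduction.** Within-ROI source time courses are reduced to the
first principal component (not the mean, which mixes phases), with the
sign fixed so the component correlates nonnegatively with the mean
source signal.

**Analytic signals.** Band-limiting uses a linear-phase FIR band-pass
(Hamming window, ~4 cycles of the band's low edge long) applied at zero
phase in the frequency domain, combined with the one-sided
analytic-signal mask in the same FFT round trip; the result is exactly a
zero-phase FIR filter followed by the Hilbert transform, applied
circularly. Three cycles of the low band edge are trimmed at each end
to remove filter transients (recorded as `discarded_edge_samples`). The
batched cohort path evaluates the same construction with one shared
rfft and two irffts per cohort and zeroes the transient phasors instead
of slicing them (identical time averages); the per-subject and batched
paths are cross-checked in the test suite.

## Connectivity estimators

**PLV.** The modulus of the time-averaged unit phasor of the phase
difference. Invariant to amplitude rescaling and global phase rotation;
the null floor for independent phases is ≈ √(π/4N). Samples with zero
amplitude (undefined phase) are dropped; more than 1% of them is an
error.

**wPLI.** |mean(imag S_xy)| / mean(|imag S_xy|) with S_xy the per-sample
cross-spectrum. Exactly zero (with a warning) when the imaginary parts
sit at rounding level, i.e. when all coupling is at zero lag — the
volume-conduction insensitivity that motivates using it as a control
estimator alongside PLV.

**Transfer entropy.** Plug-in (maximum-likelihood) entropies on
uniformly amplitude-binned signals, in bits:
TE = H(future | target past) − H(future | target past, source past).
Defaults: 4 bins, target history 1, source lag 1 sample — the smallest
defensible configuration; all are exposed. TE operates on the real part
of the band-limited analytic signal (the filtered series itself), not on
phase alone: information transfer is a signal-level notion and phase-only
TE is a different estimator family. Records too short to populate the
joint state space (fewer than ~5 samples per possible state) raise an
"underdetermined estimate" error. The estimator is biased upward by
finite sampling; the bias shrinks with record length, which the test
suite verifies, and directional conclusions are drawn from forward /
reverse comparisons on the same record.

**Inward/outward profiles.** A directed TE matrix is summarised per node
as the sum of couplings directed toward it (inward, column sums —
receiver role) or away from it (outward, row sums — sender role). In
the multiplex path the same distinction is applied after density
thresholding: the directed matrix is binarised over the n(n−1) ordered
pairs at the common density and the functional-layer degree counts
inward or outward suprathreshold couplings; threshold-then-split is the
default order.

## Multiplex construction and metrics

Each subject's two layers (weighted FA structural; weighted PLV, wPLI or
TE functional, per band) are binarised by keeping exactly
⌊density × possible edges⌋ strongest edges — the floor never exceeds
the target density — with ties at the cut broken by lexicographic node
pair order so the result is deterministic and scale-invariant. The
default density is 22%, the minimum structural density of the older
group in the reference cohort; the pipeline can instead re-derive the
minimum from a designated group's structural matrices. Diagonals
(auto-correlations) are excluded everywhere.

The multiplex participation coefficient of node i over M layers with
per-layer degrees k_i^[α] and overlapping degree o_i = Σ_α k_i^[α] is

    p_i = M/(M−1) · [1 − Σ_α (k_i^[α]/o_i)²]

1 when the node engages both layers equally, 0 when one layer holds all
of its edges. Isolated nodes (o_i = 0, formula 0/0) are assigned
p_i = 0: a node participating in no layer participates equally in none.
Per-layer degrees and totals are reported alongside for the
layer-contribution analyses.

## Statistical workflow

Group contrasts are pooled two-sample t tests (first-listed group minus
second); with covariates (education, grey-matter volume, total
intracranial volume) the statistic is the group term of the linear model
`metric ~ group + covariates`, sign-flipped to the same orientation — a
plain t test cannot carry covariates, so this is the natural
operationalisation of "t-tests controlling covariates". A pooled t from
printed summary statistics is provided for worked examples on published
cohort tables.

Subgroups use a median split with the `n_remove_per_side` (default 4)
individuals nearest the median on each side removed to reduce split
bias; 46 subjects yield 19 per subgroup. Ranking is by (value,
subject id), making tie resolution deterministic, and the split is
invariant under strictly monotone transforms of the metric. Odd group
sizes are rejected (the design removes equally many from both sides).

Cognition associations are partial correlations given the covariates
(with the covariate-adjusted OLS slope and its standard error reported),
or Spearman rank correlations on covariate-residualised values for
non-continuous scores. FDR control is Benjamini–Hochberg at q = 0.05,
applied within each analysis family (the nodal family of one
modality × band for group contrasts; the regression family for
cognition tests) — one correction per analysis step.

Layer contributions are paired t tests between per-layer degrees at a
region across subjects, FDR-corrected over layer pairs. The unimodal
baseline contrasts the global mean weight and the per-node binarised
degrees of a single modality between groups, quantifying what the
multiplex analysis adds.

## Synthetic data

The generator defines the study conditions; nothing downstream is fit to
real data.

**Oscillators.** ROI i is a noisy phase oscillator
x_i(t) = cos(φ_i(t)) + directed terms + observation noise, with
φ_i(t) = 2π·IAF·t + δ_i + σ_φ B_i(t) and B a standard Brownian motion
whose increments are correlated across ROIs: the increment correlation
equals the requested coupling c_ij (projected to the nearest valid
correlation matrix when the requested matrix is not one). The relative
phase of a pair is then Brownian with diffusion 2σ_φ²(1−c_ij), so the
record-averaged PLV has a closed form in the coupling
(`plv_ground_truth`): coupling 1 means identical phases (PLV exactly 1)
and coupling 0 decorrelates on a timescale 1/σ_φ². Defaults: σ_φ =
3 rad/√s (an alpha line width of order 1 Hz), observation noise SD 0.3
on a unit carrier, 250 Hz, 60 s. Pairwise phase lags are realised as
per-node phase potentials fitted by least squares (mutually
inconsistent lag matrices are approximated). Directed influence adds
`coef × carrier_source(t − lag)` to the target, so transfer entropy
ground truth is nonzero exactly where the influence matrix is. Phase
integration runs in single precision; the phase statistics of interest
live far above float32 resolution, and generation stays cheap enough
for replicate studies.

**Functional cohort structure.** Each subject receives a random module
partition; module sizes are chosen once per configuration (deterministic
local search) so the within-module pair count equals the
density-matched edge budget, e.g. sizes (6, 5, 5, 4) for 20 ROIs at
22%. Within-module increment correlation is 0.998 — deliberately near
unity so a single 60-s record separates coupled from uncoupled pairs
cleanly (single-record PLV under diffusive coupling is highly variable
at lower correlations); empirical MEG PLV values are lower, which is one
of the stated gaps between the generator and real data. Per-subject
alpha peaks are drawn at 10.2 ± 0.8 Hz (young) and 9.4 ± 0.8 Hz (old),
and small random per-node phase offsets give the wPLI estimator a
nonzero-lag signal to detect.

**Structural matrices and planting.** Because the participation
coefficient is a pure function of per-layer degrees, group effects are
planted in degree space. The structural degree prescription is
k_s(i) = k_f(i) · r^{±1} with r = R^{1−a_i}, R = 3 the full-imbalance
ratio and a_i the node's *alignment*; the up-branch probability
1/(r+1) makes E[k_s | k_f] = k_f exactly, so the marginal degree
distribution of every node is centred independently of the alignment —
alignment effects are visible only to joint (multiplex) statistics.
Participation is ≈ 4r/(1+r)² for both branches, so the alignment
controls its mean tightly (range ≈ 0.80–0.99 at 20 ROIs). Branch
assignment is count-balanced within each alignment stratum (each node's
marginal branch probability is preserved, but the subject-level sum of
prescriptions is nearly deterministic); without this, per-subject
budget fluctuations would shift every node of a subject together and
leak group variance differences into non-target nodes. The small
remaining residual is absorbed by the exact-edge-count realisation,
which preferentially shorts the most extreme prescription (usually the
node that produced the excess). The realisation adopts
functional edges with probability `structural_overlap` (the
edge-identity overlap of the layers) and fills remaining stubs
randomly, always producing exactly the budgeted edge count. FA-like
weights put tract-bearing edges in (0.45, 0.75), a sprinkling of weak
background tracts in (0.05, 0.40) — fewer in the old group, so the
group-minimum density convention is realised there — and 0 elsewhere;
the disjoint ranges make binarisation recover the built edge set
exactly.

The alignment shift that realises a requested standardised effect size
d at the target nodes is calibrated once per configuration by an
internal Monte Carlo over the generator's own randomness (400 virtual
subjects per grid point, fixed internal seed, no signals involved); the
map is monotone and cached, and requested effects beyond the achievable
response range are clipped to it. The effect size is defined as the
shift in mean true participation in units of the baseline
between-subject SD; when the calibrated alignment sits near its ceiling
the old group's variance shrinks, so the *pooled*-SD effect measured
downstream can exceed the planted value.

**Cognition.** Score baselines mimic a published two-group cohort table
(MMSE, VSTM, Cattell, Hotel); the planted score (default VSTM) of old
subjects adds `cognition_slope × (p_true(target) − baseline mean)` plus
Gaussian noise (SD 0.05). Demographics and covariates (age, sex,
education, grey-matter and intracranial volumes) are drawn from
plausible group-specific normals and are independent of the planted
effects.

All generators are pure functions of their spec including the seed:
identical seeds give byte-identical cohorts.

## Calibration studies and problem sizes

`neuroplex.validation` runs the full chain — simulate, detect IAF,
band-limit, estimate PLV, binarise, build multiplexes, score
participation, test — per replicate at the study conditions (46+46
subjects, 20 ROIs, 60 s at 250 Hz, alpha band, 22% density):

* type-I: fraction of null replicates (80 by default) with any
  FDR-corrected nodal discovery; under the global null the BH
  family-wise rate is ≈ q, so the check is against q plus a 99%
  binomial sampling allowance.
* power: per-target FDR rejection rate with d = 1.2 planted at two
  nodes (50 replicates); essentially 1 at these conditions.
* slope recovery: coverage of the planted cognition slope by the
  education-adjusted estimate ± 2 SE (10 replicates, planted without a
  group shift so the old group keeps its baseline variance).
* multiplex specificity: a group-wide alignment shift (0.9 vs 0.45, within the range the
  graph realisation can express for all nodes simultaneously)
  preserves unimodal marginals; the participation contrast detects it
  in ≈ all replicates while the unimodal baseline (two FDR families:
  structural and functional, global + nodal) stays at its null rate
  (20 replicates).

The replicate counts are the package defaults and were chosen to keep a
full calibration run to roughly ten minutes on one CPU; the binomial
allowances quoted above are computed for whatever count is used.

## Known limitations

* The oscillator model has no 1/f background, no amplitude dynamics, no
  cross-frequency structure, and its coupled-pair PLV is far higher
  than typical resting MEG values; passing calibration here shows the
  pipeline's statistics are sound, not that effect sizes transfer to
  real recordings.
* Source reconstruction, leakage and volume conduction are not
  modelled beyond the zero-lag mixing scenario used to characterise
  wPLI; the PCA ROI reduction is exercised on synthetic source stacks
  only.
* Planting works in degree space because the participation coefficient
  is degree-based; edge-identity effects that preserve degrees are
  invisible to it by construction.
* The achievable planted effect range is bounded by the generator's
  alignment response (about ±2 baseline SDs at 20 ROIs); stronger
  requested effects are clipped and reported via the ground-truth
  record.
* The fixed edge budget makes nodal degrees compositional: an extreme
  target prescription (|d| around 2, alignment at its floor) perturbs
  the subject-level degree budget and induces a small opposite-signed
  participation shift (~0.01-0.02, d ~ 0.2-0.3) at non-target nodes of
  the planted group. The branch assignment is count-balanced within
  alignment strata precisely to keep this coupling small; at the
  calibration conditions (planted d = 1.2) the non-target shift is
  indistinguishable from zero.
* The TE plug-in estimator is biased at short records; only
  directional comparisons and permutation-referenced values are used.
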