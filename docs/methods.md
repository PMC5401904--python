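# Methods

This note documents the models behind each pipeline stage, the parameters
that matter, the numerical choices, and what the synthetic generators do and
do not emulate.

## Synthetic cluster recordings

**Topology.** A cluster of n neurons (default range 9–25, matching
medium-sized cultured clusters) is wired by one of four generative models:
Watts–Strogatz small-world (ring degree 4, rewiring probability 0.1),
Barabási–Albert preferential attachment, Erdős–Rényi random, or complete.
The adjacency matrix is symmetric, binary, zero-diagonal. Which topology real
control networks actually have is a hypothesis, not a measurement; the
generator therefore treats it as a configurable mode rather than a fact. The
two preset conditions are

| mode | wiring | transmission |
|---|---|---|
| `control_like` | small-world, ring degree 4, β = 0.1 | 0.2 per edge per frame |
| `mutant_like` | random, edge probability 0.8 | 0.6 per edge per frame |

**Cascade dynamics.** Activity is a discrete-time branching process at the
imaging frame rate (dt = 0.1 s, 1200 frames = 2 min): each neuron initiates
spontaneously per frame with probability 1 − exp(−λ·dt) (λ = 0.01 s⁻¹ per
neuron by default), each spike excites each neighbour on the next frame with
the mode's transmission probability, and a neuron is refractory for 10 frames
(1 s) after firing. This is deliberately the minimal model that produces both
solo events (branching ratio degree×transmission < 1, the control-like
regime) and whole-cluster ignition (dense wiring with supercritical
transmission, the mutant-like regime). It makes no claim about conductances,
synaptic dynamics, or inhibition. Setting λ = 0 and transmission 0 silences
the network entirely (the pharmacological-blockade analogue).

**Indicator model.** Fluorescence is F(t) = F₀·(1 + Σ A·e^(−(t−tₛ)/τ)) plus
white Gaussian noise of SD F₀·σ: instantaneous rise, single-exponential decay
τ = 1.0 s, amplitude A = 0.3 ΔF/F, σ = 0.02 ΔF/F — generic fast synthetic-dye
kinetics, linear summation. Real indicators have finite rise times,
saturation, and correlated (photon + motion) noise; none of that is
emulated, so detection results on synthetic data bound what is achievable on
real recordings from above.

**Seeding.** Every generator is deterministic given its seed. A set-level
seed is expanded with `numpy.random.SeedSequence(seed).spawn(...)`: one child
per cluster, each cluster child spawning (topology, cascade, indicator)
streams. Integer seeds handed to graph generators are the first 32-bit word
of the child's state reduced mod 2³¹.

## ΔF/F and onset detection

Baseline F₀ is the per-neuron rolling 20th percentile over a centred
100-frame window, truncated (not padded) at the recording edges; ΔF/F =
(F−F₀)/F₀, and a non-positive baseline anywhere is an error rather than a
silent clamp. The per-neuron noise scale is 1.4826×MAD of ΔF/F — robust to
the sparse transients that inflate a plain SD — floored at 0.005 ΔF/F
(`noise_floor`) so that noiseless traces still have a finite, re-crossable
threshold. An onset is the first frame at which ΔF/F crosses
median(ΔF/F) + z·scale from below; crossings within 5 frames
(`min_separation_frames`) of an accepted onset are suppressed greedily,
earliest first (this ordering is what makes "raising z never adds events"
provable). Two choices deserve emphasis:

* The threshold is referenced to the ΔF/F **median**, not zero, because a
  20th-percentile baseline sits below the noise median and offsets ΔF/F
  upward by ≈ +0.84·σ on Gaussian noise; an origin-referenced threshold
  would admit far more false crossings.
* The default is z = 3.5. For white Gaussian noise the expected up-crossing
  count in a 1200-frame recording is ≈ 1199·Φc(z); z = 3 would give ≈ 1.6
  false onsets per neuron per recording, while z = 3.5 gives ≈ 0.28,
  comfortably below the design bound of 0.5.

All detection parameters are analysis choices (the assays report responses,
not an operational detection rule) and should be reported with results.

**Resolvability limit.** With τ = 1 s and A = 0.3, ΔF/F decays below the
noiseless threshold (0.0175) in ≈ 29 frames; events of one neuron closer than
that ride on the previous transient and produce no new upward crossing.
Round-trip tests that require exact raster recovery therefore use ground
truth with ≥ 40-frame separations. On noisy traces, threshold re-crossings
during a slow decay can also double-count a transient; raising
`min_separation_frames` trades this against resolving genuine short-interval
events.

## Synchrony statistics

Onsets are merged into synchronous groups when their frames lie within the
synchrony window (default 1 frame = 100 ms, the imaging interval) of another
onset in the group, transitively. Because the criterion is one-dimensional in
time this equals splitting the sorted onset frames at gaps larger than the
window — and is verified in tests against explicit connected components on
the co-occurrence graph. Chain merging was chosen over a fixed time lattice
because a lattice splits events straddling bin edges. Group size counts
distinct neurons. The "all" bin collects groups of size exactly n.

Active fraction is 100·(neurons with ≥ 1 onset)/n; its histogram keeps exact
0 and exact 100 as separate bins and divides (0, 100) into ten half-open bins
[10k, 10(k+1)) — bin edges are a convention the histogram states explicitly.

The response-frequency distribution uses unit-width bins over observed
frequencies ≥ 1. The power-law fit is an ordinary least-squares line through
(log₁₀ f, log₁₀ N(f)) over non-empty bins, requiring ≥ 3 of them — the
estimator that matches the log–log presentation convention, not a
maximum-likelihood exponent estimate. Two consequences are documented
deliberately: the fit is exact on analytically exact power-law histograms,
but on *sampled* histograms the combination of zero-bin exclusion and the
concavity of the logarithm biases the recovered slope toward zero. At the
benchmark scale (280 samples, exponent 0.981, support {1..64}) the mean
recovered slope over replicate fits is ≈ −0.87 rather than −0.981; this is a
property of the estimator at that sample size, and the benchmark reports the
honestly recovered value.

Group comparisons run a two-sided Mann–Whitney U per histogram bin with star
tiers at p < 0.05 / 0.005 / 0.0001. Exact enumeration is used when both
groups have ≤ 8 clusters and the pooled values are tie-free (the exact null
does not correct ties); otherwise the tie-corrected normal approximation.
Per-bin p-values are reported uncorrected, matching how such histogram
comparisons are conventionally annotated, with a Bonferroni column emitted
alongside as an extension.

## Puncta colocalization

Spot detection is Laplacian-of-Gaussian filtering at the PSF scale, local
maxima above a relative threshold with a minimum separation of one PSF sigma
(so sub-resolution doublets merge, as they must), and centre-of-mass
sub-pixel refinement. Neurite pairing accepts an (A, B) polyline pair when a
contiguous stretch ≥ 5 µm (configurable) stays within 0.5 µm point-to-curve
distance. Colocalization is one-to-one greedy nearest-first matching of
centroids within 0.5 µm — the radius reuses the neurite-separation criterion
since no separate dot-overlap radius is established — with ties broken by
index order; one-to-one matching avoids double-counting in dense fields, and
centroid distance (not pixel overlap) is the implemented definition of
"overlapping". For parallel lines at separation d, the chance rate of B spots
within radius r of an A spot is 2·√(r²−d²)·density_B, used for chance
correction in fraction-recovery tests.

The scene generator places straight near-parallel line pairs (length 40 µm)
with a minimum 2 µm clearance between distinct pairs — without the clearance,
chance proximity of unrelated neurites contaminates both the pairing count
and the colocalization ground truth. Real micrographs have curved,
branching, crossing neurites and uneven background; automatic tracing is out
of scope, so polylines are an input.

Survival ratios are round(100·dp/total, 1). Published tables sometimes print
percentages that are not the ratio of the printed pooled counts (per-section
averaging is a common unstated cause); `verify_reported_percent` flags such
rows (tolerance 0.05 percentage points) instead of attempting to reproduce
an unstated averaging scheme.

## Ventral-root rhythm

The envelope is a moving average (default 0.1 s) of |trace − median|. Burst
detection estimates its threshold in two passes — a first robust cut selects
baseline samples, then threshold = baseline median + k·baseline robust SD —
so the bursts themselves do not inflate the noise estimate. The default is
k = 5: after 0.1 s smoothing the baseline SD is an order of magnitude below
the burst plateau, and a lower k lets brief pre-burst noise excursions merge
into the burst run and corrupt onset timing. Sub-threshold gaps < 0.1 s are
fused; runs < 0.2 s discarded. Phases are right-burst **onsets** (not
centres, which shift with duty cycle) expressed within consecutive left-onset
cycles; ≥ 3 left bursts are required. Classification uses the circular mean µ
and resultant length R: R < 0.6 → arrhythmic, else µ within 0.125 cycle of
0.5 → alternating, of 0.0 → synchronous, else arrhythmic; no usable bursts →
no rhythm. The real assays classify these patterns by inspection, so R_min
and the phase tolerance are explicit analysis definitions to be reported with
results. The generator renders bursts as high-variance noise epochs
(amplitude SD 1.0 on baseline SD 0.1, cycle 2 s, duty 0.3, 30 s recordings) —
it does not emulate slow drift, movement artefacts, or cycle-period
variability beyond the chosen mode.

## Benchmark problem sizes

The repository's benchmark computations are desk-scale by design: 20
replicates × 280 sampled frequencies for slope recovery; 35 clusters × 1200
frames through the full fluorescence→detection→classification pipeline for
complete-synchronization recovery; 50-seed batteries for the stochastic
property suites (false-positive rate, colocalization fraction, CPG mode
recovery, topology contrast).

## Known limitations

* The cascade model has no inhibition, latency distribution, or adaptation;
  it is a wiring-density testbed, not a biophysical simulation.
* The log–log least-squares slope is biased on sparse sampled histograms
  (see above); an MLE exponent estimator would remove this but is out of
  scope by design.
* Onset detection double-counts slowly decaying transients on noisy traces
  when threshold re-crossings fall outside `min_separation_frames`.
* Colocalization is 2-D; axial structure is ignored.
* Intensity-correlation colocalization measures (Pearson/Manders) are
  intentionally absent — the analyses are counting-based.
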