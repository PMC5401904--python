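# neurophen

Quantitative phenotyping of neuronal-culture and spinal-cord assays in which
combinatorial cell-surface identity (e.g. loss of all clustered-protocadherin
isoforms) reshapes network wiring. The package implements four analyses as a
reusable, tested pipeline, together with seeded synthetic-data generators so
every stage can be validated against known ground truth without any external
recordings:

1. **Calcium-imaging synchrony.** Multi-neuron fluorescence recordings
   (neurons × frames, 100 ms frame interval, 2-minute recordings) are
   converted to ΔF/F with a rolling-percentile baseline, transient onsets are
   detected at a robust threshold (median + z·1.4826·MAD), and onsets are
   merged into synchronous groups by transitive closure over a time window.
   From the groups come the cluster-level summaries: the synchrony-size
   histogram with a distinguished "all" bin (every neuron of the cluster
   co-active), the active-neuron fraction histogram (exact 0% and 100% kept
   as separate bins around ten interior bins), the per-neuron
   response-frequency distribution with a least-squares power-law fit in
   log–log coordinates (neuron count N(f) ∝ f^s), a complete-synchronization
   classifier, and per-bin two-sided Mann–Whitney U comparisons between
   genotype groups.
2. **Topology-contrast simulation.** A discrete-time branching cascade on a
   configurable graph (small-world / scale-free / random / complete) realises
   the hypothesis that sparse, short-range wiring yields solo-dominated
   activity while dense random wiring yields whole-cluster synchronization.
3. **Two-channel puncta colocalization.** Laplacian-of-Gaussian spot
   detection with sub-pixel centroids, pairing of neurite polylines that run
   side-by-side closer than 0.5 µm, and one-to-one greedy centroid-distance
   matching of the two channels' puncta, with the analytic 1-D chance-overlap
   rate (2·√(r²−d²)·density) available for chance correction. One-way ANOVA
   with post-hoc Tukey HSD compares conditions; survival-ratio arithmetic
   (100·double-positive/total, one decimal) covers chimera cell-count tables.
4. **Locomotor CPG rhythm.** Paired left/right ventral-root traces are
   reduced to rectified-integrated envelopes, bursts are detected with an
   iteratively estimated robust threshold, right-burst onsets are expressed
   as phases of the left burst cycle, and circular statistics (mean µ,
   resultant length R) label the pattern: alternating (µ ≈ 0.5), synchronous
   (µ ≈ 0.0), arrhythmic (low R), or no rhythm.

## Worked example

Simulate the two study conditions and run the full calcium pipeline
(fluorescence synthesis → ΔF/F → onset detection → synchrony statistics):

```python
import numpy as np
from neurophen import simulate, events, synchrony

control = simulate.generate_cluster_set(40, "control_like", seed=1)
mutant = simulate.generate_cluster_set(35, "mutant_like", seed=2)

def analyse(samples):
    rasters = [events.detect(s.recording) for s in samples]
    full_sync = 100 * np.mean([synchrony.classify_full_sync(r) for r in rasters])
    counts = np.concatenate([synchrony.response_frequencies(r) for r in rasters])
    freqs, hist = synchrony.frequency_histogram(counts)
    return full_sync, synchrony.fit_power_law(freqs, hist)

for name, samples in (("control-like", control), ("mutant-like", mutant)):
    full_sync, fit = analyse(samples)
    print(f"{name:13s} n={len(samples):2d}  full-sync clusters: {full_sync:5.1f}%   {fit.summary()}")
```

which prints

```
control-like  n=40  full-sync clusters:   2.5%   power-law fit: slope=-0.816 intercept=2.137 r2=0.354 over 12 bins
mutant-like   n=35  full-sync clusters: 100.0%   power-law fit: slope=1.246 intercept=-0.456 r2=0.134 over 24 bins
```

Control-like clusters are dominated by solo events: almost none reach
complete synchronization and their response-frequency distribution is
heavy-tailed with a negative log–log slope. Mutant-like (densely, randomly
wired) clusters synchronize completely, and their frequency distribution is
bell-shaped — the power-law relationship disappears (positive slope, low r²).

A command-line interface wraps the same functions
(`neurophen simulate|detect|synchrony|coloc|counts|cpg`); e.g.

```bash
neurophen simulate --mode mutant_like --n-clusters 5 --seed 3 --out-dir sim/
neurophen detect sim/traces_*.csv --out-dir detected/
neurophen synchrony detected/raster_*.csv --out report.json
```

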