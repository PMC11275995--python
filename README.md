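# bindloop

Quantitative machinery for linking the **chromatin binding kinetics** of a
DNA-binding factor (such as CTCF and its zinc-finger mutants) to **genome
organization**. The package covers both halves of that comparison:

- **FRAP kinetics** — turn fluorescence-recovery-after-photobleaching movies
  into photobleaching-corrected, normalized recovery curves; fit a two-state
  reaction-dominant binding model; report the specific bound fraction and
  residence time with bootstrap uncertainty.
- **Hi-C statistics** — ICE matrix balancing, relative contact probability
  P(s), the P'max loop-size estimate from the log-log derivative of P(s),
  diamond-window insulation scores with boundary calls, and aggregate
  peak/site pileups.
- **Associations** — ordinary least-squares fits relating per-condition
  kinetic parameters to genomic summaries (R², p-value, optional permutation
  test), plus a BED interval-overlap helper.
- **Synthetic data** — generators for FRAP movies (drifting nucleus, 1 µm
  bleach spot, two-phase acquisition, acquisition photobleaching, noise) and
  Hi-C contact matrices (power-law decay, TADs, loops) with known ground
  truth, so every stage of the pipeline is verifiable without any download.

## The model

A bleached spot recovers as unbleached molecules exchange with binding sites.
In the reaction-dominant regime the normalized recovery is

```
FRAP(t) = 1 − C_eq,fast · exp(−k_off,fast · t) − C_eq,slow · exp(−k_off,slow · t),
          k_off,slow < k_off,fast
```

where the fast component reflects transient, non-specific binding and the
slow component specific chromatin binding. `C_eq,slow` is the **specific
bound fraction** and `1 / k_off,slow` the **specific residence time**
(minutes). Before fitting, the measured spot intensity `I_bleach(t)` is
background-subtracted, divided by a correction series
`C(t) = smooth(I_nonbleach − I_background) / ⟨·⟩_prebleach` that tracks
acquisition photobleaching, and scaled so the prebleach mean is 1.
Parameter distributions come from resampling movies with replacement and
refitting the pointwise-mean curve of each resample.

On the Hi-C side, the insulation score of a bin is the log2 ratio of the mean
of the w×w diamond of contacts crossing it to the genome-wide mean diamond;
minima below a threshold are TAD boundaries. P'max is the distance at which
the first derivative of log10 P(s) vs log10 s (after Loess smoothing) peaks —
a proxy for the average extruded loop length.

## Worked example

```
$ python examples/fit_kinetics.py
specific bound fraction:  0.282  (truth 0.300)
specific residence time:  1.54 min  (truth 1.50)
bootstrap 95% interval of the bound fraction: [0.221, 0.341]
bootstrap residence-time median: 1.54 min
```

Thirty recovery curves are simulated on the reference acquisition schedule
(25 frames at 0.5 s, then 160 at 4 s, bleach after frame 8) from a ground
truth of 30% stably bound molecules with a 1.5 min residence time; the fit of
the mean curve recovers both, and the bootstrap interval covers the truth.

```
$ python examples/hic_summaries.py
contact decay slope (log P vs log s): -1.15  (generated with exponent -1)
P'max loop-size estimate: 125 kb  (loops placed at 200 kb)
insulation boundaries at bins: [60, 120, 160, 240]  (TAD edges at 60, 120, 160, 240)
loop pileup center/corner enrichment: 4.17 over 30 anchors
```

The other examples (`frap_pipeline.py`, `kinetics_to_genome.py`) walk through
movie preprocessing and the kinetics-to-genomics regression.

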