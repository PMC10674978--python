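# cecgstress

Stress-level detection from capacitive ECG (cECG) recorded during driving.

The package implements a four-stage pipeline for single-channel cECG:

1. **Artifact reduction** (`cecgstress.artifacts`) — the signal's
   centralized cumulative-sum profile is split into fixed-length segments
   and each segment's detrended-fluctuation value (FD, the mean squared
   residual of a within-segment linear fit) is compared against
   data-driven thresholds. When a global range-vs-power check flags coarse
   motion artifacts, high-FD segments are eliminated, neighbours that
   differ by more than half the threshold go with them (spill-over), and a
   fixed low threshold removes slow-drift segments. The denoised signal is
   the concatenation of kept segments.
2. **Feature extraction** (`cecgstress.features`) — R peaks are detected
   with a Pan–Tompkins-family detector refined to raw-signal maxima; each
   non-overlapping 50-s window yields four features: mean R amplitude,
   heart rate, pNN50, and BinEn.
3. **Binarized approximate entropy** (`cecgstress.binen`) — approximate
   entropy of the sign sequence of first differences, computed in linear
   time by counting binary embedding vectors and comparing them through a
   Hamming-distance matrix.
4. **Classification** (`cecgstress.classify`) — kNN, SVM, or a
   two-hidden-layer tanh network (20 units per layer, squared-error loss,
   learning rate 0.5) evaluated with subject-grouped cross-validation and
   reported as balanced accuracy, sensitivity, specificity, PPV, NPV and
   MCC (with explicit undefined markers for empty denominators).

A synthetic generator (`cecgstress.synthetic`) produces labeled cECG with
known R-peak positions, artifact masks and class-conditional heart-rate
structure, so the entire pipeline is testable without external recordings.

## Command line

```sh
# synthetic cECG with one 20 mV motion artifact per 2 minutes
cecgstress simulate --duration-s 180 --artifact-rate-per-min 0.5 \
    --artifact-amp-mv 20 --seed 1 --out sig.csv

cecgstress preprocess sig.csv --out denoised.csv   # + denoised.segments.csv
cecgstress features denoised.csv --label low_stress --subject s0 --out feat.csv
cecgstress binen denoised.csv -m 2 -r 0
cecgstress evaluate features.csv --kind ann --out metrics.json

# full pipeline on the built-in separable synthetic two-class dataset
cecgstress run-all --outdir out/ --seed 1
```

Signals are two-column CSV (`time_s, amplitude_mv`); features a flat CSV
table; metrics JSON. Every output carries a header with the package
version and a configuration hash.

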