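# broadlrtc

Short- and long-range temporal correlation analysis of broadband EEG
during movement, as a tested Python pipeline:

- **Sliding-window DFA**: Hurst exponent of every causal 2 s window
  (256 samples at 128 Hz, stepped by 100 ms), 25 box sizes
  log2-equispaced in [10, N/4], forward/backward averaging, optional
  Hanning taper, ML model comparison validating the log-log linearity,
  exponential smoothing of the H time course.
- **ARFIMA(p, d, 0) modeling**: two-stage fit with d = H − 0.5 from DFA,
  FFT-based fractional differencing, ADF stationarity check, AIC order
  selection, conditional-ML AR estimation, Ljung-Box / KS residual
  diagnostics — 11 parameters (d + AR1..AR10) per window.
- **ERD**: percent alpha-band (8–13 Hz) Hilbert power change against a
  resting-state baseline.
- **Complementarity ablations**: remove long-range correlation by
  fractional differencing, or fix the alpha-band Fourier magnitudes to a
  random donor window; Mann-Whitney condition contrasts; ERD–LRTC
  correlation and cross-correlation lag analysis.
- **Classification**: per-window movement-vs-rest LDA over five feature
  sets (LRTC 3, ERD 2, ARFIMA 21, LRTC+ERD 5, ARFIMA+ERD 23 features),
  repeated stratified 10×10-fold CV, exact-binomial chance threshold and
  detection-time extraction.
- **Synthetic data**: exact fractional Gaussian noise (circulant
  embedding), ARFIMA simulation, and full movement experiments with a
  programmed fractional-integration ramp and alpha suppression around
  onset, so everything is testable without external downloads.

## CLI

```sh
broadlrtc simulate --config sim.yaml --out data/ --seed 1
broadlrtc preprocess --in data/participant_00.tsv --band 0.5 45 --notch 50 --fs-out 128 --out prep.tsv
broadlrtc dfa       --in prep.tsv --taper --smooth 0.3 --out dfa.tsv
broadlrtc arfima    --in prep.tsv --p 10 --out arfima.tsv
broadlrtc erd       --in prep.tsv --band 8 13 --out erd.tsv
broadlrtc ablate    --in prep.tsv --mode suppress-erd --seed 1 --out ablated.tsv
broadlrtc classify  --store arfima.tsv --features arfima+erd --seed 1 --out metrics.tsv
broadlrtc report    --stores a.tsv --stores b.tsv --quantity H --out grand.tsv
```

Recordings are plain TSV matrices (one column per channel, `# fs=` header
line) with a sibling `.events.tsv` (onset_seconds, condition). Feature
stores are long-format TSV (trial, condition, channel, t, H, d,
ar1..ar10, band_power, erd_percent).

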