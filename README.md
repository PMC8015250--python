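# nucleodrift

Quantification of interphase nuclear movement in rod-shaped, tip-growing
cells (fission-yeast-like geometry) from fluorescence time-lapse movies —
plus a matched synthetic-movie generator so the whole measurement chain can
be validated against ground truth.

## The problem

In tip-growing rod cells the interphase nucleus is actively kept at the
cell center, and its position sets the division plane. Microtubule pushing
forces are the classical centering mechanism, but a slower,
microtubule-independent movement also directs the nucleus toward the
growing cell tip (~12 nm/min, never faster than tip growth, strongest when
the nucleus is near the growing tip). Quantifying this requires measuring
very slow (nanometers per minute) directed motion of a ~2.4 µm organelle
inside a growing cell from movies at 5-min (movement) or 1-min
(fluctuation) intervals — which is what this package does.

For a cell with non-growing tip `tip_ng` and growing tip `tip_g`, the
package measures per movie:

- **net nuclear velocity** `v = Δd_ng / T` (nm/min), where
  `d_ng = x − tip_ng` is the nucleus-to-non-growing-tip distance — positive
  toward the growing tip, reported uncorrected for tip swelling;
- **direction class** (toward / stationary / away) with a ±0.25 µm dead
  band on net displacement;
- **centering ratio** `s/l` and `s/(s+l)` (shorter/longer nucleus-to-tip
  distances), late-interphase `a/b` (analyzed as log2), septum position
  `s/(s+l)`;
- the **velocity vs. fractional start distance** regression (`g/L` at movie
  start; slope, r², p), which separates a centering regime (positive slope)
  from distance-independent drift (no relationship);
- **detrended RMS fluctuation**: residuals of the nuclear track about a
  centered `W`-frame running average; for iid noise of sd σ the residual
  variance is σ²(1 − 1/W);
- 11-px-wide **kymographs** along the cell axis as a QC product.

The synthetic generator simulates the matching motion regimes —
midpoint-directed Ornstein–Uhlenbeck centering (`wt_dmso`), tip-directed
drift `v(g) = vmax·exp(−g/lam)` after microtubule depolymerization
(`wt_mbc`), driftless diffusion (`cable_null_mbc`), and Markov-switched
intermittent drift (`myo52_mbc`) — and renders them as noisy 16-bit movies
with ground-truth tables. See `docs/methods.md` for the model, parameter
defaults, and numerical choices.

## Worked example

Simulate a small microtubule-depolymerized cohort, analyze it, and report:

```sh
nucleodrift simulate --mode wt_mbc --n 5 --seed 7 --out demo/
nucleodrift analyze demo/ --pixel-size 0.10 --interval 5 --out demo/summary.csv
nucleodrift report demo/summary.csv
```

The analysis step writes one kymograph per cell and a per-cell summary;
the report prints:

```
== net velocity (nm/min) ==
         n       mean        sd
mode
summary  5  17.043189  2.189182

== centering s/(s+l) ==
         n      mean        sd
mode
summary  5  0.422298  0.032383

== a/b ratio ==
         n      mean       sd
mode
summary  5  0.892438  0.20525

== net velocity vs fractional start distance (OLS) ==
summary: slope=17.8 nm/min per unit, r2=0.489, P=0.1887, n=5
```

All five cells move toward the growing tip, at 17 ± 2 nm/min for this
particular draw (the v(g) drift — ~12 nm/min for a centered nucleus,
stronger for the cells that start nearer the tip — plus the ~2 nm/min
tip-swelling artifact the estimator deliberately leaves uncorrected). They
start near-centered (s/(s+l) ≈ 0.42), end the movie with the nucleus
biased toward the growing tip (a/b < 1), and at n=5 show no significant
velocity-position relationship (P = 0.19) — the drift regime produces no
such relationship even at large n, whereas a centering regime yields a
strongly significant positive slope.

The same machinery is available as a library: `simulate_trajectory` /
`render_stack` / `generate_cohort`, `analyze_stack`, `make_kymograph`,
`detrend` / `rms` / `compare_rms`, and `direction_assay` for
simulate-and-measure cohorts (see docstrings).

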