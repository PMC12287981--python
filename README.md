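# mobispect

Frequency-domain analysis of smartphone GPS mobility for mood-disorder
digital phenotyping.

Passively sensed GPS trajectories carry behavioral signatures of mood:
people move less, over smaller ranges, and between fewer places when
depressed, and bipolar disorder expresses itself in multi-day *rhythms*
of mobility that unipolar depression lacks. `mobispect` is a complete,
reproducible pipeline for studying these signatures — aimed at
researchers in psychiatric epidemiology and digital phenotyping who
want to test frequency-domain mobility analyses without access to raw
patient data.

The pipeline:

1. **simulate** — a synthetic three-group cohort (healthy control /
   bipolar / unipolar depression) of duty-cycled GPS fixes (60 s on at
   1 Hz, 600 s off) and daily four-item mood EMAs (1–5), with
   mood-modulated mobility and group-specific rhythm structure;
2. **preprocess** — 50 m accuracy gate, 10-s position bins,
   stationary/moving segmentation (move when a 10-s displacement
   exceeds √10 m; gaps resolve by a 75 m / 6 min rule), linear
   trajectory imputation under 10 stochastic completions, and a
    6-valid-hours day filter;
3. **features** — the eight standard daily mobility features:
   location variance LV = ln(σ²ₓ + σ²ᵧ), speed mean SM and variance SV,
   number of clusters NC, location entropy −Σpᵢln pᵢ, homestay,
   transition time TT, and total distance TD;
4. **spectral** — hourly feature series → power spectrum
   P(f) = |X(f)|²/N over 28-day windows; per participant the top-5
   peaks ranked by power, each with period 1/f; per group the
   consensus cycle lengths carried by >50% of members;
5. **analyze** — Kruskal-Wallis / Mann-Whitney group tests on ranked
   powers, VIF-pruned person-day logistic models of depressive status
   on GPS features (weekday/weekend strata), spectrum-power logistic
   models under four covariate sets, mood-fluctuation day rates, and
   the Fisher-z sample-size rule.

## Worked example

Duty-cycle arithmetic and the design's power calculation:

```pycon
>>> from mobispect import synthetic as syn, inference as inf
>>> syn.expected_fix_count(on_s=60, off_s=600, rate_hz=1)
327
>>> inf.sample_size_correlation(r=0.5, alpha=0.05, power=0.90)
38
```

327 is the expected GPS yield per hour under the 60 s/600 s duty cycle;
38 participants are needed to detect a correlation of 0.5 at α = .05
with 90% power.

Rhythm recovery on a synthetic bipolar group (12 participants, 28 days,
hourly location variance, cycles injected at 1, 4 and 9 days):

```pycon
>>> from mobispect.config import CohortConfig
>>> from mobispect import features as feat, spectral as sp
>>> cfg = CohortConfig(n_hc=0, n_bp=12, n_mdd=19, n_days=28, seed=1)
>>> peaks = []
>>> for p in syn.generate_cohort(cfg):
...     if p.group != "BP":
...         continue
...     hourly = syn.simulate_hourly_features(p, cfg)
...     series, step, ok = feat.build_feature_series(hourly, "LV", "hourly", window=(0, 672))
...     peaks.append(sp.top_k_peaks(sp.periodogram(series, step), 5, p.id, "LV"))
>>> tab = sp.cohort_period_consensus(peaks)
>>> tab[tab["majority"]]
   period_days  count  rank_sum  majority
0            1     12        25      True
1            4     12        21      True
2            9     12        26      True
```

All 12 simulated bipolar participants carry the 1-, 4- and 9-day cycles
among their top-5 spectral peaks (count = 12); the summed ranks grade
intensity (lower = stronger). The aperiodic depressed group produces no
majority period under the same procedure.

The same analysis runs end to end from the shell:

```bash
mobispect run-all --out runs/demo --seed 1
```

which writes `features.csv` (one row per participant-day),
`spectra.csv` (ranked peaks), `consensus.csv` (group cycle tallies),
`daylevel_models.csv` / `spectrum_models.csv` (logistic fits:
β, OR, 95% CI, p) and `group_tests.csv` (Mann-Whitney on maximum
power) under a JSON manifest; re-running with the same config and seed
skips completed stages.

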