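# fpvs

Frequency-tagging (FPVS) oddball analysis for MEG/EEG sensor data: stimulus
sequence construction, synthetic cohort simulation, SNR spectra, and a
sensor-space cluster-based permutation test — with the validation studies
that demonstrate every stage on data with known ground truth.

## The problem

In a fast-periodic-visual-stimulation oddball experiment, stimuli stream at
a fixed base rate *F* (6 Hz here) with a deviant item every *n*-th position
(*n* = 5, so the oddball rate is *F/n* = 1.2 Hz). Any neural process that
discriminates oddballs from base items — for instance, recognizing the stem
*soft* inside the pseudoword *softity* while the surrounding stream shows
*trumess*-like items — produces periodic signal exactly at 1.2 Hz and its
harmonics. The analysis question is: **on which sensors is the spectral
response at the oddball frequencies reliably above the noise floor?**

The chain implemented here:

1. **Stimuli** (`fpvs.stimuli`): morpheme inventories (4-letter stems /
   nonstems × 3-letter suffixes / nonsuffixes) crossed within subsets into
   7-letter pseudowords — 2·s² combinations per class — and assembled into
   360-item, 60-s sequences with oddballs at positions 5, 10, …, 360 and no
   identical item within 5 positions.
2. **Simulation** (`fpvs.simulate`): 160-sensor upper-hemisphere layouts,
   trials of tagged sinusoids (base + oddball harmonics, spatially weighted)
   in 1/f + white noise, log-normal between-subject gains, all seeded.
3. **Spectra** (`fpvs.spectral`): trim the onset transient, average trials,
   take the plain DFT amplitude sqrt(Re²+Im²)/N, normalize each bin by the
   mean of 20 surrounding bins (10 per side, skipping the adjacent bin) into
   an SNR spectrum, and average SNR over the oddball bin and its first three
   harmonics into one scalar per sensor.
4. **Statistics** (`fpvs.cluster`): a one-tailed one-sample cluster
   permutation test of those scalars against the noise level 1 — per-sensor
   t = (x̄ − 1)/(s/√n), cluster-forming threshold t₁₋α(df), clusters =
   connected suprathreshold sensors under Delaunay adjacency (each needing
   ≥ 2 suprathreshold neighbors), cluster score = Σt, null distribution from
   5,000 subject-wise sign flips of the deviations, p = (1 + #{max ≥
   score})/(1 + N).

See `docs/methods.md` for the model, parameter defaults, numerical choices,
and limitations.

## Worked example

Run the scaled-down developmental scenario — 17 subjects × 3 conditions ×
160 sensors, six 12-s trials each, oddball response seeded in a posterior
patch for the manipulation-check condition (0) and one morphological
condition (1), none in condition 3:

```bash
fpvs run --scenario child --trial-duration 12 --seed 0 --out runs/child
fpvs report --run-dir runs/child | head
```

which prints

```
condition 0: significant clusters: 1 (p=0.0002)
condition 1: significant clusters: 0 (none)
condition 3: significant clusters: 0 (none)
```

The condition-0 cluster spans 13 posterior sensors with a summed t of 33.1
against a threshold of t(16) = 1.75 — a word-in-nonwords response well above
the SNR noise floor — and its Monte Carlo p of 0.0002 is the smallest value
5,000 permutations can resolve.

Condition 0 carries the strongest seeded effect and survives at these
reduced trial lengths; the weaker condition-1 effect needs the full 60-s
trials to rise above the noise floor, and the zero-effect condition 3 stays
silent. `runs/child/` then contains `responses.tsv` (8,160 oddball-response
scalars: 17 × 3 × 160), a per-condition cluster report
(`clusters_condition*.json`: member sensors, summed t, Monte Carlo p), the
per-sensor t maps, and `report.json` with a content hash that reproduces
bit-for-bit from the same config and seed.

The same stages are available as library calls (`fpvs.pipeline.run_pipeline`)
and as separate CLI verbs (`simulate`, `spectra`, `cluster`, `report`).

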