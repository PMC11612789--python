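# shrewvoc

Vocal-repertoire analysis for Etruscan shrew (*Suncus etruscus*) ultrasonic
calls: a tested, reusable re-implementation of the full analysis chain that
takes high-frequency recordings (192–200 kHz WAV) from call detection to
graded/discrete call-type classification and behavioural-context statistics.
It is aimed at bioacousticians who want to reproduce or extend
repertoire-gradation analyses on their own recordings, and it ships a
synthetic-call generator with known ground truth so every stage is testable
without animal data.

## What it computes

1. **Call units** — energy-threshold detection; for pups, bursts separated
   by gaps < 50 ms are merged into one call.
2. **22 acoustic parameters** per high-quality call: duration and time of
   peak amplitude; voiced percentage, harmonics-to-noise ratio and Wiener
   entropy (dB → linear, `10^(dB/10)`); F0-contour statistics from an
   autocorrelation pitch tracker (5–100 kHz search range); power-spectral
   moments (centre of gravity, SD, skewness, excess kurtosis); and LPC
   formant-like resonances for non-tonal calls, with the formant ceiling
   scaled from a 1.2 cm vocal tract. Parameter availability follows the
   tonality class (tonal / non-tonal / mixed).
3. **Soft clustering** — the nine all-call parameters are z-scored, embedded
   with UMAP, and clustered with from-scratch fuzzy c-means
   (c = 3, fuzzifier μ = 2, ≤ 100 iterations). Memberships `u_ik` follow

       u_ik = [ Σ_j (d_ik / d_jk)^{2/(μ−1)} ]^{−1}

   with Euclidean `d`, alternated with `u^μ`-weighted centroid updates.
4. **Gradation** — typicality coefficient = largest − second-largest
   membership; tercile thresholds split calls into typical / atypical /
   neither; voiced-percentage boundaries assign final call types
   (scream ≥ 95 %, screech = 0 %, graded screech-scream in between, chirps
   from the short-tonal cluster).
5. **Context and rates** — ethogram alignment (interactions outrank
   position events), per-behaviour call-type shares, proximity shares,
   call rates (N/min), linear mixed models (ML) with individual random
   intercepts, Tukey-adjusted least-squares means, Fisher omnibus
   combination, Cohen's κ, and backward stepwise elimination of
   interaction terms.

## Worked example

```python
import shrewvoc as sv

cfg = sv.PipelineConfig(seed=1)       # default: 600-call synthetic campaign
result = sv.run_pipeline(cfg)
print(result.repertoire.summary())
print(f"kappa vs ground truth: {result.kappa_vs_truth():.3f}")
```

prints

```
Vocal repertoire soft clustering
================================================
calls: 600   clusters: 3 (mu=2.0, space=features)
typicality thresholds: atypical < 0.498 < neither < 0.852 < typical

            n_calls  mean_voiced  mean_duration  mean_typicality         role
hard_label
0               217       97.237          0.197            0.469   long_tonal
1               138       89.341          0.077            0.542  short_tonal
2               245        5.782          0.129            0.834        noisy

call types: screech=200, scream=199, chirp=138, screech_scream=63
typicality: typical=200, neither=200, atypical=200

kappa vs ground truth: 0.912
```

Reading this: the three clusters recover the long-tonal screams (cluster 0,
mean duration 0.20 s, 97 % voiced), the short-tonal chirps (cluster 1,
0.08 s) and the noisy screeches (cluster 2, 6 % voiced). Graded
screech-screams, synthesized with tonal fractions between 0.15 and 0.85,
are the least typical calls and are labelled by the voiced-percentage
boundaries; κ = 0.91 against the generator's ground-truth types.

The same pipeline runs from the shell:

```bash
shrewvoc synthesize --config cfg.yaml --out data/      # WAV + TextGrid + CSV
shrewvoc run-all    --config cfg.yaml --out results/
```

and on real recordings with `input_mode: recordings` pointing at a
directory of WAV files with TextGrid/CSV behaviour annotations and a dyad
metadata table.

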