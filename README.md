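# topomap

Objective detection and quantification of topography in neural maps.

Topographic maps — arrangements in which anatomically nearby neurons have
similar functional selectivity — are usually identified by eye. When a map
is weak, noisy, or sampled at only a few dozen recording sites (serial
single-unit electrophysiology, small imaging fields), subjective judgement
is unreliable. `topomap` provides statistics and tests that settle the
question objectively, for anyone working with scattered "position +
characteristic stimulus" data: auditory tonotopy and spatial-cue maps,
retinotopy at coarse sampling, voxel-level feature maps, and the like.

## What it computes

A *sampled map* is `n` units with 2-D map-space (anatomical) coordinates
`r_i` and a scalar feature label `s_i` (characteristic frequency, preferred
azimuth, IID...), optionally circular. Seven measures compare distances in
the two spaces, most of them instances of the generic functional
`C = Σ_{i<j} d_F(s_i, s_j) · d_M(r_i, r_j)`:

| measure | idea | more ordered |
|---|---|---|
| PC | Pearson correlation of pairwise feature vs map distances | larger |
| SC | Spearman (rank) version of PC | larger |
| TC | correlation of Delaunay-graph geodesics with label rank differences | larger |
| WL | anatomical wiring length over feature-adjacent pairs (normalized) | smaller |
| PL | feature travel along anatomical Delaunay edges (normalized) | smaller |
| ZM | Zrehen measure: feature-space "intruders" between anatomical neighbors | smaller |
| TP | topographic product: distortion of k-nearest-neighbor orderings | smaller |

Significance comes from label-shuffling permutation tests (Monte-Carlo
`p = (b* + 1)/(m + 1)`, or exact enumeration when the label multiset has few
distinct arrangements), with Benjamini–Hochberg or (uncapped) Bonferroni
correction across tests, and a pooled multi-subject test based on the
multi-subject Pearson distance correlation. Generative map models (linear
gradient, orientation-map-like angle maps, homogeneous clusters) with
quasi-random disc sampling and SNR-controlled label noise support power
analysis: `N80`, the number of sampled units needed for 80% detection power
at α = 0.05, per measure/model/SNR. A tuning module extracts
characteristic-stimulus labels from Gaussian/sigmoid tuning-curve fits and
estimates map SNR from a bilinear (planar) fit.

## Worked example

```python
import numpy as np
import topomap as tm

# simulate a noisy linear map sampled at 40 sites in the unit disc
field = tm.generate_linear_map(seed=2)
smap = tm.sample_map(field, tm.SamplingConfig(n_points=40, snr=2.0, seed=3))

res = tm.permutation_test(smap, "PC", m=9999, seed=4)
print(f"PC = {res.measure.value:.3f}, p = {res.p:.4f} ({res.mode})")
```

prints

```
PC = 0.491, p = 0.0001 (monte_carlo)
```

a Pearson distance correlation of 0.491 — pairs of sites that are far apart
anatomically tend to carry more dissimilar labels — with the smallest
p-value attainable from 9999 shuffles: none of the shuffled maps was as
ordered as the observed one, so the map is significantly topographic.
The same workflow is available from a shell:

```sh
topomap simulate --model linear --n 40 --snr 2 --seed 3 -o map.csv
topomap test map.csv --perms 9999 --correction bh --seed 4 -o results.csv
```

which tests all seven measures and appends a BH-corrected p-value column.

## Layout

- `topomap.core` — sampled-map container, distances, ranks, Delaunay
  neighbor graphs, geodesics
- `topomap.measures` — the seven measures and their polarity registry
- `topomap.significance` — permutation tests (vectorized kernels, exact
  mode), multi-subject pooling, multiple-test corrections
- `topomap.models` — generative map models, Halton sampling, label noise
- `topomap.power` — power estimation, N80 search, measure comparison
- `topomap.tuning` — tuning-curve fits, characteristic labels, bilinear SNR
- `topomap.io` / `topomap.cli` — delimited-text tables and the `topomap`
  command

See `docs/methods.md` for the modeling assumptions and numerical choices.
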