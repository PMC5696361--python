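# spinemap

Spatial and intensity statistics for maps of potentiated dendritic spines.

Activity-dependent tagging reporters mark the spines of a neuron that
underwent late-phase synaptic potentiation, turning each imaged dendrite
into a *labeled point pattern*: an ordered list of spines with 3D
coordinates (μm) and a binary "potentiated" label. `spinemap` implements
the quantitative pipeline for such maps, for neuroscientists who have
already segmented their images into per-spine coordinate/intensity tables
and want the downstream statistics to be reproducible and testable:

* **First-neighbor distances.** For each potentiated spine, the 3D
  Euclidean distance to its nearest potentiated (d<sub>PP</sub>) and
  nearest non-potentiated (d<sub>PN</sub>) neighbor within the same
  dendrite, compared against a null built by randomly permuting the labels
  over the fixed spine positions (five shuffles per dendrite).
* **Neighbor-rank probability curve.** For each potentiated focal spine,
  the labels of its 20 nearest neighbors form one row of an N×20 matrix;
  the column means estimate P(potentiated at rank *i*), normalized by the
  exchangeable-label expectation (p−1)/(T−1) — where p and T are the
  dendrite's potentiated and total spine counts — and tested against 1
  with a one-sample z-test. Dendrites with p/T < 0.05 or T < 21 are
  excluded from this analysis only.
* **Spine units.** Single-linkage clustering of potentiated spines at a
  strict < 2 μm cutoff; units of size ≥ 2 are clusters, isolated spines
  are units of dimension 1. Summaries: mean unit size, 5th/95th
  percentiles of cluster dimension, fraction of potentiated spines in
  clusters.
* **Separation Index.** Per slice, f = Σp / ΣT over its dendrites; per
  dendrite, p\* = f·T and SI = |p − p\*| / p\*, measuring how far a
  dendrite deviates from a uniform allocation of potentiated spines.
* **Intensity metrics.** Enrichment Index
  EI = (I<sub>spine</sub> − bg) / (I<sub>shaft,1–2 μm</sub> − bg);
  PSD-normalized enrichment (non-expressing spines assigned 0);
  docked / positive-not-docked / negative classification by reporter-peak
  distance to the PSD (0.6 μm search circle); ΔCh/Ch and ΔV/V time
  courses relative to the −5′ reference; ΔF/F integration over the first
  200 post-stimulus frames after dark-level subtraction; laminar profile
  alignment (anchor at 100 μm), 5 μm binning, averaging and
  max-normalization.
* **Synthetic data.** A generator producing dendrites as smooth 3D curves
  carrying 20–150 spines at realistic densities, labels that are either
  exchangeable or cluster-seeded (characteristic radius ~2 μm), per-spine
  intensity tables and stimulation-locked traces — so every statistic can
  be validated against known ground truth.

## Worked example

Simulate a cluster-seeded dataset and analyze it in one step:

```sh
cat > clustered.yaml <<EOF
out_dir: demo_clustered
seed: 42
generator:
  n_dendrites_per_slice: 10
  label_mode: clustered
  within_cluster_label_prob: 0.9
EOF
spinemap analyze --config clustered.yaml
spinemap report demo_clustered
```

The report (40 dendrites, 2567 spines) includes, per region × condition,
the probability-increase table — for CA1/home-cage:

```
| region | condition | position | mean_increase |    sem |      z | p_value |
|:-------|:----------|---------:|--------------:|-------:|-------:|--------:|
| CA1    | home_cage |        1 |        3.9022 | 0.8159 | 3.5569 |  0.0004 |
| CA1    | home_cage |        2 |        3.1563 | 0.8202 | 2.6289 |  0.0086 |
| CA1    | home_cage |        3 |        3.0950 | 0.8149 | 2.5710 |  0.0101 |
```

The rank-1 spine of a potentiated spine is ~3.9× more likely to be
potentiated than the exchangeable-label expectation — the generator
seeded label clusters of ~2 μm radius, and the statistic recovers them
(z-test against 1, p = 4·10⁻⁴). The spine-unit table shows the same
structure as clustering: 83% of potentiated CA1/home-cage spines belong
to a cluster (mean unit size 3.0, cluster dimension 95th percentile 9).
With `label_mode: random` the same pipeline yields increase values
statistically indistinguishable from 1 and observed d<sub>PP</sub> equal
to the shuffle null — the calibration checked by the test suite.

Outputs are tidy TSVs (`neighbor_distances.tsv`, `probability_curves.tsv`,
`cluster_units.tsv`, `separation_index.tsv`, `intensity_metrics.tsv`), a
JSON run summary (counts, exclusions, seeds, sha256 manifest) and a
markdown report. The same functions are importable from Python
(`spinemap.run_analyze`, `spinemap.neighbor_probability_curve`, …).

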