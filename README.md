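# mcsquant

Quantification of organelle contact-site association from fluorescence
time-lapse microscopy and immunogold electron microscopy.

Membrane contact sites (MCS) — in particular mitochondria-associated ER
membranes (MAMs) — tether the endoplasmic reticulum to mitochondria within
tens of nanometers. Candidate contact-site proteins appear in fluorescence
imaging as diffraction-limited puncta that sit on, or very near, the
organelles they bridge. Because a dense ER network fills much of a cell, a
punctum can be "near the ER" purely by chance; deciding whether proximity
is real therefore requires an explicit chance model. `mcsquant` implements
the quantitative toolkit for that question, for biologists analyzing
punctum-organelle association:

* **Trajectory-randomization proximity statistics.** Puncta are detected
  per frame (Laplacian-of-Gaussian, subpixel refinement), linked into
  trajectories (greedy mutual-nearest neighbor with gap closing), and each
  detection contributes one sample of the minimal Euclidean distance d
  (nm) from the punctum centroid to the nearest organelle-positive pixel.
  The statistic per cell is the fraction of samples with d ≤ 100 nm. The
  null is built by rigidly repositioning each whole trajectory — uniform
  translation, optionally plus rotation about its centroid — within the
  cytoplasm mask, preserving trajectory shape exactly. Across n cells,
  observed and randomized fractions are compared with a two-sided
  Student's paired t-test, t = mean(d)/(SD(d)/√n), df = n − 1.
* **Immunogold quantification.** Fixed-area EM images with gold-cluster
  centroids and mitochondrial outlines yield cluster density (mean ± SEM
  of per-image clusters/µm²) and the fraction of clusters "directly
  associated" with mitochondria (inside an outline or within 30 nm of its
  boundary by default).
* **Cofractionation correlation.** Pearson r between density-gradient
  profiles of two markers, with the exact two-sided p-value from
  t = r·√(n−2)/√(1−r²) at n − 2 df.
* **Manders colocalization coefficients** M1/M2 between two channels.
* **A synthetic-data generator** that produces every input above with
  known ground truth: cells with a dense tubular ER, elongated
  mitochondria, moving puncta whose organelle association is controlled
  by a seeding probability `p_assoc`, rendered stacks with Gaussian PSF
  and Poisson + Gaussian noise; immunogold point fields; and correlated
  fraction profiles.

## Worked example

Simulate four cells at the default study conditions (45% of puncta seeded
ER-associated within 100 nm; an ER whose 100 nm neighborhood covers about
half the cytoplasm), then run the proximity analysis on the ground-truth
tracks with 50 randomization replicates per cell:

```python
from mcsquant import (SyntheticCellParams, simulate_cell,
                      RandomizationConfig, association_analysis)

cells = []
for seed in range(4):
    cell = simulate_cell(SyntheticCellParams(seed=seed))
    cells.append((cell.truth_tracks, cell.er_masks, cell.cytoplasm_mask))

summary = association_analysis(cells, RandomizationConfig(n_replicates=50,
                                                          seed=7),
                               threshold=100.0)
print(f"observed   {100*summary.mean_observed:.2f} +/- {100*summary.sem_observed:.2f} %")
print(f"randomized {100*summary.mean_randomized:.2f} +/- {100*summary.sem_randomized:.2f} %")
print(f"paired t = {summary.paired_test.t_stat:.2f}, df = {summary.paired_test.df}, "
      f"p = {summary.paired_test.p_two_sided:.2e}")
```

prints

```
observed   69.42 +/- 4.57 %
randomized 47.41 +/- 0.21 %
paired t = 4.63, df = 3, p = 1.90e-02
```

69% of punctum-frames lie within 100 nm of the ER, against a chance level
of 47% estimated by repositioning the same trajectories uniformly in the
cytoplasm; the paired test across the four cells rejects chance placement.
With more cells the excess becomes overwhelming (see
`scripts/acceptance.py`, which runs 13).

Quantifying a synthetic immunogold experiment (41 images of 11.125 µm²,
0.8 clusters/µm², 60% associated):

```python
from mcsquant import quantify_group
from mcsquant.synthetic import GoldFieldParams, generate_gold_field

gold = quantify_group(generate_gold_field(GoldFieldParams(seed=1)), 0.03)
print(f"gold density {gold.density_mean:.3f} +/- {gold.density_sem:.3f} /um^2; "
      f"{gold.n_associated}/{gold.n_clusters} associated "
      f"({100*gold.association_fraction:.2f} %)")
```

```
gold density 0.851 +/- 0.047 /um^2; 236/388 associated (60.82 %)
```

A command-line interface mirrors the library (`mcsquant simulate
cells|gold|fractions`, `segment`, `track`, `proximity`, `immunogold`,
`fractionation`); each subcommand reads/writes TIFF, CSV and JSON.

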