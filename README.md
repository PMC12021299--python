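# crowdcontact

Crowding and social-distancing violations in public space: a tested,
reproducible pipeline for pedestrian-detection data on the ground plane.

During the COVID-19 pandemic, a *social distancing violation* was defined
(in the Netherlands) as having at least one other person within 1.5 m at an
observed moment. Given tables of pedestrian detections in metric
coordinates — one row per person per camera still frame — this package
answers the question: **how much of the violation rate is driven by how
many people are present, and how much of that is geometric necessity rather
than behavioral attraction?**

It is aimed at quantitative social scientists and epidemiologists who work
with ground-plane detection data (or want to prototype such analyses before
data access). Because real surveillance detections are rarely shareable,
the package includes a first-class synthetic scene generator that emulates
the statistical structure of busy-street footage: frames of 2–67 persons
(median 7), companion groups, and pedestrian clustering beyond what uniform
placement predicts.

## The models

**Person level.** For person *i* in frame *f*, let `y_if ∈ {0,1}` indicate
a violation and `n_f` the number of persons present. The linear probability
model (LPM)

    y_if = α + B·n_f + ε_if

is fit by OLS; *B* is the change in violation probability per additional
person present. Standard errors are cluster-robust (CR1 sandwich, persons
nested in still frames), with variants adjusting for camera fixed effects,
using a stricter outcome (≥2 close contacts, a proxy that discounts
household companions), and winsorizing the crowding measure at the Tukey
outer fence Q3 + 3·IQR. Binned scatterplots (equal-count quantile bins)
show the functional form nonparametrically.

**Frame level.** Aggregating removes the mechanical within-frame dependence:
the count of violators per frame is regressed on `n_f` by OLS with R².

**Null model.** To separate geometry from behavior, *n* individuals are
placed uniformly at random in a rectangle of walkable area *A* and pairs
within *d* = 1.5 m are counted. Without edge effects the expectation is
`C(n,2)·πd²/A`, exact on a torus and an upper bound for a plain rectangle.
An observed violating-pair curve above this null means pedestrians stand
closer than random navigation would produce. Related arithmetic: a 650 m²
viewshed nominally holds `floor(650/1.5) = 433` persons without violations
under the linear convention (the hexagonal-packing bound, 333, is provided
alongside), and 7 persons in 650 m² average `650/7 ≈ 93 m²` of personal
space each.

**Reliability.** Agreement between two violation-count raters (e.g. the
scorer and a degraded scorer missing 10% of detections) is measured by
Krippendorff's α at the interval level.

## Worked example

```python
import numpy as np
from crowdcontact import (GeneratorConfig, generate_dataset, filter_frames,
                          score_dataset, fit_lpm_clustered, fit_frame_ols,
                          NullModelConfig, simulate_random_placement,
                          compare_observed_to_null)

cfg = GeneratorConfig(n_cameras=5, frames_per_camera=200, seed=7)
det, dropped = filter_frames(generate_dataset(cfg))
persons, frames = score_dataset(det, cfg.threshold_m)
print(f"{len(persons)} persons in {len(frames)} frames; "
      f"violation rate {persons['violation'].mean():.3f}")

lpm = fit_lpm_clustered(persons)
print(f"LPM slope {lpm.slope:.4f} "
      f"(99.95% CI {lpm.ci_low:.4f}-{lpm.ci_high:.4f}, {lpm.n_clusters} clusters)")

agg = fit_frame_ols(frames)
print(f"frame OLS slope {agg.slope:.3f}, R^2 {agg.r_squared:.3f}")

null = simulate_random_placement(NullModelConfig(n_values=(2, 7, 12, 17, 22), seed=7))
row = compare_observed_to_null(frames, [null]).query("n_present == 7").iloc[0]
print(f"at n=7: observed {row.obs_mean_pairs:.2f} violating pairs/frame "
      f"vs {row.null_mean_pairs:.3f} under random placement")
```

Output:

```
9365 persons in 1000 frames; violation rate 0.451
LPM slope 0.0056 (99.95% CI 0.0033-0.0079, 1000 clusters)
frame OLS slope 0.535, R^2 0.803
at n=7: observed 1.80 violating pairs/frame vs 0.217 under random placement
```

Read: 45% of synthetic pedestrians are in a violation at any moment; each
additional person present raises an individual's violation probability by
about half a percentage point; each additional person adds about 0.54
violators to a frame, with crowding explaining 80% of the frame-level
variance; and a typical 7-person frame shows roughly eight times the close
pairs that uniform placement would produce — pedestrians cluster.

## Command line

```sh
crowdcontact run-all --seed 1 --out results/
```

runs generate → filter → score → fit → null → compare, writing every stage
as CSV, figures as SVG+PNG, and a manifest with checksums and seeds. The
stages are also available as individual subcommands (`generate`, `score`,
`fit`, `null`, `compare`) operating on the same CSV artifacts; see
`crowdcontact --help`.

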