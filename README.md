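# colonyscope

Simulation and analysis toolkit for the *cell-losing problem* in long
time-lapse microscopy: a motile cell colony (for example a mouse embryonic
stem-cell colony with a nuclear fluorescent label) wanders out of the fixed
camera field of view before its full division lineage has been recorded, so
only a fraction of the pre-programmed stage positions in a multi-day
recording yield usable movies.  The package is aimed at microscopists and
quantitative biologists who want to predict that fraction — the
*effective-throughput* of an experiment design — and at developers of
lineage-tracking pipelines who need synthetic movies with ground truth.

It provides:

- **Exact capture geometry** — the area fraction of a circular colony
  footprint inside the rectangular FOV, in closed form
  (`colonyscope.fov`).
- **Colony simulators** (`colonyscope.colony`) — a rigid-disk random walk
  for migration, with either a synchronized cell cycle
  (n(t) = 2^⌊t/τ⌋, area doubling every τ = 12 h) or a continuous
  stochastic pure-birth (Gillespie) model with waiting times
  t_next = −(τ/n)·ln u.
- **Monte-Carlo throughput statistics** (`colonyscope.montecarlo`) —
  batched experiments reporting, per capture threshold θ ∈ {0.5, 0.9}, the
  mean ± SD across batches of 100 movies of the fraction of positions that
  keep ≥ θ of the colony in view throughout the recording.
- **Random-walk analytics** (`colonyscope.analytics`) — the
  mean-displacement estimator D_rw = ⟨r⟩²/(π·dt) and the mean
  first-passage (escape) time T = R²/(4·D_rw) from a disk-shaped adhesive
  zone.
- **Synthetic fluorescence movies with ground truth**
  (`colonyscope.movies`) and a **segmentation / lineage-tracking
  pipeline** (`colonyscope.tracking`): paraboloid flat-field correction,
  threshold segmentation, globally optimal frame-to-frame assignment on
  positions and intensities, and discontinuity heuristics for transient
  merges and divisions.

See `docs/methods.md` for the models, their assumptions and the open
modelling choices (notably the two readings of the colony step convention).

## Worked example

```python
from colonyscope import (
    GrowthParams, MigrationParams, ExperimentDesign, AdhesiveZone,
    paper_fov, simulate_movie, run_experiment, summarize_to_table,
    throughput_improvement, estimate_drw, escape_time,
)

# one 4-day movie: a single 7.5-um cell at the centre of a 222-um FOV,
# dividing every 12 h, stepping 1 um per minute in random directions
movie = simulate_movie(GrowthParams(), MigrationParams.per_minute(),
                       paper_fov(), duration_hr=96.0, seed=42)
print(movie.summary())
# {'movie_id': 0, 'seed': 42, 'n_frames': 385, 'final_n_cells': 256,
#  'final_radius_um': 120.0, 'min_fraction': 0.506, 'final_fraction': 0.569}

# a 2,000-movie experiment (20 batches of 100 stage positions)
stats = run_experiment(ExperimentDesign(
    growth=GrowthParams(), migration=MigrationParams.per_minute(),
    n_batches=20, batch_size=100, seed=7))
print(summarize_to_table(stats, label="no-pattern").round(2))
#       label         model   criterion  threshold_pct  mean_pct  sd_pct  n_movies
#  no-pattern  synchronized  throughout           50.0      80.2    3.75      2000
#  no-pattern  synchronized  throughout           90.0       7.0    2.38      2000

# effective-throughput improvement of a patterned surface whose observed
# full-lineage rate is 72.3%, relative to the simulated no-pattern rate
print(round(throughput_improvement(0.723, stats.pass_rate(0.9)), 1))  # 10.3

# closed-form analytics at the measured colony displacement
print(round(estimate_drw(15.0, 15.0), 1))                  # 4.8 um^2/min
print(round(escape_time(AdhesiveZone(125.0), 4.8), 1))     # 13.6 hr
```

The movie summary reads: after 4 days the colony has 256 cells and a 120-µm
footprint, and at its worst frame 50.6 % of that footprint was inside the
FOV — this particular position (barely) keeps a >50 % lineage but loses the
>90 % ("entire lineage") criterion.  In the batched experiment, 80 % of
positions keep half the colony in view under the literal 1 µm/min
step reading, but only 7 % keep ≥ 90 % — the cell-losing problem at work.

A command-line interface mirrors the library: `colonyscope simulate`,
`analyze`, `render`, `track`, `evaluate`, `reproduce` (see `--help` on
each).  For example `colonyscope render --n-pixels 256 --pixel-size 0.65
--duration-hr 24 --out movie.tif` writes a synthetic movie plus its
ground-truth CSV, and `colonyscope track movie.tif` tracks it.

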