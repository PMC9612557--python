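"""Monte-Carlo estimate of time-lapse effective-throughput.

Runs many independent simulated movies, grouped into batches of (by
default) 100 movies - one batch standing in for one experiment's worth of
stage positions - and reports, per capture threshold, the mean and standard
deviation across batches of the fraction of movies passing.  The "+/-"
spread quoted alongside a pass percentage is therefore the between-batch SD,
which for batch size ``b`` and pass probability ``p`` is approximately the
binomial ``sqrt(p (1 - p) / b)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .colony import (
    CAPTURE_CRITERIA,
    GrowthParams,
    MigrationParams,
    paper_fov,
    simulate_capture_batch,
)
from .fov import FieldOfView

__all__ = ["ExperimentDesign", "BatchStats", "run_experiment", "throughput_improvement", "summarize_to_table"]

logger = logging.getLogger(__name__)

# refuse absurdly large designs instead of hanging for hours
DEFAULT_MOVIE_CAP = 2_000_000


@dataclass(frozen=True)
class ExperimentDesign:
    """A batched movie-simulation experiment.

    ``n_batches * batch_size`` movies are simulated in total; each batch uses
    an independent random substream spawned deterministically from ``seed``,
    so enlarging ``n_batches`` leaves earlier batches' outcomes unchanged.
    """

    growth: GrowthParams = field(default_factory=GrowthParams)
    migration: MigrationParams = field(default_factory=MigrationParams.per_minute)
    fov: FieldOfView = field(default_factory=paper_fov)
    duration_hr: float = 96.0
    n_batches: int = 1000
    batch_size: int = 100
    thresholds: tuple[float, ...] = (0.5, 0.9)
    criterion: str = "throughout"
    seed: int = 0
    movie_cap: int = DEFAULT_MOVIE_CAP

    def __post_init__(self) -> None:
        if self.n_batches <= 0 or self.batch_size <= 0:
            raise ValueError("n_batches and batch_size must be positive")
        if self.duration_hr <= 0:
            raise ValueError("duration must be positive")
        if self.criterion not in CAPTURE_CRITERIA:
            raise ValueError(f"criterion must be one of {CAPTURE_CRITERIA}")
        for t in self.thresholds:
            if not (0 < t <= 1):
                raise ValueError("thresholds must lie in (0, 1]")
        if self.n_movies > self.movie_cap:
            raise ValueError(
                f"design requests {self.n_movies} movies, above the cap of {self.movie_cap}; "
                "reduce n_batches/batch_size or raise movie_cap explicitly"
            )

    @property
    def n_movies(self) -> int:
        return self.n_batches * self.batch_size


@dataclass
class BatchStats:
    """Across-batch pass statistics, one entry per threshold."""

    thresholds: tuple[float, ...]
    mean: dict[float, float]
    sd: dict[float, float]
    pass_count: dict[float, int]
    n_movies: int
    n_batches: int
    batch_size: int
    criterion: str
    growth_mode: str
    step_convention: str
    per_batch: dict[float, np.ndarray]
    min_fraction: np.ndarray | None = None
    final_fraction: np.ndarray | None = None

    def mean_percent(self, threshold: float) -> float:
        return 100.0 * self.mean[threshold]

    def sd_percent(self, threshold: float) -> float:
        return 100.0 * self.sd[threshold]

    def pass_rate(self, threshold: float) -> float:
        return self.pass_count[threshold] / self.n_movies


def run_experiment(design: ExperimentDesign, keep_movies: bool = False) -> BatchStats:
    """Simulate the full design and summarise pass fractions across batches.

    Deterministic given ``design.seed``: batch ``k`` always consumes the
    ``k``-th spawned substream regardless of how many batches follow it.
    With ``keep_movies=True`` the per-movie minimum and final capture
    fractions are retained on the returned :class:`BatchStats`.
    """
    children = np.random.SeedSequence(design.seed).spawn(design.n_batches)
    thr = tuple(float(t) for t in design.thresholds)
    per_batch = {t: np.empty(design.n_batches) for t in thr}
    pass_count = {t: 0 for t in thr}
    all_min = np.empty(design.n_movies) if keep_movies else None
    all_final = np.empty(design.n_movies) if keep_movies else None
    log_every = max(1, design.n_batches // 10)
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        min_frac, final_frac = simulate_capture_batch(
            design.batch_size, design.growth, design.migration, design.fov, design.duration_hr, rng
        )
        if keep_movies:
            sl = slice(k * design.batch_size, (k + 1) * design.batch_size)
            all_min[sl] = min_frac
            all_final[sl] = final_frac
        score = min_frac if design.criterion == "throughout" else final_frac
        for t in thr:
            npass = int(np.count_nonzero(score >= t))
            per_batch[t][k] = npass / design.batch_size
            pass_count[t] += npass
        if (k + 1) % log_every == 0:
            logger.info("batch %d/%d done", k + 1, design.n_batches)
    mean = {t: float(np.mean(per_batch[t])) for t in thr}
    sd = {t: float(np.std(per_batch[t], ddof=1)) if design.n_batches > 1 else 0.0 for t in thr}
    return BatchStats(
        thresholds=thr,
        mean=mean,
        sd=sd,
        pass_count=pass_count,
        n_movies=design.n_movies,
        n_batches=design.n_batches,
        batch_size=design.batch_size,
        criterion=design.criterion,
        growth_mode=design.growth.mode,
        step_convention=design.migration.convention,
        per_batch=per_batch,
        min_fraction=all_min,
        final_fraction=all_final,
    )


def throughput_improvement(patterned_rate: float, unpatterned_rate: float) -> float:
    """Fold improvement in effective-throughput: patterned / unpatterned pass rate."""
    if not (0 <= patterned_rate <= 1) or not (0 <= unpatterned_rate <= 1):
        raise ValueError("rates must be fractions in [0, 1]")
    if unpatterned_rate == 0:
        raise ZeroDivisionError(
            "unpatterned rate is zero; report a lower bound instead, e.g. "
            "patterned_rate * total_movies (no unpatterned success in the sample)"
        )
    return patterned_rate / unpatterned_rate


def summarize_to_table(stats: BatchStats | None, label: str = "") -> pd.DataFrame:
    """Flatten :class:`BatchStats` to report rows (percent units)."""
    columns = ["label", "model", "criterion", "threshold_pct", "mean_pct", "sd_pct", "n_movies"]
    if stats is None:
        return pd.DataFrame(columns=columns)
    rows = [
        {
            "label": label,
            "model": stats.growth_mode,
            "criterion": stats.criterion,
            "threshold_pct": 100.0 * t,
            "mean_pct": stats.mean_percent(t),
            "sd_pct": stats.sd_percent(t),
            "n_movies": stats.n_movies,
        }
        for t in sorted(stats.thresholds)
    ]
    return pd.DataFrame(rows, columns=columns)
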