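"""Two-stage simulated-annealing calibration of an influence matrix.

A model is scored by simulating from the observed initial state of one
treatment time course and taking the gene-count-weighted correlation with
the observations.  Each annealing step proposes a single structural or
numerical move:

* with probability ``p_add`` a zero off-diagonal cell gains a new influence
  drawn uniformly from (-f, f),
* with probability ``p_remove`` a nonzero off-diagonal influence is deleted,
* otherwise a nonzero cell (diagonal included -- the per-cluster decay term
  is tuned but never deleted) is rescaled by y -> y * (1 + f) with
  f ~ U(-0.6, 0.6).

Improving moves are always accepted; deleterious ones with probability
p0 * (1 - cooling)^step, a geometric cooling schedule.  Stage one runs
``n_runs`` short anneals from the starting matrix at a hot acceptance
probability (0.80) to explore broadly; stage two reanneals from the stage-one
champion with long runs at a cold acceptance probability (0.10) to refine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dynamics import (
    InfluenceModel,
    TimeCourse,
    simulate_trajectory,
    weighted_correlation_performance,
)

__all__ = [
    "SAConfig",
    "SARun",
    "Ensemble",
    "perturb_matrix",
    "anneal_stage",
    "optimize_two_stage",
    "DynamicCalibration",
    "CalibrationResults",
]


@dataclass(frozen=True)
class SAConfig:
    """Annealing protocol parameters (defaults are the standard protocol)."""

    n_runs: int = 25
    steps_stage1: int = 5000
    steps_stage2: int = 25000
    p_accept0_stage1: float = 0.80
    p_accept0_stage2: float = 0.10
    cooling: float = 0.002  # multiplicative decay of the acceptance prob per step
    perturb_range: float = 0.6  # |f| bound for relative tweaks and new edges
    p_add: float = 0.001
    p_remove: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_accept0_stage1", "p_accept0_stage2", "p_add", "p_remove", "cooling"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_add + self.p_remove > 1:
            raise ValueError("p_add + p_remove must not exceed 1")
        if self.steps_stage1 < 0 or self.steps_stage2 < 0 or self.n_runs < 1:
            raise ValueError("step and run counts must be non-negative")
        if self.perturb_range <= 0:
            raise ValueError("perturb_range must be positive")


def perturb_matrix(
    model: InfluenceModel, config: SAConfig, rng: np.random.Generator
) -> tuple[InfluenceModel, str]:
    """Apply exactly one add / remove / tweak move to a copy of the model.

    If the cell class a drawn move needs is empty (no zero off-diagonal cell
    to add to, or no nonzero off-diagonal cell to remove), the move degrades
    to a tweak.
    """
    a = model.a.copy()
    k = a.shape[0]
    off = ~np.eye(k, dtype=bool)
    nonzero_any = np.argwhere(a != 0)
    if nonzero_any.size == 0:
        raise ValueError("model has no nonzero entries to perturb")
    u = rng.uniform()
    f_lim = config.perturb_range
    move = "tweak"
    if u < config.p_add:
        zeros = np.argwhere((a == 0) & off)
        if len(zeros):
            i, j = zeros[rng.integers(len(zeros))]
            a[i, j] = rng.uniform(-f_lim, f_lim)
            move = "add"
    elif u < config.p_add + config.p_remove:
        nz_off = np.argwhere((a != 0) & off)
        if len(nz_off):
            i, j = nz_off[rng.integers(len(nz_off))]
            a[i, j] = 0.0
            move = "remove"
    if move == "tweak":
        i, j = nonzero_any[rng.integers(len(nonzero_any))]
        f = rng.uniform(-f_lim, f_lim)
        a[i, j] = a[i, j] * (1.0 + f)
    return InfluenceModel(a, model.gene_counts), move


def _fitness(model: InfluenceModel, course: TimeCourse) -> float:
    sim = simulate_trajectory(model, course.initial_state, course.times)
    return weighted_correlation_performance(sim, course, model.gene_counts)


@dataclass
class SARun:
    """Trace and best model of a single annealing run."""

    index: int
    seed: int
    trace_fitness: np.ndarray  # fitness of the current model per step
    trace_best: np.ndarray  # best-so-far fitness per step (non-decreasing)
    best_model: InfluenceModel
    best_fitness: float

    def trace_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "step": np.arange(1, self.trace_fitness.size + 1),
                "fitness": self.trace_fitness,
                "best": self.trace_best,
            }
        )


@dataclass
class Ensemble:
    """A stage's collection of annealing runs."""

    runs: list[SARun]
    stage: int

    @property
    def best_index(self) -> int:
        fits = [r.best_fitness for r in self.runs]
        return int(np.argmax(fits))  # argmax takes the lowest index on ties

    @property
    def best_run(self) -> SARun:
        return self.runs[self.best_index]

    def models(self) -> list[InfluenceModel]:
        return [r.best_model for r in self.runs]


def anneal_stage(
    start: InfluenceModel,
    course: TimeCourse,
    config: SAConfig,
    p_accept0: float,
    steps: int,
    seed: int,
    run_index: int = 0,
) -> SARun:
    """One annealing run, fully reproducible from its seed."""
    if steps < 0:
        raise ValueError("steps must be >= 0")
    rng = np.random.default_rng(seed)
    current = start.copy()
    current_fit = _fitness(current, course)
    best = current.copy()
    best_fit = current_fit
    trace_fit = np.empty(steps)
    trace_best = np.empty(steps)
    for step in range(steps):
        proposal, _ = perturb_matrix(current, config, rng)
        prop_fit = _fitness(proposal, course)
        if prop_fit > current_fit:
            accept = True
        elif prop_fit < current_fit:
            p_t = p_accept0 * (1.0 - config.cooling) ** step
            accept = rng.uniform() < p_t
        else:
            accept = False
        if accept:
            current, current_fit = proposal, prop_fit
            if current_fit > best_fit:
                best, best_fit = current.copy(), current_fit
        trace_fit[step] = current_fit
        trace_best[step] = best_fit
    return SARun(run_index, seed, trace_fit, trace_best, best, best_fit)


def optimize_two_stage(
    start: InfluenceModel, course: TimeCourse, config: SAConfig
) -> tuple[Ensemble, Ensemble, InfluenceModel]:
    """Explore from ``start`` (stage 1), then refine from its champion (stage 2).

    All run seeds derive deterministically from ``config.seed``.
    """
    seeds = np.random.SeedSequence(config.seed).generate_state(2 * config.n_runs)
    seeds = (seeds % np.uint32(2**31)).astype(int)
    stage1 = Ensemble(
        [
            anneal_stage(
                start, course, config, config.p_accept0_stage1,
                config.steps_stage1, int(seeds[i]), run_index=i,
            )
            for i in range(config.n_runs)
        ],
        stage=1,
    )
    champion = stage1.best_run.best_model
    stage2 = Ensemble(
        [
            anneal_stage(
                champion, course, config, config.p_accept0_stage2,
                config.steps_stage2, int(seeds[config.n_runs + i]), run_index=i,
            )
            for i in range(config.n_runs)
        ],
        stage=2,
    )
    return stage1, stage2, stage2.best_run.best_model.copy()


class DynamicCalibration:
    """Calibrate an influence model against one observed time course.

    Parameters
    ----------
    start : InfluenceModel
        Starting matrix, typically the steady-state consensus model.
    course : TimeCourse
        Observed cluster-mean profiles of the treatment to calibrate on; its
        first time point is the simulation's initial state.
    """

    def __init__(self, start: InfluenceModel, course: TimeCourse):
        if start.n_clusters != course.observed.shape[0]:
            raise ValueError("model and time course cluster counts differ")
        self.start = start
        self.course = course

    def initial_fitness(self) -> float:
        return _fitness(self.start, self.course)

    def fit(self, config: SAConfig | None = None, **overrides) -> "CalibrationResults":
        config = replace(config or SAConfig(), **overrides)
        stage1, stage2, best = optimize_two_stage(self.start, self.course, config)
        return CalibrationResults(
            self, config, stage1, stage2, best,
            initial_fitness=self.initial_fitness(),
        )


@dataclass
class CalibrationResults:
    """Outcome of a two-stage calibration: ensembles, champion, traces."""

    calibration: DynamicCalibration
    config: SAConfig
    stage1: Ensemble
    stage2: Ensemble
    best_model: InfluenceModel
    initial_fitness: float
    _extra: dict = field(default_factory=dict, repr=False)

    @property
    def best_fitness(self) -> float:
        return self.stage2.best_run.best_fitness

    def simulate(self, course: TimeCourse | None = None):
        """Simulate the champion on (by default) the training course."""
        course = course or self.calibration.course
        return simulate_trajectory(
            self.best_model, course.initial_state, course.times
        )

    def cross_performance(self, course: TimeCourse) -> float:
        """Score the champion on another treatment's time course."""
        return _fitness_on(self.best_model, course)

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Two-stage simulated-annealing calibration",
            f"  training course: {self.calibration.course.treatment!r}",
            f"  runs per stage: {cfg.n_runs}; steps: {cfg.steps_stage1}/{cfg.steps_stage2}",
            f"  initial weighted correlation: {self.initial_fitness:.3f}",
            f"  stage-1 best: {self.stage1.best_run.best_fitness:.3f} "
            f"(run {self.stage1.best_index})",
            f"  stage-2 best: {self.best_fitness:.3f} (run {self.stage2.best_index})",
            f"  champion edges: {self.best_model.n_edges}",
        ]
        return "\n".join(lines)

    def plot_traces(self, ax=None):
        """Best-so-far fitness of every run in both stages."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        for run in self.stage1.runs:
            ax.plot(run.trace_best, color="tab:blue", alpha=0.3, lw=0.8)
        offset = self.config.steps_stage1
        for run in self.stage2.runs:
            ax.plot(
                np.arange(run.trace_best.size) + offset,
                run.trace_best,
                color="tab:orange",
                alpha=0.3,
                lw=0.8,
            )
        ax.set_xlabel("step")
        ax.set_ylabel("best weighted correlation")
        return ax


def _fitness_on(model: InfluenceModel, course: TimeCourse) -> float:
    return _fitness(model, course)
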