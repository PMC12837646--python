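"""Synthetic extraction campaigns.

The generator emulates the statistical structure the downstream analysis
assumes: a smooth nonlinear response surface over the three process factors
(time, temperature, solvent ratio) plus independent Gaussian replicate
noise.  Surfaces are full quadratics with interactions — the simplest
family with an interior optimum like the one the real campaign exhibits —
and the bundled default surfaces are calibrated against the in-study
campaign: a least-squares quadratic fit to each measured response,
affinely corrected so its range over the 15-run design equals the measured
range, with the replicate noise set to the median printed SD.

This makes parameter-recovery experiments possible: the true optimum of a
noiseless surface is known (dense grid search, or in closed form for the
quadratic), so a pipeline that simulates a campaign, fits a surrogate and
optimizes it can be scored on whether it finds that optimum.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import data as _data
from .data import ExtractionDesign, ResponseMatrix, design_matrix

__all__ = ["SurfaceSpec", "DESIGN_BOX", "PAPER_LEVELS",
           "generate_design", "simulate_responses", "true_optimum",
           "paper_calibrated_surfaces", "recovery_trial"]

# factor box spanned by the in-study campaign
DESIGN_BOX = {"time": (10.0, 30.0), "temperature": (25.0, 75.0),
              "ratio": (10.0, 20.0)}
PAPER_LEVELS = ((10.0, 20.0, 30.0), (25.0, 50.0, 75.0), (10.0, 15.0, 20.0))

# quadratic term order: 1, t, T, r, t^2, T^2, r^2, tT, tr, Tr
TERM_NAMES = ("const", "t", "T", "r", "t2", "T2", "r2", "tT", "tr", "Tr")


def _quad_design(X: np.ndarray) -> np.ndarray:
    t, T, r = X[:, 0], X[:, 1], X[:, 2]
    return np.column_stack([np.ones_like(t), t, T, r, t * t, T * T, r * r,
                            t * T, t * r, T * r])


@dataclass
class SurfaceSpec:
    """One response's quadratic surface and replicate noise level.

    ``coefficients`` holds the ten terms (intercept, linear, quadratic,
    interaction) in the order const, t, T, r, t2, T2, r2, tT, tr, Tr;
    ``noise_sd`` is the replicate standard deviation in response units.
    """

    name: str
    coefficients: np.ndarray
    noise_sd: float = 0.0

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (10,):
            raise ValueError("a quadratic surface needs exactly 10 "
                             "coefficients")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        """Noiseless surface value at factor settings (n, 3)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return _quad_design(X) @ self.coefficients

    def to_dict(self) -> dict:
        return {"name": self.name, "noise_sd": self.noise_sd,
                "coefficients": dict(zip(TERM_NAMES,
                                         self.coefficients.tolist()))}

    @classmethod
    def from_dict(cls, doc: dict) -> "SurfaceSpec":
        coef = [doc["coefficients"][k] for k in TERM_NAMES]
        return cls(name=doc["name"], coefficients=np.array(coef),
                   noise_sd=float(doc["noise_sd"]))


def generate_design(levels=PAPER_LEVELS, replicate_of_paper: bool = False
                    ) -> list[ExtractionDesign]:
    """Full-factorial design over the given levels, or the 15-run subset
    actually used in the study."""
    if replicate_of_paper:
        return _data.load_design("paper")
    if any(len(axis) == 0 for axis in levels):
        raise ValueError("every factor needs at least one level")
    return [ExtractionDesign(sample_id=i, time=t, temperature=T, ratio=r)
            for i, (t, T, r) in enumerate(itertools.product(*levels),
                                          start=1)]


def simulate_responses(design: list[ExtractionDesign],
                       specs: list[SurfaceSpec] | dict[str, SurfaceSpec],
                       n_replicates: int = 3,
                       seed: int = 0) -> ResponseMatrix:
    """Simulate a measured campaign: replicate means and SDs per run.

    Each replicate is the noiseless surface value plus independent Gaussian
    noise of the spec's ``noise_sd``; the returned matrix carries the
    replicate means and (sample, ddof = 1) SDs, mirroring how a triplicate
    campaign is reported.
    """
    if not design:
        raise ValueError("design must be non-empty")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if isinstance(specs, dict):
        specs = list(specs.values())
    X = design_matrix(design)
    rng = np.random.default_rng(seed)
    n, m = len(design), len(specs)
    means = np.empty((n, m))
    sds = np.zeros((n, m))
    units = _data.response_units()
    for j, spec in enumerate(specs):
        truth = spec.evaluate(X)
        reps = truth[:, None] + rng.normal(
            0.0, spec.noise_sd, size=(n, n_replicates))
        means[:, j] = reps.mean(axis=1)
        if n_replicates > 1:
            sds[:, j] = reps.std(axis=1, ddof=1)
    return ResponseMatrix(
        sample_ids=[d.sample_id for d in design],
        response_names=[s.name for s in specs], means=means, sds=sds,
        units={s.name: units.get(s.name, "") for s in specs},
        n_replicates=n_replicates)


def true_optimum(spec: SurfaceSpec, box: dict = DESIGN_BOX,
                 grid_step: float = 0.5) -> tuple[float, float, float]:
    """Argmax of the noiseless surface on a dense grid over the box.

    Ties are broken toward the lowest time, then temperature, then ratio
    (the grid is enumerated in exactly that lexicographic order and the
    first maximum wins).
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    axes = [np.arange(lo, hi + 0.5 * grid_step, grid_step)
            for lo, hi in (box["time"], box["temperature"], box["ratio"])]
    grid = np.array(np.meshgrid(*axes, indexing="ij")).reshape(3, -1).T
    values = spec.evaluate(grid)
    best = np.argmax(values)          # first occurrence = lexicographic tie-break
    return tuple(grid[best])


def paper_calibrated_surfaces(response_names=None) -> dict[str, SurfaceSpec]:
    """Default surfaces calibrated against the in-study campaign.

    For each response a quadratic is least-squares fitted to the 15
    measured means, then affinely rescaled so its minimum and maximum over
    the 15 design points equal the measured minimum and maximum — the
    simulated campaign therefore spans the same range as the real one.
    ``noise_sd`` is the median printed replicate SD of that response.
    """
    design = _data.load_design("paper")
    responses = _data.load_responses("paper")
    X = design_matrix(design)
    Q = _quad_design(X)
    if response_names is None:
        response_names = responses.response_names
    specs = {}
    for name in response_names:
        j = responses.response_names.index(name)
        y = responses.means[:, j]
        coef, *_ = np.linalg.lstsq(Q, y, rcond=None)
        fitted = Q @ coef
        span = fitted.max() - fitted.min()
        beta = (y.max() - y.min()) / span if span > 0 else 1.0
        alpha = y.min() - beta * fitted.min()
        coef = coef * beta
        coef[0] += alpha
        specs[name] = SurfaceSpec(
            name=name, coefficients=coef,
            noise_sd=float(np.median(responses.sds[:, j])))
    return specs


def save_surfaces(specs: dict[str, SurfaceSpec], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps([s.to_dict() for s in specs.values()],
                               indent=1))
    return path


def load_surfaces(path: str | Path) -> dict[str, SurfaceSpec]:
    docs = json.loads(Path(path).read_text())
    specs = [SurfaceSpec.from_dict(d) for d in docs]
    return {s.name: s for s in specs}


def recovery_trial(spec: SurfaceSpec, seed: int, hidden_size: int = 4,
                   restarts: int = 20, n_replicates: int = 3,
                   levels=PAPER_LEVELS) -> dict:
    """One end-to-end parameter-recovery experiment.

    Simulates a full-factorial campaign from ``spec``, fits an MLP
    surrogate, maximizes it over the design box with the genetic
    optimizer, and reports whether the recovered optimum lies within one
    factor level of the surface's true optimum.

    The surrogate is kept small (4 hidden units), most of the campaign
    (80%) goes to the training partition, and restarts are scored on the
    held-out test partition: the truth is a smooth quadratic, and a
    higher-capacity net selected on training fit interpolates the
    replicate noise, which wrecks the location of its maximum.
    """
    from .mlp import TrainConfig, train
    from .optimize import ga_optimize

    design = generate_design(levels=levels)
    campaign = simulate_responses(design, [spec],
                                  n_replicates=n_replicates, seed=seed)
    X = design_matrix(design)
    surrogate = train(X, campaign.means, hidden_size,
                      TrainConfig(restarts=restarts, seed=seed,
                                  fractions=(0.8, 0.1, 0.1),
                                  select_by="test"),
                      response_names=[spec.name])
    result = ga_optimize([surrogate], DESIGN_BOX, {spec.name: "max"},
                         population=60, max_generations=40, seed=seed)
    top = result.front.sort_values(spec.name, ascending=False).iloc[0]
    recovered = (top["time"], top["temperature"], top["ratio"])
    truth = true_optimum(spec, grid_step=0.5)
    steps = [np.diff(axis).min() if len(axis) > 1 else 1.0
             for axis in levels]
    hit = all(abs(a - b) <= s
              for a, b, s in zip(recovered, truth, steps))
    return {"true_optimum": truth, "recovered": recovered, "hit": hit,
            "train_r2": surrogate.performance["train"]}
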