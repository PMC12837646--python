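"""Multi-objective optimization and multi-response ranking.

Two routes to "the best extraction condition" are provided.  The genetic
route searches the continuous factor box over one or more trained
surrogates with an NSGA-II-style algorithm (simulated binary crossover,
polynomial mutation, fast non-dominated sorting, crowding distance) and
returns a capped Pareto front.  The ranking route scores measured or
predicted response vectors with a standard score per response and ranks by
the mean score across responses.

The default standard-score convention is the min-max standard score — the
mean over responses of (x - min)/(max - min), with the fraction reversed
for responses to be minimized.  Classic z-scoring (sample or population
SD) is available as an alternative convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ResponseMatrix

__all__ = ["ParetoResult", "pareto_front", "crowding_distance",
           "ga_optimize", "standard_score_rank", "zscore_rank",
           "select_optimum"]

FACTORS = ("time", "temperature", "ratio")


def _oriented(objectives: np.ndarray, senses) -> np.ndarray:
    """Flip minimized columns so that larger is always better."""
    F = np.array(objectives, dtype=float)
    if F.ndim != 2:
        raise ValueError("objectives must be a 2-D array")
    if senses is not None:
        for j, sense in enumerate(senses):
            if sense not in ("max", "min"):
                raise ValueError(f"sense must be 'max' or 'min', got "
                                 f"{sense!r}")
            if sense == "min":
                F[:, j] *= -1
    return F


def pareto_front(objectives: np.ndarray, senses=None,
                 cap: int | None = None) -> np.ndarray:
    """Indices of the non-dominated candidates (exact pairwise filtering).

    A candidate is dominated if some other candidate is at least as good in
    every objective and strictly better in one.  Duplicated objective
    vectors keep their first occurrence only.  If the front exceeds
    ``cap``, it is thinned by crowding distance with the per-objective
    extremes always retained.
    """
    F = _oriented(objectives, senses)
    if F.shape[0] == 0:
        raise ValueError("candidate set must be non-empty")
    _, first = np.unique(F, axis=0, return_index=True)
    candidates = np.sort(first)
    keep = []
    for i in candidates:
        others = F[candidates[candidates != i]]
        dominated = np.any((others >= F[i]).all(axis=1) &
                           (others > F[i]).any(axis=1))
        if not dominated:
            keep.append(i)
    front = np.array(keep, dtype=int)
    if cap is not None and front.size > cap:
        front = front[_thin_by_crowding(F[front], cap)]
    return front


def crowding_distance(F: np.ndarray) -> np.ndarray:
    """NSGA-II crowding distance within one front (larger = more isolated)."""
    n, m = F.shape
    distance = np.zeros(n)
    for j in range(m):
        order = np.argsort(F[:, j], kind="stable")
        span = F[order[-1], j] - F[order[0], j]
        distance[order[0]] = distance[order[-1]] = np.inf
        if span > 0 and n > 2:
            gaps = (F[order[2:], j] - F[order[:-2], j]) / span
            distance[order[1:-1]] += gaps
    return distance


def _thin_by_crowding(F: np.ndarray, cap: int) -> np.ndarray:
    distance = crowding_distance(F)
    return np.sort(np.argsort(-distance, kind="stable")[:cap])


def _fast_nondominated_sort(F: np.ndarray) -> list[np.ndarray]:
    n = F.shape[0]
    dominated_by = [[] for _ in range(n)]
    domination_count = np.zeros(n, dtype=int)
    for i in range(n):
        better = (F >= F[i]).all(axis=1) & (F > F[i]).any(axis=1)
        worse = (F <= F[i]).all(axis=1) & (F < F[i]).any(axis=1)
        domination_count[i] = int(better.sum())
        dominated_by[i] = np.flatnonzero(worse)
    fronts = []
    current = np.flatnonzero(domination_count == 0)
    while current.size:
        fronts.append(current)
        counts = domination_count.copy()
        for i in current:
            counts[dominated_by[i]] -= 1
            counts[i] = -1
        domination_count = counts
        domination_count[np.concatenate(fronts)] = -1
        current = np.flatnonzero(domination_count == 0)
    return fronts


def _sbx(parents_a, parents_b, lo, hi, rng, eta=15.0):
    u = rng.random(parents_a.shape)
    beta = np.where(u <= 0.5, (2 * u) ** (1 / (eta + 1)),
                    (1 / (2 * (1 - u))) ** (1 / (eta + 1)))
    child_a = 0.5 * ((1 + beta) * parents_a + (1 - beta) * parents_b)
    child_b = 0.5 * ((1 - beta) * parents_a + (1 + beta) * parents_b)
    return (np.clip(child_a, lo, hi), np.clip(child_b, lo, hi))


def _polynomial_mutation(X, lo, hi, rng, eta=20.0, prob=None):
    if prob is None:
        prob = 1.0 / X.shape[1]
    mask = rng.random(X.shape) < prob
    u = rng.random(X.shape)
    span = hi - lo
    delta = np.where(u < 0.5, (2 * u) ** (1 / (eta + 1)) - 1,
                     1 - (2 * (1 - u)) ** (1 / (eta + 1)))
    return np.clip(np.where(mask, X + delta * span, X), lo, hi)


@dataclass
class ParetoResult:
    """Capped non-dominated set found by the genetic optimizer."""

    front: pd.DataFrame          # factor columns + one column per objective
    objective_names: list[str]
    senses: dict[str, str]
    generations: int
    population: int
    front_cap: int


def _combined_predictor(surrogates, objective_names):
    """Resolve each named objective to a (surrogate, column) pair."""
    lookup = {}
    for surrogate in surrogates:
        for j, name in enumerate(surrogate.response_names):
            lookup.setdefault(name, (surrogate, j))
    missing = [n for n in objective_names if n not in lookup]
    if missing:
        raise ValueError(f"no surrogate predicts objective(s) {missing}")

    def predict(X):
        columns = []
        cache = {}
        for name in objective_names:
            surrogate, j = lookup[name]
            key = id(surrogate)
            if key not in cache:
                cache[key] = surrogate.predict(X)
            columns.append(cache[key][:, j])
        return np.column_stack(columns)

    return predict


def ga_optimize(surrogates, bounds: dict, senses: dict[str, str],
                population: int = 100, max_generations: int = 100,
                front_cap: int = 50, patience: int = 20,
                seed: int = 0) -> ParetoResult:
    """NSGA-II search for Pareto-optimal factor settings.

    ``surrogates`` is a list of trained surrogates jointly covering the
    named objectives; ``senses`` maps objective name -> "max"/"min".  The
    run stops early once the leading front's objective signature has not
    changed for ``patience`` generations, so the generation count is an
    outcome, not an input.  Fully reproducible for a given seed.
    """
    if population < 4:
        raise ValueError("population must be at least 4")
    objective_names = list(senses)
    predict = _combined_predictor(surrogates, objective_names)
    sense_list = [senses[n] for n in objective_names]
    lo = np.array([bounds[f][0] for f in FACTORS], float)
    hi = np.array([bounds[f][1] for f in FACTORS], float)

    rng = np.random.default_rng(seed)
    pop = population if population % 2 == 0 else population + 1
    P = rng.uniform(lo, hi, size=(pop, 3))
    F = _oriented(predict(P), sense_list)

    generations_run = 0
    stable, last_signature = 0, None
    for generation in range(1, max_generations + 1):
        fronts = _fast_nondominated_sort(F)
        rank = np.empty(pop, dtype=int)
        crowd = np.empty(pop)
        for level, front in enumerate(fronts):
            rank[front] = level
            crowd[front] = crowding_distance(F[front])
        # binary tournament on (rank, crowding)
        a, b = (rng.integers(0, pop, pop) for _ in range(2))
        better = (rank[a] < rank[b]) | ((rank[a] == rank[b]) &
                                        (crowd[a] >= crowd[b]))
        parents = np.where(better, a, b)
        pa, pb = P[parents[0::2]], P[parents[1::2]]
        ca, cb = _sbx(pa, pb, lo, hi, rng)
        Q = _polynomial_mutation(np.vstack([ca, cb]), lo, hi, rng)
        FQ = _oriented(predict(Q), sense_list)

        R = np.vstack([P, Q])
        FR = np.vstack([F, FQ])
        fronts = _fast_nondominated_sort(FR)
        chosen = []
        for front in fronts:
            if len(chosen) + front.size <= pop:
                chosen.extend(front.tolist())
            else:
                need = pop - len(chosen)
                order = np.argsort(-crowding_distance(FR[front]),
                                   kind="stable")
                chosen.extend(front[order[:need]].tolist())
                break
        chosen = np.array(chosen)
        P, F = R[chosen], FR[chosen]
        generations_run = generation

        signature = np.unique(np.round(F[_fast_nondominated_sort(F)[0]], 6),
                              axis=0).tobytes()
        stable = stable + 1 if signature == last_signature else 0
        last_signature = signature
        if stable >= patience:
            break

    front_idx = pareto_front(F, senses=None, cap=front_cap)
    table = pd.DataFrame(P[front_idx], columns=FACTORS)
    raw = predict(P[front_idx])
    for j, name in enumerate(objective_names):
        table[name] = raw[:, j]
    table = table.sort_values(list(FACTORS)).reset_index(drop=True)
    return ParetoResult(front=table, objective_names=objective_names,
                        senses=dict(senses), generations=generations_run,
                        population=population, front_cap=front_cap)


def standard_score_rank(responses: ResponseMatrix, senses=None,
                        convention: str = "minmax") -> pd.DataFrame:
    """Score and rank samples by their mean standard score.

    ``convention`` is one of:

    * ``"minmax"`` (default): per response, (x - min)/(max - min); this is
      the standard-score convention under which the in-study campaign's
      best run scores 0.794.
    * ``"zscore-sample"`` / ``"zscore-population"``: classic z-scores with
      the n-1 or n SD.

    Responses with a "min" sense are reversed before averaging.  A
    constant response contributes its neutral value (0.5 for min-max, 0
    for z-scores) with a warning.
    """
    if responses.n_samples < 2:
        raise ValueError("ranking needs at least 2 samples")
    if senses is None:
        senses = {name: "max" for name in responses.response_names}
    X = responses.means
    scores = np.empty_like(X, dtype=float)
    for j, name in enumerate(responses.response_names):
        col = X[:, j]
        sense = senses.get(name, "max")
        span = np.ptp(col)
        if span == 0:
            warnings.warn(f"constant response {name!r} contributes its "
                          "neutral score", stacklevel=2)
            scores[:, j] = 0.5 if convention == "minmax" else 0.0
            continue
        if convention == "minmax":
            s = (col - col.min()) / span
            scores[:, j] = 1.0 - s if sense == "min" else s
        elif convention in ("zscore-sample", "zscore-population"):
            ddof = 1 if convention == "zscore-sample" else 0
            z = (col - col.mean()) / col.std(ddof=ddof)
            scores[:, j] = -z if sense == "min" else z
        else:
            raise ValueError(f"unknown convention {convention!r}")
    table = pd.DataFrame(scores, columns=responses.response_names,
                         index=pd.Index(responses.sample_ids,
                                        name="sample_id"))
    table["mean_score"] = scores.mean(axis=1)
    table["rank"] = table["mean_score"].rank(ascending=False,
                                             method="min").astype(int)
    return table.sort_values("rank")


def zscore_rank(responses: ResponseMatrix, senses=None,
                convention: str = "zscore-sample") -> pd.DataFrame:
    """Classic z-score ranking (see :func:`standard_score_rank`)."""
    return standard_score_rank(responses, senses=senses,
                               convention=convention)


def select_optimum(source, designs=None, senses=None,
                   convention: str = "minmax") -> dict:
    """Pick the best condition from measurements or from a Pareto front.

    For a measured :class:`ResponseMatrix` the samples are ranked by mean
    standard score and the winner's factor settings (looked up in
    ``designs``) and full measured response vector are returned.  For a
    :class:`ParetoResult` the front's predicted objective vectors are
    ranked the same way.
    """
    if isinstance(source, ResponseMatrix):
        if source.n_samples == 1:
            best_id = int(source.sample_ids[0])
            result = {"sample_id": best_id, "score": np.nan,
                      "responses": {
                          name: float(value) for name, value in
                          zip(source.response_names, source.means[0])}}
            if designs is not None:
                match = [d for d in designs if d.sample_id == best_id]
                if match:
                    d = match[0]
                    result["conditions"] = {"time": d.time,
                                            "temperature": d.temperature,
                                            "ratio": d.ratio}
            return result
        ranking = standard_score_rank(source, senses=senses,
                                      convention=convention)
        best_id = int(ranking.index[0])
        result = {"sample_id": best_id,
                  "score": float(ranking["mean_score"].iloc[0]),
                  "responses": {
                      name: float(value) for name, value in zip(
                          source.response_names,
                          source.means[source.sample_ids.index(best_id)])}}
        if designs is not None:
            match = [d for d in designs if d.sample_id == best_id]
            if match:
                d = match[0]
                result["conditions"] = {"time": d.time,
                                        "temperature": d.temperature,
                                        "ratio": d.ratio}
        return result
    if isinstance(source, ParetoResult):
        if source.front.empty:
            raise ValueError("empty Pareto front")
        if len(source.front) == 1:
            row = source.front.iloc[0]
            return {"conditions": {f: float(row[f]) for f in FACTORS},
                    "responses": {n: float(row[n])
                                  for n in source.objective_names},
                    "score": np.nan}
        fake = ResponseMatrix(
            sample_ids=list(range(1, len(source.front) + 1)),
            response_names=source.objective_names,
            means=source.front[source.objective_names].to_numpy(),
            sds=np.zeros((len(source.front), len(source.objective_names))),
            n_replicates=1)
        ranking = standard_score_rank(fake, senses=source.senses,
                                      convention=convention)
        row = source.front.iloc[int(ranking.index[0]) - 1]
        return {"conditions": {f: float(row[f]) for f in FACTORS},
                "responses": {n: float(row[n])
                              for n in source.objective_names},
                "score": float(ranking["mean_score"].iloc[0])}
    raise TypeError("source must be a ResponseMatrix or ParetoResult")
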