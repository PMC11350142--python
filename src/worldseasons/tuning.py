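"""Budgeted search over the classifier's nine free parameters.

The objective is the mean per-city error of the full classification pipeline
against reference records.  The search is an iterated random search: an
initial phase of uniform sampling within bounds, then Gaussian perturbation
around the incumbent elites (truncated to bounds).  The top configurations by
training error ("elites") are re-scored on held-out cities and the one with
the lowest test error wins — training data pick the candidates, test data pick
among them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .climate import PixelClimate
from .clustering import classify_pixel
from .params import FREE_PARAM_BOUNDS, Params
from .reference import ReferenceRecord, mean_error

__all__ = ["ParamSpace", "sample_params", "evaluate_params", "tune", "select_final"]


@dataclass(frozen=True)
class ParamSpace:
    """The bounded 9-dimensional box the search explores.

    Two zone thresholds (temperature difference 3..14 °C, precipitation
    difference 80..130 mm) and seven k-means weights, each 0.25..4.
    """

    bounds: dict = field(default_factory=lambda: dict(FREE_PARAM_BOUNDS))

    def __post_init__(self) -> None:
        if len(self.bounds) != 9:
            raise ValueError(f"parameter space must have exactly 9 dimensions, got {len(self.bounds)}")
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"empty bound for {name}: [{lo}, {hi}]")

    @property
    def names(self) -> list[str]:
        return list(self.bounds)

    def lo(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds.values()])

    def hi(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds.values()])

    def contains(self, params: Params) -> bool:
        v = np.asarray(params.free_vector())
        return bool(np.all(v >= self.lo()) and np.all(v <= self.hi()))


def sample_params(space: ParamSpace, rng: np.random.Generator) -> Params:
    """One configuration drawn uniformly within the space's bounds."""
    v = rng.uniform(space.lo(), space.hi())
    return Params.from_free_vector(v)


def evaluate_params(
    params: Params,
    records: list[ReferenceRecord],
    pixel_lookup: dict,
    *,
    restarts: int = 20,
    seed: int = 0,
) -> float:
    """Mean city error of the pipeline under ``params`` over paired records.

    ``pixel_lookup`` maps ``(city, country)`` to the record's
    :class:`PixelClimate`.  Records without pixel data are skipped; scoring
    every record against one configuration is cheap enough that no
    per-instance racing or subsampling is applied.
    """
    kept, preds = [], []
    for rec in records:
        pix = pixel_lookup.get((rec.city, rec.country))
        if pix is None:
            continue
        preds.append(classify_pixel(pix, params, seed=seed, restarts=restarts))
        kept.append(rec)
    if not kept:
        raise ValueError("no record has pixel data")
    err, _ = mean_error(preds, kept)
    return err


def tune(
    space: ParamSpace,
    train_records: list[ReferenceRecord],
    pixel_lookup: dict,
    budget: int = 2000,
    seed: int = 0,
    n_elites: int = 5,
    *,
    explore_frac: float = 0.4,
    sigma_frac: float = 0.08,
    restarts: int = 20,
) -> list[tuple[Params, float]]:
    """Iterated random search; returns the elite (Params, train error) pairs.

    The first ``explore_frac`` of the budget samples uniformly; the remainder
    perturbs parameters of randomly chosen current elites with Gaussian noise
    of standard deviation ``sigma_frac`` of each bound's width, truncated to
    the bounds.  Elites are the ``n_elites`` configurations with the lowest
    training error, sorted ascending.  Deterministic for a given seed.
    """
    if budget < n_elites:
        raise ValueError("budget must be at least n_elites")
    if not train_records:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    lo, hi = space.lo(), space.hi()
    width = hi - lo
    n_explore = max(n_elites, int(round(explore_frac * budget)))
    evaluated: list[tuple[float, int, np.ndarray]] = []  # (error, order, vector)
    for i in range(budget):
        if i < n_explore or not evaluated:
            v = rng.uniform(lo, hi)
        else:
            elites_now = sorted(evaluated)[:n_elites]
            base = elites_now[int(rng.integers(len(elites_now)))][2]
            v = np.clip(base + rng.normal(0.0, sigma_frac * width), lo, hi)
        p = Params.from_free_vector(v)
        err = evaluate_params(p, train_records, pixel_lookup, restarts=restarts)
        evaluated.append((err, i, v))
    elites = sorted(evaluated)[:n_elites]
    return [(Params.from_free_vector(v), err) for err, _, v in elites]


def select_final(
    elites: list[tuple[Params, float]],
    test_records: list[ReferenceRecord],
    pixel_lookup: dict,
    *,
    restarts: int = 20,
) -> Params:
    """Pick the elite with the lowest held-out error (ties: lower train error)."""
    if not elites or not test_records:
        raise ValueError("need non-empty elites and test records")
    scored = []
    for i, (p, train_err) in enumerate(elites):
        test_err = evaluate_params(p, test_records, pixel_lookup, restarts=restarts)
        scored.append((test_err, train_err, i, p))
    return min(scored)[3]
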