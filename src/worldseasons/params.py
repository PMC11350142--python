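"""Tunable constants of the classifier: zone thresholds and cluster weights.

The classifier has nine free parameters: the two tropical-gate thresholds
(intra-annual temperature and precipitation ranges) plus seven k-means feature
weights (four temperate, three tropical).  The tuned optimum ships as the
defaults, so classification works out of the box without re-tuning.  The three
remaining thresholds (arctic 10 °C ceiling, tropical 18 °C coldest-month
floor, desert 0.2 aridity cutoff) are fixed by convention and never tuned.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

from .zones import ZoneThresholds

__all__ = ["WeightSet", "Params", "FREE_PARAM_BOUNDS"]

#: bounds of the 9 free parameters, in the order of Params.free_vector()
FREE_PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "temp_diff_thresh": (3.0, 14.0),      # °C
    "precip_diff_thresh": (80.0, 130.0),  # mm
    "temperate_temperature": (0.25, 4.0),
    "temperate_precip_lag": (0.25, 4.0),
    "temperate_temp_lag": (0.25, 4.0),
    "temperate_ndvi_lag": (0.25, 4.0),
    "tropical_temperature": (0.25, 4.0),
    "tropical_precip_lag": (0.25, 4.0),
    "tropical_ndvi_lag": (0.25, 4.0),
}


@dataclass(frozen=True)
class WeightSet:
    """Feature weights of the zone-specific k-means.

    A weight ``w`` makes its variable contribute ``w`` times as much squared
    distance as an unweighted variable (columns are scaled by sqrt(w) after
    z-normalization).  Desert and arctic clustering is unweighted: their two
    variables are correlated and equal importance works.
    """

    temperate_temperature: float = 3.521
    temperate_precip_lag: float = 3.237
    temperate_temp_lag: float = 2.031
    temperate_ndvi_lag: float = 0.312
    tropical_temperature: float = 3.958
    tropical_precip_lag: float = 3.72
    tropical_ndvi_lag: float = 1.713

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (0.25 <= v <= 4.0):
                raise ValueError(f"weight {f.name}={v} outside [0.25, 4]")


@dataclass(frozen=True)
class Params:
    """Complete classifier configuration: thresholds plus weights."""

    thresholds: ZoneThresholds = ZoneThresholds()
    weights: WeightSet = WeightSet()

    def free_vector(self) -> list[float]:
        """The 9 tunable values, in :data:`FREE_PARAM_BOUNDS` order."""
        out = []
        for name in FREE_PARAM_BOUNDS:
            src = self.thresholds if hasattr(self.thresholds, name) else self.weights
            out.append(float(getattr(src, name)))
        return out

    @classmethod
    def from_free_vector(cls, v, base: "Params | None" = None) -> "Params":
        v = list(map(float, v))
        if len(v) != len(FREE_PARAM_BOUNDS):
            raise ValueError(f"expected {len(FREE_PARAM_BOUNDS)} values, got {len(v)}")
        base = base or cls()
        named = dict(zip(FREE_PARAM_BOUNDS, v))
        th = dataclasses.replace(
            base.thresholds,
            temp_diff_thresh=named["temp_diff_thresh"],
            precip_diff_thresh=named["precip_diff_thresh"],
        )
        w = WeightSet(**{k: x for k, x in named.items() if k not in
                         ("temp_diff_thresh", "precip_diff_thresh")})
        return cls(thresholds=th, weights=w)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self.thresholds)
        d.update(dataclasses.asdict(self.weights))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Params":
        th_names = {f.name for f in dataclasses.fields(ZoneThresholds)}
        w_names = {f.name for f in dataclasses.fields(WeightSet)}
        unknown = set(d) - th_names - w_names
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        return cls(
            thresholds=ZoneThresholds(**{k: v for k, v in d.items() if k in th_names}),
            weights=WeightSet(**{k: v for k, v in d.items() if k in w_names}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "Params":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
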