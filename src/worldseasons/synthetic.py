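"""Synthetic climate archetypes with known ground truth.

Each archetype emulates the annual cycle that defines one climate zone:

* ``temperate`` — sinusoidal temperature (mean 10 °C, half-amplitude 12 °C),
  mildly seasonal rainfall, NDVI tracking temperature with a one-month delay;
* ``tropical_unimodal`` / ``tropical_bimodal`` — near-constant heat
  (26 ± 1 °C) with monsoonal rainfall (one or two peaks, range well above any
  tropical gate), NDVI tracking rainfall with a one-month delay;
* ``desert_hot`` / ``desert_cold`` — PET far above precipitation (annual
  aridity < 0.1) with a 15 °C (hot) or 25 °C (cold) peak-to-peak temperature
  cycle;
* ``arctic`` — monthly-mean minimum temperature below 10 °C all year, solar
  radiation peaking at the summer solstice.

Ground-truth seasons come from the generating series, not from the
classifier: two-season zones take the six months with the warmest (or, in the
tropics, rainiest) noise-free values; temperate truth is the phase quarters
of the temperature sinusoid centred on its coldest month.  Gaussian noise is
controlled by a single ``noise_sd`` multiplier of per-variable base sigmas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .climate import ClimateStack, PixelClimate
from .clustering import SeasonCalendar, SeasonLabel, classify_pixel
from .params import Params
from .reference import ReferenceRecord
from .zones import Zone, classify_zone

__all__ = ["ArchetypeSpec", "make_pixel", "make_raster", "make_reference_set", "ARCHETYPES"]

MONTHS = 12
ARCHETYPES = (
    "temperate",
    "tropical_unimodal",
    "tropical_bimodal",
    "desert_hot",
    "desert_cold",
    "arctic",
)

_ARCHETYPE_ZONE = {
    "temperate": Zone.TEMPERATE,
    "tropical_unimodal": Zone.TROPICAL,
    "tropical_bimodal": Zone.TROPICAL,
    "desert_hot": Zone.DESERT,
    "desert_cold": Zone.DESERT,
    "arctic": Zone.ARCTIC_MONTANE,
}

#: per-variable noise sigmas at noise_sd = 1 (°C, mm, W/m^2-ish, unitless, mm)
_BASE_SIGMA = {"tmid": 0.5, "precip_frac": 0.06, "srad": 5.0, "ndvi": 0.02, "pet_frac": 0.04}


@dataclass(frozen=True)
class ArchetypeSpec:
    """Recipe for one synthetic pixel.

    ``noise_sd`` scales the per-variable Gaussian noise sigmas (0 = exact
    sinusoids); ``jitter`` multiplicatively perturbs means and amplitudes by
    up to that fraction (drawn from ``seed``) for between-pixel variety;
    ``phase_shift`` rolls the whole annual cycle by that many months.
    Parameters keep every archetype inside its zone's gate with a margin of
    at least twice the noise it injects.
    """

    archetype: str
    hemisphere: str = "N"
    noise_sd: float = 0.0
    jitter: float = 0.0
    phase_shift: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}; choose from {ARCHETYPES}")
        if self.hemisphere not in ("N", "S"):
            raise ValueError("hemisphere must be 'N' or 'S'")
        if not 0 <= self.jitter < 0.2:
            raise ValueError("jitter must stay below 0.2 to preserve zone-gate margins")

    @property
    def zone(self) -> Zone:
        return _ARCHETYPE_ZONE[self.archetype]


def _cycle(peak_month: int, half_amplitude: float) -> np.ndarray:
    """12-month cosine with its maximum at ``peak_month`` (0-based)."""
    m = np.arange(MONTHS)
    return half_amplitude * np.cos(2 * np.pi * (m - peak_month) / MONTHS)


def _base_series(spec: ArchetypeSpec, rng: np.random.Generator) -> dict:
    """Noise-free raw series for the archetype, before phase roll."""
    warm_peak = 6 if spec.hemisphere == "N" else 0  # Jul vs Jan
    j = lambda: 1.0 + spec.jitter * rng.uniform(-1, 1)

    a = spec.archetype
    if a == "temperate":
        tmid = 10.0 * j() + _cycle(warm_peak, 12.0 * j())
        half_diurnal = 4.0
        precip = 60.0 * j() + _cycle(warm_peak, 20.0 * j())
        srad = 180.0 + _cycle(warm_peak, 80.0 * j())
        ndvi = 0.45 + _cycle(warm_peak + 1, 0.25 * j())
        pet = 60.0 * j() + _cycle(warm_peak, 40.0)
    elif a in ("tropical_unimodal", "tropical_bimodal"):
        tmid = 26.0 * j() + _cycle(warm_peak, 1.0 * j())
        half_diurnal = 3.0
        if a == "tropical_unimodal":
            precip = 110.0 * j() + _cycle(warm_peak, 95.0 * j())
        else:
            m = np.arange(MONTHS)
            precip = 110.0 * j() + 80.0 * j() * np.cos(4 * np.pi * (m - warm_peak) / MONTHS)
        srad = 220.0 + _cycle(warm_peak, 15.0)
        ndvi = 0.5 + 0.2 * j() * np.roll((precip - precip.mean()) / np.ptp(precip), 1)
        pet = 120.0 * j() + _cycle(warm_peak, 10.0)
    elif a == "desert_hot":
        tmid = 28.0 * j() + _cycle(warm_peak, 7.5 * j())
        half_diurnal = 8.0
        precip = np.clip(4.0 * j() + _cycle(warm_peak, 2.0), 0.0, None)
        srad = 250.0 + _cycle(warm_peak, 40.0)
        ndvi = np.full(MONTHS, 0.08)
        pet = 160.0 * j() + _cycle(warm_peak, 30.0)
    elif a == "desert_cold":
        tmid = 2.0 * j() + _cycle(warm_peak, 12.5 * j())
        half_diurnal = 10.0
        precip = np.clip(8.0 * j() + _cycle(warm_peak, 4.0), 0.0, None)
        srad = 200.0 + _cycle(warm_peak, 60.0)
        ndvi = np.full(MONTHS, 0.1)
        pet = 80.0 * j() + _cycle(warm_peak, 40.0)
    elif a == "arctic":
        tmid = -8.0 * j() + _cycle(warm_peak, 10.0 * j())
        half_diurnal = 5.0
        precip = 30.0 * j() + _cycle(warm_peak, 10.0)
        srad = 120.0 + _cycle(warm_peak, 110.0 * j())
        ndvi = np.clip(0.1 + _cycle(warm_peak + 1, 0.1), 0.0, None)
        pet = np.clip(25.0 * j() + _cycle(warm_peak, 15.0), 1.0, None)
    else:  # pragma: no cover
        raise AssertionError(a)

    return {
        "tmid": tmid, "half_diurnal": half_diurnal, "precip": precip,
        "srad": srad, "ndvi": ndvi, "pet": pet,
    }


def _truth_labels(spec: ArchetypeSpec, clean: dict) -> np.ndarray:
    """Analytic ground-truth season codes from the noise-free series."""
    zone = spec.zone
    out = np.zeros(MONTHS, dtype=np.uint8)
    if zone == Zone.TEMPERATE:
        coldest = int(np.argmin(clean["tmid"]))
        quarters = [
            (SeasonLabel.WINTER, (-1, 0, 1)),
            (SeasonLabel.SPRING, (2, 3, 4)),
            (SeasonLabel.SUMMER, (5, 6, 7)),
            (SeasonLabel.AUTUMN, (8, 9, 10)),
        ]
        for label, offsets in quarters:
            for o in offsets:
                out[(coldest + o) % MONTHS] = label
        return out
    if zone == Zone.TROPICAL:
        driver, hi, lo = clean["precip"], SeasonLabel.WET, SeasonLabel.DRY
    elif zone == Zone.ARCTIC_MONTANE:
        driver, hi, lo = clean["tmid"], SeasonLabel.SUMMER, SeasonLabel.WINTER
    else:
        driver, hi, lo = clean["tmid"], SeasonLabel.HOTTER, SeasonLabel.COOLER
    top6 = np.argsort(-driver, kind="stable")[:6]
    out[:] = lo
    out[top6] = hi
    return out


def make_pixel(spec: ArchetypeSpec) -> tuple[PixelClimate, SeasonCalendar]:
    """Generate one archetype pixel and its analytic ground-truth calendar."""
    rng = np.random.default_rng(spec.seed)
    clean = _base_series(spec, rng)
    truth = np.roll(_truth_labels(spec, clean), spec.phase_shift)

    s = spec.noise_sd
    tmid = clean["tmid"] + rng.normal(0, s * _BASE_SIGMA["tmid"], MONTHS)
    half = clean["half_diurnal"] * (1 + 0.1 * s * rng.normal(0, 1, MONTHS)).clip(0.2, None)
    precip = np.clip(
        clean["precip"] * (1 + rng.normal(0, s * _BASE_SIGMA["precip_frac"], MONTHS)), 0, None
    )
    srad = np.clip(clean["srad"] + rng.normal(0, s * _BASE_SIGMA["srad"], MONTHS), 0, None)
    ndvi = np.clip(clean["ndvi"] + rng.normal(0, s * _BASE_SIGMA["ndvi"], MONTHS), -1, 1)
    pet = np.clip(
        clean["pet"] * (1 + rng.normal(0, s * _BASE_SIGMA["pet_frac"], MONTHS)), 0.5, None
    )
    roll = lambda v: np.roll(v, spec.phase_shift)
    pixel = PixelClimate(
        tmin=roll(tmid - half), tmax=roll(tmid + half), precip=roll(precip),
        srad=roll(srad), ndvi=roll(ndvi), pet=roll(pet),
    )
    if s == 0 and classify_zone(pixel) != spec.zone:
        raise ValueError(
            f"archetype {spec.archetype!r} violates its zone gate after jittering"
        )
    return pixel, SeasonCalendar(zone=spec.zone, labels=truth)


def make_raster(
    width: int,
    height: int,
    archetype_field: np.ndarray,
    seed: int = 0,
    *,
    noise_sd: float = 0.0,
    mask: np.ndarray | None = None,
    hemisphere: str = "N",
) -> tuple[ClimateStack, np.ndarray, np.ndarray]:
    """Build a synthetic stack plus truth zone and season rasters.

    ``archetype_field`` is an (height, width) array of archetype names; cells
    may be masked out via ``mask``.  Within each archetype block, means and
    amplitudes drift smoothly across space (a Gaussian-filtered random field
    of ±8%), so neighbouring cells are similar but not identical.
    """
    archetype_field = np.asarray(archetype_field, dtype=object)
    if archetype_field.shape != (height, width):
        raise ValueError("archetype_field shape must be (height, width)")
    if mask is None:
        mask = np.ones((height, width), dtype=bool)
    rng = np.random.default_rng(seed)
    smooth = gaussian_filter(rng.normal(size=(height, width)), sigma=2.0, mode="nearest")
    if smooth.std() > 0:
        smooth = 0.08 * smooth / (3 * smooth.std())  # roughly ±8%

    variables = ("tmin", "tmax", "precip", "srad", "ndvi", "pet")
    layers = {v: np.full((MONTHS, height, width), np.nan) for v in variables}
    truth_zone = np.zeros((height, width), dtype=np.uint8)
    truth_season = np.zeros((MONTHS, height, width), dtype=np.uint8)
    for r in range(height):
        for c in range(width):
            if not mask[r, c]:
                continue
            spec = ArchetypeSpec(
                archetype=str(archetype_field[r, c]),
                hemisphere=hemisphere,
                noise_sd=noise_sd,
                seed=int(rng.integers(2**31)),
            )
            pixel, truth = make_pixel(spec)
            scale = 1.0 + smooth[r, c]
            for v in variables:
                vec = getattr(pixel, v)
                if v in ("precip", "pet", "srad"):
                    vec = vec * scale
                elif v in ("tmin", "tmax"):
                    vec = vec + 10.0 * smooth[r, c]  # smooth ±~1 °C drift
                layers[v][:, r, c] = vec
            truth_zone[r, c] = int(truth.zone)
            truth_season[:, r, c] = truth.labels
    # a 1-degree grid anchored at the origin keeps coordinates interpretable
    transform = (1.0, 0.0, 0.0, 0.0, -1.0, float(height))
    stack = ClimateStack(layers=layers, mask=mask.copy(), transform=transform, crs="EPSG:4326")
    return stack, truth_zone, truth_season


def make_reference_set(
    params: Params | None = None,
    n_per_archetype: int = 10,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    label_flip_p: float = 0.0,
) -> tuple[list[ReferenceRecord], dict]:
    """Synthetic stand-in for a surveyed city reference calendar set.

    Draws varied temperate and tropical pixels (the two vocabularies reference
    records may use), labels each by the classification pipeline under
    ``params``, and optionally flips each month's label to a same-zone
    alternative with probability ``label_flip_p`` to emulate imperfect local
    season reports.  Returns the records and a ``(city, country) -> pixel``
    lookup for the tuner.
    """
    params = params or Params()
    rng = np.random.default_rng(seed)
    vocab_of = {
        Zone.TEMPERATE: ["winter", "spring", "summer", "autumn"],
        Zone.TROPICAL: ["wet", "dry"],
    }
    records, lookup = [], {}
    i = 0
    for archetype in ("temperate", "tropical_unimodal", "tropical_bimodal"):
        for _ in range(n_per_archetype):
            spec = ArchetypeSpec(
                archetype=archetype,
                hemisphere="N" if rng.random() < 0.5 else "S",
                noise_sd=noise_sd,
                jitter=0.15,
                phase_shift=int(rng.integers(-1, 2)),
                seed=int(rng.integers(2**31)),
            )
            pixel, _ = make_pixel(spec)
            cal = classify_pixel(pixel, params, seed=0)
            labels = list(cal.names())
            zone_vocab = vocab_of[cal.zone]
            if label_flip_p > 0:
                for m in range(MONTHS):
                    if rng.random() < label_flip_p:
                        others = [v for v in zone_vocab if v != labels[m]]
                        labels[m] = others[int(rng.integers(len(others)))]
            city, country = f"city{i:04d}", archetype
            records.append(ReferenceRecord(
                city=city, country=country,
                lon=float(rng.uniform(-180, 180)), lat=float(rng.uniform(-60, 70)),
                labels=tuple(labels),
            ))
            lookup[(city, country)] = pixel
            i += 1
    return records, lookup
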