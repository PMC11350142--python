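"""Reference season calendars for cities and the error function against them.

Reference records carry one city's canonical month->season labels plus its
location.  Raw labels from heterogeneous sources (local season names such as
"Harmattan" or "Rainy Season") are recoded onto the canonical two-season
tropical vocabulary; temperate names pass through lowercased.

A prediction is scored per city by counting the months whose season disagrees
with the reference.  When the predicted zone and the reference vocabulary
disagree across the temperate/tropical pair, the city's error is capped at 6
— a fixed high penalty for zone confusion that avoids letting the 12
guaranteed mismatches dominate the mean.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .clustering import SeasonCalendar

__all__ = [
    "ReferenceRecord",
    "RecodeTable",
    "DEFAULT_RECODE",
    "recode_label",
    "infer_reference_zone",
    "city_error",
    "mean_error",
    "train_test_split",
    "read_reference_csv",
]

MONTHS = 12
MONTH_COLUMNS = ["jan", "feb", "mar", "apr", "may", "jun",
                 "jul", "aug", "sep", "oct", "nov", "dec"]

TEMPERATE_VOCAB = frozenset({"winter", "spring", "summer", "autumn"})
TROPICAL_VOCAB = frozenset({"dry", "wet"})
#: full canonical vocabulary a reference record may use
CANONICAL_VOCAB = TEMPERATE_VOCAB | TROPICAL_VOCAB

#: months a zone-confused city contributes at most
ZONE_CONFUSION_CAP = 6

#: raw label -> canonical label for the two-season tropics
_TROPICAL_RECODE: dict[str, str] = {
    "dry season": "dry",
    "hot and dry": "dry",
    "harmattan": "dry",
    "warm and dry": "dry",
    "hot": "dry",
    "sunny and dry": "dry",
    "cool and dry": "dry",
    "rainy": "wet",
    "wet season": "wet",
    "rainy season": "wet",
    "wet-season": "wet",
    "warm and humid": "wet",
    "hot and wet": "wet",
    "hot and humid": "wet",
    "short rainy season": "wet",
    "rain": "wet",
    "humid": "wet",
    "warm and wet": "wet",
    "long rainy season": "wet",
}


class RecodeTable:
    """Case-insensitive raw-label -> canonical-label mapping.

    Seeded with the 19 tropical recodings plus identity for the canonical
    vocabulary itself; extra mappings may be layered on top.
    """

    def __init__(self, extra: dict[str, str] | None = None) -> None:
        self._map = dict(_TROPICAL_RECODE)
        self._map.update({v: v for v in CANONICAL_VOCAB})
        if extra:
            self._map.update({k.strip().lower(): v.strip().lower() for k, v in extra.items()})
        bad = set(self._map.values()) - CANONICAL_VOCAB
        if bad:
            raise ValueError(f"recode targets outside canonical vocabulary: {sorted(bad)}")

    def __contains__(self, raw: str) -> bool:
        return raw.strip().lower() in self._map

    def __getitem__(self, raw: str) -> str:
        key = raw.strip().lower()
        try:
            return self._map[key]
        except KeyError:
            raise KeyError(f"unmapped season label: {raw!r}") from None

    def items(self):
        return self._map.items()


DEFAULT_RECODE = RecodeTable()


def recode_label(raw: str, table: RecodeTable | None = None) -> str:
    """Canonicalize one raw season label (KeyError on unknown labels)."""
    return (table or DEFAULT_RECODE)[raw]


@dataclass(frozen=True)
class ReferenceRecord:
    """One city's canonical 12-month season calendar with location metadata."""

    city: str
    country: str
    lon: float
    lat: float
    labels: tuple

    def __post_init__(self) -> None:
        if len(self.labels) != MONTHS:
            raise ValueError(f"{self.city}: expected {MONTHS} labels, got {len(self.labels)}")
        bad = set(self.labels) - CANONICAL_VOCAB
        if bad:
            raise ValueError(f"{self.city}: non-canonical labels {sorted(bad)}")


def infer_reference_zone(labels: Sequence[str]) -> str:
    """'tropical-like' or 'temperate-like' from a record's vocabulary."""
    present = set(labels)
    if present <= TROPICAL_VOCAB:
        return "tropical-like"
    if present <= TEMPERATE_VOCAB:
        return "temperate-like"
    raise ValueError(f"mixed season vocabularies: {sorted(present)}")


def _calendar_kind(pred: SeasonCalendar | Sequence[str]) -> tuple[list[str], str | None]:
    """Prediction's month names plus its temperate/tropical side (None for
    desert/arctic vocabularies, which never trigger the cap)."""
    names = pred.names() if isinstance(pred, SeasonCalendar) else [str(s).lower() for s in pred]
    present = set(names)
    if present <= TROPICAL_VOCAB:
        return names, "tropical-like"
    if present <= TEMPERATE_VOCAB:
        return names, "temperate-like"
    return names, None


def city_error(pred: SeasonCalendar | Sequence[str], ref: ReferenceRecord) -> int:
    """Months of disagreement between a prediction and one reference record.

    The raw error is the count of mismatching months (0..12).  If the
    reference vocabulary is temperate-like but the prediction tropical-like,
    or vice versa, the error is capped at :data:`ZONE_CONFUSION_CAP`.  Desert
    and arctic predictions mismatch month-wise as usual but carry no cap.
    """
    names, pred_kind = _calendar_kind(pred)
    raw = sum(p != r for p, r in zip(names, ref.labels))
    ref_kind = infer_reference_zone(ref.labels)
    if pred_kind is not None and pred_kind != ref_kind:
        return min(raw, ZONE_CONFUSION_CAP)
    return raw


def mean_error(
    preds: Iterable[SeasonCalendar | Sequence[str]],
    refs: Sequence[ReferenceRecord],
) -> tuple[float, Counter]:
    """Mean city error plus the error-score histogram across cities."""
    preds = list(preds)
    if len(preds) != len(refs):
        raise ValueError(f"{len(preds)} predictions for {len(refs)} references")
    errors = [city_error(p, r) for p, r in zip(preds, refs)]
    return float(np.mean(errors)), Counter(errors)


def train_test_split(records: Sequence, train_frac: float = 0.7, seed: int = 0):
    """Random disjoint train/test partition; |train| = round(frac * n)."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie strictly between 0 and 1")
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    n_train = int(np.floor(train_frac * n + 0.5))  # round-half-up
    order = np.random.default_rng(seed).permutation(n)
    train = [records[i] for i in sorted(order[:n_train])]
    test = [records[i] for i in sorted(order[n_train:])]
    return train, test


def read_reference_csv(path, table: RecodeTable | None = None) -> list[ReferenceRecord]:
    """Load reference records from CSV (city, country, lon, lat, jan..dec).

    Month columns may hold raw labels; each is recoded to the canonical
    vocabulary on the way in.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in ["city", "country", "lon", "lat", *MONTH_COLUMNS] if c not in df.columns]
    if missing:
        raise ValueError(f"reference CSV is missing columns: {missing}")
    table = table or DEFAULT_RECODE
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        labels = tuple(recode_label(str(d[m]), table) for m in MONTH_COLUMNS)
        records.append(ReferenceRecord(
            city=str(d["city"]), country=str(d["country"]),
            lon=float(d["lon"]), lat=float(d["lat"]), labels=labels,
        ))
    return records
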