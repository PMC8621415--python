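"""Input tables, validation, and automatic model construction.

Four tabular text inputs drive a run:

* occurrence records — one concentration measurement per row, possibly
  censored against the limit of detection (LOD) and limit of quantification
  (LOQ);
* optional prevalence samples — sample positives ``x`` out of ``n`` per
  hazard x food pair;
* a consumption diary — per respondent and day, the consumed amount of each
  food (zero meaning no consumption that day);
* body weights — one weight per respondent.

The likelihood components a model needs are determined automatically from
the data features (:func:`build_model_spec`): e.g. if no record is censored,
no censored-data component is included.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class Censor(enum.Enum):
    """Censoring status of a concentration measurement."""

    EXACT = "exact"          # quantified value above LOQ
    INTERVAL = "interval"    # detected but below LOQ: in (LOD, LOQ)
    BELOW_LOD = "nd"         # not detected: below LOD


class OccurrenceOption(enum.Enum):
    SEPARATE = "separate"           # positives-only distribution + binomial prevalence
    ZERO_INFLATED = "zero_inflated"  # prevalence folded into the concentration model


class FrequencyOption(enum.Enum):
    INDEPENDENT_DAYS = "independent_days"
    MARKOV = "markov"


class HazardType(enum.Enum):
    CHEMICAL = "chemical"
    MICROBIOLOGICAL = "microbiological"


@dataclass(frozen=True)
class OccurrenceRecord:
    """One concentration measurement with its censoring state.

    ``value`` is present iff the record is EXACT (then value > loq).
    INTERVAL records lie in (lod, loq); BELOW_LOD records lie below lod.
    Units are free text and pass through untouched.
    """

    hazard_id: str
    food_id: str
    censor: Censor
    lod: float
    loq: float
    value: float | None = None
    unit: str = ""

    def __post_init__(self) -> None:
        if not (self.lod >= 0):
            raise ValueError(f"lod must be >= 0, got {self.lod}")
        if self.lod > self.loq:
            raise ValueError(
                f"lod ({self.lod}) must not exceed loq ({self.loq}) "
                f"for {self.hazard_id}/{self.food_id}"
            )
        if self.censor is Censor.EXACT:
            if self.value is None or not math.isfinite(self.value):
                raise ValueError("EXACT record requires a finite value")
            if self.value <= self.loq:
                raise ValueError(
                    f"EXACT value {self.value} is not above LOQ {self.loq}: "
                    "a value inside the censoring interval must be recorded "
                    "as interval-censored"
                )
        else:
            if self.value is not None:
                raise ValueError(f"{self.censor.name} record must not carry a value")
            if self.censor is Censor.INTERVAL and not (self.lod < self.loq):
                raise ValueError("INTERVAL record requires lod < loq")


@dataclass(frozen=True)
class PrevalenceSample:
    """Binomial sample for contamination prevalence: x positives of n."""

    hazard_id: str
    food_id: str
    n_positive: int
    n_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_positive <= self.n_total):
            raise ValueError(
                f"need 0 <= x <= n, got x={self.n_positive}, n={self.n_total}"
            )


@dataclass(frozen=True)
class DiaryEntry:
    """Amounts (raw mass units) consumed by one respondent on one day.

    ``amounts`` is aligned to the run's fixed food ordering; zeros mean the
    food was not consumed that day.
    """

    respondent_id: str
    day_index: int
    amounts: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.day_index < 1:
            raise ValueError("day_index must be >= 1")
        if any(a < 0 or not math.isfinite(a) for a in self.amounts):
            raise ValueError(f"negative or non-finite amount for {self.respondent_id}")


@dataclass(frozen=True)
class BodyWeightRecord:
    respondent_id: str
    weight: float  # kg

    def __post_init__(self) -> None:
        if not (self.weight > 0 and math.isfinite(self.weight)):
            raise ValueError(f"weight must be positive, got {self.weight}")


#: Names of likelihood components that may be active in a model.
LIKELIHOOD_COMPONENTS = frozenset(
    {"L1", "L2", "L3", "L4", "L5", "L6", "L7", "Lw", "Lr", "Ljr", "Lj"}
)


@dataclass
class ModelSpec:
    """Which likelihood components are active, and run configuration."""

    occurrence_option: OccurrenceOption = OccurrenceOption.SEPARATE
    frequency_option: FrequencyOption = FrequencyOption.INDEPENDENT_DAYS
    active_likelihoods: set[str] = field(default_factory=set)
    hazard_types: dict[str, HazardType] = field(default_factory=dict)
    foods: tuple[str, ...] = ()
    hazards: tuple[str, ...] = ()
    pairs: tuple[tuple[str, str], ...] = ()  # (hazard, food) with occurrence data
    chains: int = 4
    iterations: int = 2000  # retained per chain
    burnin: int = 1000
    seed: int = 0
    conc_factor: dict[tuple[str, str], float] = field(default_factory=dict)
    prev_factor: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.active_likelihoods) - LIKELIHOOD_COMPONENTS
        if unknown:
            raise ValueError(f"unknown likelihood components: {sorted(unknown)}")


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV/TSV text table with a header row (separator sniffed)."""
    return pd.read_csv(path, sep=None, engine="python", encoding="utf-8")


def read_occurrence(path: str | Path) -> list[OccurrenceRecord]:
    """Read and validate occurrence records.

    Expected columns: ``hazard, food, value, censor, lod, loq, unit`` where
    ``censor`` is one of ``exact``/``interval``/``nd`` and ``value`` is blank
    unless exact. Raises on invariant violations and when a hazard x food
    pair carries no exact value at all — the concentration distribution is
    not estimable without at least some quantified values above LOQ.
    """
    df = _read_table(path)
    required = {"hazard", "food", "value", "censor", "lod", "loq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"occurrence table missing columns: {sorted(missing)}")
    records: list[OccurrenceRecord] = []
    for row in df.itertuples(index=False):
        censor = Censor(str(row.censor).strip().lower())
        raw_value = getattr(row, "value")
        value = None if pd.isna(raw_value) else float(raw_value)
        raw_unit = getattr(row, "unit", "")
        unit = "" if pd.isna(raw_unit) else str(raw_unit)
        records.append(
            OccurrenceRecord(
                hazard_id=str(row.hazard),
                food_id=str(row.food),
                censor=censor,
                lod=float(row.lod),
                loq=float(row.loq),
                value=value,
                unit=unit,
            )
        )
    _require_exact_per_pair(records)
    return records


def _require_exact_per_pair(records: list[OccurrenceRecord]) -> None:
    pairs = {(r.hazard_id, r.food_id) for r in records}
    for hz, fd in sorted(pairs):
        if not any(
            r.censor is Censor.EXACT
            for r in records
            if (r.hazard_id, r.food_id) == (hz, fd)
        ):
            raise ValueError(
                f"no exact values for {hz}/{fd}: at least some measurements "
                "above LOQ are required to estimate the concentration "
                "distribution"
            )


def write_occurrence(records: list[OccurrenceRecord], path: str | Path) -> None:
    rows = [
        {
            "hazard": r.hazard_id,
            "food": r.food_id,
            "value": r.value if r.value is not None else "",
            "censor": r.censor.value,
            "lod": r.lod,
            "loq": r.loq,
            "unit": r.unit,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_prevalence(path: str | Path) -> list[PrevalenceSample]:
    """Read prevalence samples; columns ``hazard, food, positive, total``."""
    df = _read_table(path)
    required = {"hazard", "food", "positive", "total"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"prevalence table missing columns: {sorted(missing)}")
    return [
        PrevalenceSample(
            hazard_id=str(r.hazard),
            food_id=str(r.food),
            n_positive=int(r.positive),
            n_total=int(r.total),
        )
        for r in df.itertuples(index=False)
    ]


def write_prevalence(samples: list[PrevalenceSample], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "hazard": s.hazard_id,
                "food": s.food_id,
                "positive": s.n_positive,
                "total": s.n_total,
            }
            for s in samples
        ]
    ).to_csv(path, index=False)


def read_consumption(
    path_diary: str | Path, path_weights: str | Path
) -> tuple[list[DiaryEntry], list[BodyWeightRecord]]:
    """Read the diary and body-weight tables.

    Diary columns: ``respondent, day`` then one column per food holding the
    raw consumed amount (0 = not consumed). Weight columns:
    ``respondent, weight``. Every diary respondent must have a body weight.
    Respondents with fewer than two diary days and foods never consumed are
    flagged in the log; both are allowed.
    """
    diary_df = _read_table(path_diary)
    weight_df = _read_table(path_weights)
    for col in ("respondent", "day"):
        if col not in diary_df.columns:
            raise ValueError(f"diary table missing column: {col}")
    for col in ("respondent", "weight"):
        if col not in weight_df.columns:
            raise ValueError(f"weight table missing column: {col}")
    foods = [c for c in diary_df.columns if c not in ("respondent", "day")]
    if not foods:
        raise ValueError("diary table has no food columns")

    weights = [
        BodyWeightRecord(respondent_id=str(r.respondent), weight=float(r.weight))
        for r in weight_df.itertuples(index=False)
    ]
    weight_ids = {w.respondent_id for w in weights}

    entries: list[DiaryEntry] = []
    for _, row in diary_df.iterrows():
        rid = str(row["respondent"])
        if rid not in weight_ids:
            raise ValueError(f"respondent {rid!r} in diary has no body weight")
        entries.append(
            DiaryEntry(
                respondent_id=rid,
                day_index=int(row["day"]),
                amounts=tuple(float(row[f]) for f in foods),
            )
        )

    seen: dict[str, set[int]] = {}
    for e in entries:
        days = seen.setdefault(e.respondent_id, set())
        if e.day_index in days:
            raise ValueError(
                f"duplicate day {e.day_index} for respondent {e.respondent_id}"
            )
        days.add(e.day_index)
    for rid, days in seen.items():
        if len(days) < 2:
            logger.warning("respondent %s has fewer than 2 diary days", rid)

    amounts = np.array([e.amounts for e in entries])
    for j, food in enumerate(foods):
        if (amounts[:, j] > 0).sum() == 0:
            logger.warning(
                "food %s never consumed in diary: its frequency is estimable "
                "but its amount distribution is not",
                food,
            )
    return entries, weights


def write_consumption(
    entries: list[DiaryEntry],
    weights: list[BodyWeightRecord],
    foods: list[str],
    path_diary: str | Path,
    path_weights: str | Path,
) -> None:
    rows = []
    for e in entries:
        row = {"respondent": e.respondent_id, "day": e.day_index}
        row.update({f: a for f, a in zip(foods, e.amounts)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path_diary, index=False)
    pd.DataFrame(
        [{"respondent": w.respondent_id, "weight": w.weight} for w in weights]
    ).to_csv(path_weights, index=False)


def diary_foods(path_diary: str | Path) -> list[str]:
    """Food ordering implied by the diary's columns."""
    df = _read_table(path_diary)
    return [c for c in df.columns if c not in ("respondent", "day")]


def build_model_spec(
    occ_records: list[OccurrenceRecord],
    prev_samples: list[PrevalenceSample] | None,
    diaries: list[DiaryEntry] | None,
    *,
    occurrence_option: OccurrenceOption = OccurrenceOption.SEPARATE,
    frequency_option: FrequencyOption = FrequencyOption.INDEPENDENT_DAYS,
    hazard_types: dict[str, HazardType] | None = None,
    foods: tuple[str, ...] = (),
    weights: bool = True,
    **mcmc_options,
) -> ModelSpec:
    """Assemble a :class:`ModelSpec` from the data features.

    The active likelihood components mirror exactly the evidence present:
    exact records activate L1 (or L7 under the zero-inflated option),
    interval-censored records L2 (L6), non-detects L3 (L5); a prevalence
    sample activates L4 (required and only meaningful under the SEPARATE
    option); diaries activate the amount component Lr and the chosen
    frequency component (Ljr independent days, Lj Markov); body weights Lw.
    A pure function of its inputs: same data features give the same spec.
    """
    censors = {r.censor for r in occ_records}
    active: set[str] = set()
    if occurrence_option is OccurrenceOption.SEPARATE:
        if Censor.EXACT in censors:
            active.add("L1")
        if Censor.INTERVAL in censors:
            active.add("L2")
        if Censor.BELOW_LOD in censors:
            active.add("L3")
        pair_ids = {(r.hazard_id, r.food_id) for r in occ_records}
        prev_pairs = {(s.hazard_id, s.food_id) for s in (prev_samples or [])}
        if prev_samples:
            active.add("L4")
        missing = pair_ids - prev_pairs
        if occ_records and missing:
            raise ValueError(
                "SEPARATE occurrence option requires a prevalence sample per "
                f"hazard/food pair; missing for {sorted(missing)}"
            )
    else:
        if Censor.EXACT in censors:
            active.add("L7")
        if Censor.INTERVAL in censors:
            active.add("L6")
        if Censor.BELOW_LOD in censors:
            active.add("L5")
    if occ_records and not ({"L1", "L7"} & active):
        raise ValueError("at least some measurements need to be exact values")

    if diaries:
        if any(any(a > 0 for a in e.amounts) for e in diaries):
            active.add("Lr")
        if frequency_option is FrequencyOption.MARKOV:
            active.add("Lj")
            _check_consecutive_days(diaries)
        else:
            active.add("Ljr")
        if weights:
            active.add("Lw")

    hazards = tuple(sorted({r.hazard_id for r in occ_records}))
    pairs = tuple(sorted({(r.hazard_id, r.food_id) for r in occ_records}))
    htypes = dict(hazard_types or {})
    for hz in hazards:
        htypes.setdefault(hz, HazardType.CHEMICAL)
    return ModelSpec(
        occurrence_option=occurrence_option,
        frequency_option=frequency_option,
        active_likelihoods=active,
        hazard_types=htypes,
        foods=tuple(foods),
        hazards=hazards,
        pairs=pairs,
        **mcmc_options,
    )


def _check_consecutive_days(diaries: list[DiaryEntry]) -> None:
    by_resp: dict[str, list[int]] = {}
    for e in diaries:
        by_resp.setdefault(e.respondent_id, []).append(e.day_index)
    for rid, days in by_resp.items():
        days = sorted(days)
        if len(days) >= 2 and days != list(range(days[0], days[0] + len(days))):
            raise ValueError(
                f"Markov frequency option requires consecutive day indices; "
                f"respondent {rid} has days {days}"
            )
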