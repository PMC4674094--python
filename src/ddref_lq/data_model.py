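"""Domain types and data handling for grouped animal-lifespan dose-response data.

The analysis operates on two levels: individual animals (used by the survival
model) and treatment groups (used by the inverse-mean-lifespan regressions).
A *stratum* is the comparability class — strain x sex x age-at-first-exposure
class, optionally x study — within which dose-response coefficients are shared.

This module provides CSV readers/writers, the inclusion-filter cascade,
group summarization (inverse mean lifespan with delta-method variance),
stratification, and the acute / acute-protracted-comparison subset rules.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AnimalRecord",
    "StratumKey",
    "TreatmentGroup",
    "GroupObservation",
    "FilterConfig",
    "CascadeStep",
    "SchemaError",
    "ValidationError",
    "read_animal_table",
    "write_animal_table",
    "read_group_table",
    "write_group_table",
    "apply_inclusion_filters",
    "summarize_groups",
    "build_strata",
    "subset_acute",
    "subset_comparison",
    "group_is_acute",
    "write_filter_report",
]

MAX_TOTAL_DOSE_GY = 1.5
MIN_GROUPS_PER_STRATUM = 3


class SchemaError(ValueError):
    """A mandatory column is missing or unparseable."""


class ValidationError(ValueError):
    """A row violates a domain invariant (e.g. non-positive lifespan)."""


@dataclass(frozen=True)
class StratumKey:
    """Comparability class within which dose-response coefficients are shared."""

    strain: str
    sex: str
    age_class: str
    study_id: str | None = None

    def with_study(self, study_id: str) -> "StratumKey":
        return replace(self, study_id=study_id)


@dataclass(frozen=True)
class AnimalRecord:
    """One animal's treatment and lifespan; the unit of the survival analysis."""

    animal_id: str
    group_id: str
    study_id: str
    strain: str
    sex: str
    age_first_exposure: float  # days
    lifespan: float  # days
    event: bool = True  # death observed (False = censored)
    radiation_quality: str = "gamma"
    exposure_mode: str = "whole-body"
    let_class: str = "low"
    other_treatment: bool = False
    total_dose: float = 0.0  # Gy
    fractions: int = 1
    fraction_interval: float = 0.0  # days
    dose_rate: float | None = None  # Gy/min

    def __post_init__(self) -> None:
        if self.lifespan <= 0:
            raise ValidationError(
                f"animal {self.animal_id!r}: lifespan must be > 0, got {self.lifespan}"
            )
        if self.total_dose < 0:
            raise ValidationError(
                f"animal {self.animal_id!r}: total_dose must be >= 0, got {self.total_dose}"
            )
        if self.fractions < 1:
            raise ValidationError(
                f"animal {self.animal_id!r}: fractions must be >= 1, got {self.fractions}"
            )

    @property
    def stratum(self) -> StratumKey:
        return StratumKey(
            strain=self.strain, sex=self.sex, age_class=_age_class(self.age_first_exposure)
        )

    @property
    def is_control(self) -> bool:
        return self.total_dose == 0.0


@dataclass(frozen=True)
class TreatmentGroup:
    """One exposure condition with summary lifespan statistics."""

    group_id: str
    stratum: StratumKey
    study_id: str
    total_dose: float  # Gy
    fractions: int
    fraction_interval: float  # days
    n: int
    mean_lifespan: float  # days
    sem_lifespan: float  # days

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"group {self.group_id!r}: n must be >= 1")
        if self.mean_lifespan <= 0:
            raise ValidationError(f"group {self.group_id!r}: mean_lifespan must be > 0")

    @property
    def is_acute(self) -> bool:
        # a fraction is any dose delivered in <= 1 hour; controls count as acute
        return self.fractions == 1


@dataclass(frozen=True)
class GroupObservation:
    """A group's inverse mean lifespan with its delta-method variance.

    y = 1/mean(lifespan); Var(y) = SEM^2 / mean^4; weight = 1/Var(y).
    """

    group: TreatmentGroup
    y: float  # 1/days
    variance: float  # 1/days^2
    weight: float

    @classmethod
    def from_group(cls, group: TreatmentGroup) -> "GroupObservation":
        m = group.mean_lifespan
        s = group.sem_lifespan
        y = 1.0 / m
        var = (s * s) / m**4
        if var <= 0:
            raise ValidationError(
                f"group {group.group_id!r}: zero variance (n={group.n}); "
                "cannot enter the weighted regression"
            )
        return cls(group=group, y=y, variance=var, weight=1.0 / var)


def group_is_acute(group: TreatmentGroup) -> bool:
    return group.is_acute


def _age_class(age_days: float) -> str:
    """Label an age at first exposure. Distinct ages form distinct classes."""
    if float(age_days).is_integer():
        return str(int(age_days))
    return f"{age_days:g}"


# ---------------------------------------------------------------------------
# CSV I/O

_ANIMAL_COLUMNS = [
    "animal_id",
    "group_id",
    "study_id",
    "strain",
    "sex",
    "age_first_exposure",
    "lifespan",
    "event",
    "radiation_quality",
    "exposure_mode",
    "let_class",
    "other_treatment",
    "total_dose",
    "fractions",
    "fraction_interval",
    "dose_rate",
]

_MANDATORY_ANIMAL_COLUMNS = [
    "animal_id",
    "group_id",
    "study_id",
    "strain",
    "sex",
    "age_first_exposure",
    "lifespan",
    "total_dose",
]

_ALIASES = {
    "id": "animal_id",
    "animal": "animal_id",
    "group": "group_id",
    "study": "study_id",
    "gender": "sex",
    "age": "age_first_exposure",
    "age_at_exposure": "age_first_exposure",
    "age_first_irradiation": "age_first_exposure",
    "dose": "total_dose",
    "dose_gy": "total_dose",
    "quality": "radiation_quality",
    "interval": "fraction_interval",
    "interval_days": "fraction_interval",
    "n_fractions": "fractions",
    "died": "event",
    "death_observed": "event",
}

_TRUTHY = {"1", "true", "t", "yes", "y"}
_FALSY = {"0", "false", "f", "no", "n", ""}


def _parse_bool(value: object, default: bool = False) -> bool:
    if isinstance(value, bool):
        return value
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return default
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValidationError(f"cannot interpret {value!r} as a boolean flag")


def _normalise_columns(df: pd.DataFrame) -> pd.DataFrame:
    renames = {}
    for col in df.columns:
        key = col.strip().lower()
        renames[col] = _ALIASES.get(key, key)
    return df.rename(columns=renames)


def read_animal_table(path) -> list[AnimalRecord]:
    """Read an individual-level animal table from CSV.

    Case-insensitive column aliases are accepted. If the ``fractions`` column
    is absent but a ``single_exposure`` flag column is present, fractions
    defaults to 1 for flagged rows (a warning is logged); rows with the flag
    unset are rejected because their fractionation is unknown.
    """
    df = _normalise_columns(pd.read_csv(path, float_precision="round_trip"))

    for col in _MANDATORY_ANIMAL_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r}")

    if "fractions" not in df.columns:
        if "single_exposure" in df.columns:
            logger.warning(
                "no 'fractions' column; defaulting fractions=1 from 'single_exposure' flag"
            )
            flags = [_parse_bool(v) for v in df["single_exposure"]]
            if not all(flags):
                bad = flags.index(False) + 2  # 1-based + header
                raise ValidationError(
                    f"row {bad}: single_exposure is false and no fractions column present"
                )
            df["fractions"] = 1
        else:
            raise SchemaError("missing mandatory column 'fractions'")

    records: list[AnimalRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            records.append(
                AnimalRecord(
                    animal_id=str(d["animal_id"]),
                    group_id=str(d["group_id"]),
                    study_id=str(d["study_id"]),
                    strain=str(d["strain"]),
                    sex=str(d["sex"]),
                    age_first_exposure=float(d["age_first_exposure"]),
                    lifespan=float(d["lifespan"]),
                    event=_parse_bool(d.get("event"), default=True),
                    radiation_quality=str(d.get("radiation_quality", "gamma")),
                    exposure_mode=str(d.get("exposure_mode", "whole-body")),
                    let_class=str(d.get("let_class", "low")),
                    other_treatment=_parse_bool(d.get("other_treatment"), default=False),
                    total_dose=float(d["total_dose"]),
                    fractions=int(d["fractions"]),
                    fraction_interval=float(d.get("fraction_interval", 0.0) or 0.0),
                    dose_rate=(
                        float(d["dose_rate"])
                        if d.get("dose_rate") is not None
                        and not (isinstance(d.get("dose_rate"), float) and math.isnan(d["dose_rate"]))
                        else None
                    ),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return records


def write_animal_table(records: Iterable[AnimalRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "animal_id": r.animal_id,
                "group_id": r.group_id,
                "study_id": r.study_id,
                "strain": r.strain,
                "sex": r.sex,
                "age_first_exposure": r.age_first_exposure,
                "lifespan": r.lifespan,
                "event": r.event,
                "radiation_quality": r.radiation_quality,
                "exposure_mode": r.exposure_mode,
                "let_class": r.let_class,
                "other_treatment": r.other_treatment,
                "total_dose": r.total_dose,
                "fractions": r.fractions,
                "fraction_interval": r.fraction_interval,
                "dose_rate": r.dose_rate,
            }
        )
    pd.DataFrame(rows, columns=_ANIMAL_COLUMNS).to_csv(path, index=False)


_GROUP_COLUMNS = [
    "group_id",
    "study_id",
    "strain",
    "sex",
    "age_class",
    "total_dose",
    "fractions",
    "fraction_interval",
    "n",
    "mean_lifespan",
    "sem_lifespan",
]


def read_group_table(path) -> list[TreatmentGroup]:
    df = _normalise_columns(pd.read_csv(path, float_precision="round_trip"))
    for col in _GROUP_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r}")
    groups = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            groups.append(
                TreatmentGroup(
                    group_id=str(d["group_id"]),
                    stratum=StratumKey(
                        strain=str(d["strain"]),
                        sex=str(d["sex"]),
                        age_class=str(d["age_class"]),
                    ),
                    study_id=str(d["study_id"]),
                    total_dose=float(d["total_dose"]),
                    fractions=int(d["fractions"]),
                    fraction_interval=float(d["fraction_interval"]),
                    n=int(d["n"]),
                    mean_lifespan=float(d["mean_lifespan"]),
                    sem_lifespan=float(d["sem_lifespan"]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return groups


def write_group_table(groups: Iterable[TreatmentGroup], path) -> None:
    rows = []
    for g in groups:
        rows.append(
            {
                "group_id": g.group_id,
                "study_id": g.study_id,
                "strain": g.stratum.strain,
                "sex": g.stratum.sex,
                "age_class": g.stratum.age_class,
                "total_dose": g.total_dose,
                "fractions": g.fractions,
                "fraction_interval": g.fraction_interval,
                "n": g.n,
                "mean_lifespan": g.mean_lifespan,
                "sem_lifespan": g.sem_lifespan,
            }
        )
    pd.DataFrame(rows, columns=_GROUP_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Inclusion-filter cascade

@dataclass(frozen=True)
class FilterConfig:
    max_total_dose: float = MAX_TOTAL_DOSE_GY  # Gy (= Sv for low-LET)
    min_groups_per_stratum: int = MIN_GROUPS_PER_STRATUM
    by_study: bool = False


@dataclass(frozen=True)
class CascadeStep:
    criterion: str
    studies: int
    groups: int
    animals: int


def _counts(records: Sequence[AnimalRecord]) -> tuple[int, int, int]:
    studies = {r.study_id for r in records}
    groups = {r.group_id for r in records}
    return len(studies), len(groups), len(records)


def apply_inclusion_filters(
    records: Sequence[AnimalRecord],
    config: FilterConfig | None = None,
) -> tuple[list[AnimalRecord], list[CascadeStep]]:
    """Apply the inclusion criteria in order and report the survivor cascade.

    Steps: individual data available (identity on an individual-level table),
    external exposure, low-LET whole-body, total dose <= 1.5 Gy, no other
    treatments, and >= 3 distinct treatment groups per stratum. The returned
    report mirrors the cascade shape of the selection table: one row of
    (studies, groups, animals) counts per criterion.
    """
    config = config or FilterConfig()
    report: list[CascadeStep] = []
    current = list(records)

    def record_step(name: str) -> None:
        s, g, a = _counts(current)
        report.append(CascadeStep(criterion=name, studies=s, groups=g, animals=a))
        logger.info("filter %-45s studies=%d groups=%d animals=%d", name, s, g, a)

    record_step("individual-level animal data available")

    current = [r for r in current if r.exposure_mode.lower() != "internal" or r.is_control]
    record_step("external radiation exposures")

    current = [
        r
        for r in current
        if r.is_control
        or (r.let_class.lower() == "low" and r.exposure_mode.lower() == "whole-body")
    ]
    record_step("low-LET, whole body exposures")

    current = [r for r in current if r.total_dose <= config.max_total_dose]
    record_step(f"total dose <= {config.max_total_dose:g} Gy")

    current = [r for r in current if not r.other_treatment]
    record_step("no other treatments")

    # groups-per-stratum rule, optionally with study in the key
    def stratum_of(r: AnimalRecord) -> StratumKey:
        key = r.stratum
        return key.with_study(r.study_id) if config.by_study else key

    by_stratum: dict[StratumKey, set[str]] = {}
    for r in current:
        by_stratum.setdefault(stratum_of(r), set()).add(r.group_id)
    keep = {
        key
        for key, gids in by_stratum.items()
        if len(gids) >= config.min_groups_per_stratum
    }
    current = [r for r in current if stratum_of(r) in keep]
    record_step(f">= {config.min_groups_per_stratum} treatment groups per stratum")

    return current, report


def write_filter_report(report: Sequence[CascadeStep], path) -> None:
    df = pd.DataFrame(
        [(s.criterion, s.studies, s.groups, s.animals) for s in report],
        columns=["step", "studies", "groups", "animals"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Group summarization

def summarize_groups(records: Sequence[AnimalRecord]) -> list[GroupObservation]:
    """Summarize animals into per-group inverse-mean-lifespan observations.

    Per group: mean lifespan m, SEM s = sd/sqrt(n) (sample sd, ddof=1), then
    y = 1/m and Var(y) = s^2/m^4 by the delta method. Groups whose variance is
    undefined or zero (n = 1, or all lifespans identical) are excluded with a
    warning — they cannot carry a finite weight.
    """
    order: list[str] = []
    by_group: dict[str, list[AnimalRecord]] = {}
    for r in records:
        if r.group_id not in by_group:
            order.append(r.group_id)
        by_group.setdefault(r.group_id, []).append(r)

    observations: list[GroupObservation] = []
    for gid in order:
        members = by_group[gid]
        lifespans = np.array([m.lifespan for m in members], dtype=float)
        n = len(lifespans)
        mean = float(lifespans.mean())
        sem = float(lifespans.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        first = members[0]
        group = TreatmentGroup(
            group_id=gid,
            stratum=first.stratum,
            study_id=first.study_id,
            total_dose=first.total_dose,
            fractions=first.fractions,
            fraction_interval=first.fraction_interval,
            n=n,
            mean_lifespan=mean,
            sem_lifespan=sem,
        )
        if sem <= 0:
            logger.warning(
                "group %s: variance undefined (n=%d, sem=%g); excluded from regression",
                gid, n, sem,
            )
            continue
        observations.append(GroupObservation.from_group(group))
    return observations


# ---------------------------------------------------------------------------
# Stratification and subsets

StrataMap = Mapping[StratumKey, Sequence[TreatmentGroup]]
ObsStrataMap = Mapping[StratumKey, Sequence[GroupObservation]]


def build_strata(
    groups: Sequence[TreatmentGroup],
    by_study: bool = False,
    min_groups: int = MIN_GROUPS_PER_STRATUM,
) -> dict[StratumKey, list[TreatmentGroup]]:
    """Partition treatment groups into strata.

    With ``by_study`` the study identifier joins the key — groups sharing
    strain/sex/age but coming from different studies then land in different
    strata, and strata left with fewer than ``min_groups`` groups are dropped
    (this is how shared control groups fall out of the by-study analysis).
    """
    strata: dict[StratumKey, list[TreatmentGroup]] = {}
    for g in groups:
        key = g.stratum.with_study(g.study_id) if by_study else g.stratum
        strata.setdefault(key, []).append(g)
    if by_study:
        dropped = {k: v for k, v in strata.items() if len(v) < min_groups}
        for key, gs in dropped.items():
            logger.info(
                "by-study stratification drops stratum %s (%d groups, %d animals)",
                key, len(gs), sum(g.n for g in gs),
            )
        strata = {k: v for k, v in strata.items() if len(v) >= min_groups}
    return strata


def stratify_observations(
    observations: Sequence[GroupObservation],
    by_study: bool = False,
    min_groups: int = MIN_GROUPS_PER_STRATUM,
) -> dict[StratumKey, list[GroupObservation]]:
    """As :func:`build_strata`, but over weighted group observations."""
    strata: dict[StratumKey, list[GroupObservation]] = {}
    for obs in observations:
        g = obs.group
        key = g.stratum.with_study(g.study_id) if by_study else g.stratum
        strata.setdefault(key, []).append(obs)
    if by_study:
        strata = {k: v for k, v in strata.items() if len(v) >= min_groups}
    return strata


def _subset(
    strata: ObsStrataMap,
    keep_group,
    keep_stratum,
    min_groups: int = MIN_GROUPS_PER_STRATUM,
) -> dict[StratumKey, list[GroupObservation]]:
    out: dict[StratumKey, list[GroupObservation]] = {}
    for key, obs_list in strata.items():
        if not keep_stratum(obs_list):
            continue
        kept = [o for o in obs_list if keep_group(o.group)]
        if len(kept) >= min_groups:
            out[key] = kept
    return out


def subset_acute(
    strata: ObsStrataMap, min_groups: int = MIN_GROUPS_PER_STRATUM
) -> dict[StratumKey, list[GroupObservation]]:
    """Restrict to acute (single-fraction) exposures, controls included.

    Strata left with fewer than ``min_groups`` groups are dropped: a
    linear-quadratic model needs at least three points.
    """
    return _subset(
        strata,
        keep_group=lambda g: g.is_acute,
        keep_stratum=lambda obs: True,
        min_groups=min_groups,
    )


def subset_comparison(
    strata: ObsStrataMap, min_groups: int = MIN_GROUPS_PER_STRATUM
) -> dict[StratumKey, list[GroupObservation]]:
    """Restrict to strata holding a direct acute-vs-protracted comparison.

    A stratum qualifies if it contains at least one acute nonzero-dose group
    and at least one protracted (multi-fraction) group; all of a qualifying
    stratum's groups are kept, controls included.
    """

    def qualifies(obs_list: Sequence[GroupObservation]) -> bool:
        has_acute_exposed = any(
            o.group.is_acute and o.group.total_dose > 0 for o in obs_list
        )
        has_protracted = any(not o.group.is_acute for o in obs_list)
        return has_acute_exposed and has_protracted

    return _subset(
        strata,
        keep_group=lambda g: True,
        keep_stratum=qualifies,
        min_groups=min_groups,
    )
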