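"""Seeded generator of BMIS-like submission streams with known ground truth.

No public accession of the registry snapshot exists, so every pipeline
stage is exercised against synthetic dumps whose generating process is
fully known.  The generator emulates the structural features of the real
download that the analysis depends on:

* a mixture of single- and multi-submission investigators (``frac_single``)
* a configurable first-to-second gap-time distribution; the default is a
  lognormal calibrated so its median is ~411 days and its 75th percentile
  ~1013 days, the two documented quantiles of the real gap distribution
* extra (third and beyond) submissions that must never affect results
* a US / non-US country mix (``frac_us``)
* arrivals uniform over a study window, with window-end censoring of
  planned second submissions (the mechanism that inflates apparent
  one-and-done counts in late years)
* invalid-name noise records ("??" / empty last name)
* name collisions between distinct simulated people

Everything is deterministic given the config seed.  Ground truth is
recorded per simulated *person* (not per name key), including the
phenotype each person would receive in an uncensored, collision-free
regime and whether window censoring truncated a planned second submission.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bmis_io import DEFAULT_DIALECT, DumpDialect, SubmissionRecord, filter_window
from .cohort_builder import (
    Location,
    build_histories,
    assign_investigator_ids,
    exclude_invalid_names,
    normalize_name,
)
from .phenotype import Phenotype, classify_cohort, nearest_rank

_Z75 = 0.6744897501960817  # standard normal 75th-percentile quantile

NON_US_COUNTRIES = (
    "CANADA",
    "GERMANY",
    "UNITED KINGDOM",
    "JAPAN",
    "BRAZIL",
    "INDIA",
    "SPAIN",
    "AUSTRALIA",
)


class SyntheticConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GapDistribution:
    """Named distribution of days between first and second submissions."""

    name: str
    params: tuple[float, ...]

    @staticmethod
    def lognormal(median: float = 411.0, p75: float = 1013.0) -> "GapDistribution":
        """Lognormal parameterised by its median and 75th percentile."""
        if not 0 < median < p75:
            raise SyntheticConfigError("need 0 < median < p75")
        mu = math.log(median)
        sigma = math.log(p75 / median) / _Z75
        return GapDistribution("lognormal", (mu, sigma))

    @staticmethod
    def fixed(days: float) -> "GapDistribution":
        if days < 0:
            raise SyntheticConfigError("gap must be nonnegative")
        return GapDistribution("fixed", (float(days),))

    @staticmethod
    def uniform(low: float, high: float) -> "GapDistribution":
        if not 0 <= low <= high:
            raise SyntheticConfigError("need 0 <= low <= high")
        return GapDistribution("uniform", (float(low), float(high)))

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Integer day counts, >= 0."""
        if self.name == "lognormal":
            mu, sigma = self.params
            draws = rng.lognormal(mu, sigma, size)
        elif self.name == "fixed":
            draws = np.full(size, self.params[0])
        elif self.name == "uniform":
            low, high = self.params
            draws = rng.uniform(low, high, size)
        else:
            raise SyntheticConfigError(f"unknown gap distribution {self.name!r}")
        return np.maximum(np.rint(draws), 0).astype(int)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic registry.

    ``arrival_start``/``arrival_end`` (defaulting to the study window)
    bound the uniform first-submission dates; narrowing them while keeping
    ``window_end`` late produces an effectively uncensored cohort for
    validation runs.
    """

    n_investigators: int = 20_000
    frac_single: float = 0.5
    gap_distribution: GapDistribution = field(
        default_factory=GapDistribution.lognormal
    )
    extra_submission_rate: float = 1.0
    frac_us: float = 0.6
    window_start: int = 1999
    window_end: int = 2015
    arrival_start: int | None = None
    arrival_end: int | None = None
    invalid_name_rate: float = 0.01
    name_collision_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_investigators <= 0:
            raise SyntheticConfigError("n_investigators must be positive")
        for name in ("frac_single", "frac_us", "invalid_name_rate", "name_collision_rate"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise SyntheticConfigError(f"{name} must be in [0, 1], got {value}")
        if self.extra_submission_rate < 0:
            raise SyntheticConfigError("extra_submission_rate must be >= 0")
        if self.window_start > self.window_end:
            raise SyntheticConfigError("window_start must be <= window_end")
        if self.arrivals[0] > self.arrivals[1]:
            raise SyntheticConfigError("arrival_start must be <= arrival_end")

    @property
    def arrivals(self) -> tuple[int, int]:
        return (
            self.arrival_start if self.arrival_start is not None else self.window_start,
            self.arrival_end if self.arrival_end is not None else self.window_end,
        )


@dataclass(frozen=True)
class PersonTruth:
    """Ground truth for one simulated person (not one name key)."""

    person_id: int
    last_name: str
    first_name: str
    true_phenotype: Phenotype
    true_location: Location
    first_date: date
    gap_days: int | None
    censored: bool  # planned second submission fell past window_end


@dataclass(frozen=True)
class GroundTruth:
    people: tuple[PersonTruth, ...]
    n_invalid_records: int
    truth_cutoff_days: int | None  # uncensored nearest-rank p75 of drawn gaps


def generate_records(
    config: SyntheticConfig,
) -> tuple[list[SubmissionRecord], GroundTruth]:
    """Draw a synthetic submission stream and its per-person ground truth.

    Record order is a seeded permutation, so file order never encodes
    person identity.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_investigators

    arrival_lo = date(config.arrivals[0], 1, 1)
    arrival_hi = date(config.arrivals[1], 12, 31)
    window_hi = date(config.window_end, 12, 31)
    n_arrival_days = (arrival_hi - arrival_lo).days + 1

    single = rng.random(n) < config.frac_single
    in_us = rng.random(n) < config.frac_us
    first_offsets = rng.integers(0, n_arrival_days, n)

    multi_idx = np.flatnonzero(~single)
    gaps = np.full(n, -1)
    if multi_idx.size:
        gaps[multi_idx] = config.gap_distribution.sample(rng, multi_idx.size)
    truth_cutoff = (
        int(nearest_rank(gaps[multi_idx], 75.0)) if multi_idx.size else None
    )

    # name pool: unique keys, then collide a configured fraction of people
    last_names = [f"LAST{i:06d}" for i in range(n)]
    first_names = [f"FIRST{i:06d}" for i in range(n)]
    n_collide = round(config.name_collision_rate * n)
    if n_collide and n > 1:
        colliders = rng.choice(np.arange(1, n), size=min(n_collide, n - 1), replace=False)
        for i in colliders:
            j = int(rng.integers(0, i))
            last_names[i] = last_names[j]
            first_names[i] = first_names[j]

    countries = np.where(
        in_us, "USA", rng.choice(NON_US_COUNTRIES, n)
    )

    records: list[SubmissionRecord] = []
    people: list[PersonTruth] = []
    doc_counter = 0

    def emit(person: int, when: date) -> None:
        nonlocal doc_counter
        doc_counter += 1
        records.append(
            SubmissionRecord(
                last_name=last_names[person],
                first_name=first_names[person],
                country_name=str(countries[person]),
                receipt_date=when,
                passthrough={"DOCUMENT_ID": f"D{doc_counter:07d}"},
            )
        )

    for i in range(n):
        first_date = arrival_lo + timedelta(days=int(first_offsets[i]))
        emit(i, first_date)
        censored = False
        gap = None
        if single[i]:
            true_phen = Phenotype.ONE_AND_DONE
        else:
            gap = int(gaps[i])
            true_phen = (
                Phenotype.STAYER if gap <= truth_cutoff else Phenotype.STOP_AND_GO
            )
            second_date = first_date + timedelta(days=gap)
            if second_date > window_hi:
                censored = True
            else:
                emit(i, second_date)
                n_extra = int(rng.poisson(config.extra_submission_rate))
                if n_extra:
                    remaining = (window_hi - second_date).days
                    extra_offsets = rng.integers(0, remaining + 1, n_extra)
                    for off in extra_offsets:
                        emit(i, second_date + timedelta(days=int(off)))
        people.append(
            PersonTruth(
                person_id=i,
                last_name=last_names[i],
                first_name=first_names[i],
                true_phenotype=true_phen,
                true_location=Location.US if in_us[i] else Location.NON_US,
                first_date=first_date,
                gap_days=gap,
                censored=censored,
            )
        )

    n_invalid = round(config.invalid_name_rate * len(records))
    for k in range(n_invalid):
        doc_counter += 1
        records.append(
            SubmissionRecord(
                last_name="??" if k % 2 == 0 else "",
                first_name=f"NOISE{k:05d}",
                country_name="USA" if rng.random() < config.frac_us else "UNKNOWN",
                receipt_date=arrival_lo
                + timedelta(days=int(rng.integers(0, n_arrival_days))),
                passthrough={"DOCUMENT_ID": f"D{doc_counter:07d}"},
            )
        )

    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    return records, GroundTruth(
        people=tuple(people),
        n_invalid_records=n_invalid,
        truth_cutoff_days=truth_cutoff,
    )


def write_dump(
    records: Sequence[SubmissionRecord],
    path: str | Path,
    dialect: DumpDialect = DEFAULT_DIALECT,
) -> None:
    """Serialize records in the dump dialect that ``read_bmis`` reads."""
    passthrough_cols = sorted(records[0].passthrough) if records else []
    semantic = {v: k for k, v in dialect.column_map.items()}
    header = list(dialect.column_map.values()) + passthrough_cols
    lines = []
    if dialect.has_header:
        lines.append(dialect.delimiter.join(str(h) for h in header))
    for record in records:
        row = []
        for col in dialect.column_map.values():
            fld = semantic[col]
            value = getattr(record, fld)
            row.append(value.isoformat() if fld == "receipt_date" else value)
        row.extend(record.passthrough.get(c, "") for c in passthrough_cols)
        lines.append(dialect.delimiter.join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding=dialect.encoding)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Ground truth as comma-delimited text, one row per simulated person."""
    frame = pd.DataFrame(
        {
            "person_id": [p.person_id for p in truth.people],
            "last_name": [p.last_name for p in truth.people],
            "first_name": [p.first_name for p in truth.people],
            "true_phenotype": [p.true_phenotype.value for p in truth.people],
            "true_location": [p.true_location.value for p in truth.people],
            "first_date": [p.first_date.isoformat() for p in truth.people],
            "gap_days": [p.gap_days for p in truth.people],
            "censored": [p.censored for p in truth.people],
        }
    )
    frame.to_csv(path, index=False)


def generate_cohort(
    config: SyntheticConfig,
    dump_path: str | Path,
    dialect: DumpDialect = DEFAULT_DIALECT,
) -> GroundTruth:
    """Write a flat-file dump readable by ``bmis_io`` and return ground truth."""
    records, truth = generate_records(config)
    write_dump(records, dump_path, dialect)
    return truth


def censoring_experiment(config: SyntheticConfig, percentile: float = 75.0) -> pd.DataFrame:
    """Quantify window-censoring misclassification by first-submission year.

    Runs the full pipeline on a generated cohort and, for each year, reports
    the fraction of truly multi-submission people the pipeline labels
    one-and-done because their second submission fell past the window end.
    Name collisions are disabled internally: the truth join is by name key.

    Returns a DataFrame with columns ``year``, ``n_multi_true``,
    ``n_misclassified_oad``, ``frac_misclassified``.
    """
    config = replace(config, name_collision_rate=0.0)
    records, truth = generate_records(config)
    filtered = filter_window(records, config.window_start, config.window_end)
    kept, _ = exclude_invalid_names(filtered)
    histories = build_histories(kept, assign_investigator_ids(kept))
    labels, _, _ = classify_cohort(histories, percentile=percentile)
    label_by_key = {
        (normalize_name(h.last_name), normalize_name(h.first_name)): lab
        for h, lab in zip(histories, labels)
    }

    rows = []
    for year in range(config.window_start, config.window_end + 1):
        multi = [
            p
            for p in truth.people
            if p.gap_days is not None and p.first_date.year == year
        ]
        mis = sum(
            1
            for p in multi
            if label_by_key[(normalize_name(p.last_name), normalize_name(p.first_name))]
            is Phenotype.ONE_AND_DONE
        )
        rows.append(
            {
                "year": year,
                "n_multi_true": len(multi),
                "n_misclassified_oad": mis,
                "frac_misclassified": mis / len(multi) if multi else 0.0,
            }
        )
    return pd.DataFrame(rows)
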