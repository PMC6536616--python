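"""Gap-time percentile threshold and investigator phenotype assignment.

The cohort's multi-submission investigators define an empirical
distribution of first-to-second-submission gaps (``secdiff``, in days).
A percentile of that distribution — the 75th by default — is the cutoff
separating continuously engaged investigators ("stayers", gap within the
cutoff) from intermittently engaged ones ("stop-and-go", gap beyond it).
Single-submission investigators are "one-and-done".  The three classes
partition the cohort.

The cutoff uses the nearest-rank percentile (the ceil(p/100·n)-th order
statistic) so it is always an observed gap value; linear interpolation is
available as an option.  "Within" is read as ``secdiff <= cutoff`` so the
two multi-submission classes are exhaustive and mutually exclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .cohort_builder import InvestigatorHistory, Location


class PhenotypeError(RuntimeError):
    """Fatal condition during threshold computation or classification."""


class Phenotype(str, Enum):
    ONE_AND_DONE = "ONE_AND_DONE"
    STOP_AND_GO = "STOP_AND_GO"
    STAYER = "STAYER"


@dataclass(frozen=True)
class ThresholdSpec:
    """The percentile parameter and the cutoff (days) computed from a cohort.

    ``n_gaps`` is the number of multi-submission histories contributing a
    gap value.
    """

    percentile: float
    cutoff_days: float
    n_gaps: int


def nearest_rank(values: Sequence[float], percentile: float) -> float:
    """The ceil(p/100·n)-th order statistic of ``values``."""
    if not 0 < percentile <= 100:
        raise PhenotypeError(f"percentile must be in (0, 100], got {percentile}")
    if len(values) == 0:
        raise PhenotypeError("cannot take a percentile of an empty sample")
    ordered = np.sort(np.asarray(values))
    k = math.ceil(percentile / 100 * len(ordered))
    return float(ordered[k - 1])


def compute_percentile_threshold(
    histories: Sequence[InvestigatorHistory],
    percentile: float = 75.0,
    method: str = "nearest_rank",
) -> ThresholdSpec:
    """Compute the gap-time cutoff from a cohort's secdiff distribution.

    ``method`` is ``"nearest_rank"`` (default; cutoff is an observed gap)
    or ``"linear"`` (numpy's linear-interpolation percentile).  Fatal if no
    history has a second submission.
    """
    gaps = [h.secdiff for h in histories if h.secdiff is not None]
    if not gaps:
        raise PhenotypeError(
            "no multi-submission investigators: the gap-time percentile "
            "is undefined for this cohort"
        )
    if not 0 < percentile <= 100:
        raise PhenotypeError(f"percentile must be in (0, 100], got {percentile}")
    if method == "nearest_rank":
        cutoff = nearest_rank(gaps, percentile)
    elif method == "linear":
        cutoff = float(np.percentile(gaps, percentile))
    else:
        raise PhenotypeError(f"unknown percentile method {method!r}")
    return ThresholdSpec(percentile=percentile, cutoff_days=cutoff, n_gaps=len(gaps))


def classify_investigator(
    history: InvestigatorHistory, threshold: ThresholdSpec
) -> Phenotype:
    """One-and-done if a single submission; otherwise stayer iff the gap is
    within (<=) the cutoff, stop-and-go beyond it."""
    if history.oad:
        return Phenotype.ONE_AND_DONE
    secdiff = history.secdiff
    if secdiff is None:  # unreachable for a well-formed history
        raise PhenotypeError(f"history {history.newid} has no oad and no secdiff")
    return Phenotype.STAYER if secdiff <= threshold.cutoff_days else Phenotype.STOP_AND_GO


def classify_cohort(
    histories: Sequence[InvestigatorHistory],
    percentile: float = 75.0,
    fixed_cutoff_days: float | None = None,
    method: str = "nearest_rank",
) -> tuple[list[Phenotype], dict[tuple[Phenotype, Location], int], ThresholdSpec | None]:
    """Label every investigator and tally counts by phenotype and location.

    The cutoff is recomputed from this cohort unless ``fixed_cutoff_days``
    is given (e.g. 1013 to replicate a published classification on new
    data).  A cohort with no multi-submission investigators is labeled all
    one-and-done without computing a threshold; the returned threshold is
    then None.
    """
    if not histories:
        raise PhenotypeError("cannot classify an empty cohort")
    if fixed_cutoff_days is not None:
        threshold = ThresholdSpec(
            percentile=percentile,
            cutoff_days=float(fixed_cutoff_days),
            n_gaps=sum(1 for h in histories if h.secdiff is not None),
        )
    elif all(h.oad for h in histories):
        threshold = None
    else:
        threshold = compute_percentile_threshold(histories, percentile, method)

    labels = [
        Phenotype.ONE_AND_DONE
        if threshold is None
        else classify_investigator(h, threshold)
        for h in histories
    ]
    counts: dict[tuple[Phenotype, Location], int] = {
        (p, loc): 0 for p in Phenotype for loc in Location
    }
    for history, label in zip(histories, labels):
        counts[(label, history.location)] += 1
    return labels, counts, threshold
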