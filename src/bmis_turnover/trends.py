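"""Annual trend tables and summary reporting for a labeled cohort.

Each investigator is counted exactly once, in the year of their first
submission (firsub) — the date they are "plotted" at.  The trend table is
a long-format year × phenotype × location table of counts with two share
columns:

* ``share_of_year`` — the cell's fraction of that year's new investigators
* ``share_of_phenotype_year`` — the location split within a (year,
  phenotype) cell (US share + non-US share = 1 where the cell is nonempty)

Printed percentages follow registry-report convention: 100·num/den rounded
half-up to one decimal place.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

from .cohort_builder import InvestigatorHistory, Location
from .phenotype import Phenotype, ThresholdSpec

PHENOTYPE_ORDER = (Phenotype.ONE_AND_DONE, Phenotype.STOP_AND_GO, Phenotype.STAYER)
LOCATION_ORDER = (Location.US, Location.NON_US)


class TrendsError(RuntimeError):
    pass


def proportion(numerator: int, denominator: int) -> float:
    """100·numerator/denominator, rounded half-up to one decimal place."""
    if denominator <= 0:
        raise TrendsError(f"denominator must be positive, got {denominator}")
    exact = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def annual_counts(
    histories: Sequence[InvestigatorHistory],
    labels: Sequence[Phenotype],
    window: tuple[int, int],
) -> pd.DataFrame:
    """Long-format trend table over year × phenotype × location.

    Every window year appears even when empty.  An investigator whose
    firsub year falls outside the window violates the pipeline contract
    (the window filter runs upstream) and is fatal.
    """
    start_year, end_year = window
    if start_year > end_year:
        raise TrendsError(f"invalid window: {start_year} > {end_year}")
    if len(histories) != len(labels):
        raise TrendsError("histories and labels must align one-to-one")
    for hist in histories:
        if not start_year <= hist.firsub.year <= end_year:
            raise TrendsError(
                f"investigator {hist.newid} has firsub {hist.firsub} "
                f"outside window {start_year}-{end_year}"
            )

    index = pd.MultiIndex.from_product(
        [
            range(start_year, end_year + 1),
            [p.value for p in PHENOTYPE_ORDER],
            [loc.value for loc in LOCATION_ORDER],
        ],
        names=["year", "phenotype", "location"],
    )
    counts = pd.Series(0, index=index, name="count")
    for hist, label in zip(histories, labels):
        counts.loc[(hist.firsub.year, label.value, hist.location.value)] += 1

    table = counts.reset_index()
    year_totals = table.groupby("year")["count"].transform("sum")
    cell_totals = table.groupby(["year", "phenotype"])["count"].transform("sum")
    table["share_of_year"] = (table["count"] / year_totals).fillna(0.0)
    table["share_of_phenotype_year"] = (table["count"] / cell_totals).fillna(0.0)
    return table


def summary_report(
    histories: Sequence[InvestigatorHistory],
    labels: Sequence[Phenotype],
    threshold: ThresholdSpec | None = None,
) -> dict:
    """Structured cohort summary with deterministic field order.

    Totals, phenotype counts with one-decimal percentages, per-year
    per-phenotype US/non-US counts and shares, and the threshold used.
    """
    if len(histories) != len(labels):
        raise TrendsError("histories and labels must align one-to-one")
    n = len(histories)
    report: dict = {"n_investigators": n}
    report["threshold"] = (
        None
        if threshold is None
        else {
            "percentile": threshold.percentile,
            "cutoff_days": threshold.cutoff_days,
            "n_gaps": threshold.n_gaps,
        }
    )

    by_class = {p: 0 for p in PHENOTYPE_ORDER}
    for label in labels:
        by_class[label] += 1
    report["phenotypes"] = {
        p.value: {"count": by_class[p], "pct": proportion(by_class[p], n) if n else 0.0}
        for p in PHENOTYPE_ORDER
    }

    years: dict[int, dict[str, dict[str, int]]] = {}
    for hist, label in zip(histories, labels):
        cell = (
            years.setdefault(hist.firsub.year, {})
            .setdefault(label.value, {"US": 0, "NON_US": 0})
        )
        cell[hist.location.value] += 1
    report["by_year"] = {}
    for year in sorted(years):
        report["by_year"][year] = {}
        for p in PHENOTYPE_ORDER:
            cell = years[year].get(p.value)
            if cell is None:
                continue
            total = cell["US"] + cell["NON_US"]
            report["by_year"][year][p.value] = {
                "US": cell["US"],
                "NON_US": cell["NON_US"],
                "US_pct": proportion(cell["US"], total),
                "NON_US_pct": proportion(cell["NON_US"], total),
            }
    return report


def plot_trends(table: pd.DataFrame, path=None):
    """Line chart of yearly counts per phenotype (convenience output).

    Requires matplotlib; returns the figure, optionally saving to ``path``.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    yearly = table.groupby(["year", "phenotype"])["count"].sum().unstack("phenotype")
    for p in PHENOTYPE_ORDER:
        if p.value in yearly:
            ax.plot(yearly.index, yearly[p.value], marker="o", label=p.value)
    ax.plot(
        yearly.index, yearly.sum(axis=1), color="black", linestyle="--", label="ALL"
    )
    ax.set_xlabel("first-submission year")
    ax.set_ylabel("new investigators")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
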