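"""Record-inclusion and outlier filters.

Museum record sets are heterogeneous: species differ wildly in how many
specimens were collected and when. Three filters clean a record table for
trend analysis:

* :class:`InclusionFilter` — keep species with more than ``min_records``
  sexed, geo-referenced records whose collection years span at least
  ``min_span_decades`` decades;
* :class:`ConcentrationFilter` — drop species whose records are almost all
  (> ``frac``) crammed into a single short window of years, where a
  "trend" would really be a between-era contrast;
* :class:`MassOutlierFilter` — drop physically implausible near-zero
  masses (data-entry artefacts, neonates), operationalized as a fraction
  of the species median.

Each filter is a transformer: ``transform(records)`` returns the filtered
:class:`~endotrend.records.RecordTable` and leaves a
:class:`FilterReport` in ``report_``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .records import RecordTable


@dataclass
class FilterReport:
    """What a filter removed and why."""

    rule: str
    n_records_in: int = 0
    n_records_out: int = 0
    removed_species: dict = field(default_factory=dict)  # species -> reason
    removed_records: int = 0

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "n_records_in": self.n_records_in,
            "n_records_out": self.n_records_out,
            "removed_records": self.removed_records,
            "removed_species": dict(self.removed_species),
        }


class _RecordFilter(BaseEstimator):
    """Base for stateless record filters with a fit/transform surface."""

    def fit(self, records: RecordTable, y=None):  # noqa: ARG002 - sklearn API
        return self

    def fit_transform(self, records: RecordTable, y=None) -> RecordTable:  # noqa: ARG002
        return self.transform(records)

    def transform(self, records: RecordTable) -> RecordTable:
        raise NotImplementedError


class InclusionFilter(_RecordFilter):
    """Keep species with > ``min_records`` records spanning >= ``min_span_decades`` decades.

    The record-count rule is strict (a species with exactly ``min_records``
    is excluded) and the span rule is length-based: last year minus first
    year must reach ``10 * min_span_decades``.
    """

    def __init__(self, min_records: int = 100, min_span_decades: int = 4):
        self.min_records = min_records
        self.min_span_decades = min_span_decades

    def transform(self, records: RecordTable) -> RecordTable:
        df = records.df
        report = FilterReport("inclusion", n_records_in=len(df))
        keep = []
        for sp, years in df.groupby("species_id")["year"]:
            if len(years) <= self.min_records:
                report.removed_species[sp] = (
                    f"n_records {len(years)} <= {self.min_records}")
            elif years.max() - years.min() < 10 * self.min_span_decades:
                report.removed_species[sp] = (
                    f"series_length {years.max() - years.min()} "
                    f"< {10 * self.min_span_decades} years")
            else:
                keep.append(sp)
        out = records.subset(df["species_id"].isin(keep))
        report.n_records_out = len(out)
        report.removed_records = report.n_records_in - report.n_records_out
        out.log("inclusion", removed_species=len(report.removed_species),
                removed_records=report.removed_records)
        self.report_ = report
        return out


class ConcentrationFilter(_RecordFilter):
    """Drop species with > ``frac`` of records inside any ``window``-year window.

    Windows are anchored at each observed collection year ``y`` and cover
    ``[y, y + window)``; a species fails if any window holds strictly more
    than ``frac`` of its records.
    """

    def __init__(self, frac: float = 0.80, window: int = 10):
        self.frac = frac
        self.window = window

    def _concentrated(self, years: np.ndarray) -> bool:
        years = np.sort(years)
        n = len(years)
        for y0 in np.unique(years):
            inside = np.count_nonzero((years >= y0) & (years < y0 + self.window))
            if inside > self.frac * n:
                return True
        return False

    def transform(self, records: RecordTable) -> RecordTable:
        df = records.df
        report = FilterReport("concentration", n_records_in=len(df))
        keep = []
        for sp, years in df.groupby("species_id")["year"]:
            if self._concentrated(years.to_numpy()):
                report.removed_species[sp] = (
                    f"> {self.frac:.0%} of records within {self.window} years")
            else:
                keep.append(sp)
        out = records.subset(df["species_id"].isin(keep))
        report.n_records_out = len(out)
        report.removed_records = report.n_records_in - report.n_records_out
        out.log("concentration", removed_species=len(report.removed_species),
                removed_records=report.removed_records)
        self.report_ = report
        return out


class MassOutlierFilter(_RecordFilter):
    """Drop non-positive masses and masses <= ``rel_threshold`` x species median."""

    def __init__(self, rel_threshold: float = 0.01):
        self.rel_threshold = rel_threshold

    def transform(self, records: RecordTable) -> RecordTable:
        df = records.df
        report = FilterReport("mass_outliers", n_records_in=len(df))
        med = df.groupby("species_id")["mass"].transform("median")
        bad = (df["mass"] <= 0) | (df["mass"] <= self.rel_threshold * med)
        out = records.subset(~bad)
        report.n_records_out = len(out)
        report.removed_records = int(bad.sum())
        out.log("mass_outliers", removed_records=report.removed_records)
        self.report_ = report
        return out


# ---------------------------------------------------------------------------
# thin functional wrappers

def apply_inclusion_criteria(records: RecordTable, min_records: int = 100,
                             min_span_decades: int = 4):
    f = InclusionFilter(min_records, min_span_decades)
    out = f.transform(records)
    return out, f.report_


def exclude_concentrated_series(records: RecordTable, frac: float = 0.80,
                                window: int = 10):
    f = ConcentrationFilter(frac, window)
    out = f.transform(records)
    return out, f.report_


def remove_mass_outliers(records: RecordTable, rel_threshold: float = 0.01):
    f = MassOutlierFilter(rel_threshold)
    out = f.transform(records)
    return out, f.report_


def apply_filter_chain(records: RecordTable, min_records: int = 100,
                       min_span_decades: int = 4, frac: float = 0.80,
                       window: int = 10, rel_threshold: float = 0.01):
    """Inclusion -> concentration -> outliers; returns (table, [reports])."""
    reports = []
    for f in (InclusionFilter(min_records, min_span_decades),
              ConcentrationFilter(frac, window),
              MassOutlierFilter(rel_threshold)):
        records = f.transform(records)
        reports.append(f.report_)
    return records, reports
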