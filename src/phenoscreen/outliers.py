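"""Gross-outlier screen for phenological date series.

For every (study site, taxon-or-climatic name, event type) series the
screen fits a von Mises distribution to the dates on the annual circle
and flags the records that fall outside the central interval holding
probability mass ``p`` of the fitted distribution.  The default mass is
the two-sided Gaussian four-sigma level, 2*Phi(4) - 1 = 0.9999367, so on
a well-behaved series roughly one date in sixteen thousand is flagged by
chance.

The screen is single-pass: the fit always uses all points of the series,
including the suspects, and there is no iterative re-fitting after
flagging.  Flagged records are for human review, not automatic removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .circular import (
    CircularSample,
    VonMisesFit,
    circ_dist_days,
    vm_central_halfwidth,
    vm_fit,
)
from .io import QUALITY_OUTLIER, Database

__all__ = [
    "DEFAULT_MIN_N",
    "OutlierReport",
    "gaussian_central_mass",
    "default_mass",
    "screen_series",
    "screen_database",
    "outlier_report_frame",
]

DEFAULT_MIN_N = 10


def gaussian_central_mass(z: float) -> float:
    """Two-sided standard-normal central mass 2*Phi(z) - 1 for z >= 0."""
    if z < 0:
        raise ValueError(f"z must be non-negative, got {z}")
    return float(2.0 * norm.cdf(z) - 1.0)


def default_mass(z: float = 4.0, decimals: int = 7) -> float:
    """The screen's default interval mass: the Gaussian ``z``-sigma
    central mass rounded to ``decimals`` places (0.9999367 for z = 4)."""
    return round(gaussian_central_mass(z), decimals)


@dataclass(frozen=True)
class OutlierReport:
    """Outcome of the outlier screen on one series.

    ``flagged`` pairs each offending record's positional index (into the
    series as given) with its circular deviation in days from the fitted
    mean direction; every listed deviation exceeds ``halfwidth_days``.
    Series shorter than the configured minimum are skipped
    (``skipped=True``) with no fit and no flags.
    """

    series_key: tuple
    n: int
    fit: VonMisesFit | None
    halfwidth_days: float | None
    flagged: list[tuple[int, float]] = field(default_factory=list)
    skipped: bool = False


def screen_series(sample: CircularSample, p: float | None = None,
                  min_n: int = DEFAULT_MIN_N,
                  series_key: tuple = ()) -> OutlierReport:
    """Screen one date series for gross outliers.

    Fits the von Mises MLE on the full series, computes the central
    interval of mass ``p`` (default :func:`default_mass`), and flags
    records whose circular distance from the fitted mean exceeds the
    interval half-width converted to days.
    """
    if p is None:
        p = default_mass()
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    n = len(sample)
    if n < min_n:
        return OutlierReport(series_key=series_key, n=n, fit=None,
                             halfwidth_days=None, skipped=True)
    fit = vm_fit(sample)
    halfwidth_days = vm_central_halfwidth(fit.kappa, p) * sample.period / (2.0 * np.pi)
    mean_day = fit.mean_day(sample.period)
    dev = circ_dist_days(sample.days, mean_day, sample.period)
    idx = np.flatnonzero(dev > halfwidth_days)
    flagged = [(int(i), float(dev[i])) for i in idx]
    return OutlierReport(series_key=series_key, n=n, fit=fit,
                         halfwidth_days=float(halfwidth_days), flagged=flagged)


def _series_groups(db: Database):
    """Iterate (key, positional row indices) over (site, name, event) triplets
    of clean records (empty quality); previously flagged records take no part."""
    rec = db.records
    doy = rec["dayofyear"]
    usable = (rec["quality"].fillna("") == "") & doy.notna()
    sub = rec.loc[usable]
    pos = pd.Series(np.flatnonzero(usable.to_numpy()), index=sub.index)
    for key, grp in sub.groupby(["studysite", "taxon", "eventtype"], sort=True):
        yield tuple(key), pos.loc[grp.index].to_numpy()


def screen_database(db: Database, p: float | None = None,
                    min_n: int = DEFAULT_MIN_N,
                    period: float = 365.25) -> tuple[list[OutlierReport], Database]:
    """Run the outlier screen on every triplet series of a database.

    Returns the per-series reports and a copy of the database whose
    flagged records carry the ``suspicious_outlier`` quality token; the
    input database is untouched.  Records already carrying a quality flag
    are excluded from fitting and never re-flagged.
    """
    reports: list[OutlierReport] = []
    flagged_db = db.copy()
    quality = flagged_db.records["quality"].fillna("").copy()
    days_all = db.records["dayofyear"].to_numpy(dtype=float, na_value=np.nan)
    for key, rows in _series_groups(db):
        sample = CircularSample(days_all[rows], period=period)
        report = screen_series(sample, p=p, min_n=min_n, series_key=key)
        if report.flagged:
            report = OutlierReport(
                series_key=report.series_key, n=report.n, fit=report.fit,
                halfwidth_days=report.halfwidth_days,
                flagged=[(int(rows[i]), dev) for i, dev in report.flagged],
                skipped=False)
            for i, _ in report.flagged:
                quality.iloc[i] = QUALITY_OUTLIER
        reports.append(report)
    flagged_db.records["quality"] = quality
    return reports, flagged_db


def outlier_report_frame(reports: list[OutlierReport],
                         period: float = 365.25) -> pd.DataFrame:
    """Tabulate reports: one row per flagged record, plus one row per
    clean or skipped series (with empty record columns) so every screened
    series is accounted for."""
    rows = []
    for r in reports:
        base = {
            "studysite": r.series_key[0] if r.series_key else "",
            "name": r.series_key[1] if len(r.series_key) > 1 else "",
            "eventtype": r.series_key[2] if len(r.series_key) > 2 else "",
            "n": r.n,
            "mu_day": r.fit.mean_day(period) if r.fit else np.nan,
            "kappa": r.fit.kappa if r.fit else np.nan,
            "halfwidth_days": r.halfwidth_days if r.halfwidth_days is not None else np.nan,
            "skipped": r.skipped,
        }
        if r.flagged:
            for idx, dev in r.flagged:
                rows.append(base | {"record_row": idx, "deviation_days": dev})
        else:
            rows.append(base | {"record_row": pd.NA, "deviation_days": np.nan})
    return pd.DataFrame(rows)
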