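"""Synthetic six-table phenological databases with known ground truth.

The generator emulates the statistical structure of a multi-site,
multi-taxon phenological archive: each (site, taxon, event type) series
has one dated record per year, with the day of year built from

    day = baseline + geographic trend(lat, lon) + site effect
          + taxon effect + year effect + noise,

rounded to an integer and wrapped into [1, 365].  Site, taxon and year
effects and the noise are independent Gaussians on the linear day scale
— appropriate for within-season events far from the year boundary, which
is the regime the variance partitioning assumes.  An optional wrap mode
shifts the baseline onto the year boundary to stress-test the circular
screens.

Two kinds of contamination can be injected, each labelled in the
returned ground truth so screen performance is measurable:

* gross outliers — a record is replaced by a uniform date at least
  ``outlier_min_shift_days`` (default 90) from its series' seasonal
  mean, emulating transcription errors;
* bimodal label confusion — a fraction of series draw each record from a
  second seasonal mode ``bimodal_separation_days`` later with
  probability ``bimodal_weight``, emulating one event name covering two
  seasonal events (spring vs autumn).

Year effects are shared across sites and taxa within a year (common
weather); in the variance partition they load onto the residual.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .io import Database, QUALITY_OUTLIER

__all__ = ["SyntheticConfig", "GroundTruth", "generate", "truth_metrics"]

_DAYS_IN_YEAR = 365


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults describe a mid-sized boreal network.

    Sizes (25 sites x 40 taxa x 20 years = 20,000 records by default)
    and effect scales (site 8 d, species 10 d, year 3 d, noise 5 d;
    about -2 d per degree latitude northwards-is-later reversed sign,
    see ``beta_lat``) are of the order seen in continental phenological
    archives.  Contamination rates default to zero: a clean database.
    """

    n_sites: int = 25
    n_taxa: int = 40
    n_years: int = 20
    events_per_series: int = 1           # distinct event types per (site, taxon)
    lat_range: tuple[float, float] = (45.0, 70.0)
    lon_range: tuple[float, float] = (20.0, 60.0)
    baseline_day: float = 160.0
    beta_lat: float = 2.0                # days per degree latitude
    beta_lon: float = 0.0                # days per degree longitude
    beta_int: float = 0.0                # days per degree^2 (lat x lon)
    sigma_site: float = 8.0
    sigma_species: float = 10.0
    sigma_year: float = 3.0
    sigma_noise: float = 5.0
    outlier_rate: float = 0.0
    outlier_min_shift_days: float = 90.0
    bimodal_series_rate: float = 0.0
    bimodal_separation_days: float = 180.0
    bimodal_weight: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for f in ("sigma_site", "sigma_species", "sigma_year", "sigma_noise"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        for f in ("outlier_rate", "bimodal_series_rate", "bimodal_weight"):
            if not 0.0 <= getattr(self, f) <= 1.0:
                raise ValueError(f"{f} must be in [0, 1]")
        if min(self.n_sites, self.n_taxa, self.n_years,
               self.events_per_series) < 1:
            raise ValueError("config implies an empty database")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SyntheticConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kw = dict(mapping)
        for k in ("lat_range", "lon_range"):
            if k in kw:
                kw[k] = tuple(kw[k])
        return cls(**kw)


@dataclass
class GroundTruth:
    """Labels and implied truth for one generated database.

    ``records`` is row-aligned with the database's phenology table and
    carries ``is_outlier`` / ``is_second_mode`` per record; ``series``
    has one row per (studysite, taxon, eventtype) with ``is_bimodal``.
    ``true_fractions`` are the variance shares implied by the
    configuration (using the realized geographic trend variance across
    the generated sites), with the year effect counted into the
    residual as the partition itself would see it.
    """

    records: pd.DataFrame
    series: pd.DataFrame
    true_fractions: dict[str, float]
    config: SyntheticConfig


def _wrap_day(day: np.ndarray) -> np.ndarray:
    return ((np.round(day).astype(int) - 1) % _DAYS_IN_YEAR) + 1


def _standardized_effect(rng: np.random.Generator, sigma: float,
                         size: int) -> np.ndarray:
    """Gaussian effect vector rescaled to realized mean 0 and SD ``sigma``."""
    z = rng.normal(0.0, 1.0, size)
    if sigma == 0.0 or size < 2 or np.std(z) == 0.0:
        return np.zeros(size)
    return sigma * (z - z.mean()) / z.std()


def generate(config: SyntheticConfig,
             seed: int | None = None) -> tuple[Database, GroundTruth]:
    """Generate one database plus its ground truth.

    ``seed`` overrides ``config.seed`` when given.  The same seed and
    configuration always produce identical tables.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    sites = pd.DataFrame({
        "studysite": [f"Site_{i + 1:03d}" for i in range(cfg.n_sites)],
        "latitude": np.round(rng.uniform(*cfg.lat_range, cfg.n_sites), 4),
        "longitude": np.round(rng.uniform(*cfg.lon_range, cfg.n_sites), 4),
    })

    kingdoms = np.where(np.arange(cfg.n_taxa) % 2 == 0, "Plantae", "Animalia")
    classes = np.where(kingdoms == "Plantae", "Magnoliopsida", "Aves")
    taxa = pd.DataFrame({
        "taxonidentifier": [f"TX{i + 1:04d}" for i in range(cfg.n_taxa)],
        "taxon": [f"Genus species{i + 1}" for i in range(cfg.n_taxa)],
        "taxonomiclevel": "Species",
        "kingdom": kingdoms,
        "phylum": np.where(kingdoms == "Plantae", "Tracheophyta", "Chordata"),
        "class": classes,
        "order": "", "family": "", "genus": "Genus",
        "species": [f"species{i + 1}" for i in range(cfg.n_taxa)],
        "gbifkey": "", "gbifstatus": "",
    })

    event_names = [f"event_{k + 1}" for k in range(cfg.events_per_series)]
    phenoevents = pd.DataFrame(
        [{"kingdom": k, "eventtype": e,
          "description": f"synthetic phenological event {e}", "bbch": ""}
         for e in event_names for k in ("Plantae", "Animalia")])
    climevents = pd.DataFrame(
        [{"group": "temperature", "eventtype": "first frost",
          "description": "synthetic climatic event definition"}])
    sources = pd.DataFrame(
        [{"project": "synthetic", "source": "generator",
          "reference": "phenoscreen synthetic database"}])

    # Effects are standardized draws: each vector is rescaled so its
    # realized mean is 0 and realized SD exactly the configured sigma.
    # The implied variance fractions are then properties of every
    # generated database, not just of the ensemble average.
    u_site = _standardized_effect(rng, cfg.sigma_site, cfg.n_sites)
    v_taxon = _standardized_effect(rng, cfg.sigma_species, cfg.n_taxa)
    w_year = _standardized_effect(rng, cfg.sigma_year, cfg.n_years)
    years = np.arange(cfg.n_years) + 1990

    lat = sites["latitude"].to_numpy()
    lon = sites["longitude"].to_numpy()
    geo = (cfg.beta_lat * lat + cfg.beta_lon * lon
           + cfg.beta_int * lat * lon)

    # full crossing: site x taxon x event x year, one record each
    si, ti, ei, yi = np.meshgrid(np.arange(cfg.n_sites), np.arange(cfg.n_taxa),
                                 np.arange(cfg.events_per_series),
                                 np.arange(cfg.n_years), indexing="ij")
    si, ti, ei, yi = (a.ravel() for a in (si, ti, ei, yi))
    n = si.size
    eps = rng.normal(0.0, cfg.sigma_noise, n)
    series_mean = cfg.baseline_day + geo[si] + u_site[si] + v_taxon[ti]
    day = series_mean + w_year[yi] + eps

    # bimodal label confusion: whole series are affected
    n_series = cfg.n_sites * cfg.n_taxa * cfg.events_per_series
    series_id = (si * cfg.n_taxa + ti) * cfg.events_per_series + ei
    bimodal_series = rng.random(n_series) < cfg.bimodal_series_rate
    is_second = bimodal_series[series_id] & (rng.random(n) < cfg.bimodal_weight)
    day = np.where(is_second, day + cfg.bimodal_separation_days, day)

    dayofyear = _wrap_day(day)

    # gross outliers: uniform replacement far from the series seasonal mean
    is_outlier = rng.random(n) < cfg.outlier_rate
    if is_outlier.any():
        if cfg.outlier_min_shift_days >= _DAYS_IN_YEAR / 2:
            raise ValueError("outlier_min_shift_days must be < half a year")
        idx = np.flatnonzero(is_outlier)
        centre = _wrap_day(series_mean[idx])
        # uniform over the arc at least min_shift from the series mean
        arc = _DAYS_IN_YEAR - 2.0 * cfg.outlier_min_shift_days
        offset = cfg.outlier_min_shift_days + rng.uniform(0.0, arc, idx.size)
        dayofyear[idx] = _wrap_day(centre + offset)
        is_second = is_second & ~is_outlier

    records = pd.DataFrame({
        "project": "synthetic",
        "dataset": "synthetic",
        "studysite": sites["studysite"].to_numpy()[si],
        "taxonidentifier": taxa["taxonidentifier"].to_numpy()[ti],
        "taxon": taxa["taxon"].to_numpy()[ti],
        "eventtype": np.asarray(event_names)[ei],
        "year": pd.array(years[yi], dtype="Int64"),
        "dayofyear": pd.array(dayofyear, dtype="Int64"),
        "quality": "",
    })

    db = Database(records=records, sites=sites, taxa=taxa,
                  phenoevents=phenoevents, climevents=climevents,
                  sources=sources)

    truth_records = pd.DataFrame({
        "is_outlier": is_outlier,
        "is_second_mode": is_second,
    })
    series_df = (records.assign(series=series_id)
                 .drop_duplicates("series")
                 .loc[:, ["studysite", "taxon", "eventtype", "series"]])
    series_df["is_bimodal"] = bimodal_series[series_df.pop("series").to_numpy()]

    var_geo = float(np.var(geo))          # realized across the generated sites
    var_site = var_geo + cfg.sigma_site**2
    var_species = cfg.sigma_species**2
    var_resid = cfg.sigma_year**2 + cfg.sigma_noise**2
    total = var_site + var_species + var_resid
    if total > 0:
        true_fractions = {
            "frac_site": var_site / total,
            "frac_geo_within_site": (var_geo / var_site if var_site > 0
                                     else float("nan")),
            "frac_species": var_species / total,
            "frac_residual": var_resid / total,
        }
    else:  # a constant database has no variance to partition
        true_fractions = dict.fromkeys(
            ("frac_site", "frac_geo_within_site", "frac_species",
             "frac_residual"), float("nan"))
    truth = GroundTruth(records=truth_records,
                        series=series_df.reset_index(drop=True),
                        true_fractions=true_fractions, config=cfg)
    return db, truth


def truth_metrics(flagged_db: Database, truth: GroundTruth,
                  bimodality_reports=None) -> pd.DataFrame:
    """Confusion counts of the screens against the generator's labels.

    Record-level rows compare the ``suspicious_outlier`` quality flags in
    ``flagged_db`` with ``truth.records.is_outlier``; when
    ``bimodality_reports`` (triplet-level) are given, a series-level row
    compares their flags with ``truth.series.is_bimodal``.  Sensitivity
    is NaN when there is no contamination to detect.
    """
    if len(flagged_db.records) != len(truth.records):
        raise ValueError("database and ground truth describe different data")
    rows = []
    pred = (flagged_db.records["quality"].fillna("") == QUALITY_OUTLIER).to_numpy()
    actual = truth.records["is_outlier"].to_numpy()
    rows.append(_confusion("outlier_records", pred, actual))
    if bimodality_reports is not None:
        key_cols = ["studysite", "taxon", "eventtype"]
        pred_map = {tuple(r.key): bool(r.flagged) for r in bimodality_reports}
        keys = [tuple(t) for t in truth.series[key_cols].itertuples(index=False)]
        pred_s = np.array([pred_map.get(k, False) for k in keys])
        rows.append(_confusion("bimodal_series",
                               pred_s, truth.series["is_bimodal"].to_numpy()))
    return pd.DataFrame(rows)


def _confusion(level: str, pred: np.ndarray, actual: np.ndarray) -> dict:
    tp = int(np.sum(pred & actual))
    fp = int(np.sum(pred & ~actual))
    fn = int(np.sum(~pred & actual))
    tn = int(np.sum(~pred & ~actual))
    return {
        "level": level, "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "sensitivity": tp / (tp + fn) if (tp + fn) else float("nan"),
        "specificity": tn / (tn + fp) if (tn + fp) else float("nan"),
    }
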