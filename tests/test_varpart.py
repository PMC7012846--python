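"""Variance partitioning: group selection, site means, the decomposition."""

import numpy as np
import pandas as pd
import pytest

from phenoscreen import (
    SyntheticConfig,
    generate,
    partition_database,
    partition_group,
    select_groups,
    site_mean_dates,
    summarize_events,
)

from conftest import make_database


def frame(records):
    return pd.DataFrame(records)


class TestGroupSelection:
    def test_threshold_is_inclusive(self):
        def db_with(n):
            return make_database([
                {"studysite": "A", "taxonidentifier": "T1", "taxon": "t",
                 "eventtype": "e", "year": 2000, "dayofyear": 100}
                for _ in range(n)])
        assert select_groups(db_with(999), min_records=1000) == []
        assert select_groups(db_with(1000), min_records=1000) == [
            ("Magnoliopsida", "e")]

    def test_empty_database(self, tiny_db):
        tiny_db.records = tiny_db.records.iloc[:0]
        assert select_groups(tiny_db) == []

    def test_counts_agree_with_summaries(self, clean_generated):
        db, _ = clean_generated
        n_by_group = {(s.group, s.eventtype): s.N for s in summarize_events(db)}
        for g in select_groups(db, min_records=500):
            assert n_by_group[g] >= 500


class TestSiteMeans:
    def test_two_records_average(self):
        rec = frame([{"studysite": "A", "dayofyear": 100.0},
                     {"studysite": "A", "dayofyear": 120.0},
                     {"studysite": "B", "dayofyear": 50.0}])
        means = site_mean_dates(rec)
        assert means["A"] == 110.0
        assert means["B"] == 50.0

    def test_brute_force_on_generated(self, clean_generated):
        db, _ = clean_generated
        rec = db.records.assign(dayofyear=db.records["dayofyear"].astype(float))
        means = site_mean_dates(rec)
        for site in rec["studysite"].unique()[:5]:
            days = [r.dayofyear for r in rec.itertuples() if r.studysite == site]
            assert means[site] == pytest.approx(sum(days) / len(days))


class TestPartitionGroup:
    def _sites(self, names):
        return pd.DataFrame({"studysite": list(names),
                             "latitude": 50.0 + np.arange(len(names)),
                             "longitude": 30.0 + np.arange(len(names))})

    def test_pure_site_structure(self):
        # every record equals its site mean; two taxa so the species axis
        # is non-degenerate but contributes nothing
        rec = frame([
            {"studysite": "A", "taxonidentifier": "T1", "dayofyear": 100.0},
            {"studysite": "A", "taxonidentifier": "T2", "dayofyear": 100.0},
            {"studysite": "B", "taxonidentifier": "T1", "dayofyear": 140.0},
            {"studysite": "B", "taxonidentifier": "T2", "dayofyear": 140.0},
        ])
        p = partition_group(rec, self._sites("AB"))
        assert p.frac_site == pytest.approx(1.0)
        assert p.frac_species == pytest.approx(0.0, abs=1e-12)
        assert p.frac_residual == pytest.approx(0.0, abs=1e-12)

    def test_shift_invariance(self, clean_generated):
        db, _ = clean_generated
        rec = db.records.assign(dayofyear=db.records["dayofyear"].astype(float))
        base = partition_group(rec, db.sites)
        shifted = partition_group(rec.assign(dayofyear=rec["dayofyear"] + 57.0),
                                  db.sites)
        for fld in ("frac_site", "frac_species", "frac_residual",
                    "frac_geo_within_site"):
            assert getattr(shifted, fld) == pytest.approx(getattr(base, fld),
                                                          abs=1e-9)

    def test_additivity_to_1e9(self, clean_generated):
        db, _ = clean_generated
        rec = db.records.assign(dayofyear=db.records["dayofyear"].astype(float))
        p = partition_group(rec, db.sites)
        assert p.frac_site + p.frac_species + p.frac_residual == pytest.approx(
            1.0, abs=1e-9)
        assert 0 <= p.frac_site <= 1 and 0 <= p.frac_species <= 1

    def test_pure_latitude_trend_geo_r2_near_one(self):
        # baseline + trend kept inside the year so no dates wrap
        cfg = SyntheticConfig(n_sites=40, n_taxa=10, n_years=5,
                              sigma_site=0.0, sigma_species=6.0,
                              sigma_year=0.0, sigma_noise=3.0,
                              baseline_day=60.0, beta_lat=2.0, seed=5)
        db, _ = generate(cfg)
        rec = db.records.assign(dayofyear=db.records["dayofyear"].astype(float))
        p = partition_group(rec, db.sites)
        assert p.frac_geo_within_site > 0.97

    def test_degenerate_geometry_gives_nan_not_zero(self):
        rec = frame([
            {"studysite": s, "taxonidentifier": t, "dayofyear": d}
            for s, t, d in [("A", "T1", 100.0), ("A", "T2", 110.0),
                            ("B", "T1", 130.0), ("B", "T2", 150.0)]])
        p = partition_group(rec, self._sites("AB"))  # 2 sites < 4 points
        assert np.isnan(p.frac_geo_within_site)

    def test_single_site_raises(self):
        rec = frame([{"studysite": "A", "taxonidentifier": t, "dayofyear": d}
                     for t, d in [("T1", 100.0), ("T2", 120.0), ("T1", 110.0)]])
        with pytest.raises(ValueError, match="degenerate"):
            partition_group(rec, self._sites("A"))


class TestPartitionDatabase:
    def test_row_per_selected_group(self, clean_generated):
        db, _ = clean_generated
        parts = partition_database(db, min_records=200)
        assert len(parts) == len(select_groups(db, min_records=200))
        for p in parts:
            assert p.frac_site + p.frac_species + p.frac_residual == \
                pytest.approx(1.0, abs=1e-9)

    def test_climatic_group_uses_eventtype_as_taxon(self, rng):
        clim_rows = []
        for site, base in (("A", 270), ("B", 300)):
            for ev, off in (("first frost", 0), ("first snowfall", 15)):
                clim_rows += [
                    {"studysite": site, "taxonidentifier": "Climate",
                     "taxon": "temperature", "eventtype": ev,
                     "year": 1990 + i,
                     "dayofyear": int(base + off + rng.integers(-5, 6))}
                    for i in range(10)]
        db = make_database(
            clim_rows,
            climevents=[{"group": "temperature", "eventtype": e,
                         "description": ""}
                        for e in ("first frost", "first snowfall")])
        parts = partition_database(db, min_records=10)
        assert len(parts) == 1
        p = parts[0]
        assert p.group == "temperature"
        assert p.S == 2  # the two climatic event types act as taxa
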