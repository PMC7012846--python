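import numpy as np
import pandas as pd
import pytest

from phenoscreen import Database, SyntheticConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_database(records: list[dict], sites: list[dict] | None = None,
                  taxa: list[dict] | None = None,
                  climevents: list[dict] | None = None) -> Database:
    """Build a small in-memory database from record dicts; referenced
    sites and taxa are synthesized unless given explicitly."""
    rec_defaults = {"project": "p", "dataset": "d", "quality": ""}
    rows = [rec_defaults | r for r in records]
    rec = pd.DataFrame(rows)
    if "year" not in rec:
        rec["year"] = 2000
    rec["year"] = pd.array(rec["year"], dtype="Int64")
    rec["dayofyear"] = pd.array(rec["dayofyear"], dtype="Int64")
    for col in ("project", "dataset", "studysite", "taxonidentifier",
                "taxon", "eventtype", "quality"):
        if col not in rec:
            rec[col] = ""

    if sites is None:
        names = sorted(rec["studysite"].unique())
        sites = [{"studysite": s, "latitude": 50.0 + i, "longitude": 30.0 + i}
                 for i, s in enumerate(names)]
    site_df = pd.DataFrame(sites)

    if taxa is None:
        tax_ids = sorted(set(rec["taxonidentifier"]) - {"Climate"})
        taxa = [{"taxonidentifier": t, "taxon": f"Taxon {t}",
                 "kingdom": "Plantae", "class": "Magnoliopsida"}
                for t in tax_ids]
    tax_df = pd.DataFrame(taxa, columns=["taxonidentifier", "taxon",
                                         "taxonomiclevel", "kingdom", "phylum",
                                         "class", "order", "family", "genus",
                                         "species", "gbifkey", "gbifstatus"])
    tax_df = tax_df.fillna("")

    pheno_ev = pd.DataFrame(
        [{"kingdom": "Plantae", "eventtype": e, "description": "", "bbch": ""}
         for e in sorted(rec["eventtype"].unique())])
    clim_df = pd.DataFrame(climevents or [],
                           columns=["group", "eventtype", "description"])
    sources = pd.DataFrame([{"project": "p", "source": "s", "reference": "r"}])
    return Database(records=rec, sites=site_df, taxa=tax_df,
                    phenoevents=pheno_ev, climevents=clim_df, sources=sources)


@pytest.fixture
def tiny_db() -> Database:
    return make_database([
        {"studysite": "A", "taxonidentifier": "T1", "taxon": "Taxon T1",
         "eventtype": "onset of blooming", "year": 2000, "dayofyear": 120},
        {"studysite": "A", "taxonidentifier": "T2", "taxon": "Taxon T2",
         "eventtype": "onset of blooming", "year": 2000, "dayofyear": 130},
        {"studysite": "B", "taxonidentifier": "T1", "taxon": "Taxon T1",
         "eventtype": "onset of blooming", "year": 2001, "dayofyear": 140},
    ])


@pytest.fixture(scope="session")
def clean_generated():
    """A clean mid-sized synthetic database shared across tests."""
    cfg = SyntheticConfig(n_sites=10, n_taxa=12, n_years=15, seed=42)
    return generate(cfg)
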