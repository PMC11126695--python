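import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import rdrkit as rk

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully featured synthetic meta-cohort."""
    table, metadata, truth = rk.generate_cohort(
        n_studies=2, n_subjects_per_study=6, n_timepoints=2, n_taxa=12,
        seed=7)
    return table, metadata, truth


@pytest.fixture(scope="session")
def prepped(small_cohort):
    table, metadata, truth = small_cohort
    tab, triads, profiles = rk.prep_pipeline(table, metadata)
    return tab, triads, profiles, truth


@pytest.fixture()
def counts_table():
    """Tiny raw-count table: 3 samples x 4 taxa."""
    values = pd.DataFrame(
        [[1000, 500, 0, 500],
         [0, 1500, 1500, 0],
         [800, 0, 400, 2800]],
        index=["s1", "s2", "s3"],
        columns=["tA", "tB", "tC", "tD"], dtype=float)
    values.index.name = "sample_id"
    meta = pd.DataFrame({"read_depth": values.sum(axis=1),
                         "study_id": ["x", "x", "y"]}, index=values.index)
    return rk.AbundanceTable(values=values, is_relative=False,
                             sample_meta=meta)


def write_wide_tsv(frame: pd.DataFrame, path) -> None:
    """Write a samples x taxa frame in the wide taxa x samples layout."""
    out = frame.T
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


@pytest.fixture()
def triad_table():
    """Hand-built relative table covering all 8 presence patterns.

    Taxa t0..t7 realize presence bits (donor, pre, post) =
    (0,0,0), (0,0,1), (0,1,0), (0,1,1), (1,0,0), (1,0,1), (1,1,0), (1,1,1)
    for the triad (donor=d, pre=p, post=q).
    """
    bits = [(i >> 2 & 1, i >> 1 & 1, i & 1) for i in range(8)]
    taxa = [f"t{i}" for i in range(8)]
    rows = {
        "d": [0.1 * b[0] for b in bits],
        "p": [0.1 * b[1] for b in bits],
        "q": [0.1 * b[2] for b in bits],
    }
    values = pd.DataFrame.from_dict(rows, orient="index", columns=taxa)
    values = values.div(values.sum(axis=1), axis=0)
    table = rk.AbundanceTable(values=values, is_relative=True)
    triad = rk.Triad(experiment_id="e1", donor_sample="d", pre_sample="p",
                     post_sample="q", subject_id="subj1", donor_id="don1",
                     study_id="st1")
    return table, triad, dict(zip(taxa, bits))
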