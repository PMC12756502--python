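"""Shared fixtures: all data is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

import docrefine as dr


@pytest.fixture(scope="session")
def clinical_cohort():
    """The packaged 88-patient clinical table."""
    return dr.load_clinical_table()


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 20-region synthetic cohort (fixed seed) with edge vectors."""
    bp = dr.small_blueprint(rng_seed=7)
    cohort, timeseries, truth = dr.simulate_cohort(bp)
    edge_vectors = dr.compute_edge_vectors(timeseries)
    return cohort, timeseries, truth, edge_vectors


@pytest.fixture(scope="session")
def toy_edge_vectors():
    """Ten subjects x 6 regions of random but reproducible edge vectors."""
    rng = np.random.default_rng(42)
    out = []
    for k in range(10):
        ts = dr.ROITimeSeries(
            data=rng.standard_normal((30, 6)), subject_id=f"t{k:02d}"
        )
        out.append(dr.vectorize_upper(dr.compute_fc_matrix(ts)))
    return out


def toy_manifest_text() -> str:
    return (
        "subject_id,label,crsr_total,timeseries_path,months_since_onset,etiology\n"
        "s1,UWS,3,,2.0,TBI\n"
        "s2,UWS,n/a,,,\n"
        "s3,MCS,9,ts/s3.tsv,5.5,HIE\n"
    )
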