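"""Shared fixtures: small synthetic studies generated at test time."""

import numpy as np
import pandas as pd
import pytest

import ewaskit as ek
from ewaskit.ewas import NUISANCE_COVARIATES


def nuisance_covariates(study, fractions=None):
    """Standard nuisance design: covariate table plus cell fractions."""
    fr = fractions if fractions is not None else study.truth.cell_proportions
    return pd.concat(
        [study.samples[NUISANCE_COVARIATES].astype(float), fr], axis=1
    )


@pytest.fixture(scope="session")
def manifest():
    return ek.generate_manifest(
        n_autosomal=1000, n_sex=50, n_snp_flagged=30, n_control=20, n_genes=100,
        seed=1)


@pytest.fixture(scope="session")
def reference():
    return ek.generate_cell_reference(n_marker_per_type=10, seed=3)


@pytest.fixture(scope="session")
def spiked_cohort(manifest, reference):
    """n=200+200 with ten probes spiked at delta-beta = 0.05."""
    genic = manifest.loc[(manifest["gene"] != "") & ~manifest["is_control"]]
    rng = np.random.default_rng(5)
    spike_ids = list(rng.choice(genic["probe_id"].to_numpy(), 10, replace=False))
    study = ek.generate_cohort(
        manifest, reference, n_case=200, n_control=200,
        spike_probes=[(p, 0.05) for p in spike_ids],
        score_index_r=0.6, seed=7, cohort_id="disc")
    return study


@pytest.fixture(scope="session")
def null_cohort(manifest, reference):
    """No spikes, batch present: the global-null study."""
    return ek.generate_cohort(
        manifest, reference, n_case=60, n_control=60, batch_sd=1.0, seed=11,
        cohort_id="null")
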