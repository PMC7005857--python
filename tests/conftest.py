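"""Shared fixtures: one small synthetic world, generated once per session."""

import warnings

import pytest

from ecogap.cleaning import clean_pipeline
from ecogap.synth import SyntheticWorldSpec, make_world


@pytest.fixture(scope="session")
def world():
    """Default-condition world: 8 taxa x 125 records = 1000 records with all
    five error types injected at the default rates."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_world(SyntheticWorldSpec(seed=1), n_per_taxon=125)


@pytest.fixture(scope="session")
def clean_world(world):
    """The same world after the full cleaning pipeline."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cleaned, report = clean_pipeline(world["records"], world["countries"],
                                         world["stack"])
    return {"cleaned": cleaned, "report": report, **world}


@pytest.fixture(scope="session")
def pristine_world():
    """Error-free world (all injection rates zero) for idempotence checks."""
    spec = SyntheticWorldSpec(
        seed=4, error_rates={k: 0.0 for k in
                             ("country_mismatch", "offshore", "centroid",
                              "duplicate", "climate_outlier")})
    return make_world(spec, n_per_taxon=60, inject=False)
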