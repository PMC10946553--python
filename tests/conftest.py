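"""Shared fixtures: one small synthetic reference and one fitted model per
session, so individual tests stay fast."""

import numpy as np
import pytest

from splicepipe.motif_scores import ScoringModels
from splicepipe.pipeline import fit_spip_model
from splicepipe.site_metascore import SiteMetascore
from splicepipe.synthetic_data import (
    CollectionSpec,
    collection_frame,
    simulate_collection,
    simulate_reference,
)


@pytest.fixture(scope="session")
def small_reference():
    return simulate_reference(n_transcripts=6, seed=1)


@pytest.fixture(scope="session")
def scoring_models(small_reference):
    r = small_reference
    return ScoringModels.from_reference(r.genome, r.transcripts, r.esr_table)


@pytest.fixture(scope="session")
def metascore(small_reference, scoring_models):
    r = small_reference
    return SiteMetascore.fit(r.transcripts, r.genome, scoring_models, seed=0)


@pytest.fixture(scope="session")
def small_collection(small_reference):
    spec = CollectionSpec(n_curated=300, n_controls=1700, prevalence=0.06, seed=7)
    return collection_frame(simulate_collection(spec, small_reference))


@pytest.fixture(scope="session")
def fitted(small_reference, small_collection):
    """(model, report) trained on the small collection; a forest small enough
    to keep the suite quick but large enough for a stable vote grid."""
    r = small_reference
    model, report = fit_spip_model(
        r.genome,
        r.transcripts,
        r.esr_table,
        small_collection,
        seed=9,
        n_trees=150,
        selection_trees=60,
    )
    return model, report


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
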