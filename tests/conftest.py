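"""Shared fixtures: synthetic bundles and the one expensive pipeline run."""

from __future__ import annotations

import pytest

from ap2erf import pipeline
from ap2erf.pipeline import SpeciesInputs
from ap2erf.synthetic import (
    SyntheticSpec,
    generate_coffee_like_allotetraploid,
    generate_counts,
    generate_diploid,
)


@pytest.fixture(scope="session")
def small_diploid():
    return generate_diploid(
        SyntheticSpec(
            seed=11,
            n_two_domain=4,
            n_single_domain=14,
            n_rav=2,
            n_soloist_like=1,
            n_tandem_events=3,
            n_segmental_events=2,
            background_genes=8,
        )
    )


@pytest.fixture(scope="session")
def allotetraploid_bundle():
    """The 12 tandem / 11 segmental / 77 homoeolog planted allotetraploid."""
    return generate_coffee_like_allotetraploid(seed=1)


@pytest.fixture(scope="session")
def allotetraploid_counts(allotetraploid_bundle):
    matrix, flags = generate_counts(
        allotetraploid_bundle, n_samples=3, expressed_fraction=0.5,
        mean_cpm_expressed=50.0, seed=2,
    )
    return matrix, flags


@pytest.fixture(scope="session")
def allotetraploid_report(allotetraploid_bundle, allotetraploid_counts):
    """Full characterize run on the allotetraploid (shared: it is the slow one)."""
    matrix, _ = allotetraploid_counts
    b = allotetraploid_bundle
    return pipeline.characterize(
        SpeciesInputs(
            species=b.species,
            prefix="Al",
            proteins=b.proteins,
            coordinates=b.coordinates,
            domain_hits=b.domain_hits,
            cds=b.cds,
            subgenome_mode=True,
            counts=matrix,
        )
    )
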