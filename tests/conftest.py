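"""Shared fixtures: a small two-clade panel, the study panel, and the
published-profile fixtures."""

from __future__ import annotations

import pytest

from mcrapipe.simulate import (
    AmpliconScheme,
    CladeSpec,
    generate_reference_panel,
    make_study_panel,
    table2_profiles,
)


@pytest.fixture(scope="session")
def scheme() -> AmpliconScheme:
    return AmpliconScheme()


@pytest.fixture(scope="session")
def two_clade_panel():
    """Two well-separated clades, three members each."""
    specs = [
        CladeSpec("cladeA", "FamX", "GenA", "cladeA", 3, 0.08, 0.015),
        CladeSpec("cladeB", "FamX", "GenB", "cladeB", 3, 0.16, 0.015),
    ]
    return generate_reference_panel(specs, peptide_length=157, seed=11)


@pytest.fixture(scope="session")
def study_panel():
    return make_study_panel(seed=1)


@pytest.fixture(scope="session")
def profiles():
    return table2_profiles()
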