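"""Shared fixtures: one synthetic world per session, reused across modules."""

from __future__ import annotations

import pytest

from canemir import synthetic


@pytest.fixture(scope="session")
def reference():
    """A default synthetic reference: 30 transcripts, 20 planted hairpins."""
    transcripts, manifest = synthetic.simulate_reference(seed=11)
    return transcripts, manifest


@pytest.fixture(scope="session")
def clean_world(reference):
    """Noise-free deep libraries on the session reference (Poisson counts,
    no junk reads): the recovery regime every planted object must survive."""
    transcripts, manifest = reference
    reads, truth, truth_var = synthetic.simulate_library(
        manifest, transcripts, depth=30000, junk_fraction=0.0, phi=0.0
    )
    return transcripts, manifest, reads, truth, truth_var


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A small on-disk fixture set (files + manifest) for I/O-level tests."""
    outdir = tmp_path_factory.mktemp("fixtures")
    result = synthetic.write_fixtures(outdir, seed=3, depth=5000)
    return outdir, result
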