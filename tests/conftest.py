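"""Shared fixtures: expensive synthetic objects are built once per session."""

from __future__ import annotations

import pytest

from pendock import synth


@pytest.fixture(scope="session")
def toy_complex():
    return synth.gen_toy_complex(seed=0)


@pytest.fixture(scope="session")
def loop_scaffold():
    return synth.gen_loop_scaffold(seed=3)


@pytest.fixture(scope="session")
def small_ensemble(loop_scaffold):
    from pendock import loops

    return loops.sample_loop_conformations(loop_scaffold, synth.MOTIF_LOOP,
                                           n=25, seed=7)


@pytest.fixture(scope="session")
def accessibility_fixture():
    return synth.accessibility_ensemble(seed=5)
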