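"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import pytest

from cilocate.testing import (  # re-exported for test modules  # noqa: F401
    StraightCurve,
    make_blob_volume,
    random_chain_instance,
    toy_spec,
)


@pytest.fixture(scope="session")
def clean_flex24():
    """One noise-free clean phantom of a widely spaced 12-contact array."""
    from cilocate.phantom import make_phantom

    return make_phantom("clean", "Flex 24", seed=0)


@pytest.fixture(scope="session")
def confusion_flex28():
    """One phantom in the deep-insertion / wide-spacing confusion regime."""
    from cilocate.phantom import make_phantom

    return make_phantom("confusion", "Flex 28", seed=0)
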