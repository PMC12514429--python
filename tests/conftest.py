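"""Shared fixtures: the baseline chamber and its solved fields.

Session scope keeps the full-chain baseline simulation (potential, slip,
Stokes flow, DEP force, 60 s tracing) to a single run shared by every test
that inspects it.
"""

from __future__ import annotations

import pytest

import aceodep as a
from aceodep.core import baseline_config


@pytest.fixture(scope="session")
def baseline_cfg():
    return baseline_config()


@pytest.fixture(scope="session")
def baseline_fields(baseline_cfg):
    """Potential + slip + flow + DEP force for the baseline chamber (no tracing)."""
    return a.run_case(baseline_cfg, with_tracing=False)


@pytest.fixture(scope="session")
def baseline_case(baseline_cfg):
    """Full baseline chain including the 60 s particle tracing."""
    return a.run_case(baseline_cfg, with_tracing=True)
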