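"""Shared fixtures: cached desk-scale condition sweeps.

Running a full (l, h) grid sweep takes tens of seconds, so each named
condition is simulated at most once per session and shared by every test
that inspects it.
"""

from __future__ import annotations

import pytest

from normsim import get_condition, pool_sweep, run_sweep
from normsim.metrics import SweepResult

_SWEEP_SEED = 1729
_cache: dict[str, SweepResult] = {}


@pytest.fixture(scope="session")
def sweep_for():
    """Factory returning the pooled desk-scale sweep of a named condition."""

    def _get(name: str) -> SweepResult:
        if name not in _cache:
            cfg = get_condition(name).scaled("small")
            _cache[name] = pool_sweep(run_sweep(cfg, seed=_SWEEP_SEED))
        return _cache[name]

    return _get
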