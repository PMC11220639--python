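"""Shared fixtures.

The large default-noise ensemble (2000 traces at the reported pattern
proportions) feeds both the recovery property tests and several acceptance
checks; it is built once per session.
"""

import numpy as np
import pytest

from ligbend.fret import CorrectionParams, TracePatternModel
from ligbend.simulate import TraceGenParams, simulate_trace_ensemble


@pytest.fixture(scope="session")
def default_params() -> TraceGenParams:
    return TraceGenParams(seed=0)


@pytest.fixture(scope="session")
def reference_ensemble(default_params):
    """2000 default-noise traces at the default pattern proportions."""
    return simulate_trace_ensemble(default_params, 2000)


@pytest.fixture(scope="session")
def reference_results(default_params, reference_ensemble):
    """Full pipeline results on the reference ensemble."""
    model = TracePatternModel(
        reference_ensemble, CorrectionParams.from_generation(default_params)
    )
    return model.fit(seed=0)


def binomial_3sigma(p: float, n: int) -> float:
    """Half-width of the 3-sigma binomial band for a proportion."""
    return 3.0 * np.sqrt(p * (1.0 - p) / n)


from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("ci", derandomize=True)
_hyp_settings.load_profile("ci")
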