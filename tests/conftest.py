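import numpy as np
import pytest

from cardiosense import (
    circuit_impedance,
    default_frequency_grid,
    reference_params,
    simulate_beating_trace,
)


@pytest.fixture(scope="session")
def ref_params():
    """Canonical day-4-7 mean circuit parameters."""
    return reference_params()


@pytest.fixture(scope="session")
def ref_spectrum(ref_params):
    """Noiseless forward-model spectrum on the standard 60-point grid."""
    return circuit_impedance(ref_params, default_frequency_grid())


@pytest.fixture(scope="session")
def clean_trace_factory():
    """Noise-free, jitter-free beating trace builder."""

    def make(amplitude=10e-6, frequency=1.0, beat_duration=0.25, length_s=10.0, **kw):
        kw.setdefault("noise_sd", 0.0)
        kw.setdefault("jitter_cv", 0.0)
        return simulate_beating_trace(
            amplitude=amplitude,
            frequency=frequency,
            beat_duration=beat_duration,
            length_s=length_s,
            **kw,
        )

    return make


@pytest.fixture(scope="session")
def day_summaries():
    """Beat summaries of the default day 4-7 traces (noise off)."""
    from cardiosense import analyze_trace

    out = []
    for day in (4, 5, 6, 7):
        trace = simulate_beating_trace(day=day, noise_sd=0.0, jitter_cv=0.0)
        out.append(analyze_trace(trace)[1])
    return out
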