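"""End-to-end analysis chains combining the generator and analysis modules."""

from __future__ import annotations

from . import beat_analysis as ba
from .device_model import CantileverSpec, spring_constant
from .drug_response import DoseResponseCurve, build_curve
from .eis import normalized_ci_course
from .synthetic import DrugExperiment

__all__ = ["DEFAULT_SPRING_CONSTANT", "analyze_trace", "curve_from_experiment"]

# 6 mm x 2 mm x 15 um SU-8 cantilever
DEFAULT_SPRING_CONSTANT = spring_constant(CantileverSpec(6e-3, 2e-3, 15e-6))


def analyze_trace(trace: ba.DisplacementTrace, k: float = DEFAULT_SPRING_CONSTANT):
    """Detect beats and summarize one displacement trace."""
    table = ba.detect_beats(trace)
    return table, ba.summarize(trace, table, k)


def curve_from_experiment(
    exp: DrugExperiment, k: float = DEFAULT_SPRING_CONSTANT
) -> DoseResponseCurve:
    """Run the full analysis chain on a generated drug experiment.

    Beats are detected and summarized per timepoint; the cell-index
    channel is normalized to its pre-drug value from the impedance
    course; both channels are assembled into a DoseResponseCurve.
    """
    ci_rows = normalized_ci_course(exp.course, predrug_time=0.0)
    ci_by_time = {float(t): float(p) for t, p in ci_rows}

    _, pre_summary = analyze_trace(exp.traces[0.0], k)
    # raw CI values: percent of pre-drug CI re-expressed on the CI scale
    pre_ci = 1.0  # build_curve only uses ratios; pre-drug CI normalized to 1

    timepoints = []
    for t, trace in exp.traces.items():
        if t == 0.0:
            continue
        _, summary = analyze_trace(trace, k)
        timepoints.append((t, summary, ci_by_time[t] / 100.0))
    return build_curve(exp.drug, exp.dose_nmol_l * 1e-9, (pre_summary, pre_ci), timepoints)
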