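"""End-to-end convenience: trajectories -> metrics -> cohort tests -> strategy call."""

from __future__ import annotations

from .metrics import metrics_frame
from .stats import classify_strategy, cohort_tests

__all__ = ["analyze_cohort"]


def analyze_cohort(trajectories, field, alpha=0.05, method="holm",
                   control_frame=None, **metric_kwargs):
    """Run the full analysis chain on one cohort.

    Returns ``(metric_frame, results, call)``: the per-individual metric
    table, the per-metric cohort test results, and the strategy
    classification of the six-metric significance pattern.
    """
    frame = metrics_frame(trajectories, field, **metric_kwargs)
    results = cohort_tests(frame, alpha=alpha, method=method,
                           control_frame=control_frame)
    call = classify_strategy(results)
    return frame, results, call
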