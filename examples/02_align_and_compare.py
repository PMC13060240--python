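"""Marker alignment, session performance and a time-point comparison.

Aligned age is chronological age minus the subject's maturation-marker
age; session performance is percent of correct antisaccade trials; two
testing time points are compared with the Mann-Whitney U test.
"""

import numpy as np

from trajalign import (
    SessionRecord,
    SubjectTimeline,
    align_ages,
    compare_timepoints,
    session_performance,
)

tl = SubjectTimeline("m1", visit_ages=[34.0, 45.0, 58.0, 69.0], marker_age=58.0)
print("chronological visit ages:", tl.visit_ages.tolist())
print("aligned ages            :", align_ages(tl).tolist())
print("(0 = tibial growth-plate closure; negative = before mid-adolescence)\n")

rec = SessionRecord("m1", aligned_age=-10.0, variant="gap", n_trials=72, n_correct=49)
print(f"session performance: {session_performance(rec):.1f}% correct\n")

# an early and a later testing time point, ~19 sessions each
rng = np.random.default_rng(0)
young = 100 * rng.binomial(72, 0.55, size=19) / 72
older = 100 * rng.binomial(72, 0.80, size=19) / 72
u, p = compare_timepoints(young, older)
print(f"young vs older time point: U = {u:.1f}, two-sided p = {p:.2e}")
print("a small U and tiny p mean nearly every older-session performance")
print("exceeds the young sessions - a large maturational gain.")
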