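"""Biological-marker age alignment and session-level behavioral metrics.

Chronological ages are re-expressed relative to a per-subject skeletal
maturation marker (closure of the distal tibial growth plate, the
"mid-adolescence" event), so that aligned age 0 is the marker event for
every subject.  Session performance is the percentage of correct trials;
group comparisons between testing time points use the Mann-Whitney U
test, with exact enumeration for small samples and a tie-corrected
normal approximation otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import LongitudinalDataset

VARIANTS = ("overlap", "zero-gap", "gap")

# combined sample size at which the Mann-Whitney p-value switches from
# exhaustive enumeration to the tie-corrected normal approximation
EXACT_ENUMERATION_MAX_N = 16


class AlignmentError(ValueError):
    pass


@dataclass
class SubjectTimeline:
    """A subject's chronological visit ages and its maturation-marker age."""

    subject_id: str
    visit_ages: np.ndarray      # months, strictly increasing
    marker_age: float | None    # months

    def __post_init__(self):
        self.visit_ages = np.asarray(self.visit_ages, dtype=float)
        if np.any(np.diff(self.visit_ages) <= 0):
            raise AlignmentError("visit ages must be strictly increasing")
        if self.marker_age is not None and not self.marker_age > 0:
            raise AlignmentError("marker_age must be positive")


@dataclass
class SessionRecord:
    subject_id: str
    aligned_age: float
    variant: str
    n_trials: int
    n_correct: int

    def __post_init__(self):
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if not 0 <= self.n_correct <= self.n_trials:
            raise ValueError("n_correct must lie in [0, n_trials]")


def align_ages(timeline: SubjectTimeline) -> np.ndarray:
    """Aligned age = chronological age - marker age (months); 0 is the
    marker event.  A missing marker age is an error, never imputed."""
    if timeline.marker_age is None or not np.isfinite(timeline.marker_age):
        raise AlignmentError(
            f"subject {timeline.subject_id!r} has no marker age; cannot align"
        )
    return timeline.visit_ages - timeline.marker_age


def align_dataset(df: pd.DataFrame, markers: dict | pd.DataFrame) -> pd.DataFrame:
    """Add/overwrite ``aligned_age_months`` from a subject->marker map.

    ``markers`` is a mapping or a DataFrame with columns ``subject_id``
    and ``marker_age_months``.
    """
    if isinstance(markers, pd.DataFrame):
        markers = dict(
            zip(markers["subject_id"], markers["marker_age_months"].astype(float))
        )
    out = df.copy()
    missing = sorted(set(out["subject_id"]) - set(markers))
    if missing:
        raise AlignmentError(f"no marker age for subjects: {missing}")
    out["aligned_age_months"] = out["age_months"].astype(float) - out[
        "subject_id"
    ].map(markers)
    return out


def session_performance(record: SessionRecord) -> float:
    """Percent of trials with a correct response, in [0, 100]."""
    return 100.0 * record.n_correct / record.n_trials


def pool_variants(
    data: LongitudinalDataset | pd.DataFrame,
    outcome: str,
    pooled_name: str | None = None,
) -> LongitudinalDataset:
    """Per-session percent correct pooled over all task variants.

    Rows of ``outcome`` are grouped by subject, aligned age and (when
    present) session; percent correct is recomputed over the combined
    trials.  The task variants are strongly correlated in this paradigm,
    so the pooled curve is the reference trajectory for similarity
    analyses.
    """
    df = getattr(data, "df", data)
    sub = df[df["outcome"] == outcome].copy()
    if sub.empty:
        raise ValueError(f"outcome {outcome!r} not present")
    if sub["n_trials"].isna().any():
        raise ValueError("pooling requires per-row trial counts")
    keys = ["subject_id", "age_months", "aligned_age_months"]
    if "session" in sub.columns:
        keys.append("session")
    sub["_ncorr"] = sub["value"] * sub["n_trials"] / 100.0
    g = sub.groupby(keys, as_index=False)[["_ncorr", "n_trials"]].sum()
    g["value"] = 100.0 * g["_ncorr"] / g["n_trials"]
    g["outcome"] = pooled_name or f"{outcome}_pooled"
    g["variant"] = pd.NA
    g = g.drop(columns=["_ncorr"])
    cols = [
        "subject_id",
        "age_months",
        "aligned_age_months",
        "outcome",
        "variant",
        "value",
        "n_trials",
    ]
    extra = [c for c in g.columns if c not in cols]
    return LongitudinalDataset(g[cols + extra])


def _u_statistic(group1: np.ndarray, group2: np.ndarray) -> float:
    pooled = np.concatenate([group1, group2])
    ranks = stats.rankdata(pooled)
    r1 = ranks[: group1.size].sum()
    return float(r1 - group1.size * (group1.size + 1) / 2.0)


def _exact_p(group1: np.ndarray, group2: np.ndarray, u_obs: float) -> float:
    """Two-sided p by exhaustive enumeration of group assignments.

    Ties are handled exactly: every C(n1+n2, n1) split of the pooled
    values is scored, and the p-value is the fraction of splits whose U
    is at least as far from its null mean as the observed U.
    """
    pooled = np.concatenate([group1, group2])
    n1 = group1.size
    ranks = stats.rankdata(pooled)
    mu = n1 * group2.size / 2.0
    d_obs = abs(u_obs - mu) - 1e-12
    offset = n1 * (n1 + 1) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(pooled.size), n1):
        u = ranks[list(idx)].sum() - offset
        count += abs(u - mu) >= d_obs
        total += 1
    return count / total


def _asymptotic_p(group1: np.ndarray, group2: np.ndarray, u_obs: float) -> float:
    """Normal approximation with tie correction and continuity correction."""
    n1, n2 = group1.size, group2.size
    N = n1 + n2
    pooled = np.concatenate([group1, group2])
    _, t = np.unique(pooled, return_counts=True)
    tie_term = (t**3 - t).sum() / (N * (N - 1)) if N > 1 else 0.0
    var = n1 * n2 / 12.0 * (N + 1 - tie_term)
    if var <= 0:
        return 1.0  # every pooled value identical: no evidence of a shift
    mu = n1 * n2 / 2.0
    num = abs(u_obs - mu) - 0.5
    z = max(num, 0.0) / np.sqrt(var)
    return min(1.0, 2.0 * stats.norm.sf(z))


def compare_timepoints(group1, group2) -> tuple[float, float]:
    """Mann-Whitney U comparison of two sets of session performances.

    Returns (U of group1, two-sided p).  Exact enumeration is used when
    the combined sample size is at most 16 (both groups <= 8 in the
    balanced case); larger samples use the tie-corrected normal
    approximation with continuity correction.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be non-empty")
    u = _u_statistic(g1, g2)
    if g1.size + g2.size <= EXACT_ENUMERATION_MAX_N:
        p = _exact_p(g1, g2, u)
    else:
        p = _asymptotic_p(g1, g2, u)
    return u, p
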