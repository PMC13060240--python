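"""Seeded synthetic longitudinal cohorts of developing macaques.

Generates the data structure the trajectory analyses consume: a small
cohort observed quarterly through adolescence, each subject with a
skeletal maturation-marker age (mean 57.9, SD 3.6 months), and outcomes
of three families on marker-aligned age:

* ``binomial-performance`` — session-level antisaccade percent correct,
  a saturating logistic rising steeply in early adolescence, with three
  task-variant difficulty offsets on the logit scale (overlap easiest);
* ``gaussian-rate`` — session-mean prefrontal firing rate rising with
  maturation;
* ``gaussian-tract`` — white-matter tract scalars: FA-type saturating
  increases and mirrored RD-type decreases.

All families carry subject-specific random intercepts and slopes on
aligned age plus observation noise.  Each outcome draws from its own
RNG stream derived by stable hashing of (seed, outcome name), so adding
an outcome never perturbs the realizations of existing ones.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .alignment import SubjectTimeline, VARIANTS
from .data import LongitudinalDataset

log = logging.getLogger(__name__)

FAMILIES = ("binomial-performance", "gaussian-rate", "gaussian-tract")


class ConfigError(ValueError):
    pass


def outcome_rng(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-outcome RNG stream from (seed, outcome name)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(name.encode())])
    )


@dataclass
class LatentShape:
    """4-parameter logistic maturation curve on aligned age (months).

    value(t) = lower + (upper - lower) * expit((t - midpoint) / slope);
    decreasing curves are encoded by upper < lower.
    """

    lower: float
    upper: float
    midpoint: float     # aligned months; 0 = maturation marker
    slope: float        # months per logistic unit; > 0

    def __post_init__(self):
        if self.slope <= 0:
            raise ConfigError("shape slope must be positive")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.lower + (self.upper - self.lower) * expit(
            (t - self.midpoint) / self.slope
        )


@dataclass
class OutcomeSpec:
    name: str
    family: str
    shape: LatentShape
    variant_offsets: dict | None = None     # logit offsets, performance only
    n_trials_per_session: int = 200
    n_sessions: int = 1
    noise_sd: float = 0.0
    random_intercept_sd: float = 0.0
    random_slope_sd: float = 0.0
    tract_sign: int = 0                     # +1 FA-type, -1 RD-type

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown family {self.family!r}")
        if self.family == "binomial-performance":
            if not (0 <= self.shape.lower <= 1 and 0 <= self.shape.upper <= 1):
                raise ConfigError("performance latent curve must map into [0,1]")
            if self.n_trials_per_session <= 0:
                raise ConfigError("n_trials_per_session must be positive")
        if self.family == "gaussian-tract":
            if self.tract_sign not in (+1, -1):
                raise ConfigError("gaussian-tract requires tract_sign = +1 (FA) or -1 (RD)")
            d = np.diff(self.shape(np.linspace(-60, 60, 512)))
            if self.tract_sign == +1 and np.any(d < -1e-12):
                raise ConfigError(f"FA-type shape for {self.name!r} must be non-decreasing")
            if self.tract_sign == -1 and np.any(d > 1e-12):
                raise ConfigError(f"RD-type shape for {self.name!r} must be non-increasing")


@dataclass
class CohortConfig:
    n_subjects: int = 4
    marker_mean: float = 57.9       # months; mean mid-adolescence age
    marker_sd: float = 3.6          # months
    age_start: float = 34.0         # months at first visit
    age_end: float = 75.0           # months at last visit
    visit_interval: float = 3.0     # quarterly visits
    seed: int = 0
    outcome_specs: list = field(default_factory=list)

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if not self.age_start < self.age_end:
            raise ConfigError("age_start must be < age_end")
        if self.visit_interval <= 0:
            raise ConfigError("visit_interval must be positive")
        if self.marker_sd < 0:
            raise ConfigError("marker_sd must be >= 0")


def gen_subjects(config: CohortConfig) -> list:
    """Draw marker ages ~ Normal(marker_mean, marker_sd^2) and lay out
    quarterly visit ages; deterministic under the config seed."""
    rng = outcome_rng(config.seed, "__subjects__")
    visits = np.arange(
        config.age_start, config.age_end + 1e-9, config.visit_interval
    )
    out = []
    for i in range(config.n_subjects):
        marker = config.marker_mean + config.marker_sd * rng.standard_normal()
        out.append(
            SubjectTimeline(
                subject_id=f"S{i + 1:02d}", visit_ages=visits.copy(),
                marker_age=float(marker),
            )
        )
    return out


def _subject_effects(rng, spec, n_subj):
    a = spec.random_intercept_sd * rng.standard_normal(n_subj)
    b = spec.random_slope_sd * rng.standard_normal(n_subj)
    return a, b


def gen_outcome(subjects: list, spec: OutcomeSpec, seed: int) -> LongitudinalDataset:
    """Simulate one outcome over all subjects and visits.

    Binomial performance draws per-session correct-trial counts at the
    subject- and variant-shifted latent probability and reports percent
    correct; Gaussian families add subject effects and Normal noise to
    the latent curve.  Probabilities pushed outside [0,1] by subject
    effects are clamped, with the clamp count logged and recorded in
    ``meta['clamped']``.
    """
    rng = outcome_rng(seed, spec.name)
    a, b = _subject_effects(rng, spec, len(subjects))
    rows = []
    clamped = 0
    for si, subj in enumerate(subjects):
        aligned = subj.visit_ages - subj.marker_age
        latent = spec.shape(aligned)
        if spec.family == "binomial-performance":
            offsets = spec.variant_offsets or {v: 0.0 for v in VARIANTS}
            for vi, age in enumerate(subj.visit_ages):
                for s in range(spec.n_sessions):
                    for variant, off in offsets.items():
                        p_lat = np.clip(latent[vi], 1e-9, 1 - 1e-9)
                        p = expit(logit(p_lat) + off)
                        p = p + a[si] + b[si] * aligned[vi]
                        if p < 0.0 or p > 1.0:
                            clamped += 1
                            p = min(max(p, 0.0), 1.0)
                        k = rng.binomial(spec.n_trials_per_session, p)
                        rows.append(
                            (subj.subject_id, age, aligned[vi], spec.name,
                             variant, 100.0 * k / spec.n_trials_per_session,
                             spec.n_trials_per_session, s + 1)
                        )
        else:
            for s in range(spec.n_sessions):
                noise = spec.noise_sd * rng.standard_normal(aligned.size)
                vals = latent + a[si] + b[si] * aligned + noise
                for vi, age in enumerate(subj.visit_ages):
                    rows.append(
                        (subj.subject_id, age, aligned[vi], spec.name,
                         None, vals[vi], None, s + 1)
                    )
    df = pd.DataFrame(
        rows,
        columns=[
            "subject_id", "age_months", "aligned_age_months", "outcome",
            "variant", "value", "n_trials", "session",
        ],
    )
    if clamped:
        log.warning(
            "%s: %d session probabilities clamped to [0,1]", spec.name, clamped
        )
    return LongitudinalDataset(df, meta={"clamped": {spec.name: clamped},
                                         "latent": {spec.name: spec.shape}})


def gen_cohort(config: CohortConfig):
    """Generate all configured outcomes; returns (subjects, dataset)."""
    subjects = gen_subjects(config)
    parts = [gen_outcome(subjects, spec, config.seed) for spec in config.outcome_specs]
    if not parts:
        raise ConfigError("no outcome_specs configured")
    ds = parts[0]
    for p in parts[1:]:
        ds = ds.concat(p)
    return subjects, ds


# ---------------------------------------------------------------------------
# default study-like configuration

BEHAVIOR_SHAPE = LatentShape(lower=0.40, upper=0.90, midpoint=-10.0, slope=6.0)
RATE_SHAPE = LatentShape(lower=10.0, upper=25.0, midpoint=-5.0, slope=8.0)
VARIANT_LOGIT_OFFSETS = {"overlap": +0.4, "zero-gap": 0.0, "gap": -0.4}
N_TRACTS = 53


def behavior_spec(n_sessions: int = 19, n_trials: int = 72) -> OutcomeSpec:
    return OutcomeSpec(
        name="antisaccade",
        family="binomial-performance",
        shape=BEHAVIOR_SHAPE,
        variant_offsets=dict(VARIANT_LOGIT_OFFSETS),
        n_trials_per_session=n_trials,
        n_sessions=n_sessions,
        random_intercept_sd=0.02,
        random_slope_sd=0.0005,
    )


def firing_rate_spec() -> OutcomeSpec:
    return OutcomeSpec(
        name="firing_rate",
        family="gaussian-rate",
        shape=RATE_SHAPE,
        noise_sd=2.0,
        random_intercept_sd=0.5,
        random_slope_sd=0.01,
    )


def tract_specs(n_tracts: int = N_TRACTS, kind: str = "FA") -> list:
    """A battery of tract outcomes with per-tract shape variation.

    FA-type tracts rise (typical range ~0.35-0.55), RD-type mirror them
    downward (scaled to ~0.65-0.85, in 1e-3 mm^2/s); midpoints and
    slopes vary deterministically across tracts around the behavioral
    shape's, emulating tracts maturing on slightly different schedules.
    """
    specs = []
    for i in range(n_tracts):
        frac = i / max(n_tracts - 1, 1)
        midpoint = -13.0 + 6.0 * frac       # months around the behavior midpoint
        slope = 5.0 + 3.0 * frac
        if kind == "FA":
            lo = 0.35 + 0.05 * frac
            hi = lo + 0.12
            sign = +1
        elif kind == "RD":
            hi_val = 0.85 - 0.05 * frac
            lo = hi_val            # start high ...
            hi = hi_val - 0.12     # ... and decrease
            sign = -1
        else:
            raise ConfigError("kind must be 'FA' or 'RD'")
        specs.append(
            OutcomeSpec(
                name=f"{kind}_tract_{i + 1:02d}",
                family="gaussian-tract",
                shape=LatentShape(lower=lo, upper=hi, midpoint=midpoint, slope=slope),
                noise_sd=0.006,
                random_intercept_sd=0.006,
                random_slope_sd=0.0001,
                tract_sign=sign,
            )
        )
    return specs


def default_study_config(seed: int = 0, n_tracts: int = N_TRACTS) -> CohortConfig:
    """The full synthetic study: behavior, firing rate, and FA/RD tract
    batteries on a 4-subject quarterly cohort."""
    return CohortConfig(
        seed=seed,
        outcome_specs=[behavior_spec(), firing_rate_spec()]
        + tract_specs(n_tracts, "FA")
        + tract_specs(n_tracts, "RD"),
    )


# ---------------------------------------------------------------------------
# I/O

def write_truth(specs: list, grid: np.ndarray, path) -> None:
    """Sidecar CSV of the latent curves sampled on the analysis grid."""
    cols = {"aligned_age_months": np.asarray(grid, dtype=float)}
    for spec in specs:
        vals = spec.shape(grid)
        if spec.family == "binomial-performance":
            vals = 100.0 * vals
        cols[spec.name] = vals
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")


def write_markers(subjects: list, path) -> None:
    pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "marker_age_months": [s.marker_age for s in subjects],
        }
    ).to_csv(path, index=False, float_format="%.10g")


def config_to_yaml(config: CohortConfig, path) -> None:
    d = asdict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def config_from_yaml(path) -> CohortConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    specs = []
    for s in d.get("outcome_specs", []):
        s = dict(s)
        s["shape"] = LatentShape(**s["shape"])
        specs.append(OutcomeSpec(**s))
    d["outcome_specs"] = specs
    return CohortConfig(**d)
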