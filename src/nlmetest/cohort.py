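"""Synthetic natural-history cohorts for longitudinal two-arm trial simulation.

Generates ADAS-cog-like trajectories (baseline driven by a baseline
covariate, approximately linear progression, inter-individual variability
on baseline and slope, additive residual error), injects simulated
treatment effects into the treated arm, and handles 1:1 randomization /
permutation of the arm labels.

An optional latent misspecification component -- an additive subject-level
term ``gamma_i * (t/36)**power`` that the fitted linear placebo model
omits -- makes the generated data detectably misspecified with respect to
the linear disease model, which is the mechanism driving type I error
inflation of naive likelihood-ratio testing.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

DEFAULT_SCHEDULE = (0.0, 6.0, 12.0, 18.0, 24.0, 36.0)

__all__ = [
    "Visit",
    "SubjectTruth",
    "Subject",
    "Cohort",
    "MisspecConfig",
    "GeneratorConfig",
    "EffectScenario",
    "generate_natural_history",
    "inject_treatment_effect",
    "randomize_allocation",
    "permute_allocation",
]


@dataclass
class Visit:
    """A single observation: months since baseline and the observed score."""

    time: float
    score: float


@dataclass
class SubjectTruth:
    """Generator-only ground truth for one subject."""

    eta_baseline: float
    eta_slope: float
    latent_gamma: float = 0.0
    latent_values: tuple = ()
    drug_eta: float = 0.0
    effect: tuple = ()  # injected effect at each visit time (treated only)


@dataclass
class Subject:
    id: int
    bmms: float
    trt: int
    visits: list  # list[Visit], sorted by time
    truth: Optional[SubjectTruth] = None

    @property
    def times(self) -> np.ndarray:
        return np.array([v.time for v in self.visits], dtype=float)

    @property
    def scores(self) -> np.ndarray:
        return np.array([v.score for v in self.visits], dtype=float)


@dataclass
class Cohort:
    """A set of subjects plus generator/provenance metadata."""

    subjects: list
    meta: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_obs(self) -> int:
        return sum(len(s.visits) for s in self.subjects)

    @property
    def allocated(self) -> bool:
        return bool(self.meta.get("allocated", False))

    def arm_sizes(self) -> tuple:
        n1 = sum(1 for s in self.subjects if s.trt == 1)
        return (self.n_subjects - n1, n1)

    def validate(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject ids")
        for s in self.subjects:
            if s.trt not in (0, 1):
                raise ValueError(f"subject {s.id}: trt must be 0 or 1, got {s.trt}")
            t = s.times
            if len(t) and (np.any(np.diff(t) <= 0) or t[0] < 0):
                raise ValueError(f"subject {s.id}: visit times must be "
                                 "non-negative and strictly increasing")


@dataclass
class MisspecConfig:
    """Latent additive component gamma_i * (t / t_ref) ** power, omitted by
    the fitted linear placebo model."""

    enabled: bool = False
    sd: float = 8.0
    mean: float = 14.0
    power: float = 2.0
    t_ref: float = 36.0

    def shape(self, t: np.ndarray) -> np.ndarray:
        return (np.asarray(t, dtype=float) / self.t_ref) ** self.power


@dataclass
class GeneratorConfig:
    """Natural-history generator settings.

    Fixed-effect defaults are chosen to give plausible ADAS-cog-like
    trajectories (scores roughly 10--50 at baseline, ~5--10 points
    progression over 36 months); they are configuration, not published
    estimates.
    """

    n_subjects: int = 200
    schedule: Sequence[float] = DEFAULT_SCHEDULE
    th_base: float = 60.0          # baseline fixed intercept
    th_bmms: float = -1.6          # baseline covariate coefficient
    th_slope: float = 0.45         # points / month before covariate effect
    th_slope_bmms: float = -0.012  # slope covariate coefficient
    om2_base: float = 16.0         # IIV variance on baseline
    om2_slope: float = 0.02        # IIV variance on slope
    sig2: float = 9.0              # additive residual variance
    bmms_mean: float = 21.0
    bmms_sd: float = 4.0
    misspec: MisspecConfig = field(default_factory=MisspecConfig)
    dropout: float = 0.0           # P(missing) per post-baseline visit
    clip: bool = False             # clip scores into [0, 70]

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        mis = d.pop("misspec", None)
        cfg = cls(**d)
        if mis is not None:
            cfg.misspec = MisspecConfig(**mis) if isinstance(mis, dict) else mis
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schedule"] = list(self.schedule)
        return d


@dataclass
class EffectScenario:
    """A simulated treatment effect to inject into the treated arm.

    ``typical_effect`` is the typical added score at month 36; ``iiv_cv``
    is the coefficient of variation of the individual effect (the
    individual effect is ``typical_effect + eta`` with
    ``eta ~ N(0, (iiv_cv * typical_effect)**2)``).
    """

    drug_form: str = "offset"      # offset | time_linear
    typical_effect: float = 8.0
    iiv_cv: float = 0.0
    t_ref: float = 36.0
    include_baseline: bool = False  # offset applied at t=0 too?

    def __post_init__(self):
        if self.drug_form not in ("offset", "time_linear"):
            raise ValueError(f"unknown drug_form {self.drug_form!r}")
        if self.typical_effect < 0:
            raise ValueError("typical_effect must be >= 0")
        if self.iiv_cv < 0:
            raise ValueError("iiv_cv must be >= 0")

    @property
    def id(self) -> str:
        tag = "_iiv" if self.iiv_cv > 0 else ""
        return f"{self.drug_form}{tag}_{self.typical_effect:g}"

    def effect_at(self, e_i: float, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.drug_form == "offset":
            on = np.ones_like(t) if self.include_baseline else (t > 0).astype(float)
            return e_i * on
        return e_i * t / self.t_ref

    @classmethod
    def paper_grid(cls) -> list:
        """The eight simulated scenarios: {offset, time_linear} x
        {2, 8 points} x {no IIV, 30% CV}."""
        out = []
        for form in ("offset", "time_linear"):
            for size in (2.0, 8.0):
                for cv in (0.0, 0.30):
                    out.append(cls(drug_form=form, typical_effect=size, iiv_cv=cv))
        return out


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValueError("a seed is required")
    return np.random.default_rng(seed)


def generate_natural_history(config: GeneratorConfig, seed) -> Cohort:
    """Generate an untreated cohort from the linear disease model.

    Per subject: ``baseline = th_base + th_bmms*bmms + eta1``,
    ``slope = th_slope + th_slope_bmms*bmms + eta2``, and
    ``score(t) = baseline + slope*t + latent(t) + eps``. Arm labels are
    initialized to 0 (no allocation yet).
    """
    if config.n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if min(config.om2_base, config.om2_slope, config.sig2) < 0:
        raise ValueError("variances must be >= 0")
    if len(config.schedule) == 0:
        raise ValueError("schedule must not be empty")
    t = np.asarray(sorted(config.schedule), dtype=float)
    if t[0] < 0 or np.any(np.diff(t) <= 0):
        raise ValueError("schedule must be non-negative and strictly increasing")

    rng = _rng(seed)
    n = config.n_subjects
    bmms = rng.normal(config.bmms_mean, config.bmms_sd, size=n)
    eta1 = rng.normal(0.0, np.sqrt(config.om2_base), size=n)
    eta2 = rng.normal(0.0, np.sqrt(config.om2_slope), size=n)
    mis = config.misspec
    if mis.enabled:
        gamma = rng.normal(mis.mean, mis.sd, size=n)
        g_t = mis.shape(t)
    else:
        gamma = np.zeros(n)
        g_t = np.zeros_like(t)
    eps = rng.normal(0.0, np.sqrt(config.sig2), size=(n, len(t)))

    subjects = []
    for i in range(n):
        baseline = config.th_base + config.th_bmms * bmms[i] + eta1[i]
        slope = config.th_slope + config.th_slope_bmms * bmms[i] + eta2[i]
        latent = gamma[i] * g_t
        scores = baseline + slope * t + latent + eps[i]
        if config.clip:
            scores = np.clip(scores, 0.0, 70.0)
        keep = np.ones(len(t), dtype=bool)
        if config.dropout > 0:
            keep[1:] = rng.random(len(t) - 1) >= config.dropout
        visits = [Visit(float(tt), float(ss))
                  for tt, ss, k in zip(t, scores, keep) if k]
        truth = SubjectTruth(
            eta_baseline=float(eta1[i]),
            eta_slope=float(eta2[i]),
            latent_gamma=float(gamma[i]),
            latent_values=tuple(float(v) for v, k in zip(latent, keep) if k),
        )
        subjects.append(Subject(id=i + 1, bmms=float(bmms[i]), trt=0,
                                visits=visits, truth=truth))
    meta = {
        "provenance": "natural",
        "seed": seed if not isinstance(seed, np.random.Generator) else None,
        "generator": config.to_dict(),
        "allocated": False,
    }
    return Cohort(subjects=subjects, meta=meta)


def inject_treatment_effect(cohort: Cohort, scenario: EffectScenario, seed) -> Cohort:
    """Add the scenario's individual effect to treated subjects' scores.

    Placebo-arm subjects are untouched; the per-subject effect and its
    realized eta are recorded in the truth record. Returns a new cohort.
    """
    if not cohort.allocated:
        raise ValueError("cohort has no arm labels; run randomize_allocation first")
    rng = _rng(seed)
    out = copy.deepcopy(cohort)
    sd = scenario.iiv_cv * scenario.typical_effect
    for s in out.subjects:
        if s.trt != 1:
            continue
        eta = float(rng.normal(0.0, sd)) if sd > 0 else 0.0
        e_i = scenario.typical_effect + eta
        t = s.times
        add = scenario.effect_at(e_i, t)
        for v, a in zip(s.visits, add):
            v.score += float(a)
        if s.truth is not None:
            s.truth.drug_eta = eta
            s.truth.effect = tuple(float(a) for a in add)
    out.meta = dict(out.meta)
    out.meta["provenance"] = "effect-injected"
    out.meta["scenario"] = dataclasses.asdict(scenario)
    return out


def randomize_allocation(cohort: Cohort, seed) -> Cohort:
    """1:1 randomization: exactly floor(n/2) / ceil(n/2) subjects per arm,
    uniform over balanced allocations. Returns a new cohort."""
    n = cohort.n_subjects
    if n < 2:
        raise ValueError("need at least 2 subjects to randomize")
    rng = _rng(seed)
    n1 = n // 2
    if n % 2 == 1 and rng.integers(2) == 1:
        n1 += 1
    treated = rng.choice(n, size=n1, replace=False)
    labels = np.zeros(n, dtype=int)
    labels[treated] = 1
    out = copy.deepcopy(cohort)
    for s, lab in zip(out.subjects, labels):
        s.trt = int(lab)
    out.meta = dict(out.meta)
    out.meta["allocated"] = True
    return out


def permute_allocation(cohort: Cohort, seed) -> Cohort:
    """Permute the existing arm labels across subjects; scores untouched."""
    if not cohort.allocated:
        raise ValueError("cohort has no arm labels to permute")
    rng = _rng(seed)
    labels = np.array([s.trt for s in cohort.subjects])
    labels = labels[rng.permutation(len(labels))]
    out = copy.deepcopy(cohort)
    for s, lab in zip(out.subjects, labels):
        s.trt = int(lab)
    out.meta = dict(out.meta)
    out.meta["provenance"] = "permuted"
    return out
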