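"""Battery-level metrics: rejection rates, exact binomial acceptance
bounds, RMSE of treatment-effect estimates, and run-status accounting."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta

__all__ = ["BatteryResult", "rejection_rate", "binomial_acceptance", "rmse",
           "summary_table", "fit_summary_table"]


@dataclass
class BatteryResult:
    """Per-trial decisions and effect estimates over replicate trials.

    For the model-averaging approaches ``decisions`` holds the per-trial H1
    weight fraction in [0, 1]; otherwise booleans. ``excluded`` counts
    trials dropped because of failed fits; rates are computed over the
    remaining trials only.
    """

    approach: str
    scenario: str
    n_trials: int
    decisions: list = field(default_factory=list)
    estimates: list = field(default_factory=list)
    truth: Optional[float] = None
    excluded: int = 0
    is_averaging: bool = False
    details: list = field(default_factory=list)

    @property
    def n_effective(self) -> int:
        return len(self.decisions)


def rejection_rate(battery: BatteryResult) -> float:
    """Percentage of trials rejecting H0 (averaging approaches: the mean H1
    weight fraction, in percent)."""
    if battery.n_effective == 0:
        raise ValueError("all trials excluded; no rate to compute")
    vals = np.asarray(battery.decisions, dtype=float)
    return float(100.0 * vals.mean())


def binomial_acceptance(alpha_nominal: float = 0.05, n_trials: int = 100,
                        level: float = 0.95) -> tuple:
    """Exact (Clopper-Pearson-type) acceptance region, in percent, around
    the nominal rate for an empirical rate over ``n_trials`` replicates.

    Computed via beta quantiles for the observed count k closest to
    ``alpha_nominal * n_trials``: lower = BetaQ((1-level)/2; k, n-k+1),
    upper = BetaQ(1-(1-level)/2; k+1, n-k). For the canonical 5% / 100
    trials this gives (1.64, 11.28).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not (0 < alpha_nominal < 1 and 0 < level < 1):
        raise ValueError("alpha_nominal and level must lie in (0, 1)")
    k = alpha_nominal * n_trials
    tail = (1.0 - level) / 2.0
    lower = beta.ppf(tail, k, n_trials - k + 1) if k > 0 else 0.0
    upper = beta.ppf(1.0 - tail, k + 1, n_trials - k)
    return (100.0 * float(lower), 100.0 * float(upper))


def rmse(estimates: Sequence[float], truth: float) -> float:
    """Root mean squared error of the effect estimates over the
    non-excluded trials."""
    est = np.asarray(list(estimates), dtype=float)
    if est.size == 0:
        raise ValueError("no estimates")
    return float(np.sqrt(np.mean((est - truth) ** 2)))


def fit_summary_table(fits) -> pd.DataFrame:
    """Flat per-model fit summary: model id, OFV, number of estimated
    parameters, AIC, minimization status."""
    rows = [{"model": f.model.id, "ofv": f.ofv, "n_params": f.n_params,
             "aic": f.aic, "status": f.status} for f in fits]
    return pd.DataFrame(rows,
                        columns=["model", "ofv", "n_params", "aic", "status"])


def summary_table(batteries: Sequence[BatteryResult]) -> pd.DataFrame:
    """Flat summary (approach x scenario): rate, RMSE where truth is known,
    and exclusion counts."""
    rows = []
    for b in batteries:
        row = {
            "approach": b.approach,
            "scenario": b.scenario,
            "n_trials": b.n_trials,
            "n_effective": b.n_effective,
            "excluded": b.excluded,
            "rate_pct": rejection_rate(b) if b.n_effective else np.nan,
        }
        if b.truth is not None and b.estimates:
            row["rmse"] = rmse(b.estimates, b.truth)
            row["truth"] = b.truth
        rows.append(row)
    return pd.DataFrame(rows)
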