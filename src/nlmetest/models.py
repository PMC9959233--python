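"""Declarative model specifications and their likelihood building blocks.

A :class:`ModelSpec` describes a placebo structural model, an optional drug
component, the arm(s) the drug applies to, an optional subject-level
mixture, and any parameters held fixed. The functions here translate a spec
into the quantities the estimation engine consumes:

* ``linear_parts`` -- mean vector, random-effect design, variance components
  for models that are linear in Gaussian random effects (closed-form
  marginal likelihood), including a first-order (FO) linearization of the
  disease-modifying-with-IIV drug model;
* ``predict_eta`` / ``residual_var`` / ``prior_neg2ll`` -- the nonlinear
  route consumed by the Laplace approximation.

Placebo forms
-------------
``published_linear``
    baseline + slope * t; baseline = th_base + th_bmms*BMMS + eta1,
    slope = th_slope + th_slope_bmms*BMMS + eta2, additive residual.
``time_exponential``
    baseline + slope * (exp(th_texp * t) - 1).
``iiv_on_ruv``
    linear model with residual SD scaled per subject by exp(eta_ruv).
``boxcox_eta1``
    eta1 passed through (exp(lambda*eta1) - 1) / lambda.
``tdist_eta1``
    eta1 with a scaled t distribution (nu_t estimated).

Drug forms (added for subjects where the component is active)
-------------------------------------------------------------
``offset``            th_de (+ eta_de) at t > 0;
``time_linear``       (th_de (+ eta_de)) * t / 36;
``disease_modifying`` slope multiplied by (1 - (th_de (+ eta_de))).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

PLACEBO_FORMS = ("published_linear", "time_exponential", "iiv_on_ruv",
                 "boxcox_eta1", "tdist_eta1")
DRUG_FORMS = ("offset", "time_linear", "disease_modifying")
APPLIES_TO = ("treated_only", "all", "arm_specific")

T_REF = 36.0  # month scaling of the time-linear drug effect

_PLACEBO_IDS = {"pub": "published_linear", "texp": "time_exponential",
                "ruv": "iiv_on_ruv", "boxcox": "boxcox_eta1",
                "tdist": "tdist_eta1"}
_DRUG_IDS = {"offset": ("offset", False), "offset_iiv": ("offset", True),
             "linear": ("time_linear", False), "linear_iiv": ("time_linear", True),
             "dm": ("disease_modifying", False), "dm_iiv": ("disease_modifying", True)}


@dataclass(frozen=True)
class DrugSpec:
    """A drug model component: functional form plus optional IIV."""

    form: str
    iiv: bool = False

    def __post_init__(self):
        if self.form not in DRUG_FORMS:
            raise ValueError(f"unknown drug form {self.form!r}")

    @property
    def id(self) -> str:
        for key, val in _DRUG_IDS.items():
            if val == (self.form, self.iiv):
                return key
        raise AssertionError

    @property
    def n_extra_params(self) -> int:
        return 2 if self.iiv else 1


@dataclass(frozen=True)
class ModelSpec:
    placebo_form: str = "published_linear"
    drug: Optional[DrugSpec] = None
    drug_applies_to: str = "treated_only"
    mixture: bool = False
    theta_mix_fixed: Optional[float] = None
    fixed: tuple = ()  # ((name, value), ...) parameters held constant

    def __post_init__(self):
        if self.placebo_form not in PLACEBO_FORMS:
            raise ValueError(f"unknown placebo form {self.placebo_form!r}")
        if self.drug_applies_to not in APPLIES_TO:
            raise ValueError(f"unknown drug_applies_to {self.drug_applies_to!r}")
        if self.mixture and self.drug is None:
            raise ValueError("a mixture model requires a drug component")
        if self.theta_mix_fixed is not None:
            if not self.mixture:
                raise ValueError("theta_mix_fixed only applies to mixture models")
            if not 0.0 <= self.theta_mix_fixed <= 1.0:
                raise ValueError("theta_mix_fixed must lie in [0, 1]")

    # -- spec-style accessors -------------------------------------------------
    @property
    def drug_form(self) -> str:
        return self.drug.form if self.drug is not None else "none"

    @property
    def drug_iiv(self) -> bool:
        return bool(self.drug and self.drug.iiv)

    @property
    def fixed_params(self) -> dict:
        d = dict(self.fixed)
        if self.mixture and self.theta_mix_fixed is not None:
            d["th_mix"] = self.theta_mix_fixed
        return d

    @property
    def id(self) -> str:
        plb = {v: k for k, v in _PLACEBO_IDS.items()}[self.placebo_form]
        if self.drug is None:
            return plb
        tag = f"{plb}+{self.drug.id}"
        if self.mixture:
            fix = "0.5fix" if self.theta_mix_fixed is not None else "est"
            return f"ima({tag},{fix})"
        if self.drug_applies_to == "all":
            tag += "@all"
        elif self.drug_applies_to == "arm_specific":
            tag += "@arm"
        return tag

    # -- parameter bookkeeping ------------------------------------------------
    def param_names(self) -> list:
        names = ["th_base", "th_bmms", "th_slope", "th_slope_bmms"]
        if self.placebo_form == "time_exponential":
            names.append("th_texp")
        names += ["om2_base", "om2_slope", "sig2"]
        if self.placebo_form == "iiv_on_ruv":
            names.append("om2_ruv")
        elif self.placebo_form == "boxcox_eta1":
            names.append("bc_lambda")
        elif self.placebo_form == "tdist_eta1":
            names.append("nu_t")
        if self.drug is not None:
            if self.drug_applies_to == "arm_specific":
                names += ["th_de_plb", "th_de_trt"]
                if self.drug.iiv:
                    names += ["om2_de_plb", "om2_de_trt"]
            else:
                names.append("th_de")
                if self.drug.iiv:
                    names.append("om2_de")
        if self.mixture:
            names.append("th_mix")
        return names

    @property
    def n_params(self) -> int:
        """Number of estimated (non-fixed) parameters."""
        fixed = self.fixed_params
        return sum(1 for n in self.param_names() if n not in fixed)

    def is_linear(self) -> bool:
        """True when the marginal likelihood is available in closed form
        (model linear in Gaussian random effects)."""
        if self.placebo_form not in ("published_linear", "time_exponential"):
            return False
        if self.drug is not None and self.drug.form == "disease_modifying" \
                and self.drug.iiv:
            return False
        return True


# -- constructors ------------------------------------------------------------

def published_placebo() -> ModelSpec:
    """The published linear disease model: 4 fixed effects, IIV on baseline
    and slope, additive residual error (7 estimated parameters)."""
    return ModelSpec()


def drug_model(form: str, iiv: bool = False) -> DrugSpec:
    return DrugSpec(form=form, iiv=iiv)


def with_drug(placebo: ModelSpec, drug: DrugSpec,
              applies_to: str = "treated_only") -> ModelSpec:
    return replace(placebo, drug=drug, drug_applies_to=applies_to,
                   mixture=False, theta_mix_fixed=None)


def alternative_placebos() -> list:
    """The four one-component-at-a-time modifications of the published
    model: time-exponential structure, IIV on RUV, Boxcox-transformed eta1,
    t-distributed eta1. Each has exactly one extra estimated parameter."""
    return [ModelSpec(placebo_form=f) for f in
            ("time_exponential", "iiv_on_ruv", "boxcox_eta1", "tdist_eta1")]


def mixture_model(placebo: ModelSpec, drug: DrugSpec,
                  theta_mix_fixed: Optional[float] = None) -> ModelSpec:
    """Subject-level two-component mixture: component 1 is the placebo
    model, component 2 the placebo plus drug model (both arms). Component
    probabilities depend on the arm: Pr(comp 1) = (1-TRT)*th_mix +
    TRT*(1-th_mix); with ``theta_mix_fixed`` given, th_mix is constant
    (the null configuration)."""
    return replace(placebo, drug=drug, mixture=True,
                   theta_mix_fixed=theta_mix_fixed,
                   drug_applies_to="treated_only")


def get_model(model_id: str) -> ModelSpec:
    """Resolve a registry id like ``pub``, ``pub+offset_iiv``, ``boxcox``,
    ``texp+dm`` into a ModelSpec (drug applied to the treated arm)."""
    parts = model_id.split("+")
    if parts[0] not in _PLACEBO_IDS:
        raise KeyError(f"unknown placebo id {parts[0]!r} in {model_id!r}")
    spec = ModelSpec(placebo_form=_PLACEBO_IDS[parts[0]])
    if len(parts) == 1:
        return spec
    if len(parts) != 2 or parts[1] not in _DRUG_IDS:
        raise KeyError(f"unknown model id {model_id!r}")
    form, iiv = _DRUG_IDS[parts[1]]
    return with_drug(spec, DrugSpec(form, iiv))


def get_drug(drug_id: str) -> DrugSpec:
    if drug_id not in _DRUG_IDS:
        raise KeyError(f"unknown drug id {drug_id!r}")
    form, iiv = _DRUG_IDS[drug_id]
    return DrugSpec(form, iiv)


# -- likelihood building blocks ----------------------------------------------

def _drug_param(spec: ModelSpec, p: dict, trt: int, name: str) -> float:
    if spec.drug_applies_to == "arm_specific":
        return p[f"{name}_{'trt' if trt else 'plb'}"]
    return p[name]


def time_basis(spec: ModelSpec, p: dict, t: np.ndarray) -> np.ndarray:
    if spec.placebo_form == "time_exponential":
        return np.expm1(p["th_texp"] * t)
    return t


def drug_regressor(form: str, t: np.ndarray) -> np.ndarray:
    if form == "offset":
        return (t > 0).astype(float)
    if form == "time_linear":
        return t / T_REF
    raise ValueError(form)


def boxcox_eta(eta: np.ndarray, lam: float) -> np.ndarray:
    """(exp(lambda*eta) - 1)/lambda, with the lambda->0 limit eta."""
    if abs(lam) < 1e-8:
        return eta
    return np.expm1(lam * eta) / lam


class LinStruct:
    """Linear-Gaussian structure of one subject group:
    y_i ~ N(mean_i + Z eta_i, sigma2 I), eta_i ~ N(0, diag(omega))."""

    __slots__ = ("mean", "Z", "omega", "sig2")

    def __init__(self, mean, Z, omega, sig2):
        self.mean = mean      # (m, n)
        self.Z = Z            # (n, q) shared or (m, n, q) subject-specific
        self.omega = omega    # (q,)
        self.sig2 = sig2      # scalar


def linear_parts(spec: ModelSpec, p: dict, group, drug_on: bool,
                 allow_fo: bool = False) -> LinStruct:
    """Mean / design / variance components for the closed-form route.

    ``allow_fo`` permits the first-order linearization (expansion of the
    random effects at zero) of the disease-modifying + IIV model, whose
    eta_slope*eta_drug cross term is otherwise not linear-Gaussian.
    """
    if spec.placebo_form not in ("published_linear", "time_exponential"):
        raise ValueError(f"{spec.placebo_form} has no linear-Gaussian form")
    t = group.times
    n = len(t)
    h = time_basis(spec, p, t)
    base = p["th_base"] + p["th_bmms"] * group.bmms            # (m,)
    slope = p["th_slope"] + p["th_slope_bmms"] * group.bmms    # (m,)
    zcols = [np.ones(n), h]
    omega = [p["om2_base"], p["om2_slope"]]
    mean = base[:, None] + slope[:, None] * h[None, :]
    z_subject = None  # (m, n, extra) columns that differ per subject

    if drug_on and spec.drug is not None:
        form, iiv = spec.drug.form, spec.drug.iiv
        th_de = _drug_param(spec, p, group.trt, "th_de")
        if form in ("offset", "time_linear"):
            d = drug_regressor(form, t)
            mean = mean + th_de * d[None, :]
            if iiv:
                zcols.append(d)
                omega.append(_drug_param(spec, p, group.trt, "om2_de"))
        else:  # disease_modifying
            fac = 1.0 - th_de
            mean = base[:, None] + fac * slope[:, None] * h[None, :]
            zcols[1] = fac * h
            if iiv:
                if not allow_fo:
                    raise ValueError(
                        "disease_modifying with IIV is not linear-Gaussian; "
                        "use the Laplace route or allow_fo=True")
                # FO linearization at eta=0 with the random-effect design
                # evaluated at the typical subject: the drug slope-IIV
                # collapses into an added slope-variance component for the
                # groups where the drug is active (om2_de is then in
                # slope-variance units).
                zcols.append(h)
                omega.append(_drug_param(spec, p, group.trt, "om2_de"))

    Z = np.column_stack(zcols)  # (n, q_shared)
    if z_subject is not None:
        m = len(group.bmms)
        Z = np.concatenate(
            [np.broadcast_to(Z, (m, n, Z.shape[1])), z_subject], axis=2)
    return LinStruct(mean, Z, np.asarray(omega, dtype=float), p["sig2"])


def profiled_design(spec: ModelSpec, p: dict, group, drug_on: bool):
    """Design columns of the fixed effects that enter the mean linearly
    (for GLS profiling), in the order given by ``profiled_names``.

    Columns for drug parameters inactive in this group are zero so that a
    single stacked design is shared across groups.
    """
    t = group.times
    h = time_basis(spec, p, t)
    b = group.bmms
    m, n = len(b), len(t)
    ones_t = np.ones(n)
    fac = 1.0
    if drug_on and spec.drug is not None and \
            spec.drug.form == "disease_modifying":
        fac = 1.0 - _drug_param(spec, p, group.trt, "th_de")
    cols = []
    for name in profiled_names(spec):
        if name == "th_base":
            cols.append(np.broadcast_to(ones_t, (m, n)))
        elif name == "th_bmms":
            cols.append(np.broadcast_to(b[:, None] * ones_t, (m, n)))
        elif name == "th_slope":
            cols.append(fac * np.broadcast_to(h, (m, n)))
        elif name == "th_slope_bmms":
            cols.append(fac * (b[:, None] * h[None, :]))
        else:  # a th_de variant
            d = np.zeros((m, n))
            if drug_on and spec.drug is not None and \
                    spec.drug.form in ("offset", "time_linear"):
                reg = drug_regressor(spec.drug.form, t)
                if spec.drug_applies_to == "arm_specific":
                    want = "th_de_trt" if group.trt == 1 else "th_de_plb"
                    if name == want:
                        d = np.broadcast_to(reg, (m, n)).copy()
                elif name == "th_de":
                    d = np.broadcast_to(reg, (m, n)).copy()
            cols.append(d)
    return np.stack(cols, axis=2)  # (m, n, p_lin)


def profiled_names(spec: ModelSpec) -> list:
    """Fixed effects that can be concentrated out by GLS (linear in the
    mean). th_de of the disease-modifying form and th_texp are nonlinear
    and stay with the outer optimizer; with the FO-linearized
    disease-modifying + IIV model the slope fixed effects also stay outer
    (they enter the linearized random-effect design); mixture models
    profile nothing."""
    if spec.mixture:
        return []
    fo_dm_iiv = (spec.drug is not None
                 and spec.drug.form == "disease_modifying" and spec.drug.iiv
                 and spec.placebo_form in ("published_linear",
                                           "time_exponential"))
    if not spec.is_linear() and not fo_dm_iiv:
        return []
    names = ["th_base", "th_bmms", "th_slope", "th_slope_bmms"]
    if spec.drug is not None and \
            spec.drug.form in ("offset", "time_linear"):
        if spec.drug_applies_to == "arm_specific":
            names += ["th_de_plb", "th_de_trt"]
        else:
            names.append("th_de")
    fixed = spec.fixed_params
    return [nm for nm in names if nm not in fixed]


def omega_names(spec: ModelSpec, trt: int, drug_on: bool) -> list:
    """Names of the variance components behind the random-effect design
    columns of ``linear_parts``, in column order."""
    names = ["om2_base", "om2_slope"]
    if drug_on and spec.drug is not None and spec.drug.iiv:
        if spec.drug_applies_to == "arm_specific":
            names.append("om2_de_trt" if trt == 1 else "om2_de_plb")
        else:
            names.append("om2_de")
    return names


# -- nonlinear (Laplace) route ------------------------------------------------

def eta_names(spec: ModelSpec, drug_on: bool) -> list:
    names = ["eta_base", "eta_slope"]
    if spec.placebo_form == "iiv_on_ruv":
        names.append("eta_ruv")
    if drug_on and spec.drug is not None and spec.drug.iiv:
        names.append("eta_de")
    return names


def eta_variances(spec: ModelSpec, p: dict, group, drug_on: bool) -> np.ndarray:
    om = [p["om2_base"], p["om2_slope"]]
    if spec.placebo_form == "iiv_on_ruv":
        om.append(p["om2_ruv"])
    if drug_on and spec.drug is not None and spec.drug.iiv:
        om.append(_drug_param(spec, p, group.trt, "om2_de"))
    return np.asarray(om, dtype=float)


def predict_eta(spec: ModelSpec, p: dict, group, eta: np.ndarray,
                drug_on: bool) -> np.ndarray:
    """Model prediction (m, n) given per-subject random effects (m, q)."""
    t = group.times
    h = time_basis(spec, p, t)
    e1 = eta[:, 0]
    if spec.placebo_form == "boxcox_eta1":
        e1 = boxcox_eta(e1, p["bc_lambda"])
    base = p["th_base"] + p["th_bmms"] * group.bmms + e1
    slope = p["th_slope"] + p["th_slope_bmms"] * group.bmms + eta[:, 1]
    pred = base[:, None] + slope[:, None] * h[None, :]
    if drug_on and spec.drug is not None:
        form, iiv = spec.drug.form, spec.drug.iiv
        de = _drug_param(spec, p, group.trt, "th_de")
        if iiv:
            de = de + eta[:, -1]
        else:
            de = np.full(eta.shape[0], de)
        if form in ("offset", "time_linear"):
            d = drug_regressor(form, t)
            pred = pred + de[:, None] * d[None, :]
        else:
            pred = base[:, None] + ((1.0 - de) * slope)[:, None] * h[None, :]
    return pred


def residual_var(spec: ModelSpec, p: dict, eta: np.ndarray):
    """Residual variance: scalar, or (m, 1) when IIV on RUV is active."""
    if spec.placebo_form == "iiv_on_ruv":
        return p["sig2"] * np.exp(2.0 * eta[:, 2])[:, None]
    return p["sig2"]


_LOG_2PI = float(np.log(2.0 * np.pi))


def prior_neg2ll(spec: ModelSpec, p: dict, group, eta: np.ndarray,
                 drug_on: bool) -> np.ndarray:
    """-2 log density of the random effects, per subject (m,)."""
    om = eta_variances(spec, p, group, drug_on)
    om = np.maximum(om, 1e-12)
    out = np.sum(eta**2 / om + np.log(om) + _LOG_2PI, axis=1)
    if spec.placebo_form == "tdist_eta1":
        # replace the Gaussian eta1 term with a scaled-t log density
        from scipy.special import gammaln
        nu = p["nu_t"]
        s2 = om[0]
        e1 = eta[:, 0]
        gauss = e1**2 / s2 + np.log(s2) + _LOG_2PI
        logt = (gammaln((nu + 1) / 2) - gammaln(nu / 2)
                - 0.5 * np.log(nu * np.pi * s2)
                - (nu + 1) / 2 * np.log1p(e1**2 / (nu * s2)))
        out = out - gauss - 2.0 * logt
    return out


def mixture_prob_comp1(spec: ModelSpec, p: dict, trt: int) -> float:
    """Pr(component 1 = placebo) as a function of the arm label:
    (1 - TRT) * th_mix + TRT * (1 - th_mix)."""
    th = spec.theta_mix_fixed if spec.theta_mix_fixed is not None else p["th_mix"]
    return (1 - trt) * th + trt * (1.0 - th)


def ima_effect_estimate(th_mix: float, th_de: float) -> float:
    """Population treatment effect implied by the mixture fit:
    (2*th_mix - 1) * th_de."""
    return (2.0 * th_mix - 1.0) * th_de
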