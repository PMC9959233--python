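"""Maximum-likelihood estimation of mixed-effects models on a cohort.

Three likelihood routes share one interface:

``exact``
    closed-form multivariate-normal marginal likelihood for models linear
    in Gaussian random effects, with the linear fixed effects concentrated
    out by generalized least squares inside the outer optimization;
``laplace``
    Laplace approximation around the per-subject empirical-Bayes mode
    (batched damped Newton, numeric derivatives) for the nonlinear models;
``fo``
    the exact machinery applied to a first-order linearization (random
    effects expanded at zero) -- identical to ``exact`` for linear models,
    and the fast approximation of the disease-modifying + IIV drug model.

Subject-level mixture models combine two per-subject component likelihoods
(each computed by the routes above) with arm-dependent component
probabilities.

The objective function value (OFV) is -2 log marginal likelihood; AIC is
OFV + 2 * n_params.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize
from scipy.stats import chi2

from . import models as M
from .cohort import Cohort
from .models import ModelSpec

_LOG_2PI = float(np.log(2.0 * np.pi))
VAR_FLOOR = 1e-10

__all__ = [
    "SubjectGroup", "CohortData", "as_data",
    "FitOptions", "FitResult",
    "marginal_ofv", "fit", "delta_ofv", "chi2_critical", "aic",
    "simulate_cohort_data",
]


# ---------------------------------------------------------------------------
# data layout
# ---------------------------------------------------------------------------

class SubjectGroup:
    """Subjects sharing one visit pattern and one arm label, stacked."""

    __slots__ = ("times", "trt", "y", "bmms", "idx")

    def __init__(self, times, trt, y, bmms, idx):
        self.times = times  # (n,)
        self.trt = int(trt)
        self.y = y          # (m, n)
        self.bmms = bmms    # (m,)
        self.idx = idx      # (m,) global subject indices

    @property
    def m(self):
        return self.y.shape[0]

    @property
    def n(self):
        return self.y.shape[1]


class CohortData:
    """Array-backed view of a cohort, grouped by visit pattern; cheap to
    re-label (permutation replicates only swap the arm vector)."""

    def __init__(self, patterns, Ys, rows, bmms, trt, ids):
        self.patterns = patterns  # list[(n,) times]
        self.Ys = Ys              # list[(mp, n)] scores per pattern
        self.rows = rows          # list[(mp,) global subject indices]
        self.bmms = np.asarray(bmms, dtype=float)
        self.trt = np.asarray(trt, dtype=int)
        self.ids = list(ids)

    @classmethod
    def from_cohort(cls, cohort: Cohort) -> "CohortData":
        buckets = {}
        bmms, trt, ids = [], [], []
        for gi, s in enumerate(cohort.subjects):
            key = tuple(s.times.tolist())
            buckets.setdefault(key, ([], []))
            buckets[key][0].append(s.scores)
            buckets[key][1].append(gi)
            bmms.append(s.bmms)
            trt.append(s.trt)
            ids.append(s.id)
        patterns, Ys, rows = [], [], []
        for key, (scores, idx) in buckets.items():
            patterns.append(np.asarray(key, dtype=float))
            Ys.append(np.vstack(scores))
            rows.append(np.asarray(idx, dtype=int))
        return cls(patterns, Ys, rows, bmms, trt, ids)

    @property
    def n_subjects(self) -> int:
        return len(self.bmms)

    @property
    def n_obs(self) -> int:
        return sum(y.size for y in self.Ys)

    def groups(self) -> list:
        out = []
        for times, Y, idx in zip(self.patterns, self.Ys, self.rows):
            arm = self.trt[idx]
            for a in (0, 1):
                mask = arm == a
                if mask.any():
                    out.append(SubjectGroup(times, a, Y[mask],
                                            self.bmms[idx[mask]], idx[mask]))
        return out

    def reallocate(self, trt) -> "CohortData":
        trt = np.asarray(trt, dtype=int)
        if trt.shape != self.trt.shape:
            raise ValueError("arm label vector has wrong length")
        return CohortData(self.patterns, self.Ys, self.rows,
                          self.bmms, trt, self.ids)

    def permuted(self, rng: np.random.Generator) -> "CohortData":
        return self.reallocate(self.trt[rng.permutation(self.n_subjects)])


def as_data(cohort) -> CohortData:
    if isinstance(cohort, CohortData):
        return cohort
    return CohortData.from_cohort(cohort)


# ---------------------------------------------------------------------------
# parameter transforms
# ---------------------------------------------------------------------------

def _is_variance(name: str) -> bool:
    return name.startswith("om2") or name == "sig2"


def to_internal(name: str, v: float) -> float:
    if _is_variance(name):
        return math.log(max(v, VAR_FLOOR))
    if name == "th_mix":
        v = min(max(v, 1e-7), 1 - 1e-7)
        return math.log(v / (1 - v))
    if name == "nu_t":
        return math.log(max(v - 2.0, 1e-6))
    return v


def from_internal(name: str, x: float) -> float:
    if _is_variance(name):
        return math.exp(x)
    if name == "th_mix":
        return 1.0 / (1.0 + math.exp(-x))
    if name == "nu_t":
        return 2.0 + math.exp(x)
    return x


def internal_bounds(name: str):
    if _is_variance(name):
        return (math.log(VAR_FLOOR), math.log(1e8))
    if name == "th_mix":
        return (-15.0, 15.0)
    if name == "nu_t":
        return (math.log(1e-6), math.log(1e12))
    return (None, None)


def validate_params(spec: ModelSpec, p: dict) -> None:
    for name in spec.param_names():
        if name not in p:
            raise ValueError(f"missing parameter {name!r}")
        v = p[name]
        if _is_variance(name) and v < 0:
            raise ValueError(f"{name} must be >= 0")
        if name == "sig2" and v <= 0:
            raise ValueError("sig2 must be > 0")
        if name == "th_mix" and not 0.0 <= v <= 1.0:
            raise ValueError("th_mix must lie in [0, 1]")
        if name == "nu_t" and v <= 2.0:
            raise ValueError("nu_t must exceed 2")


# ---------------------------------------------------------------------------
# closed-form route
# ---------------------------------------------------------------------------

def _lin_neg2ll_group(ls: M.LinStruct, y: np.ndarray) -> np.ndarray:
    """-2 log likelihood per subject for one linear-Gaussian group."""
    R = y - ls.mean
    n = y.shape[1]
    if ls.Z.ndim == 2:
        S = (ls.Z * ls.omega) @ ls.Z.T + ls.sig2 * np.eye(n)
        L = np.linalg.cholesky(S)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        W = solve_triangular(L, R.T, lower=True, check_finite=False)
        quad = np.einsum("nm,nm->m", W, W)
        return n * _LOG_2PI + logdet + quad
    S = np.einsum("mnq,q,mkq->mnk", ls.Z, ls.omega, ls.Z)
    ii = np.arange(n)
    S[:, ii, ii] += ls.sig2
    L = np.linalg.cholesky(S)
    logdet = 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)), axis=1)
    X = np.linalg.solve(S, R[:, :, None])[:, :, 0]
    quad = np.einsum("mn,mn->m", R, X)
    return n * _LOG_2PI + logdet + quad


def _group_precision(ls: M.LinStruct, n: int, m: int):
    """(P, total_logdet) of the marginal covariance for GLS profiling."""
    if ls.Z.ndim == 2:
        S = (ls.Z * ls.omega) @ ls.Z.T + ls.sig2 * np.eye(n)
        c = cho_factor(S, lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(c[0])))
        P = cho_solve(c, np.eye(n))
        return P, m * logdet
    S = np.einsum("mnq,q,mkq->mnk", ls.Z, ls.omega, ls.Z)
    ii = np.arange(n)
    S[:, ii, ii] += ls.sig2
    L = np.linalg.cholesky(S)
    logdet = 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)))
    P = np.linalg.inv(S)
    return P, logdet


def _profiled_ofv(spec: ModelSpec, p: dict, groups, drug_on_fn,
                  allow_fo: bool):
    """OFV with the linear fixed effects concentrated out by GLS.

    The profiled parameters must be set to zero in ``p``; returns
    (ofv, beta_hat, names). Generic fallback for profiled specs the
    whitened fast path does not cover (e.g. the time-exponential placebo).
    """
    names = M.profiled_names(spec)
    k = len(names)
    XtX = np.zeros((k, k))
    Xty = np.zeros(k)
    cache = []
    total = 0.0
    items = []
    for g in groups:
        on = drug_on_fn(g)
        ls = M.linear_parts(spec, p, g, on, allow_fo=allow_fo)
        A = M.profiled_design(spec, p, g, on)           # (m, n, k)
        items.append((g, g.y - ls.mean, ls.Z, ls.omega, A))
    sig2 = p["sig2"]
    for g, R0, Z, omega, A in items:
        ls = M.LinStruct(None, Z, omega, sig2)
        P, logdet = _group_precision(ls, g.n, g.m)
        if P.ndim == 2:
            AtP = np.einsum("mnp,nk->mkp", A, P)
        else:
            AtP = np.einsum("mnp,mnk->mkp", A, P)
        XtX += np.einsum("mkp,mkq->pq", AtP, A)
        Xty += np.einsum("mkp,mk->p", AtP, R0)
        cache.append((A, R0, P, logdet, g))
        total += g.m * g.n * _LOG_2PI + logdet
    beta = np.linalg.lstsq(XtX, Xty, rcond=None)[0]
    for A, R0, P, logdet, g in cache:
        R = R0 - A @ beta
        if P.ndim == 2:
            quad = np.einsum("mn,nk,mk->", R, P, R)
        else:
            quad = np.einsum("mn,mnk,mk->", R, P, R)
        total += quad
    return total, beta, names


def _prebuild_profiled(spec: ModelSpec, groups, drug_on_fn,
                       allow_fo: bool = False):
    """Prebuilt per-group structures for the whitened GLS fast path.

    Covers the published-linear placebo with any drug form (the
    disease-modifying factor (1 - th_de) only rescales fixed column
    slices, applied per evaluation). Returns None when unsupported.
    """
    if spec.mixture or spec.placebo_form != "published_linear":
        return None
    prof = M.profiled_names(spec)
    if not prof:
        return None
    zero = {nm: 0.0 for nm in spec.param_names()}
    zero["sig2"] = 1.0
    dm = spec.drug is not None and spec.drug.form == "disease_modifying"
    scale_idx = [i for i, nm in enumerate(prof)
                 if nm in ("th_slope", "th_slope_bmms")] if dm else []
    items = []
    for g in groups:
        on = drug_on_fn(g)
        try:
            ls = M.linear_parts(spec, zero, g, on, allow_fo=allow_fo)
        except ValueError:
            return None
        A = M.profiled_design(spec, zero, g, on)        # (m, n, k) raw
        A3 = np.ascontiguousarray(A.transpose(1, 0, 2))  # (n, m, k)
        if ls.Z.ndim != 2:
            return None
        m, n = g.m, g.n
        k = A3.shape[2]
        y2 = np.ascontiguousarray(g.y.T)                 # (n, m)
        items.append({
            "g": g,
            "Z": ls.Z,                                   # (n, q) raw
            "om_names": M.omega_names(spec, g.trt, on),
            "rhs": np.concatenate([A3.reshape(n, m * k), y2], axis=1),
            "Ar": A3.reshape(n * m, k),
            "y2": y2,
            "dm_on": dm and on,
            "scale_idx": scale_idx,
            "k": k,
        })
    return items


def _fast_profiled_ofv(spec: ModelSpec, p: dict, prebuilt):
    """GLS profiling in normal-equation form: one Cholesky (log-det) and
    one linear solve per group per evaluation; the residual quadratic form
    comes from the identity y'Py - 2 b'X'Py + b'X'PX b."""
    k = prebuilt[0]["k"]
    XtX = np.zeros((k, k))
    Xty = np.zeros(k)
    total = 0.0
    cache = []
    sig2 = p["sig2"]
    for it in prebuilt:
        g = it["g"]
        m, n = g.m, g.n
        Z = it["Z"]
        if it["dm_on"]:
            fac = 1.0 - M._drug_param(spec, p, g.trt, "th_de")
            Z = Z.copy()
            Z[:, 1] *= fac
        omega = [p[nm] for nm in it["om_names"]]
        S = (Z * omega) @ Z.T
        S.flat[:: n + 1] += sig2
        L = np.linalg.cholesky(S)
        T = solve_triangular(L, it["rhs"], lower=True, check_finite=False)
        mk = m * k
        TA = T[:, :mk].reshape(n * m, k)
        Ty = T[:, mk:].reshape(n * m)
        G = TA.T @ TA
        v = TA.T @ Ty
        d = None
        if it["dm_on"] and it["scale_idx"]:
            # column rescaling of the design commutes with the solve
            d = np.ones(k)
            d[it["scale_idx"]] = fac
            G = d[:, None] * G * d[None, :]
            v = d * v
        XtX += G
        Xty += v
        cache.append((TA, Ty, d))
        total += m * n * _LOG_2PI + 2.0 * m * np.sum(np.log(np.diag(L)))
    try:
        beta = np.linalg.solve(XtX, Xty)
        # ill-conditioned normal equations (e.g. a deliberately redundant
        # drug term) fall back to the min-norm solution on the ridge
        if not np.isfinite(beta).all() or \
                np.abs(XtX @ beta - Xty).max() > 1e-6 * (1 + np.abs(Xty).max()):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(XtX, Xty, rcond=None)[0]
    for TA, Ty, d in cache:
        b = beta if d is None else d * beta
        r = Ty - TA @ b
        total += float(r @ r)
    return total, beta


def _fast_profiled_ofv_grad(spec: ModelSpec, p: dict, prebuilt, outer):
    """Profiled OFV and its analytic gradient on the transformed outer
    scale (log for variances; natural for the disease-modifying th_de).

    With the fixed effects concentrated out, the envelope theorem makes
    the outer gradient the partial derivative at beta-hat:
    d OFV / d v = m * tr(S^-1 dS) - sum_i r_i' S^-1 dS S^-1 r_i, plus a
    mean term for the disease-modifying factor.
    """
    k = prebuilt[0]["k"]
    XtX = np.zeros((k, k))
    Xty = np.zeros(k)
    total = 0.0
    cache = []
    sig2 = p["sig2"]
    for it in prebuilt:
        g = it["g"]
        m, n = g.m, g.n
        Z = it["Z"]
        fac = 1.0
        if it["dm_on"]:
            fac = 1.0 - M._drug_param(spec, p, g.trt, "th_de")
            Z = Z.copy()
            Z[:, 1] *= fac
        omega = [p[nm] for nm in it["om_names"]]
        S = (Z * omega) @ Z.T
        S.flat[:: n + 1] += sig2
        L = np.linalg.cholesky(S)
        T = solve_triangular(L, it["rhs"], lower=True, check_finite=False)
        mk = m * k
        TA = T[:, :mk].reshape(n * m, k)
        Ty = T[:, mk:].reshape(n * m)
        G = TA.T @ TA
        v = TA.T @ Ty
        d = None
        if it["dm_on"] and it["scale_idx"]:
            d = np.ones(k)
            d[it["scale_idx"]] = fac
            G = d[:, None] * G * d[None, :]
            v = d * v
        XtX += G
        Xty += v
        cache.append((it, L, Z, TA, Ty, d, fac, omega))
        total += m * n * _LOG_2PI + 2.0 * m * np.sum(np.log(np.diag(L)))
    try:
        beta = np.linalg.solve(XtX, Xty)
        if not np.isfinite(beta).all() or \
                np.abs(XtX @ beta - Xty).max() > 1e-6 * (1 + np.abs(Xty).max()):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(XtX, Xty, rcond=None)[0]

    grad = dict.fromkeys(outer, 0.0)
    for it, L, Z, TA, Ty, d, fac, omega in cache:
        g = it["g"]
        m, n = g.m, g.n
        b = beta if d is None else d * beta
        W = (Ty - TA @ b).reshape(n, m)       # whitened residuals, L^-1 r_i
        total += float((W ** 2).sum())
        Linv = solve_triangular(L, np.eye(n), lower=True, check_finite=False)
        Zw = Linv @ Z                          # (n, q) whitened Z columns
        # variance components
        for j, nm in enumerate(it["om_names"]):
            if nm not in grad:
                continue
            zw = Zw[:, j]
            dv = m * float(zw @ zw) - float(((zw @ W) ** 2).sum())
            grad[nm] += dv * max(p[nm], VAR_FLOOR)    # log-scale chain rule
        if "sig2" in grad:
            V = Linv.T @ W                     # S^-1 r_i, all subjects
            dv = m * float((Linv ** 2).sum()) - float((V ** 2).sum())
            grad["sig2"] += dv * sig2
        # disease-modifying factor
        if it["dm_on"]:
            de_name = "th_de"
            if spec.drug_applies_to == "arm_specific":
                de_name = "th_de_trt" if g.trt == 1 else "th_de_plb"
            if de_name in grad:
                h = it["Z"][:, 1]              # raw slope regressor
                hw = Linv @ h
                hwW = hw @ W                   # (m,)
                ds = -2.0 * fac * omega[1] * (m * float(hw @ hw)
                                              - float((hwW ** 2).sum()))
                # mean term: d mu_i / d th_de = -slope_i * h
                names = M.profiled_names(spec)
                i_s = names.index("th_slope")
                i_sb = names.index("th_slope_bmms")
                slope_i = beta[i_s] + beta[i_sb] * g.bmms
                dmean = 2.0 * float((slope_i * hwW).sum())
                grad[de_name] += ds + dmean
    return total, beta, np.array([grad[nm] for nm in outer])


# ---------------------------------------------------------------------------
# Laplace route
# ---------------------------------------------------------------------------

def _laplace_neg2ll_group(spec: ModelSpec, p: dict, g: SubjectGroup,
                          drug_on: bool, eta0: Optional[np.ndarray] = None,
                          max_newton: int = 60, gtol: float = 1e-7):
    """Per-subject -2 log marginal likelihood by Laplace approximation.

    Batched damped Newton over all subjects of the group at once; numeric
    central-difference derivatives (exact to rounding for models quadratic
    in eta, which makes Laplace coincide with the closed form on
    linear-Gaussian models).
    """
    q = len(M.eta_names(spec, drug_on))
    m, n = g.m, g.n
    y = g.y

    def gfun(eta):
        f = M.predict_eta(spec, p, g, eta, drug_on)
        v = M.residual_var(spec, p, eta)
        r2 = (y - f) ** 2
        if np.ndim(v) == 0:
            res = r2.sum(axis=1) / v + n * (math.log(v) + _LOG_2PI)
        else:
            res = (r2 / v).sum(axis=1) + n * (np.log(v[:, 0]) + _LOG_2PI)
        return res + M.prior_neg2ll(spec, p, g, eta, drug_on)

    eta = np.zeros((m, q)) if eta0 is None else eta0.copy()
    h = 1e-4
    g0 = gfun(eta)
    converged = False
    for _ in range(max_newton):
        grad = np.empty((m, q))
        gp = np.empty((m, q))
        gm = np.empty((m, q))
        for k in range(q):
            ep = eta.copy(); ep[:, k] += h
            em = eta.copy(); em[:, k] -= h
            gp[:, k] = gfun(ep)
            gm[:, k] = gfun(em)
            grad[:, k] = (gp[:, k] - gm[:, k]) / (2 * h)
        H = np.empty((m, q, q))
        for k in range(q):
            H[:, k, k] = (gp[:, k] + gm[:, k] - 2 * g0) / h**2
        for k in range(q):
            for l in range(k + 1, q):
                epp = eta.copy(); epp[:, k] += h; epp[:, l] += h
                epm = eta.copy(); epm[:, k] += h; epm[:, l] -= h
                emp = eta.copy(); emp[:, k] -= h; emp[:, l] += h
                emm = eta.copy(); emm[:, k] -= h; emm[:, l] -= h
                off = (gfun(epp) - gfun(epm) - gfun(emp) + gfun(emm)) / (4 * h**2)
                H[:, k, l] = off
                H[:, l, k] = off
        if np.max(np.abs(grad)) < gtol:
            converged = True
            break
        # positive-definite regularization
        ev = np.linalg.eigvalsh(H)
        ridge = np.maximum(0.0, 1e-6 - ev[:, 0])
        Hreg = H + ridge[:, None, None] * np.eye(q)
        step = np.linalg.solve(Hreg, grad[:, :, None])[:, :, 0]
        alpha = np.ones(m)
        for _bt in range(25):
            trial = eta - alpha[:, None] * step
            gt = gfun(trial)
            worse = gt > g0 + 1e-12
            if not worse.any():
                break
            alpha[worse] *= 0.5
        eta = eta - alpha[:, None] * step
        g0 = gfun(eta)
    # final curvature at the mode
    ev = np.linalg.eigvalsh(H)
    ev = np.maximum(ev, 1e-12)
    logdet_half = np.sum(np.log(ev / 2.0), axis=1)
    neg2ll = g0 - q * _LOG_2PI + logdet_half
    if not converged and np.max(np.abs(grad)) > 1e-2:
        raise FloatingPointError("inner Laplace optimization did not converge")
    return neg2ll, eta


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def _drug_active(spec: ModelSpec, group: SubjectGroup) -> bool:
    if spec.drug is None:
        return False
    if spec.drug_applies_to == "treated_only":
        return group.trt == 1
    return True  # "all" and "arm_specific" apply in both arms


def resolve_route(spec: ModelSpec, route: str) -> str:
    if route == "auto":
        return "exact" if spec.is_linear() else "laplace"
    if route not in ("exact", "laplace", "fo"):
        raise ValueError(f"unknown route {route!r}")
    return route


def _component_neg2ll(spec, p, g, drug_on, route, eta_cache=None, key=None):
    if route in ("exact", "fo"):
        ls = M.linear_parts(spec, p, g, drug_on, allow_fo=(route == "fo"))
        return _lin_neg2ll_group(ls, g.y)
    eta0 = eta_cache.get(key) if eta_cache is not None else None
    vals, eta = _laplace_neg2ll_group(spec, p, g, drug_on, eta0=eta0)
    if eta_cache is not None:
        eta_cache[key] = eta
    return vals


def _neg2ll_total(spec: ModelSpec, p: dict, groups, route: str,
                  eta_cache=None) -> float:
    total = 0.0
    for gi, g in enumerate(groups):
        if spec.mixture:
            l1 = _component_neg2ll(spec, p, g, False, route,
                                   eta_cache, (gi, 0))
            l2 = _component_neg2ll(spec, p, g, True, route,
                                   eta_cache, (gi, 1))
            pr1 = M.mixture_prob_comp1(spec, p, g.trt)
            pr1 = min(max(pr1, 0.0), 1.0)
            if pr1 <= 0.0:
                vals = l2
            elif pr1 >= 1.0:
                vals = l1
            else:
                a = math.log(pr1) - l1 / 2.0
                b = math.log1p(-pr1) - l2 / 2.0
                vals = -2.0 * np.logaddexp(a, b)
        else:
            vals = _component_neg2ll(spec, p, g, _drug_active(spec, g),
                                     route, eta_cache, (gi, 0))
        total += float(vals.sum())
    return total


def marginal_ofv(model: ModelSpec, cohort, params: dict,
                 route: str = "auto") -> float:
    """-2 log marginal likelihood of the cohort under ``params``.
    Parameters held fixed by the spec may be omitted from ``params``."""
    params = {**model.fixed_params, **params}
    validate_params(model, params)
    data = as_data(cohort)
    route = resolve_route(model, route)
    return _neg2ll_total(model, params, data.groups(), route)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitOptions:
    route: str = "auto"
    maxiter: int = 400
    n_starts: int = 3
    jitter: float = 0.3
    seed: int = 0
    pgtol: float = 1e-5
    ftol: float = 1e-9   # relative; passed to L-BFGS-B


@dataclass
class FitResult:
    """A maximum-likelihood fit: parameter estimates, OFV, status."""

    model: ModelSpec
    params: dict
    ofv: float
    n_params: int
    status: str                    # "converged" | "failed"
    diagnostics: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return self.status == "converged"

    @property
    def aic(self) -> float:
        return self.ofv + 2.0 * self.n_params


def aic(ofv: float, n_params: int) -> float:
    """Akaike information criterion, OFV + 2 * n_params."""
    return ofv + 2.0 * n_params


def default_inits(spec: ModelSpec, data: CohortData) -> dict:
    """Rough moment-based initial estimates from the observed data."""
    groups = data.groups()
    y0, b0 = [], []
    slopes, resid_var = [], []
    chg_by_arm = {0: [], 1: []}
    for g in groups:
        t = g.times
        if t[0] == 0:
            y0.append(g.y[:, 0])
            b0.append(g.bmms)
        if g.n >= 2:
            sl = (g.y[:, -1] - g.y[:, 0]) / max(t[-1] - t[0], 1e-9)
            slopes.append(sl)
            chg_by_arm[g.trt].append(g.y[:, -1] - g.y[:, 0])
        if g.n >= 3:
            X = np.column_stack([np.ones(g.n), t])
            coef, *_ = np.linalg.lstsq(X, g.y.T, rcond=None)
            R = g.y.T - X @ coef
            resid_var.append(np.sum(R**2, axis=0) / max(g.n - 2, 1))
    p = {}
    if y0:
        y0 = np.concatenate(y0)
        b0 = np.concatenate(b0)
        X = np.column_stack([np.ones(len(b0)), b0])
        coef, *_ = np.linalg.lstsq(X, y0, rcond=None)
        p["th_base"], p["th_bmms"] = float(coef[0]), float(coef[1])
        v0 = float(np.var(y0 - X @ coef))
    else:
        p["th_base"], p["th_bmms"] = 20.0, 0.0
        v0 = 25.0
    sl = np.concatenate(slopes) if slopes else np.array([0.1])
    p["th_slope"], p["th_slope_bmms"] = float(np.mean(sl)), 0.0
    p["sig2"] = float(np.mean(np.concatenate(resid_var))) if resid_var else 4.0
    p["sig2"] = max(p["sig2"], 1e-3)
    p["om2_base"] = max(v0 - p["sig2"], 0.5)
    p["om2_slope"] = max(float(np.var(sl)) - 2 * p["sig2"] / 36.0**2, 1e-3)
    if spec.placebo_form == "time_exponential":
        p["th_texp"] = 0.02
        t_last = max(float(g.times[-1]) for g in groups)
        p["th_slope"] = float(np.mean(sl)) * t_last / math.expm1(0.02 * t_last)
    if spec.placebo_form == "iiv_on_ruv":
        p["om2_ruv"] = 0.05
    if spec.placebo_form == "boxcox_eta1":
        p["bc_lambda"] = 0.2
    if spec.placebo_form == "tdist_eta1":
        p["nu_t"] = 10.0
    if spec.drug is not None:
        d_trt = np.mean(np.concatenate(chg_by_arm[1])) if chg_by_arm[1] else 0.0
        d_plb = np.mean(np.concatenate(chg_by_arm[0])) if chg_by_arm[0] else 0.0
        est = float(np.clip(d_trt - d_plb, -20.0, 20.0))
        if spec.drug.form == "disease_modifying":
            est = 0.1
        if spec.drug_applies_to == "arm_specific":
            p["th_de_plb"], p["th_de_trt"] = est / 2, est / 2
            if spec.drug.iiv:
                p["om2_de_plb"] = p["om2_de_trt"] = 0.5
        else:
            p["th_de"] = est
            if spec.drug.iiv:
                p["om2_de"] = 0.5
    if spec.mixture:
        p["th_mix"] = 0.6
    for k, v in spec.fixed_params.items():
        p[k] = v
    return p


def fit(model: ModelSpec, cohort, inits: Optional[dict] = None,
        options: Optional[FitOptions] = None) -> FitResult:
    """Maximize the marginal likelihood. Never raises on optimizer trouble:
    returns ``status="failed"`` instead."""
    opts = options or FitOptions()
    data = as_data(cohort)
    groups = data.groups()
    route = resolve_route(model, opts.route)

    fixed = model.fixed_params
    all_names = model.param_names()
    free = [n for n in all_names if n not in fixed]
    use_profile = (route in ("exact", "fo")) and not model.mixture
    prof = M.profiled_names(model) if use_profile else []
    outer = [n for n in free if n not in prof]

    base_inits = default_inits(model, data)
    if inits:
        base_inits.update(inits)

    drug_on_fn = (lambda g: _drug_active(model, g))
    last_beta = {}

    def build_params(x, beta=None):
        p = dict(fixed)
        for name, xv in zip(outer, x):
            p[name] = from_internal(name, xv)
        for name in prof:
            p[name] = 0.0
        if beta is not None:
            for name, bv in zip(prof, beta):
                p[name] = float(bv)
        return p

    eta_cache = {}
    prebuilt = _prebuild_profiled(model, groups, drug_on_fn,
                                  allow_fo=(route == "fo")) \
        if prof and route in ("exact", "fo") else None
    # analytic gradients are available when every outer parameter is a
    # variance component, sig2, or a disease-modifying th_de
    _om_all = {nm for nm in model.param_names() if nm.startswith("om2")}
    use_grad = prebuilt is not None and all(
        n == "sig2" or n in _om_all or n.startswith("th_de") for n in outer)

    def objective(x):
        p = build_params(x)
        try:
            if prebuilt is not None:
                val, beta = _fast_profiled_ofv(model, p, prebuilt)
                last_beta["beta"] = beta
            elif prof:
                val, beta, _ = _profiled_ofv(model, p, groups, drug_on_fn,
                                             allow_fo=(route == "fo"))
                last_beta["beta"] = beta
            else:
                val = _neg2ll_total(model, p, groups, route,
                                    eta_cache=eta_cache)
        except (np.linalg.LinAlgError, FloatingPointError, ValueError):
            return 1e12
        if not np.isfinite(val):
            return 1e12
        return val

    def objective_grad(x):
        p = build_params(x)
        try:
            val, beta, grad = _fast_profiled_ofv_grad(model, p, prebuilt,
                                                      outer)
            last_beta["beta"] = beta
        except (np.linalg.LinAlgError, FloatingPointError, ValueError):
            return 1e12, np.zeros(len(outer))
        if not np.isfinite(val) or not np.isfinite(grad).all():
            return 1e12, np.zeros(len(outer))
        return val, grad

    x0 = np.array([to_internal(n, base_inits[n]) for n in outer])
    bounds = [internal_bounds(n) for n in outer]
    rng = np.random.default_rng(opts.seed)

    best = None
    for attempt in range(max(1, opts.n_starts)):
        xs = x0 if attempt == 0 else x0 + rng.normal(0, opts.jitter, len(x0))
        xs = np.array([np.clip(v, lo if lo is not None else -np.inf,
                               hi if hi is not None else np.inf)
                       for v, (lo, hi) in zip(xs, bounds)])
        try:
            if use_grad:
                res = minimize(objective_grad, xs, method="L-BFGS-B",
                               jac=True, bounds=bounds,
                               options={"maxiter": opts.maxiter,
                                        "maxfun": 50 * opts.maxiter,
                                        "gtol": opts.pgtol,
                                        "ftol": opts.ftol})
            else:
                res = minimize(objective, xs, method="L-BFGS-B",
                               bounds=bounds,
                               options={"maxiter": opts.maxiter,
                                        "maxfun": 50 * opts.maxiter,
                                        "gtol": opts.pgtol,
                                        "ftol": opts.ftol})
        except (np.linalg.LinAlgError, FloatingPointError):
            continue
        fval = objective(res.x)  # refresh last_beta at the optimum
        ok = bool(res.success) and np.isfinite(fval) and fval < 1e11
        if best is None or (ok and not best[0]) or \
                (ok == best[0] and fval < best[1]):
            grad_norm = float(np.max(np.abs(np.atleast_1d(res.jac)))) \
                if res.jac is not None else float("nan")
            best = (ok, fval, res.x.copy(),
                    dict(last_beta) if prof else None,
                    {"n_iter": int(res.nit), "grad_norm": grad_norm,
                     "message": str(res.message), "attempt": attempt})
        if ok:
            break

    if best is None:
        return FitResult(model, dict(base_inits), float("nan"),
                         model.n_params, "failed",
                         {"message": "all optimizer attempts raised"})
    ok, fval, x, beta_box, diag = best
    params = build_params(x, beta_box["beta"] if beta_box else None)
    status = "converged" if ok else "failed"
    diag["route"] = route
    diag["profiled"] = list(prof)
    return FitResult(model, params, float(fval), model.n_params, status, diag)


# ---------------------------------------------------------------------------
# test statistics
# ---------------------------------------------------------------------------

def delta_ofv(fit_h0: FitResult, fit_h1: FitResult) -> float:
    """OFV(H1) - OFV(H0); negative values favor H1."""
    if not fit_h0.converged or not fit_h1.converged:
        raise ValueError("delta_ofv requires two converged fits")
    return fit_h1.ofv - fit_h0.ofv


def chi2_critical(df: int, alpha: float = 0.05) -> float:
    """Rejection cutoff on the dOFV scale: minus the upper-alpha quantile
    of chi-square with ``df`` degrees of freedom (reject when dOFV is below
    the cutoff)."""
    if not (isinstance(df, (int, np.integer)) and df >= 1):
        raise ValueError("df must be a positive integer")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return -float(chi2.ppf(1.0 - alpha, df))


# ---------------------------------------------------------------------------
# simulation from a fitted model (used by the H0-simulation null)
# ---------------------------------------------------------------------------

def simulate_cohort_data(spec: ModelSpec, params: dict, data: CohortData,
                         seed) -> CohortData:
    """Simulate new scores at the observed design points from ``spec`` with
    ``params`` (new random effects and residuals), keeping covariates and
    arm labels."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    out = [y.copy() for y in data.Ys]
    for times, Y, idx, buf in zip(data.patterns, data.Ys, data.rows, out):
        arm = data.trt[idx]
        for a in (0, 1):
            mask = arm == a
            if not mask.any():
                continue
            g = SubjectGroup(times, a, Y[mask], data.bmms[idx[mask]],
                             idx[mask])
            drug_on = _drug_active(spec, g)
            q = len(M.eta_names(spec, drug_on))
            om = M.eta_variances(spec, params, g, drug_on)
            eta = rng.normal(0.0, np.sqrt(np.maximum(om, 0.0)),
                             size=(g.m, q))
            if spec.placebo_form == "tdist_eta1":
                nu = params["nu_t"]
                eta[:, 0] = rng.standard_t(nu, size=g.m) * \
                    math.sqrt(max(om[0], 0.0))
            pred = M.predict_eta(spec, params, g, eta, drug_on)
            v = M.residual_var(spec, params, eta)
            eps = rng.normal(0.0, 1.0, size=pred.shape) * np.sqrt(v)
            buf[mask] = pred + eps
    return CohortData(data.patterns, out, data.rows, data.bmms,
                      data.trt.copy(), data.ids)
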