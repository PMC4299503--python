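"""Hierarchical Bayes linear meta-regression with publication-level dependence.

Model
-----
    y = X beta + delta + eps,   eps ~ N(0, diag(v)),   delta ~ N(0, tau^2 M(phi))

where M(phi) is block-diagonal by publication with unit diagonal and phi on
the off-diagonal within a block, so phi is the share of between-effect
variance attributable to the shared publication-level deviation.

Inference uses a flat prior on beta, a DuMouchel log-logistic prior on tau,
p(tau) = s0 / (s0 + tau)^2 with s0 = sqrt(harmonic mean of v), and a uniform
prior over a finite phi grid.  The conditional GLS solution beta_hat(tau,
phi) and its covariance are integrated over the joint (tau, phi) posterior
on a deterministic quadrature grid (trapezoid in tau, pointwise in phi), so
identical inputs and grid settings give bitwise-identical output.

Each marginal covariance block is diagonal-plus-rank-one,

    Sigma_j = diag(v_j + tau^2 (1 - phi)) + tau^2 phi 11',

so Sherman-Morrison gives closed-form inverses and determinants; the whole
grid is evaluated with vectorised array arithmetic rather than per-node
matrix factorisations.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.linalg import qr as _qr
from scipy.special import logsumexp

from .effects import EffectSize
from .io import StudyRecord

__all__ = [
    "DesignMatrix",
    "FitResult",
    "build_design",
    "fit_hblm",
    "credible_interval",
    "heterogeneity",
    "residuals_and_precision",
    "typical_within_variance",
    "DEFAULT_PHI_GRID",
]

DEFAULT_PHI_GRID = tuple(np.round(np.arange(0.0, 1.0, 0.05), 10))


@dataclass
class DesignMatrix:
    """Fixed-effect design: one row per effect size, labelled columns."""

    X: np.ndarray
    labels: list[str]

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_cols(self) -> int:
        return self.X.shape[1]


@dataclass
class FitResult:
    beta: np.ndarray
    post_se: np.ndarray
    post_cov: np.ndarray
    labels: list[str]
    tau2: float
    tau: float
    var_tau: float
    var_tau2: float
    phi: float
    phi_mean: float
    I2: float
    s2_typical: float
    residuals: np.ndarray
    N: int
    p: int
    log_evidence: float
    tau_grid: np.ndarray
    phi_grid: np.ndarray
    config: dict = dc_field(default_factory=dict)


def _get_value(rec: StudyRecord, var: str, scale: float = 1.0):
    val = getattr(rec, var)
    if val is None:
        raise ValueError(f"record {rec.observation_id!r} has no value for {var!r}")
    return val if isinstance(val, str) else val * scale


def build_design(
    records: Sequence[StudyRecord],
    terms: Sequence[dict],
    *,
    intercept: bool = True,
) -> DesignMatrix:
    """Build a treatment-contrast design matrix from study records.

    Each term is a dict with keys:

    - ``var``: record attribute name
    - ``kind``: "categorical" or "continuous"
    - ``reference``: reference level absorbed into the intercept
      (categorical only; required when an intercept is present)
    - ``levels``: optional explicit level order; data levels outside it
      are an error
    - ``by``: categorical variable for a separate-slopes interaction
      (continuous only): one slope column per level, no common slope
    - ``scale``: multiplier applied to continuous values (e.g. 0.01 to
      express pct_arable as a proportion)
    """
    cols: list[np.ndarray] = []
    labels: list[str] = []
    n = len(records)
    if intercept:
        cols.append(np.ones(n))
        labels.append("intercept")
    for term in terms:
        var = term["var"]
        kind = term.get("kind", "categorical")
        if kind == "categorical":
            values = [str(_get_value(r, var)) for r in records]
            levels = _resolve_levels(values, term, var)
            ref = term.get("reference")
            if intercept and not term.get("cell_means", False):
                if ref is None:
                    ref = levels[0]
                if ref not in levels:
                    raise ValueError(f"reference level {ref!r} not found for {var!r}")
                use = [lv for lv in levels if lv != ref]
            else:
                use = levels
            for lv in use:
                cols.append(np.array([1.0 if x == lv else 0.0 for x in values]))
                labels.append(f"{var}:{lv}")
        elif kind == "continuous":
            scale = float(term.get("scale", 1.0))
            vals = np.array([float(_get_value(r, var, scale)) for r in records])
            by = term.get("by")
            if by is None:
                cols.append(vals)
                labels.append(var)
            else:
                byvals = [str(_get_value(r, by)) for r in records]
                for lv in _resolve_levels(byvals, {}, by):
                    mask = np.array([1.0 if x == lv else 0.0 for x in byvals])
                    cols.append(vals * mask)
                    labels.append(f"{var}:{by}={lv}")
        else:
            raise ValueError(f"unknown term kind {kind!r}")
    X = np.column_stack(cols)
    _check_rank(X, labels)
    return DesignMatrix(X=X, labels=labels)


def _resolve_levels(values: list[str], term: dict, var: str) -> list[str]:
    seen = sorted(set(values))
    declared = term.get("levels")
    if declared is not None:
        extra = [lv for lv in seen if lv not in declared]
        if extra:
            raise ValueError(f"unseen level(s) for {var!r}: {extra}")
        return list(declared)
    return seen


def _check_rank(X: np.ndarray, labels: list[str]) -> None:
    _, R, piv = _qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        aliased = [labels[j] for j in piv[rank:]]
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")


def _group_codes(effects: Sequence[EffectSize]) -> np.ndarray:
    seen: dict[str, int] = {}
    codes = []
    for e in effects:
        codes.append(seen.setdefault(e.publication_id, len(seen)))
    return np.asarray(codes, dtype=np.intp)


def typical_within_variance(v: np.ndarray) -> float:
    """Higgins-Thompson "typical" within-study sampling variance."""
    v = np.asarray(v, dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("typical within-study variance requires N >= 2")
    w = 1.0 / v
    sw = w.sum()
    return float((n - 1) * sw / (sw**2 - (w**2).sum()))


def fit_hblm(
    effects: Sequence[EffectSize],
    design: DesignMatrix | None = None,
    *,
    tau: float | None = None,
    phi: float | None = None,
    tau_grid_size: int = 201,
    tau_max: float | None = None,
    phi_grid: Sequence[float] = DEFAULT_PHI_GRID,
) -> FitResult:
    """Fit the hierarchical model on a deterministic (tau, phi) grid.

    ``tau`` / ``phi`` pin the corresponding parameter to a single value
    (fixed-parameter mode, used for limits and tests); otherwise tau is
    integrated over a trapezoid grid on [0, tau_max] and phi over
    ``phi_grid`` with uniform weights.
    """
    y = np.array([e.y for e in effects], dtype=float)
    v = np.array([e.v for e in effects], dtype=float)
    if np.any(v <= 0):
        raise ValueError("all sampling variances must be > 0")
    n = y.size
    if design is None:
        design = DesignMatrix(X=np.ones((n, 1)), labels=["intercept"])
    X = np.asarray(design.X, dtype=float)
    p = X.shape[1]
    if X.shape[0] != n:
        raise ValueError("design row count does not match number of effects")
    if tau is None and n <= p:
        raise ValueError(f"need more effects than coefficients (N={n}, p={p})")
    if tau is not None and n < p:
        raise ValueError(f"need at least as many effects as coefficients (N={n}, p={p})")

    codes = _group_codes(effects)
    # sort effects so publication blocks are contiguous (stable: preserves
    # within-block order); all grid algebra runs on the sorted arrays
    order = np.argsort(codes, kind="stable")
    inv_order = np.argsort(order, kind="stable")
    ys, vs, Xs = y[order], v[order], X[order]
    gs = codes[order]
    starts = np.flatnonzero(np.r_[True, gs[1:] != gs[:-1]])

    s2_typ = typical_within_variance(v) if n >= 2 else float(v[0])

    # --- quadrature grid ---------------------------------------------------
    if tau is not None:
        tau_nodes = np.array([float(tau)])
        log_tau_w = np.array([0.0])
    else:
        if tau_max is None:
            tau_max = 10.0 * np.sqrt(s2_typ)
        tau_nodes = np.linspace(0.0, tau_max, tau_grid_size)
        trap = np.full(tau_grid_size, tau_nodes[1] - tau_nodes[0])
        trap[0] *= 0.5
        trap[-1] *= 0.5
        s0 = np.sqrt(n / (1.0 / v).sum())  # sqrt of harmonic-mean variance
        prior = s0 / (s0 + tau_nodes) ** 2  # DuMouchel log-logistic
        log_tau_w = np.log(prior) + np.log(trap)
    if phi is not None:
        phi_nodes = np.array([float(phi)])
    else:
        phi_nodes = np.asarray(phi_grid, dtype=float)
    if np.any((phi_nodes < 0) | (phi_nodes >= 1)):
        raise ValueError("phi grid values must lie in [0, 1)")

    nt, nf = tau_nodes.size, phi_nodes.size
    t2 = np.repeat(tau_nodes**2, nf)  # (K,)
    ph = np.tile(phi_nodes, nt)
    log_prior_k = np.repeat(log_tau_w, nf) - np.log(nf)
    K = t2.size

    # --- per-node GLS via diagonal + rank-one algebra ---------------------
    a = vs[None, :] + (t2 * (1.0 - ph))[:, None]  # (K, N) diagonal of A
    u = 1.0 / a
    tp = (t2 * ph)[:, None]  # rank-one weight per node
    S = np.add.reduceat(u, starts, axis=1)  # (K, G) block sums of u
    denom = 1.0 + tp * S
    c = tp / denom  # Sherman-Morrison factor per block

    uX = u[:, :, None] * Xs[None, :, :]  # (K, N, p)
    Sx = np.add.reduceat(uX, starts, axis=1)  # (K, G, p)
    uy = u * ys[None, :]
    Sy = np.add.reduceat(uy, starts, axis=1)  # (K, G)

    XtSiX = np.einsum("kn,np,nq->kpq", u, Xs, Xs) - np.einsum(
        "kg,kgp,kgq->kpq", c, Sx, Sx
    )
    XtSiy = np.einsum("kn,np->kp", uy, Xs) - np.einsum("kg,kg,kgp->kp", c, Sy, Sx)
    ytSiy = (uy * ys[None, :]).sum(axis=1) - (c * Sy**2).sum(axis=1)

    sign, logdet_XtSiX = np.linalg.slogdet(XtSiX)
    if np.any(sign <= 0):
        raise np.linalg.LinAlgError("non-positive-definite information matrix on grid")
    beta_k = np.linalg.solve(XtSiX, XtSiy[:, :, None])[:, :, 0]  # (K, p)
    cov_k = np.linalg.inv(XtSiX)  # (K, p, p)

    logdet_sigma = np.log(a).sum(axis=1) + np.log(denom).sum(axis=1)
    quad = ytSiy - np.einsum("kp,kp->k", beta_k, XtSiy)  # residual quadratic form
    loglik = -0.5 * (logdet_sigma + logdet_XtSiX + quad)

    log_w = loglik + log_prior_k
    log_evidence = float(logsumexp(log_w))
    w = np.exp(log_w - log_evidence)

    # --- posterior moments -------------------------------------------------
    beta_mean = w @ beta_k
    second = np.einsum("k,kpq->pq", w, cov_k + np.einsum("kp,kq->kpq", beta_k, beta_k))
    post_cov = second - np.outer(beta_mean, beta_mean)
    post_se = np.sqrt(np.clip(np.diag(post_cov), 0.0, None))

    tau_mean = float(w @ np.sqrt(t2))
    tau2_mean = float(w @ t2)
    var_tau = max(0.0, float(w @ t2) - tau_mean**2)
    var_tau2 = max(0.0, float(w @ t2**2) - tau2_mean**2)

    # phi estimate: maximiser of the tau-integrated marginal evidence
    log_w_mat = log_w.reshape(nt, nf)
    phi_evidence = logsumexp(log_w_mat, axis=0)
    phi_map = float(phi_nodes[int(np.argmax(phi_evidence))])
    phi_mean = float(w @ ph)

    I2 = 100.0 * tau2_mean / (tau2_mean + s2_typ) if tau2_mean + s2_typ > 0 else 0.0

    resid = (ys - Xs @ beta_mean)[inv_order]

    return FitResult(
        beta=beta_mean,
        post_se=post_se,
        post_cov=post_cov,
        labels=list(design.labels),
        tau2=tau2_mean,
        tau=tau_mean,
        var_tau=var_tau,
        var_tau2=var_tau2,
        phi=phi_map if phi is None else float(phi),
        phi_mean=phi_mean,
        I2=float(I2),
        s2_typical=s2_typ,
        residuals=resid,
        N=n,
        p=p,
        log_evidence=log_evidence,
        tau_grid=tau_nodes,
        phi_grid=phi_nodes,
        config={
            "tau_fixed": tau,
            "phi_fixed": phi,
            "tau_grid_size": int(tau_nodes.size),
            "tau_max": float(tau_nodes[-1]),
            "phi_grid": [float(x) for x in phi_nodes],
        },
    )


def credible_interval(fit: FitResult, level: float = 0.95) -> np.ndarray:
    """Per-coefficient credible interval: beta +/- t_{N-p} quantile * SE.

    Uses the two-sided quantile (the 1 - (1-level)/2 point) of a
    t-distribution with N - p degrees of freedom.  Returns an array of
    shape (p, 2).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    df = fit.N - fit.p
    if df <= 0:
        raise ValueError("credible interval undefined for N <= p")
    tq = stats.t.ppf(1.0 - (1.0 - level) / 2.0, df)
    lo = fit.beta - tq * fit.post_se
    hi = fit.beta + tq * fit.post_se
    return np.column_stack([lo, hi])


def heterogeneity(fit: FitResult, v: Sequence[float]) -> dict:
    """Between-effect variance and the Higgins-Thompson I^2 (percent)."""
    v = np.asarray(v, dtype=float)
    s2 = typical_within_variance(v)
    tau2 = fit.tau2
    return {
        "tau2": tau2,
        "tau": fit.tau,
        "s2_typical": s2,
        "I2": 100.0 * tau2 / (tau2 + s2),
    }


def residuals_and_precision(
    fit: FitResult, effects: Sequence[EffectSize]
) -> list[tuple[float, float]]:
    """(observed - fitted fixed part, 1/sqrt(v)) per effect, order preserved."""
    return [
        (float(r), float(1.0 / np.sqrt(e.v)))
        for r, e in zip(fit.residuals, effects, strict=True)
    ]
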