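"""Publication-bias and temporal-stability diagnostics.

Implements the rank-based trim-and-fill assessment (L0 estimator), the
cumulative meta-analysis trace (studies added in order of sampling variance
or publication year) and hierarchical slope tests of effect size against
sampling variance or publication year.  In pipeline mode trim-and-fill
operates on hierarchical-model residuals, matching a residual-based funnel
plot; a classical raw-effect mode exists for textbook cross-checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .effects import EffectSize
from .hblm import DesignMatrix, credible_interval, fit_hblm

__all__ = [
    "TrimFillResult",
    "CumulativeStep",
    "CumulativeTrace",
    "l0_estimate",
    "trim_and_fill",
    "cumulative_meta",
    "slope_test",
]


@dataclass
class TrimFillResult:
    k0: int
    estimate: float
    ci_low: float
    ci_high: float
    unadjusted_estimate: float
    unadjusted_ci_low: float
    unadjusted_ci_high: float
    side: str
    iterations: int
    mode: str

    @property
    def adjustment(self) -> float:
        return self.estimate - self.unadjusted_estimate


@dataclass
class CumulativeStep:
    step: int
    key: float
    estimate: float
    ci_low: float
    ci_high: float
    n: int


@dataclass
class CumulativeTrace:
    sort_key: str
    steps: list[CumulativeStep] = field(default_factory=list)

    @property
    def estimates(self) -> list[float]:
        return [s.estimate for s in self.steps]

    def minimum(self) -> CumulativeStep:
        """Most conservative estimate over steps pooling >= 2 effects."""
        pooled = [s for s in self.steps if s.n >= 2]
        return min(pooled, key=lambda s: s.estimate)

    @property
    def final(self) -> CumulativeStep:
        return self.steps[-1]


def l0_estimate(values: Sequence[float], side: str = "right", center: float = 0.0):
    """One pass of the L0 missing-study estimator.

    Ranks |value - center| over all values; T is the rank sum of values on
    the suspected-excess side; L0 = (4T - n(n+1)) / (2n - 1).  Returns
    (T, L0, k0) with k0 = max(0, round(L0)).
    """
    x = np.asarray(values, dtype=float) - center
    if side == "left":
        x = -x
    elif side != "right":
        raise ValueError("side must be 'left' or 'right'")
    n = x.size
    ranks = stats.rankdata(np.abs(x))
    T = float(ranks[x > 0].sum())
    L0 = (4.0 * T - n * (n + 1)) / (2.0 * n - 1.0)
    k0 = max(0, int(round(L0)))
    return T, L0, k0


def _pooled_fe(y: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    w = 1.0 / v
    est = float((w * y).sum() / w.sum())
    se = float(1.0 / math.sqrt(w.sum()))
    return est, se


def trim_and_fill(
    effects: Sequence[EffectSize],
    side: str = "right",
    max_iter: int = 20,
    *,
    mode: str = "residual",
    fit_kwargs: dict | None = None,
) -> TrimFillResult:
    """Trim-and-fill assessment of funnel asymmetry.

    ``mode="residual"`` (pipeline default): k0 is estimated from the
    residuals of an intercept-only hierarchical fit; the k0 most extreme
    residuals are mirrored about the trimmed centre, turned back into
    pseudo effect sizes and the hierarchical model is refitted on the
    augmented data.  ``mode="raw"`` runs the classical algorithm on raw
    effects with fixed-effect pooling (for cross-checks).
    """
    if len(effects) < 3:
        raise ValueError("trim_and_fill requires at least 3 effect sizes")
    fit_kwargs = dict(fit_kwargs or {})

    if mode == "raw":
        y = np.array([e.y for e in effects])
        v = np.array([e.v for e in effects])
        est0, se0 = _pooled_fe(y, v)
        z = stats.norm.ppf(0.975)
        k0, iters, center = _iterate_k0(y, v, est0, side, max_iter, pool=_pooled_fe)
        if k0 == 0:
            return TrimFillResult(0, est0, est0 - z * se0, est0 + z * se0,
                                  est0, est0 - z * se0, est0 + z * se0,
                                  side, iters, mode)
        y_aug, v_aug = _mirror(y, v, center, side, k0)
        est1, se1 = _pooled_fe(y_aug, v_aug)
        return TrimFillResult(k0, est1, est1 - z * se1, est1 + z * se1,
                              est0, est0 - z * se0, est0 + z * se0,
                              side, iters, mode)

    if mode != "residual":
        raise ValueError("mode must be 'residual' or 'raw'")

    fit0 = fit_hblm(effects, **fit_kwargs)
    ci0 = credible_interval(fit0)
    est0 = float(fit0.beta[0])
    r = fit0.residuals.copy()
    v = np.array([e.v for e in effects])

    def pool(rr, vv):  # weighted mean of residuals for re-centring
        return _pooled_fe(rr, vv)

    wmean0, _ = _pooled_fe(r, v)
    k0, iters, center = _iterate_k0(r, v, wmean0, side, max_iter, pool=pool)
    if k0 == 0:
        return TrimFillResult(0, est0, float(ci0[0, 0]), float(ci0[0, 1]),
                              est0, float(ci0[0, 0]), float(ci0[0, 1]),
                              side, iters, mode)

    # mirror the k0 most extreme residuals and rebuild pseudo effect sizes
    r_aug, v_aug = _mirror(r, v, center, side, k0)
    filled = list(effects)
    for i, (rr, vv) in enumerate(zip(r_aug[len(effects):], v_aug[len(effects):])):
        filled.append(
            EffectSize(y=est0 + float(rr), v=float(vv),
                       publication_id=f"__filled_{i}",
                       observation_id=f"__filled_{i}")
        )
    fit1 = fit_hblm(filled, **fit_kwargs)
    ci1 = credible_interval(fit1)
    return TrimFillResult(k0, float(fit1.beta[0]), float(ci1[0, 0]), float(ci1[0, 1]),
                          est0, float(ci0[0, 0]), float(ci0[0, 1]),
                          side, iters, mode)


def _iterate_k0(values, v, center0, side, max_iter, pool):
    """trim -> re-centre -> re-rank until k0 stabilises."""
    values = np.asarray(values, dtype=float)
    v = np.asarray(v, dtype=float)
    center = center0
    k0_prev = -1
    k0 = 0
    iters = 0
    for iters in range(1, max_iter + 1):
        _, _, k0 = l0_estimate(values, side=side, center=center)
        if k0 == k0_prev:
            break
        k0_prev = k0
        if k0 > 0:
            keep = _trim_indices(values, center, side, k0)
            center, _ = pool(values[keep], v[keep])
        else:
            center, _ = pool(values, v)
    return k0, iters, center


def _trim_indices(values, center, side, k0):
    signed = values - center if side == "right" else center - values
    order = np.argsort(signed, kind="stable")  # most extreme excess-side last
    return order[: max(1, len(values) - k0)]


def _mirror(values, v, center, side, k0):
    signed = values - center if side == "right" else center - values
    order = np.argsort(signed, kind="stable")
    extreme = order[-k0:]
    mirrored = 2.0 * center - values[extreme]
    return np.concatenate([values, mirrored]), np.concatenate([v, v[extreme]])


def _sort_key_values(effects: Sequence[EffectSize], sort_key: str) -> list[float]:
    if sort_key == "sampling_variance":
        return [e.v for e in effects]
    if sort_key == "publication_year":
        vals = []
        for e in effects:
            if e.record is None:
                raise ValueError(
                    f"effect {e.observation_id!r} has no record: publication year missing"
                )
            vals.append(float(e.record.pub_year))
        return vals
    raise ValueError("sort_key must be 'sampling_variance' or 'publication_year'")


def cumulative_meta(
    effects: Sequence[EffectSize],
    sort_key: str = "sampling_variance",
    *,
    fit_kwargs: dict | None = None,
) -> CumulativeTrace:
    """Refit the intercept-only hierarchical model on growing prefixes.

    Effects are sorted by the key (ties broken by publication then
    observation id) and added one at a time; step k pools exactly the first
    k effects.  The single-effect first step reports the raw effect with an
    undefined (NaN) interval since no pooling has occurred.
    """
    if len(effects) < 2:
        raise ValueError("cumulative_meta requires at least 2 effect sizes")
    fit_kwargs = dict(fit_kwargs or {})
    keys = _sort_key_values(effects, sort_key)
    order = sorted(
        range(len(effects)),
        key=lambda i: (keys[i], effects[i].publication_id, effects[i].observation_id),
    )
    ordered = [effects[i] for i in order]
    okeys = [keys[i] for i in order]

    trace = CumulativeTrace(sort_key=sort_key)
    trace.steps.append(
        CumulativeStep(step=1, key=okeys[0], estimate=ordered[0].y,
                       ci_low=math.nan, ci_high=math.nan, n=1)
    )
    for k in range(2, len(ordered) + 1):
        fit = fit_hblm(ordered[:k], **fit_kwargs)
        if fit.N > fit.p:
            ci = credible_interval(fit)
            lo, hi = float(ci[0, 0]), float(ci[0, 1])
        else:
            lo = hi = math.nan
        trace.steps.append(
            CumulativeStep(step=k, key=okeys[k - 1], estimate=float(fit.beta[0]),
                           ci_low=lo, ci_high=hi, n=k)
        )
    return trace


def slope_test(
    effects: Sequence[EffectSize],
    covariate: str = "sampling_variance",
    *,
    fit_kwargs: dict | None = None,
) -> dict:
    """Hierarchical metaregression of effect size on one diagnostic covariate."""
    x = np.array(_sort_key_values(effects, covariate), dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError(f"degenerate regressor: {covariate} is constant")
    design = DesignMatrix(
        X=np.column_stack([np.ones(x.size), x]),
        labels=["intercept", covariate],
    )
    fit = fit_hblm(effects, design, **(fit_kwargs or {}))
    ci = credible_interval(fit)
    return {
        "covariate": covariate,
        "slope": float(fit.beta[1]),
        "ci_low": float(ci[1, 0]),
        "ci_high": float(ci[1, 1]),
        "fit": fit,
    }
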