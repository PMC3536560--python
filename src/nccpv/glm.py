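"""Weighted logistic regression on the grouped 2x2 nested-sample data.

The model is ``logit P(disease | x) = alpha + beta * x`` with ``x = 1`` for
a positive index test. Each case carries weight ``N1/N`` and each sampled
control ``(N1/N)/sf``, so the weights sum to the nested sample size N1:
the weighting undoes the control under-sampling while keeping the
effective sample size at the number of subjects actually observed, which
is what makes the model-based covariance usable for inference.

Because the model is saturated (two parameters, two covariate patterns),
``invlogit(alpha + beta)`` equals the weighted proportion of diseased among
test-positives exactly, i.e. the sampling-fraction-corrected PPV, and
``1 - invlogit(alpha)`` the corrected NPV.

Fitting is Newton-Raphson (equivalently IRLS) on the grouped
weight-weighted Bernoulli log-likelihood: four weighted binomial rows, one
O(1) update per iteration. The covariance is the inverse of the weighted
Fisher information at the optimum (model-based; no sandwich correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConvergenceError, SeparationError, ValidationError
from .tables import NestedSample, Target

__all__ = ["WeightSpec", "WeightedGLMFit", "make_weights", "fit_weighted_logit", "logit_se"]


def _invlogit(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@dataclass(frozen=True)
class WeightSpec:
    """Per-subject case/control weights.

    ``w_case = N1/N`` and ``w_control = (N1/N)/sf`` so that the total weight
    over the nested sample equals N1.
    """

    w_case: float
    w_control: float

    def __post_init__(self):
        if self.w_case <= 0 or self.w_control <= 0:
            raise ValidationError("weights must be positive")


@dataclass(frozen=True)
class WeightedGLMFit:
    """Converged state of the two-parameter weighted logistic fit.

    ``alpha`` is the log-odds of disease given a negative index test,
    ``beta`` the log odds ratio for a positive test, ``cov`` the 2x2
    model-based covariance of (alpha, beta).
    """

    alpha: float
    beta: float
    cov: np.ndarray
    iterations: int
    converged: bool
    deviance: float
    trace: tuple = field(default=(), repr=False, compare=False)

    def __post_init__(self):
        cov = np.asarray(self.cov, dtype=float)
        if cov.shape != (2, 2):
            raise ValidationError("cov must be a 2x2 matrix")
        if not np.allclose(cov, cov.T):
            raise ValidationError("cov must be symmetric")
        if cov[0, 0] < 0 or cov[1, 1] < 0:
            raise ValidationError("cov diagonal must be non-negative")
        object.__setattr__(self, "cov", cov)

    def predicted(self, target: Target | str) -> float:
        """Fitted predictive value implied by the coefficients."""
        target = Target.coerce(target)
        if target is Target.PPV:
            return _invlogit(self.alpha + self.beta)
        return 1.0 - _invlogit(self.alpha)


def make_weights(sample: NestedSample) -> WeightSpec:
    """Inverse-sampling-fraction weights normalised to sum to N1."""
    base = sample.n1 / sample.cohort_size
    return WeightSpec(w_case=base, w_control=base / sample.sampling_fraction)


def _grouped_rows(
    sample: NestedSample, weights: WeightSpec, shift: float
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted successes and failures per covariate pattern (x=0, x=1)."""
    s = np.array(
        [weights.w_case * (sample.c + shift), weights.w_case * (sample.a + shift)]
    )
    f = np.array(
        [
            weights.w_control * (sample.d1 + shift),
            weights.w_control * (sample.b1 + shift),
        ]
    )
    return s, f


def _loglik(s: np.ndarray, f: np.ndarray, alpha: float, beta: float) -> float:
    eta = np.array([alpha, alpha + beta])
    # log p and log(1-p) via the numerically stable log1p(exp(.)) forms
    logp = -np.logaddexp(0.0, -eta)
    logq = -np.logaddexp(0.0, eta)
    return float(s @ logp + f @ logq)


def fit_weighted_logit(
    sample: NestedSample,
    weights: WeightSpec | None = None,
    *,
    tol: float = 1e-8,
    ll_tol: float = 1e-10,
    max_iter: int = 50,
    continuity_correction: bool = False,
) -> WeightedGLMFit:
    """Maximise the weighted Bernoulli log-likelihood by Newton-Raphson.

    Parameters
    ----------
    sample
        Nested case-control counts with cohort context.
    weights
        Case/control weights; derived from the sample when omitted.
    tol
        Gradient max-norm convergence threshold.
    ll_tol
        Relative log-likelihood change convergence threshold.
    max_iter
        Iteration budget; exceeding it raises
        :class:`~nccpv.exceptions.ConvergenceError` with the trace.
    continuity_correction
        Add 0.5 to all four nested counts, allowing zero cells to be fitted.

    Raises
    ------
    SeparationError
        If any of the four cells is zero and no continuity correction is
        requested (the saturated MLE then lies on the boundary).
    """
    if weights is None:
        weights = make_weights(sample)
    shift = 0.5 if continuity_correction else 0.0
    if shift == 0.0 and min(sample.a, sample.c, sample.b1, sample.d1) == 0:
        raise SeparationError(
            "a zero cell puts the saturated logistic MLE on the boundary; "
            "enable the continuity correction to proceed"
        )
    s, f = _grouped_rows(sample, weights, shift)
    n = s + f

    # start at the weighted overall disease proportion, no test effect
    alpha = math.log(s.sum() / f.sum())
    beta = 0.0
    ll = _loglik(s, f, alpha, beta)
    trace = [(alpha, beta, ll)]
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        p = np.array([_invlogit(alpha), _invlogit(alpha + beta)])
        resid = s - n * p
        grad = np.array([resid.sum(), resid[1]])
        w = np.maximum(n * p * (1.0 - p), 1e-300)
        info = np.array([[w.sum(), w[1]], [w[1], w[1]]])
        step = np.linalg.solve(info, grad)
        # damped Newton: halve the step until the likelihood improves
        # (the weighted saturated log-likelihood is concave, so a short
        # enough step along the Newton direction always ascends)
        scale = 1.0
        for _ in range(60):
            new_alpha = alpha + scale * step[0]
            new_beta = beta + scale * step[1]
            new_ll = _loglik(s, f, new_alpha, new_beta)
            if new_ll >= ll - 1e-12:
                break
            scale /= 2.0
        alpha, beta = new_alpha, new_beta
        trace.append((alpha, beta, new_ll))
        if np.max(np.abs(grad)) < tol or abs(new_ll - ll) <= ll_tol * (abs(ll) + 1.0):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    if not converged:
        raise ConvergenceError(
            f"weighted logistic fit did not converge in {max_iter} iterations",
            trace=trace,
        )

    p = np.array([_invlogit(alpha), _invlogit(alpha + beta)])
    w = n * p * (1.0 - p)
    info = np.array([[w.sum(), w[1]], [w[1], w[1]]])
    cov = np.linalg.inv(info)
    cov = (cov + cov.T) / 2.0
    # saturated model: deviance vs. the (weighted) saturated fit
    ll_sat = sum(
        si * math.log(si / ni) + fi * math.log(fi / ni)
        for si, fi, ni in zip(s, f, n)
        if si > 0 and fi > 0
    )
    deviance = max(2.0 * (ll_sat - ll), 0.0)
    return WeightedGLMFit(
        alpha=alpha,
        beta=beta,
        cov=cov,
        iterations=iterations,
        converged=converged,
        deviance=deviance,
        trace=tuple(trace),
    )


def logit_se(fit: WeightedGLMFit, target: Target | str) -> float:
    """Delta-method SE of the logit predictive value from the fit covariance.

    ``logit(PPV) = alpha + beta`` so its variance is
    ``var(alpha) + var(beta) + 2 cov(alpha, beta)``;
    ``logit(NPV) = -alpha`` and negation preserves the SE.
    """
    target = Target.coerce(target)
    if not fit.converged:
        raise ConvergenceError("logit_se requires a converged fit")
    if target is Target.PPV:
        var = fit.cov[0, 0] + fit.cov[1, 1] + 2.0 * fit.cov[0, 1]
    else:
        var = fit.cov[0, 0]
    return math.sqrt(max(var, 0.0))
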