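"""Clever-covariate targeting of the treated-arm outcome regression.

The imputation-based loss is not orthogonal because the empirical score

    S_j = (1/n) sum_i A_i (1-g(L_i))/g(L_i) (Y_i - Q(L_i)) b_j(Z_i)

is only O_p(n^{-b}) when Q is estimated adaptively.  The i-learner shrinks
this score in every basis direction by fluctuating the initial fit
Q^(0) along the parametric submodel

    h(E(Y|A=1,L)) = h(Q^(0)(L)) + eps' b(Z) (1-g(L))/g(L),

fitting eps on treated rows by l1-penalized regression with the penalty at
the standard order sqrt(log J / n_treated).  With the identity link, the
lasso Karush-Kuhn-Tucker conditions bound every post-targeting score
coordinate by the penalty level; with the logistic link the fluctuation
operates on the logit scale with offset logit(Q^(0)), which keeps the
updated predictions inside the unit interval.

The clever-covariate features are deliberately not standardized before
penalization: the KKT bound applies to the score coordinates exactly as
written above, and standardizing would distort that guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .sieve import fit_sieve, lambda_anchor

__all__ = [
    "TargetedOutcome",
    "clever_covariates",
    "score_vector",
    "target_outcome",
    "apply_fluctuation",
    "default_Jn",
]


def clever_covariates(B: np.ndarray, ghat: np.ndarray) -> np.ndarray:
    """Row i of the output is b(Z_i) * (1 - ghat_i) / ghat_i."""
    B = np.asarray(B, dtype=float)
    g = np.asarray(ghat, dtype=float)
    if np.any(g <= 0.0) or np.any(g >= 1.0):
        raise ValueError("propensities must lie strictly in (0, 1); clip upstream")
    return B * ((1.0 - g) / g)[:, None]


def score_vector(Y, A, qhat, ghat, B) -> np.ndarray:
    """Orthogonalizing score, one coordinate per basis function.

    Component j is (1/n) sum_i A_i (1-ghat_i)/ghat_i (Y_i - qhat_i) b_j(Z_i).
    """
    Y = np.asarray(Y, dtype=float)
    A = np.asarray(A, dtype=float)
    qhat = np.asarray(qhat, dtype=float)
    g = np.asarray(ghat, dtype=float)
    B = np.asarray(B, dtype=float)
    resid = A * (1.0 - g) / g * (Y - qhat)
    return resid @ B / len(Y)


def apply_fluctuation(qhat0, ghat, B, eps, link: str = "identity") -> np.ndarray:
    """Evaluate the fluctuated predictions Q* on arbitrary observations."""
    shift = clever_covariates(B, ghat) @ np.asarray(eps, dtype=float)
    qhat0 = np.asarray(qhat0, dtype=float)
    if link == "identity":
        return qhat0 + shift
    return np.clip(expit(logit(qhat0) + shift), 1e-12, 1.0 - 1e-12)


@dataclass
class TargetedOutcome:
    """Fluctuation coefficients and updated outcome predictions."""

    eps: np.ndarray
    lam_target: float
    link: str
    qstar: np.ndarray = field(repr=False)
    score_before: np.ndarray = field(repr=False)
    score_after: np.ndarray = field(repr=False)


def target_outcome(Y, A, qhat0, ghat, B, link: str = "identity",
                   lam: float | None = None) -> TargetedOutcome:
    """Fit the clever-covariate submodel on treated rows and update Q everywhere.

    Identity link: lasso of the residuals Y - Q^(0) on the clever covariates
    over treated rows (no extra intercept — the constant basis function
    already contributes a clever covariate).  Logistic link: l1-penalized
    Bernoulli regression with offset logit(Q^(0)).  The penalty defaults to
    sqrt(log J / n_treated); every coordinate is penalized.
    """
    Y = np.asarray(Y, dtype=float)
    A = np.asarray(A, dtype=int)
    qhat0 = np.asarray(qhat0, dtype=float)
    g = np.asarray(ghat, dtype=float)
    B = np.asarray(B, dtype=float)
    treated = A == 1
    n_t = int(treated.sum())
    if n_t == 0:
        raise ValueError("targeting requires treated rows")
    J = B.shape[1]
    if lam is None:
        lam = lambda_anchor(J, n_t)
    X = clever_covariates(B, g)
    if link == "identity":
        model = fit_sieve(X[treated], Y[treated] - qhat0[treated], link="identity",
                          lam=lam, penalize_all=True)
    elif link == "logistic":
        if np.any(Y[treated] < 0) or np.any(Y[treated] > 1):
            raise ValueError("logistic targeting requires Y in [0, 1]")
        if np.any(qhat0 <= 0) or np.any(qhat0 >= 1):
            raise ValueError("logistic targeting requires qhat0 in (0, 1); clip upstream")
        model = fit_sieve(X[treated], Y[treated], offset=logit(qhat0[treated]),
                          link="logistic", lam=lam, penalize_all=True)
    else:
        raise ValueError(f"unknown link {link!r}")
    eps = model.gamma
    qstar = apply_fluctuation(qhat0, g, B, eps, link=link)
    return TargetedOutcome(
        eps=eps,
        lam_target=float(lam),
        link=link,
        qstar=qstar,
        score_before=score_vector(Y, A, qhat0, g, B),
        score_after=score_vector(Y, A, qstar, g, B),
    )


def default_Jn(n: int, d: int, D_prime: int = 1, C: float = 1.0) -> int:
    """Sample-size rule for the number of basis functions:
    round(C * d**D' * n**(1/3) * log(n)**(D'-1)), floored at 1.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    val = C * d**D_prime * n ** (1.0 / 3.0) * np.log(n) ** (D_prime - 1)
    return max(1, int(round(val)))
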