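"""l1-penalized sieve regression with identity or logistic link.

Fits coefficient vectors gamma of a cosine tensor-product expansion by
minimizing

    (1/(2S)) sum_i w_i (y_i - o_i - B_i gamma)^2            (identity)
    (1/S)    sum_i w_i [log(1+e^{eta_i}) - y_i eta_i]       (logistic)

plus ``lam * sum_{j penalized} |gamma_j|``, where ``o`` is an optional
offset on the link scale, ``eta = o + B gamma`` and ``S`` is the sum of the
(mean-one normalized) observation weights.  The constant basis function is
not penalized by default, so the fitted mean is unconstrained; the clever
covariate fluctuation in :mod:`ilearner.targeting` penalizes every
coordinate instead.

The solver is cyclic coordinate descent with exact soft-thresholding
updates; the logistic link wraps it in an iteratively reweighted
least-squares (proximal Newton) outer loop with step halving.  Fractional
responses in [0, 1] are allowed under the logistic loss: imputed outcome
probabilities are regressed on the probability scale, which is how the
imputation-based learners respect a binary outcome space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.special import expit

from .basis import SieveBasis

__all__ = [
    "SieveModel",
    "fit_sieve",
    "predict_sieve",
    "select_lambda",
    "lambda_anchor",
    "save_sieve",
    "load_sieve",
]

CD_TOL = 1e-7
CD_MAX_PASSES = 100_000
_PCLIP = 1e-9


@njit(cache=True)
def _cd_solve(B, r, w, gamma, lam, pen, S, tol, max_passes):
    """Cyclic coordinate descent for weighted lasso.

    Minimizes (1/(2S)) sum w_i (resid_i)^2 + lam * sum_{pen} |gamma_j|,
    where ``r`` holds the current residual y - o - B @ gamma and is updated
    in place along with ``gamma``.
    """
    n, J = B.shape
    d = np.empty(J)
    for j in range(J):
        acc = 0.0
        for i in range(n):
            acc += w[i] * B[i, j] * B[i, j]
        d[j] = acc / S
    for _ in range(max_passes):
        delta = 0.0
        for j in range(J):
            if d[j] <= 0.0:
                continue
            c = 0.0
            for i in range(n):
                c += w[i] * B[i, j] * r[i]
            c = c / S + d[j] * gamma[j]
            if pen[j]:
                if c > lam:
                    new = (c - lam) / d[j]
                elif c < -lam:
                    new = (c + lam) / d[j]
                else:
                    new = 0.0
            else:
                new = c / d[j]
            diff = new - gamma[j]
            if diff != 0.0:
                for i in range(n):
                    r[i] -= diff * B[i, j]
                gamma[j] = new
                if abs(diff) > delta:
                    delta = abs(diff)
        if delta < tol:
            break
    return gamma


def _normalize_weights(weights, n):
    if weights is None:
        return np.ones(n)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError("weights must be a length-n vector")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    pos = w > 0
    if not pos.any():
        raise ValueError("all observation weights are zero")
    return w / w[pos].mean()


def _penalty_mask(J, penalize_all, unpenalized):
    pen = np.ones(J, dtype=np.bool_)
    if not penalize_all:
        if unpenalized is None:
            unpenalized = [0]
        pen[list(unpenalized)] = False
    return pen


def _objective(B, y, w, offset, gamma, lam, pen, S, link):
    eta = offset + B @ gamma
    if link == "identity":
        loss = 0.5 * np.sum(w * (y - eta) ** 2) / S
    else:
        loss = np.sum(w * (np.logaddexp(0.0, eta) - y * eta)) / S
    return loss + lam * np.sum(np.abs(gamma[pen]))


@dataclass
class SieveModel:
    """A fitted l1-penalized sieve regression."""

    link: str
    gamma: np.ndarray = field(repr=False)
    lam: float
    basis: SieveBasis | None = None
    weight_normalization: float = 1.0

    def predict(self, Z: np.ndarray, offset=None) -> np.ndarray:
        if self.basis is None:
            raise ValueError("model has no attached basis; use predict_sieve on a design matrix")
        return predict_sieve(self, Z, offset=offset)


def fit_sieve(
    B: np.ndarray,
    y: np.ndarray,
    weights=None,
    offset=None,
    link: str = "identity",
    lam: float = 0.0,
    basis: SieveBasis | None = None,
    penalize_all: bool = False,
    unpenalized=None,
    gamma0=None,
    tol: float = CD_TOL,
    max_passes: int = CD_MAX_PASSES,
) -> SieveModel:
    """Fit a weighted l1-penalized regression of ``y`` on the design ``B``.

    ``weights`` are normalized internally to mean one over positive-weight
    rows, so rescaling all weights leaves the fit unchanged and zero-weight
    rows are equivalent to deleted rows.  ``offset`` is on the link scale.
    By default coordinate 0 (the constant basis function) is unpenalized;
    ``penalize_all=True`` penalizes every coordinate (used by the targeting
    step).  Deterministic given its inputs.
    """
    if link not in ("identity", "logistic"):
        raise ValueError(f"unknown link {link!r}")
    B = np.ascontiguousarray(B, dtype=float)
    y = np.asarray(y, dtype=float)
    n, J = B.shape
    if n < 2:
        raise ValueError("need at least 2 rows")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if link == "logistic" and (np.any(y < 0) or np.any(y > 1)):
        raise ValueError("logistic link requires responses in [0, 1]")
    w = _normalize_weights(weights, n)
    S = w.sum()
    o = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    if not np.all(np.isfinite(o)):
        raise ValueError("offset must be finite on the link scale")
    pen = _penalty_mask(J, penalize_all, unpenalized)
    gamma = np.zeros(J) if gamma0 is None else np.array(gamma0, dtype=float)

    if link == "identity":
        r = y - o - B @ gamma
        _cd_solve(B, r, w, gamma, lam, pen, S, tol, max_passes)
    else:
        # proximal Newton: weighted-lasso solves on the IRLS working response
        obj = _objective(B, y, w, o, gamma, lam, pen, S, link)
        for _ in range(200):
            eta = o + B @ gamma
            p = np.clip(expit(eta), _PCLIP, 1.0 - _PCLIP)
            irls_w = w * p * (1.0 - p)
            z = (eta - o) + (y - p) / (p * (1.0 - p))
            prev = gamma.copy()
            cand = prev.copy()
            r = z - B @ cand
            _cd_solve(B, r, irls_w, cand, lam, pen, S, tol, max_passes)
            # step halving toward the previous iterate if the true objective worsens
            step = 1.0
            new_obj = _objective(B, y, w, o, cand, lam, pen, S, link)
            while new_obj > obj + 1e-12 and step > 1e-4:
                step *= 0.5
                cand = prev + step * (cand - prev)
                new_obj = _objective(B, y, w, o, cand, lam, pen, S, link)
            change = np.max(np.abs(cand - gamma)) if J else 0.0
            gamma = cand
            if new_obj > obj + 1e-12:
                gamma = prev
                break
            converged = change < max(tol, 1e-9)
            obj = new_obj
            if converged:
                break

    if not np.all(np.isfinite(gamma)):
        raise FloatingPointError("non-finite coefficients in sieve fit")
    return SieveModel(link=link, gamma=gamma, lam=float(lam), basis=basis)


def predict_sieve(model: SieveModel, Z: np.ndarray, offset=None) -> np.ndarray:
    """Predictions on the response scale at raw covariate values ``Z``.

    If the model has an attached basis, ``Z`` is rescaled and expanded; a
    bare coefficient model expects ``Z`` to already be a design matrix.
    """
    if model.basis is not None:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[1] != model.basis.q:
            raise ValueError(f"expected {model.basis.q} columns, got {Z.shape[1]}")
        B = model.basis.design(Z)
    else:
        B = np.atleast_2d(np.asarray(Z, dtype=float))
    eta = B @ model.gamma
    if offset is not None:
        eta = eta + np.asarray(offset, dtype=float)
    if model.link == "identity":
        return eta
    return np.clip(expit(eta), 1e-12, 1.0 - 1e-12)


def lambda_anchor(J: int, n: int) -> float:
    """Theoretical-order penalty level sqrt(log(J) / n)."""
    if n < 1 or J < 1:
        raise ValueError("J and n must be positive")
    return float(np.sqrt(np.log(max(J, 2)) / n))


def _holdout_loss(model_gamma, B, y, w, offset, link):
    eta = offset + B @ model_gamma
    if link == "identity":
        return float(np.sum(w * (y - eta) ** 2))
    p = np.clip(expit(eta), _PCLIP, 1.0 - _PCLIP)
    return float(np.sum(w * -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


def select_lambda(
    B: np.ndarray,
    y: np.ndarray,
    weights=None,
    link: str = "identity",
    n_folds: int = 5,
    seed: int = 0,
    offset=None,
    n_grid: int = 50,
    span: float = 2.5,
    penalize_all: bool = False,
    unpenalized=None,
) -> float:
    """Cross-validated penalty level on a log grid around sqrt(log(J)/n).

    The grid has ``n_grid`` log-spaced points spanning ``10**(+-span)``
    around the anchor and always contains the anchor itself.  Folds are a
    seeded random partition; ties in CV loss resolve to the larger lambda.
    """
    B = np.asarray(B, dtype=float)
    y = np.asarray(y, dtype=float)
    n, J = B.shape
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n < n_folds:
        raise ValueError("fewer rows than folds")
    w = _normalize_weights(weights, n)
    o = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    anchor = lambda_anchor(J, n)
    grid = anchor * 10.0 ** np.linspace(-span, span, n_grid)
    grid[np.argmin(np.abs(np.log(grid) - np.log(anchor)))] = anchor
    grid = np.sort(grid)[::-1]  # descending for warm starts

    rng = np.random.default_rng(seed)
    fold = rng.permutation(n) % n_folds
    losses = np.zeros(len(grid))
    for k in range(n_folds):
        tr, te = fold != k, fold == k
        gamma = None
        for gi, lam in enumerate(grid):
            m = fit_sieve(
                B[tr], y[tr], weights=w[tr], offset=o[tr], link=link, lam=lam,
                penalize_all=penalize_all, unpenalized=unpenalized, gamma0=gamma,
            )
            gamma = m.gamma
            losses[gi] += _holdout_loss(gamma, B[te], y[te], w[te], o[te], link)
    best = np.min(losses)
    # ties -> larger lambda; grid is descending so take the first within tolerance
    idx = int(np.nonzero(losses <= best * (1 + 1e-12) + 1e-15)[0][0])
    return float(grid[idx])


# --- flat text serialization ------------------------------------------------

def save_sieve(model: SieveModel, path) -> None:
    """Write a model as flat key=value text with bit-exact float round-trip."""
    if model.basis is None:
        raise ValueError("only models with an attached basis can be serialized")
    b = model.basis
    lines = [
        "format=ilearner-sieve-v1",
        f"link={model.link}",
        f"lam={float(model.lam).hex()}",
        f"q={b.q}",
        f"D_prime={b.D_prime}",
        f"J={b.J}",
    ]
    for idx in b.index_list:
        lines.append("index=" + ",".join(str(j) for j in idx))
    for lo, hi in b.ranges:
        lines.append(f"range={float(lo).hex()},{float(hi).hex()}")
    for g in model.gamma:
        lines.append(f"gamma={float(g).hex()}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_sieve(path) -> SieveModel:
    """Read a model written by :func:`save_sieve`."""
    fields: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            fields.setdefault(key, []).append(val)
    if fields.get("format") != ["ilearner-sieve-v1"]:
        raise ValueError("not an ilearner sieve model file")
    q = int(fields["q"][0])
    index_list = [tuple(int(x) for x in v.split(",")) for v in fields.get("index", [])]
    ranges = np.array(
        [[float.fromhex(x) for x in v.split(",")] for v in fields.get("range", [])]
    )
    gamma = np.array([float.fromhex(v) for v in fields.get("gamma", [])])
    basis = SieveBasis(
        q=q,
        D_prime=int(fields["D_prime"][0]),
        J=int(fields["J"][0]),
        index_list=index_list,
        ranges=ranges,
    )
    return SieveModel(
        link=fields["link"][0],
        gamma=gamma,
        lam=float.fromhex(fields["lam"][0]),
        basis=basis,
    )
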