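"""Meta-learners of the conditional counterfactual mean E(Y^1 | Z).

Six learners share the same final stage — an l1-penalized cosine-sieve
regression on Z — and differ in which rows and pseudo-responses they use:

* naive        : Y on Z, treated rows only (ignores confounding);
* ipw          : Y on Z, treated rows weighted by 1/ghat;
* imputation   : A*Y + (1-A)*Qhat(L) on Z, all rows (non-orthogonal);
* dr           : the doubly robust pseudo-outcome (A/ghat)(Y-Qhat) + Qhat on
                 Z, all rows, always with the identity link because the
                 pseudo-outcomes are unbounded;
* cdr          : dr with predictions clipped to [0, 1];
* ilearner     : imputation applied to the targeted predictions Q*, whose
                 clever-covariate fluctuation makes the loss orthogonal
                 while keeping imputed outcomes in the outcome space.

Cross-fitting protocol: nuisances (and the targeting fluctuation) for each
fold are estimated on the other K-1 folds; per-fold imputations are pooled
and the final sieve regression is run once on all n rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .basis import SieveBasis
from .data import ObservationTable
from .nuisance import LearnerSpec, NuisanceFit, crossfit_nuisances
from .sieve import SieveModel, fit_sieve, lambda_anchor, select_lambda
from .targeting import apply_fluctuation, target_outcome

__all__ = [
    "ImputedDataset",
    "MetaLearnerOutput",
    "LEARNER_NAMES",
    "naive_learner",
    "ipw_learner",
    "imputation_learner",
    "dr_pseudo_outcomes",
    "dr_learner",
    "constrain_unit",
    "i_learner",
    "crossfit_pipeline",
]

LEARNER_NAMES = ("naive", "ipw", "imputation", "dr", "cdr", "ilearner")


@dataclass
class ImputedDataset:
    """Outcomes with the untreated arm imputed from Qhat."""

    ytilde: np.ndarray
    observed: np.ndarray  # True where the outcome is the subject's own Y
    qhat: np.ndarray = field(repr=False)

    @classmethod
    def build(cls, Y, A, qhat) -> "ImputedDataset":
        Y = np.asarray(Y, dtype=float)
        A = np.asarray(A, dtype=int)
        qhat = np.asarray(qhat, dtype=float)
        ytilde = np.where(A == 1, Y, qhat)
        return cls(ytilde=ytilde, observed=A == 1, qhat=qhat)


@dataclass
class MetaLearnerOutput:
    """A fitted meta-learner: final sieve model plus per-subject predictions."""

    name: str
    model: SieveModel | None
    predictions: np.ndarray = field(repr=False)
    diagnostics: dict = field(default_factory=dict)
    clip_unit: bool = False

    def predict(self, Z: np.ndarray) -> np.ndarray:
        if self.model is None:
            raise ValueError(f"learner {self.name!r} has no predictive model")
        pred = self.model.predict(Z)
        if self.clip_unit:
            pred = np.clip(pred, 0.0, 1.0)
        return pred


def _make_basis(data: ObservationTable, J=None, D_prime=2) -> SieveBasis:
    return SieveBasis.from_data(data.Z, J=J, D_prime=D_prime)


def _resolve_lambda(B, y, weights, link, lam_policy, seed, offset=None):
    if isinstance(lam_policy, (int, float)) and not isinstance(lam_policy, bool):
        return float(lam_policy)
    if lam_policy == "anchor":
        return lambda_anchor(B.shape[1], B.shape[0])
    if lam_policy == "cv":
        return select_lambda(B, y, weights=weights, link=link, seed=seed, offset=offset)
    raise ValueError(f"unknown lambda policy {lam_policy!r}")


def _final_fit(name, basis, B, y, weights, link, lam_policy, seed, extra=None):
    rows = slice(None) if weights is None else np.asarray(weights) > 0
    lam = _resolve_lambda(B[rows], np.asarray(y, dtype=float)[rows],
                          None if weights is None else np.asarray(weights)[rows],
                          link, lam_policy, seed)
    model = fit_sieve(B, y, weights=weights, link=link, lam=lam, basis=basis)
    pred = B @ model.gamma
    if link == "logistic":
        pred = np.clip(expit(pred), 1e-12, 1.0 - 1e-12)
    diag = {"lambda": lam, "link": link}
    if extra:
        diag.update(extra)
    return MetaLearnerOutput(name=name, model=model, predictions=pred, diagnostics=diag)


def naive_learner(data: ObservationTable, J=None, D_prime=2, link="identity",
                  lam_policy="cv", seed=0) -> MetaLearnerOutput:
    """Penalized sieve of Y on Z fitted in the treated subgroup only."""
    A = data.A
    if not (A == 1).any():
        raise ValueError("naive learner requires treated rows")
    basis = _make_basis(data, J, D_prime)
    if (A == 1).sum() < basis.J:
        import warnings

        warnings.warn(f"fewer treated rows ({int((A == 1).sum())}) than basis functions ({basis.J})")
    B = basis.design(data.Z)
    w = (A == 1).astype(float)
    return _final_fit("naive", basis, B, data.Y, w, link, lam_policy, seed)


def ipw_learner(data: ObservationTable, nuisance: NuisanceFit, J=None, D_prime=2,
                link="identity", lam_policy="cv", seed=0) -> MetaLearnerOutput:
    """Sieve in the treated subgroup with inverse-propensity weights A/ghat,
    normalized to mean one over the treated rows."""
    if nuisance is None or nuisance.ghat is None:
        raise ValueError("ipw learner requires fitted propensity scores")
    A = data.A
    w = np.where(A == 1, 1.0 / nuisance.ghat, 0.0)
    basis = _make_basis(data, J, D_prime)
    B = basis.design(data.Z)
    return _final_fit("ipw", basis, B, data.Y, w, link, lam_policy, seed)


def imputation_learner(data: ObservationTable, nuisance_or_qhat, J=None, D_prime=2,
                       link="identity", lam_policy="cv", seed=0,
                       name="imputation") -> MetaLearnerOutput:
    """Sieve of the imputed outcomes A*Y + (1-A)*Qhat on Z over all rows."""
    if isinstance(nuisance_or_qhat, NuisanceFit):
        qhat = nuisance_or_qhat.qhat0
    else:
        qhat = np.asarray(nuisance_or_qhat, dtype=float)
    if qhat is None or len(qhat) != data.n:
        raise ValueError("imputation learner requires Qhat for every row")
    imputed = ImputedDataset.build(data.Y, data.A, qhat)
    basis = _make_basis(data, J, D_prime)
    B = basis.design(data.Z)
    out = _final_fit(name, basis, B, imputed.ytilde, None, link, lam_policy, seed)
    out.diagnostics["n_imputed"] = int((~imputed.observed).sum())
    return out


def dr_pseudo_outcomes(Y, A, ghat, qhat) -> np.ndarray:
    """Doubly robust pseudo-outcome (A/ghat)(Y - Qhat) + Qhat."""
    Y = np.asarray(Y, dtype=float)
    A = np.asarray(A, dtype=float)
    g = np.asarray(ghat, dtype=float)
    q = np.asarray(qhat, dtype=float)
    if np.any(g <= 0) or np.any(g >= 1):
        raise ValueError("propensities must lie strictly in (0, 1)")
    return A / g * (Y - q) + q


def dr_learner(data: ObservationTable, nuisance: NuisanceFit, J=None, D_prime=2,
               lam_policy="cv", seed=0) -> MetaLearnerOutput:
    """Identity-link sieve of the DR pseudo-outcome on Z over all rows.

    The identity link is used regardless of the outcome type because the
    pseudo-outcomes are unbounded.
    """
    if nuisance is None:
        raise ValueError("dr learner requires fitted nuisances")
    phi = dr_pseudo_outcomes(data.Y, data.A, nuisance.ghat, nuisance.qhat0)
    basis = _make_basis(data, J, D_prime)
    B = basis.design(data.Z)
    out = _final_fit("dr", basis, B, phi, None, "identity", lam_policy, seed)
    out.diagnostics["pseudo_outcome_range"] = (float(phi.min()), float(phi.max()))
    return out


def constrain_unit(output: MetaLearnerOutput) -> MetaLearnerOutput:
    """Clip a learner's predictions to [0, 1] (the cDR construction)."""
    pred = output.predictions
    outside = (pred < 0.0) | (pred > 1.0)
    diag = dict(output.diagnostics)
    diag["fraction_clipped"] = float(outside.mean())
    return MetaLearnerOutput(
        name="cdr" if output.name == "dr" else f"c{output.name}",
        model=output.model,
        predictions=np.clip(pred, 0.0, 1.0),
        diagnostics=diag,
        clip_unit=True,
    )


def _targeted_imputations(data: ObservationTable, nuisance: NuisanceFit, J, D_prime,
                          link, target_lam=None):
    """Per-fold clever-covariate targeting following the cross-fitting protocol.

    For each fold k the fluctuation is fitted on the treated rows of the
    other K-1 folds (with that fold's nuisance models evaluated there) and
    then applied to fold k with the out-of-fold ghat and Q^(0).
    """
    if not nuisance.g_models or not nuisance.q_models:
        raise ValueError("targeting requires per-fold nuisance models")
    Z, L, A, Y = data.Z, data.L, data.A, data.Y
    fold = nuisance.fold_id
    qstar = np.empty(data.n)
    diags = []
    for k in range(nuisance.K):
        tr = fold != k
        te = fold == k
        basis_k = SieveBasis.from_data(Z[tr], J=J, D_prime=D_prime)
        g_tr = nuisance.g_models[k].predict(L[tr])
        q0_tr = nuisance.q_models[k].predict(L[tr])
        B_tr = basis_k.design(Z[tr])
        tg = target_outcome(Y[tr], A[tr], q0_tr, g_tr, B_tr, link=link, lam=target_lam)
        B_te = basis_k.design(Z[te])
        qstar[te] = apply_fluctuation(nuisance.qhat0[te], nuisance.ghat[te],
                                      B_te, tg.eps, link=link)
        diags.append({
            "fold": k,
            "lam_target": tg.lam_target,
            "eps_l1": float(np.abs(tg.eps).sum()),
            "score_before_sup": float(np.abs(tg.score_before).max()),
            "score_after_sup": float(np.abs(tg.score_after).max()),
        })
    return qstar, diags


def i_learner(data: ObservationTable, nuisance: NuisanceFit, J=None, D_prime=2,
              link="identity", lam_policy="cv", target_lam=None, seed=0) -> MetaLearnerOutput:
    """Imputation learner on targeted imputations Q* (the orthogonal i-learner)."""
    if nuisance is None:
        raise ValueError("i-learner requires fitted nuisances")
    qstar, diags = _targeted_imputations(data, nuisance, J, D_prime, link, target_lam)
    out = imputation_learner(data, qstar, J=J, D_prime=D_prime, link=link,
                             lam_policy=lam_policy, seed=seed, name="ilearner")
    out.diagnostics["targeting"] = diags
    return out


def crossfit_pipeline(data: ObservationTable, K: int = 5,
                      g_spec: LearnerSpec | None = None,
                      q_spec: LearnerSpec | None = None,
                      learner_set=LEARNER_NAMES, seed: int = 0,
                      link: str = "identity", J=None, D_prime: int = 2,
                      lam_policy="cv", clip_lo: float = 0.01,
                      nuisance: NuisanceFit | None = None,
                      target_lam=None) -> dict:
    """Run the requested meta-learners under K-fold cross-fitting.

    Nuisance models are only trained if some requested learner needs them.
    A precomputed ``nuisance`` (e.g. oracle nuisances) can be supplied
    instead of learner specs.  Returns a dict name -> MetaLearnerOutput.
    """
    learner_set = list(learner_set)
    unknown = set(learner_set) - set(LEARNER_NAMES)
    if unknown:
        raise ValueError(f"unknown learner(s): {sorted(unknown)}")
    needs_nuisance = set(learner_set) & {"ipw", "imputation", "dr", "cdr", "ilearner"}
    if needs_nuisance and nuisance is None:
        if g_spec is None:
            g_spec = LearnerSpec("random_forest")
        if q_spec is None:
            q_spec = LearnerSpec("random_forest")
        nuisance = crossfit_nuisances(data, K, g_spec, q_spec, seed=seed,
                                      link=link, clip_lo=clip_lo)
    out: dict[str, MetaLearnerOutput] = {}
    common = dict(J=J, D_prime=D_prime, lam_policy=lam_policy)
    if "naive" in learner_set:
        out["naive"] = naive_learner(data, link=link, seed=seed + 1, **common)
    if "ipw" in learner_set:
        out["ipw"] = ipw_learner(data, nuisance, link=link, seed=seed + 2, **common)
    if "imputation" in learner_set:
        out["imputation"] = imputation_learner(data, nuisance, link=link,
                                               seed=seed + 3, **common)
    if "dr" in learner_set or "cdr" in learner_set:
        dr = dr_learner(data, nuisance, seed=seed + 4, **common)
        if "dr" in learner_set:
            out["dr"] = dr
        if "cdr" in learner_set:
            out["cdr"] = constrain_unit(dr)
    if "ilearner" in learner_set:
        out["ilearner"] = i_learner(data, nuisance, link=link, seed=seed + 5,
                                    target_lam=target_lam, **common)
    return out
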