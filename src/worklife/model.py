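"""Discrete-time multinomial logistic transition model.

One model per gender stratum regresses the destination state at t+step
on the origin state at t, a restricted cubic spline in age, covariate
main effects and the education x parity interaction.  The likelihood is
maximised by Newton-Raphson on *aggregated* person-period counts: all
records sharing a design row (ages and covariates are discrete) are
collapsed into one multinomial cell, which makes refitting cheap enough
for person-resampling bootstraps.  Frequency weights are supported and
are exactly equivalent to duplicating records.

The estimator follows scikit-learn conventions (``fit`` / ``predict_proba``
/ ``get_params``; fitted attributes carry a trailing underscore).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .design import (
    CovariateProfile,
    ModelSpec,
    design_matrix,
    profile_design,
    term_names,
)
from .errors import ConfigurationError, EmptyGroupError, FitError
from .expectancy import TransitionProbabilities
from .states import DEAD, GENDERS, STATES, TRANSIENT_STATES


def destination_order(spec: ModelSpec) -> tuple[str, ...]:
    ref = spec.reference_destination
    return (ref,) + tuple(s for s in STATES if s != ref)


def _stable_probs(eta: np.ndarray) -> np.ndarray:
    """Softmax over [0, eta_1, ..., eta_D-1]; column 0 is the reference."""
    full = np.concatenate([np.zeros((eta.shape[0], 1)), eta], axis=1)
    full -= full.max(axis=1, keepdims=True)
    np.exp(full, out=full)
    full /= full.sum(axis=1, keepdims=True)
    return full


def multinomial_loglik(design: np.ndarray, y_codes: np.ndarray, coef: np.ndarray,
                       weights: np.ndarray | None = None) -> float:
    """Log-likelihood of record-level outcomes under coefficient array
    ``coef`` (p x D-1, reference destination pinned at zero)."""
    eta = design @ coef
    full = np.concatenate([np.zeros((eta.shape[0], 1)), eta], axis=1)
    mx = full.max(axis=1)
    lse = mx + np.log(np.exp(full - mx[:, None]).sum(axis=1))
    picked = full[np.arange(len(y_codes)), y_codes]
    contrib = picked - lse
    if weights is not None:
        contrib = contrib * weights
    return float(contrib.sum())


def _newton_fit(X: np.ndarray, Y: np.ndarray, ridge: float, tol: float,
                max_iter: int, start: np.ndarray | None = None,
                need_info: bool = True):
    """Maximise the grouped multinomial likelihood.

    X: (m, p) unique design rows; Y: (m, D) outcome counts with the
    reference destination in column 0.  Returns (B, loglik, converged,
    n_iter, information_matrix).  ``start`` warm-starts the iteration
    (e.g. at the full-sample solution when refitting a resample).
    """
    m, p = X.shape
    D = Y.shape[1]
    n_eq = D - 1
    N = Y.sum(axis=1)
    n_total = float(N.sum())
    lam = ridge * max(n_total, 1.0)
    B = np.zeros((p, n_eq)) if start is None else np.array(start, dtype=float)
    if n_eq == 0:
        # every observed outcome is the reference destination
        return B, 0.0, True, 0, np.zeros((0, 0))

    def penalized_ll(Bm):
        ll = multinomial_loglik_grouped(X, Y, Bm)
        return ll - 0.5 * lam * float((Bm**2).sum())

    ll = penalized_ll(B)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        P = _stable_probs(X @ B)
        resid = Y[:, 1:] - N[:, None] * P[:, 1:]
        grad = (X.T @ resid).ravel(order="F") - lam * B.ravel(order="F")
        if np.max(np.abs(grad)) <= tol * max(1.0, n_total):
            converged = True
            break
        info = _information(X, P, N)
        info[np.diag_indices_from(info)] += lam
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular information matrix: {exc}") from exc
        # damped update: halve until the penalized log-likelihood improves
        scale = 1.0
        for _ in range(30):
            B_new = B + scale * step.reshape((n_eq, p)).T
            ll_new = penalized_ll(B_new)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-10 * abs(ll):
                break
            scale *= 0.5
        else:
            raise FitError("step halving failed to improve the likelihood")
        B, ll = B_new, ll_new
    if not np.all(np.isfinite(B)):
        raise FitError("non-finite coefficients")
    info = _information(X, _stable_probs(X @ B), N) if need_info else None
    return B, multinomial_loglik_grouped(X, Y, B), converged, it, info


def _information(X: np.ndarray, P: np.ndarray, N: np.ndarray) -> np.ndarray:
    """Observed information: blocks X' diag(N P_d (delta_de - P_e)) X."""
    m, p = X.shape
    n_eq = P.shape[1] - 1
    info = np.empty((n_eq * p, n_eq * p))
    for d in range(n_eq):
        for e in range(d, n_eq):
            w = N * P[:, d + 1] * ((1.0 if d == e else 0.0) - P[:, e + 1])
            block = (X * w[:, None]).T @ X
            info[d * p : (d + 1) * p, e * p : (e + 1) * p] = block
            if e != d:
                info[e * p : (e + 1) * p, d * p : (d + 1) * p] = block
    return info


def multinomial_loglik_grouped(X: np.ndarray, Y: np.ndarray, B: np.ndarray) -> float:
    eta = X @ B
    full = np.concatenate([np.zeros((eta.shape[0], 1)), eta], axis=1)
    mx = full.max(axis=1)
    lse = mx + np.log(np.exp(full - mx[:, None]).sum(axis=1))
    return float((Y * full).sum() - (Y.sum(axis=1) * lse).sum())


class MultinomialTransitionModel(BaseEstimator):
    """Multinomial logistic regression of destination on origin-state,
    age spline and covariates, within one gender stratum.

    Parameters
    ----------
    spec : ModelSpec, optional
        Term structure; defaults to the full specification (all main
        effects plus the education x parity interaction, 5 age knots).
    tol : float
        Gradient tolerance for Newton convergence, relative to the
        number of observations.
    max_iter : int
        Maximum Newton iterations.
    ridge : float
        Ridge penalty per observation.  Zero by default; on separation
        or non-convergence the fit is retried with ``ridge_fallback``
        and ``regularized_`` is set.
    ridge_fallback : float
        Penalty used for the automatic retry.

    Attributes
    ----------
    coef_ : pandas.DataFrame
        Terms x non-reference destinations (absent destinations dropped).
    bse_ : pandas.DataFrame
        Asymptotic standard errors from the observed information.
    knots_ : ndarray
        Resolved age-spline knots.
    loglik_ : float
    converged_ : bool
    absent_destinations_ : tuple of str
        Destinations never observed; their predicted probability is
        exactly zero.
    """

    def __init__(self, spec: ModelSpec | None = None, tol: float = 1e-8,
                 max_iter: int = 500, ridge: float = 0.0,
                 ridge_fallback: float = 1e-6):
        self.spec = spec
        self.tol = tol
        self.max_iter = max_iter
        self.ridge = ridge
        self.ridge_fallback = ridge_fallback

    # -- fitting -----------------------------------------------------------

    def _resolved_spec(self) -> ModelSpec:
        return self.spec if self.spec is not None else ModelSpec()

    def fit(self, X: pd.DataFrame, y, sample_weight=None):
        """Fit to person-period records.

        ``X`` must provide columns ``origin`` and ``age`` plus one column
        per main-effect block; ``y`` holds destination state labels.
        """
        spec = self._resolved_spec()
        y = np.asarray(y)
        if len(X) == 0:
            raise EmptyGroupError("cannot fit on zero records")
        if len(y) != len(X):
            raise ConfigurationError("X and y length mismatch")
        bad = set(np.unique(y)) - set(STATES)
        if bad:
            raise ConfigurationError(f"unknown destination label(s): {sorted(bad)}")

        dests = destination_order(spec)
        dest_code = {s: i for i, s in enumerate(dests)}
        y_codes = np.asarray([dest_code[v] for v in y], dtype=np.int64)
        w = None if sample_weight is None else np.asarray(sample_weight, dtype=float)

        knots = spec.resolve_knots(X["age"].to_numpy(dtype=float))
        Xu, Y = self._aggregate(X, spec, knots, y_codes, len(dests), w)

        present = Y.sum(axis=0) > 0
        if not present[0]:
            raise FitError(
                f"reference destination {dests[0]!r} never observed in this stratum"
            )
        keep_eq = np.flatnonzero(present[1:])
        Yk = Y[:, np.concatenate([[0], keep_eq + 1])]

        try:
            B, ll, conv, n_iter, info = _newton_fit(
                Xu, Yk, self.ridge, self.tol, self.max_iter
            )
            regularized = self.ridge > 0
            if not conv:
                raise FitError("Newton did not converge")
        except FitError:
            B, ll, conv, n_iter, info = _newton_fit(
                Xu, Yk, self.ridge_fallback, self.tol, self.max_iter
            )
            regularized = True
            if not conv:
                raise FitError(
                    "multinomial fit failed to converge even with ridge fallback"
                )

        p = Xu.shape[1]
        names = term_names(spec, knots)
        kept_dests = [dests[1:][i] for i in keep_eq]
        try:
            cov = np.linalg.inv(info)
            se = np.sqrt(np.clip(np.diag(cov), 0, None)).reshape((len(kept_dests), p)).T
        except np.linalg.LinAlgError:
            se = np.full((p, len(kept_dests)), np.nan)

        self.spec_ = spec
        self.knots_ = knots
        self.terms_ = names
        self.classes_ = dests
        self.coef_ = pd.DataFrame(B, index=names, columns=kept_dests)
        self.bse_ = pd.DataFrame(se, index=names, columns=kept_dests)
        self.loglik_ = ll
        self.converged_ = conv
        self.n_iter_ = n_iter
        self.regularized_ = regularized
        self.absent_destinations_ = tuple(
            d for i, d in enumerate(dests[1:]) if i not in keep_eq
        )
        self.n_obs_ = float(Y.sum())
        return self

    @staticmethod
    def _aggregate(X: pd.DataFrame, spec: ModelSpec, knots,
                   y_codes: np.ndarray, n_dest: int,
                   weights: np.ndarray | None):
        """Collapse records sharing a design row into multinomial cells.

        Ages and covariates are discrete, so the design matrix takes few
        distinct values; grouping on the integer covariate codes (not the
        float rows) keeps aggregation linear-time.
        """
        code_cols = ["age", "origin", *spec.blocks()]
        codes, dims = [], []
        for col in code_cols:
            u, inv = np.unique(X[col].to_numpy(), return_inverse=True)
            codes.append(inv.ravel())
            dims.append(len(u))
        cell = np.ravel_multi_index(codes, dims)
        _, first, inv = np.unique(cell, return_index=True, return_inverse=True)
        inv = inv.ravel()
        Y = np.bincount(
            inv * n_dest + y_codes, weights=weights,
            minlength=first.size * n_dest,
        ).astype(float).reshape((first.size, n_dest))
        Xu = design_matrix(X.iloc[first], spec, knots)
        keep = Y.sum(axis=1) > 0
        return Xu[keep], Y[keep]

    # -- prediction --------------------------------------------------------

    def _full_probs(self, design: np.ndarray) -> np.ndarray:
        """(n, 4) probabilities in canonical STATES order."""
        P = _stable_probs(design @ self.coef_.to_numpy())
        probs = {self.classes_[0]: P[:, 0]}
        for j, d in enumerate(self.coef_.columns):
            probs[d] = P[:, j + 1]
        for d in self.absent_destinations_:
            probs[d] = np.zeros(design.shape[0])
        return np.column_stack([probs[s] for s in STATES])

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Destination probabilities for person-period records, columns in
        canonical state order (employed, jobless, retired, dead)."""
        design = design_matrix(X, self.spec_, self.knots_)
        return self._full_probs(design)

    def transition_probabilities(
        self,
        profile: CovariateProfile,
        ages,
        step: int,
        zero_cells: list[tuple[str, str]] | None = None,
    ) -> TransitionProbabilities:
        """Age-specific transition matrices at a covariate profile.

        ``zero_cells`` optionally names (origin, destination) cells that
        are forced to zero, with the row renormalized (structural-zero
        mask; off by default so that rare back-flows stay estimable).
        """
        return matrices_at_profile(
            self.coef_.to_numpy(), list(self.coef_.columns), self.classes_,
            self.spec_, self.knots_, profile, ages, step, zero_cells,
        )


def matrices_at_profile(
    coef: np.ndarray,
    coef_dests: list[str],
    classes: tuple[str, ...],
    spec: ModelSpec,
    knots,
    profile: CovariateProfile,
    ages,
    step: int,
    zero_cells=None,
) -> TransitionProbabilities:
    """Transition matrices at a profile from a raw coefficient array.

    ``coef`` is (p, k) for the k present non-reference destinations named
    in ``coef_dests``; ``classes`` is the full destination order with the
    reference first.  Destinations missing from ``coef_dests`` get
    probability exactly zero.
    """
    ages = np.asarray(ages, dtype=float)
    probs = np.empty((ages.size, len(TRANSIENT_STATES), len(STATES)))
    state_col = {s: j for j, s in enumerate(STATES)}
    for i, origin in enumerate(TRANSIENT_STATES):
        design = profile_design(profile, origin, ages, spec, knots)
        P = _stable_probs(design @ coef)
        out = np.zeros((ages.size, len(STATES)))
        out[:, state_col[classes[0]]] = P[:, 0]
        for j, d in enumerate(coef_dests):
            out[:, state_col[d]] = P[:, j + 1]
        probs[:, i, :] = out
    if zero_cells:
        for origin, dest in zero_cells:
            if dest == DEAD:
                raise ConfigurationError("cannot zero a death cell")
            probs[:, TRANSIENT_STATES.index(origin), STATES.index(dest)] = 0.0
        probs /= probs.sum(axis=2, keepdims=True)
    return TransitionProbabilities(ages=ages, step=step, probs=probs)


def probabilities_from_coefficients(
    coef: pd.DataFrame,
    spec: ModelSpec,
    knots,
    profile: CovariateProfile,
    ages,
    step: int,
) -> TransitionProbabilities:
    """Transition matrices implied by an explicit coefficient table.

    ``coef`` is terms x non-reference destinations in the layout produced
    by fitting; used for ground-truth chains and serialized models.
    """
    model = MultinomialTransitionModel(spec=spec)
    model.spec_ = spec
    model.knots_ = np.asarray(knots, dtype=float)
    model.terms_ = list(coef.index)
    model.classes_ = destination_order(spec)
    model.coef_ = coef
    model.absent_destinations_ = tuple(
        d for d in model.classes_[1:] if d not in coef.columns
    )
    return model.transition_probabilities(profile, ages, step)


def fit_transition_models(
    records: pd.DataFrame,
    spec: ModelSpec | None = None,
    sample_weight=None,
    **fit_kwargs,
) -> dict[str, MultinomialTransitionModel]:
    """Fit one gender-stratified model per stratum present in ``records``.

    Stratifying by gender is equivalent to interacting gender with every
    term of a pooled model.
    """
    out: dict[str, MultinomialTransitionModel] = {}
    genders = [g for g in GENDERS if (records["gender"] == g).any()]
    if not genders:
        raise EmptyGroupError("no recognised gender stratum in records")
    for g in genders:
        mask = (records["gender"] == g).to_numpy()
        w = None if sample_weight is None else np.asarray(sample_weight)[mask]
        if w is not None and w.sum() <= 0:
            raise EmptyGroupError(f"stratum {g!r} has zero total weight")
        model = MultinomialTransitionModel(spec=spec, **fit_kwargs)
        model.fit(records.loc[mask], records.loc[mask, "destination"], sample_weight=w)
        out[g] = model
    return out
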