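"""Random-intercept logistic regression of citation likelihood.

Citation paths leading to the same citing publication share its random
intercept: with y_ij the realization of path i under citing publication
j, the model is

    logit P(y_ij = 1 | u_j) = x_ij' beta + u_j,     u_j ~ N(0, sigma^2),

where x_ij describes the *cited* publication.  The marginal
log-likelihood integrates the per-group Bernoulli likelihood over the
Normal random effect; the integral is evaluated by Gauss-Hermite
quadrature, either on fixed nodes or adaptively re-centered at each
group's posterior mode (the default for fitting, which matters for
large groups).  Maximization is quasi-Newton on (beta, log sigma) with
the quadrature centering refreshed between rounds, followed by Newton
polishing so the reported gradient norm is honest.

Effects are reported as odds ratios with Wald 95% intervals; the suite
driver fits one crude model per determinant and one adjusted model that
adds the study-design block, mirroring the crude/adjusted table layout
of citation-bias analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp, roots_hermite

from .corpus import Corpus
from .determinants import (
    MODEL_DETERMINANTS,
    AuthorityLedger,
    CategorySpec,
    DesignMatrix,
    build_authority_ledger,
    build_design_rows,
)
from .errors import ConfigError, FitError, NotEstimableError, SeparationError
from .paths import (
    CitationSummary,
    PathSet,
    TemporalRule,
    enumerate_potential_paths,
    mark_realized,
    summarize_citations,
)

__all__ = [
    "GroupedDesign",
    "ModelSpec",
    "FittedModel",
    "EffectEstimate",
    "marginal_loglik",
    "fit_random_intercept_logistic",
    "fit_plain_logistic",
    "odds_ratio_table",
    "run_analysis_suite",
    "sensitivity_exclude_highly_cited",
    "AnalysisSuite",
    "DeterminantResult",
]

_Z95 = 1.96  # Wald 95% multiplier


# ---------------------------------------------------------------------------
# Data container


@dataclass
class GroupedDesign:
    """Design rows sorted by citing-publication group.

    ``X`` includes a leading intercept column; ``starts`` are the group
    boundary indices used for segmented reductions.
    """

    X: np.ndarray
    y: np.ndarray
    group_codes: np.ndarray
    starts: np.ndarray
    colnames: list[str]
    group_labels: list[str]

    @classmethod
    def from_design(cls, dm: DesignMatrix) -> "GroupedDesign":
        frame = dm.frame
        codes, labels = pd.factorize(frame["group"], sort=True)
        order = np.argsort(codes, kind="stable")
        cols = dm.columns
        X = np.column_stack(
            [np.ones(len(frame))] + [frame[c].to_numpy(dtype=float) for c in cols]
        )[order]
        y = frame["y"].to_numpy(dtype=float)[order]
        codes = codes[order]
        starts = np.flatnonzero(np.r_[True, np.diff(codes) != 0])
        return cls(X=X, y=y, group_codes=codes, starts=starts,
                   colnames=["(intercept)"] + cols, group_labels=list(labels))

    @property
    def n_rows(self) -> int:
        return len(self.y)

    @property
    def n_groups(self) -> int:
        return len(self.starts)

    @property
    def n_params(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: covariate blocks, optional study-design adjustment,
    and whether a citing-publication random intercept is included."""

    covariates: tuple[str, ...]
    adjust_for_design: bool = False
    random_intercept: bool = True

    @property
    def terms(self) -> tuple[str, ...]:
        terms = self.covariates
        if self.adjust_for_design and "design" not in terms:
            terms = terms + ("design",)
        return terms


# ---------------------------------------------------------------------------
# Marginal likelihood


def _group_sum(values: np.ndarray, starts: np.ndarray) -> np.ndarray:
    return np.add.reduceat(values, starts)


def _bernoulli_part(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    # y*eta - log(1 + exp(eta)), stable for large |eta|
    return y * eta - np.logaddexp(0.0, eta)


def _adaptive_centers(beta: np.ndarray, sigma: float, data: GroupedDesign,
                      tol: float = 1e-10, max_iter: int = 80,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mode u*_j and Laplace scale tau_j for every group."""
    eta0 = data.X @ beta
    u = np.zeros(data.n_groups)
    g = data.group_codes
    for _ in range(max_iter):
        eta = eta0 + sigma * u[g]
        p = expit(eta)
        score = -u + sigma * _group_sum(data.y - p, data.starts)
        hess = -(1.0 + sigma**2 * _group_sum(p * (1.0 - p), data.starts))
        step = np.clip(-score / hess, -2.0, 2.0)
        u = u + step
        if np.max(np.abs(step)) < tol:
            break
    eta = eta0 + sigma * u[g]
    p = expit(eta)
    hess = -(1.0 + sigma**2 * _group_sum(p * (1.0 - p), data.starts))
    tau = 1.0 / np.sqrt(-hess)
    return u, tau


def _quad_nodes(beta: np.ndarray, sigma: float, data: GroupedDesign, K: int,
                adaptive: bool) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature abscissae ``U`` (G, K) on the random-effect scale and
    log-weights ``LW`` (G, K) such that
    log ∫ φ(u) g_j(u) du = logsumexp_k [ LW_jk + log g_j(U_jk) ]."""
    t, w = roots_hermite(K)
    logw = np.log(w)
    G = data.n_groups
    if not adaptive or sigma == 0.0:
        U = np.broadcast_to(math.sqrt(2.0) * t, (G, K)).copy()
        LW = np.broadcast_to(logw - 0.5 * math.log(math.pi), (G, K)).copy()
        return U, LW
    u_star, tau = _adaptive_centers(beta, sigma, data)
    U = u_star[:, None] + math.sqrt(2.0) * tau[:, None] * t[None, :]
    LW = (
        logw[None, :]
        + t[None, :] ** 2
        - 0.5 * U**2
        - 0.5 * math.log(2.0 * math.pi)
        + 0.5 * math.log(2.0)
        + np.log(tau)[:, None]
    )
    return U, LW


def _frozen_negll_grad(theta: np.ndarray, data: GroupedDesign,
                       U: np.ndarray, LW: np.ndarray,
                       fix_sigma: float | None,
                       ) -> tuple[float, np.ndarray]:
    """Negative log-likelihood and gradient with the quadrature nodes
    held fixed.  ``theta`` is (beta, log sigma), or just beta when the
    random-effect SD is fixed."""
    p = data.n_params
    beta = theta[:p]
    sigma = fix_sigma if fix_sigma is not None else math.exp(theta[p])
    eta0 = data.X @ beta
    g = data.group_codes
    K = U.shape[1]
    B = np.empty((data.n_groups, K))
    mus = []
    for k in range(K):
        eta = eta0 + sigma * U[g, k]
        B[:, k] = _group_sum(_bernoulli_part(eta, data.y), data.starts)
        mus.append(expit(eta))
    M = LW + B
    ll_j = logsumexp(M, axis=1)
    ll = float(ll_j.sum())
    P = np.exp(M - ll_j[:, None])  # posterior quadrature weights per group

    grad_beta = np.zeros(p)
    grad_sigma = 0.0
    for k in range(K):
        r = (data.y - mus[k]) * P[g, k]
        grad_beta += data.X.T @ r
        grad_sigma += float(r @ U[g, k])
    if fix_sigma is not None:
        return -ll, -grad_beta
    grad = np.append(grad_beta, grad_sigma * sigma)  # chain rule to log sigma
    return -ll, -grad


def marginal_loglik(beta: Sequence[float], sigma: float, data: GroupedDesign,
                    K: int = 15, adaptive: bool = False) -> float:
    """Marginal log-likelihood of the random-intercept logistic model.

    Sum over citing groups j of
    ``log ∫ φ(u) Π_{i∈j} p_ij^y (1-p_ij)^(1-y) du`` with
    ``logit p_ij = x_ij·β + σu``, evaluated by K-node Gauss-Hermite
    quadrature (exact in the limit K → ∞).  ``adaptive=True`` re-centers
    the nodes at each group's posterior mode.  With ``sigma = 0`` this
    reduces exactly to the plain Bernoulli log-likelihood.
    """
    if K < 1:
        raise ConfigError(f"quadrature order K must be >= 1, got {K}")
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(data.X)) or not np.all(np.isfinite(beta)):
        raise FitError("non-finite covariates or coefficients")
    if sigma < 0:
        raise ConfigError("sigma must be nonnegative")
    U, LW = _quad_nodes(beta, float(sigma), data, K, adaptive)
    negll, _ = _frozen_negll_grad(
        np.append(beta, 0.0), data, U, LW, fix_sigma=float(sigma))
    return -negll


# ---------------------------------------------------------------------------
# Fitted models


@dataclass
class FittedModel:
    """A maximized (marginal) logistic likelihood.

    ``beta`` is on the log-odds scale in the order of ``colnames``;
    ``sigma`` is the random-intercept SD (0 for plain logistic);
    ``vcov`` is the coefficient covariance for the beta block.
    """

    colnames: list[str]
    beta: np.ndarray
    sigma: float
    vcov: np.ndarray
    loglik: float
    converged: bool
    n_groups: int
    n_rows: int
    grad_norm: float = math.nan
    sigma_se: float | None = None
    K: int | None = None
    adaptive: bool | None = None

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))

    def coef(self, name: str) -> float:
        return float(self.beta[self.colnames.index(name)])


def _check_estimable(data: GroupedDesign) -> None:
    y = data.y
    if y.min() == y.max():
        raise SeparationError(
            "degenerate outcome: all paths share the same realization")
    for k, name in enumerate(data.colnames):
        if name == "(intercept)":
            continue
        x = data.X[:, k]
        n1 = x.sum()
        if n1 == 0:
            raise NotEstimableError(f"empty category: no paths with {name} = 1")
        e1 = float(y @ x)
        if e1 == 0.0 or e1 == n1:
            raise SeparationError(
                f"monotone likelihood in {name}: "
                f"{int(e1)} events among {int(n1)} paths")
    # The reference-cell check is conclusive only when each row activates
    # at most one indicator (single covariate block): there the direction
    # (intercept down, every indicator up) moves only the reference rows.
    row_active = data.X[:, 1:].sum(axis=1)
    if row_active.max(initial=0) <= 1:
        base = row_active == 0
        if base.any():
            eb, nb = float(y[base].sum()), int(base.sum())
            if eb == 0.0 or eb == nb:
                raise SeparationError(
                    f"monotone likelihood in the reference cell: "
                    f"{int(eb)} events among {nb} paths")


def _check_rank(data: GroupedDesign) -> None:
    _, r = np.linalg.qr(data.X)
    small = np.abs(np.diag(r)) < 1e-8 * max(1.0, np.abs(np.diag(r)).max())
    if small.any():
        bad = [data.colnames[i] for i in np.flatnonzero(small)]
        raise FitError(f"design matrix is rank deficient; collinear columns: {bad}")


def _numeric_hessian(fun, theta: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian from an analytic gradient."""
    d = len(theta)
    H = np.zeros((d, d))
    for i in range(d):
        step = np.zeros(d)
        step[i] = h
        _, g_plus = fun(theta + step)
        _, g_minus = fun(theta - step)
        H[:, i] = (g_plus - g_minus) / (2 * h)
    return 0.5 * (H + H.T)


def fit_random_intercept_logistic(data: GroupedDesign, K: int = 15,
                                  adaptive: bool = True,
                                  fix_sigma: float | None = None,
                                  gtol: float = 1e-5,
                                  max_outer: int = 12) -> FittedModel:
    """Maximize the marginal likelihood over (beta, log sigma).

    Starts from beta = 0, log sigma = 0.  With adaptive quadrature the
    node centering is refreshed between quasi-Newton rounds until the
    estimates stabilize; a Newton polish then drives the gradient norm
    of the (final-centred) objective below ``gtol`` so the ``converged``
    flag is honest.  Standard errors come from the numerically
    differentiated observed information.

    ``fix_sigma`` pins the random-effect SD (0 gives the plain logistic
    MLE through the same code path).
    """
    if K < 1:
        raise ConfigError(f"quadrature order K must be >= 1, got {K}")
    _check_estimable(data)  # empty categories first: the clearer diagnosis
    _check_rank(data)
    if fix_sigma is None and data.n_groups < 2:
        raise FitError("need >= 2 citing groups to estimate a random intercept")

    p = data.n_params
    theta = np.zeros(p + (0 if fix_sigma is not None else 1))

    def current_sigma(th: np.ndarray) -> float:
        return fix_sigma if fix_sigma is not None else math.exp(th[p])

    bounds = None
    if fix_sigma is None:
        bounds = [(None, None)] * p + [(-10.0, 3.0)]

    nodes = _quad_nodes(theta[:p], current_sigma(theta), data, K, adaptive)
    for _ in range(max_outer):
        res = minimize(
            _frozen_negll_grad, theta, args=(data, *nodes, fix_sigma),
            method="L-BFGS-B", jac=True, bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        moved = np.max(np.abs(res.x - theta))
        theta = res.x
        if not adaptive or fix_sigma == 0.0:
            break
        nodes = _quad_nodes(theta[:p], current_sigma(theta), data, K, adaptive)
        if moved < 1e-7:
            break

    # Newton polish on the final-centred objective.
    def fg(th: np.ndarray):
        return _frozen_negll_grad(th, data, *nodes, fix_sigma)

    negll, grad = fg(theta)
    for _ in range(25):
        if np.max(np.abs(grad)) < 1e-8:
            break
        H = _numeric_hessian(fg, theta)
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(len(H)), -grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(20):
            cand = theta + scale * step
            n2, g2 = fg(cand)
            if n2 <= negll + 1e-12:
                theta, negll, grad = cand, n2, g2
                break
            scale *= 0.5
        else:
            break

    grad_norm = float(np.max(np.abs(grad)))
    sigma = current_sigma(theta)
    at_bound = fix_sigma is None and theta[p] <= -10.0 + 1e-8
    converged = grad_norm < gtol or (at_bound and np.max(np.abs(grad[:p])) < gtol)

    H = _numeric_hessian(fg, theta)
    try:
        vcov_full = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vcov_full = np.full_like(H, np.nan)
        converged = False
    sigma_se = None
    if fix_sigma is None and np.isfinite(vcov_full[p, p]) and vcov_full[p, p] > 0:
        sigma_se = sigma * math.sqrt(vcov_full[p, p])  # delta method from log sigma

    return FittedModel(
        colnames=list(data.colnames), beta=theta[:p].copy(), sigma=float(sigma),
        vcov=vcov_full[:p, :p], loglik=-negll, converged=bool(converged),
        n_groups=data.n_groups, n_rows=data.n_rows, grad_norm=grad_norm,
        sigma_se=sigma_se, K=K, adaptive=adaptive,
    )


def fit_plain_logistic(data: GroupedDesign) -> FittedModel:
    """Ordinary (single-level) logistic MLE via IRLS.

    Used for the concordance analysis, where no random intercept is
    modelled; delegates the fit to statsmodels' binomial GLM.
    """
    import statsmodels.api as sm

    _check_estimable(data)
    _check_rank(data)
    model = sm.GLM(data.y, data.X, family=sm.families.Binomial())
    res = model.fit()
    return FittedModel(
        colnames=list(data.colnames), beta=np.asarray(res.params, dtype=float),
        sigma=0.0, vcov=np.asarray(res.cov_params(), dtype=float),
        loglik=float(res.llf), converged=bool(res.converged),
        n_groups=data.n_groups, n_rows=data.n_rows,
    )


# ---------------------------------------------------------------------------
# Odds-ratio tables


@dataclass(frozen=True)
class EffectEstimate:
    """One odds-ratio row: OR = exp(beta) with Wald 95% CI."""

    term: str
    level: str
    or_: float
    ci_low: float
    ci_high: float
    beta: float = 0.0
    se: float = 0.0
    reference: bool = False

    def format(self) -> str:
        if self.reference:
            return "1.00 (ref)"
        return f"{self.or_:.2f} ({self.ci_low:.2f}-{self.ci_high:.2f})"


def odds_ratio_table(model: FittedModel,
                     dm: DesignMatrix | None = None,
                     terms: Sequence[str] | None = None) -> list[EffectEstimate]:
    """Exponentiated coefficients with Wald 95% intervals.

    When a :class:`DesignMatrix` is supplied, reference levels are
    emitted as explicit "1.00 (ref)" rows and ``terms`` may restrict the
    output to a subset of blocks (e.g. only the determinant of interest
    in an adjusted model).
    """
    se = model.se
    rows: list[EffectEstimate] = []

    def estimate_for(col: str) -> EffectEstimate:
        k = model.colnames.index(col)
        term, _, lvl = col.partition("[")
        b, s = float(model.beta[k]), float(se[k])
        return EffectEstimate(
            term=term, level=lvl.rstrip("]"), or_=math.exp(b),
            ci_low=math.exp(b - _Z95 * s), ci_high=math.exp(b + _Z95 * s),
            beta=b, se=s)

    if dm is None:
        for col in model.colnames:
            if col != "(intercept)":
                rows.append(estimate_for(col))
        return rows

    for term, cols in dm.blocks.items():
        if terms is not None and term not in terms:
            continue
        ref = dm.references[term]
        rows.append(EffectEstimate(term=term, level=ref, or_=1.0,
                                   ci_low=1.0, ci_high=1.0, reference=True))
        rows.extend(estimate_for(c) for c in cols)
    return rows


# ---------------------------------------------------------------------------
# Analysis suite


@dataclass
class DeterminantResult:
    """Crude and design-adjusted estimates for one determinant, or the
    reason it was not estimable (mirroring an 'NA' table cell)."""

    determinant: str
    crude: list[EffectEstimate] | None = None
    crude_error: str | None = None
    crude_model: FittedModel | None = None
    adjusted: list[EffectEstimate] | None = None
    adjusted_error: str | None = None
    adjusted_model: FittedModel | None = None

    @property
    def estimable(self) -> bool:
        return self.crude is not None


@dataclass
class AnalysisSuite:
    """Everything the analysis of one corpus produces."""

    results: dict[str, DeterminantResult]
    concordance: EffectEstimate | None
    concordance_error: str | None
    summary: CitationSummary
    pathset: PathSet
    specs: dict[str, CategorySpec]
    rule: TemporalRule

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: determinant, level, crude/adjusted OR and CI."""
        recs = []
        for name, r in self.results.items():
            if not r.estimable:
                recs.append({"determinant": name, "level": "", "reference": False,
                             "crude_or": np.nan, "crude_low": np.nan,
                             "crude_high": np.nan, "adjusted_or": np.nan,
                             "adjusted_low": np.nan, "adjusted_high": np.nan,
                             "note": r.crude_error})
                continue
            adj = {(e.term, e.level): e for e in (r.adjusted or [])}
            for e in r.crude:
                a = adj.get((e.term, e.level))
                recs.append({
                    "determinant": name, "level": e.level, "reference": e.reference,
                    "crude_or": e.or_, "crude_low": e.ci_low, "crude_high": e.ci_high,
                    "adjusted_or": a.or_ if a else np.nan,
                    "adjusted_low": a.ci_low if a else np.nan,
                    "adjusted_high": a.ci_high if a else np.nan,
                    "note": r.adjusted_error or "",
                })
        return pd.DataFrame(recs)


def run_analysis_suite(corpus: Corpus,
                       rule: TemporalRule | None = None,
                       determinants: Sequence[str] = MODEL_DETERMINANTS,
                       K: int = 15,
                       adaptive: bool = True,
                       authority_mode: Literal["cumulative", "per_year"] = "cumulative",
                       authority_offset: int = 1,
                       specs: dict[str, CategorySpec] | None = None,
                       ) -> AnalysisSuite:
    """Crude and design-adjusted odds-ratio tables for every determinant.

    For each determinant a univariate random-intercept model is fitted
    first; the adjusted model adds the study-design indicator block
    (study design itself gets no separate adjusted model).  Determinants
    with empty categories or separated outcomes are reported as
    not-estimable with the reason, and the suite continues.  The
    concordance analysis is a plain logistic fit on the eligible paths.
    """
    rule = rule or TemporalRule()
    pathset = mark_realized(enumerate_potential_paths(corpus, rule), corpus)
    ledger = build_authority_ledger(corpus, pathset, mode=authority_mode)
    shared_specs: dict[str, CategorySpec] = dict(specs) if specs else {}

    def fit_terms(terms: tuple[str, ...]):
        dm = build_design_rows(pathset, corpus, ledger=ledger, specs=shared_specs,
                               covariates=terms, authority_offset=authority_offset)
        shared_specs.update(dm.specs)
        data = GroupedDesign.from_design(dm)
        model = fit_random_intercept_logistic(data, K=K, adaptive=adaptive)
        return dm, model

    results: dict[str, DeterminantResult] = {}
    for det in determinants:
        r = DeterminantResult(determinant=det)
        try:
            dm, model = fit_terms((det,))
            r.crude = odds_ratio_table(model, dm)
            r.crude_model = model
        except (SeparationError, NotEstimableError, FitError) as exc:
            r.crude_error = f"{det}: {exc}"
            results[det] = r
            continue
        if det != "design":
            try:
                dm_a, model_a = fit_terms((det, "design"))
                r.adjusted = odds_ratio_table(model_a, dm_a, terms=[det])
                r.adjusted_model = model_a
            except (SeparationError, NotEstimableError, FitError) as exc:
                r.adjusted_error = f"{det} (adjusted): {exc}"
        results[det] = r

    concordance = None
    concordance_error = None
    try:
        dm_c = build_design_rows(pathset, corpus, ledger=ledger,
                                 covariates=("concordance",))
        model_c = fit_plain_logistic(GroupedDesign.from_design(dm_c))
        concordance = odds_ratio_table(model_c, dm_c)[1]  # non-reference row
    except (SeparationError, NotEstimableError, FitError) as exc:
        concordance_error = str(exc)

    return AnalysisSuite(
        results=results, concordance=concordance,
        concordance_error=concordance_error,
        summary=summarize_citations(pathset), pathset=pathset,
        specs=shared_specs, rule=rule,
    )


@dataclass
class SensitivityResult:
    suite: AnalysisSuite
    excluded_ids: list[str]
    threshold: float


def sensitivity_exclude_highly_cited(corpus: Corpus,
                                     threshold: float = 50,
                                     rule: TemporalRule | None = None,
                                     **suite_kwargs) -> SensitivityResult:
    """Re-run the full suite after removing hub publications.

    Publications that received more than ``threshold`` citations are
    removed in both roles (citing and cited); paths are re-enumerated,
    the authority ledger rebuilt, and every model refitted on the
    reduced network.  With an infinite threshold this is a no-op.
    """
    rule = rule or TemporalRule()
    pathset = mark_realized(enumerate_potential_paths(corpus, rule), corpus)
    received = summarize_citations(pathset).received
    excluded = [pid for pid, n in received.items() if n > threshold]
    if len(excluded) == len(corpus):
        raise ConfigError(
            f"threshold {threshold} removes every publication in the corpus")
    reduced = corpus.subset([pid for pid in corpus.ids if pid not in excluded])
    suite = run_analysis_suite(reduced, rule=rule, **suite_kwargs)
    return SensitivityResult(suite=suite, excluded_ids=excluded,
                             threshold=threshold)
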