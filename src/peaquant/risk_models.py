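"""Case-cohort survival modelling.

The clinical layer analyses a case-cohort sample: every subject who
experienced the event plus a random subcohort of roughly twice as many
non-cases, analysed with inverse-probability sampling weights
(Barlow-style: cases weight 1, subcohort non-cases weight
1 / sampling-fraction).  On top of that design this module provides

* restricted cubic splines (Harrell's truncated-power basis, four knots at
  the 5th/35th/65th/95th percentiles by default) for flexible continuous
  effects,
* a weighted Cox proportional-hazards fitter (Breslow tie handling, damped
  Newton) with a robust sandwich variance built from weighted score
  residuals,
* Q3-vs-Q1 hazard ratios read off the fitted spline contribution,
* a weighted Harrell's C concordance index,
* the fraction of new information, FNI = 1 - chi2_reduced / chi2_full, of a
  variable within a model,
* Harrell-Efron bootstrap optimism correction of the C-index, and
* a multi-model comparison harness with paired-bootstrap confidence
  intervals for C-index differences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("peaquant")

RESERVED_COLUMNS = ("subject_id", "time", "event", "weight", "in_subcohort")


class CoxError(RuntimeError):
    """Weighted Cox fit failed (non-convergence, separation, rank deficiency)."""


# ---------------------------------------------------------------------------
# Cohort container
# ---------------------------------------------------------------------------


@dataclass
class SurvivalCohort:
    """Case-cohort survival data.

    ``data`` columns: ``subject_id, time, event, weight, in_subcohort`` plus
    one column per covariate.  ``weight`` carries the sampling design: 1 for
    cases, inverse subcohort-sampling-fraction for sampled non-cases.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in RESERVED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"SurvivalCohort missing columns: {missing}")
        if (self.data["time"] <= 0).any():
            raise ValueError("follow-up times must be positive")
        w = self.data["weight"].to_numpy(dtype=float)
        if not np.all(np.isfinite(w)) or np.any(w < 1.0 - 1e-12):
            raise ValueError("sampling weights must be finite and >= 1")

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in RESERVED_COLUMNS]

    @property
    def n_events(self) -> int:
        return int(self.data["event"].sum())

    def __len__(self) -> int:
        return len(self.data)


def derive_case_cohort_weights(
    df: pd.DataFrame, n_cohort_total: int | None = None
) -> pd.DataFrame:
    """Fill in Barlow-style weights from ``event`` / ``in_subcohort`` flags.

    Cases get weight 1.  Sampled non-cases get the inverse of the non-case
    sampling fraction, which requires the size of the full source cohort;
    without it the table is taken to be the full cohort (all weights 1).
    """
    out = df.copy()
    if n_cohort_total is None:
        out["weight"] = 1.0
        return out
    n_cases = int(out["event"].sum())
    n_noncases_sampled = int(((out["event"] == 0)).sum())
    n_noncases_total = n_cohort_total - n_cases
    if n_noncases_sampled == 0 or n_noncases_total <= 0:
        raise ValueError("cannot derive weights: no non-cases")
    frac = n_noncases_sampled / n_noncases_total
    out["weight"] = np.where(out["event"] == 1, 1.0, 1.0 / frac)
    return out


# ---------------------------------------------------------------------------
# Restricted cubic splines
# ---------------------------------------------------------------------------

AUTO_KNOT_PERCENTILES = (5.0, 35.0, 65.0, 95.0)


@dataclass(frozen=True)
class SplineBasis:
    """Four-knot restricted cubic spline basis (Harrell convention).

    Columns: the linear term plus two nonlinear truncated-power terms,
    normalised by the squared boundary-knot span.  The function represented
    is linear beyond the boundary knots and the nonlinear columns vanish at
    and below the first knot.
    """

    knots: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if len(set(self.knots)) != 4 or list(self.knots) != sorted(self.knots):
            raise ValueError(f"need 4 distinct increasing knots, got {self.knots}")

    @property
    def n_columns(self) -> int:
        return 3

    def transform(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        t = np.asarray(self.knots)
        k = 4
        norm = (t[k - 1] - t[0]) ** 2
        cols = [x]
        for j in range(k - 2):
            term = (
                np.maximum(x - t[j], 0.0) ** 3
                - np.maximum(x - t[k - 2], 0.0) ** 3 * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
                + np.maximum(x - t[k - 1], 0.0) ** 3 * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2])
            )
            cols.append(term / norm)
        return np.column_stack(cols)


def rcs_basis(x, knots="auto") -> tuple[SplineBasis, np.ndarray]:
    """Build the restricted cubic spline basis for covariate values ``x``.

    ``knots="auto"`` places the four knots at the 5th/35th/65th/95th
    percentiles of ``x``.
    """
    x = np.asarray(x, dtype=float)
    if isinstance(knots, str) and knots == "auto":
        if np.unique(x).size < 4:
            raise ValueError("need >=4 distinct values for automatic knots")
        kn = tuple(float(v) for v in np.percentile(x, AUTO_KNOT_PERCENTILES))
        if len(set(kn)) != 4:
            raise ValueError(f"automatic knots are not distinct: {kn}")
    else:
        kn = tuple(float(v) for v in knots)
    basis = SplineBasis(knots=kn)  # type: ignore[arg-type]
    return basis, basis.transform(x)


# ---------------------------------------------------------------------------
# Weighted Cox partial likelihood (Breslow ties), Newton optimisation
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    """Result of a weighted Cox fit."""

    coef: np.ndarray
    columns: tuple[str, ...]
    loglik_null: float
    loglik_full: float
    robust_se: np.ndarray
    robust_cov: np.ndarray
    info_inv: np.ndarray
    converged: bool
    n_events: int
    n: int

    @property
    def lr_chisq(self) -> float:
        return 2.0 * (self.loglik_full - self.loglik_null)

    def to_row(self) -> dict:
        row = {"loglik_null": self.loglik_null, "loglik_full": self.loglik_full,
               "lr_chisq": self.lr_chisq, "n_events": self.n_events, "n": self.n}
        for name, b, se in zip(self.columns, self.coef, self.robust_se):
            row[f"coef_{name}"] = b
            row[f"robust_se_{name}"] = se
        return row


def _cox_loglik_grad_hess(beta, time, event, X, w):
    """Weighted Breslow partial log-likelihood with gradient and Hessian.

    Rows must be sorted by ascending time; the risk set of an event at t is
    every subject with time >= t (ties share one risk set).
    """
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -500, 500)
    r = w * np.exp(eta)

    # reverse cumulative sums -> risk-set aggregates at each index
    s0_rev = np.cumsum(r[::-1])[::-1]
    s1_rev = np.cumsum((r[:, None] * X)[::-1], axis=0)[::-1]
    # tie groups: subjects with equal time share the risk set of the first
    first_idx = np.zeros(n, dtype=int)
    start = 0
    for i in range(1, n + 1):
        if i == n or time[i] != time[start]:
            first_idx[start:i] = start
            start = i
    ev = event.astype(bool)
    idx = first_idx[ev]
    we = w[ev]
    s0 = s0_rev[idx]
    s1 = s1_rev[idx]
    xbar = s1 / s0[:, None]

    ll = float(np.sum(we * (eta[ev] - np.log(s0))))
    grad = (we[:, None] * (X[ev] - xbar)).sum(axis=0)

    # Hessian: sum_e w_e (S2/S0 - xbar xbar^T); S2 accumulated per tie group
    hess = np.zeros((p, p))
    order = np.argsort(idx, kind="stable")
    uniq, ug_start = np.unique(idx[order], return_index=True)
    # accumulate S2 from the tail so each unique event time is O(group size)
    s2 = np.zeros((p, p))
    pos = n
    s2_at: dict[int, np.ndarray] = {}
    for u in uniq[::-1]:
        while pos > u:
            pos -= 1
            s2 += r[pos] * np.outer(X[pos], X[pos])
        s2_at[int(u)] = s2.copy()
    for j, u in enumerate(uniq):
        members = order[ug_start[j]: ug_start[j + 1]] if j + 1 < len(uniq) else order[ug_start[j]:]
        w_sum = float(we[members].sum())
        s0_u = s0_rev[u]
        xb = s1_rev[u] / s0_u
        hess += w_sum * (s2_at[int(u)] / s0_u - np.outer(xb, xb))
    return ll, grad, hess


def fit_weighted_cox(
    cohort_or_df,
    design: pd.DataFrame | np.ndarray,
    columns: tuple[str, ...] | None = None,
) -> CoxFit:
    """Fit a Cox proportional-hazards model with sampling weights.

    Maximises the weighted partial likelihood (Breslow ties) by damped
    Newton iterations; robust standard errors come from the sandwich of the
    inverse information with weighted score residuals (Lin-Wei / Barlow),
    appropriate for the case-cohort design.
    """
    df = cohort_or_df.data if isinstance(cohort_or_df, SurvivalCohort) else cohort_or_df
    if isinstance(design, pd.DataFrame):
        columns = tuple(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if columns is None:
            columns = tuple(f"x{i}" for i in range(X.shape[1]))
    time = df["time"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=int)
    w = df["weight"].to_numpy(dtype=float) if "weight" in df.columns else np.ones(len(df))

    if event.sum() < 1:
        raise CoxError("no events in the data")
    # rank check on centred design
    Xc = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if rank < X.shape[1]:
        sv = np.linalg.svd(Xc, compute_uv=False)
        bad = [columns[i] for i in range(X.shape[1]) if i >= rank]
        raise CoxError(f"design is rank deficient (rank {rank} < {X.shape[1]}); "
                       f"check columns {bad} (singular values {sv.round(6)})")

    order = np.argsort(time, kind="stable")
    time_s, event_s, X_s, w_s = time[order], event[order], X[order], w[order]

    p = X.shape[1]
    beta = np.zeros(p)
    ll_null, _, _ = _cox_loglik_grad_hess(beta, time_s, event_s, X_s, w_s)
    ll = ll_null
    converged = False
    for _ in range(50):
        ll, grad, hess = _cox_loglik_grad_hess(beta, time_s, event_s, X_s, w_s)
        if np.linalg.norm(grad) < 1e-9:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise CoxError(f"singular information matrix: {exc}") from exc
        # damped Newton: halve until the likelihood does not decrease
        factor = 1.0
        for _ in range(30):
            ll_new, _, _ = _cox_loglik_grad_hess(beta + factor * step, time_s, event_s, X_s, w_s)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta = beta + factor * step
    else:
        ll, grad, hess = _cox_loglik_grad_hess(beta, time_s, event_s, X_s, w_s)
        if np.linalg.norm(grad) < 1e-6:
            converged = True
    if not converged:
        _, grad, _ = _cox_loglik_grad_hess(beta, time_s, event_s, X_s, w_s)
        raise CoxError(
            f"no convergence after 50 iterations (|grad| = {np.linalg.norm(grad):.3g}); "
            "possible separation"
        )

    ll_full, _, hess = _cox_loglik_grad_hess(beta, time_s, event_s, X_s, w_s)
    info_inv = np.linalg.inv(hess)
    U = _score_residuals(beta, time_s, event_s, X_s, w_s)
    dfbeta = (w_s[:, None] * U) @ info_inv.T
    robust_cov = dfbeta.T @ dfbeta
    robust_se = np.sqrt(np.diag(robust_cov))
    return CoxFit(
        coef=beta, columns=columns, loglik_null=ll_null, loglik_full=ll_full,
        robust_se=robust_se, robust_cov=robust_cov, info_inv=info_inv,
        converged=converged, n_events=int(event.sum()), n=len(df),
    )


def _score_residuals(beta, time, event, X, w):
    """Per-subject score residuals U_i for the weighted Breslow model.

    U_i = delta_i (x_i - xbar(t_i))
          - sum_{event times t_e <= t_i} w_e dN(t_e)/S0(t_e) * r_i (x_i - xbar(t_e))
    evaluated so that sum_i w_i U_i equals the score vector.
    """
    n, p = X.shape
    eta = np.clip(X @ beta, -500, 500)
    r = w * np.exp(eta)
    s0_rev = np.cumsum(r[::-1])[::-1]
    s1_rev = np.cumsum((r[:, None] * X)[::-1], axis=0)[::-1]
    first_idx = np.zeros(n, dtype=int)
    start = 0
    for i in range(1, n + 1):
        if i == n or time[i] != time[start]:
            first_idx[start:i] = start
            start = i
    ev = event.astype(bool)
    e_idx = first_idx[ev]           # risk-set start index per event
    we = w[ev]
    s0_e = s0_rev[e_idx]
    xbar_e = s1_rev[e_idx] / s0_e[:, None]

    U = np.zeros((n, p))
    U[ev] += X[ev] - xbar_e

    # cumulative hazard-increment sums over event times with t_e <= t_i,
    # i.e. event risk-set index <= i's own position
    inc0 = we / s0_e                           # per event: w_e / S0
    inc1 = (we / s0_e)[:, None] * xbar_e       # per event: w_e xbar / S0
    # positions: events sorted by time already; map each subject i to the
    # number of event groups with start index <= i
    cum0 = np.concatenate([[0.0], np.cumsum(inc0)])
    cum1 = np.vstack([np.zeros(p), np.cumsum(inc1, axis=0)])
    counts = np.searchsorted(e_idx, np.arange(n), side="right")
    rr = np.exp(eta)  # subject's own risk factor; its sampling weight enters via dfbeta
    U -= rr[:, None] * (X * cum0[counts][:, None] - cum1[counts])
    return U


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------


def hr_q3_vs_q1(
    fit: CoxFit,
    basis_columns: np.ndarray,
    x,
    col_indices,
    z: float = 1.959963984540054,
) -> tuple[float, float, float]:
    """Hazard ratio for the 3rd vs 1st quartile of a covariate's distribution.

    ``basis_columns`` evaluates the covariate's design columns at arbitrary
    values (shape (2, k) for [q1, q3] when passed precomputed, or a callable
    applied to [q1, q3]); ``col_indices`` are those columns' positions in the
    fit.  The CI uses the delta method with the robust covariance.
    """
    x = np.asarray(x, dtype=float)
    q1, q3 = np.percentile(x, [25.0, 75.0])
    if callable(basis_columns):
        Z = np.asarray(basis_columns(np.array([q1, q3])), dtype=float)
    else:
        Z = np.asarray(basis_columns, dtype=float)
    g = Z[1] - Z[0]
    idx = np.asarray(col_indices, dtype=int)
    log_hr = float(g @ fit.coef[idx])
    var = float(g @ fit.robust_cov[np.ix_(idx, idx)] @ g)
    half = z * math.sqrt(max(var, 0.0))
    return math.exp(log_hr), math.exp(log_hr - half), math.exp(log_hr + half)


def harrells_c(time, event, risk_score, weight=None) -> float:
    """Weighted Harrell's concordance index.

    A pair (i, j) is comparable when i fails strictly before j's observed
    time, or when the times tie and i is an event while j is censored.  A
    comparable pair is concordant when the earlier failure has the higher
    risk score; score ties count 1/2.  Pairs are weighted by the product of
    the members' sampling weights.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    score = np.asarray(risk_score, dtype=float)
    w = np.ones_like(time) if weight is None else np.asarray(weight, dtype=float)
    n = time.size
    if n < 2:
        raise ValueError("need at least two subjects")
    ti = time[:, None]
    tj = time[None, :]
    ev_i = event[:, None].astype(bool)
    ev_j = event[None, :].astype(bool)
    comparable = (ev_i & (ti < tj)) | (ev_i & ~ev_j & (ti == tj))
    np.fill_diagonal(comparable, False)
    if not comparable.any():
        raise ValueError("no comparable pairs")
    si = score[:, None]
    sj = score[None, :]
    conc = np.where(si > sj, 1.0, np.where(si == sj, 0.5, 0.0))
    pw = w[:, None] * w[None, :]
    num = float(np.sum(pw * conc * comparable))
    den = float(np.sum(pw * comparable))
    return num / den


def fni(fit_without: CoxFit | None, fit_with: CoxFit) -> float:
    """Fraction of new information of the variables present only in the
    larger model: 1 - chi2(reduced) / chi2(full), clipped to [0, 1].
    ``fit_without=None`` denotes the null (empty) model, whose
    likelihood-ratio chi-square is 0, giving FNI = 1.
    """
    chi_b = fit_with.lr_chisq
    chi_a = 0.0 if fit_without is None else fit_without.lr_chisq
    if chi_b <= 0:
        raise ValueError("full-model likelihood-ratio chi-square is zero; FNI undefined")
    val = 1.0 - chi_a / chi_b
    if val < 0.0 or val > 1.0:
        log.info("FNI %.4f outside [0, 1] (sampling noise); clipping", val)
        val = min(max(val, 0.0), 1.0)
    return val


# ---------------------------------------------------------------------------
# Model specification and fitting harness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """A named covariate configuration.

    ``spline`` lists the continuous covariates modelled with a four-knot
    restricted cubic spline; the rest enter linearly.
    """

    name: str
    covariates: tuple[str, ...]
    spline: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        unknown = set(self.spline) - set(self.covariates)
        if unknown:
            raise ValueError(f"spline covariates not in model: {sorted(unknown)}")


@dataclass
class FittedModel:
    """A weighted Cox fit plus the design recipe needed to score new data."""

    spec: ModelSpec
    fit: CoxFit
    knots: dict[str, SplineBasis]
    columns: tuple[str, ...]
    groups: dict[str, list[int]] = field(default_factory=dict)

    def design(self, df: pd.DataFrame) -> np.ndarray:
        cols = []
        for cov in self.spec.covariates:
            x = df[cov].to_numpy(dtype=float)
            if cov in self.knots:
                cols.append(self.knots[cov].transform(x))
            else:
                cols.append(x[:, None])
        return np.hstack(cols)

    def score(self, df: pd.DataFrame) -> np.ndarray:
        """Linear predictor (risk score) for arbitrary data."""
        return self.design(df) @ self.fit.coef


def build_design(
    df: pd.DataFrame, spec: ModelSpec, knots: dict[str, SplineBasis] | None = None
) -> tuple[np.ndarray, tuple[str, ...], dict[str, SplineBasis], dict[str, list[int]]]:
    """Assemble the design matrix for a model spec.

    Returns (X, column names, spline bases by covariate, covariate -> column
    indices).  Existing ``knots`` are reused (needed when scoring new data
    with knots estimated on training data).
    """
    missing = [c for c in spec.covariates if c not in df.columns]
    if missing:
        raise ValueError(f"model {spec.name}: missing covariate columns {missing}")
    knots = dict(knots or {})
    cols: list[np.ndarray] = []
    names: list[str] = []
    groups: dict[str, list[int]] = {}
    for cov in spec.covariates:
        x = df[cov].to_numpy(dtype=float)
        start = len(names)
        if cov in spec.spline:
            if cov not in knots:
                basis, _ = rcs_basis(x, "auto")
                knots[cov] = basis
            Z = knots[cov].transform(x)
            cols.append(Z)
            names.extend([cov, f"{cov}'", f"{cov}''"])
        else:
            knots.pop(cov, None)
            cols.append(x[:, None])
            names.append(cov)
        groups[cov] = list(range(start, len(names)))
    X = np.hstack(cols)
    return X, tuple(names), {c: knots[c] for c in spec.spline if c in knots}, groups


def fit_model(cohort: SurvivalCohort, spec: ModelSpec) -> FittedModel:
    X, names, knots, groups = build_design(cohort.data, spec)
    fit = fit_weighted_cox(cohort, X, columns=names)
    return FittedModel(spec=spec, fit=fit, knots=knots, columns=names, groups=groups)


def select_spline_covariates(
    cohort: SurvivalCohort,
    covariates: tuple[str, ...],
    continuous: tuple[str, ...],
    top_k: int = 5,
) -> tuple[str, ...]:
    """Choose which continuous covariates keep their splines.

    Fits the all-spline model, ranks each continuous covariate by the
    likelihood-ratio chi-square of dropping it, and keeps splines for the
    top ``top_k``; the rest become linear.  This lowers the total degrees of
    freedom and with it the amount of overfitting.
    """
    full_spec = ModelSpec("all_spline", covariates, tuple(continuous))
    full = fit_model(cohort, full_spec)
    chis: list[tuple[float, str]] = []
    for cov in continuous:
        reduced_covs = tuple(c for c in covariates if c != cov)
        reduced = fit_model(
            cohort, ModelSpec("drop", reduced_covs, tuple(c for c in continuous if c != cov))
        )
        chis.append((full.fit.lr_chisq - reduced.fit.lr_chisq, cov))
    chis.sort(reverse=True)
    return tuple(cov for _, cov in chis[:top_k])


# ---------------------------------------------------------------------------
# Bootstrap internal validation and model comparison
# ---------------------------------------------------------------------------


def bootstrap_optimism(
    cohort: SurvivalCohort,
    spec: ModelSpec | None,
    B: int = 300,
    seed: int = 0,
    fixed_score=None,
) -> dict:
    """Harrell-Efron optimism-corrected C-index.

    For each bootstrap resample of subjects (weights carried along) the model
    is refit; the optimism is the mean of (C on the resample) minus (C of the
    resample's model on the original data), and the corrected C is the
    apparent C minus that mean.  A resample without events is redrawn
    (logged).  With ``fixed_score`` (a per-subject risk score not produced by
    fitting) nothing is estimated, so the optimism is exactly 0.
    """
    df = cohort.data
    t = df["time"].to_numpy(float)
    e = df["event"].to_numpy(int)
    w = df["weight"].to_numpy(float)
    if fixed_score is not None:
        apparent = harrells_c(t, e, np.asarray(fixed_score, float), w)
        return {"apparent_c": apparent, "optimism": 0.0, "corrected_c": apparent, "B": 0}
    if spec is None:
        raise ValueError("either spec or fixed_score is required")
    model = fit_model(cohort, spec)
    apparent = harrells_c(t, e, model.score(df), w)
    rng = np.random.default_rng(seed)
    n = len(df)
    opts = []
    b = 0
    while b < B:
        idx = rng.integers(0, n, size=n)
        boot = df.iloc[idx].reset_index(drop=True)
        if boot["event"].sum() == 0:
            log.info("bootstrap resample without events redrawn")
            continue
        try:
            m_b = fit_model(SurvivalCohort(boot), spec)
        except CoxError:
            log.info("bootstrap resample with failed fit redrawn")
            continue
        c_boot = harrells_c(boot["time"], boot["event"], m_b.score(boot), boot["weight"])
        c_orig = harrells_c(t, e, m_b.score(df), w)
        opts.append(c_boot - c_orig)
        b += 1
    optimism = float(np.mean(opts)) if opts else 0.0
    return {"apparent_c": apparent, "optimism": optimism,
            "corrected_c": apparent - optimism, "B": B}


def compare_models(
    cohort: SurvivalCohort,
    model_specs: list[ModelSpec],
    B_optimism: int = 300,
    B_pairwise: int = 2000,
    seed: int = 0,
    compute_fni: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit several model configurations and compare their C-indices.

    Returns (per-model table, pairwise table).  Per model: apparent C,
    optimism-corrected C, and the FNI of each covariate (likelihood-ratio
    chi-square of the model with and without it).  Pairwise C-index
    differences are assessed by a paired bootstrap over subjects using the
    fitted risk scores.
    """
    df = cohort.data
    t = df["time"].to_numpy(float)
    e = df["event"].to_numpy(int)
    w = df["weight"].to_numpy(float)
    fitted: dict[str, FittedModel] = {}
    scores: dict[str, np.ndarray] = {}
    rows = []
    for k, spec in enumerate(model_specs):
        m = fit_model(cohort, spec)
        fitted[spec.name] = m
        scores[spec.name] = m.score(df)
        val = bootstrap_optimism(cohort, spec, B=B_optimism, seed=seed + 1000 + k)
        row = {"model": spec.name, "n_covariates": len(spec.covariates),
               "c_index": val["apparent_c"],
               "c_index_optimism_corrected": val["corrected_c"],
               "lr_chisq": m.fit.lr_chisq}
        if compute_fni:
            for cov in spec.covariates:
                reduced = ModelSpec(
                    f"{spec.name}-{cov}",
                    tuple(c for c in spec.covariates if c != cov),
                    tuple(c for c in spec.spline if c != cov),
                )
                if not reduced.covariates:
                    row[f"fni_{cov}"] = 1.0
                    continue
                m_red = fit_model(cohort, reduced)
                row[f"fni_{cov}"] = fni(m_red.fit, m.fit)
        rows.append(row)
    per_model = pd.DataFrame(rows)

    rng = np.random.default_rng(seed)
    n = len(df)
    pair_rows = []
    names = [s.name for s in model_specs]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            si, sj = scores[names[i]], scores[names[j]]
            d_obs = harrells_c(t, e, si, w) - harrells_c(t, e, sj, w)
            diffs = np.empty(B_pairwise)
            for b in range(B_pairwise):
                idx = rng.integers(0, n, size=n)
                while e[idx].sum() == 0:
                    idx = rng.integers(0, n, size=n)
                diffs[b] = (harrells_c(t[idx], e[idx], si[idx], w[idx])
                            - harrells_c(t[idx], e[idx], sj[idx], w[idx]))
            lo, hi = np.percentile(diffs, [2.5, 97.5])
            pair_rows.append({"model_a": names[i], "model_b": names[j],
                              "c_diff": d_obs, "ci_lo": float(lo), "ci_hi": float(hi)})
    return per_model, pd.DataFrame(pair_rows)
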