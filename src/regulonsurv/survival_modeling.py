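"""Cox screening of regulator activities, risk scores and risk-group survival.

The prognostic model is built in two stages, both on z-standardized
activities (raw recovery-AUC scores live in [0, 1], so hazard ratios are only
interpretable per standard deviation of activity):

1. univariate Cox proportional-hazards screening keeps regulators whose
   activity associates with overall survival at Wald p < alpha;
2. one multivariate Cox fit weights the kept regulators, and the per-sample
   risk score is the linear predictor
   ``score(s) = sum_i coefficient_i * standardized_activity_i(s)``.

Cohorts are split into high/low risk at the cohort's own median risk score
(ties at the median go low) and compared by Kaplan-Meier curves and the
two-group log-rank test.  The training standardization is frozen inside the
risk model so validation cohorts are scored on the training scale.

``fit_cox`` is a Newton-Raphson maximizer of the Cox partial likelihood with
Efron (default) or Breslow handling of tied event times; lifelines provides
the Kaplan-Meier estimator and the log-rank test.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .activity_scoring import ActivityMatrix
from .io_formats import SurvivalTable

log = logging.getLogger("regulonsurv")

__all__ = [
    "CoxFit",
    "CoxConvergenceError",
    "CoxScreenResult",
    "RiskModel",
    "RiskAssignment",
    "KMCurve",
    "fit_cox",
    "wald_ci",
    "univariate_screen",
    "fit_risk_model",
    "compute_risk_scores",
    "assign_risk_groups",
    "logrank_test",
    "km_curve",
    "write_screen_results",
]


class CoxConvergenceError(RuntimeError):
    """Raised when the partial-likelihood Newton iteration fails; carries the
    iteration trace of (iteration, log partial likelihood, max step)."""

    def __init__(self, message: str, trace: list[tuple[int, float, float]]):
        super().__init__(message)
        self.trace = trace


@dataclass
class CoxFit:
    coefficients: np.ndarray
    standard_errors: np.ndarray
    log_partial_likelihood: float
    n_iterations: int


# ---------------------------------------------------------------------------
# partial likelihood machinery
# ---------------------------------------------------------------------------


def _partial_likelihood_parts(
    X: np.ndarray, time: np.ndarray, event: np.ndarray, beta: np.ndarray, ties: str
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log partial likelihood, gradient and information (negative Hessian)."""
    order = np.argsort(time, kind="stable")
    X, time, event = X[order], time[order], event[order]
    n, p = X.shape
    eta = X @ beta
    eta -= eta.max()  # guard exp overflow; cancels in every ratio
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]

    # suffix sums over the risk set {j : t_j >= t}
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    loglik = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        deaths = [k for k in range(i, j) if event[k]]
        d = len(deaths)
        if d:
            loglik += float(eta[deaths].sum())
            grad += X[deaths].sum(axis=0)
            s0, s1, s2 = S0[i], S1[i], S2[i]
            if ties == "breslow" or d == 1:
                loglik -= d * np.log(s0)
                mu = s1 / s0
                grad -= d * mu
                info += d * (s2 / s0 - np.outer(mu, mu))
            elif ties == "efron":
                t0 = w[deaths].sum()
                t1 = wx[deaths].sum(axis=0)
                t2 = wxx[deaths].sum(axis=0)
                for l in range(d):
                    f = l / d
                    s0l = s0 - f * t0
                    s1l = s1 - f * t1
                    s2l = s2 - f * t2
                    loglik -= np.log(s0l)
                    mu = s1l / s0l
                    grad -= mu
                    info += s2l / s0l - np.outer(mu, mu)
            else:
                raise ValueError(f"unknown ties method {ties!r}")
        i = j
    return loglik, grad, info


def fit_cox(
    covariates: np.ndarray | pd.DataFrame,
    survival: SurvivalTable,
    ties: str = "efron",
    tol: float = 1e-8,
    max_iterations: int = 100,
    ridge: float = 0.0,
) -> CoxFit:
    """Maximize the Cox partial likelihood by damped Newton-Raphson.

    Converges when the largest coefficient change drops below ``tol``
    (default 1e-8) or raises :class:`CoxConvergenceError` with the iteration
    trace after ``max_iterations``.  ``ridge`` adds an optional L2 penalty for
    collinear covariates (off by default).
    """
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n != survival.n_samples:
        raise ValueError("covariate rows do not match survival table")
    if survival.n_events < 2:
        raise ValueError(f"need at least 2 observed events, have {survival.n_events}")
    variances = X.var(axis=0)
    if np.any(variances == 0):
        dead = np.flatnonzero(variances == 0).tolist()
        raise ValueError(f"covariate columns with zero variance: {dead}")
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method {ties!r}")

    beta = np.zeros(p)
    loglik, grad, info = _regularized_parts(X, survival, beta, ties, ridge)
    trace: list[tuple[int, float, float]] = [(0, loglik, np.inf)]
    for iteration in range(1, max_iterations + 1):
        try:
            delta = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise CoxConvergenceError(
                f"singular information matrix at iteration {iteration}; "
                "covariates may be collinear (consider the ridge option)", trace
            ) from exc
        step = 1.0
        for _ in range(30):
            candidate = beta + step * delta
            new_loglik, new_grad, new_info = _regularized_parts(X, survival, candidate, ties, ridge)
            if np.isfinite(new_loglik) and new_loglik >= loglik - 1e-12:
                break
            step /= 2.0
        else:
            raise CoxConvergenceError(
                f"step halving failed at iteration {iteration} (possible complete separation)",
                trace,
            )
        max_change = float(np.abs(step * delta).max())
        beta, loglik, grad, info = candidate, new_loglik, new_grad, new_info
        trace.append((iteration, loglik, max_change))
        if max_change <= tol:
            covariance = np.linalg.inv(info)
            return CoxFit(beta, np.sqrt(np.diag(covariance)), loglik, iteration)
    raise CoxConvergenceError(
        f"no convergence in {max_iterations} iterations (last step {trace[-1][2]:.3g}); "
        "possible complete separation", trace
    )


def _regularized_parts(X, survival, beta, ties, ridge):
    loglik, grad, info = _partial_likelihood_parts(X, survival.time, survival.event, beta, ties)
    if ridge > 0:
        loglik -= 0.5 * ridge * float(beta @ beta)
        grad -= ridge * beta
        info += ridge * np.eye(len(beta))
    return loglik, grad, info


def wald_ci(
    beta: float, se: float, level: float = 0.95
) -> tuple[float, float, float, float]:
    """Hazard ratio, Wald confidence limits and two-sided p for one coefficient."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    z = norm.ppf(0.5 + level / 2)
    hr = float(np.exp(beta))
    ci_low = float(np.exp(beta - z * se))
    ci_high = float(np.exp(beta + z * se))
    p = float(2 * norm.sf(abs(beta / se)))
    return hr, ci_low, ci_high, p


# ---------------------------------------------------------------------------
# screening and risk model
# ---------------------------------------------------------------------------


@dataclass
class CoxScreenResult:
    regulator: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    wald_p: float
    logrank_p: float
    coefficient: float = 0.0
    standard_error: float = 0.0


def _common_samples(act: ActivityMatrix, survival: SurvivalTable) -> list[str]:
    surv = set(survival.sample_ids)
    common = [s for s in act.sample_ids if s in surv]
    if not common:
        raise ValueError("no samples shared between activity matrix and survival table")
    return common


def univariate_screen(
    act: ActivityMatrix,
    survival: SurvivalTable,
    alpha: float = 0.05,
    ties: str = "efron",
    level: float = 0.95,
    standardize: bool = True,
) -> list[CoxScreenResult]:
    """Single-covariate Cox fit per regulator on its z-scored activity.

    Also reports the log-rank p for a median split of the activity, mirroring
    the two association statistics usually tabulated for screened markers.
    Regulators whose fit fails are excluded with a logged reason.  Returns
    regulators with Wald p < ``alpha`` sorted by Wald p ascending.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    common = _common_samples(act, survival)
    surv = survival.align(common)
    frame = act.to_frame()[common]
    results: list[CoxScreenResult] = []
    for regulator, row in frame.iterrows():
        a = row.to_numpy(float)
        mask = np.isfinite(a)
        if mask.sum() < len(a):
            log.info("regulator %s: %d unscored samples excluded", regulator, (~mask).sum())
        used = a[mask]
        surv_used = surv.align([s for s, ok in zip(common, mask) if ok])
        try:
            sd = used.std()
            if sd == 0:
                raise ValueError("zero activity variance")
            z = (used - used.mean()) / sd if standardize else used
            fit = fit_cox(z[:, None], surv_used, ties=ties)
            hr, lo, hi, wp = wald_ci(float(fit.coefficients[0]), float(fit.standard_errors[0]), level)
            groups = np.where(used > np.median(used), "high", "low")
            _, lp = logrank_test(groups, surv_used)
        except (ValueError, CoxConvergenceError) as exc:
            log.warning("regulator %s excluded from screen: %s", regulator, exc)
            continue
        results.append(
            CoxScreenResult(
                regulator=str(regulator), hazard_ratio=hr, ci_low=lo, ci_high=hi,
                wald_p=wp, logrank_p=lp,
                coefficient=float(fit.coefficients[0]),
                standard_error=float(fit.standard_errors[0]),
            )
        )
    results = [r for r in results if r.wald_p < alpha]
    results.sort(key=lambda r: r.wald_p)
    return results


@dataclass
class RiskModel:
    """Selected regulators with multivariate Cox weights and the frozen
    training standardization (so validation cohorts score on the same scale)."""

    regulators: list[str]
    coefficients: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    ties: str = "efron"
    cutoff_policy: str = "median"
    n_training_samples: int = 0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        k = len(self.regulators)
        if not (len(self.coefficients) == len(self.means) == len(self.sds) == k):
            raise ValueError("model arrays must have one entry per regulator")

    def to_json(self, path: str | Path) -> None:
        doc = {
            "regulators": self.regulators,
            "coefficients": self.coefficients.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "ties": self.ties,
            "cutoff_policy": self.cutoff_policy,
            "n_training_samples": self.n_training_samples,
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RiskModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            regulators=doc["regulators"],
            coefficients=np.array(doc["coefficients"]),
            means=np.array(doc["means"]),
            sds=np.array(doc["sds"]),
            ties=doc.get("ties", "efron"),
            cutoff_policy=doc.get("cutoff_policy", "median"),
            n_training_samples=doc.get("n_training_samples", 0),
        )


def fit_risk_model(
    act: ActivityMatrix,
    survival: SurvivalTable,
    selected: Sequence[str],
    ties: str = "efron",
    ridge: float = 0.0,
    standardize: bool = True,
) -> RiskModel:
    """One multivariate Cox fit over the selected regulators' activities.

    With ``standardize=False`` activities enter on their raw [0, 1] scale and
    the stored standardization is the identity.
    """
    selected = list(selected)
    if not selected:
        raise ValueError("no regulators selected for the risk model")
    missing = [r for r in selected if r not in act.regulators]
    if missing:
        raise KeyError(f"selected regulators absent from activity matrix: {missing}")
    common = _common_samples(act, survival)
    frame = act.to_frame().loc[selected, common]
    complete = frame.notna().all(axis=0)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info("risk model: %d samples with unscored activities excluded", n_dropped)
    frame = frame.loc[:, complete]
    surv = survival.align(list(frame.columns))
    values = frame.to_numpy(float)
    if np.any(values.std(axis=1, ddof=0) == 0):
        flat = [selected[i] for i in np.flatnonzero(values.std(axis=1, ddof=0) == 0)]
        raise ValueError(f"zero activity variance for regulators: {flat}")
    if standardize:
        means = values.mean(axis=1)
        sds = values.std(axis=1, ddof=0)
    else:
        means = np.zeros(len(selected))
        sds = np.ones(len(selected))
    Z = ((values - means[:, None]) / sds[:, None]).T  # samples x regulators
    try:
        fit = fit_cox(Z, surv, ties=ties, ridge=ridge)
    except CoxConvergenceError as exc:
        raise CoxConvergenceError(
            f"{exc}; activities may be collinear — retry with ridge > 0", exc.trace
        ) from exc
    return RiskModel(
        regulators=selected,
        coefficients=fit.coefficients,
        means=means,
        sds=sds,
        ties=ties,
        n_training_samples=surv.n_samples,
    )


def compute_risk_scores(model: RiskModel, act: ActivityMatrix) -> pd.Series:
    """Risk score per sample: coefficient-weighted sum of standardized activities.

    Standardization uses the frozen training means/SDs.  Samples missing any
    required activity are excluded with a logged count.
    """
    missing = [r for r in model.regulators if r not in act.regulators]
    if missing:
        raise KeyError(f"model regulators absent from activity matrix: {missing}")
    frame = act.to_frame().loc[model.regulators]
    complete = frame.notna().all(axis=0)
    if (~complete).any():
        log.info("risk scoring: %d samples with unscored activities excluded", (~complete).sum())
    frame = frame.loc[:, complete]
    Z = (frame.to_numpy(float) - model.means[:, None]) / model.sds[:, None]
    return pd.Series(model.coefficients @ Z, index=frame.columns, name="risk_score")


@dataclass
class RiskAssignment:
    sample_ids: list[str]
    scores: np.ndarray
    group: list[str]
    cutoff: float

    def groups_series(self) -> pd.Series:
        return pd.Series(self.group, index=self.sample_ids, name="risk_group")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample": self.sample_ids, "risk_score": self.scores, "risk_group": self.group}
        )


def assign_risk_groups(
    scores: pd.Series | np.ndarray,
    cutoff: str | float = "median",
    sample_ids: Sequence[str] | None = None,
) -> RiskAssignment:
    """Split a cohort at its (or an explicit) risk-score cutoff.

    High risk means score strictly above the cutoff; ties at the cutoff go to
    the low-risk group, so the split is deterministic.
    """
    if isinstance(scores, pd.Series):
        sample_ids = list(scores.index)
        values = scores.to_numpy(float)
    else:
        values = np.asarray(scores, dtype=float)
        sample_ids = list(sample_ids) if sample_ids is not None else [str(i) for i in range(len(values))]
    if len(values) < 2:
        raise ValueError("need at least 2 samples to stratify")
    if np.all(values == values[0]):
        raise ValueError("all risk scores identical; no stratification possible")
    cut = float(np.median(values)) if cutoff == "median" else float(cutoff)
    group = ["high" if v > cut else "low" for v in values]
    return RiskAssignment(sample_ids, values, group, cut)


# ---------------------------------------------------------------------------
# survival comparison
# ---------------------------------------------------------------------------


def logrank_test(
    groups: Sequence[str] | np.ndarray, survival: SurvivalTable
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square on 1 df, p)."""
    from lifelines.statistics import logrank_test as _ll_logrank

    groups = np.asarray(groups)
    if len(groups) != survival.n_samples:
        raise ValueError("group labels do not match survival table")
    labels = sorted(set(groups.tolist()))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    a = groups == labels[0]
    res = _ll_logrank(
        survival.time[a], survival.time[~a],
        event_observed_A=survival.event[a], event_observed_B=survival.event[~a],
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass
class KMCurve:
    """Product-limit survival estimate for one group, with censoring marks."""

    times: np.ndarray
    survival_prob: np.ndarray
    censor_times: np.ndarray
    label: str = ""

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival_prob[idx]) if idx >= 0 else 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival_prob})


def km_curve(survival: SurvivalTable, label: str = "") -> KMCurve:
    """Kaplan-Meier estimate for one group of records."""
    if survival.n_samples == 0:
        raise ValueError("no records")
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(survival.time, survival.event, label=label or "KM")
    sf = kmf.survival_function_
    return KMCurve(
        times=sf.index.to_numpy(float),
        survival_prob=sf.iloc[:, 0].to_numpy(float),
        censor_times=np.sort(survival.time[survival.event == 0]),
        label=label,
    )


def write_screen_results(results: list[CoxScreenResult], path: str | Path) -> None:
    """Screening TSV with the usual marker-table columns."""
    frame = pd.DataFrame(
        [
            {
                "regulator": r.regulator,
                "logrank_p": r.logrank_p,
                "HR": r.hazard_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "wald_p": r.wald_p,
                "coefficient": r.coefficient,
                "standard_error": r.standard_error,
            }
            for r in results
        ]
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def chi2_p(chi_square: float, df: int = 1) -> float:
    return float(chi2.sf(chi_square, df))
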