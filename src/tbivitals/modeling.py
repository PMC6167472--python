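"""Stepwise logistic modeling, repeated stratified CV, AUROC, and Youden
operating points.

Model building mirrors the study protocol: multivariable logistic
regression with forward/backward stepwise selection driven by the Wald
chi-square statistic, generalization assessed by 10-fold cross-validation
repeated 10 times with stratified sampling, AUROC as the overall metric,
and sensitivity/specificity/PPV/NPV reported at the Youden-index optimal
threshold. The whole fitting procedure — standardization and stepwise
selection included — is re-run inside every training fold by default, so
out-of-fold predictions never touch held-out rows ("leak-free"); a
fidelity mode selecting once on all data is available and is optimistic.

The AUROC is the tie-aware Mann-Whitney statistic: ties between a case and
a control count one half.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import chi2, rankdata
from sklearn.model_selection import StratifiedKFold

from tbivitals.types import InputError, ParameterError

__all__ = [
    "FitResult",
    "CVResult",
    "ModelSpec",
    "MODEL_SPECS",
    "fit_logistic",
    "stepwise_select",
    "auroc",
    "youden_operating_point",
    "stratified_fold_indices",
    "repeated_cv",
    "ppg15_probability",
    "mortality_model",
]

P_ENTER_DEFAULT = 0.05
P_REMOVE_DEFAULT = 0.10
_MAX_STEPWISE_ITER = 50
_SEPARATION_COEF = 15.0  # |log-odds| beyond which we flag quasi-separation


@dataclass
class FitResult:
    """A fitted logistic model with per-variable Wald statistics."""

    variables: list[str]
    coefficients: dict[str, float]  # includes 'intercept'
    standard_errors: dict[str, float]
    wald_chi2: dict[str, float]
    wald_p: dict[str, float]
    intercept: float
    converged: bool
    separation: bool
    log_likelihood: float
    # standardization learned at fit time, applied at prediction time
    scaler: dict[str, tuple[float, float]] = field(default_factory=dict)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predicted probabilities for new rows (applies the stored scaler)."""
        lp = np.full(len(X), self.intercept)
        for var in self.variables:
            v = X[var].to_numpy(dtype=float)
            if var in self.scaler:
                mu, sd = self.scaler[var]
                v = (v - mu) / sd
            lp = lp + self.coefficients[var] * v
        return 1.0 / (1.0 + np.exp(-lp))


@dataclass
class CVResult:
    """Repeated stratified cross-validation performance."""

    auroc_point: float
    auroc_ci_low: float
    auroc_ci_high: float
    youden_threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    fold_aurocs: np.ndarray  # k * repeats fold-level AUROCs
    repeat_aurocs: np.ndarray  # pooled out-of-fold AUROC per repeat
    oof_probabilities: np.ndarray  # per subject, mean across repeats
    oof_matrix: np.ndarray  # (n, repeats)


def _standardize(X: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    scaler = {}
    out = X.copy()
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        mu, sd = float(v.mean()), float(v.std(ddof=0))
        if sd > 0:
            out[col] = (v - mu) / sd
            scaler[col] = (mu, sd)
    return out, scaler


def fit_logistic(
    X: pd.DataFrame,
    y: np.ndarray,
    standardize: bool = False,
) -> FitResult:
    """Maximum-likelihood logistic fit with Wald chi-square per variable.

    ``X`` holds the design columns (no constant; one is added). Requires
    complete data and both outcome classes. Perfect or quasi-complete
    separation is detected and flagged on the result rather than raised.
    """
    y = np.asarray(y, dtype=float)
    if X.isna().any().any() or np.isnan(y).any():
        raise InputError("design matrix and outcome must have no missing cells")
    if len(np.unique(y)) < 2:
        raise InputError("outcome must contain both classes")
    scaler: dict[str, tuple[float, float]] = {}
    if standardize and len(X.columns):
        X, scaler = _standardize(X)
    design = sm.add_constant(X.astype(float), has_constant="add")
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=100, tol=1e-8)
        except Exception:  # PerfectSeparationError and numerical failures
            # ridge-stabilized refit so a flagged result is still returned
            res = sm.Logit(y, design).fit_regularized(disp=0, alpha=1e-4, maxiter=200)
            separation = True
    params = np.asarray(res.params, dtype=float)
    try:
        bse = np.asarray(res.bse, dtype=float)
    except Exception:
        bse = np.full_like(params, np.nan)
    if np.any(np.abs(params) > _SEPARATION_COEF) or np.any(~np.isfinite(bse)):
        separation = True
    names = list(design.columns)
    coef = dict(zip(names, params))
    se = dict(zip(names, bse))
    wald = {k: (coef[k] / se[k]) ** 2 if se[k] and np.isfinite(se[k]) and se[k] > 0 else np.inf for k in names}
    pvals = {k: float(chi2.sf(w, 1)) if np.isfinite(w) else 0.0 for k, w in wald.items()}
    converged = bool(getattr(res, "mle_retvals", {}).get("converged", True)) and not separation
    variables = [c for c in X.columns]
    return FitResult(
        variables=variables,
        coefficients={("intercept" if k == "const" else k): v for k, v in coef.items()},
        standard_errors={("intercept" if k == "const" else k): v for k, v in se.items()},
        wald_chi2={("intercept" if k == "const" else k): float(w) for k, w in wald.items()},
        wald_p={("intercept" if k == "const" else k): v for k, v in pvals.items()},
        intercept=float(coef["const"]),
        converged=converged,
        separation=separation,
        log_likelihood=float(res.llf) if hasattr(res, "llf") else np.nan,
        scaler=scaler,
    )


def _irls_wald_p(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Wald p-values from a Newton/IRLS logistic fit (intercept prepended).

    Fast path for the stepwise forward scan, which needs only the Wald
    statistic of each trial fit; matches the maximum-likelihood fit of
    :func:`fit_logistic` (same model, same convergence criterion). Returns
    p-values for the non-intercept columns; quasi-separated fits get p=0 so
    they still enter and are flagged by the final full fit.
    """
    n = y.size
    D = np.column_stack([np.ones(n), X])
    beta = np.zeros(D.shape[1])
    ll_old = -np.inf
    for _ in range(100):
        eta = D @ beta
        p = expit(eta)
        w = p * (1 - p)
        ll = float(np.sum(y * np.log(p + 1e-300) + (1 - y) * np.log(1 - p + 1e-300)))
        if abs(ll - ll_old) < 1e-8:
            break
        ll_old = ll
        grad = D.T @ (y - p)
        hess = (D * w[:, None]).T @ D
        try:
            step = np.linalg.solve(hess + 1e-10 * np.eye(D.shape[1]), grad)
        except np.linalg.LinAlgError:
            break
        # step-halving for stability
        for _ in range(20):
            cand = beta + step
            if np.all(np.abs(cand) < 200):
                eta_c = D @ cand
                ll_c = float(np.sum(y * eta_c - np.logaddexp(0.0, eta_c)))
                if ll_c >= ll - 1e-12:
                    break
            step *= 0.5
        beta = beta + step
    eta = D @ beta
    p = expit(eta)
    w = p * (1 - p)
    hess = (D * w[:, None]).T @ D
    try:
        cov = np.linalg.inv(hess + 1e-10 * np.eye(D.shape[1]))
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(D.shape[1], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = (beta / se) ** 2
    out = chi2.sf(wald[1:], 1)
    out[~np.isfinite(wald[1:]) | (np.abs(beta[1:]) > _SEPARATION_COEF)] = 0.0
    return out


def _intercept_only(y: np.ndarray) -> FitResult:
    p = float(np.mean(y))
    eps = 1e-12
    b0 = float(np.log((p + eps) / (1 - p + eps)))
    n = y.size
    se = float(np.sqrt(1.0 / max(n * p * (1 - p), eps)))
    ll = float(n * (p * np.log(p + eps) + (1 - p) * np.log(1 - p + eps)))
    return FitResult(
        variables=[],
        coefficients={"intercept": b0},
        standard_errors={"intercept": se},
        wald_chi2={"intercept": (b0 / se) ** 2 if se > 0 else np.inf},
        wald_p={"intercept": float(chi2.sf((b0 / se) ** 2, 1)) if se > 0 else 0.0},
        intercept=b0,
        converged=True,
        separation=False,
        log_likelihood=ll,
    )


def stepwise_select(
    X: pd.DataFrame,
    y: np.ndarray,
    p_enter: float = P_ENTER_DEFAULT,
    p_remove: float = P_REMOVE_DEFAULT,
    standardize: bool = True,
) -> FitResult:
    """Forward/backward stepwise logistic selection by Wald chi-square.

    Each iteration forward-adds the candidate with the smallest Wald p-value
    below ``p_enter`` (ties broken by smaller p then column order), then
    backward-drops any included variable whose Wald p exceeds ``p_remove``,
    until neither move applies. Deterministic given the column order. An
    empty candidate list yields the intercept-only model. More than 50
    iterations (cycling) aborts with a diagnostic.
    """
    if p_enter > p_remove:
        raise ParameterError("p_enter must be <= p_remove")
    y = np.asarray(y, dtype=float)
    if len(X.columns) == 0:
        return _intercept_only(y)
    if standardize:
        X, scaler = _standardize(X)
    else:
        scaler = {}
    selected: list[str] = []
    candidates = list(X.columns)
    for _ in range(_MAX_STEPWISE_ITER):
        changed = False
        # forward step: fast IRLS trial fits, Wald p of the new variable
        base = X[selected].to_numpy(dtype=float) if selected else np.empty((len(X), 0))
        best_p, best_var = None, None
        for var in candidates:
            if var in selected:
                continue
            trial = np.column_stack([base, X[var].to_numpy(dtype=float)])
            p = float(_irls_wald_p(trial, y)[-1])
            if p < p_enter and (best_p is None or p < best_p):
                best_p, best_var = p, var
        if best_var is not None:
            selected.append(best_var)
            changed = True
        # backward step(s)
        while selected:
            pvals = _irls_wald_p(X[selected].to_numpy(dtype=float), y)
            worst = int(np.argmax(pvals))
            if pvals[worst] > p_remove:
                selected.pop(worst)
                changed = True
            else:
                break
        if not changed:
            break
    else:
        raise RuntimeError(
            f"stepwise selection did not stabilize in {_MAX_STEPWISE_ITER} iterations "
            f"(p_enter={p_enter}, p_remove={p_remove}); likely cycling"
        )
    result = fit_logistic(X[selected], y) if selected else _intercept_only(y)
    result.scaler = {k: v for k, v in scaler.items() if k in selected}
    return result


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-aware AUROC: the Mann-Whitney U statistic over n1*n0.

    Each (case, control) pair contributes 1 if the case scores higher, 0.5
    on a tie. Raises :class:`InputError` if only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise InputError("AUROC requires both classes")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def youden_operating_point(scores: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """Operating point maximizing the Youden index J = sens + spec - 1.

    A subject is called positive when its score is >= the threshold; J is
    maximized over the observed scores (ties resolved to the lowest
    threshold). PPV and NPV use the sample prevalence; an empty predicted
    class yields NaN for the corresponding predictive value.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise InputError("operating point requires both classes")
    best = None
    for thr in np.unique(scores):
        pred = scores >= thr
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        sens = tp / n1
        spec = (n0 - fp) / n0
        j = sens + spec - 1.0
        if best is None or j > best["j"] + 1e-12:
            tn, fn = n0 - fp, n1 - tp
            best = {
                "threshold": float(thr),
                "j": j,
                "sensitivity": sens,
                "specificity": spec,
                "ppv": tp / (tp + fp) if tp + fp else float("nan"),
                "npv": tn / (tn + fn) if tn + fn else float("nan"),
            }
    return best


def stratified_fold_indices(
    labels: np.ndarray,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> list[list[np.ndarray]]:
    """Deterministic stratified fold test-index sets, one list per repeat.

    Folds are stratified on the outcome. If a fold ends up single-class in
    either its training or test part (possible when the minority class is
    small), the repeat is re-drawn with a perturbed seed, with a warning.
    """
    labels = np.asarray(labels).astype(int)
    out = []
    for rep in range(repeats):
        for attempt in range(10):
            skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=(seed * 1009 + rep * 131 + attempt * 7919) % (2**31))
            folds = [test for _, test in skf.split(np.zeros(labels.size), labels)]
            ok = all(len(np.unique(labels[f])) == 2 and len(np.unique(np.delete(labels, f))) == 2 for f in folds)
            if ok:
                break
            warnings.warn(f"repeat {rep}: single-class fold, re-drawing")
        out.append(folds)
    return out


def repeated_cv(
    data: pd.DataFrame,
    outcome: str,
    candidates: list[str],
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    selection: str = "stepwise",
    p_enter: float = P_ENTER_DEFAULT,
    p_remove: float = P_REMOVE_DEFAULT,
    leak_free: bool = True,
) -> CVResult:
    """Repeated stratified k-fold cross-validation of the model pipeline.

    Inside every training fold the features are standardized and — with
    ``selection="stepwise"`` and ``leak_free=True`` (default) — the stepwise
    selection is re-run from scratch, so held-out rows never influence any
    part of the fit. ``leak_free=False`` selects once on all rows first (the
    optimistic fidelity mode); ``selection="fixed"`` skips selection and
    fits all candidates.

    The AUROC point estimate is the mean over repeats of the pooled
    out-of-fold AUROC; the 95% CI is the 2.5/97.5 percentile of the
    ``k * repeats`` fold-level AUROCs. The operating point is the Youden
    optimum of the across-repeat mean out-of-fold probabilities.
    """
    y = data[outcome].to_numpy(dtype=int)
    n1, n0 = int(y.sum()), int((y == 0).sum())
    if n1 < k or n0 < k:
        raise InputError(f"need at least k={k} events and non-events (have {n1}/{n0})")
    X = data[candidates]

    fixed_vars: list[str] | None = None
    if selection == "fixed":
        fixed_vars = list(candidates)
    elif selection == "stepwise" and not leak_free:
        fixed_vars = stepwise_select(X, y, p_enter, p_remove).variables
    elif selection != "stepwise":
        raise ParameterError(f"unknown selection mode {selection!r}")

    all_folds = stratified_fold_indices(y, k=k, repeats=repeats, seed=seed)
    n = len(data)
    oof = np.full((n, repeats), np.nan)
    fold_aurocs = []
    repeat_aurocs = []
    for rep, folds in enumerate(all_folds):
        for test_idx in folds:
            train_mask = np.ones(n, dtype=bool)
            train_mask[test_idx] = False
            X_tr, y_tr = X.iloc[train_mask.nonzero()[0]], y[train_mask]
            X_te = X.iloc[test_idx]
            if fixed_vars is not None:
                fit = fit_logistic(X_tr[fixed_vars], y_tr, standardize=True) if fixed_vars else _intercept_only(y_tr)
            else:
                fit = stepwise_select(X_tr, y_tr, p_enter, p_remove)
            probs = fit.predict(X_te) if fit.variables else np.full(len(X_te), 1 / (1 + np.exp(-fit.intercept)))
            oof[test_idx, rep] = probs
            fold_aurocs.append(auroc(probs, y[test_idx]))
        repeat_aurocs.append(auroc(oof[:, rep], y))
    fold_aurocs = np.array(fold_aurocs)
    repeat_aurocs = np.array(repeat_aurocs)
    mean_oof = oof.mean(axis=1)
    op = youden_operating_point(mean_oof, y)
    ci_low, ci_high = np.percentile(fold_aurocs, [2.5, 97.5])
    return CVResult(
        auroc_point=float(repeat_aurocs.mean()),
        auroc_ci_low=float(ci_low),
        auroc_ci_high=float(ci_high),
        youden_threshold=op["threshold"],
        sensitivity=op["sensitivity"],
        specificity=op["specificity"],
        ppv=op["ppv"],
        npv=op["npv"],
        fold_aurocs=fold_aurocs,
        repeat_aurocs=repeat_aurocs,
        oof_probabilities=mean_oof,
        oof_matrix=oof,
    )


_CLINICAL_BASE = ("age", "sex_male", "hr", "rr", "sbp", "dbp")


@dataclass(frozen=True)
class ModelSpec:
    """One of the nine candidate-variable sets for ND prediction.

    Models 1-3 are clinical (admission vitals, +GCS, +Marshall); models 4-7
    are pure physiologic feature sets (ECG/PPG at the 15- or 60-minute
    window); models 8 and 9 union model 2 with models 4 and 5 respectively.
    """

    id: int
    description: str
    clinical: tuple[str, ...] = ()
    signal: str | None = None  # "ecg" | "ppg"
    window_tag: str | None = None  # "w15" | "w60"
    selection: str = "stepwise"

    def resolve(self, columns: list[str]) -> list[str]:
        """Candidate columns available in ``columns``, in stable order."""
        cand = [c for c in self.clinical if c in columns]
        if self.signal is not None:
            suffix = f"_{self.window_tag}"
            cand += [c for c in columns if c.startswith(f"{self.signal}_") and c.endswith(suffix)]
        return cand


MODEL_SPECS: dict[int, ModelSpec] = {
    1: ModelSpec(1, "age, sex, first recorded vitals (HR, RR, SBP, DBP)", _CLINICAL_BASE),
    2: ModelSpec(2, "model 1 + initial GCS", _CLINICAL_BASE + ("gcs",)),
    3: ModelSpec(3, "model 2 + Marshall score", _CLINICAL_BASE + ("gcs", "marshall")),
    4: ModelSpec(4, "ECG HRV + waveform features, first 15 min", signal="ecg", window_tag="w15"),
    5: ModelSpec(5, "PPG variability + waveform features, first 15 min", signal="ppg", window_tag="w15"),
    6: ModelSpec(6, "ECG HRV + waveform features, first 60 min", signal="ecg", window_tag="w60"),
    7: ModelSpec(7, "PPG variability + waveform features, first 60 min", signal="ppg", window_tag="w60"),
    8: ModelSpec(8, "model 2 + model 4", _CLINICAL_BASE + ("gcs",), signal="ecg", window_tag="w15"),
    9: ModelSpec(9, "model 2 + model 5", _CLINICAL_BASE + ("gcs",), signal="ppg", window_tag="w15"),
}


def ppg15_probability(
    data: pd.DataFrame,
    outcome: str = "nd",
    seed: int = 0,
    k: int = 10,
    repeats: int = 10,
) -> pd.Series:
    """Per-subject ND probability from the PPG 15-minute model (PPG15).

    Out-of-fold probabilities from the repeated-CV pipeline of model 5
    (leak-free by construction), averaged across repeats and clipped to
    (0, 1). Subjects with missing PPG features are excluded and listed in
    ``series.attrs['excluded']``.
    """
    cols = MODEL_SPECS[5].resolve(list(data.columns))
    if not cols:
        raise InputError("no PPG 15-minute feature columns present")
    complete = data[cols].notna().all(axis=1)
    excluded = data.loc[~complete, data.columns[0]].tolist()
    sub = data.loc[complete].reset_index(drop=True)
    cv = repeated_cv(sub, outcome, cols, k=k, repeats=repeats, seed=seed)
    probs = np.clip(cv.oof_probabilities, 1e-6, 1 - 1e-6)
    out = pd.Series(probs, index=data.index[complete], name="ppg15")
    out.attrs["excluded"] = excluded
    out.attrs["cv_result"] = cv
    return out


MORTALITY_COVARIATES = ("age", "marshall", "mechanism_penetrating", "ppg15")
MORTALITY_ADJUSTERS = ("sex_male", "map", "hr", "rr", "gcs")


def mortality_model(
    data: pd.DataFrame,
    outcome: str = "mortality",
) -> pd.DataFrame:
    """In-hospital mortality model with the PPG15 probability covariate.

    Logistic regression of mortality on age, Marshall score, penetrating
    mechanism, and PPG15, adjusted for sex, admission MAP, heart rate,
    respiratory rate, and GCS. Returns one row per covariate with the odds
    ratio ``exp(coef)`` and its 95% CI ``exp(coef +/- 1.96*se)``.
    """
    covs = [c for c in MORTALITY_COVARIATES + MORTALITY_ADJUSTERS if c in data.columns]
    missing = set(MORTALITY_COVARIATES) - set(covs)
    if missing:
        raise InputError(f"mortality model requires covariates {sorted(missing)}")
    fit = fit_logistic(data[covs], data[outcome].to_numpy())
    rows = []
    for var in covs:
        coef, se = fit.coefficients[var], fit.standard_errors[var]
        with np.errstate(over="ignore"):
            rows.append(
            {
                "covariate": var,
                "odds_ratio": float(np.exp(coef)),
                "ci_low": float(np.exp(coef - 1.96 * se)),
                "ci_high": float(np.exp(coef + 1.96 * se)),
                "p_value": fit.wald_p[var],
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["separation"] = fit.separation
    return out
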