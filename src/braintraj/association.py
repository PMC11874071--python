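"""Association of regional complexity with behavioral scores.

Candidate regional entropy predictors are first screened for collinearity
with the variance inflation factor (VIF = 1/(1-R^2) of each predictor
regressed on the others), iteratively dropping the worst predictor while it
exceeds the threshold. The surviving regions, together with age and sex
(coded 0 = male, 1 = female), enter a multiple linear regression of each
behavioral scale:

    score = b0 + sum_r b_r * entropy_r + b_age * age + b_sex * sex + eps

fitted by OLS on the full complete-case sample (point estimates, R^2, F,
model p), with uncertainty from 1000 bootstrap refits each drawing
floor(0.85 * n) subjects. The per-predictor significance level is
Bonferroni-corrected by the number of predictors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ParameterError
from .io import SubjectRecord

logger = logging.getLogger(__name__)

SEX_CODE = {"male": 0.0, "female": 1.0}


def corrected_alpha_for_model(n_predictors: int) -> float:
    """Per-predictor Bonferroni level 0.05 / n_predictors."""
    if not (isinstance(n_predictors, (int, np.integer)) and n_predictors >= 1):
        raise ParameterError(f"n_predictors must be a positive integer, got {n_predictors}")
    return 0.05 / n_predictors


@dataclass
class RegressionSpec:
    """One response model: predictors, bootstrap settings, corrected level."""

    response: str
    predictors: list[str]
    n_boot: int = 1000
    subsample_frac: float = 0.85
    replace: bool = True      # draw bootstrap subjects with replacement (see docs/methods.md)
    resample: bool = True     # False + subsample_frac=1 reproduces the full-sample fit
    alpha: float | None = None

    def __post_init__(self) -> None:
        if not self.predictors:
            raise ParameterError("predictors must be nonempty")
        if not (0 < self.subsample_frac <= 1):
            raise ParameterError(f"subsample_frac must be in (0, 1], got {self.subsample_frac}")
        if self.n_boot < 1:
            raise ParameterError(f"n_boot must be >= 1, got {self.n_boot}")
        if self.alpha is None:
            self.alpha = corrected_alpha_for_model(len(self.predictors))


@dataclass
class RegressionResult:
    """Full-sample OLS fit plus bootstrap distributions per predictor."""

    spec: RegressionSpec
    terms: pd.DataFrame        # term, beta, boot_mean, boot_se, ci_low, ci_high, p_boot, p_ols, significant
    r2: float
    fstat: float
    model_p: float
    n_used: int
    n_boot_ok: int
    n_boot_skipped: int
    boot_betas: np.ndarray = field(repr=False, default=None)  # (n_boot_ok, n_terms)


def vif_values(X: np.ndarray) -> np.ndarray:
    """VIF_j = 1/(1 - R^2_j) from regressing column j on the others (+intercept)."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    out = np.empty(p)
    for j in range(p):
        y = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, res, rank, _ = np.linalg.lstsq(others, y, rcond=None)
        fitted = others @ beta
        ss_tot = float(((y - y.mean()) ** 2).sum())
        ss_res = float(((y - fitted) ** 2).sum())
        if ss_tot == 0:
            out[j] = float("inf")  # constant predictor: degenerate, drop first
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[j] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_screen(design: pd.DataFrame, threshold: float = 10.0
               ) -> tuple[list[str], pd.DataFrame]:
    """Iteratively drop the max-VIF predictor while it exceeds ``threshold``.

    Returns (surviving predictor names, trace frame with one row per
    iteration x predictor). Exactly collinear predictors show infinite VIF
    and are dropped first.
    """
    cols = list(design.columns)
    if len(cols) < 2:
        raise ParameterError("VIF screening needs at least 2 predictors")
    if design.shape[0] <= len(cols) + 1:
        raise ParameterError("VIF screening needs n > n_predictors + 1")
    trace_rows = []
    it = 0
    while True:
        it += 1
        vifs = vif_values(design[cols].to_numpy())
        for c, v in zip(cols, vifs):
            trace_rows.append(dict(iteration=it, predictor=c, vif=v, dropped=False))
        worst = int(np.argmax(vifs))
        if vifs[worst] > threshold and len(cols) > 1:
            trace_rows[-len(cols) + worst]["dropped"] = True
            logger.info("vif_screen: dropping %s (VIF=%.3g)", cols[worst], vifs[worst])
            cols = cols[:worst] + cols[worst + 1:]
            if len(cols) < 2:
                break
        else:
            break
    return cols, pd.DataFrame(trace_rows)


def build_design(profiles: pd.DataFrame, records: list[SubjectRecord],
                 regions: list[int], response: str) -> pd.DataFrame:
    """Complete-case frame of response, regional entropies, age, sex for case subjects."""
    rows = []
    for r in records:
        if r.subject_id not in profiles.index:
            continue
        score = r.behavioral_scores.get(response)
        if score is None:
            continue
        row = {"subject_id": r.subject_id, response: score,
               "age": r.age, "sex": SEX_CODE[r.sex]}
        for rid in regions:
            row[f"R{rid}"] = profiles.loc[r.subject_id, f"R{rid}"]
        rows.append(row)
    frame = pd.DataFrame(rows)
    if frame.empty:
        return frame
    n0 = len(frame)
    frame = frame.dropna().set_index("subject_id")
    if len(frame) < n0:
        logger.info("build_design(%s): %d of %d rows dropped as incomplete",
                    response, n0 - len(frame), n0)
    return frame


def _batched_ols(Xb: np.ndarray, yb: np.ndarray) -> np.ndarray:
    """Solve OLS for a batch of designs (n_boot, m, p); raises on any singular batch."""
    XtX = np.einsum("bij,bik->bjk", Xb, Xb)
    Xty = np.einsum("bij,bi->bj", Xb, yb)
    return np.linalg.solve(XtX, Xty[:, :, None])[:, :, 0]


def fit_bootstrap_regression(spec: RegressionSpec, data: pd.DataFrame,
                             seed: int = 0) -> RegressionResult:
    """OLS point fit plus bootstrap beta distributions.

    The full complete-case sample gives point betas, R^2, F and the model p;
    each of ``n_boot`` resamples draws floor(subsample_frac * n) subjects
    (with replacement by default), refits, and contributes to the per-beta
    bootstrap mean/SE/percentile CI. The bootstrap p-value is
    2*min(P(beta* <= 0), P(beta* >= 0)), floored at 1/n_boot; singular
    resamples are skipped and counted.
    """
    cols = list(spec.predictors)
    missing = [c for c in cols + [spec.response] if c not in data.columns]
    if missing:
        raise ParameterError(f"data is missing columns {missing}")
    frame = data[[spec.response] + cols].dropna()
    n = len(frame)
    if n < len(cols) + 2:
        raise ParameterError(f"need at least {len(cols) + 2} complete cases, have {n}")
    y = frame[spec.response].to_numpy(dtype=float)
    X = sm.add_constant(frame[cols].to_numpy(dtype=float), has_constant="add")
    terms = ["intercept"] + cols

    full = sm.OLS(y, X).fit()
    point = np.asarray(full.params)

    rng = np.random.default_rng(seed)
    m = int(np.floor(spec.subsample_frac * n))
    if m < len(cols) + 2:
        raise ParameterError(f"bootstrap sample size {m} too small for {len(cols)} predictors")
    if not spec.resample:
        idx = np.tile(np.arange(m), (spec.n_boot, 1))
    elif spec.replace:
        idx = rng.integers(0, n, size=(spec.n_boot, m))
    else:
        idx = rng.permuted(np.tile(np.arange(n), (spec.n_boot, 1)), axis=1)[:, :m]
    Xb, yb = X[idx], y[idx]
    skipped = 0
    try:
        betas = _batched_ols(Xb, yb)
    except np.linalg.LinAlgError:
        betas_list = []
        for b in range(spec.n_boot):
            sol, _, rank, _ = np.linalg.lstsq(Xb[b], yb[b], rcond=None)
            if rank < X.shape[1]:
                skipped += 1
                continue
            betas_list.append(sol)
        betas = np.array(betas_list) if betas_list else np.empty((0, X.shape[1]))
    n_ok = betas.shape[0]
    if spec.n_boot and skipped > 0.1 * spec.n_boot:
        logger.warning("bootstrap: %d/%d resamples skipped as singular", skipped, spec.n_boot)

    rows = []
    for j, term in enumerate(terms):
        bj = betas[:, j] if n_ok else np.empty(0)
        if n_ok:
            p_boot = 2.0 * min(float(np.mean(bj <= 0)), float(np.mean(bj >= 0)))
            p_boot = min(1.0, max(p_boot, 1.0 / n_ok))
            ci = np.percentile(bj, [2.5, 97.5])
            boot_mean = float(bj.mean())
            boot_se = float(bj.std(ddof=1)) if n_ok > 1 else 0.0
        else:
            p_boot, ci, boot_mean, boot_se = np.nan, (np.nan, np.nan), np.nan, np.nan
        rows.append(dict(term=term, beta=float(point[j]), boot_mean=boot_mean,
                         boot_se=boot_se, ci_low=float(ci[0]), ci_high=float(ci[1]),
                         p_boot=p_boot, p_ols=float(full.pvalues[j]),
                         significant=bool(p_boot < spec.alpha) if n_ok else False))
    return RegressionResult(spec=spec, terms=pd.DataFrame(rows), r2=float(full.rsquared),
                            fstat=float(full.fvalue), model_p=float(full.f_pvalue),
                            n_used=n, n_boot_ok=n_ok, n_boot_skipped=skipped,
                            boot_betas=betas)
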