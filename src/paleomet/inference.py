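"""Linear modeling of log10 mass-independent MMR on phylogenetic
eigenvectors plus log10 blood flow, with forward AICc selection, fossil
retrodiction intervals, leave-one-out cross-validation, and residual
normality checking.

The response and co-predictor are base-10 logs throughout; back-transformed
intervals are therefore log-symmetric about the point estimate.  AICc uses
the Gaussian maximum-likelihood convention with the residual variance
counted among the k parameters:

    AICc = -2*loglik + 2k + 2k(k+1)/(n-k-1),   loglik at sigma^2 = RSS/n.
"""
from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pem import PEMBasis, build_pem, location_scores
from .phylo import PhyloTree, graft_fossil, prune_tip

__all__ = [
    "PerfectFitError",
    "FitResult",
    "Retrodiction",
    "LoocvFold",
    "ValidationReport",
    "gaussian_aicc",
    "fit_linear_model",
    "forward_select",
    "predict_point",
    "retrodict",
    "loocv",
    "shapiro_wilk",
]

logger = logging.getLogger(__name__)


class PerfectFitError(RuntimeError):
    """Residual sum of squares fell below the guard; AICc would be -inf."""


def _rss_guard(y: np.ndarray) -> float:
    return 1e-12 * max(1.0, float(y @ y))


def gaussian_aicc(rss: float, n: int, n_coef: int) -> float:
    """Small-sample AIC from an OLS residual sum of squares.

    ``n_coef`` counts the regression coefficients; the residual variance is
    added on top, k = n_coef + 1.  Requires n - k - 1 >= 1.
    """
    k = n_coef + 1
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined: n - k - 1 = {n - k - 1} <= 0")
    if rss <= 0:
        raise PerfectFitError("zero residual sum of squares")
    loglik = -0.5 * n * (math.log(2.0 * math.pi * rss / n) + 1.0)
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


@dataclasses.dataclass
class FitResult:
    """Ordinary-least-squares fit of the retrodiction model.

    ``indices`` are the selected eigenvector numbers (1-based, ascending);
    coefficient order is intercept, eigenvectors (ascending index), then
    the co-predictor when present.
    """

    indices: tuple[int, ...]
    coef_names: tuple[str, ...]
    coef: np.ndarray
    residuals: np.ndarray
    fitted: np.ndarray
    n: int
    k: int                      # all coefficients + residual variance
    rss: float
    adj_r2: float
    aicc: float
    f_pvalue: float
    sigma2: float               # RSS / (n - n_coef)
    df_resid: int
    xtx_inv: np.ndarray
    has_copredictor: bool
    X: np.ndarray
    y: np.ndarray

    @property
    def n_coef(self) -> int:
        return self.k - 1


def fit_linear_model(
    y: np.ndarray,
    X: np.ndarray,
    coef_names: Sequence[str],
    indices: Sequence[int] = (),
    has_copredictor: bool = False,
) -> FitResult:
    """OLS fit with AICc, adjusted R^2 and the overall-F p-value.

    ``X`` is the full design including the intercept column.  A fit whose
    RSS falls below the numerical guard raises :class:`PerfectFitError`
    rather than reporting an infinite AICc.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > number of coefficients ({n} <= {p})")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    resid = y - fitted
    rss = float(resid @ resid)
    if rss < _rss_guard(y):
        raise PerfectFitError(
            "perfect fit: residual sum of squares below the 1e-12 guard"
        )
    aicc = gaussian_aicc(rss, n, p)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1.0) / (n - p)
    if p > 1 and tss > rss:
        f_stat = ((tss - rss) / (p - 1)) / (rss / (n - p))
        f_pvalue = float(stats.f.sf(f_stat, p - 1, n - p))
    else:
        f_pvalue = float("nan")
    return FitResult(
        indices=tuple(sorted(int(i) for i in indices)),
        coef_names=tuple(coef_names),
        coef=coef,
        residuals=resid,
        fitted=fitted,
        n=n,
        k=p + 1,
        rss=rss,
        adj_r2=float(adj_r2),
        aicc=float(aicc),
        f_pvalue=f_pvalue,
        sigma2=rss / (n - p),
        df_resid=n - p,
        xtx_inv=np.linalg.inv(X.T @ X),
        has_copredictor=has_copredictor,
        X=X,
        y=y,
    )


def _assemble_design(
    U: np.ndarray, z: np.ndarray | None, indices: Sequence[int]
) -> tuple[np.ndarray, list[str]]:
    n = U.shape[0]
    cols = [np.ones(n)]
    names = ["intercept"]
    for i in sorted(indices):
        cols.append(U[:, i - 1])
        names.append(f"V{i}")
    if z is not None:
        cols.append(np.asarray(z, dtype=float))
        names.append("log_q")
    return np.column_stack(cols), names


def forward_select(
    y: np.ndarray,
    basis: PEMBasis | np.ndarray,
    copredictor: np.ndarray | None = None,
    max_terms: int | None = None,
) -> FitResult:
    """Greedy forward selection of eigenvectors by AICc.

    The intercept and the co-predictor (when given) are always in the
    model.  Each step adds the single eigenvector that most decreases AICc;
    selection stops when no addition decreases it.  Ties break toward the
    smaller eigenvector index.  The greedy search runs on incremental
    orthogonalized updates; the returned fit is an exact refit of the
    selected design.
    """
    U = basis.U if isinstance(basis, PEMBasis) else np.asarray(basis, float)
    y = np.asarray(y, dtype=float)
    n, m = U.shape
    if len(y) != n:
        raise ValueError("response length does not match basis tips")
    if copredictor is not None and len(copredictor) != n:
        raise ValueError("co-predictor length does not match basis tips")

    X0, _ = _assemble_design(U[:, :0], copredictor, ())
    Q, _ = np.linalg.qr(X0)
    ry = y - Q @ (Q.T @ y)
    rss = float(ry @ ry)
    guard = _rss_guard(y)
    col_norms0 = np.einsum("ij,ij->j", U, U)
    C = U - Q @ (Q.T @ U)

    selected: list[int] = []      # 0-based column indices, selection order
    n_base = X0.shape[1]
    perfect = rss < guard

    def crit(r: float, n_coef: int) -> float:
        if r < guard:
            return -math.inf
        if n - (n_coef + 1) - 1 <= 0:
            return math.inf
        return gaussian_aicc(r, n, n_coef)

    current = crit(rss, n_base)
    while not perfect:
        if max_terms is not None and len(selected) >= max_terms:
            break
        n_coef_new = n_base + len(selected) + 1
        if n - (n_coef_new + 1) - 1 <= 0:
            break
        norms2 = np.einsum("ij,ij->j", C, C)
        usable = norms2 > 1e-10 * np.maximum(col_norms0, 1e-300)
        usable[selected] = False
        if not np.any(usable):
            break
        proj = C.T @ ry
        rss_new = np.where(usable, rss - proj**2 / np.where(usable, norms2, 1.0), np.inf)
        rss_new = np.maximum(rss_new, 0.0)
        cand_aicc = np.full(m, math.inf)
        for j in np.flatnonzero(usable):
            cand_aicc[j] = crit(float(rss_new[j]), n_coef_new)
        best = int(np.argmin(cand_aicc))
        if not cand_aicc[best] < current:
            break
        q = C[:, best] / math.sqrt(norms2[best])
        ry = ry - q * (q @ ry)
        rss = float(ry @ ry)
        C = C - np.outer(q, q @ C)
        selected.append(best)
        current = cand_aicc[best]
        if rss < guard or current == -math.inf:
            perfect = True

    indices = tuple(sorted(j + 1 for j in selected))
    X, names = _assemble_design(U, copredictor, indices)
    try:
        return fit_linear_model(
            y, X, names, indices=indices,
            has_copredictor=copredictor is not None,
        )
    except PerfectFitError:
        # exact-fit design: report coefficients with degenerate statistics
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ coef
        resid = y - fitted
        n_, p = X.shape
        return FitResult(
            indices=indices,
            coef_names=tuple(names),
            coef=coef,
            residuals=resid,
            fitted=fitted,
            n=n_,
            k=p + 1,
            rss=float(resid @ resid),
            adj_r2=1.0,
            aicc=-math.inf,
            f_pvalue=0.0,
            sigma2=0.0,
            df_resid=n_ - p,
            xtx_inv=np.linalg.pinv(X.T @ X),
            has_copredictor=copredictor is not None,
            X=X,
            y=y,
        )


@dataclasses.dataclass(frozen=True)
class Retrodiction:
    """Back-transformed point estimate and interval for one fossil tip."""

    label: str
    point_log10: float
    lower_log10: float
    upper_log10: float
    point: float
    lower: float
    upper: float
    b: float | None
    level: float
    kind: str                   # "confidence" (conditional mean) or "prediction"

    def __post_init__(self) -> None:
        if not (self.lower < self.point < self.upper):
            raise ValueError("interval must bracket the point estimate")


def retrodict(
    fit: FitResult,
    scores: np.ndarray,
    z_fossil: float | None = None,
    level: float = 0.95,
    kind: str = "confidence",
    label: str = "fossil",
    b: float | None = None,
    extant_scores: np.ndarray | None = None,
    stem_variance: float = 0.0,
) -> Retrodiction:
    """Predict log10 mass-independent MMR for a fossil design row.

    ``scores`` is the fossil's full eigenvector score row (the selected
    columns are picked out by the fit).  ``kind='confidence'`` gives the
    interval for the conditional mean x0' beta; ``kind='prediction'``
    inflates the variance by the residual variance for a single new
    observation plus ``stem_variance``, the Brownian variance accumulated
    along the fossil's private stem (no basis column represents that edge;
    see :func:`paleomet.pem.unrepresented_length` and
    :func:`paleomet.phylo.brownian_rate`).  A warning is logged when any
    selected fossil score lies outside 1.5x the extant score range
    (extrapolation).
    """
    if kind not in ("confidence", "prediction"):
        raise ValueError("kind must be 'confidence' or 'prediction'")
    scores = np.asarray(scores, dtype=float)
    x0 = [1.0]
    for i in fit.indices:
        if i - 1 >= len(scores):
            raise ValueError(f"fossil scores do not cover eigenvector {i}")
        x0.append(scores[i - 1])
    if fit.has_copredictor:
        if z_fossil is None:
            raise ValueError("model includes the co-predictor; z_fossil required")
        x0.append(float(z_fossil))
    x0 = np.asarray(x0)

    if extant_scores is not None and len(fit.indices) > 0:
        sel = [i - 1 for i in fit.indices]
        lo = extant_scores[:, sel].min(axis=0)
        hi = extant_scores[:, sel].max(axis=0)
        mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
        s = scores[sel]
        out = (s < mid - 1.5 * half) | (s > mid + 1.5 * half)
        if np.any(out):
            which = [fit.indices[j] for j in np.flatnonzero(out)]
            logger.warning(
                "retrodiction for %s extrapolates beyond 1.5x the extant "
                "score range on eigenvector(s) %s", label, which,
            )

    point = float(x0 @ fit.coef)
    lev = x0 @ fit.xtx_inv @ x0
    var = fit.sigma2 * lev
    if kind == "prediction":
        var += fit.sigma2 + max(stem_variance, 0.0)
    tcrit = stats.t.ppf(0.5 + level / 2.0, fit.df_resid)
    half_width = float(tcrit * math.sqrt(max(var, 0.0)))
    lo_log, hi_log = point - half_width, point + half_width
    return Retrodiction(
        label=label,
        point_log10=point,
        lower_log10=lo_log,
        upper_log10=hi_log,
        point=10.0**point,
        lower=10.0**lo_log,
        upper=10.0**hi_log,
        b=b,
        level=level,
        kind=kind,
    )


def predict_point(fit: FitResult, scores: np.ndarray, z_fossil: float | None) -> float:
    """Point prediction x0' beta for a score row (no interval)."""
    x0 = [1.0]
    for i in fit.indices:
        x0.append(float(scores[i - 1]))
    if fit.has_copredictor:
        if z_fossil is None:
            raise ValueError("model includes the co-predictor; z_fossil required")
        x0.append(float(z_fossil))
    return float(np.asarray(x0) @ fit.coef)


@dataclasses.dataclass(frozen=True)
class LoocvFold:
    taxon: str
    observed: float
    predicted: float | None
    ok: bool
    message: str = ""


@dataclasses.dataclass
class ValidationReport:
    """LOOCV predictions, their paired test, and residual normality."""

    folds: list[LoocvFold]
    test_name: str
    statistic: float
    pvalue: float
    zero_variance: bool
    shapiro_w: float
    shapiro_p: float

    @property
    def n_failed(self) -> int:
        return sum(not f.ok for f in self.folds)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon": [f.taxon for f in self.folds],
                "observed_log10": [f.observed for f in self.folds],
                "predicted_log10": [
                    f.predicted if f.predicted is not None else np.nan
                    for f in self.folds
                ],
                "ok": [f.ok for f in self.folds],
                "message": [f.message for f in self.folds],
            }
        )

    @property
    def mean_bias(self) -> float:
        d = [f.observed - f.predicted for f in self.folds if f.ok]
        return float(np.mean(d)) if d else float("nan")


def shapiro_wilk(residuals: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W and p-value for residual normality."""
    r = np.asarray(residuals, dtype=float)
    if not (3 <= len(r) <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(r) == 0:
        raise ValueError("residuals are constant")
    w, p = stats.shapiro(r)
    return float(w), float(p)


def loocv(
    df: pd.DataFrame,
    tree: PhyloTree,
    a: float = 0.0,
    psi: float = 1.0,
    test: str = "t",
    response: str = "log_mmr_mi",
    copredictor: str = "log_q",
    full_fit: FitResult | None = None,
) -> ValidationReport:
    """Leave-one-out cross-validation over the extant taxa.

    For each extant taxon the eigenvector basis is rebuilt on the remaining
    tips, forward selection is re-run, and the held-out taxon is scored at
    its true tree position (prune + re-graft) and predicted.  The observed
    minus predicted differences are compared with a paired two-sided t-test
    (or Wilcoxon signed-rank, ``test='wilcoxon'``); Shapiro-Wilk is applied
    to the full-model residuals.  Folds whose selection fails are flagged
    and excluded from the test.
    """
    if test not in ("t", "wilcoxon"):
        raise ValueError("test must be 't' or 'wilcoxon'")
    extant = df[df[response].notna()]
    taxa = list(extant.index)
    if len(taxa) < 10:
        raise ValueError("LOOCV requires at least 10 extant taxa")
    tree_tips = set(tree.tip_labels())
    if not set(taxa) <= tree_tips:
        raise ValueError("extant taxa missing from the tree")

    et = _extant_tree(tree, taxa)
    if full_fit is None:
        basis = build_pem(et, a=a, psi=psi)
        yv = extant.loc[basis.tip_labels, response].to_numpy(float)
        zv = extant.loc[basis.tip_labels, copredictor].to_numpy(float)
        full_fit = forward_select(yv, basis, zv)

    folds: list[LoocvFold] = []
    for taxon in taxa:
        obs = float(extant.loc[taxon, response])
        try:
            pruned, spec = prune_tip(et, taxon)
            fold_basis = build_pem(pruned, a=a, psi=psi)
            order = fold_basis.tip_labels
            y_i = extant.loc[order, response].to_numpy(float)
            z_i = extant.loc[order, copredictor].to_numpy(float)
            fit_i = forward_select(y_i, fold_basis, z_i)
            grafted = graft_fossil(pruned, spec)
            scores = location_scores(fold_basis, grafted, taxon)
            pred = predict_point(
                fit_i, scores, float(extant.loc[taxon, copredictor])
            )
            folds.append(LoocvFold(taxon, obs, pred, True))
        except Exception as exc:  # noqa: BLE001 - fold isolation by design
            logger.warning("LOOCV fold for %s failed: %s", taxon, exc)
            folds.append(LoocvFold(taxon, obs, None, False, str(exc)))

    diffs = np.array([f.observed - f.predicted for f in folds if f.ok])
    if len(diffs) < 3:
        raise ValueError("too few successful LOOCV folds for a paired test")
    zero_var = bool(np.ptp(diffs) == 0 or np.allclose(diffs, diffs[0]))
    if zero_var:
        statistic, pvalue = float("nan"), 1.0
    elif test == "t":
        res = stats.ttest_1samp(diffs, 0.0)
        statistic, pvalue = float(res.statistic), float(res.pvalue)
    else:
        res = stats.wilcoxon(diffs)
        statistic, pvalue = float(res.statistic), float(res.pvalue)

    try:
        w, p_sw = shapiro_wilk(full_fit.residuals)
    except ValueError:
        # degenerate residuals (e.g. an exact fit): normality undefined
        w, p_sw = float("nan"), float("nan")
    return ValidationReport(
        folds=folds,
        test_name=test,
        statistic=statistic,
        pvalue=pvalue,
        zero_variance=zero_var,
        shapiro_w=w,
        shapiro_p=p_sw,
    )


def _extant_tree(tree: PhyloTree, taxa: Sequence[str]) -> PhyloTree:
    """Prune tree down to the given taxa (drops fossils already grafted)."""
    extra = [lab for lab in tree.tip_labels() if lab not in set(taxa)]
    t = tree
    for lab in extra:
        t, _ = prune_tip(t, lab)
    return t
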