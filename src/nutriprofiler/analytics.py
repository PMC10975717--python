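"""Descriptive and inferential reporting on a scored product catalogue.

Covers the study-style outputs: class distributions per analysis group,
original-vs-refined algorithm reallocation, median/IQR nutrient summaries,
and a univariate logistic model of flavour-enhancer presence against salt
content.  The logistic model captures the reformulation trade-off seen on
real labels: products with less salt more often declare flavour enhancers
(glutamate, yeast extract, ...) to compensate for taste, so the slope on
salt is expected to be negative.

Quantiles throughout use linear interpolation between order statistics
(numpy's default), applied to scores and nutrient values alike.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import rankdata

from .catalog import ProductRecord, assign_analysis_group
from .scoring import (
    CLASS_LETTERS,
    AlgorithmVariant,
    ScoreTableSet,
    nutriscore,
)

__all__ = [
    "class_distribution",
    "VariantComparison",
    "compare_variants",
    "group_summaries",
    "LogisticFit",
    "SaltEnhancerModel",
    "fit_salt_enhancer_logistic",
    "predicted_curve",
    "rank_auc",
    "SeparationError",
    "AnalyticsError",
]


class AnalyticsError(ValueError):
    """Invalid input to an analytics operation."""


class SeparationError(AnalyticsError):
    """The logistic likelihood has no finite maximiser (complete separation)."""


def _scored_frame(
    products: Sequence[ProductRecord],
    variant: AlgorithmVariant,
    tables: ScoreTableSet | None = None,
) -> pd.DataFrame:
    rows = []
    for r in products:
        res = nutriscore(r, variant, tables)
        c = res.components
        rows.append(
            {
                "product_id": r.product_id,
                "group": assign_analysis_group(r).label,
                "meat_class": r.meat_class.value,
                "total_score": res.total,
                "class": res.letter,
                "protein_counted": res.protein_counted,
                "energy_kj": r.profile.energy_kj,
                "energy_pts": c.energy_pts,
                "sugars_g": r.profile.sugars_g,
                "sugars_pts": c.sugars_pts,
                "sfa_g": r.profile.sfa_g,
                "sfa_pts": c.sfa_pts,
                "sodium_mg": r.profile.sodium_resolved_mg,
                "sodium_pts": c.sodium_pts,
                "protein_g": r.profile.protein_g,
                "protein_pts": c.protein_pts,
                "fibre_g": r.profile.fibre_g,
                "fibre_pts": c.fibre_pts,
            }
        )
    return pd.DataFrame(rows)


def class_distribution(
    products: Sequence[ProductRecord],
    variant: AlgorithmVariant = AlgorithmVariant.REFINED,
    tables: ScoreTableSet | None = None,
    include_overall: bool = True,
) -> pd.DataFrame:
    """Counts and percentages per Nutri-Score class, per analysis group.

    Long format: ``group, class, count, pct``; percentages are relative to
    the group's own size.  With ``include_overall`` an ``"all products"``
    block over the whole catalogue is appended.
    """
    frame = _scored_frame(products, variant, tables)
    rows: list[dict[str, object]] = []

    def block(label: str, sub: pd.DataFrame) -> None:
        n = len(sub)
        counts = sub["class"].value_counts()
        for letter in CLASS_LETTERS:
            k = int(counts.get(letter, 0))
            rows.append(
                {
                    "group": label,
                    "class": letter,
                    "count": k,
                    "pct": 100.0 * k / n if n else 0.0,
                }
            )

    for label, sub in frame.groupby("group", sort=True):
        block(label, sub)
    if include_overall:
        block("all products", frame)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class VariantComparison:
    """Original vs refined algorithm, product by product and aggregated."""

    per_product: pd.DataFrame  # product_id, group, meat_class, totals, classes
    moves: pd.DataFrame  # 5x5 counts, rows original class, cols refined class
    group_means: pd.DataFrame  # group, variant, mean_score (2 decimals)

    @property
    def n_moved(self) -> int:
        m = self.moves.to_numpy()
        return int(m.sum() - np.trace(m))


def compare_variants(
    products: Sequence[ProductRecord],
    tables: ScoreTableSet | None = None,
) -> VariantComparison:
    """Score every product under both algorithm variants and aggregate moves.

    For white meat the variants coincide, so white products always sit on
    the diagonal of the move matrix; red products can only move toward E
    (the refined protein cap removes up to 3 subtracted points).
    """
    orig = _scored_frame(products, AlgorithmVariant.ORIGINAL, tables)
    refi = _scored_frame(products, AlgorithmVariant.REFINED, tables)
    per_product = pd.DataFrame(
        {
            "product_id": orig["product_id"],
            "group": orig["group"],
            "meat_class": orig["meat_class"],
            "original_total": orig["total_score"],
            "refined_total": refi["total_score"],
            "original_class": orig["class"],
            "refined_class": refi["class"],
        }
    )
    idx = {letter: i for i, letter in enumerate(CLASS_LETTERS)}
    counts = np.zeros((5, 5), dtype=int)
    for a, b in zip(per_product["original_class"], per_product["refined_class"]):
        counts[idx[a], idx[b]] += 1
    moves = pd.DataFrame(counts, index=list(CLASS_LETTERS), columns=list(CLASS_LETTERS))
    means = []
    for variant, frame in (("original", orig), ("refined", refi)):
        g = frame.groupby("group")["total_score"].mean().round(2)
        for label, value in g.items():
            means.append({"group": label, "variant": variant, "mean_score": value})
    return VariantComparison(
        per_product=per_product, moves=moves, group_means=pd.DataFrame(means)
    )


_SUMMARY_VARIABLES = (
    "total_score",
    "energy_kj",
    "energy_pts",
    "sugars_g",
    "sugars_pts",
    "sfa_g",
    "sfa_pts",
    "sodium_mg",
    "sodium_pts",
    "protein_g",
    "protein_pts",
    "fibre_g",
    "fibre_pts",
)


def group_summaries(
    products: Sequence[ProductRecord],
    variant: AlgorithmVariant = AlgorithmVariant.REFINED,
    by_class: bool = False,
    tables: ScoreTableSet | None = None,
) -> pd.DataFrame:
    """Median and quartiles of scores and nutrient contents per group.

    Long format: ``group, [class,] variable, n, median, q25, q75``.  With
    ``by_class`` the summaries are additionally split by Nutri-Score class.
    Quantiles use linear interpolation; the result is invariant to record
    order.
    """
    frame = _scored_frame(products, variant, tables)
    keys = ["group", "class"] if by_class else ["group"]
    rows: list[dict[str, object]] = []
    for key, sub in frame.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        for var in _SUMMARY_VARIABLES:
            values = sub[var].dropna().to_numpy(dtype=float)
            if values.size == 0:
                continue
            q25, med, q75 = np.quantile(values, [0.25, 0.5, 0.75])
            row: dict[str, object] = dict(zip(keys, key))
            row.update(
                {"variable": var, "n": int(values.size), "median": med, "q25": q25, "q75": q75}
            )
            rows.append(row)
    return pd.DataFrame(rows)


def rank_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve via the rank (concordance) statistic.

    Equals the probability that a random positive outscores a random
    negative; ties contribute 1/2 through midranks.  Identical to
    trapezoidal integration of the empirical ROC curve.
    """
    y = np.asarray(y, dtype=bool)
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise AnalyticsError("AUC undefined: only one outcome level present")
    ranks = rankdata(scores)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass(frozen=True)
class LogisticFit:
    """Results of the salt -> flavour-enhancer logistic regression.

    ``chi2`` is the likelihood-ratio statistic of the model against the
    intercept-only null (1 degree of freedom for the univariate model);
    ``pct_correct`` classifies at the configured probability cut-off;
    ``auc`` is the rank-based concordance of fitted probabilities with the
    observed outcomes.
    """

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    cov_params: np.ndarray
    chi2: float
    df: int
    p_value: float
    pct_correct: float
    auc: float
    converged: bool
    n: int
    threshold: float = 0.5

    def predict(self, salt_g: np.ndarray | float) -> np.ndarray:
        """Fitted probability of enhancer presence at the given salt content."""
        return expit(self.intercept + self.slope * np.asarray(salt_g, dtype=float))

    def summary(self) -> str:
        lines = [
            "Flavour-enhancer presence ~ salt content (logistic regression)",
            f"  n = {self.n}, converged = {self.converged}",
            f"  intercept = {self.intercept:+.4f} (SE {self.se_intercept:.4f})",
            f"  slope     = {self.slope:+.4f} (SE {self.se_slope:.4f})  [log-odds per g salt/100 g]",
            f"  LR chi2 = {self.chi2:.1f}, df = {self.df}, p = {self.p_value:.3g}",
            f"  correctly classified at {self.threshold:g} cut-off: {self.pct_correct:.1f}%",
            f"  AUC = {self.auc:.3f}",
        ]
        return "\n".join(lines)


class SaltEnhancerModel:
    """Univariate logistic model of flavour-enhancer presence on salt.

    Thin modelling front-end: build from records or raw arrays, ``fit()``
    returns a :class:`LogisticFit` with estimates, uncertainties and
    validation measures.  Estimation is maximum likelihood via iteratively
    reweighted least squares.
    """

    def __init__(self, y: np.ndarray, salt_g: np.ndarray) -> None:
        y = np.asarray(y, dtype=float)
        salt = np.asarray(salt_g, dtype=float)
        if y.shape != salt.shape or y.ndim != 1:
            raise AnalyticsError("y and salt_g must be equal-length 1-d arrays")
        mask = ~(np.isnan(y) | np.isnan(salt))
        self.y = y[mask]
        self.salt = salt[mask]
        if self.y.size < 2:
            raise AnalyticsError("need at least 2 observations")
        if not set(np.unique(self.y)) <= {0.0, 1.0}:
            raise AnalyticsError("outcome must be binary 0/1")
        if self.y.min() == self.y.max():
            raise AnalyticsError("both outcome levels must be present")

    @classmethod
    def from_products(cls, products: Sequence[ProductRecord]) -> "SaltEnhancerModel":
        """Build from records; salt is taken from the declaration or back-
        converted from sodium (g = mg / 400)."""
        ys, salts = [], []
        for r in products:
            if r.has_flavour_enhancer is None:
                continue
            salt = r.profile.salt_g
            if salt is None and r.profile.sodium_mg is not None:
                salt = r.profile.sodium_mg / 400.0
            if salt is None:
                continue
            ys.append(float(r.has_flavour_enhancer))
            salts.append(salt)
        return cls(np.array(ys), np.array(salts))

    def fit(
        self, threshold: float = 0.5, maxiter: int = 100, tol: float = 1e-8
    ) -> LogisticFit:
        X = sm.add_constant(self.salt)
        try:
            result = sm.Logit(self.y, X).fit(
                disp=0, maxiter=maxiter, tol=tol, warn_convergence=False
            )
        except Exception as exc:  # statsmodels raises on perfect separation
            raise SeparationError(
                f"logistic fit failed (likely complete separation): {exc}"
            ) from exc
        converged = bool(result.mle_retvals.get("converged", False))
        if not converged or not np.all(np.isfinite(result.bse)):
            raise SeparationError(
                "logistic fit did not converge; check for complete separation "
                f"(|slope| reached {abs(result.params[1]):.3g})"
            )
        probs = np.asarray(result.predict(X))
        pct_correct = 100.0 * float(np.mean((probs >= threshold) == (self.y == 1.0)))
        return LogisticFit(
            intercept=float(result.params[0]),
            slope=float(result.params[1]),
            se_intercept=float(result.bse[0]),
            se_slope=float(result.bse[1]),
            cov_params=np.asarray(result.cov_params()),
            chi2=float(result.llr),
            df=int(result.df_model),
            p_value=float(result.llr_pvalue),
            pct_correct=pct_correct,
            auc=rank_auc(self.y == 1.0, probs),
            converged=converged,
            n=int(self.y.size),
            threshold=threshold,
        )


def fit_salt_enhancer_logistic(
    products: Sequence[ProductRecord], threshold: float = 0.5
) -> LogisticFit:
    """Fit the salt -> flavour-enhancer logistic model on a product list."""
    return SaltEnhancerModel.from_products(products).fit(threshold=threshold)


def predicted_curve(
    fit: LogisticFit,
    salt_grid: Sequence[float] | np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fitted probability curve with a delta-method confidence band.

    The band is computed on the linear predictor (where the estimator is
    asymptotically normal) and mapped through the inverse logit, so it stays
    inside (0, 1).  Columns: ``salt_g, prob, lower, upper``.
    """
    if not fit.converged:
        raise AnalyticsError("predicted_curve requires a converged fit")
    from scipy.stats import norm

    grid = np.asarray(salt_grid, dtype=float)
    X = np.column_stack([np.ones_like(grid), grid])
    eta = X @ np.array([fit.intercept, fit.slope])
    var = np.einsum("ij,jk,ik->i", X, fit.cov_params, X)
    se = np.sqrt(np.maximum(var, 0.0))
    z = norm.ppf(1 - alpha / 2)
    return pd.DataFrame(
        {
            "salt_g": grid,
            "prob": expit(eta),
            "lower": expit(eta - z * se),
            "upper": expit(eta + z * se),
        }
    )
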