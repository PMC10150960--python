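"""Mixed-effects logistic association analysis of hypoglycemia causes.

For each cause category k the outcome is the binary indicator "episode
belongs to k" and observations are clustered by subject, so every fit is a
random-intercept logit (:mod:`hypocause.mixedlogit`). Two arms:

* *single-variable scan* — one model per feature on that feature's own
  complete cases (keeps the sample as large as possible);
* *multiple regression* — advisor features excluded (they are mostly
  missing), candidate features screened by single-feature-model BIC, the
  survivors filtered for collinearity by iterative VIF (threshold 10), and
  one multi-predictor model fitted per category on the shared complete-case
  rows.

Features are centered (never scaled) before fitting, so coefficients stay in
per-unit-of-predictor log-odds. Significance stars follow the usual raw
two-sided Wald convention: * p<0.05, ** p<0.01, *** p<0.001 (no
multiple-testing correction — a deliberate, documented caveat).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import ADVISOR_FEATURES, FEATURE_REGISTRY, EXTRA_FEATURES
from .mixedlogit import MixedLogitFit, SeparationError, fit_mixed_logit

__all__ = [
    "AssociationConfig",
    "significance_stars",
    "single_variable_scan",
    "bic_rank_features",
    "vif_filter",
    "correlation_pairs",
    "multiple_regression_report",
]

log = logging.getLogger(__name__)

CATEGORIES = ("ACTIVITY", "FOOD", "MEDICATION")


@dataclass(frozen=True)
class AssociationConfig:
    bic_top_k: int = 40  # features entering multiple regression per category
    vif_threshold: float = 10.0
    rho_threshold: float = 0.7
    min_complete_rows: int = 20
    n_quadrature_nodes: int = 15


def significance_stars(p: float) -> str:
    """'*' p<0.05, '**' p<0.01, '***' p<0.001, '' otherwise (or p missing)."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _scan_feature_names(features: pd.DataFrame) -> list[str]:
    return [c for c in FEATURE_REGISTRY + EXTRA_FEATURES if c in features.columns]


def _fit_single(
    x: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    config: AssociationConfig,
    compute_se: bool = True,
) -> MixedLogitFit | None:
    ok = np.isfinite(x)
    x, y, groups = x[ok], y[ok], groups[ok]
    if len(x) < config.min_complete_rows:
        return None
    if np.nanstd(x) == 0 or y.min() == y.max() or len(np.unique(groups)) < 2:
        return None
    xc = x - x.mean()  # centered, not scaled
    try:
        return fit_mixed_logit(
            xc, y, groups,
            n_nodes=config.n_quadrature_nodes,
            compute_se=compute_se,
        )
    except (SeparationError, ValueError) as exc:
        log.warning("single-variable fit skipped: %s", exc)
        return None


def single_variable_scan(
    features: pd.DataFrame,
    category: str,
    config: AssociationConfig = AssociationConfig(),
    columns: list[str] | None = None,
    compute_se: bool = True,
) -> pd.DataFrame:
    """One random-intercept logit per feature for outcome "category == k",
    each on the feature's own complete cases.

    Returns a frame with columns (feature, category, beta, z, p, stars,
    n, bic); skipped features (too few complete rows, constant, separation)
    are logged and omitted.
    """
    cols = columns if columns is not None else _scan_feature_names(features)
    y_all = (features["category"].to_numpy() == category).astype(float)
    g_all = features["subject_id"].to_numpy()
    rows = []
    for name in cols:
        x = features[name].to_numpy(dtype=float)
        fit = _fit_single(x, y_all, g_all, config, compute_se=compute_se)
        if fit is None:
            log.info("feature %s skipped for category %s (insufficient or degenerate data)", name, category)
            continue
        r = fit.summary_row(1)
        rows.append(
            {
                "feature": name,
                "category": category,
                "beta": r["beta"],
                "z": r["z"],
                "p": r["p"],
                "stars": significance_stars(r["p"]),
                "n": fit.n_used,
                "bic": fit.bic,
            }
        )
    return pd.DataFrame(rows, columns=["feature", "category", "beta", "z", "p", "stars", "n", "bic"])


def bic_rank_features(
    features: pd.DataFrame,
    category: str,
    config: AssociationConfig = AssociationConfig(),
    columns: list[str] | None = None,
) -> list[str]:
    """Feature names sorted ascending by single-feature-model BIC (better fit
    first); ties broken by registry order. SEs are skipped (not needed for
    ranking), which keeps the screen cheap."""
    scan = single_variable_scan(features, category, config, columns=columns, compute_se=False)
    if scan.empty:
        return []
    order = {n: i for i, n in enumerate(FEATURE_REGISTRY + EXTRA_FEATURES)}
    ranked = sorted(
        scan.itertuples(index=False),
        key=lambda r: (r.bic, order.get(r.feature, 10**6)),
    )
    return [r.feature for r in ranked]


def vif_filter(
    X: pd.DataFrame | np.ndarray,
    threshold: float = 10.0,
) -> list:
    """Iteratively drop the column with the largest variance inflation factor
    until all VIFs are below ``threshold``.

    VIF_j = 1/(1 - R^2_j) from regressing column j on the remaining columns
    (with intercept). Exactly collinear columns give infinite VIF and are
    dropped first (the latest such column goes first, keeping earlier /
    registry-ordered features). Returns the retained column labels
    (DataFrame) or indices (ndarray).
    """
    if isinstance(X, pd.DataFrame):
        labels = list(X.columns)
        M = X.to_numpy(dtype=float)
    else:
        M = np.asarray(X, dtype=float)
        labels = list(range(M.shape[1]))
    if M.shape[1] < 2:
        return labels
    keep = list(range(M.shape[1]))
    while len(keep) >= 2:
        vifs = []
        A = M[:, keep]
        Ac = A - A.mean(axis=0)
        for pos in range(len(keep)):
            target = Ac[:, pos]
            others = np.delete(Ac, pos, axis=1)
            tss = float(target @ target)
            if tss <= 0:
                vifs.append(np.inf)  # constant column is useless in a design
                continue
            coef, *_ = np.linalg.lstsq(others, target, rcond=None)
            resid = target - others @ coef
            r2 = 1.0 - float(resid @ resid) / tss
            vifs.append(np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2))
        worst = int(np.argmax(vifs))
        # ties (e.g. several infinite VIFs): drop the latest column so that
        # earlier, registry-ordered features survive
        worst_val = vifs[worst]
        if not worst_val >= threshold:
            break
        tied = [i for i, v in enumerate(vifs) if v == worst_val or (np.isinf(v) and np.isinf(worst_val))]
        keep.pop(tied[-1])
    return [labels[i] for i in keep]


def correlation_pairs(
    X: pd.DataFrame,
    rho_threshold: float = 0.7,
) -> dict:
    """All unordered pairs of non-binary columns with |Pearson rho| >= the
    threshold (pairwise complete observations), plus the correlation
    submatrix of the implicated features and any constant columns (whose
    correlation is undefined)."""
    nonbin = []
    constant = []
    for c in X.columns:
        vals = X[c].dropna().unique()
        if len(vals) <= 1:
            constant.append(c)
        elif len(vals) > 2:
            nonbin.append(c)
    corr = X[nonbin].corr(method="pearson")  # pairwise complete
    pairs = []
    for i, a in enumerate(nonbin):
        for b in nonbin[i + 1 :]:
            rho = corr.loc[a, b]
            # inclusive threshold, with float slack so an exactly-0.7 pair
            # is not lost to rounding in the correlation computation
            if np.isfinite(rho) and abs(rho) >= rho_threshold - 1e-12:
                pairs.append((a, b, float(rho)))
    implicated = sorted({a for a, _, _ in pairs} | {b for _, b, _ in pairs},
                        key=list(X.columns).index)
    return {
        "pairs": pairs,
        "implicated": implicated,
        "submatrix": corr.loc[implicated, implicated] if implicated else corr.iloc[:0, :0],
        "constant_columns": constant,
    }


def multiple_regression_report(
    features: pd.DataFrame,
    config: AssociationConfig = AssociationConfig(),
) -> pd.DataFrame:
    """Per-category multi-predictor mixed logit after the screening pipeline:
    drop advisor features and the raw ``tod`` float -> rank by single-feature
    BIC and keep the top ``bic_top_k`` -> shared complete-case rows -> VIF
    filter -> one joint fit per category. Returns tidy rows (feature,
    category, beta, z, p, stars, n)."""
    candidates = [
        c for c in FEATURE_REGISTRY
        if c in features.columns and c not in ADVISOR_FEATURES
    ]
    out = []
    for category in CATEGORIES:
        ranked = bic_rank_features(features, category, config, columns=candidates)
        selected = ranked[: config.bic_top_k]
        if not selected:
            continue
        # registry order makes VIF tie-breaking among exact-collinear pairs
        # (e.g. the two time-of-day offsets, which sum to 12 h) deterministic
        selected = [c for c in candidates if c in selected]
        sub = features[["subject_id", "category"] + selected].dropna()
        X = sub[selected]
        kept = vif_filter(X, config.vif_threshold)
        Xk = X[kept].to_numpy(dtype=float)
        Xc = Xk - Xk.mean(axis=0)
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(Xc)), Xc]))
        if rank < len(kept) + 1:
            raise ValueError(
                f"rank-deficient design after VIF filtering for {category}: "
                f"columns {kept}"
            )
        y = (sub["category"].to_numpy() == category).astype(float)
        fit = fit_mixed_logit(
            Xc, y, sub["subject_id"].to_numpy(),
            n_nodes=config.n_quadrature_nodes,
            feature_names=kept,
        )
        for j, name in enumerate(kept, start=1):
            r = fit.summary_row(j)
            out.append(
                {
                    "feature": name,
                    "category": category,
                    "beta": r["beta"],
                    "z": r["z"],
                    "p": r["p"],
                    "stars": significance_stars(r["p"]),
                    "n": fit.n_used,
                }
            )
    return pd.DataFrame(out, columns=["feature", "category", "beta", "z", "p", "stars", "n"])
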