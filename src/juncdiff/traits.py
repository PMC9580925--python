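"""Junction-trait association: correlation, ANOVA and covariate-adjusted
linear models, plus ranking of top associations for radar-style display.

Expression is a junctions x samples matrix (typically logCPM); traits are
per-sample numeric or categorical variables.  Missing values are handled
pairwise-complete and the number of observations used is recorded.
BH adjustment is applied per trait across junctions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .dje import bh_adjust

__all__ = [
    "bicor",
    "correlate",
    "anova_assoc",
    "linear_assoc",
    "spliceradar_data",
]


def bicor(x: np.ndarray, y: np.ndarray) -> float:
    """Biweight midcorrelation of two vectors.

    Observations are weighted by (1 - u^2)^2 with u = (x - median) /
    (9 * MAD); points beyond 9 MADs get zero weight.  Falls back to
    Pearson (with a warning) when either vector has zero MAD.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("bicor needs >= 3 finite pairs")
    madx = np.median(np.abs(x - np.median(x)))
    mady = np.median(np.abs(y - np.median(y)))
    if madx == 0 or mady == 0:
        warnings.warn("zero MAD; falling back to Pearson correlation", stacklevel=2)
        if np.std(x) == 0 or np.std(y) == 0:
            return np.nan
        return float(np.corrcoef(x, y)[0, 1])
    xt = _biweight_transform(x, madx)
    yt = _biweight_transform(y, mady)
    denom = np.sqrt((xt**2).sum()) * np.sqrt((yt**2).sum())
    if denom == 0:
        return np.nan
    return float((xt * yt).sum() / denom)


def _biweight_transform(x: np.ndarray, mad: float) -> np.ndarray:
    u = (x - np.median(x)) / (9.0 * mad)
    a = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    return (x - np.median(x)) * a


def _corr_p(r: float, n: int) -> float:
    if not np.isfinite(r) or n < 3:
        return np.nan
    r = min(max(r, -1.0), 1.0)
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def _pair_corr(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, int]:
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        return np.nan, n
    xs, ys = x[ok], y[ok]
    if np.std(xs) == 0 or np.std(ys) == 0:
        return np.nan, n
    if method == "pearson":
        return float(np.corrcoef(xs, ys)[0, 1]), n
    if method == "spearman":
        return float(np.corrcoef(stats.rankdata(xs), stats.rankdata(ys))[0, 1]), n
    if method == "bicor":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return bicor(xs, ys), n
    raise ValueError(f"unknown correlation method {method!r}")


def correlate(
    expr: pd.DataFrame, traits: pd.DataFrame, method: str = "bicor"
) -> pd.DataFrame:
    """Correlate every junction with every numeric trait.

    Returns a long table with one row per (junction, trait): coefficient,
    Student-t p (n_used - 2 df), BH FDR per trait, and n_used.  Zero-
    variance pairs yield NaN coefficients (warned, excluded from FDR).
    """
    rows = []
    n_undefined = 0
    for trait in traits.columns:
        tv = traits[trait].reindex(expr.columns).to_numpy(dtype=float)
        for jid in expr.index:
            r, n = _pair_corr(expr.loc[jid].to_numpy(dtype=float), tv, method)
            if not np.isfinite(r):
                n_undefined += 1
            rows.append((jid, trait, method, r, _corr_p(r, n), n))
    if n_undefined:
        warnings.warn(
            f"{n_undefined} (junction, trait) pairs had undefined correlation "
            "(zero variance or too few complete pairs)",
            stacklevel=2,
        )
    out = pd.DataFrame(
        rows, columns=["junction_id", "trait", "method", "coefficient", "p", "n_used"]
    )
    out["fdr"] = np.nan
    for trait, sub in out.groupby("trait"):
        out.loc[sub.index, "fdr"] = bh_adjust(sub["p"].to_numpy())
    return out


def anova_assoc(expr: pd.DataFrame, trait: pd.Series) -> pd.DataFrame:
    """One-way ANOVA of each junction's expression across trait levels.

    Levels with fewer than 2 samples are dropped with a warning; needs at
    least two remaining levels.  BH FDR across junctions.
    """
    trait = trait.reindex(expr.columns)
    counts = trait.dropna().value_counts()
    keep_levels = counts[counts >= 2].index
    dropped = counts[counts < 2].index.tolist()
    if dropped:
        warnings.warn(f"levels with < 2 samples dropped: {dropped}", stacklevel=2)
    if len(keep_levels) < 2:
        raise ValueError("ANOVA needs >= 2 levels with >= 2 samples each")
    groups_idx = [trait.index[trait == lev] for lev in keep_levels]
    rows = []
    for jid in expr.index:
        vals = [expr.loc[jid, gi].to_numpy(dtype=float) for gi in groups_idx]
        vals = [v[np.isfinite(v)] for v in vals]
        n = sum(len(v) for v in vals)
        if any(len(v) < 2 for v in vals):
            rows.append((jid, "anova", np.nan, np.nan, n))
            continue
        F, p = stats.f_oneway(*vals)
        rows.append((jid, "anova", float(F), float(p), n))
    out = pd.DataFrame(
        rows, columns=["junction_id", "method", "coefficient", "p", "n_used"]
    )
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out


def linear_assoc(
    expr: pd.DataFrame,
    trait: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Covariate-adjusted association between junctions and a numeric trait.

    Expression and trait are residualized on [intercept | covariates]; the
    reported coefficient is the Pearson correlation of the residuals with
    t = r * sqrt((n - c - 2) / (1 - r^2)) on n - c - 2 df (the large-matrix
    eQTL-style statistic).  With no covariates this reduces to plain
    Pearson correlation.
    """
    samples = list(expr.columns)
    tv = trait.reindex(samples).to_numpy(dtype=float)
    if covariates is None or covariates.shape[1] == 0:
        C = np.ones((len(samples), 1))
        c = 0
    else:
        cov = covariates.reindex(samples).to_numpy(dtype=float)
        C = np.column_stack([np.ones(len(samples)), cov])
        c = cov.shape[1]
        if np.linalg.matrix_rank(C) < C.shape[1]:
            # identify an offending column by dropping one at a time
            for k, name in enumerate(covariates.columns):
                sub = np.delete(C, k + 1, axis=1)
                if np.linalg.matrix_rank(sub) == sub.shape[1]:
                    raise ValueError(f"collinear covariate column: {name!r}")
            raise ValueError("collinear covariate matrix")
    ok = np.isfinite(tv) & np.isfinite(C).all(axis=1)
    n = int(ok.sum())
    if n <= c + 2:
        raise ValueError(f"need n > c + 2 samples, got n={n}, c={c}")
    Q, _ = np.linalg.qr(C[ok])
    resid_t = tv[ok] - Q @ (Q.T @ tv[ok])
    sd_t = float(np.std(resid_t))
    rows = []
    for jid in expr.index:
        e = expr.loc[jid].to_numpy(dtype=float)[ok]
        resid_e = e - Q @ (Q.T @ e)
        if sd_t < 1e-12 * (abs(tv[ok]).max() + 1) or np.std(resid_e) == 0:
            rows.append((jid, "linear", np.nan, np.nan, n))
            continue
        r = float(np.dot(resid_e, resid_t) / (np.linalg.norm(resid_e) * np.linalg.norm(resid_t)))
        df = n - c - 2
        r = min(max(r, -1.0), 1.0)
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * np.sqrt(df / (1.0 - r**2))
            p = float(2.0 * stats.t.sf(abs(t), df))
        rows.append((jid, "linear", r, p, n))
    if sd_t < 1e-12 * (abs(tv[ok]).max() + 1):
        warnings.warn(
            "trait is (nearly) a linear function of the covariates; "
            "associations undefined",
            stacklevel=2,
        )
    out = pd.DataFrame(
        rows, columns=["junction_id", "method", "coefficient", "p", "n_used"]
    )
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out


def spliceradar_data(
    assoc: pd.DataFrame,
    junctions: list[str],
    fdr_max: float = 0.05,
    rho_min: float = 0.2,
    top_k: int = 20,
) -> pd.DataFrame:
    """Top-ranked trait associations for a set of junctions.

    Keeps traits passing (fdr < fdr_max and |coefficient| > rho_min) for at
    least one selected junction, ranks them by their maximum |coefficient|
    and truncates to ``top_k``; the output has one row per (trait, junction)
    with the signed coefficient (positive values plot in the outer radar
    ring, negative in the inner).
    """
    missing = set(junctions) - set(assoc["junction_id"])
    if missing:
        raise KeyError(f"junctions not in association table: {sorted(missing)[:5]}")
    sel = assoc[assoc["junction_id"].isin(junctions)].copy()
    passing = sel[(sel["fdr"] < fdr_max) & (sel["coefficient"].abs() > rho_min)]
    if passing.empty:
        warnings.warn("no trait passes the fdr/coefficient thresholds", stacklevel=2)
        return pd.DataFrame(columns=["trait", "junction_id", "coefficient", "rank"])
    strength = passing.groupby("trait")["coefficient"].agg(lambda s: s.abs().max())
    ranked = strength.sort_values(ascending=False).index[:top_k]
    out = sel[sel["trait"].isin(ranked)][["trait", "junction_id", "coefficient"]].copy()
    rank_of = {t: i + 1 for i, t in enumerate(ranked)}
    out["rank"] = out["trait"].map(rank_of)
    return out.sort_values(["rank", "junction_id"]).reset_index(drop=True)
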