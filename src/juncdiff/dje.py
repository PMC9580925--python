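"""Differential junction expression and within-gene differential usage.

The pipeline mirrors the moderated-statistics approach standard in
RNA-seq: counts are transformed to log2 counts per million, observation
weights are derived from the empirical mean-variance trend, a weighted
linear model is fit per junction, and residual variances are shrunk by
empirical Bayes before t-testing.  On top of the absolute (between-
condition) log-fold change, each junction is compared against the
precision-weighted average of the other junctions of its gene (relative
logFC = differential usage), and junctions are classified into four
groups by the interplay of the two effects:

* Group 0 - neither differential expression nor differential usage;
* Group 1 - both, with similar absolute and relative logFC (a splicing
  change at constant gene output);
* Group 2 - exactly one of the two (gene-level expression change, or a
  usage shift without abundance change);
* Group 3 - both, with divergent absolute and relative logFC (splicing
  change riding on a gene-expression change).

Neojunctions are junctions detected in the test condition but absent
from every control sample.
"""

from __future__ import annotations

import dataclasses
import difflib
import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .io import JunctionCountMatrix, parse_junction_id

__all__ = [
    "DesignSpec",
    "FitResult",
    "ModeratedStats",
    "DJEResult",
    "two_group_design",
    "filter_junctions",
    "logcpm",
    "mean_variance_weights",
    "fit_linear_model",
    "ebayes_moderate",
    "relative_usage",
    "gene_level_p",
    "classify_junctions",
    "detect_neojunctions",
    "dje_analyze",
    "splice_plot_data",
]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs propagate)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


@dataclasses.dataclass
class DesignSpec:
    """Experimental design for the per-junction linear model.

    ``design`` is a samples x p matrix (intercept included) and ``coef``
    names the column whose coefficient is reported as the absolute logFC.
    """

    design: pd.DataFrame
    coef: str

    def __post_init__(self) -> None:
        X = self.design.to_numpy(dtype=float)
        if self.coef not in self.design.columns:
            raise ValueError(f"coefficient {self.coef!r} not in design columns")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank-deficient")
        if X.shape[0] <= X.shape[1]:
            raise ValueError("need more samples than design columns")

    @property
    def samples(self) -> list[str]:
        return list(self.design.index)


def two_group_design(
    groups: Mapping[str, str] | pd.Series,
    test_label: str = "test",
    control_label: str = "control",
) -> DesignSpec:
    """Intercept + indicator design; the reported logFC is test minus control."""
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    bad = set(groups.unique()) - {test_label, control_label}
    if bad:
        raise ValueError(f"unexpected condition labels: {sorted(bad)}")
    design = pd.DataFrame(
        {
            "intercept": 1.0,
            test_label: (groups == test_label).astype(float),
        },
        index=groups.index,
    )
    return DesignSpec(design, test_label)


def filter_junctions(m: JunctionCountMatrix, min_mean: float = 10.0) -> JunctionCountMatrix:
    """Keep junctions whose raw-count mean across all samples is >= ``min_mean``."""
    if min_mean < 0:
        raise ValueError("min_mean must be >= 0")
    keep = m.counts.mean(axis=1) >= min_mean
    if not keep.any():
        raise ValueError(
            f"no junction has mean count >= {min_mean}; "
            "adjust the threshold based on the mean-variance trend"
        )
    return m.subset(m.counts.index[keep])


def logcpm(m: JunctionCountMatrix) -> pd.DataFrame:
    """log2 counts per million: log2((count + 0.5) / (libsize + 1) * 1e6).

    Library size is the per-sample column sum over all junctions passed in.
    """
    lib = m.counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        zero = lib.index[lib <= 0].tolist()
        raise ValueError(f"zero library size for samples {zero}")
    return np.log2((m.counts + 0.5).div(lib + 1.0, axis=1) * 1e6)


def _ols_common_design(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS for many responses sharing one design; returns (coef, fitted)."""
    coef, *_ = np.linalg.lstsq(X, y.T, rcond=None)
    fitted = (X @ coef).T
    return coef.T, fitted


def mean_variance_weights(
    y: pd.DataFrame, m: JunctionCountMatrix, d: DesignSpec, span: float = 0.5
) -> pd.DataFrame:
    """Observation-level precision weights from the mean-variance trend.

    The square root of each junction's residual standard deviation is
    smoothed against average log2 count with LOWESS; each observation's
    weight is the trend prediction at its fitted log-count, raised to the
    power -4 (i.e. inverse predicted variance on the logCPM scale).
    """
    if y.shape[0] < 10:
        raise ValueError(
            "mean-variance trend needs >= 10 junctions; run an unweighted analysis"
        )
    X = d.design.loc[y.columns].to_numpy(dtype=float)
    n, p = X.shape
    Y = y.to_numpy(dtype=float)
    _, fitted = _ols_common_design(Y, X)
    resid = Y - fitted
    s2 = (resid**2).sum(axis=1) / (n - p)
    sqrt_sd = np.sqrt(s2) ** 0.5

    lib = m.counts.sum(axis=0).astype(float).to_numpy()
    log2_gm_lib = float(np.mean(np.log2(lib + 1.0)))
    abar = Y.mean(axis=1) + log2_gm_lib - np.log2(1e6)

    trend = lowess(sqrt_sd, abar, frac=span, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]
    tx, idx = np.unique(tx, return_index=True)
    ty = ty[idx]
    if len(tx) < 2:
        raise ValueError("degenerate mean-variance trend; run an unweighted analysis")

    fitted_logcount = fitted + (np.log2(lib + 1.0) - np.log2(1e6))[None, :]
    pred = np.interp(fitted_logcount, tx, ty)
    pred = np.clip(pred, 1e-4, None)
    w = pred**-4.0
    return pd.DataFrame(w, index=y.index, columns=y.columns)


@dataclasses.dataclass
class FitResult:
    """Per-junction weighted least-squares fit.

    beta is the coefficient of interest on the log2 scale, ``u`` its
    unscaled standard error (sqrt of the corresponding diagonal of
    (X'WX)^-1), ``s2`` the weighted residual variance and ``df`` the
    residual degrees of freedom.
    """

    beta: pd.Series
    u: pd.Series
    s2: pd.Series
    df: pd.Series
    weights: pd.DataFrame
    design: DesignSpec


def fit_linear_model(y: pd.DataFrame, d: DesignSpec, w: pd.DataFrame) -> FitResult:
    """Weighted least squares per junction with a shared design matrix."""
    X = d.design.loc[y.columns].to_numpy(dtype=float)
    n, p = X.shape
    if n - p <= 0:
        raise ValueError("no residual degrees of freedom")
    W = w.loc[y.index, y.columns].to_numpy(dtype=float)
    if (W <= 0).any() or not np.isfinite(W).all():
        raise ValueError("weights must be strictly positive and finite")
    ci = list(d.design.columns).index(d.coef)
    Y = y.to_numpy(dtype=float)

    beta = np.empty(len(Y))
    u = np.empty(len(Y))
    s2 = np.empty(len(Y))
    for j in range(len(Y)):
        wj = W[j]
        A = X.T @ (X * wj[:, None])
        b = X.T @ (wj * Y[j])
        cov_u = np.linalg.inv(A)
        bj = cov_u @ b
        r = Y[j] - X @ bj
        beta[j] = bj[ci]
        u[j] = np.sqrt(cov_u[ci, ci])
        s2[j] = float((wj * r**2).sum()) / (n - p)

    idx = y.index
    return FitResult(
        beta=pd.Series(beta, index=idx, name="beta"),
        u=pd.Series(u, index=idx, name="u"),
        s2=pd.Series(s2, index=idx, name="s2"),
        df=pd.Series(float(n - p), index=idx, name="df"),
        weights=w.loc[y.index, y.columns],
        design=d,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


@dataclasses.dataclass
class ModeratedStats:
    """Empirical-Bayes moderated statistics.

    The prior (d0, s0_2) is estimated by the method of moments on
    log residual variances; posterior variances are the precision-weighted
    convex combination (d0*s0_2 + df*s2) / (d0 + df).
    """

    d0: float
    s0_2: float
    s2_post: pd.Series
    t: pd.Series
    p: pd.Series
    fdr: pd.Series
    df_total: pd.Series


def ebayes_moderate(f: FitResult) -> ModeratedStats:
    """Moderated t-statistics with variance shrinkage toward a pooled prior."""
    s2 = f.s2.to_numpy(dtype=float)
    df = f.df.to_numpy(dtype=float)
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise ValueError("degenerate data: fewer than 2 junctions with positive s2")

    z = np.log(s2[ok])
    dfo = df[ok]
    e = z - special.digamma(dfo / 2.0) + np.log(dfo / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(np.mean(special.polygamma(1, dfo / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no excess variability between junctions: infinite prior df, and the
        # pooled variance is the geometric mean of the observed variances, so
        # identical variances shrink to exactly their common value
        d0 = np.inf
        s0_2 = float(np.exp(np.mean(z)))

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.full_like(df, np.inf)
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = d0 + df

    t = f.beta.to_numpy() / (f.u.to_numpy() * np.sqrt(s2_post))
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    idx = f.beta.index
    return ModeratedStats(
        d0=d0,
        s0_2=s0_2,
        s2_post=pd.Series(s2_post, index=idx, name="s2_post"),
        t=pd.Series(t, index=idx, name="t"),
        p=pd.Series(p, index=idx, name="p"),
        fdr=pd.Series(bh_adjust(p), index=idx, name="fdr"),
        df_total=pd.Series(df_total, index=idx, name="df_total"),
    )


def relative_usage(
    f: FitResult, mod: ModeratedStats, gene_map: pd.Series
) -> pd.DataFrame:
    """Within-gene differential usage: each junction vs the others of its gene.

    For junction j in a gene with >= 2 fitted junctions, the relative logFC
    is beta_j minus the precision-weighted (1/u^2) leave-one-out mean of the
    other junctions' coefficients.  Junctions of single-junction genes get
    NaN throughout.
    """
    idx = f.beta.index
    out = pd.DataFrame(
        np.nan, index=idx, columns=["rel_logFC", "rel_t", "rel_p", "rel_fdr"]
    )
    gene_map = gene_map.reindex(idx)
    v = 1.0 / f.u**2
    for gene, members in gene_map.dropna().groupby(gene_map.dropna()).groups.items():
        members = list(members)
        if len(members) < 2:
            continue
        b = f.beta.loc[members].to_numpy()
        vv = v.loc[members].to_numpy()
        vsum = vv.sum()
        vbsum = (vv * b).sum()
        loo_sum = vsum - vv
        m_j = (vbsum - vv * b) / loo_sum
        rel = b - m_j
        se_rel = np.sqrt(f.u.loc[members].to_numpy() ** 2 + 1.0 / loo_sum)
        s2_post = mod.s2_post.loc[members].to_numpy()
        t = rel / (se_rel * np.sqrt(s2_post))
        p = 2.0 * stats.t.sf(np.abs(t), mod.df_total.loc[members].to_numpy())
        out.loc[members, "rel_logFC"] = rel
        out.loc[members, "rel_t"] = t
        out.loc[members, "rel_p"] = p
    out["rel_fdr"] = bh_adjust(out["rel_p"].to_numpy())
    return out


def gene_level_p(rel: pd.DataFrame, gene_map: pd.Series) -> pd.DataFrame:
    """Gene-level differential-usage p by Simes combination, BH across genes."""
    tested = rel["rel_p"].dropna()
    genes = gene_map.reindex(tested.index)
    rows = []
    for gene, pvals in tested.groupby(genes):
        p = np.sort(pvals.to_numpy())
        k = len(p)
        simes = float(np.min(k * p / np.arange(1, k + 1)))
        rows.append((gene, k, min(simes, 1.0)))
    tbl = pd.DataFrame(rows, columns=["gene_id", "n_junctions", "p"]).set_index("gene_id")
    tbl["fdr"] = bh_adjust(tbl["p"].to_numpy())
    return tbl


def classify_junctions(
    tbl: pd.DataFrame,
    lfc_thresh: float = 1.0,
    fdr_thresh: float = 0.05,
    sd_k: float = 2.0,
) -> pd.Series:
    """Assign Group 0-3 from absolute and relative logFC significance.

    D = rel_logFC - abs_logFC; its standard deviation over the doubly
    significant junctions separates Group 1 (|D| inside sd_k standard
    deviations) from Group 3 (outside).  With fewer than 3 doubly
    significant junctions the spread is undefined and all of them are
    assigned Group 1 with a warning.
    """
    abs_sig = (tbl["abs_fdr"] < fdr_thresh) & (tbl["abs_logFC"].abs() > lfc_thresh)
    rel_sig = (
        (tbl["rel_fdr"] < fdr_thresh)
        & (tbl["rel_logFC"].abs() > lfc_thresh)
        & tbl["rel_logFC"].notna()
    )
    abs_sig = abs_sig.fillna(False)
    rel_sig = rel_sig.fillna(False)
    group = pd.Series(0, index=tbl.index, dtype=int, name="group")
    group[abs_sig ^ rel_sig] = 2
    doubly = abs_sig & rel_sig
    if doubly.sum() == 0:
        return group
    D = tbl["rel_logFC"] - tbl["abs_logFC"]
    if doubly.sum() < 3:
        warnings.warn(
            "fewer than 3 doubly significant junctions; divergence spread "
            "undefined, assigning Group 1",
            stacklevel=2,
        )
        group[doubly] = 1
        return group
    sigma = float(D[doubly].std(ddof=0))
    if sigma == 0:
        group[doubly] = 1
        return group
    outside = D.abs() >= sd_k * sigma
    group[doubly & ~outside] = 1
    group[doubly & outside] = 3
    return group


def detect_neojunctions(
    m: JunctionCountMatrix,
    groups: Mapping[str, str] | pd.Series,
    min_frac: float = 0.25,
    test_label: str = "test",
    control_label: str = "control",
) -> pd.Series:
    """Flag junctions absent from every control sample but detected in the
    test condition (in at least ``ceil(min_frac * n_test)`` samples)."""
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    test_samples = [s for s in m.samples if groups.get(s) == test_label]
    control_samples = [s for s in m.samples if groups.get(s) == control_label]
    missing = [s for s in m.samples if s not in groups.index]
    if missing:
        raise ValueError(f"samples without condition label: {missing[:5]}")
    if not test_samples or not control_samples:
        raise ValueError("both test and control conditions need >= 1 sample")
    n_needed = max(1, int(np.ceil(min_frac * len(test_samples))))
    absent_control = (m.counts[control_samples] == 0).all(axis=1)
    present_test = (m.counts[test_samples] > 0).sum(axis=1) >= n_needed
    return (absent_control & present_test).rename("neojunction")


@dataclasses.dataclass
class DJEResult:
    """Full differential-junction-expression output.

    ``table`` has one row per junction (absolute and relative statistics,
    group, flags, per-condition summaries); ``gene_table`` carries the
    Simes-combined gene-level usage p-values.
    """

    table: pd.DataFrame
    gene_table: pd.DataFrame
    d0: float
    s0_2: float


def dje_analyze(
    m: JunctionCountMatrix,
    design: DesignSpec,
    groups: Mapping[str, str] | pd.Series,
    lfc_thresh: float = 1.0,
    fdr_thresh: float = 0.05,
    sd_k: float = 2.0,
    min_frac: float = 0.25,
    test_label: str = "test",
    control_label: str = "control",
) -> DJEResult:
    """Run the complete analysis on an annotated, filtered count matrix.

    Stages: logCPM -> mean-variance weights -> weighted fit -> empirical
    Bayes moderation -> relative usage -> gene-level p -> group
    classification -> neojunction detection -> per-condition summaries.
    Deterministic given its inputs.
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    y = logcpm(m)
    w = mean_variance_weights(y, m, design)
    fit = fit_linear_model(y, design, w)
    mod = ebayes_moderate(fit)
    gene_map = m.meta["gene_id"]
    rel = relative_usage(fit, mod, gene_map)
    gene_tbl = gene_level_p(rel, gene_map)
    neo = detect_neojunctions(
        m, groups, min_frac=min_frac, test_label=test_label, control_label=control_label
    )

    tbl = pd.DataFrame(index=m.counts.index)
    tbl["gene_id"] = gene_map
    tbl["annotated"] = m.meta["annotated"]
    tbl["novel"] = ~m.meta["annotated"]
    tbl["shares_splice_site"] = m.meta["shares_splice_site"]
    tbl["abs_logFC"] = fit.beta
    tbl["abs_t"] = mod.t
    tbl["abs_p"] = mod.p
    tbl["abs_fdr"] = mod.fdr
    tbl[["rel_logFC", "rel_t", "rel_p", "rel_fdr"]] = rel
    tbl["group"] = classify_junctions(tbl, lfc_thresh, fdr_thresh, sd_k)
    tbl["neojunction"] = neo

    for label in (test_label, control_label):
        cols = [s for s in m.samples if groups.get(s) == label]
        sub = m.counts[cols]
        tbl[f"mean_{label}"] = sub.mean(axis=1)
        tbl[f"median_{label}"] = sub.median(axis=1)
        tbl[f"n_expr_{label}"] = (sub > 0).sum(axis=1)
    tbl.index.name = "junction_id"
    return DJEResult(table=tbl, gene_table=gene_tbl, d0=mod.d0, s0_2=mod.s0_2)


def splice_plot_data(
    tbl: pd.DataFrame,
    gene_id: str,
    lfc_thresh: float = 1.0,
    fdr_thresh: float = 0.05,
) -> dict:
    """Per-junction records for a gene-wise splice plot.

    Junctions are ordered by genomic coordinate; each record carries the
    relative logFC, a color class (up/down in red/blue when both the
    magnitude and FDR thresholds are met; suprathreshold-nonsignificant in
    black when only the magnitude is), arc endpoints, and the neojunction
    and novel flags.  The grey significance band spans +/- lfc_thresh.
    """
    rows = tbl[tbl["gene_id"] == gene_id]
    if rows.empty:
        known = sorted({g for g in tbl["gene_id"].dropna().unique()})
        near = difflib.get_close_matches(gene_id, known, n=3)
        raise KeyError(f"gene {gene_id!r} not in table; close matches: {near}")
    records = []
    for jid_str, row in rows.iterrows():
        j = parse_junction_id(jid_str)
        rel = row["rel_logFC"]
        if pd.isna(rel):
            color = "ns"
        elif abs(rel) > lfc_thresh and row["rel_fdr"] < fdr_thresh:
            color = "up" if rel > 0 else "down"
        elif abs(rel) > lfc_thresh:
            color = "suprathreshold-nonsignificant"
        else:
            color = "ns"
        records.append(
            {
                "junction_id": jid_str,
                "start": j.start,
                "end": j.end,
                "rel_logFC": None if pd.isna(rel) else float(rel),
                "rel_fdr": None if pd.isna(row["rel_fdr"]) else float(row["rel_fdr"]),
                "color_class": color,
                "neojunction": bool(row["neojunction"]),
                "novel": bool(row["novel"]),
            }
        )
    records.sort(key=lambda r: (r["start"], r["end"]))
    return {
        "gene_id": gene_id,
        "band": [-lfc_thresh, lfc_thresh],
        "junctions": records,
    }
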