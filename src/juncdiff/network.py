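"""Weighted junction co-expression network analysis.

A soft-thresholded adjacency is built from pairwise junction
correlations, converted to topological overlap (TOM), clustered with
average linkage, and cut into modules summarized by eigengenes (first
principal components) that are correlated against sample traits.  The
optional 2-pass step removes junctions whose trait correlation merely
mirrors that of their host gene, so the rebuilt network reflects
splicing-driven co-expression rather than gene-expression-driven
co-expression.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import pdist, squareform

from .dje import bh_adjust

__all__ = [
    "NetworkConfig",
    "SoftThresholdTable",
    "Eigengenes",
    "TwoPassStats",
    "remove_outlier_samples",
    "good_features",
    "correlation_matrix",
    "pick_soft_threshold",
    "adjacency",
    "tom_similarity",
    "detect_modules",
    "module_eigengenes",
    "module_trait_correlation",
    "two_pass_filter",
    "export_network",
]

# static branch-cut heights indexed by deep_split 0..4 (higher sensitivity
# for cluster splitting cuts lower in the dendrogram)
_DEEP_SPLIT_HEIGHTS = (0.99, 0.97, 0.95, 0.93, 0.91)


@dataclasses.dataclass
class NetworkConfig:
    """Parameters of the network construction.

    Defaults follow common co-expression practice: unsigned network,
    biweight midcorrelation, candidate soft powers 1..20 with a
    scale-free fit target of 0.8, minimum module size 20, medium
    branch-splitting sensitivity (deep_split 2) and eigengene merge cut
    height 0.25.  At least 15 samples per condition are recommended.
    """

    method: str = "bicor"
    network_type: str = "unsigned"
    powers: tuple[int, ...] = tuple(range(1, 21))
    scale_free_target: float = 0.8
    min_module_size: int = 20
    deep_split: int = 2
    merge_cut_height: float = 0.25
    min_samples: int = 15
    # powers whose mean connectivity falls below this are excluded from
    # selection: a near-empty network's connectivity tail fits a power law
    # spuriously, so the fit index is only meaningful while the network
    # retains non-trivial connectivity
    min_mean_connectivity: float = 1.0

    def __post_init__(self) -> None:
        if self.network_type not in ("unsigned", "signed"):
            raise ValueError("network_type must be 'unsigned' or 'signed'")
        if any(p < 1 for p in self.powers):
            raise ValueError("powers must be positive integers")
        if not 0 < self.scale_free_target <= 1:
            raise ValueError("scale_free_target must be in (0, 1]")
        if self.deep_split not in range(5):
            raise ValueError("deep_split must be in 0..4")


def remove_outlier_samples(
    expr: pd.DataFrame, cut_height: float | None = None, min_samples: int = 15
) -> list[str]:
    """Samples surviving average-linkage outlier pruning.

    Samples are clustered on Euclidean distance between their expression
    profiles; the tree is cut at ``cut_height`` (default: mean + 2.5 SD of
    the merge heights) and only the largest cluster is kept.
    """
    samples = list(expr.columns)
    if len(samples) < min_samples:
        raise ValueError(f"need >= {min_samples} samples, got {len(samples)}")
    D = pdist(expr.to_numpy(dtype=float).T, metric="euclidean")
    if np.allclose(D, 0):
        return samples
    Z = average(D)
    heights = Z[:, 2]
    if cut_height is None:
        cut_height = float(heights.mean() + 2.5 * heights.std(ddof=0))
    labels = fcluster(Z, t=cut_height, criterion="distance")
    largest = np.bincount(labels).argmax()
    kept = [s for s, lab in zip(samples, labels) if lab == largest]
    if len(kept) < min_samples:
        warnings.warn(
            f"only {len(kept)} samples remain after outlier removal", stacklevel=2
        )
    return kept


def good_features(
    expr: pd.DataFrame, max_missing_frac: float = 0.5, min_variance: float = 0.0
) -> list[str]:
    """Junctions with acceptable missingness and non-zero variance."""
    missing = expr.isna().mean(axis=1)
    var = expr.var(axis=1, ddof=0)
    keep = (missing <= max_missing_frac) & (var > min_variance) & var.notna()
    return list(expr.index[keep])


def _bicor_matrix(X: np.ndarray) -> np.ndarray:
    med = np.median(X, axis=1, keepdims=True)
    mad = np.median(np.abs(X - med), axis=1, keepdims=True)
    T = np.empty_like(X)
    for i in range(X.shape[0]):
        if mad[i, 0] == 0:
            # zero MAD: fall back to Pearson-style centering for this row
            T[i] = X[i] - X[i].mean()
        else:
            u = (X[i] - med[i, 0]) / (9.0 * mad[i, 0])
            a = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
            T[i] = (X[i] - med[i, 0]) * a
    norms = np.sqrt((T**2).sum(axis=1))
    norms[norms == 0] = np.nan
    C = (T @ T.T) / np.outer(norms, norms)
    return np.clip(C, -1.0, 1.0)


def correlation_matrix(expr: pd.DataFrame, method: str = "bicor") -> np.ndarray:
    """Junction x junction correlation matrix (pearson/spearman/bicor)."""
    X = expr.to_numpy(dtype=float)
    if method == "pearson":
        C = np.corrcoef(X)
    elif method == "spearman":
        ranks = np.apply_along_axis(stats.rankdata, 1, X)
        C = np.corrcoef(ranks)
    elif method == "bicor":
        C = _bicor_matrix(X)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return np.clip(C, -1.0, 1.0)


def adjacency(
    expr: pd.DataFrame, power: float, network_type: str = "unsigned",
    method: str = "bicor",
) -> np.ndarray:
    """Soft-thresholded adjacency: |cor|^power (unsigned) or
    ((1 + cor)/2)^power (signed), with unit diagonal."""
    if power < 1:
        raise ValueError("power must be >= 1")
    C = correlation_matrix(expr, method)
    return _adjacency_from_cor(C, power, network_type)


def _adjacency_from_cor(C: np.ndarray, power: float, network_type: str) -> np.ndarray:
    if network_type == "unsigned":
        A = np.abs(C) ** power
    elif network_type == "signed":
        A = ((1.0 + C) / 2.0) ** power
    else:
        raise ValueError(f"unknown network type {network_type!r}")
    np.fill_diagonal(A, 1.0)
    return A


@dataclasses.dataclass
class SoftThresholdTable:
    """Scale-free topology diagnostics per candidate power."""

    table: pd.DataFrame  # power, fit_index, mean_k, median_k, max_k
    chosen_power: int
    target_reached: bool


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free fit index from binned connectivities.

    Connectivities are split into equal-width bins; log10 of the per-bin
    frequency p(k) is regressed on log10 of the per-bin mean connectivity.
    Returns R^2 with the sign flipped when the slope is positive
    (scale-free topology implies a decreasing frequency in k, so a good
    fit scores near +1).
    """
    k = np.asarray(k, dtype=float)
    if np.ptp(k) == 0:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        mk = k[mask].mean()
        pk = mask.mean()
        if mk > 0 and pk > 0:
            xs.append(np.log10(mk))
            ys.append(np.log10(pk))
    if len(set(np.round(xs, 12))) < 3 or len(set(np.round(ys, 12))) < 2:
        return 0.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    if not np.isfinite(slope) or not np.isfinite(r):
        return 0.0
    return float(-np.sign(slope) * r**2)


def pick_soft_threshold(expr: pd.DataFrame, cfg: NetworkConfig) -> SoftThresholdTable:
    """Evaluate candidate powers and pick the smallest reaching the
    scale-free target (or the best-fitting one, flagged, if none does)."""
    var = expr.var(axis=1, ddof=0)
    if (var == 0).any():
        raise ValueError(
            "zero-variance junctions present; filter with good_features first"
        )
    if expr.shape[0] < 50:
        warnings.warn(
            f"only {expr.shape[0]} junctions; soft-threshold diagnostics are "
            "unreliable below ~50",
            stacklevel=2,
        )
    C = correlation_matrix(expr, cfg.method)
    rows = []
    for beta in cfg.powers:
        A = _adjacency_from_cor(C, beta, cfg.network_type)
        k = A.sum(axis=1) - 1.0
        rows.append(
            (beta, _scale_free_fit(k), float(k.mean()), float(np.median(k)), float(k.max()))
        )
    tbl = pd.DataFrame(rows, columns=["power", "fit_index", "mean_k", "median_k", "max_k"])
    eligible = tbl[tbl["mean_k"] >= cfg.min_mean_connectivity]
    if eligible.empty:
        eligible = tbl
    reached = eligible[eligible["fit_index"] >= cfg.scale_free_target]
    if len(reached):
        chosen = int(reached["power"].iloc[0])
        ok = True
    else:
        chosen = int(eligible.loc[eligible["fit_index"].idxmax(), "power"])
        ok = False
        warnings.warn(
            f"no power reaches fit index {cfg.scale_free_target}; using "
            f"best-fitting power {chosen}",
            stacklevel=2,
        )
    return SoftThresholdTable(table=tbl, chosen_power=chosen, target_reached=ok)


def tom_similarity(a: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an adjacency with unit diagonal.

    TOM_ij = (sum_u a_iu * a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j (the sum excludes u in {i, j}); TOM_ii = 1.
    """
    a = np.asarray(a, dtype=float)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    k = a.sum(axis=1) - np.diag(a)
    # (a @ a)_ij includes u = i and u = j; subtract their diagonal-weighted terms
    shared = a @ a
    diag = np.diag(a)
    inner = shared - diag[:, None] * a - a * diag[None, :]
    numer = inner + a
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = numer / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(
    dissim: np.ndarray,
    cfg: NetworkConfig,
    expr: pd.DataFrame | None = None,
) -> pd.Series:
    """Cluster junctions and assign module labels (0 = unassigned).

    Average-linkage clustering on the dissimilarity; branches are
    extracted by a static cut at a deep_split-indexed height, clusters
    below ``min_module_size`` are dropped to label 0, and modules whose
    eigengenes correlate above 1 - merge_cut_height are merged (requires
    ``expr``).  Final labels are 1.. by decreasing module size.
    """
    n = dissim.shape[0]
    index = expr.index if expr is not None else pd.RangeIndex(n)
    if n < cfg.min_module_size:
        warnings.warn("fewer junctions than min_module_size; all unassigned", stacklevel=2)
        return pd.Series(0, index=index, name="module")
    height = _DEEP_SPLIT_HEIGHTS[cfg.deep_split]
    D = squareform(np.clip(dissim, 0, None), checks=False)
    Z = average(D)
    raw = fcluster(Z, t=height, criterion="distance")
    labels = pd.Series(raw, index=index)
    sizes = labels.value_counts()
    small = sizes[sizes < cfg.min_module_size].index
    labels[labels.isin(small)] = 0

    if expr is not None:
        labels = _merge_close_modules(labels, expr, cfg.merge_cut_height)

    # relabel contiguously by decreasing size
    sizes = labels[labels != 0].value_counts()
    mapping = {old: i + 1 for i, old in enumerate(sizes.index)}
    return labels.map(lambda x: mapping.get(x, 0)).rename("module")


def _merge_close_modules(
    labels: pd.Series, expr: pd.DataFrame, merge_cut_height: float
) -> pd.Series:
    labels = labels.copy()
    while True:
        mods = sorted(set(labels) - {0})
        if len(mods) < 2:
            return labels
        eig = module_eigengenes(expr, labels)
        ME = eig.eigengenes[[f"ME{m}" for m in mods]].to_numpy()
        C = np.corrcoef(ME.T)
        np.fill_diagonal(C, -np.inf)
        i, j = np.unravel_index(np.argmax(C), C.shape)
        if C[i, j] < 1.0 - merge_cut_height:
            return labels
        labels[labels == mods[j]] = mods[i]


@dataclasses.dataclass
class Eigengenes:
    """Module summary profiles.

    ``eigengenes``: samples x modules (columns ME<label>), each the first
    principal component of the standardized member expression, unit norm,
    sign-oriented to correlate positively with the mean member profile.
    ``var_explained``: fraction of member variance captured.
    ``membership``: per-junction correlation with its own module's
    eigengene.
    """

    eigengenes: pd.DataFrame
    var_explained: pd.Series
    membership: pd.Series


def module_eigengenes(expr: pd.DataFrame, modules: pd.Series) -> Eigengenes:
    """First-principal-component summary of each module."""
    modules = modules.reindex(expr.index)
    samples = expr.columns
    me_cols = {}
    varexp = {}
    mm = pd.Series(np.nan, index=expr.index, name="module_membership")
    for mod in sorted(set(modules) - {0}):
        members = expr.index[modules == mod]
        X = expr.loc[members].to_numpy(dtype=float)
        sd = X.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        Z = (X - X.mean(axis=1, keepdims=True)) / sd
        U, S, Vt = np.linalg.svd(Z, full_matrices=False)
        me = Vt[0]
        mean_profile = Z.mean(axis=0)
        if len(members) > 1:
            if np.corrcoef(me, mean_profile)[0, 1] < 0:
                me = -me
        else:
            me = Z[0] / np.linalg.norm(Z[0])
        varexp[mod] = float(S[0] ** 2 / (S**2).sum())
        me_cols[f"ME{mod}"] = me
        for jid in members:
            mm[jid] = float(np.corrcoef(expr.loc[jid].to_numpy(dtype=float), me)[0, 1])
    eig = pd.DataFrame(me_cols, index=samples)
    return Eigengenes(
        eigengenes=eig,
        var_explained=pd.Series(varexp, name="var_explained", dtype=float),
        membership=mm,
    )


def module_trait_correlation(
    eg: Eigengenes, traits: pd.DataFrame, method: str = "pearson"
) -> pd.DataFrame:
    """Correlation of each module eigengene with each numeric trait.

    Summarizing modules by eigengenes keeps the multiple-testing burden at
    (modules x traits) instead of (junctions x traits).  BH FDR across the
    whole matrix.
    """
    from .traits import _corr_p, _pair_corr

    rows = []
    for me in eg.eigengenes.columns:
        x = eg.eigengenes[me].to_numpy(dtype=float)
        for trait in traits.columns:
            tv = traits[trait].reindex(eg.eigengenes.index).to_numpy(dtype=float)
            r, n = _pair_corr(x, tv, method)
            rows.append((me, trait, r, _corr_p(r, n), n))
    out = pd.DataFrame(rows, columns=["module", "trait", "cor", "p", "n_used"])
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out


@dataclasses.dataclass
class TwoPassStats:
    """Gene-expression subtraction diagnostics for the 2-pass network.

    GS_junction/GS_gene are absolute trait correlations; junctions whose
    standardized residual from the GS_junction ~ GS_gene regression is at
    least 2 in magnitude carry trait signal not explained by their host
    gene and are kept for network re-construction.
    """

    table: pd.DataFrame  # GS_junction, GS_gene, residual_z, kept
    slope: float
    intercept: float

    @property
    def kept(self) -> list[str]:
        return list(self.table.index[self.table["kept"]])


def two_pass_filter(
    junc_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    host_gene: pd.Series,
    trait: pd.Series,
    z_thresh: float = 2.0,
) -> TwoPassStats:
    """Drop junctions whose trait correlation is gene-expression-driven."""
    host_gene = host_gene.reindex(junc_expr.index)
    missing = host_gene[host_gene.isna() | ~host_gene.isin(gene_expr.index)]
    if len(missing):
        raise ValueError(
            f"junctions without host-gene expression: {list(missing.index[:5])}"
        )
    tv = trait.reindex(junc_expr.columns).to_numpy(dtype=float)
    gs_j = np.array(
        [
            abs(_safe_pearson(junc_expr.loc[j].to_numpy(dtype=float), tv))
            for j in junc_expr.index
        ]
    )
    gene_gs = {
        g: abs(_safe_pearson(gene_expr.loc[g].to_numpy(dtype=float), tv))
        for g in host_gene.unique()
    }
    gs_g = host_gene.map(gene_gs).to_numpy(dtype=float)

    X = np.column_stack([np.ones(len(gs_g)), gs_g])
    coef, *_ = np.linalg.lstsq(X, gs_j, rcond=None)
    resid = gs_j - X @ coef
    sd = float(resid.std(ddof=0))
    if sd == 0:
        raise ValueError(
            "degenerate two-pass distribution; all junction-trait signal is gene-driven"
        )
    z = resid / sd
    tbl = pd.DataFrame(
        {
            "GS_junction": gs_j,
            "GS_gene": gs_g,
            "residual_z": z,
            "kept": np.abs(z) >= z_thresh,
        },
        index=junc_expr.index,
    )
    return TwoPassStats(table=tbl, slope=float(coef[1]), intercept=float(coef[0]))


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        return 0.0
    return float(np.corrcoef(x[ok], y[ok])[0, 1])


def export_network(
    weights: np.ndarray,
    junction_ids: list[str],
    modules: pd.Series,
    out_dir: str | Path,
    weight_min: float = 0.1,
    gene_map: pd.Series | None = None,
) -> dict[str, Path]:
    """Write Cytoscape and VisANT edge lists plus a node attribute file.

    Undirected edges with weight >= weight_min are emitted once, with
    source < target lexicographically; no self loops.
    """
    if not 0 <= weight_min <= 1:
        raise ValueError("weight_min must be in [0, 1]")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mods = modules.reindex(junction_ids).fillna(0).astype(int)
    edges = []
    n = len(junction_ids)
    for i in range(n):
        for j in range(i + 1, n):
            w = float(weights[i, j])
            if w >= weight_min:
                a, b = sorted((junction_ids[i], junction_ids[j]))
                edges.append((a, b, w, int(mods[a]), int(mods[b])))
    edges.sort()
    cyto = out_dir / "edges_cytoscape.tsv"
    with open(cyto, "w") as fh:
        fh.write("source\ttarget\tweight\tsource_module\ttarget_module\n")
        for a, b, w, ma, mb in edges:
            fh.write(f"{a}\t{b}\t{w:.6g}\t{ma}\t{mb}\n")
    visant = out_dir / "edges_visant.tsv"
    with open(visant, "w") as fh:
        for a, b, w, _, _ in edges:
            fh.write(f"{a}\t{b}\t0\t{w:.6g}\n")
    nodes = out_dir / "nodes.tsv"
    with open(nodes, "w") as fh:
        fh.write("junction_id\tgene_id\tmodule\n")
        for jid in junction_ids:
            gene = "" if gene_map is None else (gene_map.get(jid) or "")
            fh.write(f"{jid}\t{gene}\t{int(mods[jid])}\n")
    return {"cytoscape": cyto, "visant": visant, "nodes": nodes}
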