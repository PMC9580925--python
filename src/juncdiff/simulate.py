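"""Synthetic junction-count datasets with known ground truth.

Counts follow a negative-binomial model: each gene has a baseline
expression (log-normal, in counts per million), its junctions split that
expression according to Dirichlet usage proportions, and per-sample
counts are drawn with mean libsize * gene_cpm * usage / 1e6 and a
common dispersion.  Spiked events construct each differential-usage
class exactly:

* usage shift — one junction's usage changes between conditions at
  constant gene output (absolute and relative logFC nearly coincide:
  Group 1 semantics);
* gene DE — all junctions of a gene scale together (Group 2);
* combined — a usage shift stacked on a gene-expression change of a
  different magnitude (divergent absolute vs relative logFC: Group 3);
* neojunction — an exon-skipping junction expressed only in the test
  condition.

Traits are generated as noisy linear readouts of a target junction's (or
gene's) standardized expression, so the true junction-trait linkages are
known.  A fixed seed fully determines every output.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import JunctionCountMatrix, JunctionID, write_star_sj

__all__ = [
    "SimConfig",
    "SimResult",
    "UsageShift",
    "GeneDE",
    "Combined",
    "Neojunction",
    "TraitSpec",
    "simulate_junction_counts",
    "simulate_traits",
    "simulate_star_files",
    "write_gtf",
    "null_config",
    "spiked_config",
]


@dataclasses.dataclass(frozen=True)
class UsageShift:
    """One junction's usage shifts between conditions at constant gene total."""

    gene: int
    rel_lfc: float
    base_usage: float = 0.06


@dataclasses.dataclass(frozen=True)
class GeneDE:
    """All junctions of a gene change expression together."""

    gene: int
    lfc: float


@dataclasses.dataclass(frozen=True)
class Combined:
    """Usage shift plus a gene-expression change of different magnitude.

    The gene's baseline is pinned to ``base_cpm`` (low, but measurable) so
    that a large expression spike stays a negligible fraction of the
    library and CPM normalization remains stable.
    """

    gene: int
    rel_lfc: float
    gene_lfc: float
    base_usage: float = 0.06
    base_cpm: float = 10.0


@dataclasses.dataclass(frozen=True)
class Neojunction:
    """Exon-skipping junction present only in the test condition."""

    gene: int
    usage: float = 0.12


@dataclasses.dataclass(frozen=True)
class TraitSpec:
    """A trait generated from a target feature's standardized expression.

    target is "gene:<index>" (host-gene aggregate), "junction:<gene>:<j>"
    (the j-th junction of a gene) or "none" (pure noise).  With effect e
    and noise SD s the theoretical correlation is e / sqrt(e^2 + s^2).
    ``n_levels`` > 0 discretizes the latent trait into equal-frequency
    categories.
    """

    name: str
    target: str = "none"
    effect: float = 1.0
    noise_sd: float = 1.0
    n_levels: int = 0


@dataclasses.dataclass
class SimConfig:
    """Study conditions for the synthetic cohort (defaults in methods note)."""

    n_genes: int = 300
    junctions_per_gene: tuple[int, int] = (3, 8)
    n_test: int = 15
    n_control: int = 15
    gene_cpm_meanlog: float = float(np.log(80.0))
    gene_cpm_sdlog: float = 1.0
    dirichlet_conc: float = 10.0
    nb_dispersion: float = 0.05
    # per-(gene, sample) biological expression variability (log2 SD); zero
    # isolates pure condition effects, positive values give genes genuine
    # sample-to-sample co-variation (needed for correlation-based analyses)
    gene_sample_sd_log2: float = 0.0
    libsize_range: tuple[float, float] = (4e6, 6e6)
    spike_floor_cpm: float = 60.0
    # spiked genes get >= this many junctions so the leave-one-out average
    # of the other junctions is stable against any single coefficient
    spike_min_junctions: int = 6
    usage_shifts: tuple[UsageShift, ...] = ()
    gene_de: tuple[GeneDE, ...] = ()
    combined: tuple[Combined, ...] = ()
    neojunctions: tuple[Neojunction, ...] = ()
    background_de: tuple[GeneDE, ...] = ()  # transcriptome DE, not truth events
    traits: tuple[TraitSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.junctions_per_gene
        if not (2 <= lo <= hi):
            raise ValueError("junctions_per_gene must satisfy 2 <= lo <= hi")
        spiked = [e.gene for e in self.all_events()] + [
            e.gene for e in self.background_de
        ]
        bad = [g for g in spiked if not 0 <= g < self.n_genes]
        if bad:
            raise ValueError(f"spiked genes out of range: {bad}")
        if len(set(spiked)) != len(spiked):
            raise ValueError("each gene may carry at most one spiked event")
        for ev in list(self.usage_shifts) + list(self.combined):
            u, f = ev.base_usage, _usage_factor(ev.rel_lfc, ev.base_usage)
            if not (0 < u < 1 and 0 < f * u < 1):
                raise ValueError(
                    f"infeasible usage shift for gene {ev.gene}: proportion leaves (0,1)"
                )
        for ev in self.neojunctions:
            if not 0 < ev.usage < 1:
                raise ValueError(f"neojunction usage must be in (0,1), got {ev.usage}")

    def all_events(self):
        return (
            list(self.usage_shifts)
            + list(self.gene_de)
            + list(self.combined)
            + list(self.neojunctions)
        )


def _usage_factor(rel_lfc: float, u: float) -> float:
    """Usage multiplier f with log2(f / c) = rel_lfc, where c rescales the
    remaining junctions so the gene total stays constant."""
    r = 2.0**rel_lfc
    return r / (1.0 - u + r * u)


@dataclasses.dataclass
class SimResult:
    """A simulated cohort with its ground truth.

    ``matrix`` has meta filled by construction; ``truth`` lists one row
    per spiked event with the generating effect sizes.
    """

    matrix: JunctionCountMatrix
    gene_map: pd.Series
    truth: pd.DataFrame
    groups: pd.Series
    config: SimConfig
    exons: dict[str, list[tuple[int, int]]]

    @property
    def junction_ids_of(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for jid, gene in self.gene_map.items():
            out.setdefault(gene, []).append(jid)
        return out


_GENE_STRIDE = 100_000
_EXON_LEN = 400
_EXON_STRIDE = 1_000


def _gene_structure(g: int, n_junc: int) -> tuple[str, list[tuple[int, int]], list[JunctionID]]:
    """Gene g on chr1: n_junc + 1 exons of 400 bp spaced 1 kb apart."""
    gene_id = f"G{g:04d}"
    gs = 1 + g * _GENE_STRIDE
    exons = [
        (gs + i * _EXON_STRIDE, gs + i * _EXON_STRIDE + _EXON_LEN - 1)
        for i in range(n_junc + 1)
    ]
    introns = [
        JunctionID("chr1", exons[j][1] + 1, exons[j + 1][0] - 1, 1)
        for j in range(n_junc)
    ]
    return gene_id, exons, introns


def simulate_junction_counts(cfg: SimConfig) -> SimResult:
    """Generate the count matrix, gene map and truth table for a config."""
    rng = np.random.default_rng(cfg.seed)
    n_samples = cfg.n_test + cfg.n_control
    sample_ids = [f"test_{i+1:02d}" for i in range(cfg.n_test)] + [
        f"control_{i+1:02d}" for i in range(cfg.n_control)
    ]
    groups = pd.Series(
        ["test"] * cfg.n_test + ["control"] * cfg.n_control, index=sample_ids
    )
    is_test = np.array([g == "test" for g in groups])

    event_by_gene = {e.gene: e for e in cfg.all_events()}
    background_by_gene = {e.gene: e for e in cfg.background_de}

    lo, hi = cfg.junctions_per_gene
    n_junc = rng.integers(lo, hi + 1, size=cfg.n_genes)
    for g in event_by_gene:
        n_junc[g] = max(n_junc[g], min(cfg.spike_min_junctions, hi))
    base_cpm = rng.lognormal(cfg.gene_cpm_meanlog, cfg.gene_cpm_sdlog, size=cfg.n_genes)
    libsizes = rng.uniform(*cfg.libsize_range, size=n_samples)
    if cfg.gene_sample_sd_log2 > 0:
        gene_factor = 2.0 ** rng.normal(
            0.0, cfg.gene_sample_sd_log2, size=(cfg.n_genes, n_samples)
        )
    else:
        gene_factor = np.ones((cfg.n_genes, n_samples))

    jid_strs: list[str] = []
    gene_of: list[str] = []
    annotated: list[bool] = []
    shares: list[bool] = []
    mu_rows: list[np.ndarray] = []
    truth_rows: list[dict] = []
    exon_map: dict[str, list[tuple[int, int]]] = {}

    for g in range(cfg.n_genes):
        J = int(n_junc[g])
        gene_id, exons, introns = _gene_structure(g, J)
        exon_map[gene_id] = exons
        ev = event_by_gene.get(g)
        cpm = base_cpm[g]
        if isinstance(ev, Combined):
            cpm = ev.base_cpm
        elif ev is not None:
            cpm = max(cpm, cfg.spike_floor_cpm)

        usage_ctrl = rng.dirichlet(np.full(J, cfg.dirichlet_conc))
        usage_test = usage_ctrl.copy()
        gene_lfc = 0.0
        if g in background_by_gene:
            gene_lfc = background_by_gene[g].lfc
        ids = [str(j) for j in introns]
        ann_flags = [True] * J
        share_flags = [False] * J

        if isinstance(ev, (UsageShift, Combined)):
            t = J // 2
            # fix the target's control usage so abs and rel logFC nearly coincide
            usage_ctrl = usage_ctrl * (1.0 - ev.base_usage) / (1.0 - usage_ctrl[t])
            usage_ctrl[t] = ev.base_usage
            f = _usage_factor(ev.rel_lfc, ev.base_usage)
            u_new = f * ev.base_usage
            c = (1.0 - u_new) / (1.0 - ev.base_usage)
            usage_test = usage_ctrl * c
            usage_test[t] = u_new
            if isinstance(ev, Combined):
                gene_lfc = ev.gene_lfc
                klass = "group3"
            else:
                klass = "group1"
            truth_rows.append(
                {
                    "event_id": f"{klass}_{gene_id}",
                    "class": klass,
                    "gene_id": gene_id,
                    "junction_id": ids[t],
                    "true_rel_lfc": ev.rel_lfc,
                    "true_abs_lfc": float(np.log2(f)) + gene_lfc,
                }
            )
        elif isinstance(ev, GeneDE):
            gene_lfc = ev.lfc
            truth_rows.append(
                {
                    "event_id": f"group2_{gene_id}",
                    "class": "group2",
                    "gene_id": gene_id,
                    "junction_id": ids[0],
                    "true_rel_lfc": 0.0,
                    "true_abs_lfc": ev.lfc,
                }
            )
        elif isinstance(ev, Neojunction):
            # exon-skipping junction over exon 1, absent from controls
            neo = JunctionID("chr1", exons[0][1] + 1, exons[2][0] - 1, 1)
            ids.append(str(neo))
            ann_flags.append(False)
            share_flags.append(True)
            usage_ctrl = np.append(usage_ctrl, 0.0)
            usage_test = np.append(usage_test * (1.0 - ev.usage), ev.usage)
            truth_rows.append(
                {
                    "event_id": f"neojunction_{gene_id}",
                    "class": "neojunction",
                    "gene_id": gene_id,
                    "junction_id": str(neo),
                    "true_rel_lfc": np.nan,
                    "true_abs_lfc": np.nan,
                }
            )

        cpm_test = cpm * 2.0**gene_lfc
        for j, jid in enumerate(ids):
            mu = (
                np.where(is_test, cpm_test * usage_test[j], cpm * usage_ctrl[j])
                * gene_factor[g]
                * libsizes
                / 1e6
            )
            mu_rows.append(mu)
            jid_strs.append(jid)
            gene_of.append(gene_id)
            annotated.append(ann_flags[j])
            shares.append(share_flags[j])

    mu = np.vstack(mu_rows)
    r = 1.0 / cfg.nb_dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)

    counts_df = pd.DataFrame(counts, index=jid_strs, columns=sample_ids, dtype="int64")
    meta = pd.DataFrame(
        {
            "gene_id": pd.Series(gene_of, index=jid_strs, dtype=object),
            "annotated": pd.Series(annotated, index=jid_strs, dtype=bool),
            "shares_splice_site": pd.Series(shares, index=jid_strs, dtype=bool),
        }
    )
    matrix = JunctionCountMatrix(counts_df, meta)
    truth = pd.DataFrame(
        truth_rows,
        columns=["event_id", "class", "gene_id", "junction_id", "true_rel_lfc", "true_abs_lfc"],
    )
    return SimResult(
        matrix=matrix,
        gene_map=meta["gene_id"],
        truth=truth,
        groups=groups,
        config=cfg,
        exons=exon_map,
    )


def simulate_traits(
    expr: pd.DataFrame,
    sim: SimResult,
    specs: Sequence[TraitSpec] | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate traits from target expression plus Gaussian noise.

    ``expr`` is a features x samples matrix (junction or gene level) whose
    index must contain each spec's resolved target.  Returns (trait table
    samples x traits, truth table with theoretical correlations).
    """
    specs = list(specs) if specs is not None else list(sim.config.traits)
    rng = np.random.default_rng(sim.config.seed + 7919 if seed is None else seed)
    samples = list(expr.columns)
    cols = {}
    rows = []
    for spec in specs:
        target_id = _resolve_target(spec.target, sim)
        if target_id == "none":
            latent = rng.normal(0.0, 1.0, size=len(samples))
            rho = 0.0
        else:
            if target_id not in expr.index:
                raise KeyError(f"trait target {target_id!r} not in expression matrix")
            x = expr.loc[target_id].to_numpy(dtype=float)
            z = (x - x.mean()) / (x.std(ddof=0) or 1.0)
            latent = spec.effect * z + rng.normal(0.0, spec.noise_sd, size=len(samples))
            rho = spec.effect / np.hypot(spec.effect, spec.noise_sd)
        if spec.n_levels > 0:
            qs = np.quantile(latent, np.linspace(0, 1, spec.n_levels + 1)[1:-1])
            cols[spec.name] = pd.Series(
                np.searchsorted(qs, latent).astype(str), index=samples
            ).map(lambda k: f"level{k}")
        else:
            cols[spec.name] = pd.Series(latent, index=samples)
        rows.append(
            {
                "trait": spec.name,
                "target": target_id,
                "effect": spec.effect,
                "noise_sd": spec.noise_sd,
                "theoretical_rho": rho,
            }
        )
    return pd.DataFrame(cols, index=samples), pd.DataFrame(rows)


def _resolve_target(target: str, sim: SimResult) -> str:
    if target == "none":
        return "none"
    parts = target.split(":")
    if parts[0] == "gene" and len(parts) == 2:
        return f"G{int(parts[1]):04d}"
    if parts[0] == "junction" and len(parts) == 3:
        gene_id = f"G{int(parts[1]):04d}"
        members = [j for j, g in sim.gene_map.items() if g == gene_id]
        return members[int(parts[2])]
    return target  # already a feature id


def simulate_star_files(
    m: JunctionCountMatrix, out_dir: str | Path
) -> pd.DataFrame:
    """Write one ``SJ.out.tab`` per sample (zero-count junctions omitted,
    rows in coordinate order).  Returns a manifest of (path, sample_id)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    junctions = m.junctions
    order = sorted(range(len(junctions)), key=lambda i: junctions[i])
    rows = []
    for sid in m.samples:
        col = m.counts[sid]
        pairs = [
            (junctions[i], int(col.iloc[i])) for i in order if col.iloc[i] > 0
        ]
        path = out_dir / f"{sid}.SJ.out.tab"
        write_star_sj(pairs, path)
        rows.append({"path": str(path), "sample_id": sid})
    return pd.DataFrame(rows)


def write_gtf(sim: SimResult, path: str | Path) -> None:
    """Write a GTF matching the simulated gene structures (one transcript
    per gene, exon features only)."""
    with open(path, "w") as fh:
        for gene_id, exons in sim.exons.items():
            tx = f"{gene_id}.t1"
            for k, (start, end) in enumerate(exons, start=1):
                attrs = (
                    f'gene_id "{gene_id}"; transcript_id "{tx}"; exon_number "{k}";'
                )
                fh.write(
                    f"chr1\tsim\texon\t{start}\t{end}\t.\t+\t.\t{attrs}\n"
                )


@dataclasses.dataclass
class TwoPassScenario:
    """A single-condition cohort with one gene-driven and one
    splicing-driven trait linkage, for exercising the 2-pass filter.

    The latent trait multiplies the driver gene's expression
    (gene-driven linkage: every junction of that gene inherits the trait
    correlation through gene expression) and shifts the logit usage of
    one junction in a second gene at constant gene output
    (splicing-driven linkage: the junction correlates with the trait but
    its host gene does not).
    """

    junc_logcpm: pd.DataFrame
    gene_logcpm: pd.DataFrame
    gene_map: pd.Series
    trait: pd.Series
    gene_driven_gene: str
    splicing_junction: str
    matrix: JunctionCountMatrix


def simulate_two_pass(
    seed: int = 0,
    n_genes: int = 80,
    n_samples: int = 40,
    gene_slope_log2: float = 0.8,
    usage_slope_logit: float = 1.2,
    gene_sample_sd_log2: float = 0.5,
    bg_trait_slope_sd: float = 0.3,
    driver_cpm: float = 400.0,
    nb_dispersion: float = 0.05,
) -> TwoPassScenario:
    """Generate the 2-pass study cohort (one condition, known linkages).

    Background genes carry small random trait slopes (SD
    ``bg_trait_slope_sd`` on the log2 scale): real traits correlate with
    many genes at varying strength, which also anchors the junction-vs-
    gene significance regression across its whole range.
    """
    rng = np.random.default_rng(seed)
    trait = rng.normal(0.0, 1.0, size=n_samples)
    libsizes = rng.uniform(4e6, 6e6, size=n_samples)
    base_cpm = rng.lognormal(np.log(80.0), 1.0, size=n_genes)
    base_cpm[0] = driver_cpm  # gene-driven gene
    base_cpm[1] = driver_cpm  # host of the splicing-driven junction
    sample_ids = [f"s{i+1:02d}" for i in range(n_samples)]

    jid_strs: list[str] = []
    gene_of: list[str] = []
    mu_rows: list[np.ndarray] = []
    driver_gene = splice_gene = splice_jid = None
    for g in range(n_genes):
        J = int(rng.integers(6, 9)) if g < 2 else int(rng.integers(3, 9))
        gene_id, _, introns = _gene_structure(g, J)
        usage = rng.dirichlet(np.full(J, 10.0))
        factor = 2.0 ** rng.normal(0.0, gene_sample_sd_log2, size=n_samples)
        cpm_s = base_cpm[g] * factor
        usage_s = np.tile(usage[:, None], (1, n_samples))
        if g == 0:
            driver_gene = gene_id
            cpm_s = cpm_s * 2.0 ** (gene_slope_log2 * trait)
        elif g >= 2:
            cpm_s = cpm_s * 2.0 ** (rng.normal(0.0, bg_trait_slope_sd) * trait)
        elif g == 1:
            splice_gene = gene_id
            t_j = J // 2
            u0 = 0.15
            usage = usage * (1.0 - u0) / (1.0 - usage[t_j])
            usage[t_j] = u0
            logit = np.log(u0 / (1.0 - u0)) + usage_slope_logit * trait
            u_t = 1.0 / (1.0 + np.exp(-logit))
            usage_s = np.tile(usage[:, None], (1, n_samples))
            scale = (1.0 - u_t) / (1.0 - u0)
            usage_s = usage_s * scale[None, :]
            usage_s[t_j] = u_t
            splice_jid = str(introns[t_j])
        for j, jid in enumerate(introns):
            mu_rows.append(cpm_s * usage_s[j] * libsizes / 1e6)
            jid_strs.append(str(jid))
            gene_of.append(gene_id)

    mu = np.vstack(mu_rows)
    r = 1.0 / nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    counts_df = pd.DataFrame(counts, index=jid_strs, columns=sample_ids, dtype="int64")
    meta = JunctionCountMatrix.empty_meta(counts_df.index)
    meta["gene_id"] = gene_of
    meta["annotated"] = True
    matrix = JunctionCountMatrix(counts_df, meta)

    keep = counts_df.mean(axis=1) >= 5
    counts_kept = counts_df[keep]
    gene_map = pd.Series(gene_of, index=jid_strs)[keep]
    lib = counts_df.sum(axis=0).astype(float)
    junc_logcpm = np.log2((counts_kept + 0.5).div(lib + 1.0, axis=1) * 1e6)
    gsum = counts_kept.groupby(gene_map).sum()
    gene_logcpm = np.log2((gsum + 0.5).div(lib + 1.0, axis=1) * 1e6)
    return TwoPassScenario(
        junc_logcpm=junc_logcpm,
        gene_logcpm=gene_logcpm,
        gene_map=gene_map,
        trait=pd.Series(trait, index=sample_ids, name="trait"),
        gene_driven_gene=driver_gene,
        splicing_junction=splice_jid,
        matrix=matrix,
    )


def null_config(n_genes: int = 360, seed: int = 0, **kw) -> SimConfig:
    """No spiked events: the null cohort for calibration checks."""
    return SimConfig(n_genes=n_genes, seed=seed, **kw)


def spiked_config(
    n_per_class: int = 40,
    n_background_genes: int = 2000,
    rel_lfc: float = 2.0,
    gene_de_lfc: float = 2.0,
    combined_gene_lfc: float = 6.0,
    neo_usage: float = 0.12,
    n_ballast: int = 320,
    ballast_lfc: float = -3.0,
    seed: int = 0,
    **kw,
) -> SimConfig:
    """Study conditions with ``n_per_class`` events of each class.

    Usage-shift and combined events alternate the sign of the relative
    logFC; combined events add a consistent gene-level upregulation of
    ``combined_gene_lfc`` so absolute and relative logFC clearly diverge.
    ``n_ballast`` background genes are downregulated in the test condition
    so the library composition stays comparable between conditions (real
    cohorts show bidirectional differential expression; without it, CPM
    normalization would shift every logFC by the spiked-in mass).
    """
    n_genes = 4 * n_per_class + n_background_genes
    if n_ballast > n_background_genes:
        raise ValueError("n_ballast cannot exceed n_background_genes")
    sign = lambda i: 1.0 if i % 2 == 0 else -1.0  # noqa: E731
    usage_shifts = tuple(
        UsageShift(gene=i, rel_lfc=sign(i) * rel_lfc) for i in range(n_per_class)
    )
    gene_de = tuple(
        GeneDE(gene=n_per_class + i, lfc=sign(i) * gene_de_lfc)
        for i in range(n_per_class)
    )
    combined = tuple(
        Combined(
            gene=2 * n_per_class + i,
            rel_lfc=sign(i) * rel_lfc,
            gene_lfc=combined_gene_lfc,
        )
        for i in range(n_per_class)
    )
    neo = tuple(
        Neojunction(gene=3 * n_per_class + i, usage=neo_usage)
        for i in range(n_per_class)
    )
    ballast = tuple(
        GeneDE(gene=4 * n_per_class + i, lfc=ballast_lfc) for i in range(n_ballast)
    )
    return SimConfig(
        n_genes=n_genes,
        usage_shifts=usage_shifts,
        gene_de=gene_de,
        combined=combined,
        neojunctions=neo,
        background_de=ballast,
        seed=seed,
        **kw,
    )
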