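"""Shared fixtures: simulated cohorts are expensive, so the spiked and
null scenarios are generated once per session and reused."""

from __future__ import annotations

import dataclasses
import warnings

import pandas as pd
import pytest

import juncdiff as jd


@dataclasses.dataclass
class AnalyzedCohort:
    sim: jd.SimResult
    matrix: jd.JunctionCountMatrix  # filtered
    result: jd.DJEResult

    @property
    def table(self) -> pd.DataFrame:
        return self.result.table


def _analyze(cfg: jd.SimConfig) -> AnalyzedCohort:
    sim = jd.simulate_junction_counts(cfg)
    m = jd.filter_junctions(sim.matrix, 10.0)
    design = jd.two_group_design(sim.groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = jd.dje_analyze(m, design, sim.groups)
    return AnalyzedCohort(sim=sim, matrix=m, result=res)


@pytest.fixture(scope="session")
def spiked_run() -> AnalyzedCohort:
    """40 spiked events per class, n = 15 + 15, fixed seed."""
    return _analyze(jd.spiked_config(seed=1))


@pytest.fixture(scope="session")
def null_run() -> AnalyzedCohort:
    """No spiked events, ~2000 junctions, n = 15 + 15, fixed seed."""
    return _analyze(jd.null_config(n_genes=360, seed=1))


@pytest.fixture()
def tiny_gtf(tmp_path):
    """Two genes on chr1 (+) and one on chr2 (-), written as GTF."""
    lines = []

    def exon(chrom, start, end, strand, gene, tx):
        attrs = f'gene_id "{gene}"; transcript_id "{tx}";'
        lines.append(f"{chrom}\tt\texon\t{start}\t{end}\t.\t{strand}\t.\t{attrs}")

    # GENE1: 3 exons -> introns (101,200) and (301,400)
    exon("chr1", 1, 100, "+", "GENE1", "GENE1.t1")
    exon("chr1", 201, 300, "+", "GENE1", "GENE1.t1")
    exon("chr1", 401, 500, "+", "GENE1", "GENE1.t1")
    # GENE1 second transcript sharing intron (101,200)
    exon("chr1", 1, 100, "+", "GENE1", "GENE1.t2")
    exon("chr1", 201, 500, "+", "GENE1", "GENE1.t2")
    # GENE2 overlaps GENE1's span: 2 exons -> intron (151,250)
    exon("chr1", 50, 150, "+", "GENE2", "GENE2.t1")
    exon("chr1", 251, 350, "+", "GENE2", "GENE2.t1")
    # GENE3 on the minus strand of chr2 -> intron (1101,1200)
    exon("chr2", 1000, 1100, "-", "GENE3", "GENE3.t1")
    exon("chr2", 1201, 1300, "-", "GENE3", "GENE3.t1")
    path = tmp_path / "tiny.gtf"
    path.write_text("\n".join(lines) + "\n")
    return path
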