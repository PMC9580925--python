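"""GTF-derived intron index and junction-to-gene annotation.

A junction is "annotated" when its intron matches an intron implied by two
consecutive exons of some transcript.  Junctions absent from the annotation
are "novel"; those sharing a single splice site with a known intron point
to unannotated exons inside known genes.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import gffutils
from intervaltree import IntervalTree

from .io import JunctionCountMatrix

__all__ = ["IntronIndex", "load_annotation", "annotate_junctions"]


@dataclasses.dataclass
class IntronIndex:
    """Introns and gene spans derived from a transcript annotation.

    introns maps (chrom, start, end, strand_sign) -> smallest gene_id;
    donors/acceptors map a single splice-site coordinate to the genes whose
    annotated introns use it; gene_spans holds (chrom, start, end, sign)
    per gene over its exon extremes.
    """

    introns: dict[tuple[str, int, int, str], str]
    donors: dict[tuple[str, int, str], set[str]]
    acceptors: dict[tuple[str, int, str], set[str]]
    gene_spans: dict[str, tuple[str, int, int, str]]
    _span_trees: dict[str, IntervalTree] = dataclasses.field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        trees: dict[str, IntervalTree] = {}
        for gene, (chrom, start, end, sign) in self.gene_spans.items():
            trees.setdefault(chrom, IntervalTree())[start : end + 1] = (gene, sign)
        self._span_trees = trees

    @property
    def n_introns(self) -> int:
        return len(self.introns)

    def genes_spanning(self, chrom: str, start: int, end: int, signs: set[str]) -> list[str]:
        """Genes whose exon span fully contains [start, end] on a compatible strand."""
        tree = self._span_trees.get(chrom)
        if tree is None:
            return []
        hits = []
        for iv in tree.overlap(start, end + 1):
            gene, sign = iv.data
            if iv.begin <= start and iv.end >= end + 1 and sign in signs:
                hits.append(gene)
        return sorted(hits)


def load_annotation(gtf: str | Path) -> IntronIndex:
    """Build an :class:`IntronIndex` from the exon features of a GTF file.

    For each transcript, exons are sorted by start and each consecutive pair
    contributes one intron (upstream exon end + 1, downstream exon start - 1).
    Transcripts with overlapping exons are skipped with a warning.
    """
    db = gffutils.create_db(
        str(gtf),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    transcripts: dict[str, list] = {}
    tx_gene: dict[str, str] = {}
    n_exons = 0
    for exon in db.features_of_type("exon"):
        n_exons += 1
        tx = exon.attributes["transcript_id"][0]
        gene = exon.attributes["gene_id"][0]
        transcripts.setdefault(tx, []).append(exon)
        tx_gene[tx] = gene
    if n_exons == 0:
        raise ValueError(f"{gtf}: no exon features found")

    introns: dict[tuple[str, int, int, str], str] = {}
    donors: dict[tuple[str, int, str], set[str]] = {}
    acceptors: dict[tuple[str, int, str], set[str]] = {}
    gene_lo: dict[str, int] = {}
    gene_hi: dict[str, int] = {}
    gene_loc: dict[str, tuple[str, str]] = {}

    for tx, exons in transcripts.items():
        gene = tx_gene[tx]
        exons = sorted(exons, key=lambda e: (e.start, e.end))
        overlapping = any(
            exons[i + 1].start <= exons[i].end for i in range(len(exons) - 1)
        )
        if overlapping:
            warnings.warn(
                f"transcript {tx}: overlapping exons, skipped", stacklevel=2
            )
            continue
        chrom = exons[0].seqid
        sign = exons[0].strand if exons[0].strand in ("+", "-") else "."
        gene_loc.setdefault(gene, (chrom, sign))
        gene_lo[gene] = min(gene_lo.get(gene, exons[0].start), exons[0].start)
        gene_hi[gene] = max(gene_hi.get(gene, exons[-1].end), exons[-1].end)
        for up, down in zip(exons, exons[1:]):
            istart, iend = up.end + 1, down.start - 1
            if iend < istart:  # abutting exons leave no intron
                continue
            key = (chrom, istart, iend, sign)
            prev = introns.get(key)
            introns[key] = gene if prev is None else min(prev, gene)
            donors.setdefault((chrom, istart, sign), set()).add(gene)
            acceptors.setdefault((chrom, iend, sign), set()).add(gene)

    gene_spans = {
        g: (gene_loc[g][0], gene_lo[g], gene_hi[g], gene_loc[g][1])
        for g in gene_lo
    }
    return IntronIndex(introns, donors, acceptors, gene_spans)


def _compatible_signs(strand_code: int) -> set[str]:
    # strand code 0 (undefined motif) is compatible with either strand
    if strand_code == 1:
        return {"+", "."}
    if strand_code == 2:
        return {"-", "."}
    return {"+", "-", "."}


def annotate_junctions(m: JunctionCountMatrix, idx: IntronIndex) -> JunctionCountMatrix:
    """Assign genes and annotation flags to every junction of a matrix.

    Priority: (1) exact intron match; (2) one shared splice site with an
    annotated intron on a compatible strand; (3) containment within exactly
    one (or, with ties, the lexicographically smallest) gene span.  Junctions
    matching no rule keep ``gene_id = None``.  Idempotent and independent of
    row order.
    """
    meta = JunctionCountMatrix.empty_meta(m.counts.index)
    for jid_str, jid in zip(m.counts.index, m.junctions):
        signs = _compatible_signs(jid.strand)
        exact = [
            idx.introns[(jid.chrom, jid.start, jid.end, s)]
            for s in signs
            if (jid.chrom, jid.start, jid.end, s) in idx.introns
        ]
        if exact:
            meta.at[jid_str, "gene_id"] = min(exact)
            meta.at[jid_str, "annotated"] = True
            continue
        shared: set[str] = set()
        for s in signs:
            shared |= idx.donors.get((jid.chrom, jid.start, s), set())
            shared |= idx.acceptors.get((jid.chrom, jid.end, s), set())
        if shared:
            meta.at[jid_str, "gene_id"] = min(shared)
            meta.at[jid_str, "shares_splice_site"] = True
            continue
        spanning = idx.genes_spanning(jid.chrom, jid.start, jid.end, signs)
        if spanning:
            meta.at[jid_str, "gene_id"] = spanning[0]
    return JunctionCountMatrix(m.counts.copy(), meta)
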