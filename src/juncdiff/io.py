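"""Reading, merging and writing splice-junction quantification data.

Junctions are identified by the genomic interval of their intron in the
``chr:start:end:strand`` convention used by STAR's ``SJ.out.tab`` files:
``start``/``end`` are the first and last intron bases (1-based, inclusive)
and strand is coded 0 (undefined), 1 (plus) or 2 (minus).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "JunctionID",
    "JunctionCountMatrix",
    "JunctionParseError",
    "parse_junction_id",
    "read_star_sj",
    "write_star_sj",
    "import_samples",
    "write_matrix_tsv",
    "read_matrix_tsv",
]

STRAND_CODES = (0, 1, 2)
_STRAND_SIGN = {0: ".", 1: "+", 2: "-"}


class JunctionParseError(ValueError):
    """Raised for malformed junction identifiers or quantification files."""


@dataclasses.dataclass(frozen=True, order=True)
class JunctionID:
    """A splice junction, keyed by its intron's genomic interval.

    Attributes
    ----------
    chrom : str
        Chromosome name (must not contain ``:``).
    start, end : int
        First and last intron base, 1-based inclusive; ``start <= end``.
    strand : int
        0 = undefined, 1 = plus strand, 2 = minus strand.
    """

    chrom: str
    start: int
    end: int
    strand: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise JunctionParseError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise JunctionParseError(
                f"start > end ({self.start} > {self.end}) in junction on {self.chrom}"
            )
        if self.strand not in STRAND_CODES:
            raise JunctionParseError(
                f"strand must be one of {STRAND_CODES}, got {self.strand!r}"
            )

    @property
    def strand_sign(self) -> str:
        """``+``/``-`` for stranded junctions, ``.`` when undefined."""
        return _STRAND_SIGN[self.strand]

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}:{self.end}:{self.strand}"


def parse_junction_id(text: str) -> JunctionID:
    """Parse a ``chr:start:end:strand`` identifier.

    >>> parse_junction_id("chr1:123:456:1")
    JunctionID(chrom='chr1', start=123, end=456, strand=1)
    """
    parts = text.split(":")
    if len(parts) != 4:
        raise JunctionParseError(
            f"junction id {text!r} must have 4 colon-delimited fields, got {len(parts)}"
        )
    chrom, start_s, end_s, strand_s = parts
    if not chrom:
        raise JunctionParseError(f"junction id {text!r}: empty chromosome field")
    try:
        start = int(start_s)
    except ValueError:
        raise JunctionParseError(
            f"junction id {text!r}: non-integer start {start_s!r}"
        ) from None
    try:
        end = int(end_s)
    except ValueError:
        raise JunctionParseError(
            f"junction id {text!r}: non-integer end {end_s!r}"
        ) from None
    try:
        strand = int(strand_s)
    except ValueError:
        raise JunctionParseError(
            f"junction id {text!r}: non-integer strand {strand_s!r}"
        ) from None
    return JunctionID(chrom, start, end, strand)


_META_COLUMNS = ["gene_id", "annotated", "shares_splice_site"]


@dataclasses.dataclass
class JunctionCountMatrix:
    """Junctions x samples integer read counts plus per-junction metadata.

    ``counts`` is a DataFrame indexed by canonical junction-id strings with
    one column per sample.  ``meta`` is aligned row-for-row and carries
    ``gene_id`` (or None), ``annotated`` and ``shares_splice_site`` flags.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate junction IDs: {dupes[:5]}")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample IDs")
        if not self.counts.index.equals(self.meta.index):
            raise ValueError("meta rows must align 1:1 with junctions")
        vals = self.counts.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("counts must be finite")
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def junctions(self) -> list[JunctionID]:
        return [parse_junction_id(j) for j in self.counts.index]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_junctions(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset(self, junction_ids: Sequence[str]) -> "JunctionCountMatrix":
        """Row-subset preserving the given order."""
        return JunctionCountMatrix(
            self.counts.loc[list(junction_ids)].copy(),
            self.meta.loc[list(junction_ids)].copy(),
        )

    @staticmethod
    def empty_meta(index: pd.Index) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": pd.Series([None] * len(index), index=index, dtype=object),
                "annotated": pd.Series(False, index=index, dtype=bool),
                "shares_splice_site": pd.Series(False, index=index, dtype=bool),
            }
        )


def read_star_sj(path: str | Path) -> list[tuple[JunctionID, int]]:
    """Read one STAR ``SJ.out.tab`` file into (junction, unique-read-count) pairs.

    The 9 tab-delimited columns are chrom, intron start, intron end, strand
    code, intron motif, annotation flag, uniquely-mapping reads,
    multi-mapping reads and maximum overhang.  Only uniquely-mapping reads
    (column 7) are used; file order is preserved.
    """
    path = Path(path)
    pairs: list[tuple[JunctionID, int]] = []
    seen: set[JunctionID] = set()
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise JunctionParseError(f"cannot read {path}: {exc}") from exc
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 9:
            raise JunctionParseError(
                f"{path}:{lineno}: expected 9 tab-delimited columns, got {len(fields)}"
            )
        try:
            jid = JunctionID(fields[0], int(fields[1]), int(fields[2]), int(fields[3]))
            count = int(fields[6])
        except (ValueError, JunctionParseError) as exc:
            raise JunctionParseError(f"{path}:{lineno}: {exc}") from None
        if count < 0:
            raise JunctionParseError(f"{path}:{lineno}: negative read count {count}")
        if jid in seen:
            raise JunctionParseError(f"{path}:{lineno}: duplicate junction {jid}")
        seen.add(jid)
        pairs.append((jid, count))
    return pairs


def write_star_sj(pairs: Iterable[tuple[JunctionID, int]], path: str | Path) -> None:
    """Write (junction, count) pairs as a 9-column ``SJ.out.tab`` file.

    Motif and annotation columns are set to 0 and the overhang to 30;
    junctions are written in the order given.
    """
    with open(path, "w") as fh:
        for jid, count in pairs:
            fh.write(
                f"{jid.chrom}\t{jid.start}\t{jid.end}\t{jid.strand}\t0\t0\t{int(count)}\t0\t30\n"
            )


def _sort_key(jid_str: str) -> tuple:
    j = parse_junction_id(jid_str)
    return (j.chrom, j.start, j.end, j.strand)


def import_samples(
    paths: Sequence[str | Path], sample_ids: Sequence[str]
) -> JunctionCountMatrix:
    """Merge per-sample SJ files into one count matrix.

    The junction set is the union across files; cells absent from a file
    are zero.  Rows are sorted by (chrom, start, end, strand) so the result
    is independent of file order.
    """
    if len(paths) == 0:
        raise ValueError("at least one input file is required")
    if len(paths) != len(sample_ids):
        raise ValueError(
            f"{len(paths)} paths but {len(sample_ids)} sample ids"
        )
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample IDs")
    columns = {}
    for path, sid in zip(paths, sample_ids):
        pairs = read_star_sj(path)
        columns[sid] = pd.Series(
            {str(j): c for j, c in pairs}, dtype="int64", name=sid
        )
    counts = pd.DataFrame(columns, columns=list(sample_ids))
    counts = counts.fillna(0).astype("int64")
    order = sorted(counts.index, key=_sort_key)
    counts = counts.loc[order]
    return JunctionCountMatrix(counts, JunctionCountMatrix.empty_meta(counts.index))


def write_matrix_tsv(m: JunctionCountMatrix, path: str | Path, with_meta: bool = False) -> None:
    """Write the matrix as TSV: ``junction_id``, optional meta columns, samples."""
    out = m.counts.copy()
    if with_meta:
        meta = m.meta.copy()
        meta["gene_id"] = meta["gene_id"].map(lambda g: "" if g is None else g)
        out = pd.concat([meta, out], axis=1)
    out.index.name = "junction_id"
    out.to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path) -> JunctionCountMatrix:
    """Read a matrix written by :func:`write_matrix_tsv` (with or without meta)."""
    df = pd.read_csv(path, sep="\t", index_col="junction_id")
    df.index.name = None
    for jid in df.index:
        parse_junction_id(jid)  # validate
    if set(_META_COLUMNS).issubset(df.columns):
        meta = df[_META_COLUMNS].copy()
        meta["gene_id"] = meta["gene_id"].map(
            lambda g: None if (pd.isna(g) or g == "") else str(g)
        )
        meta["annotated"] = meta["annotated"].astype(bool)
        meta["shares_splice_site"] = meta["shares_splice_site"].astype(bool)
        counts = df.drop(columns=_META_COLUMNS)
    else:
        meta = JunctionCountMatrix.empty_meta(df.index)
        counts = df
    counts = counts.astype("int64")
    return JunctionCountMatrix(counts, meta)
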