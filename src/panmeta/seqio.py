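"""Readers and writers for every format the pipeline touches.

Formats: FASTA (plain or gzip), 12-column BLAST-tabular TSV, CD-HIT-style
``.clstr`` cluster exchange files, Newick trees (via dendropy) and labeled
matrix TSVs.  Parsers reject malformed input with informative errors; they
never silently repair it.

Conventions
-----------
* FASTA record id = first whitespace-delimited token of the header.
* Hit coordinates are 1-based inclusive (BLAST convention).  All internal
  sequence indices are 0-based half-open; converters are the only place the
  two conventions meet.
* Matrix TSV: first row = column labels, first column = row labels, UTF-8,
  ``.`` decimal separator.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "GeneRecord",
    "HitRecord",
    "ProfileMatrix",
    "read_fasta",
    "write_fasta",
    "read_tabular_hits",
    "write_tabular_hits",
    "read_cluster_file",
    "write_cluster_file",
    "read_newick",
    "write_newick",
]

#: Residues accepted in protein sequences (20 standard + common ambiguity
#: codes scored by BLOSUM62).
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBZXJUO*-")


@dataclass(frozen=True)
class GeneRecord:
    """One protein (or contig) sequence with a stable id and source label.

    Parameters
    ----------
    id : str
        Unique identifier within a collection.
    source : str
        Strain or sample label the record originates from.
    sequence : str
        Residue string (uppercase protein alphabet).
    """

    id: str
    source: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("GeneRecord id must be nonempty")
        if not self.sequence:
            raise ValueError(f"GeneRecord {self.id!r}: sequence must be nonempty")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"GeneRecord {self.id!r}: sequence contains residues outside "
                f"the declared alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HitRecord:
    """One row of a 12-column BLAST-tabular (``-outfmt 6``) alignment hit."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_openings: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: percent_identity "
                f"{self.percent_identity} outside [0, 100]"
            )
        if self.evalue < 0:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: negative evalue"
            )
        for name in ("query_start", "query_end", "subject_start", "subject_end"):
            if getattr(self, name) < 1:
                raise ValueError(
                    f"hit {self.query_id}->{self.subject_id}: {name} must be "
                    "positive (1-based inclusive coordinates)"
                )


class ProfileMatrix:
    """A labeled numeric matrix with explicit row/column order.

    Used for Jaccard matrices, coverage-ratio profiles and KO
    presence/absence matrices.
    """

    def __init__(
        self,
        row_labels: Sequence[str],
        col_labels: Sequence[str],
        values,
    ) -> None:
        row_labels = list(row_labels)
        col_labels = list(col_labels)
        if len(set(row_labels)) != len(row_labels):
            raise ValueError("duplicate row labels")
        if len(set(col_labels)) != len(col_labels):
            raise ValueError("duplicate column labels")
        values = np.asarray(values, dtype=float)
        if values.shape != (len(row_labels), len(col_labels)):
            raise ValueError(
                f"matrix shape {values.shape} inconsistent with "
                f"{len(row_labels)} rows x {len(col_labels)} columns"
            )
        self.row_labels = row_labels
        self.col_labels = col_labels
        self.values = values
        self._row_index = {r: i for i, r in enumerate(row_labels)}
        self._col_index = {c: j for j, c in enumerate(col_labels)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __getitem__(self, key: tuple[str, str]) -> float:
        r, c = key
        return float(self.values[self._row_index[r], self._col_index[c]])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProfileMatrix):
            return NotImplemented
        return (
            self.row_labels == other.row_labels
            and self.col_labels == other.col_labels
            and np.array_equal(self.values, other.values)
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.row_labels, columns=self.col_labels
        )

    def to_tsv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = ""
        df.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "ProfileMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            [str(r) for r in df.index],
            [str(c) for c in df.columns],
            df.to_numpy(dtype=float),
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"ProfileMatrix({len(self.row_labels)}x{len(self.col_labels)})"
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode, encoding="utf-8")


def read_fasta(path, source_label: str) -> list[GeneRecord]:
    """Read a FASTA file into :class:`GeneRecord` objects.

    The id of each record is the first whitespace-delimited token of its
    header line; wrapped sequence lines are joined.  Order is preserved.

    Raises
    ------
    ValueError
        On an empty file, a duplicate id (named in the message), or
        sequence data before the first header.
    """
    records: list[GeneRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        if header is None:
            return
        rec = GeneRecord(id=header, source=source_label, sequence="".join(chunks))
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(rec)

    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                chunks = []
            else:
                if header is None:
                    raise ValueError(f"{path}: sequence data before first header")
                chunks.append(line.strip().upper())
        _flush()
    if not records:
        raise ValueError(f"{path}: empty FASTA file")
    return records


def write_fasta(records: Iterable[GeneRecord], path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width``."""
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BLAST-tabular hits
# ---------------------------------------------------------------------------

_HIT_COLUMNS = 12


def read_tabular_hits(path) -> list[HitRecord]:
    """Read 12-column BLAST-tabular (``-outfmt 6``) hits.

    An empty file yields an empty list.  A line with the wrong column count
    or an unparseable field raises ``ValueError`` naming the line number.
    """
    hits: list[HitRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _HIT_COLUMNS:
                raise ValueError(
                    f"{path}: line {lineno}: expected {_HIT_COLUMNS} "
                    f"tab-separated columns, found {len(fields)}"
                )
            try:
                hit = HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_openings=int(fields[5]),
                    query_start=int(fields[6]),
                    query_end=int(fields[7]),
                    subject_start=int(fields[8]),
                    subject_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_tabular_hits(hits: Iterable[HitRecord], path) -> None:
    with _open_text(path, "wt") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id,
                        h.subject_id,
                        repr(h.percent_identity),
                        h.alignment_length,
                        h.mismatches,
                        h.gap_openings,
                        h.query_start,
                        h.query_end,
                        h.subject_start,
                        h.subject_end,
                        repr(h.evalue),
                        repr(h.bitscore),
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# CD-HIT-style cluster files
# ---------------------------------------------------------------------------

def write_cluster_file(cluster_set, path) -> None:
    """Write a :class:`~panmeta.clustering.ClusterSet` as a ``.clstr`` file.

    Identity and coverage are written as full-precision fractions
    (``at <identity>/<coverage>``) so the file round-trips exactly; the
    block structure otherwise follows CD-HIT's ``.clstr`` layout.
    """
    with _open_text(path, "wt") as fh:
        for idx, cluster in enumerate(cluster_set.clusters):
            member_ids = {m.gene_id for m in cluster.members}
            if cluster.representative not in member_ids:
                raise ValueError(
                    f"cluster {idx}: unknown representative "
                    f"{cluster.representative!r}"
                )
            fh.write(f">Cluster {idx}\n")
            for mno, member in enumerate(cluster.members):
                length = cluster_set.lengths.get(member.gene_id, 0)
                if member.gene_id == cluster.representative:
                    fh.write(f"{mno}\t{length}aa, >{member.gene_id}... *\n")
                else:
                    fh.write(
                        f"{mno}\t{length}aa, >{member.gene_id}... at "
                        f"{member.identity!r}/{member.coverage!r}\n"
                    )


def read_cluster_file(path):
    """Read a ``.clstr`` file written by :func:`write_cluster_file`.

    Returns a :class:`~panmeta.clustering.ClusterSet`.  An empty file yields
    an empty cluster set; a cluster without a representative line raises.
    """
    from panmeta.clustering import ClusterMember, ClusterSet, GeneCluster

    clusters: list[GeneCluster] = []
    lengths: dict[str, int] = {}
    current: list[ClusterMember] | None = None
    current_rep: str | None = None

    def _flush(lineno: int) -> None:
        nonlocal current, current_rep
        if current is None:
            return
        if current_rep is None:
            raise ValueError(
                f"{path}: cluster ending before line {lineno} has no "
                "representative ('*') line"
            )
        clusters.append(GeneCluster(representative=current_rep, members=current))
        current, current_rep = None, None

    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">Cluster"):
                _flush(lineno)
                current = []
                continue
            if current is None:
                raise ValueError(
                    f"{path}: line {lineno}: member line before cluster header"
                )
            try:
                _, rest = line.split("\t", 1)
                size_part, id_part = rest.split(", >", 1)
                length = int(size_part.rstrip("a"))
                gene_id, tail = id_part.split("...", 1)
                tail = tail.strip()
                if tail == "*":
                    current_rep = gene_id
                    member = ClusterMember(gene_id, 1.0, 1.0)
                else:
                    if not tail.startswith("at "):
                        raise ValueError(f"unrecognised member suffix {tail!r}")
                    ident_s, cov_s = tail[3:].split("/")
                    member = ClusterMember(gene_id, float(ident_s), float(cov_s))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            lengths[gene_id] = length
            current.append(member)
        _flush(lineno=-1)
    return ClusterSet(clusters, lengths=lengths)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(path, taxon_namespace=None) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path),
        schema="newick",
        taxon_namespace=taxon_namespace,
        preserve_underscores=True,
    )


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", unquoted_underscores=True).strip()
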