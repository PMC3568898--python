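"""Multi-genome alignment container with coordinate liftover.

The three ingroup genomes (plus optionally the ancestor) are held as rows of
a gapped multiple alignment; every analysis that needs cross-genome
coordinates (splice-site windows, SSR liftover, divergence columns) goes
through this container.  Rows are byte arrays over {A,C,G,T,N,-}; a column
with a gap in some genome marks an insertion/deletion, and any interval
query that touches a gapped column in a required genome reports
"not gap-free" rather than guessing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

GAP = ord("-")


@dataclass
class ThreeWayAlignment:
    """Gapped alignment of named genome rows sharing one column space."""

    rows: dict[str, np.ndarray]  # name -> uint8 array of byte codes, equal length
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")
        self._col_of: dict[str, np.ndarray] = {}
        self._pos_of: dict[str, np.ndarray] = {}
        for name, row in self.rows.items():
            ungapped = row != GAP
            pos_of = np.cumsum(ungapped) - 1  # column -> genome pos (of last base)
            self._pos_of[name] = np.where(ungapped, pos_of, -1)
            self._col_of[name] = np.flatnonzero(ungapped)

    @classmethod
    def from_sequences(cls, seqs: Mapping[str, str], chrom: str = "chr1") -> "ThreeWayAlignment":
        return cls(
            rows={
                n: np.frombuffer(s.upper().encode(), dtype=np.uint8).copy()
                for n, s in seqs.items()
            },
            chrom=chrom,
        )

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    def genome_length(self, name: str) -> int:
        return len(self._col_of[name])

    def sequence(self, name: str) -> str:
        row = self.rows[name]
        return row[row != GAP].tobytes().decode()

    def col_of(self, name: str, pos: int) -> int:
        """Alignment column of genome position ``pos`` of row ``name``."""
        return int(self._col_of[name][pos])

    def columns_of(self, name: str, start: int, end: int) -> tuple[int, int]:
        """Column interval spanning genome interval [start, end) of ``name``."""
        if end <= start:
            raise ValueError("empty interval")
        cols = self._col_of[name]
        return int(cols[start]), int(cols[end - 1]) + 1

    def gap_free(self, col_start: int, col_end: int, names: Iterable[str] | None = None) -> bool:
        """True when no row in ``names`` has a gap in the column interval."""
        for name in names or self.rows:
            if np.any(self.rows[name][col_start:col_end] == GAP):
                return False
        return True

    def fetch_columns(self, name: str, col_start: int, col_end: int) -> str:
        """Row slice by columns, gaps included, as a string."""
        return self.rows[name][col_start:col_end].tobytes().decode()

    def fetch(self, name: str, ref: str, start: int, end: int) -> str | None:
        """Sequence of ``name`` aligned to [start, end) of genome ``ref``.

        Returns None unless the interval is gap-free in both rows, so the
        returned string has exactly end - start bases.
        """
        c0, c1 = self.columns_of(ref, start, end)
        if not self.gap_free(c0, c1, (ref, name)):
            return None
        return self.fetch_columns(name, c0, c1)

    def lift(self, src: str, dst: str, start: int, end: int) -> tuple[int, int] | None:
        """Map a genome interval of ``src`` onto ``dst`` coordinates.

        Requires the interval to be gap-free in both genomes; returns the
        half-open destination interval, or None.
        """
        c0, c1 = self.columns_of(src, start, end)
        if not self.gap_free(c0, c1, (src, dst)):
            return None
        p0 = int(self._pos_of[dst][c0])
        p1 = int(self._pos_of[dst][c1 - 1])
        return p0, p1 + 1

    def lift_span(self, src: str, dst: str, start: int, end: int) -> tuple[int, int] | None:
        """Destination bases falling within the column span of a source
        interval; tolerant of indels inside the interval (unlike ``lift``)."""
        c0, c1 = self.columns_of(src, start, end)
        dst_cols = self._col_of[dst]
        p0 = int(np.searchsorted(dst_cols, c0))
        p1 = int(np.searchsorted(dst_cols, c1))
        if p1 <= p0:
            return None
        return p0, p1

    # -- aligned FASTA round trip ------------------------------------------

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name in self.rows:
                fh.write(f">{name}\n")
                seq = self.rows[name].tobytes().decode()
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

    @classmethod
    def read_fasta(cls, path, chrom: str = "chr1") -> "ThreeWayAlignment":
        from Bio import SeqIO

        rows = {
            rec.id: np.frombuffer(str(rec.seq).upper().encode(), dtype=np.uint8).copy()
            for rec in SeqIO.parse(str(path), "fasta")
        }
        return cls(rows=rows, chrom=chrom)

    def write_maf(self, path) -> None:
        """Write the alignment as a single MAF block."""
        with open(path, "w") as fh:
            fh.write("##maf version=1\n\na\n")
            for name, row in self.rows.items():
                seq = row.tobytes().decode()
                size = int((row != GAP).sum())
                fh.write(f"s {self.chrom}.{name} 0 {size} + {size} {seq}\n")
            fh.write("\n")


def build_columns(
    aln: ThreeWayAlignment,
    genomes: Sequence[str] = ("osj", "og", "osi"),
    ref: str = "osj",
    annotation: Mapping[int, str] | None = None,
):
    """Per-reference-position comparison table as a pandas DataFrame.

    Columns: chrom, pos (ref genome coordinate), one base column per genome
    (None where the genome is gapped at that column), annotation_class.
    """
    import pandas as pd

    cols = {}
    ref_cols = aln._col_of[ref]
    for g in genomes:
        row = aln.rows[g][ref_cols]
        cols[f"base_{g}"] = [None if b == GAP else chr(b) for b in row]
    n = len(ref_cols)
    df = pd.DataFrame(
        {
            "chrom": aln.chrom,
            "pos": np.arange(n),
            **cols,
        }
    )
    if annotation is not None:
        df["annotation_class"] = [annotation.get(i, "non-transcribed") for i in range(n)]
    return df


def annotation_classes(genes, ref_length: int) -> dict[int, str]:
    """Per-position annotation class on the reference genome.

    Classes: 'CDS-exon' (inside coding sequence), 'other-exon' (exonic but
    not coding), 'non-exonic' (inside a transcript but not exonic, i.e.
    intronic), 'non-transcribed' (outside all transcripts; the default for
    positions not in the returned mapping).
    """
    out: dict[int, str] = {}
    for g in genes:
        s, e = g.span
        for i in range(s, e):
            out.setdefault(i, "non-exonic")
    for g in genes:
        for xs, xe in g.exons:
            for i in range(xs, xe):
                out[i] = "other-exon"
    for g in genes:
        for cs, ce in g.cds:
            for i in range(cs, ce):
                out[i] = "CDS-exon"
    return out
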