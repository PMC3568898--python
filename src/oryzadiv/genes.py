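"""Gene models and GFF3 input/output.

Coordinates are 0-based half-open internally; GFF3 (1-based inclusive) is
converted at the I/O boundary.  A gene model carries its transcript span,
exon intervals and CDS intervals on the reference genome; introns, intron
phases and the spliced CDS are derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

COMPLEMENT = str.maketrans("ACGTacgtN", "TGCAtgcaN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]  # transcript exons, genomic order, half-open
    cds: list[tuple[int, int]]  # coding subintervals, genomic order

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for s, e in self.exons + self.cds:
            if s >= e:
                raise ValueError(f"{self.gene_id}: empty or inverted interval")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        """Intron intervals in transcript order (genomic order reversed on '-')."""
        gaps = [
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        ]
        return gaps if self.strand == "+" else gaps[::-1]

    def coding_introns(self) -> list[tuple[int, int]]:
        """Introns whose two flanking exons both contain coding sequence."""
        out = []
        gaps = [
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        ]
        for left, right in gaps:
            left_coding = any(s < left <= e for s, e in self.cds)
            right_coding = any(s <= right < e for s, e in self.cds)
            if left_coding and right_coding:
                out.append((left, right))
        return out if self.strand == "+" else out[::-1]

    def intron_phase(self, intron: tuple[int, int]) -> int:
        """Codon offset of the intron's first base: coding bases upstream mod 3."""
        start, end = intron
        if self.strand == "+":
            upstream = sum(min(e, start) - s for s, e in self.cds if s < start)
        else:
            upstream = sum(e - max(s, end) for s, e in self.cds if e > end)
        return upstream % 3

    def cds_sequence(self, genome: str) -> str:
        parts = [genome[s:e] for s, e in self.cds]
        seq = "".join(parts)
        return seq.upper() if self.strand == "+" else revcomp(seq).upper()

    def transcript_interval_contains(self, start: int, end: int) -> bool:
        s, e = self.span
        return s <= start and end <= e


def cds_intervals(genes: Iterable[GeneModel]) -> list[tuple[int, int]]:
    out = []
    for g in genes:
        out.extend(g.cds)
    return sorted(out)


def exon_intervals(genes: Iterable[GeneModel]) -> list[tuple[int, int]]:
    out = []
    for g in genes:
        out.extend(g.exons)
    return sorted(out)


def transcript_intervals(genes: Iterable[GeneModel]) -> list[tuple[int, int]]:
    return sorted(g.span for g in genes)


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            base = f"{g.chrom}\toryzadiv\t"
            fh.write(f"{base}gene\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            fh.write(
                f"{base}mRNA\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.1;Parent={g.gene_id}\n"
            )
            for xs, xe in g.exons:
                fh.write(
                    f"{base}exon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\tParent={g.gene_id}.1\n"
                )
            for cs, ce in g.cds:
                fh.write(
                    f"{base}CDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t0\tParent={g.gene_id}.1\n"
                )


def read_gff3(path) -> list[GeneModel]:
    """Read gene models from GFF3 (gene/mRNA/exon/CDS features) via gffutils."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    out = []
    for gene in db.features_of_type("gene"):
        exons, cds = [], []
        for mrna in db.children(gene, featuretype="mRNA"):
            exons.extend((f.start - 1, f.end) for f in db.children(mrna, featuretype="exon"))
            cds.extend((f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS"))
        out.append(
            GeneModel(
                gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
                exons=sorted(set(exons)), cds=sorted(set(cds)),
            )
        )
    return out
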