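"""Lineage-specific substitutions at splice sites.

Donor (first 2 intron nt) and acceptor (last 2 nt) dinucleotides are read on
the transcript strand from the reference (Osj) gene models, compared across
the three aligned genomes in windows that must align without gaps, assigned
to a lineage by parsimony over the three motifs, optionally restricted to
records whose 10-nt flanks are identical in all three genomes, and — for
introns between protein-coding exons — checked for retained coding
potential (whether translating straight through the intron in the frame of
the upstream exon yields no stop codon and preserves the reading frame).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .align import ThreeWayAlignment
from .genes import GeneModel, revcomp

FLANK = 10
TAXA = ("osj", "osi", "og")
STOPS = {"TAA", "TAG", "TGA"}
_LINEAGE_LABEL = {"osj": "Osj", "osi": "Osi", "og": "Og"}


@dataclass
class SpliceSiteRecord:
    gene_id: str
    intron_index: int
    kind: str  # 'donor' | 'acceptor'
    motif: dict  # taxon -> 2-nt string on the transcript strand
    flank5: dict  # taxon -> 10-nt string (transcript strand)
    flank3: dict
    gap_free: bool
    lineage: str | None = None  # 'Osj' | 'Osi' | 'Og' | 'none' | 'ambiguous'
    unpolarized: bool = False  # Og assignments lack an outgroup
    in_coding_context: bool = False
    canonical: dict | None = None  # taxon -> motif is GT (donor) / AG (acceptor)

    @property
    def flank_clean(self) -> bool:
        return (
            len(set(self.flank5.values())) == 1
            and len(set(self.flank3.values())) == 1
        )


def _site_windows(gene: GeneModel, intron: tuple[int, int], kind: str):
    """Genomic (ascending) intervals of motif, 5' flank and 3' flank."""
    s, e = intron
    plus = gene.strand == "+"
    if (kind == "donor") == plus:
        motif = (s, s + 2)
    else:
        motif = (e - 2, e)
    up = (motif[0] - FLANK, motif[0])
    down = (motif[1], motif[1] + FLANK)
    return motif, up, down


def extract_splice_contexts(
    genes: Iterable[GeneModel], aln: ThreeWayAlignment, ref: str = "osj"
) -> list[SpliceSiteRecord]:
    """One record per donor/acceptor of every reference-gene intron.

    A record is flagged gap_free only when the motif and both 10-nt flanks
    align without gaps in all three genomes; introns shorter than 4 nt are
    skipped.
    """
    out = []
    for gene in genes:
        coding_introns = set(gene.coding_introns())
        for idx, intron in enumerate(gene.introns()):
            if intron[1] - intron[0] < 4:
                continue
            for kind in ("donor", "acceptor"):
                motif_iv, up_iv, down_iv = _site_windows(gene, intron, kind)
                lo = min(motif_iv[0], up_iv[0], down_iv[0])
                hi = max(motif_iv[1], up_iv[1], down_iv[1])
                ref_len = aln.genome_length(ref)
                if lo < 0 or hi > ref_len:
                    continue
                c0, c1 = aln.columns_of(ref, lo, hi)
                gap_free = aln.gap_free(c0, c1, TAXA)
                motifs, f5, f3 = {}, {}, {}
                for taxon in TAXA:
                    pieces = {}
                    for name, iv in (("motif", motif_iv), ("up", up_iv), ("down", down_iv)):
                        seq = aln.fetch(taxon, ref, iv[0], iv[1])
                        pieces[name] = seq
                    if any(v is None for v in pieces.values()):
                        gap_free = False
                        pieces = {k: (v or "") for k, v in pieces.items()}
                    if gene.strand == "+":
                        motifs[taxon] = pieces["motif"]
                        f5[taxon], f3[taxon] = pieces["up"], pieces["down"]
                    else:
                        motifs[taxon] = revcomp(pieces["motif"])
                        f5[taxon] = revcomp(pieces["down"])
                        f3[taxon] = revcomp(pieces["up"])
                want = "GT" if kind == "donor" else "AG"
                out.append(
                    SpliceSiteRecord(
                        gene_id=gene.gene_id,
                        intron_index=idx,
                        kind=kind,
                        motif=motifs,
                        flank5=f5,
                        flank3=f3,
                        gap_free=gap_free,
                        in_coding_context=intron in coding_introns,
                        canonical={t: motifs[t] == want for t in TAXA},
                    )
                )
    return out


def assign_splice_lineage(record: SpliceSiteRecord) -> SpliceSiteRecord:
    """Parsimony: the single taxon whose motif differs from the two equal
    others gets the assignment; Og assignments are unpolarized (no outgroup
    can say whether the Og state is ancestral or derived)."""
    if not record.gap_free:
        raise ValueError("lineage assignment requires a gap-free record")
    m = record.motif
    values = [m[t] for t in TAXA]
    if len(set(values)) == 1:
        record.lineage = "none"
        return record
    if len(set(values)) == 3:
        record.lineage = "ambiguous"
        return record
    # exactly two distinct motifs: find the odd taxon out, if unique
    odd = [t for t in TAXA if sum(m[t] == m[u] for u in TAXA) == 1]
    if len(odd) != 1:
        record.lineage = "ambiguous"
        return record
    record.lineage = _LINEAGE_LABEL[odd[0]]
    record.unpolarized = record.lineage == "Og"
    return record


def flank_clean_filter(records: Iterable[SpliceSiteRecord]) -> list[SpliceSiteRecord]:
    """Records whose 10-nt flanks are identical across all three genomes."""
    return [r for r in records if r.gap_free and r.flank_clean]


@dataclass
class IntronCodingResult:
    intron_length: int
    length_mod3: int
    has_inframe_stop: bool
    coding_potential_retained: bool


def intron_coding_potential(intron_seq: str, phase: int = 0) -> IntronCodingResult:
    """Can translation run straight through the intron?

    ``phase`` is the codon offset of the intron's first base (coding bases
    upstream mod 3).  Codons are scanned in the frame continuing the
    upstream exon; retained coding potential additionally requires the
    intron length to be a multiple of 3, otherwise the downstream exon's
    frame cannot reconnect.
    """
    seq = intron_seq.upper()
    n = len(seq)
    start = (3 - phase) % 3  # first position opening a full codon inside the intron
    has_stop = any(
        seq[i : i + 3] in STOPS for i in range(start, n - 2, 3)
    )
    mod3 = n % 3
    return IntronCodingResult(
        intron_length=n,
        length_mod3=mod3,
        has_inframe_stop=has_stop,
        coding_potential_retained=(mod3 == 0 and not has_stop),
    )


def summarize_table4(
    records: Sequence[SpliceSiteRecord],
    coding_results: dict | None = None,
) -> dict:
    """Per-lineage intron counts in the shape of the splice-site summary.

    For each ingroup lineage: number of introns with site changes (with the
    donor:acceptor split; an intron appears in both only when both sites
    changed), the subset between protein-coding exons (with the
    canonical-GT/AG subcount on the reference genome), and the subset with
    retained coding potential.  ``coding_results`` maps
    (gene_id, intron_index) -> IntronCodingResult.
    """
    per_intron: dict[tuple, dict] = defaultdict(lambda: {"donor": False, "acceptor": False})
    rec_by_intron: dict[tuple, list] = defaultdict(list)
    for r in records:
        if r.lineage in ("Osj", "Osi", "Og"):
            key = (r.lineage, r.gene_id, r.intron_index)
            per_intron[key][r.kind] = True
            rec_by_intron[key].append(r)
    out = {}
    for lineage in ("Osj", "Osi", "Og"):
        keys = [k for k in per_intron if k[0] == lineage]
        donors = sum(per_intron[k]["donor"] for k in keys)
        acceptors = sum(per_intron[k]["acceptor"] for k in keys)
        coding_keys = [
            k for k in keys if any(r.in_coding_context for r in rec_by_intron[k])
        ]
        canonical = sum(
            all(r.canonical["osj"] for r in rec_by_intron[k]) for k in coding_keys
        )
        retained_keys = []
        retained_canonical = 0
        if coding_results is not None:
            for k in coding_keys:
                res = coding_results.get((k[1], k[2]))
                if res is not None and res.coding_potential_retained:
                    retained_keys.append(k)
                    if all(r.canonical["osj"] for r in rec_by_intron[k]):
                        retained_canonical += 1
        out[lineage] = {
            "introns": len(keys),
            "donor_sites": donors,
            "acceptor_sites": acceptors,
            "between_coding_exons": len(coding_keys),
            "between_coding_exons_gt_ag": canonical,
            "coding_potential_retained": len(retained_keys),
            "coding_potential_retained_gt_ag": retained_canonical,
        }
    return out


def write_records_tsv(records: Sequence[SpliceSiteRecord], path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            ["gene_id", "intron_index", "kind", "motif_osj", "motif_osi", "motif_og",
             "gap_free", "flank_clean", "lineage", "unpolarized", "in_coding_context"]
        )
        for r in records:
            w.writerow(
                [r.gene_id, r.intron_index, r.kind,
                 r.motif.get("osj", ""), r.motif.get("osi", ""), r.motif.get("og", ""),
                 int(r.gap_free), int(r.flank_clean) if r.gap_free else 0,
                 r.lineage or "", int(r.unpolarized), int(r.in_coding_context)]
            )
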