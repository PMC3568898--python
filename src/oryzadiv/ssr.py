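"""Perfect-microsatellite detection, cross-genome clustering, polymorphism
classification and the SSR enrichment tests.

Detection mirrors SSRIT: maximal perfect tandem tracts of a primitive 2-4 nt
motif with minimum unit counts of 9 (di-), 6 (tri-) and 5 (tetra-).  Tracts
found separately in the three genomes are lifted onto the reference (Osj),
clustered by overlap, required to be present in all three genomes with
gap-free 50-bp flanks, and classified: identical in all three (shared),
length differing in exactly one genome (length polymorphism, assigned to
that lineage), equal lengths with exactly one genome's sequence differing
(same-length sequence polymorphism), anything else 'other'.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .align import ThreeWayAlignment
from .genes import GeneModel, revcomp
from .stats import ContingencyTable2x2, TestResult, gtest_2x2, pearson_chi2

MIN_UNITS_DEFAULT = {2: 9, 3: 6, 4: 5}
GENOMES = ("osj", "osi", "og")
_LIN = {"osj": "Osj", "osi": "Osi", "og": "Og"}


@dataclass(frozen=True)
class SSRConfig:
    min_units: Mapping[int, int] = field(default_factory=lambda: dict(MIN_UNITS_DEFAULT))
    flank_bp: int = 50


@dataclass(frozen=True)
class SSRLocus:
    genome: str
    chrom: str
    start: int
    end: int  # half-open; end - start == unit * n_units
    motif: str
    n_units: int

    @property
    def unit(self) -> int:
        return len(self.motif)

    @property
    def length(self) -> int:
        return self.end - self.start


def is_primitive(motif: str) -> bool:
    for p in range(1, len(motif)):
        if len(motif) % p == 0 and motif == motif[:p] * (len(motif) // p):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Lexicographic minimum of the motif and its reverse complement.

    Rotations are deliberately not merged: CGC/GCG, CGG/CCG and GGC/GCC are
    reported as three distinct classes, following SSR-survey convention.
    """
    motif = motif.upper()
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    return min(motif, revcomp(motif))


def _run_length(seq: str, start: int, unit: int) -> int:
    """Number of whole tandem units of seq[start:start+unit] at start."""
    motif = seq[start : start + unit]
    k = unit
    while seq.startswith(motif, start + k):
        k += unit
    return k // unit


def detect_ssrs(
    sequence: str,
    genome: str = "",
    chrom: str = "chr1",
    cfg: SSRConfig = SSRConfig(),
) -> list[SSRLocus]:
    """All maximal perfect tandem tracts passing the unit-count thresholds.

    Tracts containing N (or soft-masked bases treated case-insensitively)
    are excluded only when a non-ACGT character interrupts them.  Candidates
    overlapping a better one are suppressed: longest tract first, then
    leftmost, then smallest unit; reported tracts are non-nested.
    """
    seq = sequence.upper()
    n = len(seq)
    candidates = []
    for unit in (2, 3, 4):
        threshold = cfg.min_units[unit]
        i = 0
        while i + unit * threshold <= n:
            motif = seq[i : i + unit]
            if not set(motif) <= set("ACGT") or not is_primitive(motif):
                i += 1
                continue
            units = _run_length(seq, i, unit)
            if units >= threshold:
                candidates.append(
                    SSRLocus(genome, chrom, i, i + units * unit, motif, units)
                )
                i += units * unit  # next candidate starts after this tract
            else:
                i += 1
    # resolve overlaps: longest tract first, then leftmost, then smallest unit
    candidates.sort(key=lambda L: (-L.length, L.start, L.unit))
    chosen: list[SSRLocus] = []
    for cand in candidates:
        if all(cand.end <= c.start or cand.start >= c.end for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda L: L.start)
    return chosen


# ---------------------------------------------------------------------------
# Cross-genome clustering
# ---------------------------------------------------------------------------

@dataclass
class SSRCluster:
    ref_start: int
    ref_end: int  # reference (Osj) interval covering the member tracts
    members: dict  # genome -> list[SSRLocus]
    tracts: dict  # genome -> tract sequence (from that genome)
    polymorphism_class: str | None = None  # shared | length_poly | seq_poly | other
    lineage: str | None = None
    region_class: str | None = None  # protein_coding | non_transcribed | other


def cluster_across_genomes(
    loci_per_genome: Mapping[str, Sequence[SSRLocus]],
    aln: ThreeWayAlignment,
    cfg: SSRConfig = SSRConfig(),
    ref: str = "osj",
) -> list[SSRCluster]:
    """Lift non-reference tracts to reference coordinates and cluster by
    overlap; keep clusters with at least one member in every genome and
    gap-free 50-bp flanks around the merged interval in all genomes."""
    lifted: list[tuple[int, int, str, SSRLocus]] = []
    for genome, loci in loci_per_genome.items():
        for locus in loci:
            if genome == ref:
                iv = (locus.start, locus.end)
            else:
                iv = aln.lift_span(genome, ref, locus.start, locus.end)
                if iv is None:
                    continue  # unliftable: locus falls entirely in a gap
            lifted.append((iv[0], iv[1], genome, locus))
    lifted.sort()
    clusters: list[list] = []
    for item in lifted:
        if clusters and item[0] < max(e for _, e, _, _ in clusters[-1]):
            clusters[-1].append(item)
        else:
            clusters.append([item])
    out = []
    ref_len = aln.genome_length(ref)
    for items in clusters:
        members: dict[str, list[SSRLocus]] = defaultdict(list)
        for s, e, genome, locus in items:
            members[genome].append(locus)
        if any(g not in members for g in GENOMES):
            continue
        start = min(s for s, _, _, _ in items)
        end = max(e for _, e, _, _ in items)
        # the 50-bp rule applies to the upstream/downstream flanks; the
        # tract itself may carry indels (that is the length polymorphism)
        flank_lo = max(0, start - cfg.flank_bp)
        flank_hi = min(ref_len, end + cfg.flank_bp)
        ok = True
        if start > flank_lo:
            c0, c1 = aln.columns_of(ref, flank_lo, start)
            ok = aln.gap_free(c0, c1, GENOMES)
        if ok and flank_hi > end:
            c0, c1 = aln.columns_of(ref, end, flank_hi)
            ok = aln.gap_free(c0, c1, GENOMES)
        if not ok:
            continue
        # tract per genome: the aligned sequence over the merged reference
        # interval, gaps stripped (insertions inside the span included)
        c0, c1 = aln.columns_of(ref, start, end)
        tracts = {
            g: aln.fetch_columns(g, c0, c1).replace("-", "") for g in GENOMES
        }
        out.append(
            SSRCluster(ref_start=start, ref_end=end, members=dict(members), tracts=tracts)
        )
    return out


def classify_cluster(cluster: SSRCluster) -> SSRCluster:
    """Shared / length / same-length-sequence polymorphism classification.

    Requires exactly one tract per genome; clusters with multiple tracts in
    any genome fall into 'other'.
    """
    if any(len(cluster.members[g]) != 1 for g in GENOMES):
        cluster.polymorphism_class, cluster.lineage = "other", None
        return cluster
    t = {g: cluster.tracts[g] for g in GENOMES}
    if len(set(t.values())) == 1:
        cluster.polymorphism_class, cluster.lineage = "shared", None
        return cluster
    lengths = {g: len(t[g]) for g in GENOMES}
    odd_len = [
        g for g in GENOMES
        if sum(lengths[g] == lengths[u] for u in GENOMES) == 1
    ]
    if len(odd_len) == 1:  # one genome differs, the other two agree
        cluster.polymorphism_class = "length_poly"
        cluster.lineage = _LIN[odd_len[0]]
        return cluster
    if len(set(lengths.values())) == 1:
        odd_seq = [
            g for g in GENOMES if sum(t[g] == t[u] for u in GENOMES) == 1
        ]
        if len(odd_seq) == 1:
            cluster.polymorphism_class = "seq_poly"
            cluster.lineage = _LIN[odd_seq[0]]
            return cluster
    cluster.polymorphism_class, cluster.lineage = "other", None
    return cluster


def assign_region(
    cluster: SSRCluster, genes: Iterable[GeneModel]
) -> SSRCluster:
    """protein_coding if the reference tract lies entirely within annotated
    CDS; non_transcribed if entirely outside all transcripts; else other."""
    s, e = cluster.ref_start, cluster.ref_end
    in_cds = any(
        cs <= s and e <= ce for g in genes for cs, ce in g.cds
    )
    if in_cds:
        cluster.region_class = "protein_coding"
        return cluster
    in_transcript = any(
        g.span[0] < e and s < g.span[1] for g in genes
    )
    cluster.region_class = "other" if in_transcript else "non_transcribed"
    return cluster


# ---------------------------------------------------------------------------
# Summaries and tests
# ---------------------------------------------------------------------------

def table5_counts(clusters: Sequence[SSRCluster]) -> dict:
    """Counts shaped like the published SSR summary: per region class and
    unit size, totals / shared / polymorphic / per-lineage length and
    same-length sequence polymorphisms."""
    out: dict = defaultdict(lambda: defaultdict(int))
    for c in clusters:
        if c.region_class not in ("non_transcribed", "protein_coding"):
            continue
        unit = c.members["osj"][0].unit if len(c.members["osj"]) == 1 else None
        if unit is None:
            continue
        key = (c.region_class, unit)
        out[key]["total"] += 1
        if c.polymorphism_class == "shared":
            out[key]["shared"] += 1
        else:
            out[key]["polymorphic"] += 1
        if c.polymorphism_class == "length_poly":
            out[key][f"length_poly_{c.lineage}"] += 1
        elif c.polymorphism_class == "seq_poly":
            out[key][f"seq_poly_{c.lineage}"] += 1
    return {k: dict(v) for k, v in out.items()}


def ssr_gtests(clusters: Sequence[SSRCluster], williams_correction: bool = False) -> dict:
    """The SSR contingency analyses over classified, region-assigned clusters.

    Emits: (i) polymorphic-vs-not x region G-test; (ii) tri-vs-other-unit x
    region G-test; (iii) per lineage, length-poly vs same-length-seq-poly
    (tri-nucleotide) x region G-test; (iv) Pearson chi-square (df=2) of
    tri-nucleotide length-poly counts across lineages x region; plus total
    tract length per genome.  Strata with empty margins are skipped with a
    reason.
    """
    counts = table5_counts(clusters)
    units = (2, 3, 4)

    def region_total(region, keys):
        return sum(
            counts.get((region, u), {}).get(k, 0) for u in units for k in keys
        )

    report: dict = {"tests": {}, "skipped": {}}

    def run(name, a, b, c, d, test="g"):
        try:
            if test == "g":
                res = gtest_2x2(ContingencyTable2x2(a, b, c, d), williams_correction)
            else:
                raise ValueError(test)
            report["tests"][name] = {"table": [a, b, c, d], **res.to_dict()}
        except Exception as exc:  # zero margin etc.
            report["skipped"][name] = str(exc)

    poly_nt = region_total("non_transcribed", ["polymorphic"])
    shared_nt = region_total("non_transcribed", ["shared"])
    poly_pc = region_total("protein_coding", ["polymorphic"])
    shared_pc = region_total("protein_coding", ["shared"])
    run("polymorphic_by_region", poly_nt, shared_nt, poly_pc, shared_pc)

    tri_nt = counts.get(("non_transcribed", 3), {}).get("total", 0)
    other_nt = region_total("non_transcribed", ["total"]) - tri_nt
    tri_pc = counts.get(("protein_coding", 3), {}).get("total", 0)
    other_pc = region_total("protein_coding", ["total"]) - tri_pc
    run("tri_proportion_by_region", tri_nt, other_nt, tri_pc, other_pc)

    tri_len_by_lineage = {}
    for lineage in ("Osj", "Osi", "Og"):
        lp_nt = counts.get(("non_transcribed", 3), {}).get(f"length_poly_{lineage}", 0)
        sp_nt = counts.get(("non_transcribed", 3), {}).get(f"seq_poly_{lineage}", 0)
        lp_pc = counts.get(("protein_coding", 3), {}).get(f"length_poly_{lineage}", 0)
        sp_pc = counts.get(("protein_coding", 3), {}).get(f"seq_poly_{lineage}", 0)
        run(f"tri_length_vs_seq_{lineage}", lp_nt, sp_nt, lp_pc, sp_pc)
        tri_len_by_lineage[lineage] = (lp_nt, lp_pc)

    table_2x3 = [
        [tri_len_by_lineage[lin][0] for lin in ("Osj", "Osi", "Og")],
        [tri_len_by_lineage[lin][1] for lin in ("Osj", "Osi", "Og")],
    ]
    try:
        res = pearson_chi2(table_2x3)
        report["tests"]["tri_length_poly_across_lineages"] = {
            "table": table_2x3, **res.to_dict()
        }
    except Exception as exc:
        report["skipped"]["tri_length_poly_across_lineages"] = str(exc)

    report["total_tract_bp"] = {
        g: int(sum(len(c.tracts[g]) for c in clusters)) for g in GENOMES
    }
    return report


def write_bed(loci: Sequence[SSRLocus], path) -> None:
    """One BED line per locus; the name column is the canonical motif."""
    with open(path, "w") as fh:
        for L in sorted(loci, key=lambda x: (x.chrom, x.start)):
            fh.write(
                f"{L.chrom}\t{L.start}\t{L.end}\t{canonical_motif(L.motif)}\t{L.n_units}\t+\n"
            )
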