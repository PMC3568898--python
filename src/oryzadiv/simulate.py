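"""Ground-truth simulator for the three-rice comparison.

Generates an ancestral genome carrying gene models (GT..AG introns, ATG..stop
coding sequences), planted perfect microsatellite tracts and soft-masked
repeat intervals, then evolves it on the fixed topology
((Og, (Osj, Osi)), outgroup) with per-branch substitution rates, a
transition/transversion rate bias kappa, and a codon-aware acceptance scheme
in coding sequence (synonymous proposals always fix, nonsynonymous fix with
probability omega, proposals creating stop codons never fix).  Splice-site
and SSR mutations are planted explicitly so every downstream detection stage
has exact ground truth; a ledger records every accepted substitution and
every planted event.

Rate defaults follow the divergence scale reported for African vs Asian rice
(Og-Osj total distance about 5e-3, transition/transversion ratio 1.72) and
the per-lineage dN/dS values 0.30 (Og) / 0.25 (Osj); the outgroup branch is
deep but kept clear of mutational saturation.

A separate, lighter codon-set simulator (``simulate_codon_alignments``)
produces three-taxon codon alignments directly for estimator-recovery and
type-I-error experiments at scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .align import ThreeWayAlignment
from .genes import GeneModel, revcomp, write_gff3
from .codons import AA_BY_CODON, IS_STOP, AlignmentFilter, CodonAlignment, encode_codons

ACGT = "ACGT"
A_, C_, G_, T_ = 0, 1, 2, 3
# transition partner in ACGT index space: A<->G, C<->T
_TS = np.array([2, 3, 0, 1])
# ACGT index -> TCAG index used by the codon tables
_ACGT_TO_TCAG = np.array([2, 1, 3, 0])
_TCAG_TO_ACGT = np.array([3, 1, 0, 2])
SENSE_CODONS = np.flatnonzero(~IS_STOP)

INGROUP_BRANCHES = ("og", "os_stem", "osj", "osi")


@dataclass
class SpliceMutation:
    gene_id: str
    intron_index: int  # transcript order, 0-based
    kind: str  # 'donor' | 'acceptor'
    taxon: str  # 'og' | 'osj' | 'osi'
    new_motif: str  # 2 nt on the transcript strand


@dataclass
class SSRPlant:
    locus_id: str
    anc_start: int
    motif: str
    n_units: int
    region: str  # 'cds' | 'intergenic'
    gene_id: str | None = None

    @property
    def length(self) -> int:
        return len(self.motif) * self.n_units

    @property
    def anc_end(self) -> int:
        return self.anc_start + self.length


@dataclass
class SSREvent:
    locus_id: str
    taxon: str
    delta_units: int = 0  # length polymorphism: +/- whole repeat units
    point_change: bool = False  # same-length sequence polymorphism


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 150_000
    gene_count: int = 30
    exons_per_gene: tuple[int, int] = (2, 5)
    exon_codons: tuple[int, int] = (25, 60)
    intron_length: tuple[int, int] = (60, 180)
    utr_length: int = 24
    minus_strand_fraction: float = 0.3
    # Per-branch expected substitution proposals per neutral site.
    branch_rates: dict = field(
        default_factory=lambda: {
            "og": 2.5e-3, "os_stem": 1.25e-3, "osj": 1.25e-3, "osi": 1.25e-3,
            "outgroup": 0.05,
        }
    )
    kappa: float = 3.44  # rate bias; implies transition/transversion counts ~ 1.72
    omega: dict = field(
        default_factory=lambda: {
            "og": 0.30, "os_stem": 0.25, "osj": 0.25, "osi": 0.25, "outgroup": 0.25,
        }
    )
    planted_splice_mutations: list = field(default_factory=list)
    n_auto_splice_mutations: int = 0
    planted_ssr_events: list = field(default_factory=list)
    n_ssr_loci: int = 0
    ssr_cds_fraction: float = 0.4
    repeat_fraction: float = 0.15
    # read simulation
    read_length: tuple[int, int] = (350, 750)
    fragment_length: tuple[int, int] = (1500, 2500)
    coverage: float = 2.0
    phred_peak: int = 40
    phred_tail: int = 6
    contaminant_fraction: float = 0.05
    organelle_length: int = 20_000


@dataclass
class SubstitutionRecord:
    branch: str
    anc_pos: int
    base_from: str
    base_to: str
    transition: bool
    coding_effect: str  # 'noncoding' | 'synonymous' | 'nonsynonymous'


@dataclass
class GroundTruth:
    substitutions: list = field(default_factory=list)
    splice_events: list = field(default_factory=list)
    ssr_events: list = field(default_factory=list)
    read_origins: dict = field(default_factory=dict)  # read id -> origin info

    def substitution_count(self, branch: str) -> int:
        return sum(1 for s in self.substitutions if s.branch == branch)


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Ancestor construction
# ---------------------------------------------------------------------------

_SAFE_CDS_MOTIFS = ("GCT", "GGC", "CGC", "AGC", "CAG", "ACG")  # sense in frame


def _random_sense_cds(rng, n_codons: int) -> str:
    idx = rng.choice(SENSE_CODONS, size=n_codons)
    from .codons import CODONS

    return "".join(CODONS[i] for i in idx)


def _build_ancestor(cfg: SimulationConfig, rng):
    """Lay out genes, repeats and SSR tracts on a random ancestral sequence."""
    from .codons import CODONS

    L = cfg.genome_length
    seq = list(rng.integers(0, 4, size=L))
    genes: list[GeneModel] = []
    ssr_loci: list[SSRPlant] = []
    repeat_iv: list[tuple[int, int]] = []

    pos = 500
    gene_no = 0
    ssr_no = 0
    want_cds_ssr = round(cfg.n_ssr_loci * cfg.ssr_cds_fraction)
    want_intergenic_ssr = cfg.n_ssr_loci - want_cds_ssr

    def write(p: int, s: str) -> int:
        for i, ch in enumerate(s):
            seq[p + i] = ACGT.index(ch)
        return p + len(s)

    while gene_no < cfg.gene_count and pos < L - 8000:
        # intergenic stretch: maybe a repeat interval and/or an SSR tract
        gap = int(rng.integers(400, 1200))
        if rng.random() < cfg.repeat_fraction * 4:
            rep_len = int(rng.integers(150, 500))
            repeat_iv.append((pos + 50, min(pos + 50 + rep_len, L)))
        if want_intergenic_ssr > 0:
            unit = int(rng.choice([2, 3, 4]))
            min_units = {2: 9, 3: 6, 4: 5}[unit]
            n_units = int(min_units + rng.integers(2, 6))
            while True:
                motif = "".join(ACGT[i] for i in rng.integers(0, 4, size=unit))
                if len(set(motif)) > 1 and not _is_periodic(motif):
                    break
            start = pos + gap - 300
            write(start, motif * n_units)
            # scrub flanks so no accidental adjacent repetition extends the tract
            write(start - len(motif), _non_extending_flank(motif, left=True))
            write(start + unit * n_units, _non_extending_flank(motif, left=False))
            ssr_loci.append(
                SSRPlant(f"ssr{ssr_no:03d}", start, motif, n_units, "intergenic")
            )
            ssr_no += 1
            want_intergenic_ssr -= 1
        pos += gap

        # gene body
        strand = "-" if rng.random() < cfg.minus_strand_fraction else "+"
        n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        exon_lens = [
            3 * int(rng.integers(cfg.exon_codons[0], cfg.exon_codons[1]))
            for _ in range(n_exons)
        ]
        total_codons = sum(exon_lens) // 3
        cds_seq = "ATG" + _random_sense_cds(rng, total_codons - 2) + "TAA"
        # optionally embed an in-frame CDS SSR tract (tri-nucleotide)
        gene_ssr = None
        if want_cds_ssr > 0 and total_codons > 40:
            motif = str(rng.choice(_SAFE_CDS_MOTIFS))
            n_units = int(6 + rng.integers(2, 6))
            # the tract must sit inside a single exon (margin 4 codons) so
            # no intron interrupts it
            margin = 4
            exon_starts_nt = np.concatenate([[0], np.cumsum(exon_lens)[:-1]])
            fits = [
                i for i, el in enumerate(exon_lens)
                if el >= 3 * (n_units + 2 * margin) and (i > 0 or el >= 3 * (n_units + margin + 2))
            ]
            if fits:
                ei = fits[int(rng.integers(0, len(fits)))]
                lo = exon_starts_nt[ei] // 3 + max(margin, 2 if ei == 0 else 0)
                hi = (exon_starts_nt[ei] + exon_lens[ei]) // 3 - n_units - margin
                cpos = 3 * int(rng.integers(lo, hi + 1))
                cds_seq = (
                    cds_seq[:cpos] + motif * n_units + cds_seq[cpos + 3 * n_units :]
                )
                gene_ssr = (cpos, motif, n_units)
                want_cds_ssr -= 1
        # split CDS into exons at arbitrary offsets (any intron phase)
        bounds = np.cumsum(exon_lens)[:-1]
        pieces = []
        prev = 0
        for b in bounds:
            pieces.append(cds_seq[prev:b])
            prev = b
        pieces.append(cds_seq[prev:])

        gene_id = f"g{gene_no:03d}"
        tx_parts: list[tuple[str, str]] = [("utr", _random_utr(rng, cfg.utr_length))]
        for i, piece in enumerate(pieces):
            tx_parts.append(("cds", piece))
            if i < len(pieces) - 1:
                ilen = int(rng.integers(*cfg.intron_length))
                interior = "".join(ACGT[j] for j in rng.integers(0, 4, size=ilen - 4))
                tx_parts.append(("intron", "GT" + interior + "AG"))
        tx_parts.append(("utr", _random_utr(rng, cfg.utr_length)))
        tx_seq = "".join(p for _, p in tx_parts)
        genomic = tx_seq if strand == "+" else revcomp(tx_seq)

        gstart = pos
        write(gstart, genomic)
        # map transcript part boundaries to genomic intervals
        exons, cds = [], []
        off = 0
        part_iv = []
        for kind, piece in tx_parts:
            part_iv.append((kind, off, off + len(piece)))
            off += len(piece)
        tlen = len(tx_seq)
        for kind, s, e in part_iv:
            if strand == "+":
                giv = (gstart + s, gstart + e)
            else:
                giv = (gstart + tlen - e, gstart + tlen - s)
            if kind == "cds":
                cds.append(giv)
            if kind != "intron":
                # exons = UTR pieces merged with adjacent CDS pieces
                exons.append(giv)
        exons = _merge_adjacent(sorted(exons))
        genes.append(GeneModel(gene_id, "chr1", strand, exons, sorted(cds)))
        if gene_ssr is not None:
            cpos, motif, n_units = gene_ssr
            # locate the tract's ancestor coordinate by walking the CDS pieces
            acc = 0
            anc_start = None
            for kind, s, e in part_iv:
                if kind != "cds":
                    continue
                if acc <= cpos < acc + (e - s):
                    tx_pos = s + (cpos - acc)
                    if strand == "+":
                        anc_start = gstart + tx_pos
                        tract_motif = motif
                    else:
                        anc_start = gstart + tlen - (tx_pos + 3 * n_units)
                        tract_motif = revcomp(motif)
                    break
                acc += e - s
            assert anc_start is not None
            ssr_loci.append(
                SSRPlant(
                    f"ssr{ssr_no:03d}", anc_start, tract_motif, n_units, "cds", gene_id
                )
            )
            ssr_no += 1
        pos = gstart + tlen
        gene_no += 1

    arr = np.array(seq, dtype=np.int8)
    return arr, genes, ssr_loci, repeat_iv


def _is_periodic(motif: str) -> bool:
    for p in range(1, len(motif)):
        if len(motif) % p == 0 and motif == motif[:p] * (len(motif) // p):
            return True
    return False


def _non_extending_flank(motif: str, left: bool) -> str:
    """A flank of motif length that cannot extend the tandem tract."""
    u = len(motif)
    alt = {"A": "C", "C": "A", "G": "T", "T": "G"}
    if left:
        return motif[:-1] + alt[motif[-1]]
    return alt[motif[0]] + motif[1:]


def _random_utr(rng, n: int) -> str:
    return "".join(ACGT[i] for i in rng.integers(0, 4, size=n))


def _merge_adjacent(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and out[-1][1] == s:
            out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return [tuple(iv) for iv in out]


# ---------------------------------------------------------------------------
# Branch evolution
# ---------------------------------------------------------------------------

def _coding_index(genes: Sequence[GeneModel], L: int):
    """Maps genome position -> (flat transcript-order CDS index, strand).

    The terminal stop codon of each gene is excluded (it is held fixed)."""
    cds_pos_parts = []
    strand_of = np.zeros(L, dtype=np.int8)  # 0 none, 1 plus, 2 minus
    tsidx = np.full(L, -1, dtype=np.int64)
    offset = 0
    for g in genes:
        positions = []
        ivs = g.cds if g.strand == "+" else g.cds[::-1]
        for s, e in ivs:
            rng_iter = range(s, e) if g.strand == "+" else range(e - 1, s - 1, -1)
            positions.extend(rng_iter)
        positions = positions[:-3]  # drop the stop codon
        n = len(positions)
        if n % 3:
            raise ConfigError(f"{g.gene_id}: CDS length not a multiple of 3")
        arr = np.array(positions, dtype=np.int64)
        tsidx[arr] = offset + np.arange(n)
        strand_of[arr] = 1 if g.strand == "+" else 2
        cds_pos_parts.append(arr)
        offset += n
    cds_pos = (
        np.concatenate(cds_pos_parts) if cds_pos_parts else np.empty(0, dtype=np.int64)
    )
    return cds_pos, tsidx, strand_of


def _codon_index_tcag(b0: int, b1: int, b2: int) -> int:
    return 16 * _ACGT_TO_TCAG[b0] + 4 * _ACGT_TO_TCAG[b1] + _ACGT_TO_TCAG[b2]


def _evolve_branch(
    parent: np.ndarray,
    branch: str,
    cfg: SimulationConfig,
    rng,
    cds_pos: np.ndarray,
    tsidx: np.ndarray,
    strand_of: np.ndarray,
    mask: np.ndarray,
    truth: GroundTruth,
) -> np.ndarray:
    """One branch of Kimura-type mutation with codon-aware acceptance."""
    child = parent.copy()
    rate = cfg.branch_rates[branch]
    omega = cfg.omega[branch]
    kappa = cfg.kappa
    L = len(child)
    proposals = np.flatnonzero((rng.random(L) < rate) & ~mask)
    p_ts = kappa / (kappa + 2.0)
    for p in proposals:
        old = int(child[p])
        r = rng.random()
        if r < p_ts:
            new, is_ts = int(_TS[old]), True
        else:
            tv = [b for b in range(4) if b != old and b != _TS[old]]
            new, is_ts = tv[int(rng.random() * 2)], False
        j = tsidx[p]
        effect = "noncoding"
        if j >= 0:
            c0 = j - j % 3
            trip = [int(child[cds_pos[c0 + k]]) for k in range(3)]
            minus = strand_of[p] == 2
            if minus:
                trip = [3 - b for b in trip]
            old_ci = _codon_index_tcag(*trip)
            trip_new = list(trip)
            trip_new[j % 3] = (3 - new) if minus else new
            new_ci = _codon_index_tcag(*trip_new)
            if IS_STOP[new_ci]:
                continue
            if AA_BY_CODON[new_ci] == AA_BY_CODON[old_ci]:
                effect = "synonymous"
            else:
                if rng.random() >= omega * _omega_factor(kappa)[old_ci]:
                    continue
                effect = "nonsynonymous"
        child[p] = new
        truth.substitutions.append(
            SubstitutionRecord(branch, int(p), ACGT[old], ACGT[new], is_ts, effect)
        )
    return child


# ---------------------------------------------------------------------------
# Planted events
# ---------------------------------------------------------------------------

def _motif_positions(gene: GeneModel, intron_index: int, kind: str) -> list[int]:
    """Genomic positions (ascending) of a donor/acceptor dinucleotide."""
    intr = gene.introns()[intron_index]
    s, e = intr
    if gene.strand == "+":
        return [s, s + 1] if kind == "donor" else [e - 2, e - 1]
    return [e - 2, e - 1] if kind == "donor" else [s, s + 1]


def _apply_splice_mutation(seqs: dict, genes_by_id: dict, mut: SpliceMutation, truth: GroundTruth):
    gene = genes_by_id[mut.gene_id]
    pos = _motif_positions(gene, mut.intron_index, mut.kind)
    motif = mut.new_motif.upper()
    if gene.strand == "-":
        motif = revcomp(motif)
    arr = seqs[mut.taxon]
    old = "".join(ACGT[arr[p]] for p in pos)
    for p, ch in zip(pos, motif):
        arr[p] = ACGT.index(ch)
    rec = asdict(mut)
    rec["ancestral_genomic_motif"] = old
    truth.splice_events.append(rec)


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    cfg: SimulationConfig
    aln: ThreeWayAlignment  # rows: ancestor, og, osj, osi (gapped)
    genes_anc: list  # gene models in ancestor coordinates
    genes: list  # gene models lifted to emitted Osj coordinates
    outgroup_cds: dict  # gene_id -> codon sequence (str)
    ssr_loci: list
    repeat_intervals: list  # ancestor coordinates
    organelle: str
    truth: GroundTruth

    def genome(self, name: str) -> str:
        return self.aln.sequence(name)

    def masked_genome(self, name: str) -> str:
        """Genome with planted repeat intervals soft-masked (lowercase)."""
        seq = list(self.genome(name))
        for s, e in self.repeat_intervals:
            iv = self.aln.lift("ancestor", name, s, e)
            if iv is None:
                continue
            for i in range(iv[0], iv[1]):
                seq[i] = seq[i].lower()
        return "".join(seq)

    def codon_alignments(self, filt: AlignmentFilter = AlignmentFilter()):
        """Three-taxon codon alignments (Osj/Og/outgroup) from the dataset."""
        from .codons import build_codon_alignment

        out = []
        for g in self.genes_anc:
            cols = []
            for s, e in g.cds:  # ascending; whole concatenation revcomped on '-'
                c0, c1 = self.aln.columns_of("ancestor", s, e)
                cols.append((c0, c1))
            gap_free = all(
                self.aln.gap_free(c0, c1, ("osj", "og")) for c0, c1 in cols
            )
            fetch = lambda name: "".join(
                self.aln.fetch_columns(name, c0, c1) for c0, c1 in cols
            )
            osj_seq, og_seq = fetch("osj"), fetch("og")
            if g.strand == "-":
                osj_seq, og_seq = revcomp(osj_seq), revcomp(og_seq)
            if not gap_free:
                from .codons import RejectedAlignment

                out.append(RejectedAlignment(g.gene_id, "gap in og"))
                continue
            osj_seq = osj_seq.replace("-", "")
            n_codons = len(osj_seq) // 3 - 1  # excluding the stop codon
            og_map = {
                i: og_seq[3 * i : 3 * i + 3] for i in range(n_codons)
            }
            outg = self.outgroup_cds[g.gene_id]
            out_map = {i: outg[3 * i : 3 * i + 3] for i in range(n_codons)}
            out.append(
                build_codon_alignment(g.gene_id, osj_seq, og_map, out_map, filt)
            )
        return out


def simulate_genomes(cfg: SimulationConfig) -> SimulatedDataset:
    rng = np.random.default_rng(cfg.seed)
    anc, genes_anc, ssr_loci, repeat_iv = _build_ancestor(cfg, rng)
    L = len(anc)
    genes_by_id = {g.gene_id: g for g in genes_anc}
    cds_pos, tsidx, strand_of = _coding_index(genes_anc, L)

    # positions held fixed under background mutation: SSR tracts (their
    # polymorphism is planted), splice dinucleotides (ditto) and gene
    # terminal stop codons (kept as stops).
    mask = np.zeros(L, dtype=bool)
    for locus in ssr_loci:
        # one motif-length of flank on each side is also held fixed, so a
        # flank substitution cannot silently extend or phase-shift a tract
        u = len(locus.motif)
        mask[max(0, locus.anc_start - u) : locus.anc_end + u] = True
    for g in genes_anc:
        for i in range(len(g.introns())):
            for kind in ("donor", "acceptor"):
                for p in _motif_positions(g, i, kind):
                    mask[p] = True
        stop_pos = _terminal_stop_positions(g)
        mask[stop_pos] = True

    truth = GroundTruth()
    og = _evolve_branch(anc, "og", cfg, rng, cds_pos, tsidx, strand_of, mask, truth)
    os_anc = _evolve_branch(anc, "os_stem", cfg, rng, cds_pos, tsidx, strand_of, mask, truth)
    osj = _evolve_branch(os_anc, "osj", cfg, rng, cds_pos, tsidx, strand_of, mask, truth)
    osi = _evolve_branch(os_anc, "osi", cfg, rng, cds_pos, tsidx, strand_of, mask, truth)

    # outgroup: CDS only, evolved at the codon level from the ancestral CDS
    outgroup_cds = {}
    for g in genes_anc:
        cds = _gene_cds_string(anc, g)
        codons = encode_codons(cds)[:-1]  # drop stop
        evolved = evolve_codon_array(
            codons, cfg.branch_rates["outgroup"], cfg.kappa, cfg.omega["outgroup"], rng
        )
        from .codons import decode_codons

        outgroup_cds[g.gene_id] = decode_codons(evolved)

    # planted splice mutations
    seqs = {"og": og, "osj": osj, "osi": osi}
    muts = list(cfg.planted_splice_mutations)
    if cfg.n_auto_splice_mutations:
        muts.extend(_auto_splice_mutations(cfg, genes_anc, rng))
    seen = set()
    for mut in muts:
        key = (mut.gene_id, mut.intron_index, mut.kind)
        if key in seen:
            raise ConfigError(f"two splice events at one site: {key}")
        seen.add(key)
        _apply_splice_mutation(seqs, genes_by_id, mut, truth)

    # planted SSR events: point changes now, indels at alignment assembly
    loci_by_id = {s.locus_id: s for s in ssr_loci}
    indels: dict[str, list[tuple[int, int, str]]] = {"og": [], "osj": [], "osi": []}
    ev_seen = set()
    for ev in cfg.planted_ssr_events:
        if (ev.locus_id, ev.taxon) in ev_seen:
            raise ConfigError(f"two SSR events for {ev.locus_id}/{ev.taxon}")
        ev_seen.add((ev.locus_id, ev.taxon))
        locus = loci_by_id[ev.locus_id]
        if ev.point_change:
            _apply_ssr_point_change(seqs[ev.taxon], locus, genes_by_id, rng)
        elif ev.delta_units:
            u = len(locus.motif)
            if ev.delta_units > 0:
                # insert extra units before the last unit, i.e. inside the
                # tract, so the new columns fall within the locus interval
                ins = locus.motif * ev.delta_units
                indels[ev.taxon].append(
                    (locus.anc_end - u, ev.delta_units * u, ins)
                )
            else:
                ndel = -ev.delta_units * u
                if ndel >= locus.length:
                    raise ConfigError(f"deletion wipes out locus {ev.locus_id}")
                indels[ev.taxon].append((locus.anc_end - ndel, -ndel, ""))
        truth.ssr_events.append(asdict(ev))

    aln = _assemble_alignment(anc, seqs, indels)
    genes_osj = [_lift_gene(aln, g) for g in genes_anc]
    organelle = "".join(ACGT[i] for i in rng.integers(0, 4, size=cfg.organelle_length))
    return SimulatedDataset(
        cfg=cfg, aln=aln, genes_anc=genes_anc, genes=genes_osj,
        outgroup_cds=outgroup_cds, ssr_loci=ssr_loci, repeat_intervals=repeat_iv,
        organelle=organelle, truth=truth,
    )


def _terminal_stop_positions(g: GeneModel) -> list[int]:
    positions = []
    ivs = g.cds if g.strand == "+" else g.cds[::-1]
    for s, e in ivs:
        it = range(s, e) if g.strand == "+" else range(e - 1, s - 1, -1)
        positions.extend(it)
    return positions[-3:]


def _gene_cds_string(arr: np.ndarray, g: GeneModel) -> str:
    parts = [
        "".join(ACGT[b] for b in arr[s:e]) for s, e in g.cds
    ]
    seq = "".join(parts)
    return seq if g.strand == "+" else revcomp(seq)


def _auto_splice_mutations(cfg, genes, rng) -> list[SpliceMutation]:
    out = []
    taxa = ["og", "osj", "osi"]
    candidates = [
        (g.gene_id, i) for g in genes for i in range(len(g.introns()))
    ]
    rng.shuffle(candidates)
    for k in range(min(cfg.n_auto_splice_mutations, len(candidates))):
        gid, i = candidates[k]
        kind = "donor" if rng.random() < 0.5 else "acceptor"
        new = ("GC" if rng.random() < 0.5 else "AT") if kind == "donor" else (
            "TG" if rng.random() < 0.5 else "AC"
        )
        out.append(SpliceMutation(gid, i, kind, taxa[k % 3], new))
    return out


def _apply_ssr_point_change(arr: np.ndarray, locus: SSRPlant, genes_by_id, rng):
    """Substitute one base near the tract end, keeping length (and CDS sense).

    The interruption sits in the second-to-last unit so the remaining
    perfect run upstream still clears the detection threshold in the
    mutated genome."""
    from .ssr import MIN_UNITS_DEFAULT

    u = len(locus.motif)
    if locus.n_units - 2 < MIN_UNITS_DEFAULT[u]:
        raise ConfigError(
            f"{locus.locus_id}: tract too short for a detectable interruption"
        )
    hit_unit = locus.n_units - 2
    for off in range(u):
        p = locus.anc_start + hit_unit * u + off
        old = int(arr[p])
        for new in range(4):
            if new == old:
                continue
            if locus.region == "cds" and not _sense_after_change(
                arr, genes_by_id[locus.gene_id], p, new
            ):
                continue
            arr[p] = new
            return
    raise ConfigError(f"no viable point change for {locus.locus_id}")


def _sense_after_change(arr, gene: GeneModel, p: int, new: int) -> bool:
    cds_pos, tsidx, strand_of = _coding_index([gene], len(arr))
    j = tsidx[p]
    if j < 0:
        return True
    c0 = j - j % 3
    trip = [int(arr[cds_pos[c0 + k]]) for k in range(3)]
    if strand_of[p] == 2:
        trip = [3 - b for b in trip]
        newb = 3 - new
    else:
        newb = new
    trip[j % 3] = newb
    return not IS_STOP[_codon_index_tcag(*trip)]


def _assemble_alignment(anc, seqs, indels) -> ThreeWayAlignment:
    """Build gapped rows from per-taxon arrays plus SSR indel operations."""
    L = len(anc)
    names = ["ancestor", "og", "osj", "osi"]
    chars = {
        "ancestor": np.frombuffer(
            "".join(ACGT[b] for b in anc).encode(), dtype=np.uint8
        ).copy()
    }
    for n in ("og", "osj", "osi"):
        chars[n] = np.frombuffer(
            "".join(ACGT[b] for b in seqs[n]).encode(), dtype=np.uint8
        ).copy()
    # deletions: replace taxon bases by gaps in ancestor columns
    gap = ord("-")
    insert_anchors: dict[int, dict[str, str]] = {}
    for taxon, ops in indels.items():
        for pos, delta, ins in ops:
            if delta < 0:
                chars[taxon][pos : pos - delta] = gap
            else:
                insert_anchors.setdefault(pos, {})[taxon] = ins
    if not insert_anchors:
        return ThreeWayAlignment(rows=chars)
    # splice insertion columns in ancestor-position order
    pieces: dict[str, list[np.ndarray]] = {n: [] for n in names}
    prev = 0
    for pos in sorted(insert_anchors):
        for n in names:
            pieces[n].append(chars[n][prev:pos])
        for taxon, ins in sorted(insert_anchors[pos].items()):
            block_len = len(ins)
            for n in names:
                if n == taxon:
                    pieces[n].append(
                        np.frombuffer(ins.encode(), dtype=np.uint8).copy()
                    )
                else:
                    pieces[n].append(np.full(block_len, gap, dtype=np.uint8))
        prev = pos
    for n in names:
        pieces[n].append(chars[n][prev:])
    rows = {n: np.concatenate(pieces[n]) for n in names}
    return ThreeWayAlignment(rows=rows)


def _lift_gene(aln: ThreeWayAlignment, g: GeneModel) -> GeneModel:
    """Map a gene model from ancestor coordinates to Osj coordinates."""

    def lift_iv(iv):
        c0, c1 = aln.columns_of("ancestor", iv[0], iv[1])
        p0 = int(aln._pos_of["osj"][c0])
        p1 = int(aln._pos_of["osj"][c1 - 1])
        return (p0, p1 + 1)

    return GeneModel(
        g.gene_id, g.chrom, g.strand,
        [lift_iv(iv) for iv in g.exons], [lift_iv(iv) for iv in g.cds],
    )


# ---------------------------------------------------------------------------
# Fast codon-set simulator (three taxa, no genome layout)
# ---------------------------------------------------------------------------

# neighbour table: NEW_CODON[codon, position, new TCAG base] -> codon index
_NEW_CODON = np.empty((64, 3, 4), dtype=np.int64)
for _c in range(64):
    _d2 = _c // 16
    _d1 = (_c // 4) % 4
    _d0 = _c % 4
    for _b in range(4):
        _NEW_CODON[_c, 0, _b] = 16 * _b + 4 * _d1 + _d0
        _NEW_CODON[_c, 1, _b] = 16 * _d2 + 4 * _b + _d0
        _NEW_CODON[_c, 2, _b] = 16 * _d2 + 4 * _d1 + _b
_BASE_AT = np.empty((64, 3), dtype=np.int64)
for _c in range(64):
    _BASE_AT[_c, 0] = _c // 16
    _BASE_AT[_c, 1] = (_c // 4) % 4
    _BASE_AT[_c, 2] = _c % 4
_AA_CODE = np.array([ord(a) for a in AA_BY_CODON])


from functools import lru_cache


@lru_cache(maxsize=8)
def _omega_factor(kappa: float) -> np.ndarray:
    """Per-codon acceptance correction planting omega on the MNG scale.

    The site-counting convention treats changes to stop codons as
    nonsynonymous positions, yet mutations to stops never fix; accepting a
    nonsynonymous proposal with probability omega * N_c / n_c (nonsynonymous
    site count over nonsynonymous non-stop mutational weight, both under the
    kappa weighting) makes the expected dN/dS of the evolved sequences equal
    the planted omega.
    """
    from .codons import _neighbors, _site_count_table

    f = np.ones(64)
    w_ts = kappa / (kappa + 2.0)
    w_tv = 1.0 / (kappa + 2.0)
    s_tab = _site_count_table(kappa)
    for c in range(64):
        if IS_STOP[c]:
            continue
        n_nonstop = 0.0
        for _pos, _b, ni, ts in _neighbors(c):
            if not IS_STOP[ni] and AA_BY_CODON[ni] != AA_BY_CODON[c]:
                n_nonstop += w_ts if ts else w_tv
        big_n = 3.0 - s_tab[c]
        if n_nonstop > 0:
            f[c] = big_n / n_nonstop
    return f


def evolve_codon_array(
    codons: np.ndarray, t: float, kappa: float, omega: float, rng,
    omega_factor: np.ndarray | None = None,
) -> np.ndarray:
    """Evolve a codon-index array for one branch (t = proposals per nt site)."""
    arr = codons.copy()
    L = 3 * len(arr)
    if omega_factor is None:
        omega_factor = _omega_factor(kappa)
    proposals = np.flatnonzero(rng.random(L) < t)
    p_ts = kappa / (kappa + 2.0)
    u = rng.random(len(proposals))
    u2 = rng.random(len(proposals))
    u3 = rng.random(len(proposals))
    for k, pos in enumerate(proposals):
        i, off = divmod(int(pos), 3)
        c = arr[i]
        b = _BASE_AT[c, off]
        if u[k] < p_ts:
            nb = b ^ 1
        else:
            nb = b ^ 2 if u2[k] < 0.5 else b ^ 3
        nc = _NEW_CODON[c, off, nb]
        if IS_STOP[nc]:
            continue
        if _AA_CODE[nc] != _AA_CODE[c] and u3[k] >= omega * omega_factor[c]:
            continue
        arr[i] = nc
    return arr


@dataclass
class CodonSimConfig:
    seed: int = 0
    n_genes: int = 2000
    codons_per_gene: int = 300
    t_og: float = 5e-3
    t_osj: float = 5e-3
    t_out: float = 0.05
    kappa: float = 3.44
    omega_og: float = 0.30
    omega_osj: float = 0.25
    omega_out: float = 0.25


def simulate_codon_alignments(cfg: CodonSimConfig) -> list[CodonAlignment]:
    """Three-taxon codon alignments with planted per-branch omega."""
    rng = np.random.default_rng(cfg.seed)
    out = []
    for gi in range(cfg.n_genes):
        anc = rng.choice(SENSE_CODONS, size=cfg.codons_per_gene)
        og = evolve_codon_array(anc, cfg.t_og, cfg.kappa, cfg.omega_og, rng)
        osj = evolve_codon_array(anc, cfg.t_osj, cfg.kappa, cfg.omega_osj, rng)
        outg = evolve_codon_array(anc, cfg.t_out, cfg.kappa, cfg.omega_out, rng)
        out.append(
            CodonAlignment(
                gene_id=f"g{gi:04d}", osj=osj, og=og, outgroup=outg, coverage=1.0
            )
        )
    return out


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _phred_profile(n: int, peak: int, tail: int) -> np.ndarray:
    """Sanger-like profile: ramp up, plateau, declining 3' tail."""
    q = np.full(n, peak, dtype=np.int64)
    ramp = min(30, n // 4)
    q[:ramp] = np.linspace(peak - 15, peak, ramp, dtype=np.int64)
    tail_start = int(n * 0.55)
    ntail = n - tail_start
    if ntail > 0:
        q[tail_start:] = np.linspace(peak, tail, ntail).astype(np.int64)
    return np.clip(q, 0, 93)


def simulate_reads(dataset: SimulatedDataset, cfg: SimulationConfig | None = None, seed: int | None = None):
    """Phred-scored shotgun reads from the (soft-masked) Og genome.

    Fragments of ~2 kb are sequenced from both ends; a configured fraction
    of reads comes from an organelle-like contaminant.  Sequencing errors
    are injected at the phred-implied rate 10^(-Q/10).  Returns
    (reads, dataset.truth) with per-read origins recorded in the ledger.
    """
    from .reads import ShotgunRead

    cfg = cfg or dataset.cfg
    rng = np.random.default_rng(dataset.cfg.seed + 7919 if seed is None else seed)
    source = dataset.masked_genome("og")
    L = len(source)
    mean_read = (cfg.read_length[0] + cfg.read_length[1]) / 2
    n_reads = max(2, int(cfg.coverage * L / mean_read))
    reads = []
    for ri in range(n_reads):
        rid = f"read{ri:05d}"
        library = "MF" if rng.random() < 0.5 else "SH"
        contaminant = rng.random() < cfg.contaminant_fraction
        template = dataset.organelle if contaminant else source
        flen = int(rng.integers(*cfg.fragment_length))
        fstart = int(rng.integers(0, max(1, len(template) - flen)))
        rlen = int(rng.integers(*cfg.read_length))
        if rng.random() < 0.5:
            start = fstart
            frag = template[start : start + rlen]
            strand = "+"
        else:
            end = min(fstart + flen, len(template))
            frag = revcomp(template[max(0, end - rlen) : end])
            start = max(0, end - rlen)
            strand = "-"
        n = len(frag)
        if n == 0:
            continue
        phreds = _phred_profile(n, cfg.phred_peak, cfg.phred_tail)
        err_p = 10.0 ** (-phreds / 10.0)
        errs = np.flatnonzero(rng.random(n) < err_p)
        bases = list(frag)
        for e in errs:
            cur = bases[e].upper()
            if cur not in ACGT:
                continue
            choices = [b for b in ACGT if b != cur]
            new = choices[int(rng.integers(0, 3))]
            bases[e] = new.lower() if bases[e].islower() else new
        read = ShotgunRead(
            id=rid, bases="".join(bases), phreds=phreds, library=library
        )
        reads.append(read)
        upper = sum(1 for b in read.bases if b.isupper())
        dataset.truth.read_origins[rid] = {
            "origin": "contaminant" if contaminant else (
                "repeat" if upper < 30 else "genuine"
            ),
            "start": start,
            "strand": strand,
            "length": n,
        }
    return reads, dataset.truth


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_dataset(dataset: SimulatedDataset, out_dir) -> dict:
    """Emit FASTA/GFF3/aligned FASTA/MAF/ledger JSON; returns path map."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name in ("og", "osj", "osi"):
        p = os.path.join(out_dir, f"{name}.fasta")
        seq = dataset.masked_genome(name) if name == "og" else dataset.genome(name)
        with open(p, "w") as fh:
            fh.write(f">chr1 {name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
        paths[f"fasta_{name}"] = p
    p = os.path.join(out_dir, "outgroup_cds.fasta")
    with open(p, "w") as fh:
        for gid, cds in dataset.outgroup_cds.items():
            fh.write(f">{gid}\n{cds}\n")
    paths["fasta_outgroup_cds"] = p
    paths["gff3"] = os.path.join(out_dir, "osj.gff3")
    write_gff3(dataset.genes, paths["gff3"])
    paths["alignment"] = os.path.join(out_dir, "threeway.aln.fasta")
    dataset.aln.write_fasta(paths["alignment"])
    paths["maf"] = os.path.join(out_dir, "threeway.maf")
    dataset.aln.write_maf(paths["maf"])
    paths["ledger"] = os.path.join(out_dir, "ground_truth.json")
    with open(paths["ledger"], "w") as fh:
        json.dump(
            {
                "substitutions": [asdict(s) for s in dataset.truth.substitutions],
                "splice_events": dataset.truth.splice_events,
                "ssr_events": dataset.truth.ssr_events,
                "read_origins": dataset.truth.read_origins,
            },
            fh,
            indent=1,
        )
    return paths


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.phreds)
            fh.write(f"@{r.id} library={r.library}\n{r.bases}\n+\n{qual}\n")
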