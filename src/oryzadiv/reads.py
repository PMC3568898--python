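"""Shotgun-read QC, best-hit selection, consensus construction and contig
statistics.

The pipeline mirrors gene-enrichment shotgun sequencing practice: 3'-end
quality trimming, a length floor, an organelle-contamination screen, a
non-repetitive-content floor on soft-masked reads, unique placement of each
read by (identity, E-value, score), and a per-site consensus where the
highest-phred base wins and methylation-filtration (MF) reads break ties
against subtractive-hybridization (SH) reads.  Mapping itself is a
pluggable interface; a bundled k-mer seed-and-extend toy aligner is
sufficient for simulated reads.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np

from .genes import revcomp


@dataclass
class ShotgunRead:
    id: str
    bases: str  # uppercase = non-repetitive, lowercase = repeat-masked
    phreds: np.ndarray  # same length, each in [0, 93]
    library: str = "SH"  # 'MF' | 'SH'

    def __post_init__(self) -> None:
        self.phreds = np.asarray(self.phreds, dtype=np.int64)
        if len(self.bases) != len(self.phreds):
            raise ValueError(f"{self.id}: bases and phreds differ in length")
        if self.library not in ("MF", "SH"):
            raise ValueError(f"{self.id}: unknown library {self.library!r}")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class QCConfig:
    trim_phred_below: int = 15
    min_length: int = 100
    organelle_min_identity: float = 95.0
    organelle_max_evalue: float = 1.0e-10
    organelle_min_coverage: float = 90.0
    min_nonrepeat_bp: int = 30
    map_min_identity: float = 90.0
    map_max_evalue: float = 1.0e-10


@dataclass(frozen=True)
class ConsensusConfig:
    min_depth: int = 2
    min_phred: int = 20

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


def trim_3prime(read: ShotgunRead, cfg: QCConfig = QCConfig()) -> ShotgunRead:
    """Remove the maximal 3' suffix whose phred scores are all below threshold."""
    keep = len(read)
    while keep > 0 and read.phreds[keep - 1] < cfg.trim_phred_below:
        keep -= 1
    if keep == len(read):
        return read
    return replace(read, bases=read.bases[:keep], phreds=read.phreds[:keep])


@dataclass(frozen=True)
class RejectedRead:
    read: ShotgunRead
    reason: str  # first failing rule: 'length' | 'organelle' | 'non-repeat'


OrganelleScreen = Callable[[ShotgunRead], tuple[float, float, float] | None]


def filter_reads(
    reads: Iterable[ShotgunRead],
    cfg: QCConfig = QCConfig(),
    organelle_screen: OrganelleScreen | None = None,
) -> tuple[list[ShotgunRead], list[RejectedRead]]:
    """Apply, in order: length floor, organelle screen, non-repeat floor.

    The organelle screen backend returns (identity %, E-value, coverage %)
    of the best organelle hit, or None; a read is rejected only when all
    three thresholds are met.  Each rejection carries its first failing rule.
    """
    kept, rejected = [], []
    for read in reads:
        if len(read) < cfg.min_length:
            rejected.append(RejectedRead(read, "length"))
            continue
        if organelle_screen is not None:
            hit = organelle_screen(read)
            if hit is not None:
                ident, evalue, cov = hit
                if (
                    ident >= cfg.organelle_min_identity
                    and evalue <= cfg.organelle_max_evalue
                    and cov >= cfg.organelle_min_coverage
                ):
                    rejected.append(RejectedRead(read, "organelle"))
                    continue
        nonrepeat = sum(1 for b in read.bases if b.isupper())
        if nonrepeat < cfg.min_nonrepeat_bp:
            rejected.append(RejectedRead(read, "non-repeat"))
            continue
        kept.append(read)
    return kept, rejected


@dataclass(frozen=True)
class HitCandidate:
    read_id: str
    chrom: str
    start: int
    end: int  # 0-based half-open on the reference
    identity: float  # percent
    evalue: float
    score: float
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("empty hit interval")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity outside [0, 100]")


def select_best_hit(
    candidates: Sequence[HitCandidate], cfg: QCConfig = QCConfig()
) -> HitCandidate | None:
    """Unique placement: highest identity, then lowest E-value, then highest
    score; full ties broken by lowest (chrom, start) then strand."""
    ok = [
        c
        for c in candidates
        if c.identity >= cfg.map_min_identity and c.evalue <= cfg.map_max_evalue
    ]
    if not ok:
        return None
    return min(ok, key=lambda c: (-c.identity, c.evalue, -c.score, c.chrom, c.start, c.strand))


# ---------------------------------------------------------------------------
# Toy k-mer aligner (pluggable mapping backend for synthetic reads)
# ---------------------------------------------------------------------------

class KmerAligner:
    """Exact-seed / Hamming-extend aligner over one reference sequence.

    Not a general-purpose mapper: reads are assumed to map gap-free, as the
    simulator guarantees.  Identity is the percent of matching bases over
    the read; the reported E-value decays with the match count so that the
    best-hit ordering behaves like a similarity search."""

    def __init__(self, reference: str, chrom: str = "chr1", k: int = 21):
        self.ref = reference.upper()
        self.chrom = chrom
        self.k = k
        self.index: dict[str, list[int]] = defaultdict(list)
        for i in range(0, len(self.ref) - k + 1):
            self.index[self.ref[i : i + k]].append(i)

    def _candidates(self, seq: str) -> set[int]:
        starts: set[int] = set()
        k = self.k
        for off in range(0, max(1, len(seq) - k + 1), k):
            for hit in self.index.get(seq[off : off + k], ()):
                starts.add(hit - off)
        return starts

    def map_read(self, read: ShotgunRead, cfg: QCConfig = QCConfig()) -> list[HitCandidate]:
        out = []
        for strand, seq in (("+", read.bases.upper()), ("-", revcomp(read.bases.upper()))):
            n = len(seq)
            for start in self._candidates(seq):
                if start < 0 or start + n > len(self.ref):
                    continue
                matches = sum(1 for a, b in zip(seq, self.ref[start : start + n]) if a == b)
                identity = 100.0 * matches / n
                if identity < cfg.map_min_identity:
                    continue
                evalue = 10.0 ** (-min(180.0, matches / 4.0))
                out.append(
                    HitCandidate(
                        read_id=read.id, chrom=self.chrom, start=start, end=start + n,
                        identity=identity, evalue=evalue, score=float(matches),
                        strand=strand,
                    )
                )
        return out


def make_organelle_screen(organelle: str, k: int = 21) -> OrganelleScreen:
    """Similarity backend over an organelle reference using the toy aligner."""
    idx = KmerAligner(organelle, chrom="organelle", k=k)

    def screen(read: ShotgunRead):
        hits = idx.map_read(read, QCConfig(map_min_identity=0.0, map_max_evalue=1.0))
        if not hits:
            return None
        best = max(hits, key=lambda h: h.identity)
        coverage = 100.0 * (best.end - best.start) / len(read)
        return best.identity, best.evalue, coverage

    return screen


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

@dataclass
class MappedRead:
    read: ShotgunRead
    start: int  # reference offset of read base 0 (gap-free placement)
    strand: str = "+"

    def oriented(self) -> tuple[str, np.ndarray]:
        if self.strand == "+":
            return self.read.bases.upper(), self.read.phreds
        return revcomp(self.read.bases).upper(), self.read.phreds[::-1]


@dataclass
class ConsensusSite:
    base: str  # consensus call, or 'N' when ambiguous
    depth: int
    best_phred: int
    ambiguous: bool
    evidence: list  # (base, phred, library) per covering read


@dataclass
class Consensus:
    sites: dict  # ref position -> ConsensusSite
    contigs: list  # maximal covered [start, end) intervals

    def coverage_bp(self) -> int:
        return sum(e - s for s, e in self.contigs)


_LIB_RANK = {"MF": 1, "SH": 0}


def build_consensus(mapped: Iterable[MappedRead], cfg: ConsensusConfig = ConsensusConfig()) -> Consensus:
    """Per-site consensus: agreement, else highest phred, phred ties prefer
    MF over SH, remaining ties are ambiguous.  Contigs are maximal runs of
    covered reference positions."""
    evidence: dict[int, list] = defaultdict(list)
    for m in mapped:
        bases, phreds = m.oriented()
        for i, (b, q) in enumerate(zip(bases, phreds)):
            evidence[m.start + i].append((b, int(q), m.read.library))
    sites = {}
    for pos, ev in evidence.items():
        bases = {b for b, _, _ in ev}
        ambiguous = False
        if len(bases) == 1:
            call = next(iter(bases))
        else:
            best = max(ev, key=lambda t: (t[1], _LIB_RANK[t[2]]))
            rivals = [
                t for t in ev
                if t[1] == best[1] and _LIB_RANK[t[2]] == _LIB_RANK[best[2]] and t[0] != best[0]
            ]
            if rivals:
                call, ambiguous = "N", True
            else:
                call = best[0]
        sites[pos] = ConsensusSite(
            base=call,
            depth=len(ev),
            best_phred=max(q for _, q, _ in ev),
            ambiguous=ambiguous,
            evidence=ev,
        )
    contigs = _runs(sorted(sites))
    return Consensus(sites=sites, contigs=contigs)


def _runs(positions: list[int]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for p in positions:
        if out and out[-1][1] == p:
            out[-1] = (out[-1][0], p + 1)
        else:
            out.append((p, p + 1))
    return [tuple(iv) for iv in out]


def supported_sites(consensus: Consensus, cfg: ConsensusConfig = ConsensusConfig()) -> dict[int, str]:
    """Sites backed by >= min_depth reads at phred >= min_phred, called by
    strict majority among the qualifying reads; exact ties are excluded."""
    out = {}
    for pos, site in consensus.sites.items():
        qual = [(b, q) for b, q, _ in site.evidence if q >= cfg.min_phred]
        if len(qual) < cfg.min_depth:
            continue
        counts: dict[str, int] = defaultdict(int)
        for b, _ in qual:
            counts[b] += 1
        ranked = sorted(counts.items(), key=lambda kv: -kv[1])
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            continue  # majority tie
        out[pos] = ranked[0][0]
    return out


# ---------------------------------------------------------------------------
# Contig statistics
# ---------------------------------------------------------------------------

def n50(lengths: Sequence[int]) -> int:
    """Largest L such that contigs of length >= L hold half the total bases."""
    if not lengths:
        raise ValueError("no contigs")
    total = sum(lengths)
    acc = 0
    for x in sorted(lengths, reverse=True):
        acc += x
        if 2 * acc >= total:
            return x
    return min(lengths)


def contig_stats(
    contigs: Sequence[tuple[int, int]],
    reference_length: int | None = None,
    annotation: dict[int, str] | None = None,
) -> dict:
    """Count, total bp, N50, reference coverage and per-class composition."""
    lengths = [e - s for s, e in contigs]
    stats = {
        "count": len(contigs),
        "total_bp": sum(lengths),
        "n50": n50(lengths) if lengths else 0,
    }
    if reference_length is not None:
        covered = set()
        for s, e in contigs:
            covered.update(range(s, e))
        stats["reference_coverage_bp"] = len(covered)
    if annotation is not None:
        comp: dict[str, int] = defaultdict(int)
        for s, e in contigs:
            for i in range(s, e):
                comp[annotation.get(i, "non-transcribed")] += 1
        stats["composition_bp"] = dict(comp)
    return stats


def read_fastq(path) -> list[ShotgunRead]:
    """Read phred-scored reads; the library tag is taken from the header."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        lib = "SH"
        if "library=" in rec.description:
            lib = rec.description.split("library=")[1].split()[0]
        out.append(
            ShotgunRead(
                id=rec.id,
                bases=str(rec.seq),
                phreds=np.array(rec.letter_annotations["phred_quality"]),
                library=lib,
            )
        )
    return out
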