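"""Codon-level selection analyses for the three-taxon comparison
(O. glaberrima, O. sativa japonica, outgroup).

Implements the modified Nei–Gojobori method (transition/transversion-weighted
potential-site counting followed by pathway-averaged difference counting and
Jukes–Cantor correction), gamma-corrected Poisson amino-acid distances,
exact three-taxon least-squares branch lengths, parsimony assignment of
substitutions to lineages, amino-acid property-change tests, and the
per-lineage dN/dS summary with a gene-resampling bootstrap.

Codons are encoded as integers 0..63 with base order T, C, A, G so that all
pairwise quantities reduce to 64x64 table lookups; the tables themselves are
built once per transition/transversion weight R by enumerating substitution
pathways.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np

from .stats import (
    BootstrapConfig,
    ContingencyTable2x2,
    InsufficientDataError,
    TestResult,
    gtest_2x2,
)

BASES = "TCAG"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

# Standard genetic code, laid out in TCAG nested order.
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
AA_BY_CODON = np.array(list(_AA))
IS_STOP = AA_BY_CODON == "*"
STOP_CODONS = {CODONS[i] for i in np.flatnonzero(IS_STOP)}

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


def is_transition(b1: str, b2: str) -> bool:
    return b1 != b2 and (
        (b1 in PURINES and b2 in PURINES) or (b1 in PYRIMIDINES and b2 in PYRIMIDINES)
    )


def encode_codons(seq: str) -> np.ndarray:
    """Encode an in-frame nucleotide string as an array of codon indices."""
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError("sequence length is not a multiple of 3")
    idx = np.empty(len(seq) // 3, dtype=np.int64)
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon not in CODON_INDEX:
            raise ValueError(f"non-ACGT codon {codon!r} at position {i}")
        idx[i // 3] = CODON_INDEX[codon]
    return idx


def decode_codons(idx: Iterable[int]) -> str:
    return "".join(CODONS[i] for i in idx)


def translate(idx: Iterable[int]) -> str:
    return "".join(AA_BY_CODON[i] for i in idx)


@dataclass(frozen=True)
class MNGParams:
    """Transition/transversion weight R for modified Nei-Gojobori counting.

    The default follows the genome-wide transition/transversion ratio
    observed between the African and Asian rice genomes (1.72).
    """

    R: float = 1.72

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("R must be positive")


@dataclass(frozen=True)
class GammaPoissonParams:
    """Gamma shape for the gamma-corrected Poisson amino-acid distance."""

    a: float = 2.25

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("gamma shape must be positive")


class SaturationError(ValueError):
    """A proportion of differences too large for the distance correction."""


def gamma_poisson_distance(p: float, params: GammaPoissonParams = GammaPoissonParams()) -> float:
    """Gamma-corrected Poisson distance d = a * ((1-p)^(-1/a) - 1).

    ``p`` is the proportion of differing amino-acid sites.  As the shape
    parameter a -> infinity the distance tends to the plain Poisson
    correction -ln(1-p).
    """
    if not 0.0 <= p < 1.0:
        raise SaturationError("proportion of differences must be in [0, 1)")
    a = params.a
    return a * ((1.0 - p) ** (-1.0 / a) - 1.0)


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor correction d = -(3/4) ln(1 - (4/3) p)."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        raise SaturationError("p >= 3/4 saturates the Jukes-Cantor correction")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


# ---------------------------------------------------------------------------
# Modified Nei-Gojobori machinery
# ---------------------------------------------------------------------------

def _neighbors(codon_idx: int):
    """All 9 single-base neighbours as (position, new_base, new_idx, is_ts)."""
    codon = CODONS[codon_idx]
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            new = codon[:pos] + b + codon[pos + 1 :]
            yield pos, b, CODON_INDEX[new], is_transition(codon[pos], b)


@lru_cache(maxsize=8)
def _site_count_table(R: float) -> np.ndarray:
    """Per-codon synonymous potential-site count s, weighted by R.

    Each position contributes weight R/(R+2) for its transition and 1/(R+2)
    for each transversion; s sums the weights of synonymous changes.  Changes
    to stop codons are never synonymous, so they fall on the nonsynonymous
    side (n = 3 - s per codon).  Stop codons get s = NaN.
    """
    s = np.full(64, np.nan)
    w_ts = R / (R + 2.0)
    w_tv = 1.0 / (R + 2.0)
    for ci in range(64):
        if IS_STOP[ci]:
            continue
        total = 0.0
        for _pos, _b, ni, ts in _neighbors(ci):
            if not IS_STOP[ni] and AA_BY_CODON[ni] == AA_BY_CODON[ci]:
                total += w_ts if ts else w_tv
        s[ci] = total
    return s


def mng_site_counts(codon_indices: np.ndarray, params: MNGParams = MNGParams()) -> tuple[float, float]:
    """Weighted synonymous (S) and nonsynonymous (N) potential site counts.

    S + N = 3 * number of codons for any R.
    """
    idx = np.asarray(codon_indices)
    if np.any(IS_STOP[idx]):
        raise ValueError("stop codon in coding sequence")
    s = float(_site_count_table(params.R)[idx].sum())
    return s, 3.0 * len(idx) - s


@lru_cache(maxsize=4)
def _pathway_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """64x64 pathway-averaged (Sd, Nd) difference counts and a validity mask.

    For a codon pair differing at k positions, every one of the k! orders of
    introducing the differences is a pathway; pathways passing through a stop
    codon are excluded, and Sd/Nd are the means over the remaining pathways
    of the synonymous / nonsynonymous step counts.  Pairs whose every pathway
    crosses a stop (and pairs involving a stop codon) are marked invalid.
    """
    sd = np.zeros((64, 64))
    nd = np.zeros((64, 64))
    valid = np.zeros((64, 64), dtype=bool)
    for x in range(64):
        if IS_STOP[x]:
            continue
        cx = CODONS[x]
        for y in range(64):
            if IS_STOP[y]:
                continue
            cy = CODONS[y]
            diff = [i for i in range(3) if cx[i] != cy[i]]
            if not diff:
                valid[x, y] = True
                continue
            syn_tot = nonsyn_tot = 0.0
            n_paths = 0
            for order in itertools.permutations(diff):
                cur = cx
                syn = nonsyn = 0
                ok = True
                for pos in order:
                    nxt = cur[:pos] + cy[pos] + cur[pos + 1 :]
                    if nxt in STOP_CODONS:
                        ok = False
                        break
                    if AA_BY_CODON[CODON_INDEX[nxt]] == AA_BY_CODON[CODON_INDEX[cur]]:
                        syn += 1
                    else:
                        nonsyn += 1
                    cur = nxt
                if ok:
                    syn_tot += syn
                    nonsyn_tot += nonsyn
                    n_paths += 1
            if n_paths:
                sd[x, y] = syn_tot / n_paths
                nd[x, y] = nonsyn_tot / n_paths
                valid[x, y] = True
    return sd, nd, valid


@dataclass(frozen=True)
class PairwiseDistances:
    Sd: float
    Nd: float
    S: float
    N: float
    pS: float
    pN: float
    dS: float
    dN: float
    skipped_codons: int = 0


def mng_pair_counts(
    x: np.ndarray, y: np.ndarray, params: MNGParams = MNGParams()
) -> tuple[float, float, float, float, int]:
    """Raw (Sd, Nd, S_bar, N_bar, skipped) for a pair of codon sequences.

    Site counts are averaged over the two sequences; codon pairs with no
    stop-free substitution pathway are skipped and counted.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("sequences differ in length")
    sd_t, nd_t, valid = _pathway_tables()
    ok = valid[x, y]
    skipped = int((~ok).sum())
    xs, ys = x[ok], y[ok]
    sx, nx = mng_site_counts(xs, params)
    sy, ny = mng_site_counts(ys, params)
    return (
        float(sd_t[xs, ys].sum()),
        float(nd_t[xs, ys].sum()),
        (sx + sy) / 2.0,
        (nx + ny) / 2.0,
        skipped,
    )


def mng_pairwise(x: np.ndarray, y: np.ndarray, params: MNGParams = MNGParams()) -> PairwiseDistances:
    """Modified Nei-Gojobori synonymous/nonsynonymous distances for a pair."""
    sd, nd, s_bar, n_bar, skipped = mng_pair_counts(x, y, params)
    ps = sd / s_bar if s_bar > 0 else 0.0
    pn = nd / n_bar if n_bar > 0 else 0.0
    return PairwiseDistances(
        Sd=sd, Nd=nd, S=s_bar, N=n_bar, pS=ps, pN=pn,
        dS=jukes_cantor(ps), dN=jukes_cantor(pn), skipped_codons=skipped,
    )


# ---------------------------------------------------------------------------
# Three-taxon machinery
# ---------------------------------------------------------------------------

def ls_branch_lengths(d_xy: float, d_xo: float, d_yo: float) -> tuple[np.ndarray, bool]:
    """Exact least-squares branch lengths for an unrooted three-taxon star.

    Returns (b_x, b_y, b_o) and a flag set when any solution was negative
    and clamped to zero (a triangle-inequality violation in the inputs).
    """
    b = np.array(
        [
            (d_xy + d_xo - d_yo) / 2.0,
            (d_xy + d_yo - d_xo) / 2.0,
            (d_xo + d_yo - d_xy) / 2.0,
        ]
    )
    clamped = bool(np.any(b < 0))
    return np.clip(b, 0.0, None), clamped


def assign_lineage_specific(og, osj, outgroup) -> str:
    """Parsimony assignment of a three-taxon site pattern to a lineage.

    Returns 'Og', 'Osj', 'none' (no change, or change on the outgroup /
    internal branch) or 'ambiguous' (three distinct states).
    """
    if og is None or osj is None or outgroup is None:
        raise ValueError("missing state")
    if og == osj:
        return "none"
    if osj == outgroup:
        return "Og"
    if og == outgroup:
        return "Osj"
    return "ambiguous"


# ---------------------------------------------------------------------------
# Alignment container and filters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentFilter:
    min_aa: int = 100
    min_coverage: float = 0.70
    trim_termini_aa: int = 10

    def __post_init__(self) -> None:
        if self.min_aa < 1:
            raise ValueError("min_aa must be >= 1")
        if not 0.0 < self.min_coverage <= 1.0:
            raise ValueError("min_coverage must be in (0, 1]")


@dataclass
class CodonAlignment:
    """Gap-free three-taxon in-frame alignment keyed on the reference (Osj).

    ``counted`` masks out the trimmed termini; only counted columns enter
    substitution counting and distances.
    """

    gene_id: str
    osj: np.ndarray
    og: np.ndarray
    outgroup: np.ndarray
    coverage: float
    counted: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.osj)
        if len(self.og) != n or len(self.outgroup) != n:
            raise ValueError("taxa differ in aligned length")
        if self.counted is None:
            self.counted = np.ones(n, dtype=bool)

    def __len__(self) -> int:
        return len(self.osj)


@dataclass(frozen=True)
class RejectedAlignment:
    gene_id: str
    reason: str


def build_codon_alignment(
    gene_id: str,
    osj_cds: str,
    og_aligned: Mapping[int, str],
    outgroup_aligned: Mapping[int, str],
    filt: AlignmentFilter = AlignmentFilter(),
):
    """Integrate two pairwise alignments into a three-taxon codon alignment.

    ``og_aligned`` / ``outgroup_aligned`` map reference codon index -> the
    aligned codon of that taxon ('---' marks a gap).  The alignment is
    rejected if either taxon carries a gap or a premature stop codon within
    its aligned span, or if it fails the length/coverage filter
    (>= min_aa aligned codons OR coverage > min_coverage).  The first and
    last ``trim_termini_aa`` codons are flagged as not counted.
    """
    if len(osj_cds) % 3 != 0:
        raise ValueError(f"{gene_id}: CDS length not a multiple of 3")
    ref = encode_codons(osj_cds)
    n_ref = len(ref)
    if n_ref and IS_STOP[ref[-1]]:
        ref = ref[:-1]
        n_ref -= 1
    common = sorted(set(og_aligned) & set(outgroup_aligned))
    cols_ref, cols_og, cols_out = [], [], []
    for i in common:
        if not 0 <= i < n_ref:
            continue
        for taxon, codon in (("og", og_aligned[i]), ("outgroup", outgroup_aligned[i])):
            if "-" in codon:
                return RejectedAlignment(gene_id, f"gap in {taxon}")
        cols_ref.append(ref[i])
        cols_og.append(CODON_INDEX[og_aligned[i].upper()])
        cols_out.append(CODON_INDEX[outgroup_aligned[i].upper()])
    og_arr = np.array(cols_og, dtype=np.int64)
    out_arr = np.array(cols_out, dtype=np.int64)
    if og_arr.size and np.any(IS_STOP[og_arr]):
        return RejectedAlignment(gene_id, "premature stop in og")
    if out_arr.size and np.any(IS_STOP[out_arr]):
        return RejectedAlignment(gene_id, "premature stop in outgroup")
    n_aa = len(cols_ref)
    coverage = n_aa / n_ref if n_ref else 0.0
    if not (n_aa >= filt.min_aa or coverage > filt.min_coverage):
        return RejectedAlignment(gene_id, "below length/coverage filter")
    counted = np.ones(n_aa, dtype=bool)
    t = filt.trim_termini_aa
    if t > 0:
        counted[:t] = False
        if t <= n_aa:
            counted[n_aa - t :] = False
    return CodonAlignment(
        gene_id=gene_id,
        osj=np.array(cols_ref, dtype=np.int64),
        og=og_arr,
        outgroup=out_arr,
        coverage=coverage,
        counted=counted,
    )


# ---------------------------------------------------------------------------
# Amino-acid property schemes
# ---------------------------------------------------------------------------

DEFAULT_PROPERTY_SCHEMES: dict[str, dict[str, str]] = {
    # Four documented default partitions of the 20 amino acids; users can
    # substitute their own published classifications via PropertyScheme.
    "charge": {
        "positive": "KRH",
        "negative": "DE",
        "neutral": "ACFGILMNPQSTVWY",
    },
    "polarity": {
        "polar": "CDEHKNQRSTWY",
        "nonpolar": "AFGILMPV",
    },
    "volume": {
        "small": "AGSCDNPT",
        "medium": "EHQV",
        "large": "FIKLMRWY",
    },
    "hydropathy": {
        "hydrophobic": "ACFILMV",
        "hydrophilic": "DEHKNQR",
        "neutral": "GPSTWY",
    },
}


@dataclass(frozen=True)
class PropertyScheme:
    name: str
    classes: Mapping[str, str]

    def __post_init__(self) -> None:
        joined = "".join(self.classes.values())
        if len(set(joined)) != 20 or len(joined) != 20:
            raise ValueError(f"scheme {self.name}: classes must partition the 20 amino acids")

    def class_of(self, aa: str) -> str:
        for name, members in self.classes.items():
            if aa in members:
                return name
        raise KeyError(aa)

    def is_change(self, aa_from: str, aa_to: str) -> bool:
        return self.class_of(aa_from) != self.class_of(aa_to)


def default_schemes() -> list[PropertyScheme]:
    return [PropertyScheme(k, v) for k, v in DEFAULT_PROPERTY_SCHEMES.items()]


def property_change_test(
    substitutions: Mapping[str, Sequence[tuple[str, str]]],
    scheme: PropertyScheme,
) -> TestResult:
    """G-test of lineage x {class-preserving, class-changing} substitutions.

    ``substitutions`` maps each of two lineage labels to its ordered
    (from_aa, to_aa) residue pairs.
    """
    lineages = list(substitutions)
    if len(lineages) != 2:
        raise ValueError("exactly two lineages required")
    rows = []
    for lin in lineages:
        subs = substitutions[lin]
        if not subs:
            raise InsufficientDataError(f"no substitutions in lineage {lin}")
        changing = sum(1 for a, b in subs if scheme.is_change(a, b))
        rows.append((len(subs) - changing, changing))
    (p1, c1), (p2, c2) = rows
    if (c1 == c2 == 0) or (p1 == p2 == 0):
        # all substitutions fall in one column: proportions are equal, G = 0
        return TestResult(statistic=0.0, df=1, p_value=1.0)
    return gtest_2x2(ContingencyTable2x2(p1, c1, p2, c2))


# ---------------------------------------------------------------------------
# Per-lineage dN/dS over a gene set
# ---------------------------------------------------------------------------

@dataclass
class BranchDistances:
    """Per-lineage synonymous / nonsynonymous branch lengths and omega."""

    bN: dict
    bS: dict
    omega: dict
    omega_sd: dict
    lineage_counts: dict  # lineage -> (nonsyn, syn) lineage-specific counts
    count_gtest: TestResult | None
    clamped: bool


PAIRS = (("og", "osj"), ("og", "outgroup"), ("osj", "outgroup"))


def _per_gene_pair_counts(alignments: Sequence[CodonAlignment], params: MNGParams):
    """Per-gene (Sd, Nd, S, N) arrays for the three taxon pairs."""
    arrays = {pair: np.zeros((len(alignments), 4)) for pair in PAIRS}
    for gi, aln in enumerate(alignments):
        mask = aln.counted
        seqs = {"og": aln.og[mask], "osj": aln.osj[mask], "outgroup": aln.outgroup[mask]}
        for pair in PAIRS:
            sd, nd, s, n, _ = mng_pair_counts(seqs[pair[0]], seqs[pair[1]], params)
            arrays[pair][gi] = (sd, nd, s, n)
    return arrays


def _jc_vec(p: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return np.where(p < 0.75, -0.75 * np.log1p(-4.0 * np.minimum(p, 0.7499) / 3.0), np.nan)


def _branch_omegas_from_sums(sums: dict) -> tuple[dict, dict, dict, bool]:
    """Summed pair counts -> JC distances -> LS branches -> omega per lineage.

    ``sums`` maps pair -> array (..., 4) of summed (Sd, Nd, S, N); all
    arithmetic broadcasts, so bootstrap replicates come through vectorized.
    """
    dn = {}
    ds = {}
    for pair in PAIRS:
        sd, nd, s, n = (sums[pair][..., i] for i in range(4))
        ds[pair] = _jc_vec(np.divide(sd, s, out=np.zeros_like(sd), where=s > 0))
        dn[pair] = _jc_vec(np.divide(nd, n, out=np.zeros_like(nd), where=n > 0))

    def branches(d):
        d_xy, d_xo, d_yo = d[PAIRS[0]], d[PAIRS[1]], d[PAIRS[2]]
        b_og = np.clip((d_xy + d_xo - d_yo) / 2.0, 0.0, None)
        b_osj = np.clip((d_xy + d_yo - d_xo) / 2.0, 0.0, None)
        b_out = np.clip((d_xo + d_yo - d_xy) / 2.0, 0.0, None)
        clamped = bool(
            np.any((d_xy + d_xo - d_yo) < 0)
            or np.any((d_xy + d_yo - d_xo) < 0)
            or np.any((d_xo + d_yo - d_xy) < 0)
        )
        return {"Og": b_og, "Osj": b_osj, "outgroup": b_out}, clamped

    bn, cl1 = branches(dn)
    bs, cl2 = branches(ds)
    with np.errstate(divide="ignore", invalid="ignore"):
        omega = {
            lin: np.where(bs[lin] > 0, bn[lin] / np.where(bs[lin] > 0, bs[lin], 1.0), np.nan)
            for lin in ("Og", "Osj")
        }
    return bn, bs, omega, (cl1 or cl2)


def lineage_specific_counts(alignments: Sequence[CodonAlignment]) -> dict:
    """Lineage-specific nonsynonymous/synonymous substitution counts.

    Codon columns are assigned to a lineage by parsimony; the change between
    the derived codon and the shared (ancestral) codon is split into
    synonymous and nonsynonymous steps by pathway averaging.
    """
    sd_t, nd_t, valid = _pathway_tables()
    totals = {"Og": [0.0, 0.0], "Osj": [0.0, 0.0]}  # [nonsyn, syn]
    for aln in alignments:
        mask = aln.counted
        og, osj, out = aln.og[mask], aln.osj[mask], aln.outgroup[mask]
        og_specific = (og != osj) & (osj == out)
        osj_specific = (osj != og) & (og == out)
        for lin, derived, ancestral, sel in (
            ("Og", og, osj, og_specific),
            ("Osj", osj, og, osj_specific),
        ):
            d, a = derived[sel], ancestral[sel]
            ok = valid[a, d]
            totals[lin][0] += float(nd_t[a[ok], d[ok]].sum())
            totals[lin][1] += float(sd_t[a[ok], d[ok]].sum())
    return {lin: tuple(v) for lin, v in totals.items()}


def lineage_dnds(
    alignments: Sequence[CodonAlignment],
    params: MNGParams = MNGParams(),
    boot: BootstrapConfig = BootstrapConfig(),
) -> BranchDistances:
    """Per-lineage dN/dS with bootstrap SDs and the substitution-count G-test.

    Pairwise Sd/Nd/S/N are concatenated over genes, corrected, and resolved
    into per-lineage branch lengths; omega = bN/bS per ingroup lineage.  The
    bootstrap resamples genes.  The G-test compares lineage-specific
    nonsynonymous vs synonymous substitution totals between the two ingroup
    lineages (counts rounded to integers).
    """
    if len(alignments) < 2:
        raise InsufficientDataError("need at least 2 alignments")
    arrays = _per_gene_pair_counts(alignments, params)
    n_genes = len(alignments)
    sums = {pair: arrays[pair].sum(axis=0) for pair in PAIRS}
    bn_a, bs_a, omega_a, clamped = _branch_omegas_from_sums(sums)
    bn = {k: float(v) for k, v in bn_a.items()}
    bs = {k: float(v) for k, v in bs_a.items()}
    omega = {k: float(v) for k, v in omega_a.items()}

    # Gene-resampling bootstrap, vectorized across replicates.
    rng = np.random.default_rng(boot.seed)
    idx = rng.integers(0, n_genes, size=(boot.n_replicates, n_genes))
    rep_sums = {pair: arrays[pair][idx].sum(axis=1) for pair in PAIRS}
    _, _, rep_omega, _ = _branch_omegas_from_sums(rep_sums)
    omega_sd = {
        lin: float(np.nanstd(rep_omega[lin], ddof=1)) for lin in ("Og", "Osj")
    }

    counts = lineage_specific_counts(alignments)
    (n_og, s_og), (n_osj, s_osj) = counts["Og"], counts["Osj"]
    table = ContingencyTable2x2(round(n_og), round(s_og), round(n_osj), round(s_osj))
    try:
        gres = gtest_2x2(table)
    except Exception:
        gres = None
    return BranchDistances(
        bN=bn, bS=bs, omega=omega, omega_sd=omega_sd,
        lineage_counts=counts, count_gtest=gres, clamped=clamped,
    )


def mutual_best_hits(scores: Mapping[tuple[str, str], float]) -> list[tuple[str, str]]:
    """Toy mutual-best-hit ortholog assignment over (query, subject) scores."""
    best_a: dict[str, tuple[str, float]] = {}
    best_b: dict[str, tuple[str, float]] = {}
    for (a, b), s in scores.items():
        if a not in best_a or s > best_a[a][1]:
            best_a[a] = (b, s)
        if b not in best_b or s > best_b[b][1]:
            best_b[b] = (a, s)
    return sorted(
        (a, b) for a, (b, _) in best_a.items() if best_b.get(b, (None,))[0] == a
    )
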