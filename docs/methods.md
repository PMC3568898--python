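# Methods

`oryzadiv` re-implements, as a tested analysis pipeline, a comparative
evolutionary study of the African cultivated rice genome (*Oryza
glaberrima*, Og) against the two Asian subspecies (*O. sativa* ssp.
*japonica*, Osj, and ssp. *indica*, Osi), with *Sorghum bicolor* as the
outgroup for polarizing coding-sequence changes.  The original study ran on
gene-enriched shotgun reads and the full rice genomes; this package
implements the same decision rules and estimators and validates them on
synthetic three-genome data with complete ground truth.

## Statistical kernel

**G-test.** Every enrichment comparison uses the log-likelihood-ratio test
of independence on a 2×2 table: G = 2·Σ O_ij ln(O_ij/E_ij), expected counts
from the margins, 0·ln 0 ≡ 0, P from the χ² df=1 upper tail.  No Williams
or continuity correction is applied by default: the uncorrected statistic
reproduces all printed enrichment P-values to their printed precision, so
it is evidently what was used; the Williams correction is exposed as an
option.  Tables with a zero margin are rejected rather than patched with
pseudo-counts.

**Tajima relative rate test.** From the counts m1, m2 of sites where
exactly one ingroup taxon differs from the other ingroup taxon and the
outgroup: χ² = (m1−m2)²/(m1+m2), df = 1.

**Bootstrap.** Standard deviations of dN/dS are obtained by resampling
*genes* (not sites) with replacement, 1000 replicates by default,
deterministic given a seed.  Genes are the natural exchangeable unit here
because all pairwise counts are accumulated per gene before concatenation.

## Read processing

Rules, applied in order, with defaults as in the original procedure:
3′-end trimming of the maximal all-below-15 phred suffix; discard of reads
< 100 bp; discard of reads hitting the organelle screen at ≥ 95 % identity,
E ≤ 1e-10 and ≥ 90 % coverage; discard of reads with < 30 bp of
non-repetitive (uppercase, soft-masked input) sequence.  Mapping is a
pluggable interface — the scientific content of this stage is the
*selection* rule (highest identity, then lowest E-value, then highest
score) and the *consensus* rule (agreeing base, else highest phred, phred
ties resolved in favour of methylation-filtration reads over
subtractive-hybridization reads, remaining ties ambiguous), not the
aligner.  A bundled k-mer seed/Hamming-extend toy aligner is sufficient for
the simulator's gap-free reads.  Where the original similarity search is
BLASTN, its stated parameters are carried as configuration metadata only.

Two policies the source procedure leaves open are fixed here and flagged as
artifact policy: exact best-hit ties break deterministically by lowest
(chrom, start, strand); majority ties among phred ≥ 20 reads at a site are
excluded from the substitution-analysis site set (conservative).

Sites feeding divergence analysis additionally require support by ≥ 2 reads
at phred ≥ 20 with a strict majority call.  N50 is the largest L such that
contigs ≥ L contain at least half the assembled bases.

## Divergence windows

Substitutions are counted in 10-kb windows with 10-kb steps, anchored at
position 0 of each chromosome, half-open intervals; windows without a
single comparable site are flagged `no_data`, distinct from observed zero.
"Non-exonic" means the complement of all annotated exons (introns plus
intergenic); "non-transcribed" means the complement of all transcripts.
Both terms appear in the source and the distinction matters: windows use
non-exonic sites, SSR region classes use non-transcribed.  The ts/tv ratio
is transitions/transversions over comparable differing sites; the genome
pair and site scope are caller options because the original scope is not
fully specified.

## Codon-level selection analysis

Three-taxon in-frame alignments keyed on Osj codons integrate the Osj–Og
and Osj–outgroup pairwise alignments.  Alignments with gaps or premature
stops in Og or the outgroup are discarded; acceptance requires ≥ 100
aligned amino acids *or* > 70 % coverage of the reference protein; 10
residues at each terminus are excluded from counting.

**Modified Nei–Gojobori.** Potential synonymous sites weight each possible
transition R/(R+2) and each transversion 1/(R+2); S is the sum of weights
of synonymous single-base changes, N = 3L − S.  Changes to stop codons are
never synonymous, so they sit on the nonsynonymous side of the ledger
(NG86 convention).  Observed differences are pathway-averaged: for a codon
pair differing at k positions all k! substitution orders contribute equally,
orders passing through a stop codon are excluded, and a pair whose every
pathway crosses a stop is skipped and counted.  pS = Sd/S̄ and pN = Nd/N̄
(site counts averaged over the two sequences) receive the Jukes–Cantor
correction d = −(3/4)ln(1 − 4p/3).  All pairwise quantities are realized as
64×64 lookup tables built once per R by explicit pathway enumeration.

R defaults to 1.72, the genome-wide ts/tv ratio the windowed analysis
reports, and is configurable; the value used by the original run is not
stated.

**Branch lengths and ω.** For three taxa the least-squares solution is the
exact closed form b_x = (d_xy + d_xo − d_yo)/2 (cyclically); negative
solutions are clamped to zero and flagged.  Per-gene (Sd, Nd, S, N) are
summed over genes *before* correction ("concatenation"); per-gene averaging
is available but concatenation matches the phrasing of the original totals.
ω = bN/bS per ingroup branch, with gene-bootstrap SDs.  The lineage
contrast G-test compares the (nonsynonymous, synonymous) totals of
parsimony-assigned lineage-specific substitutions between Og and Osj;
pathway-fractional counts are rounded to integers for the table.

**Amino-acid distances.** The gamma-corrected Poisson distance
d = a·((1−p)^(−1/a) − 1) with shape a = 2.25 measures amino-acid branch
lengths.

**Property changes.** Four default partitions of the 20 amino acids ship
with the package (charge, polarity, volume, hydropathy).  The original
study cites four published classifications without reproducing them; the
partitions here are documented stand-ins with the same shape, and users can
substitute exact published schemes via `PropertyScheme`.  Each scheme
yields a 2×2 (lineage × class-changing/preserving) G-test; if every
substitution falls in one column the test degenerates to G = 0, P = 1.

## Splice sites

Donor = first two intron bases, acceptor = last two, read on the transcript
strand (minus-strand genes reverse-complemented); intron positions come
exclusively from the Osj gene models, so splice variants unique to Og are
out of reach by construction (a stated limitation of the original design).
A site enters the analysis only if the motif and both 10-nt flanks align
without gaps in all three genomes.  Parsimony assignment: the single taxon
whose motif differs from the two equal others; Og assignments are marked
unpolarized (no outgroup genome).  The flank-clean filter additionally
requires both flanks identical across the three genomes.  Canonical GT/AG
flags are reported but not filtered on.

Intron coding potential: codons are scanned in the frame continuing the
upstream exon (phase = upstream coding bases mod 3).  "Translatable without
stops" is interpreted as *also* requiring intron length ≡ 0 (mod 3) —
otherwise the downstream exon's frame cannot reconnect; the raw stop-scan
is reported alongside so the weaker reading remains available.

## SSRs

Perfect tandem tracts of primitive 2–4-nt motifs with ≥ 9/6/5 units
(di/tri/tetra), maximal, non-nested; overlaps resolved longest-first, then
leftmost, then smallest unit.  Motif canonicalization takes the
lexicographic minimum of motif and reverse complement but does **not**
merge rotations (CGC/GCG, CGG/CCG, GGC/GCC stay distinct classes, following
the convention of rice SSR surveys).  Tracts from Og and Osi are lifted to
Osj coordinates through the alignment; a locus falling entirely into an
alignment gap is dropped with a log entry.  Clusters = overlap groups on
the reference; a cluster is kept only if every genome contributed a
detected tract and the 50-bp flanks on both sides are gap-free in all
genomes.  The 50-bp rule deliberately excludes the tract interior —
an indel *inside* the tract is the length polymorphism being measured.

Classification compares the aligned sequences over the merged reference
interval (gaps stripped): all equal → shared; exactly one genome's length
differs → length polymorphism of that lineage; equal lengths and exactly
one genome's sequence differs → same-length sequence polymorphism of that
lineage; anything else → other.  Clusters with more than one tract in a
genome are classed other.  Region classes: protein_coding (tract entirely
inside annotated CDS), non_transcribed (entirely outside all transcripts),
other (UTR/intron/boundary; excluded from the two-region tables, which is
why the published two-region totals sum below the global SSR count).

The "length changed vs did not change" lineage comparison is implemented
as length-poly vs same-length-seq-poly counts: this is the only reading
that reproduces the printed P = 0.006 for Osi while leaving Og and Osj
non-significant, which the original text asserts.  The across-genome
comparison is a Pearson χ² on the 2×3 (region × lineage) length-poly
table, df = 2; the original reports this test without counts or statistic,
so it is implemented in its standard form and flagged unverifiable.

## Synthetic data generator

The generator defines the study conditions for everything the printed
tables cannot: it emits an ancestral genome with gene models (ATG…stop
CDS, GT..AG introns, arbitrary intron phases, ~30 % minus-strand genes,
UTRs), evolves Og, Osj, Osi and an outgroup CDS set on the fixed topology
((Og,(Osj,Osi)),outgroup), and emits the exact alignment, so no aligner
sits between simulation and analysis.

*Substitutions.* Per branch, each site proposes a mutation with the branch
rate; transitions are favoured κ:1 per transversion with κ = 3.44, which
makes the expected substitution count ratio ts/tv = κ/2 = 1.72, the
genome-wide value the windowed analysis reports.  Ingroup branch rates
(2.5e-3 on Og; 1.25e-3 each on the Os stem, Osj and Osi) put the Og–Osj
distance at ≈ 5e-3, the scale of the reported branch lengths; the outgroup
CDS branch uses 0.05 per site — deep enough to polarize, shallow enough to
keep multiple-hit and pathway-averaging error far from the estimator
tolerances (sorghum's true synonymous distance is several-fold larger;
realism there is not what these tests establish).

*Selection.* In coding sequence a proposal is accepted with probability 1
if synonymous, never if it creates a stop, and with probability
ω·N_c/n_c if nonsynonymous, where N_c is the codon's nonsynonymous site
count (stop changes included, per the NG86 convention) and n_c its
nonsynonymous non-stop mutational weight.  The correction factor plants ω
on the scale the estimator measures: the site-counting convention charges
stop-codon changes to the nonsynonymous denominator while evolution never
fixes them, so a bare acceptance probability of ω would be recovered as
≈ 0.93·ω.  Planted defaults ω_Og = 0.30, ω_Osj = 0.25 are the reported
per-lineage values.

*Planted events.* Splice mutations (taxon, intron, donor/acceptor, new
motif) and SSR events (±whole repeat units, or a single interrupting base
placed in the second-to-last unit so the remnant run stays detectable) are
applied explicitly and recorded in a ledger.  SSR tracts, splice
dinucleotides (plus one motif-length of SSR flank) and terminal stop codons
are excluded from background substitution, so every cross-genome difference
at those elements traces to a planted event — this is what makes "100 %
recovery, zero false positives" a meaningful assertion rather than a
statistical accident.  A consequence worth stating: the simulator's SSR
and splice polymorphism rates are exactly the planted rates, and the tests
validate the *detection and classification logic*, not any mutational model
of microsatellite evolution.

*Reads.* ~2-kb fragments sequenced from both ends; read lengths 350–750;
a Sanger-like phred profile (ramp to 40, plateau, declining 3′ tail below
15 so the trimming rule has work to do); sequencing errors injected at the
phred-implied rate 10^(−Q/10); reads tagged MF/SH at random; organelle
contaminants at a configured fraction drawn from a separate random
20-kb sequence; repeat intervals soft-masked into the reads.

*What the generator does not emulate:* indel evolution outside planted SSR
events, recombination, demography, paralogy, alignment error (alignments
are emitted exactly), base-composition heterogeneity, and realistic
microsatellite slippage dynamics.  Tests passing on these data show the
decision rules and estimators are implemented correctly and are calibrated
under the stated model — not that the model captures everything in real
rice genomes.

## Numerical and scale choices

Problem sizes were chosen so the full suite exercises every rule at
statistically meaningful depth: the shared test dataset uses a 150-kb
genome with 30 genes; the ts/tv recovery uses 600 kb; the ω-recovery
experiment uses 20 seeded simulations of 2000 genes × 300 codons (the
study's alignment set is 2161–7656 genes of comparable length); type-I
calibration uses 1000 replicates of 100 genes × 150 codons.  The
ω-recovery acceptance compares the *mean* recovered ω over the 20
simulations against the planted value at 2 mean bootstrap SDs plus a 5 %
mean-bias bound; per-simulation two-SD checks would fail by construction
about once per 20 draws even for a perfect estimator.

Degenerate inputs are contracts, not accidents: saturated proportions
(p ≥ 3/4 for Jukes–Cantor, p ≥ 1 for the gamma distance) raise; zero
transversions raise an undefined-ratio signal; ω is undefined when bS = 0;
the Tajima test requires m1 + m2 > 0; codon pairs with no stop-free
pathway are skipped and counted.  Coordinates are 0-based half-open
internally with GFF3/BED conversion at I/O boundaries.

## Known limitations

- The toy aligner handles gap-free placements only; real read data should
  come with externally produced hits (the interface accepts them).
- The mapping from the published per-gene tables to exact per-gene inputs
  is not reproducible without the original genomes and reads; genome-scale
  numbers are therefore validated by parameter recovery, not by replay.
- The four property schemes are documented defaults, not the four cited
  published classifications.
- The 2×3 across-genome SSR χ² follows the standard Pearson form; the
  original's exact construction is unverifiable from the text.
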