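# oryzadiv

Comparative evolutionary analysis of the African cultivated rice genome
(*Oryza glaberrima*, **Og**) against the two Asian rice subspecies
(*O. sativa* ssp. *japonica*, **Osj**, and ssp. *indica*, **Osi**), with
*Sorghum bicolor* as outgroup.  The package is aimed at molecular
evolution / comparative genomics work on closely related plant genomes and
implements, end to end:

- **Shotgun-read processing** — 3′ phred trimming, length and
  organelle-contamination filters, non-repeat content floor, unique
  best-hit placement, phred-weighted consensus with
  methylation-filtration (MF) preference on ties, contig statistics (N50,
  coverage, composition).
- **Windowed divergence** — substitution counts in 10-kb windows and
  transition/transversion ratios over non-exonic sites.
- **Selection on coding genes** — three-taxon codon alignments, the
  modified Nei–Gojobori estimator (transition/transversion-weighted site
  counts, pathway-averaged differences, Jukes–Cantor correction),
  gamma-Poisson amino-acid distances (shape a = 2.25), exact three-taxon
  least-squares branch lengths, per-lineage ω = bN/bS with gene-bootstrap
  SDs, Tajima's relative rate test, amino-acid property-change G-tests.
- **Splice-site novelty** — donor/acceptor extraction on the transcript
  strand, parsimony lineage assignment across the three genomes,
  flank-clean filtering, and intron coding-potential testing.
- **SSR polymorphism** — SSRIT-style perfect microsatellite detection
  (unit minima 9/6/5 for di/tri/tetra), cross-genome clustering with
  gap-free 50-bp flanks, shared / length-polymorphic /
  same-length-sequence-polymorphic classification, region stratification
  and the associated G-tests.
- **Statistics** — uncorrected 2×2 G-tests (Williams correction optional),
  chi-square tails, bootstrap machinery.
- **Ground-truth simulator** — three ingroup genomes plus outgroup CDS
  evolved on ((Og,(Osj,Osi)),outgroup) with per-branch rates, κ bias,
  per-branch ω, planted splice and SSR events, and phred-scored shotgun
  reads with contaminants; every event is ledgered so recovery can be
  asserted exactly.

The central statistic is the per-lineage dN/dS.  With weighted potential
sites S, N (each possible transition weighted R/(R+2), each transversion
1/(R+2)) and pathway-averaged observed differences Sd, Nd, the corrected
distances per taxon pair are

    pS = Sd/S̄,  pN = Nd/N̄,  d = −(3/4)·ln(1 − 4p/3)

and the three pairwise distances resolve into branch lengths
b_x = (d_xy + d_xo − d_yo)/2 (exact least squares for three taxa), giving
ω_lineage = bN/bS.  G-tests are G = 2·Σ O ln(O/E) against χ² (df = 1).

## Worked example

Generate a synthetic study set, run the selection analysis, and check the
recovery of planted parameters:

```
python analysis/01_simulate_dataset.py --seed 1
python analysis/04_codon_selection.py  --seed 1
```

which prints (seed 1):

```
recovered omega Og 0.295 (planted 0.30), Osj 0.257 (planted 0.25); Tajima RRT p = 0.180 on the genome set
```

The 2000-gene recovery experiment returns ω within two bootstrap SDs of
the planted per-lineage values (0.295 ± 0.009 against 0.30, 0.257 ± 0.008
against 0.25), and on the 50-gene simulated genome the relative-rate test
is, correctly, non-significant (the two ingroup branches evolve at equal
rates by construction).  The remaining drivers cover the other stages:

```
python analysis/02_read_qc_and_consensus.py   # QC + consensus: kept 1022 reads, 190 contigs, N50 1699 bp
python analysis/03_divergence_windows.py      # ts/tv Og-Osj 1.65 under planted 1.72 (600-kb runs land within 3 SE)
python analysis/05_splice_sites.py            # 9 planted splice mutations recovered: Osj 3, Osi 3, Og 3
python analysis/06_ssr_polymorphism.py        # 24 SSR clusters classified; planted classes recovered exactly
python analysis/07_enrichment_tables.py       # published count tables through the G-test
```

Each driver writes its tables under `results/` and large intermediates
under `scratch/`.  The last one prints, for example:

```
NB-ARC                           G=  40.4750  p=1.992e-10  (published 1.99e-10)
ssr_osi_tri_length_vs_seq        G=   7.6926  p=5.545e-03  (published 6e-03)
```

i.e. the uncorrected log-likelihood-ratio G-test reproduces the published
enrichment P-values from the printed counts at printed precision.

A `oryzadiv` command-line entry point exposes the same stages
(`oryzadiv simulate --seed 1 --out-dir run`, then `qc`, `consensus`,
`windows`, `codon`, `splice`, `ssr`, `enrich`, `report`), each leaving a
manifest with parameter values and input/output checksums in the run
directory.

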