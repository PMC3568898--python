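"""SSR detection, canonicalization, clustering, classification and the
contingency analyses."""

import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oryzadiv.align import ThreeWayAlignment
from oryzadiv.genes import GeneModel, revcomp
from oryzadiv.ssr import (
    MIN_UNITS_DEFAULT,
    SSRCluster,
    SSRConfig,
    SSRLocus,
    assign_region,
    canonical_motif,
    classify_cluster,
    cluster_across_genomes,
    detect_ssrs,
    is_primitive,
    ssr_gtests,
    table5_counts,
)

# ---------------------------------------------------------------------------
# Independent regex oracle for perfect-SSR detection
# ---------------------------------------------------------------------------

_ORACLE_PATTERNS = {
    u: re.compile(rf"([ACGT]{{{u}}})\1{{{MIN_UNITS_DEFAULT[u] - 1},}}")
    for u in (2, 3, 4)
}


def regex_oracle(seq: str):
    seq = seq.upper()
    candidates = []
    for u, pat in _ORACLE_PATTERNS.items():
        for m in pat.finditer(seq):
            motif = m.group(1)
            if not is_primitive(motif):
                continue
            length = len(m.group(0))
            candidates.append((m.start(), m.start() + length, motif))
    # same overlap policy: longest first, then leftmost, then smallest unit
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0], len(c[2])))
    chosen = []
    for c in candidates:
        if all(c[1] <= k[0] or c[0] >= k[1] for k in chosen):
            chosen.append(c)
    return sorted(chosen)


def rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestDetection:
    def test_simple_dinucleotide_tract(self):
        loci = detect_ssrs("AC" * 10)
        assert len(loci) == 1
        L = loci[0]
        assert (L.start, L.end, L.motif, L.n_units) == (0, 20, "AC", 10)

    def test_below_threshold_not_reported(self):
        assert detect_ssrs("ATG" * 5) == []  # tri needs 6 units
        assert detect_ssrs("ATG" * 6) != []

    def test_embedded_tract_exact_coordinates(self):
        rng = np.random.default_rng(3)
        left, right = rand_seq(rng, 57), rand_seq(rng, 61)
        seq = left + "AT" * 9 + right
        expected = regex_oracle(seq)
        got = [(L.start, L.end, L.motif) for L in detect_ssrs(seq)]
        assert got == expected
        assert (len(left), len(left) + 18, "AT") in got

    def test_non_primitive_motif_never_reported(self):
        loci = detect_ssrs("AT" * 12)
        assert all(is_primitive(L.motif) for L in loci)
        assert loci[0].unit == 2  # (AT)x12, not (ATAT)x6

    def test_tract_with_n_excluded(self):
        seq = "AC" * 5 + "N" + "AC" * 5
        assert detect_ssrs(seq) == []

    def test_matches_regex_oracle_on_seeded_strings(self):
        rng = np.random.default_rng(11)
        motifs = ["AT", "CT", "GCC", "AAG", "ACGT", "CGC"]
        for i in range(300):
            seq = rand_seq(rng, 400)
            if i % 2:  # plant one tract to make the comparison informative
                m = motifs[i % len(motifs)]
                k = MIN_UNITS_DEFAULT[len(m)] + int(rng.integers(0, 5))
                p = int(rng.integers(0, 380 - len(m) * k))
                seq = seq[:p] + m * k + seq[p + len(m) * k :]
            got = [(L.start, L.end, L.motif) for L in detect_ssrs(seq)]
            assert got == regex_oracle(seq), seq


class TestCanonicalMotif:
    @pytest.mark.parametrize(
        "motif,expected", [("GCG", "CGC"), ("CGG", "CCG"), ("AT", "AT"), ("GGC", "GCC")]
    )
    def test_reverse_complement_pairing(self, motif, expected):
        assert canonical_motif(motif) == expected

    def test_rotations_not_merged(self):
        # CGC/GCG, CGG/CCG and GGC/GCC stay three distinct classes
        assert len({canonical_motif(m) for m in ("CGC", "CCG", "GCC")}) == 3

    @given(
        motif=st.text(alphabet="ACGT", min_size=2, max_size=4).filter(is_primitive)
    )
    @settings(max_examples=100, deadline=None)
    def test_idempotent_and_strand_symmetric(self, motif):
        c = canonical_motif(motif)
        assert canonical_motif(c) == c
        assert canonical_motif(revcomp(motif)) == c

    def test_non_primitive_rejected(self):
        with pytest.raises(ValueError):
            canonical_motif("ATAT")


def _aln_identical(seq):
    return ThreeWayAlignment.from_sequences({"osj": seq, "osi": seq, "og": seq})


class TestClustering:
    def test_identical_tract_clusters_once(self):
        rng = np.random.default_rng(0)
        seq = rand_seq(rng, 100) + "ACT" * 8 + rand_seq(rng, 100)
        aln = _aln_identical(seq)
        loci = {g: detect_ssrs(seq, genome=g) for g in ("osj", "osi", "og")}
        clusters = cluster_across_genomes(loci, aln)
        assert len(clusters) == 1

    def test_tract_in_single_genome_dropped(self):
        rng = np.random.default_rng(0)
        base = rand_seq(rng, 100) + "GAT" * 8 + rand_seq(rng, 100)
        broken = base[:100] + rand_seq(rng, 24) + base[124:]
        aln = ThreeWayAlignment.from_sequences(
            {"osj": broken, "osi": broken, "og": base}
        )
        loci = {
            "osj": detect_ssrs(broken, genome="osj"),
            "osi": detect_ssrs(broken, genome="osi"),
            "og": detect_ssrs(base, genome="og"),
        }
        assert cluster_across_genomes(loci, aln) == []

    def test_gap_in_flank_drops_cluster(self):
        rng = np.random.default_rng(2)
        seq = rand_seq(rng, 100) + "TCA" * 8 + rand_seq(rng, 100)
        rows = {
            g: np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            for g in ("osj", "osi", "og")
        }
        rows["og"][70] = ord("-")  # alignment gap 30 bp upstream of the tract
        aln = ThreeWayAlignment(rows=rows)
        og_seq = aln.sequence("og")
        loci = {
            "osj": detect_ssrs(seq, genome="osj"),
            "osi": detect_ssrs(seq, genome="osi"),
            "og": detect_ssrs(og_seq, genome="og"),
        }
        assert cluster_across_genomes(loci, aln) == []


class TestClassification:
    def _cluster(self, osj, osi, og):
        members = {
            g: [SSRLocus(g, "chr1", 0, len(t), t[:2], len(t) // 2)]
            for g, t in (("osj", osj), ("osi", osi), ("og", og))
        }
        return SSRCluster(0, len(osj), members, {"osj": osj, "osi": osi, "og": og})

    def test_identical_tracts_shared(self):
        c = classify_cluster(self._cluster("AT" * 10, "AT" * 10, "AT" * 10))
        assert (c.polymorphism_class, c.lineage) == ("shared", None)

    def test_single_genome_length_change(self):
        c = classify_cluster(self._cluster("AT" * 10, "AT" * 10, "AT" * 12))
        assert (c.polymorphism_class, c.lineage) == ("length_poly", "Og")

    def test_equal_length_single_sequence_change(self):
        osi = "AT" * 4 + "AG" + "AT" * 5
        c = classify_cluster(self._cluster("AT" * 10, osi, "AT" * 10))
        assert (c.polymorphism_class, c.lineage) == ("seq_poly", "Osi")

    def test_all_distinct_lengths_other(self):
        c = classify_cluster(self._cluster("AT" * 9, "AT" * 10, "AT" * 11))
        assert (c.polymorphism_class, c.lineage) == ("other", None)

    def test_classes_partition_clusters(self, dataset):
        from oryzadiv.ssr import detect_ssrs

        loci = {
            g: detect_ssrs(dataset.genome(g), genome=g) for g in ("osj", "osi", "og")
        }
        clusters = cluster_across_genomes(loci, dataset.aln)
        for c in clusters:
            classify_cluster(c)
        classes = [c.polymorphism_class for c in clusters]
        assert all(
            x in ("shared", "length_poly", "seq_poly", "other") for x in classes
        )
        counts = {
            x: classes.count(x) for x in ("shared", "length_poly", "seq_poly", "other")
        }
        assert sum(counts.values()) == len(clusters)


class TestRegionAssignment:
    GENE = GeneModel("g", "chr1", "+", [(100, 400)], [(150, 350)])

    def test_tract_inside_cds(self):
        c = SSRCluster(200, 230, {}, {})
        assert assign_region(c, [self.GENE]).region_class == "protein_coding"

    def test_intergenic_tract(self):
        c = SSRCluster(500, 530, {}, {})
        assert assign_region(c, [self.GENE]).region_class == "non_transcribed"

    def test_boundary_straddling_is_other(self):
        c = SSRCluster(140, 170, {}, {})  # spans UTR/CDS boundary
        assert assign_region(c, [self.GENE]).region_class == "other"


class TestPlantedRecovery:
    def test_classification_recovers_planted_truth(self, dataset):
        loci = {
            g: detect_ssrs(dataset.genome(g), genome=g) for g in ("osj", "osi", "og")
        }
        clusters = cluster_across_genomes(loci, dataset.aln)
        for c in clusters:
            classify_cluster(c)
            assign_region(c, dataset.genes)
        label = {"osj": "Osj", "osi": "Osi", "og": "Og"}
        planted_by_locus = {
            e["locus_id"]: e for e in dataset.truth.ssr_events
        }
        loci_by_id = {s.locus_id: s for s in dataset.ssr_loci}
        # match clusters to planted loci through the reference interval
        matched = 0
        for c in clusters:
            hits = [
                s for s in dataset.ssr_loci
                if s.anc_start < c.ref_end and c.ref_start < s.anc_end + 8
            ]
            assert len(hits) == 1
            locus = hits[0]
            ev = planted_by_locus.get(locus.locus_id)
            if ev is None:
                assert c.polymorphism_class == "shared"
            elif ev["point_change"]:
                assert (c.polymorphism_class, c.lineage) == ("seq_poly", label[ev["taxon"]])
            else:
                assert (c.polymorphism_class, c.lineage) == (
                    "length_poly", label[ev["taxon"]],
                )
            expected_region = (
                "protein_coding" if locus.region == "cds" else "non_transcribed"
            )
            assert c.region_class == expected_region
            matched += 1
        assert matched == len(dataset.ssr_loci)

    def test_label_symmetry_under_genome_permutation(self):
        t1, t2 = "GA" * 10, "GA" * 12
        def cluster(osj, osi, og):
            members = {
                g: [SSRLocus(g, "chr1", 0, len(t), t[:2], len(t) // 2)]
                for g, t in (("osj", osj), ("osi", osi), ("og", og))
            }
            return classify_cluster(
                SSRCluster(0, 20, members, {"osj": osj, "osi": osi, "og": og})
            )

        assert cluster(t2, t1, t1).lineage == "Osj"
        assert cluster(t1, t2, t1).lineage == "Osi"
        assert cluster(t1, t1, t2).lineage == "Og"


class TestGTestReport:
    def test_published_tables_reproduce(self):
        """The printed SSR contingency comparisons, fed with the published
        counts, reproduce the printed conclusions."""
        from oryzadiv.stats import ContingencyTable2x2, gtest_2x2

        assert gtest_2x2(ContingencyTable2x2(52, 11, 54, 33)).p_value == pytest.approx(
            0.006, abs=5e-4
        )
        assert gtest_2x2(ContingencyTable2x2(680, 261, 425, 362)).p_value <= 3.4e-15
        assert gtest_2x2(ContingencyTable2x2(777, 10, 496, 445)).p_value <= 2.2e-16
        assert gtest_2x2(ContingencyTable2x2(139, 37, 175, 51)).p_value > 0.05
        assert gtest_2x2(ContingencyTable2x2(8, 9, 22, 23)).p_value > 0.05

    def test_report_structure_on_dataset(self, dataset):
        loci = {
            g: detect_ssrs(dataset.genome(g), genome=g) for g in ("osj", "osi", "og")
        }
        clusters = cluster_across_genomes(loci, dataset.aln)
        for c in clusters:
            classify_cluster(c)
            assign_region(c, dataset.genes)
        report = ssr_gtests(clusters)
        assert set(report["total_tract_bp"]) == {"osj", "osi", "og"}
        # every attempted test either produced a result or a reason
        assert report["tests"] or report["skipped"]
        counts = table5_counts(clusters)
        total = sum(v.get("total", 0) for v in counts.values())
        shared = sum(v.get("shared", 0) for v in counts.values())
        poly = sum(v.get("polymorphic", 0) for v in counts.values())
        assert shared + poly == total
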