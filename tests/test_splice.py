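"""Splice-site extraction, lineage assignment, flank filtering and intron
coding potential."""

import numpy as np
import pytest

from oryzadiv.align import ThreeWayAlignment
from oryzadiv.genes import GeneModel, revcomp
from oryzadiv.splice import (
    SpliceSiteRecord,
    assign_splice_lineage,
    extract_splice_contexts,
    flank_clean_filter,
    intron_coding_potential,
    summarize_table4,
)


def make_locus(intron="GTAAGTTTCCCTTTCAG", strand="+"):
    """A one-intron gene inside a 120-bp locus, identical in three genomes."""
    rng = np.random.default_rng(0)
    up = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
    ex1 = "ATGGCTGCT" + "GCA" * 5
    ex2 = "GGTGCC" * 4 + "TAA"
    down = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
    tx = ex1 + intron + ex2
    locus = up + (tx if strand == "+" else revcomp(tx)) + down
    if strand == "+":
        e1 = (30, 30 + len(ex1))
        intr = (e1[1], e1[1] + len(intron))
        e2 = (intr[1], intr[1] + len(ex2))
    else:
        total = len(tx)
        e2 = (30, 30 + len(ex2))
        intr = (e2[1], e2[1] + len(intron))
        e1 = (intr[1], 30 + total)
    gene = GeneModel("g1", "chr1", strand, [e1, e2], [e1, e2])
    return locus, gene


def aln_from(osj, osi=None, og=None):
    return ThreeWayAlignment.from_sequences(
        {"osj": osj, "osi": osi or osj, "og": og or osj}
    )


class TestExtraction:
    def test_plus_strand_donor_acceptor(self):
        locus, gene = make_locus()
        records = extract_splice_contexts([gene], aln_from(locus))
        by_kind = {r.kind: r for r in records}
        assert by_kind["donor"].motif["osj"] == "GT"
        assert by_kind["acceptor"].motif["osj"] == "AG"
        assert all(r.gap_free for r in records)

    def test_minus_strand_reads_transcript_strand(self):
        locus, gene = make_locus(strand="-")
        records = extract_splice_contexts([gene], aln_from(locus))
        by_kind = {r.kind: r for r in records}
        assert by_kind["donor"].motif["osj"] == "GT"
        assert by_kind["acceptor"].motif["osj"] == "AG"

    def test_strand_reversal_round_trip(self):
        """Reverse-complementing the locus and flipping the strand yields
        identical motifs and flanks."""
        locus, gene = make_locus()
        fwd = extract_splice_contexts([gene], aln_from(locus))

        n = len(locus)
        rc = revcomp(locus)

        def flip(iv):
            return (n - iv[1], n - iv[0])

        gene_rc = GeneModel(
            "g1", "chr1", "-", [flip(iv) for iv in gene.exons],
            [flip(iv) for iv in gene.cds],
        )
        rev = extract_splice_contexts([gene_rc], aln_from(rc))
        key = lambda r: (r.kind,)
        for a, b in zip(sorted(fwd, key=key), sorted(rev, key=key)):
            assert a.motif == b.motif
            assert a.flank5 == b.flank5
            assert a.flank3 == b.flank3

    def test_alignment_gap_near_site_marks_not_gap_free(self):
        locus, gene = make_locus()
        # delete 1 bp in og three bases downstream of the donor
        intron_start = gene.exons[0][1]
        og = list(locus)
        del og[intron_start + 5]
        rows = {
            "osj": locus,
            "osi": locus,
            "og": "".join(og) + "-",
        }
        # build gapped alignment explicitly: og loses one column
        arr = {
            "osj": np.frombuffer(locus.encode(), dtype=np.uint8).copy(),
            "osi": np.frombuffer(locus.encode(), dtype=np.uint8).copy(),
        }
        og_row = np.frombuffer(locus.encode(), dtype=np.uint8).copy()
        og_row[intron_start + 5] = ord("-")
        arr["og"] = og_row
        aln = ThreeWayAlignment(rows=arr)
        records = extract_splice_contexts([gene], aln)
        donor = next(r for r in records if r.kind == "donor")
        assert not donor.gap_free


class TestLineageAssignment:
    def _rec(self, osj, osi, og, kind="donor"):
        return SpliceSiteRecord(
            gene_id="g", intron_index=0, kind=kind,
            motif={"osj": osj, "osi": osi, "og": og},
            flank5={t: "A" * 10 for t in ("osj", "osi", "og")},
            flank3={t: "C" * 10 for t in ("osj", "osi", "og")},
            gap_free=True,
        )

    def test_osj_specific_new_donor(self):
        # donor GT in Osj while Osi and Og carry GC: change on the Osj branch
        r = assign_splice_lineage(self._rec("GT", "GC", "GC"))
        assert r.lineage == "Osj" and not r.unpolarized

    def test_og_divergence_is_unpolarized(self):
        # acceptor AG in both Os lineages, TG in Og: assigned to Og but the
        # ancestral state cannot be polarized without an outgroup
        r = assign_splice_lineage(self._rec("AG", "AG", "TG", kind="acceptor"))
        assert r.lineage == "Og" and r.unpolarized

    def test_identical_motifs_none(self):
        assert assign_splice_lineage(self._rec("GT", "GT", "GT")).lineage == "none"

    def test_three_states_ambiguous(self):
        assert assign_splice_lineage(self._rec("GT", "GC", "AT")).lineage == "ambiguous"

    def test_gapped_record_rejected(self):
        r = self._rec("GT", "GT", "GT")
        r.gap_free = False
        with pytest.raises(ValueError):
            assign_splice_lineage(r)


class TestFlankFilter:
    def _rec(self, f5_og="A" * 10):
        return SpliceSiteRecord(
            gene_id="g", intron_index=0, kind="donor",
            motif={t: "GT" for t in ("osj", "osi", "og")},
            flank5={"osj": "A" * 10, "osi": "A" * 10, "og": f5_og},
            flank3={t: "C" * 10 for t in ("osj", "osi", "og")},
            gap_free=True,
        )

    def test_identical_flanks_kept(self):
        assert flank_clean_filter([self._rec()])

    def test_single_mismatch_removed(self):
        assert not flank_clean_filter([self._rec(f5_og="A" * 9 + "G")])


class TestCodingPotential:
    def test_inframe_stop_detected(self):
        res = intron_coding_potential("GTATAGCCC", phase=0)
        assert res.has_inframe_stop and not res.coding_potential_retained

    def test_clean_frame_retained(self):
        res = intron_coding_potential("GTTGGCAAG", phase=0)
        assert not res.has_inframe_stop and res.coding_potential_retained

    def test_length_not_multiple_of_three_never_retained(self):
        res = intron_coding_potential("GTTGGCAAGA", phase=0)
        assert res.length_mod3 == 1 and not res.coding_potential_retained

    def test_phase_shifts_reading_frame(self):
        # with phase 2, one base completes the upstream codon; codons then
        # start at intron offset 1: "TAT", "AGC" - no stop in that frame
        res = intron_coding_potential("GTATAGCCC", phase=2)
        assert not res.has_inframe_stop

    def test_retained_implies_full_translation_clean(self, dataset):
        """Cross-check: when coding potential is retained, translating
        exon1+intron+exon2 straight through yields no stop inside the
        intron segment."""
        from oryzadiv.codons import encode_codons, translate

        checked = 0
        for gene in dataset.genes:
            osj = dataset.genome("osj")
            for intron in gene.coding_introns():
                phase = gene.intron_phase(intron)
                seq = osj[intron[0] : intron[1]]
                if gene.strand == "-":
                    seq = revcomp(seq)
                res = intron_coding_potential(seq, phase)
                if not res.coding_potential_retained:
                    continue
                # build the read-through coding sequence and translate
                cds_parts = []
                ivs = gene.cds if gene.strand == "+" else gene.cds[::-1]
                for s, e in ivs:
                    sub = osj[s:e]
                    cds_parts.append(sub if gene.strand == "+" else revcomp(sub))
                full = "".join(cds_parts)
                # locate intron insertion point in transcript coordinates
                if gene.strand == "+":
                    upstream = sum(
                        min(e, intron[0]) - s for s, e in gene.cds if s < intron[0]
                    )
                else:
                    upstream = sum(
                        e - max(s, intron[1]) for s, e in gene.cds if e > intron[1]
                    )
                readthrough = full[:upstream] + seq + full[upstream:]
                n_keep = (len(readthrough) // 3) * 3
                aa = translate(encode_codons(readthrough[:n_keep]))
                intron_aa = aa[upstream // 3 : (upstream + len(seq)) // 3 + 1]
                assert "*" not in intron_aa
                checked += 1
        # the fixture has no retained-intron guarantee; just require the
        # cross-check to have been exercised when any case exists
        assert checked >= 0


class TestPlantedRecovery:
    def test_all_planted_mutations_recovered_with_lineage(self, dataset):
        records = extract_splice_contexts(dataset.genes, dataset.aln)
        for r in records:
            if r.gap_free:
                assign_splice_lineage(r)
        found = {
            (r.gene_id, r.intron_index, r.kind): r.lineage
            for r in records
            if r.lineage in ("Osj", "Osi", "Og")
        }
        label = {"osj": "Osj", "osi": "Osi", "og": "Og"}
        planted = {
            (e["gene_id"], e["intron_index"], e["kind"]): label[e["taxon"]]
            for e in dataset.truth.splice_events
        }
        assert found == planted

    def test_zero_false_positives_at_zero_rate(self):
        from oryzadiv.simulate import SimulationConfig, simulate_genomes

        cfg = SimulationConfig(
            seed=5,
            branch_rates={k: 0.0 for k in ("og", "os_stem", "osj", "osi", "outgroup")},
        )
        ds = simulate_genomes(cfg)
        records = extract_splice_contexts(ds.genes, ds.aln)
        for r in records:
            assign_splice_lineage(r)
        assert all(r.lineage == "none" for r in records)

    def test_summary_counts_match_planted_truth(self, dataset):
        records = extract_splice_contexts(dataset.genes, dataset.aln)
        for r in records:
            if r.gap_free:
                assign_splice_lineage(r)
        summary = summarize_table4(records)
        label = {"osj": "Osj", "osi": "Osi", "og": "Og"}
        planted_by_lineage = {}
        for e in dataset.truth.splice_events:
            planted_by_lineage.setdefault(label[e["taxon"]], set()).add(
                (e["gene_id"], e["intron_index"])
            )
        for lineage in ("Osj", "Osi", "Og"):
            assert summary[lineage]["introns"] == len(
                planted_by_lineage.get(lineage, set())
            )


def test_intron_counted_in_both_kinds_only_if_both_changed():
    recs = []
    for kind, lineage in (("donor", "Osj"), ("acceptor", "Osj")):
        r = SpliceSiteRecord(
            gene_id="g", intron_index=0, kind=kind,
            motif={"osj": "XX", "osi": "GT", "og": "GT"},
            flank5={t: "A" * 10 for t in ("osj", "osi", "og")},
            flank3={t: "C" * 10 for t in ("osj", "osi", "og")},
            gap_free=True, lineage=lineage,
        )
        recs.append(r)
    both = summarize_table4(recs)
    assert both["Osj"]["introns"] == 1
    assert both["Osj"]["donor_sites"] == 1 and both["Osj"]["acceptor_sites"] == 1
    only_donor = summarize_table4(recs[:1])
    assert only_donor["Osj"]["acceptor_sites"] == 0
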