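"""Codon evolution machinery: site counting, pathway-averaged differences,
distances, branch lengths, lineage assignment and property tests."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oryzadiv.codons import (
    AA_BY_CODON,
    CODONS,
    IS_STOP,
    STOP_CODONS,
    AlignmentFilter,
    CodonAlignment,
    GammaPoissonParams,
    MNGParams,
    PropertyScheme,
    RejectedAlignment,
    SaturationError,
    assign_lineage_specific,
    build_codon_alignment,
    default_schemes,
    encode_codons,
    gamma_poisson_distance,
    jukes_cantor,
    ls_branch_lengths,
    mng_pair_counts,
    mng_site_counts,
    mutual_best_hits,
    property_change_test,
)

SENSE = [c for c in CODONS if c not in STOP_CODONS]


# ---------------------------------------------------------------------------
# Independent oracle: direct enumeration of weighted sites and pathways
# ---------------------------------------------------------------------------

CODE = dict(zip(CODONS, AA_BY_CODON))


def oracle_syn_sites(codon: str, R: float) -> float:
    s = 0.0
    ts_pairs = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    for pos in range(3):
        for b in "TCAG":
            if b == codon[pos]:
                continue
            new = codon[:pos] + b + codon[pos + 1 :]
            if CODE[new] == "*":
                continue
            if CODE[new] == CODE[codon]:
                s += R / (R + 2) if (codon[pos], b) in ts_pairs else 1 / (R + 2)
    return s


def oracle_pathways(x: str, y: str):
    """Mean (syn, nonsyn) steps over stop-free substitution orders."""
    diff = [i for i in range(3) if x[i] != y[i]]
    results = []
    for order in itertools.permutations(diff):
        cur, syn, nonsyn = x, 0, 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + y[pos] + cur[pos + 1 :]
            if CODE[nxt] == "*":
                ok = False
                break
            syn += CODE[nxt] == CODE[cur]
            nonsyn += CODE[nxt] != CODE[cur]
            cur = nxt
        if ok:
            results.append((syn, nonsyn))
    if not results:
        return None
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


class TestSiteCounts:
    def test_met_has_no_synonymous_sites(self):
        s, n = mng_site_counts(encode_codons("ATG"), MNGParams(R=1.7))
        assert s == 0.0 and n == 3.0

    def test_phe_with_unit_weights(self):
        # TTT: only T->C at position 3 is synonymous; R=1 weights all 1/3
        s, n = mng_site_counts(encode_codons("TTT"), MNGParams(R=1.0))
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    @given(
        codons=st.lists(st.sampled_from(SENSE), min_size=1, max_size=40),
        R=st.floats(0.2, 8.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_sites_sum_to_three_per_codon(self, codons, R):
        s, n = mng_site_counts(encode_codons("".join(codons)), MNGParams(R=R))
        assert s + n == pytest.approx(3 * len(codons))

    @given(codon=st.sampled_from(SENSE), R=st.floats(0.3, 6.0))
    @settings(max_examples=80, deadline=None)
    def test_matches_enumeration_oracle(self, codon, R):
        s, _ = mng_site_counts(encode_codons(codon), MNGParams(R=R))
        assert s == pytest.approx(oracle_syn_sites(codon, R))

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            mng_site_counts(encode_codons("TAA"))


class TestPairwiseCounts:
    def test_single_synonymous_difference(self):
        sd, nd, _, _, _ = mng_pair_counts(encode_codons("TTT"), encode_codons("TTC"))
        assert (sd, nd) == (1.0, 0.0)

    def test_two_step_pathway_average(self):
        # TTT -> TCC via TCT (nonsyn, then syn) or TTC (syn, then nonsyn)
        sd, nd, _, _, _ = mng_pair_counts(encode_codons("TTT"), encode_codons("TCC"))
        assert (sd, nd) == (1.0, 1.0)

    def test_identical_sequences_zero(self):
        x = encode_codons("ATGGCTAAA")
        sd, nd, s, n, skipped = mng_pair_counts(x, x)
        assert sd == nd == 0.0 and skipped == 0

    def test_pathways_through_stops_excluded(self):
        # find a sense pair whose pathway set shrinks due to a stop
        for x, y in itertools.product(SENSE, SENSE):
            expected = oracle_pathways(x, y)
            if expected is None:
                continue
            diff = sum(a != b for a, b in zip(x, y))
            if diff >= 2:
                sd, nd, _, _, _ = mng_pair_counts(encode_codons(x), encode_codons(y))
                assert (sd, nd) == pytest.approx(expected)


class TestDistances:
    def test_gamma_poisson_zero(self):
        assert gamma_poisson_distance(0.0) == 0.0

    def test_gamma_poisson_closed_form(self):
        assert gamma_poisson_distance(0.1, GammaPoissonParams(a=2.25)) == pytest.approx(
            0.10787, abs=1e-5
        )

    def test_gamma_poisson_poisson_limit(self):
        d = gamma_poisson_distance(0.2, GammaPoissonParams(a=1e6))
        assert d == pytest.approx(-math.log(0.8), abs=1e-4)

    @given(p=st.floats(0.0, 0.89), a=st.floats(0.5, 10.0))
    @settings(max_examples=60, deadline=None)
    def test_gamma_poisson_monotone(self, p, a):
        params = GammaPoissonParams(a=a)
        assert gamma_poisson_distance(p + 0.1, params) > gamma_poisson_distance(p, params)

    def test_saturation_errors(self):
        with pytest.raises(SaturationError):
            gamma_poisson_distance(1.0)
        with pytest.raises(SaturationError):
            jukes_cantor(0.75)


class TestBranchLengths:
    def test_closed_form(self):
        b, clamped = ls_branch_lengths(0.2, 0.3, 0.4)
        assert np.allclose(b, [0.05, 0.15, 0.25])
        assert not clamped

    def test_symmetric_distances(self):
        b, _ = ls_branch_lengths(0.2, 0.2, 0.2)
        assert np.allclose(b, 0.1)

    def test_triangle_violation_clamped_and_flagged(self):
        b, clamped = ls_branch_lengths(0.1, 0.5, 0.1)
        assert clamped and b.min() == 0.0

    @given(
        bx=st.floats(0.0, 1.0), by=st.floats(0.0, 1.0), bo=st.floats(0.0, 1.0)
    )
    @settings(max_examples=60, deadline=None)
    def test_recovers_additive_distances_exactly(self, bx, by, bo):
        b, clamped = ls_branch_lengths(bx + by, bx + bo, by + bo)
        assert not clamped
        assert np.allclose(b, [bx, by, bo], atol=1e-12)


class TestLineageAssignment:
    @pytest.mark.parametrize(
        "og,osj,out,expected",
        [
            ("A", "G", "G", "Og"),
            ("G", "A", "G", "Osj"),
            ("G", "G", "C", "none"),
            ("G", "G", "G", "none"),
            ("A", "G", "C", "ambiguous"),
        ],
    )
    def test_patterns(self, og, osj, out, expected):
        assert assign_lineage_specific(og, osj, out) == expected

    @given(
        states=st.lists(
            st.tuples(
                st.sampled_from("ACGT"), st.sampled_from("ACGT"), st.sampled_from("ACGT")
            ),
            min_size=1,
            max_size=60,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_label_swap_symmetry(self, states):
        fwd = [assign_lineage_specific(a, b, c) for a, b, c in states]
        rev = [assign_lineage_specific(b, a, c) for a, b, c in states]
        swap = {"Og": "Osj", "Osj": "Og", "none": "none", "ambiguous": "ambiguous"}
        assert [swap[x] for x in fwd] == rev

    def test_missing_state_raises(self):
        with pytest.raises(ValueError):
            assign_lineage_specific(None, "A", "A")


class TestAlignmentConstruction:
    def _maps(self, codons, n):
        return {i: codons[3 * i : 3 * i + 3] for i in range(n)}

    def _cds(self, n):
        rng = np.random.default_rng(0)
        from oryzadiv.codons import decode_codons, CODON_INDEX

        sense_idx = [CODON_INDEX[c] for c in SENSE if c != "ATG"]
        return "ATG" + decode_codons(rng.choice(sense_idx, size=n - 2)) + "TAA"

    def test_short_low_coverage_rejected(self):
        cds = self._cds(165)  # 165 codons incl. stop -> 164 ref codons
        og = self._maps(cds, 99)
        out = self._maps(cds, 99)
        res = build_codon_alignment("g", cds, og, out)
        assert isinstance(res, RejectedAlignment)  # 99 aa, 60% coverage

    def test_high_coverage_short_alignment_accepted(self):
        cds = self._cds(140)  # 139 ref codons; 99 aligned = 71% coverage
        og = self._maps(cds, 99)
        out = self._maps(cds, 99)
        res = build_codon_alignment("g", cds, og, out)
        assert isinstance(res, CodonAlignment)

    def test_internal_stop_rejected(self):
        cds = self._cds(120)
        og = self._maps(cds, 110)
        og[50] = "TAA"
        out = self._maps(cds, 110)
        res = build_codon_alignment("g", cds, og, out)
        assert isinstance(res, RejectedAlignment) and "stop" in res.reason

    def test_gap_rejected(self):
        cds = self._cds(120)
        og = self._maps(cds, 110)
        og[50] = "G--"
        out = self._maps(cds, 110)
        res = build_codon_alignment("g", cds, og, out)
        assert isinstance(res, RejectedAlignment) and "gap" in res.reason

    def test_frame_error(self):
        with pytest.raises(ValueError):
            build_codon_alignment("g", "ATGC", {}, {})

    def test_termini_trimmed_from_counting(self):
        cds = self._cds(130)
        og = self._maps(cds, 129)
        out = self._maps(cds, 129)
        res = build_codon_alignment("g", cds, og, out, AlignmentFilter())
        assert isinstance(res, CodonAlignment)
        assert not res.counted[:10].any() and not res.counted[-10:].any()
        assert res.counted[10:-10].all()


class TestPropertySchemes:
    def test_default_schemes_partition_the_twenty(self):
        assert len(default_schemes()) == 4  # charge, polarity, volume, hydropathy

    def test_invalid_partition_rejected(self):
        with pytest.raises(ValueError):
            PropertyScheme("bad", {"x": "ACDEFGHIK", "y": "LMNPQRSTV"})  # misses WY

    def test_conservative_change_within_charge_class(self):
        charge = default_schemes()[0]
        assert not charge.is_change("D", "E")  # both negative
        assert charge.is_change("D", "K")

    def test_single_class_scheme_gives_null_result(self):
        one = PropertyScheme("one", {"all": "ACDEFGHIKLMNPQRSTVWY"})
        res = property_change_test(
            {"Og": [("A", "V"), ("D", "K")], "Osj": [("L", "P")]}, one
        )
        assert res.statistic == 0.0 and res.p_value == 1.0


def test_mutual_best_hits_requires_reciprocity():
    scores = {
        ("a1", "b1"): 10.0, ("a1", "b2"): 3.0,
        ("a2", "b1"): 9.0, ("a2", "b2"): 4.0,
    }
    # b1's best is a1, so only (a1, b1) is mutual; a2's best b1 prefers a1
    assert mutual_best_hits(scores) == [("a1", "b1")]
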