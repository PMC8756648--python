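"""Per-peptide property computations and the published-table regression."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from sigpep import sp_properties as props
from sigpep.records import AlphabetError, SignalPeptideRecord

AA = "ACDEFGHIKLMNPQRSTVWY"
sequences = st.text(alphabet=AA, min_size=1, max_size=60).map(lambda s: "M" + s)

# Printed net charges that the stated N-domain rule cannot reproduce: for
# these peptides the published values imply an N-domain ending before a
# positively charged residue close to the cleavage site (and, for two of
# them, no acidic subtraction). Documented in the methods note.
CHARGE_EXCEPTIONS = {
    "LP_23680": 3,   # published 2
    "PA_18600": 4,   # published 3
    "PA_13510": 8,   # published 9 (positive_count mode reproduces it)
    "PA_10610": 4,   # published 3
    "PA_14540": 3,   # published 2
    "PA_07000": 6,   # published 7 (positive_count mode reproduces it)
}
# PA_07000's published length (38) exceeds its published 37-residue sequence;
# the published hydrophobicity (59 = 22/37) is consistent with the sequence.
LENGTH_EXCEPTIONS = {"PA_07000": 37}


class TestNDomain:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("MKKFNFKTMLLLVLASCVFGVVVNVTTSLGPQTTITAQA", 7),  # last K at 7
            ("MAAALLL", 1),  # no K/R: falls back to the initial residue
            ("MNYRSILFTTAIATMGAFSFGHSPVSA", 4),  # single R
        ],
    )
    def test_last_positive_residue(self, seq, expected):
        assert props.n_domain(seq) == expected

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            props.n_domain("")

    @given(sequences)
    def test_matches_linear_scan_oracle(self, seq):
        expected = max(
            (i for i, ch in enumerate(seq, 1) if ch in "KR"), default=1
        )
        assert props.n_domain(seq) == expected


class TestNetCharge:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("MKKFNFKTMLLLVLASCVFGVVVNVTTSLGPQTTITAQA", 3),  # LP_23790
            ("MIKLRQVLKKILIVLMVFVLVFTAFSSSVDTVSA", 4),       # LP_08330
            ("MKDRLLLAAA", 1),  # +1 -1 +1 over the MKDR N-domain
        ],
    )
    def test_signed_mode(self, seq, expected):
        assert props.net_charge(seq) == expected

    def test_positive_count_mode_ignores_acidics(self):
        assert props.net_charge("MKDRLLL", mode="positive_count") == 2

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            props.net_charge("MKR", mode="weird")

    @given(sequences)
    def test_additivity_against_per_residue_oracle(self, seq):
        nd = props.n_domain(seq)
        charge = {"K": 1, "R": 1, "D": -1, "E": -1}
        assert props.net_charge(seq) == sum(charge.get(ch, 0) for ch in seq[:nd])

    @given(sequences)
    def test_bounded_by_length(self, seq):
        assert -len(seq) <= props.net_charge(seq) <= len(seq)


class TestHydrophobicity:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("MKKFNFKTMLLLVLASCVFGVVVNVTTSLGPQTTITAQA", 59),  # 39 aa
            ("MMMM", 100),
            ("KKKK", 0),
        ],
    )
    def test_percent(self, seq, expected):
        assert props.hydrophobicity(seq) == expected

    def test_half_up_rounding(self):
        # 3 of 8 hydrophobic = 37.5% -> 38
        assert props.hydrophobicity("MMMKKKKK") == 38

    @given(sequences)
    def test_complement_shares_the_count(self, seq):
        total = props.hydrophobicity(seq) + props.hydrophilicity(seq)
        assert total in (100, 101)  # 101 only when both halves end in .5


class TestAxaMotif:
    def test_published_positive_row(self):
        assert props.axa_motif("MKKFNFKTMLLLVLASCVFGVVVNVTTSLGPQTTITAQA")

    def test_published_negative_row_ends_in_gly(self):
        assert not props.axa_motif("MKRKWFSLLVAVFLIIGVAIGFGGILHSKSSG")

    def test_boundary_length_three(self):
        assert not props.axa_motif("MAA")  # -3 is Met
        assert props.axa_motif("AXA".replace("X", "M"))

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            props.axa_motif("MA")

    @given(sequences, st.text(alphabet=AA, min_size=0, max_size=2))
    def test_independent_of_downstream_residues(self, seq, ds):
        if len(seq) < 3:
            return
        with_ds = SignalPeptideRecord(id="r", sp_seq=seq, downstream=ds)
        without = SignalPeptideRecord(id="r", sp_seq=seq, downstream="")
        flag_with = props.property_table([with_ds])[0].axa_motif
        flag_without = props.property_table([without])[0].axa_motif
        assert flag_with == flag_without == props.axa_motif(seq)


class TestAmbiguousResidues:
    def test_rejected_by_default(self):
        with pytest.raises(AlphabetError):
            props.hydrophobicity("MKXA")

    def test_count_as_neither_when_allowed(self):
        # X is neither charged nor hydrophobic
        assert props.net_charge("MKXR", allow_ambiguous=True) == 2
        assert props.hydrophobicity("MXXX", allow_ambiguous=True) == 25


class TestPropertyTable:
    def test_duplicate_ids_rejected(self):
        recs = [
            SignalPeptideRecord(id="a", sp_seq="MKKA"),
            SignalPeptideRecord(id="a", sp_seq="MLLA"),
        ]
        with pytest.raises(ValueError, match="a"):
            props.property_table(recs)

    def test_empty_input_gives_empty_table(self):
        assert props.property_table([]) == []

    def test_helix_flags_attached_and_unknown_left_none(self):
        recs = [
            SignalPeptideRecord(id="a", sp_seq="MKKA"),
            SignalPeptideRecord(id="b", sp_seq="MLLA"),
        ]
        table = props.property_table(recs, {"a": True})
        assert table[0].tm_helix is True and table[1].tm_helix is None


class TestPublishedTableRegression:
    """Computed properties vs the published 29-row screening table."""

    def test_lengths_match_except_documented_slip(self, screened_props, screened_df):
        published = dict(zip(screened_df.id, screened_df.length))
        for p in screened_props:
            expected = LENGTH_EXCEPTIONS.get(p.id, published[p.id])
            assert p.length == expected, p.id

    def test_hydrophobicity_matches_all_rows(self, screened_props, screened_df):
        published = dict(zip(screened_df.id, screened_df.hydrophobicity_pct))
        for p in screened_props:
            assert p.hydrophobicity_pct == published[p.id], p.id

    def test_signed_charges_match_outside_exception_set(
        self, screened_props, screened_df
    ):
        published = dict(zip(screened_df.id, screened_df.net_charge))
        for p in screened_props:
            expected = CHARGE_EXCEPTIONS.get(p.id, published[p.id])
            assert p.net_charge == expected, p.id

    def test_positive_count_mode_reproduces_the_two_no_subtraction_rows(
        self, screened_records
    ):
        by_id = {r.id: r for r in screened_records}
        assert props.net_charge(by_id["PA_13510"].sp_seq, mode="positive_count") == 9
        assert props.net_charge(by_id["PA_07000"].sp_seq, mode="positive_count") == 7

    def test_motif_flags_match(self, screened_props, screened_df):
        published = dict(zip(screened_df.id, screened_df.axa_motif))
        for p in screened_props:
            assert p.axa_motif == bool(published[p.id]), p.id

    def test_reference_row_values(self, screened_props):
        by_id = {p.id: p for p in screened_props}
        lp = by_id["LP_23790"]
        assert (lp.length, lp.net_charge, lp.hydrophobicity_pct) == (39, 3, 59)
        assert by_id["LP_08330"].net_charge == 4
        assert by_id["PA_13510"].length == 51
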