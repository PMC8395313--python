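"""Sequence amphipathicity metrics: published-value reproduction, an
independent brute-force moment oracle, and algebraic invariants."""

import cmath
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helimem import (
    PeptideSequence,
    amphipathicity_profile,
    get_scale,
    helical_wheel,
    metrics_table,
    net_charge,
    parse_peptide,
    segment_metrics,
)
from helimem.sequences import AMINO_ACIDS, round_half_up

SCALE = get_scale()


def brute_force_muH(residues, window=11, delta=100.0):
    """Independent windowed-moment implementation by direct summation."""
    L = len(residues)
    wins = [residues] if L < window else [
        residues[j : j + window] for j in range(L - window + 1)
    ]
    means = []
    for win in wins:
        s = sum(SCALE[aa] * math.sin(math.radians(delta) * k)
                for k, aa in enumerate(win))
        c = sum(SCALE[aa] * math.cos(math.radians(delta) * k)
                for k, aa in enumerate(win))
        means.append(math.sqrt(s * s + c * c) / len(win))
    return sum(means) / len(means)


class TestParsing:
    def test_valid_sequences(self):
        p = parse_peptide("VNWKKILGKIIKVVK", "lasio", amidated=True)
        assert len(p) == 15 and p.c_terminal_amidated
        assert len(parse_peptide("gfgmalkllkkvl ", "m", amidated=True)) == 13

    def test_non_canonical_residue_rejected_with_position(self):
        with pytest.raises(ValueError, match="position 3"):
            parse_peptide("VNXKK", "bad")

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            parse_peptide("   ", "empty")

    def test_interval_out_of_bounds(self, peptides):
        with pytest.raises(ValueError, match="out of bounds"):
            segment_metrics(peptides["Macro1"], [(1, 14)])


class TestNetCharge:
    @pytest.mark.parametrize(
        "name, expected",
        [("LasioIII", 6), ("Macro1", 4), ("TempoLa", 3), ("FK-16", 5)],
    )
    def test_study_peptides(self, peptides, name, expected):
        assert net_charge(peptides[name]) == expected

    def test_termini_only(self):
        p = PeptideSequence("g5", "GGGGG", c_terminal_amidated=True)
        assert net_charge(p) == 1
        free_acid = PeptideSequence("g5", "GGGGG", c_terminal_amidated=False)
        assert net_charge(free_acid) == 0

    def test_his_is_neutral(self):
        amidated = PeptideSequence("h", "HHHH", c_terminal_amidated=True)
        assert net_charge(amidated) == 1


class TestPublishedMetrics:
    """The windowed <H>/<muH> of the four short study peptides, to 2 dp."""

    @pytest.mark.parametrize(
        "name, exp_H, exp_muH",
        [
            ("LasioIII", 0.54, 0.77),
            ("Macro1", 0.57, 0.54),
            ("TempoLa", 0.49, 0.73),
            ("FK-16", 0.32, 0.78),
        ],
    )
    def test_whole_sequence(self, peptides, name, exp_H, exp_muH):
        prof = amphipathicity_profile(peptides[name])
        assert round_half_up(prof.mean_H) == pytest.approx(exp_H)
        assert round_half_up(prof.mean_muH) == pytest.approx(exp_muH)

    def test_ll37_segments(self, peptides):
        seg_1_11, seg_13_24 = segment_metrics(
            peptides["LL-37"], [(1, 11), (13, 24)]
        )
        assert round_half_up(seg_1_11.mean_H) == pytest.approx(0.23)
        assert round_half_up(seg_1_11.mean_muH) == pytest.approx(0.60)
        assert round_half_up(seg_13_24.mean_H) == pytest.approx(0.16)

    def test_lasio_window_means_direct_sum(self, peptides):
        # five 11-residue windows, averaged: 0.537 by direct summation
        prof = amphipathicity_profile(peptides["LasioIII"])
        assert len(prof.per_window_H) == 5
        assert prof.mean_H == pytest.approx(0.5373, abs=1e-3)

    def test_identity_interval_equals_whole_sequence(self, peptides):
        p = peptides["TempoLa"]
        (seg,) = segment_metrics(p, [(1, len(p))])
        whole = amphipathicity_profile(p)
        assert seg.per_window_H == pytest.approx(whole.per_window_H)
        assert seg.per_window_muH == pytest.approx(whole.per_window_muH)

    def test_poly_gly_is_zero(self):
        p = PeptideSequence("g13", "G" * 13, c_terminal_amidated=True)
        prof = amphipathicity_profile(p)
        assert prof.mean_H == 0.0 and prof.mean_muH == 0.0

    def test_metrics_table_reproduces_published_columns(self, peptides):
        df = metrics_table(list(peptides.values()))
        row = df.set_index("id").loc["FK-16"]
        assert row["length"] == 16
        assert row["net_charge"] == 5
        assert row["mean_H"] == pytest.approx(0.32)
        assert row["mean_muH"] == pytest.approx(0.78)


class TestMomentOracle:
    def test_matches_brute_force_on_200_random_sequences(self):
        rng = np.random.default_rng(12345)
        for _ in range(200):
            L = int(rng.integers(5, 41))
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=L))
            p = PeptideSequence("r", seq, c_terminal_amidated=True)
            prof = amphipathicity_profile(p)
            assert prof.mean_muH == pytest.approx(
                brute_force_muH(seq), abs=1e-9
            )


@settings(deadline=None, max_examples=60)
@given(st.text(alphabet=AMINO_ACIDS, min_size=2, max_size=30), st.randoms())
def test_permutation_preserves_mean_H_full_window(seq, rnd):
    """With window = L, mean hydrophobicity is order-independent while the
    moment generally is not."""
    shuffled = list(seq)
    rnd.shuffle(shuffled)
    p1 = PeptideSequence("a", seq, c_terminal_amidated=True)
    p2 = PeptideSequence("b", "".join(shuffled), c_terminal_amidated=True)
    w = len(seq)
    assert amphipathicity_profile(p1, window=w).mean_H == pytest.approx(
        amphipathicity_profile(p2, window=w).mean_H
    )


@settings(deadline=None, max_examples=60)
@given(st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=40))
def test_moment_bounded_by_max_abs_hydrophobicity(seq):
    p = PeptideSequence("a", seq, c_terminal_amidated=True)
    prof = amphipathicity_profile(p)
    bound = max(abs(SCALE[aa]) for aa in seq)
    assert prof.mean_muH <= bound + 1e-12


class TestHelicalWheel:
    def test_azimuth_wraps(self, peptides):
        wheel = helical_wheel(peptides["LL-37"])
        assert wheel.per_residue_azimuth[0] == 0.0
        assert wheel.per_residue_azimuth[18] == pytest.approx(0.0)  # 1800 mod 360

    def test_poly_gly_face_undefined(self):
        p = PeptideSequence("g", "GGGGGG", c_terminal_amidated=True)
        wheel = helical_wheel(p)
        assert wheel.face_magnitude == 0.0 and wheel.face_azimuth is None

    def test_face_magnitude_equals_full_window_moment(self, peptides):
        p = peptides["FK-16"]
        wheel = helical_wheel(p)
        full = amphipathicity_profile(p, window=len(p))
        assert wheel.face_magnitude == pytest.approx(full.mean_muH, abs=1e-12)

    def test_face_azimuth_matches_complex_argument(self, peptides):
        p = peptides["LasioIII"]
        wheel = helical_wheel(p)
        vec = sum(
            SCALE[aa] * cmath.exp(1j * math.radians(100.0) * k)
            for k, aa in enumerate(p.residues)
        )
        assert wheel.face_azimuth == pytest.approx(
            math.degrees(cmath.phase(vec)) % 360.0
        )
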