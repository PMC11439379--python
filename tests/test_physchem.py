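"""Physicochemical property engine vs published values and independent oracles.

The structural oracle for scale means, masses and the instability index is
Biopython's ProteinAnalysis (an independent code path over the same
published constants); charge and pI checks use closed forms and an
explicit per-group summation oracle written here.
"""

from __future__ import annotations

import math

import pytest
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from hypothesis import given, settings, strategies as st

from pepscan import (
    ANTICP_INTEGER,
    PanelConfig,
    QUARTER_PH7,
    aliphatic_index,
    get_pka_set,
    get_scale,
    gravy,
    hydrophilicity,
    hydrophobic_fraction,
    instability_index,
    isoelectric_point,
    molecular_weight,
    net_charge_fixed,
    net_charge_hh,
    parse_peptide,
    property_panel,
    round_half_up,
    scale_mean,
)
from pepscan.scales import PkaSet
from pepscan.sequence import STANDARD20

valid_sequences = st.text(alphabet=STANDARD20, min_size=1, max_size=30)
pair_sequences = st.text(alphabet=STANDARD20, min_size=2, max_size=30)


def hh_oracle(seq: str, pk: PkaSet, pH: float) -> float:
    """Brute-force per-group Henderson–Hasselbalch summation, one term per group."""
    groups = [("+", pk.n_terminus), ("-", pk.c_terminus)]
    for r in seq:
        if r in "HKR":
            groups.append(("+", pk.side_chain[r]))
        elif r in "DECY":
            groups.append(("-", pk.side_chain[r]))
    total = 0.0
    for sign, pka in groups:
        if sign == "+":
            total += 1.0 / (1.0 + 10.0 ** (pH - pka))
        else:
            total -= 1.0 / (1.0 + 10.0 ** (pka - pH))
    return total


class TestFixedCharge:
    def test_published_convention_pair(self, atmp5, atmp6):
        assert net_charge_fixed(atmp6, QUARTER_PH7) == 1.25
        assert net_charge_fixed(atmp5, QUARTER_PH7) == 0.25
        assert net_charge_fixed(atmp6, ANTICP_INTEGER) == 1.50
        assert net_charge_fixed(atmp5, ANTICP_INTEGER) == 0.50

    def test_no_ionizable_side_chains_is_zero(self):
        for conv in (QUARTER_PH7, ANTICP_INTEGER):
            assert net_charge_fixed("GGGG", conv) == 0.0

    def test_unknown_convention(self):
        with pytest.raises(KeyError):
            net_charge_fixed("GG", "nope")

    @given(seq=valid_sequences, pos=st.integers(0, 29), sub=st.sampled_from("KHY"))
    @settings(max_examples=60, derandomize=True)
    def test_substitution_deltas_quarter(self, seq, pos, sub):
        """T→K adds +1.00, T→H +0.25, T→Y 0.00 under the quarter convention."""
        pos = pos % len(seq)
        base = seq[:pos] + "T" + seq[pos + 1 :]
        mutated = base[:pos] + sub + base[pos + 1 :]
        delta = {"K": 1.0, "H": 0.25, "Y": 0.0}[sub]
        assert net_charge_fixed(mutated) - net_charge_fixed(base) == pytest.approx(delta)


class TestHendersonHasselbalch:
    def test_full_protonation_limit(self, atmp6):
        # at pH 0 every basic group is protonated and acids are neutral
        assert net_charge_hh(atmp6, pH=0.0) == pytest.approx(1 + 2, abs=0.01)  # N-term + H + R

    def test_two_group_midpoint(self):
        pk = PkaSet("toy", dict.fromkeys("DECYHKR", 7.0), n_terminus=9.0, c_terminus=2.0)
        assert net_charge_hh("GG", pk, pH=5.5) == pytest.approx(0.0, abs=1e-9)

    def test_ph_out_of_range(self):
        with pytest.raises(ValueError):
            net_charge_hh("GG", pH=14.5)

    @given(seq=valid_sequences, pH=st.floats(0.0, 14.0))
    @settings(max_examples=80, derandomize=True)
    def test_matches_group_sum_oracle(self, seq, pH):
        pk = get_pka_set("calibrated")
        assert net_charge_hh(seq, pk, pH) == pytest.approx(hh_oracle(seq, pk, pH), abs=1e-10)

    @given(seq=valid_sequences)
    @settings(max_examples=40, derandomize=True)
    def test_strictly_decreasing_in_ph(self, seq):
        pk = get_pka_set("calibrated")
        grid = [i * 0.5 for i in range(29)]
        charges = [net_charge_hh(seq, pk, x) for x in grid]
        assert all(a > b for a, b in zip(charges, charges[1:]))


class TestIsoelectricPoint:
    def test_published_pair_with_calibrated_set(self, atmp5, atmp6):
        assert isoelectric_point(atmp5) == pytest.approx(7.09, abs=0.05)
        assert isoelectric_point(atmp6) == pytest.approx(10.11, abs=0.05)

    def test_two_group_closed_form(self):
        pk = PkaSet("toy", dict.fromkeys("DECYHKR", 7.0), n_terminus=9.0, c_terminus=2.0)
        assert isoelectric_point("GG", pk, tol=1e-6) == pytest.approx(5.5, abs=1e-5)

    @given(nt=st.floats(6.0, 11.0), ct=st.floats(2.0, 5.0))
    @settings(max_examples=30, derandomize=True)
    def test_no_side_chain_pi_is_terminus_midpoint(self, nt, ct):
        pk = PkaSet("toy", dict.fromkeys("DECYHKR", 7.0), n_terminus=nt, c_terminus=ct)
        assert isoelectric_point("GAGS", pk, tol=1e-6) == pytest.approx((nt + ct) / 2, abs=1e-4)

    @given(seq=valid_sequences)
    @settings(max_examples=30, derandomize=True)
    def test_root_property(self, seq):
        pk = get_pka_set("lehninger")
        pI = isoelectric_point(seq, pk, tol=1e-6)
        assert 0 < pI < 14
        assert net_charge_hh(seq, pk, pI) == pytest.approx(0.0, abs=1e-3)

    def test_tol_must_be_positive(self):
        with pytest.raises(ValueError):
            isoelectric_point("GG", tol=0.0)


class TestScaleMeans:
    def test_published_gravy_pair(self, atmp5, atmp6):
        assert round(gravy(atmp6), 2) == -0.76
        assert round(gravy(atmp5), 2) == -0.63

    def test_hand_summed_dipeptide(self):
        assert gravy("AG") == pytest.approx((1.8 - 0.4) / 2)

    def test_single_residue_hopp_woods(self):
        assert hydrophilicity("R") == pytest.approx(3.0)

    def test_scale_constants_match_published_copies(self):
        from Bio.SeqUtils.ProtParamData import hw, kd

        assert dict(get_scale("kyte_doolittle").values) == kd
        assert dict(get_scale("hopp_woods").values) == hw

    @given(seq=valid_sequences, name=st.sampled_from(["kyte_doolittle", "hopp_woods"]))
    @settings(max_examples=60, derandomize=True)
    def test_mean_matches_summation_oracle(self, seq, name):
        table = get_scale(name)
        expected = math.fsum(table[r] for r in seq) / len(seq)
        assert scale_mean(seq, name) == pytest.approx(expected, abs=1e-12)

    @given(a=valid_sequences, b=valid_sequences)
    @settings(max_examples=50, derandomize=True)
    def test_gravy_concatenation_is_weighted_mean(self, a, b):
        combined = gravy(a + b)
        weighted = (len(a) * gravy(a) + len(b) * gravy(b)) / (len(a) + len(b))
        assert combined == pytest.approx(weighted, abs=1e-12)

    @given(seq=valid_sequences)
    @settings(max_examples=40, derandomize=True)
    def test_gravy_agrees_with_biopython(self, seq):
        assert gravy(seq) == pytest.approx(ProteinAnalysis(seq).gravy(), abs=1e-9)


class TestHydrophobicFraction:
    def test_published_13_percent(self, atmp5, atmp6):
        for p in (atmp5, atmp6):
            frac, pct = hydrophobic_fraction(p)
            assert frac == pytest.approx(3 / 24)
            assert pct == 13  # 12.5 rounds half-up

    @pytest.mark.parametrize("seq, pct", [("AAAA", 100), ("TTTT", 0)])
    def test_extremes(self, seq, pct):
        assert hydrophobic_fraction(seq)[1] == pct

    def test_half_up_rounding(self):
        assert round_half_up(12.5) == 13.0
        assert round_half_up(12.4) == 12.0
        assert round_half_up(0.125 * 100) == 13.0

    @given(seq=valid_sequences)
    @settings(max_examples=40, derandomize=True)
    def test_fraction_in_unit_interval(self, seq):
        frac, pct = hydrophobic_fraction(seq)
        assert 0.0 <= frac <= 1.0
        assert abs(pct - 100 * frac) <= 0.5 + 1e-9


class TestMassAndIndices:
    def test_glycine_masses(self):
        assert molecular_weight("G") == pytest.approx(75.07, abs=0.005)
        assert molecular_weight("GG") == pytest.approx(132.12, abs=0.005)

    def test_dipeptide_instability(self):
        assert instability_index("AA") == pytest.approx(5.0)

    def test_instability_needs_two_residues(self):
        with pytest.raises(ValueError):
            instability_index("A")

    @pytest.mark.parametrize("seq, expected", [
        ("AAAA", 100.0),
        ("TTTT", 0.0),
        ("AVIL", 100 * (0.25 + 2.9 * 0.25 + 3.9 * 0.5)),
    ])
    def test_aliphatic_index_hand_values(self, seq, expected):
        assert aliphatic_index(seq) == pytest.approx(expected)

    @given(seq=pair_sequences)
    @settings(max_examples=40, derandomize=True)
    def test_mass_and_instability_agree_with_biopython(self, seq):
        pa = ProteinAnalysis(seq)
        assert molecular_weight(seq) == pytest.approx(pa.molecular_weight(), abs=0.06)
        assert instability_index(seq) == pytest.approx(pa.instability_index(), abs=1e-6)


class TestPropertyPanel:
    def test_published_panel_values(self, atmp6):
        panel = property_panel(atmp6)
        assert panel.net_charge_quarter == 1.25
        assert panel.net_charge_anticp == 1.50
        assert round(panel.gravy, 2) == -0.76
        assert panel.hydrophobic_percent_rounded == 13
        assert panel.length == 24

    def test_deterministic(self, atmp5):
        assert property_panel(atmp5) == property_panel(atmp5)

    def test_config_names_must_resolve(self, atmp5):
        with pytest.raises(KeyError):
            property_panel(atmp5, PanelConfig(pka_set="nope"))
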