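"""Descriptor contracts: dimensions, canonical values, and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from acpmeta.encoders import (
    CANONICAL_SCHEMES,
    SCHEME_DIMENSIONS,
    EncodingScheme,
    encode_aac,
    encode_aaif,
    encode_ctd,
    encode_ctf,
    encode_dpc,
    encode_matrix,
    encode_nc5,
    encode_peptide,
    encode_qso,
    hybrid_concat,
)
from acpmeta.seqio import Peptide, PeptideSet
from acpmeta.tables import AA_ORDER, PropertyTables, default_tables

from conftest import make_set, random_peptide

peptides = st.text(alphabet=AA_ORDER, min_size=5, max_size=50)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(seq=peptides)
@pytest.mark.parametrize("scheme", CANONICAL_SCHEMES)
def test_dimension_contract(scheme, seq):
    fv = encode_peptide(seq, scheme)
    assert len(fv.values) == SCHEME_DIMENSIONS[scheme]
    assert np.all(np.isfinite(fv.values))


@settings(max_examples=60, derandomize=True, deadline=None)
@given(seq=peptides)
def test_aac_dpc_sum_to_one(seq):
    assert encode_aac(seq).values.sum() == pytest.approx(1.0, abs=1e-9)
    assert encode_dpc(seq).values.sum() == pytest.approx(1.0, abs=1e-9)


class TestAAC:
    def test_homopolymer(self):
        v = encode_aac("AAAAA").values
        assert v[0] == 1.0 and v[1:].sum() == 0.0

    def test_uniform_composition(self):
        v = encode_aac("ACDEF").values
        assert np.allclose(v[:5], 0.2) and v[5:].sum() == 0.0

    def test_reversal_invariance(self, rng):
        seq = random_peptide(rng)
        assert np.array_equal(encode_aac(seq).values, encode_aac(seq[::-1]).values)


class TestDPC:
    def test_homopolymer(self):
        v = encode_dpc("AAAA").values
        assert v[0] == 1.0 and v.sum() == 1.0

    def test_hand_enumerated_pairs(self):
        # ACAC: dipeptides AC, CA, AC over L-1 = 3
        fv = encode_dpc("ACAC")
        d = dict(zip(fv.names, fv.values))
        assert d["DPC.AC"] == pytest.approx(2 / 3)
        assert d["DPC.CA"] == pytest.approx(1 / 3)

    def test_too_short(self):
        with pytest.raises(ValueError):
            encode_dpc("A")


class TestQSO:
    def test_homopolymer_coupling_is_zero(self, tables):
        fv = encode_qso("AAAAAAA", tables)
        half = len(fv.values) // 2
        for block in (fv.values[:half], fv.values[half:]):
            comp, coup = block[:20], block[20:]
            assert np.all(coup == 0.0)
            assert comp[0] == pytest.approx(1.0)  # reduces to plain composition

    def test_half_blocks_sum_to_one(self, rng, tables):
        fv = encode_qso(random_peptide(rng), tables)
        assert fv.values[:50].sum() == pytest.approx(1.0, abs=1e-9)
        assert fv.values[50:].sum() == pytest.approx(1.0, abs=1e-9)

    def test_toy_matrix_hand_computation(self):
        # dist(A, C) = 1, everything else 0, for both matrices
        toy = np.zeros((20, 20))
        toy[0, 1] = toy[1, 0] = 1.0
        tables = PropertyTables(
            aaindex8=default_tables().aaindex8,
            qso_distance={"grantham": toy.copy(), "sw_synthetic": toy.copy()},
        )
        fv = encode_qso("ACACA", tables)
        # brute-force double loop oracle
        seq = "ACACA"
        tau = np.zeros(30)
        for d in range(1, 5):
            tau[d - 1] = sum(
                toy["ACDEFGHIKLMNPQRSTVWY".index(seq[i]),
                    "ACDEFGHIKLMNPQRSTVWY".index(seq[i + d])] ** 2
                for i in range(len(seq) - d)
            )
        assert list(tau[:4]) == [4.0, 0.0, 2.0, 0.0]
        denom = 1.0 + 0.1 * tau.sum()
        freq = np.zeros(20)
        freq[0], freq[1] = 3 / 5, 2 / 5
        expected_half = np.concatenate([freq / denom, 0.1 * tau / denom])
        assert np.allclose(fv.values[:50], expected_half, atol=1e-12)
        assert np.allclose(fv.values[50:], expected_half, atol=1e-12)


def ctf_raw_counts(seq, tables):
    cls = {a: c for c, grp in enumerate(tables.ctf_classes) for a in grp}
    v = np.zeros(343)
    for i in range(len(seq) - 2):
        v[cls[seq[i]] * 49 + cls[seq[i + 1]] * 7 + cls[seq[i + 2]]] += 1
    return v


class TestCTF:
    def test_homopolymer_single_triad(self, tables):
        v = encode_ctf("AAAAA", tables).values
        assert np.count_nonzero(v) == 1 and v.max() == 1.0

    def test_arndc_triads(self, tables):
        fv = encode_ctf("ARNDC", tables)
        d = dict(zip(fv.names, fv.values))
        # classes (1-based): A=1, R=5, N=4, D=6, C=7
        for name in ("CTF.154", "CTF.546", "CTF.467"):
            assert d[name] == 1.0
        assert sum(v > 0 for v in fv.values) == 3

    def test_matches_minmax_of_raw_counts(self, rng, tables):
        for _ in range(20):
            seq = random_peptide(rng)
            raw = ctf_raw_counts(seq, tables)
            assert raw.sum() == len(seq) - 2  # one triad per window
            lo, hi = raw.min(), raw.max()
            expect = np.zeros(343) if hi == lo else (raw - lo) / (hi - lo)
            assert np.allclose(encode_ctf(seq, tables).values, expect)

    def test_too_short(self, tables):
        with pytest.raises(ValueError):
            encode_ctf("AC", tables)


class TestNC5:
    def test_one_hot_blocks(self):
        fv = encode_nc5("ACDEFGHIKL")
        v = fv.values
        assert v[0] == 1.0 and v[:20].sum() == 1.0          # N1 = A
        assert v[20 + 1] == 1.0 and v[20:40].sum() == 1.0   # N2 = C
        assert v.sum() == 10.0  # ten one-hot blocks

    def test_full_overlap_at_length_five(self):
        v = encode_nc5("ACDEF").values
        assert np.array_equal(v[:100], v[100:])

    def test_reversal_swaps_halves(self, rng):
        # reversing the peptide maps N-position p to C-position 6-p
        seq = random_peptide(rng, 10, 30)
        fwd = encode_nc5(seq).values.reshape(10, 20)
        rev = encode_nc5(seq[::-1]).values.reshape(10, 20)
        assert np.array_equal(rev[:5], fwd[5:][::-1])
        assert np.array_equal(rev[5:], fwd[:5][::-1])

    def test_too_short(self):
        with pytest.raises(ValueError):
            encode_nc5("ACDE")


class TestAAIF:
    def test_absent_residue_contributes_zeros(self, tables):
        fv = encode_aaif("KKKKK", tables)  # no A anywhere
        for name, val in zip(fv.names, fv.values):
            if name.endswith(".A"):
                assert val == 0.0

    def test_homopolymer_equals_standardized_index(self, tables):
        fv = encode_aaif("AAAAA", tables)
        d = dict(zip(fv.names, fv.values))
        for idx_id, vec in tables.aaindex8.items():
            z = (vec - vec.mean()) / vec.std()
            assert d[f"AAIF.{idx_id}.A"] == pytest.approx(z[0])
            assert sum(abs(v) > 0 for n, v in d.items() if idx_id in n) == 1


class TestCTD:
    def test_block_structure(self, rng, tables):
        fv = encode_ctd(random_peptide(rng), tables)
        names = list(fv.names)
        assert sum(n.startswith("CTD.C.") for n in names) == 21
        assert sum(n.startswith("CTD.T.") for n in names) == 21
        assert sum(n.startswith("CTD.D.") for n in names) == 105

    def test_charge_distribution_of_krkrk(self, tables):
        fv = encode_ctd("KRKRK", tables)
        d = dict(zip(fv.names, fv.values))
        assert d["CTD.C.charge.1"] == 1.0
        assert d["CTD.C.charge.2"] == 0.0 and d["CTD.C.charge.3"] == 0.0
        for pair in ("12", "13", "23"):
            assert d[f"CTD.T.charge.{pair}"] == 0.0
        got = [d[f"CTD.D.charge.1.p{q}"] for q in (0, 25, 50, 75, 100)]
        assert got == [pytest.approx(x) for x in (20, 40, 60, 80, 100)]

    def test_charge_transition_of_dk(self, tables):
        fv = encode_ctd("DK", tables)
        d = dict(zip(fv.names, fv.values))
        assert d["CTD.T.charge.13"] == 1.0  # positive<->negative adjacent pair

    def test_composition_sums_and_distribution_range(self, rng, tables):
        for _ in range(10):
            fv = encode_ctd(random_peptide(rng), tables)
            d = dict(zip(fv.names, fv.values))
            for prop in ("hydrophobicity", "charge", "polarity"):
                total = sum(d[f"CTD.C.{prop}.{c}"] for c in (1, 2, 3))
                assert total == pytest.approx(1.0, abs=1e-9)
            dist = [v for n, v in d.items() if n.startswith("CTD.D.")]
            assert all(v == 0.0 or 0.0 < v <= 100.0 for v in dist)


class TestMatrixAndHybrid:
    def test_matrix_rows_match_single_encodings(self, tables):
        pset = make_set(["KWKLFKK", "ACDEFGH"])
        fm = encode_matrix(pset, "CTD", tables)
        assert fm.shape == (2, 147)
        assert np.array_equal(fm.values[0], encode_ctd("KWKLFKK", tables).values)
        assert np.array_equal(fm.values[1], encode_ctd("ACDEFGH", tables).values)

    def test_matrix_is_deterministic(self, random_set, tables):
        a = encode_matrix(random_set, "QSO", tables)
        b = encode_matrix(random_set, "QSO", tables)
        assert np.array_equal(a.values, b.values)
        assert a.feature_names == b.feature_names

    def test_error_names_offending_peptide(self, tables):
        pset = PeptideSet([Peptide("shorty", "ACDE"), Peptide("ok", "KWKLFKK")])
        with pytest.raises(ValueError, match="shorty"):
            encode_matrix(pset, "NC5", tables)

    @pytest.mark.parametrize(
        "schemes,dim",
        [
            (["AAIF", "AAC"], 180),                                     # H1
            (["AAIF", "AAC", "QSO"], 280),                              # H2
            (["AAIF", "AAC", "QSO", "DPC", "CTD", "CTF", "NC5"], 1370), # H6
        ],
    )
    def test_hybrid_dimensions(self, random_set, tables, schemes, dim):
        fm = hybrid_concat(random_set, schemes, tables)
        assert fm.shape == (len(random_set), dim)

    def test_hybrid_rejects_duplicates(self, random_set, tables):
        with pytest.raises(ValueError):
            hybrid_concat(random_set, ["AAC", "AAC"], tables)

    def test_scheme_dimension_validation(self):
        with pytest.raises(ValueError):
            EncodingScheme("AAC", 21)
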