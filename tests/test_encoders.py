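"""Feature encoders: dimensions, worked cases, brute-force oracles, invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from aipkit.encoders import (
    AA_INDEX,
    AAIndexEncoder,
    AAIndexTable,
    EncodingError,
    KSAAPEncoder,
    N_AA,
    PSSMKSAAPEncoder,
    PSSMProfile,
    StructuralEncoder,
    StructuralTable,
    build_feature_matrices,
    encode_aaindex,
    encode_ksaap,
    encode_pksaap,
    encode_structural,
    ksaap_feature_names,
    read_pssm,
    write_pssm,
)
from aipkit.peptide_io import AMINO_ACIDS, PeptideRecord, pad_peptide

valid_seq = st.text(alphabet=AMINO_ACIDS, min_size=2, max_size=25)


def ksaap_oracle(sequence: str, k_max: int = 4) -> np.ndarray:
    """Brute-force enumeration of every (i, i+k+1) index pair."""
    out = np.zeros((k_max + 1) * N_AA * N_AA)
    for k in range(k_max + 1):
        pairs = [
            (sequence[i], sequence[i + k + 1])
            for i in range(len(sequence) - k - 1)
        ]
        if not pairs:
            continue
        for a, b in pairs:
            out[k * 400 + AA_INDEX[a] * 20 + AA_INDEX[b]] += 1.0 / len(pairs)
    return out


def pksaap_oracle(matrix: np.ndarray, k_max: int = 4) -> np.ndarray:
    """Brute-force sum over the 400 pairs and all valid positions."""
    M = expit(matrix)
    L = len(M)
    out = np.zeros((k_max + 1) * N_AA * N_AA)
    for k in range(k_max + 1):
        n = L - k - 1
        if n <= 0:
            continue
        for ia in range(N_AA):
            for ib in range(N_AA):
                out[k * 400 + ia * 20 + ib] = sum(
                    M[i, ia] * M[i + k + 1, ib] for i in range(n)
                ) / n
    return out


class TestKSAAP:
    def test_dimension_2000(self):
        assert encode_ksaap(pad_peptide("KLLR")).shape == (2000,)
        assert len(ksaap_feature_names()) == 2000

    def test_homopolymer_pair_composition_one(self):
        v = encode_ksaap(pad_peptide("A" * 7)).reshape(5, 20, 20)
        for k in range(5):
            assert v[k, 0, 0] == 1.0
            assert v[k].sum() == 1.0

    def test_acde_k1_block(self):
        v = encode_ksaap(pad_peptide("ACDE")).reshape(5, 20, 20)
        k1 = v[1]
        assert k1[AA_INDEX["A"], AA_INDEX["D"]] == 0.5
        assert k1[AA_INDEX["C"], AA_INDEX["E"]] == 0.5
        assert k1.sum() == 1.0

    def test_k_too_large_for_window(self):
        with pytest.raises(EncodingError):
            encode_ksaap(pad_peptide("ACDE"), k_max=24)

    def test_matches_bruteforce_on_random_peptides(self, random_peptides):
        for rec in random_peptides(200, min_len=2):
            np.testing.assert_allclose(
                encode_ksaap(rec.padded()), ksaap_oracle(rec.sequence), atol=1e-12
            )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seq=valid_seq, extra=st.integers(min_value=0, max_value=20))
    def test_padding_invariance(self, seq, extra):
        window = min(25, max(len(seq) + extra, 6))  # window must fit k_max+2
        np.testing.assert_array_equal(
            encode_ksaap(pad_peptide(seq, window=window)),
            encode_ksaap(pad_peptide(seq)),
        )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seq=valid_seq)
    def test_blocks_nonnegative_and_normalized(self, seq):
        v = encode_ksaap(pad_peptide(seq)).reshape(5, 20, 20)
        assert (v >= 0).all()
        for k in range(5):
            valid_pairs = len(seq) - k - 1
            assert v[k].sum() == pytest.approx(1.0 if valid_pairs > 0 else 0.0)


class TestAAIndex:
    def test_default_table_eight_indices_dimension_200(self):
        table = AAIndexTable.default()
        assert table.n_indices == 8
        v = encode_aaindex(pad_peptide("KLLR"), table)
        assert v.shape == (200,)

    def test_gap_positions_zero(self):
        table = AAIndexTable.default()
        v = encode_aaindex(pad_peptide("KLLR"), table).reshape(25, 8)
        assert (v[4:] == 0).all()
        assert (v[:4] != 0).any()

    def test_toy_table_lookup(self):
        values = pd.DataFrame(
            [{aa: (0.5 if aa == "A" else 0.0) for aa in AMINO_ACIDS}], index=["HI1"]
        )
        table = AAIndexTable(values=values)
        v = encode_aaindex(pad_peptide("A"), table)
        assert v[0] == 0.5
        assert (v[1:] == 0).all()

    def test_missing_residue_column_errors(self):
        values = pd.DataFrame(
            [{aa: 1.0 for aa in AMINO_ACIDS if aa != "W"}], index=["HI1"]
        )
        with pytest.raises(EncodingError, match="W"):
            AAIndexTable(values=values)

    def test_minmax_scaling_to_unit_interval(self):
        table = AAIndexTable.default(scaled=True)
        assert table.scaled
        v = table.values.to_numpy()
        assert v.min() == 0.0 and v.max() == 1.0
        np.testing.assert_allclose(v.max(axis=1), 1.0)

    def test_tsv_round_trip(self, tmp_path):
        table = AAIndexTable.default(scaled=False)
        table.to_tsv(tmp_path / "t.tsv")
        back = AAIndexTable.from_tsv(tmp_path / "t.tsv")
        pd.testing.assert_frame_equal(back.values, table.values, check_names=False)


PSSM_FIXTURE = """
Last position-specific scoring matrix computed, weighted observed percentages rounded down, information per position, and relative weight of gapless real matches to pseudocounts
            A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V
    1 K    -1   2   0  -1  -3   1   1  -2  -1  -3  -3   5  -1  -3  -1   0  -1  -3  -2  -2
    2 L    -2  -2  -4  -4  -1  -2  -3  -4  -3   2   4  -3   2   0  -3  -3  -1  -2  -1   1
    3 R    -2   6  -1  -2  -4   1   0  -3   0  -3  -2   2  -2  -3  -2  -1  -1  -3  -2  -3

                      K         Lambda
Standard Ungapped    0.1347     0.3179
"""


class TestPSSM:
    def test_fixture_hand_parsed_values(self, tmp_path):
        path = tmp_path / "p1.pssm"
        path.write_text(PSSM_FIXTURE)
        prof = read_pssm(path)
        assert prof.matrix.shape == (3, 20)
        assert prof.sequence == "KLR"
        # file columns are in PSI-BLAST order; matrix is alphabetical
        assert prof.matrix[0, AA_INDEX["K"]] == 5.0
        assert prof.matrix[0, AA_INDEX["A"]] == -1.0
        assert prof.matrix[1, AA_INDEX["L"]] == 4.0
        assert prof.matrix[2, AA_INDEX["R"]] == 6.0
        assert prof.matrix[2, AA_INDEX["V"]] == -3.0

    def test_narrow_row_errors(self, tmp_path):
        bad = PSSM_FIXTURE.replace(
            "    3 R    -2   6  -1  -2  -4   1   0  -3   0  -3  -2   2  -2  -3  -2  -1  -1  -3  -2  -3",
            "    3 R    -2   6  -1",
        )
        path = tmp_path / "bad.pssm"
        path.write_text(bad)
        with pytest.raises(EncodingError, match="columns"):
            read_pssm(path)

    def test_non_numeric_cell_errors(self, tmp_path):
        path = tmp_path / "bad.pssm"
        path.write_text(PSSM_FIXTURE.replace("    1 K    -1   2", "    1 K    xx   2"))
        with pytest.raises(EncodingError, match="non-numeric"):
            read_pssm(path)

    def test_empty_matrix_section_errors(self, tmp_path):
        header_only = "\n".join(PSSM_FIXTURE.splitlines()[:3]) + "\n"
        path = tmp_path / "empty.pssm"
        path.write_text(header_only)
        with pytest.raises(EncodingError, match="empty"):
            read_pssm(path)

    def test_write_read_round_trip(self, rng):
        prof = PSSMProfile(
            peptide_id="x", matrix=rng.normal(size=(6, 20)), sequence="KLRACD"
        )
        import tempfile, pathlib

        path = pathlib.Path(tempfile.mkdtemp()) / "x.pssm"
        write_pssm(prof, path)
        back = read_pssm(path)
        np.testing.assert_allclose(back.matrix, np.round(prof.matrix, 3))
        assert back.sequence == prof.sequence


class TestPKSAAP:
    def test_dimension_2000(self, rng):
        prof = PSSMProfile(peptide_id="x", matrix=rng.normal(size=(10, 20)))
        assert encode_pksaap(prof).shape == (2000,)

    def test_two_row_k0_outer_product(self, rng):
        raw = rng.normal(size=(2, 20))
        prof = PSSMProfile(peptide_id="x", matrix=raw)
        M = expit(raw)
        v = encode_pksaap(prof).reshape(5, 20, 20)
        np.testing.assert_allclose(v[0], np.outer(M[0], M[1]))
        assert (v[1:] == 0).all()  # no valid pairs for k >= 1 at L=2

    def test_matches_bruteforce_on_random_profiles(self, rng):
        for _ in range(200):
            L = int(rng.integers(2, 26))
            raw = rng.normal(size=(L, 20)) * 3
            prof = PSSMProfile(peptide_id="x", matrix=raw)
            np.testing.assert_allclose(
                encode_pksaap(prof), pksaap_oracle(raw), atol=1e-12
            )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seq=valid_seq)
    def test_one_hot_profile_equals_ksaap(self, seq):
        rec = PeptideRecord(id="x", sequence=seq)
        np.testing.assert_allclose(
            encode_pksaap(PSSMProfile.one_hot(rec)),
            encode_ksaap(rec.padded()),
            atol=1e-12,
        )


class TestStructural:
    def _spider2(self, n, rng):
        from aipkit.synthetic import simulate_structural

        return simulate_structural(
            PeptideRecord(id="x", sequence="".join(rng.choice(list(AMINO_ACIDS), n))),
            flavor="SPIDER2",
            seed=3,
        )

    def test_spider2_eight_channels_dimension_200(self, rng):
        v = encode_structural(self._spider2(10, rng))
        assert v.shape == (200,)

    def test_pep2d_three_channels_dimension_75(self, rng):
        from aipkit.synthetic import simulate_structural

        t = simulate_structural(PeptideRecord(id="x", sequence="KLLR"), "PEP2D", seed=1)
        assert encode_structural(t).shape == (75,)

    def test_short_table_zero_padded(self, rng):
        v = encode_structural(self._spider2(4, rng)).reshape(25, 8)
        assert (v[4:] == 0).all()

    def test_angles_rescaled_to_unit(self, rng):
        t = self._spider2(10, rng)
        v = encode_structural(t).reshape(25, 8)
        # channels 1..4 are phi/psi/theta/tau
        assert np.abs(v[:10, 1:5]).max() <= 1.0
        np.testing.assert_allclose(v[:10, 1], t.values["phi"].to_numpy() / 180.0)

    def test_pep2d_rows_must_sum_to_one(self):
        values = pd.DataFrame(
            {"helix_prob": [0.5], "sheet_prob": [0.4], "coil_prob": [0.3]}
        )
        with pytest.raises(EncodingError, match="sum to 1"):
            StructuralTable(peptide_id="x", flavor="PEP2D", values=values)

    def test_overlong_table_truncated_with_warning(self, rng):
        t = self._spider2(25, rng)
        t30 = StructuralTable(
            peptide_id="x",
            flavor="SPIDER2",
            values=pd.concat([t.values, t.values.iloc[:5]], ignore_index=True),
        )
        with pytest.warns(UserWarning, match="truncating"):
            v = encode_structural(t30)
        assert v.shape == (200,)

    def test_flavor_mismatch_rejected(self, rng):
        enc = StructuralEncoder(flavor="PEP2D").fit([])
        with pytest.raises(EncodingError, match="flavor"):
            enc.transform([self._spider2(5, rng)])

    def test_tsv_round_trip(self, tmp_path, rng):
        t = self._spider2(6, rng)
        t.to_tsv(tmp_path / "s.tsv")
        back = StructuralTable.from_tsv(tmp_path / "s.tsv", "SPIDER2", peptide_id="x")
        np.testing.assert_allclose(back.values.to_numpy(), t.values.to_numpy(), atol=1e-6)


class TestTransformers:
    def test_determinism_bit_identical(self, random_peptides):
        recs = random_peptides(20, min_len=4)
        enc = KSAAPEncoder().fit(recs)
        np.testing.assert_array_equal(enc.transform(recs), enc.transform(recs))
        aae = AAIndexEncoder().fit(recs)
        np.testing.assert_array_equal(aae.transform(recs), aae.transform(recs))

    def test_build_feature_matrices_shapes_and_fallback(self, random_peptides):
        recs = random_peptides(10, min_len=4)
        X = build_feature_matrices(recs)  # no profiles: one-hot fallback
        assert X["KSAAP"].shape == (10, 2000)
        assert X["pKSAAP"].shape == (10, 2000)
        assert X["AAindex"].shape == (10, 200)
        np.testing.assert_allclose(X["pKSAAP"], X["KSAAP"], atol=1e-12)

    def test_missing_structural_tables_error(self, random_peptides):
        recs = random_peptides(3, min_len=4)
        with pytest.raises(EncodingError, match="SPIDER2"):
            build_feature_matrices(recs, encoders=["SPIDER2"])
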