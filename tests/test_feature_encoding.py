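import numpy as np
import pytest

import sumoacet as sa
from sumoacet.feature_encoding import (
    ATCHLEY_FACTORS,
    BLOCK_SIZES,
    FACTOR_NAMES,
    SA_STATES,
    SS_STATES,
    ProviderBundle,
    assemble_features,
    descriptor_frame,
    descriptor_table,
    encode_aafactors,
    encode_disorder,
    encode_pssm,
    encode_secondary_structure,
    encode_solvent_accessibility,
    features_to_frame,
    read_features_tsv,
    read_pssm_psiblast,
)
from sumoacet.peptide_windows import BLANK, STANDARD_AA, PeptideWindow


def _window(slots, protein_id="P", center_pos=11, label="negative"):
    return PeptideWindow(protein_id, center_pos, tuple(slots), label)


def _bundle(rng, length):
    return ProviderBundle(
        pssm=rng.normal(size=(length, 20)),
        ss="".join(rng.choice(list(SS_STATES), size=length)),
        sa="".join(rng.choice(list(SA_STATES), size=length)),
        disorder=rng.uniform(size=length),
    )


def test_descriptor_table_structure():
    frame = descriptor_frame()
    counts = frame["block"].value_counts().to_dict()
    assert counts == BLOCK_SIZES
    assert len(frame) == sa.TOTAL_FEATURES == 646
    assert list(frame["index"]) == list(range(646))
    aaf = frame[frame["block"] == "AAFactor"]
    assert 11 not in set(aaf["site"])
    assert len(aaf) == 100


def test_pssm_passthrough_and_padding():
    """A 15-residue protein with the site at position 5: slots 1-6 are BLANK
    and contribute zeros; every covered slot passes its PSSM row through."""
    seq = "AAAAKAAAAAAAAAA"
    record = sa.ProteinRecord("P", seq, [(5, "acetylation")])
    (w,) = sa.extract_windows(record)
    pssm = np.arange(15 * 20, dtype=float).reshape(15, 20)
    bundle = ProviderBundle(pssm=pssm, ss="O" * 15, sa="X" * 15, disorder=np.zeros(15))
    vec = encode_pssm(w, bundle).reshape(21, 20)
    assert np.all(vec[:6] == 0)
    for slot in range(7, 22):
        seq_pos = 5 + slot - 11
        assert np.array_equal(vec[slot - 1], pssm[seq_pos - 1])


def test_aafactor_uniform_window_repeats_table_row():
    w = _window("A" * 10 + "K" + "A" * 10)
    vec = encode_aafactors(w).reshape(20, 5)
    assert np.allclose(vec, np.array(ATCHLEY_FACTORS["A"]))


def test_aafactor_blank_flanks_are_zero():
    w = _window([BLANK] * 10 + ["K"] + [BLANK] * 10)
    assert np.all(encode_aafactors(w) == 0)
    assert encode_aafactors(w).shape == (100,)


def test_secondary_structure_onehot_codes():
    bundle = ProviderBundle(
        pssm=np.zeros((21, 20)), ss="H" + "E" + "O" * 19, sa="B" * 21,
        disorder=np.zeros(21),
    )
    w = _window("A" * 10 + "K" + "A" * 10)
    vec = encode_secondary_structure(w, bundle).reshape(21, 3)
    assert list(vec[0]) == [1, 0, 0]
    assert list(vec[1]) == [0, 1, 0]
    assert list(vec[2]) == [0, 0, 1]
    sav = encode_solvent_accessibility(w, bundle).reshape(21, 2)
    assert np.all(sav == [1, 0])


def test_unknown_state_characters_raise():
    bundle = ProviderBundle(
        pssm=np.zeros((21, 20)), ss="Z" * 21, sa="B" * 21, disorder=np.zeros(21)
    )
    w = _window("A" * 10 + "K" + "A" * 10)
    with pytest.raises(ValueError, match="secondary-structure"):
        encode_secondary_structure(w, bundle)
    bundle2 = ProviderBundle(
        pssm=np.zeros((21, 20)), ss="O" * 21, sa="Q" * 21, disorder=np.zeros(21)
    )
    with pytest.raises(ValueError, match="solvent-accessibility"):
        encode_solvent_accessibility(w, bundle2)


def test_provider_too_short_names_protein():
    w = _window("A" * 10 + "K" + "A" * 10, protein_id="P42")
    bundle = ProviderBundle(
        pssm=np.zeros((10, 20)), ss="O" * 10, sa="B" * 10, disorder=np.zeros(10)
    )
    with pytest.raises(ValueError, match="P42"):
        encode_pssm(w, bundle)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_column_identity_roundtrip(seed):
    """Reading any assembled value back through its descriptor reproduces the
    raw provider entry (or the Atchley table entry, or zero for BLANK)."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(STANDARD_AA), size=30))
    pos = int(rng.integers(1, 31))
    seq = seq[: pos - 1] + "K" + seq[pos:]
    record = sa.ProteinRecord("P", seq, [(pos, "sumoylation")])
    (w,) = sa.extract_windows(record)
    bundle = _bundle(rng, 30)
    vec = assemble_features(w, bundle)
    assert vec.shape == (646,)
    aa_idx = {aa: i for i, aa in enumerate(STANDARD_AA)}
    for d in descriptor_table():
        seq_pos = pos + d.site - 11
        blank = not (1 <= seq_pos <= 30)
        got = vec[d.index]
        if blank:
            assert got == 0
            continue
        if d.block == "PSSM":
            assert got == bundle.pssm[seq_pos - 1, aa_idx[d.subtype]]
        elif d.block == "AAFactor":
            res = seq[seq_pos - 1]
            assert got == ATCHLEY_FACTORS[res][FACTOR_NAMES.index(d.subtype)]
        elif d.block == "SecondaryStructure":
            state = bundle.ss[seq_pos - 1]
            expect = float(("H", "E", "O")[("helix", "strand", "other").index(d.subtype)] == state)
            assert got == expect
        elif d.block == "SolventAccessibility":
            state = bundle.sa[seq_pos - 1]
            expect = float(("B", "X")[("buried", "exposed").index(d.subtype)] == state)
            assert got == expect
        else:
            assert got == bundle.disorder[seq_pos - 1]


def test_onehot_block_sums(tiny_dataset):
    """Per covered slot the 3 SS features sum to 1 and the 2 SA features sum
    to 1; every feature of a BLANK slot is zero in every block."""
    frame = descriptor_frame()
    ss_idx = frame[frame["block"] == "SecondaryStructure"].groupby("site")["index"].apply(list)
    sa_idx = frame[frame["block"] == "SolventAccessibility"].groupby("site")["index"].apply(list)
    by_site = frame.groupby("site")["index"].apply(list)
    for w, x in zip(tiny_dataset["windows"], tiny_dataset["X"]):
        for site in range(1, 22):
            if w.is_blank(site):
                assert np.all(x[by_site[site]] == 0)
            else:
                assert x[ss_idx[site]].sum() == 1.0
                assert x[sa_idx[site]].sum() == 1.0


def test_assembly_is_deterministic(tiny_dataset):
    w = tiny_dataset["windows"][0]
    bundle = tiny_dataset["providers"][w.protein_id]
    a = assemble_features(w, bundle)
    b = assemble_features(w, bundle)
    assert np.array_equal(a, b)


PSIBLAST_SNIPPET = """
Last position-specific scoring matrix computed, weighted observed percentages rounded down, information per position, and relative weight of gapped matches

            A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V   A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V
    1 M    -1  -2  -3  -4  -2  -1  -3  -3  -2   1   2  -2   8   0  -3  -2  -1  -2  -1   1    0   0   0   0   0   0   0   0   0   0   0   0 100   0   0   0   0   0   0   0  0.50 0.20
    2 K    -1   2   0  -1  -3   1   1  -2  -1  -3  -3   5  -2  -3  -1   0  -1  -3  -2  -3    0   8   0   0   0   4   4   0   0   0   0  84   0   0   0   0   0   0   0   0  0.60 0.25
"""


def test_psiblast_ascii_parser_reorders_columns(tmp_path):
    path = tmp_path / "p.pssm"
    path.write_text(PSIBLAST_SNIPPET)
    mat = read_pssm_psiblast(path)
    assert mat.shape == (2, 20)
    # row 1 is an M profile: the M column (PSI-BLAST column 13) holds 8
    m_col = STANDARD_AA.index("M")
    assert mat[0, m_col] == 8
    # row 2 is a K profile: K column holds 5, R column holds 2
    assert mat[1, STANDARD_AA.index("K")] == 5
    assert mat[1, STANDARD_AA.index("R")] == 2
    assert mat[0, STANDARD_AA.index("A")] == -1


def test_features_tsv_roundtrip(tmp_path, tiny_dataset):
    path = tmp_path / "features.tsv"
    frame = features_to_frame(tiny_dataset["windows"], tiny_dataset["X"])
    frame.to_csv(path, sep="\t", index=False, float_format="%.4f")
    meta, X, y = read_features_tsv(path)
    assert np.allclose(X, tiny_dataset["X"], atol=1e-3)
    assert np.array_equal(y, tiny_dataset["y"])
    assert list(meta["protein_id"]) == [w.protein_id for w in tiny_dataset["windows"]]
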