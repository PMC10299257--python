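"""Amino-acid lookups, neighbour windows, PSSM, AAindex, assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aldhdrivers.curation import VariantRecord
from aldhdrivers.sequence_features import (
    GROUP_ORDER,
    NeighbourScheme,
    aa_group5,
    aa_properties,
    aaindex_feature,
    assemble_features,
    build_pssm,
    load_aaindex,
    neighbour_frequency,
    one_hot,
    pssm_variant_scores,
)
from aldhdrivers.tables import AA_PROPERTIES, AMINO_ACIDS


@pytest.mark.parametrize(
    "aa, group",
    [("A", "hydrophobic"), ("N", "polar"), ("D", "negative"),
     ("K", "positive"), ("G", "special")],
)
def test_group5_assignments(aa, group):
    assert aa_group5(aa) == group


def test_group5_partitions_alphabet():
    assert sorted(len([a for a in AMINO_ACIDS if aa_group5(a) == g])
                  for g in {"hydrophobic", "polar", "negative", "positive", "special"}
                  ) == [2, 3, 3, 4, 8]
    with pytest.raises(ValueError):
        aa_group5("B")


def test_aa_properties_orderings():
    # glycine has the smallest molecular volume of the 20
    volumes = {aa: aa_properties(aa)[2] for aa in AMINO_ACIDS}
    assert min(volumes, key=volumes.get) == "G"
    # substitution deltas: identity is zero, G->W grows
    g, w = aa_properties("G"), aa_properties("W")
    assert w[2] - g[2] > 0
    assert aa_properties("R")[0] == max(v[0] for v in AA_PROPERTIES.values())


def test_neighbour_frequency_homogeneous_and_truncated():
    seq = "G" * 31
    full = neighbour_frequency(seq, 16)
    idx = GROUP_ORDER.index("structure_breaking")
    assert full[idx] == pytest.approx(14 / 31)
    assert neighbour_frequency(seq, 1)[idx] == pytest.approx(7 / 31)
    # entries over groups sum to (window actually present) / L
    assert full.sum() == pytest.approx(14 / 31)


def test_neighbour_frequency_worked_example():
    seq = "ACDEFGHIKLMNPQRST"
    vec = neighbour_frequency(seq, 9)
    # {E, Q, K, R} at positions 2-8 and 10-16: E@4, K@9 excluded (site), K? pos9 is K
    idx = GROUP_ORDER.index("long_polar")
    assert vec[idx] == pytest.approx(3 / 17)


def test_neighbour_frequency_rejects_bad_position():
    with pytest.raises(ValueError):
        neighbour_frequency("ACD", 4)
    with pytest.raises(ValueError):
        NeighbourScheme(half_width=0)


@given(st.integers(1, 40), st.integers(0, 2 ** 16))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_neighbour_frequency_bounds(pos, seed):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=40))
    vec = neighbour_frequency(seq, pos)
    assert (vec >= 0).all() and (vec <= 14 / 40).all()
    window = min(40, pos + 7) - max(1, pos - 7)  # excludes the site itself
    assert vec.sum() == pytest.approx(window / 40)


def test_pssm_uniform_column_scores_zero():
    msa = [AMINO_ACIDS[i % 20] for i in range(20)]
    profile = build_pssm(msa, pseudocount=1.0)
    assert np.allclose(profile.scores, 0.0)


def test_pssm_conserved_column_worked_values():
    profile = build_pssm(["A"] * 80, pseudocount=1.0)
    a, c = AMINO_ACIDS.index("A"), AMINO_ACIDS.index("C")
    assert profile.scores[0, a] == pytest.approx(np.log2(0.81 / 0.05), abs=1e-9)
    assert profile.scores[0, c] == pytest.approx(np.log2(0.01 / 0.05), abs=1e-9)
    s_wt, s_mut, delta = pssm_variant_scores(profile, 1, "A", "C")
    assert delta == pytest.approx(-6.340, abs=2e-3)


def test_pssm_row_order_invariance_and_query_gap_columns():
    msa = ["AC-D", "AAGD", "CCGD", "ACGD"]
    shuffled = [msa[0], msa[3], msa[1], msa[2]]
    p1, p2 = build_pssm(msa), build_pssm(shuffled)
    assert np.allclose(p1.scores, p2.scores)
    assert p1.length == 3  # query gap column dropped
    with pytest.raises(ValueError):
        build_pssm(["AC", "ACD"])


def test_pssm_expected_score_under_background_nonpositive():
    rng = np.random.default_rng(2)
    msa = ["".join(rng.choice(list(AMINO_ACIDS), size=15)) for _ in range(30)]
    profile = build_pssm(msa)
    expectation = (profile.background * profile.scores).sum(axis=1)
    assert (expectation <= 1e-9).all()


def test_pssm_variant_scores_identity_and_range():
    profile = build_pssm(["A" * 5] * 10)
    assert pssm_variant_scores(profile, 3, "A", "A")[2] == 0.0
    with pytest.raises(ValueError):
        pssm_variant_scores(profile, 6, "A", "C")


AAINDEX_TEXT = """\
H TEST000101
D synthetic hydrophobicity-like index
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.10    0.20    0.30    0.40    0.50    0.60    0.70    0.80    0.90    1.00
    1.10    1.20    1.30    1.40    1.50    1.60    1.70    1.80    1.90    2.00
//
H TESTM00101
D synthetic substitution matrix
M rows = ACD, cols = ACD
     1.0
     1.5     2.0
     0.5     0.7     3.0
//
"""


def test_aaindex_round_trip_and_lookups():
    entries = load_aaindex(AAINDEX_TEXT)
    assert [e.accession for e in entries] == ["TEST000101", "TESTM00101"]
    idx, mat = entries
    # index entries: antisymmetric difference, zero on identity
    assert aaindex_feature(idx, "A", "A") == 0.0
    assert aaindex_feature(idx, "A", "R") == pytest.approx(-aaindex_feature(idx, "R", "A"))
    # order of the I line: A then R in the first two slots
    assert aaindex_feature(idx, "A", "R") == pytest.approx(0.2 - 0.1)
    # matrix entries: symmetric lower-triangle lookup
    assert aaindex_feature(mat, "A", "C") == 1.5
    assert aaindex_feature(mat, "C", "A") == 1.5
    with pytest.raises(ValueError):
        load_aaindex("H TRUNC\nI A/L\n    0.1\n//")


def test_one_hot_round_trip():
    vocab = ("helix", "strand", "coil")
    vec = one_hot("helix", vocab)
    assert vec.tolist() == [1, 0, 0]
    assert vec.sum() == 1
    assert vocab[int(np.argmax(vec))] == "helix"
    with pytest.raises(ValueError):
        one_hot("sheet", vocab)


def test_assemble_features_gating_and_flags():
    rec = VariantRecord("ALDH1A1", 395, "R", "H")
    seq_feats = {"delta_pI": -3.17}
    struct_feats = {"rsa": 0.2, "dist_interface": 12.0}
    external = {"ddg_ppi1": -1.4, "ddg_nad": 0.5, "dist_nad": 4.0}
    vec = assemble_features(rec, seq_feats, struct_feats, external)
    assert vec["ddg_ppi1"] == 0.0          # 12 A > 10 A gate
    assert vec["ddg_nad"] == 0.5           # 4 A inside the gate
    assert vec["external_missing"] == 0.0
    bare = assemble_features(rec, seq_feats, struct_feats, None)
    assert bare["external_missing"] == 1.0
    assert "ddg_ppi1" not in bare
    with pytest.raises(ValueError):
        assemble_features(rec, {"x": 1.0}, {"x": 2.0}, None)


def test_assembled_schema_constant_across_records(curated_dataset, fixture_bundle):
    import pandas as pd

    from aldhdrivers.pipeline import featurize_dataset, read_fasta

    table, _ = curated_dataset
    subset = table.head(6)
    feats = featurize_dataset(
        subset,
        read_fasta(fixture_bundle.fasta),
        msa_dir=fixture_bundle.msa_dir,
        external=pd.read_csv(fixture_bundle.external, sep="\t"),
    )
    assert len(feats) == len(subset)
    assert not feats.columns.duplicated().any()
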