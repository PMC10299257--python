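"""Geometry, surface, and signature computations on toy structures."""

import numpy as np
import pytest

from aldhdrivers.structure_features import (
    GateConfig,
    ResidueSite,
    SignatureConfig,
    contact_counts,
    dihedral,
    gate_by_distance,
    graph_signature,
    min_distance_to_set,
    phi_psi,
    read_structure,
    residue_depth,
    rsa,
    sasa,
    secondary_structure,
    signature_feature_names,
)
from aldhdrivers.tables import pharmacophore_class
from aldhdrivers.synthetic import generate_toy_structure, write_pdb

from conftest import make_structure


# --- PDB round trip ---------------------------------------------------------

def test_pdb_round_trip_preserves_atoms_and_ligands(tmp_path):
    st = generate_toy_structure(12, seed=3, dimer=False, ligands=True)
    path = tmp_path / "toy.pdb"
    write_pdb(st, path)
    back = read_structure(path)
    assert len(back) == len(st)
    assert "NAD" in back.ligand_sets and "aldehyde" in back.ligand_sets
    assert np.allclose(back.xyz, st.xyz, atol=1e-3)


def test_read_structure_two_chains(tmp_path):
    st = generate_toy_structure(8, seed=3, dimer=True)
    path = tmp_path / "dimer.pdb"
    write_pdb(st, path)
    assert read_structure(path).chains == ["A", "B"]


# --- distances and gating ---------------------------------------------------

def test_min_distance_three_four_five():
    st = make_structure([[0, 0, 0], [3, 4, 0]])
    assert min_distance_to_set(st, ResidueSite("A", 1), np.array([1])) == pytest.approx(5.0)


def test_min_distance_matches_brute_force_and_symmetry():
    rng = np.random.default_rng(5)
    xyz = rng.normal(size=(6, 3)) * 5
    st = make_structure(xyz, resis=[1, 1, 1, 2, 2, 2])
    a = st.residue_atoms(ResidueSite("A", 1))
    b = st.residue_atoms(ResidueSite("A", 2))
    brute = min(np.linalg.norm(xyz[i] - xyz[j]) for i in a for j in b)
    assert min_distance_to_set(st, ResidueSite("A", 1), b) == pytest.approx(brute)
    assert min_distance_to_set(st, ResidueSite("A", 2), a) == pytest.approx(brute)


@pytest.mark.parametrize(
    "value, distance, expected",
    [(-1.2, 12.0, 0.0), (-1.2, 9.9, -1.2), (0.5, 10.0, 0.5)],
)
def test_gate_by_distance(value, distance, expected):
    assert gate_by_distance(value, distance) == expected


def test_gate_idempotent_and_rejects_negative_distance():
    g = GateConfig()
    once = gate_by_distance(-2.0, 7.0, g)
    assert gate_by_distance(once, 7.0, g) == once
    with pytest.raises(ValueError):
        gate_by_distance(1.0, -1.0, g)


# --- SASA / RSA / depth -----------------------------------------------------

def test_sasa_single_sphere_analytic():
    st = make_structure([[0, 0, 0]], names=["CA"], elements=["C"])
    area = sasa(st, n_points=960)[0]
    analytic = 4 * np.pi * (1.7 + 1.4) ** 2
    assert abs(area - analytic) / analytic < 0.01
    # convergence: doubling the sampling changes the result by < 0.5%
    finer = sasa(st, n_points=1920)[0]
    assert abs(finer - area) / analytic < 0.005


def test_sasa_occlusion_monotone():
    one = make_structure([[0, 0, 0]])
    two = make_structure([[0, 0, 0], [2.0, 0, 0]])
    assert sasa(two).sum() < 2 * sasa(one)[0]
    assert sasa(two)[0] < sasa(one)[0]


def test_sasa_buried_atom_near_zero():
    # central atom enclosed by a dense icosahedral-ish shell
    rng = np.random.default_rng(0)
    shell = rng.normal(size=(80, 3))
    shell = 2.2 * shell / np.linalg.norm(shell, axis=1, keepdims=True)
    st = make_structure(np.vstack([[0, 0, 0], shell]))
    assert sasa(st)[0] < 1.0


def test_rsa_limits_and_consistency():
    lone = make_structure([[0, 0, 0]], names=["CA"], resnames=["GLY"])
    assert rsa(lone, ResidueSite("A", 1)) >= 0.9
    # buried residue in a dense cluster
    rng = np.random.default_rng(1)
    shell = rng.normal(size=(100, 3))
    shell = 2.2 * shell / np.linalg.norm(shell, axis=1, keepdims=True)
    st = make_structure(
        np.vstack([[0, 0, 0], shell]),
        resnames=["GLY"] + ["ALA"] * 100,
        resis=[1] + [2] * 100,
    )
    val = rsa(st, ResidueSite("A", 1))
    assert 0 <= val <= 0.05
    # rsa equals the per-atom area sum over the reference value
    from aldhdrivers.tables import MAX_ASA

    tri = make_structure(
        [[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]],
        resnames=["ALA", "GLY", "SER"],
    )
    areas = sasa(tri)
    assert rsa(tri, ResidueSite("A", 2), atom_areas=areas) == pytest.approx(
        min(1.0, areas[1] / MAX_ASA["G"])
    )


def test_residue_depth_orderings(helix):
    # surface residue of a small cluster is shallow
    st = make_structure([[0, 0, 0], [3.8, 0, 0]])
    assert residue_depth(st, ResidueSite("A", 1)) < 1.5
    # centre of a 3-shell lattice is strictly deeper than the periphery
    grid = np.array(
        [[i, j, k] for i in range(-2, 3) for j in range(-2, 3) for k in range(-2, 3)],
        dtype=float,
    ) * 2.0
    centre_idx = int(np.flatnonzero((grid == 0).all(axis=1))[0])
    resis = [1 if i == centre_idx else 2 for i in range(len(grid))]
    st = make_structure(grid, resis=resis)
    d_centre = residue_depth(st, ResidueSite("A", 1))
    corner_idx = 0
    resis2 = [1 if i == corner_idx else 2 for i in range(len(grid))]
    st2 = make_structure(grid, resis=resis2)
    assert d_centre > residue_depth(st2, ResidueSite("A", 1))


def test_depth_symmetry():
    st = make_structure([[0, 0, 0], [5, 0, 0]], resis=[1, 2])
    d1 = residue_depth(st, ResidueSite("A", 1))
    d2 = residue_depth(st, ResidueSite("A", 2))
    assert d1 == pytest.approx(d2, abs=0.3)


# --- dihedrals and secondary structure -------------------------------------

def test_dihedral_worked_example_and_properties():
    p = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)]
    assert dihedral(*p) == pytest.approx(90.0)
    # reversal identity
    assert dihedral(*p[::-1]) == pytest.approx(dihedral(*p))
    # mirror image flips the sign
    m = [(x, y, -z) for x, y, z in p]
    assert dihedral(*m) == pytest.approx(-90.0)
    # planar cis arrangement
    assert dihedral((0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


def test_phi_psi_on_ideal_helix(helix):
    phi, psi = phi_psi(helix, ResidueSite("A", 10))
    assert phi == pytest.approx(-57.0, abs=2.0)
    assert psi == pytest.approx(-47.0, abs=2.0)
    # termini carry the undefined sentinel
    phi1, psi1 = phi_psi(helix, ResidueSite("A", 1))
    assert np.isnan(phi1) and not np.isnan(psi1)
    phiN, psiN = phi_psi(helix, ResidueSite("A", 20))
    assert not np.isnan(phiN) and np.isnan(psiN)


@pytest.mark.parametrize(
    "phi, psi, expected",
    [(-57, -47, "helix"), (-120, 130, "strand"), (60, 60, "coil"),
     (float("nan"), -47, "coil")],
)
def test_secondary_structure_regions(phi, psi, expected):
    assert secondary_structure(phi, psi) == expected


# --- pharmacophores, signatures, contacts ----------------------------------

@pytest.mark.parametrize(
    "resname, atom, expected",
    [
        ("LYS", "NZ", "positive"),
        ("ASP", "OD1", "negative"),
        ("MET", "SD", "sulfur"),
        ("PHE", "CZ", "aromatic"),
        ("ALA", "O", "acceptor"),
        ("ALA", "N", "donor"),
        ("ALA", "CB", "hydrophobic"),
        ("XXX", "X1", "neutral"),
    ],
)
def test_pharmacophore_assignments(resname, atom, expected):
    assert pharmacophore_class(resname, atom) == expected


def test_graph_signature_three_atom_example():
    st = make_structure(
        [[0, 0, 0], [3, 0, 0], [0, 4, 0]],
        names=["CA", "CB", "O"],
        elements=["C", "C", "O"],
        resis=[1, 1, 2],
    )
    cfg = SignatureConfig(cutoffs=(4.0, 6.0))
    sig = dict(zip(signature_feature_names(cfg),
                   graph_signature(st, ResidueSite("A", 1), cfg)))
    assert sig["sig_hydrophobic_hydrophobic_4"] == 1
    assert sig["sig_hydrophobic_hydrophobic_6"] == 1
    assert sig["sig_hydrophobic_acceptor_4"] == 1
    assert sig["sig_hydrophobic_acceptor_6"] == 2
    others = [v for k, v in sig.items()
              if k not in {"sig_hydrophobic_hydrophobic_4", "sig_hydrophobic_hydrophobic_6",
                           "sig_hydrophobic_acceptor_4", "sig_hydrophobic_acceptor_6"}]
    assert all(v == 0 for v in others)


def test_graph_signature_single_atom_and_cumulativity(helix):
    lone = make_structure([[0, 0, 0]])
    assert not graph_signature(lone, ResidueSite("A", 1)).any()
    cfg = SignatureConfig()
    sig = graph_signature(helix, ResidueSite("A", 10), cfg).reshape(-1, len(cfg.cutoffs))
    assert (np.diff(sig, axis=1) >= 0).all()


def test_signature_config_rejects_bad_cutoffs():
    with pytest.raises(ValueError):
        SignatureConfig(cutoffs=(6.0, 4.0))
    with pytest.raises(ValueError):
        SignatureConfig(cutoffs=(-1.0, 2.0))


def test_contact_counts_polar_pair_and_isolated():
    lone = make_structure([[0, 0, 0]])
    assert all(v == 0 for v in contact_counts(lone, ResidueSite("A", 1)).values())
    # donor backbone N 3.0 A from an acceptor backbone O two residues away
    st = make_structure(
        [[0, 0, 0], [3.0, 0, 0]],
        names=["N", "O"],
        elements=["N", "O"],
        resis=[1, 3],
    )
    counts = contact_counts(st, ResidueSite("A", 1))
    assert counts["polar"] == 1
    # adjacent residues are excluded
    st_adj = make_structure(
        [[0, 0, 0], [3.0, 0, 0]], names=["N", "O"], elements=["N", "O"], resis=[1, 2]
    )
    assert contact_counts(st_adj, ResidueSite("A", 1))["polar"] == 0


def test_contact_counts_match_brute_force(helix):
    from aldhdrivers.structure_features import CONTACT_RULES

    site = ResidueSite("A", 10)
    counts = contact_counts(helix, site)
    idx = helix.residue_atoms(site)
    classes = [
        pharmacophore_class(str(helix.resname[i]), str(helix.atom_name[i]),
                            str(helix.element[i]))
        for i in range(len(helix))
    ]
    expected = {k: 0 for k in CONTACT_RULES}
    for i in idx:
        for j in range(len(helix)):
            if helix.chain[j] == site.chain and abs(helix.resi[j] - site.resi) <= 1:
                continue
            d = np.linalg.norm(helix.xyz[i] - helix.xyz[j])
            ci, cj = classes[i], classes[j]
            if ci == cj == "hydrophobic" and d <= 4.5:
                expected["hydrophobic"] += 1
            if {ci, cj} == {"donor", "acceptor"} and d <= 3.5:
                expected["polar"] += 1
            if {ci, cj} == {"positive", "negative"} and d <= 4.0:
                expected["charged"] += 1
            if ci == cj == "aromatic" and d <= 5.0:
                expected["aromatic"] += 1
    assert counts == expected
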