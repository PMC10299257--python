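"""Structure-derived per-residue features.

Works on a light-weight atom-array container parsed from PDB files.
Implements Shrake–Rupley solvent accessibility, relative solvent
accessibility, residue depth (distance to the sampled accessible
surface), backbone dihedrals with a region-based secondary-structure
assignment, distances to interface/ligand atom sets with the 10 Å
affinity gating rule, cumulative pharmacophore pair-count graph
signatures around the mutation site, and simplified typed contact
counts.

Secondary structure and contacts here are deliberately simplified
stand-ins for DSSP / Arpeggio-style assignments: both accept externally
computed per-residue values through the feature-assembly path when a
user has them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .tables import (
    DEFAULT_VDW_RADIUS,
    PHARMACOPHORE_CLASSES,
    VDW_RADII,
    pharmacophore_class,
)

__all__ = [
    "Structure",
    "ResidueSite",
    "SignatureConfig",
    "GateConfig",
    "read_structure",
    "min_distance_to_set",
    "gate_by_distance",
    "sasa",
    "rsa",
    "residue_depth",
    "dihedral",
    "phi_psi",
    "secondary_structure",
    "graph_signature",
    "signature_feature_names",
    "contact_counts",
    "UNDEFINED_ANGLE",
]

UNDEFINED_ANGLE = float("nan")

NAD_CODES = frozenset({"NAD", "NAI"})
DEFAULT_ALDEHYDE_CODE = "ALD"

CONTACT_RULES = {
    "hydrophobic": 4.5,   # apolar carbon pairs
    "polar": 3.5,         # donor-acceptor pairs
    "charged": 4.0,       # positive-negative pairs
    "aromatic": 5.0,      # ring-atom pairs
}


@dataclass(frozen=True)
class ResidueSite:
    chain: str
    resi: int


@dataclass
class SignatureConfig:
    """Distance ladder for the graph-based signature.

    ``cutoffs`` must be strictly ascending; the collection sphere radius
    about the site Cα defaults to the largest cutoff.
    """

    cutoffs: tuple = (4.0, 6.0, 8.0, 10.0)
    sphere_radius: float | None = None

    def __post_init__(self) -> None:
        cut = tuple(float(c) for c in self.cutoffs)
        if any(c <= 0 for c in cut) or any(b <= a for a, b in zip(cut, cut[1:])):
            raise ValueError("cutoffs must be positive and strictly ascending")
        self.cutoffs = cut
        if self.sphere_radius is None:
            self.sphere_radius = cut[-1]


@dataclass
class GateConfig:
    cutoff: float = 10.0
    fill: float = 0.0

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("gate cutoff must be positive")


@dataclass
class Structure:
    """Atom-array representation of a (possibly multi-chain) structure."""

    chain: np.ndarray
    resi: np.ndarray
    resname: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    xyz: np.ndarray
    radius: np.ndarray
    ligand_sets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite coordinates")
        if np.any(self.radius <= 0):
            raise ValueError("non-positive van der Waals radius")

    def __len__(self) -> int:
        return len(self.resi)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain:
            seen.setdefault(str(c))
        return list(seen)

    @property
    def is_ligand(self) -> np.ndarray:
        mask = np.zeros(len(self), dtype=bool)
        for idx in self.ligand_sets.values():
            mask[idx] = True
        return mask

    def residue_atoms(self, site: ResidueSite) -> np.ndarray:
        idx = np.flatnonzero((self.chain == site.chain) & (self.resi == site.resi))
        if idx.size == 0:
            raise KeyError(f"site {site.chain}:{site.resi} has no atoms")
        return idx

    def atom_index(self, site: ResidueSite, name: str) -> int | None:
        idx = self.residue_atoms(site)
        hit = idx[self.atom_name[idx] == name]
        return int(hit[0]) if hit.size else None

    def chain_residues(self, chain: str) -> np.ndarray:
        resis = self.resi[self.chain == chain]
        return np.unique(resis)


def read_structure(
    path,
    aldehyde_code: str = DEFAULT_ALDEHYDE_CODE,
) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Element-based van der Waals radii come from the bundled table;
    unknown elements get the default carbon radius with a warning.
    HETATM residues named NAD/NAI and the configured aldehyde code are
    collected into ``ligand_sets``.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    chains, resis, resnames, names, elements, coords, radii = [], [], [], [], [], [], []
    ligand_sets: dict[str, list[int]] = {}
    i = 0
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    el = atom.element.name.upper()
                    if el not in VDW_RADII:
                        warnings.warn(f"unknown element {el!r}; using default radius")
                    chains.append(chain.name)
                    resis.append(res.seqid.num)
                    resnames.append(res.name)
                    names.append(atom.name)
                    elements.append(el)
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    radii.append(VDW_RADII.get(el, DEFAULT_VDW_RADIUS))
                    if res.name in NAD_CODES:
                        ligand_sets.setdefault("NAD", []).append(i)
                    elif res.name == aldehyde_code:
                        ligand_sets.setdefault("aldehyde", []).append(i)
                    i += 1
        break  # first model only
    if i == 0:
        raise ValueError(f"no atoms in {path}")
    return Structure(
        chain=np.array(chains, dtype=object),
        resi=np.array(resis, dtype=int),
        resname=np.array(resnames, dtype=object),
        atom_name=np.array(names, dtype=object),
        element=np.array(elements, dtype=object),
        xyz=np.array(coords, dtype=float),
        radius=np.array(radii, dtype=float),
        ligand_sets={k: np.array(v, dtype=int) for k, v in ligand_sets.items()},
    )


def min_distance_to_set(structure: Structure, site: ResidueSite, atom_set: np.ndarray) -> float:
    """Minimum Euclidean distance between the site's atoms and an atom set."""
    atom_set = np.asarray(atom_set, dtype=int)
    if atom_set.size == 0:
        raise ValueError("empty atom set")
    a = structure.xyz[structure.residue_atoms(site)]
    b = structure.xyz[atom_set]
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return float(d.min())


def gate_by_distance(value: float, distance: float, gate: GateConfig | None = None) -> float:
    """Zero out an affinity change for sites beyond the distance cutoff.

    Mutations further than ``gate.cutoff`` (inclusive boundary keeps the
    value) from the relevant interface or ligand are assigned the fill
    value to mark a negligible effect.
    """
    gate = gate or GateConfig()
    if distance < 0:
        raise ValueError("negative distance")
    return float(value) if distance <= gate.cutoff else float(gate.fill)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic near-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def sasa(
    structure: Structure,
    probe: float = 1.4,
    n_points: int = 960,
    return_surface_points: bool = False,
):
    """Shrake–Rupley solvent-accessible surface area per atom (Å²).

    Each atom is expanded by the probe radius and sampled with
    ``n_points`` sphere points; the exposed fraction times the expanded
    sphere's area is that atom's contribution.
    """
    if n_points < 10:
        raise ValueError("n_points must be >= 10")
    if len(structure) < 1:
        raise ValueError("empty structure")
    unit = _sphere_points(n_points)
    xyz = structure.xyz
    rad = structure.radius + probe
    tree = cKDTree(xyz)
    max_r = rad.max()
    areas = np.empty(len(structure))
    surface_points = []
    for i in range(len(structure)):
        pts = xyz[i] + rad[i] * unit
        neighbours = tree.query_ball_point(xyz[i], rad[i] + max_r)
        neighbours = [j for j in neighbours if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            exposed &= d2 > rad[j] ** 2
        frac = exposed.mean()
        areas[i] = frac * 4.0 * np.pi * rad[i] ** 2
        if return_surface_points and exposed.any():
            surface_points.append(pts[exposed])
    if return_surface_points:
        surf = (
            np.vstack(surface_points) if surface_points else np.empty((0, 3))
        )
        return areas, surf
    return areas


def rsa(
    structure: Structure,
    site: ResidueSite,
    probe: float = 1.4,
    n_points: int = 960,
    atom_areas: np.ndarray | None = None,
) -> float:
    """Relative solvent accessibility of the site residue, in [0, 1].

    ``atom_areas`` may carry a precomputed :func:`sasa` result to avoid
    recomputing the whole-structure surface per site.
    """
    from .tables import MAX_ASA, THREE_TO_ONE

    idx = structure.residue_atoms(site)
    resname = str(structure.resname[idx[0]])
    one = THREE_TO_ONE.get(resname)
    if one is None or one not in MAX_ASA:
        raise KeyError(f"no max-ASA reference for residue type {resname!r}")
    if atom_areas is None:
        atom_areas = sasa(structure, probe=probe, n_points=n_points)
    return float(np.clip(atom_areas[idx].sum() / MAX_ASA[one], 0.0, 1.0))


def residue_depth(
    structure: Structure,
    site: ResidueSite,
    probe: float = 1.4,
    n_points: int = 960,
    surface_points: np.ndarray | None = None,
) -> float:
    """Mean burial depth of the residue's atoms below the surface (Å).

    The surface is the set of exposed Shrake–Rupley sample points; each
    atom's depth is its distance to the nearest surface point with the
    expanded-sphere offset (vdW radius + probe) subtracted, floored at
    zero, so solvent-exposed residues sit at depth ≈ 0.
    """
    if len(structure) < 2:
        raise ValueError("need >= 2 atoms for residue depth")
    if surface_points is None:
        _, surface_points = sasa(
            structure, probe=probe, n_points=n_points, return_surface_points=True
        )
    if len(surface_points) == 0:
        raise ValueError("structure exposes no surface points")
    idx = structure.residue_atoms(site)
    tree = cKDTree(surface_points)
    d, _ = tree.query(structure.xyz[idx])
    depth = np.clip(d - (structure.radius[idx] + probe), 0.0, None)
    return float(np.mean(depth))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle in degrees, in (−180, 180].

    Uses the atan2 convention on the two plane normals; degenerate
    geometry (coincident or collinear points) raises.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise ValueError("degenerate geometry for dihedral")
    b2n = b2 / np.linalg.norm(b2)
    angle = np.degrees(np.arctan2(np.dot(np.cross(n1, n2), b2n), np.dot(n1, n2)))
    if angle <= -180.0:
        angle += 360.0
    return float(angle)


def phi_psi(structure: Structure, site: ResidueSite) -> tuple[float, float]:
    """Backbone (φ, ψ) for a residue; NaN sentinel at chain termini.

    φ needs the preceding residue's C, ψ the following residue's N;
    a missing neighbour residue yields the sentinel, while a missing
    backbone atom on the residue itself is an error.
    """
    for name in ("N", "CA", "C"):
        if structure.atom_index(site, name) is None:
            raise ValueError(f"missing backbone atom {name} at {site.chain}:{site.resi}")
    n = structure.xyz[structure.atom_index(site, "N")]
    ca = structure.xyz[structure.atom_index(site, "CA")]
    c = structure.xyz[structure.atom_index(site, "C")]

    prev_site = ResidueSite(site.chain, site.resi - 1)
    next_site = ResidueSite(site.chain, site.resi + 1)
    phi = UNDEFINED_ANGLE
    psi = UNDEFINED_ANGLE
    try:
        c_prev = structure.atom_index(prev_site, "C")
    except KeyError:
        c_prev = None
    if c_prev is not None:
        phi = dihedral(structure.xyz[c_prev], n, ca, c)
    try:
        n_next = structure.atom_index(next_site, "N")
    except KeyError:
        n_next = None
    if n_next is not None:
        psi = dihedral(n, ca, c, structure.xyz[n_next])
    return phi, psi


def secondary_structure(phi: float, psi: float) -> str:
    """Region-based secondary-structure call from backbone dihedrals.

    α-helical and β-strand basins of the Ramachandran plot map to
    ``helix`` and ``strand``; everything else (including undefined
    dihedrals at termini) is ``coil``.
    """
    if np.isnan(phi) or np.isnan(psi):
        return "coil"
    if -100 <= phi <= -30 and -80 <= psi <= -5:
        return "helix"
    if -180 <= phi <= -90 and 90 <= psi <= 180:
        return "strand"
    return "coil"


def _unordered_pairs() -> list[tuple[str, str]]:
    cls = PHARMACOPHORE_CLASSES
    return [(cls[i], cls[j]) for i in range(len(cls)) for j in range(i, len(cls))]


def signature_feature_names(config: SignatureConfig | None = None) -> list[str]:
    config = config or SignatureConfig()
    return [
        f"sig_{c1}_{c2}_{cut:g}"
        for c1, c2 in _unordered_pairs()
        for cut in config.cutoffs
    ]


def graph_signature(
    structure: Structure,
    site: ResidueSite,
    config: SignatureConfig | None = None,
) -> np.ndarray:
    """Cumulative pharmacophore pair counts around the mutation site.

    Heavy atoms within ``sphere_radius`` of the site Cα become graph
    nodes labelled by pharmacophore class; for each distance cutoff the
    number of node pairs of each unordered class combination within that
    distance is counted. Counts are cumulative, i.e. non-decreasing
    along the cutoff ladder. Vector layout matches
    :func:`signature_feature_names`.
    """
    config = config or SignatureConfig()
    ca = structure.atom_index(site, "CA")
    if ca is None:
        raise ValueError(f"site {site.chain}:{site.resi} has no CA atom")
    heavy = np.flatnonzero(structure.element != "H")
    dist_to_ca = np.linalg.norm(structure.xyz[heavy] - structure.xyz[ca], axis=1)
    sphere = heavy[dist_to_ca <= config.sphere_radius]

    classes = [
        pharmacophore_class(
            str(structure.resname[i]), str(structure.atom_name[i]), str(structure.element[i])
        )
        for i in sphere
    ]
    pairs = _unordered_pairs()
    pair_index = {frozenset(p) if p[0] != p[1] else frozenset([p[0]]): k
                  for k, p in enumerate(pairs)}
    ncut = len(config.cutoffs)
    counts = np.zeros((len(pairs), ncut))
    xyz = structure.xyz[sphere]
    for a in range(len(sphere)):
        for b in range(a + 1, len(sphere)):
            d = np.linalg.norm(xyz[a] - xyz[b])
            if d > config.cutoffs[-1]:
                continue
            key = frozenset([classes[a], classes[b]])
            row = pair_index[key]
            for k, cut in enumerate(config.cutoffs):
                if d <= cut:
                    counts[row, k] += 1
                    break
    # convert per-bin tallies into cumulative counts along the ladder
    counts = np.cumsum(counts, axis=1)
    return counts.reshape(-1)


def contact_counts(structure: Structure, site: ResidueSite) -> dict[str, int]:
    """Typed contacts between the site residue and non-adjacent residues.

    Distance rules (heavy atoms): hydrophobic–hydrophobic ≤ 4.5 Å,
    donor–acceptor ≤ 3.5 Å, positive–negative ≤ 4.0 Å,
    aromatic–aromatic ≤ 5.0 Å. Residues adjacent in sequence on the
    same chain are excluded.
    """
    idx = structure.residue_atoms(site)
    others = np.flatnonzero(
        ~(
            (structure.chain == site.chain)
            & (np.abs(structure.resi - site.resi) <= 1)
        )
        & (structure.element != "H")
    )
    site_classes = [
        pharmacophore_class(str(structure.resname[i]), str(structure.atom_name[i]),
                            str(structure.element[i]))
        for i in idx
    ]
    other_classes = [
        pharmacophore_class(str(structure.resname[j]), str(structure.atom_name[j]),
                            str(structure.element[j]))
        for j in others
    ]
    out = {k: 0 for k in CONTACT_RULES}
    for i, ci in zip(idx, site_classes):
        if structure.element[i] == "H":
            continue
        for j, cj in zip(others, other_classes):
            d = np.linalg.norm(structure.xyz[i] - structure.xyz[j])
            pair = {ci, cj}
            if ci == "hydrophobic" and cj == "hydrophobic" and d <= CONTACT_RULES["hydrophobic"]:
                out["hydrophobic"] += 1
            if pair == {"donor", "acceptor"} and d <= CONTACT_RULES["polar"]:
                out["polar"] += 1
            if pair == {"positive", "negative"} and d <= CONTACT_RULES["charged"]:
                out["charged"] += 1
            if ci == "aromatic" and cj == "aromatic" and d <= CONTACT_RULES["aromatic"]:
                out["aromatic"] += 1
    return out
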