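"""Synthetic study data: toy structures, catalogues, MSAs, feature tables.

The generator fabricates everything the pipeline consumes so it can be
exercised without downloads: ideal-helix toy structures (monomer, dimer,
and a complex with NAD and aldehyde ligand clusters), source catalogues
engineered so that curation reproduces the study's per-gene label
distribution exactly (30 benign / 40 cancer-risk / 38 non-cancer
disease across the 19 human ALDH genes), multiple sequence alignments
with controllable column conservation, and labelled feature tables with
planted distributional effects: pathogenic variants are more
destabilising, less mutation-tolerant, and more buried, while
substrate-binding affinity changes are mild (|ΔΔG| below 1 kcal/mol)
and most sites lie more than 10 Å from the ligands.

Everything is deterministic per seed. The planted effect sizes are
invented defaults chosen to reproduce the qualitative directions of the
real data; they live in :class:`SyntheticConfig` only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .structure_features import Structure
from .tables import AMINO_ACIDS, ONE_TO_THREE, VDW_RADII

__all__ = [
    "TABLE1_COUNTS",
    "SyntheticConfig",
    "FixtureBundle",
    "generate_toy_structure",
    "write_pdb",
    "generate_msa",
    "generate_fixture",
    "generate_feature_table",
]

# Per-gene (benign, cancer_risk, non_cancer_disease) counts of the
# curated study dataset.
TABLE1_COUNTS: dict[str, tuple[int, int, int]] = {
    "ALDH1A1": (0, 4, 0),
    "ALDH1A2": (1, 8, 4),
    "ALDH1A3": (1, 2, 6),
    "ALDH1B1": (4, 2, 0),
    "ALDH1L1": (0, 1, 0),
    "ALDH1L2": (0, 0, 0),
    "ALDH2": (1, 2, 0),
    "ALDH3A1": (2, 4, 0),
    "ALDH3A2": (0, 0, 0),
    "ALDH3B1": (1, 0, 0),
    "ALDH3B2": (5, 3, 0),
    "ALDH4A1": (5, 0, 0),
    "ALDH5A1": (4, 0, 5),
    "ALDH6A1": (0, 1, 3),
    "ALDH7A1": (1, 1, 9),
    "ALDH8A1": (1, 6, 0),
    "ALDH9A1": (0, 0, 0),
    "ALDH16A1": (2, 4, 0),
    "ALDH18A1": (2, 2, 11),
}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic generator.

    Group means/sds for the planted effects (kcal/mol for ΔΔG columns,
    dimensionless for MTR and RSA) reproduce the qualitative directions
    of the curated data; the ligand-binding bound keeps substrate
    affinity changes mild.
    """

    per_gene_counts: dict = field(default_factory=lambda: dict(TABLE1_COUNTS))
    ddg_stability: dict = field(default_factory=lambda: {
        "benign": (-0.2, 0.6),
        "cancer_risk": (-0.7, 0.8),
        "non_cancer_disease": (-1.5, 0.8),
    })
    mtr: dict = field(default_factory=lambda: {
        "benign": (0.95, 0.05),
        "cancer_risk": (0.70, 0.10),
        "non_cancer_disease": (0.70, 0.10),
    })
    rsa: dict = field(default_factory=lambda: {
        "benign": (0.45, 0.15),
        "cancer_risk": (0.25, 0.12),
        "non_cancer_disease": (0.25, 0.12),
    })
    ligand_ddg_sd: float = 0.35
    ligand_ddg_bound: float = 1.0
    frac_far_from_ligand: float = 0.8
    gate_cutoff: float = 10.0
    tumour_mix: tuple = (("adenocarcinoma", 0.35), ("cutaneous_melanoma", 0.35),
                         ("other", 0.30))
    n_noise_features: int = 5
    sequence_length: int = 120
    decoys_per_source: int = 3
    msa_rows: int = 30
    n_benign_clinvar_overlap: int = 3

    def __post_init__(self) -> None:
        if any(min(v) < 0 for v in self.per_gene_counts.values()):
            raise ValueError("negative per-gene counts")
        if self.ligand_ddg_bound <= 0:
            raise ValueError("ligand bound must be positive")
        for table in (self.ddg_stability, self.mtr, self.rsa):
            if any(sd <= 0 for _, sd in table.values()):
                raise ValueError("standard deviations must be positive")


@dataclass
class FixtureBundle:
    root: Path
    catalogs: dict            # source name -> TSV path
    fasta: Path
    msa_dir: Path
    structure_dir: Path
    external: Path
    manifest: Path
    expected_counts: dict


# ---------------------------------------------------------------------------
# toy structures

_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231, "CA-CB": 1.53}
_ANGLE = {"N-CA-C": 111.0, "CA-C-N": 116.6, "C-N-CA": 121.7,
          "CA-C-O": 120.8, "C-CA-CB": 110.1}
_HELIX_PHI, _HELIX_PSI, _OMEGA = -57.0, -47.0, 180.0


def _place(a, b, c, bond, angle_deg, torsion_deg):
    """Natural-extension placement: new atom bonded to c with the given
    internal coordinates relative to (a, b, c)."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def generate_toy_structure(
    n_residues: int,
    sequence: str | None = None,
    geometry: str = "ideal_helix",
    seed: int = 0,
    dimer: bool = False,
    ligands: bool = False,
    pocket_residue: int | None = None,
) -> Structure:
    """Ideal α-helix toy structure with optional dimer partner and ligands.

    Backbone atoms (N, CA, C, O) plus CB (except glycine) are placed by
    internal-coordinate chaining at canonical helix dihedrals
    (φ = −57°, ψ = −47°, ω = 180°). The dimer adds a translated copy as
    chain B; ``ligands`` adds two small HETATM clusters (NAD and an
    aldehyde) near the pocket residue's Cα.
    """
    if n_residues < 5:
        raise ValueError("need at least 5 residues")
    if geometry != "ideal_helix":
        raise ValueError(f"unknown geometry {geometry!r}")
    rng = np.random.default_rng(seed)
    if sequence is None:
        sequence = "".join(rng.choice(list(AMINO_ACIDS), size=n_residues))
    if len(sequence) != n_residues:
        raise ValueError("sequence length mismatch")

    # backbone chain
    N = [np.array([0.0, 0.0, 0.0])]
    ca0 = np.array([_BOND["N-CA"], 0.0, 0.0])
    ang = np.radians(_ANGLE["N-CA-C"])
    c0 = ca0 + _BOND["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    CA, C = [ca0], [c0]
    for _ in range(1, n_residues):
        n_next = _place(N[-1], CA[-1], C[-1], _BOND["C-N"], _ANGLE["CA-C-N"], _HELIX_PSI)
        ca_next = _place(CA[-1], C[-1], n_next, _BOND["N-CA"], _ANGLE["C-N-CA"], _OMEGA)
        c_next = _place(C[-1], n_next, ca_next, _BOND["CA-C"], _ANGLE["N-CA-C"], _HELIX_PHI)
        N.append(n_next)
        CA.append(ca_next)
        C.append(c_next)

    chains, resis, resnames, names, elements, coords = [], [], [], [], [], []

    def add_atom(chain, resi, resname, name, element, pos):
        chains.append(chain)
        resis.append(resi)
        resnames.append(resname)
        names.append(name)
        elements.append(element)
        coords.append(np.asarray(pos, dtype=float))

    def add_chain(chain_id, offset):
        for i in range(n_residues):
            resname = ONE_TO_THREE[sequence[i]]
            add_atom(chain_id, i + 1, resname, "N", "N", N[i] + offset)
            add_atom(chain_id, i + 1, resname, "CA", "C", CA[i] + offset)
            add_atom(chain_id, i + 1, resname, "C", "C", C[i] + offset)
            o = _place(N[i], CA[i], C[i], _BOND["C-O"], _ANGLE["CA-C-O"], _HELIX_PSI + 180.0)
            add_atom(chain_id, i + 1, resname, "O", "O", o + offset)
            if sequence[i] != "G":
                cb = _place(N[i], C[i], CA[i], _BOND["CA-CB"], _ANGLE["C-CA-CB"], 122.6)
                add_atom(chain_id, i + 1, resname, "CB", "C", cb + offset)

    add_chain("A", np.zeros(3))
    if dimer:
        add_chain("B", np.array([0.0, 9.0, 0.0]))

    ligand_sets: dict[str, list[int]] = {}
    if ligands:
        pocket = pocket_residue or (n_residues // 2)
        anchor = CA[pocket - 1]
        nad_offsets = rng.normal(0, 0.8, size=(6, 3)) + np.array([4.5, -3.0, 0.0])
        ald_offsets = rng.normal(0, 0.6, size=(3, 3)) + np.array([-4.0, -3.5, 0.0])
        start = len(coords)
        for k, off in enumerate(nad_offsets):
            add_atom("L", 900, "NAD", f"C{k + 1}", "C", anchor + off)
        ligand_sets["NAD"] = list(range(start, start + len(nad_offsets)))
        start = len(coords)
        for k, off in enumerate(ald_offsets):
            add_atom("L", 901, "ALD", f"C{k + 1}", "C", anchor + off)
        ligand_sets["aldehyde"] = list(range(start, start + len(ald_offsets)))

    return Structure(
        chain=np.array(chains, dtype=object),
        resi=np.array(resis, dtype=int),
        resname=np.array(resnames, dtype=object),
        atom_name=np.array(names, dtype=object),
        element=np.array(elements, dtype=object),
        xyz=np.array(coords, dtype=float),
        radius=np.array([VDW_RADII[e] for e in elements], dtype=float),
        ligand_sets={k: np.array(v, dtype=int) for k, v in ligand_sets.items()},
    )


def write_pdb(structure: Structure, path) -> None:
    """Write a Structure as fixed-format PDB ATOM/HETATM records."""
    is_ligand = structure.is_ligand
    lines = []
    for i in range(len(structure)):
        record = "HETATM" if is_ligand[i] else "ATOM  "
        name = str(structure.atom_name[i])
        name_field = f" {name:<3s}" if len(name) < 4 else name
        x, y, z = structure.xyz[i]
        lines.append(
            f"{record}{i + 1:5d} {name_field} {structure.resname[i]:<3s} "
            f"{structure.chain[i]:1s}{structure.resi[i]:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{structure.element[i]:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# MSAs

def generate_msa(
    query: str,
    n_rows: int,
    conservation: np.ndarray | None = None,
    seed: int = 0,
) -> list[str]:
    """Aligned homolog set: per column, rows mutate away from the query
    with probability (1 − conservation[column])."""
    if n_rows < 2:
        raise ValueError("need at least 2 rows")
    L = len(query)
    rng = np.random.default_rng(seed)
    if conservation is None:
        conservation = rng.uniform(0.6, 0.98, size=L)
    conservation = np.asarray(conservation, dtype=float)
    if len(conservation) != L:
        raise ValueError("conservation profile length mismatch")
    rows = [query]
    alphabet = list(AMINO_ACIDS)
    for _ in range(n_rows - 1):
        row = []
        for c in range(L):
            if rng.random() < 1.0 - conservation[c]:
                choices = [a for a in alphabet if a != query[c]]
                row.append(choices[int(rng.integers(len(choices)))])
            else:
                row.append(query[c])
        rows.append("".join(row))
    return rows


# ---------------------------------------------------------------------------
# source catalogues + fixture bundle

def _random_sequence(rng, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _variant_token(seq: str, pos: int, mut: str) -> str:
    return f"{seq[pos - 1]}{pos}{mut}"


def _draw_mut(rng, wt: str) -> str:
    choices = [a for a in AMINO_ACIDS if a != wt]
    return choices[int(rng.integers(len(choices)))]


def generate_fixture(
    config: SyntheticConfig | None = None,
    out_dir=None,
    seed: int = 0,
) -> FixtureBundle:
    """Write the full fixture bundle and a manifest of expected counts.

    Catalogues are engineered so the curation rules recover exactly the
    configured per-gene label counts: cancer-risk keys appear in all
    three cancer-like sources with passing quality flags (with decoys
    failing at least one requirement), gnomAD-like allele frequencies
    straddle the 1% threshold, ClinVar-like records carry the
    literature-validation flags, including benign-overlap records that
    corroborate population benign labels, and one deliberate
    conflicting key exercises conflict removal.
    """
    config = config or SyntheticConfig()
    if out_dir is None:
        raise ValueError("out_dir is required")
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    genes = list(config.per_gene_counts)
    sequences = {g: _random_sequence(rng, config.sequence_length) for g in genes}

    cosmic_rows, tcga_rows, cbio_rows = [], [], []
    gnomad_rows, clinvar_rows = [], []
    cancer_keys, benign_keys, noncancer_keys = [], [], []

    for gene in genes:
        n_benign, n_cancer, n_noncancer = config.per_gene_counts[gene]
        seq = sequences[gene]
        n_total = n_benign + n_cancer + n_noncancer + 4 * config.decoys_per_source + 2
        if n_total > len(seq):
            raise ValueError(f"{gene}: more variants requested than positions")
        positions = rng.choice(
            np.arange(1, len(seq) + 1), size=n_total, replace=False
        )
        cursor = 0

        def take(n):
            nonlocal cursor
            out = positions[cursor:cursor + n]
            cursor += n
            return [int(p) for p in out]

        for pos in take(n_cancer):
            mut = _draw_mut(rng, seq[pos - 1])
            token = _variant_token(seq, pos, mut)
            cancer_keys.append((gene, pos, seq[pos - 1], mut))
            cosmic_rows.append((gene, token, "confirmed", "clear", "yes", None))
            tcga_rows.append((gene, token, None))
            cbio_rows.append((gene, token, "true", None))

        for pos in take(n_benign):
            mut = _draw_mut(rng, seq[pos - 1])
            token = _variant_token(seq, pos, mut)
            benign_keys.append((gene, pos, seq[pos - 1], mut))
            gnomad_rows.append((gene, token, float(rng.uniform(0.012, 0.2))))

        for pos in take(n_noncancer):
            mut = _draw_mut(rng, seq[pos - 1])
            token = _variant_token(seq, pos, mut)
            noncancer_keys.append((gene, pos, seq[pos - 1], mut))
            clinvar_rows.append((gene, token, "pathogenic", "true", "developmental_disorder"))

        # decoys: fail at least one curation requirement each
        for pos in take(config.decoys_per_source):
            token = _variant_token(seq, pos, _draw_mut(rng, seq[pos - 1]))
            cosmic_rows.append((gene, token, "unknown", "clear", "yes", None))
            tcga_rows.append((gene, token, None))
            cbio_rows.append((gene, token, "true", None))
        for pos in take(config.decoys_per_source):
            token = _variant_token(seq, pos, _draw_mut(rng, seq[pos - 1]))
            cosmic_rows.append((gene, token, "confirmed", "clear", "yes", None))
            tcga_rows.append((gene, token, None))  # absent from cbio
        for pos in take(config.decoys_per_source):
            token = _variant_token(seq, pos, _draw_mut(rng, seq[pos - 1]))
            gnomad_rows.append((gene, token, float(rng.uniform(1e-5, 0.0099))))
        for pos in take(config.decoys_per_source):
            token = _variant_token(seq, pos, _draw_mut(rng, seq[pos - 1]))
            clinvar_rows.append((gene, token, "pathogenic", "false", "case_report"))

    # deliberate conflicting key: passes the cancer intersection AND the
    # population-frequency rule, so conflict removal drops it entirely
    conflict_gene = next(iter(genes))
    seq = sequences[conflict_gene]
    used = {k[1] for k in cancer_keys + benign_keys + noncancer_keys
            if k[0] == conflict_gene}
    conflict_pos = next(p for p in range(1, len(seq) + 1) if p not in used)
    mut = _draw_mut(rng, seq[conflict_pos - 1])
    token = _variant_token(seq, conflict_pos, mut)
    cosmic_rows.append((conflict_gene, token, "confirmed", "clear", "yes", None))
    tcga_rows.append((conflict_gene, token, None))
    cbio_rows.append((conflict_gene, token, "true", None))
    gnomad_rows.append((conflict_gene, token, 0.05))

    # tumour-type mix over the cancer records
    mix_counts = _mix_counts(len(cancer_keys), config.tumour_mix)
    types = [t for (t, _), n in zip(config.tumour_mix, mix_counts) for _ in range(n)]
    rng.shuffle(types)
    type_by_key = dict(zip(cancer_keys, types))
    cosmic_rows = [
        (g, tok, s, st, lit,
         type_by_key.get(_row_key(g, tok, sequences), tt))
        for (g, tok, s, st, lit, tt) in cosmic_rows
    ]
    tcga_rows = [(g, tok, type_by_key.get(_row_key(g, tok, sequences), tt))
                 for (g, tok, tt) in tcga_rows]
    cbio_rows = [(g, tok, cur, type_by_key.get(_row_key(g, tok, sequences), tt))
                 for (g, tok, cur, tt) in cbio_rows]

    # ClinVar benign-overlap records corroborating population labels
    overlap = [benign_keys[i] for i in
               rng.choice(len(benign_keys), size=config.n_benign_clinvar_overlap,
                          replace=False)]
    for gene, pos, wt, mut in overlap:
        clinvar_rows.append((gene, f"{wt}{pos}{mut}", "benign", "true", None))

    # write everything
    catalogs = {}
    frames = {
        "cosmic_like": pd.DataFrame(
            cosmic_rows,
            columns=["gene", "variant", "somatic_status", "sample_type",
                     "literature_support", "tumour_type"],
        ),
        "tcga_like": pd.DataFrame(tcga_rows, columns=["gene", "variant", "tumour_type"]),
        "cbio_like": pd.DataFrame(
            cbio_rows, columns=["gene", "variant", "curated_set", "tumour_type"]
        ),
        "gnomad_like": pd.DataFrame(
            gnomad_rows, columns=["gene", "variant", "allele_frequency"]
        ),
        "clinvar_like": pd.DataFrame(
            clinvar_rows,
            columns=["gene", "variant", "clinical_significance",
                     "literature_validated", "condition"],
        ),
    }
    for name, df in frames.items():
        path = root / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        catalogs[name] = path

    fasta = root / "sequences.fasta"
    with open(fasta, "w") as fh:
        for gene in genes:
            fh.write(f">{gene}\n{sequences[gene]}\n")

    msa_dir = root / "msa"
    msa_dir.mkdir(exist_ok=True)
    for k, gene in enumerate(genes):
        rows = generate_msa(sequences[gene], config.msa_rows,
                            seed=int(rng.integers(2 ** 31)))
        with open(msa_dir / f"{gene}.afa", "w") as fh:
            for j, row in enumerate(rows):
                fh.write(f">{gene}_{j}\n{row}\n")

    structure_dir = root / "structures"
    structure_dir.mkdir(exist_ok=True)
    for gene in genes:
        st_seed = int(rng.integers(2 ** 31))
        mono = generate_toy_structure(config.sequence_length, sequences[gene], seed=st_seed)
        dim = generate_toy_structure(config.sequence_length, sequences[gene],
                                     seed=st_seed, dimer=True)
        comp = generate_toy_structure(config.sequence_length, sequences[gene],
                                      seed=st_seed, ligands=True)
        write_pdb(mono, structure_dir / f"{gene}_monomer.pdb")
        write_pdb(dim, structure_dir / f"{gene}_dimer.pdb")
        write_pdb(comp, structure_dir / f"{gene}_complex.pdb")

    # externally supplied predictor columns for every curated variant
    ext_rows = []
    for keys, label in ((benign_keys, "benign"), (cancer_keys, "cancer_risk"),
                        (noncancer_keys, "non_cancer_disease")):
        mtr_label = "benign" if label == "benign" else label
        for gene, pos, wt, mut in keys:
            mu, sd = config.ddg_stability[label]
            m_mu, m_sd = config.mtr[mtr_label]
            bound = config.ligand_ddg_bound
            ext_rows.append({
                "gene": gene, "protein_position": pos, "wt_aa": wt, "mut_aa": mut,
                "ddg_stability": float(rng.normal(mu, sd)),
                "ddg_ppi1": float(rng.normal(-0.3, 0.5)),
                "ddg_ppi2": float(rng.normal(-0.3, 0.5)),
                "ddg_nad": float(np.clip(rng.normal(0.0, config.ligand_ddg_sd),
                                          -0.999 * bound, 0.999 * bound)),
                "ddg_aldehyde": float(np.clip(rng.normal(0.0, config.ligand_ddg_sd),
                                               -0.999 * bound, 0.999 * bound)),
                "dvib_entropy": float(rng.normal(0.0, 0.5)),
                "mtr": float(np.clip(rng.normal(m_mu, m_sd), 0.0, 1.0)),
                "plddt": float(np.clip(rng.normal(85.0, 8.0), 0.0, 100.0)),
            })
    external = root / "external.tsv"
    pd.DataFrame(ext_rows).to_csv(external, sep="\t", index=False)

    expected = {
        gene: dict(zip(("benign", "cancer_risk", "non_cancer_disease"),
                       config.per_gene_counts[gene]))
        for gene in genes
    }
    totals = {
        label: sum(v[label] for v in expected.values())
        for label in ("benign", "cancer_risk", "non_cancer_disease")
    }
    manifest_data = {
        "seed": seed,
        "expected_counts": expected,
        "expected_totals": totals,
        "tumour_type_counts": dict(
            zip([t for t, _ in config.tumour_mix], [int(n) for n in mix_counts])
        ),
        "n_benign_clinvar_overlap": config.n_benign_clinvar_overlap,
    }
    manifest = root / "manifest.json"
    manifest.write_text(json.dumps(manifest_data, indent=2))

    return FixtureBundle(
        root=root, catalogs=catalogs, fasta=fasta, msa_dir=msa_dir,
        structure_dir=structure_dir, external=external, manifest=manifest,
        expected_counts=manifest_data["expected_counts"],
    )


def _row_key(gene, token, sequences):
    from .curation import parse_variant_notation

    wt, pos, mut = parse_variant_notation(token)
    return (gene, pos, wt, mut)


def _mix_counts(n: int, mix) -> list[int]:
    """Largest-remainder apportionment of n records over the mix."""
    raw = [n * frac for _, frac in mix]
    counts = [int(np.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])
    for i in range(remainder):
        counts[order[i]] += 1
    return counts


# ---------------------------------------------------------------------------
# feature tables with planted effects

def generate_feature_table(
    config: SyntheticConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Labelled feature table drawn from the configured distributions.

    One row per variant of the per-gene label counts. Planted effects:
    stability ΔΔG and MTR shift with pathogenicity, RSA marks
    pathogenic variants as more buried; ligand-binding ΔΔG is drawn and
    clipped so |value| stays below the configured bound, and the
    distance columns place ~80% of sites beyond the 10 Å gate.
    Independent standard-normal noise features are appended. Affinity
    columns are raw (ungated); apply :func:`...gate_by_distance` or the
    pipeline's gating step downstream.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    rows = []
    bound = config.ligand_ddg_bound
    for gene, (n_benign, n_cancer, n_noncancer) in config.per_gene_counts.items():
        for label, n in (("benign", n_benign), ("cancer_risk", n_cancer),
                         ("non_cancer_disease", n_noncancer)):
            for _ in range(n):
                mu, sd = config.ddg_stability[label]
                m_mu, m_sd = config.mtr[label]
                r_mu, r_sd = config.rsa[label]
                far = rng.random() < config.frac_far_from_ligand
                cut = config.gate_cutoff
                row = {
                    "gene": gene,
                    "label": label,
                    "ddg_stability": float(rng.normal(mu, sd)),
                    "mtr": float(np.clip(rng.normal(m_mu, m_sd), 0.0, 1.0)),
                    "rsa": float(np.clip(rng.normal(r_mu, r_sd), 0.0, 1.0)),
                    "dist_nad": float(rng.uniform(cut + 0.5, 35.0) if far
                                      else rng.uniform(2.5, cut)),
                    "dist_aldehyde": float(rng.uniform(cut + 0.5, 35.0) if far
                                           else rng.uniform(2.5, cut)),
                    "dist_interface": float(rng.uniform(2.0, 25.0)),
                    "ddg_nad": float(np.clip(rng.normal(0.0, config.ligand_ddg_sd),
                                              -0.999 * bound, 0.999 * bound)),
                    "ddg_aldehyde": float(np.clip(rng.normal(0.0, config.ligand_ddg_sd),
                                                   -0.999 * bound, 0.999 * bound)),
                    "ddg_ppi1": float(rng.normal(-0.3, 0.5)),
                    "plddt": float(np.clip(rng.normal(85.0, 8.0), 0.0, 100.0)),
                }
                for k in range(config.n_noise_features):
                    row[f"noise_{k + 1}"] = float(rng.normal())
                rows.append(row)
    return pd.DataFrame(rows)
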