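"""Sequence-derived features for missense variants.

Covers the physicochemical lookups (five-group side-chain class,
isoelectric point, molecular weight, molecular volume), neighbour-window
group frequencies around the mutation site, position-specific scoring
matrix (PSSM) construction from a multiple sequence alignment with
per-variant score retrieval, AAindex flat-file ingestion, one-hot
encoding, and the final assembly of a named feature vector combining
sequence, structure, and externally supplied predictor columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curation import VariantRecord
from .structure_features import GateConfig, gate_by_distance
from .tables import AA_GROUP5, AA_PROPERTIES, AMINO_ACIDS, NEIGHBOUR_GROUPS

__all__ = [
    "NeighbourScheme",
    "PSSMProfile",
    "AAIndexEntry",
    "aa_group5",
    "aa_properties",
    "neighbour_frequency",
    "build_pssm",
    "pssm_variant_scores",
    "load_aaindex",
    "aaindex_feature",
    "one_hot",
    "assemble_features",
]

GROUP_ORDER = tuple(NEIGHBOUR_GROUPS)


@dataclass
class NeighbourScheme:
    """Fifteen-residue window: seven residues either side of the site."""

    half_width: int = 7
    include_site: bool = False

    def __post_init__(self) -> None:
        if self.half_width < 1:
            raise ValueError("half_width must be >= 1")


@dataclass
class PSSMProfile:
    """Per-position log-odds (bits) over the 20 amino acids."""

    scores: np.ndarray          # L x 20
    background: np.ndarray      # 20 fractions summing to 1
    pseudocount: float

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite PSSM scores")

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass
class AAIndexEntry:
    """One AAindex record: a 20-vector index or a 20x20 matrix."""

    accession: str
    kind: str                   # "index" | "matrix"
    payload: dict


def aa_group5(aa: str) -> str:
    """Five-group side-chain class of an amino acid."""
    try:
        return AA_GROUP5[aa.upper()]
    except KeyError:
        raise ValueError(f"unknown amino acid {aa!r}") from None


def aa_properties(aa: str) -> tuple[float, float, float]:
    """(isoelectric point, molecular weight Da, molecular volume Å³)."""
    try:
        return AA_PROPERTIES[aa.upper()]
    except KeyError:
        raise ValueError(f"unknown amino acid {aa!r}") from None


def neighbour_frequency(
    sequence: str,
    position: int,
    scheme: NeighbourScheme | None = None,
) -> np.ndarray:
    """Group frequencies of the residues flanking a 1-based position.

    Counts the members of each of the seven composition groups among up
    to ``half_width`` residues before and after the site (site excluded,
    window truncated at the termini), divided by the full sequence
    length — mirroring the convention of normalising by protein length
    rather than window size.
    """
    scheme = scheme or NeighbourScheme()
    L = len(sequence)
    if not 1 <= position <= L:
        raise ValueError(f"position {position} outside sequence of length {L}")
    lo = max(1, position - scheme.half_width)
    hi = min(L, position + scheme.half_width)
    window = [
        sequence[i - 1]
        for i in range(lo, hi + 1)
        if scheme.include_site or i != position
    ]
    out = np.zeros(len(GROUP_ORDER))
    for k, group in enumerate(GROUP_ORDER):
        members = NEIGHBOUR_GROUPS[group]
        out[k] = sum(1 for aa in window if aa in members) / L
    return out


def build_pssm(
    msa: list[str],
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
) -> PSSMProfile:
    """Build a log-odds PSSM from an aligned set of sequences.

    The first row is the query and defines the profile columns: columns
    where the query has a gap are dropped. Per column the frequency of
    amino acid *a* is ``(n_a + α) / (N + 20α)`` with N the number of
    residues observed (gaps excluded), and the score is
    ``log2(f_a / background_a)`` in bits.
    """
    if len(msa) < 2:
        raise ValueError("need at least two aligned sequences")
    width = len(msa[0])
    if any(len(row) != width for row in msa):
        raise ValueError("ragged alignment")
    if background is None:
        background = np.full(20, 1.0 / 20.0)
    background = np.asarray(background, dtype=float)
    aa_index = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
    query = msa[0]
    columns = [c for c in range(width) if query[c] != "-"]
    scores = np.zeros((len(columns), 20))
    for out_c, c in enumerate(columns):
        counts = np.zeros(20)
        for row in msa:
            aa = row[c].upper()
            if aa in aa_index:
                counts[aa_index[aa]] += 1
        n = counts.sum()
        freqs = (counts + pseudocount) / (n + 20.0 * pseudocount)
        scores[out_c] = np.log2(freqs / background)
    return PSSMProfile(scores=scores, background=background, pseudocount=pseudocount)


def pssm_variant_scores(
    profile: PSSMProfile, position: int, wt: str, mut: str
) -> tuple[float, float, float]:
    """(score_wt, score_mut, score_mut − score_wt) at a 1-based position."""
    if not 1 <= position <= profile.length:
        raise ValueError(f"position {position} outside profile of length {profile.length}")
    aa_index = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
    row = profile.scores[position - 1]
    s_wt = float(row[aa_index[wt.upper()]])
    s_mut = float(row[aa_index[mut.upper()]])
    return s_wt, s_mut, s_mut - s_wt


# AAindex flat-format order of the 'I' line values.
_AAINDEX_I_ORDER = "ARNDCQEGHILKMFPSTWYV"


def load_aaindex(text: str) -> list[AAIndexEntry]:
    """Parse AAindex flat-format records (H/I/M lines, '//' terminated).

    'I' records carry a 20-vector over two value lines; 'M' records carry
    a (possibly lower-triangular) 20x20 matrix, mirrored to symmetric.
    """
    entries = []
    for block in text.split("//"):
        lines = [ln for ln in block.splitlines() if ln.strip()]
        if not lines:
            continue
        accession = None
        i = 0
        while i < len(lines):
            line = lines[i]
            tag = line[:1]
            if tag == "H":
                accession = line[1:].strip()
            elif tag == "I":
                values: list[float] = []
                i += 1
                while i < len(lines) and lines[i][:1] == " ":
                    values.extend(float(v) for v in lines[i].split())
                    i += 1
                if accession is None or len(values) != 20:
                    raise ValueError(
                        f"truncated AAindex index record {accession or '<no accession>'}"
                    )
                payload = dict(zip(_AAINDEX_I_ORDER, values))
                entries.append(AAIndexEntry(accession, "index", payload))
                continue
            elif tag == "M":
                spec = line[1:]
                rows_order = _field(spec, "rows") or _AAINDEX_I_ORDER
                cols_order = _field(spec, "cols") or _AAINDEX_I_ORDER
                mat_rows: list[list[float]] = []
                i += 1
                while i < len(lines) and lines[i][:1] == " ":
                    mat_rows.append([float(v) for v in lines[i].split()])
                    i += 1
                if accession is None or len(mat_rows) != len(rows_order):
                    raise ValueError(
                        f"truncated AAindex matrix record {accession or '<no accession>'}"
                    )
                payload = {}
                for r, aa_r in enumerate(rows_order):
                    for c, val in enumerate(mat_rows[r]):
                        payload[(aa_r, cols_order[c])] = val
                entries.append(AAIndexEntry(accession, "matrix", payload))
                continue
            i += 1
    return entries


def _field(spec: str, name: str) -> str | None:
    # parses "rows = ARNDCQEGHILKMFPSTWYV, cols = ..." fragments
    for part in spec.split(","):
        if "=" in part:
            k, v = part.split("=", 1)
            if k.strip() == name:
                return v.strip()
    return None


def aaindex_feature(entry: AAIndexEntry, wt: str, mut: str) -> float:
    """Substitution feature from an AAindex entry.

    Index entries give ``value(mut) − value(wt)`` (antisymmetric);
    matrix entries give the symmetric matrix lookup.
    """
    wt, mut = wt.upper(), mut.upper()
    if entry.kind == "index":
        return float(entry.payload[mut] - entry.payload[wt])
    if (wt, mut) in entry.payload:
        return float(entry.payload[(wt, mut)])
    return float(entry.payload[(mut, wt)])


def one_hot(category: str, vocabulary: tuple) -> np.ndarray:
    """0/1 indicator vector over an ordered vocabulary."""
    if category not in vocabulary:
        raise ValueError(f"category {category!r} not in vocabulary {vocabulary}")
    out = np.zeros(len(vocabulary))
    out[vocabulary.index(category)] = 1.0
    return out


# External predictor columns gated by distance: column -> distance column.
GATED_COLUMNS = {
    "ddg_ppi1": "dist_interface",
    "ddg_ppi2": "dist_interface",
    "ddg_nad": "dist_nad",
    "ddg_aldehyde": "dist_aldehyde",
}


def assemble_features(
    record: VariantRecord,
    sequence_features: dict[str, float],
    structure_features: dict[str, float],
    external_columns: dict[str, float] | None = None,
    gate: GateConfig | None = None,
) -> dict[str, float]:
    """Merge the per-variant feature groups into one named vector.

    Duplicate names across groups are an error. Ligand/interface
    affinity-change columns are gated by their distance columns (a
    mutation beyond the cutoff contributes 0). When no external table is
    supplied the vector carries only the internally computed features and
    an ``external_missing`` flag.
    """
    gate = gate or GateConfig()
    out: dict[str, float] = {}
    for group in (sequence_features, structure_features):
        for name, value in group.items():
            if name in out:
                raise ValueError(f"duplicate feature name {name!r}")
            out[name] = float(value)
    if external_columns:
        for name, value in external_columns.items():
            if name in out:
                raise ValueError(f"duplicate feature name {name!r}")
            if name in GATED_COLUMNS:
                dist_col = GATED_COLUMNS[name]
                distance = external_columns.get(dist_col, out.get(dist_col))
                if distance is not None and np.isfinite(value):
                    value = gate_by_distance(value, float(distance), gate)
            out[name] = float(value)
        out["external_missing"] = 0.0
    else:
        out["external_missing"] = 1.0
    return out
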