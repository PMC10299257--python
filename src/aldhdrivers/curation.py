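"""Curation and labelling of ALDH missense variants.

Variants are gathered from five kinds of source catalogue — three
cancer-oriented somatic lists (COSMIC-like, TCGA-like, cBioPortal-like),
a population list with allele frequencies (gnomAD-like), and a clinical
list with literature-validation flags (ClinVar-like) — and distilled
into a single table with one of three labels:

* ``cancer_risk``          — present in all three cancer catalogues after
  per-source quality filters;
* ``benign``               — population allele frequency strictly above a
  threshold (default 1%);
* ``non_cancer_disease``   — clinically pathogenic with literature
  validation.

Keys appearing under two distinct labels are removed entirely, so the
curated table carries a single label per (gene, position, wt, mut) key.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .tables import AMINO_ACIDS

__all__ = [
    "VariantRecord",
    "CurationConfig",
    "VariantParseError",
    "parse_variant_notation",
    "validate_against_sequence",
    "filter_cosmic_like",
    "filter_cbio_like",
    "intersect_cancer_sources",
    "label_benign_by_af",
    "label_noncancer",
    "remove_conflicts",
    "build_dataset",
]

LABELS = ("benign", "cancer_risk", "non_cancer_disease")

_VARIANT_RE = re.compile(r"^(?:p\.)?([A-Za-z])(\d+)([A-Za-z])$")

_TRUTHY = {"true", "yes", "y", "1", "confirmed", "clear"}


class VariantParseError(ValueError):
    """Raised for malformed variant tokens or catalogue rows."""


@dataclass(frozen=True)
class VariantRecord:
    """One missense variant with its curated label and provenance."""

    gene: str
    protein_position: int
    wt_aa: str
    mut_aa: str
    label: str = "unlabelled"
    sources: frozenset = field(default_factory=frozenset)
    allele_frequency: float | None = None
    tumour_type: str | None = None
    condition: str | None = None
    literature_validated: bool | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.gene, self.protein_position, self.wt_aa, self.mut_aa)


@dataclass
class CurationConfig:
    """Thresholds applied during curation.

    ``af_threshold`` is a fraction; "common" variants must exceed it
    strictly (a frequency exactly at the threshold is not benign).
    """

    af_threshold: float = 0.01
    alpha: float = 0.05
    conflict_policy: str = "drop"

    def __post_init__(self) -> None:
        if not 0 < self.af_threshold < 1:
            raise ValueError("af_threshold must be in (0, 1)")


def parse_variant_notation(token: str) -> tuple[str, int, str]:
    """Parse protein-level variant notation like ``R395H`` or ``p.S86L``.

    Returns ``(wt_aa, position, mut_aa)`` with upper-cased letters.
    """
    m = _VARIANT_RE.match(token.strip())
    if m is None:
        raise VariantParseError(f"malformed variant token: {token!r}")
    wt, pos, mut = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    if wt not in AMINO_ACIDS or mut not in AMINO_ACIDS:
        raise VariantParseError(f"non-amino-acid letter in token: {token!r}")
    if wt == mut:
        raise VariantParseError(f"synonymous token (wt == mut): {token!r}")
    if pos < 1:
        raise VariantParseError(f"position must be >= 1: {token!r}")
    return wt, pos, mut


def validate_against_sequence(record: VariantRecord, sequence: str) -> bool:
    """True iff the record's position and WT residue match the sequence.

    Positions are 1-based; out-of-range positions and WT mismatches both
    return False rather than raising.
    """
    if not sequence:
        raise ValueError("empty sequence")
    pos = record.protein_position
    return 1 <= pos <= len(sequence) and sequence[pos - 1] == record.wt_aa


def _is_true(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in _TRUTHY


def filter_cosmic_like(entries: pd.DataFrame) -> pd.DataFrame:
    """Keep somatic entries with clear sample type and literature support."""
    for col in ("somatic_status", "sample_type", "literature_support"):
        if col not in entries.columns:
            raise VariantParseError(f"cosmic-like catalogue missing field {col!r}")
    if entries.empty:
        return entries
    mask = (
        entries["somatic_status"].map(_is_true)
        & entries["sample_type"].map(_is_true)
        & entries["literature_support"].map(_is_true)
    )
    return entries[mask]


def filter_cbio_like(entries: pd.DataFrame) -> pd.DataFrame:
    """Keep entries from the curated, non-redundant study set."""
    if "curated_set" not in entries.columns:
        raise VariantParseError("cbio-like catalogue missing field 'curated_set'")
    if entries.empty:
        return entries
    return entries[entries["curated_set"].map(_is_true)]


def intersect_cancer_sources(cosmic_keys, tcga_keys, cbio_keys) -> set:
    """Three-way intersection of variant keys across the cancer sources."""
    return set(cosmic_keys) & set(tcga_keys) & set(cbio_keys)


def label_benign_by_af(entries: pd.DataFrame, af_threshold: float = 0.01) -> list[VariantRecord]:
    """Label population variants with AF strictly above the threshold benign."""
    records = []
    for _, row in entries.iterrows():
        af = float(row["allele_frequency"])
        if not 0 <= af <= 1:
            raise ValueError(f"allele frequency outside [0, 1]: {af}")
        if af > af_threshold:
            records.append(
                VariantRecord(
                    gene=row["gene"],
                    protein_position=int(row["protein_position"]),
                    wt_aa=row["wt_aa"],
                    mut_aa=row["mut_aa"],
                    label="benign",
                    sources=frozenset({"gnomad_like"}),
                    allele_frequency=af,
                )
            )
    return records


def label_noncancer(entries: pd.DataFrame) -> list[VariantRecord]:
    """Label literature-validated pathogenic clinical variants."""
    records = []
    for _, row in entries.iterrows():
        if not _is_true(row["literature_validated"]):
            continue
        if str(row["clinical_significance"]).strip().lower() != "pathogenic":
            continue
        records.append(
            VariantRecord(
                gene=row["gene"],
                protein_position=int(row["protein_position"]),
                wt_aa=row["wt_aa"],
                mut_aa=row["mut_aa"],
                label="non_cancer_disease",
                sources=frozenset({"clinvar_like"}),
                condition=row.get("condition"),
                literature_validated=True,
            )
        )
    return records


def remove_conflicts(records: list[VariantRecord]) -> list[VariantRecord]:
    """Drop keys labelled with >= 2 distinct labels; merge duplicate sources.

    Order of the surviving records follows first appearance.
    """
    by_key: dict[tuple, list[VariantRecord]] = {}
    order: list[tuple] = []
    for rec in records:
        if rec.key not in by_key:
            order.append(rec.key)
        by_key.setdefault(rec.key, []).append(rec)
    out = []
    for key in order:
        group = by_key[key]
        labels = {r.label for r in group}
        if len(labels) > 1:
            continue
        merged_sources = frozenset().union(*(r.sources for r in group))
        base = group[0]
        out.append(
            VariantRecord(
                gene=base.gene,
                protein_position=base.protein_position,
                wt_aa=base.wt_aa,
                mut_aa=base.mut_aa,
                label=base.label,
                sources=merged_sources,
                allele_frequency=next(
                    (r.allele_frequency for r in group if r.allele_frequency is not None),
                    None,
                ),
                tumour_type=next((r.tumour_type for r in group if r.tumour_type), None),
                condition=next((r.condition for r in group if r.condition), None),
                literature_validated=next(
                    (r.literature_validated for r in group if r.literature_validated is not None),
                    None,
                ),
            )
        )
    return out


def _parse_catalog(df: pd.DataFrame, sequences: dict[str, str] | None) -> pd.DataFrame:
    """Expand the 'variant' column into (wt_aa, protein_position, mut_aa)
    and drop rows that do not map onto the canonical sequence."""
    parsed = []
    for _, row in df.iterrows():
        try:
            wt, pos, mut = parse_variant_notation(str(row["variant"]))
        except VariantParseError as exc:
            raise VariantParseError(f"gene {row.get('gene')}: {exc}") from exc
        parsed.append((wt, pos, mut))
    out = df.copy()
    out[["wt_aa", "protein_position", "mut_aa"]] = pd.DataFrame(
        parsed, index=df.index, columns=["wt_aa", "protein_position", "mut_aa"]
    ) if parsed else pd.DataFrame(columns=["wt_aa", "protein_position", "mut_aa"], dtype=object)
    if parsed and sequences is not None:
        keep = [
            validate_against_sequence(
                VariantRecord(row["gene"], int(row["protein_position"]),
                              row["wt_aa"], row["mut_aa"]),
                sequences.get(row["gene"], ""),
            ) if row["gene"] in sequences else False
            for _, row in out.iterrows()
        ]
        out = out[keep]
    return out


def _keys(df: pd.DataFrame) -> set:
    return {
        (row["gene"], int(row["protein_position"]), row["wt_aa"], row["mut_aa"])
        for _, row in df.iterrows()
    }


def build_dataset(
    catalogs: dict[str, pd.DataFrame],
    sequences: dict[str, str],
    config: CurationConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the full curation pipeline over parsed source catalogues.

    Parameters
    ----------
    catalogs
        Mapping with keys ``cosmic_like``, ``tcga_like``, ``cbio_like``,
        ``gnomad_like``, ``clinvar_like``; each value is a raw catalogue
        DataFrame with ``gene`` and ``variant`` columns plus the
        source-specific fields.
    sequences
        Canonical protein sequence per gene symbol; variants that do not
        match their sequence are discarded.

    Returns
    -------
    (table, counts)
        ``table`` has one row per surviving variant; ``counts`` maps
        gene -> {label: n} plus a ``totals`` entry.
    """
    config = config or CurationConfig()
    empty = pd.DataFrame(columns=["gene", "variant"])
    parsed = {
        name: _parse_catalog(catalogs.get(name, empty), sequences)
        for name in ("cosmic_like", "tcga_like", "cbio_like", "gnomad_like", "clinvar_like")
    }

    cosmic = filter_cosmic_like(parsed["cosmic_like"]) if not parsed["cosmic_like"].empty else parsed["cosmic_like"]
    cbio = filter_cbio_like(parsed["cbio_like"]) if not parsed["cbio_like"].empty else parsed["cbio_like"]
    tcga = parsed["tcga_like"]

    cancer_keys = intersect_cancer_sources(_keys(cosmic), _keys(tcga), _keys(cbio))
    tumour_types = {}
    for _, row in cosmic.iterrows():
        key = (row["gene"], int(row["protein_position"]), row["wt_aa"], row["mut_aa"])
        if key in cancer_keys and "tumour_type" in row:
            tumour_types.setdefault(key, row["tumour_type"])

    records: list[VariantRecord] = []
    for key in sorted(cancer_keys):
        records.append(
            VariantRecord(
                gene=key[0], protein_position=key[1], wt_aa=key[2], mut_aa=key[3],
                label="cancer_risk",
                sources=frozenset({"cosmic_like", "tcga_like", "cbio_like"}),
                tumour_type=tumour_types.get(key),
            )
        )
    records.extend(label_benign_by_af(parsed["gnomad_like"], config.af_threshold))
    records.extend(label_noncancer(parsed["clinvar_like"]))

    # ClinVar entries flagged benign with literature validation corroborate
    # population-frequency benign labels (merged, not double counted).
    cv = parsed["clinvar_like"]
    if not cv.empty:
        for _, row in cv.iterrows():
            if (
                _is_true(row["literature_validated"])
                and str(row["clinical_significance"]).strip().lower() == "benign"
            ):
                records.append(
                    VariantRecord(
                        gene=row["gene"], protein_position=int(row["protein_position"]),
                        wt_aa=row["wt_aa"], mut_aa=row["mut_aa"],
                        label="benign", sources=frozenset({"clinvar_like"}),
                        literature_validated=True,
                    )
                )

    curated = remove_conflicts(records)

    table = pd.DataFrame(
        [
            {
                "gene": r.gene,
                "protein_position": r.protein_position,
                "wt_aa": r.wt_aa,
                "mut_aa": r.mut_aa,
                "label": r.label,
                "sources": ",".join(sorted(r.sources)),
                "allele_frequency": r.allele_frequency,
                "tumour_type": r.tumour_type,
                "condition": r.condition,
            }
            for r in curated
        ],
        columns=["gene", "protein_position", "wt_aa", "mut_aa", "label",
                 "sources", "allele_frequency", "tumour_type", "condition"],
    )

    counts: dict = {}
    for gene in sorted({r.gene for r in curated}):
        sub = table[table["gene"] == gene]
        counts[gene] = {label: int((sub["label"] == label).sum()) for label in LABELS}
    counts["totals"] = {
        label: int((table["label"] == label).sum()) for label in LABELS
    }
    return table, counts
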