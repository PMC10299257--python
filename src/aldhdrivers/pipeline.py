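"""End-to-end orchestration: simulate → curate → featurize → screen →
embed → train → report.

Each stage writes its artifact under the run directory and the run
manifest records seeds, row counts, and content checksums, so a rerun
with the same configuration is bit-identical apart from file
timestamps.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import curation, models, screen, sequence_features as seqf, structure_features as stf
from .synthetic import SyntheticConfig, generate_fixture

__all__ = ["RunConfig", "run_pipeline", "featurize_dataset", "read_fasta", "read_msa"]


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    af_threshold: float = 0.01
    alpha: float = 0.05
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    cv_repetitions: int = 5
    schemes: tuple = ("bootstrapped_kcv", "lopo")
    embed_method: str = "pca"
    n_estimators: int = 100
    include_signatures: bool = True


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_msa(path) -> list[str]:
    from Bio import SeqIO

    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]


def _structure_cache(structure_dir: Path, gene: str):
    """Load the gene's monomer/dimer/complex and precompute surfaces."""
    mono = stf.read_structure(structure_dir / f"{gene}_monomer.pdb")
    dim = stf.read_structure(structure_dir / f"{gene}_dimer.pdb")
    comp = stf.read_structure(structure_dir / f"{gene}_complex.pdb")
    areas, surface = stf.sasa(mono, return_surface_points=True)
    chain_b = np.flatnonzero(dim.chain == "B")
    return {
        "monomer": mono, "dimer": dim, "complex": comp,
        "areas": areas, "surface": surface, "chain_b": chain_b,
    }


def _variant_structure_features(cache, resi: int, sig_config) -> dict[str, float]:
    mono = cache["monomer"]
    site = stf.ResidueSite("A", resi)
    phi, psi = stf.phi_psi(mono, site)
    ss = stf.secondary_structure(phi, psi)
    feats = {
        "rsa": stf.rsa(mono, site, atom_areas=cache["areas"]),
        "residue_depth": stf.residue_depth(mono, site, surface_points=cache["surface"]),
        "phi": 0.0 if np.isnan(phi) else phi,
        "psi": 0.0 if np.isnan(psi) else psi,
    }
    for k, name in enumerate(("helix", "strand", "coil")):
        feats[f"ss_{name}"] = float(ss == name)
    feats["dist_interface"] = stf.min_distance_to_set(cache["dimer"], site, cache["chain_b"])
    comp = cache["complex"]
    feats["dist_nad"] = stf.min_distance_to_set(comp, site, comp.ligand_sets["NAD"])
    feats["dist_aldehyde"] = stf.min_distance_to_set(
        comp, site, comp.ligand_sets["aldehyde"]
    )
    if sig_config is not None:
        sig = stf.graph_signature(mono, site, sig_config)
        for name, value in zip(stf.signature_feature_names(sig_config), sig):
            feats[name] = float(value)
    contacts = stf.contact_counts(mono, site)
    for k, v in contacts.items():
        feats[f"contacts_{k}"] = float(v)
    return feats


def featurize_dataset(
    curated: pd.DataFrame,
    sequences: dict[str, str],
    msa_dir: Path | None = None,
    structure_dir: Path | None = None,
    external: pd.DataFrame | None = None,
    include_signatures: bool = True,
) -> pd.DataFrame:
    """Assemble the full feature table for a curated variant set.

    Sequence features always; structure features when a structure
    directory is available; external predictor columns merged by
    (gene, position, wt, mut) with distance gating of affinity columns.
    """
    from .tables import GROUP5_VOCAB

    sig_config = stf.SignatureConfig() if include_signatures else None
    pssm_cache: dict[str, seqf.PSSMProfile] = {}
    struct_cache: dict[str, dict] = {}
    ext_index = {}
    if external is not None:
        for _, row in external.iterrows():
            key = (row["gene"], int(row["protein_position"]), row["wt_aa"], row["mut_aa"])
            ext_index[key] = {
                k: float(v) for k, v in row.items()
                if k not in ("gene", "protein_position", "wt_aa", "mut_aa")
            }

    rows = []
    for _, rec in curated.iterrows():
        gene = rec["gene"]
        pos = int(rec["protein_position"])
        wt, mut = rec["wt_aa"], rec["mut_aa"]
        seq = sequences[gene]

        sf: dict[str, float] = {}
        for tag, aa in (("wt", wt), ("mut", mut)):
            onehot = seqf.one_hot(seqf.aa_group5(aa), GROUP5_VOCAB)
            for g, v in zip(GROUP5_VOCAB, onehot):
                sf[f"{tag}_group_{g}"] = float(v)
        p_wt, p_mut = seqf.aa_properties(wt), seqf.aa_properties(mut)
        for k, name in enumerate(("pI", "mw", "volume")):
            sf[f"delta_{name}"] = p_mut[k] - p_wt[k]
        for g, v in zip(seqf.GROUP_ORDER, seqf.neighbour_frequency(seq, pos)):
            sf[f"nbr_{g}"] = float(v)
        if msa_dir is not None:
            if gene not in pssm_cache:
                pssm_cache[gene] = seqf.build_pssm(read_msa(Path(msa_dir) / f"{gene}.afa"))
            s_wt, s_mut, delta = seqf.pssm_variant_scores(pssm_cache[gene], pos, wt, mut)
            sf.update(pssm_wt=s_wt, pssm_mut=s_mut, pssm_delta=delta)

        stf_feats: dict[str, float] = {}
        if structure_dir is not None:
            if gene not in struct_cache:
                struct_cache[gene] = _structure_cache(Path(structure_dir), gene)
            stf_feats = _variant_structure_features(struct_cache[gene], pos, sig_config)

        record = curation.VariantRecord(gene, pos, wt, mut, label=rec["label"])
        key = (gene, pos, wt, mut)
        vector = seqf.assemble_features(record, sf, stf_feats, ext_index.get(key))
        vector["gene"] = gene
        vector["label"] = rec["label"]
        vector["protein_position"] = pos
        vector["wt_aa"] = wt
        vector["mut_aa"] = mut
        rows.append(vector)
    out = pd.DataFrame(rows)
    lead = ["gene", "protein_position", "wt_aa", "mut_aa", "label"]
    return out[lead + [c for c in out.columns if c not in lead]]


TASKS = {
    "cancer": ("cancer_risk", "gradient_boosting"),
    "noncancer": ("non_cancer_disease", "adaptive_boosting"),
}


def task_labels(labels: pd.Series, task: str) -> np.ndarray:
    """Binary labels: the task's pathogenic class vs everything else."""
    positive, _ = TASKS[task]
    return (labels == positive).astype(int).to_numpy()


def _numeric_features(features: pd.DataFrame) -> pd.DataFrame:
    drop = {"gene", "protein_position", "wt_aa", "mut_aa", "label"}
    cols = [
        c for c in features.columns
        if c not in drop and np.issubdtype(features[c].dtype, np.number)
    ]
    return features[cols].fillna(0.0)


def train_task(
    features: pd.DataFrame,
    task: str,
    scheme_kind: str,
    seed: int = 0,
    repetitions: int = 5,
    n_estimators: int = 100,
) -> dict:
    """Cross-validate one task under one validation scheme."""
    _, algorithm = TASKS[task]
    y = task_labels(features["label"], task)
    X = _numeric_features(features).to_numpy(dtype=float)
    spec = models.ModelSpec(algorithm=algorithm, n_estimators=n_estimators, seed=seed)
    scheme = models.ValidationScheme(
        kind=scheme_kind, repetitions=repetitions, seed=seed
    )
    metrics, detail = models.cross_validate(
        spec, X, y, scheme, groups=features["gene"].to_numpy()
    )
    return {"task": task, "scheme": scheme_kind, "metrics": metrics.as_dict(),
            "sd": detail.get("sd", {})}


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write artifacts plus a manifest.

    Returns the run directory. Any stage failure raises with the stage
    name prepended.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrap

    # simulate
    bundle = stage("simulate")(
        lambda: generate_fixture(config.synthetic, out / "fixture", seed=config.seed)
    )
    manifest["stages"]["simulate"] = {"root": str(bundle.root)}

    # curate
    def _curate():
        catalogs = {
            name: pd.read_csv(path, sep="\t") for name, path in bundle.catalogs.items()
        }
        sequences = read_fasta(bundle.fasta)
        table, counts = curation.build_dataset(
            catalogs, sequences, curation.CurationConfig(af_threshold=config.af_threshold)
        )
        table.to_csv(out / "curated.tsv", sep="\t", index=False)
        (out / "counts.json").write_text(json.dumps(counts, indent=2))
        return table, counts, sequences

    curated, counts, sequences = stage("curate")(_curate)
    manifest["stages"]["curate"] = {"totals": counts["totals"]}

    # featurize
    def _featurize():
        table = featurize_dataset(
            curated, sequences,
            msa_dir=bundle.msa_dir,
            structure_dir=bundle.structure_dir,
            external=pd.read_csv(bundle.external, sep="\t"),
            include_signatures=config.include_signatures,
        )
        table.to_csv(out / "features.tsv", sep="\t", index=False)
        return table

    features = stage("featurize")(_featurize)
    manifest["stages"]["featurize"] = {"rows": len(features),
                                       "columns": len(features.columns)}

    # screen
    def _screen():
        report = screen.screen_features(
            _numeric_features(features), features["label"], alpha=config.alpha
        )
        report.to_frame().to_csv(out / "screen.tsv", sep="\t", index=False)
        (out / "screen.json").write_text(json.dumps(
            {"alpha": report.alpha, "significant": report.significant}, indent=2))
        return report

    stage("screen")(_screen)

    # embed
    def _embed():
        coords = models.embed_2d(
            _numeric_features(features).to_numpy(dtype=float),
            method=config.embed_method, seed=config.seed,
        )
        emb = pd.DataFrame(coords, columns=["dim1", "dim2"])
        emb["label"] = features["label"].to_numpy()
        emb.to_csv(out / "embedding.tsv", sep="\t", index=False)

    stage("embed")(_embed)

    # train
    def _train():
        reports = []
        for task in TASKS:
            for scheme_kind in config.schemes:
                reports.append(
                    train_task(
                        features, task, scheme_kind, seed=config.seed,
                        repetitions=config.cv_repetitions,
                        n_estimators=config.n_estimators,
                    )
                )
        (out / "validation.json").write_text(json.dumps(reports, indent=2))
        return reports

    reports = stage("train")(_train)
    manifest["stages"]["train"] = {
        f"{r['task']}_{r['scheme']}_MCC": r["metrics"]["MCC"] for r in reports
    }

    # report
    lines = ["# Run summary", "", f"seed: {config.seed}", "",
             "## Curated totals", ""]
    for label, n in counts["totals"].items():
        lines.append(f"- {label}: {n}")
    lines += ["", "## Validation (MCC)", ""]
    for r in reports:
        lines.append(f"- {r['task']} / {r['scheme']}: {r['metrics']['MCC']:.3f}")
    (out / "report.md").write_text("\n".join(lines) + "\n")

    for artifact in ("curated.tsv", "features.tsv", "screen.tsv", "embedding.tsv",
                     "validation.json", "counts.json"):
        path = out / artifact
        df_rows = None
        if artifact.endswith(".tsv"):
            df_rows = sum(1 for _ in open(path)) - 1
        manifest["files"][artifact] = {"sha256": _checksum(path), "rows": df_rows}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
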