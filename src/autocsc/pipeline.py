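"""End-to-end orchestration: simulate -> sites -> quant -> compare.

A single config (YAML-serializable dataclass) drives every stage; all
randomness flows from its one seed, stages deriving sub-seeds
deterministically, so a rerun with identical config and inputs reproduces
byte-identical primary outputs.  A run manifest records the config hash,
package version and per-stage row counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

import autocsc
from autocsc import io as aio
from autocsc import populations, quant, simulate, sites

logger = logging.getLogger("autocsc")


@dataclass
class PipelineConfig:
    """All knobs of an end-to-end run.

    Thresholds mirror the analysis contract: identification q-value <= 0.01,
    differential significance at |fold-change| > 1.5 and BH-adjusted
    p < 0.05, and >= 4 populations for cross-modality correlation.
    """

    seed: int = 0
    # synthetic-data conditions
    n_proteins: int = 200
    length_range: tuple[int, int] = (300, 600)
    sequon_density: float = 0.005
    conditions: tuple[str, ...] = ("A", "B")
    n_bioreps: int = 4
    n_techreps: int = 2
    noise_sigma: float = simulate.DEFAULT_NOISE_SIGMA
    decoy_fraction: float = 0.05
    missing_rate: float = 0.05
    semi_tryptic_fraction: float = 0.1
    log2fc: float = 2.0
    frac_changed: float = 0.1
    # thresholds / flags
    q_threshold: float = 0.01
    fc_threshold: float = 1.5
    alpha: float = 0.05
    min_populations: int = 4
    exclude_proline_x: bool = False
    proteotypic_only: bool = True
    cv_scale: str = "linear"
    contaminant_prefixes: tuple[str, ...] = sites.DEFAULT_CONTAMINANT_PREFIXES

    def __post_init__(self) -> None:
        if not 0.0 <= self.q_threshold <= 1.0:
            raise ValueError("q_threshold must be in [0, 1]")
        if self.fc_threshold <= 0 or not 0.0 < self.alpha < 1.0:
            raise ValueError("invalid differential thresholds")
        if self.min_populations < 2:
            raise ValueError("min_populations must be >= 2")
        if self.cv_scale not in ("linear", "log2"):
            raise ValueError("cv_scale must be linear or log2")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("length_range", "conditions", "contaminant_prefixes"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _count_rows(path: Path) -> int:
    with open(path) as fh:
        return max(sum(1 for _ in fh) - 1, 0)  # minus header


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run simulate -> sites -> quant -> populations, writing all outputs
    under `outdir` and returning the manifest (also written as JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": autocsc.__version__,
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": {},
    }
    config.to_yaml(outdir / "config.yaml")

    # --- simulate ---------------------------------------------------------
    truth = simulate.make_truth(
        n_proteins=config.n_proteins,
        length_range=config.length_range,
        sequon_density=config.sequon_density,
        conditions=config.conditions,
        noise_sigma=config.noise_sigma,
        decoy_fraction=config.decoy_fraction,
        log2fc=config.log2fc,
        frac_changed=config.frac_changed,
        seed=config.seed,
    )
    bundle = simulate.generate_report(
        truth,
        n_bioreps=config.n_bioreps,
        n_techreps=config.n_techreps,
        missing_rate=config.missing_rate,
        semi_tryptic_fraction=config.semi_tryptic_fraction,
    )
    annotation_truth = simulate.generate_annotation(truth)
    fasta_path = outdir / "proteome.fasta"
    report_path = outdir / "report.tsv"
    design_path = outdir / "design.tsv"
    annotation_path = outdir / "annotation.tsv"
    aio.write_fasta(truth.proteome, fasta_path)
    dialect = aio.write_peptide_report(
        bundle.observations, report_path, bundle.design.run_ids
    )
    aio.write_design(bundle.design, design_path)
    aio.write_annotation(annotation_truth.records, annotation_path)
    truth.to_json(outdir / "truth.json")
    manifest["stages"]["simulate"] = {
        "n_proteins": len(truth.proteome),
        "n_true_sites": len(truth.true_sites),
        "report_rows": _count_rows(report_path),
        "design_rows": _count_rows(design_path),
        "annotation_rows": _count_rows(annotation_path),
    }

    # --- sites ------------------------------------------------------------
    if not fasta_path.exists():
        raise FileNotFoundError(f"sites stage: missing FASTA {fasta_path}")
    proteome = sites.Proteome(aio.read_fasta(fasta_path))
    observations = aio.read_peptide_report(report_path, dialect)
    design = aio.read_design(design_path)
    filtered = sites.filter_glycopeptides(
        observations,
        proteome,
        q_threshold=config.q_threshold,
        contaminant_prefixes=config.contaminant_prefixes,
        exclude_proline_x=config.exclude_proline_x,
    )
    assignments, unmappable = sites.assign_sites(
        filtered.retained, proteome, exclude_proline_x=config.exclude_proline_x
    )
    site_census = sites.census(assignments, proteotypic_only=config.proteotypic_only)
    observed = sites.unique_sites(assignments, proteotypic_only=config.proteotypic_only)
    annotation = aio.read_annotation(annotation_path)
    comparison = sites.compare_to_annotation(observed, annotation)

    sites_path = outdir / "sites.tsv"
    support: dict[sites.GlycoSite, int] = {}
    for a in assignments:
        for s in a.sites:
            support[s] = support.get(s, 0) + 1
    with open(sites_path, "w") as fh:
        fh.write("accession\tposition\tmotif_class\tn_supporting_peptides\n")
        for s in observed:
            fh.write(f"{s.accession}\t{s.position}\t{s.motif_class}\t{support.get(s, 0)}\n")
    (outdir / "census.json").write_text(json.dumps(site_census.to_dict(), indent=1))
    (outdir / "annotation_comparison.json").write_text(json.dumps(comparison, indent=1))
    manifest["stages"]["sites"] = {
        "n_observations": len(observations),
        "n_retained": len(filtered.retained),
        "n_removed": len(filtered.removed),
        "n_unmappable": len(filtered.unmappable) + len(unmappable),
        "sites_rows": _count_rows(sites_path),
        "census": {
            "n_sites": site_census.n_sites,
            "n_protein_groups": site_census.n_protein_groups,
            "median_sites_per_group": site_census.median_sites_per_group,
        },
        "annotation_comparison": comparison,
    }

    # --- quant ------------------------------------------------------------
    feature_matrix, _ = quant.matrix_from_observations(filtered.retained, design)
    feature_to_protein = {}
    by_obs = {
        f"{a.peptide.peptide_sequence}@{','.join(map(str, a.peptide.deamidated_positions('N')))}": a.assigned_accession
        for a in assignments
    }
    for fid in feature_matrix.values.index:
        if fid in by_obs:
            feature_to_protein[fid] = by_obs[fid]
    log2m = feature_matrix.to_log2()
    consolidated = quant.consolidate_technical_replicates(log2m)
    normalized = quant.normalize_median(consolidated)
    protein_matrix = quant.rollup_protein(normalized, feature_to_protein)
    aio.write_matrix(protein_matrix.values, outdir / "protein_matrix.tsv", "protein")

    cv_group = design.runs_for_condition(config.conditions[0])
    cv_input = feature_matrix if config.cv_scale == "linear" else feature_matrix.to_log2()
    cv_summary = quant.compute_cv(cv_input, cv_group)

    results = quant.differential_test(
        protein_matrix,
        config.conditions[0],
        config.conditions[1],
        fc_threshold=config.fc_threshold,
        alpha=config.alpha,
    )
    diff_path = outdir / "differential.tsv"
    with open(diff_path, "w") as fh:
        fh.write("protein\tlog2_fold_change\tp_value\tadjusted_p\tsignificant\ttested\n")
        for r in results:
            fh.write(
                f"{r.protein}\t{r.log2_fold_change:.6g}\t"
                f"{'NA' if r.p_value is None else format(r.p_value, '.6g')}\t"
                f"{'NA' if r.adjusted_p is None else format(r.adjusted_p, '.6g')}\t"
                f"{int(r.significant)}\t{int(r.tested)}\n"
            )
    manifest["stages"]["quant"] = {
        "n_features": int(feature_matrix.values.shape[0]),
        "n_proteins_quantified": int(protein_matrix.values.shape[0]),
        "median_cv": cv_summary.median_cv,
        "n_significant": sum(r.significant for r in results),
        "diff_rows": _count_rows(diff_path),
    }

    # --- populations ------------------------------------------------------
    presence = populations.presence_matrix(protein_matrix.values, protein_matrix.design)
    counts = populations.intersections(presence)
    inter_path = outdir / "intersections.tsv"
    with open(inter_path, "w") as fh:
        fh.write("populations\tn_proteins\n")
        for key in sorted(counts, key=lambda k: (len(k), sorted(k))):
            fh.write(f"{','.join(sorted(key))}\t{counts[key]}\n")
    zpath = outdir / "zscores.tsv"
    zrows = protein_matrix.values[protein_matrix.values.notna().sum(axis=1) >= 2]
    aio.write_matrix(populations.zscore_rows(zrows), zpath, "protein")
    manifest["stages"]["populations"] = {
        "n_present_proteins": int(presence.shape[0]),
        "intersections_rows": _count_rows(inter_path),
        "zscore_rows": _count_rows(zpath),
    }

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
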