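"""End-to-end pipeline: synthesis -> isochores -> expression -> enrichment
-> compartment bias -> phenotypes.

A single YAML (or dict) config drives a run; all randomness flows from one
root seed split per stage. Outputs land in a flat directory with stable
names and a JSON manifest recording the package version, the seed and a
SHA-256 per output file, so a rerun with the same config is verifiable by
hash comparison.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from hecpipe import io as hio
from hecpipe.compartment import compartment_bmcw, dichotomy_summary
from hecpipe.enrichment import gsea
from hecpipe.expression import contrast_gene_bias, enumerate_contrasts
from hecpipe.isochores import assign_genes, segment_genome
from hecpipe.mcw import MCWConfig
from hecpipe.phenotypes import clean_plasma, trait_mcw
from hecpipe.synthetic import (
    SyntheticDesign,
    generate_annotation,
    generate_counts,
    generate_gene_sets,
    generate_genome,
    generate_phenotypes,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run."""

    out_dir: Path
    seed: int = 0
    design: SyntheticDesign | None = None
    max_rearrangements: int = 10_000
    n_perm: int = 1000
    alpha: float = 0.05
    gsea_min_size: int = 15
    gsea_max_size: int = 500
    isochore_min_genes: int = 5
    run_phenotypes: bool = True
    extra: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        design_kwargs = raw.pop("design", {}) or {}
        seed = int(raw.pop("seed", 0))
        design = SyntheticDesign(
            seed=int(design_kwargs.pop("seed", seed)),
            **{
                k: (tuple(v) if isinstance(v, list) else v)
                for k, v in design_kwargs.items()
            },
        )
        out_dir = Path(raw.pop("out_dir", "hecpipe_run"))
        known = {f for f in cls.__dataclass_fields__ if f not in ("out_dir", "design", "extra")}
        kwargs = {k: raw.pop(k) for k in list(raw) if k in known}
        return cls(out_dir=out_dir, design=design, seed=seed, extra=raw, **kwargs)

    @property
    def mcw(self) -> MCWConfig:
        return MCWConfig(max_rearrangements=self.max_rearrangements, seed=self.seed)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    from hecpipe import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.design or SyntheticDesign(seed=config.seed)
    mcw_config = config.mcw

    logger.info("stage synth: generating genome, annotation, counts, phenotypes")
    try:
        sequences, blocks = generate_genome(design)
        annotation = generate_annotation(design, blocks)
        counts, meta, truth = generate_counts(design, annotation)
        gene_sets, set_truth = generate_gene_sets(design, annotation)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage synth failed: {exc}") from exc
    hio.write_fasta(sequences, out / "genome.fa")
    hio.write_gtf(annotation, out / "genes.gtf")
    hio.write_bed_genes(annotation, out / "genes.bed")
    hio.write_counts(counts, out / "counts.tsv")
    meta.to_csv(out / "samples.tsv", sep="\t", index=False)
    truth.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    set_truth.to_csv(out / "truth_sets.tsv", sep="\t", index=False)
    hio.write_gmt(gene_sets, out / "gene_sets.gmt")

    logger.info("stage isochores: segmentation and gene assignment")
    try:
        isochores = segment_genome(sequences)
        assignments = assign_genes(annotation, isochores)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage isochores failed: {exc}") from exc
    hio.write_isochore_bed(isochores, out / "isochores.bed")
    assignments.to_csv(out / "gene_assignments.tsv", sep="\t", index=False)

    gene_chroms = annotation.set_index("gene_id")["chrom"]
    design_dict = {
        "sexes": design.sexes,
        "tissues": design.tissues,
        "exposure_groups": tuple(
            g for g in design.groups if g != design.control_group
        ),
        "control_group": design.control_group,
    }
    contrasts = enumerate_contrasts(design_dict)

    logger.info("stage expression: per-gene uMCW over %d contrasts", len(contrasts))
    bias_tables = []
    enrich_tables = []
    reports = {}
    for contrast in contrasts:
        try:
            bias = contrast_gene_bias(counts, meta, contrast, gene_chroms, mcw_config)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage expression failed at {contrast.name}: {exc}") from exc
        bias_tables.append(bias.reset_index(names="gene_id"))

        stats = bias["bias_index"]
        stats.index.name = "gene"
        try:
            enr = gsea(
                stats, gene_sets, n_perm=config.n_perm, seed=config.seed,
                min_size=config.gsea_min_size, max_size=config.gsea_max_size,
            )
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage enrichment failed at {contrast.name}: {exc}") from exc
        enr.insert(0, "contrast", contrast.name)
        enrich_tables.append(enr)

        try:
            reports[contrast.name] = compartment_bmcw(
                bias["bias_index"], assignments, gene_chroms, mcw_config,
                contrast=contrast.name,
                isochore_min_genes=config.isochore_min_genes,
                alpha=config.alpha,
            )
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage compartment failed at {contrast.name}: {exc}") from exc

    pd.concat(bias_tables).to_csv(out / "gene_bias.tsv", sep="\t", index=False)
    pd.concat(enrich_tables).to_csv(out / "enrichment.tsv", sep="\t", index=False)
    pd.concat([r.to_frame() for r in reports.values()]).to_csv(
        out / "compartment_bias.tsv", sep="\t", index=False
    )
    hio.write_json(dichotomy_summary(reports), out / "dichotomy.json")

    if config.run_phenotypes:
        logger.info("stage phenotypes")
        try:
            traits, panel, in_range = generate_phenotypes(design)
            panel_clean = clean_plasma(panel, in_range)
            pheno_rows = []
            exposure_groups = [g for g in design.groups if g != design.control_group]
            for trait in sorted(traits["trait"].unique()):
                for group in exposure_groups:
                    res = trait_mcw(traits, trait, group, design.control_group, mcw_config)
                    pheno_rows.append(
                        {"trait": trait, "group": group, **res.summary_row()}
                    )
            pheno = pd.DataFrame(pheno_rows)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage phenotypes failed: {exc}") from exc
        traits.to_csv(out / "traits.csv", index=False)
        panel_clean.to_csv(out / "plasma_panel.csv")
        pheno.to_csv(out / "phenotype_mcw.tsv", sep="\t", index=False)

    outputs = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "design_seed": design.seed,
        "n_contrasts": len(contrasts),
        "files": {p.name: _sha256(p) for p in outputs},
    }
    hio.write_json(manifest, out / "manifest.json")
    return manifest
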