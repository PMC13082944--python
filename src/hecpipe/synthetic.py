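"""Synthetic inputs with planted ground truth.

Everything the pipeline consumes can be generated here: a genome whose
100-kb windows hit prescribed GC targets (so segmentation realises all five
isochore classes), a gene annotation placed on that genome, RNA-seq-like
count tables with class-dependent planted fold changes, gene-set
collections with class-skewed members, and phenotype tables with planted
group effects. Every artifact records its ground truth, so recovery can be
scored exactly.

The default design mirrors the study layout this package analyses: 2 sexes
x 2 tissues x 5 experimental groups (a DMSO control and four exposures) x
5 replicates per cell = 100 RNA samples. Counts are negative-binomial
around gene baselines; exposure-group means are shifted by
``2**log2fc(class)`` for genes of each isochore class, which plants the
AT-rich versus GC-rich expression dichotomy when the two sides are given
opposite-signed shifts. Dispersion defaults to 0.1, a typical bulk RNA-seq
value. The genome defaults to 3 chromosomes x 5 Mb so a full run stays at
desk scale.

All randomness flows from the design seed through named substreams, so
every artifact is byte-identical across runs with the same design.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from hecpipe.isochores import WINDOW_SIZE, classify_window

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: one block per isochore class, window-aligned, cycled to fill a chromosome
DEFAULT_GC_BLOCKS: tuple[tuple[int, float], ...] = (
    (500_000, 0.30),
    (500_000, 0.39),
    (500_000, 0.43),
    (500_000, 0.50),
    (500_000, 0.60),
)


@dataclass(frozen=True)
class SyntheticDesign:
    """Generative blueprint for one synthetic study."""

    seed: int = 0
    n_chromosomes: int = 3
    chromosome_length: int = 5_000_000
    gc_block_profile: tuple[tuple[int, float], ...] = DEFAULT_GC_BLOCKS
    gap_length: int = 100_000
    n_genes: int = 300
    gene_length_range: tuple[int, int] = (2_000, 10_000)
    sexes: tuple[str, ...] = ("female", "male")
    tissues: tuple[str, ...] = ("gWAT", "liver")
    groups: tuple[str, ...] = ("DMSO", "5TBT", "50TBT", "IAS", "TWD")
    control_group: str = "DMSO"
    replicates_per_cell: int = 5
    planted_class_log2fc: Mapping[str, float] = field(default_factory=dict)
    nb_dispersion: float = 0.1
    baseline_mean: float = 100.0
    n_mice_per_cell: int = 10
    phenotype_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    plasma_out_of_range_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.replicates_per_cell < 2:
            raise ValueError("replicates_per_cell must be >= 2")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        for _, gc in self.gc_block_profile:
            if not 0.0 <= gc <= 1.0:
                raise ValueError(f"GC target {gc} outside [0, 1]")
        if self.control_group not in self.groups:
            raise ValueError("control_group must be one of groups")

    def rng(self, stream: str) -> np.random.Generator:
        # crc32 is stable across processes (unlike hash()), keeping artifacts
        # byte-identical for a fixed design
        return np.random.default_rng(
            [zlib.crc32(stream.encode()) & 0x7FFFFFFF, self.seed]
        )


def _chromosome_blocks(design: SyntheticDesign, chrom: str) -> list[dict]:
    """Deterministic block layout: profile cycles with one gap per chromosome.

    The gap (an all-N run) is inserted after the first profile cycle;
    blocks are window-aligned so each 100-kb window sits inside one block.
    """
    blocks: list[dict] = []
    pos = 0
    cycle = 0
    while pos < design.chromosome_length:
        for length, gc in design.gc_block_profile:
            if pos >= design.chromosome_length:
                break
            length = min(length, design.chromosome_length - pos)
            blocks.append(
                {"chrom": chrom, "start": pos, "end": pos + length,
                 "gc_target": gc, "is_gap": False,
                 "class": classify_window(gc)}
            )
            pos += length
        if cycle == 0 and pos < design.chromosome_length:
            length = min(design.gap_length, design.chromosome_length - pos)
            blocks.append(
                {"chrom": chrom, "start": pos, "end": pos + length,
                 "gc_target": float("nan"), "is_gap": True, "class": None}
            )
            pos += length
        cycle += 1
    return blocks


def generate_genome(design: SyntheticDesign) -> tuple[dict[str, str], pd.DataFrame]:
    """Random genome hitting the design's per-block GC targets.

    Returns (chromosome name -> sequence, block truth table). Each 100-kb
    window of a non-gap block has expected GC equal to the block target;
    at 1e5 bases the binomial fluctuation is ~0.2% GC, well within the
    1%-GC tolerance the design promises.
    """
    rng = design.rng("genome")
    sequences: dict[str, str] = {}
    truth_rows: list[dict] = []
    for c in range(design.n_chromosomes):
        chrom = f"chr{c + 1}"
        parts: list[bytes] = []
        for block in _chromosome_blocks(design, chrom):
            length = block["end"] - block["start"]
            if block["is_gap"]:
                parts.append(b"N" * length)
            else:
                gc = block["gc_target"]
                p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
                idx = rng.choice(4, size=length, p=p)
                parts.append(_BASES[idx].tobytes())
            truth_rows.append(block)
        sequences[chrom] = b"".join(parts).decode("ascii")
    return sequences, pd.DataFrame(truth_rows)


def generate_annotation(
    design: SyntheticDesign, blocks: pd.DataFrame
) -> pd.DataFrame:
    """Place non-overlapping gene spans uniformly over non-gap blocks.

    Genes sit fully inside one block, so each gene's true isochore class is
    the block class. Returns a frame with ``gene_id``, ``chrom``, ``start``,
    ``end``, ``strand`` and ``true_class`` (0-based half-open coordinates).
    """
    rng = design.rng("annotation")
    usable = blocks[~blocks["is_gap"]].reset_index(drop=True)
    lengths = (usable["end"] - usable["start"]).to_numpy()
    weights = lengths / lengths.sum()
    lo, hi = design.gene_length_range

    placed: dict[str, list[tuple[int, int]]] = {}
    rows: list[dict] = []
    attempts = 0
    while len(rows) < design.n_genes:
        attempts += 1
        if attempts > design.n_genes * 200:
            raise RuntimeError("could not place genes without overlap; lower n_genes")
        bi = rng.choice(len(usable), p=weights)
        block = usable.iloc[bi]
        glen = int(rng.integers(lo, hi + 1))
        if block["end"] - block["start"] <= glen:
            continue
        start = int(rng.integers(block["start"], block["end"] - glen))
        end = start + glen
        spans = placed.setdefault(block["chrom"], [])
        if any(s < end and start < e for s, e in spans):
            continue
        spans.append((start, end))
        rows.append(
            {"gene_id": f"g{len(rows) + 1:05d}", "chrom": block["chrom"],
             "start": start, "end": end,
             "strand": "+" if rng.random() < 0.5 else "-",
             "true_class": block["class"]}
        )
    genes = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    genes["gene_id"] = [f"g{i + 1:05d}" for i in range(len(genes))]
    return genes


def sample_metadata(design: SyntheticDesign) -> pd.DataFrame:
    """Sample sheet for the full design grid (sex x tissue x group x replicate)."""
    rows = [
        {"sample_id": f"{sex}_{tissue}_{group}_r{rep}",
         "sex": sex, "tissue": tissue, "group": group, "replicate": rep}
        for sex in design.sexes
        for tissue in design.tissues
        for group in design.groups
        for rep in range(1, design.replicates_per_cell + 1)
    ]
    return pd.DataFrame(rows)


def generate_counts(
    design: SyntheticDesign, annotation: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix with planted class-dependent shifts.

    Control samples draw from each gene's baseline mean; exposure samples
    from ``baseline * 2**log2fc(true_class)`` (zero shift for classes not in
    ``planted_class_log2fc``). Gene baselines are log-normal around
    ``baseline_mean`` to span a realistic dynamic range.

    Returns (counts genes x samples, sample metadata, truth table with each
    gene's class and planted shift).
    """
    rng = design.rng("counts")
    meta = sample_metadata(design)
    n_genes = len(annotation)
    baselines = design.baseline_mean * rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    lfc = annotation["true_class"].map(
        lambda c: float(design.planted_class_log2fc.get(c, 0.0))
    ).to_numpy()

    size = 1.0 / design.nb_dispersion
    cols = {}
    for row in meta.itertuples(index=False):
        mean = baselines * (
            2.0**lfc if row.group != design.control_group else 1.0
        )
        p = size / (size + mean)
        cols[row.sample_id] = rng.negative_binomial(size, p)
    counts = pd.DataFrame(cols, index=annotation["gene_id"].to_numpy())
    counts.index.name = "gene_id"
    truth = annotation[["gene_id", "chrom", "true_class"]].copy()
    truth["planted_log2fc"] = lfc
    truth["baseline_mean"] = baselines
    return counts, meta, truth


def generate_gene_sets(
    design: SyntheticDesign,
    annotation: pd.DataFrame,
    n_sets: int = 30,
    size_range: tuple[int, int] = (10, 600),
    skewed_classes: Sequence[str] = ("L1", "H3"),
    skew_weight: float = 0.9,
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Gene sets with configurable sizes, some skewed toward one class.

    A skewed set draws a fraction ``skew_weight`` of its members from genes
    of one isochore class and the rest uniformly. Returns (name -> members,
    truth table with each set's skew class or None).
    """
    rng = design.rng("gene_sets")
    genes = annotation["gene_id"].to_numpy()
    by_class = {
        cls: annotation.loc[annotation["true_class"] == cls, "gene_id"].to_numpy()
        for cls in annotation["true_class"].dropna().unique()
    }
    lo, hi = size_range
    sets: dict[str, list[str]] = {}
    truth_rows = []
    for i in range(n_sets):
        name = f"SET{i + 1:04d}"
        size = int(np.exp(rng.uniform(np.log(lo), np.log(min(hi, len(genes))))))
        skew = skewed_classes[i % len(skewed_classes)] if i < 2 * len(skewed_classes) else None
        if skew is not None and skew in by_class:
            pool = by_class[skew]
            n_skew = min(int(round(size * skew_weight)), len(pool))
            members = set(rng.choice(pool, size=n_skew, replace=False))
            rest = np.setdiff1d(genes, list(members))
            extra = rng.choice(rest, size=min(size - n_skew, len(rest)), replace=False)
            members |= set(extra)
        else:
            members = set(rng.choice(genes, size=min(size, len(genes)), replace=False))
        sets[name] = sorted(members)
        truth_rows.append({"set": name, "skew_class": skew, "size": len(members)})
    return sets, pd.DataFrame(truth_rows)


def generate_phenotypes(
    design: SyntheticDesign,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gaussian trait table and plasma panel with planted group effects.

    Traits are drawn per mouse as ``base + effect_sd * sd + noise`` where
    ``effect_sd`` comes from ``phenotype_effects[trait][group]`` (standardised
    effect sizes, 0 when unspecified). The plasma panel is log-normal with a
    configurable fraction of entries flagged outside the standard curve
    range (exercising the zeroing rule downstream).

    Returns (trait table, plasma panel, in-range mask).
    """
    rng = design.rng("phenotypes")
    base_traits = {
        "body_weight": (22.0, 2.0),  # g
        "fasting_glucose": (140.0, 20.0),  # mg/dL
        "gWAT_weight": (0.35, 0.08),  # g
        "liver_weight": (1.1, 0.15),  # g
    }
    rows = []
    mouse_ids = []
    for sex in design.sexes:
        for group in design.groups:
            for m in range(1, design.n_mice_per_cell + 1):
                mouse = f"{sex}_{group}_m{m:02d}"
                mouse_ids.append((mouse, sex, group))
                age = float(rng.integers(80, 90))
                for trait, (mu, sd) in base_traits.items():
                    effect = float(
                        design.phenotype_effects.get(trait, {}).get(group, 0.0)
                    )
                    value = mu + effect * sd + rng.normal(0.0, sd)
                    rows.append(
                        {"mouse_id": mouse, "sex": sex, "group": group,
                         "age_days": age, "timepoint": "terminal",
                         "trait": trait, "value": max(value, 0.01)}
                    )
    traits = pd.DataFrame(rows)

    metabolites = [
        "amylin", "GIP", "ghrelin", "GLP-1", "insulin", "leptin",
        "PYY", "glucagon", "PP", "resistin", "C-peptide",
    ]
    index = [m for m, _, _ in mouse_ids]
    panel = pd.DataFrame(
        rng.lognormal(mean=6.0, sigma=0.5, size=(len(index), len(metabolites))),
        index=index, columns=metabolites,
    )
    for met in metabolites:
        effects = design.phenotype_effects.get(f"plasma_{met}", {})
        if effects:
            sd = panel[met].std()
            for i, (_, _, group) in enumerate(mouse_ids):
                panel.iloc[i, panel.columns.get_loc(met)] += effects.get(group, 0.0) * sd
    in_range = pd.DataFrame(
        rng.random(panel.shape) >= design.plasma_out_of_range_fraction,
        index=panel.index, columns=panel.columns,
    )
    panel.index.name = "mouse_id"
    in_range.index.name = "mouse_id"
    return traits, panel, in_range


def generate_litters(design: SyntheticDesign, n_litters_per_group: int = 8) -> pd.DataFrame:
    """Litter table (group, n_pups, n_females) with optional planted size shift."""
    rng = design.rng("litters")
    rows = []
    for group in design.groups:
        shift = float(design.phenotype_effects.get("litter_size", {}).get(group, 0.0))
        for i in range(n_litters_per_group):
            n_pups = max(1, int(rng.poisson(7.0 + shift)))
            n_females = int(rng.binomial(n_pups, 0.5))
            rows.append(
                {"litter_id": f"{group}_L{i + 1}", "group": group,
                 "n_pups": n_pups, "n_females": n_females}
            )
    return pd.DataFrame(rows)
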