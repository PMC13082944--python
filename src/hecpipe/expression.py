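"""Count-table filtering, normalisation and per-gene uMCW contrast statistics.

The working object is a pair of pandas frames: a genes x samples count
matrix (index = gene ids, columns = sample ids) and a sample-metadata frame
with columns ``sample_id``, ``sex``, ``tissue``, ``group``, ``replicate``.
Analyses run per *contrast* — one (sex, tissue, exposure-group) cell
compared against the control group in the same sex and tissue.

Processing order per contrast: restrict to the contrast's samples, drop
non-expressed genes (fewer than 2 samples with at least 2 reads), drop
mitochondrial / Y / unassembled-scaffold genes, normalise the surviving
table to counts per million (cpm), and run one unmatched-measures MCW test
per gene on exposure-vs-control cpm values. The per-gene bias indexes feed
pre-ranked enrichment and the compartment-bias tests downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from hecpipe.mcw import MCWConfig, umcw_test_many

CONTROL_GROUP = "DMSO"

#: default study design: 2 sexes x 2 tissues x 4 exposure groups vs control
DEFAULT_DESIGN = {
    "sexes": ("female", "male"),
    "tissues": ("gWAT", "liver"),
    "exposure_groups": ("5TBT", "50TBT", "IAS", "TWD"),
    "control_group": CONTROL_GROUP,
}

_MAIN_CHROM_RE = re.compile(r"^(chr)?(\d+|X)$")


@dataclass(frozen=True)
class ContrastSpec:
    """One exposure-vs-control comparison cell."""

    sex: str
    tissue: str
    exposure_group: str
    control_group: str = CONTROL_GROUP

    def __post_init__(self) -> None:
        if self.exposure_group == self.control_group:
            raise ValueError("exposure group must differ from control group")

    @property
    def name(self) -> str:
        return f"{self.sex}_{self.tissue}_{self.exposure_group}_vs_{self.control_group}"


def enumerate_contrasts(design: dict | None = None) -> list[ContrastSpec]:
    """All (sex, tissue, exposure group) contrast cells, in deterministic order.

    The default design yields the 16 contrasts of a 2 sexes x 2 tissues x
    4 exposure groups layout, each against the shared control group.
    """
    design = {**DEFAULT_DESIGN, **(design or {})}
    control = design.get("control_group")
    if not control:
        raise ValueError("design must name a control group")
    return [
        ContrastSpec(sex, tissue, group, control)
        for sex in design["sexes"]
        for tissue in design["tissues"]
        for group in design["exposure_groups"]
    ]


def contrast_samples(
    meta: pd.DataFrame, contrast: ContrastSpec
) -> tuple[list[str], list[str]]:
    """Sample ids of the exposure and control cells of a contrast."""
    cell = meta[(meta["sex"] == contrast.sex) & (meta["tissue"] == contrast.tissue)]
    exposure = cell.loc[cell["group"] == contrast.exposure_group, "sample_id"].tolist()
    control = cell.loc[cell["group"] == contrast.control_group, "sample_id"].tolist()
    if not exposure or not control:
        raise ValueError(f"contrast {contrast.name} has an empty sample cell")
    return exposure, control


def filter_expressed(
    counts: pd.DataFrame,
    samples: Sequence[str] | None = None,
    min_reads: int = 2,
    min_samples: int = 2,
) -> pd.Index:
    """Gene ids considered expressed within a contrast.

    A gene is expressed if at least ``min_reads`` raw reads map to it in at
    least ``min_samples`` of the contrast's samples (exposure plus control).
    """
    table = counts if samples is None else counts[list(samples)]
    if table.shape[1] == 0:
        raise ValueError("no samples to evaluate expression filter on")
    keep = (table >= min_reads).sum(axis=1) >= min_samples
    return table.index[keep]


def chromosome_filter(gene_chroms: pd.Series) -> pd.Index:
    """Keep genes on autosomes and the X chromosome.

    Mitochondrial, Y-chromosome and unassembled-scaffold genes are dropped;
    unrecognised labels are treated as unassembled.
    """
    keep = gene_chroms.astype(str).str.match(_MAIN_CHROM_RE)
    return gene_chroms.index[keep]


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: per-sample counts scaled to a 1e6 total."""
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"samples with zero total counts: {list(zero.index)[:5]}")
    return counts.div(totals, axis=1) * 1e6


def top_expressed(counts: pd.DataFrame, n: int) -> pd.Index:
    """The ``n`` genes with the largest cumulative raw counts.

    Ties at the cutoff are broken by gene id (lexicographic, stable).
    """
    totals = counts.sum(axis=1)
    ranked = sorted(zip(-totals.values, totals.index))
    n = min(n, len(ranked))
    return pd.Index([gid for _, gid in ranked[:n]], name=counts.index.name)


def rescale01(values: pd.DataFrame) -> pd.DataFrame:
    """Per-gene 0-1 rescaling (x - min) / (max - min) across samples.

    Constant genes map to all zeros (the max-min denominator would be 0);
    this only affects visualisation matrices.
    """
    if values.shape[1] < 2:
        raise ValueError("rescale01 needs at least 2 samples")
    mins = values.min(axis=1)
    span = values.max(axis=1) - mins
    out = values.sub(mins, axis=0).div(span.replace(0, np.inf), axis=0)
    return out


def per_gene_umcw(
    cpm: pd.DataFrame,
    exposure_samples: Sequence[str],
    control_samples: Sequence[str],
    config: MCWConfig | None = None,
) -> pd.DataFrame:
    """One uMCW test per gene: exposure cpm versus control cpm.

    Positive BI means higher expression in the exposure group. Returns a
    frame indexed by gene with columns ``bias_index``, ``p_upper``,
    ``p_lower`` and ``path``.
    """
    config = config or MCWConfig()
    a = cpm[list(exposure_samples)].to_numpy(dtype=float)
    b = cpm[list(control_samples)].to_numpy(dtype=float)
    bi, p_upper, p_lower, path = umcw_test_many(a, b, config)
    return pd.DataFrame(
        {"bias_index": bi, "p_upper": p_upper, "p_lower": p_lower, "path": path},
        index=cpm.index,
    )


def contrast_gene_bias(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    contrast: ContrastSpec,
    gene_chroms: pd.Series | None = None,
    config: MCWConfig | None = None,
) -> pd.DataFrame:
    """Full per-contrast pipeline: filter, normalise, per-gene uMCW.

    ``gene_chroms`` (gene id -> chromosome label) enables the
    main-chromosome filter; when omitted all genes are retained.
    """
    exposure, control = contrast_samples(meta, contrast)
    samples = exposure + control
    expressed = filter_expressed(counts, samples)
    if gene_chroms is not None:
        expressed = expressed.intersection(chromosome_filter(gene_chroms))
    working = counts.loc[expressed.sort_values(), samples]
    cpm = cpm_normalize(working)
    result = per_gene_umcw(cpm, exposure, control, config)
    result.insert(0, "contrast", contrast.name)
    return result
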