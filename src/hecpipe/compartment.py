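"""Compartment-bias analysis: concerted expression shifts by isochore class.

For one contrast, the per-gene uMCW bias indexes are treated as a set of
bias measures and fed to a biased-measures MCW test. The whole-transcriptome
index (wBI) asks whether expression changes are concerted overall; subset
indexes (sBIs) ask the same for genes grouped by isochore class, by
individual isochore and by chromosome.

The heterochromatin/euchromatin dichotomy is called when the AT-rich
classes (L1, L2) and the GC-rich classes (H2, H3) show opposite-signed
mean sBIs and each side carries at least one class significant at the
chosen alpha. H1, the intermediate class, is deliberately unconstrained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from hecpipe.isochores import AT_RICH_CLASSES, GC_RICH_CLASSES
from hecpipe.mcw import MCWConfig, MCWResult, bmcw_test

logger = logging.getLogger(__name__)

DICHOTOMY_ABSENT = "absent"
DICHOTOMY_GC_UP = "present_GC_up"
DICHOTOMY_AT_UP = "present_AT_up"


@dataclass
class CompartmentReport:
    """bMCW results for one contrast at every compartment resolution."""

    contrast: str
    whole: MCWResult
    by_class: dict[str, MCWResult] = field(default_factory=dict)
    by_isochore: dict[str, MCWResult] = field(default_factory=dict)
    by_chromosome: dict[str, MCWResult] = field(default_factory=dict)
    dichotomy: str = DICHOTOMY_ABSENT

    def to_frame(self) -> pd.DataFrame:
        """Long table (subset_kind, subset_id, BI, p_upper, p_lower)."""
        rows = [
            {"contrast": self.contrast, "subset_kind": "whole", "subset_id": "all",
             **self.whole.summary_row()}
        ]
        for kind, mapping in (
            ("class", self.by_class),
            ("isochore", self.by_isochore),
            ("chromosome", self.by_chromosome),
        ):
            for sid, res in mapping.items():
                rows.append(
                    {"contrast": self.contrast, "subset_kind": kind,
                     "subset_id": sid, **res.summary_row()}
                )
        return pd.DataFrame(rows)


def compartment_bmcw(
    gene_bias: pd.Series,
    assignments: pd.DataFrame,
    gene_chroms: pd.Series | None = None,
    config: MCWConfig | None = None,
    contrast: str = "",
    isochore_min_genes: int = 2,
    isochores_of_interest: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> CompartmentReport:
    """bMCW tests over the transcriptome, classes, isochores and chromosomes.

    Parameters
    ----------
    gene_bias
        Gene id -> uMCW bias index for one contrast. All genes enter the
        whole-set test; genes without an isochore assignment are excluded
        from class/isochore subsets only.
    assignments
        Gene assignment table from :func:`hecpipe.isochores.assign_genes`
        (columns ``gene_id``, ``assigned_isochore_id``, ``assigned_class``).
    gene_chroms
        Optional gene id -> chromosome label; enables per-chromosome subsets.
    isochore_min_genes, isochores_of_interest
        Per-isochore tests are run for isochores holding at least
        ``isochore_min_genes`` scored genes, or for the explicitly listed
        isochores (e.g. those housing a gene family of interest), to bound
        the number of tests.
    """
    config = config or MCWConfig()
    genes = gene_bias.index
    lookup = assignments.set_index("gene_id")
    assigned = lookup.reindex(genes)

    subsets: dict[str, np.ndarray] = {}
    kinds: dict[str, str] = {}

    cls = assigned["assigned_class"]
    for name in cls.dropna().unique():
        key = f"class:{name}"
        subsets[key] = np.flatnonzero((cls == name).to_numpy())
        kinds[key] = "class"

    iso = assigned["assigned_isochore_id"]
    iso_counts = iso.value_counts()
    wanted = set(isochores_of_interest or [])
    for iso_id, count in iso_counts.items():
        if count >= isochore_min_genes or iso_id in wanted:
            key = f"isochore:{iso_id}"
            subsets[key] = np.flatnonzero((iso == iso_id).to_numpy())
            kinds[key] = "isochore"

    if gene_chroms is not None:
        chroms = gene_chroms.reindex(genes)
        for chrom in sorted(chroms.dropna().unique()):
            key = f"chromosome:{chrom}"
            subsets[key] = np.flatnonzero((chroms == chrom).to_numpy())
            kinds[key] = "chromosome"

    empty = [k for k, v in subsets.items() if v.size == 0]
    for key in empty:
        logger.info("skipping empty subset %s", key)
        del subsets[key]

    result = bmcw_test(gene_bias.to_numpy(float), subsets=subsets, config=config)
    report = CompartmentReport(contrast=contrast, whole=result.whole_set)
    for key, res in result.per_subset.items():
        kind, _, sid = key.partition(":")
        getattr(report, f"by_{kind}")[sid] = res
    report.dichotomy = dichotomy_call(report, alpha=alpha)
    return report


def dichotomy_call(report: CompartmentReport, alpha: float = 0.05) -> str:
    """Label the heterochromatin/euchromatin dichotomy of one contrast.

    Present iff the mean sBI over the AT-rich classes {L1, L2} and the mean
    over the GC-rich classes {H2, H3} have opposite signs and each side has
    at least one class with min(p_upper, p_lower) < alpha. The label
    records which side is up-regulated.
    """
    def side(names: Sequence[str]) -> tuple[float, bool] | None:
        present = [report.by_class[n] for n in names if n in report.by_class]
        if len(present) < len(names):
            logger.warning("missing class sBIs for %s: dichotomy absent", names)
            return None
        mean_sbi = float(np.mean([r.bias_index for r in present]))
        significant = any(min(r.p_upper, r.p_lower) < alpha for r in present)
        return mean_sbi, significant

    at_side = side(AT_RICH_CLASSES)
    gc_side = side(GC_RICH_CLASSES)
    if at_side is None or gc_side is None:
        return DICHOTOMY_ABSENT
    (at_mean, at_sig), (gc_mean, gc_sig) = at_side, gc_side
    if at_mean * gc_mean >= 0 or not (at_sig and gc_sig):
        return DICHOTOMY_ABSENT
    return DICHOTOMY_GC_UP if gc_mean > 0 else DICHOTOMY_AT_UP


def dichotomy_summary(reports: Mapping[str, CompartmentReport]) -> dict:
    """JSON-ready dichotomy summary per contrast."""
    out = {}
    for name, rep in reports.items():
        out[name] = {
            "dichotomy": rep.dichotomy,
            "wBI": rep.whole.bias_index,
            "class_sBI": {c: r.bias_index for c, r in rep.by_class.items()},
            "class_p": {
                c: min(r.p_upper, r.p_lower) for c, r in rep.by_class.items()
            },
        }
    return out
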