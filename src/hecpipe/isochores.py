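"""Isochore segmentation and gene-to-isochore assignment.

Isochores are long chromosomal segments of fairly uniform base composition.
They are mapped here the classic way: the sequence is cut into
non-overlapping 100-kb windows, each window is assigned to one of five GC
classes — L1 (< 37% GC), L2 (37-41%), H1 (41-46%), H2 (46-53%), H3
(>= 53%) — and juxtaposed windows of the same class are concatenated into
isochores. AT-rich L1/L2 isochores proxy the heterochromatic compartment
and GC-rich H2/H3 the euchromatic one; H1 is intermediate.

Class intervals are lower-inclusive half-open ([0.37, 0.41) etc.), a
convention choice where the percent boundaries themselves are the only
fixed points. GC is computed over non-N bases; windows with more than half
N bases (assembly gaps) are left unclassified and break isochore runs.
Coordinates are 0-based half-open throughout; GTF input is converted from
1-based closed on read.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

WINDOW_SIZE = 100_000

#: class name -> (gc lower bound, gc upper bound), fractions, lower-inclusive
ISOCHORE_CLASSES: dict[str, tuple[float, float]] = {
    "L1": (0.0, 0.37),
    "L2": (0.37, 0.41),
    "H1": (0.41, 0.46),
    "H2": (0.46, 0.53),
    "H3": (0.53, 1.0),
}

_CLASS_EDGES = [0.37, 0.41, 0.46, 0.53]
_CLASS_NAMES = ["L1", "L2", "H1", "H2", "H3"]

AT_RICH_CLASSES = ("L1", "L2")
GC_RICH_CLASSES = ("H2", "H3")


@dataclass(frozen=True)
class Window:
    """One fixed-size segmentation window."""

    chrom: str
    start: int
    end: int
    gc: float
    n_fraction: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Isochore:
    """A maximal run of same-class windows."""

    chrom: str
    start: int
    end: int
    class_name: str
    mean_gc: float
    isochore_id: str

    @property
    def length(self) -> int:
        return self.end - self.start


def classify_window(gc: float) -> str:
    """Isochore class of a window from its GC fraction in [0, 1]."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc fraction {gc} outside [0, 1]")
    return _CLASS_NAMES[bisect_right(_CLASS_EDGES, gc)]


def segment_windows(
    sequence: str, chrom: str = "chr", window_size: int = WINDOW_SIZE
) -> list[Window]:
    """Cut a sequence into consecutive non-overlapping windows.

    The terminal window may be shorter than ``window_size``. GC is the
    fraction of G/C among non-N bases (0 if the window is all N).
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = np.frombuffer(sequence.upper().encode("ascii"), dtype="S1")
    allowed = np.isin(seq, np.array([b"A", b"C", b"G", b"T", b"N"]))
    if not allowed.all():
        bad = seq[~allowed][:5]
        raise ValueError(f"unexpected characters in sequence: {bad}")
    is_gc = np.isin(seq, np.array([b"G", b"C"]))
    is_n = seq == b"N"
    windows = []
    for start in range(0, len(seq), window_size):
        end = min(start + window_size, len(seq))
        n_count = int(is_n[start:end].sum())
        non_n = (end - start) - n_count
        gc = float(is_gc[start:end].sum()) / non_n if non_n else 0.0
        windows.append(Window(chrom, start, end, gc, n_count / (end - start)))
    return windows


def merge_isochores(
    windows: Sequence[Window], gap_n_fraction: float = 0.5
) -> list[Isochore]:
    """Concatenate juxtaposed same-class windows into isochores.

    Windows with ``n_fraction > gap_n_fraction`` are assembly-gap windows:
    they are excluded from the output and break runs, so isochores never
    span a gap. Mean GC is length-weighted over non-gap windows.
    """
    windows = list(windows)
    if not windows:
        return []
    chroms = {w.chrom for w in windows}
    if len(chroms) > 1:
        raise ValueError("merge_isochores expects windows from one chromosome")
    starts = [w.start for w in windows]
    if starts != sorted(starts):
        raise ValueError("windows must be ordered by start coordinate")

    isochores: list[Isochore] = []
    run: list[Window] = []

    def flush() -> None:
        if not run:
            return
        total = sum(w.length for w in run)
        gc = sum(w.gc * w.length for w in run) / total
        cls = classify_window(run[0].gc)
        iso_id = f"{run[0].chrom}:{run[0].start}-{run[-1].end}:{cls}"
        isochores.append(
            Isochore(run[0].chrom, run[0].start, run[-1].end, cls, gc, iso_id)
        )
        run.clear()

    for w in windows:
        if w.n_fraction > gap_n_fraction:
            flush()
            continue
        if run and classify_window(run[-1].gc) != classify_window(w.gc):
            flush()
        run.append(w)
    flush()
    return isochores


def segment_genome(
    sequences: Mapping[str, str] | Iterable[tuple[str, str]],
    window_size: int = WINDOW_SIZE,
    gap_n_fraction: float = 0.5,
) -> list[Isochore]:
    """Segment every chromosome of a genome into isochores."""
    items = sequences.items() if isinstance(sequences, Mapping) else sequences
    isochores: list[Isochore] = []
    for chrom, seq in items:
        windows = segment_windows(str(seq), chrom=chrom, window_size=window_size)
        isochores.extend(merge_isochores(windows, gap_n_fraction=gap_n_fraction))
    return isochores


def assign_genes(
    genes: pd.DataFrame, isochores: Sequence[Isochore]
) -> pd.DataFrame:
    """Assign each gene to the isochore it overlaps most.

    ``genes`` needs columns ``gene_id``, ``chrom``, ``start``, ``end``
    (0-based half-open; ``strand`` is carried through if present). Each gene
    is assigned to the single overlapping isochore with the largest base-pair
    overlap; ties go to the isochore with the lower start coordinate. Genes
    overlapping no classified isochore get null assignments.

    Returns a copy of ``genes`` with ``assigned_isochore_id`` and
    ``assigned_class`` columns.
    """
    by_chrom: dict[str, list[Isochore]] = {}
    for iso in isochores:
        by_chrom.setdefault(iso.chrom, []).append(iso)
    for lst in by_chrom.values():
        lst.sort(key=lambda i: i.start)

    iso_ids: list[str | None] = []
    iso_classes: list[str | None] = []
    for row in genes.itertuples(index=False):
        if row.start >= row.end:
            raise ValueError(f"gene {row.gene_id} has start >= end")
        best: tuple[int, int] | None = None  # (-overlap, start) for min()
        best_iso: Isochore | None = None
        for iso in by_chrom.get(row.chrom, []):
            if iso.end <= row.start:
                continue
            if iso.start >= row.end:
                break
            overlap = min(iso.end, row.end) - max(iso.start, row.start)
            key = (-overlap, iso.start)
            if best is None or key < best:
                best, best_iso = key, iso
        iso_ids.append(best_iso.isochore_id if best_iso else None)
        iso_classes.append(best_iso.class_name if best_iso else None)

    out = genes.copy()
    out["assigned_isochore_id"] = iso_ids
    out["assigned_class"] = iso_classes
    return out


def relative_gene_fraction(
    subset_genes: Iterable[str], assignments: pd.DataFrame
) -> pd.DataFrame:
    """Per-class relative gene fraction log10((x/n) / (X/N)).

    ``x``/``X`` count subset genes in the class / in any class; ``n``/``N``
    count all assigned genes in the class / in any class. A class with
    ``x = 0`` gets ``value = -inf`` (a sentinel, not an error). Classes with
    ``n = 0`` are reported with a null value.
    """
    assigned = assignments.dropna(subset=["assigned_class"])
    subset = set(subset_genes)
    unknown = subset - set(assignments["gene_id"])
    if unknown:
        raise ValueError(f"subset genes not in assignment table: {sorted(unknown)[:5]}")
    n_by_class = assigned["assigned_class"].value_counts()
    sub_assigned = assigned[assigned["gene_id"].isin(subset)]
    x_by_class = sub_assigned["assigned_class"].value_counts()
    big_n = int(len(assigned))
    big_x = int(len(sub_assigned))
    if big_n == 0 or big_x == 0:
        raise ValueError("no assigned genes in transcriptome or subset")

    rows = []
    for cls in _CLASS_NAMES:
        n = int(n_by_class.get(cls, 0))
        x = int(x_by_class.get(cls, 0))
        if n == 0:
            value = np.nan
        elif x == 0:
            value = -np.inf
        else:
            value = float(np.log10((x / n) / (big_x / big_n)))
        rows.append({"class": cls, "x": x, "n": n, "X": big_x, "N": big_n, "value": value})
    return pd.DataFrame(rows)


def isochores_to_bed(isochores: Sequence[Isochore]) -> pd.DataFrame:
    """BED4-style frame (chrom, start, end, name=class) for export."""
    return pd.DataFrame(
        [
            {"chrom": i.chrom, "start": i.start, "end": i.end, "name": i.class_name}
            for i in isochores
        ]
    )
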