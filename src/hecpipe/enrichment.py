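"""Pre-ranked gene-set enrichment on bias-index-ranked gene lists.

Genes are ranked by their per-gene uMCW bias index, highest first (top =
more expressed under exposure). For a gene set, a weighted running sum
walks the ranked list: a hit (set member) adds ``|stat| / sum_set |stat|``,
a miss subtracts ``1 / (N - N_set)``; the enrichment score (ES) is the
maximal-magnitude deviation of the walk, with its sign. Positive ES means
the set crowds the top of the list.

Significance comes from a permutation null: ``n_perm`` uniformly drawn
same-size gene sets (equivalent to permuting the gene ranks for a fixed
set). The p-value is the proportion of same-sign null ES at least as
extreme as the observed one, over the same-sign null count; the normalised
enrichment score (NES) divides ES by the mean magnitude of same-sign null
ES, which absorbs the set-size dependence of the raw score.

Ties in the ranking statistic are broken by gene id so that ranked lists
are deterministic.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


def filter_sets(
    sets: Mapping[str, Sequence[str]],
    universe: Iterable[str],
    min_size: int = 15,
    max_size: int = 500,
) -> dict[str, list[str]]:
    """Intersect each set with the ranked universe and filter by size.

    Sets keep genes present in ``universe`` (the ranked list); a set is
    retained when ``min_size <= size < max_size`` *after* intersection.
    """
    uni = set(universe)
    out: dict[str, list[str]] = {}
    for name, members in sets.items():
        kept = sorted(set(members) & uni)
        if min_size <= len(kept) < max_size:
            out[name] = kept
    return out


def rank_genes(stats: pd.Series) -> pd.Series:
    """Order a gene -> statistic series descending, ties broken by gene id."""
    frame = stats.rename("stat").rename_axis("gene").reset_index()
    frame = frame.sort_values(["stat", "gene"], ascending=[False, True], kind="stable")
    return frame.set_index("gene")["stat"]


def running_es(ranked: pd.Series, members: Iterable[str]) -> float:
    """Enrichment score of a gene set along a ranked list (weight exponent 1)."""
    member_set = set(members)
    missing = member_set - set(ranked.index)
    if missing:
        raise ValueError(f"set members not in ranked list: {sorted(missing)[:5]}")
    hit = ranked.index.isin(member_set)
    return float(_es_from_hits(hit[None, :], np.abs(ranked.to_numpy(float)))[0])


def _es_from_hits(hits: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """ES per row of a boolean (R, N) hit matrix against shared weights."""
    n = weights.size
    n_set = hits.sum(axis=1)
    if np.any(n_set == 0) or np.any(n_set >= n):
        raise ValueError("gene set must be a proper non-empty subset of the list")
    hit_mass = hits @ weights
    if np.any(hit_mass == 0):
        raise ValueError("all-zero ranking statistics over a gene set: ES undefined")
    steps = np.where(
        hits,
        weights[None, :] / hit_mass[:, None],
        -1.0 / (n - n_set)[:, None],
    )
    walk = np.cumsum(steps, axis=1)
    imax = np.argmax(np.abs(walk), axis=1)
    return walk[np.arange(len(walk)), imax]


def gsea_null(
    ranked: pd.Series,
    set_size: int,
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Null ES distribution from uniformly drawn same-size gene sets."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n = len(ranked)
    if not 0 < set_size < n:
        raise ValueError("set size must be a proper subset size")
    rng = np.random.default_rng([5, seed])
    weights = np.abs(ranked.to_numpy(float))
    hits = np.zeros((n_perm, n), dtype=bool)
    idx = np.argsort(rng.random((n_perm, n)), axis=1)[:, :set_size]
    np.put_along_axis(hits, idx, True, axis=1)
    return _es_from_hits(hits, weights)


def _p_and_nes(es: float, null_es: np.ndarray, n_perm: int) -> tuple[float, float]:
    same_sign = null_es >= 0 if es >= 0 else null_es <= 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        return 1.0 / n_perm, float("nan")
    p = float(np.sum(np.abs(null_es[same_sign]) >= abs(es) - 1e-12)) / n_same
    mean_mag = float(np.mean(np.abs(null_es[same_sign])))
    nes = es / mean_mag if mean_mag > 0 else float("nan")
    return p, nes


def gsea(
    stats: pd.Series,
    sets: Mapping[str, Sequence[str]],
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 15,
    max_size: int = 500,
) -> pd.DataFrame:
    """Pre-ranked enrichment over a gene-set collection.

    Parameters
    ----------
    stats
        Gene -> ranking statistic (per-gene uMCW bias indexes).
    sets
        Gene-set collection (e.g. GO-BP terms), name -> member gene ids.

    Returns a frame with one row per retained set: ``es``, ``nes``,
    ``p_value``, ``size``, ``n_permutations``. Null distributions are
    shared across sets of equal size, so the permutation cost is paid once
    per distinct size.
    """
    ranked = rank_genes(stats)
    kept = filter_sets(sets, ranked.index, min_size=min_size, max_size=max_size)
    null_by_size: dict[int, np.ndarray] = {}
    rows = []
    for name in sorted(kept):
        members = kept[name]
        es = running_es(ranked, members)
        size = len(members)
        if size not in null_by_size:
            null_by_size[size] = gsea_null(ranked, size, n_perm=n_perm, seed=seed)
        p, nes = _p_and_nes(es, null_by_size[size], n_perm)
        rows.append(
            {
                "set": name,
                "es": es,
                "nes": nes,
                "p_value": p,
                "size": size,
                "n_permutations": n_perm,
            }
        )
    return pd.DataFrame(
        rows, columns=["set", "es", "nes", "p_value", "size", "n_permutations"]
    )
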