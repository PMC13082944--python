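"""Monte Carlo-Wilcoxon (MCW) tests.

The MCW family quantifies the direction and consistency of a difference
between two conditions with a *bias index* (BI) in [-1, 1]: +1 means every
comparison favours the first condition, -1 the second, 0 no net bias.
Significance is assessed against a rearrangement null: the data are
repeatedly reassorted, a BI is computed for each rearrangement, and
``p_upper`` / ``p_lower`` are the proportions of null BIs equal-or-above /
equal-or-below the observed one (both proportions include exact ties, so
``p_upper + p_lower >= 1``).

Three variants are implemented:

uMCW (unmatched measures)
    Two independent sets ``a`` and ``b``. Every cross-set pair ``(a_i, b_j)``
    is formed, differences ``a_i - b_j`` are signed-ranked, and
    ``BI = sum(signed ranks) / sum(|ranks|)``. The null reassorts the pooled
    measures between the two sets.

mbMCW (matched-measures bivariate)
    Two sets of within-subject pairs. Per-pair differences
    ``first - second`` from both sets are ranked jointly;
    ``BI = (S_x - S_y) / M`` where ``S_g`` is the signed-rank sum of set
    ``g`` and ``M`` the most-extreme achievable value of ``S_x - S_y``
    (all ranks positive in ``x``, negative in ``y``, i.e. the total rank
    mass). The null reassorts whole pairs between the two sets.

bMCW (biased measures)
    One set of per-element bias measures (here: per-gene uMCW BIs) plus
    designated subsets. The whole-set index
    ``wBI = sum(signed ranks) / sum(ranks)`` is tested against random sign
    flips; each subset index ``sBI = sum(signed ranks over subset) /
    sum(|S| largest ranks)`` is tested against random same-size memberships.

Ranking rules shared by all variants: differences of exactly zero receive
rank 0; nonzero differences are ranked ascending by absolute value starting
at 1 among the nonzeros; tied absolute values all receive the lowest of
their would-be ranks; each rank carries the sign of its difference.

Every test follows an exact path (full enumeration of the rearrangement
space) when the number of distinct rearrangements is strictly below
``max_rearrangements``, and otherwise a Monte-Carlo path drawing
``max_rearrangements`` uniform rearrangements (with replacement) from a
seeded generator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

# float guard for tie comparisons between null and observed bias indexes
_TIE_TOL = 1e-12

EXACT = "exact"
APPROXIMATE = "approximate"


@dataclass(frozen=True)
class MCWConfig:
    """Shared test configuration.

    Parameters
    ----------
    max_rearrangements
        Size threshold between the exact and Monte-Carlo paths, and the
        number of Monte-Carlo draws on the approximate path. Default 10,000.
    seed
        Seed for the Monte-Carlo generator.
    """

    max_rearrangements: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_rearrangements < 1:
            raise ValueError("max_rearrangements must be >= 1")


@dataclass(frozen=True)
class MCWResult:
    """Observed bias index with its rearrangement-null p-values."""

    bias_index: float
    p_upper: float
    p_lower: float
    n_rearrangements_used: int
    path: str

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.bias_index <= 1.0 + 1e-9:
            raise ValueError(f"bias index {self.bias_index} outside [-1, 1]")

    def summary_row(self) -> dict:
        return {
            "BI": self.bias_index,
            "p_upper": self.p_upper,
            "p_lower": self.p_lower,
            "n_rearrangements": self.n_rearrangements_used,
            "path": self.path,
        }


@dataclass(frozen=True)
class BmcwResult:
    """Whole-set (wBI) and per-subset (sBI) results of a bMCW test."""

    whole_set: MCWResult
    per_subset: Mapping[str, MCWResult] = field(default_factory=dict)


def _as_finite_array(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-d sequence")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def signed_ranks(differences: Sequence[float]) -> np.ndarray:
    """Signed ranks of a sequence of differences.

    Zeros receive rank 0. Nonzero values are ranked by absolute value,
    ascending, starting at 1 among the nonzeros; tied absolute values all
    receive the lowest of their would-be ranks; each rank carries the sign
    of its difference.

    >>> signed_ranks([3, -1, 0, 3]).tolist()
    [2, -1, 0, 2]
    """
    d = _as_finite_array(differences, "differences")
    return _signed_rank_rows(d[None, :])[0].astype(int)


def _signed_rank_rows(d: np.ndarray) -> np.ndarray:
    """Row-wise signed ranks for a (..., k) array of differences."""
    absd = np.abs(d)
    ranks = rankdata(absd, method="min", axis=-1).astype(float)
    nonzero = d != 0
    n_zero = np.sum(~nonzero, axis=-1, keepdims=True)
    # zeros occupy the lowest |d| ranks; shift nonzeros down and zero the zeros
    out = np.where(nonzero, ranks - n_zero, 0.0)
    return out * np.sign(d)


def _bi_rows(d: np.ndarray) -> np.ndarray:
    """Bias index per row: signed-rank sum over total rank mass (0/0 -> 0)."""
    sr = _signed_rank_rows(d)
    num = sr.sum(axis=-1)
    den = np.abs(sr).sum(axis=-1)
    return np.divide(num, den, out=np.zeros_like(num), where=den > 0)


def count_rearrangements(test_kind: str, **sizes: int) -> int:
    """Number of potentially distinct data rearrangements for a test.

    ``test_kind`` is one of ``"umcw"`` / ``"mbmcw"`` (pass ``n_a``, ``n_b``),
    ``"bmcw_whole"`` (pass ``n``) or ``"bmcw_subset"`` (pass ``n``,
    ``subset_size``). Python integers are exact, so no overflow handling is
    needed; callers compare the result against ``max_rearrangements``.
    """
    if test_kind in ("umcw", "mbmcw"):
        n_a, n_b = sizes["n_a"], sizes["n_b"]
        if n_a < 1 or n_b < 1:
            raise ValueError("set sizes must be positive")
        return math.comb(n_a + n_b, n_a)
    if test_kind == "bmcw_whole":
        n = sizes["n"]
        if n < 1:
            raise ValueError("n must be positive")
        return 2**n
    if test_kind == "bmcw_subset":
        n, k = sizes["n"], sizes["subset_size"]
        if not 1 <= k <= n:
            raise ValueError("subset size must satisfy 1 <= |S| <= N")
        return math.comb(n, k)
    raise ValueError(f"unknown test kind {test_kind!r}")


def _pvalues(null_bi: np.ndarray, observed: float) -> tuple[float, float]:
    p_upper = float(np.mean(null_bi >= observed - _TIE_TOL))
    p_lower = float(np.mean(null_bi <= observed + _TIE_TOL))
    if p_upper == 0.0 or p_lower == 0.0:
        logger.info(
            "zero Monte-Carlo p-value: report as < 1/%d", null_bi.size
        )
    return p_upper, p_lower


def _cross_diffs(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Flattened Cartesian-product differences a_i - b_j, shape (..., na*nb)."""
    d = a[..., :, None] - b[..., None, :]
    return d.reshape(*d.shape[:-2], -1)


def _partition_indices(
    n: int, n_a: int, total: int, config: MCWConfig, rng_stream: int
) -> tuple[np.ndarray, np.ndarray, str]:
    """Index matrices (R, n_a) and (R, n - n_a) splitting range(n) into two sets.

    Exact path enumerates all C(n, n_a) splits when that count is strictly
    below ``max_rearrangements``; otherwise ``max_rearrangements`` uniform
    splits are drawn with replacement.
    """
    if total < config.max_rearrangements:
        idx_a = np.fromiter(
            (i for comb in combinations(range(n), n_a) for i in comb),
            dtype=np.intp,
            count=total * n_a,
        ).reshape(total, n_a)
        mask = np.ones((total, n), dtype=bool)
        np.put_along_axis(mask, idx_a, False, axis=1)
        idx_b = np.nonzero(mask)[1].reshape(total, n - n_a)
        return idx_a, idx_b, EXACT
    rng = np.random.default_rng([rng_stream, config.seed])
    r = config.max_rearrangements
    perms = np.argsort(rng.random((r, n)), axis=1)
    return perms[:, :n_a], perms[:, n_a:], APPROXIMATE


def umcw_test(
    a: Sequence[float], b: Sequence[float], config: MCWConfig | None = None
) -> MCWResult:
    """Unmatched-measures MCW test of directional bias between two sets.

    ``BI > 0`` means measures in ``a`` tend to exceed those in ``b``. All
    cross-set pairs ``(a_i, b_j)`` are formed; the null rearranges the
    pooled measures between the two sets.
    """
    config = config or MCWConfig()
    a_arr = _as_finite_array(a, "a")
    b_arr = _as_finite_array(b, "b")
    observed = float(_bi_rows(_cross_diffs(a_arr, b_arr)[None, :])[0])

    pooled = np.concatenate([a_arr, b_arr])
    n, n_a = pooled.size, a_arr.size
    total = count_rearrangements("umcw", n_a=n_a, n_b=b_arr.size)
    idx_a, idx_b, path = _partition_indices(n, n_a, total, config, rng_stream=1)
    null_bi = _bi_rows(_cross_diffs(pooled[idx_a], pooled[idx_b]))
    p_upper, p_lower = _pvalues(null_bi, observed)
    return MCWResult(observed, p_upper, p_lower, null_bi.size, path)


def _pair_diffs(pairs: Sequence[Sequence[float]], name: str) -> np.ndarray:
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] == 0:
        raise ValueError(f"{name} must be a non-empty sequence of (first, second) pairs")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr[:, 0] - arr[:, 1]


def mbmcw_test(
    x: Sequence[Sequence[float]],
    y: Sequence[Sequence[float]],
    config: MCWConfig | None = None,
) -> MCWResult:
    """Matched-measures bivariate MCW test.

    ``x`` and ``y`` are sequences of ``(first, second)`` within-subject
    pairs. Per-pair differences ``first - second`` from both sets are
    signed-ranked jointly; ``BI = (S_x - S_y) / M`` with ``M`` the total
    rank mass (the most extreme achievable ``S_x - S_y``). ``BI > 0`` means
    the paired differences in ``x`` are more positively biased than those
    in ``y``. The null reassorts whole pairs between the sets; the joint
    ranking is assignment-invariant, so ranks are computed once.
    """
    config = config or MCWConfig()
    dx = _pair_diffs(x, "x")
    dy = _pair_diffs(y, "y")
    pooled = np.concatenate([dx, dy])
    ranks = _signed_rank_rows(pooled[None, :])[0]
    mass = np.abs(ranks).sum()

    n, n_x = pooled.size, dx.size

    def bi_for(idx_x: np.ndarray, idx_y: np.ndarray) -> np.ndarray:
        s = ranks[idx_x].sum(axis=-1) - ranks[idx_y].sum(axis=-1)
        return s / mass if mass > 0 else np.zeros(np.shape(s))

    observed = float(
        bi_for(np.arange(n_x)[None, :], np.arange(n_x, n)[None, :])[0]
    )
    total = count_rearrangements("mbmcw", n_a=n_x, n_b=dy.size)
    idx_x, idx_y, path = _partition_indices(n, n_x, total, config, rng_stream=2)
    null_bi = np.asarray(bi_for(idx_x, idx_y))
    p_upper, p_lower = _pvalues(null_bi, observed)
    return MCWResult(observed, p_upper, p_lower, null_bi.size, path)


def _sign_matrix(n: int, total: int, config: MCWConfig) -> tuple[np.ndarray, str]:
    if total < config.max_rearrangements:
        codes = np.arange(total, dtype=np.int64)
        bits = (codes[:, None] >> np.arange(n)) & 1
        return bits * 2.0 - 1.0, EXACT
    rng = np.random.default_rng([3, config.seed])
    r = config.max_rearrangements
    return rng.integers(0, 2, size=(r, n)) * 2.0 - 1.0, APPROXIMATE


def _membership_indices(
    n: int, k: int, total: int, config: MCWConfig
) -> tuple[np.ndarray, str]:
    if total < config.max_rearrangements:
        idx = np.fromiter(
            (i for comb in combinations(range(n), k) for i in comb),
            dtype=np.intp,
            count=total * k,
        ).reshape(total, k)
        return idx, EXACT
    rng = np.random.default_rng([4, config.seed])
    r = config.max_rearrangements
    idx = np.argsort(rng.random((r, n)), axis=1)[:, :k]
    return idx, APPROXIMATE


def bmcw_test(
    bias_values: Sequence[float],
    subsets: Mapping[str, Sequence[int]] | None = None,
    element_ids: Sequence[str] | None = None,
    config: MCWConfig | None = None,
) -> BmcwResult:
    """Biased-measures MCW test on a set of per-element bias measures.

    Parameters
    ----------
    bias_values
        Per-element bias measures (e.g. per-gene uMCW BIs).
    subsets
        Mapping from subset name to member element ids (when
        ``element_ids`` is given) or to integer positions.
    element_ids
        Optional element identifiers aligned with ``bias_values``.

    The whole-set index wBI is tested against random sign flips of the
    signed ranks; each subset index sBI against random same-size
    memberships.
    """
    config = config or MCWConfig()
    values = _as_finite_array(bias_values, "bias_values")
    n = values.size

    positions: dict[str, np.ndarray] = {}
    if subsets:
        if element_ids is not None:
            lookup = {eid: i for i, eid in enumerate(element_ids)}
            if len(lookup) != n:
                raise ValueError("element_ids must be unique and match bias_values")
            for name, members in subsets.items():
                missing = [m for m in members if m not in lookup]
                if missing:
                    raise ValueError(f"subset {name!r} has unknown elements {missing[:5]}")
                positions[name] = np.asarray([lookup[m] for m in members], dtype=np.intp)
        else:
            for name, members in subsets.items():
                idx = np.asarray(list(members), dtype=np.intp)
                if idx.size and (idx.min() < 0 or idx.max() >= n):
                    raise ValueError(f"subset {name!r} has out-of-range positions")
                positions[name] = idx
        for name, idx in positions.items():
            if not 1 <= idx.size <= n:
                raise ValueError(f"subset {name!r} must satisfy 1 <= |S| <= N")
            if np.unique(idx).size != idx.size:
                raise ValueError(f"subset {name!r} has duplicate members")

    ranks = _signed_rank_rows(values[None, :])[0]
    mags = np.abs(ranks)
    total_mass = mags.sum()

    # whole-set index against sign rearrangement
    wbi = ranks.sum() / total_mass if total_mass > 0 else 0.0
    total_w = count_rearrangements("bmcw_whole", n=n)
    signs, path_w = _sign_matrix(n, total_w, config)
    null_w = (signs @ mags) / total_mass if total_mass > 0 else np.zeros(len(signs))
    pu_w, pl_w = _pvalues(null_w, wbi)
    whole = MCWResult(float(wbi), pu_w, pl_w, len(signs), path_w)

    # subset indexes against membership rearrangement; Monte-Carlo draws share
    # one permutation matrix across subsets (slices of a permutation are
    # uniform same-size memberships), keeping cost independent of subset count
    sorted_mags = np.sort(mags)[::-1]
    top_cumsum = np.concatenate([[0.0], np.cumsum(sorted_mags)])
    mc_perms: np.ndarray | None = None
    per_subset: dict[str, MCWResult] = {}
    for name, idx in positions.items():
        k = idx.size
        denom = top_cumsum[k]
        sbi = ranks[idx].sum() / denom if denom > 0 else 0.0
        total_s = count_rearrangements("bmcw_subset", n=n, subset_size=k)
        if total_s < config.max_rearrangements:
            members, path_s = _membership_indices(n, k, total_s, config)
        else:
            if mc_perms is None:
                rng = np.random.default_rng([4, config.seed])
                mc_perms = np.argsort(
                    rng.random((config.max_rearrangements, n)), axis=1
                )
            members, path_s = mc_perms[:, :k], APPROXIMATE
        null_s = (
            ranks[members].sum(axis=1) / denom if denom > 0 else np.zeros(len(members))
        )
        pu, pl = _pvalues(null_s, sbi)
        per_subset[name] = MCWResult(float(sbi), pu, pl, len(members), path_s)

    return BmcwResult(whole, per_subset)


def umcw_test_many(
    a: np.ndarray, b: np.ndarray, config: MCWConfig | None = None, chunk: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, str]:
    """Vectorised uMCW over many rows sharing one group layout.

    ``a`` has shape (G, n_a) and ``b`` (G, n_b); row g is one test (one gene).
    Returns arrays (bias_index, p_upper, p_lower) of length G and the common
    path label. Used for per-gene contrast statistics where thousands of
    identical-layout tests are needed.
    """
    config = config or MCWConfig()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[0] != b.shape[0]:
        raise ValueError("a and b must be 2-d with matching row counts")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in input")
    n_g, n_a = a.shape
    n_b = b.shape[1]
    n = n_a + n_b
    total = count_rearrangements("umcw", n_a=n_a, n_b=n_b)
    idx_a, idx_b, path = _partition_indices(n, n_a, total, config, rng_stream=1)
    if chunk is None:
        # bound the (chunk, R, n_a*n_b) working array to ~2e7 elements
        chunk = max(1, int(2e7 / (len(idx_a) * n_a * n_b)))

    bi = np.empty(n_g)
    p_upper = np.empty(n_g)
    p_lower = np.empty(n_g)
    for lo in range(0, n_g, chunk):
        hi = min(lo + chunk, n_g)
        a_c, b_c = a[lo:hi], b[lo:hi]
        obs = _bi_rows(_cross_diffs(a_c, b_c))
        pooled = np.concatenate([a_c, b_c], axis=1)  # (g, n)
        # (g, R, n_a) and (g, R, n_b) gathered per rearrangement
        null = _bi_rows(
            _cross_diffs(pooled[:, idx_a], pooled[:, idx_b])
        )  # (g, R)
        bi[lo:hi] = obs
        p_upper[lo:hi] = np.mean(null >= obs[:, None] - _TIE_TOL, axis=1)
        p_lower[lo:hi] = np.mean(null <= obs[:, None] + _TIE_TOL, axis=1)
    return bi, p_upper, p_lower, path
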