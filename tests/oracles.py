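"""Independent brute-force oracles for the MCW tests and enrichment walk.

Everything here is written with plain Python loops and itertools, sharing
no code with the package: sorting-based ranking, exhaustive enumeration of
rearrangement spaces, and a literal running-sum walk. Deliberately slow and
obvious.
"""

from itertools import combinations


def oracle_signed_ranks(diffs):
    """Zeros -> 0; nonzeros ranked ascending by |d| from 1, ties -> min rank."""
    nonzero = sorted((abs(d), i) for i, d in enumerate(diffs) if d != 0)
    rank_of = {}
    for pos, (mag, i) in enumerate(nonzero, start=1):
        first = next(p for p, (m, _) in enumerate(nonzero, start=1) if m == mag)
        rank_of[i] = first
    out = []
    for i, d in enumerate(diffs):
        if d == 0:
            out.append(0)
        else:
            out.append(rank_of[i] if d > 0 else -rank_of[i])
    return out


def oracle_umcw_bi(a, b):
    diffs = [ai - bj for ai in a for bj in b]
    ranks = oracle_signed_ranks(diffs)
    denom = sum(abs(r) for r in ranks)
    return sum(ranks) / denom if denom else 0.0


def oracle_umcw(a, b):
    """Exact uMCW: BI plus p-values over all measure assortments."""
    observed = oracle_umcw_bi(a, b)
    pooled = list(a) + list(b)
    n_a = len(a)
    nulls = []
    for idx in combinations(range(len(pooled)), n_a):
        aa = [pooled[i] for i in idx]
        bb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        nulls.append(oracle_umcw_bi(aa, bb))
    tol = 1e-12
    p_upper = sum(1 for v in nulls if v >= observed - tol) / len(nulls)
    p_lower = sum(1 for v in nulls if v <= observed + tol) / len(nulls)
    return observed, p_upper, p_lower, len(nulls)


def oracle_mbmcw_bi(x_pairs, y_pairs):
    dx = [p[0] - p[1] for p in x_pairs]
    dy = [p[0] - p[1] for p in y_pairs]
    ranks = oracle_signed_ranks(dx + dy)
    mass = sum(abs(r) for r in ranks)
    if mass == 0:
        return 0.0
    s_x = sum(ranks[: len(dx)])
    s_y = sum(ranks[len(dx):])
    return (s_x - s_y) / mass


def oracle_mbmcw(x_pairs, y_pairs):
    observed = oracle_mbmcw_bi(x_pairs, y_pairs)
    pooled = list(x_pairs) + list(y_pairs)
    n_x = len(x_pairs)
    nulls = []
    for idx in combinations(range(len(pooled)), n_x):
        xx = [pooled[i] for i in idx]
        yy = [pooled[i] for i in range(len(pooled)) if i not in idx]
        nulls.append(oracle_mbmcw_bi(xx, yy))
    tol = 1e-12
    p_upper = sum(1 for v in nulls if v >= observed - tol) / len(nulls)
    p_lower = sum(1 for v in nulls if v <= observed + tol) / len(nulls)
    return observed, p_upper, p_lower, len(nulls)


def oracle_bmcw_whole(values):
    """wBI plus exact p-values over all 2^N sign configurations."""
    ranks = oracle_signed_ranks(values)
    mags = [abs(r) for r in ranks]
    mass = sum(mags)
    wbi = sum(ranks) / mass if mass else 0.0
    n = len(values)
    nulls = []
    for code in range(2**n):
        signs = [1 if (code >> i) & 1 else -1 for i in range(n)]
        s = sum(sg * m for sg, m in zip(signs, mags))
        nulls.append(s / mass if mass else 0.0)
    tol = 1e-12
    p_upper = sum(1 for v in nulls if v >= wbi - tol) / len(nulls)
    p_lower = sum(1 for v in nulls if v <= wbi + tol) / len(nulls)
    return wbi, p_upper, p_lower, len(nulls)


def oracle_bmcw_subset(values, subset_positions):
    """sBI plus exact p-values over all same-size memberships."""
    ranks = oracle_signed_ranks(values)
    mags = sorted((abs(r) for r in ranks), reverse=True)
    k = len(subset_positions)
    denom = sum(mags[:k])
    sbi = sum(ranks[i] for i in subset_positions) / denom if denom else 0.0
    nulls = []
    for idx in combinations(range(len(values)), k):
        s = sum(ranks[i] for i in idx)
        nulls.append(s / denom if denom else 0.0)
    tol = 1e-12
    p_upper = sum(1 for v in nulls if v >= sbi - tol) / len(nulls)
    p_lower = sum(1 for v in nulls if v <= sbi + tol) / len(nulls)
    return sbi, p_upper, p_lower, len(nulls)


def oracle_running_es(ordered_stats, members):
    """Literal running-sum walk over a (gene, stat) list in ranked order."""
    hit_mass = sum(abs(s) for g, s in ordered_stats if g in members)
    n = len(ordered_stats)
    n_set = sum(1 for g, _ in ordered_stats if g in members)
    walk, best = 0.0, 0.0
    for gene, stat in ordered_stats:
        if gene in members:
            walk += abs(stat) / hit_mass
        else:
            walk -= 1.0 / (n - n_set)
        if abs(walk) > abs(best):
            best = walk
    return best
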