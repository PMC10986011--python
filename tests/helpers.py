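"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — expand multiplicities, enumerate all
substrings / rank assignments / candidate thresholds — and shares no code with
the implementation paths it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from bldm.metrics import BlockHaplotypes


# --- haplotype-load / AMF / PDR oracles ------------------------------------

def expand_reads(bh: BlockHaplotypes) -> list[str]:
    """Clipped patterns with counts expanded to one entry per read."""
    out = []
    for (_, pat), count in sorted(bh.patterns.items()):
        out.extend([pat] * count)
    return out


def brute_mhl(bh: BlockHaplotypes, k: float = 1, state: str = "1") -> float | None:
    reads = expand_reads(bh)
    if not reads:
        return None
    per_l: dict[int, list[int]] = {}
    for pat in reads:
        for l in range(1, len(pat) + 1):
            subs = [pat[i : i + l] for i in range(len(pat) - l + 1)]
            tot, full = per_l.setdefault(l, [0, 0])
            per_l[l][0] = tot + len(subs)
            per_l[l][1] = full + sum(1 for s in subs if set(s) == {state})
    num = 0.0
    den = 0.0
    for l, (tot, full) in per_l.items():
        if tot == 0:
            continue
        w = l**k
        num += w * full / tot
        den += w
    return num / den


def brute_umhl(bh: BlockHaplotypes, k: float = 1) -> float | None:
    return brute_mhl(bh, k, state="0")


def brute_amf(bh: BlockHaplotypes) -> float | None:
    reads = expand_reads(bh)
    calls = sum(len(p) for p in reads)
    if calls == 0:
        return None
    return sum(p.count("1") for p in reads) / calls


def brute_pdr(bh: BlockHaplotypes, min_cpgs: int = 3) -> float | None:
    reads = [p for p in expand_reads(bh) if len(p) >= min_cpgs]
    if not reads:
        return None
    return sum(1 for p in reads if "0" in p and "1" in p) / len(reads)


def random_block(rng: np.random.Generator, max_L: int = 6, max_reads: int = 8) -> BlockHaplotypes:
    L = int(rng.integers(1, max_L + 1))
    bh = BlockHaplotypes("rand", L)
    for _ in range(int(rng.integers(1, max_reads + 1))):
        ln = int(rng.integers(1, L + 1))
        off = int(rng.integers(0, L - ln + 1))
        pat = "".join(rng.choice(["0", "1"], size=ln))
        bh.add(off, pat, int(rng.integers(1, 4)))
    return bh


# --- exact Mann-Whitney oracle ---------------------------------------------

def exact_mwu_two_sided_p(x, y) -> float:
    """Two-sided exact p by full enumeration of rank assignments (no ties)."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    n1 = len(x)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_of = lambda grp: sum(ranks[v] for v in grp) - n1 * (n1 + 1) / 2
    u_obs = u_of(x)
    mean_u = n1 * len(y) / 2
    dev = abs(u_obs - mean_u)
    total = 0
    extreme = 0
    for combo in combinations(pooled, n1):
        total += 1
        u = sum(ranks[v] for v in combo) - n1 * (n1 + 1) / 2
        if abs(u - mean_u) >= dev - 1e-12:
            extreme += 1
    return extreme / total


# --- Youden / AUC oracles ---------------------------------------------------

def brute_youden(scores, labels) -> tuple[float, float]:
    """(best J, threshold) via dense scan, rule score >= t positive; ties -> smallest t."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    distinct = np.unique(scores)
    cands = [distinct[0]] + [(a + b) / 2 for a, b in zip(distinct[:-1], distinct[1:])]
    cands += [np.nextafter(distinct[-1], np.inf)]
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    best = (None, None)
    for t in cands:
        calls = scores >= t
        # integer-exact J ranking: tp/n_pos + tn/n_neg maximal iff
        # tp*n_neg + tn*n_pos maximal
        j = int((calls & y).sum()) * n_neg + int(((~calls) & (~y)).sum()) * n_pos
        if best[0] is None or j > best[0]:
            best = (j, t)
    return best[0] / (n_pos * n_neg) - 1, best[1]


def brute_auc(scores, labels) -> float:
    """Pairwise-comparison AUC, ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos = scores[y]
    neg = scores[~y]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


# --- block-calling oracle ---------------------------------------------------

def brute_call_blocks(pair_ok: list[bool], min_cpgs: int) -> list[tuple[int, int]]:
    """Maximal-by-inclusion contiguous index stretches whose every internal
    consecutive pair is OK, with at least ``min_cpgs`` members.

    Enumerate *all* contiguous sub-runs, keep qualifying ones, drop any that
    is contained in another qualifying one.
    """
    n = len(pair_ok) + 1
    qualifying = []
    for a in range(n):
        for b in range(a + min_cpgs, n + 1):
            if all(pair_ok[a:b - 1]):
                qualifying.append((a, b))
    maximal = [
        (a, b)
        for (a, b) in qualifying
        if not any((c <= a and b <= d) and (c, d) != (a, b) for (c, d) in qualifying)
    ]
    return sorted(maximal)
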