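"""Independent brute-force reference implementations used by the tests.

These deliberately re-derive each quantity with naive, explicit loops
(enumeration, closed forms) and share no code with the package paths
they check.
"""

from __future__ import annotations

import math

import numpy as np

TIERS = ["N", "VLOW", "LOW", "OK", "SOK"]


def oracle_splice_call(
    records: dict,
    controls: list[str],
    perturbed: list[str],
    min_dpsi: float = 15.0,
    min_pairwise: float = 5.0,
    min_tier: str = "VLOW",
    is_ir: bool = False,
    ir_alpha: float = 0.05,
) -> bool:
    """Naive re-derivation of the per-event differential-splicing verdict.

    ``records`` maps sample -> (psi, tier, inc, exc, b5, b3).
    """
    samples = controls + perturbed
    floor = TIERS.index(min_tier)
    for s in samples:
        psi, tier = records[s][0], records[s][1]
        if psi is None or (isinstance(psi, float) and math.isnan(psi)):
            return False
        if TIERS.index(tier) < floor:
            return False
    c = [records[s][0] for s in controls]
    p = [records[s][0] for s in perturbed]
    dpsi = sum(c) / len(c) - sum(p) / len(p)
    if abs(dpsi) < min_dpsi:
        return False
    pairs = [cv - pv for cv in c for pv in p]
    pos = all(v >= min_pairwise for v in pairs)
    neg = all(v <= -min_pairwise for v in pairs)
    if not (pos or neg):
        return False
    if is_ir:
        for s in samples:
            b5, b3 = records[s][4], records[s][5]
            if b5 is None or b3 is None or (b5 + b3) == 0:
                return False
            if oracle_binom_two_sided(int(b5), int(b3)) < ir_alpha:
                return False
    return True


def oracle_binom_two_sided(b5: int, b3: int) -> float:
    """Exhaustive two-sided exact binomial p at p=0.5 (minimum-likelihood
    enumeration over all outcomes)."""
    n = b5 + b3
    p_obs = math.comb(n, b5) * 0.5**n
    total = 0.0
    for k in range(n + 1):
        pk = math.comb(n, k) * 0.5**n
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(total, 1.0)


def oracle_fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher p by exhaustive enumeration of all tables with the
    observed margins and a cell >= a."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    denom = math.comb(n, c1)
    total = 0.0
    for aa in range(max(0, c1 - r2), min(r1, c1) + 1):
        if aa >= a:
            total += math.comb(r1, aa) * math.comb(r2, c1 - aa) / denom
    return min(total, 1.0)


def oracle_expr_call(
    crpkm: dict,
    reads: dict,
    controls: list[str],
    perturbed: list[str],
    min_crpkm: float = 2.0,
    min_reads: int = 50,
    min_avg_fold: float = 2.0,
    min_pairwise_fold: float = 1.5,
    floor: float = 0.01,
) -> str | None:
    """Naive differential-expression verdict; returns 'up', 'down' or None."""
    c = [crpkm[s] for s in controls]
    p = [crpkm[s] for s in perturbed]
    if not (all(v > min_crpkm for v in c) or all(v > min_crpkm for v in p)):
        return None
    if max(reads[s] for s in controls + perturbed) < min_reads:
        return None

    def fold(x, y):
        x, y = max(x, floor), max(y, floor)
        return max(x, y) / min(x, y)

    ac, ap = max(sum(c) / len(c), floor), max(sum(p) / len(p), floor)
    if fold(ac, ap) < min_avg_fold:
        return None
    dirs = set()
    for cv in c:
        for pv in p:
            if fold(cv, pv) < min_pairwise_fold:
                return None
            dirs.add(max(pv, floor) >= max(cv, floor))
    if len(dirs) != 1:
        return None
    direction = "up" if ap > ac else "down"
    if (ap >= ac) != dirs.pop():
        return None
    return direction


def oracle_window_profile(seq: str, motifs: set[str], k: int, window: int) -> list[float]:
    """Windowed motif-coverage fraction by direct position counting."""
    s = seq.upper().replace("U", "T")
    covered = [False] * len(s)
    for i in range(len(s) - k + 1):
        if s[i : i + k] in motifs:
            for j in range(i, i + k):
                covered[j] = True
    half = window // 2
    out = []
    for p in range(len(s)):
        lo, hi = max(0, p - half), min(len(s), p + half + 1)
        out.append(sum(covered[lo:hi]) / (hi - lo))
    return out


def oracle_smooth(values, window: int = 10) -> list[float]:
    """Trailing windowed mean by direct summation."""
    out = []
    n = len(values)
    for i in range(n):
        chunk = values[i : min(n, i + window)]
        out.append(sum(chunk) / len(chunk))
    return out
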