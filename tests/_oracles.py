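"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately naive and coded without reference to the
package internals: exhaustive span enumeration for digestion, a hand-typed
residue-mass table, O(n^2) graph-component clustering for exclusion lists,
a prefix-scan FDR walk, and closed-form least squares.
"""

from __future__ import annotations

import math

# Monoisotopic residue masses (Da), typed by hand from the standard table.
RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER = 18.010565
TMT6 = 229.162932
PROTON = 1.0072765


def oracle_peptide_mass(sequence: str, n_tmt: int = 0) -> float:
    return sum(RESIDUE_MASS[a] for a in sequence) + WATER + n_tmt * TMT6


def oracle_digest(sequence: str, max_missed: int, min_length: int):
    """Every fully tryptic (start, end) span with <= max_missed internal
    missed cleavages and length >= min_length, as a sorted multiset of
    (peptide, n_missed)."""
    n = len(sequence)
    out = []
    for start in range(n):
        if not (start == 0 or sequence[start - 1] in "KR"):
            continue
        for end in range(start + 1, n + 1):
            if not (end == n or sequence[end - 1] in "KR"):
                continue
            # internal cleavage sites strictly inside the span
            missed = sum(
                1 for i in range(start, end - 1) if sequence[i] in "KR"
            )
            if missed > max_missed:
                continue
            if end - start >= min_length:
                out.append((sequence[start:end], missed))
    return sorted(out)


def oracle_fdr_walk(scores, is_decoy, alpha):
    """Indices of accepted targets: rank by descending score (ties: decoys
    first), take the largest prefix in which EVERY step keeps
    decoys/targets <= alpha; decoys are never accepted."""
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], 0 if is_decoy[i] else 1))
    accepted = []
    d = t = 0
    for i in order:
        if is_decoy[i]:
            d += 1
        else:
            t += 1
        if d / max(t, 1) > alpha:
            break
        if not is_decoy[i]:
            accepted.append(i)
    return set(accepted)


def oracle_cluster_merge(entries, ppm, rt_gap=0.0):
    """Naive merge-to-fixpoint: repeatedly build the full O(n^2) mergeable
    graph over current groups, collapse its connected components (tracking
    the original leaf entries so the merged m/z is the leaf mean), until
    nothing changes. Entries are (mz, rt_start, rt_end) triples.

    Returns sorted (mz, rt_start, rt_end) triples.
    """
    groups = [[e] for e in entries]

    def mz(g):
        return sum(e[0] for e in g) / len(g)

    def lo(g):
        return min(e[1] for e in g)

    def hi(g):
        return max(e[2] for e in g)

    def mergeable(a, b):
        lo_mz = min(mz(a), mz(b))
        if abs(mz(a) - mz(b)) / lo_mz * 1e6 > ppm:
            return False
        return lo(a) <= hi(b) + rt_gap and lo(b) <= hi(a) + rt_gap

    while True:
        n = len(groups)
        adj = {i: [] for i in range(n)}
        any_edge = False
        for i in range(n):
            for j in range(i + 1, n):
                if mergeable(groups[i], groups[j]):
                    adj[i].append(j)
                    adj[j].append(i)
                    any_edge = True
        if not any_edge:
            break
        seen = set()
        new_groups = []
        for i in range(n):
            if i in seen:
                continue
            stack, comp = [i], []
            seen.add(i)
            while stack:
                u = stack.pop()
                comp.append(u)
                for v in adj[u]:
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
            new_groups.append([e for u in comp for e in groups[u]])
        groups = new_groups

    return sorted((mz(g), lo(g), hi(g)) for g in groups)


def oracle_ols(x, y):
    """Closed-form simple least squares plus squared Pearson correlation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((xi - mx) ** 2 for xi in x)
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    syy = sum((yi - my) ** 2 for yi in y)
    slope = sxy / sxx
    intercept = my - slope * mx
    r2 = sxy * sxy / (sxx * syy) if syy > 0 else float("nan")
    return slope, intercept, r2


def random_exclusion_triples(rng, n_max=100):
    """Random (mz, rt_start, rt_end) triples with deliberate near-collisions
    so clustering actually happens: a few m/z centers, +-20 ppm jitter."""
    n = int(rng.integers(1, n_max + 1))
    n_centers = max(1, n // 4)
    centers = rng.uniform(400.0, 1600.0, n_centers)
    out = []
    for _ in range(n):
        c = centers[rng.integers(0, n_centers)]
        mz = c * (1 + rng.uniform(-20e-6, 20e-6))
        start = rng.uniform(0.0, 80.0)
        out.append((float(mz), float(start), float(start + rng.uniform(0.5, 6.0))))
    return out
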