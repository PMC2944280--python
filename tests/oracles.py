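"""Independent brute-force oracles used by unit and acceptance tests.

Deliberately naive implementations (transitive closure over a distance
matrix, all-substrings enumeration) kept separate from the library code
they check.
"""

import math


def brute_force_partition(points: list[tuple[float, float]],
                          threshold: float) -> set[frozenset[int]]:
    """Partition point indices by transitive closure of dist < threshold."""
    n = len(points)
    adj = [[math.dist(points[i], points[j]) < threshold for j in range(n)]
           for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                adj[i][j] = adj[i][j] or (adj[i][k] and adj[k][j])
    return {frozenset(j for j in range(n) if adj[i][j] or i == j)
            for i in range(n)}


def brute_force_lcs(a: str, b: str) -> int:
    """Longest common substring length by enumerating all substrings."""
    best = 0
    for i in range(len(a)):
        for j in range(i + best + 1, len(a) + 1):
            if a[i:j] in b:
                best = j - i
    return best
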