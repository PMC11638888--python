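"""Independent brute-force oracles shared across test modules."""

from __future__ import annotations


def brute_force_daura(rmsd, cutoff):
    """Exclusive clustering by explicit neighbour-count enumeration.

    Plain-Python re-statement of the greedy exclusive algorithm (most
    neighbours within cutoff seeds a cluster; ties to the lowest index),
    kept deliberately separate from the library implementation.
    """
    n = len(rmsd)
    alive = set(range(n))
    clusters = []
    while alive:
        best, best_count = None, -1
        for i in sorted(alive):
            count = sum(1 for j in alive if j != i and rmsd[i][j] <= cutoff)
            if count > best_count:
                best, best_count = i, count
        members = [best] + [j for j in sorted(alive)
                            if j != best and rmsd[best][j] <= cutoff]
        clusters.append(sorted(members))
        alive -= set(members)
    clusters.sort(key=lambda m: (-len(m), m[0]))
    return clusters
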