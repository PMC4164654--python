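"""Independent brute-force oracles used by the tests.

Everything here is deliberately written with plain Python loops and
collections, independent of the package's vectorized implementations.
"""

from __future__ import annotations

import math
from collections import Counter


def plain_mutual_information(x, y) -> float:
    """Plug-in MI in bits via explicit summation over the contingency table."""
    n = len(x)
    joint = Counter(zip(x, y))
    px = Counter(x)
    py = Counter(y)
    mi = 0.0
    for (a, b), c in joint.items():
        pab = c / n
        mi += pab * math.log2(pab * n * n / (px[a] * py[b]))
    return mi


def plain_mrmr_order(columns, labels) -> list[int]:
    """Greedy mRMR-MID ordering by exhaustive evaluation of every step.

    ``columns`` is a list of equal-length sequences of categorical codes.
    Returns the feature indices in rank order; ties go to the smaller index.
    """
    p = len(columns)
    relevance = [plain_mutual_information(col, labels) for col in columns]
    selected: list[int] = []
    remaining = list(range(p))
    while remaining:
        best_j, best_score = None, None
        for j in remaining:
            if selected:
                red = sum(
                    plain_mutual_information(columns[j], columns[s]) for s in selected
                ) / len(selected)
            else:
                red = 0.0
            score = relevance[j] - red
            if best_score is None or score > best_score + 1e-12:
                best_j, best_score = j, score
        selected.append(best_j)
        remaining.remove(best_j)
    return selected
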