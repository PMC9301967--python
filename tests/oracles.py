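"""Independent reference implementations used to validate the library.

These deliberately use the naive definitions (exponential recursion,
explicit window enumeration) rather than the optimized algorithms under
test.
"""

from functools import lru_cache


def brute_force_edit_distance(a: str, b: str) -> int:
    """Edit distance straight from the recursive definition."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == len(a):
            return len(b) - j
        if j == len(b):
            return len(a) - i
        return min(
            rec(i + 1, j) + 1,
            rec(i, j + 1) + 1,
            rec(i + 1, j + 1) + (a[i] != b[j]),
        )

    return rec(0, 0)


def all_windows_partial_ratio(a: str, b: str) -> float:
    """Explicit maximization over every equal-length window of the longer
    sequence, scoring each window with the brute-force edit distance."""
    short, long = (a, b) if len(a) <= len(b) else (b, a)
    w = len(short)
    return max(
        1.0 - brute_force_edit_distance(short, long[i : i + w]) / max(w, 1)
        for i in range(len(long) - w + 1)
    )


def random_peptides(rng, n, max_len, min_len=0):
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    return [
        "".join(rng.choice(aas, size=rng.integers(min_len, max_len + 1)))
        for _ in range(n)
    ]
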