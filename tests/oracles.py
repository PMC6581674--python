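"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check: the aligner
oracle is a plain Gotoh dynamic program, and the tetramer oracle counts
4-mers with a dict, one position at a time.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

NEG = float("-inf")


def gotoh_identity(
    a: str,
    b: str,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = -12.0,
    gap_extend: float = -3.0,
) -> tuple[float, float]:
    """Affine-gap global alignment with free terminal gaps.

    Returns (score, identity_pct) where identity is counted over
    non-terminal columns of a traceback alignment (internal gap columns
    count as non-identical). A gap of length L costs
    gap_open + (L-1)*gap_extend.
    """
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (consumes a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (consumes b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = 0.0  # free leading gap
    for j in range(1, m + 1):
        Y[0, j] = 0.0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend,
                          X[i, j - 1] + gap_open)
    cells = [max(M[i, m], X[i, m], Y[i, m]) for i in range(n + 1)]
    cells += [max(M[n, j], X[n, j], Y[n, j]) for j in range(m + 1)]
    score = max(cells)

    # end cell for traceback: prefer (n, m), else last row/column
    end = None
    if max(M[n, m], X[n, m], Y[n, m]) == score:
        end = (n, m)
    else:
        for i in range(n, -1, -1):
            if max(M[i, m], X[i, m], Y[i, m]) == score:
                end = (i, m)
                break
        if end is None:
            for j in range(m, -1, -1):
                if max(M[n, j], X[n, j], Y[n, j]) == score:
                    end = (n, j)
                    break
    i, j = end
    st = "M" if M[i, j] == score else ("X" if X[i, j] == score else "Y")
    ident = cols = 0
    while i > 0 and j > 0:
        if st == "M":
            s = match if a[i - 1] == b[j - 1] else mismatch
            if a[i - 1] == b[j - 1]:
                ident += 1
            cols += 1
            if M[i - 1, j - 1] + s == M[i, j]:
                st = "M"
            elif X[i - 1, j - 1] + s == M[i, j]:
                st = "X"
            else:
                st = "Y"
            i, j = i - 1, j - 1
        elif st == "X":
            cols += 1
            if M[i - 1, j] + gap_open == X[i, j]:
                st = "M"
            elif X[i - 1, j] + gap_extend == X[i, j]:
                st = "X"
            else:
                st = "Y"
            i -= 1
        else:
            cols += 1
            if M[i, j - 1] + gap_open == Y[i, j]:
                st = "M"
            elif Y[i, j - 1] + gap_extend == Y[i, j]:
                st = "Y"
            else:
                st = "X"
            j -= 1
    return float(score), (100.0 * ident / cols if cols else 0.0)


def naive_tetramer_freqs(sequence: str) -> np.ndarray:
    """Position-by-position 4-mer frequencies (N-containing 4-mers skipped)."""
    counts: Counter[str] = Counter()
    for i in range(len(sequence) - 3):
        kmer = sequence[i : i + 4]
        if set(kmer) <= set("ACGT"):
            counts[kmer] += 1
    vec = np.zeros(256)
    bases = "ACGT"
    for kmer, c in counts.items():
        idx = 0
        for ch in kmer:
            idx = idx * 4 + bases.index(ch)
        vec[idx] = c
    total = vec.sum()
    return vec / total if total else vec


def substitution_pair(rng: np.random.Generator, length: int, rate: float) -> tuple[str, str]:
    """A random sequence and a copy with substitutions at the given rate."""
    a = "".join(rng.choice(list("ACGT"), length))
    b = list(a)
    n_sub = int(round(rate * length))
    for p in rng.choice(length, n_sub, replace=False):
        b[p] = rng.choice([c for c in "ACGT" if c != b[p]])
    return a, "".join(b)
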