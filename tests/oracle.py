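"""Independent brute-force oracles used to cross-check the implementation.

These re-derive expected results from first principles (exhaustive window
checks, pairwise cut-interval intersection) without sharing code paths with
the package's scanning or scenario engine.
"""

from __future__ import annotations

import numpy as np

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "H": "ACT", "D": "AGT", "N": "ACGT",
}

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def window_matches(window: str, pattern: str) -> bool:
    return len(window) == len(pattern) and all(
        b in IUPAC[c] for b, c in zip(window, pattern)
    )


def brute_scan(seq: str, pattern: str) -> list[tuple[int, str]]:
    """All (start, strand) matches by exhaustive window check, both strands."""
    k = len(pattern)
    out = []
    for i in range(len(seq) - k + 1):
        if window_matches(seq[i : i + k], pattern):
            out.append((i, "+"))
    for i in range(len(seq) - k + 1):
        if window_matches(rc(seq[i : i + k]), pattern):
            out.append((i, "-"))
    return out


def brute_cnnr_loci(seq: str) -> list[tuple[int, str]]:
    """(C position, strand) of every CNNR occurrence, both strands."""
    out = []
    for start, strand in brute_scan(seq, "CNNR"):
        out.append((start, "+") if strand == "+" else (start + 3, "-"))
    return sorted(out)


def brute_two_way_fragments(
    seq: str, methylated: set[tuple[int, str]] | None = None
) -> set[tuple[int, int, str]]:
    """Two-way cleavage products by pairwise cut intersection.

    For every (minus-strand mC q, plus-strand mC p) pair the released
    product spans [q-16, p+17).  The pair is two-way (E for 1 <= q-p <= 15,
    F for q < p); the product survives only when both double-strand break
    windows fit the chromosome and no other methylated site's break window
    touches the product's open interior.

    Returns {(start, end, scenario)}.
    """
    loci = brute_cnnr_loci(seq)
    if methylated is not None:
        loci = [l for l in loci if l in methylated]
    L = len(seq)

    def break_window(pos: int, strand: str) -> tuple[int, int] | None:
        if strand == "+":
            lo, hi = pos + 13, pos + 17
            return (lo, hi) if hi <= L else None
        lo, hi = pos - 16, pos - 12
        return (lo, hi) if lo >= 0 else None

    windows = []
    for pos, strand in loci:
        w = break_window(pos, strand)
        if w is not None:
            windows.append((w[0], w[1], pos, strand))
    lows = np.array([w[0] for w in windows])
    highs = np.array([w[1] for w in windows])

    def invaded(start: int, end: int, own: set[tuple[int, str]]) -> bool:
        mask = (lows < end) & (highs > start)
        for idx in np.nonzero(mask)[0]:
            if (windows[idx][2], windows[idx][3]) not in own:
                return True
        return False

    plus = [(pos, strand) for pos, strand in loci if strand == "+"]
    minus = [(pos, strand) for pos, strand in loci if strand == "-"]
    positions = sorted(pos for pos, _ in loci)
    out: set[tuple[int, int, str]] = set()
    for q, _ in minus:
        if break_window(q, "-") is None:
            continue
        for p, _ in plus:
            if break_window(p, "+") is None:
                continue
            d = q - p
            if 1 <= d <= 15:
                scen = "E"
            elif d <= -1:
                scen = "F"
            else:
                continue
            start, end = q - 16, p + 17
            if scen == "F":
                # distant pairs are always invaded; skip the quadratic blowup
                between = [x for x in positions if q < x < p]
                if between:
                    continue
            if not invaded(start, end, {(p, "+"), (q, "-")}):
                out.add((start, end, scen))
    return out


def brute_count_occurrences(seq: str, sub: str) -> int:
    """Overlapping occurrence count by exhaustive comparison."""
    return sum(seq[i : i + len(sub)] == sub for i in range(len(seq) - len(sub) + 1))
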