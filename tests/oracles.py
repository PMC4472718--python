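"""Independent brute-force oracles used by the test suite.

Each oracle re-derives the quantity from first principles with its own
formulation and its own constants, deliberately sharing no code with the
package: dimer scores slide one strand against the *reversed* other strand,
the hairpin oracle enumerates every (start, end, stem-length) triple, and
the binding-site oracle is a plain sliding-window comparison.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _paired(x: str, y: str) -> bool:
    return _COMP[x] == y


def oracle_dimer_any(a: str, b: str) -> int:
    """Max WC pair count over ungapped antiparallel alignments: slide ``a``
    along the reverse of ``b`` and count complementary facing bases."""
    br = b[::-1]
    best = 0
    for shift in range(-(len(br) - 1), len(a)):
        n = 0
        for i, ch in enumerate(br):
            j = shift + i
            if 0 <= j < len(a) and _paired(a[j], ch):
                n += 1
        best = max(best, n)
    return best


def oracle_self_any(s: str) -> int:
    return oracle_dimer_any(s, s)


def oracle_self_end3(s: str) -> int:
    """3'-anchored variant: only shifts where the 3'-terminal base of the
    first copy faces a base of the second copy."""
    br = s[::-1]
    best = 0
    for shift in range(0, len(s)):  # 3' base inside overlap iff shift >= 0
        n = 0
        for i, ch in enumerate(br):
            j = shift + i
            if 0 <= j < len(s) and _paired(s[j], ch):
                n += 1
        best = max(best, n)
    return best


# unified nearest-neighbor dH (kcal/mol) / dS (cal/mol/K) stack table,
# independent literal copy
_NN_DH_DS = {
    "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
_LOOP = {
    3: 3.5, 4: 3.5, 5: 3.3, 6: 4.0, 7: 4.2, 8: 4.3, 9: 4.5, 10: 4.6,
    12: 5.0, 14: 5.1, 16: 5.3, 18: 5.5, 20: 5.7, 25: 6.1, 30: 6.3,
}


def _oracle_stack_dg(x: str, y: str) -> float:
    step = x + y
    if step not in _NN_DH_DS:
        step = _COMP[y] + _COMP[x]  # read the other strand 5'->3'
    dh, ds = _NN_DH_DS[step]
    return dh - 310.15 * ds / 1000.0


def _oracle_loop(n: int) -> float:
    import math

    if n in _LOOP:
        return _LOOP[n]
    if n > 30:
        return _LOOP[30] + 1.75 * 0.0019872 * 310.15 * math.log(n / 30.0)
    ks = sorted(_LOOP)
    for lo, hi in zip(ks, ks[1:]):
        if lo < n < hi:
            return _LOOP[lo] + (n - lo) / (hi - lo) * (_LOOP[hi] - _LOOP[lo])
    raise AssertionError(n)


def oracle_hairpin(seq: str, min_loop: int = 3) -> Optional[float]:
    """Exhaustive stem-loop enumeration over every (i, j, p) partition."""
    n = len(seq)
    best = None
    for i in range(n):
        for j in range(i + 1, n):
            max_p = (j - i + 1 - min_loop) // 2
            for p in range(2, max_p + 1):
                if any(not _paired(seq[i + k], seq[j - k]) for k in range(p)):
                    continue
                dg = sum(
                    _oracle_stack_dg(seq[i + k], seq[i + k + 1])
                    for k in range(p - 1)
                ) + _oracle_loop(j - i + 1 - 2 * p)
                if best is None or dg < best:
                    best = dg
    if best is None or best >= 0:
        return None
    return best


def oracle_find_sites(
    oligo_seq: str, template_seq: str, max_mm: int, clamp3: int
) -> List[Tuple[str, int, int]]:
    """Naive sliding-window scan; returns (strand, start, mismatches),
    1-based starts, for a linear template."""
    out = []
    n = len(oligo_seq)
    rc = "".join(_COMP[c] for c in reversed(oligo_seq))
    for pos in range(len(template_seq) - n + 1):
        win = template_seq[pos : pos + n]
        mm = sum(a != b for a, b in zip(oligo_seq, win))
        # plus strand: 3' clamp is the right end of the window
        if mm <= max_mm and sum(
            a != b for a, b in zip(oligo_seq[n - clamp3 :], win[n - clamp3 :])
        ) == 0:
            out.append(("+", pos + 1, mm))
        mm = sum(a != b for a, b in zip(rc, win))
        # minus strand: oligo 3' end faces the left end of the window
        if mm <= max_mm and sum(
            a != b for a, b in zip(rc[:clamp3], win[:clamp3])
        ) == 0:
            out.append(("-", pos + 1, mm))
    return out
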