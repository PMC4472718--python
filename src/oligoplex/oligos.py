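"""Oligonucleotide primitives: sequence utilities, nearest-neighbor melting
temperature, self/cross-complementarity scores and a stem-loop hairpin model.

The duplex-stability scores used throughout the panel checks are transparent
whole-base-pair counts over ungapped antiparallel alignments: in an
antiparallel duplex base ``i`` of the first strand faces base ``j`` of the
second whenever ``i + j`` is constant, so every alignment is indexed by that
constant and scored by its number of Watson-Crick pairs.  G:T wobbles never
count.  This is deliberately simpler than Primer3's weighted alignment score;
the two agree on what "self-complementary" means but not numerically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

from Bio.SeqUtils import MeltingTemp as _mt

__all__ = [
    "Oligo",
    "OligoReport",
    "DyeSpec",
    "revcomp",
    "gc_content",
    "nn_tm",
    "self_any_score",
    "self_end3_score",
    "cross_dimer_score",
    "hairpin_dg",
    "oligo_report",
    "DnaError",
]

_DNA = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_PAIRS = frozenset({("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")})

Role = Literal["forward", "reverse", "probe"]


class DnaError(ValueError):
    """Raised for malformed DNA input (bad alphabet, unsupported length)."""


def _check_dna(seq: str, *, min_len: int = 1) -> str:
    if not isinstance(seq, str):
        raise DnaError(f"sequence must be a string, got {type(seq).__name__}")
    s = seq.upper()
    if len(s) < min_len:
        raise DnaError(f"sequence shorter than {min_len} nt: {seq!r}")
    bad = set(s) - _DNA
    if bad:
        raise DnaError(f"non-DNA characters {sorted(bad)} in {seq!r}")
    return s


def revcomp(seq: str) -> str:
    """Reverse complement of a strict-ACGT sequence."""
    return _check_dna(seq)[::-1].translate(_COMPLEMENT)


def gc_content(seq: str) -> float:
    """G+C percentage (0-100) of a non-empty DNA sequence."""
    s = _check_dna(seq)
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def nn_tm(
    seq: str,
    oligo_conc: float = 50e-9,
    monovalent: float = 50e-3,
    divalent: float = 1.5e-3,
    dntp: float = 0.6e-3,
) -> float:
    """Duplex melting temperature (degC) from unified nearest-neighbor
    thermodynamics.

    Parameters are molar concentrations.  Defaults emulate the reaction
    conditions of a typical primer-design run: 50 nM oligo, 50 mM monovalent
    cation, 1.5 mM Mg2+ and 0.6 mM total dNTP, with the Owczarzy divalent
    correction.  Deterministic for fixed inputs.
    """
    s = _check_dna(seq)
    if len(s) < 8:
        raise DnaError(f"nearest-neighbor Tm needs >= 8 nt, got {len(s)}")
    return float(
        _mt.Tm_NN(
            s,
            selfcomp=(s == revcomp(s)),
            nn_table=_mt.DNA_NN3,
            dnac1=oligo_conc * 1e9,
            dnac2=0,
            Na=monovalent * 1e3,
            Mg=divalent * 1e3,
            dNTPs=dntp * 1e3,
            saltcorr=7,
        )
    )


def _alignment_pairs(a: str, b: str, c: int) -> int:
    """WC pair count for the antiparallel alignment where a[i] faces b[c-i]."""
    lo = max(0, c - len(b) + 1)
    hi = min(len(a) - 1, c)
    n = 0
    for i in range(lo, hi + 1):
        if (a[i], b[c - i]) in _PAIRS:
            n += 1
    return n


def cross_dimer_score(a: str, b: str) -> int:
    """Maximum Watson-Crick pair count over all ungapped antiparallel
    alignments of ``a`` against ``b``.  Symmetric in its arguments."""
    sa, sb = _check_dna(a), _check_dna(b)
    return max(_alignment_pairs(sa, sb, c) for c in range(len(sa) + len(sb) - 1))


def self_any_score(seq: str) -> int:
    """Self-dimer score: best antiparallel alignment of the oligo against a
    second copy of itself."""
    return cross_dimer_score(seq, seq)


def self_end3_score(seq: str) -> int:
    """3'-anchored self-dimer score.

    Only alignments in which the 3'-terminal base of one copy lies inside the
    duplex overlap are considered (``c >= len - 1`` in the antiparallel
    indexing), so the result never exceeds :func:`self_any_score`.
    """
    s = _check_dna(seq)
    n = len(s)
    return max(_alignment_pairs(s, s, c) for c in range(n - 1, 2 * n - 1))


# dG37 stacking energies (kcal/mol) derived from the unified NN dH/dS table;
# computed once at import from the same table nn_tm uses.
def _dg37_table() -> dict:
    out = {}
    for key, (dh, ds) in _mt.DNA_NN3.items():
        out[key] = dh - 310.15 * ds / 1000.0
    return out


_DG37 = _dg37_table()

# Hairpin-loop closure penalties dG37 (kcal/mol) by loop length; values
# interpolated between tabulated sizes, Jacobson-Stockmayer extrapolated
# beyond 30 nt.
_LOOP_DG = {
    3: 3.5, 4: 3.5, 5: 3.3, 6: 4.0, 7: 4.2, 8: 4.3, 9: 4.5, 10: 4.6,
    12: 5.0, 14: 5.1, 16: 5.3, 18: 5.5, 20: 5.7, 25: 6.1, 30: 6.3,
}
_RT37 = 0.0019872 * 310.15


def _loop_penalty(n: int) -> float:
    if n in _LOOP_DG:
        return _LOOP_DG[n]
    if n > 30:
        return _LOOP_DG[30] + 1.75 * _RT37 * math.log(n / 30.0)
    ks = sorted(_LOOP_DG)
    for lo, hi in zip(ks, ks[1:]):
        if lo < n < hi:
            f = (n - lo) / (hi - lo)
            return _LOOP_DG[lo] + f * (_LOOP_DG[hi] - _LOOP_DG[lo])
    raise AssertionError(f"loop length {n} outside table")


def _stack_dg(x: str, y: str) -> float:
    """dG37 of the dimer step 5'-xy-3' paired to its complement."""
    key = f"{x}{y}/{x.translate(_COMPLEMENT)}{y.translate(_COMPLEMENT)}"
    if key in _DG37:
        return _DG37[key]
    return _DG37[key[::-1]]


def hairpin_dg(seq: str, min_loop: int = 3) -> Optional[float]:
    """Most favorable single stem-loop free energy (kcal/mol, dG37) of the
    oligo, or ``None`` when no stem of >= 2 pairs folds with negative energy.

    Every stem is enumerated exhaustively: pairs ``(i+k, j-k)`` for a stem of
    ``p`` complementary pairs closing a loop of ``j - i + 1 - 2p >= min_loop``
    unpaired bases.  Energy is the sum of nearest-neighbor stacking terms over
    the stem plus a loop-length closure penalty.  This is a deliberately
    simple surrogate for full secondary-structure folding: one stem, no
    bulges, no dangling ends.
    """
    if min_loop < 3:
        raise ValueError("min_loop must be >= 3")
    s = _check_dna(seq)
    n = len(s)
    best: Optional[float] = None
    for i in range(n):
        for j in range(i + 2 * 2 + min_loop - 1, n):
            # grow the stem inward from the closing pair (i, j)
            if (s[i], s[j]) not in _PAIRS:
                continue
            stack = 0.0
            p = 1
            while True:
                ii, jj = i + p, j - p
                if jj - ii - 1 < min_loop or (s[ii], s[jj]) not in _PAIRS:
                    break
                stack += _stack_dg(s[ii - 1], s[ii])
                p += 1
                if p >= 2:
                    dg = stack + _loop_penalty(j - i + 1 - 2 * p)
                    if best is None or dg < best:
                        best = dg
    if best is None or best >= 0:
        return None
    return best


@dataclass(frozen=True)
class Oligo:
    """A named directional oligonucleotide, written 5'->3'.

    Probes are stored 5'->3' exactly like primers; the role only affects how
    downstream placement rules treat the sequence.
    """

    name: str
    sequence: str
    role: Role = "forward"

    def __post_init__(self):
        object.__setattr__(self, "sequence", _check_dna(self.sequence))
        if not (10 <= len(self.sequence) <= 60):
            raise DnaError(
                f"{self.name}: oligo length {len(self.sequence)} outside 10-60 nt"
            )
        if self.role not in ("forward", "reverse", "probe"):
            raise ValueError(f"{self.name}: unknown role {self.role!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def revcomp(self) -> str:
        return revcomp(self.sequence)

    @property
    def end3_seed(self) -> str:
        """3'-terminal 8-mer, the extension-critical seed."""
        return self.sequence[-8:]


@dataclass(frozen=True)
class OligoReport:
    """Per-oligo property report: length, GC%, Tm, self-complementarity
    scores and the hairpin stem-loop dG (absent when nothing folds)."""

    name: str
    length: int
    gc: float
    tm: float
    self_any: int
    self_end3: int
    hairpin_dg: Optional[float]


def oligo_report(oligo: Oligo, **tm_kwargs) -> OligoReport:
    s = oligo.sequence
    return OligoReport(
        name=oligo.name,
        length=len(s),
        gc=round(gc_content(s), 1),
        tm=round(nn_tm(s, **tm_kwargs), 1),
        self_any=self_any_score(s),
        self_end3=self_end3_score(s),
        hairpin_dg=hairpin_dg(s),
    )


@dataclass(frozen=True)
class DyeSpec:
    """A reporter fluorophore: excitation/emission maxima and its quencher."""

    dye_name: str
    excitation: float
    emission: float
    quencher: str = ""

    def __post_init__(self):
        if not self.emission > self.excitation:
            raise ValueError(
                f"{self.dye_name}: emission {self.emission} must exceed "
                f"excitation {self.excitation} (Stokes shift)"
            )
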