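"""In-silico PCR: primer binding-site search, amplicon prediction, multiplex
specificity matrices, probe placement and a virtual gel.

Coordinates are 1-based inclusive on the plus strand.  An amplicon spans both
primer footprints, so its length is ``reverse_hit.end - forward_hit.start + 1``
— the same arithmetic that makes a 115 bp product out of a forward start and a
reverse end 115 bases apart inclusive.  Circular templates are searched on the
doubled sequence with start positions restricted to the first copy, which
finds wrap-around sites exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .oligos import Oligo, revcomp, _check_dna
from .panel import Panel, PrimerPair

__all__ = [
    "Template",
    "PrimerHit",
    "Amplicon",
    "ProbeSite",
    "AmbiguityError",
    "find_binding_sites",
    "predict_amplicons",
    "simulate_multiplex",
    "SpecificityMatrix",
    "locate_probe",
    "virtual_gel",
    "GelReport",
]


class AmbiguityError(ValueError):
    """Raised when a probe has multiple interior sites in one amplicon."""


@dataclass(frozen=True)
class Template:
    """A DNA record to search: genomic fragment, plasmid, or fixture."""

    id: str
    sequence: str
    topology: str = "linear"
    description: str = ""

    def __post_init__(self):
        object.__setattr__(self, "sequence", _check_dna(self.sequence))
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"{self.id}: topology must be linear or circular")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def search_space(self) -> str:
        if self.topology == "circular":
            return self.sequence + self.sequence
        return self.sequence


@dataclass(frozen=True)
class PrimerHit:
    template_id: str
    oligo_name: str
    strand: str  # "+" | "-"
    start: int  # 1-based inclusive, plus strand
    end: int
    mismatches: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if self.start > self.end:
            raise ValueError("start must be <= end")


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    assay_name: str
    forward_hit: PrimerHit
    reverse_hit: PrimerHit
    length: int
    sequence: str


@dataclass(frozen=True)
class ProbeSite:
    strand: str
    start: int  # 1-based within the amplicon
    end: int


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def find_binding_sites(
    oligo: Oligo,
    template: Template,
    max_mismatch: int = 0,
    clamp3: int = 3,
) -> List[PrimerHit]:
    """All plus- and minus-strand annealing sites of ``oligo`` on ``template``
    with at most ``max_mismatch`` mismatches overall and none within the
    3'-terminal ``clamp3`` bases.  Sorted by start position."""
    if clamp3 > len(oligo):
        raise ValueError("clamp3 cannot exceed oligo length")
    space = template.search_space
    n, L = len(oligo), len(template.sequence)
    hits: List[PrimerHit] = []
    if n > len(space):
        return hits
    fwd = oligo.sequence
    rc = revcomp(fwd)
    for pos in range(len(space) - n + 1):
        if pos >= L:  # circular second copy: starts restricted to first copy
            break
        window = space[pos : pos + n]
        # plus strand: oligo reads 5'->3' left-to-right; 3' end is the right end
        mm = _mismatches(fwd, window)
        if mm <= max_mismatch and (
            clamp3 == 0 or fwd[n - clamp3 :] == window[n - clamp3 :]
        ):
            hits.append(
                PrimerHit(template.id, oligo.name, "+", pos + 1, pos + n, mm)
            )
        # minus strand: revcomp(oligo) matches plus strand; the oligo 3' end
        # maps to the left end of the window
        mm = _mismatches(rc, window)
        if mm <= max_mismatch and (
            clamp3 == 0 or rc[:clamp3] == window[:clamp3]
        ):
            hits.append(
                PrimerHit(template.id, oligo.name, "-", pos + 1, pos + n, mm)
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def predict_amplicons(
    pair: PrimerPair,
    template: Template,
    max_mismatch: int = 0,
    clamp3: int = 3,
    max_len: int = 3000,
) -> List[Amplicon]:
    """Every productive forward-plus / reverse-minus hit pairing with the
    forward site upstream and product length <= ``max_len``, sorted by
    length."""
    if max_len < len(pair.fwd) + len(pair.rev):
        raise ValueError("max_len below combined primer length")
    fhits = [
        h
        for h in find_binding_sites(pair.fwd, template, max_mismatch, clamp3)
        if h.strand == "+"
    ]
    rhits = [
        h
        for h in find_binding_sites(pair.rev, template, max_mismatch, clamp3)
        if h.strand == "-"
    ]
    space = template.search_space
    out: List[Amplicon] = []
    L = len(template.sequence)
    for fh in fhits:
        for rh in rhits:
            if fh.start < rh.start:
                rh_end = rh.end
            elif template.topology == "circular":
                # wrap-around product: reverse site read in the second copy
                rh_end = rh.end + L
            else:
                continue
            length = rh_end - fh.start + 1
            if length < len(pair.fwd) + len(pair.rev) or length > max_len:
                continue
            if rh_end > len(space):
                continue
            rh_out = rh
            if rh_end != rh.end:  # shift wrapped hit into doubled coordinates
                rh_out = PrimerHit(
                    rh.template_id, rh.oligo_name, "-",
                    rh.start + L, rh.end + L, rh.mismatches,
                )
            out.append(
                Amplicon(
                    template_id=template.id,
                    assay_name=pair.name,
                    forward_hit=fh,
                    reverse_hit=rh_out,
                    length=length,
                    sequence=space[fh.start - 1 : rh_end],
                )
            )
    out.sort(key=lambda a: (a.length, a.forward_hit.start))
    return out


@dataclass
class SpecificityMatrix:
    """Cross-product of assay primer pairs against templates, plus the
    cross-assay (mispriming) pairings of forward and reverse oligos drawn
    from different targets."""

    entries: Dict[Tuple[str, str], List[Amplicon]]
    cross_entries: Dict[Tuple[str, str], List[Amplicon]]
    pair_names: List[str]
    template_ids: List[str]

    def amplicons(self, pair_name: str, template_id: str) -> List[Amplicon]:
        return self.entries.get((pair_name, template_id), [])

    def is_diagonal(self, target_of_template: Dict[str, str]) -> bool:
        """True iff every pair amplifies exactly the templates mapped to its
        own target and nothing else (cross-pairings included)."""
        for (pname, tid), amps in self.entries.items():
            target = pname.split(":")[0]
            expected = target_of_template.get(tid) == target
            if expected and not amps:
                return False
            if not expected and amps:
                return False
        return not any(self.cross_entries.values())

    def to_tsv(self) -> str:
        lines = ["\t".join(["pair"] + self.template_ids)]
        for p in self.pair_names:
            row = [p] + [
                ",".join(str(a.length) for a in self.amplicons(p, t)) or "-"
                for t in self.template_ids
            ]
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


def simulate_multiplex(
    panel: Panel,
    templates: Sequence[Template],
    max_mismatch: int = 0,
    clamp3: int = 3,
    max_len: int = 3000,
) -> SpecificityMatrix:
    if not panel.assays or not templates:
        raise ValueError("need a non-empty panel and template list")
    entries: Dict[Tuple[str, str], List[Amplicon]] = {}
    pairs: List[PrimerPair] = []
    for assay in panel:
        pairs.extend(assay.pairs())
    for pair in pairs:
        for t in templates:
            entries[(pair.name, t.id)] = predict_amplicons(
                pair, t, max_mismatch, clamp3, max_len
            )
    cross: Dict[Tuple[str, str], List[Amplicon]] = {}
    for pa in pairs:
        for pb in pairs:
            if pa.name.split(":")[0] == pb.name.split(":")[0]:
                continue
            xp = PrimerPair(f"{pa.fwd.name}x{pb.rev.name}", pa.fwd, pb.rev)
            for t in templates:
                amps = predict_amplicons(xp, t, max_mismatch, clamp3, max_len)
                if amps:
                    cross[(xp.name, t.id)] = amps
    return SpecificityMatrix(
        entries=entries,
        cross_entries=cross,
        pair_names=[p.name for p in pairs],
        template_ids=[t.id for t in templates],
    )


def locate_probe(
    probe: Oligo, amplicon: Amplicon, allow_overlap: bool = False
) -> Optional[ProbeSite]:
    """Exact-match site of the probe strictly inside the amplicon, on either
    strand; ``None`` when absent.  With ``allow_overlap`` false the site must
    not intersect either primer footprint.  Multiple qualifying interior
    sites raise :class:`AmbiguityError`."""
    seq = amplicon.sequence
    n = len(probe)
    flen = amplicon.forward_hit.end - amplicon.forward_hit.start + 1
    rlen = amplicon.reverse_hit.end - amplicon.reverse_hit.start + 1
    sites: List[ProbeSite] = []
    for strand, query in (("+", probe.sequence), ("-", revcomp(probe.sequence))):
        pos = seq.find(query)
        while pos != -1:
            start, end = pos + 1, pos + n
            interior = start > 1 and end < len(seq)
            clear = start > flen and end <= len(seq) - rlen
            if interior and (allow_overlap or clear):
                sites.append(ProbeSite(strand, start, end))
            pos = seq.find(query, pos + 1)
    if not sites:
        return None
    if len(sites) > 1:
        raise AmbiguityError(
            f"probe {probe.name} has {len(sites)} interior sites in "
            f"{amplicon.assay_name} amplicon"
        )
    return sites[0]


@dataclass(frozen=True)
class GelLane:
    size: int
    label: str = ""


@dataclass
class GelReport:
    """Ordered band sizes with discriminability flags."""

    sizes: List[int]
    labels: List[str]
    min_separation: int
    indistinct_pairs: List[Tuple[int, int]] = field(default_factory=list)

    @property
    def all_distinguishable(self) -> bool:
        return not self.indistinct_pairs

    def to_text(self) -> str:
        lines = [f"virtual gel (min separation {self.min_separation} bp)"]
        for s, lab in zip(self.sizes, self.labels):
            flag = any(s in p for p in self.indistinct_pairs)
            lines.append(f"  {s:>5d} bp  {lab}{'  [indistinct]' if flag else ''}")
        return "\n".join(lines) + "\n"


def virtual_gel(
    amplicons: Sequence, min_separation: int = 20
) -> GelReport:
    """Size-sort amplicons (descending, as run on a gel) and flag adjacent
    bands closer than ``min_separation``.  Accepts Amplicons or bare sizes."""
    if min_separation < 0:
        raise ValueError("min_separation must be >= 0")
    items: List[Tuple[int, str]] = []
    for a in amplicons:
        if isinstance(a, Amplicon):
            items.append((a.length, a.assay_name))
        else:
            items.append((int(a), ""))
    items.sort(key=lambda x: -x[0])
    sizes = [s for s, _ in items]
    labels = [l for _, l in items]
    bad = [
        (hi, lo)
        for hi, lo in zip(sizes, sizes[1:])
        if hi - lo < min_separation
    ]
    return GelReport(
        sizes=sizes, labels=labels, min_separation=min_separation,
        indistinct_pairs=bad,
    )
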