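"""Multi-target artificial positive control (APC) design.

An APC is a synthetic insert carrying, for every assay in a panel, a tandem
block of priming sites: the endpoint (outer) forward primer, the qPCR
(inner) forward primer, the hydrolysis probe site, the inner reverse and the
outer reverse primer — reverse elements embedded as reverse complements so
each primer anneals in productive orientation.  Spacer DNA between elements
is tuned so every primer pair amplifies exactly its requested product size,
and each block carries a short random barcode so every APC amplicon has a
unique identifiable internal sequence distinguishable from the genomic
product of the same primers.

Design proceeds in four steps mirroring how such constructs are built for
synthesis: plan block coordinates, synthesize screened spacers, assemble,
verify by in-silico PCR.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .oligos import Oligo, revcomp
from .panel import AssaySet, Panel, PrimerPair
from .ispcr import Template, locate_probe, predict_amplicons

__all__ = [
    "ApcDesignError",
    "ElementPlan",
    "ApcBlockPlan",
    "ConstructPlan",
    "Feature",
    "ApcConstruct",
    "VerificationReport",
    "plan_blocks",
    "plan_construct",
    "synthesize_spacers",
    "assemble_construct",
    "verify_construct",
    "design_apc",
]

MIN_SPACER = 2          # nt between adjacent functional elements
MIN_INTER_SPACER = 10   # nt between blocks
BARCODE_LEN = 8
BARCODE_MIN_HAMMING = 4
SEED_KMER = 8           # 3'-terminal seed screened out of spacers
MAX_OLIGO_MATCH = 12    # spacers must not share a >= 12 nt run with any oligo


class ApcDesignError(ValueError):
    """Raised for infeasible size requests or failed assembly/synthesis."""


@dataclass
class ElementPlan:
    """One laid-out element of a block: a primer/probe footprint or a spacer
    slot awaiting synthesis."""

    name: str
    kind: str           # primer | probe | spacer
    strand: str         # "+" | "-" (spacers are "+")
    length: int
    sequence: Optional[str] = None  # None until synthesized (spacers)
    carries_barcode: bool = False


@dataclass
class ApcBlockPlan:
    """Coordinate plan for one target's nested assay block."""

    target: str
    elements: List[ElementPlan]
    outer_size: Optional[int]   # endpoint product size on the APC
    inner_size: Optional[int]   # qPCR product size on the APC
    genomic_sizes: Dict[str, Optional[int]] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return sum(e.length for e in self.elements)


@dataclass
class ConstructPlan:
    blocks: List[ApcBlockPlan]
    inter_spacer_lens: List[int]
    adapters: Tuple[str, str] = ("", "")
    inter_sequences: Optional[List[str]] = None


@dataclass(frozen=True)
class Feature:
    name: str
    type: str    # primer_bind | misc_binding | misc_feature
    strand: str
    start: int   # 1-based inclusive on the construct
    end: int


@dataclass
class ApcConstruct:
    sequence: str
    features: List[Feature]
    blocks: List[ApcBlockPlan]
    adapters: Tuple[str, str]
    name: str = "apc"

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def template(self) -> Template:
        return Template(self.name, self.sequence, "linear", "artificial positive control")

    def designed_sizes(self) -> Dict[str, Dict[str, Optional[int]]]:
        return {
            b.target: {"endpoint": b.outer_size, "qpcr": b.inner_size}
            for b in self.blocks
        }


# ---------------------------------------------------------------------------
# planning

def _layout_assay(
    assay: AssaySet,
    outer_size: Optional[int],
    inner_size: Optional[int],
    min_spacer: int,
) -> List[ElementPlan]:
    """Compute the ordered element chain and spacer lengths for one block."""
    t = assay.target
    ep, qp = assay.endpoint_pair, assay.qpcr_pair
    shared_pair = (
        ep is not None
        and qp is not None
        and ep.fwd.name == qp.fwd.name
        and ep.rev.name == qp.rev.name
    )

    def prim(o: Oligo, strand: str) -> ElementPlan:
        seq = o.sequence if strand == "+" else revcomp(o.sequence)
        return ElementPlan(o.name, "primer", strand, len(o), seq)

    def probe_el() -> ElementPlan:
        p = assay.probe
        return ElementPlan(p.name, "probe", "+", len(p), p.sequence)

    def spacer(idx: int, length: int) -> ElementPlan:
        if length < min_spacer:
            raise ApcDesignError(
                f"{t}: requested size leaves spacer {idx} below {min_spacer} nt"
            )
        return ElementPlan(f"{t}_spacer{idx}", "spacer", "+", length)

    def split(total: int, k: int = 2) -> Tuple[int, int]:
        """Split slack into two spacers, both >= min_spacer, remainder left."""
        a = max(min_spacer, total // 2)
        return a, total - a

    if shared_pair or (ep is None) or (qp is None and assay.probe is not None):
        # single-level block: F [sp P sp] R'
        pair = ep if ep is not None else qp
        size = outer_size if outer_size is not None else inner_size
        if shared_pair and outer_size is not None and inner_size is not None \
                and outer_size != inner_size:
            raise ApcDesignError(
                f"{t}: endpoint and qPCR share both primers but request "
                f"different sizes {outer_size}/{inner_size}"
            )
        if size is None:
            raise ApcDesignError(f"{t}: no size requested")
        if assay.probe is not None:
            core = len(pair.fwd) + len(assay.probe) + len(pair.rev)
            slack = size - core
            if slack < 2 * min_spacer:
                raise ApcDesignError(
                    f"{t}: size {size} infeasible, minimum {core + 2 * min_spacer}"
                )
            s2, s3 = split(slack)
            return [
                prim(pair.fwd, "+"), spacer(1, s2), probe_el(),
                spacer(2, s3), prim(pair.rev, "-"),
            ]
        core = len(pair.fwd) + len(pair.rev)
        slack = size - core
        if slack < min_spacer:
            raise ApcDesignError(
                f"{t}: size {size} infeasible, minimum {core + min_spacer}"
            )
        return [prim(pair.fwd, "+"), spacer(1, slack), prim(pair.rev, "-")]

    if qp is None:
        # endpoint-only, no probe
        core = len(ep.fwd) + len(ep.rev)
        slack = (outer_size or 0) - core
        if outer_size is None:
            raise ApcDesignError(f"{t}: no endpoint size requested")
        if slack < min_spacer:
            raise ApcDesignError(
                f"{t}: size {outer_size} infeasible, minimum {core + min_spacer}"
            )
        return [prim(ep.fwd, "+"), spacer(1, slack), prim(ep.rev, "-")]

    if outer_size is None or inner_size is None:
        raise ApcDesignError(f"{t}: nested block needs both endpoint and qPCR sizes")

    shared_rev = ep.rev.name == qp.rev.name
    shared_fwd = ep.fwd.name == qp.fwd.name

    # When one primer's site is contained inside another element's realized
    # footprint (the pairs overlap in the source gene), nesting would plant a
    # second annealing site inside the outer amplicon and yield a spurious
    # short product; lay the two amplicons side by side instead.
    if not (shared_rev or shared_fwd) and _nested_containment_conflict(assay):
        s1 = outer_size - len(ep.fwd) - len(ep.rev)
        if s1 < min_spacer:
            raise ApcDesignError(
                f"{t}: endpoint size {outer_size} infeasible, minimum "
                f"{len(ep.fwd) + len(ep.rev) + min_spacer}"
            )
        inner_slack_sbs = inner_size - len(qp.fwd) - len(assay.probe) - len(qp.rev)
        if inner_slack_sbs < 2 * min_spacer:
            raise ApcDesignError(f"{t}: qPCR size {inner_size} infeasible")
        s2 = max(min_spacer, inner_slack_sbs // 2)
        s3 = inner_slack_sbs - s2
        return [
            prim(ep.fwd, "+"), spacer(1, s1), prim(ep.rev, "-"),
            ElementPlan(f"{t}_subblock_spacer", "spacer", "+", MIN_INTER_SPACER),
            prim(qp.fwd, "+"), spacer(2, s2), probe_el(), spacer(3, s3),
            prim(qp.rev, "-"),
        ]
    inner_core = len(qp.fwd) + len(assay.probe) + len(qp.rev)
    inner_slack = inner_size - inner_core
    if inner_slack < 2 * min_spacer:
        raise ApcDesignError(
            f"{t}: qPCR size {inner_size} infeasible, minimum "
            f"{inner_core + 2 * min_spacer}"
        )
    s2, s3 = max(min_spacer, inner_slack // 2), None
    s3 = inner_slack - s2
    inner = [
        prim(qp.fwd, "+"), spacer(2, s2), probe_el(), spacer(3, s3),
        prim(qp.rev, "-"),
    ]
    if shared_rev:
        # outer forward upstream; outer shares the inner reverse
        outer_slack = outer_size - inner_size - len(ep.fwd)
        if outer_slack < min_spacer:
            raise ApcDesignError(
                f"{t}: endpoint size {outer_size} infeasible with shared reverse"
            )
        return [prim(ep.fwd, "+"), spacer(1, outer_slack)] + inner
    if shared_fwd:
        outer_slack = outer_size - inner_size - len(ep.rev)
        if outer_slack < min_spacer:
            raise ApcDesignError(
                f"{t}: endpoint size {outer_size} infeasible with shared forward"
            )
        return inner + [spacer(4, outer_slack), prim(ep.rev, "-")]
    outer_slack = outer_size - inner_size - len(ep.fwd) - len(ep.rev)
    if outer_slack < 2 * min_spacer:
        raise ApcDesignError(
            f"{t}: endpoint size {outer_size} infeasible, minimum "
            f"{inner_size + len(ep.fwd) + len(ep.rev) + 2 * min_spacer}"
        )
    s1 = max(min_spacer, outer_slack // 2)
    s4 = outer_slack - s1
    return (
        [prim(ep.fwd, "+"), spacer(1, s1)]
        + inner
        + [spacer(4, s4), prim(ep.rev, "-")]
    )


def _nested_containment_conflict(assay: AssaySet) -> bool:
    """True when any primer of the assay has an exact site (either
    orientation) inside another of the assay's realized element footprints —
    nesting those elements would create extra annealing sites."""
    elems = []
    for o in (assay.endpoint_fwd, assay.qpcr_fwd):
        elems.append((o.name, o.sequence))
    if assay.probe is not None:
        elems.append((assay.probe.name, assay.probe.sequence))
    for o in (assay.qpcr_rev, assay.endpoint_rev):
        elems.append((o.name, revcomp(o.sequence)))
    primers = [
        o for o in (assay.endpoint_fwd, assay.endpoint_rev,
                    assay.qpcr_fwd, assay.qpcr_rev)
    ]
    for o in primers:
        for host_name, host_seq in elems:
            if host_name == o.name:
                continue
            if o.sequence in host_seq or revcomp(o.sequence) in host_seq:
                return True
    return False


def _check_size_conflicts(
    sizes: Dict[str, Dict[str, Optional[int]]],
    min_gap_endpoint: int,
    min_gap_qpcr: int,
) -> None:
    for use, gap in (("endpoint", min_gap_endpoint), ("qpcr", min_gap_qpcr)):
        named = [(t, s[use]) for t, s in sizes.items() if s.get(use) is not None]
        for (ta, sa), (tb, sb) in itertools.combinations(named, 2):
            if sa == sb:
                raise ApcDesignError(
                    f"duplicate {use} size {sa} bp for {ta} and {tb}"
                )
            if abs(sa - sb) < gap:
                raise ApcDesignError(
                    f"{use} sizes {sa} ({ta}) and {sb} ({tb}) closer than "
                    f"{gap} bp"
                )


def _auto_sizes(
    panel: Panel, min_size: int, max_size: int, gap: int = 20
) -> Dict[str, Dict[str, Optional[int]]]:
    """Choose per-assay product sizes automatically.

    qPCR sizes start from the largest minimal feasible inner core and step
    apart by ``gap``; endpoint sizes then build on the chosen inner sizes
    (nested assays cannot be shorter than inner + outer primers) and are
    pushed apart until every pair differs by at least ``gap``.  Assays whose
    endpoint and qPCR readouts share both primers get one common size.
    ``max_size`` is a soft ceiling: feasibility wins over compactness."""
    out: Dict[str, Dict[str, Optional[int]]] = {
        a.target: {"endpoint": None, "qpcr": None} for a in panel
    }
    q = sorted(
        (a for a in panel if a.qpcr_pair is not None), key=lambda a: a.target
    )
    if q:
        base = max(
            len(a.qpcr_fwd) + len(a.probe) + len(a.qpcr_rev) + 2 * MIN_SPACER
            for a in q
        )
        base = max(base, min_size)
        for i, a in enumerate(q):
            out[a.target]["qpcr"] = base + gap * i
    taken: List[int] = []
    free: List[AssaySet] = []
    for a in sorted(
        (a for a in panel if a.endpoint_pair is not None),
        key=lambda a: a.target,
    ):
        shared = (
            a.qpcr_pair is not None
            and a.endpoint_fwd.name == a.qpcr_fwd.name
            and a.endpoint_rev.name == a.qpcr_rev.name
        )
        if shared:
            out[a.target]["endpoint"] = out[a.target]["qpcr"]
            taken.append(out[a.target]["qpcr"])
        else:
            free.append(a)
    for a in free:
        floor = len(a.endpoint_fwd) + len(a.endpoint_rev) + MIN_SPACER
        if a.qpcr_pair is not None:
            inner = out[a.target]["qpcr"]
            if a.endpoint_rev.name == a.qpcr_rev.name:
                floor = inner + len(a.endpoint_fwd) + MIN_SPACER
            elif a.endpoint_fwd.name == a.qpcr_fwd.name:
                floor = inner + len(a.endpoint_rev) + MIN_SPACER
            else:
                floor = (
                    inner + len(a.endpoint_fwd) + len(a.endpoint_rev)
                    + 2 * MIN_SPACER
                )
        size = max(floor, min_size)
        while any(abs(size - t) < gap for t in taken):
            size += gap
        taken.append(size)
        out[a.target]["endpoint"] = size
    return out


def plan_blocks(
    panel: Panel,
    size_requests: "Dict[str, Dict[str, Optional[int]]] | str" = "auto",
    min_spacer: int = MIN_SPACER,
    min_gap_endpoint: int = 20,
    min_gap_qpcr: int = 0,
    auto_range: Tuple[int, int] = (100, 450),
) -> List[ApcBlockPlan]:
    """Per-target coordinate plans hitting each requested amplicon size
    exactly.  ``size_requests`` maps target -> {"endpoint": bp, "qpcr": bp}
    (either may be None); ``"auto"`` spreads sizes to maximize pairwise gaps
    within ``auto_range``."""
    if size_requests == "auto":
        size_requests = _auto_sizes(panel, *auto_range)
    _check_size_conflicts(size_requests, min_gap_endpoint, min_gap_qpcr)
    plans: List[ApcBlockPlan] = []
    for assay in panel:
        req = size_requests.get(assay.target)
        if req is None:
            raise ApcDesignError(f"no size request for {assay.target}")
        outer, inner = req.get("endpoint"), req.get("qpcr")
        elements = _layout_assay(assay, outer, inner, min_spacer)
        # collapse to a single size record for shared-pair blocks
        ep, qp = assay.endpoint_pair, assay.qpcr_pair
        plans.append(
            ApcBlockPlan(
                target=assay.target,
                elements=elements,
                outer_size=outer if ep is not None else None,
                inner_size=inner if qp is not None else None,
                genomic_sizes={
                    "endpoint": assay.genomic_endpoint_size,
                    "qpcr": assay.genomic_qpcr_size,
                },
            )
        )
    return plans


# ---------------------------------------------------------------------------
# cross-product de-confusion

def _designed_size_set(blocks: Sequence[ApcBlockPlan]) -> List[int]:
    out = set()
    for b in blocks:
        for s in (b.outer_size, b.inner_size):
            if s is not None:
                out.add(s)
    return sorted(out)


def _planned_priming_sites(
    blocks: Sequence[ApcBlockPlan],
    inter: Sequence[int],
    panel: Panel,
) -> Tuple[List[Tuple[int, str, int]], List[Tuple[int, str, int]]]:
    """Forward-site starts and reverse-site ends of every panel primer on the
    planned construct, scanned from the fixed-sequence elements (primer and
    probe footprints; spacers are screened and carry no sites).

    Returns ``(fwd_sites, rev_sites)`` as ``(position, target, block_index)``
    tuples; positions are 0-based construct offsets.  The scan sees sites
    contained inside other oligos' footprints, which coordinate-only
    bookkeeping would miss."""
    target_of = {
        o.name: a.target for a in panel for o in a.multiplex_oligos()
    }
    primers = [
        o for a in panel for o in a.multiplex_oligos() if o.role != "probe"
    ]
    fwd_sites: List[Tuple[int, str, int]] = []
    rev_sites: List[Tuple[int, str, int]] = []
    pos = 0
    for k, b in enumerate(blocks):
        for e in b.elements:
            if e.sequence is not None:
                for o in primers:
                    tgt = target_of[o.name]
                    idx = e.sequence.find(o.sequence)
                    while idx != -1:
                        fwd_sites.append((pos + idx, tgt, k))
                        idx = e.sequence.find(o.sequence, idx + 1)
                    rc = revcomp(o.sequence)
                    idx = e.sequence.find(rc)
                    while idx != -1:
                        rev_sites.append((pos + idx + len(rc), tgt, k))
                        idx = e.sequence.find(rc, idx + 1)
            pos += e.length
        if k < len(blocks) - 1:
            pos += inter[k]
    return fwd_sites, rev_sites


def _cross_product_sizes(
    blocks: Sequence[ApcBlockPlan],
    inter: Sequence[int],
    panel: Panel,
) -> List[Tuple[int, int, int]]:
    """(size, i, j) for every convergent cross-target primer pairing on the
    planned construct, blocks i <= j."""
    fwd_sites, rev_sites = _planned_priming_sites(blocks, inter, panel)
    out: List[Tuple[int, int, int]] = []
    for fs, ftgt, i in fwd_sites:
        for re_, rtgt, j in rev_sites:
            if ftgt == rtgt or re_ <= fs:
                continue
            out.append((re_ - fs, i, j))
    return out


def _tune_inter_spacers(
    blocks: Sequence[ApcBlockPlan],
    inter_spacer_len: int,
    min_size_gap: int,
    panel: Panel,
    max_rounds: int = 200,
) -> List[int]:
    """Pad inter-block spacers so no cross-target product size falls within
    ``min_size_gap`` of a designed amplicon size (gel confusability)."""
    inter = [inter_spacer_len] * (len(blocks) - 1)
    designed = _designed_size_set(blocks)
    for _ in range(max_rounds):
        clash = None
        for size, i, j in _cross_product_sizes(blocks, inter, panel):
            if any(abs(size - d) < min_size_gap for d in designed):
                clash = (size, i, j)
                break
        if clash is None:
            return inter
        size, i, j = clash
        if j == i:  # same-block clash: no junction to widen
            raise ApcDesignError(
                f"cross-target product of {size} bp inside one block cannot "
                "be shifted; change the requested sizes"
            )
        # widen the junction just upstream of block j; every product crossing
        # it shifts out of the designed-size window together
        inter[j - 1] += min_size_gap
    raise ApcDesignError("could not de-confuse cross-target product sizes")


def plan_construct(
    blocks: Sequence[ApcBlockPlan],
    panel: Panel,
    inter_spacer_len: int = MIN_INTER_SPACER,
    adapters: Tuple[str, str] = ("", ""),
    min_size_gap: int = 20,
) -> ConstructPlan:
    if not blocks:
        raise ApcDesignError("no blocks to assemble")
    inter = (
        _tune_inter_spacers(blocks, inter_spacer_len, min_size_gap, panel)
        if len(blocks) > 1
        else []
    )
    return ConstructPlan(list(blocks), inter, adapters)


# ---------------------------------------------------------------------------
# spacer synthesis

def _kmers(s: str, k: int):
    for i in range(len(s) - k + 1):
        yield s[i : i + k]


def _screen_sets(panel: Panel) -> Tuple[frozenset, frozenset]:
    """(forbidden 3'-seed k-mers, forbidden long k-mers), both strands."""
    seeds = set()
    longs = set()
    for o in panel.all_oligos():
        for s in (o.sequence, revcomp(o.sequence)):
            seeds.add(s[-SEED_KMER:])
            seeds.add(revcomp(s)[-SEED_KMER:])
            for km in _kmers(s, MAX_OLIGO_MATCH):
                longs.add(km)
    return frozenset(seeds), frozenset(longs)


def _spacer_ok(seq: str, seeds: frozenset, longs: frozenset) -> bool:
    for strand in (seq, revcomp(seq)):
        for km in _kmers(strand, SEED_KMER):
            if km in seeds:
                return False
        for km in _kmers(strand, MAX_OLIGO_MATCH):
            if km in longs:
                return False
    return True


def _balanced_random(rng: np.random.Generator, length: int) -> str:
    """Random DNA with GC held to 40-60% (exactly balanced up to rounding)."""
    n_gc = length // 2 + (int(rng.integers(0, 2)) if length % 2 else 0)
    bases = [str(rng.choice(["G", "C"])) for _ in range(n_gc)]
    bases += [str(rng.choice(["A", "T"])) for _ in range(length - n_gc)]
    rng.shuffle(bases)
    return "".join(bases)


def _make_barcodes(
    rng: np.random.Generator, n: int, seeds: frozenset, longs: frozenset,
    max_tries: int = 2000,
) -> List[str]:
    codes: List[str] = []
    for _ in range(max_tries):
        cand = _balanced_random(rng, BARCODE_LEN)
        if not _spacer_ok(cand, seeds, longs):
            continue
        if all(
            sum(a != b for a, b in zip(cand, c)) >= BARCODE_MIN_HAMMING
            for c in codes
        ):
            codes.append(cand)
            if len(codes) == n:
                return codes
    raise ApcDesignError(f"could not generate {n} screened barcodes")


def synthesize_spacers(
    plan: ConstructPlan,
    seed: int,
    forbidden_oligos: Panel,
    max_tries: int = 200,
) -> ConstructPlan:
    """Fill every spacer slot with screened, GC-balanced random DNA and embed
    a unique barcode in each block's largest spacer.  Deterministic for a
    fixed seed."""
    rng = np.random.default_rng(seed)
    seeds, longs = _screen_sets(forbidden_oligos)

    def synth(length: int) -> str:
        for _ in range(max_tries):
            cand = _balanced_random(rng, length)
            if length < SEED_KMER or _spacer_ok(cand, seeds, longs):
                return cand
        raise ApcDesignError(
            f"could not synthesize a screened {length} nt spacer"
        )

    barcodes = _make_barcodes(rng, len(plan.blocks), seeds, longs)
    for block, code in zip(plan.blocks, barcodes):
        spacers = [e for e in block.elements if e.kind == "spacer"]
        host = max(spacers, key=lambda e: e.length, default=None)
        for e in spacers:
            if e is host and e.length >= BARCODE_LEN:
                pad = e.length - BARCODE_LEN
                left = synth(pad // 2)
                right = synth(pad - pad // 2)
                cand = left + code + right
                if not (len(cand) < SEED_KMER or _spacer_ok(cand, seeds, longs)):
                    # rare: junction of pad+code hits a screen; resynthesize pads
                    for _ in range(max_tries):
                        left = synth(pad // 2)
                        right = synth(pad - pad // 2)
                        cand = left + code + right
                        if _spacer_ok(cand, seeds, longs):
                            break
                    else:
                        raise ApcDesignError("barcode embedding failed screens")
                e.sequence = cand
                e.carries_barcode = True
            else:
                e.sequence = synth(e.length)
    plan.inter_sequences = [synth(n) for n in plan.inter_spacer_lens]
    return plan


# ---------------------------------------------------------------------------
# assembly

def assemble_construct(plan: ConstructPlan, name: str = "apc") -> ApcConstruct:
    """Concatenate adapters, blocks and inter-block spacers; record a 1-based
    feature table; check length and uniqueness invariants."""
    if not plan.blocks:
        raise ApcDesignError("no blocks to assemble")
    if plan.inter_sequences is None:
        raise ApcDesignError("spacers not synthesized yet")
    parts: List[str] = []
    features: List[Feature] = []
    pos = 0

    def emit(seq: str):
        nonlocal pos
        parts.append(seq)
        pos += len(seq)

    left, right = plan.adapters
    if left:
        features.append(Feature("adapter_5p", "misc_feature", "+", 1, len(left)))
        emit(left)
    for k, block in enumerate(plan.blocks):
        for e in block.elements:
            if e.sequence is None:
                raise ApcDesignError(f"element {e.name} has no sequence")
            ftype = {
                "primer": "primer_bind",
                "probe": "misc_binding",
                "spacer": "misc_feature",
            }[e.kind]
            fname = e.name + ("_barcode" if e.carries_barcode else "")
            features.append(
                Feature(fname, ftype, e.strand, pos + 1, pos + e.length)
            )
            emit(e.sequence)
        if k < len(plan.blocks) - 1:
            s = plan.inter_sequences[k]
            features.append(
                Feature(
                    f"inter_spacer_{k + 1}", "misc_feature", "+",
                    pos + 1, pos + len(s),
                )
            )
            emit(s)
    if right:
        features.append(
            Feature("adapter_3p", "misc_feature", "+", pos + 1, pos + len(right))
        )
        emit(right)
    sequence = "".join(parts)
    expected = (
        len(left) + len(right)
        + sum(b.length for b in plan.blocks)
        + sum(plan.inter_spacer_lens)
    )
    if len(sequence) != expected:
        raise ApcDesignError("assembled length does not match plan")
    return ApcConstruct(
        sequence=sequence, features=features, blocks=list(plan.blocks),
        adapters=plan.adapters, name=name,
    )


# ---------------------------------------------------------------------------
# verification

@dataclass
class CheckResult:
    name: str
    passed: bool
    informational: bool = False
    detail: str = ""


@dataclass
class VerificationReport:
    checks: List[CheckResult]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks if not c.informational)

    def failures(self) -> List[CheckResult]:
        return [c for c in self.checks if not c.passed and not c.informational]

    def to_text(self) -> str:
        lines = ["APC verification report"]
        for c in self.checks:
            tag = "info" if c.informational else ("PASS" if c.passed else "FAIL")
            lines.append(f"  [{tag}] {c.name}: {c.detail}")
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "checks": [
                {
                    "name": c.name,
                    "passed": c.passed,
                    "informational": c.informational,
                    "detail": c.detail,
                }
                for c in self.checks
            ],
        }


def verify_construct(
    construct: ApcConstruct,
    panel: Panel,
    min_size_gap: int = 20,
    max_len: int = 3000,
) -> VerificationReport:
    """Round-trip verification by in-silico PCR.

    Checks: each assay pair yields exactly one amplicon of its designed size;
    each probe sits strictly between its primers; every designed oligo has
    exactly one exact-match site; no cross-target product size is confusable
    (within ``min_size_gap``) with a designed size; amplicon internal
    sequences are pairwise distinct.  Genomic-size collisions are reported
    as informational flags."""
    checks: List[CheckResult] = []
    tpl = construct.template
    designed = construct.designed_sizes()
    amps_by_pair: Dict[str, list] = {}

    for assay in panel:
        sizes = designed.get(assay.target)
        if sizes is None:
            continue
        for use, pair in (("endpoint", assay.endpoint_pair), ("qpcr", assay.qpcr_pair)):
            if pair is None or sizes.get(use) is None:
                continue
            amps = predict_amplicons(pair, tpl, max_len=max_len)
            amps_by_pair[f"{assay.target}:{use}"] = amps
            want = sizes[use]
            got = [a.length for a in amps]
            checks.append(
                CheckResult(
                    f"size:{assay.target}:{use}",
                    got == [want],
                    detail=f"designed {want} bp, predicted {got or 'none'}",
                )
            )
            if use == "qpcr" and assay.probe is not None and len(amps) == 1:
                site = locate_probe(assay.probe, amps[0], allow_overlap=False)
                checks.append(
                    CheckResult(
                        f"probe:{assay.target}",
                        site is not None,
                        detail=(
                            f"probe {assay.probe.name} at {site.start}-{site.end} ({site.strand})"
                            if site else f"probe {assay.probe.name} not between primers"
                        ),
                    )
                )
            g = assay.genomic_endpoint_size if use == "endpoint" else assay.genomic_qpcr_size
            if g is not None and g == want:
                checks.append(
                    CheckResult(
                        f"genomic-size-collision:{assay.target}:{use}",
                        False,
                        informational=True,
                        detail=f"APC size equals genomic size ({g} bp); "
                        "discrimination relies on the sequence barcode",
                    )
                )

    # oligo-site uniqueness: exactly one designed site per oligo; additional
    # sites are tolerated only when fully contained inside another designed
    # oligo's footprint (pairs that overlap in the source gene)
    from .ispcr import find_binding_sites  # local import avoids cycle at module load

    footprints = [
        (f.name, f.start, f.end)
        for f in construct.features
        if f.type in ("primer_bind", "misc_binding")
    ]
    designed_oligos = {
        o.name: o for a in panel for o in a.multiplex_oligos()
        if a.target in designed
    }
    bad = []
    for o in designed_oligos.values():
        hits = find_binding_sites(o, tpl, max_mismatch=0, clamp3=0)
        own = [
            h for h in hits
            if any(n == o.name and h.start == s and h.end == e
                   for n, s, e in footprints)
        ]
        stray = [
            h for h in hits
            if h not in own
            and not any(
                n != o.name and s <= h.start and h.end <= e
                for n, s, e in footprints
            )
        ]
        if len(own) != 1 or stray:
            bad.append(f"{o.name}(designed={len(own)},stray={len(stray)})")
    checks.append(
        CheckResult(
            "oligo-site-uniqueness",
            not bad,
            detail="each designed oligo has exactly one designed site"
            if not bad
            else f"non-unique sites: {', '.join(bad)}",
        )
    )

    # cross-target products confusable with designed sizes
    designed_sizes = sorted(
        s for d in designed.values() for s in d.values() if s is not None
    )
    cross_bad = []
    assays = [a for a in panel if a.target in designed]
    for aa, ab in itertools.permutations(assays, 2):
        for pa in aa.pairs():
            for pb in ab.pairs():
                xp = PrimerPair(f"{pa.fwd.name}x{pb.rev.name}", pa.fwd, pb.rev)
                for amp in predict_amplicons(xp, tpl, max_len=max_len):
                    if any(abs(amp.length - d) < min_size_gap for d in designed_sizes):
                        cross_bad.append(f"{xp.name}={amp.length}bp")
    checks.append(
        CheckResult(
            "cross-assay-products",
            not cross_bad,
            detail="no cross-target product confusable with a designed size"
            if not cross_bad
            else f"confusable cross products: {', '.join(sorted(set(cross_bad)))}",
        )
    )

    # sequence identifiability: internal sequences pairwise distinct across
    # distinct primer pairs (a pair shared by endpoint and qPCR readout is a
    # single product and compares once)
    internals = {}
    seen_pairs = set()
    for key, amps in amps_by_pair.items():
        if len(amps) == 1:
            a = amps[0]
            ident = (a.forward_hit.oligo_name, a.reverse_hit.oligo_name)
            if ident in seen_pairs:
                continue
            seen_pairs.add(ident)
            flen = a.forward_hit.end - a.forward_hit.start + 1
            rlen = a.reverse_hit.end - a.reverse_hit.start + 1
            internals[key] = a.sequence[flen : len(a.sequence) - rlen]
    dup = [
        (k1, k2)
        for (k1, s1), (k2, s2) in itertools.combinations(internals.items(), 2)
        if s1 == s2
    ]
    checks.append(
        CheckResult(
            "amplicon-identifiability",
            not dup,
            detail="internal sequences pairwise distinct"
            if not dup
            else f"identical internal sequences: {dup}",
        )
    )
    return VerificationReport(checks)


# ---------------------------------------------------------------------------
# one-call driver

def design_apc(
    panel: Panel,
    size_requests: "Dict[str, Dict[str, Optional[int]]] | str" = "auto",
    seed: int = 0,
    inter_spacer_len: int = MIN_INTER_SPACER,
    adapters: Tuple[str, str] = ("", ""),
    min_size_gap: int = 20,
    max_attempts: int = 10,
    name: str = "apc",
) -> Tuple[ApcConstruct, VerificationReport]:
    """Plan, synthesize, assemble and verify; resynthesizes spacers with a
    derived sub-seed if a random accident breaks verification."""
    last_report = None
    for attempt in range(max_attempts):
        plan = plan_construct(
            plan_blocks(panel, size_requests), panel, inter_spacer_len,
            adapters, min_size_gap,
        )
        plan = synthesize_spacers(plan, seed + 1000003 * attempt, panel)
        construct = assemble_construct(plan, name=name)
        report = verify_construct(construct, panel, min_size_gap)
        if report.passed:
            return construct, report
        last_report = report
    raise ApcDesignError(
        "design failed verification after retries:\n" + last_report.to_text()
    )
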