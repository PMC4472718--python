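"""Panel-level compatibility checks: fluorophore-to-channel assignment,
cross-dimer matrix, annealing-temperature uniformity, endpoint size spacing
and exclusivity against non-target templates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .oligos import DyeSpec, cross_dimer_score, nn_tm
from .panel import Panel
from .ispcr import GelReport, Template, simulate_multiplex, virtual_gel

__all__ = [
    "Channel",
    "DEFAULT_CHANNELS",
    "SpectralConflictError",
    "assign_channels",
    "CompatibilityReport",
    "compatibility_report",
    "ExclusivityResult",
    "exclusivity_check",
]


class SpectralConflictError(ValueError):
    """Two dyes compete for one detection channel or sit too close in
    emission wavelength."""


@dataclass(frozen=True)
class Channel:
    """A real-time instrument acquisition channel: excitation source band and
    detection band centers in nm."""

    name: str
    source_nm: float
    detect_nm: float


# Rotor-Gene-style five-channel optics; instrument constants, editable.
DEFAULT_CHANNELS: List[Channel] = [
    Channel("green", 470, 510),
    Channel("yellow", 530, 555),
    Channel("orange", 585, 610),
    Channel("red", 625, 660),
    Channel("crimson", 680, 712),
]


def assign_channels(
    dyes: Sequence[DyeSpec],
    channels: Sequence[Channel] = tuple(DEFAULT_CHANNELS),
    min_gap_nm: float = 25.0,
) -> Dict[str, str]:
    """Map each reporter dye to the channel whose detection band is nearest
    its emission maximum.

    The assignment must be injective and all pairwise emission gaps must be
    at least ``min_gap_nm``; violations raise :class:`SpectralConflictError`
    naming the offending dye pair."""
    if len(dyes) > len(channels):
        raise SpectralConflictError(
            f"{len(dyes)} dyes cannot share {len(channels)} channels"
        )
    for a, b in itertools.combinations(dyes, 2):
        if abs(a.emission - b.emission) < min_gap_nm:
            raise SpectralConflictError(
                f"dyes {a.dye_name} and {b.dye_name} emit within "
                f"{min_gap_nm} nm of each other "
                f"({a.emission} vs {b.emission} nm)"
            )
    assignment: Dict[str, str] = {}
    taken: Dict[str, str] = {}
    for dye in dyes:
        best = min(channels, key=lambda c: abs(c.detect_nm - dye.emission))
        if best.name in taken:
            raise SpectralConflictError(
                f"dyes {taken[best.name]} and {dye.dye_name} both nearest to "
                f"channel {best.name}"
            )
        taken[best.name] = dye.dye_name
        assignment[dye.dye_name] = best.name
    return assignment


@dataclass
class CompatibilityReport:
    channel_assignment: Dict[str, str]
    dimer_matrix: Dict[Tuple[str, str], int]
    dimer_flags: List[Tuple[str, str, int]]
    tms: Dict[str, float]
    tm_spread: float
    tm_flags: List[Tuple[str, float]]
    gel: Optional[GelReport]
    notes: List[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return (
            not self.dimer_flags
            and not self.tm_flags
            and (self.gel is None or self.gel.all_distinguishable)
        )

    def dimer_tsv(self) -> str:
        names = sorted({n for pair in self.dimer_matrix for n in pair})
        lines = ["\t".join([""] + names)]
        for a in names:
            lines.append(
                "\t".join([a] + [str(self.dimer_matrix[(a, b)]) for b in names])
            )
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        return {
            "channel_assignment": self.channel_assignment,
            "dimer_flags": self.dimer_flags,
            "tm_spread": self.tm_spread,
            "tm_flags": self.tm_flags,
            "gel_sizes": self.gel.sizes if self.gel else [],
            "gel_distinguishable": self.gel.all_distinguishable if self.gel else None,
            "clean": self.clean,
            "notes": self.notes,
        }


def _reaction_sets(panel: Panel) -> List[frozenset]:
    """Oligo names co-occurring in one tube: the endpoint multiplex and the
    qPCR multiplex (primers + probes)."""
    endpoint = set()
    qpcr = set()
    for a in panel:
        if a.endpoint_pair is not None:
            endpoint.update({a.endpoint_fwd.name, a.endpoint_rev.name})
        if a.qpcr_pair is not None:
            qpcr.update({a.qpcr_fwd.name, a.qpcr_rev.name})
            if a.probe is not None:
                qpcr.add(a.probe.name)
    return [frozenset(endpoint), frozenset(qpcr)]


def compatibility_report(
    panel: Panel,
    dimer_threshold: Optional[int] = None,
    tm_window: float = 3.0,
    anneal_temp: float = 60.0,
    min_size_gap: int = 20,
    min_gap_nm: float = 25.0,
) -> CompatibilityReport:
    """Multiplex compatibility audit of a panel.

    Computes the full symmetric cross-dimer matrix over all multiplex oligos
    (diagonal equals the self-dimer score) and flags pairs that share a
    reaction tube and pair at or above ``dimer_threshold`` complementary
    bases (default: three quarters of the shorter oligo, the point where a
    stable duplex becomes plausible).  Primer melting temperatures are
    checked against a ``tm_window`` band around the shared annealing
    temperature, endpoint product sizes are spaced on a virtual gel, and dye
    channels are assigned when the panel carries probes.  Findings are
    report entries, never errors."""
    oligos = panel.multiplex_oligos()
    reactions = _reaction_sets(panel)
    matrix: Dict[Tuple[str, str], int] = {}
    flags: List[Tuple[str, str, int]] = []
    for a in oligos:
        for b in oligos:
            if (a.name, b.name) in matrix:
                continue
            s = cross_dimer_score(a.sequence, b.sequence)
            matrix[(a.name, b.name)] = s
            matrix[(b.name, a.name)] = s
            threshold = (
                dimer_threshold
                if dimer_threshold is not None
                else math.ceil(0.75 * min(len(a), len(b)))
            )
            co_reacting = any(
                a.name in r and b.name in r for r in reactions
            )
            if s >= threshold and co_reacting and a.name <= b.name:
                flags.append((a.name, b.name, s))
    primers = [o for o in oligos if o.role != "probe"]
    tms = {o.name: nn_tm(o.sequence) for o in primers}
    tm_flags = [
        (n, t) for n, t in tms.items() if abs(t - anneal_temp) > tm_window
    ]
    spread = max(tms.values()) - min(tms.values()) if tms else 0.0
    sizes = [
        a.genomic_endpoint_size
        for a in panel
        if a.endpoint_pair is not None and a.genomic_endpoint_size is not None
    ]
    gel = virtual_gel(sizes, min_size_gap) if sizes else None
    notes: List[str] = []
    dyes = panel.dyes()
    try:
        channels = assign_channels(dyes, min_gap_nm=min_gap_nm) if dyes else {}
    except SpectralConflictError as exc:
        channels = {}
        notes.append(str(exc))
    return CompatibilityReport(
        channel_assignment=channels,
        dimer_matrix=matrix,
        dimer_flags=sorted(flags),
        tms=tms,
        tm_spread=spread,
        tm_flags=sorted(tm_flags),
        gel=gel,
        notes=notes,
    )


@dataclass
class ExclusivityResult:
    matrix: Dict[Tuple[str, str], List[int]]  # (pair, template) -> product sizes
    verdict: bool
    failures: List[str]

    def to_tsv(self) -> str:
        pairs = sorted({p for p, _ in self.matrix})
        tids = sorted({t for _, t in self.matrix})
        lines = ["\t".join(["pair"] + tids)]
        for p in pairs:
            lines.append(
                "\t".join(
                    [p]
                    + [
                        ",".join(map(str, self.matrix.get((p, t), []))) or "-"
                        for t in tids
                    ]
                )
            )
        return "\n".join(lines) + "\n"


def exclusivity_check(
    panel: Panel,
    target_templates: Dict[str, Sequence[Template]],
    decoy_templates: Sequence[Template],
    max_mismatch: int = 0,
    clamp3: int = 3,
    max_len: int = 3000,
) -> ExclusivityResult:
    """Inclusivity/exclusivity verdict: pass iff every assay amplifies all of
    its designated target templates and no assay amplifies any decoy
    (near-neighbor, out-group or host) template."""
    for a in panel:
        if not target_templates.get(a.target):
            raise ValueError(f"assay {a.target} has no designated target template")
    all_templates: List[Template] = []
    owner: Dict[str, Optional[str]] = {}
    for tgt, tpls in target_templates.items():
        for t in tpls:
            all_templates.append(t)
            owner[t.id] = tgt
    for t in decoy_templates:
        all_templates.append(t)
        owner[t.id] = None
    sm = simulate_multiplex(panel, all_templates, max_mismatch, clamp3, max_len)
    matrix: Dict[Tuple[str, str], List[int]] = {
        k: [a.length for a in v] for k, v in sm.entries.items()
    }
    failures: List[str] = []
    for (pname, tid), sizes in matrix.items():
        tgt = pname.split(":")[0]
        if owner[tid] == tgt and not sizes:
            failures.append(f"{pname} fails to amplify its target {tid}")
        if owner[tid] != tgt and sizes:
            failures.append(f"{pname} amplifies non-target {tid} ({sizes} bp)")
    for (xname, tid), amps in sm.cross_entries.items():
        failures.append(
            f"cross pairing {xname} amplifies {tid} "
            f"({[a.length for a in amps]} bp)"
        )
    return ExclusivityResult(matrix, not failures, sorted(failures))
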