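"""Panel containers: per-target assay sets and the multiplex panel.

An :class:`AssaySet` groups everything belonging to one target species: an
endpoint primer pair sized for gel readout, a qPCR primer pair sized for
probe-based readout, the hydrolysis probe and its reporter dye.  The two
pairs may share oligos (a reverse primer serving both sizes, or one pair
doing double duty for endpoint and qPCR).  Auxiliary single-reaction primers
ride along as metadata and take no part in multiplex simulation or construct
design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional

from .oligos import DyeSpec, Oligo

__all__ = ["PrimerPair", "AssaySet", "Panel", "PanelError"]


class PanelError(ValueError):
    """Raised when a panel violates its structural invariants."""


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair with the name used in reports."""

    name: str
    fwd: Oligo
    rev: Oligo

    def __post_init__(self):
        if self.fwd.role == "probe" or self.rev.role == "probe":
            raise PanelError(f"{self.name}: probes cannot act as pair members")


@dataclass
class AssaySet:
    target: str
    endpoint_fwd: Optional[Oligo] = None
    endpoint_rev: Optional[Oligo] = None
    qpcr_fwd: Optional[Oligo] = None
    qpcr_rev: Optional[Oligo] = None
    probe: Optional[Oligo] = None
    dye: Optional[DyeSpec] = None
    aux: List[Oligo] = field(default_factory=list)
    genomic_endpoint_size: Optional[int] = None
    genomic_qpcr_size: Optional[int] = None
    notes: str = ""

    def __post_init__(self):
        if (self.endpoint_fwd is None) != (self.endpoint_rev is None):
            raise PanelError(f"{self.target}: endpoint pair must be complete")
        if (self.qpcr_fwd is None) != (self.qpcr_rev is None):
            raise PanelError(f"{self.target}: qPCR pair must be complete")
        if self.endpoint_fwd is None and self.qpcr_fwd is None:
            raise PanelError(f"{self.target}: assay has no primer pair")
        if self.qpcr_fwd is not None and self.probe is None:
            raise PanelError(f"{self.target}: qPCR use requires a probe")

    @property
    def endpoint_pair(self) -> Optional[PrimerPair]:
        if self.endpoint_fwd is None:
            return None
        return PrimerPair(
            f"{self.target}:endpoint", self.endpoint_fwd, self.endpoint_rev
        )

    @property
    def qpcr_pair(self) -> Optional[PrimerPair]:
        if self.qpcr_fwd is None:
            return None
        return PrimerPair(f"{self.target}:qpcr", self.qpcr_fwd, self.qpcr_rev)

    def pairs(self) -> List[PrimerPair]:
        """Distinct primer pairs of this assay (one entry when endpoint and
        qPCR share both primers)."""
        out: List[PrimerPair] = []
        ep, qp = self.endpoint_pair, self.qpcr_pair
        if ep is not None:
            out.append(ep)
        if qp is not None and not (
            ep is not None
            and ep.fwd.name == qp.fwd.name
            and ep.rev.name == qp.rev.name
        ):
            out.append(qp)
        return out

    def multiplex_oligos(self) -> List[Oligo]:
        """Oligos participating in multiplex reactions (no aux primers),
        deduplicated by name."""
        seen: Dict[str, Oligo] = {}
        for o in (
            self.endpoint_fwd,
            self.endpoint_rev,
            self.qpcr_fwd,
            self.qpcr_rev,
            self.probe,
        ):
            if o is not None:
                seen.setdefault(o.name, o)
        return list(seen.values())


@dataclass
class Panel:
    """The multiplex collection of per-target assay sets."""

    assays: List[AssaySet]
    name: str = "panel"

    def __post_init__(self):
        if not self.assays:
            raise PanelError("panel has no assays")
        targets = [a.target for a in self.assays]
        if len(set(targets)) != len(targets):
            raise PanelError("duplicate target names in panel")
        names: Dict[str, str] = {}
        for a in self.assays:
            for o in a.multiplex_oligos() + a.aux:
                prev = names.get(o.name)
                if prev is not None and prev != o.sequence:
                    raise PanelError(f"oligo name {o.name} reused with a different sequence")
                names[o.name] = o.sequence

    def __iter__(self) -> Iterator[AssaySet]:
        return iter(self.assays)

    def __len__(self) -> int:
        return len(self.assays)

    def assay(self, target: str) -> AssaySet:
        for a in self.assays:
            if a.target == target:
                return a
        raise KeyError(target)

    def multiplex_oligos(self) -> List[Oligo]:
        seen: Dict[str, Oligo] = {}
        for a in self.assays:
            for o in a.multiplex_oligos():
                seen.setdefault(o.name, o)
        return list(seen.values())

    def all_oligos(self) -> List[Oligo]:
        seen: Dict[str, Oligo] = {}
        for a in self.assays:
            for o in a.multiplex_oligos() + a.aux:
                seen.setdefault(o.name, o)
        return list(seen.values())

    def dyes(self) -> List[DyeSpec]:
        return [a.dye for a in self.assays if a.dye is not None]
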