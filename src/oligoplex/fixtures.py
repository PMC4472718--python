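"""Seeded fixture generators: planted templates that carry a target's
priming sites at exact product sizes, decoy templates emulating near-neighbor
species (sites corrupted at primer 3' ends), and simulated dilution-series
Ct data.  Everything is deterministic under a fixed seed, so the whole test
and validation workflow runs without any real sequence data.

A planted template reuses the construct planner: the target's nested priming
sites are laid out at the requested (e.g. genomic) product sizes with
screened spacers, then embedded in screened random background — structurally
the same nesting the real barcoding locus presents to the assays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .apc import (
    ApcDesignError,
    ConstructPlan,
    _balanced_random,
    _screen_sets,
    _spacer_ok,
    assemble_construct,
    plan_blocks,
    synthesize_spacers,
)
from .curves import DilutionPoint, DilutionSeries
from .ispcr import Template
from .panel import AssaySet, Panel
from .oligos import revcomp

__all__ = [
    "FixtureError",
    "FixtureSpec",
    "make_planted_template",
    "make_decoy_template",
    "make_background_template",
    "make_exclusivity_set",
    "simulate_ct_series",
    "DEFAULT_AMOUNTS_NG",
]

DEFAULT_AMOUNTS_NG = (1.0, 0.1, 0.01, 1e-3, 1e-4, 1e-5, 1e-6)

# 3'-transversion map: breaks the Watson-Crick pair without creating a wobble
_CORRUPT = {"A": "C", "C": "A", "G": "T", "T": "G"}


class FixtureError(ValueError):
    """Raised when a fixture specification cannot be realized."""


@dataclass
class FixtureSpec:
    """Declarative recipe for a set of fixtures (used by the CLI)."""

    seed: int
    flank: int = 120
    sizes: Dict[str, Dict[str, Optional[int]]] = field(default_factory=dict)
    n_decoys: int = 8
    background_len: int = 600
    ct_slope: float = -3.32
    ct_intercept: float = 30.0
    ct_sigma: float = 0.15
    ct_replicates: int = 3


def _screened_random(
    rng: np.random.Generator, length: int, seeds: frozenset, longs: frozenset,
    max_tries: int = 200,
) -> str:
    for _ in range(max_tries):
        cand = _balanced_random(rng, length)
        if _spacer_ok(cand, seeds, longs):
            return cand
    raise FixtureError(f"could not generate screened background of {length} nt")


def _planted_core(
    assay: AssaySet,
    sizes: Dict[str, Optional[int]],
    seed: int,
    screen_panel: Panel,
):
    single = Panel([assay], name=f"fx_{assay.target}")
    blocks = plan_blocks(single, {assay.target: sizes})
    plan = ConstructPlan(blocks, [], ("", ""))
    plan = synthesize_spacers(plan, seed, screen_panel)
    return assemble_construct(plan, name=f"fx_{assay.target}")


def make_planted_template(
    assay: AssaySet,
    sizes: Dict[str, Optional[int]],
    seed: int,
    screen_panel: Panel,
    flank: int = 120,
    template_id: Optional[str] = None,
) -> Template:
    """A template carrying the assay's priming sites nested at the given
    product sizes, flanked by screened random background."""
    core = _planted_core(assay, sizes, seed, screen_panel)
    rng = np.random.default_rng(seed + 7919)
    seeds, longs = _screen_sets(screen_panel)
    left = _screened_random(rng, flank, seeds, longs)
    right = _screened_random(rng, flank, seeds, longs)
    return Template(
        template_id or f"target_{assay.target}",
        left + core.sequence + right,
        "linear",
        f"planted fixture for {assay.target}",
    )


def make_decoy_template(
    assay: AssaySet,
    sizes: Dict[str, Optional[int]],
    seed: int,
    screen_panel: Panel,
    mismatch_plan: Optional[Sequence[Tuple[str, int]]] = None,
    flank: int = 120,
    template_id: Optional[str] = None,
) -> Template:
    """A near-neighbor decoy: the assay's planted template with substitutions
    at primer 3' ends so the assay yields no product at default stringency.

    ``mismatch_plan`` lists ``(oligo_name, offset_from_3prime)`` positions to
    corrupt; by default the 3'-terminal base of every planted primer site.
    A plan that leaves the assay productive raises :class:`FixtureError`.
    """
    core = _planted_core(assay, sizes, seed, screen_panel)
    rng = np.random.default_rng(seed + 104729)
    seeds, longs = _screen_sets(screen_panel)
    left = _screened_random(rng, flank, seeds, longs)
    right = _screened_random(rng, flank, seeds, longs)

    primer_feats = {
        f.name: f for f in core.features if f.type == "primer_bind"
    }
    if mismatch_plan is None:
        mismatch_plan = [(name, 0) for name in primer_feats]
    seq = list(core.sequence)
    for name, off in mismatch_plan:
        f = primer_feats.get(name)
        if f is None:
            raise FixtureError(f"no planted primer site named {name!r}")
        # the primer's 3' end maps to the right edge of a plus-strand
        # footprint and the left edge of a minus-strand footprint
        pos = (f.end - 1 - off) if f.strand == "+" else (f.start - 1 + off)
        if not (f.start - 1 <= pos <= f.end - 1):
            raise FixtureError(f"{name}: offset {off} outside the footprint")
        seq[pos] = _CORRUPT[seq[pos]]
    tpl = Template(
        template_id or f"decoy_{assay.target}",
        left + "".join(seq) + right,
        "linear",
        f"decoy fixture derived from {assay.target}",
    )
    from .ispcr import predict_amplicons  # deferred: fixtures are lower level

    for pair in assay.pairs():
        if predict_amplicons(pair, tpl):
            raise FixtureError(
                f"mismatch plan leaves {pair.name} productive on the decoy"
            )
    return tpl


def make_background_template(
    seed: int,
    screen_panel: Panel,
    length: int = 600,
    template_id: str = "background",
    description: str = "screened random background",
) -> Template:
    """Pure screened random DNA: an out-group or host stand-in with no panel
    priming sites."""
    rng = np.random.default_rng(seed)
    seeds, longs = _screen_sets(screen_panel)
    return Template(
        template_id,
        _screened_random(rng, length, seeds, longs),
        "linear",
        description,
    )


def make_exclusivity_set(
    panel: Panel,
    sizes: Dict[str, Dict[str, Optional[int]]],
    seed: int,
    n_decoys: int = 8,
    flank: int = 120,
) -> Tuple[Dict[str, List[Template]], List[Template]]:
    """Fixture analogue of an inclusivity/exclusivity panel: one planted
    template per target plus ``n_decoys`` near-neighbor decoys, an out-group
    and a host background template."""
    targets: Dict[str, List[Template]] = {}
    for i, assay in enumerate(panel):
        targets[assay.target] = [
            make_planted_template(
                assay, sizes[assay.target], seed + i, panel, flank
            )
        ]
    decoys: List[Template] = []
    assays = list(panel)
    for j in range(n_decoys):
        assay = assays[j % len(assays)]
        decoys.append(
            make_decoy_template(
                assay,
                sizes[assay.target],
                seed + 1000 + j,
                panel,
                template_id=f"decoy_{j + 1}_{assay.target}",
            )
        )
    decoys.append(
        make_background_template(
            seed + 5000, panel, template_id="outgroup",
            description="out-group insect stand-in",
        )
    )
    decoys.append(
        make_background_template(
            seed + 6000, panel, template_id="host",
            description="host grain stand-in",
        )
    )
    return targets, decoys


def simulate_ct_series(
    slope: float = -3.32,
    intercept: float = 30.0,
    sigma: float = 0.15,
    replicates: int = 3,
    amounts_ng: Sequence[float] = DEFAULT_AMOUNTS_NG,
    seed: int = 0,
    channel: str = "sim",
    kit: str = "sim",
) -> DilutionSeries:
    """Simulated dilution series: Ct = intercept + slope*log10(amount_ng) +
    Normal(0, sigma) per replicate.  ``intercept`` is the expected Ct at
    1 ng.  Deterministic per seed."""
    if sigma < 0:
        raise FixtureError("sigma must be >= 0")
    if replicates < 1:
        raise FixtureError("need >= 1 replicate")
    if any(a <= 0 for a in amounts_ng):
        raise FixtureError("amounts must be positive")
    rng = np.random.default_rng(seed)
    points = []
    for a in sorted(amounts_ng, reverse=True):
        mu = intercept + slope * math.log10(a)
        cts = [float(mu + rng.normal(0.0, sigma)) for _ in range(replicates)]
        points.append(DilutionPoint(a, cts=cts))
    return DilutionSeries(channel=channel, kit=kit, points=points)
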