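"""File I/O: FASTA and GenBank records, panel TSV/JSON, dilution-series CSV,
and loaders for the data files shipped with the package (the published
five-species booklouse panel and its dilution-series table).
"""

from __future__ import annotations

import csv
import json
import math
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .apc import ApcConstruct, Feature
from .curves import DilutionPoint, DilutionSeries
from .ispcr import Template
from .oligos import DyeSpec, Oligo, oligo_report
from .panel import AssaySet, Panel, PanelError

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_panel",
    "read_dyes",
    "read_ct_csv",
    "write_oligo_report",
    "write_construct",
    "read_construct",
    "load_default_panel",
    "load_default_dilutions",
    "load_apc_config",
    "load_printed_properties",
]

PathLike = Union[str, Path]
_DATA = resources.files("oligoplex") / "data"


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: PathLike) -> List[Template]:
    """Read a (multi-record) FASTA into templates; sequences uppercased.
    A record description containing ``circular`` sets circular topology."""
    out: List[Template] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        topo = "circular" if "circular" in rec.description.lower() else "linear"
        out.append(
            Template(rec.id, str(rec.seq).upper(), topo, rec.description)
        )
    return out


def write_fasta(templates: Sequence[Template], path: PathLike) -> None:
    recs = [
        SeqRecord(Seq(t.sequence), id=t.id, description=t.description or "")
        for t in templates
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# panel

def read_dyes(path: Optional[PathLike] = None) -> Dict[str, DyeSpec]:
    """Dye table: dye, excitation_nm, emission_nm, quencher."""
    src = Path(path) if path else _DATA / "dyes.tsv"
    dyes: Dict[str, DyeSpec] = {}
    with src.open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            dyes[row["dye"]] = DyeSpec(
                row["dye"],
                float(row["excitation_nm"]),
                float(row["emission_nm"]),
                row.get("quencher", ""),
            )
    return dyes


_ROLES = {"forward": "forward", "reverse": "reverse", "probe": "probe"}
_USES = {"endpoint", "qpcr", "both", "single"}


def _panel_from_rows(rows: List[dict], dyes: Dict[str, DyeSpec], name: str) -> Panel:
    seen_names = set()
    by_target: Dict[str, List[dict]] = {}
    for row in rows:
        if row["name"] in seen_names:
            raise PanelError(f"duplicate oligo name {row['name']}")
        seen_names.add(row["name"])
        if row["role"] not in _ROLES:
            raise PanelError(f"{row['name']}: unknown role {row['role']!r}")
        if row["use"] not in _USES:
            raise PanelError(f"{row['name']}: unknown use {row['use']!r}")
        if row["role"] == "probe" and not row.get("dye"):
            raise PanelError(f"{row['name']}: probe needs a dye")
        by_target.setdefault(row["target"], []).append(row)
    assays: List[AssaySet] = []
    for target, trows in by_target.items():
        slots: Dict[str, Optional[Oligo]] = {
            "endpoint_fwd": None, "endpoint_rev": None,
            "qpcr_fwd": None, "qpcr_rev": None,
        }
        probe = dye = None
        aux: List[Oligo] = []
        for row in trows:
            o = Oligo(row["name"], row["sequence"], _ROLES[row["role"]])
            use = row["use"]
            if row["role"] == "probe":
                probe = o
                dname = row.get("dye", "")
                if dname and dname not in dyes:
                    raise PanelError(f"{row['name']}: unknown dye {dname!r}")
                dye = dyes.get(dname)
                if dye is not None and row.get("quencher"):
                    dye = DyeSpec(
                        dye.dye_name, dye.excitation, dye.emission,
                        row["quencher"],
                    )
                continue
            if use == "single":
                aux.append(o)
                continue
            side = "fwd" if row["role"] == "forward" else "rev"
            for u in ("endpoint", "qpcr") if use == "both" else (use,):
                if slots[f"{u}_{side}"] is not None:
                    raise PanelError(f"{target}: two {u} {side} primers")
                slots[f"{u}_{side}"] = o
        assays.append(
            AssaySet(
                target=target, probe=probe, dye=dye, aux=aux, **slots
            )
        )
    return Panel(assays, name=name)


def read_panel(
    path: PathLike, dyes: Optional[Dict[str, DyeSpec]] = None
) -> Panel:
    """Read a panel from TSV (columns target, name, role, sequence, dye,
    quencher, use) or JSON (a list of such row objects)."""
    p = Path(path)
    dyes = dyes if dyes is not None else read_dyes()
    if p.suffix.lower() == ".json":
        rows = json.loads(p.read_text())
        if not isinstance(rows, list):
            raise PanelError("panel JSON must be a list of oligo rows")
    else:
        with p.open() as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
    return _panel_from_rows(rows, dyes, name=p.stem)


def write_oligo_report(panel: Panel, path: PathLike, **tm_kwargs) -> None:
    """Property table mirroring the published column order: name, sequence,
    length, GC%, Tm, hairpin dG, self-any, self-3'."""
    rows = []
    for o in panel.all_oligos():
        r = oligo_report(o, **tm_kwargs)
        rows.append(
            {
                "name": r.name,
                "sequence": o.sequence,
                "length": r.length,
                "gc": r.gc,
                "tm": r.tm,
                "hairpin_dg": "" if r.hairpin_dg is None else round(r.hairpin_dg, 2),
                "any": r.self_any,
                "end3": r.self_end3,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# dilution series CSV

def read_ct_csv(path: PathLike) -> List[DilutionSeries]:
    """Dilution-series CSV with columns ``kit, channel, amount_ng`` and
    either replicate columns ``rep1..repN`` or ``ct_mean``/``ct_sd``.
    Empty replicate cells are undetected (NaN)."""
    df = pd.read_csv(path)
    rep_cols = [c for c in df.columns if c.startswith("rep")]
    out: List[DilutionSeries] = []
    for (kit, channel), grp in df.groupby(["kit", "channel"], sort=False):
        grp = grp.sort_values("amount_ng", ascending=False)
        points = []
        for _, row in grp.iterrows():
            if rep_cols:
                cts = [
                    float(row[c]) if not pd.isna(row[c]) else math.nan
                    for c in rep_cols
                ]
                points.append(DilutionPoint(float(row["amount_ng"]), cts=cts))
            else:
                sd = float(row["ct_sd"]) if "ct_sd" in row and not pd.isna(row["ct_sd"]) else None
                points.append(
                    DilutionPoint(
                        float(row["amount_ng"]),
                        mean=float(row["ct_mean"]),
                        sd=sd,
                    )
                )
        out.append(DilutionSeries(channel=str(channel), kit=str(kit), points=points))
    return out


# ---------------------------------------------------------------------------
# GenBank flat file for constructs

_FEATURE_TYPES = {"primer_bind", "misc_binding", "misc_feature"}


def write_construct(
    construct: ApcConstruct, gb_path: PathLike, fasta_path: Optional[PathLike] = None
) -> None:
    """Write the construct as a minimal GenBank flat file (1-based inclusive
    feature coordinates) and optionally as FASTA."""
    rec = SeqRecord(
        Seq(construct.sequence),
        id=construct.name,
        name=construct.name[:16],
        description="multi-target artificial positive control",
        annotations={"molecule_type": "DNA", "topology": "linear"},
    )
    for f in construct.features:
        rec.features.append(
            SeqFeature(
                FeatureLocation(f.start - 1, f.end, strand=1 if f.strand == "+" else -1),
                type=f.type,
                qualifiers={"label": [f.name]},
            )
        )
    SeqIO.write([rec], str(gb_path), "genbank")
    if fasta_path is not None:
        SeqIO.write(
            [SeqRecord(Seq(construct.sequence), id=construct.name, description="")],
            str(fasta_path),
            "fasta",
        )


def read_construct(path: PathLike) -> ApcConstruct:
    """Re-read an exported construct (GenBank keeps features; FASTA loses
    them)."""
    p = Path(path)
    fmt = "genbank" if p.suffix.lower() in (".gb", ".gbk", ".genbank") else "fasta"
    rec = next(SeqIO.parse(str(p), fmt))
    feats = []
    for f in rec.features:
        if f.type not in _FEATURE_TYPES:
            continue
        feats.append(
            Feature(
                name=f.qualifiers.get("label", [f.type])[0],
                type=f.type,
                strand="+" if (f.location.strand or 1) >= 0 else "-",
                start=int(f.location.start) + 1,
                end=int(f.location.end),
            )
        )
    return ApcConstruct(
        sequence=str(rec.seq).upper(),
        features=feats,
        blocks=[],
        adapters=("", ""),
        name=rec.id,
    )


# ---------------------------------------------------------------------------
# shipped data

def load_default_panel() -> Panel:
    """The five-species booklouse identification panel (20 primers, 5
    hydrolysis probes) shipped with the package."""
    dyes = read_dyes()
    with (_DATA / "liposcelis_panel.tsv").open() as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    panel = _panel_from_rows(rows, dyes, name="liposcelis5")
    cfg = load_apc_config()
    for a in panel:
        g = cfg["genomic_sizes"].get(a.target, {})
        a.genomic_endpoint_size = g.get("endpoint")
        a.genomic_qpcr_size = g.get("qpcr")
    return panel


def load_apc_config() -> dict:
    return json.loads((_DATA / "apc_config.json").read_text())


def load_default_dilutions() -> List[DilutionSeries]:
    """Published comparative dilution-series table: per-channel mean(SD) Ct
    for 10-fold dilutions from 1 ng to 1 fg under two master mixes."""
    with resources.as_file(_DATA / "dilution_series.csv") as p:
        return read_ct_csv(p)


def load_printed_properties() -> pd.DataFrame:
    """Published per-oligo property table (length, GC%, Tm, dG, any, 3') as
    printed, for regression comparisons."""
    with resources.as_file(_DATA / "printed_properties.tsv") as p:
        return pd.read_csv(p, sep="\t")
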