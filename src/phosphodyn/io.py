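"""Tabular input/output: quantification tables, reaction tables, ID maps, networks.

All inputs are plain TSV with a header row.  The quantification table carries
one phosphopeptide per row: an identifier, a protein accession, the cellular
fraction it was isolated from (cytoplasm or nucleus), and a relative-abundance
ratio per time point.  A peptide measured in both fractions appears as two rows
and becomes two distinct network nodes; node identity is the
``(peptide_id, fraction)`` pair throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

FRACTIONS = ("cytoplasm", "nucleus")

#: default column-name schema of a quantification table; time columns are every
#: column not named here, in file order
DEFAULT_SCHEMA = {
    "peptide_id": "peptide_id",
    "protein_accession": "protein_accession",
    "fraction": "fraction",
}


@dataclass(frozen=True)
class PhosphoPeptide:
    """One quantified phosphopeptide (one node candidate).

    ``profile`` holds relative-abundance ratios in time order; missing
    measurements are ``None``.  ``standard_id`` is filled in by
    :func:`standardize_ids` and is ``None`` until then.
    """

    peptide_id: str
    protein_accession: str
    fraction: str
    profile: tuple
    time_labels: tuple
    standard_id: str | None = None

    def __post_init__(self):
        if self.fraction not in FRACTIONS:
            raise ValueError(
                f"unknown fraction {self.fraction!r} for peptide "
                f"{self.peptide_id!r}; expected one of {FRACTIONS}"
            )
        if len(self.profile) != len(self.time_labels):
            raise ValueError(
                f"peptide {self.peptide_id!r}: profile has {len(self.profile)} "
                f"values but {len(self.time_labels)} time labels"
            )

    @property
    def node_id(self) -> tuple:
        return (self.peptide_id, self.fraction)

    @property
    def is_complete(self) -> bool:
        return all(v is not None and not math.isnan(v) for v in self.profile)


@dataclass(frozen=True)
class ReactionRecord:
    """A directed enzyme->substrate reaction from a curated pathway resource."""

    enzyme_accession: str
    substrate_accession: str
    reaction_kind: str = "phosphorylation"
    pathway_tag: str = ""

    def __post_init__(self):
        if not self.enzyme_accession or not self.substrate_accession:
            raise ValueError("reaction with empty enzyme or substrate accession")


@dataclass
class IdMap:
    """Flat raw-accession -> standardized-ID map (many-to-one allowed)."""

    entries: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.entries)

    def get(self, accession: str) -> str | None:
        return self.entries.get(accession)


def _parse_float(cell, row_no: int, column: str) -> float | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    if isinstance(cell, str):
        cell = cell.strip()
        if cell == "" or cell.upper() in {"NA", "NAN"}:
            return None
    try:
        return float(cell)
    except (TypeError, ValueError):
        raise ValueError(
            f"row {row_no}: cannot parse abundance {cell!r} in column {column!r}"
        ) from None


def load_quant_table(path, schema: Mapping[str, str] | None = None) -> list[PhosphoPeptide]:
    """Read a phosphopeptide quantification TSV into :class:`PhosphoPeptide` records.

    ``schema`` maps the logical names ``peptide_id`` / ``protein_accession`` /
    ``fraction`` to column names, and may give ``time_columns`` (a list) plus
    ``time_labels`` (minutes).  Without ``time_columns`` every remaining column
    is taken as a time point, in file order, and labels are parsed from the
    column names where possible (``t0`` / ``min5`` / ``10``...).
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for key in ("peptide_id", "protein_accession", "fraction"):
        if schema[key] not in df.columns:
            raise ValueError(f"quant table {path}: missing column {schema[key]!r}")
    time_cols = schema.get("time_columns")
    if time_cols is None:
        reserved = {schema["peptide_id"], schema["protein_accession"], schema["fraction"]}
        time_cols = [c for c in df.columns if c not in reserved]
    if len(time_cols) < 3:
        raise ValueError(f"quant table {path}: need >= 3 time-point columns, got {len(time_cols)}")
    time_labels = schema.get("time_labels")
    if time_labels is None:
        time_labels = []
        for i, c in enumerate(time_cols):
            digits = "".join(ch for ch in str(c) if ch.isdigit() or ch == ".")
            try:
                time_labels.append(float(digits))
            except ValueError:
                time_labels.append(float(i))
    time_labels = tuple(float(t) for t in time_labels)

    peptides = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        rowd = dict(zip(df.columns, row))
        fraction = str(rowd[schema["fraction"]]).strip().lower()
        if fraction not in FRACTIONS:
            raise ValueError(
                f"row {idx}: unknown fraction {rowd[schema['fraction']]!r} "
                f"(expected one of {FRACTIONS})"
            )
        profile = tuple(_parse_float(rowd[c], idx, c) for c in time_cols)
        peptides.append(
            PhosphoPeptide(
                peptide_id=str(rowd[schema["peptide_id"]]).strip(),
                protein_accession=str(rowd[schema["protein_accession"]]).strip(),
                fraction=fraction,
                profile=profile,
                time_labels=time_labels,
            )
        )
    return peptides


def filter_complete_profiles(peptides: Sequence[PhosphoPeptide]) -> tuple[list[PhosphoPeptide], dict]:
    """Keep only peptides whose profiles have a measurement at every time point.

    Returns ``(retained, report)`` where the report counts retained and dropped
    records overall and per fraction; ``retained + dropped == input`` always.
    Input order is preserved and the operation is idempotent.
    """
    retained = [p for p in peptides if p.is_complete]
    report = {
        "input": len(peptides),
        "retained": len(retained),
        "dropped": len(peptides) - len(retained),
        "retained_by_fraction": {
            f: sum(1 for p in retained if p.fraction == f) for f in FRACTIONS
        },
    }
    return retained, report


def load_idmap(path) -> IdMap:
    """Read a raw-accession -> standard-ID TSV (header row, two columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"idmap {path}: expected two columns")
    raw_col, std_col = df.columns[:2]
    entries = {}
    for raw, std in zip(df[raw_col], df[std_col]):
        raw, std = str(raw).strip(), str(std).strip()
        if raw and std:
            entries[raw] = std
    return IdMap(entries)


def standardize_ids(records: Sequence, idmap: IdMap):
    """Replace raw accessions with standardized IDs; report the unmapped.

    ``records`` may be :class:`PhosphoPeptide` (the ``standard_id`` field is
    filled; the peptide is kept either way so network construction is not
    affected) or :class:`ReactionRecord` (unmapped reactions are excluded,
    since pathway comparison requires both endpoints standardized).  Several
    raw accessions may map to one ID.
    """
    if len(idmap) == 0:
        raise ValueError("empty identifier map")
    mapped, unmapped = [], []
    for rec in records:
        if isinstance(rec, PhosphoPeptide):
            std = idmap.get(rec.protein_accession)
            if std is None:
                unmapped.append(rec.protein_accession)
                mapped.append(rec)
            else:
                mapped.append(replace(rec, standard_id=std))
        elif isinstance(rec, ReactionRecord):
            e = idmap.get(rec.enzyme_accession)
            s = idmap.get(rec.substrate_accession)
            if e is None or s is None:
                unmapped.extend(
                    a for a, m in ((rec.enzyme_accession, e), (rec.substrate_accession, s)) if m is None
                )
            else:
                mapped.append(
                    ReactionRecord(e, s, rec.reaction_kind, rec.pathway_tag)
                )
        else:
            raise TypeError(f"cannot standardize records of type {type(rec).__name__}")
    report = {
        "input": len(records),
        "mapped": len(mapped),
        "unmapped_accessions": sorted(set(unmapped)),
        "n_unmapped": len(unmapped),
    }
    return mapped, report


def load_reactions(path) -> list[ReactionRecord]:
    """Read a reaction TSV with columns [enzyme, substrate, kind, pathway_tag]."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError(f"reaction table {path}: expected >= 2 columns")
    out = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        vals = [str(v).strip() for v in row]
        kind = vals[2] if len(vals) > 2 and vals[2] else "phosphorylation"
        tag = vals[3] if len(vals) > 3 else ""
        try:
            out.append(ReactionRecord(vals[0], vals[1], kind, tag))
        except ValueError as err:
            raise ValueError(f"reaction table row {idx}: {err}") from None
    return out


# ---------------------------------------------------------------------------
# network serialization

_NODE_SEP = "|"


def _node_to_str(node) -> str:
    if isinstance(node, tuple):
        return _NODE_SEP.join(str(p) for p in node)
    return str(node)


def _str_to_node(s: str):
    if _NODE_SEP in s:
        return tuple(s.split(_NODE_SEP))
    return s


def write_network(network: nx.Graph, path, format: str = "edge-list") -> None:
    """Write a network as an edge-list TSV or a SIF file.

    Edge-list TSV: header ``source<TAB>target<TAB>source_protein<TAB>target_protein``;
    an isolated node is a row with an empty ``target``.  SIF: ``node corr node``
    lines, isolated nodes on single-name lines.  Both round-trip the node set,
    edge set, and fraction labels (encoded in the node name for peptide nodes).
    """
    path = Path(path)
    lines = []
    if format in ("edge-list", "tsv"):
        lines.append("source\ttarget\tsource_protein\ttarget_protein")
        for u, v in sorted(network.edges(), key=lambda e: (_node_to_str(e[0]), _node_to_str(e[1]))):
            pu = network.nodes[u].get("protein", "")
            pv = network.nodes[v].get("protein", "")
            lines.append(f"{_node_to_str(u)}\t{_node_to_str(v)}\t{pu or ''}\t{pv or ''}")
        for n in sorted(nx.isolates(network), key=_node_to_str):
            lines.append(f"{_node_to_str(n)}\t\t{network.nodes[n].get('protein', '') or ''}\t")
    elif format == "sif":
        for u, v in sorted(network.edges(), key=lambda e: (_node_to_str(e[0]), _node_to_str(e[1]))):
            lines.append(f"{_node_to_str(u)}\tcorr\t{_node_to_str(v)}")
        for n in sorted(nx.isolates(network), key=_node_to_str):
            lines.append(_node_to_str(n))
    else:
        raise ValueError(f"unknown network format {format!r}")
    path.write_text("\n".join(lines) + "\n")


def _annotate_peptide_node(g: nx.Graph, node, protein: str | None = None) -> None:
    attrs = {}
    if isinstance(node, tuple) and len(node) == 2 and node[1] in FRACTIONS:
        attrs["fraction"] = node[1]
        attrs["peptide_id"] = node[0]
    if protein:
        attrs["protein"] = protein
    g.add_node(node, **attrs)


def read_network(path, format: str = "edge-list") -> nx.Graph:
    """Inverse of :func:`write_network`."""
    path = Path(path)
    g = nx.Graph()
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if format in ("edge-list", "tsv"):
        if lines and lines[0].startswith("source"):
            lines = lines[1:]
        for ln in lines:
            parts = ln.split("\t")
            u = _str_to_node(parts[0])
            _annotate_peptide_node(g, u, parts[2] if len(parts) > 2 and parts[2] else None)
            if len(parts) > 1 and parts[1]:
                v = _str_to_node(parts[1])
                _annotate_peptide_node(g, v, parts[3] if len(parts) > 3 and parts[3] else None)
                g.add_edge(u, v)
    elif format == "sif":
        for ln in lines:
            parts = ln.split("\t")
            if len(parts) == 1:
                _annotate_peptide_node(g, _str_to_node(parts[0]))
            else:
                u, v = _str_to_node(parts[0]), _str_to_node(parts[2])
                _annotate_peptide_node(g, u)
                _annotate_peptide_node(g, v)
                g.add_edge(u, v)
    else:
        raise ValueError(f"unknown network format {format!r}")
    return g
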