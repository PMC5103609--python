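"""Ligand-receptor interaction database and mouse→human homolog mapping.

The interaction database is a curated list of (ligand, receptor) ordered
pairs keyed by human gene symbols.  Autocrine pairs (ligand == receptor) are
permitted; the ordered pair is the unique key.  Mouse expression is brought
onto human gene symbols through a Homologene-style many-to-one map before
scoring: when several mouse genes map to one human gene their expression
values are summed.

File formats are plain TSV with a header row (UTF-8).  Interactions need at
least ``ligand`` and ``receptor`` columns; ``source`` and ``pmid`` are
optional free-text evidence columns.  The homolog map needs ``mouse_gene``
and ``human_gene`` columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)


class DatabaseFormatError(ValueError):
    """The interaction/homolog file is malformed (missing columns, empty)."""


@dataclass(frozen=True)
class InteractionRecord:
    """One curated ligand→receptor interaction, human-symbol keyed."""

    ligand_gene: str
    receptor_gene: str
    source: str = ""
    evidence: str = ""

    @property
    def key(self) -> tuple[str, str]:
        return (self.ligand_gene, self.receptor_gene)


def _canon(symbol: str) -> str:
    """Canonical (case-insensitive) gene key: uppercase, stripped."""
    return str(symbol).strip().upper()


def load_interaction_db(path: str | Path | None = None) -> list[InteractionRecord]:
    """Load an interaction TSV; collapse duplicate ordered pairs.

    With no path the small curated core database shipped with the package is
    loaded.  Duplicate (ligand, receptor) ordered pairs are merged into one
    record with ';'-joined evidence.  Matching is case-insensitive; human
    symbols are canonicalised to uppercase.

    Raises
    ------
    DatabaseFormatError
        If the ligand/receptor columns are missing or the file has no rows.
    """
    if path is None:
        with resources.as_file(
            resources.files("xenolink") / "data" / "ligand_receptor_core.tsv"
        ) as p:
            return load_interaction_db(p)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    df.columns = [c.strip().lower() for c in df.columns]
    if "ligand" not in df.columns or "receptor" not in df.columns:
        raise DatabaseFormatError(
            f"{path}: interaction table must have 'ligand' and 'receptor' columns"
        )
    if len(df) == 0:
        raise DatabaseFormatError(f"{path}: interaction table is empty")

    merged: dict[tuple[str, str], dict[str, list[str]]] = {}
    order: list[tuple[str, str]] = []
    for row in df.itertuples(index=False):
        lig, rec = _canon(row.ligand), _canon(row.receptor)
        key = (lig, rec)
        src = str(getattr(row, "source", "") or "")
        ev = str(getattr(row, "pmid", getattr(row, "evidence", "")) or "")
        if key not in merged:
            merged[key] = {"source": [], "evidence": []}
            order.append(key)
        if src and src not in merged[key]["source"]:
            merged[key]["source"].append(src)
        if ev and ev not in merged[key]["evidence"]:
            merged[key]["evidence"].append(ev)

    records = [
        InteractionRecord(
            ligand_gene=k[0],
            receptor_gene=k[1],
            source=";".join(merged[k]["source"]),
            evidence=";".join(merged[k]["evidence"]),
        )
        for k in order
    ]
    logger.info("loaded %d interactions from %s", len(records), path)
    return records


def write_interaction_db(records: Iterable[InteractionRecord], path: str | Path) -> None:
    """Write records back to TSV (columns: ligand, receptor, source, pmid)."""
    df = pd.DataFrame(
        [
            {
                "ligand": r.ligand_gene,
                "receptor": r.receptor_gene,
                "source": r.source,
                "pmid": r.evidence,
            }
            for r in records
        ],
        columns=["ligand", "receptor", "source", "pmid"],
    )
    df.to_csv(path, sep="\t", index=False)


@dataclass
class HomologMap:
    """Mouse→human gene map (many-to-one allowed in both roles)."""

    mouse_to_human: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.mouse_to_human)

    def get(self, mouse_gene: str) -> str | None:
        return self.mouse_to_human.get(_canon(mouse_gene))


def load_homolog_map(path: str | Path) -> HomologMap:
    """Load a two-column (mouse_gene, human_gene) TSV into a HomologMap."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    df.columns = [c.strip().lower() for c in df.columns]
    if "mouse_gene" not in df.columns or "human_gene" not in df.columns:
        raise DatabaseFormatError(
            f"{path}: homolog map must have 'mouse_gene' and 'human_gene' columns"
        )
    mapping = {
        _canon(m): _canon(h)
        for m, h in zip(df["mouse_gene"], df["human_gene"])
        if m and h
    }
    return HomologMap(mouse_to_human=mapping)


def collapse_mouse_homologs(
    expr: Mapping[str, float], homolog_map: HomologMap
) -> tuple[dict[str, float], list[str]]:
    """Re-key a mouse expression table onto human gene symbols.

    Mouse genes mapping to the same human gene have their expression values
    summed.  Mouse genes absent from the map are dropped and returned in the
    second element (also logged as a warning).

    Parameters
    ----------
    expr
        mouse gene → nonnegative expression value.
    homolog_map
        mouse→human mapping.

    Returns
    -------
    (human-keyed expression dict, list of unmapped mouse genes)
    """
    out: dict[str, float] = {}
    unmapped: list[str] = []
    for mouse_gene, value in expr.items():
        if value < 0:
            raise ValueError(f"negative expression for {mouse_gene}")
        human = homolog_map.get(mouse_gene)
        if human is None:
            unmapped.append(mouse_gene)
            continue
        out[human] = out.get(human, 0.0) + float(value)
    if unmapped:
        logger.warning(
            "%d mouse genes had no human homolog and were dropped (e.g. %s)",
            len(unmapped),
            unmapped[:5],
        )
    return out, unmapped
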