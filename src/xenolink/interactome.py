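"""Ligand-receptor interaction scoring: dependency indices, zones, summaries.

For an interaction between ligand gene *i* and receptor gene *j*, with
normalised expression L_C, L_S (human/cancer and mouse/stroma ligand) and
R_C, R_S (receptors), the three indices in the cancer→stroma (C-S)
direction are

    X = L_C / (L_C + L_S)     ligand dependency
    Y = R_S / (R_C + R_S)     receptor dependency
    Z = sqrt(L_C · R_S)       signal strength

and in the stroma→cancer (S-C) direction X = L_S/(L_C+L_S),
Y = R_C/(R_C+R_S), Z = sqrt(L_S·R_C).  X and Y live on [0, 1] and are
complementary across directions; Z is on the normalised copy-number scale
(geometric mean of sender ligand and receiver receptor).

The (X, Y) unit square is split into four zones at 0.5 (boundary counts as
"strong"): zone 1 (X≥0.5, Y≥0.5) holds the mutually dependent interactions,
zone 2 (X≥0.5, Y<0.5) sender-side autoregulation, zone 3 (X<0.5, Y≥0.5)
receiver-side autoregulation, zone 4 the rest.  A zero ligand (or receptor)
total leaves X (or Y) undefined; such scores carry no zone and are excluded
from counts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from xenolink.lrdb import InteractionRecord

CS = "C-S"
SC = "S-C"
DIRECTIONS = (CS, SC)
ZONE_BOUNDARY = 0.5


@dataclass(frozen=True)
class InteractionScore:
    ligand: str
    receptor: str
    direction: str  # "C-S" | "S-C"
    x: float | None  # ligand dependency, None when ligand totals are 0
    y: float | None  # receptor dependency, None when receptor totals are 0
    z: float  # signal strength, always defined
    zone: int | None = None

    @property
    def defined(self) -> bool:
        return self.x is not None and self.y is not None

    @property
    def zone_label(self) -> str | None:
        if self.zone is None:
            return None
        return ("CS" if self.direction == CS else "SC") + str(self.zone)


def classify_zone(x: float, y: float) -> int:
    """Quadrant of the (X, Y) unit square at the 0.5 boundary (inclusive)."""
    strong_x = x >= ZONE_BOUNDARY
    strong_y = y >= ZONE_BOUNDARY
    if strong_x and strong_y:
        return 1
    if strong_x:
        return 2
    if strong_y:
        return 3
    return 4


def compute_indices(
    l_c: float, l_s: float, r_c: float, r_s: float,
    ligand: str = "", receptor: str = "",
) -> tuple[InteractionScore, InteractionScore]:
    """Score one interaction in both directions from the four expression levels."""
    for name, val in (("L_C", l_c), ("L_S", l_s), ("R_C", r_c), ("R_S", r_s)):
        if val < 0:
            raise ValueError(f"negative expression {name}={val}")
    lig_total = l_c + l_s
    rec_total = r_c + r_s
    x_cs = l_c / lig_total if lig_total > 0 else None
    y_cs = r_s / rec_total if rec_total > 0 else None
    x_sc = l_s / lig_total if lig_total > 0 else None
    y_sc = r_c / rec_total if rec_total > 0 else None
    cs = InteractionScore(
        ligand, receptor, CS, x_cs, y_cs, math.sqrt(l_c * r_s),
        zone=classify_zone(x_cs, y_cs) if x_cs is not None and y_cs is not None else None,
    )
    sc = InteractionScore(
        ligand, receptor, SC, x_sc, y_sc, math.sqrt(l_s * r_c),
        zone=classify_zone(x_sc, y_sc) if x_sc is not None and y_sc is not None else None,
    )
    return cs, sc


def score_profile(
    records: Iterable[InteractionRecord],
    human_expr: Mapping[str, float],
    mouse_expr: Mapping[str, float],
) -> list[InteractionScore]:
    """Score every database interaction against the two expression profiles.

    ``mouse_expr`` must already be keyed by human symbols (homolog-collapsed).
    Genes absent from a profile contribute expression 0.
    """
    scores: list[InteractionScore] = []
    for rec in records:
        cs, sc = compute_indices(
            human_expr.get(rec.ligand_gene, 0.0),
            mouse_expr.get(rec.ligand_gene, 0.0),
            human_expr.get(rec.receptor_gene, 0.0),
            mouse_expr.get(rec.receptor_gene, 0.0),
            ligand=rec.ligand_gene,
            receptor=rec.receptor_gene,
        )
        scores.extend((cs, sc))
    return scores


def count_strong_by_zone(
    scores: Iterable[InteractionScore],
    zones: set[int],
    z_min: float,
    direction: str | None = None,
) -> int:
    """Number of classified interactions with zone in ``zones`` and Z > z_min."""
    return sum(
        1
        for s in scores
        if s.zone in zones
        and s.z > z_min
        and (direction is None or s.direction == direction)
    )


def extract_mutually_dependent(
    scores: Iterable[InteractionScore],
    x_min: float = 0.75,
    y_min: float = 0.75,
    z_min: float = 50.0,
) -> pd.DataFrame:
    """Candidate druggable interactions: strong, strictly mutually dependent.

    Keeps scores with X > x_min, Y > y_min and Z > z_min (all strict), and
    returns them grouped by direction (C-S first), strongest signal first.
    """
    kept = [
        s
        for s in scores
        if s.defined and s.x > x_min and s.y > y_min and s.z > z_min
    ]
    kept.sort(key=lambda s: (s.direction != CS, -s.z, s.ligand, s.receptor))
    return pd.DataFrame(
        [
            {
                "ligand": s.ligand,
                "receptor": s.receptor,
                "direction": s.direction,
                "ligand_dependency": s.x,
                "receptor_dependency": s.y,
                "signal_strength": s.z,
            }
            for s in kept
        ],
        columns=[
            "ligand", "receptor", "direction",
            "ligand_dependency", "receptor_dependency", "signal_strength",
        ],
    )


def _stable_mean(values: Sequence[float]) -> float:
    arr = np.asarray(values, dtype=np.float64)
    if arr.min() == arr.max():  # identical samples average exactly
        return float(arr[0])
    # sort before summing so the result is bit-identical under sample permutation
    return float(np.sort(arr).sum() / arr.size)


def average_profiles(samples: Sequence[Sequence[InteractionScore]]) -> list[InteractionScore]:
    """Summarise several per-sample profiles into one averaged profile.

    X, Y and Z are averaged per interaction per direction over the samples
    where each index is defined (pairwise-available mean); the zone is then
    reclassified from the averaged X and Y.  Sample order does not affect
    the output.
    """
    if not samples:
        raise ValueError("need at least one sample profile")
    grouped: dict[tuple[str, str, str], list[InteractionScore]] = {}
    order: list[tuple[str, str, str]] = []
    for sample in samples:
        for s in sample:
            key = (s.ligand, s.receptor, s.direction)
            if key not in grouped:
                grouped[key] = []
                order.append(key)
            grouped[key].append(s)
    out = []
    for key in order:
        bucket = grouped[key]
        xs = [s.x for s in bucket if s.x is not None]
        ys = [s.y for s in bucket if s.y is not None]
        x = _stable_mean(xs) if xs else None
        y = _stable_mean(ys) if ys else None
        z = _stable_mean([s.z for s in bucket])
        zone = classify_zone(x, y) if x is not None and y is not None else None
        out.append(InteractionScore(key[0], key[1], key[2], x, y, z, zone))
    return out


def scores_to_dataframe(scores: Iterable[InteractionScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ligand": s.ligand,
                "receptor": s.receptor,
                "direction": s.direction,
                "ligand_dependency": s.x,
                "receptor_dependency": s.y,
                "signal_strength": s.z,
                "zone": s.zone_label,
            }
            for s in scores
        ],
        columns=[
            "ligand", "receptor", "direction",
            "ligand_dependency", "receptor_dependency", "signal_strength", "zone",
        ],
    )


def write_scores_tsv(scores: Iterable[InteractionScore], path: str | Path) -> None:
    scores_to_dataframe(scores).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_scores_tsv(path: str | Path) -> list[InteractionScore]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        x = None if pd.isna(row.ligand_dependency) else float(row.ligand_dependency)
        y = None if pd.isna(row.receptor_dependency) else float(row.receptor_dependency)
        zone = None
        if isinstance(row.zone, str) and row.zone[-1].isdigit():
            zone = int(row.zone[-1])
        out.append(
            InteractionScore(row.ligand, row.receptor, row.direction, x, y,
                             float(row.signal_strength), zone)
        )
    return out


def export_viewer_json(
    scores: Iterable[InteractionScore], path: str | Path,
    averaged: bool = False,
) -> None:
    """Two scatter datasets (one per direction) for the interactive viewer.

    Each point carries x = ligand dependency, y = receptor dependency and a
    radius proportional to log signal strength.  Undefined scores are
    omitted (they have no position in the unit square).
    """
    datasets: dict[str, list[dict]] = {CS: [], SC: []}
    for s in scores:
        if not s.defined:
            continue
        datasets[s.direction].append(
            {
                "ligand": s.ligand,
                "receptor": s.receptor,
                "x": s.x,
                "y": s.y,
                "signal_strength": s.z,
                "radius": math.log10(1.0 + s.z),
                "zone": s.zone_label,
            }
        )
    payload = {
        "metadata": {
            "zone_boundary": ZONE_BOUNDARY,
            "zones_recomputed_from_averaged_indices": bool(averaged),
        },
        "CS": datasets[CS],
        "SC": datasets[SC],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
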