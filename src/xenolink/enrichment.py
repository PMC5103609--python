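"""GO functional-module analysis of the interactome profile.

An interaction belongs to a GO category when its ligand *or* receptor gene
is a member.  For a target zone set (e.g. {1, 2} in the C-S direction) the
null hypothesis is that category members fall into those zones at the
background rate of all classified interactions of that direction; the
alternative is enrichment, tested with an upper-tail binomial test.
P-values are converted to q-values (Storey by default, Benjamini-Hochberg
as an option).  Categories are ranked by the fraction of member
interactions in the target zones, ties broken by mean signal strength, and
categories whose members average a signal strength below 10 are dropped as
too weak to interpret.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from xenolink.interactome import InteractionScore

logger = logging.getLogger(__name__)

#: zone sets mirroring the figure panels
ZONE_SETS = {
    "CS1+CS2": ("C-S", frozenset({1, 2})),
    "CS1+CS3": ("C-S", frozenset({1, 3})),
    "SC1+SC2": ("S-C", frozenset({1, 2})),
    "SC1+SC3": ("S-C", frozenset({1, 3})),
}


def load_go_table(path: str | Path) -> dict[str, set[str]]:
    """Category → member genes from a two-column (category, gene) TSV.

    An optional third ``name`` column is tolerated and ignored here (use
    :func:`load_go_names` for display names).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    if "category" not in df.columns or "gene" not in df.columns:
        raise ValueError(f"{path}: GO table must have 'category' and 'gene' columns")
    out: dict[str, set[str]] = {}
    for cat, gene in zip(df["category"], df["gene"]):
        out.setdefault(cat, set()).add(str(gene).strip().upper())
    return out


def load_go_gaf(path: str | Path) -> dict[str, set[str]]:
    """Category → genes from a GAF 2.x subset (columns 3 = symbol, 5 = GO id)."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("!") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                continue
            symbol, go_id = parts[2].strip().upper(), parts[4].strip()
            if symbol and go_id:
                out.setdefault(go_id, set()).add(symbol)
    return out


@dataclass
class GOModuleResult:
    category: str
    name: str
    direction: str
    n_members: int  # classified member interactions
    zone_counts: dict[int, int]
    k_in_zone_set: int
    fraction: float
    p_value: float
    q_value: float | None
    mean_signal: float
    member_interactions: list[tuple[str, str]] = field(default_factory=list)


def _category_members(
    members: set[str], scores: Sequence[InteractionScore], direction: str
) -> list[InteractionScore]:
    return [
        s
        for s in scores
        if s.direction == direction
        and s.zone is not None
        and (s.ligand in members or s.receptor in members)
    ]


def test_zone_enrichment(
    category: str,
    members: set[str],
    scores: Sequence[InteractionScore],
    zone_set: frozenset[int] | set[int],
    direction: str,
    name: str = "",
) -> GOModuleResult | None:
    """Upper-tail binomial test of one category against the background rate.

    With k member interactions in ``zone_set`` out of n classified members,
    and p0 the fraction of *all* classified interactions of this direction
    in ``zone_set``, p = P(Bin(n, p0) ≥ k).  Returns None when the category
    has no classified member interaction.
    """
    classified = [s for s in scores if s.direction == direction and s.zone is not None]
    if not classified:
        return None
    member_scores = _category_members(members, scores, direction)
    n = len(member_scores)
    if n == 0:
        return None
    p0 = sum(1 for s in classified if s.zone in zone_set) / len(classified)
    k = sum(1 for s in member_scores if s.zone in zone_set)
    p = float(stats.binom.sf(k - 1, n, p0))  # P(X >= k)
    zone_counts = {z: sum(1 for s in member_scores if s.zone == z) for z in (1, 2, 3, 4)}
    mean_signal = float(np.mean([s.z for s in member_scores]))
    return GOModuleResult(
        category=category,
        name=name,
        direction=direction,
        n_members=n,
        zone_counts=zone_counts,
        k_in_zone_set=k,
        fraction=k / n,
        p_value=min(p, 1.0),
        q_value=None,
        mean_signal=mean_signal,
        member_interactions=[(s.ligand, s.receptor) for s in member_scores],
    )


def storey_pi0(pvalues: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's π0 estimate with a cubic smoother over a λ grid.

    π0(λ) = #{p > λ} / (m(1-λ)) is fit with a cubic polynomial in λ and
    evaluated at the largest grid point, then clipped to (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.95, 0.05)
    m = p.size
    pi0_grid = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    if np.allclose(pi0_grid, pi0_grid[0]):
        pi0 = pi0_grid[-1]
    else:
        coeffs = np.polyfit(lambdas, pi0_grid, deg=3)
        pi0 = float(np.polyval(coeffs, lambdas[-1]))
    return float(min(max(pi0, 1.0 / m if m else 1.0), 1.0)) if m else 1.0


def compute_qvalues(pvalues: Sequence[float], method: str = "storey") -> np.ndarray:
    """q-values for a p-value vector (monotone in p-rank).

    ``storey``: q_(i) = min_{j≥i} π̂0·m·p_(j)/j with the smoother π̂0.
    ``bh``: the same with π̂0 = 1 (Benjamini-Hochberg adjusted p-values).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "storey":
        pi0 = storey_pi0(p)
    elif method == "bh":
        pi0 = 1.0
    else:
        raise ValueError(f"unknown q-value method {method!r}")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty_like(q)
    out[order] = q
    return out


def attach_qvalues(results: list[GOModuleResult], method: str = "storey") -> None:
    """Fill ``q_value`` in place across a family of category tests."""
    if not results:
        return
    q = compute_qvalues([r.p_value for r in results], method=method)
    for r, qv in zip(results, q):
        r.q_value = float(qv)


def rank_categories(
    results: Iterable[GOModuleResult],
    min_mean_signal: float = 10.0,
) -> list[GOModuleResult]:
    """Rank by zone-set fraction (desc), then mean signal strength (desc).

    Categories whose member interactions average a signal strength below
    ``min_mean_signal`` are removed before ranking.
    """
    kept = [r for r in results if r.mean_signal >= min_mean_signal]
    kept.sort(key=lambda r: (-r.fraction, -r.mean_signal, r.category))
    return kept


def representative_genes(
    results: Sequence[GOModuleResult],
    scores: Sequence[InteractionScore],
    min_categories: int = 2,
    z_min: float = 10.0,
) -> list[str]:
    """Genes appearing in ≥ ``min_categories`` categories with a strong interaction.

    A gene qualifies when it occurs (as ligand or receptor of a member
    interaction) in at least ``min_categories`` of the ranked categories and
    at least one of its interactions has signal strength > ``z_min``.
    """
    gene_categories: dict[str, set[str]] = {}
    for r in results:
        for lig, rec in r.member_interactions:
            gene_categories.setdefault(lig, set()).add(r.category)
            gene_categories.setdefault(rec, set()).add(r.category)
    strong: dict[str, float] = {}
    for s in scores:
        strong[s.ligand] = max(strong.get(s.ligand, 0.0), s.z)
        strong[s.receptor] = max(strong.get(s.receptor, 0.0), s.z)
    return sorted(
        g
        for g, cats in gene_categories.items()
        if len(cats) >= min_categories and strong.get(g, 0.0) > z_min
    )


def results_to_dataframe(results: Iterable[GOModuleResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "category": r.category,
                "name": r.name,
                "direction": r.direction,
                "n_members": r.n_members,
                "zone1": r.zone_counts.get(1, 0),
                "zone2": r.zone_counts.get(2, 0),
                "zone3": r.zone_counts.get(3, 0),
                "zone4": r.zone_counts.get(4, 0),
                "fraction_in_zone_set": r.fraction,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "mean_signal": r.mean_signal,
            }
            for r in results
        ],
        columns=[
            "category", "name", "direction", "n_members",
            "zone1", "zone2", "zone3", "zone4",
            "fraction_in_zone_set", "p_value", "q_value", "mean_signal",
        ],
    )


def analyze_go_modules(
    go_table: Mapping[str, set[str]],
    scores: Sequence[InteractionScore],
    zone_set_name: str = "CS1+CS2",
    qvalue_method: str = "storey",
    min_mean_signal: float = 10.0,
    go_names: Mapping[str, str] | None = None,
) -> list[GOModuleResult]:
    """Full module analysis for one zone set: test, q-values, rank, filter."""
    direction, zone_set = ZONE_SETS[zone_set_name]
    results = []
    for category, members in sorted(go_table.items()):
        res = test_zone_enrichment(
            category, members, scores, zone_set, direction,
            name=(go_names or {}).get(category, ""),
        )
        if res is not None:
            results.append(res)
    attach_qvalues(results, method=qvalue_method)
    return rank_categories(results, min_mean_signal=min_mean_signal)
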