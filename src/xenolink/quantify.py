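"""Bias-corrected per-gene copy-number estimation from positional read counts.

The coverage count ``c_ij`` at the j-th nucleotide from the poly-A tail of
gene *i* is modelled as Poisson with a log link:

    log E[c_ij] = log(m_ij / Σ_k m_ik) + log v_i + α g_ij + β d_ij

where ``m_ij`` is the per-nucleotide 50 bp mappability, ``g_ij`` the GC
fraction of the 50 nt window around position j, ``d_ij = j`` the distance
from the poly-A tail in nucleotides, ``v_i`` the gene's expression level,
and α, β sample-wide bias coefficients shared between human and mouse (the
library passed through one sequencing process).  Fitting alternates a
Poisson GLM for (α, β) — with the mappability/expression term as offset —
against a closed-form update of each ``v_i``, i.e. block-coordinate ascent
on the joint likelihood with gene fixed effects.

The final copy number uses the sparser but less GC-smeared read-start
counts ``c'``:

    ṽ_i = Σ_k c'_ik / Σ_{k: m_ik>0} exp(α g_ik + β d_ik)

so the denominator is the bias-weighted *mappable* length — positions where
no read could ever be assigned uniquely do not dilute the estimate.  Per
species, a normalisation constant Z scales ṽ so that the genes at or below
the 95th percentile sum to 300,000 normalised copies, roughly the mRNA
complement of an average cell; ṽ'_i = ṽ_i / Z.

Coverage counts drive the α/β regression (read starts are too sparse for
stable coefficients); read starts drive the final estimate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from xenolink.assignment import AssignedPairCounts, TranscriptSet
from xenolink.mappability import MappabilityTrack

logger = logging.getLogger(__name__)

GC_WINDOW = 50
INIT_MAX_POSITIONS = 3000
NORMALIZATION_TARGET = 300_000.0
NORMALIZATION_PERCENTILE = 95.0


def compute_covariates(sequence: str, window: int = GC_WINDOW) -> tuple[np.ndarray, np.ndarray]:
    """GC fraction ``g`` and poly-A distance ``d`` per nucleotide.

    ``g[j]`` is the GC fraction of the ``window``-nt window centred on the
    nucleotide (clipped at the transcript ends); ``d[j] = j + 1``.  Both are
    indexed by distance from the poly-A tail: index 0 is the 3'-terminal
    nucleotide of the 5'→3' input sequence.
    """
    seq = sequence.upper()
    n = len(seq)
    is_gc = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_gc = ((is_gc == ord("G")) | (is_gc == ord("C"))).astype(np.float64)
    cum = np.concatenate([[0.0], np.cumsum(is_gc)])
    half_lo = (window - 1) // 2  # 24 for a 50 nt window
    pos = np.arange(n)
    lo = np.maximum(pos - half_lo, 0)
    hi = np.minimum(pos - half_lo + window, n)
    g = (cum[hi] - cum[lo]) / (hi - lo)
    d = np.arange(1, n + 1, dtype=np.float64)
    return g[::-1].copy(), d


@dataclass
class GeneData:
    """Everything the model needs for one gene, poly-A-distance indexed."""

    species: str
    gene_id: str
    length: int
    n_variants: int
    coverage: np.ndarray
    read_start: np.ndarray
    m: np.ndarray
    g: np.ndarray
    d: np.ndarray

    @property
    def covered_fraction(self) -> float:
        return float(np.count_nonzero(self.coverage)) / self.length


def build_gene_data(
    counts: AssignedPairCounts,
    tracks: Mapping[tuple[str, str], MappabilityTrack],
    transcripts: TranscriptSet,
) -> dict[tuple[str, str], GeneData]:
    """Join counts, mappability and covariates for every annotated gene."""
    out: dict[tuple[str, str], GeneData] = {}
    for species, gene in transcripts.genes():
        rep = transcripts.representative(species, gene)
        n = rep.length
        g, d = compute_covariates(rep.sequence)
        cov = counts.coverage.get((species, gene))
        cs = counts.read_start.get((species, gene))
        track = tracks.get((species, gene))
        out[(species, gene)] = GeneData(
            species=species,
            gene_id=gene,
            length=n,
            n_variants=transcripts.n_variants(species, gene),
            coverage=cov if cov is not None else np.zeros(n, dtype=np.int64),
            read_start=cs if cs is not None else np.zeros(n, dtype=np.int64),
            m=track.m if track is not None else np.full(n, 50, dtype=np.int32),
            g=g,
            d=d,
        )
    return out


@dataclass(frozen=True)
class TrainingFilter:
    """Transcript filters for the bias regression (defaults as published)."""

    min_length: int = 8000
    min_covered_fraction: float = 0.8
    require_single_variant: bool = True


def select_training_genes(
    gene_data: Mapping[tuple[str, str], GeneData],
    filters: TrainingFilter = TrainingFilter(),
) -> list[tuple[str, str]]:
    """Genes eligible for α/β optimisation: single-variant, long, well covered."""
    keys = []
    for key, gd in gene_data.items():
        if filters.require_single_variant and gd.n_variants != 1:
            continue
        if gd.length <= filters.min_length:
            continue
        if gd.covered_fraction <= filters.min_covered_fraction:
            continue
        keys.append(key)
    return sorted(keys)


def initialize_v(gd: GeneData, max_positions: int = INIT_MAX_POSITIONS) -> float:
    """Mappability-weighted initial expression over the 3'-most positions.

    v_i(0) = Σ_{k=1..N'} (Σ_{l=1..N'} m_il) / (N' m_ik) · c_ik  over m_ik>0,
    with N' = min(N_i, max_positions).  Restricting to the poly-A-proximal
    window keeps the initial value away from the strongest 3'-bias region's
    tail and speeds convergence.
    """
    n_prime = min(gd.length, max_positions)
    m = gd.m[:n_prime].astype(np.float64)
    c = gd.coverage[:n_prime].astype(np.float64)
    usable = m > 0
    if not np.any(usable):
        return 0.0
    total_m = m.sum()
    return float(np.sum(total_m / (n_prime * m[usable]) * c[usable]))


@dataclass
class BiasModel:
    alpha: float
    beta: float
    v: dict[tuple[str, str], float] = field(default_factory=dict)
    n_iterations: int = 0
    converged: bool = False

    def to_json(self, path: str | Path) -> None:
        payload = {
            "alpha": self.alpha,
            "beta": self.beta,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "v": {f"{sp}:{gene}": _fmt(v) for (sp, gene), v in sorted(self.v.items())},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _fmt(x: float) -> float:
    """Fixed 6-significant-digit numeric formatting for outputs."""
    return float(f"{x:.6g}")


def fit_bias_model(
    gene_data: Mapping[tuple[str, str], GeneData],
    training_keys: Iterable[tuple[str, str]] | None = None,
    filters: TrainingFilter = TrainingFilter(),
    relaxed_filters: TrainingFilter = TrainingFilter(
        min_length=2000, min_covered_fraction=0.5
    ),
    max_iterations: int = 50,
    tol: float = 1e-6,
    stride: int = 1,
) -> BiasModel:
    """Alternating optimisation of (α, β) and the per-gene levels v_i.

    Coverage counts of the training genes are regressed on (GC, poly-A
    distance) under a Poisson log link with offset log(m_ij/Σ_k m_ik) +
    log v_i; the v_i are then updated in closed form given (α, β).  The GLM
    carries an intercept (redundant with the v_i block and folded into it at
    each update) so a common scale error in the current v iterate cannot
    leak into α or β.  Convergence: relative change of (α, β) below ``tol``.

    ``stride`` thins training positions to every s-th nucleotide to bound
    the design matrix; the default uses every position.
    """
    if training_keys is None:
        training_keys = select_training_genes(gene_data, filters)
        if not training_keys:
            logger.warning(
                "no gene passed the training filters %s; relaxing to %s",
                filters, relaxed_filters,
            )
            training_keys = select_training_genes(gene_data, relaxed_filters)
    training_keys = [k for k in training_keys if initialize_v(gene_data[k]) > 0]
    if len(training_keys) < 2:
        raise ValueError("need at least 2 usable training genes for the bias fit")

    y_parts, g_parts, d_parts, off_parts, idx_parts = [], [], [], [], []
    for i, key in enumerate(training_keys):
        gd = gene_data[key]
        usable = np.nonzero(gd.m > 0)[0][::stride]
        m = gd.m.astype(np.float64)
        y_parts.append(gd.coverage[usable].astype(np.float64))
        g_parts.append(gd.g[usable])
        d_parts.append(gd.d[usable])
        off_parts.append(np.log(m[usable] / m.sum()))
        idx_parts.append(np.full(usable.size, i, dtype=np.int64))
    y = np.concatenate(y_parts)
    X = np.column_stack(
        [np.ones_like(y), np.concatenate(g_parts), np.concatenate(d_parts)]
    )
    offset_base = np.concatenate(off_parts)
    gene_idx = np.concatenate(idx_parts)
    n_genes = len(training_keys)

    v = np.array([initialize_v(gene_data[k]) for k in training_keys])
    params = np.zeros(3)
    alpha = beta = 0.0
    converged = False
    iteration = 0
    for iteration in range(1, max_iterations + 1):
        offset = offset_base + np.log(v)[gene_idx]
        glm = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
        try:
            res = glm.fit(start_params=params, maxiter=100)
        except Exception:  # fall back to cold start if warm start stalls
            res = glm.fit(maxiter=100)
        params = np.asarray(res.params)
        intercept, new_alpha, new_beta = params
        # closed-form v update (Poisson MLE of a per-gene multiplier),
        # intercept folded in
        eta = offset_base + intercept + new_alpha * X[:, 1] + new_beta * X[:, 2]
        denom = np.bincount(gene_idx, weights=np.exp(eta), minlength=n_genes)
        numer = np.bincount(gene_idx, weights=y, minlength=n_genes)
        v = np.where(denom > 0, numer / np.maximum(denom, 1e-300), 0.0)
        v = np.maximum(v, 1e-300)
        params[0] = 0.0  # intercept absorbed into v
        delta = np.hypot(new_alpha - alpha, new_beta - beta)
        scale = np.hypot(alpha, beta)
        alpha, beta = float(new_alpha), float(new_beta)
        if delta <= tol * max(scale, 1.0):
            converged = True
            break
    if not converged:
        logger.warning("bias model did not converge in %d iterations", max_iterations)
    return BiasModel(
        alpha=alpha,
        beta=beta,
        v={k: float(vi) for k, vi in zip(training_keys, v)},
        n_iterations=iteration,
        converged=converged,
    )


@dataclass
class ExpressionProfile:
    """Per-species copy-number estimates (raw ṽ and normalised ṽ')."""

    species: str
    raw: dict[str, float]
    normalized: dict[str, float]
    z: float
    percentile_cutoff: float

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "gene": sorted(self.raw),
                "v_raw": [_fmt(self.raw[g]) for g in sorted(self.raw)],
                "v_norm": [_fmt(self.normalized[g]) for g in sorted(self.raw)],
            }
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path, species: str) -> "ExpressionProfile":
        df = pd.read_csv(path, sep="\t", dtype={"gene": str})
        raw = dict(zip(df["gene"], df["v_raw"].astype(float)))
        norm = dict(zip(df["gene"], df["v_norm"].astype(float)))
        return cls(species=species, raw=raw, normalized=norm, z=float("nan"),
                   percentile_cutoff=float("nan"))


def estimate_copy_numbers(
    gene_data: Mapping[tuple[str, str], GeneData],
    model: BiasModel,
    target_sum: float = NORMALIZATION_TARGET,
    percentile: float = NORMALIZATION_PERCENTILE,
) -> dict[str, ExpressionProfile]:
    """Read-start-based copy numbers, normalised per species.

    ṽ_i = Σ_k c'_ik / Σ_{k: m_ik>0} exp(α g_ik + β d_ik).  Z is chosen per
    species so that the sum of ṽ'_i over genes with ṽ at or below the
    species' 95th percentile (linear-interpolation definition, over genes
    with ṽ > 0, boundary gene included) equals ``target_sum``; genes above
    the percentile are scaled by the same Z but excluded from the sum.
    """
    per_species: dict[str, dict[str, float]] = {}
    for (species, gene), gd in gene_data.items():
        usable = gd.m > 0
        denom = float(
            np.sum(np.exp(model.alpha * gd.g[usable] + model.beta * gd.d[usable]))
        )
        v = float(gd.read_start.sum()) / denom if denom > 0 else 0.0
        per_species.setdefault(species, {})[gene] = v

    profiles: dict[str, ExpressionProfile] = {}
    for species, raw in per_species.items():
        values = np.array([x for x in raw.values() if x > 0])
        if values.size == 0:
            raise ValueError(f"all-zero expression for species {species!r}")
        cutoff = float(np.percentile(values, percentile))
        pool = values[values <= cutoff].sum()
        z = pool / target_sum
        normalized = {g: v / z for g, v in raw.items()}
        profiles[species] = ExpressionProfile(
            species=species, raw=raw, normalized=normalized, z=z,
            percentile_cutoff=cutoff,
        )
    return profiles
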