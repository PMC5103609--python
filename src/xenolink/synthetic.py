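"""Seeded two-species fixtures: transcriptomes, biased reads, annotation tables.

The generator emulates the experimental design the pipeline targets: a
poly-A-primed, 50 bp paired-end library sequenced from a mixture of human
and mouse RNA.  Transcript sequences are random with GC composition varying
along the transcript in blocks (so the GC covariate is informative within
genes), and a configurable fraction of gene pairs shares a verbatim
homologous block between one human and one mouse gene — the situation that
makes cross-species read assignment ambiguous and mappability drop to zero.

Read pairs are emitted as already-placed alignments (the aligner step is
bypassed; FASTQ/SAM emission is available for integration tests).  The
fragment 3'-end position within a gene is sampled with weight
exp(α·g + β·d), and the number of pairs per gene is proportional to the
true copy number v_i, i.e. read-start counts follow exactly the Poisson
bias model the quantification stage fits — with known coefficients, so
parameter and expression recovery can be scored against ground truth.
Pairs whose mate windows fall entirely inside a shared homologous block
receive the homologous placement as well, with the same mismatch count;
the assignment stage must exclude them as cross-species ties.

Base-calling errors are applied post-placement, at most one mismatch per
mate, respecting the alignment contract.  Everything is determined by the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from xenolink.assignment import (
    HUMAN,
    MOUSE,
    AlignedPair,
    Placement,
    TranscriptInfo,
    TranscriptSet,
)
from xenolink.lrdb import HomologMap, InteractionRecord
from xenolink.quantify import compute_covariates

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic xenograft sample.

    Defaults follow the sequencing design the pipeline models: 50 bp
    paired-end reads, ~200 nt fragments, a 1:1 human:mouse mixture, GC and
    poly-A-distance bias coefficients in the regime the bias model is meant
    to correct (a mild GC effect, a strong 3' decay), and transcripts in
    the 2-4 kb range typical of mammalian mRNA.
    """

    seed: int = 0
    n_genes: int = 60  # per species
    length_range: tuple[int, int] = (2000, 4000)
    gc_block_length: int = 750
    gc_range: tuple[float, float] = (0.3, 0.7)
    homolog_fraction: float = 0.1  # gene pairs sharing a verbatim block
    block_length: int = 300
    v_sigma: float = 1.2  # lognormal spread of true copy numbers
    alpha_true: float = -2.0  # per unit GC fraction
    beta_true: float = -1e-3  # per nucleotide from the poly-A tail
    n_pairs: int = 20000  # sequenced pair depth (both species combined)
    read_length: int = 50
    fragment_mean: float = 200.0
    fragment_sd: float = 20.0
    error_rate: float = 0.0  # per-base; at most 1 error per mate
    human_fraction: float = 0.5
    n_splice_variant_genes: int = 0  # genes given a second, 3'-shared variant


@dataclass
class Transcriptomes:
    """Synthetic two-species transcript set with full ground truth."""

    transcripts: TranscriptSet
    homolog_map: HomologMap
    v_true: dict[tuple[str, str], float]
    blocks: pd.DataFrame  # human_gene, human_start, mouse_gene, mouse_start, length
    config: SimulationConfig

    def genes(self, species: str) -> list[str]:
        return [g for sp, g in self.transcripts.genes() if sp == species]

    def write_fasta(self, path: str | Path) -> None:
        prefix = {HUMAN: "hs", MOUSE: "mm"}
        with open(path, "w") as fh:
            for tx_id in sorted(self.transcripts.by_id):
                t = self.transcripts.by_id[tx_id]
                fh.write(f">{prefix[t.species]}|{t.gene_id}|{t.transcript_id}\n")
                seq = t.sequence
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    def write_truth_tables(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        rows = [
            {
                "species": t.species,
                "gene": t.gene_id,
                "transcript": t.transcript_id,
                "length": t.length,
                "v_true": self.v_true.get((t.species, t.gene_id), 0.0),
            }
            for t in self.transcripts.by_id.values()
        ]
        pd.DataFrame(rows).sort_values(["species", "gene", "transcript"]).to_csv(
            outdir / "truth_genes.tsv", sep="\t", index=False
        )
        self.blocks.to_csv(outdir / "truth_blocks.tsv", sep="\t", index=False)

    def write_homolog_map(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.homolog_map.mouse_to_human.items()),
            columns=["mouse_gene", "human_gene"],
        ).to_csv(path, sep="\t", index=False)


def _random_sequence(rng: np.random.Generator, length: int, cfg: SimulationConfig) -> np.ndarray:
    """Random bases with blockwise GC composition (uint8 ASCII array)."""
    out = np.empty(length, dtype=np.uint8)
    pos = 0
    while pos < length:
        block = min(cfg.gc_block_length, length - pos)
        gc = rng.uniform(*cfg.gc_range)
        # A, C, G, T probabilities for this block
        probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        out[pos : pos + block] = _BASES[rng.choice(4, size=block, p=probs)]
        pos += block
    return out


def simulate_transcriptomes(config: SimulationConfig) -> Transcriptomes:
    """Deterministic two-species transcriptome with shared homologous blocks."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    n_hom = int(round(config.homolog_fraction * config.n_genes))
    if config.block_length > lo and n_hom > 0:
        raise ValueError(
            f"homologous block ({config.block_length} nt) longer than the "
            f"shortest allowed transcript ({lo} nt)"
        )
    transcripts: list[TranscriptInfo] = []
    seqs: dict[tuple[str, str], np.ndarray] = {}
    v_true: dict[tuple[str, str], float] = {}
    for species, gene_fmt, tx_fmt in (
        (HUMAN, "GENE{:04d}", "HTX{:04d}"),
        (MOUSE, "Gene{:04d}", "MTX{:04d}"),
    ):
        for i in range(config.n_genes):
            length = int(rng.integers(lo, hi + 1))
            seqs[(species, gene_fmt.format(i))] = _random_sequence(rng, length, config)
            v_true[(species, gene_fmt.format(i))] = float(
                rng.lognormal(mean=np.log(50.0), sigma=config.v_sigma)
            )
    block_rows = []
    for i in range(n_hom):
        hkey = (HUMAN, f"GENE{i:04d}")
        mkey = (MOUSE, f"Gene{i:04d}")
        bl = config.block_length
        h_len, m_len = len(seqs[hkey]), len(seqs[mkey])
        if bl >= h_len or bl >= m_len:
            raise ValueError("homologous block longer than transcript")
        h_start = int(rng.integers(0, h_len - bl + 1))
        m_start = int(rng.integers(0, m_len - bl + 1))
        seqs[mkey][m_start : m_start + bl] = seqs[hkey][h_start : h_start + bl]
        block_rows.append(
            {
                "human_gene": hkey[1], "human_start": h_start,
                "mouse_gene": mkey[1], "mouse_start": m_start,
                "length": bl,
            }
        )
    for (species, gene), arr in seqs.items():
        tx_fmt = "HTX{}" if species == HUMAN else "MTX{}"
        idx = gene[-4:]
        seq = arr.tobytes().decode("ascii")
        transcripts.append(
            TranscriptInfo(tx_fmt.format(idx), gene, species, len(seq), seq)
        )
        gene_no = int(idx)
        if gene_no < config.n_splice_variant_genes:
            # a second variant sharing the 3' end (suffix of the sequence)
            var = seq[len(seq) // 2 :]
            transcripts.append(
                TranscriptInfo(tx_fmt.format(idx) + "v2", gene, species,
                               len(var), var)
            )
    homolog_map = HomologMap(
        {f"GENE{i:04d}": f"GENE{i:04d}" for i in range(config.n_genes)}
    )
    return Transcriptomes(
        transcripts=TranscriptSet(transcripts),
        homolog_map=homolog_map,
        v_true=v_true,
        blocks=pd.DataFrame(
            block_rows,
            columns=["human_gene", "human_start", "mouse_gene", "mouse_start",
                     "length"],
        ),
        config=config,
    )


@dataclass
class SimulatedReads:
    pairs: list[AlignedPair]
    truth: pd.DataFrame  # read_id, species, gene, d3 (3'-end distance), fragment
    config: SimulationConfig


def simulate_reads(
    config: SimulationConfig, transcriptomes: Transcriptomes
) -> SimulatedReads:
    """Paired reads with the model's positional bias, as placed alignments.

    The 3'-proximal fragment end of each pair is sampled with probability
    ∝ exp(α_true·g + β_true·d) over positions that can hold a full fragment;
    pairs per gene are proportional to v_i scaled by the species mixing
    fraction.  Pairs fully contained in a shared homologous block get the
    cross-species placement too (same mismatch count).
    """
    rng = np.random.default_rng(config.seed + 1)
    ts = transcriptomes.transcripts
    read_len = config.read_length
    frag_min = 2 * read_len

    # expected pairs per gene: v_i * species mixing weight, normalised
    keys = sorted(transcriptomes.v_true)
    weights = np.array(
        [
            transcriptomes.v_true[k]
            * (config.human_fraction if k[0] == HUMAN else 1 - config.human_fraction)
            for k in keys
        ]
    )
    if weights.sum() <= 0:
        raise ValueError("all genes have zero expression")
    n_per_gene = rng.poisson(config.n_pairs * weights / weights.sum())

    blocks_by_gene: dict[tuple[str, str], tuple[int, int, tuple[str, str], int]] = {}
    for row in transcriptomes.blocks.itertuples(index=False):
        blocks_by_gene[(HUMAN, row.human_gene)] = (
            row.human_start, row.length, (MOUSE, row.mouse_gene), row.mouse_start
        )
        blocks_by_gene[(MOUSE, row.mouse_gene)] = (
            row.mouse_start, row.length, (HUMAN, row.human_gene), row.human_start
        )

    pairs: list[AlignedPair] = []
    truth_rows = []
    pair_no = 0
    for key, n_g in zip(keys, n_per_gene):
        if n_g == 0:
            continue
        species, gene = key
        rep = ts.representative(species, gene)
        n = rep.length
        if n < frag_min:
            continue
        g, d = compute_covariates(rep.sequence)
        # fragment 3'-end distance j (1-based); leave room for a minimal fragment
        max_d3 = n - frag_min + 1
        w = np.exp(config.alpha_true * g[:max_d3] + config.beta_true * d[:max_d3])
        w /= w.sum()
        d3s = rng.choice(max_d3, size=n_g, p=w) + 1  # 1-based distances
        frags = np.clip(
            np.round(rng.normal(config.fragment_mean, config.fragment_sd, size=n_g)),
            frag_min, None,
        ).astype(int)
        for d3, frag in zip(d3s, frags):
            frag = int(min(frag, n - d3 + 1))  # truncate at the 5' end
            end = n - d3 + 1  # 0-based exclusive transcript coordinate
            start = end - frag
            n_errors = int(rng.random() < config.error_rate * read_len) + int(
                rng.random() < config.error_rate * read_len
            )
            read_id = f"sim{pair_no:08d}"
            pair_no += 1
            placements = [
                Placement(species, rep.transcript_id, gene, start, end, n_errors)
            ]
            block = blocks_by_gene.get(key)
            if block is not None:
                b_start, b_len, partner_key, pb_start = block
                mate1 = (start, start + read_len)
                mate2 = (end - read_len, end)
                if (
                    mate1[0] >= b_start
                    and mate2[1] <= b_start + b_len
                ):
                    partner_rep = ts.representative(*partner_key)
                    shift = pb_start - b_start
                    placements.append(
                        Placement(
                            partner_key[0], partner_rep.transcript_id,
                            partner_key[1], start + shift, end + shift, n_errors,
                        )
                    )
            pairs.append(AlignedPair(read_id=read_id, placements=placements))
            truth_rows.append((read_id, species, gene, int(d3), frag))
    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "species", "gene", "d3", "fragment"]
    )
    return SimulatedReads(pairs=pairs, truth=truth, config=config)


def simulate_counts(
    config: SimulationConfig,
    transcriptomes: Transcriptomes,
    tracks: dict | None = None,
) -> "AssignedCountsLike":
    """Positional count vectors drawn exactly from the quantification model.

    Coverage counts are independent Poisson draws with mean
    (m_ij/Σ_k m_ik)·v_i·exp(α g_ij + β d_ij) scaled so that total coverage
    equals ``n_pairs`` × fragment length; read-start counts are Poisson with
    mean ∝ v_i·exp(α g_ij + β d_ij) on mappable positions, totalling
    ``n_pairs``.  Unlike :func:`simulate_reads` there is no fragment-level
    smearing, so the bias coefficients are recoverable without attenuation —
    this is the generator mode for coefficient-recovery checks, while the
    read-level mode exercises the full assignment path.

    ``tracks`` are mappability tracks keyed by (species, gene); when absent,
    full mappability is assumed (appropriate for block-free configurations).
    """
    from xenolink.assignment import AssignedPairCounts

    rng = np.random.default_rng(config.seed + 5)
    ts = transcriptomes.transcripts
    keys = sorted(transcriptomes.v_true)
    mix = {HUMAN: config.human_fraction, MOUSE: 1 - config.human_fraction}

    mu_cov: dict[tuple[str, str], np.ndarray] = {}
    mu_start: dict[tuple[str, str], np.ndarray] = {}
    for key in keys:
        species, gene = key
        rep = ts.representative(species, gene)
        g, d = compute_covariates(rep.sequence)
        if tracks is not None and key in tracks:
            m = tracks[key].m.astype(np.float64)
        else:
            m = np.full(rep.length, 50.0)
        bias = np.exp(config.alpha_true * g + config.beta_true * d)
        w = transcriptomes.v_true[key] * mix[species]
        mu_cov[key] = w * (m / max(m.sum(), 1e-300)) * bias
        mu_start[key] = w * bias * (m > 0)
    cov_total = sum(v.sum() for v in mu_cov.values())
    start_total = sum(v.sum() for v in mu_start.values())
    cov_scale = config.n_pairs * config.fragment_mean / cov_total
    start_scale = config.n_pairs / start_total

    counts = AssignedPairCounts()
    for key in keys:
        counts.coverage[key] = rng.poisson(cov_scale * mu_cov[key])
        counts.read_start[key] = rng.poisson(start_scale * mu_start[key])
        counts.assigned[key[0]] += int(counts.read_start[key].sum())
    return counts


def misassignment_rate(
    reads: SimulatedReads, assignments: Iterable
) -> float:
    """Percent of assigned pairs placed on the wrong species (vs. truth)."""
    truth_species = dict(zip(reads.truth["read_id"], reads.truth["species"]))
    assigned = wrong = 0
    for a in assignments:
        if not a.assigned:
            continue
        assigned += 1
        if a.species != truth_species[a.read_id]:
            wrong += 1
    if assigned == 0:
        raise ValueError("no assigned pairs")
    return 100.0 * wrong / assigned


# ---------------------------------------------------------------------------
# companion annotation fixtures


def make_interaction_db(
    transcriptomes: Transcriptomes, n_interactions: int = 40, seed: int | None = None
) -> list[InteractionRecord]:
    """A ligand-receptor table over the simulated human gene symbols."""
    rng = np.random.default_rng(
        transcriptomes.config.seed + 2 if seed is None else seed
    )
    genes = transcriptomes.genes(HUMAN)
    records = []
    used = set()
    while len(records) < min(n_interactions, len(genes) * (len(genes) - 1)):
        lig, rec = (genes[i] for i in rng.choice(len(genes), size=2, replace=False))
        if (lig, rec) in used:
            continue
        used.add((lig, rec))
        records.append(InteractionRecord(lig, rec, source="synthetic"))
    return records


def make_go_table(
    transcriptomes: Transcriptomes,
    n_categories: int = 10,
    genes_per_category: int = 8,
    seed: int | None = None,
) -> dict[str, set[str]]:
    """Random GO-style category memberships over the human gene symbols."""
    rng = np.random.default_rng(
        transcriptomes.config.seed + 3 if seed is None else seed
    )
    genes = transcriptomes.genes(HUMAN)
    return {
        f"GO:{7000000 + i}": {
            genes[j]
            for j in rng.choice(len(genes), size=min(genes_per_category, len(genes)),
                                replace=False)
        }
        for i in range(n_categories)
    }


def write_go_table(go_table: dict[str, set[str]], path: str | Path) -> None:
    rows = [(cat, gene) for cat in sorted(go_table) for gene in sorted(go_table[cat])]
    pd.DataFrame(rows, columns=["category", "gene"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# optional FASTQ / SAM emission


def _read_sequences(
    reads: SimulatedReads, transcriptomes: Transcriptomes, rng: np.random.Generator
) -> Iterable[tuple[str, str, str, tuple[int, int]]]:
    """Yield (read_id, mate1_seq, mate2_seq, per-mate error counts).

    Mate 1 is the 5' fragment end read on the forward strand; mate 2 the 3'
    end, reverse-complemented.  Errors respect the placement's mismatch
    budget: at most one substitution per mate.
    """
    comp = str.maketrans("ACGT", "TGCA")
    ts = transcriptomes.transcripts
    rl = reads.config.read_length
    for pair in reads.pairs:
        p = pair.placements[0]
        seq = ts.by_id[p.transcript_id].sequence
        m1 = seq[p.start : p.start + rl]
        m2 = seq[p.end - rl : p.end]
        errors = [0, 0]
        for _ in range(p.mismatches):
            mate = int(rng.integers(2))
            if errors[mate] >= 1:
                mate = 1 - mate
                if errors[mate] >= 1:
                    continue
            pos = int(rng.integers(rl))
            target = m1 if mate == 0 else m2
            orig = target[pos]
            subs = [b for b in "ACGT" if b != orig]
            mutated = target[:pos] + subs[int(rng.integers(3))] + target[pos + 1:]
            if mate == 0:
                m1 = mutated
            else:
                m2 = mutated
            errors[mate] += 1
        m2 = m2.translate(comp)[::-1]
        yield pair.read_id, m1, m2, (errors[0], errors[1])


def write_fastq(
    reads: SimulatedReads, transcriptomes: Transcriptomes,
    path_r1: str | Path, path_r2: str | Path,
) -> None:
    rng = np.random.default_rng(reads.config.seed + 4)
    rl = reads.config.read_length
    qual = "I" * rl
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for read_id, m1, m2, _ in _read_sequences(reads, transcriptomes, rng):
            f1.write(f"@{read_id}/1\n{m1}\n+\n{qual}\n")
            f2.write(f"@{read_id}/2\n{m2}\n+\n{qual}\n")


def write_sam(
    reads: SimulatedReads, transcriptomes: Transcriptomes, path: str | Path
) -> None:
    """Minimal SAM with one alignment record per mate per placement."""
    rng = np.random.default_rng(reads.config.seed + 4)
    ts = transcriptomes.transcripts
    rl = reads.config.read_length
    prefix = {HUMAN: "hs", MOUSE: "mm"}
    qual = "I" * rl
    comp = str.maketrans("ACGT", "TGCA")
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:queryname\n")
        for tx_id in sorted(ts.by_id):
            t = ts.by_id[tx_id]
            fh.write(
                f"@SQ\tSN:{prefix[t.species]}|{t.gene_id}|{t.transcript_id}"
                f"\tLN:{t.length}\n"
            )
        for pair, (read_id, m1, m2, errs) in zip(
            reads.pairs, _read_sequences(reads, transcriptomes, rng)
        ):
            m2_fwd = m2.translate(comp)[::-1]
            for p in pair.placements:
                ref = f"{prefix[p.species]}|{p.gene_id}|{p.transcript_id}"
                tlen = p.end - p.start
                # mate 1 forward at fragment 5' end; mate 2 reverse at 3' end
                fh.write(
                    f"{read_id}\t99\t{ref}\t{p.start + 1}\t60\t{rl}M\t=\t"
                    f"{p.end - rl + 1}\t{tlen}\t{m1}\t{qual}\tNM:i:{errs[0]}\n"
                )
                fh.write(
                    f"{read_id}\t147\t{ref}\t{p.end - rl + 1}\t60\t{rl}M\t=\t"
                    f"{p.start + 1}\t{-tlen}\t{m2_fwd}\t{qual}\tNM:i:{errs[1]}\n"
                )
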