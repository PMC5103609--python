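"""Species/gene assignment of aligned read pairs and positional counting.

Reads from a xenograft sample are aligned against the combined human+mouse
transcript set.  A pair placement is valid only when both mates hit the same
transcript.  The assignment rule is deterministic best-hit: among all
placements, those with the minimum total pair mismatches are kept; if they
all fall on one gene of one species (splice variants of that gene count as
one), the pair is assigned there, otherwise it is excluded (cross-species or
multi-gene tie at equal mismatch count).

Counts are kept per gene on the coordinate system of the gene's
representative (longest) transcript, indexed by distance from the poly-A
tail: position ``j`` (1-based) is the j-th nucleotide from the 3' end.  Two
vectors are maintained: coverage ``c`` (pairs whose fragment covers the
position) and read-start ``c'`` (pairs whose 3'-proximal fragment end lies
at the position) — the latter matches the poly-A-primed library chemistry
where fragments are counted from their 3' end.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HUMAN = "human"
MOUSE = "mouse"
#: reference-name prefixes in the combined transcript FASTA / SAM
SPECIES_PREFIX = {"hs": HUMAN, "mm": MOUSE}


@dataclass(frozen=True)
class Placement:
    """One candidate placement of a mate pair on a transcript.

    ``start``/``end`` delimit the fragment span (0-based half-open, in the
    transcript's 5'→3' orientation); ``mismatches`` is the pair total.
    """

    species: str
    transcript_id: str
    gene_id: str
    start: int
    end: int
    mismatches: int


@dataclass
class AlignedPair:
    read_id: str
    placements: list[Placement]


@dataclass(frozen=True)
class Assignment:
    read_id: str
    status: str  # "assigned" | "excluded"
    species: str | None = None
    gene_id: str | None = None
    reason: str | None = None
    placement: Placement | None = None

    @property
    def assigned(self) -> bool:
        return self.status == "assigned"


@dataclass
class TranscriptInfo:
    transcript_id: str
    gene_id: str
    species: str
    length: int
    sequence: str | None = None


class TranscriptSet:
    """Transcript annotation with a representative (longest) transcript per gene."""

    def __init__(self, transcripts: Iterable[TranscriptInfo]):
        self.by_id: dict[str, TranscriptInfo] = {}
        self.by_gene: dict[tuple[str, str], list[TranscriptInfo]] = defaultdict(list)
        for t in transcripts:
            self.by_id[t.transcript_id] = t
            self.by_gene[(t.species, t.gene_id)].append(t)

    def representative(self, species: str, gene_id: str) -> TranscriptInfo:
        variants = self.by_gene[(species, gene_id)]
        return max(variants, key=lambda t: (t.length, t.transcript_id))

    def n_variants(self, species: str, gene_id: str) -> int:
        return len(self.by_gene[(species, gene_id)])

    def genes(self) -> list[tuple[str, str]]:
        return sorted(self.by_gene)

    @classmethod
    def from_fasta(cls, fasta_path: str | Path, annotation: Mapping[str, str] | None = None
                   ) -> "TranscriptSet":
        """Build from a combined FASTA with ``hs|``/``mm|`` prefixed names.

        Record names are ``hs|TRANSCRIPT`` (gene looked up in ``annotation``)
        or self-describing ``hs|GENE|TRANSCRIPT``.
        """
        from Bio import SeqIO

        transcripts = []
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            species, gene, tx = parse_reference_name(rec.id, annotation)
            transcripts.append(
                TranscriptInfo(tx, gene, species, len(rec.seq), str(rec.seq).upper())
            )
        return cls(transcripts)


def parse_reference_name(
    name: str, annotation: Mapping[str, str] | None = None
) -> tuple[str, str, str]:
    """Split ``hs|GENE|TX`` or ``hs|TX`` (+annotation) into (species, gene, tx)."""
    parts = name.split("|")
    if parts[0] not in SPECIES_PREFIX:
        raise ValueError(f"reference {name!r} lacks an hs|/mm| species prefix")
    species = SPECIES_PREFIX[parts[0]]
    if len(parts) >= 3:
        return species, parts[1], parts[2]
    tx = parts[1]
    if annotation is None or tx not in annotation:
        raise ValueError(f"no gene annotation for transcript {tx!r}")
    return species, annotation[tx], tx


def assign_pair(pair: AlignedPair, max_mismatches: int | None = None) -> Assignment:
    """Assign a pair to (species, gene) by the deterministic best-hit rule.

    Placements with the fewest total mismatches win; a tie across species or
    across different genes of one species excludes the pair.  Multiple
    splice-variant placements of one gene are a single candidate.
    """
    placements = pair.placements
    if max_mismatches is not None:
        placements = [p for p in placements if p.mismatches <= max_mismatches]
    if not placements:
        return Assignment(pair.read_id, "excluded", reason="unmapped")
    best_mm = min(p.mismatches for p in placements)
    best = [p for p in placements if p.mismatches == best_mm]
    genes = {(p.species, p.gene_id) for p in best}
    if len(genes) == 1:
        species, gene = next(iter(genes))
        # deterministic representative placement among splice variants
        chosen = min(best, key=lambda p: (p.transcript_id, p.start))
        return Assignment(pair.read_id, "assigned", species, gene, placement=chosen)
    if len({p.species for p in best}) > 1:
        reason = "cross-species tie"
    else:
        reason = "multi-gene tie"
    return Assignment(pair.read_id, "excluded", reason=reason)


@dataclass
class AssignedPairCounts:
    """Per-gene positional counts plus assignment tallies.

    ``coverage[(species, gene)][j]`` counts pairs covering the (j+1)-th
    nucleotide from the poly-A tail; ``read_start`` counts pairs whose
    3'-proximal fragment end lies there.  Both vectors have the length of
    the gene's representative transcript.
    """

    coverage: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    read_start: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    assigned: dict[str, int] = field(default_factory=lambda: {HUMAN: 0, MOUSE: 0})
    excluded: dict[str, int] = field(default_factory=dict)
    dropped_out_of_bounds: int = 0

    @property
    def total_pairs(self) -> int:
        return sum(self.assigned.values()) + sum(self.excluded.values())

    def gene_read_totals(self, species: str) -> dict[str, float]:
        return {
            gene: float(v.sum())
            for (sp, gene), v in self.read_start.items()
            if sp == species
        }


def accumulate_counts(
    assignments: Iterable[Assignment], transcripts: TranscriptSet
) -> AssignedPairCounts:
    """Accumulate coverage and read-start vectors from assignments.

    Each assigned pair increments coverage over its fragment span and the
    read-start vector once, at the fragment end nearest the poly-A tail.
    Positions are re-indexed as distance from the 3' end and projected onto
    the gene's representative transcript; distances beyond its length (or
    fragments outside the source transcript) are dropped with a warning.
    """
    counts = AssignedPairCounts()
    for a in assignments:
        if not a.assigned:
            counts.excluded[a.reason] = counts.excluded.get(a.reason, 0) + 1
            continue
        p = a.placement
        src = transcripts.by_id[p.transcript_id]
        if p.start < 0 or p.end > src.length or p.end <= p.start:
            counts.dropped_out_of_bounds += 1
            logger.warning("pair %s outside transcript bounds; dropped", a.read_id)
            continue
        key = (a.species, a.gene_id)
        rep = transcripts.representative(a.species, a.gene_id)
        if key not in counts.coverage:
            counts.coverage[key] = np.zeros(rep.length, dtype=np.int64)
            counts.read_start[key] = np.zeros(rep.length, dtype=np.int64)
        counts.assigned[a.species] += 1
        n = src.length
        # distance-from-poly-A of transcript position q (0-based) is n - q;
        # array index is distance - 1
        d_lo = n - p.end  # index of the 3'-most covered nucleotide
        d_hi = n - p.start  # one past the 5'-most covered nucleotide
        d_hi = min(d_hi, rep.length)
        if d_lo < rep.length:
            counts.coverage[key][d_lo:d_hi] += 1
            counts.read_start[key][d_lo] += 1
    return counts


@dataclass(frozen=True)
class SampleSummary:
    total_pairs: int
    assigned_human: int
    assigned_mouse: int
    excluded: int
    mouse_percent: float
    misassignment_percent: float | None = None
    truth_species: str | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def summarize_sample(
    counts: AssignedPairCounts | None = None,
    truth_species: str | None = None,
    *,
    assigned_human: int | None = None,
    assigned_mouse: int | None = None,
    total_pairs: int | None = None,
) -> SampleSummary:
    """Sample-level tallies: mouse-read percentage and misassignment rate.

    The mouse percentage is 100·d/(c+d) for c pairs assigned human and d
    assigned mouse, rounded to 2 decimals.  When ``truth_species`` is given
    (single-species sample), the misassignment rate is the percentage of
    assigned pairs on the wrong species, rounded to 4 decimals.  Tallies may
    come from an :class:`AssignedPairCounts` or be passed directly.
    """
    if counts is not None:
        c = counts.assigned[HUMAN]
        d = counts.assigned[MOUSE]
        total = counts.total_pairs
    else:
        if assigned_human is None or assigned_mouse is None:
            raise ValueError("need counts or explicit assigned_human/assigned_mouse")
        c, d = assigned_human, assigned_mouse
        total = total_pairs if total_pairs is not None else c + d
    if c + d == 0:
        raise ValueError("no assigned pairs: sample summary undefined")
    mouse_percent = round(100.0 * d / (c + d), 2)
    misassignment = None
    if truth_species is not None:
        wrong = d if truth_species == HUMAN else c
        misassignment = round(100.0 * wrong / (c + d), 4)
    return SampleSummary(
        total_pairs=total,
        assigned_human=c,
        assigned_mouse=d,
        excluded=total - c - d,
        mouse_percent=mouse_percent,
        misassignment_percent=misassignment,
        truth_species=truth_species,
    )


# ---------------------------------------------------------------------------
# input readers


def read_placements_tsv(path: str | Path) -> Iterator[AlignedPair]:
    """Read a pre-tabulated placements TSV.

    Columns: read_id, species, transcript, gene, start, end, mismatches.
    Rows for one read id must be contiguous (they are grouped in order).
    """
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str}, comment="#")
    for read_id, grp in df.groupby("read_id", sort=False):
        placements = [
            Placement(
                species=row.species,
                transcript_id=row.transcript,
                gene_id=str(row.gene),
                start=int(row.start),
                end=int(row.end),
                mismatches=int(row.mismatches),
            )
            for row in grp.itertuples(index=False)
        ]
        yield AlignedPair(read_id=str(read_id), placements=placements)


def write_placements_tsv(pairs: Iterable[AlignedPair], path: str | Path) -> None:
    rows = []
    for pair in pairs:
        for p in pair.placements:
            rows.append(
                (pair.read_id, p.species, p.transcript_id, p.gene_id,
                 p.start, p.end, p.mismatches)
            )
    pd.DataFrame(
        rows,
        columns=["read_id", "species", "transcript", "gene", "start", "end",
                 "mismatches"],
    ).to_csv(path, sep="\t", index=False)


def read_placements_sam(
    path: str | Path, annotation: Mapping[str, str] | None = None
) -> Iterator[AlignedPair]:
    """Group a (queryname-collated) SAM of paired alignments into AlignedPairs.

    Reference names carry the ``hs|``/``mm|`` species prefix.  Mate records
    sharing a reference are joined into a fragment placement; per-mate
    mismatches are taken from the NM tag and summed.  Mates that never share
    a reference yield a pair with no valid placements (excluded downstream).
    """
    import pysam

    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        current: str | None = None
        bucket: list = []
        for rec in sam:
            if rec.is_unmapped:
                continue
            if current is not None and rec.query_name != current:
                yield _pair_from_sam_records(current, bucket, annotation)
                bucket = []
            current = rec.query_name
            bucket.append(rec)
        if current is not None:
            yield _pair_from_sam_records(current, bucket, annotation)


def _pair_from_sam_records(read_id, records, annotation) -> AlignedPair:
    by_ref: dict[str, dict[bool, list]] = defaultdict(lambda: {True: [], False: []})
    for rec in records:
        by_ref[rec.reference_name][rec.is_read1].append(rec)
    placements = []
    for ref, mates in by_ref.items():
        if not mates[True] or not mates[False]:
            continue  # both mates must hit the same transcript
        r1 = min(mates[True], key=lambda r: r.reference_start)
        r2 = min(mates[False], key=lambda r: r.reference_start)
        species, gene, tx = parse_reference_name(ref, annotation)
        mm = int(r1.get_tag("NM")) + int(r2.get_tag("NM"))
        start = min(r1.reference_start, r2.reference_start)
        end = max(r1.reference_end, r2.reference_end)
        placements.append(Placement(species, tx, gene, start, end, mm))
    return AlignedPair(read_id=read_id, placements=placements)


def write_counts_tsv(counts: AssignedPairCounts, path: str | Path) -> None:
    """Sparse dump of nonzero positions: species, gene, j, coverage, read_start."""
    rows = []
    for (species, gene), cov in sorted(counts.coverage.items()):
        cs = counts.read_start[(species, gene)]
        nz = np.nonzero((cov > 0) | (cs > 0))[0]
        for j in nz:
            rows.append((species, gene, int(j) + 1, int(cov[j]), int(cs[j])))
    pd.DataFrame(
        rows, columns=["species", "gene", "j", "coverage", "read_start"]
    ).to_csv(path, sep="\t", index=False)
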