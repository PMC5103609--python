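"""Per-nucleotide k-mer mappability over the combined two-species transcript set.

A 50 bp window of a transcript is *unique* when no other location in the
combined human+mouse database matches it within the mismatch tolerance.
Hits on other splice variants of the same gene (same species) do not break
uniqueness — the downstream model is gene-level.  Reverse-complement hits
are counted by default, since reads align to either strand of a transcript
database in practice; this can be disabled for strand-specific fixtures.

The per-nucleotide track ``m_j`` is the number of unique windows covering
the j-th nucleotide (an integer in [0, k]); a homologous region shared
verbatim across species therefore drops to 0 and its flanks ramp down.

Duplicate detection is done with exact k-mer hashing on 2-bit encoded
sequence; the 1-mismatch tolerance uses a pigeonhole split into two
half-window seeds (a window pair within Hamming distance 1 shares at least
one exact half) with verification against the candidate sequence.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from xenolink.assignment import TranscriptSet

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
    _CODE[b + 32] = i
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}
#: bits reserved for the window position in a packed candidate id
_POS_BITS = 24


def encode_sequence(seq: str) -> np.ndarray:
    """2-bit encode; non-ACGT becomes 255 (never matches anything)."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    return arr


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    valid = out < 4
    out[valid] = 3 - out[valid]
    return out


def _seed_values(codes: np.ndarray, length: int, offset: int, n_windows: int) -> np.ndarray:
    """Packed integer value of codes[s+offset : s+offset+length] per window start s."""
    vals = np.zeros(n_windows, dtype=np.uint64)
    bad = np.zeros(n_windows, dtype=bool)
    for i in range(length):
        chunk = codes[offset + i : offset + i + n_windows]
        bad |= chunk >= 4
        vals = (vals << np.uint64(2)) | chunk.astype(np.uint64)
    # poison ambiguous-base windows so they never collide
    vals[bad] = np.uint64(0xFFFFFFFFFFFFFFFF)
    return vals


@dataclass
class MappabilityTrack:
    """Uniqueness flags and per-nucleotide mappability for one gene.

    ``window_flags`` is in transcript (5'→3') orientation, one flag per
    window start.  ``m`` is per-nucleotide, indexed by distance from the
    poly-A tail (index 0 = 3'-terminal nucleotide), matching the count
    vectors of :mod:`xenolink.assignment`.
    """

    species: str
    gene_id: str
    transcript_id: str
    k: int
    window_flags: np.ndarray
    m: np.ndarray


class MappabilityIndex:
    """k-mer index over all transcripts of a combined two-species database."""

    def __init__(
        self,
        transcripts: TranscriptSet,
        k: int = 50,
        max_mismatches: int = 1,
        check_revcomp: bool = True,
    ):
        if max_mismatches not in (0, 1):
            raise ValueError("max_mismatches must be 0 or 1")
        self.transcripts = transcripts
        self.k = k
        self.max_mismatches = max_mismatches
        self.check_revcomp = check_revcomp
        self._half = k // 2
        self._tx_ids: list[str] = []
        self._tx_index: dict[str, int] = {}
        self._tx_gene: list[tuple[str, str]] = []
        self._codes: dict[str, np.ndarray] = {}
        self._rc_codes: dict[str, np.ndarray] = {}
        # seed value -> list of encoded (tx_idx, window_start, strand) ints
        self._left: dict[int, list[int]] = defaultdict(list)
        self._right: dict[int, list[int]] = defaultdict(list)
        self._build()

    def _strands(self):
        return ("+", "-") if self.check_revcomp else ("+",)

    def _build(self) -> None:
        k, h = self.k, self._half
        self._tx_ids = list(self.transcripts.by_id)
        self._tx_index = {t: i for i, t in enumerate(self._tx_ids)}
        self._tx_gene = [
            (self.transcripts.by_id[t].species, self.transcripts.by_id[t].gene_id)
            for t in self._tx_ids
        ]
        for tx_id, info in self.transcripts.by_id.items():
            if info.sequence is None:
                raise ValueError(f"transcript {tx_id} has no sequence")
            codes = encode_sequence(info.sequence)
            self._codes[tx_id] = codes
            self._rc_codes[tx_id] = revcomp_codes(codes)
            n_win = info.length - k + 1
            if n_win <= 0:
                continue
            tx_idx = self._tx_index[tx_id]
            for strand_bit, strand in enumerate(self._strands()):
                c = codes if strand == "+" else self._rc_codes[tx_id]
                left = _seed_values(c, h, 0, n_win)
                right = _seed_values(c, k - h, h, n_win)
                base = (tx_idx << _POS_BITS + 1) | strand_bit
                for s in range(n_win):
                    cand = base | (s << 1)
                    self._left[int(left[s])].append(cand)
                    self._right[int(right[s])].append(cand)

    def _decode(self, cand: int) -> tuple[str, int, str]:
        strand = "-" if cand & 1 else "+"
        pos = (cand >> 1) & ((1 << _POS_BITS) - 1)
        tx_id = self._tx_ids[cand >> (_POS_BITS + 1)]
        return tx_id, pos, strand

    def _window_codes(self, tx_id: str, start: int, strand: str) -> np.ndarray:
        c = self._codes[tx_id] if strand == "+" else self._rc_codes[tx_id]
        return c[start : start + self.k]

    def window_unique(self, transcript_id: str, start: int) -> int:
        """1 iff the k-mer at ``start`` occurs nowhere else outside its gene.

        "Elsewhere" means any window (either strand when reverse-complement
        checking is on) of a transcript belonging to a different (species,
        gene), within the mismatch tolerance.
        """
        info = self.transcripts.by_id[transcript_id]
        if start < 0 or start + self.k > info.length:
            raise ValueError(
                f"window [{start}, {start + self.k}) outside {transcript_id}"
            )
        k, h = self.k, self._half
        codes = self._codes[transcript_id]
        win = codes[start : start + k]
        if np.any(win >= 4):
            return 0  # ambiguous bases: treat as unmappable
        left_val = 0
        for v in win[:h]:
            left_val = (left_val << 2) | int(v)
        right_val = 0
        for v in win[h:]:
            right_val = (right_val << 2) | int(v)
        own_gene = (info.species, info.gene_id)
        seen: set[int] = set()
        for index, val in ((self._left, left_val), (self._right, right_val)):
            for cand in index.get(val, ()):
                if cand in seen:
                    continue
                seen.add(cand)
                if self._tx_gene[cand >> (_POS_BITS + 1)] == own_gene:
                    continue
                cand_tx, cand_start, cand_strand = self._decode(cand)
                other = self._window_codes(cand_tx, cand_start, cand_strand)
                if int(np.count_nonzero(win != other)) <= self.max_mismatches:
                    return 0
        return 1

    def gene_track(self, species: str, gene_id: str) -> MappabilityTrack:
        """Window flags + per-nucleotide m for a gene's representative transcript."""
        rep = self.transcripts.representative(species, gene_id)
        k, h = self.k, self._half
        codes = self._codes[rep.transcript_id]
        n_win = max(rep.length - k + 1, 0)
        flags = np.zeros(n_win, dtype=np.int8)
        if n_win:
            left = _seed_values(codes, h, 0, n_win)
            right = _seed_values(codes, k - h, h, n_win)
            poison = np.uint64(0xFFFFFFFFFFFFFFFF)
            own_gene = (species, gene_id)
            for s in range(n_win):
                if left[s] == poison or right[s] == poison:
                    continue  # ambiguous bases: unmappable
                win = codes[s : s + k]
                unique = 1
                for index, val in ((self._left, int(left[s])),
                                   (self._right, int(right[s]))):
                    for cand in index.get(val, ()):
                        if self._tx_gene[cand >> (_POS_BITS + 1)] == own_gene:
                            continue
                        cand_tx, cand_start, cand_strand = self._decode(cand)
                        other = self._window_codes(cand_tx, cand_start, cand_strand)
                        if int(np.count_nonzero(win != other)) <= self.max_mismatches:
                            unique = 0
                            break
                    if not unique:
                        break
                flags[s] = unique
        m = mappable_per_nucleotide(flags, self.k, rep.length)
        return MappabilityTrack(
            species=species,
            gene_id=gene_id,
            transcript_id=rep.transcript_id,
            k=self.k,
            window_flags=flags,
            m=m[::-1].copy(),  # re-index by distance from poly-A
        )


def mappable_per_nucleotide(window_flags: np.ndarray, k: int, length: int) -> np.ndarray:
    """Number of unique windows covering each nucleotide (transcript orientation)."""
    m = np.zeros(length, dtype=np.int32)
    if window_flags.size == 0:
        return m
    # nucleotide j is covered by window starts in [j-k+1, j]
    cum = np.concatenate([[0], np.cumsum(window_flags)])
    starts_lo = np.maximum(np.arange(length) - k + 1, 0)
    starts_hi = np.minimum(np.arange(length), window_flags.size - 1)
    valid = starts_hi >= starts_lo
    m[valid] = cum[starts_hi[valid] + 1] - cum[starts_lo[valid]]
    return m


def compute_mappability(
    transcripts: TranscriptSet,
    k: int = 50,
    max_mismatches: int = 1,
    check_revcomp: bool = True,
) -> dict[tuple[str, str], MappabilityTrack]:
    """Mappability tracks for every gene's representative transcript."""
    index = MappabilityIndex(transcripts, k=k, max_mismatches=max_mismatches,
                             check_revcomp=check_revcomp)
    return {
        (species, gene): index.gene_track(species, gene)
        for species, gene in transcripts.genes()
    }


def write_mappability_tsv(
    tracks: Iterable[MappabilityTrack] | dict, path: str | Path
) -> None:
    """Run-length encoded dump: species, gene, j_start, j_end, m (1-based, from 3')."""
    if isinstance(tracks, dict):
        tracks = tracks.values()
    rows = []
    for t in tracks:
        m = t.m
        if m.size == 0:
            continue
        change = np.nonzero(np.diff(m))[0]
        starts = np.concatenate([[0], change + 1])
        ends = np.concatenate([change, [m.size - 1]])
        for s, e in zip(starts, ends):
            rows.append((t.species, t.gene_id, int(s) + 1, int(e) + 1, int(m[s])))
    pd.DataFrame(rows, columns=["species", "gene", "j_start", "j_end", "m"]).to_csv(
        path, sep="\t", index=False
    )


def read_mappability_tsv(path: str | Path) -> dict[tuple[str, str], np.ndarray]:
    """Inverse of :func:`write_mappability_tsv`; returns per-gene m vectors."""
    df = pd.read_csv(path, sep="\t")
    out: dict[tuple[str, str], np.ndarray] = {}
    for (species, gene), grp in df.groupby(["species", "gene"], sort=False):
        length = int(grp["j_end"].max())
        m = np.zeros(length, dtype=np.int32)
        for row in grp.itertuples(index=False):
            m[row.j_start - 1 : row.j_end] = row.m
        out[(species, gene)] = m
    return out
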