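"""Independent brute-force oracle for window mappability.

Exhaustive window-vs-window Hamming comparison, deliberately sharing no
code with the package's seeded k-mer index.
"""

import numpy as np

from xenolink.assignment import TranscriptSet

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_force_flags(transcripts: TranscriptSet, species, gene, k=50,
                      max_mm=1, check_revcomp=True) -> np.ndarray:
    """Oracle: exhaustive window-vs-window Hamming comparison.

    Independent of the k-mer index: every window of the gene's
    representative transcript is compared against every window (both
    strands when enabled) of every transcript of a different gene.
    """
    rep = transcripts.representative(species, gene)
    seq = rep.sequence
    n_win = len(seq) - k + 1
    flags = np.ones(n_win, dtype=np.int8)
    others = []
    for t in transcripts.by_id.values():
        if (t.species, t.gene_id) == (species, gene):
            continue
        others.append(t.sequence)
        if check_revcomp:
            others.append(_revcomp(t.sequence))
    enc = {c: i for i, c in enumerate("ACGT")}
    win_mat = np.array([[enc[c] for c in seq[s:s + k]] for s in range(n_win)],
                       dtype=np.int8)
    for other in others:
        m = len(other) - k + 1
        if m <= 0:
            continue
        arr = np.array([enc[c] for c in other], dtype=np.int8)
        mism = np.zeros((n_win, m), dtype=np.int16)
        for i in range(k):
            mism += win_mat[:, i][:, None] != arr[i:i + m][None, :]
        flags[np.any(mism <= max_mm, axis=1)] = 0
    return flags


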