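"""Small synthetic example datasets used in tests and demonstrations."""

from __future__ import annotations

import numpy as np

__all__ = ["cluster_strand_sets", "cluster_strand_flags"]

#: Synthetic per-cluster beta-strand table for the 42-mer peptide: for each
#: of twelve representative cluster conformations (six from a free-peptide
#: ensemble, six from a receptor-bound one), the 1-based inclusive residue
#: ranges that form beta strands.  The table is constructed so that the
#: conserved-region grouping rule (beta in more than two clusters, short
#: gaps with residual beta evidence bridged) recovers the five canonical
#: regions A2-H6, Y10-H13, Q15-V24, N27-V36 and G38-I41.  F19 appears in
#: only two clusters and is bridged into the Q15-V24 region; H14, G25-S26
#: and G37 never form strands and separate the regions.
CLUSTER_STRAND_SETS = {
    "C1": [(2, 6), (15, 18), (20, 24), (27, 36)],
    "C2": [(10, 13), (38, 41)],
    "C3": [(15, 18), (20, 22), (28, 36), (39, 41)],
    "C4": [(2, 6), (10, 13), (16, 24), (28, 35)],
    "C5": [(15, 24), (27, 36), (38, 41)],
    "C6": [(2, 6), (10, 13), (16, 18), (20, 23), (29, 36)],
    "C1p": [(15, 18), (27, 31), (33, 36)],
    "C2p": [(15, 18), (30, 36), (38, 41)],
    "C3p": [(30, 36), (38, 41)],
    "C4p": [(27, 33), (39, 41)],
    "C5p": [(10, 12), (15, 17)],
    "C6p": [(2, 5), (16, 18), (38, 41)],
}


def cluster_strand_sets() -> dict:
    """The synthetic per-cluster strand table (1-based inclusive ranges)."""
    return {k: list(v) for k, v in CLUSTER_STRAND_SETS.items()}


def cluster_strand_flags(n_residues: int = 42) -> np.ndarray:
    """The strand table as a (clusters x residues) boolean matrix (0-based)."""
    flags = np.zeros((len(CLUSTER_STRAND_SETS), n_residues), dtype=bool)
    for row, ranges in enumerate(CLUSTER_STRAND_SETS.values()):
        for lo, hi in ranges:
            flags[row, lo - 1:hi] = True
    return flags
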