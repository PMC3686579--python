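"""Pairwise-alignment helpers shared by read QC, chimera screening and OTU
clustering.

Two engines are used deliberately:

* edlib — unit-cost global alignment with an extended-CIGAR path. Fast enough
  for all-vs-all identity (clustering, taxonomy) and per-position match
  profiles (chimera screening).
* Bio.Align.PairwiseAligner — affine-gap, end-free global alignment used once
  per read for reading-frame classification, where gap-run consolidation
  matters (match +1, mismatch −2, gap open −10, extend −1; end gaps free).
"""

from __future__ import annotations

import re
from functools import lru_cache

import edlib
import numpy as np
from Bio import Align

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _cigar_ops(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment columns, end-gap columns
    excluded from the denominator. Identical sequences -> 1.0."""
    if a == b:
        return 1.0
    res = edlib.align(a, b, task="path", mode="NW")
    ops = _cigar_ops(res["cigar"])
    # trim terminal indel runs (end gaps)
    while ops and ops[0][1] in "ID":
        ops = ops[1:]
    while ops and ops[-1][1] in "ID":
        ops = ops[:-1]
    matches = sum(n for n, op in ops if op == "=")
    columns = sum(n for n, op in ops)
    return matches / columns if columns else 0.0


def dissimilarity(a: str, b: str) -> float:
    return 1.0 - pairwise_identity(a, b)


def edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance", mode="NW")["editDistance"]


def match_profile(read: str, ref: str) -> np.ndarray:
    """Boolean array over read positions: True where the global alignment to
    ``ref`` places a matching base."""
    out = np.zeros(len(read), dtype=bool)
    res = edlib.align(read, ref, task="path", mode="NW")
    qpos = 0
    for n, op in _cigar_ops(res["cigar"]):
        if op == "=":
            out[qpos:qpos + n] = True
            qpos += n
        elif op in ("X", "M"):
            qpos += n
        elif op == "I":  # extra bases in read
            qpos += n
        # 'D': consumes ref only
    return out


@lru_cache(maxsize=8)
def _aligner(match: float, mismatch: float, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = -abs(gap_open)
    al.extend_gap_score = -abs(gap_extend)
    al.end_insertion_score = 0  # free end gaps in the target
    al.end_deletion_score = 0   # free end gaps in the query
    return al


def endfree_affine_align(read: str, ref: str, match: float = 1, mismatch: float = -2,
                         gap_open: float = 10, gap_extend: float = 1):
    """One optimal end-free affine alignment of ``read`` (query) against
    ``ref`` (target). Returns the Bio.Align.Alignment."""
    al = _aligner(match, mismatch, gap_open, gap_extend)
    return al.align(ref, read)[0]


def alignment_gap_runs(alignment) -> tuple[list[tuple[int, int, int]], list[tuple[int, int, int]], int, int]:
    """Internal gap runs of a Bio.Align alignment (target=ref, query=read).

    Returns (read_insertions, read_deletions, ref_start, read_start) where each
    run is (run_length, ref_position, read_position) at the run start, with
    positions in the original sequences. Terminal overhangs (end gaps) are not
    reported. ref_start/read_start are the coordinates where the aligned core
    begins.
    """
    tblocks, qblocks = alignment.aligned  # target (ref), query (read) blocks
    insertions: list[tuple[int, int, int]] = []
    deletions: list[tuple[int, int, int]] = []
    if len(tblocks) == 0:
        return insertions, deletions, 0, 0
    for i in range(1, len(tblocks)):
        t_gap = int(tblocks[i][0] - tblocks[i - 1][1])
        q_gap = int(qblocks[i][0] - qblocks[i - 1][1])
        ref_pos = int(tblocks[i - 1][1])
        read_pos = int(qblocks[i - 1][1])
        if q_gap > 0:  # extra read bases not in ref
            insertions.append((q_gap, ref_pos, read_pos))
        if t_gap > 0:  # ref bases missing from read
            deletions.append((t_gap, ref_pos, read_pos))
    return insertions, deletions, int(tblocks[0][0]), int(qblocks[0][0])
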