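"""Pairwise global alignment helpers shared by the QC and profile builders.

Wraps Bio.Align.PairwiseAligner with affine gap penalties (match +2,
mismatch -1, gap open -10, gap extend -1 by default) and free terminal
gaps, so truncated reads align without penalty while short spurious
internal gaps are strongly discouraged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align


def make_aligner(
    match: float = 2.0,
    mismatch: float = -1.0,
    open_gap: float = -10.0,
    extend_gap: float = -1.0,
    free_end_gaps: bool = True,
) -> Align.PairwiseAligner:
    """Affine-gap global aligner.

    With ``free_end_gaps`` (the nucleotide QC default) terminal gaps cost
    nothing, so truncated reads and trailing junction sequence hang off the
    reference unpenalized; without it (the amino acid profile default)
    terminal mismatches are aligned rather than trimmed.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    if free_end_gaps:
        try:
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # older Bio.Align releases
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
    return aligner


@dataclass
class AlignmentMap:
    """Global alignment of a query against a reference (target).

    ``mapping[i]`` is the query index aligned to reference position ``i``,
    or -1 where the reference position falls in a gap (including the
    unaligned terminal overhangs). ``gap_runs`` lists the lengths of
    internal gap runs in either sequence. ``identity`` is matches over
    alignment columns inside the aligned span (terminal gaps excluded).
    """

    mapping: np.ndarray
    gap_runs: list[int]
    identity: float
    score: float


def align_map(aligner: Align.PairwiseAligner, reference: str, query: str) -> AlignmentMap:
    alignment = aligner.align(reference, query)[0]
    t_blocks, q_blocks = alignment.aligned
    mapping = np.full(len(reference), -1, dtype=np.int64)
    matches = 0
    aligned_cols = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        mapping[ts:te] = np.arange(qs, qe)
        aligned_cols += te - ts
        for t, q in zip(range(ts, te), range(qs, qe)):
            if reference[t] == query[q]:
                matches += 1
    gap_runs: list[int] = []
    for i in range(len(t_blocks) - 1):
        dt = int(t_blocks[i + 1][0] - t_blocks[i][1])  # gap in query
        dq = int(q_blocks[i + 1][0] - q_blocks[i][1])  # gap in reference
        if dt > 0:
            gap_runs.append(dt)
        if dq > 0:
            gap_runs.append(dq)
    if aligned_cols == 0:
        return AlignmentMap(mapping, gap_runs, 0.0, float(alignment.score))
    columns = aligned_cols + sum(gap_runs)
    return AlignmentMap(
        mapping=mapping,
        gap_runs=gap_runs,
        identity=matches / columns,
        score=float(alignment.score),
    )
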