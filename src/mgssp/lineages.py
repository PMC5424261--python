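"""Clonal lineage clustering and representative selection.

A clonal lineage groups transcripts with the same V gene, same J gene,
equal-length CDR3 (junction), and at least 90% CDR3 nucleotide identity
under single linkage — the connectivity rule that turns the pairwise
criterion into a partition. One representative per lineage (the member
closest to the lineage consensus) carries the lineage into profile
building; single-transcript lineages are discarded because their
substitutions cannot be distinguished from sequencing error.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class Lineage:
    lineage_id: str
    v_gene: str
    j_gene: str
    cdr3_length: int
    member_ids: list[str]
    representative_id: str | None = None

    @property
    def size(self) -> int:
        return len(self.member_ids)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _hamming_identity(a: str, b: str) -> float:
    matches = sum(x == y for x, y in zip(a, b))
    return matches / len(a)


def cluster_lineages(
    transcripts,
    identity_threshold: float = 0.90,
    min_size: int = 2,
) -> list[Lineage]:
    """Single-linkage clonal clustering of pass-QC transcripts.

    Transcripts are partitioned by (V gene, J gene, CDR3 length) and then
    joined whenever a pair of CDR3s reaches ``identity_threshold`` Hamming
    identity (boundary inclusive). Lineages smaller than ``min_size``
    (singletons, by default) are excluded; transcripts lacking a junction
    are skipped with a logged count. Output is independent of input order.
    """
    groups: dict[tuple, list] = {}
    n_missing = 0
    for t in transcripts:
        if not t.junction_nt:
            n_missing += 1
            continue
        key = (t.v_gene, t.j_gene, len(t.junction_nt))
        groups.setdefault(key, []).append(t)
    if n_missing:
        logger.info("clustering: %d transcripts skipped (missing junction)", n_missing)

    lineages: list[Lineage] = []
    n_singletons = 0
    for (v_gene, j_gene, cdr3_len) in sorted(groups, key=str):
        members = sorted(groups[(v_gene, j_gene, cdr3_len)], key=lambda t: t.id)
        uf = _UnionFind(len(members))
        for i, j in itertools.combinations(range(len(members)), 2):
            if (
                _hamming_identity(members[i].junction_nt, members[j].junction_nt)
                >= identity_threshold
            ):
                uf.union(i, j)
        clusters: dict[int, list] = {}
        for i, t in enumerate(members):
            clusters.setdefault(uf.find(i), []).append(t)
        for root in sorted(clusters):
            ids = sorted(t.id for t in clusters[root])
            if len(ids) < min_size:
                n_singletons += 1
                continue
            lineages.append(
                Lineage(
                    lineage_id=f"{v_gene}_{j_gene}_{cdr3_len}_{ids[0]}",
                    v_gene=v_gene,
                    j_gene=j_gene,
                    cdr3_length=cdr3_len,
                    member_ids=ids,
                )
            )
    if n_singletons:
        logger.info("clustering: %d lineages below size %d discarded",
                    n_singletons, min_size)
    return lineages


def consensus_sequence(seqs: list[str]) -> str:
    """Per-column majority-rule nucleotide consensus.

    Ties within a column are resolved by alphabetical base. Sequences of
    unequal length are compared over the shortest common length; trailing
    bases follow the majority of sequences long enough to cover them.
    """
    length = max(len(s) for s in seqs)
    out = []
    for col in range(length):
        counts: dict[str, int] = {}
        for s in seqs:
            if col < len(s):
                counts[s[col]] = counts.get(s[col], 0) + 1
        best = min(counts, key=lambda b: (-counts[b], b))
        out.append(best)
    return "".join(out)


def select_representative(lineage: Lineage, sequences: dict[str, str]) -> str:
    """Pick the member closest to the lineage consensus.

    ``sequences`` maps member id -> full-length nucleotide sequence. The
    member with the fewest mismatches to the majority consensus wins; ties
    go to the lexicographically smallest id. Sets and returns
    ``lineage.representative_id``.
    """
    member_seqs = {mid: sequences[mid] for mid in lineage.member_ids}
    cons = consensus_sequence(list(member_seqs.values()))

    def distance(mid: str) -> int:
        s = member_seqs[mid]
        d = sum(a != b for a, b in zip(s, cons))
        return d + abs(len(cons) - len(s))

    best = min(sorted(member_seqs), key=lambda mid: (distance(mid), mid))
    lineage.representative_id = best
    return best


def representative_robustness(
    lineages: list[Lineage],
    sequences: dict[str, str],
    gene,
    trials: int = 100,
    seed: int = 0,
    min_members: int = 10,
    min_count: int = 1,
) -> np.ndarray:
    """Sensitivity of rarity scores to the choice of lineage representative.

    For each trial a random member of every qualifying lineage (at least
    ``min_members`` members) stands in as representative, a profile is
    rebuilt from the trial's representatives, and its rarity table
    computed. Returns the Pearson correlations between the rarity tables
    of every pair of trials.
    """
    from mgssp.compare import rarity_correlation
    from mgssp.profile import build_gssp, rarity_of, translate_nt

    qualifying = [lin for lin in lineages if lin.size >= min_members]
    if len(qualifying) < 2:
        raise ValueError(
            f"need >= 2 lineages with >= {min_members} members, got {len(qualifying)}"
        )
    rng = np.random.default_rng(seed)
    tables = []
    for _ in range(trials):
        reps = [
            translate_nt(sequences[rng.choice(lin.member_ids)]) for lin in qualifying
        ]
        gssp = build_gssp(reps, gene, min_count=min_count, warn_below=0)
        tables.append(rarity_of(gssp))
    corrs = [
        rarity_correlation(tables[i], tables[j])
        for i, j in itertools.combinations(range(trials), 2)
    ]
    return np.asarray(corrs)
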