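"""Gene-specific substitution profiles (GSSPs).

A GSSP records, for every position of a germline V gene, the substitution
frequency m (fraction of clonal lineages carrying a non-germline residue
there) and the substitution bias f (among mutated lineages, the frequency
of each particular replacement residue). The rarity of substitution a at
position i is r = 1 - m_i * f_i,a: the per-lineage improbability of that
substitution, undefined for germline residues and exactly 1.0 for
substitutions never observed.

Representatives are aligned (amino acid level, global) to the best-matching
allele of their gene; positions are mapped to IMGT labels through that
allele, and residues appearing in any allele of the gene are treated as
germline polymorphism, never as substitution. Gaps and undefined residues
(X) are excluded from counting.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from mgssp._align import align_map, make_aligner
from mgssp.germline import GermlineGene

logger = logging.getLogger(__name__)

#: The 20 amino acids in alphabetical one-letter order; the column order of
#: every f vector and of the GSSP TSV format.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}


def translate_nt(nt_seq: str) -> str:
    """Codon-wise translation truncated to full codons (N -> X)."""
    usable = len(nt_seq) - len(nt_seq) % 3
    return str(Seq(nt_seq[:usable]).translate())


@dataclass
class PositionProfile:
    """Substitution counts and frequencies at one V-gene position."""

    position: int
    germline_residues: frozenset[str]
    n_covered: int = 0
    n_mutated: int = 0
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def m(self) -> float:
        """Substitution frequency: mutated lineages / covered lineages."""
        return self.n_mutated / self.n_covered if self.n_covered else 0.0

    @property
    def f(self) -> np.ndarray:
        """20-way substitution bias over AA_ORDER; zero at germline residues,
        sums to 1 when any substitution was observed, all-zero otherwise."""
        vec = np.zeros(20)
        total = sum(self.counts.values())
        if total:
            for aa, n in self.counts.items():
                vec[AA_INDEX[aa]] = n / total
        return vec


@dataclass
class GSSP:
    """Substitution profile of one germline V gene."""

    gene: str
    numbering_dialect: str
    n_lineages: int
    positions: list[PositionProfile]
    simulated: bool = False

    @property
    def by_position(self) -> dict[int, PositionProfile]:
        return {p.position: p for p in self.positions}

    def m_series(self) -> pd.Series:
        return pd.Series(
            {p.position: p.m for p in self.positions}, name="substitution_frequency"
        )


@dataclass
class RarityTable:
    """Rarity r = 1 - m*f keyed by (gene, position, amino acid).

    Entries exist only for non-germline residues; r = 1.0 exactly for
    substitutions never observed.
    """

    entries: dict[tuple[str, int, str], float]

    def values_for(self, keys) -> np.ndarray:
        return np.asarray([self.entries[k] for k in keys])

    def shared_keys(self, other: "RarityTable") -> list[tuple[str, int, str]]:
        return sorted(set(self.entries) & set(other.entries))


def make_aa_aligner():
    # end gaps are penalized so substitutions at the first/last positions
    # are aligned (and counted) rather than trimmed off
    return make_aligner(free_end_gaps=False)


def _best_allele(aa_seq: str, gene: GermlineGene, aligner=None):
    """Best-scoring allele for an amino acid sequence (ties: smallest name)."""
    if aligner is None:
        aligner = make_aa_aligner()
    best = None
    for allele in sorted(gene.alleles, key=lambda a: a.allele_name):
        am = align_map(aligner, allele.aa_seq, aa_seq)
        if best is None or am.score > best[1].score:
            best = (allele, am)
    return best


def align_to_germline(
    representative_aa: str,
    gene: GermlineGene,
    aligner=None,
    min_identity: float = 0.5,
) -> dict[int, str] | None:
    """Observed residue per position label for one representative.

    The representative is globally aligned to its best-matching allele and
    columns mapped to position labels through that allele. Gap columns and
    X residues are uncovered (absent from the result). Returns None (and
    logs a warning) when alignment identity falls below ``min_identity``.
    """
    allele, am = _best_allele(representative_aa, gene, aligner)
    if am.identity < min_identity:
        logger.warning(
            "representative excluded: %.2f identity to %s",
            am.identity,
            allele.allele_name,
        )
        return None
    observed: dict[int, str] = {}
    for k, label in enumerate(allele.imgt_map):
        q = am.mapping[k]
        if q < 0:
            continue
        aa = representative_aa[q]
        if aa in ("X", "*"):
            continue
        observed[label] = aa
    return observed


def build_gssp(
    representatives: list[str],
    gene: GermlineGene,
    min_count: int = 100,
    warn_below: int = 300,
    simulated: bool = False,
    aligner=None,
) -> GSSP:
    """Build the GSSP of ``gene`` from lineage-representative amino acid
    sequences.

    Requires at least ``min_count`` representatives (profiles from fewer
    sequences are unreliable); below ``warn_below`` a convergence warning
    is logged. A lineage counts at most once toward m at a position, and
    residues present in any allele never count as substitutions.
    """
    if len(representatives) < min_count:
        raise ValueError(
            f"{gene.name}: {len(representatives)} representatives, "
            f"need at least {min_count} to build a profile"
        )
    if len(representatives) < warn_below:
        logger.warning(
            "%s: %d lineages < %d; profile may not have converged",
            gene.name,
            len(representatives),
            warn_below,
        )
    if aligner is None:
        aligner = make_aa_aligner()
    residues = gene.germline_residues
    profiles = {
        pos: PositionProfile(position=pos, germline_residues=aas)
        for pos, aas in residues.items()
    }
    # repeated builds (resampling analyses) re-align the same sequences;
    # alignments depend only on (sequence, gene) so memoize on the gene
    cache = gene.__dict__.setdefault("_observation_cache", {})
    n_used = 0
    for rep in representatives:
        if rep not in cache:
            cache[rep] = align_to_germline(rep, gene, aligner=aligner)
        observed = cache[rep]
        if observed is None:
            continue
        n_used += 1
        for pos, aa in observed.items():
            prof = profiles.get(pos)
            if prof is None:
                continue
            prof.n_covered += 1
            if aa not in prof.germline_residues:
                prof.n_mutated += 1
                prof.counts[aa] = prof.counts.get(aa, 0) + 1
    return GSSP(
        gene=gene.name,
        numbering_dialect=gene.numbering_dialect,
        n_lineages=n_used,
        positions=[profiles[pos] for pos in sorted(profiles)],
        simulated=simulated,
    )


def rarity_of(gssp: GSSP) -> RarityTable:
    """Rarity r = 1 - m*f for every possible non-germline substitution."""
    entries: dict[tuple[str, int, str], float] = {}
    for prof in gssp.positions:
        f = prof.f
        for aa in AA_ORDER:
            if aa in prof.germline_residues:
                continue
            entries[(gssp.gene, prof.position, aa)] = 1.0 - prof.m * f[AA_INDEX[aa]]
    return RarityTable(entries)


def merge_gssps(profiles: list[GSSP]) -> GSSP:
    """Pool the underlying counts of several profiles of the same gene.

    Counts (n_covered, n_mutated, per-residue tallies) are summed per
    position and m and f recomputed, exactly as if all lineages had been
    profiled together.
    """
    if not profiles:
        raise ValueError("nothing to merge")
    first = profiles[0]
    merged: dict[int, PositionProfile] = {}
    for g in profiles:
        if g.gene != first.gene:
            raise ValueError(f"gene mismatch: {g.gene} != {first.gene}")
        if g.numbering_dialect != first.numbering_dialect:
            raise ValueError("numbering dialect mismatch")
        for prof in g.positions:
            agg = merged.setdefault(
                prof.position,
                PositionProfile(
                    position=prof.position,
                    germline_residues=prof.germline_residues,
                ),
            )
            if agg.germline_residues != prof.germline_residues:
                agg.germline_residues = agg.germline_residues | prof.germline_residues
            agg.n_covered += prof.n_covered
            agg.n_mutated += prof.n_mutated
            for aa, n in prof.counts.items():
                agg.counts[aa] = agg.counts.get(aa, 0) + n
    return GSSP(
        gene=first.gene,
        numbering_dialect=first.numbering_dialect,
        n_lineages=sum(g.n_lineages for g in profiles),
        positions=[merged[pos] for pos in sorted(merged)],
        simulated=any(g.simulated for g in profiles),
    )


# ---------------------------------------------------------------------------
# GSSP TSV format

_COLUMNS = [
    "position",
    "germline_residues",
    "n_covered",
    "n_mutated",
    "substitution_frequency",
    *AA_ORDER,
]


def write_gssp(gssp: GSSP, path: str | Path) -> None:
    """Write a profile in the mGSSP TSV format (v1)."""
    header = (
        f"#mGSSP v1 gene={gssp.gene} dialect={gssp.numbering_dialect} "
        f"n_lineages={gssp.n_lineages}"
    )
    if gssp.simulated:
        header += " simulated=true"
    lines = [header, "\t".join(_COLUMNS)]
    for prof in gssp.positions:
        f = prof.f
        row = [
            str(prof.position),
            ",".join(sorted(prof.germline_residues)),
            str(prof.n_covered),
            str(prof.n_mutated),
            f"{prof.m:.6f}",
            *(f"{x:.6f}" for x in f),
        ]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gssp(path: str | Path) -> GSSP:
    """Read a profile written by :func:`write_gssp`.

    Per-residue counts are reconstructed from n_mutated and the stored f
    (rounded to the nearest integer), so round-tripping preserves counts.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    if not lines or not lines[0].startswith("#mGSSP v1"):
        raise ValueError(f"{path}: not an mGSSP v1 file")
    meta = dict(
        tok.split("=", 1) for tok in lines[0].removeprefix("#mGSSP v1").split() if "=" in tok
    )
    df = pd.read_csv(io.StringIO("\n".join(lines[1:])), sep="\t", dtype={"germline_residues": str})
    positions = []
    for row in df.itertuples(index=False):
        n_mut = int(row.n_mutated)
        counts: dict[str, int] = {}
        for aa in AA_ORDER:
            n = round(getattr(row, aa) * n_mut)
            if n:
                counts[aa] = int(n)
        positions.append(
            PositionProfile(
                position=int(row.position),
                germline_residues=frozenset((row.germline_residues or "").split(",")) - {""},
                n_covered=int(row.n_covered),
                n_mutated=n_mut,
                counts=counts,
            )
        )
    return GSSP(
        gene=meta["gene"],
        numbering_dialect=meta["dialect"],
        n_lineages=int(meta["n_lineages"]),
        positions=positions,
        simulated=meta.get("simulated") == "true",
    )


def subsample_convergence(
    representatives: list[str],
    gene: GermlineGene,
    sizes: tuple[int, ...] = (25, 50, 100, 200, 300),
    replicates: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Profile convergence as a function of lineage count.

    For each size, ``replicates`` disjoint subsamples are drawn without
    replacement, a profile built from each, and the weighted Jensen-Shannon
    divergence recorded for every replicate pair. Divergence shrinking with
    size indicates the profile has enough lineages to be stable.

    Returns a tidy DataFrame with columns size, rep_a, rep_b, divergence.
    """
    from mgssp.compare import weighted_profile_distance

    rng = np.random.default_rng(seed)
    rows = []
    n = len(representatives)
    for size in sizes:
        if size * replicates > n:
            raise ValueError(
                f"cannot draw {replicates} disjoint subsamples of {size} from {n}"
            )
        perm = rng.permutation(n)
        gssps = []
        for r in range(replicates):
            idx = perm[r * size : (r + 1) * size]
            gssps.append(
                build_gssp(
                    [representatives[i] for i in idx],
                    gene,
                    min_count=1,
                    warn_below=0,
                )
            )
        for a in range(replicates):
            for b in range(a + 1, replicates):
                rows.append(
                    {
                        "size": size,
                        "rep_a": a,
                        "rep_b": b,
                        "divergence": weighted_profile_distance(gssps[a], gssps[b]),
                    }
                )
    return pd.DataFrame(rows)
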