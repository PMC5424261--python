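"""Somatic hypermutation simulation.

Generates virtual antibody repertoires from a germline allele under either
a 5-mer nucleotide-context model (S5F-style: each site's mutability and
substitution preference depend on the two flanking bases on each side) or
a 20x20 amino acid exchange model (AB-style) with positions drawn from an
empirical per-position substitution frequency. Mutations creating internal
stop codons are rejected and redrawn; re-mutation of a previously mutated
site is allowed, so a lineage's final Hamming distance from germline may
be smaller than its event count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from mgssp.germline import GermlineAllele, GermlineGene
from mgssp.profile import AA_INDEX, AA_ORDER, GSSP, build_gssp, translate_nt

BASES = "ACGT"
BASE_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass
class ContextMutabilityModel:
    """5-mer context mutation model: per-5-mer mutability of the center base
    and a substitution distribution over the three alternative bases.

    ``table`` maps 5-mer -> (weight >= 0, probabilities over A,C,G,T with the
    center/germline base at 0); 5-mers absent from the table (for instance
    those containing N) receive ``default_weight``.
    """

    table: dict[str, tuple[float, np.ndarray]]
    default_weight: float = 0.0

    def mutability(self, fivemer: str) -> float:
        entry = self.table.get(fivemer)
        return entry[0] if entry is not None else self.default_weight

    def substitution_row(self, fivemer: str) -> np.ndarray:
        entry = self.table.get(fivemer)
        if entry is not None:
            return entry[1]
        row = np.full(4, 1 / 3)
        center = fivemer[2]
        if center in BASE_IDX:
            row[BASE_IDX[center]] = 0.0
        return row

    @classmethod
    def from_tsv(cls, path: str | Path, default_weight: float = 0.0):
        """Read the TSV layout: fivemer, mutability, p_to_A..p_to_T."""
        df = pd.read_csv(path, sep="\t")
        table = {}
        for row in df.itertuples(index=False):
            probs = np.array([row.p_to_A, row.p_to_C, row.p_to_G, row.p_to_T], float)
            if not np.isclose(probs.sum(), 1.0, atol=1e-9):
                raise ValueError(f"{row.fivemer}: substitution row sums to {probs.sum()}")
            table[str(row.fivemer).upper()] = (float(row.mutability), probs)
        return cls(table=table, default_weight=default_weight)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "fivemer": k,
                "mutability": w,
                "p_to_A": p[0],
                "p_to_C": p[1],
                "p_to_G": p[2],
                "p_to_T": p[3],
            }
            for k, (w, p) in sorted(self.table.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class AminoAcidSubstitutionModel:
    """Row-stochastic 20x20 amino acid exchange matrix, zero diagonal,
    rows and columns in AA_ORDER."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (20, 20):
            raise ValueError("matrix must be 20x20")
        if np.any(m < 0) or not np.allclose(np.diag(m), 0.0):
            raise ValueError("matrix must be non-negative with a zero diagonal")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows must sum to 1")
        self.matrix = m

    def row(self, aa: str) -> np.ndarray:
        return self.matrix[AA_INDEX[aa]]

    @classmethod
    def uniform(cls):
        m = np.full((20, 20), 1 / 19)
        np.fill_diagonal(m, 0.0)
        return cls(m)

    @classmethod
    def from_tsv(cls, path: str | Path):
        """21-column TSV: row residue then 20 probabilities in AA_ORDER."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.loc[list(AA_ORDER), list(AA_ORDER)].to_numpy(float))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix, index=list(AA_ORDER), columns=list(AA_ORDER)).to_csv(
            path, sep="\t", index_label="residue"
        )


@dataclass
class SimulatedLineage:
    id: str
    allele_name: str
    nt_seq: str
    n_events: int
    seed: int


def site_mutabilities(seq: str, model: ContextMutabilityModel) -> np.ndarray:
    """Per-site mutation probabilities under the 5-mer context model.

    The two terminal positions at each end lack a complete 5-mer and get
    probability zero; interior weights are normalized to sum to 1.
    """
    if len(seq) < 5:
        raise ValueError("sequence shorter than one 5-mer")
    weights = np.zeros(len(seq))
    for i in range(2, len(seq) - 2):
        weights[i] = model.mutability(seq[i - 2 : i + 3])
    total = weights.sum()
    if total <= 0:
        raise ValueError("no site has positive mutability")
    return weights / total


def _has_internal_stop(nt_seq: str) -> bool:
    return "*" in translate_nt(nt_seq)


def mutate_once(
    seq: str,
    model: ContextMutabilityModel,
    rng: np.random.Generator,
    max_rejections: int = 1000,
) -> str:
    """Apply one accepted point mutation.

    The site is drawn from the context mutabilities of the current
    sequence, the replacement base from that 5-mer's substitution row
    (current base excluded). Draws creating an internal stop codon are
    fully redrawn (site and base), up to ``max_rejections`` times.
    """
    probs = site_mutabilities(seq, model)
    sites = np.arange(len(seq))
    for _ in range(max_rejections):
        site = int(rng.choice(sites, p=probs))
        row = model.substitution_row(seq[site - 2 : site + 3]).copy()
        if seq[site] in BASE_IDX:
            row[BASE_IDX[seq[site]]] = 0.0
        total = row.sum()
        if total <= 0:
            continue
        base = BASES[int(rng.choice(4, p=row / total))]
        candidate = seq[:site] + base + seq[site + 1 :]
        if not _has_internal_stop(candidate):
            return candidate
    raise RuntimeError(
        f"no stop-free mutation found after {max_rejections} rejections"
    )


def simulate_repertoire(
    allele: GermlineAllele,
    model: ContextMutabilityModel,
    per_count: int = 15,
    max_events: int = 28,
    seed: int = 0,
) -> list[SimulatedLineage]:
    """Simulate an artificial repertoire under the context model.

    For every event count k in 1..max_events, ``per_count`` independent
    lineages each receive exactly k accepted mutation events (defaults give
    15 x 28 = 420 lineages). Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    lineages = []
    for k in range(1, max_events + 1):
        for i in range(per_count):
            seq = allele.nt_seq
            for _ in range(k):
                seq = mutate_once(seq, model, rng)
            lineages.append(
                SimulatedLineage(
                    id=f"sim|{allele.allele_name}|events={k}|rep={i}|seed={seed}",
                    allele_name=allele.allele_name,
                    nt_seq=seq,
                    n_events=k,
                    seed=seed,
                )
            )
    return lineages


def simulate_repertoire_aa(
    allele: GermlineAllele,
    positional_m: dict[int, float],
    model: AminoAcidSubstitutionModel,
    n_lineages: int,
    events_per_lineage: int,
    seed: int = 0,
) -> list[str]:
    """Simulate amino acid sequences under a 20x20 exchange model.

    Positions are drawn proportional to ``positional_m`` (an empirical
    per-position substitution frequency keyed by the allele's position
    labels) and the replacement residue from the model row of the germline
    residue at the drawn position.
    """
    labels = list(allele.imgt_map)
    weights = np.array([max(positional_m.get(lab, 0.0), 0.0) for lab in labels])
    if weights.sum() <= 0:
        raise ValueError("positional frequencies are all zero")
    probs = weights / weights.sum()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_lineages):
        seq = list(allele.aa_seq)
        for _ in range(events_per_lineage):
            k = int(rng.choice(len(labels), p=probs))
            germ = allele.aa_seq[k]
            if germ not in AA_INDEX:
                continue
            row = model.row(germ)
            seq[k] = AA_ORDER[int(rng.choice(20, p=row))]
        out.append("".join(seq))
    return out


def gssp_from_simulation(
    lineages: list[SimulatedLineage],
    gene: GermlineGene,
) -> GSSP:
    """Build a profile from simulated lineages.

    Translations identical to the germline residue sets (silent-only
    lineages) are dropped, mirroring the no-amino-acid-change filter; the
    lineage-count floor is waived and the profile flagged as simulated.
    """
    residues = gene.germline_residues
    reps = []
    for lin in lineages:
        aa = translate_nt(lin.nt_seq)
        allele = next(
            (a for a in gene.alleles if a.allele_name == lin.allele_name),
            gene.alleles[0],
        )
        changed = any(
            obs not in residues.get(lab, frozenset())
            for lab, obs in zip(allele.imgt_map, aa)
            if obs not in ("X", "*")
        )
        if changed:
            reps.append(aa)
    if not reps:
        raise ValueError("no simulated lineage carries an amino acid change")
    return build_gssp(reps, gene, min_count=1, warn_below=0, simulated=True)


def write_simulated_fasta(lineages: list[SimulatedLineage], path: str | Path) -> None:
    with open(path, "w") as fh:
        for lin in lineages:
            fh.write(f">{lin.id}\n{lin.nt_seq}\n")
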