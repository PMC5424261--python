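"""Germline V-gene allele databases.

Loads IMGT-style germline FASTA files (gapped with dots, or ungapped),
groups alleles into genes, applies gene aliasing rules, and exposes the
IMGT position numbering needed to compare substitution profiles across
genes. With IMGT-gapped input, alignment gaps are codon-aligned and the
codon index in the gapped frame is the IMGT position label; ungapped
input falls back to sequential numbering from 1 and is tagged with the
``sequential`` dialect, which restricts downstream comparisons to the
same gene.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP_CHARS = ".-"
_NT_RE = re.compile(r"^[ACGTN]+$")

#: Alleles reassigned to another gene before profile building.  IGHV4-4*07
#: and *08 are sequence-wise alleles of IGHV4-59 and are grouped with it.
DEFAULT_ALIASES: dict[str, str] = {
    "IGHV4-4*07": "IGHV4-59",
    "IGHV4-4*08": "IGHV4-59",
}


class GermlineError(ValueError):
    """Raised for malformed germline databases."""


@dataclass(frozen=True)
class GermlineAllele:
    """One germline V-gene allele.

    ``imgt_map`` gives, for each complete codon of the ungapped sequence,
    its position label (IMGT codon number for gapped input, sequential
    otherwise); labels are strictly increasing.
    """

    gene_name: str
    allele_name: str
    nt_seq: str
    aa_seq: str
    imgt_map: tuple[int, ...]
    gapped_seq: str = ""

    def __post_init__(self):
        if any(b < a for a, b in zip(self.imgt_map, self.imgt_map[1:])):
            raise GermlineError(
                f"{self.allele_name}: position labels not strictly increasing"
            )

    @property
    def positions(self) -> dict[int, str]:
        """Mapping of position label -> amino acid for this allele."""
        return dict(zip(self.imgt_map, self.aa_seq))


@dataclass
class GermlineGene:
    """A V gene: one or more alleles plus the per-position germline residue
    union used to distinguish polymorphism from somatic substitution."""

    name: str
    family: str
    alleles: list[GermlineAllele] = field(default_factory=list)
    numbering_dialect: str = "sequential"

    @property
    def germline_residues(self) -> dict[int, frozenset[str]]:
        """Per position, the set of amino acids present in any allele.

        All documented polymorphisms are treated as germline so that they
        are never counted as somatic substitutions. ``X`` (from N bases)
        is not a germline residue.
        """
        union: dict[int, set[str]] = {}
        for allele in self.alleles:
            for pos, aa in allele.positions.items():
                if aa == "X":
                    continue
                union.setdefault(pos, set()).add(aa)
        return {pos: frozenset(aas) for pos, aas in sorted(union.items())}

    def best_allele_for(self, aa_seq: str):  # pragma: no cover - thin alias
        from mgssp.profile import _best_allele

        return _best_allele(aa_seq, self)


def _parse_header(description: str) -> str:
    """Extract the allele name from a FASTA header.

    Accepts the IMGT reference-directory dialect (pipe-separated, allele
    name in the second field) and plain ``>IGHV3-23*01`` headers.
    """
    if "|" in description:
        fields = description.split("|")
        if len(fields) < 2 or "*" not in fields[1]:
            raise GermlineError(f"unparseable IMGT header: {description!r}")
        return fields[1].strip()
    name = description.split()[0].strip()
    if not name or "*" not in name:
        raise GermlineError(f"unparseable germline header: {description!r}")
    return name


def _gene_of(allele_name: str) -> str:
    return allele_name.split("*")[0]


def _family_of(gene_name: str) -> str:
    return gene_name.split("-")[0]


def _build_allele(allele_name: str, gene_name: str, gapped: str) -> GermlineAllele:
    ungapped = "".join(c for c in gapped if c not in GAP_CHARS)
    if not ungapped or not _NT_RE.match(ungapped):
        bad = sorted(set(ungapped) - set("ACGTN"))
        raise GermlineError(
            f"{allele_name}: sequence contains non-nucleotide characters {bad}"
        )
    # Walk gapped codons: a codon is present only when all three of its
    # alignment columns are bases; all-gap codons are skipped (absent IMGT
    # positions), mixed codons would break the reading frame.
    labels: list[int] = []
    codons: list[str] = []
    n_full = len(gapped) // 3
    for codon_idx in range(n_full):
        triplet = gapped[3 * codon_idx : 3 * codon_idx + 3]
        gaps = sum(c in GAP_CHARS for c in triplet)
        if gaps == 3:
            continue
        if gaps:
            raise GermlineError(
                f"{allele_name}: alignment gap not codon-aligned at codon "
                f"{codon_idx + 1}"
            )
        labels.append(codon_idx + 1)
        codons.append(triplet)
    aa_seq = str(Seq("".join(codons)).translate())
    return GermlineAllele(
        gene_name=gene_name,
        allele_name=allele_name,
        nt_seq=ungapped,
        aa_seq=aa_seq,
        imgt_map=tuple(labels),
        gapped_seq=gapped,
    )


def load_germline_fasta(
    path: str | Path,
    alias_rules: dict[str, str] | None = None,
) -> dict[str, GermlineGene]:
    """Load a germline V-gene allele database from FASTA.

    Parameters
    ----------
    path
        FASTA file; IMGT gap dots (or dashes) are accepted and define the
        IMGT position map.
    alias_rules
        Mapping allele name -> target gene applied before grouping
        (default: :data:`DEFAULT_ALIASES`). Pass ``{}`` to disable.

    Returns
    -------
    dict mapping gene name to :class:`GermlineGene`, in input order.
    """
    if alias_rules is None:
        alias_rules = DEFAULT_ALIASES
    seen: set[str] = set()
    genes: dict[str, GermlineGene] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        allele_name = _parse_header(record.description)
        if allele_name in seen:
            raise GermlineError(f"duplicate allele name: {allele_name}")
        seen.add(allele_name)
        gene_name = alias_rules.get(allele_name, _gene_of(allele_name))
        gapped = str(record.seq).upper()
        allele = _build_allele(allele_name, gene_name, gapped)
        dialect = "imgt" if any(c in gapped for c in GAP_CHARS) else "sequential"
        gene = genes.setdefault(
            gene_name,
            GermlineGene(name=gene_name, family=_family_of(gene_name)),
        )
        gene.alleles.append(allele)
        if dialect == "imgt":
            gene.numbering_dialect = "imgt"
    return genes


def read_alias_rules(path: str | Path) -> dict[str, str]:
    """Read aliasing rules from a two-column TSV (allele, target_gene)."""
    rules: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        allele, target = line.split("\t")[:2]
        rules[allele] = target
    return rules


def write_germline_fasta(genes: dict[str, GermlineGene], path: str | Path) -> None:
    """Write the database back to FASTA (gapped sequences preserved)."""
    records = [
        SeqRecord(Seq(a.gapped_seq or a.nt_seq), id=a.allele_name, description="")
        for gene in genes.values()
        for a in gene.alleles
    ]
    SeqIO.write(records, str(path), "fasta")


def imgt_position_of(allele: GermlineAllele, column: int) -> int:
    """Position label covering ungapped nucleotide index ``column`` (0-based).

    Gaps in the IMGT alignment are codon-aligned, so ungapped codon *k*
    corresponds one-to-one with the *k*-th present codon of the gapped frame.
    """
    if column < 0 or column >= len(allele.nt_seq):
        raise IndexError(
            f"column {column} outside sequence of length {len(allele.nt_seq)}"
        )
    codon = column // 3
    if codon >= len(allele.imgt_map):
        raise IndexError(f"column {column} beyond the last complete codon")
    return allele.imgt_map[codon]
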