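"""Transcript quality control.

Assigns germline V genes by best global-alignment identity (for inputs
that lack a V call) and applies the quality filters used before profile
building: out-of-frame junctions, internal stop codons in the V region,
non-codon-length (frameshift) indels against the assigned germline, and
transcripts with no amino acid change (which carry no substitution
information). Every rejection is labelled with its triggering rule and
per-rule counts are reported.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from mgssp._align import AlignmentMap, align_map, make_aligner
from mgssp.germline import GermlineAllele, GermlineGene

logger = logging.getLogger(__name__)

QC_STATUSES = (
    "pass",
    "no_assignment",
    "stop_codon",
    "out_of_frame",
    "frameshift_indel",
    "no_aa_change",
)


@dataclass
class Transcript:
    """One B-cell receptor read with V/J calls, junction, and QC status."""

    id: str
    nt_seq: str
    v_call: str | None = None
    j_call: str | None = None
    junction_nt: str | None = None
    qc_status: str | None = None
    v_identity: float = float("nan")

    @property
    def v_gene(self) -> str | None:
        return self.v_call.split("*")[0] if self.v_call else None

    @property
    def j_gene(self) -> str | None:
        return self.j_call.split("*")[0] if self.j_call else None


def _allele_index(db: dict[str, GermlineGene]) -> dict[str, tuple[GermlineGene, GermlineAllele]]:
    return {a.allele_name: (gene, a) for gene in db.values() for a in gene.alleles}


def assign_germline(
    transcript: Transcript,
    db: dict[str, GermlineGene],
    min_identity: float = 0.70,
    aligner=None,
) -> Transcript:
    """Assign ``v_call`` by best global nucleotide identity over all alleles.

    Ties are broken by lexicographically smallest allele name. An identity
    below ``min_identity`` marks the transcript ``no_assignment``.
    """
    if aligner is None:
        aligner = make_aligner()
    index = _allele_index(db)
    best_name, best_identity = None, -1.0
    for allele_name in sorted(index):
        _, allele = index[allele_name]
        am = align_map(aligner, allele.nt_seq, transcript.nt_seq)
        if am.identity > best_identity:
            best_name, best_identity = allele_name, am.identity
    transcript.v_call = best_name
    transcript.v_identity = best_identity
    if best_identity < min_identity:
        transcript.qc_status = "no_assignment"
    return transcript


def translate_aligned(
    transcript_nt: str,
    allele: GermlineAllele,
    aligner=None,
    alignment: AlignmentMap | None = None,
) -> dict[int, str]:
    """Translate a transcript codon-wise in the germline reading frame.

    Returns position label -> observed amino acid for every germline codon
    whose three nucleotides align to three contiguous transcript bases.
    Codons overlapping gaps or truncated ends are absent (uncovered).
    Codons with N translate to ``X``; stop codons appear as ``*``.
    """
    if alignment is None:
        if aligner is None:
            aligner = make_aligner()
        alignment = align_map(aligner, allele.nt_seq, transcript_nt)
    mapping = alignment.mapping
    observed: dict[int, str] = {}
    for k, label in enumerate(allele.imgt_map):
        i = 3 * k
        q0, q1, q2 = mapping[i], mapping[i + 1], mapping[i + 2]
        if q0 < 0 or q1 != q0 + 1 or q2 != q0 + 2:
            continue
        codon = transcript_nt[q0 : q0 + 3]
        observed[label] = str(Seq(codon).translate())
    return observed


def filter_transcript(
    transcript: Transcript,
    allele: GermlineAllele,
    gene: GermlineGene | None = None,
    aligner=None,
) -> Transcript:
    """Apply the quality filters and set the final ``qc_status``.

    Checks, in order: junction reading frame (length divisible by 3 when a
    junction is present), non-codon-length indels against the assigned
    allele, internal stop codons in the V-region translation, and absence
    of any amino acid change relative to the germline residue sets. The
    indel check precedes the stop check because the reading frame is
    undefined downstream of a frameshift.

    When ``gene`` is given, its per-position germline residue union (all
    allelic polymorphisms) defines "no change"; otherwise the assigned
    allele alone does. N bases translate to X and never count as changes.
    """
    if aligner is None:
        aligner = make_aligner()
    if transcript.junction_nt and len(transcript.junction_nt) % 3 != 0:
        transcript.qc_status = "out_of_frame"
        return transcript
    am = align_map(aligner, allele.nt_seq, transcript.nt_seq)
    if any(run % 3 != 0 for run in am.gap_runs):
        transcript.qc_status = "frameshift_indel"
        return transcript
    observed = translate_aligned(transcript.nt_seq, allele, alignment=am)
    if "*" in observed.values():
        transcript.qc_status = "stop_codon"
        return transcript
    if gene is not None:
        residues = gene.germline_residues
    else:
        residues = {pos: frozenset((aa,)) for pos, aa in allele.positions.items()}
    n_changes = sum(
        1
        for pos, aa in observed.items()
        if aa != "X" and aa not in residues.get(pos, frozenset())
    )
    if n_changes == 0:
        transcript.qc_status = "no_aa_change"
        return transcript
    transcript.qc_status = "pass"
    return transcript


def _resolve_allele(
    v_call: str,
    db: dict[str, GermlineGene],
    transcript_nt: str,
    aligner,
) -> tuple[GermlineGene, GermlineAllele] | None:
    """Find the allele for an input V call (allele or gene level)."""
    index = _allele_index(db)
    if v_call in index:
        return index[v_call]
    candidates = [
        (gene, a)
        for gene in db.values()
        for a in gene.alleles
        if v_call in (gene.name, a.gene_name, a.allele_name.split("*")[0])
    ]
    if not candidates:
        return None
    if len(candidates) == 1:
        return candidates[0]
    best = max(
        sorted(candidates, key=lambda ga: ga[1].allele_name),
        key=lambda ga: align_map(aligner, ga[1].nt_seq, transcript_nt).identity,
    )
    return best


def run_qc(
    transcripts: list[Transcript],
    db: dict[str, GermlineGene],
    min_identity: float = 0.70,
    aligner=None,
) -> tuple[list[Transcript], Counter]:
    """Assign (where needed) and filter a transcript set.

    Returns the transcripts with final statuses plus per-rule rejection
    counts (the run report).
    """
    if aligner is None:
        aligner = make_aligner()
    index = _allele_index(db)
    report: Counter = Counter()
    for t in transcripts:
        if not t.v_call:
            assign_germline(t, db, min_identity=min_identity, aligner=aligner)
            if t.qc_status == "no_assignment":
                report["no_assignment"] += 1
                continue
        resolved = _resolve_allele(t.v_call, db, t.nt_seq, aligner)
        if resolved is None:
            t.qc_status = "no_assignment"
            report["no_assignment"] += 1
            continue
        gene, allele = resolved
        t.v_call = allele.allele_name
        filter_transcript(t, allele, gene=gene, aligner=aligner)
        report[t.qc_status] += 1
    for status, n in sorted(report.items()):
        logger.info("qc: %s -> %d transcripts", status, n)
    return transcripts, report


# ---------------------------------------------------------------------------
# I/O: AIRR rearrangement TSV and FASTA

_AIRR_COLS = {"sequence_id", "sequence", "v_call", "j_call", "junction"}


def read_airr(path: str | Path) -> tuple[list[Transcript], pd.DataFrame]:
    """Read an AIRR-style rearrangement TSV.

    Honours sequence_id, sequence, v_call, j_call, junction; all columns
    are returned in the accompanying DataFrame so extras pass through.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = {"sequence_id", "sequence"} - set(df.columns)
    if missing:
        raise ValueError(f"AIRR TSV missing required columns: {sorted(missing)}")
    transcripts = [
        Transcript(
            id=row.sequence_id,
            nt_seq=row.sequence.upper(),
            v_call=getattr(row, "v_call", "") or None,
            j_call=getattr(row, "j_call", "") or None,
            junction_nt=(getattr(row, "junction", "") or None),
        )
        for row in df.itertuples(index=False)
    ]
    return transcripts, df


def read_fasta_transcripts(path: str | Path) -> list[Transcript]:
    """Read transcripts from FASTA (no V/J calls or junctions)."""
    return [
        Transcript(id=rec.id, nt_seq=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_airr(
    transcripts: list[Transcript],
    path: str | Path,
    passthrough: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Write transcripts as AIRR-style TSV with qc_status and v_identity.

    Extra columns of ``passthrough`` (matched on sequence_id) are kept.
    """
    out = pd.DataFrame(
        {
            "sequence_id": [t.id for t in transcripts],
            "sequence": [t.nt_seq for t in transcripts],
            "v_call": [t.v_call or "" for t in transcripts],
            "j_call": [t.j_call or "" for t in transcripts],
            "junction": [t.junction_nt or "" for t in transcripts],
            "qc_status": [t.qc_status or "" for t in transcripts],
            "v_identity": [t.v_identity for t in transcripts],
        }
    )
    if passthrough is not None:
        extra_cols = [c for c in passthrough.columns if c not in out.columns]
        if extra_cols:
            out = out.merge(
                passthrough[["sequence_id", *extra_cols]], on="sequence_id", how="left"
            )
    out.to_csv(path, sep="\t", index=False)
    return out
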