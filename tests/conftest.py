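"""Shared fixtures: synthetic germline databases and repertoires.

All sequence data are generated programmatically; records named after real
IMGT alleles (IGHV3-23 etc.) carry synthetic stand-in sequences used only
to exercise naming, aliasing, and numbering logic.
"""

import numpy as np
import pytest

import mgssp
from mgssp import synth
from mgssp.qc import Transcript

# Synthetic stand-in sequences under IMGT-style names; position 3 of the
# *01/*02 pair is an IMGT alignment gap, and *02 differs at position 5
# (N -> S polymorphism).
GAPPED_FASTA = """\
>IGHV3-23*01
ATGGCT...TCTAAT
>IGHV3-23*02
ATGGCT...TCTAGT
>X00001|IGHV4-4*07|Homo sapiens|F|V-REGION
ATGGCTTGGTCTAAT
>IGHV4-59*01
ATGGCTTGGTCTAAC
"""


@pytest.fixture()
def gapped_db_path(tmp_path):
    path = tmp_path / "germline.fasta"
    path.write_text(GAPPED_FASTA)
    return path


@pytest.fixture(scope="session")
def syn_gene():
    """A 30-codon synthetic germline gene (single allele, ungapped)."""
    spec = synth.SyntheticRepertoireSpec(gene_length=90, n_alleles=1)
    return synth.generate_germline(spec, seed=11)


@pytest.fixture(scope="session")
def syn_gene_poly():
    """Two-allele synthetic gene with a polymorphism at codon 7."""
    spec = synth.SyntheticRepertoireSpec(
        gene_length=90, n_alleles=2, allele_variant_positions=(7,)
    )
    return synth.generate_germline(spec, seed=12)


def substitute_codon(nt_seq: str, codon_pos: int, new_codon: str) -> str:
    """Replace the 1-based codon ``codon_pos`` of an in-frame sequence."""
    i = 3 * (codon_pos - 1)
    return nt_seq[:i] + new_codon + nt_seq[i + 3 :]


def nonsynonymous_codon(aa: str, rng: np.random.Generator) -> str:
    """A codon encoding some amino acid other than ``aa``."""
    choices = sorted(a for a in synth.CODONS_BY_AA if a != aa)
    new_aa = choices[rng.integers(len(choices))]
    return sorted(synth.CODONS_BY_AA[new_aa])[0]


@pytest.fixture(scope="session")
def crafted_ten(syn_gene):
    """Ten transcripts with constructed defects: 3 stop-codon, 2 frameshift,
    1 germline-identical, 4 clean single-substitution reads."""
    rng = np.random.default_rng(5)
    germ = syn_gene.alleles[0].nt_seq
    reads = {}
    for i, codon in enumerate((5, 12, 20)):
        reads[f"stop{i}"] = substitute_codon(germ, codon, "TAA")
    reads["fs0"] = germ[:30] + germ[31:]  # 1-nt deletion
    reads["fs1"] = germ[:45] + germ[47:]  # 2-nt deletion
    reads["identical"] = germ
    for i, codon in enumerate((3, 9, 15, 25)):
        aa = syn_gene.alleles[0].aa_seq[codon - 1]
        reads[f"clean{i}"] = substitute_codon(
            germ, codon, nonsynonymous_codon(aa, rng)
        )
    return [Transcript(id=k, nt_seq=v) for k, v in reads.items()]


@pytest.fixture(scope="session")
def recovery_bundle():
    """1,000-lineage synthetic repertoire (default noise) pushed through the
    full pipeline: QC, clustering, representative selection, GSSP."""
    spec = synth.SyntheticRepertoireSpec(n_lineages=1000)
    bundle = synth.generate_repertoire(spec, seed=2024)
    df = bundle["transcripts"]
    transcripts = [
        Transcript(
            id=r.sequence_id, nt_seq=r.sequence, j_call=r.j_call, junction_nt=r.junction
        )
        for r in df.itertuples(index=False)
    ]
    transcripts, report = mgssp.run_qc(transcripts, {bundle["gene"].name: bundle["gene"]})
    passed = [t for t in transcripts if t.qc_status == "pass"]
    lineages = mgssp.cluster_lineages(passed)
    seqs = {t.id: t.nt_seq for t in passed}
    reps = {}
    for lin in lineages:
        rep_id = mgssp.select_representative(lin, seqs)
        reps[lin.lineage_id] = mgssp.profile.translate_nt(seqs[rep_id])
    gssp = mgssp.build_gssp(list(reps.values()), bundle["gene"], warn_below=0)
    bundle.update(
        transcripts_qc=transcripts,
        report=report,
        passed=passed,
        lineages=lineages,
        sequences=seqs,
        rep_aa=reps,
        gssp=gssp,
    )
    return bundle


@pytest.fixture(scope="session")
def robust_bundle():
    """300 noise-free lineages with ~12 members each (for representative
    resampling, which needs lineages of at least 10 members)."""
    spec = synth.SyntheticRepertoireSpec(
        n_lineages=300,
        mean_lineage_size=12.0,
        error_sub_rate=0.002,
        frameshift_rate=0.0,
        stop_rate=0.0,
        cdr3_divergence_rate=0.01,
    )
    bundle = synth.generate_repertoire(spec, seed=77)
    df = bundle["transcripts"]
    transcripts = [
        Transcript(
            id=r.sequence_id,
            nt_seq=r.sequence,
            v_call=bundle["gene"].alleles[0].allele_name,
            j_call=r.j_call,
            junction_nt=r.junction,
        )
        for r in df.itertuples(index=False)
    ]
    lineages = mgssp.cluster_lineages(transcripts)
    bundle.update(
        lineages=lineages, sequences={t.id: t.nt_seq for t in transcripts}
    )
    return bundle
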