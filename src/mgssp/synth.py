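"""Synthetic germline genes, repertoires, and mutation-model tables.

Generates, from a seed, everything the pipeline consumes: a germline
V gene (optionally with allelic variants), a repertoire of clonal lineages
with a known position-specific substitution process (true per-position
substitution frequency m* and bias vectors f*), sequencing noise including
frameshift indels and stop codons to exercise the quality filters, and
complete 5-mer context-model tables. Ground truth (lineage membership and
founder substitutions) is returned alongside, so parameter recovery can be
checked end to end.

The default repertoire emulates the statistical structure of an IgG 454
repertoire at desk scale: a ~300-codon V gene, clonal lineage sizes that
are small and skewed (geometric), a low per-base substitution error rate
and per-read frameshift rate, and sparse, dominant substitution biases
(1-3 preferred replacements per position).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from mgssp.germline import GermlineGene, _build_allele, _family_of
from mgssp.profile import AA_INDEX, AA_ORDER, translate_nt
from mgssp.simulate import BASES, ContextMutabilityModel

_STOPS = {"TAA", "TAG", "TGA"}
CODONS_BY_AA: dict[str, list[str]] = {}
for _codon in ("".join(c) for c in itertools.product(BASES, repeat=3)):
    if _codon in _STOPS:
        continue
    CODONS_BY_AA.setdefault(translate_nt(_codon), []).append(_codon)


@dataclass
class SyntheticRepertoireSpec:
    """Parameters of the synthetic repertoire generator.

    Noise defaults follow 454 pyrosequencing error structure: substitution
    errors around 0.09% per base with indels the dominant error mode
    (modelled as a per-read frameshift probability).
    """

    gene_name: str = "SYNV1-1"
    gene_length: int = 294  # nt; ~98 codons, a typical V-region length
    n_alleles: int = 1
    allele_variant_positions: tuple[int, ...] = ()
    n_lineages: int = 300
    mean_lineage_size: float = 3.0  # geometric; singletons occur naturally
    cdr3_length: int = 30
    cdr3_divergence_rate: float = 0.02  # per base, per member
    error_sub_rate: float = 0.0009  # per base, per read
    frameshift_rate: float = 0.02  # per read: 1-2 nt indel
    stop_rate: float = 0.01  # per read: one internal codon -> TAA
    n_j_genes: int = 2
    mean_m: float = 0.08  # mean of exponential prior on true m*
    max_m: float = 0.6
    bias_concentration: float = 0.3  # Dirichlet concentration of true f*
    true_m: dict[int, float] | None = None  # override: position -> m*
    true_f: dict[int, dict[str, float]] | None = None  # override: position -> {aa: p}


def generate_germline(spec: SyntheticRepertoireSpec, seed: int) -> GermlineGene:
    """Random in-frame, stop-free germline gene with optional allele variants.

    Variant alleles differ from *01 by a non-synonymous codon change at
    each position in ``allele_variant_positions`` (1-based codon labels).
    """
    if spec.gene_length % 3 != 0:
        raise ValueError("gene_length must be divisible by 3")
    rng = np.random.default_rng(seed)
    n_codons = spec.gene_length // 3
    aas = list(CODONS_BY_AA)
    base_codons = [
        rng.choice(CODONS_BY_AA[aas[rng.integers(len(aas))]]) for _ in range(n_codons)
    ]
    gene = GermlineGene(
        name=spec.gene_name,
        family=_family_of(spec.gene_name),
        numbering_dialect="sequential",
    )
    for a in range(spec.n_alleles):
        codons = list(base_codons)
        if a > 0:
            for pos in spec.allele_variant_positions:
                old_aa = translate_nt(codons[pos - 1])
                choices = [x for x in CODONS_BY_AA if x != old_aa]
                new_aa = choices[rng.integers(len(choices))]
                codons[pos - 1] = rng.choice(CODONS_BY_AA[new_aa])
        gene.alleles.append(
            _build_allele(f"{spec.gene_name}*{a + 1:02d}", spec.gene_name, "".join(codons))
        )
    return gene


def generate_truth(
    spec: SyntheticRepertoireSpec, gene: GermlineGene, seed: int
) -> tuple[pd.Series, pd.DataFrame]:
    """True per-position substitution frequency m* and bias vectors f*.

    m* is exponential (mean ``mean_m``, clipped to ``max_m``), mimicking
    many cold framework positions and a few hot ones; f* is Dirichlet with
    low concentration over non-germline residues, so each position has a
    handful of dominant replacements. Spec-level overrides win.
    """
    rng = np.random.default_rng(seed)
    residues = gene.germline_residues
    labels = sorted(residues)
    m = {}
    f_rows = {}
    for pos in labels:
        if spec.true_m is not None:
            m[pos] = float(spec.true_m.get(pos, 0.0))
        else:
            m[pos] = float(min(rng.exponential(spec.mean_m), spec.max_m))
        vec = np.zeros(20)
        allowed = [aa for aa in AA_ORDER if aa not in residues[pos]]
        if spec.true_f is not None and pos in spec.true_f:
            for aa, p in spec.true_f[pos].items():
                vec[AA_INDEX[aa]] = p
        else:
            draw = rng.dirichlet(np.full(len(allowed), spec.bias_concentration))
            for aa, p in zip(allowed, draw):
                vec[AA_INDEX[aa]] = p
        total = vec.sum()
        if total > 0:
            vec = vec / total
        f_rows[pos] = vec
    true_m = pd.Series(m, name="true_m")
    true_f = pd.DataFrame(f_rows, index=list(AA_ORDER)).T
    return true_m, true_f


def _mutate_bases(seq: list[str], rate: float, rng: np.random.Generator) -> None:
    if rate <= 0:
        return
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        seq[i] = rng.choice([b for b in BASES if b != seq[i]])


def generate_repertoire(
    spec: SyntheticRepertoireSpec,
    seed: int,
    gene: GermlineGene | None = None,
    truth: tuple[pd.Series, pd.DataFrame] | None = None,
) -> dict:
    """Generate a synthetic repertoire with known truth tables.

    Each lineage's founder receives substitutions drawn position-wise by
    m* with replacement residues by f* (realized as a random codon of the
    target amino acid); members add CDR3 diversification and sequencing
    noise, including frameshift indels and stop codons at the spec's rates.

    Returns a dict with keys:
      gene          GermlineGene
      transcripts   AIRR-style DataFrame (sequence_id, sequence, v_call,
                    j_call, junction)
      truth_lineages  DataFrame (sequence_id, true_lineage)
      true_m, true_f  the generating parameters
      founder_subs  DataFrame (lineage, position, residue)

    ``gene`` and ``truth`` may be supplied to reuse a germline gene and/or
    substitution process across repertoires (e.g., two donors with the same
    gene, or two distinct processes on one gene).
    """
    rng = np.random.default_rng(seed)
    germline_seed, truth_seed = (int(s) for s in rng.integers(2**31, size=2))
    if gene is None:
        gene = generate_germline(spec, germline_seed)
    if truth is None:
        truth = generate_truth(spec, gene, truth_seed)
    true_m, true_f = truth
    allele = gene.alleles[0]
    n_codons = len(allele.imgt_map)

    records = []
    truth_rows = []
    founder_rows = []
    read_no = 0
    for li in range(spec.n_lineages):
        lineage_id = f"lin{li:05d}"
        # founder: position-wise substitution process
        codons = [allele.nt_seq[3 * k : 3 * k + 3] for k in range(n_codons)]
        for k, label in enumerate(allele.imgt_map):
            if rng.random() < true_m[label]:
                probs = true_f.loc[label].to_numpy()
                if probs.sum() <= 0:
                    continue
                aa = AA_ORDER[int(rng.choice(20, p=probs))]
                codons[k] = rng.choice(CODONS_BY_AA[aa])
                founder_rows.append(
                    {"lineage": lineage_id, "position": label, "residue": aa}
                )
        founder_v = "".join(codons)
        junction = "".join(rng.choice(list(BASES), size=spec.cdr3_length))
        j_call = f"SYNJ{1 + int(rng.integers(spec.n_j_genes))}"
        size = int(rng.geometric(1.0 / spec.mean_lineage_size))
        for _ in range(size):
            v = list(founder_v)
            _mutate_bases(v, spec.error_sub_rate, rng)
            if rng.random() < spec.stop_rate:
                k = int(rng.integers(1, n_codons - 1))
                v[3 * k : 3 * k + 3] = list("TAA")
            if rng.random() < spec.frameshift_rate:
                indel_len = int(rng.integers(1, 3))
                at = int(rng.integers(3, len(v) - 3))
                if rng.random() < 0.5:
                    del v[at : at + indel_len]
                else:
                    for b in rng.choice(list(BASES), size=indel_len):
                        v.insert(at, b)
            jx = list(junction)
            _mutate_bases(jx, spec.cdr3_divergence_rate, rng)
            read_no += 1
            sid = f"read{read_no:06d}"
            records.append(
                {
                    "sequence_id": sid,
                    "sequence": "".join(v) + "".join(jx),
                    "v_call": "",
                    "j_call": j_call,
                    "junction": "".join(jx),
                }
            )
            truth_rows.append({"sequence_id": sid, "true_lineage": lineage_id})
    return {
        "gene": gene,
        "transcripts": pd.DataFrame(records),
        "truth_lineages": pd.DataFrame(truth_rows),
        "true_m": true_m,
        "true_f": true_f,
        "founder_subs": pd.DataFrame(founder_rows, columns=["lineage", "position", "residue"]),
    }


def generate_context_model(
    hot_fivemers: tuple[str, ...] = (),
    hot_weight: float = 10.0,
    cold_weight: float = 1.0,
) -> ContextMutabilityModel:
    """Complete 1,024-row 5-mer context model.

    Listed 5-mers get ``hot_weight``, all others ``cold_weight``
    (hotspot/coldspot structure); substitution rows are uniform over the
    three alternative bases.
    """
    hot = {f.upper() for f in hot_fivemers}
    table: dict[str, tuple[float, np.ndarray]] = {}
    for combo in itertools.product(BASES, repeat=5):
        fivemer = "".join(combo)
        row = np.full(4, 1 / 3)
        row["ACGT".index(fivemer[2])] = 0.0
        weight = hot_weight if fivemer in hot else cold_weight
        table[fivemer] = (weight, row)
    return ContextMutabilityModel(table=table, default_weight=0.0)
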