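"""SHM simulation under 5-mer context and amino acid exchange models."""

import numpy as np
import pytest
from scipy import stats

from mgssp import synth
from mgssp.profile import AA_INDEX, AA_ORDER, translate_nt
from mgssp.simulate import (
    BASE_IDX,
    BASES,
    AminoAcidSubstitutionModel,
    ContextMutabilityModel,
    gssp_from_simulation,
    mutate_once,
    simulate_repertoire,
    simulate_repertoire_aa,
    site_mutabilities,
    SimulatedLineage,
)


@pytest.fixture(scope="module")
def uniform_model():
    return synth.generate_context_model()


def single_event_law(seq: str, model) -> dict[tuple[int, str], float]:
    """Brute-force law of one accepted event: product of site mutability and
    substitution row, restricted to non-stop outcomes and renormalized."""
    probs = site_mutabilities(seq, model)
    law = {}
    for site in range(len(seq)):
        if probs[site] == 0:
            continue
        row = model.substitution_row(seq[site - 2 : site + 3]).copy()
        row[BASE_IDX[seq[site]]] = 0.0
        row = row / row.sum()
        for b, base in enumerate(BASES):
            if row[b] == 0:
                continue
            candidate = seq[:site] + base + seq[site + 1 :]
            if "*" in translate_nt(candidate):
                continue
            law[(site, base)] = probs[site] * row[b]
    total = sum(law.values())
    return {k: v / total for k, v in law.items()}


class TestSiteMutabilities:
    def test_uniform_model_interior_equiprobable(self, uniform_model, syn_gene):
        seq = syn_gene.alleles[0].nt_seq
        p = site_mutabilities(seq, uniform_model)
        assert np.all(p[:2] == 0.0) and np.all(p[-2:] == 0.0)
        assert np.allclose(p[2:-2], 1.0 / (len(seq) - 4))

    def test_hot_fivemer_probability_is_direct_ratio(self, syn_gene):
        seq = syn_gene.alleles[0].nt_seq
        fivemer = seq[10:15]
        occurrences = [
            i for i in range(2, len(seq) - 2) if seq[i - 2 : i + 3] == fivemer
        ]
        model = synth.generate_context_model((fivemer,), hot_weight=10.0)
        p = site_mutabilities(seq, model)
        n_interior = len(seq) - 4
        total = 10.0 * len(occurrences) + (n_interior - len(occurrences))
        assert p[12] == pytest.approx(10.0 / total)

    def test_short_sequence_errors(self, uniform_model):
        with pytest.raises(ValueError, match="5-mer"):
            site_mutabilities("ACGT", uniform_model)


class TestMutateOnce:
    def test_hamming_distance_is_one(self, uniform_model, syn_gene):
        rng = np.random.default_rng(0)
        seq = syn_gene.alleles[0].nt_seq
        out = mutate_once(seq, uniform_model, rng)
        assert sum(a != b for a, b in zip(seq, out)) == 1

    def test_stop_only_site_hits_rejection_bound(self):
        seq = "ATGTACGGG"  # codon 2 TAC; C -> A yields internal stop TAA
        model = ContextMutabilityModel(
            table={"TACGG": (1.0, np.array([1.0, 0.0, 0.0, 0.0]))},
            default_weight=0.0,
        )
        with pytest.raises(RuntimeError, match="rejections"):
            mutate_once(seq, model, np.random.default_rng(0), max_rejections=50)

    def test_single_event_law_chi_square(self, syn_gene):
        seq = syn_gene.alleles[0].nt_seq
        hot = (seq[20:25], seq[47:52])
        model = synth.generate_context_model(hot, hot_weight=5.0)
        law = single_event_law(seq, model)
        rng = np.random.default_rng(123)
        counts = {}
        n = 10_000
        for _ in range(n):
            out = mutate_once(seq, model, rng)
            site = next(i for i, (a, b) in enumerate(zip(seq, out)) if a != b)
            counts[(site, out[site])] = counts.get((site, out[site]), 0) + 1
        keys = sorted(law)
        observed = np.array([counts.get(k, 0) for k in keys])
        expected = np.array([law[k] * n for k in keys])
        result = stats.chisquare(observed, expected * observed.sum() / expected.sum())
        assert result.pvalue > 0.01


class TestSimulateRepertoire:
    def test_default_protocol_gives_420_lineages(self, uniform_model, syn_gene):
        allele = syn_gene.alleles[0]
        lineages = simulate_repertoire(allele, uniform_model, seed=1)
        assert len(lineages) == 420
        assert sorted({l.n_events for l in lineages}) == list(range(1, 29))

    def test_no_internal_stop_codons(self, uniform_model, syn_gene):
        lineages = simulate_repertoire(syn_gene.alleles[0], uniform_model, seed=1)
        assert all("*" not in translate_nt(l.nt_seq) for l in lineages)

    def test_single_event_lineages_at_hamming_one(self, uniform_model, syn_gene):
        allele = syn_gene.alleles[0]
        lineages = simulate_repertoire(allele, uniform_model, seed=2)
        for lin in lineages:
            d = sum(a != b for a, b in zip(allele.nt_seq, lin.nt_seq))
            if lin.n_events == 1:
                assert d == 1
            assert d <= lin.n_events

    def test_amino_acid_changes_bounded_by_events(self, uniform_model, syn_gene):
        allele = syn_gene.alleles[0]
        for lin in simulate_repertoire(allele, uniform_model, seed=3):
            aa_changes = sum(
                a != b for a, b in zip(allele.aa_seq, translate_nt(lin.nt_seq))
            )
            assert aa_changes <= lin.n_events

    def test_fixed_seed_reproducible(self, uniform_model, syn_gene):
        allele = syn_gene.alleles[0]
        a = simulate_repertoire(allele, uniform_model, per_count=3, max_events=5, seed=9)
        b = simulate_repertoire(allele, uniform_model, per_count=3, max_events=5, seed=9)
        assert a == b


class TestAminoAcidModel:
    def test_rows_validated(self):
        bad = np.full((20, 20), 1 / 19)
        with pytest.raises(ValueError, match="zero diagonal"):
            AminoAcidSubstitutionModel(bad)

    def test_tsv_round_trip(self, tmp_path):
        model = AminoAcidSubstitutionModel.uniform()
        model.to_tsv(tmp_path / "ab.tsv")
        back = AminoAcidSubstitutionModel.from_tsv(tmp_path / "ab.tsv")
        assert np.allclose(back.matrix, model.matrix)

    def test_concentrated_position_gets_all_events(self, syn_gene):
        allele = syn_gene.alleles[0]
        target = 12
        sims = simulate_repertoire_aa(
            allele, {target: 1.0}, AminoAcidSubstitutionModel.uniform(),
            n_lineages=20, events_per_lineage=1, seed=4,
        )
        for s in sims:
            diffs = [k + 1 for k, (a, b) in enumerate(zip(allele.aa_seq, s)) if a != b]
            assert diffs == [target]

    def test_onehot_rows_are_deterministic(self, syn_gene):
        allele = syn_gene.alleles[0]
        shift = np.zeros((20, 20))
        for i in range(20):
            shift[i, (i + 1) % 20] = 1.0
        model = AminoAcidSubstitutionModel(shift)
        sims = simulate_repertoire_aa(
            allele, {5: 1.0}, model, n_lineages=5, events_per_lineage=1, seed=0
        )
        germ = allele.aa_seq[4]
        expected = AA_ORDER[(AA_INDEX[germ] + 1) % 20]
        assert all(s[4] == expected for s in sims)

    def test_position_usage_proportional_to_m(self, syn_gene):
        allele = syn_gene.alleles[0]
        positional_m = {5: 0.5, 10: 0.3, 20: 0.2}
        sims = simulate_repertoire_aa(
            allele, positional_m, AminoAcidSubstitutionModel.uniform(),
            n_lineages=10_000, events_per_lineage=1, seed=5,
        )
        counts = {p: 0 for p in positional_m}
        for s in sims:
            for k, (a, b) in enumerate(zip(allele.aa_seq, s)):
                if a != b:
                    counts[k + 1] += 1
        observed = np.array([counts[p] for p in (5, 10, 20)])
        # replacement residues are always non-germline, so every event changes
        # the sequence and observed counts total n_lineages
        expected = np.array([0.5, 0.3, 0.2]) * observed.sum()
        assert stats.chisquare(observed, expected).pvalue > 0.01


class TestGsspFromSimulation:
    def test_unmutated_repertoire_errors(self, syn_gene):
        allele = syn_gene.alleles[0]
        lineages = [
            SimulatedLineage("s0", allele.allele_name, allele.nt_seq, 0, 0)
        ]
        with pytest.raises(ValueError, match="no simulated lineage"):
            gssp_from_simulation(lineages, syn_gene)

    def test_hot_codon_dominates_profile(self, syn_gene):
        allele = syn_gene.alleles[0]
        codon = 8
        hot = tuple(
            allele.nt_seq[site - 2 : site + 3]
            for site in range(3 * (codon - 1), 3 * codon)
        )
        model = synth.generate_context_model(hot, hot_weight=60.0)
        lineages = simulate_repertoire(allele, model, per_count=300, max_events=1, seed=6)
        gssp = gssp_from_simulation(lineages, syn_gene)
        assert gssp.simulated
        m = gssp.m_series()
        assert m.idxmax() == codon

    def test_context_model_tsv_round_trip(self, tmp_path):
        model = synth.generate_context_model(("AACGT",), hot_weight=7.0)
        model.to_tsv(tmp_path / "ctx.tsv")
        back = ContextMutabilityModel.from_tsv(tmp_path / "ctx.tsv")
        assert back.mutability("AACGT") == 7.0
        assert back.mutability("CCCCC") == 1.0
        assert np.allclose(back.substitution_row("AACGT"),
                           model.substitution_row("AACGT"))
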