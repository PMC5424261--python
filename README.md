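# mgssp — gene-specific substitution profiles of antibody somatic hypermutation

Somatic hypermutation (SHM) diversifies antibody variable regions during
affinity maturation, but it does not sample amino acid changes uniformly:
the mutability of each site depends on its nucleotide context, and the
machinery has strong substitution preferences. `mgssp` builds
**gene-specific substitution profiles (GSSPs)** — per-position catalogues of
which amino acid replacements a germline V gene actually explores, and how
often — from bulk B-cell receptor transcript sets. It is aimed at antibody
repertoire analysts and vaccine/antibody engineers who need to know, for a
given V gene and position, how plausible a particular substitution is.

## The model

For germline V gene *V*, position *i* (IMGT numbering), and amino acid *a*:

- **Substitution frequency** `m_{V,i}`: the fraction of clonal lineages
  whose representative carries a non-germline residue at position *i*
  (among lineages covering *i* with a defined residue).
- **Substitution bias** `f_{Vi,a}`: among lineages mutated at *i*, the
  frequency with which the replacement is specifically *a*. Residues found
  in any allele of the gene are germline polymorphism and never count.
- **Rarity**: `r_{Vi,a} = 1 − m_{V,i} · f_{Vi,a}` — the per-lineage
  improbability of observing substitution *a* at *i*. Undefined for
  germline residues, exactly 1.0 for substitutions never observed.

Profiles are compared position-wise with the Jensen–Shannon divergence (in
bits) between bias vectors,

    J(P_A,i, P_B,i) = H((P_A,i + P_B,i)/2) − [H(P_A,i) + H(P_B,i)]/2,

averaged with weights `w_i = (m_{A,i} + m_{B,i})/2`, and the resulting
divergence matrix is embedded with classical MDS.

The pipeline upstream of the profile follows standard repertoire practice:
quality filtering (stop codons, out-of-frame junctions, non-codon-length
indels, reads with no amino acid change), clonal lineage clustering (same V
and J gene, equal CDR3 length, ≥90% CDR3 nucleotide identity, single
linkage), and one consensus-closest representative per lineage (singleton
lineages are discarded). A simulator generates virtual repertoires under a
5-mer nucleotide-context model (S5F-style tables are read from TSV) or a
20×20 amino acid exchange model, rejecting mutations that create stop
codons. A synthetic-data generator (`mgssp.synth`) produces germline genes
and repertoires with known substitution structure so the whole pipeline can
be validated end to end.

## Worked example

`examples/01_build_profile.py` generates a 400-lineage synthetic repertoire,
runs QC, clusters lineages, and builds the profile:

```
QC report (reads per rule): {'pass': 1090, 'stop_codon': 36, 'frameshift_indel': 21}
234 clonal lineages (singletons discarded)

Five most substituted positions (substitution frequency m =
fraction of lineages carrying a non-germline residue there):
  position  35  germline G  m = 0.504  dominant substitution -> Q (f = 0.33)
  position  38  germline K  m = 0.244  dominant substitution -> P (f = 0.25)
  ...

Rarity r = 1 - m*f at position 35 (per-lineage improbability; 1.0 = never observed):
  A: r = 0.9188
  C: r = 1.0000
```

Half the lineages are mutated at position 35, a third of those to Q, so a
G35Q substitution has rarity 1 − 0.504·0.33 ≈ 0.83 — a common change —
while G35C was never sampled (r = 1.0). The other examples cover profile
comparison and MDS (`02`), SHM simulation (`03`), and the summary analytics
and logo export (`04`).

The same steps are available from the shell:

```bash
mgssp synth --seed 5 --out data/
mgssp filter --germline data/germline.fasta --in data/reads.tsv --out filtered.tsv
mgssp cluster --in filtered.tsv --out lineages.tsv
mgssp build --lineages lineages.tsv --reps filtered.tsv \
      --germline data/germline.fasta --gene SYNV1-1 --out SYNV1-1.gssp.tsv
mgssp compare --profiles a.gssp.tsv --profiles b.gssp.tsv --out dist.tsv --mds mds.tsv
mgssp plot --profile SYNV1-1.gssp.tsv --out logo.png
```

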