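# Methods

## Profile construction

A GSSP summarizes, per position of a germline V gene, the substitution
frequency `m` and the 20-way substitution bias `f` observed across clonal
lineages. The unit of observation is the lineage, not the read: members of
an expanded clone share substitutions that did not arise independently, so
each lineage contributes exactly one representative sequence. The counting
rules are:

- `m = n_mutated / n_covered`, where `n_covered` counts lineages whose
  representative has a defined residue aligned at the position. Using
  covered lineages (not all lineages) as the denominator avoids deflating
  frequencies at read edges where coverage drops.
- A lineage counts at most once toward `m` at a position; the observed
  residue contributes one count to `f`. `f` is the count vector normalized
  to 1 (all-zero when the position was never mutated), and is zero at
  germline residues by construction.
- Residues present in **any** allele of the gene are germline polymorphism
  and never count as substitutions; the per-position residue union is built
  when the allele database is loaded. Novel alleles are handled by simply
  adding them to the input FASTA.
- Alignment gaps and undefined residues (X, from N bases) are uncovered:
  excluded from both numerator and denominator.
- Rarity is `r = 1 − m·f` per possible substitution; undefined for germline
  residues and exactly 1.0 for substitutions never observed.

Representatives are aligned at the amino acid level to the single
best-scoring allele of their gene (global, affine gaps), and columns mapped
to IMGT position labels through that allele. Aligning to the best allele
rather than building a joint multiple alignment is deterministic and
cheaper; the residue union over alleles still protects against counting
polymorphism as substitution. Representatives aligning at under 50%
identity are excluded with a warning.

Profiles require at least `min_count = 100` representatives (hard floor)
and log a warning under `warn_below = 300`; both are exposed because the
convergence analysis (below) shows between-replicate divergence still
shrinking up to roughly 300 lineages. Profiles of the same gene can be
merged by summing the underlying counts, which is exactly equivalent to
profiling the pooled lineage set.

## Numbering dialects

IMGT-gapped references (dots as alignment gaps, codon-aligned) yield IMGT
codon labels, enabling cross-gene comparison at homologous positions.
Ungapped references are accepted and numbered sequentially from 1; the
dialect is recorded in the profile and its TSV header, and
sequential-dialect profiles may only be compared within the same gene.

## Quality control

Filters are applied in a fixed order, and every rejection is labelled:

1. **out_of_frame** — junction length not divisible by 3 (when a junction
   is provided; FASTA-only input skips this rule).
2. **frameshift_indel** — any internal gap run, in either sequence of the
   global alignment to the assigned allele, with length not divisible by 3.
   Codon-length indels (3, 6, 9 nt) pass.
3. **stop_codon** — an internal stop in the codon-wise V-region translation
   in the germline frame. The indel check runs first because the reading
   frame is undefined downstream of a frameshift.
4. **no_aa_change** — translation identical to the germline residue sets;
   such reads carry no information for the profile.

V assignment (for inputs without a V call) picks the allele with the
highest global-alignment nucleotide identity, ties broken by smallest
allele name; identities below a configurable floor (default 0.70 — a
plumbing default, not an empirical constant) are `no_assignment`.
Alignments use match +2, mismatch −1, gap open −10, gap extend −1;
the heavy gap-open penalty suppresses spurious short gaps so that real
sequencing indels are detected as such. Nucleotide alignments leave
terminal gaps free (reads may be truncated and carry CDR3/junction tails);
amino acid alignments for profile building penalize end gaps so terminal
substitutions are aligned and counted rather than trimmed.

## Lineage clustering and representatives

Lineages group reads with the same V gene, same J gene (gene-level calls —
allele calls are noisier), equal junction length, and ≥90% junction
nucleotide identity (boundary inclusive) under single linkage. Single
linkage is the only linkage for which the stated pairwise criterion induces
a partition (connectivity), and it makes the output independent of input
order. Singleton lineages are discarded: a substitution seen in a single
read cannot be distinguished from sequencing error.

The representative is the member with the fewest mismatches to the
per-column majority consensus (ties within a consensus column resolved by
alphabetical base; ties between members by smallest read id). Consensus is
computed on nucleotide sequences. The sensitivity of rarity scores to this
choice is measured by `representative_robustness`: over many trials a
random member stands in as representative for every lineage with ≥10
members, and the Pearson correlation of rarity tables between trials is
reported.

## Profile comparison

Position-wise Jensen–Shannon divergence (base-2 logarithms, so values in
[0, 1] bits) between bias vectors, weighted by the mean substitution
frequency of the position in the two profiles. Positions where one profile
has zero substitutions have no bias distribution on that side and are
excluded from both numerator and denominator; no pseudocounts are added
(0·log 0 = 0). Distance matrices are embedded with classical (Torgerson)
MDS: double-center −½D², eigendecompose, scale eigenvectors by the root
eigenvalues; negative eigenvalues are truncated to zero with a warning, and
the reflection ambiguity is fixed by making the largest-magnitude
coordinate on each axis positive.

## SHM simulation

Under the 5-mer context model, each accepted event draws a site from the
normalized per-site mutabilities of the *current* sequence (the two
terminal positions at each end lack a complete 5-mer and get zero weight —
the model tables say nothing about shorter contexts) and a replacement base
from the 5-mer's substitution row. Draws creating an internal stop codon
are fully redrawn (site and base), bounded at 1,000 rejections per event;
re-mutation of a previously mutated site is allowed, so a lineage's final
Hamming distance can be below its event count and silent or reverted
changes occur naturally. "k nucleotide changes" therefore means k accepted
events, not final distance. The default protocol (15 lineages at each of
1–28 events = 420 lineages) matches the standard simulated-repertoire
design. Under the 20×20 amino acid model, positions are drawn proportional
to a user-supplied per-position substitution frequency and the replacement
from the model row of the germline residue.

Model tables are plain TSV (context: fivemer, mutability, p_to_A..p_to_T;
amino acid: residue + 20 columns); published S5F-style tables in this
layout are consumed directly, and `mgssp.synth.generate_context_model`
writes complete 1,024-row synthetic tables so nothing need be downloaded.

## Summary analytics

- The average substitution matrix averages normalized bias vectors per
  germline residue over qualifying positions: positions with `m < 0.05`
  are excluded (bias is undersampled there), as are positions with
  polymorphic germline residues. Rows with no qualifying position are NaN,
  never silently zero.
- The rarity histogram reports, separately, the fraction of possible
  substitutions never observed (r exactly 1.0); default bin edges place
  breaks at 0.975 and 0.995 ("extremely rare") above uniform bins.
- SHM stratification: low ≤ 8 amino acid substitutions, high ≥ 21; counts
  of 9–20 belong to neither stratum, matching the usual "8 or fewer" /
  "more than 20" phrasing.
- Logo export emits letter heights `m·f` (stack height = m) with a
  physicochemical colour grouping (R/K/H; D/E; G/S/T/Y/C; P/A/W/F/L/I/M/V;
  N/Q); the rendered image is a thin matplotlib layer and all tests assert
  on the numeric specification.

## Synthetic data

`mgssp.synth` emulates the statistical structure the profile builder
assumes: one germline gene (optionally with allelic variants), clonal
lineages with geometric sizes (mean 3; singletons occur and exercise their
removal), founders mutated position-wise by a true `m*` (exponential, mean
0.08, clipped at 0.6 — many cold framework positions, a few hot ones) with
replacements from sparse Dirichlet bias vectors `f*` (concentration 0.3,
giving 1–3 dominant substitutions per position, realized as a random codon
of the target residue), random same-length CDR3s per lineage with per-base
member divergence, and sequencing noise in the 454 regime: substitution
errors at 0.09% per base, frameshift indels as the dominant error mode
(2% of reads by default), and occasional stop codons (1%).

It does **not** emulate: homopolymer-specific indel structure, clonal
genealogy within lineages (members are star-shaped around the founder),
phased mutations, D-gene/CDR3 assignment ambiguity, or primer/chimera
artifacts. Passing recovery tests therefore demonstrates the correctness of
the counting, clustering, and comparison machinery under the model's own
assumptions — not robustness to every artifact of real repertoire data.

## Scale choices

Analyses in the test suite and acceptance script run at desk scale chosen
so sampling error is small relative to the tested effects: 1,000 lineages
for parameter recovery, 300 lineages × ~12 members for representative
resampling (mirroring the usual ≥10-member requirement), sizes 25–300 with
disjoint replicate pairs (10 independent draws) for convergence, 10,000
draws for the single-event law, and 5,000 single-event lineages for the
hot-codon bias check.

## Known limitations

- Consensus computation assumes equal-length members; codon-length indels
  surviving QC are handled by length-tolerant mismatch counting rather
  than a true multiple alignment.
- Cross-gene comparison relies on shared IMGT labels; no structural
  alignment is attempted for positions without labels.
- The rarity of substitutions requiring 2–3 nucleotide changes is not
  modelled separately; all substitutions are counted identically.
- No within-lineage phylogenetics: the representative stands for the whole
  lineage, so late, subclonal substitutions are invisible by design.
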