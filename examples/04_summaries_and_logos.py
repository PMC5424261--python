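"""Summaries: average substitution matrix, rarity histogram, logo export.

Builds a profile from a synthetic repertoire and derives the per-amino-acid
average substitution matrix (which replacements each germline residue
prefers), the distribution of rarity scores, the low/high-SHM strata, and
the numeric logo specification used for plotting.
"""

import mgssp
from mgssp import synth
from mgssp.profile import translate_nt
from mgssp.qc import Transcript

spec = synth.SyntheticRepertoireSpec(n_lineages=500)
bundle = synth.generate_repertoire(spec, seed=2)
gene = bundle["gene"]
ts = [
    Transcript(id=r.sequence_id, nt_seq=r.sequence, j_call=r.j_call,
               junction_nt=r.junction)
    for r in bundle["transcripts"].itertuples(index=False)
]
ts, _ = mgssp.run_qc(ts, {gene.name: gene})
passed = [t for t in ts if t.qc_status == "pass"]
lineages = mgssp.cluster_lineages(passed)
seqs = {t.id: t.nt_seq for t in passed}
reps = [translate_nt(seqs[mgssp.select_representative(l, seqs)]) for l in lineages]
gssp = mgssp.build_gssp(reps, gene, warn_below=0)

mat = mgssp.average_substitution_matrix([gssp], min_m=0.05)
frame = mat.to_frame().dropna(how="all")
print("Average substitution bias by germline residue "
      f"({int(mat.row_counts.sum())} qualifying positions, m >= 0.05):")
print(frame.round(2).iloc[:5, :8])

table = mgssp.rarity_of(gssp)
hist = mgssp.rarity_histogram(table)
print(f"\nRarity distribution over {hist.attrs['n_entries']} possible "
      "substitutions:")
print(hist.round(3).to_string(index=False))
print(f"never observed (r = 1.0): {hist.attrs['fraction_unobserved']:.1%}")

strata = mgssp.stratify_by_shm(reps, gene)
print(f"\nSHM strata: {strata['low_n']} low (<=8 substitutions), "
      f"{strata['high_n']} high (>=21); "
      f"{len(strata['unique_to_high'])} substitutions seen only in high-SHM "
      "lineages")

logo = mgssp.logo_export(gssp)
print(f"\nLogo specification: {len(logo)} letters; stack heights equal each "
      "position's substitution frequency m")
mgssp.plot_logo(gssp, path="logo.png")
print("rendered logo written to logo.png")
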