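"""Per-column conservation profiles and sequence-logo matrices.

Computes residue frequencies and information content per reference column
for each cysteine-profile group, recovers the conserved-cysteine column sets,
and exports a logo height matrix (height = frequency x information content)
that any logo plotter can render.
"""

from epdrsurvey import SyntheticConfig, column_profile, conserved_columns, \
    generate_family, logo_matrix
from epdrsurvey.synthetic import family_alignment

sequences, truth = generate_family(
    SyntheticConfig(n_per_profile=50, n_decoys=0, seed=7)
)

groups = {}
for profile in ("1", "2", "3"):
    ids = [r.id for r in truth.records if r.true_profile == profile]
    aln = family_alignment(sequences, truth, ids)
    prof = column_profile(aln)
    cys_cols = conserved_columns(prof, "C", min_freq=0.9)
    groups[profile] = set(cys_cols)
    print(f"profile {profile}: conserved cysteine columns {cys_cols}")
    ic_at = {c: prof.information[c - 1] for c in cys_cols}
    print("   information content: "
          + ", ".join(f"col {c}: {ic:.2f} bits" for c, ic in ic_at.items()))

universal = sorted(groups["1"] & groups["2"] & groups["3"])
print(f"universal cysteines (all three profiles): {universal}")

prof1 = column_profile(family_alignment(
    sequences, truth, [r.id for r in truth.records if r.true_profile == "1"]
))
heights = logo_matrix(prof1)
print(f"logo matrix shape: {heights.shape} "
      f"(column sums equal the per-column information content)")
# Cysteine columns approach the 4.32-bit maximum; background columns carry
# little information, reproducing the spiky logo structure of the family.
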