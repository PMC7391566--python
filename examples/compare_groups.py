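"""Two-group occupancy comparison with bootstrap + Bhattacharyya overlap.

Builds a synthetic two-group ordination-like trait space (unequal group
sizes, decreasing per-dimension variance) whose second group is displaced
along the first axis, bootstraps each group 500 times per measure, and
prints the per-measure overlap between the two bootstrap distributions.
Overlap near 1 = the groups are indistinguishable under that measure;
near 0 = clearly separated.
"""

from traitspaces import make_empirical_fixture, compare_groups

gs = make_empirical_fixture("pco_like", n_per_group=(83, 202), n_dim=6,
                            shift=1.0, seed=0)
print(f"trait space: {gs.space.n_obs} observations x {gs.space.n_dim} dimensions; "
      f"groups: {dict((g, len(v)) for g, v in gs.group_sizes().items())}\n")
table = compare_groups(gs, n_boot=500, seed=1)
print(table.round(3).to_string())
print("\nThe groups differ in position, not spread: the displacement overlap")
print("collapses while variance-based size measures stay high. Measures")
print("sensitive to sample size (ranges, MST distances) also react to the")
print("unequal group sizes — exactly why several measures should be read together.")
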