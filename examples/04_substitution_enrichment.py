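"""Find alignment sites substituted specifically in fragment clades.

Simulates a retained-domain alignment in which 5 'interface' sites evolve
10x faster on branches inside the fragment clades, reconstructs ancestral
residues, maps substitutions to branches, and asks which sites are enriched
for fragment-specific changes.
"""

from convloss import stats, substitutions as sub, synthetic

sc = synthetic.simulate_two_clade_tree(
    n_clade_a=16, n_clade_f=16, path_a_len=3, path_f_len=3, seed=0, clade_depth=0.7
)
interface = (10, 40, 70, 100, 130)
dm = synthetic.simulate_domain_msa(
    sc.tree, len_aldh=150, len_adh=100,
    fragment_clades=[sc.clade_a_tips, sc.clade_f_tips],
    interface_sites=interface, rate_multiplier=10.0, seed=100, base_rate=0.3,
)

msa = {k: v[:150] for k, v in dm.alignment.items()}  # retained-domain columns
post = sub.marginal_asr_aa(sc.tree, msa)
calls = sub.call_states(post, threshold=0.5)
events, diag = sub.map_substitutions(sc.tree, calls, msa)
print(f"substitution events on the tree: {len(events)} "
      f"({diag['skipped_uncertain']} branch-sites skipped as uncertain)")

frag_branches = sub.fragment_branch_set(sc.tree, sc.clade_a_tips | sc.clade_f_tips)
enr = sub.site_fragment_ratio(events, frag_branches, min_events=5)
top = sub.top_sites(enr, k=15)
print(f"sites with >=5 substitutions: {len(enr)}; top-15 by fragment ratio: {top}")
print("planted interface sites recovered in top-15:",
      sorted(s for s in interface if s in top))

groups = {s: ("interface" if s in interface else "other") for s in range(1, 151)}
table = sub.group_enrichment(enr, groups)
row = table.iloc[0]
print(f"interface vs other fragment-ratio Mann-Whitney p = {row.p_ratio:.2e} "
      f"(medians {row.median_ratio1:.2f} vs {row.median_ratio2:.2f})")
# All 5 planted fast sites rank in the top 15, and the interface group's
# fragment-specific substitution ratio is significantly higher than the rest.
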