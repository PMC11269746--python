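"""Simulate binary gene-content evolution and reconstruct it with an Mk model.

Builds a 64-species ultrametric tree, simulates presence/absence of 300
ortholog groups under gain/loss rates (0.3, 0.9), then re-estimates the
rates by maximum likelihood, draws posterior rate samples by MCMC, and
jointly reconstructs ancestral states for one ortholog group.
"""

import numpy as np

from convloss import mk, synthetic

tree = synthetic.simulate_tree(64, seed=1)
table, truth = synthetic.simulate_binary_ogs(tree, q_gain=0.3, q_loss=0.9, n_ogs=300, seed=2)
print(f"tree: {tree.n_tips} tips, depth {tree.node_depths().max():.2f}")
print(f"ortholog table: {table.shape[0]} species x {table.shape[1]} OGs, "
      f"presence fraction {table.values.mean():.3f}")

fit = mk.fit_ml(tree, table)
print(f"pooled ML rates: gain {fit.rates.q01:.3f}, loss {fit.rates.q10:.3f} "
      f"(simulated at 0.3 / 0.9)")

# per-OG posterior over rates for the first ortholog group
og = table.columns[0]
samples = mk.mcmc_sample(tree, table[og].to_dict(), n_samples=100,
                         burn_in=200, thin=10, seed=3)
med = samples.median()
print(f"{og}: posterior median gain {med.q01:.3f}, loss {med.q10:.3f}; "
      f"acceptance {samples.acceptance_rate:.2f}")
acf = mk.autocorrelation(samples.samples[:, 1], max_lag=5)
print(f"loss-rate chain autocorrelation, lags 1-5: "
      + " ".join(f"{a:+.2f}" for a in acf[1:]))

recon = mk.joint_reconstruct(tree, table[og].to_dict(), med)
true_states = truth.node_states[og]
agree = np.mean([recon.states[n] == true_states[n] for n in tree.names])
print(f"joint reconstruction matches the simulated history at "
      f"{100 * agree:.1f}% of nodes")
# Rates near the truth and >95% node agreement mean the reconstruction is
# recovering the simulated gain/loss history, not just the tip pattern.
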