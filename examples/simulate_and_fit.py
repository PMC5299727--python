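"""Generate an overdispersed taxa count table with known sparse effects,
fit the DM regression by MCMC, and select associations.

Run:  python examples/simulate_and_fit.py
"""

import numpy as np

import dmreg

# A desk-scale version of the default study design: 60 samples, 20
# covariates, 20 taxa, 8 true associations confined to a 4 x 3 block.
config = dmreg.SimulationConfig(
    n=60, P=20, J=20, P_r=4, J_r=3, n_assoc=8, psi=0.01, seed=42
)
Y, X, truth = dmreg.simulate_dataset(config)
Xs = dmreg.standardize(X)

chain = dmreg.run_mcmc(
    Y, Xs,
    dmreg.Hyperparameters.from_mean_inclusion(0.01),
    dmreg.McmcSettings(n_iterations=4000, thin=5, seed=1, progress_every=0),
)
result = dmreg.select(chain, fdr_alpha=0.1)

selected = result.selected_median_model
counts = dmreg.confusion(selected, truth.xi_true)
print(f"true associations: {truth.xi_true.sum()}")
print(f"median model selects: {selected.sum()} "
      f"(TP {counts.tp}, FP {counts.fp}, FN {counts.fn})")
print(f"MCC {dmreg.mcc(counts):.3f}  "
      f"FPR {dmreg.fpr(counts):.4f}  FNR {dmreg.fnr(counts):.3f}")
_, auc = dmreg.roc_auc(result.ppi, truth.xi_true)
print(f"AUC from sweeping the PPI threshold: {auc:.3f}")

# The conditional posterior medians estimate the log-linear effects of
# the associations the sampler kept.
for p, j in np.argwhere(selected):
    print(f"  cov {p:2d} -> taxon {j:2d}: "
          f"beta_hat {result.beta_cond_median[p, j]:+.2f} "
          f"(true {truth.beta_true[p, j]:+.2f}, PPI {result.ppi[p, j]:.2f})")
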