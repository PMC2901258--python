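"""Simulate a birth-death chronogram and recover its rates.

Generates a crown-conditioned 150-tip reconstructed tree under known
speciation/extinction rates, then fits the constant-rate birth-death
model with profile-likelihood confidence intervals.
"""

from divclock import fit_bd, relative_extinction, simulate_bd_tree

LAM_TRUE, MU_TRUE = 0.8, 0.4  # events/lineage/My

tree = simulate_bd_tree(lam=LAM_TRUE, mu=MU_TRUE, n_tips=150, seed=11)
print(f"simulated tree: {tree.n_tips} tips, crown age {tree.crown_age:.2f} My")

fit = fit_bd(tree, f=1.0)
print(f"lambda-hat = {fit.mle.lam:.3f}  95% CI ({fit.ci_lam[0]:.3f}, {fit.ci_lam[1]:.3f})")
print(f"mu-hat     = {fit.mle.mu:.3f}  95% CI ({fit.ci_mu[0]:.3f}, {fit.ci_mu[1]:.3f})")
print(f"epsilon    = {fit.epsilon:.3f}  (true {relative_extinction(LAM_TRUE, MU_TRUE):.3f})")
print(f"log-likelihood at MLE = {fit.loglik:.2f}")

# The CIs are profile-likelihood intervals: lambda (and mu) are within
# them with ~95% confidence; a mu lower bound of 0 marks a fit where
# extinction is indistinguishable from zero on this tree.
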