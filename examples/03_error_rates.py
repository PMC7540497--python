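"""Estimate the design's family-wise false-positive rates by simulation.

Under a complete null (920 independent exposures, outcome independent of
all of them) Benjamini-Hochberg FDR at 0.05 behaves like a family-wise
test: about 5% of replicate cohorts show at least one significant variable
after a single discovery stage, and about 0.25% (= 0.05^2) survive the full
discovery -> test procedure.
"""
import enwas

one_stage = enwas.estimate_fwer(m=920, n=500, stages=1, n_reps=300, seed=3)
print(f"single-stage FWER: {one_stage.fwer:.3f} "
      f"(95% CI {one_stage.fwer_ci[0]:.3f}-{one_stage.fwer_ci[1]:.3f}; expect ~0.05)")

two_stage = enwas.estimate_fwer(m=920, n=800, stages=2, n_reps=1000, seed=3)
print(f"two-stage FWER:   {two_stage.fwer:.4f} "
      f"(95% CI {two_stage.fwer_ci[0]:.4f}-{two_stage.fwer_ci[1]:.4f}; expect ~0.0025)")

power = enwas.estimate_power([0.10, 0.20], m=100, n=800, n_reps=150, seed=3)
for beta, (est, ci) in power.power.items():
    print(f"two-stage power at B={beta}: {est:.2f} (95% CI {ci[0]:.2f}-{ci[1]:.2f})")
# Use more replicates (1000 / 4000) for publication-grade estimates; these
# run sizes keep the example fast.
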