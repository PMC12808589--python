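"""Small estimator-recovery study: simulate-and-refit at the known truth.

Runs 25 replications at n=300 (the full study uses 500) and prints the
replication-mean estimate, bias and variance per parameter, mirroring the
standard consistency diagnostics for a new estimator.
"""

from mcpgig.simulate import SimulationConfig, run_study

cfg = SimulationConfig(n=300, replications=25, gamma_shape=-0.5, seed=42)
report = run_study(cfg)

print(f"{cfg.replications} replications at n={cfg.n}, gamma={cfg.gamma_shape} "
      f"({report.n_failures} convergence failures)\n")
print(f"{'parameter':>10} {'true':>8} {'mean':>9} {'bias':>9} {'variance':>9} {'mc_se':>8}")
for name, rec in report.summary().items():
    print(f"{name:>10} {rec['true']:8.3f} {rec['mean']:9.3f} {rec['bias']:+9.4f} "
          f"{rec['variance']:9.4f} {rec['mc_se']:8.4f}")
print("\nBias shrinks and variance tightens as n and the replication count")
print("grow; tau/xi are recovered only through their identified combination.")
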