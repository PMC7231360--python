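"""Fit the equivalent circuit R_s + CPE + (R_p || C_p) to an impedance
spectrum and report the recovered parameters with standard errors."""

from cardiosense import fit_circuit, reference_params, simulate_spectrum

# Simulate one acquisition (100 Hz - 2 MHz, 60 points) with 1%
# proportional noise, standing in for a measured cell-covered spectrum.
truth = reference_params()
spectrum = simulate_spectrum(truth, noise_rel=0.01, seed=42)

fit = fit_circuit(spectrum, n_starts=8, seed=0)
print(f"converged: {fit.converged} (starts used: {fit.n_starts_used})")
print(f"weighted residual norm: {fit.residual_norm:.4f}")
print(f"{'parameter':>10} {'fitted':>12} {'stderr':>12} {'truth':>12}")
for name in ("r_s", "q", "n", "r_p", "c_p"):
    print(f"{name:>10} {getattr(fit.params, name):12.4g} "
          f"{fit.stderr[name]:12.2g} {getattr(truth, name):12.4g}")
# R_s is the series (solution + electrode) resistance, Q/n the electrode
# double-layer CPE, and R_p/C_p the cell-electrode interface -- the
# cell-sensitive parameters an ECIS experiment tracks over time.
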