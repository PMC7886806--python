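"""Equal absolute fitness, different composition: the sharer wins.

Framework 2 gives both populations the same omega = alpha - beta + gamma
(here 0.06) but population A earns it mostly through the sharing bonus
(gamma_A = 0.08) while B earns it through own use (alpha_B = 0.08).
Desk scale: 600 samples.
"""

import epmoran as em

config = em.SimConfig(
    framework=2,
    alpha_a=0.01, gamma_a=0.08,  # A: modest own-use bonus, big sharing bonus
    alpha_b=0.08, gamma_b=0.01,  # B: the mirror image
    beta_a=0.03, beta_b=0.03,
)
om_a = em.omega(config.alpha_a, config.beta_a, config.gamma_a).omega
om_b = em.omega(config.alpha_b, config.beta_b, config.gamma_b).omega
print(f"omega_A = {om_a:.2f}, omega_B = {om_b:.2f} (identical by construction)")

records, summary = em.run_batch(config, n_graphs=3, samples_per_graph=200, base_seed=0)
print(f"samples: {summary.n_samples}")
print(f"fixation of A (high gamma): {summary.frac_fixed_a:.3f}")
print(f"fixation of B (high alpha): {summary.frac_fixed_b:.3f}")
print(f"undefined:                  {summary.frac_undefined:.3f}")
print("\nWith omega tied, the population that earns its fitness through")
print("REUSING abandoned extended phenotypes out-fixes the one that earns")
print("it by using its own.")
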