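"""Reference arithmetic for the aspirin–albumin unbinding experiment.

Three deterministic conversions: the experimental affinity constant of the
HSA–acetylsalicylic-acid complex to a free-energy magnitude, the viscous
correction of reported pull-work estimates with quadrature error
propagation, and the interior-region fraction of the pull path.
"""

import pullwork as pw

# quenching-fluorescence affinity constant of the HSA-aspirin complex
ka = 18.79e3            # 1/M
temperature = 300.0     # K
dg = pw.delta_g_from_ka(ka, temperature)
kBT = 1.380649e-23 * temperature
print(f"Ka = {ka:.4g} 1/M at {temperature:g} K")
print(f"  dG = kBT ln(Ka c0) = {dg:.3g} J = {dg / kBT:.2f} kBT")

# viscous correction of reported work estimates (units of 1e-19 J):
# bound W^x = 4.0 +/- 0.6, viscous W^x = 0.4 +/- 0.2
bound = pw.EstimatorResult(Wa=5.0e-19, Wx=4.0e-19, se_Wa=0.6e-19,
                           se_Wx=0.6e-19, N_s=30, temperature_T=temperature,
                           kBT=kBT, label="bound")
viscous = pw.EstimatorResult(Wa=0.8e-19, Wx=0.4e-19, se_Wa=0.2e-19,
                             se_Wx=0.2e-19, N_s=30,
                             temperature_T=temperature, kBT=kBT,
                             label="viscous")
corr = pw.viscous_correction(bound, viscous)
value, err = pw.display_correction(corr, bound, viscous, scale=1e-19)
print(f"corrected W^x = ({value} ± {err}) x 1e-19 J "
      f"(raw uncertainty {corr.se_Wx / 1e-19:.3f} before display rounding)")

# interior (binding-pocket) region of a 5-unit pull with threshold at 1.47
import numpy as np
x = np.linspace(0.0, 5.0, 101)
series = [pw.WorkSeries(pull_coordinate=x, cumulative_work=x)]
part = pw.partition_work(series, 1.47, 5.0)
print(f"interior region: {100 * part.interior_fraction:.1f}% of the pull "
      f"(boundary {part.boundary_coordinate:g} of {part.total_distance:g})")
print()
print("The corrected W^x remains well above the experimental dG, as a "
      "finite-sampling upper bound must.")
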