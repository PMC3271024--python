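"""Fit a retinal sensitivity function to a simulated mapping session.

Generates the 400-trial eccentricity-mapping design (5 eccentricities x 2
sides x 2 configurations x 20 repetitions), simulates responses from a known
ground-truth psi, and refits it.
"""

from sacstrat import (
    PsychometricParams,
    build_mapping_design,
    exp1_mapping_design_spec,
    fit_sensitivity,
    simulate_mapping_responses,
)

truth = PsychometricParams(alpha=1.0, beta=0.5, e_half=5.93, gamma=1.0)
design = build_mapping_design(exp1_mapping_design_spec(), seed=1)
trials = simulate_mapping_responses(design, truth, seed=1)
fit = fit_sensitivity(trials)

print(f"simulated {len(trials)} mapping trials from truth e_half={truth.e_half}")
print(fit.to_text())
# alpha/beta are the foveal and asymptotic probabilities correct; e_half is
# the eccentricity of the 75%-correct point (when alpha~1, beta~0.5); the
# fitted e_half should land within a fraction of a degree of 5.93.
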