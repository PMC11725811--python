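"""Ratiometric MYO7A quantification at five landmarks along a hair cell.

Control stacks carry the full compartment-specific MYO7A/F-actin ratios; a
knockout stack scales them by 0.1 (a 90% knockdown).  Each landmark is
measured as the MYO7A intensity averaged in an anisotropic Gaussian volume
divided by the F-actin average with identical weights.
"""

from metkit.confocal import Landmark, local_ratio, profile_cells, reduction_table
from metkit.synthetic import StackSpec, simulate_confocal_stack

base = StackSpec()
measurements = []
for genotype, scale in (("control", 1.0), ("ko", 0.1)):
    spec = base.scaled_ratios(scale)
    for cell in range(4):
        sim = simulate_confocal_stack(spec, seed=10 * cell + 1)
        for name, pos in spec.landmarks.items():
            measurements.append(
                local_ratio(sim.stack, Landmark(name, pos),
                            cell_id=f"{genotype}{cell}", genotype=genotype)
            )

summary = profile_cells(measurements)
print(summary.to_string(index=False))
red = reduction_table(summary, ko="ko", control="control")
print()
print(red.to_string(index=False))
print("\npercent_reduction = 100 * (1 - mean_ko / mean_control); the")
print("generator's true knockdown is 90% at every landmark.")
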