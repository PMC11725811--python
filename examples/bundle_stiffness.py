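"""Hair-bundle stiffness from a fluid-jet force step.

A 900-frame movie (5 kHz) of the bundle edge is resliced into a kymograph;
each row is fitted with a Gaussian amplitude function to localize the edge
at sub-pixel resolution, and the steady-state displacement at the end of
the step gives k = F / x_steady.
"""

from metkit.bundle_motion import (
    estimate_stiffness,
    reslice_kymograph,
    track_displacement,
)
from metkit.synthetic import FluidJetModel, MovieSpec, simulate_bundle_movie

jet = FluidJetModel(k_true=3.0)                 # ground truth: 3 mN/m
spec = MovieSpec()                              # 50 nm pixels, shot noise
sim = simulate_bundle_movie(spec, jet, [(0.3, 60.0, 90.0)], seed=1)

kymo = reslice_kymograph(sim.movie)             # space x time reslice
trace = track_displacement(kymo)                # per-frame Gaussian fits
est = estimate_stiffness(trace, sim.movie.stimulus_force)

print(f"force step:        {est.force * 1000:.0f} pN")
print(f"steady-state x:    {est.x_steady:.1f} nm (truth {sim.truth_steady_nm[0]:.0f} nm)")
print(f"stiffness k:       {est.k:.3f} mN/m (truth {jet.k_true} mN/m)")
print(f"fit quality (CV):  {est.quality:.3f}")
print("k = F / x_steady over the final 20% of the step; the Gaussian-fit")
print("tracker resolves the edge to a few nanometres despite 50 nm pixels.")
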