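# metkit

Quantitative analysis of hair-cell mechanoelectrical transduction (MET)
data, for auditory-physiology labs working on cochlear hair cells. The
package covers the four measurement modalities of a typical MET study and
ships a ground-truth synthetic-data generator so every analysis stage can
be validated end to end without raw recordings:

* **MET currents** (`metkit.met_traces`) — cycle-averaged responses to
  sinusoidal fluid-jet stimuli, the peak-to-peak transducer current
  `i_max = i_exc − i_inhib`, the resting open probability
  `P_open = (i_hold − i_inhib) / i_max` (the fraction of the maximal MET
  current active with the bundle at rest), peak-to-peak I–V curves with an
  interpolated reversal potential, and a saturation check for gradually
  increased stimuli.
* **Bundle motion and stiffness** (`metkit.bundle_motion`) — kymograph
  reslicing of bundle movies, sub-pixel localization of the bundle edge by
  fitting `offset + A·exp(−(p−c)²/2σ²)` to each normalized line profile,
  displacement tracking, and the apparent steady-state bundle stiffness
  `k = F / x_steady` from fluid-jet force steps.
* **Ratiometric confocal quantification** (`metkit.confocal`) — MYO7A
  immunofluorescence normalized to F-actin in anisotropic Gaussian volumes
  at five anatomical landmarks (stereocilia tips and bases, cuticular
  plate, apical and basal cytoplasm), group summaries and percent
  reduction `100·(1 − mean_ko / mean_control)`.
* **Gene-set overlap** (`metkit.genesets`) — DEG thresholding
  (`|log2FC| > 0.5`, `lfcSE < 0.5`, `padj < 0.01`, all strict), exact Venn
  partitions, overlap percentages (raw + round-half-up), and bundle-gene
  panel overlap with up/down splits.
* **Cohort statistics and orchestration** (`metkit.cohort`,
  `metkit.pipeline`) — tip-link percentages, Welch's t and exact
  Mann–Whitney U tests (full enumeration for combined n ≤ 20), and a
  deterministic end-to-end pipeline with a replayable manifest.

The generator (`metkit.synthetic`) models the transducer as a two-state
Boltzmann, `P_open(x) = 1/(1 + exp(−(x − x_half)/λ))`, driven by the
damped-spring response of the bundle to the low-passed fluid-jet force,
with a Ca²⁺-dependent adaptation shift of the set point that vanishes
under 5 mM BAPTA. See `docs/methods.md` for the model, units and defaults.

## Worked example

`examples/bundle_stiffness.py` simulates a 900-frame movie (5 kHz, 50 nm
pixels, shot noise) of a bundle with true stiffness 3 mN/m responding to a
300 pN force step, then runs the full tracking chain:

```text
force step:        300 pN
steady-state x:    100.3 nm (truth 100 nm)
stiffness k:       2.991 mN/m (truth 3.0 mN/m)
fit quality (CV):  0.051
```

The steady-state displacement is Hooke's law (300 pN / 3 mN/m = 100 nm)
and the Gaussian-fit tracker recovers it to a few nanometres despite the
50 nm pixel size, giving a stiffness estimate within 1% in this run.

`examples/met_current_analysis.py` runs the voltage series. A condensed
version of its output:

```text
V_m (mV)   i_max (pA)   P_open   true P_open
   -124       -986.7    0.055      0.054
    -84       -671.1    0.102      0.102
     96        769.0    0.500      0.500

reversal potential: +0.12 mV (model e_rev = 0 mV)
```

The transduction current reverses near 0 mV (nonselective cation channel)
and the resting open probability rises toward positive potentials, where
the Ca²⁺-dependent adaptation shift vanishes. The other examples
(`confocal_ratios.py`, `gene_overlap.py`, `group_statistics.py`) follow
the same pattern: build a small synthetic input, run the analysis, print
the recovered numbers next to the ground truth.

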