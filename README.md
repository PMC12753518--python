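# cochsim

Simulation of auditory-nerve-fiber (ANF) excitation by cochlear-implant
electrode arrays in the scala tympani (ST) and scala vestibuli (SV).

Cochlear implants restore hearing by injecting current through intracochlear
contacts; how much current a fiber needs, and where along the fiber the spike
starts, depends on the array's position (peri-modiolar `pm` vs lateral-wall
`lw`), the scala it sits in, the fiber's health, and the electrical makeup of
the surrounding tissue. `cochsim` builds a fully synthetic, parametric human
cochlea (two-turn spiral, three scalae, modiolus, bone, 25 fiber
trajectories), fits the four array centerlines `pmST | pmSV | lwST | lwSV`
under the constant-minimum-distance constraint (255 μm to every fiber), and
then runs the standard two-step excitation pipeline:

1. **Volume conductor** — the extracellular potential `Ve` of a monopolar
   contact at unit current, from a finite-volume discretization of
   `∇·(σ∇V) = −s` on a voxelized conductivity map (harmonic-mean face
   conductivities, grounded far boundary, conjugate-gradient solve to 1e-8).
2. **Cable model** — a human type-I spiral-ganglion-cell compartment chain
   (terminal, myelinated internodes, nodes of Ranvier, pre-somatic segment,
   three-layered soma, post-somatic segment, central axon) with
   temperature-adjusted Hodgkin–Huxley kinetics, integrated semi-implicitly.
   The threshold of a 50 μs monophasic pulse is found by bracketing and
   bisection to 1 %; the spike initiation site (SIS) is the compartment with
   the earliest suprathreshold peak.

On top of that sit the population analyses: fiber×contact threshold matrices,
stimulation specificity and selectivity maps, neural-degeneration experiments
(thin or absent dendrites), conductivity sensitivity (modiolus ×10, bone ×2)
and progressive ST-ossification sweeps, and normalized potential profiles
along the carrier. `docs/methods.md` describes the model, every default, and
what the synthetic geometry can and cannot reproduce.

## Worked example

```python
import numpy as np
from cochsim import (build_geometry, place_anfs, fit_centerline, place_contacts,
                     voxelize, solve_field, assemble_chain, threshold_search)

geom = build_geometry()                      # default synthetic cochlea
fibers = place_anfs(geom)                    # 25 fibers, ANF23 ... ANF680
cl = fit_centerline(geom, fibers, "ST", "lw")
print(f"lwST centerline: {cl.total_length/1000:.2f} mm")

arr = place_contacts(cl, [fibers[12].alpha_deg])   # contact at the median fiber
cmap = voxelize(geom, [arr], spacing=300.0)        # voxel conductivity map
field = solve_field(cmap, "EL352")                 # unit-current potential (mV/uA)
chain = assemble_chain(fibers[12])                 # healthy compartment chain
res = threshold_search(chain, field)
print(f"ANF352 cathodic threshold: {res.threshold_ua:.1f} uA, "
      f"SIS = {res.sis_kind}, latency = {res.latency_ms:.2f} ms")
```

prints

```
lwST centerline: 26.91 mm
ANF352 cathodic threshold: 75.3 uA, SIS = terminal, latency = 1.55 ms
```

i.e. the fitted lateral-wall ST array is 26.9 mm long; its mid-cochlear
contact excites the target fiber at 75 μA of cathodic current, the action
potential starts at the dendritic terminal (the typical lateral-wall
initiation site), and the spike reaches the central axon about 1.5 ms after
pulse onset. Lateral-wall contacts sit closest to the fiber terminals;
peri-modiolar contacts approach basal fibers mid-dendrite, which shifts
thresholds and initiation sites accordingly.

A command-line interface mirrors the library
(`cochsim generate-geometry | build-arrays | solve-field | simulate-fiber |
threshold-matrix | run-experiment | analyze | run | summarize`); `cochsim run
--config cfg.yaml --out rundir` executes the configured pipeline end to end
with content-hash caching of the expensive field stage.

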