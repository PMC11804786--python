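# coralflow

Internal flow and acidification risk of branching-coral skeletons, at desk
scale.

Dead *Acropora* coral skeletons are porous aragonite structures: a ring of
radial corallite cavities connects a central axial channel to the rough,
bumpy outer surface. When an ambient current flows past a submerged branch,
pressure gradients drive a weak but persistent seepage flow *through* the
skeleton. That internal flow matters twice over: it transports dissolved
material through the pore network (relevant to how polyps grow and how dead
branches re-colonize), and under ocean acidification it carries protons into
the skeleton, dissolving aragonite from the inside and weakening the branch.

`coralflow` packages that whole computational chain for researchers in
biophysical hydrodynamics and coral-reef science who want to study it
without micro-CT data or a supercomputer:

1. **`coralflow.geometry`** — a synthetic voxel generator that rasterizes
   the structural motifs of an *A. pulchra* branch (surface bumps, radial
   corallites, bending axial channel, apical corallite, optional defect)
   onto a regular grid, plus porosity accounting and inner/external pore
   labelling for segmented volumes (TIFF stacks + JSON sidecar).
2. **`coralflow.lbm`** — a D3Q19 single-relaxation-time (BGK)
   lattice-Boltzmann solver with the submerged-branch boundary set:
   velocity inlet with an open-channel profile, constant-pressure outlet,
   periodic transverse sides, free-slip sea surface, no-slip seabed, and
   half-way bounce-back on the skeleton. Runs are monitored to a
   quasi-steady state through the domain-average kinetic energy.
3. **`coralflow.analysis`** — vorticity and enstrophy
   (`E = |∇×u|²/2`), streamline tracing (RK4, trilinear interpolation),
   per-sub-volume residence times (`t = Σ |Δl|/|u|`), pore volume flux
   (`Q = V_pores / t̄`), upstream/downstream asymmetry statistics and the
   axial-channel velocity decomposition (`u_z/|u|` per section).
4. **`coralflow.dissolution`** — the acidification model: an equivalent
   CaCO₃ tube with 1-D proton advection-reaction
   (`∂C/∂t + u ∂C/∂x = −r(C)`, `r(C) = 2.5×10⁻⁷(e^{1.98×10⁵C} − 1)`,
   `C = 10^(3−pH)` mol m⁻³), its closed-form characteristic solution, an
   independent upwind solver, two acid-source scenarios, and the projected
   inner-radius growth, porosity change ratio `N` and flexural-rigidity
   reduction `G = (V₀^e − V_t^e)/V₀^e` with `e = 2/1.4728 = 1.358`.
5. **`coralflow.pipeline` / the `coralflow` CLI** — a YAML-configured
   generate → simulate → analyze → dissolve chain with per-stage artifacts
   (TIFF/HDF5/CSV/VTK) and a checksummed JSON manifest.

## Worked example

```python
from coralflow import lbm
from coralflow.dissolution import (PipeModel, AcidScenario,
                                   project_scenario, JULIAN_YEAR)

print("Re =", lbm.reynolds(u_inlet=0.0009, width=0.012, nu=1.0e-6))

pipe = PipeModel(R_O=0.006, R_I=0.001, H=0.04, n0=0.5)
for label, pH in [("2023", 8.10), ("2100", 7.87)]:
    res = project_scenario(pipe, AcidScenario("inside-acid", pH=pH,
                                              t=JULIAN_YEAR, label=label))
    print(f"{label}: rate = {res.rate:.3e} mol m^-3 s^-1, "
          f"N = {res.porosity_change_percent:.4f} %, "
          f"G = {res.rigidity_reduction_percent:.4f} %")
```

prints

```
Re = 10.8
2023: rate = 9.550e-07 mol m^-3 s^-1, N = 0.0062 %, G = 0.0043 %
2100: rate = 3.363e-06 mol m^-3 s^-1, N = 0.0219 %, G = 0.0153 %
```

`Re = 10.8` is the Reynolds number of a 0.09 cm/s ambient current over a
1.2 cm branch — the low-flow laminar regime. The dissolution lines project
one year of a maintained low-pH microenvironment inside a 4 cm carbonate
tube: dropping ambient pH from 8.10 to 7.87 multiplies the dissolution rate
by ~3.5 and, for this tube, the porosity change ratio `N` and rigidity loss
`G` in proportion. (`N` and `G` scale with the rate, the horizon, and the
tube geometry; a thin-walled tube or a century horizon yields damage orders
of magnitude larger.)

A full end-to-end run from a config file:

```bash
coralflow run --config examples/demo.yaml --outdir out/
```

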