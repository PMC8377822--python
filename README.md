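# rvflow

Regional intracardiac-flow quantification for the right ventricle (RV) from
4D-flow cardiovascular MR.  Chronic pulmonary regurgitation (PR) — the
dominant residual lesion after tetralogy-of-Fallot repair — drives a
diastolic regurgitant jet back through the RV outflow tract (RVOT) that
disrupts the normal "donut"-shaped ring vortex around the tricuspid inflow.
`rvflow` turns a time-resolved 3D velocity field and an RV segmentation into
regional vorticity and viscous energy-loss curves and condenses them into
three unitless quotient biomarkers that grade this flow disturbance, then
runs the cohort-level statistics that relate them to conventional CMR and
exercise measures.

It is written for imaging scientists post-processing 4D-flow exports
(per-component NIfTI velocity volumes plus a label volume and landmark
picks) and for methodologists who want a fully synthetic, ground-truthed
test bed for regional flow metrics.

## The quantities

With velocity field $\vec u$ (m/s) on a voxel grid, vorticity is the curl

$$\vec\omega = \nabla\times\vec u,$$

integrated as *absolute vorticity* $\int_V \lVert\vec\omega\rVert\,dV$ (L/s)
over each region $V$ and normalized by the region volume to $\omega$ (1/s).
Viscous energy loss (mW) is the dissipation integral

$$\mathrm{VEL} = \int_V \tfrac{1}{2}\mu \sum_{i,j}\left(\frac{\partial u_i}{\partial x_j} + \frac{\partial u_j}{\partial x_i}\right)^{\!2} dV,
\qquad \mu = 0.004\ \mathrm{Pa\,s}.$$

The RV is divided by two static end-diastolic planes — one through the
antero-septal commissure of the tricuspid annulus parallel to the 4-chamber
plane (separating the RVOT), one bisecting the long axis (inflow vs apex).
Per-window peaks of the regional curves give the biomarkers

- **RV-DVQ** $= \omega_{\mathrm{RVOT\text{-}Dia}}/\omega_{\mathrm{Inflow\text{-}Dia}}$ — values > 1 mean the diastolic vorticity lives in the outflow tract rather than the inflow ring vortex;
- **RVOT-VQ** $= \omega_{\mathrm{RVOT\text{-}Dia}}/\omega_{\mathrm{RVOT\text{-}Sys}}$;
- **RVOT-EQ** $= \mathrm{VEL}_{\mathrm{RVOT\text{-}Dia}}/\mathrm{VEL}_{\mathrm{RVOT\text{-}Sys}}$.

## Worked example

A synthetic RV phantom at regurgitation severity `s = 0.6` (diastolic
regurgitant jet at 60% of full strength, inflow vortex attenuated
accordingly), pushed through the complete measurement chain:

```bash
python analysis/02_phantom_subject.py
```

prints

```
{
  "omega_inflow_diastole_per_s": 73.94301750715628,
  "omega_rvot_diastole_per_s": 84.2121458328205,
  "omega_rvot_systole_per_s": 102.8780440727639,
  "rv_dvq": 1.1388789458676116,
  "rvot_eq": 0.843439338589106,
  "rvot_vq": 0.8185628584973745,
  "vel_rvot_diastole_mw": 0.46893123485102606,
  "vel_rvot_systole_mw": 0.5559750575962558
}
```

The diastolic RVOT vorticity (84 s⁻¹) already exceeds the weakened inflow
vortex (74 s⁻¹), so RV-DVQ = 1.14 — the outflow tract dominates diastole,
the signature of significant regurgitation.  Sweeping severity
(`analysis/03_severity_sweep.py`) shows RV-DVQ rising monotonically from
0.08 at `s = 0` to 2.73 at `s = 1`, crossing 1 as the jet overtakes the
ring vortex, and `analysis/04_cohort_stats.py` runs the group ANOVA and
correlation tables on a 98-subject synthetic cohort.

The same pipeline runs on real exports from the shell:

```bash
rvflow metrics --vx vx.nii.gz --vy vy.nii.gz --vz vz.nii.gz \
    --rv-mask rv.nii.gz --landmarks landmarks.yaml --venc 2.5 \
    --systole 0:7 --diastole 8:19 --out results/
```

Subcommands: `metrics`, `divide`, `phantom`, `cohort`, `stats`.

## Layout

- `src/rvflow/` — the library: `fields` (data model, NIfTI/YAML I/O,
  background-phase correction, noise screening), `regions` (two-plane
  division), `hemodynamics` (gradients, curl, VEL, peaks, quotients,
  particle advection), `phantom` (analytic flows, RV phantom, cohorts),
  `stats` (ANOVA, Pearson, tables), `pipeline` + `cli`.
- `analysis/` — numbered drivers reproducing the analysis narrative.
- `docs/methods.md` — models, assumptions, numerical choices, limitations.
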