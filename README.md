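# excidock

Blind docking of formulation excipients onto protein surfaces: hotspot
mapping, aggregation-interface overlap, and melting-temperature
correlation.

## The problem

Therapeutic proteins (antibody Fab fragments, for instance) aggregate
through non-covalent protein–protein contacts, and formulation scientists
suppress this by adding excipients — sugars (trehalose, sucrose), polyols
(mannitol, sorbitol), amino acids (glycine, arginine) and surfactants
(polysorbate 20/80). Which excipient helps a given protein is usually found
by brute-force screening. `excidock` implements a structure-based
alternative: dock each candidate excipient **blindly over the entire
protein surface** (no binding-site prior), consolidate the resulting poses
into residue-level *interaction hotspots*, dock a second copy of the
protein against itself to locate surfaces prone to self-association, and
ask whether the excipient hotspots sit on those aggregation-prone
interfaces. A per-excipient mean binding energy is finally correlated with
the measured melting temperature T_m of the co-formulated protein.

## The models

**Rigid protein–protein docking** scores a pose with a softened
Lennard-Jones potential over intermolecular heavy-atom pairs,

```
V(r) = 1/(α σ⁶ + r⁶) · (4 ε σ¹² / (α σ⁶ + r⁶) − 4 ε σ⁶)
```

with α = 0.4, σ = 3.3 Å (0.33 nm), ε = 0.5, finite at r = 0
(V(0) = 4ε(1−α)/α² = 7.5) and reducing to the standard 12-6 potential as
α → 0, plus a small-weight screened electrostatic term. The search is a
direct exhaustive scan over a quasi-uniform orientation set × a 1 Å
translation lattice, followed by local refinement; the 100 best solutions
are clustered greedily at a 3 Å Cα RMSD threshold.

**Flexible excipient docking** uses a genetic algorithm (population 800,
10 generations, ≤ 5 active torsions, 10 reported solutions) minimising an
empirical score

```
E_tot = E_bind + E_pharma + E_ligpre
```

where E_bind sums piecewise-linear hydrogen-bond and steric pair wells
(plus Coulomb between formally charged atoms) over inter- and
intramolecular pairs together with a fixed 10000 penalty for leaving the
search box, and E_ligpre = WP_elec + WP_hb penalises poses that leave a
charged or hydrogen-bonding-capable ligand unsatisfied.

**Analysis** layers: 4 Å contact residues and typed 3.5 Å interaction maps,
connectivity-based pose→spot→hotspot consolidation, hotspot/interface
overlap tables, trajectory contact persistence against the 4 Å cutoff,
RMSD/RMSF, and an OLS fit of T_m on mean binding energy.

## Worked example

A reference dataset from a published Fab excipient screen (eight common
excipients with measured T_m and per-pose docking energies) ships with the
package:

```python
from excidock.stability_corr import (
    load_reference_dataset, apply_exclusions, fit_linear)

records = apply_exclusions(load_reference_dataset(), ["arginine"])
for r in records[:3]:
    print(f"{r.excipient:10s} Tm={r.t_m:5.2f}  mean_E={r.mean_e:7.2f}")
res = fit_linear(records)
print(f"slope={res.slope:.4f}  intercept={res.intercept:.2f}  "
      f"r={res.pearson_r:.3f}  R^2={res.r_squared:.3f}  n={res.n_used}")
```

prints

```
trehalose  Tm=80.40  mean_E= -13.05
sucrose    Tm=80.16  mean_E= -15.40
mannitol   Tm=80.06  mean_E= -10.13
slope=-0.0699  intercept=79.37  r=-0.769  R^2=0.591  n=7
```

The negative slope says stronger predicted binding (more negative mean
energy) accompanies a higher melting temperature across the non-arginine
excipients; arginine is excluded as a negative control because it binds
well yet *destabilises* the Fab through a detergent-like mechanism.

The full pipeline runs on generated inputs in one command:

```
excidock demo --seed 0 --out demo_out
```

which builds a toy receptor with a planted polar pocket, four excipient
classes, a complementary protein pair and a snapshot trajectory, then
docks, consolidates hotspots, overlaps them with the protein–protein
interface, validates contact persistence (1.0 on the held-contact
trajectory) and fits the T_m correlation, writing JSON/CSV/Markdown
reports. Individual stages are exposed as `dock-flex`, `dock-rigid`,
`hotspots`, `overlap`, `traj` and `correlate` subcommands whose outputs
chain into each other.

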