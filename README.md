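# cdsolv

Hydrogen-mass modification of united-atom molecular topologies, and
solvent-structure analysis of MD trajectories around pseudo-cylindrical
host–guest complexes — built around the 2:1 α-cyclodextrin/dodecyl-sulfate
(α-CD₂SDS₁) inclusion complex, but driven entirely by atom labels and
selections so any two-ring nanocylinder scaffold works.

## Who this is for

Simulators of cyclodextrin (and similar macrocyclic) complexes who want to

1. **speed up sampling** by making hydrogens heavier so a longer integration
   time step is stable, and
2. **characterise the solvent** around the complex in the bulk and at a
   water/air interface: density and dipole-orientation maps, ring-breathing
   dynamics, adsorption geometry, per-ring hydration, hydrogen bonds.

## The two mass schemes

The fastest motions in any force field belong to the lightest atoms, the
hydrogens; they limit the integration time step. For a united-atom force
field only the *polar* hydrogens (the hydroxyl H2, H3, H6 of each
glucopyranoside unit) are explicit, so manipulating their mass is cheap:

* **HMR** (hydrogen mass repartitioning): each polar H gains Δ = 3 Da taken
  from its bonded heavy atom (O2, O3 or O6). Total molecular mass is
  conserved exactly: m(H) → m(H)+Δ, m(X) → m(X)−Δ.
* **H2Q** (hydrogen → quadium): each polar H mass is set from 1 to 4 Da and
  nothing is compensated, emulating substitution by the mass-4 hydrogen
  isotope. The molecule gains Δ per polar hydrogen.

For α-CD (C₃₆H₆₀O₃₀, 972.8 Da) adding 3 Da to *all* 60 H (the all-atom
case) inflates the mass by 18.5 %, but adding it only to the 18 polar H of
the united-atom representation costs just 5.5 % — and the surfactant, with
no polar H at all in united-atom form, does not change. The
`cdsolv.topology` module applies either scheme to GROMACS-dialect `.top`/
`.itp` files byte-conservatively: a diff against the input touches only the
mass fields of the modified atoms.

## The analysis stack

Trajectories are aligned on the twelve O4 ether oxygens (six per
cyclodextrin) of the complex: the segment joining the two O4 centroids
defines the body axis, placed along a lab axis. Around the aligned complex
the package measures

* **density/dipole maps**: nine 3 Å slices perpendicular to the axis
  (central ±1.5 Å, then 1–4, 4–7, 7–10, 10–13 Å toward each ring), one 3 Å
  slice containing the axis, and thirteen 1 Å coaxial cylindrical shells —
  all at 0.5 × 0.5 Å² with per-bin mean water-dipole vectors in Debye;
* **hexagon areas** of the O2/O3/O4/O5/O6 hexagons of each ring vs time;
* **interface orientation**: yaw, pitch, and unwrapped roll of the body
  axis relative to the water surface, plus the axis-to-water-COM distance;
* **per-ring hydration** at 3/5 Å cutoffs (any-atom and ring-centre modes)
  and minimum-hydration frame selection, which identifies the air-facing
  ring per frame for conditioning interface maps;
* **hydrogen bonds** by the geometric 3.5 Å / 30° criterion, with average
  counts per group and continuous (uninterrupted-run) lifetimes.

A synthetic-trajectory generator (`cdsolv.synth`) produces a labelled
two-ring scaffold plus rigid three-site waters with controllable radial
density layering, dipole-orientation bias, rigid-body motion, roll, and a
dry cap over a chosen ring — every analysis is validated by recovering the
generator's parameters.

## Worked example

```bash
python examples/01_mass_schemes.py
```

prints

```
macrocycle, all-atom, all 60 H:   972.38 Da, +3 Da per H adds  180.0 Da = 18.51 % of the molecule
macrocycle, united-atom, 18 polar H:   972.71 Da, +3 Da per H adds   54.0 Da =  5.55 % of the molecule
surfactant salt, all-atom, 25 H:   288.18 Da, +3 Da per H adds   75.0 Da = 26.03 % of the molecule

HMR on the united-atom macrocycle: total mass change +0.0 Da (mass moves O->H, sum conserved)
```

— the all-atom vs united-atom contrast (18.5 % vs 5.5 %, and 26 % vs 0 %
for the surfactant) is the arithmetic case for heavier polar hydrogens in
united-atom force fields. The other examples demonstrate density-layer
recovery by the shell analysis (`02`), roll-turn counting and pitch at an
interface (`03`), dry-cap detection by minimum hydration (`04`) and
hydrogen-bond lifetime estimation (`05`).

The same operations are scriptable from a shell:

```bash
cdsolv massmod --mode h2q --in topol.itp --out topol_h2q.itp --report report.txt
cdsolv synth --out-structure s.gro --out-traj t.trr --n-frames 100 --seed 1
cdsolv align bulk --structure s.gro --traj t.trr --out-structure a.gro --out-traj a.trr
cdsolv maps shell --structure s.gro --traj t.trr --out mapdir/
cdsolv hydration --structure s.gro --traj t.trr --out hyd.tsv
```

## Layout

```
src/cdsolv/        topology, trajectory, maps, geometry, hydration,
                   hbonds, synth, config, cli
examples/          one narrative script per capability
tests/             pytest suite (unit, property and acceptance tests)
docs/methods.md    models, conventions, parameter choices, limitations
```
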