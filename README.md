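# lipidlens

Trajectory analysis of triglyceride (TG) handling by the lipid droplet
assembly complex (LDAC) — the toroidal seipin–LDAF1 oligomer in the ER
membrane that nucleates lipid droplets.  Aimed at membrane-simulation
practitioners who need the standard battery of protein–lipid observables
computed reproducibly from molecular-dynamics trajectories: TG–residue
binding and a dissociation constant, spatially partitioned lateral
diffusion, a per-residue interaction score, oil-lens (phase-separation)
detection, and the lumenal-domain tilt angle.

Because microsecond-scale simulations of ~4000-lipid bilayers are not
reproducible at desk scale, the package ships first-class synthetic-data
generators with known ground truth, and every analysis is validated
end-to-end against them.

## The observables

**Dissociation constant** from bound/unbound frame counts of a TG molecule
against a residue group (e.g. the conserved serines of the inner-ring
protein):

    K_D = [TG] · N_unbound / N_bound

with [TG] carried verbatim in the configured unit (e.g. mol%).  Bound state
is a hysteresis rule on the minimum-image distance between the TG central
glycerol centroid and the nearest residue bead (default 7 Å).  Uncertainty
comes from a moving-block bootstrap over contiguous segments.

**Lateral diffusion coefficient** via the 2-D Einstein relation on the
time-origin-averaged mean-squared displacement of TG glycerol XY
coordinates,

    D = ¼ d/dt ⟨ (1/N) Σᵢ |rᵢ(t₀+τ) − rᵢ(t₀)|² ⟩_{t₀},

computed separately for TG "within the complex" and "in the bulk membrane"
(radial whole-window classification; boundary crossers excluded), with the
fold reduction D_bulk/D_complex as the headline number.

**Interaction score** per protein residue, summing a logistic kernel over
all (TG bead, residue bead) minimum-image pairs:

    s = Σ_{i,j} 2 / (1 + e^{0.5 r_ij}),     r in Å.

All-atom trajectories are first mapped to coarse-grained bead resolution
(centroid mapping) so AA and CG profiles are comparable.

**Lens nucleation**: single-linkage clustering of TG glycerol centroids
(12 Å default cutoff); "phase-separated" when the largest cluster exceeds
50% of TG over a sustained final span, with chamber-annulus localisation.

**Tilt angle**: θ = arccos(|v·n|/|v|) between the membrane normal and the
vector joining two residue centroids (default Ser126→Ser131).

## Worked example

Recover the two diffusion regimes from a synthetic two-regime walk (500
particles, 2000 frames, ground truth D_bulk = 1.1, D_trap = 0.2 Å²/ns):

```bash
python analysis/02_diffusion_recovery.py --seed 1
```

```
window assignments: {'bulk': 6081, 'complex': 2918, 'excluded': 1001}
D_bulk = 1.0974 ± 0.0002 Å²/ns (R² = 1.00000)
D_complex = 0.1945 ± 0.0000 Å²/ns (R² = 1.00000)
fold reduction = 5.64 ± 0.00 (truth 5.50)
```

Both coefficients land within a few percent of truth and the fold
reduction within 3%.  The same battery is available through the CLI:

```bash
lipidlens analyze --scenario trap-recovery --seed 1 --out results/run
lipidlens generate nucleation --seed 1 --out scratch/fix
lipidlens validate --config my_run.yaml
```

`analysis/01…06` run the full narrative: synthetic generation, diffusion
recovery, K_D estimation (`KD = 0.5075, 95% CI 0.4995–0.5152` against truth
0.5), the interaction profile (the four conserved contact residues Phe57,
Ser61, Leu105, Ser109 rank top-4 of 16), nucleation detection (onset frame
25 detected exactly; dispersed control negative), and the tilt closed
forms (0°/90°/45°).

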