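# ionpore

Concentration-dependent ion selectivity analysis for wide membrane
channels, built around the physics of the voltage-dependent anion channel
(VDAC) family: a pore whose fixed positive wall charges attract anions at
low salt, and whose selectivity fades at high salt as the electrolyte
screens those charges.

The package is for computational biophysicists who want the full
permeation-analysis pipeline — from trajectories to selectivity numbers —
without carrying an MD engine: a Brownian-dynamics (BD) ion/channel
simulator generates the trajectories, and every analysis stage consumes
either those or standard files (PDB structures, FASTA/Clustal alignments,
a documented columnar trajectory format).

## What it computes

* **Permeation statistics** — time-averaged pore occupancies N_anion,
  N_cation inside the slab −15 < z < 15 Å, translocation events (complete
  directed crossings), passage times, and the two selectivity measures:
  the *permeation ratio* (anion/cation crossing events) and the
  *occupancy ratio* N_anion/N_cation.
* **Free-energy profiles** — the density-inversion estimator
  ΔG_i(z) = −RT ln(C_i(z)/C_bulk) in 1D and on 3D grids, constant-z
  reduction, and identification of residues whose side-chain N/O atoms
  flank the low-energy regions.
* **Continuum electrostatics** — a finite-difference linearized
  Poisson–Boltzmann solver (harmonic-mean edge dielectrics, SOR,
  focusing) with the three-dielectric membrane model (water/headgroups
  80, protein 4, 25 Å hydrophobic core 2), ion-transfer free-energy
  grids, and time-averaged smeared-charge electric-field maps.
* **Solution structure** — RDFs and coordination numbers, contact /
  solvent-separated ion-pair classification (CIP ≤ 3.95 Å,
  SSIP ≤ 6.37 Å), pairing and solvation profiles along the pore axis,
  dipole-orientation profiles.
* **Reversal potentials** — GHK and Planck (constrained liquid-junction)
  models, permeability-ratio inversion, ionic-strength scans at fixed
  concentration ratio.
* **Conservation** — MSA column scoring into physicochemical exchange
  classes with a strict >90% conservation rule, and the pH-7 net-charge
  model of a sequence.

The BD generator is first-class, tested code: overdamped Langevin ions
with Yukawa (Debye-screened) interactions q₁q₂·l_B·e^(−r/λ)/r, a
soft-core contact, a reflecting membrane slab pierced by a cylindrical
pore, and fixed charge rings lining the wall. Because λ shrinks with
concentration (9.6 Å at 0.1 M, 3.0 Å at 1 M), the simulator reproduces
the screening mechanism the analyses are designed to detect.

## Worked example

```python
import ionpore as ip

# a channel with +6 e of fixed positive charge lining the pore wall
system = ip.ChannelSystem(fixed_charges=ip.default_pore_charges(6.0))
pore = ip.PoreGeometry(-15.0, 15.0)

for c in (0.1, 1.0):
    n = int(round(ip.synthetic.expected_counts(system, c)))
    params = ip.BDParams(dt=0.5, n_steps=40000, n_equil=5000,
                         stride=20, seed=1, c_bulk=c)
    traj = ip.run_bd(system, params, {"cation": n, "anion": n})
    oa = ip.count_occupancy(traj, pore, "anion")
    oc = ip.count_occupancy(traj, pore, "cation")
    events = ip.detect_translocations(traj, pore)
    na = sum(e.species == "anion" for e in events)
    nc = sum(e.species == "cation" for e in events)
    print(f"[{c} M] N_an={oa.mean:.2f} N_cat={oc.mean:.2f} "
          f"occupancy ratio={ip.occupancy_ratio(oa, oc).value:.2f} "
          f"events an/cat={na}/{nc}")
```

Output:

```
[0.1 M] N_an=1.34 N_cat=0.28 occupancy ratio=4.87 events an/cat=7/2
[1.0 M] N_an=6.97 N_cat=4.82 occupancy ratio=1.45 events an/cat=71/31
```

At 0.1 M the pore holds ~5× more anions than cations — the unscreened
wall charges dominate — while at 1.0 M the ratio collapses toward ~1.5:
more ions screen the fixed charges and the channel becomes only mildly
anion-selective. The event counts tell the same story (anions cross far
more often at low salt; cation crossings become routine at high salt),
which is exactly the concentration dependence the analysis pipeline is
built to quantify.

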