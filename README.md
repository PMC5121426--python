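# poreform

Analysis toolkit for membrane simulations of pore-forming antimicrobial
peptides (AMPs), built around maculatin 1.1 (GLFGVLAKVAAHVVPAIAEHF-NH₂),
a 21-residue amphiphilic helix from frog skin. AMPs like maculatin do not
form a single well-defined channel: they assemble an ensemble of transient
low-order transmembrane (TM) oligomers that continually form and dissolve.
Quantifying that ensemble from multi-microsecond trajectories requires a
census of who is bound to whom in every frame, a structural similarity
measure that ignores which physical peptide occupies which position, and
kinetic extrapolation of pore lifetimes measured at elevated temperature.
`poreform` provides all of these, plus the matching bench-top calculators,
for anyone analysing homo-oligomerisation of identical peptides in a
bilayer.

## What it computes

- **Oligomer census** (`oligomers`): an oligomer of order *n* is any set of
  *n* peptides in mutual contact, with contact defined as a heavy-atom
  minimum-image distance < 3.5 Å and "mutual" read transitively (connected
  components of the contact graph — ring pores have non-touching opposite
  members). Populations are mass-weighted: occupancy of order *n* is
  *n*·(count)/*N*, so each frame's occupancies sum to 1.
- **Permutational clustering** (`permclust`): the similarity between two
  order-*n* oligomers is min over all *n*! peptide correspondences of the
  least-squares (Kabsch) backbone RMSD, enumerated with Heap's algorithm;
  observations are leader-clustered at a 4 Å cutoff and labelled with ring
  orientation schemes (N = N terminus up, C = C terminus up).
- **Insertion states** (`memstate`): helix tilt and centre-of-mass depth
  classify each peptide as surface-bound (S) or TM with a hysteresis dead
  band; the split gives ΔG(S→TM) = −RT ln(p_TM/p_S). Density maps and
  10-block standard errors included.
- **Conduction** (`conduction`): ion/water slab crossings counted by a
  hysteresis state machine (events only when a particle commits to the
  opposite side), per-species rates and selectivity ratios.
- **Pore kinetics** (`kinetics`): pore dissolution times from sustained
  RMSD rises, Arrhenius fit ln τ = ln A + Ea/RT over a temperature ladder,
  extrapolation with delta-method confidence intervals.
- **Bench-top calculators** (`biophys`): average peptide masses from
  sequence, mole-fraction partition coefficient K_X and ΔG = −RT ln K_X
  from CD titrations, leakage normalisation, dye radius → minimum pore
  oligomer order.
- **Synthetic data** (`synthgen`): seeded generators for all of the above
  with recorded ground truth, so every analysis is testable at desk scale
  without running molecular dynamics.

## Worked example

Generate a synthetic 16-peptide trajectory containing a persistent
tetramer and a late-forming dimer, then census it:

```bash
$ cat spec.yaml
n_peptides: 16
n_frames: 100
schedule:
  - {frame_start: 0, frame_stop: 100, members: [2, 5, 9, 12], scheme: NCNC}
  - {frame_start: 50, frame_stop: 100, members: [0, 1], scheme: NC}

$ poreform synth --what assembly --spec spec.yaml --out-prefix demo --seed 1
$ poreform oligomers --top demo.gro --traj demo.xtc --out-prefix demo
$ cat demo_population.json
{
 "mean_occupancy": {"1": 0.6875, "2": 0.0625, "4": 0.25},
 "sem_occupancy":  {"1": 0.0208, "2": 0.0208, "4": 0.0}
}
```

The tetramer holds 4/16 = 25 % of the peptide mass in every frame; the
dimer exists half the time, so its mass-weighted occupancy is
0.5 · 2/16 = 6.25 %; the remainder are monomers. The per-frame table
(`demo_oligomers.tsv`) lists each oligomer with its members and ring
orientation scheme (`NCNC` = alternating antiparallel).

Fit pore lifetimes from a synthetic unfolding-time table and extrapolate
to body temperature:

```bash
$ poreform synth --what lifetimes --spec lt.yaml --out-prefix lt --seed 2
$ poreform lifetime --lifetimes lt_lifetimes.tsv --extrapolate 310 --out-prefix lt
Ea = 19.95 kcal/mol, ln A = -8.65
```

With a true activation energy of 20 kcal/mol and lognormal replicate noise
(σ = 0.3), the fit recovers Ea = 19.95 kcal/mol and extrapolates a mean
pore lifetime at 310 K of 20.5 ms (95 % CI 8.2–51.3 ms) — the
tens-of-milliseconds regime typical of transient AMP pores.

Bench-top helpers:

```bash
$ poreform mass --seq GLFGVLAKVAAHVVPAIAEHF --cterm amide
GLFGVLAKVAAHVVPAIAEHF (amide): 2145.58 g/mol
$ poreform poresize --mw 427.33
dye radius 4.98 Å -> minimum ring of 7 helices (order-of-magnitude estimate)
```

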