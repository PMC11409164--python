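# shiftcryst

Chemical-shift-driven ensemble selection and structural analysis for
amorphous molecular solids.

Given (a) periodic snapshots of a molecular system, (b) predicted per-atom
chemical shifts (or shieldings) for each local molecular environment, and
(c) experimental shift distributions fitted to 1D spectra, `shiftcryst`
scores every environment's agreement with the experiment, selects the
best-matching subset (the *NMR set*), and characterizes it against the
background pool (the *MD set*) through hydrogen-bond statistics, torsion
histograms, element-resolved 3D atomic density maps, and formation-energy
comparisons.

## What is in the box

| Module | Purpose |
| --- | --- |
| `shiftcryst.molecule` | molecule bond graph, atom labels, bond-shell ("W-n") subsets |
| `shiftcryst.ensemble` | extended-XYZ frames, frame-time sampling, periodic environment extraction |
| `shiftcryst.spectra` | Gaussian-mixture fits of 1D spectra, HETCOR-based proton assignment |
| `shiftcryst.scoring` | shielding→shift conversion, per-shift tail probabilities, geometric-mean match probability, NMR-set selection, per-run random baselines |
| `shiftcryst.analysis` | H-bond detection and acceptor classification, signed torsions, promotion/demotion tables, periodic angle histograms |
| `shiftcryst.density` | Kabsch / bond-axis alignment, amplitude-1 Gaussian density maps, Gaussian-cube export |
| `shiftcryst.energetics` | formation energies with a pluggable backend (toy pair potential shipped; external-command contract for real codes) |
| `shiftcryst.synthetic` | planted-truth synthetic ensembles (H-bond partners, torsion modes, forward shift model) for validating the whole pipeline |

## Command-line usage

A complete synthetic round trip:

```bash
shiftcryst synth --n-runs 2 --n-frames 5 --n-molecules 50 --seed 1 --out ws
shiftcryst extract ws/run00.extxyz --cutoff 7.0 --run-id run00 --out ws/envs.xyz
shiftcryst score --shifts ws/shifts.csv --dists ws/dists.csv \
    --molecule ws/molecule.json --shell-center N1 --shell-n 3 --out ws/scores.csv
shiftcryst select ws/scores.csv --mode top_fraction --fraction 0.01 --out ws/sel.csv
shiftcryst hbond ws/envs.xyz --molecule ws/molecule.json --donor-h H1 --out ws/hbonds.csv
shiftcryst dihedral ws/envs.xyz --molecule ws/molecule.json --quad C3,C4,C7,C8 --out ws/dih.csv
shiftcryst density ws/envs.xyz --molecule ws/molecule.json \
    --ref-atoms N1,H1 --orient C1 --elements O --out-prefix ws/map
shiftcryst energy ws/envs.xyz --molecule ws/molecule.json --out ws/energies.csv
```

(`ws/dists.csv` is produced either by `shiftcryst fit-spectrum` on a
two-column trace, or programmatically — see
`shiftcryst.synthetic.subpopulation_distributions` for the synthetic path.)

Other commands: `shiftcryst sample-frames`, `shiftcryst fit-spectrum`.
Every command has `--help`.

## File formats

All formats are plain text: extended XYZ with a `Lattice="..."` header and a
per-atom molecule-id column for frames; concatenated XYZ clusters with
`env_id=` comments for environments; CSV for shifts, distributions, scores,
selections and records; Gaussian cube files for density channels; JSON for
molecule topologies.
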