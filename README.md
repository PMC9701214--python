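# confdyn

Conformational-ensemble analysis for enzyme-engineering studies, built around
the question of *why* an engineered cofactor-dependent enzyme gains or loses
activity: not through direct contacts, but through shifts in its
conformational dynamics. The motivating system is a water-forming NADH
oxidase (Nox) engineered to accept truncated noncanonical nicotinamide
cofactors (NMNH, MNAH): the wild type with the small cofactor is floppy and
rarely catalytically competent, while the engineered variant regains the
wild-type-with-native-cofactor behavior.

`confdyn` quantifies this with three ensemble metrics over multi-model PDB
trajectories, plus the directed-evolution library arithmetic used to build
such variants:

1. **Loop flexibility** — each frame is superposed on a reference structure
   by Kabsch alignment over all alpha carbons, then the RMSD is computed
   (without re-fitting) over the Rossmann-fold loops that envelop the AMP
   pocket (default residues 153–157, 177–188, 238–242). Reported as
   mean ± sd with a histogram.
2. **Hydride-transfer occupancy** — the per-frame distance between the
   nicotinamide C4 (hydride donor) and the flavin N5 (acceptor). Frames with
   d ≤ 4.5 Å are catalytically *active* poses; the occupancy (fraction of
   active frames) tracks catalytic competence.
3. **Free-energy landscape** — backbone φ/ψ torsions of all conditions are
   pooled, standard-scaled and reduced by PCA to a shared 2-D latent space;
   sample density is Boltzmann-inverted (F = −ln p, minimum shifted to 0, kT
   units) and frames are assigned to conformational states A/B/C by K-Means,
   yielding per-condition state occupancies.
4. **Library coverage** — degenerate-codon (NNK/NNS/NNN) site-saturation
   diversity, fold coverage and Poisson completeness
   (e.g. 3 NNK sites → 20³ = 8000 proteins; 2.4×10⁶ transformants → 300-fold).

Because production MD trajectories are rarely shareable, the package ships a
**synthetic ensemble generator** with planted ground truth (basin-hopping
backbone dihedrals via a Markov chain, region-specific Cartesian jitter, a
two-state bound/unbound ligand-distance process), so every stage is verified
by parameter recovery at desk scale.

## Worked example

Generate a synthetic trajectory whose ligand is bound 60% of the time with a
bound-state distance of 3.1 Å, and measure the active-pose occupancy and the
flexibility of a jittered loop:

```sh
confdyn simulate --out traj.pdb --truth truth.json --ref ref.pdb \
    --n-residues 60 --n-frames 2000 --seed 1 \
    --bound-fraction 0.60 --jitter 20-30:0.433
confdyn hydride --traj traj.pdb
confdyn flex --traj traj.pdb --ref ref.pdb --regions 20-30
```

prints

```json
{
  "threshold": 4.5,
  "occupancy": 0.6195,
  "n_frames": 2000
}
{
  "mean": 0.7298713478896021,
  "std": 0.09051129701862516,
  "n_frames": 2000
}
```

The occupancy recovers the planted bound fraction (0.6195 vs 0.60 is under
two binomial standard errors at 2000 frames), and the mean loop RMSD
recovers σ√3 = 0.433 × 1.732 ≈ 0.75 Å — the expected root-mean-square
displacement of an atom jittered by σ per coordinate — to within a few
percent (the global alpha-carbon fit absorbs a little of the jitter on a
short 60-residue chain). A full three-condition
run (flexibility + occupancy + pooled landscape) is driven by a YAML config:

```sh
confdyn analyze --config run.yml
```

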