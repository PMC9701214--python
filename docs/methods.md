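# Methods

## Scope and data model

`confdyn` analyzes conformational ensembles of a single protein chain stored
as multi-model PDB files (one `MODEL`/`ENDMDL` block per frame). The in-memory
unit is the `Ensemble`: an ordered atom topology shared by all frames plus an
F×A×3 coordinate tensor in Å. Only this text dialect is supported — the
ensembles the package targets are desk-scale (10²–10⁴ frames), where a
fixed-column text format keeps everything inspectable and dependency-free.
Insertion codes are rejected and only the first alternate location is kept:
refined models and synthetic inputs never carry them, and silently
mishandling either would corrupt residue-number-based selections. Residue
numbering is 1-based, taken verbatim from the PDB columns, and all residue
intervals are inclusive on both ends. Analyses operate on one caller-named
chain; multi-chain files require explicit chain filters.

## Loop flexibility

Protocol: *global fit, local no-refit*. Each frame is rigidly superposed on
the reference structure using all alpha carbons of the analysis chain
(Kabsch superposition: SVD of the cross-covariance with the reflection
corrected to a proper rotation, implemented via
`scipy.spatial.transform.Rotation.align_vectors`), the transform is applied
to the whole frame, and the RMSD is then computed over the region selection
without re-fitting. Local loop displacement on an otherwise rigid scaffold
therefore appears directly as region RMSD. The default regions are the three
Rossmann-fold loops lining the AMP pocket of the motivating oxidase
(residues 153–157, 177–188, 238–242); any interval list can be supplied.

Summary statistics: mean and *sample* standard deviation (n−1) over frames —
the frames are a finite sample of the ensemble. The histogram default is 30
equal-width bins on [0, max]. The reference is the energy-minimized starting
model supplied as a 1-frame ensemble; when none is given, frame 0 is used
and a notice is logged (frame 0 of a noisy trajectory inflates the RMSD by
roughly √2 and should not be used for quantitative recovery).

When replicate trajectories exist, they are concatenated before summarizing
(per-replicate summaries can be obtained by running each file separately);
pooling by concatenation weights every frame equally.

`sample_frames` draws a uniform sample without replacement (deterministic
given its seed, temporal order preserved) and optionally aligns the sample
to the reference — the usual way a few dozen frames are overlaid to
visualize conformational spread.

## Hydride-transfer occupancy

The donor–acceptor distance (nicotinamide C4 to flavin N5 in the motivating
system) is the per-frame Euclidean distance between two single-atom
selections; no periodic-image handling is applied because inputs are
whole-molecule ensembles. Frames are classified active when
d ≤ threshold (default 4.5 Å), *inclusive* at the boundary so the documented
default behaves deterministically for distances exactly on it. Distances are
never capped: a cofactor 10 Å out of the pocket is no more inactive than one
at 5 Å, so only the binary classification feeds aggregates, and the raw
series is retained for inspection.

## Dihedral-PCA free-energy landscape

Backbone φ/ψ torsions are computed per frame with the IUPAC sign convention
(right-handed, cis = 0°), φ(i) = C(i−1)–N(i)–CA(i)–C(i) and
ψ(i) = N(i)–CA(i)–C(i)–N(i+1); a chain of R residues yields 2R−2 columns.
Chains must be consecutively numbered with complete N/CA/C backbones —
breaks and missing atoms are hard errors, not silences.

All conditions of one run are **pooled** before scaling and PCA; each
condition is then projected with the shared scaling and basis. This is the
only supported mode: separately fitted projections are not comparable, which
defeats the purpose of cross-condition occupancy comparison. Conventions
fixed for reproducibility:

* standard scaling divides by the **population** standard deviation (the
  choice only rescales the latent space globally);
* PCA is computed by SVD of the scaled pooled matrix; eigenvalues use the
  n−1 normalization; component signs are fixed by forcing the
  largest-magnitude loading of each component positive;
* a zero-variance column is an error (a structureless coordinate cannot be
  standard-scaled — synthetic inputs must carry dihedral noise).

Raw angles in (−180°, 180°] feed PCA directly by default. Raw-angle PCA
distorts near the ±180° seam; a classical dPCA mode replacing each angle by
its (sin, cos) pair is available (`dihedral_mode="sincos"`). The default
stays raw because the target workflow scales and transforms plain angles;
the synthetic generator places its basins well away from the seam so
recovery results are mode-independent. A plausible alternative reading of
"alpha-carbon dihedrals" — pseudo-torsions over consecutive CA atoms — is
noted but not implemented; φ/ψ is the standard choice.

The free-energy surface is the Boltzmann inversion of the 2-D histogram of
the pooled projection: F_bin = −ln(count/F), shifted so the occupied minimum
is exactly 0. Units are kT (no temperature factor — only relative well
depths matter here); empty bins are masked rather than assigned a finite
value. Default grid 60×60 over the pooled bounding box so all conditions
share one grid.

Conformational states are assigned by K-Means on the pooled projections
(k = 3 by default, k-means++ initialization, 10 restarts, fixed seed 0),
then relabeled A, B, C … by ascending PC1 coordinate of the cluster centers —
an arbitrary but deterministic naming rule. Per-condition occupancy is the
fraction of that condition's frames under each letter. Temporal shading of
scatter plots is a plotting option only; no analysis depends on frame order.

## Synthetic ensemble generator

The generator stands in for production MD output and plants every quantity
the analyses measure:

* **Backbone.** An idealized N/CA/C backbone (bond lengths N–CA 1.458,
  CA–C 1.525, C–N 1.329 Å; angles 111°/117°/121°; ω fixed at 180°) is built
  from torsions by sequential natural-extension (NeRF) placement. The
  builder and the torsion measurement are exact mutual inverses (verified to
  1e-6° at zero noise), which anchors both implementations. The default
  conformation is extended (φ, ψ = −135°, 135°), chosen off the ±180° seam.
* **Conformational states.** A Markov chain hops among dihedral basins
  (each a (φ, ψ) mean, optionally per-residue) with a stated row-stochastic
  transition matrix; the initial state is drawn from the stationary
  distribution when it is unique, else state 0 is used and the ground truth
  flags the chain as reducible. Per-frame torsions are basin means plus iid
  Gaussian noise.
* **Loop flexibility.** iid Gaussian Cartesian jitter of per-coordinate σ is
  added to every backbone atom of each jitter region. The planted mean
  region RMSD is σ√3 (E‖Δ‖² = 3σ² per atom).
* **Ligand.** Bound/unbound is iid Bernoulli(bound_fraction); the
  donor–acceptor distance is drawn from a positive-truncated normal per
  state (defaults: bound 3.1 ± 0.2 Å — the crystallographic contact
  distance — unbound 8.0 ± 0.8 Å) and imposed exactly by placing the donor
  on a fixed axis from a fixed acceptor. iid binding keeps the occupancy
  recovery bands exact binomial SEs; no excluded-volume checks are made
  (toy geometry).

All randomness flows from one root seed through named substreams (chain,
dihedrals, jitter, ligand), so enabling one feature never perturbs
another's draws, and identical spec + seed is bit-identical.

**Test matrix.** Cartesian jitter corrupts the local dihedrals of jittered
residues, and basin hopping moves loops through lever-arm effects, so each
recovery study plants only the feature it measures: occupancy studies are
geometry-free, flexibility studies are single-basin and dihedral-noise-free,
landscape studies are jitter-free. A pipeline run over a fully noised
condition still produces all three metrics, but only the planted feature of
each study has a closed-form expectation.

**What the generator does not emulate:** side chains, solvent, force-field
energetics, correlated loop–ligand coupling, kinetic realism of transitions.
Passing recovery tests therefore demonstrates that the *measurement* stages
are correct and unbiased at realistic signal sizes — not that the
biophysical conclusions of any particular MD study are right.

## Reference study conditions

The shipped scenario (`confdyn.scenarios`) emulates a three-condition
enzyme-dynamics comparison — wild type with native cofactor (`WT+NADH`),
wild type with a truncated biomimetic (`WT+MNAH`), engineered variant with
the biomimetic (`Mut+MNAH`):

* bound fractions 0.74 / 0.01 / 0.60, recovered within 3 binomial SEs at
  5000 frames;
* planted loop RMSD means 0.74 / 0.94 / 0.75 Å over the default loop
  regions on a 250-residue chain (σ = target/√3), recovered within 5% at
  2000 frames — including the ≈1.27× flexible-vs-rigid ratio;
* three dihedral basins at (−110°, 110°), (0°, 0°), (110°, −110°) with 10°
  noise; `WT+MNAH` shuttles between the outer basins (central-state
  occupancy ≈ 1–2%) while the other conditions dwell centrally (> 95%),
  reproducing the disjoint-versus-focused landscape pattern. A two-basin
  variant recovers realized state frequencies within 2% absolute.

Problem sizes (5000 / 2000 / 2000 frames; 250-residue flexibility chains,
12-residue landscape chains) were chosen so each recovery band is several
times wider than its Monte-Carlo error while the whole reference study runs
in seconds.

## Library arithmetic

Degenerate codons are enumerated against the standard genetic code
(NNK: 32 codons, all 20 amino acids, one stop TAG). For n sites: 32ⁿ codon
and 20ⁿ protein combinations, stop-carrying fraction 1 − (31/32)ⁿ. Coverage
assumes uniform variant abundance (real libraries skew — these are
optimistic back-of-envelope numbers): with N transformants over V variants,
expected observed fraction 1 − e^(−N/V) and completeness probability
(1 − e^(−N/V))^V under Poissonization. Fold coverage uses protein-level
diversity by default, with a codon-level option. The Poisson approximation
is validated in tests against exact inclusion–exclusion and direct
multinomial simulation at V = 20, where all three agree to < 1e-3.

## Numerical choices and degenerate inputs

* Kabsch requires ≥ 3 non-collinear points; a rank-deficient cross-covariance
  raises a degenerate-geometry error rather than returning an arbitrary
  rotation.
* PDB coordinates are written to 3 decimals; values that overflow the
  8-column field are errors. Round-tripping is exact on topology and to
  3 decimals on coordinates.
* Occupancy requires positive, finite distances; an empty series is an
  error.
* Free-energy surfaces require a non-degenerate bounding box (distinct
  points on both axes).
* K-Means requires at least k distinct projected points.
* The pipeline records any stage failure (condition + stage + message) in
  the report and continues with the remaining stages; a fully noise-free
  condition intentionally fails the landscape stage with a scaling error
  while flexibility and occupancy still report.

## Known limitations

* Raw-angle dPCA is seam-sensitive; use `sincos` mode for ensembles
  sampling near ±180°.
* Loop RMSD recovery carries a small negative bias (≈1–3%) because the
  global alpha-carbon fit absorbs part of the planted jitter; the bias
  shrinks as the jittered fraction of fit atoms falls.
* Concatenating replicates assumes equal frame weighting.
* No solvent, side-chain or kinetic realism in the generator (see above).
* Coverage statistics assume uniform variant abundance.
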