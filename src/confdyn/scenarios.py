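"""Reference study conditions for the three parameter-recovery analyses.

The generator emulates a three-condition comparison of a flavin-dependent
oxidase: the wild-type enzyme with its native dinucleotide cofactor
(``WT+NADH``), the wild type with a truncated nicotinamide biomimetic
(``WT+MNAH``), and an engineered variant with the biomimetic (``Mut+MNAH``).
The planted values are the headline statistics of that comparison:

* active-pose occupancies 0.74 / 0.01 / 0.60 for WT+NADH / WT+MNAH /
  Mut+MNAH, with a bound-state distance of 3.1 A (the crystallographic
  donor-acceptor contact) against a 4.5 A activity threshold;
* loop RMSD means 0.74 / 0.94 / 0.75 A over the cofactor-pocket loops,
  planted as per-coordinate jitter sigma = target / sqrt(3);
* a three-basin conformational landscape in which WT+MNAH shuttles between
  the two outer basins and rarely visits the central one, while the other
  two conditions concentrate in the central basin.

Because Cartesian jitter corrupts local dihedrals and dihedral motion moves
loops, each recovery study uses a spec that plants only the feature it
measures: occupancy specs are geometry-free, flexibility specs are
single-basin and noise-free, landscape specs are jitter-free.
"""

from __future__ import annotations

import numpy as np

from .flexibility import DEFAULT_LOOP_INTERVALS
from .synthetic import JitterRegion, LigandProcess, SyntheticSpec

CONDITIONS = ("WT+NADH", "WT+MNAH", "Mut+MNAH")

BOUND_FRACTIONS = {"WT+NADH": 0.74, "WT+MNAH": 0.01, "Mut+MNAH": 0.60}
LOOP_RMSD_TARGETS = {"WT+NADH": 0.74, "WT+MNAH": 0.94, "Mut+MNAH": 0.75}

# three dihedral basins on a line in (phi, psi), well off the +/-180 seam,
# adjacent separation 110 degrees per coordinate
LANDSCAPE_BASINS = ((-110.0, 110.0), (0.0, 0.0), (110.0, -110.0))

# outer-basin shuttler: rarely enters the central basin
_T_OUTER = (
    (0.97, 0.01, 0.02),
    (0.35, 0.30, 0.35),
    (0.02, 0.01, 0.97),
)
# central-basin dweller
_T_CENTRAL = (
    (0.30, 0.70, 0.00),
    (0.005, 0.99, 0.005),
    (0.00, 0.70, 0.30),
)
LANDSCAPE_TRANSITIONS = {
    "WT+NADH": _T_CENTRAL,
    "WT+MNAH": _T_OUTER,
    "Mut+MNAH": _T_CENTRAL,
}
LANDSCAPE_NOISE_DEG = 10.0


def occupancy_specs(
    seed: int = 0, n_frames: int = 5000, n_residues: int = 10
) -> dict[str, SyntheticSpec]:
    """Three conditions planting the reference active-pose occupancies."""
    return {
        name: SyntheticSpec(
            n_residues=n_residues,
            n_frames=n_frames,
            seed=seed + i,
            ligand=LigandProcess(bound_fraction=BOUND_FRACTIONS[name]),
        )
        for i, name in enumerate(CONDITIONS)
    }


def flexibility_specs(
    seed: int = 0, n_frames: int = 2000, n_residues: int = 250
) -> dict[str, SyntheticSpec]:
    """Three single-basin conditions planting the loop RMSD means.

    Jitter sigma = target / sqrt(3) per region, since iid per-coordinate
    Gaussian jitter of sigma gives E||displacement||^2 = 3 sigma^2 per atom.
    """
    out = {}
    for i, name in enumerate(CONDITIONS):
        sigma = LOOP_RMSD_TARGETS[name] / np.sqrt(3.0)
        out[name] = SyntheticSpec(
            n_residues=n_residues,
            n_frames=n_frames,
            seed=seed + 10 + i,
            jitter_regions=tuple(
                JitterRegion(lo, hi, sigma) for lo, hi in DEFAULT_LOOP_INTERVALS
            ),
            ligand=LigandProcess(bound_fraction=BOUND_FRACTIONS[name]),
        )
    return out


def landscape_specs(
    seed: int = 0, n_frames: int = 3000, n_residues: int = 12
) -> dict[str, SyntheticSpec]:
    """Three jitter-free conditions planting the basin-occupancy pattern."""
    return {
        name: SyntheticSpec(
            n_residues=n_residues,
            n_frames=n_frames,
            seed=seed + 20 + i,
            basins=LANDSCAPE_BASINS,
            transition_matrix=LANDSCAPE_TRANSITIONS[name],
            dihedral_noise_deg=LANDSCAPE_NOISE_DEG,
            ligand=LigandProcess(bound_fraction=BOUND_FRACTIONS[name]),
        )
        for i, name in enumerate(CONDITIONS)
    }
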