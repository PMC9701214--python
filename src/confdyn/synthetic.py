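"""Synthetic conformational-ensemble generator with known ground truth.

Stands in for undeposited MD trajectories: every statistical feature the
analysis stages measure is planted with a known value, so each stage can be
verified by parameter recovery.

The generative model per frame:

1. a Markov chain hops among dihedral *basins* (each basin is a (phi, psi)
   mean, optionally per residue) with a stated row-stochastic transition
   matrix;
2. backbone torsions are the basin means plus iid Gaussian noise
   (``dihedral_noise_deg``), and an idealized backbone (N, CA, C per
   residue; fixed bond lengths and angles, omega = 180) is rebuilt from
   internal coordinates;
3. iid Gaussian Cartesian jitter of a stated per-coordinate sigma is added
   to atoms inside each *jitter region* (flexible-loop surrogate);
4. a two-state ligand process draws bound/unbound per frame
   (iid Bernoulli(bound_fraction)) and places a donor pseudo-atom on a fixed
   axis from a fixed acceptor pseudo-atom at the sampled distance, so the
   donor-acceptor distance is exact by construction.

All randomness flows from one root seed through named substreams (chain,
dihedrals, jitter, ligand) so enabling one feature never perturbs another's
draws.  Identical spec + seed gives bit-identical coordinates.

Note: Cartesian jitter corrupts the local dihedrals of jittered residues, so
landscape-recovery studies use jitter-free specs while flexibility-recovery
studies use single-basin, dihedral-noise-free specs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ProvenanceError, SpecError, ValidationError
from .structure_io import AtomRecord, Ensemble, HETERO, POLYMER

# Idealized backbone internal coordinates (Angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 117.0
ANGLE_C_N_CA = 121.0
OMEGA = 180.0
# default extended (beta-strand-like) conformation, kept off the +/-180 seam
EXTENDED_PHI = -135.0
EXTENDED_PSI = 135.0

DONOR_NAME, DONOR_RESNAME = "C4", "MNA"
ACCEPTOR_NAME, ACCEPTOR_RESNAME = "N5", "FAD"

_STREAMS = {"chain": 0, "dihedrals": 1, "jitter": 2, "ligand": 3}


@dataclass(frozen=True)
class JitterRegion:
    """Inclusive residue interval receiving Cartesian jitter of ``sigma`` A."""

    start: int
    end: int
    sigma: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise SpecError("jitter region start > end")
        if self.sigma < 0:
            raise SpecError("jitter sigma must be >= 0")


@dataclass(frozen=True)
class LigandProcess:
    """Two-state bound/unbound distance process for the donor-acceptor pair."""

    bound_fraction: float = 0.74
    bound_distance_mean: float = 3.1
    bound_distance_sd: float = 0.2
    unbound_distance_mean: float = 8.0
    unbound_distance_sd: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.bound_fraction <= 1.0:
            raise SpecError("bound_fraction must lie in [0, 1]")
        if self.bound_distance_mean >= self.unbound_distance_mean:
            raise SpecError("bound distance mean must be below unbound mean")
        if min(self.bound_distance_mean, self.unbound_distance_mean) <= 0:
            raise SpecError("distance means must be positive")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full generative parameterization; ground truth is derivable from it."""

    n_residues: int = 30
    n_frames: int = 100
    seed: int = 0
    basins: tuple[tuple[float, float], ...] = ((EXTENDED_PHI, EXTENDED_PSI),)
    transition_matrix: tuple[tuple[float, ...], ...] = ((1.0,),)
    dihedral_noise_deg: float = 0.0
    jitter_regions: tuple[JitterRegion, ...] = ()
    ligand: LigandProcess = field(default_factory=LigandProcess)
    chain_id: str = "A"

    def __post_init__(self) -> None:
        if self.n_residues < 5:
            raise SpecError("need n_residues >= 5")
        if self.n_frames < 1:
            raise SpecError("need n_frames >= 1")
        if self.dihedral_noise_deg < 0:
            raise SpecError("dihedral noise must be >= 0")
        t = np.asarray(self.transition_matrix, dtype=float)
        b = len(self.basins)
        if t.shape != (b, b):
            raise SpecError(
                f"transition matrix shape {t.shape} does not match {b} basin(s)"
            )
        if np.any(t < 0) or np.any(np.abs(t.sum(axis=1) - 1.0) > 1e-12):
            raise SpecError("transition matrix rows must be non-negative and sum to 1")
        for r in self.jitter_regions:
            if r.end > self.n_residues:
                raise SpecError(f"jitter region {r} exceeds chain length")

    @property
    def n_basins(self) -> int:
        return len(self.basins)


@dataclass
class GroundTruth:
    """Planted parameters of one realization, for parameter-recovery checks."""

    state_sequence: np.ndarray
    stationary_distribution: np.ndarray
    stationary_unique: bool
    bound_mask: np.ndarray
    realized_bound_fraction: float
    expected_region_rmsd: dict[tuple[int, int], float]

    def realized_state_frequencies(self, n_basins: int) -> np.ndarray:
        return np.bincount(self.state_sequence, minlength=n_basins) / len(
            self.state_sequence
        )


@dataclass
class Realization:
    """Raw random draws of one simulation, tied to the spec that made them."""

    spec: SyntheticSpec
    state_sequence: np.ndarray
    bound_mask: np.ndarray


def _rng(spec: SyntheticSpec, stream: str) -> np.random.Generator:
    return np.random.default_rng([spec.seed, _STREAMS[stream]])


def _place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: np.ndarray | float,
) -> np.ndarray:
    """NeRF placement of atom D from A-B-C, batched over leading axes."""
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc, axis=-1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)
    d_local = np.stack(
        [
            -bond * np.cos(theta) * np.ones_like(chi),
            bond * np.sin(theta) * np.cos(chi),
            bond * np.sin(theta) * np.sin(chi),
        ],
        axis=-1,
    )
    return (
        c
        + d_local[..., 0:1] * bc
        + d_local[..., 1:2] * m
        + d_local[..., 2:3] * n
    )


def build_backbone(phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Rebuild N/CA/C coordinates from torsions by sequential NeRF placement.

    ``phi`` and ``psi`` have shape (F, R); phi[:, 0] and psi[:, -1] are
    ignored (undefined at the termini).  Returns (F, 3R, 3).
    """
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    if phi.shape != psi.shape:
        raise ValidationError("phi and psi must have the same shape")
    f, r = phi.shape
    coords = np.zeros((f, 3 * r, 3))
    # first residue in the xy-plane
    coords[:, 0] = [0.0, 0.0, 0.0]
    coords[:, 1] = [BOND_N_CA, 0.0, 0.0]
    ang = np.radians(180.0 - ANGLE_N_CA_C)
    coords[:, 2] = coords[:, 1] + BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, r):
        n_prev, ca_prev, c_prev = 3 * (i - 1), 3 * (i - 1) + 1, 3 * (i - 1) + 2
        # N(i): torsion psi(i-1) about N(i-1)-CA(i-1)-C(i-1)
        coords[:, 3 * i] = _place_atom(
            coords[:, n_prev], coords[:, ca_prev], coords[:, c_prev],
            BOND_C_N, ANGLE_CA_C_N, psi[:, i - 1],
        )
        # CA(i): omega about CA(i-1)-C(i-1)-N(i)
        coords[:, 3 * i + 1] = _place_atom(
            coords[:, ca_prev], coords[:, c_prev], coords[:, 3 * i],
            BOND_N_CA, ANGLE_C_N_CA, OMEGA,
        )
        # C(i): phi(i) about C(i-1)-N(i)-CA(i)
        coords[:, 3 * i + 2] = _place_atom(
            coords[:, c_prev], coords[:, 3 * i], coords[:, 3 * i + 1],
            BOND_CA_C, ANGLE_N_CA_C, phi[:, i],
        )
    return coords


def _topology(n_residues: int, chain_id: str) -> tuple[list[AtomRecord], int, int]:
    """Backbone topology plus donor/acceptor pseudo-atoms; returns their indices."""
    records: list[AtomRecord] = []
    serial = 1
    for resnum in range(1, n_residues + 1):
        for name, element in (("N", "N"), ("CA", "C"), ("C", "C")):
            records.append(
                AtomRecord(serial, name, "GLY", chain_id, resnum, element, POLYMER)
            )
            serial += 1
    donor_idx = len(records)
    records.append(
        AtomRecord(serial, DONOR_NAME, DONOR_RESNAME, chain_id, n_residues + 1, "C", HETERO)
    )
    acceptor_idx = len(records)
    records.append(
        AtomRecord(
            serial + 1, ACCEPTOR_NAME, ACCEPTOR_RESNAME, chain_id, n_residues + 2, "N", HETERO
        )
    )
    return records, donor_idx, acceptor_idx


def _acceptor_position(backbone_ref: np.ndarray) -> np.ndarray:
    """Fixed acceptor site: offset along +x from the reference bounding box."""
    return np.array(
        [backbone_ref[:, 0].max() + 5.0, backbone_ref[:, 1].mean(), backbone_ref[:, 2].mean()]
    )


def build_reference(n_residues: int, chain_id: str = "A") -> Ensemble:
    """Idealized extended 1-frame reference with donor/acceptor pseudo-atoms."""
    if n_residues < 5:
        raise SpecError("need n_residues >= 5")
    phi = np.full((1, n_residues), EXTENDED_PHI)
    psi = np.full((1, n_residues), EXTENDED_PSI)
    backbone = build_backbone(phi, psi)[0]
    records, donor_idx, acceptor_idx = _topology(n_residues, chain_id)
    acceptor = _acceptor_position(backbone)
    donor = acceptor + np.array([3.1, 0.0, 0.0])
    coords = np.vstack([backbone, donor[None], acceptor[None]])[None]
    # keep donor before acceptor in index order as built by _topology
    coords[0, donor_idx] = donor
    coords[0, acceptor_idx] = acceptor
    return Ensemble(topology=records, coordinates=coords)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Positive-support normal draws (truncated at zero)."""
    if sd == 0:
        return np.full(size, mean)
    from scipy.stats import truncnorm

    a = (0.0 - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def _stationary(t: np.ndarray) -> tuple[np.ndarray, bool]:
    """Leading left eigenvector of the transition matrix, and uniqueness."""
    w, v = np.linalg.eig(t.T)
    close = np.flatnonzero(np.abs(w - 1.0) < 1e-9)
    unique = len(close) == 1
    vec = np.real(v[:, close[0]])
    vec = np.abs(vec)
    return vec / vec.sum(), unique


def simulate_ensemble(spec: SyntheticSpec) -> tuple[Ensemble, Realization]:
    """Draw one ensemble realization; deterministic given spec + seed."""
    f, r = spec.n_frames, spec.n_residues
    t = np.asarray(spec.transition_matrix, dtype=float)

    # 1. basin Markov chain
    rng_chain = _rng(spec, "chain")
    stationary, unique = _stationary(t)
    states = np.empty(f, dtype=int)
    if unique:
        states[0] = rng_chain.choice(spec.n_basins, p=stationary)
    else:
        states[0] = 0
    cumulative = np.cumsum(t, axis=1)
    draws = rng_chain.random(f - 1) if f > 1 else np.empty(0)
    for i in range(1, f):
        states[i] = np.searchsorted(cumulative[states[i - 1]], draws[i - 1], side="right")
    states = np.minimum(states, spec.n_basins - 1)

    # 2. torsions = basin means + noise, rebuild backbone
    basin_means = np.asarray(spec.basins, dtype=float)  # (B, 2) or (B, R, 2)
    if basin_means.ndim == 2:
        basin_means = np.broadcast_to(basin_means[:, None, :], (spec.n_basins, r, 2))
    elif basin_means.shape != (spec.n_basins, r, 2):
        raise SpecError("per-residue basins must have shape (B, R, 2)")
    means = basin_means[states]  # (F, R, 2)
    rng_dih = _rng(spec, "dihedrals")
    noise = (
        rng_dih.normal(0.0, spec.dihedral_noise_deg, size=(f, r, 2))
        if spec.dihedral_noise_deg > 0
        else np.zeros((f, r, 2))
    )
    angles = means + noise
    backbone = build_backbone(angles[:, :, 0], angles[:, :, 1])

    # 3. Cartesian jitter inside each region
    rng_jit = _rng(spec, "jitter")
    for region in spec.jitter_regions:
        atom_idx = np.concatenate(
            [np.arange(3 * (num - 1), 3 * num) for num in range(region.start, region.end + 1)]
        )
        if region.sigma > 0:
            backbone[:, atom_idx, :] += rng_jit.normal(
                0.0, region.sigma, size=(f, len(atom_idx), 3)
            )

    # 4. two-state ligand distance process
    rng_lig = _rng(spec, "ligand")
    lig = spec.ligand
    bound_mask = rng_lig.random(f) < lig.bound_fraction
    distances = np.empty(f)
    n_bound = int(bound_mask.sum())
    distances[bound_mask] = _truncated_normal(
        rng_lig, lig.bound_distance_mean, lig.bound_distance_sd, n_bound
    )
    distances[~bound_mask] = _truncated_normal(
        rng_lig, lig.unbound_distance_mean, lig.unbound_distance_sd, f - n_bound
    )

    records, donor_idx, acceptor_idx = _topology(r, spec.chain_id)
    reference_backbone = build_backbone(
        np.full((1, r), EXTENDED_PHI), np.full((1, r), EXTENDED_PSI)
    )[0]
    acceptor = _acceptor_position(reference_backbone)
    coords = np.zeros((f, len(records), 3))
    coords[:, : 3 * r] = backbone
    coords[:, acceptor_idx] = acceptor
    coords[:, donor_idx] = acceptor + np.outer(distances, [1.0, 0.0, 0.0])

    ensemble = Ensemble(topology=records, coordinates=coords)
    return ensemble, Realization(spec=spec, state_sequence=states, bound_mask=bound_mask)


def ground_truth(spec: SyntheticSpec, realization: Realization) -> GroundTruth:
    """Assemble the planted truth for a realization produced by ``spec``."""
    if realization.spec != spec:
        raise ProvenanceError("realization was not produced by this spec")
    t = np.asarray(spec.transition_matrix, dtype=float)
    stationary, unique = _stationary(t)
    if not unique:
        # absorbing / reducible chain: report the realized occupancy instead
        stationary = np.bincount(
            realization.state_sequence, minlength=spec.n_basins
        ) / len(realization.state_sequence)
    return GroundTruth(
        state_sequence=realization.state_sequence,
        stationary_distribution=stationary,
        stationary_unique=unique,
        bound_mask=realization.bound_mask,
        realized_bound_fraction=float(np.mean(realization.bound_mask)),
        expected_region_rmsd={
            (reg.start, reg.end): reg.sigma * np.sqrt(3.0)
            for reg in spec.jitter_regions
        },
    )
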