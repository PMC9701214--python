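"""Active-site loop flexibility via Kabsch superposition and region RMSD.

Protocol: each frame is rigidly superposed onto a reference structure using
a *fit* selection (all alpha carbons of the analysis chain by default), the
transform is applied to the whole frame, and the RMSD is then computed over
a *region* selection (the flexible loops lining the cofactor pocket)
WITHOUT re-fitting.  A flexible loop on a rigid scaffold therefore shows up
directly as region RMSD.

The default loop regions are residues 153-157, 177-188 and 238-242, the
Rossmann-fold loops that envelop the AMP moiety of the native dinucleotide
cofactor in the NADH-oxidase system this package was built around.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import (
    CorrespondenceError,
    DegenerateGeometryError,
    SamplingError,
    ValidationError,
)
from .structure_io import Ensemble, Selection, SelectionExpression, select_atoms

logger = logging.getLogger(__name__)

DEFAULT_LOOP_INTERVALS: tuple[tuple[int, int], ...] = ((153, 157), (177, 188), (238, 242))


@dataclass(frozen=True)
class Region:
    """A named inclusive residue interval on one chain."""

    name: str
    chain_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"region {self.name}: start > end")


@dataclass(frozen=True)
class RegionSet:
    """Named, non-overlapping residue intervals defining the flexible loops."""

    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        by_chain: dict[str, list[Region]] = {}
        for r in self.regions:
            by_chain.setdefault(r.chain_id, []).append(r)
        for chain, regs in by_chain.items():
            regs = sorted(regs, key=lambda r: r.start)
            for a, b in zip(regs, regs[1:]):
                if b.start <= a.end:
                    raise ValidationError(
                        f"regions {a.name} and {b.name} overlap on chain {chain}"
                    )

    def to_expression(self, atom_names: frozenset[str] = frozenset({"CA"})) -> SelectionExpression:
        """Selection expression covering all intervals (single-chain sets only)."""
        chains = {r.chain_id for r in self.regions}
        if len(chains) != 1:
            raise ValidationError("to_expression requires a single-chain RegionSet")
        return SelectionExpression(
            chain=next(iter(chains)),
            resnum_ranges=tuple((r.start, r.end) for r in self.regions),
            atom_names=atom_names,
            hetero=False,
        )


def default_loop_regions(chain_id: str = "A") -> RegionSet:
    """The three cofactor-pocket loop intervals shipped as the default."""
    return RegionSet(
        tuple(
            Region(f"loop{i + 1}", chain_id, lo, hi)
            for i, (lo, hi) in enumerate(DEFAULT_LOOP_INTERVALS)
        )
    )


def regions_from_string(text: str, chain_id: str = "A") -> RegionSet:
    """Build a RegionSet from ``"153-157,177-188,238-242"``."""
    from .structure_io import parse_residue_ranges

    ranges = parse_residue_ranges(text)
    return RegionSet(
        tuple(
            Region(f"region{i + 1}", chain_id, lo, hi)
            for i, (lo, hi) in enumerate(ranges)
        )
    )


@dataclass
class FlexibilityResult:
    """Per-frame loop RMSD with summary statistics and a histogram."""

    per_frame_rmsd: np.ndarray
    mean: float
    std: float
    histogram: tuple[np.ndarray, np.ndarray]  # (bin_edges, counts)

    @property
    def n_frames(self) -> int:
        return len(self.per_frame_rmsd)

    def summary(self) -> dict:
        return {"mean": self.mean, "std": self.std, "n_frames": self.n_frames}


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, fit_rmsd)`` with a proper rotation
    (determinant +1; reflections corrected).  Apply as
    ``mobile @ rotation.T + translation``.  ``fit_rmsd`` is the minimum RMSD
    over all rigid motions.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValidationError(
            f"point sets must both be N x 3, got {mobile.shape} vs {reference.shape}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need at least 3 points, got {n}")
    mob_centroid = mobile.mean(axis=0)
    ref_centroid = reference.mean(axis=0)
    mob_c = mobile - mob_centroid
    ref_c = reference - ref_centroid
    cross_cov = mob_c.T @ ref_c
    if np.linalg.matrix_rank(cross_cov, tol=1e-9 * max(1.0, float(np.abs(cross_cov).max()))) < 2:
        raise DegenerateGeometryError(
            "rank-deficient cross-covariance (collinear or coincident points)"
        )
    rot, rssd = Rotation.align_vectors(ref_c, mob_c)
    rotation = rot.as_matrix()
    translation = ref_centroid - rotation @ mob_centroid
    fit_rmsd = float(rssd / np.sqrt(n))
    return rotation, translation, fit_rmsd


def _corresponding_indices(
    ensemble: Ensemble, reference: Ensemble, selection: Selection
) -> tuple[np.ndarray, np.ndarray]:
    """Resolve ``selection`` on both topologies, enforcing atom-wise match."""
    try:
        ref_sel = select_atoms(reference, selection.expression)
    except Exception as exc:
        raise CorrespondenceError(
            f"selection does not resolve on the reference: {exc}"
        ) from exc
    if len(ref_sel) != len(selection):
        raise CorrespondenceError(
            f"selection resolves to {len(selection)} atoms on the ensemble but "
            f"{len(ref_sel)} on the reference"
        )
    for i, j in zip(selection.resolved_indices, ref_sel.resolved_indices):
        if ensemble.topology[i].key != reference.topology[j].key:
            raise CorrespondenceError(
                f"atom {ensemble.topology[i].key} pairs with "
                f"{reference.topology[j].key} on the reference"
            )
    return selection.indices, ref_sel.indices


def region_rmsd_series(
    ensemble: Ensemble,
    reference: Ensemble | None,
    fit_selection: Selection,
    region_selection: Selection,
    n_bins: int = 30,
) -> FlexibilityResult:
    """Loop RMSD per frame after whole-frame superposition on the fit atoms.

    ``reference`` is a 1-frame ensemble (the energy-minimized starting
    model); if ``None``, frame 0 of ``ensemble`` is used and a notice is
    logged.  The region RMSD is computed without re-fitting, so it measures
    genuine local displacement in the frame of the global fit.
    """
    if reference is None:
        logger.info("no reference supplied; using frame 0 of the ensemble")
        reference = ensemble.frame(0)
    if reference.n_frames != 1:
        raise ValidationError("reference must be a 1-frame ensemble")

    fit_idx, fit_ref_idx = _corresponding_indices(ensemble, reference, fit_selection)
    reg_idx, reg_ref_idx = _corresponding_indices(ensemble, reference, region_selection)

    ref_fit = reference.coordinates[0, fit_ref_idx]
    ref_reg = reference.coordinates[0, reg_ref_idx]

    rmsds = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        rotation, translation, _ = kabsch_superpose(
            ensemble.coordinates[f, fit_idx], ref_fit
        )
        moved_region = ensemble.coordinates[f, reg_idx] @ rotation.T + translation
        delta = moved_region - ref_reg
        rmsds[f] = np.sqrt(np.mean(np.sum(delta**2, axis=1)))

    mean = float(np.mean(rmsds))
    std = float(np.std(rmsds, ddof=1)) if len(rmsds) > 1 else 0.0
    top = float(rmsds.max()) if rmsds.max() > 0 else 1.0
    counts, edges = np.histogram(rmsds, bins=n_bins, range=(0.0, top))
    return FlexibilityResult(
        per_frame_rmsd=rmsds, mean=mean, std=std, histogram=(edges, counts)
    )


def align_ensemble(
    ensemble: Ensemble, reference: Ensemble, fit_selection: Selection
) -> Ensemble:
    """Return a copy with every frame superposed onto the reference."""
    fit_idx, fit_ref_idx = _corresponding_indices(ensemble, reference, fit_selection)
    ref_fit = reference.coordinates[0, fit_ref_idx]
    out = np.empty_like(ensemble.coordinates)
    for f in range(ensemble.n_frames):
        rotation, translation, _ = kabsch_superpose(
            ensemble.coordinates[f, fit_idx], ref_fit
        )
        out[f] = ensemble.coordinates[f] @ rotation.T + translation
    return Ensemble(topology=ensemble.topology, coordinates=out,
                    frame_labels=ensemble.frame_labels)


def sample_frames(
    ensemble: Ensemble,
    n: int,
    seed: int,
    reference: Ensemble | None = None,
    fit_selection: Selection | None = None,
) -> Ensemble:
    """Uniform sample of ``n`` frames without replacement, temporal order kept.

    Deterministic given ``seed``.  When ``reference`` and ``fit_selection``
    are supplied the sampled frames are aligned to the reference, matching
    the usual practice of overlaying a few dozen random frames to visualize
    the conformational spread.
    """
    if n > ensemble.n_frames:
        raise SamplingError(f"cannot sample {n} frames from {ensemble.n_frames}")
    if n < 1:
        raise SamplingError("need n >= 1")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(ensemble.n_frames, size=n, replace=False))
    sampled = Ensemble(
        topology=ensemble.topology,
        coordinates=ensemble.coordinates[idx].copy(),
        frame_labels=[str(i) for i in idx],
    )
    if reference is not None and fit_selection is not None:
        sampled = align_ensemble(sampled, reference, fit_selection)
    return sampled
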