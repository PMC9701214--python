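"""Dihedral-PCA free-energy landscape with K-Means state assignment.

The global conformational state of each frame is summarized by its backbone
phi/psi torsions.  All conditions are pooled, standard-scaled (zero mean,
unit population variance per column) and reduced by PCA; each condition is
then projected into the shared 2-D latent space so occupancies are directly
comparable.  Sample density over the latent plane is inverted into a free
energy, F_bin = -ln p_bin shifted so the occupied minimum is zero (kT
units), and frames are assigned to conformational states by K-Means on the
pooled projections, with states relabeled A, B, C ... by ascending PC1 of
their centers.

By default the raw angles in (-180, 180] feed PCA directly.  Raw-angle PCA
distorts near the +/-180 seam, so a classical dPCA mode replacing each angle
by its (sin, cos) pair is available via ``dihedral_mode="sincos"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .exceptions import (
    ChainBreakError,
    ClusteringError,
    DegenerateExtentError,
    MissingAtomError,
    ScalingError,
    SchemaError,
    ValidationError,
)
from .structure_io import Ensemble, POLYMER

STATE_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def torsion(
    p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
) -> np.ndarray:
    """Signed dihedral p0-p1-p2-p3 in degrees, IUPAC convention.

    Right-handed sign, cis = 0, returned in the principal range (-180, 180].
    Accepts batched inputs of shape ``(..., 3)``.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    m1 = np.cross(b1n, n1)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    angle = np.degrees(np.arctan2(y, x))
    # principal range (-180, 180]
    return np.where(angle <= -180.0, angle + 360.0, angle)


@dataclass
class DihedralMatrix:
    """F x D matrix of backbone torsions (degrees) for one condition.

    Columns are labeled ``(residue_number, "phi"|"psi")``; a chain of R
    residues yields D = 2R - 2 columns (phi is undefined at the first
    residue, psi at the last).
    """

    values: np.ndarray
    column_labels: tuple[tuple[int, str], ...]
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.column_labels):
            raise ValidationError("values shape does not match column labels")


def phi_psi_matrix(ensemble: Ensemble, chain: str, condition_label: str = "") -> DihedralMatrix:
    """Extract per-frame phi/psi for every residue of ``chain``.

    phi(i) = torsion(C(i-1), N(i), CA(i), C(i));
    psi(i) = torsion(N(i), CA(i), C(i), N(i+1)).
    Residues must be consecutively numbered and each carry N, CA and C.
    """
    residues: dict[int, dict[str, int]] = {}
    for i, atom in enumerate(ensemble.topology):
        if atom.chain_id == chain and atom.record_class == POLYMER:
            residues.setdefault(atom.residue_number, {})[atom.atom_name] = i
    if not residues:
        raise MissingAtomError(f"chain {chain!r} has no polymer atoms")
    numbers = sorted(residues)
    if numbers[-1] - numbers[0] + 1 != len(numbers):
        missing = sorted(set(range(numbers[0], numbers[-1] + 1)) - set(numbers))
        raise ChainBreakError(
            f"chain {chain!r} residue numbering not consecutive; missing {missing}"
        )
    for num in numbers:
        for name in ("N", "CA", "C"):
            if name not in residues[num]:
                raise MissingAtomError(f"residue {num} of chain {chain!r} lacks {name}")

    coords = ensemble.coordinates
    n_idx = np.array([residues[num]["N"] for num in numbers])
    ca_idx = np.array([residues[num]["CA"] for num in numbers])
    c_idx = np.array([residues[num]["C"] for num in numbers])

    cols: list[np.ndarray] = []
    labels: list[tuple[int, str]] = []
    for k, num in enumerate(numbers):
        if k > 0:
            labels.append((num, "phi"))
            cols.append(
                torsion(
                    coords[:, c_idx[k - 1]],
                    coords[:, n_idx[k]],
                    coords[:, ca_idx[k]],
                    coords[:, c_idx[k]],
                )
            )
        if k < len(numbers) - 1:
            labels.append((num, "psi"))
            cols.append(
                torsion(
                    coords[:, n_idx[k]],
                    coords[:, ca_idx[k]],
                    coords[:, c_idx[k]],
                    coords[:, n_idx[k + 1]],
                )
            )
    return DihedralMatrix(
        values=np.column_stack(cols),
        column_labels=tuple(labels),
        condition_label=condition_label,
    )


@dataclass
class FreeEnergySurface:
    """2-D free-energy grid in kT over the latent plane; empty bins masked."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    grid: np.ma.MaskedArray  # shape (bins_x, bins_y)

    @property
    def minimum(self) -> float:
        return float(self.grid.min())


@dataclass
class LandscapeModel:
    """Shared scaling + PCA basis, per-condition projections and states."""

    column_labels: tuple[tuple[int, str], ...]
    scaling_mean: np.ndarray
    scaling_std: np.ndarray
    components: np.ndarray           # 2 x D, rows orthonormal
    explained_variance: np.ndarray   # first 2 eigenvalues, non-increasing
    all_eigenvalues: np.ndarray      # full spectrum, for the variance identity
    total_variance: float
    projections: dict[str, np.ndarray]  # condition -> F x 2
    dihedral_mode: str = "raw"
    fes: FreeEnergySurface | None = None
    cluster_centers: np.ndarray | None = None
    cluster_labels: dict[str, np.ndarray] = field(default_factory=dict)
    cluster_occupancy: dict[str, dict[str, float]] = field(default_factory=dict)

    def pooled_projection(self) -> np.ndarray:
        return np.vstack(list(self.projections.values()))

    def explained_variance_ratio(self) -> np.ndarray:
        return self.explained_variance / self.all_eigenvalues.sum()


def _sincos_expand(
    values: np.ndarray, labels: tuple[tuple[int, str], ...]
) -> tuple[np.ndarray, tuple[tuple[int, str], ...]]:
    rad = np.radians(values)
    out = np.empty((values.shape[0], 2 * values.shape[1]))
    out[:, 0::2] = np.sin(rad)
    out[:, 1::2] = np.cos(rad)
    new_labels = []
    for num, kind in labels:
        new_labels.append((num, f"sin_{kind}"))
        new_labels.append((num, f"cos_{kind}"))
    return out, tuple(new_labels)


def fit_landscape(
    matrices: list[DihedralMatrix],
    n_components: int = 2,
    dihedral_mode: str = "raw",
) -> LandscapeModel:
    """Pool all conditions, standard-scale, fit PCA, project each condition.

    Scaling and the PCA basis are computed on the row-concatenation of ALL
    conditions so every condition lives in one comparable latent space.
    Scaling divides by the population standard deviation; component signs
    are fixed by forcing the largest-magnitude loading of each component to
    be positive, making projections reproducible.
    """
    if not matrices:
        raise ValidationError("need at least one dihedral matrix")
    if dihedral_mode not in ("raw", "sincos"):
        raise ValidationError(f"unknown dihedral_mode {dihedral_mode!r}")
    labels = matrices[0].column_labels
    for m in matrices[1:]:
        if m.column_labels != labels:
            raise SchemaError(
                f"condition {m.condition_label!r} has different dihedral columns "
                f"than {matrices[0].condition_label!r}"
            )
    names = []
    for i, m in enumerate(matrices):
        name = m.condition_label or f"condition{i + 1}"
        if name in names:
            raise SchemaError(f"duplicate condition label {name!r}")
        names.append(name)

    pooled = np.vstack([m.values for m in matrices])
    if dihedral_mode == "sincos":
        pooled, labels = _sincos_expand(pooled, labels)

    mean = pooled.mean(axis=0)
    std = pooled.std(axis=0)  # population std
    zero = np.flatnonzero(std == 0)
    if zero.size:
        raise ScalingError(
            f"zero-variance column(s) {[labels[j] for j in zero[:5]]}; "
            "standard scaling is undefined (the generator must add noise)"
        )
    scaled = (pooled - mean) / std

    n = scaled.shape[0]
    _, svals, vt = np.linalg.svd(scaled, full_matrices=False)
    eigenvalues = svals**2 / max(n - 1, 1)
    k = min(n_components, vt.shape[0])
    components = vt[:k].copy()
    # deterministic sign: largest-|loading| positive per component
    for row in components:
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1.0

    scores = scaled @ components.T
    projections: dict[str, np.ndarray] = {}
    offset = 0
    for name, m in zip(names, matrices):
        f = m.values.shape[0]
        projections[name] = scores[offset : offset + f]
        offset += f

    return LandscapeModel(
        column_labels=labels,
        scaling_mean=mean,
        scaling_std=std,
        components=components,
        explained_variance=eigenvalues[:k],
        all_eigenvalues=eigenvalues,
        total_variance=float(np.var(scaled, axis=0, ddof=1).sum()),
        projections=projections,
        dihedral_mode=dihedral_mode,
    )


def free_energy_surface(projection: np.ndarray, bins: int = 60) -> FreeEnergySurface:
    """Boltzmann-invert the 2-D sample density: F = -ln p, minimum at zero.

    The histogram spans the bounding box of ``projection`` (pass the pooled
    projection so all conditions share one grid).  Empty bins are masked;
    units are kT (no temperature factor is applied).
    """
    projection = np.asarray(projection, dtype=float)
    if projection.ndim != 2 or projection.shape[1] != 2:
        raise ValidationError("projection must be F x 2")
    if bins < 2:
        raise ValidationError("need at least 2 bins per axis")
    if np.ptp(projection[:, 0]) == 0 or np.ptp(projection[:, 1]) == 0:
        raise DegenerateExtentError("all projected points coincide on an axis")
    counts, x_edges, y_edges = np.histogram2d(
        projection[:, 0], projection[:, 1], bins=bins
    )
    p = counts / counts.sum()
    occupied = p > 0
    grid = np.ma.masked_all(p.shape)
    grid[occupied] = -np.log(p[occupied])
    grid -= grid.min()
    return FreeEnergySurface(x_edges=x_edges, y_edges=y_edges, grid=grid)


def kmeans_states(
    model: LandscapeModel, k: int = 3, seed: int = 0
) -> tuple[np.ndarray, dict[str, np.ndarray], dict[str, dict[str, float]]]:
    """Assign frames to conformational states by K-Means on pooled projections.

    k-means++ initialization with 10 restarts and a fixed seed; clusters are
    relabeled A, B, C ... by ascending PC1 of their centers.  Returns
    ``(centers, per-condition letter labels, per-condition occupancy)`` and
    stores them on the model.
    """
    pooled = model.pooled_projection()
    if len(np.unique(pooled, axis=0)) < k:
        raise ClusteringError(f"fewer than {k} distinct projected points")
    if k > len(STATE_LETTERS):
        raise ClusteringError(f"k={k} exceeds available state letters")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    raw_labels = km.fit_predict(pooled)
    order = np.argsort(km.cluster_centers_[:, 0])
    centers = km.cluster_centers_[order]
    letter_of = {int(old): STATE_LETTERS[new] for new, old in enumerate(order)}
    letters = [STATE_LETTERS[i] for i in range(k)]

    labels: dict[str, np.ndarray] = {}
    occupancy: dict[str, dict[str, float]] = {}
    offset = 0
    for name, proj in model.projections.items():
        f = proj.shape[0]
        cond = np.array([letter_of[int(c)] for c in raw_labels[offset : offset + f]])
        labels[name] = cond
        occupancy[name] = {
            letter: float(np.mean(cond == letter)) for letter in letters
        }
        offset += f

    model.cluster_centers = centers
    model.cluster_labels = labels
    model.cluster_occupancy = occupancy
    return centers, labels, occupancy


def plot_landscape(model: LandscapeModel, path: str, temporal_shading: bool = True) -> None:
    """Optional scatter + free-energy plot (PNG). Plotting only; no analysis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(11, 4.5))
    if model.fes is not None:
        fes = model.fes
        mesh = axes[0].pcolormesh(
            fes.x_edges, fes.y_edges, fes.grid.T, shading="auto", cmap="viridis"
        )
        fig.colorbar(mesh, ax=axes[0], label="free energy (kT)")
    axes[0].set_title("free-energy landscape")
    for name, proj in model.projections.items():
        c = np.linspace(0.3, 1.0, proj.shape[0]) if temporal_shading else None
        axes[1].scatter(proj[:, 0], proj[:, 1], s=4, alpha=0.5, c=c, label=name)
    if model.cluster_centers is not None:
        for i, ctr in enumerate(model.cluster_centers):
            axes[1].annotate(
                STATE_LETTERS[i], ctr, fontsize=14, fontweight="bold", color="red"
            )
    axes[1].legend(markerscale=3, fontsize=8)
    for ax in axes:
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
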