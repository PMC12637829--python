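"""Helical geometry of fibril stacks.

Axis estimation, best-fit planes and the layer "warping RMSD", helical
rise/twist measurement and stack generation, crossover length and
handedness, and rigid-body segment superposition.

Conventions
-----------
The fibril axis is oriented from the first to the last layer of the
stack.  The per-layer twist is signed by the right-hand rule about that
direction, calibrated so that a fibril with +3.95 deg twist per layer is
right-handed.  The crossover is the half-turn length ``rise * 180 / |twist|``
of a 1-start helix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import (
    AtomRecord,
    FibrilModel,
    HelicalParams,
    ResidueSpan,
    generate_chain_ids,
)

__all__ = [
    "Axis",
    "Plane",
    "WarpingResult",
    "SuperpositionResult",
    "DegeneracyError",
    "estimate_axis",
    "best_fit_plane",
    "warping_rmsd",
    "build_helical_stack",
    "measure_rise_twist",
    "crossover_length",
    "handedness",
    "segment_rmsd",
    "kabsch",
]


class DegeneracyError(ValueError):
    """Raised for degenerate point sets (collinear, too few points)."""


@dataclass(frozen=True)
class Axis:
    """Fibril axis: anchor point plus unit direction."""

    anchor: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "anchor", np.asarray(self.anchor, float).reshape(3))
        d = np.asarray(self.direction, float).reshape(3)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("axis direction must be nonzero")
        object.__setattr__(self, "direction", d / n)


@dataclass(frozen=True)
class Plane:
    """Plane given by unit normal and signed offset from the origin."""

    normal: np.ndarray
    offset: float

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, float).reshape(3)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("plane normal must be nonzero")
        object.__setattr__(self, "normal", n / norm)

    def distances(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float).reshape(-1, 3)
        return pts @ self.normal - self.offset


@dataclass(frozen=True)
class WarpingResult:
    """Layer non-planarity: RMS Calpha distance from two reference planes.

    ``rmsd_normal_plane`` uses the plane normal to the fibril axis through
    the Calpha centroid; ``rmsd_best_fit`` uses the least-squares plane and
    is therefore never larger.
    """

    rmsd_normal_plane: float
    rmsd_best_fit: float
    n_calpha: int
    chain: str


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray
    rmsd: float
    n_atoms: int


# ---------------------------------------------------------------------------


def _layer_ca_centroids(model: FibrilModel) -> np.ndarray:
    cents = []
    for cid in model.layers:
        ca = model.ca_coords(cid)
        pts = ca if len(ca) else model.coords(model.chain_atoms(cid))
        cents.append(pts.mean(axis=0))
    return np.array(cents)


def estimate_axis(model: FibrilModel) -> Axis:
    """Least-squares line through per-layer Calpha centroids.

    Oriented from the first to the last layer of ``model.layers``.
    """
    if len(model.layers) < 2:
        raise ValueError("axis estimation needs at least 2 layers")
    cents = _layer_ca_centroids(model)
    anchor = cents.mean(axis=0)
    centered = cents - anchor
    if len(model.layers) == 2:
        direction = centered[-1] - centered[0]
    else:
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        direction = vt[0]
    if direction @ (cents[-1] - cents[0]) < 0:
        direction = -direction
    return Axis(anchor=anchor, direction=direction)


def best_fit_plane(points: np.ndarray) -> tuple[Plane, float]:
    """Least-squares plane and RMS orthogonal distance of a point cloud.

    The normal is the smallest principal direction of the centered
    points; collinear or under-determined inputs raise
    :class:`DegeneracyError`.
    """
    pts = np.asarray(points, float).reshape(-1, 3)
    if len(pts) < 3:
        raise DegeneracyError("plane fit needs at least 3 points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # collinear: only one significant singular value
    scale = max(s[0], 1e-12)
    if s[1] / scale < 1e-9:
        raise DegeneracyError("points are collinear; plane is undetermined")
    normal = vt[2]
    plane = Plane(normal=normal, offset=float(normal @ centroid))
    rmsd = float(np.sqrt(np.mean(plane.distances(pts) ** 2)))
    return plane, rmsd


def warping_rmsd(
    model: FibrilModel,
    chain: str,
    axis: Axis,
    core: list[ResidueSpan] | None = None,
) -> WarpingResult:
    """Warping of one layer: RMS Calpha deviation from a reference plane.

    Uses the Calpha atoms of the core residues of ``chain``.  Two numbers
    are reported: deviation from the plane normal to the fibril axis
    through the Calpha centroid, and deviation from the least-squares
    best-fit plane.  ``core=None`` uses all modelled residues of the chain.
    """
    atoms = model.chain_atoms(chain)
    wanted = {a.residue_index for a in atoms}
    if core is not None:
        wanted = {i for i in wanted if any(i in sp for sp in core)}
        missing = {
            i
            for sp in (core or [])
            for i in range(sp.first, sp.last + 1)
            if i not in wanted
        }
        if missing:
            warnings.warn(
                f"{len(missing)} core residues missing from chain {chain}; skipped",
                stacklevel=2,
            )
    ca = {}
    for a in atoms:
        if a.atom_name == "CA" and a.residue_index in wanted:
            ca[a.residue_index] = a.coords
    no_ca = wanted - set(ca)
    if no_ca:
        warnings.warn(
            f"{len(no_ca)} residues of chain {chain} lack a CA atom; skipped",
            stacklevel=2,
        )
    pts = np.array([ca[i] for i in sorted(ca)])
    if len(pts) < 3:
        raise ValueError("warping RMSD needs at least 3 Calpha atoms")
    _, rmsd_bf = best_fit_plane(pts)
    centroid = pts.mean(axis=0)
    normal_plane = Plane(normal=axis.direction, offset=float(axis.direction @ centroid))
    rmsd_np = float(np.sqrt(np.mean(normal_plane.distances(pts) ** 2)))
    return WarpingResult(
        rmsd_normal_plane=rmsd_np,
        rmsd_best_fit=rmsd_bf,
        n_calpha=len(pts),
        chain=chain,
    )


# ---------------------------------------------------------------------------
# helical symmetry


def _axis_rotation(axis: Axis, angle_deg: float) -> Rotation:
    return Rotation.from_rotvec(np.deg2rad(angle_deg) * axis.direction)


def build_helical_stack(
    layer: FibrilModel,
    rise: float,
    twist: float,
    n_layers: int,
    axis: Axis | None = None,
) -> FibrilModel:
    """Generate an ``n_layers`` stack from a single-chain layer.

    Layer *k* is the input chain rotated by ``k * twist`` about the axis
    and translated by ``k * rise`` along it.  Chain ids are generated
    deterministically (A, B, C, ...).
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    if len(layer.chain_ids()) != 1:
        raise ValueError("build_helical_stack expects a single-chain layer")
    if axis is None:
        axis = Axis(anchor=np.zeros(3), direction=np.array([0.0, 0.0, 1.0]))
    src = layer.atoms
    chain_ids = generate_chain_ids(n_layers)
    atoms: list[AtomRecord] = []
    for k in range(n_layers):
        rot = _axis_rotation(axis, k * twist)
        shift = axis.anchor + k * rise * axis.direction
        for a in src:
            new_xyz = rot.apply(a.coords - axis.anchor) + shift
            atoms.append(replace(a, chain_id=chain_ids[k], coords=new_xyz))
    return FibrilModel(
        atoms=atoms,
        layers=chain_ids,
        helical=HelicalParams(rise=rise, twist=twist) if rise > 0 else None,
        label=layer.label,
        central_layer=(n_layers - 1) // 2,
    )


def kabsch(moving: np.ndarray, fixed: np.ndarray) -> SuperpositionResult:
    """Optimal proper-rotation least-squares superposition of paired points.

    Returns the rigid transform mapping ``moving`` onto ``fixed``:
    ``fixed ~ R @ moving + t``.
    """
    a = np.asarray(moving, float).reshape(-1, 3)
    b = np.asarray(fixed, float).reshape(-1, 3)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("superposition needs >= 3 paired points of equal count")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    rot, rssd = Rotation.align_vectors(b - cb, a - ca)
    R = rot.as_matrix()
    t = cb - R @ ca
    rmsd = float(rssd / np.sqrt(len(a)))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms=len(a))


def _matched_layer_coords(model: FibrilModel, cid_a: str, cid_b: str) -> tuple[np.ndarray, np.ndarray]:
    def keyed(cid: str) -> dict[tuple[int, str], np.ndarray]:
        return {
            (a.residue_index, a.atom_name): a.coords
            for a in model.chain_atoms(cid)
            if not a.is_hydrogen
        }

    ka, kb = keyed(cid_a), keyed(cid_b)
    if set(ka) != set(kb):
        raise ValueError(
            f"layers {cid_a} and {cid_b} have non-identical atom composition"
        )
    keys = sorted(ka)
    return np.array([ka[k] for k in keys]), np.array([kb[k] for k in keys])


def measure_rise_twist(model: FibrilModel) -> HelicalParams:
    """Recover per-layer rise and signed twist from a stack.

    For each consecutive layer pair the least-squares rigid transform
    (Kabsch) is computed; the twist is the rotation angle signed by the
    right-hand rule about the stack direction, the rise the translation
    component along it.  Values are averaged over pairs and the standard
    deviations reported as quality metrics.
    """
    if len(model.layers) < 2:
        raise ValueError("rise/twist needs at least 2 layers")
    axis = estimate_axis(model)
    rises, twists = [], []
    for cid_a, cid_b in zip(model.layers, model.layers[1:]):
        xa, xb = _matched_layer_coords(model, cid_a, cid_b)
        sup = kabsch(xa, xb)
        rotvec = Rotation.from_matrix(sup.rotation).as_rotvec()
        angle = np.linalg.norm(rotvec)
        if angle < 1e-12:
            direction = axis.direction
            twist = 0.0
        else:
            direction = rotvec / angle
            if direction @ axis.direction < 0:
                direction = -direction
            twist = float(np.rad2deg(rotvec @ direction))
        # rise: displacement of the centroid along the screw axis
        rise = float((xb.mean(axis=0) - xa.mean(axis=0)) @ direction)
        rises.append(rise)
        twists.append(twist)
    rise_mean = float(np.mean(rises))
    if rise_mean < 0:  # stack listed against its own axis; flip convention
        rise_mean, twists = -rise_mean, [-t for t in twists]
    return HelicalParams(
        rise=rise_mean,
        twist=float(np.mean(twists)),
        twist_std=float(np.std(twists)),
        rise_std=float(np.std(rises)),
    )


def crossover_length(params: HelicalParams) -> float:
    """Half-turn (crossover) length of a 1-start helix, in Angstrom."""
    if params.twist == 0:
        raise ValueError("crossover undefined for zero twist")
    return params.rise * 180.0 / abs(params.twist)


def handedness(params: HelicalParams) -> str:
    """``right`` for positive twist, ``left`` for negative, else ``undefined``."""
    return params.handedness


# ---------------------------------------------------------------------------


_BACKBONE = ("N", "CA", "C", "O")


def segment_rmsd(
    model_a: FibrilModel,
    span_a: ResidueSpan,
    chain_a: str,
    model_b: FibrilModel,
    span_b: ResidueSpan,
    chain_b: str,
) -> SuperpositionResult:
    """Backbone superposition RMSD between two residue segments.

    Residue ``span_a.first + i`` pairs with ``span_b.first + i``; the
    backbone atoms (N, CA, C, O) present in *both* residues are matched.
    Spans of unequal length, or mismatched atom counts after
    intersection, raise an error.
    """
    if len(span_a) != len(span_b):
        raise ValueError("spans must cover equal numbers of residues")

    def backbone(model: FibrilModel, chain: str, span: ResidueSpan):
        table: dict[tuple[int, str], np.ndarray] = {}
        for a in model.chain_atoms(chain):
            if a.residue_index in span and a.atom_name in _BACKBONE:
                table[(a.residue_index - span.first, a.atom_name)] = a.coords
        return table

    ta = backbone(model_a, chain_a, span_a)
    tb = backbone(model_b, chain_b, span_b)
    shared = sorted(set(ta) & set(tb))
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared backbone atoms")
    if len(shared) != len(ta) or len(shared) != len(tb):
        raise ValueError(
            f"backbone atom sets differ after intersection "
            f"({len(ta)} vs {len(tb)}, {len(shared)} shared)"
        )
    xa = np.array([ta[k] for k in shared])
    xb = np.array([tb[k] for k in shared])
    return kabsch(xa, xb)
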