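"""Ground-truth-bearing synthetic inputs: ideal cross-beta fibrils and
simulated optical-tweezers pulls.

Every generated dataset carries a machine-readable ground-truth record so
downstream analyses can be checked against the construction rather than
against hard-coded numbers.  All randomness flows through a single
``numpy`` generator seeded from the spec.

Fibrils are idealized: Calpha atoms follow a 2D path in the layer plane
(straight strand, U-bend or S-fold serpentine, or a user path), backbone
N/C/O and Cbeta atoms are placed with ideal bond lengths and a cross-beta
pleat, side chains beyond Cbeta are omitted, and layers are generated by
helical symmetry.  Optional out-of-plane sinusoidal warp and Gaussian
coordinate noise emulate the non-planarity and coordinate error of real
reconstructions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
import numpy as np

from .forcespec import ForceExtensionCurve, TetherModel, tether_extension
from .geometry import Axis, build_helical_stack
from .structure_io import AtomRecord, FibrilModel

__all__ = [
    "IdealFibrilSpec",
    "FibrilGroundTruth",
    "FecSimSpec",
    "make_ideal_fibril",
    "simulate_fec",
]


_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

_CA_SPACING = 3.8  # A, consecutive Calpha in an extended strand
_TURN_RADIUS = 4.8  # A, half the sheet-to-sheet separation


@dataclass(frozen=True)
class IdealFibrilSpec:
    """Recipe for an idealized cross-beta stack.

    ``warp`` is ``None`` or ``(amplitude_A, period_residues)``: an
    out-of-plane displacement ``a * sin(2*pi*i/period)`` applied to
    residue i of every layer before stacking.
    """

    sequence: str
    rise: float = 4.8
    twist: float = -1.5
    n_layers: int = 5
    template: str = "linear"  # linear | U_bend | S_fold
    backbone_path: np.ndarray | None = None  # (n, 2) Calpha trace, overrides template
    warp: tuple[float, float] | None = None
    noise_sigma: float = 0.0
    seed: int = 0
    first_residue: int = 1
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.warp is not None and self.warp[0] < 0:
            raise ValueError("warp amplitude must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        bad = [c for c in self.sequence if c not in _AA3]
        if bad:
            raise ValueError(f"invalid residue letters: {sorted(set(bad))}")
        if self.backbone_path is not None:
            path = np.asarray(self.backbone_path, float)
            if path.shape != (len(self.sequence), 2):
                raise ValueError("backbone_path must be (len(sequence), 2)")
            object.__setattr__(self, "backbone_path", path)


@dataclass(frozen=True)
class FibrilGroundTruth:
    """Exact construction parameters of a generated fibril."""

    rise: float
    twist: float
    n_layers: int
    chain_ids: tuple[str, ...]
    central_chain: str
    warp_dz: np.ndarray  # per-residue out-of-plane displacement, A
    warp_rms: float  # RMS of warp_dz about its mean (normal-plane warping)
    noise_sigma: float
    seed: int
    sequence: str
    first_residue: int

    def to_json(self) -> str:
        d = asdict(self)
        d["warp_dz"] = list(map(float, self.warp_dz))
        d["chain_ids"] = list(self.chain_ids)
        return json.dumps(d, indent=1)


# ---------------------------------------------------------------------------
# Calpha paths


def _resample_polyline(points: np.ndarray, n: int, spacing: float) -> np.ndarray:
    """n points spaced ``spacing`` apart in arc length along a polyline."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(n) * spacing
    if targets[-1] > s[-1] + 1e-9:
        raise ValueError("template path too short for sequence")
    x = np.interp(targets, s, points[:, 0])
    y = np.interp(targets, s, points[:, 1])
    return np.column_stack([x, y])


def _arc(center: np.ndarray, radius: float, a0: float, a1: float, n: int = 64) -> np.ndarray:
    t = np.linspace(a0, a1, n)
    return center + radius * np.column_stack([np.cos(t), np.sin(t)])


def _template_path(template: str, n: int) -> np.ndarray:
    total = _CA_SPACING * (n - 1) + 1e-6
    r = _TURN_RADIUS
    if template == "linear":
        poly = np.array([[0.0, 0.0], [total + 1.0, 0.0]])
    elif template == "U_bend":
        arm = (total - np.pi * r) / 2.0
        if arm <= 0:
            raise ValueError("sequence too short for U_bend template")
        poly = np.vstack(
            [
                [[-arm - 1.0, 0.0], [0.0, 0.0]],
                _arc(np.array([0.0, r]), r, -np.pi / 2, np.pi / 2),
                [[0.0, 2 * r], [-arm - 1.0, 2 * r]],
            ]
        )
    elif template == "S_fold":
        arm = (total - 2 * np.pi * r) / 3.0
        if arm <= 0:
            raise ValueError("sequence too short for S_fold template")
        poly = np.vstack(
            [
                [[-arm - 1.0, 0.0], [0.0, 0.0]],
                _arc(np.array([0.0, r]), r, -np.pi / 2, np.pi / 2),
                [[0.0, 2 * r], [-arm, 2 * r]],
                _arc(np.array([-arm, 3 * r]), r, -np.pi / 2, -3 * np.pi / 2),
                [[-arm, 4 * r], [1.0, 4 * r]],
            ]
        )
    else:
        raise ValueError(f"unknown template {template!r}")
    return _resample_polyline(poly, n, _CA_SPACING)


# ---------------------------------------------------------------------------
# backbone construction

# offsets in the local (tangent t, in-plane normal p, layer normal z) frame;
# chosen to give ideal-length bonds (N-CA 1.458, CA-C 1.525, C-N ~1.33 A)
# with a cross-beta pleat alternating along the strand
_N_T, _N_P = -1.18, -0.86
_C_T, _C_P = 1.25, 0.87
_O_Z = 1.23
_CB_LEN = 1.53
_CB_DIR = np.array([-0.3, 0.55, 0.77])  # (t, p, z), normalized below
_CB_DIR = _CB_DIR / np.linalg.norm(_CB_DIR)


def _layer_atoms(spec: IdealFibrilSpec, path: np.ndarray, dz: np.ndarray) -> list[AtomRecord]:
    n = len(path)
    # tangents from central differences in the layer plane
    t2 = np.empty_like(path)
    t2[1:-1] = path[2:] - path[:-2]
    t2[0] = path[1] - path[0]
    t2[-1] = path[-1] - path[-2]
    t2 /= np.linalg.norm(t2, axis=1, keepdims=True)

    atoms: list[AtomRecord] = []
    zhat = np.array([0.0, 0.0, 1.0])
    for i in range(n):
        letter = spec.sequence[i]
        res3 = _AA3[letter]
        ridx = spec.first_residue + i
        s = 1.0 if i % 2 == 0 else -1.0
        t = np.array([t2[i, 0], t2[i, 1], 0.0])
        p = np.array([-t2[i, 1], t2[i, 0], 0.0])
        ca = np.array([path[i, 0], path[i, 1], dz[i]])

        def rec(name: str, element: str, xyz: np.ndarray) -> AtomRecord:
            from .structure_io import DEFAULT_VDW_RADII

            return AtomRecord(
                element=element,
                atom_name=name,
                residue_index=ridx,
                residue_name=res3,
                chain_id="A",
                coords=xyz,
                vdw_radius=DEFAULT_VDW_RADII[element],
            )

        atoms.append(rec("N", "N", ca + _N_T * t + s * _N_P * p))
        atoms.append(rec("CA", "C", ca))
        c = ca + _C_T * t + s * _C_P * p
        atoms.append(rec("C", "C", c))
        atoms.append(rec("O", "O", c + s * _O_Z * zhat))
        if res3 != "GLY":
            d = _CB_DIR[0] * t + s * _CB_DIR[1] * p - s * _CB_DIR[2] * zhat
            atoms.append(rec("CB", "C", ca + _CB_LEN * d))
    return atoms


def make_ideal_fibril(spec: IdealFibrilSpec) -> tuple[FibrilModel, FibrilGroundTruth]:
    """Build an idealized fibril stack and its ground-truth record.

    The Calpha trace is centered on the helical axis (z through the
    origin), warped out of plane per the spec, stacked with the given
    rise/twist, and perturbed with seeded Gaussian coordinate noise.
    """
    n = len(spec.sequence)
    if spec.backbone_path is not None:
        path = np.asarray(spec.backbone_path, float)
    else:
        path = _template_path(spec.template, n)
    path = path - path.mean(axis=0)  # axis through the layer centroid

    i = np.arange(n)
    if spec.warp is not None and spec.warp[0] > 0:
        amplitude, period = spec.warp
        dz = amplitude * np.sin(2.0 * np.pi * i / period)
    else:
        dz = np.zeros(n)

    layer = FibrilModel(atoms=_layer_atoms(spec, path, dz), label=spec.label)
    axis = Axis(anchor=np.zeros(3), direction=np.array([0.0, 0.0, 1.0]))
    stack = build_helical_stack(layer, spec.rise, spec.twist, spec.n_layers, axis)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        jitter = rng.normal(0.0, spec.noise_sigma, size=(len(stack.atoms), 3))
        atoms = [
            AtomRecord(
                element=a.element,
                atom_name=a.atom_name,
                residue_index=a.residue_index,
                residue_name=a.residue_name,
                chain_id=a.chain_id,
                coords=a.coords + jitter[k],
                vdw_radius=a.vdw_radius,
                is_hydrogen=a.is_hydrogen,
            )
            for k, a in enumerate(stack.atoms)
        ]
        stack = FibrilModel(
            atoms=atoms,
            layers=list(stack.layers),
            helical=stack.helical,
            label=stack.label,
            central_layer=stack.central_layer,
        )

    truth = FibrilGroundTruth(
        rise=spec.rise,
        twist=spec.twist,
        n_layers=spec.n_layers,
        chain_ids=tuple(stack.layers),
        central_chain=stack.central_chain(),
        warp_dz=dz,
        warp_rms=float(np.sqrt(np.mean((dz - dz.mean()) ** 2))),
        noise_sigma=spec.noise_sigma,
        seed=spec.seed,
        sequence=spec.sequence,
        first_residue=spec.first_residue,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# simulated force-extension curves


@dataclass(frozen=True)
class FecSimSpec:
    """Recipe for a quasi-static stretch/relax pull.

    ``segments`` lists (n_residues, rupture_force_pN) of programmed
    unfolding events; each segment adds its residues to the unfolded
    contour when the force first exceeds its rupture force during the
    stretch.  ``trap_stiffness`` (pN/nm) adds bead displacement to the
    ramp coordinate; ``None`` models a stiff-trap extension ramp.
    """

    tether: TetherModel = field(default_factory=TetherModel)
    segments: tuple[tuple[int, float], ...] = ()
    force_window: tuple[float, float] = (2.0, 35.0)
    samples_per_nm: float = 5.0
    noise_sigma: float = 0.2
    seed: int = 0
    trap_stiffness: float | None = None
    pulling_speed: float = 100.0

    def __post_init__(self) -> None:
        fmin, fmax = self.force_window
        if not 0 < fmin < fmax:
            raise ValueError("force window must satisfy 0 < min < max")
        for n_res, f_rupt in self.segments:
            if n_res < 1:
                raise ValueError("segment sizes must be >= 1")
            if not fmin < f_rupt < fmax:
                raise ValueError(
                    f"rupture force {f_rupt} outside force window {self.force_window}"
                )


def _ramp_coordinate(spec: FecSimSpec, force: np.ndarray, n_unfolded: int) -> np.ndarray:
    d = tether_extension(force, spec.tether, n_unfolded)
    if spec.trap_stiffness is not None:
        d = d + force / spec.trap_stiffness
    return d


def simulate_fec(spec: FecSimSpec) -> list[ForceExtensionCurve]:
    """Simulate one quasi-static pull: a stretch and a relax branch.

    Deterministic given the seed.  Segments unfold in order of rupture
    force; segments whose rupture force is exceeded immediately after a
    preceding rip unfold at the same ramp position (a merged rip).  The
    relax branch keeps everything unfolded (no refolding events).
    """
    segments = sorted(spec.segments, key=lambda s: s[1])
    fmin, fmax = spec.force_window
    flo = min(0.5, fmin / 4.0)
    fgrid = np.linspace(flo, fmax * 1.02, 4096)

    # cumulative unfolded residues per state and ramp position of each rip
    n_unfolded = [0]
    for n_res, _ in segments:
        n_unfolded.append(n_unfolded[-1] + n_res)
    d_of_state = [_ramp_coordinate(spec, fgrid, u) for u in n_unfolded]

    d_start = float(np.interp(fmin, fgrid, d_of_state[0]))
    d_end = float(np.interp(fmax, fgrid, d_of_state[-1]))
    rip_d = []
    for k, (_, f_rupt) in enumerate(segments):
        d_rupt = float(np.interp(f_rupt, fgrid, d_of_state[k]))
        if rip_d and d_rupt < rip_d[-1]:
            d_rupt = rip_d[-1]  # cascade: unfolds immediately after previous rip
        rip_d.append(d_rupt)

    n_samples = max(10, int(np.ceil((d_end - d_start) * spec.samples_per_nm)))
    d = np.linspace(d_start, d_end, n_samples)
    state = np.searchsorted(np.asarray(rip_d), d, side="right")
    force = np.empty(n_samples)
    for k in range(len(n_unfolded)):
        sel = state == k
        if np.any(sel):
            force[sel] = np.interp(d[sel], d_of_state[k], fgrid)

    rng = np.random.default_rng(spec.seed)
    noisy = force + rng.normal(0.0, spec.noise_sigma, n_samples)
    if spec.trap_stiffness is not None:
        extension = d - force / spec.trap_stiffness
    else:
        extension = d
    stretch = ForceExtensionCurve(
        extension=extension,
        force=noisy,
        pulling_speed=spec.pulling_speed,
        direction="stretch",
    )

    # relax: everything stays unfolded
    d_rel = d[::-1]
    force_rel = np.interp(d_rel, d_of_state[-1], fgrid)
    noisy_rel = force_rel + rng.normal(0.0, spec.noise_sigma, n_samples)
    if spec.trap_stiffness is not None:
        ext_rel = d_rel - force_rel / spec.trap_stiffness
    else:
        ext_rel = d_rel
    relax = ForceExtensionCurve(
        extension=ext_rel,
        force=noisy_rel,
        pulling_speed=spec.pulling_speed,
        direction="relax",
    )
    return [stretch, relax]
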