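"""Solvation-based fibril stabilization energetics.

The stabilization free energy of a fibril layer is estimated with an
atomic-solvation-parameter (ASP) model: every heavy atom carries a free
energy per unit of solvent-accessible surface area (SASA), and the energy
of moving a chain from an unassembled reference state into the fibril is

    dG_stab(chain) = sum_atoms ASP(class) * [A_fibril(atom) - A_reference(atom)]

Burial of apolar carbon (positive ASP) is favorable, burial of charged
nitrogen/oxygen (negative ASP) unfavorable; negative totals mean a
stabilized fibril.  The default parameters are Eisenberg-McLachlan-class
values in kcal/(mol*A^2) and the default reference is the chain rebuilt
with extended backbone dihedrals, so that both intra-layer side-chain
packing and inter-layer burial contribute.

SASA is computed with a deterministic sphere-sampling (Shrake-Rupley)
engine using a golden-spiral point set, so results are bit-reproducible.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .geometry import Axis, build_helical_stack, estimate_axis, kabsch
from .structure_io import AtomRecord, FibrilModel, ResidueSpan

__all__ = [
    "SolvationParameterSet",
    "SasaResult",
    "StabilityProfile",
    "DEFAULT_ASP",
    "compute_sasa",
    "chain_sasa",
    "reference_sasa",
    "build_extended_chain",
    "stabilization_energy",
    "subunit_decomposition",
    "energy_map_values",
    "calibration_scale",
]


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class SolvationParameterSet:
    """Atomic solvation parameters, kcal/(mol*A^2), by atom class.

    Classes: apolar carbon, uncharged polar N/O, carboxylate O(-),
    protonated N(+) (Lys NZ, Arg guanidinium), and sulfur.
    """

    apolar_carbon: float = 0.016
    polar_no: float = -0.006
    charged_o: float = -0.024
    charged_n: float = -0.050
    sulfur: float = 0.021
    name: str = "eisenberg-mclachlan"
    reference_state: str = "extended_chain"  # or "isolated_chain"

    def __post_init__(self) -> None:
        if self.apolar_carbon <= 0:
            raise ValueError("apolar carbon parameter must be positive")
        if self.charged_o >= 0 or self.charged_n >= 0:
            raise ValueError("charged-atom parameters must be negative")
        if self.reference_state not in ("extended_chain", "isolated_chain"):
            raise ValueError(f"unknown reference state {self.reference_state!r}")

    def asp_for(self, atom: AtomRecord) -> float:
        el = atom.element.upper()
        if el == "S":
            return self.sulfur
        if el == "C":
            return self.apolar_carbon
        name = atom.atom_name
        if el == "O":
            if name == "OXT" or (atom.residue_name, name) in _CHARGED_O:
                return self.charged_o
            return self.polar_no
        if el == "N":
            if (atom.residue_name, name) in _CHARGED_N:
                return self.charged_n
            return self.polar_no
        warnings.warn(f"no solvation parameter for element {el}; using 0", stacklevel=2)
        return 0.0

    def scaled(self, factor: float) -> "SolvationParameterSet":
        return replace(
            self,
            apolar_carbon=self.apolar_carbon * factor,
            polar_no=self.polar_no * factor,
            charged_o=self.charged_o * factor,
            charged_n=self.charged_n * factor,
            name=f"{self.name} x{factor:.4g}",
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SolvationParameterSet":
        data = json.loads(Path(path).read_text())
        return cls(**data)


_CHARGED_O = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_CHARGED_N = {("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2")}

DEFAULT_ASP = SolvationParameterSet()


# ---------------------------------------------------------------------------
# SASA engine


@dataclass(frozen=True)
class SasaResult:
    """Per-atom accessible areas (A^2) aligned with ``atoms``."""

    areas: np.ndarray
    atoms: tuple  # AtomRecord tuple, non-hydrogen, in model order
    probe_radius: float
    n_sphere_points: int

    @property
    def total(self) -> float:
        return float(self.areas.sum())


def _golden_spiral(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (Fibonacci lattice)."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def compute_sasa(
    model: FibrilModel,
    probe: float = 1.4,
    n_points: int = 960,
) -> SasaResult:
    """Shrake-Rupley accessible surface area of all heavy atoms.

    For every atom, the fraction of ``n_points`` quasi-uniform test points
    on its probe-expanded sphere that are not inside any other
    probe-expanded sphere, times ``4*pi*(r+probe)^2``.  Deterministic:
    no random numbers are used.
    """
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    if n_points < 100:
        raise ValueError("n_points must be >= 100")
    atoms = tuple(a for a in model.atoms if not a.is_hydrogen)
    centers = np.array([a.coords for a in atoms])
    radii = np.array([a.vdw_radius for a in atoms]) + probe

    tree = cKDTree(centers)
    if tree.query_pairs(1e-6):
        raise ValueError("duplicate atom coordinates in model")

    sphere = _golden_spiral(n_points)
    rmax = radii.max()
    areas = np.empty(len(atoms))
    neighbor_lists = tree.query_ball_point(centers, r=radii + rmax)
    for i in range(len(atoms)):
        nbrs = [j for j in neighbor_lists[i] if j != i]
        full = 4.0 * math.pi * radii[i] ** 2
        if not nbrs:
            areas[i] = full
            continue
        nbrs = np.array(nbrs)
        keep = np.linalg.norm(centers[nbrs] - centers[i], axis=1) < radii[i] + radii[nbrs]
        nbrs = nbrs[keep]
        if len(nbrs) == 0:
            areas[i] = full
            continue
        pts = centers[i] + radii[i] * sphere  # (m, 3)
        d2 = ((pts[:, None, :] - centers[nbrs][None, :, :]) ** 2).sum(axis=2)
        buried = (d2 < (radii[nbrs] ** 2)[None, :]).any(axis=1)
        areas[i] = full * (1.0 - buried.mean())
    return SasaResult(
        areas=areas, atoms=atoms, probe_radius=probe, n_sphere_points=n_points
    )


def chain_sasa(result: SasaResult, chain_id: str) -> tuple[np.ndarray, tuple]:
    """Areas and atoms of one chain, in chain atom order."""
    idx = [i for i, a in enumerate(result.atoms) if a.chain_id == chain_id]
    if not idx:
        raise KeyError(f"no chain {chain_id!r} in SASA result")
    return result.areas[idx], tuple(result.atoms[i] for i in idx)


# ---------------------------------------------------------------------------
# reference states


_BB_GEOM = {
    "n_ca": 1.458,
    "ca_c": 1.525,
    "c_n": 1.329,
    "c_o": 1.231,
    "ang_n_ca_c": 111.0,
    "ang_ca_c_n": 116.2,
    "ang_c_n_ca": 121.7,
    "ang_ca_c_o": 120.5,
}
_EXTENDED_PHI = -140.0
_EXTENDED_PSI = 135.0


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Place atom d given three predecessors and internal coordinates (NeRF)."""
    ang = math.radians(angle)
    dih = math.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(dih),
            bond * math.sin(ang) * math.sin(dih),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_extended_chain(model: FibrilModel, chain: str) -> FibrilModel:
    """Rebuild one chain with extended backbone dihedrals.

    Backbone N/CA/C/O atoms are regenerated with ideal geometry at
    phi = -140 deg, psi = +135 deg, omega = 180 deg; all remaining heavy
    atoms of each residue (side chain, OXT) are transplanted rigidly from
    the deposited conformation via the local (N, CA, C) frame, i.e. the
    observed rotamer is kept.  Atom order and identity match the input
    chain exactly, so per-atom area differences are well defined.
    """
    atoms = [a for a in model.chain_atoms(chain)]
    by_res: dict[int, list[AtomRecord]] = {}
    for a in atoms:
        by_res.setdefault(a.residue_index, []).append(a)
    res_order = sorted(by_res)

    g = _BB_GEOM
    backbone: dict[int, dict[str, np.ndarray]] = {}
    prev = None
    for ridx in res_order:
        if prev is None:
            n = np.zeros(3)
            ca = np.array([g["n_ca"], 0.0, 0.0])
            ang = math.radians(g["ang_n_ca_c"])
            c = ca + g["ca_c"] * np.array([-math.cos(ang), math.sin(ang), 0.0])
        else:
            pn, pca, pc = prev["N"], prev["CA"], prev["C"]
            n = _place(pn, pca, pc, g["c_n"], g["ang_ca_c_n"], _EXTENDED_PSI)
            ca = _place(pca, pc, n, g["n_ca"], g["ang_c_n_ca"], 180.0)
            c = _place(pc, n, ca, g["ca_c"], g["ang_n_ca_c"], _EXTENDED_PHI)
        backbone[ridx] = {"N": n, "CA": ca, "C": c}
        prev = backbone[ridx]
    # carbonyl O trans to the next amide N (psi - 180)
    for ridx in res_order:
        bb = backbone[ridx]
        bb["O"] = _place(
            bb["N"], bb["CA"], bb["C"], g["c_o"], g["ang_ca_c_o"], _EXTENDED_PSI - 180.0
        )

    new_atoms: list[AtomRecord] = []
    for a in atoms:
        bb = backbone[a.residue_index]
        if a.atom_name in bb:
            new_atoms.append(replace(a, coords=bb[a.atom_name]))
            continue
        # rigid transplant via the (N, CA, C) frame plus CA-anchored pivot
        old = {x.atom_name: x.coords for x in by_res[a.residue_index]}
        if not all(k in old for k in ("N", "CA", "C")):
            raise ValueError(
                f"residue {a.residue_index} of chain {chain} lacks N/CA/C; "
                "cannot build extended reference"
            )
        src = np.array([old["N"], old["CA"], old["C"]])
        dst = np.array([bb["N"], bb["CA"], bb["C"]])
        sup = kabsch(src, dst)
        new_atoms.append(replace(a, coords=sup.rotation @ a.coords + sup.translation))
    return FibrilModel(atoms=new_atoms, label=f"{model.label}:{chain}:extended")


def reference_sasa(
    model: FibrilModel,
    chain: str,
    reference_state: str = "extended_chain",
    probe: float = 1.4,
    n_points: int = 960,
) -> SasaResult:
    """Per-atom SASA of the unassembled reference state of one chain.

    ``isolated_chain``: the chain in its deposited conformation with all
    other chains removed.  ``extended_chain``: the chain rebuilt with
    extended backbone dihedrals (see :func:`build_extended_chain`).
    """
    if reference_state == "isolated_chain":
        iso = FibrilModel(
            atoms=list(model.chain_atoms(chain)), label=f"{model.label}:{chain}"
        )
        return compute_sasa(iso, probe=probe, n_points=n_points)
    if reference_state == "extended_chain":
        ext = build_extended_chain(model, chain)
        return compute_sasa(ext, probe=probe, n_points=n_points)
    raise ValueError(f"unknown reference state {reference_state!r}")


# ---------------------------------------------------------------------------
# stabilization energy


@dataclass(frozen=True)
class StabilityProfile:
    """Per-chain and per-residue stabilization energies (kcal/mol)."""

    dg_per_chain: float
    dg_per_residue_mean: float
    per_residue: dict[int, float]
    buried_area_per_atom: np.ndarray
    atoms: tuple
    context_layers: int
    chain: str
    params: SolvationParameterSet


_MIN_CONTEXT_LAYERS = 5


def _context_model(model: FibrilModel, chain: str) -> tuple[FibrilModel, str, int]:
    """Ensure the scored chain is interior (>=2 neighbors each side).

    If the stack is too short and helical parameters are known, a
    5-layer stack is regenerated from the requested chain by helical
    symmetry and its central chain scored instead.
    """
    n = len(model.layers)
    pos = model.layers.index(chain)
    if min(pos, n - 1 - pos) >= 2:
        return model, chain, n
    if model.helical is None:
        raise ValueError(
            f"chain {chain} is within 2 layers of the stack edge and no helical "
            "parameters are available to extend the stack"
        )
    if n >= 2:
        axis = estimate_axis(model)
    else:
        axis = Axis(anchor=np.zeros(3), direction=np.array([0.0, 0.0, 1.0]))
    layer = FibrilModel(atoms=list(model.chain_atoms(chain)), label=model.label)
    stack = build_helical_stack(
        layer, model.helical.rise, model.helical.twist, _MIN_CONTEXT_LAYERS, axis
    )
    return stack, stack.central_chain(), _MIN_CONTEXT_LAYERS


def stabilization_energy(
    model: FibrilModel,
    chain: str | None = None,
    params: SolvationParameterSet = DEFAULT_ASP,
    probe: float = 1.4,
    n_points: int = 960,
) -> StabilityProfile:
    """ASP stabilization free energy of one (interior) chain of a fibril.

    ``chain=None`` scores the central chain.  Negative values are
    stabilizing.  The per-residue map sums exactly to the per-chain total.
    """
    if chain is None:
        chain = model.central_chain()
    ctx, scored_chain, n_layers = _context_model(model, chain)
    fib = compute_sasa(ctx, probe=probe, n_points=n_points)
    a_fib, atoms = chain_sasa(fib, scored_chain)
    ref = reference_sasa(
        ctx, scored_chain, params.reference_state, probe=probe, n_points=n_points
    )
    a_ref = ref.areas
    if len(a_ref) != len(a_fib):
        raise RuntimeError("reference and fibril atom sets differ")
    asp = np.array([params.asp_for(a) for a in atoms])
    dg_atom = asp * (a_fib - a_ref)
    per_residue: dict[int, float] = {}
    for a, dg in zip(atoms, dg_atom):
        per_residue[a.residue_index] = per_residue.get(a.residue_index, 0.0) + float(dg)
    total = float(dg_atom.sum())
    n_res = len(per_residue)
    return StabilityProfile(
        dg_per_chain=total,
        dg_per_residue_mean=total / n_res,
        per_residue=per_residue,
        buried_area_per_atom=a_ref - a_fib,
        atoms=atoms,
        context_layers=n_layers,
        chain=scored_chain,
        params=params,
    )


def subunit_decomposition(
    model: FibrilModel,
    chain: str | None,
    subunits: Sequence[ResidueSpan],
    params: SolvationParameterSet = DEFAULT_ASP,
    mode: str = "in_context",
    probe: float = 1.4,
    n_points: int = 960,
) -> dict[str, float]:
    """Stabilization energy per subunit span (kcal/mol).

    ``in_context``: per-residue terms of the full-model calculation summed
    within each span -- additive, sums to the chain total.  ``alone``:
    the model is rebuilt with only that subunit's residues present in
    every layer, then scored.
    """
    if chain is None:
        chain = model.central_chain()
    subunits = list(subunits)
    for i, a in enumerate(subunits):
        for b in subunits[i + 1 :]:
            if a.overlaps(b):
                raise ValueError(f"overlapping subunit spans {a} and {b}")
    residues = set(model.residue_indices(chain))
    covered = {r for r in residues if any(r in sp for sp in subunits)}
    if covered != residues:
        raise ValueError(
            "subunit spans do not partition the chain's ordered residues "
            f"({len(residues - covered)} uncovered)"
        )

    def label(sp: ResidueSpan) -> str:
        return sp.label or f"{sp.first}-{sp.last}"

    if mode == "in_context":
        profile = stabilization_energy(model, chain, params, probe, n_points)
        out = {}
        for sp in subunits:
            out[label(sp)] = float(
                sum(v for r, v in profile.per_residue.items() if r in sp)
            )
        return out
    if mode == "alone":
        out = {}
        for sp in subunits:
            atoms = [a for a in model.atoms if a.residue_index in sp]
            sub = FibrilModel(
                atoms=atoms,
                layers=list(model.layers),
                helical=model.helical,
                label=f"{model.label}:{label(sp)}",
                central_layer=model.central_layer,
            )
            out[label(sp)] = stabilization_energy(
                sub, chain, params, probe, n_points
            ).dg_per_chain
        return out
    raise ValueError(f"unknown mode {mode!r}")


def energy_map_values(
    profile: StabilityProfile, limit: float = 2.5
) -> dict[int, float]:
    """Per-residue energies clipped to [-limit, +limit] kcal/mol for display."""
    return {
        r: float(np.clip(v, -limit, limit)) for r, v in sorted(profile.per_residue.items())
    }


def calibration_scale(
    computed: Mapping[str, float], reference: Mapping[str, float]
) -> float:
    """Least-squares scale factor mapping computed dG values onto a
    user-supplied reference table (shared keys only)."""
    keys = sorted(set(computed) & set(reference))
    if not keys:
        raise ValueError("no shared labels between computed and reference values")
    c = np.array([computed[k] for k in keys])
    r = np.array([reference[k] for k in keys])
    denom = float(c @ c)
    if denom == 0:
        raise ValueError("computed values are all zero; cannot calibrate")
    return float(c @ r) / denom
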