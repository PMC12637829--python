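"""Reading, writing and layer bookkeeping for fibril atomic models.

A fibril model is a finite stack of (nominally identical) protein chains,
one chain per layer along the fibril axis.  This module loads deposited
mmCIF/PDB coordinates into a light-weight :class:`FibrilModel`, assigns van
der Waals radii from a documented table, orders chains along the axis, and
extracts the ordered-core residue spans that the geometry and energy
modules consume.

Residue numbering follows the author (``auth_*``) numbering of the
deposition, which for Sup35NM models coincides with the 1-based sequence
position (S17 is residue 17).
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

import gemmi

__all__ = [
    "AtomRecord",
    "FibrilModel",
    "HelicalParams",
    "ResidueSpan",
    "EmptyModelError",
    "FormatError",
    "DEFAULT_VDW_RADII",
    "read_structure",
    "write_structure",
    "order_layers",
    "ordered_spans",
    "count_span_residues",
    "span_report",
]


class FormatError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class EmptyModelError(ValueError):
    """Raised when a coordinate file contains no protein atoms."""


#: Chothia-style united-atom van der Waals radii (Angstrom), applied
#: uniformly by element.  Hydrogens are flagged, not used for SASA.
DEFAULT_VDW_RADII: dict[str, float] = {
    "C": 1.87,
    "N": 1.50,
    "O": 1.40,
    "S": 1.85,
    "H": 1.00,
    "P": 1.80,
    "SE": 1.90,
}
_FALLBACK_RADIUS = 1.80


@dataclass(frozen=True)
class AtomRecord:
    """One heavy (or flagged hydrogen) atom of a fibril model."""

    element: str
    atom_name: str
    residue_index: int
    residue_name: str
    chain_id: str
    coords: np.ndarray  # shape (3,), Angstrom
    vdw_radius: float
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "coords", np.asarray(self.coords, dtype=float).reshape(3)
        )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.atom_name}")
        if self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive")


@dataclass(frozen=True)
class HelicalParams:
    """Helical symmetry of a fibril: per-layer rise (A) and signed twist (deg).

    The twist sign follows the right-hand rule about the fibril axis
    oriented from the first to the last layer; positive twist is a
    right-handed helix.
    """

    rise: float
    twist: float
    twist_std: float = 0.0
    rise_std: float = 0.0

    def __post_init__(self) -> None:
        if self.rise <= 0:
            raise ValueError("helical rise must be positive")

    @property
    def handedness(self) -> str:
        if self.twist > 0:
            return "right"
        if self.twist < 0:
            return "left"
        return "undefined"


@dataclass(frozen=True)
class ResidueSpan:
    """Inclusive run of residue indices, e.g. the ordered core Y69-Q132."""

    first: int
    last: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.first > self.last:
            raise ValueError(f"span first ({self.first}) > last ({self.last})")

    def __len__(self) -> int:
        return self.last - self.first + 1

    def __contains__(self, residue_index: int) -> bool:
        return self.first <= residue_index <= self.last

    def overlaps(self, other: "ResidueSpan") -> bool:
        return self.first <= other.last and other.first <= self.last


@dataclass
class FibrilModel:
    """Multi-layer fibril atomic model.

    ``layers`` lists chain ids ordered by projection of the chain Calpha
    centroid on the fibril axis; it is a permutation of all protein chains
    present in ``atoms``.  ``central_layer`` is the index into ``layers``
    of the chain used for single-layer analyses (lower of the two middle
    layers for even stacks).
    """

    atoms: list[AtomRecord]
    layers: list[str] = field(default_factory=list)
    helical: HelicalParams | None = None
    label: str = ""
    central_layer: int | None = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyModelError("model contains no atoms")
        chain_ids = self.chain_ids()
        if not self.layers:
            self.layers = chain_ids
        if sorted(self.layers) != sorted(chain_ids):
            raise ValueError("layers must be a permutation of all chains")

    # -- convenience accessors -------------------------------------------------

    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def chain_atoms(self, chain_id: str) -> list[AtomRecord]:
        sel = [a for a in self.atoms if a.chain_id == chain_id]
        if not sel:
            raise KeyError(f"no chain {chain_id!r} in model")
        return sel

    def coords(self, atoms: Sequence[AtomRecord] | None = None) -> np.ndarray:
        src = self.atoms if atoms is None else atoms
        return np.array([a.coords for a in src], dtype=float)

    def ca_coords(self, chain_id: str) -> np.ndarray:
        pts = [a.coords for a in self.chain_atoms(chain_id) if a.atom_name == "CA"]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def residue_indices(self, chain_id: str) -> list[int]:
        return sorted({a.residue_index for a in self.chain_atoms(chain_id)})

    def central_chain(self) -> str:
        idx = self.central_layer
        if idx is None:
            idx = (len(self.layers) - 1) // 2
        return self.layers[idx]

    def n_residues(self) -> int:
        """Total modelled residues over all chains."""
        return len({(a.chain_id, a.residue_index) for a in self.atoms})

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "FibrilModel":
        """Rigidly moved copy (same chains, same ordering)."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float).reshape(3)
        atoms = [replace(a, coords=R @ a.coords + t) for a in self.atoms]
        return FibrilModel(
            atoms=atoms,
            layers=list(self.layers),
            helical=self.helical,
            label=self.label,
            central_layer=self.central_layer,
        )


# ---------------------------------------------------------------------------
# reading / writing


def _radius_for(element: str, radii: dict[str, float]) -> float:
    return radii.get(element.upper(), _FALLBACK_RADIUS)


def read_structure(
    path: str | Path,
    format: str = "auto",
    include_het: bool = False,
    radii: dict[str, float] | None = None,
    label: str | None = None,
) -> FibrilModel:
    """Load a fibril model from an mmCIF or PDB file.

    Protein atoms are loaded with author residue numbering; waters and
    (by default) non-protein heteroatoms are dropped.  Alternate locations
    keep the highest-occupancy conformer; insertion codes are rejected.

    Parameters
    ----------
    format
        ``"mmcif"``, ``"pdb"`` or ``"auto"`` (by extension/content).
    include_het
        Keep non-water heteroatoms (ligands) as part of the model.
    radii
        Element -> vdW radius table; defaults to :data:`DEFAULT_VDW_RADII`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    radii = dict(DEFAULT_VDW_RADII if radii is None else radii)

    fmt = format.lower()
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        elif fmt == "auto":
            st = gemmi.read_structure(str(path))
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        if isinstance(exc, ValueError) and "unknown format" in str(exc):
            raise
        raise FormatError(f"cannot parse {path} as {format}: {exc}") from exc

    st.setup_entities()
    st.remove_alternative_conformations()  # keeps highest occupancy
    if not len(st):
        raise FormatError(f"{path}: no models in file")

    atoms: list[AtomRecord] = []
    model = st[0]
    for chain in model:
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            is_water = info is not None and info.is_water()
            is_aa = info is not None and info.is_amino_acid()
            if is_water:
                continue
            if not is_aa and not include_het:
                continue
            if res.seqid.icode not in ("", " "):
                raise FormatError(
                    f"{path}: insertion code {res.seqid.icode!r} at "
                    f"{chain.name} {res.seqid.num} is not supported"
                )
            for atom in res:
                el = atom.element.name.upper()
                atoms.append(
                    AtomRecord(
                        element=el,
                        atom_name=atom.name,
                        residue_index=res.seqid.num,
                        residue_name=res.name,
                        chain_id=chain.name,
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        vdw_radius=_radius_for(el, radii),
                        is_hydrogen=atom.is_hydrogen(),
                    )
                )
    if not atoms:
        raise EmptyModelError(f"{path}: no protein atoms")
    return FibrilModel(atoms=atoms, label=label if label is not None else path.stem)


def write_structure(model: FibrilModel, path: str | Path, format: str = "auto") -> Path:
    """Write a model to mmCIF or PDB (by extension when ``auto``)."""
    path = Path(path)
    fmt = format.lower()
    if fmt == "auto":
        fmt = "pdb" if path.suffix.lower() in (".pdb", ".ent") else "mmcif"

    st = gemmi.Structure()
    st.name = model.label or "fibril"
    gm = gemmi.Model("1")
    for chain_id in model.layers:
        ch = gemmi.Chain(chain_id)
        by_res: dict[int, list[AtomRecord]] = {}
        for a in model.chain_atoms(chain_id):
            by_res.setdefault(a.residue_index, []).append(a)
        for idx in sorted(by_res):
            recs = by_res[idx]
            res = gemmi.Residue()
            res.name = recs[0].residue_name
            res.seqid = gemmi.SeqId(idx, " ")
            for a in recs:
                at = gemmi.Atom()
                at.name = a.atom_name
                at.element = gemmi.Element(a.element)
                at.pos = gemmi.Position(*a.coords)
                at.occ = 1.0
                res.add_atom(at)
            ch.add_residue(res)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    if fmt == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))
    return path


# ---------------------------------------------------------------------------
# layer ordering and spans


def generate_chain_ids(n: int) -> list[str]:
    """Deterministic chain ids A..Z, AA, AB, ... for generated stacks."""
    letters = string.ascii_uppercase
    out = []
    for k in range(n):
        if k < 26:
            out.append(letters[k])
        else:
            out.append(letters[(k // 26) - 1] + letters[k % 26])
    return out


def order_layers(model: FibrilModel, axis) -> FibrilModel:
    """Order chains by centroid projection on the fibril axis.

    The per-chain Calpha centroid (all atoms if a chain has no CA) is
    projected on ``axis.direction``; chains are sorted ascending, ties
    broken by chain id, and the central layer (lower middle for even
    stacks) is recorded.  Chains whose residue sets differ trigger a
    heterogeneity warning, not an error.
    """
    direction = np.asarray(axis.direction, float).reshape(3)
    projections: list[tuple[float, str]] = []
    residue_sets = []
    for cid in model.chain_ids():
        ca = model.ca_coords(cid)
        pts = ca if len(ca) else model.coords(model.chain_atoms(cid))
        proj = float(np.mean(pts @ direction))
        projections.append((proj, cid))
        residue_sets.append(frozenset(model.residue_indices(cid)))
    if len(set(residue_sets)) > 1:
        warnings.warn(
            "chains have non-identical residue sets; layer ordering may mix entities",
            stacklevel=2,
        )
    projections.sort(key=lambda t: (t[0], t[1]))
    ordered = [cid for _, cid in projections]
    return FibrilModel(
        atoms=list(model.atoms),
        layers=ordered,
        helical=model.helical,
        label=model.label,
        central_layer=(len(ordered) - 1) // 2,
    )


def ordered_spans(model: FibrilModel, chain: str) -> list[ResidueSpan]:
    """Maximal runs of consecutive modelled residue indices of one chain."""
    indices = model.residue_indices(chain)
    return spans_from_indices(indices)


def spans_from_indices(indices: Iterable[int]) -> list[ResidueSpan]:
    idx = sorted(set(int(i) for i in indices))
    if not idx:
        return []
    spans: list[ResidueSpan] = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i == prev + 1:
            prev = i
            continue
        spans.append(ResidueSpan(start, prev))
        start = prev = i
    spans.append(ResidueSpan(start, prev))
    return spans


def count_span_residues(spans: Sequence[ResidueSpan]) -> int:
    """Total residues covered by non-overlapping inclusive spans."""
    ordered = sorted(spans, key=lambda s: s.first)
    for a, b in zip(ordered, ordered[1:]):
        if a.overlaps(b):
            raise ValueError(f"overlapping spans {a} and {b}")
    return sum(len(s) for s in ordered)


def span_report(model: FibrilModel) -> "pandas.DataFrame":  # noqa: F821
    """Chain/span table (chain, first, last, n_residues) for `fibril info`."""
    import pandas as pd

    rows = []
    for cid in model.layers:
        for sp in ordered_spans(model, cid):
            rows.append(
                {"chain": cid, "first": sp.first, "last": sp.last, "n_residues": len(sp)}
            )
    return pd.DataFrame(rows, columns=["chain", "first", "last", "n_residues"])
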