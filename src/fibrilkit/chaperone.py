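"""Accessibility of the Ssa1/Sis1 chaperone-binding region.

Fragmentation of Sup35 fibrils by the Hsp104/Ssa1/Sis1 machinery requires
Ssa1/Sis1 binding to residues 143-164 of Sup35.  This module measures,
per polymorph, how far the ordered fibril core is from that site in
sequence (and optionally in 3D), classifies whether the site itself is
ordered, and assembles the tidy strain-landscape table relating
stabilization energy, core-to-site distance and polymorph abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import FibrilModel, ResidueSpan

__all__ = [
    "BindingSite",
    "StrainRecord",
    "DEFAULT_BINDING_SITE",
    "chaperone_sequence_distance",
    "chaperone_3d_distance",
    "site_exposure",
    "strain_landscape_table",
]


@dataclass(frozen=True)
class BindingSite:
    """Chaperone-binding residue span (default 143-164 of Sup35NM)."""

    span: ResidueSpan = field(default_factory=lambda: ResidueSpan(143, 164))
    label: str = "Ssa1/Sis1"


DEFAULT_BINDING_SITE = BindingSite()


@dataclass(frozen=True)
class StrainRecord:
    """One polymorph's coordinates in the structure-phenotype landscape."""

    polymorph: str
    dg_per_chain: float
    core_to_site_distance: int
    polymorph_fraction: float
    handedness: str = "undefined"
    core_spans: tuple = ()
    preparation: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.polymorph_fraction <= 1.0:
            raise ValueError("polymorph_fraction must be within [0, 1]")


def chaperone_sequence_distance(
    core: Sequence[ResidueSpan], site: BindingSite = DEFAULT_BINDING_SITE
) -> int:
    """Sequence gap (residues) between the ordered core and the binding site.

    Zero if any core span overlaps the site; otherwise the minimum number
    of residues strictly between the nearest core boundary and the site
    boundary.  Symmetric in the two span roles.
    """
    if not core:
        raise ValueError("empty core")
    s = site.span
    best = None
    for sp in core:
        if sp.overlaps(s):
            return 0
        gap = s.first - sp.last - 1 if sp.last < s.first else sp.first - s.last - 1
        best = gap if best is None else min(best, gap)
    return int(best)


def chaperone_3d_distance(
    model: FibrilModel, chain: str, site: BindingSite = DEFAULT_BINDING_SITE
) -> float:
    """Minimum heavy-atom distance (A) between site residues and the rest
    of the chain's ordered residues; ``inf`` if the site is not modelled.

    Provided as a complement to the sequence metric; the landscape table
    uses sequence separation.
    """
    atoms = [a for a in model.chain_atoms(chain) if not a.is_hydrogen]
    in_site = [a.coords for a in atoms if a.residue_index in site.span]
    outside = [a.coords for a in atoms if a.residue_index not in site.span]
    if not in_site or not outside:
        return float("inf")
    d, _ = cKDTree(np.array(outside)).query(np.array(in_site))
    return float(np.min(d))


_CONTACT_CUTOFF = 5.0  # A, heavy-atom


def site_exposure(
    model: FibrilModel, site: BindingSite = DEFAULT_BINDING_SITE
) -> str:
    """Classify the chaperone site against the model's ordered residues.

    Returns ``absent_from_model`` when no site residue is modelled,
    ``ordered_overlapping_core`` when modelled site residues contact the
    rest of the core (any heavy-atom pair < 5 A), else ``ordered_adjacent``.
    """
    heavy = [a for a in model.atoms if not a.is_hydrogen]
    in_site = [a.coords for a in heavy if a.residue_index in site.span]
    if not in_site:
        return "absent_from_model"
    outside = [a.coords for a in heavy if a.residue_index not in site.span]
    if outside:
        d, _ = cKDTree(np.array(outside)).query(np.array(in_site))
        if np.min(d) < _CONTACT_CUTOFF:
            return "ordered_overlapping_core"
    return "ordered_adjacent"


def strain_landscape_table(records: Sequence[StrainRecord]) -> pd.DataFrame:
    """Tidy one-row-per-polymorph landscape table, sorted by dG ascending.

    Columns: polymorph, dG_kcal_mol_chain, core_site_gap_res, fraction,
    handedness.  Polymorph fractions within one preparation must sum to
    at most 1.  No phenotype is predicted; these are coordinates only.
    """
    if not records:
        raise ValueError("at least one record required")
    groups: dict[str, float] = {}
    for i, r in enumerate(records):
        key = r.preparation if r.preparation is not None else f"__solo_{i}"
        groups[key] = groups.get(key, 0.0) + r.polymorph_fraction
    for key, total in groups.items():
        if total > 1.0 + 1e-9:
            raise ValueError(
                f"polymorph fractions of preparation {key!r} sum to {total:.3f} > 1"
            )
    rows = [
        {
            "polymorph": r.polymorph,
            "dG_kcal_mol_chain": r.dg_per_chain,
            "core_site_gap_res": r.core_to_site_distance,
            "fraction": r.polymorph_fraction,
            "handedness": r.handedness,
        }
        for r in records
    ]
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["dG_kcal_mol_chain", "polymorph"], kind="stable", ignore_index=True
    )
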