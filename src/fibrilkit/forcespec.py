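"""Worm-like-chain analysis of single-molecule force-extension curves.

A protein tethered between two dsDNA handles in an optical trap is
modelled as worm-like chains in series: the combined handles plus, once
part of the protein has unfolded, an unfolded-polypeptide chain whose
contour length grows by one residue length per unfolded residue.  A
"rip" -- an abrupt force drop with extension gain during stretching --
marks an unfolding event; fitting the branches before and after the rip
with the tether model yields the contour-length gain, which converts to
the number of residues released.

Forces are in pN, lengths in nm, temperatures in K.  The Marko-Siggia
interpolation formula is used throughout:

    F(x) = (kT/P) * [ 1/(4 (1 - x/L)^2) - 1/4 + x/L ]
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BOLTZMANN_PN_NM",
    "WlcParams",
    "TetherModel",
    "ForceExtensionCurve",
    "RipEvent",
    "RipSummary",
    "wlc_force",
    "wlc_extension",
    "tether_extension",
    "detect_rips",
    "contour_length_to_residues",
    "summarize_rips",
    "read_fec",
    "write_fec",
]

#: Boltzmann constant in pN nm / K (k_B = 1.380649e-23 J/K).
BOLTZMANN_PN_NM = 1.380649e-2

#: dsDNA rise per base pair, nm.
DNA_NM_PER_BP = 0.338


@dataclass(frozen=True)
class WlcParams:
    """Worm-like chain: persistence length P, contour length L, temperature."""

    persistence_length: float
    contour_length: float
    temperature: float = 298.0

    def __post_init__(self) -> None:
        if min(self.persistence_length, self.contour_length, self.temperature) <= 0:
            raise ValueError("WLC parameters must be positive")

    @property
    def kT(self) -> float:
        return BOLTZMANN_PN_NM * self.temperature


@dataclass(frozen=True)
class TetherModel:
    """Dual-handle tether: combined dsDNA handles + unfolded protein WLC.

    Defaults model two 2,000 bp handles in series (contour length
    2 * 2000 * 0.338 = 1352 nm, persistence length 45 nm) and an
    unfolded polypeptide with 0.365 nm contour length per residue and
    0.65 nm persistence length.  ``folded_offset`` (nm) is subtracted
    from the total extension; the default 0 means the folded end-to-end
    distance is not corrected for.
    """

    handle: WlcParams = field(
        default_factory=lambda: WlcParams(45.0, 2 * 2000 * DNA_NM_PER_BP, 298.0)
    )
    lc_per_residue: float = 0.365
    protein_persistence: float = 0.65
    folded_offset: float = 0.0

    def protein_wlc(self, n_residues: int) -> WlcParams:
        if n_residues < 1:
            raise ValueError("need at least 1 unfolded residue")
        return WlcParams(
            self.protein_persistence,
            n_residues * self.lc_per_residue,
            self.handle.temperature,
        )


@dataclass
class ForceExtensionCurve:
    """One stretch or relax branch: extension (nm) vs force (pN)."""

    extension: np.ndarray
    force: np.ndarray
    pulling_speed: float = 100.0
    direction: str = "stretch"

    def __post_init__(self) -> None:
        self.extension = np.asarray(self.extension, float)
        self.force = np.asarray(self.force, float)
        if self.extension.shape != self.force.shape or self.extension.ndim != 1:
            raise ValueError("extension and force must be equal-length 1-D arrays")
        if len(self.extension) < 10:
            raise ValueError("curve must have at least 10 samples")
        if self.direction not in ("stretch", "relax"):
            raise ValueError("direction must be 'stretch' or 'relax'")


@dataclass(frozen=True)
class RipEvent:
    """One detected unfolding event."""

    rupture_force: float
    extension_change: float
    delta_contour_length: float
    n_residues: int

    def __post_init__(self) -> None:
        if self.rupture_force <= 0:
            raise ValueError("rupture force must be positive")
        if self.delta_contour_length <= 0:
            raise ValueError("contour-length gain must be positive")
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")


@dataclass(frozen=True)
class RipSummary:
    """Cohort statistics over many stretches (rip sizes, forces, frequency)."""

    fraction_with_rip: float
    histogram: pd.DataFrame  # bin_left, bin_right (residues), fraction of events
    scatter: pd.DataFrame  # stretch_id, rupture_force_pN, n_residues
    n_stretches: int
    n_events: int


# ---------------------------------------------------------------------------
# worm-like chain


def wlc_force(x: float, params: WlcParams) -> float:
    """Marko-Siggia force (pN) at extension ``x`` (nm); diverges as x -> L."""
    L = params.contour_length
    if x < 0:
        raise ValueError("extension must be non-negative")
    if x >= L:
        raise ValueError(f"extension {x} >= contour length {L}: force diverges")
    z = x / L
    return (params.kT / params.persistence_length) * (
        0.25 / (1.0 - z) ** 2 - 0.25 + z
    )


def _ms_fraction(force: np.ndarray, persistence: float, kT: float) -> np.ndarray:
    """Fractional extension z = x/L solving Marko-Siggia for each force.

    Vectorized bisection on z in [0, 1); monotone, so the root is unique.
    80 iterations bound the error by 2^-80.
    """
    f = np.atleast_1d(np.asarray(force, float)) * persistence / kT
    if np.any(f < 0):
        raise ValueError("force must be non-negative")
    lo = np.zeros_like(f)
    hi = np.full_like(f, 1.0 - 1e-15)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        val = 0.25 / (1.0 - mid) ** 2 - 0.25 + mid
        high = val > f
        hi = np.where(high, mid, hi)
        lo = np.where(high, lo, mid)
    return 0.5 * (lo + hi)


def wlc_extension(F: float, params: WlcParams) -> float:
    """Inverse of :func:`wlc_force`: extension (nm) at force ``F`` (pN)."""
    z = _ms_fraction(np.array([F]), params.persistence_length, params.kT)[0]
    return float(z * params.contour_length)


def tether_extension(
    F: float | np.ndarray, tether: TetherModel, n_unfolded_residues: int = 0
) -> float | np.ndarray:
    """Total tether extension at force F: series handle + unfolded protein.

    Series-connected worm-like chains add their extensions at equal
    force; ``folded_offset`` is subtracted.  Accepts scalar or array F.
    """
    farr = np.atleast_1d(np.asarray(F, float))
    kT = tether.handle.kT
    x = (
        _ms_fraction(farr, tether.handle.persistence_length, kT)
        * tether.handle.contour_length
    )
    if n_unfolded_residues > 0:
        p = tether.protein_wlc(n_unfolded_residues)
        x = x + _ms_fraction(farr, p.persistence_length, kT) * p.contour_length
    x = x - tether.folded_offset
    return float(x[0]) if np.isscalar(F) else x


def contour_length_to_residues(delta_lc: float, lc_per_residue: float = 0.365) -> int:
    """Residues released by an unfolding event of contour-length gain delta_lc."""
    if delta_lc < 0:
        raise ValueError("contour-length gain must be non-negative")
    return int(round(delta_lc / lc_per_residue))


# ---------------------------------------------------------------------------
# rip detection


_FIT_WINDOW = 10  # samples per side for the step matched filter
_RUPTURE_FIT_SAMPLES = 30  # pre-drop samples for the rupture-force fit


def _step_heights(f: np.ndarray, m: int = _FIT_WINDOW) -> np.ndarray:
    """Slope-corrected force-step height at every sample.

    ``step[i]`` extrapolates straight-line fits of the ``m`` samples
    ending at ``i`` and starting at ``i+1`` to the midpoint ``i+0.5`` and
    returns their difference, so a rip between samples ``i`` and ``i+1``
    yields its full drop height regardless of the loading slope.  The
    same difference is recomputed with the post window starting one
    sample later and the minimum of the two taken, so a single outlier
    sample cannot mimic a persistent level shift.  Positions too close
    to either end are ``-inf``.
    """
    n = len(f)
    step = np.full(n, -np.inf)
    if n < 2 * m + 2:
        return step
    x = np.arange(m, dtype=float)
    X = np.column_stack([np.ones(m), x])
    proj = np.linalg.inv(X.T @ X) @ X.T  # (2, m)
    w_end = np.array([1.0, m - 0.5]) @ proj  # predict at x = m - 0.5
    w_start = np.array([1.0, -0.5]) @ proj  # predict at x = -0.5
    w_start2 = np.array([1.0, -1.5]) @ proj  # window shifted one sample later
    windows = np.lib.stride_tricks.sliding_window_view(f, m)  # (n-m+1, m)
    pred_end = windows @ w_end  # index j -> window f[j:j+m], prediction past i=j+m-1
    pred_start = windows @ w_start  # index j -> prediction before i=j
    pred_start2 = windows @ w_start2  # index j -> prediction before i=j-1
    i = np.arange(m - 1, n - m - 1)
    step[i] = np.minimum(
        pred_end[i - m + 1] - pred_start[i + 1],
        pred_end[i - m + 1] - pred_start2[i + 2],
    )
    return step


def _handle_compliance(force: np.ndarray, tether: TetherModel) -> np.ndarray:
    """dx/dF (nm/pN) of the handle WLC at each force."""
    kT = tether.handle.kT
    P = tether.handle.persistence_length
    z = _ms_fraction(force, P, kT)
    dFdz = (kT / P) * (0.5 / (1.0 - z) ** 3 + 1.0)
    return tether.handle.contour_length / dFdz


def _fit_protein_lc(
    ext: np.ndarray, force: np.ndarray, tether: TetherModel
) -> float:
    """Closed-form weighted least-squares unfolded contour length of a branch.

    The tether model is linear in the protein contour length Lc:
    x(F) = x_handle(F) + Lc * g(F) - offset, with g the fractional
    extension of the protein WLC, so the optimum is a ratio of sums.
    Samples are inverse-variance weighted: force noise enters the
    extension residual through the handle compliance dx/dF, which grows
    steeply at low force, so low-force samples carry little weight.
    """
    kT = tether.handle.kT
    xh = (
        _ms_fraction(force, tether.handle.persistence_length, kT)
        * tether.handle.contour_length
    )
    g = _ms_fraction(force, tether.protein_persistence, kT)
    w = 1.0 / _handle_compliance(force, tether) ** 2
    resid = ext + tether.folded_offset - xh
    denom = float((w * g) @ g)
    if denom == 0:
        return 0.0
    return max(0.0, float((w * g) @ resid) / denom)


def detect_rips(
    fec: ForceExtensionCurve,
    noise_sigma: float,
    tether: TetherModel | None = None,
) -> list[RipEvent]:
    """Detect unfolding rips in a stretch-direction force-extension curve.

    A rip is a force drop exceeding ``max(4*noise_sigma, 0.5 pN)`` while
    the trap position advances; the drop height at each sample is
    measured with a slope-corrected matched filter over a short window
    on either side (see :func:`_step_heights`).  The rupture force is
    the pre-drop branch extrapolated to the drop; the contour-length
    gain is the difference of the unfolded contour lengths fitted to the
    branches after and before the rip with the tether model.  Events are
    returned ordered by rupture force.
    """
    if fec.direction != "stretch":
        raise ValueError("rip detection operates on stretch-direction curves")
    if np.any(np.diff(fec.extension) < -1e-9):
        raise ValueError("non-monotone trap positions in stretch curve")
    if tether is None:
        tether = TetherModel()
    threshold = max(4.0 * noise_sigma, 0.5)

    f = fec.force
    x = fec.extension
    n = len(f)
    step = _step_heights(f)
    cand = np.flatnonzero(step > threshold)
    if len(cand) == 0:
        return []

    # cluster candidate indices closer than the fit window
    clusters: list[tuple[int, int]] = []
    start = prev = cand[0]
    for c in cand[1:]:
        if c - prev <= _FIT_WINDOW:
            prev = c
            continue
        clusters.append((start, prev))
        start = prev = c
    clusters.append((start, prev))

    # p = last pre-drop sample (step statistic peak) per event
    peaks = [c0 + int(np.argmax(step[c0 : c1 + 1])) for c0, c1 in clusters]

    events: list[RipEvent] = []
    prev_end = 0
    for k, p in enumerate(peaks):
        pre = slice(prev_end, max(prev_end + 2, p))
        nxt = peaks[k + 1] - 1 if k + 1 < len(peaks) else n
        post = slice(min(p + 3, n - 2), nxt)
        lc_pre = _fit_protein_lc(x[pre], f[pre], tether)
        lc_post = _fit_protein_lc(x[post], f[post], tether)
        delta_lc = lc_post - lc_pre

        # rupture force: quadratic fit of the pre-drop samples extrapolated
        # half a sample past the last pre-drop point (the loading curve is
        # gently convex, so a straight line underestimates at the edge)
        i0 = max(prev_end, p - _RUPTURE_FIT_SAMPLES + 1)
        idx = np.arange(i0, p + 1)
        if len(idx) >= 6:
            coef = np.polyfit(idx, f[idx], 2)
            rupture = float(np.polyval(coef, p + 0.5))
        elif len(idx) >= 3:
            coef = np.polyfit(idx, f[idx], 1)
            rupture = float(np.polyval(coef, p + 0.5))
        else:
            rupture = float(f[p])

        n_res = contour_length_to_residues(max(delta_lc, 0.0), tether.lc_per_residue)
        if delta_lc <= 0 or rupture <= 0 or n_res < 1:
            # sub-residue contour gain: not a resolvable unfolding event
            prev_end = min(p + 3, n - 1)
            continue
        kT = tether.handle.kT
        g_rupt = float(
            _ms_fraction(np.array([rupture]), tether.protein_persistence, kT)[0]
        )
        events.append(
            RipEvent(
                rupture_force=rupture,
                extension_change=delta_lc * g_rupt,
                delta_contour_length=delta_lc,
                n_residues=n_res,
            )
        )
        prev_end = min(p + 3, n - 1)
    return sorted(events, key=lambda e: e.rupture_force)


# ---------------------------------------------------------------------------
# cohort summary and I/O


def summarize_rips(
    events_per_stretch: Sequence[Sequence[RipEvent]],
    bin_width: int = 20,
) -> RipSummary:
    """Rip-size histogram, force-vs-size scatter and >=1-rip fraction."""
    if len(events_per_stretch) == 0:
        raise ValueError("at least one stretch required")
    n_stretches = len(events_per_stretch)
    rows = []
    for sid, events in enumerate(events_per_stretch):
        for ev in events:
            rows.append(
                {
                    "stretch_id": sid,
                    "rupture_force_pN": ev.rupture_force,
                    "n_residues": ev.n_residues,
                }
            )
    scatter = pd.DataFrame(
        rows, columns=["stretch_id", "rupture_force_pN", "n_residues"]
    )
    n_events = len(scatter)
    fraction = sum(1 for ev in events_per_stretch if len(ev) > 0) / n_stretches
    if n_events:
        top = int(np.ceil((scatter["n_residues"].max() + 1) / bin_width)) * bin_width
        edges = np.arange(0, top + bin_width, bin_width)
        counts, _ = np.histogram(scatter["n_residues"], bins=edges)
        hist = pd.DataFrame(
            {
                "bin_left": edges[:-1],
                "bin_right": edges[1:],
                "fraction": counts / n_events,
            }
        )
    else:
        hist = pd.DataFrame(columns=["bin_left", "bin_right", "fraction"])
    return RipSummary(
        fraction_with_rip=fraction,
        histogram=hist,
        scatter=scatter,
        n_stretches=n_stretches,
        n_events=n_events,
    )


def read_fec(
    path: str | Path, pulling_speed: float = 100.0, direction: str = "stretch"
) -> ForceExtensionCurve:
    """Read a two-column (extension_nm, force_pN) TSV/CSV curve."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "extension_nm" in cols and "force_pn" in cols:
        ext, force = df["extension_nm"], df["force_pn"]
    elif len(cols) >= 2:
        ext, force = df.iloc[:, 0], df.iloc[:, 1]
    else:
        raise ValueError(f"{path}: expected two columns (extension_nm, force_pN)")
    return ForceExtensionCurve(
        extension=ext.to_numpy(float),
        force=force.to_numpy(float),
        pulling_speed=pulling_speed,
        direction=direction,
    )


def write_fec(fec: ForceExtensionCurve, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"extension_nm": fec.extension, "force_pN": fec.force}
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path
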