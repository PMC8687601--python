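"""Hydration-shell census: water counts by distance class around a probe.

Per frame, the population universe is every water whose oxygen lies within
10 Å of any heavy atom of the probe's indole ring.  Within that universe the
census counts waters within 5 and 7 Å of any protein heavy atom ("surface"),
within 5 Å of the ring itself, and beyond 7 Å of the surface (the outer
hydration layers).  Distances are minimum heavy-atom distances; waters are
represented by their oxygen; hydrogens are ignored throughout.  Counts can be
averaged across symmetry-equivalent monomer sites.

No periodic-boundary handling is applied by default (the geometry of
interest is a closed cavity); an orthorhombic box may be passed for real
trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .scenes import RING_ATOM_NAMES, SyntheticScene

__all__ = ["ShellCensus", "shell_counts", "census_scene", "census_universe",
           "monomer_average", "CLASSES"]

CLASSES = (
    "within_10_of_ring",
    "within_5_of_surface",
    "within_7_of_surface",
    "within_5_of_ring",
    "beyond_7_of_surface",
)

DEFAULT_RING_SELECTION = (
    "resname TRP and name " + " ".join(RING_ATOM_NAMES)
)
DEFAULT_WATER_SELECTION = "resname HOH TIP3 SOL WAT and name O OW OH2"
DEFAULT_PROTEIN_SELECTION = "not resname HOH TIP3 SOL WAT"


@dataclass
class ShellCensus:
    """Per-frame water counts by distance class, optionally site-averaged."""

    frame_times: np.ndarray  # ps
    counts: dict  # class -> (n_frames,) int array, or (n_sites, n_frames)
    monomer_mean: dict = field(default_factory=dict)  # class -> (n_frames,)
    monomer_sd: dict = field(default_factory=dict)
    n_sites: int = 1


def _min_dist(points, ref, box=None):
    if len(points) == 0:
        return np.empty(0)
    if box is not None:
        tree = cKDTree(np.mod(ref, box), boxsize=box)
        d, _ = tree.query(np.mod(points, box))
    else:
        d, _ = cKDTree(ref).query(points)
    return d


def shell_counts(ring_xyz, protein_xyz, water_xyz, box=None,
                 ring_universe: float = 10.0, surface_cuts=(5.0, 7.0),
                 ring_inner: float = 5.0) -> dict:
    """Exact counts for one frame from raw coordinate arrays.

    ``ring_xyz`` must be the probe ring heavy atoms (a subset of
    ``protein_xyz``); ``water_xyz`` the water oxygens.  ``box`` optionally
    enables orthorhombic periodic boundaries.
    """
    if len(ring_xyz) == 0:
        raise ValueError("no probe ring atoms found")
    if len(water_xyz) == 0:
        return {c: 0 for c in CLASSES}
    d_ring = _min_dist(water_xyz, ring_xyz, box)
    d_surf = _min_dist(water_xyz, protein_xyz, box)
    universe = d_ring <= ring_universe
    lo, hi = surface_cuts
    return {
        "within_10_of_ring": int(np.sum(universe)),
        "within_5_of_surface": int(np.sum(universe & (d_surf <= lo))),
        "within_7_of_surface": int(np.sum(universe & (d_surf <= hi))),
        "within_5_of_ring": int(np.sum(universe & (d_ring <= ring_inner))),
        "beyond_7_of_surface": int(np.sum(universe & (d_surf > hi))),
    }


def census_scene(scene: SyntheticScene, frame_time: float = 0.0, **kw) -> ShellCensus:
    """Census of a synthetic scene, one row per monomer site."""
    rows = []
    for m in range(scene.n_monomers):
        ring, prot, wat = scene.monomer(m)
        rows.append(shell_counts(ring, prot, wat, **kw))
    counts = {c: np.array([[row[c]] for row in rows]) for c in CLASSES}
    census = ShellCensus(
        frame_times=np.array([frame_time]), counts=counts,
        n_sites=scene.n_monomers,
    )
    _aggregate(census)
    return census


def census_universe(
    universe,
    probe_selection: str = DEFAULT_RING_SELECTION,
    water_selection: str = DEFAULT_WATER_SELECTION,
    protein_selection: str = DEFAULT_PROTEIN_SELECTION,
    frame_times=None,
    box=None,
    **kw,
) -> ShellCensus:
    """Census over the frames of an MDAnalysis Universe (e.g. multi-model PDB).

    The probe selection may match several symmetry-equivalent tryptophans;
    each distinct residue is treated as one site and averaged over.
    """
    ring = universe.select_atoms(probe_selection)
    if ring.n_atoms == 0:
        raise ValueError(f"probe selection {probe_selection!r} matched no atoms")
    waters = universe.select_atoms(water_selection)
    protein = universe.select_atoms(protein_selection)
    sites = [ring.select_atoms(f"resid {r}") for r in np.unique(ring.resids)]

    n_frames = len(universe.trajectory)
    counts = {c: np.zeros((len(sites), n_frames), dtype=int) for c in CLASSES}
    times = []
    for i, ts in enumerate(universe.trajectory):
        times.append(ts.time if frame_times is None else frame_times[i])
        for s, site in enumerate(sites):
            row = shell_counts(
                site.positions.astype(float),
                protein.positions.astype(float),
                waters.positions.astype(float),
                box=box, **kw,
            )
            for c in CLASSES:
                counts[c][s, i] = row[c]
    census = ShellCensus(
        frame_times=np.asarray(times, dtype=float), counts=counts,
        n_sites=len(sites),
    )
    _aggregate(census)
    return census


def _aggregate(census: ShellCensus):
    for c, arr in census.counts.items():
        arr = np.atleast_2d(arr)
        census.monomer_mean[c] = arr.mean(axis=0)
        census.monomer_sd[c] = (
            arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(arr.shape[1])
        )


def monomer_average(censuses: list) -> ShellCensus:
    """Combine per-site censuses (equal frame grids) into mean and sd per class."""
    if not censuses:
        raise ValueError("need at least one census")
    t0 = censuses[0].frame_times
    for c in censuses[1:]:
        if c.frame_times.shape != t0.shape or not np.allclose(c.frame_times, t0):
            raise ValueError("censuses have mismatched frame grids")
    counts = {
        cls: np.vstack([np.atleast_2d(c.counts[cls]) for c in censuses])
        for cls in CLASSES
    }
    out = ShellCensus(
        frame_times=t0.copy(), counts=counts,
        n_sites=sum(c.n_sites for c in censuses),
    )
    _aggregate(out)
    return out
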