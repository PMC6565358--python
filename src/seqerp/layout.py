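"""Synthetic 62-channel scalp layout (10-10 subset).

Electrode names follow the extended 10-20 convention; 2-D positions are a
schematic top-view projection (rows at fixed anterior-posterior heights,
lateral spread shrinking towards the forehead/occiput) generated
procedurally rather than taken from a digitised cap.  The geometry is
synthetic but preserves the neighbourhood structure the analyses rely on:
Delaunay adjacency, distance-based spatial noise smoothing, and the named
regions of interest (parieto-central CP1/CPz/CP2/P1/Pz/P2 and
fronto-central F1/Fz/F2).
"""
from __future__ import annotations

import numpy as np
from scipy.spatial import Delaunay

__all__ = [
    "standard_62",
    "channel_index",
    "delaunay_adjacency",
    "PARIETO_CENTRAL_ROI",
    "FRONTO_CENTRAL_ROI",
]

# (row height y, [(lateral column, name), ...]); column unit = 1/5 head radius
_ROWS = [
    (0.85, [(-1, "Fp1"), (0, "Fpz"), (1, "Fp2")]),
    (0.68, [(-3, "AF7"), (-1.5, "AF3"), (0, "AFz"), (1.5, "AF4"), (3, "AF8")]),
    (0.50, [(-4, "F7"), (-3, "F5"), (-2, "F3"), (-1, "F1"), (0, "Fz"),
            (1, "F2"), (2, "F4"), (3, "F6"), (4, "F8")]),
    (0.28, [(-5, "FT9"), (-4, "FT7"), (-3, "FC5"), (-2, "FC3"), (-1, "FC1"),
            (1, "FC2"), (2, "FC4"), (3, "FC6"), (4, "FT8"), (5, "FT10")]),
    (0.00, [(-4, "T7"), (-3, "C5"), (-2, "C3"), (-1, "C1"), (0, "Cz"),
            (1, "C2"), (2, "C4"), (3, "C6"), (4, "T8")]),
    (-0.28, [(-4, "TP7"), (-3, "CP5"), (-2, "CP3"), (-1, "CP1"), (0, "CPz"),
             (1, "CP2"), (2, "CP4"), (3, "CP6"), (4, "TP8")]),
    (-0.50, [(-4, "P7"), (-3, "P5"), (-2, "P3"), (-1, "P1"), (0, "Pz"),
             (1, "P2"), (2, "P4"), (3, "P6"), (4, "P8")]),
    (-0.68, [(-3, "PO7"), (-1.5, "PO3"), (0, "POz"), (1.5, "PO4"), (3, "PO8")]),
    (-0.85, [(-1, "O1"), (0, "Oz"), (1, "O2")]),
]

PARIETO_CENTRAL_ROI = ("CP1", "CPz", "CP2", "P1", "Pz", "P2")
FRONTO_CENTRAL_ROI = ("F1", "Fz", "F2")


def standard_62() -> tuple[list[str], np.ndarray]:
    """(names, coords) for the 62-channel layout; coords shape (62, 2)."""
    names: list[str] = []
    coords: list[tuple[float, float]] = []
    for y, row in _ROWS:
        half_width = np.sqrt(max(1.21 - y * y, 0.0))
        for col, name in row:
            names.append(name)
            coords.append((col / 5.0 * half_width, y))
    assert len(names) == 62
    return names, np.asarray(coords, dtype=float)


def channel_index(names: list[str], wanted) -> np.ndarray:
    """Indices of ``wanted`` channel names within ``names``."""
    lookup = {n: i for i, n in enumerate(names)}
    try:
        return np.array([lookup[w] for w in wanted], dtype=int)
    except KeyError as err:
        raise KeyError(f"unknown channel {err.args[0]!r}") from None


def delaunay_adjacency(coords: np.ndarray,
                       prune_factor: float = 1.5) -> np.ndarray:
    """Boolean channel-adjacency matrix from a pruned Delaunay triangulation.

    Edges longer than ``prune_factor`` times the median edge length are
    removed so that the triangulation's long hull chords (e.g. straight
    across the head) do not count as neighbours.
    """
    n = len(coords)
    adj = np.zeros((n, n), dtype=bool)
    tri = Delaunay(coords)
    edges = set()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = sorted((simplex[i], simplex[(i + 1) % 3]))
            edges.add((a, b))
    lengths = {e: float(np.linalg.norm(coords[e[0]] - coords[e[1]]))
               for e in edges}
    cutoff = prune_factor * float(np.median(list(lengths.values())))
    for (a, b), d in lengths.items():
        if d <= cutoff:
            adj[a, b] = adj[b, a] = True
    return adj


def adjacency_dict(names: list[str], adj: np.ndarray) -> dict[str, list[str]]:
    """JSON-serialisable name -> neighbour-name-list view of ``adj``."""
    return {
        names[i]: [names[j] for j in np.flatnonzero(adj[i])]
        for i in range(len(names))
    }
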