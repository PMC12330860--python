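"""Corpus-callosum sectional analysis.

Computes the cross-sectional-area-weighted effective fiber diameter from
a diameter histogram, divides a midsagittal callosal mask tip-to-tip
into four equal-length sections (genu, anterior body, isthmus,
splenium), and summarises R2 per section against effective diameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree
from scipy.stats import pearsonr, spearmanr
from skimage.morphology import skeletonize

__all__ = [
    "SECTION_NAMES",
    "DiameterHistogram",
    "CallosumSectioning",
    "effective_diameter",
    "section_callosum",
    "section_stats",
]

SECTION_NAMES = ("genu", "anterior_body", "isthmus", "splenium")


@dataclass(frozen=True)
class DiameterHistogram:
    """Fiber diameters (um) with their frequencies (counts or proportions)."""

    diameters: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters, dtype=float)
        f = np.asarray(self.frequencies, dtype=float)
        if d.shape != f.shape or d.ndim != 1:
            raise ValueError("diameters and frequencies must be matching 1-D arrays")
        if np.any(d <= 0):
            raise ValueError("diameters must be positive")
        if np.any(f < 0):
            raise ValueError("frequencies must be non-negative")
        if not np.any(f > 0):
            raise ValueError("at least one frequency must be positive")
        object.__setattr__(self, "diameters", d)
        object.__setattr__(self, "frequencies", f)

    @classmethod
    def from_csv(cls, path) -> "DiameterHistogram":
        df = pd.read_csv(path)
        return cls(df["diameter_um"].to_numpy(), df["frequency"].to_numpy())


def effective_diameter(hist: DiameterHistogram) -> float:
    """Area-weighted effective diameter: sum(f d^3) / sum(f d^2) (um).

    A weighted mean of the diameters with weights f*d^2, hence bounded
    by min/max diameter and equivariant under rescaling of d.
    """
    d, f = hist.diameters, hist.frequencies
    return float(np.sum(f * d**3) / np.sum(f * d**2))


@dataclass
class CallosumSectioning:
    """Section label per mask voxel; -1 outside the mask.

    Sections are ordered anterior -> posterior along the medial curve:
    0 genu, 1 anterior body, 2 isthmus, 3 splenium.
    """

    section_map: np.ndarray
    arc_coordinate: np.ndarray  # medial arc coordinate per voxel (NaN outside)
    section_names: tuple = SECTION_NAMES

    def voxels(self, section: int | str) -> np.ndarray:
        if isinstance(section, str):
            section = self.section_names.index(section)
        return np.argwhere(self.section_map == section)


def _mask_graph(coords: np.ndarray):
    """Sparse 8/26-connected graph over voxel coordinates, Euclidean weights."""
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=np.sqrt(coords.shape[1]) + 1e-9, output_type="ndarray")
    w = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    n = len(coords)
    g = coo_matrix(
        (np.r_[w, w], (np.r_[pairs[:, 0], pairs[:, 1]], np.r_[pairs[:, 1], pairs[:, 0]])),
        shape=(n, n),
    )
    return g.tocsr()


def _medial_path(mask2d: np.ndarray) -> np.ndarray:
    """Ordered (row, col) pixels of the longest skeleton path (tip to tip)."""
    skel = skeletonize(mask2d)
    coords = np.argwhere(skel)
    if len(coords) < 2:
        raise ValueError("mask is degenerate (skeleton shorter than 2 pixels)")
    g = _mask_graph(coords)
    n_comp, comp = connected_components(g, directed=False)
    if n_comp > 1:
        # keep the largest skeleton component (spurs from small islands
        # are rejected earlier by the mask connectivity check)
        main = np.bincount(comp).argmax()
        coords = coords[comp == main]
        g = _mask_graph(coords)
    deg = np.diff(g.indptr)
    endpoints = np.flatnonzero(deg == 1)
    if endpoints.size < 2:
        endpoints = np.arange(len(coords))  # loop-like skeleton: search all
    dist, pred = dijkstra(g, indices=endpoints, return_predecessors=True)
    finite = np.where(np.isfinite(dist), dist, -1.0)
    i, j = np.unravel_index(np.argmax(finite), finite.shape)
    path = [j]
    while pred[i, path[-1]] >= 0:
        path.append(pred[i, path[-1]])
    return coords[np.array(path[::-1])]


def section_callosum(
    mask: np.ndarray, mode: str = "arc", anterior_axis: int = 0
) -> CallosumSectioning:
    """Divide a callosal mask tip-to-tip into four equal-length sections.

    ``mode='arc'`` (default) measures length along the medial (skeleton)
    curve: every voxel gets an arc coordinate by projecting onto the
    curve, and the coordinate range is cut into four equal parts.
    ``mode='extent'`` instead cuts the anterior-posterior bounding
    extent into four equal parts.  ``anterior_axis`` is the axis of the
    mask array pointing anterior -> posterior (2-D masks) — for 3-D
    masks the left-right axis is assumed to be axis 0 and sections are
    computed on the sagittal projection.

    The mask must be a single connected component.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if mask.ndim == 3:
        mask2d = mask.any(axis=0)
    elif mask.ndim == 2:
        mask2d = mask
    else:
        raise ValueError("mask must be 2-D or 3-D")

    coords_all = np.argwhere(mask2d)
    g_all = _mask_graph(coords_all)
    n_comp, _ = connected_components(g_all, directed=False)
    if n_comp > 1:
        raise ValueError("mask must be a single connected component")

    if mode == "extent":
        coord = coords_all[:, anterior_axis].astype(float)
    elif mode == "arc":
        path = _medial_path(mask2d).astype(float)
        seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        # orient the path anterior -> posterior
        if path[0, anterior_axis] > path[-1, anterior_axis]:
            path, arc = path[::-1], arc[-1] - arc[::-1]
        tangents = np.gradient(path, arc, axis=0) if len(path) > 2 else np.diff(
            path, axis=0
        ).repeat(2, axis=0)
        tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
        tree = cKDTree(path)
        _, nearest = tree.query(coords_all.astype(float))
        resid = coords_all - path[nearest]
        coord = arc[nearest] + np.einsum("ij,ij->i", resid, tangents[nearest])
    else:
        raise ValueError("mode must be 'arc' or 'extent'")

    lo, hi = coord.min(), coord.max()
    if hi <= lo:
        raise ValueError("mask is degenerate along the sectioning direction")
    frac = (coord - lo) / (hi - lo)
    sec = np.minimum((frac * 4).astype(int), 3)

    sec2d = np.full(mask2d.shape, -1, dtype=np.int8)
    arc2d = np.full(mask2d.shape, np.nan)
    sec2d[tuple(coords_all.T)] = sec
    arc2d[tuple(coords_all.T)] = coord
    if mask.ndim == 3:
        sec_map = np.where(mask, sec2d[None, ...], -1).astype(np.int8)
        arc_map = np.where(mask, arc2d[None, ...], np.nan)
    else:
        sec_map, arc_map = sec2d, arc2d
    return CallosumSectioning(section_map=sec_map, arc_coordinate=arc_map)


def section_stats(
    R2_map: np.ndarray,
    sectioning: CallosumSectioning,
    d_eff: dict | None = None,
    slices: slice | np.ndarray | None = None,
    axis: int = 0,
) -> dict:
    """Per-section R2 mean/SD and (optionally) association with d_eff.

    ``slices`` restricts a 3-D map to selected sagittal indices (e.g. the
    central 3 slices); ``d_eff`` maps section names to effective
    diameters.  Association (Pearson and Spearman of section means vs
    d_eff) is reported when d_eff is given; if the section means have
    zero variance the association is undefined and flagged.
    """
    sec_map = sectioning.section_map
    if R2_map.shape != sec_map.shape:
        raise ValueError("R2 map and sectioning shapes differ")
    if slices is not None and R2_map.ndim == 3:
        sl = [slice(None)] * 3
        sl[axis] = slices
        R2_map = R2_map[tuple(sl)]
        sec_map = sec_map[tuple(sl)]
    per_section = []
    for idx, name in enumerate(SECTION_NAMES):
        vals = R2_map[sec_map == idx]
        vals = vals[np.isfinite(vals)]
        per_section.append(
            {
                "section": name,
                "n_voxels": int(vals.size),
                "R2_mean": float(vals.mean()) if vals.size else np.nan,
                "R2_sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                "d_eff_um": float(d_eff[name]) if d_eff else np.nan,
            }
        )
    out = {"sections": per_section}
    if d_eff is not None:
        means = np.array([s["R2_mean"] for s in per_section])
        deffs = np.array([s["d_eff_um"] for s in per_section])
        if np.ptp(means) == 0 or np.ptp(deffs) == 0:
            out["association"] = {
                "defined": False,
                "reason": "zero variance in section means or d_eff",
            }
        else:
            pr, pp = pearsonr(means, deffs)
            sr, sp = spearmanr(means, deffs)
            out["association"] = {
                "defined": True,
                "pearson_r": float(pr),
                "pearson_p": float(pp),
                "spearman_rho": float(sr),
                "spearman_p": float(sp),
            }
    return out
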