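"""Per-frame cell segmentation and feature extraction.

Two interchangeable backends satisfy the same contract (a callable mapping a
brightfield :class:`~eventscope.devices.Frame` to a label map):

* the default *classical* pipeline — background estimation, darkness
  threshold on the cell-wall rings, hole filling, distance-transform
  watershed and a size filter — which segments ring-rendered yeast;
* an *oracle* backend that reads the simulator's ground-truth masks, used to
  exercise the scenario engine's trigger/tracking semantics independently of
  pixel-classification error.

Feature extraction produces one record per labelled region: area, centroid,
per-channel mean intensities and a bud-candidate flag from the size filter
(buds are identified as regions smaller than a fraction of the median region
area, and linked to the nearest larger region).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import regionprops
from skimage.morphology import disk
from skimage.segmentation import watershed

from .devices import BUD_LABEL_BASE, Frame


@dataclass(frozen=True)
class SegParams:
    background_sigma_px: float = 25.0
    smooth_sigma_px: float = 1.5
    close_radius_px: int = 2
    ring_contrast_frac: float = 0.12   # wall pixels darker than (1-frac)*background
    min_area_px: int = 60
    max_area_px: int = 5000
    min_marker_px: int = 10
    min_marker_inradius_px: float = 2.8
    max_marker_compactness: float = 1.65   # area / (pi * inradius^2); pockets are slivers
    marker_merge_dist_px: float = 8.0
    interior_contrast_frac: float = 0.045  # interiors are slightly shaded vs background
    bud_max_frac: float = 0.4      # region is a bud candidate below this x median area


@dataclass
class RegionFeatures:
    label: int
    area_px: float
    centroid: tuple                # (row, col) px
    mean_intensity: dict = field(default_factory=dict)  # channel -> mean
    is_bud_candidate: bool = False
    mother_label: Optional[int] = None


def segment_cells(frame: Frame, params: Optional[SegParams] = None) -> np.ndarray:
    """Rule-based brightfield segmentation returning a label map.

    Cells are rendered as dark boundary rings on a bright background, so the
    edge magnitude of the flattened image traces every cell outline; filling
    the closed outlines gives cell bodies, which a distance-transform
    watershed splits where cells touch.
    """
    if frame.channel != "brightfield":
        raise ValueError("the classical backend segments brightfield frames")
    p = params or SegParams()
    img = frame.pixels.astype(float)
    sm = ndi.gaussian_filter(img, sigma=p.smooth_sigma_px)
    background = float(np.median(ndi.gaussian_filter(img, sigma=p.background_sigma_px)))
    if background <= 0:
        return np.zeros_like(frame.pixels, dtype=np.int32)
    # cell walls are dark rings; threshold darkness relative to background
    mask = sm < background * (1.0 - p.ring_contrast_frac)
    if not mask.any():
        return np.zeros_like(frame.pixels, dtype=np.int32)
    # dilate so thin wall bands are watertight for hole filling, then erode
    grown = ndi.binary_dilation(mask, structure=disk(p.close_radius_px))
    filled = ndi.binary_fill_holes(grown)
    filled = ndi.binary_erosion(filled, structure=disk(p.close_radius_px),
                                border_value=1)
    if not filled.any():
        return np.zeros_like(frame.pixels, dtype=np.int32)
    # every cell wall is a double-ring boundary, so the enclosed interiors
    # are disconnected even where cells touch: they seed the watershed
    # (computed against the un-closed edge band, which is thinner).
    # Pockets enclosed between neighbouring rings are rejected by their
    # inscribed radius: a real interior is a disk, a pocket is a sliver.
    interiors, n_int = ndi.label(filled & ~mask)
    if n_int:
        idx = np.arange(1, n_int + 1)
        sizes = ndi.sum_labels(np.ones_like(interiors), interiors, index=idx)
        inradius = ndi.maximum(ndi.distance_transform_edt(~mask), interiors,
                               index=idx)
        compact = sizes / np.maximum(np.pi * inradius**2, 1e-9)
        # pockets of enclosed background are at background brightness,
        # cell bodies are shaded: require a darkened marker interior
        mean_int = ndi.mean(sm, interiors, index=idx)
        bad = ((sizes < p.min_marker_px)
               | (inradius < p.min_marker_inradius_px)
               | (compact > p.max_marker_compactness)
               | (mean_int > background * (1.0 - p.interior_contrast_frac)))
        kill = np.concatenate([[False], bad])
        interiors[kill[interiors]] = 0
    if interiors.max() == 0:
        return np.zeros_like(frame.pixels, dtype=np.int32)
    # a neighbour's wall crossing a cell can split its interior in two;
    # markers closer than a cell radius belong to the same cell
    labs = np.unique(interiors)
    labs = labs[labs > 0]
    if len(labs) > 1:
        coms = np.array(ndi.center_of_mass(interiors > 0, interiors, labs))
        parent = {int(l): int(l) for l in labs}

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i in range(len(labs)):
            for j in range(i + 1, len(labs)):
                if np.hypot(*(coms[i] - coms[j])) < p.marker_merge_dist_px:
                    parent[find(int(labs[i]))] = find(int(labs[j]))
        remap = np.zeros(int(labs.max()) + 1, dtype=np.int32)
        for l in labs:
            remap[int(l)] = find(int(l))
        interiors = remap[interiors]
    dist = ndi.distance_transform_edt(filled)
    labels = watershed(-dist, interiors, mask=filled)
    # size filter + sequential relabel
    out = np.zeros_like(labels, dtype=np.int32)
    nxt = 1
    for r in regionprops(labels):
        if p.min_area_px <= r.area <= p.max_area_px:
            out[labels == r.label] = nxt
            nxt += 1
    return out


def oracle_backend(microscope, label_buds: bool = False):
    """Segmentation backend reading the simulator's ground-truth masks.

    Labels are the ground-truth cell ids (bud regions get
    ``BUD_LABEL_BASE + mother_id`` when ``label_buds``), so region identity
    is directly comparable with the lineage.
    """
    def run(frame: Frame) -> np.ndarray:
        return microscope.render_labels(label_buds=label_buds)
    return run


def count_cells(labels: np.ndarray) -> int:
    """Number of distinct nonzero labels in a label map."""
    u = np.unique(labels)
    return int((u > 0).sum())


def extract_features(labels: np.ndarray, frames: dict,
                     bud_max_frac: float = 0.4,
                     size_flag_buds: bool = True) -> list:
    """One :class:`RegionFeatures` per label with per-channel mean intensities.

    ``frames`` maps channel name to :class:`Frame` (all the same shape).
    Bud candidates are flagged by the size filter (area below
    ``bud_max_frac`` x the median region area) and linked to the nearest
    larger region.  ``size_flag_buds=False`` disables the size heuristic,
    for label maps whose regions are known to be whole cells (ground-truth
    masks with buds merged into their mothers).
    """
    for f in frames.values():
        if f.pixels.shape != labels.shape:
            raise ValueError("frame shape does not match label map")
    props = regionprops(labels.astype(np.int64))
    if not props:
        return []
    areas = np.array([r.area for r in props], dtype=float)
    med = float(np.median(areas))
    feats = []
    for r in props:
        means = {}
        sl = r.slice
        m = labels[sl] == r.label
        for chname, f in frames.items():
            means[chname] = float(f.pixels[sl][m].mean())
        feats.append(RegionFeatures(
            label=int(r.label), area_px=float(r.area),
            centroid=(float(r.centroid[0]), float(r.centroid[1])),
            mean_intensity=means,
            is_bud_candidate=bool((size_flag_buds
                                   and r.area < bud_max_frac * med)
                                  or r.label >= BUD_LABEL_BASE),
        ))
    # bud -> mother linkage: the adjacent larger region with the longest
    # shared boundary (the neck contact), falling back to nearest centroid
    bigs = [f for f in feats if not f.is_bud_candidate]
    big_labels = {f.label for f in bigs}
    struct = np.ones((3, 3), bool)
    for f in feats:
        if not f.is_bud_candidate or not bigs:
            continue
        if f.label >= BUD_LABEL_BASE and (f.label - BUD_LABEL_BASE) in big_labels:
            # ground-truth mask labels carry the mother id directly
            f.mother_label = f.label - BUD_LABEL_BASE
            continue
        mask = labels == f.label
        sl = ndi.find_objects(mask.astype(np.int8))[0]
        sl = tuple(slice(max(s.start - 2, 0), s.stop + 2) for s in sl)
        ring = ndi.binary_dilation(mask[sl], structure=struct) & ~mask[sl]
        touching = labels[sl][ring]
        touching = touching[np.isin(touching, list(big_labels))]
        if touching.size:
            vals, counts = np.unique(touching, return_counts=True)
            f.mother_label = int(vals[np.argmax(counts)])
        else:
            d = [np.hypot(f.centroid[0] - b.centroid[0],
                          f.centroid[1] - b.centroid[1]) for b in bigs]
            f.mother_label = bigs[int(np.argmin(d))].label
    return feats


def nuclear_localization_score(cell_mask: np.ndarray, nucleus_mask: np.ndarray,
                               gfp_pixels: np.ndarray) -> float:
    """Mean GFP in the nucleus normalised to the mean GFP over the cell.

    Invariant to affine rescaling of the GFP frame with zero offset.
    """
    cell_mask = np.asarray(cell_mask, bool)
    nucleus_mask = np.asarray(nucleus_mask, bool)
    if not cell_mask.any() or not nucleus_mask.any():
        raise ValueError("masks must be non-empty")
    if (nucleus_mask & ~cell_mask).any():
        raise ValueError("nucleus mask must lie inside the cell mask")
    gfp = np.asarray(gfp_pixels, float)
    cell_mean = gfp[cell_mask].mean()
    if cell_mean == 0:
        return float("nan")
    return float(gfp[nucleus_mask].mean() / cell_mean)


def top_quartile_nucleus_mask(cell_mask: np.ndarray,
                              gfp_pixels: np.ndarray) -> np.ndarray:
    """Default nucleus proxy when no nuclear channel exists: the brightest
    quartile of GFP pixels within the cell."""
    cell_mask = np.asarray(cell_mask, bool)
    vals = np.asarray(gfp_pixels, float)[cell_mask]
    k = max(1, int(round(0.25 * vals.size)))
    top = np.argsort(vals)[-k:]          # rank-based: exactly the top quartile
    inner = np.zeros(vals.size, bool)
    inner[top] = True
    out = np.zeros_like(cell_mask)
    out[cell_mask] = inner
    return out
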