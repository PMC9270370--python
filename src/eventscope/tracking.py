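"""Frame-to-frame cell tracking and stage-feedback recentering.

Tracking follows the two-stage scheme used in closed-loop microscopes: a
global translation estimate between consecutive frames by cross-correlation,
then greedy nearest-centroid assignment of segmented regions after applying
that translation.  The recentering command converts the tracked centroid's
offset from the image centre into a stage move (full proportional
correction, gain 1) under the convention that stage +x shifts image content
by -x.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .devices import CameraConfig, image_center_px


def register_translation(frame_a: np.ndarray, frame_b: np.ndarray):
    """Integer-pixel displacement of ``frame_b`` relative to ``frame_a``.

    Returns ``((dy, dx), degenerate)`` where ``frame_b ~ frame_a`` shifted by
    ``(dy, dx)`` (circular).  The estimate is the argmax of the normalised
    circular cross-correlation (FFT-based, constant denominator, zero-mean);
    a constant frame has no correlation structure and yields (0, 0) with the
    degenerate flag set.
    """
    a = np.asarray(frame_a, float)
    b = np.asarray(frame_b, float)
    if a.shape != b.shape:
        raise ValueError("frames must share a shape")
    a = a - a.mean()
    b = b - b.mean()
    if not a.any() or not b.any():
        return (0, 0), True
    corr = np.fft.ifft2(np.fft.fft2(b) * np.conj(np.fft.fft2(a))).real
    dy, dx = np.unravel_index(np.argmax(corr), corr.shape)
    h, w = corr.shape
    if dy > h // 2:
        dy -= h
    if dx > w // 2:
        dx -= w
    return (int(dy), int(dx)), False


def match_regions(prev, curr, displacement=(0, 0), gate_px: Optional[float] = None):
    """Greedy nearest-centroid assignment between two region lists.

    Previous centroids are first translated by ``displacement`` (dy, dx);
    candidate pairs within ``gate_px`` are matched in order of ascending
    distance, ties broken by smaller area difference.  Returns a dict
    ``prev_label -> curr_label``; unmatched current regions start new tracks
    and unmatched previous regions end theirs (decided by the caller).

    The default gate is the median equivalent radius of the current regions.
    """
    if gate_px is None:
        if curr:
            med_area = float(np.median([f.area_px for f in curr]))
            gate_px = max(np.sqrt(med_area / np.pi), 1.0)
        else:
            gate_px = 1.0
    dy, dx = displacement
    pairs = []
    for f0 in prev:
        p = (f0.centroid[0] + dy, f0.centroid[1] + dx)
        for f1 in curr:
            d = np.hypot(p[0] - f1.centroid[0], p[1] - f1.centroid[1])
            if d <= gate_px:
                pairs.append((d, abs(f0.area_px - f1.area_px), f0.label, f1.label))
    pairs.sort()
    assigned = {}
    used = set()
    for d, _, l0, l1 in pairs:
        if l0 in assigned or l1 in used:
            continue
        assigned[l0] = l1
        used.add(l1)
    return assigned


def recentering_command(centroid_px, camera: CameraConfig):
    """Stage move (dx_um, dy_um) that brings ``centroid_px`` to the image centre.

    Stage +x shifts image content -x, so the correction equals the pixel
    offset times the pixel size (gain 1).
    """
    cy, cx = image_center_px(camera)
    row, col = centroid_px
    return ((col - cx) * camera.pixel_size_um,
            (row - cy) * camera.pixel_size_um)


@dataclass
class Track:
    """History of one followed cell: (t_sim, label, centroid_px, area_px)."""
    track_id: int
    history: list = field(default_factory=list)
    active: bool = True

    def append(self, t_sim: float, label: int, centroid, area_px: float):
        if self.history and t_sim <= self.history[-1][0]:
            raise ValueError("track history must be strictly time-ordered")
        self.history.append((float(t_sim), int(label), (float(centroid[0]),
                             float(centroid[1])), float(area_px)))

    @property
    def last(self):
        return self.history[-1]


class CellTracker:
    """Follows a single region across frames using correlation + proximity."""

    def __init__(self, camera: CameraConfig, gate_px: Optional[float] = None):
        self.camera = camera
        self.gate_px = gate_px
        self.track: Optional[Track] = None
        self._prev_pixels = None
        self._prev_feats = None
        self._prev_stage = None

    def start(self, t_sim, label, feats, pixels, stage_xy):
        feat = next(f for f in feats if f.label == label)
        self.track = Track(track_id=1)
        self.track.append(t_sim, label, feat.centroid, feat.area_px)
        self._prev_pixels = pixels
        self._prev_feats = feats
        self._prev_stage = stage_xy
        return self.track

    def update(self, t_sim, feats, pixels, stage_xy):
        """Advance the track by one frame; returns the matched feature or None.

        If the stage moved between frames the induced image shift is known
        exactly (-delta_stage / pixel_size) and is composed with the
        image-measured residual displacement.
        """
        if self.track is None or not self.track.active:
            return None
        sdx = (stage_xy[0] - self._prev_stage[0]) / self.camera.pixel_size_um
        sdy = (stage_xy[1] - self._prev_stage[1]) / self.camera.pixel_size_um
        (dy, dx), _ = register_translation(self._prev_pixels, pixels)
        last_label = self.track.last[1]
        assigned = match_regions(self._prev_feats, feats, (dy, dx),
                                 gate_px=self.gate_px)
        new_label = assigned.get(last_label)
        if new_label is None:
            # fall back to the predicted position under the known stage shift
            pred = (self.track.last[2][0] - sdy, self.track.last[2][1] - sdx)
            cands = [(np.hypot(f.centroid[0] - pred[0], f.centroid[1] - pred[1]), f)
                     for f in feats]
            cands.sort(key=lambda t: t[0])
            if cands and cands[0][0] <= (self.gate_px or 12):
                new_label = cands[0][1].label
        if new_label is None:
            self.track.active = False
            return None
        feat = next(f for f in feats if f.label == new_label)
        self.track.append(t_sim, new_label, feat.centroid, feat.area_px)
        self._prev_pixels = pixels
        self._prev_feats = feats
        self._prev_stage = stage_xy
        return feat

    def recenter_command(self):
        """Stage correction for the current track position, or None."""
        if self.track is None or not self.track.active:
            return None
        return recentering_command(self.track.last[2], self.camera)
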