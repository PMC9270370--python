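"""Contract-compatible virtual microscope devices backed by the sample model.

:class:`VirtualMicroscope` bundles the camera, X-Y-Z stage, illumination,
electrofluidic valve bank, autofocus and the simulated clock into the device
surface the scenario engine drives.  Rendering projects the agent-based
colony into 16-bit frames: brightfield draws a dark ring at each cell
boundary on a bright background; fluorescence channels draw the reporter
distributions (nuclear RFP, Hog1-partitioned GFP, uniform Venus/YFP), scaled
linearly by exposure x LED intensity, followed by PSF blur, optional Poisson
shot noise and Gaussian read noise from a seeded generator.

Axis convention: image origin top-left, row index = y, column index = x,
pixel centres at half-integer multiples of the pixel size; moving the stage
by +dx um shifts image content by -dx/pixel_size px.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage as ndi

from .sample import (SampleState, accumulate_photodose, advance, set_medium)

CHANNELS = ("brightfield", "GFP", "RFP", "YFP", "blue_stim")
_FLUOR = ("GFP", "RFP", "YFP")
BUD_LABEL_BASE = 1_000_000  # oracle-mask label offset for bud regions


@dataclass(frozen=True)
class ChannelSettings:
    channel: str
    exposure_ms: float = 150.0
    led_intensity_pct: float = 100.0

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if not self.exposure_ms > 0:
            raise ValueError("exposure_ms must be > 0")
        if not 0.0 <= self.led_intensity_pct <= 100.0:
            raise ValueError("led_intensity_pct must be in [0, 100]")


@dataclass
class StagePose:
    x: float = 0.0
    y: float = 0.0
    z: float = 0.0


@dataclass(frozen=True)
class CameraConfig:
    width: int = 512
    height: int = 512
    pixel_size_um: float = 0.25
    psf_sigma_px: float = 1.0
    defocus_zc_um: float = 1.0     # defocus |z| scales blur by (1 + |z|/zc)
    bf_background: float = 1000.0
    bf_ref_exposure_ms: float = 50.0
    ring_depth: float = 0.45       # fractional darkening of the boundary ring
    interior_depth: float = 0.07   # fractional darkening of the cell body
    ring_width_um: float = 0.75
    fluor_background: float = 100.0
    fluor_ref: float = 150.0 * 100.0  # exposure_ms * led_pct giving unit gain
    read_noise_sd: float = 3.0
    shot_noise: bool = True


@dataclass
class Frame:
    pixels: np.ndarray             # uint16 (H, W)
    channel_settings: ChannelSettings
    stage: StagePose
    t_sim: float
    position_id: int = 0
    autofocus_used: bool = False

    @property
    def channel(self) -> str:
        return self.channel_settings.channel


@dataclass
class ValveBank:
    states: list
    switch_log: list = field(default_factory=list)  # (t_sim, index, new_state)

    def set(self, index: int, state: bool, t_sim: float) -> bool:
        """Set a valve; re-asserting the current state is not logged."""
        if self.states[index] == bool(state):
            return False
        self.states[index] = bool(state)
        self.switch_log.append((t_sim, index, bool(state)))
        return True


@dataclass
class ValveRoute:
    """Maps a valve index onto a chamber's perfused medium."""
    index: int
    chamber: int
    on_medium: str = "sucrose"
    off_medium: str = "glucose"


class VirtualMicroscope:
    """Camera + stage + valves + autofocus + clock over one or more chambers.

    ``chambers`` is a list of :class:`SampleState`; multiple entries model a
    chip with several independent chambers at different stage coordinates.
    Valve switches are logged immediately but take effect on the sample at
    the next clock advance (no dead volume beyond one step is modelled).
    """

    def __init__(
        self,
        chambers,
        camera: Optional[CameraConfig] = None,
        noise_seed: int = 0,
        valve_routes=(),
        n_valves: int = 4,
        z_travel_um: float = 100.0,
        xy_travel_um: float = 1e5,
        z_tol_um: float = 0.2,
    ):
        if isinstance(chambers, SampleState):
            chambers = [chambers]
        self.chambers = list(chambers)
        self.camera = camera or CameraConfig()
        self.noise_rng = np.random.default_rng(noise_seed)
        self.pose = StagePose()
        self.valve_routes = {r.index: r for r in valve_routes}
        n_valves = max([n_valves] + [r.index + 1 for r in valve_routes])
        self.valves = ValveBank(states=[False] * n_valves)
        self._pending_media: dict = {}
        self.z_travel_um = z_travel_um
        self.xy_travel_um = xy_travel_um
        self.z_tol_um = z_tol_um

    # -- clock ----------------------------------------------------------
    @property
    def t_sim(self) -> float:
        return self.chambers[0].environment.time

    def advance_to(self, t: float) -> None:
        dt = t - self.t_sim
        if dt < -1e-9:
            raise ValueError("simulated clock cannot move backwards")
        for idx, medium in self._pending_media.items():
            set_medium(self.chambers[idx], medium)
        self._pending_media.clear()
        if dt > 0:
            for ch in self.chambers:
                advance(ch, dt)

    # -- stage and valves ----------------------------------------------
    def move_stage(self, pose: StagePose) -> StagePose:
        if abs(pose.z) > self.z_travel_um or max(abs(pose.x), abs(pose.y)) > self.xy_travel_um:
            raise ValueError("stage target outside travel range")
        self.pose = StagePose(pose.x, pose.y, pose.z)
        return self.pose

    def set_valve(self, index: int, state: bool) -> ValveBank:
        changed = self.valves.set(index, state, self.t_sim)
        if changed and index in self.valve_routes:
            r = self.valve_routes[index]
            self._pending_media[r.chamber] = r.on_medium if state else r.off_medium
        return self.valves

    # -- optics ---------------------------------------------------------
    def fov_rect(self):
        cam = self.camera
        hw = cam.width * cam.pixel_size_um / 2.0
        hh = cam.height * cam.pixel_size_um / 2.0
        return (self.pose.x - hw, self.pose.y - hh, self.pose.x + hw, self.pose.y + hh)

    def _to_px(self, xy) -> tuple:
        """World um -> (row, col) in pixel-index coordinates."""
        cam = self.camera
        fx, fy = self.fov_rect()[:2]
        col = (xy[0] - fx) / cam.pixel_size_um - 0.5
        row = (xy[1] - fy) / cam.pixel_size_um - 0.5
        return row, col

    def _visible_cells(self, margin_um: float = 6.0):
        x0, y0, x1, y1 = self.fov_rect()
        for ch in self.chambers:
            for c in ch.cells:
                x, y = c.centroid
                if (x0 - margin_um <= x <= x1 + margin_um
                        and y0 - margin_um <= y <= y1 + margin_um):
                    yield ch, c

    def _disk(self, img, center_um, radius_um, op):
        """Apply ``op(sub, mask, d_px)`` on the bounding box of a disk."""
        cam = self.camera
        row, col = self._to_px(center_um)
        r_px = radius_um / cam.pixel_size_um
        r0 = max(0, int(math.floor(row - r_px - 2)))
        r1 = min(cam.height, int(math.ceil(row + r_px + 3)))
        c0 = max(0, int(math.floor(col - r_px - 2)))
        c1 = min(cam.width, int(math.ceil(col + r_px + 3)))
        if r0 >= r1 or c0 >= c1:
            return
        rr, cc = np.mgrid[r0:r1, c0:c1]
        d = np.hypot(rr - row, cc - col)
        op(img[r0:r1, c0:c1], d, r_px)

    def render(self, settings: ChannelSettings, noise: Optional[bool] = None,
               rng: Optional[np.random.Generator] = None) -> np.ndarray:
        """Render the current scene; returns float64 counts (H, W).

        ``noise=False`` yields the deterministic pre-noise image (exactly
        linear in exposure x intensity for fluorescence channels).
        """
        cam = self.camera
        ch = settings.channel
        if ch == "brightfield":
            img = np.full((cam.height, cam.width),
                          cam.bf_background * settings.exposure_ms / cam.bf_ref_exposure_ms)
            ring_w = cam.ring_width_um / cam.pixel_size_um

            def body(sub, d, r_px):
                sub[d <= r_px] *= (1.0 - cam.interior_depth)

            def ring(sub, d, r_px):
                sub[np.abs(d - r_px) <= ring_w / 2.0] *= (1.0 - cam.ring_depth)

            for _, c in self._visible_cells():
                self._disk(img, c.centroid, c.radius, body)
                if c.bud_area > 0:
                    self._disk(img, c.bud_center(), c.bud_radius, body)
            for _, c in self._visible_cells():
                self._disk(img, c.centroid, c.radius, ring)
                if c.bud_area > 0:
                    self._disk(img, c.bud_center(), c.bud_radius, ring)
        else:
            img = np.full((cam.height, cam.width), cam.fluor_background)
            gain = settings.exposure_ms * settings.led_intensity_pct / cam.fluor_ref
            if ch in _FLUOR and gain > 0:
                px_area = cam.pixel_size_um**2
                for chamber, c in self._visible_cells():
                    p = chamber.params
                    r_nuc = p.nucleus_radius_frac * c.radius
                    a_cell = c.area / px_area
                    a_nuc = math.pi * r_nuc**2 / px_area

                    def add(val, center, radius):
                        def op(sub, d, r_px):
                            sub[d <= r_px] += val
                        self._disk(img, center, radius, op)

                    if ch == "GFP" and c.gfp_total_level > 0:
                        frac = c.hog1_nuclear_fraction
                        cyto = (1 - frac) * c.gfp_total_level / max(a_cell - a_nuc, 1.0)
                        nuc = frac * c.gfp_total_level / max(a_nuc, 1.0)
                        add(cyto * gain, c.centroid, c.radius)
                        if c.bud_area > 0:
                            add(cyto * gain, c.bud_center(), c.bud_radius)
                        add((nuc - cyto) * gain, c.centroid, r_nuc)
                    elif ch == "RFP" and c.rfp_tagged:
                        sep = (c.bud_area > 0
                               and c.bud_area >= chamber.params.sep_bud_frac * c.area)
                        add(c.rfp_nuclear_level * gain, c.centroid, r_nuc)
                        if sep:
                            add(c.rfp_nuclear_level * gain, c.bud_center(),
                                p.nucleus_radius_frac * c.bud_radius)
                    elif ch == "YFP" and c.venus_level > 0:
                        add(c.venus_level * gain, c.centroid, c.radius)
                        if c.bud_area > 0:
                            add(c.venus_level * gain, c.bud_center(), c.bud_radius)
        sigma = cam.psf_sigma_px * (1.0 + abs(self.pose.z) / cam.defocus_zc_um)
        img = ndi.gaussian_filter(img, sigma=sigma)
        use_noise = cam.shot_noise or cam.read_noise_sd > 0
        if noise if noise is not None else use_noise:
            rng = rng or self.noise_rng
            if cam.shot_noise:
                img = rng.poisson(np.clip(img, 0, None)).astype(float)
            if cam.read_noise_sd > 0:
                img = img + rng.normal(0.0, cam.read_noise_sd, img.shape)
        return img

    def render_labels(self, label_buds: bool = False) -> np.ndarray:
        """Ground-truth label map at the current pose; labels are cell ids.

        With ``label_buds`` each bud gets its own label ``BUD_LABEL_BASE +
        mother id`` so buds appear as distinct regions, as a segmenter would
        see them; otherwise a budded cell is a single region.
        """
        cam = self.camera
        labels = np.zeros((cam.height, cam.width), dtype=np.int32)
        depth = np.full((cam.height, cam.width), np.inf)

        # contested pixels go to the cell whose boundary reaches deepest past
        # them, so overlapping footprints split along the midline
        def disk(center, radius, lab):
            row, col = self._to_px(center)
            r_px = radius / cam.pixel_size_um
            r0 = max(0, int(math.floor(row - r_px - 2)))
            r1 = min(cam.height, int(math.ceil(row + r_px + 3)))
            c0 = max(0, int(math.floor(col - r_px - 2)))
            c1 = min(cam.width, int(math.ceil(col + r_px + 3)))
            if r0 >= r1 or c0 >= c1:
                return
            rr, cc = np.mgrid[r0:r1, c0:c1]
            d = np.hypot(rr - row, cc - col)
            sel = (d <= r_px) & (d - r_px < depth[r0:r1, c0:c1])
            labels[r0:r1, c0:c1][sel] = lab
            depth[r0:r1, c0:c1][sel] = (d - r_px)[sel]

        for _, c in self._visible_cells():
            disk(c.centroid, c.radius, c.id)
        for _, c in self._visible_cells():
            if c.bud_area > 0:
                lab = (BUD_LABEL_BASE + c.id) if label_buds else c.id
                disk(c.bud_center(), c.bud_radius, lab)
        return labels

    def acquire(self, settings: ChannelSettings, position_id: int = 0,
                autofocus_used: bool = False) -> Frame:
        """Render a frame and apply illumination side effects.

        Fluorescence exposures add photodose to every in-FOV cell; a
        blue_stim exposure (re)sets the optogenetic light dose of the
        chambers under the FOV.
        """
        img = self.render(settings)
        pixels = np.clip(np.round(img), 0, 65535).astype(np.uint16)
        fov = self.fov_rect()
        if settings.channel in _FLUOR:
            for ch in self.chambers:
                accumulate_photodose(ch, settings.channel, settings.exposure_ms,
                                     settings.led_intensity_pct, fov=fov)
        elif settings.channel == "blue_stim":
            for ch in self.chambers:
                if self._chamber_in_fov(ch, fov):
                    ch.environment.light_dose_pct = settings.led_intensity_pct
        return Frame(pixels=pixels, channel_settings=settings,
                     stage=StagePose(self.pose.x, self.pose.y, self.pose.z),
                     t_sim=self.t_sim, position_id=position_id,
                     autofocus_used=autofocus_used)

    @staticmethod
    def _chamber_in_fov(chamber: SampleState, fov) -> bool:
        x0, y0, x1, y1 = chamber.chamber
        return not (x1 < fov[0] or x0 > fov[2] or y1 < fov[1] or y0 > fov[3])

    # -- autofocus ------------------------------------------------------
    def _sharpness(self, z: float) -> float:
        saved_z, saved_cam = self.pose.z, self.camera
        # the metric only ranks z planes, so render at half resolution
        self.camera = replace(saved_cam, width=max(saved_cam.width // 2, 32),
                              height=max(saved_cam.height // 2, 32),
                              pixel_size_um=saved_cam.pixel_size_um * 2)
        self.pose.z = z
        try:
            img = self.render(ChannelSettings("brightfield", exposure_ms=50.0,
                                              led_intensity_pct=0.0), noise=False)
        finally:
            self.pose.z = saved_z
            self.camera = saved_cam
        hp = img - ndi.gaussian_filter(img, sigma=3.0)
        return float(np.var(hp))

    def autofocus(self, scan_range_um: float = 3.0, n_points: int = 11) -> StagePose:
        """Bracketed coarse-to-fine z-scan maximising a high-pass sharpness metric.

        The simulator's defocus blur is unimodal in |z|, so the scan is
        guaranteed to land within ``z_tol_um`` of focus.
        """
        z0 = self.pose.z
        coarse = np.linspace(z0 - scan_range_um, z0 + scan_range_um, n_points)
        best = max(coarse, key=self._sharpness)
        step = coarse[1] - coarse[0]
        fine = np.linspace(best - step, best + step, 13)
        best = max(fine, key=self._sharpness)
        self.pose.z = float(best)
        return self.pose


def image_center_px(camera: CameraConfig) -> tuple:
    return ((camera.height - 1) / 2.0, (camera.width - 1) / 2.0)
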