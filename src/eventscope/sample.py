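"""Agent-based simulator of a budding-yeast monolayer in a microfluidic chamber.

The sample model is the single source of ground truth for every downstream
component: cells grow exponentially in area, bud, divide, and displace each
other by pairwise overlap relaxation inside a rectangular chamber.  Reporter
kinetics (Hog1 nuclear import under hyperosmotic stress, light-dose-dependent
Venus expression, a constitutive nuclear RFP tag) and cumulative photodose
with growth arrest above a safe dose rate are part of the state, so that
closed-loop acquisition scenarios can be exercised end-to-end against known
ground truth.

Coordinates are in micrometres in the chamber (world) frame; time in seconds.
All stochastic choices (bud angles, G1-length jitter, initial placement) draw
from a single seeded generator owned by the state, so identical seeds and
call sequences give bit-identical trajectories.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

MEDIA = ("glucose", "sucrose", "sorbitol_stress")
LN2 = math.log(2.0)


@dataclass
class SampleParams:
    """Kinetic and geometric constants of the virtual sample.

    Growth is area-exponential with a 90 min doubling time in glucose
    (standard budding-yeast physiology at 30 C).  A budded cell puts all
    growth into its bud and divides when the bud reaches ``f_div`` times the
    mother area.  Photodose is the trailing-window rate of
    ``exposure_ms * intensity_pct`` units; one 150 ms / 100% fluorescence
    exposure per 5 min (rate 50 /s) is safe, one per 25 s (rate 600 /s)
    arrests growth.
    """

    doubling_time_s: float = 5400.0
    t_g1_s: float = 1800.0
    g1_jitter: float = 0.2
    f_div: float = 0.6
    bud_init_frac: float = 0.05
    r_max_um: float = 2.4          # unbudded area cap -> mother size homeostasis
    nuc_sep_s: float = 600.0       # nuclei rendered separated this long before division
    nucleus_radius_frac: float = 0.35
    sucrose_rate_factor: float = 0.9
    sorbitol_rate_factor: float = 0.5
    k_suc: float = 1e-3            # hexose a.u. per cell per s (shared pool)
    h_min: float = 36.0            # hexose level at which growth resumes
    dose_window_s: float = 600.0
    d_safe: float = 60.0           # dose-rate a.u./s below which growth is unaffected
    d_arrest: float = 600.0        # dose-rate a.u./s above which growth arrests
    hog1_base: float = 0.25
    hog1_amp: float = 0.45
    tau_in_s: float = 40.0
    tau_adapt_s: float = 600.0
    tau_release_s: float = 60.0
    venus_vmax: float = 2.0        # a.u./s maximal production
    venus_k: float = 10.0          # % LED at half-maximal induction
    venus_n: float = 2.0
    venus_delta: float = 1.0 / 1800.0  # 1/s first-order decay
    gfp_total: float = 30000.0
    rfp_level: float = 1000.0
    max_substep_s: float = 5.0
    relax_iters: int = 10
    relax_eps_um: float = 0.05

    @property
    def growth_rate(self) -> float:
        """Base exponential area growth rate in glucose, 1/s."""
        return LN2 / self.doubling_time_s

    @property
    def area_max_um2(self) -> float:
        return math.pi * self.r_max_um**2

    @property
    def sep_bud_frac(self) -> float:
        """Bud area (fraction of mother area) at nuclear-separation onset.

        Chosen so that, growing at the glucose rate, the bud reaches the
        division threshold ``f_div`` exactly ``nuc_sep_s`` later.
        """
        return (1.0 + self.f_div) * math.exp(-self.growth_rate * self.nuc_sep_s) - 1.0


@dataclass
class Cell:
    id: int
    centroid: np.ndarray           # (x, y) um
    radius: float                  # um
    phase: str = "unbudded"        # "unbudded" | "budded"
    bud_area: float = 0.0          # um^2
    bud_angle: float = 0.0
    mother_id: Optional[int] = None
    rfp_tagged: bool = False
    gfp_total_level: float = 0.0
    hog1_nuclear_fraction: float = 0.0
    venus_level: float = 0.0
    photodose: float = 0.0
    birth_time: float = 0.0
    cycle_start: float = 0.0
    t_g1: float = 1800.0
    bud_start_time: Optional[float] = None
    sep_onset_time: Optional[float] = None
    dose_events: list = field(default_factory=list)  # (t, dose) within window

    @property
    def area(self) -> float:
        """Mother-body area, um^2 (excludes the bud)."""
        return math.pi * self.radius**2

    @property
    def total_area(self) -> float:
        return self.area + self.bud_area

    @property
    def bud_radius(self) -> float:
        return math.sqrt(self.bud_area / math.pi) if self.bud_area > 0 else 0.0

    @property
    def collision_radius(self) -> float:
        """Effective circular footprint used by overlap relaxation."""
        return math.sqrt(self.total_area / math.pi)

    def bud_center(self) -> np.ndarray:
        """Bud disk centre; the bud neck overlaps the mother by 30% of r_bud."""
        off = self.radius + 0.7 * self.bud_radius
        return self.centroid + off * np.array(
            [math.cos(self.bud_angle), math.sin(self.bud_angle)]
        )

    @property
    def rfp_nuclear_level(self) -> float:
        return 0.0 if not self.rfp_tagged else self._rfp_level

    _rfp_level: float = 0.0


@dataclass
class Environment:
    medium: str = "glucose"
    hexose: float = 0.0
    light_dose_pct: float = 0.0
    time: float = 0.0
    stress_start: Optional[float] = None
    stress_release: Optional[float] = None
    hog1_at_release: float = 0.0


@dataclass
class LineageRecord:
    mother_id: int
    daughter_id: int
    division_time_s: float
    sep_onset_time_s: float
    bud_start_time_s: float


@dataclass
class SampleState:
    """The virtual colony: cells + environment + chamber + seeded RNG."""

    cells: list
    environment: Environment
    chamber: tuple                 # (x0, y0, x1, y1) um
    rng: np.random.Generator
    params: SampleParams = field(default_factory=SampleParams)
    lineage: list = field(default_factory=list)
    open_side: Optional[str] = None  # None or "+x" | "-x" | "+y" | "-y"
    next_id: int = 1

    def copy(self) -> "SampleState":
        return copy.deepcopy(self)

    def count(self) -> int:
        return len(self.cells)

    def cell_by_id(self, cid: int) -> Cell:
        for c in self.cells:
            if c.id == cid:
                return c
        raise KeyError(cid)


# ---------------------------------------------------------------------------
# closed-form reporter kinetics


def hog1_fraction(t_since_stress, base: float, amp: float,
                  tau_in: float, tau_adapt: float):
    """Hog1 nuclear fraction t seconds after hyperosmotic stress onset.

    base + A * (1 - exp(-t/tau_in)) * exp(-t/tau_adapt); the analytic peak is
    at t* = tau_in * ln(1 + tau_adapt/tau_in), 1-2 min for the defaults.
    """
    t = np.asarray(t_since_stress, dtype=float)
    return base + amp * (1.0 - np.exp(-t / tau_in)) * np.exp(-t / tau_adapt)


def hog1_peak_time(params: SampleParams) -> float:
    return params.tau_in_s * math.log(1.0 + params.tau_adapt_s / params.tau_in_s)


def hog1_response(state: SampleState, t_since_stress) :
    """Per-cell nuclear fraction of Hog1 at the given time since stress onset."""
    p = state.params
    val = hog1_fraction(t_since_stress, p.hog1_base, p.hog1_amp,
                        p.tau_in_s, p.tau_adapt_s)
    return np.full(len(state.cells), val) if np.isscalar(t_since_stress) else val


def venus_steady_state(intensity_pct: float, params: SampleParams) -> float:
    """Closed-form steady state of the Hill-production / first-order-decay ODE."""
    if intensity_pct <= 0:
        return 0.0
    hill = intensity_pct**params.venus_n / (
        params.venus_k**params.venus_n + intensity_pct**params.venus_n
    )
    return params.venus_vmax * hill / params.venus_delta


def _venus_step(level: float, intensity_pct: float, dt: float,
                params: SampleParams) -> float:
    # exact update of dv/dt = Vmax*hill(I) - delta*v over dt
    ss = venus_steady_state(intensity_pct, params)
    return ss + (level - ss) * math.exp(-params.venus_delta * dt)


def venus_induction(state: SampleState, intensity_pct: float,
                    dt: float) -> SampleState:
    """Apply blue-light stimulation at ``intensity_pct`` for ``dt`` seconds.

    Sets the chamber light dose and integrates only the Venus reporter ODE
    (exactly, via the linear closed form); growth and the clock are advanced
    by :func:`advance`, which uses the stored light dose.
    """
    if not 0.0 <= intensity_pct <= 100.0:
        raise ValueError("intensity_pct must be in [0, 100]")
    state.environment.light_dose_pct = float(intensity_pct)
    for cell in state.cells:
        cell.venus_level = _venus_step(cell.venus_level, intensity_pct, dt,
                                       state.params)
    return state


# ---------------------------------------------------------------------------
# medium switching and photodose


def set_medium(state: SampleState, medium: str) -> SampleState:
    """Switch the perfused medium (the effect of an electrofluidic valve).

    glucose -> sucrose empties the shared extracellular hexose pool; growth
    stays frozen until the population's secreted invertase rebuilds it to
    ``h_min`` at rate ``k_suc * N``, so the lag shortens with cell count.
    Entering/leaving ``sorbitol_stress`` starts/releases the Hog1 response.
    """
    if medium not in MEDIA:
        raise ValueError(f"unknown medium {medium!r}; expected one of {MEDIA}")
    env = state.environment
    if medium == env.medium:
        return state
    if medium == "sucrose":
        env.hexose = 0.0
    if medium == "sorbitol_stress":
        env.stress_start = env.time
        env.stress_release = None
    elif env.medium == "sorbitol_stress":
        env.hog1_at_release = _env_hog1(env, env.time, state.params)
        env.stress_release = env.time
        env.stress_start = None
    env.medium = medium
    return state


def _env_hog1(env: Environment, t: float, p: SampleParams) -> float:
    if env.stress_start is not None:
        return float(hog1_fraction(t - env.stress_start, p.hog1_base,
                                   p.hog1_amp, p.tau_in_s, p.tau_adapt_s))
    if env.stress_release is not None:
        return p.hog1_base + (env.hog1_at_release - p.hog1_base) * math.exp(
            -(t - env.stress_release) / p.tau_release_s
        )
    return p.hog1_base


_FLUOR_CHANNELS = ("GFP", "RFP", "YFP")


def accumulate_photodose(state: SampleState, channel: str, exposure_ms: float,
                         intensity_pct: float, fov=None) -> SampleState:
    """Record one fluorescence exposure on every in-FOV cell.

    ``fov`` is a world-frame rectangle (x0, y0, x1, y1) or None for the whole
    chamber.  Brightfield and the blue stimulation channel contribute zero
    dose (stimulation intensities are orders of magnitude below excitation).
    """
    if channel not in _FLUOR_CHANNELS:
        return state
    dose = float(exposure_ms) * float(intensity_pct)
    if dose <= 0:
        return state
    t = state.environment.time
    for cell in state.cells:
        if fov is not None:
            x, y = cell.centroid
            if not (fov[0] <= x <= fov[2] and fov[1] <= y <= fov[3]):
                continue
        cell.photodose += dose
        cell.dose_events.append((t, dose))
    return state


def phototox_factor(cell: Cell, t: float, params: SampleParams) -> float:
    """Growth factor in [0,1] from the trailing-window fluorescence dose rate."""
    w0 = t - params.dose_window_s
    if cell.dose_events and cell.dose_events[0][0] < w0:
        cell.dose_events = [(te, d) for (te, d) in cell.dose_events if te >= w0]
    rate = sum(d for (_, d) in cell.dose_events) / params.dose_window_s
    if rate <= params.d_safe:
        return 1.0
    if rate >= params.d_arrest:
        return 0.0
    return (params.d_arrest - rate) / (params.d_arrest - params.d_safe)


# ---------------------------------------------------------------------------
# time stepping


def _base_growth_rate(env: Environment, p: SampleParams) -> float:
    g = p.growth_rate
    if env.medium == "glucose":
        return g
    if env.medium == "sucrose":
        return 0.0 if env.hexose < p.h_min else g * p.sucrose_rate_factor
    return g * p.sorbitol_rate_factor  # sorbitol_stress


def advance(state: SampleState, dt: float) -> SampleState:
    """Advance the colony by ``dt`` seconds (deterministic given the RNG state).

    Each sub-step applies, in order: hexose pool update, per-cell growth
    (scaled by the phototoxicity factor), bud initiation, division, reporter
    updates, pairwise overlap relaxation, and the clock.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if dt == 0:
        return state
    remaining = float(dt)
    while remaining > 1e-9:
        h = min(state.params.max_substep_s, remaining)
        _substep(state, h)
        remaining -= h
    return state


def _substep(state: SampleState, h: float) -> None:
    p = state.params
    env = state.environment
    t0 = env.time
    t1 = t0 + h

    if env.medium == "sucrose":
        env.hexose += p.k_suc * len(state.cells) * h
    g0 = _base_growth_rate(env, p)

    # growth
    for cell in state.cells:
        g = g0 * phototox_factor(cell, t0, p)
        if g <= 0:
            continue
        grow = math.exp(g * h)
        if cell.phase == "unbudded":
            new_area = min(cell.area * grow, p.area_max_um2)
            cell.radius = math.sqrt(new_area / math.pi)
        else:
            cell.bud_area += cell.total_area * (grow - 1.0)
            if (cell.sep_onset_time is None
                    and cell.bud_area >= p.sep_bud_frac * cell.area):
                cell.sep_onset_time = t1

    # bud initiation (age-gated, jittered G1)
    for cell in state.cells:
        if cell.phase == "unbudded" and (t1 - cell.cycle_start) >= cell.t_g1:
            cell.phase = "budded"
            cell.bud_area = p.bud_init_frac * cell.area
            cell.bud_angle = float(state.rng.uniform(0.0, 2.0 * math.pi))
            cell.bud_start_time = t1
            cell.sep_onset_time = None

    # division
    daughters = []
    for cell in state.cells:
        if cell.phase == "budded" and cell.bud_area >= p.f_div * cell.area:
            d_radius = math.sqrt(cell.bud_area / math.pi)
            # the daughter body continues where the bud was rendered
            daughter = Cell(
                id=state.next_id,
                centroid=cell.bud_center(),
                radius=d_radius,
                mother_id=cell.id,
                rfp_tagged=cell.rfp_tagged,
                gfp_total_level=p.gfp_total,
                hog1_nuclear_fraction=cell.hog1_nuclear_fraction,
                venus_level=cell.venus_level,
                birth_time=t1,
                cycle_start=t1,
                t_g1=p.t_g1_s * (1.0 + p.g1_jitter * float(state.rng.uniform(-1, 1))),
            )
            daughter._rfp_level = p.rfp_level
            state.next_id += 1
            daughters.append(daughter)
            sep = cell.sep_onset_time if cell.sep_onset_time is not None else t1
            bud_start = (cell.bud_start_time
                         if cell.bud_start_time is not None else t1)
            state.lineage.append(LineageRecord(cell.id, daughter.id, t1, sep,
                                               bud_start))
            cell.phase = "unbudded"
            cell.bud_area = 0.0
            cell.cycle_start = t1
            cell.t_g1 = p.t_g1_s * (1.0 + p.g1_jitter * float(state.rng.uniform(-1, 1)))
            cell.sep_onset_time = None
            cell.bud_start_time = None
    state.cells.extend(daughters)

    # reporters (uniform across the chamber)
    frac = _env_hog1(env, t1, p)
    decay = math.exp(-p.venus_delta * h)
    ss = venus_steady_state(env.light_dose_pct, p)
    for cell in state.cells:
        cell.hog1_nuclear_fraction = frac
        cell.venus_level = ss + (cell.venus_level - ss) * decay

    _relax(state)
    env.time = t1


def _relax(state: SampleState) -> None:
    """Iterated pairwise projection: push overlapping cells apart, clamp to walls.

    Three closed walls and one optional open side; growth pressure in a
    dead-end chamber therefore produces net directed motion toward the open
    side, which is the displacement the tracking scenarios exercise.
    """
    cells = state.cells
    n = len(cells)
    if n == 0:
        return
    p = state.params
    pos = np.array([c.centroid for c in cells], dtype=float)
    rad = np.array([c.collision_radius for c in cells], dtype=float)
    x0, y0, x1, y1 = state.chamber
    open_side = state.open_side
    for _ in range(p.relax_iters):
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        overlap = rad[:, None] + rad[None, :] - dist
        if overlap.max() <= p.relax_eps_um:
            break
        ii, jj = np.nonzero(np.triu(overlap > p.relax_eps_um, k=1))
        d = dist[ii, jj]
        u = np.where(d[:, None] > 1e-9, diff[ii, jj] / np.maximum(d, 1e-9)[:, None],
                     np.array([1.0, 0.0]))
        push = (0.5 * overlap[ii, jj])[:, None] * u
        disp = np.zeros_like(pos)
        np.add.at(disp, ii, push)
        np.add.at(disp, jj, -push)
        pos += disp
        lo = np.array([x0, y0]) + rad[:, None]
        hi = np.array([x1, y1]) - rad[:, None]
        if open_side == "+x":
            hi[:, 0] = np.inf
        elif open_side == "-x":
            lo[:, 0] = -np.inf
        elif open_side == "+y":
            hi[:, 1] = np.inf
        elif open_side == "-y":
            lo[:, 1] = -np.inf
        pos = np.clip(pos, lo, hi)
    # keep centroids inside the chamber rectangle proper
    pos[:, 0] = np.clip(pos[:, 0], x0, x1)
    pos[:, 1] = np.clip(pos[:, 1], y0, y1)
    for c, xy in zip(cells, pos):
        c.centroid = xy


def max_pairwise_overlap(state: SampleState) -> float:
    cells = state.cells
    if len(cells) < 2:
        return 0.0
    pos = np.array([c.centroid for c in cells])
    rad = np.array([c.collision_radius for c in cells])
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    np.fill_diagonal(dist, np.inf)
    return float((rad[:, None] + rad[None, :] - dist).max())


# ---------------------------------------------------------------------------
# colony construction


def init_colony(
    n: int,
    chamber: tuple,
    seed: int,
    params: Optional[SampleParams] = None,
    tag_fraction: float = 0.0,
    tagged_region: Optional[tuple] = None,
    cycle_randomized: bool = True,
    region: Optional[tuple] = None,
    open_side: Optional[str] = None,
    radius_um: tuple = (1.8, 2.3),
) -> SampleState:
    """Seed a colony of ``n`` cells inside ``chamber`` (or a sub-``region``).

    ``tag_fraction`` of the cells carry the nuclear RFP tag; if
    ``tagged_region`` is given the tagged cells are drawn from cells inside
    that rectangle (used to position trackable cells mid-chamber).  With
    ``cycle_randomized`` cells start at random points of the cycle so
    population growth is smooth from t = 0; otherwise all start unbudded with
    uniformly jittered ages.
    """
    params = params or SampleParams()
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = region if region is not None else chamber
    cells = []
    for i in range(n):
        r = float(rng.uniform(*radius_um))
        c = Cell(
            id=i + 1,
            centroid=np.array([rng.uniform(x0 + r, x1 - r),
                               rng.uniform(y0 + r, y1 - r)]),
            radius=r,
            gfp_total_level=params.gfp_total,
            hog1_nuclear_fraction=params.hog1_base,
            t_g1=params.t_g1_s * (1.0 + params.g1_jitter * float(rng.uniform(-1, 1))),
        )
        c._rfp_level = params.rfp_level
        if cycle_randomized and rng.uniform() < 0.45:
            c.phase = "budded"
            c.bud_area = float(rng.uniform(params.bud_init_frac, 0.35)) * c.area
            c.bud_angle = float(rng.uniform(0, 2 * math.pi))
            c.bud_start_time = 0.0
        else:
            c.cycle_start = -float(rng.uniform(0, c.t_g1))
        cells.append(c)

    state = SampleState(
        cells=cells,
        environment=Environment(),
        chamber=chamber,
        rng=rng,
        params=params,
        open_side=open_side,
        next_id=n + 1,
    )
    if tag_fraction > 0 and n > 0:
        pool = [
            c for c in cells
            if tagged_region is None
            or (tagged_region[0] <= c.centroid[0] <= tagged_region[2]
                and tagged_region[1] <= c.centroid[1] <= tagged_region[3])
        ] or cells
        k = max(1, int(round(tag_fraction * n)))
        for idx in rng.choice(len(pool), size=min(k, len(pool)), replace=False):
            pool[int(idx)].rfp_tagged = True
    # settle initial overlaps
    for _ in range(20):
        if max_pairwise_overlap(state) <= params.relax_eps_um:
            break
        _relax(state)
    return state
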