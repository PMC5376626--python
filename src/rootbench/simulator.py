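"""Random 2D structural root-system generator.

The generator follows the classical principles of minimal structural root
models: apical elongation proportional to apical diameter, acropetal lateral
emission at a fixed spacing along the parent, daughter apical diameters drawn
as a fixed fraction of the mother's with multiplicative noise, growth arrest
below a minimum diameter, and a heading updated each step by gravitropism
plus Gaussian angular noise.  Tap-rooted systems additionally thicken
radially in proportion to the number of growing apices downstream of each
node (a pipe-model-like rule).

Growth is confined to the vertical plane: the seed sits at the origin and
the y axis points downward (depth-positive imaging convention); all
coordinates are millimetres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from rootbench.config import load_sampling_ranges

PLANT_TYPES = ("fibrous", "tap")

# Safety bound: daughter diameters shrink geometrically with order, so deep
# orders die out on their own; the cap only guards pathological parameters.
_MAX_ORDER = 6

# Determinate growth: a root elongates for a duration proportional to the
# square of its apical diameter (thin roots are short-lived), a classical
# allometry of minimal root models.  Units: day per mm².
GROWTH_DURATION_COEFF = 300.0


@dataclass
class SimulationParams:
    """Full parameter set for one simulated root system."""

    plant_type: str
    n_axes: int
    duration_days: float
    time_step_days: float
    elong_coeff: float            # mm·day⁻¹ per mm of apical diameter
    d_axis_mm: float              # initial apical diameter of the axes
    d_min_mm: float               # tips thinner than this stop elongating
    diam_ratio: float             # daughter/mother apical diameter ratio
    diam_cv: float                # relative s.d. of the daughter diameter
    interbranch_mm: float         # spacing between lateral insertion points
    insertion_angle_mean_deg: float
    insertion_angle_sd_deg: float
    tropism_strength: float       # per-step downward reorientation weight
    direction_noise_sd_deg: float
    sec_growth_coeff: float       # mm per downstream apex per day (tap only)
    rng_seed: int

    def validate(self) -> None:
        if self.plant_type not in PLANT_TYPES:
            raise ValueError(
                f"unknown plant_type {self.plant_type!r}; expected one of {PLANT_TYPES}"
            )
        if self.plant_type == "fibrous":
            if self.sec_growth_coeff != 0:
                raise ValueError("fibrous systems have no secondary growth")
            if not 1 <= self.n_axes <= 20:
                raise ValueError("fibrous n_axes must be in [1, 20]")
        else:
            if self.n_axes != 1:
                raise ValueError("tap-rooted systems have exactly one axis")
            if self.sec_growth_coeff <= 0:
                raise ValueError("tap-rooted systems require sec_growth_coeff > 0")
        if not 0 < self.diam_ratio < 1:
            raise ValueError("diam_ratio must lie in (0, 1)")
        for name in ("elong_coeff", "d_axis_mm", "d_min_mm", "diam_cv",
                     "interbranch_mm", "insertion_angle_sd_deg",
                     "tropism_strength", "direction_noise_sd_deg",
                     "sec_growth_coeff"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.time_step_days <= 0:
            raise ValueError("time_step_days must be positive")
        if self.duration_days < 0:
            raise ValueError("duration_days must be non-negative")


@dataclass
class RootNode:
    x_mm: float
    y_mm: float
    diameter_mm: float


class Root:
    """A single root: an ordered polyline (base to tip) with node diameters.

    ``order`` is 1 for axes (attached to the seed) and parent order + 1 for
    laterals; ``insertion_position_mm`` is the curvilinear abscissa on the
    parent where a lateral attaches.
    """

    __slots__ = ("xs", "ys", "diams", "order", "parent", "insertion_position_mm",
                 "children", "_heading", "_apical_diam", "_next_branch",
                 "_alive", "_cumlen", "_age")

    def __init__(self, x: float, y: float, diameter: float, order: int,
                 parent: "Root | None" = None, insertion_position_mm: float = 0.0,
                 heading: tuple[float, float] = (0.0, 1.0)):
        self.xs: list[float] = [x]
        self.ys: list[float] = [y]
        self.diams: list[float] = [diameter]
        self.order = order
        self.parent = parent
        self.insertion_position_mm = insertion_position_mm
        self.children: list[Root] = []
        self._heading = heading
        self._apical_diam = diameter
        self._next_branch = 0.0   # set by the simulator
        self._alive = True
        self._cumlen: list[float] = [0.0]  # node abscissas, kept incrementally
        self._age = 0.0

    @property
    def nodes(self) -> list[RootNode]:
        return [RootNode(x, y, d) for x, y, d in zip(self.xs, self.ys, self.diams)]

    @property
    def n_nodes(self) -> int:
        return len(self.xs)

    def length(self) -> float:
        return self._cumlen[-1]

    def set_polyline(self, xs, ys, diams) -> None:
        """Replace the geometry wholesale (deserialization path)."""
        self.xs, self.ys, self.diams = list(xs), list(ys), list(diams)
        seg = np.hypot(np.diff(self.xs), np.diff(self.ys))
        self._cumlen = [0.0] + list(np.cumsum(seg))

    def abscissas(self) -> np.ndarray:
        """Curvilinear abscissa of every node, base to tip."""
        return np.asarray(self._cumlen)

    def _segment_of(self, abscissa: float) -> tuple[int, float]:
        import bisect

        s = self._cumlen
        a = min(max(abscissa, 0.0), s[-1])
        i = bisect.bisect_right(s, a) - 1
        i = max(0, min(i, len(s) - 2)) if len(s) > 1 else 0
        return i, a

    def point_at(self, abscissa: float) -> tuple[float, float]:
        """Interpolated point on the polyline at a given abscissa."""
        i, a = self._segment_of(abscissa)
        s = self._cumlen
        if len(s) == 1 or s[i + 1] == s[i]:
            return self.xs[i], self.ys[i]
        f = (a - s[i]) / (s[i + 1] - s[i])
        return (self.xs[i] + f * (self.xs[i + 1] - self.xs[i]),
                self.ys[i] + f * (self.ys[i + 1] - self.ys[i]))

    def tangent_at(self, abscissa: float) -> tuple[float, float]:
        """Unit tangent of the polyline at a given abscissa (base→tip)."""
        if len(self._cumlen) < 2:
            return self._heading
        i, _ = self._segment_of(abscissa)
        dx = self.xs[i + 1] - self.xs[i]
        dy = self.ys[i + 1] - self.ys[i]
        n = math.hypot(dx, dy)
        if n == 0:
            return self._heading
        return dx / n, dy / n


@dataclass
class RootSystem:
    roots: list[Root]
    plant_type: str
    params: SimulationParams | None = None

    @property
    def axes(self) -> list[Root]:
        return [r for r in self.roots if r.order == 1]

    @property
    def laterals(self) -> list[Root]:
        return [r for r in self.roots if r.order >= 2]

    def total_length(self) -> float:
        return float(sum(r.length() for r in self.roots))

    def validate(self) -> None:
        n_axes = sum(1 for r in self.roots if r.order == 1)
        if self.params is not None and n_axes != self.params.n_axes:
            raise ValueError("axis count does not match parameters")
        if n_axes == 0:
            raise ValueError("a root system must contain at least one axis")
        for r in self.roots:
            if (r.order == 1) != (r.parent is None):
                raise ValueError("order-1 roots and only they must be parentless")


def sample_parameters(plant_type: str, rng_seed: int,
                      ranges: dict | None = None,
                      time_step_days: float = 1.0) -> SimulationParams:
    """Draw a random, valid parameter set for one system.

    Sampling is uniform within the configured intervals (see
    ``rootbench.config.load_sampling_ranges``); identical
    ``(plant_type, rng_seed)`` pairs give identical parameter sets.
    """
    if plant_type not in PLANT_TYPES:
        raise ValueError(
            f"unknown plant_type {plant_type!r}; expected one of {PLANT_TYPES}"
        )
    if ranges is None:
        ranges = load_sampling_ranges()
    iv = ranges[plant_type]
    rng = np.random.default_rng(rng_seed)

    def u(name: str) -> float:
        lo, hi = iv[name]
        return float(lo) if lo == hi else float(rng.uniform(lo, hi))

    n_lo, n_hi = iv["n_axes"]
    n_axes = int(rng.integers(n_lo, n_hi + 1))
    params = SimulationParams(
        plant_type=plant_type,
        n_axes=n_axes,
        duration_days=u("duration_days"),
        time_step_days=time_step_days,
        elong_coeff=u("elong_coeff"),
        d_axis_mm=u("d_axis_mm"),
        d_min_mm=u("d_min_mm"),
        diam_ratio=u("diam_ratio"),
        diam_cv=u("diam_cv"),
        interbranch_mm=u("interbranch_mm"),
        insertion_angle_mean_deg=u("insertion_angle_mean_deg"),
        insertion_angle_sd_deg=u("insertion_angle_sd_deg"),
        tropism_strength=u("tropism_strength"),
        direction_noise_sd_deg=u("direction_noise_sd_deg"),
        sec_growth_coeff=u("sec_growth_coeff"),
        rng_seed=int(rng.integers(2**31)),
    )
    params.validate()
    return params


def _rotate(vx: float, vy: float, angle_rad: float) -> tuple[float, float]:
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return c * vx - s * vy, s * vx + c * vy


def _clamp_downward(hx: float, hy: float) -> tuple[float, float]:
    """Keep headings in the downward hemisphere (plagiotropic limit):
    gravitropic roots may grow sideways but not back up toward the shoot."""
    if hy < 0.0:
        return (1.0 if hx >= 0 else -1.0), 0.0
    return hx, hy


def _daughter_diameter(rng: np.random.Generator, params: SimulationParams,
                       mother_diam: float) -> float:
    factor = 1.0 + params.diam_cv * rng.standard_normal()
    factor = min(max(factor, 0.6), 1.4)  # truncate the multiplicative noise
    # Daughters are at most half their mother: diameters (and with them the
    # branching cascade) decay at least geometrically with order.
    return min(params.diam_ratio * mother_diam * factor, 0.5 * mother_diam)


def simulate(params: SimulationParams) -> RootSystem:
    """Grow one root system; deterministic given ``params.rng_seed``."""
    params.validate()
    rng = np.random.default_rng(params.rng_seed)

    roots: list[Root] = []
    for _ in range(params.n_axes):
        if params.plant_type == "fibrous" and params.n_axes > 1:
            theta = rng.uniform(-math.radians(70), math.radians(70))
        else:
            theta = rng.normal(0.0, math.radians(3.0))
        heading = (math.sin(theta), math.cos(theta))  # unit vector, y-down
        r = Root(0.0, 0.0, params.d_axis_mm, order=1, heading=heading)
        r._next_branch = params.interbranch_mm
        roots.append(r)

    t = 0.0
    eps = 1e-12
    while t < params.duration_days - eps:
        dt = min(params.time_step_days, params.duration_days - t)
        # Iterate over a snapshot: laterals emitted this step start growing
        # at the next one.
        for root in list(roots):
            _grow_root(root, roots, rng, params, dt)
        if params.sec_growth_coeff > 0:
            _secondary_growth(roots, params, dt)
        t += dt

    # Primordia emitted on the final step never elongated; drop them.
    for root in roots:
        root.children = [c for c in root.children if c.n_nodes >= 2]
    roots = [r for r in roots if r.order == 1 or r.n_nodes >= 2]

    system = RootSystem(roots=roots, plant_type=params.plant_type, params=params)
    system.validate()
    return system


def _grow_root(root: Root, roots: list[Root], rng: np.random.Generator,
               params: SimulationParams, dt: float) -> None:
    if not root._alive:
        return
    if root._apical_diam < params.d_min_mm or \
            root._age >= GROWTH_DURATION_COEFF * root._apical_diam**2:
        root._alive = False
        return
    root._age += dt

    hx, hy = root._heading
    # Gravitropism: pull the heading toward straight-down, then jitter it.
    hy += params.tropism_strength * dt
    n = math.hypot(hx, hy)
    hx, hy = hx / n, hy / n
    noise = math.radians(params.direction_noise_sd_deg) * math.sqrt(dt)
    hx, hy = _rotate(hx, hy, rng.normal(0.0, noise))
    hx, hy = _clamp_downward(hx, hy)
    root._heading = (hx, hy)

    step = params.elong_coeff * root._apical_diam * dt
    if step <= 0:
        return
    root.xs.append(root.xs[-1] + hx * step)
    root.ys.append(root.ys[-1] + hy * step)
    root.diams.append(root._apical_diam)
    root._cumlen.append(root._cumlen[-1] + step)

    # Acropetal lateral emission at fixed spacing along this root.
    if root.order >= _MAX_ORDER or not math.isfinite(params.interbranch_mm):
        return
    while root._next_branch <= root._cumlen[-1]:
        abscissa = root._next_branch
        root._next_branch += params.interbranch_mm
        d_child = _daughter_diameter(rng, params, root._apical_diam)
        if d_child < params.d_min_mm:
            continue
        px, py = root.point_at(abscissa)
        tx, ty = root.tangent_at(abscissa)
        angle = rng.normal(params.insertion_angle_mean_deg,
                           params.insertion_angle_sd_deg)
        angle = math.radians(min(max(angle, 5.0), 140.0))
        if rng.random() < 0.5:
            angle = -angle
        cx, cy = _clamp_downward(*_rotate(tx, ty, angle))
        child = Root(px, py, d_child, order=root.order + 1, parent=root,
                     insertion_position_mm=abscissa, heading=(cx, cy))
        child._next_branch = params.interbranch_mm
        root.children.append(child)
        roots.append(child)


def _secondary_growth(roots: list[Root], params: SimulationParams,
                      dt: float) -> None:
    """Radial thickening proportional to the active apices downstream.

    Each node's diameter grows by ``sec_growth_coeff × n_downstream × dt``
    where ``n_downstream`` counts growing tips in the subtree distal to the
    node — so older, more proximal segments thicken fastest, as in
    pipe-model allometry.
    """
    # Post-order accumulation of active-apex counts per subtree.
    subtree: dict[int, int] = {}

    def count(root: Root) -> int:
        key = id(root)
        if key not in subtree:
            subtree[key] = int(root._alive and root._apical_diam >= params.d_min_mm) \
                + sum(count(c) for c in root.children)
        return subtree[key]

    for root in roots:
        count(root)

    inc = params.sec_growth_coeff * dt
    for root in roots:
        if not root.children:
            n_down = subtree[id(root)]
            if n_down:
                add = inc * n_down
                root.diams = [d + add for d in root.diams]
            continue
        s = root.abscissas()
        child_abs = np.array(sorted(c.insertion_position_mm for c in root.children))
        child_counts = np.array([subtree[id(c)] for c in
                                 sorted(root.children,
                                        key=lambda c: c.insertion_position_mm)])
        suffix = np.concatenate([np.cumsum(child_counts[::-1])[::-1], [0]])
        own = int(root._alive and root._apical_diam >= params.d_min_mm)
        # For node at abscissa a: apices of children inserted at ≥ a, plus own tip.
        idx = np.searchsorted(child_abs, s, side="left")
        n_down = suffix[idx] + own
        root.diams = [d + inc * int(k) * 1.0 if k else d
                      for d, k in zip(root.diams, n_down)]


def generate_library(n: int, fibrous_fraction: float, base_seed: int,
                     ranges: dict | None = None,
                     time_step_days: float = 1.0,
                     ) -> list[tuple[RootSystem, SimulationParams]]:
    """Generate a seeded library of simulated root systems.

    ``round(n × fibrous_fraction)`` systems are fibrous, the remainder
    tap-rooted; per-system seeds derive deterministically from ``base_seed``
    so the whole library is reproducible end to end.
    """
    if n < 0:
        raise ValueError("library size must be non-negative")
    if not 0 <= fibrous_fraction <= 1:
        raise ValueError("fibrous_fraction must lie in [0, 1]")
    if n == 0:
        return []
    n_fibrous = round(n * fibrous_fraction)
    seeds = np.random.SeedSequence(base_seed).generate_state(n, dtype=np.uint32)
    seeds = (seeds % (2**31)).astype(int)
    out = []
    for i in range(n):
        plant_type = "fibrous" if i < n_fibrous else "tap"
        params = sample_parameters(plant_type, int(seeds[i]), ranges=ranges,
                                   time_step_days=time_step_days)
        out.append((simulate(params), params))
    return out
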