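"""Synthetic multiplexed-IHC cortical tissue with per-cell ground truth.

This module generates 2D multi-channel fluorescence images that emulate
cortical fields of microglia as seen in a multiplexed panel (Hoechst,
pTDP-43, HLA-DR, CD68, Iba1), together with an exact per-cell ground
truth table. Three microglial morphology classes are modelled:

* **ramified** — small soma, many long branching processes;
* **hypertrophic** — enlarged soma, fewer short processes with little
  branching;
* **dystrophic** — small soma with short, beaded/fragmented processes.

Marker levels are class-conditional (hypertrophic and dystrophic cells
carry higher CD68 and Iba1 than ramified cells) and class mixtures and
pTDP-43 aggregate burden are group-conditional, so a simulated "disease"
group shows higher phagocytic-marker signal, larger somata and reduced
outgrowth — the qualitative contrasts the analysis pipeline is meant to
detect.

Geometry model
--------------
Each cell is a soma disk plus a forest of process polylines rooted on the
soma perimeter. Growth is radially outward with collision checking: a new
segment is only accepted if it keeps a clearance from every non-adjacent
segment already drawn, so the rendered skeleton's topology is identical
to the generated tree. Dystrophic beading is modelled as mid-segment gaps
that disconnect the distal part of a process. Process extent is capped at
a safety margin inside each cell's territory (half the distance to its
nearest neighbour) so that every process stays inside the watershed
domain of its own soma.

All randomness flows from a single integer seed; identical spec + seed
produce bit-identical images and truth tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MARKERS_HUMAN = ("hoechst", "ptdp43", "hladr", "cd68", "iba1")
MARKERS_MOUSE = ("hoechst", "ptdp43", "cd68", "iba1")

_MIN_SEGMENT_UM = 2.5    # segments shorter than this are not drawn
_GAP_LENGTH_UM = 2.0     # beading gap length (stays open after rasterization)
_MIN_PIECE_UM = 2.0      # shortest piece a gap may leave behind
_CLEARANCE_UM = 1.6      # min distance between non-adjacent segments
_MAX_RADIAL_DEV = math.radians(55.0)  # growth stays within this of radial


# --------------------------------------------------------------------------
# specifications


@dataclass(frozen=True)
class MorphClassSpec:
    """Generative parameters of one morphology class.

    ``soma_radius_um`` and ``segment_length_um`` are (mean, sd) pairs;
    ``n_primary_processes`` is an inclusive (lo, hi) integer range sampled
    uniformly. ``branch_prob`` is the per-segment probability of a
    bifurcation (while depth < ``max_depth``); ``fragmentation_prob`` the
    per-segment probability of a beading gap. ``marker_means`` maps marker
    name to the class-mean intensity (arbitrary units); per-cell values
    are lognormal with coefficient of variation ``marker_cv``.
    """

    class_name: str
    soma_radius_um: tuple[float, float]
    n_primary_processes: tuple[int, int]
    segment_length_um: tuple[float, float]
    branch_prob: float
    max_depth: int
    fragmentation_prob: float
    marker_means: dict[str, float]
    marker_cv: float = 0.25

    def validate(self) -> None:
        if self.class_name not in {"ramified", "hypertrophic", "dystrophic"}:
            raise ValueError(f"unknown morphology class {self.class_name!r}")
        if self.soma_radius_um[0] <= 0:
            raise ValueError("soma radius must be positive")
        for p in (self.branch_prob, self.fragmentation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_primary_processes[0] < 0 or (
            self.n_primary_processes[1] < self.n_primary_processes[0]
        ):
            raise ValueError("invalid primary-process range")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if any(v < 0 for v in self.marker_means.values()):
            raise ValueError("marker means must be non-negative")


def default_class_specs() -> dict[str, MorphClassSpec]:
    """Default generative parameters for the three morphology classes.

    Soma radii 3/6/3 um, 5/4/3 primary processes and branch probabilities
    0.6/0.2/0.2 for ramified/hypertrophic/dystrophic give the expected
    qualitative ordering: hypertrophic somata largest, ramified cells most
    branched, dystrophic processes fragmented. CD68 and Iba1 class means
    put hypertrophic and dystrophic cells above ramified ones.
    """
    return {
        "ramified": MorphClassSpec(
            class_name="ramified",
            soma_radius_um=(3.0, 0.3),
            n_primary_processes=(4, 6),
            segment_length_um=(6.0, 1.5),
            branch_prob=0.6,
            max_depth=3,
            fragmentation_prob=0.0,
            marker_means={"iba1": 120.0, "cd68": 40.0, "hladr": 70.0},
        ),
        "hypertrophic": MorphClassSpec(
            class_name="hypertrophic",
            soma_radius_um=(6.0, 0.5),
            n_primary_processes=(3, 5),
            segment_length_um=(5.0, 1.2),
            branch_prob=0.2,
            max_depth=2,
            fragmentation_prob=0.0,
            marker_means={"iba1": 210.0, "cd68": 150.0, "hladr": 95.0},
        ),
        "dystrophic": MorphClassSpec(
            class_name="dystrophic",
            soma_radius_um=(3.0, 0.3),
            n_primary_processes=(2, 4),
            segment_length_um=(4.5, 1.2),
            branch_prob=0.2,
            max_depth=2,
            fragmentation_prob=0.5,
            marker_means={"iba1": 180.0, "cd68": 125.0, "hladr": 85.0},
        ),
    }


@dataclass(frozen=True)
class NoiseModel:
    background: float = 15.0
    read_noise_sd: float = 12.0
    shot_noise: bool = False


@dataclass(frozen=True)
class GroupSpec:
    name: str
    n_cases: int
    class_mixture: dict[str, float]
    ptdp43_density_per_mm2: float = 0.0

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class mixture of group {self.name!r} sums to {total}, not 1")
        if any(p < 0 for p in self.class_mixture.values()):
            raise ValueError("mixture probabilities must be >= 0")
        if self.ptdp43_density_per_mm2 < 0:
            raise ValueError("pTDP-43 density must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort.

    One image is rendered per case. ``cells_per_image`` is an inclusive
    (lo, hi) range. ``min_separation_um`` is a hard-core distance between
    soma centres; process extent is additionally capped inside each
    cell's territory so watershed domains are unambiguous.
    """

    groups: tuple[GroupSpec, ...]
    class_specs: dict[str, MorphClassSpec] = field(default_factory=default_class_specs)
    markers: tuple[str, ...] = MARKERS_HUMAN
    cells_per_image: tuple[int, int] = (16, 20)
    image_shape_px: tuple[int, int] = (800, 800)
    pixel_size_um: float = 0.32
    min_separation_um: float = 20.0
    process_radius_um: float = 0.25
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("cohort needs at least one group")
        for g in self.groups:
            g.validate()
            for cls in g.class_mixture:
                if cls not in self.class_specs:
                    raise ValueError(f"group {g.name!r} references unknown class {cls!r}")
        for spec in self.class_specs.values():
            spec.validate()
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.min_separation_um <= 0:
            raise ValueError("min_separation_um must be positive")
        if self.cells_per_image[0] < 1 or self.cells_per_image[1] < self.cells_per_image[0]:
            raise ValueError("invalid cells_per_image range")


def default_human_cohort(seed: int = 0, n_control: int = 10, n_stage13: int = 5,
                         n_stage4: int = 5) -> CohortSpec:
    """Human-like three-group cohort: control vs stage 1-3 vs stage 4 ALS.

    Class mixtures shift from mostly ramified (control) toward
    hypertrophic/dystrophic with disease stage, and pTDP-43 aggregate
    burden rises with stage (zero in controls).
    """
    groups = [
        GroupSpec("control", n_control,
                  {"ramified": 0.85, "hypertrophic": 0.10, "dystrophic": 0.05},
                  ptdp43_density_per_mm2=0.0),
        GroupSpec("ALS_stage1_3", n_stage13,
                  {"ramified": 0.55, "hypertrophic": 0.33, "dystrophic": 0.12},
                  ptdp43_density_per_mm2=60.0),
        GroupSpec("ALS_stage4", n_stage4,
                  {"ramified": 0.35, "hypertrophic": 0.35, "dystrophic": 0.30},
                  ptdp43_density_per_mm2=220.0),
    ]
    return CohortSpec(
        groups=tuple(g for g in groups if g.n_cases > 0),
        seed=seed,
    )


def default_mouse_cohort(seed: int = 0) -> CohortSpec:
    """rNLS-like two-genotype x three-timepoint cohort.

    Group labels are ``{genotype}_{wod}wod``. In rNLS groups, Iba1 is
    elevated from 2 weeks off dox while the CD68-high (hypertrophic /
    dystrophic) mixture shift only appears from 4 weeks, so a two-way
    genotype x timepoint analysis should flag Iba1 before CD68.
    """
    specs = default_class_specs()
    ram_hi_iba1 = replace(
        specs["ramified"],
        marker_means={**specs["ramified"].marker_means, "iba1": 180.0},
    )
    specs_early = {**specs, "ramified": ram_hi_iba1}
    control_mix = {"ramified": 0.88, "hypertrophic": 0.08, "dystrophic": 0.04}
    groups = [
        GroupSpec("control_2wod", 4, control_mix),
        GroupSpec("control_4wod", 4, control_mix),
        GroupSpec("control_6wod", 4, control_mix),
        GroupSpec("rNLS_2wod", 5, {"ramified": 0.80, "hypertrophic": 0.14, "dystrophic": 0.06},
                  ptdp43_density_per_mm2=80.0),
        GroupSpec("rNLS_4wod", 5, {"ramified": 0.45, "hypertrophic": 0.40, "dystrophic": 0.15},
                  ptdp43_density_per_mm2=160.0),
        GroupSpec("rNLS_6wod", 5, {"ramified": 0.35, "hypertrophic": 0.30, "dystrophic": 0.35},
                  ptdp43_density_per_mm2=220.0),
    ]
    return CohortSpec(
        groups=tuple(groups),
        class_specs=specs_early,  # rNLS ramified cells already Iba1-high at 2 WOD
        markers=MARKERS_MOUSE,
        seed=seed,
    )


# --------------------------------------------------------------------------
# cell geometry


@dataclass
class CellGeometry:
    """Exact (pre-raster) geometry of one synthetic cell.

    ``pieces`` are the drawn polyline pieces as (p0, p1) point pairs in um
    relative to the soma centre (post-gap: a fragmented segment appears as
    two pieces). ``truth`` holds the exact morphometric quantities of this
    geometry.
    """

    soma_radius_um: float
    pieces: list[tuple[tuple[float, float], tuple[float, float]]]
    truth: dict


def _seg_distance(a0, a1, b0, b1) -> float:
    """Minimum distance between two 2D segments."""

    def pt_seg(p, s0, s1):
        vx, vy = s1[0] - s0[0], s1[1] - s0[1]
        wx, wy = p[0] - s0[0], p[1] - s0[1]
        vv = vx * vx + vy * vy
        t = 0.0 if vv == 0 else max(0.0, min(1.0, (wx * vx + wy * vy) / vv))
        dx, dy = wx - t * vx, wy - t * vy
        return math.hypot(dx, dy)

    # segments are short; endpoint-to-segment distances suffice unless they
    # cross, which the orientation test detects
    def orient(p, q, r):
        return (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])

    d1, d2 = orient(a0, a1, b0), orient(a0, a1, b1)
    d3, d4 = orient(b0, b1, a0), orient(b0, b1, a1)
    if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
        return 0.0
    return min(pt_seg(b0, a0, a1), pt_seg(b1, a0, a1),
               pt_seg(a0, b0, b1), pt_seg(a1, b0, b1))


class _Forest:
    """Drawn pieces of one cell with endpoint connectivity bookkeeping."""

    def __init__(self) -> None:
        self.pieces: list[tuple[tuple[float, float], tuple[float, float]]] = []
        self.segments: list[tuple[tuple[float, float], tuple[float, float]]] = []
        self.degree: dict[tuple[float, float], int] = {}
        self._parent: dict[tuple[float, float], tuple[float, float]] = {}

    def _find(self, a):
        while self._parent[a] != a:
            self._parent[a] = self._parent[self._parent[a]]
            a = self._parent[a]
        return a

    def add_piece(self, p0, p1):
        for p in (p0, p1):
            if p not in self._parent:
                self._parent[p] = p
                self.degree[p] = 0
            self.degree[p] += 1
        ra, rb = self._find(p0), self._find(p1)
        if ra != rb:
            self._parent[ra] = rb
        self.pieces.append((p0, p1))

    def collides(self, s0, s1, clearance: float) -> bool:
        """True if segment (s0, s1) comes closer than ``clearance`` to any
        existing segment it does not share an endpoint with."""
        for (q0, q1) in self.segments:
            if s0 in (q0, q1) or s1 in (q0, q1):
                continue
            if _seg_distance(s0, s1, q0, q1) < clearance:
                return True
        return False

    @property
    def n_components(self) -> int:
        return len({self._find(p) for p in self._parent})

    @property
    def branch_number(self) -> int:
        return sum(1 for d in self.degree.values() if d >= 3)


def generate_cell(spec: MorphClassSpec, rng: np.random.Generator,
                  max_extent_um: float = 40.0) -> CellGeometry:
    """Grow one cell's soma + process forest and measure its exact truth.

    The truth row records, for the *drawn* (post-gap) geometry: the
    number of connected skeleton components (``true_process_number``,
    i.e. what a domain-restricted measurement sees), the pre-gap primary
    count (``true_primary_processes``), summed drawn length
    (``true_outgrowth_um``) and the number of bifurcation nodes
    (``true_branch_number``).
    """
    spec.validate()
    soma_r = float(np.clip(rng.normal(*spec.soma_radius_um),
                           max(0.5, spec.soma_radius_um[0] - 2 * spec.soma_radius_um[1]),
                           spec.soma_radius_um[0] + 2 * spec.soma_radius_um[1]))
    soma_r = max(soma_r, 1.5)
    lo, hi = spec.n_primary_processes
    n_primary = int(rng.integers(lo, hi + 1))

    forest = _Forest()
    stats = {"len": 0.0, "gaps": 0, "primaries": 0}

    if n_primary > 0:
        base = rng.uniform(0.0, 2.0 * math.pi)
        spacing = 2.0 * math.pi / n_primary
        for i in range(n_primary):
            angle = base + i * spacing + rng.uniform(-0.10, 0.10) * spacing
            root = (soma_r * math.cos(angle), soma_r * math.sin(angle))
            direction = angle + math.radians(rng.uniform(-10.0, 10.0))
            before = stats["len"]
            _grow(spec, rng, root, direction, depth=1, max_extent=max_extent_um,
                  forest=forest, stats=stats)
            if stats["len"] > before:
                stats["primaries"] += 1

    truth = {
        "true_class": spec.class_name,
        "true_soma_radius_um": soma_r,
        "true_soma_area_um2": math.pi * soma_r**2,
        "true_primary_processes": stats["primaries"],
        "true_process_number": forest.n_components,
        "true_outgrowth_um": stats["len"],
        "true_branch_number": forest.branch_number,
        "true_n_gaps": stats["gaps"],
    }
    for marker, mean in spec.marker_means.items():
        if mean <= 0:
            truth[f"true_{marker}"] = 0.0
            continue
        sigma2 = math.log(1.0 + spec.marker_cv**2)
        mu = math.log(mean) - sigma2 / 2.0
        truth[f"true_{marker}"] = float(rng.lognormal(mu, math.sqrt(sigma2)))
    return CellGeometry(soma_radius_um=soma_r, pieces=forest.pieces, truth=truth)


def _radial_clamp(direction: float, point: tuple[float, float]) -> float:
    """Clamp ``direction`` to within _MAX_RADIAL_DEV of the outward radial
    direction at ``point`` so processes never curl back to the soma."""
    radial = math.atan2(point[1], point[0])
    dev = (direction - radial + math.pi) % (2.0 * math.pi) - math.pi
    dev = max(-_MAX_RADIAL_DEV, min(_MAX_RADIAL_DEV, dev))
    return radial + dev


def _grow(spec, rng, start, direction, depth, max_extent, forest, stats):
    """Recursively grow one segment and its children.

    Segments are rejected (up to a few retries with a new direction) when
    they would come within the clearance distance of a non-adjacent
    segment, which keeps the drawn forest topology identical to the
    generated tree after rasterization.
    """
    direction = _radial_clamp(direction, start)
    length = float(np.clip(rng.normal(*spec.segment_length_um),
                           0.5 * spec.segment_length_um[0],
                           1.5 * spec.segment_length_um[0]))

    fragment = rng.random() < spec.fragmentation_prob
    min_frag_len = _GAP_LENGTH_UM + 2.0 * _MIN_PIECE_UM
    if fragment:
        length = max(length, min_frag_len + 0.5)

    end = None
    for _ in range(8):
        ux, uy = math.cos(direction), math.sin(direction)
        # cap the segment so the endpoint stays inside the allowed extent
        cap = length
        if math.hypot(start[0] + length * ux, start[1] + length * uy) > max_extent:
            b = start[0] * ux + start[1] * uy
            c = start[0] ** 2 + start[1] ** 2 - max_extent**2
            t = -b + math.sqrt(max(b * b - c, 0.0))
            cap = min(length, max(t, 0.0))
        if cap < _MIN_SEGMENT_UM:
            return
        candidate = (start[0] + cap * ux, start[1] + cap * uy)
        if not forest.collides(start, candidate, _CLEARANCE_UM):
            end = candidate
            length = cap
            break
        direction = _radial_clamp(
            direction + math.radians(rng.uniform(-25.0, 25.0)), start)
    if end is None:
        return

    forest.segments.append((start, end))
    if fragment and length >= min_frag_len:
        ux, uy = math.cos(direction), math.sin(direction)
        centre_t = rng.uniform(0.45, 0.55) * length
        g0 = centre_t - _GAP_LENGTH_UM / 2.0
        g1 = centre_t + _GAP_LENGTH_UM / 2.0
        mid0 = (start[0] + g0 * ux, start[1] + g0 * uy)
        mid1 = (start[0] + g1 * ux, start[1] + g1 * uy)
        forest.add_piece(start, mid0)
        forest.add_piece(mid1, end)
        stats["len"] += length - _GAP_LENGTH_UM
        stats["gaps"] += 1
    else:
        forest.add_piece(start, end)
        stats["len"] += length

    if depth >= spec.max_depth:
        return
    budget = max_extent - math.hypot(*end)
    if rng.random() < spec.branch_prob and budget >= 1.6 * _MIN_SEGMENT_UM:
        # bifurcate with a wide opening angle so the rasterized arms
        # separate within a couple of pixels of the junction
        half_open = math.radians(rng.uniform(25.0, 40.0))
        for sign in (-1.0, 1.0):
            _grow(spec, rng, end, direction + sign * half_open, depth + 1,
                  max_extent, forest, stats)
    else:
        jitter = math.radians(rng.uniform(-15.0, 15.0))
        _grow(spec, rng, end, direction + jitter, depth + 1,
              max_extent, forest, stats)


# --------------------------------------------------------------------------
# rasterization


def _draw_disk(img: np.ndarray, centre_px: tuple[float, float], radius_px: float,
               value: float, accumulate: bool = False) -> None:
    from skimage.draw import disk

    rr, cc = disk(centre_px, radius_px, shape=img.shape)
    if accumulate:
        img[rr, cc] += value
    else:
        img[rr, cc] = np.maximum(img[rr, cc], value)


def _stamp_footprint(mask: np.ndarray, geometry: CellGeometry,
                     centre_px: tuple[float, float], pixel_size_um: float,
                     process_radius_um: float) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize one cell into boolean (soma, processes) masks.

    Process polylines are drawn 1 px wide, then dilated by the process
    radius with a disk when the radius spans a full pixel; anti-aliasing
    is off, so the noise-free footprint is exactly reproducible. At the
    default 0.25 um radius and 0.32 um pixels (a typical 20x/0.9 NA
    sampling) the ribbons stay one pixel wide (fine distal processes).
    """
    from skimage.draw import disk, line
    from skimage.morphology import binary_dilation, disk as disk_se

    soma = np.zeros(mask.shape, dtype=bool)
    rr, cc = disk(centre_px, geometry.soma_radius_um / pixel_size_um, shape=mask.shape)
    soma[rr, cc] = True

    proc = np.zeros(mask.shape, dtype=bool)
    for (p0, p1) in geometry.pieces:
        r0 = int(round(centre_px[0] + p0[1] / pixel_size_um))
        c0 = int(round(centre_px[1] + p0[0] / pixel_size_um))
        r1 = int(round(centre_px[0] + p1[1] / pixel_size_um))
        c1 = int(round(centre_px[1] + p1[0] / pixel_size_um))
        r0 = np.clip(r0, 0, mask.shape[0] - 1)
        c0 = np.clip(c0, 0, mask.shape[1] - 1)
        r1 = np.clip(r1, 0, mask.shape[0] - 1)
        c1 = np.clip(c1, 0, mask.shape[1] - 1)
        rr, cc = line(r0, c0, r1, c1)
        proc[rr, cc] = True
    radius_px = int(process_radius_um / pixel_size_um)  # floor: sub-pixel radii stay 1-px lines
    if radius_px >= 1:
        proc = binary_dilation(proc, disk_se(radius_px))
    proc &= ~soma
    return soma, proc


@dataclass
class SyntheticCase:
    case_id: str
    group: str
    channels: dict[str, np.ndarray]      # channel name -> 2D float32 image
    roi: np.ndarray                      # 2D bool
    soma_centres_px: list[tuple[float, float]]
    soma_labels: np.ndarray              # int label image of true somata
    pixel_size_um: float


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    cases: list[SyntheticCase]
    metadata: pd.DataFrame               # case_id, group, ...
    truth: pd.DataFrame                  # one row per rendered cell

    def case(self, case_id: str) -> SyntheticCase:
        for c in self.cases:
            if c.case_id == case_id:
                return c
        raise KeyError(case_id)


def _place_somata(rng, n_cells, shape, pixel_size_um, min_sep_um, margin_um):
    """Hard-core rejection placement of soma centres (in px, row/col)."""
    min_sep_px = min_sep_um / pixel_size_um
    margin_px = margin_um / pixel_size_um
    h, w = shape
    centres: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 20000
    while len(centres) < n_cells and attempts < max_attempts:
        attempts += 1
        r = rng.uniform(margin_px, h - margin_px)
        c = rng.uniform(margin_px, w - margin_px)
        if all((r - r2) ** 2 + (c - c2) ** 2 >= min_sep_px**2 for r2, c2 in centres):
            centres.append((r, c))
    if len(centres) < n_cells:
        raise RuntimeError(
            f"could not place {n_cells} somata at {min_sep_um} um separation "
            f"in a {h}x{w} px image"
        )
    return centres


def render_cohort(cohort: CohortSpec) -> SyntheticCohort:
    """Render every case of the cohort to multi-channel images + truth.

    Deterministic: the same ``CohortSpec`` (including its seed) yields
    bit-identical images and tables.
    """
    cohort.validate()
    root = np.random.SeedSequence(cohort.seed)
    case_specs = []
    for g in cohort.groups:
        for i in range(g.n_cases):
            case_specs.append((f"{g.name}_{i + 1:02d}", g))
    seeds = root.spawn(len(case_specs))

    cases = []
    truth_rows = []
    meta_rows = []
    for (case_id, group), ss in zip(case_specs, seeds):
        rng = np.random.default_rng(ss)
        case = _render_case(case_id, group, cohort, rng, truth_rows)
        cases.append(case)
        meta_rows.append(
            {"case_id": case_id, "group": group.name,
             "roi_area_um2": float(case.roi.sum()) * cohort.pixel_size_um**2}
        )
    truth = pd.DataFrame(truth_rows)
    metadata = pd.DataFrame(meta_rows)
    return SyntheticCohort(spec=cohort, cases=cases, metadata=metadata, truth=truth)


def _render_case(case_id, group: GroupSpec, cohort: CohortSpec, rng, truth_rows):
    shape = cohort.image_shape_px
    px = cohort.pixel_size_um
    roi = np.zeros(shape, dtype=bool)
    roi[4:-4, 4:-4] = True

    n_cells = int(rng.integers(cohort.cells_per_image[0], cohort.cells_per_image[1] + 1))
    max_soma_r = max(s.soma_radius_um[0] + 2 * s.soma_radius_um[1]
                     for s in cohort.class_specs.values())
    centres = _place_somata(rng, n_cells, shape, px,
                            cohort.min_separation_um, margin_um=max_soma_r + 3.0)

    # per-cell extent cap: stay inside own territory and inside the ROI
    centres_arr = np.array(centres)
    extents = []
    for i, (r, c) in enumerate(centres):
        if len(centres) > 1:
            d2 = np.sum((centres_arr - centres_arr[i]) ** 2, axis=1)
            d2[i] = np.inf
            nn_um = math.sqrt(d2.min()) * px
        else:
            nn_um = 1e9
        border_um = min(r - 4, c - 4, shape[0] - 5 - r, shape[1] - 5 - c) * px
        extents.append(max(min(nn_um / 2.0 - 2.5, border_um - 1.0), 3.0))

    class_names = sorted(group.class_mixture)
    probs = np.array([group.class_mixture[c] for c in class_names])
    assigned = rng.choice(len(class_names), size=n_cells, p=probs)

    channels = {m: np.zeros(shape, dtype=np.float64) for m in cohort.markers}
    soma_labels = np.zeros(shape, dtype=np.int32)

    for i, ((r, c), cls_idx) in enumerate(zip(centres, assigned)):
        spec = cohort.class_specs[class_names[cls_idx]]
        geom = generate_cell(spec, rng, max_extent_um=extents[i])
        soma, proc = _stamp_footprint(soma_labels > -1, geom, (r, c), px,
                                      cohort.process_radius_um)
        footprint = soma | proc
        label = i + 1
        soma_labels[soma] = label

        iba1 = geom.truth.get("true_iba1", 0.0)
        if "iba1" in channels:
            channels["iba1"][footprint] = np.maximum(channels["iba1"][footprint], iba1)
        if "hladr" in channels:
            hladr = geom.truth.get("true_hladr", 0.0)
            channels["hladr"][footprint] = np.maximum(channels["hladr"][footprint], hladr)
        if "cd68" in channels:
            cd68 = geom.truth.get("true_cd68", 0.0)
            # diffuse somal signal plus brighter perinuclear puncta
            channels["cd68"][soma] = np.maximum(channels["cd68"][soma], 0.5 * cd68)
            n_puncta = max(1, int(round(cd68 / 40.0)))
            for _ in range(n_puncta):
                ang = rng.uniform(0, 2 * math.pi)
                rad = rng.uniform(0.2, 0.75) * geom.soma_radius_um / px
                _draw_disk(channels["cd68"],
                           (r + rad * math.sin(ang), c + rad * math.cos(ang)),
                           max(1.0, 0.8 / px), 2.0 * cd68)
        if "hoechst" in channels:
            _draw_disk(channels["hoechst"], (r, c),
                       0.55 * geom.soma_radius_um / px, 150.0)

        row = {"cell_id": f"{case_id}_c{label:03d}", "case_id": case_id,
               "group": group.name, "label": label,
               "centre_row_px": r, "centre_col_px": c,
               "max_extent_um": extents[i]}
        row.update(geom.truth)
        truth_rows.append(row)

    if "hoechst" in channels:  # non-microglial nuclei (neurons etc.)
        for _ in range(2 * n_cells):
            rr = rng.uniform(6, shape[0] - 6)
            cc = rng.uniform(6, shape[1] - 6)
            _draw_disk(channels["hoechst"], (rr, cc), rng.uniform(2.5, 4.0) / px, 150.0)

    if "ptdp43" in channels and group.ptdp43_density_per_mm2 > 0:
        roi_area_mm2 = roi.sum() * (px / 1000.0) ** 2
        n_agg = int(rng.poisson(group.ptdp43_density_per_mm2 * roi_area_mm2))
        for _ in range(n_agg):
            rr = rng.uniform(6, shape[0] - 6)
            cc = rng.uniform(6, shape[1] - 6)
            _draw_disk(channels["ptdp43"], (rr, cc),
                       max(1.0, rng.normal(1.4, 0.25) / px), 800.0)

    noise = cohort.noise
    for name, img in channels.items():
        img = img + noise.background
        if noise.shot_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
        if noise.read_noise_sd > 0:
            img = img + rng.normal(0.0, noise.read_noise_sd, size=img.shape)
        channels[name] = np.clip(img, 0.0, None).astype(np.float32)

    return SyntheticCase(case_id=case_id, group=group.name, channels=channels,
                         roi=roi, soma_centres_px=centres,
                         soma_labels=soma_labels, pixel_size_um=px)


# --------------------------------------------------------------------------
# feature-level sampling (no rasterization)


def sample_cell_features(
    class_specs: dict[str, MorphClassSpec] | None = None,
    n_per_class: int = 1000,
    seed: int = 0,
    markers: tuple[str, ...] = ("iba1", "cd68"),
    max_extent_um: float = 14.0,
) -> pd.DataFrame:
    """Draw per-cell feature vectors straight from the generative model.

    Produces the same class-conditional morphology and marker statistics
    as a render-and-measure round trip, without rasterizing images; used
    for clustering experiments where thousands of cells are needed.
    ``max_extent_um`` matches the typical territory cap of the default
    rendering density.
    """
    specs = class_specs or default_class_specs()
    rng = np.random.default_rng(seed)
    rows = []
    for cls in sorted(specs):
        spec = specs[cls]
        for i in range(n_per_class):
            geom = generate_cell(spec, rng, max_extent_um=max_extent_um)
            t = geom.truth
            row = {
                "cell_id": f"{cls}_{i:05d}",
                "true_class": cls,
                "cell_body_area": t["true_soma_area_um2"],
                "process_number": t["true_process_number"],
                "total_outgrowth": t["true_outgrowth_um"],
                "branch_number": t["true_branch_number"],
            }
            for m in markers:
                row[m] = t.get(f"true_{m}", 0.0)
            rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# disk I/O


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write images (multi-channel TIFF), ROI masks, metadata and truth.

    Channel names are recorded in the TIFF ImageDescription metadata.
    """
    import json
    from pathlib import Path

    import tifffile

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    for case in cohort.cases:
        stack = np.stack([case.channels[m] for m in cohort.spec.markers])
        tifffile.imwrite(
            out / "images" / f"{case.case_id}.tif", stack,
            description=json.dumps(
                {"channels": list(cohort.spec.markers),
                 "pixel_size_um": case.pixel_size_um}),
        )
        tifffile.imwrite(out / "images" / f"{case.case_id}_roi.tif",
                         case.roi.astype(np.uint8) * 255)
    cohort.metadata.to_csv(out / "metadata.csv", index=False)
    cohort.truth.to_csv(out / "truth.csv", index=False)
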