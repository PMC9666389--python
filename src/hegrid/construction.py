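"""Build a risk grid from clinician questionnaire responses.

Each rater defines five glucose ranges via four ascending cutpoints in
(0, 10) mmol/L and assigns a risk category (A-D) to every (true range,
measured range) combination — a 5x5 matrix. The pipeline is:

1. rasterize each response over the 100x100 grid ([0, 10) mmol/L at 0.1);
2. collate responses to a per-cell mean numeric risk (A=1 ... D=4);
3. discretize the mean back to categories (half rounds up, toward risk);
4. optionally merge slim regions into their most severe neighbour;
5. replace staggered (staircase) boundaries with least-squares straight
   lines, leaving horizontal/vertical boundaries untouched;
6. emit zone polygons, optionally extended beyond 10 mmol/L with the edge
   zones prolonged unchanged.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import LineString, Polygon, box
from shapely.ops import polygonize, unary_union

from .grid import RiskGrid
from .units import MMOLL
from .zones import RISK_SCORE, RiskZone

logger = logging.getLogger(__name__)

N_CELLS = 100
RESOLUTION = 0.1


class ResponseError(ValueError):
    """Raised for malformed rater responses."""


@dataclass(frozen=True)
class RaterResponse:
    """One clinician's questionnaire answers.

    ``risk[i, j]`` is the category assigned when the true (SMBG) glucose
    falls in range ``i`` and the measured (CGM) glucose in range ``j``;
    ranges are half-open, lower-inclusive, delimited by the four cutpoints.
    """

    rater_id: str
    cutpoints: tuple[float, float, float, float]
    risk: tuple  # 5x5 nested tuple of RiskZone

    def __post_init__(self):
        cps = tuple(float(c) for c in self.cutpoints)
        if len(cps) != 4:
            raise ResponseError(f"{self.rater_id}: expected 4 cutpoints, got {len(cps)}")
        if any(not (0.0 < c < 10.0) for c in cps):
            raise ResponseError(f"{self.rater_id}: cutpoints must lie in (0, 10) mmol/L")
        if any(b <= a for a, b in zip(cps, cps[1:])):
            raise ResponseError(f"{self.rater_id}: cutpoints must be strictly ascending")
        object.__setattr__(self, "cutpoints", cps)
        matrix = tuple(
            tuple(RiskZone.from_label(z) if not isinstance(z, RiskZone) else z for z in row)
            for row in self.risk
        )
        if len(matrix) != 5 or any(len(row) != 5 for row in matrix):
            raise ResponseError(f"{self.rater_id}: risk matrix must be 5x5")
        if any(z not in RISK_SCORE for row in matrix for z in row):
            raise ResponseError(f"{self.rater_id}: questionnaire risks must be A-D")
        object.__setattr__(self, "risk", matrix)
        if any(matrix[i][i] != RiskZone.A for i in range(5)):
            warnings.warn(
                f"rater {self.rater_id}: same-range (diagonal) cells are not all "
                "risk A — unusual for a no-discrepancy scenario",
                stacklevel=2,
            )

    def risk_array(self) -> np.ndarray:
        return np.array([[RISK_SCORE[z] for z in row] for row in self.risk], dtype=int)


@dataclass
class MeanRiskGrid:
    """Per-cell mean numeric risk over the 100x100 raster."""

    mean: np.ndarray  # shape (100, 100), float in [1, 4]; [i, j] = (smbg, cgm) cell
    n_raters: int

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        if self.mean.shape != (N_CELLS, N_CELLS):
            raise ValueError(f"mean risk raster must be {N_CELLS}x{N_CELLS}")
        if self.mean.min() < 1.0 - 1e-9 or self.mean.max() > 4.0 + 1e-9:
            raise ValueError("mean risk must lie in [1, 4]")


def _range_index(values: np.ndarray, cutpoints) -> np.ndarray:
    # lower-inclusive half-open ranges: value == cutpoint goes to the upper range
    return np.searchsorted(np.asarray(cutpoints), values, side="right")


def rasterize_response(response: RaterResponse) -> np.ndarray:
    """Plot one rater's categories across the 100x100 grid.

    Cell membership is decided by the cell-centre value against the rater's
    cutpoints. Returns an int array (A=1 ... D=4) indexed [smbg, cgm].
    """
    centres = (np.arange(N_CELLS) + 0.5) * RESOLUTION
    idx = _range_index(centres, response.cutpoints)
    risk = response.risk_array()
    return risk[np.ix_(idx, idx)]


def collate(responses) -> MeanRiskGrid:
    """Mean numeric risk (A=1 ... D=4) per cell over all raters."""
    responses = list(responses)
    if not responses:
        raise ResponseError("need at least one rater response to collate")
    stack = np.stack([rasterize_response(r) for r in responses]).astype(float)
    return MeanRiskGrid(mean=stack.mean(axis=0), n_raters=len(responses))


def discretize(mean_grid: MeanRiskGrid) -> np.ndarray:
    """Nearest-integer category per cell; exact .5 rounds up (toward risk)."""
    return np.floor(mean_grid.mean + 0.5).astype(int)


# ---------------------------------------------------------------------------
# boundary smoothing


@dataclass
class SmoothingConfig:
    """Knobs for staircase smoothing and region merging.

    min_alternations : minimum number of consecutive unit-step direction
        changes for a boundary section to count as staggered (default 3).
    merge_width : regions slimmer than this (mmol/L) are absorbed into
        their most severe adjacent region before smoothing (default 0.3,
        i.e. three raster cells).
    line_overrides : optional {(low_zone, high_zone): (slope, intercept)}
        forcing the smoothed y = slope*x + intercept boundary between a zone
        pair, standing in for the consensus panel's manual placements.
    """

    min_alternations: int = 3
    merge_width: float = 0.3
    line_overrides: dict = field(default_factory=dict)


@dataclass
class SmoothingDiagnostics:
    n_staircase_runs: int = 0
    n_staircase_cells: int = 0
    n_cells_changed: int = 0
    fitted_lines: list = field(default_factory=list)  # (zlo, zhi, slope, intercept)


def merge_slim_regions(raster: np.ndarray, merge_width: float = 0.3) -> np.ndarray:
    """Absorb connected regions slimmer than ``merge_width`` into the most
    severe adjacent zone (mirrors the hand-merge of the slim column in the
    consensus grid). Width is the smaller bounding-box dimension."""
    out = raster.copy()
    width_cells = int(round(merge_width / RESOLUTION))
    if width_cells <= 0:
        return out
    changed = True
    while changed:
        changed = False
        for value in np.unique(out):
            mask = out == value
            labels, n = ndimage.label(mask)
            for comp in range(1, n + 1):
                comp_mask = labels == comp
                xs, ys = np.nonzero(comp_mask)
                w = min(xs.max() - xs.min() + 1, ys.max() - ys.min() + 1)
                if w >= width_cells:
                    continue
                ring = ndimage.binary_dilation(comp_mask) & ~comp_mask
                neighbours = out[ring]
                if neighbours.size == 0:
                    continue
                target = int(neighbours.max())
                if target == value:
                    continue
                out[comp_mask] = target
                changed = True
    return out


def _boundary_edges(raster: np.ndarray):
    """Unit edges between cells of different zones.

    Each edge is ((a, b), (c, d)) in lattice coordinates (cell-size units)
    with the unordered zone pair it separates.
    """
    edges = {}
    nx, ny = raster.shape
    for i in range(nx - 1):
        for j in range(ny):
            za, zb = raster[i, j], raster[i + 1, j]
            if za != zb:
                e = ((i + 1, j), (i + 1, j + 1))
                edges[e] = tuple(sorted((int(za), int(zb))))
    for i in range(nx):
        for j in range(ny - 1):
            za, zb = raster[i, j], raster[i, j + 1]
            if za != zb:
                e = ((i, j + 1), (i + 1, j + 1))
                edges[e] = tuple(sorted((int(za), int(zb))))
    return edges


def _chain_edges(edge_list):
    """Chain unit edges sharing endpoints into vertex polylines."""
    from collections import defaultdict

    adj = defaultdict(list)
    for a, b in edge_list:
        adj[a].append(b)
        adj[b].append(a)
    chains = []
    edge_set = {(min(a, b), max(a, b)) for a, b in edge_list}

    def neighbours(v, used):
        out = []
        for w in adj[v]:
            e = (min(v, w), max(v, w))
            if e in edge_set and e not in used:
                out.append(w)
        return out

    used = set()
    # start at odd-degree vertices first (open chains), then cycles
    starts = [v for v in adj if len(adj[v]) % 2 == 1 or len(adj[v]) == 1]
    starts += list(adj)
    for start in starts:
        while True:
            nbrs = neighbours(start, used)
            if not nbrs:
                break
            chain = [start]
            v = start
            while True:
                nbrs = neighbours(v, used)
                if not nbrs:
                    break
                w = nbrs[0]
                used.add((min(v, w), max(v, w)))
                chain.append(w)
                v = w
            if len(chain) > 1:
                chains.append(chain)
    return chains


def _step_directions(chain):
    return ["H" if b[1] == a[1] else "V" for a, b in zip(chain, chain[1:])]


def _staggered_runs(chain, min_alternations: int):
    """Maximal sub-chains whose unit steps alternate H/V for at least
    ``min_alternations`` direction changes. Returns (start, end) vertex
    index pairs into ``chain``."""
    dirs = _step_directions(chain)
    runs = []
    k = 0
    while k < len(dirs) - 1:
        if dirs[k] != dirs[k + 1]:
            m = k
            while m < len(dirs) - 1 and dirs[m] != dirs[m + 1]:
                m += 1
            n_alt = m - k  # number of direction changes in the window
            if n_alt >= min_alternations:
                runs.append((k, m + 1))  # vertex indices [k, m+1]
            k = m
        else:
            k += 1
    return runs


def _severe_side_corners(chain, lo, hi, raster, zhigh):
    """Vertices of the run where the more severe zone occupies the majority
    of the incident cells — the corners the consensus line passes through."""
    nx, ny = raster.shape
    pts = []
    for idx in range(lo, hi + 1):
        a, b = chain[idx]
        n_sev = n_other = 0
        for ci, cj in ((a - 1, b - 1), (a, b - 1), (a - 1, b), (a, b)):
            if 0 <= ci < nx and 0 <= cj < ny:
                if raster[ci, cj] == zhigh:
                    n_sev += 1
                else:
                    n_other += 1
        if n_sev > n_other:
            pts.append((a, b))
    return pts


def _fit_line(points):
    """Least-squares line through lattice points.

    Returns ("y", a, b) for y = a*x + b or ("x", a, b) for x = a*y + b,
    choosing the orientation with the larger coordinate spread.
    """
    pts = np.asarray(points, dtype=float)
    dx = np.ptp(pts[:, 0])
    dy = np.ptp(pts[:, 1])
    if dx >= dy:
        a, b = np.polyfit(pts[:, 0], pts[:, 1], 1)
        return ("y", float(a), float(b))
    a, b = np.polyfit(pts[:, 1], pts[:, 0], 1)
    return ("x", float(a), float(b))


def _line_signed(form, a, b, x, y):
    if form == "y":
        return y - (a * x + b)
    return x - (a * y + b)


def _project(form, a, b, x, y):
    """Foot of the perpendicular from (x, y) onto the fitted line."""
    if form == "y":
        # line: y = a x + b
        t = (x + a * (y - b)) / (1 + a * a)
        return (t, a * t + b)
    t = (y + a * (x - b)) / (1 + a * a)
    return (a * t + b, t)


def smooth_boundaries(
    raster: np.ndarray,
    config: SmoothingConfig | None = None,
    name: str = "consensus",
    version: str = "0.1.0",
):
    """Convert a discretized raster into a polygon grid with staggered
    boundaries replaced by straight lines.

    Horizontal/vertical boundary sections are left untouched. For each
    staggered section a least-squares line is fitted through its
    severe-side step corners; cells incident to the section are reassigned
    by which side of the line their centre lies (centres exactly on the
    line go to the more severe zone). Returns ``(RiskGrid, diagnostics)``;
    the grid covers [0, 10]^2 mmol/L.
    """
    if config is None:
        config = SmoothingConfig()
    raster = np.asarray(raster, dtype=int)
    diag = SmoothingDiagnostics()
    working = raster.copy()

    edges = _boundary_edges(raster)
    by_pair = {}
    for e, pair in edges.items():
        by_pair.setdefault(pair, []).append(e)

    # linework for polygonization, in lattice units
    lines = []
    replaced_edges = set()

    for (zlo, zhi), edge_list in sorted(by_pair.items()):
        for chain in _chain_edges(edge_list):
            runs = _staggered_runs(chain, config.min_alternations)
            covered = set()
            for lo, hi in runs:
                override = config.line_overrides.get((zlo, zhi))
                if override is not None:
                    slope, intercept = override
                    form, a, b = "y", float(slope), float(intercept) / RESOLUTION
                else:
                    pts = _severe_side_corners(chain, lo, hi, raster, zhi)
                    if len(pts) < 2:
                        continue
                    form, a, b = _fit_line(pts)
                diag.n_staircase_runs += 1
                diag.fitted_lines.append(
                    (zlo, zhi, form, a, b * RESOLUTION if form in ("y", "x") else b)
                )
                # reassign cells incident to the run's edges
                incident = set()
                for k in range(lo, hi):
                    va, vb = chain[k], chain[k + 1]
                    replaced_edges.add((min(va, vb), max(va, vb)))
                    if va[0] == vb[0]:  # vertical edge separates x-neighbours
                        x = va[0]
                        j = min(va[1], vb[1])
                        for ci in (x - 1, x):
                            if 0 <= ci < raster.shape[0]:
                                incident.add((ci, j))
                    else:  # horizontal edge separates y-neighbours
                        y = va[1]
                        i = min(va[0], vb[0])
                        for cj in (y - 1, y):
                            if 0 <= cj < raster.shape[1]:
                                incident.add((i, cj))
                diag.n_staircase_cells += len(incident)
                # which sign of the line is the severe side, by vote of
                # currently-severe incident cells
                sev_signs = []
                for ci, cj in incident:
                    if raster[ci, cj] == zhi:
                        s = _line_signed(form, a, b, ci + 0.5, cj + 0.5)
                        if s != 0:
                            sev_signs.append(np.sign(s))
                severe_sign = np.sign(sum(sev_signs)) or 1.0
                for ci, cj in incident:
                    if raster[ci, cj] not in (zlo, zhi):
                        continue
                    s = _line_signed(form, a, b, ci + 0.5, cj + 0.5)
                    new = zhi if (s == 0 or np.sign(s) == severe_sign) else zlo
                    if working[ci, cj] != new:
                        working[ci, cj] = new
                        diag.n_cells_changed += 1
                # replacement linework: run endpoints joined via their
                # projections onto the fitted line
                v0 = chain[lo]
                v1 = chain[hi]
                # snap projections to 6 decimals: float error here leaves
                # micro cut-edges that break ring assembly in polygonize
                p0 = tuple(round(c, 6) for c in _project(form, a, b, *map(float, v0)))
                p1 = tuple(round(c, 6) for c in _project(form, a, b, *map(float, v1)))
                path = [tuple(map(float, v0)), p0, p1, tuple(map(float, v1))]
                dedup = [path[0]]
                for p in path[1:]:
                    if abs(p[0] - dedup[-1][0]) > 1e-9 or abs(p[1] - dedup[-1][1]) > 1e-9:
                        dedup.append(p)
                if len(dedup) > 1:
                    lines.append(LineString(dedup))
                covered.update(range(lo, hi))
            # untouched sections of the chain stay as-is
            seg = []
            for k in range(len(chain) - 1):
                if k in covered:
                    if len(seg) > 1:
                        lines.append(LineString([tuple(map(float, v)) for v in seg]))
                    seg = []
                else:
                    if not seg:
                        seg = [chain[k]]
                    seg.append(chain[k + 1])
            if len(seg) > 1:
                lines.append(LineString([tuple(map(float, v)) for v in seg]))

    # frame and polygonization (lattice units -> mmol/L at the end)
    n = raster.shape[0]
    frame = box(0, 0, n, n).exterior
    merged = unary_union(lines + [frame])
    faces = list(polygonize(merged))
    # assign each face the majority zone of the cell centres it contains
    # (robust when a cell straddles a fitted line)
    ii, jj = np.meshgrid(np.arange(n) + 0.5, np.arange(n) + 0.5, indexing="ij")
    centre_pts = shapely.points(ii.ravel(), jj.ravel())
    zone_polys = {}
    for face in faces:
        inside = shapely.contains(face, centre_pts)
        if inside.any():
            vals, counts = np.unique(working.ravel()[inside], return_counts=True)
            z = int(vals[np.argmax(counts)])
        else:  # sliver smaller than a cell: fall back to the containing cell
            rep = face.representative_point()
            ci = min(int(rep.x), n - 1)
            cj = min(int(rep.y), n - 1)
            z = int(working[ci, cj])
        zone_polys.setdefault(z, []).append(face)

    zones = []
    for z, polys in sorted(zone_polys.items()):
        union = unary_union(polys)
        geoms = union.geoms if hasattr(union, "geoms") else [union]
        for geom in geoms:
            zones.append((RiskZone(z), shapely_scale_to_mmol(geom)))

    grid = RiskGrid(
        name=name,
        zones=zones,
        domain=((0.0, n * RESOLUTION), (0.0, n * RESOLUTION)),
        resolution=RESOLUTION,
        unit=MMOLL,
        version=version,
        meta={"provenance": "constructed from questionnaire responses"},
    )
    return grid, diag


def shapely_scale_to_mmol(geom: Polygon) -> Polygon:
    from shapely import affinity

    return affinity.scale(geom, xfact=RESOLUTION, yfact=RESOLUTION, origin=(0, 0))


def extend_grid(grid: RiskGrid, to: float = 12.0) -> RiskGrid:
    """Extend a grid's domain, prolonging the edge zones unchanged.

    Risk is taken as constant beyond the current ceiling (the consensus
    panel held risks constant beyond 4.0 mmol/L): the zone at (x, top-) is
    continued through (x, top..to) and symmetrically on the SMBG axis, with
    the corner square taking the corner zone.
    """
    (xlo, xhi), (ylo, yhi) = grid.domain
    if to <= xhi or to <= yhi:
        raise ValueError(f"extension target {to} must exceed current bound {max(xhi, yhi)}")
    eps = grid.resolution / 2.0
    extra = {}

    def strips(axis):
        # sample zone membership along the inner edge at cell-centre spacing
        centres = grid.cell_centres(xlo if axis == "x" else ylo,
                                    xhi if axis == "x" else yhi)
        if axis == "x":
            zones = grid.classify_points(centres, np.full_like(centres, yhi - eps))
        else:
            zones = grid.classify_points(np.full_like(centres, xhi - eps), centres)
        # group consecutive identical zones into rectangles
        out = []
        start = 0
        for k in range(1, len(centres) + 1):
            if k == len(centres) or zones[k] != zones[start]:
                lo_edge = centres[start] - grid.resolution / 2
                hi_edge = centres[k - 1] + grid.resolution / 2
                out.append((zones[start], lo_edge, hi_edge))
                start = k
        return out

    for zone, lo_e, hi_e in strips("x"):  # top strip
        extra.setdefault(zone, []).append(box(lo_e, yhi, hi_e, to))
    for zone, lo_e, hi_e in strips("y"):  # right strip
        extra.setdefault(zone, []).append(box(xhi, lo_e, to, hi_e))
    corner_zone = grid.classify(xhi - eps, yhi - eps)
    extra.setdefault(corner_zone, []).append(box(xhi, yhi, to, to))

    new_zones = []
    grouped = {}
    for zone, poly in grid.zones:
        grouped.setdefault(zone, []).append(poly)
    for zone, polys in extra.items():
        grouped.setdefault(zone, []).extend(polys)
    for zone, polys in sorted(grouped.items()):
        union = unary_union(polys)
        geoms = union.geoms if hasattr(union, "geoms") else [union]
        for geom in geoms:
            new_zones.append((zone, geom))

    return RiskGrid(
        name=grid.name,
        zones=new_zones,
        domain=((xlo, to), (ylo, to)),
        resolution=grid.resolution,
        unit=grid.unit,
        version=grid.version,
        meta=dict(grid.meta),
    )


def build_grid(
    responses,
    config: SmoothingConfig | None = None,
    smooth: bool = True,
    extend_to: float | None = 12.0,
    name: str = "consensus-HEG",
    version: str = "0.1.0",
) -> RiskGrid:
    """Full questionnaire-to-grid pipeline."""
    if config is None:
        config = SmoothingConfig()
    mean = collate(responses)
    raster = discretize(mean)
    raster = merge_slim_regions(raster, config.merge_width)
    if smooth:
        grid, _ = smooth_boundaries(raster, config, name=name, version=version)
    else:
        grid, _ = smooth_boundaries(
            raster, SmoothingConfig(min_alternations=10 ** 9, merge_width=0.0),
            name=name, version=version,
        )
    if extend_to is not None:
        grid = extend_grid(grid, to=extend_to)
    grid.validate()
    return grid


# ---------------------------------------------------------------------------
# rater-response file I/O


def load_responses(path) -> list[RaterResponse]:
    """Read rater responses from JSON (list of records) or CSV.

    JSON record: {"rater_id": ..., "cutpoints": [c1..c4],
    "risk": [[...5 labels...] x5]} with risk[i][j] = (true range i,
    measured range j). CSV: one row per rater with columns rater_id,
    cutpoint_1..4, and risk_i_j for i,j in 0..4.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        return [
            RaterResponse(r["rater_id"], tuple(r["cutpoints"]), tuple(map(tuple, r["risk"])))
            for r in records
        ]
    responses = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            cuts = tuple(float(row[f"cutpoint_{k}"]) for k in range(1, 5))
            risk = tuple(
                tuple(row[f"risk_{i}_{j}"] for j in range(5)) for i in range(5)
            )
            responses.append(RaterResponse(row["rater_id"], cuts, risk))
    return responses


def save_responses(responses, path) -> None:
    payload = [
        {
            "rater_id": r.rater_id,
            "cutpoints": list(r.cutpoints),
            "risk": [[z.name for z in row] for row in r.risk],
        }
        for r in responses
    ]
    Path(path).write_text(json.dumps(payload, indent=2))
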