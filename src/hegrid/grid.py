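"""Error-grid representation and risk-zone classification.

An error grid partitions the (SMBG, CGM) glucose plane into clinical risk
zones. SMBG (the fingerprick reference) is the x axis, CGM the y axis. Zones
are stored as polygons in mmol/L; a raster view over [0, 10) mmol/L at
0.1 mmol/L resolution (the 100x100 = 10,000 cell convention of the consensus
questionnaire) is derived from the polygons on demand.

Classification is deterministic: a point covered by several zone polygons
(i.e. exactly on a shared boundary) is assigned to the most severe of them,
a patient-safety tie-break.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import Polygon

from .units import MGDL, MMOLL, convert_units, normalize_unit
from .zones import RiskZone

logger = logging.getLogger(__name__)

#: Names of the grid definition files bundled with the package.
BUNDLED_GRIDS = {
    "heg": "heg_default.json",
    "clarke": "clarke.json",
    "parkes": "parkes_type1.json",
    "parkes_type1": "parkes_type1.json",
}


class GridSchemaError(ValueError):
    """Raised when a grid definition file is malformed or does not tile."""


class ClampWarning(UserWarning):
    """Emitted when a glucose value above the grid ceiling is clamped."""


def _validate_glucose(value: float, name: str) -> float:
    value = float(value)
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} glucose must be positive and finite, got {value!r}")
    return value


@dataclass(frozen=True)
class GlucosePair:
    """One SMBG (reference) / CGM measurement pair in mmol/L."""

    smbg: float
    cgm: float

    def __post_init__(self):
        object.__setattr__(self, "smbg", _validate_glucose(self.smbg, "SMBG"))
        object.__setattr__(self, "cgm", _validate_glucose(self.cgm, "CGM"))


def is_false_negative(pair, hypo_threshold: float = 3.5) -> bool:
    """True iff the reference shows hypoglycaemia but the CGM does not.

    Hypoglycaemia is strictly below the threshold (UK consensus cutoff
    3.5 mmol/L), so ``smbg < threshold and cgm >= threshold``. This is the
    clinically dangerous error for hyperinsulinism patients.
    """
    if hypo_threshold <= 0:
        raise ValueError("hypo_threshold must be positive")
    if hasattr(pair, "smbg"):
        smbg, cgm = pair.smbg, pair.cgm
    else:
        smbg, cgm = pair
    smbg = _validate_glucose(smbg, "SMBG")
    cgm = _validate_glucose(cgm, "CGM")
    return smbg < hypo_threshold and cgm >= hypo_threshold


def false_negative_mask(smbg, cgm, hypo_threshold: float = 3.5) -> np.ndarray:
    """Vectorised :func:`is_false_negative`."""
    smbg = np.asarray(smbg, dtype=float)
    cgm = np.asarray(cgm, dtype=float)
    return (smbg < hypo_threshold) & (cgm >= hypo_threshold)


@dataclass
class RiskGrid:
    """A named risk surface over (SMBG, CGM) glucose space.

    Parameters
    ----------
    name, version : str
        Identification of the grid definition.
    zones : list of (RiskZone, shapely Polygon)
        Zone polygons in mmol/L. A label may own several polygons; together
        they must tile the domain.
    domain : ((xlo, xhi), (ylo, yhi))
        Extent per axis in mmol/L.
    resolution : float
        Cell width of the raster view (default 0.1 mmol/L).
    """

    name: str
    zones: list[tuple[RiskZone, Polygon]]
    domain: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 12.0), (0.0, 12.0))
    resolution: float = 0.1
    unit: str = MMOLL
    version: str = "unversioned"
    meta: dict = field(default_factory=dict)

    # -- classification ----------------------------------------------------

    def classify_points(self, smbg, cgm, clamp: bool = True) -> np.ndarray:
        """Classify arrays of paired values; returns an array of RiskZone.

        Values above the domain ceiling are clamped to it with a warning
        (the consensus grid tops out at 12 mmol/L and values beyond are
        rare); non-positive or non-finite values raise.
        """
        smbg = np.atleast_1d(np.asarray(smbg, dtype=float)).copy()
        cgm = np.atleast_1d(np.asarray(cgm, dtype=float)).copy()
        if smbg.shape != cgm.shape:
            raise ValueError("smbg and cgm arrays must have the same shape")
        for arr, axis_name in ((smbg, "SMBG"), (cgm, "CGM")):
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                raise ValueError(f"{axis_name} values must be positive and finite")
        (xlo, xhi), (ylo, yhi) = self.domain
        n_clamped = int(np.sum(smbg > xhi) + np.sum(cgm > yhi))
        if n_clamped:
            if not clamp:
                raise ValueError(f"{n_clamped} values above grid ceiling and clamp disabled")
            warnings.warn(
                f"{n_clamped} glucose value(s) above the {self.name} ceiling "
                f"({xhi:g}/{yhi:g} mmol/L) clamped",
                ClampWarning,
                stacklevel=2,
            )
            np.clip(smbg, None, xhi, out=smbg)
            np.clip(cgm, None, yhi, out=cgm)
        points = shapely.points(smbg.ravel(), cgm.ravel())
        out = np.zeros(points.shape, dtype=int)
        # Ascending severity, overwriting: boundary points end up in the
        # most severe covering zone.
        for zone, poly in sorted(self.zones, key=lambda zp: int(zp[0])):
            covered = shapely.covers(poly, points)
            out[covered] = int(zone)
        if np.any(out == 0):
            bad = np.argwhere(out == 0).ravel()[:5]
            pts = [(smbg.ravel()[i], cgm.ravel()[i]) for i in bad]
            raise GridSchemaError(f"grid {self.name!r} does not cover points {pts}")
        return np.array([RiskZone(v) for v in out], dtype=object).reshape(smbg.shape)

    def classify(self, smbg: float, cgm: float, clamp: bool = True) -> RiskZone:
        """Classify a single pair; see :meth:`classify_points`."""
        return self.classify_points([smbg], [cgm], clamp=clamp)[0]

    def classify_pair(self, pair: GlucosePair, clamp: bool = True) -> RiskZone:
        return self.classify(pair.smbg, pair.cgm, clamp=clamp)

    # -- raster view -------------------------------------------------------

    def cell_centres(self, lo: float = 0.0, hi: float = 10.0) -> np.ndarray:
        n = int(round((hi - lo) / self.resolution))
        return lo + (np.arange(n) + 0.5) * self.resolution

    def raster(self, lo: float = 0.0, hi: float = 10.0) -> np.ndarray:
        """Zone raster over [lo, hi) with half-open cells of width
        ``resolution``; entry ``[i, j]`` is the zone of the cell whose SMBG
        index is ``i`` and CGM index ``j``, decided at the cell centre.

        The default covers [0, 10) in 0.1 mmol/L steps: the 100x100 grid of
        10,000 cells used for questionnaire collation.
        """
        c = self.cell_centres(lo, hi)
        xx, yy = np.meshgrid(c, c, indexing="ij")
        zones = self.classify_points(xx.ravel(), yy.ravel())
        return np.array([int(z) for z in zones], dtype=int).reshape(xx.shape)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Check zone polygons tile the domain; raise GridSchemaError if not.

        Coverage is checked at every cell centre of the full-domain raster;
        overlap is checked as pairwise interior intersection area between
        polygons of different labels (shared edges are allowed, they are what
        the severity tie-break is for).
        """
        (xlo, xhi), (ylo, yhi) = self.domain
        if not (xhi > xlo and yhi > ylo):
            raise GridSchemaError("empty grid domain")
        if not self.zones:
            raise GridSchemaError("grid has no zones")
        for zone, poly in self.zones:
            if not poly.is_valid or poly.is_empty:
                raise GridSchemaError(f"invalid polygon for zone {zone.name}")
        cx = self.cell_centres(xlo, xhi)
        cy = self.cell_centres(ylo, yhi)
        xx, yy = np.meshgrid(cx, cy, indexing="ij")
        points = shapely.points(xx.ravel(), yy.ravel())
        covered = np.zeros(points.shape, dtype=bool)
        for _, poly in self.zones:
            covered |= shapely.covers(poly, points)
        if not covered.all():
            holes = np.argwhere(~covered).ravel()
            cells = [(float(xx.ravel()[i]), float(yy.ravel()[i])) for i in holes[:20]]
            raise GridSchemaError(
                f"grid {self.name!r} leaves {holes.size} cell(s) uncovered, "
                f"first centres: {cells}"
            )
        cell_area = self.resolution ** 2
        for i, (za, pa) in enumerate(self.zones):
            for zb, pb in self.zones[i + 1:]:
                if za == zb:
                    continue
                inter = pa.intersection(pb)
                if inter.area > 0.5 * cell_area:
                    raise GridSchemaError(
                        f"zones {za.name} and {zb.name} overlap with area {inter.area:.3g}"
                    )

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "version": self.version,
            "unit": self.unit,
            "domain": [list(self.domain[0]), list(self.domain[1])],
            "resolution": self.resolution,
            "zones": [
                {
                    "label": zone.name,
                    "polygon": [[float(x), float(y)] for x, y in poly.exterior.coords],
                }
                for zone, poly in self.zones
            ],
            **({"meta": self.meta} if self.meta else {}),
        }

    @classmethod
    def from_dict(cls, payload: dict, validate: bool = True) -> "RiskGrid":
        try:
            unit = normalize_unit(payload.get("unit", MMOLL))
            name = payload["name"]
            raw_zones = payload["zones"]
            domain = payload["domain"]
        except KeyError as exc:
            raise GridSchemaError(f"grid definition missing key {exc}") from None
        scale = 1.0 if unit == MMOLL else 1.0 / convert_units(1.0, MMOLL, MGDL)
        zones = []
        for entry in raw_zones:
            zone = RiskZone.from_label(entry["label"])
            coords = [(x * scale, y * scale) for x, y in entry["polygon"]]
            if len(coords) < 3:
                raise GridSchemaError(f"zone {zone.name} polygon has <3 vertices")
            poly = Polygon(coords)
            if not poly.is_valid:
                poly = poly.buffer(0)
            zones.append((zone, poly))
        dom = (
            (domain[0][0] * scale, domain[0][1] * scale),
            (domain[1][0] * scale, domain[1][1] * scale),
        )
        grid = cls(
            name=name,
            zones=zones,
            domain=dom,
            resolution=float(payload.get("resolution", 0.1)),
            unit=MMOLL,
            version=str(payload.get("version", "unversioned")),
            meta=dict(payload.get("meta", {})),
        )
        if unit != MMOLL:
            grid.meta.setdefault("source_unit", unit)
        if validate:
            grid.validate()
        return grid

    def zone_labels(self) -> list[RiskZone]:
        return sorted({zone for zone, _ in self.zones})


def save_grid(grid: RiskGrid, path) -> None:
    """Write a grid to the JSON boundary schema (always in mmol/L)."""
    payload = grid.to_dict()
    Path(path).write_text(json.dumps(payload, indent=2))


def load_grid(path, validate: bool = True) -> RiskGrid:
    """Load a grid definition file; mg/dL files are converted to mmol/L.

    ``path`` may also be a bundled grid name: ``"heg"``, ``"clarke"`` or
    ``"parkes"``.
    """
    key = str(path).lower()
    if key in BUNDLED_GRIDS:
        text = resources.files("hegrid.data").joinpath(BUNDLED_GRIDS[key]).read_text()
    else:
        text = Path(path).read_text()
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise GridSchemaError(f"cannot parse grid file {path}: {exc}") from exc
    return RiskGrid.from_dict(payload, validate=validate)


def default_heg() -> RiskGrid:
    """The bundled (reconstructed) hypoglycaemia error grid."""
    return load_grid("heg")
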