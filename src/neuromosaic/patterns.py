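"""Typed planar point patterns in micrometre coordinates.

A :class:`PointPattern` is the package's central container: cell centroids
(x, y) in μm, an optional type label per point (e.g. ``"PV"``, ``"SST"``),
an observation window (a shapely polygon, usually the annotated ROI), and an
optional per-pattern soma radius used by the double-positive rule.

Patterns round-trip through plain CSV (columns ``x_um, y_um, type, layer``)
so they interoperate with any downstream tooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, box
from shapely.prepared import prep

from .exceptions import InvalidSpecError

__all__ = ["PointPattern", "rectangle_window", "window_extent"]


def rectangle_window(width_um: float, height_um: float) -> Polygon:
    """Axis-aligned rectangular window with its lower-left corner at (0, 0)."""
    if width_um <= 0 or height_um <= 0:
        raise InvalidSpecError("window sides must be positive")
    return box(0.0, 0.0, float(width_um), float(height_um))


def window_extent(window: Polygon) -> tuple[float, float]:
    """(width, height) of the window's axis-aligned bounding box, μm."""
    x0, y0, x1, y1 = window.bounds
    return x1 - x0, y1 - y0


def _as_rectangle(window: Polygon) -> tuple[float, float, float, float] | None:
    """Return bounds if *window* is (numerically) its own bounding box, else None."""
    x0, y0, x1, y1 = window.bounds
    rect = box(x0, y0, x1, y1)
    if abs(window.area - rect.area) <= 1e-9 * max(rect.area, 1.0):
        return x0, y0, x1, y1
    return None


@dataclass(frozen=True)
class PointPattern:
    """A typed point pattern observed in a planar window.

    Parameters
    ----------
    points : (n, 2) float array
        Cell coordinates in μm.
    window : shapely.Polygon
        Observation window in μm. Points are expected to lie inside it
        (within a small numerical tolerance).
    types : (n,) array of str, optional
        Marker label per point; a single implicit type ``"cell"`` if omitted.
    layers : (n,) array of str, optional
        Cortical layer label per point (filled in by layer assignment).
    soma_radius : float, optional
        Measured cell-body radius in μm (per pattern), used by the
        double-positive merging rule.
    """

    points: np.ndarray
    window: Polygon
    types: np.ndarray | None = None
    layers: np.ndarray | None = None
    soma_radius: float | None = None
    _skip_validation: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "points", pts)
        if self.types is not None:
            t = np.asarray(self.types, dtype=object)
            if t.shape[0] != pts.shape[0]:
                raise InvalidSpecError("types length must match point count")
            object.__setattr__(self, "types", t)
        if self.layers is not None:
            lay = np.asarray(self.layers, dtype=object)
            if lay.shape[0] != pts.shape[0]:
                raise InvalidSpecError("layers length must match point count")
            object.__setattr__(self, "layers", lay)
        if self.window is None or self.window.area <= 0:
            raise InvalidSpecError("window must be a polygon with positive area")
        if not self._skip_validation and len(pts):
            buffered = prep(self.window.buffer(1e-6))
            inside = [buffered.contains(Point(x, y)) for x, y in pts]
            if not all(inside):
                n_out = len(inside) - sum(inside)
                raise InvalidSpecError(f"{n_out} point(s) fall outside the window")

    # ------------------------------------------------------------------ basics
    @property
    def n(self) -> int:
        return self.points.shape[0]

    def __len__(self) -> int:
        return self.n

    @property
    def area(self) -> float:
        """Window area in μm²."""
        return float(self.window.area)

    @property
    def intensity(self) -> float:
        """Empirical intensity, points per μm²."""
        return self.n / self.area

    @property
    def type_labels(self) -> list[str]:
        if self.types is None:
            return ["cell"] if self.n else []
        return sorted(set(self.types.tolist()))

    def effective_types(self) -> np.ndarray:
        """Type labels, materialising the implicit single type."""
        if self.types is not None:
            return self.types
        return np.full(self.n, "cell", dtype=object)

    # ------------------------------------------------------------------ views
    def subset(self, type_label: str) -> "PointPattern":
        """Points of one type, same window (type array dropped)."""
        mask = self.effective_types() == type_label
        return PointPattern(
            self.points[mask],
            self.window,
            layers=None if self.layers is None else self.layers[mask],
            soma_radius=self.soma_radius,
            _skip_validation=True,
        )

    def with_layers(self, layers) -> "PointPattern":
        return replace(self, layers=np.asarray(layers, dtype=object))

    def coords_of(self, type_label: str | None) -> np.ndarray:
        if type_label is None:
            return self.points
        return self.points[self.effective_types() == type_label]

    # ------------------------------------------------------------------ I/O
    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"x_um": self.points[:, 0], "y_um": self.points[:, 1]})
        df["type"] = self.effective_types()
        if self.layers is not None:
            df["layer"] = self.layers
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, window: Polygon, **kw) -> "PointPattern":
        pts = df[["x_um", "y_um"]].to_numpy(dtype=float)
        types = df["type"].to_numpy(dtype=object) if "type" in df else None
        layers = df["layer"].to_numpy(dtype=object) if "layer" in df else None
        return cls(pts, window, types=types, layers=layers, **kw)

    @classmethod
    def from_csv(cls, path, window: Polygon, **kw) -> "PointPattern":
        return cls.from_dataframe(pd.read_csv(path), window, **kw)

    # ------------------------------------------------------------------ algebra
    def superpose(self, other: "PointPattern", label_self: str, label_other: str) -> "PointPattern":
        """Union of two patterns over the same window, carrying type labels."""
        if _as_rectangle(self.window) != _as_rectangle(other.window) or not self.window.equals(
            other.window
        ):
            raise InvalidSpecError("patterns must share the same window")
        pts = np.vstack([self.points, other.points])
        types = np.concatenate(
            [np.full(self.n, label_self, object), np.full(other.n, label_other, object)]
        )
        return PointPattern(pts, self.window, types=types, soma_radius=self.soma_radius,
                            _skip_validation=True)
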