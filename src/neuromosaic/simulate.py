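"""Synthetic point patterns with known spatial structure.

Three generative regimes cover the behaviours the spatial statistics must
distinguish:

* complete spatial randomness (CSR) — homogeneous Poisson, the null model
  against which the pair correlation function is read (g(r) = 1);
* Matérn type-II hard-core thinning — "spatial inhibition" (g(r) < 1 below
  the inhibition radius), with a closed-form retained intensity
  ``(1 - exp(-λπh²)) / (πh²)`` usable as an oracle;
* Thomas cluster process — "spatial clustering" (g(r) > 1 at short range),
  with closed form ``g(r) = 1 + exp(-r²/4σ²) / (4πκσ²)``.

Layered sampling places independent CSR populations inside each annotated
cortical layer, emulating laminar intensity profiles (most cells in L5,
none in L1 — L1 is simply never part of the annotation).

All intensities are given in cells/mm² (the field's reporting unit) and are
converted to μm⁻² internally. Every generator is deterministic under its
seed; compound generators split seeds via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

from .exceptions import InvalidSpecError
from .geometry import ADULT_LAYERS, CorticalAnnotation, _boundary_names
from .patterns import PointPattern, _as_rectangle

__all__ = [
    "SimulationSpec",
    "simulate_csr",
    "simulate_matern_ii",
    "simulate_thomas",
    "simulate_bitype",
    "dart_throw_pattern",
    "matern_ii_retained_intensity",
    "thomas_pcf",
    "make_layered_annotation",
    "sample_layered_pattern",
]

MM2_PER_UM2 = 1e-6  # cells/mm² → cells/μm²


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated point process.

    ``intensity`` is in cells/mm²; for ``matern_ii`` it is the *proposal*
    intensity before thinning, for ``thomas`` the *parent* intensity.
    """

    process_kind: str
    intensity: float
    window: Polygon
    seed: int
    inhibition_radius: float = 0.0  # μm, matern_ii only
    offspring_mean: float = 0.0     # thomas only
    cluster_sd: float = 0.0         # μm, thomas only

    def __post_init__(self):
        if self.process_kind not in {"csr", "matern_ii", "thomas"}:
            raise InvalidSpecError(f"unknown process kind {self.process_kind!r}")
        if not np.isfinite(self.intensity) or self.intensity <= 0:
            raise InvalidSpecError("intensity must be positive")
        if self.window is None or self.window.area <= 0:
            raise InvalidSpecError("window must have positive area")
        if self.inhibition_radius < 0:
            raise InvalidSpecError("inhibition_radius must be >= 0")
        if self.process_kind == "thomas" and self.cluster_sd < 0:
            raise InvalidSpecError("cluster_sd must be >= 0")

    @property
    def intensity_um2(self) -> float:
        return self.intensity * MM2_PER_UM2


# -------------------------------------------------------------------- sampling
def _uniform_in_polygon(window: Polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. uniform points in a polygon (direct for rectangles, else rejection)."""
    rect = _as_rectangle(window)
    x0, y0, x1, y1 = window.bounds
    if rect is not None:
        xy = rng.random((n, 2))
        xy[:, 0] = x0 + xy[:, 0] * (x1 - x0)
        xy[:, 1] = y0 + xy[:, 1] * (y1 - y0)
        return xy
    prepared = prep(window)
    out = np.empty((n, 2))
    filled = 0
    frac = window.area / ((x1 - x0) * (y1 - y0))
    while filled < n:
        m = max(int((n - filled) / max(frac, 1e-6) * 1.2), 16)
        cand = rng.random((m, 2))
        cand[:, 0] = x0 + cand[:, 0] * (x1 - x0)
        cand[:, 1] = y0 + cand[:, 1] * (y1 - y0)
        keep = [prepared.contains(Point(x, y)) for x, y in cand]
        kept = cand[np.asarray(keep, bool)]
        take = min(len(kept), n - filled)
        out[filled : filled + take] = kept[:take]
        filled += take
    return out


def _poisson_points(
    window: Polygon, intensity_um2: float, rng: np.random.Generator
) -> np.ndarray:
    n = rng.poisson(intensity_um2 * window.area)
    return _uniform_in_polygon(window, n, rng)


# -------------------------------------------------------------------- processes
def simulate_csr(spec: SimulationSpec) -> PointPattern:
    """Homogeneous Poisson pattern: count ~ Poisson(λ|W|), locations uniform."""
    if spec.process_kind != "csr":
        raise InvalidSpecError("spec.process_kind must be 'csr'")
    rng = np.random.default_rng(spec.seed)
    pts = _poisson_points(spec.window, spec.intensity_um2, rng)
    return PointPattern(pts, spec.window, _skip_validation=True)


def simulate_matern_ii(spec: SimulationSpec) -> PointPattern:
    """Matérn type-II hard-core pattern.

    CSR proposals at the proposal intensity receive i.i.d. uniform marks; a
    point is deleted if any neighbour within the inhibition radius carries an
    older (smaller) mark. No surviving pair is closer than the radius. An
    empty result (radius so large nothing survives) is valid output; a zero
    radius applies no thinning and reduces to CSR at the proposal intensity.
    """
    if spec.process_kind != "matern_ii":
        raise InvalidSpecError("spec.process_kind must be 'matern_ii'")
    rng = np.random.default_rng(spec.seed)
    pts = _poisson_points(spec.window, spec.intensity_um2, rng)
    marks = rng.random(len(pts))
    if len(pts) == 0:
        return PointPattern(pts, spec.window, _skip_validation=True)
    from scipy.spatial import cKDTree

    tree = cKDTree(pts)
    pairs = tree.query_pairs(spec.inhibition_radius, output_type="ndarray")
    keep = np.ones(len(pts), bool)
    for i, j in pairs:
        if marks[i] < marks[j]:
            keep[j] = False
        else:
            keep[i] = False
    return PointPattern(pts[keep], spec.window, _skip_validation=True)


def matern_ii_retained_intensity(proposal_intensity_mm2: float, h_um: float) -> float:
    """Closed-form retained intensity of Matérn II, cells/mm²."""
    lam = proposal_intensity_mm2 * MM2_PER_UM2
    a = np.pi * h_um**2
    return (1.0 - np.exp(-lam * a)) / a / MM2_PER_UM2


def simulate_thomas(spec: SimulationSpec) -> PointPattern:
    """Thomas cluster pattern restricted to the window.

    Parents are Poisson at the parent intensity in a window dilated by
    4·cluster_sd (so the restriction to the observation window is a true
    stationary Thomas process); Poisson(offspring_mean) children per parent
    are displaced by isotropic Gaussians of sd cluster_sd, and children
    falling outside the window are discarded.
    """
    if spec.process_kind != "thomas":
        raise InvalidSpecError("spec.process_kind must be 'thomas'")
    if spec.offspring_mean <= 0:
        raise InvalidSpecError("thomas requires offspring_mean > 0")
    rng = np.random.default_rng(spec.seed)
    pad = 4.0 * spec.cluster_sd
    parent_window = spec.window.buffer(pad, join_style="mitre") if pad > 0 else spec.window
    parents = _poisson_points(parent_window, spec.intensity_um2, rng)
    counts = rng.poisson(spec.offspring_mean, size=len(parents))
    total = int(counts.sum())
    if total == 0:
        return PointPattern(np.empty((0, 2)), spec.window, _skip_validation=True)
    centers = np.repeat(parents, counts, axis=0)
    children = centers + rng.normal(0.0, max(spec.cluster_sd, 0.0), size=(total, 2))
    rect = _as_rectangle(spec.window)
    if rect is not None:
        x0, y0, x1, y1 = rect
        inside = (
            (children[:, 0] >= x0) & (children[:, 0] <= x1)
            & (children[:, 1] >= y0) & (children[:, 1] <= y1)
        )
    else:
        prepared = prep(spec.window)
        inside = np.array([prepared.contains(Point(x, y)) for x, y in children])
    return PointPattern(children[inside], spec.window, _skip_validation=True)


def thomas_pcf(r_um, parent_intensity_mm2: float, cluster_sd_um: float) -> np.ndarray:
    """Closed-form Thomas pair correlation g(r) = 1 + exp(-r²/4σ²)/(4πκσ²)."""
    r = np.asarray(r_um, float)
    kappa = parent_intensity_mm2 * MM2_PER_UM2
    sigma = cluster_sd_um
    return 1.0 + np.exp(-(r**2) / (4 * sigma**2)) / (4 * np.pi * kappa * sigma**2)


def dart_throw_pattern(
    n: int,
    window: Polygon,
    min_separation: float,
    margin: float = 0.0,
    seed: int = 0,
    max_tries: int = 500_000,
) -> PointPattern:
    """Exactly ``n`` points with pairwise separation ≥ ``min_separation``.

    Sequential rejection ("dart throwing"); useful for rendering test scenes
    of non-overlapping somata. ``margin`` keeps points away from the window
    boundary. Raises if the window cannot accommodate the request.
    """
    if n < 0 or min_separation < 0:
        raise InvalidSpecError("n and min_separation must be non-negative")
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = window.bounds
    shrunk = window if margin == 0 else window.buffer(-margin)
    if shrunk.is_empty or shrunk.area <= 0:
        raise InvalidSpecError("margin leaves no room in the window")
    prepared = prep(shrunk)
    rect = _as_rectangle(shrunk)
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > max_tries:
            raise InvalidSpecError(
                f"could not place {n} points at separation {min_separation}"
            )
        p = rng.uniform([x0 + margin, y0 + margin], [x1 - margin, y1 - margin])
        if rect is None and not prepared.contains(Point(*p)):
            continue
        if all(np.hypot(*(p - q)) >= min_separation for q in pts):
            pts.append(p)
    return PointPattern(
        np.asarray(pts, float).reshape(-1, 2), window, _skip_validation=True
    )


_SIMULATORS = {
    "csr": simulate_csr,
    "matern_ii": simulate_matern_ii,
    "thomas": simulate_thomas,
}


def simulate(spec: SimulationSpec) -> PointPattern:
    """Dispatch on ``spec.process_kind``."""
    return _SIMULATORS[spec.process_kind](spec)


def simulate_bitype(
    spec_a: SimulationSpec, spec_b: SimulationSpec, labels: tuple[str, str] = ("A", "B")
) -> PointPattern:
    """Superposition of two independently simulated patterns with type labels."""
    if not spec_a.window.equals(spec_b.window):
        raise InvalidSpecError("both specs must share the same window")
    pat_a = simulate(spec_a)
    pat_b = simulate(spec_b)
    return pat_a.superpose(pat_b, labels[0], labels[1])


# -------------------------------------------------------------------- annotation
def make_layered_annotation(
    layer_thicknesses,
    width: float = 1000.0,
    waviness: float = 0.0,
    seed: int = 0,
    layer_names: list[str] | None = None,
    n_vertices: int = 65,
) -> CorticalAnnotation:
    """Synthetic layered annotation: an ROI of the given width partitioned by
    non-crossing boundary polylines.

    ``layer_thicknesses`` is ordered pial-side first (L2/3 → L6 by default;
    the 1-mm default width matches a typical analysis ROI). ``waviness`` is
    the amplitude (μm) of a smooth random lateral undulation applied to each
    boundary; 0 yields straight horizontal boundaries. Boundaries that would
    cross after perturbation raise an error (amplitude must stay below half
    the smallest thickness).
    """
    t = np.asarray(layer_thicknesses, float)
    if np.any(t <= 0):
        raise InvalidSpecError("all layer thicknesses must be positive")
    if layer_names is None:
        layer_names = list(ADULT_LAYERS)[: len(t)] if len(t) == 4 else [
            f"layer{i+1}" for i in range(len(t))
        ]
        if len(t) == 3:
            layer_names = ["L2-4", "L5", "L6"]
    if len(layer_names) != len(t):
        raise InvalidSpecError("layer_names length must match thickness list")
    if waviness < 0:
        raise InvalidSpecError("waviness must be >= 0")
    if waviness > 0 and waviness >= t.min() / 2:
        raise InvalidSpecError("waviness must be below half the smallest layer thickness")

    rng = np.random.default_rng(seed)
    depths = np.concatenate([[0.0], np.cumsum(t)])
    xs = np.linspace(0.0, width, n_vertices)
    names = _boundary_names(list(layer_names))
    boundaries: dict[str, np.ndarray] = {}
    for name, depth in zip(names, depths):
        if waviness > 0:
            phase = rng.uniform(0, 2 * np.pi, size=2)
            amp = rng.uniform(0.5, 1.0, size=2) * waviness
            wave = amp[0] * np.sin(2 * np.pi * xs / width + phase[0]) * 0.7
            wave += amp[1] * np.sin(4 * np.pi * xs / width + phase[1]) * 0.3
        else:
            wave = np.zeros_like(xs)
        boundaries[name] = np.column_stack([xs, depth + wave])

    top = boundaries[names[0]]
    bottom = boundaries[names[-1]]
    roi = Polygon(np.vstack([top, bottom[::-1]]))
    return CorticalAnnotation(roi, boundaries, list(layer_names))


def sample_layered_pattern(
    annotation: CorticalAnnotation, per_layer_intensity, seed: int = 0
) -> PointPattern:
    """CSR within each annotated layer at that layer's intensity (cells/mm²).

    Expected per-layer counts are intensity × layer area, so programmed
    laminar fractions are proportional to intensity × area.
    """
    lam = np.asarray(per_layer_intensity, float)
    if len(lam) != len(annotation.layer_names):
        raise InvalidSpecError(
            f"need one intensity per layer ({len(annotation.layer_names)}), got {len(lam)}"
        )
    if np.any(lam < 0):
        raise InvalidSpecError("intensities must be >= 0")
    seeds = np.random.SeedSequence(seed).spawn(len(lam))
    pts_all, layers_all = [], []
    for layer, lam_i, ss in zip(annotation.layer_names, lam, seeds):
        if lam_i == 0:
            continue
        rng = np.random.default_rng(ss)
        poly = annotation.layer_polygon(layer)
        pts = _poisson_points(poly, lam_i * MM2_PER_UM2, rng)
        pts_all.append(pts)
        layers_all.append(np.full(len(pts), layer, object))
    if not pts_all:
        return PointPattern(np.empty((0, 2)), annotation.roi, _skip_validation=True)
    return PointPattern(
        np.vstack(pts_all),
        annotation.roi,
        layers=np.concatenate(layers_all),
        _skip_validation=True,
    )
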