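"""Study orchestration: ROIs → per-ROI statistics → per-animal → per-group.

A study is a manifest of ROIs (image stacks or pre-extracted coordinate
tables) with animal ids and group labels. Each ROI yields a laminar summary,
NND/CV for every ordered type pair, and PCF estimates for every type pair;
scalar metrics are then averaged with the two-level rule — unweighted mean
of the technical-replicate ROIs within each animal, then unweighted mean of
animals within each group — so every animal carries equal weight regardless
of its ROI count. The per-animal table is the unit intended for external
hypothesis testing.

Blinding assigns each input file a random code that reveals nothing about
the group, and is losslessly reversible.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .exceptions import InsufficientDataError, InvalidSpecError
from .geometry import CorticalAnnotation, laminar_summary
from .patterns import PointPattern
from .segment import SegmentationParams, records_to_dataframe, segment_cells
from .spatial import average_pcf, merge_double_positive, nnd, pcf

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "BlindingMap",
    "blind",
    "unblind",
    "ROIResult",
    "run_roi",
    "aggregate",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Resolved configuration for one study run."""

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    soma_radius_um: float | None = None     # enables double-positive merging
    pcf_bandwidth_um: float | None = None   # None → Stoyan rule per estimate
    pcf_correction: str = "translation"
    pcf_r_max_um: float | None = None
    compute_pcf: bool = True
    compute_nnd: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        seg = SegmentationParams(**raw.pop("segmentation", {}))
        return cls(segmentation=seg, **raw)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["segmentation"] = dict(self.segmentation.__dict__)
        return d


# ===================================================================== blinding
@dataclass(frozen=True)
class BlindingMap:
    """Bijective original-name ↔ code mapping, reproducible under its seed."""

    mapping: dict[str, str]
    seed: int

    def code(self, original: str) -> str:
        return self.mapping[original]

    def original(self, coded: str) -> str:
        inverse = {v: k for k, v in self.mapping.items()}
        return inverse[coded]


def blind(manifest: pd.DataFrame, seed: int, group_column: str = "group",
          file_column: str = "file") -> tuple[BlindingMap, pd.DataFrame]:
    """Assign each file a random code carrying no group information.

    The coded manifest keeps all columns except the group (and replaces file
    names by codes); ``unblind`` restores the original exactly. Codes are
    regenerated on the (astronomically unlikely) event of a collision or of
    a group name appearing as a substring of a code.
    """
    files = manifest[file_column].tolist()
    if len(set(files)) != len(files):
        raise InvalidSpecError("file names must be unique for blinding")
    groups = {str(g).lower() for g in manifest.get(group_column, [])}
    rng = np.random.default_rng(seed)
    mapping: dict[str, str] = {}
    taken: set[str] = set()
    for name in files:
        while True:
            code = "roi-" + "".join(rng.choice(list("0123456789abcdef"), 8))
            if code in taken or any(g and g in code for g in groups):
                continue
            taken.add(code)
            mapping[name] = code
            break
    coded = manifest.drop(columns=[group_column], errors="ignore").copy()
    coded[file_column] = [mapping[f] for f in files]
    return BlindingMap(mapping, seed), coded


def unblind(coded_manifest: pd.DataFrame, blinding: BlindingMap,
            file_column: str = "file") -> pd.DataFrame:
    out = coded_manifest.copy()
    inverse = {v: k for k, v in blinding.mapping.items()}
    out[file_column] = [inverse[c] for c in out[file_column]]
    return out


# ===================================================================== per-ROI
@dataclass
class ROIResult:
    """All statistics for one ROI (one field of view)."""

    roi_id: str
    laminar: pd.DataFrame            # tidy rows: type × layer metrics
    nnd_table: pd.DataFrame          # from_type, to_type, mean, sd, cv, n
    pcf_estimates: dict              # (type_a, type_b) → PCFEstimate
    pattern: PointPattern | None = None
    errors: list = field(default_factory=list)


def _pattern_from_input(data, annotation, config, type_map) -> PointPattern:
    """Accept a PointPattern, a dict of per-channel ImageStacks, or a DataFrame."""
    if isinstance(data, PointPattern):
        return data
    if isinstance(data, pd.DataFrame):
        return PointPattern.from_dataframe(data, annotation.roi, _skip_validation=True)
    # dict channel → ImageStack
    per_type = {}
    for channel, stack in data.items():
        label = (type_map or {}).get(channel, channel)
        records = segment_cells(stack, config.segmentation, type_label=label)
        df = records_to_dataframe(records)
        pts = df[["x_um", "y_um"]].to_numpy()
        per_type[label] = pts
    labels = sorted(per_type)
    if len(labels) == 2 and config.soma_radius_um:
        pa = PointPattern(per_type[labels[0]], annotation.roi, _skip_validation=True)
        pb = PointPattern(per_type[labels[1]], annotation.roi, _skip_validation=True)
        return merge_double_positive(
            pa, pb, config.soma_radius_um,
            labels=(labels[0], labels[1], "+".join(labels)),
        )
    pts = np.vstack([per_type[t] for t in labels]) if per_type else np.empty((0, 2))
    types = np.concatenate(
        [np.full(len(per_type[t]), t, object) for t in labels]
    ) if per_type else np.empty(0, object)
    return PointPattern(pts, annotation.roi, types=types, _skip_validation=True)


def run_roi(
    data,
    annotation: CorticalAnnotation,
    config: AnalysisConfig | None = None,
    roi_id: str = "roi",
    type_map: dict | None = None,
) -> ROIResult:
    """Analyze one ROI end to end.

    ``data`` may be a :class:`PointPattern` (coordinates already extracted),
    a coordinates DataFrame (columns ``x_um, y_um[, type]``), or a dict of
    channel-name → :class:`ImageStack` to be segmented first. Double
    positives are merged when exactly two channels are segmented and a soma
    radius is configured. Statistics that fail (e.g. too few cells of a
    type) are recorded in ``errors`` without aborting the ROI.
    """
    config = config or AnalysisConfig()
    result_errors: list = []

    pattern = _pattern_from_input(data, annotation, config, type_map)
    from .geometry import assign_layers

    layer_labels = assign_layers(pattern.points, annotation)
    pattern = pattern.with_layers(layer_labels)

    # laminar summaries per type and overall
    lam_rows = []
    type_labels = pattern.type_labels or []
    for label in type_labels:
        sub = pattern.subset(label)
        summ = laminar_summary(sub.points, annotation)
        t = summ.table.copy()
        t.insert(0, "type", label)
        t.insert(0, "roi_id", roi_id)
        lam_rows.append(t)
    laminar = pd.concat(lam_rows, ignore_index=True) if lam_rows else pd.DataFrame(
        columns=["roi_id", "type", "layer", "count", "area_mm2", "density",
                 "fraction", "thickness_um"]
    )

    # NND / CV for every ordered pair of types
    nnd_rows = []
    if config.compute_nnd:
        for ta, tb in itertools.product(type_labels, repeat=2):
            try:
                res = nnd(pattern, ta, tb)
                nnd_rows.append(
                    {
                        "roi_id": roi_id,
                        "from_type": ta,
                        "to_type": tb,
                        "n": res.n,
                        "mean_um": res.mean,
                        "sd_um": res.sd,
                        "cv": res.cv,
                    }
                )
            except InsufficientDataError as exc:
                result_errors.append((f"nnd {ta}->{tb}", str(exc)))
    nnd_table = pd.DataFrame(
        nnd_rows,
        columns=["roi_id", "from_type", "to_type", "n", "mean_um", "sd_um", "cv"],
    )

    # PCF for every unordered pair (within + cross)
    pcf_estimates = {}
    if config.compute_pcf:
        pairs = [(t, t) for t in type_labels] + list(
            itertools.combinations(type_labels, 2)
        )
        for ta, tb in pairs:
            try:
                r = None
                if config.pcf_r_max_um:
                    r = np.arange(1.0, config.pcf_r_max_um + 1e-9, 1.0)
                pcf_estimates[(ta, tb)] = pcf(
                    pattern, ta, tb,
                    r=r,
                    bandwidth=config.pcf_bandwidth_um,
                    correction=config.pcf_correction,
                )
            except InsufficientDataError as exc:
                result_errors.append((f"pcf {ta}-{tb}", str(exc)))

    return ROIResult(
        roi_id=roi_id,
        laminar=laminar,
        nnd_table=nnd_table,
        pcf_estimates=pcf_estimates,
        pattern=pattern,
        errors=result_errors,
    )


# ===================================================================== aggregate
def aggregate(
    per_roi: pd.DataFrame,
    manifest: pd.DataFrame | None = None,
    value_columns: list[str] | None = None,
    mouse_column: str = "mouse_id",
    group_column: str = "group",
    roi_column: str = "roi_id",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-level averaging of scalar per-ROI metrics.

    Technical-replicate ROIs are averaged (unweighted) within each animal,
    then animals are averaged (unweighted) within each group. Metrics
    missing in an ROI are averaged over the available ROIs, with the
    contributing count logged in an ``n_rois`` column. Returns
    ``(per_mouse, per_group)`` tidy tables; the per-mouse table is the unit
    for external statistics.
    """
    df = per_roi.copy()
    if manifest is not None:
        key_cols = [c for c in (roi_column, mouse_column, group_column) if c in manifest]
        df = df.merge(manifest[key_cols].drop_duplicates(), on=roi_column, how="left")
    if mouse_column not in df:
        raise InvalidSpecError(f"no {mouse_column!r} column to aggregate over")

    if value_columns is None:
        skip = {roi_column, mouse_column, group_column}
        value_columns = [
            c for c in df.columns
            if c not in skip and pd.api.types.is_numeric_dtype(df[c])
        ]
    id_cols = [c for c in df.columns if c not in value_columns + [roi_column]
               and not pd.api.types.is_numeric_dtype(df[c])]
    if mouse_column not in id_cols:
        id_cols.append(mouse_column)

    grouped = df.groupby(id_cols, dropna=False, sort=True)
    per_mouse = grouped[value_columns].mean().reset_index()
    per_mouse["n_rois"] = grouped[roi_column].nunique().reset_index(drop=True)

    if group_column in per_mouse:
        group_keys = [c for c in id_cols if c != mouse_column]
        g2 = per_mouse.groupby(group_keys, dropna=False, sort=True)
        per_group = g2[value_columns].mean().reset_index()
        per_group["n_mice"] = g2[mouse_column].nunique().reset_index(drop=True)
    else:
        per_group = pd.DataFrame()
    return per_mouse, per_group


def aggregate_pcf(estimates_by_mouse: dict) -> dict:
    """ROIs → animal mean curves; returns {mouse: PCFEstimate}."""
    return {m: average_pcf(v) for m, v in estimates_by_mouse.items()}


def write_run_manifest(path, config: AnalysisConfig, seed: int, extra: dict | None = None):
    """Record resolved config, seed and software version for provenance."""
    payload = {
        "software": f"neuromosaic {_version}",
        "seed": seed,
        "config": config.to_dict(),
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=str)
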