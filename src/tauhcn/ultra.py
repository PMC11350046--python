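"""Presynaptic ultrastructure quantification from vesicle coordinate maps.

A :class:`VesicleMap` holds per-synapse 2-D vesicle centre coordinates (nm,
single-section projection), per-vesicle diameters and dense-core flags, the
active-zone segment, and the presynaptic area.  Quantification covers the
synapse inclusion filter (defined PSD and 10-250 synaptic vesicles),
per-synapse counts/areas/docked fractions, and the nearest-neighbour
clustering statistic summarised per synapse as a cumulative frequency
distribution on a fixed 0-200 nm grid and then averaged across synapses
(per-synapse-then-average, never pooled).

Dense-core vesicles are a separate class: they are excluded from synaptic
vesicle counts and from the nearest-neighbour analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "VesicleMap",
    "NNResult",
    "SynapseMetrics",
    "filter_synapses",
    "synapse_metrics",
    "nn_analysis",
    "group_nn_summary",
    "synapse_density",
    "write_vesicle_map",
    "read_vesicle_map",
]

MIN_SV = 10
MAX_SV = 250
DOCKED_GAP_NM = 2.0      # max membrane-to-active-zone gap for a docked SV
ECDF_GRID_NM = np.arange(0.0, 401.0, 1.0)  # covers the preset NN range


@dataclass
class VesicleMap:
    synapse_id: str
    coords: np.ndarray            # (n, 2) vesicle centres, nm
    diameters: np.ndarray         # (n,) nm
    is_dcv: np.ndarray            # (n,) bool
    active_zone: np.ndarray       # (2, 2) segment endpoints, nm
    presyn_area: float            # µm²
    psd_defined: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.diameters = np.asarray(self.diameters, dtype=float)
        self.is_dcv = np.asarray(self.is_dcv, dtype=bool)
        self.active_zone = np.asarray(self.active_zone, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("vesicle coordinates must be finite")
        if np.any(self.diameters <= 0):
            raise ValueError("vesicle diameters must be positive")
        if np.allclose(self.active_zone[0], self.active_zone[1]):
            raise ValueError("active-zone endpoints must be distinct")

    @property
    def sv_mask(self) -> np.ndarray:
        return ~self.is_dcv

    @property
    def sv_count(self) -> int:
        """Number of synaptic (non-dense-core) vesicles."""
        return int(self.sv_mask.sum())


@dataclass(frozen=True)
class NNResult:
    synapse_id: str
    nn_distances: np.ndarray   # per-SV nearest-neighbour distance, nm
    ecdf_grid: np.ndarray      # nm
    ecdf: np.ndarray           # cumulative frequency on the grid
    mean_nn: float             # nm


@dataclass(frozen=True)
class SynapseMetrics:
    synapse_id: str
    sv_count: int
    presyn_area: float     # µm²
    mean_sv_diameter: float  # nm
    docked_pct: float
    has_dcv: bool


def filter_synapses(maps: list[VesicleMap], min_sv: int = MIN_SV,
                    max_sv: int = MAX_SV) -> list[VesicleMap]:
    """Inclusion filter: defined PSD and min_sv <= SV count <= max_sv."""
    return [m for m in maps
            if m.psd_defined and min_sv <= m.sv_count <= max_sv]


def _point_segment_distance(points: np.ndarray, seg: np.ndarray) -> np.ndarray:
    """Euclidean distance from each point to a line segment."""
    a, b = seg[0], seg[1]
    ab = b - a
    t = np.clip(((points - a) @ ab) / (ab @ ab), 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def synapse_metrics(m: VesicleMap) -> SynapseMetrics:
    """Counts, mean diameter, docked percentage and DCV presence.

    A vesicle counts as docked when its membrane sits within
    ``DOCKED_GAP_NM`` of the active-zone segment, i.e. centre-to-segment
    distance minus radius <= 2 nm.
    """
    sv = m.sv_mask
    count = int(sv.sum())
    if count:
        d = _point_segment_distance(m.coords[sv], m.active_zone)
        gaps = d - m.diameters[sv] / 2.0
        docked_pct = 100.0 * float((gaps <= DOCKED_GAP_NM).sum()) / count
        mean_diam = float(m.diameters[sv].mean())
    else:
        docked_pct = 0.0
        mean_diam = np.nan
    return SynapseMetrics(
        synapse_id=m.synapse_id, sv_count=count, presyn_area=m.presyn_area,
        mean_sv_diameter=mean_diam, docked_pct=docked_pct,
        has_dcv=bool(m.is_dcv.any()),
    )


def nn_analysis(m: VesicleMap, grid: np.ndarray = ECDF_GRID_NM) -> NNResult:
    """Per-SV nearest-neighbour distances and the per-synapse ECDF."""
    pts = m.coords[m.sv_mask]
    if pts.shape[0] < 2:
        raise ValueError("nearest-neighbour analysis needs at least 2 SVs")
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=2)
    nn = dist[:, 1]
    ecdf = np.searchsorted(np.sort(nn), grid, side="right") / nn.size
    return NNResult(synapse_id=m.synapse_id, nn_distances=nn,
                    ecdf_grid=grid, ecdf=ecdf, mean_nn=float(nn.mean()))


def group_nn_summary(results: list[NNResult]):
    """Average per-synapse ECDFs pointwise; unweighted mean of synapse means.

    Returns ``(mean_ecdf, group_mean_nn, per_synapse_means)``.  Averaging is
    per synapse first (each synapse contributes equally regardless of its
    vesicle count), matching the averaged cumulative-frequency convention.
    """
    if not results:
        raise ValueError("need at least one synapse")
    grids = {tuple(r.ecdf_grid) for r in results}
    if len(grids) != 1:
        raise ValueError("all ECDFs must share one grid")
    mean_ecdf = np.mean([r.ecdf for r in results], axis=0)
    per_synapse = np.array([r.mean_nn for r in results])
    return mean_ecdf, float(per_synapse.mean()), per_synapse


def synapse_density(centroids: list | np.ndarray, field_area: float) -> float:
    """Synapses per µm² in a panoramic field."""
    if field_area <= 0:
        raise ValueError("field area must be positive")
    return len(centroids) / field_area


# ---------------------------------------------------------------------------
# on-disk format: CSV per synapse + JSON sidecar

def write_vesicle_map(m: VesicleMap, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({
        "vesicle_id": np.arange(len(m.diameters)),
        "x_nm": m.coords[:, 0],
        "y_nm": m.coords[:, 1],
        "diameter_nm": m.diameters,
        "is_dcv": m.is_dcv.astype(int),
    }).to_csv(path, index=False)
    sidecar = {
        "synapse_id": m.synapse_id,
        "active_zone_nm": m.active_zone.tolist(),
        "presynaptic_area_um2": m.presyn_area,
        "psd_defined": m.psd_defined,
        "meta": m.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_vesicle_map(path: str | Path) -> VesicleMap:
    path = Path(path)
    df = pd.read_csv(path)
    sc = json.loads(path.with_suffix(".json").read_text())
    return VesicleMap(
        synapse_id=sc["synapse_id"],
        coords=df[["x_nm", "y_nm"]].to_numpy(),
        diameters=df["diameter_nm"].to_numpy(),
        is_dcv=df["is_dcv"].to_numpy().astype(bool),
        active_zone=np.asarray(sc["active_zone_nm"]),
        presyn_area=float(sc["presynaptic_area_um2"]),
        psd_defined=bool(sc["psd_defined"]),
        meta=sc.get("meta", {}),
    )
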