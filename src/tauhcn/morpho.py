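"""Neuronal morphometry: Sholl profiles, branch metrics, spine analysis.

Morphologies are SWC node tables (id, type, x, y, z, radius, parent; µm)
with a single root; spines live in a companion CSV table.  Sholl analysis
counts true sphere-segment crossings in 3-D around the soma centroid: a
straight segment contributes one intersection per strict crossing of a
sphere, and a tree node lying exactly on a sphere counts once when the path
through it actually passes from inside to outside (a terminal tip touching a
sphere is not a crossing).  A 2-D projected variant is available for
comparison with projection-based reconstructions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Morphology",
    "Spine",
    "ShollResult",
    "sholl",
    "branch_metrics",
    "spine_metrics",
    "classify_spine",
    "read_swc",
    "write_swc",
    "read_spines",
    "write_spines",
]

SWC_SOMA = 1
SWC_AXON = 2
SWC_BASAL = 3
SWC_APICAL = 4

MUSHROOM_HEAD_NECK_RATIO = 1.5
MUSHROOM_MIN_HEAD_UM = 0.35
STUBBY_LENGTH_NECK_RATIO = 1.0


@dataclass
class Morphology:
    """SWC tree with optional ground-truth annotations in ``meta``."""

    ids: np.ndarray       # (n,) int
    types: np.ndarray     # (n,) int SWC type codes
    xyz: np.ndarray       # (n, 3) µm
    radius: np.ndarray    # (n,) µm
    parent: np.ndarray    # (n,) int, -1 for the root
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.types = np.asarray(self.types, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.parent = np.asarray(self.parent, dtype=int)
        if (self.parent == -1).sum() != 1:
            raise ValueError("morphology must have exactly one root")
        self._index = {int(i): k for k, i in enumerate(self.ids)}
        for k, p in enumerate(self.parent):
            if p != -1 and self._index[int(p)] >= k:
                raise ValueError("parent nodes must precede children")

    @property
    def n(self) -> int:
        return self.ids.size

    def row_of(self, node_id: int) -> int:
        return self._index[int(node_id)]

    def soma_centroid(self) -> np.ndarray:
        soma = self.types == SWC_SOMA
        if not soma.any():
            return self.xyz[self.parent == -1][0]
        return self.xyz[soma].mean(axis=0)

    def dendrite_segments(self, compartment: str = "all") -> np.ndarray:
        """(m, 2, 3) array of (parent_xyz, child_xyz) dendritic segments."""
        comp_types = {
            "all": (SWC_BASAL, SWC_APICAL),
            "basal": (SWC_BASAL,),
            "apical": (SWC_APICAL,),
        }[compartment]
        rows = [
            (self.xyz[self.row_of(p)], self.xyz[k])
            for k, p in enumerate(self.parent)
            if p != -1 and self.types[k] in comp_types
        ]
        return np.asarray(rows).reshape(-1, 2, 3)

    def children_count(self) -> np.ndarray:
        counts = np.zeros(self.n, dtype=int)
        for p in self.parent:
            if p != -1:
                counts[self.row_of(p)] += 1
        return counts


@dataclass(frozen=True)
class Spine:
    attach_position: float  # µm along the dendritic cable
    length: float           # µm
    head_diam: float        # µm
    neck_diam: float        # µm
    true_type: str | None = None

    def __post_init__(self) -> None:
        if self.length <= 0 or self.head_diam <= 0 or self.neck_diam <= 0:
            raise ValueError("spine geometry must be positive")


@dataclass(frozen=True)
class ShollResult:
    radii: np.ndarray
    intersections: np.ndarray


def _segment_sphere_crossings(seg: np.ndarray, center: np.ndarray,
                              r: float) -> int:
    """Number of strict crossings (t in (0, 1)) of |p(t) - center| = r."""
    a = seg[0] - center
    d = seg[1] - seg[0]
    A = d @ d
    if A == 0:
        return 0
    B = 2.0 * (a @ d)
    C = a @ a - r * r
    disc = B * B - 4 * A * C
    if disc <= 0:
        return 0
    sq = np.sqrt(disc)
    count = 0
    for t in ((-B - sq) / (2 * A), (-B + sq) / (2 * A)):
        if 0.0 < t < 1.0:
            count += 1
    return count


def sholl(m: Morphology, step: float = 10.0, compartment: str = "all",
          max_radius: float | None = None, project_2d: bool = False) -> ShollResult:
    """Sholl intersection profile on concentric spheres around the soma.

    ``project_2d`` drops the z coordinate first (circles in the x-y plane),
    for parity with projection-based reconstructions.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    center = m.soma_centroid()
    segs = m.dendrite_segments(compartment)
    if project_2d:
        center = center.copy()
        center[2] = 0.0
        segs = segs.copy()
        segs[:, :, 2] = 0.0
    if segs.size == 0:
        radii = np.arange(step, step * 2, step)
        return ShollResult(radii=radii, intersections=np.zeros(radii.size, dtype=int))

    dists = np.linalg.norm(segs - center, axis=2)
    if max_radius is None:
        max_radius = float(dists.max())
    radii = np.arange(step, max_radius + step * 0.5, step)

    counts = np.zeros(radii.size, dtype=int)
    for j, r in enumerate(radii):
        c = sum(_segment_sphere_crossings(seg, center, r) for seg in segs)
        # nodes lying exactly on the sphere: count once per pass-through
        for k, p in enumerate(m.parent):
            if p == -1:
                continue
            node = m.xyz[k] if not project_2d else np.r_[m.xyz[k][:2], 0.0]
            if not np.isclose(np.linalg.norm(node - center), r):
                continue
            dp = np.linalg.norm(
                (m.xyz[m.row_of(p)] if not project_2d
                 else np.r_[m.xyz[m.row_of(p)][:2], 0.0]) - center)
            kids = [q for q, pp in enumerate(m.parent) if pp == m.ids[k]]
            for q in kids:
                dq = np.linalg.norm(
                    (m.xyz[q] if not project_2d
                     else np.r_[m.xyz[q][:2], 0.0]) - center)
                if (dp - r) * (dq - r) < 0:
                    c += 1
        counts[j] = c
    return ShollResult(radii=radii, intersections=counts)


def branch_metrics(m: Morphology):
    """(branch_points, mean_dendrite_length µm, soma_area µm²).

    Branch points are dendritic nodes with >= 2 children; mean dendrite
    length is total dendritic cable length divided by the number of primary
    dendrites (dendritic nodes whose parent is a soma node); soma area is
    pi r² of the root soma node (point-soma convention).
    """
    kids = m.children_count()
    dend = np.isin(m.types, (SWC_BASAL, SWC_APICAL))
    branch_points = int(((kids >= 2) & dend).sum())

    total_len = 0.0
    n_primary = 0
    for k, p in enumerate(m.parent):
        if p == -1 or not dend[k]:
            continue
        pk = m.row_of(p)
        total_len += float(np.linalg.norm(m.xyz[k] - m.xyz[pk]))
        if m.types[pk] == SWC_SOMA:
            n_primary += 1
    mean_len = total_len / n_primary if n_primary else 0.0

    soma_rows = np.flatnonzero(m.types == SWC_SOMA)
    soma_area = float(np.pi * m.radius[soma_rows[0]] ** 2) if soma_rows.size else np.nan
    return branch_points, mean_len, soma_area


def classify_spine(s: Spine) -> str:
    """Deterministic geometry-based spine typing.

    mushroom: head/neck ratio > 1.5 and head > 0.35 µm;
    stubby:   length/neck ratio < 1;
    thin:     otherwise.
    """
    if (s.head_diam / s.neck_diam > MUSHROOM_HEAD_NECK_RATIO
            and s.head_diam > MUSHROOM_MIN_HEAD_UM):
        return "mushroom"
    if s.length / s.neck_diam < STUBBY_LENGTH_NECK_RATIO:
        return "stubby"
    return "thin"


def spine_metrics(m: Morphology, spines: list[Spine]):
    """(density per µm, {type: fraction}) over the whole dendritic cable."""
    dend = np.isin(m.types, (SWC_BASAL, SWC_APICAL))
    total_len = sum(
        float(np.linalg.norm(m.xyz[k] - m.xyz[m.row_of(p)]))
        for k, p in enumerate(m.parent) if p != -1 and dend[k]
    )
    if total_len <= 0:
        raise ValueError("dendritic length must be positive")
    density = len(spines) / total_len
    labels = [classify_spine(s) for s in spines]
    fractions = {t: labels.count(t) / len(labels) if labels else 0.0
                 for t in ("stubby", "thin", "mushroom")}
    return density, fractions


# ---------------------------------------------------------------------------
# SWC and spine-table IO (plain text)

def write_swc(m: Morphology, path: str | Path) -> None:
    lines = ["# id type x y z radius parent"]
    for k in range(m.n):
        x, y, z = m.xyz[k]
        lines.append(
            f"{m.ids[k]} {m.types[k]} {x:.4f} {y:.4f} {z:.4f} "
            f"{m.radius[k]:.4f} {m.parent[k]}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_swc(path: str | Path) -> Morphology:
    text = Path(path).read_text()
    rows = []
    for line in io.StringIO(text):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split()
        rows.append((int(f[0]), int(f[1]), float(f[2]), float(f[3]),
                     float(f[4]), float(f[5]), int(f[6])))
    return Morphology(
        ids=np.array([r[0] for r in rows]),
        types=np.array([r[1] for r in rows]),
        xyz=np.array([[r[2], r[3], r[4]] for r in rows]),
        radius=np.array([r[5] for r in rows]),
        parent=np.array([r[6] for r in rows]),
    )


def write_spines(spines: list[Spine], path: str | Path) -> None:
    pd.DataFrame({
        "id": np.arange(len(spines)),
        "attach_position_um": [s.attach_position for s in spines],
        "length_um": [s.length for s in spines],
        "head_diam_um": [s.head_diam for s in spines],
        "neck_diam_um": [s.neck_diam for s in spines],
        "true_type": [s.true_type for s in spines],
    }).to_csv(path, index=False)


def read_spines(path: str | Path) -> list[Spine]:
    df = pd.read_csv(path)
    return [
        Spine(attach_position=r.attach_position_um, length=r.length_um,
              head_diam=r.head_diam_um, neck_diam=r.neck_diam_um,
              true_type=r.true_type if isinstance(r.true_type, str) else None)
        for r in df.itertuples()
    ]
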