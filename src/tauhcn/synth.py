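"""Synthetic-data generators with controllable ground truth.

Every input type the pipeline consumes can be generated here with known
ground truth: current-clamp step responses from the conductance-based
simulator, spontaneous-EPSC traces (homogeneous Poisson events convolved
with a biexponential kernel in Gaussian noise), clustered vesicle coordinate
maps with a hard-core packing constraint, and stochastic branched dendritic
trees with typed spines.  Genotype presets ("WT", "Tau35") encode the
between-group effect sizes the analysis pipeline is expected to recover:

* h-conductance doubled sag (Tau35 g_h calibrated against the WT preset);
* sEPSC rate reduced 77 %, equal amplitudes, slower Tau35 kernel calibrated
  so the analytic rate-of-rise ratio is 0.43 and the half-width ratio 2.3;
* synaptic-vesicle counts reduced 27 % (4-month) and 39 % (10-month),
  dense-core-vesicle prevalence reduced 74 % at 10 months, and cluster
  spread calibrated so mean nearest-neighbour distance grows by 10 nm;
* branch points reduced 44 %, mean dendrite length 20 %, spine density 59 %,
  with spine-type mass shifted from mushroom to thin spines.

All generators are bit-reproducible under a fixed seed.  For paired
group-comparison experiments the generators draw their "structural" random
numbers in a fixed order, so two presets run on the same seed share their
underlying uniforms (common random numbers).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import fftconvolve
from scipy.stats import gamma as gamma_dist, poisson as poisson_dist

from .morpho import Morphology, Spine, SWC_BASAL, SWC_SOMA, write_spines, write_swc
from .sepsc import biexp_kernel
from .simulate import NeuronParams, simulate_neuron
from .traces import GAP_FREE, StepProtocol, Trace, write_trace
from .ultra import VesicleMap, write_vesicle_map

__all__ = [
    "SepscPreset",
    "VesiclePreset",
    "MorphPreset",
    "GroundTruth",
    "NEURON_PRESETS",
    "SEPSC_PRESETS",
    "VESICLE_PRESETS",
    "MORPH_PRESETS",
    "generate_sepsc_trace",
    "generate_vesicle_map",
    "generate_vesicle_cohort",
    "generate_morphology",
    "generate_cohort",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class GroundTruth:
    """Generator-side truth attached to a synthetic dataset."""

    event_times_s: np.ndarray | None = None
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.event_times_s is not None:
            t = np.asarray(self.event_times_s, dtype=float)
            if np.any(np.diff(t) < 0):
                raise ValueError("ground-truth event times must be sorted")
            object.__setattr__(self, "event_times_s", t)


# ---------------------------------------------------------------------------
# spontaneous EPSC traces

@dataclass(frozen=True)
class SepscPreset:
    rate: float        # events/s
    amp: float         # kernel peak, pA (negative = inward)
    tau_rise: float    # ms
    tau_decay: float   # ms
    noise_sd: float    # pA
    duration: float    # s

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be non-negative")
        if not self.tau_decay > self.tau_rise > 0:
            raise ValueError("need tau_decay > tau_rise > 0")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def generate_sepsc_trace(preset: SepscPreset, seed,
                         dt: float = 0.1) -> tuple[Trace, GroundTruth]:
    """Poisson event train convolved with a biexponential kernel, plus noise."""
    if preset.rate * preset.duration > 1e6:
        raise ValueError("refusing to generate more than 1e6 events")
    rng = _rng(seed)
    dur_ms = preset.duration * 1000.0
    n = int(round(dur_ms / dt)) + 1

    n_events = rng.poisson(preset.rate * preset.duration)
    times_ms = np.sort(rng.uniform(0.0, dur_ms, size=n_events))

    impulses = np.zeros(n)
    np.add.at(impulses, np.round(times_ms / dt).astype(int).clip(0, n - 1), 1.0)
    k_len = int(round(10.0 * preset.tau_decay / dt)) + 1
    kernel = biexp_kernel(np.arange(k_len) * dt, preset.tau_rise,
                          preset.tau_decay, preset.amp)
    y = fftconvolve(impulses, kernel)[:n]
    if preset.noise_sd > 0:
        y = y + rng.normal(0.0, preset.noise_sd, size=n)

    meta = {"kind": "sepsc-gap-free", "preset": _asdict(preset), "seed": _seed_repr(seed),
            "true_event_times_s": (times_ms / 1000.0).tolist()}
    trace = Trace(dt=dt, samples=y, unit="pA", protocol=GAP_FREE, meta=meta)
    return trace, GroundTruth(event_times_s=times_ms / 1000.0)


# ---------------------------------------------------------------------------
# vesicle coordinate maps

@dataclass(frozen=True)
class VesiclePreset:
    mean_sv_count: float
    count_dispersion: float      # negative-binomial dispersion r (var = m + m²/r)
    cluster_sd: float            # nm, isotropic Gaussian cluster spread
    sv_diameter_mean: float      # nm
    sv_diameter_sd: float        # nm
    az_length: float             # nm
    docked_fraction_true: float
    dcv_prob: float
    presyn_area_mean: float      # µm²

    def __post_init__(self) -> None:
        if self.mean_sv_count <= 0 or self.cluster_sd <= 0:
            raise ValueError("mean_sv_count and cluster_sd must be positive")
        if not 0.0 <= self.dcv_prob <= 1.0:
            raise ValueError("dcv_prob must be a probability")


def _nb_count(rng: np.random.Generator, mean: float, dispersion: float,
              u_gamma: float | None = None) -> int:
    """Overdispersed count via the gamma-Poisson mixture.

    Drawn through inverse-CDF uniforms so that two presets sampled with the
    same generator state produce strongly correlated counts (common random
    numbers for paired designs).  ``u_gamma`` overrides the mixing quantile
    (used for stratified cohort draws); the stream is consumed either way.
    """
    u_g = rng.uniform()
    if u_gamma is not None:
        u_g = u_gamma
    g = gamma_dist.ppf(u_g, dispersion, scale=1.0 / dispersion)
    u = rng.uniform()
    return int(poisson_dist.ppf(u, mean * g))


def generate_vesicle_map(preset: VesiclePreset, seed,
                         synapse_id: str = "syn",
                         has_dcv: bool | None = None,
                         count_quantile: float | None = None,
                         max_tries: int = 2000) -> VesicleMap:
    """Clustered vesicle point pattern near an active zone.

    The SV count is negative binomial (mean ``mean_sv_count``); a
    ``docked_fraction_true`` share of the vesicles is placed touching the
    active-zone segment and the remainder forms an isotropic Gaussian
    cluster centred one ``cluster_sd`` above the AZ midpoint.  Placement is
    sequential with hard-core rejection at centre-to-centre distance below
    ``sv_diameter_mean``.  ``has_dcv`` overrides the Bernoulli(dcv_prob)
    draw (used for quota assignment at the cohort level); the flag's uniform
    is consumed either way to keep streams aligned between presets.
    """
    rng = _rng(seed)
    count = max(_nb_count(rng, preset.mean_sv_count, preset.count_dispersion,
                          u_gamma=count_quantile), 2)
    u_dcv = rng.uniform()
    if has_dcv is None:
        has_dcv = u_dcv < preset.dcv_prob
    area = preset.presyn_area_mean * rng.lognormal(0.0, 0.2)
    # per-vesicle coordinate substreams keyed by vesicle index: maps drawn
    # from the same seed with different presets then share their underlying
    # Gaussian offsets (common random numbers for paired cohorts)
    coord_base = int(rng.integers(2 ** 62))

    def vesicle_rng(index: int) -> np.random.Generator:
        # index >= 100: vesicles; 1: diameters; 2+j: dense-core vesicles
        return np.random.default_rng(
            np.random.SeedSequence(entropy=[coord_base, index]))

    az = np.array([[0.0, 0.0], [preset.az_length, 0.0]])
    center = np.array([preset.az_length / 2.0, preset.cluster_sd])
    hard_core = preset.sv_diameter_mean

    # docked vesicles pack in one dimension along the AZ; cap at the
    # sequential-packing limit so large count draws stay feasible
    n_docked = min(int(round(preset.docked_fraction_true * count)),
                   int(0.6 * preset.az_length / hard_core))
    coords: list[np.ndarray] = []

    def try_place(candidate) -> bool:
        if coords:
            arr = np.asarray(coords)
            d2 = (arr[:, 0] - candidate[0]) ** 2 + (arr[:, 1] - candidate[1]) ** 2
            if d2.min() < hard_core * hard_core:
                return False
        coords.append(candidate)
        return True

    for i in range(count):
        docked = i < n_docked
        rng_i = vesicle_rng(100 + i)
        for attempt in range(max_tries):
            if docked:
                x = rng_i.uniform(0.0, preset.az_length)
                y = hard_core / 2.0 + rng_i.uniform(0.0, 2.0)
                cand = np.array([x, y])
            else:
                cand = center + rng_i.normal(0.0, preset.cluster_sd, size=2)
            if try_place(cand):
                break
        else:
            raise RuntimeError(
                "hard-core packing infeasible; increase cluster_sd or lower "
                "mean_sv_count"
            )

    coords_arr = np.array(coords)
    diam = vesicle_rng(1).normal(preset.sv_diameter_mean,
                                  preset.sv_diameter_sd, size=count)
    diam = np.clip(diam, preset.sv_diameter_mean * 0.5, None)
    is_dcv = np.zeros(count, dtype=bool)

    if has_dcv:
        n_dcv = 1 + rng.poisson(0.7)
        dcv_coords = []
        for j in range(n_dcv):
            rng_j = vesicle_rng(2 + j)
            for attempt in range(max_tries):
                cand = center + rng_j.normal(0.0, 1.5 * preset.cluster_sd, size=2)
                if try_place(cand):
                    dcv_coords.append(cand)
                    break
        k = len(dcv_coords)
        if k:
            coords_arr = np.array(coords)
            diam = np.r_[diam, rng.normal(80.0, 8.0, size=k)]
            is_dcv = np.r_[is_dcv, np.ones(k, dtype=bool)]

    return VesicleMap(
        synapse_id=synapse_id, coords=coords_arr, diameters=diam,
        is_dcv=is_dcv, active_zone=az, presyn_area=area, psd_defined=True,
        meta={"preset": _asdict(preset), "seed": _seed_repr(seed),
              "true_sv_count": int(count),
              "true_docked": int(n_docked), "true_has_dcv": bool(has_dcv)},
    )


def generate_vesicle_cohort(preset: VesiclePreset, n: int, seed,
                            id_prefix: str = "syn") -> list[VesicleMap]:
    """A cohort of synapse maps with quota-assigned DCV prevalence.

    The estimand for dense-core vesicles is the cohort prevalence itself, so
    the cohort is designed to carry ``round(n * dcv_prob)`` DCV-positive
    synapses in a seed-shuffled order, and the vesicle-count mixing
    quantiles are the shuffled stratum midpoints of the negative-binomial
    distribution (the cohort's count spectrum is a fixed representative
    sample of the preset, in randomized order; coordinates, diameters and
    areas remain fully random).  Per-synapse generator streams are derived
    from ``(seed, i)`` so that two cohorts built from different presets with
    the same seed form matched pairs (common random numbers).
    """
    ss = np.random.SeedSequence(entropy=[_entropy(seed), 0xC0307])
    order_rng = np.random.default_rng(ss)
    n_dcv = int(round(n * preset.dcv_prob))
    flags = np.zeros(n, dtype=bool)
    flags[order_rng.permutation(n)[:n_dcv]] = True
    quantiles = (order_rng.permutation(n) + 0.5) / n
    return [
        generate_vesicle_map(
            preset,
            np.random.default_rng(np.random.SeedSequence(entropy=[_entropy(seed), i])),
            synapse_id=f"{id_prefix}{i:03d}",
            has_dcv=bool(flags[i]),
            count_quantile=float(quantiles[i]),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# dendritic morphologies with spines

@dataclass(frozen=True)
class MorphPreset:
    branch_prob: float            # per-segment-end bifurcation probability
    segment_len_mean: float       # µm
    max_depth: int
    soma_radius: float            # µm
    spine_density_true: float     # spines/µm
    spine_type_probs: tuple       # (stubby, thin, mushroom)
    n_primary: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError("branch_prob must be a probability")
        if abs(sum(self.spine_type_probs) - 1.0) > 1e-9:
            raise ValueError("spine type probabilities must sum to 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.spine_density_true < 0:
            raise ValueError("spine density must be non-negative")


def _stratified_decisions(rng: np.random.Generator, n_primary: int, depth: int,
                          n_slots: int) -> np.ndarray:
    """Branching-decision uniforms, systematic within each tree level.

    Each decision is marginally U(0,1) — every segment end branches with
    probability ``branch_prob`` — but within one level of one neuron the
    uniforms form a randomly permuted systematic sample, so the number of
    bifurcations per neuron concentrates near its expectation (a
    variance-balanced draw; cell-to-cell dispersion of branch counts stays
    well below a fully independent Bernoulli cascade).
    """
    decide = np.empty((n_primary, n_slots))
    decide.fill(np.nan)
    for level in range(1, depth):
        slots = np.arange(2 ** (level - 1) - 1, 2 ** level - 1)
        m = n_primary * slots.size
        u = rng.uniform()
        vals = (np.arange(m) + u) / m
        vals = vals[rng.permutation(m)]
        decide[:, slots] = vals.reshape(n_primary, slots.size)
    return np.nan_to_num(decide, nan=1.0)


_SPINE_GEOMETRY = {
    # per-type (length, neck_diam, head_diam) uniform ranges, µm
    "stubby": ((0.20, 0.45), (0.50, 0.80), (0.30, 0.50)),
    "thin": ((1.00, 2.00), (0.10, 0.20), (0.15, 0.30)),
    "mushroom": ((0.80, 1.50), (0.15, 0.25), (0.45, 0.80)),
}


def _unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def generate_morphology(preset: MorphPreset, seed) -> tuple[Morphology, list[Spine]]:
    """Stochastic binary dendritic tree with typed spines.

    Each of ``n_primary`` basal primaries grows by recursive bifurcation:
    a segment end branches with probability ``branch_prob`` until
    ``max_depth`` levels.  Branch decisions, segment lengths and directions
    are pre-drawn indexed by the node's position in the full binary tree, so
    trees generated from two presets with the same seed are nested (the
    lower-probability tree is a pruning of the other) — the coupling used by
    paired effect-recovery experiments.  Ground truth (branch-point count,
    total length, spine labels) is attached to ``Morphology.meta``.
    """
    rng = _rng(seed)
    d = preset.max_depth
    n_slots = 2 ** d  # node slots per primary in the full binary tree
    decide = _stratified_decisions(rng, preset.n_primary, d, n_slots)
    lengths = rng.gamma(10.0, preset.segment_len_mean / 10.0,
                        size=(preset.n_primary, 2 * n_slots))
    turns = _unit_vectors(rng, preset.n_primary * 2 * n_slots).reshape(
        preset.n_primary, 2 * n_slots, 3)
    primary_dirs = _unit_vectors(rng, preset.n_primary)

    ids = [1]
    types = [SWC_SOMA]
    xyz = [np.zeros(3)]
    radius = [preset.soma_radius]
    parent = [-1]
    next_id = 2
    branch_nodes = 0
    total_len = 0.0

    def grow(prim: int, slot: int, depth: int, start: np.ndarray,
             direction: np.ndarray, parent_id: int) -> None:
        nonlocal next_id, branch_nodes, total_len
        seg_len = lengths[prim, slot % (2 * n_slots)]
        # child direction: parent direction nudged by a random turn
        direction = direction + 0.45 * turns[prim, slot % (2 * n_slots)]
        direction = direction / np.linalg.norm(direction)
        end = start + seg_len * direction
        node_id = next_id
        next_id += 1
        ids.append(node_id)
        types.append(SWC_BASAL)
        xyz.append(end)
        radius.append(0.5)
        parent.append(parent_id)
        total_len += seg_len
        if depth < d and decide[prim, slot % n_slots] < preset.branch_prob:
            branch_nodes += 1
            grow(prim, 2 * slot + 1, depth + 1, end, direction, node_id)
            grow(prim, 2 * slot + 2, depth + 1, end, direction, node_id)

    for prim in range(preset.n_primary):
        grow(prim, 0, 1, np.zeros(3), primary_dirs[prim], 1)

    morph = Morphology(
        ids=np.array(ids), types=np.array(types), xyz=np.array(xyz),
        radius=np.array(radius), parent=np.array(parent),
        meta={
            "preset": _asdict(preset), "seed": _seed_repr(seed),
            "true_branch_points": int(branch_nodes),
            "true_total_length_um": float(total_len),
            "true_n_primary": int(preset.n_primary),
        },
    )

    n_spines = rng.poisson(preset.spine_density_true * total_len)
    type_names = ("stubby", "thin", "mushroom")
    type_idx = rng.choice(3, size=n_spines, p=np.asarray(preset.spine_type_probs))
    spines = []
    for j in range(n_spines):
        t = type_names[type_idx[j]]
        (l0, l1), (n0, n1), (h0, h1) = _SPINE_GEOMETRY[t]
        spines.append(Spine(
            attach_position=float(rng.uniform(0.0, total_len)),
            length=float(rng.uniform(l0, l1)),
            neck_diam=float(rng.uniform(n0, n1)),
            head_diam=float(rng.uniform(h0, h1)),
            true_type=t,
        ))
    morph.meta["true_spine_count"] = n_spines
    morph.meta["true_spine_types"] = [s.true_type for s in spines]
    return morph, spines


# ---------------------------------------------------------------------------
# genotype presets
#
# Calibrated constants below were frozen by brute-force calibration against
# the analytic kernel (sEPSC kinetics), the passive-fit sag pipeline (g_h),
# the closed-form branching recursions (branch_prob, segment lengths) and
# >= 1e4-vesicle nearest-neighbour simulation (cluster_sd); see
# docs/methods.md.

GH_WT = 2.0
GH_TAU35 = 6.23          # calibrated: sag_sub(Tau35)/sag_sub(WT) ~= 2

NEURON_PRESETS: dict[str, NeuronParams] = {
    "WT": NeuronParams(g_h=GH_WT),
    "Tau35": NeuronParams(g_h=GH_TAU35),
}

SEPSC_PRESETS: dict[str, SepscPreset] = {
    "WT": SepscPreset(rate=2.0, amp=-20.0, tau_rise=0.8, tau_decay=4.0,
                      noise_sd=2.0, duration=30.0),
    # Tau35: 77 % rate reduction, equal amplitude, kernel calibrated so the
    # analytic rate-of-rise ratio is 0.43 and the half-width ratio 2.3
    "Tau35": SepscPreset(rate=0.46, amp=-20.0, tau_rise=1.87, tau_decay=9.11,
                         noise_sd=2.0, duration=30.0),
}

_VESICLE_COMMON = dict(count_dispersion=10.0, sv_diameter_mean=40.0,
                       sv_diameter_sd=4.0, az_length=500.0,
                       docked_fraction_true=0.05, presyn_area_mean=0.35)

VESICLE_PRESETS: dict[str, VesiclePreset] = {
    "WT-4mo": VesiclePreset(mean_sv_count=110.0, cluster_sd=220.0,
                            dcv_prob=0.30, **_VESICLE_COMMON),
    "Tau35-4mo": VesiclePreset(mean_sv_count=80.3, cluster_sd=236.3,
                               dcv_prob=0.30, **_VESICLE_COMMON),
    "WT-10mo": VesiclePreset(mean_sv_count=100.0, cluster_sd=220.0,
                             dcv_prob=0.30, **_VESICLE_COMMON),
    "Tau35-10mo": VesiclePreset(mean_sv_count=61.0, cluster_sd=215.0,
                                dcv_prob=0.078, **_VESICLE_COMMON),
}

MORPH_PRESETS: dict[str, MorphPreset] = {
    # branch_prob solved from the closed-form branching recursion
    # (5 primaries, depth 4): expected branch points 9.0 (WT) and 5.04
    # (Tau35, 44 % fewer); Tau35 segment length set for a 20 % shorter
    # mean dendrite given its sparser tree
    "WT": MorphPreset(branch_prob=0.54699, segment_len_mean=35.0, max_depth=4,
                      soma_radius=8.0, spine_density_true=0.80,
                      spine_type_probs=(0.25, 0.30, 0.45)),
    "Tau35": MorphPreset(branch_prob=0.40701, segment_len_mean=42.706,
                         max_depth=4, soma_radius=8.0,
                         spine_density_true=0.328,
                         spine_type_probs=(0.25, 0.55, 0.20)),
}


# ---------------------------------------------------------------------------
# cohort assembly

def generate_cohort(design: dict, seed: int, outdir: str | Path) -> dict:
    """Write a reproducible dataset bundle to ``outdir``.

    ``design`` maps group names to preset names and sample sizes, e.g.::

        {"groups": [
            {"name": "WT-4mo", "genotype": "WT", "age": "4mo",
             "n_traces": 8, "n_sepsc": 8, "n_maps": 16, "n_morphologies": 10}
        ]}

    Presets are looked up by genotype (neurons, sEPSC, morphology) and by
    ``genotype-age`` (vesicle maps).  The same seed yields byte-identical
    output.  Returns a manifest dict (also written as ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "groups": []}
    protocol = StepProtocol()

    for gi, grp in enumerate(design["groups"]):
        name, genotype, age = grp["name"], grp["genotype"], grp.get("age", "")
        for key, presets in (("neuron", NEURON_PRESETS),
                             ("sepsc", SEPSC_PRESETS),
                             ("morph", MORPH_PRESETS)):
            if genotype not in presets:
                raise KeyError(f"unknown {key} preset {genotype!r}")
        gdir = outdir / name
        for sub in ("traces", "sepsc", "maps", "morphologies"):
            (gdir / sub).mkdir(parents=True, exist_ok=True)

        entry = {"name": name, "genotype": genotype, "age": age, "files": {}}

        n_traces = grp.get("n_traces", 0)
        for i in range(n_traces):
            tr = simulate_neuron(NEURON_PRESETS[genotype], protocol,
                                 seed=_child_seed(seed, gi, 0, i))
            write_trace(tr, gdir / "traces" / f"cc{i:03d}.csv")
        entry["files"]["traces"] = n_traces

        n_sepsc = grp.get("n_sepsc", 0)
        for i in range(n_sepsc):
            tr, _ = generate_sepsc_trace(SEPSC_PRESETS[genotype],
                                         _child_seed(seed, gi, 1, i))
            write_trace(tr, gdir / "sepsc" / f"vc{i:03d}.csv")
        entry["files"]["sepsc"] = n_sepsc

        n_maps = grp.get("n_maps", 0)
        if n_maps:
            vkey = f"{genotype}-{age}" if age else genotype
            if vkey not in VESICLE_PRESETS:
                raise KeyError(f"unknown vesicle preset {vkey!r}")
            child = int(_child_seed(seed, gi, 2, 0).integers(2 ** 31))
            maps = generate_vesicle_cohort(
                VESICLE_PRESETS[vkey], n_maps, child, id_prefix=f"{name}-")
            for i, m in enumerate(maps):
                write_vesicle_map(m, gdir / "maps" / f"syn{i:03d}.csv")
        entry["files"]["maps"] = n_maps

        n_morph = grp.get("n_morphologies", 0)
        for i in range(n_morph):
            morph, spines = generate_morphology(MORPH_PRESETS[genotype],
                                                _child_seed(seed, gi, 3, i))
            write_swc(morph, gdir / "morphologies" / f"n{i:03d}.swc")
            write_spines(spines, gdir / "morphologies" / f"n{i:03d}_spines.csv")
        entry["files"]["morphologies"] = n_morph

        manifest["groups"].append(entry)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


# ---------------------------------------------------------------------------
# helpers

def _asdict(preset) -> dict:
    return {k: getattr(preset, k) for k in preset.__dataclass_fields__}


def _seed_repr(seed):
    if isinstance(seed, np.random.Generator):
        return "generator"
    return int(seed) if seed is not None else None


def _entropy(seed) -> int:
    if isinstance(seed, np.random.Generator):
        raise TypeError("cohort generation needs an integer seed")
    return int(seed)


def _child_seed(seed: int, *path: int):
    return np.random.default_rng(np.random.SeedSequence(entropy=[int(seed), *path]))
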