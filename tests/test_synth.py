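"""Synthetic-data generators: ground truth, constraints, reproducibility."""

import numpy as np
import pytest

from tauhcn import synth
from tauhcn.morpho import branch_metrics
from tauhcn.synth import (MORPH_PRESETS, SEPSC_PRESETS, VESICLE_PRESETS,
                          MorphPreset, SepscPreset, VesiclePreset,
                          generate_cohort, generate_morphology,
                          generate_sepsc_trace, generate_vesicle_cohort,
                          generate_vesicle_map)


# ------------------------------------------------------------- sEPSC traces

def test_zero_rate_gives_pure_noise_and_empty_truth():
    preset = SepscPreset(rate=0.0, amp=-20.0, tau_rise=0.8, tau_decay=4.0,
                         noise_sd=2.0, duration=10.0)
    tr, gt = generate_sepsc_trace(preset, 4)
    assert gt.event_times_s.size == 0
    assert abs(tr.samples.mean()) < 0.2
    assert tr.samples.std() == pytest.approx(2.0, rel=0.05)


def test_noiseless_trace_has_one_minimum_per_event():
    preset = SepscPreset(rate=5 / 30.0, amp=-20.0, tau_rise=0.8, tau_decay=4.0,
                         noise_sd=0.0, duration=30.0)
    for seed in range(5):
        tr, gt = generate_sepsc_trace(preset, seed)
        y = tr.samples
        minima = np.flatnonzero((y[1:-1] < y[:-2]) & (y[1:-1] <= y[2:])
                                & (y[1:-1] < -15.0))
        # well-separated events each produce exactly one deep minimum
        if gt.event_times_s.size and np.diff(gt.event_times_s).min() > 0.05:
            assert minima.size == gt.event_times_s.size


def test_empirical_rate_matches_preset():
    """Law of large numbers: across many traces the mean event count per
    trace sits within 3 SE of rate * duration, for both genotype presets."""
    for name, preset in SEPSC_PRESETS.items():
        counts = [generate_sepsc_trace(preset, 5000 + i)[1].event_times_s.size
                  for i in range(100)]
        expected = preset.rate * preset.duration
        se = np.sqrt(expected / 100)
        assert abs(np.mean(counts) - expected) < 3 * se, name


def test_runaway_event_count_refused():
    preset = SepscPreset(rate=1e6, amp=-20.0, tau_rise=0.8, tau_decay=4.0,
                         noise_sd=0.0, duration=10.0)
    with pytest.raises(ValueError):
        generate_sepsc_trace(preset, 0)


# ------------------------------------------------------------ vesicle maps

def test_hard_core_constraint_every_seed():
    preset = VESICLE_PRESETS["WT-4mo"]
    for seed in range(30):
        m = generate_vesicle_map(preset, seed)
        pts = m.coords[m.sv_mask]
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= preset.sv_diameter_mean - 1e-9


def test_negative_binomial_count_mean():
    preset = VESICLE_PRESETS["WT-4mo"]
    counts = [generate_vesicle_map(preset, 4000 + i).sv_count
              for i in range(200)]
    se = np.std(counts) / np.sqrt(len(counts))
    assert abs(np.mean(counts) - preset.mean_sv_count) < 3 * se
    # overdispersion: variance well above the Poisson level
    assert np.var(counts) > 2 * preset.mean_sv_count


def test_small_count_preset_can_fall_below_inclusion_bound():
    from tauhcn.ultra import filter_synapses
    preset = VesiclePreset(mean_sv_count=10.0, count_dispersion=10.0,
                           cluster_sd=220.0, sv_diameter_mean=40.0,
                           sv_diameter_sd=4.0, az_length=500.0,
                           docked_fraction_true=0.0, dcv_prob=0.0,
                           presyn_area_mean=0.35)
    maps = [generate_vesicle_map(preset, i, synapse_id=f"s{i}")
            for i in range(60)]
    kept = filter_synapses(maps)
    assert any(m.sv_count < 10 for m in maps)      # some draws below 10 SVs
    assert all(m.sv_count >= 10 for m in kept)     # ... and they are excluded


def test_cohort_dcv_prevalence_is_quota_assigned():
    maps = generate_vesicle_cohort(VESICLE_PRESETS["WT-10mo"], 40, 7)
    frac = np.mean([m.is_dcv.any() for m in maps])
    assert frac == pytest.approx(0.30, abs=0.013)  # round(40*0.3)/40


def test_infeasible_packing_raises_helpful_error():
    preset = VesiclePreset(mean_sv_count=200.0, count_dispersion=1e6,
                           cluster_sd=30.0, sv_diameter_mean=40.0,
                           sv_diameter_sd=4.0, az_length=500.0,
                           docked_fraction_true=0.0, dcv_prob=0.0,
                           presyn_area_mean=0.35)
    with pytest.raises(RuntimeError, match="cluster_sd"):
        generate_vesicle_map(preset, 0, max_tries=20)


# ------------------------------------------------------------- morphologies

def test_branch_prob_zero_gives_unbranched_neurites():
    preset = MorphPreset(branch_prob=0.0, segment_len_mean=30.0, max_depth=4,
                         soma_radius=8.0, spine_density_true=0.0,
                         spine_type_probs=(1.0, 0.0, 0.0), n_primary=3)
    m, spines = generate_morphology(preset, 0)
    bp, _, _ = branch_metrics(m)
    assert bp == 0
    assert m.meta["true_branch_points"] == 0
    assert spines == []


def test_ground_truth_branch_count_matches_tree_traversal():
    """The generator's branch-point label equals an independent recount by
    child-counting traversal, for both genotype presets across seeds."""
    for name, preset in MORPH_PRESETS.items():
        for seed in range(25):
            m, _ = generate_morphology(preset, seed)
            children = {}
            for k, p in enumerate(m.parent):
                if p != -1 and m.types[k] != 1:
                    children[p] = children.get(p, 0) + 1
            recount = sum(1 for nid, c in children.items()
                          if c >= 2 and m.types[m.row_of(nid)] != 1)
            assert m.meta["true_branch_points"] == recount, name
            assert branch_metrics(m)[0] == recount


def test_spine_count_matches_poisson_mean():
    """0.5 spines/µm over the generated cable: mean count within 3 SE."""
    preset = MorphPreset(branch_prob=0.0, segment_len_mean=200.0, max_depth=1,
                         soma_radius=8.0, spine_density_true=0.5,
                         spine_type_probs=(0.3, 0.4, 0.3), n_primary=1)
    counts, lengths = [], []
    for seed in range(60):
        m, spines = generate_morphology(preset, seed)
        counts.append(len(spines))
        lengths.append(m.meta["true_total_length_um"])
    expected = 0.5 * np.mean(lengths)
    se = np.sqrt(expected / 60)
    assert abs(np.mean(counts) - expected) < 3 * se


# ---------------------------------------------------------------- cohorts

def _checksum(root):
    import hashlib
    h = hashlib.sha256()
    for f in sorted(p for p in root.rglob("*") if p.is_file()):
        h.update(f.name.encode())
        h.update(f.read_bytes())
    return h.hexdigest()


def test_cohort_is_bit_reproducible(tmp_path):
    design = {"groups": [
        {"name": "WT-4mo", "genotype": "WT", "age": "4mo",
         "n_traces": 1, "n_sepsc": 1, "n_maps": 3, "n_morphologies": 2},
        {"name": "Tau35-4mo", "genotype": "Tau35", "age": "4mo",
         "n_traces": 1, "n_sepsc": 1, "n_maps": 3, "n_morphologies": 2},
    ]}
    generate_cohort(design, 42, tmp_path / "a")
    generate_cohort(design, 42, tmp_path / "b")
    generate_cohort(design, 43, tmp_path / "c")
    assert _checksum(tmp_path / "a") == _checksum(tmp_path / "b")
    assert _checksum(tmp_path / "a") != _checksum(tmp_path / "c")


def test_cohort_unknown_preset_is_config_error(tmp_path):
    design = {"groups": [{"name": "x", "genotype": "HET", "age": "4mo",
                          "n_maps": 1}]}
    with pytest.raises(KeyError):
        generate_cohort(design, 1, tmp_path)


def test_distinct_seeds_give_distinct_event_times():
    a = generate_sepsc_trace(SEPSC_PRESETS["WT"], 1)[1].event_times_s
    b = generate_sepsc_trace(SEPSC_PRESETS["WT"], 2)[1].event_times_s
    assert a.size != b.size or not np.allclose(a, b)
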