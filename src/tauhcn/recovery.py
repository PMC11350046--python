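"""Ground-truth effect-recovery experiments.

Each function generates a synthetic two-genotype cohort from the frozen
presets, runs the corresponding analysis pipeline (detection, counting,
fitting — never the generator's labels), and returns the recovered
between-group effect.  Group comparisons use a paired common-random-numbers
design: unit ``i`` of each genotype is generated from the same seed stream,
so preset differences are measured against matched realisations and the
Monte-Carlo variance of ratio estimates collapses without touching sample
sizes.  These experiments back both the acceptance test-suite and
``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from . import morpho, sepsc, synth, ultra

__all__ = [
    "sepsc_effect_recovery",
    "vesicle_nn_difference",
    "sv_count_reduction",
    "dcv_fraction_reduction",
    "morphology_effect_recovery",
]


def _pair_rng(seed: int, tag: int, i: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=[int(seed), tag, i]))


def sepsc_effect_recovery(seed: int, n_per_group: int = 20) -> dict:
    """Detect sEPSCs in generated 30 s traces and compare genotype means.

    Returns the percent reduction in mean detected frequency, the Tau35/WT
    rate-of-rise ratio (as %), and the Tau35/WT half-width fold-change, each
    computed from per-cell statistics of the averaged detected events.  One
    WT-kinetics template and the default criterion threshold are used for
    both genotypes.
    """
    template = sepsc.make_template()
    out: dict[str, dict] = {}
    for genotype in ("WT", "Tau35"):
        preset = synth.SEPSC_PRESETS[genotype]
        freqs, rises, widths = [], [], []
        for i in range(n_per_group):
            trace, _ = synth.generate_sepsc_trace(preset, _pair_rng(seed, 11, i))
            events = sepsc.detect_events(trace, template)
            mean_wave = sepsc.average_events(trace, events)
            stats = sepsc.waveform_stats(mean_wave, events, preset.duration,
                                         trace.dt)
            freqs.append(stats.frequency)
            if events.n:
                rises.append(stats.rate_of_rise)
                widths.append(stats.half_width)
        out[genotype] = {
            "frequency_hz": float(np.mean(freqs)),
            "rate_of_rise_pa_ms": float(np.mean(rises)),
            "half_width_ms": float(np.mean(widths)),
        }
    wt, tau = out["WT"], out["Tau35"]
    return {
        "per_group": out,
        "n_per_group": n_per_group,
        "frequency_reduction_pct":
            100.0 * (1.0 - tau["frequency_hz"] / wt["frequency_hz"]),
        "rate_of_rise_ratio_pct":
            100.0 * tau["rate_of_rise_pa_ms"] / wt["rate_of_rise_pa_ms"],
        "half_width_fold": tau["half_width_ms"] / wt["half_width_ms"],
    }


def _vesicle_cohorts(seed: int, age: str, n_per_group: int):
    for genotype in ("WT", "Tau35"):
        preset = synth.VESICLE_PRESETS[f"{genotype}-{age}"]
        yield genotype, synth.generate_vesicle_cohort(
            preset, n_per_group, seed, id_prefix=f"{genotype}-")


def vesicle_nn_difference(seed: int, age: str = "4mo",
                          n_per_group: int = 16) -> dict:
    """Group mean nearest-neighbour distance difference (Tau35 - WT, nm).

    All generated maps enter the comparison (the clustering statistic needs
    only >= 2 vesicles); the count-based inclusion filter belongs to the
    counting experiments.
    """
    means = {}
    for genotype, maps in _vesicle_cohorts(seed, age, n_per_group):
        results = [ultra.nn_analysis(m) for m in maps if m.sv_count >= 2]
        _, group_mean, _ = ultra.group_nn_summary(results)
        means[genotype] = group_mean
    return {
        "per_group_mean_nn_nm": means,
        "n_per_group": n_per_group,
        "age": age,
        "nn_difference_nm": means["Tau35"] - means["WT"],
    }


def sv_count_reduction(seed: int, age: str, n_per_group: int = 100) -> dict:
    """Percent reduction in mean SV count after the 10-250 inclusion filter."""
    means = {}
    for genotype, maps in _vesicle_cohorts(seed, age, n_per_group):
        included = ultra.filter_synapses(maps)
        counts = [ultra.synapse_metrics(m).sv_count for m in included]
        means[genotype] = float(np.mean(counts))
    return {
        "per_group_mean_sv": means,
        "n_per_group": n_per_group,
        "age": age,
        "sv_reduction_pct": 100.0 * (1.0 - means["Tau35"] / means["WT"]),
    }


def dcv_fraction_reduction(seed: int, age: str = "10mo",
                           n_per_group: int = 200) -> dict:
    """Percent reduction in the fraction of synapses containing DCVs."""
    fracs = {}
    for genotype, maps in _vesicle_cohorts(seed, age, n_per_group):
        included = ultra.filter_synapses(maps)
        flags = [ultra.synapse_metrics(m).has_dcv for m in included]
        fracs[genotype] = float(np.mean(flags))
    return {
        "per_group_dcv_fraction": fracs,
        "n_per_group": n_per_group,
        "age": age,
        "dcv_reduction_pct": 100.0 * (1.0 - fracs["Tau35"] / fracs["WT"]),
    }


def morphology_effect_recovery(seed: int, n_per_group: int = 50) -> dict:
    """Recover spine-density and branch-point reductions from morphometry."""
    out: dict[str, dict] = {}
    for genotype in ("WT", "Tau35"):
        preset = synth.MORPH_PRESETS[genotype]
        densities, branches, lengths = [], [], []
        for i in range(n_per_group):
            m, spines = synth.generate_morphology(preset, _pair_rng(seed, 31, i))
            bp, mean_len, _ = morpho.branch_metrics(m)
            density, _ = morpho.spine_metrics(m, spines)
            densities.append(density)
            branches.append(bp)
            lengths.append(mean_len)
        out[genotype] = {
            "spine_density_per_um": float(np.mean(densities)),
            "branch_points": float(np.mean(branches)),
            "mean_dendrite_length_um": float(np.mean(lengths)),
        }
    wt, tau = out["WT"], out["Tau35"]
    return {
        "per_group": out,
        "n_per_group": n_per_group,
        "spine_density_reduction_pct":
            100.0 * (1.0 - tau["spine_density_per_um"] / wt["spine_density_per_um"]),
        "branch_point_reduction_pct":
            100.0 * (1.0 - tau["branch_points"] / wt["branch_points"]),
        "dendrite_length_reduction_pct":
            100.0 * (1.0 - tau["mean_dendrite_length_um"]
                     / wt["mean_dendrite_length_um"]),
    }
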