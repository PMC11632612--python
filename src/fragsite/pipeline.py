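"""End-to-end synthetic demonstration pipeline.

Generates every input with the synthetic-data module, runs each analysis
stage, and writes deterministic JSON reports (config hash + seed embedded,
no timestamps). Used by the ``fragsite demo`` CLI subcommand.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np

from . import features, fish, mnase, simulate, sizing, stats
from .io import RunConfig, json_report

logger = logging.getLogger(__name__)

STAGES = ("map-breaks", "size-repeats", "mnase", "stats", "features")


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES) -> dict[str, dict]:
    """Run the requested stages on synthetic inputs; write one report per stage."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reports: dict[str, dict] = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.perf_counter()
        payload = _STAGE_FUNCS[stage](config)
        reports[stage] = payload
        (outdir / f"{stage}.json").write_text(json_report(payload, config))
        logger.info("stage %s finished in %.2f s", stage, time.perf_counter() - t0)
    return reports


def _stage_map_breaks(config: RunConfig) -> dict:
    panel = simulate.default_panel()
    profile = simulate.default_profile()
    obs, breaks = simulate.simulate_metaphase_breaks(
        profile, panel, n_metaphases=5000, fragility_freq=0.10,
        resolution_bp=20_000, seed=simulate.substream(config.seed, "breaks"),
    )
    inferred = fish.infer_breakage_profile(
        panel, list(obs.values()), spanning_split=config.spanning_split,
        enforce_monotone=True,
    )
    freq = fish.fragility_frequency(7, 100, alpha=config.ci_alpha)
    return {
        "n_metaphases": 5000,
        "n_breaks": len(breaks),
        "boundaries": list(inferred.boundaries),
        "percent_breakage": list(inferred.percent),
        "fragility_example": {
            "frequency_pct": 100.0 * freq.frequency,
            "ci_low": freq.ci_low, "ci_high": freq.ci_high,
            "p_vs_background": fish.fragility_significance(
                7, 100, background_rate=config.background_rate),
        },
    }


def _stage_size_repeats(config: RunConfig) -> dict:
    digest = sizing.DIGESTS[config.digest]
    ladder = [(10.0 + 5.0 * i, 31_000.0 - 3_300.0 * i) for i in range(10)]
    repeats = [2, 300, 770, 4400]
    fragments = [(float(sizing.repeats_to_bp(r, digest)), 1.0) for r in repeats]
    lane = simulate.simulate_gel_lane(
        ladder, fragments, migration_model="linear", noise_sd=0.0,
        seed=simulate.substream(config.seed, "gel"),
    )
    cal = sizing.fit_ladder(ladder, model="linear")
    summary = sizing.summarize_mosaicism(lane, cal, digest)
    return {
        "digest": config.digest,
        "planted_repeats": repeats,
        "recovered_repeats": [e.repeats for e in summary.estimates],
        "modal_repeats": summary.modal_repeats,
    }


def _stage_mnase(config: RunConfig) -> dict:
    series = simulate.simulate_mnase_series(
        {"expanded": (100.0, 1.5), "non_expanded": (5.0, 1.5)},
        doses=[0, 1, 2.5, 5, 10, 25, 50, 100, 200],
        seed=simulate.substream(config.seed, "mnase"), noise_sd=0.02,
    )
    curve = mnase.resistance_curve(series)
    comp = mnase.compare_alleles(curve)
    sites = [("SphI", -3335), ("PvuII_up", -1252), ("EcoRI", -697), ("AflII", -404),
             ("PciI", 689), ("BamHI", 1714), ("PvuII_down", 2440), ("PsiI", 3750)]
    retention = mnase.RetentionMatrix(
        sites=sites,
        retention={"P3": np.array([0.04, 0.35, 0.6, 0.8, 0.8, 0.55, 0.3, 0.05])},
    )
    bmap = mnase.map_boundaries(retention, "P3", threshold=config.retention_threshold)
    return {
        "half_max": curve.half_max,
        "half_max_ratio": comp.half_max_ratio,
        "auc_ratio": comp.auc_ratio,
        "upstream_extent": list(bmap.upstream.interval),
        "downstream_extent": list(bmap.downstream.interval),
    }


def _stage_stats(config: RunConfig) -> dict:
    seed = simulate.substream(config.seed, "counts")
    case, control = simulate.simulate_count_tables(0.03, 0.01, 1000, seed)
    mn = stats.mn_nbud_test(case, control)
    exp = simulate.simulate_fluctuation_cultures(
        rate=1e-6, n_cultures=30, n_final=10**7,
        seed=simulate.substream(config.seed, "fluctuation"),
    )
    rate = stats.lea_coulson_rate(exp)
    return {
        "mn_nbud": {"p_value": mn.p_value, "odds_ratio": mn.effect},
        "fluctuation": {"m": rate.m, "rate": rate.rate, "censored": rate.censored},
    }


def _stage_features(config: RunConfig) -> dict:
    seed = simulate.substream(config.seed, "tracks")
    rng = np.random.default_rng(seed)
    fsfs = features.LocusSet(
        [features.Locus("chrF", 1_000_000 + i * 3_000_000,
                        1_000_000 + i * 3_000_000 + 100,
                        id=f"fsfs_{i}", repeat_units=8.7) for i in range(10)],
        label="fsfs",
    )
    pool = simulate.simulate_control_loci(200, simulate.substream(config.seed, "controls"))
    controls, median_units = features.select_controls(pool, min_units=4.5, n_target=30,
                                                      seed=int(rng.integers(2**31 - 1)))
    track = simulate.simulate_feature_tracks(
        fsfs, controls, effect=1.0, half_width=config.window_sizes[0], seed=seed)
    comparisons = []
    for hw in config.window_sizes:
        fs = features.window_aggregate(track, fsfs, hw)
        cs = features.window_aggregate(track, controls, hw)
        comparisons.append(features.compare_sets(fs, cs, feature="sim"))
    raw = [c.p_value for c in comparisons]
    adj = features.bh_adjust(raw)
    return {
        "control_median_units": median_units,
        "comparisons": [
            {"half_width": c.half_width, "p_raw": c.p_value, "p_bh": a,
             "direction": c.direction}
            for c, a in zip(comparisons, adj)
        ],
    }


_STAGE_FUNCS = {
    "map-breaks": _stage_map_breaks,
    "size-repeats": _stage_size_repeats,
    "mnase": _stage_mnase,
    "stats": _stage_stats,
    "features": _stage_features,
}
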