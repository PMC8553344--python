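"""Orchestration: the full spike-synchrony analysis over a pair dataset.

``run_spike_analysis`` executes, for every pair of a dataset: convolution
and trial-averaged cross-correlograms, rate-matched Poisson surrogate
nulls and null-corrected central peaks, CPSD/APSD spectrograms, the
dataset-pooled 95th-percentile ridge threshold (computed before any
per-pair ridge detection), ridge detection and summaries, CV2 and
rate-vs-ridge coupling, and theta-band CPSD averages.  ``run_reports``
aggregates bundles into group-level prevalence tables (chi-squared),
ridge CDFs, occupancy tables and BH-adjusted statistics.

All randomness flows from a single root seed through named substreams;
outputs carry the config hash and seed so reruns are bit-reproducible.
"""

from __future__ import annotations

import zlib

import numpy as np

from . import correlogram as cg
from . import ridge as rg
from . import spectral as sp
from .config import AnalysisConfig
from .core_events import cv2_series
from .stats_infer import ContingencyTable2x2, bh_adjust, chi2_2x2
from .synth import SurrogateSpec, poisson_surrogate

__all__ = ["run_spike_analysis", "run_reports", "substream"]


def substream(root_seed: int, name: str) -> int:
    """Derive a named child seed (< 2**31) from the root seed.

    Uses a stable (process-independent) digest of the name so reruns with
    the same root seed reproduce every substream exactly.
    """
    digest = zlib.crc32(name.encode())
    ss = np.random.SeedSequence([int(root_seed), digest])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _surrogate_pair_sets(pair, config, seed):
    spec_a = SurrogateSpec(seed=substream(seed, f"{pair.pair_id}:a"),
                           n_repeats=config.n_surrogates,
                           psth_bin=config.psth_bin,
                           psth_sigma=config.psth_sigma)
    spec_b = SurrogateSpec(seed=substream(seed, f"{pair.pair_id}:b"),
                           n_repeats=config.n_surrogates,
                           psth_bin=config.psth_bin,
                           psth_sigma=config.psth_sigma)
    surr_a = poisson_surrogate(pair.cell_a, spec_a)
    surr_b = poisson_surrogate(pair.cell_b, spec_b)
    return [
        type(pair)(sa, sb, pair.cell_types, pair.glomerular_relation,
                   pair.intersomatic_um, f"{pair.pair_id}:surr{k}")
        for k, (sa, sb) in enumerate(zip(surr_a, surr_b))
    ]


def run_spike_analysis(pairs, config: AnalysisConfig | None = None,
                       seed: int | None = None) -> dict:
    """Run the spike-time synchrony pipeline over a list of pairs.

    Returns a bundle dict keyed by pair_id plus dataset-level entries
    (ridge thresholds, summaries, config provenance).
    """
    config = config or AnalysisConfig()
    seed = config.seed if seed is None else seed

    per_pair = {}
    cpsd_all, apsd_all = [], []
    for pair in pairs:
        surr = _surrogate_pair_sets(pair, config, seed)
        expt_cg = cg.cross_correlogram(pair, fs=config.fs,
                                       sigma=config.kernel_sigma)
        null_cg = cg.average_correlograms(
            [cg.cross_correlogram(s, fs=config.fs, sigma=config.kernel_sigma)
             for s in surr])
        peak = cg.correlogram_peak(expt_cg, null_cg,
                                   half_window=config.dt_spike)
        cpsd = sp.cpsd_spectrogram(pair, config.welch_window,
                                   config.welch_overlap, fs=config.fs,
                                   sigma=config.kernel_sigma)
        theta_cpsd = sp.cpsd_spectrogram(pair, fs=config.fs,
                                         sigma=config.kernel_sigma, theta=True)
        apsd_a = sp.apsd_spectrogram(pair.cell_a, config.welch_window,
                                     config.welch_overlap, fs=config.fs,
                                     sigma=config.kernel_sigma)
        apsd_b = sp.apsd_spectrogram(pair.cell_b, config.welch_window,
                                     config.welch_overlap, fs=config.fs,
                                     sigma=config.kernel_sigma)
        cpsd_all.append(cpsd)
        apsd_all.extend([apsd_a, apsd_b])
        per_pair[pair.pair_id] = {
            "pair": pair,
            "correlogram": expt_cg,
            "null_correlogram": null_cg,
            "corrected_peak": peak,
            "cpsd": cpsd,
            "theta_band_power": sp.band_average(theta_cpsd,
                                                *config.theta_band),
            "apsd_a": apsd_a,
            "apsd_b": apsd_b,
            "cv2_a": [cv2_series(tr).median for tr in pair.cell_a.trains],
            "cv2_b": [cv2_series(tr).median for tr in pair.cell_b.trains],
        }

    # dataset-pooled thresholds precede any per-pair ridge detection
    xi = rg.ridge_threshold(cpsd_all, config.ridge_band,
                            config.ridge_percentile, scope="spike-CPSD",
                            symbol="xi")
    lam = rg.ridge_threshold(apsd_all, config.ridge_band,
                             config.ridge_percentile, scope="spike-APSD",
                             symbol="lambda")
    for pair in pairs:
        b = per_pair[pair.pair_id]
        b["cpsd_ridges"] = rg.detect_ridges(b["cpsd"], xi,
                                            config.ridge_continuity,
                                            config.ridge_band,
                                            config.ridge_min_bins)
        b["apsd_ridges_a"] = rg.detect_ridges(b["apsd_a"], lam,
                                              config.ridge_continuity,
                                              config.ridge_band,
                                              config.ridge_min_bins)
        b["apsd_ridges_b"] = rg.detect_ridges(b["apsd_b"], lam,
                                              config.ridge_continuity,
                                              config.ridge_band,
                                              config.ridge_min_bins)
        b["rate_vs_ridge"] = rg.rate_vs_ridge(pair, b["cpsd_ridges"])

    protocol = pairs[0].protocol if pairs else None
    summary = rg.ridge_summary(
        [per_pair[p.pair_id]["cpsd_ridges"] for p in pairs], protocol) \
        if pairs else None
    return {
        "pairs": per_pair,
        "xi": xi,
        "lambda": lam,
        "cpsd_ridge_summary": summary,
        "config": config.to_dict(),
        "seed": seed,
    }


def run_reports(bundles_by_group: dict) -> dict:
    """Group-level report: prevalence tables with chi-squared, pooled CDFs.

    ``bundles_by_group`` maps a group name (e.g. "TC", "MC") to a bundle
    from :func:`run_spike_analysis`.  Prevalence compares the fraction of
    pairs with >= 1 CPSD ridge between the first two groups.
    """
    report = {"groups": {}}
    prevalence = []
    for name, bundle in bundles_by_group.items():
        s = bundle["cpsd_ridge_summary"]
        report["groups"][name] = {
            "n_pairs": s["n_pairs"],
            "n_with_ridge": s["n_with_ridge"],
            "fraction_with_ridge": s["fraction_with_ridge"],
            "ridge_freqs": s["freqs"],
            "ridge_powers": s["powers"],
            "occupancy": s["occupancy"],
            "corrected_peaks": [b["corrected_peak"]
                                for b in bundle["pairs"].values()],
        }
        prevalence.append((s["n_with_ridge"], s["n_pairs"] - s["n_with_ridge"]))
    if len(prevalence) >= 2:
        (a, b), (c, d) = prevalence[:2]
        if (a + b) and (c + d) and (a + c) and (b + d):
            stat, p = chi2_2x2(ContingencyTable2x2(a, b, c, d))
            report["prevalence_chi2"] = {"chi2": stat, "p": p,
                                         "table": (a, b, c, d)}
        else:
            report["prevalence_chi2"] = {"chi2": float("nan"), "p": float("nan"),
                                         "table": (a, b, c, d),
                                         "flag": "degenerate margin"}
    ps = [g.get("p") for g in [report.get("prevalence_chi2", {})] if "p" in g]
    if ps and np.all(np.isfinite(ps)):
        report["p_bh"] = list(bh_adjust(ps))
    return report
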