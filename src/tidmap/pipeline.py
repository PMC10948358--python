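"""Full-analysis orchestration: from a config mapping to a report.

Runs the stages of the TID analysis in dependency order — simulate (or
load) a contact map, balance it, mask white lines, call bundles, call
boundaries by both methods, compute gene-anchored pileups, fit the
polymerase occupancy models and correlate tracks — and collects every
result in a JSON-serializable :class:`AnalysisReport`.  Stages are
toggled by the config; every random stage draws from the single
explicit ``seed`` recorded in the report, so identical config+seed give
byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from tidmap import border_callers as bc
from tidmap import pileup as pu
from tidmap import polymerase_model as pm
from tidmap import synthetic as syn
from tidmap import tid_caller as tc
from tidmap import tracks as tk
from tidmap.contact_map import (
    ContactMap,
    detect_white_lines,
    distance_decay,
    ice_balance,
    read_map,
    rebin,
)

__all__ = ["AnalysisReport", "run_pipeline", "epod_style_overlap"]

DEFAULT_STAGES = ("bundles", "borders", "pileup", "model_fit", "track_correlations")


@dataclass
class AnalysisReport:
    """Machine-readable record of one full analysis run."""

    inputs: dict[str, Any] = field(default_factory=dict)
    bundles: list[dict] = field(default_factory=list)
    bundle_total_kb: float = 0.0
    borders: dict[str, list[dict]] = field(default_factory=dict)
    border_overlap: dict[str, int] = field(default_factory=dict)
    pileup: dict[str, Any] = field(default_factory=dict)
    model_fit: dict[str, Any] = field(default_factory=dict)
    track_correlations: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | None = None) -> str:
        def _default(obj):
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            raise TypeError(f"not serializable: {type(obj)}")

        text = json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True,
                          default=_default)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _require(config: dict, key: str, stage: str):
    if key not in config:
        raise ValueError(f"stage '{stage}' requires config key '{key}'")


def run_pipeline(config: dict) -> AnalysisReport:
    """Execute the configured stages and return the analysis report.

    Config keys (all optional unless a stage needs them):

    ``map_path``
        Path of a contact map (dense or triplet TSV), or
    ``scenario``
        kwargs for :func:`tidmap.synthetic.make_scenario` to simulate one.
    ``seed``
        Seed for every stochastic stage (required when any is enabled).
    ``stages``
        Iterable of stage names among ``bundles``, ``borders``,
        ``pileup``, ``model_fit``, ``track_correlations``.
    ``genes``
        List of :class:`tidmap.pileup.Gene` (defaults to the simulated
        layout when a scenario is used).
    ``chip``
        Per-bin occupancy/ChIP array for the model fit (defaults to the
        simulated occupancy).

    Missing inputs for an enabled stage raise before any computation.
    """
    stages = tuple(config.get("stages", DEFAULT_STAGES))
    known = set(DEFAULT_STAGES)
    unknown = set(stages) - known
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    seed = config.get("seed")

    scenario = None
    genes = config.get("genes")
    chip = config.get("chip")
    if "scenario" in config:
        if seed is None:
            raise ValueError("simulating a scenario requires an explicit 'seed'")
        scenario = syn.make_scenario(seed=seed, **config["scenario"])
        cmap = syn.simulate_map(scenario)
        if genes is None:
            genes = scenario.gene_layout
        if chip is None:
            chip = syn.simulate_occupancy(scenario).values
    elif "map_path" in config:
        cmap = read_map(config["map_path"])
    else:
        raise ValueError("config must provide 'map_path' or 'scenario'")
    if "pileup" in stages and not genes:
        raise ValueError("stage 'pileup' requires gene annotations")
    if "model_fit" in stages and chip is None:
        raise ValueError("stage 'model_fit' requires a chip/occupancy track")
    if ("pileup" in stages or "model_fit" in stages) and seed is None:
        raise ValueError("stochastic stages require an explicit 'seed'")

    report = AnalysisReport()
    report.inputs = {
        "seed": seed,
        "stages": list(stages),
        "map_path": config.get("map_path"),
        "scenario": {k: str(v) for k, v in config.get("scenario", {}).items()},
        "bin_size": cmap.bin_size,
        "genome_length": cmap.genome_length,
        "n_bins": cmap.n_bins,
        "total_contacts": cmap.total_contacts(),
    }

    coverage = np.nansum(cmap.matrix, axis=1)
    white = detect_white_lines(coverage[list(cmap.valid_bins())])
    # white-line detection runs on unmasked coverage; map back to bin ids
    valid = cmap.valid_bins()
    extra_mask = frozenset(int(valid[i]) for i in white)
    cmap = dataclasses.replace(cmap, matrix=cmap.matrix,
                               mask=cmap.mask | extra_mask)
    balanced = ice_balance(cmap)
    report.inputs["masked_bins"] = sorted(int(i) for i in balanced.mask)

    if "bundles" in stages:
        score = tc.diagonal_convolution_score(balanced)
        corrected = tc.remove_second_envelope(score, circular=balanced.circular)
        bundles = tc.call_bundles(corrected, raw_score=score,
                                  circular=balanced.circular, mask=balanced.mask)
        bs = balanced.bin_size
        report.bundles = [
            {
                "start_bp": b.start_bin * bs,
                "end_bp": b.end_bin * bs,
                "peak_bp": b.peak_bin * bs,
                "peak_score": b.peak_score,
            }
            for b in bundles
        ]
        report.bundle_total_kb = float(
            sum(b.n_bins for b in bundles) * bs / 1000.0
        )

    if "borders" in stages:
        ins_corr = bc.insulation_multiscale(balanced)
        ins = bc.call_insulation_borders(ins_corr, circular=balanced.circular)
        di_map = balanced
        factor = config.get("di_rebin_factor", 5)
        if factor > 1:
            di_map = ice_balance(rebin(cmap, factor))
        t_track = bc.directionality_index(
            di_map, window_bins=config.get("di_window_bins", 20)
        )
        di = bc.call_di_borders(t_track)
        report.borders = {
            "insulation": [
                {"bin": c.bin, "bp": c.bin * balanced.bin_size,
                 "statistic": c.statistic} for c in ins
            ],
            "DI": [
                {"bin": c.bin, "bp": c.bin * di_map.bin_size,
                 "statistic": c.statistic} for c in di
            ],
        }
        ins_bp = [c.bin * balanced.bin_size for c in ins]
        di_bp = [c.bin * di_map.bin_size for c in di]
        tol = config.get("border_tol_bins", 2) * di_map.bin_size
        matched, a_only, b_only = bc.compare_border_sets(
            [b // di_map.bin_size for b in ins_bp],
            [b // di_map.bin_size for b in di_bp],
            tol_bins=config.get("border_tol_bins", 2),
        )
        report.border_overlap = {
            "matched": matched, "insulation_only": a_only, "di_only": b_only,
            "tol_bp": tol,
        }

    if "pileup" in stages:
        fraction = config.get("active_fraction", 0.10)
        width_bp = config.get("pileup_width_bp", 50_000)
        active = pu.select_active_genes(list(genes), fraction)
        tu_starts = pu.select_tu_starts(
            active, genome_length=cmap.genome_length, circular=cmap.circular
        )
        anchors = [g.start_codon for g in tu_starts]
        strands = [g.strand for g in tu_starts]
        pile = pu.pileup_at_anchors(balanced, anchors, strands, width_bp)
        ratio = pu.pileup_ratio(pile, balanced, anchors, strands, width_bp,
                                seed=seed)
        w = pile.matrix.shape[0]
        c = w // 2
        central = np.nanmean(np.diagonal(ratio, offset=1)[c - 2 : c + 2])
        report.pileup = {
            "n_active": len(active),
            "n_tu_starts": len(tu_starts),
            "width_bp": width_bp,
            "central_adjacent_ratio": float(central),
        }

    if "model_fit" in stages:
        p = distance_decay(balanced)
        fits = pm.compare_variants(
            cmap, np.asarray(chip, dtype=float), p,
            grid=config.get("epsilon_grid", pm.DEFAULT_EPSILON_GRID),
            balanced=balanced,
        )
        report.model_fit = {
            str(v): {
                "best_epsilon": f.best_epsilon,
                "best_spearman": f.best_spearman,
                "log_likelihood": f.log_likelihood,
                "objective": f.objective,
            }
            for v, f in fits.items()
        }
        if all(np.isfinite(f.log_likelihood) for f in fits.values()):
            report.model_fit["preferred_variant"] = int(
                max(fits, key=lambda v: fits[v].log_likelihood)
            )

    if "track_correlations" in stages:
        sr = tk.short_range_signal(balanced)
        corrs = {}
        if chip is not None and np.ptp(np.asarray(chip, float)) > 0:
            chip_track = tk.GenomicTrack(
                values=np.asarray(chip, float), bin_size=cmap.bin_size,
                genome_length=cmap.genome_length, circular=cmap.circular,
                units="occupancy",
            )
            corrs["short_range_vs_occupancy"] = tk.track_spearman(sr, chip_track)
        if genes:
            rna = np.zeros(cmap.n_bins)
            for g in genes:
                b0 = g.start // cmap.bin_size
                b1 = -(-g.end // cmap.bin_size)
                idx = np.arange(b0, b1) % cmap.n_bins
                rna[idx] = np.maximum(rna[idx], g.expression)
            if np.ptp(rna) > 0:
                rna_track = tk.GenomicTrack(
                    values=rna, bin_size=cmap.bin_size,
                    genome_length=cmap.genome_length, circular=cmap.circular,
                )
                corrs["short_range_vs_rna"] = tk.track_spearman(sr, rna_track)
        report.track_correlations = corrs

    return report


def epod_style_overlap(bundles, annotations) -> dict[str, float]:
    """Venn-style overlap of bundle intervals with an annotation set, in kb.

    Both arguments are bp interval lists; returns per-set and
    intersection coverage plus the fraction of the annotation set covered
    by bundles (the statistic used to ask how much of a silent-region
    annotation, e.g. EPODs, lies inside called bundles).
    """
    a_kb, b_kb, inter_kb = bc.interval_overlap_kb(bundles, annotations)
    return {
        "bundles_kb": a_kb,
        "annotations_kb": b_kb,
        "intersection_kb": inter_kb,
        "annotation_fraction_in_bundles": (inter_kb / b_kb) if b_kb > 0 else 0.0,
    }
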