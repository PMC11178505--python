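"""End-to-end batch runs: synthesize, polarity scoring, paired daughters,
and a self-contained recovery benchmark.

Every run writes CSV tables plus a JSON parameter record holding the
effective parameter set and seed, and reruns with identical
configuration and seed produce byte-identical outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .angles import angular_distance
from .errors import AmbiguousPair, NoCellFound, NotAPair
from .io import (
    parse_channels,
    read_manifest,
    read_stack,
    write_csv,
    write_params_record,
    write_stack,
)
from .params import PolarityParams
from .pairs import score_pair
from .polarity import score_cell
from .stats import summarize_cohort
from .synth import make_cohort, make_pair_cohort

logger = logging.getLogger("polarcell")


def _record(params: PolarityParams, seed: int | None, **extra) -> dict:
    rec = {
        "software": "polarcell",
        "version": __version__,
        "seed": seed,
        "params": params.to_dict(),
    }
    rec.update(extra)
    return rec


# ---------------------------------------------------------------------------
# synthesize


def run_synthesize(
    outdir: Path,
    n_cells: int = 60,
    n_pairs: int = 30,
    seed: int = 0,
    polar_fraction_of_cohort: float = 0.6,
    pair_ratio: float = 2.0,
    noise_model: str = "poisson",
    conditions: tuple[str, ...] = ("CTRL",),
) -> pd.DataFrame:
    """Write a synthetic cohort (cells + doublets) with manifest and truth.

    Each condition gets its own ``n_cells`` single cells and ``n_pairs``
    doublets; seeds are derived per condition so conditions differ.
    """
    outdir = Path(outdir)
    imgdir = outdir / "images"
    imgdir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    truth_frames = []
    for ci, condition in enumerate(conditions):
        cond_seed = seed + 1000 * ci
        if n_cells > 0:
            cells, truth = make_cohort(
                n_cells,
                polar_fraction_of_cohort=polar_fraction_of_cohort,
                seed=cond_seed,
                condition=condition,
                noise_model=noise_model,
            )
            for i, (stack, _) in enumerate(cells):
                cell_id = f"{condition}_cell_{i:04d}"
                fname = f"{cell_id}.tif"
                write_stack(imgdir / fname, stack)
                manifest_rows.append(
                    {
                        "file": f"images/{fname}",
                        "cell_id": cell_id,
                        "condition": condition,
                        "replicate": f"rep{i % 3 + 1}",
                        "role": "single",
                        "channels": ";".join(stack.channel_names),
                    }
                )
            truth = truth.assign(
                cell_id=condition + "_" + truth["cell_id"], role="single"
            )
            truth_frames.append(truth)
        if n_pairs > 0:
            pairs, ptruth = make_pair_cohort(
                n_pairs,
                ratio=pair_ratio,
                seed=cond_seed + 500,
                condition=condition,
                noise_model=noise_model,
            )
            for i, (stack, _) in enumerate(pairs):
                pair_id = f"{condition}_pair_{i:04d}"
                fname = f"{pair_id}.tif"
                write_stack(imgdir / fname, stack)
                manifest_rows.append(
                    {
                        "file": f"images/{fname}",
                        "cell_id": pair_id,
                        "condition": condition,
                        "replicate": f"rep{i % 3 + 1}",
                        "role": "pair",
                        "channels": ";".join(stack.channel_names),
                    }
                )
            ptruth = ptruth.assign(
                pair_id=condition + "_" + ptruth["pair_id"], role="pair"
            )
            truth_frames.append(ptruth)
    manifest = pd.DataFrame(manifest_rows)
    write_csv(outdir / "manifest.csv", manifest)
    write_csv(outdir / "truth.csv", pd.concat(truth_frames, ignore_index=True))
    write_params_record(
        outdir / "params.json",
        _record(
            PolarityParams(),
            seed,
            mode="synthesize",
            n_cells=n_cells,
            n_pairs=n_pairs,
            noise_model=noise_model,
            conditions=list(conditions),
        ),
    )
    return manifest


# ---------------------------------------------------------------------------
# polarity


def _cell_rows(cell_id, condition, replicate, score):
    rows = []
    for name, call in score.calls.items():
        angle = score.angles.get(name)
        rows.append(
            {
                "cell_id": cell_id,
                "condition": condition,
                "replicate": replicate,
                "channel": name,
                "is_polar": call.is_polar,
                "n_clusters": call.n_clusters,
                "direction_deg": call.direction_deg,
                "angle_to_axis_deg": call.angle_to_axis_deg,
                "cluster_sizes": ";".join(
                    str(c.size_px) for c in call.clusters
                ),
                "cluster_mean_intensities": ";".join(
                    f"{c.mean_intensity:.6g}" for c in call.clusters
                ),
                "polarization_angle_deg": (
                    angle.angle_deg if angle is not None else None
                ),
                "copolarized": (
                    angle.copolarized if angle is not None else None
                ),
                "flag": "" if call.clusters else "no_clusters",
            }
        )
    return rows


def run_polarity(
    manifest_path: Path,
    outdir: Path,
    params: PolarityParams | None = None,
    reference_channel: str = "tubulin",
    seed: int | None = None,
) -> pd.DataFrame:
    """Score every single-cell image in a manifest for polarity.

    Writes ``cells.csv`` (one row per cell per channel),
    ``polarity_summary.csv`` / ``polarity_comparisons.csv`` and a
    parameter record. Returns the per-cell table.
    """
    params = params or PolarityParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(Path(manifest_path))
    manifest = manifest[manifest["role"] == "single"]
    if len(manifest) == 0:
        raise ValueError("manifest lists no single-cell images")
    base = Path(manifest_path).parent
    rows = []
    for rec in manifest.itertuples():
        channels = parse_channels(rec.channels)
        if reference_channel not in channels:
            raise ValueError(
                f"{rec.cell_id}: reference channel {reference_channel!r} "
                f"not among {channels}"
            )
        stack = read_stack(base / rec.file, channels)
        try:
            score = score_cell(stack, params, reference_channel)
        except NoCellFound as exc:
            logger.warning("%s: %s", rec.cell_id, exc)
            continue
        logger.info("scored %s", rec.cell_id)
        rows.extend(_cell_rows(rec.cell_id, rec.condition, rec.replicate,
                               score))
    cells = pd.DataFrame(rows)
    write_csv(outdir / "cells.csv", cells)

    cells["polarity_class"] = np.where(cells["is_polar"], "polar", "nonpolar")
    summary = summarize_cohort(
        cells, "polarity_class", include_classes=["polar", "nonpolar"]
    )
    write_csv(outdir / "polarity_summary.csv", summary.per_condition)
    write_csv(
        outdir / "polarity_comparisons.csv",
        pd.DataFrame(summary.comparisons),
    )
    write_params_record(
        outdir / "params.json",
        _record(params, seed, mode="polarity",
                reference_channel=reference_channel,
                n_cells=int(manifest.shape[0])),
    )
    return cells


# ---------------------------------------------------------------------------
# paired daughters


def run_paired_daughter(
    manifest_path: Path,
    outdir: Path,
    params: PolarityParams | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Classify every doublet image in a manifest.

    Writes ``pairs.csv`` plus ACD/SCD summaries under both denominator
    conventions (indeterminate pairs excluded vs. included).
    """
    params = params or PolarityParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(Path(manifest_path))
    manifest = manifest[manifest["role"] == "pair"]
    if len(manifest) == 0:
        raise ValueError("manifest lists no doublet images")
    base = Path(manifest_path).parent
    rows = []
    for rec in manifest.itertuples():
        channels = parse_channels(rec.channels)
        stack = read_stack(base / rec.file, channels)
        try:
            pair, calls, coseg = score_pair(stack, params)
        except (NotAPair, AmbiguousPair, NoCellFound) as exc:
            logger.warning("%s: %s", rec.cell_id, exc)
            continue
        coseg_by_channel: dict[str, str] = {}
        for (n1, n2), cs in coseg.items():
            coseg_by_channel.setdefault(n1, cs.coseg_class)
        for name in channels:
            call = calls.get(name)
            rows.append(
                {
                    "pair_id": rec.cell_id,
                    "condition": rec.condition,
                    "replicate": rec.replicate,
                    "channel": name,
                    "ratio": call.ratio if call else None,
                    "division_class": (
                        call.division_class if call else "undefined"
                    ),
                    "high_daughter": call.high_daughter if call else None,
                    "flag": "" if call else "undefined_ratio",
                }
            )
        for (n1, n2), cs in coseg.items():
            rows.append(
                {
                    "pair_id": rec.cell_id,
                    "condition": rec.condition,
                    "replicate": rec.replicate,
                    "channel": f"{n1}+{n2}",
                    "ratio": None,
                    "division_class": cs.coseg_class,
                    "high_daughter": None,
                    "flag": "cosegregation",
                }
            )
    pairs_df = pd.DataFrame(rows)
    write_csv(outdir / "pairs.csv", pairs_df)

    single = pairs_df[pairs_df["flag"].isin(["", "undefined_ratio"])]
    single = single[single["division_class"] != "undefined"]
    excl = summarize_cohort(
        single, "division_class", include_classes=["asymmetric", "symmetric"]
    )
    incl = summarize_cohort(
        single,
        "division_class",
        include_classes=["asymmetric", "symmetric", "indeterminate"],
    )
    write_csv(outdir / "division_summary_excluding_indeterminate.csv",
              excl.per_condition)
    write_csv(outdir / "division_summary_including_indeterminate.csv",
              incl.per_condition)
    write_csv(outdir / "division_comparisons.csv",
              pd.DataFrame(excl.comparisons))
    write_params_record(
        outdir / "params.json",
        _record(params, seed, mode="paired_daughter",
                n_pairs=int(manifest.shape[0])),
    )
    return pairs_df


# ---------------------------------------------------------------------------
# benchmark


def run_benchmark(
    outdir: Path,
    seed: int = 0,
    n_cells: int = 100,
    n_pairs_per_ratio: int = 50,
    ratios: tuple[float, ...] = (1.0, 1.6, 2.0),
    noise_model: str = "poisson",
    params: PolarityParams | None = None,
) -> dict:
    """Self-contained recovery benchmark against generator ground truth.

    Generates a polarity cohort and doublet cohorts in memory, scores
    them, and reports polar-call accuracy, direction recovery RMSE (over
    cells whose truth and call are both polar) and the division-class
    confusion per programmed ratio. Writes ``benchmark.json``.
    """
    params = params or PolarityParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cells, truth = make_cohort(
        n_cells, seed=seed, noise_model=noise_model
    )
    n_calls = n_correct = 0
    sq_err: list[float] = []
    for i, (stack, gt) in enumerate(cells):
        score = score_cell(stack, params, reference_channel="tubulin")
        for name, call in score.calls.items():
            n_calls += 1
            n_correct += call.is_polar == gt.is_polar[name]
            if (
                call.is_polar
                and gt.is_polar[name]
                and gt.true_direction_deg[name] is not None
            ):
                err = angular_distance(
                    call.direction_deg, gt.true_direction_deg[name]
                )
                sq_err.append(err**2)
    accuracy = n_correct / n_calls
    angle_rmse = float(np.sqrt(np.mean(sq_err))) if sq_err else float("nan")

    confusion: dict[str, dict[str, int]] = {}
    division_accuracy: dict[str, float] = {}
    for ri, ratio in enumerate(ratios):
        pairs, _ = make_pair_cohort(
            n_pairs_per_ratio,
            ratio=ratio,
            seed=seed + 7000 + ri,
            noise_model=noise_model,
        )
        true_class = (
            "asymmetric" if ratio > params.asym_threshold
            else "symmetric" if ratio < params.sym_threshold
            else "indeterminate"
        )
        counts = {"asymmetric": 0, "symmetric": 0, "indeterminate": 0,
                  "undefined": 0}
        for stack, _gt in pairs:
            _, calls, _ = score_pair(stack, params)
            for call in calls.values():
                counts[call.division_class] += 1
        total = sum(counts.values())
        confusion[f"{ratio:g}"] = counts
        division_accuracy[f"{ratio:g}"] = (
            counts[true_class] / total if total else float("nan")
        )

    report = {
        "seed": seed,
        "noise_model": noise_model,
        "params": params.to_dict(),
        "version": __version__,
        "n_cells": n_cells,
        "n_channel_calls": n_calls,
        "polar_call_accuracy": accuracy,
        "direction_rmse_deg": angle_rmse,
        "n_pairs_per_ratio": n_pairs_per_ratio,
        "division_confusion": confusion,
        "division_accuracy": division_accuracy,
    }
    write_params_record(outdir / "benchmark.json", report)
    return report
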