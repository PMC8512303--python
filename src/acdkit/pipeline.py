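"""End-to-end pipeline: synthesis/ingest -> morphometry -> polarity ->
lineage -> coordination, with a provenance-stamped report directory.

Every output file is derived deterministically from the configuration and
its seeds (no timestamps), so two runs with the same config produce
byte-identical reports.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import coordination as coord
from . import lineage as lin
from . import morphometry as morph
from . import polarity as pol
from .io import (PipelineConfig, read_label_image, write_json,
                 write_label_image)
from .synthetic.lineages import LineageSimSpec, generate_lineage
from .synthetic.pairs import PairSimSpec, generate_sister_pairs
from .synthetic.profiles import ProfileSpec, generate_profiles
from .synthetic.tissue import TissueSpec, generate_epidermis


class PipelineStageError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run all stages and write the report bundle under ``out_dir``.

    Returns the machine-readable summary (also written as summary.json).
    Stage failures raise :class:`PipelineStageError`; outputs of earlier
    stages are retained on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {"config_hash": config.config_hash(), "seeds": dict(config.seeds),
               "parameters": config.to_dict(), "stages": {}}

    # --- tissue + morphometry ------------------------------------------
    stage = "morphometry"
    try:
        block = config.tissue or {}
        if "path" in block:
            labels = read_label_image(block["path"])
            truth = None
            types = None
        else:
            spec = TissueSpec(seed=config.seeds.get("tissue", 0),
                              pixel_size_um=config.pixel_size_um, **block)
            labels, truth = generate_epidermis(spec)
            types = dict(zip(truth["cell_id"], truth["type"]))
            write_label_image(out / "labels.tif", labels)
            truth.to_csv(out / "cells_truth.csv", index=False)
        cells = morph.measure_cells(labels, config.pixel_size_um,
                                    config.small_threshold_um2, types=types)
        adjacency = morph.build_adjacency(labels)
        clusters = morph.find_small_cell_clusters(cells, adjacency,
                                                  config.min_cluster_size)
        stomata = morph.count_stomatal_clusters(cells, adjacency)
        cells.to_csv(out / "cells.csv", index=False)
        write_json(out / "morphometry.json", {
            "n_cells": int(len(cells)),
            "n_small": clusters.n_small,
            "n_clusters": len(clusters.clusters),
            "clusters": [sorted(c) for c in clusters.clusters],
            "fraction_small_in_clusters": clusters.fraction_in_clusters,
            "n_stomata": stomata.n_stomata,
            "n_stomata_in_contact": stomata.n_in_contact,
            "percent_stomata_clustered": stomata.percent_clustered,
        })
        summary["stages"][stage] = {
            "n_cells": int(len(cells)),
            "fraction_small_in_clusters": clusters.fraction_in_clusters,
            "n_clusters": len(clusters.clusters),
            "percent_stomata_clustered": stomata.percent_clustered,
        }
    except Exception as e:  # noqa: BLE001 - stage-labelled diagnostics
        raise PipelineStageError(stage, e) from e

    # --- polarity -------------------------------------------------------
    stage = "polarity"
    try:
        block = config.profiles or {}
        if "path" in block:
            prof_df = pd.read_csv(block["path"])
            profiles = []
            for cid, g in prof_df.groupby("cell_id"):
                profiles.append(pol.AngularProfile(
                    theta_deg=g["theta_deg"].to_numpy(),
                    intensity=g["intensity"].to_numpy(), cell_id=cid))
        else:
            n_cells = block.get("n_cells", 20)
            spec = ProfileSpec(seed=config.seeds.get("profiles", 0),
                               **{k: v for k, v in block.items()
                                  if k != "n_cells"})
            profiles, _ = generate_profiles(spec, n_cells=n_cells)
        fits = [pol.fit_crescent(p, cutoff_deg=config.polarity_cutoff_deg)
                for p in profiles]
        fit_df = pd.DataFrame([{
            "cell_id": f.cell_id, "sigma_deg": f.sigma_deg, "mu_deg": f.mu_deg,
            "amplitude": f.amplitude, "baseline": f.baseline, "rss": f.rss,
            "polarized": f.polarized} for f in fits])
        fit_df.to_csv(out / "crescent_fits.csv", index=False)
        summary["stages"][stage] = {
            "n_profiles": len(fits),
            "n_polarized": int(fit_df["polarized"].sum()),
            "median_sigma_deg": float(fit_df["sigma_deg"].median()),
        }
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError(stage, e) from e

    # --- lineage --------------------------------------------------------
    stage = "lineage"
    try:
        block = config.lineage or {}
        if "path" in block:
            p = Path(block["path"])
            if not p.exists():
                raise FileNotFoundError(f"lineage input {p} not found")
            table = lin.LineageTable.from_json(p)
        else:
            spec = LineageSimSpec(seed=config.seeds.get("lineage", 0), **block)
            table, _ = generate_lineage(spec)
        classes = lin.classify_divisions(table)
        cycles, n_censored = lin.cell_cycle_lengths(table, classes)
        pairs, n_excluded = lin.pair_outcomes(table, classes)
        classes.to_csv(out / "division_classes.csv", index=False)
        cycles.to_csv(out / "cell_cycles.csv", index=False)
        pairs.to_csv(out / "sister_pairs.csv", index=False)
        summary["stages"][stage] = {
            "n_divisions": int(len(classes)),
            "class_counts": classes["division_class"].value_counts().to_dict(),
            "n_censored_cells": n_censored,
            "n_pairs": int(len(pairs)),
            "n_pairs_excluded": n_excluded,
        }
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError(stage, e) from e

    # --- coordination ---------------------------------------------------
    stage = "coordination"
    try:
        block = config.pairs or {}
        if "path" in block:
            pair_df = pd.read_csv(block["path"])
        elif block:
            spec = PairSimSpec(seed=config.seeds.get("pairs", 0), **block)
            pair_df = generate_sister_pairs(spec)
        else:
            pair_df = pairs  # pairs traced from the lineage stage
        stats = coord.coordination_stats(pair_df)
        stats.p_perm = coord.coordination_permutation_test(
            pair_df, n_perm=config.n_perm,
            seed=config.seeds.get("permutation", 0))
        write_json(out / "coordination.json", {
            "obs_spa": stats.obs_spa, "obs_amp": stats.obs_amp,
            "obs_both": stats.obs_both, "exp_both": stats.exp_both,
            "deficit": stats.deficit, "n_pairs": stats.n_pairs,
            "p_perm": stats.p_perm,
        })
        summary["stages"][stage] = {
            "obs_both": stats.obs_both, "exp_both": stats.exp_both,
            "deficit": stats.deficit, "p_perm": stats.p_perm,
        }
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError(stage, e) from e

    write_json(out / "summary.json", summary)
    log_lines = [f"config_hash: {summary['config_hash']}"]
    log_lines += [f"seed[{k}]: {v}" for k, v in sorted(config.seeds.items())]
    log_lines += [f"param[{k}]: {v}" for k, v in
                  sorted(config.to_dict().items()) if k != "seeds"]
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return summary
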