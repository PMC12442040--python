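"""End-to-end orchestration: imzML dataset in, annotated KMD maps out.

Stage order follows the workflow this package implements:
(optional) recalibration -> centroiding -> cross-pixel realignment ->
KMD projection and lipid-window filtering -> matrix-cluster flagging ->
horizontal/vertical series grouping -> adduct/isotopologue collapsing ->
exact-mass annotation.  The result object keeps every intermediate so
callers can inspect, image or export any stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import annotate as ann
from . import kmd as kmdmod
from .config import PipelineConfig, config_hash
from .imzml_io import MSIDataset
from .kmd import CloudSelection, SeriesGroup
from .phantom import matrix_ion_set
from .spectral import (
    AlignedPeakMatrix,
    align_centroids,
    pick_dataset,
    recalibrate,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    config: PipelineConfig
    config_hash: str
    matrix: AlignedPeakMatrix
    points: pd.DataFrame  # all consensus bins with km/kmd/flags
    filtered: pd.DataFrame  # lipid-window subset (matrix flags retained)
    ch2_series: List[SeriesGroup]
    ch2_singletons: List[int]
    vertical_series: Dict[str, List[SeriesGroup]]
    collapse: pd.DataFrame
    annotations: pd.DataFrame
    clouds: Dict[str, CloudSelection]
    summary: Dict

    def series_of(self, label: int) -> Optional[int]:
        for i, g in enumerate(self.ch2_series):
            if label in g.members:
                return i
        return None


def run_pipeline(
    dataset: MSIDataset,
    config: Optional[PipelineConfig] = None,
    lipid_table: Optional[List[ann.LipidRecord]] = None,
    matrix_ions: Optional[List[float]] = None,
) -> PipelineResult:
    """Run the full analysis on a dataset and return every stage."""
    config = config or PipelineConfig()
    if matrix_ions is None:
        matrix_ions = matrix_ion_set()
    if lipid_table is None:
        lipid_table = ann.load_lipid_table(config.lipid_table_path)

    peak_lists = pick_dataset(dataset, config.picking)
    n_peaks = sum(len(p) for p in peak_lists)
    if config.recalibrate:
        recal = [
            recalibrate(pl, matrix_ions, config.recalibration_tolerance_ppm)[0]
            for pl in peak_lists
        ]
        peak_lists = recal

    matrix = align_centroids(
        peak_lists, config.alignment_tolerance_ppm, shape=dataset.shape
    )
    if matrix.n_bins == 0:
        empty = pd.DataFrame(columns=["bin", "mz", "km", "kmd", "intensity", "matrix_flag"])
        return PipelineResult(
            config=config, config_hash=config_hash(config), matrix=matrix,
            points=empty, filtered=empty, ch2_series=[], ch2_singletons=[],
            vertical_series={}, collapse=pd.DataFrame(), annotations=pd.DataFrame(),
            clouds={}, summary={"n_peaks": n_peaks, "n_bins": 0, "n_filtered": 0,
                                "n_ch2_series": 0, "n_annotated": 0},
        )

    points = kmdmod.compute_kmd_points(matrix, config.kendrick)
    points["matrix_flag"] = kmdmod.flag_matrix_points(
        points, matrix_ions, config.matrix_flag_ppm
    )
    filtered = kmdmod.filter_window(points, config.window)

    exclude = filtered["matrix_flag"]
    ch2_series, ch2_singles = kmdmod.chain_ch2_series(
        filtered, config.ch2_ppm, config.ch2_k_max, exclude=exclude
    )
    vertical = {
        step: kmdmod.chain_vertical(
            filtered, step, config.vertical_ppm, config.vertical_span_steps,
            exclude=exclude,
        )[0]
        for step in ("H2", "O")
    }
    nonmatrix = filtered.loc[~filtered["matrix_flag"]]
    collapse = kmdmod.collapse_adducts_isotopes(nonmatrix, ppm_tolerance=config.collapse_ppm)

    rows = []
    for lab, row in nonmatrix.iterrows():
        res = ann.annotate_mz(float(row["mz"]), lipid_table, policy=config.policy)
        rec = res.to_row()
        rec["point"] = lab
        rec["kmd"] = row["kmd"]
        rec["intensity"] = row["intensity"]
        rec["canonical"] = collapse.at[lab, "canonical"]
        rows.append(rec)
    annotations = pd.DataFrame(rows).set_index("point") if rows else pd.DataFrame()

    clouds = {
        name: kmdmod.select_cloud(filtered, geom, name=name)
        for name, geom in config.clouds.items()
    }

    summary = {
        "n_peaks": int(n_peaks),
        "n_bins": int(matrix.n_bins),
        "n_matrix_flagged": int(points["matrix_flag"].sum()),
        "n_filtered": int(len(filtered)),
        "n_ch2_series": len(ch2_series),
        "n_vertical_H2": len(vertical["H2"]),
        "n_vertical_O": len(vertical["O"]),
        "n_collapsed_groups": int(collapse["canonical"].nunique()) if len(collapse) else 0,
        "n_annotated": int((annotations["best_match"] != "").sum()) if len(annotations) else 0,
        "clouds": {k: len(v.members) for k, v in clouds.items()},
    }
    logger.info("pipeline summary: %s", summary)
    return PipelineResult(
        config=config,
        config_hash=config_hash(config),
        matrix=matrix,
        points=points,
        filtered=filtered,
        ch2_series=ch2_series,
        ch2_singletons=ch2_singles,
        vertical_series=vertical,
        collapse=collapse,
        annotations=annotations,
        clouds=clouds,
        summary=summary,
    )
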