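"""Bundled datasets: printed skull-measurement tables, calibration tables,
the four-area biogeographic coding, and a synthetic stand-in working tree.

The measurement, calibration and area tables transcribe printed tables from
the beaked-whale systematics literature (values in mm and Ma).  The working
tree in ``study_tree_synthetic.nwk`` is *synthetic*: a stand-in topology
assembled from relationships described in prose, shipped so the calibration
and trait-mapping layers are exercisable end-to-end; it is not a published
machine-readable tree.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path

from ..chronostrat import CalibrationSet
from ..traits import MeasurementTable, TraitTable
from ..trees import Tree


def data_path(name: str) -> Path:
    return Path(str(resources.files("cladistron.data") / name))


def measurement_table(name: str) -> MeasurementTable:
    """One of: table1_musm2538, table2_musm2548, table3_comparison."""
    return MeasurementTable.from_csv(data_path(f"{name}.csv"))


def ratio_claims() -> list[tuple[str, float, float, float]]:
    """(name, numerator, denominator, printed) rows transcribed from the
    source tables, for the verify-ratios report."""
    with open(data_path("ratio_claims.csv"), newline="") as fh:
        return [
            (r["name"], float(r["numerator"]), float(r["denominator"]), float(r["printed"]))
            for r in csv.DictReader(fh)
        ]


def synthetic_study_tree() -> Tree:
    """Synthetic stand-in for the study's working tree (see module docstring)."""
    return Tree.from_newick(data_path("study_tree_synthetic.nwk").read_text())


def study_calibrations() -> CalibrationSet:
    return CalibrationSet.from_tsv(
        data_path("node_calibrations.tsv"), data_path("tip_ranges.tsv")
    )


def study_areas() -> TraitTable:
    return TraitTable.from_csv(data_path("areas.csv"))
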