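"""Lineage forests: division classification, cycles, origins, pair outcomes."""

import numpy as np
import pandas as pd
import pytest

from acdkit.lineage import (LineageError, LineageTable, cell_cycle_lengths,
                            classify_cluster_origin, classify_divisions,
                            pair_outcomes)
from acdkit.synthetic import LineageSimSpec, generate_lineage


def build_table(cells, divisions):
    cdf = pd.DataFrame(cells, columns=["cell_id", "parent_division_id",
                                       "birth_time_min", "end_time_min",
                                       "fate", "birth_area_um2"])
    ddf = pd.DataFrame(divisions, columns=["division_id", "mother_id",
                                           "daughter1_id", "daughter2_id",
                                           "time_min", "plane_axis_deg",
                                           "crescent_daughter_id"])
    return LineageTable(cells=cdf, divisions=ddf)


@pytest.fixture
def manual_lineage():
    """Founder F entry-divides into meristemoid M (small) and SLGC S; M
    amplifies, S performs a spacing division."""
    cells = [
        ("F", np.nan, 0.0, 2880.0, "protodermal", 300.0),
        ("M", "d1", 600.0, 2880.0, "meristemoid", 100.0),
        ("S", "d1", 600.0, 2880.0, "SLGC", 200.0),
        ("M1", "d2", 1200.0, 2880.0, "meristemoid", 50.0),
        ("M2", "d2", 1200.0, 2880.0, "SLGC", 90.0),
        ("S1", "d3", 1500.0, 2880.0, "meristemoid", 90.0),
        ("S2", "d3", 1500.0, 2880.0, "SLGC", 180.0),
    ]
    divisions = [
        ("d1", "F", "M", "S", 600.0, 10.0, "S"),
        ("d2", "M", "M1", "M2", 1200.0, 40.0, "M2"),
        ("d3", "S", "S1", "S2", 1500.0, 80.0, "S2"),
    ]
    return build_table(cells, divisions)


class TestClassify:
    def test_entry_amplifying_spacing(self, manual_lineage):
        classes = classify_divisions(manual_lineage).set_index("division_id")
        assert classes.loc["d1", "division_class"] == "entry"
        assert classes.loc["d2", "division_class"] == "amplifying"
        assert classes.loc["d3", "division_class"] == "spacing"

    def test_gmc_mother_gives_symmetric_class(self):
        cells = [("F", np.nan, 0.0, 100.0, "GMC", 80.0),
                 ("G1", "d1", 50.0, 100.0, "guard", 40.0),
                 ("G2", "d1", 50.0, 100.0, "guard", 40.0)]
        divisions = [("d1", "F", "G1", "G2", 50.0, 0.0, np.nan)]
        classes = classify_divisions(build_table(cells, divisions))
        assert classes.division_class.tolist() == ["gmc_symmetric"]

    def test_tie_resolved_by_crescent_annotation(self):
        # sisters born equal: the crescent marks the SLGC, so the crescent
        # bearer's division is spacing, the sister's amplifying
        cells = [("F", np.nan, 0.0, 900.0, "protodermal", 300.0),
                 ("A", "d1", 100.0, 900.0, "SLGC", 150.0),
                 ("B", "d1", 100.0, 900.0, "meristemoid", 150.0),
                 ("A1", "d2", 500.0, 900.0, "meristemoid", 60.0),
                 ("A2", "d2", 500.0, 900.0, "SLGC", 120.0)]
        divisions = [("d1", "F", "A", "B", 100.0, 0.0, "A"),
                     ("d2", "A", "A1", "A2", 500.0, 0.0, "A2")]
        classes = classify_divisions(build_table(cells, divisions))
        assert classes.set_index("division_id").loc["d2",
                                                    "division_class"] == "spacing"

    def test_tie_without_crescent_is_ambiguous(self):
        cells = [("F", np.nan, 0.0, 900.0, "protodermal", 300.0),
                 ("A", "d1", 100.0, 900.0, "SLGC", 150.0),
                 ("B", "d1", 100.0, 900.0, "meristemoid", 150.0),
                 ("A1", "d2", 500.0, 900.0, "meristemoid", 60.0),
                 ("A2", "d2", 500.0, 900.0, "SLGC", 120.0)]
        divisions = [("d1", "F", "A", "B", 100.0, 0.0, np.nan),
                     ("d2", "A", "A1", "A2", 500.0, 0.0, np.nan)]
        classes = classify_divisions(build_table(cells, divisions))
        assert classes.set_index("division_id").loc["d2",
                                                    "division_class"] == "ambiguous"

    def test_missing_birth_area_warns_and_is_ambiguous(self):
        cells = [("F", np.nan, 0.0, 900.0, "protodermal", 300.0),
                 ("A", "d1", 100.0, 900.0, "SLGC", np.nan),
                 ("B", "d1", 100.0, 900.0, "meristemoid", 150.0),
                 ("A1", "d2", 500.0, 900.0, "meristemoid", 60.0),
                 ("A2", "d2", 500.0, 900.0, "SLGC", 120.0)]
        divisions = [("d1", "F", "A", "B", 100.0, 0.0, np.nan),
                     ("d2", "A", "A1", "A2", 500.0, 0.0, np.nan)]
        with pytest.warns(UserWarning):
            classes = classify_divisions(build_table(cells, divisions))
        assert classes.set_index("division_id").loc["d2",
                                                    "division_class"] == "ambiguous"

    def test_relabeling_invariance(self, manual_lineage):
        mapping = {"F": "x9", "M": "x2", "S": "x7", "M1": "x1", "M2": "x4",
                   "S1": "x5", "S2": "x6"}
        cells = manual_lineage.cells.copy()
        divs = manual_lineage.divisions.copy()
        cells["cell_id"] = cells["cell_id"].map(mapping)
        for col in ("mother_id", "daughter1_id", "daughter2_id",
                    "crescent_daughter_id"):
            divs[col] = divs[col].map(mapping)
        relabelled = LineageTable(cells=cells, divisions=divs)
        a = classify_divisions(manual_lineage).sort_values("division_id")
        b = classify_divisions(relabelled).sort_values("division_id")
        assert a.division_class.tolist() == b.division_class.tolist()


class TestCycles:
    def test_lengths_and_censoring(self, manual_lineage):
        lengths, n_censored = cell_cycle_lengths(manual_lineage)
        by_cell = lengths.set_index("cell_id")
        assert by_cell.loc["M", "cycle_min"] == 600.0   # born 600, divides 1200
        assert by_cell.loc["S", "cycle_min"] == 900.0
        assert n_censored == 4  # M1, M2, S1, S2 never divide

    def test_negative_duration_rejected(self):
        cells = [("F", np.nan, 500.0, 900.0, "protodermal", 300.0),
                 ("A", "d1", 100.0, 900.0, "SLGC", 150.0),
                 ("B", "d1", 100.0, 900.0, "meristemoid", 150.0)]
        divisions = [("d1", "F", "A", "B", 100.0, 0.0, np.nan)]
        with pytest.raises(LineageError):
            build_table(cells, divisions)

    def test_generator_recovers_cycle_ratio(self):
        """Smaller daughters cycle at ~0.7x the larger daughters' time."""
        table, _ = generate_lineage(LineageSimSpec(n_founders=200, seed=5))
        lengths, _ = cell_cycle_lengths(table)
        med = lengths.groupby("division_class")["cycle_min"].median()
        ratio = med["amplifying"] / med["spacing"]
        assert ratio == pytest.approx(0.7, rel=0.05)


class TestClusterOrigin:
    def fate_error_table(self):
        """Both daughters of one division become GMCs -> adjacent stomata."""
        cells = [("F", np.nan, 0.0, 900.0, "protodermal", 300.0),
                 ("A", "d1", 100.0, 900.0, "GMC", 140.0),
                 ("B", "d1", 100.0, 900.0, "GMC", 160.0),
                 ("A1", "d2", 400.0, 900.0, "stoma", 70.0),
                 ("A2", "d2", 400.0, 900.0, "stoma", 70.0),
                 ("B1", "d3", 450.0, 900.0, "stoma", 80.0),
                 ("B2", "d3", 450.0, 900.0, "stoma", 80.0)]
        divisions = [("d1", "F", "A", "B", 100.0, 0.0, np.nan),
                     ("d2", "A", "A1", "A2", 400.0, 0.0, np.nan),
                     ("d3", "B", "B1", "B2", 450.0, 0.0, np.nan)]
        return build_table(cells, divisions)

    def test_sister_pair_origin_is_fate_error(self):
        origin = classify_cluster_origin(["A1", "B1"], self.fate_error_table())
        assert origin.origin == "fate_error"
        assert origin.evidence == "d1"

    def test_misplaced_spacing_division_origin(self):
        # existing stoma X; SLGC S spacing-divides placing precursor P beside X
        cells = [("F", np.nan, 0.0, 2000.0, "protodermal", 300.0),
                 ("M", "d1", 100.0, 2000.0, "GMC", 100.0),
                 ("S", "d1", 100.0, 2000.0, "SLGC", 200.0),
                 ("X1", "d2", 500.0, 2000.0, "stoma", 50.0),
                 ("X2", "d2", 500.0, 2000.0, "stoma", 50.0),
                 ("P", "d3", 900.0, 2000.0, "stoma", 90.0),
                 ("Q", "d3", 900.0, 2000.0, "SLGC", 180.0)]
        divisions = [("d1", "F", "M", "S", 100.0, 0.0, "S"),
                     ("d2", "M", "X1", "X2", 500.0, 0.0, np.nan),
                     ("d3", "S", "P", "Q", 900.0, 0.0, "Q")]
        table = build_table(cells, divisions)
        origin = classify_cluster_origin(["X1", "P"], table)
        assert origin.origin == "spacing_error"
        assert origin.evidence == "d3"

    def test_untraceable_stoma_unresolvable(self):
        origin = classify_cluster_origin(["A1", "ZZZ"], self.fate_error_table())
        assert origin.origin == "unresolvable"


class TestPairOutcomes:
    def test_manual_outcomes(self, manual_lineage):
        pairs, n_excluded = pair_outcomes(manual_lineage,
                                          division_classes=("entry",))
        assert n_excluded == 0
        rec = pairs.set_index("pair_id").loc["d1"]
        assert rec.amp and rec.spa

    def test_gmc_transition_counts_as_no_amplifying_division(self):
        cells = [("F", np.nan, 0.0, 2000.0, "protodermal", 300.0),
                 ("M", "d1", 100.0, 2000.0, "GMC", 100.0),
                 ("S", "d1", 100.0, 2000.0, "SLGC", 200.0),
                 ("G1", "d2", 700.0, 2000.0, "guard", 50.0),
                 ("G2", "d2", 700.0, 2000.0, "guard", 50.0),
                 ("P", "d3", 900.0, 2000.0, "meristemoid", 90.0),
                 ("Q", "d3", 900.0, 2000.0, "SLGC", 180.0)]
        divisions = [("d1", "F", "M", "S", 100.0, 0.0, "S"),
                     ("d2", "M", "G1", "G2", 700.0, 0.0, np.nan),
                     ("d3", "S", "P", "Q", 900.0, 0.0, "Q")]
        pairs, _ = pair_outcomes(build_table(cells, divisions),
                                 division_classes=("entry",))
        rec = pairs.set_index("pair_id").loc["d1"]
        assert not rec.amp    # GMC division is not an amplifying division
        assert rec.spa

    def test_lost_daughters_excluded_and_counted(self):
        cells = [("F", np.nan, 0.0, 900.0, "protodermal", 300.0),
                 ("A", "d1", 100.0, 200.0, "lost", 150.0),
                 ("B", "d1", 100.0, 900.0, "SLGC", 200.0)]
        divisions = [("d1", "F", "A", "B", 100.0, 0.0, "B")]
        pairs, n_excluded = pair_outcomes(build_table(cells, divisions))
        assert len(pairs) == 0 and n_excluded == 1

    def test_generator_round_trip_recovers_planted_outcomes(self):
        table, truth = generate_lineage(LineageSimSpec(n_founders=150, seed=3))
        classes = classify_divisions(table)
        pairs, _ = pair_outcomes(table, classes, division_classes=("entry",))
        merged = pairs.merge(truth.pairs.rename(columns={"division_id":
                                                         "pair_id"}),
                             on="pair_id", suffixes=("", "_t"))
        assert len(merged) == 150
        assert (merged.amp == merged.amp_t).all()
        assert (merged.spa == merged.spa_t).all()


class TestTableValidation:
    def test_duplicate_daughter_rejected(self):
        cells = [("F", np.nan, 0.0, 900.0, "protodermal", 300.0),
                 ("G", np.nan, 0.0, 900.0, "protodermal", 300.0),
                 ("A", "d1", 100.0, 900.0, "SLGC", 150.0),
                 ("B", "d1", 100.0, 900.0, "meristemoid", 150.0)]
        divisions = [("d1", "F", "A", "B", 100.0, 0.0, np.nan),
                     ("d2", "G", "A", "B", 100.0, 0.0, np.nan)]
        with pytest.raises(LineageError):
            build_table(cells, divisions)

    def test_daughter_birth_time_must_match_division(self):
        cells = [("F", np.nan, 0.0, 900.0, "protodermal", 300.0),
                 ("A", "d1", 150.0, 900.0, "SLGC", 150.0),
                 ("B", "d1", 100.0, 900.0, "meristemoid", 150.0)]
        divisions = [("d1", "F", "A", "B", 100.0, 0.0, np.nan)]
        with pytest.raises(LineageError):
            build_table(cells, divisions)

    def test_generator_classification_round_trip(self):
        table, truth = generate_lineage(LineageSimSpec(n_founders=100, seed=8))
        classes = classify_divisions(table)
        merged = classes.merge(truth.divisions, on="division_id")
        assert (merged.division_class == merged.class_truth).all()

    def test_csv_and_json_round_trip(self, manual_lineage, tmp_path):
        manual_lineage.to_csv(tmp_path / "cells.csv", tmp_path / "divisions.csv")
        again = LineageTable.from_csv(tmp_path / "cells.csv",
                                      tmp_path / "divisions.csv")
        assert len(again.cells) == len(manual_lineage.cells)
        manual_lineage.to_json(tmp_path / "lineage.json")
        again2 = LineageTable.from_json(tmp_path / "lineage.json")
        assert set(again2.divisions.division_id) == {"d1", "d2", "d3"}
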