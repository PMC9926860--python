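"""Readers/writers, probe collapse and config loading."""

import numpy as np
import pandas as pd
import pytest
import yaml

from glycotraits.omics_io import (
    GenePanel,
    collapse_probes,
    read_expression_matrix,
    read_fab_labels,
    read_gene_panels,
    read_glycomics_table,
    read_trait_rules,
    read_trait_table,
    write_expression_matrix,
    write_glycomics_table,
    write_trait_matrix,
)
from glycotraits.trait_engine import compute_trait_matrix, default_rules


def write_small_glycomics(path):
    pd.DataFrame(
        {
            "glycan_id": ["g1", "g2", "g3"],
            "structure": [
                "Neu5Ac(a2-3)Gal(b1-3)GalNAc",
                "Gal(b1-3)GalNAc",
                "GalNAc",
            ],
            "glytoucan_id": ["G00001", "", ""],
            "A": [20.0, 30.0, 50.0],
            "B": [10.0, 40.0, 50.0],
        }
    ).to_csv(path, sep="\t", index=False)


def test_read_glycomics_small_fixture(tmp_path):
    path = tmp_path / "o.tsv"
    write_small_glycomics(path)
    panel = read_glycomics_table(path, "O")
    assert panel.samples == ["A", "B"]
    assert panel.abundances.sum(axis=0).tolist() == pytest.approx([100.0, 100.0])
    assert panel.record("g1").glytoucan_id == "G00001"


def test_negative_abundance_names_the_cell(tmp_path):
    path = tmp_path / "o.tsv"
    df = pd.DataFrame(
        {"glycan_id": ["g1", "g2"], "structure": ["GalNAc", "GalNAc"], "A": [101.0, -1.0]}
    )
    df.to_csv(path, sep="\t", index=False)
    with pytest.raises(ValueError, match="negative abundance.*'g2'.*'A'"):
        read_glycomics_table(path, "O")


def test_duplicate_glycan_id_rejected(tmp_path):
    path = tmp_path / "o.tsv"
    pd.DataFrame(
        {"glycan_id": ["g1", "g1"], "structure": ["GalNAc", "GalNAc"], "A": [50.0, 50.0]}
    ).to_csv(path, sep="\t", index=False)
    with pytest.raises(ValueError, match="duplicate glycan_id"):
        read_glycomics_table(path, "O")


def test_glycomics_write_read_round_trip(tmp_path, cohort):
    panel = cohort.panels["GSL"]
    path = tmp_path / "gsl.tsv"
    write_glycomics_table(panel, path)
    again = read_glycomics_table(path, "GSL")
    pd.testing.assert_frame_equal(
        again.abundances, panel.abundances, check_exact=False, atol=1e-9,
        check_names=False,
    )
    assert [g.glycan_id for g in again.glycans] == [g.glycan_id for g in panel.glycans]
    # trait values identical after the round trip
    rules = default_rules()
    pd.testing.assert_frame_equal(
        compute_trait_matrix(again, rules).values,
        compute_trait_matrix(panel, rules).values,
        atol=1e-9,
    )


# ---------------------------------------------------------------------------
# expression + probes
# ---------------------------------------------------------------------------


def test_read_expression_and_panel_tags(tmp_path):
    path = tmp_path / "e.tsv"
    pd.DataFrame(
        {"gene": ["FUT7", "SPI1", "ACTB"], "S1": [1.0, 2.0, 3.0], "S2": [2.0, 1.0, 3.0]}
    ).to_csv(path, sep="\t", index=False)
    expr = read_expression_matrix(
        path, panels=[GenePanel("GST", ["FUT7"]), GenePanel("TF", ["SPI1"])]
    )
    assert expr.panel_tags["FUT7"] == "GST"
    assert expr.panel_tags["SPI1"] == "TF"
    assert expr.panel_tags["ACTB"] == "other"


def test_non_numeric_cell_reports_coordinates(tmp_path):
    path = tmp_path / "e.csv"
    path.write_text("gene,S1,S2\nFUT7,1.0,oops\n")
    with pytest.raises(ValueError, match="'FUT7'.*'S2'"):
        read_expression_matrix(path)


def test_expression_round_trip(tmp_path, cohort):
    path = tmp_path / "e.tsv"
    write_expression_matrix(cohort.expression, path)
    again = read_expression_matrix(path)
    pd.testing.assert_frame_equal(
        again.values, cohort.expression.values, atol=1e-9, check_names=False
    )


def test_collapse_probes_max_mean_rule():
    probes = pd.DataFrame(
        {"S1": [5.0, 7.0, 1.0], "S2": [5.0, 7.0, 1.0]},
        index=["p_a", "p_b", "p_c"],
    )
    expr = collapse_probes(probes, {"p_a": "FUT7", "p_b": "FUT7", "p_c": "SPI1"})
    assert expr.values.loc["FUT7"].tolist() == [7.0, 7.0]  # mean-7 probe retained
    assert list(expr.values.index) == ["FUT7", "SPI1"]


def test_collapse_probes_tie_breaks_lexicographically():
    probes = pd.DataFrame({"S1": [3.0, 3.0]}, index=["p_z", "p_a"])
    expr = collapse_probes(probes, {"p_z": "G", "p_a": "G"})
    # equal means -> lexicographically smaller probe id retained
    assert expr.values.loc["G", "S1"] == 3.0
    assert expr.values.shape == (1, 1)


def test_collapse_probes_matches_groupby_max_oracle():
    rng = np.random.default_rng(11)
    probes = [f"p{i:03d}" for i in range(50)]
    genes = {p: f"G{rng.integers(0, 12)}" for p in probes}
    mat = pd.DataFrame(
        rng.normal(size=(50, 6)), index=probes, columns=[f"S{j}" for j in range(6)]
    )
    expr = collapse_probes(mat, genes)
    # oracle: pandas group-by on mean, taking idxmax over sorted probe ids
    means = mat.mean(axis=1)
    expected_rows = {}
    for gene in sorted(set(genes.values())):
        members = sorted([p for p in probes if genes[p] == gene])
        best = max(members, key=lambda p: (means[p], ))
        # ties toward smaller id: max on (mean,) keeps last max, so rescan
        best = sorted([p for p in members if means[p] == means[best]])[0]
        expected_rows[gene] = mat.loc[best]
    expected = pd.DataFrame(expected_rows).T
    pd.testing.assert_frame_equal(expr.values, expected, check_names=False)
    assert expr.values.shape[0] == len(set(genes.values()))


def test_unmapped_probes_dropped_with_warning(caplog):
    import logging

    probes = pd.DataFrame({"S1": [1.0, 2.0]}, index=["p1", "p2"])
    with caplog.at_level(logging.WARNING, logger="glycotraits.omics_io"):
        expr = collapse_probes(probes, {"p1": "G1"})
    assert expr.values.shape[0] == 1
    assert any("unmapped" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------


def test_gene_panels_yaml(tmp_path):
    path = tmp_path / "panels.yaml"
    path.write_text(yaml.safe_dump({"GST": ["FUT7", "ST3GAL4"], "TF": ["SPI1"]}))
    panels = {p.name: p for p in read_gene_panels(path)}
    assert panels["GST"].genes == ["FUT7", "ST3GAL4"]


def test_trait_rules_yaml_builtin_and_custom(tmp_path):
    path = tmp_path / "rules.yaml"
    path.write_text(
        yaml.safe_dump(
            [
                "H antigen",
                {
                    "name": "my-sLex",
                    "classes": ["N", "O"],
                    "motifs": [
                        {
                            "pattern": "Neu5Ac(a2-3)Gal(b1-4)[Fuc(a1-3)]GlcNAc",
                        }
                    ],
                },
            ]
        )
    )
    rules = read_trait_rules(path)
    assert [r.trait_name for r in rules] == ["H antigen", "my-sLex"]
    assert rules[1].applicable_classes == {"N", "O"}


def test_trait_table_and_fab_labels_round_trip(tmp_path, cohort):
    from glycotraits.trait_engine import integrate_traits

    rules = default_rules()
    tm = compute_trait_matrix(cohort.panels["O"], rules)
    path = tmp_path / "traits.csv"
    write_trait_matrix(tm, path)
    again = read_trait_table(path, "O")
    pd.testing.assert_frame_equal(again.values, tm.values, atol=1e-9, check_names=False)

    fab_path = tmp_path / "fab.tsv"
    cohort.fab_labels.rename_axis("sample_id").to_frame().to_csv(fab_path, sep="\t")
    fab = read_fab_labels(fab_path)
    assert (fab == cohort.fab_labels).all()
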