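import json

import numpy as np
import pandas as pd
import pytest

import gpcrmi as g
from gpcrmi.hotspots import ScanEntry, ScanResult
from gpcrmi.mi import MIResult
from gpcrmi.significance import SignificanceResult


def small_scan(seed=0, planted=(), n_receptors=40, ligands=(4, 8)):
    cfg = g.SimulationConfig(
        n_receptors=n_receptors, n_positions=12, n_descriptors=8,
        ligands_per_receptor=ligands, planted=planted, seed=seed,
    )
    sim = g.simulate_dataset(cfg)
    sub = g.build_subset(sim.dataset, "agonist")
    scan = g.scan_subset(
        sub, sim.position_table, sim.descriptor_matrix, g.ScanConfig(), seed=seed
    )
    return sim, scan


def test_conserved_position_yields_zero_mi():
    """A single-residue column carries no information about any descriptor."""
    sim, scan = small_scan(seed=2)
    aln = {rid: "A" + seq[1:] for rid, seq in sim.alignment.items()}  # force column 0
    table = g.label_positions(aln, sim.position_map)
    sub = g.build_subset(sim.dataset, "agonist")
    scan = g.scan_subset(sub, table, sim.descriptor_matrix, g.ScanConfig(), seed=2)
    label = sim.position_map.entries[0]
    entries = [e for e in scan.entries if e.position == label]
    assert entries and all(e.mi.i_raw == 0.0 for e in entries)
    assert all(e.sig is None for e in entries)  # degenerate ensembles: S undefined


def test_constant_descriptor_yields_zero_mi_everywhere():
    sim, _ = small_scan(seed=3)
    sim.descriptor_matrix.values["n_rings"] = 1
    sub = g.build_subset(sim.dataset, "agonist")
    scan = g.scan_subset(
        sub, sim.position_table, sim.descriptor_matrix, g.ScanConfig(), seed=3
    )
    entries = [e for e in scan.entries if e.descriptor == "n_rings"]
    assert entries and all(e.mi.i_raw == 0.0 for e in entries)


def test_strongly_planted_association_ranks_first():
    # planting couples residue class to descriptors at the receptor level,
    # so detectability scales with the receptor count, not the pair count
    planted = (g.PlantedAssociation(5, 2, "all", 0.95),)
    sim, scan = small_scan(seed=4, planted=planted, n_receptors=80, ligands=(6, 10))
    (pos, desc, _, _), = sim.ground_truth.planted
    assert (scan.entries[0].position, scan.entries[0].descriptor) == (pos, desc)
    assert scan.entries[0].sig.reject_null


def _fake_entry(pos, desc, mi_val, s_val):
    mi = MIResult(1, 1, 1, mi_val, 0.0, mi_val, 100, 2, 2, 4)
    sig = SignificanceResult(
        s=s_val, threshold=2.6264, reject_null=s_val > 2.6264, alpha=0.005,
        surrogate_mean=0.0, surrogate_sd=1.0,
    )
    return ScanEntry(pos, desc, mi, sig)


def fake_scan(entries):
    entries = sorted(
        entries, key=lambda e: (-e.mi.i_corrected, -e.sig.s, e.position, e.descriptor)
    )
    return ScanResult("agonist", entries, [], 2.6264, 500)


def test_top_fraction_count_is_ceiling():
    entries = [_fake_entry(f"1.{i:02d}", "d", 1.0 / (i + 1), 5.0) for i in range(1000)]
    scan = fake_scan(entries)
    top, hot = g.select_top_fraction(scan, 0.005)
    assert len(top) == 5
    top_all, _ = g.select_top_fraction(scan, 1.0)
    assert len(top_all) == 1000
    with pytest.raises(ValueError):
        g.select_top_fraction(scan, 0.0)


def test_significance_filter_applies_after_top_fraction():
    entries = [_fake_entry(f"2.{i:02d}", "d", 1.0 - 0.01 * i, 5.0) for i in range(9)]
    entries.append(_fake_entry("7.39", "d", 2.0, 1.0))  # highest MI, not significant
    top, hot = g.select_top_fraction(fake_scan(entries), 0.5)
    assert len(top) == 5
    assert "7.39" in {e.position for e in top}
    assert "7.39" not in {e.position for e in hot}


def test_tie_break_is_deterministic():
    a = _fake_entry("3.36", "n_rings", 0.5, 4.0)
    b = _fake_entry("3.36", "n_carbon", 0.5, 3.0)  # same MI, lower S
    c = _fake_entry("1.31", "n_rings", 0.9, 5.0)
    for order in ([a, b, c], [b, c, a], [c, a, b]):
        top, _ = g.select_top_fraction(fake_scan(order), 2 / 3)
        assert [(e.position, e.descriptor) for e in top] == [
            ("1.31", "n_rings"), ("3.36", "n_rings"),
        ]


def test_classify_position_effects():
    ago = [_fake_entry("3.33", d, 0.5, 5.0) for d in ("a", "b", "c")]
    ant = [_fake_entry("5.36", "a", 0.5, 5.0), _fake_entry("6.58", "a", 0.4, 5.0)]
    both = [_fake_entry("7.39", "a", 0.5, 5.0)]
    df = g.classify_position_effects(ago + both, ant + both)
    rec = df.set_index("position")
    assert rec.loc["3.33", "effect_class"] == "agonist_selective"
    assert rec.loc["3.33", "n_agonist"] == 3
    assert rec.loc["5.36", "effect_class"] == "antagonist_selective"
    assert rec.loc["7.39", "effect_class"] == "both"
    assert "1.50" not in rec.index  # untouched positions omitted


def test_classify_gprotein_selectivity():
    gi = [_fake_entry("3.36", f"d{i}", 0.5, 5.0) for i in range(21)]
    gq = [_fake_entry("3.36", f"d{i}", 0.5, 5.0) for i in range(8)]
    gs = [_fake_entry("3.36", f"d{i}", 0.5, 5.0) for i in range(3)]
    gs += [_fake_entry("8.53", "d0", 0.5, 5.0)]
    gi += [_fake_entry("2.64", "d0", 0.5, 5.0)]
    gq += [_fake_entry("2.64", "d1", 0.5, 5.0)]
    df = g.classify_gprotein_selectivity(gi, gq, gs).set_index("position")
    assert df.loc["3.36", "g_class"] == "triple"
    assert (df.loc["3.36", ["n_Gi", "n_Gq", "n_Gs"]] == [21, 8, 3]).all()
    assert df.loc["8.53", "g_class"] == "Gs"
    assert df.loc["2.64", "g_class"] == "Gi/Gq"


def test_descriptor_frequency_counts_and_flags():
    ago = [_fake_entry(f"1.{i:02d}", "n_rings", 0.5, 5.0) for i in range(4)]
    shared = [_fake_entry("2.60", "n_carbon", 0.5, 5.0)]
    ant = [_fake_entry("5.40", "n_carbon", 0.5, 5.0)]
    df = g.descriptor_frequency({"agonist": ago + shared, "antagonist": ant})
    rec = df.set_index("descriptor")
    assert rec.loc["n_rings", "n_agonist"] == 4
    assert rec.loc["n_rings", "n_antagonist"] == 0
    assert rec.loc["n_rings", "occurrence"] == "agonist_only"
    assert rec.loc["n_carbon", "occurrence"] == "shared"
    assert list(df["descriptor"]) == ["n_rings", "n_carbon"]  # sorted by total


def test_write_reports_files_and_headers(tmp_path):
    cfg = g.SimulationConfig(
        n_receptors=30, n_positions=8, n_descriptors=6,
        ligands_per_receptor=(3, 6), seed=5,
    )
    sim = g.simulate_dataset(cfg)
    report = g.run_pipeline(
        sim.dataset, sim.position_table, sim.descriptor_matrix,
        g.ScanConfig(master_seed=5),
    )
    written = g.write_reports(report, tmp_path, attribute_file=True)
    names = {p.name for p in written}
    assert {"scan.csv", "hotspots.csv", "position_classes.csv",
            "descriptor_frequencies.csv", "run_summary.json"} <= names
    summary = json.loads((tmp_path / "run_summary.json").read_text())
    assert set(summary["subsets"]) == {"agonist", "antagonist", "Gi", "Gs", "Gq"}
    scan_df = pd.read_csv(tmp_path / "scan.csv")
    assert {"subset", "position", "descriptor", "i_corrected", "s"} <= set(scan_df.columns)
    # hotspot files are valid even when empty: header row only
    hot = pd.read_csv(tmp_path / "hotspots.csv")
    assert list(hot.columns) == ["subset", "position", "descriptor", "i_corrected", "s", "n"]


def test_empty_subset_scan_warns_and_returns_empty():
    sim = g.simulate_dataset(g.SimulationConfig(
        n_receptors=10, n_positions=5, n_descriptors=4,
        ligands_per_receptor=(2, 3), ligand_type_proportions=(1.0, 0.0, 0.0), seed=6,
    ))
    sub = g.AnalysisSubset("antagonist", [])
    with pytest.warns(UserWarning, match="nothing to scan"):
        scan = g.scan_subset(sub, sim.position_table, sim.descriptor_matrix, g.ScanConfig())
    assert scan.entries == []


def test_whole_row_permutation_mode_runs_and_differs():
    sim, _ = small_scan(seed=8)
    sub = g.build_subset(sim.dataset, "agonist")
    per_desc = g.scan_subset(sub, sim.position_table, sim.descriptor_matrix,
                             g.ScanConfig(permutation_mode="per_descriptor"), seed=8)
    whole = g.scan_subset(sub, sim.position_table, sim.descriptor_matrix,
                          g.ScanConfig(permutation_mode="whole_row"), seed=8)
    assert len(per_desc.entries) == len(whole.entries)
    # observed MI identical; surrogate draws differ between the two nulls
    key = lambda scan: {(e.position, e.descriptor): e.mi.i_corrected for e in scan.entries}
    assert key(per_desc) == key(whole)
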