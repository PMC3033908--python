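import pytest

import gpcrmi as g


@pytest.fixture
def toy_tables(tmp_path):
    """3 receptors, 4 ligands, 5 pairs as TSV inputs."""
    rec = tmp_path / "receptors.tsv"
    rec.write_text(
        "receptor_id\tg_proteins\n"
        "R1\tGs\n"
        "R2\tGi;Gq\n"
        "R3\tGi\n"
    )
    lig = tmp_path / "ligands.tsv"
    lig.write_text(
        "ligand_id\tligand_type\n"
        "A1\tfull_agonist\n"
        "A2\tpartial_agonist\n"
        "B1\tantagonist\n"
        "B2\tantagonist\n"
    )
    pair = tmp_path / "pairs.tsv"
    pair.write_text(
        "receptor_id\tligand_id\n"
        "R1\tA1\n"
        "R1\tB1\n"
        "R2\tA2\n"
        "R2\tB2\n"
        "R3\tA1\n"
    )
    return {"receptors": rec, "ligands": lig, "pairs": pair, "dir": tmp_path}


@pytest.fixture
def toy_dataset(toy_tables):
    return g.load_pairs(
        toy_tables["receptors"], toy_tables["ligands"], toy_tables["pairs"]
    )


@pytest.fixture(scope="session")
def default_pipeline():
    """One full pipeline run on the default synthetic dataset (seed 0).

    The default config plants no associations, so this run doubles as the
    null-calibration dataset: every (position, descriptor) ensemble realizes
    the independence hypothesis. Shared session-wide because the scan of
    all five subsets is the most expensive computation in the suite.
    """
    sim = g.simulate_dataset(g.SimulationConfig(seed=0))
    cfg = g.ScanConfig(master_seed=0)
    report = g.run_pipeline(sim.dataset, sim.position_table, sim.descriptor_matrix, cfg)
    return sim, report
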