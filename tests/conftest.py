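import numpy as np
import pytest

import qbc2 as q


@pytest.fixture(scope="session")
def small_whitelist():
    """Six 6-mers at pairwise Hamming >= 3 (unambiguous radius-1 correction)."""
    return q.generate_whitelist(6, 6, min_distance=3, rng=3)


@pytest.fixture(scope="session")
def default_schema():
    return q.default_schema()


@pytest.fixture(scope="session")
def noiseless_run(tmp_path_factory):
    """Small two-cell-line simulation with zero noise: error rate 0, one
    read per molecule, no swaps, perfect ligation.  Shared across tests."""
    out = tmp_path_factory.mktemp("noiseless")
    schema, cfg = q.fixture_config(
        "two_lines", seed=5, n_cells=150,
        error_rate=0.0, mean_reads_per_molecule=1.0, swap_rate=0.0)
    cells, molecules, sim_out = q.run_simulation(schema, cfg, out)
    return dict(schema=schema, config=cfg, cells=cells, molecules=molecules,
                sim=sim_out)


@pytest.fixture(scope="session")
def noiseless_counts(noiseless_run):
    r = noiseless_run
    # no PCR duplication in this fixture, so exact UMI counting is the
    # faithful inverse (directional could merge colliding true molecules)
    cm, ledger = q.demux_fastq(r["sim"].r1_fastq, r["sim"].r2_fastq,
                               r["schema"], r["config"].panel, min_umi=1,
                               collapse="exact")
    return cm, ledger


@pytest.fixture(scope="session")
def two_pop_clr():
    """CLR matrix of two well-separated simulated populations (truth counts,
    no sequencing), with truth labels."""
    _, cfg = q.fixture_config("two_lines", seed=9, n_cells=300,
                              ht2_spike_fraction=0.0, ht3_spike_fraction=0.0)
    cfg.sample_composition = {"mix": {"jurkat": 0.5, "hek293t": 0.5}}
    cells = q.simulate_cells(cfg)
    cm = q.counts_from_truth(cells, cfg.panel)
    labels = np.array([c.cell_type for c in cells])
    return q.clr_transform(cm), labels
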