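import itertools

import numpy as np
import pytest

import ecmopt as e


@pytest.fixture(scope="session")
def bounds():
    return e.default_bounds()


@pytest.fixture(scope="session")
def ccd(bounds):
    """The study's 23-run face-centered CCD (canonical order)."""
    return e.build_ccd(bounds, 9)


@pytest.fixture(scope="session")
def coded_basis(ccd):
    return e.quadratic_basis(ccd.coded_values())


@pytest.fixture(scope="session")
def ccd_weights(ccd):
    return e.run_weights(ccd).to_numpy()


@pytest.fixture(scope="session")
def small_sim_config():
    """Desk-scale simulation used across tests."""
    return e.SimulationConfig(
        n_emt_up=8, n_emt_down=8, n_basal=10, n_classical=10, n_housekeeping=3
    )


@pytest.fixture(scope="session")
def fitted_small_spec(bounds, ccd):
    """A small fitted objective spec (3 up + 2 down genes) on simulated data."""
    cfg = e.SimulationConfig(
        n_emt_up=3, n_emt_down=2, n_basal=5, n_classical=5, n_housekeeping=2
    )
    truth = e.simulate_ground_truth(80, bounds, cfg, seed=11)
    design = e.randomize_runs(ccd, 5)
    exp = e.simulate_counts(truth, design, n_reps=3, seed=12)
    raw = e.ExpressionMatrix(exp.counts, "raw")
    vst = e.depth_normalize_transform(raw).subset_genes(e.filter_genes(raw))
    ref, _ = e.select_reference_gene(vst)
    avg = e.average_replicates(
        e.reference_normalize(vst, ref), exp.samples.set_index("sample")["run_id"]
    )
    models = e.fit_all_genes(avg, design, weights=e.run_weights(design))
    up = truth.program_genes("emt_up")
    down = truth.program_genes("emt_down")
    genes = up + down
    weights = np.clip([models[g].adjusted_r2 for g in genes], 0.05, 1.0)
    spec = e.ObjectiveSpec(
        genes, ["up"] * len(up) + ["down"] * len(down), weights,
        [models[g] for g in genes], bounds,
    )
    return spec, truth


def composition_grid(bounds, n=51):
    axes = [np.linspace(fb.low, fb.high, n) for fb in bounds]
    return np.array(list(itertools.product(*axes)))
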