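"""Shared fixtures: small seeded simulations reused across test modules."""

import dataclasses
import math
import warnings

import numpy as np
import pytest

import isletime as it

warnings.filterwarnings("ignore")


def small_config(**overrides) -> it.SimulationConfig:
    """Two-donor, one-replicate design small enough for fast unit tests."""
    defaults = dict(
        n_donors=2,
        n_replicates_per_donor=1,
        n_genes=900,
        n_cells_per_well=40,
        effect_spec=it.EffectSpec(n_time_genes=80, time_log_fc=1.2,
                                  n_glucose_genes=40, glucose_log_fc=1.0,
                                  n_interaction_genes=20,
                                  interaction_log_fc=1.25),
    )
    defaults.update(overrides)
    return dataclasses.replace(it.SimulationConfig(), **defaults)


def single_type_config(**overrides) -> it.SimulationConfig:
    """One beta-cell population: strips annotation out of the picture."""
    defaults = dict(
        cell_types=(it.CellTypeSpec("beta", 1.0, ("INS",)),),
        n_donors=2,
        n_replicates_per_donor=1,
        n_genes=800,
        n_cells_per_well=60,
        base_log_sd=0.8,
        hurdle_spec=it.HurdleSpec(mean_detection=0.8),
        depth_spec=it.DepthSpec(log_mean=math.log(20000.0)),
    )
    defaults.update(overrides)
    return dataclasses.replace(it.SimulationConfig(), **defaults)


@pytest.fixture(scope="session")
def small_dataset():
    """(counts AnnData, GroundTruth) for the small mixed-type design."""
    return it.simulate_dataset(small_config(), seed=7)


@pytest.fixture(scope="session")
def small_expr(small_dataset):
    """Filtered + ln(CP10K+1)-normalized version of the small dataset."""
    counts, truth = small_dataset
    filtered, report = it.apply_qc_filters(counts)
    expr = it.normalize_log_cp10k(filtered)
    return expr, truth, report


@pytest.fixture(scope="session")
def true_labels(small_expr):
    expr, truth, _ = small_expr
    return truth.cells.loc[expr.obs_names, "cell_type"]
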