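import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from lipid2h.compounds import parse_lipid_label
from lipid2h.isotope import pool_fractionation
from lipid2h.pipeline import reduce_study
from lipid2h.simulate import SimConfig, generate_study
from lipid2h.types import DeltaValue


@pytest.fixture(scope="session")
def noise_free_study(tmp_path_factory):
    """A complete synthetic study with every noise source switched off."""
    out = tmp_path_factory.mktemp("study_nf")
    files, truth = generate_study(
        SimConfig(seed=3, noise_permil=0.0, abundance_rel_noise=0.0), out
    )
    return files, truth


@pytest.fixture(scope="session")
def noisy_study(tmp_path_factory):
    """A synthetic study at the default 5.5‰ measurement noise."""
    out = tmp_path_factory.mktemp("study_noisy")
    files, truth = generate_study(SimConfig(seed=1), out)
    return files, truth


@pytest.fixture(scope="session")
def noise_free_reduction(noise_free_study):
    files, truth = noise_free_study
    return reduce_study(files.peaks, files.samples, files.standards), truth


def truth_cell(truth: pd.DataFrame, strain: str, donor: str, sulfate: float):
    return truth[
        (truth.strain == strain)
        & (truth.donor == donor)
        & (truth.sulfate_mM == f"{sulfate:.10f}")
    ]


def truth_eps_total(truth: pd.DataFrame, strain: str, donor: str, sulfate: float) -> float:
    """Hydrogen-weighted ε_total recomputed from the generator's truth table."""
    cell = truth_cell(truth, strain, donor, sulfate)
    lip = cell[cell.key == "lipid"]
    water = float(cell[cell.key == "water_delta_permil"].value.iloc[0])
    items = [
        (
            parse_lipid_label(r.compound),
            float(r.abundance_pct),
            DeltaValue(float(r.delta_vsmow_permil)),
        )
        for r in lip.itertuples()
    ]
    _, eps_total = pool_fractionation(items, DeltaValue(water))
    return eps_total.eps


def truth_lipid_delta(truth, strain, donor, sulfate, compound) -> float:
    cell = truth_cell(truth, strain, donor, sulfate)
    lip = cell[(cell.key == "lipid") & (cell.compound == compound)]
    return float(lip.delta_vsmow_permil.iloc[0])


def truth_mu_avg(truth, strain, donor, sulfate) -> float:
    cell = truth_cell(truth, strain, donor, sulfate)
    return float(cell[cell.key == "mu_avg"].value.iloc[0])
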