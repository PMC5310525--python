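import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import pharmbench as pb

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort() -> pb.SyntheticCohort:
    """A tiny mixed cohort shared by fast tests (200 genes, 60/40 cells)."""
    cfg = pb.GeneratorConfig(
        n_genes=200,
        n_cells_release1=60,
        n_cells_new_release2=40,
        drug_specs=pb.default_drug_panel(2, 2, 2),
        seed=7,
    )
    return pb.generate_cohort(cfg)


@pytest.fixture()
def tiny_expression() -> pb.ExpressionMatrix:
    frame = pd.DataFrame(
        [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]],
        index=["CL_A", "CL_B"],
        columns=["TP53", "KRAS", "BRAF"],
    )
    return pb.ExpressionMatrix(frame)


@pytest.fixture()
def tiny_mutations() -> pb.MutationTable:
    raw = pd.DataFrame(
        {
            "TP53": ["p.R175H::0<cn<8", "wt::0<cn<8", "wt::0<cn<8"],
            "KRAS": ["wt::0<cn<8", "na::cn=0", "wt::0<cn<8"],
        },
        index=["CL_A", "CL_B", "CL_C"],
    )
    return pb.MutationTable(raw)


def make_response(release: str, rows: list[tuple[str, str, float]]) -> pb.ResponseTable:
    frame = pd.DataFrame(rows, columns=["drug_id", "cell_line_id", "logic50"])
    return pb.ResponseTable(release, frame)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
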