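import pandas as pd
import pytest

from ecothresh.community import CommunityTable
from ecothresh.models import FitConfig
from ecothresh.simulate import ScenarioConfig, generate


@pytest.fixture
def toy_table() -> CommunityTable:
    """Two landscapes, 2 forest + 2 matrix plots each, three species:
    A lives in forests, B everywhere, C in the matrix."""
    rows = []
    for lid in ("L1", "L2"):
        for habitat, (a, b, c) in (("forest", (3, 2, 0)), ("matrix", (0, 1, 4))):
            for p in range(2):
                rows.append(
                    {
                        "landscape_id": lid,
                        "habitat": habitat,
                        "plot_id": f"{habitat[0]}{p}",
                        "A": a + p,
                        "B": b,
                        "C": c,
                    }
                )
    plots = pd.DataFrame(rows)
    covariates = pd.Series({"L1": 10.0, "L2": 40.0})
    return CommunityTable(plots=plots, covariates=covariates).with_labels(
        {"A": "FS", "B": "G", "C": "OS"}
    )


@pytest.fixture(scope="session")
def synthetic_table():
    """One default-scenario synthetic table with its generating truth."""
    return generate(ScenarioConfig(seed=7))


@pytest.fixture(scope="session")
def fast_fit() -> FitConfig:
    """Fewer restarts for Monte-Carlo-heavy tests."""
    return FitConfig(n_restarts=6, seed=0)
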