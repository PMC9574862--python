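import numpy as np
import pytest

import protacsol as ps


@pytest.fixture
def benchmark():
    """The bundled 21-compound degrader panel (5 censored)."""
    from protacsol.datasets import load_protac_benchmark

    return load_protac_benchmark()


@pytest.fixture
def synthetic_panel():
    """A fixed synthetic 21-compound dataset (default study conditions)."""
    return ps.generate_dataset(ps.GeneratorConfig(n_compounds=21, seed=7))


@pytest.fixture
def compounds_csv(tmp_path):
    path = tmp_path / "compounds.csv"
    path.write_text(
        "id,name,smiles,mw,role\n"
        "CAF,caffeine,Cn1cnc2c1c(=O)n(C)c(=O)n2C,194.19,building_block\n"
        "ASP,aspirin,CC(=O)Oc1ccccc1C(=O)O,180.16,building_block\n"
    )
    return path


def ols_oracle(x, y):
    """Closed-form simple OLS, independent of the package implementation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    slope = float(np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2))
    intercept = float(ym - slope * xm)
    ss_res = float(np.sum((y - slope * x - intercept) ** 2))
    ss_tot = float(np.sum((y - ym) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot else 0.0
    return slope, intercept, r2
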