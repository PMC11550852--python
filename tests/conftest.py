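import numpy as np
import pandas as pd
import pytest

from fertconv.sample_builder import ConvergenceSample


def make_panel(rows):
    """Long-format panel from (country, year, indicator, value) tuples."""
    return pd.DataFrame(rows, columns=["country", "year", "indicator", "value"])


@pytest.fixture
def tiny_tfr_panel():
    """2 countries x 3 quinquennial years of TFR."""
    rows = []
    for c, base in (("AAA", 4.0), ("BBB", 6.0)):
        for i, year in enumerate((1950, 1955, 1960)):
            rows.append((c, year, "TFR", base * 0.8**i))
    return make_panel(rows)


@pytest.fixture
def linked_panel():
    """3 countries x 3 years with TFR and a schooling indicator."""
    rows = []
    for c, (f0, e0) in (("AAA", (4.0, 2.0)), ("BBB", (6.0, 1.0)), ("CCC", (2.5, 5.0))):
        for i, year in enumerate((1950, 1955, 1960)):
            rows.append((c, year, "TFR", f0 * 0.8**i))
            rows.append((c, year, "schooling", e0 + 1.5 * i))
    return make_panel(rows)


def make_sample(countries, base, ratio, delta=1.0, **covs):
    """ConvergenceSample straight from arrays (bypasses panel plumbing)."""
    n = len(ratio)
    data = pd.DataFrame(
        {
            "country": countries,
            "base_year": np.arange(n) * 5 + 1950,
            "base_fertility": base,
            "ratio": ratio,
            "delta_edu": delta,
        }
    )
    for name, vals in covs.items():
        data[name] = vals
    return ConvergenceSample(
        data=data,
        fert_indicator="TFR",
        edu_indicator="schooling",
        covariate_names=tuple(covs),
    )


def random_cluster_sample(rng, n_clusters=None, n_per=None, n_covs=0):
    """Random panel-shaped regression sample for estimator equivalence tests."""
    G = n_clusters or rng.integers(3, 9)
    rows = []
    for g in range(G):
        T = n_per or rng.integers(2, 7)
        base = rng.uniform(1.0, 8.0, T)
        ratio = (
            -0.02
            - 0.04 * base
            + rng.normal(0, 0.05)
            + rng.normal(0, 0.03, T)
        )
        for t in range(T):
            rows.append((f"G{g:02d}", 1950 + 5 * t, base[t], ratio[t]))
    data = pd.DataFrame(
        rows, columns=["country", "base_year", "base_fertility", "ratio"]
    )
    data["delta_edu"] = 1.0
    covs = []
    for j in range(n_covs):
        name = f"x{j}"
        data[name] = rng.normal(size=len(data))
        covs.append(name)
    return ConvergenceSample(
        data=data,
        fert_indicator="TFR",
        edu_indicator="schooling",
        covariate_names=tuple(covs),
    )
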