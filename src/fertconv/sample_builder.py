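"""Construction of the convergence regression sample.

The estimating statistic is the growth of a (natural-logged) fertility
indicator between consecutive lattice years, divided either by the elapsed
time (classical growth-convergence over time) or by the contemporaneous
change in an education indicator (convergence over education):

    time:       ratio_it = [ln Y_{i,t+n} - ln Y_{i,t}] / n
    education:  ratio_it = [ln FER_{i,t+5} - ln FER_{i,t}]
                           / (EDU_{i,t+5} - EDU_{i,t})

Each retained row carries the base-year fertility level FER_{i,t}, which is
the regressor of the convergence model.  Because a near-zero education
change makes the education-denominated ratio explode, rows with
|ΔEDU| below a tolerance are excluded before anything else; remaining
extremes are handled by the quartile fence rule (Q1 - k·IQR, Q3 + k·IQR,
default k = 3) applied once, per regression cell, before standardization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._exceptions import DegenerateSampleError, EmptySampleError, SchemaError

#: default tolerance (education-indicator units) below which an education
#: change counts as zero and the ratio is undefined
ZERO_DELTA_TOL = 1e-9

SAMPLE_COLUMNS = ["country", "base_year", "base_fertility", "ratio", "delta_edu"]


@dataclass
class ConvergenceSample:
    """Per-country-per-interval regression rows plus exclusion bookkeeping.

    ``data`` holds one row per (country, base_year) with columns
    ``country, base_year, base_fertility, ratio, delta_edu`` plus any
    covariate columns.  ``removed`` holds rows dropped by the fence rule.
    """

    data: pd.DataFrame
    fert_indicator: str
    edu_indicator: str | None = None  # None for the time-denominated sample
    horizon: int = 5
    covariate_names: tuple[str, ...] = ()
    n_zero_delta: int = 0
    n_nonpositive: int = 0
    n_trimmed: int = 0
    standardized: bool = False
    removed: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=SAMPLE_COLUMNS)
    )

    @property
    def n_obs(self) -> int:
        return len(self.data)

    @property
    def n_countries(self) -> int:
        return self.data["country"].nunique()

    def to_csv(self, path) -> None:
        """Serialize retained and removed rows with a ``retained`` flag."""
        kept = self.data.copy()
        kept["retained"] = True
        dropped = self.removed.copy()
        dropped["retained"] = False
        pd.concat([kept, dropped], ignore_index=True).to_csv(path, index=False)


def _wide(panel: pd.DataFrame, indicators: list[str]) -> pd.DataFrame:
    present = set(panel["indicator"].unique())
    missing = [ind for ind in indicators if ind not in present]
    if missing:
        raise SchemaError(f"indicator(s) not in panel: {missing}")
    sub = panel[panel["indicator"].isin(indicators)]
    wide = sub.pivot_table(
        index=["country", "year"], columns="indicator", values="value", sort=False
    ).reset_index()
    wide.columns.name = None
    return wide.sort_values(["country", "year"], kind="mergesort")


def _intervals(wide: pd.DataFrame, horizon: int) -> pd.DataFrame:
    """Pair each (country, year) row with the row ``horizon`` years later."""
    nxt = wide.copy()
    nxt["year"] = nxt["year"] - horizon
    paired = wide.merge(
        nxt, on=["country", "year"], suffixes=("", "_next"), how="inner"
    )
    return paired.rename(columns={"year": "base_year"})


def build_time_sample(
    panel: pd.DataFrame, fert: str, horizon: int = 5
) -> ConvergenceSample:
    """Annualized log-growth sample: ratio = [ln Y_{t+n} - ln Y_t] / n.

    Rows with a nonpositive fertility value at either endpoint are excluded
    (the log is undefined) and counted in ``n_nonpositive``.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    paired = _intervals(_wide(panel, [fert]), horizon)
    ok = (paired[fert] > 0) & (paired[f"{fert}_next"] > 0)
    n_bad = int((~ok).sum())
    paired = paired[ok]
    data = pd.DataFrame(
        {
            "country": paired["country"],
            "base_year": paired["base_year"].astype(int),
            "base_fertility": paired[fert].to_numpy(),
            "ratio": (
                np.log(paired[f"{fert}_next"].to_numpy())
                - np.log(paired[fert].to_numpy())
            )
            / horizon,
            "delta_edu": float(horizon),  # the denominator is time itself
        }
    ).reset_index(drop=True)
    if data.empty:
        raise EmptySampleError(f"no usable intervals for indicator {fert!r}")
    return ConvergenceSample(
        data=data, fert_indicator=fert, horizon=horizon, n_nonpositive=n_bad
    )


def build_edu_sample(
    panel: pd.DataFrame,
    fert: str,
    edu: str,
    horizon: int = 5,
    covariates: tuple[str, ...] = (),
    zero_tol: float = ZERO_DELTA_TOL,
    drop_negative_delta: bool = False,
) -> ConvergenceSample:
    """Education-denominated growth sample.

    ratio = [ln FER_{t+h} - ln FER_t] / (EDU_{t+h} - EDU_t), with the base
    fertility level and the education change recorded per row.  Rows with
    |ΔEDU| < ``zero_tol`` are excluded and counted in ``n_zero_delta``
    (the ratio is undefined); nonpositive fertility endpoints are likewise
    excluded.  Negative education changes are retained unless
    ``drop_negative_delta`` — the sign of the ratio simply flips and the
    fence rule handles any resulting extremes.  Covariates are taken at the
    base year.  Raises :class:`EmptySampleError` if nothing survives.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    paired = _intervals(_wide(panel, [fert, edu, *covariates]), horizon)
    delta = paired[f"{edu}_next"].to_numpy() - paired[edu].to_numpy()

    zero = np.abs(delta) < zero_tol
    if drop_negative_delta:
        zero |= delta < 0
    n_zero = int(zero.sum())
    nonpos = (paired[fert].to_numpy() <= 0) | (paired[f"{fert}_next"].to_numpy() <= 0)
    n_nonpos = int((nonpos & ~zero).sum())
    keep = ~zero & ~nonpos

    paired = paired[keep]
    delta = delta[keep]
    data = pd.DataFrame(
        {
            "country": paired["country"],
            "base_year": paired["base_year"].astype(int),
            "base_fertility": paired[fert].to_numpy(),
            "ratio": (
                np.log(paired[f"{fert}_next"].to_numpy())
                - np.log(paired[fert].to_numpy())
            )
            / delta,
            "delta_edu": delta,
        }
    )
    for cov in covariates:
        data[cov] = paired[cov].to_numpy()
    data = data.dropna(subset=list(data.columns)).reset_index(drop=True)
    if data.empty:
        raise EmptySampleError(
            f"every interval excluded for {fert!r} over {edu!r} "
            f"({n_zero} zero-change, {n_nonpos} nonpositive-fertility)"
        )
    return ConvergenceSample(
        data=data,
        fert_indicator=fert,
        edu_indicator=edu,
        horizon=horizon,
        covariate_names=tuple(covariates),
        n_zero_delta=n_zero,
        n_nonpositive=n_nonpos,
    )


def iqr_fences(ratios: np.ndarray, k: float = 3.0) -> tuple[float, float]:
    """Quartile fences [Q1 - k·IQR, Q3 + k·IQR] on a ratio distribution.

    Quartiles use linear interpolation between order statistics.
    """
    q1, q3 = np.percentile(ratios, [25.0, 75.0])
    iqr = q3 - q1
    return q1 - k * iqr, q3 + k * iqr


def trim_outliers(sample: ConvergenceSample, k: float = 3.0) -> ConvergenceSample:
    """Remove ratio outliers outside the quartile fences.

    Fences are computed once on the input sample's ratio distribution;
    rows outside [Q1 - k·IQR, Q3 + k·IQR] move to ``removed``.  The rule is
    applied exactly once per regression cell — re-fencing a trimmed sample
    can remove further rows and is deliberately not done by the pipeline.
    """
    if sample.n_obs == 0:
        raise EmptySampleError("cannot trim an empty sample")
    lo, hi = iqr_fences(sample.data["ratio"].to_numpy(), k=k)
    inside = (sample.data["ratio"] >= lo) & (sample.data["ratio"] <= hi)
    removed = sample.data[~inside].reset_index(drop=True)
    n_new = len(removed)
    if not sample.removed.empty:
        removed = pd.concat([sample.removed, removed], ignore_index=True)
    return replace(
        sample,
        data=sample.data[inside].reset_index(drop=True),
        n_trimmed=sample.n_trimmed + n_new,
        removed=removed,
    )


def standardize(sample: ConvergenceSample) -> ConvergenceSample:
    """Z-score the ratio, base fertility, and any covariates.

    Uses the sample standard deviation (n-1 denominator) computed on the
    rows passed in, i.e. on the post-trimming estimation sample.  Raises
    :class:`DegenerateSampleError` when any column to be standardized has
    zero variance.
    """
    cols = ["ratio", "base_fertility", *sample.covariate_names]
    data = sample.data.copy()
    for col in cols:
        x = data[col].to_numpy(dtype=float)
        if len(x) < 2:
            raise DegenerateSampleError(
                f"need at least 2 rows to standardize {col!r}"
            )
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise DegenerateSampleError(f"zero variance in {col!r}")
        data[col] = (x - x.mean()) / sd
    return replace(sample, data=data, standardized=True)
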