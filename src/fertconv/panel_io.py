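"""Reading, validating, linking, and subsetting country-year indicator panels.

A *panel* is a long-format :class:`pandas.DataFrame` with columns
``country``, ``year``, ``indicator``, ``value`` — one row per
(country, year, indicator) triple.  Country metadata (World Bank income
group, sub-Saharan-Africa flag, ...) travels in a separate table keyed by
country, because classifications are an analyst input rather than something
derivable from the indicators themselves.

Indicator values are range-checked according to their kind:

=============  ======================================  =================
kind           typical indicators                      admissible range
=============  ======================================  =================
``level``      TFR, NRR (births / daughters per woman) value > 0
``age``        MACB (mean age at childbearing, years)  10 < value < 60
``years``      mean years of schooling                 value >= 0
``share``      % attended/completed a schooling cycle  0 <= value <= 100
=============  ======================================  =================

Unknown indicators are accepted without a range check.
"""

from __future__ import annotations

import logging
import re
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from ._exceptions import (
    IntegrityError,
    LinkageError,
    SchemaError,
    SubgroupSpecError,
    ValidationError,
)

logger = logging.getLogger("fertconv")

PANEL_COLUMNS = ["country", "year", "indicator", "value"]

INCOME_GROUPS = ["low", "lower-middle", "upper-middle", "high"]

#: Regex patterns mapping indicator names to range-check kinds.
_KIND_PATTERNS = [
    (re.compile(r"^(tfr|nrr)$", re.I), "level"),
    (re.compile(r"macb|age_at|mean_age", re.I), "age"),
    (re.compile(r"years|schooling|yos", re.I), "years"),
    (re.compile(r"attended|completed|share|pct|percent", re.I), "share"),
]

_RANGES = {
    # (low, high, low_open, high_open)
    "level": (0.0, np.inf, True, True),
    "age": (10.0, 60.0, True, True),
    "years": (0.0, np.inf, False, True),
    "share": (0.0, 100.0, False, False),
}


def indicator_kind(name: str, kinds: Mapping[str, str] | None = None) -> str | None:
    """Classify an indicator name for range checking.

    An explicit ``kinds`` mapping takes precedence over the built-in name
    patterns; unrecognized names return ``None`` (no range check).
    """
    if kinds and name in kinds:
        return kinds[name]
    for pattern, kind in _KIND_PATTERNS:
        if pattern.search(name):
            return kind
    return None


def _check_ranges(df: pd.DataFrame, kinds: Mapping[str, str] | None) -> None:
    offenders = []
    for name, group in df.groupby("indicator", sort=False):
        kind = indicator_kind(str(name), kinds)
        if kind is None:
            continue
        lo, hi, lo_open, hi_open = _RANGES[kind]
        vals = group["value"].to_numpy(dtype=float)
        bad = (vals < lo) | (vals > hi)
        if lo_open:
            bad |= vals == lo
        if hi_open:
            bad |= vals == hi
        bad |= ~np.isfinite(vals)
        if bad.any():
            rows = group.loc[group.index[bad], ["country", "year", "indicator"]]
            offenders.extend(map(tuple, rows.itertuples(index=False)))
    if offenders:
        raise ValidationError(
            f"{len(offenders)} value(s) outside admissible range: "
            f"{offenders[:10]}{' ...' if len(offenders) > 10 else ''}",
            offenders=offenders,
        )


def validate_panel(
    panel: pd.DataFrame, kinds: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Validate a long-format panel in place and return it.

    Checks column presence, key uniqueness, and indicator ranges; raises
    :class:`SchemaError`, :class:`IntegrityError`, or :class:`ValidationError`.
    """
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise SchemaError(f"panel is missing required column(s): {missing}")
    dup = panel.duplicated(subset=["country", "year", "indicator"], keep=False)
    if dup.any():
        keys = (
            panel.loc[dup, ["country", "year", "indicator"]]
            .drop_duplicates()
            .itertuples(index=False)
        )
        keys = list(map(tuple, keys))
        raise IntegrityError(
            f"duplicate (country, year, indicator) key(s): "
            f"{keys[:10]}{' ...' if len(keys) > 10 else ''}"
        )
    _check_ranges(panel, kinds)
    return panel


def read_panel(
    path,
    schema: Mapping[str, str] | None = None,
    kinds: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a CSV panel, accepting both long and wide dialects.

    Long dialect: columns ``country, year, indicator, value``.  Wide dialect:
    ``country, year`` plus one column per indicator, melted on read.
    ``schema`` renames file columns (wide) or indicator labels (long) to
    canonical indicator names, e.g. ``{"tfr_wpp": "TFR"}``.

    Raises :class:`SchemaError` for missing columns, :class:`IntegrityError`
    for duplicate keys, and :class:`ValidationError` (listing offending keys)
    for out-of-range values.
    """
    df = pd.read_csv(path)
    df.columns = [str(c).strip() for c in df.columns]
    for col in ("country", "year"):
        if col not in df.columns:
            raise SchemaError(f"{path}: required column {col!r} not found")
    if "indicator" in df.columns and "value" in df.columns:
        long = df[PANEL_COLUMNS].copy()
        if schema:
            long["indicator"] = long["indicator"].replace(dict(schema))
    else:
        value_cols = [c for c in df.columns if c not in ("country", "year")]
        if not value_cols:
            raise SchemaError(f"{path}: no indicator columns found")
        if schema:
            df = df.rename(columns=dict(schema))
            value_cols = [schema.get(c, c) for c in value_cols]
        long = df.melt(
            id_vars=["country", "year"],
            value_vars=value_cols,
            var_name="indicator",
            value_name="value",
        )
    long["year"] = long["year"].astype(int)
    long["country"] = long["country"].astype(str)
    long["value"] = pd.to_numeric(long["value"], errors="coerce")
    n_missing = int(long["value"].isna().sum())
    if n_missing:
        logger.info("read_panel: dropped %d row(s) with missing values", n_missing)
        long = long.dropna(subset=["value"])
    long = long.reset_index(drop=True)
    return validate_panel(long, kinds)


def write_panel(panel: pd.DataFrame, path) -> None:
    """Write a long-format panel to CSV (UTF-8, header row)."""
    panel[PANEL_COLUMNS].to_csv(path, index=False)


def read_metadata(path) -> pd.DataFrame:
    """Read a country metadata CSV keyed by ``country``.

    Recognized columns: ``income_group`` (one of low / lower-middle /
    upper-middle / high) and ``is_ssa`` (boolean).  Extra columns pass
    through untouched for use in custom subgroup predicates.
    """
    meta = pd.read_csv(path)
    if "country" not in meta.columns:
        raise SchemaError(f"{path}: metadata requires a 'country' column")
    meta["country"] = meta["country"].astype(str)
    if meta["country"].duplicated().any():
        dups = meta.loc[meta["country"].duplicated(), "country"].tolist()
        raise IntegrityError(f"duplicate country key(s) in metadata: {dups[:10]}")
    if "income_group" in meta.columns:
        bad = ~meta["income_group"].isin(INCOME_GROUPS)
        if bad.any():
            raise ValidationError(
                f"unknown income_group value(s): "
                f"{sorted(meta.loc[bad, 'income_group'].unique())}",
                offenders=meta.loc[bad, "country"].tolist(),
            )
    if "is_ssa" in meta.columns:
        meta["is_ssa"] = meta["is_ssa"].astype(bool)
    return meta


def _lattice_years(years: np.ndarray, step: int) -> np.ndarray:
    """Years on the ``step`` lattice anchored at the minimum year given."""
    anchor = int(years.min())
    return years[(years - anchor) % step == 0]


def link_panels(
    fertility: pd.DataFrame,
    education: pd.DataFrame,
    step: int = 5,
    require_balanced: bool = True,
) -> pd.DataFrame:
    """Merge fertility and education panels onto a common year lattice.

    The lattice is the set of years present in *both* sources that fall on a
    ``step``-year grid anchored at the minimum common year (annual fertility
    linked to quinquennial education keeps every fifth year).  Rows are kept
    only for (country, year) pairs observed in both sources.  With
    ``require_balanced`` (default), countries missing any lattice year for
    any of their indicators are dropped and the drops logged, yielding a
    balanced panel.

    Raises :class:`LinkageError` when no (country, year) pair survives.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if fertility.empty or education.empty:
        raise LinkageError("cannot link: an input panel is empty")
    common_years = np.intersect1d(
        fertility["year"].unique(), education["year"].unique()
    )
    if common_years.size == 0:
        raise LinkageError("no common years between fertility and education panels")
    lattice = _lattice_years(common_years, step)

    merged = pd.concat([fertility, education], ignore_index=True)
    merged = merged[merged["year"].isin(lattice)]

    # keep (country, year) pairs present in both sources
    f_keys = set(
        map(tuple, fertility.loc[fertility["year"].isin(lattice),
                                 ["country", "year"]].itertuples(index=False))
    )
    e_keys = set(
        map(tuple, education.loc[education["year"].isin(lattice),
                                 ["country", "year"]].itertuples(index=False))
    )
    keep = f_keys & e_keys
    if not keep:
        raise LinkageError("no (country, year) pair present in both panels")
    mask = [
        (c, y) in keep for c, y in merged[["country", "year"]].itertuples(index=False)
    ]
    merged = merged.loc[mask].reset_index(drop=True)

    n_na = int(merged["value"].isna().sum())
    if n_na:
        logger.info("link_panels: dropped %d row(s) with missing values", n_na)
        merged = merged.dropna(subset=["value"])

    if require_balanced:
        n_lattice = len(lattice)
        counts = merged.groupby(["country", "indicator"])["year"].nunique()
        incomplete = counts[counts < n_lattice].index.get_level_values(0).unique()
        if len(incomplete):
            logger.info(
                "link_panels: dropped %d unbalanced country(ies): %s",
                len(incomplete),
                sorted(incomplete)[:20],
            )
            merged = merged[~merged["country"].isin(incomplete)]
        if merged.empty:
            raise LinkageError("balance requirement dropped every country")

    merged = merged.sort_values(["country", "indicator", "year"], kind="mergesort")
    return merged.reset_index(drop=True)


#: Built-in subgroup rules mirroring the subregional analyses:
#: each maps a metadata row mask to *keep*.
_RULES: dict[str, Callable[[pd.DataFrame], pd.Series]] = {
    "all": lambda m: pd.Series(True, index=m.index),
    "exclude-high-income": lambda m: m["income_group"] != "high",
    "exclude-low-and-lower-middle-income": lambda m: ~m["income_group"].isin(
        ["low", "lower-middle"]
    ),
    "exclude-ssa": lambda m: ~m["is_ssa"],
    "ssa-only": lambda m: m["is_ssa"].astype(bool),
}
_RULES["keep-ssa-only"] = _RULES["ssa-only"]

_RULE_COLUMNS = {
    "all": [],
    "exclude-high-income": ["income_group"],
    "exclude-low-and-lower-middle-income": ["income_group"],
    "exclude-ssa": ["is_ssa"],
    "ssa-only": ["is_ssa"],
    "keep-ssa-only": ["is_ssa"],
}


def filter_subgroup(
    panel: pd.DataFrame,
    rule: str | Callable[[pd.DataFrame], pd.Series],
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Restrict a panel to a country subgroup.

    ``rule`` is either a built-in name (``all``, ``exclude-high-income``,
    ``exclude-low-and-lower-middle-income``, ``exclude-ssa``, ``ssa-only``)
    or a callable taking the metadata table and returning a boolean keep-mask
    over its rows.  Raises :class:`SubgroupSpecError` for unknown rules or
    metadata columns the rule needs but that are absent.
    """
    if callable(rule):
        fn, needed = rule, []
    else:
        if rule not in _RULES:
            raise SubgroupSpecError(
                f"unknown subgroup rule {rule!r}; known: {sorted(_RULES)}"
            )
        fn, needed = _RULES[rule], _RULE_COLUMNS[rule]

    if metadata is None:
        metadata = panel[["country"]].drop_duplicates().reset_index(drop=True)
    for col in needed:
        if col not in metadata.columns:
            raise SubgroupSpecError(
                f"subgroup rule {rule!r} needs metadata column {col!r}"
            )
    try:
        mask = fn(metadata)
    except KeyError as exc:  # custom predicate referencing an absent column
        raise SubgroupSpecError(f"subgroup predicate needs metadata column {exc}")
    keep = set(metadata.loc[np.asarray(mask, dtype=bool), "country"])
    return panel[panel["country"].isin(keep)].reset_index(drop=True)
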