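"""Orchestration of the full indicator x education x subgroup analysis.

Each grid cell runs the complete pipeline for one
(fertility indicator, education measure, subgroup, covariate set):

    filter_subgroup -> build_edu_sample (zero-change exclusion)
    -> trim_outliers -> standardize -> fit_convergence

Cell failures (empty samples, unidentified designs) are recorded in the
cell rather than raised, so a grid always completes.  The default grid
mirrors the global analysis: 3 fertility indicators x 7 education measures
(years of schooling; attended/completed x primary/secondary/tertiary)
x 5 subgroups (all, excl. high income, excl. low & lower-middle income,
excl. sub-Saharan Africa, SSA only) = 105 cells.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from ._exceptions import (
    DegenerateSampleError,
    EmptySampleError,
    FertconvError,
    SchemaError,
)
from .estimator import FitResult, fit_convergence
from .panel_io import filter_subgroup, _RULES
from .sample_builder import (
    ZERO_DELTA_TOL,
    build_edu_sample,
    standardize,
    trim_outliers,
)
from .synthetic_data import YEARS_INDICATOR

logger = logging.getLogger("fertconv")

DEFAULT_FERTILITY = ("TFR", "MACB", "NRR")
DEFAULT_EDUCATION = (
    YEARS_INDICATOR,
    "primary_attended",
    "primary_completed",
    "secondary_attended",
    "secondary_completed",
    "tertiary_attended",
    "tertiary_completed",
)
DEFAULT_SUBGROUPS = (
    "all",
    "exclude-high-income",
    "exclude-low-and-lower-middle-income",
    "exclude-ssa",
    "ssa-only",
)

#: education measures by (level, mode) for the gradient summary
_LEVELS = ("primary", "secondary", "tertiary")
_MODES = ("attended", "completed")


@dataclass
class GridSpec:
    """What to run: the cross of indicators, measures, and subgroups."""

    fertility: tuple[str, ...] = DEFAULT_FERTILITY
    education: tuple[str, ...] = DEFAULT_EDUCATION
    subgroups: tuple[str, ...] = DEFAULT_SUBGROUPS
    covariates: tuple[str, ...] = ()
    horizon: int = 5
    trim_k: float = 3.0
    zero_tol: float = ZERO_DELTA_TOL
    fixed_effects: bool = True
    standardize: bool = True
    keep_list: pd.DataFrame | None = None  # optional (country, year) restriction

    def cells(self):
        for fert in self.fertility:
            for edu in self.education:
                for sub in self.subgroups:
                    yield fert, edu, sub


@dataclass
class GridCell:
    fertility: str
    education: str
    subgroup: str
    result: FitResult | None = None
    failure: str | None = None


@dataclass
class AnalysisGrid:
    cells: list[GridCell]
    provenance: dict = field(default_factory=dict)

    def get(self, fertility: str, education: str, subgroup: str) -> GridCell:
        for cell in self.cells:
            if (cell.fertility, cell.education, cell.subgroup) == (
                fertility,
                education,
                subgroup,
            ):
                return cell
        raise KeyError((fertility, education, subgroup))

    def to_frame(self) -> pd.DataFrame:
        """One tidy row per cell (failed cells keep their reason string)."""
        rows = []
        for cell in self.cells:
            row = {
                "fertility": cell.fertility,
                "education": cell.education,
                "subgroup": cell.subgroup,
                "failure": cell.failure or "",
            }
            if cell.result is not None:
                row.update(cell.result.to_row())
                row.pop("fert_indicator", None)
                row.pop("edu_indicator", None)
            rows.append(row)
        return pd.DataFrame(rows)


def _spec_hash(spec: GridSpec) -> str:
    payload = dataclasses.asdict(spec)
    kl = payload.pop("keep_list", None)
    if kl is not None:
        payload["keep_list"] = sorted(map(tuple, np.asarray(kl)))
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_grid(
    panel: pd.DataFrame,
    metadata: pd.DataFrame | None,
    spec: GridSpec | None = None,
) -> AnalysisGrid:
    """Run every requested cell; never raise for per-cell failures.

    Unknown indicators or subgroup rules in the spec raise
    :class:`SchemaError` before any fitting.  Per-cell errors (everything
    excluded, no within-country variation, too few clusters, ...) are
    recorded on the cell with the exception message.
    """
    spec = spec or GridSpec()
    present = set(panel["indicator"].unique())
    unknown = [
        ind
        for ind in (*spec.fertility, *spec.education, *spec.covariates)
        if ind not in present
    ]
    if unknown:
        raise SchemaError(f"grid spec references absent indicator(s): {unknown}")
    for rule in spec.subgroups:
        if not callable(rule) and rule not in _RULES:
            raise SchemaError(f"grid spec references unknown subgroup {rule!r}")

    if spec.keep_list is not None:
        keys = set(map(tuple, spec.keep_list[["country", "year"]].itertuples(index=False)))
        mask = [
            (c, y) in keys
            for c, y in panel[["country", "year"]].itertuples(index=False)
        ]
        panel = panel.loc[mask]

    cells = []
    for fert, edu, sub in spec.cells():
        cell = GridCell(fert, edu, sub)
        try:
            cell.result = _run_cell(panel, metadata, spec, fert, edu, sub)
        except FertconvError as exc:
            cell.failure = f"{type(exc).__name__}: {exc}"
            logger.info("grid cell (%s, %s, %s) failed: %s", fert, edu, sub, exc)
        cells.append(cell)

    provenance = {
        "spec_hash": _spec_hash(spec),
        "n_cells": len(cells),
        "n_failed": sum(c.failure is not None for c in cells),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    return AnalysisGrid(cells=cells, provenance=provenance)


def _run_cell(panel, metadata, spec: GridSpec, fert, edu, sub) -> FitResult:
    subset = filter_subgroup(panel, sub, metadata)
    if subset.empty:
        raise EmptySampleError(f"subgroup {sub!r} leaves no countries")
    sample = build_edu_sample(
        subset,
        fert,
        edu,
        horizon=spec.horizon,
        covariates=spec.covariates,
        zero_tol=spec.zero_tol,
    )
    sample = trim_outliers(sample, k=spec.trim_k)
    if spec.standardize:
        sample = standardize(sample)
    return fit_convergence(
        sample,
        fixed_effects=spec.fixed_effects,
        covariate_names=spec.covariates,
    )


def run_cell(
    panel: pd.DataFrame,
    metadata: pd.DataFrame | None,
    spec: GridSpec,
    fertility: str,
    education: str,
    subgroup: str = "all",
) -> FitResult:
    """Run a single cell, raising on failure (the grid records instead)."""
    return _run_cell(panel, metadata, spec, fertility, education, subgroup)


def _status(ordered_abs: list[float], tol: float = 1e-12) -> str:
    """'holds' if |beta| is nonincreasing along the list, 'tie' if flat."""
    if any(np.isnan(ordered_abs)):
        return "incomplete"
    if max(ordered_abs) - min(ordered_abs) <= tol:
        return "tie"
    ok = all(a >= b - tol for a, b in zip(ordered_abs, ordered_abs[1:]))
    return "holds" if ok else "violated"


def _cis_overlap(results: list[FitResult | None]) -> bool | None:
    if any(r is None for r in results):
        return None
    los = [r.ci_low for r in results]
    his = [r.ci_high for r in results]
    return max(los) <= min(his)


def gradient_summary(grid: AnalysisGrid) -> pd.DataFrame:
    """Descriptive check of the two educational gradients.

    For each fertility indicator and subgroup, reports (a) whether
    |beta_tertiary| >= |beta_secondary| >= |beta_primary| within each
    attendance mode, and (b) whether |beta_completed| >= |beta_attended|
    within each cycle level, with confidence-interval overlap flags.
    Missing cells yield 'incomplete' rows rather than gaps.  Purely
    descriptive: no new inference is performed.
    """

    def lookup(fert, edu, sub):
        try:
            cell = grid.get(fert, edu, sub)
        except KeyError:
            return None
        return cell.result

    ferts = sorted({c.fertility for c in grid.cells})
    subs = list(dict.fromkeys(c.subgroup for c in grid.cells))
    rows = []
    for fert in ferts:
        for sub in subs:
            for mode in _MODES:
                res = [
                    lookup(fert, f"{lvl}_{mode}", sub) for lvl in reversed(_LEVELS)
                ]
                betas = [abs(r.beta) if r else np.nan for r in res]
                rows.append(
                    {
                        "fertility": fert,
                        "subgroup": sub,
                        "comparison": f"threshold-ordering ({mode})",
                        "status": _status(betas),
                        "ci_overlap": _cis_overlap(res),
                        "abs_betas": betas,
                    }
                )
            for lvl in _LEVELS:
                res = [lookup(fert, f"{lvl}_{m}", sub) for m in reversed(_MODES)]
                betas = [abs(r.beta) if r else np.nan for r in res]
                rows.append(
                    {
                        "fertility": fert,
                        "subgroup": sub,
                        "comparison": f"completed-vs-attended ({lvl})",
                        "status": _status(betas),
                        "ci_overlap": _cis_overlap(res),
                        "abs_betas": betas,
                    }
                )
    return pd.DataFrame(rows)


def report(grid: AnalysisGrid, outdir, plot: bool = True) -> dict:
    """Write the grid to disk: tidy CSV, provenance JSON, optional plots.

    The CSV is deterministic for a fixed (panel, spec, seed); the timestamp
    lives only in the JSON provenance.  Plotting is best-effort and never
    fails the run.  Returns the paths written.
    """
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = grid.to_frame()
    csv_path = outdir / "grid_results.csv"
    frame.to_csv(csv_path, index=False)
    json_path = outdir / "provenance.json"
    json_path.write_text(json.dumps(grid.provenance, indent=2, default=str))
    written = {"csv": str(csv_path), "json": str(json_path), "plots": []}

    if plot:
        try:
            written["plots"] = _forest_plots(frame, outdir)
        except Exception as exc:  # plotting must never fail the run
            logger.warning("coefficient plot skipped: %s", exc)
    return written


def _forest_plots(frame: pd.DataFrame, outdir) -> list[str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    ok = frame[frame["failure"] == ""]
    if "beta" not in ok.columns or ok.empty:
        return paths
    for fert, sub in ok.groupby("fertility"):
        fig, ax = plt.subplots(figsize=(7, 0.4 * len(sub) + 1.5))
        labels = sub["education"] + " | " + sub["subgroup"]
        y = np.arange(len(sub))
        ax.errorbar(
            sub["beta"],
            y,
            xerr=[sub["beta"] - sub["ci_low"], sub["ci_high"] - sub["beta"]],
            fmt="o",
            capsize=2,
        )
        ax.axvline(0.0, color="grey", lw=0.8)
        ax.set_yticks(y, labels, fontsize=7)
        ax.set_xlabel("convergence coefficient (95% CI)")
        ax.set_title(fert)
        fig.tight_layout()
        path = str(outdir / f"coefficients_{fert}.png")
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
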