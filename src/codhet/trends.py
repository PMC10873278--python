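"""Panel computation of heterogeneity indices and ordinal association.

Applies the inequality and diversity indices across a collection of
population-year-sex profiles, optionally with Monte-Carlo uncertainty
intervals and a first-versus-last-year significance flag per series, and
exposes Kendall's tau-b for quantifying the ordinal association between the
two indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AlignmentError, CodhetError
from .metrics import CauseProfile, cod_inequality, simpson_diversity
from .taxonomy import CauseTree, dissimilarity_matrix
from .uncertainty import McConfig, difference_significance, index_uncertainty

__all__ = ["PanelResult", "compute_panel", "kendall_tau", "panel_kendall_tau"]

PANEL_COLUMNS = (
    "location",
    "sex",
    "year",
    "S",
    "S_lower",
    "S_upper",
    "I",
    "I_lower",
    "I_upper",
)


@dataclass(frozen=True)
class PanelResult:
    """Per-(location, sex, year) index values, plus optional per-series
    significance of the first-versus-last-year change."""

    table: pd.DataFrame = field(repr=False)
    significance: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        keys = ["location", "sex", "year"]
        if self.table.duplicated(keys).any():
            dup = self.table[self.table.duplicated(keys)][keys].values.tolist()
            raise CodhetError(f"duplicate panel rows for {dup!r}")


def _profile_key(profile: CauseProfile) -> tuple:
    meta = profile.meta
    return (
        str(meta.get("location", "all")),
        str(meta.get("sex", "both")),
        int(meta.get("year", 0)),
    )


def compute_panel(
    profiles: Iterable[CauseProfile],
    tree: CauseTree,
    cfg: McConfig | None = None,
) -> PanelResult:
    """Compute S and I for every profile in a panel.

    All profiles must share one cause universe alignable to ``tree``.  When
    ``cfg`` is given, each row gets 95%-style uncertainty intervals (seeds
    derived deterministically per row from ``cfg.seed``) and each
    (location, sex) series gets a first-vs-last-year significance flag for
    both indices.
    """
    profiles = list(profiles)
    if not profiles:
        raise CodhetError("empty profile collection")
    universe = profiles[0].causes
    for prof in profiles[1:]:
        if set(prof.causes) != set(universe):
            raise AlignmentError(
                "profiles have inconsistent cause sets; align them (e.g. with "
                "records_to_profiles policy='zero-fill') before computing a panel"
            )
    dmat = dissimilarity_matrix(tree, universe)

    seeds = None
    if cfg is not None:
        ss = np.random.SeedSequence(cfg.seed)
        seeds = [int(child.generate_state(1)[0]) for child in ss.spawn(2 * len(profiles))]

    rows = []
    ui_results: dict[tuple, dict[str, object]] = {}
    for i, prof in enumerate(profiles):
        prof = prof.reorder(universe)
        loc, sex, year = _profile_key(prof)
        s_res = simpson_diversity(prof)
        i_res = cod_inequality(prof, dmat)
        row = {
            "location": loc,
            "sex": sex,
            "year": year,
            "S": s_res.value,
            "S_lower": np.nan,
            "S_upper": np.nan,
            "I": i_res.value,
            "I_lower": np.nan,
            "I_upper": np.nan,
        }
        if cfg is not None:
            s_ui = index_uncertainty(prof, None, replace(cfg, seed=seeds[2 * i]))
            i_ui = index_uncertainty(prof, dmat, replace(cfg, seed=seeds[2 * i + 1]))
            row.update(
                S_lower=s_ui.lower, S_upper=s_ui.upper,
                I_lower=i_ui.lower, I_upper=i_ui.upper,
            )
            ui_results[(loc, sex, year)] = {"S": s_ui, "I": i_ui}
        rows.append(row)

    table = (
        pd.DataFrame(rows, columns=list(PANEL_COLUMNS))
        .sort_values(["location", "sex", "year"], kind="mergesort")
        .reset_index(drop=True)
    )

    significance = None
    if cfg is not None:
        sig_rows = []
        for (loc, sex), group in table.groupby(["location", "sex"], sort=False):
            years = group["year"].tolist()
            first, last = min(years), max(years)
            if first == last:
                continue
            row = {"location": loc, "sex": sex, "first_year": first, "last_year": last}
            for kind in ("S", "I"):
                res = difference_significance(
                    ui_results[(loc, sex, first)][kind],
                    ui_results[(loc, sex, last)][kind],
                    cfg,
                )
                row[f"{kind}_difference"] = res.point
                row[f"{kind}_diff_lower"] = res.lower
                row[f"{kind}_diff_upper"] = res.upper
                row[f"{kind}_significant"] = res.significant
            sig_rows.append(row)
        significance = pd.DataFrame(sig_rows)

    return PanelResult(table=table, significance=significance)


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> float:
    """Kendall's tau-b (tie-corrected) rank correlation of paired vectors.

    Returns NaN (with a warning) when either vector is constant, where the
    coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise CodhetError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise CodhetError("need at least two pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("kendall_tau undefined for a constant vector; returning NaN")
        return float("nan")
    return float(stats.kendalltau(x, y, variant="b").statistic)


def panel_kendall_tau(
    panel: PanelResult,
    year: int | None = None,
    sex: str | None = None,
    mode: str = "cross-sectional",
) -> float:
    """Ordinal association between I and S within a panel.

    ``cross-sectional`` (default): across locations in one year (the latest
    year if unspecified), optionally restricted to one sex.
    ``longitudinal``: across years, pooling all series matching the filters.
    """
    table = panel.table
    if sex is not None:
        table = table[table["sex"] == sex]
    if mode == "cross-sectional":
        year = int(table["year"].max()) if year is None else year
        table = table[table["year"] == year]
    elif mode != "longitudinal":
        raise CodhetError(f"unknown mode {mode!r}")
    if len(table) < 2:
        raise CodhetError("fewer than two panel rows after filtering")
    return kendall_tau(table["I"].to_numpy(), table["S"].to_numpy())
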