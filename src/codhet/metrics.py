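"""Mortality profiles, heterogeneity indices and cause-specific decompositions.

Thin domain-object layer over the estimators in :mod:`codhet.estimators`:
a :class:`CauseProfile` carries cause ids, shares and optional per-cause
uncertainty bounds, and the functions here align profiles with dissimilarity
matrices by cause id before delegating the arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .estimators import RENORM_TOL, CodInequality, SimpsonDiversity
from .exceptions import AlignmentError, ProfileError
from .taxonomy import CauseTree, DissimilarityMatrix

__all__ = [
    "CauseProfile",
    "HeterogeneityResult",
    "profile_from_counts",
    "cod_inequality",
    "simpson_diversity",
    "decompose",
    "aggregate_contributions",
]

DECOMPOSITION_COLUMNS = (
    "cause_id",
    "cause_name",
    "level",
    "share",
    "mean_distance",
    "contribution",
    "contribution_pct",
)


@dataclass(frozen=True)
class CauseProfile:
    """Death shares over an ordered set of mutually exclusive causes.

    ``shares`` must be non-negative and sum to 1 within 1e-6 (renormalised
    exactly on construction).  ``bounds`` is an optional (k, 2) array of
    per-cause (lower, upper) interval endpoints on the share scale with
    lower <= share <= upper.
    """

    causes: tuple[str, ...]
    shares: np.ndarray = field(repr=False)
    meta: Mapping[str, object] = field(default_factory=dict)
    bounds: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        causes = tuple(str(c) for c in self.causes)
        if len(set(causes)) != len(causes):
            dup = sorted({c for c in causes if causes.count(c) > 1})
            raise ProfileError(f"duplicate cause ids in profile: {dup!r}")
        shares = np.asarray(self.shares, dtype=float)
        if shares.ndim != 1 or shares.shape[0] != len(causes):
            raise ProfileError(
                f"shares shape {shares.shape} does not match {len(causes)} causes"
            )
        if np.any(shares < -1e-12):
            raise ProfileError("shares must be non-negative")
        shares = np.clip(shares, 0.0, None)
        total = shares.sum()
        if abs(total - 1.0) > RENORM_TOL:
            raise ProfileError(
                f"shares sum to {total:.8f}, not 1 within {RENORM_TOL}; use "
                "profile_from_counts for count data"
            )
        shares = shares / total
        object.__setattr__(self, "causes", causes)
        object.__setattr__(self, "shares", shares)
        object.__setattr__(self, "meta", dict(self.meta))
        if self.bounds is not None:
            bounds = np.asarray(self.bounds, dtype=float)
            if bounds.shape != (len(causes), 2):
                raise ProfileError(
                    f"bounds shape {bounds.shape} must be ({len(causes)}, 2)"
                )
            if np.any(bounds[:, 0] < -1e-12):
                raise ProfileError("lower bounds must be non-negative")
            # allow slack of the silent renormalisation applied to shares
            if np.any(bounds[:, 0] > shares + 1e-9) or np.any(
                bounds[:, 1] < shares - 1e-9
            ):
                raise ProfileError("bounds must satisfy lower <= share <= upper")
            object.__setattr__(self, "bounds", bounds)

    @property
    def k(self) -> int:
        return len(self.causes)

    def with_bounds(self, lower, upper) -> "CauseProfile":
        return replace(self, bounds=np.column_stack([lower, upper]))

    def reorder(self, causes: Sequence[str]) -> "CauseProfile":
        """Permute to a new cause order (same cause set)."""
        index = {c: i for i, c in enumerate(self.causes)}
        missing = [c for c in causes if c not in index]
        if missing or len(causes) != self.k:
            raise AlignmentError(f"cannot reorder: unmatched causes {missing!r}")
        perm = np.array([index[c] for c in causes])
        bounds = self.bounds[perm] if self.bounds is not None else None
        return CauseProfile(tuple(causes), self.shares[perm], self.meta, bounds)


@dataclass(frozen=True)
class HeterogeneityResult:
    """Point value of an index plus its exact cause-specific decomposition."""

    index_kind: str  # "inequality" | "diversity"
    value: float
    causes: tuple[str, ...]
    shares: np.ndarray = field(repr=False)
    per_cause_mean_distance: np.ndarray = field(repr=False)
    contributions: np.ndarray = field(repr=False)
    meta: Mapping[str, object] = field(default_factory=dict)
    ui: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0 + 1e-12:
            raise ProfileError(f"index value {self.value} outside [0, 1]")
        if abs(self.contributions.sum() - self.value) > 1e-9:
            raise ProfileError("contributions do not sum to the index value")


def profile_from_counts(
    causes: Sequence[str], deaths, meta: Mapping[str, object] | None = None
) -> CauseProfile:
    """Normalise a vector of death counts into a share profile."""
    deaths = np.asarray(deaths, dtype=float)
    if np.any(deaths < 0):
        raise ProfileError("death counts must be non-negative")
    total = deaths.sum()
    if total <= 0:
        raise ProfileError("all-zero death counts: no profile can be formed")
    return CauseProfile(tuple(causes), deaths / total, meta or {})


def _aligned_matrix(profile: CauseProfile, dmat: DissimilarityMatrix) -> np.ndarray:
    if profile.causes == dmat.causes:
        return dmat.values
    return dmat.reorder(profile.causes).values


def cod_inequality(
    profile: CauseProfile, dmat: DissimilarityMatrix
) -> HeterogeneityResult:
    """Cause-of-death inequality I = sum_ij d_ij p_i p_j with decomposition.

    ``dmat`` is aligned to the profile by cause id; a mismatch in the cause
    sets raises :class:`AlignmentError` listing the unmatched ids.
    """
    D = _aligned_matrix(profile, dmat)
    est = CodInequality(dissimilarity=D)
    X = profile.shares[None, :]
    est.fit(X)
    return HeterogeneityResult(
        index_kind="inequality",
        value=float(est.transform(X)[0, 0]),
        causes=profile.causes,
        shares=profile.shares,
        per_cause_mean_distance=est.mean_distances(X)[0],
        contributions=est.contributions(X)[0],
        meta=profile.meta,
    )


def simpson_diversity(profile: CauseProfile) -> HeterogeneityResult:
    """Simpson diversity S = 1 - sum_c p_c^2 with contributions p_c(1-p_c)."""
    est = SimpsonDiversity()
    X = profile.shares[None, :]
    est.fit(X)
    return HeterogeneityResult(
        index_kind="diversity",
        value=float(est.transform(X)[0, 0]),
        causes=profile.causes,
        shares=profile.shares,
        per_cause_mean_distance=est.mean_distances(X)[0],
        contributions=est.contributions(X)[0],
        meta=profile.meta,
    )


def decompose(
    result: HeterogeneityResult, tree: CauseTree | None = None
) -> pd.DataFrame:
    """Tabulate the cause-specific decomposition of an index.

    Rows are ordered by descending contribution with a stable tie-break on
    cause id.  ``contribution_pct`` is the percent share C_c / value; when
    the index value is 0 the percentages are undefined and reported as 0
    with ``frame.attrs['contribution_pct_defined'] = False``.
    """
    names = [tree.name(c) if tree is not None else c for c in result.causes]
    levels = [tree.node(c).level if tree is not None else np.nan for c in result.causes]
    frame = pd.DataFrame(
        {
            "cause_id": list(result.causes),
            "cause_name": names,
            "level": levels,
            "share": result.shares,
            "mean_distance": result.per_cause_mean_distance,
            "contribution": result.contributions,
        }
    )
    defined = result.value > 0
    frame["contribution_pct"] = (
        100.0 * frame["contribution"] / result.value if defined else 0.0
    )
    frame = frame.sort_values(
        ["contribution", "cause_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    frame.attrs["index_kind"] = result.index_kind
    frame.attrs["index_value"] = result.value
    frame.attrs["contribution_pct_defined"] = bool(defined)
    return frame


def aggregate_contributions(
    decomposition: pd.DataFrame, tree: CauseTree, target_level: int
) -> pd.DataFrame:
    """Sum per-cause contributions into their ancestor groups at a level.

    ``target_level == tree.depth`` is the identity.  Group totals conserve
    the index value at every level.
    """
    if not 1 <= target_level <= tree.depth:
        raise AlignmentError(
            f"target_level must be in [1, {tree.depth}], got {target_level}"
        )
    if target_level == tree.depth:
        return decomposition.copy()
    frame = decomposition.copy()
    frame["group_id"] = [
        tree.ancestor_at(c, target_level) for c in frame["cause_id"]
    ]
    grouped = (
        frame.groupby("group_id", sort=False)
        .agg(
            share=("share", "sum"),
            contribution=("contribution", "sum"),
            contribution_pct=("contribution_pct", "sum"),
        )
        .reset_index()
    )
    grouped.insert(1, "group_name", [tree.name(g) for g in grouped["group_id"]])
    grouped.insert(2, "level", target_level)
    grouped = grouped.sort_values(
        ["contribution", "group_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    grouped.attrs.update(decomposition.attrs)
    return grouped
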