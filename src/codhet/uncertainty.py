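"""Monte-Carlo uncertainty intervals for heterogeneity indices.

GBD-style inputs report a 95% interval (lower, upper) around each cause's
share.  To propagate these into an interval for I or S, each cause is
sampled independently from a distribution calibrated so that its central
``ci_level`` mass spans (lower, upper), the draw is clamped at 0 and
renormalised onto the simplex, and the index is evaluated on every draw;
the reported interval is the pair of central percentiles of those index
values.  Cross-cause correlations are not modelled (the results-tool
extracts do not publish them) — a documented limitation.

Three per-cause sampling families are available:

``truncated-normal`` (default)
    Normal(share, sd) truncated at 0, sd = (upper - lower) / (2 z), with z
    the standard-normal quantile at (1 + ci_level)/2.  Handles the nearly
    symmetric intervals typical of large-count causes.
``scaled-beta``
    Beta on [0, 1] matched to mean = share and the same sd by moments;
    respects the unit interval without truncation.
``dirichlet-calibrated``
    A single Dirichlet over all causes with total concentration chosen from
    the median per-cause moment match; the only family with built-in
    negative cross-cause dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import CodhetError, ProfileError
from .metrics import CauseProfile
from .taxonomy import DissimilarityMatrix

__all__ = [
    "McConfig",
    "UncertaintyResult",
    "DifferenceResult",
    "sample_shares",
    "sample_profiles",
    "index_uncertainty",
    "difference_significance",
]

FAMILIES = ("truncated-normal", "scaled-beta", "dirichlet-calibrated")


@dataclass(frozen=True)
class McConfig:
    """Monte-Carlo settings for uncertainty propagation."""

    n_draws: int = 1000
    seed: int | None = None
    family: str = "truncated-normal"
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_draws < 2:
            raise CodhetError(f"n_draws must be >= 2, got {self.n_draws}")
        if not 0 < self.ci_level < 1:
            raise CodhetError(f"ci_level must be in (0, 1), got {self.ci_level}")
        if self.family not in FAMILIES:
            raise CodhetError(
                f"unknown sampling family {self.family!r}; choose from {FAMILIES}"
            )


@dataclass(frozen=True)
class UncertaintyResult:
    """Plug-in index value with a percentile interval over MC draws.

    ``lower <= point <= upper`` is not guaranteed: percentile intervals of
    renormalised draws can exclude the plug-in point in extreme cases.
    """

    index_kind: str
    point: float
    lower: float
    upper: float
    draws: np.ndarray = field(repr=False)
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.lower > self.upper + 1e-12:
            raise CodhetError("interval lower endpoint exceeds upper endpoint")


@dataclass(frozen=True)
class DifferenceResult:
    """Interval on the difference (b - a) of two index distributions."""

    point: float
    lower: float
    upper: float
    significant: bool
    marginal_intervals_disjoint: bool


def _target_sds(profile: CauseProfile, ci_level: float) -> np.ndarray:
    if profile.bounds is None:
        raise ProfileError(
            "profile has no per-cause bounds; supply degenerate bounds "
            "(lower = share = upper) for causes known exactly"
        )
    z = stats.norm.ppf(0.5 + ci_level / 2)
    return (profile.bounds[:, 1] - profile.bounds[:, 0]) / (2 * z)


def sample_shares(profile: CauseProfile, cfg: McConfig) -> np.ndarray:
    """Draw an (n_draws, k) matrix of renormalised share vectors.

    Fully reproducible from ``cfg.seed``; every row sums to 1 exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    p = profile.shares
    sd = _target_sds(profile, cfg.ci_level)
    k = profile.k
    exact = sd <= 0
    if cfg.family == "truncated-normal":
        draws = np.tile(p, (cfg.n_draws, 1))
        if not exact.all():
            loc, scale = p[~exact], sd[~exact]
            a = (0.0 - loc) / scale  # truncate at zero
            draws[:, ~exact] = stats.truncnorm.rvs(
                a, np.inf, loc=loc, scale=scale,
                size=(cfg.n_draws, int((~exact).sum())), random_state=rng,
            )
    elif cfg.family == "scaled-beta":
        draws = np.tile(p, (cfg.n_draws, 1))
        idx = np.flatnonzero(~exact & (p > 0) & (p < 1))
        if idx.size:
            m = p[idx]
            # moment match; cap sd below the Bernoulli limit sqrt(m(1-m))
            var = np.minimum(sd[idx], 0.999 * np.sqrt(m * (1 - m))) ** 2
            nu = m * (1 - m) / var - 1.0
            draws[:, idx] = rng.beta(m * nu, (1 - m) * nu, size=(cfg.n_draws, idx.size))
    else:  # dirichlet-calibrated
        if exact.all():
            draws = np.tile(p, (cfg.n_draws, 1))
        else:
            m, s = p[~exact], sd[~exact]
            with np.errstate(divide="ignore"):
                nu = m * (1 - m) / s**2 - 1.0
            nu = nu[np.isfinite(nu) & (nu > 0)]
            alpha0 = float(np.median(nu)) if nu.size else 1.0
            alpha = np.maximum(p * alpha0, 1e-10)
            draws = rng.dirichlet(alpha, size=cfg.n_draws)
    draws = np.clip(draws, 0.0, None)
    totals = draws.sum(axis=1)
    if np.any(totals <= 0):
        bad = totals <= 0  # all-zero draw: fall back to the point profile
        draws[bad] = p
        totals[bad] = 1.0
    return draws / totals[:, None]


def sample_profiles(profile: CauseProfile, cfg: McConfig) -> list[CauseProfile]:
    """Materialise draws as :class:`CauseProfile` objects (convenience)."""
    return [
        CauseProfile(profile.causes, row, profile.meta)
        for row in sample_shares(profile, cfg)
    ]


def _index_values(draws: np.ndarray, dmat: DissimilarityMatrix | None) -> np.ndarray:
    if dmat is None:
        return 1.0 - np.einsum("ni,ni->n", draws, draws)
    D = dmat.values
    return np.einsum("ni,ij,nj->n", draws, D, draws)


def index_uncertainty(
    profile: CauseProfile,
    dmat: DissimilarityMatrix | None,
    cfg: McConfig,
) -> UncertaintyResult:
    """Percentile uncertainty interval for I (``dmat`` given) or S (None).

    The point estimate is the plug-in value on the (renormalised) point
    shares; the interval spans the central ``cfg.ci_level`` percentiles of
    the index over share draws.
    """
    aligned = dmat.reorder(profile.causes) if dmat is not None else None
    draws = sample_shares(profile, cfg)
    values = _index_values(draws, aligned)
    point = float(_index_values(profile.shares[None, :], aligned)[0])
    alpha = (1.0 - cfg.ci_level) / 2
    lower, upper = np.quantile(values, [alpha, 1.0 - alpha])
    return UncertaintyResult(
        index_kind="diversity" if dmat is None else "inequality",
        point=point,
        lower=float(lower),
        upper=float(upper),
        draws=values,
        ci_level=cfg.ci_level,
    )


def difference_significance(
    result_a: UncertaintyResult,
    result_b: UncertaintyResult,
    cfg: McConfig | None = None,
) -> DifferenceResult:
    """Flag whether two index distributions differ at the interval level.

    Differences are paired by draw index (b - a, independent draws); the
    change is flagged significant when the central ``ci_level`` interval of
    the differences excludes 0.  The more conservative disjoint-marginal-
    intervals criterion is reported alongside.
    """
    if len(result_a.draws) != len(result_b.draws):
        raise CodhetError(
            f"draw counts differ: {len(result_a.draws)} vs {len(result_b.draws)}"
        )
    ci_level = cfg.ci_level if cfg is not None else result_a.ci_level
    diffs = result_b.draws - result_a.draws
    alpha = (1.0 - ci_level) / 2
    lower, upper = np.quantile(diffs, [alpha, 1.0 - alpha])
    significant = bool(lower > 0.0 or upper < 0.0)
    disjoint = bool(
        result_a.upper < result_b.lower or result_b.upper < result_a.lower
    )
    return DifferenceResult(
        point=result_b.point - result_a.point,
        lower=float(lower),
        upper=float(upper),
        significant=significant,
        marginal_intervals_disjoint=disjoint,
    )
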