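"""Additive partitioning of net biodiversity effects.

For a mixture of ``N`` species with observed per-species biomass ``Y_i`` and
monoculture biomass ``M_i``, the net biodiversity effect is the observed
community biomass minus its expectation under no interaction:

    NE = sum(Y) - mean(M)

and splits exactly into two additive components,

    CE = N * mean(dRY) * mean(M)        (complementarity effect)
    SE = N * cov(dRY, M)                (selection effect)

where ``dRY_i = Y_i / M_i - 1/N`` is the deviation of the observed relative
yield from the sown expectation and the covariance is the population form
(denominator ``N``) — the only convention under which NE = CE + SE holds as
an identity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "MixtureYield",
    "EffectPartition",
    "partition",
    "partition_all",
    "mixture_yields_from_tables",
    "partition_frame",
    "test_overall_mean",
    "OverallMeanTest",
]

logger = logging.getLogger(__name__)


@dataclass
class MixtureYield:
    """Observed mixture yields plus matched monoculture yields for one plot."""

    plot_id: str
    species_ids: list[str]
    Y: np.ndarray  # per-species biomass in mixture, g m^-2
    M: np.ndarray  # per-species monoculture biomass, g m^-2

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        n = len(self.species_ids)
        if self.Y.shape != (n,) or self.M.shape != (n,):
            raise ValueError(f"plot {self.plot_id}: Y/M length mismatch with species")
        if n < 2:
            raise ValueError(f"plot {self.plot_id}: partitioning requires N >= 2")
        if np.any(~np.isfinite(self.M)) or np.any(self.M <= 0):
            bad = [s for s, m in zip(self.species_ids, self.M) if not (m > 0)]
            raise ValueError(
                f"plot {self.plot_id}: non-positive or missing monoculture "
                f"biomass for species {bad}"
            )
        if np.any(self.Y < 0):
            raise ValueError(f"plot {self.plot_id}: negative mixture biomass")

    @property
    def N(self) -> int:
        return len(self.species_ids)


@dataclass
class EffectPartition:
    """Net effect and its complementarity/selection components for one plot."""

    plot_id: str
    NE: float
    CE: float
    SE: float
    delta_RY: np.ndarray = field(repr=False)


def partition(mix: MixtureYield) -> EffectPartition:
    """Partition one mixture's net biodiversity effect into CE + SE."""
    N = mix.N
    dRY = mix.Y / mix.M - 1.0 / N
    mean_M = float(mix.M.mean())
    NE = float(mix.Y.sum() - mean_M)
    CE = float(N * dRY.mean() * mean_M)
    # population covariance (denominator N): the additive convention
    cov = float(np.mean(dRY * mix.M) - dRY.mean() * mean_M)
    SE = float(N * cov)
    return EffectPartition(plot_id=mix.plot_id, NE=NE, CE=CE, SE=SE, delta_RY=dRY)


def partition_all(mixtures: Iterable[MixtureYield]) -> list[EffectPartition]:
    """Partition every mixture, skipping (and logging) invalid ones.

    Mixtures are usually constructed via :class:`MixtureYield`, whose
    validation raises eagerly; this wrapper additionally accepts raw
    ``(plot_id, species_ids, Y, M)`` tuples so that a batch containing e.g. a
    species without monoculture biomass yields the valid partitions plus a
    logged exclusion rather than a hard failure.
    """
    out: list[EffectPartition] = []
    seen: set[str] = set()
    for item in mixtures:
        if isinstance(item, MixtureYield):
            mix = item
        else:
            plot_id = item[0]
            try:
                mix = MixtureYield(*item)
            except ValueError as err:
                logger.warning("excluding plot %s from partitioning: %s", plot_id, err)
                continue
        if mix.plot_id in seen:
            raise ValueError(f"duplicate plot id {mix.plot_id!r}")
        seen.add(mix.plot_id)
        out.append(partition(mix))
    return out


def mixture_yields_from_tables(
    mixture_table: pd.DataFrame,
    monoculture_table: pd.DataFrame,
    min_richness: int = 2,
) -> list[tuple]:
    """Pair mixture rows with averaged monoculture biomass per plot.

    ``mixture_table`` is long format (plot_id, species_id, biomass) listing
    every sown species (zero-biomass species included); replicate
    monocultures are averaged per species.  Returns raw tuples suitable for
    :func:`partition_all`, so plots containing a species without monoculture
    data become logged exclusions rather than hard errors.
    """
    mono = monoculture_table.groupby("species_id")["biomass"].mean()
    out: list[tuple] = []
    for plot_id, sub in mixture_table.groupby("plot_id", sort=False):
        species = [str(s) for s in sub["species_id"]]
        if len(species) < min_richness:
            continue
        Y = sub["biomass"].to_numpy(dtype=float)
        M = mono.reindex(species).to_numpy(dtype=float)
        out.append((str(plot_id), species, Y, M))
    return out


def partition_frame(effects: Sequence[EffectPartition]) -> pd.DataFrame:
    """Per-plot partition results as a tidy table."""
    return pd.DataFrame(
        {
            "plot_id": [e.plot_id for e in effects],
            "NE": [e.NE for e in effects],
            "CE": [e.CE for e in effects],
            "SE": [e.SE for e in effects],
        }
    )


class OverallMeanTest(NamedTuple):
    F: float
    df: tuple[int, int]
    p_value: float


def test_overall_mean(
    effects: Sequence[float] | np.ndarray,
    block: Sequence[str],
    covariate: Sequence[float] | np.ndarray | None = None,
) -> OverallMeanTest:
    """Test whether the mean effect differs from zero, adjusting for block.

    Fits ``effect ~ intercept + block`` by least squares with sum-to-zero
    block coding (so the intercept is the across-block mean) and returns the
    F test of the intercept.  An optional continuous covariate — in the
    experimental design, log sown species richness — can be included; with 66
    mixtures, 4 blocks and the richness covariate the denominator df is 61.
    """
    y = np.asarray(effects, dtype=float)
    blocks = pd.Categorical(list(block))
    n = len(y)
    if len(blocks) != n:
        raise ValueError("effects and block labels differ in length")
    levels = list(blocks.categories)
    b = len(levels)
    if b < 2:
        raise ValueError("test_overall_mean requires >= 2 blocks")
    if n < 3:
        raise ValueError("test_overall_mean requires >= 3 mixtures")
    counts = pd.Series(blocks).value_counts()
    singletons = [lv for lv in levels if counts.get(lv, 0) == 1]
    if singletons:
        warnings.warn(
            f"block(s) with a single observation: {singletons}; "
            "test computed anyway",
            stacklevel=2,
        )

    # sum-to-zero (effect) coding: columns for the first b-1 levels,
    # the last level coded -1 everywhere
    codes = np.asarray(blocks.codes)
    X = np.zeros((n, b - 1))
    for j in range(b - 1):
        X[codes == j, j] = 1.0
    X[codes == b - 1, :] = -1.0
    cols = [f"block_{levels[j]}" for j in range(b - 1)]
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)
        if cov.shape != (n,):
            raise ValueError("covariate length mismatch")
        X = np.column_stack([X, cov - cov.mean()])
        cols = cols + ["covariate"]
    design = pd.DataFrame(np.column_stack([np.ones(n), X]), columns=["intercept"] + cols)
    fit = sm.OLS(y, design).fit()
    t = fit.tvalues["intercept"]
    F = float(t * t)
    df = (1, int(fit.df_resid))
    p = float(fit.pvalues["intercept"])
    if not np.isfinite(F):  # degenerate zero-variance case (e.g. effects all 0)
        F, p = 0.0, 1.0
    return OverallMeanTest(F=F, df=df, p_value=p)
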