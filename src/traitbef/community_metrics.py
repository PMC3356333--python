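"""Community-level trait metrics: weighted means and Rao quadratic diversity.

For a community of ``S`` species with biomass proportions ``p_i`` and trait
values ``t_i``:

* the community-weighted mean is ``CWM = sum_i p_i t_i`` — the trait value of
  the dominants (mass-ratio perspective);
* Rao's quadratic diversity for one standardized trait ``z`` is the full
  double sum ``FD_Q = sum_i sum_j p_i p_j d_ij`` with ``d_ij = (z_i - z_j)^2``
  and ``d_ii = 0`` — the expected squared trait distance between two random
  draws from the community, zero in monoculture.

With squared-Euclidean distances the multi-trait quantity is additive over
traits: ``FD_Q(w) = sum_k w_k FD_Q(trait k)``, which is what lets per-trait
weights be estimated as relative importances downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .trait_data import TraitTable

__all__ = [
    "CommunityComposition",
    "PredictorMatrix",
    "cwm",
    "rao_q_single",
    "rao_q_weighted",
    "build_predictor_matrix",
    "compositions_from_table",
]


@dataclass
class CommunityComposition:
    """Per-plot species relative abundances derived from observed biomass."""

    plot_id: str
    species_ids: list[str]
    biomass: np.ndarray
    p: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.biomass = np.asarray(self.biomass, dtype=float)
        if len(self.species_ids) != len(self.biomass):
            raise ValueError(f"plot {self.plot_id}: species/biomass length mismatch")
        if np.any(self.biomass < 0):
            raise ValueError(f"plot {self.plot_id}: negative biomass")
        total = self.biomass.sum()
        if total > 0:
            self.p = self.biomass / total
        else:
            self.p = np.zeros_like(self.biomass)

    @property
    def total_biomass(self) -> float:
        return float(self.biomass.sum())


def _trait_vector(
    composition: CommunityComposition,
    trait_values: Mapping[str, float] | pd.Series | Sequence[float] | np.ndarray,
) -> np.ndarray:
    """Align trait values to the composition's species order."""
    if isinstance(trait_values, (pd.Series, Mapping)):
        series = pd.Series(trait_values)
        missing = [s for s in composition.species_ids if s not in series.index]
        if missing:
            raise ValueError(
                f"plot {composition.plot_id}: species without trait value: {missing}"
            )
        return series.reindex(composition.species_ids).to_numpy(dtype=float)
    arr = np.asarray(trait_values, dtype=float)
    if arr.shape != (len(composition.species_ids),):
        raise ValueError(
            f"plot {composition.plot_id}: trait vector length {arr.shape} does "
            f"not match {len(composition.species_ids)} species"
        )
    return arr


def cwm(
    composition: CommunityComposition,
    trait_values: Mapping[str, float] | pd.Series | Sequence[float] | np.ndarray,
) -> float:
    """Community-weighted mean ``sum_i p_i t_i`` of one trait."""
    t = _trait_vector(composition, trait_values)
    if np.any(~np.isfinite(t)):
        raise ValueError(f"plot {composition.plot_id}: non-finite trait value")
    return float(composition.p @ t)


def rao_q_single(
    composition: CommunityComposition,
    trait_values: Mapping[str, float] | pd.Series | Sequence[float] | np.ndarray,
    *,
    standardized: bool = True,
) -> float:
    """Rao quadratic diversity of one standardized trait.

    Full double sum over ordered pairs with squared differences as distances.
    Computed via the algebraic identity
    ``sum_ij p_i p_j (z_i - z_j)^2 = 2 (E_p[z^2] - E_p[z]^2)``,
    i.e. twice the abundance-weighted trait variance.  The ``standardized``
    flag is the caller's declaration that the trait column went through
    :func:`~traitbef.trait_data.standardize_traits`; passing ``False`` raises.
    """
    if not standardized:
        raise ValueError("rao_q_single requires standardized trait values")
    z = _trait_vector(composition, trait_values)
    p = composition.p
    mean = p @ z
    q = 2.0 * float(p @ (z * z) - mean * mean)
    return max(q, 0.0)  # clip the rounding of an exactly-zero case


def rao_q_weighted(
    composition: CommunityComposition,
    table: TraitTable,
    weights: Mapping[str, float] | Sequence[float] | np.ndarray,
) -> float:
    """Weighted multi-trait Rao diversity ``sum_k w_k FD_Q(trait k)``.

    Equivalent (by additivity of squared-Euclidean distances) to a single
    evaluation with the multi-trait distance
    ``d_ij = sum_k w_k (z_ik - z_jk)^2``.
    """
    if not table.standardized:
        raise ValueError("rao_q_weighted requires a standardized trait table")
    if isinstance(weights, Mapping):
        w = np.array([float(weights.get(a, 0.0)) for a in table.trait_abbrevs])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(table.trait_abbrevs),):
            raise ValueError("weight vector length does not match trait count")
    if np.any(w < 0):
        bad = [a for a, wi in zip(table.trait_abbrevs, w) if wi < 0]
        raise ValueError(f"negative weight for trait(s): {bad}")
    total = 0.0
    for abbrev, wi in zip(table.trait_abbrevs, w):
        if wi == 0.0:
            continue
        z = table.values[abbrev]
        total += wi * rao_q_single(composition, z, standardized=True)
    return total


@dataclass
class PredictorMatrix:
    """Per-plot CWM and single-trait FD_Q candidate predictors.

    ``cwm`` holds community-weighted means on transformed (interpretable-unit)
    trait values; ``fd`` holds single-trait Rao diversities on standardized
    values, so the FD block is non-negative and exactly zero in monoculture.
    """

    plot_ids: list[str]
    cwm: pd.DataFrame
    fd: pd.DataFrame
    trait_abbrevs: list[str]
    excluded_plots: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.fd.to_numpy() < -1e-12).any():
            raise ValueError("FD_Q entries must be non-negative")

    @property
    def n_plots(self) -> int:
        return len(self.plot_ids)

    def to_frame(self) -> pd.DataFrame:
        """Combined matrix with columns ``cwm_<abbrev>`` then ``fd_<abbrev>``."""
        cwm_part = self.cwm.add_prefix("cwm_")
        fd_part = self.fd.add_prefix("fd_")
        out = pd.concat([cwm_part, fd_part], axis=1)
        out.index.name = "plot_id"
        return out


def build_predictor_matrix(
    compositions: Iterable[CommunityComposition],
    table: TraitTable,
) -> PredictorMatrix:
    """Assemble the plot x (CWM + FD_Q) candidate-predictor matrix.

    ``table`` must be transformed; CWM uses its values as given while FD_Q
    always uses a standardized copy.  Plots with zero total biomass carry no
    abundance information and are excluded (recorded in ``excluded_plots``).
    """
    from .trait_data import standardize_traits

    if not table.transformed:
        raise ValueError("build_predictor_matrix requires a transformed trait table")
    std = table if table.standardized else standardize_traits(table)

    abbrevs = table.trait_abbrevs
    plot_ids: list[str] = []
    excluded: list[str] = []
    cwm_rows: list[list[float]] = []
    fd_rows: list[list[float]] = []
    seen: set[str] = set()
    for comp in compositions:
        if comp.plot_id in seen:
            raise ValueError(f"duplicate plot id {comp.plot_id!r}")
        seen.add(comp.plot_id)
        if comp.total_biomass <= 0:
            excluded.append(comp.plot_id)
            continue
        missing = [s for s in comp.species_ids if s not in table.values.index]
        if missing:
            raise ValueError(
                f"plot {comp.plot_id}: species without trait data: {missing}"
            )
        raw = table.values.loc[comp.species_ids]
        zstd = std.values.loc[comp.species_ids]
        p = comp.p
        cwm_rows.append(list(p @ raw.to_numpy()))
        zmat = zstd.to_numpy()
        mean = p @ zmat
        fd = 2.0 * (p @ (zmat * zmat) - mean * mean)
        fd_rows.append(list(np.maximum(fd, 0.0)))
        plot_ids.append(comp.plot_id)

    cwm_df = pd.DataFrame(cwm_rows, index=plot_ids, columns=abbrevs)
    fd_df = pd.DataFrame(fd_rows, index=plot_ids, columns=abbrevs)
    return PredictorMatrix(
        plot_ids=plot_ids,
        cwm=cwm_df,
        fd=fd_df,
        trait_abbrevs=list(abbrevs),
        excluded_plots=excluded,
    )


def compositions_from_table(biomass_table: pd.DataFrame) -> list[CommunityComposition]:
    """Build per-plot compositions from a long plot x species biomass table.

    Expects columns ``plot_id``, ``species_id``, ``biomass``; rows of one
    plot become one composition in first-appearance plot order.
    """
    required = {"plot_id", "species_id", "biomass"}
    missing = required - set(biomass_table.columns)
    if missing:
        raise ValueError(f"biomass table missing column(s): {sorted(missing)}")
    out: list[CommunityComposition] = []
    for plot_id, sub in biomass_table.groupby("plot_id", sort=False):
        out.append(
            CommunityComposition(
                plot_id=str(plot_id),
                species_ids=[str(s) for s in sub["species_id"]],
                biomass=sub["biomass"].to_numpy(dtype=float),
            )
        )
    return out
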