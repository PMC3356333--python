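"""Synthetic grassland biodiversity-experiment data with known ground truth.

Emulates the design of a large grassland biodiversity experiment: a pool of
60 species in four functional groups (16 grasses, 12 small herbs, 20 tall
herbs, 12 legumes), 82 large plots spanning sown richness 1, 2, 4, 8, 16 and
60 in four blocks (16 plots per richness level, except 14 at richness 16 —
pure small-herb and pure legume mixtures are infeasible there — and 4 plots
of the full pool), plus two small monocultures per species.

Traits come from a two-latent-axis factor model: axis 1 is a "nutrient
economy" spectrum (legumes: high leaf N, low shoot biomass:N, low foliar
d15N, long flowering; grasses at the opposite end), axis 2 a plant
size/rooting-depth spectrum (tall herbs large, small herbs small).  Ordinal
traits are discretized onto their declared level sets by empirical quantile
cuts, so every level is realized.

Biomass comes from a known ground-truth model: log-normal monoculture
yields, mixture community biomass linear in standardized community-weighted
means and single-trait Rao diversities of the planted traits plus Gaussian
noise, disaggregated to species by a dominance rule (share proportional to
monoculture biomass raised to a configurable exponent).  A null mode sets
every species' mixture yield to exactly its expectation M/N, which zeroes
all biodiversity effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .trait_data import (
    FUNCTIONAL_GROUPS,
    TraitMeta,
    TraitTable,
    standardize_traits,
    transform_traits,
)

__all__ = [
    "SpeciesPool",
    "DesignPlan",
    "PlotRecord",
    "GroundTruth",
    "SimulatedDataset",
    "default_truth",
    "generate_pool_and_traits",
    "generate_design",
    "generate_biomass",
    "simulate_dataset",
    "design_frame",
    "monoculture_means",
]

GROUP_SIZES = {"grass": 16, "small_herb": 12, "tall_herb": 20, "legume": 12}

# latent group positions: axis 1 nutrient economy, axis 2 size/rooting
_GROUP_AXIS1 = {"legume": 1.5, "grass": -1.5, "small_herb": 0.0, "tall_herb": 0.0}
_GROUP_AXIS2 = {"tall_herb": 1.2, "grass": 0.3, "small_herb": -1.5, "legume": 0.0}
_AXIS_NOISE_SD = 0.7

# (name, abbrev, kind, log?, source, levels, axis1 loading, axis2 loading,
#  location, scale) — location/scale are median/sdlog for log-flagged traits,
#  mean/sd otherwise; ordinal traits use quantile cuts instead.
_TRAIT_DEFS: list[tuple] = [
    ("shoot length", "l.shoot", "continuous", True, "measurement", None, 0.00, 0.60, 45.0, 0.45),
    ("leaf distribution", "vert.leaf", "ordinal", False, "literature", (0, 1, 2), 0.00, 0.55, (0.35, 0.70), None),
    ("stem mass fraction", "SMF", "continuous", False, "measurement", None, -0.25, 0.45, 0.45, 0.12),
    ("specific leaf area", "SLA", "continuous", False, "measurement", None, 0.30, -0.25, 22.0, 6.0),
    ("foliar d13C", "d13C", "continuous", False, "measurement", None, 0.15, 0.10, -28.0, 1.5),
    ("leaf nitrogen concentration", "N.leaf", "continuous", True, "measurement", None, 0.60, 0.00, 22.0, 0.30),
    ("biomass:N ratio", "biom:N", "continuous", False, "measurement", None, -0.60, 0.10, 80.0, 25.0),
    ("foliar d15N", "d15N", "continuous", True, "measurement", None, -0.55, 0.00, 2.0, 2.0),
    ("depth of the root system", "root.depth", "ordinal", False, "literature", (1, 2, 3, 4, 5), 0.00, 0.55, (0.15, 0.40, 0.70, 0.90), None),
    ("type of the root system", "root.type", "ordinal", False, "literature", (1, 2, 3), -0.50, 0.00, (0.30, 0.60), None),
    ("life cycle", "life", "ordinal", False, "literature", (1, 2, 3), 0.25, 0.15, (0.10, 0.30), None),
    ("clonal growth", "clonal", "binary", False, "literature", (0, 1), -0.45, 0.00, (0.45,), None),
    ("seasonality of foliage", "l.rhythm", "ordinal", False, "literature", (1, 2, 3), -0.40, 0.00, (0.30, 0.70), None),
    ("start of flowering period", "flower.st", "ordinal", False, "literature", (1, 2, 3, 4), -0.15, 0.35, (0.20, 0.50, 0.80), None),
    ("duration of flowering period", "flower.dur", "ordinal", False, "literature", (1, 2, 3, 4), 0.50, -0.15, (0.25, 0.55, 0.85), None),
    ("inflorescence mass fraction", "IMF", "continuous", True, "measurement", None, -0.40, 0.10, 0.10, 0.50),
    ("seed mass", "m.seed", "continuous", True, "measurement", None, 0.10, 0.55, 1.2, 0.90),
    ("seedling number", "#seed", "continuous", True, "measurement", None, -0.10, -0.50, 400.0, 0.70),
]


@dataclass
class SpeciesPool:
    """The experimental species pool with its functional-group assignment."""

    species_ids: list[str]
    groups: pd.Series

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def group_members(self, group: str) -> list[str]:
        return [s for s in self.species_ids if self.groups[s] == group]


@dataclass
class DesignPlan:
    """Plot counts per richness level, block structure, pool, seed."""

    richness_levels: tuple[int, ...] = (1, 2, 4, 8, 16, 60)
    plots_per_level: dict[int, int] = field(
        default_factory=lambda: {1: 16, 2: 16, 4: 16, 8: 16, 16: 16, 60: 4}
    )
    n_blocks: int = 4
    pool: SpeciesPool | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for r in self.richness_levels:
            if r not in self.plots_per_level:
                raise ValueError(f"no plot count for richness level {r}")


@dataclass(frozen=True)
class PlotRecord:
    plot_id: str
    block: int
    richness: int
    n_groups: int
    groups: tuple[str, ...]
    species: tuple[str, ...]


@dataclass
class GroundTruth:
    """The planted data-generating model for mixture biomass.

    Coefficients are per-standard-deviation effects (g m^-2) on standardized
    CWM / FD_Q predictor columns; FD coefficients must share one sign.  With
    ``noise_sd`` unset, the residual standard deviation is calibrated so the
    planted model explains ``target_r2`` of the community-biomass variance.
    """

    cwm_effects: dict[str, float]
    fd_effects: dict[str, float]
    intercept: float = 600.0
    noise_sd: float | None = None
    target_r2: float = 0.8
    dominance_exponent: float = 1.0
    mode: Literal["model", "null"] = "model"
    mono_log_mean: float = 5.85  # log g m^-2, about 350 g m^-2 median
    mono_log_sd: float = 0.30
    replicate_log_sd: float = 0.15
    missing_monoculture: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        signs = {np.sign(v) for v in self.fd_effects.values() if v != 0}
        if len(signs) > 1:
            raise ValueError("FD coefficients must share one sign")

    @property
    def fd_sign(self) -> int:
        for v in self.fd_effects.values():
            if v != 0:
                return int(np.sign(v))
        return 0


def default_truth() -> GroundTruth:
    """Ground truth with several CWM traits plus one positive-sign FD trait.

    The planted CWM set mirrors the structure of the community-biomass model
    of the study system: tall shoots, rosette leaf distribution, high leaf N,
    low foliar d15N, perennial life cycle, summer-green foliage and few
    seedlings raise biomass; diversity in foliar d15N adds a positive FD
    effect.  Effects are equal-magnitude per SD so no planted trait is
    privileged a priori.
    """
    return GroundTruth(
        cwm_effects={
            "l.shoot": 40.0,
            "vert.leaf": -40.0,
            "N.leaf": 40.0,
            "d15N": -40.0,
            "life": 40.0,
            "l.rhythm": -40.0,
            "#seed": -40.0,
        },
        fd_effects={"d15N": 40.0},
    )


# ---------------------------------------------------------------------------
# species pool and traits
# ---------------------------------------------------------------------------


def _discretize(latent: np.ndarray, levels: tuple, cuts: tuple) -> np.ndarray:
    """Map a latent vector onto ordered levels by empirical quantile cuts."""
    edges = np.quantile(latent, cuts)
    codes = np.searchsorted(edges, latent, side="right")
    return np.asarray(levels, dtype=float)[codes]


def generate_pool_and_traits(seed: int) -> tuple[SpeciesPool, TraitTable]:
    """Generate the 60-species pool and its raw (untransformed) trait table.

    Deterministic given the seed.  Group-level structure is planted through
    the two latent axes, e.g. legume mean leaf N exceeds grass mean leaf N,
    and a standardized PCA of the table separates legumes from grasses on
    its first axis.
    """
    rng = np.random.default_rng(seed)
    prefix = {"grass": "gra", "small_herb": "shb", "tall_herb": "thb", "legume": "leg"}
    species_ids = [
        f"{prefix[g]}_{i + 1:02d}"
        for g in FUNCTIONAL_GROUPS
        for i in range(GROUP_SIZES[g])
    ]
    group_list = [g for g in FUNCTIONAL_GROUPS for _ in range(GROUP_SIZES[g])]
    groups = pd.Series(group_list, index=species_ids, name="group")

    n = len(species_ids)
    ax1 = np.array([_GROUP_AXIS1[g] for g in group_list]) + rng.normal(
        0, _AXIS_NOISE_SD, n
    )
    ax2 = np.array([_GROUP_AXIS2[g] for g in group_list]) + rng.normal(
        0, _AXIS_NOISE_SD, n
    )

    values: dict[str, np.ndarray] = {}
    meta: list[TraitMeta] = []
    for (name, abbrev, kind, logf, source, levels, a1, a2, loc, scale) in _TRAIT_DEFS:
        unique = max(0.2, 1.0 - a1 * a1 - a2 * a2)
        latent = a1 * ax1 + a2 * ax2 + rng.normal(0, np.sqrt(unique), n)
        if kind in ("ordinal", "binary"):
            values[abbrev] = _discretize(latent, levels, loc)
        elif logf:
            values[abbrev] = (
                np.exp(np.log(loc) + scale * latent)
                if abbrev != "d15N"
                else loc + scale * latent  # d15N stays linear: can be <= 0
            )
        else:
            values[abbrev] = loc + scale * latent
        meta.append(
            TraitMeta(
                name=name,
                abbreviation=abbrev,
                value_kind=kind,
                log_transform=logf,
                source=source,
                levels=tuple(float(v) for v in levels) if levels else None,
            )
        )

    table = TraitTable(
        species_ids=species_ids,
        groups=groups,
        values=pd.DataFrame(values, index=species_ids),
        meta=meta,
    )
    return SpeciesPool(species_ids=species_ids, groups=groups), table


# ---------------------------------------------------------------------------
# experimental design
# ---------------------------------------------------------------------------


def _feasible_combos(groups: Sequence[str], g: int, richness: int) -> list[tuple[str, ...]]:
    from itertools import combinations

    return [
        combo
        for combo in combinations(groups, g)
        if sum(GROUP_SIZES[gr] for gr in combo) >= richness
    ]


def generate_design(plan: DesignPlan) -> list[PlotRecord]:
    """Generate the plot list: richness, functional-group mix, species draw.

    Functional-group number cycles within each richness level (near-orthogonal
    crossing), group combinations cycle within each (level, group-number)
    cell, and species are drawn at random from the chosen groups with a
    near-even split.  Combinations whose pooled group sizes cannot supply the
    richness — pure small-herb or pure legume 16-species mixtures — are
    skipped, which is what makes the default plan total 82 plots rather than
    84.  Blocks are assigned cyclically within each level.
    """
    if plan.pool is None:
        pool, _ = generate_pool_and_traits(plan.seed)
    else:
        pool = plan.pool
    rng = np.random.default_rng(plan.seed)
    from itertools import combinations

    records: list[PlotRecord] = []
    plot_no = 0
    for richness in plan.richness_levels:
        n_plots = plan.plots_per_level[richness]
        allowed_g = [
            g
            for g in range(1, min(4, richness) + 1)
            if _feasible_combos(FUNCTIONAL_GROUPS, g, richness)
        ]
        combo_cycle = {
            g: list(combinations(FUNCTIONAL_GROUPS, g)) for g in allowed_g
        }
        combo_pos = {g: 0 for g in allowed_g}
        level_records: list[PlotRecord] = []
        for slot in range(n_plots):
            g = allowed_g[slot % len(allowed_g)]
            combo = combo_cycle[g][combo_pos[g] % len(combo_cycle[g])]
            combo_pos[g] += 1
            if sum(GROUP_SIZES[gr] for gr in combo) < richness:
                continue  # infeasible cell: plot dropped, as in the design
            species = _draw_species(pool, combo, richness, rng)
            plot_no += 1
            level_records.append(
                PlotRecord(
                    plot_id=f"P{plot_no:03d}",
                    block=0,  # assigned below
                    richness=richness,
                    n_groups=g,
                    groups=combo,
                    species=tuple(species),
                )
            )
        for i, rec in enumerate(level_records):
            records.append(
                PlotRecord(
                    plot_id=rec.plot_id,
                    block=(i % plan.n_blocks) + 1,
                    richness=rec.richness,
                    n_groups=rec.n_groups,
                    groups=rec.groups,
                    species=rec.species,
                )
            )
    return records


def _draw_species(
    pool: SpeciesPool,
    combo: tuple[str, ...],
    richness: int,
    rng: np.random.Generator,
) -> list[str]:
    """Near-even split of the richness across chosen groups, random draw."""
    g = len(combo)
    counts = {gr: richness // g for gr in combo}
    spare = richness - sum(counts.values())
    order = list(combo)
    rng.shuffle(order)
    for gr in order:
        if spare == 0:
            break
        if counts[gr] < GROUP_SIZES[gr]:
            counts[gr] += 1
            spare -= 1
    # cap at group size, pushing overflow to groups with room
    for gr in combo:
        over = counts[gr] - GROUP_SIZES[gr]
        if over > 0:
            counts[gr] = GROUP_SIZES[gr]
            for other in combo:
                room = GROUP_SIZES[other] - counts[other]
                take = min(room, over)
                counts[other] += take
                over -= take
                if over == 0:
                    break
            if over > 0:
                raise ValueError(f"cannot place {richness} species in {combo}")
    species: list[str] = []
    for gr in combo:
        members = pool.group_members(gr)
        pick = rng.choice(len(members), size=counts[gr], replace=False)
        species.extend(members[i] for i in sorted(pick))
    return species


def design_frame(design: Sequence[PlotRecord]) -> pd.DataFrame:
    """The plot design as a tidy table (species list ';'-joined)."""
    return pd.DataFrame(
        {
            "plot_id": [r.plot_id for r in design],
            "block": [r.block for r in design],
            "richness": [r.richness for r in design],
            "n_groups": [r.n_groups for r in design],
            "species": [";".join(r.species) for r in design],
        }
    )


# ---------------------------------------------------------------------------
# biomass
# ---------------------------------------------------------------------------

_BIOMASS_FLOOR = 30.0  # g m^-2: truncation floor for extreme noise draws


def generate_biomass(
    pool: SpeciesPool,
    traits: TraitTable,
    design: Sequence[PlotRecord],
    truth: GroundTruth,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate monoculture and plot x species biomass tables.

    Returns ``(monoculture, mixture)``: the monoculture table has one row per
    species and replicate (two small monocultures each); the mixture table
    has one row per plot and sown species.  Community biomass of a mixture
    follows the planted linear model in standardized CWM / FD predictors of
    the planted traits; per-species shares follow the dominance rule.
    """
    rng = np.random.default_rng(seed)
    table = traits if traits.transformed else transform_traits(traits)
    std = standardize_traits(table) if not table.standardized else table

    # species-level monoculture potential, log-normal
    z_shoot = std.values["l.shoot"].to_numpy()
    z_nleaf = std.values["N.leaf"].to_numpy()
    log_m = (
        truth.mono_log_mean
        + 0.35 * z_shoot
        + 0.20 * z_nleaf
        + rng.normal(0, truth.mono_log_sd, pool.n_species)
    )
    M = pd.Series(np.exp(log_m), index=pool.species_ids)

    mono_rows = []
    for sp in pool.species_ids:
        if sp in truth.missing_monoculture:
            continue
        for rep in (1, 2):
            # null mode needs exact no-interaction bookkeeping: the averaged
            # monoculture must equal the M used for the mixture yields
            noise = 0.0 if truth.mode == "null" else rng.normal(0, truth.replicate_log_sd)
            mono_rows.append(
                {
                    "species_id": sp,
                    "replicate": rep,
                    "biomass": float(M[sp] * np.exp(noise)),
                }
            )
    mono_df = pd.DataFrame(mono_rows)

    mixtures = [r for r in design if r.richness >= 2]
    mono_plots = [r for r in design if r.richness == 1]

    # plot-level shares by the dominance rule
    shares: dict[str, np.ndarray] = {}
    for rec in mixtures:
        m = M[list(rec.species)].to_numpy()
        w = m**truth.dominance_exponent
        shares[rec.plot_id] = w / w.sum()

    # expected community biomass from the planted model, on standardized
    # predictor columns computed across the mixtures
    expected = np.full(len(mixtures), truth.intercept)
    if truth.mode == "model" and (truth.cwm_effects or truth.fd_effects):
        cols = []
        coefs = []
        for abbrev, coef in truth.cwm_effects.items():
            z = std.values[abbrev]
            vals = np.array(
                [float(shares[r.plot_id] @ z[list(r.species)].to_numpy()) for r in mixtures]
            )
            cols.append(vals)
            coefs.append(coef)
        for abbrev, coef in truth.fd_effects.items():
            z = std.values[abbrev]
            vals = []
            for r in mixtures:
                zv = z[list(r.species)].to_numpy()
                p = shares[r.plot_id]
                mean = p @ zv
                vals.append(2.0 * float(p @ (zv * zv) - mean * mean))
            cols.append(np.array(vals))
            coefs.append(coef)
        for vals, coef in zip(cols, coefs):
            sd = vals.std(ddof=1)
            zcol = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)
            expected = expected + coef * zcol

    if truth.mode == "null":
        noise_sd = 0.0
    elif truth.noise_sd is not None:
        noise_sd = truth.noise_sd
    else:
        sig_sd = float(expected.std(ddof=1))
        r2 = truth.target_r2
        noise_sd = sig_sd * np.sqrt((1.0 - r2) / r2) if sig_sd > 0 else 1.0

    mix_rows = []
    for j, rec in enumerate(mixtures):
        if truth.mode == "null":
            y = M[list(rec.species)].to_numpy() / rec.richness
        else:
            total = expected[j] + rng.normal(0, noise_sd)
            if total <= _BIOMASS_FLOOR:
                warnings.warn(
                    f"plot {rec.plot_id}: expected biomass {total:.1f} below "
                    f"floor; truncated to {_BIOMASS_FLOOR}",
                    stacklevel=2,
                )
                total = _BIOMASS_FLOOR
            y = shares[rec.plot_id] * total
        for sp, yi in zip(rec.species, y):
            mix_rows.append({"plot_id": rec.plot_id, "species_id": sp, "biomass": float(yi)})
    for rec in mono_plots:
        sp = rec.species[0]
        if truth.mode == "null":
            yi = float(M[sp])
        else:
            yi = float(M[sp] * np.exp(rng.normal(0, truth.replicate_log_sd)))
        mix_rows.append({"plot_id": rec.plot_id, "species_id": sp, "biomass": yi})
    mixture_df = pd.DataFrame(mix_rows)
    return mono_df, mixture_df


def monoculture_means(mono_df: pd.DataFrame) -> pd.Series:
    """Average the replicate monocultures per species."""
    return mono_df.groupby("species_id")["biomass"].mean()


# ---------------------------------------------------------------------------
# one-call scenarios
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    pool: SpeciesPool
    traits: TraitTable  # raw (untransformed) table, as a loader would return
    design: list[PlotRecord]
    monoculture: pd.DataFrame
    mixture: pd.DataFrame
    truth: GroundTruth


SCENARIOS = ("default", "null", "cwm-only", "fd-only", "pathological")


def simulate_dataset(seed: int, scenario: str = "default") -> SimulatedDataset:
    """Generate a complete dataset for one scenario.

    ``default``: the full planted model; ``null``: no-interaction yields
    (all biodiversity effects exactly zero); ``cwm-only`` / ``fd-only``: one
    predictor block only; ``pathological``: injects species with missing
    monocultures and a zero-biomass mixture entry to exercise error paths.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    pool, traits = generate_pool_and_traits(seed)
    plan = DesignPlan(pool=pool, seed=seed)
    design = generate_design(plan)

    truth = default_truth()
    if scenario == "null":
        truth.mode = "null"
    elif scenario == "cwm-only":
        truth.fd_effects = {}
    elif scenario == "fd-only":
        truth.cwm_effects = {}
    elif scenario == "pathological":
        truth.missing_monoculture = tuple(pool.species_ids[:3])

    mono_df, mixture_df = generate_biomass(pool, traits, design, truth, seed + 1)
    if scenario == "pathological":
        # a sown species recorded at zero biomass in one mixture
        first_mix = next(r for r in design if r.richness >= 2)
        mask = (mixture_df["plot_id"] == first_mix.plot_id) & (
            mixture_df["species_id"] == first_mix.species[0]
        )
        mixture_df.loc[mask, "biomass"] = 0.0
    return SimulatedDataset(
        pool=pool,
        traits=traits,
        design=design,
        monoculture=mono_df,
        mixture=mixture_df,
        truth=truth,
    )
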