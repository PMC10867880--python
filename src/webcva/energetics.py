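"""Energy-flux estimation: densities, biomasses, metabolic demands, and
per-link interaction strengths.

The model follows the food-web energetics approach: each consumer's total
energy influx F_j is set by a steady-state balance

    ē_j · F_j = X_j + Σ_k W[j, k] · F_k

where X_j is the consumer's metabolic demand, W[i, j] is the fraction of
consumer j's intake taken from resource i (here: biomass-proportional over
its resources), ē_j = Σ_i e_i W[i, j] is its diet-weighted assimilation
efficiency, and the sum on the right is the flux lost to j's own consumers.
Per-link fluxes are f_ij = W[i, j] F_j, and the interaction strength of a
link is its share of the consumer's intake, s_ij = f_ij / F_j — which under
biomass-proportional preferences equals W itself. Cascade results therefore
depend on biomasses only through the diet fractions, not on the metabolic
constants.

Densities come from the allometric size–density relationship D = a·M^b with
b ≈ −0.75 (individuals/km², mass in g); vertebrate biomass is B = M·D.
Aggregated nodes (invertebrate orders) take surveyed/imputed biomasses as
direct overrides, and plant nodes share a single aboveground biomass pool,
obtainable from winter precipitation via a log-log production regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from webcva.core import FoodWeb, Group, MetabolicType

__all__ = [
    "AllometryParams",
    "PlantProductionParams",
    "MetabolicParams",
    "EfficiencyParams",
    "FluxResult",
    "allometric_density",
    "plant_aboveground_production",
    "compute_traits",
    "diet_preferences",
    "metabolic_demands",
    "solve_fluxes",
    "interaction_strengths",
    "read_traits",
    "write_traits",
    "write_strengths",
]


class EnergeticsError(ValueError):
    pass


@dataclass(frozen=True)
class AllometryParams:
    """Size–density power law: log10 D = log10_intercept + exponent·log10 M.

    ``log10_intercept`` is log10 density (individuals/km²) at M = 1 g.
    The exponent must be negative (density falls with body size).
    """

    log10_intercept: float = 4.23
    exponent: float = -0.75

    def __post_init__(self) -> None:
        if self.exponent >= 0:
            raise ValueError("SDR exponent must be negative")


def allometric_density(mass_g, params: AllometryParams = AllometryParams()):
    """Population density (individuals/km²) from body mass (g).

    D = 10^(intercept + exponent·log10 M); strictly decreasing in M.
    """
    mass = np.asarray(mass_g, dtype=float)
    if np.any(mass <= 0):
        raise EnergeticsError("body mass must be positive")
    out = 10.0 ** (params.log10_intercept + params.exponent * np.log10(mass))
    return float(out) if np.isscalar(mass_g) else out


@dataclass(frozen=True)
class PlantProductionParams:
    """Aboveground net production regression on Sept–March precipitation.

    Parsed as log10(ANP g/m²) = slope·log10(precip − precip_offset_mm)
    + log10_intercept. Undefined at or below the precipitation offset.
    """

    slope: float = 1.976
    precip_offset_mm: float = 26.2
    log10_intercept: float = -2.746


def plant_aboveground_production(
    precip_sept_march_mm: float,
    params: PlantProductionParams = PlantProductionParams(),
) -> float:
    """Aboveground net production (g/m²) from winter-season precipitation (mm)."""
    if precip_sept_march_mm <= params.precip_offset_mm:
        raise EnergeticsError(
            f"production model undefined for precipitation ≤ "
            f"{params.precip_offset_mm} mm (got {precip_sept_march_mm})"
        )
    return float(
        10.0
        ** (
            params.slope * np.log10(precip_sept_march_mm - params.precip_offset_mm)
            + params.log10_intercept
        )
    )


@dataclass(frozen=True)
class MetabolicParams:
    """Per-individual metabolic rate x0·M^a by metabolic type; plants are 0.

    The normalization constants are editable configuration, not a claim
    about any particular laboratory regression; downstream diet fractions
    are independent of them.
    """

    coefficients: Mapping[MetabolicType, tuple[float, float]] = field(
        default_factory=lambda: {
            MetabolicType.vertebrate_endotherm: (38.8, 0.71),
            MetabolicType.vertebrate_ectotherm: (3.9, 0.71),
            MetabolicType.invertebrate: (1.8, 0.71),
            MetabolicType.plant: (0.0, 0.0),
        }
    )

    def rate(self, mass_g: float, mtype: MetabolicType) -> float:
        x0, a = self.coefficients[MetabolicType(mtype)]
        if x0 == 0.0:
            return 0.0
        return float(x0 * mass_g**a)


@dataclass(frozen=True)
class EfficiencyParams:
    """Assimilation efficiency by resource category (0 < e ≤ 1)."""

    plant: float = 0.545
    animal: float = 0.906

    def __post_init__(self) -> None:
        for v in (self.plant, self.animal):
            if not (0 < v <= 1):
                raise ValueError("efficiencies must lie in (0, 1]")

    def of_resource(self, group: Group) -> float:
        return self.plant if Group(group) is Group.plant else self.animal


TRAIT_COLUMNS = [
    "mass_g",
    "density_per_km2",
    "biomass_g_per_km2",
    "biomass_ci_low",
    "biomass_ci_high",
]


def compute_traits(
    web: FoodWeb,
    masses: Mapping[str, float],
    *,
    allometry: AllometryParams = AllometryParams(),
    plant_biomass_g_per_km2: float | None = None,
    biomass_overrides: Mapping[str, float] | None = None,
    biomass_ci: Mapping[str, tuple[float, float]] | None = None,
    plant_split: str = "equal",
) -> pd.DataFrame:
    """Per-node traits: mass, density, biomass (+ optional biomass CI).

    Vertebrate (and any non-overridden, non-plant) nodes get density from
    the size–density relationship and biomass B = M·D. Nodes named in
    ``biomass_overrides`` (typically aggregated invertebrate orders) keep
    the supplied biomass regardless of mass. Plant nodes share
    ``plant_biomass_g_per_km2`` — one aggregated pool split equally across
    plant nodes (``plant_split='equal'``) or assigned whole to each
    (``'pooled'``).
    """
    overrides = dict(biomass_overrides or {})
    cis = dict(biomass_ci or {})
    plant_ids = web.group_members(Group.plant)
    rows: dict[str, dict[str, float]] = {}
    missing: list[str] = []
    for i, node in web.nodes.items():
        mass = masses.get(i, np.nan)
        density = np.nan
        if i in overrides:
            biomass = float(overrides[i])
            if not np.isnan(mass) and mass > 0:
                density = biomass / mass
        elif node.group is Group.plant:
            if plant_biomass_g_per_km2 is None:
                raise EnergeticsError(
                    "plant nodes present but no plant biomass supplied"
                )
            biomass = (
                plant_biomass_g_per_km2 / len(plant_ids)
                if plant_split == "equal"
                else plant_biomass_g_per_km2
            )
        else:
            if np.isnan(mass) or mass <= 0:
                missing.append(i)
                continue
            density = allometric_density(mass, allometry)
            biomass = mass * density
        if biomass <= 0:
            raise EnergeticsError(f"non-positive biomass for node {i!r}")
        lo, hi = cis.get(i, (np.nan, np.nan))
        if not np.isnan(lo) and not (lo <= biomass <= hi):
            raise EnergeticsError(
                f"biomass CI ({lo}, {hi}) does not bracket biomass of node {i!r}"
            )
        rows[i] = {
            "mass_g": mass,
            "density_per_km2": density,
            "biomass_g_per_km2": biomass,
            "biomass_ci_low": lo,
            "biomass_ci_high": hi,
        }
    if missing:
        raise EnergeticsError(
            "mass missing (and no biomass override) for node(s): "
            + ", ".join(sorted(missing))
        )
    return pd.DataFrame.from_dict(rows, orient="index").loc[web.ids, TRAIT_COLUMNS]


def diet_preferences(web: FoodWeb, traits: pd.DataFrame) -> pd.DataFrame:
    """Biomass-proportional diet preference matrix W.

    ``W.loc[i, j]`` is the fraction of consumer j's intake taken from
    resource i: B_i / Σ_{i' ∈ resources(j)} B_{i'}. Columns of consumers sum
    to 1; basal columns are all zero. Scale-invariant in the biomasses.
    """
    ids = web.ids
    b = traits["biomass_g_per_km2"]
    missing = [i for i in ids if web.consumers_of(i) and i not in b.index]
    if missing:
        raise EnergeticsError(f"biomass missing for consumed node(s): {missing}")
    w = pd.DataFrame(0.0, index=ids, columns=ids)
    for j in ids:
        res = sorted(web.resources_of(j))
        if not res:
            continue
        bv = b.loc[res].to_numpy(dtype=float)
        tot = bv.sum()
        if tot <= 0:
            raise EnergeticsError(
                f"consumer {j!r}: all resources have zero biomass"
            )
        w.loc[res, j] = bv / tot
    return w


def metabolic_demands(
    web: FoodWeb,
    traits: pd.DataFrame,
    params: MetabolicParams = MetabolicParams(),
) -> pd.Series:
    """Population-level metabolic demand X_j = per-individual rate × density.

    For nodes carrying a biomass override without an allometric density, the
    density is taken as B/M (requires a representative mass). Plants are 0.
    """
    out = {}
    for i, node in web.nodes.items():
        if node.metabolic_type is MetabolicType.plant:
            out[i] = 0.0
            continue
        mass = traits.loc[i, "mass_g"]
        density = traits.loc[i, "density_per_km2"]
        if np.isnan(density):
            raise EnergeticsError(
                f"node {i!r}: density unavailable for metabolic demand "
                "(supply a representative mass alongside the biomass override)"
            )
        out[i] = params.rate(float(mass), node.metabolic_type) * float(density)
    return pd.Series(out).loc[web.ids]


@dataclass
class FluxResult:
    """Solved energy fluxes.

    Attributes
    ----------
    order : node ids in matrix order.
    W : diet preference matrix (resources × consumers), columns sum to 1
        for consumers.
    F : per-consumer total influx (0 for basal nodes).
    fluxes : per-link flux matrix, ``fluxes[i, j] = W[i, j] * F[j]``.
    demands, ebar : the X and diet-weighted efficiency vectors used.
    """

    order: list[str]
    W: pd.DataFrame
    F: pd.Series
    fluxes: pd.DataFrame
    demands: pd.Series
    ebar: pd.Series

    def balance_residuals(self) -> pd.Series:
        """|ē_j F_j − X_j − Σ_k W[j,k] F_k| / max(1, X_j), consumers only."""
        loss = self.W.to_numpy() @ self.F.to_numpy()
        lhs = self.ebar.to_numpy() * self.F.to_numpy()
        rhs = self.demands.to_numpy() + loss
        rel = np.abs(lhs - rhs) / np.maximum(1.0, self.demands.to_numpy())
        consumers = self.W.sum(axis=0).to_numpy() > 0
        return pd.Series(rel, index=self.order)[consumers]


def solve_fluxes(
    web: FoodWeb,
    W: pd.DataFrame,
    demands: pd.Series,
    efficiencies: EfficiencyParams = EfficiencyParams(),
) -> FluxResult:
    """Solve the steady-state energy-flux balance for all consumers.

    Assimilated influx of each consumer equals its metabolic demand plus the
    flux it loses to its own consumers; basal nodes have zero influx. Raises
    on a singular system or on any negative flux, naming offending nodes.
    """
    ids = web.ids
    wm = W.loc[ids, ids].to_numpy(dtype=float)
    x = demands.loc[ids].to_numpy(dtype=float)
    e_res = np.array(
        [efficiencies.of_resource(web.group_of(i)) for i in ids], dtype=float
    )
    ebar = e_res @ wm  # ē_j = Σ_i e_i W[i, j]
    is_consumer = wm.sum(axis=0) > 0
    n = len(ids)
    f = np.zeros(n)
    cidx = np.nonzero(is_consumer)[0]
    if cidx.size:
        # (diag(ē) − U) F = X over consumers; U[j, k] = W[j, k]
        m = np.diag(ebar[cidx]) - wm[np.ix_(cidx, cidx)]
        try:
            fc = np.linalg.solve(m, x[cidx])
        except np.linalg.LinAlgError:
            raise EnergeticsError(
                "flux balance system is singular; check diet preferences and "
                "efficiencies"
            ) from None
        neg = [ids[cidx[k]] for k in np.nonzero(fc < -1e-9)[0]]
        if neg:
            raise EnergeticsError(f"negative flux for node(s): {neg}")
        f[cidx] = np.maximum(fc, 0.0)
    fluxes = wm * f[np.newaxis, :]
    return FluxResult(
        order=list(ids),
        W=pd.DataFrame(wm, index=ids, columns=ids),
        F=pd.Series(f, index=ids),
        fluxes=pd.DataFrame(fluxes, index=ids, columns=ids),
        demands=pd.Series(x, index=ids),
        ebar=pd.Series(ebar, index=ids),
    )


def interaction_strengths(flux: FluxResult) -> pd.DataFrame:
    """Per-link interaction strengths s_ij = f_ij / F_j.

    Returned as a (resources × consumers) DataFrame whose columns are the
    consumers only; each column sums to 1. Basal nodes have no column. A
    consumer with links but zero total influx is an error.
    """
    w = flux.W
    has_prey = w.sum(axis=0) > 0
    consumers = [j for j in flux.order if has_prey[j]]
    bad = [j for j in consumers if flux.F[j] <= 0]
    if bad:
        raise EnergeticsError(
            f"consumer(s) with prey but zero influx: {bad}; strengths undefined"
        )
    s = flux.fluxes.loc[:, consumers].div(flux.F[consumers], axis=1)
    return s


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------


def read_traits(path) -> pd.DataFrame:
    """Read a traits CSV (columns ``id`` + :data:`TRAIT_COLUMNS` subset)."""
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise ValueError("traits table must have an 'id' column")
    df = df.set_index("id")
    for col in TRAIT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[TRAIT_COLUMNS]


def write_traits(traits: pd.DataFrame, path) -> None:
    traits.rename_axis("id").to_csv(path)


def write_strengths(strengths: pd.DataFrame, path) -> None:
    """Write per-link strengths as tidy CSV (consumer, resource, strength)."""
    rows = []
    for j in strengths.columns:
        col = strengths[j]
        for i in col.index[col.to_numpy() > 0]:
            rows.append({"consumer": j, "resource": i, "strength": col[i]})
    pd.DataFrame(rows, columns=["consumer", "resource", "strength"]).to_csv(
        path, index=False
    )
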