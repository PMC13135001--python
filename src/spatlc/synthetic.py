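"""Synthetic graphs, ground-truth parameters and Poisson count datasets.

The generator emulates the structure of province-level mortality
registers: Poisson death counts over (age, year, province) with
province-varying exposures spanning orders of magnitude, a realistic age
profile (high infant mortality, a young-adult accident hump, a
log-linear Gompertz rise at older ages), a near-linear declining time
index, spatially autocorrelated province effects that vary by 10-year
age group, and an optional shift of the spatial field between two
calendar periods.  Provinces sit on a planar lattice with an optional
detached island component, nested in contiguous region blocks.

The default configuration is the desk-scale study condition used
throughout the test-suite and the acceptance experiments: 20 provinces
in 4 regions, single ages 0-50, 10 calendar years, and cell exposures
derived from province population scales between 1e3 and 1e5
person-years.  All draws are deterministic functions of
``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data_io import (
    AgeGrouping,
    MortalityDataset,
    PeriodMapping,
    ValidationError,
    default_age_grouping,
    make_period_mapping,
)
from .model_core import ModelSpec, ParameterState, PriorSettings, linear_predictor
from .spatial_graph import AdjacencyGraph, besag_basis, scaled_besag

__all__ = ["SimConfig", "generate_graph", "region_assignment", "generate_truth",
           "generate_dataset", "simulate"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic replicate.  ``seed`` is mandatory.

    ``period_shift`` controls how the spatial field changes between the
    two periods when ``cutpoint_year`` is set: the period-2 raw fields
    are ``c * period-1 + sqrt(1 - c^2) * fresh`` with ``c = 1 -
    period_shift``, so 0 leaves the field identical, 1 makes it
    independent, and 2 flips its sign, always preserving the variance.
    """

    seed: int
    n_provinces: int = 20
    n_regions: int = 4
    n_island_provinces: int = 2
    max_age: int = 50
    year_start: int = 2010
    n_years: int = 10
    cutpoint_year: int | None = None
    exposure_range: tuple[float, float] = (1e3, 1e5)
    # truth hyperparameters
    sigma_omega: float = 0.15
    phi: float = 0.6
    sigma_r: float = 0.1
    sigma_z: float = 0.03
    sigma_kappa: float = 0.05
    kappa_decline: float = 7.6
    period_shift: float = 0.0
    # age-profile shape (rates per person-year)
    infant_rate: float = 4e-3
    infant_decay: float = 1.0
    hump_rate: float = 2e-4
    hump_age: float = 22.0
    hump_width: float = 8.0
    gompertz_rate: float = 2e-5
    gompertz_slope: float = 0.095

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("a seed is mandatory")
        if min(self.n_provinces, self.n_regions, self.n_years) < 1 or self.max_age < 0:
            raise ValidationError("all sizes must be >= 1")
        if not (0.0 <= self.phi <= 1.0):
            raise ValidationError("phi must lie in [0, 1]")
        for name in ("sigma_omega", "sigma_r", "sigma_z", "sigma_kappa"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_island_provinces >= self.n_provinces:
            raise ValidationError("island must be smaller than the whole graph")

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_start + self.n_years)

    def age_grouping(self) -> AgeGrouping:
        return default_age_grouping(self.max_age)

    def period_mapping(self) -> PeriodMapping:
        return make_period_mapping(self.years, self.cutpoint_year)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generator stage
    return np.random.default_rng([int(config.seed), stream])


# ---------------------------------------------------------------------------
# graph and regions


def generate_graph(config: SimConfig) -> AdjacencyGraph:
    """Planar lattice over the mainland provinces plus an optional island path.

    The mainland is a near-square grid with rook adjacency; the last
    ``n_island_provinces`` nodes form a detached path component,
    mimicking islands that make the national graph disconnected.
    """
    n = config.n_provinces
    n_isl = config.n_island_provinces
    n_main = n - n_isl
    ncol = int(np.ceil(np.sqrt(n_main)))
    nbrs: dict[int, set[int]] = {i: set() for i in range(1, n + 1)}
    for k in range(n_main):
        r, c = divmod(k, ncol)
        for dr, dc in ((0, 1), (1, 0)):
            rr, cc = r + dr, c + dc
            k2 = rr * ncol + cc
            if cc < ncol and k2 < n_main:
                nbrs[k + 1].add(k2 + 1)
                nbrs[k2 + 1].add(k + 1)
    for k in range(n_main, n - 1):
        nbrs[k + 1].add(k + 2)
        nbrs[k + 2].add(k + 1)
    return AdjacencyGraph(n, {i: frozenset(s) for i, s in nbrs.items()})


def region_assignment(config: SimConfig) -> dict[int, int]:
    """Contiguous blocks of provinces -> regions 1..n_regions (partition)."""
    n, R = config.n_provinces, config.n_regions
    return {p: (p - 1) * R // n + 1 for p in range(1, n + 1)}


# ---------------------------------------------------------------------------
# ground truth


def _age_profile(config: SimConfig) -> np.ndarray:
    x = np.arange(config.max_age + 1, dtype=float)
    rate = (
        config.infant_rate * np.exp(-config.infant_decay * x)
        + config.hump_rate * np.exp(-0.5 * ((x - config.hump_age) / config.hump_width) ** 2)
        + config.gompertz_rate * np.exp(config.gompertz_slope * x)
    )
    return np.log(rate)


def generate_truth(config: SimConfig, graph: AdjacencyGraph, grouping: AgeGrouping,
                   periods: PeriodMapping) -> ParameterState:
    """Draw a constrained ground-truth ParameterState.

    ``beta`` sums to one, ``kappa`` is centred, and the BYM2 raw fields
    are centred within every non-singleton graph component, so the
    returned state is a fixed point of the constraint projection.
    """
    rng = _rng(config, 0)
    A = config.max_age + 1
    T = len(periods.years)
    S = graph.n_nodes
    G = grouping.n_groups
    P = periods.n_periods

    alpha = _age_profile(config)
    beta = 0.35 + np.exp(-np.arange(A) / 25.0)
    beta = beta / beta.sum()

    lin = -config.kappa_decline * (np.arange(T) - (T - 1) / 2.0) / max(T - 1, 1)
    eps = rng.normal(0.0, config.sigma_kappa, size=max(T - 2, 0))
    kappa = lin.copy()
    if T > 2:
        kappa[2:] += np.cumsum(np.cumsum(eps))
    kappa -= kappa.mean()

    structure = scaled_besag(graph)
    B = besag_basis(structure)                 # (S, m)
    m = B.shape[1]

    def draw_pair():
        v1 = rng.normal(size=(S, G))
        u1 = np.einsum("sm,mg->sg", B, rng.normal(size=(m, G)))
        return v1, u1

    v1, u1 = draw_pair()
    v = np.empty((S, G, P))
    u = np.empty((S, G, P))
    v[:, :, 0], u[:, :, 0] = v1, u1
    if P == 2:
        c = 1.0 - config.period_shift
        if not (-1.0 <= c <= 1.0):
            raise ValidationError("period_shift must lie in [0, 2]")
        v2f, u2f = draw_pair()
        v[:, :, 1] = c * v1 + np.sqrt(1.0 - c * c) * v2f
        u[:, :, 1] = c * u1 + np.sqrt(1.0 - c * c) * u2f
    for comp in structure.components:          # centre v like the projection does
        if len(comp) > 1:
            sidx = np.array(comp) - 1
            v[sidx] -= v[sidx].mean(axis=0)

    n_regions = len(set(region_assignment(config).values()))
    u_region = rng.normal(0.0, config.sigma_r, size=n_regions) if config.sigma_r > 0 \
        else np.zeros(n_regions)
    z = rng.normal(0.0, config.sigma_z, size=(A, T, S)) if config.sigma_z > 0 \
        else np.zeros((A, T, S))

    return ParameterState(
        alpha=alpha, beta=beta, kappa=kappa, v=v, u=u,
        sigma_omega=config.sigma_omega, phi=config.phi,
        u_region=u_region, sigma_r=config.sigma_r,
        z=z, sigma_z=config.sigma_z, sigma_kappa=config.sigma_kappa,
    )


# ---------------------------------------------------------------------------
# counts


def generate_dataset(truth: ParameterState, config: SimConfig,
                     graph: AdjacencyGraph) -> MortalityDataset:
    """Poisson(E exp(eta)) death counts with log-uniform province exposure scales."""
    rng = _rng(config, 1)
    grouping = config.age_grouping()
    periods = config.period_mapping()
    region_of = region_assignment(config)
    regions = sorted(set(region_of.values()))
    lookup = {r: i for i, r in enumerate(regions)}
    region_idx = np.array([lookup[region_of[p]] for p in range(1, graph.n_nodes + 1)])

    A = config.max_age + 1
    T = config.n_years
    S = graph.n_nodes
    lo, hi = config.exposure_range
    scale = np.exp(rng.uniform(np.log(lo), np.log(hi), size=S))
    pyramid = np.exp(-np.arange(A) / 100.0)
    pyramid = pyramid / pyramid.mean()
    exposures = np.broadcast_to(pyramid[:, None, None] * scale[None, None, :], (A, T, S)).copy()

    eta = linear_predictor(truth, grouping, periods, region_idx)
    mu = exposures * np.exp(eta)
    if np.any(mu > 1e12):
        idx = np.argwhere(mu > 1e12)[0]
        raise ValidationError(f"expected count overflow at (age,year,province) index {tuple(idx)}")
    deaths = rng.poisson(mu)

    return MortalityDataset(
        deaths=deaths, exposures=exposures,
        age_values=np.arange(A), year_values=np.array(list(config.years)),
        province_ids=np.arange(1, S + 1), region_of=region_of, sex="all",
    )


def simulate(config: SimConfig, priors: PriorSettings | None = None):
    """Full generative pipeline: (graph, spec, truth, dataset)."""
    graph = generate_graph(config)
    grouping = config.age_grouping()
    periods = config.period_mapping()
    truth = generate_truth(config, graph, grouping, periods)
    dataset = generate_dataset(truth, config, graph)
    spec = ModelSpec.from_dataset(dataset, graph, cutpoint=config.cutpoint_year, priors=priors)
    return graph, spec, truth, dataset
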