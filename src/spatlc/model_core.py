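"""Densities and deterministic mappings of the spatial Lee-Carter model.

The observation model is ``Y_xts | lambda_xts ~ Poisson(E_xts lambda_xts)``
with log rates

    log lambda_xts = alpha_x + beta_x kappa_t + omega_{s, g_x[, p_t]}
                     + u_{r_s} + z_xts

where ``alpha`` is the age profile, ``kappa`` a second-order random-walk
time index with ``beta`` its age-specific loading, ``omega`` an
age-group-specific BYM2 province effect (optionally split into two
calendar periods), ``u_r`` an iid Gaussian region effect and ``z`` an iid
Gaussian cell-level overdispersion term.  The BYM2 effect mixes an
unstructured and a scaled-Besag structured component,

    omega = sigma_omega * (sqrt(1 - phi) * v + sqrt(phi) * u),

so ``phi`` is the proportion of the marginal variance carried by spatial
structure.  Hyperparameter priors are penalized-complexity: exponential
on each standard deviation, and the KLD-distance exponential for ``phi``.

Everything here is a pure function of a ``ParameterState``; the sampler
in :mod:`spatlc.inference` and the generator in :mod:`spatlc.synthetic`
both consume these definitions, which keeps the model, its simulation
and its inference consistent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

from .data_io import AgeGrouping, PeriodMapping, ValidationError, default_age_grouping, make_period_mapping
from .spatial_graph import AdjacencyGraph, ScaledStructure, scaled_besag

__all__ = [
    "ParameterState",
    "PriorSettings",
    "ModelSpec",
    "bym2_effect",
    "linear_predictor",
    "poisson_loglik",
    "rw2_logdensity",
    "calibrate_pc_sigma",
    "pc_sigma_logpdf",
    "phi_distance",
    "calibrate_pc_phi",
    "pc_phi_cdf",
    "pc_phi_logpdf",
    "apply_constraints",
    "joint_logdensity",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class ParameterState:
    """One complete realization of all model parameters.

    Used both as a posterior draw and as synthetic ground truth.  ``v``
    and ``u`` are the unstructured / structured BYM2 components on the
    standard (unit-variance) scale, shape ``(S, G, P)``; ``z`` and
    ``u_region`` are on their natural scale.
    """

    alpha: np.ndarray          # (A,)
    beta: np.ndarray           # (A,)
    kappa: np.ndarray          # (T,)
    v: np.ndarray              # (S, G, P) unstructured, standard scale
    u: np.ndarray              # (S, G, P) structured (scaled Besag), standard scale
    sigma_omega: float
    phi: float
    u_region: np.ndarray       # (R,)
    sigma_r: float
    z: np.ndarray              # (A, T, S)
    sigma_z: float
    sigma_kappa: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "kappa", "v", "u", "u_region", "z"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.v.shape != self.u.shape:
            raise ValidationError("v and u must share shape (S, G, P)")
        if self.z.shape != (len(self.alpha), len(self.kappa), self.v.shape[0]):
            raise ValidationError(
                f"z shape {self.z.shape} inconsistent with (A,T,S)="
                f"{(len(self.alpha), len(self.kappa), self.v.shape[0])}"
            )
        if not (0.0 <= self.phi <= 1.0):
            raise ValidationError(f"phi must lie in [0, 1], got {self.phi}")
        for name in ("sigma_omega", "sigma_r", "sigma_z", "sigma_kappa"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    def omega(self) -> np.ndarray:
        """Assembled BYM2 province effect, shape (S, G, P)."""
        return bym2_effect(self.v, self.u, self.sigma_omega, self.phi)

    def copy(self) -> "ParameterState":
        return replace(
            self,
            alpha=self.alpha.copy(), beta=self.beta.copy(), kappa=self.kappa.copy(),
            v=self.v.copy(), u=self.u.copy(), u_region=self.u_region.copy(), z=self.z.copy(),
        )


@dataclass(frozen=True)
class PriorSettings:
    """Hyperprior calibration knobs.

    ``sigma_upper``/``sigma_tail_prob`` state the tail condition for every
    standard-deviation parameter.  ``sigma_tail`` selects its orientation:
    ``"upper"`` (the conventional penalized-complexity reading
    ``P(sigma > upper) = prob``, the default) or ``"lower"``
    (``P(sigma < upper) = prob``).  ``phi_threshold``/``phi_prob`` state
    ``P(phi < threshold) = prob`` for the BYM2 mixing parameter.
    """

    sigma_upper: float = 3.0
    sigma_tail_prob: float = 0.05
    sigma_tail: str = "upper"
    phi_threshold: float = 0.5
    phi_prob: float = 2.0 / 3.0
    alpha_beta_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.sigma_upper <= 0:
            raise ValidationError("sigma_upper must be positive")
        for p in (self.sigma_tail_prob, self.phi_prob):
            if not (0.0 < p < 1.0):
                raise ValidationError("tail probabilities must lie in (0, 1)")
        if self.sigma_tail not in ("upper", "lower"):
            raise ValidationError("sigma_tail must be 'upper' or 'lower'")

    @property
    def sigma_rate(self) -> float:
        return calibrate_pc_sigma(self.sigma_upper, self.sigma_tail_prob, self.sigma_tail)


@dataclass(frozen=True)
class ModelSpec:
    """Age grouping, period mapping, spatial structure and priors for one fit."""

    grouping: AgeGrouping
    periods: PeriodMapping
    structure: ScaledStructure
    region_index: np.ndarray          # 0-based region index per province
    age_values: np.ndarray
    priors: PriorSettings = field(default_factory=PriorSettings)

    def __post_init__(self) -> None:
        object.__setattr__(self, "region_index", np.asarray(self.region_index, dtype=int))
        object.__setattr__(self, "age_values", np.asarray(self.age_values, dtype=int))

    @property
    def year_values(self) -> np.ndarray:
        return np.asarray(self.periods.years, dtype=int)

    @property
    def n_groups(self) -> int:
        return self.grouping.n_groups

    @property
    def n_periods(self) -> int:
        return self.periods.n_periods

    @property
    def n_regions(self) -> int:
        return int(self.region_index.max()) + 1

    def group_index(self) -> np.ndarray:
        """0-based age-group index per age."""
        return self.grouping.index_array(self.age_values)

    def period_index(self) -> np.ndarray:
        """0-based period index per year."""
        return self.periods.index_array()

    @classmethod
    def from_dataset(cls, dataset, graph: AdjacencyGraph, cutpoint: int | None = None,
                     priors: PriorSettings | None = None) -> "ModelSpec":
        grouping = default_age_grouping(int(dataset.age_values.max()))
        periods = make_period_mapping(dataset.year_values, cutpoint)
        return cls(
            grouping=grouping,
            periods=periods,
            structure=scaled_besag(graph),
            region_index=dataset.region_index(),
            age_values=dataset.age_values,
            priors=priors or PriorSettings(),
        )


# ---------------------------------------------------------------------------
# deterministic mappings


def bym2_effect(v: np.ndarray, u_structured: np.ndarray, sigma: float, phi: float) -> np.ndarray:
    """omega = sigma * (sqrt(1-phi) v + sqrt(phi) u)."""
    if not (0.0 <= phi <= 1.0):
        raise ValidationError(f"phi must lie in [0, 1], got {phi}")
    v = np.asarray(v, dtype=float)
    u = np.asarray(u_structured, dtype=float)
    if v.shape != u.shape:
        raise ValidationError("v and u must share a shape")
    return sigma * (np.sqrt(1.0 - phi) * v + np.sqrt(phi) * u)


def linear_predictor(state: ParameterState, grouping: AgeGrouping, periods: PeriodMapping,
                     region_of: np.ndarray | dict) -> np.ndarray:
    """eta_xts = alpha_x + beta_x kappa_t + omega_{s,g_x[,p_t]} + u_{r_s} + z_xts.

    ``region_of`` is either a 0-based region-index array over provinces or
    a province-id -> region-id map (converted via sorted unique regions).
    Ages are ``0..A-1`` aligned with ``alpha``; years are those of
    ``periods``.
    """
    A, T, S = state.z.shape
    if len(state.alpha) != A or len(state.beta) != A or len(state.kappa) != T:
        raise ValidationError("alpha/beta/kappa lengths inconsistent with z")
    if len(periods.years) != T:
        raise ValidationError(f"period mapping covers {len(periods.years)} years but kappa has {T}")
    if isinstance(region_of, dict):
        regions = np.unique(list(region_of.values()))
        lookup = {int(r): i for i, r in enumerate(regions)}
        region_idx = np.array([lookup[region_of[p]] for p in sorted(region_of)])
    else:
        region_idx = np.asarray(region_of, dtype=int)
    if len(region_idx) != S:
        raise ValidationError("region map length inconsistent with number of provinces")

    g_idx = grouping.index_array(np.arange(A))
    p_idx = periods.index_array()
    omega = state.omega()                       # (S, G, P)
    if omega.shape[1] <= g_idx.max() or omega.shape[2] <= p_idx.max():
        raise ValidationError("omega dimensions inconsistent with grouping/periods")
    omega_xts = omega[:, g_idx, :][:, :, p_idx].transpose(1, 2, 0)   # (A, T, S)

    eta = (
        state.alpha[:, None, None]
        + state.beta[:, None, None] * state.kappa[None, :, None]
        + omega_xts
        + state.u_region[region_idx][None, None, :]
        + state.z
    )
    return eta


# ---------------------------------------------------------------------------
# log densities


def poisson_loglik(deaths: np.ndarray, exposures: np.ndarray, eta: np.ndarray) -> float:
    """Sum of Poisson(E e^eta) log-pmfs: sum y(log E + eta) - E e^eta - log y!."""
    y = np.asarray(deaths, dtype=float)
    E = np.asarray(exposures, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if y.shape != E.shape or y.shape != eta.shape:
        raise ValidationError("deaths, exposures and eta must share a shape")
    if not np.all(np.isfinite(eta)):
        raise ValidationError("non-finite linear predictor")
    return float(np.sum(y * (np.log(E) + eta) - E * np.exp(eta) - gammaln(y + 1.0)))


def rw2_logdensity(kappa: np.ndarray, sigma_kappa: float) -> float:
    """Second-order random-walk log density with flat priors on the first two values.

    Only the innovations ``kappa_t - 2 kappa_{t-1} + kappa_{t-2}`` for
    t = 3..T contribute; the density is therefore flat on any linear
    function of time.
    """
    kappa = np.asarray(kappa, dtype=float)
    if len(kappa) < 3:
        raise ValidationError("RW2 needs at least 3 time points")
    d2 = np.diff(kappa, n=2)
    return float(np.sum(-0.5 * (d2 / sigma_kappa) ** 2 - np.log(sigma_kappa) - 0.5 * _LOG_2PI))


def _gaussian_logpdf(x: np.ndarray, sd: float) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.sum(-0.5 * (x / sd) ** 2 - np.log(sd) - 0.5 * _LOG_2PI))


# ---------------------------------------------------------------------------
# penalized-complexity priors


def calibrate_pc_sigma(upper: float, prob: float, orientation: str = "upper") -> float:
    """Rate of the exponential PC prior on a standard deviation.

    ``orientation="upper"`` solves ``P(sigma > upper) = prob`` (the
    conventional penalized-complexity statement); ``"lower"`` solves
    ``P(sigma < upper) = prob``.
    """
    if upper <= 0 or not (0.0 < prob < 1.0):
        raise ValidationError("need upper > 0 and prob in (0, 1)")
    if orientation == "upper":
        return float(-np.log(prob) / upper)
    if orientation == "lower":
        return float(-np.log1p(-prob) / upper)
    raise ValidationError("orientation must be 'upper' or 'lower'")


def pc_sigma_logpdf(sigma: float, rate: float) -> float:
    """Exponential(rate) log density on the standard-deviation scale."""
    if sigma < 0:
        return -np.inf
    return float(np.log(rate) - rate * sigma)


def _structure_gammas(structure: ScaledStructure) -> np.ndarray:
    """Marginal-variance eigenvalues of the constrained scaled-Besag field."""
    evals = np.linalg.eigvalsh(structure.structure)
    pos = evals[evals > 1e-10 * max(evals.max(), 1.0)]
    return 1.0 / pos


def phi_distance(phi: float | np.ndarray, gammas: np.ndarray) -> np.ndarray:
    """KLD distance d(phi) of the BYM2 model from its unstructured base (phi=0).

    ``d(phi) = sqrt(sum_i [phi (gamma_i - 1) - log(1 + phi (gamma_i - 1))])``
    over the constrained eigen-directions with marginal variances gamma_i.
    """
    phi = np.asarray(phi, dtype=float)
    t = phi[..., None] * (gammas - 1.0)
    return np.sqrt(np.maximum(np.sum(t - np.log1p(t), axis=-1), 0.0))


def calibrate_pc_phi(structure: ScaledStructure, threshold: float = 0.5,
                     prob: float = 2.0 / 3.0) -> float:
    """Rate lambda of the PC prior on phi such that P(phi < threshold) = prob.

    The prior is exponential in the distance ``d(phi)``, truncated to the
    reachable range ``[0, d(1)]`` and normalized, so the CDF is
    ``(1 - exp(-lambda d(phi))) / (1 - exp(-lambda d(1)))``.
    """
    if not (0.0 < threshold < 1.0) or not (0.0 < prob < 1.0):
        raise ValidationError("threshold and prob must lie in (0, 1)")
    gammas = _structure_gammas(structure)

    def gap(lam: float) -> float:
        return pc_phi_cdf(threshold, lam, gammas) - prob

    lo, hi = 1e-9, 1e4
    if gap(lo) * gap(hi) > 0:
        raise ValidationError(
            "PC-prior rate for phi not bracketed: the requested tail condition "
            "is unreachable for this graph"
        )
    return float(brentq(gap, lo, hi, xtol=1e-14, rtol=1e-14))


def pc_phi_cdf(phi: float | np.ndarray, lam: float, gammas: np.ndarray) -> float | np.ndarray:
    """Prior CDF of phi under the truncated-exponential-in-distance PC prior."""
    d = phi_distance(phi, gammas)
    dmax = phi_distance(1.0, gammas)
    out = -np.expm1(-lam * d) / -np.expm1(-lam * dmax)
    return float(out) if np.isscalar(phi) or np.ndim(phi) == 0 else out


def _phi_distance_deriv(phi: float, gammas: np.ndarray) -> float:
    """d'(phi), with the analytic phi -> 0 limit."""
    g1 = gammas - 1.0
    if phi < 1e-12:
        return float(np.sqrt(0.5 * np.sum(g1**2)))
    d = float(phi_distance(phi, gammas))
    num = np.sum(g1**2 * phi / (1.0 + phi * g1))
    return float(num / (2.0 * d))


def pc_phi_logpdf(phi: float, lam: float, gammas: np.ndarray) -> float:
    """Log density of the PC prior on phi (for 0 < phi < 1)."""
    if not (0.0 < phi < 1.0):
        return -np.inf
    d = float(phi_distance(phi, gammas))
    dmax = float(phi_distance(1.0, gammas))
    logZ = np.log(-np.expm1(-lam * dmax))
    return float(np.log(lam) - lam * d + np.log(_phi_distance_deriv(phi, gammas)) - logZ)


# ---------------------------------------------------------------------------
# identifiability constraints


def apply_constraints(state: ParameterState, spec: ModelSpec) -> ParameterState:
    """Project a draw onto the identified parameterization, leaving eta invariant.

    * ``beta`` is rescaled to sum to one, ``kappa`` multiplied by the
      reciprocal factor (products ``beta_x kappa_t`` unchanged);
    * ``kappa`` is centred, the shift absorbed into ``alpha``;
    * ``omega`` is centred over provinces within every (age group,
      period, non-singleton graph component) by centring ``v`` and ``u``
      there; the removed block means are absorbed into the matching cells
      of the overdispersion term ``z`` so the linear predictor is exactly
      unchanged.  (Singleton components carry a single free value which a
      sum-to-zero constraint would annihilate, so they are left alone.)

    The projection is idempotent and leaves the Poisson likelihood
    invariant to machine precision.
    """
    out = state.copy()

    bsum = float(np.sum(out.beta))
    if abs(bsum) < 1e-12:
        raise ValidationError("sum of beta is zero; rescaling to sum 1 is undefined")
    out.beta = out.beta / bsum
    out.kappa = out.kappa * bsum

    kmean = float(np.mean(out.kappa))
    out.kappa = out.kappa - kmean
    out.alpha = out.alpha + out.beta * kmean

    g_idx = spec.group_index()
    p_idx = spec.period_index()
    sig, phi = out.sigma_omega, out.phi
    for comp in spec.structure.components:
        if len(comp) == 1:
            continue
        sidx = np.array(comp) - 1
        mv = out.v[sidx].mean(axis=0)                   # (G, P)
        mu = out.u[sidx].mean(axis=0)
        out.v[sidx] -= mv
        out.u[sidx] -= mu
        momega = sig * (np.sqrt(1.0 - phi) * mv + np.sqrt(phi) * mu)   # (G, P)
        out.z[:, :, sidx] += momega[g_idx][:, p_idx][:, :, None]
    return out


# ---------------------------------------------------------------------------
# joint density


def joint_logdensity(state: ParameterState, dataset, spec: ModelSpec) -> float:
    """Unnormalized log posterior: likelihood plus every prior term.

    The structured BYM2 component ``u`` contributes the proper density on
    the constrained subspace of the scaled structure (quadratic form plus
    the log-pseudo-determinant); directions in the intrinsic null space
    are flat.
    """
    eta = linear_predictor(state, spec.grouping, spec.periods, spec.region_index)
    lp = poisson_loglik(dataset.deaths, dataset.exposures, eta)
    lp += rw2_logdensity(state.kappa, state.sigma_kappa)

    Q = spec.structure.structure
    evals = np.linalg.eigvalsh(Q)
    pos = evals[evals > 1e-10 * max(evals.max(), 1.0)]
    logdet_half = 0.5 * float(np.sum(np.log(pos)))
    rank = len(pos)
    G, P = state.u.shape[1], state.u.shape[2]
    for g in range(G):
        for p in range(P):
            ug = state.u[:, g, p]
            lp += -0.5 * float(ug @ Q @ ug) + logdet_half - 0.5 * rank * _LOG_2PI
    lp += _gaussian_logpdf(state.v, 1.0)

    lp += _gaussian_logpdf(state.z, state.sigma_z)
    lp += _gaussian_logpdf(state.u_region, state.sigma_r)
    lp += _gaussian_logpdf(state.alpha, spec.priors.alpha_beta_sd)
    lp += _gaussian_logpdf(state.beta, spec.priors.alpha_beta_sd)

    rate = spec.priors.sigma_rate
    for sigma in (state.sigma_omega, state.sigma_r, state.sigma_z, state.sigma_kappa):
        lp += pc_sigma_logpdf(sigma, rate)
    lam = calibrate_pc_phi(spec.structure, spec.priors.phi_threshold, spec.priors.phi_prob)
    lp += pc_phi_logpdf(state.phi, lam, _structure_gammas(spec.structure))
    return float(lp)
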