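"""Ground-truth generators for validating the interaction chain.

Three generators cover the validation needs:

* a generalized Lotka-Volterra (gLV) integrator that treats a single
  environmental gradient as pseudo-time — pairwise interaction signs and
  effective strengths (``r_i * B_ij / K_i``) are known exactly, and the
  right-hand side provides the true abundance slopes at every sample;
* an analytic generator whose abundances are explicit polynomials of the
  gradients, so true partial derivatives are available symbolically — the
  oracle for the regression estimators;
* a study-shaped emulator (150 samples x 17 taxa x 13 parameters along a
  pH 4-8 gradient) for end-to-end and robustness exercises at realistic
  scale, closed to relative abundances with roughly conserved total
  community size.

Noise everywhere is the same multiplicative uniform kernel used by the
robustness machinery, for internal consistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np
from scipy.integrate import solve_ivp

from .tables import AbundanceTable, EnvironmentTable


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class GLVParams:
    """Parameters of a gLV system integrated along a gradient.

    ``B[i, j]`` is the dimensionless interaction coefficient of taxon j on
    taxon i; the effective coefficient recovered by the inference chain is
    ``r_i * B_ij / K_i``.
    """

    r: np.ndarray
    K: np.ndarray
    B: np.ndarray
    A0: np.ndarray
    theta_grid: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        K = np.asarray(self.K, dtype=float)
        B = np.asarray(self.B, dtype=float)
        A0 = np.asarray(self.A0, dtype=float)
        grid = np.asarray(self.theta_grid, dtype=float)
        for name, v in (("r", r), ("K", K), ("B", B), ("A0", A0),
                        ("theta_grid", grid)):
            object.__setattr__(self, name, v)
        d = r.size
        if not (K.size == d and A0.size == d and B.shape == (d, d)):
            raise ValueError("inconsistent gLV parameter dimensions")
        if (K <= 0).any() or (A0 <= 0).any():
            raise ValueError("carrying capacities and initial abundances "
                             "must be positive")
        if grid.ndim != 1 or grid.size < 2 or (np.diff(grid) <= 0).any():
            raise ValueError("theta_grid must be strictly increasing")

    @property
    def effective_beta(self) -> np.ndarray:
        """Effective interaction matrix ``r_i * B_ij / K_i``."""
        return self.r[:, None] * self.B / self.K[:, None]


@dataclass(frozen=True)
class SyntheticTruth:
    """A generated dataset bundled with its ground truth."""

    abundance: AbundanceTable
    environment: EnvironmentTable
    true_p: np.ndarray  # d x m x N, dA_i/dTheta_a at each sample (raw units)
    true_beta_sign: np.ndarray  # d x d expected sign of off-diagonal interactions
    generator: str
    seed: int | None = None
    metadata: dict = field(default_factory=dict)
    #: pre-closure absolute table when the relative table was produced by closure
    absolute: AbundanceTable | None = None
    #: symbolic dp_i/dA_j when known (analytic generator), else None
    true_dp_dA: np.ndarray | None = None


def multiplicative_noise(values: np.ndarray, level: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Entrywise ``x * (1 + u * level)`` with ``u ~ Uniform(-1, 1)``."""
    if level < 0:
        raise ValueError("noise level must be nonnegative")
    if level == 0:
        return values.copy()
    return values * (1 + rng.uniform(-1, 1, size=values.shape) * level)


def glv_rhs(theta: float, A: np.ndarray, r: np.ndarray, K: np.ndarray,
            B: np.ndarray) -> np.ndarray:
    """dA_i/dTheta = r_i A_i (1 - A_i/K_i + sum_j B_ij A_j / K_i)."""
    return r * A * (1 - A / K + (B @ A) / K)


def simulate_glv_gradient(params: GLVParams, noise: float = 0.0,
                          seed: int | None = None) -> SyntheticTruth:
    """Integrate the gLV system along the gradient and sample it.

    Adaptive Runge-Kutta at relative tolerance 1e-8.  ``true_p`` is the
    right-hand side evaluated on the noise-free trajectory.  Optional
    multiplicative noise is applied to the sampled abundances only.
    """
    grid = params.theta_grid
    sol = solve_ivp(glv_rhs, (grid[0], grid[-1]), params.A0, t_eval=grid,
                    args=(params.r, params.K, params.B),
                    rtol=1e-8, atol=1e-10, method="RK45")
    if not sol.success:
        raise SimulationError(f"gLV integration failed: {sol.message}")
    A = sol.y.T  # N x d
    if (A <= 0).any():
        raise SimulationError("gLV trajectory reached a non-positive abundance")
    true_p = np.stack([glv_rhs(t, a, params.r, params.K, params.B)
                       for t, a in zip(grid, A)], axis=1)[:, None, :]  # d x 1 x N
    rng = np.random.default_rng(seed)
    A_obs = multiplicative_noise(A, noise, rng)
    if (A_obs <= 0).any():
        raise SimulationError("noise level pushed an abundance below zero")
    d = len(params.r)
    samples = tuple(f"s{k:03d}" for k in range(len(grid)))
    taxa = tuple(f"taxon{i + 1}" for i in range(d))
    abundance = AbundanceTable(samples, taxa, A_obs, mode="absolute")
    environment = EnvironmentTable(samples, ("theta",), grid[:, None])
    eff = params.effective_beta
    return SyntheticTruth(
        abundance, environment, true_p, np.sign(eff),
        generator="glv_gradient", seed=seed,
        metadata={"noise": noise, "effective_beta": eff,
                  "params": params})


def predator_prey_params(strength: float = 0.6, n_samples: int = 60,
                         theta_max: float = 4.0) -> GLVParams:
    """Two-species predator-prey preset in the transient regime.

    The predator (taxon 1) starts rare far below carrying capacity and
    benefits from the abundant prey (taxon 2), which it suppresses.
    Distinct growth rates, capacities and initial abundances keep the two
    abundance curves from collapsing onto one line, which would make the
    difference design singular.
    """
    return GLVParams(r=np.array([1.2, 0.5]), K=np.array([1.0, 0.6]),
                     B=np.array([[0.0, strength], [-strength, 0.0]]),
                     A0=np.array([0.05, 0.9]),
                     theta_grid=np.linspace(0.0, theta_max, n_samples))


def mutualism_params(strength: float = 0.5, n_samples: int = 60,
                     theta_max: float = 4.0) -> GLVParams:
    """Two-species mutualism preset (both interaction signs positive).

    One partner starts above the interacting equilibrium and declines, the
    other starts rare and grows: the anti-correlated transients keep the
    two abundance curves linearly independent (mutual growth from similar
    starting points makes them collinear and the cross-coefficients
    unidentifiable).
    """
    return GLVParams(r=np.array([0.8, 1.2]), K=np.array([1.0, 1.0]),
                     B=np.array([[0.0, strength], [strength, 0.0]]),
                     A0=np.array([3.0, 0.3]),
                     theta_grid=np.linspace(0.0, theta_max, n_samples))


def make_analytic_dataset(coeffs: np.ndarray | None = None,
                          n_samples: int = 40, m_params: int = 2,
                          noise: float = 0.0, seed: int | None = None,
                          quadratic_pair: bool = False) -> SyntheticTruth:
    """Polynomial abundances with symbolically known derivatives.

    Default: each taxon is a positive multilinear function of the gradients,
    ``A_i = c_i0 + sum_a coeffs[i, a] * Theta_a``, so ``true_p`` equals
    ``coeffs`` at every sample and the regression estimators must recover it
    exactly in the noise-free case.

    With ``quadratic_pair`` the classic two-taxon construction ``A_1 =
    Theta^2, A_2 = Theta`` (single gradient) is produced instead; there
    ``p_1 = 2 Theta = 2 A_2``, so the true cross-derivative ``dp_1/dA_2``
    is exactly 2 (``true_dp_dA``).
    """
    rng = np.random.default_rng(seed)
    if quadratic_pair:
        theta = np.linspace(1.0, 3.0, n_samples)[:, None]
        A = np.column_stack([theta[:, 0] ** 2, theta[:, 0]])
        true_p = np.stack([2 * theta[:, 0], np.ones(n_samples)], axis=0)[:, None, :]
        true_dp_dA = np.array([[0.0, 2.0], [0.0, 0.0]])
        coeffs = np.zeros((2, 1))
        m_params = 1
    else:
        if coeffs is None:
            coeffs = rng.uniform(0.5, 3.0, size=(3, m_params))
        coeffs = np.asarray(coeffs, dtype=float)
        m_params = coeffs.shape[1]
        d = coeffs.shape[0]
        if n_samples <= m_params + d:
            raise ValueError("need n_samples > m_params + n_taxa")
        theta = rng.uniform(0.5, 2.0, size=(n_samples, m_params))
        intercepts = np.abs(coeffs).sum(axis=1) * 2.5 + 1.0  # keep A positive
        A = intercepts[None, :] + theta @ coeffs.T
        true_p = np.repeat(coeffs[:, :, None], n_samples, axis=2)
        true_dp_dA = np.zeros((d, d))
    d = A.shape[1]
    if n_samples <= m_params + d:
        raise ValueError("need n_samples > m_params + n_taxa")
    A_obs = multiplicative_noise(A, noise, rng)
    samples = tuple(f"s{k:03d}" for k in range(n_samples))
    taxa = tuple(f"taxon{i + 1}" for i in range(d))
    params = tuple(f"theta{a + 1}" for a in range(m_params))
    return SyntheticTruth(
        AbundanceTable(samples, taxa, A_obs, mode="absolute"),
        EnvironmentTable(samples, params, theta),
        true_p, np.zeros((d, d)), generator="analytic", seed=seed,
        metadata={"noise": noise, "coeffs": coeffs},
        true_dp_dA=true_dp_dA)


def closure(absolute: AbundanceTable) -> AbundanceTable:
    """Close absolute abundances to relative fractions (rows sum to 1)."""
    sums = absolute.values.sum(axis=1)
    if (sums <= 0).any():
        k = int(np.argmax(sums <= 0))
        raise ValueError(f"zero row sum at sample {absolute.sample_ids[k]!r}")
    return AbundanceTable(absolute.sample_ids, absolute.taxon_ids,
                          absolute.values / sums[:, None], mode="relative")


# Realistic soil-parameter templates for the study-shaped emulator: name,
# (low, high) range over the pH gradient, and the pH-linked trend shape.
_SOIL_PARAMS: list[tuple[str, float, float, float]] = [
    # name, baseline, pH slope, independent scatter (fraction of range)
    ("moisture", 25.0, 3.0, 0.15),
    ("nitrate", 8.0, 1.5, 0.25),
    ("mineral_N", 12.0, 1.0, 0.2),
    ("microbial_C", 300.0, 40.0, 0.2),
    ("organic_C", 30.0, -2.5, 0.2),
    ("inorganic_C", 2.0, 0.8, 0.3),
    ("root_biomass", 0.5, -0.05, 0.25),
    ("root_N", 1.2, 0.1, 0.2),
    ("root_C", 42.0, -1.0, 0.15),
    ("soil_CN", 12.0, -0.8, 0.15),
    ("microbial_CN", 7.0, 0.4, 0.2),
    ("root_CN", 35.0, -2.0, 0.2),
]


def emulate_study(seed: int = 0, n_samples: int = 150, n_taxa: int = 17,
                  noise: float = 0.05, sparsity: float = 0.2,
                  interaction_range: tuple[float, float] = (0.05, 0.5),
                  displacement: float = 3.5, background_share: float = 8.0,
                  growth_range: tuple[float, float] = (0.3, 0.5)
                  ) -> SyntheticTruth:
    """Study-shaped community: 150 samples x 17 taxa x 13 parameters.

    A pH 4-8 gradient drives a gLV community with a sparse random
    interaction matrix (~20% of off-diagonal entries nonzero, magnitudes
    0.05-0.5, balanced signs).  The community starts displaced from its
    interacting equilibrium; the displacement is drawn in the subspace
    whose linearized relaxation leaves total community size invariant, so
    taxa redistribute abundance along the gradient rather than growing or
    shrinking collectively — soil communities are resource-buffered, and
    this is also the regime in which relative abundances track absolute
    dynamics.  Relative fractions are computed over the whole community
    including a constant unclassified remainder (``background_share`` times
    the reported total), as in real surveys where named groups cover only
    part of the reads; row sums therefore stay well below 1 and closure
    does not make abundance differences exactly collinear.

    Twelve further soil parameters co-vary smoothly with pH plus
    independent scatter.  Abundances carry 5% multiplicative noise (typical
    high-throughput precision for abundant groups).  The pre-closure
    absolute table is kept alongside the relative one.
    """
    rng = np.random.default_rng(seed)
    d = n_taxa
    K = rng.uniform(0.5, 2.0, d)
    # slow relaxation keeps transients — and hence interaction structure —
    # alive across the whole gradient instead of equilibrating early
    r = rng.uniform(*growth_range, d)
    lo, hi = interaction_range
    off = [(i, j) for i in range(d) for j in range(d) if i != j]
    n_edges = int(round(sparsity * len(off)))
    for _ in range(200):
        B = np.zeros((d, d))
        picks = rng.choice(len(off), size=n_edges, replace=False)
        for idx in picks:
            i, j = off[idx]
            B[i, j] = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
        # feasible equilibrium of dA/dTheta = 0:  A* = K + B A*
        A_star = np.linalg.solve(np.eye(d) - B, K)
        if (A_star > 0.05).all():
            break
    else:
        raise SimulationError("could not draw a feasible interaction matrix")
    # displacement restricted to the subspace whose relaxation conserves
    # the community total (to linear order): project out the Krylov space
    # of J^T on the ones vector, J the gLV Jacobian at equilibrium, then
    # clip into the positive orthant and re-project
    lam = r * A_star / K
    J = lam[:, None] * (B - np.eye(d))
    V = [np.ones(d)]
    for _ in range(4):  # (J^T)^k 1 decays ~lam^k; order 4 suffices
        V.append(J.T @ V[-1])
    Q, _ = np.linalg.qr(np.array(V).T)
    # large per-taxon relative displacements (taxa several-fold off their
    # equilibria, as soil taxa are across a pH range), alternately signed
    g = rng.uniform(0.5, displacement, d) * rng.choice([-1.0, 1.0], d) * A_star
    for _ in range(80):
        g -= Q @ (Q.T @ g)
        g = np.clip(g, -0.97 * A_star, 4.0 * A_star)
    g -= Q @ (Q.T @ g)
    A0 = np.maximum(A_star + g, 0.01 * A_star)
    ph = np.linspace(4.0, 8.0, n_samples)
    params = GLVParams(r=r, K=K, B=B, A0=A0, theta_grid=ph)
    base = simulate_glv_gradient(params, noise=0.0, seed=None)
    A_true = base.abundance.values

    env = np.empty((n_samples, 13))
    env[:, 0] = ph
    names = ["pH"]
    for c, (name, base_v, slope, scatter) in enumerate(_SOIL_PARAMS, start=1):
        trend = base_v + slope * (ph - 6.0)
        jitter = rng.normal(0.0, scatter * abs(base_v) * 0.1, n_samples)
        env[:, c] = np.maximum(trend + jitter, 0.01 * abs(base_v))
        names.append(name)

    A_obs = multiplicative_noise(A_true, noise, rng)
    background = background_share * A_star.sum()
    totals = A_obs.sum(axis=1) + background
    rel = A_obs / totals[:, None]
    samples = tuple(f"plot{k + 1:03d}" for k in range(n_samples))
    taxa = tuple(f"taxon{i + 1:02d}" for i in range(n_taxa))
    absolute = AbundanceTable(samples, taxa, A_obs, mode="absolute")
    relative = AbundanceTable(samples, taxa, rel, mode="relative")
    environment = EnvironmentTable(samples, tuple(names), env)
    eff = params.effective_beta
    return SyntheticTruth(
        relative, environment, base.true_p, np.sign(eff),
        generator="emulate_study", seed=seed,
        metadata={"noise": noise, "effective_beta": eff,
                  "params": params, "true_abundance": A_true,
                  "background": background, "total_abundance": totals},
        absolute=absolute)
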