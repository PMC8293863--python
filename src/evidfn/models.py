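"""Model space: probability models, Kullback-Leibler divergences, log-LR moments.

A model comparison problem is a triple (g, f1, f2): ``g`` is the process that
actually generates the data ("truth"), and ``f1``, ``f2`` are the two candidate
models under comparison.  Everything downstream — Neyman-Pearson error rates,
evidential error rates, information-criterion asymptotics — is driven by six
scalar summaries of the triple:

* ``K12 = K(f1, f2)`` and ``K21 = K(f2, f1)``: the KL divergences between the
  candidates (in nats),
* ``deltaK = K(g, f2) − K(g, f1) = E_g[log(f1/f2)]``: positive when f1 is
  closer to truth,
* ``sigma1, sigma2, sigma_g``: standard deviations of the single-observation
  log-likelihood ratio ``log(f1(X)/f2(X))`` under f1, f2 and g respectively.

By the central limit theorem the n-observation log-LR is approximately normal
with mean n·K12 (under f1), −n·K21 (under f2) or n·deltaK (under g), and
standard deviation √n times the matching sigma.

Discrete supports are summed exactly; continuous supports use adaptive
quadrature (absolute tolerance 1e-10 in one dimension).  All logarithms are
natural logarithms, so divergences are in nats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import integrate, special

__all__ = [
    "DiscreteSupport",
    "IntervalSupport",
    "BoxSupport",
    "ModelSpec",
    "DivergenceSet",
    "LogLRSample",
    "SupportMismatchError",
    "QuadratureError",
    "kl_divergence",
    "divergence_set",
    "bernoulli_closed_forms",
    "equidistant_pg",
    "loglr_clt_params",
    "bernoulli",
    "normal",
    "laplace",
    "bivariate_normal",
    "bivariate_laplace",
    "bivariate_laplace_mixture",
    "model_from_config",
]

_QUAD_ABS_TOL = 1e-10
_VAR_CLAMP = 1e-12


class SupportMismatchError(ValueError):
    """The denominator model assigns zero probability where the reference
    model assigns positive probability, so the divergence is infinite."""


class QuadratureError(ArithmeticError):
    """Adaptive quadrature failed to reach the requested tolerance."""


@dataclass(frozen=True)
class DiscreteSupport:
    """Finite set of atoms of a discrete distribution."""

    points: tuple

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float)


@dataclass(frozen=True)
class IntervalSupport:
    """Continuous univariate support with integration bounds (may be ±inf)."""

    lower: float = -math.inf
    upper: float = math.inf


@dataclass(frozen=True)
class BoxSupport:
    """Continuous bivariate support: a rectangle used as integration region.

    For unbounded densities the bounds must be wide enough to hold all but a
    negligible sliver (< 1e-8) of every model's mass; the built-in factories
    guarantee this for their own models.
    """

    x_bounds: tuple[float, float]
    y_bounds: tuple[float, float]


Support = DiscreteSupport | IntervalSupport | BoxSupport


@dataclass(frozen=True)
class ModelSpec:
    """One probability model: vectorized log-density, seeded sampler, support.

    ``log_density`` maps an array of observations (shape ``(m,)`` for
    univariate, ``(m, 2)`` for bivariate models) to an array of natural-log
    densities; ``-inf`` marks points outside the support.  ``sampler(count,
    seed)`` returns ``count`` iid observations.  ``n_params`` is the number of
    free parameters r (0 for a completely specified model — which every model
    used in the simple-vs-simple operations must be).
    """

    label: str
    log_density: Callable[[np.ndarray], np.ndarray]
    sampler: Callable[[int, object], np.ndarray]
    support: Support
    n_params: int = 0
    meta: dict = field(default_factory=dict, compare=False)

    def logpdf(self, x) -> np.ndarray:
        return np.asarray(self.log_density(np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class DivergenceSet:
    """The six scalar summaries of a (g, f1, f2) triple, all in nats."""

    K12: float
    K21: float
    deltaK: float
    sigma1: float
    sigma2: float
    sigma_g: float


@dataclass(frozen=True)
class LogLRSample:
    """Realized values of log(L1/L2), one per simulated replicate."""

    values: np.ndarray
    n: int
    seed: int
    source_labels: tuple[str, str, str]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("log-LR replicates contain non-finite values")
        object.__setattr__(self, "values", v)


# ---------------------------------------------------------------------------
# expectations over a model's support


def _expect_discrete(p: ModelSpec, func) -> float:
    x = p.support.as_array()
    logp = p.logpdf(x)
    mass = np.exp(logp)
    vals = np.asarray(func(x), dtype=float)
    keep = mass > 0.0
    return float(np.sum(mass[keep] * vals[keep]))


def _expect_interval(p: ModelSpec, func) -> float:
    lo, hi = p.support.lower, p.support.upper

    def integrand(x):
        xv = np.atleast_1d(x)
        w = np.exp(p.logpdf(xv))
        out = np.where(w > 0.0, w * np.asarray(func(xv), dtype=float), 0.0)
        return float(out[0])

    val, err = integrate.quad(integrand, lo, hi, epsabs=_QUAD_ABS_TOL, limit=400)
    if not math.isfinite(val) or err > max(1e-6, 1e-6 * abs(val)):
        raise QuadratureError(
            f"quadrature over [{lo}, {hi}] achieved abs error {err:.3g}"
        )
    return val


_GL_NODES = 240  # per axis; the tensor rule is vectorized over all nodes


def _expect_box(p: ModelSpec, func) -> float:
    # tensor-product Gauss-Legendre over the declared box.  The rule is
    # symmetric in the two axes, so expectations of geometrically mirrored
    # integrands agree to rounding, and every expectation of the same triple
    # shares one grid (making internal cross-checks exact identities).
    (x0, x1), (y0, y1) = p.support.x_bounds, p.support.y_bounds
    t, u = np.polynomial.legendre.leggauss(_GL_NODES)
    xs = 0.5 * (x1 - x0) * t + 0.5 * (x1 + x0)
    ys = 0.5 * (y1 - y0) * t + 0.5 * (y1 + y0)
    wx = 0.5 * (x1 - x0) * u
    wy = 0.5 * (y1 - y0) * u
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    weight = np.exp(p.logpdf(pts))
    vals = np.asarray(func(pts), dtype=float)
    vals = np.where(weight > 0.0, vals, 0.0)
    w2d = np.outer(wx, wy).ravel()
    mass = float(np.sum(w2d * weight))
    total = float(np.sum(w2d * weight * vals))
    if not math.isfinite(total) or not math.isfinite(mass):
        raise QuadratureError("2-D quadrature produced a non-finite value")
    if abs(mass - 1.0) > 0.02:
        raise QuadratureError(
            f"integration box captures mass {mass:.6f}; bounds look wrong"
        )
    # self-normalize: the residual grid-mass deficit sits at density spikes
    # where the integrand factors are smooth, so dividing it out removes the
    # leading quadrature error (exactly, for integrands linear there)
    return total / mass


def expectation(p: ModelSpec, func) -> float:
    """E_p[func(X)] by exact summation or adaptive quadrature."""
    if isinstance(p.support, DiscreteSupport):
        return _expect_discrete(p, func)
    if isinstance(p.support, IntervalSupport):
        return _expect_interval(p, func)
    if isinstance(p.support, BoxSupport):
        return _expect_box(p, func)
    raise TypeError(f"unknown support type {type(p.support)!r}")


def _check_discrete_support(p: ModelSpec, q: ModelSpec) -> None:
    x = p.support.as_array()
    mass_p = np.exp(p.logpdf(x))
    logq = q.logpdf(x)
    bad = (mass_p > 0.0) & ~np.isfinite(logq)
    if np.any(bad):
        pts = x[bad][:5]
        raise SupportMismatchError(
            f"{q.label} assigns zero probability at points {pts.tolist()} "
            f"where {p.label} has positive mass"
        )


# ---------------------------------------------------------------------------
# divergences


def kl_divergence(p: ModelSpec, q: ModelSpec) -> float:
    """KL divergence K(p, q) = E_p[log(p(X)/q(X))], in nats.

    Always >= 0, and 0 iff the two models are identical on the support.
    Raises :class:`SupportMismatchError` when q has zero probability on a
    region where p has positive probability (discrete supports checked
    explicitly; continuous quadrature surfaces the infinity as a
    :class:`QuadratureError`).
    """
    if isinstance(p.support, DiscreteSupport):
        _check_discrete_support(p, q)

    def log_ratio(x):
        return p.logpdf(x) - q.logpdf(x)

    val = expectation(p, log_ratio)
    # exact-summation round-off can leave a tiny negative residue at p == q
    if val < 0.0 and val > -_VAR_CLAMP:
        val = 0.0
    return val


def _clamped_sd(second_moment: float, mean: float) -> float:
    var = second_moment - mean * mean
    if var < 0.0:
        if abs(var) < _VAR_CLAMP:
            var = 0.0
        else:
            raise QuadratureError(f"negative variance {var:.3g} beyond round-off")
    return math.sqrt(var)


def divergence_set(g: ModelSpec, f1: ModelSpec, f2: ModelSpec) -> DivergenceSet:
    """All six divergence/variance summaries of the triple (g, f1, f2).

    ``deltaK`` is computed directly as E_g[log(f1/f2)] and cross-checked
    against K(g, f2) − K(g, f1).
    """
    for ref in (g, f1):
        if isinstance(ref.support, DiscreteSupport):
            _check_discrete_support(ref, f2)
    if isinstance(g.support, DiscreteSupport):
        _check_discrete_support(g, f1)
    if isinstance(f2.support, DiscreteSupport):
        _check_discrete_support(f2, f1)

    def h(x):
        return f1.logpdf(x) - f2.logpdf(x)

    def h2(x):
        d = f1.logpdf(x) - f2.logpdf(x)
        return d * d

    K12 = expectation(f1, h)
    K21 = -expectation(f2, h)
    deltaK = expectation(g, h)

    check = kl_divergence(g, f2) - kl_divergence(g, f1)
    tol = 1e-7 if isinstance(g.support, BoxSupport) else 1e-9
    if abs(check - deltaK) > tol:
        raise QuadratureError(
            f"deltaK cross-check failed: direct {deltaK:.12g} vs "
            f"K(g,f2)-K(g,f1) {check:.12g}"
        )

    sigma1 = _clamped_sd(expectation(f1, h2), K12)
    sigma2 = _clamped_sd(expectation(f2, h2), -K21)
    sigma_g = _clamped_sd(expectation(g, h2), deltaK)
    return DivergenceSet(K12, K21, deltaK, sigma1, sigma2, sigma_g)


def bernoulli_closed_forms(p1: float, p2: float, pg: float) -> DivergenceSet:
    """Divergence set for a Bernoulli triple via the printed closed forms.

    With a = log(p1/p2) and b = log((1-p1)/(1-p2)), the single-observation
    log-LR is x·a + (1-x)·b, so under Bernoulli(p) its mean is p·a + (1-p)·b
    and its second moment p·a² + (1-p)·b².  In particular

        K12    = p1·a + (1-p1)·b
        deltaK = b + pg·(a - b)        (linear in pg)

    Agrees with :func:`divergence_set` on the matching ModelSpecs to 1e-12.
    """
    for name, p in (("p1", p1), ("p2", p2), ("pg", pg)):
        if not 0.0 < p < 1.0:
            raise ValueError(f"{name}={p} must lie strictly in (0, 1)")
    a = math.log(p1 / p2)
    b = math.log((1.0 - p1) / (1.0 - p2))

    def stats(p):
        mean = p * a + (1.0 - p) * b
        sd = _clamped_sd(p * a * a + (1.0 - p) * b * b, mean)
        return mean, sd

    K12, sigma1 = stats(p1)
    m2, sigma2 = stats(p2)
    deltaK, sigma_g = stats(pg)
    return DivergenceSet(K12, -m2, deltaK, sigma1, sigma2, sigma_g)


def equidistant_pg(p1: float, p2: float) -> float:
    """Generating probability at which both Bernoulli candidates are equally
    far from truth (deltaK = 0): the root of the linear-in-pg deltaK."""
    num = math.log((1.0 - p2) / (1.0 - p1))
    den = math.log(p1 * (1.0 - p2) / ((1.0 - p1) * p2))
    return num / den


def loglr_clt_params(ds: DivergenceSet, n: float, regime: str) -> tuple[float, float]:
    """CLT (mean, sd) of log(L1/L2) for n iid observations.

    regime: 'under_f1' -> (n·K12, √n·σ1); 'under_f2' -> (−n·K21, √n·σ2);
    'under_g' -> (n·deltaK, √n·σg).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    r = math.sqrt(n)
    if regime == "under_f1":
        return n * ds.K12, r * ds.sigma1
    if regime == "under_f2":
        return -n * ds.K21, r * ds.sigma2
    if regime == "under_g":
        return n * ds.deltaK, r * ds.sigma_g
    raise ValueError(f"unknown regime {regime!r}")


# ---------------------------------------------------------------------------
# built-in families


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def bernoulli(p: float, label: str | None = None) -> ModelSpec:
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly in (0, 1)")
    lp, lq = math.log(p), math.log1p(-p)

    def logpdf(x):
        return np.where(x > 0.5, lp, lq)

    def sampler(count, seed):
        return _rng(seed).binomial(1, p, size=count).astype(float)

    return ModelSpec(
        label or f"bernoulli({p})",
        logpdf,
        sampler,
        DiscreteSupport((0.0, 1.0)),
        meta={"family": "bernoulli", "params": {"p": p}},
    )


def normal(mu: float, sigma: float, label: str | None = None) -> ModelSpec:
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    c = -0.5 * math.log(2.0 * math.pi * sigma * sigma)

    def logpdf(x):
        z = (x - mu) / sigma
        return c - 0.5 * z * z

    def sampler(count, seed):
        return _rng(seed).normal(mu, sigma, size=count)

    return ModelSpec(
        label or f"normal({mu}, {sigma}^2)",
        logpdf,
        sampler,
        IntervalSupport(),
        meta={"family": "normal", "params": {"mu": mu, "sigma": sigma}},
    )


def laplace(loc: float, scale: float, label: str | None = None) -> ModelSpec:
    """Univariate Laplace (double exponential): heavier-tailed than any
    normal, handy as a misspecified generating process."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    c = -math.log(2.0 * scale)

    def logpdf(x):
        return c - np.abs(x - loc) / scale

    def sampler(count, seed):
        return _rng(seed).laplace(loc, scale, size=count)

    return ModelSpec(
        label or f"laplace({loc}, {scale})",
        logpdf,
        sampler,
        IntervalSupport(),
        meta={"family": "laplace", "params": {"loc": loc, "scale": scale}},
    )


def _as_cov(cov) -> np.ndarray:
    c = np.asarray(cov, dtype=float)
    if c.shape != (2, 2):
        raise ValueError("covariance must be 2x2")
    if not np.all(np.linalg.eigvalsh(c) > 0):
        raise ValueError("covariance must be positive definite")
    return c


def _box_for(mean, cov, radius_sd: float) -> BoxSupport:
    sds = np.sqrt(np.diag(cov))
    lo = np.asarray(mean) - radius_sd * sds
    hi = np.asarray(mean) + radius_sd * sds
    return BoxSupport((float(lo[0]), float(hi[0])), (float(lo[1]), float(hi[1])))


def bivariate_normal(mean, cov, label: str | None = None) -> ModelSpec:
    mean = np.asarray(mean, dtype=float)
    cov = _as_cov(cov)
    inv = np.linalg.inv(cov)
    c = -math.log(2.0 * math.pi) - 0.5 * math.log(np.linalg.det(cov))
    chol = np.linalg.cholesky(cov)

    def logpdf(x):
        d = np.atleast_2d(x) - mean
        q = np.einsum("ij,jk,ik->i", d, inv, d)
        return c - 0.5 * q

    def sampler(count, seed):
        z = _rng(seed).standard_normal((count, 2))
        return mean + z @ chol.T

    return ModelSpec(
        label or f"bvnormal({mean.tolist()})",
        logpdf,
        sampler,
        _box_for(mean, cov, 8.0),
        meta={"family": "bvnormal", "params": {"mean": mean.tolist(), "cov": cov.tolist()}},
    )


def bivariate_laplace(mean, cov, label: str | None = None) -> ModelSpec:
    """Symmetric bivariate Laplace built as an exponential scale mixture of
    bivariate normals: X = mean + √W · N(0, cov) with W ~ Exp(1).

    Density (Kotz et al. form, d = 2):  f(x) = K0(√(2 q)) / (π √|cov|)
    with q = (x-mean)' cov⁻¹ (x-mean) and K0 the modified Bessel function.
    The covariance of X equals ``cov`` (E W = 1).  Tails are exponential
    (radial rate √2 in standardized units), so an integration box of 15
    component standard deviations holds all but < 1e-8 of the mass.
    """
    mean = np.asarray(mean, dtype=float)
    cov = _as_cov(cov)
    inv = np.linalg.inv(cov)
    c = -math.log(math.pi) - 0.5 * math.log(np.linalg.det(cov))
    chol = np.linalg.cholesky(cov)

    def logpdf(x):
        d = np.atleast_2d(x) - mean
        q = np.einsum("ij,jk,ik->i", d, inv, d)
        # K0 has an integrable log-singularity at the centre; clamp the
        # radius at 1e-12 so quadrature nodes that land exactly on the mode
        # see a large finite value (mass affected < 1e-22).  k0e keeps the
        # far tail from underflowing.
        r = np.maximum(np.sqrt(2.0 * np.maximum(q, 0.0)), 1e-12)
        logk0 = np.log(special.k0e(r)) - r
        return c + logk0

    def sampler(count, seed):
        rng = _rng(seed)
        w = rng.exponential(1.0, size=count)
        z = rng.standard_normal((count, 2))
        return mean + np.sqrt(w)[:, None] * (z @ chol.T)

    return ModelSpec(
        label or f"bvlaplace({mean.tolist()})",
        logpdf,
        sampler,
        _box_for(mean, cov, 15.0),
        meta={"family": "bvlaplace", "params": {"mean": mean.tolist(), "cov": cov.tolist()}},
    )


def bivariate_laplace_mixture(
    mean1, cov1, mean2, cov2, weight: float = 0.7, label: str | None = None
) -> ModelSpec:
    """Two-component bivariate-Laplace mixture: an asymmetric surrogate truth
    with a large mode at ``mean1`` (weight ``weight``) and a smaller mode at
    ``mean2``."""
    if not 0.0 < weight < 1.0:
        raise ValueError("weight must lie strictly in (0, 1)")
    comp1 = bivariate_laplace(mean1, cov1)
    comp2 = bivariate_laplace(mean2, cov2)
    lw1, lw2 = math.log(weight), math.log1p(-weight)

    def logpdf(x):
        return np.logaddexp(lw1 + comp1.logpdf(x), lw2 + comp2.logpdf(x))

    def sampler(count, seed):
        rng = _rng(seed)
        pick = rng.random(count) < weight
        a = comp1.sampler(count, rng.integers(2**31))
        b = comp2.sampler(count, rng.integers(2**31))
        return np.where(pick[:, None], a, b)

    b1, b2 = comp1.support, comp2.support
    box = BoxSupport(
        (min(b1.x_bounds[0], b2.x_bounds[0]), max(b1.x_bounds[1], b2.x_bounds[1])),
        (min(b1.y_bounds[0], b2.y_bounds[0]), max(b1.y_bounds[1], b2.y_bounds[1])),
    )
    return ModelSpec(
        label or "bvlaplace-mixture",
        logpdf,
        sampler,
        box,
        meta={"family": "bvlaplace_mixture", "params": {"weight": weight}},
    )


_FAMILIES = {
    "bernoulli": lambda prm: bernoulli(prm["p"]),
    "normal": lambda prm: normal(prm["mu"], prm["sigma"]),
    "laplace": lambda prm: laplace(prm["loc"], prm["scale"]),
    "bvnormal": lambda prm: bivariate_normal(prm["mean"], prm["cov"]),
    "bvlaplace": lambda prm: bivariate_laplace(prm["mean"], prm["cov"]),
}


def model_from_config(cfg: dict) -> ModelSpec:
    """Build a ModelSpec from a ``{family: ..., params: {...}}`` mapping."""
    fam = cfg.get("family")
    if fam not in _FAMILIES:
        raise ValueError(f"unknown family {fam!r}; choose from {sorted(_FAMILIES)}")
    return _FAMILIES[fam](cfg.get("params", {}))
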