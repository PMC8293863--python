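"""Simulation and exact-enumeration estimates of every error rate.

The CLT formulas in :mod:`evidfn.clt` are smooth approximations; this module
provides the two empirical routes against which they are judged:

* ``simulate_loglr`` / ``estimate_rates``: draw replicate data sets from the
  generating model, realize log(L1/L2) for each, and count decision outcomes
  (with binomial standard errors).
* ``exact_bernoulli_rates``: for Bernoulli candidates the log-LR is a linear
  function of the binomial success count, so every rate is an exact finite
  sum of binomial masses — the oracle that reproduces the jagged (serrated)
  curves that discreteness produces.

``build_scenario`` constructs the bivariate benchmark geometries: a
bivariate-Laplace truth approximated by two bivariate-normal candidates,
aligned or misaligned with the candidate axis, with either candidate closer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from . import models
from .clt import EvidenceDesign, NPDesign, RateRecord, evidential_rates, misspecified_rates, np_design
from .models import DivergenceSet, LogLRSample, ModelSpec, bernoulli_closed_forms, divergence_set

__all__ = [
    "SimulationPlan",
    "ScenarioConfig",
    "ScenarioError",
    "simulate_loglr",
    "estimate_rates",
    "exact_bernoulli_rates",
    "rate_curves",
    "build_scenario",
]


@dataclass(frozen=True)
class SimulationPlan:
    """A full simulation study: triple, sample-size grid, replicates, seed."""

    g: ModelSpec
    f1: ModelSpec
    f2: ModelSpec
    n_grid: Sequence[int]
    replicates: int = 10_000
    root_seed: int = 0
    evidence: Optional[EvidenceDesign] = None
    np_alpha: Optional[float] = None

    def __post_init__(self):
        grid = tuple(int(n) for n in self.n_grid)
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("n_grid must be strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        object.__setattr__(self, "n_grid", grid)

    @property
    def triple(self) -> tuple[ModelSpec, ModelSpec, ModelSpec]:
        return (self.g, self.f1, self.f2)


def _derived_seed(root_seed: int, n: int) -> np.random.SeedSequence:
    # one deterministic stream per (root_seed, n); replicates are contiguous
    # blocks of that stream, so results are bit-reproducible for a root seed
    return np.random.SeedSequence(entropy=int(root_seed), spawn_key=(int(n),))


def simulate_loglr(plan: SimulationPlan, n: int) -> LogLRSample:
    """Replicate-many realized log(L1/L2) values, each from n iid draws of
    the generating model's sampler.  Deterministic given ``root_seed``."""
    reps = plan.replicates
    seed = _derived_seed(plan.root_seed, n)
    obs = plan.g.sampler(n * reps, seed)
    obs = np.asarray(obs, dtype=float)
    h = plan.f1.logpdf(obs) - plan.f2.logpdf(obs)
    vals = h.reshape(reps, n).sum(axis=1)
    return LogLRSample(
        values=vals,
        n=n,
        seed=plan.root_seed,
        source_labels=(plan.g.label, plan.f1.label, plan.f2.label),
    )


def _binom_se(p_hat: float, reps: int) -> float:
    return math.sqrt(max(p_hat * (1.0 - p_hat), 0.0) / reps)


def estimate_rates(
    sample: LogLRSample,
    design: EvidenceDesign | NPDesign,
    truth_side: str = "f1_closer",
) -> RateRecord:
    """Empirical decision frequencies of the trichotomy (or NP rule) over the
    replicates of ``sample``, with binomial standard errors.

    ``truth_side`` says which candidate is closer to the generating process
    and therefore which side's error labels apply.
    """
    if truth_side not in ("f1_closer", "f2_closer"):
        raise ValueError("truth_side must be 'f1_closer' or 'f2_closer'")
    vals = sample.values
    reps = vals.size
    if reps == 0:
        raise ValueError("empty log-LR sample")

    if isinstance(design, NPDesign):
        reject = float(np.mean(vals <= design.log_c))
        if truth_side == "f1_closer":
            return RateRecord(
                n=sample.n, mode="misspecified", method="simulation",
                alpha_like=reject, se={"alpha_like": _binom_se(reject, reps)},
            )
        accept = 1.0 - reject
        return RateRecord(
            n=sample.n, mode="misspecified", method="simulation",
            beta_like=accept, se={"beta_like": _binom_se(accept, reps)},
        )

    strong_f1 = float(np.mean(vals >= design.log_k_upper))
    strong_f2 = float(np.mean(vals <= design.log_k_lower))
    weak = 1.0 - strong_f1 - strong_f2
    if truth_side == "f1_closer":
        m, w, v = strong_f2, weak, strong_f1
        fields = dict(M1=m, W1=w, V1=v)
        se = {k: _binom_se(val, reps) for k, val in zip(("M1", "W1", "V1"), (m, w, v))}
    else:
        m, w, v = strong_f1, weak, strong_f2
        fields = dict(M2=m, W2=w, V2=v)
        se = {k: _binom_se(val, reps) for k, val in zip(("M2", "W2", "V2"), (m, w, v))}
    return RateRecord(n=sample.n, mode="misspecified", method="simulation", se=se, **fields)


def _bernoulli_params(m: ModelSpec) -> float:
    if m.meta.get("family") != "bernoulli":
        raise ValueError(f"{m.label} is not a Bernoulli ModelSpec")
    return float(m.meta["params"]["p"])


def exact_bernoulli_rates(
    p1: float,
    p2: float,
    pg: float,
    n: int,
    design: EvidenceDesign | NPDesign,
) -> RateRecord:
    """Exact error rates for the Bernoulli triple by summing binomial masses.

    With s successes out of n, log(L1/L2) = s·log(p1/p2) + (n−s)·log((1−p1)/
    (1−p2)); summing Binomial(n, pg) masses over the counts falling in each
    decision region gives exact probabilities (the serrated curves).  Both
    side labelings are filled: side 1 reads "strong evidence for f2 is
    misleading" and vice versa.
    """
    if n > 100_000:
        raise ValueError("n too large for enumeration (limit 1e5)")
    a = math.log(p1 / p2)
    b = math.log((1.0 - p1) / (1.0 - p2))
    s = np.arange(n + 1)
    loglr = s * a + (n - s) * b
    pmf = binom.pmf(s, n, pg)

    mode = "correct_spec" if (pg == p1 or pg == p2) else "misspecified"
    if isinstance(design, NPDesign):
        reject = float(pmf[loglr <= design.log_c].sum())
        return RateRecord(
            n=n, mode=mode, method="exact",
            alpha_like=reject, beta_like=1.0 - reject,
        )
    upper = float(pmf[loglr >= design.log_k_upper].sum())
    lower = float(pmf[loglr <= design.log_k_lower].sum())
    mid = float(np.clip(1.0 - upper - lower, 0.0, 1.0))
    return RateRecord(
        n=n, mode=mode, method="exact",
        M1=lower, W1=mid, V1=upper,
        M2=upper, W2=mid, V2=lower,
    )


_QUANTITIES = ("M1", "W1", "V1", "M2", "W2", "V2", "alpha_like", "beta_like")


def _records_to_frame(records) -> pd.DataFrame:
    rows = []
    for rec in records:
        for q in _QUANTITIES:
            v = getattr(rec, q)
            if v is None:
                continue
            rows.append(
                {
                    "n": rec.n,
                    "method": rec.method,
                    "mode": rec.mode,
                    "quantity": q,
                    "value": v,
                    "se": rec.se.get(q, float("nan")),
                }
            )
    return pd.DataFrame(rows, columns=["n", "method", "mode", "quantity", "value", "se"])


def rate_curves(plan: SimulationPlan) -> pd.DataFrame:
    """Tidy long table of rates over the plan's n-grid: simulated frequencies
    always; CLT rates always; exact enumeration when the whole triple is
    Bernoulli.  Columns: n, method, mode, quantity, value, se."""
    if not plan.n_grid:
        return _records_to_frame([])

    all_bern = all(m.meta.get("family") == "bernoulli" for m in plan.triple)
    if all_bern:
        pg, p1, p2 = (_bernoulli_params(m) for m in plan.triple)
        ds = bernoulli_closed_forms(p1, p2, pg)
    else:
        ds = divergence_set(*plan.triple)
    truth_side = "f1_closer" if ds.deltaK >= 0.0 else "f2_closer"

    records: list[RateRecord] = []
    for n in plan.n_grid:
        sample = simulate_loglr(plan, n) if plan.replicates else None
        if plan.evidence is not None:
            records.append(misspecified_rates(ds, plan.evidence, n))
            if sample is not None:
                records.append(estimate_rates(sample, plan.evidence, truth_side))
            if all_bern:
                records.append(exact_bernoulli_rates(p1, p2, pg, n, plan.evidence))
        if plan.np_alpha is not None:
            npd = np_design(ds, plan.np_alpha, n)
            if sample is not None:
                records.append(estimate_rates(sample, npd, truth_side))
            if all_bern:
                records.append(exact_bernoulli_rates(p1, p2, pg, n, npd))
    return _records_to_frame(records)


# ---------------------------------------------------------------------------
# bivariate scenarios


class ScenarioError(ValueError):
    """The realized deltaK sign contradicts the declared geometry."""


_GEOMETRIES = {
    # candidate means (f1, f2); truth sits at the origin
    "aligned_f1_close": ((1.0, 0.0), (2.0, 0.0)),
    "misaligned_f1_close": ((1.0, 0.0), (0.0, 2.0)),
    "aligned_f2_close": ((2.0, 0.0), (1.0, 0.0)),
    "misaligned_f2_close": ((0.0, 2.0), (1.0, 0.0)),
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Benchmark geometry: bivariate-Laplace truth at the origin, two unit-
    covariance bivariate-normal candidates at radius 1 and 2.

    ``asymmetric_truth`` swaps the symmetric Laplace for a two-mode mixture
    (large mode at the origin, smaller mode at ``mixture_mean``)."""

    geometry: str = "aligned_f1_close"
    truth_cov: tuple = ((1.0, 0.0), (0.0, 1.0))
    asymmetric_truth: bool = False
    mixture_mean: tuple = (1.5, 0.0)
    mixture_weight: float = 0.7

    def __post_init__(self):
        if self.geometry not in _GEOMETRIES:
            raise ValueError(f"unknown geometry {self.geometry!r}")


def build_scenario(cfg: ScenarioConfig):
    """(g, f1, f2) ModelSpecs plus their DivergenceSet (2-D quadrature).

    Raises :class:`ScenarioError` when the computed deltaK sign contradicts
    the geometry's declared ordering of the candidates.
    """
    mu1, mu2 = _GEOMETRIES[cfg.geometry]
    eye = np.eye(2)
    if cfg.asymmetric_truth:
        g = models.bivariate_laplace_mixture(
            (0.0, 0.0), cfg.truth_cov, cfg.mixture_mean, cfg.truth_cov,
            weight=cfg.mixture_weight, label="truth",
        )
    else:
        g = models.bivariate_laplace((0.0, 0.0), cfg.truth_cov, label="truth")
    f1 = models.bivariate_normal(mu1, eye, label="f1")
    f2 = models.bivariate_normal(mu2, eye, label="f2")
    ds = divergence_set(g, f1, f2)
    want_f1 = cfg.geometry.endswith("f1_close")
    if (ds.deltaK > 0) != want_f1:
        raise ScenarioError(
            f"geometry {cfg.geometry!r} declares "
            f"{'f1' if want_f1 else 'f2'} closer but deltaK = {ds.deltaK:.6g}"
        )
    return g, f1, f2, ds
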