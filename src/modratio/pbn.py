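"""Probabilistic Boolean network simulator and exact oracles.

The proof-of-principle network has five observable binary variables
x1..x5 (one per neuronal population) and two latent binary interface
variables y1, y2, all with values in {1, 2}. y1 gates the module
{x3, x4} and y2 the module {x2, x3, x4}; x5 serves as the reference
component. Population spike counts are Poisson with a state-dependent
mean (10 expected spikes in the low-rate state, 50 in the high-rate
state with the default 10 neurons, 5/25 Hz and 200 ms bins).

Besides ancestral sampling, the module provides exact enumeration of
the joint distribution (the network is small), closed-form count
moments, the population moment-ratio matrix, the linear-predictor R^2
of x5, and covariance-matched linear surrogate data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .samples import SampleMatrix, center_samples

__all__ = [
    "PBNSpec",
    "SpikeConfig",
    "CountMoments",
    "default_spec",
    "flat_star_spec",
    "single_module_spec",
    "sample_states",
    "exact_joint",
    "observable_joint",
    "spike_count_samples",
    "exact_count_moments",
    "population_b_matrix",
    "linear_r2",
    "linear_surrogate",
    "true_modularization_sets",
]

Config = tuple[int, ...]


@dataclass
class PBNSpec:
    """A network of binary variables (values {1, 2}) with CPTs.

    ``variables`` is a topological order. ``cpts`` maps each variable to
    its parent tuple and a table of P(var = 2) per parent configuration
    (parents ordered as in the tuple, states in {1, 2}).
    """

    variables: list[str]
    parents: dict[str, tuple[str, ...]]
    p2: dict[str, dict[Config, float]]
    observables: list[str]
    latents: list[str] = field(default_factory=list)

    def __post_init__(self):
        seen: set[str] = set()
        for v in self.variables:
            for p in self.parents[v]:
                if p not in seen:
                    raise ValueError(f"variable {v} precedes its parent {p}")
            seen.add(v)
            for cfg, prob in self.p2[v].items():
                if not 0.0 <= prob <= 1.0:
                    raise ValueError(f"invalid probability {prob} for {v}|{cfg}")

    def prob2(self, var: str, parent_states: Config) -> float:
        return self.p2[var][parent_states]


@dataclass
class SpikeConfig:
    """Spike-count observation model for the population network."""

    neurons_per_population: int = 10
    rate_low: float = 5.0
    rate_high: float = 25.0
    bin_width: float = 0.2
    n_bins: int = 4500

    def __post_init__(self):
        if self.rate_low < 0 or self.rate_high < 0 or self.bin_width <= 0:
            raise ValueError("rates must be non-negative and the bin width positive")

    @property
    def mean_low(self) -> float:
        return self.neurons_per_population * self.rate_low * self.bin_width

    @property
    def mean_high(self) -> float:
        return self.neurons_per_population * self.rate_high * self.bin_width


def default_spec() -> PBNSpec:
    """The five-population network with two nested latent interfaces.

    x4 is a fair coin; x3 follows x4 with fidelity 0.85; y1 is the AND
    of x3 and x4; x2 follows y1 with fidelity 0.85; y2 is 2 with
    probability 0.85 when y1 = x2 = 2, certainly 2 when y1 != x2 and
    certainly 1 otherwise; x1 follows y2 with fidelity 0.85; x5 is the
    AND of x1 and y2.
    """
    follow = lambda hi: {(1,): 1 - hi, (2,): hi}
    and_gate = {
        (1, 1): 0.0,
        (1, 2): 0.0,
        (2, 1): 0.0,
        (2, 2): 1.0,
    }
    variables = ["x4", "x3", "y1", "x2", "y2", "x1", "x5"]
    parents = {
        "x4": (),
        "x3": ("x4",),
        "y1": ("x3", "x4"),
        "x2": ("y1",),
        "y2": ("x2", "y1"),
        "x1": ("y2",),
        "x5": ("x1", "y2"),
    }
    p2 = {
        "x4": {(): 0.5},
        "x3": follow(0.85),
        "y1": dict(and_gate),
        "x2": follow(0.85),
        "y2": {(1, 1): 0.0, (2, 2): 0.85, (1, 2): 1.0, (2, 1): 1.0},
        "x1": follow(0.85),
        "x5": dict(and_gate),
    }
    return PBNSpec(
        variables=variables,
        parents=parents,
        p2=p2,
        observables=["x1", "x2", "x3", "x4", "x5"],
        latents=["y1", "y2"],
    )


def true_modularization_sets() -> list[set[int]]:
    """Module index sets of the generating network: {3,4} nested in {2,3,4}."""
    return [{3, 4}, {2, 3, 4}]


def flat_star_spec(follow_probs: tuple[float, ...] = (0.9, 0.85, 0.8, 0.75, 0.85)) -> PBNSpec:
    """A star network: one latent root y drives every observable.

    Every pair of observables is conditionally independent given y, so
    every flat modularization of the observables holds exactly; used as
    a null model for calibration experiments.
    """
    d = len(follow_probs)
    variables = ["y"] + [f"x{i}" for i in range(1, d + 1)]
    parents = {"y": ()}
    p2: dict[str, dict[Config, float]] = {"y": {(): 0.5}}
    for i, hi in enumerate(follow_probs, start=1):
        parents[f"x{i}"] = ("y",)
        p2[f"x{i}"] = {(1,): 1 - hi, (2,): hi}
    return PBNSpec(
        variables=variables,
        parents=parents,
        p2=p2,
        observables=[f"x{i}" for i in range(1, d + 1)],
        latents=["y"],
    )


def single_module_spec() -> PBNSpec:
    """Four observables with one exact module {x1, x2} behind a latent y.

    y is driven by x3 (which also drives the reference x4), so all
    components are pairwise correlated while {x1, x2} communicate with
    the rest only through y. The flat modularization {{1, 2}} holds
    exactly; it imposes a single equality constraint (zeta = 1/2), so
    the null statistic is gamma-distributed without any cross-constraint
    correlation.
    """
    variables = ["x3", "y", "x4", "x1", "x2"]
    parents = {"x3": (), "y": ("x3",), "x4": ("x3",), "x1": ("y",), "x2": ("y",)}
    p2 = {
        "x3": {(): 0.5},
        "y": {(1,): 0.2, (2,): 0.8},
        "x4": {(1,): 0.25, (2,): 0.75},
        "x1": {(1,): 0.1, (2,): 0.9},
        "x2": {(1,): 0.15, (2,): 0.85},
    }
    return PBNSpec(
        variables=variables,
        parents=parents,
        p2=p2,
        observables=["x1", "x2", "x3", "x4"],
        latents=["y"],
    )


def sample_states(spec: PBNSpec, n: int, rng: np.random.Generator | int) -> np.ndarray:
    """Draw ``n`` i.i.d. joint samples ancestrally; values in {1, 2}.

    Returns an (n, n_observables) array of the observable variables in
    ``spec.observables`` order.
    """
    if n < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(rng)
    states: dict[str, np.ndarray] = {}
    for v in spec.variables:
        pars = spec.parents[v]
        if not pars:
            prob = spec.p2[v][()]
            states[v] = 1 + (rng.random(n) < prob).astype(np.int8)
            continue
        prob = np.empty(n)
        parent_states = np.stack([states[p] for p in pars], axis=1)
        for cfg, p_val in spec.p2[v].items():
            mask = np.all(parent_states == np.array(cfg, dtype=np.int8), axis=1)
            prob[mask] = p_val
        states[v] = 1 + (rng.random(n) < prob).astype(np.int8)
    return np.stack([states[v] for v in spec.observables], axis=1)


def exact_joint(spec: PBNSpec) -> tuple[np.ndarray, np.ndarray]:
    """Enumerate the joint distribution over all variables.

    Returns (configs, probs) where configs is (2^m, m) over
    ``spec.variables`` order with values in {1, 2} and probs sums to 1.
    """
    m = len(spec.variables)
    if m > 20:
        raise ValueError("too many variables for enumeration")
    idx = {v: i for i, v in enumerate(spec.variables)}
    configs = np.array(list(itertools.product((1, 2), repeat=m)), dtype=np.int8)
    probs = np.ones(configs.shape[0])
    for v in spec.variables:
        pars = spec.parents[v]
        col = configs[:, idx[v]]
        if not pars:
            p_two = np.full(configs.shape[0], spec.p2[v][()])
        else:
            p_two = np.empty(configs.shape[0])
            parent_states = configs[:, [idx[p] for p in pars]]
            for cfg, p_val in spec.p2[v].items():
                mask = np.all(parent_states == np.array(cfg, dtype=np.int8), axis=1)
                p_two[mask] = p_val
        probs *= np.where(col == 2, p_two, 1.0 - p_two)
    return configs, probs


def observable_joint(spec: PBNSpec) -> tuple[np.ndarray, np.ndarray]:
    """Marginal joint distribution of the observable variables."""
    configs, probs = exact_joint(spec)
    idx = [spec.variables.index(v) for v in spec.observables]
    obs = configs[:, idx]
    table: dict[Config, float] = {}
    for row, p in zip(obs, probs):
        table[tuple(int(x) for x in row)] = table.get(tuple(int(x) for x in row), 0.0) + p
    keys = sorted(table)
    return np.array(keys, dtype=np.int8), np.array([table[k] for k in keys])


def spike_count_samples(
    states: np.ndarray,
    cfg: SpikeConfig | None = None,
    rng: np.random.Generator | int = 0,
) -> SampleMatrix:
    """Poisson population spike counts for binary rate states, centered.

    Each population of independent Poisson neurons yields a Poisson
    population count with mean ``mean_low`` (state 1) or ``mean_high``
    (state 2) per bin. Counts are normalized to zero mean per component.
    """
    cfg = cfg or SpikeConfig()
    rng = np.random.default_rng(rng)
    states = np.asarray(states)
    means = np.where(states == 2, cfg.mean_high, cfg.mean_low)
    counts = rng.poisson(means).astype(float)
    return center_samples(counts.T)


@dataclass
class CountMoments:
    """Exact moments of the centered population counts.

    ``cov`` includes the Poisson noise variance on its diagonal;
    off-diagonal entries and all entries of ``third`` (valid for
    distinct index triples) coincide with the central moments of the
    conditional count means, because the Poisson noise is independent
    across populations given the binary states.
    """

    means: np.ndarray
    cov: np.ndarray
    third: np.ndarray  # (d, d, d); meaningful for distinct indices

    @property
    def corr(self) -> np.ndarray:
        sd = np.sqrt(np.diag(self.cov))
        return self.cov / sd[:, None] / sd[None, :]


def exact_count_moments(spec: PBNSpec, cfg: SpikeConfig | None = None) -> CountMoments:
    """Closed-form first/second/third moments of the population counts."""
    cfg = cfg or SpikeConfig()
    obs_configs, probs = observable_joint(spec)
    mu = np.where(obs_configs == 2, cfg.mean_high, cfg.mean_low).astype(float)
    means = probs @ mu
    centered = mu - means
    cov = (centered * probs[:, None]).T @ centered
    cov += np.diag(probs @ mu)  # Poisson noise variance per component
    third = np.einsum("n,ni,nj,nk->ijk", probs, centered, centered, centered)
    return CountMoments(means=means, cov=cov, third=third)


def population_b_matrix(spec: PBNSpec, cfg: SpikeConfig | None = None) -> np.ndarray:
    """Exact moment-ratio matrix of the counts; NaN diagonal.

    B_kl = E[s_k s_l s_d] / (E[s_k s_d] E[s_l s_d]) on centered counts,
    with d the last observable (the reference).
    """
    mom = exact_count_moments(spec, cfg)
    d = mom.means.shape[0]
    ref = d - 1
    n = d - 1
    b = np.full((n, n), np.nan)
    for k in range(n):
        for l in range(n):
            if k == l:
                continue
            b[k, l] = mom.third[k, l, ref] / (mom.cov[k, ref] * mom.cov[l, ref])
    return b


def linear_r2(spec: PBNSpec, target: str = "x5") -> float:
    """R^2 of the optimal linear predictor of one observable from the rest.

    Computed under the exact joint distribution: R^2 = c' C^{-1} c / Var
    where C is the covariance of the predictors and c their covariance
    with the target.
    """
    obs_configs, probs = observable_joint(spec)
    names = spec.observables
    t = names.index(target)
    x = obs_configs.astype(float)
    means = probs @ x
    centered = x - means
    cov = (centered * probs[:, None]).T @ centered
    pred = [i for i in range(len(names)) if i != t]
    c = cov[np.ix_(pred, [t])].ravel()
    cc = cov[np.ix_(pred, pred)]
    var_t = cov[t, t]
    if var_t == 0:
        raise ValueError("target has zero variance")
    explained = float(c @ np.linalg.solve(cc, c))
    return explained / float(var_t)


def linear_surrogate(
    s: SampleMatrix,
    rng: np.random.Generator | int = 0,
    standardize: bool = True,
) -> SampleMatrix:
    """Covariance-matched linear surrogate of a centered sample matrix.

    Each component is permuted independently across samples, destroying
    all cross-component dependencies, then (optionally) scaled to unit
    variance and mixed with the Cholesky factor L of the original sample
    covariance so the surrogate's population covariance equals it. The
    surrogate satisfies every modularization that a purely linear model
    does, while matching the recorded correlation matrix.
    """
    if not s.centered:
        raise ValueError("samples must be centered")
    rng = np.random.default_rng(rng)
    cov = np.cov(s.values)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise ValueError("sample covariance is singular") from err
    shuffled = np.stack([rng.permutation(row) for row in s.values])
    if standardize:
        shuffled = shuffled / shuffled.std(axis=1, ddof=0, keepdims=True)
    mixed = chol @ shuffled
    return center_samples(mixed, labels=list(s.labels))
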