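"""Seeded benchmark generators with known ground truth, plus oracles.

The generators cover the standard test systems for directed-information
estimators:

* a bivariate Gaussian pair with known DI,
* a binary symmetric channel driven by a Bernoulli source,
* an 11-node linear-Gaussian autoregressive network (extended path,
  sink, multipath and an isolated node) with closed-form DI/GDI,
* the same topology with squared interactions and uniform sources,
* three-node masking demos (continuous and spiking) in which an
  inhibitory edge hides behind a strong excitatory one,
* a logistic-Bernoulli spiking surrogate producing spike tables.

The oracle functions return exact information values (closed forms for
the Gaussian families, enumeration/plug-in for discrete models) and are
used by the tests as estimator-independent references.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .timeseries import TimeSeriesSet

__all__ = [
    "NetworkSpec",
    "default_network_spec",
    "gen_gaussian_pair",
    "gen_bsc",
    "gen_gaussian_network",
    "gen_nonlinear_network",
    "gen_three_node_demo",
    "gen_spiking_network",
    "analytic_pair_di",
    "analytic_bsc_di",
    "analytic_network_di",
    "analytic_network_gdi",
    "plugin_discrete_mi",
    "plugin_discrete_cmi",
    "binary_entropy",
]


@dataclass
class NetworkSpec:
    """Ground-truth generative description of an autoregressive network.

    ``edges`` maps (source, target) 1-based node ids to signed coupling
    weights beta at unit lag.  Per target node the absolute couplings and
    the noise weight alpha sum to 1, which keeps the linear dynamics
    stationary.  ``interaction`` selects linear or squared coupling;
    ``source_dist`` the marginal of input/isolated nodes.
    """

    n_nodes: int
    edges: list[tuple[int, int, float]]
    interaction: str = "linear"
    source_dist: str = "gaussian"
    noise_sd: float = 1.0
    lags: dict = field(default_factory=dict)  # (j, k) -> lag in samples, default 1

    def __post_init__(self) -> None:
        seen = set()
        for j, k, _ in self.edges:
            if j == k:
                raise ValueError("self-edges are not allowed")
            if not (1 <= j <= self.n_nodes and 1 <= k <= self.n_nodes):
                raise ValueError("edge endpoints out of range")
            if (j, k) in seen:
                raise ValueError(f"duplicate edge ({j}, {k})")
            seen.add((j, k))
        if self.interaction not in ("linear", "squared"):
            raise ValueError("interaction must be 'linear' or 'squared'")
        s = self.beta_matrix()
        if np.any(np.abs(s).sum(axis=0) > 1 + 1e-9):
            raise ValueError("per-target sum of |beta| must not exceed 1")

    def beta_matrix(self) -> np.ndarray:
        B = np.zeros((self.n_nodes, self.n_nodes))
        for j, k, b in self.edges:
            B[j - 1, k - 1] = b
        return B

    def alpha(self) -> np.ndarray:
        """Noise weights: alpha_k = 1 - sum_j |beta_{jk}|."""
        return 1.0 - np.abs(self.beta_matrix()).sum(axis=0)

    def parents(self, k: int) -> list[tuple[int, float]]:
        return [(j, b) for j, kk, b in self.edges if kk == k]

    def source_nodes(self) -> list[int]:
        has_parent = {k for _, k, _ in self.edges}
        return [n for n in range(1, self.n_nodes + 1) if n not in has_parent]

    def true_edge_set(self) -> set[tuple[int, int]]:
        return {(j, k) for j, k, _ in self.edges}

    def to_json(self) -> str:
        return json.dumps({
            "n_nodes": self.n_nodes,
            "edges": [[j, k, b] for j, k, b in self.edges],
            "interaction": self.interaction,
            "source_dist": self.source_dist,
            "noise_sd": self.noise_sd,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        d = json.loads(text)
        return cls(n_nodes=d["n_nodes"],
                   edges=[tuple(e) for e in d["edges"]],
                   interaction=d.get("interaction", "linear"),
                   source_dist=d.get("source_dist", "gaussian"),
                   noise_sd=d.get("noise_sd", 1.0))


# Default 11-node topology: extended path 6->1->4->11, sink {6,8,9}->2,
# multipath 6->3->10 and 6->5->10, node 7 isolated.  Edges 6->1 and 5->10
# are inhibitory.  Extended-path couplings are stronger (0.65) than the
# fan-out/multipath ones (0.45) so that third-hop influence survives the
# squared interaction of the nonlinear variant; sink couplings are weak
# (0.25) to exercise the conditioning gain at the sink.
_DEFAULT_EDGES = [
    (6, 1, -0.65), (1, 4, 0.65), (4, 11, 0.65),
    (6, 3, 0.45), (6, 5, 0.45),
    (3, 10, 0.45), (5, 10, -0.45),
    (6, 2, 0.25), (8, 2, 0.25), (9, 2, 0.25),
]


def default_network_spec(interaction: str = "linear") -> NetworkSpec:
    """The 11-node benchmark topology shared by all network generators."""
    return NetworkSpec(n_nodes=11, edges=list(_DEFAULT_EDGES),
                       interaction=interaction,
                       source_dist="gaussian" if interaction == "linear" else "uniform",
                       noise_sd=1.0 if interaction == "linear" else 0.5)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def gen_gaussian_pair(rho: float, N: int, seed=0) -> TimeSeriesSet:
    """Bivariate Gaussian model: (X_{i-1}, Y_i) ~ N(0, [[1, rho], [rho, 1]]).

    ``N`` is the number of independent (past, current) sample pairs; the
    returned series has T = 2N samples laid out so that non-overlapping
    windows with M = 1 recover exactly those pairs (remaining slots are
    filled with independent unit Gaussians).
    """
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    rng = np.random.default_rng(seed)
    x = rng.normal(size=2 * N)
    y = rng.normal(size=2 * N)
    # window w covers times (2w, 2w+1); Y current = correlated copy of X past
    y[1::2] = rho * x[0::2] + np.sqrt(1 - rho ** 2) * rng.normal(size=N)
    return TimeSeriesSet(np.column_stack([x, y]), channel_names=["X", "Y"])


def gen_bsc(p_flip: float, bern_p: float, N: int, seed=0) -> TimeSeriesSet:
    """Binary symmetric channel: X iid Bernoulli, Y_i = X_{i-1} xor flip.

    ``N`` counts (past, current) pairs; T = 2N as in :func:`gen_gaussian_pair`.
    """
    if not 0 <= p_flip <= 0.5:
        raise ValueError("p_flip must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    x = (rng.random(2 * N) < bern_p).astype(float)
    flips = rng.random(2 * N) < p_flip
    y = np.empty(2 * N)
    y[0] = x[0]
    y[1:] = np.where(flips[1:], 1 - x[:-1], x[:-1])
    return TimeSeriesSet(np.column_stack([x, y]), channel_names=["X", "Y"],
                         kind="binary")


def _simulate_network(spec: NetworkSpec, N: int, seed, burn_in: int = 100) -> np.ndarray:
    rng = np.random.default_rng(seed)
    R = spec.n_nodes
    B = spec.beta_matrix()
    alpha = spec.alpha()
    sources = [n - 1 for n in spec.source_nodes()]
    X = np.zeros((N + burn_in, R))
    Z = rng.normal(0.0, spec.noise_sd, size=(N + burn_in, R))
    if spec.source_dist == "uniform":
        U = rng.uniform(0.0, 1.0, size=(N + burn_in, R))
    for i in range(N + burn_in):
        if i == 0:
            drive = np.zeros(R)
        else:
            past = X[i - 1] ** 2 if spec.interaction == "squared" else X[i - 1]
            drive = past @ B
        X[i] = drive + alpha * Z[i]
        if spec.source_dist == "uniform":
            X[i, sources] = U[i, sources]
    return X[burn_in:]


def gen_gaussian_network(spec: NetworkSpec | None = None, N: int = 100_000,
                         seed=0) -> TimeSeriesSet:
    """Linear-Gaussian network x_i^k = sum_j beta_jk x_{i-1}^j + alpha_k z_i^k."""
    spec = spec or default_network_spec("linear")
    if spec.interaction != "linear":
        raise ValueError("gen_gaussian_network requires a linear spec")
    return TimeSeriesSet(_simulate_network(spec, N, seed))


def gen_nonlinear_network(spec: NetworkSpec | None = None, N: int = 100_000,
                          seed=0) -> TimeSeriesSet:
    """Squared-interaction network with Uniform(0,1) sources and
    Gaussian target noise of variance 0.25."""
    spec = spec or default_network_spec("squared")
    if spec.interaction != "squared":
        raise ValueError("gen_nonlinear_network requires a squared spec")
    return TimeSeriesSet(_simulate_network(spec, N, seed))


def gen_three_node_demo(kind: str = "continuous", N: int = 8000,
                        seed=0) -> TimeSeriesSet:
    """Three-node sign-masking demo: W excites Y, X inhibits Y, both with a
    0.125 s delay; X co-oscillates with W so its inhibition is masked.

    Continuous: 1 Hz sinusoids at dt = 1/400 s (the delay is 50 samples);
    X carries a narrow dip on every peak and Y(t) = W(t - 0.125) -
    X(t - 0.125).  Without the dip the inhibitory sign of X would be
    unidentifiable.

    Spikes: binary bins of 25 ms (the delay is 5 bins); W and X fire in
    synchronous periodic bursts, X drops out every fourth cycle, and Y
    spikes in proportion to W minus X activity five bins earlier.
    """
    rng = np.random.default_rng(seed)
    if kind == "continuous":
        dt = 1.0 / 400.0
        delay = 50  # 0.125 s
        t = np.arange(N) * dt
        w = np.sin(2 * np.pi * t)
        phase = t % 1.0
        dip = 0.6 * np.exp(-0.5 * ((phase - 0.25) / 0.02) ** 2)  # at the sine peak
        x = np.sin(2 * np.pi * t) - dip
        y = np.zeros(N)
        y[delay:] = w[:-delay] - x[:-delay]
        noise = 0.01
        vals = np.column_stack([x, y, w]) + rng.normal(0, noise, size=(N, 3))
        return TimeSeriesSet(vals, dt=dt, channel_names=["X", "Y", "W"])
    if kind == "spikes":
        dt = 0.025
        delay = 5  # 0.125 s
        period, burst = 40, 10
        phase = np.arange(N) % period
        in_burst = phase < burst
        cycle = np.arange(N) // period
        dropout = (cycle % 4) == 3
        p_w = np.where(in_burst, 0.8, 0.02)
        p_x = np.where(in_burst & ~dropout, 0.8, 0.02)
        w = (rng.random(N) < p_w).astype(float)
        x = (rng.random(N) < p_x).astype(float)
        y = np.zeros(N)
        logit = -3.0 + 4.0 * np.roll(w, delay) - 2.5 * np.roll(x, delay)
        logit[:delay] = -3.0
        y = (rng.random(N) < 1.0 / (1.0 + np.exp(-logit))).astype(float)
        return TimeSeriesSet(np.column_stack([x, y, w]), dt=dt,
                             channel_names=["X", "Y", "W"], kind="binary")
    raise ValueError("kind must be 'continuous' or 'spikes'")


def gen_spiking_network(spec: NetworkSpec | None = None, T: float = 300.0,
                        bin_width: float = 0.035, seed=0,
                        baseline: float = -1.8, gain: float = 6.0) -> pd.DataFrame:
    """Probabilistic spiking surrogate: logistic-Bernoulli network dynamics.

    Each unit spikes per bin with probability
    ``sigmoid(baseline + gain * sum_j beta_jk * s_j(i - 1))`` where s_j is
    the presynaptic spike indicator.  Returns a (unit, time) spike table;
    spike times are bin centers.  ``spec`` supplies topology and signed
    weights (its alpha/noise fields are unused here).
    """
    spec = spec or default_network_spec("linear")
    rng = np.random.default_rng(seed)
    n_bins = int(np.floor(T / bin_width))
    R = spec.n_nodes
    Bm = spec.beta_matrix()
    S = np.zeros((n_bins, R))
    S[0] = rng.random(R) < 1.0 / (1.0 + np.exp(-baseline))
    for i in range(1, n_bins):
        logit = baseline + gain * (S[i - 1] @ Bm)
        S[i] = rng.random(R) < 1.0 / (1.0 + np.exp(-logit))
    units, times = np.nonzero(S.T)
    return pd.DataFrame({
        "unit": units + 1,
        "time": (times + 0.5) * bin_width,
    })


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def binary_entropy(p: float) -> float:
    """Entropy of a Bernoulli(p) in nats."""
    if p <= 0 or p >= 1:
        return 0.0
    return float(-p * np.log(p) - (1 - p) * np.log(1 - p))


def analytic_pair_di(rho: float) -> float:
    """DI of the bivariate Gaussian pair: -0.5 ln(1 - rho^2)."""
    return float(-0.5 * np.log(1 - rho ** 2))


def analytic_bsc_di(p_flip: float, bern_p: float) -> float:
    """Exact DI of the binary symmetric channel, by enumeration of the
    2x2 joint distribution: H_b(marginal of Y) - H_b(p_flip)."""
    p_y = bern_p * (1 - p_flip) + (1 - bern_p) * p_flip
    return binary_entropy(p_y) - binary_entropy(p_flip)


def _edge_weight(spec: NetworkSpec, j: int, k: int) -> float:
    for jj, kk, b in spec.edges:
        if (jj, kk) == (j, k):
            return b
    raise ValueError(f"({j}, {k}) is not an edge of the spec")


def analytic_network_di(spec: NetworkSpec, j: int, k: int) -> float:
    """Closed-form pairwise DI for an edge of the linear-Gaussian network.

    Source-fed single-input targets: 0.5 ln(1 + beta^2 / alpha_k^2);
    multi-input targets see the other couplings as extra noise:
    0.5 ln(1 + beta^2 / (alpha_k^2 + sum_l beta_{lk}^2)).  Assumes the
    parent has unit variance (exact when the parent is a source node).
    """
    if spec.interaction != "linear":
        raise ValueError("closed forms exist only for the linear network")
    beta = _edge_weight(spec, j, k)
    alpha = spec.alpha()
    others = sum(b ** 2 for jj, b in spec.parents(k) if jj != j)
    return float(0.5 * np.log1p(beta ** 2 / (alpha[k - 1] ** 2 + others)))


def analytic_network_gdi(spec: NetworkSpec, j: int, k: int) -> float:
    """Closed-form GDI for an edge of the linear-Gaussian network.

    Conditioning removes the other parents of k, so any edge obeys
    0.5 ln(1 + beta^2 sigma_j^2 / alpha_k^2) where sigma_j^2 is the
    conditional variance of the source given everything observed:
    1 for source nodes, alpha_j^2 for driven nodes.  Off-edges have GDI 0.
    """
    if spec.interaction != "linear":
        raise ValueError("closed forms exist only for the linear network")
    if (j, k) not in spec.true_edge_set():
        return 0.0
    beta = _edge_weight(spec, j, k)
    alpha = spec.alpha()
    sigma_j2 = 1.0 if j in spec.source_nodes() else alpha[j - 1] ** 2
    return float(0.5 * np.log1p(beta ** 2 * sigma_j2 / alpha[k - 1] ** 2))


def _codes(X: np.ndarray) -> np.ndarray:
    """Factorize rows of a discrete block into integer codes."""
    X = np.asarray(X)
    if X.ndim == 1:
        X = X[:, None]
    elif X.shape[0] == 1 and X.shape[1] > 1:
        X = X.T
    _, inv = np.unique(X, axis=0, return_inverse=True)
    return inv.ravel()


def plugin_discrete_mi(A: np.ndarray, B: np.ndarray) -> float:
    """Empirical plug-in MI (nats) between discrete blocks A and B."""
    a = _codes(A)
    b = _codes(B)
    n = len(a)
    joint = pd.crosstab(a, b).to_numpy() / n
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    return float(np.sum(joint[mask] * np.log(joint[mask] / (pa @ pb)[mask])))


def plugin_discrete_cmi(A: np.ndarray, B: np.ndarray, Z: np.ndarray) -> float:
    """Empirical plug-in conditional MI (nats) for discrete blocks."""
    if Z is None or np.size(Z) == 0:
        return plugin_discrete_mi(A, B)
    a = _codes(A)
    b = _codes(B)
    z = _codes(Z)
    total = 0.0
    for zv in np.unique(z):
        m = z == zv
        total += m.mean() * plugin_discrete_mi(a[m], b[m])
    return float(total)
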