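"""Classifier-based estimation of KL divergence, MI and conditional MI.

The estimator follows the Donsker-Varadhan route: a probabilistic binary
classifier is trained to separate samples of the dependent distribution p
from samples of an independence surrogate q (row-permuted copies).  Its
pointwise likelihood ratio L(x) = P(l=1|x) / (1 - P(l=1|x)) plugs into

    D_KL(p || q)  ~=  mean_p log L  -  log mean_q L,

and MI is the KL divergence between the joint and the product of block
marginals.  Conditional MI is the difference of two MI terms that share
the same A block; both terms are estimated with identical bootstrap
splits and permutations so that their correlated biases cancel in the
difference.

All information values are in nats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._ratio_net import MLPRatioNet
from .embedding import SamplePairSet

__all__ = [
    "ClassifierSpec",
    "EstimatorConfig",
    "MIEstimate",
    "RatioModel",
    "fit_ratio_model",
    "estimate_kl",
    "estimate_mi",
    "estimate_cmi",
]


@dataclass
class ClassifierSpec:
    """Architecture and training knobs of the ratio classifier.

    ``prob_clip`` bounds predicted probabilities into
    ``[prob_clip, 1 - prob_clip]`` so the likelihood ratio stays finite;
    it must lie in (0, 0.5).  ``gaussian_feature`` enables the closed-form
    Gaussian discriminant input (with squares of the A block when
    ``square_a``); ``ridge`` regularizes its covariance estimate.
    """

    hidden_layers: tuple[int, ...] = (64, 64)
    activation: str = "relu"
    max_epochs: int = 60
    batch_size: int = 256
    learning_rate: float = 2e-3
    prob_clip: float = 1e-3
    val_fraction: float = 0.15
    patience: int = 6
    gaussian_feature: bool = True
    square_a: bool = True
    ridge: float = 1e-2
    calibrate: bool = True

    def __post_init__(self) -> None:
        self.hidden_layers = tuple(self.hidden_layers)
        if not 0 < self.prob_clip < 0.5:
            raise ValueError("prob_clip must lie in (0, 0.5)")
        if self.activation != "relu":
            raise ValueError("only 'relu' activation is supported")


@dataclass
class EstimatorConfig:
    """Bootstrap schedule and classifier settings for MI estimation.

    Each of the ``bootstrap_iters`` iterations draws a fresh 2/3-train /
    1/3-test row split (``train_fraction``) and a fresh permutation of the
    A block, trains the classifier, and evaluates the KL plug-in on the
    held-out third; the reported value is the arithmetic mean.
    ``n_q_eval`` controls how many independent permutations of the test
    rows are pooled when evaluating the q-side average, which reduces the
    variance of the log-mean term.
    """

    bootstrap_iters: int = 10
    train_fraction: float = 2.0 / 3.0
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    seed: int = 0
    n_q_eval: int = 8

    def __post_init__(self) -> None:
        if self.bootstrap_iters < 1:
            raise ValueError("bootstrap_iters must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class MIEstimate:
    """Bootstrap-averaged information estimate (nats) with its trace."""

    value: float
    per_iteration: list[float]
    n_samples_test: int

    def cumulative_mean(self) -> np.ndarray:
        trace = np.asarray(self.per_iteration, dtype=float)
        return np.cumsum(trace) / np.arange(1, len(trace) + 1)


class RatioModel:
    """Fitted likelihood-ratio model with standardization and clipping."""

    def __init__(self, net: MLPRatioNet, mean: np.ndarray, scale: np.ndarray,
                 prob_clip: float, calibrated: bool):
        self._net = net
        self._mean = mean
        self._scale = scale
        self._calibrated = calibrated
        self.prob_clip = prob_clip
        self._logit_cap = float(np.log((1 - prob_clip) / prob_clip))

    @property
    def n_features(self) -> int:
        return len(self._mean)

    def log_ratio(self, x: np.ndarray) -> np.ndarray:
        """Clipped pointwise log-likelihood ratio log L(x)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.n_features:
            raise ValueError(
                f"dimensionality mismatch: model expects {self.n_features}, got {x.shape[1]}")
        xs = ((x - self._mean) / self._scale).astype(np.float32)
        z = (self._net.calibrated_logit(xs) if self._calibrated
             else self._net.logit(xs))
        return np.clip(z.astype(float), -self._logit_cap, self._logit_cap)

    def likelihood_ratio(self, x: np.ndarray) -> np.ndarray:
        """Pointwise L(x) = P(l=1|x)/(1-P(l=1|x)), probability clipped."""
        return np.exp(self.log_ratio(x))


def fit_ratio_model(train_p: np.ndarray, train_q: np.ndarray,
                    spec: ClassifierSpec | None = None, seed=0,
                    a_cols: np.ndarray | None = None) -> RatioModel:
    """Train the p-vs-q classifier and wrap it as a :class:`RatioModel`.

    ``a_cols`` (optional) tells the Gaussian discriminant feature which
    columns form the permuted A block; without it the feature is skipped
    and a plain MLP is trained.  Training is fully seeded.
    """
    spec = spec or ClassifierSpec()
    train_p = np.atleast_2d(np.asarray(train_p, dtype=float))
    train_q = np.atleast_2d(np.asarray(train_q, dtype=float))
    if train_p.size == 0 or train_q.size == 0:
        raise ValueError("training sets must be non-empty")
    if train_p.shape[1] != train_q.shape[1]:
        raise ValueError("dimensionality mismatch between p and q samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    both = np.vstack([train_p, train_q])
    mean = both.mean(axis=0)
    scale = both.std(axis=0)
    scale[scale == 0] = 1.0

    net = MLPRatioNet(
        hidden_layers=spec.hidden_layers,
        learning_rate=spec.learning_rate,
        batch_size=spec.batch_size,
        max_epochs=spec.max_epochs,
        val_fraction=spec.val_fraction,
        patience=spec.patience,
        ridge=spec.ridge,
        use_gaussian_feature=spec.gaussian_feature,
        square_a=spec.square_a,
    )
    net.fit(((train_p - mean) / scale).astype(np.float32),
            ((train_q - mean) / scale).astype(np.float32),
            rng, a_cols=a_cols)
    return RatioModel(net, mean, scale, spec.prob_clip, spec.calibrate)


def estimate_kl(test_p: np.ndarray, test_q: np.ndarray, model: RatioModel) -> float:
    """Donsker-Varadhan plug-in estimate of D_KL(p || q) in nats."""
    test_p = np.atleast_2d(np.asarray(test_p, dtype=float))
    test_q = np.atleast_2d(np.asarray(test_q, dtype=float))
    if test_p.size == 0 or test_q.size == 0:
        raise ValueError("test sets must be non-empty")
    log_lp = model.log_ratio(test_p)
    log_lq = model.log_ratio(test_q)
    return float(np.mean(log_lp) - np.log(np.mean(np.exp(log_lq))))


def _bootstrap_schedule(cfg: EstimatorConfig) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(cfg.seed).spawn(cfg.bootstrap_iters)


def _estimate_mi_scheduled(pair: SamplePairSet, cfg: EstimatorConfig,
                           schedule: list[np.random.SeedSequence]) -> MIEstimate:
    n = pair.n_windows
    if n < 3:
        raise ValueError("need at least 3 windows to split train/test")
    a_idx = pair.block_index
    values = []
    n_test = 0
    for ss in schedule:
        rng = np.random.default_rng(ss)
        perm = rng.permutation(n)
        split = rng.permutation(n)
        n_train = int(n * cfg.train_fraction)
        tr, te = split[:n_train], split[n_train:]
        n_test = len(te)

        q = pair.joint.copy()
        q[:, a_idx] = pair.joint[perm][:, a_idx]
        model = fit_ratio_model(pair.joint[tr], q[tr], cfg.classifier,
                                seed=rng, a_cols=a_idx)
        # pooled permutations of the held-out rows for the q-side average
        q_test = []
        for _ in range(max(1, cfg.n_q_eval)):
            pm = rng.permutation(len(te))
            qt = pair.joint[te].copy()
            qt[:, a_idx] = pair.joint[te][pm][:, a_idx]
            q_test.append(qt)
        values.append(estimate_kl(pair.joint[te], np.vstack(q_test), model))
    return MIEstimate(value=float(np.mean(values)),
                      per_iteration=[float(v) for v in values],
                      n_samples_test=n_test)


def estimate_mi(pair: SamplePairSet, cfg: EstimatorConfig | None = None) -> MIEstimate:
    """Bootstrap-averaged MI between the A and B blocks of ``pair``."""
    cfg = cfg or EstimatorConfig()
    return _estimate_mi_scheduled(pair, cfg, _bootstrap_schedule(cfg))


def estimate_cmi(A: np.ndarray, B: np.ndarray, Z: np.ndarray | None,
                 cfg: EstimatorConfig | None = None) -> MIEstimate:
    """I(A; B | Z) = I(A; B, Z) - I(A; Z), with a shared bootstrap schedule.

    ``A``, ``B``, ``Z`` are row-aligned sample blocks; ``Z`` may be None
    or have zero columns, in which case the estimate reduces to the plain
    MI between A and B.
    """
    cfg = cfg or EstimatorConfig()
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.ndim == 2 and A.shape[0] == 1 and B.shape[0] != 1:
        A = A.T
    if B.shape[0] == 1 and A.shape[0] != 1:
        B = B.T
    if Z is None or np.size(Z) == 0:
        a_idx = np.arange(A.shape[1])
        joint = np.hstack([A, B])
        pair = SamplePairSet(joint, permute_rows(joint, a_idx, cfg.seed), a_idx)
        return estimate_mi(pair, cfg)
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] == 1 and A.shape[0] != 1:
        Z = Z.T
    if not (A.shape[0] == B.shape[0] == Z.shape[0]):
        raise ValueError("A, B, Z must be row-aligned")

    a_idx = np.arange(A.shape[1])
    joint_full = np.hstack([A, B, Z])
    joint_red = np.hstack([A, Z])
    schedule = _bootstrap_schedule(cfg)
    pair_full = SamplePairSet(joint_full, permute_rows(joint_full, a_idx, cfg.seed), a_idx)
    pair_red = SamplePairSet(joint_red, permute_rows(joint_red, a_idx, cfg.seed), a_idx)
    est_full = _estimate_mi_scheduled(pair_full, cfg, schedule)
    est_red = _estimate_mi_scheduled(pair_red, cfg, schedule)
    trace = [a - b for a, b in zip(est_full.per_iteration, est_red.per_iteration)]
    return MIEstimate(value=float(np.mean(trace)), per_iteration=trace,
                      n_samples_test=est_full.n_samples_test)


def permute_rows(joint: np.ndarray, a_idx: np.ndarray, seed) -> np.ndarray:
    """Seeded A-block row permutation (thin wrapper for internal use)."""
    from .embedding import permute_block

    return permute_block(joint, a_idx, seed)
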