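"""Directed-information graphs: pairwise DI, conditional DI and full GDI.

The pairwise DI from channel j to channel k is the MI between the M past
samples of j and the current sample of k, conditioned on k's own past.
GDI additionally conditions on the pasts of other channels — all of them,
or only those with appreciable incoming normalized DI to the target
(``di-thresholded`` policy, threshold 0.01) when samples are scarce.
Edge weights are signed: magnitude from (normalized) GDI, sign from the
time-lagged partial correlation.

For binary (spike) data, values are normalized by the plug-in conditional
entropy of the target's current sample given its own past, H(Y_i | Y
past), which bounds DI from above, giving weights on a common 0..1 scale.
Spike analyses may sweep several bin widths and average magnitudes and
signs across them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classifier_mi import EstimatorConfig, MIEstimate, _estimate_mi_scheduled
from .embedding import SamplePairSet, embed_windows, permute_block
from .signs import infer_sign
from .timeseries import TimeSeriesSet, bin_spike_trains

logger = logging.getLogger(__name__)

__all__ = [
    "DIGraph",
    "EdgeRecord",
    "GraphConfig",
    "estimate_di",
    "estimate_gdi",
    "select_conditioning_set",
    "normalize_di",
    "conditional_entropy",
    "build_graph",
    "average_over_bin_widths",
]


@dataclass
class EdgeRecord:
    """Everything known about one directed edge j -> k."""

    raw_di: float | None = None
    raw_gdi: float | None = None
    normalized: float | None = None
    sign: int = 0                     # -1, +1, or 0 = undetermined
    weight: float = 0.0
    tau_star: int | None = None
    conditioning: tuple = ()
    error: str | None = None


@dataclass
class DIGraph:
    """Directed weighted graph with signed DI/GDI edge weights."""

    nodes: list[str]
    edges: dict = field(default_factory=dict)  # (j_name, k_name) -> EdgeRecord
    config: dict = field(default_factory=dict)

    def weight_matrix(self, attr: str = "weight") -> np.ndarray:
        R = len(self.nodes)
        W = np.zeros((R, R))
        idx = {n: i for i, n in enumerate(self.nodes)}
        for (j, k), rec in self.edges.items():
            v = getattr(rec, attr)
            W[idx[j], idx[k]] = np.nan if v is None else v
        return W

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (j, k), rec in sorted(self.edges.items()):
            rows.append({
                "source": j, "target": k,
                "raw_di_nats": rec.raw_di, "raw_gdi_nats": rec.raw_gdi,
                "normalized": rec.normalized,
                "sign": rec.sign if rec.sign != 0 else None,
                "weight": rec.weight, "tau_star_samples": rec.tau_star,
            })
        cols = ["source", "target", "raw_di_nats", "raw_gdi_nats",
                "normalized", "sign", "weight", "tau_star_samples"]
        return pd.DataFrame(rows, columns=cols)

    def to_networkx(self):
        import networkx as nx

        G = nx.DiGraph()
        G.add_nodes_from(self.nodes)
        for (j, k), rec in self.edges.items():
            if rec.weight != 0:
                G.add_edge(j, k, weight=rec.weight, sign=rec.sign)
        return G


@dataclass
class GraphConfig:
    """Settings for assembling a DI graph from a series."""

    M: int = 3
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    mode: str = "graphical"                    # "pairwise" | "graphical"
    conditioning_policy: str = "all-others"    # "all-others" | "di-thresholded"
    di_threshold: float = 0.01
    normalize: bool | None = None              # None = auto (binary only)
    floor_negative: bool = True
    bin_widths: tuple[float, ...] = ()
    sign_lag_range: tuple[int, int] | None = None  # (lo, hi) inclusive, negative
    pairwise_di: bool | None = None            # None = only when needed

    def __post_init__(self) -> None:
        if self.mode not in ("pairwise", "graphical"):
            raise ValueError("mode must be 'pairwise' or 'graphical'")
        if self.conditioning_policy not in ("all-others", "di-thresholded"):
            raise ValueError("unknown conditioning policy")
        if self.di_threshold < 0:
            raise ValueError("di_threshold must be >= 0")
        if self.bin_widths:
            bw = tuple(float(w) for w in self.bin_widths)
            if len(set(bw)) != len(bw) or any(w <= 0 for w in bw):
                raise ValueError("bin_widths must be positive and distinct")
            self.bin_widths = bw

    def sign_lags(self) -> range:
        if self.sign_lag_range is not None:
            lo, hi = self.sign_lag_range
        else:
            lo, hi = -5 * self.M, -1
        if lo > hi or hi > -1:
            raise ValueError("sign lag range must be negative, lo <= hi <= -1")
        return range(lo, hi + 1)


# ---------------------------------------------------------------------------
# per-edge estimation
# ---------------------------------------------------------------------------

def _edge_seed(base_seed: int, *key: int) -> int:
    """Order-independent per-edge substream seed (< 2**31)."""
    ss = np.random.SeedSequence([int(base_seed) & 0x7FFFFFFF, *[int(x) for x in key]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _blocks(series: TimeSeriesSet, M: int, j: int, k: int,
            conditioning: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    wins = embed_windows(series, M)
    A = wins[:, :M, j]
    cur = wins[:, M, k][:, None]
    pasts = [wins[:, :M, k]] + [wins[:, :M, c] for c in conditioning]
    return A, cur, np.concatenate(pasts, axis=1)


def _coupled_cmi(A, cur, Z, est: EstimatorConfig) -> MIEstimate:
    from .classifier_mi import estimate_cmi

    return estimate_cmi(A, cur, Z, est)


def estimate_di(series: TimeSeriesSet, j, k,
                cfg: GraphConfig | None = None) -> MIEstimate:
    """Raw pairwise DI (nats) from channel j to channel k."""
    cfg = cfg or GraphConfig()
    j = series.channel_index(j)
    k = series.channel_index(k)
    if j == k:
        raise ValueError("source and target must differ")
    A, cur, Z = _blocks(series, cfg.M, j, k, ())
    est = replace(cfg.estimator, seed=_edge_seed(cfg.estimator.seed, 0, j, k))
    return _coupled_cmi(A, cur, Z, est)


def estimate_gdi(series: TimeSeriesSet, j, k, conditioning_set=None,
                 cfg: GraphConfig | None = None) -> MIEstimate:
    """Raw GDI (nats): DI conditioned on the pasts of ``conditioning_set``
    (default: all channels other than j and k)."""
    cfg = cfg or GraphConfig()
    j = series.channel_index(j)
    k = series.channel_index(k)
    if j == k:
        raise ValueError("source and target must differ")
    if conditioning_set is None:
        cond = tuple(r for r in range(series.n_channels) if r not in (j, k))
    else:
        cond = tuple(series.channel_index(c) for c in conditioning_set)
    if j in cond or k in cond:
        raise ValueError("conditioning set may not contain j or k")
    A, cur, Z = _blocks(series, cfg.M, j, k, cond)
    est = replace(cfg.estimator, seed=_edge_seed(cfg.estimator.seed, 1, j, k))
    return _coupled_cmi(A, cur, Z, est)


def select_conditioning_set(pairwise_normalized_di: np.ndarray, j: int, k: int,
                            threshold: float) -> tuple[int, ...]:
    """Channels r (other than j, k) whose incoming normalized DI to the
    target, DI(r -> k), is at least ``threshold``."""
    D = np.asarray(pairwise_normalized_di)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("pairwise DI matrix must be square")
    R = D.shape[0]
    return tuple(r for r in range(R)
                 if r not in (j, k) and D[r, k] >= threshold)


def normalize_di(raw: float, target_entropy: float) -> float:
    """Scale a raw DI value by the target's conditional entropy into [0, 1]."""
    if target_entropy <= 0:
        raise ValueError("target entropy must be positive (constant channel?)")
    v = raw / target_entropy
    if v < 0 or v > 1:
        warnings.warn(f"normalized DI {v:.3f} outside [0, 1]; clipping",
                      stacklevel=2)
    return float(np.clip(v, 0.0, 1.0))


def conditional_entropy(series: TimeSeriesSet, k, M: int) -> float:
    """Plug-in conditional entropy H(Y_i | Y_{i-M..i-1}) in nats for a
    binary channel, from empirical frequencies over sliding windows."""
    if series.kind != "binary":
        raise ValueError("plug-in conditional entropy requires binary data")
    k = series.channel_index(k)
    y = series.values[:, k].astype(int)
    T = len(y)
    if T <= M:
        raise ValueError("series too short")
    past = np.zeros(T - M, dtype=np.int64)
    for m in range(M):
        past = past * 2 + y[m: T - M + m]
    cur = y[M:]
    joint = past * 2 + cur

    def _H(codes: np.ndarray) -> float:
        _, counts = np.unique(codes, return_counts=True)
        p = counts / counts.sum()
        return float(-(p * np.log(p)).sum())

    return _H(joint) - _H(past)


# ---------------------------------------------------------------------------
# whole-graph assembly
# ---------------------------------------------------------------------------

def _gdi_all_pairs_shared(series: TimeSeriesSet, cfg: GraphConfig) -> dict:
    """GDI for every ordered pair under all-others conditioning.

    For a fixed source j the reduced MI term I(past_j ; all other pasts)
    does not depend on the target, so it is estimated once per source and
    shared across the R-1 edges, with a common bootstrap schedule so the
    correlated estimator bias cancels in each difference.
    """
    from .classifier_mi import _bootstrap_schedule

    R = series.n_channels
    M = cfg.M
    wins = embed_windows(series, M)
    out = {}
    for j in range(R):
        est_j = replace(cfg.estimator, seed=_edge_seed(cfg.estimator.seed, 1, j))
        schedule = _bootstrap_schedule(est_j)
        A = wins[:, :M, j]
        others = [r for r in range(R) if r != j]
        pasts = np.concatenate([wins[:, :M, r] for r in others], axis=1)
        a_idx = np.arange(M)
        joint_red = np.hstack([A, pasts])
        pair_red = SamplePairSet(joint_red, permute_block(joint_red, a_idx, est_j.seed),
                                 a_idx)
        red = _estimate_mi_scheduled(pair_red, est_j, schedule)
        for k in others:
            cur = wins[:, M, k][:, None]
            joint_full = np.hstack([A, cur, pasts])
            pair_full = SamplePairSet(joint_full,
                                      permute_block(joint_full, a_idx, est_j.seed),
                                      a_idx)
            full = _estimate_mi_scheduled(pair_full, est_j, schedule)
            trace = [a - b for a, b in zip(full.per_iteration, red.per_iteration)]
            out[(j, k)] = MIEstimate(value=float(np.mean(trace)),
                                     per_iteration=trace,
                                     n_samples_test=full.n_samples_test)
    return out


def build_graph(series: TimeSeriesSet, cfg: GraphConfig | None = None) -> DIGraph:
    """Estimate the full signed DI/GDI graph of a multichannel series."""
    cfg = cfg or GraphConfig()
    R = series.n_channels
    if R < 2:
        raise ValueError("need at least 2 channels")
    normalize = cfg.normalize if cfg.normalize is not None else series.kind == "binary"
    if normalize and series.kind != "binary":
        raise ValueError("normalization is defined for binary series only")

    need_di = (cfg.mode == "pairwise"
               or cfg.conditioning_policy == "di-thresholded"
               or bool(cfg.pairwise_di))

    entropies = {}
    if normalize:
        for k in range(R):
            entropies[k] = conditional_entropy(series, k, cfg.M)

    def _norm(raw: float, k: int) -> float | None:
        if not normalize:
            return None
        return normalize_di(max(raw, 0.0), entropies[k])

    di_vals: dict[tuple[int, int], MIEstimate] = {}
    di_norm = np.zeros((R, R))
    if need_di:
        for j in range(R):
            for k in range(R):
                if j == k:
                    continue
                try:
                    di_vals[(j, k)] = estimate_di(series, j, k, cfg)
                except Exception as exc:  # per-edge failures are recorded
                    logger.warning("DI %d->%d failed: %s", j, k, exc)
                    continue
                if normalize:
                    v = _norm(di_vals[(j, k)].value, k)
                    di_norm[j, k] = v if v >= cfg.di_threshold else 0.0
                else:
                    di_norm[j, k] = max(di_vals[(j, k)].value, 0.0)

    edges: dict = {}
    names = series.channel_names

    if cfg.mode == "pairwise":
        for (j, k), est in di_vals.items():
            rec = EdgeRecord(raw_di=est.value)
            rec.normalized = _norm(est.value, k)
            mag = rec.normalized if normalize else est.value
            if cfg.floor_negative:
                mag = max(mag, 0.0)
            rec.sign, rec.tau_star = infer_sign(series, j, k, (), cfg.sign_lags())
            rec.weight = rec.sign * abs(mag) if rec.sign != 0 else abs(mag)
            edges[(names[j], names[k])] = rec
        return DIGraph(nodes=list(names), edges=edges, config=_config_echo(cfg, series))

    # graphical mode
    gdi_vals: dict[tuple[int, int], MIEstimate] = {}
    cond_sets: dict[tuple[int, int], tuple[int, ...]] = {}
    if cfg.conditioning_policy == "all-others":
        gdi_vals = _gdi_all_pairs_shared(series, cfg)
        for (j, k) in gdi_vals:
            cond_sets[(j, k)] = tuple(r for r in range(R) if r not in (j, k))
    else:
        for j in range(R):
            for k in range(R):
                if j == k:
                    continue
                cond = select_conditioning_set(di_norm, j, k, cfg.di_threshold)
                cond_sets[(j, k)] = cond
                try:
                    gdi_vals[(j, k)] = estimate_gdi(series, j, k, cond, cfg)
                except Exception as exc:
                    logger.warning("GDI %d->%d failed: %s", j, k, exc)

    for (j, k), est in gdi_vals.items():
        rec = EdgeRecord(raw_gdi=est.value,
                         raw_di=di_vals[(j, k)].value if (j, k) in di_vals else None,
                         conditioning=tuple(names[c] for c in cond_sets[(j, k)]))
        rec.normalized = _norm(est.value, k)
        if normalize:
            mag = rec.normalized if rec.normalized >= cfg.di_threshold else 0.0
        else:
            mag = est.value
        if cfg.floor_negative:
            mag = max(mag, 0.0)
        rec.sign, rec.tau_star = infer_sign(series, j, k, cond_sets[(j, k)],
                                            cfg.sign_lags())
        rec.weight = rec.sign * abs(mag) if rec.sign != 0 else abs(mag)
        edges[(names[j], names[k])] = rec
    return DIGraph(nodes=list(names), edges=edges, config=_config_echo(cfg, series))


def _config_echo(cfg: GraphConfig, series: TimeSeriesSet) -> dict:
    return {
        "M": cfg.M, "mode": cfg.mode, "policy": cfg.conditioning_policy,
        "di_threshold": cfg.di_threshold,
        "bootstrap_iters": cfg.estimator.bootstrap_iters,
        "seed": cfg.estimator.seed, "kind": series.kind, "dt": series.dt,
        "n_samples": series.n_samples,
    }


def combine_sign_votes(signs) -> int:
    """Sign of the mean of per-width sign votes; 0 on a tie or no votes."""
    if not signs:
        return 0
    return int(np.sign(np.mean(signs)))


def average_over_bin_widths(spikes: pd.DataFrame, cfg: GraphConfig,
                            t_start: float | None = None,
                            t_end: float | None = None) -> DIGraph:
    """Spike-table analysis averaged over several bin widths.

    Per width: bin, normalize, zero normalized values below the threshold,
    estimate the signed graph; the final magnitude is the mean of the
    per-width magnitudes and the final sign is the sign of the mean of the
    per-width signs over widths with a non-zero estimate.  A sign tie
    leaves the edge's sign undetermined (0) and its weight unsigned.
    """
    if len(cfg.bin_widths) < 2:
        raise ValueError("need at least 2 bin widths to average")
    if t_start is None:
        t_start = float(spikes["time"].min())
    if t_end is None:
        t_end = float(spikes["time"].max()) + 1e-9
    units = sorted(pd.unique(spikes["unit"]))

    mags: dict[tuple[str, str], list[float]] = {}
    signs: dict[tuple[str, str], list[int]] = {}
    taus: dict[tuple[str, str], list[int]] = {}
    names = [str(u) for u in units]
    n_used = 0
    for w in cfg.bin_widths:
        series = bin_spike_trains(spikes, w, t_start, t_end, units=units)
        if series.n_samples < 2 * (cfg.M + 1):
            warnings.warn(f"bin width {w} yields too few windows; skipped",
                          stacklevel=2)
            continue
        g = build_graph(series, cfg)
        n_used += 1
        for (j, k), rec in g.edges.items():
            mag = abs(rec.weight)
            mags.setdefault((j, k), []).append(mag)
            if mag > 0 and rec.sign != 0:
                signs.setdefault((j, k), []).append(rec.sign)
                if rec.tau_star is not None:
                    taus.setdefault((j, k), []).append(rec.tau_star)
    if n_used == 0:
        raise ValueError("no bin width produced enough windows")

    edges = {}
    for key, vals in mags.items():
        mean_mag = float(np.mean(vals))
        s_list = signs.get(key, [])
        sign = combine_sign_votes(s_list)
        rec = EdgeRecord(normalized=mean_mag, sign=sign,
                         weight=sign * mean_mag if sign != 0 else mean_mag,
                         tau_star=int(np.round(np.mean(taus[key]))) if key in taus else None)
        if sign == 0 and s_list:
            logger.warning("sign tie for edge %s; reported unsigned", key)
        edges[key] = rec
    return DIGraph(nodes=names, edges=edges,
                   config={"bin_widths": list(cfg.bin_widths), "M": cfg.M,
                           "mode": cfg.mode, "di_threshold": cfg.di_threshold,
                           "seed": cfg.estimator.seed})
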