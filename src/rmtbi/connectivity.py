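"""Region-to-region functional connectivity and graph-theory statistics.

The resting-state analysis works on per-region BOLD signals (voxel
averages within each atlas area).  Signals are cleaned by nuisance
regression (six motion parameters, motion-outlier spikes, mean white
matter and CSF) and a 0.01-0.1 Hz zero-phase band-pass, correlated over
all node pairs (Pearson r, Fisher Z = atanh r), combined across subjects
per edge with a one-sample t-test mapped to a standard-normal deviate, and
thresholded at |Z| >= 2.3 to form an undirected binary graph.  Degree
centrality C_D(j) = sum_i A_ij, graph density and average shortest-path
length are the global readouts; regional degree differences between
groups are tested with Shapiro-Wilk-gated paired t / Wilcoxon signed-rank
tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "ConnectivityMatrix",
    "NetworkMetrics",
    "preprocess_timeseries",
    "pearson_fisher_matrix",
    "group_edge_z",
    "threshold_binarize",
    "network_metrics",
    "degree_table",
    "cluster_nodes",
    "compare_degree_by_region",
    "n_unique_pairs",
]

#: Fisher-Z clip bound: r is clipped to +/- (1 - 1e-7) before atanh.
_R_CLIP = 1.0 - 1e-7
#: sentinel for zero-variance edges in the group map
_Z_SENTINEL = 40.0


@dataclass
class ConnectivityMatrix:
    """Symmetric node x node matrix with labels and a kind tag."""

    labels: np.ndarray
    values: np.ndarray
    kind: str  # {"r", "z", "group_z", "binary"}

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = self.labels.size
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match label count")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if self.kind not in ("r", "z", "group_z", "binary"):
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        if self.kind == "r" and np.any(np.abs(self.values) > 1 + 1e-12):
            raise ValueError("r values must lie in [-1, 1]")
        if self.kind == "binary":
            if not set(np.unique(self.values)) <= {0.0, 1.0}:
                raise ValueError("binary matrix must be 0/1")
            if np.any(np.diag(self.values) != 0):
                raise ValueError("binary matrix must have zero diagonal")

    @property
    def n_nodes(self) -> int:
        return self.labels.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_edge_list(self) -> pd.DataFrame:
        """Upper-triangle edge list (source, target, weight)."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return pd.DataFrame(
            {
                "source": self.labels[iu[0]],
                "target": self.labels[iu[1]],
                "weight": self.values[iu],
            }
        )


@dataclass
class NetworkMetrics:
    """Global graph metrics of a binarized connectivity matrix."""

    degree: pd.Series
    average_degree: float
    density: float
    average_path_length: float | None
    n_nodes: int
    n_edges: int
    n_disconnected_pairs: int


def n_unique_pairs(n_nodes: int) -> int:
    """Number of unique region pairs, N (N - 1) / 2 (171 nodes -> 14,535)."""
    if n_nodes < 2:
        raise ValueError("need >= 2 nodes")
    return n_nodes * (n_nodes - 1) // 2


def preprocess_timeseries(
    signals: np.ndarray,
    tr_s: float,
    nuisance: np.ndarray | pd.DataFrame | None = None,
    band_hz: tuple[float, float] = (0.01, 0.1),
    filter_order: int = 4,
) -> np.ndarray:
    """Nuisance regression followed by zero-phase band-pass filtering.

    Parameters
    ----------
    signals : (T, N) region signals.
    tr_s : repetition time in seconds (sampling interval).
    nuisance : optional (T, K) design of confounds — six motion
        parameters, outlier spike indicators, mean white-matter and CSF
        signals.  An intercept is always added.
    band_hz : pass band; default 0.01-0.1 Hz keeps the resting-state band,
        removing slow drift and high-frequency physiological noise.
    filter_order : Butterworth section order, applied forward-backward
        (filtfilt) for zero phase.

    Returns the zero-mean residual signals, same shape as the input.
    """
    y = np.asarray(signals, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    t = y.shape[0]
    nyquist = 0.5 / tr_s
    lo, hi = band_hz
    if not 0 < lo < hi < nyquist:
        raise ValueError(
            f"band {band_hz} must satisfy 0 < low < high < Nyquist ({nyquist} Hz)"
        )
    design = np.ones((t, 1))
    if nuisance is not None:
        nuis = np.asarray(nuisance, dtype=float)
        if nuis.ndim == 1:
            nuis = nuis[:, None]
        if nuis.shape[0] != t:
            raise ValueError("nuisance series must share length with signals")
        design = np.hstack([design, nuis])
    if design.shape[1] >= t:
        raise ValueError("nuisance design has rank >= number of time points")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta

    sos = signal.butter(
        filter_order, [lo, hi], btype="bandpass", fs=1.0 / tr_s, output="sos"
    )
    filtered = signal.sosfiltfilt(sos, resid, axis=0)
    return filtered - filtered.mean(axis=0, keepdims=True)


def pearson_fisher_matrix(
    signals: np.ndarray, labels: np.ndarray | None = None
) -> tuple[ConnectivityMatrix, ConnectivityMatrix]:
    """Pearson r over all node pairs and its Fisher Z transform.

    Constant signals get their row/column set to 0 with a warning; r is
    clipped to +/-(1 - 1e-7) so Z stays finite.  An N-node network yields
    N (N - 1) / 2 unique pairs.
    """
    y = np.asarray(signals, dtype=float)
    if y.ndim != 2 or y.shape[0] < 3:
        raise ValueError("signals must be (T >= 3, N)")
    n = y.shape[1]
    labels = np.arange(1, n + 1) if labels is None else np.asarray(labels)
    sd = y.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"constant signals at nodes {list(labels[constant])}; rows set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(y, rowvar=False)
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    z = np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))
    np.fill_diagonal(z, 0.0)
    return (
        ConnectivityMatrix(labels=labels, values=r, kind="r"),
        ConnectivityMatrix(labels=labels, values=z, kind="z"),
    )


def group_edge_z(
    subject_z: list[ConnectivityMatrix],
) -> tuple[ConnectivityMatrix, np.ndarray]:
    """One-sample t-test of subject Fisher-Z values per edge, as a Z map.

    Each edge's subject values are tested against 0 with a one-sample
    t-test; the signed t is converted to a standard-normal deviate through
    the t cumulative distribution, so edges reliable across subjects get
    large |Z|.  Zero-variance edges receive sign(mean) * 40 and are
    returned in a flag mask.
    """
    if len(subject_z) < 2:
        raise ValueError("need >= 2 subjects for a group map")
    labels = subject_z[0].labels
    for m in subject_z[1:]:
        if not np.array_equal(m.labels, labels):
            raise ValueError("subject matrices must share node labels")
    stack = np.stack([m.values for m in subject_z])  # (S, N, N)
    n_sub = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    df = n_sub - 1
    # zero variance up to float fuzz of the mean
    zero_var = sd <= np.abs(mean) * 1e-10 + 1e-300
    flagged = zero_var & (mean != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = mean / (sd / np.sqrt(n_sub))
    t_stat = np.where(zero_var, 0.0, t_stat)
    # symmetric tail-stable conversion: z = sign(t) * isf(sf(|t|))
    tail = stats.t.sf(np.abs(t_stat), df=df)
    z = np.sign(t_stat) * stats.norm.isf(np.clip(tail, 1e-300, 1.0))
    z = np.where(flagged, np.sign(mean) * _Z_SENTINEL, z)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2  # numerical symmetry
    return ConnectivityMatrix(labels=labels, values=z, kind="group_z"), flagged


def threshold_binarize(
    matrix: ConnectivityMatrix, zthr: float = 2.3
) -> ConnectivityMatrix:
    """Binarize at |Z| >= zthr (ties kept), removing weak/spurious edges."""
    a = (np.abs(matrix.values) >= zthr).astype(float)
    np.fill_diagonal(a, 0.0)
    return ConnectivityMatrix(labels=matrix.labels, values=a, kind="binary")


def network_metrics(binary: ConnectivityMatrix) -> NetworkMetrics:
    """Degree centrality, density, and average shortest-path length.

    Degree of node j is the row sum C_D(j) = sum_i A_ij.  Density is
    2 E / (N (N - 1)).  Average path length is the mean BFS shortest-path
    length over all connected ordered node pairs; disconnected pairs are
    excluded and counted.  An empty graph has no defined path length.
    """
    if binary.kind != "binary":
        raise ValueError("network metrics require a binarized matrix")
    a = binary.values
    n = binary.n_nodes
    degree = a.sum(axis=1)
    n_edges = int(degree.sum() / 2)
    assert degree.sum() == 2 * n_edges, "sum of degrees must equal 2E"
    density = 2 * n_edges / (n * (n - 1)) if n > 1 else 0.0
    g = nx.from_numpy_array(a)
    total, count = 0, 0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        for target, dist in lengths.items():
            if dist > 0:
                total += dist
                count += 1
    n_disconnected = n * (n - 1) - count
    apl = total / count if count else None
    return NetworkMetrics(
        degree=pd.Series(degree, index=binary.labels, name="degree"),
        average_degree=float(degree.mean()),
        density=float(density),
        average_path_length=apl,
        n_nodes=n,
        n_edges=n_edges,
        n_disconnected_pairs=int(n_disconnected),
    )


def degree_table(
    binary: ConnectivityMatrix, weights: ConnectivityMatrix | None = None
) -> pd.DataFrame:
    """Per-node degree, with weighted degree (sum |Z|) as a secondary column."""
    deg = binary.values.sum(axis=1)
    out = pd.DataFrame({"label_id": binary.labels, "degree": deg})
    if weights is not None:
        w = np.abs(weights.values).copy()
        np.fill_diagonal(w, 0.0)
        out["weighted_degree"] = w.sum(axis=1)
    return out


def cluster_nodes(group_z: ConnectivityMatrix, k: int = 3) -> np.ndarray:
    """Module assignment from a k-nearest-neighbour graph on the nodes.

    Distance between nodes is 1 - |Z| / max|Z|; each node is joined to its
    k nearest neighbours (undirected union) and connected components of
    the resulting graph are the modules.  Deterministic: ties break by
    node order.  Returns an integer module label per node.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    n = group_z.n_nodes
    if k >= n:
        raise ValueError("k must be smaller than the node count")
    absz = np.abs(group_z.values).copy()
    np.fill_diagonal(absz, 0.0)
    zmax = absz.max()
    dist = 1.0 - (absz / zmax if zmax > 0 else absz)
    np.fill_diagonal(dist, np.inf)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    order = np.argsort(dist, axis=1, kind="stable")
    for i in range(n):
        for j in order[i, :k]:
            g.add_edge(i, int(j))
    modules = np.empty(n, dtype=int)
    for mod_id, comp in enumerate(
        sorted(nx.connected_components(g), key=lambda c: min(c))
    ):
        for node in comp:
            modules[node] = mod_id
    return modules


def _paired_test(diffs: np.ndarray) -> tuple[str, float, float]:
    """Shapiro-Wilk-gated paired test on a vector of paired differences.

    Returns (test name, statistic, two-sided p).  All-zero differences are
    the exact null (p = 1).  Zero-variance nonzero differences fall back to
    the exact signed-rank distribution, where the paired t is undefined.
    """
    diffs = np.asarray(diffs, dtype=float)
    if np.all(diffs == 0):
        return "none", 0.0, 1.0
    if np.ptp(diffs) == 0:  # constant nonzero difference
        res = stats.wilcoxon(diffs, alternative="two-sided", method="exact")
        return "wilcoxon", float(res.statistic), float(res.pvalue)
    sw_p = float(stats.shapiro(diffs).pvalue)
    if sw_p > 0.05:
        t_res = stats.ttest_1samp(diffs, 0.0)
        return "paired_t", float(t_res.statistic), float(t_res.pvalue)
    try:
        res = stats.wilcoxon(diffs, alternative="two-sided", method="exact")
    except ValueError:  # zeros present: exact method unavailable
        res = stats.wilcoxon(diffs, alternative="two-sided")
    return "wilcoxon", float(res.statistic), float(res.pvalue)


def compare_degree_by_region(
    degrees_a: pd.DataFrame,
    degrees_b: pd.DataFrame,
    regions: pd.DataFrame,
    labels=("a", "b"),
) -> tuple[pd.DataFrame, dict]:
    """Regional and global degree comparison between two networks.

    ``degrees_a`` / ``degrees_b`` are per-node degree tables
    (label_id, degree) for the two group networks over the same nodes;
    ``regions`` maps label_id -> region_group.  Per region group with at
    least 3 areas, paired differences (b - a) are tested with a
    Shapiro-Wilk-gated paired t-test (normal) or Wilcoxon signed-rank
    (non-normal); the global comparison pools all node degrees.
    """
    a = degrees_a.set_index("label_id")["degree"]
    b = degrees_b.set_index("label_id")["degree"]
    if not a.index.equals(b.index):
        if set(a.index) != set(b.index):
            raise ValueError("networks must share node labels")
        b = b.reindex(a.index)
    rmap = regions.set_index("label_id")["region_group"]
    diffs = (b - a).rename("diff").to_frame()
    diffs["region_group"] = rmap.reindex(diffs.index)
    rows = []
    for region, sub in diffs.groupby("region_group"):
        if len(sub) < 3:
            warnings.warn(
                f"region group {region!r} has < 3 areas; not tested", stacklevel=2
            )
            continue
        test, statistic, p = _paired_test(sub["diff"].to_numpy())
        rows.append(
            {
                "region_group": region,
                "n_areas": len(sub),
                f"mean_degree_{labels[0]}": float(
                    a.loc[sub.index].mean()
                ),
                f"mean_degree_{labels[1]}": float(
                    b.loc[sub.index].mean()
                ),
                "test": test,
                "statistic": statistic,
                "p": p,
                "flagged": bool(p < 0.05),
                "direction": (
                    f"{labels[1]} < {labels[0]}"
                    if sub["diff"].mean() < 0
                    else f"{labels[1]} > {labels[0]}"
                    if sub["diff"].mean() > 0
                    else "none"
                ),
            }
        )
    g_test, g_stat, g_p = _paired_test(diffs["diff"].to_numpy())
    global_result = {
        "test": g_test,
        "statistic": g_stat,
        "p": g_p,
        f"mean_degree_{labels[0]}": float(a.mean()),
        f"mean_degree_{labels[1]}": float(b.mean()),
    }
    return pd.DataFrame(rows), global_result
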