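"""Detection calling and cross-group concordance statistics.

Detection: a non-control probe is called expressed in a group when its
across-array mean sample-channel signal exceeds a fixed threshold (default
300, strict inequality).  Concordance between a test group and a pooled-cell
gold standard is summarized by sensitivity/specificity with equal-tailed
Beta posterior credible intervals (uniform prior), M-ratio Pearson/Spearman
correlations, a seeded random-pair difference-of-M-ratio correlation, a
pairwise-correlation outlier scan, and top-variable-gene hierarchical
clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import beta, pearsonr, spearmanr

from .array_io import ExperimentSet
from .preprocess import NormalizedSet
from .qc import QCReport, flag_outlier_samples

__all__ = [
    "DetectionProfile",
    "ConcordanceReport",
    "MRatioProfile",
    "ClusterResult",
    "call_detection",
    "sensitivity_specificity",
    "build_m_ratio_profiles",
    "m_ratio_correlations",
    "random_pair_difference_correlation",
    "pairwise_outlier_scan",
    "cluster_top_variable",
    "rank_percentile",
]

DEFAULT_THRESHOLD = 300.0

SignalSet = Union[ExperimentSet, NormalizedSet]


@dataclass
class DetectionProfile:
    group: str
    mean_signal: pd.Series        # per non-control probe, mean AF3 over arrays
    threshold: float
    n_arrays: int

    @property
    def detected(self) -> pd.Series:
        return self.mean_signal > self.threshold

    @property
    def n_detected(self) -> int:
        return int(self.detected.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean_af3": self.mean_signal,
                             "detected": self.detected})


def call_detection(ns: SignalSet, group: str,
                   threshold: float = DEFAULT_THRESHOLD) -> DetectionProfile:
    """Mean-signal detection calls for one group (control probes excluded)."""
    ids = ns.samples_in_group(group)
    if not ids:
        raise ValueError(f"group {group!r} has no non-excluded arrays")
    probes = ns.noncontrol_probes()
    mean_sig = ns.af3.loc[probes, ids].mean(axis=1)
    return DetectionProfile(group=str(group), mean_signal=mean_sig,
                            threshold=float(threshold), n_arrays=len(ids))


# ---------------------------------------------------------------------------
# sensitivity / specificity with Beta credible intervals


def _beta_interval(successes: int, failures: int, level: float) -> tuple[float, float]:
    """Equal-tailed credible interval of Beta(s+1, f+1) — uniform prior."""
    tail = (1.0 - level) / 2.0
    dist = beta(successes + 1, failures + 1)
    return float(dist.ppf(tail)), float(dist.ppf(1.0 - tail))


@dataclass
class ConcordanceReport:
    gold_group: str
    test_group: str
    n_both: int
    n_gold_only: int
    n_test_only: int
    n_neither: int
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    level: float
    pearson_m: Optional[float] = None
    spearman_m: Optional[float] = None
    pair_diff_pearson: Optional[float] = None
    n_pairs: Optional[int] = None
    pair_seed: Optional[int] = None

    @property
    def universe(self) -> int:
        return self.n_both + self.n_gold_only + self.n_test_only + self.n_neither

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def sensitivity_specificity(test: DetectionProfile, gold: DetectionProfile,
                            level: float = 0.95) -> ConcordanceReport:
    """Score test-group detection against a gold-standard group.

    Sensitivity = detected-in-both / detected-in-gold; specificity =
    undetected-in-both / undetected-in-gold.  Credible intervals are
    equal-tailed quantiles of Beta(s+1, f+1) (uniform prior), with s the
    concordant and f the discordant count for each proportion.
    """
    if not test.mean_signal.index.equals(gold.mean_signal.index):
        raise ValueError("profiles must share an identical probe universe")
    t = test.detected.to_numpy()
    g = gold.detected.to_numpy()
    both = int(np.sum(t & g))
    gold_only = int(np.sum(~t & g))
    test_only = int(np.sum(t & ~g))
    neither = int(np.sum(~t & ~g))
    sens = both / (both + gold_only) if (both + gold_only) else float("nan")
    spec = neither / (neither + test_only) if (neither + test_only) else float("nan")
    return ConcordanceReport(
        gold_group=gold.group, test_group=test.group,
        n_both=both, n_gold_only=gold_only, n_test_only=test_only,
        n_neither=neither,
        sensitivity=sens, sensitivity_ci=_beta_interval(both, gold_only, level),
        specificity=spec, specificity_ci=_beta_interval(neither, test_only, level),
        level=level)


# ---------------------------------------------------------------------------
# M-ratio concordance


@dataclass
class MRatioProfile:
    """Per-probe mean M for one group, restricted to a shared detected set."""

    group: str
    mean_m: pd.Series


def build_m_ratio_profiles(ns: NormalizedSet, groups: Sequence[str],
                           threshold: float = DEFAULT_THRESHOLD
                           ) -> dict[str, MRatioProfile]:
    """Mean M per group over probes detected in *every* requested group."""
    detected = None
    for g in groups:
        d = call_detection(ns, g, threshold=threshold).detected
        detected = d if detected is None else (detected & d)
    probes = detected[detected].index
    out = {}
    for g in groups:
        ids = ns.samples_in_group(g)
        out[str(g)] = MRatioProfile(str(g), ns.m.loc[probes, ids].mean(axis=1))
    return out


def m_ratio_correlations(a: MRatioProfile, b: MRatioProfile,
                         method: Literal["pearson", "spearman"] = "pearson"
                         ) -> float:
    shared = a.mean_m.index.intersection(b.mean_m.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared probes")
    x = a.mean_m.loc[shared].to_numpy()
    y = b.mean_m.loc[shared].to_numpy()
    if method == "pearson":
        return float(pearsonr(x, y).statistic)
    if method == "spearman":
        return float(spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


def _sample_pairs(n: int, n_pairs: int, rng: np.random.Generator
                  ) -> np.ndarray:
    """Distinct unordered index pairs, uniform without replacement."""
    total = n * (n - 1) // 2
    if n_pairs > total:
        raise ValueError(f"n_pairs={n_pairs} exceeds C({n},2)={total}")
    if n_pairs == total:
        return np.array([(i, j) for i in range(n) for j in range(i + 1, n)])
    chosen: set[tuple[int, int]] = set()
    pairs = []
    while len(pairs) < n_pairs:
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        key = (int(min(i, j)), int(max(i, j)))
        if key in chosen:
            continue
        chosen.add(key)
        pairs.append(key)
    return np.array(pairs)


def random_pair_difference_correlation(a: MRatioProfile, b: MRatioProfile,
                                       n_pairs: int = 10_000,
                                       seed: int = 0
                                       ) -> tuple[float, pd.DataFrame]:
    """Pearson correlation of within-group M differences over random gene pairs.

    Samples ``n_pairs`` distinct unordered probe pairs (seeded, without
    replacement) from the shared detected universe, forms D = M_i - M_j in
    each group, and correlates the two D vectors.  Returns the coefficient
    and the sampled pair list.
    """
    shared = a.mean_m.index.intersection(b.mean_m.index)
    if len(shared) < 2:
        raise ValueError("need >= 2 shared probes")
    rng = np.random.default_rng(seed)
    pairs = _sample_pairs(len(shared), n_pairs, rng)
    xa = a.mean_m.loc[shared].to_numpy()
    xb = b.mean_m.loc[shared].to_numpy()
    da = xa[pairs[:, 0]] - xa[pairs[:, 1]]
    db = xb[pairs[:, 0]] - xb[pairs[:, 1]]
    r = float(pearsonr(da, db).statistic)
    log = pd.DataFrame({"probe_i": shared[pairs[:, 0]],
                        "probe_j": shared[pairs[:, 1]],
                        "diff_a": da, "diff_b": db})
    return r, log


# ---------------------------------------------------------------------------
# pairwise-correlation outlier scan


def pairwise_outlier_scan(ns: NormalizedSet, group: str,
                          alpha: float = 0.05, seed: int = 0) -> QCReport:
    """Dixon scan on each array's mean M-vector correlation to its peers."""
    ids = ns.samples_in_group(group)
    if len(ids) < 3:
        raise ValueError(f"group {group!r} needs >= 3 arrays for the scan")
    m = ns.m[ids].to_numpy()
    corr = np.corrcoef(m.T)
    np.fill_diagonal(corr, np.nan)
    mean_corr = pd.Series(np.nanmean(corr, axis=1), index=ids,
                          name="mean_pairwise_correlation")
    if mean_corr.max() == mean_corr.min():
        # identical arrays — nothing to scan
        return QCReport(rows=pd.DataFrame(
            columns=["sample_id", "criterion", "metric", "group", "value",
                     "q_statistic", "critical_value", "p_value", "flagged"]),
            exclusions={}, warnings=["all pairwise correlations equal"])
    return flag_outlier_samples({"m_ratio_pairwise_correlation": mean_corr},
                                alpha=alpha, seed=seed)


# ---------------------------------------------------------------------------
# clustering and rank percentiles


@dataclass
class ClusterResult:
    selected_genes: list[str]
    linkage_matrix: np.ndarray
    leaf_order: list[str]
    sample_labels: dict[str, str]   # sample_id -> group

    def top_level_partition(self) -> tuple[set[str], set[str]]:
        """Sample sets of the two clades below the root."""
        tree = to_tree(self.linkage_matrix)
        ids = list(self.sample_labels)
        left = {ids[i] for i in tree.get_left().pre_order()}
        right = {ids[i] for i in tree.get_right().pre_order()}
        return left, right

    def to_newick(self) -> str:
        tree = to_tree(self.linkage_matrix)
        ids = list(self.sample_labels)

        def rec(node, parent_dist):
            length = max(parent_dist - node.dist, 0.0)
            if node.is_leaf():
                return f"{ids[node.id]}:{length:.6g}"
            return (f"({rec(node.get_left(), node.dist)},"
                    f"{rec(node.get_right(), node.dist)}):{length:.6g}")

        return f"({rec(tree.get_left(), tree.dist)},{rec(tree.get_right(), tree.dist)});"


def cluster_top_variable(ns: NormalizedSet, n_genes: int = 1000,
                         linkage_method: str = "average",
                         distance: Literal["correlation", "euclidean"] = "correlation"
                         ) -> ClusterResult:
    """Hierarchical clustering of samples on the top-variance probes.

    Selects the ``n_genes`` probes with highest variance of log2 sample-channel
    signal across arrays (all probes if fewer are available), then clusters
    samples with 1 - Pearson distance and average linkage by default.
    """
    ids = [s for s in ns.sample_ids
           if not ns.samples.set_index("sample_id").loc[s, "qc_excluded"]]
    if len(ids) < 2:
        raise ValueError("need >= 2 samples to cluster")
    logv = np.log2(ns.af3[ids].to_numpy(dtype=float).clip(min=1e-12))
    variances = logv.var(axis=1)
    k = min(n_genes, logv.shape[0])
    top = np.argsort(-variances, kind="stable")[:k]
    sel = logv[top]
    if distance == "correlation":
        corr = np.corrcoef(sel.T)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
        condensed = squareform(dist, checks=False)
    else:
        from scipy.spatial.distance import pdist
        condensed = pdist(sel.T)
    lk = linkage(condensed, method=linkage_method)
    order = [ids[i] for i in leaves_list(lk)]
    groups = ns.samples.set_index("sample_id")["group"].astype(str)
    probe_index = ns.probe_ids
    return ClusterResult(
        selected_genes=[probe_index[i] for i in top],
        linkage_matrix=lk,
        leaf_order=order,
        sample_labels={s: groups.loc[s] for s in ids})


def rank_percentile(ns: SignalSet, gene_symbols: Sequence[str],
                    threshold: float = DEFAULT_THRESHOLD,
                    decimals: int = 0) -> pd.DataFrame:
    """Per-group expression rank percentile of each gene.

    A gene's signal is the max mean sample-channel signal over its probes;
    its percentile is the fraction of the full non-control probe universe
    with mean signal <= that value, times 100 (rounded to ``decimals``).
    """
    ann = ns.annotation
    sym2probes: dict[str, list[str]] = {}
    for pid, sym in zip(ann["probe_id"], ann["gene_symbol"]):
        if sym:
            sym2probes.setdefault(sym, []).append(pid)
    missing = [g for g in gene_symbols if g not in sym2probes]
    if len(missing) == len(gene_symbols):
        raise ValueError(f"no requested gene maps to a probe: {missing}")
    out = {}
    for group in ns.groups():
        prof = call_detection(ns, group, threshold=threshold)
        sig = prof.mean_signal
        n = len(sig)
        col = {}
        for g in gene_symbols:
            if g not in sym2probes:
                col[g] = np.nan
                continue
            probes = [p for p in sym2probes[g] if p in sig.index]
            val = sig.loc[probes].max()
            pct = 100.0 * float((sig <= val).sum()) / n
            col[g] = round(pct, decimals) if decimals else round(pct)
        out[str(group)] = col
    return pd.DataFrame(out)
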