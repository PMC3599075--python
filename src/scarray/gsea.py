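"""Gene set enrichment on mean-centered log2 signal profiles.

A per-group ranked list is built from mean log2 sample-channel signal
(probes collapsed to genes by max mean signal, then mean-centered across
genes).  Enrichment uses the weighted Kolmogorov-Smirnov running sum; the
null is gene-label permutation, with sign-stratified NES normalization and
FDR q-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .array_io import GeneSet
from .preprocess import NormalizedSet

__all__ = [
    "RankedList",
    "GseaResult",
    "build_ranked_list",
    "enrichment_score",
    "nes_and_fdr",
    "correlate_nes",
]


@dataclass
class RankedList:
    """Genes ordered by descending score; ties broken lexicographically."""

    genes: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("duplicate gene symbols in ranked list")
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != self.scores.size:
            raise ValueError("genes and scores differ in length")

    def __len__(self) -> int:
        return len(self.genes)


def build_ranked_list(ns: NormalizedSet, group: str) -> RankedList:
    """Ranked list of mean-centered mean log2 AF3 for one group.

    Probes collapse to gene symbols by max mean signal; unnamed probes are
    dropped; scores are centered to zero mean across genes and sorted
    descending with lexicographic tie-breaks.
    """
    ids = ns.samples_in_group(group)
    if not ids:
        raise ValueError(f"group {group!r} has no non-excluded arrays")
    mean_log = np.log2(ns.af3[ids].to_numpy(dtype=float).clip(min=1e-12)).mean(axis=1)
    sym = ns.annotation["gene_symbol"].to_numpy()
    ctrl = ns.annotation["is_control"].astype(bool).to_numpy()
    per_gene: dict[str, float] = {}
    for s, v, c in zip(sym, mean_log, ctrl):
        if not s or c:
            continue
        if s not in per_gene or v > per_gene[s]:
            per_gene[s] = float(v)
    if not per_gene:
        raise ValueError("no named non-control probes to rank")
    genes = list(per_gene)
    scores = np.array([per_gene[g] for g in genes])
    scores = scores - scores.mean()
    order = sorted(range(len(genes)), key=lambda i: (-scores[i], genes[i]))
    return RankedList([genes[i] for i in order], scores[order])


def build_difference_ranked_list(ns: NormalizedSet, group_a: str,
                                 group_b: str) -> RankedList:
    """Ranked list of the difference of two groups' mean-centered profiles.

    Supports patient-vs-patient enrichment when each side is a single
    averaged profile: score = centered(a) - centered(b) over shared genes,
    re-centered and sorted descending.  This is an assumption-laden stand-in
    for a two-class design, which is impossible with one list per group.
    """
    ra = build_ranked_list(ns, group_a)
    rb = build_ranked_list(ns, group_b)
    sa = dict(zip(ra.genes, ra.scores))
    sb = dict(zip(rb.genes, rb.scores))
    shared = sorted(set(sa) & set(sb))
    if not shared:
        raise ValueError("groups share no ranked genes")
    diff = np.array([sa[g] - sb[g] for g in shared])
    diff = diff - diff.mean()
    order = sorted(range(len(shared)), key=lambda i: (-diff[i], shared[i]))
    return RankedList([shared[i] for i in order], diff[order])


def _es_from_hits(scores: np.ndarray, hit_mask: np.ndarray,
                  p: float) -> tuple[float, np.ndarray, int]:
    """Signed-extremum ES and the running sum for a boolean hit mask."""
    n = scores.size
    n_hit = int(hit_mask.sum())
    if n_hit == 0:
        raise ValueError("gene set has no member in the ranked list")
    if n_hit == n:
        # degenerate: every gene is a hit; defined as +1 by convention
        return 1.0, np.ones(n), 0
    w = np.abs(scores) ** p if p != 0 else np.ones(n)
    hit_w = np.where(hit_mask, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        hit_w = hit_mask.astype(float)
        denom = hit_w.sum()
    inc = hit_w / denom
    dec = np.where(hit_mask, 0.0, 1.0 / (n - n_hit))
    running = np.cumsum(inc - dec)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if running[i_max] >= -running[i_min]:
        return float(running[i_max]), running, i_max
    return float(running[i_min]), running, i_min


def enrichment_score(ranked: RankedList, gene_set: GeneSet,
                     p: float = 1.0) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score and its running sum.

    Hits step up by |score|^p normalized over hit weights; misses step down
    by 1/(N - N_hits); ES is the signed extremum of the running sum.
    """
    hit_mask = np.array([g in gene_set.members for g in ranked.genes])
    es, running, _ = _es_from_hits(ranked.scores, hit_mask, p)
    return es, running


@dataclass
class GseaResult:
    name: str
    size: int
    es: float
    nes: float
    p_value: float
    fdr_q: float
    extremum_rank: int
    n_perm: int


def nes_and_fdr(ranked: RankedList, sets: Sequence[GeneSet],
                n_perm: int = 1000, seed: int = 0,
                p: float = 1.0) -> list[GseaResult]:
    """Permutation-normalized enrichment with sign-stratified FDR q-values.

    The null permutes gene labels (equivalently: redraws each set's hit
    positions uniformly), shared across sets per permutation.  NES divides
    ES by the mean |null ES| of matching sign; q for a set is the ratio of
    the null and observed tail fractions at its NES, per the standard
    sign-stratified procedure, clipped to [0, 1] with a monotonicity pass.
    """
    rng = np.random.default_rng(seed)
    n = len(ranked)
    observed = []
    masks = []
    for s in sets:
        mask = np.array([g in s.members for g in ranked.genes])
        if not mask.any():
            raise ValueError(f"gene set {s.name!r} has no member in the list")
        es, _, idx = _es_from_hits(ranked.scores, mask, p)
        observed.append(es)
        masks.append(mask)
    observed = np.array(observed)

    null = np.empty((n_perm, len(sets)))
    for b in range(n_perm):
        perm = rng.permutation(n)
        for k, mask in enumerate(masks):
            null[b, k], _, _ = _es_from_hits(ranked.scores, mask[perm], p)

    results = []
    # normalize observed and null ES by sign-matched mean |null ES| per set
    pos_mean = np.array([null[null[:, k] > 0, k].mean()
                         if (null[:, k] > 0).any() else np.nan
                         for k in range(len(sets))])
    neg_mean = np.array([(-null[null[:, k] < 0, k]).mean()
                         if (null[:, k] < 0).any() else np.nan
                         for k in range(len(sets))])

    def normalize(es_val: float, k: int) -> float:
        if es_val >= 0:
            return es_val / pos_mean[k] if np.isfinite(pos_mean[k]) else np.nan
        return es_val / neg_mean[k] if np.isfinite(neg_mean[k]) else np.nan

    nes_obs = np.array([normalize(observed[k], k) for k in range(len(sets))])
    nes_null = np.empty_like(null)
    for k in range(len(sets)):
        col = null[:, k]
        nes_null[:, k] = np.where(col >= 0, col / pos_mean[k], col / neg_mean[k])
    null_flat = nes_null.ravel()
    null_flat = null_flat[np.isfinite(null_flat)]

    qs = np.empty(len(sets))
    ps = np.empty(len(sets))
    for k, s in enumerate(sets):
        es, col = observed[k], null[:, k]
        if es >= 0:
            same = col[col >= 0]
            ps[k] = (np.sum(same >= es) + 1) / (same.size + 1) if same.size else 1.0
            null_tail = np.mean(null_flat >= nes_obs[k]) if null_flat.size else 1.0
            obs_tail = np.mean(nes_obs[nes_obs >= 0] >= nes_obs[k])
        else:
            same = col[col < 0]
            ps[k] = (np.sum(same <= es) + 1) / (same.size + 1) if same.size else 1.0
            null_tail = np.mean(null_flat <= nes_obs[k]) if null_flat.size else 1.0
            obs_tail = np.mean(nes_obs[nes_obs < 0] <= nes_obs[k])
        qs[k] = min(null_tail / obs_tail, 1.0) if obs_tail > 0 else 1.0

    # enforce q monotone in |NES| within each sign stratum
    for sign_sel in (nes_obs >= 0, nes_obs < 0):
        idx = np.where(sign_sel)[0]
        if idx.size:
            order = idx[np.argsort(-np.abs(nes_obs[idx]))]
            running_min = np.inf
            for k in order:
                running_min = min(running_min, qs[k])
                qs[k] = running_min

    for k, s in enumerate(sets):
        mask = masks[k]
        _, _, ext = _es_from_hits(ranked.scores, mask, p)
        results.append(GseaResult(name=s.name, size=int(mask.sum()),
                                  es=float(observed[k]), nes=float(nes_obs[k]),
                                  p_value=float(ps[k]), fdr_q=float(qs[k]),
                                  extremum_rank=int(ext), n_perm=n_perm))
    return results


def results_to_frame(results: Sequence[GseaResult]) -> pd.DataFrame:
    return pd.DataFrame([{"name": r.name, "size": r.size, "ES": r.es,
                          "NES": r.nes, "p": r.p_value, "q": r.fdr_q}
                         for r in results]).set_index("name")


def correlate_nes(a: Sequence[GseaResult], b: Sequence[GseaResult]) -> float:
    """Pearson correlation of NES over gene sets shared by name."""
    nes_a = {r.name: r.nes for r in a}
    nes_b = {r.name: r.nes for r in b}
    shared = sorted(set(nes_a) & set(nes_b))
    if len(shared) < 3:
        raise ValueError("need >= 3 shared gene sets")
    x = np.array([nes_a[n] for n in shared])
    y = np.array([nes_b[n] for n in shared])
    return float(pearsonr(x, y).statistic)
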