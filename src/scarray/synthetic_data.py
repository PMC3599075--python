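"""Synthetic two-color array experiments, qPCR plates and electropherograms.

The generative model mirrors the structure the downstream statistics assume:

* per-probe reference abundance ``lambda_g`` drawn log-normally, with a
  fixed fraction of probes truly expressed;
* a ``k``-cell sample draws a transcript count ``Poisson(k * lambda_g)``,
  each transcript surviving capture/amplification independently with
  probability ``capture_prob`` (binomial thinning) — so low-abundance
  transcripts drop out first, and dropout worsens as input cells decrease;
* sample-channel signal AF3 = gain * captured count, times log-normal
  measurement noise, plus a non-negative nonspecific background floor and an
  additive per-channel day-2 batch shift;
* reference-channel signal AF5 = gain * lambda_g (a shared pooled reference)
  with its own noise, floor and day shift.

Ground truth (expressed per group, captured per sample, true abundance) is
attached so detection sensitivity/specificity can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .array_io import ExperimentSet, SimTruth, _normalize_annotation, _normalize_meta

__all__ = [
    "SimConfig",
    "simulate_experiment",
    "simulate_patient_experiment",
    "simulate_qpcr",
    "simulate_electropherogram",
    "QPCRPlate",
    "Electropherogram",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated amplification experiment.

    ``groups`` lists ``(cell_count, n_replicates)`` pairs; replicates are
    split across ``days`` labels round-robin unless an explicit assignment
    is given.  The seed fully determines the output.
    """

    n_probes: int = 2000
    groups: tuple[tuple[int, int], ...] = ((1, 10), (5, 10), (10, 10))
    days: tuple[str, ...] = ("d1", "d2")
    abundance_logmean: float = 2.0
    abundance_logsd: float = 1.5
    frac_expressed: float = 0.643
    capture_prob: float = 0.35
    gain: float = 50.0
    nonspecific_floor_mean: float = 60.0
    nonspecific_floor_sd: float = 20.0
    day_shift_af3: float = 0.0
    day_shift_af5: float = 0.0
    noise_logsd: float = 0.25
    # per-probe lognormal divergence of the pooled reference from the sample
    # biology; gives M a stable biological component across replicate arrays
    ref_divergence_logsd: float = 0.5
    frac_control: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        for p, name in ((self.capture_prob, "capture_prob"),
                        (self.frac_expressed, "frac_expressed"),
                        (self.frac_control, "frac_control")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for k, r in self.groups:
            if k < 1 or r < 1:
                raise ValueError("cell counts and replicate counts must be >= 1")
        if self.noise_logsd < 0 or self.nonspecific_floor_sd < 0:
            raise ValueError("spread parameters must be non-negative")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


_GENE_POOL_SIZE = 26 * 26  # two-letter gene symbols GAA..GZZ, recycled


def _gene_symbols(n: int) -> list[str]:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    out = []
    for i in range(n):
        j = i % _GENE_POOL_SIZE
        out.append(f"G{letters[j // 26]}{letters[j % 26]}{i // _GENE_POOL_SIZE}")
    return out


def simulate_experiment(config: SimConfig) -> ExperimentSet:
    """Simulate a multi-group two-color experiment with attached truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_probes

    probe_ids = [f"P{i:06d}" for i in range(n)]
    n_ctrl = int(round(config.frac_control * n))
    is_control = np.zeros(n, dtype=bool)
    if n_ctrl:
        is_control[rng.choice(n, size=n_ctrl, replace=False)] = True
    annotation = _normalize_annotation(pd.DataFrame({
        "probe_id": probe_ids,
        "gene_symbol": _gene_symbols(n),
        "is_control": is_control,
    }))

    abundance = rng.lognormal(config.abundance_logmean, config.abundance_logsd, size=n)
    expressed_vec = rng.random(n) < config.frac_expressed
    expressed_vec &= ~is_control  # control probes carry no biology
    abundance = np.where(expressed_vec, abundance, 0.0)
    ref_abundance = abundance * (
        rng.lognormal(0.0, config.ref_divergence_logsd, size=n)
        if config.ref_divergence_logsd > 0 else 1.0)

    meta_rows = []
    for k, n_rep in config.groups:
        for r in range(1, n_rep + 1):
            day = config.days[(r - 1) % len(config.days)] if config.days else "d1"
            meta_rows.append({"sample_id": f"g{k}_r{r:02d}", "group": str(k),
                              "day": day, "replicate": r})
    samples = _normalize_meta(pd.DataFrame(meta_rows))

    group_labels = [str(k) for k, _ in config.groups]
    expressed = pd.DataFrame(
        {g: expressed_vec for g in group_labels}, index=pd.Index(probe_ids))

    af3 = np.empty((n, len(samples)))
    af5 = np.empty((n, len(samples)))
    captured = np.zeros((n, len(samples)), dtype=bool)
    day2 = config.days[1] if len(config.days) > 1 else None

    for j, row in samples.iterrows():
        k = int(row["group"])
        counts = rng.poisson(k * abundance)
        kept = rng.binomial(counts, config.capture_prob)
        captured[:, j] = kept > 0
        noise3 = (rng.lognormal(0.0, config.noise_logsd, size=n)
                  if config.noise_logsd > 0 else 1.0)
        noise5 = (rng.lognormal(0.0, config.noise_logsd, size=n)
                  if config.noise_logsd > 0 else 1.0)
        # folded normal: positive floor without an atom at zero (exact
        # zero ties would break downstream quantile normalization checks)
        floor3 = np.abs(rng.normal(config.nonspecific_floor_mean,
                                   config.nonspecific_floor_sd, size=n)) \
            if (config.nonspecific_floor_mean or config.nonspecific_floor_sd) else 0.0
        floor5 = np.abs(rng.normal(config.nonspecific_floor_mean,
                                   config.nonspecific_floor_sd, size=n)) \
            if (config.nonspecific_floor_mean or config.nonspecific_floor_sd) else 0.0
        sig3 = config.gain * kept * noise3 + floor3
        sig5 = config.gain * ref_abundance * noise5 + floor5
        if day2 is not None and row["day"] == day2:
            sig3 = sig3 + config.day_shift_af3
            sig5 = sig5 + config.day_shift_af5
        af3[:, j] = np.clip(sig3, 0, None)
        af5[:, j] = np.clip(sig5, 0, None)

    idx = pd.Index(probe_ids)
    sample_ids = samples["sample_id"].tolist()
    truth = SimTruth(
        expressed=expressed,
        captured=pd.DataFrame(captured, index=idx, columns=sample_ids),
        true_abundance=pd.Series(abundance, index=idx, name="true_abundance"),
    )
    es = ExperimentSet(
        annotation, samples,
        pd.DataFrame(af3, index=idx, columns=sample_ids),
        pd.DataFrame(af5, index=idx, columns=sample_ids),
        truth=truth,
    )
    return es


def simulate_patient_experiment(config: SimConfig, patients: Sequence[str],
                                n_cells: int = 10,
                                profile_shift_logsd: float = 1.0) -> ExperimentSet:
    """Single-cell arrays for several patients with distinct mean profiles.

    Each patient becomes a group of ``n_cells`` single-cell arrays; per-patient
    abundances are the shared abundance vector perturbed by an independent
    log-normal factor, so patients separate in cluster analysis.
    """
    rng = np.random.default_rng(config.seed)
    base = simulate_experiment(config.with_(groups=((1, 1),)))
    n = config.n_probes
    abundance = base.truth.true_abundance.to_numpy()
    expressed_vec = base.truth.expressed.iloc[:, 0].to_numpy()

    ref_abundance = abundance * (
        rng.lognormal(0.0, config.ref_divergence_logsd, size=n)
        if config.ref_divergence_logsd > 0 else 1.0)
    meta_rows = []
    per_patient_abund = {}
    for p in patients:
        shift = rng.lognormal(0.0, profile_shift_logsd, size=n)
        per_patient_abund[p] = abundance * shift
        for r in range(1, n_cells + 1):
            day = config.days[(r - 1) % len(config.days)] if config.days else "d1"
            meta_rows.append({"sample_id": f"{p}_c{r:02d}", "group": p,
                              "day": day, "replicate": r})
    samples = _normalize_meta(pd.DataFrame(meta_rows))

    af3 = np.empty((n, len(samples)))
    af5 = np.empty((n, len(samples)))
    captured = np.zeros((n, len(samples)), dtype=bool)
    day2 = config.days[1] if len(config.days) > 1 else None
    for j, row in samples.iterrows():
        lam = per_patient_abund[row["group"]]
        counts = rng.poisson(lam)
        kept = rng.binomial(counts, config.capture_prob)
        captured[:, j] = kept > 0
        noise3 = (rng.lognormal(0.0, config.noise_logsd, size=n)
                  if config.noise_logsd > 0 else 1.0)
        noise5 = (rng.lognormal(0.0, config.noise_logsd, size=n)
                  if config.noise_logsd > 0 else 1.0)
        # folded normal: positive floor without an atom at zero (exact
        # zero ties would break downstream quantile normalization checks)
        floor3 = np.abs(rng.normal(config.nonspecific_floor_mean,
                                   config.nonspecific_floor_sd, size=n)) \
            if (config.nonspecific_floor_mean or config.nonspecific_floor_sd) else 0.0
        floor5 = np.abs(rng.normal(config.nonspecific_floor_mean,
                                   config.nonspecific_floor_sd, size=n)) \
            if (config.nonspecific_floor_mean or config.nonspecific_floor_sd) else 0.0
        sig3 = config.gain * kept * noise3 + floor3
        sig5 = config.gain * ref_abundance * noise5 + floor5
        if day2 is not None and row["day"] == day2:
            sig3 = sig3 + config.day_shift_af3
            sig5 = sig5 + config.day_shift_af5
        af3[:, j] = np.clip(sig3, 0, None)
        af5[:, j] = np.clip(sig5, 0, None)

    idx = base.probe_ids
    sample_ids = samples["sample_id"].tolist()
    truth = SimTruth(
        expressed=pd.DataFrame({p: expressed_vec for p in patients}, index=idx),
        captured=pd.DataFrame(captured, index=idx, columns=sample_ids),
        true_abundance=base.truth.true_abundance,
    )
    return ExperimentSet(base.annotation.copy(), samples,
                         pd.DataFrame(af3, index=idx, columns=sample_ids),
                         pd.DataFrame(af5, index=idx, columns=sample_ids),
                         truth=truth)


# ---------------------------------------------------------------------------
# qPCR plates


@dataclass
class QPCRPlate:
    """Long-format plate: one row per (sample, gene, replicate).

    ``cq`` is NaN when no amplification was seen within ``max_cycles``.
    No-template-control rows are flagged via ``is_ntc``.
    """

    data: pd.DataFrame  # columns: sample_id, group, gene, rep, cq, is_ntc
    max_cycles: int = 46

    def __post_init__(self) -> None:
        cq = self.data["cq"]
        ok = cq.isna() | ((cq > 0) & (cq <= self.max_cycles))
        if not ok.all():
            raise ValueError("Cq values must be positive and <= max_cycles")

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out["cq"] = out["cq"].map(lambda v: "na" if pd.isna(v) else repr(float(v)))
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, max_cycles: int = 46) -> "QPCRPlate":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene": str})
        df["cq"] = pd.to_numeric(df["cq"].replace({"na": np.nan, "NA": np.nan}),
                                 errors="coerce")
        if "is_ntc" not in df.columns:
            df["is_ntc"] = False
        if "group" not in df.columns:
            df["group"] = ""
        return cls(df, max_cycles=max_cycles)


def simulate_qpcr(config: SimConfig, genes: Mapping[str, float], seed: int,
                  base_cq: float = 30.0, cq_noise_sd: float = 0.0,
                  n_replicates: int = 3, max_cycles: int = 46) -> QPCRPlate:
    """Triplicate Cq values per sample x gene.

    ``genes`` maps gene symbol to its per-cell abundance; RPL13A must be
    present (it is the downstream reference gene).  The deterministic part is
    ``Cq = base_cq - log2(k * abundance * capture_prob)``; genes with zero
    captured abundance, or a Cq beyond ``max_cycles``, are not amplified.
    """
    if "RPL13A" not in genes:
        raise ValueError("genes must include the reference gene RPL13A")
    rng = np.random.default_rng(seed)
    rows = []
    for k, n_rep in config.groups:
        for r in range(1, n_rep + 1):
            sid = f"g{k}_r{r:02d}"
            for gene, abund in genes.items():
                eff = k * abund * config.capture_prob
                for rep in range(1, n_replicates + 1):
                    if eff <= 0:
                        cq = np.nan
                    else:
                        cq = base_cq - np.log2(eff)
                        if cq_noise_sd > 0:
                            cq += rng.normal(0.0, cq_noise_sd)
                        if cq > max_cycles or cq <= 0:
                            cq = np.nan
                    rows.append({"sample_id": sid, "group": str(k), "gene": gene,
                                 "rep": rep, "cq": cq, "is_ntc": False})
    # one no-template control row set per gene
    for gene in genes:
        for rep in range(1, n_replicates + 1):
            rows.append({"sample_id": "NTC", "group": "NTC", "gene": gene,
                         "rep": rep, "cq": np.nan, "is_ntc": True})
    return QPCRPlate(pd.DataFrame(rows), max_cycles=max_cycles)


# ---------------------------------------------------------------------------
# electropherograms


@dataclass
class Electropherogram:
    """Fluorescence trace over an increasing fragment-size grid (nt)."""

    size_nt: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.size_nt = np.asarray(self.size_nt, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.size_nt.shape != self.fluorescence.shape:
            raise ValueError("size_nt and fluorescence must have equal length")
        if not np.all(np.diff(self.size_nt) > 0):
            raise ValueError("size_nt must be strictly increasing")
        if (self.fluorescence < 0).any():
            raise ValueError("fluorescence must be non-negative")

    def to_tsv(self, path) -> None:
        pd.DataFrame({"size_nt": self.size_nt,
                      "fluorescence": self.fluorescence}).to_csv(
            path, sep="\t", index=False)


def simulate_electropherogram(mean_nt: float, spread_nt: float, seed: int,
                              n_points: int = 500) -> Electropherogram:
    """Smooth unimodal (Gaussian-bump) trace centred at ``mean_nt``.

    The seed only perturbs the overall amplitude, which downstream fragment
    sizing is invariant to, keeping the trace smooth and exactly unimodal.
    """
    if mean_nt <= 0:
        raise ValueError("mean_nt must be positive")
    rng = np.random.default_rng(seed)
    lo = max(1.0, mean_nt - 5 * spread_nt)
    hi = mean_nt + 5 * spread_nt
    grid = np.linspace(lo, hi, n_points)
    amp = rng.lognormal(0.0, 0.2)
    fl = amp * np.exp(-0.5 * ((grid - mean_nt) / max(spread_nt, 1e-9)) ** 2)
    return Electropherogram(grid, fl)
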