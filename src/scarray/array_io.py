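"""Tabular I/O for two-color array experiments, sample metadata and gene sets.

All files are tab-separated UTF-8 with a header row.  A signal table has a
``probe_id`` column, optional ``gene_symbol``/``is_control`` annotation
columns, and one ``<sample>_AF3`` / ``<sample>_AF5`` column pair per sample
(AF3 = sample channel, AF5 = shared reference channel, both linear scale).
A metadata table has one row per sample with columns ``sample_id``,
``group``, ``day``, ``replicate`` and optional ``qc_excluded``/``qc_reason``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ArrayIOError",
    "DuplicateProbeError",
    "DimensionMismatchError",
    "NegativeSignalError",
    "GMTParseError",
    "ExperimentSet",
    "SimTruth",
    "GeneSet",
    "read_experiment",
    "write_experiment",
    "read_gmt",
    "write_gmt",
    "from_channel_matrices",
]


class ArrayIOError(ValueError):
    """Base class for malformed experiment tables."""


class DuplicateProbeError(ArrayIOError):
    pass


class DimensionMismatchError(ArrayIOError):
    pass


class NegativeSignalError(ArrayIOError):
    pass


class GMTParseError(ValueError):
    pass


META_COLUMNS = ["sample_id", "group", "day", "replicate", "qc_excluded", "qc_reason"]
ANNOT_COLUMNS = ["probe_id", "gene_symbol", "is_control"]


@dataclass
class SimTruth:
    """Ground truth attached to simulated experiments.

    ``expressed`` is probe x group (biology of the input amount),
    ``captured`` is probe x sample (survived capture/amplification), and
    ``captured`` implies ``expressed`` for the sample's group.
    """

    expressed: pd.DataFrame
    captured: pd.DataFrame
    true_abundance: pd.Series

    def validate(self, groups: Mapping[str, str]) -> None:
        for sample, grp in groups.items():
            if sample not in self.captured.columns:
                continue
            bad = self.captured[sample] & ~self.expressed[grp]
            if bad.any():
                raise ValueError("captured probe not expressed in its group")


@dataclass
class ExperimentSet:
    """Probe x sample two-channel signal matrices plus annotation/metadata.

    ``af3``/``af5`` are DataFrames indexed by probe_id with sample_id
    columns, finite and non-negative, on the linear scale.
    """

    annotation: pd.DataFrame
    samples: pd.DataFrame
    af3: pd.DataFrame
    af5: pd.DataFrame
    truth: Optional[SimTruth] = None

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        ann = self.annotation
        if ann["probe_id"].duplicated().any():
            dupes = ann.loc[ann["probe_id"].duplicated(), "probe_id"].tolist()
            raise DuplicateProbeError(f"duplicate probe_id(s): {dupes[:5]}")
        if self.samples["sample_id"].duplicated().any():
            raise ArrayIOError("duplicate sample_id in metadata")
        gr = self.samples[["group", "replicate"]].astype(str).agg("/".join, axis=1)
        if gr.duplicated().any():
            raise ArrayIOError("(group, replicate) pairs must be unique")
        probes = ann["probe_id"].tolist()
        sample_ids = self.samples["sample_id"].tolist()
        for name, mat in (("af3", self.af3), ("af5", self.af5)):
            if list(mat.index) != probes or list(mat.columns) != sample_ids:
                raise DimensionMismatchError(
                    f"{name} matrix does not match annotation x samples "
                    f"({mat.shape} vs {len(probes)}x{len(sample_ids)})"
                )
            vals = mat.to_numpy(dtype=float)
            if not np.isfinite(vals).all():
                raise ArrayIOError(f"{name} contains non-finite values")
            if (vals < 0).any():
                raise NegativeSignalError(f"{name} contains negative signal")
        excl = self.samples["qc_excluded"].astype(bool)
        reasons = self.samples["qc_reason"].fillna("").astype(str)
        if (excl & (reasons.str.len() == 0)).any():
            raise ArrayIOError("excluded samples must carry a non-empty qc_reason")

    # -- convenience ------------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.annotation["probe_id"])

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.samples["sample_id"])

    @property
    def n_probes(self) -> int:
        return len(self.annotation)

    def groups(self) -> Sequence[str]:
        return list(dict.fromkeys(self.samples["group"].astype(str)))

    def samples_in_group(self, group: str, include_excluded: bool = False) -> list[str]:
        sel = self.samples["group"].astype(str) == str(group)
        if not include_excluded:
            sel &= ~self.samples["qc_excluded"].astype(bool)
        return self.samples.loc[sel, "sample_id"].tolist()

    def noncontrol_probes(self) -> pd.Index:
        keep = ~self.annotation["is_control"].astype(bool)
        return pd.Index(self.annotation.loc[keep.to_numpy(), "probe_id"])

    def exclude_samples(self, reasons: Mapping[str, str]) -> "ExperimentSet":
        """Return a copy with the given samples flagged as QC-excluded."""
        samples = self.samples.copy()
        for sid, why in reasons.items():
            if not why:
                raise ArrayIOError("exclusion reason must be non-empty")
            mask = samples["sample_id"] == sid
            samples.loc[mask, "qc_excluded"] = True
            samples.loc[mask, "qc_reason"] = why
        return ExperimentSet(self.annotation.copy(), samples, self.af3.copy(),
                             self.af5.copy(), truth=self.truth)

    def drop_excluded(self) -> "ExperimentSet":
        keep = ~self.samples["qc_excluded"].astype(bool)
        samples = self.samples.loc[keep].reset_index(drop=True)
        ids = samples["sample_id"].tolist()
        return ExperimentSet(self.annotation.copy(), samples,
                             self.af3[ids], self.af5[ids], truth=self.truth)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")


# ---------------------------------------------------------------------------
# readers / writers


def _normalize_meta(meta: pd.DataFrame) -> pd.DataFrame:
    meta = meta.copy()
    for col in ("sample_id", "group", "day"):
        if col not in meta.columns:
            raise ArrayIOError(f"metadata table missing column {col!r}")
        meta[col] = meta[col].astype(str)
    if "replicate" not in meta.columns:
        meta["replicate"] = 1
    meta["replicate"] = meta["replicate"].astype(int)
    if (meta["replicate"] < 1).any():
        raise ArrayIOError("replicate must be >= 1")
    if "qc_excluded" not in meta.columns:
        meta["qc_excluded"] = False
    meta["qc_excluded"] = meta["qc_excluded"].astype(bool)
    if "qc_reason" not in meta.columns:
        meta["qc_reason"] = ""
    meta["qc_reason"] = meta["qc_reason"].fillna("").astype(str)
    return meta[META_COLUMNS]


def _normalize_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    ann = ann.copy()
    ann["probe_id"] = ann["probe_id"].astype(str)
    if "gene_symbol" not in ann.columns:
        ann["gene_symbol"] = ""
    ann["gene_symbol"] = ann["gene_symbol"].fillna("").astype(str)
    if "is_control" not in ann.columns:
        ann["is_control"] = False
    ann["is_control"] = ann["is_control"].astype(bool)
    return ann[ANNOT_COLUMNS]


def read_experiment(signal_path, meta_path) -> ExperimentSet:
    """Read a signal table plus a metadata table into an :class:`ExperimentSet`.

    Probe and sample order are taken verbatim from the files; samples present
    in the signal table but absent from the metadata table are an error.
    """
    sig = pd.read_csv(signal_path, sep="\t", dtype={"probe_id": str},
                      float_precision="round_trip")
    if "probe_id" not in sig.columns:
        raise ArrayIOError("signal table has no probe_id column")
    meta = _normalize_meta(pd.read_csv(meta_path, sep="\t"))

    suffixed = [c for c in sig.columns if c.endswith("_AF3") or c.endswith("_AF5")]
    sample_order = list(dict.fromkeys(c[:-4] for c in suffixed))
    known = set(meta["sample_id"])
    unknown = [s for s in sample_order if s not in known]
    if unknown:
        raise ArrayIOError(f"signal table has samples missing from metadata: {unknown}")
    for s in sample_order:
        if f"{s}_AF3" not in sig.columns or f"{s}_AF5" not in sig.columns:
            raise DimensionMismatchError(f"sample {s!r} lacks a paired AF3/AF5 column")

    # keep metadata rows in signal-table column order, then any signal-less rows
    meta_by_id = meta.set_index("sample_id", drop=False)
    missing = [s for s in meta["sample_id"] if s not in sample_order]
    if missing:
        raise DimensionMismatchError(
            f"metadata samples absent from signal table: {missing}")
    meta = meta_by_id.loc[sample_order].reset_index(drop=True)

    annot_cols = [c for c in ANNOT_COLUMNS if c in sig.columns]
    annotation = _normalize_annotation(sig[annot_cols])
    probes = annotation["probe_id"]
    af3 = sig[[f"{s}_AF3" for s in sample_order]].astype(float)
    af3.columns = sample_order
    af3.index = probes
    af5 = sig[[f"{s}_AF5" for s in sample_order]].astype(float)
    af5.columns = sample_order
    af5.index = probes
    return ExperimentSet(annotation, meta, af3, af5)


def write_experiment(es: ExperimentSet, signal_path, meta_path) -> None:
    sig = es.annotation.copy()
    for s in es.sample_ids:
        sig[f"{s}_AF3"] = es.af3[s].to_numpy()
        sig[f"{s}_AF5"] = es.af5[s].to_numpy()
    # %.17g round-trips IEEE doubles exactly
    sig.to_csv(signal_path, sep="\t", index=False, float_format="%.17g")
    es.samples.to_csv(meta_path, sep="\t", index=False)


def write_truth(truth: SimTruth, path) -> None:
    out = truth.expressed.astype(int).add_prefix("expressed_")
    out = out.join(truth.captured.astype(int).add_prefix("captured_"))
    out.insert(0, "true_abundance", truth.true_abundance)
    out.to_csv(path, sep="\t", index_label="probe_id")


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: ``name TAB description TAB member...`` per line.

    Blank lines are skipped; duplicate members within a line are collapsed.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}")
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in seen:
                raise GMTParseError(f"line {lineno}: duplicate set name {name!r}")
            seen.add(name)
            sets.append(GeneSet(name, desc, frozenset(members)))
    return sets


def write_gmt(sets: Sequence[GeneSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


def from_channel_matrices(af3_path, af5_path, meta_path,
                          annotation_path=None) -> ExperimentSet:
    """Converter from a GEO series-matrix-like layout.

    Each channel lives in its own probe x sample TSV whose first column is
    the probe identifier; metadata follows the usual layout.  An optional
    annotation TSV supplies gene_symbol/is_control.
    """
    af3 = pd.read_csv(af3_path, sep="\t", index_col=0,
                      float_precision="round_trip")
    af5 = pd.read_csv(af5_path, sep="\t", index_col=0,
                      float_precision="round_trip")
    if list(af3.index) != list(af5.index) or list(af3.columns) != list(af5.columns):
        raise DimensionMismatchError("channel matrices disagree in shape/labels")
    af3.index = af3.index.astype(str)
    af5.index = af5.index.astype(str)
    meta = _normalize_meta(pd.read_csv(meta_path, sep="\t"))
    meta = meta.set_index("sample_id", drop=False).loc[list(af3.columns)]
    meta = meta.reset_index(drop=True)
    if annotation_path is not None:
        annotation = _normalize_annotation(
            pd.read_csv(annotation_path, sep="\t", dtype={"probe_id": str}))
        annotation = annotation.set_index("probe_id", drop=False)
        annotation = annotation.loc[list(af3.index)].reset_index(drop=True)
    else:
        annotation = _normalize_annotation(pd.DataFrame({"probe_id": af3.index}))
    return ExperimentSet(annotation, meta, af3, af5)


# ---------------------------------------------------------------------------
# report serialization helpers shared by downstream modules


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
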