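"""RT-qPCR validation arm: triplicate Cq aggregation, delta-Cq normalization
to a reference gene, detection calls, and housekeeping-based failure flags."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .qc import QCReport, flag_outlier_samples
from .synthetic_data import QPCRPlate

__all__ = [
    "ExpressionCall",
    "summarize_plate",
    "calls_to_frame",
    "flag_failed_samples",
    "detection_count_table",
    "HOUSEKEEPING_GENES",
    "REFERENCE_GENE",
]

REFERENCE_GENE = "RPL13A"
HOUSEKEEPING_GENES = ("ACTB", "RPL13A", "YWHAZ", "GAPDH")

# a gene counts as detected when at least this many triplicates amplify
MIN_AMPLIFIED_REPLICATES = 2


@dataclass
class ExpressionCall:
    sample_id: str
    group: str
    gene: str
    n_amplified: int
    mean_cq: Optional[float]
    delta_cq: Optional[float]          # vs reference gene, same sample
    relative_expression: Optional[float]  # 2^(-delta_cq)
    detected: bool


def summarize_plate(plate: QPCRPlate,
                    reference_gene: str = REFERENCE_GENE
                    ) -> list[ExpressionCall]:
    """Aggregate triplicates into per-(sample, gene) expression calls.

    Mean Cq uses amplified replicates only; a gene is detected when >= 2 of
    its replicates amplified within ``max_cycles``.  delta-Cq and relative
    expression 2^(-dCq) are computed against the sample's reference-gene
    mean Cq, and left undefined when the reference itself is undetected.
    """
    df = plate.data[~plate.data["is_ntc"].astype(bool)]
    calls: list[ExpressionCall] = []
    for sid, sub in df.groupby("sample_id", sort=False):
        group = str(sub["group"].iloc[0])
        means: dict[str, Optional[float]] = {}
        amp_counts: dict[str, int] = {}
        for gene, rows in sub.groupby("gene", sort=False):
            amplified = rows["cq"].dropna()
            amp_counts[gene] = len(amplified)
            means[gene] = float(amplified.mean()) if len(amplified) else None
        ref_detected = amp_counts.get(reference_gene, 0) >= MIN_AMPLIFIED_REPLICATES
        ref_cq = means.get(reference_gene) if ref_detected else None
        for gene in means:
            detected = amp_counts[gene] >= MIN_AMPLIFIED_REPLICATES
            mean_cq = means[gene] if detected else None
            if detected and ref_cq is not None:
                dcq = mean_cq - ref_cq
                rel = float(2.0 ** (-dcq))
            else:
                dcq = rel = None
            calls.append(ExpressionCall(sample_id=str(sid), group=group,
                                        gene=gene,
                                        n_amplified=amp_counts[gene],
                                        mean_cq=mean_cq, delta_cq=dcq,
                                        relative_expression=rel,
                                        detected=detected))
    return calls


def calls_to_frame(calls: Sequence[ExpressionCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])


def flag_failed_samples(calls: Sequence[ExpressionCall],
                        housekeeping: Sequence[str] = HOUSEKEEPING_GENES,
                        alpha: float = 0.05, seed: int = 0) -> QCReport:
    """Dixon scan of per-sample mean housekeeping Cq, within each group.

    A sample whose mean Cq across the housekeeping panel is a Dixon outlier
    within its comparison group is marked failed.  Undetected housekeeping
    genes are ignored in the mean; a sample detecting none is failed outright.
    """
    df = calls_to_frame(list(calls))
    hk = df[df["gene"].isin(housekeeping)]
    mean_hk = (hk[hk["detected"]]
               .groupby("sample_id")["mean_cq"].mean())
    groups = df.drop_duplicates("sample_id").set_index("sample_id")["group"]
    no_hk = [s for s in groups.index if s not in mean_hk.index]

    metric = mean_hk.reindex([s for s in groups.index if s in mean_hk.index])
    report = flag_outlier_samples(
        {"housekeeping_cq": metric}, alpha=alpha,
        groups={s: str(groups.loc[s]) for s in metric.index}, seed=seed)
    for s in no_hk:
        report.exclusions[s] = "no housekeeping gene detected"
    return report


def detection_count_table(calls: Sequence[ExpressionCall],
                          genes: Sequence[str],
                          groups: Sequence[str]) -> pd.DataFrame:
    """Gene x group table of how many samples detected each gene."""
    df = calls_to_frame(list(calls))
    out = pd.DataFrame(0, index=list(genes), columns=[str(g) for g in groups])
    for g in genes:
        for grp in groups:
            sel = (df["gene"] == g) & (df["group"].astype(str) == str(grp))
            out.loc[g, str(grp)] = int(df.loc[sel, "detected"].sum())
    return out
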