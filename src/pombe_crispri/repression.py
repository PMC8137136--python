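"""RT-qPCR repression quantification: Cq -> relative mRNA -> %Repression.

The quantification chain mirrors the standard CRISPRi readout in fission
yeast. For each sample the target-gene Cq is normalized to the act1+
reference by the delta-Cq model, relative quantity = E^(Cq_ref - Cq_target)
with amplification efficiency E (2.0 = perfect doubling). Relative
quantities are converted to relative mRNA levels by dividing each replicate
by the mean of the nonsense-control (non-targeting sgRNA) group. The
repression index of a sample is the reciprocal of its relative mRNA level,
R_x = 1 / rel_mRNA, and percent repression scales R between the control
background and the strongest guide:

    %R_i = (R_i - mean(R_ns)) / (mean(R_max) - mean(R_ns)) * 100

so the nonsense group averages exactly 0% and the designated R_max group
exactly 100%, by construction, for any positive replicate values. Summaries
are mean +/- sample standard deviation (n-1 denominator) over biological
replicates; groups with fewer than three replicates are summarized but
flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

QPCR_CSV_COLUMNS = ["sample_id", "guide_id", "gene_role", "replicate", "cq"]


@dataclass(frozen=True)
class QpcrMeasurement:
    """One Cq value: a sample's target- or reference-gene amplification."""

    sample_id: str
    guide_id: str
    gene_role: str  # "target" or "reference"
    replicate: int
    cq: float

    def __post_init__(self) -> None:
        if self.gene_role not in ("target", "reference"):
            raise ValueError(
                f"gene_role must be 'target' or 'reference', got {self.gene_role!r}"
            )
        if self.replicate < 1:
            raise ValueError(f"replicate must be a positive integer, got {self.replicate}")
        if not math.isfinite(self.cq) or self.cq <= 0:
            raise ValueError(f"cq must be finite and > 0, got {self.cq}")


@dataclass(frozen=True)
class RepressionSummary:
    """Per-guide replicate summary of the full quantification chain."""

    guide_id: str
    n: int
    rel_mrna_mean: float
    rel_mrna_sd: float
    r_mean: float
    pct_repression_mean: float
    pct_repression_sd: float
    pct_reduction: float
    low_replicate: bool


def relative_quantity(cq_target: float, cq_reference: float, efficiency: float = 2.0) -> float:
    """Target quantity relative to the reference gene: E^(Cq_ref - Cq_target)."""
    if not (1.0 < efficiency <= 2.2):
        raise ValueError(f"efficiency must be in (1, 2.2], got {efficiency}")
    if not (math.isfinite(cq_target) and math.isfinite(cq_reference)):
        raise ValueError("Cq values must be finite")
    return efficiency ** (cq_reference - cq_target)


def percent_reduction(rel_mrna: float) -> float:
    """(1 - relative mRNA) * 100: e.g. a level of 0.13 is an 87% reduction."""
    if rel_mrna <= 0:
        raise ValueError(f"relative mRNA must be > 0, got {rel_mrna}")
    return (1.0 - rel_mrna) * 100.0


def _sample_sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if len(values) > 1 else float("nan")


def percent_repression(
    test_rel: Sequence[float],
    nonsense_rel: Sequence[float],
    rmax_rel: Sequence[float],
) -> tuple[np.ndarray, float, float]:
    """Per-replicate % repression of a test group, plus (mean, sample SD).

    All three inputs are relative quantities (vs. the reference gene) or
    relative mRNA levels — any common positive scaling cancels. Each value is
    first divided by the nonsense-control mean, reciprocals give repression
    indices, and the indices are rescaled so that mean(R_ns) maps to 0% and
    mean(R_max) to 100%.

    Raises ValueError on nonpositive inputs or when the R_max and control
    group means coincide (degenerate normalization).
    """
    test = np.asarray(test_rel, dtype=float)
    ns = np.asarray(nonsense_rel, dtype=float)
    rmax = np.asarray(rmax_rel, dtype=float)
    if ns.size == 0 or rmax.size == 0:
        raise ValueError("nonsense and rmax groups must be non-empty")
    for arr, name in ((test, "test"), (ns, "nonsense"), (rmax, "rmax")):
        if np.any(arr <= 0):
            raise ValueError(f"{name} group contains nonpositive values")

    ns_mean = ns.mean()
    r_test = 1.0 / (test / ns_mean)
    r_ns = 1.0 / (ns / ns_mean)
    r_max = 1.0 / (rmax / ns_mean)
    denom = r_max.mean() - r_ns.mean()
    if denom == 0:
        raise ValueError(
            "degenerate normalization: mean(R_max) equals mean(R_ns)"
        )
    pct = (r_test - r_ns.mean()) / denom * 100.0
    return pct, float(pct.mean()), _sample_sd(pct)


def read_qpcr_csv(path: str | Path) -> list[QpcrMeasurement]:
    """Read the qPCR input CSV (sample_id, guide_id, gene_role, replicate, cq)."""
    df = pd.read_csv(path)
    missing = [c for c in QPCR_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        QpcrMeasurement(
            sample_id=str(r.sample_id),
            guide_id=str(r.guide_id),
            gene_role=str(r.gene_role),
            replicate=int(r.replicate),
            cq=float(r.cq),
        )
        for r in df.itertuples(index=False)
    ]


def _paired_quantities(
    measurements: Iterable[QpcrMeasurement], efficiency: float
) -> pd.DataFrame:
    """Pair target/reference Cq per (sample, replicate) into relative quantities."""
    df = pd.DataFrame([m.__dict__ for m in measurements])
    if df.empty:
        raise ValueError("no measurements provided")
    dup = df.duplicated(subset=["sample_id", "gene_role", "replicate"])
    if dup.any():
        bad = df[dup].iloc[0]
        raise ValueError(
            f"duplicate measurement for sample {bad.sample_id!r} "
            f"role {bad.gene_role!r} replicate {bad.replicate}"
        )
    wide = df.pivot_table(
        index=["sample_id", "guide_id", "replicate"],
        columns="gene_role",
        values="cq",
        aggfunc="first",
    ).reset_index()
    if "target" not in wide.columns or "reference" not in wide.columns:
        raise ValueError("measurements must include both target and reference roles")
    unpaired = wide[wide["target"].isna() | wide["reference"].isna()]
    if not unpaired.empty:
        bad = unpaired.iloc[0]
        raise ValueError(
            f"sample {bad.sample_id!r} replicate {int(bad.replicate)} lacks a "
            "matching target/reference Cq pair"
        )
    wide["quantity"] = [
        relative_quantity(t, r, efficiency)
        for t, r in zip(wide["target"], wide["reference"])
    ]
    return wide[["sample_id", "guide_id", "replicate", "quantity"]]


def summarize_repression(
    measurements: Iterable[QpcrMeasurement],
    control_guide: str,
    rmax_guide: str = "auto",
    efficiency: float = 2.0,
) -> list[RepressionSummary]:
    """Apply the full quantification chain and summarize per guide.

    control_guide names the nonsense (non-targeting) group; rmax_guide names
    the guide whose mean repression index anchors 100%, or "auto" to pick the
    guide with the highest mean index. Guides with fewer than three
    replicates are summarized with low_replicate=True. Output is sorted by
    guide_id for determinism.
    """
    quantities = _paired_quantities(measurements, efficiency)
    groups = {
        gid: np.asarray(sub["quantity"], dtype=float)
        for gid, sub in quantities.groupby("guide_id")
    }
    if control_guide not in groups:
        raise KeyError(f"control guide {control_guide!r} absent from measurements")

    ns_mean = groups[control_guide].mean()
    rel = {gid: q / ns_mean for gid, q in groups.items()}
    r_mean = {gid: float((1.0 / v).mean()) for gid, v in rel.items()}

    if rmax_guide == "auto":
        rmax_guide = max(sorted(r_mean), key=lambda g: r_mean[g])
    elif rmax_guide not in groups:
        raise KeyError(f"rmax guide {rmax_guide!r} absent from measurements")

    summaries = []
    for gid in sorted(groups):
        pct, pct_mean, pct_sd = percent_repression(
            groups[gid], groups[control_guide], groups[rmax_guide]
        )
        v = rel[gid]
        summaries.append(
            RepressionSummary(
                guide_id=gid,
                n=len(v),
                rel_mrna_mean=float(v.mean()),
                rel_mrna_sd=_sample_sd(v),
                r_mean=r_mean[gid],
                pct_repression_mean=pct_mean,
                pct_repression_sd=pct_sd,
                pct_reduction=percent_reduction(float(v.mean())),
                low_replicate=len(v) < 3,
            )
        )
    return summaries


def summaries_to_tsv(summaries: Sequence[RepressionSummary]) -> str:
    """One row per guide; floats at 4 significant digits; flags in the last column."""
    cols = [
        "guide_id",
        "n",
        "rel_mrna_mean",
        "rel_mrna_sd",
        "r_mean",
        "pct_repression_mean",
        "pct_repression_sd",
        "pct_reduction",
        "flags",
    ]
    lines = ["\t".join(cols)]
    for s in summaries:
        flags = "low_replicate" if s.low_replicate else ""
        lines.append(
            "\t".join(
                [
                    s.guide_id,
                    str(s.n),
                    f"{s.rel_mrna_mean:.4g}",
                    f"{s.rel_mrna_sd:.4g}",
                    f"{s.r_mean:.4g}",
                    f"{s.pct_repression_mean:.4g}",
                    f"{s.pct_repression_sd:.4g}",
                    f"{s.pct_reduction:.4g}",
                    flags,
                ]
            )
        )
    return "\n".join(lines) + "\n"
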