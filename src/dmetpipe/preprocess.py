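"""Cleaning of genotype tables and the genotype-distribution matrix.

"Low information content" rows are removed before any analysis: probes whose
NoCall fraction exceeds a threshold, and (optionally) monomorphic probes —
those showing fewer than two distinct called genotypes, which cannot drive
any association, rule or survival contrast downstream.  The distribution
matrix counts each genotype category (NoCall included) per probe and is the
data behind the heat-map view of how SNPs distribute over the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io_dmet import NOCALL, GenotypeTable

REASON_NOCALL = "excess-NoCall"
REASON_MONOMORPHIC = "monomorphic"


@dataclass
class PreprocessReport:
    removed: list[tuple[str, str]] = field(default_factory=list)  # (probe_id, reason)
    retained_count: int = 0
    nocall_fraction: dict[str, float] = field(default_factory=dict)

    @property
    def removed_probe_ids(self) -> list[str]:
        return [p for p, _ in self.removed]

    def to_frame(self) -> pd.DataFrame:
        reason = dict(self.removed)
        return pd.DataFrame(
            {
                "probe_id": list(self.nocall_fraction),
                "status": ["removed" if p in reason else "retained" for p in self.nocall_fraction],
                "reason": [reason.get(p, "") for p in self.nocall_fraction],
                "nocall_fraction": [self.nocall_fraction[p] for p in self.nocall_fraction],
            }
        )


@dataclass
class DistributionMatrix:
    """Per-probe genotype-category counts; each row sums to the sample count."""

    counts: pd.DataFrame  # probes x categories, NoCall last

    @property
    def probe_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def category_labels(self) -> list[str]:
        return list(self.counts.columns)


def filter_uninformative(
    table: GenotypeTable,
    max_nocall_fraction: float = 0.1,
    drop_monomorphic: bool = True,
) -> tuple[GenotypeTable, PreprocessReport]:
    """Drop probes with excess NoCall or (optionally) a single called genotype.

    A probe failing both checks is recorded once, with the NoCall reason
    taking precedence; monomorphism is judged on the called cells only.
    Probe order is preserved; an empty result is legal.
    """
    if not 0 <= max_nocall_fraction <= 1:
        raise ValueError("max_nocall_fraction must lie in [0, 1]")
    report = PreprocessReport()
    keep: list[str] = []
    n = len(table.sample_ids)
    for probe in table.probe_ids:
        row = table.calls.loc[probe]
        nocall = (row == NOCALL).sum()
        frac = nocall / n if n else 0.0
        report.nocall_fraction[probe] = frac
        if frac > max_nocall_fraction:
            report.removed.append((probe, REASON_NOCALL))
            continue
        if drop_monomorphic and row[row != NOCALL].nunique() < 2:
            report.removed.append((probe, REASON_MONOMORPHIC))
            continue
        keep.append(probe)
    report.retained_count = len(keep)
    return table.subset_probes(keep), report


def genotype_distribution(table: GenotypeTable) -> DistributionMatrix:
    """Count genotype categories per probe, NoCall as its own category."""
    if not table.probe_ids:
        raise ValueError("empty genotype table")
    counts = (
        table.calls.apply(lambda r: r.value_counts(), axis=1)
        .fillna(0)
        .astype(int)
    )
    cats = sorted(c for c in counts.columns if c != NOCALL)
    if NOCALL not in counts.columns:
        counts[NOCALL] = 0
    counts = counts[cats + [NOCALL]]
    return DistributionMatrix(counts)
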