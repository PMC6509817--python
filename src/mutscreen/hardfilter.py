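"""Hard filtering of variant calls.

Per-metric threshold rules in the GATK hard-filter style, split by variant
class, plus a depth window and a clustered-SNP rule (any SNP inside a 10 bp
reference window holding 3 or more SNPs fails).  Thresholds are strict
inequalities exactly as configured, so DP=4 and DP=200 pass the default
depth rule.  A rule whose metric is absent from a record is skipped, never
failed: rank-sum statistics are routinely missing at homozygous sites and
their absence carries no evidence against the call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ValidationError
from .formats import SNP, VariantRecord

LT = "lt"
GT = "gt"

CLUSTER_RULE = "SNPcluster"
DEPTH_RULE = "DP"


@dataclass(frozen=True)
class ThresholdRule:
    """Fail a record when ``metric <op> threshold`` (strict inequality)."""

    name: str
    metric: str
    op: str
    threshold: float

    def __post_init__(self) -> None:
        if self.op not in (LT, GT):
            raise ValidationError(f"rule {self.name}: op must be 'lt' or 'gt'")
        if not math.isfinite(self.threshold):
            raise ValidationError(f"rule {self.name}: non-finite threshold")

    def fires(self, metrics: dict[str, float]) -> bool | None:
        """True/False if the metric is present, None if skipped."""
        value = metrics.get(self.metric)
        if value is None:
            return None
        return value < self.threshold if self.op == LT else value > self.threshold


def _default_snp_rules() -> tuple[ThresholdRule, ...]:
    return (
        ThresholdRule("QD", "QD", LT, 2.0),
        ThresholdRule("MQ", "MQ", LT, 40.0),
        ThresholdRule("FS", "FS", GT, 60.0),
        ThresholdRule("HaplotypeScore", "HaplotypeScore", GT, 13.0),
        ThresholdRule("MQRankSum", "MQRankSum", LT, -12.5),
        ThresholdRule("ReadPosRankSum", "ReadPosRankSum", LT, -8.0),
    )


def _default_indel_rules() -> tuple[ThresholdRule, ...]:
    return (
        ThresholdRule("QD", "QD", LT, 2.0),
        ThresholdRule("ReadPosRankSum", "ReadPosRankSum", LT, -20.0),
        ThresholdRule("FS", "FS", GT, 200.0),
    )


@dataclass
class FilterConfig:
    """Thresholds for both variant classes plus the cluster-window rule.

    ``dp_min``/``dp_max`` bound read depth for SNPs and indels alike; the
    record fails when DP < dp_min or DP > dp_max.
    """

    snp_rules: tuple[ThresholdRule, ...] = field(default_factory=_default_snp_rules)
    indel_rules: tuple[ThresholdRule, ...] = field(default_factory=_default_indel_rules)
    dp_min: float = 4.0
    dp_max: float = 200.0
    cluster_window_bp: int = 10
    cluster_min_snps: int = 3

    def __post_init__(self) -> None:
        if self.cluster_window_bp < 1:
            raise ValidationError("cluster window must be >= 1 bp")
        if self.cluster_min_snps < 2:
            raise ValidationError("cluster rule needs min_snps >= 2")
        if not (math.isfinite(self.dp_min) and math.isfinite(self.dp_max)):
            raise ValidationError("depth bounds must be finite")


@dataclass
class FilterVerdict:
    variant: VariantRecord
    failed_rules: list[str] = field(default_factory=list)
    skipped_rules: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.failed_rules


def apply_site_filters(
    records: Iterable[VariantRecord], config: FilterConfig | None = None
) -> list[FilterVerdict]:
    """Evaluate per-site threshold rules; every failed rule is recorded."""
    config = config or FilterConfig()
    verdicts: list[FilterVerdict] = []
    for rec in records:
        rules = config.snp_rules if rec.is_snp else config.indel_rules
        verdict = FilterVerdict(rec)
        for rule in rules:
            outcome = rule.fires(rec.metrics)
            if outcome is None:
                verdict.skipped_rules.append(rule.name)
            elif outcome:
                verdict.failed_rules.append(rule.name)
        dp = rec.metrics.get("DP")
        if dp is None:
            verdict.skipped_rules.append(DEPTH_RULE)
        elif dp < config.dp_min or dp > config.dp_max:
            verdict.failed_rules.append(DEPTH_RULE)
        verdicts.append(verdict)
    return verdicts


def _check_sorted(records: Sequence[VariantRecord]) -> None:
    for a, b in zip(records, records[1:]):
        if (a.contig_id, a.pos) > (b.contig_id, b.pos):
            raise ValidationError(
                f"records not sorted by (contig, pos) at {b.contig_id}:{b.pos}"
            )


def apply_cluster_filter(
    records: Sequence[VariantRecord], config: FilterConfig | None = None
) -> list[FilterVerdict]:
    """Flag clustered SNPs; indels neither trigger nor receive the rule.

    A SNP fails when at least one window of ``cluster_window_bp`` consecutive
    reference bases on its contig contains ``cluster_min_snps`` or more SNPs
    including itself — equivalently, when some run of ``cluster_min_snps``
    SNPs including it spans at most ``cluster_window_bp`` bases.
    """
    config = config or FilterConfig()
    _check_sorted(records)
    failing: set[int] = set()
    snp_idx = [i for i, r in enumerate(records) if r.is_snp]
    k, w = config.cluster_min_snps, config.cluster_window_bp
    # two-pointer scan over SNP positions per contig
    by_contig: dict[str, list[int]] = {}
    for i in snp_idx:
        by_contig.setdefault(records[i].contig_id, []).append(i)
    for idxs in by_contig.values():
        positions = [records[i].pos for i in idxs]
        n = len(positions)
        for j in range(n - k + 1):
            if positions[j + k - 1] - positions[j] <= w - 1:
                lo, hi = positions[j], positions[j] + w - 1
                for m in range(j, n):
                    if positions[m] > hi:
                        break
                    if positions[m] >= lo:
                        failing.add(idxs[m])
    verdicts = []
    for i, rec in enumerate(records):
        verdict = FilterVerdict(rec)
        if i in failing:
            verdict.failed_rules.append(CLUSTER_RULE)
        verdicts.append(verdict)
    return verdicts


def filter_pipeline(
    records: Sequence[VariantRecord], config: FilterConfig | None = None
) -> tuple[list[VariantRecord], list[FilterVerdict]]:
    """Site rules + cluster rule; returns (passing records, full report)."""
    config = config or FilterConfig()
    ordered = sorted(records, key=lambda v: v.key)
    site = apply_site_filters(ordered, config)
    cluster = apply_cluster_filter(ordered, config)
    report: list[FilterVerdict] = []
    passing: list[VariantRecord] = []
    for sv, cv in zip(site, cluster):
        merged = FilterVerdict(
            sv.variant,
            failed_rules=sv.failed_rules + cv.failed_rules,
            skipped_rules=sv.skipped_rules,
        )
        report.append(merged)
        if merged.passed:
            passing.append(merged.variant)
    return passing, report


def summarize_filter(report: Iterable[FilterVerdict]) -> dict[str, int]:
    """Per-rule failure counts plus pass counts per variant class."""
    summary: dict[str, int] = {"pass_SNP": 0, "pass_indel": 0, "fail_total": 0}
    for verdict in report:
        if verdict.passed:
            key = "pass_SNP" if verdict.variant.is_snp else "pass_indel"
            summary[key] += 1
        else:
            summary["fail_total"] += 1
        for rule in verdict.failed_rules:
            summary[f"fail_{rule}"] = summary.get(f"fail_{rule}", 0) + 1
    return summary
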