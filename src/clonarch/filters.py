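"""Post-caller somatic filter rules for exome calls and targeted deep-seq
validation rules, operating on tumor/normal read-count tables.

The exome rules assume a caller already ran (MuTect for SNVs, Strelka for
indels); these filters tighten its output to a confident somatic set.  The
deep-seq rules decide, for each exome call re-sequenced at high depth, whether
it is validated.  Every failed decision names the rules it violated, so the
filters double as an audit trail.

Rule semantics at the normal-VAF boundary: a tumor/normal VAF-ratio test with
normal VAF = 0 passes (the limit of the ratio), and all VAF thresholds use
``>=`` at the boundary (configurable nowhere; documented here).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .types import MutationKey, VariantRecord


class ZeroDepthError(ValueError):
    """Tumor depth is zero, so the VAF (and every VAF rule) is undefined."""


class MissingExomeMembershipError(ValueError):
    """Deep-seq SNV validation requires the exome-called membership flag."""


# rule identifiers, referenced in decision tables and tests
R_NORMAL_ALT_COUNT = "normal_alt_count"      # <=5 alt reads in the normal
R_NORMAL_VAF = "normal_vaf"                  # normal VAF <= 0.05
R_MIN_ALT_READS = "min_alt_reads"            # minimum tumor alt reads
R_LOW_VAF_RATIO = "low_vaf_ratio"            # VAF<0.2 needs >=10x normal VAF
R_MIN_VAF = "min_vaf"                        # tumor VAF floor
R_LOW_VAF_ALT_READS = "low_vaf_alt_reads"    # VAF<0.05 needs >=15 alt reads
R_TUMOR_NORMAL_RATIO = "tumor_normal_ratio"  # tumor VAF >= 5x normal VAF
R_EXOME_MEMBERSHIP = "exome_membership"      # must have been called in exome
R_STRAND_BIAS = "strand_bias"                # <=90% of alt reads on one strand


@dataclass
class FilterDecision:
    """Outcome of applying a rule set to one variant observation."""

    key: MutationKey
    sector_id: str
    passed: bool
    failed_rules: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.passed != (not self.failed_rules):
            raise ValueError("passed must be equivalent to failed_rules being empty")


def _decision(v: VariantRecord, failed: list[str]) -> FilterDecision:
    return FilterDecision(
        key=v.key, sector_id=v.sector_id, passed=not failed, failed_rules=failed
    )


def _require_depth(v: VariantRecord) -> float:
    if v.tumor_depth == 0:
        raise ZeroDepthError(
            f"zero tumor depth for {v.key} in sector {v.sector_id}: VAF undefined"
        )
    return v.tumor_vaf


def filter_exome_snv(v: VariantRecord) -> FilterDecision:
    """Somatic filter for exome SNV calls.

    Pass requires: <=5 alt reads in the normal at <=0.05 normal VAF (the
    caller's contamination guard), >=6 tumor alt reads, and for calls with
    tumor VAF < 0.2, a tumor VAF at least 10x the normal VAF.
    """
    tvaf = _require_depth(v)
    nvaf = v.normal_vaf
    failed = []
    if v.n_alt > 5:
        failed.append(R_NORMAL_ALT_COUNT)
    if nvaf > 0.05:
        failed.append(R_NORMAL_VAF)
    if v.t_alt < 6:
        failed.append(R_MIN_ALT_READS)
    if not (tvaf >= 0.2 or tvaf >= 10.0 * nvaf):
        failed.append(R_LOW_VAF_RATIO)
    return _decision(v, failed)


def filter_exome_indel(v: VariantRecord) -> FilterDecision:
    """Somatic filter for exome indel calls: >4 supporting reads and tumor
    VAF >= 0.1 (MAPQ filtering is assumed upstream of the count table)."""
    tvaf = _require_depth(v)
    failed = []
    if v.t_alt <= 4:
        failed.append(R_MIN_ALT_READS)
    if tvaf < 0.1:
        failed.append(R_MIN_VAF)
    return _decision(v, failed)


def validate_deepseq_snv(v: VariantRecord, exome_called: Optional[bool]) -> FilterDecision:
    """Deep-seq validation for an SNV previously screened by exome-seq.

    Pass requires exome membership, >=10 tumor alt reads (>=15 when tumor
    VAF < 0.05), tumor VAF >= 0.01, and tumor VAF >= 5x normal VAF.
    """
    if exome_called is None:
        raise MissingExomeMembershipError(
            f"exome membership flag missing for {v.key} in sector {v.sector_id}"
        )
    tvaf = _require_depth(v)
    nvaf = v.normal_vaf
    failed = []
    if not exome_called:
        failed.append(R_EXOME_MEMBERSHIP)
    if v.t_alt < 10:
        failed.append(R_MIN_ALT_READS)
    if tvaf < 0.05 and v.t_alt < 15:
        failed.append(R_LOW_VAF_ALT_READS)
    if tvaf < 5.0 * nvaf:
        failed.append(R_TUMOR_NORMAL_RATIO)
    if tvaf < 0.01:
        failed.append(R_MIN_VAF)
    return _decision(v, failed)


def validate_deepseq_indel(v: VariantRecord) -> FilterDecision:
    """Deep-seq validation for an indel: balanced strands (<=90% of alt reads
    on one strand), >=10 alt reads, tumor VAF >= 0.03 and >= 5x normal VAF.

    With zero alt reads the strand fraction is undefined; the decision fails
    with the strand-bias rule (and the read-count rules) rather than raising.
    """
    tvaf = _require_depth(v)
    nvaf = v.normal_vaf
    failed = []
    if v.alt_fwd is None or v.alt_rev is None:
        raise ValueError(
            f"strand counts required for deep-seq indel validation of {v.key}"
        )
    if v.t_alt == 0 or max(v.alt_fwd, v.alt_rev) / v.t_alt > 0.9:
        failed.append(R_STRAND_BIAS)
    if v.t_alt < 10:
        failed.append(R_MIN_ALT_READS)
    if tvaf < 0.03:
        failed.append(R_MIN_VAF)
    if tvaf < 5.0 * nvaf:
        failed.append(R_TUMOR_NORMAL_RATIO)
    return _decision(v, failed)


def apply_filters(
    v: VariantRecord, exome_called: Optional[bool] = None
) -> FilterDecision:
    """Dispatch to the rule set matching the record's assay and class."""
    if v.assay == "exome":
        return filter_exome_snv(v) if v.variant_class == "SNV" else filter_exome_indel(v)
    if v.variant_class == "SNV":
        return validate_deepseq_snv(v, exome_called)
    return validate_deepseq_indel(v)


def validation_rate(
    exome_calls: Iterable[VariantRecord],
    deepseq_decisions: Mapping[tuple[MutationKey, str], FilterDecision],
) -> dict[str, float]:
    """Per-class validation rate of exome calls re-tested by deep sequencing.

    ``deepseq_decisions`` is keyed by (mutation key, sector id); exome calls
    without a deep-seq decision are treated as lacking deep-seq coverage and
    excluded from the denominator.  Rates are NaN when nothing was attempted.
    """
    attempted = {"snv": 0, "indel": 0}
    validated = {"snv": 0, "indel": 0}
    for call in exome_calls:
        decision = deepseq_decisions.get((call.key, call.sector_id))
        if decision is None:
            continue
        cls = "snv" if call.variant_class == "SNV" else "indel"
        attempted[cls] += 1
        if decision.passed:
            validated[cls] += 1
    return {
        "snv_rate": validated["snv"] / attempted["snv"] if attempted["snv"] else math.nan,
        "indel_rate": (
            validated["indel"] / attempted["indel"] if attempted["indel"] else math.nan
        ),
    }
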