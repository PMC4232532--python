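"""Validation-rate arithmetic for Sanger-checked SNP panels.

Given the counts from a resequencing validation experiment (SNPs detected
by the pipeline across the validated regions, those with no usable Sanger
data, and those confirmed), this module computes the validation and
false-positive rates on both the with-data and the all-detected
denominators, plus the false-negative rate among Sanger-discovered SNPs in
adequately covered regions. All rates are integer percents, rounded
half-up, which is the convention the input tables are reported in.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


def round_half_up_percent(numerator: int, denominator: int) -> int:
    """round(100 * numerator / denominator) with exact half-up tie-breaking."""
    if denominator == 0:
        raise ZeroDivisionError("zero denominator in rate computation")
    return (200 * numerator + denominator) // (2 * denominator)


@dataclass(frozen=True)
class ValidationCounts:
    """Counts over the validated regions: detected / no-data / confirmed."""

    n_detected: int
    n_no_data: int
    n_confirmed: int

    def __post_init__(self) -> None:
        if min(self.n_detected, self.n_no_data, self.n_confirmed) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_confirmed > self.n_detected - self.n_no_data:
            raise ValueError("confirmed SNPs exceed those with Sanger data")


@dataclass(frozen=True)
class FalseNegativeCounts:
    """SNPs found in the Sanger reads, by pipeline outcome."""

    n_sanger_total: int
    n_called: int
    n_below_coverage: int
    n_missed: int

    def __post_init__(self) -> None:
        if min(self.n_sanger_total, self.n_called,
               self.n_below_coverage, self.n_missed) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_called + self.n_below_coverage + self.n_missed != self.n_sanger_total:
            raise ValueError("called + below_coverage + missed must equal total")


@dataclass(frozen=True)
class ValidationRates:
    """Integer-percent rates; with-data rates use the detected - no-data
    denominator, overall rates the full detected denominator."""

    validation_rate_with_data: int
    fp_rate_with_data: int
    validation_rate_overall: int
    fp_rate_overall: int
    unknown_rate: int
    fn_rate: int | None = None


def compute_validation_rates(counts: ValidationCounts) -> ValidationRates:
    """Validation/false-positive/unknown rates from a validation count table."""
    with_data = counts.n_detected - counts.n_no_data
    false_pos = with_data - counts.n_confirmed
    return ValidationRates(
        validation_rate_with_data=round_half_up_percent(counts.n_confirmed, with_data),
        fp_rate_with_data=round_half_up_percent(false_pos, with_data),
        validation_rate_overall=round_half_up_percent(counts.n_confirmed, counts.n_detected),
        fp_rate_overall=round_half_up_percent(false_pos, counts.n_detected),
        unknown_rate=round_half_up_percent(counts.n_no_data, counts.n_detected),
    )


def compute_false_negative_rate(counts: FalseNegativeCounts) -> int:
    """Missed / (called + missed): the false-negative rate where coverage was
    adequate, as an integer percent."""
    return round_half_up_percent(counts.n_missed, counts.n_called + counts.n_missed)


def rates_report(vc: ValidationCounts, fnc: FalseNegativeCounts | None = None
                 ) -> pd.DataFrame:
    """A one-row rates table, suitable for TSV export."""
    rates = compute_validation_rates(vc)
    row = {
        "validation_rate_with_data": rates.validation_rate_with_data,
        "fp_rate_with_data": rates.fp_rate_with_data,
        "validation_rate_overall": rates.validation_rate_overall,
        "fp_rate_overall": rates.fp_rate_overall,
        "unknown_rate": rates.unknown_rate,
    }
    if fnc is not None:
        row["fn_rate"] = compute_false_negative_rate(fnc)
    return pd.DataFrame([row])
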