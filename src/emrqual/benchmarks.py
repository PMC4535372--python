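"""Benchmark rules, outlier flagging, and physician frequency distributions.

Fields whose ideal completeness is 100% for every patient carry fixed
benchmarks: 95% for the two most safety-critical fields (visit
documentation and allergies) and 80% for the remaining practice-style-
independent fields.  Practice-style-dependent fields (labs, prescriptions,
referrals, consultation letters) vary legitimately with clinical style, so
their benchmark is data-driven — the peer mean less one standard deviation
— and flags only the low outliers likely to reflect systemic EMR non-use.

Conventions (logged in output metadata): sample (n-1) standard deviation;
strict inequality, so a physician exactly at a benchmark meets it; the
mean - 1 SD threshold is computed within the stratum being reported, not
pooled across strata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .completeness import ALL_FIELDS

__all__ = [
    "BenchmarkRule",
    "BenchmarkResult",
    "benchmark_rule_for",
    "compute_benchmark",
    "rate_histogram",
    "FIXED_95_FIELDS",
    "FIXED_80_FIELDS",
    "MEAN_MINUS_SD_FIELDS",
]

FIXED_95_FIELDS = ("visit_documentation", "cpp_allergies")
FIXED_80_FIELDS = (
    "blood_pressure",
    "weight",
    "cpp_immunizations",
    "cpp_active_treatment",
    "cpp_risk_factors",
    "cpp_personal_traits",
    "cpp_family_history",
    "cpp_medical_history",
)
MEAN_MINUS_SD_FIELDS = ("lab_test", "prescription", "referral", "consult_letter")


@dataclass(frozen=True)
class BenchmarkRule:
    field: str
    rule_kind: str  # "fixed_95" | "fixed_80" | "mean_minus_sd"
    threshold: float


@dataclass(frozen=True)
class BenchmarkResult:
    rule: BenchmarkRule
    n_physicians: int
    below: frozenset[str]
    sd_ddof: int = 1

    @property
    def proportion_meeting(self) -> float:
        return 1.0 - len(self.below) / self.n_physicians


def benchmark_rule_for(field: str) -> str:
    """The rule kind applying to a completeness field."""
    if field in FIXED_95_FIELDS:
        return "fixed_95"
    if field in FIXED_80_FIELDS:
        return "fixed_80"
    if field in MEAN_MINUS_SD_FIELDS:
        return "mean_minus_sd"
    raise ValueError(f"no benchmark rule for field: {field!r}")


def compute_benchmark(
    field: str,
    rates: Mapping[str, float],
    rule_kind: str | None = None,
    sd_ddof: int = 1,
) -> BenchmarkResult:
    """Apply the field's benchmark rule to physician-level rates.

    ``rates`` maps physician id -> defined rate.  ``below`` holds the
    physicians strictly below the threshold.  The mean - 1 SD rule needs
    at least two rates; ``sd_ddof=1`` (sample sd) is the default,
    ``sd_ddof=0`` selects the population sd.
    """
    if field not in ALL_FIELDS:
        raise ValueError(f"unknown field: {field!r}")
    kind = rule_kind or benchmark_rule_for(field)
    vals = list(rates.values())
    if kind == "fixed_95":
        threshold = 0.95
        if len(vals) < 1:
            raise ValueError(f"benchmark for {field!r}: no rates supplied")
    elif kind == "fixed_80":
        threshold = 0.80
        if len(vals) < 1:
            raise ValueError(f"benchmark for {field!r}: no rates supplied")
    elif kind == "mean_minus_sd":
        if len(vals) < 2:
            raise ValueError(
                f"benchmark for {field!r}: mean - 1 SD needs >= 2 rates, "
                f"got {len(vals)}")
        mean = sum(vals) / len(vals)
        var = sum((v - mean) ** 2 for v in vals) / (len(vals) - sd_ddof)
        threshold = max(0.0, mean - math.sqrt(var))
    else:
        raise ValueError(f"unknown rule kind: {rule_kind!r}")

    below = frozenset(p for p, r in rates.items() if r < threshold)
    return BenchmarkResult(
        rule=BenchmarkRule(field=field, rule_kind=kind, threshold=threshold),
        n_physicians=len(rates),
        below=below,
        sd_ddof=sd_ddof,
    )


def rate_histogram(
    rates, bin_width: float = 0.05
) -> list[tuple[tuple[float, float], int]]:
    """Frequency distribution of physician rates over [0, 1].

    Half-open bins [0, w), ..., with the top bin closed ([1-w, 1]) so a
    rate of exactly 1.0 is counted.  ``bin_width`` must divide 1 evenly.
    Counts always sum to the number of rates supplied.
    """
    n_bins = round(1.0 / bin_width)
    if abs(n_bins * bin_width - 1.0) > 1e-9:
        raise ValueError(f"bin_width {bin_width} does not divide 1 evenly")
    counts = [0] * n_bins
    for r in rates:
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"rate {r} outside [0, 1]")
        # tolerance guards float quotients like 0.35/0.05 = 6.999...
        idx = min(int(math.floor(r / bin_width + 1e-9)), n_bins - 1)
        counts[idx] += 1
    return [
        ((round(i * bin_width, 10), round((i + 1) * bin_width, 10)), counts[i])
        for i in range(n_bins)
    ]
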