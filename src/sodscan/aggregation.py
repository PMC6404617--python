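"""Inclusion-assay count tables and the consequence/aggregation association.

The assay transfects SOD1:YFP variant constructs into cells and counts, at
24 h and 48 h, how many fluorescent cells contain bright inclusions.
This module recomputes the percentage cells-with-inclusions, dichotomises
variants into aggregators vs non-aggregators against the wild-type
background, and formalises the qualitative claim that predicted structural
consequences track aggregation as a 2x2 Fisher exact test. The source
assay reports counts only, no statistic; the association test is this
package's own formalisation and is labelled as such in reports.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InclusionCounts",
    "AssociationResult",
    "inclusion_fraction",
    "format_percentage",
    "round_half_up",
    "call_aggregator",
    "associate",
    "read_counts_table",
    "load_packaged_counts",
    "packaged_expected_labels",
    "aggregator_table",
]

# raw percentages strictly below this render as "<= 1%" rather than a
# rounded integer (reproduces the published table's display convention)
LE_ONE_DISPLAY_BELOW = 0.8

REQUIRED_COLUMNS = ("variant", "timepoint_hr", "n_counted", "n_inclusions")


@dataclass(frozen=True)
class InclusionCounts:
    """One variant x timepoint cell count record."""

    variant: str
    timepoint: int  # hours
    n_counted: int
    n_inclusions: int
    als_associated: bool = False

    def __post_init__(self):
        if self.n_counted <= 0:
            raise ValueError(f"{self.variant}: n_counted must be positive")
        if not 0 <= self.n_inclusions <= self.n_counted:
            raise ValueError(
                f"{self.variant}: need 0 <= n_inclusions <= n_counted, got "
                f"{self.n_inclusions}/{self.n_counted}"
            )


def inclusion_fraction(counts: InclusionCounts) -> float:
    """Raw percentage of counted cells bearing inclusions."""
    return 100.0 * counts.n_inclusions / counts.n_counted


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def format_percentage(counts: InclusionCounts) -> str:
    """Display form of the percentage: round half-up to integer percent;
    small non-zero values render as "<= 1%"."""
    raw = inclusion_fraction(counts)
    if 0.0 < raw < LE_ONE_DISPLAY_BELOW:
        return "≤ 1%"
    return f"{round_half_up(raw)}%"


def call_aggregator(
    counts_24: InclusionCounts,
    counts_48: InclusionCounts,
    cutoff: float = 5.0,
    background: tuple[InclusionCounts, InclusionCounts] | None = None,
) -> tuple[bool, float]:
    """Dichotomise a variant: aggregator when the raw inclusion percentage
    strictly exceeds ``cutoff`` at either timepoint.

    Returns (is_aggregator, margin over the background percentage), where
    the margin uses the variant's larger timepoint value against the
    background's larger one (0 background when none is given).
    """
    if counts_24.variant != counts_48.variant:
        raise ValueError(
            f"timepoint records disagree on the variant: "
            f"{counts_24.variant!r} vs {counts_48.variant!r}"
        )
    peak = max(inclusion_fraction(counts_24), inclusion_fraction(counts_48))
    bg = 0.0
    if background is not None:
        bg = max(inclusion_fraction(background[0]), inclusion_fraction(background[1]))
    return peak > cutoff, peak - bg


@dataclass
class AssociationResult:
    """2x2 association between predicted consequence and aggregation."""

    contingency: np.ndarray  # rows: consequence predicted / none; cols: aggregator / not
    p_value: float
    odds_ratio: float
    threshold_used: float
    haldane_corrected: bool = False

    def to_dict(self) -> dict:
        return {
            "contingency": self.contingency.tolist(),
            "p_value": self.p_value,
            "odds_ratio": self.odds_ratio,
            "aggregation_cutoff_pct": self.threshold_used,
            "haldane_corrected": self.haldane_corrected,
            "note": "association statistic is this package's formalisation; "
            "the source assay reports counts only",
        }


def associate(
    consequence_flags: list[bool],
    aggregator_flags: list[bool],
    threshold_used: float = 5.0,
) -> AssociationResult:
    """Fisher exact test of consequence-predicted vs aggregating.

    ``consequence_flags`` is True where the structural call is anything
    other than None; ``aggregator_flags`` is the assay dichotomy.
    """
    if len(consequence_flags) != len(aggregator_flags):
        raise ValueError("flag lists must have equal length")
    if len(consequence_flags) < 2:
        raise ValueError("association needs at least 2 variants")
    table = np.zeros((2, 2), dtype=int)
    for cons, agg in zip(consequence_flags, aggregator_flags):
        table[0 if cons else 1, 0 if agg else 1] += 1
    _or, p = stats.fisher_exact(table, alternative="two-sided")
    a, b, c, d = table.ravel().astype(float)
    haldane = False
    if min(table.sum(axis=0).min(), table.sum(axis=1).min()) == 0 or b * c == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        haldane = True
    odds = (a * d) / (b * c)
    return AssociationResult(
        contingency=table,
        p_value=float(p),
        odds_ratio=float(odds),
        threshold_used=threshold_used,
        haldane_corrected=haldane,
    )


def read_counts_table(text: str) -> list[InclusionCounts]:
    """Parse a delimited counts table (CSV or TSV) into validated records.

    Requires columns variant, timepoint_hr, n_counted, n_inclusions;
    display strings such as "<= 1%" in any percentage column are ignored
    in favour of the raw counts. Row-level invariant violations are
    collected and reported together.
    """
    text = text.strip()
    if not text:
        raise ValueError("empty counts table")
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(io.StringIO(text), sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"counts table lacks required column(s): {missing}")
    records: list[InclusionCounts] = []
    row_errors: list[str] = []
    for idx, row in df.iterrows():
        try:
            records.append(
                InclusionCounts(
                    variant=str(row["variant"]),
                    timepoint=int(row["timepoint_hr"]),
                    n_counted=int(row["n_counted"]),
                    n_inclusions=int(row["n_inclusions"]),
                    als_associated=bool(int(row["als_associated"]))
                    if "als_associated" in df.columns
                    else False,
                )
            )
        except (ValueError, TypeError) as exc:
            row_errors.append(f"row {idx}: {exc}")
    if row_errors:
        raise ValueError("invalid counts table rows:\n" + "\n".join(row_errors))
    return records


def _packaged_text() -> str:
    return resources.files("sodscan.data").joinpath("inclusion_counts.csv").read_text()


def load_packaged_counts() -> list[InclusionCounts]:
    """The packaged 12-variant x 2-timepoint inclusion count table."""
    return read_counts_table(_packaged_text())


def packaged_expected_labels() -> dict[str, str]:
    """Expected consequence labels shipped with the packaged count table
    (keyed by variant string; WT carries no expectation)."""
    # keep_default_na: the literal label "None" and the WT "N/A" are data
    df = pd.read_csv(io.StringIO(_packaged_text()), keep_default_na=False)
    out = {}
    for _, row in df.drop_duplicates("variant").iterrows():
        if row["variant"] == "WT":
            continue
        out[str(row["variant"])] = str(row["expected_consequence"])
    return out


def aggregator_table(
    records: list[InclusionCounts], cutoff: float = 5.0
) -> pd.DataFrame:
    """Per-variant summary: raw and displayed percentages at both
    timepoints plus the aggregator call (WT is the background row)."""
    by_variant: dict[str, dict[int, InclusionCounts]] = {}
    for rec in records:
        by_variant.setdefault(rec.variant, {})[rec.timepoint] = rec
    background = by_variant.get("WT")
    rows = []
    for variant, tps in by_variant.items():
        if set(tps) != {24, 48}:
            raise ValueError(f"{variant}: need exactly the 24 h and 48 h records")
        c24, c48 = tps[24], tps[48]
        bg = (background[24], background[48]) if background else None
        is_agg, margin = call_aggregator(c24, c48, cutoff=cutoff, background=bg)
        rows.append(
            {
                "variant": variant,
                "als_associated": c24.als_associated,
                "pct_24h_raw": inclusion_fraction(c24),
                "pct_24h": format_percentage(c24),
                "pct_48h_raw": inclusion_fraction(c48),
                "pct_48h": format_percentage(c48),
                "aggregator": is_agg,
                "margin_over_background_pct": margin,
            }
        )
    return pd.DataFrame(rows)
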