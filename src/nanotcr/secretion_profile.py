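"""Granzyme-B secretion tiering, gated-population statistics, candidate
ranking, functional recovery rates, polyfunctional quadrants and purity.

Secretion levels are the integer counts of the oligo-tagged anti-granzyme-B
detection antibody.  Cells (and, via max- or mean-aggregation, clonotypes) are
tiered High (level >= 2,000), Medium (500 <= level < 2,000) or Low
(level < 500); the High bound is closed by default, with an open-bound variant
available through :class:`TierThresholds`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .clonotypes import Clonotype
from .sc_io import ValidationError

TIERS = ("High", "Medium", "Low")


@dataclass(frozen=True)
class TierThresholds:
    """Secretion-tier bounds. ``high_inclusive`` keeps the closed lower bound
    (level >= high_min is High); setting it False uses a strict bound."""

    high_min: int = 2000
    medium_min: int = 500
    high_inclusive: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.medium_min < self.high_min:
            raise ValidationError(
                f"require 0 < medium_min < high_min, got {self.medium_min}, {self.high_min}")


@dataclass(frozen=True)
class SecretionAnnotation:
    subject_id: str
    level: int
    tier: str
    gate_label: str = "unknown"  # positive | negative | unknown


@dataclass(frozen=True)
class TierRecovery:
    tested: int
    functional: int

    @property
    def rate(self) -> float:
        return self.functional / self.tested if self.tested else 0.0

    @property
    def undefined(self) -> bool:
        """True when no candidate of this tier was tested (rate reported as 0)."""
        return self.tested == 0


@dataclass(frozen=True)
class RecoveryReport:
    per_tier: Mapping[str, TierRecovery]


@dataclass(frozen=True)
class QuadrantLabel:
    subject_id: str
    quadrant: str  # Q1..Q4


def classify_tier(level: int, thresholds: TierThresholds = TierThresholds()) -> str:
    if level < 0:
        raise ValidationError(f"secretion level must be nonnegative, got {level}")
    above_high = level >= thresholds.high_min if thresholds.high_inclusive \
        else level > thresholds.high_min
    if above_high:
        return "High"
    if level >= thresholds.medium_min:
        return "Medium"
    return "Low"


def annotate_secretion(levels: Mapping[str, int],
                       thresholds: TierThresholds = TierThresholds(),
                       gate_labels: Mapping[str, str] | None = None
                       ) -> list[SecretionAnnotation]:
    """Tier every subject in ``levels`` (subject_id -> secretion count)."""
    gate_labels = gate_labels or {}
    return [SecretionAnnotation(subject_id=s, level=lvl,
                                tier=classify_tier(lvl, thresholds),
                                gate_label=gate_labels.get(s, "unknown"))
            for s, lvl in levels.items()]


def _round_half_up(value: Decimal, decimals: int = 1) -> float:
    exp = Decimal(1).scaleb(-decimals)
    return float(value.quantize(exp, rounding=ROUND_HALF_UP))


def tier_summary(annotations: Sequence[SecretionAnnotation]
                 ) -> dict[str, dict[str, float]]:
    """Per-tier counts and percentages (half-up, one decimal).

    Returns {tier: {"count": int, "percent": float}}; counts sum to the input
    size.  Percentages are computed in exact decimal arithmetic before
    rounding, so e.g. 9 of 68 reports 13.2 (13.235... rounds down).
    """
    if not annotations:
        raise ValidationError("tier_summary of an empty annotation list is undefined")
    total = len(annotations)
    counts = {tier: 0 for tier in TIERS}
    for ann in annotations:
        counts[ann.tier] += 1
    return {tier: {"count": counts[tier],
                   "percent": _round_half_up(Decimal(counts[tier] * 100) / Decimal(total))}
            for tier in TIERS}


def compare_gated_populations(pos_levels: Sequence[int], neg_levels: Sequence[int],
                              test: str = "mannwhitney") -> dict[str, float]:
    """Summary statistics and a two-sided test between the sorted positive and
    negative secretion gates.

    Means and SDs use the n-1 denominator.  The default test is Mann–Whitney U
    (barcode levels are heavily right-skewed: SD can exceed the mean); a Welch
    t-test is available via ``test="welch"``.
    """
    if len(pos_levels) < 2 or len(neg_levels) < 2:
        raise ValidationError("each population needs at least 2 observations")
    pos = np.asarray(pos_levels, dtype=float)
    neg = np.asarray(neg_levels, dtype=float)
    if np.all(pos == pos[0]) and np.all(neg == neg[0]) and pos[0] == neg[0]:
        p_value = 1.0  # degenerate: every observation identical
    elif test == "mannwhitney":
        p_value = float(stats.mannwhitneyu(pos, neg, alternative="two-sided").pvalue)
    elif test == "welch":
        p_value = float(stats.ttest_ind(pos, neg, equal_var=False).pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return {
        "mean_pos": float(pos.mean()), "sd_pos": float(pos.std(ddof=1)),
        "mean_neg": float(neg.mean()), "sd_neg": float(neg.std(ddof=1)),
        "p_value": p_value,
    }


def clonotype_secretion_level(clonotype: Clonotype, cell_levels: Mapping[str, int],
                              aggregate: str = "max") -> float:
    """Aggregate member-cell secretion levels: ``max`` (default — a clonotype
    is High if any sorted member exceeded the High bound) or ``mean``."""
    levels = []
    for barcode in clonotype.cell_barcodes:
        if barcode not in cell_levels:
            raise ValidationError(f"no secretion level for cell {barcode!r}")
        levels.append(cell_levels[barcode])
    if aggregate == "max":
        return float(max(levels))
    if aggregate == "mean":
        return float(np.mean(levels))
    raise ValueError(f"unknown aggregate {aggregate!r}")


def rank_candidates(clonotypes: Sequence[Clonotype], cell_levels: Mapping[str, int],
                    by: str = "secretion", top_n: int = 6,
                    min_level: int | None = None,
                    aggregate: str = "max") -> list[tuple[str, float, int]]:
    """Rank clonotypes for re-expression.

    ``by="secretion"`` sorts descending on the aggregated secretion level,
    keeping only clonotypes with level strictly above ``min_level`` when given;
    ``by="frequency"`` sorts descending on cell count.  Ties break on
    clonotype id.  Returns at most ``top_n`` tuples
    (clonotype_id, secretion_level, frequency).
    """
    if by not in ("secretion", "frequency"):
        raise ValueError(f"unknown ranking criterion {by!r}")
    rows = [(c.clonotype_id, clonotype_secretion_level(c, cell_levels, aggregate),
             c.frequency) for c in clonotypes]
    if by == "secretion":
        if min_level is not None:
            rows = [r for r in rows if r[1] > min_level]
        rows.sort(key=lambda r: (-r[1], r[0]))
    else:
        rows.sort(key=lambda r: (-r[2], r[0]))
    return rows[:top_n]


def recovery_rate(candidates: Sequence[SecretionAnnotation],
                  validation: Mapping[str, bool]) -> RecoveryReport:
    """Per-tier functional recovery among validated candidates.

    ``validation`` maps subject_id to the re-expression outcome (functional
    yes/no); every candidate must carry a label.
    """
    tested = {tier: 0 for tier in TIERS}
    functional = {tier: 0 for tier in TIERS}
    for cand in candidates:
        if cand.subject_id not in validation:
            raise ValidationError(f"candidate {cand.subject_id!r} has no validation label")
        tested[cand.tier] += 1
        functional[cand.tier] += int(validation[cand.subject_id])
    return RecoveryReport(per_tier={
        tier: TierRecovery(tested=tested[tier], functional=functional[tier])
        for tier in TIERS})


def classify_quadrant(signal_a: float, signal_b: float,
                      threshold_a: float, threshold_b: float) -> str:
    """Two-cytokine quadrant gate: Q1 = A only, Q2 = polyfunctional (both),
    Q3 = B only, Q4 = nonsecretor.  Events exactly at a threshold fall in the
    lower class (strict ">" gating)."""
    above_a = signal_a > threshold_a
    above_b = signal_b > threshold_b
    if above_a and not above_b:
        return "Q1"
    if above_a and above_b:
        return "Q2"
    if above_b:
        return "Q3"
    return "Q4"


def classify_quadrants(events: Mapping[str, tuple[float, float]],
                       threshold_a: float, threshold_b: float) -> list[QuadrantLabel]:
    """Quadrant label per subject for (signal_a, signal_b) event pairs."""
    return [QuadrantLabel(subject_id=s,
                          quadrant=classify_quadrant(a, b, threshold_a, threshold_b))
            for s, (a, b) in events.items()]


def compute_purity(selected: Iterable[str], marker_positive: Iterable[str]) -> float:
    """Fraction of selected subjects carrying the positivity marker, e.g. the
    NGFR+ fraction of sorted CD3+/CD8+ cells."""
    selected = set(selected)
    if not selected:
        raise ValidationError("compute_purity of an empty selection is undefined")
    return len(selected & set(marker_positive)) / len(selected)
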