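"""Dominant-epitope assignment from pMHC-identity feature barcodes.

Each nanovial carries one pMHC species tagged by an oligo barcode, so the
pMHC-barcode counts of a cell are expected to be dominated by the epitope of
the nanovial it was sorted on, with a small ambient background.  A cell (or a
clonotype, by pooled counts or per-cell majority) is assigned the epitope
whose barcode exceeds a fraction threshold of its total pMHC counts — strictly
greater than 0.90 by default.  Secretion-class barcodes never enter the
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .clonotypes import Clonotype
from .sc_io import FeatureCounts, PMHC_BARCODE, ValidationError


@dataclass(frozen=True)
class EpitopeCall:
    """Dominant-epitope call for one cell or clonotype.

    ``epitope_id`` is None (and ``matched`` False) when no feature exceeds the
    threshold or there are no pMHC counts at all.
    """

    subject_id: str
    epitope_id: str | None
    dominant_fraction: float
    total_pmhc_umis: int

    @property
    def matched(self) -> bool:
        return self.epitope_id is not None


def epitope_fractions(fc: FeatureCounts, cell_barcode: str) -> dict[str, float]:
    """Per-epitope count fractions over pMHC-class features for one cell.

    Empty dict when the cell has zero pMHC counts; otherwise fractions sum to 1.
    """
    counts = fc.class_counts(cell_barcode, PMHC_BARCODE)
    if not counts:
        raise ValidationError("feature matrix contains no pmhc_barcode features")
    total = sum(counts.values())
    if total == 0:
        return {}
    return {fid: c / total for fid, c in counts.items()}


def call_dominant_epitope(fractions: Mapping[str, float], total_umis: int,
                          subject_id: str = "",
                          threshold: float = 0.90,
                          min_total_umis: int = 1) -> EpitopeCall:
    """Apply the dominance rule: call the argmax epitope iff its fraction is
    strictly above ``threshold`` and the pMHC total reaches ``min_total_umis``.

    Ties at the argmax yield no call (unreachable at the default threshold with
    >=2 features, but defined for configurability).
    """
    if not 0 < threshold < 1:
        raise ValidationError(f"threshold must be in (0, 1), got {threshold}")
    if not fractions or total_umis == 0:
        return EpitopeCall(subject_id, None, 0.0, total_umis)
    top = max(fractions.values())
    winners = [fid for fid, f in fractions.items() if f == top]
    if len(winners) > 1 or top <= threshold or total_umis < min_total_umis:
        return EpitopeCall(subject_id, None, top, total_umis)
    return EpitopeCall(subject_id, winners[0], top, total_umis)


def cell_epitope_call(fc: FeatureCounts, cell_barcode: str,
                      threshold: float = 0.90, min_total_umis: int = 1) -> EpitopeCall:
    counts = fc.class_counts(cell_barcode, PMHC_BARCODE)
    total = sum(counts.values())
    fractions = {fid: c / total for fid, c in counts.items()} if total else {}
    return call_dominant_epitope(fractions, total, subject_id=cell_barcode,
                                 threshold=threshold, min_total_umis=min_total_umis)


def clonotype_epitope_call(clonotype: Clonotype, fc: FeatureCounts,
                           mode: str = "pooled_counts",
                           threshold: float = 0.90,
                           min_total_umis: int = 1) -> EpitopeCall:
    """Aggregate a clonotype's member cells into one epitope call.

    ``pooled_counts`` sums member pMHC counts and applies the dominance rule;
    ``cell_majority`` calls each cell and assigns the strict-majority epitope
    among matched cells (None if no strict majority).  The two agree whenever
    every member cell individually calls the same epitope.
    """
    if mode not in ("pooled_counts", "cell_majority"):
        raise ValueError(f"unknown mode {mode!r}")
    members = sorted(clonotype.cell_barcodes)
    pooled: dict[str, int] = {}
    for barcode in members:
        for fid, c in fc.class_counts(barcode, PMHC_BARCODE).items():
            pooled[fid] = pooled.get(fid, 0) + c
    total = sum(pooled.values())
    if mode == "pooled_counts":
        fractions = {fid: c / total for fid, c in pooled.items()} if total else {}
        return call_dominant_epitope(fractions, total, subject_id=clonotype.clonotype_id,
                                     threshold=threshold, min_total_umis=min_total_umis)
    votes: dict[str, int] = {}
    for barcode in members:
        call = cell_epitope_call(fc, barcode, threshold=threshold,
                                 min_total_umis=min_total_umis)
        if call.matched:
            votes[call.epitope_id] = votes.get(call.epitope_id, 0) + 1
    n_matched = sum(votes.values())
    if n_matched:
        top_id, top_votes = max(votes.items(), key=lambda kv: (kv[1], kv[0]))
        if top_votes * 2 > n_matched:
            return EpitopeCall(clonotype.clonotype_id, top_id,
                               top_votes / n_matched, total)
    return EpitopeCall(clonotype.clonotype_id, None, 0.0, total)


def matched_fraction(calls: Sequence[EpitopeCall]) -> float:
    """Fraction of calls that matched an epitope."""
    if not calls:
        raise ValidationError("matched_fraction of an empty call list is undefined")
    return sum(c.matched for c in calls) / len(calls)
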