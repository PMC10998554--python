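"""Cross-method repertoire comparisons and the final annotated TCR report.

``venn_partition`` tallies exclusive Venn regions over the αβ pairs recovered
by up to three isolation methods (e.g. nanovial, tetramer, CD137);
``inclusive_overlaps`` gives the companion pairwise/triple-intersection
cardinalities.  ``match_known`` joins recovered pairs against a user-provided
reference of published TCR sequences.  ``build_report`` runs the whole
pipeline on in-memory inputs and emits one annotated row per expanded pair
plus a stage-by-stage run summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Hashable, Mapping, Sequence

import pandas as pd

from . import clonotypes as ct
from . import epitope_deconv as ed
from . import secretion_profile as sp
from .config import PipelineConfig
from .sc_io import ChainRecord, FeatureCounts, FormatError, SECRETION_BARCODE


@dataclass(frozen=True)
class MethodSet:
    method_name: str
    pairs: frozenset[Hashable]


def venn_partition(sets: Sequence[MethodSet]) -> dict[frozenset[str], int]:
    """Exclusive region counts for 2 or 3 method sets.

    Keys are frozensets of method names; the region keyed {A, B} counts
    elements in A and B but in no other method.  Regions are disjoint and sum
    to the union cardinality.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError(f"venn_partition supports 2 or 3 sets, got {len(sets)}")
    names = [s.method_name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("method names must be unique")
    regions: dict[frozenset[str], int] = {}
    for r in range(1, len(sets) + 1):
        for combo in combinations(names, r):
            regions[frozenset(combo)] = 0
    membership = {s.method_name: set(s.pairs) for s in sets}
    union = set().union(*membership.values())
    for element in union:
        region = frozenset(n for n in names if element in membership[n])
        regions[region] += 1
    return regions


def inclusive_overlaps(sets: Sequence[MethodSet]) -> dict[frozenset[str], int]:
    """Plain intersection cardinalities |∩ combo| for every method combination."""
    if not 2 <= len(sets) <= 3:
        raise ValueError(f"inclusive_overlaps supports 2 or 3 sets, got {len(sets)}")
    membership = {s.method_name: set(s.pairs) for s in sets}
    out: dict[frozenset[str], int] = {}
    for r in range(1, len(sets) + 1):
        for combo in combinations(membership, r):
            inter = set.intersection(*(membership[n] for n in combo))
            out[frozenset(combo)] = len(inter)
    return out


REFERENCE_COLUMNS = ("cdr3_alpha_aa", "cdr3_beta_aa")


def match_known(pairs: pd.DataFrame, reference: pd.DataFrame,
                mode: str = "joint") -> pd.DataFrame:
    """Exact amino-acid matches of recovered pairs against a known-TCR table.

    ``pairs`` needs columns cdr3_alpha_aa and cdr3_beta_aa (plus any carry-over
    columns); ``reference`` needs the same two columns (``beta_only`` mode only
    needs cdr3_beta_aa) and gets a ``reference_row`` id from its index.
    """
    if mode not in ("joint", "beta_only"):
        raise ValueError(f"unknown mode {mode!r}")
    key_cols = list(REFERENCE_COLUMNS) if mode == "joint" else ["cdr3_beta_aa"]
    for col in key_cols:
        if col not in reference.columns:
            raise FormatError(f"reference table lacks required column {col!r}")
        if col not in pairs.columns:
            raise FormatError(f"pair table lacks required column {col!r}")
    if reference.empty or pairs.empty:
        return pairs.head(0).assign(reference_row=pd.Series(dtype=int))
    ref = reference.reset_index().rename(columns={"index": "reference_row"})
    return pairs.merge(ref[key_cols + ["reference_row"]], on=key_cols, how="inner")


def build_report(records: Sequence[ChainRecord], fc: FeatureCounts,
                 config: PipelineConfig | None = None,
                 validation: Mapping[str, bool] | None = None
                 ) -> tuple[pd.DataFrame, dict]:
    """Filter, assemble, expand and annotate — one row per expanded αβ pair.

    Returns the annotated pair table (sorted by clonotype id then chain keys,
    so reruns are byte-identical) and a run-summary dict of stage counts.
    Secretion columns are present only when the feature matrix carries a
    secretion-class barcode.
    """
    cfg = config or PipelineConfig()
    filtered = ct.filter_chains(
        records,
        require_productive=cfg.require_productive,
        require_full_length=cfg.require_full_length,
        require_high_confidence=cfg.require_high_confidence,
        require_is_cell=cfg.require_is_cell)
    clones = ct.assemble_clonotypes(filtered, max_chains_per_locus=cfg.max_chains_per_locus,
                                    key_level=cfg.clonotype_key_level)
    kept = ct.filter_by_frequency(clones, cfg.min_frequency)

    missing = sorted({b for c in kept for b in c.cell_barcodes if b not in fc})
    if missing:
        raise KeyError(
            f"{len(missing)} clonotype member cells absent from the feature matrix, "
            f"e.g. {missing[:5]}")

    aa_of = {ct.ChainKey(r.locus, r.v_gene, r.j_gene, r.cdr3_nt): r.cdr3_aa
             for r in filtered}
    has_secretion = bool(fc.features_of_class(SECRETION_BARCODE))
    if has_secretion:
        sec_feature = fc.features_of_class(SECRETION_BARCODE)[0].feature_id
        cell_levels = {b: fc.count(b, sec_feature) for b in fc.cell_barcodes}

    rows = []
    calls = []
    annotations = []
    n_pairs_total = 0
    for clone in kept:
        call = ed.clonotype_epitope_call(clone, fc, mode=cfg.epitope_mode,
                                         threshold=cfg.epitope_threshold,
                                         min_total_umis=cfg.min_total_umis)
        calls.append(call)
        if has_secretion:
            level = int(sp.clonotype_secretion_level(clone, cell_levels,
                                                     aggregate=cfg.secretion_aggregate))
            ann = sp.SecretionAnnotation(
                subject_id=clone.clonotype_id, level=level,
                tier=sp.classify_tier(level, cfg.tier_thresholds))
            annotations.append(ann)
        pairs = ct.expand_pairs(clone)
        n_pairs_total += len(pairs)
        for pair in pairs:
            row = {
                "clone_id": clone.clonotype_id,
                "frequency": clone.frequency,
                "v_gene_alpha": pair.alpha.v_gene, "j_gene_alpha": pair.alpha.j_gene,
                "cdr3_alpha_nt": pair.alpha.cdr3,
                "cdr3_alpha_aa": aa_of.get(pair.alpha, ""),
                "v_gene_beta": pair.beta.v_gene, "j_gene_beta": pair.beta.j_gene,
                "cdr3_beta_nt": pair.beta.cdr3,
                "cdr3_beta_aa": aa_of.get(pair.beta, ""),
                "epitope_id": call.epitope_id or "",
                "epitope_fraction": round(call.dominant_fraction, 6),
                "total_pmhc_umis": call.total_pmhc_umis,
                "epitope_matched": call.matched,
            }
            if has_secretion:
                row["secretion_level"] = ann.level
                row["secretion_tier"] = ann.tier
            if validation is not None:
                row["functional"] = validation.get(clone.clonotype_id, "")
            rows.append(row)

    report = pd.DataFrame(rows)
    if not report.empty:
        report = report.sort_values(
            ["clone_id", "cdr3_alpha_nt", "cdr3_beta_nt"]).reset_index(drop=True)

    summary: dict = {
        "input_contigs": len(records),
        "filtered_contigs": len(filtered),
        "input_cells": len({r.cell_barcode for r in records}),
        "cells_with_retained_chains": sum(c.frequency for c in clones),
        "clonotypes": len(clones),
        "clonotypes_at_min_frequency": len(kept),
        "expanded_pairs": n_pairs_total,
        "matched_epitope_fraction": (
            round(ed.matched_fraction(calls), 6) if calls else None),
    }
    if has_secretion and annotations:
        tiers = sp.tier_summary(annotations)
        for tier in sp.TIERS:
            summary[f"tier_{tier.lower()}_count"] = tiers[tier]["count"]
            summary[f"tier_{tier.lower()}_percent"] = tiers[tier]["percent"]
    return report, summary


def write_report(report: pd.DataFrame, summary: dict, outdir) -> None:
    """Write ``report.tsv`` and a key→value ``run_summary.txt`` (deterministic)."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.to_csv(outdir / "report.tsv", sep="\t", index=False, lineterminator="\n")
    with open(outdir / "run_summary.txt", "w", newline="\n") as fh:
        for key, value in summary.items():
            fh.write(f"{key}\t{value}\n")
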