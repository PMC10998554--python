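"""Chain filtering, clonotype assembly and αβ pair expansion.

A clonotype is the set of cells sharing an identical set of retained chain
keys; its frequency is the number of member cells.  Because some cells carry
two α and/or two β chains, a clonotype expands into the Cartesian product of
its α and β keys when candidates are re-expressed one pair at a time.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .sc_io import ChainRecord, TR_LOCI, ValidationError

logger = logging.getLogger("nanotcr")


@dataclass(frozen=True, order=True)
class ChainKey:
    """Identity key of one TCR chain: locus, V gene, J gene and CDR3 sequence.

    Nucleotide-level identity (``cdr3`` holds CDR3 nt) is the default, matching
    Cell Ranger clonotype semantics; amino-acid keys are produced by
    ``assemble_clonotypes(..., key_level="aa")``.
    """

    locus: str
    v_gene: str
    j_gene: str
    cdr3: str


@dataclass
class Clonotype:
    clonotype_id: str
    alpha_keys: frozenset[ChainKey]
    beta_keys: frozenset[ChainKey]
    cell_barcodes: frozenset[str]

    @property
    def frequency(self) -> int:
        return len(self.cell_barcodes)


@dataclass(frozen=True)
class TcrPair:
    alpha: ChainKey
    beta: ChainKey
    parent_clonotype_id: str

    def __post_init__(self) -> None:
        if self.alpha.locus != "TRA" or self.beta.locus != "TRB":
            raise ValidationError("TcrPair requires alpha.locus=TRA and beta.locus=TRB")


def filter_chains(records: Sequence[ChainRecord],
                  require_productive: bool = True,
                  require_full_length: bool = True,
                  require_high_confidence: bool = True,
                  require_is_cell: bool = True) -> list[ChainRecord]:
    """Keep TRA/TRB contigs passing the enabled quality flags.

    Non-TRA/TRB loci are always removed here (they are retained by the readers
    only so their removal can be counted).  Per-flag removal counts are logged.
    """
    removed = defaultdict(int)
    kept = []
    for rec in records:
        if rec.locus not in TR_LOCI:
            removed["locus"] += 1
            continue
        if require_productive and not rec.productive:
            removed["productive"] += 1
            continue
        if require_full_length and not rec.full_length:
            removed["full_length"] += 1
            continue
        if require_high_confidence and not rec.high_confidence:
            removed["high_confidence"] += 1
            continue
        if require_is_cell and not rec.is_cell:
            removed["is_cell"] += 1
            continue
        kept.append(rec)
    if removed:
        logger.info("filter_chains removed %s",
                    ", ".join(f"{k}={v}" for k, v in sorted(removed.items())))
    return kept


def _chain_key(rec: ChainRecord, key_level: str) -> ChainKey:
    cdr3 = rec.cdr3_nt if key_level == "nt" else rec.cdr3_aa
    return ChainKey(locus=rec.locus, v_gene=rec.v_gene, j_gene=rec.j_gene, cdr3=cdr3)


def assemble_clonotypes(records: Sequence[ChainRecord],
                        max_chains_per_locus: int = 2,
                        key_level: str = "nt",
                        discard_excess: bool = False) -> list[Clonotype]:
    """Group cells with identical retained chain-key sets into clonotypes.

    Per cell, at most ``max_chains_per_locus`` chains are retained per locus,
    ranked by UMI count (ties broken by reads, then contig id).  Cells whose
    chain count exceeds the cap are truncated by default; ``discard_excess``
    drops such cells entirely.  Clonotype ids are assigned deterministically by
    descending frequency, then lexicographic key order.
    """
    if key_level not in ("nt", "aa"):
        raise ValueError(f"key_level must be 'nt' or 'aa', got {key_level!r}")
    by_cell: dict[str, list[ChainRecord]] = defaultdict(list)
    for rec in records:
        by_cell[rec.cell_barcode].append(rec)

    groups: dict[tuple, set[str]] = defaultdict(set)
    n_zero = 0
    n_discarded = 0
    for barcode, recs in by_cell.items():
        retained: list[ChainKey] = []
        over_cap = False
        for locus in TR_LOCI:
            locus_recs = [r for r in recs if r.locus == locus]
            locus_recs.sort(key=lambda r: (-r.umis, -r.reads, r.contig_id))
            if len(locus_recs) > max_chains_per_locus:
                over_cap = True
            retained.extend(_chain_key(r, key_level) for r in locus_recs[:max_chains_per_locus])
        if not retained:
            n_zero += 1
            continue
        if over_cap and discard_excess:
            n_discarded += 1
            continue
        groups[tuple(sorted(set(retained)))].add(barcode)
    if n_zero:
        logger.info("assemble_clonotypes excluded %d cells with zero retained chains", n_zero)
    if n_discarded:
        logger.info("assemble_clonotypes discarded %d cells exceeding the chain cap", n_discarded)

    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    clonotypes = []
    for i, (keys, barcodes) in enumerate(ordered, start=1):
        clonotypes.append(Clonotype(
            clonotype_id=f"clonotype{i}",
            alpha_keys=frozenset(k for k in keys if k.locus == "TRA"),
            beta_keys=frozenset(k for k in keys if k.locus == "TRB"),
            cell_barcodes=frozenset(barcodes),
        ))
    return clonotypes


def expand_pairs(clonotype: Clonotype) -> list[TcrPair]:
    """All single-α × single-β permutations of a clonotype, in sorted key order.

    Clonotypes lacking either locus yield no pairs (logged)."""
    if not clonotype.alpha_keys or not clonotype.beta_keys:
        logger.info("clonotype %s lacks an %s chain; no pairs emitted",
                    clonotype.clonotype_id,
                    "alpha" if not clonotype.alpha_keys else "beta")
        return []
    return [TcrPair(alpha=a, beta=b, parent_clonotype_id=clonotype.clonotype_id)
            for a in sorted(clonotype.alpha_keys)
            for b in sorted(clonotype.beta_keys)]


def filter_by_frequency(clonotypes: Iterable[Clonotype], min_freq: int) -> list[Clonotype]:
    """Clonotypes with at least ``min_freq`` member cells (order preserved)."""
    if min_freq < 1:
        raise ValidationError(f"min_freq must be >= 1, got {min_freq}")
    return [c for c in clonotypes if c.frequency >= min_freq]
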