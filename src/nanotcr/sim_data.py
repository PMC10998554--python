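"""Synthetic nanovial TCR-screening datasets with ground truth.

The generator emulates the statistical structure of a sorted single-cell
V(D)J + feature-barcode experiment: a zipf-clonal repertoire with occasional
multi-chain cells and nonproductive contigs; per-cell pMHC barcode counts
concentrated on the cell's cognate epitope with a small uniform ambient
background; tier-conditional granzyme-B secretion barcode counts whose
positive/negative-gate laws are log-normals moment-matched to mean/SD
1,022/1,286 and 288/149; and sorted-gate labels.  A separate Poisson loading
simulator models cell capture on nanovials as binomially thinned Poisson
occupancy.

Everything is deterministic for a fixed seed, down to the bytes of the files
``write_dataset`` emits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq
from scipy import stats

from .sc_io import (ChainRecord, Feature, FeatureCounts, PMHC_BARCODE,
                    SECRETION_BARCODE, ValidationError, write_contig_table,
                    write_feature_matrix)
from .secretion_profile import TierThresholds, classify_tier

# 10-plex prostate/splicing panel and 3-plex viral panel used as defaults.
PANEL_10PLEX = ("PAP14", "PAP21", "PAP22", "PAP23", "CTNND1",
                "CLASP1", "MEAF6", "PXDN", "SCAMP3", "TCF12")
PANEL_3PLEX = ("CMV1", "CMV2", "EBV")

SECRETION_FEATURE = "GZMB-secretion"

# Small human V/J gene-name pools (names only) for realistic fixtures.
TRAV = tuple(f"TRAV{n}" for n in
             ("1-1", "1-2", "2", "3", "4", "5", "8-1", "8-2", "9-2", "12-1",
              "13-1", "14/DV4", "17", "19", "21", "22", "24", "26-1", "29/DV5", "38-1"))
TRAJ = tuple(f"TRAJ{n}" for n in
             ("4", "6", "9", "12", "15", "20", "23", "27", "31", "33",
              "37", "40", "43", "45", "49", "52"))
TRBV = tuple(f"TRBV{n}" for n in
             ("2", "4-1", "5-1", "6-1", "6-5", "7-2", "7-9", "9", "10-3", "11-2",
              "12-3", "13", "15", "18", "19", "20-1", "25-1", "27", "28", "30"))
TRBJ = tuple(f"TRBJ{n}" for n in
             ("1-1", "1-2", "1-3", "1-4", "1-5", "1-6",
              "2-1", "2-2", "2-3", "2-4", "2-5", "2-6", "2-7"))

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES
                if a + b + c not in _STOPS)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults follow the granzyme-B screening conditions: a 10-plex pMHC panel,
    ~13% of sequenced cells from the positive sort gate, positive-gate tier
    shares (9, 40, 19)/68, and secretion laws moment-matched to the printed
    gate means and SDs.
    """

    n_cells: int = 5000
    n_clonotypes: int = 300
    epitope_panel: tuple[str, ...] = PANEL_10PLEX
    clonal_zipf_exponent: float = 1.5
    multi_alpha_rate: float = 0.10
    multi_beta_rate: float = 0.05
    productive_rate: float = 0.9
    pmhc_total_mean: float = 200.0
    pmhc_total_dispersion: float = 10.0
    dominant_fraction_alpha: float = 97.0   # Beta law, mean 0.97
    dominant_fraction_beta: float = 3.0     # 0 = point mass at 1 (no spread)
    ambient_noise: float = 0.01
    secretion_pos_mean: float = 1022.0
    secretion_pos_sd: float = 1286.0
    secretion_neg_mean: float = 288.0
    secretion_neg_sd: float = 149.0
    tier_proportions: tuple[float, float, float] = (9 / 68, 40 / 68, 19 / 68)
    positive_gate_fraction: float = 87 / 657
    gate_false_positive_rate: float = 0.0004
    tier_thresholds: TierThresholds = field(default_factory=TierThresholds)
    seed: int = 0

    def validate(self) -> None:
        if self.n_clonotypes > self.n_cells:
            raise ValidationError(
                f"n_clonotypes ({self.n_clonotypes}) exceeds n_cells ({self.n_cells})")
        if self.n_clonotypes < 1 or self.n_cells < 1:
            raise ValidationError("n_cells and n_clonotypes must be positive")
        for name in ("multi_alpha_rate", "multi_beta_rate", "productive_rate",
                     "ambient_noise", "positive_gate_fraction",
                     "gate_false_positive_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.tier_proportions) - 1) > 1e-9:
            raise ValidationError("tier_proportions must sum to 1")
        for name in ("clonal_zipf_exponent", "pmhc_total_mean", "pmhc_total_dispersion",
                     "dominant_fraction_alpha", "secretion_pos_mean",
                     "secretion_pos_sd", "secretion_neg_mean", "secretion_neg_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.dominant_fraction_beta < 0:
            raise ValidationError("dominant_fraction_beta must be nonnegative")
        if len(self.epitope_panel) < 2:
            raise ValidationError("epitope panel needs at least 2 epitopes")


@dataclass
class TruthTable:
    """Ground-truth assignments aligned with the emitted files."""

    cells: pd.DataFrame        # cell_barcode, clonotype_id, epitope_id, tier, gate_label, secretion_level
    clonotypes: pd.DataFrame   # clonotype_id, epitope_id, alpha_keys, beta_keys, n_cells


@dataclass
class SimulatedDataset:
    records: list[ChainRecord]
    feature_counts: FeatureCounts
    truth: TruthTable
    config: SimulationConfig


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match a log-normal: return (mu, sigma) of the underlying normal."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return float(mu), float(np.sqrt(sigma2))


def _truncated_lognormal(rng: np.random.Generator, mu: float, sigma: float,
                         lo: float, hi: float) -> float:
    """Inverse-CDF draw from LogNormal(mu, sigma) restricted to [lo, hi)."""
    dist = stats.lognorm(s=sigma, scale=np.exp(mu))
    a, b = dist.cdf(lo), dist.cdf(hi)
    if b <= a:  # interval beyond numerical support; pin to the boundary
        return lo
    return float(dist.ppf(a + rng.random() * (b - a)))


def _cell_barcode(i: int) -> str:
    digits = []
    x = i
    for _ in range(16):
        digits.append(_BASES[x % 4])
        x //= 4
    return "".join(reversed(digits)) + "-1"


def _random_cdr3(rng: np.random.Generator) -> tuple[str, str]:
    n_aa = int(rng.integers(12, 21))
    codons = rng.choice(len(_CODONS), size=n_aa)
    nt = "".join(_CODONS[c] for c in codons)
    return nt, str(Seq(nt).translate())


def _clone_chains(rng: np.random.Generator, cfg: SimulationConfig,
                  seen: set[tuple]) -> tuple[list[dict], list[dict]]:
    def make(locus: str, v_pool, j_pool) -> dict:
        while True:
            nt, aa = _random_cdr3(rng)
            chain = {"locus": locus,
                     "v_gene": str(rng.choice(v_pool)),
                     "j_gene": str(rng.choice(j_pool)),
                     "cdr3_nt": nt, "cdr3_aa": aa}
            key = (locus, chain["v_gene"], chain["j_gene"], nt)
            if key not in seen:
                seen.add(key)
                return chain

    n_alpha = 2 if rng.random() < cfg.multi_alpha_rate else 1
    n_beta = 2 if rng.random() < cfg.multi_beta_rate else 1
    alphas = [make("TRA", TRAV, TRAJ) for _ in range(n_alpha)]
    betas = [make("TRB", TRBV, TRBJ) for _ in range(n_beta)]
    return alphas, betas


def simulate_repertoire(cfg: SimulationConfig | None = None) -> SimulatedDataset:
    """Generate contig records, feature counts and a truth table for one cohort."""
    cfg = cfg or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    panel = list(cfg.epitope_panel)

    # Clonotype definitions: chains and a cognate epitope each.
    seen_keys: set[tuple] = set()
    clone_defs = []
    for k in range(cfg.n_clonotypes):
        alphas, betas = _clone_chains(rng, cfg, seen_keys)
        clone_defs.append({
            "clonotype_id": f"SIMCLONE{k:04d}",
            "alphas": alphas, "betas": betas,
            "epitope_id": panel[int(rng.integers(len(panel)))],
        })

    # Clone identity per cell from a zipf-weighted pmf over clone ranks, so
    # realised clonal sizes follow a truncated-zipf law.
    weights = np.arange(1, cfg.n_clonotypes + 1, dtype=float) ** (-cfg.clonal_zipf_exponent)
    weights /= weights.sum()
    clone_of_cell = rng.choice(cfg.n_clonotypes, size=cfg.n_cells, p=weights)

    mu_pos, sig_pos = lognormal_params(cfg.secretion_pos_mean, cfg.secretion_pos_sd)
    mu_neg, sig_neg = lognormal_params(cfg.secretion_neg_mean, cfg.secretion_neg_sd)
    t = cfg.tier_thresholds
    tier_intervals = {"High": (t.high_min, np.inf),
                      "Medium": (t.medium_min, t.high_min),
                      "Low": (0.5, t.medium_min)}

    # Negative-binomial pMHC totals parameterised by (mean, dispersion r):
    # numpy wants (r, p) with p = r / (r + mean).
    nb_r = cfg.pmhc_total_dispersion
    nb_p = nb_r / (nb_r + cfg.pmhc_total_mean)

    records: list[ChainRecord] = []
    truth_rows = []
    counts = np.zeros((cfg.n_cells, len(panel) + 1), dtype=np.int64)

    for i in range(cfg.n_cells):
        barcode = _cell_barcode(i)
        clone = clone_defs[int(clone_of_cell[i])]

        # Contigs: each clone chain is emitted; nonproductive draws get a
        # frameshifted CDR3 and are dropped by downstream filtering.
        n_contig = 0
        for chain in clone["alphas"] + clone["betas"]:
            n_contig += 1
            umis = 1 + int(rng.poisson(4))
            reads = umis * (8 + int(rng.poisson(12)))
            productive = bool(rng.random() < cfg.productive_rate)
            nt, aa = chain["cdr3_nt"], chain["cdr3_aa"]
            if not productive:
                nt, aa = nt + "A", ""  # out-of-frame junction
            records.append(ChainRecord(
                cell_barcode=barcode,
                contig_id=f"{barcode}_contig_{n_contig}",
                locus=chain["locus"], v_gene=chain["v_gene"], d_gene="",
                j_gene=chain["j_gene"], c_gene="TRAC" if chain["locus"] == "TRA" else "TRBC2",
                cdr3_aa=aa, cdr3_nt=nt, reads=reads, umis=umis,
                productive=productive, full_length=True, high_confidence=True,
                is_cell=True, length=450 + len(nt),
                raw_clonotype_id=clone["clonotype_id"],
            ))

        # pMHC counts: dominant mass (1 - ambient) * Beta-draw on the cognate
        # epitope, remainder uniform over the non-cognate panel.
        total = int(rng.negative_binomial(nb_r, nb_p))
        dom = (1.0 if cfg.dominant_fraction_beta == 0
               else float(rng.beta(cfg.dominant_fraction_alpha, cfg.dominant_fraction_beta)))
        p_true = (1.0 - cfg.ambient_noise) * dom
        probs = np.full(len(panel), (1.0 - p_true) / (len(panel) - 1))
        probs[panel.index(clone["epitope_id"])] = p_true
        counts[i, :len(panel)] = rng.multinomial(total, probs)

        # Secretion level conditional on sort gate and (for positives) tier.
        if rng.random() < cfg.positive_gate_fraction:
            gate = "positive"
            tier = str(rng.choice(TIER_ORDER, p=cfg.tier_proportions))
            lo, hi = tier_intervals[tier]
            level = int(np.floor(_truncated_lognormal(rng, mu_pos, sig_pos, lo, hi)))
            level = max(level, int(np.ceil(lo)) if tier != "Low" else 0)
        else:
            gate = "negative"
            level = int(np.floor(rng.lognormal(mu_neg, sig_neg)))
        counts[i, len(panel)] = level
        truth_rows.append({
            "cell_barcode": barcode, "clonotype_id": clone["clonotype_id"],
            "epitope_id": clone["epitope_id"],
            "tier": classify_tier(level, t), "gate_label": gate,
            "secretion_level": level,
        })

    features = [Feature(e, PMHC_BARCODE, f"{e} pMHC") for e in panel]
    features.append(Feature(SECRETION_FEATURE, SECRETION_BARCODE, "anti-Granzyme B"))
    fc = FeatureCounts(cell_barcodes=[_cell_barcode(i) for i in range(cfg.n_cells)],
                       features=features, counts=counts)

    def _fmt(chains: list[dict]) -> str:
        return ";".join(f"{c['v_gene']}|{c['j_gene']}|{c['cdr3_nt']}" for c in chains)

    realised = pd.Series(clone_of_cell).value_counts().to_dict()
    truth_clonotypes = pd.DataFrame([
        {"clonotype_id": d["clonotype_id"], "epitope_id": d["epitope_id"],
         "alpha_keys": _fmt(d["alphas"]), "beta_keys": _fmt(d["betas"]),
         "n_cells": int(realised.get(k, 0))}
        for k, d in enumerate(clone_defs)])
    truth = TruthTable(cells=pd.DataFrame(truth_rows), clonotypes=truth_clonotypes)
    return SimulatedDataset(records=records, feature_counts=fc, truth=truth, config=cfg)


TIER_ORDER = ("High", "Medium", "Low")


def simulate_loading(lambda_: float, n_nanovials: int, capture_prob: float = 1.0,
                     seed: int = 0) -> np.ndarray:
    """Occupancy histogram of cells captured per nanovial.

    Cells encountering a nanovial follow Poisson(``lambda_``); each is captured
    independently with ``capture_prob``, so captured occupancy is a binomially
    thinned Poisson — distributed Poisson(lambda_ * capture_prob).  Returns
    counts over occupancy k = 0, 1, 2, ...
    """
    if lambda_ < 0 or not 0 <= capture_prob <= 1 or n_nanovials < 1:
        raise ValidationError("invalid loading parameters")
    rng = np.random.default_rng(seed)
    arrivals = rng.poisson(lambda_, size=n_nanovials)
    captured = rng.binomial(arrivals, capture_prob)
    return np.bincount(captured)


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    """Write the dataset in the 10x dialects plus truth TSVs and a manifest.

    Layout: ``contigs.csv`` (tenx_csv), ``feature_matrix/`` (MTX triplet),
    ``truth_cells.tsv``, ``truth_clonotypes.tsv``, ``manifest.yaml``.  The
    manifest records the full config including the seed, so regenerating from
    it reproduces identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_contig_table(dataset.records, outdir / "contigs.csv", dialect="tenx_csv")
    write_feature_matrix(dataset.feature_counts, outdir / "feature_matrix")
    dataset.truth.cells.to_csv(outdir / "truth_cells.tsv", sep="\t", index=False,
                               lineterminator="\n")
    dataset.truth.clonotypes.to_csv(outdir / "truth_clonotypes.tsv", sep="\t",
                                    index=False, lineterminator="\n")
    cfg = asdict(dataset.config)
    cfg["tier_thresholds"] = asdict(dataset.config.tier_thresholds)
    cfg["epitope_panel"] = list(dataset.config.epitope_panel)
    cfg["tier_proportions"] = list(dataset.config.tier_proportions)
    with open(outdir / "manifest.yaml", "w", newline="\n") as fh:
        yaml.safe_dump({"generator": "nanotcr.sim_data", "config": cfg}, fh,
                       sort_keys=True)


def config_from_manifest(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    cfg = dict(manifest["config"])
    cfg["tier_thresholds"] = TierThresholds(**cfg["tier_thresholds"])
    cfg["epitope_panel"] = tuple(cfg["epitope_panel"])
    cfg["tier_proportions"] = tuple(cfg["tier_proportions"])
    return SimulationConfig(**cfg)
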