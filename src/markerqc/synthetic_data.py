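"""Synthetic genotype collections with planted diagnostic structure.

Generates collections that statistically resemble a multi-species
genebank validation panel: five taxa of configurable sizes, six planted
group-diagnostic marker contrasts, near-fixed diagnostic alleles with a
configurable fixation probability, a small per-call heterozygosity rate,
per-locus missingness (one designated high-missing locus whose no-calls
are concentrated in the Asian taxa), a handful of wild-species "hybrid"
accessions carrying the cultivated sister species' haplotype at the
wild-vs-cultivated contrast loci, and structureless background loci with
allele frequencies shared across taxa.

Every collection is emitted with a ground-truth record so downstream
selection, classification and validation stages can be tested without
external data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .diagnostic_panel import DEFAULT_TAXA, GroupContrast, default_contrasts
from .genotype_io import MISSING, GenotypeMatrix, LabeledDataset

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"), ("A", "T"), ("C", "G")]

DEFAULT_GROUP_SIZES = {
    "barthii": 88,
    "glaberrima": 169,
    "longistaminata": 69,
    "indica": 178,
    "japonica": 121,
}

DEFAULT_CONTRAST_LOCI = {"G1": 4, "G2": 28, "G3": 16, "G4": 9, "G5": 7, "G6": 1}

#: Group sizes of the small five-taxon testing panel.
SMALL_PANEL_GROUP_SIZES = {
    "barthii": 18,
    "glaberrima": 18,
    "longistaminata": 9,
    "indica": 20,
    "japonica": 15,
}


class ConfigError(ValueError):
    """Raised for inconsistent collection configurations."""


@dataclass(frozen=True)
class CollectionConfig:
    """Parameters of a synthetic collection.

    ``fixation`` is the fraction of each group carrying its expected
    homozygous state at a diagnostic locus, realized as an exact count:
    round((1 - fixation) * n_group) accessions per group per locus
    deviate (heterozygote with probability ``het_share``, otherwise the
    opposite homozygote), so realized per-group concordance is
    deterministic given sizes.  Per-contrast overrides go in
    ``fixation_overrides``.  ``missing_rate_max`` bounds
    the per-locus uniform missingness draw, with one designated
    high-missing locus (a G1 locus by default) at ``high_missing_rate``
    concentrated on the ``high_missing_taxa``.  ``n_hybrids`` wild
    accessions carry the cultivated sister taxon's states at the G1 loci.
    """

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    contrast_loci: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CONTRAST_LOCI)
    )
    n_background: int = 93
    fixation: float = 0.99
    fixation_overrides: Mapping[str, float] = field(default_factory=dict)
    het_share: float = 0.5
    het_rate: float = 0.005
    missing_rate_max: float = 0.11
    high_missing_rate: float = 0.21
    high_missing_taxa: tuple[str, ...] = ("indica", "japonica")
    n_hybrids: int = 7
    hybrid_taxon: str = "barthii"
    hybrid_like: str = "glaberrima"
    background_maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def validate(self) -> None:
        rates = [
            self.fixation,
            self.het_rate,
            self.het_share,
            self.missing_rate_max,
            self.high_missing_rate,
            *self.fixation_overrides.values(),
        ]
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise ConfigError("all rates must lie in [0, 1]")
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ConfigError("group sizes must be positive")
        if any(n < 0 for n in self.contrast_loci.values()) or self.n_background < 0:
            raise ConfigError("locus counts must be non-negative")
        if self.n_hybrids > self.group_sizes.get(self.hybrid_taxon, 0):
            raise ConfigError(
                f"n_hybrids={self.n_hybrids} exceeds the "
                f"{self.hybrid_taxon!r} group size"
            )

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes.values())

    @property
    def n_diagnostic(self) -> int:
        return sum(self.contrast_loci.values())

    @property
    def n_loci(self) -> int:
        return self.n_diagnostic + self.n_background

    def fixation_for(self, contrast_id: str) -> float:
        return self.fixation_overrides.get(contrast_id, self.fixation)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["group_sizes"] = dict(self.group_sizes)
        d["contrast_loci"] = dict(self.contrast_loci)
        d["fixation_overrides"] = dict(self.fixation_overrides)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CollectionConfig":
        d = json.loads(text)
        for key in ("high_missing_taxa", "background_maf_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class CollectionTruth:
    """Ground truth of a simulated collection."""

    locus_contrast: dict[str, str]  # locus -> contrast id or "background"
    diagnostic_allele: dict[str, int]  # planted loci only (allele index)
    hybrid_ids: list[str]
    high_missing_locus: str | None
    concordance: dict[str, dict[str, float]]  # locus -> taxon -> realized

    def planted_loci(self, contrast_id: str | None = None) -> list[str]:
        return [
            l
            for l, c in self.locus_contrast.items()
            if (c != "background" if contrast_id is None else c == contrast_id)
        ]

    def to_json(self) -> str:
        return json.dumps(
            {
                "locus_contrast": self.locus_contrast,
                "diagnostic_allele": self.diagnostic_allele,
                "hybrid_ids": self.hybrid_ids,
                "high_missing_locus": self.high_missing_locus,
                "concordance": self.concordance,
            },
            indent=2,
            sort_keys=True,
        )


def small_panel_config(seed: int = 0, **overrides) -> CollectionConfig:
    """Config emulating the small 80-accession testing panel.

    Five taxa sized 18/18/9/20/15, no hybrid accessions; all other
    defaults unchanged.  At these group sizes the deterministic deviant
    counts at fixation 0.99 are zero, so groups are internally clean.
    """
    return CollectionConfig(
        group_sizes=dict(SMALL_PANEL_GROUP_SIZES),
        n_hybrids=0,
        seed=seed,
        **overrides,
    )


def scale_config(cfg: CollectionConfig, factor: float) -> CollectionConfig:
    """Scale group sizes and locus counts, keeping rates unchanged.

    Used for fast test fixtures.  Raises if any group would drop below 2
    samples.
    """
    if factor <= 0:
        raise ConfigError("scale factor must be positive")
    if factor == 1:
        return cfg
    sizes = {t: int(round(n * factor)) for t, n in cfg.group_sizes.items()}
    if any(n < 2 for n in sizes.values()):
        bad = [t for t, n in sizes.items() if n < 2]
        raise ConfigError(f"scaled groups below 2 samples: {bad}")
    # contrasts keep >= 2 loci (when they had >= 2) so pair rescue stays
    # possible after scaling; singleton contrasts stay singletons
    loci = {
        c: (min(n, 2) if n else 0) if round(n * factor) < 2 else int(round(n * factor))
        for c, n in cfg.contrast_loci.items()
    }
    n_hyb = min(int(round(cfg.n_hybrids * factor)), sizes.get(cfg.hybrid_taxon, 0))
    return dataclasses.replace(
        cfg,
        group_sizes=sizes,
        contrast_loci=loci,
        n_background=max(0, int(round(cfg.n_background * factor))),
        n_hybrids=n_hyb,
    )


def _expected_state_matrix(
    taxa_order: list[str],
    contrasts: list[GroupContrast],
    contrast_of_locus: list[str | None],
) -> np.ndarray:
    """Per-taxon expected dosage at each diagnostic locus (alt allele = 1).

    The diagnostic allele is always the second (alt) allele, so target
    taxa expect dosage 2 and everything else dosage 0; taxa outside a
    restricted contrast take the complement (majority) state, which keeps
    the diagnostic allele the panel-wide minor allele.
    """
    by_id = {c.contrast_id: c for c in contrasts}
    exp = np.zeros((len(taxa_order), len(contrast_of_locus)), dtype=np.int8)
    for j, cid in enumerate(contrast_of_locus):
        c = by_id[cid]
        for i, t in enumerate(taxa_order):
            exp[i, j] = 2 if t in c.target else 0
    return exp


def simulate_collection(
    cfg: CollectionConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, CollectionTruth]:
    """Simulate a genotype collection with planted diagnostic structure.

    Returns the genotype matrix, a sample metadata table (sample_id,
    taxon) and the ground truth.  Fully deterministic for a fixed config
    (including the seed).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    taxa_order = [t for t in DEFAULT_TAXA if t in cfg.group_sizes] + [
        t for t in cfg.group_sizes if t not in DEFAULT_TAXA
    ]
    contrasts = [
        c for c in default_contrasts() if c.contrast_id in cfg.contrast_loci
    ]

    sample_ids: list[str] = []
    taxa: list[str] = []
    for t in taxa_order:
        for i in range(cfg.group_sizes[t]):
            sample_ids.append(f"{t[:4].upper()}-{i + 1:04d}")
            taxa.append(t)
    n = len(sample_ids)
    taxa_arr = np.array(taxa, dtype=object)

    locus_ids: list[str] = []
    contrast_of: list[str] = []
    for c in contrasts:
        for k in range(cfg.contrast_loci[c.contrast_id]):
            locus_ids.append(f"{c.contrast_id}-M{k + 1:02d}")
            contrast_of.append(c.contrast_id)
    n_diag = len(locus_ids)
    for k in range(cfg.n_background):
        locus_ids.append(f"BG-M{k + 1:03d}")
    m = len(locus_ids)

    dosage = np.zeros((n, m), dtype=np.int8)

    # diagnostic loci: expected state per group with an exact number of
    # deviating accessions (het or opposite homozygote)
    exp = _expected_state_matrix(taxa_order, contrasts, contrast_of)
    taxon_index = {t: i for i, t in enumerate(taxa_order)}
    row_exp = exp[[taxon_index[t] for t in taxa], :]  # n x n_diag
    dosage[:, :n_diag] = row_exp
    for j, cid in enumerate(contrast_of):
        fix = cfg.fixation_for(cid)
        for t in taxa_order:
            rows = np.flatnonzero(taxa_arr == t)
            n_dev = int(round((1.0 - fix) * len(rows)))
            if n_dev == 0:
                continue
            dev = rng.choice(rows, size=n_dev, replace=False)
            expected = exp[taxon_index[t], j]
            as_het = rng.random(n_dev) < cfg.het_share
            dosage[dev, j] = np.where(as_het, 1, 2 - expected).astype(np.int8)

    # background loci: shared allele frequencies, inbred (homozygous)
    # calls plus per-call heterozygotes
    if cfg.n_background:
        lo, hi = cfg.background_maf_range
        p_bg = rng.uniform(lo, hi, size=cfg.n_background)
        bg = 2 * (rng.random((n, cfg.n_background)) < p_bg[None, :]).astype(np.int8)
        if cfg.het_rate > 0:
            het = rng.random((n, cfg.n_background)) < cfg.het_rate
            bg[het] = 1
        dosage[:, n_diag:] = bg

    # hybrids: first n_hybrids accessions of the hybrid taxon carry the
    # sister taxon's states at the G1 loci
    hybrid_ids: list[str] = []
    g1_cols = [j for j, c in enumerate(contrast_of) if c == "G1"]
    if cfg.n_hybrids and g1_cols:
        hyb_rows = np.flatnonzero(taxa_arr == cfg.hybrid_taxon)[: cfg.n_hybrids]
        like_row = exp[taxon_index[cfg.hybrid_like], g1_cols]
        for r in hyb_rows:
            dosage[r, g1_cols] = like_row
        hybrid_ids = [sample_ids[r] for r in hyb_rows]

    # missingness: per-locus MCAR, one designated high-missing G1 locus
    # whose no-calls are concentrated in the high_missing_taxa
    miss_rate = rng.uniform(0.0, cfg.missing_rate_max, size=m)
    high_j: int | None = None
    if g1_cols:
        high_j = g1_cols[-1]
        miss_rate[high_j] = 0.0
    miss = rng.random((n, m)) < miss_rate[None, :]
    if high_j is not None:
        conc = np.isin(taxa_arr, cfg.high_missing_taxa)
        n_target = int(round(cfg.high_missing_rate * n))
        pool = np.flatnonzero(conc)
        if len(pool) < n_target:
            pool = np.arange(n)
        pick = rng.choice(pool, size=n_target, replace=False)
        miss[pick, high_j] = True
    dosage[miss] = MISSING

    alleles = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(m)]
    g = GenotypeMatrix(
        sample_ids=sample_ids,
        locus_ids=locus_ids,
        dosage=dosage,
        alleles=alleles,
    )
    meta = pd.DataFrame({"sample_id": sample_ids, "taxon": taxa})

    truth = CollectionTruth(
        locus_contrast={
            l: (contrast_of[j] if j < n_diag else "background")
            for j, l in enumerate(locus_ids)
        },
        diagnostic_allele={l: 1 for l in locus_ids[:n_diag]},
        hybrid_ids=hybrid_ids,
        high_missing_locus=locus_ids[high_j] if high_j is not None else None,
        concordance=_realized_concordance(
            g, taxa_arr, contrasts, contrast_of, exp, taxa_order
        ),
    )
    return g, meta, truth


def _realized_concordance(
    g: GenotypeMatrix,
    taxa_arr: np.ndarray,
    contrasts: list[GroupContrast],
    contrast_of: list[str],
    exp: np.ndarray,
    taxa_order: list[str],
) -> dict[str, dict[str, float]]:
    by_id = {c.contrast_id: c for c in contrasts}
    out: dict[str, dict[str, float]] = {}
    for j, cid in enumerate(contrast_of):
        c = by_id[cid]
        col = g.dosage[:, j]
        obs = col != MISSING
        per: dict[str, float] = {}
        for t in sorted(c.taxa):
            idx = (taxa_arr == t) & obs
            if not idx.any():
                per[t] = float("nan")
                continue
            expected = exp[taxa_order.index(t), j]
            per[t] = float(np.mean(col[idx] == expected))
        out[g.locus_ids[j]] = per
    return out


def filter_fixture(
    n_samples: int = 80,
    n_good: int = 117,
    n_bad: tuple[int, int, int, int] = (10, 11, 10, 10),
    seed: int = 0,
) -> tuple[GenotypeMatrix, dict[str, str]]:
    """A genotype matrix with a prescribed number of filter violations.

    Builds ``n_good`` clean loci plus ``n_bad`` loci violating, in order,
    the MAF, PIC, het-rate and missing-rate rules (each violating only
    that rule and the ones after it in cascade order).  Returns the
    matrix and the expected rejection reason per bad locus.  Defaults
    yield 158 loci of which 41 violate at least one rule.

    Dosage layouts per category (for the default 80 samples):
    monomorphic (MAF), alt frequency 1/16 (PIC: ~0.11 < 0.18 while MAF
    0.0625 passes), 10/80 heterozygotes at 50% MAF (het 0.125 > 0.09),
    and 20/80 no-calls at 50% MAF (missing 0.25 > 0.24).
    """
    rng = np.random.default_rng(seed)
    n = n_samples
    cols: list[np.ndarray] = []
    locus_ids: list[str] = []
    reasons: dict[str, str] = {}

    def balanced() -> np.ndarray:
        col = np.zeros(n, dtype=np.int8)
        col[rng.choice(n, size=n // 2, replace=False)] = 2
        return col

    for k in range(n_good):
        locus_ids.append(f"OK-{k + 1:03d}")
        cols.append(balanced())
    n_maf, n_pic, n_het, n_miss = n_bad
    for k in range(n_maf):
        lid = f"LOWMAF-{k + 1:02d}"
        locus_ids.append(lid)
        cols.append(np.zeros(n, dtype=np.int8))
        reasons[lid] = "MAF"
    for k in range(n_pic):
        lid = f"LOWPIC-{k + 1:02d}"
        locus_ids.append(lid)
        col = np.zeros(n, dtype=np.int8)
        col[rng.choice(n, size=max(1, n // 16), replace=False)] = 2
        cols.append(col)
        reasons[lid] = "PIC"
    for k in range(n_het):
        lid = f"HIGHHET-{k + 1:02d}"
        locus_ids.append(lid)
        col = balanced()
        het_idx = rng.choice(n, size=int(0.125 * n) + 1, replace=False)
        col[het_idx] = 1
        cols.append(col)
        reasons[lid] = "het"
    for k in range(n_miss):
        lid = f"HIGHMISS-{k + 1:02d}"
        locus_ids.append(lid)
        col = balanced()
        miss_idx = rng.choice(n, size=int(0.25 * n), replace=False)
        col[miss_idx] = MISSING
        cols.append(col)
        reasons[lid] = "missing"
    g = GenotypeMatrix(
        sample_ids=[f"S{i + 1:03d}" for i in range(n)],
        locus_ids=locus_ids,
        dosage=np.column_stack(cols),
        alleles=[_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(len(cols))],
    )
    return g, reasons


def labeled_collection(cfg: CollectionConfig) -> tuple[LabeledDataset, CollectionTruth]:
    """Convenience wrapper: simulate and label in one step."""
    g, meta, truth = simulate_collection(cfg)
    taxa = np.array(meta["taxon"], dtype=object)
    return LabeledDataset(genotype=g, taxa=taxa, metadata=meta), truth
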