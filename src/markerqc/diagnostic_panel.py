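"""Selection of taxon-diagnostic markers and panel assembly.

A *contrast* splits the taxon set into a target group and its complement
("complex"); a marker is diagnostic for a contrast when essentially all
accessions of every taxon involved carry the expected homozygous state:
the diagnostic (typically minor) allele in the target taxa and the other
allele elsewhere.  Heterozygotes count as mismatches (the species handled
here are predominantly inbred); missing calls are dropped from
denominators rather than counted as failures.

The module provides single-marker scoring, rescue of contrasts via
jointly-diagnostic marker pairs, greedy reduction to a minimal panel with
configurable redundancy, per-accession classification against a panel's
expected haplotypes, and haplotype-pattern reporting.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, LabeledDataset

#: Canonical taxon order used by default contrasts.
DEFAULT_TAXA = ("barthii", "glaberrima", "longistaminata", "indica", "japonica")

DEFAULT_THRESHOLD = 0.97
PAIR_FLOOR = 0.85


class NoDiagnosticAlleleError(ValueError):
    """Raised for loci that are monomorphic in the labeled dataset."""


class PanelSeparationError(ValueError):
    """Raised when a panel fails to separate a taxon pair."""


class UnclassifiableError(ValueError):
    """Raised when an accession has no non-missing calls on the panel."""


@dataclass(frozen=True)
class GroupContrast:
    """A target taxon set versus a complement taxon set.

    The two sets must be disjoint.  A contrast may be *restricted* (the
    union need not cover all taxa): taxa outside the union are ignored
    when scoring concordance for this contrast.
    """

    contrast_id: str
    target: frozenset[str]
    complement: frozenset[str]

    def __post_init__(self) -> None:
        if self.target & self.complement:
            raise ValueError(
                f"{self.contrast_id}: target and complement overlap"
            )
        if not self.target or not self.complement:
            raise ValueError(f"{self.contrast_id}: empty taxon set")

    @property
    def taxa(self) -> frozenset[str]:
        return self.target | self.complement

    def is_restricted(self, all_taxa: Iterable[str]) -> bool:
        return bool(set(all_taxa) - self.taxa)


def default_contrasts(taxa: Sequence[str] = DEFAULT_TAXA) -> list[GroupContrast]:
    """The six default group contrasts over the five standard taxa.

    G1 is the restricted wild-vs-cultivated African contrast; G2-G6 span
    the full taxon set.
    """
    barthii, glab, longi, indica, japonica = taxa
    full = frozenset(taxa)

    def c(cid, target):
        t = frozenset(target)
        return GroupContrast(cid, t, full - t)

    return [
        GroupContrast("G1", frozenset({barthii}), frozenset({glab})),
        c("G2", {barthii, glab}),
        c("G3", {indica, japonica}),
        c("G4", {longi}),
        c("G5", {indica}),
        c("G6", {japonica}),
    ]


@dataclass
class DiagnosticScore:
    """Concordance of one marker (or pair) with a contrast's grouping."""

    loci: tuple[str, ...]
    contrast_id: str
    diagnostic_allele: int  # allele index; target state dosage = 2*index
    per_group_concordance: dict[str, float]
    threshold: float
    overall_pass: bool

    @property
    def min_concordance(self) -> float:
        vals = [v for v in self.per_group_concordance.values()]
        if any(math.isnan(v) for v in vals):
            return float("nan")
        return min(vals)


# ----------------------------------------------------------------------
# Single-marker scoring


def _scope_mask(ds: LabeledDataset, contrast: GroupContrast) -> np.ndarray:
    return np.array([t in contrast.taxa for t in ds.taxa])


def diagnostic_allele(
    ds: LabeledDataset, contrast: GroupContrast, locus_id: str
) -> int:
    """Pick the candidate diagnostic allele index for a locus.

    The panel-wide minor allele wins if it is the majority state within
    the target group; otherwise the allele maximally enriched in the
    target relative to the complement is used, with ties broken toward
    the minor allele.
    """
    g = ds.genotype
    j = g.locus_index(locus_id)
    col = g.dosage[:, j].astype(float)
    obs = col != MISSING
    if not obs.any() or len(np.unique(col[obs])) == 1 and col[obs][0] != 1:
        # all-missing, or a single homozygous state everywhere
        raise NoDiagnosticAlleleError(
            f"locus {locus_id!r} is monomorphic or uncalled"
        )
    p_alt = col[obs].sum() / (2 * obs.sum())
    if p_alt in (0.0, 1.0):
        raise NoDiagnosticAlleleError(f"locus {locus_id!r} is monomorphic")
    minor = 1 if p_alt <= 0.5 else 0

    in_target = np.array([t in contrast.target for t in ds.taxa]) & obs
    in_comp = np.array([t in contrast.complement for t in ds.taxa]) & obs

    def freq(allele: int, mask: np.ndarray) -> float:
        if not mask.any():
            return float("nan")
        pa = col[mask].sum() / (2 * mask.sum())
        return pa if allele == 1 else 1.0 - pa

    f_minor_target = freq(minor, in_target)
    if f_minor_target > 0.5:
        return minor
    enrich = {a: freq(a, in_target) - freq(a, in_comp) for a in (0, 1)}
    if enrich[0] == enrich[1]:
        return minor
    return max(enrich, key=lambda a: (enrich[a], a == minor))


def concordance(
    ds: LabeledDataset,
    locus_id: str,
    contrast: GroupContrast,
    threshold: float = DEFAULT_THRESHOLD,
    allele: int | None = None,
) -> DiagnosticScore:
    """Per-taxon concordance of one marker with a contrast.

    For each taxon in the contrast's scope, the fraction of its
    non-missing accessions carrying the expected homozygous state: the
    diagnostic allele for target taxa, the other allele for complement
    taxa.  Passing requires every taxon's concordance to exceed
    ``threshold``; a taxon with zero non-missing calls is undefined and
    the marker cannot pass.
    """
    if allele is None:
        allele = diagnostic_allele(ds, contrast, locus_id)
    g = ds.genotype
    col = g.dosage[:, g.locus_index(locus_id)]
    obs = col != MISSING
    target_state = 2 * allele
    other_state = 2 - target_state
    conc: dict[str, float] = {}
    for taxon in sorted(contrast.taxa):
        idx = (ds.taxa == taxon) & obs
        n = int(idx.sum())
        if n == 0:
            conc[taxon] = float("nan")
            continue
        expected = target_state if taxon in contrast.target else other_state
        conc[taxon] = float(np.mean(col[idx] == expected))
    ok = all(
        (not math.isnan(v)) and v > threshold for v in conc.values()
    )
    return DiagnosticScore(
        loci=(locus_id,),
        contrast_id=contrast.contrast_id,
        diagnostic_allele=allele,
        per_group_concordance=conc,
        threshold=threshold,
        overall_pass=ok,
    )


@dataclass
class SelectionResult:
    """Per-contrast passing loci plus the loci passing no contrast."""

    by_contrast: dict[str, list[str]]
    scores: dict[tuple[str, str], DiagnosticScore]  # (contrast_id, locus)
    non_diagnostic: list[str]
    threshold: float


def select_diagnostic_markers(
    ds: LabeledDataset,
    contrasts: Sequence[GroupContrast] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    loci: Sequence[str] | None = None,
) -> SelectionResult:
    """Assign each locus to the contrast(s) whose grouping it matches.

    A locus may pass several contrasts (rare in practice); loci passing
    none are reported as non-diagnostic.
    """
    contrasts = list(contrasts) if contrasts is not None else default_contrasts()
    loci = list(loci) if loci is not None else list(ds.genotype.locus_ids)
    by_contrast: dict[str, list[str]] = {c.contrast_id: [] for c in contrasts}
    scores: dict[tuple[str, str], DiagnosticScore] = {}
    non_diag: list[str] = []
    for lid in loci:
        passed_any = False
        for c in contrasts:
            try:
                sc = concordance(ds, lid, c, threshold=threshold)
            except NoDiagnosticAlleleError:
                continue
            scores[(c.contrast_id, lid)] = sc
            if sc.overall_pass:
                by_contrast[c.contrast_id].append(lid)
                passed_any = True
        if not passed_any:
            non_diag.append(lid)
    return SelectionResult(
        by_contrast=by_contrast,
        scores=scores,
        non_diagnostic=non_diag,
        threshold=threshold,
    )


# ----------------------------------------------------------------------
# Jointly-diagnostic pairs


def pair_concordance(
    ds: LabeledDataset,
    loci: tuple[str, str],
    contrast: GroupContrast,
    alleles: tuple[int, int],
    threshold: float = DEFAULT_THRESHOLD,
) -> DiagnosticScore:
    """Concordance of a two-marker haplotype with a contrast.

    An accession is concordant when it shows its taxon's expected state
    at *at least one* non-missing locus of the pair, so independent
    single-locus errors do not compound; accessions missing at both loci
    are excluded from the denominator.
    """
    g = ds.genotype
    cols = [g.dosage[:, g.locus_index(l)] for l in loci]
    obs = [c != MISSING for c in cols]
    any_obs = obs[0] | obs[1]
    conc: dict[str, float] = {}
    for taxon in sorted(contrast.taxa):
        idx = (ds.taxa == taxon) & any_obs
        n = int(idx.sum())
        if n == 0:
            conc[taxon] = float("nan")
            continue
        is_target = taxon in contrast.target
        hit = np.zeros(len(ds.taxa), dtype=bool)
        for col, ob, a in zip(cols, obs, alleles):
            expected = 2 * a if is_target else 2 - 2 * a
            hit |= ob & (col == expected)
        conc[taxon] = float(np.mean(hit[idx]))
    ok = all((not math.isnan(v)) and v > threshold for v in conc.values())
    return DiagnosticScore(
        loci=loci,
        contrast_id=contrast.contrast_id,
        diagnostic_allele=alleles[0],
        per_group_concordance=conc,
        threshold=threshold,
        overall_pass=ok,
    )


@dataclass
class PairScore:
    score: DiagnosticScore
    alleles: tuple[int, int]
    flagged: bool  # True when reported despite missing the threshold


def joint_diagnostic_pairs(
    ds: LabeledDataset,
    contrast: GroupContrast,
    candidate_loci: Sequence[str],
    threshold: float = DEFAULT_THRESHOLD,
    floor: float = PAIR_FLOOR,
) -> list[PairScore]:
    """Search marker pairs that jointly match a contrast's grouping.

    Candidates are loci that individually failed the contrast but whose
    minimum per-taxon concordance is at least ``floor`` (keeps the O(L^2)
    search tractable).  Pairs are returned best-first by minimum
    concordance; pairs below ``threshold`` are included but flagged, as a
    near-miss pair can still be the best available rescue for a contrast.
    """
    singles: list[tuple[str, int, float]] = []
    for lid in candidate_loci:
        try:
            a = diagnostic_allele(ds, contrast, lid)
        except NoDiagnosticAlleleError:
            continue
        sc = concordance(ds, lid, contrast, threshold=threshold, allele=a)
        mc = sc.min_concordance
        if not math.isnan(mc) and mc >= floor and not sc.overall_pass:
            singles.append((lid, a, mc))
    results: list[PairScore] = []
    for (l1, a1, _), (l2, a2, _) in itertools.combinations(singles, 2):
        sc = pair_concordance(ds, (l1, l2), contrast, (a1, a2), threshold)
        mc = sc.min_concordance
        if math.isnan(mc):
            continue
        results.append(PairScore(score=sc, alleles=(a1, a2), flagged=not sc.overall_pass))
    results.sort(key=lambda r: (-r.score.min_concordance, r.score.loci))
    return results


# ----------------------------------------------------------------------
# Panel assembly and reduction


@dataclass
class PanelSelection:
    """An ordered diagnostic panel with expected haplotypes per taxon.

    ``expected`` maps taxon -> expected dosage (0 or 2) at each panel
    locus, in ``loci`` order.  ``concordance_of`` carries each locus's
    minimum per-taxon concordance for its contrast (used for tie-breaks
    during reduction).
    """

    contrast_to_loci: dict[str, list[str]]
    loci: list[str]
    expected: dict[str, np.ndarray]
    concordance_of: dict[str, float]
    threshold: float
    flagged_contrasts: dict[str, float] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def taxa(self) -> list[str]:
        return list(self.expected)

    def locus_positions(self) -> dict[str, int]:
        return {l: i for i, l in enumerate(self.loci)}

    def separating_loci(self, taxon_a: str, taxon_b: str) -> list[str]:
        ea, eb = self.expected[taxon_a], self.expected[taxon_b]
        return [l for l, x, y in zip(self.loci, ea, eb) if x != y]

    def check_separation(self) -> None:
        for a, b in itertools.combinations(self.taxa, 2):
            if not self.separating_loci(a, b):
                raise PanelSeparationError(
                    f"panel does not separate taxa {a!r} and {b!r}"
                )

    def subset(self, loci: Sequence[str]) -> "PanelSelection":
        keep = [l for l in self.loci if l in set(loci)]
        pos = self.locus_positions()
        idx = [pos[l] for l in keep]
        return PanelSelection(
            contrast_to_loci={
                cid: [l for l in ls if l in set(keep)]
                for cid, ls in self.contrast_to_loci.items()
            },
            loci=keep,
            expected={t: e[idx].copy() for t, e in self.expected.items()},
            concordance_of={l: self.concordance_of[l] for l in keep},
            threshold=self.threshold,
            flagged_contrasts=dict(self.flagged_contrasts),
            provenance={**self.provenance, "reduced_from": len(self.loci)},
        )

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "loci": list(self.loci),
            "contrasts": {k: list(v) for k, v in self.contrast_to_loci.items()},
            "expected_haplotypes": {
                t: [int(x) for x in e] for t, e in self.expected.items()
            },
            "concordance": {l: self.concordance_of[l] for l in self.loci},
            "flagged_contrasts": dict(self.flagged_contrasts),
            "provenance": dict(self.provenance),
        }


def _consensus_state(ds: LabeledDataset, locus_id: str, taxon: str, fallback: int) -> int:
    """Majority homozygous state of a taxon at a locus (fallback on tie)."""
    g = ds.genotype
    col = g.dosage[:, g.locus_index(locus_id)]
    idx = ds.taxa == taxon
    n0 = int(np.sum(col[idx] == 0))
    n2 = int(np.sum(col[idx] == 2))
    if n0 == n2:
        return fallback
    return 0 if n0 > n2 else 2


def build_panel(
    ds: LabeledDataset,
    contrasts: Sequence[GroupContrast] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    loci: Sequence[str] | None = None,
    pair_floor: float = PAIR_FLOOR,
    selection: SelectionResult | None = None,
) -> PanelSelection:
    """Assemble a diagnostic panel from single markers plus pair rescues.

    Contrasts without a single passing marker are rescued with their best
    jointly-diagnostic pair (both loci enter the panel, and the contrast
    is flagged with the pair's achieved minimum concordance when that is
    below the threshold).  Expected haplotypes are defined for every
    taxon at every panel locus: contrast-defined states where the taxon
    is in the contrast's scope, empirical consensus states otherwise.
    """
    contrasts = list(contrasts) if contrasts is not None else default_contrasts()
    loci = list(loci) if loci is not None else list(ds.genotype.locus_ids)
    if selection is None:
        selection = select_diagnostic_markers(ds, contrasts, threshold, loci)

    taxa = ds.taxon_names
    contrast_to_loci: dict[str, list[str]] = {}
    panel_loci: list[str] = []
    conc_of: dict[str, float] = {}
    flagged: dict[str, float] = {}
    locus_scores: dict[str, DiagnosticScore] = {}

    for c in contrasts:
        cid = c.contrast_id
        passing = selection.by_contrast.get(cid, [])
        if passing:
            chosen = sorted(passing)
            for l in chosen:
                locus_scores[l] = selection.scores[(cid, l)]
        else:
            failing = [l for l in loci if l not in set(panel_loci)]
            pairs = joint_diagnostic_pairs(
                ds, c, failing, threshold=threshold, floor=pair_floor
            )
            if not pairs:
                contrast_to_loci[cid] = []
                continue
            best = pairs[0]
            chosen = list(best.score.loci)
            if best.flagged:
                flagged[cid] = best.score.min_concordance
            for l, a in zip(best.score.loci, best.alleles):
                locus_scores[l] = concordance(ds, l, c, threshold, allele=a)
        contrast_to_loci[cid] = chosen
        for l in chosen:
            if l not in set(panel_loci):
                panel_loci.append(l)
                mc = locus_scores[l].min_concordance
                conc_of[l] = mc if not math.isnan(mc) else 0.0

    contrast_by_id = {c.contrast_id: c for c in contrasts}
    expected: dict[str, np.ndarray] = {t: np.zeros(len(panel_loci), dtype=np.int8) for t in taxa}
    locus_contrast: dict[str, str] = {}
    for cid, ls in contrast_to_loci.items():
        for l in ls:
            locus_contrast.setdefault(l, cid)
    for k, l in enumerate(panel_loci):
        c = contrast_by_id[locus_contrast[l]]
        a = locus_scores[l].diagnostic_allele
        target_state, other_state = 2 * a, 2 - 2 * a
        for t in taxa:
            if t in c.target:
                expected[t][k] = target_state
            elif t in c.complement:
                expected[t][k] = other_state
            else:
                expected[t][k] = _consensus_state(ds, l, t, fallback=other_state)

    return PanelSelection(
        contrast_to_loci=contrast_to_loci,
        loci=panel_loci,
        expected=expected,
        concordance_of=conc_of,
        threshold=threshold,
        flagged_contrasts=flagged,
        provenance={"n_input_loci": len(loci)},
    )


def minimal_panel(
    panel: PanelSelection,
    ds: LabeledDataset | None = None,
    redundancy: int = 2,
) -> PanelSelection:
    """Greedy set-cover reduction of a panel.

    Repeatedly keeps the marker separating the most still-uncovered
    taxon pairs (ties: higher minimum concordance, then lexicographic
    locus id) until every pair is covered by ``redundancy`` markers, or
    by all available markers for that pair if fewer exist.  When ``ds``
    is given, the reduced panel is verified to classify every accession
    identically to the full panel.

    Raises
    ------
    PanelSeparationError
        If the full panel itself fails to separate some taxon pair.
    """
    panel.check_separation()
    taxa = panel.taxa
    pairs = [tuple(sorted(pr)) for pr in itertools.combinations(taxa, 2)]
    separates: dict[str, set[tuple[str, str]]] = {
        l: set() for l in panel.loci
    }
    for pr in pairs:
        for l in panel.separating_loci(*pr):
            separates[l].add(pr)
    need = {
        pr: min(redundancy, sum(pr in s for s in separates.values()))
        for pr in pairs
    }
    chosen: list[str] = []
    remaining = set(panel.loci)
    while any(n > 0 for n in need.values()):
        best = max(
            sorted(remaining),
            key=lambda l: (
                sum(1 for pr in separates[l] if need[pr] > 0),
                panel.concordance_of[l],
                # id ascending as final tie-break: max() keeps the first of
                # equals from the sorted iterable
            ),
        )
        gain = sum(1 for pr in separates[best] if need[pr] > 0)
        if gain == 0:  # pragma: no cover - need exhausted concurrently
            break
        chosen.append(best)
        remaining.discard(best)
        for pr in separates[best]:
            if need[pr] > 0:
                need[pr] -= 1
    reduced = panel.subset([l for l in panel.loci if l in set(chosen)])
    reduced.check_separation()
    if ds is None:
        return reduced

    # classification equality with the full panel is part of the
    # contract: add back markers separating any still-divergent taxon
    # pairs until every accession classifies identically
    full = classify_all(ds, panel)
    while True:
        red = classify_all(ds, reduced)
        diverging = {
            tuple(sorted((a.taxon, b.taxon)))
            for a, b in zip(full, red)
            if a.taxon != b.taxon
        }
        if not diverging:
            return reduced
        added = False
        for pr in sorted(diverging):
            candidates = [
                l for l in sorted(remaining) if pr in separates[l]
            ]
            if candidates:
                best = max(
                    candidates,
                    key=lambda l: (
                        len(separates[l]),
                        panel.concordance_of[l],
                    ),
                )
                chosen.append(best)
                remaining.discard(best)
                added = True
        if not added:  # pragma: no cover - full panel would also diverge
            raise PanelSeparationError(
                "cannot reconcile reduced-panel classification with the "
                f"full panel for taxon pairs {sorted(diverging)}"
            )
        reduced = panel.subset([l for l in panel.loci if l in set(chosen)])


# ----------------------------------------------------------------------
# Classification and reporting


@dataclass
class Classification:
    sample_id: str | None
    taxon: str
    mismatches: dict[str, int]
    n_used: int
    ties: list[str]
    intermediate: bool

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "taxon": self.taxon,
            "mismatches": dict(self.mismatches),
            "n_loci_used": self.n_used,
            "ties": list(self.ties),
            "intermediate": self.intermediate,
        }


def classify_accession(
    row: np.ndarray, panel: PanelSelection, sample_id: str | None = None
) -> Classification:
    """Assign one accession to the taxon minimizing haplotype mismatches.

    ``row`` is the accession's dosage vector aligned with ``panel.loci``.
    Heterozygous calls mismatch every expected homozygote; missing loci
    are skipped.  Ties are broken alphabetically and reported; the
    ``intermediate`` flag is set when the runner-up taxon is within one
    mismatch of the winner.
    """
    row = np.asarray(row)
    obs = row != MISSING
    n_used = int(obs.sum())
    if n_used == 0:
        raise UnclassifiableError("all panel loci missing for accession")
    mm = {
        t: int(np.sum(obs & (row != e))) for t, e in panel.expected.items()
    }
    ranked = sorted(mm.items(), key=lambda kv: (kv[1], kv[0]))
    best_taxon, best = ranked[0]
    ties = [t for t, v in ranked[1:] if v == best]
    intermediate = len(ranked) > 1 and ranked[1][1] - best <= 1
    return Classification(
        sample_id=sample_id,
        taxon=best_taxon,
        mismatches=mm,
        n_used=n_used,
        ties=ties,
        intermediate=intermediate,
    )


def classify_all(ds: LabeledDataset, panel: PanelSelection) -> list[Classification]:
    g = ds.genotype.subset_loci(panel.loci)
    return [
        classify_accession(g.dosage[i], panel, sample_id=s)
        for i, s in enumerate(g.sample_ids)
    ]


def haplotype_pattern(
    ds: LabeledDataset,
    panel: PanelSelection,
    n_per_group: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """Seeded per-taxon sample of accessions with their panel states.

    Up to ``n_per_group`` accessions per taxon (the whole taxon when it
    is smaller); columns are panel loci ordered by contrast group then
    locus id; values are dosages (``NA`` for missing).
    """
    rng = np.random.default_rng(seed)
    ordered_loci: list[str] = []
    for cid in panel.contrast_to_loci:
        for l in sorted(panel.contrast_to_loci[cid]):
            if l not in ordered_loci:
                ordered_loci.append(l)
    g = ds.genotype.subset_loci(ordered_loci)
    rows = []
    index = []
    for taxon in ds.taxon_names:
        idx = ds.sample_indices(taxon)
        if len(idx) > n_per_group:
            idx = np.sort(rng.choice(idx, size=n_per_group, replace=False))
        for i in idx:
            rows.append(
                [
                    "NA" if d == MISSING else int(d)
                    for d in g.dosage[i]
                ]
            )
            index.append((taxon, g.sample_ids[i]))
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["taxon", "sample_id"]),
        columns=ordered_loci,
    )
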