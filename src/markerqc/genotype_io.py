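"""Genotype matrix I/O: delimited call/dosage tables and a HapMap-like dialect.

Genotypes are held as allele dosages: the count of the locus's second
("alt-like") allele per sample, so values are 0, 1 or 2, with ``MISSING``
(-1) for no-calls.  All downstream statistics are symmetric in allele
labelling, so the choice of which allele is counted is arbitrary.

Three text dialects are supported:

``calls``
    Samples in rows, loci in columns; cells are two-character genotypes
    (``AA``, ``AG``), single homozygous letters (``A``) or IUPAC
    heterozygote codes (``R``, ``Y``, ``S``, ``W``, ``K``, ``M``).
``dosage``
    Same layout; cells are 0/1/2 or a missing token.  Allele labels, when
    known, are carried in the column header as ``locus|A/G``.
``hapmap``
    Loci in rows with columns ``rs#``, ``alleles``, ``chrom``, ``pos``
    followed by one column per sample (HapMap convention: positions are
    1-based and purely descriptive).

Missing tokens accepted on input: ``NA``, ``--``, ``NN``, ``N``, ``.``
and the empty string.  ``NA`` is always written on output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

MISSING_TOKENS = {"NA", "--", "NN", "N", ".", "", "nan"}

VALID_ALLELES = frozenset("ACGT")

#: IUPAC ambiguity codes for heterozygous calls.
IUPAC_HET: dict[str, frozenset[str]] = {
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
}

DIALECTS = ("calls", "dosage", "hapmap")


class GenotypeParseError(ValueError):
    """Raised when a genotype table cannot be parsed or validated."""


class UnlabeledSampleError(KeyError):
    """Raised when samples in a matrix have no metadata entry."""

    def __init__(self, missing_ids: Sequence[str]):
        self.missing_ids = list(missing_ids)
        super().__init__(
            f"{len(self.missing_ids)} sample(s) missing from metadata: "
            + ", ".join(self.missing_ids[:10])
            + ("..." if len(self.missing_ids) > 10 else "")
        )


@dataclass
class GenotypeMatrix:
    """A samples x loci allele-dosage matrix.

    Attributes
    ----------
    sample_ids : list of str
        Ordered, unique sample identifiers (rows).
    locus_ids : list of str
        Ordered, unique locus identifiers (columns).
    dosage : ndarray of int8, shape (n_samples, n_loci)
        Count of each locus's second allele; ``MISSING`` (-1) for no-calls.
    alleles : list of (str, str or None) or None
        Per-locus allele pair (ref-like, alt-like).  ``None`` entries mean
        the pair (or the alt allele) is unknown, e.g. for a monomorphic
        locus read from a calls table.
    chrom, pos : lists or None
        Optional per-locus chromosome label and 1-based position; carried
        through I/O but never used in computation.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    dosage: np.ndarray
    alleles: list[tuple[str, str | None] | None] | None = None
    chrom: list[str | None] | None = None
    pos: list[int | None] | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise GenotypeParseError("dosage must be 2-dimensional")
        self.validate()

    # -- core protocol -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def validate(self) -> None:
        n, m = self.dosage.shape
        if n != len(self.sample_ids):
            raise GenotypeParseError(
                f"dosage has {n} rows but {len(self.sample_ids)} sample ids"
            )
        if m != len(self.locus_ids):
            raise GenotypeParseError(
                f"dosage has {m} columns but {len(self.locus_ids)} locus ids"
            )
        if len(set(self.sample_ids)) != n:
            raise GenotypeParseError("duplicate sample ids")
        if len(set(self.locus_ids)) != m:
            raise GenotypeParseError("duplicate locus ids")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeParseError(
                f"invalid dosage {self.dosage[i, j]} at sample "
                f"{self.sample_ids[i]!r}, locus {self.locus_ids[j]!r}"
            )
        if self.alleles is not None:
            if len(self.alleles) != m:
                raise GenotypeParseError("alleles length != number of loci")
            for lid, pair in zip(self.locus_ids, self.alleles):
                if pair is None:
                    continue
                a, b = pair
                if a not in VALID_ALLELES or (
                    b is not None and (b not in VALID_ALLELES or a == b)
                ):
                    raise GenotypeParseError(
                        f"invalid allele pair {pair!r} at locus {lid!r}"
                    )

    def locus_index(self, locus_id: str) -> int:
        try:
            return self.locus_ids.index(locus_id)
        except ValueError:
            raise KeyError(f"unknown locus {locus_id!r}") from None

    def subset_loci(self, locus_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.locus_index(l) for l in locus_ids]
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            locus_ids=list(locus_ids),
            dosage=self.dosage[:, idx].copy(),
            alleles=None if self.alleles is None else [self.alleles[i] for i in idx],
            chrom=None if self.chrom is None else [self.chrom[i] for i in idx],
            pos=None if self.pos is None else [self.pos[i] for i in idx],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return GenotypeMatrix(
            sample_ids=list(sample_ids),
            locus_ids=list(self.locus_ids),
            dosage=self.dosage[idx, :].copy(),
            alleles=None if self.alleles is None else list(self.alleles),
            chrom=None if self.chrom is None else list(self.chrom),
            pos=None if self.pos is None else list(self.pos),
        )

    def swap_alleles(self, locus_id: str) -> "GenotypeMatrix":
        """Return a copy with the allele labelling flipped at one locus.

        Non-missing dosages map d -> 2 - d; statistics are unaffected.
        """
        j = self.locus_index(locus_id)
        dosage = self.dosage.copy()
        obs = dosage[:, j] != MISSING
        dosage[obs, j] = 2 - dosage[obs, j]
        alleles = None
        if self.alleles is not None:
            alleles = list(self.alleles)
            pair = alleles[j]
            if pair is not None and pair[1] is not None:
                alleles[j] = (pair[1], pair[0])
        return replace(self, dosage=dosage, alleles=alleles)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.dosage, other.dosage)
            and self.alleles == other.alleles
        )


@dataclass
class LabeledDataset:
    """A genotype matrix joined with per-sample taxon labels."""

    genotype: GenotypeMatrix
    taxa: np.ndarray  # dtype=object/str, aligned with genotype.sample_ids
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.taxa = np.asarray(self.taxa, dtype=object)
        if len(self.taxa) != self.genotype.n_samples:
            raise ValueError("taxon labels not aligned with sample ids")

    @property
    def taxon_names(self) -> list[str]:
        """Distinct taxa in order of first appearance."""
        seen: dict[str, None] = {}
        for t in self.taxa:
            seen.setdefault(t, None)
        return list(seen)

    def group_sizes(self) -> dict[str, int]:
        return {t: int(np.sum(self.taxa == t)) for t in self.taxon_names}

    def sample_indices(self, taxon: str) -> np.ndarray:
        return np.flatnonzero(self.taxa == taxon)

    def subset_taxa(self, taxa: Iterable[str]) -> "LabeledDataset":
        keep = set(taxa)
        mask = np.array([t in keep for t in self.taxa])
        ids = [s for s, m in zip(self.genotype.sample_ids, mask) if m]
        return LabeledDataset(
            genotype=self.genotype.subset_samples(ids), taxa=self.taxa[mask]
        )


# ----------------------------------------------------------------------
# Parsing helpers


def _delimiter_for(path: str | os.PathLike) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _call_to_dosage(
    token: str, pair: tuple[str, str | None] | None, locus_id: str, line_no: int
) -> tuple[int, tuple[str, str | None] | None]:
    """Decode one genotype call, updating the locus allele pair as needed.

    Returns (dosage, updated_pair).  The pair accumulates alleles in order
    of first observation when it was not supplied up front.
    """
    token = token.strip()
    if token in MISSING_TOKENS:
        return MISSING, pair
    if len(token) == 1:
        if token in IUPAC_HET:
            het = IUPAC_HET[token]
            if pair is not None and pair[1] is not None:
                if frozenset(pair) != het:
                    raise GenotypeParseError(
                        f"line {line_no}: IUPAC code {token!r} inconsistent "
                        f"with alleles {pair} at locus {locus_id!r}"
                    )
                return 1, pair
            a, b = sorted(het)
            if pair is not None and pair[0] is not None:
                if pair[0] not in het:
                    raise GenotypeParseError(
                        f"line {line_no}: IUPAC code {token!r} inconsistent "
                        f"with allele {pair[0]!r} at locus {locus_id!r}"
                    )
                other = next(iter(het - {pair[0]}))
                return 1, (pair[0], other)
            return 1, (a, b)
        token = token + token  # single homozygous letter
    if len(token) != 2:
        raise GenotypeParseError(
            f"line {line_no}: malformed call {token!r} at locus {locus_id!r}"
        )
    a1, a2 = token[0].upper(), token[1].upper()
    for a in (a1, a2):
        if a not in VALID_ALLELES:
            raise GenotypeParseError(
                f"line {line_no}: unknown allele {a!r} at locus {locus_id!r}"
            )
    if pair is None:
        pair = (None, None)  # type: ignore[assignment]
    known = [a for a in pair if a is not None] if pair else []
    for a in dict.fromkeys((a1, a2)):
        if a not in known:
            if len(known) >= 2:
                raise GenotypeParseError(
                    f"line {line_no}: allele {a!r} at locus {locus_id!r} "
                    f"conflicts with pair {tuple(known)}"
                )
            known.append(a)
    new_pair: tuple[str, str | None] = (
        known[0],
        known[1] if len(known) > 1 else None,
    )
    if a1 != a2:
        dos = 1
    elif a1 == new_pair[0]:
        dos = 0
    else:
        dos = 2
    return dos, new_pair


def _parse_locus_header(token: str) -> tuple[str, tuple[str, str | None] | None]:
    """Split a ``locus|A/G`` dosage-dialect column header."""
    if "|" in token:
        lid, allele_part = token.split("|", 1)
        a, _, b = allele_part.partition("/")
        pair = (a, b or None)
        return lid, pair
    return token, None


def _format_locus_header(locus_id: str, pair) -> str:
    if pair is None:
        return locus_id
    a, b = pair
    return f"{locus_id}|{a}/{b}" if b is not None else f"{locus_id}|{a}/"


def _dosage_to_call(d: int, pair) -> str:
    if d == MISSING:
        return "NA"
    if pair is None or pair[0] is None:
        raise GenotypeParseError("cannot write calls without allele labels")
    a, b = pair
    if d == 0:
        return a + a
    if d == 1:
        if b is None:
            raise GenotypeParseError("heterozygote at locus with unknown alt allele")
        return a + b
    if b is None:
        raise GenotypeParseError("dosage 2 at locus with unknown alt allele")
    return b + b


# ----------------------------------------------------------------------
# Public readers / writers


def read_genotype_table(
    path: str | os.PathLike,
    dialect: str = "calls",
    alleles: Sequence[tuple[str, str | None]] | None = None,
) -> GenotypeMatrix:
    """Read a genotype table into dosage coding.

    Parameters
    ----------
    path : path
        Input file; comma-delimited if the name ends in ``.csv``, else
        tab-delimited.
    dialect : {"calls", "dosage", "hapmap"}
        Table layout and cell coding (see module docstring).
    alleles : sequence of allele pairs, optional
        Per-locus (ref-like, alt-like) pairs for the ``calls`` dialect.
        When omitted, pairs are inferred from the observed calls (ref =
        first allele observed).
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    sep = _delimiter_for(path)
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        raise GenotypeParseError(f"{path}: empty file")

    if dialect == "hapmap":
        return _read_hapmap(lines, sep, path)

    header = lines[0].split(sep)
    if len(header) < 1:
        raise GenotypeParseError(f"{path}: missing header")
    raw_locus_cols = header[1:]
    if dialect == "dosage":
        parsed = [_parse_locus_header(t) for t in raw_locus_cols]
        locus_ids = [lid for lid, _ in parsed]
        pairs: list[tuple[str, str | None] | None] = [p for _, p in parsed]
        any_pair = any(p is not None for p in pairs)
    else:
        locus_ids = list(raw_locus_cols)
        if alleles is not None:
            if len(alleles) != len(locus_ids):
                raise GenotypeParseError(
                    f"{len(alleles)} allele pairs supplied for "
                    f"{len(locus_ids)} loci"
                )
            pairs = [tuple(p) for p in alleles]  # type: ignore[misc]
        else:
            pairs = [None] * len(locus_ids)
        any_pair = True

    sample_ids: list[str] = []
    rows: list[list[int]] = []
    for line_no, ln in enumerate(lines[1:], start=2):
        fields = ln.split(sep)
        if len(fields) != len(header):
            raise GenotypeParseError(
                f"{path}: line {line_no} has {len(fields)} fields, "
                f"expected {len(header)}"
            )
        sample_ids.append(fields[0])
        row: list[int] = []
        for j, tok in enumerate(fields[1:]):
            if dialect == "dosage":
                tok = tok.strip()
                if tok in MISSING_TOKENS:
                    row.append(MISSING)
                elif tok in ("0", "1", "2"):
                    row.append(int(tok))
                else:
                    raise GenotypeParseError(
                        f"{path}: line {line_no}: invalid dosage {tok!r} "
                        f"at locus {locus_ids[j]!r}"
                    )
            else:
                d, pairs[j] = _call_to_dosage(tok, pairs[j], locus_ids[j], line_no)
                row.append(d)
        rows.append(row)

    dosage = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.empty((0, len(locus_ids)), dtype=np.int8)
    )
    out_alleles = pairs if any_pair and any(p is not None for p in pairs) else None
    return GenotypeMatrix(
        sample_ids=sample_ids,
        locus_ids=locus_ids,
        dosage=dosage,
        alleles=out_alleles,
    )


def _read_hapmap(lines: list[str], sep: str, path) -> GenotypeMatrix:
    header = lines[0].split(sep)
    fixed = ["rs#", "alleles", "chrom", "pos"]
    if [h.lower() for h in header[:4]] != fixed:
        raise GenotypeParseError(
            f"{path}: hapmap header must start with {fixed}, got {header[:4]}"
        )
    sample_ids = header[4:]
    locus_ids: list[str] = []
    pairs: list[tuple[str, str | None] | None] = []
    chrom: list[str | None] = []
    pos: list[int | None] = []
    cols: list[list[int]] = []
    for line_no, ln in enumerate(lines[1:], start=2):
        fields = ln.split(sep)
        if len(fields) != len(header):
            raise GenotypeParseError(
                f"{path}: line {line_no} has {len(fields)} fields, "
                f"expected {len(header)}"
            )
        lid = fields[0]
        locus_ids.append(lid)
        a, _, b = fields[1].partition("/")
        pair: tuple[str, str | None] | None = (a, b or None) if a else None
        chrom.append(fields[2] or None)
        pos.append(int(fields[3]) if fields[3] not in ("", "NA") else None)
        col: list[int] = []
        for tok in fields[4:]:
            d, pair = _call_to_dosage(tok, pair, lid, line_no)
            col.append(d)
        pairs.append(pair)
        cols.append(col)
    dosage = (
        np.array(cols, dtype=np.int8).T
        if cols
        else np.empty((len(sample_ids), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        sample_ids=sample_ids,
        locus_ids=locus_ids,
        dosage=dosage,
        alleles=pairs if any(p is not None for p in pairs) else None,
        chrom=chrom,
        pos=pos,
    )


def write_genotype_table(
    g: GenotypeMatrix, path: str | os.PathLike, dialect: str = "calls"
) -> None:
    """Write a genotype table; ``read_genotype_table`` inverts it.

    Output is bit-stable for a fixed matrix (no timestamps or floats in
    the data body).
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    sep = _delimiter_for(path)
    alleles = g.alleles if g.alleles is not None else [None] * g.n_loci
    with open(path, "w", encoding="utf-8") as fh:
        if dialect == "hapmap":
            fh.write(sep.join(["rs#", "alleles", "chrom", "pos"] + g.sample_ids) + "\n")
            for j, lid in enumerate(g.locus_ids):
                pair = alleles[j]
                allele_tok = (
                    f"{pair[0]}/{pair[1] or ''}" if pair is not None else ""
                )
                ch = g.chrom[j] if g.chrom is not None else None
                po = g.pos[j] if g.pos is not None else None
                row = [lid, allele_tok, ch or "", "" if po is None else str(po)]
                row += [_dosage_to_call(int(d), pair) for d in g.dosage[:, j]]
                fh.write(sep.join(row) + "\n")
            return
        if dialect == "dosage":
            head = [_format_locus_header(l, a) for l, a in zip(g.locus_ids, alleles)]
            fh.write(sep.join(["sample_id"] + head) + "\n")
            for i, sid in enumerate(g.sample_ids):
                row = [sid] + [
                    "NA" if d == MISSING else str(int(d)) for d in g.dosage[i]
                ]
                fh.write(sep.join(row) + "\n")
            return
        # calls
        fh.write(sep.join(["sample_id"] + g.locus_ids) + "\n")
        for i, sid in enumerate(g.sample_ids):
            row = [sid] + [
                _dosage_to_call(int(d), alleles[j]) for j, d in enumerate(g.dosage[i])
            ]
            fh.write(sep.join(row) + "\n")


# ----------------------------------------------------------------------
# Metadata


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    """Read sample metadata (two-column minimum: sample_id, taxon)."""
    sep = _delimiter_for(path)
    meta = pd.read_csv(path, sep=sep, dtype=str)
    required = {"sample_id", "taxon"}
    if not required.issubset(meta.columns):
        raise GenotypeParseError(
            f"{path}: metadata must contain columns {sorted(required)}"
        )
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise GenotypeParseError(f"{path}: duplicate sample ids {dups[:5]}")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | os.PathLike) -> None:
    meta.to_csv(path, sep=_delimiter_for(path), index=False)


def attach_labels(g: GenotypeMatrix, meta: pd.DataFrame) -> LabeledDataset:
    """Join a genotype matrix with taxon labels, preserving sample order.

    Raises
    ------
    UnlabeledSampleError
        If any matrix sample is missing from the metadata, naming the ids.
    """
    taxon_of = dict(zip(meta["sample_id"], meta["taxon"]))
    missing = [s for s in g.sample_ids if s not in taxon_of]
    if missing:
        raise UnlabeledSampleError(missing)
    taxa = np.array([taxon_of[s] for s in g.sample_ids], dtype=object)
    return LabeledDataset(genotype=g, taxa=taxa, metadata=meta)
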