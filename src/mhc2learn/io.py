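"""Domain types, peptide-table I/O, allele-name normalization and the
immunogenicity data-cleaning rules.

Peptide observations are one row per peptide x allele pair with a binary
label (presented / immunogenic vs. not), optional source gene and flanking
context, and a domain tag separating the mass-spectrometry presentation
domain (``antigenic``) from the T-cell assay domain (``immunogenic``).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AA_ALPHABET)
PAD_CHAR = "X"

LABEL_UNKNOWN = -1

DOMAIN_ANTIGENIC = "antigenic"
DOMAIN_IMMUNOGENIC = "immunogenic"

TABLE_COLUMNS = ["peptide", "allele", "label", "gene",
                 "n_flank", "c_flank", "domain"]


class FormatError(ValueError):
    """A table or sequence file violates the expected layout."""


class EmptyDatasetError(ValueError):
    """An input contained no usable records."""


@dataclass
class PeptideRecord:
    """One peptide x allele observation."""

    peptide: str
    allele: str
    label: int = LABEL_UNKNOWN          # 0, 1, or LABEL_UNKNOWN
    gene: str = ""
    n_flank: str = ""
    c_flank: str = ""
    domain: str = DOMAIN_ANTIGENIC
    source: str = ""
    assay_supported: bool | None = None

    def __post_init__(self):
        if not self.peptide:
            raise ValueError("peptide must be non-empty")
        bad = set(self.peptide) - AA_SET
        if bad:
            raise ValueError(
                f"peptide {self.peptide!r} has invalid characters {sorted(bad)}")
        if self.label not in (0, 1, LABEL_UNKNOWN):
            raise ValueError(f"label must be 0, 1 or unknown, got {self.label}")


@dataclass
class AllelePseudosequence:
    """Allele name with its 34-residue contact pseudosequence and the
    269-residue full groove sequence."""

    name: str
    short_seq: str
    full_seq: str = ""

    def __post_init__(self):
        if len(self.short_seq) != 34:
            raise ValueError(
                f"short_seq must be 34 residues, got {len(self.short_seq)}")
        if self.full_seq and len(self.full_seq) != 269:
            raise ValueError(
                f"full_seq must be 269 residues, got {len(self.full_seq)}")


@dataclass
class Dataset:
    """A collection of peptide records plus allele definitions and
    cross-validation assignments."""

    records: list[PeptideRecord]
    alleles: dict[str, AllelePseudosequence] = field(default_factory=dict)
    split_assignments: np.ndarray | None = None  # (n_repeats, n_records)

    def __len__(self) -> int:
        return len(self.records)

    def peptides(self) -> list[str]:
        return [r.peptide for r in self.records]

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.peptide, r.allele, r.label, r.gene, r.n_flank, r.c_flank,
              r.domain) for r in self.records],
            columns=TABLE_COLUMNS)

    def subset(self, idx) -> "Dataset":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return Dataset([self.records[i] for i in idx], alleles=self.alleles)


# ---------------------------------------------------------------------------
# allele-name normalization

_CHAIN_RE = re.compile(
    r"^(?P<locus>D[RPQ][AB]?\d?)\s*[*_\- ]?\s*"
    r"(?P<g1>\d{2})(?:[:_\-.]?(?P<g2>\d{2,3}))?$")


def _normalize_chain(token: str) -> str | None:
    token = token.strip().upper()
    if token.startswith("HLA-"):
        token = token[4:]
    if token.startswith("HLA"):
        token = token[3:]
    m = _CHAIN_RE.match(token)
    if m is None:
        # compact 4-digit form e.g. DRB10701
        m2 = re.match(r"^(D[RPQ][AB]?\d*?)(\d{2})(\d{2})$", token)
        if m2 and len(m2.group(1)) >= 3:
            return f"{m2.group(1)}*{m2.group(2)}:{m2.group(3)}"
        return None
    if m.group("g2") is None:
        return None  # two-digit resolution only: un-normalizable
    return f"{m.group('locus')}*{m.group('g1')}:{m.group('g2')}"


def normalize_allele(raw: str) -> str | None:
    """Canonicalize an HLA class II allele name to ``LOCUS*GG:PP``.

    DQ/DP heterodimers become an ``alpha/beta`` pair joined with "/".
    Returns ``None`` when the input lacks explicit four-digit typing,
    in which case callers drop the record.
    """
    if not raw or not raw.strip():
        raise ValueError("allele name must be non-empty")
    s = raw.strip()
    # explicit pair separators first
    for sep in ("/", "+"):
        if sep in s:
            parts = [_normalize_chain(p) for p in s.split(sep)]
            if any(p is None for p in parts):
                return None
            return "/".join(parts)
    # "-" may join two chains, or be the HLA- prefix
    chunks = re.split(r"-(?=HLA-|D[RPQ])", s)
    chunks = [c for c in chunks if c not in ("", "HLA")]
    if len(chunks) > 1:
        parts = [_normalize_chain(c) for c in chunks]
        if any(p is None for p in parts):
            return None
        return "/".join(parts)
    return _normalize_chain(s)


def allele_locus(name: str) -> str:
    """Locus group of a normalized allele: DR, DQ or DP."""
    return name[:2].upper() if name else ""


# ---------------------------------------------------------------------------
# table I/O

def _read_table(path) -> pd.DataFrame:
    # native dialect is TSV; fall back to comma-sniffing
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise EmptyDatasetError(f"{path}: empty file")
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_peptide_table(path, domain: str | None = None) -> Dataset:
    """Read a peptide table (TSV or CSV) into a validated :class:`Dataset`.

    Required columns: peptide, allele, label.  Rows whose peptide contains
    characters outside the 20-letter amino-acid alphabet are rejected with
    row-indexed diagnostics in the log.
    """
    df = _read_table(path)
    for col in ("peptide", "allele", "label"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    records: list[PeptideRecord] = []
    n_rejected = 0
    for i, row in df.iterrows():
        pep = str(row["peptide"]).strip().upper()
        bad = set(pep) - AA_SET
        if not pep or bad:
            logger.warning("row %d: peptide %r rejected (invalid: %s)",
                           i, pep, sorted(bad))
            n_rejected += 1
            continue
        raw_label = str(row["label"]).strip()
        label = int(float(raw_label)) if raw_label not in ("", "NA") \
            else LABEL_UNKNOWN
        supported = None
        if "assay_supported" in df.columns:
            supported = str(row["assay_supported"]).strip().lower() in (
                "1", "true", "yes")
        records.append(PeptideRecord(
            peptide=pep,
            allele=str(row["allele"]).strip(),
            label=label,
            gene=str(row.get("gene", "")).strip(),
            n_flank=str(row.get("n_flank", "")).strip().upper(),
            c_flank=str(row.get("c_flank", "")).strip().upper(),
            domain=(domain or str(row.get("domain", DOMAIN_ANTIGENIC)).strip()
                    or DOMAIN_ANTIGENIC),
            assay_supported=supported,
        ))
    if n_rejected:
        logger.info("%s: rejected %d rows", path, n_rejected)
    return Dataset(records)


def write_peptide_table(data: Dataset, path) -> None:
    data.to_frame().to_csv(path, sep="\t", index=False)


def read_pseudosequences(path) -> dict[str, AllelePseudosequence]:
    """Read a TSV mapping allele -> short (34-mer) and optional full
    (269-mer) pseudosequence."""
    df = _read_table(path)
    for col in ("allele", "short_seq"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    out = {}
    for _, row in df.iterrows():
        name = normalize_allele(row["allele"]) or str(row["allele"]).strip()
        out[name] = AllelePseudosequence(
            name=name,
            short_seq=str(row["short_seq"]).strip().upper(),
            full_seq=str(row.get("full_seq", "")).strip().upper())
    return out


def read_proteome(path) -> dict[str, str]:
    """Read a FASTA proteome into {identifier: sequence}."""
    seqs = {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise EmptyDatasetError(f"{path}: no FASTA records")
    return seqs


def read_expression_table(path) -> dict[str, float]:
    """Read a TSV gene -> TPM table."""
    df = _read_table(path)
    for col in ("gene", "tpm"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    return {str(g): float(t) for g, t in zip(df["gene"], df["tpm"])}


# ---------------------------------------------------------------------------
# cleaning rules for immunogenicity data

def clean_immunogenicity(data: Dataset, min_len: int = 11,
                         max_len: int = 19) -> Dataset:
    """Apply the immunogenicity-curation filters.

    In order: drop records without explicit four-digit HLA typing;
    restrict peptide length to [min_len, max_len]; drop records whose
    label lacks experimental assay support; remove beta-chain-only DP
    entries; collapse duplicate peptide x allele groups, treating
    conflicting labels as positive.  Idempotent; removal counts per rule
    are logged.
    """
    counts = {"no_4digit_hla": 0, "length": 0, "no_support": 0,
              "dpb_only": 0, "dedup": 0}
    kept: list[PeptideRecord] = []
    for rec in data.records:
        norm = normalize_allele(rec.allele)
        if norm is None:
            counts["no_4digit_hla"] += 1
            continue
        if not (min_len <= len(rec.peptide) <= max_len):
            counts["length"] += 1
            continue
        if rec.assay_supported is False:
            counts["no_support"] += 1
            continue
        if "DPB" in norm and "DPA" not in norm:
            counts["dpb_only"] += 1
            continue
        kept.append(replace(rec, allele=norm))

    # collapse duplicates; conflicting labels -> positive
    groups: dict[tuple[str, str], PeptideRecord] = {}
    order: list[tuple[str, str]] = []
    for rec in kept:
        key = (rec.peptide, rec.allele)
        if key not in groups:
            groups[key] = rec
            order.append(key)
        else:
            counts["dedup"] += 1
            if rec.label != groups[key].label:
                groups[key] = replace(groups[key], label=1)
    for rule, n in counts.items():
        if n:
            logger.info("clean_immunogenicity: removed %d records (%s)",
                        n, rule)
    return Dataset([groups[k] for k in order], alleles=data.alleles)


# ---------------------------------------------------------------------------
# cross-validation splits

def make_cv_splits(data: Dataset, folds: int = 5, repeats: int = 10,
                   seed: int = 0) -> Dataset:
    """Assign repeated peptide-level cross-validation folds.

    Identical peptide strings never straddle a fold boundary, so a
    peptide tested in one fold cannot occur in that fold's training or
    validation partition.  Deterministic given ``seed``.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    uniq = sorted(set(data.peptides()))
    if len(uniq) < folds:
        raise ValueError(
            f"dataset has {len(uniq)} unique peptides < folds={folds}")
    rng = np.random.default_rng(seed)
    n = len(data.records)
    assignments = np.empty((repeats, n), dtype=np.int64)
    for rep in range(repeats):
        perm = rng.permutation(len(uniq))
        # shuffled order, split into `folds` contiguous chunks for balance
        shuffled = [uniq[j] for j in perm]
        fold_of = {pep: k * folds // len(shuffled)
                   for k, pep in enumerate(shuffled)}
        assignments[rep] = [fold_of[r.peptide] for r in data.records]
    data.split_assignments = assignments
    return data
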