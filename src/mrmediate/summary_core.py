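"""GWAS summary-statistic containers, file I/O, harmonisation, and LD clumping.

The unit of two-sample Mendelian randomisation is a per-SNP pair of
association estimates: the SNP's effect on the exposure and its effect on
the outcome, expressed for the *same* effect allele. This module provides

* :class:`SnpAssociation` / :class:`SummarySet` — one trait's per-SNP
  association estimates (beta, SE, p, allele frequency),
* :func:`read_summary_stats` / :func:`write_summary_stats` — the flat
  tab-delimited exchange format (``SNP CHR BP EA OA EAF BETA SE P N``),
* :func:`harmonise` — allele alignment of an exposure and an outcome panel,
  including strand flips and the palindromic-SNP policy,
* :func:`clump` — greedy p-value-ordered linkage-disequilibrium pruning,
* :func:`rescale_per_sd` — conversion of per-unit betas to per-SD betas.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order of the exchange format
STANDARD_COLUMNS = ["SNP", "CHR", "BP", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]

#: mandatory fields a summary-statistics file must provide
MANDATORY_FIELDS = ["snp_id", "effect_allele", "other_allele", "beta", "se"]

#: standard field name -> standard column name
FIELD_TO_COLUMN = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
    "n": "N",
}


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's estimated association with one trait.

    ``beta`` is the effect per copy of ``effect_allele`` in the trait's
    native units; ``eaf`` is the effect-allele frequency (``None`` when
    unreported); ``n`` is the analysed sample size (``None`` when
    unreported).
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    chrom: str = ""
    pos: int = 0
    eaf: float | None = None
    pvalue: float = 1.0
    n: float | None = None

    def validate(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if not (self.se > 0 and math.isfinite(self.se)):
            raise ValueError(f"{self.snp_id}: se must be a positive finite number")
        if not math.isfinite(self.beta):
            raise ValueError(f"{self.snp_id}: beta must be finite")
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"{self.snp_id}: pvalue must be in (0, 1]")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValueError(f"{self.snp_id}: eaf must be in [0, 1]")

    @property
    def is_palindromic(self) -> bool:
        """A/T or G/C pairs are strand-ambiguous."""
        return COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass
class SummarySet:
    """One instrument panel: per-SNP associations with a single trait."""

    trait_name: str
    records: dict[str, SnpAssociation] = field(default_factory=dict)
    trait_sd: float | None = None
    per_sd: bool = False
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def add(self, rec: SnpAssociation) -> None:
        rec.validate()
        if rec.snp_id in self.records:
            raise ValueError(f"duplicate snp_id {rec.snp_id!r} in set {self.trait_name!r}")
        self.records[rec.snp_id] = rec

    def subset(self, snp_ids: Iterable[str]) -> "SummarySet":
        """Restrict to the given SNPs (missing ids are silently dropped)."""
        keep = {s: self.records[s] for s in snp_ids if s in self.records}
        return SummarySet(self.trait_name, keep, self.trait_sd, self.per_sd)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "SNP": r.snp_id, "CHR": r.chrom, "BP": r.pos,
                "EA": r.effect_allele, "OA": r.other_allele,
                "EAF": r.eaf, "BETA": r.beta, "SE": r.se,
                "P": r.pvalue, "N": r.n,
            }
            for r in self.records.values()
        ]
        return pd.DataFrame(rows, columns=STANDARD_COLUMNS)


@dataclass(frozen=True)
class HarmonisedRow:
    snp_id: str
    bx: float
    sx: float
    by: float
    sy: float
    eaf: float | None = None


@dataclass
class HarmonisedSet:
    """Per-SNP exposure/outcome estimates aligned to a common effect allele."""

    exposure_name: str
    outcome_name: str
    rows: list[HarmonisedRow] = field(default_factory=list)
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        bx = np.array([r.bx for r in self.rows])
        sx = np.array([r.sx for r in self.rows])
        by = np.array([r.by for r in self.rows])
        sy = np.array([r.sy for r in self.rows])
        return bx, sx, by, sy

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.snp_id, r.bx, r.sx, r.by, r.sy, r.eaf) for r in self.rows],
            columns=["SNP", "BX", "SX", "BY", "SY", "EAF"],
        )


@dataclass
class LdMatrix:
    """Squared-correlation matrix between SNPs plus their genomic positions."""

    snp_ids: list[str]
    r2: np.ndarray
    positions: dict[str, tuple[str, int]]

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ValueError("r2 matrix shape does not match snp_ids")
        if not np.allclose(self.r2, self.r2.T):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("r2 diagonal must be exactly 1")
        if self.r2.min() < 0 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 values must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def value(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _parse_optional(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_name: str | None = None,
    delimiter: str = "\t",
) -> SummarySet:
    """Read a delimited summary-statistics table into a :class:`SummarySet`.

    ``column_map`` maps standard field names (``snp_id``, ``chrom``, ``pos``,
    ``effect_allele``, ``other_allele``, ``eaf``, ``beta``, ``se``,
    ``pvalue``, ``n``) to the file's column names; by default the standard
    header ``SNP CHR BP EA OA EAF BETA SE P N`` is assumed. Rows violating
    field invariants are skipped with a logged reason and counted in
    ``SummarySet.skipped``; a missing mandatory column is a hard error.
    """
    path = Path(path)
    cmap = dict(FIELD_TO_COLUMN)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=delimiter, na_values=["NA"], dtype={cmap.get("chrom", "CHR"): str})
    for fld in MANDATORY_FIELDS:
        if cmap[fld] not in df.columns:
            raise ValueError(f"missing mandatory column {cmap[fld]!r} (field {fld!r}) in {path}")
    sset = SummarySet(trait_name or path.stem)
    for idx, row in df.iterrows():
        def get(fld, default=None):
            col = cmap.get(fld)
            if col is None or col not in df.columns:
                return default
            v = row[col]
            return default if pd.isna(v) else v

        try:
            rec = SnpAssociation(
                snp_id=str(get("snp_id")),
                chrom="" if get("chrom") is None else str(get("chrom")),
                pos=int(get("pos", 0) or 0),
                effect_allele=str(get("effect_allele", "")).upper(),
                other_allele=str(get("other_allele", "")).upper(),
                eaf=_parse_optional(get("eaf")),
                beta=float(get("beta")),
                se=float(get("se")),
                pvalue=float(get("pvalue", 1.0) if get("pvalue") is not None else 1.0),
                n=_parse_optional(get("n")),
            )
            sset.add(rec)
        except (ValueError, TypeError) as exc:
            logger.warning("skipping row %s of %s: %s", idx, path.name, exc)
            sset.skipped.append((str(get("snp_id")), str(exc)))
    return sset


def write_summary_stats(sset: SummarySet, path: str | Path) -> None:
    """Write a :class:`SummarySet` as a tab-delimited table.

    Columns follow :data:`STANDARD_COLUMNS`; missing values are written as
    ``NA``; numeric fields are written at full (repr) precision so a
    read/write round trip is lossless for finite values.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(STANDARD_COLUMNS) + "\n")
        for r in sset.records.values():
            fields = [
                r.snp_id, r.chrom, repr(int(r.pos)),
                r.effect_allele, r.other_allele,
                "NA" if r.eaf is None else repr(float(r.eaf)),
                repr(float(r.beta)), repr(float(r.se)), repr(float(r.pvalue)),
                "NA" if r.n is None else repr(float(r.n)),
            ]
            fh.write("\t".join(fields) + "\n")


def read_ld_matrix(matrix_path: str | Path, positions_path: str | Path) -> LdMatrix:
    """Read a square tab-delimited r² matrix plus a ``SNP CHR BP`` positions file."""
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    pos = pd.read_csv(positions_path, sep="\t", dtype={"CHR": str})
    positions = {row.SNP: (str(row.CHR), int(row.BP)) for row in pos.itertuples()}
    return LdMatrix(list(mat.index), mat.to_numpy(dtype=float), positions)


def write_ld_matrix(ld: LdMatrix, matrix_path: str | Path, positions_path: str | Path) -> None:
    pd.DataFrame(ld.r2, index=ld.snp_ids, columns=ld.snp_ids).to_csv(matrix_path, sep="\t")
    pd.DataFrame(
        [(s, *ld.positions[s]) for s in ld.snp_ids], columns=["SNP", "CHR", "BP"]
    ).to_csv(positions_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# harmonisation
# ---------------------------------------------------------------------------

def _align_orientation(
    ref: SnpAssociation,
    other: SnpAssociation,
    palindrome_policy: str,
    eaf_ambiguity_window: float,
) -> tuple[int, str | None]:
    """Sign with which ``other``'s beta maps onto ``ref``'s effect allele.

    Returns ``(+1 | -1, None)`` on success or ``(0, reason)`` when the pair
    must be dropped. Non-palindromic pairs are aligned directly or after a
    strand (complement) flip; palindromic pairs fall to ``palindrome_policy``:

    * ``keep`` — trust the reported alleles as same-strand,
    * ``drop_ambiguous`` / ``infer_by_eaf`` — orient by comparing which side
      of 0.5 each study's effect-allele frequency falls on, dropping SNPs
      whose minor-allele frequency is within ``eaf_ambiguity_window`` of 0.5
      (frequency no longer identifies the allele) or whose eaf is missing.
    """
    ea, oa = other.effect_allele, other.other_allele
    if ref.is_palindromic:
        if {ea, oa} != {ref.effect_allele, ref.other_allele}:
            return 0, "allele_mismatch"
        sign = 1 if ea == ref.effect_allele else -1
        if palindrome_policy == "keep":
            return sign, None
        if palindrome_policy not in ("drop_ambiguous", "infer_by_eaf"):
            raise ValueError(f"unknown palindrome policy {palindrome_policy!r}")
        if ref.eaf is None or other.eaf is None:
            return 0, "palindromic_missing_eaf"
        eaf_other = other.eaf if sign == 1 else 1 - other.eaf
        cutoff = 0.5 - eaf_ambiguity_window
        if min(ref.eaf, 1 - ref.eaf) > cutoff or min(eaf_other, 1 - eaf_other) > cutoff:
            return 0, "palindromic_ambiguous"
        if (ref.eaf - 0.5) * (eaf_other - 0.5) < 0:
            # frequencies disagree: the outcome study reported the other strand
            return -sign, None
        return sign, None
    pair = (ea, oa)
    flipped = (COMPLEMENT[ea], COMPLEMENT[oa])
    target = (ref.effect_allele, ref.other_allele)
    if pair == target or flipped == target:
        return 1, None
    if pair == target[::-1] or flipped == target[::-1]:
        return -1, None
    return 0, "allele_mismatch"


def harmonise(
    exposure: SummarySet,
    outcome: SummarySet,
    palindrome_policy: str = "drop_ambiguous",
    eaf_ambiguity_window: float = 0.08,
) -> HarmonisedSet:
    """Align outcome associations to the exposure's effect alleles.

    For each SNP shared between the panels the outcome beta is copied
    (same orientation) or negated with ``eaf -> 1 - eaf`` (swapped alleles);
    strand flips are resolved via allele complements; palindromic SNPs are
    handled per ``palindrome_policy`` (see :func:`_align_orientation`).
    Irreconcilable allele pairs are dropped with a reason.
    """
    if not exposure.records or not outcome.records:
        raise ValueError("harmonise requires nonempty exposure and outcome sets")
    shared = [s for s in exposure.records if s in outcome.records]
    if not shared:
        raise ValueError(
            f"no shared SNPs between {exposure.trait_name!r} and {outcome.trait_name!r}"
        )
    h = HarmonisedSet(exposure.trait_name, outcome.trait_name)
    for sid in shared:
        e, o = exposure.records[sid], outcome.records[sid]
        sign, reason = _align_orientation(e, o, palindrome_policy, eaf_ambiguity_window)
        if sign == 0:
            h.dropped.append((sid, reason))
            continue
        eaf = e.eaf
        if eaf is None and o.eaf is not None:
            eaf = o.eaf if sign == 1 else 1 - o.eaf
        h.rows.append(HarmonisedRow(sid, e.beta, e.se, sign * o.beta, o.se, eaf))
    return h


# ---------------------------------------------------------------------------
# LD clumping
# ---------------------------------------------------------------------------

def clump(
    sset: SummarySet,
    ld: LdMatrix,
    r2_threshold: float = 0.001,
    window_kb: int = 10_000,
) -> SummarySet:
    """Greedy p-value-ordered LD pruning.

    SNPs are visited in order of ascending p-value (ties broken by larger
    ``|beta/se|``, then lexicographic snp_id); each accepted SNP discards all
    remaining same-chromosome SNPs within ``window_kb`` whose r² with it
    exceeds ``r2_threshold``. The result contains no pair violating the
    (r², window) constraint.
    """
    missing = [s for s in sset.records if s not in ld._index]
    if missing:
        raise ValueError(f"SNPs absent from LD matrix: {missing}")

    def sort_key(rec: SnpAssociation):
        return (rec.pvalue, -abs(rec.beta / rec.se), rec.snp_id)

    remaining = sorted(sset.records.values(), key=sort_key)
    kept: list[SnpAssociation] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        b_chrom, b_pos = ld.positions[best.snp_id]
        survivors = []
        for rec in remaining:
            chrom, pos = ld.positions[rec.snp_id]
            in_window = chrom == b_chrom and abs(pos - b_pos) <= window_kb * 1000
            if in_window and ld.value(best.snp_id, rec.snp_id) > r2_threshold:
                continue
            survivors.append(rec)
        remaining = survivors
    out = SummarySet(sset.trait_name, trait_sd=sset.trait_sd, per_sd=sset.per_sd)
    for rec in kept:
        out.add(rec)
    return out


# ---------------------------------------------------------------------------
# per-SD rescaling
# ---------------------------------------------------------------------------

def rescale_per_sd(sset: SummarySet, sd: float) -> SummarySet:
    """Convert per-unit betas to per-SD betas (beta and se multiplied by sd).

    The returned set records ``trait_sd`` and flags ``per_sd``; rescaling an
    already per-SD set is permitted (e.g. to invert a scaling) but warned
    about, since double conversion is usually an accident.
    """
    if not sd > 0:
        raise ValueError("sd must be positive")
    if sset.per_sd:
        logger.warning(
            "set %r is already per-SD; rescaling again by %g", sset.trait_name, sd
        )
    out = SummarySet(sset.trait_name, trait_sd=sd, per_sd=True)
    for rec in sset.records.values():
        out.add(replace(rec, beta=rec.beta * sd, se=rec.se * sd))
    return out
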