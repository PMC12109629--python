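"""Reading, validation and harmonization of GWAS summary statistics.

Two-sample MR consumes per-variant association estimates from two (or, for
mediation, three) independent GWAS.  Before any estimator can run, the
exposure and outcome records have to be expressed for the *same* effect
allele at every shared SNP.  This module provides the record container, a
delimited-text reader with a configurable column map, and the harmonization
step that aligns outcome effects to the exposure's effect allele, dealing
with swapped labels, strand flips and palindromic (A/T, C/G) variants.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, EmptyInputError, NoInstrumentsError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: standard field -> default column name in delimited input
DEFAULT_COLUMN_MAP = {
    "variant_id": "variant_id",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
    "chrom": "chrom",
    "pos": "pos",
}

_MANDATORY = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pval")
_OPTIONAL = ("eaf", "n", "chrom", "pos")


@dataclass(frozen=True)
class SummaryStatRecord:
    """One variant's association estimate in one GWAS.

    ``beta`` is in trait units for quantitative traits and on the log-odds
    scale for binary outcomes.  ``eaf`` is the effect-allele frequency and
    may be missing for non-palindromic SNPs.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: float | None = None
    chrom: str | None = None
    pos: int | None = None

    @property
    def is_palindromic(self) -> bool:
        return _COMPLEMENT.get(self.effect_allele) == self.other_allele

    def validate(self) -> None:
        """Raise ``ValueError`` if any container invariant is violated."""
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.variant_id}: alleles must be one of A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele identical")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise ValueError(f"{self.variant_id}: se must be > 0")
        if not math.isfinite(self.beta):
            raise ValueError(f"{self.variant_id}: beta must be finite")
        if not (0 < self.pval <= 1):
            raise ValueError(f"{self.variant_id}: pval must be in (0, 1]")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValueError(f"{self.variant_id}: eaf must be in [0, 1]")
        if self.n is not None and self.n < 1:
            raise ValueError(f"{self.variant_id}: n must be >= 1")


def _is_valid_row(rec: SummaryStatRecord) -> bool:
    try:
        rec.validate()
    except ValueError:
        return False
    return True


def read_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = "\t",
) -> list[SummaryStatRecord]:
    """Read GWAS summary statistics from delimited text (gzip transparent).

    ``column_map`` maps standard field names (keys of
    :data:`DEFAULT_COLUMN_MAP`) to the file's column names.  Rows violating
    record invariants are dropped with a logged count.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    try:
        df = pd.read_csv(path, sep=delimiter)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: file is empty") from exc
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    missing = [cmap[f] for f in _MANDATORY if cmap[f] not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing mandatory column(s) {missing}")

    present_optional = [f for f in _OPTIONAL if cmap[f] in df.columns]
    records: list[SummaryStatRecord] = []
    n_dropped = 0
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        try:
            kwargs = {
                "variant_id": str(row[cmap["variant_id"]]),
                "effect_allele": str(row[cmap["effect_allele"]]).upper(),
                "other_allele": str(row[cmap["other_allele"]]).upper(),
                "beta": float(row[cmap["beta"]]),
                "se": float(row[cmap["se"]]),
                "pval": float(row[cmap["pval"]]),
            }
            for f in present_optional:
                val = row[cmap[f]]
                if val is None or (isinstance(val, float) and math.isnan(val)):
                    kwargs[f] = None
                elif f == "chrom":
                    kwargs[f] = str(val)
                elif f == "pos":
                    kwargs[f] = int(val)
                else:
                    kwargs[f] = float(val)
        except (TypeError, ValueError):
            n_dropped += 1
            continue
        rec = SummaryStatRecord(**kwargs)
        if _is_valid_row(rec):
            records.append(rec)
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("%s: dropped %d invalid row(s)", path, n_dropped)
    return records


def write_summary_stats(records: Sequence[SummaryStatRecord], path, delimiter: str = "\t") -> None:
    """Write records in the same TSV dialect :func:`read_summary_stats` reads."""
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    df.to_csv(path, sep=delimiter, index=False)


@dataclass
class HarmonizedSet:
    """Per-SNP exposure/outcome effect pairs aligned to a common effect allele.

    The substrate of every MR estimator: equal-length arrays of exposure and
    outcome betas and SEs, with each outcome beta expressed for the same
    effect allele as the exposure beta at that SNP.
    """

    variant_id: np.ndarray
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"

    def __post_init__(self) -> None:
        self.variant_id = np.asarray(self.variant_id, dtype=object)
        for field in ("beta_exposure", "se_exposure", "beta_outcome", "se_outcome"):
            setattr(self, field, np.asarray(getattr(self, field), dtype=float))
        n = len(self.variant_id)
        if n < 1:
            raise ValueError("HarmonizedSet requires at least one SNP")
        for field in ("beta_exposure", "se_exposure", "beta_outcome", "se_outcome"):
            if len(getattr(self, field)) != n:
                raise ValueError("HarmonizedSet arrays must have equal length")
        if len(set(self.variant_id)) != n:
            raise ValueError("duplicate variant_id in HarmonizedSet")
        if np.any(self.se_exposure < 0) or np.any(self.se_outcome < 0):
            raise ValueError("standard errors must be non-negative")

    @property
    def n_snp(self) -> int:
        return len(self.variant_id)

    def __len__(self) -> int:
        return self.n_snp

    def subset(self, index) -> "HarmonizedSet":
        """Return a new set restricted to a boolean mask or index array."""
        index = np.asarray(index)
        return HarmonizedSet(
            variant_id=self.variant_id[index],
            beta_exposure=self.beta_exposure[index],
            se_exposure=self.se_exposure[index],
            beta_outcome=self.beta_outcome[index],
            se_outcome=self.se_outcome[index],
            exposure_name=self.exposure_name,
            outcome_name=self.outcome_name,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": self.variant_id,
                "b_x": self.beta_exposure,
                "s_x": self.se_exposure,
                "b_y": self.beta_outcome,
                "s_y": self.se_outcome,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **names) -> "HarmonizedSet":
        return cls(
            variant_id=df["variant_id"].to_numpy(dtype=object),
            beta_exposure=df["b_x"].to_numpy(float),
            se_exposure=df["s_x"].to_numpy(float),
            beta_outcome=df["b_y"].to_numpy(float),
            se_outcome=df["s_y"].to_numpy(float),
            **names,
        )


def _dedupe(records: Iterable[SummaryStatRecord], label: str) -> dict[str, SummaryStatRecord]:
    """Index records by variant_id, keeping the smallest-p row on duplicates."""
    out: dict[str, SummaryStatRecord] = {}
    n_dup = 0
    for rec in records:
        prev = out.get(rec.variant_id)
        if prev is None or rec.pval < prev.pval:
            if prev is not None:
                n_dup += 1
            out[rec.variant_id] = rec
        elif prev is not None:
            n_dup += 1
    if n_dup:
        logger.info("%s: %d duplicate variant_id row(s) resolved by smallest p", label, n_dup)
    return out


def _in_band(eaf: float, band: tuple[float, float]) -> bool:
    return band[0] <= eaf <= band[1]


def harmonize(
    exposure: Sequence[SummaryStatRecord],
    outcome: Sequence[SummaryStatRecord],
    palindrome_policy: str = "infer_by_eaf",
    eaf_ambiguity_band: tuple[float, float] = (0.42, 0.58),
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect allele at shared SNPs.

    Swapped allele labels (and their strand complements) flip the outcome
    beta sign; palindromic SNPs are dropped outright (``palindrome_policy=
    "drop"``) or resolved through effect-allele frequencies, dropping only
    when either study's EAF falls inside ``eaf_ambiguity_band`` or is
    missing.  SNPs whose allele pairs cannot be reconciled are removed with
    a log entry.
    """
    if palindrome_policy not in ("drop", "infer_by_eaf"):
        raise ConfigurationError(f"unknown palindrome_policy {palindrome_policy!r}")
    if not exposure or not outcome:
        raise EmptyInputError("harmonize requires non-empty exposure and outcome records")

    exp_ix = _dedupe(exposure, exposure_name)
    out_ix = _dedupe(outcome, outcome_name)

    ids, bx, sx, by, sy = [], [], [], [], []
    n_incompatible = n_palindromic_dropped = 0
    # preserve exposure input order over the intersection
    for vid, e in exp_ix.items():
        o = out_ix.get(vid)
        if o is None:
            continue
        e_pair = frozenset((e.effect_allele, e.other_allele))
        o_pair = frozenset((o.effect_allele, o.other_allele))
        o_pair_flipped = frozenset(_COMPLEMENT[a] for a in o_pair)
        if e.is_palindromic:
            # strand cannot be resolved from labels; both pairs read the same
            if o_pair != e_pair:
                n_incompatible += 1
                continue
            if palindrome_policy == "drop":
                n_palindromic_dropped += 1
                continue
            if e.eaf is None or o.eaf is None:
                n_palindromic_dropped += 1
                continue
            if _in_band(e.eaf, eaf_ambiguity_band) or _in_band(o.eaf, eaf_ambiguity_band):
                n_palindromic_dropped += 1
                continue
            # labels say whether the outcome's effect allele matches the
            # exposure's; frequencies say whether that labeling is
            # strand-consistent (same side of 0.5) or strand-flipped
            label_flip = o.effect_allele != e.effect_allele
            o_eaf = 1.0 - o.eaf if label_flip else o.eaf
            strand_consistent = (e.eaf - 0.5) * (o_eaf - 0.5) > 0
            beta_out = -o.beta if label_flip else o.beta
            if not strand_consistent:
                beta_out = -beta_out
        else:
            if (o.effect_allele, o.other_allele) == (e.effect_allele, e.other_allele):
                beta_out = o.beta
            elif (o.effect_allele, o.other_allele) == (e.other_allele, e.effect_allele):
                beta_out = -o.beta
            elif o_pair == o_pair_flipped:
                # outcome palindromic but exposure not: labels irreconcilable
                n_incompatible += 1
                continue
            elif (_COMPLEMENT[o.effect_allele], _COMPLEMENT[o.other_allele]) == (
                e.effect_allele,
                e.other_allele,
            ):
                beta_out = o.beta  # strand flip, same orientation
            elif (_COMPLEMENT[o.effect_allele], _COMPLEMENT[o.other_allele]) == (
                e.other_allele,
                e.effect_allele,
            ):
                beta_out = -o.beta  # strand flip and swapped
            else:
                n_incompatible += 1
                continue
        ids.append(vid)
        bx.append(e.beta)
        sx.append(e.se)
        by.append(beta_out)
        sy.append(o.se)

    if n_incompatible:
        logger.info("harmonize: removed %d SNP(s) with incompatible allele pairs", n_incompatible)
    if n_palindromic_dropped:
        logger.info("harmonize: dropped %d ambiguous palindromic SNP(s)", n_palindromic_dropped)
    if not ids:
        raise NoInstrumentsError(
            f"no harmonizable SNPs shared by {exposure_name} and {outcome_name}"
        )
    return HarmonizedSet(
        variant_id=np.array(ids, dtype=object),
        beta_exposure=np.array(bx),
        se_exposure=np.array(sx),
        beta_outcome=np.array(by),
        se_outcome=np.array(sy),
        exposure_name=exposure_name,
        outcome_name=outcome_name,
    )
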