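"""Instrumental-variable selection: significance, LD clumping, strength.

A valid MR instrument must be robustly associated with the exposure
(genome-wide significance, p < 5e-8 by default), independent of the other
instruments (greedy LD clumping at r^2 <= 0.001 within a 10,000 kb window),
and strong (F = beta^2/SE^2 >= 10).  LD is always supplied as a matrix of
squared correlations; no reference-panel computation happens here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .sumstats import SummaryStatRecord

logger = logging.getLogger(__name__)


@dataclass
class InstrumentCriteria:
    """Thresholds governing instrument selection."""

    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    f_min: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ConfigurationError("p_threshold must be in (0, 1)")
        if not (0 <= self.clump_r2 <= 1):
            raise ConfigurationError("clump_r2 must be in [0, 1]")
        if self.clump_window_kb <= 0:
            raise ConfigurationError("clump_window_kb must be > 0")
        if self.f_min < 0:
            raise ConfigurationError("f_min must be >= 0")


@dataclass
class LDMatrix:
    """Symmetric matrix of squared correlations between variants."""

    variant_ids: list[str]
    r2: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.variant_ids)
        if self.r2.shape != (n, n):
            raise ValueError("r2 must be square and match variant_ids")
        if not np.allclose(self.r2, self.r2.T):
            raise ValueError("r2 must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("r2 diagonal must be 1")
        if np.any(self.r2 < 0) or np.any(self.r2 > 1):
            raise ValueError("r2 values must be in [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def r2_between(self, a: str, b: str) -> float:
        """r^2 between two variants; variants absent from the matrix are
        treated as independent (0)."""
        ia = self._index.get(a)
        ib = self._index.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r2[ia, ib])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.r2, columns=self.variant_ids).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t")
        return cls(variant_ids=list(df.columns), r2=df.to_numpy(float))


def select_significant(
    records: Sequence[SummaryStatRecord], p_threshold: float = 5e-8
) -> list[SummaryStatRecord]:
    """Keep records with p strictly below the significance threshold,
    preserving input order."""
    return [r for r in records if r.pval < p_threshold]


def _within_window(a: SummaryStatRecord, b: SummaryStatRecord, window_kb: float) -> bool:
    # when coordinates are absent the window is ignored and r2 alone governs
    if a.chrom is None or b.chrom is None or a.pos is None or b.pos is None:
        return True
    if a.chrom != b.chrom:
        return False
    return abs(a.pos - b.pos) <= window_kb * 1000.0


def clump(
    records: Sequence[SummaryStatRecord],
    ld: LDMatrix,
    criteria: InstrumentCriteria | None = None,
) -> list[SummaryStatRecord]:
    """Greedy p-value-ordered LD clumping.

    SNPs are visited by ascending p (ties broken by lexicographic
    variant_id for determinism); a SNP is accepted iff its r^2 with every
    already-accepted SNP within the kb window is <= ``clump_r2``.
    """
    criteria = criteria or InstrumentCriteria()
    missing = [r.variant_id for r in records if r.variant_id not in ld]
    if missing:
        logger.info("clump: %d SNP(s) absent from LD matrix, treated as independent", len(missing))
    ordered = sorted(records, key=lambda r: (r.pval, r.variant_id))
    accepted: list[SummaryStatRecord] = []
    for rec in ordered:
        ok = all(
            not _within_window(rec, a, criteria.clump_window_kb)
            or ld.r2_between(rec.variant_id, a.variant_id) <= criteria.clump_r2
            for a in accepted
        )
        if ok:
            accepted.append(rec)
    return accepted


def f_statistic(beta: float, se: float) -> float:
    """Instrument strength, F = beta^2 / SE^2."""
    if se <= 0:
        raise ValueError("se must be > 0")
    return (beta / se) ** 2


def filter_weak(
    records: Sequence[SummaryStatRecord], f_min: float = 10.0
) -> list[SummaryStatRecord]:
    """Exclude weak instruments: keep records with F >= ``f_min``."""
    return [r for r in records if f_statistic(r.beta, r.se) >= f_min]
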