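"""Instrument selection: p-value winnowing, LD clumping, and strength filters.

An instrumental variable for two-sample MR must be (a) associated with the
exposure at a chosen significance threshold, (b) independent of the other
candidate instruments (LD clumping), and (c) strong enough that weak-
instrument bias is negligible (F statistic).  This module implements those
three gates over :class:`~mrmediate.io.GwasRecord` collections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, DomainError
from .io import GwasRecord, as_frame, frame_to_records

logger = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 5e-5
DEFAULT_CLUMP_R2 = 0.001
DEFAULT_CLUMP_WINDOW_BP = 10_000_000
DEFAULT_F_MIN = 10.0


class PairwiseLD:
    """Pairwise LD (r-squared) lookup over a set of known SNPs.

    Pairs absent from the store default to r² = 0; SNPs absent from the
    store entirely are treated as uncovered, which :func:`clump` reports as
    a data error.
    """

    def __init__(self, snp_ids, pairs: dict[tuple[str, str], float] | None = None):
        self._snps = set(map(str, snp_ids))
        self._pairs: dict[frozenset, float] = {}
        for (a, b), r2 in (pairs or {}).items():
            self.set_r2(a, b, r2)

    def set_r2(self, a: str, b: str, r2: float) -> None:
        self._snps.update((str(a), str(b)))
        if a != b:
            self._pairs[frozenset((str(a), str(b)))] = float(r2)

    def covers(self, snp_id: str) -> bool:
        return str(snp_id) in self._snps

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._pairs.get(frozenset((str(a), str(b))), 0.0)

    @classmethod
    def from_pairs_tsv(cls, path: str | Path) -> "PairwiseLD":
        """Load from a TSV with columns ``snp_a  snp_b  r2``."""
        table = pd.read_csv(path, sep="\t", dtype={"snp_a": str, "snp_b": str})
        ld = cls(snp_ids=())
        for t in table.itertuples(index=False):
            ld.set_r2(t.snp_a, t.snp_b, t.r2)
        return ld

    @classmethod
    def from_dense(cls, snp_ids, matrix) -> "PairwiseLD":
        """Build from a dense symmetric r² matrix aligned with ``snp_ids``."""
        snp_ids = [str(s) for s in snp_ids]
        matrix = np.asarray(matrix, dtype=float)
        ld = cls(snp_ids=snp_ids)
        ii, jj = np.nonzero(np.triu(matrix, k=1))
        for i, j in zip(ii, jj):
            ld.set_r2(snp_ids[i], snp_ids[j], matrix[i, j])
        return ld

    def to_pairs_tsv(self, path: str | Path) -> Path:
        rows = [
            {"snp_a": a, "snp_b": b, "r2": r2}
            for pair, r2 in sorted(self._pairs.items(), key=lambda kv: sorted(kv[0]))
            for a, b in [sorted(pair)]
        ]
        # singleton SNPs kept as self-pairs so coverage survives a round trip
        paired = {s for pair in self._pairs for s in pair}
        rows.extend({"snp_a": s, "snp_b": s, "r2": 1.0} for s in sorted(self._snps - paired))
        pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"]).to_csv(path, sep="\t", index=False)
        return Path(path)


@dataclass
class InstrumentSet:
    """The selected instruments for one exposure, with strength diagnostics."""

    exposure_name: str
    records: list[GwasRecord]
    p_threshold: float = DEFAULT_P_THRESHOLD
    clump_r2: float = DEFAULT_CLUMP_R2
    clump_window_bp: int = DEFAULT_CLUMP_WINDOW_BP
    r2_per_snp: np.ndarray = field(default_factory=lambda: np.array([]))
    r2_total: float = 0.0
    f_stat: float = float("nan")


def select_by_pvalue(records, p_threshold: float = DEFAULT_P_THRESHOLD) -> list[GwasRecord]:
    """Keep exactly the records with ``pval < p_threshold``, order preserved."""
    frame = as_frame(records)
    if len(frame) == 0:
        raise DataError("select_by_pvalue: empty record collection")
    kept = frame.loc[frame["pval"] < p_threshold]
    if len(kept) == 0:
        logger.warning(
            "select_by_pvalue: no records below p < %.3g (min p = %.3g)",
            p_threshold,
            float(frame["pval"].min()),
        )
    return frame_to_records(kept)


def clump(
    records,
    ld_matrix: PairwiseLD,
    r2_threshold: float = DEFAULT_CLUMP_R2,
    window_bp: int = DEFAULT_CLUMP_WINDOW_BP,
) -> list[GwasRecord]:
    """Greedy p-value-ordered LD clumping.

    Repeatedly take the remaining record with the smallest p-value as an
    index SNP and remove every other remaining record on the same chromosome
    within ``window_bp`` of it with pairwise r² >= ``r2_threshold``.  Ties on
    p are broken by (chrom, pos, snp_id) so the result is deterministic and
    independent of input row order.  Index SNPs are returned sorted by
    ascending p-value.
    """
    recs = frame_to_records(as_frame(records))
    for r in recs:
        if not ld_matrix.covers(r.snp_id):
            raise DataError(f"clump: SNP {r.snp_id!r} is missing from the LD matrix")
    order = sorted(recs, key=lambda r: (r.pval, r.chrom, r.pos, r.snp_id))
    removed: set[str] = set()
    index_snps: list[GwasRecord] = []
    for cand in order:
        if cand.snp_id in removed:
            continue
        index_snps.append(cand)
        for other in order:
            if other.snp_id in removed or other.snp_id == cand.snp_id:
                continue
            if any(other.snp_id == kept.snp_id for kept in index_snps):
                continue
            if (
                other.chrom == cand.chrom
                and abs(other.pos - cand.pos) <= window_bp
                and ld_matrix.r2(cand.snp_id, other.snp_id) >= r2_threshold
            ):
                removed.add(other.snp_id)
    return index_snps


def snp_r2(record: GwasRecord, mode: str = "normalized") -> float:
    """Per-SNP variance in the exposure explained by the variant.

    ``mode="printed"`` returns the textbook shorthand
    ``2*EAF*(1-EAF)*(beta/se)**2``; note this quantity approximates N times
    the variance explained and can exceed 1.  ``mode="normalized"`` returns
    ``z**2 / (n + z**2)`` with ``z = beta/se``, which is bounded by 1 and is
    the pipeline default for F-statistic computation.
    """
    z2 = (record.beta / record.se) ** 2
    if mode == "printed":
        return 2.0 * record.eaf * (1.0 - record.eaf) * z2
    if mode == "normalized":
        return z2 / (record.n + z2)
    raise ValueError(f"unknown snp_r2 mode {mode!r}")


def f_statistic(r2_total: float, n: float, k: int) -> float:
    """Instrument-set F statistic ``(R²/K) / ((1−R²)/(N−K−1))``."""
    if not 0.0 <= r2_total < 1.0:
        raise DomainError(f"f_statistic: R² must lie in [0, 1), got {r2_total}")
    if k < 1 or n <= k + 1:
        raise DomainError(f"f_statistic: need N > K+1 >= 2, got N={n}, K={k}")
    return (r2_total / k) / ((1.0 - r2_total) / (n - k - 1))


def _strength(records: list[GwasRecord], r2_mode: str) -> tuple[np.ndarray, float, float]:
    r2s = np.array([snp_r2(r, mode=r2_mode) for r in records])
    r2_total = float(r2s.sum())
    n = float(min(r.n for r in records))
    f = f_statistic(min(r2_total, 1.0 - 1e-12), n, len(records))
    return r2s, r2_total, f


def filter_weak(
    instrument_set: InstrumentSet,
    f_min: float = DEFAULT_F_MIN,
    r2_mode: str = "normalized",
) -> InstrumentSet:
    """Drop weak instruments until the set-level F statistic reaches ``f_min``.

    The published convention excludes instruments with F < 10, but F is a
    property of the set; this operationalization iteratively removes the
    SNP contributing the least variance explained, recomputing F after each
    drop, and stops when F >= ``f_min`` or a single SNP remains.
    """
    records = list(instrument_set.records)
    if not records:
        raise DataError("filter_weak: empty instrument set")
    r2s, r2_total, f = _strength(records, r2_mode)
    if f >= f_min:
        logger.info("filter_weak(%s): F = %.1f >= %.1f, set unchanged", instrument_set.exposure_name, f, f_min)
    while f < f_min and len(records) > 1:
        weakest = int(np.argmin(r2s))
        logger.info(
            "filter_weak(%s): F = %.2f < %.1f, dropping %s (per-SNP R² = %.3g)",
            instrument_set.exposure_name, f, f_min, records[weakest].snp_id, r2s[weakest],
        )
        del records[weakest]
        r2s, r2_total, f = _strength(records, r2_mode)
    return replace(
        instrument_set,
        records=records,
        r2_per_snp=r2s,
        r2_total=r2_total,
        f_stat=f,
    )


def select_instruments(
    records,
    exposure_name: str = "exposure",
    ld_matrix: PairwiseLD | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    clump_r2: float = DEFAULT_CLUMP_R2,
    clump_window_bp: int = DEFAULT_CLUMP_WINDOW_BP,
    f_min: float = DEFAULT_F_MIN,
    r2_mode: str = "normalized",
) -> InstrumentSet:
    """Full instrument-selection pipeline for one exposure.

    Applies the p-value gate, LD clumping (skipped with a log message when
    no LD information is supplied), and the weak-instrument filter; returns
    the surviving index SNPs sorted by ascending p with their strength
    diagnostics.
    """
    kept = select_by_pvalue(records, p_threshold)
    if not kept:
        raise DataError(
            f"select_instruments({exposure_name}): no variant passes p < {p_threshold:g}"
        )
    if ld_matrix is not None:
        kept = clump(kept, ld_matrix, r2_threshold=clump_r2, window_bp=clump_window_bp)
    else:
        logger.info("select_instruments(%s): no LD matrix supplied, clumping skipped", exposure_name)
        kept = sorted(kept, key=lambda r: (r.pval, r.chrom, r.pos, r.snp_id))
    iset = InstrumentSet(
        exposure_name=exposure_name,
        records=kept,
        p_threshold=p_threshold,
        clump_r2=clump_r2,
        clump_window_bp=clump_window_bp,
    )
    return filter_weak(iset, f_min=f_min, r2_mode=r2_mode)
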