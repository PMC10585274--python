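"""Reading and writing GWAS summary statistics and analysis reports.

The canonical on-disk dialect is a tab-separated table with one header line
and the columns

    snp_id  chrom  pos  effect_allele  other_allele  eaf  beta  se  pval  n

``beta`` is the per-allele effect on the trait (log odds ratio for binary
traits), ``se`` its standard error, ``eaf`` the effect-allele frequency and
``n`` the GWAS sample size.  Coordinates are 1-based and the strand is
assumed forward; palindromic ambiguity is the harmonization step's problem,
not the reader's.

In memory a collection of records is either a list of :class:`GwasRecord`
or a :class:`pandas.DataFrame` with the canonical columns; every operation
in the package accepts both (see :func:`as_frame`).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DataError, FormatError, UsageError

logger = logging.getLogger(__name__)

#: Canonical column order of the summary-statistics dialect.
CANONICAL_COLUMNS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)


@dataclass(frozen=True)
class GwasRecord:
    """One variant's summary statistics for one trait."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: float

    def is_valid(self) -> bool:
        """Whether the record satisfies the type invariants
        (se > 0, 0 < eaf < 1, distinct alleles, pos >= 1, pval in (0, 1],
        finite beta)."""
        try:
            return (
                self.se > 0
                and 0.0 < self.eaf < 1.0
                and self.effect_allele != self.other_allele
                and self.pos >= 1
                and 0.0 < self.pval <= 1.0
                and math.isfinite(self.beta)
                and self.n > 0
            )
        except TypeError:
            return False


def records_to_frame(records: Iterable[GwasRecord]) -> pd.DataFrame:
    """Convert records to a canonical-column DataFrame (order preserved)."""
    rows = [dataclasses.asdict(r) for r in records]
    if not rows:
        return pd.DataFrame(columns=list(CANONICAL_COLUMNS))
    return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def frame_to_records(frame: pd.DataFrame) -> list[GwasRecord]:
    """Convert a canonical-column DataFrame to a list of records."""
    return [
        GwasRecord(
            snp_id=str(t.snp_id),
            chrom=str(t.chrom),
            pos=int(t.pos),
            effect_allele=str(t.effect_allele),
            other_allele=str(t.other_allele),
            eaf=float(t.eaf),
            beta=float(t.beta),
            se=float(t.se),
            pval=float(t.pval),
            n=float(t.n),
        )
        for t in frame.itertuples(index=False)
    ]


def as_frame(records) -> pd.DataFrame:
    """Normalize any accepted record collection to a canonical DataFrame."""
    if isinstance(records, pd.DataFrame):
        missing = [c for c in CANONICAL_COLUMNS if c not in records.columns]
        if missing:
            raise FormatError(f"record table is missing required columns: {missing}")
        return records.loc[:, list(CANONICAL_COLUMNS)].reset_index(drop=True)
    return records_to_frame(records)


def _validity_mask(frame: pd.DataFrame) -> pd.Series:
    return (
        (frame["se"] > 0)
        & (frame["eaf"] > 0)
        & (frame["eaf"] < 1)
        & (frame["effect_allele"] != frame["other_allele"])
        & (frame["pos"] >= 1)
        & (frame["pval"] > 0)
        & (frame["pval"] <= 1)
        & frame["beta"].notna()
        & (frame["n"] > 0)
    )


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[GwasRecord]:
    """Read a summary-statistics TSV into records, dropping invalid rows.

    Parameters
    ----------
    path
        Tab-separated file with a header line.
    column_map
        Optional mapping from the file's header names to canonical names,
        e.g. ``{"SNP": "snp_id", "P": "pval"}`` for nonstandard exports.

    Rows violating the :class:`GwasRecord` invariants are dropped and the
    count is logged; row order is otherwise preserved.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", dtype={0: str})
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty") from None
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    missing = [c for c in CANONICAL_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(
            f"{path}: missing mandatory column(s) {missing}; "
            f"required columns are {list(CANONICAL_COLUMNS)}"
        )
    if len(raw) == 0:
        raise FormatError(f"{path}: no data rows")
    frame = raw.loc[:, list(CANONICAL_COLUMNS)].copy()
    frame["snp_id"] = frame["snp_id"].astype(str)
    frame["chrom"] = frame["chrom"].astype(str)
    for col in ("eaf", "beta", "se", "pval", "n"):
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
    frame["pos"] = pd.to_numeric(frame["pos"], errors="coerce")
    keep = _validity_mask(frame) & frame["pos"].notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%s: dropped %d row(s) violating record invariants", path, n_dropped)
    frame = frame.loc[keep]
    frame["pos"] = frame["pos"].astype(int)
    return frame_to_records(frame)


def write_summary_stats(records, path: str | Path) -> Path:
    """Write records to ``path`` in the canonical TSV dialect.

    Floats are written at full ``repr`` precision so that a read/write
    round trip is the identity on valid records.
    """
    frame = as_frame(records)
    if len(frame) == 0:
        raise DataError("refusing to write an empty summary-statistics table")
    path = Path(path)
    # default float repr is the shortest exact round-trip representation
    frame.to_csv(path, sep="\t", index=False)
    return path


def write_report(results: Sequence, path: str | Path, kind: str = "mr") -> Path:
    """Write a homogeneous collection of results as a report TSV.

    ``MREstimate`` collections produce the columns
    ``Exposure  Outcome  nSNP  Beta  LCI  UCI  p`` and ``MediationResult``
    collections produce ``Exposure  Mediate  Outcome  OR  LCI  UCI  p``,
    mirroring the layout of published two-sample / two-step MR result
    tables.  ``kind`` ("mr" or "mediation") picks the header when
    ``results`` is empty (a header-only file is written).
    """
    # local imports: estimators/mediation import io types, avoid cycles
    from .estimators import MREstimate
    from .mediation import MediationResult

    path = Path(path)
    kinds = {type(r) for r in results}
    if len(kinds) > 1:
        raise UsageError(f"write_report requires a homogeneous result type, got {kinds}")
    if kinds == {MediationResult} or (not results and kind == "mediation"):
        kinds = {MediationResult}
    if kinds == {MREstimate} or (not results and kind == "mr"):
        rows = [
            {
                "Exposure": r.exposure,
                "Outcome": r.outcome,
                "nSNP": r.n_snp,
                "Beta": r.beta,
                "LCI": r.lci,
                "UCI": r.uci,
                "p": r.pval,
            }
            for r in results
        ]
        frame = pd.DataFrame(rows, columns=["Exposure", "Outcome", "nSNP", "Beta", "LCI", "UCI", "p"])
    elif kinds == {MediationResult}:
        rows = [
            {
                "Exposure": r.exposure,
                "Mediate": r.mediator,
                "Outcome": r.outcome,
                "OR": r.or_point,
                "LCI": r.or_lci,
                "UCI": r.or_uci,
                "p": r.indirect_pval,
            }
            for r in results
        ]
        frame = pd.DataFrame(rows, columns=["Exposure", "Mediate", "Outcome", "OR", "LCI", "UCI", "p"])
    else:
        raise UsageError(f"unsupported result type(s) {kinds}")
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path
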