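"""Harmonization of exposure and outcome effects onto one effect allele.

Two GWAS rarely report the same variant with the same allele coding.  For
every SNP shared between the exposure and outcome tables this module
rewrites the outcome effect so that it refers to the exposure's effect
allele:

* same alleles, same roles           -> keep as-is;
* same alleles, roles swapped        -> negate beta, complement EAF;
* alleles match after strand
  complement (A<->T, C<->G)          -> complement, then the above;
* palindromic pair (A/T or G/C) with
  EAF near 0.5 on either side        -> dropped (strand unresolvable);
* palindromic, EAF away from 0.5     -> orientation inferred from EAF
                                        agreement between the two studies;
* anything else                      -> dropped as an allele mismatch.

Strand complementing applies to single-base alleles only; indels and
multi-base alleles are compared literally.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DataError
from .io import as_frame

DEFAULT_PALINDROMIC_EAF_WINDOW = 0.08

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _complement(alleles: np.ndarray) -> np.ndarray:
    return np.array([_COMPLEMENT.get(a, a) if len(a) == 1 else a for a in alleles], dtype=object)


@dataclass
class HarmonizedSet:
    """Aligned per-SNP exposure and outcome effects on one effect allele."""

    exposure_name: str
    outcome_name: str
    snp_ids: np.ndarray
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    n_dropped_palindromic: int = 0
    n_dropped_mismatch: int = 0

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    def without(self, index: int) -> "HarmonizedSet":
        """A copy omitting the SNP at ``index`` (for leave-one-out)."""
        keep = np.ones(self.n_snp, dtype=bool)
        keep[index] = False
        return replace(
            self,
            snp_ids=self.snp_ids[keep],
            beta_exp=self.beta_exp[keep],
            se_exp=self.se_exp[keep],
            beta_out=self.beta_out[keep],
            se_out=self.se_out[keep],
        )


def harmonize(
    exposure_records,
    outcome_records,
    palindromic_eaf_window: float = DEFAULT_PALINDROMIC_EAF_WINDOW,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect allele per shared SNP.

    Returns vectors ordered by ``snp_id``.  Raises
    :class:`~mrmediate.errors.DataError` when no SNPs are shared or none
    survive harmonization.
    """
    e = as_frame(exposure_records)
    o = as_frame(outcome_records)
    merged = e.merge(o, on="snp_id", suffixes=("_e", "_o"), how="inner")
    if len(merged) == 0:
        raise DataError(
            f"harmonize({exposure_name}, {outcome_name}): no shared SNPs between the two tables"
        )
    merged = merged.sort_values("snp_id", kind="mergesort").reset_index(drop=True)

    up = lambda s: np.array([str(a).upper() for a in s], dtype=object)
    ea_e, oa_e = up(merged["effect_allele_e"]), up(merged["other_allele_e"])
    ea_o, oa_o = up(merged["effect_allele_o"]), up(merged["other_allele_o"])
    cea_o, coa_o = _complement(ea_o), _complement(oa_o)
    eaf_e = merged["eaf_e"].to_numpy(float)
    eaf_o = merged["eaf_o"].to_numpy(float)
    beta_out = merged["beta_o"].to_numpy(float).copy()

    palindromic = (ea_e == _complement(oa_e)) & (ea_e != oa_e)

    direct = (ea_o == ea_e) & (oa_o == oa_e)
    swapped = (ea_o == oa_e) & (oa_o == ea_e)
    comp_direct = (cea_o == ea_e) & (coa_o == oa_e)
    comp_swapped = (cea_o == oa_e) & (coa_o == ea_e)
    reconcilable = direct | swapped | comp_direct | comp_swapped

    near_half = (np.abs(eaf_e - 0.5) < palindromic_eaf_window) | (
        np.abs(eaf_o - 0.5) < palindromic_eaf_window
    )
    drop_pal = palindromic & reconcilable & near_half
    drop_mismatch = ~reconcilable
    keep = ~(drop_pal | drop_mismatch)

    # For palindromic pairs the allele comparison cannot separate "same
    # strand" from "flipped": infer the orientation from EAF agreement.
    flip = np.where(
        palindromic,
        (eaf_e - 0.5) * (eaf_o - 0.5) < 0,
        swapped | comp_swapped,
    )
    beta_out[flip] = -beta_out[flip]

    n_pal = int(drop_pal.sum())
    n_mis = int(drop_mismatch.sum())
    if not keep.any():
        raise DataError(
            f"harmonize({exposure_name}, {outcome_name}): no SNPs survive harmonization "
            f"({n_pal} dropped as ambiguous palindromic, {n_mis} as allele mismatches)"
        )
    return HarmonizedSet(
        exposure_name=exposure_name,
        outcome_name=outcome_name,
        snp_ids=merged["snp_id"].to_numpy(object)[keep],
        beta_exp=merged["beta_e"].to_numpy(float)[keep],
        se_exp=merged["se_e"].to_numpy(float)[keep],
        beta_out=beta_out[keep],
        se_out=merged["se_o"].to_numpy(float)[keep],
        n_dropped_palindromic=n_pal,
        n_dropped_mismatch=n_mis,
    )
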