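"""Bundled reference tables: published IVW estimates for the air-pollution /
obesity / COVID-19 causal chain.

A published large-scale genetic-correlation study estimated, by two-sample
MR on public GWAS summary statistics, the effects of three air pollutants
(PM2.5, NO2, NOx) on nine obesity-related traits (ASAT, BMI, HC, OB1-3,
VAT, WC, WHR), of the pollutants on three COVID-19 phenotypes
(Susceptibility, Hospitalization, Severity), and of the obesity traits on
the COVID-19 phenotypes, then combined them by two-step MR mediation.  Its
printed IVW tables (beta, 95% CI, p per pair) and the table of significant
indirect effects (OR, 95% CI, p per triple) are bundled here as TSVs.

They serve as a worked example and as a fixed oracle: applying this
package's product-of-coefficients mediation to the printed step-one and
step-two estimates must reproduce the printed indirect-effect table.

Only betas, CI bounds and p-values are printed, so standard errors are
recovered two ways and both are exposed:

* ``se_from_ci`` — CI width / 3.92 (two normal 97.5% quantiles);
* ``se_from_p``  — |beta| / z(p), the normal quantile of the printed
  p-value, which preserves more significant figures than the 2-figure CI
  bounds and is therefore the default for significance classification.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .estimators import MREstimate
from .mediation import MediationResult, mediation_from_estimates

POLLUTANTS = ("PM2.5", "NO2", "NOx")
OBESITY_TRAITS = ("ASAT", "BMI", "HC", "OB1", "OB2", "OB3", "VAT", "WC", "WHR")
COVID_PHENOTYPES = ("Susceptibility", "Hospitalization", "Severity")


def _load(name: str) -> pd.DataFrame:
    with resources.files("mrmediate.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def _with_se(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    frame["se_from_ci"] = (frame["uci"] - frame["lci"]) / 3.92
    frame["se_from_p"] = frame["beta"].abs() / stats.norm.isf(frame["pval"] / 2.0)
    return frame


def load_pollution_obesity_ivw() -> pd.DataFrame:
    """Step-one reference estimates: air pollutant -> obesity trait (27 rows)."""
    return _with_se(_load("air_pollution_obesity_ivw.tsv"))


def load_pollution_covid_ivw() -> pd.DataFrame:
    """Total-effect reference estimates: air pollutant -> COVID-19 phenotype (9 rows)."""
    return _with_se(_load("air_pollution_covid_ivw.tsv"))


def load_obesity_covid_ivw() -> pd.DataFrame:
    """Step-two reference estimates: obesity trait -> COVID-19 phenotype (27 rows)."""
    return _with_se(_load("obesity_covid_ivw.tsv"))


def load_reference_mediation() -> pd.DataFrame:
    """Published significant indirect effects (OR scale, 29 rows).

    The odds-ratio column is exposed as ``or_point`` (``or`` is a Python
    keyword and would be mangled by DataFrame accessors).
    """
    return _load("air_pollution_covid_mediation.tsv").rename(columns={"or": "or_point"})


def _row(frame: pd.DataFrame, **keys) -> pd.Series:
    mask = np.ones(len(frame), dtype=bool)
    for col, val in keys.items():
        mask &= frame[col] == val
    hit = frame.loc[mask]
    if len(hit) != 1:
        raise DataError(f"expected exactly one reference row for {keys}, found {len(hit)}")
    return hit.iloc[0]


def _as_estimate(row: pd.Series, se_mode: str) -> MREstimate:
    se = float(row["se_from_ci"] if se_mode == "ci" else row["se_from_p"])
    return MREstimate(
        method="ivw_random",
        beta=float(row["beta"]),
        se=se,
        lci=float(row["lci"]),
        uci=float(row["uci"]),
        pval=float(row["pval"]),
        n_snp=int(row["n_snp"]),
        exposure=str(row["exposure"]),
        outcome=str(row["outcome"]),
    )


def reference_mediation_grid(se_mode: str = "p", alpha: float = 0.05) -> list[MediationResult]:
    """Two-step mediation over every (pollutant, obesity trait, COVID
    phenotype) triple buildable from the reference IVW tables (81 triples).

    ``se_mode`` chooses how step SEs are recovered from the printed tables:
    ``"p"`` (default) from the printed p-values, ``"ci"`` from the printed
    CI widths.
    """
    if se_mode not in ("p", "ci"):
        raise ValueError(f"unknown se_mode {se_mode!r}")
    step1 = load_pollution_obesity_ivw()
    step2 = load_obesity_covid_ivw()
    total = load_pollution_covid_ivw()
    results = []
    for pollutant in POLLUTANTS:
        for trait in OBESITY_TRAITS:
            for phenotype in COVID_PHENOTYPES:
                est0 = _as_estimate(_row(total, exposure=pollutant, outcome=phenotype), se_mode)
                est1 = _as_estimate(_row(step1, exposure=pollutant, outcome=trait), se_mode)
                est2 = _as_estimate(_row(step2, exposure=trait, outcome=phenotype), se_mode)
                results.append(mediation_from_estimates(est0, est1, est2, alpha=alpha))
    return results
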