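"""Configuration-driven orchestration of the three-arm analysis.

Given trait tables in three roles — exposures, mediators, outcomes — the
pipeline runs, for every (exposure, mediator), (exposure, outcome) and
(mediator, outcome) pair, the full estimator battery (random-effects IVW,
MR-Egger, weighted median, Cochran's Q, Egger intercept, leave-one-out),
and for every complete triple the two-step mediation.  It writes five
report TSVs plus a plain-text run log:

* ``exposure_mediator_ivw.tsv``, ``exposure_outcome_ivw.tsv``,
  ``mediator_outcome_ivw.tsv`` — IVW rows, one per pair;
* ``mediation.tsv`` — one row per triple (OR scale);
* ``sensitivity.tsv`` — Egger slope/intercept, weighted median, Q, and
  leave-one-out influence flags per pair;
* ``run.log`` — seeds, thresholds, and SNP counts at each filtering stage.

Failures of a single pair are logged and skipped; only configuration
errors abort the run.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigError, MrError
from .estimators import egger, ivw, leave_one_out, weighted_median
from .harmonize import harmonize
from .instruments import PairwiseLD, select_instruments
from .io import read_summary_stats, records_to_frame, write_report
from .mediation import MediationResult, MrSettings, run_two_step

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class AnalysisConfig:
    """Trait files by role plus analysis settings."""

    exposures: dict[str, str]
    mediators: dict[str, str]
    outcomes: dict[str, str]
    output_dir: str
    ld: str | None = None
    settings: MrSettings = field(default_factory=MrSettings)

    def validate(self) -> None:
        for role in ("exposures", "mediators", "outcomes"):
            traits = getattr(self, role)
            if not traits:
                raise ConfigError(f"config: at least one trait is required in role {role!r}")
            for name, path in traits.items():
                if not Path(path).exists():
                    raise ConfigError(f"config: {role}[{name!r}] file not found: {path}")
        if self.ld is not None and not Path(self.ld).exists():
            raise ConfigError(f"config: LD file not found: {self.ld}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        version = raw.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ConfigError(
                f"{path}: unsupported schema_version {version!r} (expected {SCHEMA_VERSION})"
            )
        traits = raw.get("traits", {})
        known = {f.name for f in dataclasses.fields(MrSettings)}
        unknown = set(raw.get("settings", {})) - known
        if unknown:
            raise ConfigError(f"{path}: unknown settings {sorted(unknown)}")
        settings = MrSettings(**raw.get("settings", {}))
        try:
            return cls(
                exposures=dict(traits["exposures"]),
                mediators=dict(traits["mediators"]),
                outcomes=dict(traits["outcomes"]),
                output_dir=str(raw["output_dir"]),
                ld=raw.get("ld"),
                settings=settings,
            )
        except KeyError as exc:
            raise ConfigError(f"{path}: missing required config key {exc}") from None


def _battery(exposure_name, exposure_records, outcome_name, outcome_records, settings, ld):
    """Instrument selection + harmonization + all estimators for one pair."""
    iset = select_instruments(
        exposure_records,
        exposure_name=exposure_name,
        ld_matrix=ld,
        p_threshold=settings.p_threshold,
        clump_r2=settings.clump_r2,
        clump_window_bp=settings.clump_window_bp,
        f_min=settings.f_min,
    )
    h = harmonize(
        records_to_frame(iset.records),
        outcome_records,
        palindromic_eaf_window=settings.palindromic_eaf_window,
        exposure_name=exposure_name,
        outcome_name=outcome_name,
    )
    est = ivw(h, effects_model=settings.effects_model)
    sens: dict = {
        "Exposure": exposure_name,
        "Outcome": outcome_name,
        "nSNP": h.n_snp,
        "F_stat": iset.f_stat,
        "Q": est.q_stat,
        "Q_df": est.q_df,
        "Q_p": est.q_pval,
    }
    if h.n_snp >= 3:
        e = egger(h)
        wm = weighted_median(h, n_boot=settings.n_boot, seed=settings.seed)
        loo = leave_one_out(h)
        sens.update(
            Egger_beta=e.beta,
            Egger_p=e.pval,
            Egger_intercept=e.egger_intercept,
            Egger_intercept_p=e.egger_intercept_pval,
            WM_beta=wm.beta,
            WM_p=wm.pval,
            LOO_influential=sum(entry.influential for entry in loo),
        )
    return est, sens, iset, h


def run_all(config: AnalysisConfig) -> dict[str, Path]:
    """Run the full three-arm design; returns the written report paths."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    settings = config.settings

    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("mrmediate")
    root.addHandler(handler)
    old_level = root.level
    root.setLevel(logging.INFO)

    try:
        logger.info("settings: %s", settings)
        tables = {
            role: {name: read_summary_stats(path) for name, path in getattr(config, role).items()}
            for role in ("exposures", "mediators", "outcomes")
        }
        for role, loaded in tables.items():
            for name, recs in loaded.items():
                logger.info("loaded %s %s: %d records", role, name, len(recs))
        ld = PairwiseLD.from_pairs_tsv(config.ld) if config.ld else None

        arms = {
            "exposure_mediator": ("exposures", "mediators"),
            "exposure_outcome": ("exposures", "outcomes"),
            "mediator_outcome": ("mediators", "outcomes"),
        }
        estimates: dict[str, dict] = {name: {} for name in arms}
        sensitivity_rows = []
        for arm_name, (role_a, role_b) in arms.items():
            for name_a, recs_a in tables[role_a].items():
                for name_b, recs_b in tables[role_b].items():
                    try:
                        est, sens, iset, h = _battery(name_a, recs_a, name_b, recs_b, settings, ld)
                    except MrError as exc:
                        logger.warning("skipping %s %s->%s: %s", arm_name, name_a, name_b, exc)
                        continue
                    logger.info(
                        "%s %s->%s: %d instruments (F=%.1f), %d harmonized "
                        "(%d palindromic, %d mismatch dropped), IVW beta=%.4g p=%.3g",
                        arm_name, name_a, name_b, len(iset.records), iset.f_stat, h.n_snp,
                        h.n_dropped_palindromic, h.n_dropped_mismatch, est.beta, est.pval,
                    )
                    estimates[arm_name][(name_a, name_b)] = est
                    sensitivity_rows.append(sens)

        mediation_results: list[MediationResult] = []
        for exp_name, exp_recs in tables["exposures"].items():
            for med_name, med_recs in tables["mediators"].items():
                for out_name, out_recs in tables["outcomes"].items():
                    needed = [
                        (exp_name, med_name) in estimates["exposure_mediator"],
                        (exp_name, out_name) in estimates["exposure_outcome"],
                        (med_name, out_name) in estimates["mediator_outcome"],
                    ]
                    if not all(needed):
                        logger.warning(
                            "skipping mediation %s->%s->%s: missing arm estimate",
                            exp_name, med_name, out_name,
                        )
                        continue
                    try:
                        res = run_two_step(
                            records_to_frame(exp_recs),
                            records_to_frame(med_recs),
                            records_to_frame(out_recs),
                            settings=settings,
                            ld=ld,
                            names=(exp_name, med_name, out_name),
                        )
                    except MrError as exc:
                        logger.warning(
                            "skipping mediation %s->%s->%s: %s", exp_name, med_name, out_name, exc
                        )
                        continue
                    logger.info(
                        "mediation %s->%s->%s: indirect OR=%.4g p=%.3g case=%s",
                        exp_name, med_name, out_name, res.or_point, res.indirect_pval, res.case,
                    )
                    mediation_results.append(res)

        paths: dict[str, Path] = {}
        for arm_name in arms:
            paths[arm_name] = write_report(
                list(estimates[arm_name].values()), out_dir / f"{arm_name}_ivw.tsv"
            )
        paths["mediation"] = write_report(
            mediation_results, out_dir / "mediation.tsv", kind="mediation"
        )
        sens_frame = pd.DataFrame(sensitivity_rows)
        sens_path = out_dir / "sensitivity.tsv"
        sens_frame.to_csv(sens_path, sep="\t", index=False, float_format="%.6g")
        paths["sensitivity"] = sens_path
        paths["log"] = log_path
        return paths
    finally:
        root.removeHandler(handler)
        root.setLevel(old_level)
        handler.close()
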