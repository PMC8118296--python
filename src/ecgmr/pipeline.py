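"""End-to-end orchestration of the ECG-score MR analysis sequence.

One :func:`run_pipeline` call takes a scenario-driven configuration and
produces, per ECG score, the publication-style outputs: score–ECG
association, quintile table with floated CIs, per-5 ms logistic estimates
for the AF / lone-AF / SVT analogues, ion-channel-subset estimates, the
full summary-data sensitivity table, a fixed-effects meta-analysis of the
individual-level and summary-data estimates, a bidirectional table, and
the instrument-strength report. Every table is tab-separated with a
schema-version header, the resolved configuration and seed are written
alongside, and each operation call is recorded in the run log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import cohort_assoc, instruments, scores, simulate, summary_mr
from .cohort_assoc import AssocResult
from .summary_mr import MREstimate

logger = logging.getLogger(__name__)

SCHEMA_HEADER = "# ecgmr table schema v1"

ION_CHANNEL_GENES = ["SCN5A", "SCN10A", "KCNQ1", "KCNJ2"]

_SCENARIOS = {
    "pwave": simulate.p_wave_scenario,
    "pr": simulate.pr_interval_scenario,
    "qt": simulate.qt_interval_scenario,
}

#: lone AF (4,805) and non-AF SVT (2,884) case counts among 278,792
SECONDARY_PREVALENCE = {"lone_af": 4_805 / 278_792, "svt": 2_884 / 278_792}


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run; fully YAML-serialisable."""

    scenarios: list[str] = field(default_factory=lambda: ["pr"])
    n_individuals: int = 20_000
    seed: int = 0
    outdir: str = "ecgmr_results"
    n_boot: int = 500
    n_sim: int = 1000
    or_alt: float = 1.15
    alpha: float = 0.05
    reverse_or_per_5ms: float = 1.0  # AF-liability -> ECG reverse effect

    def __post_init__(self) -> None:
        unknown = set(self.scenarios) - set(_SCENARIOS)
        if unknown:
            raise ValueError(f"unknown scenarios: {sorted(unknown)}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _write_table(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(SCHEMA_HEADER + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    """Read a pipeline output table, skipping the schema header."""
    return pd.read_csv(path, sep="\t", comment="#")


def _assoc_row(label: str, res: AssocResult) -> dict:
    row = {
        "analysis": label,
        "beta": res.beta,
        "se": res.se,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "p": res.p,
        "n": res.n,
        "scale": res.scale,
        "flag": res.significance_flag,
    }
    if res.family == "logistic":
        row["or"] = res.odds_ratio
        row["or_ci_low"], row["or_ci_high"] = res.or_ci
    return row


def _mr_row(res: MREstimate) -> dict:
    flag = "significant" if res.p < 0.01 else ("suggestive" if res.p < 0.05 else "ns")
    return {
        "method": res.method,
        "beta": res.beta,
        "se": res.se,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "or": res.odds_ratio,
        "p": res.p,
        "n_variants": res.n_variants,
        "scale": res.scale,
        "q": res.q_statistic,
        "q_df": res.q_df,
        "flag": flag,
    }


def _assoc_to_mr(res: AssocResult, method: str) -> MREstimate:
    """Bridge an individual-level logistic estimate onto the MR scale for pooling."""
    return MREstimate(
        method=method,
        beta=res.beta,
        se=res.se,
        ci_low=res.ci_low,
        ci_high=res.ci_high,
        p=res.p,
        n_variants=0,
        scale=res.scale,
    )


def _annotate_ion_channels(records):
    """Tag ~one third of variants with ion-channel gene symbols (synthetic)."""
    out = []
    for j, rec in enumerate(records):
        if j % 3 == 0:
            gene = ION_CHANNEL_GENES[(j // 3) % len(ION_CHANNEL_GENES)]
            out.append(replace(rec, gene_annotation=gene))
        else:
            out.append(replace(rec, gene_annotation=f"GENE{j:03d}"))
    return out


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the full analysis sequence; returns a name → path map of outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_log = outdir / "run.log"
    handler = logging.FileHandler(run_log, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("ecgmr")
    root.addHandler(handler)
    old_level = root.level
    root.setLevel(logging.INFO)
    outputs: dict[str, Path] = {"run_log": run_log}
    try:
        config.to_yaml(outdir / "resolved_config.yaml")
        outputs["resolved_config"] = outdir / "resolved_config.yaml"
        for name in config.scenarios:
            outputs.update(_run_scenario(name, config, outdir))
    except Exception:
        logger.exception("pipeline aborted")
        raise
    finally:
        root.removeHandler(handler)
        root.setLevel(old_level)
        handler.close()
    return outputs


def _run_scenario(name: str, config: PipelineConfig, outdir: Path) -> dict[str, Path]:
    logger.info("stage=simulate scenario=%s n=%d seed=%d", name, config.n_individuals, config.seed)
    sim_config = _SCENARIOS[name](n_individuals=config.n_individuals, seed=config.seed)
    cohort = simulate.simulate_cohort(sim_config)
    cohort.variants = _annotate_ion_channels(cohort.variants)
    weights = {v.id: v.beta_exposure for v in cohort.variants}

    logger.info("stage=build_score scenario=%s n_variants=%d", name, len(weights))
    score = scores.build_score(cohort.genotypes, weights, cohort.variant_ids)
    out: dict[str, Path] = {}

    # score -> measured ECG interval (Fig 1 analogue)
    logger.info("stage=linear_assoc scenario=%s outcome=ecg_interval", name)
    lin = cohort_assoc.linear_assoc(score, cohort.exposure, cohort.covariates,
                                    outcome_label="ecg_interval")
    assoc_rows = [_assoc_row("score_on_ecg_interval", lin)]

    # primary per-5 ms logistic estimate and secondary-outcome analogues (Fig 3)
    logger.info("stage=logistic_assoc scenario=%s outcome=af", name)
    logit_ms = cohort_assoc.logistic_assoc(score, cohort.outcome, cohort.covariates,
                                           outcome_label="af")
    logit_5ms = cohort_assoc.scale_per_5ms(logit_ms)
    assoc_rows.append(_assoc_row("score_on_af_per5ms", logit_5ms))
    for offset, (label, prev) in enumerate(SECONDARY_PREVALENCE.items(), start=101):
        logger.info("stage=logistic_assoc scenario=%s outcome=%s", name, label)
        sec_cfg = replace(sim_config, baseline_prevalence=prev, seed=sim_config.seed + offset)
        y_sec = simulate.simulate_outcome(cohort.exposure, cohort.genotypes, sec_cfg,
                                          confounder=cohort.confounder)
        try:
            sec = cohort_assoc.logistic_assoc(score, y_sec, cohort.covariates, outcome_label=label)
            assoc_rows.append(_assoc_row(f"score_on_{label}_per5ms", cohort_assoc.scale_per_5ms(sec)))
        except (ValueError, RuntimeError) as exc:
            logger.warning("stage=logistic_assoc outcome=%s failed: %s (partial output)", label, exc)

    # ion-channel-subset estimate
    logger.info("stage=ion_channel_subset scenario=%s", name)
    channel_variants = instruments.ion_channel_subset(cohort.variants, ION_CHANNEL_GENES)
    if len(channel_variants) >= 2:
        ch_weights = {v.id: v.beta_exposure for v in channel_variants}
        ch_score = scores.build_score(cohort.genotypes, ch_weights, cohort.variant_ids)
        ch = cohort_assoc.logistic_assoc(ch_score, cohort.outcome, cohort.covariates,
                                         outcome_label="af")
        assoc_rows.append(_assoc_row("ion_channel_score_on_af_per5ms",
                                     cohort_assoc.scale_per_5ms(ch)))
    path = outdir / f"{name}_associations.tsv"
    _write_table(pd.DataFrame(assoc_rows), path)
    out[f"{name}_associations"] = path

    # quintile contrasts with floated variances (Fig 2 analogue)
    logger.info("stage=quintile_contrasts scenario=%s", name)
    groups, max_err = cohort_assoc.quintile_contrasts(score, cohort.outcome, cohort.covariates)
    qrows = []
    for g in groups:
        lo, hi = g.ci
        qrows.append({
            "quintile": g.group,
            "log_or": g.log_or,
            "or": float(np.exp(g.log_or)),
            "floated_variance": g.floated_variance,
            "ci_low_or": float(np.exp(lo)),
            "ci_high_or": float(np.exp(hi)),
            "max_contrast_rel_error": max_err,
        })
    path = outdir / f"{name}_quintiles.tsv"
    _write_table(pd.DataFrame(qrows), path)
    out[f"{name}_quintiles"] = path

    # two-sample summary-data sensitivity suite (Table J analogue)
    logger.info("stage=make_summary_pair scenario=%s", name)
    pairs = simulate.make_summary_pair(cohort, split_fraction=0.5, seed=config.seed + 29)
    mr_rows = []
    ivw_fixed = summary_mr.ivw(pairs, "fixed")
    mr_rows.append(_mr_row(ivw_fixed))
    mr_rows.append(_mr_row(summary_mr.ivw(pairs, "random")))
    mr_rows.append(_mr_row(summary_mr.weighted_median(pairs, n_boot=config.n_boot,
                                                      seed=config.seed + 31)))
    mr_rows.append(_mr_row(summary_mr.weighted_mode(pairs, n_boot=config.n_boot,
                                                    seed=config.seed + 37)))
    slope, intercept = summary_mr.mr_egger(pairs)
    mr_rows.append(_mr_row(slope))
    mr_rows.append(_mr_row(intercept))
    logger.info("stage=mr_presso scenario=%s n_sim=%d", name, config.n_sim)
    presso = summary_mr.mr_presso(pairs, n_sim=config.n_sim, seed=config.seed + 41)
    presso_row = _mr_row(presso.corrected if presso.corrected is not None else presso.original)
    presso_row["method"] = "presso_corrected" if presso.corrected is not None else "presso_no_outliers"
    presso_row["presso_global_p"] = presso.global_p
    presso_row["presso_n_outliers"] = int(presso.outlier_flags.sum())
    mr_rows.append(presso_row)
    path = outdir / f"{name}_sensitivity.tsv"
    _write_table(pd.DataFrame(mr_rows), path)
    out[f"{name}_sensitivity"] = path

    # funnel-plot coordinates (Figs E–G analogue)
    funnel = summary_mr.funnel_table(pairs)
    path = outdir / f"{name}_funnel.tsv"
    _write_table(pd.DataFrame(funnel), path)
    out[f"{name}_funnel"] = path

    # fixed-effects meta-analysis of cohort and summary-data estimates (Fig 4)
    logger.info("stage=meta_fixed scenario=%s", name)
    meta = summary_mr.meta_fixed([_assoc_to_mr(logit_ms, "cohort_logistic"), ivw_fixed])
    path = outdir / f"{name}_meta.tsv"
    _write_table(pd.DataFrame([_mr_row(meta)]), path)
    out[f"{name}_meta"] = path

    # bidirectional analysis (Table I analogue): AF liability -> ECG interval
    logger.info("stage=bidirectional scenario=%s", name)
    reverse_pairs = simulate.simulate_summary_pairs(
        n_variants=20,
        causal_beta=np.log(config.reverse_or_per_5ms) / 5.0,
        seed=config.seed + 43,
        mean_beta_x=0.1,
        sd_beta_x=0.03,
        se_x=0.005,
        se_y=0.05,
    )
    reverse = summary_mr.bidirectional_mr(reverse_pairs, forward_estimate=ivw_fixed)
    rev_row = _mr_row(reverse)
    rev_row["reverse_to_forward_ratio"] = reverse.notes.get("reverse_to_forward_ratio")
    path = outdir / f"{name}_bidirectional.tsv"
    _write_table(pd.DataFrame([rev_row]), path)
    out[f"{name}_bidirectional"] = path

    # instrument-strength report (Table F analogue)
    logger.info("stage=strength_report scenario=%s", name)
    report = scores.strength_report(
        score, cohort.exposure, n=cohort.n,
        case_fraction=float(cohort.outcome.mean()),
        or_alt=config.or_alt, alpha=config.alpha,
    )
    path = outdir / f"{name}_strength.tsv"
    _write_table(pd.DataFrame([{
        "r2": report.r2, "f_stat": report.f_stat, "power": report.power,
        "alpha": report.alpha, "n": report.n, "case_fraction": report.case_fraction,
        "or_alt": report.or_alt,
    }]), path)
    out[f"{name}_strength"] = path
    (outdir / f"{name}_strength.txt").write_text(report.to_text() + "\n")
    return out
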