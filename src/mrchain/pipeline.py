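"""Orchestration of the four-step MR mediation design.

Step 1 — each exposure against the outcome (genome-wide instrument
thresholds); Step 2 — each mediator against the outcome (suggestive
thresholds) plus a reverse-direction MR check for screened mediators;
Step 3 — screened exposures against screened mediators; Step 4 — two-step
mediation on the triples in which all three links are significant.

Runs are fully reproducible: every stochastic component receives a sub-seed
derived deterministically from the master seed and the pair labels, so adding
a pair never perturbs the others.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimators import MrResult, ivw, run_all
from .mediation import mediation_screen, two_step_mediation
from .sensitivity import sensitivity_report
from .sumstats import (
    DropRecord,
    GwasTable,
    LdMatrix,
    clump,
    drop_log_frame,
    filter_weak_instruments,
    harmonize,
    read_gwas_table,
    select_instruments,
    steiger_filter,
)
from .synthetic import ChainSimConfig, merge_studies, simulate_battery

__all__ = ["LayerParams", "StudyConfig", "StudyReport", "run_study", "derive_seed"]


def derive_seed(master_seed: int, *labels: str) -> int:
    """Deterministic sub-seed from the master seed and a label path."""
    key = f"{master_seed}|" + "|".join(labels)
    return int(hashlib.sha256(key.encode()).hexdigest()[:8], 16) % (2**31)


@dataclass
class LayerParams:
    """Instrument-selection thresholds for one analysis layer."""

    p_threshold: float = 5e-8
    clump_r2: float = 0.1
    clump_window_kb: float = 10_000.0


@dataclass
class StudyConfig:
    """Everything needed to reproduce one study run.

    Inputs are either simulation configs (``simulation``) or file paths
    (``exposure_paths`` / ``mediator_paths`` / ``outcome_path``). Layer
    defaults follow the emulated design: genome-wide thresholds with lenient
    clumping (p < 5e-8, r² < 0.1) for the eQTL exposure layer and suggestive
    thresholds with strict clumping (p < 5e-6, r² < 0.001) for the abundance
    mediator layer, both with a 10,000 kb window.
    """

    simulation: list[ChainSimConfig] | None = None
    exposure_paths: list[str] = field(default_factory=list)
    mediator_paths: list[str] = field(default_factory=list)
    outcome_path: str | None = None
    ld_path: str | None = None
    dialect: dict[str, str] | None = None
    exposure_layer: LayerParams = field(default_factory=LayerParams)
    mediator_layer: LayerParams = field(
        default_factory=lambda: LayerParams(5e-6, 0.001, 10_000.0)
    )
    reverse_layer: LayerParams = field(
        default_factory=lambda: LayerParams(5e-8, 0.001, 10_000.0)
    )
    f_min: float = 10.0
    steiger: bool = True
    palindrome_band: float = 0.08
    alpha: float = 0.05
    multiple_testing: str = "none"  # none | bonferroni | bh
    n_boot: int = 1000
    presso_nsim: int = 1000
    run_sensitivity: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiple_testing not in ("none", "bonferroni", "bh"):
            raise ValueError(f"unknown multiple_testing {self.multiple_testing!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        kwargs = dict(raw)
        sims = kwargs.pop("simulation", None)
        if sims is not None:
            studies = sims.get("studies", sims) if isinstance(sims, dict) else sims
            if isinstance(studies, dict):
                studies = [studies]
            kwargs["simulation"] = [
                s if isinstance(s, ChainSimConfig) else ChainSimConfig(**_tuplify(s))
                for s in studies
            ]
        for name in ("exposure_layer", "mediator_layer", "reverse_layer"):
            if name in kwargs and isinstance(kwargs[name], dict):
                kwargs[name] = LayerParams(**kwargs[name])
        return cls(**kwargs)

    def echo(self) -> dict:
        d = asdict(self)
        return d


def _tuplify(d: dict) -> dict:
    d = dict(d)
    if "maf_range" in d and isinstance(d["maf_range"], list):
        d["maf_range"] = tuple(d["maf_range"])
    return d


@dataclass
class StudyReport:
    """Tables and provenance for one complete study run."""

    step1: pd.DataFrame
    step2: pd.DataFrame
    reverse: pd.DataFrame
    step3: pd.DataFrame
    mediation: pd.DataFrame
    drop_log: pd.DataFrame
    screening: dict
    aborted: list[dict]
    config_echo: dict
    seeds: dict
    sensitivity: dict = field(default_factory=dict)
    version: str = __version__

    def write(self, outdir) -> list[Path]:
        """Write the TSV/JSON bundle; returns the written paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, df in (
            ("step1_exposure_outcome", self.step1),
            ("step2_mediator_outcome", self.step2),
            ("step2_reverse_mr", self.reverse),
            ("step3_exposure_mediator", self.step3),
            ("step4_mediation", self.mediation),
            ("drop_log", self.drop_log),
        ):
            p = outdir / f"{name}.tsv"
            df.to_csv(p, sep="\t", index=False)
            written.append(p)
        summary = {
            "version": self.version,
            "config": self.config_echo,
            "seeds": self.seeds,
            "screening": self.screening,
            "aborted": self.aborted,
            "sensitivity": self.sensitivity,
        }
        p = outdir / "report.json"
        with open(p, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        written.append(p)
        return written


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _annotate(df: pd.DataFrame, alpha: float, mode: str) -> pd.DataFrame:
    """Multiple-testing annotation on the primary (IVW) rows of a step table."""
    if df.empty:
        return df
    ivw_mask = df["method"] == "ivw"
    n_tests = int(ivw_mask.sum())
    df = df.copy()
    df["n_tests"] = n_tests
    df["alpha"] = alpha
    df["expected_false_positives"] = n_tests * alpha
    if mode == "bonferroni":
        thr = alpha / n_tests if n_tests else alpha
        df["bonferroni_threshold"] = thr
        df["significant"] = (df["pval"] < thr) & ivw_mask
    elif mode == "bh":
        padj = np.full(len(df), np.nan)
        padj[ivw_mask.to_numpy()] = _bh_adjust(df.loc[ivw_mask, "pval"].to_numpy())
        df["p_bh"] = padj
        df["significant"] = df["p_bh"] < alpha
    else:
        df["significant"] = (df["pval"] < alpha) & ivw_mask
    return df


def _prepare_instruments(
    table: GwasTable,
    ld: LdMatrix | None,
    layer: LayerParams,
    f_min: float,
) -> GwasTable:
    """Selection → clumping → instrument-strength filter for one trait."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sel = select_instruments(table, layer.p_threshold)
        sel = clump(sel, ld, layer.clump_r2, layer.clump_window_kb)
    if layer.clump_r2 >= 0.1:
        # flagged: downstream estimators assume independent instruments
        sel.drop_log.append(
            DropRecord("*", "clump", f"lenient_r2_threshold_{layer.clump_r2}")
        )
    return filter_weak_instruments(sel, f_min)


def _one_pair(
    exposure: GwasTable,
    outcome: GwasTable,
    ld: LdMatrix | None,
    layer: LayerParams,
    config: StudyConfig,
    seed: int,
    with_sensitivity: bool,
):
    """Full QC + estimation for one exposure-outcome pair."""
    inst = _prepare_instruments(exposure, ld, layer, config.f_min)
    if len(inst) == 0:
        raise ValueError("no instruments survive selection/QC")
    hset = harmonize(inst, outcome, config.palindrome_band)
    if config.steiger:
        hset, _ = steiger_filter(hset)
        if hset.n_snp == 0:
            raise ValueError("no instruments survive Steiger filtering")
    results, skipped = run_all(hset, n_boot=config.n_boot, seed=seed)
    sens = None
    if with_sensitivity and hset.n_snp >= 2:
        sens = sensitivity_report(
            hset, results, n_sim=config.presso_nsim, seed=seed
        )
    drops = inst.drop_log + hset.drop_log
    return hset, results, skipped, sens, drops


def _resolve_inputs(config: StudyConfig):
    if config.simulation:
        studies = simulate_battery(config.simulation)
        exposures, mediators, outcome = merge_studies(studies)
        ld = studies[0].ld if len(studies) == 1 else None
        return exposures, mediators, outcome, ld
    if not config.exposure_paths or config.outcome_path is None:
        raise ValueError("config must provide simulation settings or input paths")
    exposures = [
        read_gwas_table(p, dialect=config.dialect, trait_id=Path(p).stem)
        for p in config.exposure_paths
    ]
    mediators = [
        read_gwas_table(p, dialect=config.dialect, trait_id=Path(p).stem)
        for p in config.mediator_paths
    ]
    # the outcome is binary when case counts are present, else quantitative
    probe = pd.read_csv(config.outcome_path, sep=None, engine="python", nrows=5)
    cols = dict(config.dialect or {})
    probe = probe.rename(columns=cols)
    binary = "N_CASES" in probe.columns and probe["N_CASES"].notna().any()
    outcome = read_gwas_table(
        config.outcome_path, dialect=config.dialect,
        trait_id=Path(config.outcome_path).stem,
        trait_type="binary" if binary else "quantitative",
    )
    ld = LdMatrix.from_square_file(config.ld_path) if config.ld_path else None
    return exposures, mediators, outcome, ld


def run_study(config: StudyConfig, outdir=None) -> StudyReport:
    """Execute the four-step design and return (optionally write) the report."""
    exposures, mediators, outcome, ld = _resolve_inputs(config)
    aborted: list[dict] = []
    drop_rows: list[pd.DataFrame] = []
    seeds: dict[str, int] = {}
    sens_summaries: dict[str, dict] = {}

    def record_drops(trait, stage_owner, drops):
        df = drop_log_frame(drops)
        if not df.empty:
            df.insert(0, "analysis", stage_owner)
            df.insert(1, "trait", trait)
            drop_rows.append(df)

    def run_layer(pairs, layer, label, with_sensitivity):
        """pairs: list of (exposure_table, outcome_table)."""
        rows = []
        primary: dict = {}
        for exp_t, out_t in pairs:
            pair_label = f"{label}:{exp_t.trait_id}->{out_t.trait_id}"
            seed = derive_seed(config.seed, pair_label)
            seeds[pair_label] = seed
            try:
                hset, results, skipped, sens, drops = _one_pair(
                    exp_t, out_t, ld, layer, config, seed, with_sensitivity
                )
            except ValueError as exc:
                aborted.append({"pair": pair_label, "error": str(exc)})
                continue
            record_drops(exp_t.trait_id, pair_label, drops)
            for res in results:
                rows.append(res.to_row())
                if res.method == "ivw":
                    primary[(exp_t.trait_id, out_t.trait_id)] = res
            for method, reason in skipped:
                rows.append(
                    {"exposure": exp_t.trait_id, "outcome": out_t.trait_id,
                     "method": method, "n_snp": hset.n_snp, "beta": np.nan,
                     "se": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                     "pval": np.nan, "or_": np.nan, "or_low": np.nan,
                     "or_high": np.nan, "skip_reason": reason}
                )
            if sens is not None:
                sens_summaries[pair_label] = sens.to_json_dict()
        return pd.DataFrame(rows), primary

    # Step 1: exposures -> outcome
    step1, exp_out = run_layer(
        [(e, outcome) for e in exposures],
        config.exposure_layer, "step1", config.run_sensitivity,
    )
    step1 = _annotate(step1, config.alpha, config.multiple_testing)

    # Step 2: mediators -> outcome
    step2, med_out = run_layer(
        [(m, outcome) for m in mediators],
        config.mediator_layer, "step2", config.run_sensitivity,
    )
    step2 = _annotate(step2, config.alpha, config.multiple_testing)

    # Reverse MR: outcome -> screened mediators (annotated, never excluded)
    screened_meds = [
        m for m in mediators
        if (m.trait_id, outcome.trait_id) in med_out
        and med_out[(m.trait_id, outcome.trait_id)].pval < config.alpha
    ]
    reverse, _ = run_layer(
        [(outcome, m) for m in screened_meds],
        config.reverse_layer, "reverse", False,
    )
    if not reverse.empty:
        reverse["reverse_significant"] = (
            (reverse["method"] == "ivw") & (reverse["pval"] < config.alpha)
        )

    # Step 3: screened exposures -> screened mediators
    screened_exps = [
        e for e in exposures
        if (e.trait_id, outcome.trait_id) in exp_out
        and exp_out[(e.trait_id, outcome.trait_id)].pval < config.alpha
    ]
    step3, exp_med = run_layer(
        [(e, m) for e in screened_exps for m in screened_meds],
        config.exposure_layer, "step3", False,
    )
    step3 = _annotate(step3, config.alpha, config.multiple_testing)

    # Step 4: mediation on qualifying triples
    eo = {e: r for (e, _o), r in exp_out.items()}
    mo = {m: r for (m, _o), r in med_out.items()}
    em = {(e, m): r for (e, m), r in exp_med.items()}
    triples = mediation_screen(eo, mo, em, alpha=config.alpha)
    med_rows = []
    for e, m in triples:
        res = two_step_mediation(total=eo[e], step1=em[(e, m)], step2=mo[m])
        med_rows.append(res.to_row())
    mediation_df = pd.DataFrame(
        med_rows,
        columns=[
            "exposure", "mediator", "outcome", "beta_total", "se_total",
            "beta1", "se1", "beta2", "se2", "indirect", "se_indirect",
            "ci_indirect_low", "ci_indirect_high", "p_indirect", "direct",
            "se_direct", "proportion", "se_proportion", "flags",
        ],
    )

    n_exp_tests = len(exposures)
    n_med_tests = len(mediators)
    screening = {
        "alpha": config.alpha,
        "multiple_testing": config.multiple_testing,
        "exposure_tests": n_exp_tests,
        "mediator_tests": n_med_tests,
        "expected_false_positive_exposures": n_exp_tests * config.alpha,
        "expected_false_positive_mediators": n_med_tests * config.alpha,
        "screened_exposures": sorted(e.trait_id for e in screened_exps),
        "screened_mediators": sorted(m.trait_id for m in screened_meds),
        "qualifying_triples": [list(t) for t in triples],
        "n_qualifying_triples": len(triples),
    }
    if config.multiple_testing == "bonferroni":
        screening["bonferroni_threshold_exposures"] = (
            config.alpha / n_exp_tests if n_exp_tests else config.alpha
        )
        screening["bonferroni_threshold_mediators"] = (
            config.alpha / n_med_tests if n_med_tests else config.alpha
        )

    drop_log = (
        pd.concat(drop_rows, ignore_index=True)
        if drop_rows
        else pd.DataFrame(columns=["analysis", "trait", "snp_id", "stage", "reason"])
    )
    report = StudyReport(
        step1=step1,
        step2=step2,
        reverse=reverse,
        step3=step3,
        mediation=mediation_df,
        drop_log=drop_log,
        screening=screening,
        aborted=aborted,
        config_echo=config.echo(),
        seeds=seeds,
        sensitivity=sens_summaries,
    )
    if outdir is not None:
        report.write(outdir)
    return report
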