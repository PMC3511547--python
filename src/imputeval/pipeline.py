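"""End-to-end orchestration: QC -> masking -> imputation channel (or external
results) -> per-SNP metrics -> panel filters -> report bundle.

The pipeline is a pure function of (configuration, input files): identical
seeds give byte-identical per-SNP tables.  External imputation software is
integrated only through a file-based adapter contract
(:class:`ImputerAdapter`): write the masked genotypes and reference, read the
posterior results back in any `core_io` format.  The built-in imputer is the
synthetic channel.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd
import yaml

from . import core_io, evaluation, panels, qc, synthetic
from .core_io import GenotypeMatrix, PosteriorMatrix
from .evaluation import (EvaluationSummary, MaskPlan, SnpMetrics,
                         build_mask_plans, concordance, contingency, iqs,
                         estimated_rsq, true_rsq, most_likely_genotype,
                         metrics_table, summarize)
from .panels import FilterResult, PanelSpec, post_impute_filter, rsq_threshold_filter
from .qc import QcReport, QcThresholds
from .synthetic import ScenarioResult, SimConfig, scenario_three_panels


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 1)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 2)."""

    def __init__(self, stage: str, code: str, message: str) -> None:
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


class ImputerAdapter(Protocol):
    """Contract for plugging in a real imputer: given the masked study
    genotypes and a reference panel, return posteriors covering (at least)
    the masked variants."""

    def __call__(self, masked: GenotypeMatrix, reference: PanelSpec) -> PosteriorMatrix:
        ...


# ---------------------------------------------------------------------------
# per-SNP metric builders
# ---------------------------------------------------------------------------

def masked_snp_metrics(
    truth: GenotypeMatrix, imputed: PosteriorMatrix, plan: MaskPlan
) -> list[SnpMetrics]:
    """Score each masked SNP: concordance, IQS and truth-based r2 across
    samples, with truth-derived MAF for binning."""
    truth_idx = {v.vid: i for i, v in enumerate(truth.variants)}
    imp_idx = {v.vid: i for i, v in enumerate(imputed.variants)}
    dosages = imputed.dosages()
    maf = truth.maf()
    out = []
    for vid in sorted(plan.masked_vids):
        ti = truth_idx.get(vid)
        ii = imp_idx.get(vid)
        if ti is None or ii is None:
            continue
        t_row = truth.calls[ti]
        ml = most_likely_genotype(imputed.probs[ii])
        table = contingency(t_row, ml)
        v = truth.variants[ti]
        out.append(
            SnpMetrics(
                vid=vid, chrom=v.chrom, pos=v.pos, rep=plan.rep,
                n_eval=table.n,
                concordance=concordance(table),
                iqs=iqs(table),
                rsq_true=true_rsq(dosages[ii], t_row),
                maf=float(maf[ti]),
            )
        )
    return out


def imputed_snp_metrics(imputed: PosteriorMatrix) -> list[SnpMetrics]:
    """Variance-ratio r2hat for every imputed SNP, with dosage-estimated MAF
    (the only frequency available without truth)."""
    dosages = imputed.dosages()
    out = []
    for i, v in enumerate(imputed.variants):
        d = dosages[i]
        p_hat = d.mean() / 2.0
        out.append(
            SnpMetrics(
                vid=v.vid, chrom=v.chrom, pos=v.pos, rep=None,
                n_eval=d.size,
                rsq_est=estimated_rsq(d),
                maf=float(min(p_hat, 1.0 - p_hat)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_FILTERS = ("rsq-threshold", "post-impute-monomorphic")


@dataclass
class RunConfig:
    """One evaluation run.  ``mode`` selects the imputation source:
    ``synthetic`` (the three-panel scenario) or ``files`` (externally
    produced truth + imputed results)."""

    mode: str = "synthetic"
    outdir: str = "imputeval-out"
    seed: int = 0
    mask_fraction: float = 0.02
    reps: int = 10
    bin_width: float = 0.01
    filters: tuple[str, ...] = ()
    rsq_threshold: float = 0.3
    filter_panel: str = "close"
    thresholds: QcThresholds = field(default_factory=QcThresholds)
    sim: SimConfig | None = None
    truth_path: str = ""
    truth_format: str = "vcf"
    imputed_path: str = ""
    imputed_format: str = "vcf-gp"
    panel_config_paths: tuple[str, ...] = ()
    ancestry_path: str = ""

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        for f in self.filters:
            if f not in _FILTERS:
                raise ConfigError(f"unknown filter {f!r}; choose from {_FILTERS}")
        if not 0.0 < self.mask_fraction < 1.0:
            raise ConfigError("mask_fraction must be in (0, 1)")
        if self.mode == "files":
            for p in (self.truth_path, self.imputed_path):
                if not p or not os.path.exists(p):
                    raise ConfigError(f"input path missing or absent: {p!r}")
            for p in self.panel_config_paths:
                if not os.path.exists(p):
                    raise ConfigError(f"panel config absent: {p!r}")


def load_run_config(path: str, seed: int | None = None,
                    outdir: str | None = None) -> RunConfig:
    """Load a RunConfig from YAML; ``seed`` and ``outdir`` override the file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    for key in ("mode", "outdir", "seed", "mask_fraction", "reps", "bin_width",
                "rsq_threshold", "filter_panel", "truth_path", "truth_format",
                "imputed_path", "imputed_format", "ancestry_path"):
        if key in raw:
            kwargs[key] = raw[key]
    if "filters" in raw:
        kwargs["filters"] = tuple(raw["filters"])
    if "panel_configs" in raw:
        kwargs["panel_config_paths"] = tuple(raw["panel_configs"])
    if "thresholds" in raw:
        kwargs["thresholds"] = QcThresholds(**raw["thresholds"])
    if "sim" in raw:
        sim_raw = dict(raw["sim"])
        if "channel" in sim_raw:
            sim_raw["channel"] = synthetic.ChannelParams(**sim_raw["channel"])
        if "maf_law" in sim_raw:
            sim_raw["maf_law"] = synthetic.MafLaw(**sim_raw["maf_law"])
        if "planted" in sim_raw:
            sim_raw["planted"] = tuple(
                synthetic.PlantedClass(
                    fraction=p["fraction"], zero_pops=tuple(p["zero_pops"]),
                    **{k: p[k] for k in ("freq_lo", "freq_hi") if k in p},
                )
                for p in sim_raw["planted"]
            )
        if "populations" in sim_raw:
            sim_raw["populations"] = tuple(
                (c, int(n)) for c, n in sim_raw["populations"]
            )
        if "admixture_law" in sim_raw:
            sim_raw["admixture_law"] = tuple(sim_raw["admixture_law"])
        if "study_ancestry" in sim_raw:
            sim_raw["study_ancestry"] = tuple(sim_raw["study_ancestry"])
        kwargs["sim"] = SimConfig(**sim_raw)
    cfg = RunConfig(**kwargs)
    if seed is not None:
        cfg.seed = seed
    if outdir is not None:
        cfg.outdir = outdir
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# run
# ---------------------------------------------------------------------------

@dataclass
class RunBundle:
    """Everything a run produced; every summary is traceable to the per-SNP
    tables in ``metrics``."""

    config: RunConfig
    qc_report: QcReport | None
    plans: list[MaskPlan]
    metrics: dict[str, list[SnpMetrics]]            # panel -> per-SNP records
    summaries: dict[tuple[str, str], EvaluationSummary]  # (panel, filter) ->
    filter_results: dict[tuple[str, str], FilterResult]
    scenario: ScenarioResult | None = None

    def comparison_table(self) -> pd.DataFrame:
        rows = []
        for (panel, filt), s in self.summaries.items():
            rows.append(
                {
                    "panel": panel, "filter": filt,
                    "concordance": s.pooled_concordance,
                    "iqs": s.pooled_iqs,
                    "rsq_mean": s.rsq_mean,
                    "n_rsq_snps": s.n_rsq_snps,
                }
            )
        return pd.DataFrame(rows)


def _apply_filters(
    config: RunConfig,
    panel_name: str,
    metrics: list[SnpMetrics],
    plans: Sequence[MaskPlan],
    panel_map: dict[str, PanelSpec],
    summaries: dict,
    filter_results: dict,
) -> None:
    for filt in config.filters:
        if filt == "rsq-threshold":
            imputed_only = [m for m in metrics if m.rep is None]
            res = rsq_threshold_filter(imputed_only, config.rsq_threshold)
            kept = [
                m for m in metrics
                if m.rep is not None or m.vid in res.kept_vids
            ]
            summaries[(panel_name, filt)] = summarize(kept, plans, config.bin_width)
            filter_results[(panel_name, filt)] = res
        elif filt == "post-impute-monomorphic":
            target = panel_map.get(config.filter_panel)
            if target is None:
                raise StageError(
                    "filter", "no-target-panel",
                    f"filter_panel {config.filter_panel!r} not among panels",
                )
            res, summ = post_impute_filter(
                metrics, target, plans, config.bin_width
            )
            summaries[(panel_name, filt)] = summ
            filter_results[(panel_name, filt)] = res


def _run_synthetic(config: RunConfig) -> RunBundle:
    sim = config.sim or synthetic.default_scenario_config(seed=config.seed)
    if config.sim is not None and config.sim.seed != config.seed:
        sim = replace(sim, seed=config.seed)
    scen = scenario_three_panels(sim)

    # SNP-level QC on the genotyped (chip) subset, mirroring study bookkeeping
    gpos = {v.vid: i for i, v in enumerate(scen.truth.variants)}
    chip = scen.truth.subset_variants([gpos[v] for v in scen.genotyped_vids])
    chip_qc, qc_report = qc.snp_qc(chip, config.thresholds)

    try:
        plans = build_mask_plans(
            [v.vid for v in chip_qc.variants],
            fraction=config.mask_fraction,
            reps=config.reps,
            base_seed=config.seed,
        )
    except ValueError as exc:
        raise StageError("mask", "degenerate-plan", str(exc)) from exc

    metrics: dict[str, list[SnpMetrics]] = {}
    summaries: dict[tuple[str, str], EvaluationSummary] = {}
    filter_results: dict[tuple[str, str], FilterResult] = {}
    for rank, (name, panel) in enumerate(scen.panels.items()):
        per_snp: list[SnpMetrics] = list(imputed_snp_metrics(scen.posteriors[name]))
        pooled = panel.pooled_af()
        sub_cfg = replace(sim, channel=scen.channels[name])
        imp_idx = [gpos[v] for v in scen.posteriors[name].vids]
        sub_truth = scen.truth.subset_variants(imp_idx)
        prior = pooled.loc[[v.vid for v in sub_truth.variants]]
        for plan in plans:
            rep_post = synthetic.imputation_channel(
                sub_truth, prior, sub_cfg, panel=scen.panels["close"],
                seed=config.seed + 100_000 * (rank + 1) + plan.rep,
            )
            per_snp.extend(masked_snp_metrics(scen.truth, rep_post, plan))
        metrics[name] = per_snp
        summaries[(name, "none")] = summarize(per_snp, plans, config.bin_width)
        _apply_filters(config, name, per_snp, plans, scen.panels,
                       summaries, filter_results)

    return RunBundle(
        config=config, qc_report=qc_report, plans=plans, metrics=metrics,
        summaries=summaries, filter_results=filter_results, scenario=scen,
    )


def _run_files(config: RunConfig) -> RunBundle:
    try:
        truth = core_io.read_genotypes(config.truth_path, config.truth_format)
        imputed = core_io.read_imputed(config.imputed_path, config.imputed_format)
    except (OSError, ValueError) as exc:
        raise StageError("read", "io-error", str(exc)) from exc
    aligned = core_io.align_alleles(imputed, truth)

    truth_vids = set(truth.vids)
    shared = [v for v in aligned.vids if v in truth_vids]
    # externally masked results: score every shared SNP as one repetition
    plan = MaskPlan(rep=1, seed=config.seed, fraction=1.0,
                    masked_vids=frozenset(shared))
    per_snp = imputed_snp_metrics(imputed)
    per_snp.extend(masked_snp_metrics(truth, aligned, plan))

    panel_map = {}
    for path in config.panel_config_paths:
        p = panels.load_panel_config(path)
        panel_map[p.name] = p

    summaries: dict[tuple[str, str], EvaluationSummary] = {
        ("files", "none"): summarize(per_snp, [plan], config.bin_width)
    }
    filter_results: dict[tuple[str, str], FilterResult] = {}
    _apply_filters(config, "files", per_snp, [plan], panel_map,
                   summaries, filter_results)
    return RunBundle(
        config=config, qc_report=None, plans=[plan],
        metrics={"files": per_snp}, summaries=summaries,
        filter_results=filter_results,
    )


def run(config: RunConfig) -> RunBundle:
    """Execute a full evaluation run and write the report bundle to
    ``config.outdir`` (per-SNP TSVs, summary JSON, MAF-bin tables, mask
    plans, QC report)."""
    config.validate()
    bundle = _run_synthetic(config) if config.mode == "synthetic" else _run_files(config)
    write_bundle(bundle, config.outdir)
    return bundle


def write_bundle(bundle: RunBundle, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    for panel, per_snp in bundle.metrics.items():
        metrics_table(per_snp).to_csv(
            os.path.join(outdir, f"per_snp_{panel}.tsv"), sep="\t",
            index=False, float_format="%.6g",
        )
    summary_obj = {
        f"{panel}::{filt}": s.to_dict()
        for (panel, filt), s in bundle.summaries.items()
    }
    with open(os.path.join(outdir, "summaries.json"), "w") as fh:
        json.dump(summary_obj, fh, indent=2, default=float)
    for (panel, filt), s in bundle.summaries.items():
        s.binned.to_csv(
            os.path.join(outdir, f"bins_{panel}_{filt}.tsv"), sep="\t",
            index=False, float_format="%.6g",
        )
    with open(os.path.join(outdir, "mask_plans.json"), "w") as fh:
        json.dump(
            [
                {"rep": p.rep, "seed": p.seed, "fraction": p.fraction,
                 "masked_vids": sorted(p.masked_vids)}
                for p in bundle.plans
            ],
            fh, indent=2,
        )
    if bundle.qc_report is not None:
        with open(os.path.join(outdir, "qc_report.json"), "w") as fh:
            fh.write(bundle.qc_report.to_json())
    bundle.comparison_table().to_csv(
        os.path.join(outdir, "comparison.tsv"), sep="\t", index=False,
        float_format="%.6g",
    )


# ---------------------------------------------------------------------------
# cross-run comparison
# ---------------------------------------------------------------------------

def compare_summaries(bundles: Sequence[RunBundle]) -> pd.DataFrame:
    """Long-format comparison keyed by (panel, filter): pooled concordance,
    IQS, mean r2hat, and per-bin r2hat rows."""
    if len(bundles) < 2:
        raise ValueError("compare_summaries needs at least 2 bundles")
    widths = {s.bin_width for b in bundles for s in b.summaries.values()}
    if len(widths) > 1:
        raise ValueError(f"mismatched MAF bin widths across bundles: {widths}")
    rows = []
    for bi, b in enumerate(bundles):
        for (panel, filt), s in b.summaries.items():
            rows.append(
                {"bundle": bi, "panel": panel, "filter": filt, "bin": None,
                 "concordance": s.pooled_concordance, "iqs": s.pooled_iqs,
                 "rsq_mean": s.rsq_mean, "n": s.n_rsq_snps}
            )
            for _, r in s.binned.iterrows():
                rows.append(
                    {"bundle": bi, "panel": panel, "filter": filt,
                     "bin": int(r["bin"]), "concordance": None, "iqs": None,
                     "rsq_mean": r["rsq_mean"], "n": int(r["n_snps"])}
                )
    return pd.DataFrame(rows)


def plot_rsq_by_maf(
    summaries: dict[str, EvaluationSummary], path: str
) -> None:
    """Mean r2hat vs MAF bin, one line per labelled summary (never
    load-bearing for tests)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for label, s in summaries.items():
        if not len(s.binned):
            continue
        ax.plot(s.binned["maf_high"], s.binned["rsq_mean"], marker="o",
                markersize=3, label=label)
    ax.set_xlabel("minor allele frequency (bin upper bound)")
    ax.set_ylabel("mean r2hat")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
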