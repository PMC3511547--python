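"""Reference-panel composition and population-aware SNP filtering.

A reference panel is a named combination of populations with per-population
ALT-allele frequencies.  Pooled panel frequency is the sample-count-weighted
mean of the member-population frequencies (haplotype counts are 2x samples
when frequencies come from phased haplotypes, which leaves the weighting
unchanged).  A variant is *monomorphic* in a panel when its pooled frequency
is exactly 0 or exactly 1 — in either case it does not segregate there, so
when it appears in a more diverse panel it is population-specific.

Two filtering strategies against a designated subpanel are provided:
``pre_impute_filter`` removes monomorphic reference SNPs before imputation
(the "-filt_rules_1" style), ``post_impute_filter`` removes them from the
evaluated results afterwards.  On an imputer that treats SNPs independently
the two are equivalent in terms of surviving variant sets.  A plain r2hat
threshold filter (inclusive, default 0.3) is also provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .evaluation import EvaluationSummary, MaskPlan, SnpMetrics, is_defined, summarize


@dataclass(frozen=True)
class PanelSpec:
    """Named reference panel: member populations with sample counts and a
    per-variant, per-population ALT-frequency table (index vid)."""

    name: str
    populations: tuple[tuple[str, int], ...]
    af: pd.DataFrame

    def __post_init__(self) -> None:
        for code, count in self.populations:
            if count <= 0:
                raise ValueError(f"population {code}: count must be positive")
            if code not in self.af.columns:
                raise ValueError(f"population {code} missing from frequency table")
        vals = self.af[[c for c, _ in self.populations]].to_numpy()
        finite = vals[np.isfinite(vals)]
        if finite.size and ((finite < 0).any() or (finite > 1).any()):
            raise ValueError("allele frequencies must lie in [0, 1]")

    @property
    def n_total(self) -> int:
        return sum(count for _, count in self.populations)

    def pooled_af(self) -> pd.Series:
        """Sample-count-weighted pooled ALT frequency per variant.

        Variants with a missing (NaN) frequency in a member population are
        treated as frequency 0 there: a reference SNP absent from a
        population does not segregate in it.
        """
        codes = [c for c, _ in self.populations]
        weights = np.array([n for _, n in self.populations], dtype=np.float64)
        freqs = self.af[codes].fillna(0.0).to_numpy()
        return pd.Series(freqs @ weights / weights.sum(), index=self.af.index)


def compose_panel(
    name: str,
    member_populations: Sequence[tuple[str, int]],
    af_source: pd.DataFrame,
) -> PanelSpec:
    """Build a panel from (population code, sample count) pairs and a
    frequency table covering those populations."""
    for code, _ in member_populations:
        if code not in af_source.columns:
            raise ValueError(f"unknown population code: {code!r}")
    codes = [c for c, _ in member_populations]
    return PanelSpec(
        name=name,
        populations=tuple((c, int(n)) for c, n in member_populations),
        af=af_source[codes].copy(),
    )


def monomorphic_set(panel: PanelSpec) -> set[str]:
    """Variant ids whose pooled panel ALT frequency is exactly 0 or 1."""
    pooled = panel.pooled_af()
    return set(pooled.index[(pooled == 0.0) | (pooled == 1.0)])


@dataclass(frozen=True)
class FilterResult:
    """Exact partition of the input into kept and removed variant ids."""

    kept_vids: frozenset[str]
    removed_vids: frozenset[str]
    reason: str

    def __post_init__(self) -> None:
        if self.kept_vids & self.removed_vids:
            raise ValueError("kept and removed sets overlap")


def pre_impute_filter(
    reference_vids: Iterable[str], target_panel: PanelSpec
) -> FilterResult:
    """Remove reference SNPs monomorphic in the target (sub)panel before
    imputation.  Variants absent from the panel's frequency table count as
    monomorphic there and are removed."""
    vids = set(reference_vids)
    covered = set(target_panel.af.index)
    mono = monomorphic_set(target_panel)
    removed = frozenset((vids - covered) | (vids & mono))
    kept = frozenset(vids - removed)
    if not kept:
        warnings.warn(
            f"pre_impute_filter({target_panel.name}): every input variant is "
            "monomorphic in the target panel",
            stacklevel=2,
        )
    return FilterResult(kept, removed, reason="monomorphic-in-subpanel")


def post_impute_filter(
    metrics: Sequence[SnpMetrics],
    target_panel: PanelSpec,
    plans: Sequence[MaskPlan] = (),
    bin_width: float = 0.01,
) -> tuple[FilterResult, EvaluationSummary]:
    """Drop already-imputed SNPs monomorphic in the target (sub)panel and
    re-summarize the remainder."""
    if not metrics:
        raise ValueError("post_impute_filter requires non-empty metrics")
    covered = set(target_panel.af.index)
    mono = monomorphic_set(target_panel)
    vids = {m.vid for m in metrics}
    removed = frozenset(v for v in vids if v in mono or v not in covered)
    kept_metrics = [m for m in metrics if m.vid not in removed]
    result = FilterResult(frozenset(vids - removed), removed,
                          reason="monomorphic-in-subpanel")
    if not kept_metrics:
        warnings.warn(
            f"post_impute_filter({target_panel.name}): no SNPs survive",
            stacklevel=2,
        )
        empty = EvaluationSummary(
            per_rep=pd.DataFrame(
                columns=["rep", "n_snps", "concordance", "iqs", "n_undefined_iqs"]
            ),
            pooled_concordance=float("nan"),
            pooled_iqs=float("nan"),
            rsq_mean=float("nan"),
            n_rsq_snps=0,
            binned=pd.DataFrame(
                columns=["bin", "maf_low", "maf_high", "n_snps", "rsq_mean"]
            ),
            counts={"n_records": 0},
            bin_width=bin_width,
        )
        return result, empty
    return result, summarize(kept_metrics, plans, bin_width)


def rsq_threshold_filter(
    metrics: Sequence[SnpMetrics], threshold: float = 0.3
) -> FilterResult:
    """Keep SNPs whose estimated r2hat meets the threshold (inclusive,
    matching the conventional "r2 >= 0.3" rule); SNPs with an undefined
    r2hat are removed."""
    if not metrics:
        raise ValueError("rsq_threshold_filter requires non-empty metrics")
    kept, removed = [], []
    for m in metrics:
        (kept if is_defined(m.rsq_est) and m.rsq_est >= threshold else removed).append(m.vid)
    return FilterResult(frozenset(kept), frozenset(removed),
                        reason="rsq-below-threshold")


# ---------------------------------------------------------------------------
# panel configuration I/O
# ---------------------------------------------------------------------------

def read_frequency_table(path: str) -> pd.DataFrame:
    """Tab-delimited per-population ALT-frequency table, indexed by vid."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_frequency_table(af: pd.DataFrame, path: str) -> None:
    af.to_csv(path, sep="\t", index_label="vid", float_format="%.6g")


def af_from_vcf(path: str, sample_pop: dict[str, str]) -> pd.DataFrame:
    """Per-population ALT frequencies from a (phased or unphased) VCF.

    ``sample_pop`` maps sample id -> population code.  Frequencies are allele
    counts over non-missing alleles; biallelic SNVs only.
    """
    from .core_io import read_genotypes

    g = read_genotypes(path, format="vcf")
    pops = sorted(set(sample_pop.values()))
    cols = {}
    sample_idx = {s: i for i, s in enumerate(g.samples)}
    for pop in pops:
        members = [sample_idx[s] for s in g.samples if sample_pop.get(s) == pop]
        calls = g.calls[:, members]
        called = calls != -1
        n_alleles = 2.0 * called.sum(axis=1)
        alt = np.where(called, calls, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cols[pop] = np.where(n_alleles > 0, alt / n_alleles, np.nan)
    return pd.DataFrame(cols, index=[v.vid for v in g.variants])


def load_panel_config(path: str) -> PanelSpec:
    """Load a panel definition from YAML.

    Schema::

        name: YRI+CEU+ASW
        populations:
          - {code: YRI, count: 88}
          - {code: CEU, count: 85}
          - {code: ASW, count: 61}
        frequency_table: path/to/af.tsv      # or:
        haplotype_vcf: path/to/phased.vcf
        sample_population_map: path/to/map.tsv   # with haplotype_vcf
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    members = [(p["code"], int(p["count"])) for p in cfg["populations"]]
    if "frequency_table" in cfg:
        af = read_frequency_table(cfg["frequency_table"])
    elif "haplotype_vcf" in cfg:
        mapping = pd.read_csv(
            cfg["sample_population_map"], sep="\t", index_col=0
        ).iloc[:, 0].to_dict()
        af = af_from_vcf(cfg["haplotype_vcf"], mapping)
    else:
        raise ValueError(f"{path}: need frequency_table or haplotype_vcf")
    return compose_panel(cfg["name"], members, af)


def write_exclusion_list(vids: Iterable[str], path: str) -> None:
    """One variant id per line — consumable as an external tool's exclusion file."""
    with open(path, "w") as fh:
        for v in sorted(vids):
            fh.write(f"{v}\n")
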