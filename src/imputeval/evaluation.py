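"""Masking harness and imputation performance metrics.

The evaluation design: a fraction of genotyped SNPs is masked (hidden) before
imputation, so the imputed results at those SNPs can be scored against the
known truth.  Three per-SNP metrics are computed:

* **concordance** — fraction of calls where the most likely imputed genotype
  equals the true genotype;
* **IQS** — imputation quality score, the concordance corrected for chance
  agreement in the style of Cohen's kappa:
  ``IQS = (P0 - Pc) / (1 - Pc)`` with ``P0`` the observed agreement and
  ``Pc`` the sum of products of marginal genotype frequencies.  IQS is the
  informative metric at low MAF, where raw concordance is inflated because a
  constant homozygous call is almost always right by chance;
* **r2hat** — estimated squared correlation between imputed dosage and the
  underlying true genotype.  For SNPs without truth this is the variance-ratio
  estimator ``Var(d) / (2 p (1 - p))`` with ``p = mean(d)/2``, which requires
  no truth and is therefore computable for *all* imputed SNPs; the literal
  squared Pearson correlation (:func:`true_rsq`) is available for masked SNPs.

Summaries average each metric per SNP first, then across SNPs, then across
masking repetitions; r2hat is additionally stratified into half-open MAF bins
``(0, 0.01], (0.01, 0.02], ...`` of configurable width.  Undefined metrics
(degenerate contingency tables, constant dosage vectors) are excluded from
averages and reported as counts, never imputed as zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_io import MISSING

UNDEFINED = float("nan")


def is_defined(x: float) -> bool:
    return x is not None and not math.isnan(x)


# ---------------------------------------------------------------------------
# masking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaskPlan:
    """One repetition's seeded selection of variants to mask."""

    rep: int
    seed: int
    fraction: float
    masked_vids: frozenset[str]


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def build_mask_plans(
    vids: Sequence[str],
    fraction: float = 0.02,
    reps: int = 10,
    base_seed: int = 0,
) -> list[MaskPlan]:
    """Draw ``reps`` independent without-replacement masking plans.

    Repetition ``r`` (1-based) uses seed ``base_seed + r``; each plan masks
    ``round(fraction * M)`` variants (round half away from zero).  Plans are
    bit-reproducible for fixed seeds; overlap between repetitions is allowed.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    vids = list(vids)
    if len(set(vids)) != len(vids):
        raise ValueError("variant ids must be unique")
    k = _round_half_away(fraction * len(vids))
    if k == 0:
        raise ValueError(
            f"degenerate plan: fraction {fraction} of {len(vids)} variants rounds to 0"
        )
    plans = []
    for r in range(1, reps + 1):
        seed = base_seed + r
        rng = np.random.default_rng(seed)
        picked = rng.choice(len(vids), size=k, replace=False)
        plans.append(
            MaskPlan(rep=r, seed=seed, fraction=fraction,
                     masked_vids=frozenset(vids[i] for i in picked))
        )
    return plans


# ---------------------------------------------------------------------------
# per-SNP metrics
# ---------------------------------------------------------------------------

def most_likely_genotype(p: np.ndarray) -> np.ndarray | int:
    """Argmax genotype of posterior triplet(s); ties break toward the smaller
    genotype index (ties are measure-zero for real posteriors)."""
    p = np.asarray(p)
    out = np.argmax(p, axis=-1)
    return int(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ContingencyTable3x3:
    """3x3 counts: rows = true genotype, columns = most-likely imputed genotype."""

    counts: tuple  # 3x3 nested tuple of ints

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (3, 3) or (arr < 0).any():
            raise ValueError("counts must be a non-negative 3x3 table")
        if arr.sum() < 1:
            raise ValueError("contingency table must have n >= 1")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)

    @property
    def n(self) -> int:
        return int(self.array.sum())


def contingency(truth: np.ndarray, imputed: np.ndarray) -> ContingencyTable3x3:
    """Tally true vs imputed genotype pairs; MISSING truth is excluded."""
    truth = np.asarray(truth)
    imputed = np.asarray(imputed)
    if truth.shape != imputed.shape:
        raise ValueError("truth and imputed call vectors must have equal length")
    use = truth != MISSING
    if not use.any():
        raise ValueError("no usable (non-missing) genotype pairs")
    t = truth[use].astype(np.int64)
    m = imputed[use].astype(np.int64)
    table = np.zeros((3, 3), dtype=np.int64)
    np.add.at(table, (t, m), 1)
    return ContingencyTable3x3(tuple(tuple(int(x) for x in row) for row in table))


def concordance(t: ContingencyTable3x3) -> float:
    """Observed agreement: trace / n."""
    a = t.array
    return float(np.trace(a) / a.sum())


def iqs(t: ContingencyTable3x3) -> float:
    """Imputation quality score: chance-corrected concordance.

    ``P0 = trace/n``; ``Pc = sum_g row_g * col_g / n^2``;
    ``IQS = (P0 - Pc) / (1 - Pc)``.  Computed in integer arithmetic so that
    the degenerate case ``Pc == 1`` (both margins concentrated on a single
    genotype) is detected exactly and returns UNDEFINED (NaN).
    """
    a = t.array
    n = int(a.sum())
    trace = int(np.trace(a))
    chance = int(np.dot(a.sum(axis=1), a.sum(axis=0)))  # sum_g row_g * col_g
    if chance == n * n:
        return UNDEFINED
    return float((trace * n - chance) / (n * n - chance))


def estimated_rsq(d: np.ndarray) -> float:
    """Variance-ratio r2hat from dosages alone: ``Var(d) / (2 p (1 - p))``.

    ``p = mean(d) / 2`` is the dosage-estimated ALT frequency.  Returns 0 for
    monomorphic dosage vectors (p in {0, 1}) and clips to [0, 1].  This is
    the truth-free estimator that makes r2hat computable for every imputed
    SNP: an imputer with no information emits prior-like dosages of near-zero
    variance, driving the ratio toward 0.
    """
    d = np.asarray(d, dtype=np.float64)
    if d.size < 2:
        raise ValueError("estimated_rsq needs at least 2 samples")
    p = d.mean() / 2.0
    if p <= 0.0 or p >= 1.0 or np.ptp(d) == 0:
        return 0.0
    return float(np.clip(d.var() / (2.0 * p * (1.0 - p)), 0.0, 1.0))


def true_rsq(d: np.ndarray, g: np.ndarray) -> float:
    """Squared Pearson correlation of dosage with true genotype.

    Pairs with MISSING truth are excluded; UNDEFINED (NaN) when fewer than 2
    usable pairs remain or either vector is constant.
    """
    d = np.asarray(d, dtype=np.float64)
    g = np.asarray(g)
    if d.shape != g.shape:
        raise ValueError("dosage and genotype vectors must have equal length")
    use = g != MISSING
    d, g = d[use], g[use].astype(np.float64)
    if d.size < 2 or np.ptp(d) == 0 or np.ptp(g) == 0:
        return UNDEFINED
    r = np.corrcoef(d, g)[0, 1]
    return float(np.clip(r * r, 0.0, 1.0))


@dataclass
class SnpMetrics:
    """Per-SNP evaluation record.

    ``rep`` is the masking repetition for masked-SNP records, or None for
    imputed-only records that contribute to the r2hat pool.  ``maf`` is the
    frequency used for binning: truth-derived for masked SNPs,
    dosage-estimated for imputed-only SNPs.
    """

    vid: str
    n_eval: int = 0
    concordance: float = UNDEFINED
    iqs: float = UNDEFINED
    rsq_est: float = UNDEFINED
    rsq_true: float = UNDEFINED
    maf: float = UNDEFINED
    rep: int | None = None
    chrom: str = ""
    pos: int = 0


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def maf_bin_index(maf: float, bin_width: float = 0.01) -> int:
    """1-based half-open bin: bin k covers ``((k-1)*w, k*w]``.

    A MAF of exactly 0.02 falls in bin 2, i.e. (0.01, 0.02] — the inclusive
    upper bound matching the "MAF <= 2%" stratum convention.  MAF 0 (or NaN)
    returns 0: below every bin, excluded from binned summaries.
    """
    if not is_defined(maf) or maf <= 0:
        return 0
    # guard against float fuzz at bin boundaries (0.02/0.01 -> 2.0000000000000004)
    return int(math.floor((maf - 1e-12) / bin_width)) + 1


@dataclass
class EvaluationSummary:
    """Pooled, per-repetition and MAF-binned metric summaries."""

    per_rep: pd.DataFrame           # rep, n_snps, concordance, iqs, n_undefined_iqs
    pooled_concordance: float
    pooled_iqs: float
    rsq_mean: float
    n_rsq_snps: int
    binned: pd.DataFrame            # bin, maf_low, maf_high, n_snps, rsq_mean
    counts: dict[str, int] = field(default_factory=dict)
    bin_width: float = 0.01

    def to_dict(self) -> dict:
        return {
            "pooled_concordance": self.pooled_concordance,
            "pooled_iqs": self.pooled_iqs,
            "rsq_mean": self.rsq_mean,
            "n_rsq_snps": self.n_rsq_snps,
            "counts": self.counts,
            "per_rep": self.per_rep.to_dict(orient="records"),
            "binned": self.binned.to_dict(orient="records"),
            "bin_width": self.bin_width,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, default=float)


def _mean_defined(values: Iterable[float]) -> tuple[float, int, int]:
    """(mean of defined values, n defined, n undefined)."""
    vals = [v for v in values]
    defined = [v for v in vals if is_defined(v)]
    mean = float(np.mean(defined)) if defined else UNDEFINED
    return mean, len(defined), len(vals) - len(defined)


def summarize(
    per_snp: Sequence[SnpMetrics],
    plans: Sequence[MaskPlan] = (),
    bin_width: float = 0.01,
) -> EvaluationSummary:
    """Average metrics per repetition, pool across repetitions, and bin r2hat.

    Concordance and IQS: mean over each repetition's masked SNPs, then mean
    of the per-repetition means (SNP-first averaging order).  r2hat: mean over
    all polymorphic imputed SNPs (records with MAF > 0 and a defined
    ``rsq_est``); monomorphic-dosage SNPs are excluded and counted.  Binned
    means recombine to ``rsq_mean`` exactly (weighted by per-bin counts).
    """
    if not per_snp:
        raise ValueError("summarize requires a non-empty metrics list")

    rep_rows = []
    n_undef_conc = n_undef_iqs = 0
    for plan in plans:
        mine = [m for m in per_snp if m.rep == plan.rep and m.vid in plan.masked_vids]
        conc_mean, _, u_c = _mean_defined(m.concordance for m in mine)
        iqs_mean, _, u_i = _mean_defined(m.iqs for m in mine)
        n_undef_conc += u_c
        n_undef_iqs += u_i
        rep_rows.append(
            {"rep": plan.rep, "n_snps": len(mine),
             "concordance": conc_mean, "iqs": iqs_mean,
             "n_undefined_iqs": u_i}
        )
    per_rep = pd.DataFrame(
        rep_rows, columns=["rep", "n_snps", "concordance", "iqs", "n_undefined_iqs"]
    )
    pooled_conc, _, _ = _mean_defined(per_rep["concordance"]) if len(per_rep) else (UNDEFINED, 0, 0)
    pooled_iqs, _, _ = _mean_defined(per_rep["iqs"]) if len(per_rep) else (UNDEFINED, 0, 0)

    # r2hat pool: all polymorphic imputed SNPs
    pool = [m for m in per_snp if m.rep is None or not plans]
    rsq_records = [
        m for m in pool
        if is_defined(m.rsq_est) and is_defined(m.maf) and m.maf > 0
    ]
    n_mono = sum(
        1 for m in pool
        if is_defined(m.rsq_est) and not (is_defined(m.maf) and m.maf > 0)
    )
    bins: dict[int, list[float]] = {}
    for m in rsq_records:
        bins.setdefault(maf_bin_index(m.maf, bin_width), []).append(m.rsq_est)
    bin_rows = [
        {
            "bin": k,
            "maf_low": (k - 1) * bin_width,
            "maf_high": k * bin_width,
            "n_snps": len(v),
            "rsq_mean": float(np.mean(v)),
        }
        for k, v in sorted(bins.items())
    ]
    binned = pd.DataFrame(
        bin_rows, columns=["bin", "maf_low", "maf_high", "n_snps", "rsq_mean"]
    )
    if len(binned):
        rsq_mean = float(
            (binned["rsq_mean"] * binned["n_snps"]).sum() / binned["n_snps"].sum()
        )
    else:
        rsq_mean = UNDEFINED
    return EvaluationSummary(
        per_rep=per_rep,
        pooled_concordance=pooled_conc,
        pooled_iqs=pooled_iqs,
        rsq_mean=rsq_mean,
        n_rsq_snps=len(rsq_records),
        binned=binned,
        counts={
            "n_records": len(per_snp),
            "n_undefined_concordance": n_undef_conc,
            "n_undefined_iqs": n_undef_iqs,
            "n_monomorphic_dosage_excluded": n_mono,
        },
        bin_width=bin_width,
    )


def metrics_table(per_snp: Sequence[SnpMetrics]) -> pd.DataFrame:
    """Per-SNP metrics as a tidy table (tab-delimited friendly)."""
    return pd.DataFrame(
        [
            {
                "vid": m.vid, "chrom": m.chrom, "pos": m.pos, "rep": m.rep,
                "maf": m.maf, "n_eval": m.n_eval, "concordance": m.concordance,
                "iqs": m.iqs, "rsq_est": m.rsq_est, "rsq_true": m.rsq_true,
            }
            for m in per_snp
        ]
    )
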