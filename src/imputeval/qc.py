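"""SNP- and subject-level quality control for genotype matrices.

Implements the standard GWAS-style pipeline: per-SNP filters (MAF, call rate,
Hardy-Weinberg exact test), duplicate removal by identity-by-state (IBS),
relatedness pruning with the stratification-robust KING kinship estimator,
and an admixture-proportion filter.  All filters are deterministic; ties on
call rate break toward the lexicographically smallest sample id.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core_io import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class QcThresholds:
    """Filter thresholds; all strict inequalities (remove when below/above).

    Defaults follow common GWAS practice: SNPs removed when MAF < 1%, call
    rate < 95% or HWE exact p < 1e-4; subject pairs with IBS > 0.99 are
    duplicates; kinship > 0.0441 marks third-degree-or-closer relatives;
    samples with African ancestry < 60% are excluded from an African-American
    analysis set.
    """

    maf_min: float = 0.01
    call_rate_min: float = 0.95
    hwe_p_min: float = 1e-4
    ibs_dup: float = 0.99
    kinship_max: float = 0.0441
    african_ancestry_min: float = 0.60

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"threshold {name}={v} outside [0, 1]")


@dataclass
class QcReport:
    """Bookkeeping for filters: removed + retained must equal the input."""

    snps_removed: dict[str, int] = field(default_factory=dict)
    subjects_removed: dict[str, list[str]] = field(default_factory=dict)
    retained_shape: tuple[int, int] = (0, 0)

    def to_json(self) -> str:
        return json.dumps(
            {
                "snps_removed": self.snps_removed,
                "subjects_removed": self.subjects_removed,
                "retained_shape": list(self.retained_shape),
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_pvalue(n0: int, n1: int, n2: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts (same parity) whose conditional probability is no
    greater than the observed one — the exact conditional test of Wigginton,
    Cutler & Abecasis (2005), as implemented in PLINK.  Monomorphic sites
    return 1.0.

    Probabilities are built by the stable two-sided recurrence from the
    observed table; a 1e-10 relative tolerance makes mathematically tied
    outcomes compare equal despite floating-point noise.
    """
    if n0 < 0 or n1 < 0 or n2 < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n0 + n1 + n2
    if n < 1:
        raise ValueError("need at least one genotype")
    n_alt = n1 + 2 * n2
    n_rare = min(n_alt, 2 * n - n_alt)
    if n_rare == 0:
        return 1.0

    # unnormalized P(h) over heterozygote counts h with h ≡ n_rare (mod 2)
    h_min = n_rare % 2
    hs = np.arange(h_min, n_rare + 1, 2)
    probs = np.empty(hs.size)
    obs_pos = int(np.searchsorted(hs, n1))
    if obs_pos >= hs.size or hs[obs_pos] != n1:
        raise ValueError(
            f"heterozygote count {n1} incompatible with allele count {n_rare}"
        )
    probs[obs_pos] = 1.0
    # P(h+2)/P(h) = 4*n_rarehom(h)*n_comhom(h) / ((h+1)(h+2))
    for k in range(obs_pos, hs.size - 1):
        h = int(hs[k])
        rare_hom = (n_rare - h) // 2
        com_hom = n - h - rare_hom
        probs[k + 1] = probs[k] * 4.0 * rare_hom * com_hom / ((h + 1) * (h + 2))
    for k in range(obs_pos, 0, -1):
        h = int(hs[k])
        rare_hom = (n_rare - h) // 2
        com_hom = n - h - rare_hom
        # inverse ratio: P(h-2) = P(h) * h*(h-1) / (4*(rare_hom+1)*(com_hom+1))
        probs[k - 1] = probs[k] * h * (h - 1) / (4.0 * (rare_hom + 1) * (com_hom + 1))
    total = probs.sum()
    p_obs = probs[obs_pos]
    tail = probs[probs <= p_obs * (1.0 + 1e-10)].sum()
    return float(min(tail / total, 1.0))


# ---------------------------------------------------------------------------
# SNP-level QC
# ---------------------------------------------------------------------------

def snp_qc(g: GenotypeMatrix, t: QcThresholds = QcThresholds()) -> tuple[GenotypeMatrix, QcReport]:
    """Remove SNPs failing MAF, call-rate or HWE criteria (strict inequalities).

    A variant may be counted under several removal reasons.  MAF and the HWE
    test use non-missing calls only.  Idempotent.
    """
    if g.n_variants == 0:
        raise ValueError("snp_qc requires a non-empty GenotypeMatrix")
    maf = g.maf()
    cr = g.call_rate()
    fail_maf = np.nan_to_num(maf, nan=0.0) < t.maf_min
    fail_cr = cr < t.call_rate_min
    fail_hwe = np.zeros(g.n_variants, dtype=bool)
    for i in range(g.n_variants):
        row = g.calls[i]
        row = row[row != MISSING]
        if row.size == 0:
            fail_hwe[i] = True
            continue
        counts = np.bincount(row, minlength=3)
        fail_hwe[i] = hwe_exact_pvalue(int(counts[0]), int(counts[1]), int(counts[2])) < t.hwe_p_min
    fail = fail_maf | fail_cr | fail_hwe
    report = QcReport(
        snps_removed={
            "maf": int(fail_maf.sum()),
            "call_rate": int(fail_cr.sum()),
            "hwe": int(fail_hwe.sum()),
            "total": int(fail.sum()),
        },
        retained_shape=(int((~fail).sum()), g.n_samples),
    )
    return g.subset_variants(~fail), report


# ---------------------------------------------------------------------------
# pairwise sample statistics
# ---------------------------------------------------------------------------

def ibs_matrix(g: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise IBS: mean over co-called variants of ``(2 - |gi - gj|) / 2``.

    Allele-sharing granularity: identical genotypes contribute 1, het vs
    homozygote 1/2, opposite homozygotes 0.  IBS of a sample with itself is
    exactly 1.
    """
    calls = g.calls.astype(np.float64)
    called = g.calls != MISSING
    n = g.n_samples
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            both = called[:, i] & called[:, j]
            m = int(both.sum())
            if m == 0:
                out[i, j] = out[j, i] = np.nan
                continue
            share = 1.0 - np.abs(calls[both, i] - calls[both, j]).sum() / (2.0 * m)
            out[i, j] = out[j, i] = share
    return pd.DataFrame(out, index=g.samples, columns=g.samples)


def king_kinship(g: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise kinship by the KING robust between-family estimator.

    ``phi = (N_het,het - 2 * N_opp_hom) / (N_het_i + N_het_j)`` over co-called
    SNPs, which is robust to population stratification because it never uses
    sample allele frequencies.  Identical samples give 0.5; unrelated samples
    have expectation 0.
    """
    n = g.n_samples
    het = g.calls == 1
    hom0 = g.calls == 0
    hom2 = g.calls == 2
    called = g.calls != MISSING
    out = np.full((n, n), 0.5)
    for i in range(n):
        for j in range(i + 1, n):
            both = called[:, i] & called[:, j]
            n_hh = int((het[:, i] & het[:, j] & both).sum())
            n_opp = int(
                ((hom0[:, i] & hom2[:, j]) | (hom2[:, i] & hom0[:, j])).sum()
            )
            denom = int((het[both, i]).sum() + (het[both, j]).sum())
            phi = (n_hh - 2.0 * n_opp) / denom if denom > 0 else 0.0
            out[i, j] = out[j, i] = phi
    return pd.DataFrame(out, index=g.samples, columns=g.samples)


def _prune_components(
    g: GenotypeMatrix, coeff: pd.DataFrame, threshold: float
) -> tuple[list[str], list[str]]:
    """Keep the highest-call-rate member of each over-threshold component."""
    cr = dict(zip(g.samples, g.sample_call_rate()))
    graph = nx.Graph()
    graph.add_nodes_from(g.samples)
    vals = coeff.to_numpy()
    for i, si in enumerate(g.samples):
        for j in range(i + 1, g.n_samples):
            if np.isfinite(vals[i, j]) and vals[i, j] > threshold:
                graph.add_edge(si, g.samples[j])
    removed: list[str] = []
    for comp in nx.connected_components(graph):
        if len(comp) == 1:
            continue
        keep = min(comp, key=lambda s: (-cr[s], s))
        removed.extend(s for s in comp if s != keep)
    removed_set = set(removed)
    retained = [s for s in g.samples if s not in removed_set]
    return retained, sorted(removed)


def duplicate_prune(
    g: GenotypeMatrix, t: QcThresholds = QcThresholds()
) -> tuple[list[str], list[str]]:
    """Drop duplicated subjects (pairwise IBS > ``ibs_dup``).

    Connected components over the duplicate graph each retain exactly the
    member with the highest call rate (lexicographically smallest id on ties).
    """
    if g.n_samples < 2:
        raise ValueError("duplicate_prune requires at least 2 samples")
    return _prune_components(g, ibs_matrix(g), t.ibs_dup)


def kinship_prune(
    g: GenotypeMatrix, t: QcThresholds = QcThresholds()
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Prune relative clusters (KING kinship > ``kinship_max``, i.e. third
    degree or closer), keeping one highest-call-rate subject per cluster."""
    if g.n_samples < 2:
        raise ValueError("kinship_prune requires at least 2 samples")
    phi = king_kinship(g)
    retained, removed = _prune_components(g, phi, t.kinship_max)
    return retained, removed, phi


# ---------------------------------------------------------------------------
# ancestry filter
# ---------------------------------------------------------------------------

def ancestry_filter(
    proportions: pd.DataFrame,
    t: QcThresholds = QcThresholds(),
    african_col: str = "African",
) -> tuple[list[str], list[str]]:
    """Exclude samples whose African ancestry fraction is below the threshold.

    ``proportions`` is indexed by sample id with one column per ancestral
    population; rows must sum to 1 within 1e-6 and include ``african_col``.
    Strict inequality: a fraction exactly at the threshold is retained.
    """
    if african_col not in proportions.columns:
        raise ValueError(f"ancestry table lacks an {african_col!r} component")
    sums = proportions.sum(axis=1).to_numpy()
    if np.abs(sums - 1.0).max() > 1e-6:
        raise ValueError("ancestry fractions must sum to 1 within 1e-6")
    afr = proportions[african_col]
    removed = afr.index[afr < t.african_ancestry_min].tolist()
    retained = afr.index[afr >= t.african_ancestry_min].tolist()
    return retained, removed


def read_ancestry_table(path: str) -> pd.DataFrame:
    """Tab-delimited ancestry proportions: sample id + one column per population."""
    return pd.read_csv(path, sep="\t", index_col=0)
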