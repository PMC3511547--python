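"""Synthetic study generator: HWE genotypes, multi-population allele-frequency
divergence, admixture, and a parameterized imputation channel.

The generator emulates the statistical structure an imputation-evaluation
study rests on, without any external data:

* **Population frequencies** follow the Balding-Nichols model: each
  population's ALT frequency is drawn from
  ``Beta(p (1-F)/F, (1-p) (1-F)/F)`` around an ancestral frequency ``p``,
  with divergence ``F`` (Fst).  A configurable fraction of SNPs is *planted*
  as population-specific: forced monomorphic (frequency 0) in designated
  "close" populations while segregating at low frequency elsewhere.
* **Study genotypes** are Hardy-Weinberg draws for admixed samples: each
  allele copies a parental population chosen by the sample's ancestry
  fraction (Beta-distributed across samples).
* **The imputation channel** is a two-parameter error model rather than a
  haplotype-copying imputer: with per-SNP probability ``e'`` the reported
  genotype is a fresh HWE draw from the SNP's prior instead of the truth, and
  the emitted posterior is ``q' * point-mass(reported) + (1 - q') * prior``.
  Every evaluation metric has a closed-form expectation under this channel
  (concordance ``1 - e' + e' * sum f_g^2``, IQS 0 at ``e' = 1``, variance-ratio
  r2hat ``q'^2`` for a well-specified prior), which is the point of the
  stand-in.  Penalties for SNPs monomorphic in a designated subpanel and for
  low-MAF SNPs raise ``e'`` *and* shrink the effective calibration
  ``q' = q * (1 - penalties)`` — a real imputer with no information emits
  prior-like, low-variance dosages, which is what drives r2hat down.
  ``base_error`` does not shrink ``q'``: a maximally wrong but confident
  caller (``e = 1, q = 1``) stays sharp, giving the exact random-caller null.

All randomness flows from a single root seed through fixed per-component
child seeds (``SeedSequence((seed, component_key))``), so every output is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import MISSING, GenotypeMatrix, PosteriorMatrix, VariantRecord
from .panels import PanelSpec, compose_panel, monomorphic_set

# fixed child-seed keys for the deterministic seeding scheme
_KEY_FREQS = 1
_KEY_GENOTYPES = 2
_KEY_CHANNEL = 3
_KEY_MISSING = 4

# study-design constants: the 1000 Genomes (Feb 2012) population sample sizes
POPULATION_SIZES: dict[str, int] = {
    "YRI": 88, "CEU": 85, "ASW": 61,
    "LWK": 97, "FIN": 93, "GBR": 89, "IBS": 14, "TSI": 98,
    "CLM": 60, "MXL": 66, "PUR": 55, "CHB": 97, "CHS": 100, "JPT": 89,
}
CLOSE_POPS = ("YRI", "CEU", "ASW")
MID_POPS = CLOSE_POPS + ("LWK", "FIN", "GBR", "IBS", "TSI")
ALL_POPS = MID_POPS + ("CLM", "MXL", "PUR", "CHB", "CHS", "JPT")

_ALLELE_CYCLE = (("A", "G"), ("T", "C"), ("C", "A"), ("G", "T"))


def _rng(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, key)))


@dataclass(frozen=True)
class MafLaw:
    """Distribution of ancestral MAF: ``uniform`` or ``loguniform`` on
    [lo, hi].  The log-uniform law weights toward rare variants (density
    proportional to 1/p), a crude neutral-spectrum stand-in."""

    kind: str = "loguniform"
    lo: float = 0.001
    hi: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.lo < self.hi <= 0.5):
            raise ValueError("maf bounds must satisfy 0 < lo < hi <= 0.5")
        if self.kind not in ("uniform", "loguniform"):
            raise ValueError(f"unknown maf law {self.kind!r}")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "uniform":
            return rng.uniform(self.lo, self.hi, size=n)
        return np.exp(rng.uniform(np.log(self.lo), np.log(self.hi), size=n))


@dataclass(frozen=True)
class PlantedClass:
    """A class of population-specific SNPs: monomorphic (frequency 0) in
    ``zero_pops``, segregating at low frequency (log-uniform on
    [freq_lo, freq_hi] per population) everywhere else."""

    fraction: float
    zero_pops: tuple[str, ...]
    freq_lo: float = 0.002
    freq_hi: float = 0.02


@dataclass(frozen=True)
class ChannelParams:
    """Imputation-channel error model.

    base_error
        probability that a reported genotype is a fresh HWE draw from the
        SNP's prior instead of the truth.
    calibration
        posterior sharpness q: emitted posterior is
        ``q * point-mass(reported) + (1 - q) * HWE prior``.
    panel_penalty
        extra error for SNPs monomorphic in the designated subpanel (no
        linkage information available to a real imputer there).
    maf_penalty
        extra error for SNPs whose prior MAF is at or below ``maf_threshold``.

    Penalties add to the miscall probability and multiplicatively shrink the
    effective calibration; everything is clipped to [0, 1].
    """

    base_error: float = 0.02
    calibration: float = 0.95
    panel_penalty: float = 0.6
    maf_penalty: float = 0.25
    maf_threshold: float = 0.02

    def __post_init__(self) -> None:
        for name in ("base_error", "calibration", "panel_penalty", "maf_penalty"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Full synthetic-study configuration (see module docstring)."""

    n_snps: int = 4000
    n_samples: int = 300
    maf_law: MafLaw = MafLaw()
    fst: float = 0.1
    populations: tuple[tuple[str, int], ...] = tuple(POPULATION_SIZES.items())
    admixture_law: tuple = ("beta", 8.0, 2.0)   # or ("fixed", theta)
    study_ancestry: tuple[str, str] = ("YRI", "CEU")
    planted: tuple[PlantedClass, ...] = ()
    channel: ChannelParams = ChannelParams()
    missing_rate: float = 0.0
    panel_calibration_gain: float = 0.015
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must be in (0, 1)")
        if sum(pc.fraction for pc in self.planted) >= 1.0:
            raise ValueError("planted fractions must sum to < 1")


def default_scenario_config(seed: int = 0, n_snps: int = 4000,
                            n_samples: int = 300) -> SimConfig:
    """Default three-panel study conditions.

    Planted population-specific classes are sized so that the MAF<=2% share
    of imputed SNPs rises with panel diversity (roughly half of the SNPs
    shared across panels are rare), and the channel penalties make those
    planted SNPs poorly imputed, mirroring the structure of an admixed-cohort
    imputation study against nested reference panels.
    """
    return SimConfig(
        n_snps=n_snps,
        n_samples=n_samples,
        planted=(
            PlantedClass(fraction=0.165, zero_pops=CLOSE_POPS),
            PlantedClass(fraction=0.143, zero_pops=MID_POPS),
        ),
        channel=ChannelParams(base_error=0.02, calibration=0.92,
                              panel_penalty=0.6, maf_penalty=0.25),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def make_variants(n: int, chrom: str = "22", start: int = 10_000,
                  spacing: int = 1_000) -> list[VariantRecord]:
    """Deterministic variant scaffold with non-strand-ambiguous alleles."""
    out = []
    for i in range(n):
        ref, alt = _ALLELE_CYCLE[i % len(_ALLELE_CYCLE)]
        out.append(VariantRecord(chrom, start + i * spacing, f"snp{i:06d}", ref, alt))
    return out


def simulate_population_freqs(cfg: SimConfig) -> pd.DataFrame:
    """Per-variant, per-population ALT frequencies (index vid).

    Balding-Nichols draws around an ancestral frequency for ordinary SNPs;
    planted classes occupy disjoint, randomly chosen SNP sets of exactly
    ``round(fraction * n_snps)`` SNPs each.
    """
    rng = _rng(cfg.seed, _KEY_FREQS)
    pops = [c for c, _ in cfg.populations]
    p_anc = cfg.maf_law.sample(rng, cfg.n_snps)
    F = cfg.fst
    a = p_anc * (1.0 - F) / F
    b = (1.0 - p_anc) * (1.0 - F) / F
    freqs = np.column_stack([rng.beta(a, b) for _ in pops])

    # plant population-specific SNPs on disjoint index sets
    order = rng.permutation(cfg.n_snps)
    cursor = 0
    planted_vids: dict[int, np.ndarray] = {}
    for ci, pc in enumerate(cfg.planted):
        k = int(np.floor(pc.fraction * cfg.n_snps + 0.5))
        idx = order[cursor: cursor + k]
        cursor += k
        planted_vids[ci] = idx
        lo, hi = np.log(pc.freq_lo), np.log(pc.freq_hi)
        freqs[idx] = np.exp(rng.uniform(lo, hi, size=(k, len(pops))))
        zero_cols = [pops.index(p) for p in pc.zero_pops]
        freqs[np.ix_(idx, zero_cols)] = 0.0

    vids = [f"snp{i:06d}" for i in range(cfg.n_snps)]
    df = pd.DataFrame(freqs, index=pd.Index(vids, name="vid"), columns=pops)
    df.attrs["planted"] = {
        ci: {vids[i] for i in idx} for ci, idx in planted_vids.items()
    }
    return df


def simulate_genotypes(
    freqs: pd.DataFrame, cfg: SimConfig
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Admixed study-cohort genotypes under HWE.

    Each sample draws an ancestry fraction theta (probability a given allele
    copy descends from the first ``study_ancestry`` population); each allele
    independently picks its source population and then Bernoulli(p_source).
    With ``("fixed", 1.0)`` admixture this reduces to an unadmixed draw.
    Missingness is injected at ``cfg.missing_rate`` if nonzero.
    """
    rng = _rng(cfg.seed, _KEY_GENOTYPES)
    pop_a, pop_b = cfg.study_ancestry
    pa = freqs[pop_a].to_numpy()
    pb = freqs[pop_b].to_numpy()
    m, n = len(freqs), cfg.n_samples

    kind = cfg.admixture_law[0]
    if kind == "beta":
        theta = rng.beta(cfg.admixture_law[1], cfg.admixture_law[2], size=n)
    elif kind == "fixed":
        theta = np.full(n, float(cfg.admixture_law[1]))
    else:
        raise ValueError(f"unknown admixture law {kind!r}")

    calls = np.zeros((m, n), dtype=np.int8)
    for allele in range(2):
        from_a = rng.random((m, n)) < theta[None, :]
        p_cell = np.where(from_a, pa[:, None], pb[:, None])
        calls += (rng.random((m, n)) < p_cell).astype(np.int8)

    if cfg.missing_rate > 0:
        miss = _rng(cfg.seed, _KEY_MISSING).random((m, n)) < cfg.missing_rate
        calls[miss] = MISSING

    variants = make_variants(m)
    # keep vids in sync with the frequency table
    variants = [
        VariantRecord(v.chrom, v.pos, vid, v.ref, v.alt)
        for v, vid in zip(variants, freqs.index)
    ]
    samples = [f"SAMP{i:04d}" for i in range(n)]
    info = pd.DataFrame(
        {"african_fraction": theta, "european_fraction": 1.0 - theta},
        index=pd.Index(samples, name="sample"),
    )
    return GenotypeMatrix(variants, samples, calls), info


def imputation_channel(
    truth: GenotypeMatrix,
    freqs: np.ndarray | pd.Series,
    cfg: SimConfig,
    panel: PanelSpec | None = None,
    seed: int | None = None,
) -> PosteriorMatrix:
    """Run the synthetic imputation channel over every variant of ``truth``.

    ``freqs`` is the channel's per-variant prior ALT frequency (the imputer's
    belief; a pd.Series is aligned on vid).  ``panel``, when given, designates
    the subpanel whose monomorphic set receives ``panel_penalty`` (variants
    absent from its table count as monomorphic there).  Missing truth calls
    are imputed from the prior alone.
    """
    ch = cfg.channel
    if isinstance(freqs, pd.Series):
        p = freqs.reindex([v.vid for v in truth.variants]).to_numpy(dtype=np.float64)
        if np.isnan(p).any():
            raise ValueError("prior frequencies missing for some variants")
    else:
        p = np.asarray(freqs, dtype=np.float64)
        if p.shape != (truth.n_variants,):
            raise ValueError("freqs must provide one prior frequency per variant")

    penalty = np.zeros(truth.n_variants)
    if panel is not None:
        mono = monomorphic_set(panel)
        covered = set(panel.af.index)
        hit = np.array(
            [v.vid in mono or v.vid not in covered for v in truth.variants]
        )
        penalty += np.where(hit, ch.panel_penalty, 0.0)
    prior_maf = np.minimum(p, 1.0 - p)
    penalty += np.where(prior_maf <= ch.maf_threshold, ch.maf_penalty, 0.0)
    penalty = np.clip(penalty, 0.0, 1.0)

    e = np.clip(ch.base_error + penalty, 0.0, 1.0)
    q = np.clip(ch.calibration * (1.0 - penalty), 0.0, 1.0)

    rng = np.random.default_rng(
        np.random.SeedSequence((cfg.seed if seed is None else seed, _KEY_CHANNEL))
    )
    m, n = truth.calls.shape
    hwe_draw = rng.binomial(2, np.broadcast_to(p[:, None], (m, n))).astype(np.int8)
    err = rng.random((m, n)) < e[:, None]
    err |= truth.calls == MISSING
    reported = np.where(err, hwe_draw, truth.calls)

    prior = np.stack(
        [(1.0 - p) ** 2, 2.0 * p * (1.0 - p), p**2], axis=-1
    )  # HWE triplet per variant
    onehot = np.eye(3)[reported]
    probs = q[:, None, None] * onehot + (1.0 - q)[:, None, None] * prior[:, None, :]
    return PosteriorMatrix(truth.variants, truth.samples, probs)


# ---------------------------------------------------------------------------
# three-panel scenario
# ---------------------------------------------------------------------------

@dataclass
class ScenarioResult:
    """Everything an end-to-end evaluation needs: truth, nested panels,
    channel outputs per panel, and bookkeeping."""

    config: SimConfig
    freqs: pd.DataFrame
    truth: GenotypeMatrix
    sample_info: pd.DataFrame
    genotyped_vids: list[str]
    panels: dict[str, PanelSpec]
    posteriors: dict[str, PosteriorMatrix]
    channels: dict[str, ChannelParams]
    planted: dict[str, set[str]]

    @property
    def panel_order(self) -> list[str]:
        return list(self.panels)


def scenario_three_panels(cfg: SimConfig | None = None) -> ScenarioResult:
    """Build the nested close / mid / all panel study on synthetic data.

    Panels are nested population sets (close subset of mid subset of all); the
    diverse panels contain the planted SNPs that are monomorphic in the close
    panel, with the channel's panel and MAF penalties active for them.  Each
    panel imputes exactly its polymorphic SNPs, using the panel's pooled
    frequency as the channel prior; calibration rises slightly with panel
    diversity (``panel_calibration_gain`` per step) to emulate the benefit of
    a larger reference for SNPs it covers well.
    """
    if cfg is None:
        cfg = default_scenario_config()
    pop_sets = {"close": CLOSE_POPS, "mid": MID_POPS, "all": ALL_POPS}
    have = {c for c, _ in cfg.populations}
    for name, pops in pop_sets.items():
        if not set(pops) <= have:
            raise ValueError(f"config lacks populations for the {name} panel")

    freqs = simulate_population_freqs(cfg)
    truth, sample_info = simulate_genotypes(freqs, cfg)
    counts = dict(cfg.populations)

    planted_union: set[str] = set()
    planted = {}
    for ci, vids in freqs.attrs.get("planted", {}).items():
        planted[f"class{ci}"] = set(vids)
        planted_union |= set(vids)

    # genotyped chip: shared SNPs that a QC'd array would carry (MAF >= 1%)
    maf = pd.Series(truth.maf(), index=freqs.index)
    genotyped = [
        v for v in freqs.index
        if v not in planted_union and maf[v] >= 0.01
    ]

    panels = {
        name: compose_panel(name, [(p, counts[p]) for p in pops], freqs)
        for name, pops in pop_sets.items()
    }
    close_panel = panels["close"]

    posteriors: dict[str, PosteriorMatrix] = {}
    channels: dict[str, ChannelParams] = {}
    vid_pos = {v: i for i, v in enumerate(freqs.index)}
    for rank, (name, panel) in enumerate(panels.items()):
        pooled = panel.pooled_af()
        poly = pooled.index[(pooled > 0.0) & (pooled < 1.0)]
        idx = np.array(sorted(vid_pos[v] for v in poly))
        sub_truth = truth.subset_variants(idx)
        chan = replace(
            cfg.channel,
            calibration=min(
                1.0, cfg.channel.calibration + rank * cfg.panel_calibration_gain
            ),
        )
        sub_cfg = replace(cfg, channel=chan)
        posteriors[name] = imputation_channel(
            sub_truth,
            pooled.loc[[v.vid for v in sub_truth.variants]],
            sub_cfg,
            panel=close_panel,
            seed=cfg.seed + 101 + rank,
        )
        channels[name] = chan

    return ScenarioResult(
        config=cfg,
        freqs=freqs,
        truth=truth,
        sample_info=sample_info,
        genotyped_vids=genotyped,
        panels=panels,
        posteriors=posteriors,
        channels=channels,
        planted=planted,
    )
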