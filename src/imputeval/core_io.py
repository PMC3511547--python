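"""Domain containers and I/O for genotype and imputation-output data.

The containers are thin, validated wrappers around numpy arrays:

* :class:`GenotypeMatrix` — discrete genotypes coded as ALT-allele copy
  counts (0/1/2, ``MISSING = -1``), variants x samples.
* :class:`PosteriorMatrix` — per-genotype probability triplets
  ``(p0, p1, p2)`` as emitted by imputation software.
* :class:`DosageMatrix` — expected ALT-allele dosage in ``[0, 2]``.

Genotypes always count ALT-allele copies; "minor allele" is a property
computed where needed (:meth:`GenotypeMatrix.maf`), never a re-coding of the
stored data.  Coordinates are 1-based throughout (VCF convention).

Supported on-disk formats: VCF 4.x (GT for truth, GP/DS for imputed results;
read through cyvcf2), IMPUTE2-style GEN probability triplets, MaCH-style
``.mldose`` dosage text (with an ``.mlinfo`` sidecar), and a site-major
matrix text for discrete genotypes.  Only biallelic SNVs are retained; indels
and multiallelic records are skipped with a logged count.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

MISSING: int = -1

_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: triplet-sum window accepted before renormalization
_TRIPLET_SUM_TOL = 0.05
#: post-load renormalization tolerance
_TRIPLET_EPS = 1e-4


class MalformedRecordError(ValueError):
    """A record violates the format contract (e.g. bad probability sum)."""


class EmptyDatasetError(ValueError):
    """No variants survived parsing/filtering."""


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNV: chromosome, 1-based position, id, REF and ALT base."""

    chrom: str
    pos: int
    vid: str
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(
                f"{self.vid}: alleles must be single bases in A/C/G/T, "
                f"got {self.ref}/{self.alt}"
            )
        if self.ref == self.alt:
            raise ValueError(f"{self.vid}: ref and alt alleles are identical")
        if self.pos < 1:
            raise ValueError(f"{self.vid}: position must be 1-based positive")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_strand_ambiguous(self) -> bool:
        """A/T and C/G pairs cannot be disambiguated by strand complement."""
        return _COMPLEMENT[self.ref] == self.alt


def _check_variants(variants: Sequence[VariantRecord]) -> None:
    keys = {v.key for v in variants}
    if len(keys) != len(variants):
        raise ValueError("duplicate (chrom, pos, ref, alt) in variant list")


class GenotypeMatrix:
    """Discrete genotypes (ALT copy counts) for variants x samples."""

    def __init__(
        self,
        variants: Sequence[VariantRecord],
        samples: Sequence[str],
        calls: np.ndarray,
    ) -> None:
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(variants), len(samples)):
            raise ValueError(
                f"calls shape {calls.shape} != "
                f"({len(variants)}, {len(samples)})"
            )
        bad = ~np.isin(calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype calls must be in {-1, 0, 1, 2}")
        _check_variants(variants)
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample ids")
        self.variants = list(variants)
        self.samples = list(samples)
        self.calls = calls

    # -- basic geometry ----------------------------------------------------
    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def vids(self) -> list[str]:
        return [v.vid for v in self.variants]

    # -- per-variant statistics -------------------------------------------
    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per variant."""
        return (self.calls != MISSING).mean(axis=1)

    def alt_freq(self) -> np.ndarray:
        """ALT-allele frequency per variant over non-missing calls (NaN if none)."""
        called = self.calls != MISSING
        n = called.sum(axis=1)
        alt = np.where(called, self.calls, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / (2.0 * n), np.nan)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per variant (fold of :meth:`alt_freq`)."""
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def sample_call_rate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=0)

    # -- subsetting ---------------------------------------------------------
    def subset_variants(self, index: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            [self.variants[i] for i in index], self.samples, self.calls[index]
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in sample_ids]
        return GenotypeMatrix(self.variants, list(sample_ids), self.calls[:, idx])


class PosteriorMatrix:
    """Genotype posterior probability triplets for variants x samples.

    Triplets are renormalized on construction when their sum is within
    ``1 +- 1e-4`` of one; larger deviations must be handled by the reader
    (readers accept ``1 +- 0.05`` and renormalize, else raise).
    """

    def __init__(
        self,
        variants: Sequence[VariantRecord],
        samples: Sequence[str],
        probs: np.ndarray,
        dosage_derived: bool = False,
    ) -> None:
        probs = np.asarray(probs, dtype=np.float64)
        if probs.shape != (len(variants), len(samples), 3):
            raise ValueError(
                f"probs shape {probs.shape} != "
                f"({len(variants)}, {len(samples)}, 3)"
            )
        if (probs < 0).any():
            raise ValueError("posterior probabilities must be non-negative")
        s = probs.sum(axis=2)
        if np.abs(s - 1.0).max() > _TRIPLET_EPS:
            raise ValueError("posterior triplets must sum to 1 within 1e-4")
        _check_variants(variants)
        self.variants = list(variants)
        self.samples = list(samples)
        self.probs = probs / s[:, :, None]
        self.dosage_derived = bool(dosage_derived)
        #: harmonization bookkeeping, populated by :func:`align_alleles`
        self.align_log: dict[str, int] = {}

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def vids(self) -> list[str]:
        return [v.vid for v in self.variants]

    def dosages(self) -> np.ndarray:
        """Expected ALT dosage per cell: ``p1 + 2*p2``, always in [0, 2]."""
        return self.probs[:, :, 1] + 2.0 * self.probs[:, :, 2]

    def to_dosage_matrix(self) -> "DosageMatrix":
        return DosageMatrix(self.variants, self.samples, self.dosages())

    def subset_variants(self, index: np.ndarray | Sequence[int]) -> "PosteriorMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return PosteriorMatrix(
            [self.variants[i] for i in index],
            self.samples,
            self.probs[index],
            dosage_derived=self.dosage_derived,
        )


class DosageMatrix:
    """Expected ALT-allele dosages in [0, 2] for variants x samples."""

    def __init__(
        self,
        variants: Sequence[VariantRecord],
        samples: Sequence[str],
        dosage: np.ndarray,
    ) -> None:
        dosage = np.asarray(dosage, dtype=np.float64)
        if dosage.shape != (len(variants), len(samples)):
            raise ValueError("dosage shape mismatch")
        if (dosage < 0).any() or (dosage > 2).any():
            raise ValueError("dosages must lie in [0, 2]")
        _check_variants(variants)
        self.variants = list(variants)
        self.samples = list(samples)
        self.dosage = dosage


# ---------------------------------------------------------------------------
# dosage <-> posterior conversion
# ---------------------------------------------------------------------------

def dosage_to_posterior(d: np.ndarray) -> np.ndarray:
    """Expand dosages to degenerate posteriors on the adjacent integers.

    A dosage ``d`` in ``[g, g+1]`` becomes mass ``1 - frac`` on genotype ``g``
    and ``frac = d - g`` on ``g + 1``, which preserves ``d = p1 + 2*p2``.
    The expansion is information-losing: any posterior with the same mean
    collapses to this one.
    """
    d = np.asarray(d, dtype=np.float64)
    lo = np.clip(np.floor(d).astype(int), 0, 1)  # d == 2 anchors at g=1
    frac = d - lo
    out = np.zeros(d.shape + (3,))
    idx = np.indices(d.shape)
    out[(*idx, lo)] = 1.0 - frac
    out[(*idx, lo + 1)] = frac
    return out


# ---------------------------------------------------------------------------
# genotype readers / writers
# ---------------------------------------------------------------------------

def _snv_ok(ref: str, alts: Sequence[str]) -> bool:
    return (
        len(alts) == 1
        and len(ref) == 1
        and len(alts[0]) == 1
        and ref in _BASES
        and alts[0] in _BASES
        and ref != alts[0]
    )


def _read_vcf_gt(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=False)
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    skipped = 0
    for rec in vcf:
        if not _snv_ok(rec.REF, rec.ALT):
            skipped += 1
            continue
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        variants.append(
            VariantRecord(str(rec.CHROM), rec.POS, vid, rec.REF, rec.ALT[0])
        )
        row = np.full(len(samples), MISSING, dtype=np.int8)
        for j, g in enumerate(rec.genotypes):
            a = g[:-1]  # drop phase flag
            if len(a) != 2 or a[0] < 0 or a[1] < 0:
                continue  # half-missing or haploid -> MISSING
            row[j] = int(a[0] == 1) + int(a[1] == 1)
        rows.append(row)
    vcf.close()
    if skipped:
        logger.info("read_genotypes(%s): skipped %d non-SNV records", path, skipped)
    if not variants:
        raise EmptyDatasetError(f"no biallelic SNVs in {path}")
    return GenotypeMatrix(variants, samples, np.array(rows, dtype=np.int8))


_MISSING_TOKENS = {".", "./.", ".|.", "NA", "-1"}


def _read_matrix_text(path: str) -> GenotypeMatrix:
    variants: list[VariantRecord] = []
    rows: list[list[int]] = []
    skipped = 0
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) < 6 or header[0].lstrip("#") != "chrom":
            raise MalformedRecordError(
                f"{path}: expected header 'chrom pos vid ref alt <samples...>'"
            )
        samples = header[5:]
        for ln, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 5 + len(samples):
                raise MalformedRecordError(f"{path}:{ln}: wrong column count")
            chrom, pos, vid, ref, alt = parts[:5]
            if not (len(ref) == 1 and len(alt) == 1 and ref in _BASES and alt in _BASES and ref != alt):
                skipped += 1
                continue
            variants.append(VariantRecord(chrom, int(pos), vid, ref, alt))
            rows.append(
                [MISSING if tok in _MISSING_TOKENS else int(tok) for tok in parts[5:]]
            )
    if skipped:
        logger.info("read_genotypes(%s): skipped %d non-SNV rows", path, skipped)
    if not variants:
        raise EmptyDatasetError(f"no variants in {path}")
    return GenotypeMatrix(variants, samples, np.array(rows, dtype=np.int8))


def read_genotypes(path: str, format: str = "vcf") -> GenotypeMatrix:
    """Read discrete genotypes from ``vcf`` or site-major ``matrix-text``."""
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    if format == "vcf":
        return _read_vcf_gt(path)
    if format == "matrix-text":
        return _read_matrix_text(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def write_genotypes(g: GenotypeMatrix, path: str, format: str = "matrix-text") -> None:
    if format == "matrix-text":
        with open(path, "w") as fh:
            fh.write("#chrom\tpos\tvid\tref\talt\t" + "\t".join(g.samples) + "\n")
            for v, row in zip(g.variants, g.calls):
                cells = "\t".join("." if c == MISSING else str(int(c)) for c in row)
                fh.write(f"{v.chrom}\t{v.pos}\t{v.vid}\t{v.ref}\t{v.alt}\t{cells}\n")
        return
    if format == "vcf":
        _GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for chrom in dict.fromkeys(v.chrom for v in g.variants):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(g.samples)
                + "\n"
            )
            for v, row in zip(g.variants, g.calls):
                cells = "\t".join(_GT[int(c)] for c in row)
                fh.write(
                    f"{v.chrom}\t{v.pos}\t{v.vid}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{cells}\n"
                )
        return
    raise ValueError(f"unknown genotype format: {format!r}")


# ---------------------------------------------------------------------------
# imputed (posterior / dosage) readers / writers
# ---------------------------------------------------------------------------

def _normalize_triplets(raw: np.ndarray, where: str) -> np.ndarray:
    if (raw < 0).any():
        raise MalformedRecordError(f"{where}: negative probability entries")
    s = raw.sum(axis=-1)
    if (s <= 1e-6).any():
        raise MalformedRecordError(f"{where}: probability triplet with zero mass")
    off = np.abs(s - 1.0) > _TRIPLET_SUM_TOL
    if off.any():
        # tolerated and renormalized: some tools emit unnormalized triplets
        logger.warning(
            "%s: %d triplets with sum outside [%.2f, %.2f]; renormalized",
            where, int(off.sum()), 1 - _TRIPLET_SUM_TOL, 1 + _TRIPLET_SUM_TOL,
        )
    return raw / s[..., None]


def _read_gen(path: str) -> PosteriorMatrix:
    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    n_samples = None
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            chrom, vid, pos, ref, alt = parts[:5]
            vals = np.array(parts[5:], dtype=np.float64)
            if vals.size % 3 != 0:
                raise MalformedRecordError(f"{path}:{ln}: triplet count not divisible by 3")
            if n_samples is None:
                n_samples = vals.size // 3
            elif vals.size // 3 != n_samples:
                raise MalformedRecordError(f"{path}:{ln}: inconsistent sample count")
            variants.append(VariantRecord(chrom, int(pos), vid, ref, alt))
            rows.append(vals.reshape(-1, 3))
    if not variants:
        raise EmptyDatasetError(f"no records in {path}")
    probs = _normalize_triplets(np.array(rows), path)
    samples = [f"S{i + 1}" for i in range(n_samples)]
    return PosteriorMatrix(variants, samples, probs)


def _mlinfo_path(path: str) -> str:
    if path.endswith(".mldose"):
        return path[: -len(".mldose")] + ".mlinfo"
    return path + ".mlinfo"


def _read_mldose(path: str) -> PosteriorMatrix:
    info = _mlinfo_path(path)
    if not os.path.exists(info):
        raise IOError(f"missing .mlinfo sidecar for {path}: {info}")
    variants: list[VariantRecord] = []
    with open(info) as fh:
        header = fh.readline().split()
        if not header or header[0] != "SNP":
            raise MalformedRecordError(f"{info}: expected header starting with 'SNP'")
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            chrom, pos, vid = parts[0].split(":", 2)
            variants.append(VariantRecord(chrom, int(pos), vid, parts[1], parts[2]))
    samples: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            sid = parts[0].split("->")[-1]
            if parts[1] not in ("MLDOSE", "ML_DOSE"):
                raise MalformedRecordError(f"{path}:{ln}: expected MLDOSE marker")
            d = np.array(parts[2:], dtype=np.float64)
            if d.size != len(variants):
                raise MalformedRecordError(
                    f"{path}:{ln}: {d.size} dosages for {len(variants)} variants"
                )
            samples.append(sid)
            rows.append(d)
    if not samples:
        raise EmptyDatasetError(f"no samples in {path}")
    dosage = np.array(rows).T  # to site-major
    if (dosage < 0).any() or (dosage > 2).any():
        raise MalformedRecordError(f"{path}: dosages outside [0, 2]")
    return PosteriorMatrix(
        variants, samples, dosage_to_posterior(dosage), dosage_derived=True
    )


def _read_vcf_gp(path: str) -> PosteriorMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    skipped = 0
    dosage_derived = False
    for rec in vcf:
        if not _snv_ok(rec.REF, rec.ALT):
            skipped += 1
            continue
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        variants.append(
            VariantRecord(str(rec.CHROM), rec.POS, vid, rec.REF, rec.ALT[0])
        )
        gp = rec.format("GP")
        if gp is not None:
            rows.append(np.asarray(gp, dtype=np.float64))
        else:
            ds = rec.format("DS")
            if ds is None:
                raise MalformedRecordError(
                    f"{path}: record {vid} has neither GP nor DS"
                )
            dosage_derived = True
            rows.append(dosage_to_posterior(np.asarray(ds, dtype=np.float64)[:, 0]))
    vcf.close()
    if skipped:
        logger.info("read_imputed(%s): skipped %d non-SNV records", path, skipped)
    if not variants:
        raise EmptyDatasetError(f"no biallelic SNVs in {path}")
    probs = _normalize_triplets(np.array(rows), path)
    return PosteriorMatrix(variants, samples, probs, dosage_derived=dosage_derived)


def read_imputed(path: str, format: str = "gen-triplet") -> PosteriorMatrix:
    """Read imputation output as a :class:`PosteriorMatrix`.

    ``gen-triplet`` — IMPUTE2-style GEN text (chrom vid pos ref alt + triplets);
    ``dosage`` — MaCH-style .mldose/.mlinfo pair, expanded to adjacent-integer
    posteriors and flagged ``dosage_derived``; ``vcf-gp`` — VCF with GP (or DS)
    FORMAT fields.
    """
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    if format == "gen-triplet":
        return _read_gen(path)
    if format == "dosage":
        return _read_mldose(path)
    if format == "vcf-gp":
        return _read_vcf_gp(path)
    raise ValueError(f"unknown imputed format: {format!r}")


def write_imputed(p: PosteriorMatrix, path: str, format: str = "gen-triplet") -> None:
    if format == "gen-triplet":
        with open(path, "w") as fh:
            for v, row in zip(p.variants, p.probs):
                cells = " ".join(f"{x:.6f}" for x in row.ravel())
                fh.write(f"{v.chrom} {v.vid} {v.pos} {v.ref} {v.alt} {cells}\n")
        return
    if format == "dosage":
        dosage = p.dosages()
        with open(_mlinfo_path(path), "w") as fh:
            fh.write("SNP\tAl1\tAl2\n")
            for v in p.variants:
                fh.write(f"{v.chrom}:{v.pos}:{v.vid}\t{v.ref}\t{v.alt}\n")
        with open(path, "w") as fh:
            for j, sid in enumerate(p.samples):
                cells = "\t".join(f"{x:.6f}" for x in dosage[:, j])
                fh.write(f"{sid}->{sid}\tMLDOSE\t{cells}\n")
        return
    if format == "vcf-gp":
        dosage = p.dosages()
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(
                '##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype probabilities">\n'
            )
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
            for chrom in dict.fromkeys(v.chrom for v in p.variants):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(p.samples)
                + "\n"
            )
            for i, v in enumerate(p.variants):
                cells = "\t".join(
                    f"{p.probs[i, j, 0]:.6f},{p.probs[i, j, 1]:.6f},"
                    f"{p.probs[i, j, 2]:.6f}:{dosage[i, j]:.6f}"
                    for j in range(p.n_samples)
                )
                fh.write(
                    f"{v.chrom}\t{v.pos}\t{v.vid}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGP:DS\t{cells}\n"
                )
        return
    raise ValueError(f"unknown imputed format: {format!r}")


# ---------------------------------------------------------------------------
# allele harmonization
# ---------------------------------------------------------------------------

def align_alleles(imputed: PosteriorMatrix, truth: GenotypeMatrix) -> PosteriorMatrix:
    """Restrict ``imputed`` to variants shared with ``truth``, harmonizing alleles.

    Variants are matched on (chrom, pos).  If the imputed REF/ALT are swapped
    relative to truth, triplets are reversed (p0 <-> p2); if they match only
    after strand complement, the complement is applied and then swap-checked.
    Strand-ambiguous pairs (A/T, C/G) are matched by allele label only and
    excluded when labels disagree.  Unmatched variants are dropped; counts are
    recorded on the returned matrix's ``align_log`` and logged.

    The operation is idempotent and preserves per-variant dosage under double
    application (swapping twice is the identity).
    """
    if imputed.n_variants == 0 or truth.n_variants == 0:
        raise EmptyDatasetError("align_alleles requires non-empty inputs")
    by_locus = {(v.chrom, v.pos): v for v in truth.variants}
    keep_idx: list[int] = []
    keep_var: list[VariantRecord] = []
    swap: list[bool] = []
    log = {"matched": 0, "swapped": 0, "complemented": 0, "ambiguous_excluded": 0,
           "mismatch_excluded": 0, "unmatched": 0}
    for i, v in enumerate(imputed.variants):
        t = by_locus.get((v.chrom, v.pos))
        if t is None:
            log["unmatched"] += 1
            continue
        if t.is_strand_ambiguous or v.is_strand_ambiguous:
            if (v.ref, v.alt) == (t.ref, t.alt):
                keep_idx.append(i)
                keep_var.append(t)
                swap.append(False)
                log["matched"] += 1
            else:
                log["ambiguous_excluded"] += 1
            continue
        pair = (v.ref, v.alt)
        comp = (_COMPLEMENT[v.ref], _COMPLEMENT[v.alt])
        if pair == (t.ref, t.alt):
            s = False
        elif pair == (t.alt, t.ref):
            s = True
            log["swapped"] += 1
        elif comp == (t.ref, t.alt):
            s = False
            log["complemented"] += 1
        elif comp == (t.alt, t.ref):
            s = True
            log["complemented"] += 1
            log["swapped"] += 1
        else:
            log["mismatch_excluded"] += 1
            continue
        keep_idx.append(i)
        keep_var.append(t)
        swap.append(s)
        log["matched"] += 1
    if not keep_idx:
        raise EmptyDatasetError("align_alleles: no variants matched")
    probs = imputed.probs[keep_idx].copy()
    swap_arr = np.asarray(swap)
    probs[swap_arr] = probs[swap_arr][:, :, ::-1]
    logger.info("align_alleles: %s", log)
    out = PosteriorMatrix(
        keep_var, imputed.samples, probs, dosage_derived=imputed.dosage_derived
    )
    out.align_log = log
    return out
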