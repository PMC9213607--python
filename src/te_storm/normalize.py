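"""Per-sample abundance scaling, expression filtering, and TMM factors.

Two abundance scalings are provided.  ``tpm_as_stated`` divides each
locus count by the sample's total count and multiplies by one million —
formally a CPM, with no length term — and is the pipeline default.
``tpm_length_normalized`` is the conventional length-normalized TPM and is
available behind a flag.  Cross-sample normalization uses TMM (trimmed
mean of M-values): for each sample against a reference, per-gene log
ratios M and log abundances A are doubly trimmed and the factor is the
inverse-variance weighted mean of the surviving M values, with factors
rescaled to geometric mean one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, UsageError


@dataclass
class ExpressionMatrix:
    """Locus x sample counts plus the sample sheet and locus lengths."""

    counts: pd.DataFrame
    meta: pd.DataFrame
    lengths: pd.Series | None = None

    def __post_init__(self):
        if not self.counts.index.is_unique:
            raise InputError("locus ids in the count matrix must be unique")
        if "sample_id" in self.meta.columns:
            missing = set(self.counts.columns) - set(self.meta["sample_id"])
            if missing:
                raise InputError(
                    f"samples missing from metadata: {sorted(missing)[:5]}"
                )

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        meta = self.meta[self.meta["sample_id"].isin(sample_ids)].reset_index(drop=True)
        return ExpressionMatrix(
            counts=self.counts[list(sample_ids)], meta=meta, lengths=self.lengths
        )


@dataclass
class NormalizationFactors:
    """TMM factors plus the per-gene audit trail of the computation."""

    factors: pd.Series
    reference_sample: str
    #: sample -> DataFrame with columns M, A, w, kept (post-trim indicator)
    audit: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self):
        if (self.factors <= 0).any():
            raise InputError("all TMM factors must be positive")
        gm = float(np.exp(np.log(self.factors).mean()))
        if abs(gm - 1.0) > 1e-9:
            raise InputError(f"TMM factors must have geometric mean 1, got {gm}")


def tpm_as_stated(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts scaled to parts-per-million of the sample total (length-free)."""
    lib = counts.sum(axis=0)
    zero = lib[lib <= 0]
    if len(zero):
        raise InputError(
            f"samples with zero total counts: {list(zero.index)}"
        )
    return counts / lib * 1e6


def tpm_length_normalized(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Length-normalized TPM: per-length read rate rescaled to 1e6 per sample."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        bad = lengths.index[lengths.isna() | (lengths <= 0)]
        raise InputError(f"missing/zero lengths for loci: {list(bad[:5])}")
    rate = counts.div(lengths, axis=0)
    total = rate.sum(axis=0)
    if (total <= 0).any():
        raise InputError("samples with zero total rate")
    return rate / total * 1e6


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    return tpm_as_stated(counts)


def expression_filter(
    counts: pd.DataFrame, min_cpm: float = 1.0, min_samples: int = 2
) -> pd.Index:
    """Loci with CPM >= min_cpm in at least min_samples samples (raw lib sizes)."""
    c = cpm(counts)
    keep = (c >= min_cpm).sum(axis=1) >= min_samples
    return counts.index[keep]


def _choose_reference(counts: pd.DataFrame) -> str:
    """Sample whose upper-quartile CPM is closest to the mean of those quartiles."""
    c = cpm(counts)
    q75 = c.apply(lambda col: np.percentile(col[col > 0], 75) if (col > 0).any() else 0.0)
    return str((q75 - q75.mean()).abs().idxmin())


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref: str | None = None,
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values normalization factors.

    For sample k against reference r, over loci with positive counts in
    both: ``M = log2((y_k/N_k)/(y_r/N_r))``, ``A = 0.5*log2((y_k/N_k)*(y_r/N_r))``,
    ``w = (N_k-y_k)/(N_k*y_k) + (N_r-y_r)/(N_r*y_r)`` (delta-method variance
    of M).  The top and bottom ``trim_m`` fraction by M and ``trim_a`` by A
    are discarded and ``log2(f_k)`` is the 1/w-weighted mean of the
    remaining M.  Factors are rescaled to geometric mean one.
    """
    if counts.shape[1] < 2:
        raise UsageError("TMM needs at least 2 samples")
    if ref is None:
        ref = _choose_reference(counts)
    elif ref not in counts.columns:
        raise UsageError(f"reference sample {ref!r} not in matrix")
    lib = counts.sum(axis=0).astype(float)
    yr = counts[ref].to_numpy(dtype=float)
    Nr = float(lib[ref])
    log2f: dict[str, float] = {}
    audit: dict[str, pd.DataFrame] = {}
    for k in counts.columns:
        yk = counts[k].to_numpy(dtype=float)
        Nk = float(lib[k])
        if k == ref:
            log2f[k] = 0.0
            continue
        ok = (yk > 0) & (yr > 0)
        if not ok.any():
            warnings.warn(f"sample {k}: no loci shared with reference; factor 1")
            log2f[k] = 0.0
            continue
        pk, pr = yk[ok] / Nk, yr[ok] / Nr
        M = np.log2(pk / pr)
        A = 0.5 * np.log2(pk * pr)
        w = (Nk - yk[ok]) / (Nk * yk[ok]) + (Nr - yr[ok]) / (Nr * yr[ok])
        n = ok.sum()
        # double trimming by rank, keeping the central band on both axes
        rM = pd.Series(M).rank().to_numpy()
        rA = pd.Series(A).rank().to_numpy()
        loM = np.floor(n * trim_m) + 1
        hiM = n + 1 - loM
        loA = np.floor(n * trim_a) + 1
        hiA = n + 1 - loA
        kept = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
        kept &= np.isfinite(M) & np.isfinite(A) & (w > 0)
        audit[k] = pd.DataFrame(
            {"M": M, "A": A, "w": w, "kept": kept},
            index=counts.index[ok],
        )
        if not kept.any():
            warnings.warn(f"sample {k}: no loci survive trimming; factor 1")
            log2f[k] = 0.0
            continue
        inv_w = 1.0 / w[kept]
        log2f[k] = float(np.sum(inv_w * M[kept]) / np.sum(inv_w))
    f = pd.Series({k: 2.0 ** v for k, v in log2f.items()})[counts.columns]
    f = f / np.exp(np.log(f).mean())
    return NormalizationFactors(factors=f, reference_sample=ref, audit=audit)


def logcpm(
    counts: pd.DataFrame,
    factors: pd.Series | NormalizationFactors | None = None,
    prior: float = 0.5,
) -> pd.DataFrame:
    """log2 counts per million on effective library sizes N*f, with a prior."""
    lib = counts.sum(axis=0).astype(float)
    if factors is None:
        eff = lib
    else:
        f = factors.factors if isinstance(factors, NormalizationFactors) else factors
        eff = lib * f[counts.columns]
    return np.log2((counts + prior).div(eff + 2 * prior, axis=1) * 1e6)
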