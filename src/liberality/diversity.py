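"""Transcriptome diversity: occupation rates and Shannon entropy per sample.

A sample's *occupation rates* are each gene's share of the total mapped
reads, i.e. the probability vector p over genes. The Shannon entropy of
that vector,

    H = -sum_i p_i * log2(p_i)        (bits; terms with p_i = 0 contribute 0)

is the transcriptome diversity index used here as a quantitative measure
of cellular (de)differentiation, termed *liberality*: a differentiated
cell concentrates expression on few genes (low H), a dedifferentiating
cell flattens its expression profile (high H). Dedifferentiation is an
increase in H; differentiation is a decrease.

Entropy is computed over the genes observed (nonzero) in each sample;
zero-count genes contribute nothing either way. No pseudocounts are added,
which preserves exact scale invariance. The plug-in estimator is known to
be negatively biased at finite library size; the Miller-Madow correction
``H + (m - 1) / (2 N ln 2)`` is offered as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyLibraryError, ValidationError
from .io import CountMatrix

__all__ = [
    "OccupationProfile",
    "DiversityResult",
    "occupation_rates",
    "shannon_entropy",
    "miller_madow_correct",
    "diversity_table",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class DiversityResult:
    """Per-sample diversity summary.

    ``H_bits`` is the Shannon entropy (in the log base used, bits by
    default), ``G_total`` the annotated gene count of the matrix, ``m``
    the observed (nonzero) gene count, ``N`` the library size,
    ``evenness = H / log2(m)`` (NaN for m < 2) and
    ``effective_genes = 2**H``, the number of equally expressed genes
    yielding the same entropy.
    """

    sample_id: str
    H_bits: float
    estimator: str
    G_total: int
    m: int
    N: float
    evenness: float
    effective_genes: float


@dataclass(frozen=True)
class OccupationProfile:
    """A probability vector over genes (occupation rate per gene)."""

    gene_ids: tuple[str, ...]
    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        if len(self.gene_ids) != p.size:
            raise ValidationError("gene_ids and p have different lengths")
        if (p < 0).any() or not np.isfinite(p).all():
            raise ValidationError("occupation rates must be finite and >= 0")
        if abs(p.sum() - 1.0) > _SUM_TOL:
            raise ValidationError(f"occupation rates sum to {p.sum()!r}, not 1")


def occupation_rates(
    counts_column: np.ndarray,
    gene_ids: tuple[str, ...] | None = None,
    sample_id: str = "<sample>",
) -> OccupationProfile:
    """Normalize a count vector to occupation rates, preserving gene order.

    Raises :class:`EmptyLibraryError` (naming the sample) on an all-zero
    column.
    """
    c = np.asarray(counts_column, dtype=float)
    if c.ndim != 1:
        raise ValidationError("counts_column must be one-dimensional")
    if (c < 0).any() or not np.isfinite(c).all():
        raise ValidationError(f"sample {sample_id!r}: counts must be finite and >= 0")
    total = c.sum()
    if total <= 0:
        raise EmptyLibraryError(f"sample {sample_id!r} has zero total counts")
    if gene_ids is None:
        gene_ids = tuple(f"g{i}" for i in range(c.size))
    return OccupationProfile(gene_ids, c / total)


def shannon_entropy(profile, base: float = 2.0) -> float:
    """Plug-in Shannon entropy of an occupation profile.

    Accepts an :class:`OccupationProfile` or a bare probability vector.
    ``0 * log 0`` is defined as 0. Base 2 gives bits (the default);
    ``base=np.e`` gives nats.
    """
    p = profile.p if isinstance(profile, OccupationProfile) else np.asarray(
        profile, dtype=float
    )
    if not isinstance(profile, OccupationProfile):
        if (p < 0).any() or abs(p.sum() - 1.0) > _SUM_TOL:
            raise ValidationError("not a probability vector")
    nz = p[p > 0]
    return float(-(nz * (np.log(nz) / np.log(base))).sum())


def miller_madow_correct(
    H_plugin: float, m: int, N: float, base: float = 2.0
) -> float:
    """Miller-Madow bias correction: H + (m - 1) / (2 N ln(base)).

    ``m`` is the number of observed (nonzero) genes and ``N`` the library
    size. With m = 1 the correction vanishes.
    """
    if N <= 0:
        raise ValidationError("library size N must be positive")
    if m < 1:
        raise ValidationError("observed gene count m must be >= 1")
    return float(H_plugin + (m - 1) / (2.0 * N * np.log(base)))


def diversity_table(
    matrix: CountMatrix, estimator: str = "plugin", base: float = 2.0
) -> pd.DataFrame:
    """Per-sample diversity results for a count matrix.

    Returns a DataFrame with one row per sample and columns
    ``sample_id, H_bits, estimator, G_total, m, N, evenness,
    effective_genes`` where evenness = H / log2(m) and
    effective_genes = 2**H (base-2 analogues are used for other bases).
    Deterministic; propagates the empty-library error with the sample id.
    """
    if estimator not in ("plugin", "miller_madow"):
        raise ValidationError(f"unknown estimator {estimator!r}")
    rows = []
    for sid in matrix.sample_ids:
        col = matrix.column(sid)
        profile = occupation_rates(col, matrix.gene_ids, sample_id=sid)
        H = shannon_entropy(profile, base=base)
        m = int((col > 0).sum())
        N = float(col.sum())
        if estimator == "miller_madow":
            H = miller_madow_correct(H, m, N, base=base)
        log_m = np.log(m) / np.log(base) if m >= 2 else np.nan
        rows.append(
            DiversityResult(
                sample_id=sid,
                H_bits=H,
                estimator=estimator,
                G_total=matrix.n_genes,
                m=m,
                N=N,
                evenness=H / log_m if m >= 2 else float("nan"),
                effective_genes=float(base**H),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
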