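"""Count normalization: upper-quantile scaling followed by Box-Cox.

Raw barcode counts are scaled so every sample shares the same upper
quantile (default 75th percentile of its nonzero counts), then power
transformed, y -> ((y + pseudocount)^lambda - 1) / lambda, to bring the
response close enough to normal for the downstream linear regression.
The Box-Cox exponent can be fixed (the screen analysis used a value
near 0.5, i.e. approximately a square-root transform) or estimated by
maximizing the profile log-likelihood over a grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .quant import CountMatrix, SampleKey

__all__ = [
    "NormalizeError",
    "NormalizedMatrix",
    "LambdaProfile",
    "upper_quantile_normalize",
    "boxcox_transform",
    "estimate_lambda",
    "normalize_counts",
    "normality_diagnostics",
]


class NormalizeError(ValueError):
    pass


@dataclass
class LambdaProfile:
    """Grid maximum of the Box-Cox profile log-likelihood."""

    lmbda: float
    grid: np.ndarray
    loglik: np.ndarray
    degenerate: bool = False


@dataclass
class NormalizedMatrix:
    """Transformed shRNA x sample matrix with its normalization provenance."""

    values: pd.DataFrame
    samples: list[SampleKey]
    lmbda: float
    pseudocount: float
    uq_factors: pd.Series

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise NormalizeError("non-finite normalized values")
        if (self.uq_factors <= 0).any():
            raise NormalizeError("non-positive upper-quantile factor")

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write(
                f"# lambda={self.lmbda!r} pseudocount={self.pseudocount!r}\n"
            )
            fh.write(f"# index_seqs={';'.join(s.index_seq for s in self.samples)}\n")
            self.values.to_csv(fh, sep="\t", index_label="shrna_id")

    @classmethod
    def from_tsv(cls, path) -> "NormalizedMatrix":
        lmbda, pseudocount = 0.5, 1.0
        index_seqs = None
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if line.startswith("# lambda="):
                    parts = dict(p.split("=") for p in line[2:].split())
                    lmbda = float(parts["lambda"])
                    pseudocount = float(parts["pseudocount"])
                if line.startswith("# index_seqs="):
                    index_seqs = line.strip().split("=", 1)[1].split(";")
        values = pd.read_csv(path, sep="\t", comment="#", index_col="shrna_id")
        if index_seqs is None:
            index_seqs = ["A" * 8] * len(values.columns)
        samples = [
            SampleKey.from_label(lab, seq)
            for lab, seq in zip(values.columns, index_seqs)
        ]
        factors = pd.Series(1.0, index=values.columns)
        return cls(values, samples, lmbda, pseudocount, factors)


def _upper_quantiles(values: pd.DataFrame, quantile: float) -> pd.Series:
    """Per-sample quantile of the nonzero counts."""
    qs = {}
    for col in values.columns:
        nonzero = values[col].to_numpy(dtype=float)
        nonzero = nonzero[nonzero > 0]
        if nonzero.size == 0:
            raise NormalizeError(f"sample {col!r} has no nonzero counts")
        qs[col] = float(np.quantile(nonzero, quantile))
    return pd.Series(qs)


def upper_quantile_normalize(
    counts: CountMatrix | pd.DataFrame, quantile: float = 0.75
) -> tuple[pd.DataFrame, pd.Series]:
    """Scale each sample so its upper quantile of nonzero counts is equal.

    Counts are divided by the sample's quantile and rescaled by the
    geometric mean of all samples' quantiles, keeping the output on a
    count-like scale. Returns the scaled matrix and the per-sample
    quantile factors. A sample with no nonzero counts is an error.
    """
    values = counts.values if isinstance(counts, CountMatrix) else counts
    if not 0 < quantile < 1:
        raise NormalizeError(f"quantile {quantile} outside (0, 1)")
    qs = _upper_quantiles(values, quantile)
    target = float(np.exp(np.log(qs).mean()))
    scaled = values.astype(float).div(qs, axis=1) * target
    return scaled, qs


def boxcox_transform(
    values: np.ndarray | pd.DataFrame, lmbda: float, pseudocount: float = 0.0
) -> np.ndarray | pd.DataFrame:
    """Box-Cox power transform of (values + pseudocount).

    ((y + c)^lambda - 1) / lambda for lambda != 0; ln(y + c) at
    lambda = 0. Strictly monotone in y; requires y + c > 0.
    """
    arr = values.to_numpy() if isinstance(values, pd.DataFrame) else np.asarray(values)
    shifted = arr + pseudocount
    if (shifted <= 0).any():
        raise NormalizeError("Box-Cox input must be positive after pseudocount shift")
    # scipy's boxcox evaluates ((y^l - 1)/l) stably through the l -> 0 limit
    out = special.boxcox(shifted, lmbda)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def estimate_lambda(
    values: np.ndarray | pd.DataFrame,
    pseudocount: float = 1.0,
    grid: tuple[float, float, float] = (-2.0, 2.0, 0.01),
    default: float = 0.5,
) -> LambdaProfile:
    """Profile-likelihood grid estimate of the Box-Cox exponent.

    All matrix entries are pooled as one sample. On degenerate input
    (a single distinct value) the supplied default is returned with a
    warning and the profile flagged degenerate.
    """
    arr = np.asarray(
        values.to_numpy() if isinstance(values, pd.DataFrame) else values, dtype=float
    ).ravel()
    shifted = arr + pseudocount
    if (shifted <= 0).any():
        raise NormalizeError("lambda estimation requires positive shifted values")
    lo, hi, step = grid
    lams = np.arange(lo, hi + step / 2, step)
    if np.unique(shifted).size < 2:
        warnings.warn(
            f"degenerate input for lambda estimation; using default {default}",
            stacklevel=2,
        )
        return LambdaProfile(default, lams, np.full_like(lams, np.nan), degenerate=True)
    llf = np.array([stats.boxcox_llf(l, shifted) for l in lams])
    return LambdaProfile(float(lams[int(np.argmax(llf))]), lams, llf)


def normalize_counts(
    counts: CountMatrix,
    lmbda: float | str = "auto",
    pseudocount: float = 1.0,
    quantile: float = 0.75,
) -> NormalizedMatrix:
    """Full normalization pipeline: upper-quantile scaling then Box-Cox.

    ``lmbda="auto"`` estimates the exponent from the scaled matrix;
    pass ``0.5`` to reproduce the square-root-like transform used in
    the original screen analysis.
    """
    scaled, qs = upper_quantile_normalize(counts, quantile)
    if lmbda == "auto":
        lmbda_val = estimate_lambda(scaled, pseudocount).lmbda
    else:
        lmbda_val = float(lmbda)
    transformed = boxcox_transform(scaled, lmbda_val, pseudocount)
    return NormalizedMatrix(transformed, counts.samples, lmbda_val, pseudocount, qs)


def normality_diagnostics(residuals_by_gene) -> pd.DataFrame:
    """Shapiro-Wilk, skewness and excess kurtosis of pooled per-gene residuals.

    Diagnostic only; never gates the analysis. Genes with fewer than 3
    residuals, or constant residuals, are flagged skipped.
    """
    rows = []
    for gene, resid in residuals_by_gene.items():
        resid = np.asarray(resid, dtype=float)
        if resid.size < 3 or np.ptp(resid) == 0:
            rows.append(
                {
                    "gene": gene,
                    "n": int(resid.size),
                    "shapiro_stat": np.nan,
                    "shapiro_p": np.nan,
                    "skewness": np.nan,
                    "kurtosis": np.nan,
                    "skipped": True,
                }
            )
            continue
        stat, p = stats.shapiro(resid)
        rows.append(
            {
                "gene": gene,
                "n": int(resid.size),
                "shapiro_stat": float(stat),
                "shapiro_p": float(p),
                "skewness": float(stats.skew(resid)),
                "kurtosis": float(stats.kurtosis(resid)),
                "skipped": False,
            }
        )
    return pd.DataFrame(rows).set_index("gene")
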