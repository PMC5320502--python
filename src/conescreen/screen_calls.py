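"""Gene-level calls: evidence strata, p-value adjustment, GSE filter.

Per-gene test statistics across the panel of cancer cell lines are
turned into evidence groups: with k the number of cancer lines where
-2ln(LRT) > 0, a gene is group 1 (k = 4), group 2 (k = 3), group 3
(k = 2), or group 4 (k = 1 and that single line's statistic exceeds a
stringency threshold, default 0.1); otherwise none. The module also
wraps standard multiple-testing adjustments and the upstream genetic
suppressor element (GSE) enrichment filter used to pick library
candidates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CallError",
    "stratify_genes",
    "adjust_pvalues",
    "gse_enrichment_filter",
]

GROUP4_THRESHOLD = 0.1

_METHODS = {"benjamini-hochberg": "fdr_bh", "bh": "fdr_bh", "holm": "holm"}


class CallError(ValueError):
    pass


def stratify_genes(
    t0: pd.DataFrame, group4_threshold: float = GROUP4_THRESHOLD
) -> pd.DataFrame:
    """Assign evidence groups from a genes x cancer-lines table of T0.

    Returns a frame indexed by gene with columns ``k`` (number of lines
    with T0 > 0), ``max_T0``, ``group`` in {"1","2","3","4","none"},
    and ``flagged`` (True when a gene is missing a line's statistic; a
    flagged gene is never grouped). Exactly one label per gene.
    """
    if t0.shape[1] < 1:
        raise CallError("empty statistic table")
    arr = t0.to_numpy(dtype=float)
    missing = ~np.isfinite(arr) & ~np.isposinf(arr)
    rows = []
    for i, gene in enumerate(t0.index):
        vals = arr[i]
        if missing[i].any():
            rows.append(
                {"gene": gene, "k": np.nan, "max_T0": np.nan,
                 "group": "none", "flagged": True}
            )
            continue
        k = int(np.count_nonzero(vals > 0))
        if k == 4:
            group = "1"
        elif k == 3:
            group = "2"
        elif k == 2:
            group = "3"
        elif k == 1 and float(vals.max()) > group4_threshold:
            group = "4"
        else:
            group = "none"
        rows.append(
            {"gene": gene, "k": k, "max_T0": float(np.max(vals)),
             "group": group, "flagged": False}
        )
    return pd.DataFrame(rows).set_index("gene")


def adjust_pvalues(p, method: str = "benjamini-hochberg") -> np.ndarray:
    """Multiple-testing adjustment (Benjamini-Hochberg step-up or Holm).

    Adjusted values are monotone in the raw values, bounded by 1, and
    never smaller than the raw p.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise CallError("p-values must lie in [0, 1]")
    key = method.lower()
    if key not in _METHODS:
        raise CallError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=_METHODS[key])[1]


def gse_enrichment_filter(
    counts: pd.DataFrame,
    n_gses: pd.Series,
    normal_line: str,
    fold: float = 1.5,
    min_lines: int = 2,
    min_gses: int = 2,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Candidate filter on per-gene GSE read counts.

    ``counts`` holds raw per-gene peak read counts (genes x cell
    lines, one column being the normal reference); counts are
    normalized to library size (column totals by default). Enrichment
    in a tumor line is the normalized tumor count over the normalized
    normal count (+inf when the normal count is zero). A gene passes
    iff enrichment > ``fold`` in at least ``min_lines`` tumor lines,
    or it was hit by at least ``min_gses`` distinct GSEs.

    Returns a frame with per-line enrichments, ``n_enriched_lines``,
    ``n_gses`` and the boolean ``candidate`` column.
    """
    if normal_line not in counts.columns:
        raise CallError(f"normal line {normal_line!r} not in count table")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    if (library_sizes <= 0).any():
        raise CallError("non-positive library size")
    norm = counts.div(library_sizes, axis=1)
    tumor_cols = [c for c in counts.columns if c != normal_line]
    ref = norm[normal_line].to_numpy()
    out = pd.DataFrame(index=counts.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        for col in tumor_cols:
            num = norm[col].to_numpy()
            enr = np.where(ref > 0, num / np.where(ref > 0, ref, 1.0),
                           np.where(num > 0, np.inf, 0.0))
            out[f"enrichment_{col}"] = enr
    enr_mat = out.to_numpy()
    out["n_enriched_lines"] = (enr_mat > fold).sum(axis=1)
    out["n_gses"] = n_gses.reindex(counts.index).fillna(0).astype(int)
    out["candidate"] = (out["n_enriched_lines"] >= min_lines) | (
        out["n_gses"] >= min_gses
    )
    return out
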