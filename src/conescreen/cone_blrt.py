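"""Cone-restricted bootstrap likelihood ratio test for dropout screens.

For one gene and one cancer cell line, the transformed barcode reads of
all hairpins targeting the gene are regressed on passage number
separately in the cancer line (slope b11) and the normal reference line
(slope b21), assuming Gaussian errors with a common variance. The
alternative hypothesis is the open cone

    b11 < 0  and  b11 < b21 < -b11,

i.e. the hairpins deplete in the cancer line while the normal line's
response is strictly less extreme. The null space is the complement of
the cone; its boundary is the pair of half-lines {b21 = -b11, b11 <= 0}
and {b21 = b11, b11 <= 0} meeting at the origin.

The test statistic is T0 = -2 ln LR = N * ln(RSS_restricted / RSS_unrestricted)
with N = n1 + n2. When the unrestricted slopes fall inside the cone, the
restricted (null) maximum-likelihood fit lies on the cone boundary; both
boundary lines admit closed-form constrained least-squares slopes, and
the smaller-RSS candidate is the restricted MLE (with the half-line
constraint b11 <= 0 enforced by clamping at the origin). Otherwise the
restricted fit equals the unrestricted one and T0 = 0.

Because the cone's vertex makes the usual chi-squared calibration
invalid, the null distribution of T0 is approximated by a residual
bootstrap: unrestricted residuals from both lines are pooled, resampled
with replacement into two groups, added to the restricted fitted
values, and the whole statistic is recomputed M times; the p-value is
the bootstrap tail probability of T0.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .manifest import LibraryManifest
from .normalize import NormalizedMatrix

__all__ = [
    "GeneObservations",
    "LineFit",
    "ConeTestResult",
    "ConeTestError",
    "fit_unrestricted",
    "in_alternative_region",
    "fit_restricted",
    "lrt_statistic",
    "bootstrap_pvalue",
    "test_gene",
    "build_gene_observations",
    "test_all_genes",
]

DEFAULT_BOOTSTRAP = 10_000


class ConeTestError(ValueError):
    pass


@dataclass
class GeneObservations:
    """Paired transformed-read vectors with passage covariates for one gene.

    ``cancer_y``/``cancer_x`` hold the n1 observations from the queried
    cancer line, ``normal_y``/``normal_x`` the n2 observations from the
    normal reference line; x is the passage number.
    """

    gene: str
    cancer_y: np.ndarray
    cancer_x: np.ndarray
    normal_y: np.ndarray
    normal_x: np.ndarray
    cell_line: str = ""

    def __post_init__(self) -> None:
        self.cancer_y = np.asarray(self.cancer_y, dtype=float)
        self.cancer_x = np.asarray(self.cancer_x, dtype=float)
        self.normal_y = np.asarray(self.normal_y, dtype=float)
        self.normal_x = np.asarray(self.normal_x, dtype=float)
        if self.cancer_y.shape != self.cancer_x.shape:
            raise ConeTestError(f"{self.gene}: cancer y/x length mismatch")
        if self.normal_y.shape != self.normal_x.shape:
            raise ConeTestError(f"{self.gene}: normal y/x length mismatch")
        if self.n1 < 3 or self.n2 < 3:
            raise ConeTestError(
                f"{self.gene}: need >= 3 observations per group "
                f"(n1={self.n1}, n2={self.n2})"
            )
        for name, x in (("cancer", self.cancer_x), ("normal", self.normal_x)):
            if np.unique(x).size < 2:
                raise ConeTestError(
                    f"{self.gene}: {name} passage covariate is constant"
                )

    @property
    def n1(self) -> int:
        return self.cancer_y.size

    @property
    def n2(self) -> int:
        return self.normal_y.size


@dataclass(frozen=True)
class LineFit:
    """Simple linear regression fit: y = intercept + slope * x."""

    intercept: float
    slope: float
    rss: float

    def fitted(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def residuals(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return np.asarray(y, dtype=float) - self.fitted(x)


@dataclass
class ConeTestResult:
    """Full result of the cone-restricted BLRT for one (gene, cancer line)."""

    gene: str
    cell_line: str
    n1: int
    n2: int
    unrestricted: tuple[LineFit, LineFit]
    restricted: tuple[LineFit, LineFit]
    sigma2_unrestricted: float
    sigma2_restricted: float
    in_region: bool
    T0: float
    M: int
    p_raw: float
    p_addone: float
    seed: int | None
    t0_infinite: bool = False

    @property
    def b11(self) -> float:
        return self.unrestricted[0].slope

    @property
    def b21(self) -> float:
        return self.unrestricted[1].slope

    @property
    def p_value(self) -> float:
        """Default p-value: the add-one bootstrap estimate, never exactly 0."""
        return self.p_addone


def _ols(x: np.ndarray, y: np.ndarray) -> LineFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise ConeTestError("degenerate covariate: single passage value")
    slope = float(xc @ (y - y.mean())) / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - intercept - slope * x
    return LineFit(intercept, slope, float(resid @ resid))


def fit_unrestricted(obs: GeneObservations) -> tuple[LineFit, LineFit, float]:
    """Per-group ordinary least squares and the pooled MLE variance.

    sigma2 = (RSS1 + RSS2) / (n1 + n2), reflecting the equal-variance
    assumption across the two cell lines.
    """
    fit1 = _ols(obs.cancer_x, obs.cancer_y)
    fit2 = _ols(obs.normal_x, obs.normal_y)
    sigma2 = (fit1.rss + fit2.rss) / (obs.n1 + obs.n2)
    return fit1, fit2, sigma2


def in_alternative_region(b11: float, b21: float) -> bool:
    """True iff (b11, b21) lies strictly inside the depletion cone.

    The cone is b11 < 0 with |b21| < |b11|; boundary points are null.
    """
    if not (np.isfinite(b11) and np.isfinite(b21)):
        raise ConeTestError("non-finite slope")
    return b11 < 0 and b11 < b21 < -b11


def _boundary_fit(
    obs: GeneObservations, sign: float
) -> tuple[LineFit, LineFit, float]:
    """Constrained LS on the boundary line b21 = sign * b11, b11 <= 0.

    With intercepts profiled out, the pooled RSS is quadratic in the
    common slope c = b11 and minimized at
        c = (S1xy + sign * S2xy) / (S1xx + S2xx),
    clamped to 0 when positive (half-line constraint, by convexity).
    """
    x1c = obs.cancer_x - obs.cancer_x.mean()
    x2c = obs.normal_x - obs.normal_x.mean()
    y1c = obs.cancer_y - obs.cancer_y.mean()
    y2c = obs.normal_y - obs.normal_y.mean()
    s1xx, s2xx = float(x1c @ x1c), float(x2c @ x2c)
    s1xy, s2xy = float(x1c @ y1c), float(x2c @ y2c)
    c = (s1xy + sign * s2xy) / (s1xx + s2xx)
    c = min(c, 0.0)
    b11, b21 = c, sign * c
    fit1 = LineFit(
        float(obs.cancer_y.mean() - b11 * obs.cancer_x.mean()),
        b11,
        float(y1c @ y1c - 2 * b11 * s1xy + b11 * b11 * s1xx),
    )
    fit2 = LineFit(
        float(obs.normal_y.mean() - b21 * obs.normal_x.mean()),
        b21,
        float(y2c @ y2c - 2 * b21 * s2xy + b21 * b21 * s2xx),
    )
    return fit1, fit2, fit1.rss + fit2.rss


def fit_restricted(obs: GeneObservations) -> tuple[LineFit, LineFit, float]:
    """Null-restricted MLE: projection of the fit onto the null space.

    If the unrestricted slopes are not inside the cone the unrestricted
    fit is already null-feasible and is returned unchanged. Otherwise
    both boundary half-lines (b21 = -b11 and b21 = b11, b11 <= 0) are
    fitted in closed form and the smaller pooled-RSS candidate wins.
    Returns the two line fits and sigma2_restricted = RSS_r / (n1 + n2).
    """
    fit1, fit2, sigma2 = fit_unrestricted(obs)
    if not in_alternative_region(fit1.slope, fit2.slope):
        return fit1, fit2, sigma2
    anti = _boundary_fit(obs, sign=-1.0)
    sym = _boundary_fit(obs, sign=+1.0)
    r1, r2, rss = anti if anti[2] <= sym[2] else sym
    return r1, r2, rss / (obs.n1 + obs.n2)


def lrt_statistic(
    rss_unrestricted: float, rss_restricted: float, n_total: int
) -> tuple[float, bool]:
    """T0 = -2 ln LR = N * ln(RSS_r / RSS_u); returns (T0, infinite_flag).

    A perfect unrestricted fit (RSS_u = 0) with a worse restricted fit
    yields +inf with the flag set. Small negative ratios from floating
    point are clipped to 0.
    """
    if rss_restricted < 0 or rss_unrestricted < 0:
        raise ConeTestError("negative RSS")
    if rss_unrestricted == 0.0:
        if rss_restricted == 0.0:
            return 0.0, False
        return float("inf"), True
    return max(0.0, n_total * float(np.log(rss_restricted / rss_unrestricted))), False


def _rng_for_gene(seed: int, gene: str) -> np.random.Generator:
    """Per-gene stream derived from the root seed by stable hashing.

    Results are independent of gene order and of parallelization.
    """
    digest = hashlib.sha256(gene.encode()).digest()
    gene_key = int.from_bytes(digest[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([seed, gene_key]))


def _bootstrap_statistics(
    obs: GeneObservations,
    restricted: tuple[LineFit, LineFit],
    pooled_resid: np.ndarray,
    M: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized bootstrap null statistics T*_1..T*_M.

    Each replicate resamples n1 + n2 residuals with replacement from the
    pooled vector, adds them to the restricted fitted values, and
    recomputes the full unrestricted/restricted/LRT chain in closed
    form. Matches the scalar path bit-for-bit up to float associativity
    (asserted in the test suite).
    """
    x1, x2 = obs.cancer_x, obs.normal_x
    n1, n2 = obs.n1, obs.n2
    n_total = n1 + n2
    mu1 = restricted[0].fitted(x1)
    mu2 = restricted[1].fitted(x2)
    idx = rng.integers(0, pooled_resid.size, size=(M, n_total))
    y1 = mu1 + pooled_resid[idx[:, :n1]]
    y2 = mu2 + pooled_resid[idx[:, n1:]]

    x1c = x1 - x1.mean()
    x2c = x2 - x2.mean()
    s1xx, s2xx = float(x1c @ x1c), float(x2c @ x2c)
    y1m = y1.mean(axis=1, keepdims=True)
    y2m = y2.mean(axis=1, keepdims=True)
    s1xy = (y1 - y1m) @ x1c
    s2xy = (y2 - y2m) @ x2c
    s1yy = ((y1 - y1m) ** 2).sum(axis=1)
    s2yy = ((y2 - y2m) ** 2).sum(axis=1)

    b11 = s1xy / s1xx
    b21 = s2xy / s2xx
    rss_u = (s1yy - s1xy**2 / s1xx) + (s2yy - s2xy**2 / s2xx)

    in_cone = (b11 < 0) & (b11 < b21) & (b21 < -b11)

    c_anti = np.minimum((s1xy - s2xy) / (s1xx + s2xx), 0.0)
    rss_anti = (
        s1yy - 2 * c_anti * s1xy + c_anti**2 * s1xx
        + s2yy + 2 * c_anti * s2xy + c_anti**2 * s2xx
    )
    c_sym = np.minimum((s1xy + s2xy) / (s1xx + s2xx), 0.0)
    rss_sym = (
        s1yy - 2 * c_sym * s1xy + c_sym**2 * s1xx
        + s2yy - 2 * c_sym * s2xy + c_sym**2 * s2xx
    )
    rss_r = np.where(in_cone, np.minimum(rss_anti, rss_sym), rss_u)

    t = np.zeros(M)
    ok = in_cone & (rss_u > 0)
    t[ok] = n_total * np.log(rss_r[ok] / rss_u[ok])
    t[in_cone & (rss_u == 0) & (rss_r > 0)] = np.inf
    return np.maximum(t, 0.0)


def bootstrap_pvalue(
    obs: GeneObservations,
    M: int = DEFAULT_BOOTSTRAP,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ConeTestResult:
    """Residual-bootstrap p-value for the cone-restricted LRT.

    Procedure per replicate: pool the unrestricted residuals of both
    groups; draw two with-replacement samples of sizes n1 and n2; add
    them to the restricted fitted values to form bootstrap responses;
    recompute the statistic. ``p_raw`` is #{T* >= T0} / M (ties count
    toward the tail); ``p_addone`` = (1 + #) / (M + 1) is the default
    report, bounded away from 0.

    When the observed slopes are not inside the cone no resampling is
    done and p = 1, T0 = 0.
    """
    if M < 1:
        raise ConeTestError(f"bootstrap replicates M={M} must be >= 1")
    fit1, fit2, sigma2 = fit_unrestricted(obs)
    inside = in_alternative_region(fit1.slope, fit2.slope)
    r1, r2, sigma2_r = fit_restricted(obs)
    n_total = obs.n1 + obs.n2
    T0, infinite = lrt_statistic(sigma2 * n_total, sigma2_r * n_total, n_total)

    if not inside:
        return ConeTestResult(
            obs.gene, obs.cell_line, obs.n1, obs.n2, (fit1, fit2), (r1, r2),
            sigma2, sigma2_r, False, 0.0, M, 1.0, 1.0, seed,
        )

    if rng is None:
        rng = (
            _rng_for_gene(seed, obs.gene)
            if seed is not None
            else np.random.default_rng()
        )
    e1 = fit1.residuals(obs.cancer_x, obs.cancer_y)
    e2 = fit2.residuals(obs.normal_x, obs.normal_y)
    pooled = np.concatenate([e1, e2])
    t_star = _bootstrap_statistics(obs, (r1, r2), pooled, M, rng)
    n_tail = int(np.count_nonzero(t_star >= T0))
    return ConeTestResult(
        obs.gene, obs.cell_line, obs.n1, obs.n2, (fit1, fit2), (r1, r2),
        sigma2, sigma2_r, True, T0, M,
        n_tail / M, (1 + n_tail) / (M + 1), seed, t0_infinite=infinite,
    )


def test_gene(
    obs: GeneObservations,
    M: int = DEFAULT_BOOTSTRAP,
    seed: int | None = None,
) -> ConeTestResult:
    """Run the full four-step test for one gene against one cancer line.

    (i) per-group linear regression, (ii) cone membership of the slope
    pair, (iii) restricted fit and T0 = -2 ln LRT, (iv) residual
    bootstrap p-value. A full result is returned even outside the cone
    (in_region False, T0 = 0, p = 1).
    """
    return bootstrap_pvalue(obs, M=M, seed=seed)


def build_gene_observations(
    norm: NormalizedMatrix,
    manifest: LibraryManifest,
    cancer_line: str,
    normal_line: str,
    aggregate: str = "stack",
) -> list[GeneObservations]:
    """Assemble per-gene observation pairs from a normalized matrix.

    ``aggregate="stack"`` (default) treats every (hairpin, passage,
    replicate) value as one observation, so n = hairpins x passages x
    replicates per group. ``aggregate="replicate-mean"`` averages
    replicates first, n = hairpins x passages.
    """
    if aggregate not in ("stack", "replicate-mean"):
        raise ConeTestError(f"unknown aggregation {aggregate!r}")
    by_line: dict[str, list] = {}
    for s in norm.samples:
        by_line.setdefault(s.cell_line, []).append(s)
    for line in (cancer_line, normal_line):
        if line not in by_line:
            raise ConeTestError(f"cell line {line!r} not present in samples")
    gene_of = manifest.gene_of()
    out = []
    for gene in manifest.genes:
        ids = [sid for sid in norm.values.index if gene_of.get(sid) == gene]
        vectors = {}
        for line in (cancer_line, normal_line):
            ys, xs = [], []
            samples = by_line[line]
            if aggregate == "stack":
                for s in samples:
                    col = norm.values.loc[ids, s.label].to_numpy()
                    ys.append(col)
                    xs.append(np.full(col.size, s.passage, dtype=float))
            else:
                passages = sorted({s.passage for s in samples})
                for p in passages:
                    labels = [s.label for s in samples if s.passage == p]
                    col = norm.values.loc[ids, labels].mean(axis=1).to_numpy()
                    ys.append(col)
                    xs.append(np.full(col.size, p, dtype=float))
            vectors[line] = (np.concatenate(ys), np.concatenate(xs))
        out.append(
            GeneObservations(
                gene,
                cancer_y=vectors[cancer_line][0],
                cancer_x=vectors[cancer_line][1],
                normal_y=vectors[normal_line][0],
                normal_x=vectors[normal_line][1],
                cell_line=cancer_line,
            )
        )
    return out


def test_all_genes(
    norm: NormalizedMatrix,
    manifest: LibraryManifest,
    normal_line: str,
    M: int = DEFAULT_BOOTSTRAP,
    seed: int | None = None,
    aggregate: str = "stack",
    cancer_lines: list[str] | None = None,
) -> pd.DataFrame:
    """Test every gene against every cancer line; tidy results table.

    Columns: gene, cell_line, n1, n2, b11, b21, in_region, T0, p_raw,
    p_addone, M, seed. Per-gene RNG streams are derived from the root
    seed by hashing the gene symbol, so results do not depend on order.
    """
    if cancer_lines is None:
        cancer_lines = [
            line
            for line in dict.fromkeys(s.cell_line for s in norm.samples)
            if line != normal_line
        ]
    rows = []
    for line in cancer_lines:
        for obs in build_gene_observations(
            norm, manifest, line, normal_line, aggregate
        ):
            res = test_gene(obs, M=M, seed=seed)
            rows.append(
                {
                    "gene": res.gene,
                    "cell_line": res.cell_line,
                    "n1": res.n1,
                    "n2": res.n2,
                    "b11": res.b11,
                    "b21": res.b21,
                    "in_region": res.in_region,
                    "T0": res.T0,
                    "p_raw": res.p_raw,
                    "p_addone": res.p_addone,
                    "M": res.M,
                    "seed": res.seed,
                }
            )
    return pd.DataFrame(rows)
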