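"""Linked-statistics core: correlation ranking, shuffle nulls, DE testing.

Every analysis here runs on the ln(TPM+1) layer. The central construct is a
gene-wise Spearman correlation between expression and a per-cell biophysical
covariate (buoyant mass, MAR, or growth efficiency), significance-called
against an empirical shuffle null: the covariate is permuted across cells
(mismatching biophysical and expression data), coefficients recomputed, and
after many iterations (default 10,000) the pooled mean and standard
deviation of the null coefficient distribution define the cut -- a gene is
significant iff its coefficient lies more than two null SDs from the null
mean.

The same machinery tests principal components against biophysical
covariates, and a self-contained Mann-Whitney U engine (exact enumeration
for small groups, tie-corrected normal approximation otherwise) provides
two-group differential expression with Bonferroni correction.

For a statsmodels-flavoured entry point, :class:`CorrelationModel` wraps the
functional pieces: build it from a matrix and covariate, ``fit()`` returns a
:class:`CorrelationResults` carrying the ranked gene list, the null, the
significance calls, and a ``summary()``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from ._exceptions import InputError

__all__ = [
    "RankedGeneList",
    "NullDistribution",
    "DEResult",
    "spearman",
    "correlate_genes",
    "shuffle_null",
    "flag_significant",
    "pc_biophysics_test",
    "wilcoxon_de",
    "mannwhitney_groups",
    "CorrelationModel",
    "CorrelationResults",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class RankedGeneList:
    """Genes ordered by correlation with a biophysical covariate.

    ``entries`` has index ``gene`` and columns ``rho`` (Spearman, or Pearson
    when requested), optionally ``rho_pearson``, and after significance
    flagging ``null_mean``, ``null_sd``, ``significant`` and ``direction``.
    Sorted by ``rho`` descending.
    """

    covariate_name: str
    entries: pd.DataFrame
    method: str = "spearman"

    def __post_init__(self) -> None:
        self.entries = self.entries.sort_values("rho", ascending=False)

    @property
    def scores(self) -> pd.Series:
        """gene -> coefficient, descending; the preranked-enrichment input."""
        return self.entries["rho"]

    def significant_genes(self, direction: str | None = None) -> list[str]:
        if "significant" not in self.entries:
            raise InputError("run flag_significant first")
        sel = self.entries["significant"]
        if direction is not None:
            sel = sel & (self.entries["direction"] == direction)
        return self.entries.index[sel].tolist()


@dataclass
class NullDistribution:
    """Pooled shuffle-null moments of gene--covariate coefficients."""

    n_iterations: int
    mean: float
    sd: float
    seed: int
    per_gene: pd.DataFrame | None = None  # columns null_mean, null_sd

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise InputError("n_iterations must be >= 1")
        if self.sd < 0:
            raise InputError("sd must be non-negative")


@dataclass
class DEResult:
    """Two-group differential expression table.

    ``table`` is indexed by gene with columns ``log_fold_change`` (difference
    of group means on the ln(TPM+1) scale), ``p_raw`` and ``p_bonferroni``.
    """

    table: pd.DataFrame
    group_a: str
    group_b: str


# ---------------------------------------------------------------------------
# rank helpers


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, axis=-1, method="average")


def _standardize_rows(r: np.ndarray) -> np.ndarray:
    """Center rows and scale to unit norm; zero-variance rows become NaN."""
    r = r - r.mean(axis=-1, keepdims=True)
    norm = np.linalg.norm(r, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(norm > 0, r / norm, np.nan)


def spearman(x, y) -> float:
    """Spearman rank correlation (mid-ranks for ties).

    Returns NaN with a warning when either input is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise InputError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman correlation undefined", stacklevel=2)
        return float("nan")
    rho, _ = sps.spearmanr(x, y)
    return float(rho)


# ---------------------------------------------------------------------------
# gene-wise correlation and its shuffle null


def _coefficient_matrix_rows(values: np.ndarray, method: str) -> np.ndarray:
    """Rows prepared so that row . z(covariate) gives the coefficient."""
    if method == "spearman":
        values = _midranks(values)
    elif method != "pearson":
        raise InputError(f"unknown method {method!r}")
    return _standardize_rows(values)


def _covariate_vector(covariate: np.ndarray, method: str) -> np.ndarray:
    c = np.asarray(covariate, dtype=float)
    if method == "spearman":
        c = _midranks(c)
    z = _standardize_rows(c[None, :])[0]
    if np.isnan(z).all():
        raise InputError("covariate is constant")
    return z


def correlate_genes(matrix, covariate, method: str = "spearman") -> RankedGeneList:
    """One coefficient per gene between expression and the covariate.

    ``matrix`` is an :class:`~smrlink.qc.ExpressionMatrix` (logTPM layer
    expected for the headline analysis, any layer accepted) whose columns
    align with ``covariate``. Zero-variance genes get NaN and sort last.
    """
    values = matrix.values.to_numpy(dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if values.shape[1] != covariate.size:
        raise InputError(
            f"matrix has {values.shape[1]} cells but covariate has {covariate.size}"
        )
    name = getattr(covariate, "name", "covariate")
    Z = _coefficient_matrix_rows(values, method)
    z = _covariate_vector(covariate, method)
    with np.errstate(invalid="ignore"):
        rho = Z @ z
    entries = pd.DataFrame({"rho": rho}, index=matrix.values.index)
    entries.index.name = "gene"
    if method == "spearman":
        zp = _covariate_vector(covariate, "pearson")
        Zp = _coefficient_matrix_rows(values, "pearson")
        with np.errstate(invalid="ignore"):
            entries["rho_pearson"] = Zp @ zp
    return RankedGeneList(covariate_name=str(name), entries=entries, method=method)


def shuffle_null(
    matrix,
    covariate,
    n_iterations: int = 10_000,
    seed: int | None = None,
    method: str = "spearman",
    per_gene: bool = False,
    chunk: int = 500,
) -> NullDistribution:
    """Empirical null of gene--covariate coefficients by covariate shuffling.

    Each iteration permutes the covariate across cells (mismatching
    biophysical and expression data) and recomputes every gene's
    coefficient. The pooled mean and SD over all gene x iteration
    coefficients are returned; per-gene moments optionally as well.
    Deterministic given ``seed`` (required).
    """
    if n_iterations < 1:
        raise InputError("n_iterations must be >= 1")
    if seed is None:
        raise InputError("seed is required for reproducibility")
    rng = np.random.default_rng(seed)
    values = matrix.values.to_numpy(dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if values.shape[1] != covariate.size:
        raise InputError("matrix / covariate cell mismatch")
    Z = _coefficient_matrix_rows(values, method)
    ok = ~np.isnan(Z).any(axis=1)
    Zok = Z[ok]
    z = _covariate_vector(covariate, method)
    n_cells = z.size

    total = 0
    s1 = 0.0
    s2 = 0.0
    g1 = np.zeros(Zok.shape[0])
    g2 = np.zeros(Zok.shape[0])
    done = 0
    while done < n_iterations:
        m = min(chunk, n_iterations - done)
        perms = np.empty((n_cells, m))
        for j in range(m):
            perms[:, j] = z[rng.permutation(n_cells)]
        rho = Zok @ perms  # genes x m
        total += rho.size
        s1 += rho.sum()
        s2 += (rho**2).sum()
        if per_gene:
            g1 += rho.sum(axis=1)
            g2 += (rho**2).sum(axis=1)
        done += m

    mean = s1 / total
    var = max(s2 / total - mean**2, 0.0)
    per_gene_df = None
    if per_gene:
        gm = g1 / n_iterations
        gv = np.maximum(g2 / n_iterations - gm**2, 0.0)
        per_gene_df = pd.DataFrame(
            {"null_mean": gm, "null_sd": np.sqrt(gv)},
            index=matrix.values.index[ok],
        )
    return NullDistribution(
        n_iterations=n_iterations,
        mean=float(mean),
        sd=float(math.sqrt(var)),
        seed=seed,
        per_gene=per_gene_df,
    )


def flag_significant(ranked: RankedGeneList, null: NullDistribution) -> RankedGeneList:
    """Two-SD rule: significant iff |rho - null mean| > 2 x null SD.

    Direction is the sign of (rho - null mean). With a pooled null the same
    (mean, sd) applies to every gene; with ``null.per_gene`` set, each gene
    is compared to its own null moments.
    """
    entries = ranked.entries.copy()
    if null.per_gene is not None:
        aligned = null.per_gene.reindex(entries.index)
        mean = aligned["null_mean"].to_numpy()
        sd = aligned["null_sd"].to_numpy()
    else:
        mean = np.full(len(entries), null.mean)
        sd = np.full(len(entries), null.sd)
    if np.any(sd == 0):
        warnings.warn("null SD is zero: every deviation is significant", stacklevel=2)
    delta = entries["rho"].to_numpy() - mean
    with np.errstate(invalid="ignore"):
        significant = np.abs(delta) > 2.0 * sd
    entries["null_mean"] = mean
    entries["null_sd"] = sd
    entries["significant"] = np.where(np.isnan(delta), False, significant)
    entries["direction"] = np.where(delta >= 0, "+", "-")
    return RankedGeneList(
        covariate_name=ranked.covariate_name, entries=entries, method=ranked.method
    )


# ---------------------------------------------------------------------------
# PC vs biophysics


def pc_biophysics_test(
    matrix,
    covariate,
    n_pcs: int = 10,
    n_iterations: int = 10_000,
    seed: int | None = None,
    n_variable_genes: int = 2000,
) -> pd.DataFrame:
    """Test the top principal components against a biophysical covariate.

    PCA is run on the top ``n_variable_genes`` by dispersion (variance /
    mean), centered and unit-scaled. Each PC's cell coordinates are Spearman
    correlated with the covariate and significance-called by the same
    two-SD shuffle rule, permuting the covariate across cells and pooling
    the null over PCs and iterations.

    Returns a DataFrame with one row per PC: ``rho``, ``null_mean``,
    ``null_sd``, ``significant``, ``direction``.
    """
    values = matrix.values.to_numpy(dtype=float)
    n_genes, n_cells = values.shape
    if n_cells < 3:
        raise InputError("need at least 3 cells")
    n_pcs = min(n_pcs, n_cells - 1, n_genes)
    covariate = np.asarray(covariate, dtype=float)
    if covariate.size != n_cells:
        raise InputError("matrix / covariate cell mismatch")

    gene_mean = values.mean(axis=1)
    gene_var = values.var(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = np.where(gene_mean > 0, gene_var / gene_mean, 0.0)
    order = np.argsort(dispersion)[::-1]
    keep = np.sort(order[: min(n_variable_genes, n_genes)])
    sub = values[keep]
    sub = sub[sub.std(axis=1) > 0]
    scaled = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, keepdims=True)

    coords = PCA(n_components=n_pcs, random_state=0).fit_transform(scaled.T)  # cells x pcs

    # reuse the gene-wise machinery with PCs standing in for genes; PC
    # coordinates are signed, so wrap the frame in a minimal values-holder
    raw = type("_PCFrame", (), {})()
    raw.values = pd.DataFrame(coords.T, index=[f"PC{i+1}" for i in range(n_pcs)])

    ranked = correlate_genes(raw, covariate, method="spearman")
    null = shuffle_null(raw, covariate, n_iterations=n_iterations, seed=seed)
    flagged = flag_significant(ranked, null)
    out = flagged.entries.loc[
        [f"PC{i+1}" for i in range(n_pcs)],
        ["rho", "null_mean", "null_sd", "significant", "direction"],
    ]
    out.index.name = "pc"
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney U engine


def _u_statistic(ranks_pooled: np.ndarray, idx_a: np.ndarray, n_a: int, n_b: int) -> float:
    r1 = ranks_pooled[idx_a].sum()
    return r1 - n_a * (n_a + 1) / 2.0


def _mw_exact_p(pooled: np.ndarray, n_a: int) -> float:
    """Two-sided permutation p over all C(n, n_a) group assignments."""
    n = pooled.size
    n_b = n - n_a
    ranks = _midranks(pooled)
    mu = n_a * n_b / 2.0
    idx_obs = np.arange(n_a)
    u_obs = _u_statistic(ranks, idx_obs, n_a, n_b)
    d_obs = abs(u_obs - mu)
    count = 0
    total = 0
    for comb in combinations(range(n), n_a):
        u = _u_statistic(ranks, np.array(comb), n_a, n_b)
        if abs(u - mu) >= d_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def _srs_moments(ranks: np.ndarray, n_a: int) -> tuple[float, float, float]:
    """Exact central moments (mu2, mu3, mu4) of the group-A rank sum.

    The rank sum of a random size-``n_a`` subset drawn without replacement
    from the (tie-adjusted) mid-ranks is a finite-population sample sum; its
    moments follow from the power sums of the centered rank population and
    the falling-factorial inclusion probabilities.
    """
    n = ranks.size
    y = ranks - ranks.mean()
    s2 = float((y**2).sum())
    s3 = float((y**3).sum())
    s4 = float((y**4).sum())

    def p(r: int) -> float:
        num = den = 1.0
        for t in range(r):
            num *= n_a - t
            den *= n - t
        return num / den

    p1, p2, p3, p4 = p(1), p(2), p(3), p(4)
    mu2 = (p1 - p2) * s2
    mu3 = (p1 - 3 * p2 + 2 * p3) * s3
    mu4 = (
        p1 * s4
        + p2 * (3 * s2**2 - 7 * s4)
        + 6 * p3 * (2 * s4 - s2**2)
        + p4 * (3 * s2**2 - 6 * s4)
    )
    return mu2, mu3, mu4


def _mw_normal_p(pooled: np.ndarray, n_a: int) -> float:
    """Edgeworth-corrected normal approximation (ties via mid-ranks).

    A continuity-corrected normal tail refined by the exact skewness and
    kurtosis of the permutation rank-sum distribution; the correction terms
    vanish as the groups grow.
    """
    n = pooled.size
    n_b = n - n_a
    ranks = _midranks(pooled)
    u = _u_statistic(ranks, np.arange(n_a), n_a, n_b)
    mu = n_a * n_b / 2.0
    mu2, mu3, mu4 = _srs_moments(ranks, n_a)
    if mu2 <= 0:
        return 1.0
    sigma = math.sqrt(mu2)
    g1 = mu3 / sigma**3
    g2 = mu4 / mu2**2 - 3.0
    z = max(abs(u - mu) - 0.5, 0.0) / sigma
    phi = math.exp(-0.5 * z * z) / math.sqrt(2.0 * math.pi)
    p = 2.0 * sps.norm.sf(z) + 2.0 * phi * (
        g2 / 24.0 * (z**3 - 3 * z) + g1**2 / 72.0 * (z**5 - 10 * z**3 + 15 * z)
    )
    return float(min(1.0, max(p, 0.0)))


def mannwhitney_groups(values_a, values_b, method: str = "auto") -> float:
    """Two-sided Mann-Whitney U p-value between two samples.

    ``method='auto'`` uses exact enumeration over all group assignments when
    both samples have at most 8 observations, else the tie-corrected normal
    approximation; ``'exact'`` / ``'normal'`` force a branch. Degenerate
    all-tied input gives p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    if method == "auto":
        method = "exact" if (a.size <= 8 and b.size <= 8) else "normal"
    if method == "exact":
        return _mw_exact_p(pooled, a.size)
    if method == "normal":
        return _mw_normal_p(pooled, a.size)
    raise InputError(f"unknown method {method!r}")


def wilcoxon_de(matrix, groups, method: str = "auto") -> DEResult:
    """Per-gene two-group Wilcoxon/Mann-Whitney differential expression.

    ``groups`` is a length-n_cells vector with exactly two levels, each with
    at least 3 cells. The log fold change is the difference of group means
    on the ln(TPM+1) scale (group A minus group B, levels in sorted order).
    P-values are Bonferroni-corrected over the genes tested.
    """
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups).tolist())
    if len(levels) != 2:
        raise InputError(f"need exactly 2 group levels, got {levels}")
    mask_a = groups == levels[0]
    mask_b = groups == levels[1]
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise InputError("both groups need >= 3 cells")
    if matrix.values.shape[1] != groups.size:
        raise InputError("matrix / groups cell mismatch")
    values = matrix.values.to_numpy(dtype=float)
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    use_exact = method == "exact" or (method == "auto" and n_a <= 8 and n_b <= 8)

    lfc = values[:, mask_a].mean(axis=1) - values[:, mask_b].mean(axis=1)
    a_vals = values[:, mask_a]
    b_vals = values[:, mask_b]

    if use_exact:
        comb_idx = np.array(list(combinations(range(n_a + n_b), n_a)))
        p_raw = np.empty(values.shape[0])
        mu = n_a * n_b / 2.0
        const = n_a * (n_a + 1) / 2.0
        for g in range(values.shape[0]):
            pooled = np.concatenate([a_vals[g], b_vals[g]])
            if np.ptp(pooled) == 0:
                p_raw[g] = 1.0
                continue
            ranks = _midranks(pooled)
            u_all = ranks[comb_idx].sum(axis=1) - const
            d_obs = abs(ranks[:n_a].sum() - const - mu)
            p_raw[g] = np.mean(np.abs(u_all - mu) >= d_obs - 1e-12)
    else:
        pooled = np.concatenate([a_vals, b_vals], axis=1)
        ranks = _midranks(pooled)
        n = n_a + n_b
        u = ranks[:, :n_a].sum(axis=1) - n_a * (n_a + 1) / 2.0
        mu = n_a * n_b / 2.0
        # vectorized Edgeworth engine (same as mannwhitney_groups)
        y = ranks - (n + 1) / 2.0  # mid-ranks always average to (n+1)/2
        s2 = (y**2).sum(axis=1)
        s3 = (y**3).sum(axis=1)
        s4 = (y**4).sum(axis=1)

        def pfall(r: int) -> float:
            num = den = 1.0
            for t in range(r):
                num *= n_a - t
                den *= n - t
            return num / den

        p1, p2, p3, p4 = pfall(1), pfall(2), pfall(3), pfall(4)
        mu2 = (p1 - p2) * s2
        mu3 = (p1 - 3 * p2 + 2 * p3) * s3
        mu4 = p1 * s4 + p2 * (3 * s2**2 - 7 * s4) + 6 * p3 * (2 * s4 - s2**2) + p4 * (
            3 * s2**2 - 6 * s4
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            sigma = np.sqrt(mu2)
            g1 = mu3 / sigma**3
            g2 = mu4 / mu2**2 - 3.0
            z = np.maximum(np.abs(u - mu) - 0.5, 0.0) / sigma
        phi = np.exp(-0.5 * z * z) / np.sqrt(2.0 * np.pi)
        p = 2.0 * sps.norm.sf(z) + 2.0 * phi * (
            g2 / 24.0 * (z**3 - 3 * z) + g1**2 / 72.0 * (z**5 - 10 * z**3 + 15 * z)
        )
        p_raw = np.where(mu2 <= 0, 1.0, np.clip(p, 0.0, 1.0))

    n_tested = values.shape[0]
    table = pd.DataFrame(
        {
            "log_fold_change": lfc,
            "p_raw": p_raw,
            "p_bonferroni": np.minimum(1.0, p_raw * n_tested),
        },
        index=matrix.values.index,
    ).sort_values("p_raw")
    table.index.name = "gene"
    return DEResult(table=table, group_a=str(levels[0]), group_b=str(levels[1]))


# ---------------------------------------------------------------------------
# model facade


class CorrelationModel:
    """Gene--covariate correlation analysis as a fittable model.

    Parameters
    ----------
    matrix
        :class:`~smrlink.qc.ExpressionMatrix`, logTPM layer.
    covariate
        Per-cell biophysical values aligned with the matrix columns.
    covariate_name
        ``mass``, ``mar`` or ``growth_efficiency`` (free-form accepted).
    method
        ``spearman`` (default) or ``pearson``.

    ``fit`` computes the ranked list, the shuffle null and the two-SD
    significance calls, returning a :class:`CorrelationResults`.
    """

    def __init__(self, matrix, covariate, covariate_name: str = "mass", method: str = "spearman"):
        self.matrix = matrix
        self.covariate = np.asarray(covariate, dtype=float)
        self.covariate_name = covariate_name
        self.method = method
        if self.matrix.values.shape[1] != self.covariate.size:
            raise InputError("matrix / covariate cell mismatch")

    @classmethod
    def from_linked(cls, linked_table: pd.DataFrame, matrix, covariate: str = "mass", **kwargs):
        """Build from a linked-cell table (columns well_id + covariates).

        The matrix is subset and ordered to the linked wells.
        """
        wells = [w for w in linked_table["well_id"] if w in set(matrix.values.columns)]
        sub = matrix.values.loc[:, wells]
        from .qc import ExpressionMatrix

        sub_matrix = ExpressionMatrix(values=sub, layer=matrix.layer, flags=dict(matrix.flags))
        cov = linked_table.set_index("well_id").loc[wells, covariate].to_numpy()
        return cls(sub_matrix, cov, covariate_name=covariate, **kwargs)

    def fit(
        self,
        n_iterations: int = 10_000,
        seed: int | None = None,
        per_gene: bool = False,
    ) -> "CorrelationResults":
        ranked = correlate_genes(self.matrix, self.covariate, method=self.method)
        ranked.covariate_name = self.covariate_name
        null = shuffle_null(
            self.matrix,
            self.covariate,
            n_iterations=n_iterations,
            seed=seed,
            method=self.method,
            per_gene=per_gene,
        )
        flagged = flag_significant(ranked, null)
        return CorrelationResults(model=self, ranked=flagged, null=null)


@dataclass
class CorrelationResults:
    """Fitted gene--covariate correlation analysis."""

    model: CorrelationModel
    ranked: RankedGeneList
    null: NullDistribution

    @property
    def n_significant(self) -> int:
        return int(self.ranked.entries["significant"].sum())

    def summary(self, top: int = 10) -> str:
        e = self.ranked.entries
        lines = [
            "Gene-covariate correlation analysis",
            "=" * 51,
            f"covariate:      {self.model.covariate_name}",
            f"method:         {self.model.method}",
            f"genes tested:   {len(e)}",
            f"cells:          {self.model.covariate.size}",
            f"null:           {self.null.n_iterations} shuffles (seed {self.null.seed})",
            f"null mean (sd): {self.null.mean:+.4f} ({self.null.sd:.4f})",
            f"significant:    {self.n_significant} "
            f"({(e['significant'] & (e['direction'] == '+')).sum()} positive, "
            f"{(e['significant'] & (e['direction'] == '-')).sum()} negative)",
            "-" * 51,
            f"top {top} by coefficient:",
        ]
        head = e.head(top)[["rho", "significant", "direction"]]
        lines.append(head.to_string(float_format=lambda v: f"{v:+.3f}"))
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        cols = [c for c in ("rho", "rho_pearson", "null_mean", "null_sd", "significant", "direction") if c in self.ranked.entries]
        self.ranked.entries[cols].to_csv(path, sep="\t")

    def plot_null(self, ax=None):
        """Observed coefficient distribution against the null band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        e = self.ranked.entries
        ax.hist(e["rho"].dropna(), bins=50, color="steelblue", alpha=0.7)
        lo = self.null.mean - 2 * self.null.sd
        hi = self.null.mean + 2 * self.null.sd
        ax.axvspan(lo, hi, color="grey", alpha=0.3, label="null +/- 2 SD")
        ax.set_xlabel(f"{self.model.method} coefficient vs {self.model.covariate_name}")
        ax.set_ylabel("genes")
        ax.legend()
        return ax
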