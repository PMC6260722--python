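"""Cell-cycle panel scoring and preranked gene-set enrichment.

Phase scores summarize a gene panel (G1/S, G2/M, or mitosis) per cell: each
panel gene is z-scored across cells and the z-scores averaged over the
panel. Cells are called G1/S or G2/M by the larger score when it clears a
margin, else left unassigned.

The enrichment engine re-implements preranked GSEA semantics: a weighted
Kolmogorov-Smirnov running sum over a correlation-ranked gene list, with
hit increments proportional to |score|^p and miss decrements 1/(N - Nh);
the enrichment score (ES) is the maximal deviation of the running sum.
Normalization (NES), permutation p-values and FDR q-values come from
gene-label permutations: random same-size sets drawn from the ranked
universe, with sign-matched pooling as in the preranked convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._exceptions import InputError
from .stats import RankedGeneList

__all__ = [
    "GenePanel",
    "panel_score",
    "assign_phase",
    "enrichment_score",
    "preranked_enrichment",
]


@dataclass(frozen=True)
class GenePanel:
    """A named gene set (G1/S, G2/M, mitosis, or custom)."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise InputError("gene panel must be non-empty")

    @classmethod
    def from_list(cls, name: str, genes) -> "GenePanel":
        return cls(name=name, genes=tuple(dict.fromkeys(genes)))


def panel_score(matrix, panel: GenePanel) -> pd.DataFrame:
    """Average z-score of a gene panel per cell.

    Each panel gene present in the matrix is z-scored across cells (subtract
    the gene's mean, divide by its SD); the per-cell score is the mean over
    panel genes. Zero-variance genes are dropped from the panel with a
    warning; a panel with no genes present is an error naming the missing
    genes.

    Returns a DataFrame indexed by cell with columns ``score`` and ``panel``.
    """
    present = [g for g in panel.genes if g in matrix.values.index]
    if not present:
        raise InputError(
            f"no gene of panel {panel.name!r} present in matrix; missing: "
            f"{list(panel.genes)[:10]}"
        )
    sub = matrix.values.loc[present]
    sd = sub.std(axis=1, ddof=0)
    flat = sd.index[sd == 0].tolist()
    if flat:
        warnings.warn(
            f"panel {panel.name!r}: {len(flat)} zero-variance gene(s) excluded",
            stacklevel=2,
        )
        sub = sub.drop(index=flat)
        if sub.empty:
            raise InputError(f"panel {panel.name!r} has only zero-variance genes")
        sd = sd.drop(index=flat)
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    out = pd.DataFrame({"score": z.mean(axis=0)})
    out.index.name = "cell"
    out["panel"] = panel.name
    return out


def assign_phase(
    g1s: pd.DataFrame, g2m: pd.DataFrame, margin: float = 0.0
) -> pd.Series:
    """Call each cell G1/S or G2/M by the larger panel score.

    A cell is assigned to the phase with the higher score provided that
    score exceeds ``margin``; ties or both-below-margin cells are
    ``unassigned``.
    """
    if not g1s.index.equals(g2m.index):
        raise InputError("G1/S and G2/M scores must cover the same cells")
    s1 = g1s["score"]
    s2 = g2m["score"]
    best = np.maximum(s1, s2)
    call = np.where(
        (best <= margin) | (s1 == s2),
        "unassigned",
        np.where(s1 > s2, "G1/S", "G2/M"),
    )
    return pd.Series(call, index=g1s.index, name="phase_call")


# ---------------------------------------------------------------------------
# preranked enrichment


def _es_from_positions(
    positions: np.ndarray, weights_abs_p: np.ndarray, total_hit_weight: float, n: int
) -> float:
    """ES via the hit positions only (running-sum extrema occur at hits).

    ``positions`` are 0-based sorted indices of the set's genes in the
    descending-ranked list; ``weights_abs_p`` the corresponding |score|^p.
    """
    k = positions.size
    miss_dec = 1.0 / (n - k)
    hit_cum = np.cumsum(weights_abs_p) / total_hit_weight
    i = np.arange(k)
    # running sum immediately after hit i, and immediately before hit i
    after = hit_cum - (positions - i) * miss_dec
    before = np.concatenate(([0.0], hit_cum[:-1])) - (positions - i) * miss_dec
    hi = after.max()
    lo = before.min()
    # positive extremum wins a (numerical) magnitude tie
    return float(hi if hi >= -lo - 1e-12 else lo)


def enrichment_score(scores: pd.Series, genes, p: float = 1.0) -> float:
    """Weighted KS enrichment score of a gene set against a ranked list.

    ``scores`` maps gene -> ranking score, sorted descending. Hits step the
    running sum up by |score|^p (normalized over hits); misses step down by
    1/(N - Nh). The ES is the deviation of maximal magnitude.
    """
    scores = scores.sort_values(ascending=False)
    n = len(scores)
    members = set(genes) & set(scores.index)
    k = len(members)
    if k == 0 or k == n:
        raise InputError("gene set must be a non-empty strict subset of the universe")
    is_hit = scores.index.isin(members)
    positions = np.nonzero(is_hit)[0]
    w = np.abs(scores.to_numpy()[positions]) ** p
    total = w.sum()
    if total == 0:
        # all hit scores are zero: fall back to unweighted steps
        w = np.ones_like(w)
        total = float(w.sum())
    return _es_from_positions(positions, w, total, n)


def preranked_enrichment(
    ranked: RankedGeneList | pd.Series,
    sets: list[GenePanel],
    p: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Preranked enrichment of gene sets with permutation NES, p and FDR.

    For each set, the observed ES is normalized by the mean |permuted ES| of
    matching sign over ``n_perm`` random same-size sets (gene-label
    permutation). The permutation p-value is the sign-matched tail fraction
    (add-one smoothed). FDR q-values compare each set's NES to the pooled
    sign-matched permutation NES distribution across all sets, in the
    preranked convention. Sets intersecting the universe in fewer than two
    genes are skipped with a warning.

    Returns a DataFrame indexed by set name with columns ``size``, ``es``,
    ``nes``, ``p_perm``, ``fdr_q``.
    """
    if seed is None:
        raise InputError("seed is required for reproducibility")
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    scores = ranked.scores if isinstance(ranked, RankedGeneList) else ranked
    scores = scores.dropna().sort_values(ascending=False)
    if scores.index.duplicated().any():
        raise InputError("ranked list must have unique genes")
    n = len(scores)
    abs_p = np.abs(scores.to_numpy()) ** p
    rng = np.random.default_rng(seed)

    rows = []
    perm_nes_pool: list[np.ndarray] = []
    perm_cache: dict[int, np.ndarray] = {}
    for gene_set in sets:
        members = set(gene_set.genes) & set(scores.index)
        k = len(members)
        if k < 2:
            warnings.warn(
                f"set {gene_set.name!r}: intersection with universe < 2, skipped",
                stacklevel=2,
            )
            continue
        if k == n:
            warnings.warn(f"set {gene_set.name!r} equals the universe, skipped", stacklevel=2)
            continue
        es = enrichment_score(scores, members, p=p)
        if k not in perm_cache:
            es_perm = np.empty(n_perm)
            for j in range(n_perm):
                pos = np.sort(rng.choice(n, size=k, replace=False))
                w = abs_p[pos]
                total = w.sum()
                if total == 0:
                    w = np.ones_like(w)
                    total = float(k)
                es_perm[j] = _es_from_positions(pos, w, total, n)
            perm_cache[k] = es_perm
        es_perm = perm_cache[k]

        same_sign = es_perm[es_perm >= 0] if es >= 0 else es_perm[es_perm < 0]
        if same_sign.size == 0:
            nes = np.nan
            p_perm = 1.0 / (n_perm + 1)
        else:
            denom = np.abs(same_sign).mean()
            nes = es / denom if denom > 0 else np.nan
            p_perm = (1 + (np.abs(same_sign) >= abs(es)).sum()) / (1 + same_sign.size)
        # permutation ES normalized the same way -> pooled NES null for FDR
        with np.errstate(invalid="ignore", divide="ignore"):
            pos_mean = np.abs(es_perm[es_perm >= 0]).mean() if (es_perm >= 0).any() else np.nan
            neg_mean = np.abs(es_perm[es_perm < 0]).mean() if (es_perm < 0).any() else np.nan
            nes_perm = np.where(es_perm >= 0, es_perm / pos_mean, es_perm / neg_mean)
        perm_nes_pool.append(nes_perm[~np.isnan(nes_perm)])
        rows.append({"set": gene_set.name, "size": k, "es": es, "nes": nes, "p_perm": p_perm})

    result = pd.DataFrame(rows, columns=["set", "size", "es", "nes", "p_perm"]).set_index("set")
    if result.empty:
        result["fdr_q"] = pd.Series(dtype=float)
        return result
    pool = np.concatenate(perm_nes_pool)
    obs = result["nes"].to_numpy()
    fdr = np.full(obs.size, np.nan)
    for i, nes in enumerate(obs):
        if np.isnan(nes):
            continue
        if nes >= 0:
            null_frac = np.mean(pool[pool >= 0] >= nes) if (pool >= 0).any() else 0.0
            obs_frac = np.mean(obs[~np.isnan(obs) & (obs >= 0)] >= nes)
        else:
            null_frac = np.mean(pool[pool < 0] <= nes) if (pool < 0).any() else 0.0
            obs_frac = np.mean(obs[~np.isnan(obs) & (obs < 0)] <= nes)
        fdr[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else np.nan
    result["fdr_q"] = fdr
    return result
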