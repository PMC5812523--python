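"""Alpha-diversity estimators and diversity-function correlations.

Chao1, ACE and the Shannon index are computed per sample on raw integer
counts — richness estimators are defined on observed frequencies, so the
count vectors are never normalized or rarefied first.  Scopes restrict the
count vector to the abundant or the rare fraction of the community before
estimating, which is how the contribution of the rare biosphere to alpha
diversity is isolated.

Pearson correlations between per-sample indices and functional metadata
(methane production rates, mcrA gene copies) use pairwise-complete
observations; absent metadata is dropped, never imputed.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from raretaxa.io import OtuTable

__all__ = [
    "shannon",
    "chao1",
    "ace",
    "rarefaction_curve",
    "sample_diversity",
    "correlate",
    "significance_stars",
]


def _clean(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float).ravel()
    if c.size == 0 or c.sum() < 1:
        raise ValueError("count vector must contain at least one read")
    if np.any(c < 0) or not np.all(c == np.floor(c)):
        raise ValueError("counts must be non-negative integers")
    return c[c > 0]


def shannon(counts, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i over detected OTUs.

    Natural log (nats) by default; pass ``base`` to change the log base.
    A single-OTU sample has H = 0; H is maximal (log S) at even abundances.
    """
    c = _clean(counts)
    p = c / c.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton/doubleton frequencies.

    The default is the bias-corrected form
    ``S_obs + f1 (f1 - 1) / (2 (f2 + 1))``, which stays defined when the
    sample has no doubletons.  ``bias_corrected=False`` selects the classic
    ``S_obs + f1^2 / (2 f2)`` form where f2 > 0 (falling back to the
    corrected form at f2 = 0).  Always >= S_obs, with equality when there
    are no singletons.
    """
    c = _clean(counts)
    s_obs = c.size
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if not bias_corrected and f2 > 0:
        return s_obs + f1 * f1 / (2 * f2)
    return s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))


def ace(counts, rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator (ACE) of richness.

    OTUs with count <= ``rare_cutoff`` form the rare group; with
    ``S_rare`` rare OTUs holding ``N_rare`` reads and ``f1`` singletons,
    the sample coverage is ``C = 1 - f1 / N_rare`` and

        ACE = S_abund + S_rare / C + (f1 / C) * gamma^2,
        gamma^2 = max((S_rare / C) * sum k(k-1) f_k / (N_rare (N_rare - 1)) - 1, 0).

    Degenerate branches: with no rare group ACE = S_obs; when every rare
    OTU is a singleton the coverage is 0 and the estimate falls back to
    Chao1, the conventional behavior of ecology toolkits.
    """
    c = _clean(counts)
    rare = c[c <= rare_cutoff]
    s_abund = int((c > rare_cutoff).sum())
    s_rare = rare.size
    if s_rare == 0:
        return float(c.size)
    n_rare = rare.sum()
    f1 = int((rare == 1).sum())
    coverage = 1.0 - f1 / n_rare
    if coverage == 0.0:
        return chao1(c)
    ks = np.arange(1, rare_cutoff + 1)
    fk = np.array([(rare == k).sum() for k in ks])
    if n_rare > 1:
        gamma_sq = max(
            (s_rare / coverage) * (ks * (ks - 1) * fk).sum() / (n_rare * (n_rare - 1))
            - 1.0,
            0.0,
        )
    else:
        gamma_sq = 0.0
    return s_abund + s_rare / coverage + (f1 / coverage) * gamma_sq


def _ln_comb(n: np.ndarray | float, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefaction_curve(counts, depths: Iterable[int]) -> np.ndarray:
    """Analytic (hypergeometric) expected richness at each subsampling depth.

    ``E[S_m] = sum_i (1 - C(N - N_i, m) / C(N, m))`` — the expectation of
    the number of OTUs seen in a uniform random subsample of m reads drawn
    without replacement.  Monotone non-decreasing in m, and exactly S_obs
    at the full depth m = N.
    """
    c = _clean(counts)
    n_total = c.sum()
    out = []
    for m in depths:
        m = int(m)
        if m < 1:
            raise ValueError("depth must be >= 1")
        if m > n_total:
            raise ValueError(f"depth {m} exceeds sample total {int(n_total)}")
        keep = n_total - c >= m
        term = np.zeros_like(c)
        if keep.any():
            term[keep] = np.exp(_ln_comb(n_total - c[keep], m) - _ln_comb(n_total, m))
        out.append(float((1.0 - term).sum()))
    return np.array(out)


def sample_diversity(
    table: OtuTable,
    scopes: Sequence[str] = ("all",),
    profiles: pd.DataFrame | None = None,
    shannon_base: float | None = None,
) -> pd.DataFrame:
    """Per-sample alpha-diversity indices, optionally per community fraction.

    Scope ``"all"`` uses the whole count vector; ``"abundant"``/``"rare"``
    restrict it to OTUs of that fraction, which requires classified
    ``profiles`` (column ``fraction_class``).  Samples where a scope has no
    reads yield NaN indices for that scope.
    """
    rows = []
    for scope in scopes:
        if scope == "all":
            sub = table.counts
        elif scope in ("abundant", "rare"):
            if profiles is None or "fraction_class" not in profiles.columns:
                raise ValueError(f"scope {scope!r} needs classified profiles")
            want = "ABUNDANT" if scope == "abundant" else "RARE_POOL"
            ids = profiles.index[profiles["fraction_class"] == want]
            sub = table.counts.loc[table.counts.index.intersection(ids)]
        else:
            raise ValueError(f"unknown scope: {scope!r}")
        for sample in table.sample_ids:
            vec = sub[sample].to_numpy()
            if vec.sum() == 0:
                rows.append((sample, scope, 0, np.nan, np.nan, np.nan))
                continue
            rows.append(
                (
                    sample,
                    scope,
                    int((vec > 0).sum()),
                    chao1(vec),
                    ace(vec),
                    shannon(vec, base=shannon_base),
                )
            )
    return pd.DataFrame(
        rows, columns=["sample_id", "scope", "s_obs", "chao1", "ace", "shannon"]
    )


def significance_stars(p: float, convention: str = "loose") -> str:
    """Map a p-value to stars.

    ``"loose"`` grades down to p < 0.1: '***' p<0.01, '**' p<0.05,
    '*' p<0.1 (the convention of the correlation table this surface
    replicates).  ``"conventional"``: '***' p<0.001, '**' p<0.01,
    '*' p<0.05.
    """
    if np.isnan(p):
        return ""
    if convention == "loose":
        cuts = ((0.01, "***"), (0.05, "**"), (0.1, "*"))
    elif convention == "conventional":
        cuts = ((0.001, "***"), (0.01, "**"), (0.05, "*"))
    else:
        raise ValueError(f"unknown star convention: {convention!r}")
    for cut, stars in cuts:
        if p < cut:
            return stars
    return ""


def correlate(
    diversity: pd.DataFrame,
    meta: pd.DataFrame,
    variables: Sequence[str] = ("mcrA_copies", "rate_ac", "rate_h2co2"),
    indices: Sequence[str] = ("chao1", "ace", "shannon"),
    star_convention: str = "loose",
) -> pd.DataFrame:
    """Pearson correlation of diversity indices against functional metadata.

    One row per (index, scope, variable): r, two-sided p (t-test on
    ``r sqrt(n-2) / sqrt(1-r^2)``), the number of complete pairs used, and
    significance stars.  Pairs with absent metadata are dropped.  Zero
    variance in either vector (or fewer than 3 pairs) makes the correlation
    undefined — flagged via ``undefined=True`` with NaN r/p rather than
    propagating NaN silently.
    """
    rows = []
    for variable in variables:
        if variable not in meta.columns:
            raise ValueError(f"metadata has no column {variable!r}")
        var = meta.set_index("sample_id")[variable]
        for scope, group in diversity.groupby("scope", sort=False):
            g = group.set_index("sample_id")
            for index_name in indices:
                pair = pd.DataFrame(
                    {"x": g[index_name], "y": var.reindex(g.index)}
                ).dropna()
                n = len(pair)
                undefined = n < 3 or pair["x"].nunique() == 1 or pair["y"].nunique() == 1
                if undefined:
                    r = p = np.nan
                else:
                    r, p = stats.pearsonr(pair["x"], pair["y"])
                rows.append(
                    {
                        "index_name": index_name,
                        "scope": scope,
                        "variable": variable,
                        "r": float(r),
                        "p": float(p),
                        "n": n,
                        "stars": significance_stars(p, star_convention),
                        "undefined": bool(undefined),
                    }
                )
    return pd.DataFrame(rows)
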