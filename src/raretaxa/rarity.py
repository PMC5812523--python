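"""Rarity classification of OTUs and threshold-gradient subsetting.

An OTU is *abundant* when its mean relative abundance across all samples
(zeros included) exceeds a threshold, by default 1%; everything else forms
the rare pool.  The rare pool is subdivided by how strongly an OTU
fluctuates across the samples where it is detected, measured as the ratio
of its maximum to its minimum nonzero relative abundance:

* **CRT** (conditionally rare taxa): ratio >= 100 — typically rare but
  blooming to prevalence in at least one sample;
* **PER** (permanently rare taxa): ratio < 5 — flat, persistently low
  abundance, including all absolute singletons (ratio 1);
* **RARE**: everything in between.

The minimum is taken over detected (nonzero) samples only; with zeros the
ratio would be infinite for nearly every rare OTU, and the nonzero
convention is the one under which every absolute singleton lands in PER.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from raretaxa.io import OtuTable

ABUNDANT = "ABUNDANT"
RARE_POOL = "RARE_POOL"
CRT = "CRT"
RARE = "RARE"
PER = "PER"
NA = "NA"
RARITY_CLASSES = (CRT, RARE, PER)

__all__ = [
    "RarityConfig",
    "profile_otus",
    "classify",
    "gradient_thresholds",
    "gradient_subsets",
    "venn_site_sharing",
    "ABUNDANT",
    "RARE_POOL",
    "CRT",
    "RARE",
    "PER",
    "RARITY_CLASSES",
]


@dataclass(frozen=True)
class RarityConfig:
    """Thresholds of the rarity classification and of the rarity gradient.

    Attributes
    ----------
    abundant_threshold : float
        Mean relative abundance above which an OTU is abundant (strict
        ``>``; ties go to the rare pool).  Default 0.01.
    crt_ratio : float
        max:min-nonzero ratio at or above which a rare OTU is CRT.
        Default 100; set ``crt_strict`` for a strict ``>`` comparison.
    per_ratio : float
        Ratio below which a rare OTU is PER (strict ``<``).  Default 5.
    gradient_start, gradient_end, gradient_step : float
        Descending gradient of rarity thresholds; defaults 1% down to 0.1%
        in steps of 0.05%, which yields 19 thresholds.
    """

    abundant_threshold: float = 0.01
    crt_ratio: float = 100.0
    per_ratio: float = 5.0
    crt_strict: bool = False
    gradient_start: float = 0.01
    gradient_end: float = 0.001
    gradient_step: float = 0.0005

    def __post_init__(self) -> None:
        if not (0 < self.gradient_end <= self.gradient_start <= self.abundant_threshold <= 1):
            raise ValueError(
                "require 0 < gradient_end <= gradient_start <= abundant_threshold <= 1"
            )
        if self.gradient_step <= 0:
            raise ValueError("gradient_step must be positive")
        if not self.per_ratio < self.crt_ratio:
            raise ValueError("per_ratio must be below crt_ratio")


def profile_otus(X: pd.DataFrame, counts: OtuTable | None = None) -> pd.DataFrame:
    """Per-OTU abundance summaries feeding the rarity classification.

    Parameters
    ----------
    X
        Relative-abundance matrix (OTUs x samples, columns summing to 1).
    counts
        Optional source count table; when given, read totals and
        singleton/doubleton flags are filled in (those are defined on
        realized counts, not on relative abundances).

    Returns
    -------
    DataFrame indexed by OTU id with columns ``mean_ra`` (mean over ALL
    samples, zeros included), ``max_ra``, ``min_nz_ra`` (minimum over
    occupied samples), ``ratio`` (= max_ra / min_nz_ra, >= 1),
    ``occupancy``, ``total_reads`` and ``singleton_flag``.
    """
    vals = X.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("relative abundances must be non-negative")
    occupancy = (vals > 0).sum(axis=1)
    if np.any(occupancy == 0):
        bad = X.index[occupancy == 0][0]
        raise ValueError(f"OTU {bad!r} is absent from every sample")
    mean_ra = vals.mean(axis=1)
    max_ra = vals.max(axis=1)
    min_nz = np.where(vals > 0, vals, np.inf).min(axis=1)
    prof = pd.DataFrame(
        {
            "mean_ra": mean_ra,
            "max_ra": max_ra,
            "min_nz_ra": min_nz,
            "ratio": max_ra / min_nz,
            "occupancy": occupancy,
        },
        index=X.index,
    )
    if counts is not None:
        totals = counts.otu_totals.reindex(X.index)
        if totals.isna().any():
            raise ValueError("count table does not cover all OTUs in X")
        prof["total_reads"] = totals.astype(np.int64)
        flag = np.full(len(prof), "none", dtype=object)
        flag[(prof["total_reads"] == 1) & (prof["occupancy"] == 1)] = "absolute_singleton"
        flag[prof["total_reads"] == 2] = "doubleton"
        prof["singleton_flag"] = flag
    else:
        prof["total_reads"] = pd.array([pd.NA] * len(prof), dtype="Int64")
        prof["singleton_flag"] = "none"
    return prof


def classify(
    profiles: pd.DataFrame, cfg: RarityConfig | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Assign fraction (abundant vs rare pool) and rarity class to profiles.

    Returns the annotated profiles plus a per-class count summary.  The
    classes always partition the community: every OTU is exactly one of
    ABUNDANT, CRT, RARE or PER.
    """
    cfg = cfg or RarityConfig()
    out = profiles.copy()
    abundant = out["mean_ra"].to_numpy() > cfg.abundant_threshold
    out["fraction_class"] = np.where(abundant, ABUNDANT, RARE_POOL)
    ratio = out["ratio"].to_numpy()
    is_crt = ratio > cfg.crt_ratio if cfg.crt_strict else ratio >= cfg.crt_ratio
    rarity = np.where(is_crt, CRT, np.where(ratio < cfg.per_ratio, PER, RARE))
    out["rarity_class"] = np.where(abundant, NA, rarity)
    summary = {
        ABUNDANT: int(abundant.sum()),
        CRT: int((out["rarity_class"] == CRT).sum()),
        RARE: int((out["rarity_class"] == RARE).sum()),
        PER: int((out["rarity_class"] == PER).sum()),
        "total": int(len(out)),
    }
    return out, summary


def gradient_thresholds(cfg: RarityConfig | None = None) -> np.ndarray:
    """Descending thresholds start, start-step, ..., end (inclusive).

    The step must divide (start - end) evenly, otherwise the gradient is
    ill-formed and a ValueError is raised.
    """
    cfg = cfg or RarityConfig()
    span = cfg.gradient_start - cfg.gradient_end
    n_steps = span / cfg.gradient_step
    k = int(round(n_steps))
    if abs(n_steps - k) > 1e-6:
        raise ValueError(
            f"gradient_step {cfg.gradient_step} does not evenly divide "
            f"[{cfg.gradient_end}, {cfg.gradient_start}]"
        )
    return cfg.gradient_start - np.arange(k + 1) * cfg.gradient_step


def gradient_subsets(
    profiles: pd.DataFrame, cfg: RarityConfig | None = None
) -> list[tuple[float, frozenset[str]]]:
    """Nested rare subsets along the rarity-threshold gradient.

    ``subset(t)`` holds the OTUs with ``mean_ra < t`` (strict, matching the
    '<1%' convention), so lowering t can only shrink the subset — the
    subsets are nested.
    """
    thresholds = gradient_thresholds(cfg)
    mean_ra = profiles["mean_ra"]
    return [
        (float(t), frozenset(profiles.index[mean_ra < t])) for t in thresholds
    ]


def venn_site_sharing(
    X: pd.DataFrame,
    meta: pd.DataFrame,
    otu_subset: set[str] | frozenset[str],
) -> dict[tuple[str, ...], int]:
    """Shared/indigenous OTU counts over every site combination.

    An OTU is *present at a site* when it has nonzero abundance in at least
    one sample of that site.  Each OTU in ``otu_subset`` is assigned to
    exactly one of the 2^S - 1 site combinations (keys are sorted tuples of
    site labels); single-site regions are the indigenous taxa.
    """
    site_of = dict(zip(meta["sample_id"], meta["site"]))
    missing = [s for s in X.columns if s not in site_of]
    if missing:
        raise ValueError(f"sample {missing[0]!r} has no site in metadata")
    sites = sorted(set(site_of[s] for s in X.columns))
    if len(sites) < 2:
        raise ValueError("venn analysis needs at least two sites")
    unknown = [o for o in otu_subset if o not in X.index]
    if unknown:
        raise ValueError(f"OTU {unknown[0]!r} not in the abundance table")

    from itertools import combinations

    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(sites) + 1):
        for combo in combinations(sites, r):
            regions[combo] = 0
    site_cols = {
        site: [s for s in X.columns if site_of[s] == site] for site in sites
    }
    for otu in sorted(otu_subset):
        present = tuple(
            site for site in sites if (X.loc[otu, site_cols[site]] > 0).any()
        )
        if present:
            regions[present] += 1
    return regions
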