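"""Bray-Curtis dissimilarity and its additive partition over OTU classes.

For communities j and k with abundances X_ij,

    BC_jk = sum_i |X_ij - X_ik| / sum_i (X_ij + X_ik).

Because the numerator is a plain sum over taxa, BC decomposes exactly over
any partition of the OTUs: the contribution of a class keeps only that
class's taxa in the numerator while the scaling denominator still runs over
all taxa.  Class contributions therefore add up to the total BC for every
sample pair, and each class's percentage of the pair's total quantifies how
much of the between-community differentiation that fraction of the
community (abundant taxa, CRT, RARE, PER) carries.

On relative-abundance input every denominator equals 2 exactly; the
functions also accept raw non-negative matrices (e.g. a rare-subset slice
of the community), where the denominator is the pair's summed mass.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["bray_curtis", "partition_bc", "summarize_contributions"]


def _as_matrix(X: pd.DataFrame) -> np.ndarray:
    vals = X.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("abundances must be non-negative")
    return vals


def bray_curtis(X: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between the columns of X.

    Returns a symmetric samples x samples DataFrame with zero diagonal and
    values in [0, 1]; identical columns give 0, disjoint supports give 1.
    A pair of empty (all-zero) columns has an undefined 0/0 ratio and is
    reported as 0 (two empty communities do not differ).
    """
    vals = _as_matrix(X)
    num = np.abs(vals[:, :, None] - vals[:, None, :]).sum(axis=0)
    totals = vals.sum(axis=0)
    den = totals[:, None] + totals[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        bc = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(bc, 0.0)
    return pd.DataFrame(bc, index=X.columns, columns=X.columns)


def partition_bc(
    X: pd.DataFrame,
    classes: Mapping[str, str],
    class_labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Partition each pair's BC into per-class numerator contributions.

    Parameters
    ----------
    X
        Abundance matrix, OTUs x samples.
    classes
        Full mapping otu_id -> class label; an OTU of X without a label is
        an error (the partition must cover the table).
    class_labels
        Optional explicit label universe, so that classes with no members
        still appear with zero contribution.

    Returns
    -------
    Tidy DataFrame with one row per (unordered sample pair, class):
    ``sample_j``, ``sample_k``, ``bc_total``, ``class_label``, ``bc_part``
    and ``pct`` (= 100 * bc_part / bc_total).  Contributions are additive:
    per pair the bc_part values sum to bc_total to machine precision.  For
    a pair with bc_total = 0 the percentage is undefined and reported NaN.
    """
    missing = [o for o in X.index if o not in classes]
    if missing:
        raise ValueError(f"OTU {missing[0]!r} has no class label")
    labels = list(class_labels) if class_labels is not None else sorted(
        set(classes[o] for o in X.index)
    )
    for o in X.index:
        if classes[o] not in labels:
            raise ValueError(f"class {classes[o]!r} missing from class_labels")

    vals = _as_matrix(X)
    samples = list(X.columns)
    totals = vals.sum(axis=0)
    label_of = np.array([classes[o] for o in X.index], dtype=object)
    masks = {lab: label_of == lab for lab in labels}

    rows = []
    for a in range(len(samples)):
        for b in range(a + 1, len(samples)):
            diff = np.abs(vals[:, a] - vals[:, b])
            den = totals[a] + totals[b]
            bc_total = diff.sum() / den if den > 0 else 0.0
            for lab in labels:
                part = diff[masks[lab]].sum() / den if den > 0 else 0.0
                pct = 100.0 * part / bc_total if bc_total > 0 else np.nan
                rows.append(
                    {
                        "sample_j": samples[a],
                        "sample_k": samples[b],
                        "bc_total": bc_total,
                        "class_label": lab,
                        "bc_part": part,
                        "pct": pct,
                    }
                )
    return pd.DataFrame(rows)


def summarize_contributions(
    parts: pd.DataFrame,
    class_label: str,
    mode: str = "total",
    rare_classes: Sequence[str] = ("CRT", "RARE", "PER"),
) -> pd.Series:
    """Quantile summary of a class's percentage contribution over pairs.

    ``mode="total"`` summarizes the class's share of each pair's total BC.
    ``mode="rare-only"`` re-expresses the contribution as a share of the
    rare-pool numerator (sum of bc_part over ``rare_classes``) — i.e. how
    much of the rare biosphere's own beta diversity the class carries.

    Pairs whose denominator is zero (identical samples, or no rare-pool
    signal) are excluded from the quantiles and counted in
    ``n_undefined_pairs``.
    """
    if class_label not in set(parts["class_label"]):
        raise ValueError(f"no rows for class {class_label!r}")
    wide = parts.pivot_table(
        index=["sample_j", "sample_k"], columns="class_label", values="bc_part"
    )
    if mode == "total":
        den = parts.pivot_table(
            index=["sample_j", "sample_k"], values="bc_total"
        )["bc_total"]
    elif mode == "rare-only":
        present = [c for c in rare_classes if c in wide.columns]
        if not present:
            raise ValueError("no rare classes present in the partition")
        den = wide[present].sum(axis=1)
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    num = wide[class_label]
    defined = den > 0
    pct = 100.0 * num[defined] / den[defined]
    return pd.Series(
        {
            "min": pct.min(),
            "q1": pct.quantile(0.25),
            "median": pct.median(),
            "mean": pct.mean(),
            "q3": pct.quantile(0.75),
            "max": pct.max(),
            "n_pairs": int(defined.sum()),
            "n_undefined_pairs": int((~defined).sum()),
        }
    )
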