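"""End-to-end workflow: classification, diversity, BC partition, BGI, Venn.

:func:`run_all` sequences the full analysis on either a real OTU table (+
optional metadata) or a freshly simulated community, and writes every
intermediate as a provenance-stamped TSV plus a plain-text summary of the
headline statistics.  Given the same config and seed the report is byte
identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from raretaxa.betapart import partition_bc, summarize_contributions
from raretaxa.dendro import gradient_bgi
from raretaxa.diversity import correlate, sample_diversity
from raretaxa.io import (
    OtuTable,
    read_metadata,
    read_otu_table,
    to_relative_abundance,
    write_metadata,
    write_otu_table,
)
from raretaxa.rarity import (
    ABUNDANT,
    RARITY_CLASSES,
    RarityConfig,
    classify,
    gradient_subsets,
    profile_otus,
    venn_site_sharing,
)
from raretaxa.simulate import SyntheticSpec, generate

logger = logging.getLogger(__name__)

try:
    from importlib.metadata import version as _pkg_version

    _version = _pkg_version("raretaxa")
except Exception:  # pragma: no cover - not installed
    _version = "unknown"

__all__ = ["RunConfig", "run_all", "summarize_classes"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``otu_table`` points at a count TSV (with optional ``metadata``)
    or, when it is None, a synthetic community is generated from
    ``synthetic`` (defaulting to :class:`SyntheticSpec`) with ``seed``.
    """

    out_dir: Path
    otu_table: Path | None = None
    metadata: Path | None = None
    synthetic: SyntheticSpec | None = None
    rarity: RarityConfig = field(default_factory=RarityConfig)
    linkage: str = "average"
    scopes: tuple[str, ...] = ("all", "abundant", "rare")
    variables: tuple[str, ...] = ("mcrA_copies", "rate_ac", "rate_h2co2")
    venn_thresholds: tuple[float, ...] = (0.01, 0.005, 0.001)
    seed: int = 0
    quiet: bool = False


def summarize_classes(
    profiles: pd.DataFrame, counts: OtuTable | None = None
) -> dict[str, float]:
    """Headline class statistics from classified profiles.

    Per class: OTU count and richness share (percent of all OTUs); the
    rare-pool aggregate; and, when the count table is given, each class's
    share of the total reads.
    """
    if "rarity_class" not in profiles.columns:
        raise ValueError("profiles are not classified")
    total = len(profiles)
    is_abundant = profiles["fraction_class"] == ABUNDANT
    out: dict[str, float] = {"n_otus": total, "n_abundant": int(is_abundant.sum())}
    for c in RARITY_CLASSES:
        out[f"n_{c.lower()}"] = int((profiles["rarity_class"] == c).sum())
    out["n_rare_pool"] = total - out["n_abundant"]
    out["richness_share_abundant_pct"] = 100.0 * out["n_abundant"] / total
    out["richness_share_rare_pool_pct"] = 100.0 * out["n_rare_pool"] / total
    for c in RARITY_CLASSES:
        out[f"richness_share_{c.lower()}_pct"] = 100.0 * out[f"n_{c.lower()}"] / total
    if counts is not None:
        totals = counts.otu_totals.reindex(profiles.index)
        grand = totals.sum()
        out["read_share_abundant_pct"] = 100.0 * totals[is_abundant].sum() / grand
        out["read_share_rare_pool_pct"] = 100.0 * totals[~is_abundant].sum() / grand
        for c in RARITY_CLASSES:
            mask = profiles["rarity_class"] == c
            out[f"read_share_{c.lower()}_pct"] = 100.0 * totals[mask].sum() / grand
    return out


def _write_tsv(df: pd.DataFrame, path: Path, provenance: str, **to_csv) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(provenance + "\n")
        df.to_csv(fh, sep="\t", **to_csv)


def run_all(cfg: RunConfig) -> dict[str, object]:
    """Run classification -> alpha diversity/correlations -> BC partition ->
    gradient BGI -> Venn, writing all outputs under ``cfg.out_dir``.

    Returns a bundle with the in-memory results and the output paths.  Any
    stage failure is re-raised annotated with the stage name.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    level = logging.WARNING if cfg.quiet else logging.INFO
    logging.basicConfig(level=level)
    prov = f"# raretaxa v{_version} seed={cfg.seed}"
    bundle: dict[str, object] = {"out_dir": out_dir}
    stage = "setup"

    def _tick(name: str) -> float:
        nonlocal stage
        stage = name
        logger.info("stage: %s", name)
        return time.perf_counter()

    try:
        t0 = _tick("load")
        if cfg.otu_table is not None:
            if not Path(cfg.otu_table).exists():
                raise FileNotFoundError(f"OTU table not found: {cfg.otu_table}")
            table = read_otu_table(cfg.otu_table)
            meta = None
            if cfg.metadata is not None:
                if not Path(cfg.metadata).exists():
                    raise FileNotFoundError(f"metadata not found: {cfg.metadata}")
                meta = read_metadata(cfg.metadata)
        else:
            spec = cfg.synthetic or SyntheticSpec()
            table, meta, truth = generate(spec, seed=cfg.seed)
            bundle["truth"] = truth
            write_otu_table(table, out_dir / "otu_table.tsv")
            write_metadata(meta, out_dir / "metadata.tsv")
        X = to_relative_abundance(table)
        logger.info("loaded %d OTUs x %d samples (%.2fs)", table.n_otus,
                    table.n_samples, time.perf_counter() - t0)

        t0 = _tick("classify")
        profiles, class_counts = classify(profile_otus(X, table), cfg.rarity)
        headline = summarize_classes(profiles, table)
        _write_tsv(profiles, out_dir / "profiles.tsv", prov, index_label="otu_id")
        _write_tsv(
            pd.Series(headline, name="value").to_frame(),
            out_dir / "class_summary.tsv",
            prov,
            index_label="statistic",
        )
        bundle["profiles"] = profiles
        bundle["class_counts"] = class_counts
        bundle["class_summary"] = headline

        t0 = _tick("diversity")
        div = sample_diversity(table, scopes=cfg.scopes, profiles=profiles)
        _write_tsv(div, out_dir / "diversity.tsv", prov, index=False)
        bundle["diversity"] = div
        if meta is not None and any(v in meta.columns for v in cfg.variables):
            variables = [v for v in cfg.variables if v in meta.columns]
            corr = correlate(div, meta, variables=variables)
            _write_tsv(corr, out_dir / "correlations.tsv", prov, index=False)
            bundle["correlations"] = corr

        t0 = _tick("beta-partition")
        class_of = {
            o: (ABUNDANT if profiles.at[o, "fraction_class"] == ABUNDANT
                else profiles.at[o, "rarity_class"])
            for o in profiles.index
        }
        parts = partition_bc(X, class_of, class_labels=[ABUNDANT, *RARITY_CLASSES])
        _write_tsv(parts, out_dir / "bc_pairs.tsv", prov, index=False)
        summaries = {}
        for c in [ABUNDANT, *RARITY_CLASSES]:
            summaries[f"{c}_of_total"] = summarize_contributions(parts, c, mode="total")
        for c in RARITY_CLASSES:
            summaries[f"{c}_of_rare"] = summarize_contributions(parts, c, mode="rare-only")
        bc_summary = pd.DataFrame(summaries).T
        _write_tsv(bc_summary, out_dir / "bc_summary.tsv", prov, index_label="contribution")
        bundle["bc_partition"] = parts
        bundle["bc_summary"] = bc_summary

        t0 = _tick("dendrogram-robustness")
        subsets = gradient_subsets(profiles, cfg.rarity)
        comparison = gradient_bgi(X, subsets, linkage=cfg.linkage)
        _write_tsv(comparison.bgi, out_dir / "bgi.tsv", prov, index_label="threshold")
        with open(out_dir / "dendrograms.nwk", "w", encoding="utf-8") as fh:
            for t, d in comparison.dendrograms.items():
                fh.write(f"[threshold={t:g}] {d.to_newick()}\n")
        bundle["bgi"] = comparison

        t0 = _tick("venn")
        if meta is not None and meta["site"].nunique() >= 2:
            venn_rows = []
            for t in cfg.venn_thresholds:
                rare_ids = frozenset(profiles.index[profiles["mean_ra"] < t])
                for combo, n in venn_site_sharing(X, meta, rare_ids).items():
                    venn_rows.append(
                        {"threshold": t, "sites": "&".join(combo),
                         "n_sites": len(combo), "n_otus": n}
                    )
            venn = pd.DataFrame(venn_rows)
            _write_tsv(venn, out_dir / "venn.tsv", prov, index=False)
            bundle["venn"] = venn

        stage = "summary"
        lines = [prov, ""]
        lines.append(f"OTUs: {headline['n_otus']}  samples: {table.n_samples}")
        lines.append(
            "classes: abundant=%d CRT=%d RARE=%d PER=%d (rare pool %d)"
            % (headline["n_abundant"], headline["n_crt"], headline["n_rare"],
               headline["n_per"], headline["n_rare_pool"])
        )
        lines.append(
            "richness share: abundant %.1f%%, rare %.1f%% (PER %.1f%%)"
            % (headline["richness_share_abundant_pct"],
               headline["richness_share_rare_pool_pct"],
               headline["richness_share_per_pct"])
        )
        if "read_share_abundant_pct" in headline:
            lines.append(
                "read share: abundant %.1f%%, rare %.1f%%"
                % (headline["read_share_abundant_pct"],
                   headline["read_share_rare_pool_pct"])
            )
        for key in ("ABUNDANT_of_total", "CRT_of_total", "CRT_of_rare"):
            s = bc_summary.loc[key]
            lines.append(
                f"BC contribution {key}: mean {s['mean']:.1f}% "
                f"(range {s['min']:.1f}-{s['max']:.1f}%)"
            )
        if "correlations" in bundle:
            corr = bundle["correlations"]
            for _, row in corr[corr["index_name"] == "chao1"].iterrows():
                lines.append(
                    "pearson chao1[%s] ~ %s: r=%.2f p=%.3g %s"
                    % (row["scope"], row["variable"], row["r"], row["p"], row["stars"])
                )
        (out_dir / "summary.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
        with open(out_dir / "config.json", "w", encoding="utf-8") as fh:
            json.dump(_config_dict(cfg), fh, indent=2, default=str)
        return bundle
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _config_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    d["out_dir"] = str(cfg.out_dir)
    return d
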