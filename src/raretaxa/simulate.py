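"""Synthetic multi-site OTU communities with planted rarity structure.

The generator emulates a small multi-site amplicon survey of a single
functional guild (a methanogen *mcrA*-style data set): four sites with
unequal numbers of depth-profile samples, ~175 OTUs, and variable
sequencing depth per sample (roughly 1,100-10,000 reads).  Each OTU is
planted into one of four classes before any sampling noise is applied:

* **abundant** — a lognormal shared core holding the large majority of the
  reads, present at every site, mean relative abundance > 1%;
* **CRT** — low baseline with 1-2 bloom samples hundreds of times above it;
* **RARE** — intermediate fluctuation (planted max:min ratio in [10, 50]);
* **PER** — flat low abundance (planted ratio <= 2), including a set of
  absolute singletons whose realized count is forced to exactly 1 read.

Planted ratios sit at least a factor of ~2 away from the 5 and 100
classification cutoffs, so in the infinite-depth (expected-abundance)
limit the classifier recovers the planted labels exactly; at finite,
realistic depths multinomial noise blurs the boundaries, which is what the
statistical recovery tests quantify.

Half of the RARE/PER taxa are endemic to a single site (zero expectation
elsewhere), with sites receiving Dirichlet-weighted shares of the endemic
pool — sites genuinely differ in rare richness, as field sites do.  The
functional metadata (methane production rates, mcrA gene copies) is
generated as a linear function of each sample's planted rare richness plus
Gaussian noise, so diversity-function coupling exists by construction for
the rare fraction and not for the abundant core.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from raretaxa.io import OtuTable
from raretaxa.rarity import ABUNDANT, CRT, PER, RARE

SITE_NAMES = ("DCL", "GAN", "HAI", "HUA")

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate", "evaluate_recovery"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted community.

    Class sizes default to 25 abundant / 18 CRT / 48 RARE / 84 PER (175
    OTUs, 40 of the PER being absolute singletons) over 4 sites with
    5+6+4+4 samples.  Mean-abundance scales put ~85% of the reads in the
    abundant core and ~13% in the rare pool, with the PER fraction holding
    a large share of richness but well under 1% of the reads.
    """

    n_sites: int = 4
    samples_per_site: tuple[int, ...] = (5, 6, 4, 4)
    n_abundant: int = 25
    n_crt: int = 18
    n_rare: int = 48
    n_per: int = 84
    n_singletons: int = 40
    # sequencing depth: most samples are deep (>= depth_deep_min reads),
    # with a few shallow exceptions down near depth_range[0] — the typical
    # profile of an uneven amplicon run
    depth_range: tuple[int, int] = (1100, 10000)
    n_shallow_samples: int = 2
    depth_shallow_max: int = 3000
    depth_deep_min: int = 5000
    # abundant core: lognormal base shares, floored so every abundant OTU
    # keeps a mean relative abundance comfortably above the 1% cutoff
    abundant_mass: float = 0.85
    abundant_lognormal: tuple[float, float] = (0.0, 1.0)
    abundant_min_share: float = 0.018
    abundant_dropout: float = 0.05
    abundant_sample_sigma: float = 0.15
    # per-OTU mean relative abundances (lognormal draw, then clipped)
    crt_mean_lognormal: tuple[float, float] = (math.log(3e-3), 0.5)
    crt_mean_clip: tuple[float, float] = (5e-4, 6e-3)
    rare_mean_lognormal: tuple[float, float] = (math.log(1.1e-3), 0.6)
    rare_mean_clip: tuple[float, float] = (5e-5, 5e-3)
    per_mean_lognormal: tuple[float, float] = (math.log(1e-4), 0.5)
    per_mean_clip: tuple[float, float] = (2e-5, 5e-4)
    # fluctuation structure
    crt_bloom_factor: float = 300.0
    crt_bloom_samples: tuple[int, int] = (1, 2)
    rare_ratio_range: tuple[float, float] = (10.0, 50.0)
    per_ratio_max: float = 2.0
    presence_prob: float = 0.8
    per_presence_prob: float = 0.5
    # endemism and site habitat quality: one Dirichlet draw sets both the
    # share of the endemic pool a site receives and how completely the
    # shared rare pool occupies its samples, so sites genuinely differ in
    # rare richness (as field sites do)
    endemic_fraction: float = 0.5
    site_weight_alpha: float = 1.0
    site_quality_clip: tuple[float, float] = (0.5, 1.6)
    # function = beta0 + beta1 * planted rare richness + N(0, sd)
    function_coupling: tuple[float, float, float] = (0.5, 0.15, 0.6)
    copies_coupling: tuple[float, float, float] = (2e6, 1.5e5, 1e6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 2 or len(self.samples_per_site) != self.n_sites:
            raise ValueError("need >= 2 sites and one sample count per site")
        if min(self.n_abundant, self.n_crt, self.n_rare, self.n_per) < 0:
            raise ValueError("class sizes must be >= 0")
        if self.n_abundant + self.n_crt + self.n_rare + self.n_per == 0:
            raise ValueError("community has no OTUs")
        if not 0 <= self.n_singletons <= self.n_per:
            raise ValueError("n_singletons must lie within n_per")
        if self.depth_range[0] < 1 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("invalid depth range")
        if self.n_shallow_samples < 0:
            raise ValueError("n_shallow_samples must be >= 0")
        if self.function_coupling[1] < 0:
            raise ValueError("function coupling slope beta1 must be >= 0")

    @property
    def n_samples(self) -> int:
        return sum(self.samples_per_site)

    @property
    def n_otus(self) -> int:
        return self.n_abundant + self.n_crt + self.n_rare + self.n_per


@dataclass
class SyntheticTruth:
    """Planted ground truth: labels, endemism, richness and expectations."""

    class_labels: pd.Series  # otu_id -> ABUNDANT | CRT | RARE | PER
    home_site: pd.Series  # otu_id -> site label or "shared"
    rare_richness: pd.Series  # sample_id -> planted rare-pool richness
    expected_ra: pd.DataFrame  # noiseless relative abundances (cols sum to 1)
    spec: SyntheticSpec


def _site_labels(n_sites: int) -> list[str]:
    if n_sites <= len(SITE_NAMES):
        return list(SITE_NAMES[:n_sites])
    return list(SITE_NAMES) + [f"S{i}" for i in range(len(SITE_NAMES) + 1, n_sites + 1)]


def _choose_present(
    rng: np.random.Generator, allowed: np.ndarray, probs: np.ndarray, minimum: int
) -> np.ndarray:
    """Boolean presence mask over all samples: Bernoulli(probs[j]) within the
    allowed columns, topped up to at least ``minimum`` present."""
    present = np.zeros(allowed.size, dtype=bool)
    idx = np.flatnonzero(allowed)
    present[idx] = rng.random(idx.size) < probs[idx]
    short = minimum - int(present.sum())
    if short > 0:
        off = idx[~present[idx]]
        extra = rng.choice(off, size=min(short, off.size), replace=False)
        present[extra] = True
    return present


def _abundant_shares(rng: np.random.Generator, spec: SyntheticSpec) -> np.ndarray:
    mu, sigma = spec.abundant_lognormal
    w = rng.lognormal(mu, sigma, spec.n_abundant)
    shares = w / w.sum() * spec.abundant_mass
    if spec.n_abundant * spec.abundant_min_share >= spec.abundant_mass:
        raise ValueError("abundant_min_share too large for abundant_mass")
    for _ in range(50):
        if shares.min() >= spec.abundant_min_share * 0.999:
            break
        shares = np.maximum(shares, spec.abundant_min_share)
        shares *= spec.abundant_mass / shares.sum()
    return shares


def generate(
    spec: SyntheticSpec | None = None, seed: int | None = None
) -> tuple[OtuTable, pd.DataFrame, SyntheticTruth]:
    """Generate (count table, sample metadata, planted truth).

    The expected-abundance matrix is built class by class, column-normalized
    (stored in the truth for infinite-depth checks), and per-sample counts
    are drawn multinomially at each sample's depth.  Realized counts define
    singleton status: the planted singletons are placed as exactly one read,
    and any OTU that the multinomial left with zero reads is given one read
    in its highest-expectation sample (taken from that sample's most
    abundant OTU, so depths stay exact).

    ``seed`` overrides ``spec.seed`` without rebuilding the spec.
    """
    spec = spec or SyntheticSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    rng = np.random.default_rng(spec.seed)

    sites = _site_labels(spec.n_sites)
    sample_ids: list[str] = []
    sample_site: list[str] = []
    sample_depth_cm: list[float] = []
    for site, n in zip(sites, spec.samples_per_site):
        for i in range(n):
            sample_ids.append(f"{site}{i + 1}")
            sample_site.append(site)
            sample_depth_cm.append(5.0 + 15.0 * i)
    n_samp = len(sample_ids)
    site_arr = np.array(sample_site)

    otu_ids: list[str] = [f"OTU_{i + 1:04d}" for i in range(spec.n_otus)]
    labels = np.array(
        [ABUNDANT] * spec.n_abundant
        + [CRT] * spec.n_crt
        + [RARE] * spec.n_rare
        + [PER] * spec.n_per,
        dtype=object,
    )
    is_singleton = np.zeros(spec.n_otus, dtype=bool)
    per_idx = np.flatnonzero(labels == PER)
    if spec.n_singletons:
        is_singleton[rng.choice(per_idx, size=spec.n_singletons, replace=False)] = True

    # endemic assignment: a fraction of the RARE + non-singleton PER pool is
    # restricted to one site, with Dirichlet-weighted site shares
    site_weights = rng.dirichlet(np.full(spec.n_sites, spec.site_weight_alpha))
    quality = np.clip(spec.n_sites * site_weights, *spec.site_quality_clip)
    site_index = np.array([sites.index(s) for s in sample_site])
    rare_probs = np.clip(spec.presence_prob * quality[site_index], 0.05, 0.95)
    per_probs = np.clip(spec.per_presence_prob * quality[site_index], 0.05, 0.95)
    home = np.array(["shared"] * spec.n_otus, dtype=object)
    eligible = np.flatnonzero(((labels == RARE) | (labels == PER)) & ~is_singleton)
    n_endemic = int(round(spec.endemic_fraction * (spec.n_rare + spec.n_per)))
    n_endemic = min(n_endemic, eligible.size)
    if n_endemic:
        endemic = rng.choice(eligible, size=n_endemic, replace=False)
        home[endemic] = rng.choice(sites, size=n_endemic, p=site_weights)

    expected = np.zeros((spec.n_otus, n_samp))
    lo, hi = spec.depth_range
    singleton_eps = 0.5 / hi

    for i in range(spec.n_otus):
        allowed = (
            np.ones(n_samp, dtype=bool) if home[i] == "shared" else site_arr == home[i]
        )
        lab = labels[i]
        if lab == ABUNDANT:
            continue  # filled as a block below
        if is_singleton[i]:
            # one tiny-expectation sample; the site choice follows the
            # endemic site weights so singletons pool where endemics pool
            site = rng.choice(sites, p=site_weights)
            cols = np.flatnonzero(site_arr == site)
            j = int(rng.choice(cols))
            expected[i, j] = singleton_eps
            home[i] = site
            continue
        if lab == CRT:
            n_bloom = int(rng.integers(spec.crt_bloom_samples[0], spec.crt_bloom_samples[1] + 1))
            present = _choose_present(rng, allowed, rare_probs, n_bloom + 1)
            idx = np.flatnonzero(present)
            mult = rng.uniform(1.0, 3.0, idx.size)
            order = rng.permutation(idx.size)
            mult[order[0]] = 1.0  # anchor the planted minimum
            mult[order[1 : 1 + n_bloom]] = spec.crt_bloom_factor
            mu, sigma = spec.crt_mean_lognormal
            m = float(np.clip(rng.lognormal(mu, sigma), *spec.crt_mean_clip))
        elif lab == RARE:
            present = _choose_present(rng, allowed, rare_probs, 2)
            idx = np.flatnonzero(present)
            r = rng.uniform(*spec.rare_ratio_range)
            mult = rng.uniform(1.0, r, idx.size)
            order = rng.permutation(idx.size)
            mult[order[0]] = 1.0
            mult[order[1]] = r  # anchor the planted maximum
            mu, sigma = spec.rare_mean_lognormal
            m = float(np.clip(rng.lognormal(mu, sigma), *spec.rare_mean_clip))
        else:  # PER
            present = _choose_present(rng, allowed, per_probs, 1)
            idx = np.flatnonzero(present)
            mult = rng.uniform(1.0, spec.per_ratio_max, idx.size)
            mu, sigma = spec.per_mean_lognormal
            m = float(np.clip(rng.lognormal(mu, sigma), *spec.per_mean_clip))
        # scale so the mean over ALL samples (zeros included) equals m
        expected[i, idx] = mult * (m * n_samp / mult.sum())

    if spec.n_abundant:
        shares = _abundant_shares(rng, spec)
        noise = rng.lognormal(0.0, spec.abundant_sample_sigma, (spec.n_abundant, n_samp))
        block = shares[:, None] * noise
        dropout = rng.random((spec.n_abundant, n_samp)) < spec.abundant_dropout
        # never drop an abundant OTU from every sample
        for i in range(spec.n_abundant):
            if dropout[i].all():
                dropout[i, rng.integers(n_samp)] = False
        block[dropout] = 0.0
        expected[:spec.n_abundant] = block

    col_tot = expected.sum(axis=0)
    expected_ra = expected / col_tot

    deep_lo = min(max(spec.depth_deep_min, lo), hi)
    depths = rng.integers(deep_lo, hi + 1, n_samp)
    n_shallow = min(spec.n_shallow_samples, n_samp)
    if n_shallow and spec.depth_shallow_max > lo:
        shallow = rng.choice(n_samp, size=n_shallow, replace=False)
        depths[shallow] = rng.integers(lo, min(spec.depth_shallow_max, hi) + 1, n_shallow)
    counts = np.zeros((spec.n_otus, n_samp), dtype=np.int64)
    draw_p = expected_ra.copy()
    draw_p[is_singleton] = 0.0
    draw_p /= draw_p.sum(axis=0)
    for j in range(n_samp):
        counts[:, j] = rng.multinomial(depths[j], draw_p[:, j])

    def _donate(j: int, receiver: int) -> None:
        col = counts[:, j]
        donor = int(np.argmax(np.where(np.arange(spec.n_otus) == receiver, -1, col)))
        col[donor] -= 1
        col[receiver] += 1

    for i in np.flatnonzero(is_singleton):
        _donate(int(np.argmax(expected_ra[i])), i)
    for i in np.flatnonzero((counts.sum(axis=1) == 0) & ~is_singleton):
        _donate(int(np.argmax(expected_ra[i])), i)

    table = OtuTable(pd.DataFrame(counts, index=otu_ids, columns=sample_ids))

    rare_mask = labels != ABUNDANT
    rare_richness = (expected_ra[rare_mask] > 0).sum(axis=0)
    b0, b1, sd = spec.function_coupling
    rate_ac = np.maximum(b0 + b1 * rare_richness + rng.normal(0, sd, n_samp), 0.0)
    rate_h2 = np.maximum(b0 + b1 * rare_richness + rng.normal(0, sd, n_samp), 0.0)
    c0, c1, csd = spec.copies_coupling
    copies = np.maximum(c0 + c1 * rare_richness + rng.normal(0, csd, n_samp), 1e3)
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "site": sample_site,
            "depth_cm": sample_depth_cm,
            "mcrA_copies": copies,
            "rate_ac": rate_ac,
            "rate_h2co2": rate_h2,
        }
    )

    truth = SyntheticTruth(
        class_labels=pd.Series(labels, index=otu_ids, name="class_label"),
        home_site=pd.Series(home, index=otu_ids, name="home_site"),
        rare_richness=pd.Series(rare_richness, index=sample_ids, name="rare_richness"),
        expected_ra=pd.DataFrame(expected_ra, index=otu_ids, columns=sample_ids),
        spec=spec,
    )
    return table, meta, truth


def evaluate_recovery(
    truth: SyntheticTruth, profiles: pd.DataFrame
) -> dict[str, object]:
    """Confusion of planted vs inferred classes, with per-class precision/recall.

    ``profiles`` must be classified (columns ``fraction_class`` and
    ``rarity_class``) over exactly the planted OTU universe.  For a class
    with no planted (or no predicted) members the recall (precision) is
    undefined and reported NaN.
    """
    if set(profiles.index) != set(truth.class_labels.index):
        raise ValueError("profiles and truth cover different OTU sets")
    pred = np.where(
        profiles["fraction_class"] == ABUNDANT, ABUNDANT, profiles["rarity_class"]
    )
    pred = pd.Series(pred, index=profiles.index, name="predicted")
    true = truth.class_labels.reindex(profiles.index)
    classes = [ABUNDANT, CRT, RARE, PER]
    confusion = pd.crosstab(true, pred).reindex(
        index=classes, columns=classes, fill_value=0
    )
    per_class = {}
    for c in classes:
        tp = confusion.at[c, c]
        n_true = int(confusion.loc[c].sum())
        n_pred = int(confusion[c].sum())
        per_class[c] = {
            "recall": tp / n_true if n_true else float("nan"),
            "precision": tp / n_pred if n_pred else float("nan"),
            "n_true": n_true,
            "n_pred": n_pred,
        }
    accuracy = float((true.to_numpy() == pred.to_numpy()).mean())
    return {
        "confusion": confusion,
        "per_class": pd.DataFrame(per_class).T,
        "accuracy": accuracy,
    }
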