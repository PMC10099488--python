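"""Genotype likelihoods, high-confidence genotype calls, and SNP filters.

From per-locus read stacks this module computes pileups, per-site genotype
likelihoods under a symmetric per-base error model, EM allele frequencies,
posterior genotype calls under a Hardy-Weinberg prior with a posterior
threshold and a minimum-depth rule, and the site filters used on RAD data:
masking around declared indels, a pooled depth-percentile window, a
maximum-missingness cut, and one-random-SNP-per-locus thinning.  A
coverage x missingness sensitivity grid evaluates all filter combinations.

The error model: for a read base b and genotype g alt copies,
P(b|g) = (g/2) p_alt + (1 - g/2) p_ref with p_x = 1 - eps if b = x else
eps/3.  Likelihoods are per-cell normalized so the maximum log-likelihood
is 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

from .rad_assembly import LocusCatalog

__all__ = [
    "GenotypingConfig",
    "Site",
    "GenotypeLikelihoods",
    "GenotypeCalls",
    "genotype_likelihoods",
    "estimate_allele_frequencies",
    "call_genotypes",
    "filter_sites",
    "thin_one_snp_per_locus",
    "run_filter_grid",
    "DEFAULT_GRID",
]

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}

#: the coverage x missingness sensitivity grid
DEFAULT_GRID = ((3, 10), (0.30, 0.10, 0.05, 0.01))


@dataclass
class GenotypingConfig:
    """Thresholds for genotype calling and site filtering."""

    error_rate: float = 0.01
    posterior_min: float = 0.95
    min_depth: int = 3
    max_missing: float = 0.30
    indel_window: int = 10
    depth_percentiles: tuple = (1, 99)
    min_alt_reads: int = 2  # pooled alt support to nominate a candidate site
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.posterior_min < 1:
            raise ValueError("posterior_min must be in (0, 1)")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


class Site(NamedTuple):
    locus_id: str
    position: int  # 0-based within the locus body
    ref: str
    alt: str


@dataclass
class GenotypeLikelihoods:
    """Per-individual, per-site genotype log-likelihoods.

    ``loglik`` has shape (n_individuals, n_sites, 3) for 0/1/2 alt copies,
    normalized so the per-cell maximum is 0; ``depth`` counts ref+alt reads
    only (other bases are third-allele noise handled at site nomination).
    ``site_depth`` is pooled over individuals.
    """

    individuals: list
    sites: list
    loglik: np.ndarray
    depth: np.ndarray

    @property
    def site_depth(self) -> np.ndarray:
        return self.depth.sum(axis=0)


@dataclass
class GenotypeCalls:
    """Called genotype matrix (0/1/2 alt copies, -1 = missing)."""

    individuals: list
    sites: list
    genotypes: np.ndarray  # int8 (n_individuals, n_sites)
    site_depth: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def missingness_per_site(self) -> np.ndarray:
        return (self.genotypes < 0).mean(axis=0)

    @property
    def missingness_per_individual(self) -> np.ndarray:
        return (self.genotypes < 0).mean(axis=1)

    @property
    def minor_allele_frequency(self) -> np.ndarray:
        miss = self.genotypes < 0
        n = 2 * (~miss).sum(axis=0)
        alt = np.where(miss, 0, self.genotypes).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        return np.minimum(p, 1 - p)

    def take_sites(self, idx: np.ndarray) -> "GenotypeCalls":
        return GenotypeCalls(
            individuals=self.individuals,
            sites=[self.sites[i] for i in idx],
            genotypes=self.genotypes[:, idx],
            site_depth=self.site_depth[idx],
        )


# ---------------------------------------------------------------------------
# pileup and likelihoods


def _pileup(stacks_for_locus: dict, individuals: list, length: int) -> np.ndarray:
    """Base counts per individual per position: (n_ind, length, 4)."""
    counts = np.zeros((len(individuals), length, 4), dtype=np.int32)
    for i, ind in enumerate(individuals):
        for seq in stacks_for_locus.get(ind, ()):
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)[:length]
            for bi, base in enumerate(b"ACGT"):
                hit = np.nonzero(arr == base)[0]
                counts[i, hit, bi] += 1
    return counts


def genotype_likelihoods(
    stacks: dict,
    reference: LocusCatalog,
    individuals: list,
    eps: float = 0.01,
):
    """Genotype log-likelihoods at candidate biallelic sites.

    Candidate sites are reference positions (non-masked) where the pooled
    count of the most common non-reference base reaches ``min_alt_reads``
    (2); positions where a third allele exceeds 20% of the pooled site
    depth are dropped as multi-allelic and logged.

    Returns ``(gls, dropped)`` with ``dropped`` a list of
    ``(locus_id, position, reason)``.
    """
    if not 0 < eps < 0.75:
        raise ValueError("eps must be in (0, 0.75)")
    sites: list = []
    ll_cols: list = []
    dp_cols: list = []
    dropped: list = []
    log_e = np.log(eps / 3)
    # P(base|g) for base in (ref, alt) and g in 0..2
    p_ref = np.array([1 - eps, 0.5 * (1 - eps) + 0.5 * eps / 3, eps / 3])
    p_alt = p_ref[::-1]
    lp_ref, lp_alt = np.log(p_ref), np.log(p_alt)

    for locus in reference.retained:
        lid = locus.locus_id
        if lid not in stacks:
            continue
        rep = locus.representative
        counts = _pileup(stacks[lid], individuals, len(rep))
        pooled = counts.sum(axis=0)  # (length, 4)
        for pos, ref_base in enumerate(rep):
            if ref_base not in _BASE_IDX:
                continue  # masked position
            ri = _BASE_IDX[ref_base]
            nonref = pooled[pos].copy()
            nonref[ri] = -1
            ai = int(nonref.argmax())
            if pooled[pos, ai] < 2:
                continue
            total = int(pooled[pos].sum())
            third = int(pooled[pos].sum() - pooled[pos, ri] - pooled[pos, ai])
            if third > 0.2 * total:
                dropped.append((lid, pos, "multi_allelic"))
                continue
            n_ref = counts[:, pos, ri].astype(np.float64)
            n_alt = counts[:, pos, ai].astype(np.float64)
            ll = (
                n_ref[:, None] * lp_ref[None, :]
                + n_alt[:, None] * lp_alt[None, :]
            )
            ll -= ll.max(axis=1, keepdims=True)
            ll_cols.append(ll)
            dp_cols.append(n_ref + n_alt)
            sites.append(Site(lid, pos, ref_base, _BASES[ai]))
    if sites:
        loglik = np.stack(ll_cols, axis=1)
        depth = np.stack(dp_cols, axis=1)
    else:
        loglik = np.zeros((len(individuals), 0, 3))
        depth = np.zeros((len(individuals), 0))
    return (
        GenotypeLikelihoods(
            individuals=list(individuals), sites=sites, loglik=loglik, depth=depth
        ),
        dropped,
    )


def estimate_allele_frequencies(
    gls: GenotypeLikelihoods, tol: float = 1e-8, max_iter: int = 100
) -> np.ndarray:
    """EM alternate-allele frequency per site under the HWE model.

    Individuals with zero depth at a site carry no information and are
    excluded from that site's update.  Returns the fixed point of
    q <- mean(E[g | data, q]) / 2 over informative individuals.
    """
    if gls.loglik.shape[1] == 0:
        return np.zeros(0)
    if not (gls.depth > 0).any():
        raise ValueError("no individual has positive depth")
    lik = np.exp(gls.loglik)  # (n_ind, n_sites, 3)
    informative = gls.depth > 0
    n_inf = np.maximum(informative.sum(axis=0), 1)
    q = np.full(gls.loglik.shape[1], 0.2)
    g = np.arange(3)[None, None, :]
    for _ in range(max_iter):
        prior = np.stack(
            [(1 - q) ** 2, 2 * q * (1 - q), q**2], axis=-1
        )  # (n_sites, 3)
        post = lik * prior[None, :, :]
        post /= post.sum(axis=2, keepdims=True)
        eg = (post * g).sum(axis=2)  # (n_ind, n_sites)
        q_new = (eg * informative).sum(axis=0) / (2 * n_inf)
        if np.abs(q_new - q).max() < tol:
            q = q_new
            break
        q = q_new
    return q


def call_genotypes(
    gls: GenotypeLikelihoods,
    frequencies: np.ndarray,
    config: GenotypingConfig,
) -> GenotypeCalls:
    """Posterior genotype calls under the HWE prior.

    The maximum-posterior genotype is called iff its posterior reaches
    ``posterior_min`` and the individual's ref+alt depth reaches
    ``min_depth``; otherwise the cell is missing.
    """
    q = np.asarray(frequencies, dtype=float)
    if q.size and (q.min() < 0 or q.max() > 1):
        raise ValueError("frequencies must be in [0, 1]")
    if q.size == 0:
        geno = np.zeros((len(gls.individuals), 0), dtype=np.int8)
        return GenotypeCalls(gls.individuals, [], geno, np.zeros(0))
    lik = np.exp(gls.loglik)
    prior = np.stack([(1 - q) ** 2, 2 * q * (1 - q), q**2], axis=-1)
    post = lik * prior[None, :, :]
    post /= post.sum(axis=2, keepdims=True)
    best = post.argmax(axis=2)
    best_p = np.take_along_axis(post, best[:, :, None], axis=2)[:, :, 0]
    geno = best.astype(np.int8)
    geno[(best_p < config.posterior_min) | (gls.depth < config.min_depth)] = -1
    return GenotypeCalls(
        individuals=gls.individuals,
        sites=list(gls.sites),
        genotypes=geno,
        site_depth=gls.site_depth.copy(),
    )


def genotype_posteriors(
    gls: GenotypeLikelihoods, frequencies: np.ndarray
) -> np.ndarray:
    """Full posterior tensor (n_ind, n_sites, 3); posteriors sum to 1."""
    q = np.asarray(frequencies, dtype=float)
    lik = np.exp(gls.loglik)
    prior = np.stack([(1 - q) ** 2, 2 * q * (1 - q), q**2], axis=-1)
    post = lik * prior[None, :, :]
    return post / post.sum(axis=2, keepdims=True)


# ---------------------------------------------------------------------------
# site filters


def filter_sites(
    calls: GenotypeCalls,
    declared_indels: dict,
    config: GenotypingConfig,
):
    """Apply the site-level filters; returns (filtered_calls, report).

    Rules, in order: (1) sites within ``indel_window`` bases of a declared
    indel on the same locus are removed; (2) sites whose pooled depth falls
    strictly outside the [1st, 99th] percentile (nearest-rank, over all
    sites) are removed; (3) sites with more than ``max_missing`` missing
    calls are removed; (4) sites monomorphic among the remaining calls are
    removed.  ``declared_indels`` maps locus_id -> indel position or list
    of positions.
    """
    n = calls.n_sites
    keep = np.ones(n, dtype=bool)
    report = {"input": n}

    indel_hits = 0
    for i, site in enumerate(calls.sites):
        positions = declared_indels.get(site.locus_id)
        if positions is None:
            continue
        if np.isscalar(positions):
            positions = [positions]
        if any(abs(site.position - p) <= config.indel_window for p in positions):
            keep[i] = False
            indel_hits += 1
    report["indel_window"] = indel_hits

    if n:
        lo_p, hi_p = config.depth_percentiles
        lo = np.percentile(calls.site_depth, lo_p, method="nearest")
        hi = np.percentile(calls.site_depth, hi_p, method="nearest")
        bad = (calls.site_depth < lo) | (calls.site_depth > hi)
        report["depth_percentile"] = int((bad & keep).sum())
        keep &= ~bad
    else:
        report["depth_percentile"] = 0

    miss = calls.missingness_per_site
    bad = miss > config.max_missing
    report["missingness"] = int((bad & keep).sum())
    keep &= ~bad

    maf = calls.minor_allele_frequency
    with np.errstate(invalid="ignore"):
        mono = ~(maf > 0)
    report["monomorphic"] = int((mono & keep).sum())
    keep &= ~mono

    report["output"] = int(keep.sum())
    return calls.take_sites(np.nonzero(keep)[0]), report


def thin_one_snp_per_locus(calls: GenotypeCalls, seed: int) -> GenotypeCalls:
    """Retain exactly one uniformly chosen SNP per locus (RADtag)."""
    rng = np.random.default_rng(seed)
    by_locus: dict = {}
    for i, site in enumerate(calls.sites):
        by_locus.setdefault(site.locus_id, []).append(i)
    chosen = sorted(
        int(rng.choice(idx)) for idx in
        (by_locus[lid] for lid in sorted(by_locus))
    )
    return calls.take_sites(np.asarray(chosen, dtype=int))


def run_filter_grid(
    gls: GenotypeLikelihoods,
    frequencies: np.ndarray,
    declared_indels: dict,
    config: GenotypingConfig | None = None,
    grid=DEFAULT_GRID,
    thin: bool = True,
):
    """Evaluate the coverage x missingness grid.

    Returns ``(cells, summary)``: ``cells`` maps
    (min_depth, max_missing) -> filtered (optionally thinned)
    GenotypeCalls; ``summary`` is a DataFrame with the SNP count per cell.
    """
    import pandas as pd

    config = config or GenotypingConfig()
    depths, missings = grid
    cells: dict = {}
    rows = []
    for md in depths:
        for mm in missings:
            cfg = replace(config, min_depth=md, max_missing=mm)
            calls = call_genotypes(gls, frequencies, cfg)
            filtered, report = filter_sites(calls, declared_indels, cfg)
            if thin:
                filtered = thin_one_snp_per_locus(filtered, config.seed)
            cells[(md, mm)] = filtered
            rows.append(
                {
                    "min_depth": md,
                    "max_missing": mm,
                    "n_snps": filtered.n_sites,
                    "sites_pre_thin": report["output"],
                }
            )
    return cells, pd.DataFrame(rows)
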