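"""Diversity, differentiation, structure, and migration-network statistics.

Implements the population-level summaries used in seascape population
genomics of SNP call matrices: per-population nucleotide diversity and
expected/observed heterozygosity with small-sample corrections, pairwise
Nei GST and the Meirmans-Hedrick standardized G''ST (the "normalized
fixation index") with permutation p-values, hierarchical AMOVA on squared
allele-count distances with the standard permutation schemes, PCA on the
individual covariance matrix, folded site-frequency spectra, and relative
directional migration networks built from a hypothetical migrant pool.

All operations take a :class:`~lakerad.genotyping.GenotypeCalls` (or a
plain 0/1/2/-1 matrix) plus an individual -> population mapping.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotyping import GenotypeCalls

__all__ = [
    "DiversityEstimates",
    "AMOVAResult",
    "MigrationNetwork",
    "diversity",
    "pairwise_fst",
    "amova",
    "pca_covariance",
    "folded_sfs",
    "SFS",
    "relative_migration_network",
]


def _as_matrix(calls) -> np.ndarray:
    if isinstance(calls, GenotypeCalls):
        return calls.genotypes
    return np.asarray(calls)


def _pop_indices(individuals, labels: dict) -> dict:
    pops: dict = {}
    for i, ind in enumerate(individuals):
        pops.setdefault(labels[ind], []).append(i)
    return {p: np.asarray(idx) for p, idx in pops.items()}


def _alt_freqs(geno: np.ndarray):
    """Per-site alt frequency and non-missing diploid count for one pop."""
    miss = geno < 0
    n = (~miss).sum(axis=0)
    alt = np.where(miss, 0, geno).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2 * np.maximum(n, 1)), np.nan)
    return p, n


# ---------------------------------------------------------------------------
# diversity


@dataclass
class DiversityEstimates:
    population: str
    n: int
    pi: float  # per-site nucleotide diversity over all sites
    pi_variable: float  # averaged over variable sites only
    He: float  # expected heterozygosity over variable sites
    Ho: float  # observed heterozygosity over variable sites
    n_variable_sites: int
    total_sites: int
    warning: str | None = None


def diversity(calls, labels: dict, total_sites: int) -> list:
    """Per-population diversity estimates.

    He per variable site is ``(2n/(2n-1)) (1 - p^2 - q^2)`` with n the
    non-missing diploid count at the site; pi sums the same per-site
    heterozygosity over variable sites and divides by ``total_sites``
    (variable plus invariant), which must be at least the number of
    variable sites.  Populations with fewer than 2 individuals are computed
    with a warning flag.
    """
    mat = _as_matrix(calls)
    individuals = (
        calls.individuals
        if isinstance(calls, GenotypeCalls)
        else [f"i{k}" for k in range(mat.shape[0])]
    )
    pops = _pop_indices(individuals, labels)
    out = []
    for pop, idx in sorted(pops.items()):
        sub = mat[idx]
        p, n = _alt_freqs(sub)
        valid = n > 0
        if total_sites < int(valid.sum()):
            raise ValueError("total_sites is smaller than the number of variable sites")
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(n > 0, 2 * n / np.maximum(2 * n - 1, 1), np.nan)
            h = corr * 2 * p * (1 - p)
        variable = valid & (p > 0) & (p < 1)
        nvar = int(variable.sum())
        he = float(np.nanmean(h[variable])) if nvar else 0.0
        pi_var = he  # same per-site estimator, averaged over variable sites
        pi = float(np.nansum(h[variable]) / total_sites) if nvar else 0.0
        het_obs = (sub == 1) & (sub >= 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ho_site = het_obs.sum(axis=0) / np.maximum(n, 1)
        ho = float(ho_site[variable].mean()) if nvar else 0.0
        out.append(
            DiversityEstimates(
                population=pop,
                n=len(idx),
                pi=pi,
                pi_variable=pi_var,
                He=he,
                Ho=ho,
                n_variable_sites=nvar,
                total_sites=total_sites,
                warning="n<2" if len(idx) < 2 else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# pairwise differentiation


def _hs_ht(p1, n1, p2, n2):
    """Unbiased within/total gene diversity for a pair, per site.

    HS is the average of the two sample-size-corrected within-population
    gene diversities; HT is the gene diversity of the mean allele
    frequencies plus the Nei-Chesser small-sample term HS/(2 n_harm k).
    """
    valid = (n1 > 0) & (n2 > 0)
    h1 = (2 * n1 / np.maximum(2 * n1 - 1, 1)) * 2 * p1 * (1 - p1)
    h2 = (2 * n2 / np.maximum(2 * n2 - 1, 1)) * 2 * p2 * (1 - p2)
    hs = (h1 + h2) / 2
    pbar = (p1 + p2) / 2
    with np.errstate(invalid="ignore", divide="ignore"):
        n_harm = 2 / (1 / np.maximum(n1, 1) + 1 / np.maximum(n2, 1))
        ht = 2 * pbar * (1 - pbar) + hs / (2 * n_harm * 2)
    return np.where(valid, hs, np.nan), np.where(valid, ht, np.nan)


def _gst_gppst(p1, n1, p2, n2):
    """Multi-locus GST and G''ST (ratio-of-averages over sites), k = 2."""
    hs, ht = _hs_ht(p1, n1, p2, n2)
    hs_bar = np.nanmean(hs)
    ht_bar = np.nanmean(ht)
    if not np.isfinite(ht_bar) or ht_bar <= 0:
        return np.nan, np.nan
    gst = (ht_bar - hs_bar) / ht_bar
    k = 2
    denom = (k * ht_bar - hs_bar) * (1 - hs_bar)
    gppst = k * (ht_bar - hs_bar) / denom if denom > 0 else np.nan
    return gst, gppst


def pairwise_fst(
    calls,
    labels: dict,
    n_perm: int = 999,
    seed: int = 0,
):
    """Pairwise GST and standardized G''ST matrices with permutation p-values.

    G''ST (Meirmans & Hedrick) standardizes GST by its maximum attainable
    value given the within-population diversity:
    ``G''ST = k (HT - HS) / ((k HT - HS)(1 - HS))`` with k = 2 computed
    pairwise.  Negative estimates are clamped to 0 (recorded in
    ``clamped``).  p-values come from permuting individuals between the two
    populations.  Monomorphic pairs are reported as NaN with a flag.

    Returns a dict with DataFrames ``gst``, ``fst_std``, ``p_value`` and
    lists ``clamped``, ``monomorphic``.
    """
    mat = _as_matrix(calls)
    individuals = (
        calls.individuals
        if isinstance(calls, GenotypeCalls)
        else [f"i{k}" for k in range(mat.shape[0])]
    )
    pops = _pop_indices(individuals, labels)
    names = sorted(pops)
    if len(names) < 2:
        raise ValueError("need at least 2 populations")
    k = len(names)
    gst_m = pd.DataFrame(np.zeros((k, k)), index=names, columns=names)
    fst_m = pd.DataFrame(np.zeros((k, k)), index=names, columns=names)
    p_m = pd.DataFrame(np.full((k, k), np.nan), index=names, columns=names)
    clamped, mono = [], []
    rng = np.random.default_rng(seed)
    for a, b in itertools.combinations(names, 2):
        ia, ib = pops[a], pops[b]
        sub_a, sub_b = mat[ia], mat[ib]
        pa, na = _alt_freqs(sub_a)
        pb, nb = _alt_freqs(sub_b)
        gst, gpp = _gst_gppst(pa, na, pb, nb)
        if not np.isfinite(gpp):
            mono.append((a, b))
            gst_m.loc[a, b] = gst_m.loc[b, a] = np.nan
            fst_m.loc[a, b] = fst_m.loc[b, a] = np.nan
            continue
        if gpp < 0 or gst < 0:
            clamped.append((a, b))
        gst_m.loc[a, b] = gst_m.loc[b, a] = max(gst, 0.0)
        fst_m.loc[a, b] = fst_m.loc[b, a] = min(max(gpp, 0.0), 1.0)
        if n_perm:
            pool = np.concatenate([ia, ib])
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(pool)
                qa, ma = _alt_freqs(mat[perm[: len(ia)]])
                qb, mb = _alt_freqs(mat[perm[len(ia) :]])
                _, g = _gst_gppst(qa, ma, qb, mb)
                if np.isfinite(g) and g >= gpp:
                    count += 1
            p_m.loc[a, b] = p_m.loc[b, a] = (1 + count) / (1 + n_perm)
    return {
        "gst": gst_m,
        "fst_std": fst_m,
        "p_value": p_m,
        "clamped": clamped,
        "monomorphic": mono,
    }


# ---------------------------------------------------------------------------
# AMOVA


@dataclass
class AMOVAResult:
    components: dict  # level -> variance component (negatives truncated)
    percents: dict  # level -> percent of total
    phi: dict  # phi-statistics
    p_values: dict
    n_permutations: int
    df: dict
    warnings: list = field(default_factory=list)


def _pairwise_sq_dist(mat: np.ndarray) -> np.ndarray:
    """Squared Euclidean distance on allele counts, pairwise-complete loci."""
    g = mat.astype(float)
    g[mat < 0] = np.nan
    n = g.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = g[i] - g[i + 1 :]
        d[i, i + 1 :] = d[i + 1 :, i] = np.nansum(diff**2, axis=1)
    return d


def _amova_components(d2: np.ndarray, pop_of: np.ndarray, group_of: np.ndarray):
    """Variance components from squared distances (Excoffier sums of squares)."""
    n = d2.shape[0]
    pops = np.unique(pop_of)
    groups = np.unique(group_of)
    npops, ngroups = len(pops), len(groups)

    def ss(idx):
        if len(idx) < 2:
            return 0.0
        sub = d2[np.ix_(idx, idx)]
        return sub[np.triu_indices(len(idx), 1)].sum() / len(idx)

    ss_total = ss(np.arange(n))
    ss_within = 0.0
    for p in pops:
        ss_within += ss(np.nonzero(pop_of == p)[0])
    ss_groups = 0.0
    for gset in groups:
        ss_groups += ss(np.nonzero(group_of == gset)[0])
    ss_ap = ss_groups - ss_within  # among populations within groups
    ss_ag = ss_total - ss_groups  # among groups

    df_ag = ngroups - 1
    df_ap = npops - ngroups
    df_wp = n - npops

    pop_sizes = {p: int((pop_of == p).sum()) for p in pops}
    grp_sizes = {gname: int((group_of == gname).sum()) for gname in groups}
    pop_group = {p: group_of[pop_of == p][0] for p in pops}

    sum_n2_over_g = sum(
        pop_sizes[p] ** 2 / grp_sizes[pop_group[p]] for p in pops
    )
    sum_n2_over_N = sum(pop_sizes[p] ** 2 for p in pops) / n
    sum_g2_over_N = sum(s**2 for s in grp_sizes.values()) / n

    n1 = (n - sum_n2_over_g) / df_ap if df_ap else np.nan
    n2 = (sum_n2_over_g - sum_n2_over_N) / df_ag if df_ag else np.nan
    n3 = (n - sum_g2_over_N) / df_ag if df_ag else np.nan

    ms_wp = ss_within / df_wp if df_wp else 0.0
    sigma_c = ms_wp
    if df_ap:
        ms_ap = ss_ap / df_ap
        sigma_b = (ms_ap - sigma_c) / n1
    else:
        sigma_b = 0.0
    if df_ag:
        ms_ag = ss_ag / df_ag
        sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
    else:
        sigma_a = 0.0
    return sigma_a, sigma_b, sigma_c, (df_ag, df_ap, df_wp)


def amova(
    calls,
    grouping: dict,
    n_perm: int = 1000,
    seed: int = 0,
) -> AMOVAResult:
    """Hierarchical analysis of molecular variance on genotype distances.

    ``grouping`` maps individual -> (group, population) for the nested
    3-level design, or individual -> population for the 2-level design.
    Distances are squared Euclidean on 0/1/2 allele counts with
    pairwise-complete handling of missing calls.  Permutation schemes:
    individuals among populations (within groups) for Phi_SC/Phi_ST, whole
    populations among groups for Phi_CT.  Negative variance components are
    truncated at 0 with a warning.
    """
    mat = _as_matrix(calls)
    individuals = (
        calls.individuals
        if isinstance(calls, GenotypeCalls)
        else [f"i{k}" for k in range(mat.shape[0])]
    )
    entry = grouping[individuals[0]]
    three_level = isinstance(entry, (tuple, list))
    if three_level:
        group_of = np.asarray([grouping[i][0] for i in individuals], dtype=object)
        pop_of = np.asarray([grouping[i][1] for i in individuals], dtype=object)
    else:
        pop_of = np.asarray([grouping[i] for i in individuals], dtype=object)
        group_of = np.asarray(["all"] * len(individuals), dtype=object)

    d2 = _pairwise_sq_dist(mat)
    sigma_a, sigma_b, sigma_c, dfs = _amova_components(d2, pop_of, group_of)
    warn = []
    raw = {"among_groups": sigma_a, "among_pops_within_groups": sigma_b,
           "within_pops": sigma_c}
    comp = {}
    for name, v in raw.items():
        if v < 0:
            warn.append(f"negative variance component {name} truncated to 0")
            v = 0.0
        comp[name] = v
    total = sum(comp.values())
    if total <= 0:
        percents = {k: 0.0 for k in comp}
        phi = {"phi_st": np.nan, "phi_sc": np.nan, "phi_ct": np.nan}
        warn.append("zero total variance; phi undefined")
        return AMOVAResult(comp, percents, phi, {}, 0, dict(zip(
            ("among_groups", "among_pops_within_groups", "within_pops"), dfs)), warn)
    percents = {k: 100 * v / total for k, v in comp.items()}
    phi = {
        "phi_st": (comp["among_groups"] + comp["among_pops_within_groups"]) / total,
        "phi_sc": (
            comp["among_pops_within_groups"]
            / (comp["among_pops_within_groups"] + comp["within_pops"])
            if (comp["among_pops_within_groups"] + comp["within_pops"]) > 0
            else np.nan
        ),
        "phi_ct": comp["among_groups"] / total,
    }

    rng = np.random.default_rng(seed)
    p_values: dict = {}
    # permutation comparisons use the raw (untruncated) statistics; the
    # truncation atom at 0 would otherwise distort the null distribution
    raw_tot = sigma_a + sigma_b + sigma_c

    def raw_stat(a, b, c):
        if three_level:
            return b / (b + c) if (b + c) != 0 else np.nan
        tot = a + b + c
        return (a + b) / tot if tot != 0 else np.nan

    obs_sc = raw_stat(sigma_a, sigma_b, sigma_c)
    if n_perm and np.isfinite(obs_sc):
        count_sc = 0
        for _ in range(n_perm):
            perm_pop = pop_of.copy()
            for gname in np.unique(group_of):
                idx = np.nonzero(group_of == gname)[0]
                perm_pop[idx] = perm_pop[rng.permutation(idx)]
            a, b, c, _ = _amova_components(d2, perm_pop, group_of)
            stat = raw_stat(a, b, c)
            if np.isfinite(stat) and stat >= obs_sc - 1e-12:
                count_sc += 1
        key = "phi_sc" if three_level else "phi_st"
        p_values[key] = (1 + count_sc) / (1 + n_perm)
        if three_level:
            # Phi_CT: permute whole populations among groups
            obs_ct = sigma_a / raw_tot if raw_tot != 0 else np.nan
            pops = np.unique(pop_of)
            grp_of_pop = np.asarray(
                [group_of[pop_of == p][0] for p in pops], dtype=object
            )
            count_ct = 0
            for _ in range(n_perm):
                shuffled = grp_of_pop[rng.permutation(len(pops))]
                perm_group = np.empty_like(group_of)
                for p, gname in zip(pops, shuffled):
                    perm_group[pop_of == p] = gname
                a, b, c, _ = _amova_components(d2, pop_of, perm_group)
                tot = a + b + c
                stat = a / tot if tot != 0 else np.nan
                if np.isfinite(stat) and np.isfinite(obs_ct) and stat >= obs_ct - 1e-12:
                    count_ct += 1
            p_values["phi_ct"] = (1 + count_ct) / (1 + n_perm)
    return AMOVAResult(
        components=comp,
        percents=percents,
        phi=phi,
        p_values=p_values,
        n_permutations=n_perm,
        df=dict(zip(("among_groups", "among_pops_within_groups", "within_pops"), dfs)),
        warnings=warn,
    )


# ---------------------------------------------------------------------------
# PCA


def pca_covariance(calls, standardize: bool = False):
    """PCA of individuals from the genotype covariance matrix.

    Genotypes are centered per site (optionally standardized by
    sqrt(p(1-p))); missing cells are mean-imputed per site.  Returns
    ``(coordinates, percent_variance)`` with axes ordered by eigenvalue.
    """
    mat = _as_matrix(calls).astype(float)
    if mat.shape[0] < 3:
        raise ValueError("need at least 3 individuals")
    mat[mat < 0] = np.nan
    mean = np.nanmean(mat, axis=0)
    centered = mat - mean
    centered = np.where(np.isnan(centered), 0.0, centered)
    if standardize:
        p = mean / 2
        scale = np.sqrt(np.maximum(p * (1 - p), 1e-12))
        centered = centered / scale
    cov = centered @ centered.T / max(centered.shape[1], 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.maximum(vals, 0)
    coords = vecs * np.sqrt(vals)[None, :]
    total = vals.sum()
    pct = 100 * vals / total if total > 0 else np.zeros_like(vals)
    return coords, pct


# ---------------------------------------------------------------------------
# folded SFS


@dataclass
class SFS:
    """Folded site-frequency spectrum of one population.

    ``bins[i-1]`` is the number of sites with minor-allele count i among
    the 2n sampled alleles (i = 1..n for n diploids).
    """

    population: str
    bins: np.ndarray
    n_alleles: int
    monomorphic_sites: int
    total_sites: int
    excluded_missing: int = 0

    @property
    def segregating_sites(self) -> int:
        return int(self.bins.sum())


def folded_sfs(calls, labels: dict, population: str, total_sites: int | None = None) -> SFS:
    """Folded SFS from complete-data sites of one population.

    Sites with any missing call within the population are excluded and
    counted in ``excluded_missing``; monomorphic complete sites are counted
    separately and not binned.
    """
    mat = _as_matrix(calls)
    individuals = (
        calls.individuals
        if isinstance(calls, GenotypeCalls)
        else [f"i{k}" for k in range(mat.shape[0])]
    )
    idx = [i for i, ind in enumerate(individuals) if labels[ind] == population]
    sub = mat[idx]
    n = len(idx)
    complete = (sub >= 0).all(axis=0)
    excluded = int((~complete).sum())
    alt = sub[:, complete].sum(axis=0)
    minor = np.minimum(alt, 2 * n - alt)
    bins = np.bincount(minor[minor > 0], minlength=n + 1)[1 : n + 1]
    mono = int((minor == 0).sum())
    return SFS(
        population=population,
        bins=bins.astype(int),
        n_alleles=2 * n,
        monomorphic_sites=mono,
        total_sites=total_sites if total_sites is not None else int(complete.sum()),
        excluded_missing=excluded,
    )


# ---------------------------------------------------------------------------
# relative migration network


@dataclass
class MigrationNetwork:
    populations: list
    weights: pd.DataFrame  # directed, normalized to max 1; NaN on diagonal
    edges: list  # (source, target, weight) for weights >= threshold
    support: pd.DataFrame  # bootstrap fraction with edge >= threshold
    threshold: float
    dropped: list = field(default_factory=list)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.populations)
        for s, t, w in self.edges:
            g.add_edge(s, t, weight=float(w))
        return g


def _directional_values(freqs: dict, counts: dict, names: list) -> np.ndarray:
    """Directed relative-migration values before normalization.

    For each pair (a, b) a hypothetical migrant pool with the mean of the
    two allele-frequency vectors is formed; the migration a -> b is the
    Wright Nm implied by the GST between b and the pool (populations
    receiving more gene flow resemble the pool more).
    """
    k = len(names)
    vals = np.full((k, k), np.nan)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i == j:
                continue
            pa, pb = freqs[a], freqs[b]
            valid = np.isfinite(pa) & np.isfinite(pb)
            if not valid.any():
                continue
            pool = (pa + pb) / 2
            hs = (2 * pb * (1 - pb) + 2 * pool * (1 - pool)) / 2
            pbar = (pb + pool) / 2
            ht = 2 * pbar * (1 - pbar)
            hs_bar = np.nanmean(np.where(valid, hs, np.nan))
            ht_bar = np.nanmean(np.where(valid, ht, np.nan))
            if not np.isfinite(ht_bar) or ht_bar <= 0:
                continue
            gst = (ht_bar - hs_bar) / ht_bar
            gst = min(max(gst, 1e-9), 1 - 1e-9)
            vals[i, j] = (1 / gst - 1) / 4
    return vals


def relative_migration_network(
    calls,
    labels: dict,
    stat: str = "GST",
    threshold: float = 0.2,
    n_boot: int = 1000,
    seed: int = 0,
) -> MigrationNetwork:
    """Relative directional migration network from the migrant-pool construction.

    All directed values are divided by the global maximum (so exactly one
    directed edge has weight 1); edges below ``threshold`` are removed.
    Bootstrapping over loci gives per-edge support: the fraction of
    bootstrap replicates in which the (re-normalized) edge stays at or
    above the threshold.  Monomorphic pairs are dropped with a flag.
    """
    if stat != "GST":
        raise ValueError("only the GST variant is implemented")
    mat = _as_matrix(calls)
    individuals = (
        calls.individuals
        if isinstance(calls, GenotypeCalls)
        else [f"i{k}" for k in range(mat.shape[0])]
    )
    pops = _pop_indices(individuals, labels)
    names = sorted(pops)
    freqs, counts = {}, {}
    for p, idx in pops.items():
        freqs[p], counts[p] = _alt_freqs(mat[idx])
    vals = _directional_values(freqs, counts, names)
    dropped = [
        (names[i], names[j])
        for i in range(len(names))
        for j in range(len(names))
        if i != j and not np.isfinite(vals[i, j])
    ]
    vmax = np.nanmax(vals)
    rel = vals / vmax if np.isfinite(vmax) and vmax > 0 else vals
    weights = pd.DataFrame(rel, index=names, columns=names)
    edges = [
        (names[i], names[j], float(rel[i, j]))
        for i in range(len(names))
        for j in range(len(names))
        if i != j and np.isfinite(rel[i, j]) and rel[i, j] >= threshold
    ]
    support = pd.DataFrame(
        np.zeros((len(names), len(names))), index=names, columns=names
    )
    if n_boot:
        rng = np.random.default_rng(seed)
        n_sites = mat.shape[1]
        hits = np.zeros((len(names), len(names)))
        valid_boot = 0
        for _ in range(n_boot):
            take = rng.integers(0, n_sites, size=n_sites)
            bf = {p: freqs[p][take] for p in names}
            bc = {p: counts[p][take] for p in names}
            bv = _directional_values(bf, bc, names)
            bmax = np.nanmax(bv)
            if not np.isfinite(bmax) or bmax <= 0:
                continue
            brel = bv / bmax
            hits += np.where(np.isfinite(brel) & (brel >= threshold), 1, 0)
            valid_boot += 1
        if valid_boot:
            support.iloc[:, :] = hits / valid_boot
    return MigrationNetwork(
        populations=names,
        weights=weights,
        edges=edges,
        support=support,
        threshold=threshold,
        dropped=dropped,
    )
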