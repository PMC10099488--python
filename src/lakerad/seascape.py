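"""Lake profiling and seascape association tests.

Marine lakes are landlocked seawater bodies connected to the adjacent sea
through caves or porous rock; their tidal amplitude, expressed as a
fraction of the open-sea amplitude, is a proxy for hydrological
connection.  This module computes tidal-connection fractions and
categories, builds the four distance matrices used in seascape genetics
(linearized genomic differentiation, great-circle geographic distance,
PCA-based environmental distance, and a resistance-style connection
distance), and runs the association tests: Mantel tests with permutation
p-values (including exact enumeration for small matrices) and Spearman
rank correlations of diversity indices against lake predictors.

``INDO_PACIFIC_SURVEY`` ships the profile table of nine Indo-Pacific
marine lakes and two open lagoon sites (Berau, East Kalimantan and Raja
Ampat, West Papua; lagoons in Berau and Darwin, Australia) that serves as
the package's reference dataset for lake summaries.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "INDO_PACIFIC_SURVEY",
    "MantelResult",
    "CorrelationResult",
    "tidal_fraction",
    "categorize_connection",
    "geographic_distance_matrix",
    "environment_distance_matrix",
    "connection_distance_matrix",
    "mantel",
    "linearize_fst",
    "spearman_diversity",
    "summarize_profiles",
    "validate_distance_matrix",
]

EARTH_RADIUS_M = 6_371_000.0

# Reference survey of nine Indo-Pacific marine lakes and two lagoons:
# code, region, lineage, connection category, tidal fraction c, area
# (x1000 m^2), max depth (m), mean temperature (C), mean salinity (ppt),
# specimens passing QC, nucleotide diversity, expected heterozygosity.
_SURVEY_ROWS = [
    ("SeaAustralia", "Australia", "B", "open", np.nan, np.nan, np.nan, np.nan, np.nan, 7, 0.0095, 0.117),
    ("SeaIndonesia", "Berau", "B", "open", np.nan, np.nan, np.nan, 29.0, 33.5, 5, 0.0101, 0.157),
    ("Kalimantan1", "Berau", "A", "low", 0.1, 4900.0, 12.0, 30.0, 23.5, 20, np.nan, np.nan),
    ("Kalimantan2", "Berau", "B", "low", 0.4, 232.0, np.nan, 29.5, 26.0, 2, 0.0074, 0.034),
    ("Kalimantan3", "Berau", "B", "medium", 0.5, 140.0, 17.0, 29.5, 27.0, 26, 0.0050, 0.081),
    ("Papua27", "Papua", "B", "medium", np.nan, 22.0, 2.0, 29.5, 31.0, 5, 0.0037, 0.038),
    ("Papua30", "Papua", "B", "high", 0.8, 13.0, 4.0, 32.4, 28.9, 8, 0.0045, 0.052),
    ("Papua32", "Papua", "B", "medium", 0.5, 6.0, 6.0, 31.2, 30.7, 4, 0.0053, 0.059),
    ("Papua1", "Papua", "B", "low", 0.1, 89.0, 19.0, 32.3, 24.0, 11, 0.0036, 0.054),
    ("Papua4", "Papua", "B", "high", 0.8, 14.0, 20.0, 31.7, 25.9, 19, 0.0047, 0.080),
    ("Papua5", "Papua", "B", "low", 0.3, 4.0, 5.0, 31.5, 28.9, 18, 0.0060, 0.095),
]

INDO_PACIFIC_SURVEY = pd.DataFrame(
    _SURVEY_ROWS,
    columns=[
        "code",
        "region",
        "lineage",
        "category",
        "tidal_fraction",
        "area_1000m2",
        "max_depth_m",
        "temperature_c",
        "salinity_ppt",
        "n_specimens",
        "nucleotide_diversity",
        "heterozygosity_he",
    ],
)


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int | None = None
    method: str = "permutation"


@dataclass
class CorrelationResult:
    predictor: str
    response: str
    rho: float
    p: float
    n: int
    strong: bool  # |rho| >= 0.5
    significant: bool  # p < 0.01


# ---------------------------------------------------------------------------
# tidal connection


def tidal_fraction(lake_series, sea_series) -> float:
    """Tidal-amplitude fraction c = max lake amplitude / max sea amplitude.

    Both series are water levels over the same interval (>= 48 h in field
    use) and are baseline-corrected by subtracting their minima, so c
    compares the maximum amplitudes.  c = 1 means unobstructed exchange,
    c = 0 no water exchange at all; values above 1 are clamped with a
    warning.
    """
    lake = np.asarray(lake_series, dtype=float)
    sea = np.asarray(sea_series, dtype=float)
    if lake.size != sea.size:
        raise ValueError("lake and sea series must span the same interval")
    lake_amp = lake.max() - lake.min()
    sea_amp = sea.max() - sea.min()
    if sea_amp <= 0:
        raise ValueError("flat sea series: tidal fraction undefined")
    c = lake_amp / sea_amp
    if c > 1:
        warnings.warn(f"tidal fraction {c:.3f} > 1 clamped to 1", stacklevel=2)
        c = 1.0
    return float(c)


def categorize_connection(c) -> str:
    """Connection category from the tidal fraction.

    low (c <= 0.4), medium (0.5-0.7), high (0.8-1); open-sea sites pass
    the literal "open" through.  Values in the scheme's gaps (0.4, 0.5)
    and (0.7, 0.8) are flagged with a warning and assigned to the nearer
    band (medium, high respectively).
    """
    if isinstance(c, str):
        if c == "open":
            return "open"
        raise ValueError(f"unknown category literal {c!r}")
    if not 0 <= c <= 1:
        raise ValueError("tidal fraction must be in [0, 1]")
    if c <= 0.4:
        return "low"
    if c < 0.5:
        warnings.warn(
            f"tidal fraction {c} falls in the (0.4, 0.5) gap; assigned medium",
            stacklevel=2,
        )
        return "medium"
    if c <= 0.7:
        return "medium"
    if c < 0.8:
        warnings.warn(
            f"tidal fraction {c} falls in the (0.7, 0.8) gap; assigned high",
            stacklevel=2,
        )
        return "high"
    return "high"


# ---------------------------------------------------------------------------
# distance matrices


def validate_distance_matrix(d: pd.DataFrame) -> None:
    arr = d.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(arr, arr.T, equal_nan=True):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0):
        raise ValueError("distance matrix must have zero diagonal")
    if np.nanmin(arr) < 0:
        raise ValueError("distance matrix must be non-negative")


def _haversine(lat1, lon1, lat2, lon2) -> float:
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_M * math.asin(math.sqrt(a))


def geographic_distance_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Great-circle (haversine) pairwise distances in meters."""
    codes = list(profiles["code"])
    lat = profiles["lat"].to_numpy(dtype=float)
    lon = profiles["lon"].to_numpy(dtype=float)
    if np.isnan(lat).any() or np.isnan(lon).any():
        raise ValueError("missing coordinates")
    n = len(codes)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _haversine(lat[i], lon[i], lat[j], lon[j])
    return pd.DataFrame(d, index=codes, columns=codes)


def environment_distance_matrix(
    profiles: pd.DataFrame,
    variables=("temperature_c", "salinity_ppt"),
) -> pd.DataFrame:
    """Euclidean distance on all retained PCA axes of standardized variables.

    Low distances indicate environmentally similar lakes.  All axes are
    retained by default, so the result equals the z-score Euclidean
    distance (PCA is a rotation).  Missing values are rejected.
    """
    from sklearn.decomposition import PCA

    sub = profiles[list(variables)].to_numpy(dtype=float)
    if np.isnan(sub).any():
        bad = profiles.loc[np.isnan(sub).any(axis=1), "code"].tolist()
        raise ValueError(f"missing environmental values for {bad}")
    z = (sub - sub.mean(axis=0)) / sub.std(axis=0, ddof=1)
    scores = PCA(n_components=len(variables)).fit_transform(z)
    diff = scores[:, None, :] - scores[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    codes = list(profiles["code"])
    return pd.DataFrame(d, index=codes, columns=codes)


def connection_distance_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Resistance-style connection distance d(i,j) = ((1-ci) + (1-cj)) / 2.

    Open-sea sites take c = 1; a pair of fully isolated lakes scores 1, a
    pair of open sites 0, and mixed pairs fall strictly between.  Lakes
    with missing tidal fraction are excluded with a warning.
    """
    c = profiles["tidal_fraction"].to_numpy(dtype=float).copy()
    open_mask = (profiles["category"] == "open").to_numpy()
    c[open_mask] = 1.0
    keep = ~np.isnan(c)
    if (~keep).any():
        dropped = profiles.loc[~keep, "code"].tolist()
        warnings.warn(
            f"excluding sites with missing tidal fraction: {dropped}",
            stacklevel=2,
        )
    codes = [str(x) for x in profiles.loc[keep, "code"]]
    iso = 1 - c[keep]
    d = (iso[:, None] + iso[None, :]) / 2
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=codes, columns=codes)


def linearize_fst(fst: pd.DataFrame, cap: float = 100.0) -> pd.DataFrame:
    """Elementwise x / (1 - x); entries equal to 1 map to ``cap`` with warning."""
    arr = fst.to_numpy(dtype=float).copy()
    at_one = arr >= 1
    if at_one.any():
        warnings.warn("differentiation of 1 mapped to cap", stacklevel=2)
    with np.errstate(divide="ignore"):
        out = np.where(at_one, cap, arr / (1 - arr))
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=fst.index, columns=fst.columns)


# ---------------------------------------------------------------------------
# Mantel test


def _upper(arr: np.ndarray) -> np.ndarray:
    return arr[np.triu_indices(arr.shape[0], 1)]


def mantel(
    d1: pd.DataFrame,
    d2: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
) -> MantelResult:
    """One-sided Mantel test between two labeled distance matrices.

    r is the Pearson correlation of the upper off-diagonal entries;
    significance comes from simultaneous row/column permutations of the
    second matrix, with the add-one estimator
    p = (1 + #{r_perm >= r_obs}) / (1 + n_perm).  ``n_perm="exact"``
    enumerates all label permutations (factorial in n; intended for small
    matrices).
    """
    if list(d1.index) != list(d2.index):
        d2 = d2.loc[d1.index, d1.index]
    validate_distance_matrix(d1)
    validate_distance_matrix(d2)
    a = d1.to_numpy(dtype=float)
    b = d2.to_numpy(dtype=float)
    x = _upper(a)
    if np.std(x) == 0 or np.std(_upper(b)) == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")

    def corr(bperm):
        return float(np.corrcoef(x, _upper(bperm))[0, 1])

    r_obs = corr(b)
    n = a.shape[0]
    if n_perm == "exact":
        rs = []
        for perm in itertools.permutations(range(n)):
            p = np.asarray(perm)
            rs.append(corr(b[np.ix_(p, p)]))
        rs = np.asarray(rs)
        # the identity permutation is part of the null set
        p_val = float((rs >= r_obs - 1e-12).sum() / len(rs))
        return MantelResult(r=r_obs, p=p_val, n_perm=len(rs), seed=None, method="exact")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(int(n_perm)):
        p = rng.permutation(n)
        if corr(b[np.ix_(p, p)]) >= r_obs - 1e-12:
            count += 1
    return MantelResult(
        r=r_obs, p=(1 + count) / (1 + int(n_perm)), n_perm=int(n_perm), seed=seed
    )


# ---------------------------------------------------------------------------
# Spearman correlations and summaries


def spearman_diversity(
    diversity_table: pd.DataFrame,
    profiles: pd.DataFrame,
    predictors=("area_1000m2", "tidal_fraction", "salinity_ppt", "temperature_c"),
    responses=("pi", "He"),
) -> list:
    """Spearman correlations of per-lake diversity with lake predictors.

    ``diversity_table`` needs a ``population`` column matching
    ``profiles.code`` plus the response columns.  Tie-corrected rho,
    two-sided p; |rho| >= 0.5 is flagged strong and p < 0.01 significant.
    Fewer than 5 paired observations triggers a warning but is computed.
    """
    merged = diversity_table.merge(
        profiles, left_on="population", right_on="code", how="inner"
    )
    out = []
    for resp in responses:
        for pred in predictors:
            sub = merged[[resp, pred]].dropna()
            n = len(sub)
            if n < 3:
                continue
            if n < 5:
                warnings.warn(
                    f"only {n} paired observations for {pred} vs {resp}",
                    stacklevel=2,
                )
            rho, p = stats.spearmanr(sub[pred], sub[resp])
            out.append(
                CorrelationResult(
                    predictor=pred,
                    response=resp,
                    rho=float(rho),
                    p=float(p),
                    n=n,
                    strong=abs(rho) >= 0.5,
                    significant=p < 0.01,
                )
            )
    return out


def summarize_profiles(profiles: pd.DataFrame) -> dict:
    """Lake means +- SD versus lagoon values, and connection-category tallies.

    Lakes are rows with category != "open"; SD uses the n-1 denominator.
    """
    lakes = profiles[profiles["category"] != "open"]
    lagoons = profiles[profiles["category"] == "open"]
    if lakes.empty or lagoons.empty:
        raise ValueError("need at least one lake and one lagoon")
    summary = {
        "n_lakes": int(len(lakes)),
        "n_lagoons": int(len(lagoons)),
        "lake_temperature_mean": float(lakes["temperature_c"].mean()),
        "lake_temperature_sd": float(lakes["temperature_c"].std(ddof=1)),
        "lake_salinity_mean": float(lakes["salinity_ppt"].mean()),
        "lake_salinity_sd": float(lakes["salinity_ppt"].std(ddof=1)),
        "lagoon_temperature": {
            str(r["code"]): float(r["temperature_c"]) for _, r in lagoons.iterrows()
        },
        "lagoon_salinity": {
            str(r["code"]): float(r["salinity_ppt"]) for _, r in lagoons.iterrows()
        },
        "category_counts": lakes["category"].value_counts().to_dict(),
    }
    if "n_specimens" in profiles:
        summary["total_individuals"] = int(profiles["n_specimens"].sum())
    if "lineage" in profiles:
        summary["individuals_per_lineage"] = (
            profiles.groupby("lineage")["n_specimens"].sum().astype(int).to_dict()
        )
    return summary
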