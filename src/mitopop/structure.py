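"""Population differentiation, isolation by distance, and Mantel tests.

Pairwise F_ST between sampling sites is the two-population AMOVA variance
ratio σ²_a / (σ²_a + σ²_w) computed from a specimen-level distance matrix:
haplotype identity (0/1) gives the conventional frequency-based F_ST,
pairwise difference counts give Φ_ST.  Significance comes from permuting
specimens between the two sites.  Negative estimates are retained — clamping
would bias downstream means and regressions.

Isolation by distance is assessed by OLS of Slatkin-linearized F_ST,
F/(1−F), on the natural log of great-circle distance, and by a Mantel
matrix-permutation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CoordinateError, MitopopError
from .seqio import DistanceMatrix, HaplotypeTable

EARTH_RADIUS_KM = 6371.0


@dataclass
class FstMatrix:
    site_labels: list[str]
    fst: np.ndarray
    p: np.ndarray
    n_perm: int
    flavor: str  # "fst" (haplotype identity) | "phist" (distance-weighted)

    def pair(self, a: str, b: str) -> tuple[float, float]:
        i, j = self.site_labels.index(a), self.site_labels.index(b)
        return float(self.fst[i, j]), float(self.p[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fst, index=self.site_labels, columns=self.site_labels)


@dataclass(frozen=True)
class GeoDistanceMatrix:
    site_labels: tuple[str, ...]
    km: np.ndarray


@dataclass(frozen=True)
class IbdResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_pairs: int
    mantel_Z: float | None = None
    mantel_r: float | None = None
    mantel_p: float | None = None


# ---------------------------------------------------------------------------
# AMOVA F_ST


def _amova_fst_batch(D: np.ndarray, groups: np.ndarray) -> float:
    """Two-population AMOVA F_ST from a specimen distance matrix.

    SSD(total) = Σ_{i<j} d_ij / N;  SSD(within) = Σ_g Σ_{i<j∈g} d_ij / n_g.
    """
    n = len(groups)
    n1 = int(groups.sum())
    n2 = n - n1
    m1 = groups.astype(float)
    m2 = 1.0 - m1
    total = D.sum() / 2.0
    w1 = m1 @ D @ m1 / 2.0
    w2 = m2 @ D @ m2 / 2.0
    ssd_total = total / n
    ssd_within = w1 / n1 + w2 / n2
    ssd_among = ssd_total - ssd_within
    msd_within = ssd_within / (n - 2)
    n_c = n - (n1**2 + n2**2) / n
    sigma_a = (ssd_among - msd_within) / n_c
    denom = sigma_a + msd_within
    if denom == 0:
        return 0.0
    return float(sigma_a / denom)


def pairwise_fst(
    haplotype_table: HaplotypeTable,
    distance_matrix: DistanceMatrix | None = None,
    n_perm: int = 10100,
    seed: int | None = None,
) -> FstMatrix:
    """Pairwise F_ST (or Φ_ST) between all sites, with permutation P-values.

    ``distance_matrix=None`` uses haplotype identity (conventional F_ST);
    passing the haplotype pairwise-difference matrix gives Φ_ST.  P is the
    one-sided fraction of specimen permutations with F* ≥ F_obs (the observed
    configuration counts as one permutation).  Sites with a single specimen
    are excluded with a warning.
    """
    ht = haplotype_table
    if distance_matrix is None:
        d_hap = 1.0 - np.eye(ht.k)
        flavor = "fst"
    else:
        if list(distance_matrix.labels) != [f"H{i+1}" for i in range(ht.k)] and len(
            distance_matrix.labels
        ) != ht.k:
            raise MitopopError("distance matrix does not match haplotype table")
        d_hap = np.asarray(distance_matrix.values, dtype=float)
        flavor = "phist"

    sites = [s for j, s in enumerate(ht.site_labels) if ht.counts[:, j].sum() >= 2]
    dropped = set(ht.site_labels) - set(sites)
    if dropped:
        warnings.warn(f"sites with n < 2 excluded: {sorted(dropped)}")
    if len(sites) < 2:
        raise MitopopError("need at least two sites with n >= 2")

    # per-site specimen haplotype indices
    hap_idx = {
        s: np.repeat(np.arange(ht.k), ht.counts[:, ht.site_labels.index(s)])
        for s in sites
    }
    rng = np.random.default_rng(seed)
    k = len(sites)
    fst = np.zeros((k, k))
    pmat = np.full((k, k), np.nan)
    for a, b in combinations(range(k), 2):
        ia, ib = hap_idx[sites[a]], hap_idx[sites[b]]
        idx = np.concatenate([ia, ib])
        D = d_hap[np.ix_(idx, idx)]
        n1 = len(ia)
        n = len(idx)
        groups = np.zeros(n)
        groups[:n1] = 1.0
        obs = _amova_fst_batch(D, groups)
        # permutations of specimens between the two sites
        ge = 1  # observed counts as one permutation
        perm_groups = np.tile(groups, (n_perm - 1, 1))
        for row in perm_groups:
            rng.shuffle(row)
        # F* for each permutation via batched quadratic forms
        w1 = np.einsum("pi,ij,pj->p", perm_groups, D, perm_groups) / 2.0
        m2 = 1.0 - perm_groups
        w2 = np.einsum("pi,ij,pj->p", m2, D, m2) / 2.0
        total = D.sum() / 2.0
        ssd_within = w1 / n1 + w2 / (n - n1)
        ssd_among = total / n - ssd_within
        msd_within = ssd_within / (n - 2)
        n_c = n - (n1**2 + (n - n1) ** 2) / n
        sigma_a = (ssd_among - msd_within) / n_c
        denom = sigma_a + msd_within
        with np.errstate(divide="ignore", invalid="ignore"):
            f_perm = np.where(denom != 0, sigma_a / denom, 0.0)
        ge += int(np.sum(f_perm >= obs - 1e-12))
        fst[a, b] = fst[b, a] = obs
        pmat[a, b] = pmat[b, a] = ge / n_perm
    return FstMatrix(sites, fst, pmat, n_perm, flavor)


def mean_significant_fst(fst_matrix: FstMatrix, alpha: float = 0.05) -> float:
    """Mean of upper-triangle F_ST values with permutation P < alpha."""
    iu = np.triu_indices(len(fst_matrix.site_labels), k=1)
    vals = fst_matrix.fst[iu]
    ps = fst_matrix.p[iu]
    mask = ps < alpha
    if not mask.any():
        raise MitopopError("no significant pairs at this alpha")
    return float(vals[mask].mean())


def linearize_fst(fst: float) -> float:
    """Slatkin's linearization F/(1−F); +inf sentinel at F = 1."""
    if fst >= 1.0:
        return float("inf")
    return float(fst / (1.0 - fst))


# ---------------------------------------------------------------------------
# geography


def haversine_km(lat1, lon1, lat2, lon2, radius_km: float = EARTH_RADIUS_KM) -> float:
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = np.sin((la2 - la1) / 2) ** 2 + np.cos(la1) * np.cos(la2) * np.sin(
        (lo2 - lo1) / 2
    ) ** 2
    return float(2 * radius_km * np.arcsin(np.sqrt(a)))


def geo_distances(
    site_metadata: pd.DataFrame, radius_km: float = EARTH_RADIUS_KM
) -> GeoDistanceMatrix:
    """Great-circle distances between sites from a (site × lat/lon) frame."""
    lats = site_metadata["latitude"].to_numpy(dtype=float)
    lons = site_metadata["longitude"].to_numpy(dtype=float)
    if np.any(np.abs(lats) > 90) or np.any(np.abs(lons) > 180):
        raise CoordinateError("latitude/longitude out of range")
    labels = tuple(site_metadata.index)
    k = len(labels)
    km = np.zeros((k, k))
    for i, j in combinations(range(k), 2):
        km[i, j] = km[j, i] = haversine_km(lats[i], lons[i], lats[j], lons[j], radius_km)
    return GeoDistanceMatrix(labels, km)


# ---------------------------------------------------------------------------
# Mantel and IBD


def _offdiag(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def mantel_test(
    matrix_a: np.ndarray,
    matrix_b: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Mantel matrix-association test.

    Returns (Z, r, p): Z = Σ_{i<j} a_ij·b_ij, r the Pearson correlation of
    the off-diagonal elements, and p the one-sided fraction of joint
    row/column permutations of B with r* ≥ r (observed counted once).
    """
    a = np.asarray(matrix_a, dtype=float)
    b = np.asarray(matrix_b, dtype=float)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise MitopopError("matrices must be square and of equal shape")
    va, vb = _offdiag(a), _offdiag(b)
    if np.std(va) == 0 or np.std(vb) == 0:
        raise MitopopError("constant matrix: Mantel r undefined")
    Z = float(np.sum(va * vb))
    r = float(np.corrcoef(va, vb)[0, 1])
    rng = np.random.default_rng(seed)
    n = a.shape[0]
    ge = 1
    for _ in range(n_perm - 1):
        perm = rng.permutation(n)
        r_p = np.corrcoef(va, _offdiag(b[np.ix_(perm, perm)]))[0, 1]
        if r_p >= r - 1e-12:
            ge += 1
    return Z, r, ge / n_perm


def ibd_regression(
    fst_matrix: FstMatrix,
    geo_matrix: GeoDistanceMatrix,
    n_perm: int = 1000,
    seed: int | None = None,
) -> IbdResult:
    """Isolation-by-distance: OLS of F/(1−F) on ln(km) over all site pairs.

    Zero-distance pairs are dropped with a warning (ln undefined).  The
    Mantel test on the same two matrices is run alongside.
    """
    order = [geo_matrix.site_labels.index(s) for s in fst_matrix.site_labels]
    km = geo_matrix.km[np.ix_(order, order)]
    lin = np.vectorize(linearize_fst)(fst_matrix.fst)
    x_all = _offdiag(km)
    y_all = _offdiag(lin)
    keep = x_all > 0
    if (~keep).any():
        warnings.warn(f"{int((~keep).sum())} zero-distance pair(s) dropped from IBD")
    x = np.log(x_all[keep])
    y = y_all[keep]
    if len(x) < 3:
        raise MitopopError("IBD regression needs >= 3 site pairs")
    res = stats.linregress(x, y)
    with np.errstate(divide="ignore"):
        ln_km = np.where(km > 0, np.log(km), 0.0)
    Z, r, p = mantel_test(lin, ln_km, n_perm=n_perm, seed=seed)
    return IbdResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n_pairs=len(x),
        mantel_Z=Z,
        mantel_r=r,
        mantel_p=p,
    )
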