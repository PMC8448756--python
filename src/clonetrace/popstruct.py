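"""Population structure: LD pruning and PCA of alternate-allele dosages.

Genotype calls become a samples x sites dosage matrix (0/1/2 alternate
alleles under the diploid calling model, NaN for no-calls). Sites in high
linkage disequilibrium (squared Pearson correlation of dosages above a
threshold within a genomic window) are greedily pruned — scanning sites in
position order, a site is dropped when it correlates above threshold with
any already-retained site within one window span; the contract is the
postcondition (no retained high-LD pair within a window), not the
particular greedy trace. PCA follows the standard genotype-PCA recipe:
per-site mean imputation of missing dosages, centering, scaling by
sqrt(2 p (1 - p)) with p the alternate-allele frequency, then an
eigendecomposition of the sample covariance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype import Call, GenotypeCalls

logger = logging.getLogger(__name__)


@dataclass
class GenotypeMatrix:
    """Samples x sites alternate-allele dosage matrix ({0,1,2}, NaN missing)."""

    samples: list[str]
    positions: np.ndarray  # bp, strictly increasing
    dosage: np.ndarray  # float (n_samples, n_sites)

    def __post_init__(self) -> None:
        if self.dosage.shape != (len(self.samples), len(self.positions)):
            raise ValueError("dosage must be samples x sites")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        finite = self.dosage[~np.isnan(self.dosage)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in {0, 1, 2}")

    @classmethod
    def from_calls(cls, cohort_calls: list[GenotypeCalls]) -> "GenotypeMatrix":
        """Dosage = number of non-reference alleles in the called pair."""
        if not cohort_calls:
            raise ValueError("no genotype calls supplied")
        positions = cohort_calls[0].positions
        for c in cohort_calls[1:]:
            if not np.array_equal(c.positions, positions):
                raise ValueError("all samples must share the same site grid")
        rows = []
        for c in cohort_calls:
            dose = (
                (c.allele1 != c.ref).astype(float) + (c.allele2 != c.ref).astype(float)
            )
            dose[c.call == Call.NO_CALL] = np.nan
            rows.append(dose)
        return cls([c.sample_id for c in cohort_calls], positions.copy(), np.vstack(rows))


@dataclass
class LDPruneParams:
    window_bp: int = 50_000
    step: int = 10
    step_unit: str = "bp"  # "bp" or "sites"
    r2_threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError(f"window_bp must be > 0, got {self.window_bp}")
        if self.step <= 0:
            raise ValueError(f"step must be > 0, got {self.step}")
        if self.step_unit not in ("bp", "sites"):
            raise ValueError(f"step_unit must be 'bp' or 'sites', got {self.step_unit!r}")
        if not 0 <= self.r2_threshold <= 1:
            raise ValueError(f"r2_threshold must be in [0, 1], got {self.r2_threshold}")


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation over jointly non-missing samples.

    Returns 0 when either vector is constant; raises when fewer than two
    jointly non-missing samples remain.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if int(ok.sum()) < 2:
        raise ValueError("pairwise_r2 needs >= 2 jointly non-missing samples")
    xs, ys = x[ok], y[ok]
    vx, vy = xs.var(), ys.var()
    if vx <= 0 or vy <= 0:
        return 0.0
    c = np.corrcoef(xs, ys)[0, 1]
    return float(c * c)


def _r2_one_vs_block(x: np.ndarray, block: np.ndarray) -> np.ndarray:
    """r^2 of one dosage vector against each row of ``block`` with exact
    pairwise-complete handling of missing values."""
    mx = ~np.isnan(x)
    mb = ~np.isnan(block)
    xv = np.where(mx, x, 0.0)
    bv = np.where(mb, block, 0.0)
    joint = mb & mx[None, :]
    n = joint.sum(axis=1).astype(float)
    sx = joint @ xv
    sxx = joint @ (xv * xv)
    sy = (bv * joint).sum(axis=1)
    syy = (bv * bv * joint).sum(axis=1)
    sxy = (bv * (joint * xv[None, :])).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / np.maximum(n, 1)
        varx = sxx - sx * sx / np.maximum(n, 1)
        vary = syy - sy * sy / np.maximum(n, 1)
        r2 = np.where((varx > 1e-12) & (vary > 1e-12), cov * cov / (varx * vary), 0.0)
    r2[n < 2] = 0.0
    return r2


def ld_prune(gm: GenotypeMatrix, params: LDPruneParams | None = None) -> np.ndarray:
    """Greedy LD pruning; returns sorted retained site indices.

    Postcondition: among retained sites, no pair within one window span has
    r^2 above the threshold.
    """
    params = params or LDPruneParams()
    pos = gm.positions
    X = gm.dosage
    n_sites = len(pos)
    n_samples = X.shape[0]

    # Standardized (mean-imputed) columns turn r^2 into a squared dot
    # product; columns containing missing values get an exact
    # pairwise-complete recomputation below.
    has_nan = np.isnan(X).any(axis=0)
    Xi = np.where(np.isnan(X), np.broadcast_to(np.nanmean(X, axis=0), X.shape), X)
    Z = Xi - Xi.mean(axis=0)
    norm = np.sqrt((Z * Z).sum(axis=0))
    nz = norm > 1e-12
    Z[:, nz] = Z[:, nz] / norm[nz]
    Z[:, ~nz] = 0.0  # constant columns -> r^2 convention 0

    retained: list[int] = []
    # contiguous buffer of retained standardized rows (sites x samples)
    R = np.empty((n_sites, n_samples))
    R_nan = np.empty(n_sites, dtype=bool)
    start = 0  # first retained row still inside the window
    for j in range(n_sites):
        m = len(retained)
        while start < m and pos[j] - pos[retained[start]] > params.window_bp:
            start += 1
        if start < m:
            zj = Z[:, j]
            r2 = (R[start:m] @ zj) ** 2
            if has_nan[j] or R_nan[start:m].any():
                fix = np.nonzero(R_nan[start:m] | has_nan[j])[0]
                cols = [retained[start + f] for f in fix]
                r2[fix] = _r2_one_vs_block(X[:, j], X[:, cols].T)
            if np.any(r2 > params.r2_threshold):
                continue
        R[len(retained)] = Z[:, j]
        R_nan[len(retained)] = has_nan[j]
        retained.append(j)
    return np.asarray(retained, dtype=np.int64)


def check_prune_contract(
    gm: GenotypeMatrix, retained: np.ndarray, params: LDPruneParams | None = None
) -> bool:
    """Brute-force all-pairs verification of the pruning postcondition."""
    params = params or LDPruneParams()
    pos = gm.positions[retained]
    for a in range(len(retained)):
        for b in range(a + 1, len(retained)):
            if pos[b] - pos[a] > params.window_bp:
                break
            r2 = pairwise_r2(gm.dosage[:, retained[a]], gm.dosage[:, retained[b]])
            if r2 > params.r2_threshold:
                return False
    return True


@dataclass
class PCAResult:
    samples: list[str]
    coordinates: np.ndarray  # (n_samples, k)
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  # (k, n_used_sites)
    used_sites: np.ndarray  # indices into the input site list

    def to_dataframe(self) -> pd.DataFrame:
        cols = {f"PC{i + 1}": self.coordinates[:, i] for i in range(self.coordinates.shape[1])}
        return pd.DataFrame({"sample": self.samples, **cols})


def pca(
    gm: GenotypeMatrix,
    site_indices: np.ndarray | None = None,
    n_components: int = 10,
) -> PCAResult:
    """Genotype PCA with mean imputation and sqrt(2p(1-p)) scaling.

    Monomorphic sites (p in {0, 1}) are dropped; raises when no polymorphic
    site remains. Sign convention: each component's largest-magnitude
    loading is positive.
    """
    if len(gm.samples) < 2:
        raise ValueError("pca requires >= 2 samples")
    idx = np.arange(len(gm.positions)) if site_indices is None else np.asarray(site_indices)
    D = gm.dosage[:, idx].astype(float).copy()
    mu = np.nanmean(D, axis=0)
    nan_mask = np.isnan(D)
    D[nan_mask] = np.take(mu, np.nonzero(nan_mask)[1])
    p = mu / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    poly = (scale > 1e-12) & (np.nanvar(D, axis=0) > 1e-12)
    if not poly.any():
        raise ValueError("all sites are monomorphic; PCA undefined")
    X = (D[:, poly] - 2.0 * p[poly]) / scale[poly]
    n = X.shape[0]
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = int(min(n_components, max(n - 1, 1), X.shape[1]))
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    coords = U * S
    ev = S**2 / (n - 1) if n > 1 else S**2
    total_var = (X**2).sum() / (n - 1) if n > 1 else (X**2).sum()
    ratio = ev / total_var if total_var > 0 else np.zeros_like(ev)
    for comp in range(k):
        jmax = int(np.argmax(np.abs(Vt[comp])))
        if Vt[comp, jmax] < 0:
            Vt[comp] *= -1.0
            coords[:, comp] *= -1.0
    return PCAResult(
        samples=list(gm.samples),
        coordinates=coords,
        explained_variance=ev,
        explained_variance_ratio=ratio,
        loadings=Vt,
        used_sites=idx[poly],
    )
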