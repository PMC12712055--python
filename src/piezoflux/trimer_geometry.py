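"""Protomer-site merging and triple-labelled trimer identification.

DNA-PAINT detects the same blade tip repeatedly, so trace centers that fall
within the localization precision plus label flexibility of one another are
merged into a single protomer site with DBSCAN (minPoints 2, epsilon 8 nm).
Triple-labelled trimers are then the site triples that satisfy three rules:

* all three pairwise 3D distances are below ``pair_max`` (40 nm, the largest
  physically possible tag-tag separation of the fully flattened channel);
* no other site lies within ``isolation_radius`` (60 nm) of any member;
* the maximum internal angle of the triangle is below ``angle_max`` (120 deg),
  rejecting near-collinear accidental triples.

The interblade distance of an accepted trimer is the arithmetic mean of its
three pairwise distances and is the flattening readout: curved channels give
small values, flattened channels large ones.

Distances and angles are computed in 3D on z-corrected coordinates; the
bivariate Gaussian fit uses the 2D in-plane projection and serves as the
visualization / alternative position estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

_XYZ = ["x_nm", "y_nm", "z_nm"]

SITE_COLUMNS = ("site_id", "x_nm", "y_nm", "z_nm", "n_traces")
TRIMER_COLUMNS = (
    "trimer_id",
    "site_1", "site_2", "site_3",
    "x1", "y1", "z1", "x2", "y2", "z2", "x3", "y3", "z3",
    "d12", "d13", "d23",
    "interblade_nm", "max_angle_deg",
    "n_traces_1", "n_traces_2", "n_traces_3",
)


class DegenerateGeometryError(ValueError):
    """Raised when triangle geometry is requested for coincident points."""


class InsufficientDataError(ValueError):
    """Raised when a fit is requested on too few points."""


@dataclass(frozen=True)
class ClusterConfig:
    """DBSCAN parameters for merging repeated trace detections.

    ``min_points`` counts the point itself, so the default ``min_points=2``
    means "self plus at least one neighbor" and makes the clustering equal to
    the connected components of the epsilon proximity graph (implementations
    differ in this convention; scikit-learn matches it).
    """

    epsilon: float = 8.0  # nm
    min_points: int = 2

    def __post_init__(self) -> None:
        if not (np.isfinite(self.epsilon) and self.epsilon > 0):
            raise ValueError("epsilon must be positive")
        if self.min_points < 1:
            raise ValueError("min_points must be >= 1")


@dataclass(frozen=True)
class TrimerRules:
    """Geometric acceptance rules for triple-labelled trimers.

    Bounds are applied strictly: pairs at exactly ``pair_max`` are rejected,
    neighbours at exactly ``isolation_radius`` do not disqualify, triangles
    whose maximum angle equals ``angle_max`` are rejected.
    """

    pair_max: float = 40.0  # nm
    isolation_radius: float = 60.0  # nm
    angle_max: float = 120.0  # degrees

    def __post_init__(self) -> None:
        if not self.pair_max < self.isolation_radius:
            raise ValueError("pair_max must be smaller than isolation_radius")
        if not (60.0 <= self.angle_max < 180.0):
            raise ValueError("angle_max must be in [60, 180)")


@dataclass(frozen=True)
class Gaussian2DFit:
    """Maximum-likelihood bivariate Gaussian of in-plane projected points."""

    mean: np.ndarray  # (2,) nm
    covariance: np.ndarray  # (2, 2) nm^2, SPD (possibly ridge-regularized)
    n_points: int
    regularized: bool = False

    @property
    def sds(self) -> np.ndarray:
        """Principal standard deviations (sqrt of covariance eigenvalues)."""
        return np.sqrt(np.linalg.eigvalsh(self.covariance))


def cluster_protomers(
    centers: pd.DataFrame, config: ClusterConfig | None = None
) -> pd.DataFrame:
    """Merge trace centers into protomer sites with DBSCAN in 3D.

    Each DBSCAN cluster becomes one site at the mean of its member centers.
    Noise points (singleton centers with no neighbour within epsilon) are
    retained as single-trace sites: a protomer detected only once is still a
    protomer.

    Parameters
    ----------
    centers:
        Trace-center table with columns ``tid, x_nm, y_nm, z_nm`` (``n_locs``
        optional), z already corrected.
    """
    config = config or ClusterConfig()
    if len(centers) == 0:
        return pd.DataFrame(columns=list(SITE_COLUMNS) + ["member_tids"])
    xyz = centers[_XYZ].to_numpy(float)
    labels = DBSCAN(eps=config.epsilon, min_samples=config.min_points).fit_predict(xyz)
    # promote noise points to singleton clusters
    next_label = labels.max() + 1 if (labels >= 0).any() else 0
    labels = labels.copy()
    for i in np.flatnonzero(labels == -1):
        labels[i] = next_label
        next_label += 1
    tids = centers["tid"].to_numpy()
    rows = []
    for site_id, lab in enumerate(np.unique(labels)):
        member = labels == lab
        pos = xyz[member].mean(axis=0)
        rows.append(
            {
                "site_id": site_id,
                "x_nm": pos[0],
                "y_nm": pos[1],
                "z_nm": pos[2],
                "n_traces": int(member.sum()),
                "member_tids": tuple(int(t) for t in tids[member]),
            }
        )
    return pd.DataFrame(rows)


def max_internal_angle(p1, p2, p3) -> float:
    """Maximum internal angle (degrees) of the triangle through three 3D points.

    Computed with the law of cosines; lies in [60, 180] for distinct points
    (180 exactly for collinear ones).

    Raises
    ------
    DegenerateGeometryError
        If any two points coincide.
    """
    p1, p2, p3 = (np.asarray(p, float) for p in (p1, p2, p3))
    a = np.linalg.norm(p2 - p3)  # opposite p1
    b = np.linalg.norm(p1 - p3)  # opposite p2
    c = np.linalg.norm(p1 - p2)  # opposite p3
    if min(a, b, c) == 0.0:
        raise DegenerateGeometryError("coincident points have no triangle angles")
    cos_a = (b * b + c * c - a * a) / (2 * b * c)
    cos_b = (a * a + c * c - b * b) / (2 * a * c)
    cos_c = (a * a + b * b - c * c) / (2 * a * b)
    cosines = np.clip([cos_a, cos_b, cos_c], -1.0, 1.0)
    return float(np.degrees(np.arccos(cosines)).max())


def interblade_distance(positions) -> float:
    """Mean of the three pairwise 3D distances of a protomer triple (nm)."""
    pos = np.asarray(positions, float).reshape(3, 3)
    d = [np.linalg.norm(pos[i] - pos[j]) for i, j in combinations(range(3), 2)]
    return float(np.mean(d))


def find_trimers(sites: pd.DataFrame, rules: TrimerRules | None = None) -> pd.DataFrame:
    """Enumerate all site triples satisfying the trimer rules.

    Returns every unordered triple where (i) all pairwise 3D distances are
    strictly below ``pair_max``, (ii) no non-member site lies strictly within
    ``isolation_radius`` of any member, and (iii) the maximum internal angle
    is strictly below ``angle_max``.  Rules (i)+(ii) imply no two accepted
    trimers share a site.
    """
    rules = rules or TrimerRules()
    if len(sites) < 3:
        return pd.DataFrame(columns=list(TRIMER_COLUMNS))
    pos = sites[_XYZ].to_numpy(float)
    n_traces = (
        sites["n_traces"].to_numpy()
        if "n_traces" in sites.columns
        else np.ones(len(sites), dtype=int)
    )
    site_ids = (
        sites["site_id"].to_numpy()
        if "site_id" in sites.columns
        else np.arange(len(sites))
    )
    tree = cKDTree(pos)
    adj: list[set[int]] = [set() for _ in range(len(pos))]
    for i, j in tree.query_pairs(rules.pair_max):
        if np.linalg.norm(pos[i] - pos[j]) < rules.pair_max:  # strict bound
            adj[i].add(j)
            adj[j].add(i)
    rows = []
    for i in range(len(pos)):
        for j in sorted(a for a in adj[i] if a > i):
            for k in sorted(a for a in (adj[i] & adj[j]) if a > j):
                members = {i, j, k}
                isolated = True
                for m in members:
                    for o in tree.query_ball_point(pos[m], rules.isolation_radius):
                        if o not in members and (
                            np.linalg.norm(pos[o] - pos[m]) < rules.isolation_radius
                        ):
                            isolated = False
                            break
                    if not isolated:
                        break
                if not isolated:
                    continue
                angle = max_internal_angle(pos[i], pos[j], pos[k])
                if angle >= rules.angle_max:
                    continue
                d12 = float(np.linalg.norm(pos[i] - pos[j]))
                d13 = float(np.linalg.norm(pos[i] - pos[k]))
                d23 = float(np.linalg.norm(pos[j] - pos[k]))
                rows.append(
                    {
                        "trimer_id": len(rows),
                        "site_1": int(site_ids[i]),
                        "site_2": int(site_ids[j]),
                        "site_3": int(site_ids[k]),
                        "x1": pos[i, 0], "y1": pos[i, 1], "z1": pos[i, 2],
                        "x2": pos[j, 0], "y2": pos[j, 1], "z2": pos[j, 2],
                        "x3": pos[k, 0], "y3": pos[k, 1], "z3": pos[k, 2],
                        "d12": d12, "d13": d13, "d23": d23,
                        "interblade_nm": (d12 + d13 + d23) / 3.0,
                        "max_angle_deg": angle,
                        "n_traces_1": int(n_traces[i]),
                        "n_traces_2": int(n_traces[j]),
                        "n_traces_3": int(n_traces[k]),
                    }
                )
    if not rows:
        return pd.DataFrame(columns=list(TRIMER_COLUMNS))
    return pd.DataFrame(rows)


def fit_bivariate_gaussian(
    locs, plane: str = "xy", ridge: float = 1e-9
) -> Gaussian2DFit:
    """ML bivariate Gaussian of the in-plane projection of raw localizations.

    Parameters
    ----------
    locs:
        DataFrame with ``x_nm, y_nm, z_nm`` columns or an (n, >=2) array.
    plane:
        Projection plane: ``"xy"`` (default), ``"xz"`` or ``"yz"``.
    ridge:
        Added to the covariance diagonal if it is singular (flagged in the
        result).

    Raises
    ------
    InsufficientDataError
        For fewer than 3 points.
    """
    if isinstance(locs, pd.DataFrame):
        cols = {"xy": ["x_nm", "y_nm"], "xz": ["x_nm", "z_nm"], "yz": ["y_nm", "z_nm"]}[plane]
        pts = locs[cols].to_numpy(float)
    else:
        pts = np.asarray(locs, float)[:, :2]
    if len(pts) < 3:
        raise InsufficientDataError(f"need >= 3 points, got {len(pts)}")
    mean = pts.mean(axis=0)
    cov = np.cov(pts.T, bias=True)  # ML estimate (1/n)
    regularized = False
    if np.linalg.eigvalsh(cov).min() <= 0:
        cov = cov + ridge * np.eye(2)
        regularized = True
    return Gaussian2DFit(mean=mean, covariance=cov, n_points=len(pts), regularized=regularized)
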