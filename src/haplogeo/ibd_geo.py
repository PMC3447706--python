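"""Geographic distances, Mantel tests, Nei's genetic distance, and
gene-flow/drift regime classification from distance scatterplots."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_model import DistanceMatrix, FormatError, PopulationTable

__all__ = [
    "MantelResult",
    "IbdClassification",
    "haversine_km",
    "great_circle_matrix",
    "mantel_test",
    "classify_ibd_regime",
    "nei_distance_matrix",
]

EARTH_RADIUS_KM = 6371.0
DEFAULT_PERMUTATIONS = 999
DEFAULT_SEED = 20120430
#: Significance threshold used by both the slope and the residual-scatter
#: trend when classifying the gene-flow/drift regime.
REGIME_ALPHA = 0.05
#: Case IV call: scatter is "restricted to larger distances" when the mean
#: absolute residual in the lower distance tercile falls below this fraction
#: of the upper tercile's.
SCATTER_TAIL_RATIO = 0.5
#: Case II call: differentiation is "uniformly low" when the mean genetic
#: distance is below this value (natural for F_ST-scaled matrices).
LOW_DIVERGENCE = 0.2


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float | None
    n_permutations: int
    n_populations: int
    scope: str = ""

    def __post_init__(self) -> None:
        if not math.isnan(self.r) and not (-1.0 - 1e-9 <= self.r <= 1.0 + 1e-9):
            raise ValueError(f"r {self.r} outside [-1, 1]")
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class IbdClassification:
    """Hutchison-Templeton style regime call.

    Case I: significant positive slope (regional gene-flow/drift
    equilibrium, isolation by distance).  Case III: no significant slope
    with scatter at all distances (drift dominant).  Case II and IV cover
    the residual-scatter corners; see :func:`classify_ibd_regime`.
    """

    case: str
    slope: float
    slope_significant: bool
    mantel_p: float
    scatter_rho: float
    scatter_p: float


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance on a sphere of radius 6371 km."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def great_circle_matrix(table: PopulationTable) -> DistanceMatrix:
    """Pairwise haversine distances (km) between population coordinates."""
    K = table.K
    out = np.zeros((K, K))
    recs = table.records
    for r in recs:
        if not (-90 <= r.latitude <= 90 and -180 <= r.longitude <= 180):
            raise FormatError(f"{r.code}: coordinates out of range")
    for i in range(K):
        for j in range(i + 1, K):
            d = haversine_km(
                recs[i].latitude, recs[i].longitude, recs[j].latitude, recs[j].longitude
            )
            out[i, j] = out[j, i] = d
    return DistanceMatrix(table.codes, out, units="km")


def mantel_test(
    d_gen: DistanceMatrix,
    d_geo: DistanceMatrix,
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int | np.random.Generator = DEFAULT_SEED,
    scope: str = "",
) -> MantelResult:
    """Simple Mantel test, one-tailed for positive association.

    ``r`` is the Pearson correlation over the ``n(n-1)/2`` off-diagonal
    pairs; the null permutes the population labels of one matrix; the
    p-value is ``(1 + #{r* >= r}) / (n_perm + 1)``.
    """
    if d_gen.labels != d_geo.labels:
        d_geo = d_geo.submatrix(d_gen.labels)
    n = len(d_gen.labels)
    if n < 4:
        raise ValueError("Mantel test needs at least 4 populations")
    x = d_gen.condensed()
    y = d_geo.condensed()
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        warnings.warn("zero-variance distance matrix: Mantel r undefined")
        return MantelResult(float("nan"), None, 0, n, scope)
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    values = d_gen.values
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        x_star = values[np.ix_(perm, perm)][iu]
        r_star = float(np.corrcoef(x_star, y)[0, 1])
        if r_star >= r_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return MantelResult(r_obs, p, n_perm, n, scope)


def classify_ibd_regime(
    d_gen: DistanceMatrix,
    d_geo: DistanceMatrix,
    mantel: MantelResult,
    alpha: float = REGIME_ALPHA,
) -> IbdClassification:
    """Classify the gene-flow/drift regime from the distance scatterplot.

    The slope comes from the least-squares regression of genetic on
    geographic distance; its significance is the Mantel p-value.  The
    residual-scatter trend (Spearman correlation between geographic
    distance and absolute regression residuals) is reported for
    diagnostics.  Rules (documented constants, threshold ``alpha``):

    * significant positive slope -> Case I (regional gene-flow/drift
      equilibrium, isolation by distance);
    * non-significant slope with uniformly low differentiation
      (mean genetic distance < ``LOW_DIVERGENCE``) -> Case II (gene flow
      dominant at all distances);
    * non-significant slope with scatter concentrated at larger distances
      (lower-tercile mean absolute residual < ``SCATTER_TAIL_RATIO`` x the
      upper tercile's) -> Case IV (drift dominating at larger distances);
    * otherwise -> Case III (scatter at all distances, drift dominant).
    """
    if d_gen.labels != d_geo.labels:
        d_geo = d_geo.submatrix(d_gen.labels)
    n = len(d_gen.labels)
    if n < 5:
        raise ValueError("classification declined: fewer than 5 populations")
    x = d_geo.condensed()
    y = d_gen.condensed()
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    rho, rho_p = stats.spearmanr(x, np.abs(resid))
    slope_sig = (
        mantel.p_value is not None and mantel.p_value < alpha and fit.slope > 0
    )
    if slope_sig:
        case = "I"
    else:
        q = np.quantile(x, [1.0 / 3.0, 2.0 / 3.0])
        lo = float(np.abs(resid)[x <= q[0]].mean())
        hi = float(np.abs(resid)[x > q[1]].mean())
        if float(y.mean()) < LOW_DIVERGENCE:
            case = "II"
        elif hi > 0 and lo < SCATTER_TAIL_RATIO * hi:
            case = "IV"
        else:
            case = "III"
    return IbdClassification(
        case=case,
        slope=float(fit.slope),
        slope_significant=bool(slope_sig),
        mantel_p=float(mantel.p_value) if mantel.p_value is not None else float("nan"),
        scatter_rho=float(rho),
        scatter_p=float(rho_p),
    )


def nei_distance_matrix(table: PopulationTable) -> DistanceMatrix:
    """Nei's standard genetic distance on haplotype frequencies.

    ``D = -ln(J_xy / sqrt(J_x J_y))`` per population pair.  Pairs sharing no
    haplotype have infinite distance; these are capped at the maximum finite
    distance plus one, with a warning, and the cap is stored on the returned
    matrix as ``nei_cap``.
    """
    freqs = table.frequency_matrix()
    K = table.K
    J = freqs @ freqs.T
    out = np.zeros((K, K))
    infinite = []
    for i in range(K):
        for j in range(i + 1, K):
            jxy = J[i, j]
            if jxy <= 0.0:
                infinite.append((i, j))
                continue
            d = -math.log(jxy / math.sqrt(J[i, i] * J[j, j]))
            out[i, j] = out[j, i] = max(0.0, d)
    cap = None
    if infinite:
        finite_max = out.max()
        cap = finite_max + 1.0
        warnings.warn(
            f"{len(infinite)} population pairs share no haplotype; "
            f"infinite Nei distances capped at {cap:.4f}"
        )
        for i, j in infinite:
            out[i, j] = out[j, i] = cap
    result = DistanceMatrix(table.codes, out, units="nei")
    result.nei_cap = cap
    return result
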