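"""Weighted co-expression network construction and module detection.

Candidate genes from one direction (up- or down-regulated) are clustered in a
reference cohort: Pearson correlation → soft-thresholded adjacency
(a_ij = |cor_ij|^power, unsigned by default) → topological overlap matrix
(TOM) → average-linkage hierarchical clustering of 1 − TOM → fixed-height
tree cut.  Branches below ``cut_height`` with at least ``min_module_size``
genes become modules "M1", "M2", … (decreasing size); everything else is
assigned the reserved label "grey".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .exceptions import ValidationError
from .io import ExpressionMatrix

GREY = "grey"

#: Candidate soft-threshold powers scanned by default.
DEFAULT_POWERS = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)


@dataclass
class NetworkParams:
    """Hyperparameters of the co-expression network.

    power=None requests automatic soft-threshold selection (scale-free fit).
    """

    correlation: str = "pearson"
    signed: bool = False
    power: float | None = 6.0
    min_module_size: int = 10
    cut_height: float = 0.99

    def __post_init__(self):
        if self.correlation != "pearson":
            raise ValidationError("only pearson correlation is supported")
        if self.power is not None and self.power < 1:
            raise ValidationError("power must be >= 1")
        if self.min_module_size < 5:
            raise ValidationError("min_module_size must be >= 5")
        if not (0 < self.cut_height <= 1):
            raise ValidationError("cut_height must be in (0, 1]")


@dataclass
class ModuleAssignment:
    """gene → module label ("M1", "M2", ... or "grey")."""

    labels: pd.Series
    dataset_tag: str = ""
    direction_tag: str = ""
    params: NetworkParams | None = None
    dendrogram_order: list[str] = field(default_factory=list)

    def module_genes(self, label: str) -> list[str]:
        return self.labels.index[self.labels == label].tolist()

    def module_names(self) -> list[str]:
        """Non-grey module labels, in size order (M1 largest)."""
        names = [l for l in self.labels.unique() if l != GREY]
        return sorted(names, key=lambda l: int(l[1:]))

    @property
    def genes(self) -> list[str]:
        return list(self.labels.index)


def correlation_matrix(expr: ExpressionMatrix, genes: list[str]) -> pd.DataFrame:
    """Pearson correlation among ``genes`` across samples.

    Zero-variance genes get correlation 0 to every other gene (warning), so
    downstream network algebra stays finite.
    """
    if expr.n_samples < 3:
        raise ValidationError("need >= 3 samples for correlations")
    sub = expr.subset_genes(list(genes)).values.to_numpy(dtype=float)
    sd = sub.std(axis=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance gene(s); "
                      "correlations set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sub)
    corr[np.isnan(corr)] = 0.0
    corr = np.clip(corr, -1.0, 1.0)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=list(genes), columns=list(genes))


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R² of the scale-free topology fit log10 p(k) ~ log10 k.

    Connectivities are binned, per-bin frequency regressed on per-bin mean
    connectivity on log-log scale.  The R² is sign-flipped when the slope is
    positive (scale-free topology requires a decreasing law), mirroring the
    conventional signed fit index.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.allclose(k, k[0]):
        return -1.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_p = [], []
    for b in range(n_bins):
        members = k[idx == b]
        if members.size == 0:
            continue
        log_k.append(np.log10(members.mean()))
        log_p.append(np.log10(members.size / k.size))
    if len(log_k) < 3:
        return -1.0
    log_k, log_p = np.asarray(log_k), np.asarray(log_p)
    slope, intercept = np.polyfit(log_k, log_p, 1)
    fitted = slope * log_k + intercept
    ss_res = float(((log_p - fitted) ** 2).sum())
    ss_tot = float(((log_p - log_p.mean()) ** 2).sum())
    if ss_tot == 0:
        return -1.0
    r2 = 1.0 - ss_res / ss_tot
    return -r2 if slope > 0 else r2


def pick_soft_threshold(corr: pd.DataFrame,
                        powers=DEFAULT_POWERS,
                        signed: bool = False,
                        r2_target: float = 0.8,
                        fallback: float = 6.0) -> float:
    """Smallest candidate power with scale-free fit R² >= target.

    Falls back to ``fallback`` (with a warning) when no candidate reaches
    the target, matching common practice for soft-threshold selection.
    """
    c = np.asarray(corr, dtype=float)
    off = c[~np.eye(c.shape[0], dtype=bool)]
    if np.allclose(off, 0.0):
        raise ValidationError("degenerate network: all correlations are 0")
    for power in powers:
        if power < 1:
            raise ValidationError("candidate powers must be >= 1")
        adj = _adjacency_array(c, power, signed)
        k = adj.sum(axis=0) - 1.0
        if scale_free_fit(k) >= r2_target:
            return float(power)
    warnings.warn(f"no candidate power reached scale-free R² >= {r2_target}; "
                  f"falling back to power {fallback}")
    return float(fallback)


def _adjacency_array(corr: np.ndarray, power: float, signed: bool) -> np.ndarray:
    if signed:
        adj = ((1.0 + corr) / 2.0) ** power
    else:
        adj = np.abs(corr) ** power
    np.fill_diagonal(adj, 1.0)
    return adj


def adjacency(corr: pd.DataFrame, params: NetworkParams) -> pd.DataFrame:
    """Soft-thresholded adjacency; unsigned |cor|^power or signed variant."""
    if params.power is None:
        raise ValidationError("params.power must be set (use pick_soft_threshold)")
    adj = _adjacency_array(np.asarray(corr, dtype=float), params.power,
                           params.signed)
    return pd.DataFrame(adj, index=corr.index, columns=corr.columns)


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    k_i = sum_{u != i} a_iu; TOM_ii = 1.  Entries lie in [0, 1] for
    adjacencies in [0, 1] with unit diagonal.
    """
    a = np.asarray(adj, dtype=float)
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValidationError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValidationError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=0)
    shared = a @ a  # (shared)_ij = sum_u a_iu a_uj, u != i,j after diag zeroed
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


class CoexpressionModules(BaseEstimator, ClusterMixin):
    """Co-expression module detector (sklearn-style clusterer).

    fit(X) expects samples × genes (sklearn orientation).  Fitted
    attributes: ``labels_`` (array of module labels per gene),
    ``power_`` (the soft threshold actually used), ``dendrogram_order_``.
    """

    def __init__(self, power: float | None = 6.0, signed: bool = False,
                 min_module_size: int = 10, cut_height: float = 0.99):
        self.power = power
        self.signed = signed
        self.min_module_size = min_module_size
        self.cut_height = cut_height

    def _params(self) -> NetworkParams:
        return NetworkParams(power=self.power, signed=self.signed,
                             min_module_size=self.min_module_size,
                             cut_height=self.cut_height)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n_samples, n_genes = X.shape
        genes = [f"g{i}" for i in range(n_genes)]
        em = ExpressionMatrix(
            pd.DataFrame(X.T, index=genes,
                         columns=[f"s{i}" for i in range(n_samples)]),
            platform="microarray_log2")
        assign = detect_modules(em, genes, self._params())
        self.labels_ = assign.labels.to_numpy()
        self.power_ = assign.params.power if assign.params else self.power
        self.dendrogram_order_ = [genes.index(g) for g in assign.dendrogram_order]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def detect_modules(expr: ExpressionMatrix, genes: list[str],
                   params: NetworkParams | None = None,
                   dataset_tag: str = "", direction_tag: str = ""
                   ) -> ModuleAssignment:
    """Detect co-expression modules among ``genes`` in one reference cohort.

    Average-linkage clustering of the TOM dissimilarity; branches below
    ``params.cut_height`` with >= ``params.min_module_size`` members become
    modules, labelled "M1", "M2", ... in decreasing size order; all other
    genes are "grey".
    """
    params = params or NetworkParams()
    genes = list(genes)
    if len(genes) < params.min_module_size:
        warnings.warn("fewer genes than min_module_size; all assigned grey")
        labels = pd.Series(GREY, index=genes)
        return ModuleAssignment(labels, dataset_tag, direction_tag, params, genes)
    corr = correlation_matrix(expr, genes)
    power = params.power
    if power is None:
        power = pick_soft_threshold(corr, signed=params.signed)
    resolved = NetworkParams(power=power, signed=params.signed,
                             min_module_size=params.min_module_size,
                             cut_height=params.cut_height)
    adj = adjacency(corr, resolved)
    tom = topological_overlap(adj)
    dissim = 1.0 - tom.to_numpy()
    np.fill_diagonal(dissim, 0.0)
    dissim = np.clip((dissim + dissim.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dissim, checks=False), method="average")
    clusters = fcluster(Z, t=params.cut_height, criterion="distance")
    labels = _label_clusters(clusters, genes, params.min_module_size)
    from scipy.cluster.hierarchy import leaves_list
    order = [genes[i] for i in leaves_list(Z)]
    return ModuleAssignment(labels, dataset_tag, direction_tag, resolved, order)


def _label_clusters(clusters: np.ndarray, genes: list[str],
                    min_size: int) -> pd.Series:
    sizes: dict[int, int] = {}
    first_member: dict[int, int] = {}
    for i, c in enumerate(clusters):
        sizes[c] = sizes.get(c, 0) + 1
        first_member.setdefault(c, i)
    kept = [c for c, s in sizes.items() if s >= min_size]
    # decreasing size; ties broken by earliest member for determinism
    kept.sort(key=lambda c: (-sizes[c], first_member[c]))
    mapping = {c: f"M{i + 1}" for i, c in enumerate(kept)}
    return pd.Series([mapping.get(c, GREY) for c in clusters], index=genes)
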