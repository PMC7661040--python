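"""Consensus co-methylation modules: signed adjacency, topological overlap,
consensus calibration, dynamic tree cut, and eigengene-based pruning.

The network is *signed*: ``a_ij = ((1 + cor_ij) / 2) ** power``, so
anticorrelated CpGs get adjacency near 0 rather than near 1.  Topological
overlap then rewards shared neighbourhoods::

    w_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_u a_iu * a_uj  (u != i, j),   k_i = sum_u a_iu  (u != i)

Consensus across datasets scales each TOM so a high quantile of its
off-diagonal values matches the first dataset's, then takes the element-wise
minimum.  Modules are branches of an average-linkage dendrogram of ``1 - w``
extracted with a Dynamic Hybrid style cut (no PAM stage): a branch is a
module when it is large enough, its core merges tightly (core scatter), and
it is well separated from its surroundings (gap).  Members whose consensus
correlation with their module eigengene falls below ``min_kme`` are moved to
the unassigned ("grey") label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from .clocks import PCClock, fit_pc_clock
from .matrix import BetaMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkConfig",
    "signed_adjacency",
    "tom",
    "consensus_tom",
    "cut_modules",
    "module_eigengene",
    "kme_prune",
    "module_clock",
    "ConsensusModules",
    "GREY",
    "MODULE_PALETTE",
]

GREY = "grey"
# labels are assigned to detected modules in decreasing size order
MODULE_PALETTE = [
    "blue", "pink", "purple", "green", "yellow", "brown", "red", "black",
    "magenta", "salmon", "cyan", "tan", "orange",
]

# deepSplit -> (maxCoreScatter, minGap), the canonical Dynamic Hybrid mapping
_DEEP_SPLIT = {
    0: (0.64, 0.27),
    1: (0.73, 0.2025),
    2: (0.82, 0.135),
    3: (0.91, 0.0675),
    4: (0.95, 0.0375),
}


@dataclass
class NetworkConfig:
    power: float = 1.0
    network_type: str = "signed"
    deep_split: int = 1
    min_module_size: int = 25
    min_kme: float = 0.4
    consensus_quantile: float = 0.95
    corr_method: str = "pearson"  # or "bicor"

    def __post_init__(self) -> None:
        if self.power <= 0:
            raise ValueError("power must be positive")
        if not (0 <= self.min_kme <= 1):
            raise ValueError("min_kme must be in [0, 1]")
        if self.deep_split not in _DEEP_SPLIT:
            raise ValueError("deep_split must be an integer 0-4")


# ----------------------------------------------------------------- adjacency
def _corr_matrix(values: np.ndarray, method: str) -> np.ndarray:
    """Site x site correlation across samples; constant sites get cor 0."""
    if method == "pearson":
        sd = values.std(axis=1)
        const = sd == 0
        if const.any():
            logger.info("%d constant CpGs: correlations set to 0", int(const.sum()))
        centered = values - values.mean(axis=1, keepdims=True)
        denom = np.where(const, 1.0, sd * np.sqrt(values.shape[1]))
        normed = centered / denom[:, None]
        C = normed @ normed.T
        C[const, :] = 0.0
        C[:, const] = 0.0
        np.fill_diagonal(C, 1.0)
        return np.clip(C, -1.0, 1.0)
    elif method == "bicor":
        med = np.median(values, axis=1, keepdims=True)
        mad = np.median(np.abs(values - med), axis=1, keepdims=True)
        zero = mad[:, 0] == 0
        u = (values - med) / np.where(mad == 0, 1.0, 9.0 * mad)
        w = (1 - u**2) ** 2 * (np.abs(u) < 1)
        t = (values - med) * w
        # rows with zero MAD fall back to centred values (Pearson-like)
        t[zero] = values[zero] - values[zero].mean(axis=1, keepdims=True)
        norm = np.sqrt((t**2).sum(axis=1))
        const = norm == 0
        t = t / np.where(const, 1.0, norm)[:, None]
        C = t @ t.T
        C[const, :] = 0.0
        C[:, const] = 0.0
        np.fill_diagonal(C, 1.0)
        return np.clip(C, -1.0, 1.0)
    raise ValueError(f"unknown correlation method {method!r}")


def signed_adjacency(matrix, power: float = 1.0, corr_method: str = "pearson") -> np.ndarray:
    """Signed network adjacency ``((1 + cor) / 2) ** power``."""
    values = matrix.values if isinstance(matrix, BetaMatrix) else np.asarray(matrix, float)
    if values.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if np.isnan(values).any():
        raise ValueError("adjacency requires a complete matrix")
    C = _corr_matrix(values, corr_method)
    A = ((1.0 + C) / 2.0) ** power
    np.fill_diagonal(A, 1.0)
    return A


# ----------------------------------------------------------------------- TOM
def tom(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a symmetric adjacency in [0, 1]."""
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    L = A @ A  # L[i,j] = sum_u a_iu a_uj; includes u == i or j only via diag-zeroed A
    kmin = np.minimum.outer(k, k)
    W = (L + A) / (kmin + 1.0 - A)
    np.fill_diagonal(W, 1.0)
    return np.clip(W, 0.0, 1.0)


def consensus_tom(toms, consensus_quantile: float = 0.95) -> np.ndarray:
    """Quantile-calibrate each TOM to the first, then take the element-wise min."""
    toms = [np.asarray(t, dtype=float) for t in toms]
    shape = toms[0].shape
    for t in toms[1:]:
        if t.shape != shape:
            raise ValueError("TOM matrices must share the same site list and order")
    off = ~np.eye(shape[0], dtype=bool)
    ref_q = np.quantile(toms[0][off], consensus_quantile)
    scaled = [toms[0]]
    for t in toms[1:]:
        q = np.quantile(t[off], consensus_quantile)
        factor = ref_q / q if q > 0 else 1.0
        scaled.append(t * factor)
    cons = np.minimum.reduce(scaled)
    np.fill_diagonal(cons, 1.0)
    return np.clip(cons, 0.0, 1.0)


# ---------------------------------------------------------- dynamic tree cut
def _dynamic_hybrid(Z: np.ndarray, min_size: int, max_core_scatter: float,
                    min_gap: float, cut_fraction: float = 0.99) -> np.ndarray:
    """Extract clusters from an average-linkage tree, Dynamic Hybrid style.

    Returns integer labels (0 = unassigned).  The merge sequence is replayed
    bottom-up while branch identities are tracked: a branch absorbs clusters
    smaller than ``min_size`` without losing its identity, and is evaluated
    as a candidate cluster at the height where it attaches to a substantial
    counterpart (or at the static cut height, ``cut_fraction`` times the top
    merge).  A branch qualifies when

    * its size reaches ``min_size``,
    * its core scatter — the mean height of the merges assembling its
      ``min_size``-member core — stays below an absolute threshold, and
    * its gap — attachment height minus the height at which the core
      completed — exceeds an absolute threshold,

    with both absolute thresholds interpolated between the 5th percentile of
    all merge heights and the cut height via ``max_core_scatter``/``min_gap``
    (the deepSplit mapping).  No PAM-style reassignment is performed; weak
    chance branches that slip through are expected to dissolve in the
    eigengene (kME) pruning step.
    """
    n = Z.shape[0] + 1
    heights = Z[:, 2]
    cut_h = cut_fraction * heights.max()
    ref_h = np.quantile(heights, 0.05)
    max_abs_scatter = ref_h + max_core_scatter * (cut_h - ref_h)
    min_abs_gap = min_gap * (cut_h - ref_h)
    core_max = max(min_size, 2)

    # per active cluster: members (leaf ids), core (sorted smallest merge
    # heights, capped), n emitted modules inside
    members: dict[int, list] = {i: [i] for i in range(n)}
    cores: dict[int, np.ndarray] = {i: np.empty(0) for i in range(n)}
    tops: dict[int, float] = {i: 0.0 for i in range(n)}
    has_module: dict[int, bool] = {i: False for i in range(n)}
    emitted: list[list] = []

    def _evaluate(x: int, attach_h: float) -> None:
        if has_module[x] or len(members[x]) < min_size:
            return
        core = cores[x]
        scatter = float(core.mean())
        core_top = float(core[-1])
        # a genuine branch assembles entirely below the scatter cap; a loose
        # composite that swallowed a tight core keeps merging right up to the
        # attachment and is rejected by the top condition
        if (scatter <= max_abs_scatter
                and tops[x] <= max_abs_scatter
                and (attach_h - core_top) >= min_abs_gap):
            emitted.append(list(members[x]))
            has_module[x] = True

    for m in range(n - 1):
        a, b = int(Z[m, 0]), int(Z[m, 1])
        h = float(heights[m])
        # a branch is emitted at the first attachment that proves its
        # separation, before it can absorb loosely attached stragglers
        attach = min(h, cut_h)
        _evaluate(a, attach)
        _evaluate(b, attach)
        # merge b into a (smaller into larger), register as node n + m
        if len(members[a]) < len(members[b]):
            a, b = b, a
        members[a].extend(members[b])
        core = np.sort(np.concatenate([cores[a], cores[b], [h]]))[:core_max - 1]
        u = n + m
        members[u] = members[a]
        cores[u] = core
        tops[u] = h
        has_module[u] = has_module[a] or has_module[b]
        del members[b], cores[b], has_module[b], tops[b]
        if a != u:
            del members[a], cores[a], has_module[a], tops[a]

    labels = np.zeros(n, dtype=np.int64)
    for ci, leaf_ids in enumerate(emitted, start=1):
        labels[np.asarray(leaf_ids, dtype=np.int64)] = ci
    return labels


def cut_modules(consensus: np.ndarray, cfg: NetworkConfig | None = None,
                site_ids=None) -> pd.Series:
    """Cluster 1 - TOM with average linkage and the dynamic hybrid cut.

    Returns a Series of colour labels (grey = unassigned) indexed by site id,
    with colours assigned by decreasing module size.
    """
    cfg = cfg or NetworkConfig()
    W = np.asarray(consensus, dtype=float)
    n = W.shape[0]
    if n < 2:
        raise ValueError("need at least 2 sites")
    if n < cfg.min_module_size:
        raise ValueError("fewer sites than min_module_size")
    D = 1.0 - W
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    max_scatter, min_gap = _DEEP_SPLIT[cfg.deep_split]
    raw = _dynamic_hybrid(Z, cfg.min_module_size, max_scatter, min_gap)
    return _colourise(raw, site_ids if site_ids is not None else pd.RangeIndex(n))


def _colourise(raw: np.ndarray, site_ids) -> pd.Series:
    labels = pd.Series(GREY, index=pd.Index(site_ids), dtype=object, name="module")
    ids, counts = np.unique(raw[raw > 0], return_counts=True)
    order = ids[np.argsort(-counts, kind="mergesort")]
    for rank, cid in enumerate(order):
        colour = MODULE_PALETTE[rank] if rank < len(MODULE_PALETTE) else f"module{rank + 1}"
        labels.iloc[np.flatnonzero(raw == cid)] = colour
    return labels


# ------------------------------------------------------------- eigengenes
@dataclass
class Eigengene:
    module: str
    scores: pd.Series      # per-sample, zero mean
    kme: pd.Series         # per-CpG correlation with the scores (all CpGs)


def module_eigengene(matrix: BetaMatrix, labels: pd.Series, module: str) -> Eigengene:
    """First principal component of a module's centred submatrix.

    Scores are centred to zero mean and oriented so the mean kME over module
    members is non-negative.
    """
    members = labels.index[labels == module]
    if len(members) == 0:
        raise ValueError(f"module {module!r} is empty")
    sub = matrix.subset_sites(members)
    V = sub.values - sub.values.mean(axis=1, keepdims=True)
    if len(members) == 1:
        scores = V[0]
    else:
        _, _, Vt = np.linalg.svd(V, full_matrices=False)
        scores = Vt[0]
    scores = scores - scores.mean()
    scores_s = pd.Series(scores, index=matrix.samples, name=module)
    kme = _kme_against(matrix, scores)
    member_mean = kme.loc[members].mean()
    if member_mean < 0:
        scores_s = -scores_s
        kme = -kme
    return Eigengene(module=module, scores=scores_s, kme=kme)


def _kme_against(matrix: BetaMatrix, scores: np.ndarray) -> pd.Series:
    V = matrix.values
    Vc = V - V.mean(axis=1, keepdims=True)
    sc = scores - scores.mean()
    denom = np.sqrt((Vc**2).sum(axis=1) * (sc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Vc @ sc) / denom
    return pd.Series(np.nan_to_num(r), index=matrix.site_ids, name="kme")


def kme_prune(matrices, labels: pd.Series, cfg: NetworkConfig | None = None) -> pd.Series:
    """Move members with consensus kME below ``min_kme`` to grey.

    Consensus kME is the minimum across datasets of a CpG's correlation with
    its own module's eigengene.  Eigengenes are recomputed once after the
    removal pass; modules falling below ``min_module_size`` dissolve to grey.
    """
    cfg = cfg or NetworkConfig()
    if isinstance(matrices, BetaMatrix):
        matrices = [matrices]
    labels = labels.copy()
    for _pass in range(2):
        modules = [m for m in labels.unique() if m != GREY]
        for module in modules:
            members = labels.index[labels == module]
            kmes = []
            for mat in matrices:
                eg = module_eigengene(mat, labels, module)
                kmes.append(eg.kme.loc[members])
            consensus_kme = pd.concat(kmes, axis=1).min(axis=1)
            drop = consensus_kme.index[consensus_kme < cfg.min_kme]
            labels.loc[drop] = GREY
            if (labels == module).sum() < cfg.min_module_size:
                labels.loc[labels == module] = GREY
        if _pass == 0 and not (labels != GREY).any():
            break
    return labels


def module_clock(matrix: BetaMatrix, train_ids, ages, labels: pd.Series,
                 module: str) -> PCClock:
    """PC clock restricted to one module's CpGs."""
    members = labels.index[labels == module]
    if len(members) < 2:
        raise ValueError(f"module {module!r} has fewer than 2 CpGs")
    sub = matrix.subset_sites(members).subset_samples(list(train_ids))
    return fit_pc_clock(sub.X, np.asarray(ages, float), sites=sub.site_ids)


# ------------------------------------------------------------- estimator
class ConsensusModules(BaseEstimator):
    """Consensus co-methylation module detection across one or more datasets.

    ``fit`` takes a list of complete :class:`BetaMatrix` objects sharing the
    same site list (e.g. the rat and mouse matrices on the common CpGs).

    Attributes (fitted)
    -------------------
    labels_ : Series, CpG -> colour label ("grey" = unassigned).
    eigengenes_ : list (per dataset) of DataFrames, samples x modules.
    kme_ : list (per dataset) of DataFrames, CpGs x modules.
    consensus_tom_ : the calibrated consensus TOM (ndarray).
    """

    def __init__(self, power: float = 1.0, deep_split: int = 1,
                 min_module_size: int = 25, min_kme: float = 0.4,
                 consensus_quantile: float = 0.95, corr_method: str = "pearson",
                 keep_tom: bool = False):
        self.power = power
        self.deep_split = deep_split
        self.min_module_size = min_module_size
        self.min_kme = min_kme
        self.consensus_quantile = consensus_quantile
        self.corr_method = corr_method
        self.keep_tom = keep_tom

    def _config(self) -> NetworkConfig:
        return NetworkConfig(
            power=self.power, deep_split=self.deep_split,
            min_module_size=self.min_module_size, min_kme=self.min_kme,
            consensus_quantile=self.consensus_quantile, corr_method=self.corr_method,
        )

    def fit(self, matrices, y=None) -> "ConsensusModules":
        cfg = self._config()
        if isinstance(matrices, BetaMatrix):
            matrices = [matrices]
        site_ids = matrices[0].site_ids
        for m in matrices[1:]:
            if not site_ids.equals(m.site_ids):
                raise ValueError("datasets must share the same site list and order")
        toms = [tom(signed_adjacency(m, power=cfg.power, corr_method=cfg.corr_method))
                for m in matrices]
        cons = consensus_tom(toms, cfg.consensus_quantile)
        labels = cut_modules(cons, cfg, site_ids=site_ids)
        labels = kme_prune(matrices, labels, cfg)
        # re-colour by final size so the palette order reflects pruned sizes
        raw = np.zeros(len(labels), dtype=np.int64)
        for i, mod in enumerate([m for m in labels.unique() if m != GREY], start=1):
            raw[np.flatnonzero((labels == mod).to_numpy())] = i
        self.labels_ = _colourise(raw, site_ids)
        self.eigengenes_ = []
        self.kme_ = []
        modules = [m for m in self.labels_.unique() if m != GREY]
        for mat in matrices:
            egs = {m: module_eigengene(mat, self.labels_, m) for m in modules}
            self.eigengenes_.append(pd.DataFrame({m: e.scores for m, e in egs.items()}))
            self.kme_.append(pd.DataFrame({m: e.kme for m, e in egs.items()}))
        if self.keep_tom:
            self.consensus_tom_ = cons
        self.module_sizes_ = self.labels_[self.labels_ != GREY].value_counts()
        return self

    def fit_predict(self, matrices, y=None) -> pd.Series:
        return self.fit(matrices).labels_
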