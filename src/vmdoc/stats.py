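"""Kruskal-Wallis feature screening, Dunn's post-hoc test, Spearman correlation.

Each feature column is screened with the rank-based Kruskal-Wallis test
across the class groups; features with p < alpha (raw, no multiplicity
correction) are selected.  Dunn's z test localizes which group pairs differ,
and the selected features are correlated (Spearman) with the behavioral
CRS-R and GCS scores.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FeatureTable

__all__ = [
    "SelectionResult",
    "kruskal_wallis",
    "dunn_posthoc",
    "select_features",
    "spearman_corr",
]


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    Degenerate input (all pooled observations identical) yields H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrs):
        raise ValueError("empty group")
    if sum(a.size for a in arrs) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrs)
    return float(h), float(p)


def dunn_posthoc(groups: Sequence[Sequence[float]],
                 adjust: Optional[str] = None) -> Dict[Tuple[int, int], float]:
    """Dunn's rank-based pairwise comparisons after Kruskal-Wallis.

    For groups i, j with mean ranks Rbar_i, Rbar_j over the pooled ranking
    of N observations,

        z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))

    with tie correction T = sum(t^3 - t) / (12(N - 1)).  Returns two-sided
    normal p-values keyed by the 0-based group-index pair; ``adjust=
    "bonferroni"`` multiplies by the number of pairs (capped at 1).
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrs):
        raise ValueError("empty group")
    pooled = np.concatenate(arrs)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (n - 1)) if n > 1 else 0.0
    mean_ranks = []
    start = 0
    for a in arrs:
        mean_ranks.append(ranks[start:start + a.size].mean())
        start += a.size
    pairs = list(itertools.combinations(range(len(arrs)), 2))
    out: Dict[Tuple[int, int], float] = {}
    var_base = n * (n + 1) / 12.0 - tie_term
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / arrs[i].size + 1.0 / arrs[j].size))
        if se == 0:
            p = 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = float(2.0 * sps.norm.sf(abs(z)))
        if adjust == "bonferroni":
            p = min(1.0, p * len(pairs))
        out[(i, j)] = p
    return out


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman rank correlation (rho, p) with tie-averaged ranks.

    Returns (nan, nan) when either variable has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class SelectionResult:
    """Per-feature screening outcome and score correlations.

    ``dunn_p``/``dunn_p_adj`` map feature name -> {pair label -> p}; Spearman
    correlations are reported for selected features only.
    """

    feature_names: List[str]
    h: np.ndarray
    p: np.ndarray
    selected: np.ndarray
    alpha: float
    group_labels: List[str]
    dunn_p: Dict[str, Dict[str, float]] = field(default_factory=dict)
    dunn_p_adj: Dict[str, Dict[str, float]] = field(default_factory=dict)
    rho_crsr: Dict[str, float] = field(default_factory=dict)
    p_crsr: Dict[str, float] = field(default_factory=dict)
    rho_gcs: Dict[str, float] = field(default_factory=dict)
    p_gcs: Dict[str, float] = field(default_factory=dict)

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    @property
    def selected_names(self) -> List[str]:
        return [n for n, s in zip(self.feature_names, self.selected) if s]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        pair_labels = [f"p_{a}_vs_{b}" for a, b in
                       itertools.combinations(self.group_labels, 2)]
        for i, name in enumerate(self.feature_names):
            row = {"feature": name, "H": self.h[i], "p": self.p[i],
                   "selected": bool(self.selected[i])}
            for lab in pair_labels:
                row[lab] = self.dunn_p.get(name, {}).get(lab, np.nan)
            row["rho_crsr"] = self.rho_crsr.get(name, np.nan)
            row["rho_gcs"] = self.rho_gcs.get(name, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def kw_mask(values: np.ndarray, labels: Sequence[str], alpha: float = 0.05) -> np.ndarray:
    """Boolean column mask of features with Kruskal-Wallis p < alpha.

    Lightweight variant of :func:`select_features` for in-fold selection.
    """
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    mask = np.zeros(values.shape[1], dtype=bool)
    for j in range(values.shape[1]):
        col = values[:, j]
        if not np.all(np.isfinite(col)):
            continue
        _, p = kruskal_wallis([col[labels == c] for c in classes])
        mask[j] = p < alpha
    return mask


def select_features(table: FeatureTable, alpha: float = 0.05) -> SelectionResult:
    """Screen every feature column across the class groups present in ``table``.

    Selection is the strict raw-p criterion p < alpha.  For >= 3 groups,
    Dunn's pairwise p-values (unadjusted and Bonferroni-adjusted) are
    attached for each selected feature; Spearman correlations with CRS-R and
    GCS are attached where scores are available.  Columns with non-finite
    entries are never selected (H = 0, p = 1).
    """
    labels = np.asarray(table.labels)
    classes = sorted(set(table.labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = {c: int((labels == c).sum()) for c in classes}
    small = [c for c, n in counts.items() if n < 2]
    if small:
        raise ValueError(f"classes with < 2 subjects: {small}")

    nfeat = table.n_features
    h = np.zeros(nfeat)
    p = np.ones(nfeat)
    for j in range(nfeat):
        col = table.values[:, j]
        if not np.all(np.isfinite(col)):
            continue
        h[j], p[j] = kruskal_wallis([col[labels == c] for c in classes])
    selected = p < alpha

    res = SelectionResult(feature_names=list(table.feature_names), h=h, p=p,
                          selected=selected, alpha=alpha, group_labels=classes)
    pair_names = [f"p_{a}_vs_{b}" for a, b in itertools.combinations(classes, 2)]
    for j in np.flatnonzero(selected):
        name = table.feature_names[j]
        col = table.values[:, j]
        groups = [col[labels == c] for c in classes]
        if len(classes) >= 3:
            raw = dunn_posthoc(groups)
            adj = dunn_posthoc(groups, adjust="bonferroni")
            res.dunn_p[name] = {pair_names[k]: raw[pair]
                                for k, pair in enumerate(sorted(raw))}
            res.dunn_p_adj[name] = {pair_names[k]: adj[pair]
                                    for k, pair in enumerate(sorted(adj))}
        if table.crs_r is not None and np.all(np.isfinite(table.crs_r)):
            rho, pv = spearman_corr(col, table.crs_r)
            res.rho_crsr[name] = rho
            res.p_crsr[name] = pv
        if table.gcs is not None and np.all(np.isfinite(table.gcs)):
            rho, pv = spearman_corr(col, table.gcs)
            res.rho_gcs[name] = rho
            res.p_gcs[name] = pv
    return res
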