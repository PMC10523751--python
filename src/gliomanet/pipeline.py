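"""End-to-end orchestration of the two-stage analysis.

Stage 1 (networks): normality filter -> per-class nonparanormal transform
-> joint fused-graphical-lasso fits over a penalty grid -> edge tables,
hubs, components and the selected-feature list at a chosen penalty pair.
Stage 2 (clustering): z-score the selected submatrix (all classes pooled),
run robust sparse K-means over (K, L1) grids, score every combination and
cross-tabulate assignments against the diagnostic labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fgl import ClassDataset, lambda_grid_fit
from .networks import (NetworkSet, connected_components, extract_edges,
                       hub_genes, selected_features)
from .preprocess import normality_filter, npn_transform, zscore
from .rskc import RSKCConfig, rskc_fit
from .validation import (ValidationScores, adjusted_rand_index,
                         calinski_harabasz, cross_tabulate,
                         simplified_silhouette)

__all__ = ["CaseConfig", "build_case", "run_network_stage",
           "run_clustering_stage", "NetworkStageResult",
           "ClusteringStageResult"]


@dataclass
class CaseConfig:
    """One case study: class grouping plus the parameter grids to sweep."""

    label: str
    grouping: dict[str, list[str]]
    lambda1_grid: list[float] = field(default_factory=lambda: [0.5])
    lambda2_grid: list[float] = field(default_factory=lambda: [0.01])
    chosen_lambda: tuple[float, float] | None = None
    K_grid: list[int] = field(default_factory=lambda: [2, 3])
    L1_grid: list[float] = field(default_factory=lambda: [2.0])
    alpha: float = 0.1
    jb_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grouping) < 2:
            raise ValueError("need at least 2 groups")


def build_case(matrix: pd.DataFrame, labels: pd.Series,
               grouping: dict[str, list[str]]) -> ClassDataset:
    """Partition samples into D group matrices over the shared feature set."""
    labels = labels.reindex(matrix.index)
    if labels.isna().any():
        missing = list(matrix.index[labels.isna()])[:5]
        raise ValueError(f"samples without a label: {missing}")
    mapped: dict[str, str] = {}
    for group, classes in grouping.items():
        for c in classes:
            if c in mapped:
                raise ValueError(f"class {c!r} mapped to two groups")
            mapped[c] = group
    unknown = sorted(set(labels.unique()) - set(mapped))
    if unknown:
        raise ValueError(f"unmapped class label(s): {unknown}")
    matrices = []
    names = []
    for group in grouping:
        members = labels.index[labels.map(mapped) == group]
        matrices.append(matrix.loc[members])
        names.append(group)
    return ClassDataset(matrices=matrices, class_names=names)


@dataclass
class NetworkStageResult:
    grid_summary: pd.DataFrame
    network: NetworkSet
    selected: list[str]
    hubs: pd.DataFrame
    components: list[set[str]]
    chosen_lambda: tuple[float, float]
    n_features_after_filter: int


def run_network_stage(matrix: pd.DataFrame, labels: pd.Series,
                      case: CaseConfig) -> NetworkStageResult:
    """Normality filter, per-class npn, FGL grid, and network artifacts."""
    filtered, _report = normality_filter(matrix, alpha=case.jb_alpha)
    dataset = build_case(filtered, labels, case.grouping)
    dataset = ClassDataset(
        matrices=[npn_transform(m) for m in dataset.matrices],
        class_names=dataset.class_names,
    )
    fits, summary = lambda_grid_fit(dataset, case.lambda1_grid,
                                    case.lambda2_grid)
    chosen = case.chosen_lambda or (case.lambda1_grid[0], case.lambda2_grid[0])
    net = extract_edges(fits[chosen])
    selected = selected_features(net)  # raises EmptyNetworkError if empty
    hubs = hub_genes(net).to_frame()
    comps = connected_components(net, scope="union")
    return NetworkStageResult(
        grid_summary=summary, network=net, selected=selected, hubs=hubs,
        components=comps, chosen_lambda=chosen,
        n_features_after_filter=filtered.shape[1],
    )


@dataclass
class ClusteringStageResult:
    scores: pd.DataFrame
    assignments: dict[tuple[int, float], np.ndarray]
    contingencies: dict[tuple[int, float], pd.DataFrame]


def run_clustering_stage(matrix: pd.DataFrame, selected: list[str],
                         case: CaseConfig,
                         labels: pd.Series | None = None
                         ) -> ClusteringStageResult:
    """Z-score the selected submatrix and sweep the (K, L1) grid with RSKC."""
    if not selected:
        raise ValueError("empty feature selection")
    sub = zscore(matrix.loc[:, selected])
    Xs = sub.to_numpy()
    rows = []
    assignments: dict[tuple[int, float], np.ndarray] = {}
    contingencies: dict[tuple[int, float], pd.DataFrame] = {}
    for K in case.K_grid:
        for L1 in case.L1_grid:
            cfg = RSKCConfig(K=K, L1=min(L1, np.sqrt(len(selected))),
                             alpha=case.alpha, seed=case.seed)
            res = rskc_fit(sub, cfg)
            assignments[(K, L1)] = res.assignment
            ari = None
            if labels is not None:
                lab = labels.reindex(sub.index).to_numpy()
                ari = adjusted_rand_index(lab, res.assignment)
                contingencies[(K, L1)] = cross_tabulate(res.assignment, lab)
            sc = ValidationScores(
                silhouette=simplified_silhouette(Xs, res.assignment),
                calinski_harabasz=calinski_harabasz(Xs, res.assignment),
                ari=ari, K=K, n_samples=len(sub),
            )
            rows.append({"K": K, "L1": L1, **sc.to_dict(),
                         "n_outliers": len(res.outliers)})
    return ClusteringStageResult(
        scores=pd.DataFrame(rows), assignments=assignments,
        contingencies=contingencies,
    )
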