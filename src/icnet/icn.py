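"""Intra-individual covariance networks (ICN) and their graph-theory
analysis: per-respondent item similarity networks, proportional
thresholding over a sparsity grid, topology screening (connectedness,
small-worldness, modularity), rank-transformed betweenness centrality,
hub-item detection, and hub-symptom associations.

For respondent r and items a, b, let ``z_a = (x_a - M_a) / SD_a`` be the
item's deviation from the cohort mean in cohort-SD units. The ICN edge
weight is

    w_ab = exp(-(z_a - z_b)^2)  in (0, 1],

equal to 1 exactly when the two items deviate identically. A sparsity
level K keeps the ``round(K * p(p-1)/2)`` largest off-diagonal weights as
binary edges. The working K is the smallest grid value at which more than
95% of respondents simultaneously satisfy connectedness > 0.8,
small-worldness sigma > 1 and modularity Q > 0.3. Hubs are items whose
within-respondent betweenness rank is at or above a rank cut in more than
a prevalence cut of respondents (default: rank <= 4 in > 40%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import random

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _cc
from scipy.sparse.csgraph import shortest_path as _sp

from .survey import ANALYSIS_COLUMNS

__all__ = [
    "ScreenCriteria",
    "GraphScreen",
    "HubCriteria",
    "HUB_PRESET_RESULTS",
    "HUB_PRESET_FIGURE",
    "ICNModel",
    "ICNResults",
    "zscore_items",
    "icn_weights",
    "proportional_threshold",
    "graph_screen",
    "select_sparsity",
    "rank_betweenness",
    "identify_hubs",
    "centrality_association",
    "NoQualifyingSparsityError",
]

DEFAULT_K_GRID = tuple(np.round(np.arange(0.05, 0.2001, 0.01), 2))


class NoQualifyingSparsityError(RuntimeError):
    """No grid sparsity satisfied the screening criteria; carries the
    per-K pass-rate table."""

    def __init__(self, pass_rates: pd.DataFrame):
        self.pass_rates = pass_rates
        super().__init__(
            "no sparsity level passed the screen:\n" + pass_rates.to_string())


@dataclass(frozen=True)
class ScreenCriteria:
    """Topology screen: thresholds a respondent's graph must exceed.

    ``connectedness_mode`` chooses how "fraction of items connected" is
    read: ``"largest_component"`` (default) uses the share of nodes in the
    largest connected component; ``"non_isolated"`` uses the share of
    nodes with at least one edge (a laxer reading of the same criterion).
    """

    min_connectedness: float = 0.8
    min_sigma: float = 1.0
    min_modularity: float = 0.3
    participant_fraction: float = 0.95  # strict: > this fraction must pass
    connectedness_mode: str = "largest_component"


@dataclass(frozen=True)
class GraphScreen:
    connectedness: float
    sigma: float | None  # None when the null ensemble is degenerate
    modularity: float

    def passes(self, criteria: ScreenCriteria) -> bool:
        return (
            self.connectedness > criteria.min_connectedness
            and self.sigma is not None
            and self.sigma > criteria.min_sigma
            and self.modularity > criteria.min_modularity
        )


@dataclass(frozen=True)
class HubCriteria:
    """An item is a hub when its rank is <= rank_threshold in more than
    prevalence_threshold of respondents."""

    rank_threshold: int = 4
    prevalence_threshold: float = 0.40

    def __post_init__(self) -> None:
        if not 1 <= self.rank_threshold:
            raise ValueError("rank_threshold must be >= 1")
        if not 0.0 < self.prevalence_threshold <= 1.0:
            raise ValueError("prevalence_threshold must be in (0, 1]")


#: Hub preset from the study's results text: top 10% (rank <= 4), > 40%.
HUB_PRESET_RESULTS = HubCriteria(rank_threshold=4, prevalence_threshold=0.40)
#: Alternative preset from the figure caption: top 12% (rank <= 5), >= 25%.
HUB_PRESET_FIGURE = HubCriteria(rank_threshold=5, prevalence_threshold=0.25)


def zscore_items(cohort: pd.DataFrame,
                 items=ANALYSIS_COLUMNS) -> pd.DataFrame:
    """Standardize each item against cohort mean and SD (ddof=1)."""
    X = cohort[list(items)].to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if len(zero):
        names = [items[i] for i in zero]
        raise ValueError(f"constant items cannot be z-scored: {names}")
    return pd.DataFrame((X - mean) / sd, index=cohort.index, columns=list(items))


def icn_weights(z: np.ndarray) -> np.ndarray:
    """Similarity matrix w_ab = exp(-(z_a - z_b)^2) for one respondent."""
    z = np.asarray(z, dtype=float)
    if z.ndim != 1:
        raise ValueError("z must be a 1-d profile")
    diff = z[:, None] - z[None, :]
    return np.exp(-diff ** 2)


def _n_edges(p: int, k: float) -> int:
    n_pairs = p * (p - 1) // 2
    m = int(round(k * n_pairs))
    return m


def _threshold_adjacency(W: np.ndarray, k: float) -> np.ndarray:
    """Boolean adjacency of the top-K proportional threshold.

    Ties at the cut are broken by lexicographic node-pair order (stable
    sort on pair index after sorting by descending weight).
    """
    W = np.asarray(W, dtype=float)
    p = W.shape[0]
    if not 0.0 < k <= 1.0:
        raise ValueError(f"K must be in (0, 1], got {k}")
    m = _n_edges(p, k)
    if m == 0:
        raise ValueError(f"K={k} keeps zero edges on {p} nodes")
    iu, ju = np.triu_indices(p, 1)
    vals = W[iu, ju]
    # stable sort on descending weight keeps lexicographic pair order in ties
    order = np.argsort(-vals, kind="stable")[:m]
    A = np.zeros((p, p), dtype=bool)
    A[iu[order], ju[order]] = True
    return A | A.T


def proportional_threshold(weights: np.ndarray, k: float) -> nx.Graph:
    """Keep the top-K fraction of off-diagonal weights as binary edges.

    Ties at the cut are broken by lexicographic node-pair order.
    """
    A = _threshold_adjacency(np.asarray(weights, dtype=float), k)
    g = nx.Graph()
    g.add_nodes_from(range(A.shape[0]))
    g.add_edges_from(zip(*np.nonzero(np.triu(A))))
    return g


# --- fast adjacency-matrix graph metrics ---------------------------------

def _mean_clustering(A: np.ndarray) -> float:
    """Average clustering coefficient over all nodes (0 for degree < 2)."""
    Af = A.astype(float)
    triangles = np.einsum("ij,jk,ki->i", Af, Af, Af) / 2.0
    d = A.sum(axis=1)
    denom = d * (d - 1) / 2.0
    return float(np.where(denom > 0, triangles / np.maximum(denom, 1.0), 0.0).mean())


def _largest_component(A: np.ndarray) -> np.ndarray:
    _, labels = _cc(csr_matrix(A), directed=False)
    sizes = np.bincount(labels)
    return np.flatnonzero(labels == np.argmax(sizes))


def _path_length(A: np.ndarray) -> float:
    """Characteristic path length on the largest component."""
    idx = _largest_component(A)
    if len(idx) < 2:
        return float("nan")
    D = _sp(csr_matrix(A[np.ix_(idx, idx)]), method="D", unweighted=True)
    return float(D[np.triu_indices(len(idx), 1)].mean())


def _rewire(A: np.ndarray, rng: np.random.Generator,
            swap_factor: int = 10, try_factor: int = 100) -> np.ndarray:
    """Degree-preserving double-edge-swap null model."""
    p = A.shape[0]
    edges = [(int(u), int(v)) for u, v in np.argwhere(np.triu(A))]
    eset = set(edges)
    m = len(edges)
    target, max_tries = swap_factor * m, try_factor * m
    swaps = tries = 0
    while swaps < target and tries < max_tries:
        chunk = min(4 * m, max_tries - tries)
        picks = rng.integers(0, m, size=(chunk, 2)).tolist()
        flips = (rng.random(chunk) < 0.5).tolist()
        for (i, j), flip in zip(picks, flips):
            tries += 1
            if swaps >= target:
                break
            if i == j:
                continue
            u, v = edges[i]
            x, y = edges[j]
            if flip:
                x, y = y, x
            if u == x or u == y or v == x or v == y:
                continue
            e1 = (u, x) if u < x else (x, u)
            e2 = (v, y) if v < y else (y, v)
            if e1 in eset or e2 in eset:
                continue
            eset.discard(edges[i])
            eset.discard(edges[j])
            eset.add(e1)
            eset.add(e2)
            edges[i] = e1
            edges[j] = e2
            swaps += 1
    H = np.zeros((p, p), dtype=bool)
    iu = np.array([e[0] for e in edges])
    ju = np.array([e[1] for e in edges])
    H[iu, ju] = True
    return H | H.T


def _modularity(A: np.ndarray, rng: np.random.Generator,
                n_restarts: int = 5) -> float:
    """Best-of-restarts Louvain modularity (seeded)."""
    edges = [tuple(e) for e in np.argwhere(np.triu(A))]
    g = ig.Graph(n=A.shape[0], edges=edges)
    best = -1.0
    for _ in range(n_restarts):
        ig.set_random_number_generator(random.Random(int(rng.integers(2 ** 31))))
        best = max(best, g.community_multilevel().modularity)
    ig.set_random_number_generator(random)
    return float(best)


def _adjacency(g) -> np.ndarray:
    if isinstance(g, np.ndarray):
        return g.astype(bool)
    return nx.to_numpy_array(g, nodelist=sorted(g.nodes())).astype(bool)


def graph_screen(g, n_null: int = 20, seed: int = 0, n_restarts: int = 5,
                 connectedness_mode: str = "largest_component") -> GraphScreen:
    """Connectedness, small-worldness sigma, and modularity Q of a graph.

    sigma = (C / C_null) / (L / L_null) against degree-preserving rewired
    nulls (10 |E| swap attempts each); Q is the best of ``n_restarts``
    seeded Louvain runs. ``g`` may be a networkx graph or a boolean
    adjacency matrix.
    """
    A = _adjacency(g)
    n = A.shape[0]
    if A.sum() == 0:
        raise ValueError("graph has no edges")
    if connectedness_mode == "largest_component":
        connectedness = len(_largest_component(A)) / n
    elif connectedness_mode == "non_isolated":
        connectedness = float((A.sum(axis=1) > 0).mean())
    else:
        raise ValueError(f"unknown connectedness mode {connectedness_mode!r}")

    c_obs = _mean_clustering(A)
    l_obs = _path_length(A)

    rng = np.random.default_rng(seed)
    c_null, l_null = [], []
    for _ in range(n_null):
        H = _rewire(A, rng)
        c_null.append(_mean_clustering(H))
        l_null.append(_path_length(H))
    c_bar = float(np.mean(c_null))
    l_bar = float(np.nanmean(l_null))
    if c_bar == 0 or not np.isfinite(l_bar) or l_bar == 0 or not np.isfinite(l_obs):
        sigma = None
    else:
        sigma = (c_obs / c_bar) / (l_obs / l_bar)

    q = _modularity(A, rng, n_restarts=n_restarts)
    return GraphScreen(connectedness=float(connectedness), sigma=sigma,
                       modularity=q)


def select_sparsity(weight_matrices, k_grid=DEFAULT_K_GRID,
                    criteria: ScreenCriteria = ScreenCriteria(),
                    n_null: int = 20, seed: int = 0):
    """Smallest K at which more than ``participant_fraction`` of
    respondents pass all three screening criteria.

    Returns ``(k_star, pass_rates)`` where pass_rates is a per-K frame.
    Raises :class:`NoQualifyingSparsityError` (with the table) otherwise.
    """
    k_grid = sorted(float(k) for k in k_grid)
    rows = []
    k_star = None
    rng = np.random.default_rng(seed)
    seeds = {k: int(rng.integers(2 ** 31)) for k in k_grid}
    for k in k_grid:
        passed = 0
        total = 0
        sub_rng = np.random.default_rng(seeds[k])
        for W in weight_matrices:
            A = _threshold_adjacency(np.asarray(W, dtype=float), k)
            screen = graph_screen(A, n_null=n_null,
                                  seed=int(sub_rng.integers(2 ** 31)),
                                  connectedness_mode=criteria.connectedness_mode)
            passed += screen.passes(criteria)
            total += 1
        rate = passed / total
        rows.append({"K": k, "pass_rate": rate})
        if k_star is None and rate > criteria.participant_fraction:
            k_star = k
            break  # smallest qualifying K; no need to scan further
    pass_rates = pd.DataFrame(rows)
    if k_star is None:
        raise NoQualifyingSparsityError(pass_rates)
    return k_star, pass_rates


def rank_betweenness(g: nx.Graph) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalized betweenness per node and descending competition ranks.

    Rank 1 is the largest betweenness; ties share the minimum rank, so a
    "rank <= r" cut keeps its top-fraction meaning under ties.
    """
    bc = nx.betweenness_centrality(g, normalized=False)
    values = np.array([bc[v] for v in sorted(g.nodes())])
    ranks = np.array([1 + int((values > v).sum()) for v in values])
    return values, ranks


def identify_hubs(ranks: np.ndarray, items,
                  criteria: HubCriteria = HUB_PRESET_RESULTS) -> pd.DataFrame:
    """Items whose rank meets the cut in more than the required share of
    respondents, sorted by prevalence descending.

    ``ranks`` is (n_respondents, n_items); returns a frame with item,
    prevalence, and is_hub for every item (hubs first).
    """
    ranks = np.asarray(ranks)
    if ranks.ndim != 2 or ranks.shape[0] < 1:
        raise ValueError("ranks must be (n_respondents, n_items) with n >= 1")
    prevalence = (ranks <= criteria.rank_threshold).mean(axis=0)
    out = pd.DataFrame({
        "item": list(items),
        "prevalence": prevalence,
        "is_hub": prevalence > criteria.prevalence_threshold,
    })
    return out.sort_values(["is_hub", "prevalence", "item"],
                           ascending=[False, False, True],
                           kind="stable").reset_index(drop=True)


def centrality_association(ranks: np.ndarray, items, totals: pd.DataFrame,
                           pairs=None, rho_threshold: float = 0.3,
                           p_threshold: float = 0.001) -> pd.DataFrame:
    """Spearman correlation of each item's betweenness rank with each
    scale total; rows flagged when |rho| > rho_threshold and p below
    p_threshold.

    ``totals`` has one column per scale total aligned with ``ranks`` rows.
    ``pairs`` optionally restricts to (item, scale) pairs.
    """
    ranks = np.asarray(ranks)
    items = list(items)
    wanted = pairs if pairs is not None else [
        (it, sc) for it in items for sc in totals.columns]
    rows = []
    for item, scale in wanted:
        x = ranks[:, items.index(item)]
        y = totals[scale].to_numpy(dtype=float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            rows.append({"item": item, "scale": scale, "rho": np.nan,
                         "p_value": np.nan, "significant": False,
                         "degenerate": True})
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append({
            "item": item, "scale": scale, "rho": float(rho),
            "p_value": float(p),
            "significant": bool(abs(rho) > rho_threshold and p < p_threshold),
            "degenerate": False,
        })
    return pd.DataFrame(rows)


@dataclass
class ICNResults:
    """Fitted ICN analysis: selected sparsity, centrality ranks, hubs."""

    items: tuple[str, ...]
    k_selected: float
    pass_rates: pd.DataFrame
    betweenness: np.ndarray  # (n, p)
    ranks: np.ndarray        # (n, p)
    criteria: ScreenCriteria
    seed: int
    n_null: int
    _totals: pd.DataFrame | None = field(default=None, repr=False)

    def hubs(self, criteria: HubCriteria = HUB_PRESET_RESULTS) -> pd.DataFrame:
        return identify_hubs(self.ranks, self.items, criteria)

    def hub_items(self, criteria: HubCriteria = HUB_PRESET_RESULTS) -> tuple[str, ...]:
        table = self.hubs(criteria)
        return tuple(table.loc[table["is_hub"], "item"])

    def associations(self, totals: pd.DataFrame | None = None,
                     pairs=None) -> pd.DataFrame:
        totals = totals if totals is not None else self._totals
        if totals is None:
            raise ValueError("no scale totals supplied")
        return centrality_association(self.ranks, self.items, totals, pairs)

    def rank_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ranks, columns=list(self.items))

    def summary(self) -> pd.DataFrame:
        hubs = self.hubs()
        hubs.insert(0, "K", self.k_selected)
        return hubs

    def plot_rank_distribution(self, ax=None):
        """Violin plot of within-respondent betweenness ranks per item."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(12, 4))
        ax.violinplot([self.ranks[:, j] for j in range(len(self.items))],
                      showmedians=True)
        ax.set_xticks(range(1, len(self.items) + 1))
        ax.set_xticklabels(self.items, rotation=90, fontsize=6)
        ax.set_ylabel("betweenness rank (1 = most central)")
        ax.invert_yaxis()
        return ax


class ICNModel:
    """Intra-individual covariance network analysis of a cohort.

    Parameters
    ----------
    cohort : DataFrame
        Cohort frame with the analysis items as columns.
    items : sequence of str, optional
        Items forming the network nodes (default: the 43 analysis items).
    """

    def __init__(self, cohort: pd.DataFrame, items=ANALYSIS_COLUMNS):
        self.items = tuple(items)
        self.cohort = cohort
        self.z = zscore_items(cohort, self.items)
        self._weights = [icn_weights(z) for z in self.z.to_numpy()]

    def weight_matrices(self) -> list[np.ndarray]:
        return self._weights

    def edge_list(self, respondent: int, k: float | None = None) -> pd.DataFrame:
        """One respondent's network as a tidy edge list.

        With ``k`` set, only the edges surviving the proportional
        threshold are returned (still carrying their weights).
        """
        W = self._weights[respondent]
        iu, ju = np.triu_indices(W.shape[0], 1)
        keep = np.ones(len(iu), dtype=bool)
        if k is not None:
            A = _threshold_adjacency(W, k)
            keep = A[iu, ju]
        return pd.DataFrame({
            "item_a": [self.items[i] for i in iu[keep]],
            "item_b": [self.items[j] for j in ju[keep]],
            "weight": W[iu[keep], ju[keep]],
        })

    def fit(self, k: float | None = None, k_grid=DEFAULT_K_GRID,
            criteria: ScreenCriteria = ScreenCriteria(),
            n_null: int = 20, seed: int = 0,
            totals: pd.DataFrame | None = None) -> ICNResults:
        """Select the working sparsity (unless ``k`` is fixed), then
        compute per-respondent betweenness ranks at that sparsity."""
        if k is None:
            k_star, pass_rates = select_sparsity(
                self._weights, k_grid=k_grid, criteria=criteria,
                n_null=n_null, seed=seed)
        else:
            k_star, pass_rates = float(k), pd.DataFrame(
                [{"K": float(k), "pass_rate": np.nan}])
        bet = np.empty((len(self._weights), len(self.items)))
        ranks = np.empty_like(bet, dtype=int)
        for r, W in enumerate(self._weights):
            g = proportional_threshold(W, k_star)
            bet[r], ranks[r] = rank_betweenness(g)
        from .survey import COHORT_COLUMNS, score_cohort

        if totals is None and set(COHORT_COLUMNS).issubset(self.cohort.columns):
            scored = score_cohort(self.cohort)
            totals = scored[["pss_total", "gad7_total", "phq9_total"]]
        return ICNResults(
            items=self.items, k_selected=k_star, pass_rates=pass_rates,
            betweenness=bet, ranks=ranks, criteria=criteria, seed=seed,
            n_null=n_null, _totals=totals,
        )
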