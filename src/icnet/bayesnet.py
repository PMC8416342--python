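"""Discrete Bayesian-network structure learning: BIC-scored hill climbing
with nonparametric-bootstrap model averaging of edge presence and direction.

All survey items are treated as multinomial variables with level sets fixed
from the instrument codings (not from the data of any given bootstrap
resample). The network score is the decomposable BIC

    score(G) = sum_i [ loglik(X_i | parents_i) - (ln n / 2) * k_i ],

where ``k_i = (r_i - 1) * prod_j r_j`` free parameters for a node with
``r_i`` levels and parent level counts ``r_j``. Hill climbing greedily
applies the single-edge move (add / delete / reverse) with the largest
strictly positive score gain, skipping moves that would create a cycle,
with deterministic lexicographic tie-breaking.

Model averaging learns one structure per bootstrap resample and tabulates,
for each unordered pair, how often it is connected (presence strength) and,
when connected, how often each orientation occurs (direction strength).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "DiscreteDataset",
    "DAGStructure",
    "DAGResults",
    "AveragedDAG",
    "BayesianNetworkModel",
    "bic_score",
    "family_bic",
    "hill_climb",
    "bootstrap_average",
]


@dataclass(frozen=True)
class DiscreteDataset:
    """Integer-coded categorical data with fixed per-variable level counts."""

    codes: np.ndarray          # (n, p) ints in 0..levels[j]-1
    variables: tuple[str, ...]
    levels: tuple[int, ...]

    def __post_init__(self) -> None:
        codes = np.ascontiguousarray(self.codes, dtype=np.int64)
        object.__setattr__(self, "codes", codes)
        if codes.ndim != 2 or codes.shape[1] != len(self.variables):
            raise ValueError("codes must be n x p matching variables")
        if len(self.levels) != len(self.variables):
            raise ValueError("levels must match variables")
        for j, (v, r) in enumerate(zip(self.variables, self.levels)):
            col = codes[:, j]
            if col.min(initial=0) < 0 or col.max(initial=0) >= r:
                raise ValueError(f"{v}: codes outside 0..{r - 1}")

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def p(self) -> int:
        return self.codes.shape[1]

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, variables, levels=None,
                       offsets=None) -> "DiscreteDataset":
        """Code dataframe columns as 0-based integers.

        ``levels`` fixes level counts per variable; ``offsets`` maps raw
        values to codes by subtraction (e.g. attitude items coded -2..+2
        get offset -2). Defaults come from the survey item ranges.
        """
        from .survey import ITEM_RANGES

        variables = tuple(variables)
        if levels is None:
            levels = tuple(ITEM_RANGES[v][1] - ITEM_RANGES[v][0] + 1 for v in variables)
        if offsets is None:
            offsets = tuple(ITEM_RANGES[v][0] for v in variables)
        codes = np.column_stack([
            frame[v].to_numpy(dtype=np.int64) - off
            for v, off in zip(variables, offsets)
        ])
        return cls(codes, variables, tuple(levels))

    def resample(self, rng: np.random.Generator) -> "DiscreteDataset":
        idx = rng.integers(0, self.n, size=self.n)
        return DiscreteDataset(self.codes[idx], self.variables, self.levels)


@dataclass(frozen=True)
class DAGStructure:
    """Directed acyclic graph as a parent map over named nodes."""

    variables: tuple[str, ...]
    parents: tuple[tuple[int, ...], ...]  # parents[j] = sorted parent indices

    def __post_init__(self) -> None:
        if len(self.parents) != len(self.variables):
            raise ValueError("parents must match variables")
        for j, ps in enumerate(self.parents):
            if j in ps:
                raise ValueError(f"self-loop at {self.variables[j]}")
            if len(set(ps)) != len(ps):
                raise ValueError(f"duplicate parents at {self.variables[j]}")
        if not self.is_acyclic():
            raise ValueError("graph contains a cycle")

    @classmethod
    def empty(cls, variables) -> "DAGStructure":
        variables = tuple(variables)
        return cls(variables, tuple(() for _ in variables))

    @classmethod
    def from_edges(cls, variables, edges) -> "DAGStructure":
        variables = tuple(variables)
        index = {v: i for i, v in enumerate(variables)}
        parents = [set() for _ in variables]
        for a, b in edges:
            parents[index[b]].add(index[a])
        return cls(variables, tuple(tuple(sorted(ps)) for ps in parents))

    def edges(self) -> tuple[tuple[str, str], ...]:
        out = []
        for j, ps in enumerate(self.parents):
            for i in ps:
                out.append((self.variables[i], self.variables[j]))
        return tuple(sorted(out))

    def edge_index_set(self) -> frozenset[tuple[int, int]]:
        return frozenset((i, j) for j, ps in enumerate(self.parents) for i in ps)

    def skeleton(self) -> frozenset[frozenset]:
        return frozenset(frozenset((i, j)) for (i, j) in self.edge_index_set())

    def is_acyclic(self) -> bool:
        p = len(self.variables)
        indeg = [len(ps) for ps in self.parents]
        children = [[] for _ in range(p)]
        for j, ps in enumerate(self.parents):
            for i in ps:
                children[i].append(j)
        stack = [i for i in range(p) if indeg[i] == 0]
        seen = 0
        while stack:
            u = stack.pop()
            seen += 1
            for w in children[u]:
                indeg[w] -= 1
                if indeg[w] == 0:
                    stack.append(w)
        return seen == p


def family_bic(dataset: DiscreteDataset, node: int,
               parents: tuple[int, ...],
               max_parameters: int | None = 100_000) -> float:
    """BIC contribution of one node given its parent set."""
    r = dataset.levels[node]
    q = 1
    for pj in parents:
        q *= dataset.levels[pj]
    n_params = (r - 1) * q
    if max_parameters is not None and n_params > max_parameters:
        raise ValueError(
            f"family {dataset.variables[node]}: {n_params} parameters exceeds "
            f"cap {max_parameters}"
        )
    n = dataset.n
    child = dataset.codes[:, node]
    if parents:
        pcfg = np.zeros(n, dtype=np.int64)
        for pj in parents:
            pcfg = pcfg * dataset.levels[pj] + dataset.codes[:, pj]
        joint = pcfg * r + child
        njk = np.bincount(joint, minlength=q * r).reshape(q, r)
    else:
        njk = np.bincount(child, minlength=r).reshape(1, r)
    nj = njk.sum(axis=1, keepdims=True)
    mask = njk > 0
    ll = float((njk[mask] * np.log(njk[mask] / np.broadcast_to(nj, njk.shape)[mask])).sum())
    return ll - 0.5 * np.log(n) * n_params


def bic_score(dataset: DiscreteDataset, dag: DAGStructure,
              max_parameters: int | None = 100_000) -> float:
    """Decomposable BIC network score (higher is better)."""
    return sum(family_bic(dataset, j, dag.parents[j], max_parameters)
               for j in range(dataset.p))


class _ScoreCache:
    def __init__(self, dataset: DiscreteDataset, max_parameters):
        self.dataset = dataset
        self.max_parameters = max_parameters
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def __call__(self, node: int, parents: tuple[int, ...]) -> float:
        key = (node, parents)
        hit = self._cache.get(key)
        if hit is None:
            hit = family_bic(self.dataset, node, parents, self.max_parameters)
            self._cache[key] = hit
        return hit


def _reachable(children: list[set[int]], src: int, dst: int) -> bool:
    """True if dst is reachable from src along directed edges."""
    stack = [src]
    seen = {src}
    while stack:
        u = stack.pop()
        if u == dst:
            return True
        for w in children[u]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return False


def hill_climb(dataset: DiscreteDataset, max_parents: int | None = None,
               max_parameters: int | None = 100_000,
               eps: float = 1e-9) -> DAGStructure:
    """Greedy BIC hill climbing over add/delete/reverse single-edge moves.

    Fully deterministic: the move with the largest gain is applied, ties
    broken by the lexicographically smallest (operation, source, target).
    """
    p = dataset.p
    score = _ScoreCache(dataset, max_parameters)
    parents: list[tuple[int, ...]] = [() for _ in range(p)]
    children: list[set[int]] = [set() for _ in range(p)]
    fam = [score(j, ()) for j in range(p)]
    op_rank = {"add": 0, "delete": 1, "reverse": 2}

    def with_parent(ps, i):
        return tuple(sorted(ps + (i,)))

    def without_parent(ps, i):
        return tuple(x for x in ps if x != i)

    while True:
        best: tuple | None = None  # key (gain, -op, -i, -j), payload (op, i, j)

        def consider(gain, op, i, j):
            nonlocal best
            if gain <= eps:
                return
            key = (gain, -op, -i, -j)
            if best is None or key > best[0]:
                best = (key, (op, i, j))

        for i in range(p):
            for j in range(p):
                if i == j:
                    continue
                if i in parents[j]:
                    # delete i -> j
                    try:
                        consider(score(j, without_parent(parents[j], i)) - fam[j],
                                 op_rank["delete"], i, j)
                    except ValueError:
                        pass
                    # reverse i -> j (becomes j -> i)
                    if (max_parents is None or len(parents[i]) < max_parents) \
                            and not _reachable_without(children, parents, i, j):
                        try:
                            consider(
                                score(j, without_parent(parents[j], i)) - fam[j]
                                + score(i, with_parent(parents[i], j)) - fam[i],
                                op_rank["reverse"], i, j)
                        except ValueError:
                            pass
                elif j not in parents[i]:
                    # add i -> j
                    if max_parents is not None and len(parents[j]) >= max_parents:
                        continue
                    if _reachable(children, j, i):
                        continue  # would create a cycle
                    try:
                        consider(score(j, with_parent(parents[j], i)) - fam[j],
                                 op_rank["add"], i, j)
                    except ValueError:
                        pass
        if best is None:
            break
        _, (op, i, j) = best
        if op == op_rank["add"]:
            parents[j] = with_parent(parents[j], i)
            children[i].add(j)
        elif op == op_rank["delete"]:
            parents[j] = without_parent(parents[j], i)
            children[i].discard(j)
        else:  # reverse i -> j
            parents[j] = without_parent(parents[j], i)
            children[i].discard(j)
            parents[i] = with_parent(parents[i], j)
            children[j].add(i)
        fam = [score(k, tuple(parents[k])) for k in range(p)]
    return DAGStructure(dataset.variables, tuple(tuple(ps) for ps in parents))


def _reachable_without(children, parents, i, j):
    """Reachability i -> j ignoring the direct edge i -> j (reverse check)."""
    stack = list(children[i] - {j})
    seen = set(stack)
    while stack:
        u = stack.pop()
        if u == j:
            return True
        for w in children[u]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return False


@dataclass(frozen=True)
class AveragedDAG:
    """Bootstrap-averaged structure: per-pair presence and direction."""

    variables: tuple[str, ...]
    n_boot: int
    # counts[(i, j)] with i < j: (absent, i->j, j->i), summing to n_boot
    pair_counts: dict[tuple[int, int], tuple[int, int, int]]
    threshold: float
    final_edges: tuple[tuple[str, str], ...]
    dropped_for_acyclicity: tuple[tuple[str, str], ...] = ()

    def presence_strength(self, a: str, b: str) -> float:
        i, j = sorted((self.variables.index(a), self.variables.index(b)))
        absent, fwd, rev = self.pair_counts[(i, j)]
        return (fwd + rev) / self.n_boot

    def direction_strength(self, a: str, b: str) -> float:
        """Fraction of structures containing the pair oriented a -> b."""
        ia, ib = self.variables.index(a), self.variables.index(b)
        i, j = sorted((ia, ib))
        absent, fwd, rev = self.pair_counts[(i, j)]
        present = fwd + rev
        if present == 0:
            return 0.0
        return (fwd if (ia, ib) == (i, j) else rev) / present

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (i, j), (absent, fwd, rev) in sorted(self.pair_counts.items()):
            present = fwd + rev
            if present == 0:
                continue
            a, b = self.variables[i], self.variables[j]
            src, dst = (a, b) if fwd >= rev else (b, a)
            rows.append({
                "source": src, "target": dst,
                "presence_strength": present / self.n_boot,
                "direction_strength": max(fwd, rev) / present,
                "in_final": (src, dst) in self.final_edges,
            })
        return pd.DataFrame(
            rows, columns=["source", "target", "presence_strength",
                           "direction_strength", "in_final"])

    def to_dot(self) -> str:
        lines = ["digraph averaged {"]
        for a, b in self.final_edges:
            w = self.presence_strength(a, b)
            lines.append(f'  "{a}" -> "{b}" [label="{w:.2f}"];')
        lines.append("}")
        return "\n".join(lines)


def _finalize_edges(variables, pair_counts, n_boot, threshold):
    """Threshold presence, orient by majority, break cycles deterministically."""
    chosen = []
    for (i, j), (absent, fwd, rev) in sorted(pair_counts.items()):
        present = fwd + rev
        if present / n_boot < threshold:
            continue
        if fwd >= rev:  # deterministic tie: lexicographic orientation
            chosen.append((i, j, present / n_boot))
        else:
            chosen.append((j, i, present / n_boot))
    dropped = []
    while True:
        dag = _try_dag(variables, chosen)
        if dag is not None:
            break
        cycle = _find_cycle(len(variables), chosen)
        victim = min(
            (e for e in chosen if (e[0], e[1]) in cycle),
            key=lambda e: (e[2], e[0], e[1]),
        )
        chosen.remove(victim)
        dropped.append((variables[victim[0]], variables[victim[1]]))
    final = tuple(sorted((variables[a], variables[b]) for a, b, _ in chosen))
    return final, tuple(dropped)


def _try_dag(variables, chosen):
    try:
        return DAGStructure.from_edges(
            variables, [(variables[a], variables[b]) for a, b, _ in chosen])
    except ValueError:
        return None


def _find_cycle(p, chosen):
    """Return the edge set of one directed cycle (as ordered index pairs)."""
    adj = [[] for _ in range(p)]
    for a, b, _ in chosen:
        adj[a].append(b)
    color = [0] * p
    stack_path: list[int] = []

    def dfs(u):
        color[u] = 1
        stack_path.append(u)
        for w in adj[u]:
            if color[w] == 1:
                k = stack_path.index(w)
                cyc = stack_path[k:] + [w]
                return {(cyc[t], cyc[t + 1]) for t in range(len(cyc) - 1)}
            if color[w] == 0:
                found = dfs(w)
                if found:
                    return found
        color[u] = 2
        stack_path.pop()
        return None

    for s in range(p):
        if color[s] == 0:
            found = dfs(s)
            if found:
                return found
    raise RuntimeError("no cycle found")  # pragma: no cover


def bootstrap_average(dataset: DiscreteDataset, n_boot: int, seed: int,
                      threshold: float = 0.5, max_parents: int | None = None,
                      max_parameters: int | None = 100_000,
                      runtime_budget: int = 10_000) -> AveragedDAG:
    """Learn a structure per bootstrap resample and average edges.

    Replicate counts above ``runtime_budget`` are allowed but warned
    about, since a full-scale run takes on the order of CPU-hours.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if n_boot > runtime_budget:
        warnings.warn(
            f"n_boot={n_boot} exceeds the runtime budget of {runtime_budget} "
            "replicates; expect a long run", stacklevel=2)
    rng = np.random.default_rng(seed)
    p = dataset.p
    counts = {(i, j): [0, 0, 0] for i, j in combinations(range(p), 2)}
    for _ in range(n_boot):
        sample = dataset.resample(rng)
        dag = hill_climb(sample, max_parents=max_parents,
                         max_parameters=max_parameters)
        edges = dag.edge_index_set()
        for (i, j), c in counts.items():
            if (i, j) in edges:
                c[1] += 1
            elif (j, i) in edges:
                c[2] += 1
            else:
                c[0] += 1
    pair_counts = {k: tuple(v) for k, v in counts.items()}
    final, dropped = _finalize_edges(dataset.variables, pair_counts, n_boot,
                                     threshold)
    return AveragedDAG(dataset.variables, n_boot, pair_counts, threshold,
                       final, dropped)


def significance_threshold(strengths: np.ndarray) -> float:
    """Data-driven presence threshold: the strength level whose induced
    0/1 step function is closest (L1) to the empirical strength CDF.

    An alternative to the fixed 0.5 cut for keeping the "most consistent"
    edges when strengths separate into noise and signal clusters.
    """
    s = np.sort(np.asarray(strengths, dtype=float))
    if len(s) == 0:
        return 0.5
    candidates = np.unique(s)
    best_t, best_l1 = 0.5, np.inf
    ecdf = np.arange(1, len(s) + 1) / len(s)
    for t in candidates:
        # step CDF that jumps from P(strength < t) to 1 at t
        step_cdf = np.where(s < t, (s < t).mean(), 1.0)
        l1 = float(np.abs(ecdf - step_cdf).mean())
        if l1 < best_l1:
            best_l1, best_t = l1, float(t)
    return best_t


@dataclass(frozen=True)
class DAGResults:
    """A single learned structure and its score."""

    structure: DAGStructure
    score: float

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(self.structure.edges(), columns=["source", "target"])


class BayesianNetworkModel:
    """Structure-learning model over discrete survey items.

    Parameters
    ----------
    data : DataFrame
        Cohort frame (one row per respondent).
    variables : sequence of str, optional
        Columns to model; defaults to the 43 analysis items.
    max_parents, max_parameters
        Complexity guards on the search.
    """

    def __init__(self, data: pd.DataFrame, variables=None,
                 max_parents: int | None = None,
                 max_parameters: int | None = 100_000):
        from .survey import ANALYSIS_COLUMNS

        self.variables = tuple(variables) if variables is not None else ANALYSIS_COLUMNS
        self.dataset = DiscreteDataset.from_dataframe(data, self.variables)
        self.max_parents = max_parents
        self.max_parameters = max_parameters

    def fit(self) -> DAGResults:
        dag = hill_climb(self.dataset, max_parents=self.max_parents,
                         max_parameters=self.max_parameters)
        return DAGResults(dag, bic_score(self.dataset, dag, self.max_parameters))

    def fit_bootstrap(self, n_boot: int = 200, seed: int = 0,
                      threshold: float | str = 0.5) -> AveragedDAG:
        """Bootstrap model averaging; ``threshold`` may be 'auto' for the
        data-driven significance threshold."""
        if threshold == "auto":
            first = bootstrap_average(self.dataset, n_boot, seed, threshold=0.0,
                                      max_parents=self.max_parents,
                                      max_parameters=self.max_parameters)
            strengths = np.array([
                (fwd + rev) / n_boot
                for (_, (absent, fwd, rev)) in sorted(first.pair_counts.items())
            ])
            t = significance_threshold(strengths[strengths > 0])
            final, dropped = _finalize_edges(self.variables, first.pair_counts,
                                             n_boot, t)
            return AveragedDAG(self.variables, n_boot, first.pair_counts, t,
                               final, dropped)
        return bootstrap_average(self.dataset, n_boot, seed,
                                 threshold=float(threshold),
                                 max_parents=self.max_parents,
                                 max_parameters=self.max_parameters)
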