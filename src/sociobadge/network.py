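"""Contact matrices, profession heatmaps, sociograms, centrality and
core/periphery structure.

Network connectivity between staff is determined by the cumulative total
length of their active face-to-face interactions: a sociogram at duration
threshold ``t`` links two badges when their cumulative minutes reach ``t``.
Degree, eigenvector and betweenness centrality are computed on the binary
thresholded graph; core/periphery structure is fitted by maximizing the
Pearson correlation between the adjacency and an ideal core/periphery block
pattern (core–core dyads present, periphery–periphery dyads absent,
core–periphery dyads left out of the correlation).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .synthgen import DOCTOR_PROFESSIONS, PROFESSIONS, Roster

# ---------------------------------------------------------------------------
# Contact matrix and profession heatmap
# ---------------------------------------------------------------------------


@dataclass
class ContactMatrix:
    """Symmetric badge × badge matrix of cumulative active pair-minutes."""

    matrix: pd.DataFrame
    window: tuple[pd.Timestamp, pd.Timestamp] | None = None

    def __post_init__(self) -> None:
        m = self.matrix.values
        if not np.allclose(m, m.T):
            raise ValueError("contact matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("contact matrix must have a zero diagonal")
        if (m < 0).any():
            raise ValueError("contact matrix entries must be non-negative")

    @property
    def badges(self) -> list[str]:
        return list(self.matrix.index)


def contact_matrix(
    active: pd.DataFrame,
    roster: Roster,
    window: tuple[pd.Timestamp, pd.Timestamp] | None = None,
) -> ContactMatrix:
    """Accumulate active interaction minutes into a person × person matrix.

    ``window``, when given, keeps interactions whose start lies in
    ``[window[0], window[1])``. Interactions naming badges outside the
    roster are rejected.
    """
    badges = roster.badge_ids()
    idx = {b: i for i, b in enumerate(badges)}
    m = np.zeros((len(badges), len(badges)))
    if not active.empty:
        sel = active
        if window is not None:
            mask = (sel["start"] >= window[0]) & (sel["start"] < window[1])
            sel = sel[mask]
        for a, b, dur in zip(sel["badge_a"], sel["badge_b"], sel["duration_min"]):
            if a not in idx or b not in idx:
                raise ValueError(f"interaction references unknown badge: {a!r}/{b!r}")
            m[idx[a], idx[b]] += dur
            m[idx[b], idx[a]] += dur
    return ContactMatrix(pd.DataFrame(m, index=badges, columns=badges), window)


@dataclass
class ProfessionMatrix:
    """9 × 9 profession-pair cumulative minutes with a log display scale.

    ``values`` holds raw minutes per unordered profession pair (each badge
    pair counted once, or twice under the ``person_minutes`` unit);
    ``display`` is ``log10(value + 1)``; ``na_mask`` marks intra-profession
    cells of professions with fewer than two members, where a within-group
    interaction is impossible.
    """

    values: pd.DataFrame
    display: pd.DataFrame
    na_mask: pd.DataFrame
    unit: str = "pair_minutes"


def profession_heatmap(
    cm: ContactMatrix, roster: Roster, unit: str = "pair_minutes"
) -> ProfessionMatrix:
    """Aggregate a contact matrix into profession-pair cumulative minutes.

    Under ``pair_minutes`` each unordered badge pair contributes its minutes
    once to its profession-pair cell; ``person_minutes`` doubles every cell
    (minutes multiplied by the two people involved).
    """
    if unit not in ("pair_minutes", "person_minutes"):
        raise ValueError("unit must be 'pair_minutes' or 'person_minutes'")
    prof = roster.profession_of()
    missing = set(cm.badges) - set(prof)
    if missing:
        raise ValueError(f"matrix badges absent from roster: {sorted(missing)}")
    vals = pd.DataFrame(0.0, index=PROFESSIONS, columns=PROFESSIONS)
    badges = cm.badges
    m = cm.matrix.values
    for i, j in itertools.combinations(range(len(badges)), 2):
        if m[i, j] == 0:
            continue
        p, q = prof[badges[i]], prof[badges[j]]
        vals.loc[p, q] += m[i, j]
        if p != q:
            vals.loc[q, p] += m[i, j]
    if unit == "person_minutes":
        vals = vals * 2.0
    counts = roster.counts()
    na = pd.DataFrame(False, index=PROFESSIONS, columns=PROFESSIONS)
    for p in PROFESSIONS:
        if counts[p] < 2:
            na.loc[p, p] = True
    display = np.log10(vals + 1.0)
    display[na] = np.nan
    return ProfessionMatrix(vals, display, na, unit)


def daily_profession_totals(active: pd.DataFrame, roster: Roster) -> pd.DataFrame:
    """Per-day, per-profession total active minutes.

    Each interaction is credited once to each participating member, so an
    intra-profession interaction counts twice toward that profession.
    """
    prof = roster.profession_of()
    out: dict[tuple[str, str], float] = {}
    if not active.empty:
        days = active["start"].dt.strftime("%Y-%m-%d")
        for a, b, d, day in zip(
            active["badge_a"], active["badge_b"], active["duration_min"], days
        ):
            for badge in (a, b):
                key = (day, prof[badge])
                out[key] = out.get(key, 0.0) + d
    if not out:
        return pd.DataFrame(columns=list(PROFESSIONS))
    ser = pd.Series(out)
    table = ser.unstack(fill_value=0.0)
    return table.reindex(columns=PROFESSIONS, fill_value=0.0).sort_index()


# ---------------------------------------------------------------------------
# Sociogram
# ---------------------------------------------------------------------------


@dataclass
class Sociogram:
    """Undirected graph of badges linked above a cumulative-minutes threshold."""

    nodes: list[str]
    edges: dict[tuple[str, str], float]
    threshold_min: float = 0.0

    def __post_init__(self) -> None:
        nodeset = set(self.nodes)
        for (a, b) in self.edges:
            if a == b:
                raise ValueError("self-loop in sociogram")
            if a not in nodeset or b not in nodeset:
                raise ValueError(f"edge endpoint outside node set: ({a}, {b})")

    @property
    def n(self) -> int:
        return len(self.nodes)

    def adjacency(self) -> np.ndarray:
        idx = {v: i for i, v in enumerate(self.nodes)}
        a = np.zeros((self.n, self.n))
        for (u, v) in self.edges:
            a[idx[u], idx[v]] = a[idx[v], idx[u]] = 1.0
        return a

    def neighbors(self) -> dict[str, list[str]]:
        nb: dict[str, list[str]] = {v: [] for v in self.nodes}
        for (u, v) in self.edges:
            nb[u].append(v)
            nb[v].append(u)
        return {v: sorted(ns) for v, ns in nb.items()}

    def components(self) -> list[list[str]]:
        """Connected components, largest first (ties: smallest member id)."""
        nb = self.neighbors()
        seen: set[str] = set()
        comps: list[list[str]] = []
        for v in self.nodes:
            if v in seen:
                continue
            stack, comp = [v], []
            seen.add(v)
            while stack:
                u = stack.pop()
                comp.append(u)
                for w in nb[u]:
                    if w not in seen:
                        seen.add(w)
                        stack.append(w)
            comps.append(sorted(comp))
        return sorted(comps, key=lambda c: (-len(c), c[0]))

    def strength(self) -> pd.Series:
        """Sum of incident edge weights (cumulative minutes) per node."""
        s = pd.Series(0.0, index=self.nodes)
        for (u, v), w in self.edges.items():
            s[u] += w
            s[v] += w
        return s

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (u, v), w in self.edges.items():
            g.add_edge(u, v, weight_minutes=float(w))
        return g


def threshold_graph(cm: ContactMatrix, threshold_min: float) -> Sociogram:
    """Sociogram with an edge wherever cumulative minutes reach the threshold.

    The edge rule is inclusive (``minutes >= threshold``) but zero-minute
    pairs never link, so threshold 0 links exactly the positive entries.
    Isolated badges stay in the node set.
    """
    if threshold_min < 0:
        raise ValueError("threshold_min must be >= 0")
    badges = cm.badges
    m = cm.matrix.values
    edges: dict[tuple[str, str], float] = {}
    for i, j in itertools.combinations(range(len(badges)), 2):
        w = m[i, j]
        if w > 0 and w >= threshold_min:
            edges[(badges[i], badges[j])] = float(w)
    return Sociogram(list(badges), edges, threshold_min)


# ---------------------------------------------------------------------------
# Centrality
# ---------------------------------------------------------------------------


def degree_centrality(g: Sociogram) -> pd.DataFrame:
    """Raw degree and degree normalized by ``n - 1`` per node."""
    nb = g.neighbors()
    raw = pd.Series({v: float(len(ns)) for v, ns in nb.items()}, dtype=float)
    if g.n >= 2:
        norm = raw / (g.n - 1)
    else:
        norm = pd.Series(np.nan, index=raw.index)
    return pd.DataFrame({"degree": raw, "degree_norm": norm}).loc[g.nodes]


def eigenvector_centrality(
    g: Sociogram, tol: float = 1e-10, max_iter: int = 1000
) -> tuple[pd.Series, bool]:
    """Leading-eigenvector scores by power iteration on the largest component.

    Iteration runs on ``A + I`` (the shift leaves the leading eigenvector
    unchanged but makes its eigenvalue strictly dominant, so bipartite
    components cannot oscillate), starting from a uniform positive vector and
    renormalizing to unit Euclidean norm each step, until successive iterates
    agree within ``tol`` in max-norm. Nodes outside the largest connected
    component score 0; the returned flag is False when ``max_iter`` was hit
    first.
    """
    if not g.edges:
        raise ValueError(
            "eigenvector centrality is undefined on an edgeless graph: "
            "there is no leading eigenvector to converge to"
        )
    comp = g.components()[0]
    sub_idx = {v: i for i, v in enumerate(comp)}
    a = np.zeros((len(comp), len(comp)))
    for (u, v) in g.edges:
        if u in sub_idx and v in sub_idx:
            a[sub_idx[u], sub_idx[v]] = a[sub_idx[v], sub_idx[u]] = 1.0
    x = np.full(len(comp), 1.0 / np.sqrt(len(comp)))
    converged = False
    for _ in range(max_iter):
        y = a @ x + x  # shifted iteration: (A + I) x
        norm = np.linalg.norm(y)
        if norm == 0:  # unreachable for a connected component with an edge
            break
        y /= norm
        if np.max(np.abs(y - x)) < tol:
            x = y
            converged = True
            break
        x = y
    scores = pd.Series(0.0, index=g.nodes)
    scores[comp] = np.abs(x)
    return scores, converged


def betweenness_centrality(g: Sociogram) -> pd.DataFrame:
    """Unweighted shortest-path betweenness (Brandes accumulation).

    Returns raw pair counts and values normalized by ``(n-1)(n-2)/2``.
    Pairs in different components contribute nothing.
    """
    nb = g.neighbors()
    bc = {v: 0.0 for v in g.nodes}
    for s in g.nodes:
        stack: list[str] = []
        pred: dict[str, list[str]] = {v: [] for v in g.nodes}
        sigma = {v: 0.0 for v in g.nodes}
        dist = {v: -1 for v in g.nodes}
        sigma[s] = 1.0
        dist[s] = 0
        queue = [s]
        head = 0
        while head < len(queue):
            v = queue[head]
            head += 1
            stack.append(v)
            for w in nb[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        delta = {v: 0.0 for v in g.nodes}
        while stack:
            w = stack.pop()
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
        # each undirected pair is counted from both endpoints
    raw = pd.Series(bc, dtype=float).loc[g.nodes] / 2.0
    n = g.n
    denom = (n - 1) * (n - 2) / 2.0
    norm = raw / denom if denom > 0 else pd.Series(np.nan, index=raw.index)
    return pd.DataFrame({"betweenness": raw, "betweenness_norm": norm})


# ---------------------------------------------------------------------------
# Core/periphery
# ---------------------------------------------------------------------------


@dataclass
class CorePeripheryFit:
    """Binary core labels with the correlation of adjacency to the ideal."""

    core: pd.Series  # bool per node
    score: float  # Pearson r; NaN when undefined
    degenerate: bool
    method: str


def _cp_score(adj: np.ndarray, core: np.ndarray) -> float:
    """Pearson r between adjacency and the ideal pattern over evaluated dyads.

    Evaluated dyads are core–core (ideal 1) and periphery–periphery
    (ideal 0); core–periphery dyads are excluded. NaN when either vector is
    constant over the evaluated dyads.
    """
    c = core.astype(bool)
    n1 = int(c.sum())
    n0 = int((~c).sum())
    ncc = n1 * (n1 - 1) // 2
    npp = n0 * (n0 - 1) // 2
    n = ncc + npp
    if ncc == 0 or npp == 0:
        return np.nan  # ideal vector constant
    s1 = float(c @ adj @ c) / 2.0
    s0 = float((~c) @ adj @ (~c)) / 2.0
    sy = s1 + s0
    var_x = n * ncc - ncc * ncc
    var_y = n * sy - sy * sy
    if var_x <= 0 or var_y <= 0:
        return np.nan
    return (n * s1 - ncc * sy) / np.sqrt(var_x * var_y)


def core_periphery_fit(
    g: Sociogram, n_restarts: int = 20, seed: int = 0, method: str = "auto"
) -> CorePeripheryFit:
    """Best-correlation core/periphery partition of a sociogram.

    Exhaustive over all labelings for up to 15 nodes; otherwise greedy
    steepest-ascent single-label swaps from ``n_restarts`` seeded random
    starts (``method`` forces one strategy). Deterministic given ``seed``.
    When no labeling yields a defined correlation (or the best one is a
    trivial split) the result carries a degeneracy flag.
    """
    if g.n < 3:
        raise ValueError("core/periphery fit needs at least 3 nodes")
    if not g.edges:
        raise ValueError("core/periphery fit needs at least one edge")
    if method not in ("auto", "exhaustive", "greedy"):
        raise ValueError("method must be 'auto', 'exhaustive' or 'greedy'")
    adj = g.adjacency()
    n = g.n
    if method == "auto":
        method = "exhaustive" if n <= 15 else "greedy"
    if method == "exhaustive" and n > 20:
        raise ValueError("exhaustive search is limited to 20 nodes")

    best_score = -np.inf
    best_core: np.ndarray | None = None
    if method == "exhaustive":
        for bits in range(1, 2**n - 1):
            core = np.array(
                [(bits >> i) & 1 for i in range(n)], dtype=bool
            )
            s = _cp_score(adj, core)
            if not np.isnan(s) and (
                s > best_score
                or (s == best_score and best_core is not None
                    and core.sum() > best_core.sum())
            ):
                best_score = s
                best_core = core
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            core = rng.uniform(size=n) < 0.5
            current = _cp_score(adj, core)
            if np.isnan(current):
                current = -np.inf
            improved = True
            while improved:
                improved = False
                flip_best = -np.inf
                flip_idx = -1
                for i in range(n):
                    core[i] = ~core[i]
                    s = _cp_score(adj, core)
                    core[i] = ~core[i]
                    if not np.isnan(s) and s > flip_best:
                        flip_best = s
                        flip_idx = i
                if flip_idx >= 0 and flip_best > current + 1e-12:
                    core[flip_idx] = ~core[flip_idx]
                    current = flip_best
                    improved = True
            if current > best_score:
                best_score = current
                best_core = core.copy()

    if best_core is None:
        # no labeling had a defined correlation; fall back to a degree split
        deg = adj.sum(axis=1)
        best_core = deg >= np.median(deg)
        return CorePeripheryFit(
            pd.Series(best_core, index=g.nodes), np.nan, True, method
        )
    degenerate = bool(best_core.all() or (~best_core).all())
    return CorePeripheryFit(
        pd.Series(best_core, index=g.nodes), float(best_score), degenerate, method
    )


# ---------------------------------------------------------------------------
# Centrality report
# ---------------------------------------------------------------------------


@dataclass
class CentralityReport:
    """Per-node centrality bundle plus per-profession rank summaries."""

    table: pd.DataFrame
    profession_summary: pd.DataFrame
    eigenvector_converged: bool = True


def _top_k(strength: pd.Series, badges: list[str], k: int = 3) -> list[str]:
    sub = strength[strength.index.isin(badges)]
    ordered = sorted(sub.items(), key=lambda kv: (-kv[1], kv[0]))
    return [b for b, _ in ordered[:k]]


def centrality_report(g: Sociogram, roster: Roster) -> CentralityReport:
    """All three centrality measures with profession context.

    Flags the top-3 most-interactive doctors and nurses (by cumulative
    minutes at this threshold, ties broken by badge id) and summarizes the
    median centrality rank per profession (rank 1 = most central; ties get
    average ranks).
    """
    prof = roster.profession_of()
    missing = set(g.nodes) - set(prof)
    if missing:
        raise ValueError(f"graph nodes absent from roster: {sorted(missing)}")
    deg = degree_centrality(g)
    if g.edges:
        eig, converged = eigenvector_centrality(g)
    else:
        eig = pd.Series(0.0, index=g.nodes)
        converged = True
    btw = betweenness_centrality(g)
    comp_id = pd.Series(0, index=g.nodes)
    for ci, comp in enumerate(g.components()):
        comp_id[comp] = ci
    strength = g.strength()
    doctors = [b for b in g.nodes if prof[b] in DOCTOR_PROFESSIONS]
    nurses = [b for b in g.nodes if prof[b] == "nurse"]
    top_docs = set(_top_k(strength, doctors))
    top_nurses = set(_top_k(strength, nurses))
    table = pd.DataFrame(
        {
            "profession": pd.Series({v: prof[v] for v in g.nodes}),
            "degree": deg["degree"],
            "degree_norm": deg["degree_norm"],
            "eigenvector": eig,
            "betweenness": btw["betweenness"],
            "betweenness_norm": btw["betweenness_norm"],
            "strength_min": strength,
            "component": comp_id,
            "top3_doctor": pd.Series({v: v in top_docs for v in g.nodes}),
            "top3_nurse": pd.Series({v: v in top_nurses for v in g.nodes}),
        }
    ).loc[g.nodes]
    ranks = {}
    for measure in ("degree", "eigenvector", "betweenness"):
        ranks[measure] = rankdata(-table[measure].values, method="average")
    rank_df = pd.DataFrame(ranks, index=table.index)
    rank_df["profession"] = table["profession"]
    summary = rank_df.groupby("profession").median()
    summary = summary.rename(
        columns={m: f"median_rank_{m}" for m in ("degree", "eigenvector", "betweenness")}
    )
    return CentralityReport(table, summary, converged)


def export_sociogram_graphml(
    g: Sociogram,
    report: CentralityReport,
    cp: CorePeripheryFit | None,
    path,
) -> None:
    """Write the sociogram with node centrality/core attributes as GraphML."""
    import networkx as nx

    nxg = g.to_networkx()
    for v in g.nodes:
        row = report.table.loc[v]
        nxg.nodes[v]["profession"] = str(row["profession"])
        nxg.nodes[v]["degree"] = float(row["degree"])
        nxg.nodes[v]["eigenvector"] = float(row["eigenvector"])
        nxg.nodes[v]["betweenness"] = float(row["betweenness"])
        nxg.nodes[v]["core"] = bool(cp.core[v]) if cp is not None else False
    nx.write_graphml(nxg, path)
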