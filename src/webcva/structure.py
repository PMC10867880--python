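"""Group structure of the web: Coleman homophily, 3-node motif censuses
(apparent competition and tri-trophic chains), driving-position tallies, and
Erdős–Rényi null-model comparisons with z-scores and p-values.

Homophily asks whether a group's links stay within the group more (or less)
than expected from its share of nodes. On the raw web, links run consumer →
resource and the index reads top-down; inverting the links first gives the
bottom-up view relevant to secondary-extinction structure.

The two motifs are the top-down risk positions: in an *apparent competition*
motif one predator consumes two prey that do not consume each other (the
prey are the driving positions — losing one can redirect predation onto the
other); in a *tri-trophic chain* an apex consumes an intermediate which
consumes a basal resource, with no direct apex → basal link (the apex is the
driving position — losing it releases the intermediate). Observed
driving-position counts per group are compared to uniform random directed
graphs with the same node and edge counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from webcva.core import FoodWeb, Group, invert_links

__all__ = [
    "coleman_homophily",
    "MotifCensus",
    "census_apparent_competition",
    "census_tritrophic",
    "driving_position_tally",
    "erdos_renyi_null",
    "motif_zscores",
    "TALLY_CELLS",
]

TALLY_CELLS = ("ac_one", "ac_both", "tt_apex")


# ---------------------------------------------------------------------------
# Coleman homophily
# ---------------------------------------------------------------------------


def coleman_homophily(web: FoodWeb, invert: bool = False) -> pd.DataFrame:
    """Coleman homophily index per group.

    For group g with n_g of N nodes, w_g is the fraction of g's out-links
    that stay within g and p_g = n_g/N its expected share; then

        H_g = (w_g − p_g) / (1 − p_g)   if w_g ≥ p_g
        H_g = (w_g − p_g) / p_g         otherwise,

    so H = 1 when all out-links are within-group, −1 when none are, and 0 at
    the group-size expectation. Groups with no out-links report NaN. With
    ``invert=True`` edges are reversed first (resource → consumer), giving
    the bottom-up reading.
    """
    if len(web) == 0:
        raise ValueError("empty web")
    if invert:
        web = invert_links(web)
    n_total = len(web)
    rows = {}
    for g in Group:
        members = set(web.group_members(g))
        if not members:
            continue
        out_links = within = 0
        for u in members:
            for v in web.resources_of(u):
                out_links += 1
                if v in members:
                    within += 1
        p = len(members) / n_total
        if out_links == 0:
            w = h = np.nan
        elif p == 1.0:
            # the group spans the whole web: no between-group link is
            # possible and the index is undefined
            w, h = within / out_links, np.nan
        else:
            w = within / out_links
            h = (w - p) / (1 - p) if w >= p else (w - p) / p
        rows[g.value] = {
            "n": len(members),
            "out_links": out_links,
            "within": within,
            "w": w,
            "p": p,
            "H": h,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Motif censuses
# ---------------------------------------------------------------------------


@dataclass
class MotifCensus:
    """Enumerated occurrences of one motif kind.

    For ``apparent_competition`` each occurrence is (predator, preyA, preyB)
    with the unordered prey pair stored sorted (counted once); for
    ``tri_trophic`` each occurrence is the ordered (apex, intermediate,
    basal) triple.
    """

    kind: str
    occurrences: list[tuple[str, str, str]]

    @property
    def count(self) -> int:
        return len(self.occurrences)


def census_apparent_competition(web: FoodWeb, induced: bool = True) -> MotifCensus:
    """All (predator, {preyA, preyB}) occurrences of apparent competition.

    With ``induced=True`` (default) a prey pair linked by a consumption edge
    in either direction is excluded — the motif must appear as an induced
    subgraph, consistent with the tri-trophic exclusion rule.
    """
    occ: list[tuple[str, str, str]] = []
    for p in web.ids:
        prey = sorted(web.resources_of(p))
        for a_i in range(len(prey)):
            for b_i in range(a_i + 1, len(prey)):
                a, b = prey[a_i], prey[b_i]
                if induced and (
                    b in web.resources_of(a) or a in web.resources_of(b)
                ):
                    continue
                occ.append((p, a, b))
    return MotifCensus("apparent_competition", occ)


def census_tritrophic(web: FoodWeb) -> MotifCensus:
    """All ordered (apex, intermediate, basal) tri-trophic chains.

    Requires apex → intermediate and intermediate → basal with *no*
    apex → basal edge (chains where the apex also depredates the basal
    resource are excluded), and three distinct nodes.
    """
    occ: list[tuple[str, str, str]] = []
    for apex in web.ids:
        apex_res = web.resources_of(apex)
        for mid in sorted(apex_res):
            for basal in sorted(web.resources_of(mid)):
                if basal == apex or basal in apex_res:
                    continue
                occ.append((apex, mid, basal))
    return MotifCensus("tri_trophic", occ)


def driving_position_tally(
    web: FoodWeb,
    *censuses: MotifCensus,
) -> pd.DataFrame:
    """Per-group counts of motifs with the group in a driving position.

    Columns: ``ac_one`` (apparent competition with exactly one prey in the
    group), ``ac_both`` (both prey in the group), ``tt_apex`` (tri-trophic
    with the group's member as apex). The one-prey and both-prey cells are
    disjoint by construction. Rows cover every group present in the web.
    """
    groups = [g.value for g in Group if web.group_members(g)]
    tally = pd.DataFrame(0, index=groups, columns=list(TALLY_CELLS))
    for census in censuses:
        if census.kind == "apparent_competition":
            for _, a, b in census.occurrences:
                ga, gb = web.group_of(a).value, web.group_of(b).value
                if ga == gb:
                    tally.loc[ga, "ac_both"] += 1
                else:
                    tally.loc[ga, "ac_one"] += 1
                    tally.loc[gb, "ac_one"] += 1
        elif census.kind == "tri_trophic":
            for apex, _, _ in census.occurrences:
                tally.loc[web.group_of(apex).value, "tt_apex"] += 1
        else:
            raise ValueError(f"unknown motif kind {census.kind!r}")
    return tally


# -- fast tally path (used for null ensembles; equals census + tally) -------


def _tally_arrays(
    a: np.ndarray, group_codes: np.ndarray, n_groups: int, induced: bool = True
) -> np.ndarray:
    """Driving-position tallies from a boolean adjacency matrix.

    Returns an (n_groups × 3) array of [ac_one, ac_both, tt_apex] counts.
    Equivalent to the enumeration censuses; vectorized for null ensembles.
    """
    out = np.zeros((n_groups, 3), dtype=np.int64)
    sym = a | a.T
    ai = a.astype(np.int64)
    a2 = ai @ ai
    # tri-trophic: 2-paths from each apex minus those closed by apex→basal,
    # minus 2-cycles back to the apex itself
    tt = a2.sum(axis=1) - np.einsum("ij,ij->i", a2, ai) - np.diag(a2)
    np.add.at(out[:, 2], group_codes, tt)
    # apparent competition per predator
    for p in range(a.shape[0]):
        prey = np.nonzero(a[p])[0]
        d = prey.size
        if d < 2:
            continue
        gg = group_codes[prey]
        cnt = np.bincount(gg, minlength=n_groups)
        both = cnt * (cnt - 1) // 2
        one = cnt * (d - cnt)
        if induced:
            iu, ju = np.triu_indices(d, 1)
            linked = sym[np.ix_(prey, prey)][iu, ju]
            if linked.any():
                ga, gb = gg[iu[linked]], gg[ju[linked]]
                same = ga == gb
                both -= np.bincount(ga[same], minlength=n_groups)
                one -= np.bincount(ga[~same], minlength=n_groups)
                one -= np.bincount(gb[~same], minlength=n_groups)
        out[:, 1] += both
        out[:, 0] += one
    return out


def _web_tally_fast(web: FoodWeb, induced: bool = True) -> pd.DataFrame:
    groups = [g.value for g in Group if web.group_members(g)]
    gmap = {g: k for k, g in enumerate(groups)}
    codes = np.array([gmap[web.group_of(i).value] for i in web.ids])
    arr = _tally_arrays(web.adjacency_matrix(), codes, len(groups), induced)
    return pd.DataFrame(arr, index=groups, columns=list(TALLY_CELLS))


# ---------------------------------------------------------------------------
# Null models and z-scores
# ---------------------------------------------------------------------------


def erdos_renyi_null(web: FoodWeb, seed: int, model: str = "gnm") -> FoodWeb:
    """A random directed web with the same nodes (groups in place) and edges.

    ``model='gnm'`` (default) draws exactly ``n_edges`` distinct directed
    non-self edges uniformly; ``'gnp'`` draws each possible edge
    independently with p = m / (n(n−1)), matching the edge count only in
    expectation.
    """
    ids = web.ids
    n, m = len(ids), web.n_edges
    if model == "gnm":
        g = nx.gnm_random_graph(n, m, seed=int(seed), directed=True)
    elif model == "gnp":
        p = m / (n * (n - 1)) if n > 1 else 0.0
        g = nx.fast_gnp_random_graph(n, p, seed=int(seed), directed=True)
    else:
        raise ValueError(f"unknown null model {model!r}")
    edges = [(ids[u], ids[v]) for u, v in g.edges()]
    return FoodWeb(web.nodes.values(), edges)


def motif_zscores(
    web: FoodWeb,
    n_null: int = 100,
    seed: int = 0,
    *,
    induced: bool = True,
    null_model: str = "gnm",
    p_method: str = "normal",
) -> pd.DataFrame:
    """Driving-position tallies vs an Erdős–Rényi null ensemble.

    Returns a tidy DataFrame with one row per (group, cell): observed count,
    null mean and sd (ddof=1), z = (obs − μ)/σ, and a one-tailed p-value —
    normal-approximation by default (``p_method='normal'``), or the
    empirical rank p = (r + 1)/(n_null + 1) with ``'empirical'``, where r is
    the number of null tallies at least as extreme in the observed
    direction. Under-representation relative to the null yields z < 0. A
    degenerate cell (σ = 0) is flagged and reports NaN for z and p rather
    than a silent zero.
    """
    if n_null < 2:
        raise ValueError("need at least 2 null replicates")
    obs = _web_tally_fast(web, induced=induced)
    groups = list(obs.index)
    gmap = {g: k for k, g in enumerate(groups)}
    codes = np.array([gmap[web.group_of(i).value] for i in web.ids])
    null = np.zeros((n_null, len(groups), 3), dtype=np.int64)
    root = np.random.SeedSequence(seed)
    child_seeds = root.generate_state(n_null)
    for k in range(n_null):
        nweb = erdos_renyi_null(web, seed=int(child_seeds[k]), model=null_model)
        null[k] = _tally_arrays(
            nweb.adjacency_matrix(), codes, len(groups), induced
        )
    mu = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    rows = []
    for gi, g in enumerate(groups):
        for ci, cell in enumerate(TALLY_CELLS):
            o = int(obs.loc[g, cell])
            m_, s_ = mu[gi, ci], sd[gi, ci]
            degenerate = s_ == 0
            z = (o - m_) / s_ if not degenerate else np.nan
            if degenerate:
                p = np.nan
            elif p_method == "normal":
                p = float(stats.norm.sf(abs(z)))
            elif p_method == "empirical":
                samples = null[:, gi, ci]
                if o >= m_:
                    r = int((samples >= o).sum())
                else:
                    r = int((samples <= o).sum())
                p = (r + 1) / (n_null + 1)
            else:
                raise ValueError(f"unknown p_method {p_method!r}")
            rows.append(
                {
                    "group": g,
                    "cell": cell,
                    "observed": o,
                    "null_mean": m_,
                    "null_sd": s_,
                    "z": z,
                    "p": p,
                    "degenerate": degenerate,
                }
            )
    return pd.DataFrame(rows)
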