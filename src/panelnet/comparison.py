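"""Permutation comparison of network edges between groups and timepoints.

The comparison statistic is the absolute edge difference (AED),
``|w_A - w_B|`` for every edge, between two independently estimated
networks.  The null distribution is generated by permuting group labels
over persons (whole persons travel together, preserving within-person
dependence) and re-estimating both networks per permutation with exactly
the estimator used for the observed networks.  P-values use the add-one
rule, ``p = (1 + #{perm >= obs}) / (1 + n_perm)``, so ``p >= 1/(n_perm+1)``
and the test is valid at any finite number of permutations.  An omnibus
statistic (the maximum AED over edges) gets its own permutation p-value.

For the longitudinal (panel GVAR) comparison the statistic is the
difference of pruned edge estimates; an edge pruned from a network
contributes 0, mirroring the "not included in network" reporting
convention.  The cross-timepoint test permutes wave labels within person
(paired permutation) -- an approximation under temporal dependence,
documented as this package's own reconstruction of an unspecified
procedure.

Holm step-down adjustment is offered alongside raw p-values; stars follow
the ^ <.10, * <.05, ** <.01, *** <.001 convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import ggm as _ggm
from . import gvar as _gvar

__all__ = [
    "EdgeComparison",
    "edge_differences",
    "nct_edges",
    "nct_waves",
    "permutation_edge_test_longitudinal",
    "holm_adjust",
    "stars",
]


@dataclass
class EdgeComparison:
    kind: str                   # cross_sectional | temporal | contemporaneous | between
    edge: tuple
    contrast: tuple             # groups or waves compared
    est_a: float
    est_b: float
    aed: float
    p: float
    n_perm: int
    seed: int
    p_holm: float = np.nan

    @property
    def stars(self) -> str:
        return stars(self.p)


def stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.10:
        return "^"
    return ""


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, >= raw, capped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="holm")[1]


def edge_differences(net_a, net_b) -> np.ndarray:
    """Entrywise absolute edge differences between two networks."""
    if list(net_a.nodes) != list(net_b.nodes):
        extra = set(net_a.nodes) ^ set(net_b.nodes)
        raise ValueError(
            f"node sets differ or are ordered differently: {sorted(extra) or net_a.nodes}")
    return np.abs(net_a.edges - net_b.edges)


def _addone(count: int, n_perm: int) -> float:
    return (1 + count) / (1 + n_perm)


def _estimate(data, estimator: dict) -> _ggm.GGMNetwork:
    return _ggm.estimate_ggm(data, **estimator)


def nct_edges(data_a: pd.DataFrame, data_b: pd.DataFrame,
              estimator: dict | None = None, n_perm: int = 1000,
              seed: int = 0) -> dict:
    """Network comparison test between two groups of persons.

    ``data_a`` / ``data_b``: rows = persons, columns = nodes (identical in
    both).  Returns per-edge :class:`EdgeComparison` objects plus the
    max-AED omnibus test.
    """
    if list(data_a.columns) != list(data_b.columns):
        raise ValueError("both samples must share the same node columns")
    estimator = dict(estimator or {})
    rng = np.random.default_rng(seed)
    net_a = _estimate(data_a, estimator)
    net_b = _estimate(data_b, estimator)
    obs = edge_differences(net_a, net_b)
    nodes = net_a.nodes
    p = len(nodes)
    iu = np.triu_indices(p, 1)
    pooled = pd.concat([data_a, data_b], ignore_index=True)
    na = len(data_a)
    counts = np.zeros(len(iu[0]))
    max_count = 0
    obs_max = float(obs[iu].max())
    failures = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pooled))
        try:
            pa = _estimate(pooled.iloc[perm[:na]], estimator)
            pb = _estimate(pooled.iloc[perm[na:]], estimator)
        except _ggm.GGMError:
            failures += 1
            if failures > 0.05 * n_perm:
                raise RuntimeError(
                    f"estimator failed in more than 5% of permutations "
                    f"({failures} failures)")
            continue
        d = np.abs(pa.edges - pb.edges)[iu]
        counts += d >= obs[iu] - 1e-15
        if d.max() >= obs_max - 1e-15:
            max_count += 1
    eff = n_perm - failures
    edges_out = []
    raw = []
    for k, (i, j) in enumerate(zip(*iu)):
        pv = _addone(int(counts[k]), eff)
        raw.append(pv)
        edges_out.append(EdgeComparison(
            kind="cross_sectional", edge=(nodes[i], nodes[j]),
            contrast=("A", "B"), est_a=float(net_a.edges[i, j]),
            est_b=float(net_b.edges[i, j]), aed=float(obs[i, j]),
            p=pv, n_perm=eff, seed=seed))
    adj = holm_adjust(raw)
    for e, ph in zip(edges_out, adj):
        e.p_holm = float(ph)
    return {
        "edges": edges_out,
        "omnibus": {"statistic": obs_max,
                    "p": _addone(max_count, eff), "n_perm": eff},
        "network_a": net_a, "network_b": net_b,
    }


def nct_waves(scores: pd.DataFrame, wave_x: int, wave_y: int,
              nodes: list[str], estimator: dict | None = None,
              n_perm: int = 1000, seed: int = 0,
              min_overlap: int = 100) -> dict:
    """Paired network comparison between two waves within one sample.

    Restricted to persons observed at both waves; the null permutes the
    two wave labels within person (a paired permutation), which respects
    the within-person pairing but treats the wave pair as exchangeable --
    an approximation under temporal dependence.
    """
    wx = scores[scores["wave"] == wave_x].set_index("person_id")[nodes]
    wy = scores[scores["wave"] == wave_y].set_index("person_id")[nodes]
    common = wx.dropna().index.intersection(wy.dropna().index)
    if len(common) < min_overlap:
        raise ValueError(f"only {len(common)} persons at both waves "
                         f"(need >= {min_overlap})")
    A = wx.loc[common].reset_index(drop=True)
    B = wy.loc[common].reset_index(drop=True)
    estimator = dict(estimator or {})
    rng = np.random.default_rng(seed)
    net_a = _estimate(A, estimator)
    net_b = _estimate(B, estimator)
    obs = edge_differences(net_a, net_b)
    p = len(nodes)
    iu = np.triu_indices(p, 1)
    counts = np.zeros(len(iu[0]))
    Xa, Xb = A.to_numpy(), B.to_numpy()
    failures = 0
    for _ in range(n_perm):
        swap = rng.random(len(common)) < 0.5
        Pa = np.where(swap[:, None], Xb, Xa)
        Pb = np.where(swap[:, None], Xa, Xb)
        try:
            na_ = _estimate(pd.DataFrame(Pa, columns=nodes), estimator)
            nb_ = _estimate(pd.DataFrame(Pb, columns=nodes), estimator)
        except _ggm.GGMError:
            failures += 1
            if failures > 0.05 * n_perm:
                raise RuntimeError("estimator failed in > 5% of permutations")
            continue
        counts += np.abs(na_.edges - nb_.edges)[iu] >= obs[iu] - 1e-15
    eff = n_perm - failures
    edges_out = []
    for k, (i, j) in enumerate(zip(*iu)):
        pv = _addone(int(counts[k]), eff)
        edges_out.append(EdgeComparison(
            kind="cross_sectional", edge=(nodes[i], nodes[j]),
            contrast=(wave_x, wave_y), est_a=float(net_a.edges[i, j]),
            est_b=float(net_b.edges[i, j]), aed=float(obs[i, j]),
            p=pv, n_perm=eff, seed=seed))
    adj = holm_adjust([e.p for e in edges_out])
    for e, ph in zip(edges_out, adj):
        e.p_holm = float(ph)
    return {"edges": edges_out, "network_a": net_a, "network_b": net_b}


# ---------------------------------------------------------------------------
# longitudinal (panel GVAR) edge comparison
# ---------------------------------------------------------------------------

def _pruned_edge_values_wide(Y, nodes, waves, edges, alpha, start=None):
    fit = _gvar.fit_prune_wide(Y, nodes, waves=len(waves), alpha=alpha,
                               start=start)
    vals = []
    for kind, frm, to in edges:
        if _gvar._edge_included(fit, kind, frm, to):
            vals.append(_gvar.edge_value(fit, kind, frm, to))
        else:
            vals.append(0.0)  # "not included in network" convention
    return np.asarray(vals), fit


def permutation_edge_test_longitudinal(
    panel_a: pd.DataFrame, panel_b: pd.DataFrame,
    edges: list[tuple[str, str, str]] | None = None,
    nodes=_gvar.NODES, waves=(3, 5, 9), n_perm: int = 500,
    alpha: float = 0.01, seed: int = 0,
    max_failure_frac: float = 0.10,
) -> dict:
    """Permutation test of panel-GVAR edge differences between two groups.

    ``panel_a`` / ``panel_b``: long score tables (one group each).  The
    observed statistic is the difference of pruned edge estimates (pruned
    edges count as 0); each permutation reassigns whole persons to groups
    (sizes preserved) and recomputes the identical fit -> prune -> edge
    statistic.  Two-sided add-one p-values.
    """
    if edges is None:
        edges = _gvar.edge_list(nodes)
    rng = np.random.default_rng(seed)
    # persons pivot to wide rows once; permutations shuffle rows
    Ya = _gvar.scores_to_wide(panel_a, nodes, waves)
    Yb = _gvar.scores_to_wide(panel_b, nodes, waves)
    obs_a, fit_a = _pruned_edge_values_wide(Ya, nodes, waves, edges, alpha)
    obs_b, fit_b = _pruned_edge_values_wide(Yb, nodes, waves, edges, alpha)
    obs = np.abs(obs_a - obs_b)

    pool = np.vstack([Ya, Yb])
    na = Ya.shape[0]
    # warm start for permutation refits: pooled-sample fit
    pooled_fit = _gvar.fit_prune_wide(pool, nodes, waves=len(waves),
                                      alpha=None)
    counts = np.zeros(len(edges))
    failures = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool.shape[0])
        try:
            va, _ = _pruned_edge_values_wide(
                pool[perm[:na]], nodes, waves, edges, alpha,
                start=pooled_fit.params.copy())
            vb, _ = _pruned_edge_values_wide(
                pool[perm[na:]], nodes, waves, edges, alpha,
                start=pooled_fit.params.copy())
        except (_gvar.GVARError, np.linalg.LinAlgError):
            failures += 1
            if failures > max_failure_frac * n_perm:
                raise RuntimeError(
                    f"panel GVAR failed in more than "
                    f"{max_failure_frac:.0%} of permutations")
            continue
        counts += np.abs(va - vb) >= obs - 1e-15
    eff = n_perm - failures
    if failures:
        warnings.warn(f"{failures} permutation refits failed", stacklevel=2)
    out = []
    for k, (kind, frm, to) in enumerate(edges):
        pv = _addone(int(counts[k]), eff)
        out.append(EdgeComparison(
            kind=kind, edge=(frm, to), contrast=("A", "B"),
            est_a=float(obs_a[k]), est_b=float(obs_b[k]),
            aed=float(obs[k]), p=pv, n_perm=eff, seed=seed))
    adj = holm_adjust([e.p for e in out])
    for e, ph in zip(out, adj):
        e.p_holm = float(ph)
    return {"edges": out, "fit_a": fit_a, "fit_b": fit_b}


def comparisons_to_frame(edges: list[EdgeComparison]) -> pd.DataFrame:
    """Tabular view used by the CSV outputs."""
    return pd.DataFrame([{
        "kind": e.kind, "from": e.edge[0], "to": e.edge[1],
        "contrast": "-".join(str(c) for c in e.contrast),
        "est_A": e.est_a, "est_B": e.est_b, "AED": e.aed,
        "p": e.p, "p_holm": e.p_holm, "stars": e.stars,
        "n_perm": e.n_perm, "seed": e.seed,
    } for e in edges])
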