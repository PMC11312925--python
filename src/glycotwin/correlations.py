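"""Intra- and inter-class trait correlation networks.

Pairs of residualized traits are tested with Pearson's product-moment
correlation; edges are retained when both ``|rho| > rho_min`` and the
p-value clears the class-specific Bonferroni bound — within a class with
effective test count N the bound is alpha / (N (N - 1) / 2), and between
classes A and B it is alpha / (N_A * N_B).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .multiple_testing import bonferroni_threshold

__all__ = ["CorrelationNetwork", "pairwise_correlations"]


@dataclass
class CorrelationNetwork:
    """Trait nodes with class labels, and significant correlation edges."""

    nodes: pd.DataFrame   # columns: trait, class_label
    edges: pd.DataFrame   # columns: trait_a, trait_b, rho, p, n, kind, threshold

    def to_graphml(self, path) -> None:
        import networkx as nx

        g = nx.Graph()
        for _, row in self.nodes.iterrows():
            g.add_node(row["trait"], class_label=row["class_label"])
        for _, row in self.edges.iterrows():
            g.add_edge(row["trait_a"], row["trait_b"],
                       rho=float(row["rho"]), p=float(row["p"]), kind=row["kind"])
        nx.write_graphml(g, path)

    def adjacency(self) -> pd.DataFrame:
        traits = list(self.nodes["trait"])
        adj = pd.DataFrame(0.0, index=traits, columns=traits)
        for _, row in self.edges.iterrows():
            adj.loc[row["trait_a"], row["trait_b"]] = row["rho"]
            adj.loc[row["trait_b"], row["trait_a"]] = row["rho"]
        return adj


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pearson rho with the t-approximation p-value on complete cases."""
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        raise ValueError("fewer than 3 complete observations for a trait pair")
    r = float(np.corrcoef(x[ok], y[ok])[0, 1])
    if abs(r) >= 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p), n


def pairwise_correlations(
    traits: pd.DataFrame,
    class_labels: dict[str, str],
    m_eff: dict[str, int],
    rho_min: float = 0.25,
    alpha: float = 0.05,
) -> CorrelationNetwork:
    """Build the correlation network over residualized traits.

    Parameters
    ----------
    traits : individuals x traits (already residualized on covariates and
        family/plate structure).
    class_labels : trait -> class (e.g. "IgA" / "IgG").
    m_eff : class -> effective number of independent tests, used in the
        Bonferroni denominators.
    rho_min : minimum absolute correlation for an edge (strict >).
    """
    cols = [c for c in traits.columns if c in class_labels]
    if set(traits.columns) - set(cols):
        missing = sorted(set(traits.columns) - set(cols))
        raise KeyError(f"traits without a class label: {missing}")
    nodes = pd.DataFrame({"trait": cols,
                          "class_label": [class_labels[c] for c in cols]})
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            la, lb = class_labels[a], class_labels[b]
            if la == lb:
                n_cls = m_eff[la]
                bound = bonferroni_threshold(alpha, n_cls * (n_cls - 1) / 2)
                kind = "intra"
            else:
                bound = bonferroni_threshold(alpha, m_eff[la] * m_eff[lb])
                kind = "inter"
            r, p, n = _pearson(traits[a].to_numpy(float), traits[b].to_numpy(float))
            if abs(r) > rho_min and p < bound:
                rows.append(dict(trait_a=a, trait_b=b, rho=r, p=p, n=n,
                                 kind=kind, threshold=bound))
    edges = pd.DataFrame(rows, columns=["trait_a", "trait_b", "rho", "p", "n",
                                        "kind", "threshold"])
    return CorrelationNetwork(nodes=nodes, edges=edges)
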