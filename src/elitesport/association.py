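"""Inter-domain correlation structure and the elite-variance resampling null.

Correlations are one-sided Pearson tests oriented toward positive
association (the direction of interest after superiority-oriented
scoring); a negative observed correlation is reported with the attained
one-sided p in the observed direction and flagged.

The variance comparison builds a resampling reference: repeatedly drawing
elite-sized subsets (default 22) of the semi-elite group without
replacement and computing each domain's sample variance yields a null
range against which the elite group's variance is positioned as below,
within, or above.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .schemes import DOMAINS
from .scoring import ScoreTable

#: Correlations above this value are drawn as network edges (strict).
EDGE_THRESHOLD = 0.15


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations over the eight domain scores."""

    r: pd.DataFrame                  # 8x8, unit diagonal
    p: pd.DataFrame                  # one-sided p in the observed direction
    n: pd.DataFrame                  # pairwise-complete sample sizes
    negative_pairs: list = field(default_factory=list)

    def edge_list(self, threshold: float = EDGE_THRESHOLD) -> list:
        """Domain pairs with |r| strictly above the threshold."""
        edges = []
        for i, a in enumerate(DOMAINS):
            for b in DOMAINS[i + 1:]:
                value = self.r.loc[a, b]
                if np.isfinite(value) and abs(value) > threshold:
                    edges.append((a, b, float(value)))
        return edges


def correlate_domains(table: ScoreTable | pd.DataFrame) -> CorrelationMatrix:
    """Pairwise-complete one-sided Pearson correlations between domains."""
    frame = table.frame if isinstance(table, ScoreTable) else table
    k = len(DOMAINS)
    r = pd.DataFrame(np.eye(k), index=DOMAINS, columns=DOMAINS)
    p = pd.DataFrame(np.zeros((k, k)), index=DOMAINS, columns=DOMAINS)
    n = pd.DataFrame(0, index=DOMAINS, columns=DOMAINS, dtype=int)
    negative = []
    for d in DOMAINS:
        n.loc[d, d] = int(frame[d].notna().sum())
    for i, a in enumerate(DOMAINS):
        for b in DOMAINS[i + 1:]:
            pair = frame[[a, b]].dropna()
            n.loc[a, b] = n.loc[b, a] = len(pair)
            if len(pair) < 3:
                raise ValidationError(
                    f"fewer than 3 complete pairs for ({a}, {b})"
                )
            if pair[a].nunique() == 1 or pair[b].nunique() == 1:
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            res = stats.pearsonr(pair[a], pair[b], alternative="greater")
            r_val = float(res.statistic)
            if r_val >= 0:
                p_val = float(res.pvalue)
            else:
                p_val = float(
                    stats.pearsonr(pair[a], pair[b], alternative="less").pvalue
                )
                negative.append((a, b, r_val))
            r.loc[a, b] = r.loc[b, a] = r_val
            p.loc[a, b] = p.loc[b, a] = p_val
    return CorrelationMatrix(r=r, p=p, n=n, negative_pairs=negative)


@dataclass
class VarianceComparison:
    """Elite per-domain variances against the resampled semi-elite range.

    ``frame`` columns: domain, elite_var, resampled_mean, resampled_min,
    resampled_max, position (below_range / within_range / above_range).
    """

    frame: pd.DataFrame
    iterations: int
    group_size: int
    n_elite: int
    n_semi_elite: int
    seed: int | None


def resample_semielite_variances(
    table: ScoreTable | pd.DataFrame,
    group_size: int = 22,
    iterations: int = 1000,
    seed: int | None = None,
) -> VarianceComparison:
    """Resampling variance null for the elite-vs-semi-elite comparison.

    Each iteration draws ``group_size`` semi-elite athletes without
    replacement and records each domain's sample variance (n-1); the
    summary is the mean/min/max over iterations. The elite variance is
    computed once on all elite athletes and positioned against [min, max].
    """
    frame = table.frame if isinstance(table, ScoreTable) else table
    if iterations < 1:
        raise ValidationError(f"iterations must be >= 1, got {iterations}")
    elite = frame[frame["elite"]]
    semi = frame[~frame["elite"]]
    if len(elite) < 2:
        raise ValidationError(
            f"need at least 2 elite athletes, got {len(elite)}"
        )
    if len(semi) < group_size:
        raise ValidationError(
            f"semi-elite group (n={len(semi)}) smaller than the resampling "
            f"group size ({group_size})"
        )
    rng = np.random.default_rng(seed)
    semi_scores = semi[list(DOMAINS)].to_numpy(dtype=float)
    idx = np.stack([
        rng.choice(len(semi), size=group_size, replace=False)
        for _ in range(iterations)
    ])
    draws = semi_scores[idx]                      # (iterations, group_size, 8)
    variances = draws.var(axis=1, ddof=1)         # (iterations, 8)
    elite_var = elite[list(DOMAINS)].var(ddof=1).to_numpy()

    lo, hi = variances.min(axis=0), variances.max(axis=0)
    position = np.where(
        elite_var < lo, "below_range",
        np.where(elite_var > hi, "above_range", "within_range"),
    )
    out = pd.DataFrame({
        "domain": DOMAINS,
        "elite_var": elite_var,
        "resampled_mean": variances.mean(axis=0),
        "resampled_min": lo,
        "resampled_max": hi,
        "position": position,
    })
    return VarianceComparison(
        frame=out, iterations=iterations, group_size=group_size,
        n_elite=len(elite), n_semi_elite=len(semi), seed=seed,
    )


def export_network(
    linear_fit,
    correlations: CorrelationMatrix,
    variance: VarianceComparison,
    threshold: float = EDGE_THRESHOLD,
) -> nx.Graph:
    """Domain network: node size ~ |beta|, edges where r > threshold (strict).

    Nodes carry the linear-model beta, the elite variance, and the
    resampled semi-elite variance range; edges carry the correlation as
    weight.
    """
    betas = linear_fit.terms.set_index("term")["beta"]
    domains_in_fit = [t for t in betas.index if t in DOMAINS]
    if set(domains_in_fit) != set(DOMAINS) or set(correlations.r.index) != set(
        DOMAINS
    ) or set(variance.frame["domain"]) != set(DOMAINS):
        raise ValidationError("mismatched domain sets across network inputs")
    var = variance.frame.set_index("domain")
    graph = nx.Graph()
    for d in DOMAINS:
        graph.add_node(
            d,
            beta=float(betas[d]),
            size=abs(float(betas[d])),
            elite_var=float(var.loc[d, "elite_var"]),
            resampled_mean=float(var.loc[d, "resampled_mean"]),
            resampled_min=float(var.loc[d, "resampled_min"]),
            resampled_max=float(var.loc[d, "resampled_max"]),
            variance_position=str(var.loc[d, "position"]),
        )
    for i, a in enumerate(DOMAINS):
        for b in DOMAINS[i + 1:]:
            r_val = correlations.r.loc[a, b]
            if np.isfinite(r_val) and r_val > threshold:
                graph.add_edge(a, b, weight=float(r_val), r=float(r_val))
    return graph


def network_to_json(graph: nx.Graph, path=None) -> dict:
    """Serialize the domain network as a nodes/edges JSON document."""
    data = nx.node_link_data(graph, edges="edges")
    if path is not None:
        Path(path).write_text(json.dumps(data, indent=2, sort_keys=True))
    return data


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)
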