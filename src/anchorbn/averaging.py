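"""Bootstrap model averaging of best-fit networks.

The data are resampled with replacement B times (default 1000); a
best-fit network is learned on each resample by hill climbing.  For
every node pair, the edge-existence probability ("strength") is the
fraction of bootstrap networks containing the edge in either
orientation, and the direction probability is the fraction of those, in
which it points a given way -- i.e. orientation conditional on
existence.  Thresholding the strengths with a data-driven significance
level yields the averaged network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .bn import BicScorer, ConstraintSet, _hill_climb_scorer
from .dataset import Dataset

__all__ = [
    "AveragedNetwork",
    "bootstrap_average",
    "edge_strength_threshold",
    "averaged_dag",
]

#: attempts to redraw a degenerate (constant-column) bootstrap resample
MAX_REDRAWS = 100


@dataclass
class AveragedNetwork:
    """Edge-existence and direction probabilities over B bootstrap nets."""

    nodes: tuple[str, ...]
    B: int
    counts: dict[tuple[str, str], int]   # directed-edge occurrence counts
    redraws: int = 0                     # degenerate resamples redrawn

    def _pair_counts(self, a: str, b: str) -> tuple[int, int]:
        return self.counts.get((a, b), 0), self.counts.get((b, a), 0)

    def strength(self, a: str, b: str) -> float:
        """P(edge between a and b exists, either orientation)."""
        fwd, bwd = self._pair_counts(a, b)
        return (fwd + bwd) / self.B

    def direction_forward(self, a: str, b: str) -> float:
        """P(a -> b | edge exists); 0.5 for never-seen pairs."""
        fwd, bwd = self._pair_counts(a, b)
        if fwd + bwd == 0:
            return 0.5
        return fwd / (fwd + bwd)

    def directed_prob(self, a: str, b: str) -> float:
        """P(a -> b occurs in a bootstrap network) = strength * direction."""
        return self.counts.get((a, b), 0) / self.B

    def pair_table(self) -> pd.DataFrame:
        """One row per unordered pair (canonical node order): strength and
        forward-direction probability."""
        rows = []
        for a, b in combinations(self.nodes, 2):
            rows.append({"a": a, "b": b, "strength": self.strength(a, b),
                         "direction_forward": self.direction_forward(a, b)})
        return pd.DataFrame(rows)


def bootstrap_average(data: Dataset, constraints: ConstraintSet | None = None,
                      B: int = 1000, seed: int = 0,
                      nodes: list[str] | None = None,
                      max_iter: int | None = None) -> AveragedNetwork:
    """Learn an averaged network from B bootstrap resamples.

    Replicate i resamples n rows with replacement using an independent
    generator derived from (seed, i), so results do not depend on
    execution order and a parallel map would reproduce the serial
    output.  A resample that leaves some column constant is redrawn from
    a further-derived stream (and counted in ``redraws``) so that all B
    replicates complete.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    scorer = BicScorer(data, nodes=nodes)
    n = scorer.n
    cs = constraints if constraints is not None else ConstraintSet()
    cs.validate(scorer.nodes)

    counts: dict[tuple[str, str], int] = {}
    redraws = 0
    for i in range(B):
        rng = np.random.default_rng([seed, i])
        idx = rng.integers(0, n, size=n)
        sub = scorer.subset(idx)
        attempt = 0
        while sub.is_degenerate() and attempt < MAX_REDRAWS:
            attempt += 1
            redraw_rng = np.random.default_rng([seed, i, attempt])
            idx = redraw_rng.integers(0, n, size=n)
            sub = scorer.subset(idx)
        redraws += attempt
        dag = _hill_climb_scorer(sub, cs, max_iter=max_iter, start_rng=rng)
        for edge in dag.edges:
            counts[edge] = counts.get(edge, 0) + 1
    return AveragedNetwork(nodes=scorer.nodes, B=B, counts=counts,
                           redraws=redraws)


def edge_strength_threshold(net: AveragedNetwork) -> float:
    """Data-driven significance threshold for edge inclusion.

    Treats the observed pair strengths as a sample whose empirical CDF
    should, for an ideal averaged network, be degenerate: a fraction of
    noise edges at strength 0 and the significant edges at strength 1.
    The threshold t minimizes the L1 distance between the empirical CDF
    and the ideal step CDF that jumps from 0 to 1 at t, by brute-force
    search over the observed strength values.
    """
    strengths = np.sort([net.strength(a, b)
                         for a, b in combinations(net.nodes, 2)])
    m = len(strengths)
    if m == 0:
        return 1.0
    # ECDF breakpoints over [0, 1]
    grid = np.unique(np.concatenate([[0.0], strengths, [1.0]]))

    def l1(t: float) -> float:
        total = 0.0
        for lo, hi in zip(grid[:-1], grid[1:]):
            mid = 0.5 * (lo + hi)
            ecdf = np.searchsorted(strengths, mid, side="right") / m
            ideal = 1.0 if mid >= t else 0.0
            total += abs(ecdf - ideal) * (hi - lo)
        return total

    candidates = np.unique(strengths)
    best_t, best_l1 = 1.0, np.inf
    for t in candidates:
        d = l1(t)
        if d < best_l1 - 1e-15:
            best_l1 = d
            best_t = t
    return float(best_t)


def averaged_dag(net: AveragedNetwork, threshold: float | None = None) -> pd.DataFrame:
    """Significance-thresholded averaged network as an edge table.

    Pairs with strength >= threshold are kept and oriented by their
    majority direction; an exact 0.5 split is broken toward the
    canonical node order and flagged ``ambiguous``.
    """
    if threshold is None:
        threshold = edge_strength_threshold(net)
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    rows = []
    for a, b in combinations(net.nodes, 2):
        s = net.strength(a, b)
        if s < threshold or s == 0.0:
            continue
        fwd = net.direction_forward(a, b)
        if fwd >= 0.5:
            rows.append({"from": a, "to": b, "strength": s,
                         "direction_prob": fwd, "ambiguous": fwd == 0.5})
        else:
            rows.append({"from": b, "to": a, "strength": s,
                         "direction_prob": 1.0 - fwd, "ambiguous": False})
    return pd.DataFrame(rows, columns=["from", "to", "strength",
                                       "direction_prob", "ambiguous"])


def edge_table_to_dot(table: pd.DataFrame, path: str | Path | None = None) -> str:
    """Best-effort DOT export with edge width proportional to strength."""
    lines = ["digraph {"]
    for _, row in table.iterrows():
        w = 0.5 + 3.0 * float(row["strength"])
        lines.append(
            f'  "{row["from"]}" -> "{row["to"]}" '
            f'[penwidth={w:.2f}, label="{row["strength"]:.2f} '
            f'({row["direction_prob"]:.2f})"];')
    lines.append("}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
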