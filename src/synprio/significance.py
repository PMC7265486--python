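"""Permutation null models, empirical p-values, Bayes factors, FDR flags.

Two shuffling schemes match the two workflows: pair-label shuffling for
prioritization (synergy values permuted across target pairs) and per-combo
cell-label shuffling for stratification. Significance summaries are the
two-tailed empirical p and a count-ratio Bayes factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class PermutationResult:
    observed_r: float
    null_rs: np.ndarray
    p_two_tailed: float
    bayes_factor: float
    B: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.null_rs) != self.B:
            raise ValueError("null_rs length must equal B")
        if not 0 <= self.p_two_tailed <= 1:
            raise ValueError("p must lie in [0, 1]")
        if self.bayes_factor < 0:
            raise ValueError("Bayes factor must be non-negative")


def empirical_p(observed_r: float, null_rs: np.ndarray, tail: str = "minmax") -> float:
    """Two-tailed empirical p-value against a permutation null.

    ``minmax``: p = 2 * min(#{null >= obs}, #{null <= obs}) / B, capped at 1.
    ``abs``: p = #{|null| >= |obs|} / B. No +1 smoothing: p = 0 is reachable
    when the observed statistic beats every null draw.
    """
    null_rs = np.asarray(null_rs, dtype=float)
    if null_rs.size == 0:
        raise ValueError("null distribution is empty")
    B = null_rs.size
    if tail == "minmax":
        n_ge = int(np.sum(null_rs >= observed_r))
        n_le = int(np.sum(null_rs <= observed_r))
        return min(1.0, 2.0 * min(n_ge, n_le) / B)
    if tail == "abs":
        return float(np.sum(np.abs(null_rs) >= abs(observed_r)) / B)
    raise ValueError("tail must be 'minmax' or 'abs'")


def bayes_factor(observed_r: float, null_rs: np.ndarray) -> float:
    """Count-ratio Bayes factor: #{null < obs} / max(1, #{null >= obs}).

    Ties count against the observed statistic. The denominator floor of 1
    keeps the statistic finite, giving B when the observed value beats all
    B null draws (and B-1 -> BF = B-1, the printed ceiling at B = 1000).
    """
    null_rs = np.asarray(null_rs, dtype=float)
    if null_rs.size == 0:
        raise ValueError("null distribution is empty")
    n_better = int(np.sum(null_rs < observed_r))
    n_worse = null_rs.size - n_better
    return n_better / max(1, n_worse)


def _summarize(observed_r, null_rs, B, seed, tail) -> PermutationResult:
    return PermutationResult(
        observed_r=float(observed_r),
        null_rs=np.asarray(null_rs, dtype=float),
        p_two_tailed=empirical_p(observed_r, null_rs, tail=tail),
        bayes_factor=bayes_factor(observed_r, null_rs),
        B=B,
        seed=seed,
    )


def permute_pair_labels(
    abs_similarity: dict,
    observed_pair_synergy: dict,
    B: int = 1000,
    seed: int = 0,
    tail: str = "minmax",
) -> PermutationResult:
    """Null for prioritization: shuffle synergy values across target pairs.

    Both inputs map target pair -> value; |similarity| is taken on the
    similarity side. Each iteration permutes the synergy values over pairs
    and recomputes the Pearson r.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    pairs = sorted(set(abs_similarity) & set(observed_pair_synergy))
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs shared by both inputs")
    x = np.abs(np.array([abs_similarity[p] for p in pairs], dtype=float))
    y = np.array([observed_pair_synergy[p] for p in pairs], dtype=float)
    observed_r = float(stats.pearsonr(x, y).statistic)
    rng = np.random.default_rng(seed)
    null_rs = np.empty(B)
    for b in range(B):
        null_rs[b] = _pearson(x, rng.permutation(y))
    return _summarize(observed_r, null_rs, B, seed, tail)


def permute_cell_labels(
    predicted_per_cell: dict,
    observed_records_per_combo: dict,
    B: int = 1000,
    seed: int = 0,
    tail: str = "minmax",
) -> PermutationResult:
    """Null for stratification: shuffle cell labels within each combination.

    ``observed_records_per_combo`` maps combo id -> {cell -> synergy}. Each
    iteration independently permutes every combo's cell labels, recomputes
    per-cell mean observed synergy, and correlates with the predictions.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    for combo, per_cell in observed_records_per_combo.items():
        if len(per_cell) < 2:
            raise ValueError(f"combo {combo!r} has fewer than 2 cells")
    combos = sorted(observed_records_per_combo)
    combo_cells = {c: sorted(observed_records_per_combo[c]) for c in combos}
    combo_vals = {
        c: np.array(
            [observed_records_per_combo[c][cell] for cell in combo_cells[c]],
            dtype=float,
        )
        for c in combos
    }

    def per_cell_mean(values_by_combo):
        sums: dict[str, float] = {}
        counts: dict[str, int] = {}
        for c in combos:
            for cell, v in zip(combo_cells[c], values_by_combo[c]):
                sums[cell] = sums.get(cell, 0.0) + v
                counts[cell] = counts.get(cell, 0) + 1
        return {cell: sums[cell] / counts[cell] for cell in sums}

    obs_means = per_cell_mean(combo_vals)
    cells = sorted(set(obs_means) & set(predicted_per_cell))
    if len(cells) < 2:
        raise ValueError("need at least 2 cells shared by predictions and records")
    pred = np.array([predicted_per_cell[c] for c in cells], dtype=float)
    obs = np.array([obs_means[c] for c in cells], dtype=float)
    observed_r = _pearson(pred, obs)

    rng = np.random.default_rng(seed)
    null_rs = np.empty(B)
    for b in range(B):
        shuffled = {c: rng.permutation(combo_vals[c]) for c in combos}
        means = per_cell_mean(shuffled)
        y = np.array([means[c] for c in cells], dtype=float)
        null_rs[b] = _pearson(pred, y)
    return _summarize(observed_r, null_rs, B, seed, tail)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def fdr_flags(pvals, q: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (pass flags, adjusted p-values)."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject, adjusted
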