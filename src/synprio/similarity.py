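"""Target functional similarity and combination prioritization.

The functional similarity of two targets is the Pearson correlation of
their rows of the interaction matrix (their interaction profiles over the
pathway set). Candidate combinations are ranked by |similarity|.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .factorization import InteractionMatrix


@dataclass
class SimilarityMatrix:
    """Targets x targets Pearson correlations over the pathway axis."""

    values: pd.DataFrame
    n_pathways: int
    tissue_label: str = ""

    @property
    def targets(self) -> list[str]:
        return list(self.values.index)


@dataclass
class PrioritizedPairs:
    """Target pairs ranked by |functional similarity|."""

    pairs: pd.DataFrame  # target1, target2, similarity, abs_similarity, pearson_p, passes_threshold
    threshold: float = 0.7


def functional_similarity(
    I: InteractionMatrix, t1: str, t2: str
) -> tuple[float, float]:
    """Pearson r between two targets' interaction profiles, with p-value.

    p comes from the t-distribution with (n_pathways - 2) degrees of
    freedom. A constant profile makes r undefined: returns (nan, nan) with
    a warning, never a silent 0.
    """
    for t in (t1, t2):
        if t not in I.values.index:
            raise KeyError(f"target {t!r} not in interaction matrix")
    n = I.values.shape[1]
    if n < 3:
        raise ValueError("need at least 3 pathways for a correlation")
    a = I.values.loc[t1].to_numpy(dtype=float)
    b = I.values.loc[t2].to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn(
            f"constant interaction profile for pair ({t1!r}, {t2!r}); r undefined",
            stacklevel=2,
        )
        return float("nan"), float("nan")
    r = float(np.corrcoef(a, b)[0, 1])
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t_stat = r * np.sqrt((n - 2) / (1 - r**2))
    p = float(2 * stats.t.sf(abs(t_stat), df=n - 2))
    return r, p


def similarity_matrix(I: InteractionMatrix, tissue_label: str = "") -> SimilarityMatrix:
    """All pairwise functional similarities (symmetric, unit diagonal)."""
    targets = I.targets
    if len(targets) < 2:
        raise ValueError("need at least 2 targets")
    n = len(targets)
    out = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        r, _ = functional_similarity(I, targets[i], targets[j])
        out[i, j] = out[j, i] = r
    return SimilarityMatrix(
        values=pd.DataFrame(out, index=targets, columns=targets),
        n_pathways=I.values.shape[1],
        tissue_label=tissue_label or I.tissue_label,
    )


def prioritize_pairs(
    sim: SimilarityMatrix,
    common_targets: set[str] | None = None,
    threshold: float = 0.7,
    annotation: dict[str, set[str]] | None = None,
) -> PrioritizedPairs:
    """Rank target pairs by |similarity|, flagging those above threshold.

    If an ``annotation`` (drug -> target set) is given, only pairs whose two
    targets are hit by two *different* drugs are kept; a drug annotating
    both targets is ignored for pairing purposes but does not disqualify
    the pair if other drugs cover it.
    """
    targets = sim.targets if common_targets is None else sorted(
        set(common_targets) & set(sim.targets)
    )
    if common_targets is not None and set(common_targets) - set(sim.targets):
        missing = sorted(set(common_targets) - set(sim.targets))
        raise KeyError(f"common targets not in similarity matrix: {missing}")
    n_path = sim.n_pathways
    rows = []
    for t1, t2 in itertools.combinations(sorted(targets), 2):
        if annotation is not None and not _two_distinct_drugs(annotation, t1, t2):
            continue
        r = float(sim.values.loc[t1, t2])
        if np.isnan(r):
            p = float("nan")
        elif abs(r) == 1.0:
            p = 0.0
        else:
            t_stat = r * np.sqrt((n_path - 2) / (1 - r**2))
            p = float(2 * stats.t.sf(abs(t_stat), df=n_path - 2))
        rows.append(
            {
                "target1": t1,
                "target2": t2,
                "similarity": r,
                "abs_similarity": abs(r),
                "pearson_p": p,
                "passes_threshold": bool(abs(r) > threshold),
            }
        )
    if not rows:
        warnings.warn("no candidate target pairs", stacklevel=2)
        df = pd.DataFrame(
            columns=[
                "target1",
                "target2",
                "similarity",
                "abs_similarity",
                "pearson_p",
                "passes_threshold",
            ]
        )
        return PrioritizedPairs(pairs=df, threshold=threshold)
    df = pd.DataFrame(rows).sort_values(
        ["abs_similarity", "target1", "target2"],
        ascending=[False, True, True],
        kind="stable",
    )
    return PrioritizedPairs(pairs=df.reset_index(drop=True), threshold=threshold)


def _two_distinct_drugs(
    annotation: dict[str, set[str]], t1: str, t2: str
) -> bool:
    d1 = {d for d, ts in annotation.items() if t1 in ts}
    d2 = {d for d, ts in annotation.items() if t2 in ts}
    return any(a != b for a in d1 for b in d2)


def cross_tissue_similarity(mats: list[SimilarityMatrix]) -> SimilarityMatrix:
    """NaN-aware elementwise mean of per-tissue similarity matrices."""
    if not mats:
        raise ValueError("no similarity matrices given")
    targets = mats[0].targets
    for m in mats[1:]:
        if m.targets != targets:
            raise ValueError("similarity matrices have different target sets")
    stack = np.stack([m.values.to_numpy(dtype=float) for m in mats])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices -> NaN
        mean = np.nanmean(stack, axis=0)
    return SimilarityMatrix(
        values=pd.DataFrame(mean, index=targets, columns=targets),
        n_pathways=mats[0].n_pathways,
        tissue_label="average",
    )


def similarity_vs_synergy(
    sim: SimilarityMatrix, pair_synergy: dict[tuple[str, str], float]
) -> float:
    """Pearson r of |similarity| against aggregated observed synergy."""
    xs, ys = [], []
    for (t1, t2), syn in pair_synergy.items():
        if t1 in sim.values.index and t2 in sim.values.columns:
            s = sim.values.loc[t1, t2]
            if np.isfinite(s) and np.isfinite(syn):
                xs.append(abs(float(s)))
                ys.append(float(syn))
    if len(xs) < 3:
        raise ValueError("need at least 3 pairs with both similarity and synergy")
    return float(stats.pearsonr(xs, ys).statistic)
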