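"""Delta Pathway Activity models for per-cell-line synergy stratification.

Two mechanisms are supported: mechanism 1 (synergy by similarity — reward
active sensitizing pathways) and mechanism 2 (synergy by compensation —
reward active resistance pathways). A model is a pair of small pathway
groups (1-3 each) plus optional signed binary genomics terms.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pathway_activity import PathwayActivityMatrix

UNDETERMINED = "UNDETERMINED"

MECHANISM_SIMILARITY = 1
MECHANISM_COMPENSATION = 2


@dataclass(frozen=True)
class SynergyRecord:
    """One (drug1, drug2, cell) observation with a synergy score."""

    drug1: str
    drug2: str
    cell: str
    synergy: float

    def __post_init__(self) -> None:
        if self.drug1 == self.drug2:
            raise ValueError("drug1 and drug2 must differ")
        if not np.isfinite(self.synergy):
            raise ValueError("synergy score must be finite")

    @property
    def combo(self) -> tuple[str, str]:
        return tuple(sorted((self.drug1, self.drug2)))


@dataclass
class SynergyModelSpec:
    """A Delta PA model: mechanism, pathway groups and genomics terms."""

    mechanism: int
    sensitive_pathways: list[str]
    resistant_pathways: list[str]
    genomics_terms: list[tuple[str, int]] = field(default_factory=list)
    anchor_target: str | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mechanism not in (MECHANISM_SIMILARITY, MECHANISM_COMPENSATION):
            raise ValueError("mechanism must be 1 or 2")
        for name, group in (
            ("sensitive", self.sensitive_pathways),
            ("resistant", self.resistant_pathways),
        ):
            if not 1 <= len(group) <= 3:
                raise ValueError(f"{name} group must contain 1-3 pathways")
        if set(self.sensitive_pathways) & set(self.resistant_pathways):
            raise ValueError("sensitive and resistant groups must be disjoint")
        for _, sign in self.genomics_terms:
            if sign not in (1, -1):
                raise ValueError("genomics term sign must be +1 or -1")


@dataclass
class DeltaPAScores:
    """Per-cell predicted synergy under one model spec."""

    values: pd.Series
    spec: SynergyModelSpec
    provenance: dict = field(default_factory=dict)


@dataclass
class PathwayRanking:
    """Pathways ordered by a target pair's interaction profile."""

    profile: pd.Series  # sensitivity-oriented profile value per pathway
    sensitive: list[str]  # descending profile value
    resistant: list[str]  # ascending profile value


def select_model(
    similarity: float, literature_override: int | None = None
) -> int | str:
    """Choose the mechanism from functional similarity (band at +/-0.4).

    A literature override always wins. Otherwise similarity >= 0.4 selects
    mechanism 1, <= -0.4 mechanism 2, and the band in between is
    UNDETERMINED (no Delta PA model should be built).
    """
    if literature_override is not None:
        if literature_override not in (1, 2):
            raise ValueError("literature_override must be 1 or 2")
        return literature_override
    if not -1 <= similarity <= 1:
        raise ValueError("similarity must lie in [-1, 1]")
    if similarity >= 0.4:
        return MECHANISM_SIMILARITY
    if similarity <= -0.4:
        return MECHANISM_COMPENSATION
    return UNDETERMINED


def rank_pathways(
    interactions,
    pair: tuple[str, str],
    mechanism: int,
    anchor_target: str | None = None,
) -> PathwayRanking:
    """Rank pathways by the pair's sensitivity-oriented interaction profile.

    Mechanism 1 uses the mean of the two targets' rows. Mechanism 2 uses a
    single anchor target's row (default: first of the pair) because the
    mean of two anticorrelated profiles cancels.
    """
    if isinstance(interactions, pd.DataFrame):
        values = interactions
    else:
        values = getattr(interactions, "values", None)
    if not isinstance(values, pd.DataFrame):
        raise TypeError("interactions must be a labeled DataFrame-backed matrix")
    for t in pair:
        if t not in values.index:
            raise KeyError(f"target {t!r} not in interaction matrix")
    if mechanism == MECHANISM_SIMILARITY:
        profile = values.loc[list(pair)].mean(axis=0)
    elif mechanism == MECHANISM_COMPENSATION:
        anchor = anchor_target if anchor_target is not None else pair[0]
        if anchor not in values.index:
            raise KeyError(f"anchor target {anchor!r} not in interaction matrix")
        profile = values.loc[anchor]
    else:
        raise ValueError("mechanism must be 1 or 2")
    # stable mergesort keeps pathway order deterministic under ties
    desc = list(profile.sort_values(ascending=False, kind="stable").index)
    asc = list(profile.sort_values(ascending=True, kind="stable").index)
    return PathwayRanking(profile=profile, sensitive=desc, resistant=asc)


def _insert_literature(
    group: list[str], ranking: list[str], lit: str, flags: list[str], label: str
) -> list[str]:
    if lit not in ranking:
        raise ValueError(f"literature pathway {lit!r} not in pathway universe")
    if lit in group:
        return group
    pos = ranking.index(lit)  # 0-based
    interval = ranking[: pos + 1]
    if len(interval) <= 3:
        group = interval
    else:
        # interval rule overflows the 3-pathway cap: keep ranks 1-2 + literature
        group = [ranking[0], ranking[1], lit]
        flags.append(f"{label} literature interval truncated for {lit!r}")
    return group


def build_model_spec(
    rankings: PathwayRanking,
    mechanism: int,
    N: int,
    M: int,
    genomics_terms: list[tuple[str, int]] | None = None,
    literature_pathways: list[tuple[str, str]] | None = None,
    anchor_target: str | None = None,
) -> SynergyModelSpec:
    """Assemble a model spec from rankings and group sizes.

    ``literature_pathways`` is a list of (pathway, group) with group in
    {"sensitive", "resistant"}. A literature pathway outside the top of its
    group is included together with every pathway ranked between the
    group's first element and it; if that interval exceeds 3 pathways, the
    top 2 plus the literature pathway are kept (flagged in the output).
    Overlapping groups are repaired: the contested pathway stays in the
    group where it ranks higher, the other group refills from its ranking.
    """
    if not (1 <= N <= 3 and 1 <= M <= 3):
        raise ValueError("group sizes N, M must be in 1..3")
    flags: list[str] = []
    sensitive = list(rankings.sensitive[:N])
    resistant = list(rankings.resistant[:M])
    for lit, grp in literature_pathways or []:
        if grp == "sensitive":
            sensitive = _insert_literature(
                sensitive, rankings.sensitive, lit, flags, "sensitive"
            )
        elif grp == "resistant":
            resistant = _insert_literature(
                resistant, rankings.resistant, lit, flags, "resistant"
            )
        else:
            raise ValueError(f"unknown group {grp!r}")

    overlap = [p for p in sensitive if p in resistant]
    for p in overlap:
        # keep in the group where the pathway ranks higher
        if rankings.sensitive.index(p) <= rankings.resistant.index(p):
            resistant.remove(p)
            pool, taken = rankings.resistant, resistant
        else:
            sensitive.remove(p)
            pool, taken = rankings.sensitive, sensitive
        for cand in pool:
            if cand not in taken and cand not in sensitive and cand not in resistant:
                taken.append(cand)
                break
        flags.append(f"group overlap on {p!r} repaired")

    return SynergyModelSpec(
        mechanism=mechanism,
        sensitive_pathways=sensitive,
        resistant_pathways=resistant,
        genomics_terms=list(genomics_terms or []),
        anchor_target=anchor_target,
        flags=flags,
    )


def delta_pa(
    spec: SynergyModelSpec,
    pa: PathwayActivityMatrix,
    genomics: pd.DataFrame | None = None,
) -> DeltaPAScores:
    """Evaluate the Delta PA formula per cell line.

    Mechanism 1: mean(sensitive group) - mean(resistant group) + genomics.
    Mechanism 2: mean(resistant group) - mean(sensitive group) + genomics.
    Genomics terms contribute sign * binary-indicator on the (standardized)
    activity scale.
    """
    missing = [
        p
        for p in spec.sensitive_pathways + spec.resistant_pathways
        if p not in pa.values.columns
    ]
    if missing:
        raise KeyError(f"pathways not in activity matrix: {missing}")
    sens = pa.values[spec.sensitive_pathways].mean(axis=1)
    res = pa.values[spec.resistant_pathways].mean(axis=1)
    score = sens - res if spec.mechanism == MECHANISM_SIMILARITY else res - sens
    if spec.genomics_terms:
        if genomics is None:
            raise ValueError("spec has genomics terms but no genomics table given")
        for marker, sign in spec.genomics_terms:
            if marker not in genomics.columns:
                raise KeyError(f"marker {marker!r} not in genomics table")
            score = score + sign * genomics[marker].reindex(score.index).astype(float)
    return DeltaPAScores(
        values=score.rename("delta_pa"),
        spec=spec,
        provenance={"standardized_activities": pa.standardized},
    )


def filter_specific_drugs(
    annotation: dict[str, set[str]],
    pair: tuple[str, str],
    max_targets: int = 3,
) -> list[tuple[str, str]]:
    """Admissible drug pairs for a target pair, dropping promiscuous drugs.

    A drug is admissible for target t if it annotates t and has at most
    ``max_targets`` annotated targets in total.
    """
    t1, t2 = pair
    adm1 = sorted(
        d for d, ts in annotation.items() if t1 in ts and len(ts) <= max_targets
    )
    adm2 = sorted(
        d for d, ts in annotation.items() if t2 in ts and len(ts) <= max_targets
    )
    pairs = [(d1, d2) for d1, d2 in itertools.product(adm1, adm2) if d1 != d2]
    if len(pairs) < 3:
        warnings.warn(
            f"fewer than 3 admissible drug pairs for {pair}: {len(pairs)}",
            stacklevel=2,
        )
    return pairs


def eligible_target_pairs(
    records: list[SynergyRecord],
    annotation: dict[str, set[str]],
    min_synergy: float = 20.0,
    min_cells: int = 10,
    min_combos_per_cell: int = 2,
) -> pd.DataFrame:
    """Eligibility report per target pair.

    A pair is eligible iff (1) its best observed synergy strictly exceeds
    ``min_synergy``, and (2) after dropping cell lines tested with fewer
    than ``min_combos_per_cell`` distinct drug combinations, at least
    ``min_cells`` cell lines remain.
    """
    if not records:
        raise ValueError("no synergy records given")
    rows = []
    by_pair: dict[tuple[str, str], list[SynergyRecord]] = {}
    for rec in records:
        for ta in sorted(annotation.get(rec.drug1, ())):
            for tb in sorted(annotation.get(rec.drug2, ())):
                if ta == tb:
                    continue
                by_pair.setdefault(tuple(sorted((ta, tb))), []).append(rec)
    for pair, recs in sorted(by_pair.items()):
        max_syn = max(r.synergy for r in recs)
        combos_per_cell: dict[str, set[tuple[str, str]]] = {}
        for r in recs:
            combos_per_cell.setdefault(r.cell, set()).add(r.combo)
        retained = sorted(
            c for c, combos in combos_per_cell.items()
            if len(combos) >= min_combos_per_cell
        )
        eligible = max_syn > min_synergy and len(retained) >= min_cells
        rows.append(
            {
                "target1": pair[0],
                "target2": pair[1],
                "max_synergy": max_syn,
                "n_cells_retained": len(retained),
                "retained_cells": retained,
                "eligible": eligible,
            }
        )
    return pd.DataFrame(rows)


def aggregate_observed_synergy(
    records: list[SynergyRecord], level: str = "pair_top3"
):
    """Aggregate observed synergy.

    ``pair_top3``: mean of the 3 largest scores among the records (all if
    fewer than 3, with a warning). ``per_cell_mean``: per-cell mean across
    that cell's combinations, returned as a Series indexed by cell.
    """
    if not records:
        raise ValueError("no records to aggregate")
    if level == "pair_top3":
        scores = sorted((r.synergy for r in records), reverse=True)
        if len(scores) < 3:
            warnings.warn(
                f"fewer than 3 records ({len(scores)}); averaging all", stacklevel=2
            )
        return float(np.mean(scores[:3]))
    if level == "per_cell_mean":
        per_cell: dict[str, list[float]] = {}
        for r in records:
            per_cell.setdefault(r.cell, []).append(r.synergy)
        return pd.Series(
            {c: float(np.mean(v)) for c, v in sorted(per_cell.items())},
            name="observed_synergy",
        )
    raise ValueError(f"unknown aggregation level {level!r}")


def select_group_sizes_loocv(
    rankings: PathwayRanking,
    mechanism: int,
    pa: PathwayActivityMatrix,
    observed: pd.Series,
    genomics: pd.DataFrame | None = None,
    genomics_terms: list[tuple[str, int]] | None = None,
    candidates=tuple(itertools.product((1, 2, 3), (1, 2, 3))),
) -> tuple[int, int, float]:
    """Pick (N, M) by leave-one-out cross-validation against observed synergy.

    For each candidate, each cell is left out in turn, the spec is built on
    the fixed rankings, and the held-out cell's Delta PA is predicted. The
    candidate maximizing the Pearson r of LOOCV predictions vs observations
    wins; ties break towards smaller N+M, then smaller N.
    """
    cells = [c for c in observed.index if c in pa.values.index]
    if len(cells) < 3:
        raise ValueError("need at least 3 cells with observed synergy")
    obs = observed.loc[cells].to_numpy(dtype=float)
    results = []
    for N, M in candidates:
        preds = np.empty(len(cells))
        for i, cell in enumerate(cells):
            spec = build_model_spec(
                rankings, mechanism, N, M, genomics_terms=genomics_terms
            )
            scores = delta_pa(spec, pa, genomics)
            preds[i] = scores.values.loc[cell]
        if np.std(preds) == 0 or np.std(obs) == 0:
            warnings.warn(
                f"constant predictions for (N={N}, M={M}); skipped", stacklevel=2
            )
            continue
        r = float(stats.pearsonr(preds, obs).statistic)
        results.append((r, N + M, N, M))
    if not results:
        raise ValueError("no valid candidate: all correlations undefined")
    # max r; ties -> smaller N+M, then smaller N
    r_best = max(res[0] for res in results)
    tied = [res for res in results if np.isclose(res[0], r_best, atol=1e-12)]
    _, _, N_star, M_star = min(tied, key=lambda res: (res[1], res[2]))
    return N_star, M_star, r_best
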