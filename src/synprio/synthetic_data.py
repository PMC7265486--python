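"""Synthetic input panels with known ground truth.

Everything downstream (pathway scoring, factorization, similarity,
stratification, significance) can be exercised against these panels: the
generator keeps the true target x pathway interaction matrix, the true
pathway weights and the true synergy model, so recovery can be measured
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pathway_activity import DEFAULT_PATHWAYS, PathwayActivityMatrix
from .stratification import (
    MECHANISM_SIMILARITY,
    SynergyModelSpec,
    SynergyRecord,
    delta_pa,
)


@dataclass
class GroundTruth:
    """The generative state shared by all panel pieces."""

    interaction_true: pd.DataFrame  # targets x pathways, sensitivity-oriented
    pathway_weights_true: pd.DataFrame  # genes x pathways, orthonormal columns
    model_spec_true: SynergyModelSpec
    seed: int

    @property
    def targets(self) -> list[str]:
        return list(self.interaction_true.index)

    @property
    def pathways(self) -> list[str]:
        return list(self.interaction_true.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.pathway_weights_true.index)


@dataclass
class SyntheticPanel:
    """One complete synthetic input set (GDSC-like shape)."""

    expression: pd.DataFrame  # genes x cells
    response: pd.DataFrame  # drugs x cells, NaN = missing, IC50-like
    target_annotation: pd.DataFrame  # drugs x targets binary
    genomics: pd.DataFrame  # cells x markers binary
    pathway_activity_true: pd.DataFrame  # cells x pathways
    combo_records: list[SynergyRecord] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def truth(self) -> GroundTruth:
        return self.provenance["truth"]


def generate_ground_truth(
    n_targets: int,
    n_pathways: int,
    n_genes: int,
    effect_sd: float = 1.0,
    sparsity: float = 0.0,
    seed: int = 0,
) -> GroundTruth:
    """Draw a ground-truth interaction matrix, pathway weights and model spec.

    Interaction entries are i.i.d. N(0, effect_sd^2) with a fraction
    ``sparsity`` zeroed; rows that end up all-zero keep their largest-
    magnitude entry so every target interacts with at least one pathway.
    Pathway weights have orthonormal columns so scoring with them is
    well-conditioned.
    """
    if n_targets < 1 or n_genes < 1:
        raise ValueError("dimensions must be positive")
    if n_pathways < 2:
        raise ValueError("need at least 2 pathways")
    if not 0 <= sparsity < 1:
        raise ValueError("sparsity must be in [0, 1)")
    if n_genes < n_pathways:
        raise ValueError("need n_genes >= n_pathways for orthonormal weights")
    rng = np.random.default_rng(seed)

    targets = [f"T{i:02d}" for i in range(n_targets)]
    pathways = (
        list(DEFAULT_PATHWAYS)
        if n_pathways == len(DEFAULT_PATHWAYS)
        else [f"PW{j:02d}" for j in range(n_pathways)]
    )
    genes = [f"G{k:04d}" for k in range(n_genes)]

    inter = rng.normal(0.0, effect_sd, size=(n_targets, n_pathways))
    mask = rng.random(size=inter.shape) < sparsity
    kept = inter.copy()
    kept[mask] = 0.0
    for i in range(n_targets):
        if not np.any(kept[i]):  # regeneration rule: keep the strongest entry
            j = int(np.argmax(np.abs(inter[i])))
            kept[i, j] = inter[i, j]

    W, _ = np.linalg.qr(rng.normal(size=(n_genes, n_pathways)))

    n_sens = int(rng.integers(1, 4))
    n_res = int(rng.integers(1, 4))
    # spec groups follow the mean profile of the first two targets so that
    # ranking the true interactions recovers them
    profile = kept[: min(2, n_targets)].mean(axis=0)
    order = np.argsort(-profile, kind="stable")
    sensitive = [pathways[j] for j in order[:n_sens]]
    resistant = [pathways[j] for j in order[::-1][:n_res]]
    spec = SynergyModelSpec(
        mechanism=MECHANISM_SIMILARITY,
        sensitive_pathways=sensitive,
        resistant_pathways=resistant,
    )
    return GroundTruth(
        interaction_true=pd.DataFrame(kept, index=targets, columns=pathways),
        pathway_weights_true=pd.DataFrame(W, index=genes, columns=pathways),
        model_spec_true=spec,
        seed=seed,
    )


def _repair_mask(observed: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Ensure every row and column keeps at least one observation."""
    out = observed.copy()
    for i in np.where(~out.any(axis=1))[0]:
        out[i, rng.integers(out.shape[1])] = True
    for j in np.where(~out.any(axis=0))[0]:
        out[rng.integers(out.shape[0]), j] = True
    return out


def generate_panel(
    truth: GroundTruth,
    n_drugs: int,
    n_cells: int,
    noise_sd: float = 0.3,
    missing_frac: float = 0.0,
    expr_noise_sd: float = 0.1,
    n_markers: int = 5,
    seed: int = 0,
) -> SyntheticPanel:
    """Generate a full panel consistent with ``truth``.

    Pathway activities P are standard normal; expression = W @ P' + noise so
    scoring with the true weights recovers P; response is IC50-oriented:
    Y = -(X_D @ interaction @ P') + per-drug offset + noise, masked at rate
    ``missing_frac`` (mask repaired so no drug/cell is fully missing).
    """
    n_targets = len(truth.targets)
    if n_drugs < n_targets:
        raise ValueError("need n_drugs >= n_targets so every target is drugged")
    if not 0 <= missing_frac < 1:
        raise ValueError("missing_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)

    cells = [f"C{j:03d}" for j in range(n_cells)]
    drugs = [f"D{i:03d}" for i in range(n_drugs)]
    pathways = truth.pathways

    P = rng.standard_normal((n_cells, len(pathways)))
    W = truth.pathway_weights_true.to_numpy()
    expression = W @ P.T + rng.normal(0.0, expr_noise_sd, size=(W.shape[0], n_cells))

    # one target per drug, cycling so each target gets >= 1 drug
    X_D = np.zeros((n_drugs, n_targets))
    X_D[np.arange(n_drugs), np.arange(n_drugs) % n_targets] = 1.0
    offsets = rng.standard_normal(n_drugs)
    Y = (
        -(X_D @ truth.interaction_true.to_numpy() @ P.T)
        + offsets[:, None]
        + rng.normal(0.0, noise_sd, size=(n_drugs, n_cells))
    )
    observed = rng.random(size=Y.shape) >= missing_frac
    observed = _repair_mask(observed, rng)
    Y = np.where(observed, Y, np.nan)

    genomics = pd.DataFrame(
        (rng.random(size=(n_cells, n_markers)) < 0.3).astype(int),
        index=cells,
        columns=[f"M{k:02d}" for k in range(n_markers)],
    )
    return SyntheticPanel(
        expression=pd.DataFrame(expression, index=truth.genes, columns=cells),
        response=pd.DataFrame(Y, index=drugs, columns=cells),
        target_annotation=pd.DataFrame(
            X_D.astype(int), index=drugs, columns=truth.targets
        ),
        genomics=genomics,
        pathway_activity_true=pd.DataFrame(P, index=cells, columns=pathways),
        provenance={
            "truth": truth,
            "noise_sd": noise_sd,
            "expr_noise_sd": expr_noise_sd,
            "missing_frac": missing_frac,
            "seed": seed,
        },
    )


def true_delta_pa(truth: GroundTruth, panel: SyntheticPanel) -> pd.Series:
    """Noiseless per-cell Delta PA under the true model spec, scaled to ~+/-30."""
    pa = PathwayActivityMatrix(panel.pathway_activity_true, standardized=True)
    raw = delta_pa(truth.model_spec_true, pa, panel.genomics).values
    peak = np.max(np.abs(raw.to_numpy()))
    scale = 30.0 / peak if peak > 0 else 1.0
    return raw * scale


def generate_synergy_labels(
    truth: GroundTruth,
    panel: SyntheticPanel,
    target_pair: tuple[str, str],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[SynergyRecord]:
    """Emit synergy records for every drug pair annotating the target pair.

    Each record's score is the cell's true Delta PA (scaled into the
    synergy-score range) plus independent N(0, noise_sd) noise.
    """
    rng = np.random.default_rng(seed)
    ann = panel.target_annotation
    for t in target_pair:
        if t not in ann.columns or ann[t].sum() == 0:
            raise ValueError(f"no drugs annotate target {t!r}")
    drugs1 = list(ann.index[ann[target_pair[0]] == 1])
    drugs2 = list(ann.index[ann[target_pair[1]] == 1])
    base = true_delta_pa(truth, panel)
    records = []
    for d1 in drugs1:
        for d2 in drugs2:
            if d1 == d2:
                continue
            for cell, score in base.items():
                records.append(
                    SynergyRecord(
                        drug1=d1,
                        drug2=d2,
                        cell=cell,
                        synergy=float(score + rng.normal(0.0, noise_sd))
                        if noise_sd > 0
                        else float(score),
                    )
                )
    return records
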