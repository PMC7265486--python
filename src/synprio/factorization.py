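"""Bayesian matrix factorization with side information (Macau-style).

The drug-response matrix is modelled as a product of two latent matrices
whose row priors are linked to side information (drug targets, cell-line
pathway activities) through link matrices. A Gibbs chain samples latents,
link matrices, normal-Wishart hyperparameters and the noise precision; the
target x pathway interaction matrix is the posterior mean of the product of
the two link matrices, sign-flipped for IC50-oriented input so positive
means "pathway activation associates with sensitivity".

Link matrices are sampled from their exact matrix-normal conditionals; the
feature dimensions here are small, so no approximate solver is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import wishart


@dataclass
class ResponseMatrix:
    """Drugs x cells response values; NaN marks a missing measurement."""

    values: pd.DataFrame
    orientation: str = "ic50"  # 'ic50' (higher = resistant) or 'sensitivity'
    standardized_per_drug: bool = False

    def __post_init__(self) -> None:
        if self.orientation not in ("ic50", "sensitivity"):
            raise ValueError("orientation must be 'ic50' or 'sensitivity'")
        obs = ~self.values.isna()
        if not obs.any(axis=1).all():
            bad = list(self.values.index[~obs.any(axis=1)])
            raise ValueError(f"drug rows with no observations: {bad}")
        if not obs.any(axis=0).all():
            bad = list(self.values.columns[~obs.any(axis=0)])
            raise ValueError(f"cell columns with no observations: {bad}")

    @property
    def drugs(self) -> list[str]:
        return list(self.values.index)

    @property
    def cells(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SideInfo:
    """Row-entity side features: binary drug targets, real cell pathways."""

    drug_side: pd.DataFrame | None = None  # drugs x targets
    cell_side: pd.DataFrame | None = None  # cells x pathways

    def __post_init__(self) -> None:
        if self.drug_side is not None:
            v = self.drug_side.to_numpy()
            if not np.isfinite(v).all():
                raise ValueError("NaN/inf in drug side information")
            if not np.isin(v, (0, 1)).all():
                raise ValueError("drug side information must be binary")
        if self.cell_side is not None and not np.isfinite(
            self.cell_side.to_numpy()
        ).all():
            raise ValueError("NaN/inf in cell side information")


@dataclass
class MacauConfig:
    L: int = 10
    n_burnin: int = 200
    n_samples: int = 600
    n_repeats: int = 40
    noise_precision_mode: str = "sampled"  # 'sampled' or 'fixed'
    tau: float = 1.0  # used when noise_precision_mode == 'fixed'
    link_prior_precision: float = 5.0
    sample_link_precision: bool = False
    sample_latent_hyperparams: bool = True
    latent_prior_precision: float = 2.0  # used when hyperparams are fixed
    standardize_per_drug: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.noise_precision_mode not in ("sampled", "fixed"):
            raise ValueError("noise_precision_mode must be 'sampled' or 'fixed'")


@dataclass
class MacauFit:
    """Collected post-burn-in Gibbs samples from one chain."""

    U: np.ndarray  # samples x drugs x L
    V: np.ndarray  # samples x cells x L
    beta_d: np.ndarray | None  # samples x targets x L
    beta_c: np.ndarray | None  # samples x pathways x L
    mu_u: np.ndarray  # samples x L
    mu_v: np.ndarray  # samples x L
    tau: np.ndarray  # samples
    rmse_trace: np.ndarray  # samples (training RMSE on observed entries)
    config: MacauConfig
    drugs: list[str] = field(default_factory=list)
    cells: list[str] = field(default_factory=list)
    targets: list[str] = field(default_factory=list)
    pathways: list[str] = field(default_factory=list)
    orientation: str = "ic50"
    drug_means: np.ndarray | None = None
    drug_sds: np.ndarray | None = None

    @property
    def n_collected(self) -> int:
        return self.U.shape[0]


@dataclass
class InteractionMatrix:
    """Targets x pathways interaction scores, sensitivity-oriented."""

    values: pd.DataFrame
    n_chains_averaged: int = 1
    tissue_label: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("interaction matrix must be finite")

    @property
    def targets(self) -> list[str]:
        return list(self.values.index)

    @property
    def pathways(self) -> list[str]:
        return list(self.values.columns)


def _sample_normal_wishart(
    rng: np.random.Generator, R: np.ndarray, b0: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior draw of (mu, Lambda) given latent residual rows R."""
    n, L = R.shape
    nu0 = L
    mu0 = np.zeros(L)
    W0_inv = np.eye(L)
    xbar = R.mean(axis=0)
    S = (R - xbar).T @ (R - xbar)
    b_n = b0 + n
    nu_n = nu0 + n
    mu_n = (b0 * mu0 + n * xbar) / b_n
    W_n_inv = W0_inv + S + (b0 * n / b_n) * np.outer(xbar - mu0, xbar - mu0)
    W_n = np.linalg.inv(W_n_inv)
    W_n = (W_n + W_n.T) / 2
    Lam = wishart.rvs(df=nu_n, scale=W_n, random_state=rng)
    Lam = np.atleast_2d(Lam)
    cov_mu = np.linalg.inv(b_n * Lam)
    mu = rng.multivariate_normal(mu_n, (cov_mu + cov_mu.T) / 2)
    return mu, Lam


def _sample_link(
    rng: np.random.Generator,
    X: np.ndarray,
    U: np.ndarray,
    mu: np.ndarray,
    Lam: np.ndarray,
    lam_beta: float,
) -> np.ndarray:
    """Exact matrix-normal draw of a link matrix beta (features x L)."""
    F = X.shape[1]
    A = X.T @ X + lam_beta * np.eye(F)
    L_A = np.linalg.cholesky(A)
    M = np.linalg.solve(A, X.T @ (U - mu))
    cov = np.linalg.inv(Lam)
    L_cov = np.linalg.cholesky((cov + cov.T) / 2)
    Z = rng.standard_normal((F, Lam.shape[0]))
    E = np.linalg.solve(L_A.T, Z) @ L_cov.T
    return M + E


def _sample_latents(
    rng: np.random.Generator,
    Y: np.ndarray,
    mask: np.ndarray,
    other: np.ndarray,
    prior_mean: np.ndarray,
    Lam: np.ndarray,
    tau: float,
) -> np.ndarray:
    """Batched conditional draw of all latent rows on one axis.

    Y, mask: n x m (missing entries zero-filled in Y); other: m x L latent
    matrix of the opposite axis; prior_mean: n x L.
    """
    n, L = Y.shape[0], Lam.shape[0]
    prior_mean = np.broadcast_to(np.atleast_2d(prior_mean), (n, L))
    # per-row precision: Lambda + tau * sum_obs v v'
    P = Lam[None, :, :] + tau * np.einsum("ij,jk,jl->ikl", mask, other, other)
    b = prior_mean @ Lam + tau * (Y * mask) @ other
    chol = np.linalg.cholesky(P)
    mean = np.linalg.solve(P, b[:, :, None])[:, :, 0]
    z = rng.standard_normal((n, L, 1))
    # solve L' x = z per row for a N(0, P^{-1}) draw
    noise = np.linalg.solve(np.transpose(chol, (0, 2, 1)), z)[:, :, 0]
    return mean + noise


def fit_macau(
    y: ResponseMatrix, side: SideInfo | None, cfg: MacauConfig
) -> MacauFit:
    """Run one Gibbs chain and return the collected posterior samples."""
    rng = np.random.default_rng(cfg.seed)
    drugs, cells = y.drugs, y.cells
    Y_raw = y.values.to_numpy(dtype=float)
    mask = ~np.isnan(Y_raw)

    drug_means = drug_sds = None
    if cfg.standardize_per_drug and not y.standardized_per_drug:
        drug_means = np.nanmean(Y_raw, axis=1)
        drug_sds = np.nanstd(Y_raw, axis=1)
        drug_sds = np.where(drug_sds > 0, drug_sds, 1.0)
        Y = (Y_raw - drug_means[:, None]) / drug_sds[:, None]
    else:
        Y = Y_raw.copy()
    Y = np.where(mask, Y, 0.0)
    maskf = mask.astype(float)
    n_obs = int(mask.sum())

    X_d = X_c = None
    targets: list[str] = []
    pathways: list[str] = []
    if side is not None and side.drug_side is not None:
        missing = [d for d in drugs if d not in side.drug_side.index]
        if missing:
            raise ValueError(f"drug side info missing rows: {missing}")
        X_d = side.drug_side.loc[drugs].to_numpy(dtype=float)
        targets = list(side.drug_side.columns)
    if side is not None and side.cell_side is not None:
        missing = [c for c in cells if c not in side.cell_side.index]
        if missing:
            raise ValueError(f"cell side info missing rows: {missing}")
        X_c = side.cell_side.loc[cells].to_numpy(dtype=float)
        pathways = list(side.cell_side.columns)

    n_d, n_c, L = len(drugs), len(cells), cfg.L
    U = rng.normal(0.0, 0.1, size=(n_d, L))
    V = rng.normal(0.0, 0.1, size=(n_c, L))
    beta_d = np.zeros((X_d.shape[1], L)) if X_d is not None else None
    beta_c = np.zeros((X_c.shape[1], L)) if X_c is not None else None
    mu_u = np.zeros(L)
    mu_v = np.zeros(L)
    Lam_u = cfg.latent_prior_precision * np.eye(L)
    Lam_v = cfg.latent_prior_precision * np.eye(L)
    tau = cfg.tau
    lam_beta = cfg.link_prior_precision

    S = cfg.n_samples
    out = MacauFit(
        U=np.empty((S, n_d, L)),
        V=np.empty((S, n_c, L)),
        beta_d=np.empty((S, X_d.shape[1], L)) if X_d is not None else None,
        beta_c=np.empty((S, X_c.shape[1], L)) if X_c is not None else None,
        mu_u=np.empty((S, L)),
        mu_v=np.empty((S, L)),
        tau=np.empty(S),
        rmse_trace=np.empty(S),
        config=cfg,
        drugs=drugs,
        cells=cells,
        targets=targets,
        pathways=pathways,
        orientation=y.orientation,
        drug_means=drug_means,
        drug_sds=drug_sds,
    )

    for it in range(cfg.n_burnin + S):
        side_mean_u = X_d @ beta_d if beta_d is not None else 0.0
        side_mean_v = X_c @ beta_c if beta_c is not None else 0.0

        if cfg.sample_latent_hyperparams:
            mu_u, Lam_u = _sample_normal_wishart(rng, U - side_mean_u)
            mu_v, Lam_v = _sample_normal_wishart(rng, V - side_mean_v)

        if beta_d is not None:
            beta_d = _sample_link(rng, X_d, U, mu_u, Lam_u, lam_beta)
            side_mean_u = X_d @ beta_d
        if beta_c is not None:
            beta_c = _sample_link(rng, X_c, V, mu_v, Lam_v, lam_beta)
            side_mean_v = X_c @ beta_c

        U = _sample_latents(rng, Y, maskf, V, mu_u + side_mean_u, Lam_u, tau)
        V = _sample_latents(rng, Y.T, maskf.T, U, mu_v + side_mean_v, Lam_v, tau)

        resid = (Y - U @ V.T) * maskf
        sse = float((resid**2).sum())
        if cfg.noise_precision_mode == "sampled":
            tau = rng.gamma(shape=2.0 + n_obs / 2.0, scale=1.0 / (2.0 + sse / 2.0))

        rmse = np.sqrt(sse / n_obs)
        if not np.isfinite(rmse):
            raise FloatingPointError(f"divergent chain: non-finite RMSE at iteration {it}")

        s = it - cfg.n_burnin
        if s >= 0:
            out.U[s] = U
            out.V[s] = V
            if beta_d is not None:
                out.beta_d[s] = beta_d
            if beta_c is not None:
                out.beta_c[s] = beta_c
            out.mu_u[s] = mu_u
            out.mu_v[s] = mu_v
            out.tau[s] = tau
            out.rmse_trace[s] = rmse
    return out


def interaction_matrix(fit: MacauFit, orientation: str | None = None) -> InteractionMatrix:
    """Posterior mean of beta_d @ beta_c', sign-fixed to sensitivity orientation."""
    if fit.beta_d is None or fit.beta_c is None:
        raise ValueError("fit has no link matrices on both axes")
    if fit.n_collected < 1:
        raise ValueError("fit has no collected samples")
    prod = np.einsum("stl,spl->tp", fit.beta_d, fit.beta_c) / fit.n_collected
    orient = orientation if orientation is not None else fit.orientation
    if orient == "ic50":
        prod = -prod
    return InteractionMatrix(
        values=pd.DataFrame(prod, index=fit.targets, columns=fit.pathways),
        n_chains_averaged=1,
    )


def averaged_interactions(
    y: ResponseMatrix, side: SideInfo, cfg: MacauConfig
) -> InteractionMatrix:
    """Average the interaction matrices of n_repeats independent chains."""
    if cfg.n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    seeds = derive_chain_seeds(cfg.seed, cfg.n_repeats)
    total = None
    for chain_seed in seeds:
        try:
            fit = fit_macau(y, side, replace(cfg, seed=chain_seed))
        except FloatingPointError as exc:
            raise RuntimeError(f"chain with seed {chain_seed} failed: {exc}") from exc
        mat = interaction_matrix(fit).values
        total = mat if total is None else total + mat
    return InteractionMatrix(
        values=total / cfg.n_repeats,
        n_chains_averaged=cfg.n_repeats,
    )


def derive_chain_seeds(master_seed: int, n: int) -> list[int]:
    """Distinct per-chain seeds derived from a master seed."""
    seq = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0]) for s in seq.spawn(n)]


def predict_response(fit: MacauFit, new_cell_side: pd.DataFrame) -> pd.DataFrame:
    """Predict drugs x new-cells response from posterior samples.

    Per sample, the new cell's latent mean is mu_v + beta_c' x; predictions
    U @ latent' are averaged over samples and mapped back to the original
    per-drug scale if the fit standardized its input.
    """
    if fit.beta_c is None:
        raise ValueError("fit was trained without cell side information")
    missing = [p for p in fit.pathways if p not in new_cell_side.columns]
    if missing:
        raise ValueError(f"new cell side info missing pathways: {missing}")
    X = new_cell_side[fit.pathways].to_numpy(dtype=float)
    S = fit.n_collected
    pred = np.zeros((len(fit.drugs), X.shape[0]))
    for s in range(S):
        v_new = fit.mu_v[s][None, :] + X @ fit.beta_c[s]
        pred += fit.U[s] @ v_new.T
    pred /= S
    if fit.drug_means is not None:
        pred = pred * fit.drug_sds[:, None] + fit.drug_means[:, None]
    return pd.DataFrame(pred, index=fit.drugs, columns=list(new_cell_side.index))


def stability_report(
    matrices: list[InteractionMatrix],
    subsample_size: int,
    n_draws: int = 50,
    seed: int = 0,
) -> dict:
    """Robustness of the averaged interaction matrix under subsampling.

    Draws ``n_draws`` random subsets of ``subsample_size`` matrices, averages
    each, and reports (i) mean/sd of pairwise Pearson correlations between
    the vectorized averages and (ii) the per-target-pair coefficient of
    variation of functional similarity across the averages.
    """
    if len(matrices) < 2:
        raise ValueError("need at least 2 interaction matrices")
    if subsample_size > len(matrices):
        raise ValueError("subsample_size exceeds number of matrices")
    if n_draws < 2:
        raise ValueError("need n_draws >= 2 for pairwise statistics")
    rng = np.random.default_rng(seed)
    stack = np.stack([m.values.to_numpy() for m in matrices])
    averages = np.stack(
        [
            stack[rng.choice(len(matrices), size=subsample_size, replace=False)].mean(
                axis=0
            )
            for _ in range(n_draws)
        ]
    )

    flat = averages.reshape(n_draws, -1)
    corr = np.corrcoef(flat)
    iu = np.triu_indices(n_draws, k=1)
    pair_r = corr[iu]

    targets = matrices[0].targets
    n_t = len(targets)
    cv_rows = []
    for a in range(n_t):
        for b in range(a + 1, n_t):
            sims = np.array(
                [np.corrcoef(avg[a], avg[b])[0, 1] for avg in averages]
            )
            mean_sim = sims.mean()
            cv = np.abs(sims.std(ddof=1) / mean_sim) if mean_sim != 0 else np.nan
            cv_rows.append(
                {
                    "target1": targets[a],
                    "target2": targets[b],
                    "mean_similarity": float(mean_sim),
                    "cv": float(cv),
                }
            )
    return {
        "mean_pairwise_r": float(pair_r.mean()),
        "sd_pairwise_r": float(pair_r.std(ddof=1)),
        "similarity_cv": pd.DataFrame(cv_rows),
        "subsample_size": subsample_size,
        "n_draws": n_draws,
    }
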