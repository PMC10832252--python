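"""Synthetic cohort generator with analytic ground truth.

The generator emulates the structure of a school-cohort lifestyle study:
an insulin-resistance-like outcome, two confounders (a binary sex
indicator and a narrow-range continuous age), a 3-variable adiposity block
with strong pairwise correlation, a 23-variable physical-activity (PA)
intensity spectrum with serial correlation decaying along the intensity
index, and a 26-variable lipoprotein-like mediator block generated from a
handful of latent factors — hence exactly rank-deficient, optionally with
duplicated columns on top.

Everything is a linear Gaussian structural model.  Writing each observed
variable as a linear map B of independent sources u (sex, age, the
explanatory shocks S, the factor shocks E_F, the outcome noise), the
population covariance is B Cov(u) B^T, so the "true" net association
pattern and the mediated variance share can be computed exactly, with no
sampling, by residualizing that covariance on the confounders and on the
population target score of the mediator block.  Those population
quantities are the ground truth against which parameter recovery is
judged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "generate",
    "population_truth",
    "recovery_report",
]

N_ADIPOSITY = 3
N_PA = 23


def _pa_bump(center: float, width: float, height: float) -> np.ndarray:
    """Smooth effect profile over the 23 PA intensity intervals."""
    i = np.arange(N_PA)
    return height * np.exp(-(((i - center) / width) ** 2))


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic cohort.

    Defaults emulate the real cohort's scale: 836 subjects, sex split
    50/50, near-inert age, adiposity r ~ 0.8 within block, PA serial
    correlation 0.9, a rank-4 mediator block of 26 observed features, and
    effect sizes giving a moderately predictive outcome (roughly a third
    of outcome variance explainable before adjustment).
    """

    n_subjects: int = 836
    seed: int = 0

    # confounders
    p_binary: float = 0.5  # Bernoulli probability of the sex indicator
    sd_continuous: float = 1.0  # age scale (standardized later anyway)

    # explanatory structure
    r_adiposity: float = 0.8  # common within-block correlation
    rho_pa: float = 0.9  # AR(1) decay along the intensity index
    r_cross: float = -0.15  # adiposity vs PA block correlation

    # mediator block
    n_mediator: int = 26
    k_factors: int = 4
    n_duplicates: int = 0  # extra exact copies of leading mediator columns
    sd_factor_noise: tuple = (0.8, 0.9, 1.0, 1.0)

    # outcome noise
    sd_y: float = 2.1

    # marginals: exponentiate all non-confounder variables so that a
    # log-transform-then-standardize pipeline recovers the Gaussian scale
    lognormal_marginals: bool = False

    # coefficient sets (filled with defaults when left None)
    sex_to_x: np.ndarray | None = None
    age_to_x: np.ndarray | None = None
    x_to_factors: np.ndarray | None = None  # M x k
    sex_to_factors: np.ndarray | None = None
    age_to_factors: np.ndarray | None = None
    factor_loadings: np.ndarray | None = None  # n_mediator x k
    factors_to_y: np.ndarray | None = None
    x_to_y: np.ndarray | None = None  # direct (net) effects
    sex_to_y: float = 0.15
    age_to_y: float = 0.02

    def __post_init__(self) -> None:
        m = self.n_explanatory
        k = self.k_factors
        if self.sex_to_x is None:
            # girls higher skinfold, boys more mid/high-intensity PA
            self.sex_to_x = np.concatenate(
                [np.array([0.0, 0.0, -0.45]), _pa_bump(12.0, 6.0, 0.30)]
            )
        if self.age_to_x is None:
            self.age_to_x = np.full(m, 0.05)
        if self.x_to_factors is None:
            g = np.zeros((m, k))
            g[:N_ADIPOSITY, 0] = 0.15  # adiposity drives the first lipid axis
            g[N_ADIPOSITY:, 0] = -_pa_bump(16.0, 6.0, 0.05)
            g[N_ADIPOSITY:, 1] = _pa_bump(10.0, 8.0, 0.075)
            self.x_to_factors = g
        if self.sex_to_factors is None:
            self.sex_to_factors = np.array([0.20, 0.0, 0.10, 0.0])[:k]
        if self.age_to_factors is None:
            self.age_to_factors = np.zeros(k)
        if self.factor_loadings is None:
            i = np.arange(self.n_mediator)
            cols = [
                np.ones(self.n_mediator),
                0.7 * np.sin(2 * np.pi * i / self.n_mediator),
                0.7 * np.cos(2 * np.pi * i / self.n_mediator),
                0.5 * np.sin(4 * np.pi * i / self.n_mediator + 0.5),
            ]
            self.factor_loadings = np.column_stack(cols[:k])
        if self.factors_to_y is None:
            self.factors_to_y = np.array([0.32, 0.16, 0.077, 0.051])[:k]
        if self.x_to_y is None:
            beta = np.concatenate(
                [np.array([0.275, 0.22, 0.22]), -_pa_bump(18.0, 5.0, 0.132)]
            )
            self.x_to_y = beta
        for name in ("sex_to_x", "age_to_x", "x_to_y"):
            if len(getattr(self, name)) != m:
                raise ValueError(f"{name} must have length {m}")

    @property
    def n_explanatory(self) -> int:
        return N_ADIPOSITY + N_PA

    # -- structural matrices ----------------------------------------------
    def explanatory_shock_cov(self) -> np.ndarray:
        """Covariance of the explanatory shocks S (the 26 x 26 block)."""
        m = self.n_explanatory
        cov = np.empty((m, m))
        for i in range(m):
            for j in range(m):
                in_a = i < N_ADIPOSITY
                jn_a = j < N_ADIPOSITY
                if in_a and jn_a:
                    cov[i, j] = 1.0 if i == j else self.r_adiposity
                elif not in_a and not jn_a:
                    cov[i, j] = self.rho_pa ** abs(i - j)
                else:
                    cov[i, j] = self.r_cross
        eig = np.linalg.eigvalsh(cov)
        if eig.min() <= 1e-10:
            raise ValueError(
                "infeasible correlation settings: explanatory shock "
                f"covariance is not positive definite (min eig {eig.min():.2e})"
            )
        return cov

    def source_maps(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Linear maps from sources u = [sex, age, S, E_F, eps] to data.

        Returns (B_y, B_X, B_Z, cov_u_diag_blocks) with shapes
        (1, d), (M, d), (V_m + dup, d); d = 2 + M + k + 1.
        """
        m, k = self.n_explanatory, self.k_factors
        d = 2 + m + k + 1
        B_X = np.zeros((m, d))
        B_X[:, 0] = self.sex_to_x
        B_X[:, 1] = self.age_to_x
        B_X[:, 2 : 2 + m] = np.eye(m)
        B_F = self.x_to_factors.T @ B_X
        B_F[:, 0] += self.sex_to_factors
        B_F[:, 1] += self.age_to_factors
        B_F[:, 2 + m : 2 + m + k] = np.eye(k)
        B_Z = self.factor_loadings @ B_F
        if self.n_duplicates:
            B_Z = np.vstack([B_Z, B_Z[: self.n_duplicates]])
        B_y = (self.x_to_y @ B_X + self.factors_to_y @ B_F).reshape(1, d)
        B_y[0, 0] += self.sex_to_y
        B_y[0, 1] += self.age_to_y
        B_y[0, -1] = 1.0
        return B_y, B_X, B_Z, self._cov_u()

    def _cov_u(self) -> np.ndarray:
        m, k = self.n_explanatory, self.k_factors
        var_sex = self.p_binary * (1 - self.p_binary)
        blocks = np.zeros((2 + m + k + 1, 2 + m + k + 1))
        blocks[0, 0] = var_sex
        blocks[1, 1] = self.sd_continuous**2
        blocks[2 : 2 + m, 2 : 2 + m] = self.explanatory_shock_cov()
        sd_f = np.asarray(self.sd_factor_noise)[:k]
        blocks[2 + m : 2 + m + k, 2 + m : 2 + m + k] = np.diag(sd_f**2)
        blocks[-1, -1] = self.sd_y**2
        return blocks

    def column_names(self) -> dict[str, list[str]]:
        adip = ["bmi", "wc_height", "skinfold"]
        pa = [f"pa_{i + 1:02d}" for i in range(N_PA)]
        med = [f"lp_{i + 1:02d}" for i in range(self.n_mediator)]
        med += [f"lp_dup_{i + 1:02d}" for i in range(self.n_duplicates)]
        return {
            "outcome": ["outcome"],
            "confounders": ["sex", "age"],
            "adiposity": adip,
            "pa": pa,
            "mediator": med,
        }


@dataclass
class GroundTruth:
    """Population quantities the pipeline is supposed to recover."""

    net_pattern: np.ndarray  # population net TP loading over explanatory vars
    net_b: np.ndarray  # population net regression coefficients
    net_explained_y_fraction: float  # after confounders + mediator adjustment
    explained_y_confounders_only: float  # after confounders only
    mediated_share: float  # drop in explained outcome variance
    correlation: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    names: list[str] = field(default_factory=list)


def _joint_correlation(spec: FixtureSpec) -> tuple[np.ndarray, dict[str, slice]]:
    """Population correlation matrix of [y, sex, age, Z, X], plus slices."""
    B_y, B_X, B_Z, cov_u = spec.source_maps()
    B = np.vstack([B_y, np.zeros((2, cov_u.shape[0])), B_Z, B_X])
    B[1, 0] = 1.0  # sex
    B[2, 1] = 1.0  # age
    sigma = B @ cov_u @ B.T
    sd = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(sd, sd)
    v_m = B_Z.shape[0]
    slices = {
        "y": slice(0, 1),
        "conf": slice(1, 3),
        "Z": slice(3, 3 + v_m),
        "X": slice(3 + v_m, 3 + v_m + spec.n_explanatory),
    }
    return corr, slices


def population_truth(spec: FixtureSpec) -> GroundTruth:
    """Exact net pattern and mediated share from the population covariance.

    Independent of the projection implementation: uses only covariance
    algebra.  The mediator's population target direction is the
    minimum-norm least-squares solution b_Z = Sigma_Z^+ sigma_Zy (which is
    what a full-predictive-rank PLS model's regression vector converges
    to); residualization on a covariate set is the Schur complement of the
    joint covariance.
    """
    corr, sl = _joint_correlation(spec)

    def residual_cov(cov: np.ndarray, keep: np.ndarray, on: np.ndarray) -> np.ndarray:
        c_kk = cov[np.ix_(keep, keep)]
        c_ko = cov[np.ix_(keep, on)]
        c_oo = cov[np.ix_(on, on)]
        return c_kk - c_ko @ np.linalg.pinv(c_oo) @ c_ko.T

    idx = np.arange(corr.shape[0])
    iy = idx[sl["y"]]
    iconf = idx[sl["conf"]]
    iZ = idx[sl["Z"]]
    iX = idx[sl["X"]]

    # population target direction of the mediator block (unadjusted fit)
    b_z = np.linalg.pinv(corr[np.ix_(iZ, iZ)]) @ corr[np.ix_(iZ, iy)].ravel()

    # extend the covariance with the score variable s = Z b_z
    n = corr.shape[0]
    ext = np.zeros((n + 1, n + 1))
    ext[:n, :n] = corr
    cov_s = corr[:, iZ] @ b_z
    ext[:n, n] = cov_s
    ext[n, :n] = cov_s
    ext[n, n] = float(b_z @ corr[np.ix_(iZ, iZ)] @ b_z)

    keep = np.concatenate([iy, iX])

    def net_explained(on: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        net = residual_cov(ext, keep, on)
        s_xy = net[1:, 0]
        s_xx = net[1:, 1:]
        b = np.linalg.pinv(s_xx) @ s_xy
        explained = float(s_xy @ b)  # Var(yhat); original Var(y) = 1
        var_t = float(b @ s_xx @ b)
        pattern = s_xx @ b / var_t if var_t > 0 else np.zeros_like(b)
        return explained, b, pattern

    expl_conf, _, _ = net_explained(iconf)
    expl_full, b_net, pattern = net_explained(np.append(iconf, n))

    return GroundTruth(
        net_pattern=pattern,
        net_b=b_net,
        net_explained_y_fraction=expl_full,
        explained_y_confounders_only=expl_conf,
        mediated_share=expl_conf - expl_full,
        correlation=corr,
        names=sum(spec.column_names().values(), []),
    )


def generate(spec: FixtureSpec):
    """Draw one cohort; returns (DataTable, GroundTruth).

    Bit-identical for a given (spec, seed).  Column roles are pre-assigned:
    outcome / covariate (sex, age, mediator block) / explanatory
    (adiposity + PA).
    """
    from .datatable import DataTable

    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    m, k = spec.n_explanatory, spec.k_factors

    sex = (rng.random(n) < spec.p_binary).astype(float)
    age = rng.normal(0.0, spec.sd_continuous, size=n)
    chol = np.linalg.cholesky(spec.explanatory_shock_cov())
    S = rng.standard_normal((n, m)) @ chol.T
    E_F = rng.standard_normal((n, k)) * np.asarray(spec.sd_factor_noise)[:k]
    eps = rng.normal(0.0, spec.sd_y, size=n)

    X = np.outer(sex, spec.sex_to_x) + np.outer(age, spec.age_to_x) + S
    F = X @ spec.x_to_factors + np.outer(sex, spec.sex_to_factors)
    F += np.outer(age, spec.age_to_factors) + E_F
    Z = F @ spec.factor_loadings.T
    if spec.n_duplicates:
        Z = np.hstack([Z, Z[:, : spec.n_duplicates]])
    y = X @ spec.x_to_y + F @ spec.factors_to_y
    y += sex * spec.sex_to_y + age * spec.age_to_y + eps

    names = spec.column_names()
    columns = [y.reshape(-1, 1), sex.reshape(-1, 1), age.reshape(-1, 1), Z, X]
    values = np.hstack(columns)
    all_names = (
        names["outcome"]
        + names["confounders"]
        + names["mediator"]
        + names["adiposity"]
        + names["pa"]
    )
    if spec.lognormal_marginals:
        keep = {"sex", "age"}
        for j, name in enumerate(all_names):
            if name not in keep:
                values[:, j] = np.exp(values[:, j])
    roles = {n_: "covariate" for n_ in names["confounders"] + names["mediator"]}
    roles["outcome"] = "outcome"
    roles.update({n_: "explanatory" for n_ in names["adiposity"] + names["pa"]})
    table = DataTable(values=values, column_names=all_names, column_roles=roles)
    return table, population_truth(spec)


def recovery_report(
    estimated_pattern: np.ndarray,
    estimated_explained_y: float,
    truth: GroundTruth,
    estimated_mediated_share: float | None = None,
) -> dict:
    """Compare an estimated net pattern and variance shares to the truth."""
    est = np.asarray(estimated_pattern, dtype=float).ravel()
    tru = truth.net_pattern
    if est.shape != tru.shape:
        raise ValueError("estimated pattern length does not match the truth")
    r = float(np.corrcoef(est, tru)[0, 1])
    report = {
        "pattern_correlation": r,
        "explained_y_bias": float(estimated_explained_y - truth.net_explained_y_fraction),
    }
    if estimated_mediated_share is not None:
        report["mediated_share_error"] = float(
            estimated_mediated_share - truth.mediated_share
        )
    return report
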