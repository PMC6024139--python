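"""Bayesian linear regression of band power on cubic age, group, and covariates.

The model regresses a subject's epoch band power (dB) on a group indicator,
centered age and its square and cube, group×age interactions at each order,
and dosing/demographic covariates. Inference uses the Jeffreys noninformative
prior p(β, σ²) ∝ 1/σ², for which the Gibbs sampler alternates the conjugate
conditionals

    β | σ², y ~ N(β̂_OLS, σ² (XᵀX)⁻¹)
    σ² | β, y ~ Inv-Gamma(n/2, ‖y − Xβ‖²/2).

Summaries report posterior medians and 80% highest-posterior-density (HPD)
intervals per coefficient, matching the study's reporting convention; group
contrasts at a given age combine the group main effect with the interaction
terms, with "certainty" defined as Pr(power_ASD < power_NT).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import Group

#: Covariates adjusted for, in design-matrix order after the age terms.
COVARIATES = ("sex", "infusion", "bolus", "midazolam", "fentanyl", "epilepsy")


@dataclass
class RegressionDesign:
    """Design matrix and response for one band's model."""

    X: np.ndarray
    y: np.ndarray
    names: list[str]
    age_center: float
    poly_order: int = 3

    def __post_init__(self) -> None:
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")


def build_design(
    data: pd.DataFrame, response: str, poly_order: int = 3
) -> RegressionDesign:
    """Build the cubic-age group-interaction design from a tidy cohort table.

    ``data`` needs columns group, age_years, sex, infusion, bolus, midazolam,
    fentanyl, epilepsy, and the ``response`` band-power column. Age is
    centered at the cohort mean before polynomial and interaction expansion;
    group (ASD), male sex and epilepsy are coded 0/1.
    """
    cols = ["group", "age_years", *COVARIATES[1:], "sex", response]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if data[cols].isna().any().any():
        raise ValueError("missing covariate or response values")
    n = len(data)
    group = np.asarray(
        [1.0 if Group(g) is Group.ASD else 0.0 for g in data["group"]]
    )
    age_c = data["age_years"].to_numpy(float)
    center = float(age_c.mean())
    age_c = age_c - center
    sex = np.asarray(
        [1.0 if str(s).lower() in ("male", "m", "1", "true") else 0.0
         for s in data["sex"]]
    )
    epilepsy = data["epilepsy"].astype(bool).to_numpy().astype(float)

    columns = [np.ones(n), group]
    names = ["intercept", "group_asd"]
    for d in range(1, poly_order + 1):
        columns.append(age_c ** d)
        names.append(f"age{d if d > 1 else ''}")
    for d in range(1, poly_order + 1):
        columns.append(group * age_c ** d)
        names.append(f"group_x_age{d if d > 1 else ''}")
    for nm, col in (("sex_male", sex),
                    ("infusion", data["infusion"].to_numpy(float)),
                    ("bolus", data["bolus"].to_numpy(float)),
                    ("midazolam", data["midazolam"].to_numpy(float)),
                    ("fentanyl", data["fentanyl"].to_numpy(float)),
                    ("epilepsy", epilepsy)):
        # constant covariates (e.g. no midazolam given in a small cohort)
        # carry no information and would only break the rank requirement
        if np.ptp(col) > 0:
            columns.append(col)
            names.append(nm)
    X = np.column_stack(columns)
    y = data[response].to_numpy(float)
    return RegressionDesign(X, y, names, center, poly_order)


@dataclass
class PosteriorSummary:
    names: list[str]
    medians: dict[str, float]
    hpd80: dict[str, tuple[float, float]]
    sigma2_median: float
    sigma2_hpd80: tuple[float, float]
    draws: np.ndarray            # kept draws × coefficients
    sigma2_draws: np.ndarray
    age_center: float
    poly_order: int
    settings: dict = field(default_factory=dict)

    def coefficient_draws(self, name: str) -> np.ndarray:
        return self.draws[:, self.names.index(name)]

    def to_table(self) -> pd.DataFrame:
        """Coefficient table in the 50% / 80% HPD reporting layout."""
        rows = [
            {"parameter": nm, "median": self.medians[nm],
             "hpd80_lo": self.hpd80[nm][0], "hpd80_hi": self.hpd80[nm][1]}
            for nm in self.names
        ]
        rows.append({"parameter": "sigma2", "median": self.sigma2_median,
                     "hpd80_lo": self.sigma2_hpd80[0],
                     "hpd80_hi": self.sigma2_hpd80[1]})
        return pd.DataFrame(rows)


def gibbs_sample(
    design: RegressionDesign,
    iterations: int = 10_000,
    burn_in: int = 1_000,
    thin: int = 1,
    seed: int = 0,
) -> PosteriorSummary:
    """Gibbs sampler for the normal linear model under the Jeffreys prior.

    Runs ``burn_in`` warm-up sweeps followed by ``iterations`` sweeps, keeping
    every ``thin``-th draw. Reproducible under ``seed``.
    """
    X, y = design.X, design.y
    n, p = X.shape
    if n <= p:
        raise ValueError("need more subjects than coefficients")
    rng = np.random.default_rng(seed)
    XtX = X.T @ X
    L = np.linalg.cholesky(XtX)
    beta_hat = np.linalg.solve(XtX, X.T @ y)
    resid0 = y - X @ beta_hat
    sigma2 = float(resid0 @ resid0) / max(n - p, 1)

    kept = iterations // thin
    draws = np.empty((kept, p))
    s2_draws = np.empty(kept)
    j = 0
    for it in range(burn_in + iterations):
        z = rng.standard_normal(p)
        beta = beta_hat + np.sqrt(sigma2) * np.linalg.solve(L.T, z)
        resid = y - X @ beta
        sse = float(resid @ resid)
        sigma2 = sse / (2.0 * rng.gamma(n / 2.0))
        if not np.isfinite(sigma2) or sigma2 <= 0:
            raise FloatingPointError("sigma^2 draw diverged")
        if it >= burn_in and (it - burn_in) % thin == 0:
            draws[j] = beta
            s2_draws[j] = sigma2
            j += 1
    draws, s2_draws = draws[:j], s2_draws[:j]

    medians = {nm: float(np.median(draws[:, i]))
               for i, nm in enumerate(design.names)}
    hpd = {nm: hpd_interval(draws[:, i], 0.80)
           for i, nm in enumerate(design.names)}
    return PosteriorSummary(
        names=list(design.names),
        medians=medians,
        hpd80=hpd,
        sigma2_median=float(np.median(s2_draws)),
        sigma2_hpd80=hpd_interval(s2_draws, 0.80),
        draws=draws,
        sigma2_draws=s2_draws,
        age_center=design.age_center,
        poly_order=design.poly_order,
        settings=dict(iterations=iterations, burn_in=burn_in, thin=thin,
                      seed=seed),
    )


def hpd_interval(draws: np.ndarray, mass: float = 0.80) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the draws.

    Empirical HPD: over the sorted draws, the shortest window spanning
    ceil(mass·n) points. An equal-tailed alternative is available via
    :func:`equal_tailed_interval`.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    if n < 100:
        raise ValueError("need at least 100 draws for an empirical HPD")
    m = int(np.ceil(mass * n))
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def equal_tailed_interval(draws: np.ndarray, mass: float = 0.80) -> tuple[float, float]:
    lo = (1.0 - mass) / 2.0
    q = np.quantile(np.asarray(draws, dtype=float), [lo, 1.0 - lo])
    return float(q[0]), float(q[1])


@dataclass
class GroupContrast:
    """Posterior ASD−NT power difference at one age."""

    age: float
    draws: np.ndarray
    certainty: float              # Pr(power_ASD < power_NT)
    extrapolated: bool = False

    @property
    def median(self) -> float:
        return float(np.median(self.draws))


def group_contrast_at_age(
    summary: PosteriorSummary,
    age: float,
    age_range: tuple[float, float] | None = None,
) -> GroupContrast:
    """Posterior of the ASD−NT difference at ``age``.

    Per draw: group main effect plus interaction terms evaluated at the
    centered age. Ages outside ``age_range`` (when given) are flagged as
    extrapolation rather than rejected.
    """
    ac = age - summary.age_center
    diff = summary.coefficient_draws("group_asd").copy()
    for d in range(1, summary.poly_order + 1):
        nm = f"group_x_age{d if d > 1 else ''}"
        diff += summary.coefficient_draws(nm) * ac ** d
    extrapolated = bool(
        age_range is not None and not (age_range[0] <= age <= age_range[1])
    )
    return GroupContrast(
        age=age, draws=diff, certainty=float(np.mean(diff < 0.0)),
        extrapolated=extrapolated,
    )


def bayes_factor_poly_order(
    data: pd.DataFrame,
    response: str,
    orders: tuple[int, ...] = (1, 2, 3),
) -> tuple[int, pd.DataFrame]:
    """Select the age polynomial order by BIC-approximated Bayes factors.

    For each candidate order the model (with matching group×age interactions)
    is fit by least squares; log marginal likelihoods are approximated by
    −BIC/2 and Bayes factors reported relative to the best model. The order
    with the largest approximate marginal likelihood wins.
    """
    rows = []
    for order in orders:
        design = build_design(data, response, poly_order=order)
        X, y = design.X, design.y
        n, p = X.shape
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        sse = float(np.sum((y - X @ beta) ** 2))
        # Gaussian log-likelihood at the MLE, up to the shared constant
        loglik = -0.5 * n * np.log(sse / n)
        bic = -2.0 * loglik + (p + 1) * np.log(n)
        rows.append({"order": order, "bic": bic, "log_marglik": -bic / 2.0})
    table = pd.DataFrame(rows)
    best = int(table.loc[table["log_marglik"].idxmax(), "order"])
    table["bf_vs_best"] = np.exp(
        table["log_marglik"] - table["log_marglik"].max()
    )
    return best, table
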