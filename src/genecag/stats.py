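"""Per-CAG association testing and annotation-level aggregation.

The read count W_sc of CAG c in specimen s, out of M_s reads assigned to
the catalog, is modeled as beta-binomial with covariates on the logit of
the expected relative abundance:

    W_s ~ BetaBinomial(M_s, mu_s, phi),  logit(mu_s) = x_s' beta

with shape parameters a = mu (1 - phi) / phi and b = (1 - mu)(1 - phi) / phi,
so phi in (0, 1) is the intra-class correlation of the underlying beta and
phi -> 0 recovers the binomial. One phi is fitted per CAG. Wald tests use
standard errors from the observed information at the MLE, and p-values are
FDR-adjusted by Benjamini-Hochberg.

CAG-level coefficients are then aggregated to taxon or function level with
an intercept-only errors-in-response (random-effects meta-analysis) model:
the per-CAG estimates y_c are treated as noisy observations, with known
sampling variances se_c^2, of a shared label-level effect beta0 plus
between-CAG heterogeneity sigma^2, both estimated by maximum likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, special, stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.numdiff import approx_fprime

from .catalog import GeneCatalog
from .cluster import CAGPartition

__all__ = [
    "CountTable",
    "CAGFit",
    "AggregateResult",
    "build_count_table",
    "build_design_matrix",
    "fit_beta_binomial",
    "fit_all_cags",
    "bh_adjust",
    "aggregate_by_annotation",
    "significant_cags",
]


@dataclass
class CountTable:
    """Reads per (specimen, CAG) and total assigned reads per specimen."""

    W: pd.DataFrame  # specimen x cag, integer counts
    M: pd.Series  # specimen -> total assigned reads


@dataclass
class CAGFit:
    cag_id: str
    coef_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    wald: np.ndarray
    p: np.ndarray
    phi: float
    loglik: float
    converged: bool
    q: np.ndarray | None = None
    message: str = ""


@dataclass
class AggregateResult:
    label: str
    beta0_hat: float
    se0: float
    sigma2_hat: float
    p0: float
    n_cags: int
    clamped: bool = False


def build_count_table(assignments: pd.DataFrame, partition: CAGPartition) -> CountTable:
    """Aggregate resolved read assignments to CAG-level counts.

    Every assigned gene must belong to the partition; specimens with zero
    resolved reads are rejected (M must be positive).
    """
    missing = set(assignments["gene_id"]) - set(partition.gene_to_cag)
    if missing:
        raise KeyError(f"gene(s) not in partition: {sorted(missing)[:5]}")
    df = assignments.copy()
    df["cag_id"] = df["gene_id"].map(partition.gene_to_cag)
    W = df.groupby(["specimen", "cag_id"]).size().unstack(fill_value=0)
    W = W.reindex(columns=partition.cag_ids, fill_value=0).astype(int)
    M = W.sum(axis=1)
    if (M == 0).any():
        raise ValueError("specimen with no resolved reads")
    return CountTable(W=W, M=M)


def build_design_matrix(manifest_covariates: pd.DataFrame, formula: str) -> pd.DataFrame:
    """Wilkinson-formula design matrix (intercept added automatically)."""
    X = patsy.dmatrix(formula, manifest_covariates, return_type="dataframe")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    X.index = manifest_covariates.index
    return X


def _bb_negloglik_and_grad(params: np.ndarray, W: np.ndarray, M: np.ndarray, X: np.ndarray):
    beta = params[:-1]
    theta = params[-1]
    phi = special.expit(theta)
    eta = X @ beta
    mu = special.expit(eta)
    r = (1.0 - phi) / phi
    a = mu * r
    b = (1.0 - mu) * r

    ll = special.betaln(W + a, M - W + b) - special.betaln(a, b)

    psi = special.digamma
    dll_da = psi(W + a) - psi(M + a + b) - psi(a) + psi(a + b)
    dll_db = psi(M - W + b) - psi(M + a + b) - psi(b) + psi(a + b)
    # chain rule through the mean link
    dmu = mu * (1.0 - mu)
    d_eta = (dll_da - dll_db) * r * dmu
    grad_beta = X.T @ d_eta
    # and through the dispersion link: da/dphi = -mu/phi^2, db/dphi = -(1-mu)/phi^2
    dphi = phi * (1.0 - phi)
    d_theta = np.sum((dll_da * (-mu / phi**2) + dll_db * (-(1.0 - mu) / phi**2)) * dphi)
    return -np.sum(ll), -np.concatenate([grad_beta, [d_theta]])


def fit_beta_binomial(
    W: np.ndarray | pd.Series,
    M: np.ndarray | pd.Series,
    X: pd.DataFrame | np.ndarray,
    cag_id: str = "",
    phi_init: float = 0.01,
) -> CAGFit:
    """Maximum-likelihood beta-binomial regression for one CAG.

    Coefficients are warm-started from a binomial logistic fit; the
    dispersion phi is optimized on a logit internal scale starting at
    `phi_init`. Standard errors come from the observed information
    (numerical Hessian at the optimum). Degenerate count vectors (all
    zero or all equal to M: complete separation of the proportion at the
    boundary) are flagged, not fitted.
    """
    W = np.asarray(W, dtype=float)
    M = np.asarray(M, dtype=float)
    coef_names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(np.asarray(X).shape[1])]
    Xa = np.asarray(X, dtype=float)
    k = Xa.shape[1]
    nan = np.full(k, np.nan)
    if len(W) < k + 1:
        raise ValueError("need more specimens than coefficients")
    if (W == 0).all() or (W == M).all():
        return CAGFit(cag_id, coef_names, nan, nan, nan, nan, np.nan, -np.inf, False, message="separation")

    # warm start: binomial logistic MLE
    import statsmodels.api as sm

    try:
        glm = sm.GLM(np.column_stack([W, M - W]), Xa, family=sm.families.Binomial())
        beta0 = glm.fit(maxiter=50).params
    except Exception:
        beta0 = np.zeros(k)
    x0 = np.concatenate([beta0, [special.logit(phi_init)]])

    # phi is kept in [1e-8, 1 - 1e-6]: below that the beta-binomial is
    # numerically indistinguishable from the binomial and the shape
    # parameters overflow the betaln difference
    bounds = [(None, None)] * k + [(special.logit(1e-8), special.logit(1 - 1e-6))]
    res = optimize.minimize(
        _bb_negloglik_and_grad,
        x0,
        args=(W, M, Xa),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    beta = res.x[:-1]
    phi = float(special.expit(res.x[-1]))
    loglik = -float(res.fun)

    # observed information: central differences of the analytic gradient
    hess = approx_fprime(
        res.x, lambda p: _bb_negloglik_and_grad(p, W, M, Xa)[1], centered=True
    )
    hess = 0.5 * (hess + hess.T)
    try:
        cov = np.linalg.inv(hess)
        se_all = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        se = se_all[:-1]
        ok = bool(res.success) and np.isfinite(se).all()
    except np.linalg.LinAlgError:
        se = nan
        ok = False
    wald = beta / se
    p = 2.0 * sps.norm.sf(np.abs(wald))
    return CAGFit(cag_id, coef_names, beta, se, wald, p, phi, loglik, ok, message=str(res.message))


def fit_all_cags(counts: CountTable, X: pd.DataFrame, coef: str | None = None) -> pd.DataFrame:
    """Fit every CAG and assemble the per-CAG association table.

    `coef` selects the coefficient whose p-values enter FDR adjustment
    (default: the first non-intercept column). Non-converged or separated
    CAGs carry q = NaN and are excluded from the adjustment.
    """
    Xa = X.loc[counts.W.index]
    if coef is None:
        non_int = [c for c in X.columns if c != "Intercept"]
        coef = non_int[0] if non_int else "Intercept"
    j = list(X.columns).index(coef)
    rows = []
    for cag in counts.W.columns:
        fit = fit_beta_binomial(counts.W[cag], counts.M, Xa, cag_id=cag)
        rows.append(
            {
                "cag_id": cag,
                "coef": coef,
                "estimate": fit.beta[j] if fit.beta is not None else np.nan,
                "se": fit.se[j],
                "wald": fit.wald[j],
                "p": fit.p[j],
                "phi": fit.phi,
                "loglik": fit.loglik,
                "converged": fit.converged,
            }
        )
    table = pd.DataFrame(rows).set_index("cag_id")
    ok = table["converged"] & table["p"].notna()
    table["q"] = np.nan
    if ok.any():
        table.loc[ok, "q"] = bh_adjust(table.loc[ok, "p"].to_numpy())
    table["neg_log10_q"] = -np.log10(table["q"])
    return table


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _eir_negloglik(sigma2: float, y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (sigma2 + v)
    beta0 = np.sum(w * y) / np.sum(w)
    return 0.5 * np.sum(np.log(sigma2 + v) + w * (y - beta0) ** 2)


def fit_errors_in_response(y: np.ndarray, se: np.ndarray) -> tuple[float, float, float, bool]:
    """Intercept-only errors-in-response fit by maximum likelihood.

    Observations y_c have known sampling variances se_c^2; the model is
    y_c = beta0 + eps_c + u_c with eps_c ~ N(0, sigma^2) and
    u_c ~ N(0, se_c^2). Profile likelihood over sigma^2 >= 0 (beta0 is the
    precision-weighted mean at any sigma^2); returns
    (beta0_hat, se0, sigma2_hat, clamped_at_zero).
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(se, dtype=float) ** 2
    if len(y) == 1:
        return float(y[0]), float(np.sqrt(v[0])), 0.0, False
    hi = max(np.var(y) * 10, v.max() * 10, 1e-6)
    res = optimize.minimize_scalar(
        _eir_negloglik, args=(y, v), bounds=(0.0, hi), method="bounded",
        options={"xatol": 1e-12},
    )
    sigma2 = float(res.x)
    # the bounded optimum may sit epsilon inside 0; snap if 0 is as good
    if _eir_negloglik(0.0, y, v) <= res.fun + 1e-10:
        sigma2 = 0.0
    clamped = sigma2 == 0.0
    w = 1.0 / (sigma2 + v)
    beta0 = float(np.sum(w * y) / np.sum(w))
    se0 = float(np.sqrt(1.0 / np.sum(w)))
    return beta0, se0, sigma2, clamped


def aggregate_by_annotation(
    fits: pd.DataFrame,
    partition: CAGPartition,
    catalog: GeneCatalog,
    label_kind: str,
) -> pd.DataFrame:
    """Aggregate per-CAG coefficients to taxon or function level.

    For each annotation label, every converged CAG containing at least one
    gene with that label contributes its (estimate, se) pair; a CAG with
    genes under several labels contributes to each. The label-level
    intercept is tested against zero by a Wald test with the heterogeneity
    variance plugged in. Labels with no contributing CAG are omitted.
    """
    if label_kind not in ("taxon", "function"):
        raise ValueError("label_kind must be 'taxon' or 'function'")
    ann = catalog.table[["gene_id", label_kind]].dropna(subset=[label_kind])
    gene_labels = ann.set_index("gene_id")[label_kind]
    label_to_cags: dict[str, set[str]] = {}
    for gene, cag in partition.gene_to_cag.items():
        lab = gene_labels.get(gene)
        if lab is None or pd.isna(lab):
            continue
        label_to_cags.setdefault(lab, set()).add(cag)

    usable = fits[fits["converged"] & fits["se"].notna()]
    rows = []
    for label in sorted(label_to_cags):
        cags = sorted(c for c in label_to_cags[label] if c in usable.index)
        if not cags:
            continue
        y = usable.loc[cags, "estimate"].to_numpy()
        se = usable.loc[cags, "se"].to_numpy()
        beta0, se0, sigma2, clamped = fit_errors_in_response(y, se)
        z = beta0 / se0
        rows.append(
            {
                "label": label,
                "beta0_hat": beta0,
                "se0": se0,
                "sigma2_hat": sigma2,
                "p0": 2.0 * sps.norm.sf(abs(z)),
                "n_cags": len(cags),
                "sigma2_clamped": clamped,
            }
        )
    return pd.DataFrame(rows, columns=["label", "beta0_hat", "se0", "sigma2_hat", "p0", "n_cags", "sigma2_clamped"]).set_index("label")


def significant_cags(fits: pd.DataFrame, q_threshold: float) -> tuple[list[str], list[str]]:
    """CAGs passing the FDR threshold, split by coefficient sign.

    Returns (positive-coefficient CAG ids, negative-coefficient CAG ids).
    """
    hit = fits[(fits["q"] <= q_threshold) & fits["q"].notna()]
    pos = sorted(hit.index[hit["estimate"] > 0])
    neg = sorted(hit.index[hit["estimate"] < 0])
    return pos, neg
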