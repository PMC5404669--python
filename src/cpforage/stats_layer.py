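"""Declarative model fitting and comparison for the movement variables.

The model set for sex-by-breeding-period comparisons: GLMMs (gaussian/identity,
poisson/log, binomial/logit) with crossed random intercepts for individual,
year and breeding colony; GAMM-style penalized smooths of day-of-year or
chick age with REML-chosen effective degrees of freedom; AIC and Akaike
weights for model selection; backward-stepwise elimination by likelihood
ratio test; Holm-corrected post-hoc contrasts with a compact letter
display; and a chi-squared homogeneity test for habitat-use counts.

Conventions: ML fits for likelihood-ratio comparisons, REML for reported
coefficients and smooths.  Percentage responses are divided by 100 before
the arcsine-square-root transform; log-transformed responses drop
non-positive values with a logged count.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from patsy import build_design_matrices, dmatrix
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .glmm import MixedFit, RandomBlock, factor_block, fit_mixed_model, make_smooth_basis

ALLOWED_FAMILIES = {"gaussian", "poisson", "binomial"}
ALPHA = 0.05


# ---------------------------------------------------------------------------
# response transforms
# ---------------------------------------------------------------------------

def transform(value, kind: str):
    """Forward response transform: ``log`` -> ln(x), ``arcsine_sqrt`` ->
    asin(sqrt(p)) with p in [0, 1] (divide percentages by 100 first)."""
    x = np.asarray(value, float)
    if kind == "none":
        out = x
    elif kind == "log":
        if np.any(x <= 0):
            raise ValueError("log transform requires positive values")
        out = np.log(x)
    elif kind == "arcsine_sqrt":
        if np.any((x < 0) | (x > 1)):
            raise ValueError("arcsine_sqrt requires values in [0, 1]")
        out = np.arcsin(np.sqrt(x))
    else:
        raise ValueError(f"unknown transform {kind!r}")
    return out if out.ndim else float(out)


def inverse_transform(value, kind: str):
    x = np.asarray(value, float)
    if kind == "none":
        out = x
    elif kind == "log":
        out = np.exp(x)
    elif kind == "arcsine_sqrt":
        out = np.sin(x) ** 2
    else:
        raise ValueError(f"unknown transform {kind!r}")
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Description of one model: response (+ transform), fixed terms,
    optional penalized smooth, family and random intercepts.

    ``fixed`` terms use formula syntax (``"sex"``, ``"sex:period"``);
    ``correction`` names terms that the backward-stepwise procedure must
    never drop (the GPS sampling-frequency correction factor).
    """

    response: str
    fixed: list = field(default_factory=list)
    transform: str = "none"
    family: str = "gaussian"
    smooth: str | None = None  # column smoothed with a penalized spline
    random: list = field(default_factory=lambda: ["individual_id", "year", "colony"])
    correction: list = field(default_factory=list)
    smooth_k: int = 10

    def __post_init__(self):
        if self.family not in ALLOWED_FAMILIES:
            raise ValueError(f"family must be one of {sorted(ALLOWED_FAMILIES)}")
        if self.transform not in {"none", "log", "arcsine_sqrt"}:
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass
class FitResult:
    """A fitted model together with its design information."""

    spec: ModelSpec
    fit: MixedFit
    design_info: object
    n_dropped: int  # rows lost to the response transform domain
    data_index: pd.Index
    smooth_basis: object | None = None

    @property
    def loglik(self) -> float:
        return self.fit.loglik

    @property
    def aic(self) -> float:
        return self.fit.aic

    @property
    def converged(self) -> bool:
        return self.fit.converged

    def coef_table(self) -> pd.DataFrame:
        return self.fit.coef_table()

    def back_transformed(self) -> pd.DataFrame:
        """Coefficient view on the original response scale."""
        tab = self.coef_table().copy()
        tab["estimate_back"] = inverse_transform(tab["estimate"].to_numpy(), self.spec.transform) \
            if self.spec.transform != "none" else tab["estimate"]
        return tab

    @property
    def smooth_edf(self) -> float | None:
        if self.spec.smooth is None:
            return None
        return 1.0 + self.fit.edf.get(f"s({self.spec.smooth})", 0.0)


def _usable_terms(terms, table):
    """Drop terms referencing single-level columns (warn) — e.g. a sampling
    frequency factor when only one cadence is present."""
    out = []
    for t in terms:
        cols = t.split(":")
        degenerate = [c for c in cols if table[c].nunique() < 2]
        if degenerate:
            warnings.warn(f"term {t!r} dropped: single level in {degenerate}")
        else:
            out.append(t)
    return out


def _prepare_response(spec: ModelSpec, table: pd.DataFrame):
    y_raw = table[spec.response]
    keep = pd.Series(True, index=table.index)
    if spec.transform == "log":
        keep = y_raw > 0
        n_drop = int((~keep).sum())
        if n_drop:
            warnings.warn(f"log response: dropped {n_drop} non-positive rows")
    else:
        n_drop = 0
    sub = table[keep]
    y = sub[spec.response].to_numpy(float)
    if spec.transform == "arcsine_sqrt":
        if np.nanmax(y) > 1.0:  # percentage scale
            y = y / 100.0
        y = transform(y, "arcsine_sqrt")
    elif spec.transform == "log":
        y = transform(y, "log")
    return y, sub, n_drop


def _build_design(spec: ModelSpec, table: pd.DataFrame, design_info=None):
    terms = _usable_terms(spec.fixed, table)
    rhs = " + ".join(terms) if terms else "1"
    if design_info is not None:
        (X,) = build_design_matrices([design_info], table)
    else:
        X = dmatrix(rhs, table, return_type="matrix")
    names = X.design_info.column_names if design_info is None else design_info.column_names
    return np.asarray(X), list(names), (X.design_info if design_info is None else design_info)


def fit_mixed(spec: ModelSpec, table: pd.DataFrame, method: str = "ML") -> FitResult:
    """Fit one GLMM from its declarative spec.

    Random factors with fewer than two observed levels are dropped with a
    warning; non-convergence is flagged on the result, never silent.
    """
    y, sub, n_drop = _prepare_response(spec, table)
    X, names, dinfo = _build_design(spec, sub)
    blocks = [factor_block(r, sub[r].to_numpy()) for r in spec.random if r in sub.columns]
    smooth_basis = None
    if spec.smooth is not None:
        smooth_basis = make_smooth_basis(sub[spec.smooth].to_numpy(float), k=spec.smooth_k)
        lin, Zs = smooth_basis.design(sub[spec.smooth].to_numpy(float))
        X = np.column_stack([X, lin])
        names = names + [f"{spec.smooth}_lin"]
        blocks = [RandomBlock(f"s({spec.smooth})", Zs, "smooth")] + blocks
        if method == "ML" and spec.family == "gaussian":
            method = "ML"
    fit = fit_mixed_model(X, y, blocks, names, family=spec.family, method=method)
    if not fit.converged:
        warnings.warn(f"model for {spec.response!r} flagged non-convergent")
    return FitResult(
        spec=spec,
        fit=fit,
        design_info=dinfo,
        n_dropped=n_drop,
        data_index=sub.index,
        smooth_basis=smooth_basis,
    )


def fit_smooth(spec: ModelSpec, table: pd.DataFrame) -> FitResult:
    """GAMM-style fit: penalized spline smooth with REML-selected effective
    degrees of freedom (gaussian family).  Requires >= 30 observations."""
    if spec.smooth is None:
        raise ValueError("spec.smooth must name the column to be smoothed")
    if len(table) < 30:
        raise ValueError("penalized smooth needs at least 30 observations")
    return fit_mixed(spec, table, method="REML")


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def aic_weights(aics) -> np.ndarray:
    """Akaike weights w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2)."""
    a = np.asarray(aics, float)
    if a.size < 1:
        raise ValueError("need at least one AIC value")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def aic_table(fits: dict, labels=None) -> pd.DataFrame:
    """AIC comparison table (labels, AIC, deltaAIC, Akaike weight)."""
    if isinstance(fits, dict):
        labels = list(fits.keys())
        fits = list(fits.values())
    aics = np.array([f.aic for f in fits])
    w = aic_weights(aics)
    out = pd.DataFrame({"model": labels, "AIC": aics, "dAIC": aics - aics.min(), "weight": w})
    return out.sort_values("AIC").reset_index(drop=True)


def lrt(full: FitResult, reduced: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested ML fits: (chi2, df, p)."""
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    df = len(full.fit.names) - len(reduced.fit.names)
    if df <= 0:
        raise ValueError("full model must have more fixed parameters")
    return chi2, df, float(sps.chi2.sf(chi2, df))


def _contained_in_interaction(term: str, terms: list) -> bool:
    parts = set(term.split(":"))
    for other in terms:
        if other == term:
            continue
        if parts < set(other.split(":")):
            return True
    return False


def drop1(spec: ModelSpec, table: pd.DataFrame, full: FitResult | None = None) -> pd.DataFrame:
    """LRT for each droppable term (marginality respected, correction kept)."""
    full = full or fit_mixed(spec, table, method="ML")
    rows = []
    for term in spec.fixed:
        if term in spec.correction:
            continue
        if _contained_in_interaction(term, spec.fixed):
            continue
        reduced_spec = replace(spec, fixed=[t for t in spec.fixed if t != term])
        reduced = fit_mixed(reduced_spec, table, method="ML")
        chi2, df, p = lrt(full, reduced)
        rows.append({"term": term, "chi2": chi2, "df": df, "p": p})
    return pd.DataFrame(rows)


def backward_stepwise(
    spec: ModelSpec, table: pd.DataFrame, alpha: float = ALPHA
) -> tuple[FitResult, pd.DataFrame]:
    """Backward-stepwise elimination by LRT.

    Repeatedly drops the least significant droppable term with p >= alpha
    (main effects are protected while their interaction remains; correction
    factors are never dropped) and stops when every remaining droppable term
    is significant.  Returns the final ML fit and the elimination trail.
    """
    current = spec
    trail = []
    while True:
        full = fit_mixed(current, table, method="ML")
        tests = drop1(current, table, full)
        if len(tests) == 0:
            break
        worst = tests.sort_values("p", ascending=False).iloc[0]
        if worst["p"] < alpha:
            break
        trail.append(dict(worst))
        current = replace(current, fixed=[t for t in current.fixed if t != worst["term"]])
    final = fit_mixed(current, table, method="ML")
    return final, pd.DataFrame(trail)


# ---------------------------------------------------------------------------
# multiple comparisons
# ---------------------------------------------------------------------------

def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order."""
    p = np.asarray(pvalues, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def _cell_rows(result: FitResult, table: pd.DataFrame, cells: list[dict]) -> np.ndarray:
    """Design rows for factor-level cells, numeric covariates at their mean
    and unrelated factors at their first level (they cancel in contrasts)."""
    proto = {}
    sub = table.loc[result.data_index]
    for col in sub.columns:
        if pd.api.types.is_numeric_dtype(sub[col]):
            proto[col] = float(sub[col].mean())
        else:
            proto[col] = sorted(sub[col].astype(str).unique())[0]
    rows = []
    for cell in cells:
        d = dict(proto)
        d.update(cell)
        rows.append(d)
    grid = pd.DataFrame(rows)
    (X,) = build_design_matrices([result.design_info], grid)
    X = np.asarray(X)
    if result.smooth_basis is not None:
        x = grid[result.spec.smooth].to_numpy(float)
        lin, _ = result.smooth_basis.design(x)
        X = np.column_stack([X, lin])
    return X


def _compact_letters(levels: list, sig_pairs: set) -> dict:
    """Compact letter display: groups not significantly different share a
    letter.  Letters are the maximal cliques of the non-significance graph."""
    n = len(levels)
    adj = {
        (i, j): (levels[i], levels[j]) not in sig_pairs and (levels[j], levels[i]) not in sig_pairs
        for i in range(n)
        for j in range(i + 1, n)
    }
    cliques = []
    for r in range(n, 0, -1):
        for combo in itertools.combinations(range(n), r):
            if all(adj[(i, j)] for i, j in itertools.combinations(combo, 2)):
                if not any(set(combo) <= set(c) for c in cliques):
                    cliques.append(combo)
    letters = {lv: "" for lv in levels}
    for letter, clique in zip("abcdefghijklmnop", cliques):
        for i in clique:
            letters[levels[i]] += letter
    return letters


def posthoc_contrasts(
    result: FitResult,
    table: pd.DataFrame,
    factor_a: str = "sex",
    factor_b: str = "period",
    one_family: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Post-hoc Wald contrasts for an ``a x b`` interaction model.

    Two families of comparisons: the ``factor_a`` difference within each
    level of ``factor_b``, and all pairwise ``factor_b`` differences within
    each level of ``factor_a``.  Holm correction is applied over the full
    set of contrasts by default (``one_family=True``) or within each family.
    Returns the contrast table and a compact letter display of the
    within-``factor_a`` comparisons (letters shared = not significantly
    different).
    """
    sub = table.loc[result.data_index]
    a_levels = sorted(sub[factor_a].astype(str).unique())
    b_levels = sorted(sub[factor_b].astype(str).unique(), key=lambda s: str(s))
    if len(a_levels) < 2:
        raise ValueError(f"{factor_a} needs >= 2 levels")

    cells = [{factor_a: a, factor_b: b} for a in a_levels for b in b_levels]
    Xc = _cell_rows(result, table, cells)
    idx = {(a, b): k for k, (a, b) in enumerate((a, b) for a in a_levels for b in b_levels)}

    beta, cov = result.fit.beta, result.fit.cov_beta
    rows = []

    def add_contrast(label, family, c):
        est = float(c @ beta)
        var = float(c @ cov @ c)
        if var <= 0:
            raise ValueError(f"rank-deficient contrast {label!r}")
        z = est / math.sqrt(var)
        rows.append(
            {"contrast": label, "family": family, "estimate": est,
             "se": math.sqrt(var), "z": z, "p": 2 * sps.norm.sf(abs(z))}
        )

    # factor_a difference within each level of factor_b
    for b in b_levels:
        c = Xc[idx[(a_levels[1], b)]] - Xc[idx[(a_levels[0], b)]]
        add_contrast(f"{a_levels[1]}-{a_levels[0]} | {b}", "between", c)
    # pairwise factor_b within each factor_a level
    for a in a_levels:
        for b1, b2 in itertools.combinations(b_levels, 2):
            c = Xc[idx[(a, b2)]] - Xc[idx[(a, b1)]]
            add_contrast(f"{b2}-{b1} | {a}", f"within_{a}", c)

    out = pd.DataFrame(rows)
    if one_family:
        out["p_holm"] = holm_adjust(out["p"].to_numpy())
    else:
        out["p_holm"] = np.nan
        for fam, grp in out.groupby("family"):
            out.loc[grp.index, "p_holm"] = holm_adjust(grp["p"].to_numpy())

    letters = {}
    for a in a_levels:
        fam = out[out["family"] == f"within_{a}"]
        sig = set()
        for _, r in fam.iterrows():
            if r["p_holm"] < ALPHA:
                b2, rest = r["contrast"].split("-", 1)
                b1 = rest.split(" | ")[0]
                sig.add((b1, b2))
        letters[a] = _compact_letters(b_levels, sig)
    return out, letters


# ---------------------------------------------------------------------------
# habitat-use homogeneity
# ---------------------------------------------------------------------------

def chisq_homogeneity(counts) -> tuple[float, int, float, np.ndarray]:
    """Pearson chi-squared test of identical habitat-use distributions
    between the sexes: a 2 x k count table, df = k - 1.

    Returns (chi2, df, p, expected).  Warns when any expected count is
    below 5 (asymptotic p-value unreliable)."""
    tab = np.asarray(counts, float)
    if tab.ndim != 2 or tab.shape[0] != 2 or tab.shape[1] < 2:
        raise ValueError("counts must be a 2 x k table with k >= 2")
    if np.any(tab < 0) or np.any(tab.sum(axis=0) <= 0) or np.any(tab.sum(axis=1) <= 0):
        raise ValueError("degenerate table: negative entries or empty margins")
    chi2, p, df, expected = sps.chi2_contingency(tab, correction=False)
    if np.any(expected < 5):
        warnings.warn("some expected counts < 5; chi-squared approximation is weak")
    return float(chi2), int(df), float(p), expected
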