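"""Quantile normalization, empirical-Bayes moderated t-tests and the
reciprocal direction-concordance gene lists.

The moderated test shrinks each gene's pooled variance toward a prior
(s0^2, d0) estimated by moment-matching the log sample variances against a
scaled-F distribution (digamma/trigamma inversion).  The posterior variance is

    s_tilde_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and the moderated statistic ``t = delta / (s_tilde * sqrt(1/n1 + 1/n2))`` is
referred to a t distribution on ``d0 + d_g`` degrees of freedom (standard
normal when d0 is infinite).  Gene-list membership combines a linear
fold-change filter (ratio >= 1.15 or <= 1/1.15, boundary inclusive) with a
per-comparison significance gate, and direction concordance across the two
reciprocal comparisons intersects the per-tissue results into tiered lists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import DegenerateDataError, DesignError
from .io import ExpressionMatrix, OrthologTable, SampleSheet

_D0_CAP = 1e8  # d0 at or above this is treated as infinite


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Map every column onto the across-column mean of order statistics.

    Ties within a column receive the mean of the reference values at their
    tied ranks, so tied inputs stay tied.
    """
    values = matrix.values
    n_genes, n_samples = values.shape
    if n_samples < 2:
        raise DesignError("quantile normalization needs >= 2 samples")
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(n_samples):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        s = col[order]
        mapped = ref.copy()
        # tie groups share the mean of the reference at their rank range
        bounds = np.flatnonzero(np.r_[True, s[1:] != s[:-1], True])
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b - a > 1:
                mapped[a:b] = ref[a:b].mean()
        out[order, j] = mapped
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    )


# ---------------------------------------------------------------------------
# empirical Bayes prior
# ---------------------------------------------------------------------------

@dataclass
class EBayesParams:
    """Hyperparameters of the variance prior: prior df d0 (may be inf) and
    prior variance s0_sq (log2-units squared)."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise ValueError("d0 must be > 0")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be > 0")

    @property
    def finite(self) -> bool:
        return self.d0 < _D0_CAP


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if -dif / y < 1e-8 and dif / y < 1e-8:
            break
    return float(y)


def fit_ebayes(sample_variances, df) -> EBayesParams:
    """Moment-match (d0, s0_sq) from per-gene pooled variances.

    If s_g^2 ~ s0^2 * F(d_g, d0) then log s_g^2 has mean
    ``log s0^2 + psi(d_g/2) - log(d_g/2) - psi(d0/2) + log(d0/2)`` and variance
    ``psi'(d_g/2) + psi'(d0/2)``; excess dispersion of the observed log
    variances over the chi-square contribution identifies d0.  Zero or
    negative excess yields d0 = inf (no gene-to-gene variance heterogeneity
    beyond sampling noise).
    """
    s2 = np.asarray(sample_variances, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = df >= 1
    s2, df = s2[ok], df[ok]
    if s2.size < 10:
        raise DegenerateDataError(
            f"eBayes fit needs >= 10 genes with df >= 1, got {s2.size}"
        )
    if np.all(s2 == 0):
        raise DegenerateDataError("all sample variances are zero")
    positive = s2 > 0
    s2, df = s2[positive], df[positive]
    if np.ptp(s2) == 0:
        # literally constant variances carry no chi-square sampling signature;
        # the common value is the prior itself
        return EBayesParams(d0=math.inf, s0_sq=float(s2[0]))
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    excess = e_var - special.polygamma(1, df / 2.0).mean()
    if excess <= 0:
        return EBayesParams(d0=math.inf, s0_sq=float(np.exp(e_mean)))
    d0 = 2.0 * _trigamma_inverse(float(excess))
    s0_sq = float(np.exp(
        e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)
    ))
    if d0 >= _D0_CAP:
        return EBayesParams(d0=math.inf, s0_sq=float(np.exp(e_mean)))
    return EBayesParams(d0=d0, s0_sq=s0_sq)


# ---------------------------------------------------------------------------
# moderated t-test
# ---------------------------------------------------------------------------

def _condition_values(matrix: ExpressionMatrix, sheet: SampleSheet, condition):
    samples = sheet.samples_for(condition)
    if not samples:
        raise DesignError(f"condition {condition!r} absent from sample sheet")
    return matrix.data[samples].to_numpy(dtype=float)


def moderated_t_test(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    contrast,
    params: EBayesParams | None = None,
) -> pd.DataFrame:
    """Per-gene moderated t-test of polyploid vs diploid condition means.

    Parameters
    ----------
    contrast : (polyploid_condition, diploid_condition)
        Condition keys understood by the sample sheet.
    params : EBayesParams, optional
        Variance prior; fitted from this comparison's pooled variances when
        omitted.

    Returns
    -------
    DataFrame indexed by gene id with columns delta (log2, polyploid minus
    diploid), ratio (2**delta), t_mod, p, df_total and s2_post.
    """
    poly_cond, dip_cond = contrast
    x1 = _condition_values(matrix, sheet, poly_cond)
    x2 = _condition_values(matrix, sheet, dip_cond)
    n1, n2 = x1.shape[1], x2.shape[1]
    dg = n1 + n2 - 2

    if params is None:
        if dg < 1:
            raise DesignError(
                "cannot fit a variance prior with a single sample per group; "
                "supply EBayesParams"
            )
        s2 = _pooled_variance(x1, x2)
        params = fit_ebayes(s2, dg)
    else:
        s2 = _pooled_variance(x1, x2) if dg >= 1 else np.zeros(x1.shape[0])
    if dg < 1 and params.finite:
        raise DesignError(
            "single-sample groups need an infinite-d0 prior to carry the variance"
        )

    delta = x1.mean(axis=1) - x2.mean(axis=1)
    if math.isinf(params.d0):
        # the d0 -> inf limit: the prior variance carries the test entirely
        s2_post = np.full_like(delta, params.s0_sq)
        df_total = np.full_like(delta, np.inf)
    else:
        s2_post = (params.d0 * params.s0_sq + dg * s2) / (params.d0 + dg)
        df_total = np.full_like(delta, params.d0 + dg)

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, delta / se, 0.0)
    if math.isinf(params.d0):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df=params.d0 + dg)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    return pd.DataFrame(
        {
            "delta": delta,
            "ratio": np.exp2(delta),
            "t_mod": t_mod,
            "p": p,
            "df_total": df_total,
            "s2_post": s2_post,
        },
        index=matrix.data.index,
    )


def _pooled_variance(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    n1, n2 = x1.shape[1], x2.shape[1]
    ss1 = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss2 = ((x2 - x2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    return (ss1 + ss2) / (n1 + n2 - 2)


def ordinary_t_test(matrix, sheet, contrast) -> pd.DataFrame:
    """Plain two-sample pooled t-test (the d0 -> 0 limit of the moderated test);
    used as an internal cross-check."""
    poly_cond, dip_cond = contrast
    x1 = _condition_values(matrix, sheet, poly_cond)
    x2 = _condition_values(matrix, sheet, dip_cond)
    n1, n2 = x1.shape[1], x2.shape[1]
    dg = n1 + n2 - 2
    s2 = _pooled_variance(x1, x2)
    delta = x1.mean(axis=1) - x2.mean(axis=1)
    se = np.sqrt(s2 * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta / se, 0.0)
    p = np.clip(2 * stats.t.sf(np.abs(t), df=dg), np.finfo(float).tiny, 1.0)
    return pd.DataFrame({"delta": delta, "t": t, "p": p, "df": dg},
                        index=matrix.data.index)


# ---------------------------------------------------------------------------
# change filter and tiered lists
# ---------------------------------------------------------------------------

def change_filter(result: pd.DataFrame, threshold: float = 0.15) -> pd.DataFrame:
    """Linear fold-change filter: pass iff ratio >= 1+threshold (up) or
    ratio <= 1/(1+threshold) (down), boundaries inclusive."""
    ratio = result["ratio"].to_numpy(dtype=float)
    up = ratio >= 1.0 + threshold
    down = ratio <= 1.0 / (1.0 + threshold)
    direction = np.where(up, "up", np.where(down, "down", "none"))
    return pd.DataFrame({"passed": up | down, "direction": direction},
                        index=result.index)


@dataclass
class ConcordantGeneLists:
    """The three tiered ploidy-associated gene lists.

    Tier A: concordant across heart, liver and decidua (ortholog group ids);
    tier B: concordant across heart and liver; tier C: the decidua-only
    result (species-B gene ids).
    """

    tier_A_up: frozenset
    tier_A_down: frozenset
    tier_B_up: frozenset
    tier_B_down: frozenset
    tier_C_up: frozenset
    tier_C_down: frozenset

    def __post_init__(self) -> None:
        assert self.tier_A_up <= self.tier_B_up
        assert self.tier_A_down <= self.tier_B_down
        assert not (self.tier_A_up & self.tier_A_down)
        assert not (self.tier_B_up & self.tier_B_down)
        assert not (self.tier_C_up & self.tier_C_down)

    def as_dict(self) -> dict:
        return {
            "tier_A_up": self.tier_A_up, "tier_A_down": self.tier_A_down,
            "tier_B_up": self.tier_B_up, "tier_B_down": self.tier_B_down,
            "tier_C_up": self.tier_C_up, "tier_C_down": self.tier_C_down,
        }


def _directional_sets(de: pd.DataFrame, p_threshold, change_threshold, require_p):
    flt = change_filter(de, change_threshold)
    sig = de["p"] < p_threshold if require_p else pd.Series(True, index=de.index)
    up = set(de.index[(flt["direction"] == "up") & sig])
    down = set(de.index[(flt["direction"] == "down") & sig])
    return up, down


def build_tiered_lists(
    heart_de: pd.DataFrame,
    liver_de: pd.DataFrame,
    decidua_de: pd.DataFrame | None,
    orthologs: OrthologTable | None = None,
    p_threshold: float = 0.01,
    change_threshold: float = 0.15,
    require_p: bool = True,
) -> ConcordantGeneLists:
    """Intersect per-comparison results into the tiered concordant lists.

    heart/liver results must be keyed by ortholog group id; the decidua result
    is keyed by species-B gene ids and is mapped through the ortholog table for
    tier A.  Decidua genes without orthologs stay in tier C (it is an
    intra-species list).
    """
    h_up, h_down = _directional_sets(heart_de, p_threshold, change_threshold, require_p)
    l_up, l_down = _directional_sets(liver_de, p_threshold, change_threshold, require_p)
    tier_b_up = h_up & l_up
    tier_b_down = h_down & l_down

    if decidua_de is not None:
        d_up, d_down = _directional_sets(
            decidua_de, p_threshold, change_threshold, require_p
        )
        if orthologs is not None:
            b2g = orthologs.b_to_group()
            mapped = set(decidua_de.index) & set(b2g)
            if not mapped:
                raise DesignError(
                    "no decidua gene maps into the ortholog table"
                )
            d_up_groups = {b2g[g] for g in d_up if g in b2g}
            d_down_groups = {b2g[g] for g in d_down if g in b2g}
        else:
            d_up_groups, d_down_groups = d_up, d_down
        tier_a_up = tier_b_up & d_up_groups
        tier_a_down = tier_b_down & d_down_groups
        tier_c_up, tier_c_down = d_up, d_down
    else:
        tier_a_up = tier_a_down = set()
        tier_c_up = tier_c_down = set()

    return ConcordantGeneLists(
        tier_A_up=frozenset(tier_a_up), tier_A_down=frozenset(tier_a_down),
        tier_B_up=frozenset(tier_b_up), tier_B_down=frozenset(tier_b_down),
        tier_C_up=frozenset(tier_c_up), tier_C_down=frozenset(tier_c_down),
    )


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class PloidyContrast:
    """Moderated-t model of one polyploid-vs-diploid comparison.

    Examples
    --------
    >>> model = PloidyContrast(matrix, sheet,
    ...                        polyploid=("HS", "heart"), diploid=("MM", "heart"))
    >>> res = model.fit()
    >>> res.table.head()
    """

    def __init__(self, matrix: ExpressionMatrix, sheet: SampleSheet,
                 polyploid, diploid, normalize: bool = False):
        sheet.validate_against(matrix)
        self.matrix = quantile_normalize(matrix) if normalize else matrix
        self.sheet = sheet
        self.contrast = (tuple(polyploid), tuple(diploid))

    def fit(self, params: EBayesParams | None = None) -> "ContrastResults":
        table = moderated_t_test(self.matrix, self.sheet, self.contrast, params)
        if params is None:
            x1 = _condition_values(self.matrix, self.sheet, self.contrast[0])
            x2 = _condition_values(self.matrix, self.sheet, self.contrast[1])
            params = fit_ebayes(_pooled_variance(x1, x2), x1.shape[1] + x2.shape[1] - 2)
        return ContrastResults(self, table, params)


class ContrastResults:
    """Fitted moderated-t results for one comparison."""

    def __init__(self, model: PloidyContrast, table: pd.DataFrame,
                 params: EBayesParams):
        self.model = model
        self.table = table
        self.params = params

    def significant(self, p_threshold=0.01, change_threshold=0.15):
        up, down = _directional_sets(self.table, p_threshold, change_threshold, True)
        return frozenset(up), frozenset(down)

    def summary(self) -> str:
        poly, dip = self.model.contrast
        up, down = self.significant()
        lines = [
            "Moderated t-test: polyploid vs diploid",
            f"  polyploid condition : {poly}",
            f"  diploid condition   : {dip}",
            f"  genes               : {len(self.table)}",
            f"  prior df d0         : {self.params.d0:.4g}",
            f"  prior variance s0^2 : {self.params.s0_sq:.4g}",
            f"  up   (p<0.01, >=15%): {len(up)}",
            f"  down (p<0.01, >=15%): {len(down)}",
        ]
        return "\n".join(lines)
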