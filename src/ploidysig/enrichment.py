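"""Interactome and gene-module enrichment statistics.

Three ingredients: an exact one-sided binomial test of the interactant
proportion in a selection against a background proportion; hypergeometric
over-representation of annotated gene sets; and Storey–Tibshirani q-values for
multiple-testing adjustment.  Module over-representation applies a double
background: a term counts as significant only if it passes both the
all-orthologs background and the all-interactants background simultaneously
(p < 0.01 and q < 0.15 by default in each family).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, stats

from .errors import DegenerateDataError, DesignError
from .io import GeneSetCollection

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# binomial interactome enrichment
# ---------------------------------------------------------------------------

@dataclass
class BinomialEnrichment:
    """Exact one-sided (upper-tail) binomial test of an interactant proportion."""

    k: int
    n: int
    p0: float
    proportion: float
    p_value: float

    def __post_init__(self) -> None:
        assert 0 <= self.k <= self.n
        assert 0 < self.p_value <= 1


def binomial_tail(k: int, n: int, p0: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p0), exact upper tail."""
    if k <= 0:
        return 1.0
    # scipy's survival function evaluates the regularized incomplete beta,
    # accurate in the far tail (agrees with exact rational summation)
    return float(stats.binom.sf(k - 1, n, p0))


def binomial_enrichment(selection, interactome, universe=None,
                        p0: float | None = None) -> BinomialEnrichment:
    """Test whether a gene selection is enriched for interactome members.

    ``p0`` defaults to the interactome rate in the supplied universe; passing
    an explicit (possibly rounded) ``p0`` reproduces published contingencies.
    """
    selection = set(selection)
    interactome = set(interactome)
    if not selection:
        raise DesignError("empty selection")
    if universe is not None:
        universe = set(universe)
        outside = selection - universe
        if outside:
            raise DesignError(
                f"selection contains genes outside the universe, e.g. "
                f"{sorted(outside)[:3]}"
            )
        if p0 is None:
            if not universe:
                raise DesignError("empty universe")
            p0 = len(interactome & universe) / len(universe)
    if p0 is None:
        raise DesignError("p0 required when no universe is supplied")
    if not 0 < p0 < 1:
        raise DesignError(f"background proportion p0={p0} outside (0, 1)")
    k = len(selection & interactome)
    n = len(selection)
    return BinomialEnrichment(
        k=k, n=n, p0=p0, proportion=k / n, p_value=binomial_tail(k, n, p0)
    )


# ---------------------------------------------------------------------------
# hypergeometric over-representation
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentRecord:
    """One gene-set over-representation test result."""

    term_id: str
    k: int            # selected ∩ term (within background)
    n: int            # selected ∩ background
    K: int            # term ∩ background
    N: int            # background size
    p: float
    q: float = math.nan
    background_id: str = ""
    description: str = ""
    significant: bool = False

    def __post_init__(self) -> None:
        assert self.k <= min(self.n, self.K)
        assert 0 < self.p <= 1


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_ora(term, selection, background, term_id: str = "",
                  background_id: str = "") -> EnrichmentRecord:
    """Upper-tail hypergeometric test of term/selection overlap within a
    background universe (term and selection intersected with it first)."""
    background = set(background)
    if len(background) < 2:
        raise DesignError("background must contain >= 2 genes")
    term_in = set(term) & background
    sel_in = set(selection) & background
    k = len(term_in & sel_in)
    record = EnrichmentRecord(
        term_id=term_id,
        k=k, n=len(sel_in), K=len(term_in), N=len(background),
        p=hypergeom_tail(k, len(background), len(term_in), len(sel_in)),
        background_id=background_id,
    )
    return record


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

@dataclass
class QValueModel:
    """Estimated null proportion pi0 and the tuning grid used."""

    pi0: float
    lambda_grid: tuple = ()
    method: str = "spline"

    def __post_init__(self) -> None:
        assert 0 < self.pi0 <= 1


def _estimate_pi0(p: np.ndarray, pi0_method: str):
    m = p.size
    if pi0_method == "fixed" or m < 100:
        lam = 0.5
        pi0 = (p > lam).sum() / ((1.0 - lam) * m)
        return min(max(pi0, 1.0 / m), 1.0), (lam,), "fixed"
    grid = np.arange(0.05, 0.951, 0.05)
    pi0_lam = np.array([(p > lam).sum() / ((1.0 - lam) * m) for lam in grid])
    # cubic smoothing of pi0(lambda), extrapolated toward lambda -> 1
    spline = interpolate.UnivariateSpline(grid, pi0_lam, k=3)
    pi0 = float(spline(grid[-1]))
    return min(max(pi0, 1.0 / m), 1.0), tuple(grid), "spline"


def storey_qvalues(p_values, pi0: float | None = None,
                   pi0_method: str = "spline"):
    """Storey–Tibshirani q-values.

    Returns (q_values in input order, QValueModel).  ``pi0`` may be forced
    (e.g. 1.0 gives Benjamini–Hochberg); otherwise it is estimated on a
    lambda grid with cubic-smoothing extrapolation, falling back to the fixed
    lambda = 0.5 estimate for families smaller than 100.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise DegenerateDataError("no p-values supplied")
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        bad = p[(p <= 0) | (p > 1) | ~np.isfinite(p)][0]
        raise DegenerateDataError(f"p-value {bad} outside (0, 1]")
    if pi0 is None:
        pi0, grid, method = _estimate_pi0(p, pi0_method)
        model = QValueModel(pi0=pi0, lambda_grid=grid, method=method)
    else:
        if not 0 < pi0 <= 1:
            raise DegenerateDataError(f"pi0={pi0} outside (0, 1]")
        model = QValueModel(pi0=pi0, lambda_grid=(), method="forced")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = model.pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, model


# ---------------------------------------------------------------------------
# double-background ORA
# ---------------------------------------------------------------------------

def merge_redundant_terms(collection: GeneSetCollection) -> GeneSetCollection:
    """Unite terms with identical member sets (redundancy removal)."""
    by_members: dict = {}
    for term, (desc, members) in collection.items():
        by_members.setdefault(members, []).append((term, desc))
    merged = {}
    for members, entries in by_members.items():
        entries.sort()
        term_id = "|".join(t for t, _ in entries)
        merged[term_id] = (entries[0][1], members)
    return GeneSetCollection(merged)


def double_background_ora(
    selection,
    collection: GeneSetCollection,
    ortholog_universe,
    interactome_universe,
    p_gate: float = 0.01,
    q_gate: float = 0.15,
    pi0_method: str = "spline",
) -> list[EnrichmentRecord]:
    """Test every term against both backgrounds; a term is significant only if
    p < p_gate and q < q_gate in BOTH families.

    q-values are computed within each background's family of tests.  Terms
    with identical member sets are united beforehand.
    """
    if len(collection) == 0:
        return []
    merged = merge_redundant_terms(collection)
    backgrounds = {
        "orthologs": set(ortholog_universe),
        "interactants": set(interactome_universe),
    }
    records: dict[str, list[EnrichmentRecord]] = {}
    for bg_id, background in backgrounds.items():
        recs = []
        for term_id, (desc, members) in merged.items():
            rec = hypergeom_ora(members, selection, background,
                                term_id=term_id, background_id=bg_id)
            rec.description = desc
            recs.append(rec)
        q, _ = storey_qvalues([r.p for r in recs], pi0_method=pi0_method)
        for rec, qv in zip(recs, q):
            rec.q = float(qv)
        records[bg_id] = recs

    passing: dict[str, set] = {}
    for bg_id, recs in records.items():
        passing[bg_id] = {r.term_id for r in recs if r.p < p_gate and r.q < q_gate}
    both = passing["orthologs"] & passing["interactants"]
    out = []
    for bg_id in ("orthologs", "interactants"):
        for rec in records[bg_id]:
            rec.significant = rec.term_id in both
            out.append(rec)
    return out


def group_summary(records, group_map: dict) -> dict:
    """Geometric mean of q per (group, background) over the member records.

    Records whose term is not mapped are skipped with a warning; q = 0 is
    floored at 1e-300 with a warning; empty groups are simply absent.
    """
    grouped: dict = {}
    for rec in records:
        group = group_map.get(rec.term_id)
        if group is None:
            logger.warning("term %s has no group; skipped", rec.term_id)
            continue
        grouped.setdefault((group, rec.background_id), []).append(rec.q)
    out = {}
    for key, qs in grouped.items():
        qs = np.asarray(qs, dtype=float)
        if np.any(qs == 0):
            logger.warning("group %s has q = 0; floored at 1e-300", key)
            qs = np.maximum(qs, 1e-300)
        out[key] = float(np.exp(np.mean(np.log(qs))))
    return out
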