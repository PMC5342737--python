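"""Correlation PCA over condition profiles with factor labeling of components.

The model follows the data-driven extraction of a "ploidy component": condition
profiles (mean expression per species x tissue condition) are the variables,
genes the statistical units.  PCA is computed on the variables' correlation
matrix, so loadings are correlations between variables and components, the
per-variable squared loadings sum to one, and the mean over variables of
squared loadings equals the component's fraction of total variance.  As many
components as variables are extracted — a pure rotation with no loss of
information.  Component scores are standardized to zero mean and unit SD, so
genes beyond |score| = 2 exceed the nominal 95% band of the component.

Components are labeled by the sign pattern of their loadings: all-same-sign is
the shared (size) component; a pattern matching the ±1 coding of tissue,
species or ploidy class (up to a global flip — eigenvector sign is arbitrary)
is labeled accordingly.  Ploidy components are canonically oriented so that
polyploid conditions carry negative loadings, hence low (negative) scores mark
genes induced by polyploidy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DesignError
from .io import ExpressionMatrix, SampleSheet

LABELS = ("shared", "tissue", "species", "ploidy", "unassigned")


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def condition_profiles(matrix: ExpressionMatrix, sheet: SampleSheet) -> pd.DataFrame:
    """Genes x conditions table of replicate-mean expression.

    Condition labels are "<species>_<tissue>" (plus the ploidy class for a
    single-tissue 2n/4n design).
    """
    sheet.validate_against(matrix)
    profiles = {}
    for cond in sheet.conditions():
        samples = sheet.samples_for(cond)
        if not samples:
            raise DesignError(f"condition {cond} has no samples")
        label = "_".join(str(c) for c in cond)
        profiles[label] = matrix.data[samples].mean(axis=1)
    return pd.DataFrame(profiles, index=matrix.data.index)


def variance_fraction_from_loadings(loadings) -> np.ndarray:
    """Per-component variance fraction implied by correlation-scale loadings:
    the mean over variables of the squared loadings."""
    L = np.asarray(loadings, dtype=float)
    return (L ** 2).mean(axis=0)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_pca(profiles: pd.DataFrame) -> "PCAResults":
    """Full-rank eigendecomposition of the condition-profile correlation matrix.

    Loadings are eigenvectors scaled by sqrt(eigenvalue) (correlation scale);
    scores are standardized projections of the standardized gene rows;
    variance fractions are eigenvalues over the number of variables.
    """
    if profiles.shape[1] < 2:
        raise DesignError("PCA needs >= 2 condition profiles")
    X = profiles.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = profiles.columns[np.argmax(sd == 0)]
        raise DesignError(f"condition profile {bad!r} has zero variance")
    Z = (X - X.mean(axis=0)) / sd
    C = (Z.T @ Z) / Z.shape[0]
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    w = np.clip(w, 0.0, None)
    # deterministic default orientation: first variable loads positively
    for k in range(V.shape[1]):
        if V[0, k] < 0:
            V[:, k] = -V[:, k]
    loadings = V * np.sqrt(w)
    scores = Z @ V
    s_sd = scores.std(axis=0, ddof=0)
    s_sd[s_sd == 0] = 1.0
    scores = (scores - scores.mean(axis=0)) / s_sd
    comp = [f"PC{k + 1}" for k in range(len(w))]
    m2 = (scores ** 2).mean(axis=0)
    m4 = (scores ** 4).mean(axis=0)
    return PCAResults(
        variables=list(profiles.columns),
        loadings=pd.DataFrame(loadings, index=profiles.columns, columns=comp),
        scores=pd.DataFrame(scores, index=profiles.index, columns=comp),
        var_fraction=pd.Series(w / len(w), index=comp),
        kurtosis=pd.Series(m4 / m2 ** 2, index=comp),
        labels={c: "unassigned" for c in comp},
        orientation={},
    )


# ---------------------------------------------------------------------------
# results object
# ---------------------------------------------------------------------------

@dataclass
class PCAResults:
    """Loadings, standardized gene scores, variance fractions and diagnostics."""

    variables: list
    loadings: pd.DataFrame      # variables x components, correlation scale
    scores: pd.DataFrame        # genes x components, mean 0 / SD 1
    var_fraction: pd.Series
    kurtosis: pd.Series
    labels: dict                # component -> label
    orientation: dict           # component -> sign convention applied

    @property
    def components(self) -> list[str]:
        return list(self.loadings.columns)

    def component_for(self, label: str) -> str:
        for comp, lab in self.labels.items():
            if lab == label:
                return comp
        raise DesignError(f"no component labeled {label!r}")

    def reconstruct(self) -> np.ndarray:
        """Standardized profiles from scores and loadings (full-rank identity)."""
        lam = self.var_fraction.to_numpy() * len(self.variables)
        V = self.loadings.to_numpy() / np.where(lam > 0, np.sqrt(lam), 1.0)
        return self.scores.to_numpy() * np.sqrt(lam) @ V.T

    # -- selection ---------------------------------------------------------

    def select_by_score(self, component_label: str = "ploidy",
                        sd_threshold: float = 2.0):
        """(induced, suppressed) gene sets beyond +-sd_threshold on the labeled
        component; thresholds strict; low scores = induced by polyploidy under
        the canonical orientation."""
        comp = self.component_for(component_label)
        s = self.scores[comp]
        induced = frozenset(s.index[s < -sd_threshold])
        suppressed = frozenset(s.index[s > sd_threshold])
        return induced, suppressed

    def score_diagnostics(self, component: str):
        """(Pearson kurtosis m4/m2^2, 99th percentile of |score|)."""
        s = self.scores[component].to_numpy()
        if s.size < 4:
            raise DesignError("score diagnostics need >= 4 genes")
        m2 = (s ** 2).mean()
        m4 = (s ** 4).mean()
        return float(m4 / m2 ** 2), float(np.quantile(np.abs(s), 0.99))

    def summary(self) -> str:
        rows = []
        for comp in self.components:
            rows.append(
                f"  {comp:<5} var={self.var_fraction[comp]:6.1%} "
                f"label={self.labels.get(comp, 'unassigned'):<10} "
                f"kurtosis={self.kurtosis[comp]:8.2f}"
            )
        head = (
            f"Correlation PCA over {len(self.variables)} condition profiles, "
            f"{len(self.scores)} genes"
        )
        return "\n".join([head, *rows])


# ---------------------------------------------------------------------------
# labeling
# ---------------------------------------------------------------------------

def _factor_codings(results: PCAResults, sheet: SampleSheet) -> dict:
    """±1 coding per non-constant factor over the profile variables."""
    metas = []
    for cond in sheet.conditions():
        label = "_".join(str(c) for c in cond)
        metas.append((label, sheet.condition_meta(cond)))
    order = {lab: i for i, (lab, _) in enumerate(metas)}
    if set(order) != set(results.variables):
        raise DesignError("sample sheet conditions do not match PCA variables")
    metas.sort(key=lambda lm: results.variables.index(lm[0]))

    codings = {}
    for factor, key in (("tissue", "tissue"), ("species", "species"),
                        ("ploidy", "ploidy_class")):
        values = [m[key] for _, m in metas]
        levels = sorted(set(values))
        if len(levels) == 1:
            continue
        if len(levels) > 2:
            raise DesignError(f"factor {factor!r} has more than two levels")
        if factor == "ploidy":
            coding = np.array([+1 if v == "polyploid" else -1 for v in values])
        else:
            coding = np.array([+1 if v == levels[0] else -1 for v in values])
        codings[factor] = coding
    names = list(codings)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = codings[names[i]], codings[names[j]]
            if np.array_equal(a, b) or np.array_equal(a, -b):
                raise DesignError(
                    f"factors {names[i]!r} and {names[j]!r} are confounded "
                    "(identical ±1 codings)"
                )
    return codings


def label_components(results: PCAResults, sheet: SampleSheet) -> PCAResults:
    """Assign factor labels from loading sign patterns and canonicalize
    orientations (in place; also returned)."""
    codings = _factor_codings(results, sheet)
    for comp in results.components:
        load = results.loadings[comp].to_numpy()
        signs = np.where(load >= 0, 1, -1)
        label = "unassigned"
        if np.all(signs == signs[0]):
            label = "shared"
        else:
            for factor, coding in codings.items():
                if np.array_equal(signs, coding) or np.array_equal(signs, -coding):
                    label = factor
                    break
        results.labels[comp] = label
        flip = False
        if label == "ploidy":
            # canonical: polyploid variables negative => low scores = induced
            poly_sign = signs[np.argmax(codings["ploidy"] == 1)]
            flip = poly_sign > 0
            results.orientation[comp] = "polyploid-negative"
        elif label != "unassigned":
            flip = load[0] < 0
            results.orientation[comp] = "first-variable-positive"
        if flip:
            results.loadings[comp] = -results.loadings[comp]
            results.scores[comp] = -results.scores[comp]
    return results


# ---------------------------------------------------------------------------
# model object
# ---------------------------------------------------------------------------

class PloidyPCA:
    """Correlation-PCA model of an expression matrix under a condition design.

    ``fit()`` averages replicates into condition profiles, eigendecomposes
    their correlation matrix, labels components by loading sign pattern and
    canonicalizes orientations.
    """

    def __init__(self, matrix: ExpressionMatrix, sheet: SampleSheet):
        sheet.validate_against(matrix)
        self.matrix = matrix
        self.sheet = sheet

    def fit(self) -> PCAResults:
        profiles = condition_profiles(self.matrix, self.sheet)
        results = fit_pca(profiles)
        return label_components(results, self.sheet)
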