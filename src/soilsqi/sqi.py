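"""Composite Soil Quality Index (SQI).

The index aggregates heterogeneous soil indicators (chemistry plus microbial
alpha diversity) in three steps:

1. *Membership*: every indicator is min-max rescaled to [0, 1], ascending
   for "more is better" indicators (SOM, AN, AP, AK, Chao1, Shannon) and
   descending for "less is better" ones (pH, EC in saline-alkaline soil).
2. *Weights*: PCA on the standardized indicator table; within each retained
   component the indicator weight is its absolute factor loading
   (eigenvector entry x sqrt(eigenvalue)) normalized to sum to one,
   W_ij = C_ij / sum_i C_ij.
3. *Aggregation*: SQI = sum_j K_j * (sum_i W_ij * F_i), with K_j the
   variance contribution rate of component j in percent, so with all
   memberships at 1 the index attains the cumulative contribution rate
   (a 0-100-point scale).

Implemented as scikit-learn style estimators so the index composes with
sklearn pipelines; thin module-level functions mirror each step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

ASCENDING = "ascending"
DESCENDING = "descending"

#: Default direction map: nutrients and diversity ascending; pH and salinity
#: (EC) descending.
DEFAULT_DIRECTIONS = {
    "SOM": ASCENDING, "AN": ASCENDING, "AP": ASCENDING, "AK": ASCENDING,
    "pH": DESCENDING, "EC": DESCENDING,
    "chao1_bacteria": ASCENDING, "shannon_bacteria": ASCENDING,
    "chao1_fungi": ASCENDING, "shannon_fungi": ASCENDING,
}


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


class MinMaxMembership(TransformerMixin, BaseEstimator):
    """Direction-aware min-max membership transform.

    Ascending indicators map (x - min)/(max - min); descending indicators
    map (max - x)/(max - min), extremes taken over the fitted entities.  A
    degenerate indicator (max == min) maps to a constant 0.5 so it cannot
    reorder entities.

    Parameters
    ----------
    directions : mapping of column name -> "ascending" | "descending".
        Columns absent from the mapping raise at fit time.
    """

    def __init__(self, directions: dict | None = None):
        self.directions = directions

    def fit(self, X, y=None):
        X = _as_frame(X)
        directions = self.directions or DEFAULT_DIRECTIONS
        missing = [c for c in X.columns if c not in directions]
        if missing:
            raise ValueError(f"no direction declared for indicators: {missing}")
        bad = {c: directions[c] for c in X.columns
               if directions[c] not in (ASCENDING, DESCENDING)}
        if bad:
            raise ValueError(f"invalid directions: {bad}")
        if len(X) < 2:
            raise ValueError("need >= 2 entities to define membership extremes")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.directions_ = {c: directions[c] for c in X.columns}
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        degenerate = self.data_max_ - self.data_min_ == 0
        self.degenerate_indicators_ = list(X.columns[degenerate])
        if self.degenerate_indicators_:
            warnings.warn(
                "degenerate indicators (max == min) mapped to constant 0.5: "
                f"{self.degenerate_indicators_}", stacklevel=2,
            )
        return self

    def transform(self, X) -> pd.DataFrame:
        X = _as_frame(X)
        if list(X.columns) != list(self.feature_names_in_):
            raise ValueError("indicator columns differ from fitted columns")
        span = self.data_max_ - self.data_min_
        out = pd.DataFrame(index=X.index, columns=X.columns, dtype=float)
        for c in X.columns:
            if c in self.degenerate_indicators_:
                out[c] = 0.5
            elif self.directions_[c] == ASCENDING:
                out[c] = (X[c] - self.data_min_[c]) / span[c]
            else:
                out[c] = (self.data_max_[c] - X[c]) / span[c]
        return out.clip(0.0, 1.0)


class PCALoadingWeights(BaseEstimator):
    """Variance-contribution rates and loading-derived indicator weights.

    Fits PCA via eigendecomposition of the correlation matrix of the
    indicator table.  Exposes, per component j: the contribution rate
    K_j = 100 * lambda_j / sum(lambda) and per indicator i the weight
    W_ij = |loading_ij| / sum_i |loading_ij| with loadings in the
    factor-loading convention (eigenvector x sqrt(eigenvalue)).

    Parameters
    ----------
    n_components : retained component count m (clamped to the number of
        indicators); ignored when ``variance_threshold`` is given.
    variance_threshold : retain the smallest m whose cumulative K reaches
        this percentage.
    loading_convention : "factor" (eigenvector x sqrt(lambda), default) or
        "eigenvector" for raw eigenvectors (sensitivity mode).
    """

    def __init__(self, n_components: int = 4,
                 variance_threshold: float | None = None,
                 loading_convention: str = "factor"):
        self.n_components = n_components
        self.variance_threshold = variance_threshold
        self.loading_convention = loading_convention

    def fit(self, X, y=None):
        X = _as_frame(X)
        if X.shape[0] < 2 or X.shape[1] < 2:
            raise ValueError("need >= 2 entities and >= 2 indicators")
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        self.dropped_indicators_ = list(X.columns[~keep])
        if self.dropped_indicators_:
            warnings.warn(
                f"dropped zero-variance indicators: {self.dropped_indicators_}",
                stacklevel=2,
            )
        X = X.loc[:, keep]
        if X.shape[1] < 2:
            raise ValueError("fewer than 2 indicators with variance")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)

        corr = np.corrcoef(X.to_numpy(float), rowvar=False)
        eigvals, eigvecs = np.linalg.eigh(corr)
        order = np.argsort(eigvals)[::-1]
        eigvals = np.clip(eigvals[order], 0.0, None)
        eigvecs = eigvecs[:, order]
        # Deterministic sign: largest-magnitude entry of each component
        # positive (irrelevant to |loading| weights, stabilizes output).
        for j in range(eigvecs.shape[1]):
            k = np.argmax(np.abs(eigvecs[:, j]))
            if eigvecs[k, j] < 0:
                eigvecs[:, j] = -eigvecs[:, j]

        self.eigenvalues_ = eigvals
        self.contribution_rates_ = 100.0 * eigvals / eigvals.sum()
        if self.loading_convention == "factor":
            loadings = eigvecs * np.sqrt(eigvals)[None, :]
        elif self.loading_convention == "eigenvector":
            loadings = eigvecs
        else:
            raise ValueError("loading_convention must be 'factor' or 'eigenvector'")
        self.loadings_ = pd.DataFrame(
            loadings.T,
            index=[f"PC{j + 1}" for j in range(len(eigvals))],
            columns=self.feature_names_in_,
        )

        if self.variance_threshold is not None:
            cum = np.cumsum(self.contribution_rates_)
            m = int(np.searchsorted(cum, self.variance_threshold) + 1)
            m = min(m, len(eigvals))
        else:
            m = min(int(self.n_components), len(eigvals))
        if m < 1:
            raise ValueError("must retain at least one component")
        self.n_components_ = m

        absload = self.loadings_.abs()
        rowsum = absload.sum(axis=1)
        weights = absload.div(rowsum.where(rowsum > 0), axis=0).fillna(0.0)
        self.weights_ = weights
        return self

    @property
    def retained_contribution_(self) -> float:
        return float(self.contribution_rates_[: self.n_components_].sum())


class SoilQualityIndex(BaseEstimator, TransformerMixin):
    """End-to-end SQI estimator: membership -> PCA weights -> aggregation.

    ``fit`` learns membership extremes and component weights from the
    entity x indicator table; ``transform`` (or ``score_samples``) maps a
    table with the same indicators to index values.  Fitted attributes:
    ``sqi_`` (index per fitted entity), ``ranks_`` (1 = best), plus the full
    audit trail (``membership_``, ``weighting_``).
    """

    def __init__(self, directions: dict | None = None, n_components: int = 4,
                 variance_threshold: float | None = None,
                 loading_convention: str = "factor"):
        self.directions = directions
        self.n_components = n_components
        self.variance_threshold = variance_threshold
        self.loading_convention = loading_convention

    def fit(self, X, y=None):
        X = _as_frame(X)
        self.membership_model_ = MinMaxMembership(self.directions).fit(X)
        if (X.std(axis=0, ddof=1) > 0).sum() < 2:
            # fully (or nearly) degenerate table: PCA is undefined, so fall
            # back to a single uniform component; memberships are constant
            # 0.5 anyway, leaving every entity tied.
            warnings.warn(
                "indicator table has <2 varying columns: uniform weights used",
                stacklevel=2,
            )
            self.weighting_ = _uniform_weighting(list(X.columns))
        else:
            self.weighting_ = PCALoadingWeights(
                n_components=self.n_components,
                variance_threshold=self.variance_threshold,
                loading_convention=self.loading_convention,
            ).fit(X)
        self.membership_ = self.membership_model_.transform(X)
        self.sqi_ = self.score_samples(X)
        self.ranks_, self.tied_ = rank_entities(self.sqi_)
        return self

    def score_samples(self, X) -> pd.Series:
        X = _as_frame(X)
        memb = self.membership_model_.transform(X)
        return aggregate_sqi(memb, self.weighting_)

    def transform(self, X):
        return self.score_samples(X).to_frame("SQI")


def _uniform_weighting(names: list) -> PCALoadingWeights:
    wt = PCALoadingWeights(n_components=1)
    wt.feature_names_in_ = np.asarray(names, dtype=object)
    wt.contribution_rates_ = np.array([100.0])
    wt.eigenvalues_ = np.array([float(len(names))])
    wt.loadings_ = pd.DataFrame([[1.0] * len(names)], index=["PC1"],
                                columns=names)
    wt.weights_ = pd.DataFrame([[1.0 / len(names)] * len(names)],
                               index=["PC1"], columns=names)
    wt.n_components_ = 1
    wt.dropped_indicators_ = []
    return wt


def aggregate_sqi(memberships: pd.DataFrame,
                  weighting: PCALoadingWeights) -> pd.Series:
    """SQI = sum over retained components of K_j (percent) times the
    weighted mean membership under that component's weights."""
    cols = list(weighting.feature_names_in_)
    missing = set(cols) - set(memberships.columns)
    if missing:
        raise ValueError(f"memberships missing indicators: {sorted(missing)}")
    f = memberships[cols].to_numpy(float)
    m = weighting.n_components_
    w = weighting.weights_.iloc[:m][cols].to_numpy(float)   # m x n
    k = weighting.contribution_rates_[:m]                   # percent
    scores = f @ w.T @ k
    return pd.Series(scores, index=memberships.index, name="SQI")


def rank_entities(sqi: pd.Series) -> tuple[pd.Series, bool]:
    """Dense ranking, 1 = highest SQI; ties broken by entity-label order."""
    order = sorted(sqi.index, key=lambda e: (-sqi.loc[e], list(sqi.index).index(e)))
    ranks = pd.Series({e: i + 1 for i, e in enumerate(order)}, name="rank")
    tied = sqi.round(12).duplicated().any()
    return ranks.loc[sqi.index], bool(tied)


# ------------------------------------------------- functional wrappers

def membership(values: pd.DataFrame, directions: dict | None = None) -> pd.DataFrame:
    return MinMaxMembership(directions).fit(values).transform(values)


def pca_weighting(values: pd.DataFrame, m: int = 4,
                  variance_threshold: float | None = None) -> PCALoadingWeights:
    return PCALoadingWeights(n_components=m,
                             variance_threshold=variance_threshold).fit(values)


def sqi(memberships: pd.DataFrame, weighting: PCALoadingWeights) -> pd.DataFrame:
    values = aggregate_sqi(memberships, weighting)
    ranks, tied = rank_entities(values)
    return pd.DataFrame({"SQI": values, "rank": ranks, "tied": tied})


# --------------------------------------------------------- full pipeline

@dataclass
class SqiPipelineResult:
    table: pd.DataFrame              # entity x indicator input table
    membership: pd.DataFrame
    loadings: pd.DataFrame
    weights: pd.DataFrame
    contribution_rates: np.ndarray   # percent, all components
    n_components: int
    sqi: pd.Series
    ranks: pd.Series
    tied: bool
    entity_mode: str
    estimator: SoilQualityIndex = field(repr=False, default=None)


def assemble_indicator_table(chem: pd.DataFrame,
                             alpha: dict[str, pd.DataFrame] | None,
                             entity_mode: str = "treatment-means",
                             indicators: list[str] | None = None) -> pd.DataFrame:
    """Join chemistry and per-domain alpha diversity into the entity table.

    ``entity_mode`` "treatment-means" averages replicates (entities are
    treatments, the default); "replicate-level" keeps every sample.
    """
    chem = chem.copy()
    chem_cols = [c for c in chem.columns
                 if c not in ("sample_id", "treatment", "replicate")]
    table = chem.set_index("sample_id")[chem_cols + ["treatment"]]
    for domain, adf in (alpha or {}).items():
        sub = adf.set_index("sample_id")
        table[f"chao1_{domain}"] = sub["chao1"]
        table[f"shannon_{domain}"] = sub["shannon"]
    if table.drop(columns="treatment").isna().any().any():
        bad = table.columns[table.isna().any()].tolist()
        raise ValueError(f"indicator table has missing values in {bad}")
    if entity_mode == "treatment-means":
        out = table.groupby("treatment", sort=False).mean()
    elif entity_mode == "replicate-level":
        out = table.drop(columns="treatment")
    else:
        raise ValueError("entity_mode must be 'treatment-means' or 'replicate-level'")
    if indicators is not None:
        missing = set(indicators) - set(out.columns)
        if missing:
            raise ValueError(f"indicators absent from table: {sorted(missing)}")
        out = out[list(indicators)]
    return out


def run_sqi_pipeline(chem: pd.DataFrame,
                     alpha: dict[str, pd.DataFrame] | None = None,
                     directions: dict | None = None,
                     n_components: int = 4,
                     variance_threshold: float | None = None,
                     entity_mode: str = "treatment-means",
                     indicators: list[str] | None = None) -> SqiPipelineResult:
    """Assemble the indicator table and run membership -> weights -> SQI."""
    table = assemble_indicator_table(chem, alpha, entity_mode=entity_mode,
                                     indicators=indicators)
    est = SoilQualityIndex(
        directions=directions, n_components=n_components,
        variance_threshold=variance_threshold,
    ).fit(table)
    return SqiPipelineResult(
        table=table,
        membership=est.membership_,
        loadings=est.weighting_.loadings_,
        weights=est.weighting_.weights_,
        contribution_rates=est.weighting_.contribution_rates_,
        n_components=est.weighting_.n_components_,
        sqi=est.sqi_,
        ranks=est.ranks_,
        tied=est.tied_,
        entity_mode=entity_mode,
        estimator=est,
    )
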