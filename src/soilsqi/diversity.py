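"""Community diversity, ordination and distance-based statistics.

Alpha diversity (bias-corrected Chao1, Shannon in nats, Pielou evenness),
rank-level composition summaries, Bray-Curtis dissimilarity, principal
coordinates analysis, redundancy analysis against soil chemistry, Mantel
tests, Spearman genus-environment panels, and the regression of pairwise
community distance on pairwise soil-quality-index differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import chao1, pielou_e, shannon
from skbio.stats.distance import mantel as _skbio_mantel

from .simulate import CommunityMatrix


# ---------------------------------------------------------------- alpha

def alpha_diversity(cm: CommunityMatrix, rarefy_to: int | None = None,
                    seed: int | None = None) -> pd.DataFrame:
    """Per-sample observed richness, Chao1, Shannon (nats) and Pielou evenness.

    Chao1 uses the bias-corrected form S_obs + F1(F1-1)/(2(F2+1)) so it is
    defined when no doubletons occur.  Optional seeded rarefaction subsamples
    each sample to ``rarefy_to`` reads without replacement.
    """
    counts = cm.counts
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        empty = counts.index[totals == 0].tolist()
        raise ValueError(f"empty samples: {empty}")
    if rarefy_to is not None:
        counts = rarefy(counts, rarefy_to, seed=seed)
    rows = []
    for sample_id, row in counts.iterrows():
        v = row.to_numpy()
        v = v[v > 0]
        s_obs = len(v)
        h = float(shannon(v, base=np.e)) if s_obs > 1 else 0.0
        rows.append(
            {
                "sample_id": sample_id,
                "domain": cm.domain,
                "observed_otus": s_obs,
                "chao1": float(chao1(v, bias_corrected=True)),
                "shannon": h,
                "pielou": h / np.log(s_obs) if s_obs > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def rarefy(counts: pd.DataFrame, depth: int, seed: int | None = None) -> pd.DataFrame:
    """Subsample every sample to ``depth`` reads without replacement."""
    rng = np.random.default_rng(seed)
    out = np.zeros_like(counts.to_numpy())
    for i, (_, row) in enumerate(counts.iterrows()):
        v = row.to_numpy()
        if v.sum() < depth:
            raise ValueError("rarefaction depth exceeds sample total")
        pool = np.repeat(np.arange(len(v)), v)
        chosen = rng.choice(pool, size=depth, replace=False)
        out[i] = np.bincount(chosen, minlength=len(v))
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


# ---------------------------------------------------------- composition

def composition_by_rank(cm: CommunityMatrix, rank: str = "phylum",
                        treatments: pd.Series | None = None) -> pd.DataFrame:
    """Relative abundance collapsed to a taxonomic rank.

    Returns a per-sample table unless ``treatments`` (sample -> label) is
    given, in which case replicate means per treatment are reported.  Rows
    sum to 1; OTUs lacking the rank go to "Unclassified".
    """
    if rank not in cm.taxonomy.columns:
        raise ValueError(f"taxonomy lacks rank: {rank}")
    labels = cm.taxonomy[rank].reindex(cm.counts.columns).fillna("Unclassified")
    collapsed = cm.counts.T.groupby(labels.values).sum().T
    rel = collapsed.div(collapsed.sum(axis=1), axis=0)
    if treatments is None:
        return rel
    rel = rel.copy()
    rel["__t"] = treatments.reindex(rel.index)
    return rel.groupby("__t").mean().rename_axis("treatment")


# ---------------------------------------------------------------- beta

def bray_curtis(cm: CommunityMatrix, use_relative: bool = True) -> DistanceMatrix:
    """Bray-Curtis dissimilarity, by default on relative abundances so
    library size differences do not masquerade as community turnover."""
    data = cm.relative_abundance() if use_relative else cm.counts.astype(float)
    return beta_diversity("braycurtis", data.to_numpy(), ids=list(data.index))


@dataclass
class OrdinationResult:
    method: str
    coordinates: pd.DataFrame          # samples x axes
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray   # percent, per plotted axis
    total_explained: float | None = None
    warnings: list = field(default_factory=list)


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Principal coordinates analysis (classical metric scaling).

    Eigendecomposes the Gower-centered -d^2/2 matrix; coordinates are
    eigenvectors scaled by sqrt(eigenvalue) for positive eigenvalues, and
    explained percentages use only the positive part of the spectrum (no
    Lingoes/Cailliez correction).
    """
    d = dm.data
    n = d.shape[0]
    if np.allclose(d, 0):
        return OrdinationResult(
            method="PCoA",
            coordinates=pd.DataFrame(np.zeros((n, 1)), index=list(dm.ids),
                                     columns=["PCo1"]),
            eigenvalues=np.zeros(1),
            proportion_explained=np.array([np.nan]),
            warnings=["degenerate: all distances zero"],
        )
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(1e-12 * eigvals.max(), 0)
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    explained = 100.0 * eigvals[pos] / eigvals[pos].sum()
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        method="PCoA",
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=cols),
        eigenvalues=eigvals,
        proportion_explained=explained,
    )


def hellinger(counts: pd.DataFrame) -> pd.DataFrame:
    rel = counts.div(counts.sum(axis=1), axis=0)
    return np.sqrt(rel)


def rda(community: pd.DataFrame, chem: pd.DataFrame,
        indicators: list[str] | None = None) -> OrdinationResult:
    """Redundancy analysis of a community table on soil indicators.

    Response: Hellinger-transformed relative abundances, column-centered.
    Explanatory: standardized indicator columns (collinear columns dropped
    deterministically, left to right).  Constrained axes are the PCA of the
    fitted values; total explained % is the trace ratio of fitted to total
    covariance.
    """
    from .chemistry import DEFAULT_INDICATORS

    indicators = indicators or [c for c in DEFAULT_INDICATORS if c in chem.columns]
    chem = chem.set_index("sample_id") if "sample_id" in chem.columns else chem
    missing = set(community.index) - set(chem.index)
    if missing:
        raise ValueError(f"chemistry missing samples: {sorted(missing)[:5]}")
    x_raw = chem.loc[community.index, indicators].to_numpy(float)

    warnings_list = []
    y = hellinger(community).to_numpy()
    y = y - y.mean(axis=0)

    sd = x_raw.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [indicators[i] for i in np.flatnonzero(~keep)]
        warnings_list.append(f"dropped zero-variance indicators: {dropped}")
    x = (x_raw[:, keep] - x_raw[:, keep].mean(axis=0)) / sd[keep]
    kept_names = [ind for ind, k in zip(indicators, keep) if k]

    # Drop collinear columns left-to-right via rank-revealing QR.
    cols: list[int] = []
    for i in range(x.shape[1]):
        trial = x[:, cols + [i]]
        if np.linalg.matrix_rank(trial, tol=1e-10) == len(cols) + 1:
            cols.append(i)
        else:
            warnings_list.append(f"dropped collinear indicator: {kept_names[i]}")
    x = x[:, cols]
    if x.shape[0] <= x.shape[1]:
        warnings_list.append(
            "number of constraints >= samples: fit is saturated/unstable"
        )

    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    total_ss = np.sum(y ** 2)
    fitted_ss = np.sum(fitted ** 2)
    total_explained = 100.0 * fitted_ss / total_ss if total_ss > 0 else np.nan

    u, s, _ = np.linalg.svd(fitted, full_matrices=False)
    eigvals = s ** 2 / max(len(community) - 1, 1)
    pos = eigvals > 1e-12 * max(eigvals.max(), 1e-300)
    coords = (u * s)[:, pos]
    explained = 100.0 * eigvals[pos] / eigvals.sum() * (fitted_ss / total_ss)
    cols_names = [f"RDA{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        method="RDA",
        coordinates=pd.DataFrame(coords, index=list(community.index),
                                 columns=cols_names),
        eigenvalues=eigvals[pos],
        proportion_explained=explained,
        total_explained=float(total_explained),
        warnings=warnings_list,
    )


# --------------------------------------------------------------- mantel

def mantel(d1: DistanceMatrix, d2: DistanceMatrix, permutations: int = 999,
           seed: int | None = None) -> tuple[float, float]:
    """One-sided (positive association) Mantel test.

    r is the Pearson correlation of the upper triangles; p is the
    add-one permutation p-value under row/column label permutation of d2.
    """
    if list(d1.ids) != list(d2.ids):
        d2 = d2.filter(d1.ids)
    tri = np.triu_indices(d1.shape[0], k=1)
    if np.ptp(d1.data[tri]) == 0 or np.ptp(d2.data[tri]) == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    r, p, _ = _skbio_mantel(d1, d2, method="pearson",
                            permutations=permutations,
                            alternative="greater", seed=seed)
    return float(r), float(p)


def mantel_panel(dms: dict[str, DistanceMatrix], chem: pd.DataFrame,
                 indicators: list[str] | None = None, permutations: int = 999,
                 seed: int | None = None) -> pd.DataFrame:
    """Mantel r/p of each community distance matrix against the Euclidean
    distance of every single (standardized) soil indicator."""
    from .chemistry import DEFAULT_INDICATORS

    indicators = indicators or [c for c in DEFAULT_INDICATORS if c in chem.columns]
    chem = chem.set_index("sample_id") if "sample_id" in chem.columns else chem
    rows = []
    for name, dm in dms.items():
        vals = chem.loc[list(dm.ids), indicators]
        for ind in indicators:
            z = vals[ind].to_numpy(float)
            sd = z.std(ddof=1)
            if sd == 0:
                rows.append({"community": name, "indicator": ind,
                             "mantel_r": np.nan, "p": np.nan})
                continue
            z = (z - z.mean()) / sd
            dz = DistanceMatrix(np.abs(z[:, None] - z[None, :]), ids=list(dm.ids))
            r, p = mantel(dm, dz, permutations=permutations, seed=seed)
            rows.append({"community": name, "indicator": ind,
                         "mantel_r": r, "p": p})
    return pd.DataFrame(rows)


# ------------------------------------------------------------- spearman

def _stars(p: float) -> str:
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def spearman_panel(cm: CommunityMatrix, chem: pd.DataFrame,
                   rank: str = "genus", top_n: int = 10,
                   indicators: list[str] | None = None) -> pd.DataFrame:
    """Spearman correlations (two-tailed, average-rank ties) between the
    top-abundance taxa at a rank and each soil indicator."""
    from .chemistry import DEFAULT_INDICATORS

    indicators = indicators or [c for c in DEFAULT_INDICATORS if c in chem.columns]
    chem = chem.set_index("sample_id") if "sample_id" in chem.columns else chem
    rel = composition_by_rank(cm, rank=rank)
    rel = rel.loc[:, rel.mean(axis=0).sort_values(ascending=False).index[:top_n]]
    rows = []
    for taxon in rel.columns:
        a = rel[taxon].to_numpy(float)
        for ind in indicators:
            b = chem.loc[rel.index, ind].to_numpy(float)
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                rows.append({"taxon": taxon, "indicator": ind,
                             "spearman_rho": np.nan, "p": np.nan, "stars": ""})
                continue
            rho, p = stats.spearmanr(a, b)
            rows.append({"taxon": taxon, "indicator": ind,
                         "spearman_rho": float(rho), "p": float(p),
                         "stars": _stars(p)})
    return pd.DataFrame(rows)


# ------------------------------------------- distance vs SQI regression

@dataclass
class DistanceSqiRegression:
    slope: float
    intercept: float
    r_squared: float
    p_permutation: float
    n_pairs: int
    degenerate: bool = False


def distance_vs_sqi_regression(dm: DistanceMatrix, sqi: pd.Series,
                               permutations: int = 999,
                               seed: int | None = None) -> DistanceSqiRegression:
    """OLS of pairwise community distance on pairwise |SQI difference|.

    Distance pairs are not independent, so significance uses Mantel-style
    permutation of sample labels on the SQI vector (one-sided: observed
    r^2 at least as large as permuted).
    """
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValueError("need >= 3 samples")
    missing = set(ids) - set(sqi.index)
    if missing:
        raise ValueError(f"SQI missing for samples: {sorted(missing)[:5]}")
    s = sqi.loc[ids].to_numpy(float)
    tri = np.triu_indices(len(ids), k=1)
    y = dm.data[tri]
    if np.ptp(s) == 0:
        return DistanceSqiRegression(np.nan, np.nan, np.nan, np.nan,
                                     len(y), degenerate=True)
    x = np.abs(s[:, None] - s[None, :])[tri]
    res = stats.linregress(x, y)
    obs_r2 = res.rvalue ** 2

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(permutations):
        sp = rng.permutation(s)
        xp = np.abs(sp[:, None] - sp[None, :])[tri]
        if np.ptp(xp) == 0:
            continue
        r = np.corrcoef(xp, y)[0, 1]
        if r ** 2 >= obs_r2:
            exceed += 1
    p = (1 + exceed) / (permutations + 1)
    return DistanceSqiRegression(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(obs_r2), p_permutation=float(p), n_pairs=len(y),
    )


def distance_to_control_vs_sqi(dm: DistanceMatrix, sqi: pd.Series,
                               treatments: pd.Series,
                               control: str = "CK") -> dict:
    """Alternative reading: per-sample mean distance to the control samples
    regressed on per-sample SQI (plain OLS)."""
    ids = list(dm.ids)
    ctrl = [i for i in ids if treatments.loc[i] == control]
    if not ctrl:
        raise ValueError("no control samples present")
    d = pd.DataFrame(dm.data, index=ids, columns=ids)
    xs, ys = [], []
    for i in ids:
        others = [c for c in ctrl if c != i]
        if not others:
            continue
        xs.append(sqi.loc[i])
        ys.append(d.loc[i, others].mean())
    res = stats.linregress(xs, ys)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r_squared": float(res.rvalue ** 2), "p": float(res.pvalue)}
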