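"""Treatment-level soil chemistry statistics.

Summaries (mean +/- sd with Tukey letter groups), one-way ANOVA per
indicator, and percent/fold change reports between treatments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_INDICATORS = ["SOM", "AN", "AP", "AK", "pH", "EC"]


def _groups(chem: pd.DataFrame, indicator: str) -> tuple[list[str], list[np.ndarray]]:
    if indicator not in chem.columns:
        raise ValueError(f"indicator column missing: {indicator}")
    labels = list(dict.fromkeys(chem["treatment"]))
    values = [chem.loc[chem["treatment"] == t, indicator].to_numpy(float)
              for t in labels]
    return labels, values


def summarize(chem: pd.DataFrame, indicators: list[str] | None = None,
              alpha: float = 0.05) -> pd.DataFrame:
    """Per (treatment, indicator): sample mean, sd (n-1 denominator), n, and
    Tukey HSD letter group (shared letter = not significantly different)."""
    indicators = indicators or [c for c in DEFAULT_INDICATORS if c in chem.columns]
    missing = [c for c in indicators if c not in chem.columns]
    if missing:
        raise ValueError(f"indicator column missing: {missing[0]}")
    rows = []
    for indicator in indicators:
        labels, values = _groups(chem, indicator)
        if any(len(v) < 2 for v in values):
            raise ValueError(f"need >=2 replicates per treatment for {indicator}")
        letters = tukey_letters(chem, indicator, alpha=alpha)
        for t, v in zip(labels, values):
            rows.append(
                {
                    "treatment": t,
                    "indicator": indicator,
                    "mean": float(np.mean(v)),
                    "sd": float(np.std(v, ddof=1)),
                    "n": len(v),
                    "tukey_letter": letters[t],
                }
            )
    return pd.DataFrame(rows)


def anova_oneway(chem: pd.DataFrame, indicator: str) -> dict:
    """Classical one-way ANOVA F = MS_between / MS_within.

    Degenerate cases: all values identical -> F=0, p=1; zero within-group
    variance with unequal means -> p=0 with a degenerate flag.
    """
    _, values = _groups(chem, indicator)
    if len(values) < 2:
        raise ValueError("need >= 2 treatment groups")
    if any(len(v) < 2 for v in values):
        raise ValueError("need >= 2 replicates in every group")
    all_vals = np.concatenate(values)
    within_var = sum(np.sum((v - v.mean()) ** 2) for v in values)
    means = np.array([v.mean() for v in values])
    if within_var == 0:
        if np.allclose(means, means[0]):
            return {"F": 0.0, "p": 1.0, "degenerate": False}
        return {"F": np.inf, "p": 0.0, "degenerate": True}
    f, p = stats.f_oneway(*values)
    if np.allclose(all_vals, all_vals[0]):
        return {"F": 0.0, "p": 1.0, "degenerate": False}
    return {"F": float(f), "p": float(p), "degenerate": False}


def anova_with_blocks(chem: pd.DataFrame, indicator: str) -> dict:
    """Additive two-way ANOVA (treatment + replicate block, no interaction).

    With one observation per treatment x replicate cell this is the
    estimable analogue of a mixed model with replication as a fixed effect.
    """
    labels, _ = _groups(chem, indicator)
    pivot = chem.pivot_table(index="treatment", columns="replicate",
                             values=indicator)
    if pivot.isna().any().any():
        raise ValueError("block ANOVA needs a complete treatment x replicate layout")
    y = pivot.to_numpy(float)
    a, b = y.shape
    grand = y.mean()
    ss_t = b * np.sum((y.mean(axis=1) - grand) ** 2)
    ss_b = a * np.sum((y.mean(axis=0) - grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_e = ss_tot - ss_t - ss_b
    df_t, df_b = a - 1, b - 1
    df_e = df_t * df_b
    ms_t, ms_e = ss_t / df_t, ss_e / df_e
    if ms_e == 0:
        return {"F": np.inf if ms_t > 0 else 0.0,
                "p": 0.0 if ms_t > 0 else 1.0, "degenerate": True}
    f = ms_t / ms_e
    return {"F": float(f), "p": float(stats.f.sf(f, df_t, df_e)),
            "degenerate": False}


def tukey_pairwise(chem: pd.DataFrame, indicator: str) -> pd.DataFrame:
    """All pairwise Tukey HSD p-values (Tukey-Kramer for unequal n)."""
    labels, values = _groups(chem, indicator)
    if len(labels) < 2:
        raise ValueError("need >= 2 treatment groups")
    within_var = sum(np.sum((v - v.mean()) ** 2) for v in values)
    if np.ptp(np.concatenate(values)) == 0:
        # identical data everywhere: no pair differs
        p = np.ones((len(labels), len(labels)))
    elif within_var == 0:
        # perfectly separated groups: any unequal-mean pair differs
        means = np.array([v.mean() for v in values])
        p = np.where(np.isclose(means[:, None], means[None, :]), 1.0, 0.0)
    else:
        res = stats.tukey_hsd(*values)
        p = res.pvalue
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rows.append({"a": labels[i], "b": labels[j], "p": float(p[i, j])})
    return pd.DataFrame(rows)


def tukey_letters(chem: pd.DataFrame, indicator: str, alpha: float = 0.05) -> dict:
    """Compact letter display for Tukey HSD groups.

    Treatments sorted by mean descending; 'a' marks the largest-mean group;
    treatments sharing any letter are not significantly different at alpha.
    """
    labels, values = _groups(chem, indicator)
    pw = tukey_pairwise(chem, indicator)
    pmat = {}
    for _, row in pw.iterrows():
        pmat[(row["a"], row["b"])] = row["p"]
        pmat[(row["b"], row["a"])] = row["p"]
    means = {t: np.mean(v) for t, v in zip(labels, values)}
    order = sorted(labels, key=lambda t: -means[t])

    nonsig = {
        t: {u for u in order if u == t or pmat[(t, u)] >= alpha} for t in order
    }
    # Sweep means-descending: each maximal run of mutually non-different
    # treatments gets the next letter; runs nested in a previous one are
    # absorbed.
    groups: list[set] = []
    for i, t in enumerate(order):
        run = {t}
        for u in order[i + 1:]:
            if all(u in nonsig[v] for v in run):
                run.add(u)
            else:
                break
        if not any(run <= g for g in groups):
            groups.append(run)
    letters = {t: "" for t in order}
    for letter_i, g in enumerate(groups):
        for t in order:
            if t in g:
                letters[t] += chr(ord("a") + letter_i)
    return letters


@dataclass(frozen=True)
class ChangeReport:
    indicator: str
    numerator: str
    denominator: str
    percent_change: float
    fold_change: float

    def __str__(self) -> str:
        return (
            f"{self.indicator} {self.numerator} vs {self.denominator}: "
            f"{self.percent_change:.2f}% ({self.fold_change:.2f}-fold)"
        )


def change_report(summary: pd.DataFrame, indicator: str,
                  num_treatment: str, den_treatment: str) -> ChangeReport:
    """Percent change and fold change between two treatment means."""
    sub = summary[summary["indicator"] == indicator].set_index("treatment")
    for t in (num_treatment, den_treatment):
        if t not in sub.index:
            raise ValueError(f"treatment missing from summary: {t}")
    num = sub.loc[num_treatment, "mean"]
    den = sub.loc[den_treatment, "mean"]
    if den <= 0:
        raise ValueError("denominator mean must be positive")
    return ChangeReport(
        indicator=indicator,
        numerator=num_treatment,
        denominator=den_treatment,
        percent_change=100.0 * (num - den) / den,
        fold_change=num / den,
    )


def change_table(summary: pd.DataFrame,
                 comparisons: list[tuple[str, str, str]]) -> pd.DataFrame:
    rows = []
    for indicator, num, den in comparisons:
        rep = change_report(summary, indicator, num, den)
        rows.append(
            {
                "indicator": indicator,
                "numerator": num,
                "denominator": den,
                "percent_change": rep.percent_change,
                "fold_change": rep.fold_change,
            }
        )
    return pd.DataFrame(rows)
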