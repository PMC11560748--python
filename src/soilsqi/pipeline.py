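"""End-to-end orchestration: simulate -> chemistry -> diversity -> SQI -> networks.

A single RunConfig (YAML-loadable, CLI-overridable) drives every stage; all
randomness flows from one global seed through fixed per-stage streams, so a
re-run with the same config and seed is byte-identical.  Every intermediate
is written as TSV under the output directory and the run closes with a JSON
report echoing parameters, stage status, key results and warnings.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chemistry import change_table, summarize
from .diversity import (alpha_diversity, bray_curtis, composition_by_rank,
                        distance_vs_sqi_regression, mantel_panel, pcoa, rda,
                        spearman_panel)
from .network import per_treatment_networks, summary_table
from .scenario import ScenarioSpec
from .simulate import (CommunityMatrix, generate_chemistry,
                       generate_communities, read_chemistry, write_chemistry)
from .sqi import run_sqi_pipeline

log = logging.getLogger("soilsqi")

DEFAULT_COMPARISONS = [
    ("SOM", "JA", "GF"), ("AN", "JA", "CK"), ("AN", "CP", "CK"),
    ("AK", "JA", "CK"), ("AK", "GF", "CK"),
    ("AP", "GF", "CK"), ("AP", "JA", "CK"), ("AP", "CP", "CK"),
]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    chemistry_path: str | None = None          # None -> synthetic
    community_paths: dict = field(default_factory=dict)  # domain -> TSV path
    scenario: dict = field(default_factory=dict)         # ScenarioSpec overrides
    outdir: str = "soilsqi_out"
    seed: int = 0
    alpha_level: float = 0.05
    stages: dict = field(default_factory=lambda: {
        "simulate": True, "chemistry": True, "diversity": True,
        "sqi": True, "network": True,
    })
    # stage parameters
    indicators: list | None = None
    directions: dict | None = None
    n_components: int = 4
    variance_threshold: float | None = None
    entity_mode: str = "treatment-means"
    rank: str = "genus"
    top_n_taxa: int = 10
    top_n_otus: int = 100
    r_threshold: float = 0.9
    p_threshold: float = 0.05
    network_pooled: bool = True
    permutations: int = 999
    comparisons: list = field(default_factory=lambda: list(DEFAULT_COMPARISONS))

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def validate_inputs(chemistry_path=None, community_paths=None) -> list[str]:
    """Schema and alignment diagnostics for user-supplied inputs.

    Returns a list of human-readable diagnostics; empty means well-formed.
    Never mutates or raises on content problems.
    """
    diagnostics: list[str] = []
    chem = None
    if chemistry_path is not None:
        try:
            chem = read_chemistry(chemistry_path)
        except Exception as exc:  # noqa: BLE001 - diagnostics only
            diagnostics.append(f"chemistry: unreadable ({exc})")
        if chem is not None:
            if chem["sample_id"].duplicated().any():
                dups = chem.loc[chem["sample_id"].duplicated(), "sample_id"]
                diagnostics.append(f"chemistry: duplicate sample_id {list(dups)}")
            value_cols = [c for c in chem.columns
                         if c not in ("sample_id", "treatment", "replicate")]
            if chem[value_cols].isna().any().any():
                diagnostics.append("chemistry: missing cells")
            for c in value_cols:
                if c == "pH":
                    bad = ~chem[c].between(0, 14, inclusive="neither")
                else:
                    bad = chem[c] <= 0
                if bad.any():
                    diagnostics.append(
                        f"chemistry: non-positive/out-of-range {c} for "
                        f"{list(chem.loc[bad, 'sample_id'])}"
                    )
    for domain, path in (community_paths or {}).items():
        try:
            raw = pd.read_csv(path, sep="\t", index_col="otu_id")
        except Exception as exc:  # noqa: BLE001
            diagnostics.append(f"{domain}: unreadable ({exc})")
            continue
        if "taxonomy" not in raw.columns:
            diagnostics.append(f"{domain}: taxonomy column missing")
        counts = raw.drop(columns=["taxonomy"], errors="ignore")
        numeric = counts.apply(pd.to_numeric, errors="coerce")
        if numeric.isna().any().any():
            diagnostics.append(f"{domain}: non-numeric counts")
            continue
        neg = np.argwhere(numeric.to_numpy() < 0)
        for i, j in neg:
            diagnostics.append(
                f"{domain}: negative count at otu {numeric.index[i]}, "
                f"sample {numeric.columns[j]}"
            )
        frac = numeric.to_numpy() % 1
        nonint = np.argwhere(frac != 0)
        for i, j in nonint[:5]:
            diagnostics.append(
                f"{domain}: non-integral count at otu {numeric.index[i]}, "
                f"sample {numeric.columns[j]}"
            )
        if chem is not None:
            chem_samples = set(chem["sample_id"])
            table_samples = set(numeric.columns)
            for missing in sorted(chem_samples - table_samples):
                diagnostics.append(f"{domain}: sample {missing} missing "
                                   "from community table")
            for extra in sorted(table_samples - chem_samples):
                diagnostics.append(f"{domain}: sample {extra} absent "
                                   "from chemistry table")
    return diagnostics


def run(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__, "seed": config.seed,
        "parameters": {k: v for k, v in asdict(config).items()
                       if k not in ("scenario",)},
        "stages": {}, "warnings": [],
    }
    rng_seed = int(config.seed)

    # --- inputs -----------------------------------------------------------
    if config.chemistry_path is None:
        if not config.stages.get("simulate", True):
            raise RuntimeError("chemistry input missing and simulate stage disabled")
        spec = ScenarioSpec.from_dict(config.scenario).with_seed(rng_seed)
        log.info("simulate: generating synthetic scenario (seed=%s)", rng_seed)
        chem = generate_chemistry(spec)
        communities = generate_communities(spec, chem)
        write_chemistry(chem, outdir / "chemistry.tsv")
        for domain, cm in communities.items():
            cm.to_tsv(outdir / f"otu_table_{domain}.tsv")
        report["stages"]["simulate"] = {"status": "ok",
                                        "samples": len(chem),
                                        "domains": list(communities)}
    else:
        chem = read_chemistry(config.chemistry_path)
        communities = {
            domain: CommunityMatrix.from_tsv(path, domain)
            for domain, path in config.community_paths.items()
        }
        report["stages"]["simulate"] = {"status": "skipped (user inputs)"}
    treatments = chem.set_index("sample_id")["treatment"]

    # --- chemistry stats --------------------------------------------------
    if config.stages.get("chemistry", True):
        log.info("chemistry: treatment summaries and change reports")
        summary = summarize(chem, alpha=config.alpha_level)
        summary.to_csv(outdir / "chemistry_summary.tsv", sep="\t", index=False)
        comparisons = [tuple(c) for c in config.comparisons]
        available = set(treatments)
        comparisons = [c for c in comparisons
                       if {c[1], c[2]} <= available]
        changes = change_table(summary, comparisons)
        changes.to_csv(outdir / "chemistry_changes.tsv", sep="\t", index=False)
        report["stages"]["chemistry"] = {
            "status": "ok",
            "summary": _table1_layout(summary).to_dict(),
            "changes": changes.round(2).to_dict(orient="records"),
        }
    else:
        summary = None
        report["stages"]["chemistry"] = {"status": "skipped"}

    # --- diversity --------------------------------------------------------
    alpha = {}
    distances = {}
    if config.stages.get("diversity", True):
        log.info("diversity: alpha, Bray-Curtis, PCoA, RDA, Mantel, Spearman")
        diversity_report = {}
        for domain, cm in communities.items():
            adf = alpha_diversity(cm)
            adf.to_csv(outdir / f"alpha_{domain}.tsv", sep="\t", index=False)
            alpha[domain] = adf
            merged = adf.merge(chem[["sample_id", "treatment"]], on="sample_id")
            means = merged.groupby("treatment", sort=False)[
                ["observed_otus", "chao1", "shannon", "pielou"]
            ].mean()
            dm = bray_curtis(cm)
            distances[domain] = dm
            pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
                outdir / f"bray_curtis_{domain}.tsv", sep="\t"
            )
            ord_res = pcoa(dm)
            ord_res.coordinates.to_csv(outdir / f"pcoa_{domain}.tsv", sep="\t")
            rda_res = rda(composition_by_rank(cm, rank=config.rank), chem)
            panel = spearman_panel(cm, chem, rank=config.rank,
                                   top_n=config.top_n_taxa)
            panel.to_csv(outdir / f"spearman_{domain}.tsv", sep="\t", index=False)
            comp = composition_by_rank(cm, rank="phylum", treatments=treatments)
            comp.to_csv(outdir / f"composition_phylum_{domain}.tsv", sep="\t")
            report["warnings"].extend(
                f"rda[{domain}]: {w}" for w in rda_res.warnings
            )
            diversity_report[domain] = {
                "alpha_treatment_means": means.round(3).to_dict(),
                "pcoa_explained_pct": [round(float(v), 2) for v in
                                       ord_res.proportion_explained[:2]],
                "rda_total_explained_pct": round(rda_res.total_explained, 2),
            }
        mantel_df = mantel_panel(distances, chem,
                                 permutations=config.permutations,
                                 seed=rng_seed)
        mantel_df.to_csv(outdir / "mantel.tsv", sep="\t", index=False)
        diversity_report["mantel"] = mantel_df.round(4).to_dict(orient="records")
        report["stages"]["diversity"] = {"status": "ok", **diversity_report}
    else:
        report["stages"]["diversity"] = {"status": "skipped"}

    # --- SQI --------------------------------------------------------------
    if config.stages.get("sqi", True):
        if not alpha:
            for domain, cm in communities.items():
                alpha[domain] = alpha_diversity(cm)
        log.info("sqi: membership -> PCA weights -> index")
        res = run_sqi_pipeline(
            chem, alpha, directions=config.directions,
            n_components=config.n_components,
            variance_threshold=config.variance_threshold,
            entity_mode=config.entity_mode, indicators=config.indicators,
        )
        sqi_df = pd.DataFrame({"SQI": res.sqi, "rank": res.ranks})
        sqi_df.to_csv(outdir / "sqi.tsv", sep="\t")
        res.membership.to_csv(outdir / "sqi_membership.tsv", sep="\t")
        res.loadings.to_csv(outdir / "sqi_loadings.tsv", sep="\t")
        res.weights.to_csv(outdir / "sqi_weights.tsv", sep="\t")
        pd.Series(res.contribution_rates,
                  index=[f"PC{j+1}" for j in range(len(res.contribution_rates))],
                  name="contribution_pct").to_csv(outdir / "sqi_contributions.tsv",
                                                  sep="\t")
        report["stages"]["sqi"] = {
            "status": "ok",
            "entity_mode": res.entity_mode,
            "n_components": res.n_components,
            "cumulative_contribution_pct": round(
                float(res.contribution_rates[: res.n_components].sum()), 2),
            "sqi": res.sqi.round(2).to_dict(),
            "ranking": res.ranks.to_dict(),
            "tied": res.tied,
        }
        if config.stages.get("diversity", True) and distances:
            reg_report = {}
            sqi_by_sample = None
            if res.entity_mode == "treatment-means":
                sqi_by_sample = treatments.map(res.sqi)
            else:
                sqi_by_sample = res.sqi
            for domain, dm in distances.items():
                reg = distance_vs_sqi_regression(
                    dm, sqi_by_sample, permutations=config.permutations,
                    seed=rng_seed)
                reg_report[domain] = {
                    "slope": round(reg.slope, 4), "r_squared": round(reg.r_squared, 4),
                    "p_permutation": round(reg.p_permutation, 4),
                }
            report["stages"]["sqi"]["distance_regression"] = reg_report
    else:
        report["stages"]["sqi"] = {"status": "skipped"}

    # --- networks ---------------------------------------------------------
    if config.stages.get("network", True):
        log.info("network: thresholded Pearson co-occurrence")
        nets = per_treatment_networks(
            communities, chem, top_n=config.top_n_otus,
            r_threshold=config.r_threshold, p_threshold=config.p_threshold,
            seed=rng_seed, pooled=config.network_pooled,
        )
        table = summary_table(nets)
        table.to_csv(outdir / "network_summary.tsv", sep="\t")
        for label, (net, _) in nets.items():
            net.to_edge_tsv(outdir / f"network_edges_{label}.tsv")
            net.to_graphml(outdir / f"network_{label}.graphml")
        report["stages"]["network"] = {
            "status": "ok",
            "summary": table.round(4).to_dict(),
            "flags": {label: s.flags for label, (_, s) in nets.items() if s.flags},
        }
    else:
        report["stages"]["network"] = {"status": "skipped"}

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    return report


def _table1_layout(summary: pd.DataFrame) -> pd.DataFrame:
    """mean +/- sd with letter, treatments x indicators."""
    cells = summary.apply(
        lambda r: f"{r['mean']:.2f} ± {r['sd']:.2f}{r['tukey_letter']}",
        axis=1)
    out = summary.assign(cell=cells).pivot(index="treatment",
                                           columns="indicator", values="cell")
    return out


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
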