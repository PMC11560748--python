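"""Synthetic data generator for the field-trial analysis pipeline.

Two stages: replicate-level soil chemistry (independent normal draws per
treatment x indicator, resampled until physically valid) and sample x OTU
count tables per microbial domain drawn from a Dirichlet-multinomial whose
mean composition follows treatment-specific phylum profiles.  Treatment
richness is controlled through the number of OTUs carrying nonzero Dirichlet
mass, so realized Chao1 fold-changes track the configured multipliers, and
correlated OTU blocks are planted through shared latent log-abundance
factors to give the co-occurrence module recoverable ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .scenario import ScenarioSpec

# Fixed per-stage RNG stream offsets derived from the single scenario seed.
_CHEM_STREAM = 11
_COMMUNITY_STREAM = {"bacteria": 23, "fungi": 37}
_GENERIC_COMMUNITY_STREAM = 53


@dataclass(frozen=True)
class PlantedBlock:
    """Ground truth for one planted correlated block."""

    otu_ids: tuple
    signs: tuple
    rho: float
    sigma: float

    def pair_signs(self) -> dict:
        """Expected correlation sign for every within-block OTU pair."""
        out = {}
        for a in range(len(self.otu_ids)):
            for b in range(a + 1, len(self.otu_ids)):
                key = tuple(sorted((self.otu_ids[a], self.otu_ids[b])))
                out[key] = self.signs[a] * self.signs[b]
        return out


@dataclass
class CommunityMatrix:
    """Sample x OTU count table with per-OTU taxonomy for one domain."""

    counts: pd.DataFrame            # samples x OTUs, non-negative integers
    taxonomy: pd.DataFrame          # indexed by otu_id: domain, phylum, genus
    domain: str
    planted_blocks: list = field(default_factory=list)

    def __post_init__(self) -> None:
        counts = self.counts
        if (counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(counts.values.dtype, np.integer):
            if not np.allclose(counts.values, np.round(counts.values)):
                raise ValueError("counts must be integral")
            self.counts = counts.round().astype(np.int64)
        if counts.columns.duplicated().any():
            raise ValueError("duplicate otu_id")
        if (counts.sum(axis=1) == 0).any():
            empty = counts.index[counts.sum(axis=1) == 0].tolist()
            raise ValueError(f"all-zero samples: {empty}")
        missing = set(counts.columns) - set(self.taxonomy.index)
        if missing:
            raise ValueError(f"taxonomy missing for OTUs: {sorted(missing)[:5]}")

    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list:
        return list(self.counts.columns)

    def relative_abundance(self) -> pd.DataFrame:
        return self.counts.div(self.counts.sum(axis=1), axis=0)

    def to_tsv(self, path) -> None:
        """Write OTU-per-row TSV with a semicolon-delimited taxonomy column."""
        table = self.counts.T.copy()
        table.index.name = "otu_id"
        lineage = (
            self.taxonomy.loc[table.index, ["domain", "phylum", "genus"]]
            .agg(";".join, axis=1)
        )
        table["taxonomy"] = lineage
        table.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, domain: str) -> "CommunityMatrix":
        raw = pd.read_csv(path, sep="\t", index_col="otu_id")
        lineage = raw.pop("taxonomy").str.split(";", expand=True)
        lineage.columns = ["domain", "phylum", "genus"][: lineage.shape[1]]
        counts = raw.T
        counts.index.name = "sample_id"
        return cls(counts=counts.astype(np.int64), taxonomy=lineage, domain=domain)


def _stage_rng(spec: ScenarioSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, int(spec.seed)])


def generate_chemistry(spec: ScenarioSpec) -> pd.DataFrame:
    """Draw a replicate-level chemistry table for the scenario.

    Each (treatment, indicator) value is an independent normal draw with the
    treatment mean and sd, resampled (never clipped, which would bias the
    mean) until positive — for pH, until inside (0, 14).
    """
    rng = _stage_rng(spec, _CHEM_STREAM)
    rows = []
    for treatment in spec.treatments:
        for rep in range(1, spec.replicates_per_treatment + 1):
            row = {"sample_id": f"{treatment}_{rep}", "treatment": treatment,
                   "replicate": rep}
            for indicator in spec.chemistry_means.columns:
                mu = spec.chemistry_means.loc[treatment, indicator]
                sd = spec.chemistry_sds.loc[treatment, indicator]
                lo, hi = (0.0, 14.0) if indicator == "pH" else (0.0, np.inf)
                if not lo < mu < hi:
                    raise ValueError(
                        f"mean for {treatment}/{indicator} outside valid range"
                    )
                value = mu if sd == 0 else rng.normal(mu, sd)
                while not lo < value < hi:
                    value = rng.normal(mu, sd)
                row[indicator] = value
            rows.append(row)
    return pd.DataFrame(rows)


def write_chemistry(chem: pd.DataFrame, path) -> None:
    chem.to_csv(path, sep="\t", index=False)


def read_chemistry(path) -> pd.DataFrame:
    chem = pd.read_csv(path, sep="\t")
    required = {"sample_id", "treatment", "replicate"}
    missing = required - set(chem.columns)
    if missing:
        raise ValueError(f"chemistry table missing columns: {sorted(missing)}")
    return chem


def _phylum_assignment(n_pool: int, mean_profile: pd.Series) -> np.ndarray:
    """Deterministically partition the OTU pool across phyla in proportion
    to the scenario-average profile (largest-remainder rounding)."""
    target = mean_profile.values * n_pool
    counts = np.floor(target).astype(int)
    remainder = n_pool - counts.sum()
    order = np.argsort(-(target - counts))
    counts[order[:remainder]] += 1
    labels = np.repeat(np.arange(len(mean_profile)), counts)
    return mean_profile.index.values[labels]


def _generate_domain(
    spec: ScenarioSpec, chem: pd.DataFrame, domain: str, rng: np.random.Generator
) -> CommunityMatrix:
    n_base = spec.n_otus_base[domain]
    mult = spec.richness_multiplier[domain]
    profiles = spec.phylum_profiles[domain].loc[list(spec.treatments)]
    blocks = spec.correlated_block_spec.get(domain, [])

    if spec.library_size < 10 * n_base:
        warnings.warn(
            f"library_size {spec.library_size} < 10 x n_otus_base {n_base} for "
            f"{domain}: undersampling will distort richness targets",
            stacklevel=3,
        )

    n_pool = int(np.ceil(n_base * mult.loc[list(spec.treatments)].max()))
    prefix = {"bacteria": "B", "fungi": "F"}.get(domain, domain[:1].upper())
    otu_ids = np.array([f"{prefix}OTU{i:04d}" for i in range(1, n_pool + 1)])
    phyla = _phylum_assignment(n_pool, profiles.mean(axis=0))

    # Heavier-than-even base weights give a realistic rank-abundance curve.
    base_w = rng.lognormal(mean=0.0, sigma=0.7, size=n_pool)

    # Planted blocks occupy the head of the pool (present in every
    # treatment's active set) and get boosted weight so the top-abundance
    # filter retains them.
    planted: list[PlantedBlock] = []
    cursor = 0
    for block in blocks:
        idx = np.arange(cursor, cursor + block.size)
        if idx[-1] >= n_base:
            raise ValueError("correlated blocks exceed the control OTU pool")
        base_w[idx] *= 12.0
        planted.append(
            PlantedBlock(
                otu_ids=tuple(otu_ids[idx]),
                signs=tuple(block.member_signs()),
                rho=block.rho,
                sigma=block.sigma,
            )
        )
        cursor += block.size

    # Active OTU sets are nested: the control uses the first n_base OTUs of a
    # seeded permutation (blocks pinned first); planted treatments extend the
    # pool in proportion to their richness multiplier.
    tail = rng.permutation(np.arange(cursor, n_pool))
    order = np.concatenate([np.arange(cursor), tail])
    active_n = {
        t: min(n_pool, int(round(n_base * mult.loc[t]))) for t in spec.treatments
    }

    chem = chem.set_index("sample_id") if "sample_id" in chem.columns else chem
    samples = chem.index.tolist()
    treatments = chem["treatment"].tolist()

    # Per-sample latent block factors, iid across all samples so planted
    # correlations survive pooling across treatments.
    n_samples = len(samples)
    block_effects = np.zeros((n_samples, n_pool))
    for pb in planted:
        f = rng.normal(size=n_samples)
        eps = rng.normal(size=(n_samples, len(pb.otu_ids)))
        latent = np.sqrt(pb.rho) * f[:, None] + np.sqrt(1.0 - pb.rho) * eps
        cols = [np.flatnonzero(otu_ids == o)[0] for o in pb.otu_ids]
        block_effects[:, cols] = pb.sigma * latent * np.asarray(pb.signs)[None, :]

    block_members = np.zeros(n_pool, dtype=bool)
    for pb in planted:
        for o in pb.otu_ids:
            block_members[np.flatnonzero(otu_ids == o)[0]] = True

    counts = np.zeros((n_samples, n_pool), dtype=np.int64)
    mean_comp = {}
    for t in spec.treatments:
        active = np.zeros(n_pool, dtype=bool)
        active[order[: active_n[t]]] = True
        m = np.zeros(n_pool)
        for ph in profiles.columns:
            sel = active & (phyla == ph)
            if not sel.any():
                continue
            w = base_w[sel]
            m[sel] = profiles.loc[t, ph] * w / w.sum()
        mean_comp[t] = m / m.sum()

    for s in range(n_samples):
        m = mean_comp[treatments[s]]
        alpha = spec.concentration * m * np.count_nonzero(m)
        active = m > 0
        p = np.zeros(n_pool)
        p[active] = rng.dirichlet(alpha[active])
        # Planted members respond linearly to the latent factor (clipped to
        # stay positive) instead of taking the Dirichlet draw: a linear
        # response preserves the planted Pearson correlation on the
        # abundance scale for negative pairs, which an exponential response
        # cannot (anti-correlated lognormals are bounded far above r = -1).
        p[block_members] = m[block_members] * np.maximum(
            1.0 + block_effects[s, block_members], 0.05
        )
        p /= p.sum()
        counts[s] = rng.multinomial(spec.library_size, p)

    # Guarantee non-empty samples even in pathological tiny configurations.
    for s in range(n_samples):
        if counts[s].sum() == 0:
            counts[s, np.argmax(mean_comp[treatments[s]])] = 1

    taxonomy = pd.DataFrame(
        {
            "domain": domain,
            "phylum": phyla,
            "genus": [f"{ph}_genus{1 + i % 25:02d}" for i, ph in enumerate(phyla)],
        },
        index=pd.Index(otu_ids, name="otu_id"),
    )
    count_df = pd.DataFrame(
        counts, index=pd.Index(samples, name="sample_id"), columns=otu_ids
    )
    return CommunityMatrix(
        counts=count_df, taxonomy=taxonomy, domain=domain, planted_blocks=planted
    )


def generate_communities(
    spec: ScenarioSpec, chem: pd.DataFrame
) -> dict[str, CommunityMatrix]:
    """Simulate one CommunityMatrix per domain for the chemistry samples."""
    if "sample_id" not in chem.columns or "treatment" not in chem.columns:
        raise ValueError("chemistry table must carry sample_id and treatment")
    unknown = set(chem["treatment"]) - set(spec.treatments)
    if unknown:
        raise ValueError(f"chemistry treatments not in scenario: {sorted(unknown)}")
    out = {}
    for domain in spec.domains:
        stream = _COMMUNITY_STREAM.get(domain, _GENERIC_COMMUNITY_STREAM)
        rng = _stage_rng(spec, stream)
        out[domain] = _generate_domain(spec, chem, domain, rng)
    return out


def simulate_scenario(
    spec: ScenarioSpec, outdir: Path | None = None
) -> tuple[pd.DataFrame, dict[str, CommunityMatrix]]:
    """Run both generator stages; optionally write TSV outputs."""
    chem = generate_chemistry(spec)
    communities = generate_communities(spec, chem)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_chemistry(chem, outdir / "chemistry.tsv")
        for domain, cm in communities.items():
            cm.to_tsv(outdir / f"otu_table_{domain}.tsv")
    return chem, communities
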