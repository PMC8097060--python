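"""Synthetic multi-cancer cohort generator.

Produces cohorts with the statistical structure the downstream analysis
assumes, so every stage can be exercised and its parameter recovery tested
without any external download:

* six-way (or fewer) cancer-type strata, each split into a mucinous subgroup
  and non-mucinous controls with matched-style clinical covariates;
* negative-binomial RNA-seq counts with planted log2 fold-changes (MUC2 and
  other gel-forming mucins up-regulated in the mucinous subgroup);
* methylation beta values with the MUC2 promoter probe anti-correlated with
  MUC2 expression at a configurable Spearman rho (Gaussian-copula coupling);
* segmented copy number realising group-specific fraction-of-genome-altered
  targets on a 22-chromosome toy genome;
* mutation tables driving log-normal tumor mutational burden (MSI-H samples
  are hypermutated);
* Bernoulli oncogenic alteration events at configurable per
  (stratum, group, gene, event-type) frequencies;
* pathology-report snippets in which every mucinous sample carries one of
  the keywords "mucin"/"mucous"/"colloid" and a configurable fraction of
  control reports carries a negated decoy phrase.

One master seed drives everything; per-layer child seeds are spawned
deterministically so layers are independently reproducible.  The realized
draws are recorded in a :class:`SimTruth` for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .expression import GEL_MUCIN_GENES, MEMBRANE_MUCIN_GENES, MUCINOUS, CONTROL
from .genomics import DEFAULT_PATHWAYS, SegmentRecord
from .stats import spearman

__all__ = ["SimConfig", "SimTruth", "CohortBundle", "simulate_cohort", "simulate_reports"]


def _default_planted_log2fc() -> dict[str, float]:
    # MUC2 strongly up in the mucinous subgroup; companions more moderate
    return {
        "MUC2": 4.0,
        "MUC5B": 2.0,
        "MUC5AC": 2.0,
        "MUC6": 1.0,
        "SEC16A": 1.5,
        "CRACR2A": 1.5,
    }


def _default_alteration_freqs() -> dict[tuple[str, str, str, str], float]:
    """Per (stratum, group, gene, event type) oncogenic alteration frequency."""
    f = {}

    def add(stratum, gene, event, muc, ctrl):
        f[(stratum, MUCINOUS, gene, event)] = muc
        f[(stratum, CONTROL, gene, event)] = ctrl

    add("CRC", "TP53", "mutation", 0.25, 0.772)
    add("CRC", "SMAD4", "mutation", 0.354, 0.074)
    add("CRC", "SMAD2", "mutation", 0.167, 0.011)
    add("CRC", "KRAS", "mutation", 0.55, 0.40)
    add("CRC", "TCF7", "epigenetic_silencing", 0.10, 0.01)
    add("BRCA", "PIK3CA", "mutation", 0.094, 0.459)
    add("BRCA", "TP53", "mutation", 0.15, 0.30)
    add("BRCA", "TCF7L2", "epigenetic_silencing", 0.12, 0.02)
    add("BRCA", "CDKN1B", "epigenetic_silencing", 0.10, 0.02)
    add("LUAD", "TP53", "mutation", 0.143, 0.485)
    add("LUAD", "KRAS", "mutation", 0.60, 0.35)
    add("STAD", "PIK3CA", "mutation", 0.09, 0.406)
    add("STAD", "TP53", "mutation", 0.30, 0.50)
    return f


def _default_msi_freqs() -> dict[tuple[str, str], float]:
    out = {("CRC", MUCINOUS): 0.356, ("CRC", CONTROL): 0.126}
    for stratum in ("BRCA", "LUAD", "STAD", "CEAD", "PAAD"):
        out[(stratum, MUCINOUS)] = 0.04
        out[(stratum, CONTROL)] = 0.02
    return out


def _default_tmb_params() -> dict[str, tuple[float, float]]:
    # (mu, sigma) of ln(mutations per Mb); lower burden in the mucinous group
    return {MUCINOUS: (0.7, 0.5), CONTROL: (1.3, 0.5)}


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort; defaults define the study conditions."""

    cancer_types: tuple[str, ...] = ("CRC", "BRCA", "LUAD", "STAD")
    n_per_stratum: int = 120
    muc_fraction: float = 0.25
    n_genes: int = 2000
    n_probes: int = 1000
    nb_dispersion: float = 0.15
    planted_log2fc: dict[str, float] = field(default_factory=_default_planted_log2fc)
    gel_mucin_genes: tuple[str, ...] = GEL_MUCIN_GENES
    membrane_mucin_genes: tuple[str, ...] = MEMBRANE_MUCIN_GENES
    meth_expr_rho: float = -0.6
    fga_mean_muc: float = 0.10
    fga_mean_ctrl: float = 0.25
    fga_concentration: float = 30.0
    tmb_lognormal_params: dict[str, tuple[float, float]] = field(default_factory=_default_tmb_params)
    bases_sequenced: int = 30_000_000
    alteration_freqs: dict[tuple[str, str, str, str], float] = field(
        default_factory=_default_alteration_freqs
    )
    background_alteration_freq: float = 0.02
    msi_h_freq: dict[tuple[str, str], float] = field(default_factory=_default_msi_freqs)
    decoy_keyword_rate: float = 0.10
    n_chromosomes: int = 22
    chromosome_size: int = 5_000_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_stratum < 8:
            raise ValueError(f"n_per_stratum must be >= 8, got {self.n_per_stratum}")
        for name in ("muc_fraction", "fga_mean_muc", "fga_mean_ctrl",
                     "background_alteration_freq", "decoy_keyword_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.nb_dispersion <= 0:
            raise ValueError(f"nb_dispersion must be > 0, got {self.nb_dispersion}")
        if not -1 <= self.meth_expr_rho <= 1:
            raise ValueError(f"meth_expr_rho must lie in [-1, 1], got {self.meth_expr_rho}")
        if not self.cancer_types:
            raise ValueError("cancer_types must be non-empty")
        universe = set(self.gene_universe())
        for glist, name in ((self.gel_mucin_genes, "gel_mucin_genes"),
                            (self.membrane_mucin_genes, "membrane_mucin_genes")):
            if not set(glist) <= universe:
                raise ValueError(f"{name} not contained in the gene universe")
        for key, v in self.alteration_freqs.items():
            if not 0 <= v <= 1:
                raise ValueError(f"alteration_freqs[{key}] must lie in [0, 1], got {v}")
        for key, v in self.msi_h_freq.items():
            if not 0 <= v <= 1:
                raise ValueError(f"msi_h_freq[{key}] must lie in [0, 1], got {v}")
        if self.n_genes < len(self._named_genes()):
            raise ValueError(
                f"n_genes={self.n_genes} smaller than the {len(self._named_genes())} named genes"
            )

    def _named_genes(self) -> list[str]:
        named = list(self.gel_mucin_genes) + list(self.membrane_mucin_genes)
        named += [g for g in self.planted_log2fc if g not in named]
        for genes in DEFAULT_PATHWAYS.values():
            named += [g for g in sorted(genes) if g not in named]
        seen, out = set(), []
        for g in named:
            if g not in seen:
                seen.add(g)
                out.append(g)
        return out

    def gene_universe(self) -> list[str]:
        named = self._named_genes()
        fillers = [f"GENE{i:05d}" for i in range(self.n_genes - len(named))]
        return named + fillers

    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i}": self.chromosome_size for i in range(1, self.n_chromosomes + 1)}


@dataclass
class SimTruth:
    """Planted parameters as configured and as realized in the draws."""

    planted_log2fc: dict[str, float]
    realized_log2fc: dict[str, dict[str, float]]  # stratum -> gene -> empirical
    fga_mean_config: dict[str, float]  # group -> configured mean
    fga_mean_realized: dict[str, float]  # group -> mean of drawn altered fractions
    alteration_freqs_config: dict[str, float]  # "stratum|group|gene|event" -> freq
    alteration_freqs_realized: dict[str, float]
    meth_expr_rho_target: float
    meth_expr_rho_realized: dict[str, float]  # stratum -> empirical Spearman rho
    msi_h_freq_config: dict[str, float]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CohortBundle:
    """One simulated (or loaded) cohort: clinical table plus all omics layers."""

    samples: pd.DataFrame  # indexed by sample_id
    counts: pd.DataFrame  # gene x sample, integers
    gene_lengths: pd.Series  # bp per gene
    betas: pd.DataFrame  # probe x sample, in [0, 1]
    probe_map: pd.Series  # probe -> gene
    mutations: pd.DataFrame  # sample_id, gene, class, oncogenic
    bases_sequenced: pd.Series  # bp per sample
    segments: list[SegmentRecord]
    alterations: pd.DataFrame  # sample_id, gene, event_type, oncogenic
    reports: dict[str, str]
    truth: SimTruth

    def validate(self) -> None:
        ids = set(self.samples.index)
        for name, cols in (("counts", self.counts.columns), ("betas", self.betas.columns)):
            if set(cols) != ids:
                raise ValueError(f"{name} columns do not equal the sample id set")
        b = self.betas.to_numpy()
        if ((b < 0) | (b > 1)).any():
            raise ValueError("betas outside [0, 1]")
        c = self.counts.to_numpy()
        if (c < 0).any() or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    def labels(self) -> pd.Series:
        return self.samples["histology_group"]

    def stratum_ids(self, stratum: str) -> list[str]:
        return self.samples.index[self.samples["cancer_type"] == stratum].tolist()


# ---------------------------------------------------------------------------
# generation layers


def _gen_samples(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    n_muc = round(config.n_per_stratum * config.muc_fraction)
    for stratum in config.cancer_types:
        female_only = stratum in ("BRCA", "CEAD")
        for i in range(config.n_per_stratum):
            group = MUCINOUS if i < n_muc else CONTROL
            sid = f"{stratum}-{'M' if group == MUCINOUS else 'C'}{i:04d}"
            age = int(np.clip(round(rng.normal(63, 11)), 25, 90))
            sex = "F" if female_only else ("F" if rng.random() < 0.5 else "M")
            year = int(rng.integers(1998, 2014))
            stage = rng.choice(["I", "II", "III", "IV"], p=[0.2, 0.35, 0.3, 0.15])
            msi_p = config.msi_h_freq.get((stratum, group), 0.0)
            msi = "MSI-H" if rng.random() < msi_p else "MSS"
            extra = {}
            if stratum == "BRCA":
                extra = {
                    "er_status": "pos" if rng.random() < 0.7 else "neg",
                    "pr_status": "pos" if rng.random() < 0.6 else "neg",
                    "her2_status": "pos" if rng.random() < 0.2 else "neg",
                }
            elif stratum == "LUAD":
                extra = {"smoking": "ever" if rng.random() < 0.6 else "never"}
            elif stratum == "CRC":
                extra = {
                    "site": "colon" if rng.random() < 0.7 else "rectum",
                    "laterality": "left" if rng.random() < 0.5 else "right",
                }
            rows.append({
                "sample_id": sid, "cancer_type": stratum, "histology_group": group,
                "age": age, "sex": sex, "year_dx": year, "stage": stage,
                "msi_status": msi, **extra,
            })
    df = pd.DataFrame(rows).set_index("sample_id")
    if df.index.duplicated().any():
        raise AssertionError("sample ids must be unique")
    return df


def _gen_counts(config: SimConfig, samples: pd.DataFrame, rng: np.random.Generator):
    genes = config.gene_universe()
    base = rng.lognormal(mean=4.0, sigma=1.2, size=len(genes))  # per-gene baseline mean
    # planted genes get a solidly expressed baseline so the fold change acts
    # on a detectable signal rather than on near-zero counts
    planted_ix = [i for i, g in enumerate(genes) if g in config.planted_log2fc]
    base[planted_ix] = rng.uniform(30.0, 100.0, size=len(planted_ix))
    lib = rng.lognormal(mean=0.0, sigma=0.15, size=len(samples))  # per-sample depth factor
    lfc = np.array([config.planted_log2fc.get(g, 0.0) for g in genes])
    is_muc = (samples["histology_group"] == MUCINOUS).to_numpy()
    mu = base[:, None] * lib[None, :]
    mu = mu * np.where(is_muc[None, :], 2.0 ** lfc[:, None], 1.0)
    r = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    lengths = rng.integers(500, 5001, size=len(genes))
    counts_df = pd.DataFrame(counts, index=genes, columns=samples.index)
    return counts_df, pd.Series(lengths, index=genes, name="length_bp")


def _gen_betas(config: SimConfig, samples: pd.DataFrame, counts: pd.DataFrame,
               rng: np.random.Generator):
    genes = config.gene_universe()
    probes = [f"cg{i:07d}" for i in range(config.n_probes)]
    probe_map = pd.Series([genes[i % len(genes)] for i in range(config.n_probes)],
                          index=probes, name="gene")
    base_means = rng.uniform(0.1, 0.9, size=config.n_probes)
    betas = np.clip(
        rng.normal(base_means[:, None], 0.05, size=(config.n_probes, len(samples))), 0.0, 1.0
    )
    is_muc = (samples["histology_group"] == MUCINOUS).to_numpy()

    # secondary planted DMPs: first probe of each planted non-MUC2 gene is
    # hypomethylated in the mucinous subgroup
    for gene in config.planted_log2fc:
        if gene == "MUC2":
            continue
        hits = probe_map.index[probe_map == gene]
        if len(hits):
            i = probes.index(hits[0])
            betas[i, is_muc] = np.clip(betas[i, is_muc] - 0.25, 0.0, 1.0)

    # MUC2 promoter probe: Gaussian-copula coupling to MUC2 expression so the
    # Spearman correlation lands near meth_expr_rho (within each stratum)
    muc2_probe = probe_map.index[probe_map == "MUC2"][0]
    pi = probes.index(muc2_probe)
    rho_s = config.meth_expr_rho
    rho_p = 2.0 * np.sin(np.pi * rho_s / 6.0)  # Spearman -> Pearson on the copula
    expr = counts.loc["MUC2"].to_numpy(dtype=float)
    realized = {}
    for stratum in config.cancer_types:
        cols = (samples["cancer_type"] == stratum).to_numpy()
        e = expr[cols]
        ranks = pd.Series(e).rank(method="average").to_numpy()
        z = (ranks - ranks.mean()) / max(ranks.std(ddof=0), 1e-12)
        eps = rng.normal(size=cols.sum())
        latent = rho_p * z + np.sqrt(max(0.0, 1.0 - rho_p**2)) * eps
        betas[pi, cols] = np.clip(0.5 + 0.18 * latent, 0.0, 1.0)
        realized[stratum] = spearman(betas[pi, cols], e)[0]

    betas_df = pd.DataFrame(betas, index=probes, columns=samples.index)
    return betas_df, probe_map, muc2_probe, realized


def _gen_mutations(config: SimConfig, samples: pd.DataFrame, rng: np.random.Generator):
    genes = config.gene_universe()
    rows = []
    for sid, row in samples.iterrows():
        mu, sigma = config.tmb_lognormal_params[row["histology_group"]]
        tmb_per_mb = rng.lognormal(mu, sigma)
        if row["msi_status"] == "MSI-H":
            tmb_per_mb *= 10.0  # hypermutated
        mb = config.bases_sequenced / 1e6
        n_nonsyn = int(rng.poisson(tmb_per_mb * mb))
        n_syn = int(rng.poisson(0.4 * tmb_per_mb * mb))
        for cls, n in (("nonsynonymous", n_nonsyn), ("synonymous", n_syn)):
            if n == 0:
                continue
            for g in rng.choice(len(genes), size=n):
                rows.append((sid, genes[g], cls, bool(rng.random() < 0.05)))
    mut = pd.DataFrame(rows, columns=["sample_id", "gene", "class", "oncogenic"])
    bases = pd.Series(config.bases_sequenced, index=samples.index, name="bases_sequenced")
    return mut, bases


def _gen_segments(config: SimConfig, samples: pd.DataFrame, rng: np.random.Generator):
    sizes = config.chrom_sizes()
    chroms = list(sizes)
    total = sum(sizes.values())
    conc = config.fga_concentration
    segments: list[SegmentRecord] = []
    drawn_fracs: dict[str, list[float]] = {MUCINOUS: [], CONTROL: []}
    for sid, row in samples.iterrows():
        mean = config.fga_mean_muc if row["histology_group"] == MUCINOUS else config.fga_mean_ctrl
        f = float(rng.beta(mean * conc, (1 - mean) * conc)) if 0 < mean < 1 else mean
        drawn_fracs[row["histology_group"]].append(f)
        budget = int(round(f * total))
        order = rng.permutation(len(chroms))
        for ci in order:
            chrom, size = chroms[ci], sizes[chroms[ci]]
            alt_len = min(budget, size)
            budget -= alt_len
            neutral_log2 = float(np.clip(rng.normal(0, 0.05), -0.15, 0.15))
            if alt_len == 0:
                segments.append(SegmentRecord(sid, chrom, 1, size, neutral_log2, size // 1000))
                continue
            sign = 1.0 if rng.random() < 0.5 else -1.0
            alt_log2 = float(sign * rng.uniform(0.3, 1.2))
            off = int(rng.integers(1, size - alt_len + 2))
            if off > 1:
                segments.append(SegmentRecord(sid, chrom, 1, off - 1, neutral_log2, off // 1000))
            segments.append(
                SegmentRecord(sid, chrom, off, off + alt_len - 1, alt_log2, alt_len // 1000)
            )
            if off + alt_len <= size:
                segments.append(
                    SegmentRecord(sid, chrom, off + alt_len, size, neutral_log2,
                                  (size - off - alt_len + 1) // 1000)
                )
    fga_real = {g: float(np.mean(v)) if v else float("nan") for g, v in drawn_fracs.items()}
    return segments, fga_real


def _gen_alterations(config: SimConfig, samples: pd.DataFrame, rng: np.random.Generator):
    rows = []
    realized: dict[str, float] = {}
    configured = set()
    for (stratum, group, gene, event), freq in sorted(config.alteration_freqs.items()):
        configured.add((stratum, group, gene))
        ids = samples.index[
            (samples["cancer_type"] == stratum) & (samples["histology_group"] == group)
        ]
        if len(ids) == 0:
            continue
        hit = rng.random(len(ids)) < freq
        for sid in ids[hit]:
            rows.append((sid, gene, event, True))
        realized[f"{stratum}|{group}|{gene}|{event}"] = float(hit.mean())
    # background oncogenic mutations across pathway genes keep the landscape dense
    bg_genes = sorted(set().union(*DEFAULT_PATHWAYS.values()))
    p_bg = config.background_alteration_freq
    if p_bg > 0:
        for gene in bg_genes:
            for stratum in config.cancer_types:
                for group in (MUCINOUS, CONTROL):
                    if (stratum, group, gene) in configured:
                        continue
                    ids = samples.index[
                        (samples["cancer_type"] == stratum)
                        & (samples["histology_group"] == group)
                    ]
                    hit = rng.random(len(ids)) < p_bg
                    for sid in ids[hit]:
                        rows.append((sid, gene, "mutation", True))
    alt = pd.DataFrame(rows, columns=["sample_id", "gene", "event_type", "oncogenic"])
    alt = alt.sort_values(["sample_id", "gene", "event_type"]).reset_index(drop=True)
    return alt, realized


_MUC_TEMPLATES = (
    "Invasive mucinous adenocarcinoma, moderately differentiated, with abundant "
    "extracellular mucin pools comprising over 50% of tumor volume.",
    "Colloid carcinoma. Tumor cells floating in lakes of extracellular mucin.",
    "Adenocarcinoma with mucous differentiation; signet ring cells not identified.",
    "Mucin-producing adenocarcinoma involving the resection margin.",
)

_CTRL_TEMPLATES = (
    "Infiltrating ductal carcinoma, not otherwise specified, grade 2.",
    "Adenocarcinoma, intestinal type, moderately differentiated.",
    "Invasive adenocarcinoma with focal necrosis; margins negative.",
    "Poorly differentiated carcinoma with solid growth pattern.",
)

_DECOY_SENTENCE = " No mucinous features identified."


def simulate_reports(samples: pd.DataFrame, decoy_keyword_rate: float, seed: int) -> dict[str, str]:
    """Pathology-report snippets for each sample.

    Every mucinous sample's report contains at least one of the keywords
    "mucin"/"mucous"/"colloid"; a ``decoy_keyword_rate`` fraction of control
    reports (Bernoulli per report) carries a negated keyword phrase.
    """
    rng = np.random.default_rng(seed)
    reports = {}
    for sid, row in samples.iterrows():
        header = f"Pathology report, accession {sid}. Site: {row['cancer_type']}. "
        if row["histology_group"] == MUCINOUS:
            body = _MUC_TEMPLATES[int(rng.integers(len(_MUC_TEMPLATES)))]
        else:
            body = _CTRL_TEMPLATES[int(rng.integers(len(_CTRL_TEMPLATES)))]
            if rng.random() < decoy_keyword_rate:
                body += _DECOY_SENTENCE
        reports[str(sid)] = header + body
    return reports


def simulate_cohort(config: SimConfig, seed: int | None = None) -> CohortBundle:
    """Generate one full synthetic cohort; deterministic given (config, seed).

    ``seed`` defaults to ``config.seed``.  Layer-specific child generators
    are spawned from one master SeedSequence, so e.g. the methylation layer
    is reproducible independently of how many mutations were drawn.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    master = np.random.SeedSequence(seed)
    kids = master.spawn(7)
    rngs = [np.random.default_rng(k) for k in kids[:6]]
    report_seed = int(kids[6].generate_state(1)[0] % (2**31))

    samples = _gen_samples(config, rngs[0])
    counts, gene_lengths = _gen_counts(config, samples, rngs[1])
    betas, probe_map, _, rho_real = _gen_betas(config, samples, counts, rngs[2])
    mutations, bases = _gen_mutations(config, samples, rngs[3])
    segments, fga_real = _gen_segments(config, samples, rngs[4])
    alterations, alt_real = _gen_alterations(config, samples, rngs[5])
    reports = simulate_reports(samples, config.decoy_keyword_rate, report_seed)

    # realized expression effects: per-stratum mean log2 ratio of depth-scaled counts
    realized_lfc: dict[str, dict[str, float]] = {}
    depth = counts.sum(axis=0) / counts.sum(axis=0).mean()
    norm = counts.div(depth, axis=1)
    for stratum in config.cancer_types:
        ids = samples.index[samples["cancer_type"] == stratum]
        g = samples.loc[ids, "histology_group"]
        muc_ids, ctl_ids = ids[g == MUCINOUS], ids[g == CONTROL]
        d = {}
        for gene in config.planted_log2fc:
            m = np.log2(norm.loc[gene, muc_ids] + 1).mean()
            c = np.log2(norm.loc[gene, ctl_ids] + 1).mean()
            d[gene] = float(m - c)
        realized_lfc[stratum] = d

    truth = SimTruth(
        planted_log2fc=dict(config.planted_log2fc),
        realized_log2fc=realized_lfc,
        fga_mean_config={MUCINOUS: config.fga_mean_muc, CONTROL: config.fga_mean_ctrl},
        fga_mean_realized=fga_real,
        alteration_freqs_config={
            f"{s}|{g}|{gn}|{e}": v for (s, g, gn, e), v in sorted(config.alteration_freqs.items())
        },
        alteration_freqs_realized=alt_real,
        meth_expr_rho_target=config.meth_expr_rho,
        meth_expr_rho_realized=rho_real,
        msi_h_freq_config={f"{s}|{g}": v for (s, g), v in sorted(config.msi_h_freq.items())},
    )

    bundle = CohortBundle(
        samples=samples, counts=counts, gene_lengths=gene_lengths, betas=betas,
        probe_map=probe_map, mutations=mutations, bases_sequenced=bases,
        segments=segments, alterations=alterations, reports=reports, truth=truth,
    )
    bundle.validate()
    return bundle
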