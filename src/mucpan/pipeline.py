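"""End-to-end orchestration: simulate -> mine -> match -> expression ->
intersection -> methylation -> genomics, with a reproducibility manifest.

Stages communicate through files only; each stage's outputs are written
before dependents run, and the manifest (config hash, master seed, per-file
SHA-256 digests) is written last.  Re-running with the same config and seed
reproduces identical digests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .expression import (
    GEL_MUC, MEMBRANE_MUC, differential_expression, mucin_signature, rpkm,
    MUCINOUS,
)
from .genomics import (
    call_cna, cna_frequency, compare_binary_freq, compute_tmb, driver_counts,
    fga_by_sample, gene_event_matrix, make_bins, msi_step, pathway_matrix,
    recurrent_oncogenic, DEFAULT_PATHWAYS,
)
from .intersection import intersect_de, mc_intersection_test
from .io import write_cohort, write_gmt
from .matching import MatchSpec, balance_table, match_controls
from .methylation import dmp_finder, meth_expr_association
from .mining import flag_reports
from .simulate import SimConfig, simulate_cohort
from .stats import mann_whitney

__all__ = ["RunManifest", "load_config", "run_pipeline", "DEFAULT_LAYERS"]

DEFAULT_LAYERS = ("reports", "matching", "expression", "intersection", "methylation", "genomics")

#: stratum-specific exact-matching covariates (sex is skipped where the
#: stratum is single-sex by design)
STRATUM_EXACT_VARS = {
    "CRC": ("sex", "stage", "site", "laterality"),
    "BRCA": ("stage", "er_status", "pr_status", "her2_status"),
    "LUAD": ("sex", "stage", "smoking"),
    "STAD": ("sex", "stage"),
    "CEAD": ("stage",),
    "PAAD": ("sex", "stage"),
}


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: list[dict] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)

    def add_stage(self, name: str, outputs: dict[str, Path]) -> None:
        digests = {
            str(Path(p).name): _digest(p) for p in outputs.values() if Path(p).is_file()
        }
        self.stages.append({"stage": name, "outputs": digests})

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        cfg = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh) or {}
    cfg.setdefault("sim", {})
    cfg.setdefault("layers", list(DEFAULT_LAYERS))
    cfg.setdefault("matching", {"ratio": 3, "continuous": ["age", "year_dx"]})
    cfg.setdefault("de", {"q_threshold": 0.05, "require_direction": False})
    cfg.setdefault("mc", {"n_sims": 10_000})
    cfg.setdefault("genomics", {"method": "auto", "bin_width": 500_000})
    return cfg


def _sim_config(cfg: dict) -> SimConfig:
    kw = dict(cfg.get("sim") or {})
    if "cancer_types" in kw:
        kw["cancer_types"] = tuple(kw["cancer_types"])
    return SimConfig(**kw)


def run_pipeline(config, seed: int, outdir) -> RunManifest:
    """Run every configured stage; returns (and writes) the manifest."""
    cfg = load_config(config)
    sim_cfg = _sim_config(cfg)
    sim_cfg.validate()
    layers = list(cfg["layers"])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cfg_for_hash = json.dumps(cfg, sort_keys=True, default=str)
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_for_hash.encode()).hexdigest(),
        seed=int(seed),
        version=__version__,
    )

    # -- simulate ------------------------------------------------------------
    bundle = simulate_cohort(sim_cfg, seed=seed)
    cohort_dir = outdir / "cohort"
    paths = write_cohort(bundle, cohort_dir)
    write_gmt(DEFAULT_PATHWAYS, cohort_dir / "pathways.gmt")
    paths["pathways.gmt"] = cohort_dir / "pathways.gmt"
    manifest.add_stage("simulate", paths)

    samples = bundle.samples
    labels = bundle.labels()
    strata = list(sim_cfg.cancer_types)
    de_by_stratum: dict[str, pd.DataFrame] = {}

    # -- report mining -------------------------------------------------------
    if "reports" in layers:
        flags = flag_reports(bundle.reports)
        fp = outdir / "flags.tsv"
        flags.to_csv(fp, sep="\t", index=False)
        manifest.add_stage("reports", {"flags.tsv": fp})
    else:
        manifest.skipped.append("reports")

    # -- matched-control selection -------------------------------------------
    if "matching" in layers:
        mcfg = cfg["matching"]
        outs = {}
        for stratum in strata:
            sub = samples[samples["cancer_type"] == stratum]
            exact = tuple(
                v for v in mcfg.get("exact", STRATUM_EXACT_VARS.get(stratum, ("stage",)))
                if v in sub.columns
            )
            spec = MatchSpec(
                exact_vars=exact,
                continuous_vars=tuple(mcfg.get("continuous", ("age", "year_dx"))),
                ratio=int(mcfg.get("ratio", 3)),
                strict=bool(mcfg.get("strict", False)),
            )
            cases = sub[sub["histology_group"] == MUCINOUS]
            pool = sub[sub["histology_group"] != MUCINOUS]
            design = match_controls(cases, pool, spec)
            dp = outdir / f"design_{stratum}.tsv"
            design.to_frame().to_csv(dp, sep="\t", index=False)
            bp = outdir / f"balance_{stratum}.tsv"
            balance_table(design, sub, spec).to_csv(bp, sep="\t", index=False)
            outs[dp.name], outs[bp.name] = dp, bp
        manifest.add_stage("matching", outs)
    else:
        manifest.skipped.append("matching")

    # -- differential expression and mucin signatures ------------------------
    if "expression" in layers:
        outs = {}
        sig_frames = []
        rpkm_all = rpkm(bundle.counts, bundle.gene_lengths)
        for stratum in strata:
            ids = bundle.stratum_ids(stratum)
            de = differential_expression(bundle.counts[ids], labels[ids])
            de_by_stratum[stratum] = de
            dp = outdir / f"de_{stratum}.tsv"
            de.to_csv(dp, sep="\t")
            outs[dp.name] = dp
            scores = pd.DataFrame({
                "sample_id": ids,
                "cancer_type": stratum,
                "histology_group": labels[ids].to_numpy(),
                "gel_muc": mucin_signature(rpkm_all[ids], GEL_MUC).to_numpy(),
                "membrane_muc": mucin_signature(rpkm_all[ids], MEMBRANE_MUC).to_numpy(),
            })
            sig_frames.append(scores)
        sp = outdir / "signatures.tsv"
        pd.concat(sig_frames).to_csv(sp, sep="\t", index=False)
        outs[sp.name] = sp
        manifest.add_stage("expression", outs)
    else:
        manifest.skipped.append("expression")

    # -- cross-cancer intersection -------------------------------------------
    if "intersection" in layers and len(de_by_stratum) >= 2:
        q_thr = float(cfg["de"]["q_threshold"])
        shared = intersect_de(de_by_stratum, q_thr, bool(cfg["de"]["require_direction"]))
        universe = set.intersection(
            *(set(de.index[~de["excluded"]]) for de in de_by_stratum.values())
        )
        sizes = [int((de["q"] < q_thr).sum()) for de in de_by_stratum.values()]
        mc = mc_intersection_test(
            sizes, len(universe), len(shared),
            n_sims=int(cfg["mc"]["n_sims"]), seed=seed,
        )
        mp = outdir / "mc.json"
        mc.to_json(mp)
        gp = outdir / "shared_genes.txt"
        gp.write_text("\n".join(sorted(shared)) + "\n")
        manifest.add_stage("intersection", {"mc.json": mp, "shared_genes.txt": gp})
    elif "intersection" in layers:
        manifest.skipped.append("intersection")
    else:
        manifest.skipped.append("intersection")

    # -- methylation ----------------------------------------------------------
    if "methylation" in layers:
        outs = {}
        rho_rows = []
        for stratum in strata:
            ids = bundle.stratum_ids(stratum)
            dmp = dmp_finder(bundle.betas[ids], labels[ids], shrink=True)
            dp = outdir / f"dmp_{stratum}.tsv"
            dmp.to_csv(dp, sep="\t")
            outs[dp.name] = dp
            muc2_probes = bundle.probe_map.index[bundle.probe_map == "MUC2"]
            if len(muc2_probes) and "MUC2" in bundle.counts.index:
                rho, p = meth_expr_association(
                    bundle.betas.loc[muc2_probes[0], ids],
                    bundle.counts.loc["MUC2", ids],
                )
                rho_rows.append((stratum, muc2_probes[0], "MUC2", rho, p))
        rp = outdir / "meth_expr.tsv"
        pd.DataFrame(
            rho_rows, columns=["cancer_type", "probe", "gene", "rho", "p"]
        ).to_csv(rp, sep="\t", index=False)
        outs[rp.name] = rp
        manifest.add_stage("methylation", outs)
    else:
        manifest.skipped.append("methylation")

    # -- genomic landscape -----------------------------------------------------
    if "genomics" in layers:
        gcfg = cfg["genomics"]
        method = gcfg.get("method", "auto")
        outs = {}

        # MSI enrichment per stratum, then exclusion
        msi_rows, kept_ids = [], []
        for stratum in strata:
            sub = samples.loc[bundle.stratum_ids(stratum)]
            tab, res, kept = msi_step(sub)
            msi_rows.append((stratum, tab.a, tab.a + tab.b, tab.c, tab.c + tab.d,
                             res.odds_ratio, res.p_value, res.method))
            kept_ids.extend(kept)
        mp = outdir / "msi.tsv"
        pd.DataFrame(
            msi_rows,
            columns=["cancer_type", "msih_muc", "n_muc", "msih_ctrl", "n_ctrl",
                     "odds_ratio", "p", "method"],
        ).to_csv(mp, sep="\t", index=False)
        outs[mp.name] = mp
        kept = samples.loc[kept_ids]

        # per-sample burden metrics (MSI-H excluded)
        nonsyn = (
            bundle.mutations[bundle.mutations["class"] == "nonsynonymous"]
            .groupby("sample_id").size().reindex(kept.index, fill_value=0)
        )
        tmb_mb = pd.Series(
            {sid: compute_tmb(int(nonsyn[sid]), int(bundle.bases_sequenced[sid]))[1]
             for sid in kept.index},
            name="tmb_per_mb",
        )
        kept_segments = [s for s in bundle.segments if s.sample_id in set(kept.index)]
        fga = fga_by_sample(kept_segments).reindex(kept.index)
        drv = driver_counts(bundle.alterations, list(kept.index))
        metrics = pd.DataFrame({
            "cancer_type": kept["cancer_type"], "histology_group": kept["histology_group"],
            "tmb_per_mb": tmb_mb, "fga": fga, "n_driver": drv,
        })
        metp = outdir / "genomic_metrics.tsv"
        metrics.to_csv(metp, sep="\t")
        outs[metp.name] = metp

        # group comparisons of the burden metrics per stratum
        test_rows = []
        for stratum in strata:
            sub = metrics[metrics["cancer_type"] == stratum]
            muc = sub[sub["histology_group"] == MUCINOUS]
            ctl = sub[sub["histology_group"] != MUCINOUS]
            for metric in ("tmb_per_mb", "fga", "n_driver"):
                u, p = mann_whitney(muc[metric], ctl[metric])
                test_rows.append((stratum, metric, float(muc[metric].median()),
                                  float(ctl[metric].median()), u, p))
        gtp = outdir / "group_tests.tsv"
        pd.DataFrame(
            test_rows,
            columns=["cancer_type", "metric", "median_muc", "median_ctrl", "U", "p"],
        ).to_csv(gtp, sep="\t", index=False)
        outs[gtp.name] = gtp

        bins = make_bins(sim_cfg.chrom_sizes(), int(gcfg.get("bin_width", 500_000)))
        for stratum in strata:
            ids = [s for s in bundle.stratum_ids(stratum) if s in set(kept.index)]
            sub = kept.loc[ids]
            seglist = [s for s in kept_segments if s.sample_id in set(ids)]

            calls = call_cna(seglist, bins)
            freq = cna_frequency(calls, sub["histology_group"])
            fp = outdir / f"cna_freq_{stratum}.tsv"
            freq.to_csv(fp, sep="\t")
            outs[fp.name] = fp

            alt = bundle.alterations[bundle.alterations["sample_id"].isin(ids)]
            rec = recurrent_oncogenic(alt, ids, min_freq=0.01)
            gm = gene_event_matrix(alt, ids, rec)
            if gm.shape[1]:
                cmp_genes = compare_binary_freq(gm, sub["histology_group"], method=method)
                gp2 = outdir / f"compare_genes_{stratum}.tsv"
                cmp_genes.to_csv(gp2, sep="\t")
                outs[gp2.name] = gp2

            pm = pathway_matrix(alt, ids)
            cmp_pw = compare_binary_freq(pm, sub["histology_group"], method=method)
            pp = outdir / f"compare_pathways_{stratum}.tsv"
            cmp_pw.to_csv(pp, sep="\t")
            outs[pp.name] = pp
        manifest.add_stage("genomics", outs)
    else:
        manifest.skipped.append("genomics")

    manifest.write(outdir / "manifest.json")
    return manifest
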