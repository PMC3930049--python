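"""End-to-end orchestration: simulate -> filter -> selstats -> ibd ->
community -> assoc as one configured, logged, seeded run.

A single global seed is propagated to every stochastic stage (each stage
derives its own sub-seed), every output file is checksummed into the run
manifest, and a failed stage halts its dependents with a recorded reason.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import amplicon, association, community, differentiation, selection, simulate

__all__ = ["RunConfig", "run_pipeline", "load_config"]

STAGES = ("simulate", "filter", "selstats", "ibd", "community", "assoc")


class DependencyError(RuntimeError):
    pass


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    sim: dict = field(default_factory=dict)
    filter: dict = field(default_factory=dict)
    selstats: dict = field(default_factory=dict)
    ibd: dict = field(default_factory=dict)
    community: dict = field(default_factory=dict)
    assoc: dict = field(default_factory=dict)

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {"outdir", "seed", "stages", "sim", "filter", "selstats", "ibd",
             "community", "assoc"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the run manifest: per-stage status, counters, output paths and
    sha256 checksums.  Re-running with an identical config reproduces
    identical checksums.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}
    ctx: dict = {}

    def record(stage: str, status: str, counters=None, reason=None):
        manifest["stages"][stage] = {
            "status": status,
            "counters": counters or {},
            **({"reason": reason} if reason else {}),
        }

    def save(stage: str, name: str, writer) -> Path:
        path = out / name
        writer(path)
        manifest["files"][name] = {"stage": stage, "sha256": _sha256(path)}
        return path

    enabled = set(config.stages)

    # --- simulate -----------------------------------------------------------
    if "simulate" in enabled:
        cfg = simulate.SimConfig(seed=config.seed, **config.sim)
        alleles = simulate.simulate_allele_pool(cfg)
        pools = simulate.assign_pool_alleles(cfg, alleles)
        tags = simulate.default_tag_map(cfg)
        reads, truth = simulate.simulate_pool_reads(cfg, pools, alleles, tags)
        genotypes, pop_assign, _, realized_slope = simulate.simulate_aflp(cfg)
        truth.realized_ibd_slope = realized_slope
        truth.programmed_assoc_beta = cfg.assoc_effect

        save("simulate", "reads.fasta", lambda p: simulate.write_fasta(reads, p))
        save("simulate", "truth.json", truth.to_json)
        save("simulate", "aflp.tsv", lambda p: genotypes.assign(
            population=pop_assign).to_csv(p, sep="\t"))
        coords = cfg.coords()
        save("simulate", "coords.tsv", lambda p: pd.DataFrame(
            coords, index=list(cfg.pop_labels), columns=["x_km", "y_km"]
        ).to_csv(p, sep="\t"))
        pool_rows = pd.DataFrame(
            [
                {"pop_id": pop, "tag": tags[pop],
                 "fwd_primer": simulate._FWD_PRIMER,
                 "rev_primer": simulate._REV_PRIMER}
                for pop in cfg.pop_labels
            ]
        )
        save("simulate", "pools.tsv", lambda p: pool_rows.to_csv(p, sep="\t", index=False))
        ref_seq = alleles["A001"]
        save("simulate", "reference.fasta",
             lambda p: Path(p).write_text(f">reference\n{ref_seq}\n"))
        mask_rows = pd.DataFrame(
            {"locus": "locus", "codon": list(cfg.pbr_mask)}
        )
        save("simulate", "pbr_mask.tsv",
             lambda p: mask_rows.to_csv(p, sep="\t", index=False))
        geo_df = pd.DataFrame(
            np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1),
            index=list(cfg.pop_labels), columns=list(cfg.pop_labels),
        )
        save("simulate", "geo.tsv", lambda p: geo_df.to_csv(p, sep="\t"))
        ctx.update(
            cfg=cfg, alleles=alleles, reads=reads, truth=truth,
            genotypes=genotypes, pop_assign=pop_assign,
            geo=differentiation.LabeledDistanceMatrix.from_coords(
                list(cfg.pop_labels), coords),
            pool_specs=[
                amplicon.PoolSpec(pop, tags[pop], simulate._FWD_PRIMER,
                                  simulate._REV_PRIMER)
                for pop in cfg.pop_labels
            ],
            reference=truth.allele_seqs[next(iter(truth.allele_seqs))],
        )
        record("simulate", "completed", {"n_reads": len(reads),
                                         "n_alleles": len(alleles)})

    # --- filter -------------------------------------------------------------
    if "filter" in enabled:
        for need in ("reads", "pool_specs", "reference"):
            if need not in ctx:
                raise DependencyError("filter requires the simulate stage outputs")
        fr = amplicon.run_filter(
            ctx["reads"], ctx["pool_specs"], ctx["reference"], **config.filter
        )
        ctx["filter_result"] = fr
        save("filter", "variants.tsv",
             lambda p: fr.variant_table().to_csv(p, sep="\t", index=False))
        save("filter", "presence.tsv", lambda p: fr.presence.to_csv(p, sep="\t"))
        record("filter", "completed", fr.stats)

    # --- selstats -----------------------------------------------------------
    if "selstats" in enabled:
        if "filter_result" not in ctx:
            raise DependencyError("selstats requires the filter stage outputs")
        fr = ctx["filter_result"]
        cfg = ctx["cfg"]
        mask = selection.PbrMask("locus", cfg.pbr_mask, cfg.n_codons)
        params = dict(config.selstats)
        n_boot = params.pop("n_boot", 1000)
        div = selection.site_diversity(fr.alignment, mask)
        table1 = selection.locus_summary(
            fr.alignment, mask, n_boot=n_boot, seed=config.seed)
        # per-population percent polymorphism on population-restricted subsets
        per_pop = {}
        for pop in fr.presence.index:
            ids = list(fr.presence.columns[fr.presence.loc[pop] > 0])
            s = selection.percent_polymorphic(fr.alignment, mask, ids, locus=pop)
            per_pop[pop] = {
                "locus_PBR": s.pct_polymorphic_pbr,
                "locus_non-PBR": s.pct_polymorphic_nonpbr,
                "locus_all": s.pct_polymorphic_all,
            }
        poly = pd.DataFrame(per_pop).T.rename_axis("population")
        ctx["site_diversity"] = div
        ctx["table1"] = table1
        ctx["polymorphism"] = poly
        save("selstats", "site_diversity.tsv",
             lambda p: div.to_csv(p, sep="\t", index=False))
        save("selstats", "dnds.tsv", lambda p: table1.to_csv(p, sep="\t", index=False))
        save("selstats", "polymorphism.tsv", lambda p: poly.to_csv(p, sep="\t"))
        record("selstats", "completed",
               {"n_variants": len(fr.alignment), "n_codons": mask.n_codons})

    # --- ibd ----------------------------------------------------------------
    if "ibd" in enabled:
        if "filter_result" not in ctx or "genotypes" not in ctx:
            raise DependencyError("ibd requires filter and simulate outputs")
        params = dict(config.ibd)
        n_perm = params.pop("n_perm", 999)
        subset_size = params.pop("subset_size", 200)
        n_subsets = params.pop("n_subsets", 100)
        geo = ctx["geo"]
        mhc = differentiation.standardize01(
            differentiation.euclidean_presence(ctx["filter_result"].presence))
        band = ctx["genotypes"].groupby(ctx["pop_assign"]).mean()
        band = band.loc[list(geo.labels)]
        aflp = differentiation.standardize01(
            differentiation.euclidean_presence((band > 0).astype(int)))
        rows = []
        m_aflp = differentiation.mantel(geo, aflp, n_perm, seed=config.seed)
        m_mhc = differentiation.mantel(geo, mhc, n_perm, seed=config.seed)
        pm = differentiation.partial_mantel(mhc, geo, aflp, n_perm, seed=config.seed)
        for name, r in (("aflp_vs_geo", m_aflp), ("mhc_vs_geo", m_mhc),
                        ("mhc_vs_geo_given_aflp", pm)):
            rows.append({"test": name, "R": r.R, "P": r.P, "n_perm": r.n_perm,
                         "slope": r.slope, "r2": r.r2, "n_pairs": r.n_pairs})
        env = differentiation.neutral_slope_envelope(
            ctx["genotypes"], ctx["pop_assign"], geo, subset_size,
            n_subsets, seed=config.seed)
        ibd_df = pd.DataFrame(rows)
        ctx["ibd"] = ibd_df
        ctx["envelope"] = env
        save("ibd", "mantel.tsv", lambda p: ibd_df.to_csv(p, sep="\t", index=False))
        save("ibd", "envelope.json", lambda p: Path(p).write_text(json.dumps(
            {"subset_size": env.subset_size, "n_subsets": env.n_subsets,
             "slopes": env.slopes, "r2s": env.r2s,
             "min_r2": env.min_r2, "max_r2": env.max_r2,
             "mhc_slope": m_mhc.slope,
             "mhc_slope_within_envelope": env.contains_slope(m_mhc.slope)})))
        record("ibd", "completed", {"n_perm": n_perm, "n_subsets": env.n_subsets})

    # --- community ----------------------------------------------------------
    if "community" in enabled:
        if "cfg" not in ctx:
            raise DependencyError("community requires the simulate stage")
        cfg = ctx["cfg"]
        params = dict(config.community)
        min_len = params.pop("min_len", 200)
        min_boot = params.pop("min_bootstrap", 0.5)
        n_perm = params.pop("n_perm", 999)
        covariate = (
            ctx["polymorphism"]["locus_PBR"]
            .reindex(list(cfg.pop_labels)).fillna(0.0).to_numpy()
            if "polymorphism" in ctx
            else np.zeros(cfg.n_pops)
        )
        records_df = simulate.simulate_communities(cfg, covariate)
        table = community.flag_pathogens(
            community.filter_records(records_df, min_len, min_boot))
        rich = pd.DataFrame(
            {
                "all": community.richness(table, "all"),
                "nonpathogen": community.richness(table, "nonpathogen"),
                "pathogen": community.richness(table, "pathogen"),
            }
        ).fillna(0).astype(int)
        counters = dict(table.qc)
        perm_stats = {}
        groups = params.pop("groups", None)
        if groups is not None:
            dis = community.community_dissimilarity(table, "all")
            res = community.permanova(dis, groups, n_perm=n_perm, seed=config.seed)
            perm_stats = {"permanova_F": res.pseudo_F, "permanova_P": res.P}
        else:
            # with one water sample per population a population factor is
            # saturated; PERMANOVA needs a user-supplied grouping
            perm_stats["permanova"] = "skipped: no grouping configured"
        ctx["community_table"] = table
        ctx["richness"] = rich
        save("community", "records.tsv",
             lambda p: records_df.to_csv(p, sep="\t", index=False))
        save("community", "community_counts.tsv",
             lambda p: table.counts.to_csv(p, sep="\t"))
        save("community", "richness.tsv", lambda p: rich.to_csv(p, sep="\t"))
        record("community", "completed", {**counters, **perm_stats})

    # --- assoc --------------------------------------------------------------
    if "assoc" in enabled:
        if "polymorphism" not in ctx or "richness" not in ctx:
            raise DependencyError("assoc requires selstats and community outputs")
        grid = association.association_grid(ctx["polymorphism"], ctx["richness"])
        ctx["assoc"] = grid
        save("assoc", "association.tsv",
             lambda p: grid.to_csv(p, sep="\t", index=False))
        record("assoc", "completed", {"n_cells": len(grid)})

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
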