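"""Config-driven orchestration of the full analysis.

``run_pipeline`` executes the stages of the study design in order --
filtering, tag grouping, species clustering, per-population diversity,
pairwise divergence and polymorphism sharing, inversion scan with
karyotype-stratified statistics, population differentiation, and folded-SFS
demographic fits -- writing tidy TSV/JSON artifacts stamped with the config
hash and seeds.  Input is either a VCF + sample sheet or the built-in
simulator.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from radpop import demography as dm
from radpop import genotypes as gt
from radpop import inversions as inv
from radpop import stats as st
from radpop.clustering import (
    assign_clusters,
    nj_tree,
    pairwise_distance_matrix,
    pca_genotypes,
    suggest_k,
    tree_to_newick,
)
from radpop.simulate import (
    InversionSpec,
    SimulationConfig,
    apply_rad_dropout,
    implant_inversion,
    simulate_species_complex,
)

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "filter", "structure", "diversity", "divergence", "inversions", "fst", "afs",
)

STAGE_DEPS = {
    "structure": (),
    "diversity": (),
    "divergence": (),
    "inversions": (),
    "fst": (),
    "afs": ("inversions",),   # AFS excludes detected inversion blocks
}


@dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from YAML or JSON."""

    seed: int = 0
    # input: either paths ...
    vcf: str | None = None
    sample_sheet: str | None = None
    # ... or simulation settings
    simulate: dict | None = None
    implant_inversion: bool = True
    dropout_scale: float = 0.0
    # filtering
    min_qual: float = 25.0
    min_depth: int = 15
    indel_excl_bp: int = 6
    pair_gap_bp: int = 150
    # analysis settings
    constants: dict = field(default_factory=lambda: {"mu_per_year": 1.1e-8,
                                                     "generations_per_year": 10})
    n_perm: int = 1000
    n_fst_subsets: int = 5
    inversion_arm: str = "2L"
    focal_species: str | None = None
    afs_models: tuple[str, ...] = ("standard_neutral", "two_epoch", "exp_growth",
                                   "bottle_growth")
    afs_bootstrap: int = 0
    exclude_chroms_afs: tuple[str, ...] = ("X",)
    stages: tuple[str, ...] = ALL_STAGES

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if (self.vcf is None) == (self.simulate is None):
            raise ValueError("config must set exactly one of 'vcf' or 'simulate'")
        if self.vcf is not None and self.sample_sheet is None:
            raise ValueError("'vcf' input requires 'sample_sheet'")
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def simulation_config(self) -> SimulationConfig:
        params = dict(self.simulate or {})
        inv_spec = params.pop("inversion", None)
        if isinstance(inv_spec, dict):
            inv_spec = InversionSpec(**inv_spec)
        demog = params.pop("demography", None)
        if isinstance(demog, dict):
            demog = dm.DemographicModel(demog["name"],
                                        {k: v for k, v in demog.items() if k != "name"})
        kwargs = dict(params)
        if inv_spec is not None:
            kwargs["inversion"] = inv_spec
        if demog is not None:
            kwargs["demography"] = demog
        kwargs.setdefault("seed", self.seed)
        return SimulationConfig(**kwargs)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run the configured stages; returns a dict of in-memory results.

    Artifacts are written under ``outdir``.  A stage whose dependency was
    disabled raises immediately, naming the missing stage.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enabled = set(config.stages)
    for stage in enabled:
        for dep in STAGE_DEPS.get(stage, ()):
            if dep not in enabled:
                raise ValueError(f"stage {stage!r} requires disabled stage {dep!r}")

    results: dict = {"config_hash": config.config_hash(), "seed": config.seed}
    meta = {"config": asdict(config), "config_hash": results["config_hash"]}
    constants = st.Constants(**config.constants)

    # ---- input ----------------------------------------------------------
    truth = None
    if config.simulate is not None:
        sim_cfg = config.simulation_config()
        m, truth = simulate_species_complex(sim_cfg)
        if config.implant_inversion:
            m, truth = implant_inversion(m, truth)
        if config.dropout_scale > 0:
            m = apply_rad_dropout(m, truth, config.dropout_scale,
                                  seed=config.seed + 1)
        results["truth"] = truth
    else:
        sheet = gt.read_sample_sheet(config.sample_sheet)
        m = gt.read_genotype_matrix(config.vcf, sheet)

    # ---- filter + tags --------------------------------------------------
    if "filter" in enabled:
        m = gt.filter_sites(m, min_qual=config.min_qual, min_depth=config.min_depth,
                            indel_excl_bp=config.indel_excl_bp)
        meta["filter_log"] = m.filter_log
    tags = gt.group_tag_locations(m, pair_gap_bp=config.pair_gap_bp)
    gt.write_tag_bed(tags, outdir / "tags.bed")
    results["matrix"] = m
    results["tags"] = tags

    species = list(dict.fromkeys(m.samples["species"]))
    locations = list(dict.fromkeys(m.samples["location"]))
    focal = config.focal_species or species[0]

    # ---- species clustering --------------------------------------------
    if "structure" in enabled:
        thinned = gt.draw_one_snp_per_tag(m, tags, seed=config.seed)
        pca = pca_genotypes(thinned, n_components=2)
        k = suggest_k(pca, k_max=5, seed=config.seed)
        labels = assign_clusters(pca, k, seed=config.seed)
        scores = pca.scores.copy()
        scores["cluster"] = labels
        scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
        tree = nj_tree(pairwise_distance_matrix(m))
        (outdir / "nj_tree.nwk").write_text(tree_to_newick(tree) + "\n")
        results["structure"] = {"pca": pca, "k": k, "labels": labels, "tree": tree}

    # ---- diversity ------------------------------------------------------
    if "diversity" in enabled:
        rows = []
        for pop in species + (locations if len(locations) > 1 else []):
            try:
                r = st.diversity_stats(m, pop, tags=tags)
            except KeyError:
                continue
            rows.append({
                "pop": pop, "n_chrom": r.n_chrom, "L": r.L, "S": r.S,
                "pi_per_site": r.pi_per_site, "pi_sd": r.pi_sd,
                "theta_w_per_site": r.theta_w_per_site, "tajimas_d": r.tajimas_d,
            })
        diversity = pd.DataFrame(rows)
        diversity.to_csv(outdir / "diversity.tsv", sep="\t", index=False)
        results["diversity"] = diversity

    # ---- divergence and site classification ----------------------------
    if "divergence" in enabled:
        rows = []
        for i in range(len(species)):
            for j in range(i + 1, len(species)):
                d = st.divergence_stats(m, species[i], species[j], constants)
                cls = st.classify_sites(m, species[i], species[j])
                rows.append({
                    "pop1": species[i], "pop2": species[j],
                    "dxy": d.dxy_per_site, "da": d.da_per_site,
                    "t_years": d.t_years,
                    **{k: v for k, v in cls.counts.items() if k != "monomorphic"},
                })
        divergence = pd.DataFrame(rows)
        divergence.to_csv(outdir / "divergence.tsv", sep="\t", index=False)
        results["divergence"] = divergence
        if len(species) == 3:
            results["venn"] = st.classify_sites_venn(m, species)
            (outdir / "polymorphism_venn.json").write_text(
                json.dumps(results["venn"], indent=2))

    # ---- inversion scan -------------------------------------------------
    blocks: list[inv.LdBlock] = []
    if "inversions" in enabled:
        focal_m = m.subset_population(focal)
        arm_tags = [t for t in tags if t.chrom == config.inversion_arm]
        inv_result = {"blocks": [], "calls": None}
        if len(arm_tags) >= 5:
            on_arm = focal_m.sites["chrom"].to_numpy() == config.inversion_arm
            if (on_arm & focal_m.polymorphic_mask()).sum() >= 5:
                ld = inv.ld_r2_matrix(focal_m, region=config.inversion_arm)
                blocks = inv.ld_block_scan(ld, tags=tags)
                inv_result["blocks"] = blocks
                with open(outdir / "ld_blocks.bed", "w") as fh:
                    for b in blocks:
                        fh.write(f"{b.chrom}\t{b.start - 1}\t{b.end}\t"
                                 f"r2={b.mean_r2_inside:.3f}\n")
                if blocks:
                    calls = inv.karyotype_call(focal_m, blocks[0], seed=config.seed)
                    calls.to_csv(outdir / "karyotypes.tsv", sep="\t", index=False)
                    outgroup = next((s for s in species if s != focal), None)
                    strat = inv.karyotype_stratified_stats(
                        focal_m if outgroup is None else m,
                        calls, blocks[0], outgroup=outgroup)
                    inv_result["calls"] = calls
                    inv_result["stratified"] = strat
        results["inversions"] = inv_result

    # ---- population differentiation ------------------------------------
    if "fst" in enabled:
        rows = []
        for sp in species:
            locs = list(dict.fromkeys(
                m.samples.loc[m.samples["species"] == sp, "location"]))
            for i in range(len(locs)):
                for j in range(i + 1, len(locs)):
                    r = st.fst(m, [locs[i], locs[j]], tags=tags,
                               n_perm=config.n_perm,
                               n_subsets=config.n_fst_subsets, seed=config.seed)
                    nm = st.nm_from_fst(r.reported) if 0 < r.reported < 1 else float("nan")
                    rows.append({"species": sp, "pop1": locs[i], "pop2": locs[j],
                                 "fst": r.reported, "p": r.permutation_p, "nm": nm})
        fst_table = pd.DataFrame(rows)
        fst_table.to_csv(outdir / "fst.tsv", sep="\t", index=False)
        results["fst"] = fst_table

    # ---- folded AFS demography -----------------------------------------
    if "afs" in enabled:
        exclude: list = list(config.exclude_chroms_afs)
        exclude += [(b.chrom, b.start, b.end) for b in blocks]
        afs_out = {}
        for pop in species:
            sfs = dm.folded_afs(m, pop, one_per_tag=True, tags=tags,
                                seed=config.seed, exclude=exclude)
            if sfs.S == 0:
                continue
            fits = [dm.fit_demographic_model(sfs, name, seed=config.seed)
                    for name in config.afs_models]
            ranked = dm.compare_models_lrt(fits)
            best = dm.best_model_by_lrt(fits)
            best_name = best.model.name
            ci = {}
            if config.afs_bootstrap > 0 and best.model.k > 0:
                ci = dm.bootstrap_ci(sfs, best_name, n_boot=config.afs_bootstrap,
                                     seed=config.seed, fit=best)
            afs_out[pop] = {
                "n_chrom": sfs.n_chrom, "S": sfs.S,
                "sfs": sfs.counts.tolist(),
                "models": ranked.to_dict(orient="records"),
                "best_model": best_name, "best_params": best.model.params,
                "ci95": ci,
            }
        (outdir / "afs_fits.json").write_text(json.dumps(afs_out, indent=2))
        results["afs"] = afs_out

    (outdir / "run_metadata.json").write_text(
        json.dumps(meta, indent=2, default=str))
    return results
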