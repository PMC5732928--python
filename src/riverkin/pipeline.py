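"""End-to-end pipeline orchestration.

Runs diversity -> differentiation -> clustering -> bottleneck -> mtdna ->
kinship -> mating over a GenePop file, a metadata CSV and (optionally) a
FASTA alignment.  Each stage gets its own RNG stream derived from the
master seed (stable under stage reordering), writes CSV/JSON outputs whose
first line records the config hash and seed, and fails in isolation:
a stage error is logged and only stages depending on it are skipped.
"""

from __future__ import annotations

import hashlib
import json
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import (bottleneck, clustering, data_model, differentiation,
               diversity, kinship, mating, mtdna)
from .simulate import IAM, SMM, MutationModel

STAGES = ("diversity", "differentiation", "clustering", "bottleneck",
          "mtdna", "kinship", "mating")


@dataclass
class RunConfig:
    genepop: str
    metadata: str
    fasta: str | None = None
    seed: int = 0
    outdir: str = "riverkin_out"
    n_perm: int = 1000
    n_bootstrap: int = 1000
    n_sims: int = 1000
    tpm_p_single: float = 0.70
    rarefaction_g: str = "auto"
    advisor_a: str = "DyadML"
    advisor_b: str = "QG"
    alpha: float = 0.05

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Flat ``key = value`` text format; '#' starts a comment."""
        kwargs = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if key not in cls.__dataclass_fields__:
                raise ValueError(f"unknown config key {key!r}")
            typ = cls.__dataclass_fields__[key].type
            if typ == "int":
                kwargs[key] = int(value)
            elif typ == "float":
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig,
               index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# riverkin config={config.hash()} seed={config.seed}\n")
        df.to_csv(fh, index=index)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the run log (also written as JSON)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(
        json.dumps({**config.__dict__, "hash": config.hash()}, indent=2))
    log: dict[str, dict] = {}
    state: dict[str, object] = {}

    genos, gp_meta = data_model.read_genepop(config.genepop)
    metadata = data_model.SampleMetadata.from_csv(config.metadata)
    for ind in genos.individuals:
        if ind not in metadata.site:
            metadata.site[ind] = gp_meta.site[ind]
            metadata.sex.setdefault(ind, "U")
    alignment = None
    if config.fasta and Path(config.fasta).exists():
        alignment = data_model.read_fasta_alignment(config.fasta)

    def run_stage(name, fn, depends=()):
        t0 = time.time()
        for dep in depends:
            if dep not in state:
                log[name] = {"status": "skipped",
                             "reason": f"dependency {dep!r} unavailable"}
                return
        try:
            params = fn()
            log[name] = {"status": "ok", "seconds": round(time.time() - t0, 2),
                         "seed": config.stage_seed(name), **(params or {})}
        except Exception as exc:  # stage isolation
            log[name] = {"status": "error", "error": str(exc),
                         "traceback": traceback.format_exc()}

    # -- diversity ---------------------------------------------------------
    def stage_diversity():
        pops = metadata.populations()
        rows = []
        for pop in pops:
            members = [i for i in metadata.members(pop)
                       if i in genos.individuals]
            if not members:
                continue
            sub = genos.subset_individuals(members)
            for j, locus in enumerate(sub.loci):
                try:
                    s = diversity.locus_summary(sub, j)
                except ValueError:
                    continue
                rows.append({"population": pop, **s.__dict__})
        df = pd.DataFrame(rows)
        _write_csv(df, out / "diversity_per_locus.csv", config, index=False)
        priv = diversity.private_alleles(genos, metadata)
        _write_csv(pd.DataFrame([priv]), out / "private_alleles.csv", config,
                   index=False)
        return {"n_rows": len(df)}

    # -- differentiation ---------------------------------------------------
    def stage_differentiation():
        pm = differentiation.pairwise_dest(
            genos, metadata, n_bootstrap=config.n_bootstrap,
            seed=config.stage_seed("differentiation"), alpha=config.alpha)
        result = {"n_pops": len(pm.labels)}
        if alignment is not None:
            phi = differentiation.pairwise_phist(
                alignment, metadata, n_perm=config.n_perm,
                seed=config.stage_seed("differentiation") + 1,
                alpha=config.alpha)
            # mirror the classic layout: phi_ST above, D_EST below diagonal
            combo = pm.values.copy()
            for i, a in enumerate(pm.labels):
                for j, b in enumerate(pm.labels):
                    if j > i and a in phi.values.index and b in phi.values.columns:
                        combo.loc[a, b] = phi.values.loc[a, b]
            _write_csv(combo, out / "pairwise_differentiation.csv", config)
            _write_csv(phi.pvalues, out / "phist_pvalues.csv", config)
        else:
            _write_csv(pm.values, out / "pairwise_differentiation.csv", config)
        _write_csv(pm.pvalues, out / "dest_pvalues.csv", config)
        return result

    # -- clustering --------------------------------------------------------
    def stage_clustering():
        table = clustering.individual_allele_table(genos)
        groups = [metadata.site[i] for i in genos.individuals]
        res = clustering.dapc(table, groups, n_pcs="auto",
                              seed=config.stage_seed("clustering"))
        _write_csv(res.membership, out / "dapc_membership.csv", config)
        dist = clustering.euclidean_distances(table)
        (out / "nj_tree.nwk").write_text(clustering.nj_tree(dist) + "\n")
        return {"n_pcs": res.n_pcs}

    # -- bottleneck --------------------------------------------------------
    def stage_bottleneck():
        models = [IAM, SMM, MutationModel("TPM", config.tpm_p_single)]
        cache: bottleneck.HeqCache = {}
        rows = []
        for pop in metadata.populations():
            members = [i for i in metadata.members(pop)
                       if i in genos.individuals]
            if len(members) < 2:
                continue
            sub = genos.subset_individuals(members)
            row = bottleneck.bottleneck_table(
                sub, models, n_sims=config.n_sims,
                seed=config.stage_seed("bottleneck"), heq_cache=cache)
            row.insert(0, "population", pop)
            rows.append(row)
        df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
        _write_csv(df, out / "bottleneck.csv", config, index=False)
        return {"n_pops": len(rows)}

    # -- mtdna -------------------------------------------------------------
    def stage_mtdna():
        rows = []
        pops = metadata.populations()
        for pop in [None] + pops:
            ids = [i for i in alignment.sequences
                   if pop is None or metadata.site.get(i) == pop]
            if not ids:
                continue
            sub = alignment.subset(ids)
            s = mtdna.mtdna_summary(sub)
            rec = {"population": pop or "overall", **{
                k: v for k, v in s.__dict__.items()
                if k != "base_composition"}}
            if s.n >= 2 and s.S >= 1:
                rec["Fs"] = mtdna.fu_fs(sub)
                rec["R2"] = mtdna.r2_statistic(sub)
                ps = mtdna.neutrality_pvalues(
                    rec["Fs"], rec["R2"], s.n, s.S,
                    n_sims=max(config.n_sims, 100),
                    seed=config.stage_seed("mtdna"))
                rec.update(ps)
            rows.append(rec)
        _write_csv(pd.DataFrame(rows), out / "mtdna_summary.csv", config,
                   index=False)
        G = mtdna.median_joining_network(alignment)
        mtdna.write_network_graphml(G, out / "haplotype_network.graphml")
        return {"n_haplotypes": alignment.n_haplotypes}

    # -- kinship -----------------------------------------------------------
    def stage_kinship():
        table = kinship.pairwise_relatedness(
            genos, seed=config.stage_seed("kinship"))
        state["relatedness"] = table
        _write_csv(table.pairs, out / "relatedness_pairs.csv", config,
                   index=False)
        return {"n_pairs": len(table.pairs)}

    # -- mating ------------------------------------------------------------
    def stage_mating():
        table: kinship.RelatednessTable = state["relatedness"]  # type: ignore
        pairs = mating.enumerate_pairings(metadata)
        plan = mating.classify_pairings(pairs, table,
                                        config.advisor_a, config.advisor_b)
        summary, matrix = mating.mating_report(plan)
        _write_csv(plan.pairs, out / "mating_plan.csv", config, index=False)
        _write_csv(summary, out / "mating_summary.csv", config, index=False)
        _write_csv(matrix, out / "mating_matrix.csv", config)
        (out / "mating_plan.json").write_text(json.dumps({
            "note": plan.note,
            "summary": summary.to_dict(orient="records")}, indent=2))
        return {"n_pairings": len(plan.pairs)}

    run_stage("diversity", stage_diversity)
    run_stage("differentiation", stage_differentiation)
    run_stage("clustering", stage_clustering)
    run_stage("bottleneck", stage_bottleneck)
    if alignment is not None:
        run_stage("mtdna", stage_mtdna)
    else:
        log["mtdna"] = {"status": "skipped", "reason": "no mtDNA input"}
    run_stage("kinship", stage_kinship)
    run_stage("mating", stage_mating, depends=("relatedness",))

    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return log
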