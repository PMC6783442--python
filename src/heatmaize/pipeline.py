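"""Pipeline orchestration: validated run configuration, staged execution in
dependency order, and a manifest recording seeds, hashes and wall times.

Stages: simulate -> qc -> aem -> hsi -> diversity -> gwp -> expect.  Each
stage writes its outputs into the run directory; re-running with the same
configuration is bit-identical (every stochastic stage derives its seed
from the master seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import expect as expect_mod
from . import genoqc, gwp, hsi, io
from . import mixmod
from . import diversity as div_mod
from .popsim import add_genotype_probabilities, simulate_study

logger = logging.getLogger(__name__)

STAGES = ["simulate", "qc", "aem", "hsi", "diversity", "gwp", "expect"]

DEFAULT_CONFIG = {
    "seed": 1,
    "out_dir": "runs/demo",
    "stages": ["all"],
    "simulate": {
        "n_progeny": 50,
        "n_markers_dense": 1088,
        "n_markers_sparse": 170,
        "n_chromosomes": 10,
        "total_length_cm": 1823.5,
        "n_traits": 3,
        "n_qtl": 40,
        "n_replicates": 3,
        "n_blocks": 16,
    },
    "qc": {
        "gp_mode": "GP098",
        "error_rate": 0.02,
        "missing_rate": 0.05,
        "segregation_alpha": 0.001,
    },
    "aem": {},
    "hsi": {"n_rounds": 25, "qst_c": 2.0},
    "diversity": {"n_axes": 2},
    "gwp": {
        "folds": 5,
        "cv_reps": 5,
        "bootstrap_sizes": [10, 20, 30, 40],
        "bootstrap_rounds": 25,
        "scenario_rounds": 25,
        "ts_size": 50,
        "validation_population": "P_D1D2",
    },
    "expect": {"genome_length_morgan": 22.36, "generation_sizes": [2, 50]},
}


def _merge_validate(config: dict) -> dict:
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if key not in merged:
            raise ValueError(f"unknown configuration key {key!r}")
        if isinstance(merged[key], dict):
            if not isinstance(val, dict):
                raise ValueError(f"section {key!r} must be a mapping")
            for k2, v2 in val.items():
                if k2 not in merged[key]:
                    raise ValueError(f"unknown configuration key {key}.{k2}")
                merged[key][k2] = v2
        else:
            merged[key] = val
    return merged


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict | None = None) -> dict:
    """Execute the configured stages and return the manifest."""
    cfg = _merge_validate(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    stages = cfg["stages"]
    if "all" in stages:
        stages = STAGES
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]

    master = np.random.default_rng(cfg["seed"])
    stage_seeds = {s: int(master.integers(2**31)) for s in STAGES}

    manifest = {"seed": cfg["seed"], "config": cfg, "stages": {}}
    state: dict = {}
    for stage in stages:
        t0 = time.time()
        outputs = _RUNNERS[stage](cfg, out, stage_seeds[stage], state)
        manifest["stages"][stage] = {
            "seed": stage_seeds[stage],
            "wall_s": round(time.time() - t0, 3),
            "outputs": {str(p.name): _sha256(p) for p in outputs},
        }
        logger.info("stage %s done in %.1fs", stage, manifest["stages"][stage]["wall_s"])
    from . import __version__

    manifest["version"] = __version__
    io.write_json(manifest, out / "manifest.json")
    return manifest


def _need(state, key, out, loader):
    """Fetch an upstream artefact from memory or the run directory."""
    if key in state:
        return state[key]
    path = out / loader[0]
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream output {path.name}; run the {loader[2]} stage first"
        )
    state[key] = loader[1](path)
    return state[key]


def _run_simulate(cfg, out, seed, state):
    sim = simulate_study(seed=seed, **cfg["simulate"])
    state["sim"] = sim
    io.write_genotypes(sim.geno_dense, out / "genotypes_dense.tsv")
    io.write_genotypes(sim.geno_sparse, out / "genotypes_sparse.tsv")
    io.write_genotypes(sim.parents, out / "genotypes_parents.tsv")
    io.write_map(sim.gmap, out / "map.tsv")
    io.write_phenotypes(sim.phenotypes, out / "phenotypes.csv")
    sim.truth.to_json(out / "truth.json")
    state["pheno"] = sim.phenotypes
    return [
        out / p
        for p in (
            "genotypes_dense.tsv",
            "genotypes_sparse.tsv",
            "genotypes_parents.tsv",
            "map.tsv",
            "phenotypes.csv",
            "truth.json",
        )
    ]


def _run_qc(cfg, out, seed, state):
    sim = state.get("sim")
    geno = sim.geno_dense if sim else io.read_genotypes(out / "genotypes_dense.tsv")
    c = cfg["qc"]
    gp = add_genotype_probabilities(geno, c["error_rate"], c["missing_rate"], seed)
    called = genoqc.gp_cutoff_filter(gp, genoqc.GPCutoffPolicy(c["gp_mode"]), geno)
    imputed = genoqc.mean_impute(called)
    state["imputed"] = imputed
    sparse = sim.geno_sparse if sim else io.read_genotypes(out / "genotypes_sparse.tsv")
    retained = genoqc.segregation_filter(sparse, 0.5, c["segregation_alpha"])
    state["retained_sparse"] = retained
    imputed.to_csv(out / "imputed_dense.csv")
    io.write_marker_list(retained, out / "retained_sparse_markers.txt")
    return [out / "imputed_dense.csv", out / "retained_sparse_markers.txt"]


def _run_aem(cfg, out, seed, state):
    pheno = _need(state, "pheno", out, ("phenotypes.csv", io.read_phenotypes, "simulate"))
    aem = mixmod.aem_table(pheno)
    state["aem"] = aem
    aem.table.to_csv(out / "aem.csv", index=False)
    cond_p = {
        t: mixmod.condition_effect_test(pheno, t) for t in dict.fromkeys(pheno["trait"])
    }
    io.write_json(cond_p, out / "condition_effect_pvalues.json")
    return [out / "aem.csv", out / "condition_effect_pvalues.json"]


def _run_hsi(cfg, out, seed, state):
    pheno = _need(state, "pheno", out, ("phenotypes.csv", io.read_phenotypes, "simulate"))
    if "aem" not in state:
        _run_aem(cfg, out, seed, state)
    aem = state["aem"]
    pops = dict(
        pheno.drop_duplicates("genotype").set_index("genotype")["population"]
    )
    table = hsi.compute_hsi(aem, pops)
    state["hsi"] = table
    table.to_csv(out / "hsi.csv", index=False)
    report = {}
    for k, trait in enumerate(dict.fromkeys(pheno["trait"])):
        h2, _ = hsi.hsi_heritability(pheno, trait, cfg["hsi"]["n_rounds"], seed + k)
        q = hsi.qst_from_phenotypes(
            pheno, trait, cfg["hsi"]["n_rounds"], seed + k, c=cfg["hsi"]["qst_c"]
        )
        report[trait] = {
            "h2_hsi": h2,
            "qst": q.qst,
            "sigma2_among": q.sigma2_among,
            "sigma2_within": q.sigma2_within,
        }
    corr = hsi.hsi_correlations(table)
    corr.to_csv(out / "hsi_correlations.csv")
    io.write_json(report, out / "hsi_report.json")
    return [out / "hsi.csv", out / "hsi_correlations.csv", out / "hsi_report.json"]


def _run_diversity(cfg, out, seed, state):
    if "imputed" not in state:
        path = out / "imputed_dense.csv"
        if not path.exists():
            raise FileNotFoundError("missing imputed_dense.csv; run the qc stage first")
        state["imputed"] = pd.read_csv(path, index_col=0)
    sim = state.get("sim")
    geno = sim.geno_dense if sim else io.read_genotypes(out / "genotypes_dense.tsv")
    d = div_mod.gene_diversity(geno)
    g_st = div_mod.gst(geno)
    dist = div_mod.mrd(geno)
    summary = div_mod.mrd_population_summary(dist, geno.populations)
    coords, pct = div_mod.pcoa(dist, cfg["diversity"]["n_axes"])
    ka = div_mod.additive_kinship(state["imputed"])
    kd = div_mod.dominance_kinship(state["imputed"])
    state["ka"], state["kd"] = ka, kd
    io.write_json({"D": d, "G_ST": g_st}, out / "diversity.json")
    io.write_matrix(summary, out / "mrd_populations.tsv")
    io.write_matrix(ka.values, out / "kinship_additive.tsv")
    io.write_matrix(kd.values, out / "kinship_dominance.tsv")
    with open(out / "pcoa.csv", "w") as fh:
        fh.write("# percent variance: " + ", ".join(f"{p:.2f}" for p in pct) + "\n")
        coords.to_csv(fh, index_label="id")
    return [
        out / "diversity.json",
        out / "mrd_populations.tsv",
        out / "kinship_additive.tsv",
        out / "kinship_dominance.tsv",
        out / "pcoa.csv",
    ]


def _run_gwp(cfg, out, seed, state):
    if "hsi" not in state:
        path = out / "hsi.csv"
        if not path.exists():
            raise FileNotFoundError("missing hsi.csv; run the hsi stage first")
        state["hsi"] = pd.read_csv(path)
    if "ka" not in state:
        path = out / "kinship_additive.tsv"
        if not path.exists():
            raise FileNotFoundError("missing kinship_additive.tsv; run the diversity stage first")
        state["ka"] = div_mod.KinshipMatrix(io.read_matrix(path), "additive", 0)
    table = state["hsi"]
    ka = state["ka"]
    pops = table.drop_duplicates("genotype").set_index("genotype")["population"]
    c = cfg["gwp"]
    results = {}
    scheme = state["sim"].scheme if "sim" in state else None
    for trait in dict.fromkeys(table["trait"]):
        y = table[table["trait"] == trait].set_index("genotype")["hsi"]
        r_a, r_pop, _ = gwp.fit_and_ability(y, [ka], pops)
        r_a_cv, r_pop_cv, _ = gwp.cross_validate(
            y, [ka], pops, c["folds"], c["cv_reps"], seed
        )
        entry = {
            "r_a": r_a,
            "r_pop": r_pop,
            "r_a_cv": r_a_cv,
            "r_pop_cv": r_pop_cv,
        }
        bsw = gwp.within_population_bootstrap(
            y, [ka], c["validation_population"], pops,
            sizes=c["bootstrap_sizes"], rounds=c["bootstrap_rounds"], seed=seed,
        )
        entry["r_pop_BSPw"] = bsw.meta["medians"]
        if scheme is not None:
            scen = gwp.resolve_scenarios(
                scheme, c["validation_population"], size=c["ts_size"],
                rounds=c["scenario_rounds"],
            )
            res = gwp.between_population_scenarios(y, [ka], pops, scen, seed)
            entry["r_pop_BSPb"] = dict(zip(res["scenario"], res["median_r"]))
        results[trait] = entry
    state["gwp"] = results
    io.write_json(results, out / "gwp_summary.json")
    return [out / "gwp_summary.json"]


def _run_expect(cfg, out, seed, state):
    if "gwp" not in state:
        path = out / "gwp_summary.json"
        if not path.exists():
            raise FileNotFoundError("missing gwp_summary.json; run the gwp stage first")
        state["gwp"] = json.loads(path.read_text())
    c = cfg["expect"]
    n_e = expect_mod.effective_population_size(c["generation_sizes"])
    m_e = expect_mod.effective_number_of_segments(n_e, c["genome_length_morgan"])
    rows = []
    for trait, entry in state["gwp"].items():
        bsw = dict(entry["r_pop_BSPw"])
        if not bsw:
            continue
        n_ts = max(int(k) for k in bsw)
        r_obs = bsw[max(bsw, key=int)]
        # realised entry-mean heritability proxy: squared non-CV ability
        h2 = min(max(float(entry["r_a"]) ** 2, 1e-3), 1.0)
        r_exp = expect_mod.expected_ability(n_ts, h2, m_e)
        rows.append((trait, n_ts, float(r_obs), r_exp))
    df = pd.DataFrame(rows, columns=["trait", "n_ts", "r_obs", "r_exp"])
    df.to_csv(out / "expected_vs_observed.csv", index=False)
    io.write_json({"N_e": n_e, "M_e": m_e}, out / "expectation_params.json")
    return [out / "expected_vs_observed.csv", out / "expectation_params.json"]


_RUNNERS = {
    "simulate": _run_simulate,
    "qc": _run_qc,
    "aem": _run_aem,
    "hsi": _run_hsi,
    "diversity": _run_diversity,
    "gwp": _run_gwp,
    "expect": _run_expect,
}
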