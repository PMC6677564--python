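"""Orchestrate the full analysis from one configuration.

Stages: microsatellite diversity statistics, population structure
(AMOVA / pairwise F_ST / DAPC), plastid haplotype diversity, and ABC
demographic inference. Each stage draws its randomness from an independent
stream split off the single run seed by stage index, so toggling one stage
never shifts another stage's results. A JSON manifest records seeds, input
checksums, package versions and every output file.
"""
from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abc_inference import (
    STAT_NAMES,
    build_reference_table,
    estimate_parameters,
    model_choice_direct,
    model_choice_logistic,
    posterior_model_check,
    predictive_error,
)
from .coalescent_gsm import MutationModel, PriorSpec, summary_stats
from .io_formats import concatenate, read_fasta_alignment, read_genotypes
from .msat_diversity import diversity_table, private_alleles
from .plastid_diversity import (
    gc_content,
    haplotype_diversity,
    identify_haplotypes,
    nucleotide_diversity,
)
from .pop_structure import amova, dapc, pairwise_fst

#: Fixed stage indices for seed splitting; stable across toggling.
_STAGE_INDEX = {"synth": 0, "stats": 1, "structure": 2, "plastid": 3, "abc": 4}


@dataclass
class RunConfig:
    seed: int
    outdir: str
    genotypes: str | None = None
    fasta_regions: list[str] = field(default_factory=list)
    run_stats: bool = True
    run_structure: bool = True
    run_plastid: bool = True
    run_abc: bool = False
    n_perm: int = 10_000
    rarefaction_g: int | None = None
    abc_n_per_scenario: int = 10_000
    abc_k_direct: int = 500
    abc_k_logistic: int = 10_000
    abc_k_est: int = 5_000
    abc_n_pods: int = 40
    prior_bounds: dict | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_perm", "abc_n_per_scenario", "abc_k_direct",
                     "abc_k_logistic", "abc_k_est", "abc_n_pods"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def validate(self) -> None:
        if (self.run_stats or self.run_structure or self.run_abc) and not self.genotypes:
            raise ValueError("genotype input required for the enabled stages")
        if self.run_plastid and not self.fasta_regions:
            raise ValueError("fasta_regions required when the plastid stage is enabled")
        if self.genotypes and not Path(self.genotypes).exists():
            raise FileNotFoundError(self.genotypes)
        for f in self.fasta_regions:
            if not Path(f).exists():
                raise FileNotFoundError(f)


def stage_seed(seed: int, stage: str) -> int:
    """Independent 31-bit stream seed for one stage of a run."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_STAGE_INDEX[stage],))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> Path:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")
    return path


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the enabled stages and return the manifest (also written to disk)."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "edgepop_version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "inputs": {},
        "stages": {},
        "outputs": [],
    }
    outputs: list[Path] = []

    g = pm = None
    if cfg.genotypes:
        dialect = "csv" if cfg.genotypes.endswith(".csv") else "genepop"
        g, pm, _ = read_genotypes(cfg.genotypes, dialect=dialect)
        manifest["inputs"][cfg.genotypes] = _sha256(Path(cfg.genotypes))
    for f in cfg.fasta_regions:
        manifest["inputs"][f] = _sha256(Path(f))

    try:
        if cfg.run_stats:
            outputs += _stats_stage(cfg, g, pm, outdir, manifest)
        if cfg.run_structure:
            outputs += _structure_stage(cfg, g, pm, outdir, manifest)
        if cfg.run_plastid:
            outputs += _plastid_stage(cfg, outdir, manifest)
        if cfg.run_abc:
            outputs += _abc_stage(cfg, g, outdir, manifest)
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        manifest["outputs"] = [str(p) for p in outputs]
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    manifest["outputs"] = [str(p) for p in outputs]
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _stats_stage(cfg, g, pm, outdir: Path, manifest) -> list[Path]:
    seed = stage_seed(cfg.seed, "stats")
    table = diversity_table(
        g, pm, rarefaction_g=cfg.rarefaction_g, n_perm=cfg.n_perm, seed=seed
    )
    out = [_write_tsv(table, outdir / "diversity_per_locus.tsv")]
    if pm is not None and len(pm.populations()) >= 2:
        priv = private_alleles(g, pm)
        out.append(_write_tsv(priv.to_frame("E"), outdir / "private_alleles.tsv"))
    manifest["stages"]["stats"] = {"seed": seed, "n_perm": cfg.n_perm}
    return out


def _structure_stage(cfg, g, pm, outdir: Path, manifest) -> list[Path]:
    seed = stage_seed(cfg.seed, "structure")
    res = amova(g, pm, n_perm=cfg.n_perm, seed=seed)
    summary = pd.DataFrame(
        {
            "value": [
                res.sigma_among, res.sigma_within, res.percent_among,
                res.percent_within, res.fst, res.p_value,
            ]
        },
        index=[
            "sigma_among", "sigma_within", "percent_among",
            "percent_within", "fst", "p_value",
        ],
    )
    out = [
        _write_tsv(summary, outdir / "amova.tsv"),
        _write_tsv(res.per_locus, outdir / "amova_per_locus.tsv"),
    ]
    fst, pv = pairwise_fst(g, pm, n_perm=cfg.n_perm, seed=seed + 1)
    out.append(_write_tsv(fst, outdir / "pairwise_fst.tsv"))
    out.append(_write_tsv(pv, outdir / "pairwise_fst_p.tsv"))
    dres = dapc(g, seed=seed)
    if dres.coordinates is not None:
        coords = pd.DataFrame(
            dres.coordinates, index=g.individuals,
            columns=[f"LD{i + 1}" for i in range(dres.coordinates.shape[1])],
        )
        coords["group"] = dres.groups
        out.append(_write_tsv(coords, outdir / "dapc_coordinates.tsv"))
    manifest["stages"]["structure"] = {
        "seed": seed, "n_perm": cfg.n_perm,
        "amova_excluded": res.excluded_populations,
        "dapc_k": dres.k, "dapc_n_pca": dres.n_pca,
    }
    return out


def _plastid_stage(cfg, outdir: Path, manifest) -> list[Path]:
    regions = read_fasta_alignment(cfg.fasta_regions)
    combined = concatenate(regions)
    haps = identify_haplotypes(combined)
    rows = []
    for hid, count, freq in zip(haps.haplotype_ids, haps.counts, haps.frequencies()):
        rows.append({"haplotype": hid, "count": int(count), "frequency": freq})
    hap_df = pd.DataFrame(rows).set_index("haplotype")
    h, h_sd = haplotype_diversity(haps.counts)
    summary = {
        "n_sequences": combined.n_sequences,
        "alignment_length": combined.length,
        "n_haplotypes": len(haps.counts),
        "variable_sites": len(haps.variable_sites),
        "parsimony_informative": haps.parsimony_informative,
        "haplotype_diversity": h,
        "haplotype_diversity_sd": h_sd,
    }
    if len(haps.counts) >= 1 and combined.n_sequences >= 2:
        pi, pi_sd = nucleotide_diversity(combined)
        summary["nucleotide_diversity"] = pi
        summary["nucleotide_diversity_percent"] = 100 * pi
        summary["nucleotide_diversity_sd"] = pi_sd
    for reg in regions:
        summary[f"gc_{reg.region}"] = gc_content(reg)
    out = [
        _write_tsv(hap_df, outdir / "haplotypes.tsv"),
        _write_tsv(pd.Series(summary, name="value").to_frame(), outdir / "plastid_summary.tsv"),
    ]
    manifest["stages"]["plastid"] = {"regions": [r.region for r in regions]}
    return out


def _abc_stage(cfg, g, outdir: Path, manifest) -> list[Path]:
    seed = stage_seed(cfg.seed, "abc")
    priors = PriorSpec(cfg.prior_bounds) if cfg.prior_bounds else PriorSpec()
    mutation = MutationModel()
    obs = summary_stats(g)
    rt = build_reference_table(
        [1, 2, 3, 4], priors, g.loci, g.n_individuals,
        cfg.abc_n_per_scenario, seed=seed, mutation=mutation,
    )
    direct = model_choice_direct(obs, rt, k_direct=cfg.abc_k_direct)
    logistic = model_choice_logistic(obs, rt, k_logistic=cfg.abc_k_logistic)
    probs = pd.DataFrame(
        {"direct": direct.direct, "logistic": logistic.logistic}
    )
    if logistic.logistic_ci is not None:
        probs["logistic_low"] = logistic.logistic_ci["low"]
        probs["logistic_high"] = logistic.logistic_ci["high"]
    best = logistic.best("logistic")
    post = estimate_parameters(obs, rt, best, priors, k_est=cfg.abc_k_est)
    post_df = pd.DataFrame(
        {"Mode": post.mode, "q050": post.q050, "q950": post.q950}
    )
    err, per_scen = predictive_error(
        priors, rt, g.loci, g.n_individuals, cfg.abc_n_pods,
        seed=seed + 1, mutation=mutation, k=cfg.abc_k_direct,
    )
    check = posterior_model_check(
        obs, best, post, g.loci, g.n_individuals, n_ppc=200,
        seed=seed + 2, mutation=mutation,
    )
    obs_df = pd.Series(obs, index=STAT_NAMES, name="observed").to_frame()
    out = [
        _write_tsv(obs_df, outdir / "observed_stats.tsv"),
        _write_tsv(probs, outdir / "scenario_probabilities.tsv"),
        _write_tsv(post_df, outdir / "posterior_parameters.tsv"),
        _write_tsv(per_scen.to_frame(), outdir / "predictive_error_per_scenario.tsv"),
        _write_tsv(check, outdir / "posterior_model_check.tsv"),
    ]
    rt_path = outdir / "reference_table.tsv"
    rt.to_dataframe().head(5000).to_csv(rt_path, sep="\t", index=False)
    out.append(rt_path)
    manifest["stages"]["abc"] = {
        "seed": seed,
        "n_per_scenario": cfg.abc_n_per_scenario,
        "best_scenario": int(best),
        "predictive_error": float(err),
        "model_choice_flags": logistic.flags,
    }
    return out
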