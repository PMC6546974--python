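"""End-to-end orchestration: cohort -> landscape -> signatures ->
immunoediting -> tcr -> tme, with a combined JSON report."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from . import __version__, landscape, signatures, tcr, tme
from .immunoediting import build_gene_rates, observed_expected_test
from .io import write_cohort, write_json
from .synthetic import CohortConfig, generate_cohort
from .trees import SampleTree, tree_concordance

log = logging.getLogger(__name__)

STAGES = ("cohort", "landscape", "signatures", "immunoediting", "tcr", "tme")


@dataclass
class RunConfig:
    """Pipeline run settings; thresholds default to the study's values."""

    outdir: str = "mima_run"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    stages: tuple[str, ...] = STAGES
    write_files: bool = True
    # immunoediting is the expensive stage; bound it for orchestrated runs
    immuno_replicates: int = 50
    immuno_max_samples: int = 2
    tcr_depth: int = 1000
    tcr_repeats: int = 20
    knn_neighbors: int = 50

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_raw = raw.pop("cohort", {})
        known = {f.name for f in fields(cls)} - {"cohort"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
        cfg = cls(**raw, cohort=CohortConfig(**cohort_raw))
        if "seed" not in cohort_raw:
            cfg.cohort.seed = cfg.seed
        return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the report dict."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
    }
    cohort = generate_cohort(config.cohort)
    if "cohort" in config.stages:
        report["cohort"] = {
            "n_cases": len(cohort.cases),
            "n_samples": len(cohort.all_sample_ids),
            "n_mutations": sum(len(c.mutations) for c in cohort.cases.values()),
        }
        if config.write_files:
            write_cohort(cohort, outdir / "cohort")

    if "landscape" in config.stages:
        per_case = {}
        for cid, case in cohort.cases.items():
            labels, counts = landscape.classify_lineage(case.presence_matrix())
            per_case[cid] = counts
        report["landscape"] = {"lineage_counts": per_case}

    if "signatures" in config.stages:
        sig = {}
        for cid, case in cohort.cases.items():
            prof = signatures.build_profile96(case.mutations)
            fit = signatures.fit_exposures(prof, cohort.signature_catalog)
            sig[cid] = {
                "total_mutations": prof.total,
                "exposures": fit.exposures.round(1).to_dict(),
                "rmse": fit.rmse,
                "entropy": signatures.profile_entropy(prof),
            }
        report["signatures"] = sig

    if "immunoediting" in config.stages:
        rates = build_gene_rates(cohort.reference_catalog)
        tests = {}
        first_case = next(iter(cohort.cases.values()))
        for sid in first_case.sample_ids[: config.immuno_max_samples]:
            counter = cohort.neoepitope_counter(first_case.case_id, sid)
            res = observed_expected_test(
                first_case.mutations_in_sample(sid),
                counter,
                rates,
                cohort.genome,
                n_replicates=config.immuno_replicates,
                seed=config.seed,
                sample_id=sid,
            )
            tests[sid] = {
                "observed": res.observed_count,
                "mean_expected": float(np.mean(res.expected_counts)),
                "empirical_p": res.empirical_p,
            }
        report["immunoediting"] = tests

    if "tcr" in config.stages:
        out = {}
        for cid, case in cohort.cases.items():
            reps = tcr.repertoires_from_frame(
                case.clonotypes[case.clonotypes["chain"] == "beta"].assign(chain="beta")
            )
            _, fractions = tcr.classify_tcr_sharing(reps)
            out[cid] = {"mean_read_fractions": fractions.mean().round(4).to_dict()}
        first = next(iter(cohort.cases.values()))
        reps = tcr.repertoires_from_frame(
            first.clonotypes[first.clonotypes["chain"] == "beta"]
        )
        _, jtree = tcr.jaccard_tree(reps, chain="beta")
        if jtree is not None:
            genomic = SampleTree.from_newick(first.tree_newick)
            conc = tree_concordance(jtree, genomic, n_perm=200, seed=config.seed)
            out[first.case_id]["tree_concordance"] = {
                "cophenetic_r": conc.cophenetic_r,
                "rf_distance": conc.rf_distance,
                "p": conc.p_value,
            }
        report["tcr"] = out

    if "tme" in config.stages:
        cyt = tme.cytolytic_score(cohort.expression)
        ipg = tme.immunophenogram(cohort.expression)
        sid = cohort.all_sample_ids[0]
        density = tme.knn_density(cohort.pointsets[sid], n_neighbors=config.knn_neighbors)
        report["tme"] = {
            "cytolytic_mean": float(cyt.mean()),
            "ips": {s: int(v) for s, v in ipg.ips.items()},
            "density_mean_first_sample": float(density.mean()),
        }

    report["elapsed_s"] = round(time.time() - t0, 2)
    if config.write_files:
        write_json(outdir / "report.json", report)
    return report
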