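"""End-to-end orchestration: simulate/load -> merge -> normalize -> DE ->
consensus -> candidates -> cluster evaluation -> modules -> enrichment.

Every stage writes its outputs as TSV under the run directory and the run
finishes with a JSON manifest (parameters, per-stage shapes, file
checksums).  A single global seed fans out deterministically to the
stages that draw random numbers, so identical configs reproduce identical
outputs bit for bit.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from emtint import de as de_mod
from emtint.cluster_eval import dendrogram_newick, evaluate_grouping
from emtint.coexpression import TomModuleDetector, regress_out_phenotype
from emtint.enrichment import fisher_enrichment
from emtint.io import (
    GeneSetCollection,
    SampleMetadata,
    intersect_and_merge,
    read_expression_tsv,
    read_gmt,
    read_metadata_tsv,
    write_expression_tsv,
    write_gene_list,
    write_gmt,
)
from emtint.normalization import METHODS, normalize
from emtint.simulate import (
    SyntheticConfig,
    config_to_dict,
    generate_multistudy,
    truth_recovery_report,
    write_simulation,
)
from emtint.io import ExpressionStudy

logger = logging.getLogger("emtint")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Everything a run needs; see the package docs for parameter meaning."""

    mode: str = "simulate"  # "simulate" | "load"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    expression_paths: list[str] = field(default_factory=list)
    metadata_path: str | None = None
    methods: tuple[str, ...] = METHODS
    top_n: int = 200
    fc_threshold: float = 1.2
    fdr_threshold: float = 0.005
    filter_methods: tuple[str, ...] = de_mod.DEFAULT_FILTER_METHODS
    cluster_metric: str = "correlation"
    module_source: str = "QN_SVA"
    module_top_n: int = 200
    min_module_size: int = 15
    beta: str | float = "auto"
    beta_rule: str = "threshold"
    sva_k: str | int = "auto"
    gmt_path: str | None = None
    seed: int = 7
    outdir: str = "emtint_run"

    def validate(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ValueError(f"unknown mode {self.mode!r}")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown normalization methods: {sorted(unknown)}")
        if self.mode == "load":
            for p in [*self.expression_paths, self.metadata_path]:
                if p is None or not Path(p).exists():
                    raise ValueError(f"load mode: missing input file {p!r}")
            if len(self.expression_paths) < 2:
                raise ValueError("load mode needs at least two expression matrices")
        if self.gmt_path is not None and not Path(self.gmt_path).exists():
            raise ValueError(f"GMT file not found: {self.gmt_path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        synth = SyntheticConfig(**raw.pop("synthetic", {}))
        for key in ("methods", "filter_methods"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(synthetic=synth, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _derive_seeds(seed: int, n: int) -> list[int]:
    # keep derived seeds below 2**31 for portability
    return [int(s) for s in (np.random.SeedSequence(seed).generate_state(n) % (2 ** 31))]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; return (and write) the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    import emtint

    manifest: dict = {
        "started": datetime.datetime.now().isoformat(timespec="seconds"),
        "versions": {
            "emtint": emtint.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
        "parameters": _config_echo(config),
        "stages": {},
        "outputs": {},
    }
    seeds = _derive_seeds(config.seed, 3)
    stage = "init"
    try:
        stage = "input"
        if config.mode == "simulate":
            synth = config.synthetic
            studies, metadata, truth = generate_multistudy(synth)
            sim_paths = write_simulation(studies, metadata, truth, outdir / "input")
            manifest["stages"]["input"] = {
                "mode": "simulate",
                "n_studies": len(studies),
                "n_samples": len(metadata.sample_ids),
                "files": sim_paths,
            }
        else:
            studies = [
                ExpressionStudy(
                    study_id=Path(p).stem, platform_id="unknown",
                    values=read_expression_tsv(p),
                )
                for p in config.expression_paths
            ]
            metadata = read_metadata_tsv(config.metadata_path)
            truth = None
            manifest["stages"]["input"] = {
                "mode": "load",
                "n_studies": len(studies),
                "n_samples": len(metadata.sample_ids),
            }
        logger.info("input: %d studies, %d samples", len(studies), len(metadata.sample_ids))

        stage = "merge"
        integrated = intersect_and_merge(studies, metadata)
        write_expression_tsv(integrated.values, outdir / "integrated.tsv")
        manifest["stages"]["merge"] = {
            "n_common_genes": len(integrated.genes),
            "n_samples": len(integrated.samples),
            "per_study_gene_counts": integrated.per_study_gene_counts,
        }
        logger.info("merge: %d common genes x %d samples",
                    len(integrated.genes), len(integrated.samples))

        stage = "normalize"
        normalized = {}
        for method in config.methods:
            if method == "MCtr":
                nm = normalize(studies, method, metadata=metadata)
                # align to the integrated sample order
                nm.values = nm.values[integrated.samples]
            else:
                nm = normalize(integrated, method, k=config.sva_k, random_state=seeds[1])
            normalized[method] = nm
            write_expression_tsv(nm.values, outdir / f"normalized_{method}.tsv")
            if nm.surrogate_variables is not None:
                sv = nm.surrogate_variables
                pd.DataFrame(
                    sv.sv_matrix,
                    index=integrated.samples,
                    columns=[f"SV{i + 1}" for i in range(sv.k)],
                ).to_csv(outdir / f"svs_{method}.tsv", sep="\t")
        manifest["stages"]["normalize"] = {
            m: {"shape": list(normalized[m].values.shape),
                "n_svs": (normalized[m].surrogate_variables.k
                          if normalized[m].surrogate_variables else None)}
            for m in normalized
        }
        logger.info("normalize: %s", ", ".join(normalized))

        stage = "differential_expression"
        phenotype = integrated.phenotype
        de_tables = {}
        for method, nm in normalized.items():
            table = de_mod.differential_expression(nm.values, phenotype)
            de_tables[method] = table
            table.to_csv(outdir / f"de_{method}.tsv", sep="\t", float_format="%.17g")
        manifest["stages"]["differential_expression"] = {
            m: {"n_genes": len(t)} for m, t in de_tables.items()
        }

        stage = "concordance"
        four = [m for m in ("QN", "SVA", "QN_SVA", "MCtr") if m in de_tables]
        rho, rho_p = de_mod.concordance(
            {m: de_tables[m]["t_statistic"].to_numpy() for m in four}
        )
        rho.to_csv(outdir / "concordance_rho.tsv", sep="\t", float_format="%.6g")
        rho_p.to_csv(outdir / "concordance_p.tsv", sep="\t", float_format="%.6g")
        off = rho.to_numpy()[~np.eye(len(four), dtype=bool)]
        manifest["stages"]["concordance"] = {
            "methods": four,
            "min_rho": float(np.nanmin(off)) if off.size else None,
        }

        stage = "consensus"
        consensus = de_mod.consensus_rank({m: de_tables[m]["rank"] for m in four})
        consensus.to_csv(outdir / "consensus.tsv", sep="\t", float_format="%.17g")
        manifest["stages"]["consensus"] = {"n_genes": len(consensus)}

        stage = "candidates"
        candidates = de_mod.select_candidates(
            consensus, de_tables,
            top_n=config.top_n, fc_threshold=config.fc_threshold,
            fdr_threshold=config.fdr_threshold,
            filter_methods=[m for m in config.filter_methods if m in de_tables],
        )
        write_gene_list(candidates, outdir / "candidates.txt")
        cand_info: dict = {"n_candidates": len(candidates)}
        if truth is not None:
            cand_info["recovery"] = truth_recovery_report(candidates, truth)
        manifest["stages"]["candidates"] = cand_info
        logger.info("candidates: %d genes", len(candidates))

        stage = "cluster_evaluation"
        bh = evaluate_grouping(
            {m: nm.values for m, nm in normalized.items()},
            phenotype, metric=config.cluster_metric,
        )
        bh.to_csv(outdir / "baker_hubert.tsv", sep="\t", float_format="%.6g")
        for m, nm in normalized.items():
            (outdir / f"dendrogram_{m}.nwk").write_text(
                dendrogram_newick(nm.values, metric=config.cluster_metric)
            )
        manifest["stages"]["cluster_evaluation"] = {
            m: (None if pd.isna(v) else float(v)) for m, v in bh["bh_index"].items()
        }
        logger.info("cluster evaluation: %s",
                    {m: round(v, 3) for m, v in bh["bh_index"].items() if pd.notna(v)})

        stage = "modules"
        source = config.module_source
        module_genes = (
            de_tables[source].sort_values("rank").index[: config.module_top_n].tolist()
        )
        module_values = normalized[source].values.loc[module_genes]
        residuals = regress_out_phenotype(module_values, phenotype)
        detector = TomModuleDetector(
            beta=config.beta, beta_rule=config.beta_rule,
            min_module_size=config.min_module_size,
        ).fit(residuals.to_numpy())
        assignment = detector.assignment(module_values)
        assignment.labels.to_frame().to_csv(outdir / "modules.tsv", sep="\t")
        if len(assignment.eigengenes):
            assignment.eigengenes.to_csv(
                outdir / "eigengenes.tsv", sep="\t", float_format="%.17g"
            )
        if detector.fit_table_ is not None:
            detector.fit_table_.to_csv(
                outdir / "beta_fit.tsv", sep="\t", index=False, float_format="%.6g"
            )
        iu = np.triu_indices(len(module_genes), k=1)
        pd.DataFrame(
            {
                "gene_i": np.asarray(module_genes)[iu[0]],
                "gene_j": np.asarray(module_genes)[iu[1]],
                "tom": detector.tom_[iu],
            }
        ).to_csv(outdir / "tom_edges.tsv", sep="\t", index=False, float_format="%.6g")
        manifest["stages"]["modules"] = {
            "source": source,
            "beta": detector.beta_,
            "n_modules": detector.n_modules_,
            "module_sizes": {
                int(m): int((assignment.labels == m).sum())
                for m in sorted(set(assignment.labels) - {0})
            },
            "variance_explained": {int(k): v for k, v in
                                   assignment.variance_explained.items()},
        }
        logger.info("modules: %d (beta=%.2f)", detector.n_modules_, detector.beta_)

        stage = "enrichment"
        background = integrated.genes
        if config.gmt_path is not None:
            collection = read_gmt(config.gmt_path)
        elif truth is not None:
            collection = synthetic_collection(background, truth.de_gene_ids, seed=seeds[2])
            write_gmt(collection, outdir / "synthetic_gene_sets.gmt")
        else:
            collection = None
        if collection is not None and candidates:
            enr = fisher_enrichment(candidates, background, collection)
            enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
                       float_format="%.6g")
            manifest["stages"]["enrichment"] = {
                "n_sets": len(enr),
                "top_set": enr.iloc[0]["set_name"] if len(enr) else None,
                "top_p": float(enr.iloc[0]["p_value"]) if len(enr) else None,
            }
        else:
            manifest["stages"]["enrichment"] = {"skipped": "no gene sets or no candidates"}

        stage = "manifest"
        for path in sorted(outdir.rglob("*")):
            # run.log carries timestamps, so it would defeat checksum comparison
            if path.is_file() and path.name not in ("manifest.json", "run.log"):
                manifest["outputs"][str(path.relative_to(outdir))] = _sha256(path)
        manifest["finished"] = datetime.datetime.now().isoformat(timespec="seconds")
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        (outdir / f"{stage}.partial").write_text(str(exc))
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc


def synthetic_collection(
    background: Sequence[str], planted: set[str], seed: int, n_random_sets: int = 10,
    random_set_size: int = 50,
) -> GeneSetCollection:
    """Synthetic gene-set collection: the planted DE set plus random sets.

    Stands in for a curated collection when none is supplied in simulate
    mode, so the enrichment stage has something meaningful to test: the
    planted set should enrich, the random ones should not.
    """
    rng = np.random.default_rng(seed)
    bg = list(background)
    sets: dict[str, set[str]] = {"PLANTED_DE_SET": set(planted) & set(bg)}
    descriptions = {"PLANTED_DE_SET": "synthetic: genes carrying the planted phenotype effect"}
    for i in range(1, n_random_sets + 1):
        members = set(rng.choice(bg, size=min(random_set_size, len(bg)), replace=False))
        sets[f"RANDOM_SET_{i:02d}"] = members
        descriptions[f"RANDOM_SET_{i:02d}"] = "synthetic: uniformly drawn background genes"
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def _config_echo(config: PipelineConfig) -> dict:
    echo = asdict(config)
    echo["synthetic"] = config_to_dict(config.synthetic)
    echo["methods"] = list(config.methods)
    echo["filter_methods"] = list(config.filter_methods)
    return echo


def _setup_logging(outdir: Path) -> None:
    logger.setLevel(logging.INFO)
    for handler in [h for h in logger.handlers if isinstance(h, logging.FileHandler)]:
        logger.removeHandler(handler)
        handler.close()
    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
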