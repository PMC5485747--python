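"""Synthetic multi-study expression generator with known ground truth.

The generator emulates the statistical structure a cross-study epithelial /
mesenchymal integration has to survive: a two-group phenotype signal in a
known subset of genes, additive per-(gene, study) batch effects, per-study
multiplicative scale and additive location shifts (platform differences),
technical replicate columns, and per-study gene dropout forcing a
common-gene intersection.

Generative model, for gene ``g``, study ``s``, sample ``i``::

    x = scale_s * (mu_g + p_i * delta_g + b_{g,s} + eps) + shift_s

with ``p_i in {0, 1}`` encoding mesenchymal / epithelial, ``delta_g``
nonzero only for differentially expressed genes (so ``delta_g`` is the
epithelial-minus-mesenchymal log2 effect), ``b ~ N(0, batch_sd^2)`` and
``eps ~ N(0, noise_sd^2)``.  Replicate columns copy a parent sample and add
``N(0, replicate_noise_sd^2)`` noise.  Identical seeds give bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from emtint.io import (
    EPITHELIAL,
    MESENCHYMAL,
    DataModelError,
    ExpressionStudy,
    SampleMetadata,
    write_expression_tsv,
    write_metadata_tsv,
)

# Baseline log2 abundance distribution; array-like scale.
_BASELINE_MEAN = 7.0
_BASELINE_SD = 2.0


@dataclass
class SyntheticConfig:
    """Parameters of the multi-study generator.

    Defaults are the study conditions used throughout the test-bed: six
    studies of 4 + 4 samples, 2000 genes of which 10% carry a ~1 log2-unit
    phenotype effect, per-(gene, study) batch noise twice the measurement
    noise, mild platform scale/location differences, 20% technical
    replicates and 5% per-study gene dropout.
    """

    n_genes: int = 2000
    n_studies: int = 6
    samples_per_group_per_study: int = 4
    frac_de: float = 0.10
    effect_size_mean: float = 1.0
    effect_size_sd: float = 0.2
    batch_sd: float = 2.0
    study_scale_range: tuple[float, float] = (0.8, 1.2)
    study_shift_sd: float = 0.5
    noise_sd: float = 1.0
    replicate_fraction: float = 0.2
    replicate_noise_sd: float = 0.1
    gene_dropout_frac: float = 0.05
    seed: int = 7

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_studies < 1 or self.samples_per_group_per_study < 1:
            raise ValueError("n_genes, n_studies and samples_per_group_per_study must be >= 1")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must lie in [0, 1]")
        if self.effect_size_sd < 0 or self.batch_sd < 0 or self.study_shift_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        lo, hi = self.study_scale_range
        if lo <= 0 or hi < lo:
            raise ValueError("study_scale_range must be positive with lower <= upper")
        if not 0.0 <= self.replicate_fraction <= 1.0:
            raise ValueError("replicate_fraction must lie in [0, 1]")
        if self.replicate_noise_sd < 0:
            raise ValueError("replicate_noise_sd must be nonnegative")
        if not 0.0 <= self.gene_dropout_frac < 1.0:
            raise ValueError("gene_dropout_frac must lie in [0, 1)")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery scoring."""

    de_gene_ids: set[str]
    effect_sizes: dict[str, float]
    batch_matrix: pd.DataFrame  # genes x studies, additive b_{g,s}
    study_scales: dict[str, float]
    study_shifts: dict[str, float]

    def __post_init__(self) -> None:
        nonzero = {g for g, d in self.effect_sizes.items() if d != 0.0}
        if nonzero != self.de_gene_ids:
            raise ValueError("effect_sizes keys with nonzero effect must equal de_gene_ids")


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_multistudy(
    config: SyntheticConfig,
) -> tuple[list[ExpressionStudy], SampleMetadata, GroundTruth]:
    """Draw a multi-study dataset plus its ground truth.

    Returns the per-study expression matrices (each with its own retained
    gene subset after dropout), the sample metadata (phenotype, study,
    replicate parentage) and the :class:`GroundTruth` record.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    study_ids = [f"study{s}" for s in range(1, config.n_studies + 1)]

    mu = rng.normal(_BASELINE_MEAN, _BASELINE_SD, size=config.n_genes)

    n_de = int(round(config.frac_de * config.n_genes))
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    delta = np.zeros(config.n_genes)
    if n_de:
        magnitude = np.abs(rng.normal(config.effect_size_mean, config.effect_size_sd, size=n_de))
        sign = rng.choice([-1.0, 1.0], size=n_de)
        delta[de_idx] = sign * magnitude

    batch = rng.normal(0.0, config.batch_sd, size=(config.n_genes, config.n_studies))
    lo, hi = config.study_scale_range
    scales = rng.uniform(lo, hi, size=config.n_studies)
    shifts = rng.normal(0.0, config.study_shift_sd, size=config.n_studies)

    n_drop = int(np.floor(config.gene_dropout_frac * config.n_genes))
    retained: list[np.ndarray] = []
    for _ in study_ids:
        dropped = rng.choice(config.n_genes, size=n_drop, replace=False)
        keep = np.ones(config.n_genes, dtype=bool)
        keep[dropped] = False
        retained.append(keep)
    common = np.logical_and.reduce(retained)
    if not common.any():
        raise DataModelError(
            "gene dropout left an empty intersection across studies "
            + ", ".join(study_ids)
        )

    studies: list[ExpressionStudy] = []
    meta_rows: list[dict] = []
    n_per_group = config.samples_per_group_per_study
    for s, sid in enumerate(study_ids):
        sample_ids: list[str] = []
        phenos: list[str] = []
        p_codes: list[int] = []
        for grp, label, code in ((0, EPITHELIAL, 1), (1, MESENCHYMAL, 0)):
            for i in range(1, n_per_group + 1):
                tag = "E" if label == EPITHELIAL else "M"
                sample_ids.append(f"{sid}_{tag}{i}")
                phenos.append(label)
                p_codes.append(code)
        p = np.asarray(p_codes, dtype=float)
        eps = rng.normal(0.0, config.noise_sd, size=(config.n_genes, len(sample_ids)))
        base = mu[:, None] + delta[:, None] * p[None, :] + batch[:, [s]] + eps
        x = scales[s] * base + shifts[s]

        n_unique = len(sample_ids)
        n_rep = int(round(config.replicate_fraction * n_unique))
        rep_cols: list[np.ndarray] = []
        rep_ids: list[str] = []
        if n_rep:
            parents = rng.choice(n_unique, size=n_rep, replace=n_rep > n_unique)
            for j, parent in enumerate(parents, start=1):
                noise = rng.normal(0.0, config.replicate_noise_sd, size=config.n_genes)
                rep_cols.append(x[:, parent] + noise)
                rep_id = f"{sid}_R{j}"
                rep_ids.append(rep_id)
                meta_rows.append(
                    {
                        "sample_id": rep_id,
                        "study_id": sid,
                        "phenotype": phenos[parent],
                        "replicate_of": sample_ids[parent],
                    }
                )
        for sample_id, pheno in zip(sample_ids, phenos):
            meta_rows.append(
                {
                    "sample_id": sample_id,
                    "study_id": sid,
                    "phenotype": pheno,
                    "replicate_of": np.nan,
                }
            )
        all_cols = np.column_stack([x] + [c[:, None] for c in rep_cols]) if rep_cols else x
        all_ids = sample_ids + rep_ids
        frame = pd.DataFrame(all_cols, index=pd.Index(genes, name="gene_id"), columns=all_ids)
        frame = frame.loc[retained[s]]
        studies.append(
            ExpressionStudy(study_id=sid, platform_id=f"platform{s + 1}", values=frame)
        )

    meta = pd.DataFrame(meta_rows, columns=["sample_id", "study_id", "phenotype", "replicate_of"])
    # keep metadata rows in column order of the generated studies
    order = [c for st in studies for c in st.samples]
    meta = meta.set_index("sample_id").loc[order].reset_index()
    metadata = SampleMetadata(table=meta)

    truth = GroundTruth(
        de_gene_ids={genes[i] for i in de_idx},
        effect_sizes={genes[i]: float(delta[i]) for i in de_idx},
        batch_matrix=pd.DataFrame(batch, index=genes, columns=study_ids),
        study_scales={sid: float(scales[i]) for i, sid in enumerate(study_ids)},
        study_shifts={sid: float(shifts[i]) for i, sid in enumerate(study_ids)},
    )
    return studies, metadata, truth


def truth_recovery_report(
    candidates: Sequence[str], truth: GroundTruth
) -> dict[str, float | int | None]:
    """Precision/recall of a candidate gene list against the planted DE set.

    Precision is reported as ``None`` for an empty candidate list (undefined
    rather than zero), and recall as ``None`` when no genes were planted.
    """
    cand = set(candidates)
    if len(cand) != len(list(candidates)):
        # duplicates collapse; report on the unique set
        pass
    hits = cand & truth.de_gene_ids
    precision = len(hits) / len(cand) if cand else None
    recall = len(hits) / len(truth.de_gene_ids) if truth.de_gene_ids else None
    return {
        "n_candidates": len(cand),
        "n_true": len(truth.de_gene_ids),
        "n_hits": len(hits),
        "precision": precision,
        "recall": recall,
    }


def write_simulation(
    studies: Sequence[ExpressionStudy],
    metadata: SampleMetadata,
    truth: GroundTruth,
    outdir: str | Path,
) -> dict[str, str]:
    """Write per-study expression, metadata and ground-truth TSVs; return paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for study in studies:
        p = outdir / f"expression_{study.study_id}.tsv"
        write_expression_tsv(study.values, p)
        paths[f"expression_{study.study_id}"] = str(p)
    mpath = outdir / "metadata.tsv"
    write_metadata_tsv(metadata, mpath)
    paths["metadata"] = str(mpath)
    tpath = outdir / "ground_truth.tsv"
    rows = [
        {"gene_id": g, "effect_size": truth.effect_sizes[g]}
        for g in sorted(truth.de_gene_ids)
    ]
    pd.DataFrame(rows, columns=["gene_id", "effect_size"]).to_csv(
        tpath, sep="\t", index=False, float_format="%.17g"
    )
    paths["ground_truth"] = str(tpath)
    return paths


def config_to_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["study_scale_range"] = list(d["study_scale_range"])
    return d
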