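"""End-to-end orchestration: derive -> score -> correlate -> associate ->
survive, from a single validated config, with provenance logging.

Every stage writes plain TSV/GMT outputs into the output directory plus a
``provenance.json`` carrying the config hash, package version and per-stage
counters, so two runs with identical config and inputs are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .enrichment import default_universe, fisher_enrichment, overlap_network, write_network
from .io import (
    CohortClinical,
    GeneSet,
    GeneSetCollection,
    read_annotations,
    read_clinical_table,
    read_expression_table,
    read_gene_sets,
    write_gene_sets,
)
from .signatures import build_core_signature, derive_signature
from .ssgsea import score_collection
from .stats import associate_feature, correlate_scores
from .survival import cox_fit, dichotomize, km_logrank, survival_frame

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Pipeline configuration failed validation."""


@dataclass
class PipelineConfig:
    """Validated configuration for :func:`run_pipeline`.

    Paths are resolved relative to the config file location when loaded via
    :meth:`from_yaml`.
    """

    sorted_expression: str | None = None
    sorted_annotations: str | None = None
    cohort_expression: str | None = None
    cohort_clinical: str | None = None
    gene_sets: str | None = None           # GMT scored alongside the derived pair
    enrichment_collection: str | None = None  # GMT for the enrichment map
    extra_stemness_sets: list[str] = field(default_factory=list)  # for the core signature

    status_key: str = "cd133_status"
    cell_line_key: str = "cell_line"
    up_threshold: float = 1.0
    down_threshold: float = -1.0
    require_sign_consistency: bool = True
    signature_name: str = "CD133"

    alpha: float = 0.25
    normalize: str = "none"

    enrichment_p: float = 0.01
    edge_p: float = 1e-10
    core_min_count: int = 2

    association_features: list[str] = field(default_factory=list)
    survival_split: str = "median"
    survival_covariates: list[str] = field(default_factory=list)

    seed: int = 0

    def validate(self) -> None:
        if not self.up_threshold > self.down_threshold:
            raise ConfigError(
                f"up_threshold ({self.up_threshold}) must exceed "
                f"down_threshold ({self.down_threshold})"
            )
        if self.alpha < 0:
            raise ConfigError("alpha must be >= 0")
        if not 0 < self.enrichment_p <= 1 or not 0 < self.edge_p <= 1:
            raise ConfigError("p thresholds must lie in (0, 1]")
        if self.normalize not in ("none", "minmax"):
            raise ConfigError(f"unknown normalization {self.normalize!r}")
        if self.core_min_count < 2:
            raise ConfigError("core_min_count must be >= 2")
        if self.survival_split not in ("median", "quantile"):
            raise ConfigError(f"unknown survival split {self.survival_split!r}")
        for label, p in [
            ("sorted_expression", self.sorted_expression),
            ("sorted_annotations", self.sorted_annotations),
            ("cohort_expression", self.cohort_expression),
            ("cohort_clinical", self.cohort_clinical),
            ("gene_sets", self.gene_sets),
            ("enrichment_collection", self.enrichment_collection),
            *[(f"extra_stemness_sets[{i}]", p) for i, p in enumerate(self.extra_stemness_sets)],
        ]:
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{label}: path does not exist: {p}")
        if self.sorted_expression is None:
            raise ConfigError("sorted_expression is required (signature derivation input)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        # resolve paths relative to the config file
        base = path.parent
        for f in (
            "sorted_expression", "sorted_annotations", "cohort_expression",
            "cohort_clinical", "gene_sets", "enrichment_collection",
        ):
            v = getattr(cfg, f)
            if v is not None and not Path(v).is_absolute():
                setattr(cfg, f, str(base / v))
        cfg.extra_stemness_sets = [
            str(base / p) if not Path(p).is_absolute() else p
            for p in cfg.extra_stemness_sets
        ]
        cfg.validate()
        return cfg

    def content_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict[str, Any]:
    """Run every configured stage; returns the provenance record.

    A stage error aborts the run with the stage name; outputs of completed
    stages are preserved in ``out_dir``.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance: dict[str, Any] = {
        "version": __version__,
        "config_hash": config.content_hash(),
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    stage = "derive"
    try:
        matrix = read_expression_table(config.sorted_expression)
        if config.sorted_annotations:
            ann = read_annotations(config.sorted_annotations)
            matrix.annotations = ann.loc[matrix.sample_ids]
        pair = derive_signature(
            matrix,
            status_key=config.status_key,
            cell_line_key=config.cell_line_key,
            up_threshold=config.up_threshold,
            down_threshold=config.down_threshold,
            require_sign_consistency=config.require_sign_consistency,
            name=config.signature_name,
        )
        sig_sets = [
            GeneSet(f"{pair.name}-up", pair.provenance, tuple(pair.up_genes)),
            GeneSet(f"{pair.name}-down", pair.provenance, tuple(pair.down_genes)),
        ]
        write_gene_sets(GeneSetCollection(sig_sets), out / "signature.gmt")
        provenance["stages"][stage] = {
            "genes_in": matrix.n_genes,
            "up_genes": len(pair.up_genes),
            "down_genes": len(pair.down_genes),
        }

        if config.extra_stemness_sets:
            stage = "core_signature"
            lists = [list(pair.up_genes)]
            for p in config.extra_stemness_sets:
                for s in read_gene_sets(p):
                    lists.append(list(s.genes))
            core = build_core_signature(lists, min_count=config.core_min_count)
            write_gene_sets(
                GeneSetCollection([GeneSet("core-stemness", "reduced signature", tuple(core))]),
                out / "core_signature.gmt",
            )
            sig_sets.append(GeneSet("core-stemness", "", tuple(core)))
            provenance["stages"][stage] = {"lists_in": len(lists), "core_genes": len(core)}

        if config.enrichment_collection:
            stage = "enrichment_map"
            coll = read_gene_sets(config.enrichment_collection)
            universe = default_universe(matrix, coll)
            for direction, genes in (("up", pair.up_genes), ("down", pair.down_genes)):
                glist = [g for g in genes if g in set(universe)]
                if not glist:
                    continue
                enriched = fisher_enrichment(glist, coll, universe, config.enrichment_p)
                enriched.to_csv(out / f"enrichment_{direction}.tsv", sep="\t", index=False)
                if len(enriched):
                    G = overlap_network(enriched, coll, universe, config.edge_p)
                    write_network(G, out / f"map_{direction}")
                provenance["stages"].setdefault(stage, {})[direction] = {
                    "enriched_sets": int(len(enriched)),
                }

        if config.cohort_expression:
            stage = "score"
            cohort = read_expression_table(config.cohort_expression)
            to_score = list(sig_sets)
            if config.gene_sets:
                to_score += list(read_gene_sets(config.gene_sets))
            scores = score_collection(
                cohort,
                GeneSetCollection(to_score),
                alpha=config.alpha,
                normalize=config.normalize,
            )
            scores.scores.to_csv(out / "scores.tsv", sep="\t", index_label="signature")
            provenance["stages"][stage] = {
                "signatures": len(scores.signature_names),
                "samples": len(scores.sample_ids),
            }

            if len(scores.signature_names) >= 2 and len(scores.sample_ids) >= 3:
                stage = "correlate"
                corr, _ = correlate_scores(scores)
                corr.to_csv(out / "correlation.tsv", sep="\t", index_label="signature")
                provenance["stages"][stage] = {"signatures": len(corr)}

            if config.cohort_clinical:
                clinical = read_clinical_table(config.cohort_clinical)
                key_score = scores.row(f"{pair.name}-up")
                if config.association_features:
                    stage = "associate"
                    rows = []
                    for feat in config.association_features:
                        res = associate_feature(key_score, clinical, feat)
                        rows.append(
                            {
                                "feature": res.feature_name,
                                "test": res.test_name,
                                "statistic": res.statistic,
                                "p_value": res.p_value,
                                "n": res.n,
                                "n_missing": res.n_missing,
                            }
                        )
                    pd.DataFrame(rows).to_csv(out / "associations.tsv", sep="\t", index=False)
                    provenance["stages"][stage] = {"features": len(rows)}

                if clinical.time_col and clinical.event_col:
                    stage = "survival"
                    records = survival_frame(clinical)
                    rows = []
                    for sig in (config.survival_covariates or [f"{pair.name}-up"]):
                        groups, cutoff = dichotomize(
                            scores.row(sig).reindex(records.index).dropna(),
                            rule=config.survival_split,
                        )
                        km = km_logrank(records, groups)
                        rows.append(
                            {
                                "signature": sig, "analysis": "km_logrank",
                                "cutoff": cutoff, "statistic": km.statistic,
                                "p_value": km.p_value,
                            }
                        )
                    if len(config.survival_covariates) >= 2:
                        df = records.copy()
                        for sig in config.survival_covariates:
                            df[sig] = scores.row(sig).reindex(df.index)
                        fit = cox_fit(df.dropna(), config.survival_covariates)
                        for cov in config.survival_covariates:
                            rows.append(
                                {
                                    "signature": cov, "analysis": "multivariate_cox",
                                    "cutoff": float("nan"),
                                    "statistic": fit.coef(cov),
                                    "p_value": fit.p(cov),
                                }
                            )
                    pd.DataFrame(rows).to_csv(out / "survival_report.tsv", sep="\t", index=False)
                    provenance["stages"][stage] = {"analyses": len(rows)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return provenance
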