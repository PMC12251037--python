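"""One-command orchestration of the full analysis.

Runs (optional) simulation -> stratification -> LINE-1 -> clock -> variants
-> burden association, writing every stage's TSV outputs plus a
consolidated, deterministic ``report.json``. A plain-text ``run.log``
records one ISO-timestamped line per event (timestamps live only in the
log, so the report itself is byte-identical across reruns with one seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import clock as clk
from . import line1 as l1
from . import stratification as strat
from . import synthetic as syn
from . import variants as var


@dataclass
class PipelineConfig:
    """Paths, thresholds and hyperparameters for one pipeline run."""

    outdir: str = "results"
    seed: int = 0
    alpha: float = 0.05
    simulate: bool = True
    sim_overrides: dict = field(default_factory=dict)
    # input paths; filled automatically when simulate is on
    cohort: str | None = None
    line1: str | None = None
    beta_before: str | None = None
    beta_after: str | None = None
    beta_train: str | None = None
    train_ages: str | None = None
    whitelist: str | None = None
    variants: str | None = None
    annotation: str | None = None
    panel: str | None = None
    pathways: str | None = None
    # hotspot thresholds (percent)
    node_threshold: float = 50.0
    highlight_in: float = 70.0
    highlight_out: float = 50.0
    # clock hyperparameters
    l1_ratio: float = 0.5
    cv: int = 10

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate_thresholds(self) -> None:
        for name in ("node_threshold", "highlight_in", "highlight_out"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be a percentage in [0, 100]")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""


def _read_beta(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="cpg_id")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 6)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


class _Logger:
    def __init__(self, path):
        self._fh = open(path, "a")

    def __call__(self, msg: str) -> None:
        stamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
        self._fh.write(f"{stamp}\t{msg}\n")
        self._fh.flush()

    def close(self):
        self._fh.close()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the consolidated cohort report."""
    config.validate_thresholds()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Logger(out / "run.log")
    report: dict = {"seed": config.seed, "alpha": config.alpha}
    try:
        # ---- stage: simulate -------------------------------------------
        if config.simulate:
            try:
                sim_cfg = syn.SimConfig(seed=config.seed, **config.sim_overrides)
                dataset = syn.generate_cohort(sim_cfg)
                paths = dataset.write(out / "data")
            except Exception as exc:
                raise StageError(f"stage simulate failed: {exc}") from exc
            for key, path in paths.items():
                setattr(config, key, path)
            log(f"simulate: wrote {len(paths)} input files under {out / 'data'}")

        # ---- stage: stratify -------------------------------------------
        try:
            cohort = pd.read_csv(config.cohort, sep="\t")
            labels = strat.label_cohort(cohort)
            biomarkers = strat.biomarker_report(cohort, labels, alpha=config.alpha)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage stratify failed on {config.cohort}: {exc}") from exc
        labels.to_csv(out / "stratification.tsv", sep="\t", index=False, float_format="%.6f")
        biomarkers.to_csv(out / "group_summary.tsv", sep="\t", index=False, float_format="%.6f")
        sizes = labels["label"].value_counts().to_dict()
        report["group_sizes"] = {
            "n_patients": int(len(labels)),
            "n_responders": int(sizes.get(strat.RESPONDER, 0)),
            "n_nonresponders": int(sizes.get(strat.NON_RESPONDER, 0)),
        }
        report["biomarkers"] = biomarkers.to_dict(orient="records")
        log(f"stratify: {len(labels)} patients labeled "
            f"({report['group_sizes']['n_responders']} responders)")

        # ---- stage: line1 ----------------------------------------------
        try:
            line1_df = pd.read_csv(config.line1, sep="\t")
            line1_report = l1.line1_change_analysis(
                line1_df, labels, cohort, alpha=config.alpha
            )
            l1.table1(line1_df, alpha=config.alpha).to_csv(
                out / "line1_table.tsv", sep="\t", index=False, float_format="%.6f"
            )
            l1.relative_change_table(line1_df).to_csv(
                out / "line1_relative_change.tsv", sep="\t", index=False, float_format="%.6f"
            )
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage line1 failed on {config.line1}: {exc}") from exc
        report["line1"] = line1_report
        log(f"line1: analyzed {len(line1_df)} profile rows")

        # ---- stage: clock ----------------------------------------------
        try:
            beta_train = _read_beta(config.beta_train)
            train_ages = pd.read_csv(config.train_ages, sep="\t", index_col="sample_id")[
                "age_years"
            ]
            whitelist = [
                w for w in Path(config.whitelist).read_text().splitlines() if w
            ]
            model = clk.train_filtered_clock(
                beta_train, train_ages.loc[beta_train.columns],
                whitelist, l1_ratio=config.l1_ratio, cv=config.cv, seed=config.seed,
            )
            clk.write_model(model, out / "clock_model.tsv")
            beta_before = _read_beta(config.beta_before)
            beta_after = _read_beta(config.beta_after)
            deltas, delta_summary = clk.cohort_age_deltas(
                model, beta_before, beta_after, labels, alpha=config.alpha
            )
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage clock failed on {config.beta_train}: {exc}") from exc
        delta_frame = pd.DataFrame(
            {
                "patient_id": [d.patient_id for d in deltas],
                "bioage_before": [d.bioage_before for d in deltas],
                "bioage_after": [d.bioage_after for d in deltas],
                "delta": [d.delta for d in deltas],
            }
        )
        delta_frame.to_csv(out / "age_deltas.tsv", sep="\t", index=False, float_format="%.6f")
        delta_summary.to_csv(out / "age_delta_summary.tsv", sep="\t", index=False, float_format="%.6f")
        report["clock"] = {
            "nonzero_count": model.nonzero_count,
            "summary": delta_summary.to_dict(orient="records"),
        }
        log(f"clock: trained ({model.nonzero_count} nonzero CpGs), "
            f"{len(deltas)} patients predicted")

        # ---- stage: variants -------------------------------------------
        try:
            records = var.read_variants(config.variants)
            panel = var.read_panel(config.panel)
            on_panel = var.restrict_to_panel(records, panel)
            db = var.read_annotation(config.annotation)
            classified, unclassified = var.classify_by_annotation(on_panel, db)
            pathway_df = pd.read_csv(config.pathways, sep="\t")
            pathway_map: dict[str, list[str]] = {}
            for row in pathway_df.itertuples():
                pathway_map.setdefault(row.gene, []).append(row.pathway)
            freqs = var.compute_frequencies(on_panel, labels, pathway_map)
            hotspots = var.call_hotspots(
                freqs, config.node_threshold, config.highlight_in, config.highlight_out
            )
            graph = var.build_pathway_graph(hotspots, pathway_map)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage variants failed on {config.variants}: {exc}") from exc
        var.write_variants(classified, out / "variants_classified.tsv")
        var.write_variants(unclassified, out / "variants_unclassified.tsv")
        hs_frame = var.hotspots_frame(hotspots)
        hs_frame.to_csv(out / "hotspots.tsv", sep="\t", index=False, float_format="%.2f")
        var.write_graphml(graph, out / "pathway_graph.graphml")
        var.write_dot(graph, out / "pathway_graph.dot")
        label_map = dict(zip(labels["patient_id"], labels["label"]))
        for group in (strat.RESPONDER, strat.NON_RESPONDER):
            group_vars = [v for v in on_panel if label_map.get(v.patient_id) == group]
            if group_vars:
                summary = var.summarize_mutations(group_vars)
                summary.oncomatrix.to_csv(
                    out / f"oncomatrix_{group}.tsv", sep="\t", index_label="gene"
                )
                report.setdefault("mutations", {})[group] = {
                    "n_variants": len(group_vars),
                    "classification_counts": summary.classification_counts,
                    "type_counts": summary.type_counts,
                    "snv_class_counts": summary.snv_class_counts,
                    "top_genes": summary.top_genes,
                }
        highlighted = hs_frame[hs_frame["is_highlighted"]]
        report["hotspots"] = {
            "n_on_panel_variants": len(on_panel),
            "n_classified": len(classified),
            "n_unclassified": len(unclassified),
            "n_graph_nodes": int(hs_frame["is_graph_node"].sum()),
            "n_highlighted": int(len(highlighted)),
            "highlighted": highlighted.to_dict(orient="records"),
        }
        log(f"variants: {len(on_panel)} on-panel, {len(classified)} classified, "
            f"{len(highlighted)} highlighted hotspots")

        # ---- stage: associate ------------------------------------------
        try:
            panel_genes = sorted({r.gene for r in panel})
            burden = assoc.burden_matrix(
                on_panel, panel_genes, list(delta_frame["patient_id"])
            )
            results = {}
            for group in (strat.RESPONDER, strat.NON_RESPONDER):
                res = assoc.associate(
                    burden, delta_frame, labels, group=group, adjust=True
                )
                res.to_csv(
                    out / f"association_{group}.tsv", sep="\t", index=False,
                    float_format="%.6f",
                )
                results[group] = res
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage associate failed: {exc}") from exc
        nonresp = results[strat.NON_RESPONDER]
        tested = nonresp[~nonresp["skipped"]]
        top = tested.loc[tested["p_value"].idxmin()] if not tested.empty else None
        report["association"] = {
            "n_genes_tested": int(len(tested)),
            "top_gene": None
            if top is None
            else {
                "gene": top["gene"],
                "spearman_r": float(top["spearman_r"]),
                "p_value": float(top["p_value"]),
                "intercept": float(top["intercept"]),
                "slope": float(top["slope"]),
                "n": int(top["n"]),
            },
        }
        log(f"associate: {len(tested)} genes tested in the non-responder group")

        # ---- report ----------------------------------------------------
        report = _jsonable(report)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        log("report: wrote report.json")
        return report
    finally:
        log.close()
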