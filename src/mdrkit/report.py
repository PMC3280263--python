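"""Pipeline orchestration and report rendering.

Runs QC -> exhaustive MDR search over orders -> model selection ->
significance validation -> entropy-based synergy analysis, and renders the
result tables: a per-order summary (best model per order), ranked top-N
lists per order, a significance table for the selected model, a pairwise
interaction-information matrix, and the selected model's risk grid.
Accuracies are printed as percentages with two decimals.

All artifacts are plain text (TSV/JSON) and contain no timestamps, so a
rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import crossval, dataset, mdr, significance
from .entropy import edge_list


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Every analysis decision surfaced as an explicit key."""

    input_path: str | None = None  # None -> simulate the study emulator
    attributes: list[str] | None = None  # None -> all attributes
    max_order: int = 3
    n_folds: int = 10
    n_permutations: int = 1000
    n_explicit: int = 1000
    seed: int = 0
    empty_cell_policy: str = "low"
    tie_rule: str = "strict"
    top_n: int = 10
    min_call_rate: float = 0.98
    statistic: str = "test_ba"
    output_dir: str = "mdr_output"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=True))


@dataclass
class RunReport:
    qc: dict
    order_summaries: list[crossval.OrderSummary]
    selection: crossval.CrossOrderSummary
    significance_rows: list[dict]
    entropy_edges: list[tuple[str, str, float]]
    risk_grid: dict
    seed_registry: dict = field(default_factory=dict)


def _pct(x: float) -> str:
    return f"{100.0 * x:.2f}"


def render_order_summary_tsv(
    per_order: list[crossval.ModelEvaluation], n_folds: int
) -> str:
    """Summary table: the best model of each order (one row per order)."""
    lines = [
        "Model\tTraining Bal. Acc. (%)\tTesting Bal. Acc. (%)\tCross-validation Consistency"
    ]
    for ev in per_order:
        lines.append(
            f"{ev.label()}\t{_pct(ev.train_ba)}\t{_pct(ev.test_ba)}\t{ev.cvc}/{n_folds}"
        )
    return "\n".join(lines) + "\n"


def parse_order_summary_tsv(text: str) -> list[dict]:
    """Inverse of :func:`render_order_summary_tsv` (round-trip exact at the
    printed precision)."""
    rows = []
    for line in text.strip().splitlines()[1:]:
        model, tr, te, cvc = line.split("\t")
        c, f = cvc.split("/")
        rows.append(
            {
                "model": tuple(model.split(", ")),
                "train_ba_pct": float(tr),
                "test_ba_pct": float(te),
                "cvc": int(c),
                "n_folds": int(f),
            }
        )
    return rows


def render_ranked_tsv(ranked: list[crossval.ModelEvaluation]) -> str:
    lines = ["Rank\tModel\tTraining Bal. Acc. (%)\tTesting Bal. Acc. (%)"]
    for r, ev in enumerate(ranked, start=1):
        lines.append(f"{r}\t{ev.label()}\t{_pct(ev.train_ba)}\t{_pct(ev.test_ba)}")
    return "\n".join(lines) + "\n"


def render_significance_tsv(rows: list[dict]) -> str:
    cols = [
        "Model",
        "Observed statistic",
        "Permutation P",
        "Explicit P",
        "LRT P",
        "Chi-square P",
    ]
    lines = ["\t".join(cols)]
    for row in rows:
        lines.append(
            "\t".join(
                [
                    row["model"],
                    f"{row['observed']:.4f}",
                    f"{row['permutation_p']:.4g}",
                    f"{row['explicit_p']:.4g}",
                    f"{row['lrt_p']:.4g}" if row["lrt_p"] is not None else "NA",
                    f"{row['chi_square_p']:.4g}",
                ]
            )
        )
    return "\n".join(lines) + "\n"


def render_entropy_tsv(edges: list[tuple[str, str, float]]) -> str:
    lines = ["Attribute A\tAttribute B\tInteraction information (bits)"]
    for a, b, w in edges:
        lines.append(f"{a}\t{b}\t{w:.6f}")
    return "\n".join(lines) + "\n"


def render_risk_grid(
    model: mdr.RiskModel, ds: dataset.CaseControlDataset
) -> tuple[dict, str]:
    """Per-cell case/control counts and high/low shading for the fitted
    model, in lexicographic cell order (the k-way genotype grid).

    Returns a JSON-serialisable document and a plain-text rendering.
    """
    names = [ds.specs[a].name for a in model.combination.attribute_indices]
    level_labels = [ds.specs[a].levels for a in model.combination.attribute_indices]
    cells = []
    for key in sorted(model.labels):
        case, ctrl = model.cells.get(key, (0, 0))
        cells.append(
            {
                "levels": {n: level_labels[i][v] for i, (n, v) in enumerate(zip(names, key))},
                "cases": case,
                "controls": ctrl,
                "label": model.labels[key],
                "empty_in_training": key not in model.cells,
            }
        )
    doc = {
        "attributes": names,
        "threshold": {
            "cases": model.threshold[0],
            "controls": model.threshold[1],
            "ratio": model.threshold_ratio,
        },
        "tie_rule": model.tie_rule,
        "empty_cell_policy": model.empty_cell_policy,
        "n_cells": len(cells),
        "cells": cells,
    }
    width = max(len(" ".join(f"{n}={c['levels'][n]}" for n in names)) for c in cells)
    text_lines = []
    for c in cells:
        lab = c["label"].upper()
        if c["empty_in_training"]:
            lab += f" (empty; policy={model.empty_cell_policy})"
        key = " ".join(f"{n}={c['levels'][n]}" for n in names)
        text_lines.append(
            f"{key:<{width}}  cases={c['cases']:<5d} controls={c['controls']:<5d} {lab}"
        )
    return doc, "\n".join(text_lines) + "\n"


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name}: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis and write all artifacts to the output dir."""
    from . import simulate

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    # deterministic per-stage sub-seeds derived from the master seed
    ss = np.random.SeedSequence(config.seed)
    sub = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(
            ("simulate", "folds", "permutation", "explicit"), ss.spawn(4)
        )
    }
    registry = {"master_seed": config.seed, **sub}

    @_stage("input")
    def load():
        if config.input_path is None:
            return simulate.study_emulator(seed=sub["simulate"])
        return dataset.read_dataset(config.input_path)

    ds = load()

    @_stage("qc")
    def qc(ds):
        cols = (
            [ds.column(n) for n in config.attributes]
            if config.attributes is not None
            else None
        )
        if cols is not None:
            ds = ds.select_attributes(cols)
        clean, rep = dataset.run_qc(ds, config.min_call_rate)
        dataset.write_qc_json(rep, out / "qc.json")
        return clean, rep

    clean, qc_report = qc(ds)

    @_stage("search")
    def search(clean):
        folds = crossval.make_folds(clean, config.n_folds, seed=sub["folds"])
        summaries = []
        for k in range(1, config.max_order + 1):
            s = crossval.evaluate_order(
                clean, k, folds, config.top_n, config.tie_rule, config.empty_cell_policy
            )
            summaries.append(s)
            (out / f"ranked_order{k}.tsv").write_text(render_ranked_tsv(s.top_n))
        selection = crossval.summary_across_orders(summaries)
        (out / "summary.tsv").write_text(
            render_order_summary_tsv(selection.per_order, config.n_folds)
        )
        return summaries, selection

    summaries, selection = search(clean)
    chosen = selection.selected
    combo = chosen.combination

    @_stage("significance")
    def validate(clean):
        perm = significance.permutation_test(
            clean, combo, config.n_permutations, config.statistic,
            seed=sub["permutation"], n_folds=config.n_folds,
            tie_rule=config.tie_rule, empty_cell_policy=config.empty_cell_policy,
        )
        expl = significance.explicit_test(
            clean, combo, config.n_explicit, config.statistic,
            seed=sub["explicit"], n_folds=config.n_folds,
            tie_rule=config.tie_rule, empty_cell_policy=config.empty_cell_policy,
        )
        lrt_p = None
        if combo.order >= 2:
            lrt = significance.lrt_interaction(clean, combo)
            lrt_p = lrt.p if lrt.converged else None
        fitted = mdr.fit_risk_model(
            clean, combo, tie_rule=config.tie_rule,
            empty_cell_policy=config.empty_cell_policy,
        )
        chi2, chi2_p, _ = significance.chi_square_high_low(clean, fitted)
        rows = [
            {
                "model": chosen.label(),
                "observed": perm.observed,
                "permutation_p": perm.p,
                "explicit_p": expl.p,
                "lrt_p": lrt_p,
                "chi_square": chi2,
                "chi_square_p": chi2_p,
            }
        ]
        (out / "significance.tsv").write_text(render_significance_tsv(rows))
        return rows, fitted

    sig_rows, fitted = validate(clean)

    @_stage("entropy")
    def synergy(clean):
        edges = edge_list(clean)
        (out / "entropy_edges.tsv").write_text(render_entropy_tsv(edges))
        return edges

    edges = synergy(clean)

    @_stage("report")
    def render(clean):
        doc, text = render_risk_grid(fitted, clean)
        (out / "risk_grid.json").write_text(json.dumps(doc, indent=2) + "\n")
        (out / "risk_grid.txt").write_text(text)
        (out / "run_log.json").write_text(
            json.dumps(
                {"config": config.__dict__, "seeds": registry}, indent=2, sort_keys=True
            )
            + "\n"
        )
        return doc

    grid_doc = render(clean)
    return RunReport(qc_report, summaries, selection, sig_rows, edges, grid_doc, registry)
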