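"""End-to-end orchestration: simulate/load -> screen -> summarize -> treemap.

A pipeline run is driven by a YAML-friendly config dict and writes a
deterministic artifact bundle into an output directory:

``results.csv``
    one row per screened (drug, PT) pair with cells, PRR, ROR, IC, IC025
    and the signal flag;
``soc_summary.csv``
    signals and reports per primary SOC (treemap input);
``demographics.csv``
    per-field category counts/percentages for the lead target drug's
    reports, overall and restricted to the subset SOC;
``subset_shares.csv``
    report shares of the signal PTs inside the subset SOC;
``treemap.svg``
    the squarified treemap (area = signals, color = log10 reports);
``truth_eval.csv``
    planted-pair sensitivity and null false-flag rate (simulation only).

Every stage logs its counts; any stage failure aborts with a
stage-labeled :class:`PipelineError`.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from .contingency import ContingencyTable
from .disproportionality import (
    DisproportionalityResult,
    SignalCriteria,
    results_frame,
    screen,
)
from .hierarchy import demographics_summary, rollup_by_soc, subset_shares
from .model import (
    Dataset,
    MedDRADictionary,
    read_icsr_table,
    read_meddra_dictionary,
    toy_dictionary,
    write_icsr_table,
)
from .synth import GroundTruth, SyntheticConfig, default_config, generate
from .treemap import render_svg, treemap_layout

__all__ = ["PipelineError", "criteria_from_dict", "read_results", "run_pipeline"]

log = logging.getLogger("pvsignal")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def criteria_from_dict(d: Mapping | None) -> SignalCriteria:
    d = dict(d or {})
    return SignalCriteria(
        min_reports=int(d.get("min_reports", 3)),
        prr_min=float(d.get("prr_min", 2.0)),
        ror_min=float(d.get("ror_min", 2.0)),
        ic025_min=float(d.get("ic025_min", 0.0)),
        ic025_strict=bool(d.get("ic025_strict", True)),
    )


def read_results(path: str | Path) -> list[DisproportionalityResult]:
    """Load a ``results.csv`` written by :func:`run_pipeline` or the CLI."""
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        t = ContingencyTable(int(row.a), int(row.b), int(row.c), int(row.d))
        out.append(
            DisproportionalityResult(
                drug=row.drug,
                event_pt=row.event_pt,
                table=t,
                prr=None if pd.isna(row.prr) else float(row.prr),
                ror=None if pd.isna(row.ror) else float(row.ror),
                ic=float(row.ic),
                ic025=float(row.ic025),
                is_signal=bool(row.is_signal),
            )
        )
    return out


def _synthetic_config(block: Mapping, seed: int | None) -> SyntheticConfig:
    """Build a SyntheticConfig from a config block, honoring a seed override."""
    block = dict(block)
    if seed is not None:
        block["seed"] = seed
    if block.get("preset") == "asthma-biologics" or "drug_catalog" not in block:
        cfg = default_config(
            n_reports=int(block.get("n_reports", 50_000)),
            seed=int(block.get("seed", 0)),
        )
        return cfg
    return SyntheticConfig.from_dict(block)


def _load_stage(config: Mapping, seed: int | None) -> tuple[Dataset, GroundTruth | None]:
    if "simulate" in config:
        cfg = _synthetic_config(config["simulate"], seed)
        dataset, truth = generate(cfg)
        log.info("simulate: generated %d reports (seed=%d)", len(dataset), cfg.seed)
        return dataset, truth
    if "input" not in config:
        raise ValueError("config needs a 'simulate' or 'input' block")
    block = config["input"]
    icsr_path = Path(block["icsr"])
    if not icsr_path.exists():
        raise FileNotFoundError(f"ICSR file not found: {icsr_path}")
    if "dictionary" in block:
        dict_path = Path(block["dictionary"])
        if not dict_path.exists():
            raise FileNotFoundError(f"dictionary file not found: {dict_path}")
        dictionary = read_meddra_dictionary(dict_path)
    else:
        dictionary = toy_dictionary()
    dataset = read_icsr_table(icsr_path, dictionary=dictionary,
                              lenient=bool(block.get("lenient", False)))
    log.info("load: read %d reports from %s", len(dataset), icsr_path)
    return dataset, None


def _truth_eval(
    results: list[DisproportionalityResult], truth: GroundTruth
) -> pd.DataFrame:
    flagged = {(r.drug, r.event_pt) for r in results if r.is_signal}
    evaluated = {(r.drug, r.event_pt) for r in results if r.table.a >= 3}
    drugs_screened = {r.drug for r in results}
    planted = {p for p in truth.planted_pairs if p[0] in drugs_screened}
    nulls = {p for p in truth.null_pairs if p[0] in drugs_screened} & evaluated
    n_planted_hit = len(planted & flagged)
    n_null_hit = len(nulls & flagged)
    rows = [
        ("n_planted_pairs", len(planted)),
        ("n_planted_flagged", n_planted_hit),
        ("sensitivity", n_planted_hit / len(planted) if planted else float("nan")),
        ("n_null_pairs_evaluated", len(nulls)),
        ("n_null_flagged", n_null_hit),
        ("false_flag_rate", n_null_hit / len(nulls) if nulls else float("nan")),
    ]
    return pd.DataFrame(rows, columns=["metric", "value"])


def run_pipeline(
    config: Mapping,
    outdir: str | Path,
    *,
    seed: int | None = None,
) -> dict[str, Path]:
    """Run the full pipeline and return the paths of the written artifacts.

    ``seed`` overrides the config's simulation seed; with a fixed seed the
    whole bundle is byte-reproducible.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:
                raise PipelineError(f"[{name}] {e}") from e
        return wrap

    dataset, truth = stage("load")(_load_stage, config, seed)
    if "simulate" in config:
        icsr_out = outdir / "icsr.csv"
        stage("load")(write_icsr_table, dataset, icsr_out)
        artifacts["icsr"] = icsr_out

    criteria = criteria_from_dict(config.get("criteria"))
    targets = list(config.get("targets") or dataset.drugs)
    results = stage("screen")(screen, dataset, targets, criteria)
    n_signals = sum(r.is_signal for r in results)
    log.info(
        "screen: %d pairs screened for %d target drug(s); %d signals",
        len(results), len(targets), n_signals,
    )
    res_path = outdir / "results.csv"
    results_frame(results).to_csv(res_path, index=False, lineterminator="\n")
    artifacts["results"] = res_path

    rollup = stage("summarize")(rollup_by_soc, results, dataset.dictionary)
    if rollup.unmapped:
        log.warning("summarize: %d signal PT(s) unmapped: %s",
                    len(rollup.unmapped), sorted(rollup.unmapped))
    soc_path = outdir / "soc_summary.csv"
    rollup.to_frame().to_csv(soc_path, index=False, lineterminator="\n")
    artifacts["soc_summary"] = soc_path
    log.info("summarize: %d SOC(s) with signals", len(rollup.summaries))

    lead_drug = targets[0]
    subset_soc = config.get("subset_soc", "Ear and labyrinth disorders")

    def in_subset(r):
        return any(
            pt in dataset.dictionary
            and dataset.dictionary.primary_soc(pt) == subset_soc
            for pt in r.events
        )

    demo_frames = []
    overall = demographics_summary(dataset, lambda r: lead_drug in r.drugs)
    df = overall.to_frame()
    df.insert(0, "scope", f"{lead_drug}: all reports")
    demo_frames.append(df)
    sub = demographics_summary(
        dataset, lambda r: lead_drug in r.drugs and in_subset(r)
    )
    df = sub.to_frame()
    df.insert(0, "scope", f"{lead_drug}: {subset_soc}")
    demo_frames.append(df)
    demo_path = outdir / "demographics.csv"
    pd.concat(demo_frames).to_csv(demo_path, index=False, lineterminator="\n")
    artifacts["demographics"] = demo_path

    subset_results = [
        r for r in results
        if r.drug == lead_drug and r.is_signal
        and r.event_pt in dataset.dictionary
        and dataset.dictionary.primary_soc(r.event_pt) == subset_soc
    ]
    if subset_results:
        rows = subset_shares(subset_results)
        by_pt = {r.event_pt: r for r in subset_results}
        share_df = pd.DataFrame(
            [
                {
                    "event_pt": row.event_pt,
                    "n_reports": row.n_reports,
                    "share_pct": row.share_pct,
                    "prr": by_pt[row.event_pt].prr,
                    "ror": by_pt[row.event_pt].ror,
                    "ic025": by_pt[row.event_pt].ic025,
                }
                for row in rows
            ]
        )
        share_path = outdir / "subset_shares.csv"
        share_df.to_csv(share_path, index=False, lineterminator="\n")
        artifacts["subset_shares"] = share_path
        log.info("summarize: %d signal PT(s) in subset SOC %r", len(rows), subset_soc)
    else:
        log.info("summarize: no signals in subset SOC %r; shares skipped", subset_soc)

    if rollup.summaries:
        rects = stage("treemap")(treemap_layout, rollup.summaries)
        svg_path = outdir / "treemap.svg"
        stage("treemap")(render_svg, rects, str(svg_path))
        artifacts["treemap"] = svg_path
    else:
        log.info("treemap: no signals; skipped")

    if truth is not None:
        eval_df = _truth_eval(results, truth)
        truth_path = outdir / "truth_eval.csv"
        eval_df.to_csv(truth_path, index=False, lineterminator="\n")
        artifacts["truth_eval"] = truth_path
        log.info(
            "truth_eval: sensitivity=%.3f false_flag_rate=%.3f",
            eval_df.set_index("metric").loc["sensitivity", "value"],
            eval_df.set_index("metric").loc["false_flag_rate", "value"],
        )
    return artifacts
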