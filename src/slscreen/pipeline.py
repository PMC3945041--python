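"""End-to-end orchestration: simulate or ingest, ratio, call, enrich.

One :func:`run` call executes the whole analysis with a single
:class:`RunConfig`, writes every intermediate table plus a JSON manifest
(config, input checksums, per-stage tallies), and is deterministic given
the config and inputs.  :func:`reproduce_screen_stats` recomputes the
headline statistics of a finished screen — per-module control SDs,
read-floor exclusion percentages, candidate gene counts under both
majority variants, and an optional gene-family rescue enrichment — from
a single per-construct table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from slscreen import calling, enrichment, ratios, simulate
from slscreen.io import (
    CountTable,
    LibraryDesign,
    ScreenConfigError,
    read_count_table,
    read_gmt,
    read_library_annotation,
    write_results,
)

logger = logging.getLogger(__name__)

#: Headline statistics of the screen this pipeline re-implements, as
#: printed in its report: per-module Luciferase-control SDs, read-floor
#: exclusion percentages, candidate synthetic-lethal gene count, library
#: universe size, and the 9-member cAMP-phosphodiesterase rescue
#: enrichment p-value.  Used by ``reproduce_screen_stats(...,
#: published=PUBLISHED_SCREEN_STATS)`` to print a side-by-side table.
PUBLISHED_SCREEN_STATS: dict[str, float] = {
    "control_sd_module1": 0.1595,
    "control_sd_module2": 0.1863,
    "excluded_pct_module1": 2.3,
    "excluded_pct_module2": 2.7,
    "n_sl_genes": 340,
    "n_genes_universe": 10455,
    "family_rescue_p": 0.047,
}


@dataclass(frozen=True)
class RunConfig:
    """Every tunable of the pipeline, defaulting to the screen's settings.

    Either ``simulation`` (a :class:`~slscreen.simulate.SimulationConfig`)
    or the three input paths must be given.  ``min_reads=100`` is the
    control-lane read floor; ``vote_threshold=0.5`` with
    ``strict_majority=False`` is the "at least half of the constructs"
    gene-calling rule; ``overlap_threshold=0.5`` the "more than 50%
    overlap" pruning rule.
    """

    simulation: simulate.SimulationConfig | None = None
    library_path: str | None = None
    ctrl_counts_path: str | None = None
    treat_counts_path: str | None = None
    gmt_path: str | None = None
    min_reads: int = 100
    vote_threshold: float = 0.5
    strict_majority: bool = False
    denominator: str = "passing"
    normalization: str = "lane"
    zero_guard: float = 1.0
    fdr_method: str = "bh"
    overlap_threshold: float = 0.5
    direction: str = "lethal"
    seed: int = 0
    out_dir: str = "slscreen_run"


@dataclass
class RunResult:
    ratio_table: pd.DataFrame
    thresholds: dict[int, calling.Threshold]
    gene_calls: pd.DataFrame
    enrichment_results: list | None
    manifest: dict
    out_dir: Path | None = None


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(
    config: RunConfig,
) -> tuple[LibraryDesign, CountTable, CountTable, dict]:
    prov: dict = {}
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        design, truth = simulate.generate_library(sim)
        ctrl, treat = simulate.simulate_counts(design, truth, sim)
        prov["simulation"] = dataclasses.asdict(sim)
        prov["truth_n_sl"] = int((truth.gene_status == simulate.SL).sum())
        prov["truth_n_rescue"] = int((truth.gene_status == simulate.RESCUE).sum())
        return design, ctrl, treat, prov
    if not (config.library_path and config.ctrl_counts_path and config.treat_counts_path):
        raise ScreenConfigError(
            "RunConfig needs either a simulation config or library + two "
            "count-table paths"
        )
    design = read_library_annotation(config.library_path)
    ctrl = read_count_table(config.ctrl_counts_path, "siCTRL")
    treat = read_count_table(config.treat_counts_path, "siFH")
    prov["input_checksums"] = {
        "library": _sha256(config.library_path),
        "ctrl_counts": _sha256(config.ctrl_counts_path),
        "treat_counts": _sha256(config.treat_counts_path),
    }
    return design, ctrl, treat, prov


def run(config: RunConfig, write: bool = True) -> RunResult:
    """Execute simulate/ingest -> ratios -> calling -> enrichment.

    Writes ``ratios.tsv``, ``thresholds.tsv``, ``gene_calls.tsv``,
    ``enrichment.tsv`` (when a GMT is configured) and ``manifest.json``
    into ``config.out_dir`` unless ``write=False``.  Any stage failure
    propagates with the stage name prepended.
    """
    stage = "inputs"
    try:
        design, ctrl, treat, prov = _load_inputs(config)

        stage = "ratios"
        ratio_table, excluded = ratios.build_ratio_table(
            design,
            ctrl,
            treat,
            min_reads=config.min_reads,
            zero_guard=config.zero_guard,
            normalization=config.normalization,
        )

        stage = "calling"
        thresholds = calling.estimate_thresholds(ratio_table)
        construct_calls = calling.call_constructs(ratio_table, thresholds)
        gene_calls = calling.call_genes(
            construct_calls,
            design,
            vote_threshold=config.vote_threshold,
            strict_majority=config.strict_majority,
            denominator=config.denominator,
        )

        stage = "enrichment"
        enr_results = None
        if config.gmt_path:
            collection = read_gmt(config.gmt_path)
            target_call = (
                calling.SYNTHETIC_LETHAL
                if config.direction == "lethal"
                else calling.SYNTHETIC_RESCUE
            )
            candidates = set(
                gene_calls.loc[gene_calls["call"] == target_call, "gene"]
            )
            universe = set(design.genes)
            enr_results = enrichment.enrich(
                candidates,
                collection,
                universe,
                fdr_method=config.fdr_method,
                overlap_threshold=config.overlap_threshold,
            )
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    n_sl = int((gene_calls["call"] == calling.SYNTHETIC_LETHAL).sum())
    n_rescue = int((gene_calls["call"] == calling.SYNTHETIC_RESCUE).sum())
    manifest = {
        "version": 1,
        "seed": config.seed,
        "config": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k != "simulation"
        },
        **prov,
        "n_constructs": len(design),
        "n_genes": len(design.genes),
        "excluded_pct_per_module": excluded,
        "n_passing": int(ratio_table["passes_filter"].sum()),
        "n_excluded": int((~ratio_table["passes_filter"]).sum()),
        "thresholds": {
            str(m): {"sigma": t.sigma, "n_controls_used": t.n_controls_used}
            for m, t in sorted(thresholds.items())
        },
        "n_synthetic_lethal": n_sl,
        "n_synthetic_rescue": n_rescue,
        "n_sets_tested": len(enr_results) if enr_results is not None else 0,
        "n_sets_kept": (
            sum(r.kept for r in enr_results) if enr_results is not None else 0
        ),
    }

    out_dir = None
    if write:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ratio_table.to_csv(
            out_dir / "ratios.tsv", sep="\t", index=False, float_format="%.12g"
        )
        pd.DataFrame(
            [
                (m, t.sigma, t.lower, t.upper, t.n_controls_used)
                for m, t in sorted(thresholds.items())
            ],
            columns=["module", "sigma", "lower", "upper", "n_controls_used"],
        ).to_csv(out_dir / "thresholds.tsv", sep="\t", index=False, float_format="%.12g")
        enr_frame = (
            enrichment.results_to_frame(enr_results)
            if enr_results is not None
            else None
        )
        write_results(gene_calls, enr_frame, out_dir)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return RunResult(ratio_table, thresholds, gene_calls, enr_results, manifest, out_dir)


REPRODUCE_REQUIRED = ("construct_id", "gene", "module", "is_control", "count_ctrl", "count_treat")


def reproduce_screen_stats(
    ratio_file: str | Path | pd.DataFrame,
    published: dict[str, float] | None = None,
    min_reads: int = 100,
    rescue_family: set[str] | None = None,
) -> pd.DataFrame:
    """Recompute a screen's headline statistics from a per-construct table.

    The input (TSV path or DataFrame) needs one row per construct with
    columns ``construct_id, gene, module, is_control, count_ctrl,
    count_treat``.  Recomputes, per module, the control-ratio SD and the
    read-floor exclusion percentage; the candidate synthetic-lethal gene
    count under both the non-strict ("at least half") and strict ("more
    than half") majority rules; the rescue gene count; and, when
    ``rescue_family`` is given, its hypergeometric rescue-enrichment
    p-value.  Returns a tidy report with a ``published`` column filled
    from the ``published`` mapping (blank where absent) for side-by-side
    comparison.
    """
    if isinstance(ratio_file, (str, Path)):
        df = pd.read_csv(ratio_file, sep="\t", dtype={"construct_id": str, "gene": str})
        df["gene"] = df["gene"].fillna("")
    else:
        df = ratio_file.copy()
    missing = [c for c in REPRODUCE_REQUIRED if c not in df.columns]
    if missing:
        raise ScreenConfigError(
            f"reproduction input missing column(s): {missing}"
        )
    df["is_control"] = df["is_control"].astype(bool)
    design = LibraryDesign(
        pd.DataFrame(
            {
                # barcodes may be absent from ratio exports; synthesize unique ones
                "barcode": [simulate._barcode(i) for i in range(len(df))],
                "construct_id": df["construct_id"].values,
                "gene": df["gene"].values,
                "module": df["module"].astype(int).values,
                "is_control": df["is_control"].values,
            }
        )
    )
    idx = pd.Index(df["construct_id"], name="construct_id")
    ctrl = CountTable("siCTRL", pd.Series(df["count_ctrl"].astype(int).values, index=idx))
    treat = CountTable("siFH", pd.Series(df["count_treat"].astype(int).values, index=idx))

    ratio_table, excluded = ratios.build_ratio_table(
        design, ctrl, treat, min_reads=min_reads
    )
    thresholds = calling.estimate_thresholds(ratio_table)
    construct_calls = calling.call_constructs(ratio_table, thresholds)

    rows: list[tuple[str, float]] = []
    for m, t in sorted(thresholds.items()):
        rows.append((f"control_sd_module{m}", round(t.sigma, 4)))
    for m, pct in sorted(excluded.items()):
        rows.append((f"excluded_pct_module{m}", pct))
    for variant, strict in (("", False), ("_strict", True)):
        gc = calling.call_genes(construct_calls, design, strict_majority=strict)
        n_sl = int((gc["call"] == calling.SYNTHETIC_LETHAL).sum())
        n_rescue = int((gc["call"] == calling.SYNTHETIC_RESCUE).sum())
        rows.append((f"n_sl_genes{variant}", n_sl))
        rows.append((f"n_rescue_genes{variant}", n_rescue))
        if not strict and rescue_family is not None:
            p = calling.rescue_enrichment_check(
                gc, rescue_family, len(design.genes)
            )
            rows.append(("family_rescue_p", round(p, 3)))
    rows.append(("n_genes_universe", len(design.genes)))

    report = pd.DataFrame(rows, columns=["metric", "computed"])
    pub = published or {}
    report["published"] = [pub.get(m, float("nan")) for m in report["metric"]]
    return report
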