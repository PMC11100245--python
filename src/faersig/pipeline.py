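"""End-to-end pipeline: ingest -> dedup -> profile -> signal tables.

Driven by a declarative YAML/JSON config::

    quarters: [path/to/2013q2, ...]      # dirs holding DEMO.txt .. THER.txt
    deleted_lists: [path/to/DELETED.txt]
    vocabulary: path/to/pt_soc_map.csv   # required for SOC-level output
    drug: {names: [vilazodone, viibryd], roles: [PS]}
    levels: [pt, soc]
    min_a: 3
    yates: false
    rule: all
    synthetic: {...}                     # alternative to quarters

Outputs land in the output directory: ``profile.csv``, ``signals_pt.csv``
(and ``signals_soc.csv``), ``dedup_summary.csv`` and ``run.log``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .contingency import all_tables, build_pairs
from .dedup import DedupSummary, deduplicate, filter_mentions, remove_deleted
from .io import QuarterBundle, load_pt_soc_map, parse_deleted_list, parse_quarter
from .profile import DrugQuery, profile_cohort, select_target_reports
from .stats import evaluate_tables
from .synthetic import SynthConfig, generate

logger = logging.getLogger("faersig")

__all__ = ["load_config", "run_pipeline", "PipelineError"]

_QUARTER_FILES = {"demo": "DEMO.txt", "drug": "DRUG.txt", "reac": "REAC.txt",
                  "outc": "OUTC.txt", "ther": "THER.txt"}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def load_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError("config: top level must be a mapping")
    return cfg


def _parse_quarter_dir(qdir: Path) -> QuarterBundle:
    paths = {k: qdir / v for k, v in _QUARTER_FILES.items()}
    return parse_quarter(paths["demo"], paths["drug"], paths["reac"],
                         paths["outc"], paths["ther"], quarter_label=qdir.name)


def run_pipeline(config: dict | str | Path, outdir: str | Path, seed: int | None = None) -> Path:
    """Run every stage; returns the output directory.

    Raises :class:`PipelineError` naming the failed stage.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, outdir, seed)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: dict, outdir: Path, seed: int | None) -> Path:
    logger.info("faersig %s", __version__)

    # --- ingest ---------------------------------------------------------
    try:
        bundles = []
        deleted: set[str] = set()
        if "synthetic" in config:
            synth = dict(config["synthetic"])
            if seed is not None:
                synth["seed"] = seed
            sdir = outdir / "synthetic"
            generate(SynthConfig.from_dict(synth), sdir)
            config.setdefault("quarters", []).append(str(sdir))
            config.setdefault("deleted_lists", []).append(str(sdir / "DELETED.txt"))
            config.setdefault("vocabulary", str(sdir / "pt_soc_map.csv"))
            logger.info("synthetic quarter generated (seed=%s)", synth.get("seed"))
        for q in config.get("quarters", []):
            bundles.append(_parse_quarter_dir(Path(q)))
        if not bundles:
            raise PipelineError("ingest: no quarters configured")
        bundle = QuarterBundle.concat(bundles) if len(bundles) > 1 else bundles[0]
        for dl in config.get("deleted_lists", []):
            deleted |= parse_deleted_list(dl)
        logger.info("ingest: %d demo rows, %d deleted caseids", len(bundle.demo), len(deleted))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"ingest: {exc}") from exc

    # --- dedup ----------------------------------------------------------
    try:
        summary = DedupSummary()
        demo = deduplicate(bundle.demo, summary)
        demo = remove_deleted(demo, deleted, summary)
        bundle = filter_mentions(bundle, demo)
        summary.to_frame().to_csv(outdir / "dedup_summary.csv", index=False, lineterminator="\n")
    except Exception as exc:
        raise PipelineError(f"dedup: {exc}") from exc

    # --- cohort + profile ----------------------------------------------
    try:
        drug_cfg = config.get("drug", {})
        query = DrugQuery(
            names=tuple(drug_cfg.get("names", ())),
            roles=frozenset(drug_cfg.get("roles", ("PS",))),
        )
        cohort = select_target_reports(bundle, query)
        if not cohort:
            logger.warning("cohort is empty — signal tables will be empty")
        profile = profile_cohort(bundle, cohort, query)
        profile.to_frame().to_csv(outdir / "profile.csv", index=False, lineterminator="\n")
        logger.info("cohort: %d reports", len(cohort))
    except Exception as exc:
        raise PipelineError(f"profile: {exc}") from exc

    # --- signals --------------------------------------------------------
    try:
        levels = [str(level).upper() for level in config.get("levels", ["pt"])]
        vocab = None
        if "vocabulary" in config:
            vocab = load_pt_soc_map(config["vocabulary"])
        min_a = int(config.get("min_a", 3))
        yates = bool(config.get("yates", False))
        rule = str(config.get("rule", "all"))
        for level in levels:
            if level == "SOC" and vocab is None:
                raise PipelineError("signals: SOC level requested without a vocabulary")
            universe = build_pairs(bundle, cohort, vocab, level=level)
            tables = all_tables(universe, min_a=min_a)
            result = evaluate_tables(tables, yates=yates, rule=rule, min_a=min_a)
            result = result.sort_values(["a", "ebgm"], ascending=[False, False], kind="mergesort")
            result.to_csv(outdir / f"signals_{level.lower()}.csv", index=False, lineterminator="\n")
            # 2-d.p. companion view alongside the full-precision table
            styled = result.copy()
            for col in styled.columns:
                if styled[col].dtype.kind == "f":
                    styled[col] = styled[col].round(2)
            styled.to_csv(outdir / f"signals_{level.lower()}_2dp.csv", index=False, lineterminator="\n")
            logger.info("signals %s: %d labels (min_a=%d)", level, len(result), min_a)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"signals: {exc}") from exc

    return outdir
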