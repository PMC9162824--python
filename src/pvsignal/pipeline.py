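"""End-to-end orchestration: simulate/load -> clean -> select -> screen -> describe.

`run_pipeline` executes the stages in order, writes every output table as
CSV under the output directory, and returns a manifest recording the counts
at each stage (reports in, cases after deduplication, cohort size, pairs
screened, signals retained) plus the files written.  The manifest is
deterministic under a fixed seed and is also written as a key=value text
file, so two runs with the same inputs produce byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import os
import time
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import yaml

from . import __version__
from .case_selection import DEFAULT_ROLES, select_cohort, enumerate_pairs
from .cleaning import VocabularyMap, deduplicate
from .descriptives import describe_cohort
from .disproportionality import SignalCriteria, screen_all_pairs
from .faers_io import read_database, write_tables
from .synthetic import SyntheticConfig, default_paper_config, generate_database

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """What to run: exactly one of input_dir / synthetic must be set."""

    input_dir: Optional[str] = None
    synthetic: Optional[SyntheticConfig] = None
    drug: str = "aspirin"
    roles: Sequence[str] = tuple(sorted(DEFAULT_ROLES))
    criteria: SignalCriteria = field(default_factory=SignalCriteria)
    out_dir: str = "pvsignal_out"
    top: Optional[int] = None
    pooled: bool = False
    use_haldane: bool = False
    vocab: Optional[VocabularyMap] = None

    def validate(self) -> None:
        if (self.input_dir is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_dir / synthetic must be set")


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Run all stages and return the manifest dictionary."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: Dict[str, object] = {"version": __version__, "drug": config.drug}
    files = []

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - reported with stage name
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        logger.info("stage=%s elapsed=%.2fs", name, time.perf_counter() - t0)
        return result

    if config.synthetic is not None:
        manifest["seed"] = config.synthetic.seed

        def simulate():
            db, truth = generate_database(config.synthetic)
            data_dir = os.path.join(config.out_dir, "synthetic_data")
            write_tables(db, data_dir)
            truth.write_csv(os.path.join(data_dir, "ground_truth.csv"))
            files.append(os.path.join(data_dir, "ground_truth.csv"))
            return db

        db = stage("simulate", simulate)
        manifest["source"] = "synthetic"
    else:
        db = stage("load", lambda: read_database(config.input_dir))
        manifest["source"] = config.input_dir
    manifest["reports_in"] = len(db.cases)

    clean = stage("clean", lambda: deduplicate(db, config.vocab))
    manifest["cases_after_dedup"] = clean.n_cases
    manifest["versions_dropped"] = clean.n_dropped

    cohort = stage("select", lambda: select_cohort(clean, config.drug, config.roles))
    manifest["cohort_cases"] = cohort.size
    manifest["indication_strata"] = len(cohort.strata)
    pairs = enumerate_pairs(cohort.pooled() if config.pooled else cohort)
    manifest["pairs_screened"] = len(pairs)
    manifest["pair_instances"] = int(sum(a for _i, _pt, a in pairs))

    signals = stage(
        "screen",
        lambda: screen_all_pairs(
            cohort, clean, config.criteria,
            use_haldane=config.use_haldane, top=config.top, pooled=config.pooled,
        ),
    )
    manifest["signals_retained"] = len(signals)
    signals_path = os.path.join(config.out_dir, "signals.csv")
    signals.to_csv(signals_path, index=False)
    files.append(signals_path)

    tables = stage("describe", lambda: describe_cohort(cohort))
    for name, frame in tables.items():
        path = os.path.join(config.out_dir, f"{name}.csv")
        frame.to_csv(path)
        files.append(path)

    manifest["files"] = sorted(os.path.relpath(p, config.out_dir) for p in files)
    _write_manifest(manifest, os.path.join(config.out_dir, "manifest.txt"))
    return manifest


def _write_manifest(manifest: Dict[str, object], path: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key in sorted(manifest):
            value = manifest[key]
            if isinstance(value, list):
                value = ";".join(map(str, value))
            fh.write(f"{key}={value}\n")


def criteria_from_file(path: str) -> SignalCriteria:
    """SignalCriteria with defaults overridden from a key/value YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        overrides = yaml.safe_load(fh) or {}
    fields = {f.name for f in dataclasses.fields(SignalCriteria)}
    unknown = set(overrides) - fields
    if unknown:
        raise ValueError(f"unknown criteria keys: {sorted(unknown)}")
    return SignalCriteria(**overrides)


def synthetic_config_from_file(path: str) -> SyntheticConfig:
    """SyntheticConfig from a YAML file; omitted keys keep the published-cohort
    defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        overrides = yaml.safe_load(fh) or {}
    base = default_paper_config()
    fields = {f.name for f in dataclasses.fields(SyntheticConfig)}
    unknown = set(overrides) - fields
    if unknown:
        raise ValueError(f"unknown synthetic config keys: {sorted(unknown)}")
    if "injected_signals" in overrides:
        overrides["injected_signals"] = [tuple(s) for s in overrides["injected_signals"]]
    if "event_vocabulary" in overrides:
        overrides["event_vocabulary"] = [tuple(e) for e in overrides["event_vocabulary"]]
    config = dataclasses.replace(base, **overrides)
    config.validate()
    return config
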