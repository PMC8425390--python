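"""End-to-end audit pipeline and report writers.

``run_pipeline`` ties the stages together: read maps → extract
phosphorylation quadruplets → group into triplets → filter repeats → find
divergent representations → lint.  Artifacts are plain text (TSV/JSON),
written atomically, and deterministic for a given configuration (no
timestamps), so two runs over the same inputs are byte-identical.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from pdlint.census import (
    ExtractionConfig,
    expand_events,
    extract_phospho_events,
    filter_repeated,
    find_divergent_representations,
    group_patterns,
)
from pdlint.io import read_map
from pdlint.lints import ALL_RULES, LintFinding, run_all_lints
from pdlint.model import MapModel

logger = logging.getLogger("pdlint.pipeline")

EXIT_OK = 0
EXIT_LINT_ERRORS = 2
EXIT_USAGE = 64


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    inputs: tuple[str, ...]
    out_dir: str
    map_name_overrides: Mapping[str, str] = field(default_factory=dict)
    mode: str = "both"  # census mode: free | complex | both
    include_stimulation: bool = False
    expand_generics: bool = False
    rules: tuple[str, ...] = ALL_RULES
    canonical_sites: Optional[Mapping[str, frozenset[str]]] = None

    def __post_init__(self) -> None:
        if self.mode not in ("free", "complex", "both"):
            raise ValueError(f"unknown census mode {self.mode!r}")
        unknown = set(self.rules) - set(ALL_RULES)
        if unknown:
            raise ValueError(f"unknown lint rule(s): {sorted(unknown)}")


@dataclass
class PipelineResult:
    exit_code: int
    artifacts: dict[str, str]
    counts: dict[str, int]


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=str(path.parent), prefix=".tmp-", text=True)
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def events_to_tsv(events) -> str:
    lines = ["kinase\ttarget\tsite\tmap\tmode\tprocess_id"]
    for ev in sorted(
        events, key=lambda e: (e.kinase, e.target, e.site, e.map_name, e.process_id)
    ):
        lines.append(
            "\t".join(
                [ev.kinase, ev.target, ev.site, ev.map_name, ev.mode, ev.process_id]
            )
        )
    return "\n".join(lines) + "\n"


def census_to_tsv(census) -> str:
    df = census.to_dataframe()
    return df.to_csv(sep="\t", index=False)


def findings_to_json(findings: Sequence[LintFinding]) -> str:
    doc = {
        "findings": [
            {
                "rule_id": f.rule_id,
                "severity": f.severity,
                "protein_key": f.protein_key,
                "pools": list(f.pools),
                "maps": list(f.maps),
                "message": f.message,
                "payload": dict(f.payload),
            }
            for f in sorted(
                findings, key=lambda f: (f.rule_id, f.severity, f.maps, f.message)
            )
        ]
    }
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def divergence_to_json(groups) -> str:
    doc = {
        "divergent_groups": [
            {
                "kinase": g.kinase,
                "target": g.target,
                "n_versions": g.n_versions,
                "per_map": {
                    name: {
                        "sites": sorted(rep.sites),
                        "modes": sorted(rep.modes),
                        "target_generic": rep.target_generic,
                        "target_signatures": sorted(
                            list(sig) for sig in rep.target_signatures
                        ),
                    }
                    for name, rep in g.per_map
                },
            }
            for g in groups
        ]
    }
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def load_maps(
    inputs: Sequence[str], overrides: Mapping[str, str] = {}
) -> list[MapModel]:
    models = []
    for path in inputs:
        models.append(read_map(path, map_name=overrides.get(str(path))))
    return models


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run read → extract → group → filter → divergence → lints.

    Artifacts (events.tsv, census.tsv, divergence.json, findings.json,
    run.log) are written atomically to ``config.out_dir``.  Exit code 0 for
    a clean run, 2 when error-severity findings are present.
    """
    if not config.inputs:
        raise ValueError("no input maps")
    models = load_maps(config.inputs, config.map_name_overrides)

    extraction = ExtractionConfig(
        include_stimulation=config.include_stimulation, mode=config.mode
    )
    events = [
        ev for m in models for ev in extract_phospho_events(m, extraction)
    ]
    if config.expand_generics:
        events = expand_events(events, {m.map_name: m for m in models})
    census = group_patterns(events)
    repeated = filter_repeated(census)
    groups = find_divergent_representations(repeated, models, extraction)
    findings = run_all_lints(
        models, reference=config.canonical_sites, rules=config.rules
    )
    n_errors = sum(1 for f in findings if f.severity == "error")

    counts = {
        "maps": len(models),
        "events": len(events),
        "triplets": len(census),
        "repeated": len(repeated),
        "divergent_groups": len(groups),
        "findings": len(findings),
        "errors": n_errors,
    }
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = {
        "events": out / "events.tsv",
        "census": out / "census.tsv",
        "divergence": out / "divergence.json",
        "findings": out / "findings.json",
        "log": out / "run.log",
    }
    _atomic_write(artifacts["events"], events_to_tsv(events))
    _atomic_write(artifacts["census"], census_to_tsv(repeated))
    _atomic_write(artifacts["divergence"], divergence_to_json(groups))
    _atomic_write(artifacts["findings"], findings_to_json(findings))
    _atomic_write(
        artifacts["log"],
        "".join(f"{k}: {v}\n" for k, v in counts.items()),
    )
    for k, v in counts.items():
        logger.info("%s: %d", k, v)
    return PipelineResult(
        exit_code=EXIT_LINT_ERRORS if n_errors else EXIT_OK,
        artifacts={k: str(v) for k, v in artifacts.items()},
        counts=counts,
    )
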