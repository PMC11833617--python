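"""Run configuration and the end-to-end pipeline driver.

A run configuration is a YAML or JSON file with per-stage sections
(``encoder``, ``cluster``, ``hits``, ``screen`` ...); command-line flags
override file values.  Every pipeline invocation emits a machine-readable
run report echoing the effective parameters, seeds, package version and
per-stage record counts, so a run can be audited and reproduced.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .encode import EncoderConfig
from .enrich import HitCallCriteria
from .expand import ClusterParams
from .simulate import ScreenSimConfig

__all__ = ["RunConfig", "load_config", "run_report", "run_pipeline"]


@dataclass
class RunConfig:
    """Aggregated per-stage parameter bundles with a global seed."""

    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    hits: HitCallCriteria = field(default_factory=HitCallCriteria)
    screen: ScreenSimConfig = field(default_factory=ScreenSimConfig)
    max_peptide_len: int = 90
    seed: int = 0
    log_level: str = "INFO"

    def effective_parameters(self) -> dict[str, Any]:
        out = asdict(self)
        out["version"] = __version__
        return out


def load_config(path: str | Path | None, **overrides: Any) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML/JSON file plus
    keyword overrides (``section__field`` or top-level field names)."""
    data: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    for key, value in overrides.items():
        if value is None:
            continue
        if "__" in key:
            section, fieldname = key.split("__", 1)
            data.setdefault(section, {})[fieldname] = value
        else:
            data[key] = value
    sections = {
        "encoder": EncoderConfig,
        "cluster": ClusterParams,
        "hits": HitCallCriteria,
        "screen": ScreenSimConfig,
    }
    kwargs: dict[str, Any] = {}
    for name, cls in sections.items():
        section = data.get(name, {})
        if isinstance(section, dict):
            coerced = {
                k: tuple(v) if isinstance(v, list) else v for k, v in section.items()
            }
            kwargs[name] = cls(**coerced)
        else:
            kwargs[name] = section
    for scalar in ("max_peptide_len", "seed", "log_level"):
        if scalar in data:
            kwargs[scalar] = data[scalar]
    return RunConfig(**kwargs)


def run_report(
    cfg: RunConfig, stage_counts: dict[str, int], out: str | Path | None = None
) -> dict[str, Any]:
    """Assemble (and optionally write) the machine-readable run report."""
    report = {
        "parameters": cfg.effective_parameters(),
        "stage_counts": stage_counts,
        "python": platform.python_version(),
    }
    if out is not None:
        Path(out).write_text(json.dumps(report, indent=2, default=str) + "\n")
    return report


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict[str, Any]:
    """Synthetic end-to-end run: design -> encode -> simulate -> call hits.

    Generates a parent database from the configured seed, extracts and
    filters the mature library, encodes it, simulates a screen over the
    encoded clones and calls hits.  Artifacts are written under ``out_dir``
    and the run report is returned (and written as ``report.json``).
    """
    from . import enrich, records, simulate
    from .encode import encode_library

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    parents = simulate.make_parent_db(cfg.screen.n_clones, cfg.seed)
    counts["parents"] = len(parents)
    mature = [p for r in parents for p in records.extract_mature(r)]
    counts["mature"] = len(mature)
    library = records.length_filter(mature, cfg.max_peptide_len, collapse=True)
    counts["library"] = len(library)
    records.write_fasta(library, out_dir / "library.fasta")

    designs, failures = encode_library(
        [(p.id, p.sequence) for p in library], cfg.encoder
    )
    counts["designs"] = len(designs)
    counts["encode_failures"] = len(failures)

    screen_cfg = ScreenSimConfig(
        n_clones=len(designs),
        n_target_reps=cfg.screen.n_target_reps,
        n_control_reps=cfg.screen.n_control_reps,
        depth=cfg.screen.depth,
        abundance_sigma=cfg.screen.abundance_sigma,
        phi=cfg.screen.phi,
        spiked=cfg.screen.spiked,
        seed=cfg.seed,
    )
    matrix, truth = simulate.simulate_screen(screen_cfg)
    matrix.counts.index = [d.peptide_id for d in designs]
    truth.index = matrix.counts.index
    matrix.to_tsv(out_dir / "counts.tsv", out_dir / "groups.tsv")
    truth.to_csv(out_dir / "truth.tsv", sep="\t")
    counts["clones"] = len(matrix.counts)

    results = enrich.call_hits(enrich.score_enrichment(matrix), matrix, cfg.hits)
    results.to_csv(out_dir / "results.tsv", sep="\t")
    counts["hits"] = int(results["is_hit"].sum())

    return run_report(cfg, counts, out_dir / "report.json")
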