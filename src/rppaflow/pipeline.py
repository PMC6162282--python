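"""End-to-end driver: normalize -> screen -> network flow -> rank.

A :class:`PipelineConfig` names the inputs (two RPPA matrices with a shared
sample sheet, a typed network, optionally a regulator whitelist), the screen
thresholds, the capacity schemes and the sink genes. :func:`run_pipeline`
executes the stages, writes every intermediate table under the output
directory, and returns a :class:`RunReport` whose numbers are recomputable
from those files. Identical configuration and seed produce byte-identical
tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as rio
from .errors import StageError, ValidationError
from .flow import default_sources, rank_report, score_candidates
from .network import CapacityScheme, DEFAULT_SCHEMES, SignalingNetwork
from .preprocess import normalize_to_baseline
from .screen import ScreenThresholds, run_screen, screen_table

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Everything one reproducible pipeline run needs.

    ``predictor_cell_line`` and ``response_cell_line`` set the direction of
    the cross-cell-line regression (which trajectory predicts which).
    ``restrict_to_screen`` optionally prunes the network to screen-selected
    molecules plus the sinks before the flow stage; by default the supplied
    network is used as-is, since pathway tools add connector molecules that
    are not on the screen list.
    """

    rppa_path: str
    sample_sheet_path: str
    network_path: str
    out_dir: str
    predictor_cell_line: str
    response_cell_line: str
    seed: int = 0
    whitelist_path: str | None = None
    baseline: str | None = None
    thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)
    schemes: list[CapacityScheme] = field(default_factory=lambda: list(DEFAULT_SCHEMES))
    sinks: list[str] = field(default_factory=lambda: ["CCNB1", "CCND1"])
    sources: list[str] | None = None
    restrict_to_screen: bool = False

    def __post_init__(self):
        if not self.sinks:
            raise ValidationError("sink list must be non-empty")
        if not self.schemes:
            raise ValidationError("capacity scheme list must be non-empty")

    def as_dict(self) -> dict:
        return {
            "rppa_path": str(self.rppa_path),
            "sample_sheet_path": str(self.sample_sheet_path),
            "network_path": str(self.network_path),
            "out_dir": str(self.out_dir),
            "predictor_cell_line": self.predictor_cell_line,
            "response_cell_line": self.response_cell_line,
            "seed": self.seed,
            "whitelist_path": self.whitelist_path and str(self.whitelist_path),
            "baseline": self.baseline,
            "thresholds": {
                "fdr_max": self.thresholds.fdr_max,
                "r_min": self.thresholds.r_min,
                "r_max": self.thresholds.r_max,
            },
            "schemes": [s.as_dict() for s in self.schemes],
            "sinks": list(self.sinks),
            "sources": self.sources and list(self.sources),
            "restrict_to_screen": self.restrict_to_screen,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML (or JSON — YAML is a superset) configuration file."""
    raw = yaml.safe_load(Path(path).read_text())
    thresholds = ScreenThresholds(**raw.pop("thresholds", {}))
    schemes = [
        CapacityScheme(**s) for s in raw.pop("schemes", [])
    ] or list(DEFAULT_SCHEMES)
    return PipelineConfig(thresholds=thresholds, schemes=schemes, **raw)


@dataclass
class RunReport:
    """Provenance plus the headline numbers of one pipeline run."""

    config_hash: str
    seed: int
    n_tested: int
    n_selected: int
    selected_ids: list[str]
    top_candidates: list[str]
    files: dict[str, str]

    def as_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "screen": {"n_tested": self.n_tested, "n_selected": self.n_selected},
            "selected_ids": self.selected_ids,
            "top_candidates": self.top_candidates,
            "files": self.files,
        }


def _restrict_network(network: SignalingNetwork, keep: set[str]) -> SignalingNetwork:
    edges = [e for e in network.edges if e.source in keep and e.target in keep]
    return SignalingNetwork(edges=edges, nodes=set(network.nodes) & keep)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute normalize -> screen -> flow scoring -> ranking, writing intermediates."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        predictor = rio.read_rppa(
            config.rppa_path, config.sample_sheet_path, config.predictor_cell_line
        )
        response = rio.read_rppa(
            config.rppa_path, config.sample_sheet_path, config.response_cell_line
        )
        network = rio.read_network(config.network_path)
    except Exception as exc:  # noqa: BLE001 - rewrap with stage name
        raise StageError("ingest", str(exc)) from exc

    try:
        norm_pred = normalize_to_baseline(predictor, config.baseline)
        norm_resp = normalize_to_baseline(response, config.baseline)
        rio.write_rppa(
            norm_pred,
            out / "normalized_predictor.tsv",
            out / "normalized_predictor_samples.tsv",
        )
        rio.write_rppa(
            norm_resp,
            out / "normalized_response.tsv",
            out / "normalized_response_samples.tsv",
        )
    except StageError:
        raise
    except Exception as exc:
        raise StageError("normalize", str(exc)) from exc

    try:
        screen = run_screen(norm_pred, norm_resp, config.thresholds)
        table = screen_table(screen)
        rio.write_table(table, out / "screen.tsv")
        rio.write_json(screen.summary(), out / "screen_summary.json")
    except Exception as exc:
        raise StageError("screen", str(exc)) from exc

    try:
        flow_network = network
        if config.restrict_to_screen:
            keep = set(screen.selected_ids) | set(config.sinks)
            flow_network = _restrict_network(network, keep)
        whitelist = None
        if config.whitelist_path:
            whitelist = [
                w.strip()
                for w in Path(config.whitelist_path).read_text().splitlines()
                if w.strip()
            ]
        sources = config.sources or default_sources(flow_network, config.sinks)
        flow_log: list[dict] = []
        scores = score_candidates(
            flow_network, config.schemes, config.sinks, sources, flow_log=flow_log
        )
        rio.write_table(pd.DataFrame(flow_log), out / "flow_log.tsv")
        ranking = rank_report(scores, whitelist)
        rio.write_table(ranking, out / "scores.tsv")
    except Exception as exc:
        raise StageError("netflow", str(exc)) from exc

    if "in_whitelist" in ranking.columns:
        candidates = ranking.loc[ranking["in_whitelist"], "molecule"]
    else:
        candidates = ranking["molecule"]
    top = candidates.head(3).tolist()

    report = RunReport(
        config_hash=config.config_hash(),
        seed=config.seed,
        n_tested=screen.n_tested,
        n_selected=screen.n_selected,
        selected_ids=screen.selected_ids,
        top_candidates=top,
        files={
            "normalized_predictor": str(out / "normalized_predictor.tsv"),
            "normalized_response": str(out / "normalized_response.tsv"),
            "screen": str(out / "screen.tsv"),
            "screen_summary": str(out / "screen_summary.json"),
            "flow_log": str(out / "flow_log.tsv"),
            "scores": str(out / "scores.tsv"),
        },
    )
    rio.write_json(report.as_dict(), out / "report.json")
    return report
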