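"""End-to-end orchestration: impute -> screen -> subsets -> search -> clusters."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

import metscreen
from metscreen.cohort import CohortMatrix, build_subset, impute_below_detection
from metscreen.correlate import clusters_table, correlate_with_cores, find_orphans
from metscreen.panels import evaluations_table, report_best, search_panels
from metscreen.screen import run_screen, screen_table

log = logging.getLogger("metscreen")


@dataclass
class RunConfig:
    alpha: float = 0.05
    fdr_threshold: float = 0.1
    depths: tuple[int, ...] = (1, 2)
    subsets: tuple[str, ...] = ("i", "ii", "iii", "iv")
    sizes: tuple[int, int] = (2, 5)
    classifier_map: dict = field(
        default_factory=lambda: {"i": "fda", "ii": "fda", "iii": "logistic", "iv": "logistic"}
    )
    strategy_map: dict = field(
        default_factory=lambda: {"i": "exhaustive", "ii": "exhaustive", "iii": "exhaustive", "iv": "beam"}
    )
    beam_width: int = 50
    budget: int = 100_000
    top_k_broad: int = 50
    expected_iv_size: int | None = None
    seed: int = 0
    outdir: str = "metscreen-run"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0 and 0.0 < self.fdr_threshold < 1.0):
            raise ValueError("alpha and fdr_threshold must lie in (0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["depths"] = list(self.depths)
        d["subsets"] = list(self.subsets)
        d["sizes"] = list(self.sizes)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("depths", "subsets", "sizes"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def _digest(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv().encode()).hexdigest()


def run_all(cfg: RunConfig, cohort: CohortMatrix) -> dict:
    """Run the full analysis; returns the reproducibility manifest.

    Stages: imputation, univariate screen, subset assembly (AUC-ranked
    broad top-k), panel search per subset, and correlation decomposition
    around the winning panel.  All stage tables are written as CSV under
    ``cfg.outdir``; any stage failure aborts with the stage name while
    earlier outputs stay on disk.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": metscreen.__version__,
        "seed": cfg.seed,
        "config": json.loads(json.dumps(asdict(cfg))),
        "input_digest": _digest(cohort.values),
        "stages": {},
    }
    stage = "impute"
    try:
        t0 = time.perf_counter()
        cohort = impute_below_detection(cohort)
        manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3)}
        log.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "screen"
        t0 = time.perf_counter()
        results = run_screen(
            cohort, alpha=cfg.alpha, depths=cfg.depths, fdr_threshold=cfg.fdr_threshold
        )
        table = screen_table(results)
        path = outdir / "screen.csv"
        table.to_csv(path, index=False)
        manifest["stages"][stage] = {
            "output": str(path),
            "n_significant": int(table["significant"].sum()),
            "seconds": round(time.perf_counter() - t0, 3),
        }

        stage = "subsets"
        t0 = time.perf_counter()
        auc_table = {r.feature: r.auc for r in results}
        subsets = {}
        for sid in cfg.subsets:
            expected = cfg.expected_iv_size if sid == "iv" else None
            subsets[sid] = build_subset(
                cohort, sid, auc_table=auc_table, top_k=cfg.top_k_broad, expected_size=expected
            )
        path = outdir / "subsets.json"
        path.write_text(
            json.dumps({sid: list(s.feature_names) for sid, s in subsets.items()}, indent=2)
        )
        manifest["stages"][stage] = {
            "output": str(path),
            "sizes": {sid: len(s.feature_names) for sid, s in subsets.items()},
            "seconds": round(time.perf_counter() - t0, 3),
        }

        stage = "search"
        t0 = time.perf_counter()
        best_by_subset = {}
        frames = []
        for sid, spec in subsets.items():
            evals = search_panels(
                cohort,
                spec,
                sizes=range(cfg.sizes[0], cfg.sizes[1] + 1),
                classifier=cfg.classifier_map.get(sid, "logistic"),
                strategy=cfg.strategy_map.get(sid, "beam"),
                budget=cfg.budget,
                beam_width=cfg.beam_width,
            )
            best_by_subset[sid] = report_best(evals, k=1).best[0]
            frames.append(evaluations_table(evals[:200]))
        path = outdir / "panels.csv"
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        per_sample = best_by_subset[list(subsets)[-1]].per_sample
        scores_path = outdir / "best_panel_predictions.csv"
        pd.DataFrame(
            per_sample, columns=["participant", "true_group", "predicted_group", "value"]
        ).to_csv(scores_path, index=False)
        manifest["stages"][stage] = {
            "output": str(path),
            "predictions": str(scores_path),
            "best": {
                sid: {
                    "features": list(e.features),
                    "type1": e.type1,
                    "type2": e.type2,
                }
                for sid, e in best_by_subset.items()
            },
            "seconds": round(time.perf_counter() - t0, 3),
        }

        stage = "correlate"
        t0 = time.perf_counter()
        final_subset = list(subsets)[-1]
        cores = list(best_by_subset[final_subset].features)
        cores = [c for c in cores if cohort.meta(c).kind == "continuous"]
        candidates = [
            f for f in subsets[final_subset].feature_names if cohort.meta(f).kind == "continuous"
        ]
        clusters, core_table = correlate_with_cores(cohort, cores, candidates)
        orphans, orphan_table = find_orphans(results, clusters, cohort)
        cpath = outdir / "clusters.csv"
        clusters_table(clusters).to_csv(cpath, index=False)
        core_table.to_csv(outdir / "core_correlations.csv", index=False)
        orphan_table.to_csv(outdir / "orphan_correlations.csv")
        (outdir / "orphans.json").write_text(json.dumps(orphans, indent=2))
        manifest["stages"][stage] = {
            "output": str(cpath),
            "cores": cores,
            "orphans": orphans,
            "seconds": round(time.perf_counter() - t0, 3),
        }
    except Exception as exc:
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for name, info in manifest["stages"].items():
        log.info("stage %-9s %ss", name, info.get("seconds"))
    return manifest
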