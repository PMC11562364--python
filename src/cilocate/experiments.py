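"""Scripted desk-scale experiment battery over synthetic phantoms.

For each (electrode array, noise seed, cost variant) the battery generates a
phantom, runs the full localization chain, and scores it against the exact
ground truth.  The per-case table and per-array aggregates mirror the
reporting axes of clinical evaluations of chain-localization algorithms —
detection rate, localization accuracy, and the frequencies of the
characteristic error classes — but over synthetic cases, where the geometry
and the failure regime are controlled.

A paired sign test across seeds is provided as a convenience for comparing
the baseline and advanced cost variants; it is a deliberately simple
stand-in for a full nonparametric repeated-measures analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .evaluate import evaluate
from .pathfind import CostParams
from .phantom import make_phantom
from .pipeline import localize
from .refine import RefineParams

__all__ = ["ExperimentConfig", "run_battery", "summarize", "paired_sign_test"]


@dataclass
class ExperimentConfig:
    """What to run: arrays x presets x seeds x cost variants."""

    spec_names: list[str] = field(default_factory=lambda: ["Flex 24"])
    preset: str | dict[str, str] = "clean"  # one preset, or per-spec mapping
    seeds: list[int] = field(default_factory=lambda: [0])
    cost_variants: list[str] = field(default_factory=lambda: ["baseline", "advanced"])
    threshold_mode: str | float = "preset"  # preset | individual | generalized | number
    refine: bool = True
    beam_width: int = 10
    noise_sigma: float | None = None  # override the preset's noise level

    def __post_init__(self) -> None:
        if not self.seeds:
            raise ValueError("at least one seed is required")

    def preset_for(self, spec_name: str) -> str:
        if isinstance(self.preset, dict):
            return self.preset[spec_name]
        return self.preset


def _run_case(cfg: ExperimentConfig, spec_name: str, seed: int, variant: str) -> dict:
    ph = make_phantom(
        cfg.preset_for(spec_name), spec_name, seed=seed, noise_sigma=cfg.noise_sigma
    )
    if cfg.threshold_mode == "preset":
        alpha1 = ph.alpha1
    elif isinstance(cfg.threshold_mode, (int, float)):
        alpha1 = float(cfg.threshold_mode)
    else:
        from . import registry

        alpha1 = registry.get_threshold(spec_name, cfg.threshold_mode)

    params = CostParams(cost_variant=variant, beam_width=cfg.beam_width)
    res = localize(
        ph.volume,
        ph.gt.positions,
        ph.spec,
        alpha1,
        params=params,
        refine_params=RefineParams() if cfg.refine else None,
    )
    rep = evaluate(res.positions, ph.gt.positions)
    # smallest alpha_12 along the chain: the anti-revisit guarantee bound
    min_a12 = min(
        params.alpha12_for_gap(ph.spec.gap_for_extension(k))
        for k in range(1, ph.spec.n_electrodes)
    )
    return {
        "spec": spec_name,
        "preset": cfg.preset_for(spec_name),
        "seed": seed,
        "variant": variant,
        "alpha1_pct": alpha1,
        "n_candidates": len(res.candidates),
        "complete": res.path.complete,
        "n_nodes": len(res.path),
        "detection_rate_pct": rep.detection_rate,
        "localization_accuracy_mm": rep.localization_accuracy,
        "conditional_accuracy_mm": rep.conditional_accuracy,
        "n_missing": rep.n_missing,
        "min_pairwise_mm": res.path.min_pairwise_distance(),
        "min_alpha12_mm": min_a12,
        "artifact_detection": "artifact_detection" in rep.error_labels,
        "double_detection": "double_detection" in rep.error_labels,
        "ab_confusion_basal_revisit": "ab_confusion_basal_revisit" in rep.error_labels,
        "ab_confusion_reversal": "ab_confusion_reversal" in rep.error_labels,
        "error": "",
    }


def run_battery(cfg: ExperimentConfig, outdir: str | Path | None = None) -> pd.DataFrame:
    """Run every configured case; failures are recorded, not raised.

    Deterministic for identical configs and seeds.  When ``outdir`` is
    given, writes ``cases.csv`` and ``summary.csv`` there.
    """
    rows = []
    for spec_name in cfg.spec_names:
        for seed in cfg.seeds:
            for variant in cfg.cost_variants:
                try:
                    rows.append(_run_case(cfg, spec_name, seed, variant))
                except Exception as exc:  # battery must survive per-case failures
                    rows.append(
                        {
                            "spec": spec_name,
                            "preset": cfg.preset_for(spec_name),
                            "seed": seed,
                            "variant": variant,
                            "error": f"{type(exc).__name__}: {exc}",
                        }
                    )
    cases = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cases.to_csv(outdir / "cases.csv", index=False)
        summarize(cases).to_csv(outdir / "summary.csv", index=False)
    return cases


def summarize(cases: pd.DataFrame) -> pd.DataFrame:
    """Per (spec, variant) aggregates: mean rates, accuracy, error frequencies."""
    ok = cases[cases["error"] == ""].copy()
    if ok.empty:
        return pd.DataFrame()
    agg = ok.groupby(["spec", "preset", "variant"], as_index=False).agg(
        n_cases=("seed", "size"),
        mean_detection_rate_pct=("detection_rate_pct", "mean"),
        mean_localization_accuracy_mm=("localization_accuracy_mm", "mean"),
        mean_conditional_accuracy_mm=("conditional_accuracy_mm", "mean"),
        pct_artifact_detection=("artifact_detection", lambda s: 100.0 * s.mean()),
        pct_double_detection=("double_detection", lambda s: 100.0 * s.mean()),
        pct_ab_basal_revisit=("ab_confusion_basal_revisit", lambda s: 100.0 * s.mean()),
        pct_ab_reversal=("ab_confusion_reversal", lambda s: 100.0 * s.mean()),
    )
    return agg


def paired_sign_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided sign-test p-value for paired samples (ties dropped)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    diff = a - b
    n = int(np.sum(diff != 0))
    if n == 0:
        return 1.0
    wins = int(np.sum(diff > 0))
    return float(stats.binomtest(wins, n, 0.5).pvalue)
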