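"""End-to-end pipelines: simulate → normalize → score → AUC / slope / bias.

These helpers wire the generators, normalizers and evaluation statistics
into the benchmark protocols used throughout the package: the asymmetric
two-condition spike-in comparison and the effect-spiking simulation sweeps
(symmetric vs asymmetric effects, invariant-set proportion).
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd

from .core import ExpressionMatrix, log2_transform
from .evaluate import (
    compression_slope,
    gene_scores,
    null_bias,
    null_ma_bias,
    roc_curve,
)
from .kdq import kdq_normalize, quantile_normalize
from .loess import kdl_normalize
from .simulate import (
    GoldenSpikeDesign,
    SpikeSimDesign,
    simulate_golden_spike,
    simulate_spikein,
)
from .summarize import global_loess_normalize

METHODS = ("kdl", "kdq", "quantile", "loess")


def normalize_matrix(
    m: ExpressionMatrix,
    method: str,
    span: float = 0.2,
    multiplicity: float = 4.0,
    invariant_proportion: float = 0.5,
    m_boundary: int = 100,
) -> ExpressionMatrix:
    """Dispatch to one of the four normalizers by name."""
    if method == "kdl":
        return kdl_normalize(m, span=span, multiplicity=multiplicity)
    if method == "kdq":
        return kdq_normalize(m, proportion=invariant_proportion, m_boundary=m_boundary)
    if method == "quantile":
        return quantile_normalize(m)
    if method == "loess":
        return global_loess_normalize(m, span=span)
    raise ValueError(f"unknown method {method!r} (expected one of {METHODS})")


def evaluate_normalized(
    normalized: ExpressionMatrix,
    truth: pd.DataFrame,
    group_a,
    group_b,
) -> dict:
    """AUC (fold-change and t-test ranking), compression slope, null bias."""
    scores = gene_scores(normalized, group_a, group_b)
    out = {
        "auc_fc": roc_curve(scores, truth, criterion="fc").auc,
        "auc_t": roc_curve(scores, truth, criterion="t").auc,
        "null_bias": null_bias(scores, truth),
        "null_ma_bias": null_ma_bias(normalized, truth),
    }
    if (truth["designed_log2_fc"] > 0).sum() >= 2:
        out["slope"] = compression_slope(scores, truth)[0]
    else:
        out["slope"] = float("nan")
    return out


def golden_spike_panel(
    seed: int,
    methods=METHODS,
    design: GoldenSpikeDesign | None = None,
    drop_empty: bool = True,
    span: float = 0.2,
    multiplicity: float = 4.0,
    invariant_proportion: float = 0.5,
) -> dict[str, dict]:
    """Run the asymmetric two-condition benchmark for several normalizers.

    One matrix is simulated, optionally stripped of empty probe sets (the
    primary protocol), log2-transformed, then normalized and evaluated per
    method.  Returns {method: {auc_fc, auc_t, slope, null_bias}}.
    """
    if design is None:
        design = GoldenSpikeDesign(seed=seed)
    else:
        design = replace(design, seed=seed)
    matrix, truth, groups = simulate_golden_spike(design)
    if drop_empty:
        keep = ~truth["is_empty"].to_numpy()
        matrix = matrix.subset_probes(keep)
        truth = truth[keep].reset_index(drop=True)
    m_log2 = log2_transform(matrix)
    results: dict[str, dict] = {}
    for method in methods:
        normalized = normalize_matrix(
            m_log2,
            method,
            span=span,
            multiplicity=multiplicity,
            invariant_proportion=invariant_proportion,
        )
        results[method] = evaluate_normalized(
            normalized, truth, group_a=groups["S"], group_b=groups["C"]
        )
    return results


def spikein_auc(
    seed: int,
    method: str,
    asymmetric: bool,
    design: SpikeSimDesign | None = None,
    span: float = 0.2,
    multiplicity: float = 4.0,
    invariant_proportion: float = 0.5,
    criterion: str = "fc",
) -> float:
    """AUC of one method on one effect-spiking simulation."""
    if design is None:
        design = SpikeSimDesign(seed=seed, asymmetric=asymmetric)
    else:
        design = replace(design, seed=seed, asymmetric=asymmetric)
    sim = simulate_spikein(design)
    m_log2 = log2_transform(sim.matrix)
    normalized = normalize_matrix(
        m_log2,
        method,
        span=span,
        multiplicity=multiplicity,
        invariant_proportion=invariant_proportion,
    )
    scores = gene_scores(normalized, sim.treatment_ids, sim.control_ids)
    return roc_curve(scores, sim.truth, criterion=criterion).auc


def run_benchmark(
    scenarios,
    methods,
    seeds,
    **kwargs,
) -> pd.DataFrame:
    """Grid runner: (scenario, method, seed) → AUC/slope rows.

    Scenarios: "golden_spike" (asymmetric two-condition design),
    "spikein_symmetric", "spikein_asymmetric".  Failures are recorded per
    cell (column ``error``) and the run continues.
    """
    rows = []
    for scenario in scenarios:
        for seed in seeds:
            panel: dict[str, dict] = {}
            if scenario == "golden_spike":
                try:
                    panel = golden_spike_panel(seed, methods=methods, **kwargs)
                except Exception as err:  # noqa: BLE001 - per-cell reporting
                    for method in methods:
                        rows.append(
                            {"scenario": scenario, "method": method, "seed": seed,
                             "error": str(err)}
                        )
                    continue
                for method, res in panel.items():
                    rows.append(
                        {"scenario": scenario, "method": method, "seed": seed, **res}
                    )
            elif scenario in ("spikein_symmetric", "spikein_asymmetric"):
                for method in methods:
                    row = {"scenario": scenario, "method": method, "seed": seed}
                    try:
                        row["auc_fc"] = spikein_auc(
                            seed,
                            method,
                            asymmetric=scenario.endswith("asymmetric"),
                            **kwargs,
                        )
                    except Exception as err:  # noqa: BLE001
                        row["error"] = str(err)
                    rows.append(row)
            else:
                raise ValueError(f"unknown scenario {scenario!r}")
    return pd.DataFrame(rows)


def aggregate_benchmark(report: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD over seeds for every (scenario, method) cell."""
    numeric = [c for c in report.columns if c not in ("scenario", "method", "seed", "error")]
    grouped = report.groupby(["scenario", "method"], sort=False)[numeric]
    agg = grouped.agg(["mean", "std"])
    agg.columns = [f"{stat}_{what}" for stat, what in agg.columns]
    return agg.reset_index()
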