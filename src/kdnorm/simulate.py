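"""Synthetic spike-in data generators with full design truth.

Two designs are provided.

``GoldenSpikeDesign`` emulates the structure of the classic two-condition
spike-in experiment with one-sided differential expression: two conditions
(C = constant, S = spike) with 3 replicates each, 2535 probe sets at equal
concentration in both conditions, 1331 probe sets *up-regulated only* in S,
and 10144 "empty" probe sets targeting no transcript, which form a second,
low-intensity null population.  Baseline log2 intensities, fold-change
palette and noise level are configurable; defaults are chosen so that MA
plots span a realistic dynamic range.

``SpikeSimDesign`` implements effect-spiking on a null pool: a matrix of
pure-noise genes over ``n_controls`` arrays is split 4 vs 4 into simulated
control/treatment groups, a fraction of genes is declared significant, and
each receives a shift of S_i·d_i on the log2 scale of its treatment arrays,
where S_i is the gene's observed control-group standard deviation and d_i an
effect size drawn from a zero-centred distribution (its absolute value in
the asymmetric variant, making every effect an up-regulation).  The shift is
then taken as an exponent of 2 to return to the raw scale.

All randomness flows from the single ``seed`` field of the design; equal
seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import RAW, ExpressionMatrix
from .evaluate import TRUTH_COLUMNS, make_truth, validate_truth


@dataclass
class GoldenSpikeDesign:
    """Asymmetric two-condition spike-in design.

    The default counts reproduce the classic design: 2535 equal-concentration
    probe sets, 1331 up-only probe sets, 10144 empty probe sets, three
    replicate arrays per condition.
    """

    n_null: int = 2535
    n_up: int = 1331
    n_empty: int = 10144
    replicates: int = 3
    fold_change_palette: Sequence[float] = (1.2, 1.5, 2.0, 3.0, 4.0)
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.25
    array_effect_sd: float = 0.1
    empty_level: float = 4.0
    empty_noise_sd: float = 0.1
    intensity_weighted_fc: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.n_null, self.n_up, self.n_empty) < 0:
            raise ValueError("gene counts must be non-negative")
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates per condition")
        if any(fc <= 1 for fc in self.fold_change_palette):
            raise ValueError("all fold changes in the palette must be > 1")


@dataclass
class SpikeSimDesign:
    """Effect-spiking simulation on a null pool, 4 vs 4 split."""

    n_genes: int = 2000
    n_controls: int = 8
    prop_significant: float = 0.10
    effect_df: float = 12.0
    effect_scale: float = 3.0
    asymmetric: bool = False
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.25
    array_effect_sd: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_controls < 4 or self.n_controls % 2:
            raise ValueError("n_controls must be even and >= 4")
        if not (0 <= self.prop_significant < 1):
            raise ValueError("prop_significant must be in [0, 1)")


def simulate_golden_spike(
    design: GoldenSpikeDesign,
) -> tuple[ExpressionMatrix, pd.DataFrame, dict]:
    """Simulate a raw-scale matrix plus truth for the asymmetric design.

    Returns (matrix, truth, groups) where groups maps "C"/"S" to array ids.
    Null and up genes draw a log2 baseline from
    Normal(baseline_mean, baseline_sd); up genes add log2(fc) on the S
    arrays with fc drawn from the palette.  With ``intensity_weighted_fc``
    higher-baseline genes are biased toward larger fold changes, emulating
    the confounding between concentration and fold change seen in the real
    experiment.  Empty probe sets sit at a common low level with small
    noise.  Per-array log2 offsets (array_effect_sd) emulate technical
    array-to-array variation.
    """
    rng = np.random.default_rng(design.seed)
    r = design.replicates
    n_arrays = 2 * r
    c_ids = [f"C{i + 1}" for i in range(r)]
    s_ids = [f"S{i + 1}" for i in range(r)]
    array_ids = c_ids + s_ids

    n_spiked = design.n_null + design.n_up
    n_total = n_spiked + design.n_empty
    gene_ids = (
        [f"null_{i + 1:05d}" for i in range(design.n_null)]
        + [f"up_{i + 1:05d}" for i in range(design.n_up)]
        + [f"empty_{i + 1:05d}" for i in range(design.n_empty)]
    )

    baseline = rng.normal(design.baseline_mean, design.baseline_sd, size=n_spiked)
    palette = np.asarray(design.fold_change_palette, dtype=float)
    log2_fc = np.zeros(n_total)
    if design.n_up:
        up_base = baseline[design.n_null :]
        if design.intensity_weighted_fc and design.n_up > 1:
            # confounded assignment: baseline quantile steers the palette
            # index, with Gaussian jitter so the coupling is soft
            q = stats_rankdata(up_base) / design.n_up
            idx = np.clip(
                np.round(q * (len(palette) - 1) + rng.normal(0, 0.8, design.n_up)),
                0,
                len(palette) - 1,
            ).astype(int)
        else:
            idx = rng.integers(0, len(palette), size=design.n_up)
        log2_fc[design.n_null : n_spiked] = np.log2(palette[idx])

    array_shift = rng.normal(0.0, design.array_effect_sd, size=n_arrays)
    log2_values = np.empty((n_total, n_arrays))
    noise = rng.normal(0.0, design.noise_sd, size=(n_spiked, n_arrays))
    log2_values[:n_spiked, :] = baseline[:, None] + noise + array_shift[None, :]
    # S arrays carry the designed up-shift
    log2_values[:n_spiked, r:] += log2_fc[:n_spiked, None]
    if design.n_empty:
        log2_values[n_spiked:, :] = (
            design.empty_level
            + rng.normal(0.0, design.empty_noise_sd, size=(design.n_empty, n_arrays))
            + array_shift[None, :]
        )

    matrix = ExpressionMatrix(
        values=np.exp2(log2_values),
        probe_ids=gene_ids,
        array_ids=array_ids,
        scale=RAW,
    )
    truth = make_truth(
        gene_ids=gene_ids,
        designed_log2_fc=log2_fc,
        is_de=log2_fc != 0,
        is_empty=[False] * n_spiked + [True] * design.n_empty,
    )
    return matrix, truth, {"C": c_ids, "S": s_ids}


def stats_rankdata(v: np.ndarray) -> np.ndarray:
    """1-based ranks with stable tie order (no averaging; ties are rare here)."""
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v), dtype=float)
    ranks[order] = np.arange(1, len(v) + 1)
    return ranks


@dataclass
class SpikeSimResult:
    """Matrix plus everything needed to audit the effect-spiking construction."""

    matrix: ExpressionMatrix
    null_pool: ExpressionMatrix
    truth: pd.DataFrame
    control_ids: list
    treatment_ids: list


def simulate_spikein(design: SpikeSimDesign) -> SpikeSimResult:
    """Effect-spiking on a simulated null pool.

    Steps: (1) build a null pool of ``n_genes`` × ``n_controls`` raw
    intensities (log2 baseline + array offset + iid noise); (2) randomly
    split the arrays 4-vs-4 (half and half) into simulated control and
    treatment groups; (3) draw round(prop_significant · n_genes) significant
    genes; (4) draw as many effect sizes d_i from a scaled Student-t
    distribution, ``effect_scale`` · t(``effect_df``) — the scale emulates
    the overdispersion of t-statistics pooled from a genuinely affected
    case/control comparison (|d_i| when asymmetric); (5) for
    each significant gene add S_i·d_i — S_i the sample SD of its log2 values
    over the simulated controls — to the log2 values of its treatment
    arrays, then exponentiate base 2.

    Non-significant genes are bit-identical between the null pool and the
    output.
    """
    rng = np.random.default_rng(design.seed)
    n, k = design.n_genes, design.n_controls
    gene_ids = [f"g{i + 1:05d}" for i in range(n)]
    array_ids = [f"a{j + 1}" for j in range(k)]

    baseline = rng.normal(design.baseline_mean, design.baseline_sd, size=n)
    array_shift = rng.normal(0.0, design.array_effect_sd, size=k)
    log2_null = (
        baseline[:, None]
        + array_shift[None, :]
        + rng.normal(0.0, design.noise_sd, size=(n, k))
    )
    null_pool = ExpressionMatrix(
        values=np.exp2(log2_null), probe_ids=gene_ids, array_ids=array_ids, scale=RAW
    )

    perm = rng.permutation(k)
    control_idx = np.sort(perm[: k // 2])
    treatment_idx = np.sort(perm[k // 2 :])

    n_sig = round(design.prop_significant * n)
    sig_idx = np.sort(rng.choice(n, size=n_sig, replace=False))
    d = design.effect_scale * rng.standard_t(design.effect_df, size=n_sig)
    if design.asymmetric:
        d = np.abs(d)

    applied = np.zeros(n)
    log2_out = log2_null.copy()
    if n_sig:
        s_i = log2_null[np.ix_(sig_idx, control_idx)].std(axis=1, ddof=1)
        applied[sig_idx] = s_i * d
        log2_out[np.ix_(sig_idx, treatment_idx)] += applied[sig_idx][:, None]

    matrix = ExpressionMatrix(
        values=np.where(applied[:, None] != 0, np.exp2(log2_out), null_pool.values),
        probe_ids=gene_ids,
        array_ids=array_ids,
        scale=RAW,
    )
    truth = make_truth(
        gene_ids=gene_ids,
        designed_log2_fc=applied,
        is_de=applied != 0,
        is_empty=[False] * n,
    )
    return SpikeSimResult(
        matrix=matrix,
        null_pool=null_pool,
        truth=truth,
        control_ids=[array_ids[j] for j in control_idx],
        treatment_ids=[array_ids[j] for j in treatment_idx],
    )


def write_truth(truth: pd.DataFrame, path) -> None:
    """Write a truth table as TSV; the round trip through read_truth is lossless."""
    validate_truth(truth)
    truth[TRUTH_COLUMNS].to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t")
    if truth.empty and list(truth.columns) == TRUTH_COLUMNS:
        truth = truth.astype(
            {"gene_id": object, "designed_log2_fc": float, "is_de": bool, "is_empty": bool}
        )
    validate_truth(truth)
    return truth
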