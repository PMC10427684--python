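"""Selection-screen scoring with confidence lower bounds.

A barcode's enrichment is the ratio of its read frequency after affinity
selection to its input frequency. Because counts of rare barcodes are
noisy, ranking uses the lower bound (lb) of an exact two-sided confidence
interval for the underlying rate ratio rather than the point estimate:
high point ratios backed by few reads are pulled down, making the score
conservative.

The interval is the conditional-binomial (exact) construction for a ratio
of Poisson rates: conditional on the total k_sel + k_in, the selection
count is binomial with success probability p = rho*N_sel/(rho*N_sel +
N_in) where rho is the rate ratio; a Clopper-Pearson bound on p is
back-transformed to the ratio scale. Signal is aggregated over cycle-1 by
pooling counts per (cy2, cy3) disynthon, and per-building-block rollups
sum the lb values of all disynthons containing that building block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class EnrichmentRecord:
    barcode: tuple[str, str, str]
    k_sel: int
    n_sel: int
    k_in: int
    n_in: int
    ratio: float  # inf when k_in == 0 and k_sel > 0
    lb: float
    control_lb: float | None = None


def enrichment_ratio(k_sel: int, n_sel: int, k_in: int, n_in: int) -> float:
    """Frequency ratio (k_sel/N_sel) / (k_in/N_in).

    Returns inf when the barcode is unseen in the input but seen in the
    selection; callers should rely on the lower bound for ranking.
    """
    if min(k_sel, k_in) < 0:
        raise ValueError("counts must be non-negative")
    if n_sel <= 0 or n_in <= 0:
        raise ValueError("sample totals must be positive")
    if k_in == 0:
        return math.inf if k_sel > 0 else float("nan")
    return (k_sel / n_sel) / (k_in / n_in)


def _ratio_bound_from_p(p: float, n_sel: float, n_in: float) -> float:
    if p >= 1.0:
        return math.inf
    return (p / (1.0 - p)) * (n_in / n_sel)


def lower_bound_enrichment(
    k_sel: int, n_sel: int, k_in: int, n_in: int,
    conf: float = 0.95, method: str = "exact",
) -> float:
    """Lower limit of the two-sided conf-level interval for the rate ratio.

    ``method`` selects the interval for the conditional binomial
    proportion: "exact" (Clopper-Pearson, default), "jeffreys", or
    "normal" (Wald on the log-ratio with a continuity fallback).
    k_sel = 0 gives lb = 0 (zero information in the selection count).
    """
    if min(k_sel, k_in) < 0:
        raise ValueError("counts must be non-negative")
    if n_sel <= 0 or n_in <= 0:
        raise ValueError("sample totals must be positive")
    total = k_sel + k_in
    if k_sel == 0 or total == 0:
        return 0.0
    alpha = 1.0 - conf
    if method == "exact":
        p_lo = stats.beta.ppf(alpha / 2.0, k_sel, k_in + 1)
    elif method == "jeffreys":
        p_lo = stats.beta.ppf(alpha / 2.0, k_sel + 0.5, k_in + 0.5)
    elif method == "normal":
        if k_in == 0:
            k_in_eff = 0.5
        else:
            k_in_eff = k_in
        log_ratio = math.log((k_sel / n_sel) / (k_in_eff / n_in))
        se = math.sqrt(1.0 / k_sel + 1.0 / k_in_eff)
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return math.exp(log_ratio - z * se)
    else:
        raise ValueError(f"unknown method {method!r}")
    return _ratio_bound_from_p(float(p_lo), n_sel, n_in)


def lower_bound_enrichment_vec(
    k_sel: np.ndarray, n_sel: float, k_in: np.ndarray, n_in: float,
    conf: float = 0.95,
) -> np.ndarray:
    """Vectorized exact lower bound (Clopper-Pearson construction)."""
    k_sel = np.asarray(k_sel, dtype=float)
    k_in = np.asarray(k_in, dtype=float)
    alpha = 1.0 - conf
    p_lo = np.where(
        k_sel > 0, stats.beta.ppf(alpha / 2.0, np.maximum(k_sel, 1e-12), k_in + 1), 0.0
    )
    with np.errstate(divide="ignore"):
        lb = np.where(p_lo < 1.0, p_lo / (1.0 - p_lo) * (n_in / n_sel), np.inf)
    return np.where(k_sel > 0, lb, 0.0)


def score_barcodes(
    count_table: pd.DataFrame,
    sel_column: str,
    in_column: str = "input",
    conf: float = 0.95,
) -> pd.DataFrame:
    """Per-barcode ratio and lb; totals are per-sample decoded-read sums."""
    n_sel = int(count_table[sel_column].sum())
    n_in = int(count_table[in_column].sum())
    k_sel = count_table[sel_column].to_numpy()
    k_in = count_table[in_column].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (k_sel / n_sel) / (k_in / n_in)
    out = pd.DataFrame(
        {
            "k_sel": k_sel, "N_sel": n_sel, "k_in": k_in, "N_in": n_in,
            "ratio": ratio,
            "lb": lower_bound_enrichment_vec(k_sel, n_sel, k_in, n_in, conf=conf),
        },
        index=count_table.index,
    )
    return out


def score_replicates(
    count_table: pd.DataFrame,
    sel_columns: list[str],
    in_column: str = "input",
    conf: float = 0.95,
    mode: str = "min_lb",
) -> pd.DataFrame:
    """Replicate summary: minimum lb across replicates (conservative) or pooled counts."""
    if mode == "min_lb":
        lbs = [
            score_barcodes(count_table, c, in_column, conf)["lb"] for c in sel_columns
        ]
        out = score_barcodes(count_table, sel_columns[0], in_column, conf)
        out["lb"] = np.minimum.reduce([lb.to_numpy() for lb in lbs])
        return out
    if mode == "pooled":
        pooled = count_table[sel_columns].sum(axis=1).to_frame("pooled")
        pooled[in_column] = count_table[in_column]
        return score_barcodes(pooled, "pooled", in_column, conf)
    raise ValueError(f"unknown replicate mode {mode!r}")


@dataclass
class DisynthonAggregate:
    key: tuple[str, str]  # (cy2, cy3)
    k_sel: int
    k_in: int
    lb: float


def disynthon_scores(
    count_table: pd.DataFrame,
    sel_column: str,
    in_column: str = "input",
    conf: float = 0.95,
) -> pd.DataFrame:
    """Pool counts over cy1 per (cy2, cy3) disynthon and score the pools."""
    pooled = count_table.groupby(level=["cy2", "cy3"])[[sel_column, in_column]].sum()
    n_sel = int(count_table[sel_column].sum())
    n_in = int(count_table[in_column].sum())
    pooled = pooled.rename(columns={sel_column: "k_sel", in_column: "k_in"})
    pooled["lb"] = lower_bound_enrichment_vec(
        pooled["k_sel"].to_numpy(), n_sel, pooled["k_in"].to_numpy(), n_in, conf=conf
    )
    return pooled.sort_values("lb", ascending=False)


def building_block_rollup(
    disynthons: pd.DataFrame, level: str = "cy2", threshold: float = 0.0
) -> pd.Series:
    """Sum of disynthon lb values per building block, optionally thresholded.

    Mirrors summary plots that drop building blocks whose summed lower
    bound falls below a display threshold.
    """
    rollup = disynthons.groupby(level=level)["lb"].sum().sort_values(ascending=False)
    return rollup[rollup >= threshold]


def compare_to_control(
    records_target: pd.DataFrame,
    records_beads_only: pd.DataFrame,
    factor: float = 3.0,
) -> pd.Series:
    """Flag barcodes whose target lb exceeds the beads-only control lb.

    Matrix binders enrich in the control too and are not flagged. The two
    frames must share the same barcode index.
    """
    if not records_target.index.equals(records_beads_only.index):
        raise ValueError("target and control tables must share one barcode universe")
    control_lb = records_beads_only["lb"].to_numpy()
    target_lb = records_target["lb"].to_numpy()
    flags = target_lb > factor * np.maximum(control_lb, 1e-12)
    # a barcode never seen in selection carries no signal to flag
    flags &= records_target["k_sel"].to_numpy() > 0
    return pd.Series(flags, index=records_target.index, name="flagged")
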