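"""Negative-binomial modelling of input counts and pooling diagnostics.

Per-barcode sequencing counts of a well-behaved DEL input sample are
overdispersed relative to Poisson; each sub-library is modelled as a
negative binomial parameterized by (mean, size r) with

    variance = mean + mean**2 / r.

The ratio of the two sub-libraries' fitted means estimates the pooling
imbalance introduced when sub-libraries are merged, which can then be
corrected by rescaling the mixing weights. Zero-count barcodes are real
outcomes of finite sequencing depth and are included in fits by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


class DegenerateDataError(ValueError):
    pass


class LabellingError(ValueError):
    pass


@dataclass
class NBParams:
    """Fitted negative-binomial parameters (mean / size-r convention)."""

    mean: float
    dispersion: float  # size parameter r; variance = mean + mean^2/r
    loglik: float
    n: int
    poisson_limit: bool = False

    @property
    def variance(self) -> float:
        return self.mean + self.mean**2 / self.dispersion


_R_MAX = 1e6  # dispersion ceiling; beyond this the NB is operationally Poisson


def fit_negative_binomial(counts: np.ndarray | list[int]) -> NBParams:
    """Maximum-likelihood NB fit with the mean profiled out.

    The MLE of the mean is the sample mean for any fixed r, so only the
    dispersion requires numerical work: a bounded 1-D optimization over
    log r, initialized from the method-of-moments estimate. Samples whose
    variance does not exceed their mean carry no overdispersion signal and
    are flagged ``poisson_limit`` with r at the ceiling.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1 or x.size < 10:
        raise ValueError("need a 1-D sample of at least 10 observations")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("counts must be finite and non-negative")
    mean = float(x.mean())
    if mean == 0.0:
        raise DegenerateDataError("all-zero count vector")
    var = float(x.var(ddof=1))

    def negll_logr(logr: float) -> float:
        r = np.exp(logr)
        p = r / (r + mean)
        return -float(stats.nbinom.logpmf(x, r, p).sum())

    if var <= mean:
        r = _R_MAX
        return NBParams(
            mean=mean, dispersion=r, loglik=-negll_logr(np.log(r)), n=x.size,
            poisson_limit=True,
        )
    r_mom = mean**2 / (var - mean)
    res = optimize.minimize_scalar(
        negll_logr,
        bracket=(np.log(r_mom) - 1.0, np.log(r_mom), np.log(r_mom) + 1.0)
        if r_mom > 0 else None,
        bounds=(np.log(1e-4), np.log(_R_MAX)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    r = float(np.exp(res.x))
    return NBParams(
        mean=mean, dispersion=r, loglik=-float(res.fun), n=x.size,
        poisson_limit=r >= _R_MAX * 0.99,
    )


def estimate_pooling_ratio(
    count_table: pd.DataFrame,
    sublibrary_labels: pd.Series | np.ndarray | list[str],
    column: str = "input",
    truncate_zeros: bool = False,
) -> tuple[float, dict[str, NBParams]]:
    """I/Br pooling ratio from per-sub-library negative-binomial fits.

    The ratio is fitted_mean(I) / fitted_mean(Br) — a property of the
    fitted distributions, not of median counts. Zero counts are kept
    unless ``truncate_zeros`` is set.
    """
    labels = np.asarray(sublibrary_labels)
    fits: dict[str, NBParams] = {}
    for sub in ("Br", "I"):
        mask = labels == sub
        if not mask.any():
            raise LabellingError(f"sub-library {sub!r} absent from labels")
        x = count_table.loc[mask, column].to_numpy(dtype=float)
        if truncate_zeros:
            x = x[x > 0]
        fits[sub] = fit_negative_binomial(x)
    return fits["I"].mean / fits["Br"].mean, fits


def correct_pooling(
    weights: dict[str, float], ratio: float
) -> dict[str, float]:
    """Rescale sub-library mixing weights to equalize representation.

    The I-side weight is divided by the measured I/Br excess and the
    weights renormalized to sum to one.
    """
    if ratio <= 0:
        raise ValueError("pooling ratio must be positive")
    adjusted = dict(weights)
    adjusted["I"] = adjusted["I"] / ratio
    total = sum(adjusted.values())
    return {k: v / total for k, v in adjusted.items()}


def count_histogram(
    count_table: pd.DataFrame,
    column: str = "input",
    by_sublibrary: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """Exact (count value -> number of barcodes) histogram.

    With the table joined to a design, the zero bin reports unobserved
    barcodes. Optionally split by sub-library label.
    """
    if by_sublibrary is None:
        vc = count_table[column].value_counts().sort_index()
        return vc.rename_axis("count").to_frame("n_barcodes")
    labels = np.asarray(by_sublibrary)
    frames = {}
    for sub in np.unique(labels):
        vc = count_table.loc[labels == sub, column].value_counts().sort_index()
        frames[sub] = vc
    out = pd.DataFrame(frames).fillna(0).astype(int)
    out.index.name = "count"
    return out


@dataclass
class UnobservedReport:
    """Zero-count diagnostics over a full design."""

    fraction_unobserved: float
    n_unobserved: int
    zero_barcodes: pd.DataFrame  # index (cy1, cy2, cy3) + sublibrary column
    by_cycle: dict[str, pd.DataFrame]  # per-tag zero counts, split by sub-library
    by_cycle_pair: pd.DataFrame  # (cy2, cy3) zero counts
    flagged: pd.DataFrame  # tags / pairs whose zero rate exceeds the threshold


def unobserved_analysis(
    count_table: pd.DataFrame,
    sublibrary_labels: pd.Series | np.ndarray,
    column: str = "input",
    enrichment_threshold: float = 10.0,
) -> UnobservedReport:
    """Attribute unobserved (zero-count) barcodes to cycle tags and tag pairs.

    The count table must be joined to the full design so that missing
    barcodes appear as zeros. A tag (or (cy2, cy3) pair) is flagged when
    its zero rate exceeds ``enrichment_threshold`` times the global zero
    rate, per sub-library — the signature of e.g. a failed tag ligation in
    one pool. Complete dropouts (zero rate 1) are always flagged.
    """
    labels = np.asarray(sublibrary_labels)
    counts = count_table[column].to_numpy()
    zero_mask = counts == 0
    n_total = len(count_table)
    n_zero = int(zero_mask.sum())
    fraction = n_zero / n_total if n_total else 0.0
    global_rate = fraction

    idx = count_table.index.to_frame(index=False)
    idx["sublibrary"] = labels
    idx["zero"] = zero_mask

    by_cycle: dict[str, pd.DataFrame] = {}
    flags = []
    for cyc in ("cy1", "cy2", "cy3"):
        grp = idx.groupby([cyc, "sublibrary"])["zero"].agg(["sum", "size", "mean"])
        grp.columns = ["n_zero", "n_total", "zero_rate"]
        by_cycle[cyc] = grp
        if global_rate > 0:
            hot = grp[
                (grp["zero_rate"] > enrichment_threshold * global_rate)
                | (grp["zero_rate"] >= 1.0)
            ]
            for (tag, sub), row in hot.iterrows():
                flags.append(
                    {"level": cyc, "key": tag, "sublibrary": sub,
                     "zero_rate": row["zero_rate"], "n_zero": int(row["n_zero"])}
                )

    pair = idx.groupby(["cy2", "cy3"])["zero"].agg(["sum", "size", "mean"])
    pair.columns = ["n_zero", "n_total", "zero_rate"]
    if global_rate > 0:
        hot = pair[
            (pair["zero_rate"] > enrichment_threshold * global_rate)
            | (pair["zero_rate"] >= 1.0)
        ]
        for (cy2, cy3), row in hot.iterrows():
            flags.append(
                {"level": "cy2_cy3", "key": (cy2, cy3), "sublibrary": "both",
                 "zero_rate": row["zero_rate"], "n_zero": int(row["n_zero"])}
            )

    zero_df = idx[idx["zero"]].drop(columns="zero").reset_index(drop=True)
    flagged = pd.DataFrame(
        flags, columns=["level", "key", "sublibrary", "zero_rate", "n_zero"]
    )
    return UnobservedReport(
        fraction_unobserved=fraction,
        n_unobserved=n_zero,
        zero_barcodes=zero_df,
        by_cycle=by_cycle,
        by_cycle_pair=pair,
        flagged=flagged,
    )
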